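import numpy as np
import pytest
from hypothesis import settings

from mosaicko.outcome_core import EditingOutcome, OutcomeDistribution, OutcomeKind

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_dist(spec, guide_id="g1", source="predicted", method="test", **meta):
    """Build an OutcomeDistribution from compact (kind, length, freq) tuples.

    ``spec`` entries: ("wt", freq), ("ins", bases, freq),
    ("del", length, start, freq).
    """
    entries = []
    for item in spec:
        if item[0] == "wt":
            entries.append((EditingOutcome(OutcomeKind.WILDTYPE), item[1]))
        elif item[0] == "ins":
            _, bases, freq = item
            entries.append(
                (EditingOutcome(OutcomeKind.INSERTION, length=len(bases), ins_bases=bases), freq)
            )
        elif item[0] == "del":
            _, length, start, freq = item
            entries.append(
                (EditingOutcome(OutcomeKind.DELETION, length=length, del_start=start), freq)
            )
        else:
            raise ValueError(item)
    return OutcomeDistribution(
        guide_id=guide_id, source=source, method=method, entries=entries, metadata=meta
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_context(rng, length=80):
    return "".join(rng.choice(list("ACGT"), size=length))
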
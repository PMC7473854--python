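"""Unit and property tests for outcome containers and spectrum rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mosaicko.outcome_core import (
    EditingOutcome,
    OutcomeDistribution,
    OutcomeKind,
    cumulative_frameshift,
    curate_to_reference_classes,
    is_frameshift,
    ko_score,
    ko_score_percent,
    match_outcomes,
    normalize_observed,
    read_outcome_table,
    write_outcome_table,
)

from .conftest import make_dist


class TestEditingOutcome:
    def test_invalid_lengths_rejected(self):
        with pytest.raises(ValueError):
            EditingOutcome(OutcomeKind.DELETION, length=0, del_start=-1)
        with pytest.raises(ValueError):
            EditingOutcome(OutcomeKind.WILDTYPE, length=2)
        with pytest.raises(ValueError):
            EditingOutcome(OutcomeKind.INSERTION, length=2, ins_bases="A")
        with pytest.raises(ValueError):
            EditingOutcome(OutcomeKind.DELETION, length=3)  # no del_start

    def test_genotype_keys_distinguish_products(self):
        d1 = EditingOutcome(OutcomeKind.DELETION, length=3, del_start=-1)
        d2 = EditingOutcome(OutcomeKind.DELETION, length=3, del_start=-2)
        d3 = EditingOutcome(OutcomeKind.DELETION, length=4, del_start=-1)
        ins = EditingOutcome(OutcomeKind.INSERTION, length=1, ins_bases="A")
        keys = {o.genotype_key for o in (d1, d2, d3, ins)}
        assert len(keys) == 4

    def test_duplicate_keys_rejected_in_distribution(self):
        o = EditingOutcome(OutcomeKind.INSERTION, length=1, ins_bases="A")
        with pytest.raises(ValueError, match="duplicate"):
            OutcomeDistribution("g", "predicted", entries=[(o, 0.5), (o, 0.5)])


class TestFrameshift:
    # brute-force mod table: a length is frameshifting iff length % 3 != 0
    @pytest.mark.parametrize("length", range(1, 31))
    @pytest.mark.parametrize("kind", [OutcomeKind.DELETION, OutcomeKind.INSERTION])
    def test_matches_mod_table(self, kind, length):
        if kind is OutcomeKind.DELETION:
            o = EditingOutcome(kind, length=length, del_start=-1)
        else:
            o = EditingOutcome(kind, length=length, ins_bases="A" * length)
        assert is_frameshift(o) == (length % 3 != 0)

    def test_wildtype_never_frameshift(self):
        assert not is_frameshift(EditingOutcome(OutcomeKind.WILDTYPE))

    def test_cumulative_frameshift_equals_loop_oracle(self, rng):
        freqs = rng.dirichlet(np.ones(10))
        spec = []
        for i, f in enumerate(freqs):
            spec.append(("del", i + 1, -1, float(f)))
        dist = make_dist(spec)
        oracle = sum(f for (_, L, _, f) in spec if L % 3 != 0)
        assert cumulative_frameshift(dist) == pytest.approx(oracle, abs=1e-12)
        # complement identity: frameshift mass = 1 - in-frame mass
        inframe = sum(f for (_, L, _, f) in spec if L % 3 == 0)
        assert cumulative_frameshift(dist) == pytest.approx(1 - inframe, abs=1e-9)

    def test_half_mass_frameshift(self):
        dist = make_dist([("ins", "A", 0.5), ("del", 3, -1, 0.5)])
        assert cumulative_frameshift(dist) == pytest.approx(0.5)

    def test_requires_normalized_mutant_only_input(self):
        with pytest.raises(ValueError, match="deviates"):
            cumulative_frameshift(make_dist([("ins", "A", 0.5)]))
        with pytest.raises(ValueError, match="wild-type"):
            cumulative_frameshift(make_dist([("wt", 0.5), ("ins", "A", 0.5)]))


class TestKoScore:
    def test_worked_example(self):
        # an 80% frameshift spectrum gives 64% biallelic-frameshift cells
        assert ko_score(0.80) == pytest.approx(0.64)
        assert ko_score_percent(0.80) == pytest.approx(64.0)

    @pytest.mark.parametrize("f,expected", [(0.0, 0.0), (1.0, 1.0), (0.5, 0.25)])
    def test_endpoints_and_square(self, f, expected):
        assert ko_score(f) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        for bad in (-0.1, 1.1):
            with pytest.raises(ValueError):
                ko_score(bad)

    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_and_bounded(self, a, b):
        lo, hi = sorted((a, b))
        assert ko_score(lo) <= ko_score(hi)
        assert ko_score(hi) <= hi


class TestNormalizeObserved:
    def test_filters_and_renormalizes(self):
        raw = make_dist([("wt", 0.8), ("ins", "A", 0.1), ("del", 2, -1, 0.1)])
        out = normalize_observed(raw)
        d = out.as_dict()
        assert len(d) == 2
        assert all(v == pytest.approx(0.5) for v in d.values())
        assert out.total() == pytest.approx(1.0, abs=1e-9)

    def test_long_insertions_dropped(self):
        raw = make_dist([("ins", "AT", 0.5), ("del", 1, 0, 0.5)])
        out = normalize_observed(raw)
        assert list(out.as_dict().values()) == [pytest.approx(1.0)]

    def test_already_clean_is_identity(self):
        raw = make_dist([("ins", "A", 1.0)])
        assert normalize_observed(raw).as_dict() == raw.as_dict()

    def test_no_signal_errors(self):
        with pytest.raises(ValueError, match="no editable signal"):
            normalize_observed(make_dist([("wt", 1.0)]))


def brute_force_curation_limit(reference):
    """Independent cumulative scan: +1 insertion mass, then deletions by
    increasing length, returning the first length crossing 0.99."""
    plus1 = sum(
        f for o, f in reference.entries
        if o.kind is OutcomeKind.INSERTION and o.length == 1
    )
    lengths = sorted({o.length for o, _ in reference.entries if o.kind is OutcomeKind.DELETION})
    cum = plus1
    for L in lengths:
        cum += sum(
            f for o, f in reference.entries
            if o.kind is OutcomeKind.DELETION and o.length == L
        )
        if cum > 0.99:
            return L
    return None


class TestCuration:
    def test_large_deletion_dropped_at_limit(self):
        # deletions <= 9 plus +1 insertions carry > 0.99 cumulative mass
        ref = make_dist(
            [("ins", "A", 0.3)]
            + [("del", L, -1, 0.077) for L in range(1, 10)]
            + [("del", 12, -1, 0.007)]
        )
        dist = make_dist([("del", 9, -1, 0.5), ("del", 12, -1, 0.5)])
        out = curate_to_reference_classes(dist, ref)
        assert out.metadata["curation_max_deletion"] == 9
        assert set(out.as_dict()) == {"del:9@-1"}
        assert out.total() == pytest.approx(1.0, abs=1e-9)

    def test_self_curation_renormalizes(self):
        ref = make_dist([("ins", "A", 0.6), ("del", 2, -1, 0.4)])
        out = curate_to_reference_classes(ref, ref)
        assert out.as_dict() == pytest.approx(ref.as_dict())

    def test_plus1_only_distribution_unchanged(self):
        ref = make_dist([("ins", "A", 0.7), ("del", 1, 0, 0.3)])
        dist = make_dist([("ins", "A", 0.4), ("ins", "T", 0.6)])
        out = curate_to_reference_classes(dist, ref)
        assert out.as_dict() == pytest.approx(dist.as_dict())

    def test_underfull_reference_errors(self):
        ref = make_dist([("ins", "AT", 0.5), ("del", 1, 0, 0.4)])  # only 0.4 countable
        with pytest.raises(ValueError, match="99%"):
            curate_to_reference_classes(ref, ref)

    def test_limit_matches_brute_force_on_random_references(self, rng):
        for _ in range(100):
            n_del = int(rng.integers(3, 15))
            lengths = rng.choice(np.arange(1, 30), size=n_del, replace=False)
            freqs = rng.dirichlet(np.ones(n_del + 1))
            spec = [("ins", "A", float(freqs[0]))]
            spec += [
                ("del", int(L), -1, float(f)) for L, f in zip(lengths, freqs[1:])
            ]
            ref = make_dist(spec)
            expected = brute_force_curation_limit(ref)
            out = curate_to_reference_classes(ref, ref)
            assert out.metadata["curation_max_deletion"] == expected
            # curation never increases the number of distinct outcomes
            assert len(out) <= len(ref)
            assert out.total() == pytest.approx(1.0, abs=1e-9)


class TestMatchOutcomes:
    def test_identical_distributions_give_identical_vectors(self):
        d = make_dist([("ins", "A", 0.5), ("del", 2, -1, 0.5)])
        keys, p, o = match_outcomes(d, d)
        assert keys == sorted(keys)
        np.testing.assert_allclose(p, o)

    def test_disjoint_supports_union_and_zero_fill(self):
        a = make_dist([("ins", "A", 0.6), ("ins", "T", 0.4)])
        b = make_dist([("del", 1, 0, 0.2), ("del", 2, -1, 0.3), ("del", 4, -2, 0.5)])
        keys, pvec, ovec = match_outcomes(a, b)
        assert len(keys) == 5
        assert pvec.sum() == pytest.approx(1.0)
        assert ovec.sum() == pytest.approx(1.0)
        assert np.all((pvec == 0) | (ovec == 0))

    def test_random_pair_matches_dictionary_merge(self, rng):
        for _ in range(20):
            def rand_dist():
                n = int(rng.integers(2, 8))
                lengths = rng.choice(np.arange(1, 20), size=n, replace=False)
                freqs = rng.dirichlet(np.ones(n))
                return make_dist(
                    [("del", int(L), -1, float(f)) for L, f in zip(lengths, freqs)]
                )

            a, b = rand_dist(), rand_dist()
            keys, pvec, ovec = match_outcomes(a, b)
            ad, bd = a.as_dict(), b.as_dict()
            merged = sorted(set(ad) | set(bd))
            assert keys == merged
            np.testing.assert_allclose(pvec, [ad.get(k, 0.0) for k in merged])
            np.testing.assert_allclose(ovec, [bd.get(k, 0.0) for k in merged])

    def test_guide_mismatch_rejected(self):
        a = make_dist([("ins", "A", 1.0)], guide_id="g1")
        b = make_dist([("ins", "A", 1.0)], guide_id="g2")
        with pytest.raises(ValueError, match="different guides"):
            match_outcomes(a, b)


class TestOutcomeTableIO:
    def test_round_trip_bit_exact(self, tmp_path, rng):
        freqs = rng.dirichlet(np.ones(6))
        dist = make_dist(
            [
                ("ins", "A", float(freqs[0])),
                ("ins", "TG", float(freqs[1])),
                ("wt", float(freqs[2])),
            ]
            + [("del", L, -L // 2, float(f)) for L, f in zip((1, 5, 9), freqs[3:])],
            guide_id="gX",
            source="observed",
            method="assay",
        )
        path = tmp_path / "outcomes.csv"
        write_outcome_table(dist, path)
        (back,) = read_outcome_table(path)
        assert back.guide_id == "gX" and back.source == "observed"
        assert back.as_dict() == dist.as_dict()  # exact, not approx

    def test_multiple_guides_per_file(self, tmp_path):
        a = make_dist([("ins", "A", 1.0)], guide_id="g1")
        b = make_dist([("del", 2, -1, 1.0)], guide_id="g2")
        path = tmp_path / "two.csv"
        write_outcome_table([a, b], path)
        back = read_outcome_table(path)
        assert {d.guide_id for d in back} == {"g1", "g2"}


@settings(deadline=None, max_examples=50)
@given(
    freqs=st.lists(st.floats(0.01, 1.0), min_size=2, max_size=10),
)
def test_normalization_conserves_unit_mass(freqs):
    """Any normalize/curate output sums to 1 within 1e-9."""
    spec = [("del", i + 1, -1, f) for i, f in enumerate(freqs)]
    raw = make_dist([("wt", 0.5)] + spec)
    out = normalize_observed(raw)
    assert out.total() == pytest.approx(1.0, abs=1e-9)
    curated = curate_to_reference_classes(out, out)
    assert curated.total() == pytest.approx(1.0, abs=1e-9)
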
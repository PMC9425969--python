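import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import composite_meta, make_table
from sipmet.errors import (
    ConsistencyError,
    IncompleteDesignError,
    InsufficientDataError,
    ParameterError,
    SelectionError,
    UndefinedEFError,
)
from sipmet.sip import (
    EnrichmentInput,
    FractionRecord,
    FractionWindows,
    classify_enriched,
    combine_fraction_counts,
    delta13C,
    ef_table,
    enrichment_factor,
    find_enrichment_peak,
    select_fractions,
)


class TestDelta13C:
    def test_reference_gives_zero(self):
        assert delta13C(0.0111802, 0.0111802) == pytest.approx(0.0)

    def test_double_reference(self):
        assert delta13C(2 * 0.0111802, 0.0111802) == pytest.approx(1000.0)

    def test_direct_formula(self):
        assert delta13C(0.011, 0.0111802) == pytest.approx(-16.1178, abs=1e-3)

    def test_nonpositive_rejected(self):
        with pytest.raises(ParameterError):
            delta13C(0.0)
        with pytest.raises(ParameterError):
            delta13C(-0.01)

    @given(st.floats(1e-6, 1.0), st.floats(1e-6, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_strictly_increasing_in_ratio(self, r1, r2):
        if r1 == r2:
            assert delta13C(r1) == delta13C(r2)
        else:
            lo, hi = sorted([r1, r2])
            assert delta13C(lo) < delta13C(hi)


def profile(densities, deltas=None, dna=None):
    deltas = deltas if deltas is not None else [None] * len(densities)
    dna = dna if dna is not None else [1.0] * len(densities)
    return [FractionRecord(i, d, a, dl)
            for i, (d, a, dl) in enumerate(zip(densities, dna, deltas))]


class TestSelectFractions:
    def test_default_windows(self):
        prof = profile([1.66, 1.67, 1.68, 1.69, 1.70, 1.71, 1.72, 1.73])
        light, heavy = select_fractions(prof)
        assert [f.density for f in light] == [1.68, 1.69]
        assert [f.density for f in heavy] == [1.71, 1.72]

    def test_closed_bounds(self):
        prof = profile([1.66, 1.68, 1.69, 1.71, 1.72])
        light, heavy = select_fractions(prof)
        assert len(light) == 2 and len(heavy) == 2

    def test_empty_window_errors(self):
        with pytest.raises(SelectionError, match="light"):
            select_fractions(profile([1.66, 1.67, 1.71, 1.72]))
        with pytest.raises(SelectionError, match="heavy"):
            select_fractions(profile([1.66, 1.68, 1.69]))

    def test_order_invariance(self, rng):
        dens = [1.66, 1.67, 1.68, 1.69, 1.70, 1.71, 1.72, 1.73]
        prof = profile(dens)
        shuffled = list(prof)
        rng.shuffle(shuffled)
        l1, h1 = select_fractions(prof)
        l2, h2 = select_fractions(shuffled)
        assert [f.density for f in l1] == [f.density for f in l2]
        assert [f.density for f in h1] == [f.density for f in h2]

    def test_rounding_absorbs_refractometer_noise(self):
        prof = profile([1.6799999, 1.69, 1.7100001, 1.72])
        light, heavy = select_fractions(prof)
        assert len(light) == 2 and len(heavy) == 2

    def test_invalid_windows(self):
        with pytest.raises(ParameterError):
            FractionWindows(light=(1.70, 1.72), heavy=(1.71, 1.73))


class TestFindEnrichmentPeak:
    def test_interior_peak_despite_rising_tail(self):
        prof = profile([1.66, 1.69, 1.71, 1.72, 1.73],
                       deltas=[-38.0, -37.0, -36.5, -37.2, -35.6])
        assert find_enrichment_peak(prof) == (1.71, -36.5)

    def test_monotone_profile_no_peak(self):
        prof = profile([1.66, 1.68, 1.70, 1.72],
                       deltas=[-38.0, -37.5, -37.0, -36.0])
        assert find_enrichment_peak(prof) is None

    def test_tie_break_by_dna_amount(self):
        prof = profile([1.66, 1.68, 1.70, 1.71, 1.72],
                       deltas=[-38.0, -36.0, -38.0, -36.0, -38.0],
                       dna=[1.0, 2.0, 1.0, 5.0, 1.0])
        assert find_enrichment_peak(prof) == (1.71, -36.0)

    def test_insufficient_measured(self):
        prof = profile([1.66, 1.68, 1.70], deltas=[-38.0, -37.0, None])
        with pytest.raises(InsufficientDataError):
            find_enrichment_peak(prof)

    def test_unmeasured_fractions_skipped(self):
        prof = profile([1.66, 1.67, 1.69, 1.71, 1.73],
                       deltas=[-38.0, None, -36.0, None, -37.0])
        assert find_enrichment_peak(prof) == (1.69, -36.0)


class TestCombineFractionCounts:
    def base(self):
        counts = {"f5": [3, 7], "f6": [5, 5], "f9": [2, 0]}
        meta = {s: composite_meta(fraction_class="heavy") for s in counts}
        return make_table(counts, meta)

    def test_additivity(self):
        out = combine_fraction_counts(self.base(), {"heavy": ["f5", "f6"]})
        assert list(out.counts["heavy"]) == [8, 12]

    def test_identity_single(self):
        out = combine_fraction_counts(self.base(), {"heavy": ["f9"]})
        assert list(out.counts["heavy"]) == [2, 0]

    def test_missing_column(self):
        with pytest.raises(ConsistencyError):
            combine_fraction_counts(self.base(), {"heavy": ["f5", "nope"]})


class TestEnrichmentFactor:
    def test_hand_evaluation(self):
        x = EnrichmentInput("o", 0.40, 0.20, 0.10, 0.10)
        assert enrichment_factor(x) == pytest.approx(1.0)

    def test_null_case(self):
        x = EnrichmentInput("o", 0.25, 0.25, 0.25, 0.25)
        assert enrichment_factor(x) == pytest.approx(0.0)

    def test_threshold_edge(self):
        x = EnrichmentInput("o", 0.30, 0.30, 0.20, 0.40)
        ef = enrichment_factor(x)
        assert ef == pytest.approx(0.5)
        assert not classify_enriched(ef, 0.3)

    def test_zero_denominator_flagged(self):
        with pytest.raises(UndefinedEFError):
            enrichment_factor(EnrichmentInput("o", 0.4, 0.0, 0.1, 0.1))

    def test_pseudocount_defines_ef(self):
        ef = enrichment_factor(EnrichmentInput("o", 0.4, 0.0, 0.1, 0.1),
                               pseudo=0.01)
        assert math.isfinite(ef)

    @given(a=st.floats(0, 1), b=st.floats(0.001, 1),
           c=st.floats(0, 1), d=st.floats(0.001, 1))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry_under_treatment_swap(self, a, b, c, d):
        x = EnrichmentInput("o", a, b, c, d)
        swapped = EnrichmentInput("o", c, d, a, b)
        assert enrichment_factor(x) == pytest.approx(-enrichment_factor(swapped))


class TestClassifyEnriched:
    @pytest.mark.parametrize("ef,ra,expected", [
        (0.6, 0.002, True),
        (0.5, 0.5, False),       # strict EF bound
        (5.0, 0.0009, False),    # abundance rule
        (5.0, 0.001, False),     # strict RA bound
        (0.51, 0.0011, True),
    ])
    def test_thresholds(self, ef, ra, expected):
        assert classify_enriched(ef, ra) is expected

    def test_nan_ef_not_enriched(self):
        assert classify_enriched(float("nan"), 0.5) is False


class TestEfTable:
    def test_single_replicate_example(self, four_composite_table):
        out = ef_table(four_composite_table)
        row = out.set_index("otu_id").loc["OTU_1"]
        assert row["ef"] == pytest.approx(1.0)
        assert row["relative_abundance"] == pytest.approx(0.3)
        assert bool(row["enriched"])

    def test_three_replicates_average(self):
        counts, meta = {}, {}
        for rep in (1, 2, 3):
            for t, fc, a in (("13C", "heavy", 4), ("13C", "light", 2),
                             ("12C", "heavy", 1), ("12C", "light", 1)):
                name = f"r{rep}_{t}_{fc}"
                counts[name] = [a, 10 - a]
                meta[name] = composite_meta(replicate=rep, treatment=t,
                                            fraction_class=fc)
        out = ef_table(make_table(counts, meta))
        row = out.set_index("otu_id").loc["OTU_1"]
        assert row["ef"] == pytest.approx(1.0)
        assert row["n_replicates"] == 3
        assert bool(row["enriched"])

    def test_uniform_community_all_zero(self):
        counts = {s: [5, 5, 5] for s in ("a", "b", "c", "d")}
        meta = {
            "a": composite_meta(treatment="13C", fraction_class="heavy"),
            "b": composite_meta(treatment="13C", fraction_class="light"),
            "c": composite_meta(treatment="12C", fraction_class="heavy"),
            "d": composite_meta(treatment="12C", fraction_class="light"),
        }
        out = ef_table(make_table(counts, meta))
        assert np.allclose(out["ef"], 0.0)
        assert not out["enriched"].any()

    def test_missing_composite_errors(self, four_composite_table):
        broken = four_composite_table.subset_samples(
            ["c13_heavy", "c13_light", "c12_heavy"])
        with pytest.raises(IncompleteDesignError, match="12C"):
            ef_table(broken)

    def test_undefined_ef_flagged_not_dropped(self):
        counts = {
            "a": [4, 6], "b": [0, 10], "c": [1, 9], "d": [1, 9],
        }
        meta = {
            "a": composite_meta(treatment="13C", fraction_class="heavy"),
            "b": composite_meta(treatment="13C", fraction_class="light"),
            "c": composite_meta(treatment="12C", fraction_class="heavy"),
            "d": composite_meta(treatment="12C", fraction_class="light"),
        }
        out = ef_table(make_table(counts, meta)).set_index("otu_id")
        assert "undefined_ef" in out.loc["OTU_1", "flags"]
        assert math.isnan(out.loc["OTU_1", "ef"])
        assert not bool(out.loc["OTU_1", "enriched"])

    def test_pooled_mode_matches_on_balanced_data(self, four_composite_table):
        per = ef_table(four_composite_table, mode="per-replicate")
        pooled = ef_table(four_composite_table, mode="pooled")
        np.testing.assert_allclose(per["ef"], pooled["ef"])

    def test_planted_actives_recovered_end_to_end(self):
        from sipmet.simulate import gen_community

        table, _, truth = gen_community(
            n_otus=200, n_active=5, heavy_shift_factor=5.0, depth=3248,
            n_replicates=3, seed=42)
        out = ef_table(table, pseudo=0.003)
        flagged = set(out.loc[out["enriched"], "otu_id"])
        assert flagged == set(truth.active_otu_ids)
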
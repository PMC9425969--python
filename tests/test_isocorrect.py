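import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sipmet.errors import EmptyInputError, ParameterError, ShapeError
from sipmet.isocorrect import (
    CorrectedCID,
    IsotopologueVector,
    build_correction_matrix,
    correct_cid,
    correct_table,
    isotopologue_ratio,
    mean_enrichment,
    summarize_enrichment,
)


class TestBuildCorrectionMatrix:
    def test_n1_pure_tracer(self):
        m = build_correction_matrix(1, natural_13C=0.0107, tracer_purity=1.0)
        expected = np.array([[0.9893, 0.0], [0.0107, 1.0]])
        np.testing.assert_allclose(m.matrix, expected, atol=1e-12)

    def test_identity_when_no_isotope_effects(self):
        # natural_13C = 0 is outside the open domain; approach it instead
        m = build_correction_matrix(2, natural_13C=1e-15, tracer_purity=1.0)
        np.testing.assert_allclose(m.matrix, np.eye(3), atol=1e-12)

    def test_fully_labeled_column_binomial_purity(self):
        m = build_correction_matrix(3, tracer_purity=0.98)
        np.testing.assert_allclose(
            m.matrix[:, 3], [0.000008, 0.001176, 0.057624, 0.941192], atol=1e-12)

    @pytest.mark.parametrize("n", range(1, 21))
    def test_columns_sum_to_one(self, n):
        m = build_correction_matrix(n)
        np.testing.assert_allclose(m.matrix.sum(axis=0), 1.0, atol=1e-12)
        assert (m.matrix >= 0).all()

    @given(n=st.integers(1, 12), nat=st.floats(1e-6, 0.49),
           purity=st.floats(0.5, 1.0))
    @settings(max_examples=60, deadline=None)
    def test_columns_sum_property(self, n, nat, purity):
        m = build_correction_matrix(n, nat, purity)
        assert np.allclose(m.matrix.sum(axis=0), 1.0, atol=1e-12)

    @pytest.mark.parametrize("kwargs", [
        dict(n_carbons=0), dict(n_carbons=3, natural_13C=0.6),
        dict(n_carbons=3, natural_13C=0.0), dict(n_carbons=3, tracer_purity=0.0),
        dict(n_carbons=3, tracer_purity=1.5),
    ])
    def test_domain_errors(self, kwargs):
        with pytest.raises(ParameterError):
            build_correction_matrix(**kwargs)


class TestCorrectCid:
    def test_unlabeled_c3_natural_envelope(self):
        # forward-convolved natural envelope of an unlabeled C3 compound
        model = build_correction_matrix(3)
        m = model.matrix @ np.array([1.0, 0.0, 0.0, 0.0])
        vec = IsotopologueVector("unlabeled", 3, m)
        cid = correct_cid(vec, model)
        np.testing.assert_allclose(cid.fractions, [1, 0, 0, 0], atol=1e-9)
        assert cid.mean_enrichment == pytest.approx(0.0, abs=1e-9)

    def test_fully_labeled_c3(self):
        model = build_correction_matrix(3, tracer_purity=0.98)
        vec = IsotopologueVector(
            "full", 3, [0.000008, 0.001176, 0.057624, 0.941192])
        cid = correct_cid(vec, model)
        np.testing.assert_allclose(cid.fractions, [0, 0, 0, 1], atol=1e-9)
        assert cid.mean_enrichment == pytest.approx(1.0, abs=1e-9)

    def test_exact_round_trip(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 11))
            x = rng.dirichlet(np.ones(n + 1))
            model = build_correction_matrix(n, tracer_purity=0.98)
            vec = IsotopologueVector("rt", n, model.matrix @ x)
            cid = correct_cid(vec, model)
            np.testing.assert_allclose(cid.fractions, x, atol=1e-9)
            assert cid.mean_enrichment == pytest.approx(
                np.arange(n + 1) @ x / n, abs=1e-9)

    def test_raw_intensities_accepted(self):
        model = build_correction_matrix(2)
        x = np.array([0.3, 0.3, 0.4])
        m = 1e6 * (model.matrix @ x)  # arbitrary scale
        cid = correct_cid(IsotopologueVector("raw", 2, m), model)
        np.testing.assert_allclose(cid.fractions, x, atol=1e-9)

    def test_all_zero_vector_rejected(self):
        model = build_correction_matrix(2)
        with pytest.raises(EmptyInputError):
            correct_cid(IsotopologueVector("z", 2, [0, 0, 0]), model)

    def test_dimension_mismatch(self):
        model = build_correction_matrix(3)
        with pytest.raises(ShapeError):
            correct_cid(IsotopologueVector("m", 2, [1, 0, 0]), model)

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_grid_search_oracle(self, n, rng):
        """NNLS solution matches exhaustive simplex grid search."""
        step = {1: 1e-3, 2: 0.01, 3: 0.05, 4: 0.1}[n]
        k = round(1 / step)
        model = build_correction_matrix(n, tracer_purity=0.98)
        x_true = rng.dirichlet(np.ones(n + 1))
        m = model.matrix @ x_true + rng.normal(0, 1e-3, n + 1)
        m = np.clip(m, 0, None)
        m = m / m.sum()
        best, best_r = None, np.inf
        for comp in itertools.product(range(k + 1), repeat=n):
            if sum(comp) > k:
                continue
            x = np.array(list(comp) + [k - sum(comp)]) / k
            r = np.linalg.norm(model.matrix @ x - m)
            if r < best_r:
                best, best_r = x, r
        cid = correct_cid(IsotopologueVector("g", n, m), model)
        x_hat = cid.fractions / cid.fractions.sum()
        assert np.linalg.norm(model.matrix @ x_hat - m) <= best_r + 1e-9
        np.testing.assert_allclose(x_hat, best, atol=2 * step)


class TestMeanEnrichment:
    @pytest.mark.parametrize("fractions,n,expected", [
        ([1, 0, 0, 0], 3, 0.0),
        ([0, 0, 0, 1], 3, 1.0),
        ([0.5, 0, 0, 0.5], 3, 0.5),
    ])
    def test_examples(self, fractions, n, expected):
        assert mean_enrichment(fractions, n) == pytest.approx(expected)

    def test_binomial_labeling_mean_is_p(self, rng):
        from scipy.stats import binom

        prev = -1.0
        for p in np.linspace(0.05, 0.95, 10):
            x = binom.pmf(np.arange(7), 6, p)
            e = mean_enrichment(x, 6)
            assert e == pytest.approx(p, abs=1e-12)
            assert e > prev
            prev = e

    def test_negative_entry_rejected(self):
        with pytest.raises(ParameterError):
            mean_enrichment([1.2, -0.2, 0, 0], 3)


class TestIsotopologueRatio:
    def cid(self, fractions):
        x = np.asarray(fractions, float)
        n = x.size - 1
        return CorrectedCID("m", x, float(np.arange(n + 1) @ x / n))

    def test_m3_over_m6(self):
        x = np.zeros(7)
        x[3], x[6] = 0.2, 0.4
        x[0] = 0.4
        assert isotopologue_ratio(self.cid(x), 3, 6) == pytest.approx(0.5)

    def test_identity_and_zero(self):
        x = np.array([0.25, 0.25, 0.5])
        assert isotopologue_ratio(self.cid(x), 0, 1) == pytest.approx(1.0)
        assert isotopologue_ratio(self.cid([0.0, 0.5, 0.5]), 0, 1) == 0.0

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            isotopologue_ratio(self.cid([0.5, 0.0, 0.5]), 0, 1)


class TestSummarizeEnrichment:
    def cid(self, e):
        return CorrectedCID("F6P", np.array([1 - e, 0, e]), e)

    def test_three_replicates(self):
        pairs = [(("F", 4), self.cid(e)) for e in (0.1, 0.2, 0.3)]
        (s,) = summarize_enrichment(pairs)
        assert s.mean == pytest.approx(0.2)
        assert s.sd == pytest.approx(0.1)
        assert s.n == 3

    def test_single_and_identical(self):
        (s,) = summarize_enrichment([(("F", 4), self.cid(0.4))])
        assert (s.mean, s.sd, s.n) == (pytest.approx(0.4), 0.0, 1)
        (s,) = summarize_enrichment([(("F", 4), self.cid(0.25))] * 3)
        assert s.sd == pytest.approx(0.0)

    def test_empty_input(self):
        assert summarize_enrichment([]) == []

    def test_missing_replicates_kept(self):
        pairs = [(("F", 4), self.cid(0.1)), (("F", 4), self.cid(0.2)),
                 (("M", 4), self.cid(0.5))]
        out = {(s.group, s.metabolite_id): s for s in summarize_enrichment(pairs)}
        assert out[(("F", 4), "F6P")].n == 2
        assert out[(("M", 4), "F6P")].n == 1


def test_correct_table_ragged(rng):
    import pandas as pd

    model2 = build_correction_matrix(2)
    m2 = model2.matrix @ np.array([0.5, 0.25, 0.25])
    df = pd.DataFrame([
        {"metabolite_id": "Gly", "n_carbons": 2, "sex": "F", "time_h": 4,
         "compartment": "gut", "replicate": 1,
         "M0": m2[0], "M1": m2[1], "M2": m2[2], "M3": None},
    ])
    out = correct_table(df)
    assert out.loc[0, "mean_enrichment"] == pytest.approx(0.375, abs=1e-9)
    np.testing.assert_allclose(
        out.loc[0, ["x0", "x1", "x2"]].astype(float), [0.5, 0.25, 0.25], atol=1e-9)
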
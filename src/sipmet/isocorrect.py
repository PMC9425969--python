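"""Natural-abundance and tracer-purity correction of carbon isotopologue clusters.

Measured mass-isotopologue vectors (M0..Mn) of a metabolite with n carbon
atoms are deconvolved into the underlying carbon labeling distribution
(CID) by inverting a forward model in which each of the j tracer-labeled
positions is actually heavy with probability ``tracer_purity`` and each of
the n-j unlabeled positions is heavy with the natural 13C abundance.

The correction is carbon-only: at sufficiently high mass resolution the
13C cluster is separated from isotopic species of other elements, so no
H/N/O/S convolution is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .errors import EmptyInputError, ParameterError, ShapeError

#: IUPAC representative isotopic composition of carbon.
NATURAL_13C = 0.0107

#: Lower bound of the tracer atom-fraction (> 98 atom% 13C).
DEFAULT_TRACER_PURITY = 0.98

#: Carbon counts of the metabolite panel used throughout; editable.
CARBON_COUNTS: dict[str, int] = {
    "F6P": 6, "FBP": 6, "G6P": 6, "6-PG": 6, "Cit": 6, "Man6P": 6,
    "Gly3P": 3, "PEP": 3, "Lact": 3, "2,3PG": 3, "Ser": 3, "PSer": 3,
    "a-KG": 5, "2-OHGlu": 5, "Glu": 5, "Pro": 5,
    "Sed7P": 7, "UMP": 9, "GMP": 10,
    "Succ": 4, "Mala": 4, "Asp": 4, "Thr": 4,
    "Ala": 3, "Gly": 2, "Val": 5, "Leu": 6, "Ile": 6,
}


@dataclass(frozen=True)
class IsotopologueVector:
    """Measured M0..Mn intensities of one metabolite's carbon cluster."""

    metabolite_id: str
    n_carbons: int
    intensities: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        if self.n_carbons < 1:
            raise ParameterError(f"n_carbons must be >= 1, got {self.n_carbons}")
        if arr.ndim != 1 or arr.size != self.n_carbons + 1:
            raise ShapeError(
                f"{self.metabolite_id}: expected {self.n_carbons + 1} intensities "
                f"(M0..M{self.n_carbons}), got {arr.size}"
            )
        if np.any(arr < 0):
            raise ParameterError(f"{self.metabolite_id}: negative intensity")
        object.__setattr__(self, "intensities", arr)


@dataclass(frozen=True)
class CorrectionModel:
    """Forward model A: column j is the measured-mass distribution of a
    molecule with j tracer-labeled carbon positions."""

    n_carbons: int
    natural_13C: float
    tracer_purity: float
    matrix: np.ndarray


@dataclass(frozen=True)
class CorrectedCID:
    """Corrected carbon labeling distribution and its mean enrichment."""

    metabolite_id: str
    fractions: np.ndarray
    mean_enrichment: float


@dataclass(frozen=True)
class EnrichmentSummary:
    """Mean +/- SD of mean enrichment across biological replicates."""

    group: tuple
    metabolite_id: str
    mean: float
    sd: float
    n: int


def _binom_pmf(n: int, p: float) -> np.ndarray:
    """Binomial(n, p) pmf as a length n+1 vector (k = 0..n)."""
    from scipy.stats import binom

    return binom.pmf(np.arange(n + 1), n, p)


def build_correction_matrix(
    n_carbons: int,
    natural_13C: float = NATURAL_13C,
    tracer_purity: float = DEFAULT_TRACER_PURITY,
) -> CorrectionModel:
    """Build the (n+1)x(n+1) carbon-only correction matrix.

    Column j is the convolution of Binomial(j, tracer_purity) over the
    labeled positions with Binomial(n-j, natural_13C) over the unlabeled
    ones. Every column sums to 1.
    """
    if n_carbons < 1:
        raise ParameterError(f"n_carbons must be >= 1, got {n_carbons}")
    if not (0.0 < natural_13C < 0.5):
        raise ParameterError(f"natural_13C must be in (0, 0.5), got {natural_13C}")
    if not (0.0 < tracer_purity <= 1.0):
        raise ParameterError(f"tracer_purity must be in (0, 1], got {tracer_purity}")

    n = n_carbons
    A = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        labeled = _binom_pmf(j, tracer_purity)
        unlabeled = _binom_pmf(n - j, natural_13C)
        col = np.convolve(labeled, unlabeled)
        A[:, j] = col / col.sum()
    return CorrectionModel(n, natural_13C, tracer_purity, A)


def mean_enrichment(fractions: Sequence[float], n_carbons: int) -> float:
    """Mean 13C enrichment: sum_j j * x_j / n for a simplex vector x."""
    x = np.asarray(fractions, dtype=float)
    if np.any(x < 0):
        raise ParameterError("fractions must be non-negative")
    if x.size != n_carbons + 1:
        raise ShapeError(f"expected {n_carbons + 1} fractions, got {x.size}")
    if not np.isclose(x.sum(), 1.0, atol=1e-6):
        raise ParameterError(f"fractions must sum to 1, got {x.sum()}")
    return float(np.arange(n_carbons + 1) @ x) / n_carbons


def correct_cid(measured: IsotopologueVector, model: CorrectionModel) -> CorrectedCID:
    """Invert the forward model by non-negative least squares.

    The measured vector is normalized to sum 1, x = argmin ||Ax - m||_2
    s.t. x >= 0 is solved, and x is renormalized onto the simplex.
    """
    if measured.n_carbons != model.n_carbons:
        raise ShapeError(
            f"{measured.metabolite_id}: vector has {measured.n_carbons} carbons "
            f"but model has {model.n_carbons}"
        )
    m = measured.intensities
    total = m.sum()
    if total <= 0:
        raise EmptyInputError(f"{measured.metabolite_id}: all-zero intensity vector")
    x, _ = nnls(model.matrix, m / total)
    s = x.sum()
    if s <= 0:  # pragma: no cover - cannot happen for a stochastic matrix
        raise EmptyInputError(f"{measured.metabolite_id}: degenerate NNLS solution")
    x /= s
    return CorrectedCID(
        metabolite_id=measured.metabolite_id,
        fractions=x,
        mean_enrichment=mean_enrichment(x, model.n_carbons),
    )


def isotopologue_ratio(cid: CorrectedCID, i: int, j: int) -> float:
    """Ratio fractions[i] / fractions[j] (e.g. M3/M6)."""
    n = cid.fractions.size - 1
    if not (0 <= i <= n and 0 <= j <= n):
        raise ShapeError(f"isotopologue index out of range 0..{n}")
    denom = cid.fractions[j]
    if denom <= 0:
        raise ZeroDivisionError(
            f"{cid.metabolite_id}: M{j} fraction is zero, M{i}/M{j} undefined"
        )
    return float(cid.fractions[i] / denom)


def summarize_enrichment(
    cids: Sequence[tuple[tuple, CorrectedCID]],
) -> list[EnrichmentSummary]:
    """Aggregate mean enrichment over replicates per (group key, metabolite).

    ``cids`` is a sequence of ``(group_key, CorrectedCID)`` pairs where the
    group key identifies the biological condition (e.g. sex, time,
    compartment) but not the replicate. SD is the sample (ddof=1) standard
    deviation, reported as 0 when n = 1.
    """
    buckets: dict[tuple, list[float]] = {}
    for key, cid in cids:
        buckets.setdefault((key, cid.metabolite_id), []).append(cid.mean_enrichment)
    out = []
    for (group, met), vals in buckets.items():
        arr = np.asarray(vals, dtype=float)
        sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        out.append(EnrichmentSummary(group, met, float(arr.mean()), sd, arr.size))
    return out


def correct_table(
    df: pd.DataFrame,
    natural_13C: float = NATURAL_13C,
    tracer_purity: float = DEFAULT_TRACER_PURITY,
) -> pd.DataFrame:
    """Correct every row of an isotopologue table.

    Expects columns ``metabolite_id``, ``n_carbons``, arbitrary key columns,
    and ``M0..Mk`` intensity columns (ragged tails allowed: entries beyond
    n_carbons, and NaN, are ignored). Returns the key columns plus
    ``x0..xk`` and ``mean_enrichment``.
    """
    m_cols = [c for c in df.columns if c.startswith("M") and c[1:].isdigit()]
    m_cols.sort(key=lambda c: int(c[1:]))
    key_cols = [c for c in df.columns if c not in m_cols]
    models: dict[int, CorrectionModel] = {}
    rows = []
    for _, row in df.iterrows():
        n = int(row["n_carbons"])
        model = models.setdefault(n, build_correction_matrix(n, natural_13C, tracer_purity))
        vals = pd.to_numeric(row[m_cols[: n + 1]], errors="coerce").to_numpy(dtype=float)
        vals = np.nan_to_num(vals, nan=0.0)
        vec = IsotopologueVector(str(row["metabolite_id"]), n, vals)
        cid = correct_cid(vec, model)
        rec = {c: row[c] for c in key_cols}
        for k, xk in enumerate(cid.fractions):
            rec[f"x{k}"] = xk
        rec["mean_enrichment"] = cid.mean_enrichment
        rows.append(rec)
    return pd.DataFrame(rows)
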
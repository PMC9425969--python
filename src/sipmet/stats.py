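"""Exact small-sample rank-sum comparisons and taxa-metabolite correlation.

The rank-sum test enumerates all C(n_a + n_b, n_a) assignments of the
pooled values (midranks for ties), so its two-sided p-value is an exact
rational count / C(N, n_a). Correlation p-values come from permutation
enumeration (exact for n <= 7) or seeded Monte-Carlo permutations.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy.stats import norm, rankdata

from .errors import (
    ConsistencyError,
    InsufficientDataError,
    ParameterError,
    UndefinedCorrelationError,
)

log = logging.getLogger(__name__)

EXACT_RANKSUM_MAX = 12
EXACT_PERM_MAX = 7
DEFAULT_N_PERM = 10_000


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided rank-sum comparison of two groups."""

    label: str
    n_a: int
    n_b: int
    statistic: float  # rank sum of group a (midranks)
    p_two_sided: float
    exact: bool
    p_fraction: Fraction | None = None


@dataclass(frozen=True)
class CorrelationEntry:
    taxon: str
    metabolite_id: str
    method: str
    coefficient: float
    p_two_sided: float
    significant: bool
    sign: str


def _ranksum_count_distribution(ranks2: np.ndarray, n_a: int) -> np.ndarray:
    """Counts of size-n_a subsets of ``ranks2`` (integer 2x midranks) by sum.

    Dynamic program over items; entry [s] of the returned vector is the
    number of subsets of size n_a whose 2x-rank sum equals s.
    """
    max_sum = int(ranks2.sum())
    f = np.zeros((n_a + 1, max_sum + 1), dtype=np.int64)
    f[0, 0] = 1
    for r in ranks2:
        r = int(r)
        for k in range(n_a, 0, -1):
            f[k, r:] += f[k - 1, : max_sum + 1 - r]
    return f[n_a]


def wilcoxon_exact(
    a: Sequence[float], b: Sequence[float], label: str = ""
) -> GroupComparison:
    """Exact two-sided rank-sum test by full assignment enumeration.

    Pooled values are midranked; the null distribution of group a's rank
    sum is obtained by counting all C(n_a+n_b, n_a) assignments, and the
    two-sided p is the fraction of assignments whose rank sum deviates
    from the null mean at least as much as the observed one. Groups
    larger than 12 fall back to the normal approximation with a logged
    note.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError(
            f"both groups need >= 2 observations, got {a.size} and {b.size}")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)  # midranks
    w_a = float(ranks[: a.size].sum())
    n_a, n_b = a.size, b.size
    N = n_a + n_b

    if max(n_a, n_b) > EXACT_RANKSUM_MAX:
        log.info("group sizes %d/%d exceed exact limit %d; using normal "
                 "approximation", n_a, n_b, EXACT_RANKSUM_MAX)
        mu = n_a * (N + 1) / 2.0
        # tie correction for the variance of the rank sum
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / ((N - 1) * N)
        sigma2 = n_a * n_b / 12.0 * (N + 1 - tie_term)
        z = (w_a - mu) / math.sqrt(sigma2)
        p = min(1.0, 2.0 * norm.sf(abs(z)))
        return GroupComparison(label, n_a, n_b, w_a, p, exact=False)

    ranks2 = np.rint(2 * ranks).astype(np.int64)
    counts = _ranksum_count_distribution(ranks2, n_a)
    total = math.comb(N, n_a)
    # integer deviation: |s*N - n_a*T| with T = sum of all 2x ranks
    T = int(ranks2.sum())
    s_obs = int(round(2 * w_a))
    dev_obs = abs(s_obs * N - n_a * T)
    sums = np.arange(counts.size, dtype=np.int64)
    extreme = np.abs(sums * N - n_a * T) >= dev_obs
    hits = int(counts[extreme].sum())
    p_frac = Fraction(hits, total)
    return GroupComparison(label, n_a, n_b, w_a, float(p_frac), exact=True,
                           p_fraction=p_frac)


def _corr_coefficient(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        x, y = rankdata(x), rankdata(y)
    elif method != "pearson":
        raise ParameterError(f"unknown correlation method {method!r}")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise UndefinedCorrelationError("constant vector: correlation undefined")
    return float(xc @ yc / denom)


def correlate_pair(
    x: Sequence[float],
    y: Sequence[float],
    method: str = "spearman",
    seed: int = 0,
    n_perm: int = DEFAULT_N_PERM,
) -> tuple[float, float]:
    """Correlation coefficient with a two-sided permutation p-value.

    For n <= 7 all n! permutations of ``y`` are enumerated (exact p =
    count / n!, the identity included); for larger n, ``n_perm`` seeded
    random permutations are drawn and p = (hits + 1) / (n_perm + 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ConsistencyError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 4:
        raise InsufficientDataError(f"need >= 4 paired observations, got {x.size}")
    r_obs = _corr_coefficient(x, y, method)

    xr = rankdata(x) if method == "spearman" else x
    yr = rankdata(y) if method == "spearman" else y
    xc = xr - xr.mean()
    yc = yr - yr.mean()
    sx = math.sqrt(xc @ xc)
    sy = math.sqrt(yc @ yc)
    tol = 1e-12
    if x.size <= EXACT_PERM_MAX:
        perms = np.array(list(itertools.permutations(range(x.size))))
        r_all = (yc[perms] @ xc) / (sx * sy)
        hits = int((np.abs(r_all) >= abs(r_obs) - tol).sum())
        p = hits / perms.shape[0]
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            r_p = (yc[rng.permutation(y.size)] @ xc) / (sx * sy)
            if abs(r_p) >= abs(r_obs) - tol:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    return r_obs, p


def benjamini_hochberg(pvals: Sequence[float]) -> np.ndarray:
    """BH-adjusted p-values (step-up, monotone)."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def correlation_matrix(
    taxa,
    metabolites,
    method: str = "spearman",
    alpha: float = 0.05,
    seed: int = 0,
    bh: bool = False,
) -> list[CorrelationEntry]:
    """All (taxon, metabolite) correlations across shared observation units.

    ``taxa`` and ``metabolites`` are DataFrames whose rows are the shared
    observation units (e.g. replicate x time within one sex) and whose
    columns are genera / metabolites. Significance is an uncorrected
    p < alpha by default; ``bh=True`` recomputes it on BH-adjusted
    p-values. Pairs involving a constant vector are reported with NaN
    coefficient and not significant.
    """
    import pandas as pd

    taxa = pd.DataFrame(taxa)
    metabolites = pd.DataFrame(metabolites)
    shared = taxa.index.intersection(metabolites.index)
    if len(shared) != len(taxa.index) or len(shared) != len(metabolites.index):
        raise ConsistencyError(
            f"observation units differ: {len(taxa.index)} taxa rows vs "
            f"{len(metabolites.index)} metabolite rows, {len(shared)} shared")
    if len(shared) < 4:
        raise InsufficientDataError(f"need >= 4 shared units, got {len(shared)}")
    taxa = taxa.loc[shared]
    metabolites = metabolites.loc[shared]

    raw: list[tuple[str, str, float, float]] = []
    rng = np.random.default_rng(seed)
    for taxon in taxa.columns:
        for met in metabolites.columns:
            sub = int(rng.integers(0, 2**31))
            try:
                r, p = correlate_pair(taxa[taxon], metabolites[met],
                                      method=method, seed=sub)
            except UndefinedCorrelationError:
                raw.append((taxon, met, float("nan"), float("nan")))
                continue
            raw.append((taxon, met, r, p))

    ps = [p for *_, p in raw]
    finite = [p for p in ps if not math.isnan(p)]
    if bh and finite:
        adj_map = dict(zip([i for i, p in enumerate(ps) if not math.isnan(p)],
                           benjamini_hochberg(finite)))
    entries = []
    for i, (taxon, met, r, p) in enumerate(raw):
        p_eff = adj_map.get(i, float("nan")) if bh else p
        sig = (not math.isnan(p_eff)) and p_eff < alpha
        sign = "+" if (not math.isnan(r) and r >= 0) else "-"
        if math.isnan(r):
            sign = ""
        entries.append(CorrelationEntry(str(taxon), str(met), method, r, p, sig, sign))
    return entries
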
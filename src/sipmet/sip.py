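"""Gradient delta13C analysis, heavy/light fraction selection and the
per-OTU enrichment-factor (EF) statistic.

EF contrasts an OTU's over-representation in heavy versus light gradient
fractions under labeled feeding against the same contrast under unlabeled
feeding:

    EF = RA(13C, heavy) / RA(13C, light) - RA(12C, heavy) / RA(12C, light)

An OTU is called enriched ("active") when EF > 0.5 and its relative
abundance exceeds 0.1%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import CountTable, relative_abundance
from .errors import (
    ConsistencyError,
    IncompleteDesignError,
    InsufficientDataError,
    ParameterError,
    SelectionError,
    UndefinedEFError,
)

#: 13C/12C isotope ratio of the V-PDB reference standard.
VPDB_RATIO = 0.0111802

EF_THRESHOLD = 0.5
RA_THRESHOLD = 0.001

DENSITY_LO, DENSITY_HI = 1.60, 1.80

#: Densities are compared after rounding to this many decimals (refractometer precision).
_DENSITY_DECIMALS = 3


@dataclass(frozen=True)
class FractionRecord:
    """One gradient fraction in top-to-bottom collection order."""

    fraction_index: int
    density: float
    dna_amount: float
    delta13C: float | None = None

    def __post_init__(self) -> None:
        if not (DENSITY_LO <= self.density <= DENSITY_HI):
            raise ParameterError(
                f"fraction {self.fraction_index}: density {self.density} outside "
                f"[{DENSITY_LO}, {DENSITY_HI}]")
        if self.dna_amount < 0:
            raise ParameterError(f"fraction {self.fraction_index}: negative DNA amount")


@dataclass(frozen=True)
class FractionWindows:
    """Closed density intervals for light and heavy DNA."""

    light: tuple[float, float] = (1.68, 1.69)
    heavy: tuple[float, float] = (1.71, 1.72)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("light", self.light), ("heavy", self.heavy)):
            if not (DENSITY_LO <= lo <= hi <= DENSITY_HI):
                raise ParameterError(f"{name} window {lo}-{hi} invalid")
        if self.light[1] >= self.heavy[0]:
            raise ParameterError(
                f"light window must lie entirely below heavy window "
                f"(light hi {self.light[1]} >= heavy lo {self.heavy[0]})")


@dataclass(frozen=True)
class EnrichmentInput:
    """Relative abundances of one OTU in the four composite samples."""

    otu_id: str
    ra_13_heavy: float
    ra_13_light: float
    ra_12_heavy: float
    ra_12_light: float

    def __post_init__(self) -> None:
        for name in ("ra_13_heavy", "ra_13_light", "ra_12_heavy", "ra_12_light"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{self.otu_id}: {name}={v} outside [0, 1]")


@dataclass(frozen=True)
class EnrichmentResult:
    otu_id: str
    ef: float
    relative_abundance: float
    enriched: bool


def delta13C(ratio_13_12: float, reference_ratio: float = VPDB_RATIO) -> float:
    """Express a 13C/12C ratio as delta in per-mil versus a reference."""
    if ratio_13_12 <= 0 or reference_ratio <= 0:
        raise ParameterError("isotope ratios must be positive")
    return (ratio_13_12 / reference_ratio - 1.0) * 1000.0


def select_fractions(
    profile: list[FractionRecord], windows: FractionWindows = FractionWindows()
) -> tuple[list[FractionRecord], list[FractionRecord]]:
    """Return the fractions falling inside the light and heavy windows.

    Intervals are closed; densities are rounded to 3 decimals first. The
    result is sorted by density and independent of input order.
    """
    if not profile:
        raise SelectionError("empty fraction profile")
    ordered = sorted(profile, key=lambda f: (round(f.density, _DENSITY_DECIMALS),
                                             f.fraction_index))
    out = []
    for name, (lo, hi) in (("light", windows.light), ("heavy", windows.heavy)):
        sel = [f for f in ordered
               if lo <= round(f.density, _DENSITY_DECIMALS) <= hi]
        if not sel:
            raise SelectionError(f"no fraction falls in the {name} window [{lo}, {hi}]")
        out.append(sel)
    return out[0], out[1]


def find_enrichment_peak(
    profile: list[FractionRecord],
) -> tuple[float, float] | None:
    """Locate an interior delta13C peak along the density gradient.

    Among fractions with a measured delta13C (sorted by density), returns
    the (density, delta13C) of a fraction strictly greater than both its
    neighbours; ties between several local maxima are broken by the larger
    DNA amount. Returns None when the profile has no interior peak.
    """
    measured = sorted((f for f in profile if f.delta13C is not None),
                      key=lambda f: f.density)
    if len(measured) < 3:
        raise InsufficientDataError(
            f"need >= 3 fractions with measured delta13C, got {len(measured)}")
    peaks = [
        f for prev, f, nxt in zip(measured, measured[1:], measured[2:])
        if f.delta13C > prev.delta13C and f.delta13C > nxt.delta13C
    ]
    if not peaks:
        return None
    best = max(peaks, key=lambda f: f.dna_amount)
    return best.density, best.delta13C


def combine_fraction_counts(
    table: CountTable,
    selected: dict[str, list[str]],
    composite_meta: dict[str, dict] | None = None,
) -> CountTable:
    """Sum selected per-fraction sample columns into composite samples.

    ``selected`` maps each composite sample name to the existing sample
    columns whose counts are summed (counts are additive; relative
    abundance is computed afterwards on the composite). Metadata for a
    composite comes from ``composite_meta`` when given, else from its
    first constituent.
    """
    new_cols, meta_rows = {}, {}
    for name, members in selected.items():
        if not members:
            raise ConsistencyError(f"composite {name!r}: empty member list")
        missing = [m for m in members if m not in table.counts.columns]
        if missing:
            raise ConsistencyError(
                f"composite {name!r}: fraction sample(s) not in table: {missing}")
        new_cols[name] = table.counts[members].sum(axis=1)
        if composite_meta and name in composite_meta:
            meta_rows[name] = composite_meta[name]
        else:
            meta_rows[name] = table.meta.loc[members[0]].to_dict()
    counts = pd.DataFrame(new_cols, index=table.counts.index)
    meta = pd.DataFrame.from_dict(meta_rows, orient="index")
    meta.index.name = table.meta.index.name
    return CountTable(counts, meta)


def enrichment_factor(x: EnrichmentInput, pseudo: float = 0.0) -> float:
    """EF = (13h+p)/(13l+p) - (12h+p)/(12l+p).

    With ``pseudo`` = 0 and non-zero denominators this is the plain EF
    formula; a zero denominator then raises :class:`UndefinedEFError` so
    the OTU can be flagged rather than silently dropped.
    """
    if pseudo < 0:
        raise ParameterError(f"pseudocount must be >= 0, got {pseudo}")
    d13 = x.ra_13_light + pseudo
    d12 = x.ra_12_light + pseudo
    if d13 == 0 or d12 == 0:
        raise UndefinedEFError(
            f"{x.otu_id}: zero light-fraction abundance with pseudo=0")
    return (x.ra_13_heavy + pseudo) / d13 - (x.ra_12_heavy + pseudo) / d12


def classify_enriched(
    ef: float,
    relative_abundance: float,
    ef_threshold: float = EF_THRESHOLD,
    ra_threshold: float = RA_THRESHOLD,
) -> bool:
    """True iff EF and relative abundance both exceed their (strict) thresholds."""
    if not (0.0 <= relative_abundance <= 1.0):
        raise ParameterError(f"relative_abundance={relative_abundance} outside [0, 1]")
    if math.isnan(ef):
        return False
    return ef > ef_threshold and relative_abundance > ra_threshold


def _composite_lookup(meta: pd.DataFrame) -> pd.DataFrame:
    needed = {"sex", "time_h", "treatment", "fraction_class", "replicate"}
    missing = needed - set(meta.columns)
    if missing:
        raise IncompleteDesignError(f"metadata lacks columns: {sorted(missing)}")
    return meta


def ef_table(
    table: CountTable,
    pseudo: float = 0.0,
    ef_threshold: float = EF_THRESHOLD,
    ra_threshold: float = RA_THRESHOLD,
    mode: str = "per-replicate",
) -> pd.DataFrame:
    """Per-OTU EF and enrichment call for every (sex, time) group.

    ``table`` must hold composite samples: for each (sex, time_h,
    replicate) the four cells 12C/13C x heavy/light. In the default
    ``per-replicate`` mode the EF is computed within each replicate and
    averaged; in ``pooled`` mode counts are summed across replicates
    first. The reported relative abundance is the mean RA of the OTU over
    the 13C composite samples of the group, and the enrichment call is
    made on these averages.

    Returns a tidy frame: otu_id, sex, time_h, ef, relative_abundance,
    enriched, n_replicates, flags.
    """
    if mode not in ("per-replicate", "pooled"):
        raise ParameterError(f"unknown EF mode {mode!r}")
    meta = _composite_lookup(table.meta)
    bio = table.biological_samples()
    meta = meta.loc[bio]
    ra = relative_abundance(table.subset_samples(bio))
    rows = []
    for (sex, time_h), gmeta in meta.groupby(["sex", "time_h"], sort=True):
        cells: dict[tuple[str, str, object], str] = {}
        for smp, m in gmeta.iterrows():
            cells[(m["treatment"], m["fraction_class"], m["replicate"])] = smp
        replicates = sorted({rep for _, _, rep in cells})
        missing = [
            (t, fc, rep)
            for rep in replicates
            for t in ("12C", "13C")
            for fc in ("heavy", "light")
            if (t, fc, rep) not in cells
        ]
        if missing:
            raise IncompleteDesignError(
                f"group (sex={sex}, time_h={time_h}) is missing composite(s): "
                f"{missing}")

        c13 = [cells[("13C", fc, rep)] for rep in replicates for fc in ("heavy", "light")]
        mean_ra_13 = ra[c13].mean(axis=1)

        undefined = np.zeros(len(ra.index), dtype=bool)
        if mode == "pooled":
            pra = {}
            for t in ("12C", "13C"):
                for fc in ("heavy", "light"):
                    pooled = table.counts[
                        [cells[(t, fc, rep)] for rep in replicates]].sum(axis=1)
                    pra[(t, fc)] = (pooled / pooled.sum()).to_numpy()
            rep_blocks = [pra]
        else:
            rep_blocks = [
                {(t, fc): ra[cells[(t, fc, rep)]].to_numpy()
                 for t in ("12C", "13C") for fc in ("heavy", "light")}
                for rep in replicates
            ]
        efs = np.full((len(rep_blocks), len(ra.index)), np.nan)
        for r, blk in enumerate(rep_blocks):
            d13 = blk[("13C", "light")] + pseudo
            d12 = blk[("12C", "light")] + pseudo
            bad = (d13 == 0) | (d12 == 0)
            undefined |= bad
            ok = ~bad
            efs[r, ok] = ((blk[("13C", "heavy")][ok] + pseudo) / d13[ok]
                          - (blk[("12C", "heavy")][ok] + pseudo) / d12[ok])

        finite = np.isfinite(efs)
        n_ok = finite.sum(axis=0)
        sums = np.where(finite, efs, 0.0).sum(axis=0)
        mean_ef = np.where(n_ok > 0, sums / np.maximum(n_ok, 1), np.nan)
        for i, otu in enumerate(ra.index):
            ef = float(mean_ef[i])
            flags = []
            if undefined[i]:
                flags.append("undefined_ef")
            enriched = (not math.isnan(ef)) and classify_enriched(
                ef, float(mean_ra_13.iloc[i]), ef_threshold, ra_threshold)
            rows.append({
                "otu_id": otu, "sex": sex, "time_h": time_h,
                "ef": ef, "relative_abundance": float(mean_ra_13.iloc[i]),
                "enriched": enriched, "n_replicates": len(replicates),
                "flags": ";".join(flags),
            })
    return pd.DataFrame(rows)
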
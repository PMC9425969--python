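"""OTU-table hygiene: contaminant removal, rarefaction, relative abundance
and taxonomic aggregation."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateSampleError, ParameterError, ValidationError

log = logging.getLogger(__name__)

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus")
UNCLASSIFIED = "unclassified"

#: Metadata columns required for every non-control sample.
META_COLUMNS = ("sex", "time_h", "treatment", "fraction_class", "replicate")


@dataclass
class CountTable:
    """OTU x sample integer counts plus per-sample metadata.

    ``counts`` is indexed by otu_id with sample_id columns; ``meta`` is
    indexed by sample_id with columns sex, time_h, treatment
    (12C/13C/none), fraction_class (heavy/light/total), replicate, and a
    boolean ``is_control`` marking negative controls.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            bad = self.counts.lt(0)
            otu = bad.any(axis=1).idxmax()
            smp = bad.loc[otu].idxmax()
            raise ValidationError(f"negative count at otu={otu!r}, sample={smp!r}")
        missing = [s for s in self.counts.columns if s not in self.meta.index]
        if missing:
            raise ValidationError(f"samples missing from metadata: {missing}")
        if "is_control" not in self.meta.columns:
            self.meta = self.meta.assign(is_control=False)
        self.meta["is_control"] = self.meta["is_control"].astype(bool)
        bio = self.meta.loc[[s for s in self.counts.columns
                             if not self.meta.at[s, "is_control"]]]
        for col in META_COLUMNS:
            if col not in self.meta.columns or bio[col].isna().any():
                bad = "all" if col not in self.meta.columns else list(
                    bio.index[bio[col].isna()])
                raise ValidationError(
                    f"metadata column {col!r} incomplete for samples: {bad}")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def biological_samples(self) -> list[str]:
        return [s for s in self.counts.columns if not self.meta.at[s, "is_control"]]

    def control_samples(self) -> list[str]:
        return [s for s in self.counts.columns if self.meta.at[s, "is_control"]]

    def subset_samples(self, samples: list[str]) -> "CountTable":
        return CountTable(self.counts[samples].copy(), self.meta.loc[samples].copy())


@dataclass(frozen=True)
class TaxonomyMap:
    """otu_id -> ordered lineage with per-rank bootstrap confidence.

    ``lineages[otu]`` maps each rank name to a ``(label, bootstrap)`` pair;
    unassigned ranks carry the explicit label ``unclassified``.
    """

    lineages: dict[str, dict[str, tuple[str, float]]]

    def label(self, otu_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise ParameterError(f"unknown rank {rank!r}; expected one of {RANKS}")
        entry = self.lineages.get(otu_id)
        if entry is None:
            return UNCLASSIFIED
        return entry.get(rank, (UNCLASSIFIED, 0.0))[0]


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Per-sample relative abundances; every column sums to 1."""
    totals = table.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise DegenerateSampleError(f"all-zero sample(s): {list(zero.index)}")
    return table.counts / totals


def contaminant_filter(table: CountTable) -> tuple[CountTable, list[str]]:
    """Remove OTUs detected in a negative control whose best biological
    relative abundance is below 10x their control relative abundance.

    With several controls the most conservative (maximum) control RA is
    used. Without any control the filter is skipped with a warning.
    """
    controls = table.control_samples()
    if not controls:
        log.warning("no negative-control sample present; contaminant filter skipped")
        return table, []
    bio = table.biological_samples()
    totals = table.counts.sum(axis=0)
    # all-zero columns (e.g. an emptied control) contribute RA 0 everywhere
    ra = table.counts / totals.where(totals > 0, 1)
    control_ra = ra[controls].max(axis=1)
    best_bio_ra = ra[bio].max(axis=1) if bio else pd.Series(0.0, index=ra.index)
    in_control = table.counts[controls].sum(axis=1) > 0
    removed = list(ra.index[in_control & (best_bio_ra < 10 * control_ra)])
    kept = table.counts.drop(index=removed)
    return CountTable(kept, table.meta.copy()), removed


def rarefy(
    table: CountTable, depth: int, seed: int
) -> tuple[CountTable, list[str]]:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples with fewer than ``depth`` total reads are dropped and returned
    in the second element. Deterministic given ``seed`` (multivariate
    hypergeometric draws, one independent substream per sample).
    """
    if depth <= 0:
        raise ParameterError(f"rarefaction depth must be positive, got {depth}")
    root = np.random.default_rng(seed)
    streams = root.spawn(len(table.counts.columns))
    new_cols, dropped = {}, []
    for rng, sample in zip(streams, table.counts.columns):
        col = table.counts[sample].to_numpy()
        total = int(col.sum())
        if total < depth:
            dropped.append(sample)
            continue
        if total == depth:
            new_cols[sample] = col
        else:
            new_cols[sample] = rng.multivariate_hypergeometric(col, depth)
    if not new_cols:
        raise DegenerateSampleError(f"no sample reaches rarefaction depth {depth}")
    counts = pd.DataFrame(new_cols, index=table.counts.index)
    return CountTable(counts, table.meta.loc[list(counts.columns)].copy()), dropped


def aggregate_taxa(table: CountTable, taxonomy: TaxonomyMap, rank: str) -> CountTable:
    """Sum counts over OTUs sharing a taxonomic label at ``rank``.

    OTUs without an assignment at that rank are pooled under
    ``unclassified``. Per-sample totals are conserved exactly.
    """
    if rank not in RANKS:
        raise ParameterError(f"unknown rank {rank!r}; expected one of {RANKS}")
    labels = pd.Series(
        [taxonomy.label(otu, rank) for otu in table.counts.index],
        index=table.counts.index,
    )
    agg = table.counts.groupby(labels).sum()
    agg.index.name = rank
    return CountTable(agg, table.meta.copy())
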
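"""Run configuration and the end-to-end orchestrated analysis.

The pipeline runs two arms and joins them:

* SIP arm: contaminant filter -> rarefaction -> (optional per-fraction
  combination) -> per-OTU enrichment factors -> genus aggregation.
* Metabolomics arm: isotopologue correction -> per-group enrichment
  summaries -> exact rank-sum sex comparisons.
* Join: taxa-metabolite correlation across replicate x time units.

Outputs are deterministic given (config, seed): no timestamps are written
and all randomness flows from the top-level seed through named substreams.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as sio
from .community import (
    CountTable,
    TaxonomyMap,
    aggregate_taxa,
    contaminant_filter,
    rarefy,
    relative_abundance,
)
from .errors import ValidationError
from .isocorrect import (
    NATURAL_13C,
    DEFAULT_TRACER_PURITY,
    correct_table,
)
from .sip import (
    VPDB_RATIO,
    FractionWindows,
    classify_enriched,
    ef_table,
    find_enrichment_peak,
)
from .simulate import Scenario, gen_linked_dataset
from .stats import correlation_matrix, wilcoxon_exact

log = logging.getLogger(__name__)

# substream labels hashed into per-stage seeds
_STAGES = ("simulate", "rarefy", "correlate")


def _stage_seed(seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little")


@dataclass
class RunConfig:
    """Everything an end-to-end run needs; every default is configurable."""

    # input files (ignored when simulate=True)
    otu_table: str | None = None
    sample_metadata: str | None = None
    taxonomy: str | None = None
    isotopologues: str | None = None
    fraction_profiles: dict = field(default_factory=dict)

    simulate: bool = True
    scenario: Scenario = field(default_factory=Scenario)

    light_window: tuple[float, float] = (1.68, 1.69)
    heavy_window: tuple[float, float] = (1.71, 1.72)
    ef_threshold: float = 0.5
    ra_threshold: float = 0.001
    ef_pseudocount: float = 0.0
    ef_mode: str = "per-replicate"
    genus_ef_mode: str = "max"  # max-EF OTU per genus; "mean" available
    rarefaction_depth: int = 3248
    natural_13C: float = NATURAL_13C
    tracer_purity: float = DEFAULT_TRACER_PURITY
    reference_ratio: float = VPDB_RATIO
    correlation_method: str = "spearman"
    alpha: float = 0.05
    bh_correction: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("ef_threshold", "ra_threshold", "rarefaction_depth", "alpha"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.ef_pseudocount < 0:
            raise ValidationError("ef_pseudocount must be >= 0")
        # FractionWindows enforces ordering / range
        FractionWindows(tuple(self.light_window), tuple(self.heavy_window))
        if self.ef_mode not in ("per-replicate", "pooled"):
            raise ValidationError(f"unknown ef_mode {self.ef_mode!r}")
        if self.genus_ef_mode not in ("max", "mean"):
            raise ValidationError(f"unknown genus_ef_mode {self.genus_ef_mode!r}")
        if self.correlation_method not in ("spearman", "pearson"):
            raise ValidationError(
                f"unknown correlation_method {self.correlation_method!r}")
        if not self.simulate:
            for name in ("otu_table", "sample_metadata", "taxonomy"):
                if getattr(self, name) is None:
                    raise ValidationError(f"{name} path required when simulate=False")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["scenario"]["sexes"] = list(self.scenario.sexes)
        d["scenario"]["times"] = list(self.scenario.times)
        d["scenario"]["planted_pairs"] = [list(p) for p in self.scenario.planted_pairs]
        d["light_window"] = list(self.light_window)
        d["heavy_window"] = list(self.heavy_window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sc = d.pop("scenario", {})
        if isinstance(sc, dict):
            sc = dict(sc)
            for key in ("sexes", "times"):
                if key in sc:
                    sc[key] = tuple(sc[key])
            if "planted_pairs" in sc:
                sc["planted_pairs"] = tuple(tuple(p) for p in sc["planted_pairs"])
            if "metabolites" in sc:
                sc["metabolites"] = {
                    k: (int(v[0]), float(v[1]))
                    for k, v in sc["metabolites"].items()}
            scenario = Scenario(**sc)
        else:
            scenario = sc
        for key in ("light_window", "heavy_window"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(scenario=scenario, **d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# -------------------------------------------------------------- sub-analyses

def genus_ef_table(ef_df: pd.DataFrame, taxonomy: TaxonomyMap,
                   mode: str = "max",
                   ef_threshold: float = 0.5,
                   ra_threshold: float = 0.001) -> pd.DataFrame:
    """Aggregate per-OTU EF rows to genus level.

    ``max`` keeps the maximum-EF OTU per genus as its representative;
    ``mean`` averages EF and relative abundance and re-applies the
    enrichment thresholds to the means.
    """
    df = ef_df.copy()
    df["genus"] = [taxonomy.label(o, "genus") for o in df["otu_id"]]
    out = []
    for (genus, sex, time_h), grp in df.groupby(["genus", "sex", "time_h"],
                                                sort=True):
        grp_ok = grp[~grp["ef"].isna()]
        if grp_ok.empty:
            grp_ok = grp
        if mode == "max":
            rep = grp_ok.loc[grp_ok["ef"].idxmax()] if grp_ok["ef"].notna().any() \
                else grp_ok.iloc[0]
            ef_val = rep["ef"]
            ra_val = rep["relative_abundance"]
            enriched = bool(rep["enriched"])
        else:
            ef_val = grp_ok["ef"].mean()
            ra_val = grp_ok["relative_abundance"].mean()
            enriched = (not math.isnan(ef_val)) and classify_enriched(
                float(ef_val), float(ra_val), ef_threshold, ra_threshold)
        out.append({"genus": genus, "sex": sex, "time_h": time_h,
                    "ef": ef_val, "relative_abundance": ra_val,
                    "enriched": enriched, "n_otus": len(grp)})
    return pd.DataFrame(out)


def sex_comparisons(summary_units: pd.DataFrame) -> pd.DataFrame:
    """Exact rank-sum F-vs-M comparison of per-replicate mean enrichment,
    one row per (metabolite, time)."""
    rows = []
    for (met, t), grp in summary_units.groupby(["metabolite_id", "time_h"],
                                               sort=True):
        a = grp.loc[grp["sex"] == "F", "mean_enrichment"].to_numpy()
        b = grp.loc[grp["sex"] == "M", "mean_enrichment"].to_numpy()
        if a.size < 2 or b.size < 2:
            continue
        cmp = wilcoxon_exact(a, b, label=f"{met}@t{t}:F-vs-M")
        rows.append({"label": cmp.label, "metabolite_id": met, "time_h": t,
                     "n_a": cmp.n_a, "n_b": cmp.n_b,
                     "statistic": cmp.statistic, "p_two_sided": cmp.p_two_sided,
                     "exact": cmp.exact})
    return pd.DataFrame(rows)


def build_correlation_units(
    table: CountTable,
    taxonomy: TaxonomyMap,
    corrected: pd.DataFrame,
    sex: str,
    genera: list[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assemble aligned taxa/metabolite matrices for one sex.

    Observation units are (time_h, replicate); the taxa matrix holds each
    genus' relative abundance in the 13C heavy composite of that unit, the
    metabolite matrix the corrected mean enrichment.
    """
    meta = table.meta
    ra = relative_abundance(table.subset_samples(table.biological_samples()))
    genus_table = aggregate_taxa(table, taxonomy, "genus")
    gra = relative_abundance(
        genus_table.subset_samples(genus_table.biological_samples()))
    taxa_rows = {}
    for smp, m in meta.iterrows():
        if m.get("is_control") or m["sex"] != sex:
            continue
        if m["treatment"] == "13C" and m["fraction_class"] == "heavy":
            unit = (int(m["time_h"]), int(m["replicate"]))
            taxa_rows[unit] = {
                g: float(gra.at[g, smp]) if g in gra.index else 0.0 for g in genera}
    taxa = pd.DataFrame.from_dict(taxa_rows, orient="index").sort_index()

    sub = corrected[corrected["sex"] == sex]
    met = sub.pivot_table(index=["time_h", "replicate"],
                          columns="metabolite_id",
                          values="mean_enrichment")
    met.index = [(int(t), int(r)) for t, r in met.index]
    met = met.sort_index()
    shared = taxa.index.intersection(met.index)
    return taxa.loc[shared], met.loc[shared]


# ------------------------------------------------------------------ the run

def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the full analysis and write all result tables to ``out_dir``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def note(msg: str) -> None:
        log.info(msg)
        log_lines.append(msg)

    note(f"seed={config.seed} config_hash={config.config_hash()}")

    # ---- inputs ----------------------------------------------------------
    if config.simulate:
        bundle = gen_linked_dataset(config.scenario,
                                    seed=_stage_seed(config.seed, "simulate"))
        table, taxonomy = bundle["community"], bundle["taxonomy"]
        gradients = bundle["gradients"]
        iso_df = bundle["isotopologues"]
        inputs = out / "inputs"
        inputs.mkdir(exist_ok=True)
        sio.write_otu_table(table, inputs / "otu_table.tsv",
                            inputs / "sample_metadata.csv")
        sio.write_taxonomy(taxonomy, inputs / "taxonomy.tsv")
        sio.write_isotopologue_table(iso_df, inputs / "isotopologues.csv")
        for (sex, t, treatment), profile in gradients.items():
            sio.write_fraction_profile(
                profile, inputs / f"gradient_{sex}_t{t}_{treatment}.csv")
        sio.write_truth(bundle["truth"], inputs / "truth.json")
        note(f"simulated inputs: {len(table.sample_ids)} samples, "
             f"{len(table.otu_ids)} OTUs, {len(iso_df)} isotopologue rows")
    else:
        table = sio.read_otu_table(config.otu_table, config.sample_metadata)
        taxonomy = sio.read_taxonomy(config.taxonomy)
        iso_df = (sio.read_isotopologue_table(config.isotopologues)
                  if config.isotopologues else None)
        gradients = {
            tuple(str(k).split("|")): sio.read_fraction_profile(v)
            for k, v in (config.fraction_profiles or {}).items()
        }
        note(f"loaded inputs: {len(table.sample_ids)} samples, "
             f"{len(table.otu_ids)} OTUs")

    # ---- gradient arm ----------------------------------------------------
    peak_rows = []
    for key, profile in sorted(gradients.items(), key=lambda kv: str(kv[0])):
        peak = find_enrichment_peak(profile)
        peak_rows.append({
            "gradient": "|".join(map(str, key)),
            "peak_density": None if peak is None else peak[0],
            "peak_delta13C": None if peak is None else peak[1],
        })
    if peak_rows:
        sio.write_tsv(pd.DataFrame(peak_rows), out / "gradient_peaks.tsv")
        note(f"gradient peaks: {sum(r['peak_density'] is not None for r in peak_rows)}"
             f"/{len(peak_rows)} gradients with an interior delta13C peak")

    # ---- SIP arm ---------------------------------------------------------
    filtered, removed = contaminant_filter(table)
    note(f"contaminant filter removed {len(removed)} OTU(s): {removed}")
    rarefied, dropped = rarefy(filtered, config.rarefaction_depth,
                               _stage_seed(config.seed, "rarefy"))
    note(f"rarefied to {config.rarefaction_depth}; dropped {len(dropped)} "
         f"sample(s): {dropped}")
    efs = ef_table(rarefied, pseudo=config.ef_pseudocount,
                   ef_threshold=config.ef_threshold,
                   ra_threshold=config.ra_threshold, mode=config.ef_mode)
    sio.write_tsv(efs, out / "ef_otu.tsv")
    genus_efs = genus_ef_table(efs, taxonomy, mode=config.genus_ef_mode,
                               ef_threshold=config.ef_threshold,
                               ra_threshold=config.ra_threshold)
    sio.write_tsv(genus_efs, out / "ef_genus.tsv")
    note(f"EF: {int(efs['enriched'].sum())} enriched OTU rows, "
         f"{int(genus_efs['enriched'].sum())} enriched genus rows")

    # ---- metabolomics arm ------------------------------------------------
    corrected = comparisons = None
    if iso_df is not None and len(iso_df):
        corrected = correct_table(iso_df, natural_13C=config.natural_13C,
                                  tracer_purity=config.tracer_purity)
        sio.write_tsv(corrected, out / "corrected_cids.tsv")
        summary = (corrected
                   .groupby(["sex", "time_h", "compartment", "metabolite_id"])
                   ["mean_enrichment"]
                   .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0,
                        n="count")
                   .reset_index())
        sio.write_tsv(summary, out / "enrichment_summary.tsv")
        comparisons = sex_comparisons(corrected)
        if len(comparisons):
            sio.write_tsv(comparisons, out / "comparisons.tsv")
        note(f"metabolomics: {len(corrected)} corrected CIDs, "
             f"{0 if comparisons is None else len(comparisons)} rank-sum comparisons")

    # ---- correlation join ------------------------------------------------
    corr_rows = []
    if corrected is not None:
        for sex in sorted(genus_efs["sex"].unique()):
            genera = sorted(genus_efs.loc[
                (genus_efs["sex"] == sex) & genus_efs["enriched"], "genus"].unique())
            if not genera:
                note(f"correlation[{sex}]: no enriched genera, skipped")
                continue
            taxa_m, met_m = build_correlation_units(
                rarefied, taxonomy, corrected, sex, genera)
            if len(taxa_m) < 4:
                note(f"correlation[{sex}]: only {len(taxa_m)} units, skipped")
                continue
            entries = correlation_matrix(
                taxa_m, met_m, method=config.correlation_method,
                alpha=config.alpha,
                seed=_stage_seed(config.seed, "correlate"),
                bh=config.bh_correction)
            for e in entries:
                corr_rows.append({
                    "sex": sex, "taxon": e.taxon, "metabolite_id": e.metabolite_id,
                    "method": e.method, "coefficient": e.coefficient,
                    "p_two_sided": e.p_two_sided, "significant": e.significant,
                    "sign": e.sign})
    if corr_rows:
        sio.write_tsv(pd.DataFrame(corr_rows), out / "correlations.tsv")
        note(f"correlations: {sum(r['significant'] for r in corr_rows)} significant "
             f"of {len(corr_rows)} pairs at alpha={config.alpha}")

    # ---- summary, config, log -------------------------------------------
    config.to_yaml(out / "config_used.yaml")
    with open(out / "summary.txt", "w") as fh:
        fh.write("enriched genera per sex x time\n")
        for (sex, t), grp in genus_efs.groupby(["sex", "time_h"]):
            names = sorted(grp.loc[grp["enriched"], "genus"])
            fh.write(f"  sex={sex} time_h={t}: {len(names)} enriched"
                     f" ({', '.join(names)})\n")
        if corr_rows:
            sig = [r for r in corr_rows if r["significant"]]
            fh.write(f"significant taxa-metabolite correlations: {len(sig)}\n")
            for r in sig:
                fh.write(f"  [{r['sex']}] {r['taxon']} {r['sign']} "
                         f"{r['metabolite_id']} (p={r['p_two_sided']:.4g})\n")
    with open(out / "run_log.txt", "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return out
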
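"""Readers and writers for the plain-text dialects used by the pipeline.

All tables are uncompressed text: OTU counts and taxonomy are
tab-separated, fraction profiles and isotopologue tables and sample
metadata are comma-separated. Every reader validates invariants at load
and raises :class:`~sipmet.errors.ParseError` naming file, line and field.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .community import CountTable, TaxonomyMap, RANKS, UNCLASSIFIED
from .errors import ParseError, ValidationError
from .sip import FractionRecord

_LINEAGE_TOKEN = re.compile(r"^(?P<label>.*?)(?:\((?P<boot>\d+(?:\.\d+)?)\))?$")


# ---------------------------------------------------------------- OTU table

def write_otu_table(table: CountTable, counts_path, meta_path) -> None:
    out = table.counts.copy()
    out.index.name = "otu_id"
    out.to_csv(counts_path, sep="\t")
    meta = table.meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path)


def read_otu_table(counts_path, meta_path) -> CountTable:
    counts_path, meta_path = Path(counts_path), Path(meta_path)
    try:
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"{counts_path}: cannot parse OTU table: {exc}") from exc
    for col in counts.columns:
        vals = pd.to_numeric(counts[col], errors="coerce")
        bad = vals.isna() | (vals < 0) | (vals % 1 != 0)
        if bad.any():
            otu = counts.index[bad.to_numpy().nonzero()[0][0]]
            line = int(np.where(counts.index == otu)[0][0]) + 2
            raise ParseError(
                f"{counts_path}: line {line}, field {col!r}: count for OTU "
                f"{otu!r} is not a non-negative integer")
        counts[col] = vals.astype(np.int64)
    try:
        meta = pd.read_csv(meta_path, index_col=0)
    except Exception as exc:
        raise ParseError(f"{meta_path}: cannot parse sample metadata: {exc}") from exc
    missing = [s for s in counts.columns if s not in meta.index]
    if missing:
        raise ValidationError(
            f"{meta_path}: sample(s) in counts but absent from metadata: {missing}")
    return CountTable(counts, meta.loc[list(counts.columns)])


# ---------------------------------------------------------------- taxonomy

def write_taxonomy(taxonomy: TaxonomyMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("otu_id\tlineage\n")
        for otu, entry in taxonomy.lineages.items():
            parts = []
            for rank in RANKS:
                label, boot = entry.get(rank, (UNCLASSIFIED, 0.0))
                parts.append(f"{label}({boot:g})")
            fh.write(f"{otu}\t{';'.join(parts)}\n")


def read_taxonomy(path) -> TaxonomyMap:
    path = Path(path)
    lineages: dict[str, dict[str, tuple[str, float]]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("otu_id"):
            raise ParseError(f"{path}: line 1: expected 'otu_id\\tlineage' header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            try:
                otu, lineage = line.split("\t", 1)
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: expected two tab-separated fields")
            tokens = lineage.split(";")
            entry = {}
            for rank, token in zip(RANKS, tokens):
                m = _LINEAGE_TOKEN.match(token.strip())
                label = m.group("label") or UNCLASSIFIED
                boot = float(m.group("boot")) if m.group("boot") else 0.0
                entry[rank] = (label, boot)
            for rank in RANKS[len(tokens):]:
                entry[rank] = (UNCLASSIFIED, 0.0)
            lineages[otu] = entry
    return TaxonomyMap(lineages)


# ---------------------------------------------------------- fraction profile

def write_fraction_profile(profile: list[FractionRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("fraction_index,density_g_per_ml,dna_ng_per_ul,delta13C_permil\n")
        for f in profile:
            d = "" if f.delta13C is None else f"{f.delta13C:.6g}"
            fh.write(f"{f.fraction_index},{f.density:.4f},{f.dna_amount:.6g},{d}\n")


def read_fraction_profile(path) -> list[FractionRecord]:
    path = Path(path)
    df = pd.read_csv(path)
    needed = ["fraction_index", "density_g_per_ml", "dna_ng_per_ul", "delta13C_permil"]
    for col in needed[:3]:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    records = []
    for i, row in df.iterrows():
        delta = row.get("delta13C_permil")
        delta = None if pd.isna(delta) else float(delta)
        try:
            records.append(FractionRecord(
                int(row["fraction_index"]), float(row["density_g_per_ml"]),
                float(row["dna_ng_per_ul"]), delta))
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: line {i + 2}: {exc}") from exc
    return records


# -------------------------------------------------------- isotopologue table

def write_isotopologue_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_isotopologue_table(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("metabolite_id", "n_carbons"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    m_cols = sorted((c for c in df.columns if re.fullmatch(r"M\d+", c)),
                    key=lambda c: int(c[1:]))
    if not m_cols:
        raise ParseError(f"{path}: no M0..Mn intensity columns found")
    for i, row in df.iterrows():
        n = row["n_carbons"]
        if pd.isna(n) or int(n) < 1:
            raise ParseError(
                f"{path}: line {i + 2}, field 'n_carbons': must be a positive integer")
        vals = pd.to_numeric(row[m_cols[: int(n) + 1]], errors="coerce")
        if (vals.dropna() < 0).any():
            raise ParseError(
                f"{path}: line {i + 2}: negative isotopologue intensity")
    return df


# ------------------------------------------------------------- result tables

def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ------------------------------------------------------------------ truth

def write_truth(truth, path) -> None:
    payload = {
        "seed": truth.seed,
        "active_otu_ids": list(truth.active_otu_ids),
        "heavy_shift_factor": truth.heavy_shift_factor,
        "contaminant_otu_ids": list(truth.contaminant_otu_ids),
        "metabolite_labeling": {
            "|".join(map(str, k)): v for k, v in truth.metabolite_labeling.items()
        },
        "planted_pairs": [list(p) for p in truth.planted_pairs],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
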
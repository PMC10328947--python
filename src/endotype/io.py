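"""Readers and writers for the on-disk formats the pipeline touches.

Formats are deliberately plain text: counts as gene-by-sample TSV, clinical
covariates as CSV, gene sets as GMT, somatic mutations as MAF-like TSV and
copy-number segments as SEG. Genomic coordinates are 1-based inclusive on
disk (the de facto SEG convention) and converted to 0-based half-open
column pairs (``start``, ``end``) at the reader/writer boundary so that all
internal interval arithmetic uses a single convention.

All readers validate their input and raise :class:`ParseError` with the
offending line number where one can be attributed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "ParseError",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_clinical",
    "read_maf",
    "write_maf",
    "read_seg",
    "write_seg",
    "load_config",
]


class ParseError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# counts


def read_counts(path) -> pd.DataFrame:
    """Read a gene-by-sample integer count matrix from TSV.

    First column holds gene identifiers; the header row holds sample IDs.
    Rejects ragged rows, duplicate identifiers and negative or non-integer
    counts, naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 2:
            raise ParseError(f"{path}: header must name at least one sample")
        samples = header[1:]
        if len(set(samples)) != len(samples):
            raise ParseError(f"{path}: duplicate sample IDs in header")
        genes, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
                )
            genes.append(fields[0])
            try:
                vals = [float(v) for v in fields[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric count: {exc}") from exc
            for v in vals:
                if v < 0:
                    raise ParseError(f"{path}:{lineno}: negative count {v:g}")
                if v != int(v):
                    raise ParseError(f"{path}:{lineno}: non-integer count {v:g}")
            rows.append([int(v) for v in vals])
    if len(set(genes)) != len(genes):
        dupes = pd.Series(genes)
        first = dupes[dupes.duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate gene ID {first!r}")
    return pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=samples)


def write_counts(matrix: pd.DataFrame, path) -> None:
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise ValueError("duplicate gene or sample IDs")
    out = matrix.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set collection: name, description, genes, tab-separated.

    The description field is discarded; duplicate genes within a set are
    collapsed (first occurrence order kept); a duplicated set name is an error.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT lines need >=3 tab-separated fields"
                )
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            if not genes:
                raise ParseError(f"{path}:{lineno}: set {name!r} is empty")
            sets[name] = genes
    return sets


def write_gmt(sets: dict[str, list[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


# ---------------------------------------------------------------------------
# clinical


_CLINICAL_REQUIRED = ["patient_id", "ki67_baseline", "ki67_2wk", "er_status", "her2_status"]
_CLINICAL_OPTIONAL = ["grade", "histology", "chemo", "estradiol", "tils"]


def _normalise_columns(df: pd.DataFrame, required: list[str], path) -> pd.DataFrame:
    """Case-insensitive column matching; raise listing any missing required columns."""
    mapping = {c: c.strip().lower() for c in df.columns}
    df = df.rename(columns=mapping)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns: {', '.join(missing)}")
    return df


def read_clinical(path) -> pd.DataFrame:
    """Read the per-patient clinical table (CSV); validates Ki67 and estradiol ranges."""
    path = Path(path)
    df = pd.read_csv(path)
    df = _normalise_columns(df, _CLINICAL_REQUIRED, path)
    for col in _CLINICAL_OPTIONAL:
        if col not in df.columns:
            df[col] = np.nan
    for col in ("ki67_baseline", "ki67_2wk", "estradiol", "tils"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("ki67_baseline", "ki67_2wk", "tils"):
        bad = df[col].dropna()
        bad = bad[(bad < 0) | (bad > 100)]
        if not bad.empty:
            raise ParseError(
                f"{path}: {col} out of [0, 100] for patient "
                f"{df.loc[bad.index[0], 'patient_id']!r} ({bad.iloc[0]:g})"
            )
    neg = df["estradiol"].dropna()
    neg = neg[neg < 0]
    if not neg.empty:
        raise ParseError(f"{path}: negative estradiol value {neg.iloc[0]:g}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise ParseError(f"{path}: duplicate patient_id {dup!r}")
    return df


def write_clinical(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# MAF-like mutation table


_MAF_ALIASES = {
    "sample_id": ["sample_id", "tumor_sample_barcode", "sample"],
    "gene": ["gene", "hugo_symbol"],
    "vaf": ["vaf", "tumor_vaf"],
    "alt_reads": ["alt_reads", "t_alt_count"],
    "depth": ["depth", "t_depth"],
    "consequence_class": ["consequence_class", "impact", "consequence"],
    "pop_af": ["pop_af", "gnomad_af", "exac_af"],
    "variant_classification": ["variant_classification"],
}


def read_maf(path) -> pd.DataFrame:
    """Read a MAF-like TSV of somatic mutations.

    Column names are matched case-insensitively with common MAF aliases.
    When a ``vaf`` column is absent it is derived as alt_reads / depth.
    Optional columns absent from the file are filled with nulls.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep="\t")
    lower = {c.strip().lower(): c for c in raw.columns}
    out = pd.DataFrame()
    for canon, aliases in _MAF_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                out[canon] = raw[lower[alias]]
                break
    missing = [c for c in ("sample_id", "gene") if c not in out.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns: {', '.join(missing)}")
    if "vaf" not in out.columns:
        if "alt_reads" in out.columns and "depth" in out.columns:
            out["vaf"] = out["alt_reads"] / out["depth"]
        else:
            out["vaf"] = np.nan
    for col in ("alt_reads", "consequence_class", "pop_af", "variant_classification"):
        if col not in out.columns:
            out[col] = np.nan
    out["vaf"] = pd.to_numeric(out["vaf"], errors="coerce")
    bad = out["vaf"].dropna()
    bad = bad[(bad < 0) | (bad > 1)]
    if not bad.empty:
        raise ParseError(f"{path}: vaf out of [0, 1]: {bad.iloc[0]:g}")
    neg = pd.to_numeric(out["alt_reads"], errors="coerce").dropna()
    if (neg < 0).any():
        raise ParseError(f"{path}: negative alt_reads")
    if "consequence_class" in out.columns:
        out["consequence_class"] = out["consequence_class"].astype(str).str.lower()
    return out.drop(columns=[c for c in ("depth",) if c in out.columns])


def write_maf(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# SEG copy-number segments


_SEG_ALIASES = {
    "sample_id": ["sample_id", "id", "sample"],
    "chrom": ["chrom", "chromosome", "chr"],
    "start": ["start", "loc.start", "loc_start"],
    "end": ["end", "loc.end", "loc_end"],
    "log2_ratio": ["log2_ratio", "seg.mean", "seg_mean", "log2"],
}


def read_seg(path) -> pd.DataFrame:
    """Read a SEG file (1-based inclusive on disk -> 0-based half-open in memory)."""
    path = Path(path)
    raw = pd.read_csv(path, sep=r"\s+")
    lower = {c.strip().lower(): c for c in raw.columns}
    out = pd.DataFrame()
    for canon, aliases in _SEG_ALIASES.items():
        for alias in aliases:
            if alias in lower:
                out[canon] = raw[lower[alias]]
                break
    missing = [c for c in _SEG_ALIASES if c not in out.columns]
    if missing:
        raise ParseError(f"{path}: missing required columns: {', '.join(missing)}")
    out["start"] = out["start"].astype(np.int64) - 1  # to 0-based half-open
    out["end"] = out["end"].astype(np.int64)
    out["log2_ratio"] = pd.to_numeric(out["log2_ratio"], errors="coerce")
    if (out["start"] >= out["end"]).any():
        i = out.index[out["start"] >= out["end"]][0]
        raise ParseError(f"{path}: segment with start > end at data row {i + 1}")
    _check_overlaps(out, path)
    return out


def _check_overlaps(segs: pd.DataFrame, path) -> None:
    for (sample, chrom), grp in segs.groupby(["sample_id", "chrom"], sort=False):
        grp = grp.sort_values("start")
        if (grp["start"].to_numpy()[1:] < grp["end"].to_numpy()[:-1]).any():
            raise ParseError(
                f"{path}: overlapping segments for sample {sample!r} on {chrom}"
            )


def write_seg(segs: pd.DataFrame, path) -> None:
    out = segs.copy()
    out["start"] = out["start"].astype(np.int64) + 1  # back to 1-based inclusive
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# configuration


def load_config(path, cls):
    """Load a YAML config into dataclass ``cls``; unknown keys are errors.

    Nested dataclass fields accept nested mappings. Silent typos in
    thresholds would corrupt results, hence the strictness.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return _build_dataclass(cls, doc, str(path))


def _build_dataclass(cls, doc: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(doc) - set(fields)
    if unknown:
        raise ParseError(f"{path}: unknown config keys: {', '.join(sorted(unknown))}")
    kwargs = {}
    for key, value in doc.items():
        ftype = fields[key].type
        target = fields[key]
        default = target.default_factory() if target.default_factory is not dataclasses.MISSING else None
        if dataclasses.is_dataclass(default) and isinstance(value, dict):
            kwargs[key] = _build_dataclass(type(default), value, path)
        else:
            kwargs[key] = value
    return cls(**kwargs)
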
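"""Readers and writers: MAF-dialect TSV, minimal VCF, CSV/JSON results.

Allele fractions and cell fractions are never mixed: column names carry
the distinction (``allele_fraction`` vs ``cell_fraction``).  Every output
artifact embeds a provenance header (package version, config hash, seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .spectrum import MutationTable

__all__ = [
    "read_mutation_table",
    "read_sample_metadata",
    "attach_metadata",
    "write_results",
    "read_results",
    "provenance",
]

logger = logging.getLogger("neutralclone")

#: default MAF column resolution; override entries via ``column_map``
MAF_COLUMNS = {
    "sample": ("Tumor_Sample_Barcode", "sample", "sample_id"),
    "allele_fraction": ("allele_fraction", "i_tumor_vaf", "vaf"),
    "alt": ("t_alt_count", "alt_count"),
    "ref": ("t_ref_count", "ref_count"),
}


def _resolve(df: pd.DataFrame, key: str, column_map: dict | None) -> str | None:
    if column_map and key in column_map:
        name = column_map[key]
        if name not in df.columns:
            raise SchemaError(f"mapped column {name!r} for {key!r} not present")
        return name
    for cand in MAF_COLUMNS[key]:
        if cand in df.columns:
            return cand
    return None


def _read_maf(path: Path, column_map: dict | None) -> list[MutationTable]:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    sample_col = _resolve(df, "sample", column_map)
    af_col = _resolve(df, "allele_fraction", column_map)
    alt_col = _resolve(df, "alt", column_map)
    ref_col = _resolve(df, "ref", column_map)
    missing = []
    if sample_col is None:
        missing.append("sample (e.g. Tumor_Sample_Barcode)")
    if af_col is None and (alt_col is None or ref_col is None):
        missing.append("allele_fraction or t_alt_count/t_ref_count")
    if missing:
        raise SchemaError(f"{path}: missing required columns: {', '.join(missing)}")

    tables = []
    for sample, grp in df.groupby(sample_col, sort=True):
        if af_col is not None:
            af = pd.to_numeric(grp[af_col], errors="coerce").to_numpy()
            bad = ~np.isfinite(af) | (af < 0) | (af > 1)
            if bad.any():
                logger.warning("%s: skipped %d unparsable rows in sample %s",
                               path, int(bad.sum()), sample)
            tables.append(MutationTable(sample=str(sample), allele_fraction=af[~bad]))
        else:
            alt = pd.to_numeric(grp[alt_col], errors="coerce").to_numpy()
            ref = pd.to_numeric(grp[ref_col], errors="coerce").to_numpy()
            tot = alt + ref
            bad = ~np.isfinite(tot) | (tot <= 0) | (alt < 0) | (ref < 0)
            if bad.any():
                logger.warning("%s: skipped %d unparsable rows in sample %s",
                               path, int(bad.sum()), sample)
            tables.append(MutationTable.from_counts(str(sample), alt[~bad], ref[~bad]))
    return tables


def _read_vcf(path: Path) -> list[MutationTable]:
    import pysam

    fractions: dict[str, list[float]] = {}
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if not samples:
            raise SchemaError(f"{path}: VCF has no sample columns")
        skipped = 0
        for rec in vf:
            for s in samples:
                ad = rec.samples[s].get("AD")
                if ad is None or len(ad) < 2 or ad[0] is None:
                    skipped += 1
                    continue
                total = sum(a for a in ad if a is not None)
                if total > 0:
                    fractions.setdefault(s, []).append(ad[1] / total)
        if skipped:
            logger.warning("%s: skipped %d genotypes without AD", path, skipped)
    if not fractions:
        raise SchemaError(f"{path}: no usable AD fields found")
    return [MutationTable(sample=s, allele_fraction=np.array(v)) for s, v in sorted(fractions.items())]


def read_mutation_table(path, fmt: str | None = None,
                        column_map: dict | None = None) -> list[MutationTable]:
    """Read a MAF-dialect TSV or a minimal VCF (AD genotype field) into one
    :class:`MutationTable` per sample."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "vcf" if path.suffix.lower() == ".vcf" else "maf"
    if fmt == "maf":
        return _read_maf(path, column_map)
    if fmt == "vcf":
        return _read_vcf(path)
    raise SchemaError(f"unknown format {fmt!r} (expected 'maf' or 'vcf')")


def load_config(path) -> dict:
    """Run configuration from YAML (.yaml/.yml) or JSON."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        import yaml

        cfg = yaml.safe_load(text)
    else:
        cfg = json.loads(text)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg


def read_sample_metadata(path) -> pd.DataFrame:
    """Sample-metadata TSV with columns sample, purity, ploidy[, msi]."""
    df = pd.read_csv(path, sep="\t")
    required = {"sample", "purity", "ploidy"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: metadata missing columns {sorted(missing)}")
    if "msi" not in df.columns:
        df["msi"] = "unknown"
    return df


def attach_metadata(tables: list[MutationTable], meta: pd.DataFrame) -> list[MutationTable]:
    """Fill purity/ploidy/MSI from a metadata table; samples without a
    metadata row are left untouched (they will be filtered later with a
    'missing-metadata' audit entry)."""
    by_sample = meta.set_index("sample")
    for t in tables:
        if t.sample in by_sample.index:
            row = by_sample.loc[t.sample]
            t.purity = float(row["purity"])
            t.ploidy = float(row["ploidy"])
            t.msi = str(row["msi"])
    return tables


def provenance(config: dict | None = None, seed: int | None = None) -> dict:
    from . import __version__

    cfg = config or {}
    digest = hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
    return {"version": __version__, "config_hash": digest, "seed": seed}


def _format_value(v):
    if isinstance(v, (float, np.floating)):
        return f"{v:.12g}"
    return v


def write_results(records, path, fmt: str = "csv",
                  config: dict | None = None, seed: int | None = None) -> None:
    """Write records (list of dicts or a DataFrame) with a provenance
    header; floats at 12 significant digits, deterministic column order."""
    path = Path(path)
    prov = provenance(config, seed)
    if isinstance(records, pd.DataFrame):
        records = records.to_dict("records")
    columns: list[str] = []
    for rec in records:
        for key in rec:
            if key not in columns:
                columns.append(key)
    if fmt == "json":
        payload = {"_provenance": prov, "records": [
            {k: _format_value(v) if isinstance(v, (float, np.floating)) else v
             for k, v in rec.items()} for rec in records]}
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        return
    if fmt != "csv":
        raise SchemaError(f"unknown output format {fmt!r}")
    lines = [f"# {k}={v}" for k, v in prov.items()]
    lines.append(",".join(columns))
    for rec in records:
        lines.append(",".join(str(_format_value(rec.get(c, ""))) for c in columns))
    path.write_text("\n".join(lines) + "\n")


def read_results(path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_results` CSV output."""
    return pd.read_csv(path, comment="#")
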
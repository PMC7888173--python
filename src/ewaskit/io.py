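"""Readers and writers for the on-disk formats used across the pipeline.

Conventions:

* beta matrix — TSV, probes in rows, first column ``probe_id``, one column
  per sample; missing betas written as ``NA``;
* sample sheet and probe manifest — CSV with headers matching the field
  names of the domain types;
* per-probe result tables — TSV with ``probe_id`` first, full-precision
  floats (round-trip safe);
* DMP exports — BED4 (0-based, half-open), one 1-bp interval per CpG.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    MANIFEST_COLUMNS,
    MethylationDataset,
    ProbeManifest,
    ValidationError,
)

logger = logging.getLogger(__name__)

NA_TOKEN = "NA"


def read_manifest(path) -> ProbeManifest:
    """Read a probe annotation manifest from CSV (``probe_id`` column required)."""
    t = pd.read_csv(path, dtype={"probe_id": str, "chrom": str, "gene": str})
    if "probe_id" not in t.columns:
        raise ValidationError(f"{path}: manifest must have a probe_id column")
    t = t.set_index("probe_id")
    t["gene"] = t["gene"].fillna("")
    for col in ("on_450k", "epic_only", "cross_reactive", "previously_reported"):
        t[col] = t[col].astype(bool)
    return ProbeManifest(t)


def write_manifest(manifest: ProbeManifest, path) -> Path:
    path = Path(path)
    out = manifest.table.reset_index()
    out.to_csv(path, index=False)
    return path


def read_sample_sheet(path) -> pd.DataFrame:
    t = pd.read_csv(
        path,
        dtype={
            "sample_id": str,
            "cohort": str,
            "chip_id": str,
            "chip_position": str,
            "family_id": str,
        },
    )
    if "sample_id" not in t.columns:
        raise ValidationError(f"{path}: sample sheet must have a sample_id column")
    t = t.set_index("sample_id")
    t["family_id"] = t["family_id"].fillna("")
    return t


def write_sample_sheet(samples: pd.DataFrame, path) -> Path:
    path = Path(path)
    samples.reset_index(names="sample_id").to_csv(path, index=False)
    return path


def read_beta_matrix(path) -> pd.DataFrame:
    """Read a probe x sample beta matrix from TSV; ``NA`` denotes missing."""
    t = pd.read_csv(
        path,
        sep="\t",
        na_values=[NA_TOKEN],
        keep_default_na=False,
        float_precision="round_trip",
    )
    first = t.columns[0]
    if first != "probe_id":
        raise ValidationError(f"{path}: first column must be probe_id, got {first!r}")
    t = t.set_index("probe_id")
    for col in t.columns:
        if not np.issubdtype(t[col].dtype, np.number):
            bad = t[col][pd.to_numeric(t[col], errors="coerce").isna() & t[col].notna()]
            if len(bad):
                raise ValidationError(
                    f"{path}: malformed numeric cell at probe {bad.index[0]!r}, "
                    f"sample {col!r}: {bad.iloc[0]!r}"
                )
            t[col] = pd.to_numeric(t[col], errors="coerce")
    if t.index.has_duplicates:
        dups = t.index[t.index.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"{path}: duplicate probe_id rows: {dups}")
    return t.astype(float)


def write_beta_matrix(betas: pd.DataFrame, path) -> Path:
    path = Path(path)
    betas.reset_index(names="probe_id").to_csv(
        path, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.17g"
    )
    return path


def read_dataset(beta_path, sheet_path, manifest_path) -> MethylationDataset:
    """Load and validate one cohort's dataset from its three files.

    Samples present in the matrix but absent from the sheet (or vice versa)
    raise an error naming them. Probes absent from the manifest are dropped
    with a logged count.
    """
    betas = read_beta_matrix(beta_path)
    samples = read_sample_sheet(sheet_path)
    manifest = read_manifest(manifest_path)

    unknown = betas.index.difference(manifest.probe_ids)
    if len(unknown):
        logger.warning(
            "dropping %d probes absent from manifest (e.g. %s)",
            len(unknown),
            list(unknown[:3]),
        )
        betas = betas.drop(index=unknown)

    matrix_ids = set(betas.columns)
    sheet_ids = set(samples.index)
    if matrix_ids != sheet_ids:
        raise ValidationError(
            "sample IDs do not match between matrix and sheet: "
            f"matrix-only={sorted(matrix_ids - sheet_ids)[:5]}, "
            f"sheet-only={sorted(sheet_ids - matrix_ids)[:5]}"
        )
    samples = samples.loc[list(betas.columns)]
    return MethylationDataset(betas=betas, samples=samples, manifest=manifest)


def write_results_table(records: pd.DataFrame, path) -> Path:
    """Write a per-probe result table as TSV with stable column order.

    Floats are written at full precision so that ``read_results_table``
    reproduces them bit-exactly. An empty record set is an error rather
    than an empty file.
    """
    if records is None or len(records) == 0:
        raise ValidationError("refusing to write an empty results table")
    path = Path(path)
    out = records.copy()
    if out.index.name is None:
        out.index.name = "probe_id"
    out.reset_index().to_csv(
        path, sep="\t", index=False, na_rep=NA_TOKEN, float_format="%.17g"
    )
    return path


def read_results_table(path) -> pd.DataFrame:
    t = pd.read_csv(
        path,
        sep="\t",
        na_values=[NA_TOKEN],
        keep_default_na=False,
        float_precision="round_trip",
    )
    return t.set_index(t.columns[0])


def export_bed(dmp_probes: Sequence[str], manifest: ProbeManifest, path) -> Path:
    """Export CpG positions as BED4: chrom, pos-1, pos, probe_id.

    The manifest is 1-based; BED is 0-based half-open, so each CpG becomes
    a 1-bp interval [pos-1, pos). Rows are sorted by chromosome then start.
    An empty probe list yields a valid empty BED file.
    """
    path = Path(path)
    probes = list(dmp_probes)
    missing = pd.Index(probes).difference(manifest.probe_ids)
    if len(missing):
        raise ValidationError(f"probes not in manifest: {list(missing[:5])}")
    rows = manifest.table.loc[probes, ["chrom", "pos"]].copy()
    rows["start"] = rows["pos"].astype(int) - 1
    rows["end"] = rows["pos"].astype(int)
    rows = rows.reset_index().sort_values(
        ["chrom", "start"], kind="mergesort"
    )
    with open(path, "w") as fh:
        for _, r in rows.iterrows():
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['probe_id']}\n")
    return path


def write_dataset(ds: MethylationDataset, outdir, prefix: str) -> dict:
    """Write one cohort's matrix + sheet under ``outdir``; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    beta_path = write_beta_matrix(ds.betas, outdir / f"{prefix}_betas.tsv")
    sheet_path = write_sample_sheet(ds.samples, outdir / f"{prefix}_samples.csv")
    return {"betas": beta_path, "samples": sheet_path}
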
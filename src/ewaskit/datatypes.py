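"""Core domain containers shared by every pipeline stage.

All tabular data live in pandas objects; the dataclasses here are thin,
validated wrappers that pin down index/column conventions so that each
stage can trust its inputs:

* :class:`ProbeManifest` — per-probe annotation, indexed by probe ID.
* :class:`MethylationDataset` — one cohort's beta matrix (probes x samples)
  plus its sample sheet and a reference to the shared manifest.
* :class:`SyntheticTruth` — the ground truth a simulated study was built
  from, used by parameter-recovery tests.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CGI_CLASSES = ("island", "shore", "shelf", "open_sea")
GENE_REGIONS = ("body", "upstream", "intergenic")
SMOKING_LEVELS = ("current", "former", "never")
SEX_LEVELS = ("F", "M")
ZYGOSITY_LEVELS = ("MZ", "DZ", "none")
CELL_TYPES = ("monocyte", "granulocyte", "nk", "cd8_naive")

MANIFEST_COLUMNS = (
    "chrom",
    "pos",
    "gene",
    "cgi_class",
    "chromhmm_class",
    "gene_region",
    "on_450k",
    "epic_only",
    "cross_reactive",
    "polymorphic_maf",
    "previously_reported",
)

SAMPLE_COLUMNS = (
    "cohort",
    "smoking_status",
    "sex",
    "age",
    "bmi",
    "monocyte",
    "granulocyte",
    "nk",
    "cd8_naive",
    "chip_id",
    "chip_position",
    "family_id",
    "zygosity",
)


class ValidationError(ValueError):
    """Raised when an input container violates a documented invariant."""


@dataclass
class ProbeManifest:
    """Per-probe annotation table, indexed by unique probe ID.

    Coordinates are 1-based base pairs (Illumina manifest convention).
    ``epic_only`` must be the complement of ``on_450k``; ``cross_reactive``
    and ``polymorphic_maf`` carry the QC flags that :func:`filter_probes`
    consumes, and ``previously_reported`` marks membership in a
    user-supplied prior smoking-DMP catalogue.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in MANIFEST_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        if t.index.has_duplicates:
            dups = t.index[t.index.duplicated()].unique().tolist()[:5]
            raise ValidationError(f"duplicate probe_id in manifest: {dups}")
        if (t["pos"] < 1).any():
            raise ValidationError("manifest positions must be >= 1 (1-based)")
        if not (t["epic_only"] == ~t["on_450k"].astype(bool)).all():
            raise ValidationError("epic_only must equal NOT on_450k for every probe")
        bad_cgi = set(t["cgi_class"].unique()) - set(CGI_CLASSES)
        if bad_cgi:
            raise ValidationError(f"unknown cgi_class values: {sorted(bad_cgi)}")
        maf = t["polymorphic_maf"].to_numpy(dtype=float)
        if ((maf < 0) | (maf > 1)).any():
            raise ValidationError("polymorphic_maf must lie in [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, probe_ids: Sequence[str]) -> "ProbeManifest":
        missing = pd.Index(probe_ids).difference(self.table.index)
        if len(missing):
            raise ValidationError(f"probes not in manifest: {list(missing[:5])}")
        return ProbeManifest(self.table.loc[list(probe_ids)])


def validate_sample_sheet(samples: pd.DataFrame) -> pd.DataFrame:
    """Check sample-sheet columns, categorical levels and cell-proportion bounds."""
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValidationError(f"sample sheet missing columns: {missing}")
    if samples.index.has_duplicates:
        raise ValidationError("duplicate sample_id in sample sheet")
    bad = set(samples["smoking_status"].unique()) - set(SMOKING_LEVELS)
    if bad:
        raise ValidationError(f"unknown smoking_status values: {sorted(bad)}")
    bad = set(samples["sex"].unique()) - set(SEX_LEVELS)
    if bad:
        raise ValidationError(f"unknown sex values: {sorted(bad)}")
    for ct in CELL_TYPES:
        v = samples[ct].to_numpy(dtype=float)
        if ((v < 0) | (v > 1)).any():
            raise ValidationError(f"cell proportion {ct} outside [0, 1]")
    return samples


@dataclass
class MethylationDataset:
    """One cohort: beta matrix (probes in rows, samples in columns) + sample sheet.

    Non-missing betas must lie in [0, 1]; matrix columns must match the
    sample sheet exactly; probe rows must be a subset of the manifest.
    """

    betas: pd.DataFrame
    samples: pd.DataFrame
    manifest: ProbeManifest
    name: str = ""

    def __post_init__(self) -> None:
        validate_sample_sheet(self.samples)
        if list(self.betas.columns) != list(self.samples.index):
            extra = set(self.betas.columns) - set(self.samples.index)
            lacking = set(self.samples.index) - set(self.betas.columns)
            raise ValidationError(
                "beta matrix columns do not match sample sheet: "
                f"unmatched in sheet={sorted(extra)[:5]}, "
                f"unmatched in matrix={sorted(lacking)[:5]}"
            )
        vals = self.betas.to_numpy(dtype=float)
        if vals.size:
            with np.errstate(invalid="ignore"):
                if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
                    raise ValidationError("beta values outside [0, 1] detected")
        if self.betas.index.has_duplicates:
            raise ValidationError("duplicate probe_id in beta matrix")
        unknown = self.betas.index.difference(self.manifest.probe_ids)
        if len(unknown):
            raise ValidationError(
                f"beta matrix probes absent from manifest: {list(unknown[:5])}"
            )
        if not self.name:
            cohorts = self.samples["cohort"].unique()
            self.name = str(cohorts[0]) if len(cohorts) == 1 else "combined"

    @property
    def n_probes(self) -> int:
        return self.betas.shape[0]

    @property
    def n_samples(self) -> int:
        return self.betas.shape[1]

    def subset_probes(self, probe_ids: Sequence[str]) -> "MethylationDataset":
        keep = self.betas.index.intersection(pd.Index(probe_ids))
        return MethylationDataset(
            self.betas.loc[keep], self.samples, self.manifest, self.name
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "MethylationDataset":
        ids = list(sample_ids)
        return MethylationDataset(
            self.betas[ids], self.samples.loc[ids], self.manifest, self.name
        )


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated study.

    ``spiked`` is indexed by probe_id with columns ``true_effect`` (beta-scale
    current-minus-never difference), ``persistence_fraction`` (0 = full
    reversal in former smokers, 1 = fully persistent) and ``heterogeneous``
    (cohort-specific effect signs/magnitudes were applied).
    """

    spiked: pd.DataFrame
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        pf = self.spiked["persistence_fraction"].to_numpy(dtype=float)
        if ((pf < 0) | (pf > 1)).any():
            raise ValidationError("persistence_fraction must lie in [0, 1]")

    @property
    def spiked_probes(self) -> pd.Index:
        return self.spiked.index

    def to_json(self, path) -> None:
        payload = {
            "seed": int(self.seed),
            "covariate_effects": {k: float(v) for k, v in self.covariate_effects.items()},
            "spiked": {
                pid: {
                    "true_effect": float(r["true_effect"]),
                    "persistence_fraction": float(r["persistence_fraction"]),
                    "heterogeneous": bool(r["heterogeneous"]),
                }
                for pid, r in self.spiked.iterrows()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        spiked = pd.DataFrame.from_dict(payload["spiked"], orient="index")
        if spiked.empty:
            spiked = pd.DataFrame(
                columns=["true_effect", "persistence_fraction", "heterogeneous"]
            )
        spiked.index.name = "probe_id"
        return cls(
            spiked=spiked,
            covariate_effects=payload.get("covariate_effects", {}),
            seed=payload.get("seed", 0),
        )
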
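"""Synthetic multi-cohort methylation studies with known ground truth.

The generator emulates the structure of a multi-cohort EPIC-array smoking
EWAS: several cohorts of a few hundred blood samples each, probe-level
beta values in [0, 1], current/former/never smoking labels, covariates
(sex, age, BMI, four blood cell-type proportions, chip and chip position),
one twin-style cohort with family-correlated samples, and a subset of
probes carrying spiked smoking effects.

Simulation happens on the logit (M-value) scale and is transformed back to
beta, which guarantees the [0, 1] range while keeping effects additive.
A spiked probe's target beta-scale difference between current and never
smokers is converted to a logit offset through a probit-style smearing
approximation so that the *expected* beta difference under the noise model
matches the recorded truth (naively offsetting the logit understates the
realized beta difference because averaging through the sigmoid shrinks
towards 0.5).

Defaults reproduce the discovery-study conditions: five cohorts of sizes
407/236/235/294/235 with per-cohort (current, former, never) counts
(23,147,237)/(23,138,75)/(53,64,118)/(125,82,87)/(45,64,126) — 269 current,
495 former, 643 never in total — one all-female family cohort, one cohort
enriched for smokers, beta-scale effect magnitudes in [0.02, 0.25] with
74% hypomethylating, and 36% of spiked probes falling in enhancers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .datatypes import (
    CELL_TYPES,
    MethylationDataset,
    ProbeManifest,
    SyntheticTruth,
    ValidationError,
)

logger = logging.getLogger(__name__)

# Marginal annotation proportions for generated manifests. CGI and gene-region
# proportions follow typical EPIC-array composition; the chromHMM enhancer
# share of 12% matches the background proportion among tested probes.
DEFAULT_CATEGORY_PROPS: dict[str, dict[str, float]] = {
    "cgi_class": {"island": 0.18, "shore": 0.20, "shelf": 0.10, "open_sea": 0.52},
    "chromhmm_class": {
        "enhancer": 0.12,
        "promoter": 0.15,
        "insulator": 0.05,
        "gene_body": 0.30,
        "other": 0.38,
    },
    "gene_region": {"body": 0.42, "upstream": 0.26, "intergenic": 0.32},
}

# Discovery-stage cohort structure: (current, former, never) per cohort.
DEFAULT_COHORT_NAMES = ("TWINS", "C1946", "C1958A", "C1958B", "C1970")
DEFAULT_SMOKING_COUNTS = (
    (23, 147, 237),
    (23, 138, 75),
    (53, 64, 118),
    (125, 82, 87),
    (45, 64, 126),
)
DEFAULT_FEMALE_FRACTIONS = (1.0, 0.60, 0.53, 0.51, 0.57)
DEFAULT_AGE_MEANS = (64.0, 63.0, 45.0, 45.0, 46.0)
DEFAULT_AGE_SDS = (8.0, 0.5, 0.5, 0.5, 0.5)

CHIP_SIZE = 8  # samples per chip, positions P1..P8


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the discovery-study conditions."""

    n_cohorts: int = 5
    cohort_names: Sequence[str] = DEFAULT_COHORT_NAMES
    cohort_sizes: Sequence[int] = tuple(sum(c) for c in DEFAULT_SMOKING_COUNTS)
    smoking_fractions: Sequence[tuple] = tuple(
        tuple(x / sum(c) for x in c) for c in DEFAULT_SMOKING_COUNTS
    )
    female_fractions: Sequence[float] = DEFAULT_FEMALE_FRACTIONS
    age_means: Sequence[float] = DEFAULT_AGE_MEANS
    age_sds: Sequence[float] = DEFAULT_AGE_SDS
    family_cohort: Sequence[bool] = (True, False, False, False, False)
    n_probes: int = 20_000
    n_spiked: int = 50
    effect_range: tuple = (0.02, 0.25)
    hypomethylated_fraction: float = 0.74
    persistence_fractions: Sequence[float] = (0.0, 0.25, 0.5, 1.0)
    n_heterogeneous: int = 0
    spike_enhancer_fraction: float = 0.36
    batch_sd: float = 0.10
    position_sd: float = 0.05
    noise_sd: float = 0.50
    family_icc: float = 0.40
    covariate_slope_sds: Mapping[str, float] = field(
        default_factory=lambda: {
            "sex": 0.05,
            "age": 0.005,
            "bmi": 0.01,
            "monocyte": 0.5,
            "granulocyte": 0.8,
            "nk": 0.5,
            "cd8_naive": 0.5,
        }
    )
    missing_rate: float = 0.0
    # Optional (lo, hi) interval for spiked-probe baseline means; None draws
    # them from the genome-wide bimodal mixture. Pinning the baseline sets
    # up controlled regimes (a hypomethylating CpG starting near 0.85
    # separates groups far better than one starting near 0.5).
    spike_baseline_range: tuple | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_cohorts != len(self.cohort_sizes):
            raise ValidationError("cohort_sizes length must equal n_cohorts")
        for name, seq in (
            ("smoking_fractions", self.smoking_fractions),
            ("female_fractions", self.female_fractions),
            ("age_means", self.age_means),
            ("family_cohort", self.family_cohort),
        ):
            if len(seq) != self.n_cohorts:
                raise ValidationError(f"{name} length must equal n_cohorts")
        for fr in self.smoking_fractions:
            if abs(sum(fr) - 1.0) > 1e-8:
                raise ValidationError("smoking fractions must sum to 1 per cohort")
        if self.n_spiked > self.n_probes:
            raise ValidationError("n_spiked cannot exceed n_probes")
        if self.n_heterogeneous > self.n_spiked:
            raise ValidationError("n_heterogeneous cannot exceed n_spiked")
        for sd in (self.batch_sd, self.position_sd, self.noise_sd):
            if sd < 0:
                raise ValidationError("scale parameters must be >= 0")
        if not 0 <= self.family_icc < 1:
            raise ValidationError("family_icc must lie in [0, 1)")
        for pf in self.persistence_fractions:
            if not 0 <= pf <= 1:
                raise ValidationError("persistence fractions must lie in [0, 1]")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must lie in [0, 1)")


def generate_manifest(
    n_probes: int,
    category_props: Mapping[str, Mapping[str, float]] | None = None,
    seed: int = 0,
    on_450k_fraction: float = 0.47,
    cross_reactive_rate: float = 0.04,
    polymorphic_rate: float = 0.05,
    previously_reported_rate: float = 0.05,
) -> ProbeManifest:
    """Draw a synthetic probe annotation manifest.

    Categorical annotations are sampled independently per family with the
    requested marginal proportions (each family's proportions must sum to 1).
    A fraction of probes is flagged cross-reactive; ``polymorphic_rate`` of
    probes receives a nonzero minor allele frequency drawn U(0, 0.25).
    ``previously_reported`` marks a random share of 450k probes, standing in
    for a prior smoking-DMP catalogue.
    """
    if n_probes <= 0:
        raise ValidationError("n_probes must be positive")
    props = {k: dict(v) for k, v in DEFAULT_CATEGORY_PROPS.items()}
    if category_props:
        for fam, p in category_props.items():
            if fam not in props:
                raise ValidationError(f"unknown annotation family: {fam}")
            merged = dict(props[fam])
            merged.update(p)
            props[fam] = merged
    for fam, p in props.items():
        total = sum(p.values())
        if abs(total - 1.0) > 1e-6:
            raise ValidationError(f"{fam} proportions sum to {total}, expected 1")

    rng = np.random.default_rng(seed)
    probe_ids = [f"cg{i:08d}" for i in range(n_probes)]
    chrom = rng.integers(1, 23, size=n_probes)
    pos = rng.integers(1, 240_000_000, size=n_probes)

    def draw(fam: str) -> np.ndarray:
        cats = list(props[fam])
        return rng.choice(cats, size=n_probes, p=[props[fam][c] for c in cats])

    cgi = draw("cgi_class")
    chromhmm = draw("chromhmm_class")
    gene_region = draw("gene_region")

    n_genes = max(1, n_probes // 8)
    gene_pool = np.array([f"GENE{i:06d}" for i in range(n_genes)])
    gene = np.where(
        gene_region == "intergenic", "", gene_pool[rng.integers(0, n_genes, n_probes)]
    )

    on_450k = rng.random(n_probes) < on_450k_fraction
    cross_reactive = rng.random(n_probes) < cross_reactive_rate
    maf = np.where(
        rng.random(n_probes) < polymorphic_rate, rng.uniform(0, 0.25, n_probes), 0.0
    )
    previously_reported = on_450k & (rng.random(n_probes) < previously_reported_rate)

    table = pd.DataFrame(
        {
            "chrom": [f"chr{c}" for c in chrom],
            "pos": pos,
            "gene": gene,
            "cgi_class": cgi,
            "chromhmm_class": chromhmm,
            "gene_region": gene_region,
            "on_450k": on_450k,
            "epic_only": ~on_450k,
            "cross_reactive": cross_reactive,
            "polymorphic_maf": maf,
            "previously_reported": previously_reported,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    return ProbeManifest(table)


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(40)


def _expected_beta(logit_mean, sd):
    """E[sigmoid(N(mu, sd^2))] by Gauss-Hermite quadrature (exact to ~1e-10)."""
    mu = np.atleast_1d(np.asarray(logit_mean, dtype=float))[:, None]
    s = np.atleast_1d(np.asarray(sd, dtype=float))[:, None]
    vals = expit(mu + np.sqrt(2.0) * s * _GH_NODES[None, :])
    return (vals @ _GH_WEIGHTS) / np.sqrt(np.pi)


def _offset_for_target_vec(
    base_logit: np.ndarray, target: np.ndarray, sd: np.ndarray
) -> np.ndarray:
    """Logit offset so the *expected* beta-scale shift under N(0, sd^2)
    perturbations equals ``target`` (solved probe-wise by bisection)."""
    base_logit = np.atleast_1d(base_logit)
    target = np.atleast_1d(target)
    sd = np.atleast_1d(sd)
    e0 = _expected_beta(base_logit, sd)
    goal = np.clip(e0 + target, 1e-4, 1 - 1e-4)
    out = np.empty(len(base_logit))
    for i in range(len(base_logit)):
        f = lambda off: float(
            _expected_beta(base_logit[i] + off, sd[i])[0] - goal[i]
        )
        out[i] = brentq(f, -25.0, 25.0, xtol=1e-10)
    return out


def _draw_baselines(rng: np.random.Generator, n: int) -> np.ndarray:
    """Bimodal baseline methylation means, typical of a blood methylome."""
    comp = rng.choice(3, size=n, p=[0.35, 0.35, 0.30])
    m = np.empty(n)
    m[comp == 0] = rng.beta(2, 10, size=(comp == 0).sum())
    m[comp == 1] = rng.beta(10, 2, size=(comp == 1).sum())
    m[comp == 2] = rng.beta(4, 4, size=(comp == 2).sum())
    return np.clip(m, 0.01, 0.99)


def _build_sample_sheet(
    config: SimulationConfig, ci: int, rng: np.random.Generator
) -> pd.DataFrame:
    name = config.cohort_names[ci]
    n = config.cohort_sizes[ci]
    fr = config.smoking_fractions[ci]
    counts = [int(round(f * n)) for f in fr]
    counts[2] = n - counts[0] - counts[1]
    status = np.repeat(["current", "former", "never"], counts)
    rng.shuffle(status)

    sex = np.where(rng.random(n) < config.female_fractions[ci], "F", "M")
    age = rng.normal(config.age_means[ci], config.age_sds[ci], size=n)
    bmi = np.clip(rng.normal(27.0, 4.5, size=n), 16, 50)
    # Dirichlet over (mono, gran, nk, cd8-naive, remainder); remainder dropped.
    cells = rng.dirichlet([8.0, 55.0, 4.0, 4.0, 29.0], size=n)[:, :4]

    chip_idx = np.arange(n) // CHIP_SIZE
    chip_id = np.array([f"{name}_chip{c:03d}" for c in chip_idx])
    chip_position = np.array([f"P{(i % CHIP_SIZE) + 1}" for i in range(n)])

    if config.family_cohort[ci]:
        n_fam = (n + 1) // 2
        fam = np.repeat([f"{name}_fam{i:04d}" for i in range(n_fam)], 2)[:n]
        zyg_per_fam = rng.choice(["MZ", "DZ"], size=n_fam)
        zyg = np.repeat(zyg_per_fam, 2)[:n]
    else:
        fam = np.array([""] * n)
        zyg = np.array(["none"] * n)

    sheet = pd.DataFrame(
        {
            "cohort": name,
            "smoking_status": status,
            "sex": sex,
            "age": age,
            "bmi": bmi,
            "monocyte": cells[:, 0],
            "granulocyte": cells[:, 1],
            "nk": cells[:, 2],
            "cd8_naive": cells[:, 3],
            "chip_id": chip_id,
            "chip_position": chip_position,
            "family_id": fam,
            "zygosity": zyg,
        },
        index=pd.Index([f"{name}_s{i:04d}" for i in range(n)], name="sample_id"),
    )
    return sheet


def _select_spiked(
    config: SimulationConfig, manifest: ProbeManifest, rng: np.random.Generator
) -> pd.Index:
    """Pick spike targets among QC-clean probes, with the enhancer share enriched."""
    t = manifest.table.iloc[: config.n_probes]
    clean = t[(~t["cross_reactive"]) & (t["polymorphic_maf"] <= 0.05)]
    if len(clean) < config.n_spiked:
        raise ValidationError("not enough QC-clean probes to spike")
    n_enh = int(round(config.spike_enhancer_fraction * config.n_spiked))
    enh_pool = clean.index[clean["chromhmm_class"] == "enhancer"]
    oth_pool = clean.index[clean["chromhmm_class"] != "enhancer"]
    n_enh = min(n_enh, len(enh_pool))
    chosen = list(rng.choice(enh_pool, size=n_enh, replace=False)) + list(
        rng.choice(oth_pool, size=config.n_spiked - n_enh, replace=False)
    )
    return pd.Index(chosen, name="probe_id")


def _make_truth(
    config: SimulationConfig, manifest: ProbeManifest, rng: np.random.Generator
) -> SyntheticTruth:
    spiked_ids = _select_spiked(config, manifest, rng)
    lo, hi = config.effect_range
    mag = np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_spiked))
    sign = np.where(rng.random(config.n_spiked) < config.hypomethylated_fraction, -1, 1)
    pf_pool = np.asarray(config.persistence_fractions, dtype=float)
    pf = pf_pool[rng.integers(0, len(pf_pool), size=config.n_spiked)]
    het = np.zeros(config.n_spiked, dtype=bool)
    if config.n_heterogeneous:
        het[rng.choice(config.n_spiked, size=config.n_heterogeneous, replace=False)] = True
    spiked = pd.DataFrame(
        {
            "true_effect": sign * mag,
            "persistence_fraction": pf,
            "heterogeneous": het,
        },
        index=spiked_ids,
    )
    return SyntheticTruth(
        spiked=spiked,
        covariate_effects=dict(config.covariate_slope_sds),
        seed=config.seed,
    )


def generate_cohorts(
    config: SimulationConfig,
    manifest: ProbeManifest,
    truth: SyntheticTruth | None = None,
) -> tuple[list[MethylationDataset], SyntheticTruth]:
    """Simulate one multi-cohort study.

    Passing an existing ``truth`` reuses its spiked probes and effects —
    the mechanism for generating replication cohorts that share the
    discovery ground truth while drawing fresh samples and noise.
    Identical ``config`` + seed yields bit-identical datasets.
    """
    config.validate()
    if len(manifest) < config.n_probes:
        raise ValidationError(
            f"manifest has {len(manifest)} probes, config wants {config.n_probes}"
        )
    rng = np.random.default_rng(config.seed)
    probes = manifest.probe_ids[: config.n_probes]

    if truth is None:
        truth = _make_truth(config, manifest, rng)
    spiked = truth.spiked
    spiked_mask = probes.isin(spiked.index)

    # Per-probe baselines; spiked probes must leave room for their effect.
    base = _draw_baselines(rng, config.n_probes)
    if len(spiked):
        idx = np.flatnonzero(spiked_mask)
        eff = spiked["true_effect"].reindex(probes[idx]).to_numpy()
        rng_base = config.spike_baseline_range
        if rng_base is not None:
            base[idx] = rng.uniform(rng_base[0], rng_base[1], size=len(idx))
        n_resampled = 0
        for j, e in zip(idx, eff):
            tries = 0
            while not (0.02 < base[j] + e < 0.98) or not (0.02 < base[j] < 0.98):
                base[j] = (
                    float(rng.uniform(*rng_base))
                    if rng_base is not None
                    else float(rng.beta(4, 4))
                )
                tries += 1
                if tries > 1000:
                    raise ValidationError(f"cannot place effect {e} at any baseline")
            n_resampled += tries > 0
        if n_resampled:
            logger.info("resampled baselines for %d spiked probes", n_resampled)
    base_logit = logit(base)

    # Per-probe covariate slopes on the logit scale.
    sds = config.covariate_slope_sds
    slopes = {
        k: rng.normal(0.0, sds.get(k, 0.0), size=config.n_probes)
        for k in ("sex", "age", "bmi", *CELL_TYPES)
    }

    # Effective non-smoking logit variance for the smearing correction,
    # averaged over cohorts (age variance differs across cohorts).
    age_var = float(np.mean(np.square(config.age_sds)))
    cov_var = (
        slopes["sex"] ** 2 * 0.25
        + slopes["age"] ** 2 * age_var
        + slopes["bmi"] ** 2 * 4.5**2
        + sum(slopes[ct] ** 2 * 0.003 for ct in CELL_TYPES)
    )
    total_var = config.noise_sd**2 + config.batch_sd**2 + config.position_sd**2 + cov_var
    sd_eff = np.sqrt(total_var)  # per-probe effective perturbation SD

    # Centering covariates keeps the baseline interpretable as the
    # never-smoker mean for an average sample.
    age_center = float(np.mean(config.age_means))
    cell_center = np.array([8, 55, 4, 4]) / 100.0

    datasets: list[MethylationDataset] = []
    for ci in range(config.n_cohorts):
        sheet = _build_sample_sheet(config, ci, rng)
        n = len(sheet)
        status = sheet["smoking_status"].to_numpy()

        # Smoking offsets per (probe, sample) built from per-probe targets.
        delta = np.zeros(config.n_probes)
        delta[spiked_mask] = spiked["true_effect"].reindex(probes[spiked_mask]).to_numpy()
        pf = np.zeros(config.n_probes)
        pf[spiked_mask] = (
            spiked["persistence_fraction"].reindex(probes[spiked_mask]).to_numpy()
        )
        het = np.zeros(config.n_probes, dtype=bool)
        het[spiked_mask] = spiked["heterogeneous"].reindex(probes[spiked_mask]).to_numpy()
        # Heterogeneous probes: cohort-specific sign and magnitude multiplier.
        if het.any():
            mult = rng.choice([-1.0, 1.0], size=het.sum()) * rng.uniform(
                0.3, 1.5, size=het.sum()
            )
            delta_c = delta.copy()
            delta_c[het] = np.clip(delta[het] * mult, -0.3, 0.3)
        else:
            delta_c = delta

        off_current = np.zeros(config.n_probes)
        off_former = np.zeros(config.n_probes)
        sp = np.flatnonzero(delta_c != 0)
        if len(sp):
            off_current[sp] = _offset_for_target_vec(
                base_logit[sp], delta_c[sp], sd_eff[sp]
            )
        spf = np.flatnonzero((delta_c * pf) != 0)
        if len(spf):
            off_former[spf] = _offset_for_target_vec(
                base_logit[spf], delta_c[spf] * pf[spf], sd_eff[spf]
            )

        smoke_off = np.zeros((config.n_probes, n))
        smoke_off[:, status == "current"] = off_current[:, None]
        smoke_off[:, status == "former"] = off_former[:, None]

        # Covariate contributions.
        sexv = (sheet["sex"] == "M").to_numpy(dtype=float)
        agev = sheet["age"].to_numpy() - age_center
        bmiv = sheet["bmi"].to_numpy() - 27.0
        cov = (
            np.outer(slopes["sex"], sexv)
            + np.outer(slopes["age"], agev)
            + np.outer(slopes["bmi"], bmiv)
        )
        for k, ct in enumerate(CELL_TYPES):
            cov += np.outer(slopes[ct], sheet[ct].to_numpy() - cell_center[k])

        # Chip and position effects (per probe x level).
        chips, chip_code = np.unique(sheet["chip_id"], return_inverse=True)
        chip_eff = rng.normal(0.0, config.batch_sd, size=(config.n_probes, len(chips)))
        positions, pos_code = np.unique(sheet["chip_position"], return_inverse=True)
        pos_eff = rng.normal(0.0, config.position_sd, size=(config.n_probes, len(positions)))
        batch = chip_eff[:, chip_code] + pos_eff[:, pos_code]

        # Residual noise, with a family-shared component in family cohorts.
        if config.family_cohort[ci] and config.family_icc > 0:
            sd_g = config.noise_sd * np.sqrt(config.family_icc)
            sd_e = config.noise_sd * np.sqrt(1.0 - config.family_icc)
            fams, fam_code = np.unique(sheet["family_id"], return_inverse=True)
            fam_eff = rng.normal(0.0, sd_g, size=(config.n_probes, len(fams)))
            noise = fam_eff[:, fam_code] + rng.normal(
                0.0, sd_e, size=(config.n_probes, n)
            )
        else:
            noise = rng.normal(0.0, config.noise_sd, size=(config.n_probes, n))

        logits = base_logit[:, None] + smoke_off + cov + batch + noise
        betas = expit(logits)
        if config.missing_rate > 0:
            mask = rng.random(betas.shape) < config.missing_rate
            betas = np.where(mask, np.nan, betas)

        bdf = pd.DataFrame(betas, index=probes.copy(), columns=sheet.index)
        datasets.append(
            MethylationDataset(
                betas=bdf,
                samples=sheet,
                manifest=manifest,
                name=config.cohort_names[ci],
            )
        )
    return datasets, truth


def null_config(
    n_probes: int,
    seed: int,
    n_cohorts: int = 5,
    cohort_size: int = 1000,
) -> SimulationConfig:
    """Balanced no-signal configuration for calibration checks.

    Five equal cohorts with (0.3, 0.2, 0.5) current/former/never fractions
    and no spiked probes or family structure: the regime for verifying
    type-I error, genomic inflation and heterogeneity-rate calibration.
    Large balanced cohorts keep per-cohort residual degrees of freedom
    high, so pooled z-statistics are close to normal; the unbalanced
    default study (one cohort has only 23 current smokers against ~45
    design columns) shows the mild small-sample inflation real studies
    report, which is expected behaviour rather than a calibration check.
    """
    return SimulationConfig(
        n_cohorts=n_cohorts,
        cohort_names=tuple(f"NULL{i}" for i in range(n_cohorts)),
        cohort_sizes=(cohort_size,) * n_cohorts,
        smoking_fractions=((0.3, 0.2, 0.5),) * n_cohorts,
        female_fractions=(0.5,) * n_cohorts,
        age_means=(50.0,) * n_cohorts,
        age_sds=(5.0,) * n_cohorts,
        family_cohort=(False,) * n_cohorts,
        n_probes=n_probes,
        n_spiked=0,
        seed=seed,
    )


def replication_config(
    seed: int,
    n_probes: int,
    scale: float = 1.0,
) -> SimulationConfig:
    """Two-replication-cohort configuration mirroring the trans-ethnic stage.

    Cohort A: 2325 samples (893 current / 748 former / 684 never); cohort B:
    1100 samples (179 current / 255 former / 666 never, sibship-correlated).
    ``scale`` shrinks sample sizes proportionally for desk-scale runs.
    """
    counts = [(893, 748, 684), (179, 255, 666)]
    sizes = [max(30, int(round(sum(c) * scale))) for c in counts]
    fracs = [tuple(x / sum(c) for x in c) for c in counts]
    return SimulationConfig(
        n_cohorts=2,
        cohort_names=("REP_A", "REP_B"),
        cohort_sizes=sizes,
        smoking_fractions=fracs,
        female_fractions=(0.59, 0.71),
        age_means=(55.0, 56.0),
        age_sds=(6.0, 10.0),
        family_cohort=(False, True),
        n_probes=n_probes,
        n_spiked=0,
        seed=seed,
    )
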
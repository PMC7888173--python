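"""Panel-based methylation classifiers of smoking status.

A panel is a small set of CpGs; the classifier is a logistic regression
on the *unadjusted* beta values at those CpGs plus covariates (age, sex,
cell-type proportions, BMI, chip and chip position). Evaluation follows
the repeated random-split protocol: 20 random 60/40 train/test splits of
the combined dataset, AUC on each test set, and the average AUC reported
per panel. The "ever smoked" contrast merges current and former smokers
into the positive class.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .datatypes import CELL_TYPES, MethylationDataset, ValidationError

logger = logging.getLogger(__name__)

PANEL_CONTRASTS = ("current_vs_never", "ever_vs_never")


@dataclass
class PanelSpec:
    name: str
    probe_ids: list
    contrast: str = "current_vs_never"

    def __post_init__(self) -> None:
        if not self.probe_ids:
            raise ValidationError(f"panel {self.name!r} has no probes")
        if self.contrast not in PANEL_CONTRASTS:
            raise ValidationError(f"unknown panel contrast {self.contrast!r}")


@dataclass
class ClassifierReport:
    panel: PanelSpec
    aucs: list
    seed: int
    n_splits: int = 20
    train_fraction: float = 0.6
    flags: list = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.aucs))

    def to_dict(self) -> dict:
        return {
            "panel": self.panel.name,
            "contrast": self.panel.contrast,
            "probes": list(self.panel.probe_ids),
            "mean_auc": self.mean_auc,
            "aucs": [float(a) for a in self.aucs],
            "n_splits": self.n_splits,
            "train_fraction": self.train_fraction,
            "seed": self.seed,
        }


def fit_logistic(train_features: np.ndarray, train_labels: np.ndarray):
    """Unpenalised binomial logistic fit; returns (coefficients, converged).

    Coefficients are ordered (intercept, features...). Complete separation
    is reported as non-convergence; the final-iterate coefficients are
    still returned and usable for scoring.
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValidationError("training labels must contain both classes")
    if X.shape[0] <= X.shape[1]:
        raise ValidationError("need n > number of features")
    if X.shape[1] == 0:
        prev = float(y.mean())
        return np.array([np.log(prev / (1 - prev))]), True
    model = LogisticRegression(penalty=None, solver="lbfgs", max_iter=200)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            model.fit(X, y)
        except ConvergenceWarning:
            converged = False
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X, y)
    return np.concatenate([model.intercept_, model.coef_[0]]), converged


def predict_proba(coef: np.ndarray, features: np.ndarray) -> np.ndarray:
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    eta = coef[0] + X @ coef[1:]
    return expit(eta)


def auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney probability, ties count 1/2)."""
    y = np.asarray(labels)
    if len(set(np.unique(y))) < 2:
        raise ValidationError("both classes must be present")
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def _feature_frame(ds: MethylationDataset, panel: PanelSpec) -> pd.DataFrame:
    missing = [p for p in panel.probe_ids if p not in ds.betas.index]
    if missing:
        raise ValidationError(f"panel probes absent from dataset: {missing}")
    feats = ds.betas.loc[list(panel.probe_ids)].T
    feats.columns = [f"beta:{p}" for p in panel.probe_ids]
    cov = ds.samples[["age", "bmi", *CELL_TYPES]].astype(float)
    sex = pd.get_dummies(ds.samples["sex"], prefix="sex", drop_first=True, dtype=float)
    chip = pd.get_dummies(
        ds.samples[["chip_id", "chip_position"]], drop_first=True, dtype=float
    )
    return pd.concat([feats, cov, sex, chip], axis=1)


def _labels(ds: MethylationDataset, contrast: str) -> pd.Series:
    status = ds.samples["smoking_status"]
    if contrast == "current_vs_never":
        keep = status.isin(["current", "never"])
        y = (status[keep] == "current").astype(int)
    else:  # ever_vs_never
        keep = status.isin(["current", "former", "never"])
        y = (status[keep] != "never").astype(int)
    return y


def evaluate_panels(
    ds: MethylationDataset,
    panels: list[PanelSpec],
    n_splits: int = 20,
    train_fraction: float = 0.6,
    seed: int = 0,
) -> list[ClassifierReport]:
    """Repeated random-split evaluation of each panel on a combined dataset.

    Splits are uniform over samples (no stratification); a split leaving
    either class absent from train or test is redrawn with a logged note.
    Per-split seeds derive from the master seed as seed + split index, so
    results are fully reproducible.
    """
    reports = []
    for panel in panels:
        feats_all = _feature_frame(ds, panel)
        y_all = _labels(ds, panel.contrast)
        feats = feats_all.loc[y_all.index]
        # Drop dummy columns that became constant after contrast subsetting.
        keep = feats.columns[(feats.nunique() > 1).to_numpy()]
        feats = feats[keep]
        X = feats.to_numpy(dtype=float)
        y = y_all.to_numpy()
        n = len(y)
        n_train = int(round(train_fraction * n))
        aucs, flags = [], []
        for split in range(n_splits):
            rng = np.random.default_rng(seed + split)
            for attempt in range(100):
                perm = rng.permutation(n)
                tr, te = perm[:n_train], perm[n_train:]
                if len(np.unique(y[tr])) == 2 and len(np.unique(y[te])) == 2:
                    break
                logger.info("split %d redrawn (single-class partition)", split)
            else:
                raise ValidationError("cannot draw a split with both classes")
            coef, converged = fit_logistic(X[tr], y[tr])
            if not converged:
                flags.append(f"split{split}:nonconverged")
            scores = predict_proba(coef, X[te])
            aucs.append(auc(scores, y[te]))
        reports.append(
            ClassifierReport(
                panel=panel,
                aucs=aucs,
                seed=seed,
                n_splits=n_splits,
                train_fraction=train_fraction,
                flags=flags,
            )
        )
    return reports


def combine_datasets(
    datasets: list[MethylationDataset], exclude_cohorts: list | None = None
) -> MethylationDataset:
    """Column-concatenate cohorts into one dataset (shared probes only).

    ``exclude_cohorts`` drops whole cohorts first — e.g. a subset selected
    for phenotypic extremes that would bias classifier evaluation.
    """
    keep = [
        d for d in datasets if not exclude_cohorts or d.name not in exclude_cohorts
    ]
    if not keep:
        raise ValidationError("no cohorts left after exclusion")
    probes = keep[0].betas.index
    for d in keep[1:]:
        probes = probes.intersection(d.betas.index)
    betas = pd.concat([d.betas.loc[probes] for d in keep], axis=1)
    samples = pd.concat([d.samples for d in keep], axis=0)
    return MethylationDataset(
        betas=betas, samples=samples, manifest=keep[0].manifest, name="combined"
    )
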
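"""Per-cohort, per-probe association of methylation with smoking status.

Each cohort's EWAS regresses per-probe methylation (rank-inverse-normal
transformed for the primary scale, untransformed for effect sizes) on a
binary smoking contrast plus covariates: sex (dropped in single-sex
cohorts), four blood cell-type proportions, BMI, optionally age, and chip
and chip-position indicator columns. Cohorts with related samples (twin
pairs, sibships) use a random-intercept model for family instead of OLS.

The OLS path is a closed-form fit vectorised across probes sharing a
design. The mixed-model path is a profiled-REML random-intercept fitter:
for a variance ratio lam = sigma_g^2 / sigma_e^2 the model whitens to OLS
by shrinking each group mean by 1 - (1 + k*lam)^(-1/2), so REML reduces to
a 1-D optimisation over lam. P-values for the smoking coefficient use a
Satterthwaite-type degrees-of-freedom approximation from the numerical
REML information, with a normal fallback flagged per probe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_solve

from .datatypes import CELL_TYPES, MethylationDataset, ValidationError
from .preprocess import transform_matrix

logger = logging.getLogger(__name__)

CONTRASTS = ("current_vs_never", "former_vs_never")


@dataclass
class DesignMatrix:
    """Fixed-effects design for one cohort and contrast."""

    X: np.ndarray
    columns: list
    smoking_idx: int
    sample_ids: pd.Index
    groups: np.ndarray | None = None  # family codes for the mixed path
    warnings: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class CohortResult:
    """Per-probe association results for one cohort and contrast.

    ``table`` is indexed by probe_id with columns estimate, se, p, n
    (normalized scale) and estimate_raw, se_raw (beta scale), plus
    ``lmm_fallback`` on mixed-model runs.
    """

    cohort: str
    contrast: str
    table: pd.DataFrame


def build_design(
    samples: pd.DataFrame,
    contrast: str,
    include_age: bool = False,
) -> DesignMatrix:
    """Encode the covariate design for a two-group smoking contrast.

    Samples are subset to the contrast's two levels (never = 0). Sex enters
    as an indicator unless the cohort is single-sex; chip and position are
    reference-coded categoricals; zero-variance covariates are dropped with
    a warning. A constant smoking indicator is an error.
    """
    if contrast not in CONTRASTS:
        raise ValidationError(f"unknown contrast {contrast!r}")
    exposed = contrast.split("_vs_")[0]
    sub = samples[samples["smoking_status"].isin([exposed, "never"])]
    smoking = (sub["smoking_status"] == exposed).astype(float)
    if smoking.nunique() < 2:
        raise ValidationError(
            f"contrast {contrast}: smoking indicator is constant "
            f"(levels present: {sorted(sub['smoking_status'].unique())})"
        )

    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(sub))}
    cols["smoking"] = smoking.to_numpy()
    warnings: list[str] = []

    if sub["sex"].nunique() > 1:
        cols["sex_M"] = (sub["sex"] == "M").to_numpy(dtype=float)
    else:
        warnings.append("single-sex cohort: sex covariate dropped")

    for ct in CELL_TYPES:
        cols[ct] = sub[ct].to_numpy(dtype=float)
    cols["bmi"] = sub["bmi"].to_numpy(dtype=float)
    if include_age:
        cols["age"] = sub["age"].to_numpy(dtype=float)

    for cat in ("chip_id", "chip_position"):
        levels = sorted(sub[cat].unique())
        for lev in levels[1:]:  # reference-level drop
            cols[f"{cat}={lev}"] = (sub[cat] == lev).to_numpy(dtype=float)

    # Drop zero-variance covariates (never the smoking column).
    drop = [
        k
        for k, v in cols.items()
        if k not in ("intercept", "smoking") and np.ptp(v) == 0
    ]
    for k in drop:
        warnings.append(f"zero-variance covariate dropped: {k}")
        del cols[k]

    X = np.column_stack(list(cols.values()))
    names = list(cols)
    groups = None
    fam = sub["family_id"].astype(str)
    if (fam != "").any():
        groups = pd.factorize(fam.where(fam != "", sub.index.astype(str)))[0]
    return DesignMatrix(
        X=X,
        columns=names,
        smoking_idx=names.index("smoking"),
        sample_ids=sub.index,
        groups=groups,
        warnings=warnings,
    )


def _drop_collinear(X: np.ndarray, columns: list, smoking_idx: int):
    """Remove linearly dependent columns via pivoted QR; error if smoking goes."""
    n, p = X.shape
    if np.linalg.matrix_rank(X) == p:
        return X, columns, smoking_idx
    # Greedy: keep columns in order while they increase rank.
    keep: list[int] = []
    cur = np.empty((n, 0))
    for j in range(p):
        cand = np.column_stack([cur, X[:, j]])
        if np.linalg.matrix_rank(cand) > cur.shape[1]:
            keep.append(j)
            cur = cand
    if smoking_idx not in keep:
        raise ValidationError("smoking column is collinear with covariates")
    dropped = [columns[j] for j in range(p) if j not in keep]
    logger.warning("dropping collinear design columns: %s", dropped)
    new_cols = [columns[j] for j in keep]
    return X[:, keep], new_cols, new_cols.index("smoking")


def fit_probe_ols(y, design: DesignMatrix):
    """OLS fit of one probe; returns (estimate, se, p, n) for smoking.

    Missing responses are dropped; the t distribution with residual df
    gives the p-value.
    """
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(y)
    X, cols, j = design.X[ok], design.columns, design.smoking_idx
    y = y[ok]
    if len(np.unique(y)) < 2:
        raise ValidationError("response has < 2 distinct values")
    if len(np.unique(X[:, j])) < 2:
        raise ValidationError("smoking indicator constant after dropping missing")
    X, cols, j = _drop_collinear(X, cols, j)
    n, p = X.shape
    if n <= p:
        raise ValidationError(f"n={n} <= design columns p={p}")
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    beta = xtx_inv @ (X.T @ y)
    resid = y - X @ beta
    df = n - p
    sigma2 = float(resid @ resid) / df
    se = float(np.sqrt(sigma2 * xtx_inv[j, j]))
    est = float(beta[j])
    if se == 0:
        pval = 0.0 if est != 0 else 1.0
    else:
        pval = float(2 * stats.t.sf(abs(est) / se, df))
    return est, se, max(pval, np.nextafter(0, 1)), n


def _ols_many(Y: np.ndarray, design: DesignMatrix):
    """Vectorised OLS across probes (rows of Y) for a complete-data design."""
    X, cols, j = _drop_collinear(design.X, design.columns, design.smoking_idx)
    n, p = X.shape
    if n <= p:
        raise ValidationError(f"n={n} <= design columns p={p}")
    xtx_inv = np.linalg.inv(X.T @ X)
    betas = xtx_inv @ (X.T @ Y.T)  # p x m
    resid = Y.T - X @ betas
    df = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / df
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[j, j], 0.0))
    est = betas[j]
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, est / np.where(se > 0, se, 1.0), np.inf)
    pval = 2 * stats.t.sf(np.abs(tval), df)
    pval = np.clip(pval, np.nextafter(0, 1), 1.0)
    return est, se, pval, np.full(Y.shape[0], n)


class RandomInterceptREML:
    """Profiled-REML solver for a single random intercept on a fixed design.

    The covariance V = sigma_e^2 (I + lam Z Z') whitens group-wise: each
    group's mean component shrinks by gamma_k = 1 - (1 + k lam)^(-1/2)
    where k is the group size. Expanding the whitened cross-products shows
    that X'V^-1X = X'X - sum_k c_k(lam) A_k with c_k = 2 gamma_k -
    gamma_k^2 and A_k the per-size aggregates of group-sum outer products
    divided by k. A_k depends only on the design, so it is precomputed
    once and every REML evaluation costs O(p^3) regardless of sample
    size. All probes sharing the design reuse the same solver.
    """

    def __init__(self, X: np.ndarray, columns: list, smoking_idx: int, groups):
        X, columns, smoking_idx = _drop_collinear(X, columns, smoking_idx)
        self.X = X
        self.columns = columns
        self.j = smoking_idx
        self.n, self.p = X.shape
        self.code = pd.factorize(np.asarray(groups))[0]
        self.n_groups = int(self.code.max()) + 1
        if self.n_groups < 2:
            raise ValidationError("mixed model requires >= 2 groups")
        if self.n <= self.p:
            raise ValidationError(f"n={self.n} <= design columns p={self.p}")
        sizes = np.bincount(self.code, minlength=self.n_groups)
        self.sizes = sizes
        self.xtx = X.T @ X
        # Group sums of X, partitioned by group size.
        gsum_x = np.zeros((self.n_groups, self.p))
        np.add.at(gsum_x, self.code, X)
        self.ks = np.unique(sizes)
        self.groups_of_k = {int(k): np.flatnonzero(sizes == k) for k in self.ks}
        self.n_k = {int(k): len(v) for k, v in self.groups_of_k.items()}
        self.gsum_x_k = {int(k): gsum_x[v] for k, v in self.groups_of_k.items()}
        self.A_k = {
            k: (g.T @ g) / k for k, g in self.gsum_x_k.items()
        }
        self.all_singletons = bool((sizes <= 1).all())

    # -- per-probe sufficient statistics --------------------------------
    def ystats(self, y: np.ndarray) -> dict:
        xty = self.X.T @ y
        yty = float(y @ y)
        gsum_y = np.bincount(self.code, weights=y, minlength=self.n_groups)
        b_k = {
            k: (self.gsum_x_k[k].T @ gsum_y[idx]) / k
            for k, idx in self.groups_of_k.items()
        }
        d_k = {
            k: float(np.sum(gsum_y[idx] ** 2)) / k
            for k, idx in self.groups_of_k.items()
        }
        return {"xty": xty, "yty": yty, "b_k": b_k, "d_k": d_k}

    # -- REML pieces at a fixed variance ratio --------------------------
    def _pieces(self, lam: float, ys: dict):
        gamma = {k: 1.0 - 1.0 / np.sqrt(1.0 + k * lam) for k in self.n_k}
        c = {k: 2.0 * g - g * g for k, g in gamma.items()}
        M = self.xtx - sum(c[k] * self.A_k[k] for k in self.n_k)
        L = np.linalg.cholesky(M)
        logdet_xtx = 2.0 * float(np.sum(np.log(np.diag(L))))
        xty = ys["xty"] - sum(c[k] * ys["b_k"][k] for k in self.n_k)
        yty = ys["yty"] - sum(c[k] * ys["d_k"][k] for k in self.n_k)
        beta = cho_solve((L, True), xty)
        rss = max(float(yty - beta @ xty), 1e-300)
        return beta, L, rss, logdet_xtx

    def logdet_v(self, lam: float) -> float:
        return float(sum(nk * np.log1p(k * lam) for k, nk in self.n_k.items()))

    def neg2_profiled(self, lam: float, ys: dict) -> float:
        df = self.n - self.p
        _, _, rss, logdet_xtx = self._pieces(lam, ys)
        return df * np.log(rss / df) + self.logdet_v(lam) + logdet_xtx + df

    def neg2_full(self, se2: float, sg2: float, ys: dict) -> float:
        lam = max(sg2, 0.0) / se2
        _, _, rss, logdet_xtx = self._pieces(lam, ys)
        return (
            (self.n - self.p) * np.log(se2)
            + self.logdet_v(lam)
            + logdet_xtx
            + rss / se2
        )

    def _var_jj(self, lam: float) -> float:
        gamma = {k: 1.0 - 1.0 / np.sqrt(1.0 + k * lam) for k in self.n_k}
        c = {k: 2.0 * g - g * g for k, g in gamma.items()}
        M = self.xtx - sum(c[k] * self.A_k[k] for k in self.n_k)
        L = np.linalg.cholesky(M)
        e = np.zeros(self.p)
        e[self.j] = 1.0
        return float(cho_solve((L, True), e)[self.j])

    # -- the fit ---------------------------------------------------------
    def fit(self, y: np.ndarray):
        """Returns (estimate, se, p, n, info) for the smoking coefficient."""
        y = np.asarray(y, dtype=float)
        if np.isnan(y).any():
            raise ValidationError("solver requires complete responses")
        ys = self.ystats(y)
        df_resid = self.n - self.p

        if self.all_singletons:
            return self._ols_result(ys, note="ols")

        obj = lambda u: self.neg2_profiled(np.exp(u), ys)
        res = optimize.minimize_scalar(
            obj, bounds=(-12.0, 6.0), method="bounded",
            options={"xatol": 1e-8},
        )
        lam_hat = float(np.exp(res.x))
        if self.neg2_profiled(0.0, ys) <= res.fun or lam_hat < 1e-7:
            return self._ols_result(ys, note="ols")

        beta, L, rss, _ = self._pieces(lam_hat, ys)
        se2 = rss / df_resid
        sg2 = lam_hat * se2
        est = float(beta[self.j])
        var_beta = se2 * self._var_jj(lam_hat)
        se = float(np.sqrt(var_beta))

        df, failed = self._satterthwaite(ys, se2, sg2, var_beta)
        if failed:
            pval = float(2 * stats.norm.sf(abs(est) / se)) if se > 0 else 1.0
            mode = "normal"
        else:
            pval = float(2 * stats.t.sf(abs(est) / se, df)) if se > 0 else 1.0
            mode = ""
        return est, se, max(pval, np.nextafter(0, 1)), self.n, {
            "sigma_g2": sg2, "sigma_e2": se2, "df": df, "fallback": mode,
        }

    def _ols_result(self, ys: dict, note: str):
        beta, L, rss, _ = self._pieces(0.0, ys)
        df = self.n - self.p
        sigma2 = rss / df
        e = np.zeros(self.p)
        e[self.j] = 1.0
        se = float(np.sqrt(sigma2 * cho_solve((L, True), e)[self.j]))
        est = float(beta[self.j])
        pval = float(2 * stats.t.sf(abs(est) / se, df)) if se > 0 else 1.0
        return est, se, max(pval, np.nextafter(0, 1)), self.n, {
            "sigma_g2": 0.0, "sigma_e2": sigma2, "df": df, "fallback": note,
        }

    def _satterthwaite(self, ys: dict, se2: float, sg2: float, var_beta: float):
        """Satterthwaite-type df = 2 v^2 / (g' A g), A from the numerical
        REML information in (sigma_e^2, sigma_g^2)."""

        def v_of(theta):
            lam = max(theta[1], 0.0) / theta[0]
            return theta[0] * self._var_jj(lam)

        def l_of(theta):
            return self.neg2_full(theta[0], max(theta[1], 1e-12), ys)

        theta = np.array([se2, sg2])
        h = np.maximum(1e-4 * theta, 1e-10)
        df_resid = float(self.n - self.p)
        try:
            e0 = np.array([h[0], 0.0])
            e1 = np.array([0.0, h[1]])
            grad = np.array(
                [
                    (v_of(theta + e0) - v_of(theta - e0)) / (2 * h[0]),
                    (v_of(theta + e1) - v_of(theta - e1)) / (2 * h[1]),
                ]
            )
            H = np.empty((2, 2))
            for a, ea in enumerate((e0, e1)):
                for b, eb in enumerate((e0, e1)):
                    H[a, b] = (
                        l_of(theta + ea + eb)
                        - l_of(theta + ea - eb)
                        - l_of(theta - ea + eb)
                        + l_of(theta - ea - eb)
                    ) / (4 * h[a] * h[b])
            A = 2.0 * np.linalg.inv(H)
            denom = float(grad @ A @ grad)
            if denom <= 0 or not np.isfinite(denom):
                return df_resid, True
            df = 2.0 * var_beta**2 / denom
            if not np.isfinite(df) or df < 1:
                return df_resid, True
            return float(min(df, df_resid)), False
        except np.linalg.LinAlgError:
            return df_resid, True


def fit_probe_lmm(y, design: DesignMatrix, groups=None):
    """Random-intercept REML fit of one probe.

    Returns ``(estimate, se, p, n, info)`` for the smoking coefficient;
    ``info`` records the variance components, the Satterthwaite-type df
    and whether a fallback was taken ("ols" when the group variance hits
    the zero boundary or every group is a singleton, "normal" when the df
    approximation fails and a Wald-normal p is used). Missing responses
    are dropped before fitting.
    """
    y = np.asarray(y, dtype=float)
    groups = design.groups if groups is None else np.asarray(groups)
    if groups is None:
        raise ValidationError("mixed model requires family grouping codes")
    ok = ~np.isnan(y)
    solver = RandomInterceptREML(
        design.X[ok], design.columns, design.smoking_idx, np.asarray(groups)[ok]
    )
    return solver.fit(y[ok])


def run_cohort_ewas(
    ds: MethylationDataset,
    contrast: str,
    use_mixed: bool = False,
    normalize: bool = True,
    include_age: bool = False,
) -> CohortResult:
    """Run the per-probe association scan for one cohort and contrast.

    The primary scale rank-inverse-normal transforms each probe before
    fitting (skipped when ``normalize`` is off); a second untransformed
    pass fills the beta-scale effect size columns. Per-probe failures are
    recorded as NaN rows with the reason logged.
    """
    design = build_design(ds.samples, contrast, include_age=include_age)
    for w in design.warnings:
        logger.info("%s [%s, %s]", w, ds.name, contrast)
    betas = ds.betas[design.sample_ids]

    raw = betas
    norm = transform_matrix(betas) if normalize else betas

    out = pd.DataFrame(
        index=betas.index,
        columns=["estimate", "se", "p", "n", "estimate_raw", "se_raw"],
        dtype=float,
    )
    if use_mixed:
        if design.groups is None:
            raise ValidationError(
                f"cohort {ds.name} has no family IDs; cannot fit mixed models"
            )
        solver = RandomInterceptREML(
            design.X, design.columns, design.smoking_idx, design.groups
        )
        norm_np = norm.to_numpy(dtype=float)
        raw_np = raw.to_numpy(dtype=float)
        vals = np.full((len(betas), 6), np.nan)
        fallback_flags = []
        for i, pid in enumerate(betas.index):
            try:
                yn, yr = norm_np[i], raw_np[i]
                if np.isnan(yn).any():
                    e, s, pv, nn, info = fit_probe_lmm(yn, design)
                    er, sr, _, _, _ = fit_probe_lmm(yr, design)
                else:
                    e, s, pv, nn, info = solver.fit(yn)
                    er, sr, _, _, _ = solver.fit(yr)
                vals[i] = [e, s, pv, nn, er, sr]
                fallback_flags.append(info["fallback"])
            except (ValidationError, np.linalg.LinAlgError) as exc:
                logger.warning("probe %s failed: %s", pid, exc)
                fallback_flags.append("failed")
        out.loc[:, :] = vals
        out["lmm_fallback"] = fallback_flags
    else:
        has_missing = betas.isna().to_numpy().any()
        if has_missing:
            for pid in betas.index:
                try:
                    e, s, pv, nn = fit_probe_ols(norm.loc[pid].to_numpy(), design)
                    er, sr, _, _ = fit_probe_ols(raw.loc[pid].to_numpy(), design)
                    out.loc[pid] = [e, s, pv, nn, er, sr]
                except ValidationError as exc:
                    logger.warning("probe %s failed: %s", pid, exc)
        else:
            e, s, pv, nn = _ols_many(norm.to_numpy(dtype=float), design)
            er, sr, _, _ = _ols_many(raw.to_numpy(dtype=float), design)
            out["estimate"], out["se"], out["p"], out["n"] = e, s, pv, nn
            out["estimate_raw"], out["se_raw"] = er, sr
    out["n"] = out["n"].astype("Int64")
    return CohortResult(cohort=ds.name, contrast=contrast, table=out)
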
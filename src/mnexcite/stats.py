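"""Cohort-level statistics for motor-unit discharge outcomes.

The central tool is a robust linear mixed-effects model with a participant
random intercept, fitted by Huber M-estimation: motor units are nested
within participants, and heavy-tailed unit-level outcomes (ΔF, brace
height, peak discharge rate) are down-weighted rather than excluded.

Group × intensity contrasts are summarised as estimated marginal means
(EMMs, balanced over sex) and their pairwise differences, with
bias-corrected and accelerated (BCa) confidence intervals from a cluster
bootstrap that resamples participants. Association models relate ΔF to
strength/power/function covariates with sex × intensity interactions and
report marginal (fixed effects only) and conditional (fixed + random)
R² as squared observed-vs-predicted correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

GROUP_ORDER = ("sarcopenic", "control", "athlete")

#: SDOC sarcopenia cut-offs: sex-specific handgrip (kg) and usual gait speed (m/s)
SDOC_HANDGRIP_KG = {"female": 20.0, "male": 35.5}
SDOC_UGS_MS = 0.8


class ConvergenceError(Exception):
    """The mixed model cannot be fitted (singular or degenerate design)."""


# ---------------------------------------------------------------------------
# robust linear mixed model


def _mad_scale(x: np.ndarray) -> float:
    """MAD-based robust scale estimate (consistent for the normal)."""
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def _variance_components(
    y: np.ndarray, X: np.ndarray, codes: np.ndarray, n_groups: int
) -> tuple[float, float]:
    """Moment-based variance components for a random-intercept model.

    Within-cluster residual scale comes from cluster-demeaned OLS residuals
    (MAD-robustified); the between-cluster component from the variance of
    cluster mean residuals, corrected for the within contribution.
    """
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    n_i = np.bincount(codes, minlength=n_groups).astype(float)
    means = np.bincount(codes, weights=r, minlength=n_groups) / np.maximum(n_i, 1)
    within = r - means[codes]
    sigma_e = _mad_scale(within)
    if sigma_e < 1e-10:
        sigma_e = max(float(np.std(within)), 1e-10)
    var_between = float(np.var(means[n_i > 0], ddof=1)) if (n_i > 0).sum() > 1 else 0.0
    sigma_b2 = max(var_between - sigma_e**2 * float(np.mean(1.0 / n_i[n_i > 0])), 0.0)
    return sigma_e**2, sigma_b2


class RobustLinearMixedModel:
    """Random-intercept linear mixed model fitted by Huber M-estimation.

    Parameters
    ----------
    endog : array
        Outcome, one value per motor unit (or other nested observation).
    exog : array (n, p)
        Fixed-effects design matrix (include the intercept explicitly).
    groups : sequence
        Cluster labels (participants) for the random intercept.
    exog_names : sequence of str, optional
        Column names for reporting.
    huber_c : float
        Huber tuning constant on the standardised residual scale. The
        default 1.345 gives 95% efficiency at the normal.
    tol, maxiter
        IRLS convergence tolerance on the coefficient update and iteration cap.

    The variance-component ratio λ = σ²_e/σ²_b is estimated once by a
    robust moment method and held fixed while the fixed effects and BLUPs
    are re-estimated by iteratively reweighted Henderson equations with
    Huber weights on the MAD-standardised conditional residuals.
    """

    def __init__(
        self,
        endog,
        exog,
        groups,
        exog_names: Sequence[str] | None = None,
        huber_c: float = 1.345,
        tol: float = 1e-8,
        maxiter: int = 200,
    ):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or len(self.endog) != len(self.exog):
            raise ValueError("exog must be (n, p) aligned with endog")
        self.group_labels, self.codes = np.unique(np.asarray(groups), return_inverse=True)
        self.n_clusters = len(self.group_labels)
        self.exog_names = list(exog_names) if exog_names is not None else [
            f"x{j}" for j in range(self.exog.shape[1])
        ]
        self.huber_c = huber_c
        self.tol = tol
        self.maxiter = maxiter
        if self.n_clusters < 2:
            raise ConvergenceError("at least two clusters are required")
        if np.linalg.matrix_rank(self.exog) < self.exog.shape[1]:
            raise ConvergenceError("rank-deficient fixed-effects design")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, outcome: str, design: "DesignInfo", **kw
    ) -> "RobustLinearMixedModel":
        X = design.matrix(df)
        return cls(df[outcome].to_numpy(), X, df["participant_id"].to_numpy(),
                   exog_names=design.names, **kw)

    def fit(
        self,
        lambda_: float | None = None,
        start_params: np.ndarray | None = None,
    ) -> "RobustMixedResults":
        y, X, codes = self.endog, self.exog, self.codes
        n, p = X.shape
        q = self.n_clusters
        if lambda_ is None:
            sigma_e2, sigma_b2 = _variance_components(y, X, codes, q)
            lambda_ = sigma_e2 / max(sigma_b2, sigma_e2 * 1e-6)
            lambda_ = float(min(lambda_, 1e8))
        beta = (
            np.asarray(start_params, dtype=float)
            if start_params is not None
            else np.linalg.lstsq(X, y, rcond=None)[0]
        )
        b = np.zeros(q)
        converged = False
        S = np.eye(p)
        for it in range(self.maxiter):
            e = y - X @ beta - b[codes]
            sigma = _mad_scale(e)
            if sigma < 1e-10:
                w = np.ones(n)
            else:
                u = np.abs(e) / sigma
                w = np.minimum(1.0, self.huber_c / np.maximum(u, 1e-12))
            Xw = X * w[:, None]
            A11 = Xw.T @ X
            A12 = np.empty((p, q))
            for j in range(p):
                A12[j] = np.bincount(codes, weights=w * X[:, j], minlength=q)
            d22 = np.bincount(codes, weights=w, minlength=q) + lambda_
            r1 = Xw.T @ y
            r2 = np.bincount(codes, weights=w * y, minlength=q)
            inv_d = 1.0 / d22
            S = A11 - (A12 * inv_d) @ A12.T
            rhs = r1 - A12 @ (inv_d * r2)
            try:
                beta_new = np.linalg.solve(S, rhs)
            except np.linalg.LinAlgError as exc:
                raise ConvergenceError(f"singular mixed-model system: {exc}") from exc
            b_new = inv_d * (r2 - A12.T @ beta_new)
            delta = np.max(np.abs(beta_new - beta)) if it else np.inf
            beta, b = beta_new, b_new
            if delta < self.tol * (1.0 + np.max(np.abs(beta))):
                converged = True
                break
        e = y - X @ beta - b[codes]
        sigma_e = max(_mad_scale(e), float(np.std(e)) * 1e-3, 1e-12)
        cov = np.linalg.inv(S) * sigma_e**2
        return RobustMixedResults(
            model=self, params=beta, cov_params_=cov, ranef=b,
            lambda_=lambda_, sigma_e=sigma_e, n_iter=it + 1, converged=converged,
        )


@dataclass
class RobustMixedResults:
    """Fit results: coefficients, covariance, BLUPs and fit diagnostics."""

    model: RobustLinearMixedModel
    params: np.ndarray
    cov_params_: np.ndarray
    ranef: np.ndarray
    lambda_: float
    sigma_e: float
    n_iter: int
    converged: bool

    @property
    def bse(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_params_))

    @property
    def tvalues(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    def conf_int(self, alpha: float = 0.05) -> np.ndarray:
        z = norm.ppf(1 - alpha / 2)
        return np.column_stack([self.params - z * self.bse, self.params + z * self.bse])

    def lincomb(self, L: np.ndarray) -> tuple[float, float]:
        """Estimate and standard error of the linear combination L·β."""
        L = np.asarray(L, dtype=float)
        return float(L @ self.params), float(np.sqrt(L @ self.cov_params_ @ L))

    @property
    def fitted_fixed(self) -> np.ndarray:
        return self.model.exog @ self.params

    @property
    def fitted(self) -> np.ndarray:
        return self.fitted_fixed + self.ranef[self.model.codes]

    def _r2(self, pred: np.ndarray) -> float:
        y = self.model.endog
        if np.std(pred) < 1e-12 or np.std(y) < 1e-12:
            return 0.0
        return float(np.corrcoef(y, pred)[0, 1] ** 2)

    @property
    def r2_marginal(self) -> float:
        """Squared correlation of the outcome with the fixed-effects prediction."""
        return self._r2(self.fitted_fixed)

    @property
    def r2_conditional(self) -> float:
        """Squared correlation of the outcome with the full-model prediction."""
        return self._r2(self.fitted)

    def summary(self) -> str:
        ci = self.conf_int()
        lines = [
            "Robust linear mixed model (Huber M-estimation, random intercept)",
            f"  clusters: {self.model.n_clusters}   observations: {len(self.model.endog)}",
            f"  lambda (sigma_e^2/sigma_b^2): {self.lambda_:.4g}   "
            f"sigma_e: {self.sigma_e:.4g}   iterations: {self.n_iter}"
            f"{'' if self.converged else '  (NOT converged)'}",
            f"  R2m: {self.r2_marginal:.3f}   R2c: {self.r2_conditional:.3f}",
            f"  {'term':<28}{'coef':>10}{'se':>10}{'t':>8}{'[0.025':>10}{'0.975]':>10}",
        ]
        for j, name in enumerate(self.model.exog_names):
            lines.append(
                f"  {name:<28}{self.params[j]:>10.4f}{self.bse[j]:>10.4f}"
                f"{self.tvalues[j]:>8.2f}{ci[j, 0]:>10.4f}{ci[j, 1]:>10.4f}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# design matrices


@dataclass
class DesignInfo:
    """Fixed-effects design: group × intensity cells plus a sex adjustment."""

    groups: tuple[str, ...]
    intensities: tuple[float, ...]
    names: list[str] = field(default_factory=list)
    extra_numeric: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.names:
            names = ["intercept"]
            names += [f"group[{g}]" for g in self.groups[1:]]
            names += [f"intensity[{intensity_name(i)}]" for i in self.intensities[1:]]
            for g in self.groups[1:]:
                for i in self.intensities[1:]:
                    names.append(f"group[{g}]:intensity[{intensity_name(i)}]")
            names.append("sex[male]")
            names += list(self.extra_numeric)
            self.names = names

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        n = len(df)
        cols = [np.ones(n)]
        gdum = {g: (df["group"] == g).to_numpy(float) for g in self.groups[1:]}
        idum = {
            i: np.isclose(df["intensity"].to_numpy(float), i).astype(float)
            for i in self.intensities[1:]
        }
        cols += [gdum[g] for g in self.groups[1:]]
        cols += [idum[i] for i in self.intensities[1:]]
        for g in self.groups[1:]:
            for i in self.intensities[1:]:
                cols.append(gdum[g] * idum[i])
        cols.append((df["sex"] == "male").to_numpy(float))
        for c in self.extra_numeric:
            cols.append(df[c].to_numpy(float))
        return np.column_stack(cols)

    def emm_vector(self, group: str, intensity: float) -> np.ndarray:
        """L-vector of the estimated marginal mean for one group × intensity
        cell, sex balanced 50/50 and numeric covariates at zero."""
        L = np.zeros(len(self.names))
        L[self.names.index("intercept")] = 1.0
        if group != self.groups[0]:
            L[self.names.index(f"group[{group}]")] = 1.0
        iname = intensity_name(intensity)
        if not np.isclose(intensity, self.intensities[0]):
            L[self.names.index(f"intensity[{iname}]")] = 1.0
            if group != self.groups[0]:
                L[self.names.index(f"group[{group}]:intensity[{iname}]")] = 1.0
        L[self.names.index("sex[male]")] = 0.5
        return L


def intensity_name(intensity: float) -> str:
    return f"i{round(float(intensity) * 100):d}"


# ---------------------------------------------------------------------------
# contrasts and bootstrap


@dataclass
class ContrastResult:
    """One EMM difference with its BCa bootstrap confidence interval."""

    name: str
    estimate: float
    ci_low: float
    ci_high: float

    @property
    def excludes_zero(self) -> bool:
        return self.ci_low > 0 or self.ci_high < 0


@dataclass
class EmmDifference:
    """Difference and percent difference between two estimated marginal means."""

    difference: float
    percent: float | None

    def rounded(self) -> tuple[float, float | None]:
        """Values at reporting precision: difference to 2 decimals, percent
        to the nearest integer."""
        return (
            round(self.difference, 2),
            None if self.percent is None else round(self.percent),
        )


def emm_difference(mean_a: float, mean_b: float) -> EmmDifference:
    """``a − b`` and the percent difference with ``b`` (the subtrahend group)
    as denominator. The percent is undefined (None) when ``b`` is zero."""
    diff = mean_a - mean_b
    pct = None if mean_b == 0 else diff / mean_b * 100.0
    return EmmDifference(difference=diff, percent=pct)


def _bca_interval(
    boot: np.ndarray, estimate: float, jack: np.ndarray, alpha: float = 0.05
) -> tuple[float, float]:
    """Bias-corrected and accelerated interval from bootstrap + jackknife draws."""
    boot = boot[np.isfinite(boot)]
    if len(boot) < 10 or np.ptp(boot) < 1e-12:
        return estimate, estimate
    prop = (np.sum(boot < estimate) + 0.5 * np.sum(boot == estimate)) / len(boot)
    prop = min(max(prop, 1.0 / (len(boot) + 1)), 1 - 1.0 / (len(boot) + 1))
    z0 = norm.ppf(prop)
    jm = jack.mean()
    num = np.sum((jm - jack) ** 3)
    den = 6.0 * np.sum((jm - jack) ** 2) ** 1.5
    a = num / den if den > 1e-12 else 0.0
    z = norm.ppf([alpha / 2, 1 - alpha / 2])
    adj = z0 + (z0 + z) / (1 - a * (z0 + z))
    lo, hi = norm.cdf(adj)
    return float(np.quantile(boot, lo)), float(np.quantile(boot, hi))


def cluster_bootstrap(
    df: pd.DataFrame,
    stat_fn: Callable[[pd.DataFrame], np.ndarray],
    B: int,
    seed: int | np.random.Generator,
    alpha: float = 0.05,
    max_redraws: int = 1000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Participant-level (cluster) bootstrap with BCa intervals.

    ``stat_fn`` maps a unit table to a vector of statistics. Participants
    are resampled with replacement; a resample missing any group level is
    redrawn (the count of redraws is returned). Jackknife leave-one-
    participant-out estimates supply the acceleration term.

    Returns ``(estimates, ci_low, ci_high, n_redrawn)``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = df["participant_id"].unique()
    groups_needed = set(df["group"].unique())
    by_id = {pid: sub for pid, sub in df.groupby("participant_id", sort=False)}
    id_group = {pid: by_id[pid]["group"].iloc[0] for pid in ids}

    estimate = np.atleast_1d(np.asarray(stat_fn(df), dtype=float))
    k = len(estimate)

    boot = np.full((B, k), np.nan)
    n_redrawn = 0
    for bi in range(B):
        for _ in range(max_redraws):
            pick = rng.choice(ids, size=len(ids), replace=True)
            if {id_group[p] for p in pick} == groups_needed:
                break
            n_redrawn += 1
        else:
            raise ConvergenceError("could not draw a resample containing all groups")
        parts = []
        for j, pid in enumerate(pick):
            blk = by_id[pid].copy()
            blk["participant_id"] = f"bs{j}"
            parts.append(blk)
        sample = pd.concat(parts, ignore_index=True)
        try:
            boot[bi] = stat_fn(sample)
        except ConvergenceError:
            continue

    jack = np.full((len(ids), k), np.nan)
    for j, pid in enumerate(ids):
        sub = df[df["participant_id"] != pid]
        if set(sub["group"].unique()) != groups_needed:
            continue
        try:
            jack[j] = stat_fn(sub)
        except ConvergenceError:
            continue

    lo = np.empty(k)
    hi = np.empty(k)
    for j in range(k):
        jj = jack[:, j]
        jj = jj[np.isfinite(jj)]
        lo[j], hi[j] = _bca_interval(boot[:, j], estimate[j], jj, alpha)
    if n_redrawn:
        logger.info("cluster bootstrap: %d resamples redrawn for missing groups", n_redrawn)
    return estimate, lo, hi, n_redrawn


# ---------------------------------------------------------------------------
# bin models


@dataclass
class BinModelResult:
    """Robust mixed-model summary for one recruitment-threshold bin."""

    bin_label: str
    results: RobustMixedResults
    design: DesignInfo
    coefficients: pd.DataFrame
    emms: pd.DataFrame
    contrasts: list[ContrastResult]
    n_redrawn: int = 0

    def emm(self, group: str, intensity: float) -> float:
        row = self.emms[
            (self.emms.group == group) & np.isclose(self.emms.intensity, intensity)
        ]
        return float(row["emm"].iloc[0])

    def contrast(self, name: str) -> ContrastResult:
        for c in self.contrasts:
            if c.name == name:
                return c
        raise KeyError(name)


def _check_bin_table(df: pd.DataFrame) -> None:
    groups = df["group"].unique()
    if len(groups) < 2:
        raise ConvergenceError("bin model needs at least two groups")
    per_group = df.groupby("group")["participant_id"].nunique()
    if (per_group < 2).any():
        raise ConvergenceError(
            f"bin model needs >= 2 participants per group, got {per_group.to_dict()}"
        )


def _contrast_specs(
    groups: Sequence[str], intensities: Sequence[float]
) -> list[tuple[str, tuple]]:
    specs = []
    for i in intensities:
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                specs.append(
                    (f"{groups[b]}-{groups[a]}@{intensity_name(i)}",
                     ("group", groups[b], groups[a], i))
                )
    for g in groups:
        for a in range(len(intensities)):
            for b in range(a + 1, len(intensities)):
                specs.append(
                    (f"{g}@{intensity_name(intensities[b])}-{intensity_name(intensities[a])}",
                     ("intensity", g, intensities[b], intensities[a]))
                )
    return specs


def fit_bin_model(
    df: pd.DataFrame,
    outcome: str = "delta_f_pps",
    bin_label: str = "",
    bootstrap_B: int = 2000,
    seed: int = 0,
    huber_c: float = 1.345,
    alpha: float = 0.05,
) -> BinModelResult:
    """Fit the robust group × intensity mixed model for one threshold bin.

    ``df`` holds one row per unit × intensity with columns
    ``participant_id, group, sex, intensity`` and the outcome. Fixed
    effects are group, intensity, their interaction and sex; participants
    contribute random intercepts. EMMs are balanced over sex; pairwise
    group differences per intensity and intensity differences per group get
    BCa cluster-bootstrap confidence intervals.
    """
    df = df.dropna(subset=[outcome]).copy()
    _check_bin_table(df)
    groups = tuple(g for g in GROUP_ORDER if g in set(df["group"]))
    intensities = tuple(sorted(df["intensity"].unique()))
    design = DesignInfo(groups=groups, intensities=intensities)

    model = RobustLinearMixedModel.from_dataframe(df, outcome, design, huber_c=huber_c)
    res = model.fit()

    ci = res.conf_int(alpha)
    coefficients = pd.DataFrame(
        {
            "term": design.names,
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
        }
    )

    emm_rows = []
    for g in groups:
        for i in intensities:
            est, se = res.lincomb(design.emm_vector(g, i))
            z = norm.ppf(1 - alpha / 2)
            emm_rows.append((g, i, est, est - z * se, est + z * se))
    emms = pd.DataFrame(emm_rows, columns=["group", "intensity", "emm", "ci_low", "ci_high"])

    specs = _contrast_specs(groups, intensities)
    lam, start = res.lambda_, res.params

    def stat_fn(sample: pd.DataFrame) -> np.ndarray:
        m = RobustLinearMixedModel.from_dataframe(sample, outcome, design, huber_c=huber_c)
        r = m.fit(lambda_=lam, start_params=start)
        out = np.empty(len(specs))
        for j, (_, (kind, x, a, b)) in enumerate(specs):
            if kind == "group":
                La = design.emm_vector(x, b)
                Lb = design.emm_vector(a, b)
                out[j] = float((La - Lb) @ r.params)
            else:
                La = design.emm_vector(x, a)
                Lb = design.emm_vector(x, b)
                out[j] = float((La - Lb) @ r.params)
        return out

    est, lo, hi, n_redrawn = cluster_bootstrap(df, stat_fn, bootstrap_B, seed, alpha)
    contrasts = [
        ContrastResult(name, est[j], lo[j], hi[j]) for j, (name, _) in enumerate(specs)
    ]
    return BinModelResult(
        bin_label=bin_label, results=res, design=design,
        coefficients=coefficients, emms=emms, contrasts=contrasts,
        n_redrawn=n_redrawn,
    )


# Contrast name convention: "groupB-groupA@i60" is the EMM of groupB minus
# groupA at i60; "control@i60-i20" is control's EMM at i60 minus at i20.


def bootstrap_contrasts(
    df: pd.DataFrame,
    outcome: str,
    B: int = 2000,
    seed: int = 0,
    huber_c: float = 1.345,
) -> list[ContrastResult]:
    """Convenience wrapper: fit the bin model and return only the contrasts."""
    return fit_bin_model(df, outcome=outcome, bootstrap_B=B, seed=seed,
                         huber_c=huber_c).contrasts


# ---------------------------------------------------------------------------
# association models


@dataclass
class AssociationModelResult:
    """ΔF–covariate association model: per-stratum slopes and R² values."""

    predictor: str
    slopes: pd.DataFrame            # sex × intensity slopes with CIs
    r2_marginal: float
    r2_conditional: float
    results: RobustMixedResults


class _AssociationDesign:
    """measure × sex × intensity design (+ optional body-mass adjustment)."""

    def __init__(self, measure: str, intensities: tuple[float, ...],
                 adjust_body_mass: bool):
        self.measure = measure
        self.intensities = intensities
        self.adjust_body_mass = adjust_body_mass
        names = ["intercept", measure, "sex[male]"]
        names += [f"intensity[{intensity_name(i)}]" for i in intensities[1:]]
        names += [f"{measure}:sex[male]"]
        names += [f"{measure}:intensity[{intensity_name(i)}]" for i in intensities[1:]]
        names += [f"sex[male]:intensity[{intensity_name(i)}]" for i in intensities[1:]]
        names += [f"{measure}:sex[male]:intensity[{intensity_name(i)}]"
                  for i in intensities[1:]]
        if adjust_body_mass:
            names.append("body_mass_kg")
        self.names = names

    def matrix(self, df: pd.DataFrame) -> np.ndarray:
        n = len(df)
        m = df[self.measure].to_numpy(float)
        male = (df["sex"] == "male").to_numpy(float)
        idum = [
            np.isclose(df["intensity"].to_numpy(float), i).astype(float)
            for i in self.intensities[1:]
        ]
        cols = [np.ones(n), m, male] + idum
        cols += [m * male]
        cols += [m * d for d in idum]
        cols += [male * d for d in idum]
        cols += [m * male * d for d in idum]
        if self.adjust_body_mass:
            cols.append(df["body_mass_kg"].to_numpy(float))
        return np.column_stack(cols)

    def slope_vector(self, sex: str, intensity: float) -> np.ndarray:
        """d(outcome)/d(measure) for one sex × intensity stratum."""
        L = np.zeros(len(self.names))
        L[self.names.index(self.measure)] = 1.0
        male = 1.0 if sex == "male" else 0.0
        L[self.names.index(f"{self.measure}:sex[male]")] = male
        if not np.isclose(intensity, self.intensities[0]):
            iname = intensity_name(intensity)
            L[self.names.index(f"{self.measure}:intensity[{iname}]")] = 1.0
            L[self.names.index(f"{self.measure}:sex[male]:intensity[{iname}]")] = male
        return L


def fit_association_model(
    df: pd.DataFrame,
    measure: str,
    outcome: str = "delta_f_pps",
    adjust_body_mass: bool = False,
    huber_c: float = 1.345,
    alpha: float = 0.05,
    min_coverage: float = 0.8,
) -> AssociationModelResult:
    """Relate a per-unit outcome to a participant-level covariate.

    Robust mixed model ``outcome ~ measure × sex × intensity`` (plus body
    mass when requested, e.g. for peak torque), with a participant random
    intercept. Reports the per-stratum slopes (change in outcome per unit
    of the measure, for each sex × intensity) with normal-approximation
    CIs, and marginal/conditional R².
    """
    need = [outcome, measure] + (["body_mass_kg"] if adjust_body_mass else [])
    covered = df.dropna(subset=[measure])["participant_id"].nunique()
    total = df["participant_id"].nunique()
    if total and covered / total < min_coverage:
        raise ValueError(
            f"{measure} present for only {covered}/{total} participants "
            f"(< {min_coverage:.0%})"
        )
    df = df.dropna(subset=need).copy()
    if df[measure].nunique() < 2:
        raise ConvergenceError(f"constant predictor {measure}")
    intensities = tuple(sorted(df["intensity"].unique()))
    design = _AssociationDesign(measure, intensities, adjust_body_mass)
    model = RobustLinearMixedModel(
        df[outcome].to_numpy(), design.matrix(df), df["participant_id"].to_numpy(),
        exog_names=design.names, huber_c=huber_c,
    )
    res = model.fit()
    z = norm.ppf(1 - alpha / 2)
    rows = []
    for sex in ("female", "male"):
        for i in intensities:
            est, se = res.lincomb(design.slope_vector(sex, i))
            rows.append((sex, i, est, est - z * se, est + z * se))
    slopes = pd.DataFrame(rows, columns=["sex", "intensity", "slope", "ci_low", "ci_high"])
    return AssociationModelResult(
        predictor=measure, slopes=slopes,
        r2_marginal=res.r2_marginal, r2_conditional=res.r2_conditional,
        results=res,
    )


# ---------------------------------------------------------------------------
# SDOC classifier


def sdoc_classify(
    sex: str, handgrip_kg: float | None, ugs_ms: float | None
) -> str | None:
    """SDOC sarcopenia screen.

    Sarcopenic iff the sex-specific handgrip cut-off (< 20 kg for females,
    < 35.5 kg for males) AND usual gait speed < 0.8 m/s are both met.
    Returns ``None`` (indeterminate) when an input is missing.
    """
    if sex not in SDOC_HANDGRIP_KG:
        raise ValueError(f"unknown sex {sex!r}")
    if handgrip_kg is None or ugs_ms is None or not (
        np.isfinite(handgrip_kg) and np.isfinite(ugs_ms)
    ):
        logger.warning("SDOC classification indeterminate: missing input")
        return None
    low_grip = handgrip_kg < SDOC_HANDGRIP_KG[sex]
    slow = ugs_ms < SDOC_UGS_MS
    return "sarcopenic" if (low_grip and slow) else "not sarcopenic"


# ---------------------------------------------------------------------------
# synthetic unit tables for calibration studies


def simulate_unit_table(
    n_per_group: Mapping[str, int],
    units_per_participant: int = 10,
    group_offsets: Mapping[str, Mapping[float, float]] | None = None,
    participant_sd: float = 0.6,
    unit_sd: float = 1.0,
    baseline: float = 3.0,
    intensities: Sequence[float] = (0.2, 0.4, 0.6),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Draw a unit-level outcome table directly from the mixed-model data
    -generating process (participant intercepts + unit noise), bypassing the
    spike-train pipeline. Used for calibration and parameter-recovery
    studies of the statistics layer; ``group_offsets[group][intensity]``
    shifts the cell mean (default: no group effect)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for group, n in n_per_group.items():
        for k in range(n):
            pid = f"{group[:3]}{k:02d}"
            sex = "female" if k % 2 == 0 else "male"
            intercept = rng.normal(0.0, participant_sd)
            for i in intensities:
                off = 0.0
                if group_offsets and group in group_offsets:
                    off = group_offsets[group].get(round(i, 2), 0.0)
                vals = baseline + off + intercept + rng.normal(
                    0.0, unit_sd, units_per_participant
                )
                for u, v in enumerate(vals):
                    rows.append((pid, group, sex, i, f"{pid}_u{u}", v))
    return pd.DataFrame(
        rows,
        columns=["participant_id", "group", "sex", "intensity", "unit_id", "delta_f_pps"],
    )
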
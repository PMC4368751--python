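"""Survival and meta-analysis statistics for prognostic evaluation.

Everything needed to judge a per-sample score against censored survival:
administrative censoring at a horizon, Cox proportional-hazards fits
(Breslow partial likelihood, Newton-Raphson via statsmodels, optional ridge
stabilisation), the concordance index with bootstrap confidence intervals,
tertile stratification with hazard ratios, DerSimonian-Laird random-effects
meta-analysis, Fisher's combined probability test, and a paired-bootstrap
comparison of two scores pooled across cohorts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.duration.hazard_regression import PHReg

from .errors import (
    AlignmentError,
    ConvergenceError,
    StratificationError,
    UndefinedTestError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SurvivalCohort:
    """Censored survival data: per-sample time (years), event flag and
    optional covariate / score columns.

    ``data`` is indexed by sample id and must contain ``time`` (> 0) and
    ``event`` (0/1); every other column is treated as a covariate or score.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        df = self.data
        if "time" not in df.columns or "event" not in df.columns:
            raise ValueError("cohort data needs 'time' and 'event' columns")
        t = df["time"].to_numpy(dtype=float)
        e = df["event"].to_numpy()
        if np.any(~np.isfinite(t)) or np.any(t <= 0):
            raise ValueError("times must be finite and positive")
        if not np.isin(e, [0, 1]).all():
            raise ValueError("events must be 0/1")
        if df.index.has_duplicates:
            raise ValueError("duplicate sample ids")

    @property
    def time(self) -> np.ndarray:
        return self.data["time"].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data["event"].to_numpy(dtype=int)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def __len__(self) -> int:
        return len(self.data)

    def design(self, columns: list[str]) -> pd.DataFrame:
        """Numeric design matrix; categorical columns are one-hot coded
        against their first (sorted) level."""
        return build_design(self.data, columns)


def build_design(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    parts = []
    for col in columns:
        s = df[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype) or s.dtype == bool:
            dummies = pd.get_dummies(s.astype(str), prefix=col, dtype=float)
            dummies = dummies[sorted(dummies.columns)]
            parts.append(dummies.iloc[:, 1:])  # drop reference level
        else:
            parts.append(s.astype(float).to_frame(col))
    if not parts:
        return pd.DataFrame(index=df.index)
    out = pd.concat(parts, axis=1)
    if out.isna().any().any():
        raise ValueError("design matrix contains missing values")
    return out


def censor_at(cohort: SurvivalCohort, horizon: float) -> SurvivalCohort:
    """Administrative censoring: times beyond the horizon become censored
    observations at the horizon; earlier observations are untouched."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    df = cohort.data.copy()
    late = df["time"] > horizon
    df.loc[late, "time"] = horizon
    df.loc[late, "event"] = 0
    return SurvivalCohort(df)


@dataclass(frozen=True)
class CoxFit:
    """Result of a proportional-hazards fit."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    loglike: float
    ties: str
    ridge: float

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.params)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = scipy.stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.params,
                "hr": self.hazard_ratios,
                "se": self.bse,
                "p": self.pvalues,
            }
        )


_MAX_ABS_BETA = 30.0  # |beta| beyond this is treated as monotone likelihood
_MAX_SE = 1e3  # a Wald SE this large signals a flat/monotone likelihood


def cox_fit(
    cohort: SurvivalCohort,
    columns: list[str],
    ties: str = "breslow",
    ridge: float = 0.0,
) -> CoxFit:
    """Cox proportional-hazards regression on the named columns.

    Maximises the Breslow-ties partial likelihood (Efron available via
    ``ties``) by Newton-Raphson and returns Wald statistics per term.  A
    positive ``ridge`` adds an L2 penalty 0.5*ridge*||beta||^2 to stabilise
    collinear designs — used by the signature-refinement fallback.

    Raises
    ------
    ConvergenceError
        On monotone likelihood / separation or non-convergence.
    """
    if ties not in ("breslow", "efron"):
        raise ValueError(f"unknown tie method {ties!r}")
    if cohort.n_events < 1:
        raise ValueError("cohort has no events")
    X = cohort.design(columns)
    if X.shape[1] == 0:
        raise ValueError("empty design matrix")
    model = PHReg(cohort.time, X.to_numpy(), status=cohort.event, ties=ties)

    if ridge > 0:
        beta, cov = _penalised_newton(model, ridge, X.shape[1])
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = model.fit(method="newton", maxiter=100, tol=1e-8, disp=False)
            except Exception as exc:  # LinAlgError etc.
                raise ConvergenceError(f"Cox fit failed: {exc}") from exc
        beta = res.params
        cov = res.cov_params()
        if (
            not np.all(np.isfinite(beta))
            or not np.all(np.isfinite(np.diag(cov)))
            or np.max(np.abs(beta)) > _MAX_ABS_BETA
            or np.sqrt(np.max(np.diag(cov))) > _MAX_SE
        ):
            raise ConvergenceError(
                "partial likelihood appears monotone (separation); "
                f"|beta| max = {np.max(np.abs(beta)):.3g}"
            )

    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2 * scipy.stats.norm.sf(np.abs(z))
    idx = list(X.columns)
    return CoxFit(
        params=pd.Series(beta, index=idx),
        bse=pd.Series(se, index=idx),
        pvalues=pd.Series(p, index=idx),
        loglike=float(model.loglike(beta)),
        ties=ties,
        ridge=ridge,
    )


def _penalised_newton(model: PHReg, ridge: float, k: int, maxiter: int = 100):
    """Ridge-penalised Newton-Raphson on the partial likelihood."""
    beta = np.zeros(k)
    for _ in range(maxiter):
        grad = model.score(beta) - ridge * beta
        hess = model.hessian(beta) - ridge * np.eye(k)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError as exc:
            raise ConvergenceError(f"ridge-stabilised fit diverged: {exc}") from exc
        beta = beta - step
        if not np.all(np.isfinite(beta)) or np.max(np.abs(beta)) > _MAX_ABS_BETA:
            raise ConvergenceError("ridge-stabilised fit diverged")
        if np.max(np.abs(grad)) < 1e-8:
            break
    else:
        if np.max(np.abs(model.score(beta) - ridge * beta)) > 1e-6:
            raise ConvergenceError("ridge-stabilised fit did not converge")
    cov = np.linalg.inv(-(model.hessian(beta) - ridge * np.eye(k)))
    return beta, cov


def concordance_index(scores, cohort: SurvivalCohort) -> float:
    """Censoring-aware concordance index, oriented so that higher score =
    higher risk (shorter survival).

    A pair is comparable when the smaller of the two times is an event
    (tied times are not comparable); score ties count 0.5.  Computed by
    exhaustive pair enumeration, vectorised.
    """
    s = _aligned_scores(scores, cohort)
    t = cohort.time
    e = cohort.event
    # pair (i, j) comparable if t_i < t_j and e_i == 1
    ti = t[:, None]
    tj = t[None, :]
    comparable = (ti < tj) & (e[:, None] == 1)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise UndefinedTestError("no comparable pairs")
    si = s[:, None]
    sj = s[None, :]
    concordant = comparable & (si > sj)  # shorter-lived i has higher score
    tied = comparable & (si == sj)
    return float((concordant.sum() + 0.5 * tied.sum()) / n_comp)


def _aligned_scores(scores, cohort: SurvivalCohort) -> np.ndarray:
    if isinstance(scores, pd.Series):
        if not scores.index.equals(cohort.data.index):
            if not set(cohort.data.index).issubset(scores.index):
                raise AlignmentError("scores do not cover the cohort samples")
            scores = scores.reindex(cohort.data.index)
        return scores.to_numpy(dtype=float)
    s = np.asarray(scores, dtype=float)
    if s.shape != (len(cohort),):
        raise AlignmentError("score length does not match cohort size")
    return s


def c_index_se(
    scores,
    cohort: SurvivalCohort,
    B: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
) -> tuple[float, tuple[float, float]]:
    """Nonparametric bootstrap standard error and percentile CI for the
    concordance index.

    Degenerate resamples (no comparable pairs) are redrawn, with at most
    10*B total attempts.
    """
    if B < 100:
        raise ValueError("need at least B=100 bootstrap resamples")
    s = _aligned_scores(scores, cohort)
    df = cohort.data
    rng = np.random.default_rng(seed)
    n = len(df)
    stats = np.empty(B)
    attempts = 0
    b = 0
    while b < B:
        if attempts >= 10 * B:
            raise UndefinedTestError("too many degenerate bootstrap resamples")
        attempts += 1
        idx = rng.integers(0, n, n)
        try:
            boot = SurvivalCohort(df.iloc[idx].reset_index(drop=True))
            stats[b] = concordance_index(s[idx], boot)
        except UndefinedTestError:
            continue
        b += 1
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(stats.std(ddof=1)), (float(lo), float(hi))


def tertile_stratify(scores) -> pd.Series:
    """Split scores into low/mid/high at the empirical 1/3 and 2/3
    quantiles (linear, "type 7" convention); boundary ties go to the lower
    group."""
    s = pd.Series(scores).astype(float)
    if s.nunique() < 3:
        raise StratificationError("need at least 3 distinct score values")
    q1, q2 = np.quantile(s.to_numpy(), [1 / 3, 2 / 3], method="linear")
    labels = np.where(s <= q1, "low", np.where(s <= q2, "mid", "high"))
    return pd.Series(pd.Categorical(labels, categories=["low", "mid", "high"]),
                     index=s.index, name="tertile")


@dataclass(frozen=True)
class HazardRatioResult:
    table: pd.DataFrame  # per non-reference group: hr, lower, upper, p
    reference: str
    fit: CoxFit = field(repr=False)


def hazard_ratio(
    groups, cohort: SurvivalCohort, reference: str = "low", alpha: float = 0.05
) -> HazardRatioResult:
    """Hazard ratios of each group versus the reference, from a Cox fit on
    group indicators, with Wald confidence intervals."""
    g = pd.Series(groups, index=cohort.data.index).astype(str)
    levels = sorted(g.unique())
    if reference not in levels:
        raise ValueError(f"reference group {reference!r} not present")
    ev = cohort.data["event"].groupby(g).sum()
    empty = [lev for lev in levels if ev.get(lev, 0) < 1]
    if empty:
        raise ValueError(f"group(s) without events: {empty}")
    df = cohort.data.copy()
    others = [lev for lev in levels if lev != reference]
    cols = []
    for lev in others:
        col = f"group_{lev}"
        df[col] = (g == lev).astype(float)
        cols.append(col)
    fit = cox_fit(SurvivalCohort(df), cols)
    ci = fit.conf_int(alpha)
    table = pd.DataFrame(
        {
            "hr": np.exp(fit.params.to_numpy()),
            "lower": np.exp(ci["lower"].to_numpy()),
            "upper": np.exp(ci["upper"].to_numpy()),
            "p": fit.pvalues.to_numpy(),
        },
        index=others,
    )
    return HazardRatioResult(table=table, reference=reference, fit=fit)


@dataclass(frozen=True)
class MetaResult:
    """Random-effects pooling of per-study estimates."""

    per_study: pd.DataFrame = field(repr=False)  # estimate, se, lower, upper
    pooled_estimate: float
    pooled_se: float
    pooled_ci: tuple[float, float]
    tau2: float
    q_statistic: float
    p: float


def meta_random_effects(estimates, ses, alpha: float = 0.05) -> MetaResult:
    """DerSimonian-Laird random-effects meta-analysis.

    Between-study variance tau^2 = max(0, (Q - (k-1)) / (S1 - S2/S1)) with
    fixed-effect weights w_i = 1/se_i^2, S1 = sum w, S2 = sum w^2; the
    pooled estimate uses weights 1/(se_i^2 + tau^2).  Two-sided z test for
    a zero pooled effect.
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.size != se.size:
        raise ValueError("estimates and standard errors differ in length")
    if est.size < 2:
        raise ValueError("meta-analysis needs at least 2 studies")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / se**2
    fixed = np.sum(w * est) / np.sum(w)
    q = float(np.sum(w * (est - fixed) ** 2))
    k = est.size
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_re = 1.0 / (se**2 + tau2)
    pooled = float(np.sum(w_re * est) / np.sum(w_re))
    pooled_se = float(np.sqrt(1.0 / np.sum(w_re)))
    z = scipy.stats.norm.ppf(1 - alpha / 2)
    ci = (pooled - z * pooled_se, pooled + z * pooled_se)
    p = float(2 * scipy.stats.norm.sf(abs(pooled / pooled_se)))
    zq = scipy.stats.norm.ppf(0.975)
    per_study = pd.DataFrame(
        {
            "estimate": est,
            "se": se,
            "lower": est - zq * se,
            "upper": est + zq * se,
        }
    )
    return MetaResult(
        per_study=per_study,
        pooled_estimate=pooled,
        pooled_se=pooled_se,
        pooled_ci=ci,
        tau2=float(tau2),
        q_statistic=q,
        p=p,
    )


def fisher_combined(p_values) -> tuple[float, float]:
    """Fisher's combined probability test.

    X = -2 sum(log p) ~ chi-square with 2k df under the global null.
    Returns (X, combined p).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values given")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError(
            "p-values must lie in (0, 1]; floor exact zeros at machine "
            "epsilon upstream if needed"
        )
    x = float(-2.0 * np.log(p).sum())
    return x, float(scipy.stats.chi2.sf(x, 2 * p.size))


def compare_scores_meta(
    score_a,
    score_b,
    cohorts: list[SurvivalCohort],
    B: int = 1000,
    seed: int | None = None,
) -> dict:
    """Compare the concordance of two scores across cohorts.

    Per cohort, a paired bootstrap (shared resample indices) of the c-index
    difference a - b yields an estimate and standard error; cohort-level
    differences are pooled by random-effects meta-analysis when more than
    one cohort is given.  Identical scores short-circuit to an exact tie
    (difference 0, p = 1).
    """
    if not isinstance(score_a, (list, tuple)):
        score_a = [score_a] * len(cohorts)
    if not isinstance(score_b, (list, tuple)):
        score_b = [score_b] * len(cohorts)
    if not (len(score_a) == len(score_b) == len(cohorts)):
        raise ValueError("need one score pair per cohort")
    rng = np.random.default_rng(seed)

    diffs, ses = [], []
    for sa, sb, cohort in zip(score_a, score_b, cohorts):
        va = _aligned_scores(sa, cohort)
        vb = _aligned_scores(sb, cohort)
        d_obs = concordance_index(va, cohort) - concordance_index(vb, cohort)
        if np.array_equal(va, vb):
            diffs.append(0.0)
            ses.append(np.nan)
            continue
        n = len(cohort)
        boot = []
        attempts = 0
        while len(boot) < B and attempts < 10 * B:
            attempts += 1
            idx = rng.integers(0, n, n)
            sub = SurvivalCohort(cohort.data.iloc[idx].reset_index(drop=True))
            try:
                boot.append(
                    concordance_index(va[idx], sub) - concordance_index(vb[idx], sub)
                )
            except UndefinedTestError:
                continue
        sd = float(np.std(boot, ddof=1))
        diffs.append(float(d_obs))
        ses.append(sd if sd > 0 else np.nan)

    diffs = np.asarray(diffs)
    ses = np.asarray(ses)
    if np.all(np.isnan(ses)) or np.allclose(diffs, 0.0):
        return {"difference": 0.0, "se": 0.0, "p": 1.0, "per_cohort": list(diffs)}
    valid = ~np.isnan(ses)
    if valid.sum() == 1:
        logger.info("single informative cohort: per-cohort bootstrap p reported")
        d, s = float(diffs[valid][0]), float(ses[valid][0])
        p = float(2 * scipy.stats.norm.sf(abs(d / s)))
        return {"difference": d, "se": s, "p": p, "per_cohort": list(diffs)}
    meta = meta_random_effects(diffs[valid], ses[valid])
    return {
        "difference": meta.pooled_estimate,
        "se": meta.pooled_se,
        "p": meta.p,
        "tau2": meta.tau2,
        "per_cohort": list(diffs),
    }
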
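"""SE prognostic score and entropy-guided signature derivation.

Computing signalling entropy needs genome-wide expression; a compact
surrogate is a two-set gene signature scored per sample as the t-statistic
contrasting the genes positively correlated with signalling entropy against
those negatively correlated, after per-gene z-normalisation.  The
derivation pipeline mirrors the entropy-guided feature selection: screen
for genes prognostic independently of clinical covariates (per-gene Cox at
a censoring horizon), screen for genes (partially) correlated with
signalling entropy given the same covariates, intersect, then backward-
eliminate genes that are not independently prognostic in a joint Cox model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .errors import (
    AlignmentError,
    ConvergenceError,
    EmptySignatureError,
    SignatureCoverageError,
)
from .survival import SurvivalCohort, build_design, censor_at, cox_fit

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Signature:
    """Two disjoint gene sets defining the SE score, plus an audit trail."""

    positive_genes: tuple[str, ...]
    negative_genes: tuple[str, ...]
    provenance: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        pos, neg = set(self.positive_genes), set(self.negative_genes)
        if pos & neg:
            raise ValueError(f"genes in both sets: {sorted(pos & neg)}")
        if not pos and not neg:
            raise ValueError("signature is empty")

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.positive_genes) + tuple(self.negative_genes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene": list(self.positive_genes) + list(self.negative_genes),
                "sign": ["+"] * len(self.positive_genes) + ["-"] * len(self.negative_genes),
            }
        )


def z_normalise(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene z-scores across samples (ddof=1).

    Genes with zero variance cannot be scaled and are excluded; their names
    are returned alongside the normalised matrix.

    Parameters
    ----------
    matrix
        genes x samples expression table.
    """
    if matrix.shape[1] < 2:
        raise ValueError("z-normalisation needs at least 2 samples")
    if matrix.index.has_duplicates:
        raise ValueError("gene identifiers must be unique")
    mu = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    keep = sd > 0
    excluded = list(matrix.index[~keep])
    if excluded:
        logger.warning("excluding %d zero-variance gene(s)", len(excluded))
    z = matrix.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)
    return z, excluded


def se_score(
    z_matrix: pd.DataFrame, sig: Signature, equal_var: bool = False
) -> pd.Series:
    """Per-sample SE score: t-statistic of positive vs negative signature
    genes on z-scored expression.

    Welch (unequal-variance) by default — robust to very unequal set sizes;
    ``equal_var=True`` switches to the pooled-variance t.  Signature genes
    absent from the matrix are dropped with a warning; at least 2 genes
    must remain in each set.
    """
    pos = [g for g in sig.positive_genes if g in z_matrix.index]
    neg = [g for g in sig.negative_genes if g in z_matrix.index]
    n_missing = len(sig.genes) - len(pos) - len(neg)
    if n_missing:
        logger.warning("%d signature gene(s) missing from the matrix", n_missing)
    if len(pos) < 2 or len(neg) < 2:
        raise SignatureCoverageError(
            f"need >= 2 genes per set after matching; got {len(pos)}+/{len(neg)}-"
        )
    xp = z_matrix.loc[pos].to_numpy(dtype=float)
    xn = z_matrix.loc[neg].to_numpy(dtype=float)
    mp, mn = xp.mean(axis=0), xn.mean(axis=0)
    vp, vn = xp.var(axis=0, ddof=1), xn.var(axis=0, ddof=1)
    np_, nn = len(pos), len(neg)
    if equal_var:
        sp2 = ((np_ - 1) * vp + (nn - 1) * vn) / (np_ + nn - 2)
        denom = np.sqrt(sp2 * (1 / np_ + 1 / nn))
    else:
        denom = np.sqrt(vp / np_ + vn / nn)
    t = (mp - mn) / denom
    return pd.Series(t, index=z_matrix.columns, name="se_score")


def prognostic_gene_screen(
    matrix: pd.DataFrame,
    cohort: SurvivalCohort,
    covariates: list[str] | None = None,
    horizon: float | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-gene Cox screen for prognosis independent of covariates.

    Fits, for every gene, a proportional-hazards model of survival
    (censored at ``horizon`` if given) on the gene plus the covariates and
    keeps genes whose own Wald p < alpha.  Returns a frame indexed by the
    retained genes with columns ``coef``, ``p`` and ``sign``.
    """
    covariates = list(covariates or [])
    cohort = _align_cohort(matrix, cohort)
    if horizon is not None:
        cohort = censor_at(cohort, horizon)
    if cohort.n_events < 1:
        raise ValueError("no events before the censoring horizon")
    if cohort.n_events < 10:
        logger.warning("only %d events; screen will be unstable", cohort.n_events)
    rows = []
    base = cohort.data[["time", "event"] + covariates]
    for gene in matrix.index:
        df = base.copy()
        df["__gene__"] = matrix.loc[gene].reindex(df.index).to_numpy(dtype=float)
        try:
            fit = cox_fit(SurvivalCohort(df), ["__gene__"] + covariates)
        except ConvergenceError as exc:
            logger.warning("gene %r skipped: %s", gene, exc)
            continue
        coef = fit.params["__gene__"]
        p = fit.pvalues["__gene__"]
        if p < alpha:
            rows.append({"gene": gene, "coef": coef, "p": p,
                         "sign": 1 if coef > 0 else -1})
    return pd.DataFrame(rows, columns=["gene", "coef", "p", "sign"]).set_index("gene")


def entropy_correlated_genes(
    matrix: pd.DataFrame,
    entropies: pd.Series,
    covariates_frame: pd.DataFrame | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genes (partially) correlated with signalling entropy.

    Correlation is Pearson on residuals after linearly adjusting both the
    gene and the entropy for the covariates (categoricals one-hot coded);
    the p-value uses the t distribution with n - q - 2 degrees of freedom,
    q the number of adjustment columns.  Returns a frame indexed by the
    retained genes with columns ``r``, ``p`` and ``sign``.
    """
    samples = list(matrix.columns)
    ent = entropies.reindex(samples)
    if ent.isna().any():
        raise AlignmentError("entropies missing for some samples")
    y = ent.to_numpy(dtype=float)
    n = len(samples)
    if covariates_frame is not None and covariates_frame.shape[1] > 0:
        cov = build_design(covariates_frame.loc[samples], list(covariates_frame.columns))
        q = cov.shape[1]
        X = np.column_stack([np.ones(n), cov.to_numpy(dtype=float)])
    else:
        q = 0
        X = np.ones((n, 1))
    # hat-matrix-free residualisation via least squares
    coef_y, *_ = np.linalg.lstsq(X, y, rcond=None)
    ry = y - X @ coef_y
    G = matrix[samples].to_numpy(dtype=float)
    coef_g, *_ = np.linalg.lstsq(X, G.T, rcond=None)
    rg = G.T - X @ coef_g  # n x genes residuals

    sy = np.linalg.norm(ry)
    sg = np.linalg.norm(rg, axis=0)
    dof = n - q - 2
    if dof < 1:
        raise ValueError("not enough samples for the adjusted correlation")
    rows = []
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (rg.T @ ry) / (sg * sy)
    for gene, ri, sgi in zip(matrix.index, r, sg):
        if sgi == 0 or not np.isfinite(ri):
            logger.debug("gene %r constant after adjustment; skipped", gene)
            continue
        ri = float(np.clip(ri, -1.0, 1.0))
        if abs(ri) == 1.0:
            p = 0.0
        else:
            t = ri * np.sqrt(dof / (1.0 - ri**2))
            p = float(2 * scipy.stats.t.sf(abs(t), dof))
        if p < alpha:
            rows.append({"gene": gene, "r": ri, "p": p, "sign": 1 if ri > 0 else -1})
    return pd.DataFrame(rows, columns=["gene", "r", "p", "sign"]).set_index("gene")


def backward_multivariate_refine(
    matrix: pd.DataFrame,
    cohort: SurvivalCohort,
    genes: list[str],
    horizon: float | None = None,
    alpha: float = 0.05,
    ridge_on_divergence: float = 1e-4,
) -> list[str]:
    """Backward elimination in a joint Cox model over the candidate genes.

    Repeatedly fits the joint model and removes the gene with the largest
    Wald p >= alpha until every remaining gene is independently prognostic
    or a single gene remains.  If the unpenalised joint fit diverges
    (collinearity, p approaching the number of events), it is retried with
    a small L2 penalty and a logged notice.
    """
    genes = list(genes)
    if not genes:
        raise ValueError("no candidate genes")
    cohort = _align_cohort(matrix, cohort)
    if horizon is not None:
        cohort = censor_at(cohort, horizon)
    if len(genes) >= cohort.n_events:
        logger.warning(
            "%d genes vs %d events: joint fit may need ridge stabilisation",
            len(genes), cohort.n_events,
        )
    while True:
        df = cohort.data[["time", "event"]].copy()
        for g in genes:
            df[g] = matrix.loc[g].reindex(df.index).to_numpy(dtype=float)
        sub = SurvivalCohort(df)
        try:
            fit = cox_fit(sub, genes)
        except ConvergenceError:
            logger.info("joint fit diverged; retrying with ridge %.1e",
                        ridge_on_divergence)
            fit = cox_fit(sub, genes, ridge=ridge_on_divergence)
        pv = fit.pvalues[genes]
        worst = pv.idxmax()
        if pv[worst] < alpha or len(genes) == 1:
            return genes
        genes.remove(worst)


def derive_signature(
    matrix: pd.DataFrame,
    cohort: SurvivalCohort,
    entropies: pd.Series,
    covariates: list[str] | None = None,
    horizon: float | None = None,
    alpha: float = 0.05,
) -> Signature:
    """Entropy-guided prognostic signature derivation.

    Intersects the prognostic-gene screen with the entropy-correlation
    screen (both adjusted for the covariates), refines the intersection by
    joint-model backward elimination, and splits the survivors by their
    entropy-correlation sign.
    """
    covariates = list(covariates or [])
    prog = prognostic_gene_screen(matrix, cohort, covariates, horizon, alpha)
    cov_frame = cohort.data[covariates] if covariates else None
    corr = entropy_correlated_genes(matrix, entropies, cov_frame, alpha)
    candidates = [g for g in matrix.index if g in prog.index and g in corr.index]
    if not candidates:
        raise EmptySignatureError(
            "no gene is both prognostic and entropy-correlated at "
            f"alpha={alpha}"
        )
    refined = backward_multivariate_refine(matrix, cohort, candidates, horizon, alpha)
    pos = tuple(g for g in refined if corr.loc[g, "sign"] > 0)
    neg = tuple(g for g in refined if corr.loc[g, "sign"] < 0)
    provenance = {
        "alpha": alpha,
        "horizon": horizon,
        "covariates": covariates,
        "n_samples": len(cohort),
        "n_events_at_horizon": int(
            (censor_at(cohort, horizon) if horizon else cohort).n_events
        ),
        "n_prognostic": int(len(prog)),
        "n_entropy_correlated": int(len(corr)),
        "n_intersection": len(candidates),
        "n_refined": len(refined),
    }
    return Signature(positive_genes=pos, negative_genes=neg, provenance=provenance)


def overlap_resampling_test(
    list_a,
    list_b,
    universe,
    B: int = 100_000,
    seed: int | None = None,
) -> float:
    """Permutation p-value for the overlap of two gene lists.

    Resamples size-matched sets uniformly from the universe and counts how
    often their overlap reaches the observed one:
    p = (1 + #{overlap >= observed}) / (B + 1).
    """
    universe = list(dict.fromkeys(universe))
    n = len(universe)
    if n == 0:
        raise ValueError("empty universe")
    set_u = set(universe)
    a = set(list_a)
    b = set(list_b)
    if not a <= set_u or not b <= set_u:
        raise ValueError("lists must be subsets of the universe")
    observed = len(a & b)
    ka, kb = len(a), len(b)
    if ka == 0 or kb == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(B, int(2e7 // max(n, 1))))
    done = 0
    while done < B:
        m = min(chunk, B - done)
        # random size-matched subsets via partial argsort of uniform keys
        keys_a = rng.random((m, n))
        keys_b = rng.random((m, n))
        sel_a = np.argpartition(keys_a, ka - 1, axis=1)[:, :ka]
        sel_b = np.argpartition(keys_b, kb - 1, axis=1)[:, :kb]
        mask_a = np.zeros((m, n), dtype=bool)
        np.put_along_axis(mask_a, sel_a, True, axis=1)
        mask_b = np.zeros((m, n), dtype=bool)
        np.put_along_axis(mask_b, sel_b, True, axis=1)
        overlap = (mask_a & mask_b).sum(axis=1)
        hits += int((overlap >= observed).sum())
        done += m
    return (1 + hits) / (B + 1)


def _align_cohort(matrix: pd.DataFrame, cohort: SurvivalCohort) -> SurvivalCohort:
    samples = list(matrix.columns)
    if not set(samples).issubset(cohort.data.index):
        missing = sorted(set(samples) - set(cohort.data.index))
        raise AlignmentError(
            f"cohort lacks {len(missing)} matrix sample(s), e.g. {missing[:5]}"
        )
    return SurvivalCohort(cohort.data.loc[samples])
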
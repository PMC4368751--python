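"""Mixtures of expression profiles and super-additivity of signalling entropy.

A 50:50 in-silico mixture of two homogeneous cell populations is the
midpoint (x + y)/2 of their log-normalised profiles.  Signalling entropy is
*super-additive* at a pair (x, y) when

    SR((x + y)/2)  >  (SR(x) + SR(y)) / 2,

i.e. the mixture is more entropic than the average of its constituents.
When super-additivity holds over the admissible profile domain, mixtures
are elevated relative to homogeneous samples on average, which is what makes
signalling entropy a correlate of intra-sample heterogeneity.  This module
enumerates all pairwise mixtures of a profile panel, classifies each pair,
summarises the panel with a paired two-tailed Wilcoxon signed-rank test,
and evaluates the two-term sign expression

    sign(1 - 1/b + 2/a) + sign(1 - a + 2b)

whose value 2 certifies super-additivity in the two-parameter reduction of
the profile pair.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .entropy import ExpressionProfile, max_entropy_rate, profile_vector, signalling_entropy
from .errors import UndefinedTestError
from .interactome import InteractomeGraph

logger = logging.getLogger(__name__)

#: strictness tolerance for the super-additivity inequality
STRICT_TOL = 1e-12


@dataclass(frozen=True)
class SuperadditivityResult:
    verdict: str  # "superadditive" | "equal" | "subadditive"
    entropy_x: float
    entropy_y: float
    entropy_mixture: float


@dataclass(frozen=True)
class MixtureSweepResult:
    """All-pairs mixture sweep over a panel of homogeneous profiles."""

    pairs: pd.DataFrame = field(repr=False)  # id_x, id_y, entropies, verdict
    homogeneous: pd.Series = field(repr=False)  # per-profile SR
    wilcoxon_statistic: float
    wilcoxon_p: float
    pairing: str

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def fraction_superadditive(self) -> float:
        return float((self.pairs["verdict"] == "superadditive").mean())

    def summary(self) -> dict:
        return {
            "n_profiles": int(len(self.homogeneous)),
            "n_pairs": int(self.n_pairs),
            "fraction_superadditive": self.fraction_superadditive,
            "wilcoxon_statistic": self.wilcoxon_statistic,
            "wilcoxon_p": self.wilcoxon_p,
            "wilcoxon_pairing": self.pairing,
        }


def mix_profiles(x, y, w: float = 0.5, mode: str = "log") -> pd.Series:
    """Weighted mixture w*x + (1-w)*y of two profiles.

    ``mode="log"`` (default) mixes in the log-normalised domain where the
    super-additivity theory is stated.  ``mode="linear"`` emulates physical
    cell mixing by averaging antilogs: log(w*exp(x) + (1-w)*exp(y)).
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError("mixing weight must lie in [0, 1]")
    xs = x.values if isinstance(x, ExpressionProfile) else pd.Series(x)
    ys = y.values if isinstance(y, ExpressionProfile) else pd.Series(y)
    if not xs.index.equals(ys.index):
        if set(xs.index) != set(ys.index):
            raise ValueError("profiles are defined over different gene sets")
        ys = ys.reindex(xs.index)
    if mode == "log":
        return w * xs + (1.0 - w) * ys
    if mode == "linear":
        return np.log(w * np.exp(xs) + (1.0 - w) * np.exp(ys))
    raise ValueError(f"unknown mixing mode {mode!r}")


def check_superadditivity(
    graph: InteractomeGraph, x, y, tol: float = STRICT_TOL, mode: str = "log"
) -> SuperadditivityResult:
    """Classify one pair as superadditive / equal / subadditive."""
    max_rate = max_entropy_rate(graph)
    sx = signalling_entropy(graph, x, _max_rate=max_rate).normalised_entropy
    sy = signalling_entropy(graph, y, _max_rate=max_rate).normalised_entropy
    xv = pd.Series(profile_vector(graph, x), index=list(graph.nodes))
    yv = pd.Series(profile_vector(graph, y), index=list(graph.nodes))
    sm = signalling_entropy(
        graph, mix_profiles(xv, yv, 0.5, mode=mode), _max_rate=max_rate
    ).normalised_entropy
    diff = sm - 0.5 * (sx + sy)
    if abs(diff) <= tol:
        verdict = "equal"
    elif diff > 0:
        verdict = "superadditive"
    else:
        verdict = "subadditive"
    return SuperadditivityResult(verdict, sx, sy, sm)


def pairwise_sweep(
    graph: InteractomeGraph,
    profiles: list[ExpressionProfile],
    tol: float = STRICT_TOL,
    mode: str = "log",
    pairing: str = "per_profile",
) -> MixtureSweepResult:
    """Evaluate every unordered pair of a profile panel (m profiles ->
    m(m-1)/2 mixtures).

    The Wilcoxon comparison of mixed vs homogeneous entropy supports two
    pairings: ``"per_profile"`` (default) pairs each profile's entropy with
    the mean entropy of all mixtures involving it, one difference per
    profile; ``"per_pair"`` pairs each mixture with the mean entropy of its
    two constituents, one difference per pair.
    """
    if len(profiles) < 2:
        raise ValueError("need at least 2 profiles")
    if pairing not in ("per_profile", "per_pair"):
        raise ValueError(f"unknown pairing {pairing!r}")

    max_rate = max_entropy_rate(graph)
    ids = []
    vecs = []
    for k, p in enumerate(profiles):
        pid = p.sample_id if isinstance(p, ExpressionProfile) else f"profile_{k}"
        ids.append(pid)
        vecs.append(profile_vector(graph, p))
    if len(set(ids)) != len(ids):
        raise ValueError("profile sample_ids must be unique")
    homo = {
        pid: signalling_entropy(graph, v, sample_id=pid, _max_rate=max_rate).normalised_entropy
        for pid, v in zip(ids, vecs)
    }

    rows = []
    mix_by_profile: dict[str, list[float]] = {pid: [] for pid in ids}
    for (ia, va), (ib, vb) in itertools.combinations(zip(ids, vecs), 2):
        if mode == "log":
            mv = 0.5 * (va + vb)
        else:
            mv = np.log(0.5 * (np.exp(va) + np.exp(vb)))
        sm = signalling_entropy(graph, mv, _max_rate=max_rate).normalised_entropy
        diff = sm - 0.5 * (homo[ia] + homo[ib])
        verdict = (
            "equal" if abs(diff) <= tol
            else "superadditive" if diff > 0
            else "subadditive"
        )
        rows.append(
            {
                "id_x": ia,
                "id_y": ib,
                "entropy_x": homo[ia],
                "entropy_y": homo[ib],
                "entropy_mixture": sm,
                "verdict": verdict,
            }
        )
        mix_by_profile[ia].append(sm)
        mix_by_profile[ib].append(sm)

    pairs = pd.DataFrame(rows)
    if pairing == "per_profile":
        diffs = np.array([np.mean(mix_by_profile[pid]) - homo[pid] for pid in ids])
    else:
        diffs = (
            pairs["entropy_mixture"]
            - 0.5 * (pairs["entropy_x"] + pairs["entropy_y"])
        ).to_numpy()
    stat, p = paired_wilcoxon(diffs)
    return MixtureSweepResult(
        pairs=pairs,
        homogeneous=pd.Series(homo, name="normalised_entropy"),
        wilcoxon_statistic=stat,
        wilcoxon_p=p,
        pairing=pairing,
    )


def sign_condition(a: float, b: float) -> int:
    """Two-term sign expression certifying super-additivity; value in
    {-2, 0, 2}, with 2 meaning both inequalities hold.

    Evaluates sign(1 - 1/b + 2/a) + sign(1 - a + 2b) with sign(0) := 0.
    """
    if a <= 0 or b <= 0:
        raise ValueError("a and b must be positive")
    return int(np.sign(1.0 - 1.0 / b + 2.0 / a) + np.sign(1.0 - a + 2.0 * b))


def sign_condition_grid(
    a_range: tuple[float, float] = (0.01, 20.0),
    b_range: tuple[float, float] = (0.01, 20.0),
    n: int = 2000,
) -> dict:
    """Evaluate the sign condition on an n x n equally incremented grid.

    Returns the per-cell values (int8 array, a varies along axis 0) and the
    fraction of cells evaluating to 2.
    """
    if n < 2 and not (a_range[0] == a_range[1] and b_range[0] == b_range[1]):
        raise ValueError("n must be >= 2")
    if min(a_range) <= 0 or min(b_range) <= 0:
        raise ValueError("ranges must be positive")
    a = np.linspace(a_range[0], a_range[1], max(n, 1))
    b = np.linspace(b_range[0], b_range[1], max(n, 1))
    aa = a[:, None]
    bb = b[None, :]
    vals = (np.sign(1.0 - 1.0 / bb + 2.0 / aa) + np.sign(1.0 - aa + 2.0 * bb)).astype(np.int8)
    return {
        "a": a,
        "b": b,
        "values": vals,
        "fraction_superadditive": float((vals == 2).mean()),
    }


def paired_wilcoxon(differences, alternative: str = "two-sided") -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test on precomputed differences.

    Zero differences are dropped; ties in the absolute values are
    mid-ranked.  The returned statistic V is the sum of the ranks of the
    positive differences.  The p-value uses exact enumeration of the 2^n
    sign patterns when n <= 25 and the absolute differences are tie-free,
    and a normal approximation with continuity correction otherwise.
    """
    if alternative != "two-sided":
        raise ValueError("only the two-sided alternative is supported")
    d = np.asarray(differences, dtype=np.float64)
    d = d[d != 0.0]
    n = d.size
    if n == 0:
        raise UndefinedTestError("all differences are zero")
    ranks = scipy.stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    has_ties = np.unique(np.abs(d)).size < n
    method = "exact" if (n <= 25 and not has_ties) else "approx"
    res = scipy.stats.wilcoxon(
        d, alternative="two-sided", correction=(method == "approx"), method=method
    )
    return v, float(res.pvalue)
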
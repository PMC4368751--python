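"""Synthetic networks, tissue panels and survival cohorts.

The analyses assume three kinds of input that real studies obtain from
public repositories: an interactome, a panel of homogeneous tissue
expression profiles with distinct active gene modules, and survival cohorts
whose hazard depends on per-sample scores or genes.  This module generates
all three with the statistical structure those analyses rely on, fully
determined by an integer seed, and emits a ground-truth manifest so
recovery can be scored automatically.

Defaults emulate the study conditions: a 2000-gene scale-free interactome,
33 tissue profiles whose active modules are disjoint connected subgraphs
(the regime in which mixtures are super-additive), and exponential
proportional-hazards cohorts with independent exponential censoring.
Expression levels are on a log2-microarray-like scale (baseline around 2,
active modules around 8).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .entropy import ExpressionProfile
from .errors import SigentropyError
from .interactome import InteractomeGraph, restrict_and_validate
from .survival import SurvivalCohort

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NetworkConfig:
    """Random-graph settings for the synthetic interactome."""

    n_genes: int = 2000
    model: str = "barabasi_albert"  # or "erdos_renyi"
    ba_m: int = 3
    er_p: float = 0.005


@dataclass(frozen=True)
class TissueConfig:
    """Homogeneous tissue panel: distinct active modules on the network."""

    n_tissues: int = 33
    module_size: int = 50
    module_overlap: float = 0.0
    active_level: float = 8.0
    baseline_level: float = 2.0
    noise_sd: float = 0.5


@dataclass(frozen=True)
class CohortConfig:
    """Survival cohort with planted entropy-correlated prognostic genes.

    Each planted gene is an independent standard-normal signal entering the
    log-hazard with coefficient ``beta`` (sign per gene); the latent
    heterogeneity score returned as ``entropies`` is the signed average of
    the planted genes plus noise, so planted genes are simultaneously
    prognostic and entropy-correlated while remaining mutually independent.
    """

    n_samples: int = 300
    n_genes: int = 100
    n_positive: int = 5
    n_negative: int = 3
    beta: float = 1.0
    entropy_noise_sd: float = 0.5
    censor_rate: float = 0.3
    base_hazard: float = 0.15
    covariate_effect: float = 0.3  # log-HR of the binary covariate


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    tissues: TissueConfig = field(default_factory=TissueConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)


@dataclass(frozen=True)
class CohortData:
    expression: pd.DataFrame = field(repr=False)  # genes x samples
    cohort: SurvivalCohort = field(repr=False)
    entropies: pd.Series = field(repr=False)  # latent heterogeneity score
    manifest: dict = field(repr=False)


def _gene_labels(n: int) -> list[str]:
    width = len(str(n - 1))
    return [f"g{i:0{width}d}" for i in range(n)]


def make_network(config: NetworkConfig = NetworkConfig(), seed: int = 0) -> InteractomeGraph:
    """Generate a validated synthetic interactome.

    Draws the requested random graph, keeps the largest connected
    component, and closes one triangle if the component happens to be
    bipartite, so the output always satisfies the walk preconditions.
    """
    n = config.n_genes
    if n < 3:
        raise ValueError("need at least 3 genes")
    for attempt in range(100):
        g_seed = int(np.random.default_rng((seed, attempt)).integers(2**31))
        if config.model == "barabasi_albert":
            if config.ba_m < 1 or config.ba_m >= n:
                raise SigentropyError("inadmissible preferential-attachment degree")
            g = nx.barabasi_albert_graph(n, config.ba_m, seed=g_seed)
        elif config.model == "erdos_renyi":
            g = nx.erdos_renyi_graph(n, config.er_p, seed=g_seed)
        else:
            raise ValueError(f"unknown network model {config.model!r}")
        components = sorted(nx.connected_components(g), key=len, reverse=True)
        if not components or len(components[0]) < 3:
            continue
        giant = g.subgraph(components[0]).copy()
        if nx.is_bipartite(giant):
            # close a triangle on a node with >= 2 neighbours
            u = max(giant.nodes, key=giant.degree)
            v, w = sorted(giant.neighbors(u))[:2]
            giant.add_edge(v, w)
        labels = _gene_labels(n)
        mapping = {node: labels[node] for node in giant.nodes}
        giant = nx.relabel_nodes(giant, mapping)
        return restrict_and_validate((tuple(e) for e in giant.edges()), None)
    raise SigentropyError(
        "could not generate a usable network in 100 attempts; "
        "check the model parameters"
    )


def make_tissue_profiles(
    graph: InteractomeGraph,
    config: TissueConfig = TissueConfig(),
    seed: int = 0,
) -> list[ExpressionProfile]:
    """Homogeneous tissue profiles with distinct active modules.

    Each tissue's active module is a connected subgraph grown breadth-first
    from a random seed gene; with ``module_overlap=0`` modules are pairwise
    disjoint.  Module genes get ``active_level`` plus Gaussian noise, the
    rest ``baseline_level`` plus noise; values are truncated below at
    ``baseline_level/10`` to stay strictly positive without breaking seed
    determinism.
    """
    rng = np.random.default_rng((seed, 1))
    n = graph.n_nodes
    if config.module_overlap == 0.0 and config.n_tissues * config.module_size > n:
        raise SigentropyError(
            f"cannot pack {config.n_tissues} disjoint modules of "
            f"{config.module_size} genes into {n} genes"
        )
    if not 0.0 <= config.module_overlap <= 1.0:
        raise ValueError("module_overlap must lie in [0, 1]")
    if not config.active_level > config.baseline_level > 0:
        raise ValueError("need active_level > baseline_level > 0")

    gnx = graph.to_networkx()
    nodes = list(graph.nodes)
    used: set[str] = set()
    modules: list[list[str]] = []
    for t in range(config.n_tissues):
        module = _grow_module(gnx, nodes, used, config, rng)
        if len(module) < config.module_size:
            raise SigentropyError(
                f"could not grow module {t} to {config.module_size} genes"
            )
        modules.append(module)
        used.update(module)

    floor = config.baseline_level / 10.0
    profiles = []
    for t, module in enumerate(modules):
        values = np.full(n, config.baseline_level)
        idx = [graph.index(g) for g in module]
        values[idx] = config.active_level
        if config.noise_sd > 0:
            values = values + rng.normal(0.0, config.noise_sd, n)
        values = np.maximum(values, floor)
        profiles.append(
            ExpressionProfile(
                sample_id=f"tissue_{t:02d}",
                values=pd.Series(values, index=nodes),
            )
        )
    return profiles


def _grow_module(gnx, nodes, used, config, rng) -> list[str]:
    """Grow one localised module breadth-first from a random free seed.

    The search may traverse genes claimed by earlier modules (so packing
    succeeds at high occupancy) but claims them for this module only with
    probability ``module_overlap``; with overlap 0 modules are disjoint."""
    free = [g for g in nodes if g not in used]
    if not free:
        return []
    start = free[int(rng.integers(len(free)))]
    module = [start]
    visited = {start}
    frontier = [start]
    while frontier and len(module) < config.module_size:
        u = frontier.pop(0)
        for v in sorted(gnx.neighbors(u)):
            if v in visited:
                continue
            visited.add(v)
            frontier.append(v)
            if v in used and rng.random() >= config.module_overlap:
                continue  # traverse but do not claim
            module.append(v)
            if len(module) == config.module_size:
                break
    return module


def exponential_censoring_rate(hazards: np.ndarray, censor_rate: float) -> float:
    """Exponential censoring intensity c with mean censored fraction
    mean(c / (c + h_i)) equal to ``censor_rate``."""
    if not 0.0 < censor_rate < 1.0:
        raise ValueError("censor_rate must lie strictly between 0 and 1")

    def frac(log_c):
        c = np.exp(log_c)
        return float(np.mean(c / (c + hazards))) - censor_rate

    lo, hi = np.log(hazards.min()) - 20, np.log(hazards.max()) + 20
    return float(np.exp(brentq(frac, lo, hi)))


def simulate_survival(
    log_hazard: np.ndarray,
    censor_rate: float,
    base_hazard: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential proportional-hazards event times with independent
    exponential censoring tuned to the target censoring fraction."""
    h = base_hazard * np.exp(np.asarray(log_hazard, dtype=float))
    t_event = rng.exponential(1.0 / h)
    c = exponential_censoring_rate(h, censor_rate)
    t_cens = rng.exponential(1.0 / c, size=h.size)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return time, event


def make_cohort(config: CohortConfig = CohortConfig(), seed: int = 0) -> CohortData:
    """Survival cohort with planted entropy-correlated prognostic genes.

    Returns expression (genes x samples), the survival cohort (with a
    binary ``er`` covariate), the latent heterogeneity score standing in
    for per-sample signalling entropy, and a manifest naming the planted
    genes, their signs and the true coefficients.
    """
    rng = np.random.default_rng((seed, 2))
    n, p = config.n_samples, config.n_genes
    k = config.n_positive + config.n_negative
    if k > p:
        raise ValueError("more planted genes than genes")
    genes = _gene_labels(p)
    samples = [f"s{i:04d}" for i in range(n)]

    G = rng.normal(0.0, 1.0, size=(p, n))
    signs = np.array([1] * config.n_positive + [-1] * config.n_negative)
    planted = genes[:k]

    # latent heterogeneity score: signed, unit-variance average of the
    # planted signals; stands in for per-sample signalling entropy
    signed_sum = (signs[:, None] * G[:k]).sum(axis=0)
    latent = signed_sum / np.sqrt(k)
    entropies = latent + rng.normal(0.0, config.entropy_noise_sd, n)

    covariate = rng.integers(0, 2, n)  # e.g. receptor status
    # each planted gene enters the log-hazard with its own coefficient
    # beta * sign, so every one is independently prognostic
    log_hazard = config.beta * signed_sum + config.covariate_effect * covariate
    time, event = simulate_survival(
        log_hazard, config.censor_rate, config.base_hazard, rng
    )

    expression = pd.DataFrame(G, index=genes, columns=samples)
    cohort = SurvivalCohort(
        pd.DataFrame(
            {
                "time": time,
                "event": event,
                "er": np.where(covariate == 1, "pos", "neg"),
            },
            index=samples,
        )
    )
    manifest = {
        "seed": seed,
        "n_samples": n,
        "n_genes": p,
        "planted_genes": planted,
        "planted_signs": signs.tolist(),
        "true_beta": config.beta,
        "beta_scale": "per-gene log-hazard coefficient beta * sign",
        "covariate_effect": config.covariate_effect,
        "censor_rate_target": config.censor_rate,
        "censor_rate_realised": float(1.0 - event.mean()),
    }
    return CohortData(
        expression=expression,
        cohort=cohort,
        entropies=pd.Series(entropies, index=samples, name="entropy"),
        manifest=manifest,
    )


def make_two_group_cohort(
    n_samples: int = 600,
    hazard_ratio: float = 2.0,
    censor_rate: float = 0.3,
    base_hazard: float = 0.15,
    seed: int = 0,
) -> tuple[SurvivalCohort, pd.Series]:
    """Two equal groups whose hazards differ by a known ratio.

    Returns the cohort and the group labels ("low"/"high"); the high group
    carries log(hazard_ratio) extra log-hazard.
    """
    rng = np.random.default_rng((seed, 3))
    half = n_samples // 2
    group = np.array(["low"] * half + ["high"] * (n_samples - half))
    log_hazard = np.where(group == "high", np.log(hazard_ratio), 0.0)
    time, event = simulate_survival(log_hazard, censor_rate, base_hazard, rng)
    samples = [f"s{i:04d}" for i in range(n_samples)]
    cohort = SurvivalCohort(
        pd.DataFrame({"time": time, "event": event}, index=samples)
    )
    return cohort, pd.Series(group, index=samples, name="group")
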
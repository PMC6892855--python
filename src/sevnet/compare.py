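"""Pairwise comparison of group networks.

Global strength is compared by a permutation test: individuals of the two
groups are pooled and repeatedly regrouped at the original group sizes,
both networks are refit with identical estimator settings, and the
absolute strength difference under each regrouping forms the null
distribution.  Structural similarity is summarized by the Spearman rank
correlation of the upper-triangle edge weights (zeros included) and the
Jaccard index of the edge sets.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .binarize import BinaryMatrix
from .estimation import (
    IsingNetwork,
    binarize_network,
    fit_ising,
    fit_ising_drop_constant,
    global_strength,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NCTResult:
    observed_strengths: tuple[float, float]
    observed_difference: float
    n_permutations: int
    permutation_differences: np.ndarray
    p_value: float
    seed: int | None
    n_constant_node_events: int = 0


@dataclass(frozen=True)
class SimilarityResult:
    spearman_rho: float
    jaccard: float
    n_edge_pairs: int


def _coerce_values(data) -> np.ndarray:
    if isinstance(data, BinaryMatrix):
        return data.values
    return np.asarray(data)


def nct_global_strength(
    binary_a,
    binary_b,
    n_permutations: int = 10000,
    seed: int | None = None,
    gamma: float = 0.25,
    rule: str = "AND",
    n_lambda: int = 100,
    lambda_ratio: float = 0.01,
    unweighted: bool = False,
) -> NCTResult:
    """Permutation test of the global-strength difference between two groups.

    With ``unweighted=True`` strength is the edge count of the binarized
    network (the robustness re-analysis).  A permutation that makes a node
    constant drops that node for that fit only; the event count is
    reported.  The p-value uses the add-one estimator
    ``(1 + #{|d_perm| >= |d_obs|}) / (1 + B)``, so its lower bound is
    1/(B+1) and it can never be zero.
    """
    a = _coerce_values(binary_a)
    b = _coerce_values(binary_b)
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must share the same node set")
    est = dict(gamma=gamma, rule=rule, n_lambda=n_lambda, lambda_ratio=lambda_ratio)

    def strength(values: np.ndarray) -> tuple[float, int]:
        net, n_dropped = fit_ising_drop_constant(values, **est)
        if unweighted:
            net = binarize_network(net)
        return global_strength(net), n_dropped

    s_a, drop_a = strength(a)
    s_b, drop_b = strength(b)
    if drop_a or drop_b:
        raise ValueError(
            "observed groups contain constant nodes; drop them before the NCT"
        )
    observed = abs(s_a - s_b)

    pooled = np.vstack([a, b])
    # canonical row order: the permutation null is then invariant to the
    # input row order and (for equal sizes) to swapping the group labels
    pooled = pooled[np.lexsort(pooled.T[::-1])]
    n_a = a.shape[0]
    n_total = pooled.shape[0]
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_permutations)
    const_events = 0
    for it in range(n_permutations):
        perm = rng.permutation(n_total)
        sa, da = strength(pooled[perm[:n_a]])
        sb, db = strength(pooled[perm[n_a:]])
        const_events += da + db
        diffs[it] = abs(sa - sb)
    p = (1.0 + np.sum(diffs >= observed - 1e-12)) / (1.0 + n_permutations)
    if const_events:
        logger.info(
            "NCT: %d constant-node events across %d permutations (nodes dropped "
            "per-fit)", const_events, n_permutations
        )
    return NCTResult(
        observed_strengths=(s_a, s_b),
        observed_difference=observed,
        n_permutations=n_permutations,
        permutation_differences=diffs,
        p_value=float(p),
        seed=seed,
        n_constant_node_events=int(const_events),
    )


def _upper_weights(net: IsingNetwork) -> np.ndarray:
    iu = np.triu_indices(net.n_nodes, 1)
    return net.weights[iu]


def edge_weight_correlation(net_a: IsingNetwork, net_b: IsingNetwork) -> float:
    """Spearman rank correlation over all unique-pair edge weights.

    Zero weights (absent edges) are included; midranks handle the heavy
    ties they create.  Returns NaN (with a warning) when either weight
    vector is constant, where rank correlation is undefined.
    """
    if net_a.nodes != net_b.nodes:
        raise ValueError("networks must share the same node set")
    wa, wb = _upper_weights(net_a), _upper_weights(net_b)
    if wa.size < 3:
        raise ValueError("need at least 3 unique node pairs")
    if np.all(wa == wa[0]) or np.all(wb == wb[0]):
        warnings.warn(
            "edge-weight vector constant in one network; Spearman rho undefined",
            stacklevel=2,
        )
        return float("nan")
    rho, _ = stats.spearmanr(wa, wb)
    return float(rho)


def jaccard_index(net_a: IsingNetwork, net_b: IsingNetwork) -> float:
    """|E_A ∩ E_B| / |E_A ∪ E_B| over nonzero-weight edge sets.

    Two empty networks are reported as identical (Jaccard 1); the
    convention is logged because 0/0 has no canonical value.
    """
    if net_a.nodes != net_b.nodes:
        raise ValueError("networks must share the same node set")
    ea, eb = net_a.edge_set(), net_b.edge_set()
    union = ea | eb
    if not union:
        logger.info("both edge sets empty; Jaccard index defined as 1")
        return 1.0
    return len(ea & eb) / len(union)


def similarity(net_a: IsingNetwork, net_b: IsingNetwork) -> SimilarityResult:
    return SimilarityResult(
        spearman_rho=edge_weight_correlation(net_a, net_b),
        jaccard=jaccard_index(net_a, net_b),
        n_edge_pairs=net_a.n_nodes * (net_a.n_nodes - 1) // 2,
    )


@dataclass(frozen=True)
class ComparisonReport:
    """All K(K-1)/2 pairwise group comparisons."""

    networks: dict[str, IsingNetwork]
    strengths: pd.Series
    pairwise: pd.DataFrame       # diff, p_value, rho, jaccard per pair
    nct_results: dict[tuple[str, str], NCTResult]

    def strength_table(self) -> pd.DataFrame:
        """Strength-difference / p-value table (one column per pair)."""
        return self.pairwise[["difference", "p_value"]].T

    def correlation_table(self) -> pd.DataFrame:
        """Lower-triangle matrix of pairwise edge-weight Spearman rho."""
        names = list(self.networks)
        out = pd.DataFrame(np.nan, index=names, columns=names)
        for (a, b), row in self.pairwise.iterrows():
            out.loc[b, a] = row["spearman_rho"]
        return out


def pairwise_comparison_report(
    binaries: dict[str, np.ndarray | BinaryMatrix],
    n_permutations: int = 10000,
    seed: int | None = None,
    gamma: float = 0.25,
    rule: str = "AND",
    n_lambda: int = 100,
    lambda_ratio: float = 0.01,
    nodes: list[str] | None = None,
) -> ComparisonReport:
    """Networks, strengths and all pairwise comparisons for K >= 2 groups."""
    if len(binaries) < 2:
        raise ValueError("need at least two groups")
    est = dict(gamma=gamma, rule=rule, n_lambda=n_lambda, lambda_ratio=lambda_ratio)
    networks = {
        name: fit_ising(_coerce_values(vals), nodes=nodes, **est)
        for name, vals in binaries.items()
    }
    strengths = pd.Series({k: global_strength(v) for k, v in networks.items()})
    ss = np.random.SeedSequence(seed)
    rows = []
    ncts: dict[tuple[str, str], NCTResult] = {}
    names = list(binaries)
    for (na, nb), child in zip(
        combinations(names, 2), ss.spawn(len(names) * (len(names) - 1) // 2)
    ):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        res = nct_global_strength(
            binaries[na], binaries[nb], n_permutations, seed=child_seed, **est
        )
        sim = similarity(networks[na], networks[nb])
        ncts[(na, nb)] = res
        rows.append(
            {
                "group_a": na,
                "group_b": nb,
                "strength_a": res.observed_strengths[0],
                "strength_b": res.observed_strengths[1],
                "difference": res.observed_difference,
                "p_value": res.p_value,
                "spearman_rho": sim.spearman_rho,
                "jaccard": sim.jaccard,
            }
        )
    pairwise = pd.DataFrame(rows).set_index(["group_a", "group_b"])
    return ComparisonReport(
        networks=networks, strengths=strengths, pairwise=pairwise, nct_results=ncts
    )
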
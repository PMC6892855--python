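"""Bootstrap edge-weight accuracy and the unweighted robustness re-analysis.

Nonparametric bootstrap: resample individuals (rows) with replacement at
the original n, re-estimate the whole network per resample, and summarize
each edge by its percentile confidence interval and selection frequency
(fraction of resamples where the edge survives regularization).
Percentile CIs need not contain the point estimate; both are reported.

Wide, overlapping CIs are the norm in symptom networks, which is why the
analyses can be repeated on unweighted (0/1) networks: if conclusions
survive discarding the weights, they do not hinge on poorly-resolved
weight differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binarize import BinaryMatrix
from .communities import Partition, edge_betweenness_communities, walktrap_communities
from .compare import NCTResult, jaccard_index, nct_global_strength
from .estimation import (
    IsingNetwork,
    binarize_network,
    fit_ising,
    fit_ising_drop_constant,
    global_strength,
)


@dataclass(frozen=True)
class BootstrapResult:
    point: IsingNetwork
    n_boot: int
    level: float
    seed: int | None
    boot_weights: np.ndarray     # (n_boot, p, p)
    ci_lower: np.ndarray         # (p, p)
    ci_upper: np.ndarray         # (p, p)
    selection_frequency: np.ndarray
    n_constant_node_events: int

    def edge_table(self) -> pd.DataFrame:
        """One row per unique node pair: point, CI, selection frequency."""
        nodes = self.point.nodes
        iu = zip(*np.triu_indices(len(nodes), 1))
        rows = []
        for i, j in iu:
            rows.append(
                {
                    "edge": f"{nodes[i]}--{nodes[j]}",
                    "point": self.point.weights[i, j],
                    "ci_lower": self.ci_lower[i, j],
                    "ci_upper": self.ci_upper[i, j],
                    "selection_frequency": self.selection_frequency[i, j],
                }
            )
        return pd.DataFrame(rows).set_index("edge")


def bootstrap_edges(
    data: BinaryMatrix | np.ndarray,
    n_boot: int = 2500,
    level: float = 0.95,
    seed: int | None = None,
    gamma: float = 0.25,
    rule: str = "AND",
    n_lambda: int = 100,
    lambda_ratio: float = 0.01,
    nodes: list[str] | None = None,
) -> BootstrapResult:
    """Bootstrap one group's network.

    Per-resample seeds are derived from the master seed by counter, so
    results are identical regardless of execution order and partial
    reruns are consistent.  A resample with a constant node drops that
    node for that resample (its edges bootstrap as 0); events are counted.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("confidence level must lie in (0, 1)")
    if isinstance(data, BinaryMatrix):
        nodes = list(data.domains)
        values = data.values
    else:
        values = np.asarray(data)
    n, p = values.shape
    est = dict(gamma=gamma, rule=rule, n_lambda=n_lambda, lambda_ratio=lambda_ratio)
    point = fit_ising(values, nodes=nodes, **est)

    master = seed if seed is not None else int(np.random.default_rng().integers(2**31))
    boot_weights = np.empty((n_boot, p, p))
    const_events = 0
    for b in range(n_boot):
        rng = np.random.default_rng(np.random.SeedSequence([master, b]))
        idx = rng.integers(0, n, size=n)
        net, dropped = fit_ising_drop_constant(values[idx], nodes=point.nodes, **est)
        const_events += dropped
        boot_weights[b] = net.weights
    alpha = 1.0 - level
    ci_lower = np.quantile(boot_weights, alpha / 2.0, axis=0)
    ci_upper = np.quantile(boot_weights, 1.0 - alpha / 2.0, axis=0)
    freq = (boot_weights != 0).mean(axis=0)
    return BootstrapResult(
        point=point,
        n_boot=n_boot,
        level=level,
        seed=seed,
        boot_weights=boot_weights,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        selection_frequency=freq,
        n_constant_node_events=const_events,
    )


def ci_overlap_summary(results: dict[str, BootstrapResult]) -> dict[str, pd.DataFrame]:
    """Pairwise CI overlap among each network's present edges.

    Returns per-group the fraction of edge pairs with overlapping CIs
    (high overlap cautions against ranking edges by weight) and a
    per-edge CI-width table.
    """
    if not results:
        raise ValueError("need at least one bootstrap result")
    frac_rows = []
    width_frames = []
    for name, res in results.items():
        table = res.edge_table()
        present = table[table["point"] != 0]
        lows = present["ci_lower"].to_numpy()
        highs = present["ci_upper"].to_numpy()
        n_e = len(present)
        n_pairs = n_e * (n_e - 1) // 2
        overlap = 0
        for i in range(n_e):
            for j in range(i + 1, n_e):
                if lows[i] <= highs[j] and lows[j] <= highs[i]:
                    overlap += 1
        frac_rows.append(
            {
                "group": name,
                "n_edges": n_e,
                "n_edge_pairs": n_pairs,
                "overlap_fraction": overlap / n_pairs if n_pairs else float("nan"),
            }
        )
        widths = table.assign(ci_width=table["ci_upper"] - table["ci_lower"], group=name)
        width_frames.append(widths[["group", "point", "ci_width"]])
    return {
        "overlap": pd.DataFrame(frac_rows).set_index("group"),
        "width": pd.concat(width_frames),
    }


def robustness_reanalysis(
    binaries: dict[str, np.ndarray | BinaryMatrix],
    networks: dict[str, IsingNetwork],
    n_permutations: int = 1000,
    seed: int | None = None,
    gamma: float = 0.25,
    rule: str = "AND",
    n_lambda: int = 100,
    lambda_ratio: float = 0.01,
) -> dict:
    """Re-run strength, NCT, Jaccard and community detection on
    unweighted (0/1) networks, side by side with the weighted results.

    Unweighted global strength degenerates to the edge count.
    """
    unweighted = {g: binarize_network(net) for g, net in networks.items()}
    names = list(networks)
    strengths = pd.DataFrame(
        {
            "weighted": [global_strength(networks[g]) for g in names],
            "unweighted_edges": [global_strength(unweighted[g]) for g in names],
        },
        index=names,
    )
    ss = np.random.SeedSequence(seed)
    rows = []
    ncts: dict[tuple[str, str], NCTResult] = {}
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    for (ga, gb), child in zip(pairs, ss.spawn(len(pairs))):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        res = nct_global_strength(
            binaries[ga],
            binaries[gb],
            n_permutations,
            seed=child_seed,
            gamma=gamma,
            rule=rule,
            n_lambda=n_lambda,
            lambda_ratio=lambda_ratio,
            unweighted=True,
        )
        ncts[(ga, gb)] = res
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "difference_unweighted": res.observed_difference,
                "p_value_unweighted": res.p_value,
                "jaccard": jaccard_index(unweighted[ga], unweighted[gb]),
            }
        )
    communities: dict[str, dict[str, Partition]] = {}
    for g in names:
        communities[g] = {
            "walktrap": walktrap_communities(unweighted[g]),
            "edge_betweenness": edge_betweenness_communities(unweighted[g]),
        }
    return {
        "strengths": strengths,
        "nct": pd.DataFrame(rows).set_index(["group_a", "group_b"]),
        "nct_results": ncts,
        "communities": communities,
        "unweighted_networks": unweighted,
    }
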
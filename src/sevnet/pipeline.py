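"""End-to-end orchestration: generate/load -> binarize -> estimate ->
compare -> communities -> stability, with all artifacts written to disk.

Every number in a report is recomputable from the configuration plus the
master seed; the configuration is echoed verbatim into the output
directory together with a provenance record (config hash, seed, package
version).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .binarize import (
    BinaryMatrix,
    ThresholdScheme,
    apply_thresholds,
    fit_thresholds,
    prevalence_table,
    variance_equality_test,
)
from .cohort import CohortSpec, SymptomCohort, generate_ordinal_cohort, read_cohort, write_cohort
from .communities import (
    Partition,
    community_report,
    edge_betweenness_communities,
    walktrap_communities,
)
from .compare import ComparisonReport, pairwise_comparison_report
from .estimation import fit_ising
from .netio import write_network
from .stability import bootstrap_edges, ci_overlap_summary, robustness_reanalysis

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    """Validated settings for a full pipeline run.

    ``cohort_dir`` loads an existing cohort (items.csv/domains.csv plus
    sidecar); otherwise a synthetic cohort is generated from
    ``synthetic`` overrides applied to the default :class:`CohortSpec`.
    """

    cohort_dir: str | None = None
    synthetic: dict = field(default_factory=dict)
    target_prevalences: float | None = None
    gamma: float = 0.25
    rule: str = "AND"
    n_lambda: int = 100
    lambda_ratio: float = 0.01
    n_permutations: int = 10000
    alpha: float = 0.05
    community_threshold: float = 0.30
    walk_length: int = 4
    n_boot: int = 2500
    ci_level: float = 0.95
    run_stability: bool = True
    run_robustness: bool = True
    seed: int = 0
    output_dir: str = "sevnet_output"

    def validate(self) -> None:
        if self.rule not in ("AND", "OR"):
            raise ValueError("rule must be 'AND' or 'OR'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.ci_level < 1:
            raise ValueError("ci_level must lie in (0, 1)")
        if self.n_permutations < 1 or self.n_boot < 1:
            raise ValueError("n_permutations and n_boot must be >= 1")
        if self.n_lambda < 2 or not 0 < self.lambda_ratio < 1:
            raise ValueError("invalid lambda grid settings")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self) -> str:
        return yaml.safe_dump(asdict(self), sort_keys=True)


@dataclass
class PipelineResult:
    cohort: SymptomCohort
    scheme: ThresholdScheme
    binary: BinaryMatrix
    describe: pd.DataFrame
    prevalences: pd.DataFrame
    variance_tests: pd.DataFrame
    comparison: ComparisonReport
    communities: dict[str, dict[str, Partition]]
    community_tables: dict[str, pd.DataFrame]
    stability: dict | None
    robustness: dict | None


def describe_cohort(
    cohort: SymptomCohort, binary: BinaryMatrix | None = None
) -> pd.DataFrame:
    """Per-group diagnostics: n, raw domain means +- SD, total score, and
    (when a binary matrix is supplied) post-threshold prevalences and the
    count of individuals endorsing 0 / 1 / 2-or-more domains."""
    rows: dict[str, dict] = {}
    for g in range(cohort.n_groups):
        idx = cohort.group_rows(g)
        scores = cohort.domain_scores[idx]
        col: dict[str, object] = {"n": len(idx)}
        total = scores.sum(axis=1)
        col["total_mean"] = total.mean()
        col["total_sd"] = total.std(ddof=1)
        for j, dom in enumerate(cohort.domains):
            col[f"{dom}_mean"] = scores[:, j].mean()
            col[f"{dom}_sd"] = scores[:, j].std(ddof=1)
        if binary is not None:
            vals = binary.group_values(g)
            for j, dom in enumerate(binary.domains):
                col[f"{dom}_prevalence"] = vals[:, j].mean()
            endorsed = vals.sum(axis=1)
            col["endorsed_0"] = int((endorsed == 0).sum())
            col["endorsed_1"] = int((endorsed == 1).sum())
            col["endorsed_2plus"] = int((endorsed >= 2).sum())
        rows[f"group{g + 1}"] = col
    return pd.DataFrame(rows)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages in order, writing artifacts after each stage."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config_text = config.to_yaml()
    (out / "config.yaml").write_text(config_text)
    (out / "provenance.json").write_text(
        json.dumps(
            {
                "config_sha256": hashlib.sha256(config_text.encode()).hexdigest(),
                "seed": config.seed,
                "version": __version__,
            },
            indent=1,
        )
    )
    master = np.random.SeedSequence(config.seed)
    ss_cohort, ss_compare, ss_boot, ss_robust = master.spawn(4)
    est = dict(
        gamma=config.gamma,
        rule=config.rule,
        n_lambda=config.n_lambda,
        lambda_ratio=config.lambda_ratio,
    )

    stage = "cohort"
    try:
        if config.cohort_dir is not None:
            cohort = read_cohort(config.cohort_dir)
        else:
            spec = CohortSpec(**{"seed": _child_seed(ss_cohort), **config.synthetic})
            cohort = generate_ordinal_cohort(spec)
        write_cohort(cohort, out / "cohort")

        stage = "binarize"
        scheme = fit_thresholds(
            cohort.domain_scores,
            cohort.group_labels,
            cohort.domains,
            target_prevalences=config.target_prevalences,
        )
        binary = apply_thresholds(cohort.domain_scores, cohort.group_labels, scheme)
        scheme.to_frame().to_csv(out / "thresholds.csv", index=False,
                                 float_format=_FLOAT_FMT)
        bin_df = pd.DataFrame(binary.values, columns=binary.domains)
        bin_df.insert(0, "group", binary.group_labels + 1)
        bin_df.to_csv(out / "binary.csv", index=False)
        prevalences = prevalence_table(binary)
        prevalences.to_csv(out / "prevalences.csv", float_format=_FLOAT_FMT)
        variance_tests = variance_equality_test(binary)
        variance_tests.to_csv(out / "variance_tests.csv", float_format=_FLOAT_FMT)
        describe = describe_cohort(cohort, binary)
        describe.to_csv(out / "describe.csv", float_format=_FLOAT_FMT)

        stage = "compare"
        groups = {
            f"group{g + 1}": binary.group_values(g) for g in range(binary.n_groups)
        }
        comparison = pairwise_comparison_report(
            groups,
            n_permutations=config.n_permutations,
            seed=_child_seed(ss_compare),
            nodes=binary.domains,
            **est,
        )
        comparison.strengths.to_csv(out / "global_strength.csv",
                                    float_format=_FLOAT_FMT, header=["strength"])
        comparison.pairwise.to_csv(out / "pairwise_comparisons.csv",
                                   float_format=_FLOAT_FMT)
        comparison.correlation_table().to_csv(out / "edge_correlations.csv",
                                              float_format=_FLOAT_FMT)

        stage = "communities"
        communities: dict[str, dict[str, Partition]] = {}
        for name, net in comparison.networks.items():
            communities[name] = {
                "walktrap": walktrap_communities(net, walk_length=config.walk_length),
                "edge_betweenness": edge_betweenness_communities(net),
            }
            write_network(net, out / "networks", name,
                          partition=communities[name]["walktrap"])
        community_tables = community_report(
            {g: communities[g]["walktrap"] for g in communities},
            threshold=config.community_threshold,
        )
        for key, frame in community_tables.items():
            frame.to_csv(out / f"communities_{key}.csv", float_format=_FLOAT_FMT)

        stability = None
        if config.run_stability:
            stage = "stability"
            results = {}
            boot_children = ss_boot.spawn(len(groups))
            for child, (name, vals) in zip(boot_children, groups.items()):
                results[name] = bootstrap_edges(
                    vals,
                    n_boot=config.n_boot,
                    level=config.ci_level,
                    seed=_child_seed(child),
                    nodes=binary.domains,
                    **est,
                )
            overlap = ci_overlap_summary(results)
            overlap["overlap"].to_csv(out / "ci_overlap.csv", float_format=_FLOAT_FMT)
            pd.concat(
                {name: res.edge_table() for name, res in results.items()},
                names=["group", "edge"],
            ).to_csv(out / "bootstrap_edges.csv", float_format=_FLOAT_FMT)
            stability = {"results": results, "overlap": overlap}

        robustness = None
        if config.run_robustness:
            stage = "robustness"
            robustness = robustness_reanalysis(
                groups,
                comparison.networks,
                n_permutations=config.n_permutations,
                seed=_child_seed(ss_robust),
                **est,
            )
            robustness["strengths"].to_csv(out / "robustness_strengths.csv",
                                           float_format=_FLOAT_FMT)
            robustness["nct"].to_csv(out / "robustness_nct.csv",
                                     float_format=_FLOAT_FMT)
    except Exception as exc:  # artifacts from completed stages stay on disk
        raise StageError(stage, exc) from exc

    return PipelineResult(
        cohort=cohort,
        scheme=scheme,
        binary=binary,
        describe=describe,
        prevalences=prevalences,
        variance_tests=variance_tests,
        comparison=comparison,
        communities=communities,
        community_tables=community_tables,
        stability=stability,
        robustness=robustness,
    )
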
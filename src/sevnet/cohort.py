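"""Synthetic multi-group ordinal symptom cohorts with known dependence.

Emulates broadband self-report questionnaire data (items rated 0/1/2)
aggregated into symptom domains, for K severity groups whose raw scores
rise with severity while the latent binary dependence structure is drawn
from a known Ising network.  The generator is the study bench for the
whole pipeline: every downstream stage can be validated against the
planted ground truth.

Generation model, per group g:

1. latent domain states Z ~ Ising(ground truth of group g), one binary
   vector per individual (exact sampler, p ≤ 16);
2. each item k of domain d is an ordinal {0,1,2} draw from a
   cumulative-logit emission with location
   ``difficulty_k + slope * Z[:, d] + severity_offset_g + trait``,
   where ``trait`` is an individual, domain-specific normal deviate — the
   simplest mechanism that yields floor effects in mild groups (most
   scores 0), rising means with severity (which the thresholding stage
   must neutralize) and the within-group score dispersion real broadband
   questionnaires show.  Traits are independent across domains, so all
   cross-domain dependence comes from the planted Ising structure;
3. domain scores are sums of their items.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ising import GroundTruthNetwork, sample_ising_exact

DEFAULT_DOMAINS = [
    "DEP",   # core depressive symptoms
    "NCOG",  # negative cognitions about oneself
    "WOR",   # worrying
    "FEAR",  # fearfulness
    "FAT",   # fatigue
    "PAIN",  # medically unexplained pain
    "EDYS",  # emotion dysregulation
    "SUB",   # substance use
    "ATT",   # attention problems
    "HYP",   # hyperactivity / restlessness
    "IMP",   # impulsiveness
]

# planted community structure: an ADHD-like triple and a
# depression/anxiety-like quadruple; remaining domains are isolated nodes
ADHD_COMMUNITY = ("ATT", "HYP", "IMP")
INTERNALIZING_COMMUNITY = ("DEP", "NCOG", "WOR", "FEAR")


def default_ground_truth(
    adhd_coupling: float = 1.5,
    internalizing_coupling: float = 1.0,
) -> GroundTruthNetwork:
    """Default planted network over the 11 symptom domains.

    All pairs inside the ADHD triple are coupled at ``adhd_coupling``, all
    pairs inside the depression/anxiety quadruple at
    ``internalizing_coupling``; the other four domains are isolated.
    Thresholds are set so that marginal endorsement prevalences are
    moderate (roughly 0.25–0.40) rather than extreme.
    """
    p = len(DEFAULT_DOMAINS)
    idx = {name: i for i, name in enumerate(DEFAULT_DOMAINS)}
    couplings = np.zeros((p, p))
    for comm, value in (
        (ADHD_COMMUNITY, adhd_coupling),
        (INTERNALIZING_COMMUNITY, internalizing_coupling),
    ):
        for a in comm:
            for b in comm:
                if a != b:
                    couplings[idx[a], idx[b]] = value
    thresholds = np.full(p, -0.85)  # isolated nodes: prevalence ≈ 0.30
    for name in ADHD_COMMUNITY:
        thresholds[idx[name]] = -2.1
    for name in INTERNALIZING_COMMUNITY:
        thresholds[idx[name]] = -2.0
    return GroundTruthNetwork(couplings, thresholds, nodes=list(DEFAULT_DOMAINS))


@dataclass(frozen=True)
class CohortSpec:
    """Full recipe for a synthetic cohort; generation is a pure function
    of the spec (including its seed).

    ``ground_truth`` may be a single network shared by all groups (the
    null configuration for group comparisons) or one network per group.
    ``severity_offsets`` are additive shifts on the ordinal-item logit
    scale and must be non-decreasing in group index — group 1 is the
    mildest, group K the most severe.
    """

    n_groups: int = 4
    group_sizes: tuple[int, ...] = (492, 205, 291, 303)
    items_per_domain: tuple[int, ...] | int = 8
    severity_offsets: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5)
    ground_truth: GroundTruthNetwork | tuple[GroundTruthNetwork, ...] = field(
        default_factory=default_ground_truth
    )
    item_slope: float = 4.0
    item_step_gap: float = 2.0
    item_difficulty_range: tuple[float, float] = (-3.5, 0.0)
    trait_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1:
            raise ValueError("n_groups: need at least one group")
        if len(self.group_sizes) != self.n_groups:
            raise ValueError("group_sizes: length must equal n_groups")
        if any(n < 1 for n in self.group_sizes):
            raise ValueError("group_sizes: all group sizes must be >= 1")
        offs = self.severity_offsets
        if len(offs) != self.n_groups:
            raise ValueError("severity_offsets: length must equal n_groups")
        if any(b < a for a, b in zip(offs, offs[1:])):
            raise ValueError("severity_offsets: must be non-decreasing")
        nets = self.networks()
        p = nets[0].n_nodes
        if any(net.n_nodes != p for net in nets):
            raise ValueError("ground_truth: all group networks must share p")
        items = self.items_per_domain
        if isinstance(items, int):
            items = (items,) * p
            object.__setattr__(self, "items_per_domain", items)
        if len(items) != p:
            raise ValueError("items_per_domain: length must equal the number of domains")
        if any(m < 1 for m in items):
            raise ValueError("items_per_domain: every domain needs >= 1 item")

    def networks(self) -> tuple[GroundTruthNetwork, ...]:
        gt = self.ground_truth
        if isinstance(gt, GroundTruthNetwork):
            return (gt,) * self.n_groups
        return tuple(gt)

    @property
    def domains(self) -> list[str]:
        return list(self.networks()[0].nodes)


@dataclass(frozen=True)
class SymptomCohort:
    """Per-individual item scores, domain scores and group labels."""

    item_scores: np.ndarray      # (n, n_items) ints in {0,1,2}
    item_names: list[str]
    domain_map: dict[str, str]   # item name -> domain name
    domain_scores: np.ndarray    # (n, p) item sums
    domains: list[str]
    group_labels: np.ndarray     # (n,) group index, 0-based

    @property
    def n_individuals(self) -> int:
        return self.item_scores.shape[0]

    @property
    def n_groups(self) -> int:
        return int(self.group_labels.max()) + 1

    def group_rows(self, g: int) -> np.ndarray:
        return np.flatnonzero(self.group_labels == g)


def aggregate_domains(
    item_scores: np.ndarray,
    item_names: list[str],
    domain_map: dict[str, str],
    domains: list[str] | None = None,
) -> np.ndarray:
    """Sum item scores into domain scores, per individual.

    Every item must map to exactly one domain; an unmapped item is an
    error (silent dropping would corrupt domain score ranges).
    """
    item_scores = np.asarray(item_scores)
    if item_scores.shape[1] != len(item_names):
        raise ValueError("item_names must match item_scores columns")
    unmapped = [name for name in item_names if name not in domain_map]
    if unmapped:
        raise ValueError(f"items not mapped to any domain: {unmapped}")
    if domains is None:
        seen: list[str] = []
        for name in item_names:
            d = domain_map[name]
            if d not in seen:
                seen.append(d)
        domains = seen
    out = np.zeros((item_scores.shape[0], len(domains)), dtype=np.int64)
    col = {d: j for j, d in enumerate(domains)}
    for k, name in enumerate(item_names):
        out[:, col[domain_map[name]]] += item_scores[:, k]
    return out


def generate_ordinal_cohort(spec: CohortSpec) -> SymptomCohort:
    """Generate a cohort from a :class:`CohortSpec`.

    Deterministic given the spec: one master seed spawns per-group child
    streams, and within a group the latent draw and the item emissions use
    that group's stream in a fixed order.
    """
    nets = spec.networks()
    domains = spec.domains
    p = len(domains)
    items_per_domain = spec.items_per_domain
    assert isinstance(items_per_domain, tuple)

    item_names: list[str] = []
    domain_map: dict[str, str] = {}
    difficulties: list[np.ndarray] = []
    lo, hi = spec.item_difficulty_range
    for d, name in enumerate(domains):
        m = items_per_domain[d]
        # spread item difficulties so domain-score distributions are smooth
        diffs = np.linspace(lo, hi, m) if m > 1 else np.array([(lo + hi) / 2.0])
        difficulties.append(diffs)
        for k in range(m):
            item = f"{name}_i{k + 1}"
            item_names.append(item)
            domain_map[item] = name

    master = np.random.SeedSequence(spec.seed)
    children = master.spawn(spec.n_groups)

    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for g in range(spec.n_groups):
        n_g = spec.group_sizes[g]
        ss_latent, ss_items = children[g].spawn(2)
        z = sample_ising_exact(nets[g], n_g, seed=ss_latent)
        rng = np.random.default_rng(ss_items)
        cols: list[np.ndarray] = []
        for d in range(p):
            trait = rng.normal(0.0, spec.trait_sd, n_g) if spec.trait_sd > 0 else 0.0
            loc = (
                spec.item_slope * z[:, d].astype(float)
                + spec.severity_offsets[g]
                + trait
            )
            for diff in difficulties[d]:
                eta = diff + loc
                p_ge1 = 1.0 / (1.0 + np.exp(-eta))
                p_ge2 = 1.0 / (1.0 + np.exp(-(eta - spec.item_step_gap)))
                u = rng.random(n_g)
                cols.append((u < p_ge1).astype(np.int64) + (u < p_ge2))
        blocks.append(np.column_stack(cols))
        labels.append(np.full(n_g, g, dtype=np.int64))

    item_scores = np.vstack(blocks)
    group_labels = np.concatenate(labels)
    domain_scores = aggregate_domains(item_scores, item_names, domain_map, domains)
    return SymptomCohort(
        item_scores=item_scores,
        item_names=item_names,
        domain_map=domain_map,
        domain_scores=domain_scores,
        domains=domains,
        group_labels=group_labels,
    )


# ---------------------------------------------------------------------------
# on-disk format: two CSV tables plus a JSON sidecar


def write_cohort(cohort: SymptomCohort, directory: str | Path) -> None:
    """Write a cohort as items.csv, domains.csv and cohort_meta.json."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ids = np.arange(cohort.n_individuals)
    items = pd.DataFrame(cohort.item_scores, columns=cohort.item_names)
    items.insert(0, "group", cohort.group_labels + 1)
    items.insert(0, "id", ids)
    items.to_csv(directory / "items.csv", index=False)
    doms = pd.DataFrame(cohort.domain_scores, columns=cohort.domains)
    doms.insert(0, "group", cohort.group_labels + 1)
    doms.insert(0, "id", ids)
    doms.to_csv(directory / "domains.csv", index=False)
    meta = {"domain_map": cohort.domain_map, "domains": cohort.domains}
    (directory / "cohort_meta.json").write_text(json.dumps(meta, indent=1))


def read_cohort(directory: str | Path) -> SymptomCohort:
    directory = Path(directory)
    items = pd.read_csv(directory / "items.csv")
    meta = json.loads((directory / "cohort_meta.json").read_text())
    item_names = [c for c in items.columns if c not in ("id", "group")]
    item_scores = items[item_names].to_numpy(dtype=np.int64)
    group_labels = items["group"].to_numpy(dtype=np.int64) - 1
    domains = meta["domains"]
    domain_scores = aggregate_domains(item_scores, item_names, meta["domain_map"], domains)
    return SymptomCohort(
        item_scores=item_scores,
        item_names=item_names,
        domain_map=meta["domain_map"],
        domain_scores=domain_scores,
        domains=domains,
        group_labels=group_labels,
    )
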
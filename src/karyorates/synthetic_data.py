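"""Synthetic inputs: posterior tree sets, CTMC tip data, karyotype tables.

The generators emulate the structure of a real comparative karyotype
study: a posterior sample of time-calibrated ultrametric trees, haploid
chromosome numbers evolved along them under the fission/fusion/
polyploidy CTMC, binary characters (sex chromosome system, reproductive
mode) under a two-state chain, order/genus taxonomy blocks, and genome
sizes on the Mbp scale of large insect genomes.

Defaults mirror the study regime the package targets: 100 trees of
~100 tips with a root age of 300 MY and per-MY chromosome rates in the
0.004-0.42 band (the high-rate roach clade regime), two-state SCS rates
of 0.002 per MY, a minority of asexual lineages, and genome sizes
log-normally spread over roughly 2 000-18 000 Mbp.

Every generator is a pure function of (config, seed): identical inputs
give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .chrommodel import ChromosomeModel
from .errors import ConfigurationError, DataError
from .karyodata import (
    ASEXUAL,
    MULTI_XY,
    SEXUAL,
    UNKNOWN,
    XO,
    XY,
    KaryotypeRecord,
    PosteriorTreeSet,
    tip_labels,
)

__all__ = [
    "SimulationConfig",
    "simulate_tree_set",
    "ChromosomeSimulation",
    "simulate_chromosomes",
    "BinaryTraitSimulation",
    "simulate_binary_trait",
    "build_karyotype_table",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults for every synthetic input."""

    # tree set
    n_tips: int = 100
    birth_rate: float = 0.03
    death_rate: float = 0.01
    root_age_my: float | None = 300.0
    n_trees: int = 100
    # chromosome model, rates per MY
    rate_fission_per_my: float = 0.385
    rate_fusion_per_my: float = 0.420
    rate_polyploidy_per_my: float = 0.004
    rate_demiploidy_per_my: float = 0.0
    root_chromosome_state: int = 12
    n_min: int = 1
    n_max: int = 50
    # sex chromosome system: two-state chain, 0 = XO, 1 = XY
    scs_q01: float = 0.002
    scs_q10: float = 0.002
    scs_root_state: int = 0
    # reproductive mode: 0 = sexual, 1 = asexual (kept a minority)
    repro_q01: float = 0.001
    repro_q10: float = 0.005
    repro_root_state: int = 0
    # genome size: lognormal in Mbp, optional per-chromosome component
    genome_size_log_mean: float = math.log(6000.0)
    genome_size_log_sd: float = 0.55
    genome_size_per_chromosome_mbp: float = 0.0
    # taxonomy blocks and table degradation
    n_orders: int = 4
    genera_per_order: int = 5
    ambiguity_fraction: float = 0.0
    missing_fractions: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 2:
            raise ConfigurationError("n_tips must be >= 2")
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise ConfigurationError("need birth_rate > 0 and death_rate >= 0")
        rates = (
            self.rate_fission_per_my,
            self.rate_fusion_per_my,
            self.rate_polyploidy_per_my,
            self.rate_demiploidy_per_my,
            self.scs_q01,
            self.scs_q10,
            self.repro_q01,
            self.repro_q10,
        )
        if min(rates) < 0:
            raise ConfigurationError("all rates must be non-negative")
        if not self.n_min <= self.root_chromosome_state <= self.n_max:
            raise ConfigurationError("root chromosome state outside state bounds")
        if not 0 <= self.ambiguity_fraction <= 1:
            raise ConfigurationError("ambiguity_fraction must lie in [0, 1]")
        for key, frac in self.missing_fractions.items():
            if not 0 <= frac <= 1:
                raise ConfigurationError(f"missing fraction for {key!r} outside [0, 1]")

    def chromosome_model(self) -> ChromosomeModel:
        """The true chromosome model, rates per MY."""
        return ChromosomeModel(
            n_min=self.n_min,
            n_max=self.n_max,
            rate_fission=self.rate_fission_per_my,
            rate_fusion=self.rate_fusion_per_my,
            rate_polyploidy=self.rate_polyploidy_per_my,
            rate_demiploidy=self.rate_demiploidy_per_my,
        )


# ---------------------------------------------------------------------------
# Birth-death tree simulation
# ---------------------------------------------------------------------------


def _simulate_one_tree(
    config: SimulationConfig, rng: np.random.Generator, rejection_budget: int = 1000
) -> tuple[list[dict], float]:
    """Forward birth-death run until n_tips lineages are extant.

    Returns the lineage table and the end time.  Runs that go extinct
    are rejected and retried up to ``rejection_budget`` times.
    """
    b, d = config.birth_rate, config.death_rate
    for _ in range(rejection_budget):
        nodes = [
            {"parent": -1, "birth": 0.0, "split": None, "children": [], "dead": None},
            {"parent": -1, "birth": 0.0, "split": None, "children": [], "dead": None},
        ]
        alive = [0, 1]
        t = 0.0
        failed = False
        while len(alive) < config.n_tips:
            k = len(alive)
            t += rng.exponential(1.0 / (k * (b + d)))
            pos = rng.integers(k)
            lineage = alive[pos]
            if rng.uniform() < b / (b + d):
                nodes[lineage]["split"] = t
                for _c in range(2):
                    nodes.append(
                        {
                            "parent": lineage,
                            "birth": t,
                            "split": None,
                            "children": [],
                            "dead": None,
                        }
                    )
                    nodes[lineage]["children"].append(len(nodes) - 1)
                alive[pos] = len(nodes) - 2
                alive.append(len(nodes) - 1)
            else:
                nodes[lineage]["dead"] = t
                alive.pop(pos)
                if not alive:
                    failed = True
                    break
        if failed:
            continue
        # extend past the last event so terminal branches are strictly positive
        w = rng.exponential(1.0 / (config.n_tips * (b + d)))
        t_end = t + rng.uniform(0.0, 1.0) * w if t > 0 else rng.exponential(1.0 / b)
        return nodes, t_end
    raise DataError(
        "birth-death simulation kept going extinct; lower death_rate or n_tips"
    )


def _build_dendropy_tree(
    nodes: list[dict], t_end: float, labels: Sequence[str], ns: dendropy.TaxonNamespace
) -> dendropy.Tree:
    """Assemble the reconstructed (extant-only) tree."""

    def make(i: int):
        info = nodes[i]
        if info["split"] is None:
            if info["dead"] is not None:
                return None
            nd = dendropy.Node()
            nd.edge.length = t_end - info["birth"]
            nd._is_tip = True
            return nd
        kids = [make(c) for c in info["children"]]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            kids[0].edge.length += info["split"] - info["birth"]
            return kids[0]
        nd = dendropy.Node()
        nd.edge.length = info["split"] - info["birth"]
        for k in kids:
            nd.add_child(k)
        return nd

    tops = [make(0), make(1)]
    tops = [x for x in tops if x is not None]
    if len(tops) == 2:
        root = dendropy.Node()
        for x in tops:
            root.add_child(x)
    else:
        root = tops[0]
    tree = dendropy.Tree(taxon_namespace=ns)
    tree.seed_node = root
    tree.is_rooted = True
    leaves = [nd for nd in tree.leaf_node_iter()]
    if len(leaves) != len(labels):
        raise DataError("internal error: extant tip count mismatch")
    for leaf, label in zip(leaves, labels):
        leaf.taxon = ns.require_taxon(label=label)
    return tree


def simulate_tree_set(config: SimulationConfig) -> PosteriorTreeSet:
    """Simulate ``n_trees`` ultrametric birth-death trees with shared labels.

    Each tree has exactly ``n_tips`` extant tips; extinct lineages are
    pruned.  When ``root_age_my`` is set, every tree is rescaled so its
    root depth equals that age (the time-calibration convention); with
    ``root_age_my=None`` trees keep their natural simulated depth.  Tip
    labels are shared across trees and shuffled per tree so topologies
    differ, as in a posterior sample.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed & 0x7FFFFFFF, 11]))
    ns = dendropy.TaxonNamespace()
    base_labels = [f"t{i + 1}" for i in range(config.n_tips)]
    trees = []
    for _ in range(config.n_trees):
        nodes, t_end = _simulate_one_tree(config, rng)
        labels = list(base_labels)
        rng.shuffle(labels)
        tree = _build_dendropy_tree(nodes, t_end, labels, ns)
        if config.root_age_my is not None:
            depth = float(tree.max_distance_from_root())
            factor = config.root_age_my / depth
            for edge in tree.preorder_edge_iter():
                if edge.length is not None:
                    edge.length *= factor
        trees.append(tree)
    return PosteriorTreeSet(trees=trees, labels=frozenset(base_labels))


# ---------------------------------------------------------------------------
# Character simulation along a tree
# ---------------------------------------------------------------------------


@dataclass
class ChromosomeSimulation:
    """Tip states plus the realized typed event history."""

    tip_states: dict[str, int]
    # (child-node postorder index, time from branch start, from, to, type)
    events: list[tuple[int, float, int, int, str]]
    root_state: int

    def replay(self, index) -> dict[str, int]:
        """Re-derive tip states from the event history (consistency check)."""
        state = {index.root: self.root_state}
        by_node: dict[int, list] = {}
        for ev in self.events:
            by_node.setdefault(ev[0], []).append(ev)
        for i in reversed(index.postorder):
            if i == index.root:
                continue
            s = state[index.parent[i]]
            for _, _, frm, to, _ in sorted(by_node.get(i, []), key=lambda e: e[1]):
                if frm != s:
                    raise DataError("inconsistent event history")
                s = to
            state[i] = s
        return {index.tip_label[i]: state[i] for i in index.tip_label}


def _chromosome_moves(
    n: int, model: ChromosomeModel
) -> tuple[list[int], list[float], list[str]]:
    targets, rates, kinds = [], [], []
    if model.rate_fission > 0 and n + 1 <= model.n_max:
        targets.append(n + 1), rates.append(model.rate_fission), kinds.append("fission")
    if model.rate_fusion > 0 and n - 1 >= model.n_min:
        targets.append(n - 1), rates.append(model.rate_fusion), kinds.append("fusion")
    if model.rate_polyploidy > 0 and 2 * n <= model.n_max:
        targets.append(2 * n), rates.append(model.rate_polyploidy), kinds.append("polyploidy")
    if model.rate_demiploidy > 0:
        tgt = math.ceil(1.5 * n)
        if tgt != n and tgt <= model.n_max:
            targets.append(tgt), rates.append(model.rate_demiploidy), kinds.append("demiploidy")
    return targets, rates, kinds


def simulate_chromosomes(
    tree, model: ChromosomeModel, root_state: int, seed: int = 0
) -> ChromosomeSimulation:
    """Exact event-sampling of chromosome numbers down every branch.

    Waiting times are exponential in the current state's total exit
    rate; the event type is drawn categorically.  Rates are interpreted
    per unit of the tree's own branch lengths (pass per-MY rates with an
    MY-scaled tree).
    """
    from .chrommodel import TreeIndex

    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    if not model.n_min <= root_state <= model.n_max:
        raise DataError("root state outside the model's state bounds")
    rng = np.random.default_rng(seed)
    state = {index.root: root_state}
    events: list[tuple[int, float, int, int, str]] = []
    for i in reversed(index.postorder):  # preorder
        if i == index.root:
            continue
        s = state[index.parent[i]]
        t, length = 0.0, index.edge_length[i]
        while True:
            targets, rates, kinds = _chromosome_moves(s, model)
            total = sum(rates)
            if total <= 0:
                break
            t += rng.exponential(1.0 / total)
            if t > length:
                break
            j = rng.choice(len(targets), p=np.asarray(rates) / total)
            events.append((i, t, s, targets[j], kinds[j]))
            s = int(targets[j])
        state[i] = s
    tips = {index.tip_label[i]: state[i] for i in index.tip_label}
    return ChromosomeSimulation(tip_states=tips, events=events, root_state=root_state)


@dataclass
class BinaryTraitSimulation:
    tip_states: dict[str, int]
    events: list[tuple[int, float, int, int, str]]
    root_state: int


def simulate_binary_trait(
    tree, q01: float, q10: float, root_state: int = 0, seed: int = 0
) -> BinaryTraitSimulation:
    """Two-state CTMC simulation (SCS or reproductive mode)."""
    from .chrommodel import TreeIndex

    if q01 < 0 or q10 < 0:
        raise DataError("rates must be non-negative")
    if root_state not in (0, 1):
        raise DataError("root state must be 0 or 1")
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    rng = np.random.default_rng(seed)
    rate = {0: q01, 1: q10}
    state = {index.root: root_state}
    events = []
    for i in reversed(index.postorder):
        if i == index.root:
            continue
        s = state[index.parent[i]]
        t, length = 0.0, index.edge_length[i]
        while True:
            r = rate[s]
            if r <= 0:
                break
            t += rng.exponential(1.0 / r)
            if t > length:
                break
            events.append((i, t, s, 1 - s, f"{s}->{1 - s}"))
            s = 1 - s
        state[i] = s
    tips = {index.tip_label[i]: state[i] for i in index.tip_label}
    return BinaryTraitSimulation(tip_states=tips, events=events, root_state=root_state)


# ---------------------------------------------------------------------------
# Karyotype table assembly
# ---------------------------------------------------------------------------


def build_karyotype_table(
    tip_counts: Mapping[str, int],
    config: SimulationConfig,
    scs_states: Mapping[str, int] | None = None,
    repro_states: Mapping[str, int] | None = None,
    seed: int | None = None,
) -> list[KaryotypeRecord]:
    """Assemble a CSV-writable karyotype table from simulated tip data.

    Tips are assigned to order/genus blocks (sorted labels, contiguous
    blocks).  ``ambiguity_fraction`` of species get a candidate count
    set (true value plus a neighbour within +/-1); per-field missing
    fractions blank SCS, reproductive mode, or genome size.  Genome
    sizes are lognormal with an optional additive per-chromosome
    component.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([(config.seed if seed is None else seed) & 0x7FFFFFFF, 13])
    )
    species = sorted(tip_counts)
    n = len(species)
    n_genera = config.n_orders * config.genera_per_order
    per_genus = max(1, math.ceil(n / n_genera))
    miss = dict(config.missing_fractions)
    records = []
    for i, sp in enumerate(species):
        genus_i = min(i // per_genus, n_genera - 1)
        order_i = genus_i // config.genera_per_order
        count = int(tip_counts[sp])
        counts: frozenset[int] = frozenset([count])
        if config.ambiguity_fraction > 0 and rng.uniform() < config.ambiguity_fraction:
            delta = 1 if count <= config.n_min else int(rng.choice([-1, 1]))
            counts = frozenset([count, max(1, count + delta)])
        scs = UNKNOWN
        if scs_states is not None and sp in scs_states:
            scs = XO if scs_states[sp] == 0 else XY
        if rng.uniform() < miss.get("scs", 0.0):
            scs = UNKNOWN
        mode = UNKNOWN
        if repro_states is not None and sp in repro_states:
            mode = SEXUAL if repro_states[sp] == 0 else ASEXUAL
        if rng.uniform() < miss.get("reproductive_mode", 0.0):
            mode = UNKNOWN
        gs: float | None = float(
            np.exp(rng.normal(config.genome_size_log_mean, config.genome_size_log_sd))
            + config.genome_size_per_chromosome_mbp * count
        )
        if rng.uniform() < miss.get("genome_size", 0.0):
            gs = None
        records.append(
            KaryotypeRecord(
                species=sp,
                genus=f"Genus{genus_i + 1:02d}",
                order=f"Order{order_i + 1}",
                haploid_counts=counts,
                scs=scs,
                reproductive_mode=mode,
                genome_size=gs,
            )
        )
    return records
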
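"""Ancestral states, two-state sex-chromosome models, stochastic mapping.

Chromosome-number ancestral states are reconstructed marginally under a
fixed-rate model (gains, losses, whole-genome duplication), combining a
postorder (pruning) pass with a preorder (outside) pass; fixed rates are
typically the per-tree posterior means from :mod:`karyorates.inference`,
and reconstructions are combined across a posterior tree set by
averaging the probability vectors at the clade's most recent common
ancestor.

Sex-chromosome systems (XO vs XY, with multi-XY collapsed into XY) are
modelled as a two-state all-rates-different (ARD) Markov chain; its
likelihood is the same pruning code restricted to two states.  Realized
transition counts come from stochastic character maps: full histories
sampled conditional on the tip data (ancestor states drawn from the
joint conditional distribution, branch paths by rejection sampling with
a uniformization-bridge fallback).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize

from .chrommodel import (
    Propagator,
    RateMatrix,
    TreeIndex,
    _pruning_partials,
    _resolve_root_prior,
    log_likelihood,
    make_tip_vectors,
)
from .errors import DataError
from .karyodata import MULTI_XY, UNKNOWN, XO, XY

__all__ = [
    "AncestralReconstruction",
    "marginal_ancestral_states",
    "mrca_state",
    "average_mrca_state",
    "Mk2Fit",
    "fit_mk2_ard",
    "mk2_rate_matrix",
    "StochasticMapSummary",
    "stochastic_map",
    "EventCountComparison",
    "count_fusion_fission_events",
]


@dataclass
class AncestralReconstruction:
    """Per-node marginal state distributions on one tree.

    Nodes are keyed by postorder index (see :class:`TreeIndex`); the
    most-probable state breaks ties toward the smaller state.
    """

    index: TreeIndex
    states: list
    probs: np.ndarray  # n_nodes x n_states, rows sum to 1
    map_state: list  # most-probable state per node

    def node_probabilities(self, node: int) -> np.ndarray:
        if not 0 <= node < self.index.n_nodes:
            raise DataError(f"node {node} is not in the tree")
        return self.probs[node]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, columns=[str(s) for s in self.states])
        df.insert(0, "node", np.arange(self.index.n_nodes))
        df.insert(1, "map_state", [str(s) for s in self.map_state])
        return df


def _branch_propagators(index: TreeIndex, prop: Propagator) -> dict[int, np.ndarray]:
    """P(t_edge) for every non-root node, keyed by child node index."""
    return {
        int(i): prop.matrix(index.edge_length[i])
        for i in range(index.n_nodes)
        if index.parent[i] >= 0
    }


def marginal_ancestral_states(
    tree,
    tips: Mapping,
    Q: RateMatrix | np.ndarray,
    root_prior="uniform",
    states: Sequence | None = None,
) -> AncestralReconstruction:
    """Marginal (empirical-Bayes) ancestral reconstruction under fixed Q.

    ``tips`` maps tip label -> count / candidate set / None, or directly
    to a probability vector.  Downward (pruning) conditionals and upward
    (outside) conditionals are combined and normalized per node.
    """
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    A = Q.matrix if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=float)
    if states is None:
        states = Q.states if isinstance(Q, RateMatrix) else list(range(A.shape[0]))
    k = A.shape[0]
    sample = next(iter(tips.values())) if tips else None
    if isinstance(sample, np.ndarray):
        vectors = {t: np.asarray(v, dtype=float) for t, v in tips.items()}
    else:
        vectors = make_tip_vectors(tips, states)
    prop = Propagator(A)
    L, log_scale = _pruning_partials(index, vectors, prop, k)
    if not np.isfinite(log_scale):
        raise DataError("tip data have zero likelihood under this model")
    P = _branch_propagators(index, prop)
    msg = {c: P[c] @ L[c] for c in P}  # child -> message to its parent

    out = np.empty((index.n_nodes, k))
    prior = _resolve_root_prior(root_prior, k, vectors)
    out[index.root] = prior
    for u in reversed(index.postorder):  # preorder
        for c in index.children[u]:
            s = out[u].copy()
            for w in index.children[u]:
                if w != c:
                    s *= msg[w]
            v = P[c].T @ s
            m = v.max()
            out[c] = v / m if m > 0 else v

    probs = out * L
    row_sums = probs.sum(axis=1, keepdims=True)
    if np.any(row_sums <= 0):
        raise DataError("degenerate marginal at some node (zero mass)")
    probs /= row_sums
    # argmax with ties broken toward the smaller state: first max wins
    map_state = [states[int(np.argmax(probs[i]))] for i in range(index.n_nodes)]
    return AncestralReconstruction(index=index, states=list(states), probs=probs, map_state=map_state)


def _mrca_node(index: TreeIndex, tip_names: Sequence[str]) -> int:
    wanted = set(tip_names)
    if not wanted:
        raise DataError("tipset must be non-empty")
    label_to_node = {lab: i for i, lab in index.tip_label.items()}
    missing = wanted - set(label_to_node)
    if missing:
        raise DataError(f"tips not in tree: {sorted(missing)}")
    nodes = [label_to_node[t] for t in wanted]
    if len(nodes) == 1:
        return nodes[0]

    def ancestors(n: int) -> list[int]:
        path = [n]
        while index.parent[path[-1]] >= 0:
            path.append(int(index.parent[path[-1]]))
        return path

    common = set(ancestors(nodes[0]))
    for n in nodes[1:]:
        common &= set(ancestors(n))
    # deepest common ancestor = the one all others are ancestors of
    for n in ancestors(nodes[0]):
        if n in common:
            return n
    raise DataError("no common ancestor found (tree is disconnected?)")


def mrca_state(recon: AncestralReconstruction, tipset: Sequence[str]) -> np.ndarray:
    """Reconstruction vector at the MRCA of ``tipset``."""
    return recon.probs[_mrca_node(recon.index, tipset)]


def average_mrca_state(
    recons: Sequence[AncestralReconstruction], tipset: Sequence[str]
) -> np.ndarray:
    """MRCA vectors averaged across a posterior tree set (pie-chart semantics)."""
    if not recons:
        raise DataError("no reconstructions to average")
    vecs = [mrca_state(r, tipset) for r in recons]
    if any(len(v) != len(vecs[0]) for v in vecs):
        raise DataError("reconstructions disagree on the state space")
    return np.mean(vecs, axis=0)


# ---------------------------------------------------------------------------
# Two-state (XO/XY) all-rates-different model
# ---------------------------------------------------------------------------


def mk2_rate_matrix(q01: float, q10: float) -> np.ndarray:
    return np.array([[-q01, q01], [q10, -q10]], dtype=float)


@dataclass
class Mk2Fit:
    """Per-tree ML fit of the two-state ARD model (rates per MY)."""

    q01: float  # XO -> XY (Y gain)
    q10: float  # XY -> XO (Y loss)
    loglik: float
    boundary: bool = False  # all tips one state: one rate unidentifiable
    n_tips: int = 0


def scs_to_binary(scs_by_tip: Mapping[str, str]) -> dict[str, int]:
    """Collapse SCS states to binary: XO -> 0, XY/multi-XY -> 1.

    Tips with unknown SCS are omitted (to be pruned by the caller).
    """
    out = {}
    for tip, s in scs_by_tip.items():
        if s == XO:
            out[tip] = 0
        elif s in (XY, MULTI_XY):
            out[tip] = 1
        elif s != UNKNOWN:
            raise DataError(f"tip {tip!r}: unknown SCS state {s!r}")
    return out


def _prune_to(tree: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    present = {lf.taxon.label.strip() for lf in tree.leaf_node_iter()}
    if present == keep:
        return tree
    return tree.extract_tree_with_taxa_labels(labels=keep)


def fit_mk2_ard(
    trees: Sequence[dendropy.Tree],
    scs_by_tip: Mapping[str, str],
    exclude: set[str] | frozenset[str] = frozenset(),
) -> tuple[list[Mk2Fit], pd.DataFrame]:
    """ML two-state ARD rates per tree, plus a pooled summary.

    Tips with unknown SCS and tips in ``exclude`` (e.g. parthenogenetic
    lineages) are dropped before fitting.  Rates are per MY (fits run on
    the trees' native branch lengths).  Returns (per-tree fits, summary
    DataFrame with pooled means).
    """
    binary = scs_to_binary(
        {t: s for t, s in scs_by_tip.items() if t not in exclude}
    )
    if len(binary) < 2:
        raise DataError("need at least two tips with known SCS")
    fits: list[Mk2Fit] = []
    for tree in trees:
        present = {lf.taxon.label.strip() for lf in tree.leaf_node_iter()}
        keep = present & set(binary)
        if len(keep) < 2:
            raise DataError("fewer than two SCS-scored tips on a tree")
        pruned = _prune_to(tree, keep)
        index = TreeIndex(pruned)
        vectors = {t: np.eye(2)[binary[t]] for t in keep}
        observed = {binary[t] for t in keep}
        boundary = len(observed) == 1
        if boundary:
            warnings.warn(
                "all tips share one SCS state; one ARD rate is unidentifiable"
            )

        def neg(x):
            ll = log_likelihood(index, vectors, mk2_rate_matrix(x[0], x[1]))
            return -ll if np.isfinite(ll) else 1e10

        depth = float(pruned.max_distance_from_root())
        starts = [(0.5 / depth, 0.5 / depth), (5.0 / depth, 5.0 / depth)]
        best = None
        for x0 in starts:
            res = optimize.minimize(
                neg, np.asarray(x0), method="L-BFGS-B", bounds=[(0.0, None)] * 2
            )
            if best is None or res.fun < best.fun:
                best = res
        fits.append(
            Mk2Fit(
                q01=float(best.x[0]),
                q10=float(best.x[1]),
                loglik=-float(best.fun),
                boundary=boundary,
                n_tips=len(keep),
            )
        )
    summary = pd.DataFrame(
        {
            "parameter": ["q_XO_to_XY", "q_XY_to_XO"],
            "mean": [np.mean([f.q01 for f in fits]), np.mean([f.q10 for f in fits])],
            "median": [
                float(np.median([f.q01 for f in fits])),
                float(np.median([f.q10 for f in fits])),
            ],
        }
    )
    return fits, summary


# ---------------------------------------------------------------------------
# Stochastic mapping
# ---------------------------------------------------------------------------


def _classify_chromosome_event(i: int, j: int) -> str:
    if j == i + 1:
        return "fission"
    if j == i - 1:
        return "fusion"
    if j == 2 * i:
        return "polyploidy"
    if j == ceil(1.5 * i):
        return "demiploidy"
    return "other"


def _event_key(states: Sequence, a: int, b: int) -> str:
    sa, sb = states[a], states[b]
    if isinstance(sa, (int, np.integer)) and isinstance(sb, (int, np.integer)):
        return _classify_chromosome_event(int(sa), int(sb))
    return f"{sa}->{sb}"


def _sample_path_rejection(
    a: int, b: int, t: float, A: np.ndarray, rng: np.random.Generator
) -> list[tuple[float, int, int]] | None:
    """Forward-simulate from state a for time t; None unless it ends at b."""
    events: list[tuple[float, int, int]] = []
    s, clock = a, 0.0
    while True:
        exit_rate = -A[s, s]
        if exit_rate <= 0:
            break
        wait = rng.exponential(1.0 / exit_rate)
        if clock + wait > t:
            break
        clock += wait
        rates = A[s].clip(min=0.0)
        rates[s] = 0.0
        nxt = int(rng.choice(len(rates), p=rates / rates.sum()))
        events.append((clock, s, nxt))
        s = nxt
    return events if s == b else None


def _sample_path_uniformization(
    a: int,
    b: int,
    t: float,
    A: np.ndarray,
    P_t: np.ndarray,
    rng: np.random.Generator,
) -> list[tuple[float, int, int]]:
    """Exact endpoint-conditioned path via the uniformization bridge."""
    mu = float(-A.diagonal().min())
    if mu <= 0 or t <= 0:
        if a != b:
            raise DataError("impossible endpoint pair on a zero-rate branch")
        return []
    k = A.shape[0]
    R = np.eye(k) + A / mu
    target = P_t[a, b]
    if target <= 0:
        raise DataError("endpoint pair has zero transition probability")
    powers = [np.eye(k), R]
    u = rng.uniform() * target
    n = 0
    log_pois = -mu * t
    acc = np.exp(log_pois) * powers[0][a, b]
    while acc < u:
        n += 1
        if len(powers) <= n:
            powers.append(powers[-1] @ R)
        log_pois += np.log(mu * t) - np.log(n)
        acc += np.exp(log_pois) * powers[n][a, b]
        if n > 10000:
            raise DataError("uniformization failed to converge")
    while len(powers) <= n:
        powers.append(powers[-1] @ R)
    # sample the jump chain bridge
    seq = [a]
    for m in range(1, n):
        prev = seq[-1]
        w = R[prev] * powers[n - m][:, b]
        seq.append(int(rng.choice(k, p=w / w.sum())))
    if n >= 1:
        seq.append(b)
    times = np.sort(rng.uniform(0, t, size=n))
    return [
        (float(times[m]), seq[m], seq[m + 1])
        for m in range(n)
        if seq[m] != seq[m + 1]  # drop virtual jumps
    ]


@dataclass
class StochasticMapSummary:
    """Transition counts over sampled character histories.

    ``counts`` has one row per map and one column per transition type;
    ``mean_counts`` is its column mean.  ``node_state_samples`` records
    the sampled state (index into ``states``) at every node per map.
    """

    n_maps: int
    counts: pd.DataFrame
    mean_counts: dict[str, float]
    states: list
    node_state_samples: np.ndarray

    def node_state_frequencies(self) -> np.ndarray:
        """Per-node empirical state frequencies across maps (nodes x states)."""
        k = len(self.states)
        n_nodes = self.node_state_samples.shape[1]
        freq = np.zeros((n_nodes, k))
        for s in range(k):
            freq[:, s] = (self.node_state_samples == s).mean(axis=0)
        return freq


def stochastic_map(
    tree,
    tips: Mapping,
    Q: RateMatrix | np.ndarray,
    n_maps: int = 100,
    seed: int = 0,
    root_prior="uniform",
    states: Sequence | None = None,
    max_rejection_attempts: int = 100,
) -> StochasticMapSummary:
    """Sample full character histories conditional on tip data.

    Per map: node states are drawn from the joint conditional
    distribution (root from its marginal, each child given its parent),
    then each branch path is sampled conditional on its endpoints by
    rejection, falling back to an exact uniformization bridge after
    ``max_rejection_attempts`` failures — never silent truncation.
    """
    if n_maps < 1:
        raise DataError("n_maps must be >= 1")
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    A = Q.matrix if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=float)
    if states is None:
        states = Q.states if isinstance(Q, RateMatrix) else list(range(A.shape[0]))
    k = A.shape[0]
    sample = next(iter(tips.values())) if tips else None
    if isinstance(sample, np.ndarray):
        vectors = {t: np.asarray(v, dtype=float) for t, v in tips.items()}
    else:
        vectors = make_tip_vectors(tips, states)
    prop = Propagator(A)
    L, log_scale = _pruning_partials(index, vectors, prop, k)
    if not np.isfinite(log_scale):
        raise DataError("tip data have zero likelihood under this model")
    P = _branch_propagators(index, prop)
    prior = _resolve_root_prior(root_prior, k, vectors)

    rng = np.random.default_rng(seed)
    preorder = list(reversed(index.postorder))
    root_w = prior * L[index.root]
    root_w = root_w / root_w.sum()

    all_counts: list[dict[str, float]] = []
    node_states = np.empty((n_maps, index.n_nodes), dtype=int)
    for m in range(n_maps):
        st = np.empty(index.n_nodes, dtype=int)
        st[index.root] = rng.choice(k, p=root_w)
        counts: dict[str, float] = {}
        for u in preorder:
            for c in index.children[u]:
                w = P[c][st[u]] * L[c]
                total = w.sum()
                if total <= 0:
                    raise DataError("zero conditional mass while sampling node states")
                st[c] = rng.choice(k, p=w / total)
                # branch path conditional on endpoints
                path = None
                for _ in range(max_rejection_attempts):
                    path = _sample_path_rejection(
                        st[u], st[c], index.edge_length[c], A, rng
                    )
                    if path is not None:
                        break
                if path is None:
                    path = _sample_path_uniformization(
                        int(st[u]), int(st[c]), index.edge_length[c], A, P[c], rng
                    )
                for _, i, j in path:
                    key = _event_key(states, i, j)
                    counts[key] = counts.get(key, 0) + 1
        node_states[m] = st
        all_counts.append(counts)
    counts_df = pd.DataFrame(all_counts).fillna(0.0)
    if counts_df.empty:
        counts_df = pd.DataFrame(index=range(n_maps))
    mean_counts = {c: float(counts_df[c].mean()) for c in counts_df.columns}
    return StochasticMapSummary(
        n_maps=n_maps,
        counts=counts_df,
        mean_counts=mean_counts,
        states=list(states),
        node_state_samples=node_states,
    )


@dataclass
class EventCountComparison:
    """Per-tree mean event counts and the paired fusion-vs-fission test."""

    per_tree: pd.DataFrame  # columns: tree, fusion, fission, polyploidy
    mean_fusions: float
    mean_fissions: float
    t_statistic: float
    pvalue: float
    degenerate: bool = False


def count_fusion_fission_events(
    maps_per_tree: Sequence[StochasticMapSummary],
) -> EventCountComparison:
    """Average event counts per tree and compare fusions vs fissions.

    The comparison is a paired t-test across trees of the per-tree mean
    fusion count against the per-tree mean fission count.  A zero-variance
    non-zero difference is flagged as degenerate instead of reporting a
    meaningless statistic.
    """
    rows = []
    for i, summ in enumerate(maps_per_tree):
        rows.append(
            {
                "tree": i,
                "fusion": summ.mean_counts.get("fusion", 0.0),
                "fission": summ.mean_counts.get("fission", 0.0),
                "polyploidy": summ.mean_counts.get("polyploidy", 0.0),
            }
        )
    per_tree = pd.DataFrame(rows)
    d = per_tree["fusion"].to_numpy() - per_tree["fission"].to_numpy()
    mean_fus = float(per_tree["fusion"].mean())
    mean_fis = float(per_tree["fission"].mean())
    if len(d) < 2 or float(np.std(d, ddof=1) if len(d) > 1 else 0.0) == 0.0:
        if np.allclose(d, 0):
            return EventCountComparison(per_tree, mean_fus, mean_fis, 0.0, 1.0)
        return EventCountComparison(
            per_tree, mean_fus, mean_fis, float("nan"), float("nan"), degenerate=True
        )
    from scipy import stats

    t, p = stats.ttest_rel(per_tree["fusion"], per_tree["fission"])
    return EventCountComparison(per_tree, mean_fus, mean_fis, float(t), float(p))
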
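"""Continuous-time Markov model of haploid chromosome-number evolution.

The state variable is the haploid chromosome number ``n`` on a bounded
integer state space ``n_min..n_max``.  Three (optionally four) event
types move the state:

* fission   ``n -> n+1``  (centromeric split / chromosome gain)
* fusion    ``n -> n-1``  (Robertsonian-type join / chromosome loss)
* polyploidy ``n -> 2n``  (whole-genome duplication)
* demiploidy ``n -> ceil(1.5 n)`` (triploid route; zero-rate by default)

Transitions whose target would leave the state space are dropped: no
probability mass is reflected or remapped, matching the convention of
bounded chromosome-evolution models.  An optional trait-linked variant
doubles the state space with a binary character (e.g. sexual/asexual
reproduction) whose two states carry their own chromosome-rate triples
and flip at rates ``q01``/``q10``.

The likelihood of tip data on a rooted tree is computed by Felsenstein
pruning with per-node rescaling.  The branch propagator ``P(t) = e^{Qt}``
is exposed as :func:`transition_probabilities` (scipy's scaling-and-
squaring Pade expm); the hot path used by ML/MCMC caches one spectral
decomposition of ``Q`` per evaluation and propagates each branch by two
matrix-vector products, falling back to ``expm`` when the eigenbasis is
ill-conditioned.

Rates are estimated on unit-depth trees for identifiability (multiplying
all rates by ``c`` while dividing branch lengths by ``c`` leaves the
likelihood unchanged) and back-transformed to per-MY units afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.linalg import expm

from .errors import DataError

__all__ = [
    "ChromosomeModel",
    "TraitLinkedRates",
    "RateMatrix",
    "build_rate_matrix",
    "transition_probabilities",
    "Propagator",
    "TreeIndex",
    "rescale_to_unit",
    "back_transform_rates",
    "tip_state_vector",
    "make_tip_vectors",
    "log_likelihood",
]


@dataclass(frozen=True)
class TraitLinkedRates:
    """Chromosome rates per binary-trait state plus trait flip rates."""

    rates_state0: tuple[float, float, float]  # fission, fusion, polyploidy
    rates_state1: tuple[float, float, float]
    q01: float
    q10: float


@dataclass(frozen=True)
class ChromosomeModel:
    """State-space bounds and event rates (per unit branch length)."""

    n_max: int
    n_min: int = 1
    rate_fission: float = 0.0
    rate_fusion: float = 0.0
    rate_polyploidy: float = 0.0
    rate_demiploidy: float = 0.0
    trait_linked: TraitLinkedRates | None = None

    def __post_init__(self) -> None:
        if self.n_min < 1:
            raise DataError("n_min must be >= 1")
        if self.n_max <= self.n_min:
            raise DataError("n_max must exceed n_min")
        for name in ("rate_fission", "rate_fusion", "rate_polyploidy", "rate_demiploidy"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be non-negative")
        if self.trait_linked is not None:
            tl = self.trait_linked
            if min(*tl.rates_state0, *tl.rates_state1, tl.q01, tl.q10) < 0:
                raise DataError("trait-linked rates must be non-negative")

    @property
    def n_states(self) -> int:
        k = self.n_max - self.n_min + 1
        return 2 * k if self.trait_linked is not None else k

    @property
    def chromosome_states(self) -> np.ndarray:
        return np.arange(self.n_min, self.n_max + 1)


@dataclass
class RateMatrix:
    """Transition-intensity matrix over the ordered state space.

    ``states`` holds the row labels: haploid numbers, or
    ``(haploid number, trait state)`` pairs for the trait-linked model.
    """

    matrix: np.ndarray
    states: list
    n_min: int
    n_max: int

    @property
    def size(self) -> int:
        return self.matrix.shape[0]

    def state_index(self) -> dict:
        return {s: i for i, s in enumerate(self.states)}

    def to_dataframe(self):
        import pandas as pd

        labels = [str(s) for s in self.states]
        return pd.DataFrame(self.matrix, index=labels, columns=labels)


def _fill_chromosome_block(
    Q: np.ndarray,
    offset: int,
    n_min: int,
    n_max: int,
    fission: float,
    fusion: float,
    polyploidy: float,
    demiploidy: float,
) -> None:
    k = n_max - n_min + 1
    for i, n in enumerate(range(n_min, n_max + 1)):
        row = offset + i
        if n + 1 <= n_max:
            Q[row, offset + i + 1] += fission
        if n - 1 >= n_min:
            Q[row, offset + i - 1] += fusion
        if polyploidy > 0 and 2 * n <= n_max:
            Q[row, offset + (2 * n - n_min)] += polyploidy
        if demiploidy > 0:
            target = ceil(1.5 * n)
            if target != n and target <= n_max:
                Q[row, offset + (target - n_min)] += demiploidy
    del k


def build_rate_matrix(model: ChromosomeModel) -> RateMatrix:
    """Generate the CTMC rate matrix for a chromosome model.

    Off-diagonals hold the event rates; each diagonal is the negated row
    sum.  Transitions whose target exceeds ``n_max`` are dropped (the
    process is absorbed more slowly near the boundary rather than mass
    being remapped).  A polyploidy rate that cannot act from most states
    (``n_max < 2 n_min``) triggers a warning, not an error.
    """
    if model.rate_polyploidy > 0 and model.n_max < 2 * model.n_min:
        warnings.warn(
            "polyploidy is unreachable from every state: n_max < 2*n_min",
            stacklevel=2,
        )
    k = model.n_max - model.n_min + 1
    if model.trait_linked is None:
        Q = np.zeros((k, k))
        _fill_chromosome_block(
            Q,
            0,
            model.n_min,
            model.n_max,
            model.rate_fission,
            model.rate_fusion,
            model.rate_polyploidy,
            model.rate_demiploidy,
        )
        states: list = list(range(model.n_min, model.n_max + 1))
    else:
        tl = model.trait_linked
        Q = np.zeros((2 * k, 2 * k))
        _fill_chromosome_block(
            Q, 0, model.n_min, model.n_max, tl.rates_state0[0], tl.rates_state0[1], tl.rates_state0[2], model.rate_demiploidy
        )
        _fill_chromosome_block(
            Q, k, model.n_min, model.n_max, tl.rates_state1[0], tl.rates_state1[1], tl.rates_state1[2], model.rate_demiploidy
        )
        for i in range(k):
            Q[i, k + i] += tl.q01
            Q[k + i, i] += tl.q10
        states = [(n, t) for t in (0, 1) for n in range(model.n_min, model.n_max + 1)]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return RateMatrix(matrix=Q, states=states, n_min=model.n_min, n_max=model.n_max)


def transition_probabilities(Q: RateMatrix | np.ndarray, t: float) -> np.ndarray:
    """Branch propagator ``P(t) = e^{Qt}``.

    Zero-length branches return the identity exactly.  Row sums are
    accurate to better than 1e-10 (scaling-and-squaring Pade).
    """
    A = Q.matrix if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=float)
    if t < 0:
        raise DataError("branch length must be non-negative")
    if t == 0:
        return np.eye(A.shape[0])
    P = expm(A * t)
    np.clip(P, 0.0, None, out=P)
    return P


class Propagator:
    """Reusable branch propagator for a fixed ``Q``.

    Fast path: one spectral decomposition ``Q = V diag(d) V^{-1}``, then
    ``e^{Qt}`` acts on partial-likelihood vectors with two matrix-vector
    products per branch.  Strongly asymmetric rate regimes make the
    eigenbasis of this non-normal generator ill-conditioned; when the
    decomposition fails its accuracy checks the propagator switches to a
    dyadic scaling-and-squaring scheme: ``expm(Q * 2^-j)`` is computed
    once per power (all powers of the same ``Q`` commute exactly) and a
    branch length is applied through its binary expansion, truncated at
    ``2^-dyadic_bits`` (a relative branch-length error of ~1e-12).
    """

    _DYADIC_BITS = 32

    def __init__(
        self,
        Q: RateMatrix | np.ndarray,
        cond_limit: float = 1e8,
        recon_tol: float = 1e-9,
        rowsum_tol: float = 1e-8,
    ):
        A = Q.matrix if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=float)
        self.A = A
        self._use_eig = False
        self._dyadic: dict[int, np.ndarray] = {}
        self._taylor: list[np.ndarray] | None = None
        self._norm = float(np.max(np.abs(A))) if A.size else 0.0
        k = A.shape[0]
        try:
            d, V = np.linalg.eig(A)
            W = np.linalg.inv(V)
            cond = np.linalg.norm(V, 1) * np.linalg.norm(W, 1)
            recon = np.max(np.abs(np.real((V * d) @ W) - A))
            scale = max(1.0, self._norm)
            with np.errstate(over="ignore", invalid="ignore"):
                # spurious positive eigenvalues overflow exp(); the
                # resulting NaN/inf simply fails the check below
                rowsum_err = np.max(
                    np.abs(np.real(V @ (np.exp(d) * (W @ np.ones(k)))) - 1.0)
                )
            if not np.isfinite(rowsum_err):
                rowsum_err = np.inf
            if (
                np.isfinite(cond)
                and cond < cond_limit
                and recon < recon_tol * scale
                and rowsum_err < rowsum_tol
            ):
                self.d = d
                self.V = V
                self.W = W
                self._use_eig = True
        except np.linalg.LinAlgError:
            pass

    @staticmethod
    def relaxed(Q) -> "Propagator":
        """Sampling-grade propagator: wider eigenbasis tolerances.

        Accepts eigenbases whose propagator error is ~1e-5 in absolute
        entry terms — ample for MCMC/ML exploration, where the strict
        likelihood contract would force the (slower) dyadic path.
        """
        return Propagator(Q, cond_limit=1e13, recon_tol=1e-5, rowsum_tol=1e-5)

    def _dyadic_power(self, j: int) -> np.ndarray:
        """``expm(A * 2^j)``: Taylor at tiny norm, squaring above it."""
        if j not in self._dyadic:
            s = 2.0 ** j
            if s * self._norm <= 0.02:
                if self._taylor is None:
                    A = self.A
                    A2 = A @ A
                    self._taylor = [A, A2, A2 @ A, A2 @ A2]
                A, A2, A3, A4 = self._taylor
                P = (
                    np.eye(A.shape[0])
                    + s * A
                    + (s * s / 2.0) * A2
                    + (s ** 3 / 6.0) * A3
                    + (s ** 4 / 24.0) * A4
                )
            else:
                half = self._dyadic_power(j - 1)
                P = half @ half
            np.clip(P, 0.0, None, out=P)
            self._dyadic[j] = P
        return self._dyadic[j]

    def apply(self, t: float, X: np.ndarray) -> np.ndarray:
        """Return ``e^{Qt} @ X`` (X may be a vector or a matrix of columns)."""
        if t == 0:
            return X.copy()
        if self._use_eig:
            Y = self.W @ X
            if Y.ndim == 1:
                Y = np.exp(self.d * t) * Y
            else:
                Y = np.exp(self.d * t)[:, None] * Y
            out = np.real(self.V @ Y)
        else:
            bits = int(round(t * 2.0 ** self._DYADIC_BITS))
            if bits == 0:
                return X.copy()
            out = X
            j = -self._DYADIC_BITS
            while bits:
                if bits & 1:
                    out = self._dyadic_power(j) @ out
                bits >>= 1
                j += 1
        out = np.asarray(out, dtype=float)
        np.clip(out, 0.0, None, out=out)
        return out

    def matrix(self, t: float) -> np.ndarray:
        if t == 0:
            return np.eye(self.A.shape[0])
        if self._use_eig:
            return self.apply(t, np.eye(self.A.shape[0]))
        P = expm(self.A * t)
        np.clip(P, 0.0, None, out=P)
        return P

    def apply_batch(self, ts: np.ndarray, X: np.ndarray) -> np.ndarray:
        """Column-wise ``e^{Q ts[b]} @ X[:, b]`` for a batch of branches."""
        ts = np.asarray(ts, dtype=float)
        if self._use_eig:
            Y = self.W @ X
            out = np.real(self.V @ (np.exp(np.outer(self.d, ts)) * Y))
        else:
            bits = np.round(ts * 2.0 ** self._DYADIC_BITS).astype(np.int64)
            out = X.astype(float).copy()
            j = -self._DYADIC_BITS
            while np.any(bits):
                mask = (bits & 1).astype(bool)
                if mask.any():
                    out[:, mask] = self._dyadic_power(j) @ out[:, mask]
                bits >>= 1
                j += 1
        np.clip(out, 0.0, None, out=out)
        return out


class TreeIndex:
    """Array view of a rooted tree for fast repeated pruning.

    Nodes are indexed in postorder; tips carry their (stripped) labels.
    """

    def __init__(self, tree: dendropy.Tree):
        nodes = list(tree.postorder_node_iter())
        self.n_nodes = len(nodes)
        self._node_pos = {id(nd): i for i, nd in enumerate(nodes)}
        self.parent = np.full(self.n_nodes, -1, dtype=int)
        self.edge_length = np.zeros(self.n_nodes)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        self.tip_label: dict[int, str] = {}
        self.postorder: list[int] = list(range(self.n_nodes))
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = self._node_pos[id(nd.parent_node)]
                self.parent[i] = p
                self.children[p].append(i)
                self.edge_length[i] = float(nd.edge.length or 0.0)
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label is None:
                    raise DataError("tree has an unlabeled tip")
                self.tip_label[i] = nd.taxon.label.strip()
        self.root = self._node_pos[id(tree.seed_node)]
        self.tips = sorted(self.tip_label)
        if any(self.edge_length < 0):
            raise DataError("tree has negative branch lengths")
        # internal nodes grouped by height above the tips, for batched pruning
        height = np.zeros(self.n_nodes, dtype=int)
        for i in self.postorder:
            if self.children[i]:
                height[i] = 1 + max(height[c] for c in self.children[i])
        self.levels: list[list[int]] = [
            [i for i in self.postorder if height[i] == h and self.children[i]]
            for h in range(1, int(height.max()) + 1 if self.n_nodes > 1 else 1)
        ]

    @property
    def labels(self) -> frozenset[str]:
        return frozenset(self.tip_label.values())

    def total_length(self) -> float:
        return float(self.edge_length.sum())


def rescale_to_unit(tree: dendropy.Tree) -> tuple[dendropy.Tree, float]:
    """Rescale a tree to unit root depth; return (copy, original depth in MY)."""
    depth = float(tree.max_distance_from_root())
    if depth <= 0:
        raise DataError("tree root depth is zero; cannot rescale")
    scaled = tree.clone(depth=1)
    for edge in scaled.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    return scaled, depth


def back_transform_rates(unit_rate: float, scale_factor: float):
    """Convert a per-unit-tree rate to per MY: ``unit_rate / scale_factor``."""
    if scale_factor <= 0:
        raise DataError("scale factor must be positive")
    return unit_rate / scale_factor


def tip_state_vector(
    counts, states: Sequence, missing: bool = False
) -> np.ndarray:
    """Probability vector over the state space for one tip.

    ``counts`` may be a single state, or an iterable of candidate states
    (uniform mass over candidates in range).  ``missing=True`` (or
    ``counts=None``) gives the all-ones vector.
    """
    idx = {s: i for i, s in enumerate(states)}
    v = np.zeros(len(states))
    if missing or counts is None:
        v[:] = 1.0
        return v
    if isinstance(counts, (int, np.integer, str)) or not hasattr(counts, "__iter__"):
        counts = [counts]
    hits = [idx[c] for c in counts if c in idx]
    if not hits:
        raise DataError(
            f"no candidate state of {sorted(counts)} lies in the state space"
        )
    v[hits] = 1.0 / len(hits)
    return v


def make_tip_vectors(
    counts_by_tip: Mapping[str, object], states: Sequence
) -> dict[str, np.ndarray]:
    """Vectorize a mapping tip -> count/candidate-set/None."""
    return {
        tip: tip_state_vector(c, states, missing=c is None)
        for tip, c in counts_by_tip.items()
    }


def _resolve_root_prior(root_prior, k: int, tip_vectors=None) -> np.ndarray:
    if root_prior is None or (isinstance(root_prior, str) and root_prior == "uniform"):
        return np.full(k, 1.0 / k)
    if isinstance(root_prior, str) and root_prior == "observed":
        if not tip_vectors:
            raise DataError("observed root prior requires tip vectors")
        freq = np.zeros(k)
        for v in tip_vectors.values():
            s = v.sum()
            if s > 0:
                freq += v / s
        total = freq.sum()
        if total == 0:
            return np.full(k, 1.0 / k)
        return freq / total
    prior = np.asarray(root_prior, dtype=float)
    if prior.shape != (k,) or prior.min() < 0 or prior.sum() <= 0:
        raise DataError("root prior must be a non-negative length-k vector")
    return prior / prior.sum()


def _pruning_partials(
    index: TreeIndex,
    tip_vectors: Mapping[str, np.ndarray],
    prop: Propagator,
    k: int,
) -> tuple[np.ndarray, float]:
    """Postorder conditional likelihoods with per-node rescaling.

    Returns (partials array n_nodes x k, accumulated log scale).
    """
    L = np.empty((index.n_nodes, k))
    log_scale = 0.0
    for i, label in index.tip_label.items():
        if label not in tip_vectors:
            raise DataError(f"no tip state vector for tip {label!r}")
        v = np.asarray(tip_vectors[label], dtype=float)
        if v.max() <= 0:
            raise DataError(f"tip {label!r} has an all-zero state vector")
        L[i] = v
    for level in index.levels:
        edges = [c for i in level for c in index.children[i]]
        M = prop.apply_batch(index.edge_length[edges], L[edges].T)
        pos = 0
        for i in level:
            nc = len(index.children[i])
            acc = M[:, pos]
            for j in range(1, nc):
                acc = acc * M[:, pos + j]
            pos += nc
            m = acc.max()
            if m <= 0:
                # conflicting certain states: likelihood is exactly zero
                return L, -np.inf
            acc = acc / m
            log_scale += np.log(m)
            L[i] = acc
    return L, log_scale


def log_likelihood(
    tree: dendropy.Tree | TreeIndex,
    tips: Mapping[str, np.ndarray],
    Q: RateMatrix | np.ndarray,
    root_prior="uniform",
    propagator: Propagator | None = None,
) -> float:
    """Felsenstein pruning log-likelihood of tip states under ``Q``.

    ``tips`` maps tip label -> probability vector over the state space
    (see :func:`tip_state_vector`).  ``root_prior`` is ``"uniform"``
    (default), ``"observed"`` (tip-frequency), or an explicit vector.
    """
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    A = Q.matrix if isinstance(Q, RateMatrix) else np.asarray(Q, dtype=float)
    k = A.shape[0]
    prop = propagator if propagator is not None else Propagator(A)
    L, log_scale = _pruning_partials(index, tips, prop, k)
    if not np.isfinite(log_scale):
        return -np.inf
    prior = _resolve_root_prior(root_prior, k, tips)
    lik = float(prior @ L[index.root])
    if lik <= 0:
        return -np.inf
    return np.log(lik) + log_scale


def default_state_space(observed_counts, n_min: int = 1) -> tuple[int, int]:
    """Bounds convention: ``n_min=1`` to ``2*max(observed)+1``.

    One polyploidy step from the largest observed state stays in range.
    """
    mx = 0
    for c in observed_counts:
        if c is None:
            continue
        if hasattr(c, "__iter__"):
            mx = max(mx, max(c))
        else:
            mx = max(mx, int(c))
    if mx < 1:
        raise DataError("no observed counts to bound the state space")
    return n_min, 2 * mx + 1
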
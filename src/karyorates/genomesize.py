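"""Tip rates of chromosome-number change and genome-size regressions.

A tip rate is the difference between a tip's chromosome number and the
most probable chromosome number of its immediate ancestor (from a
marginal ancestral reconstruction), divided by the connecting branch
length — a per-MY rate of recent change.  The directional rate keeps
the sign; the absolute rate averages magnitudes.  Both are averaged
across a posterior tree set.

Regressions of chromosome number (or tip rate) on genome size come in
two flavours: ordinary least squares, and phylogenetic generalized
least squares (PGLS) under a Brownian-motion residual covariance — the
matrix of shared root-to-MRCA branch lengths.  On a star phylogeny with
equal tip depths that covariance is proportional to the identity, so
PGLS collapses to OLS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ancestry import AncestralReconstruction
from .errors import DataError

logger = logging.getLogger("karyorates")

__all__ = [
    "TipRate",
    "tip_rates",
    "RegressionResult",
    "ols_fit",
    "pgls_fit",
    "brownian_covariance",
]


@dataclass
class TipRate:
    """Per-species tip rate averaged over a posterior tree set (per MY)."""

    species: str
    directional_rate: float
    absolute_rate: float
    n_trees: int


def tip_rates(
    recons: Sequence[AncestralReconstruction],
    tip_counts: Mapping[str, float],
) -> list[TipRate]:
    """Tip rates from per-tree reconstructions.

    Per tree and tip: ``(tip value - most probable immediate-ancestor
    state) / branch length``; zero-length terminal branches are skipped
    with a log note.  The directional rate is the mean of signed values
    across trees, the absolute rate the mean of their magnitudes.
    """
    values: dict[str, list[float]] = {t: [] for t in tip_counts}
    for recon in recons:
        index = recon.index
        for node, label in index.tip_label.items():
            if label not in tip_counts:
                continue
            parent = index.parent[node]
            if parent < 0:
                continue
            bl = index.edge_length[node]
            if bl <= 0:
                logger.info(
                    "tip %s: zero-length terminal branch, skipping this tree", label
                )
                continue
            anc = recon.map_state[parent]
            values[label].append((float(tip_counts[label]) - float(anc)) / bl)
    out = []
    for species in sorted(values):
        v = np.asarray(values[species])
        if len(v) == 0:
            continue
        out.append(
            TipRate(
                species=species,
                directional_rate=float(v.mean()),
                absolute_rate=float(np.abs(v).mean()),
                n_trees=len(v),
            )
        )
    return out


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    pvalue_slope: float
    n: int
    method: str

    def report(self) -> str:
        return (
            f"{self.method}: slope={self.slope:.6g}, "
            f"intercept={self.intercept:.6g}, p(slope)={self.pvalue_slope:.4g}, "
            f"n={self.n}"
        )


def ols_fit(x: Sequence[float], y: Sequence[float]) -> RegressionResult:
    """Ordinary least squares of y on x with the standard slope t-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise DataError("OLS needs at least 3 paired finite observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise DataError("OLS inputs must be finite")
    if np.ptp(x) == 0:
        raise DataError("predictor is constant; slope is undefined")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        pvalue_slope=float(fit.pvalues[1]),
        n=len(x),
        method="OLS",
    )


def brownian_covariance(
    tree: dendropy.Tree, taxa: Sequence[str]
) -> np.ndarray:
    """Brownian-motion covariance: shared root-to-MRCA path lengths.

    ``C[i, j]`` is the depth (from the root) of the MRCA of taxa i and j;
    the diagonal holds root-to-tip depths.
    """
    order = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    C = np.zeros((n, n))
    depths: dict[int, float] = {}
    leafsets: dict[int, list[int]] = {}
    for nd in tree.preorder_node_iter():
        d = depths.get(id(nd.parent_node), 0.0) + float(nd.edge.length or 0.0)
        depths[id(nd)] = d if nd.parent_node is not None else 0.0
    missing = set(taxa) - {
        lf.taxon.label.strip() for lf in tree.leaf_node_iter()
    }
    if missing:
        raise DataError(f"taxa absent from tree: {sorted(missing)}")
    for nd in tree.postorder_node_iter():
        if nd.is_leaf():
            label = nd.taxon.label.strip()
            leafsets[id(nd)] = [order[label]] if label in order else []
            if label in order:
                i = order[label]
                C[i, i] = depths[id(nd)]
        else:
            kids = [leafsets[id(c)] for c in nd.child_nodes()]
            merged: list[int] = []
            d = depths[id(nd)]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            C[i, j] = C[j, i] = d
                merged.extend(kids[a])
            if kids:
                merged = [i for ks in kids for i in ks]
            leafsets[id(nd)] = merged
    return C


def pgls_fit(
    tree: dendropy.Tree,
    x_by_tip: Mapping[str, float],
    y_by_tip: Mapping[str, float],
) -> RegressionResult:
    """Phylogenetic GLS under a fixed Brownian residual covariance.

    Only tips with both traits enter; the covariance is the shared
    branch-length matrix of those tips.  Estimates are invariant to a
    global rescaling of branch lengths.  Duplicate zero-distance tips
    make the covariance singular and raise a :class:`DataError` naming
    the offending tips.
    """
    taxa = sorted(set(x_by_tip) & set(y_by_tip))
    if len(taxa) < 3:
        raise DataError("PGLS needs at least 3 tips with both traits")
    present = {lf.taxon.label.strip() for lf in tree.leaf_node_iter()}
    taxa = [t for t in taxa if t in present]
    if len(taxa) < 3:
        raise DataError("PGLS needs at least 3 tips present on the tree")
    work = tree
    if present != set(taxa):
        work = tree.extract_tree_with_taxa_labels(labels=set(taxa))
    C = brownian_covariance(work, taxa)
    x = np.array([x_by_tip[t] for t in taxa])
    y = np.array([y_by_tip[t] for t in taxa])
    if np.ptp(x) == 0:
        raise DataError("predictor is constant; slope is undefined")
    # scale invariance + conditioning: normalize C to unit mean diagonal
    C = C / np.mean(np.diag(C))
    try:
        np.linalg.cholesky(C + 0.0)
    except np.linalg.LinAlgError:
        dup = []
        for i in range(len(taxa)):
            for j in range(i + 1, len(taxa)):
                if np.allclose(C[i], C[j]) and np.isclose(C[i, i], C[i, j]):
                    dup.append((taxa[i], taxa[j]))
        raise DataError(
            f"singular Brownian covariance (zero-distance tip pairs): {dup}"
        )
    X = sm.add_constant(x)
    fit = sm.GLS(y, X, sigma=C).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        pvalue_slope=float(fit.pvalues[1]),
        n=len(taxa),
        method="PGLS",
    )
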
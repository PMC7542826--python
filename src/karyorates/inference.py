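"""Rate inference: ML fits, likelihood-ratio tests, per-tree MCMC, pooling.

The estimation protocol mirrors a Bayesian analysis over a posterior
tree set: every tree is rescaled to unit depth, a Metropolis-Hastings
chain is run over the (unit-tree) event rates for each tree, the first
quarter of each chain is discarded as burnin, a fixed number of states
is subsampled from the remainder, each draw is back-transformed to per-
MY units with that tree's depth, and the per-tree samples are pooled
into one posterior (e.g. 100 trees x 100 samples = 10 000 draws).

Model comparison is a 1-df likelihood-ratio test between the nested
simple (fission + fusion) and complex (+ polyploidy) models.  Clade
rate differences are judged by whether 95% highest-posterior-density
(HPD) intervals are disjoint.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .chrommodel import (
    ChromosomeModel,
    Propagator,
    TreeIndex,
    build_rate_matrix,
    back_transform_rates,
    log_likelihood,
    make_tip_vectors,
)
from .errors import DataError

__all__ = [
    "MCMCSettings",
    "MLFit",
    "fit_ml",
    "LRTResult",
    "likelihood_ratio_test",
    "Chain",
    "run_mcmc",
    "PosteriorRates",
    "pool_posterior",
    "hpd_interval",
    "RateComparison",
    "compare_rates",
]

PARAM_NAMES = ("fission", "fusion", "polyploidy")


@dataclass(frozen=True)
class MCMCSettings:
    """Chain-length and prior settings for the per-tree MCMC."""

    generations: int = 1000
    burnin_fraction: float = 0.25
    samples_per_tree: int = 100
    seed: int = 0
    proposal_scale: float | None = None  # None: tuned during burnin
    prior_mean: Mapping[str, float] = field(
        default_factory=lambda: {"fission": 100.0, "fusion": 100.0, "polyploidy": 100.0}
    )

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise DataError("generations must be positive")
        if not 0 <= self.burnin_fraction < 1:
            raise DataError("burnin_fraction must lie in [0, 1)")
        post = self.generations - int(self.generations * self.burnin_fraction)
        if self.samples_per_tree > post:
            raise DataError(
                f"samples_per_tree ({self.samples_per_tree}) exceeds the "
                f"post-burnin chain length ({post})"
            )

    @property
    def burnin_generations(self) -> int:
        return int(self.generations * self.burnin_fraction)


def _resolve_ambiguity(counts_by_tip: Mapping, rng: np.random.Generator) -> dict:
    """One seeded uniform draw per tip from each candidate set."""
    resolved = {}
    for tip in sorted(counts_by_tip):
        c = counts_by_tip[tip]
        if c is None or isinstance(c, (int, np.integer)):
            resolved[tip] = c
        else:
            cand = sorted(c)
            resolved[tip] = cand[0] if len(cand) == 1 else int(rng.choice(cand))
    return resolved


class _LikelihoodCache:
    """Negative log-likelihood of unit-tree rates, with propagator reuse."""

    def __init__(self, index: TreeIndex, tip_vectors, template: ChromosomeModel, root_prior):
        self.index = index
        self.tips = tip_vectors
        self.template = template
        self.root_prior = root_prior

    def loglik(self, fission: float, fusion: float, polyploidy: float) -> float:
        model = replace(
            self.template,
            rate_fission=fission,
            rate_fusion=fusion,
            rate_polyploidy=polyploidy,
        )
        Q = build_rate_matrix(model)
        prop = Propagator.relaxed(Q)
        return log_likelihood(
            self.index, self.tips, Q, root_prior=self.root_prior, propagator=prop
        )


@dataclass
class MLFit:
    """Maximum-likelihood rates (unit-tree scale) and the maximized loglik."""

    rates: dict[str, float]
    loglik: float
    include_polyploidy: bool
    converged: bool = True
    n_evaluations: int = 0


def fit_ml(
    tree,
    tips: Mapping,
    model_template: ChromosomeModel,
    include_polyploidy: bool = True,
    root_prior="uniform",
    starts: Sequence[Sequence[float]] | None = None,
) -> MLFit:
    """Maximize the pruning likelihood over unit-tree event rates.

    ``tips`` maps tip label -> count / candidate set / None (missing);
    candidate sets are collapsed to a uniform tip vector here (ML has no
    per-iteration resampling).  The polyploidy rate is fixed at 0 when
    ``include_polyploidy`` is off, making the two fits nested.
    """
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    states = list(model_template.chromosome_states)
    vectors = make_tip_vectors({t: tips[t] for t in tips}, states)
    cache = _LikelihoodCache(index, vectors, model_template, root_prior)
    evals = [0]

    if include_polyploidy:

        def neg(x):
            evals[0] += 1
            ll = cache.loglik(x[0], x[1], x[2])
            return -ll if np.isfinite(ll) else 1e10

        default_starts = [(1.0, 1.0, 0.1), (20.0, 20.0, 0.5)]
        bounds = [(0.0, None)] * 3
    else:

        def neg(x):
            evals[0] += 1
            ll = cache.loglik(x[0], x[1], 0.0)
            return -ll if np.isfinite(ll) else 1e10

        default_starts = [(1.0, 1.0), (20.0, 20.0)]
        bounds = [(0.0, None)] * 2

    best_x, best_fun = None, np.inf
    converged = False
    for x0 in starts if starts is not None else default_starts:
        x0 = np.asarray(x0, dtype=float)
        res = optimize.minimize(neg, x0, method="L-BFGS-B", bounds=bounds)
        # L-BFGS-B reports the final iterate, which with numerical
        # gradients can sit marginally above the start point
        f0 = neg(x0)
        cand_x, cand_fun = (res.x, res.fun) if res.fun <= f0 else (x0, f0)
        if cand_fun < best_fun:
            best_x, best_fun = cand_x, cand_fun
            converged = bool(res.success)
    if not converged:
        warnings.warn("ML optimizer did not report convergence; returning best point")
    x = best_x
    rates = {"fission": float(x[0]), "fusion": float(x[1])}
    rates["polyploidy"] = float(x[2]) if include_polyploidy else 0.0
    return MLFit(
        rates=rates,
        loglik=-float(best_fun),
        include_polyploidy=include_polyploidy,
        converged=converged,
        n_evaluations=evals[0],
    )


@dataclass
class LRTResult:
    statistic: float
    dof: int
    pvalue: float
    supports_complex: bool


def likelihood_ratio_test(
    simple: MLFit, complex: MLFit, alpha: float = 0.05
) -> LRTResult:
    """1-df chi-square LRT of the nested simple vs. complex model."""
    if complex.loglik < simple.loglik - 1e-6:
        warnings.warn(
            "complex-model loglik below simple-model loglik: optimizer failure "
            f"({complex.loglik:.6f} < {simple.loglik:.6f})"
        )
    stat = max(0.0, 2.0 * (complex.loglik - simple.loglik))
    p = float(stats.chi2.sf(stat, df=1))
    return LRTResult(statistic=stat, dof=1, pvalue=p, supports_complex=p < alpha)


@dataclass
class Chain:
    """One per-tree MCMC chain over unit-tree rates (all generations kept)."""

    samples: np.ndarray  # generations x n_params
    log_posterior: np.ndarray
    param_names: tuple[str, ...]
    tree_id: int
    scale_factor: float  # tree depth in MY, for per-MY back-transform
    acceptance_rate: float
    resolved_counts: dict


def _log_prior(x: np.ndarray, means: np.ndarray) -> float:
    if np.any(x < 0):
        return -np.inf
    return float(np.sum(-np.log(means) - x / means))


def run_mcmc(
    tree,
    counts_by_tip: Mapping,
    model_template: ChromosomeModel,
    settings: MCMCSettings,
    tree_id: int = 0,
    scale_factor: float = 1.0,
    include_polyploidy: bool = True,
    root_prior="uniform",
    use_likelihood: bool = True,
    initial: Sequence[float] | None = None,
) -> Chain:
    """Metropolis-Hastings over unit-tree rates for one tree.

    Tip-count ambiguity is resolved by a single seeded uniform draw per
    (seed, tree) before the chain starts.  Proposals are per-parameter
    sliding windows reflected at zero, tuned toward 25-45% acceptance
    during burnin.  The chain starts at the ML fit unless ``initial`` is
    given (with the likelihood disabled it starts at a prior draw), and
    every generation is stored.
    """
    rng = np.random.default_rng(np.random.SeedSequence([settings.seed & 0x7FFFFFFF, tree_id]))
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    resolved = _resolve_ambiguity(counts_by_tip, rng)
    states = list(model_template.chromosome_states)
    vectors = make_tip_vectors(resolved, states)
    cache = _LikelihoodCache(index, vectors, model_template, root_prior)

    names = PARAM_NAMES if include_polyploidy else PARAM_NAMES[:2]
    means = np.array([float(settings.prior_mean.get(n, 10.0)) for n in names])

    def log_post(x: np.ndarray) -> float:
        lp = _log_prior(x, means)
        if not np.isfinite(lp):
            return -np.inf
        if not use_likelihood:
            return lp
        ll = (
            cache.loglik(x[0], x[1], x[2])
            if include_polyploidy
            else cache.loglik(x[0], x[1], 0.0)
        )
        return lp + ll

    if initial is not None:
        x = np.asarray(initial, dtype=float)
    elif use_likelihood:
        fit = fit_ml(
            index, resolved, model_template,
            include_polyploidy=include_polyploidy, root_prior=root_prior,
            starts=[(5.0, 5.0, 0.25)] if include_polyploidy else [(5.0, 5.0)],
        )
        x = np.array([fit.rates[n] for n in names])
    else:
        x = rng.exponential(means)
    lp = log_post(x)

    window = np.full(
        len(names),
        settings.proposal_scale if settings.proposal_scale else 1.0,
    ) * np.maximum(means * 0.2, np.abs(x) * 0.3 + 0.05)
    tune = settings.proposal_scale is None
    burnin = settings.burnin_generations

    # move cycle: one sliding-window update per parameter, then one joint
    # multiplicative rescaling of all rates (the posterior is ridged along
    # the total-rate direction; the scale move traverses it directly)
    n_moves = len(names) + 1
    scale_idx = len(names)
    log_scale_window = 0.4
    samples = np.empty((settings.generations, len(names)))
    log_posts = np.empty(settings.generations)
    accepted = 0
    block_acc = np.zeros(n_moves)
    block_try = np.zeros(n_moves)
    for g in range(settings.generations):
        j = g % n_moves
        if j == scale_idx:
            eps = rng.uniform(-log_scale_window, log_scale_window)
            prop = x * np.exp(eps)
            # Hastings correction for the multiplicative proposal; exact
            # zeros are fixed points of the move and carry no Jacobian
            log_hastings = eps * np.count_nonzero(x)
        else:
            prop = x.copy()
            step = rng.uniform(-window[j], window[j])
            prop[j] = abs(prop[j] + step)  # reflect at zero
            log_hastings = 0.0
        lp_prop = log_post(prop)
        if np.log(rng.uniform()) < lp_prop - lp + log_hastings:
            x, lp = prop, lp_prop
            accepted += 1
            block_acc[j] += 1
        block_try[j] += 1
        samples[g] = x
        log_posts[g] = lp
        if tune and g < burnin and block_try[j] == 25:
            frac = block_acc[j] / block_try[j]
            if j == scale_idx:
                if frac > 0.45:
                    log_scale_window *= 1.6
                elif frac < 0.25:
                    log_scale_window /= 1.6
            elif frac > 0.45:
                window[j] *= 1.6
            elif frac < 0.25:
                window[j] /= 1.6
            block_acc[j] = 0
            block_try[j] = 0
    return Chain(
        samples=samples,
        log_posterior=log_posts,
        param_names=tuple(names),
        tree_id=tree_id,
        scale_factor=scale_factor,
        acceptance_rate=accepted / settings.generations,
        resolved_counts=resolved,
    )


@dataclass
class PosteriorRates:
    """Pooled post-burnin draws across a tree set, on the per-MY scale.

    ``draws`` columns: tree, generation, then one column per parameter.
    """

    draws: pd.DataFrame
    param_names: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.draws)

    def parameter(self, name: str) -> np.ndarray:
        if name not in self.param_names:
            raise KeyError(f"posterior has no parameter {name!r}")
        return self.draws[name].to_numpy()

    def summary(self, mass: float = 0.95) -> pd.DataFrame:
        rows = []
        for name in self.param_names:
            v = self.parameter(name)
            lo, hi = hpd_interval(v, mass)
            rows.append(
                {
                    "parameter": name,
                    "mean": v.mean(),
                    "median": float(np.median(v)),
                    "hpd_low": lo,
                    "hpd_high": hi,
                }
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        tidy = self.draws.melt(
            id_vars=["tree", "generation"], var_name="parameter", value_name="value"
        )
        tidy.to_csv(path, index=False)


def pool_posterior(chains: Sequence[Chain], settings: MCMCSettings) -> PosteriorRates:
    """Drop burnin, subsample each chain, back-transform, concatenate.

    Per chain: the first ``burnin_fraction`` of generations is discarded,
    ``samples_per_tree`` post-burnin states are drawn uniformly without
    replacement (seeded), and each draw is divided by that tree's depth
    in MY so pooled draws are per-MY rates.
    """
    if not chains:
        raise DataError("no chains to pool")
    names = chains[0].param_names
    frames = []
    for chain in chains:
        if chain.param_names != names:
            raise DataError("chains disagree on parameter names")
        burnin = int(len(chain.samples) * settings.burnin_fraction)
        post = np.arange(burnin, len(chain.samples))
        if len(post) < settings.samples_per_tree:
            raise DataError(
                f"tree {chain.tree_id}: post-burnin length {len(post)} is "
                f"shorter than samples_per_tree {settings.samples_per_tree}"
            )
        rng = np.random.default_rng(
            np.random.SeedSequence([settings.seed & 0x7FFFFFFF, chain.tree_id, 1])
        )
        pick = np.sort(rng.choice(post, size=settings.samples_per_tree, replace=False))
        block = pd.DataFrame(
            back_transform_rates(chain.samples[pick], chain.scale_factor),
            columns=list(names),
        )
        block.insert(0, "generation", pick)
        block.insert(0, "tree", chain.tree_id)
        frames.append(block)
    draws = pd.concat(frames, ignore_index=True)
    return PosteriorRates(draws=draws, param_names=names)


def hpd_interval(draws, mass: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ``ceil(mass*N)`` sorted draws."""
    v = np.sort(np.asarray(draws, dtype=float))
    n = len(v)
    if n == 0:
        raise DataError("cannot compute an HPD interval from no draws")
    if not 0 < mass <= 1:
        raise DataError("mass must lie in (0, 1]")
    m = int(math.ceil(mass * n))
    if m >= n:
        return float(v[0]), float(v[-1])
    widths = v[m - 1 :] - v[: n - m + 1]
    i = int(np.argmin(widths))
    return float(v[i]), float(v[i + m - 1])


@dataclass
class RateComparison:
    parameter: str
    interval_a: tuple[float, float]
    interval_b: tuple[float, float]
    disjoint: bool

    @property
    def significantly_different(self) -> bool:
        return self.disjoint


def compare_rates(
    a: PosteriorRates, b: PosteriorRates, parameter: str, mass: float = 0.95
) -> RateComparison:
    """Compare two posteriors by overlap of their HPD intervals.

    Disjoint intervals are reported as a significant rate difference;
    overlapping intervals are not.
    """
    ia = hpd_interval(a.parameter(parameter), mass)
    ib = hpd_interval(b.parameter(parameter), mass)
    disjoint = ia[1] < ib[0] or ib[1] < ia[0]
    return RateComparison(parameter=parameter, interval_a=ia, interval_b=ib, disjoint=disjoint)
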
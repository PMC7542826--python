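"""End-to-end orchestration: data -> fits -> MCMC -> ASR -> tables.

:func:`run_pipeline` drives the whole comparative analysis from a
karyotype table and a posterior tree set: per-clade model fitting with
likelihood-ratio tests on every tree, per-tree MCMC pooled into a
per-MY posterior, fixed-rate ancestral reconstruction (posterior-mean
rates per tree), the two-state SCS model with stochastic maps and
transition counts, the genus-level SCS table, and the genome-size
regressions.  Outputs land as CSV under a run directory together with a
manifest recording seeds, settings and input digests so a rerun with
the same config is bit-identical.

Clades are defined by the karyotype table's order column intersected
with the tree tips (or by explicit tip lists), with optional nested
exclusion ("order A excluding suborder B"); clades below a minimum size
(default 20, the threshold below which rate estimates are unreliable)
are skipped with a logged warning.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from . import __version__
from .ancestry import (
    average_mrca_state,
    count_fusion_fission_events,
    fit_mk2_ard,
    marginal_ancestral_states,
    mk2_rate_matrix,
    stochastic_map,
)
from .chrommodel import (
    ChromosomeModel,
    TreeIndex,
    build_rate_matrix,
    default_state_space,
    rescale_to_unit,
)
from .errors import ConfigurationError, DataError
from .inference import (
    MCMCSettings,
    fit_ml,
    likelihood_ratio_test,
    pool_posterior,
    run_mcmc,
)
from .karyodata import (
    ASEXUAL,
    UNKNOWN,
    KaryotypeRecord,
    PosteriorTreeSet,
    read_karyotype_table,
    read_tree_set,
    tip_labels,
)
from .genomesize import ols_fit, pgls_fit, tip_rates
from .scs_analysis import (
    classify_mechanism,
    summaries_to_dataframe,
    summarize_all_genera,
    tabulate_mechanisms,
)

logger = logging.getLogger("karyorates")

__all__ = ["RunConfig", "CladeSpec", "clade_subtree", "run_pipeline", "PipelineResult"]


@dataclass(frozen=True)
class CladeSpec:
    """A clade: explicit tips, or an order name, with optional exclusion."""

    name: str
    tips: tuple[str, ...] = ()
    order: str | None = None
    exclude: tuple[str, ...] = ()  # tip names or a nested order name


@dataclass
class RunConfig:
    karyotype_path: str | Path | None = None
    tree_paths: Sequence[str | Path] = ()
    tree_format: str = "newick"
    clades: Sequence[CladeSpec] = ()
    min_clade_size: int = 20
    include_polyploidy: bool = True
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    n_stochastic_maps: int = 100
    seed: int = 0
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.min_clade_size < 2:
            raise ConfigurationError("min_clade_size must be >= 2")


def clade_subtree(tree: dendropy.Tree, spec: CladeSpec | Sequence[str]) -> dendropy.Tree:
    """Extract the MRCA-rooted subtree for a clade spec.

    The subtree contains every tip descending from the MRCA of the
    spec's tips; ``exclude`` then prunes a nested clade's tips (the
    "order A excluding suborder B" construction).
    """
    if not isinstance(spec, CladeSpec):
        spec = CladeSpec(name="clade", tips=tuple(spec))
    present = tip_labels(tree)
    wanted = set(spec.tips) & present
    if not wanted:
        raise DataError(f"clade {spec.name!r}: no spec tips present on the tree")
    if wanted == present:
        sub_labels = set(present)
    else:
        mrca = tree.mrca(taxon_labels=wanted)
        sub_labels = {lf.taxon.label.strip() for lf in mrca.leaf_iter()}
    sub_labels -= set(spec.exclude)
    if len(sub_labels) < 2:
        raise DataError(f"clade {spec.name!r}: fewer than 2 tips after exclusion")
    return tree.extract_tree_with_taxa_labels(labels=sub_labels)


@dataclass
class CladeResult:
    name: str
    n_tips: int
    posterior: object  # PosteriorRates
    lrt_fraction_complex: float
    lrt_pvalues: list[float]
    root_state_probs: np.ndarray | None
    states: list | None


@dataclass
class PipelineResult:
    clades: dict[str, CladeResult]
    scs_table: pd.DataFrame
    scs_tally: object
    mk2_summary: pd.DataFrame | None
    scs_transition_counts: dict[str, float] | None
    event_counts: object | None
    regressions: dict[str, object]
    manifest: dict


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _counts_by_tip(records: Sequence[KaryotypeRecord]) -> dict[str, object]:
    out: dict[str, object] = {}
    for r in records:
        c = sorted(r.haploid_counts)
        out[r.species] = c[0] if len(c) == 1 else frozenset(c)
    return out


def _resolve_clades(
    config: RunConfig, records: Sequence[KaryotypeRecord]
) -> list[CladeSpec]:
    if config.clades:
        specs = []
        for spec in config.clades:
            tips = set(spec.tips)
            exclude = set(spec.exclude)
            if spec.order:
                tips |= {r.species for r in records if r.order == spec.order}
            nested = {r.species for r in records if r.order in spec.exclude}
            exclude |= nested
            specs.append(
                CladeSpec(name=spec.name, tips=tuple(sorted(tips)), exclude=tuple(sorted(exclude)))
            )
        return specs
    orders = sorted({r.order for r in records if r.order})
    return [
        CladeSpec(name=o, tips=tuple(sorted(r.species for r in records if r.order == o)))
        for o in orders
    ]


def analyze_clade(
    name: str,
    trees: Sequence[dendropy.Tree],
    counts: Mapping[str, object],
    config: RunConfig,
) -> CladeResult:
    """Full chromosome-rate analysis of one clade across a tree set."""
    n_min, n_max = default_state_space(counts.values())
    template = ChromosomeModel(n_min=n_min, n_max=n_max)
    chains = []
    lrt_pvals = []
    asr_vecs = []
    states = None
    for i, tree in enumerate(trees):
        unit, scale = rescale_to_unit(tree)
        index = TreeIndex(unit)
        clade_counts = {t: counts[t] for t in index.labels}
        simple = fit_ml(index, clade_counts, template, include_polyploidy=False)
        complex_fit = fit_ml(index, clade_counts, template, include_polyploidy=True)
        lrt_pvals.append(likelihood_ratio_test(simple, complex_fit).pvalue)
        chain = run_mcmc(
            index,
            clade_counts,
            template,
            config.mcmc,
            tree_id=i,
            scale_factor=scale,
            include_polyploidy=config.include_polyploidy,
        )
        chains.append(chain)
        burnin = config.mcmc.burnin_generations
        mean_rates = chain.samples[burnin:].mean(axis=0)
        rates = dict(zip(chain.param_names, mean_rates))
        model = ChromosomeModel(
            n_min=n_min,
            n_max=n_max,
            rate_fission=rates.get("fission", 0.0),
            rate_fusion=rates.get("fusion", 0.0),
            rate_polyploidy=rates.get("polyploidy", 0.0),
        )
        Q = build_rate_matrix(model)
        recon = marginal_ancestral_states(index, chain.resolved_counts, Q)
        asr_vecs.append(recon.probs[recon.index.root])
        states = recon.states
    posterior = pool_posterior(chains, config.mcmc)
    alpha = 0.05
    frac = float(np.mean([p < alpha for p in lrt_pvals]))
    return CladeResult(
        name=name,
        n_tips=len(next(iter(trees)).leaf_nodes()),
        posterior=posterior,
        lrt_fraction_complex=frac,
        lrt_pvalues=lrt_pvals,
        root_state_probs=np.mean(asr_vecs, axis=0) if asr_vecs else None,
        states=states,
    )


def run_pipeline(
    config: RunConfig,
    records: Sequence[KaryotypeRecord] | None = None,
    tree_set: PosteriorTreeSet | None = None,
) -> PipelineResult:
    """Run the full analysis; inputs may be paths (in config) or objects."""
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "mcmc": asdict(config.mcmc),
        "inputs": {},
    }
    if records is None:
        if config.karyotype_path is None:
            raise ConfigurationError("no karyotype table given")
        table = read_karyotype_table(config.karyotype_path)
        records = table.records
        manifest["inputs"]["karyotype"] = _digest(Path(config.karyotype_path))
    if tree_set is None:
        if not config.tree_paths:
            raise ConfigurationError("no tree files given")
        tree_set = read_tree_set(config.tree_paths, format=config.tree_format)
        manifest["inputs"]["trees"] = [_digest(Path(p)) for p in config.tree_paths]

    by_species = {r.species: r for r in records}
    shared = tree_set.labels & set(by_species)
    if not shared:
        raise DataError("no overlap between tree tips and karyotype table")
    counts = _counts_by_tip([by_species[s] for s in shared])

    # per-clade rate analyses
    clade_results: dict[str, CladeResult] = {}
    for spec in _resolve_clades(config, records):
        tips = set(spec.tips) & shared
        if len(tips) < config.min_clade_size:
            logger.warning(
                "clade %s skipped: %d tips < minimum %d",
                spec.name,
                len(tips),
                config.min_clade_size,
            )
            continue
        spec = CladeSpec(name=spec.name, tips=tuple(sorted(tips)), exclude=spec.exclude)
        subtrees = [clade_subtree(t, spec) for t in tree_set]
        clade_results[spec.name] = analyze_clade(spec.name, subtrees, counts, config)

    # genus-level SCS table
    summaries = [classify_mechanism(s) for s in summarize_all_genera(records)]
    scs_table = summaries_to_dataframe(summaries)
    scs_tally = tabulate_mechanisms(summaries)

    # two-state SCS model + stochastic maps on the full trees
    scs_by_tip = {
        s: by_species[s].scs
        for s in shared
        if by_species[s].scs != UNKNOWN
        and by_species[s].reproductive_mode != ASEXUAL
    }
    mk2_summary = None
    map_means: dict[str, float] | None = None
    if len(set(scs_by_tip.values())) >= 2:
        fits, mk2_summary = fit_mk2_ard(list(tree_set), scs_by_tip)
        from .ancestry import scs_to_binary

        binary = scs_to_binary(scs_by_tip)
        labelled = {t: "XO" if v == 0 else "XY" for t, v in binary.items()}
        totals: dict[str, float] = {}
        for i, (tree, fit) in enumerate(zip(tree_set, fits)):
            pruned = tree.extract_tree_with_taxa_labels(labels=set(binary))
            summ = stochastic_map(
                pruned,
                labelled,
                mk2_rate_matrix(fit.q01, fit.q10),
                n_maps=config.n_stochastic_maps,
                seed=(config.seed & 0x7FFFFFFF) + i,
                states=["XO", "XY"],
            )
            for key, val in summ.mean_counts.items():
                totals[key] = totals.get(key, 0.0) + val
        map_means = {k: v / len(tree_set) for k, v in totals.items()}

    # genome-size regressions on the full dataset
    regressions: dict[str, object] = {}
    gs = {r.species: r.genome_size for r in records if r.genome_size is not None}
    cn = {r.species: r.mean_count for r in records}
    both = sorted(set(gs) & set(cn))
    if len(both) >= 3:
        try:
            regressions["chromnum_vs_gsize_ols"] = ols_fit(
                [gs[s] for s in both], [cn[s] for s in both]
            )
        except DataError as exc:
            logger.warning("OLS skipped: %s", exc)
        on_tree = sorted(set(both) & shared)
        if len(on_tree) >= 3:
            try:
                regressions["chromnum_vs_gsize_pgls"] = pgls_fit(
                    tree_set[0],
                    {s: gs[s] for s in on_tree},
                    {s: cn[s] for s in on_tree},
                )
            except DataError as exc:
                logger.warning("PGLS skipped: %s", exc)

    result = PipelineResult(
        clades=clade_results,
        scs_table=scs_table,
        scs_tally=scs_tally,
        mk2_summary=mk2_summary,
        scs_transition_counts=map_means,
        event_counts=None,
        regressions=regressions,
        manifest=manifest,
    )
    if config.output_dir is not None:
        _write_outputs(result, Path(config.output_dir))
    return result


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.scs_table.to_csv(outdir / "scs_genus_table.csv", index=False)
    if result.mk2_summary is not None:
        result.mk2_summary.to_csv(outdir / "scs_ard_rates.csv", index=False)
    for name, clade in result.clades.items():
        clade.posterior.to_csv(outdir / f"posterior_{name}.csv")
        pd.DataFrame({"pvalue": clade.lrt_pvalues}).to_csv(
            outdir / f"lrt_{name}.csv", index=False
        )
    reg_rows = [
        {"name": k, "slope": v.slope, "intercept": v.intercept, "pvalue": v.pvalue_slope}
        for k, v in result.regressions.items()
    ]
    if reg_rows:
        pd.DataFrame(reg_rows).to_csv(outdir / "regressions.csv", index=False)
    (outdir / "manifest.json").write_text(json.dumps(result.manifest, indent=2, sort_keys=True))
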
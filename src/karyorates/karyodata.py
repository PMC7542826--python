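"""Data model and I/O for karyotype tables and posterior tree sets.

A :class:`KaryotypeRecord` is one species' observation: its taxonomy
(genus, order), its candidate haploid chromosome counts (a set, singleton
when the literature is unambiguous), its sex chromosome system (SCS),
its reproductive mode, and optionally a genome size in Mbp.

A :class:`PosteriorTreeSet` wraps an ordered collection of rooted,
time-calibrated trees (branch lengths in millions of years, MY) sampled
from the posterior of a Bayesian phylogenetic analysis.  All trees must
share an identical tip-label set; downstream inference iterates over the
trees to propagate phylogenetic uncertainty.

The module also ships, as a packaged fixture, the published genus-level
table of mean autosome numbers by sex chromosome system for the 23
Polyneoptera genera that contain more than one SCS.
"""

from __future__ import annotations

import csv
import gzip
import io
import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import dendropy

from .errors import ConfigurationError, DataError

logger = logging.getLogger("karyorates")

# Sex chromosome system states.
XO = "XO"
XY = "XY"
MULTI_XY = "multiXY"
UNKNOWN = "unknown"
SCS_STATES = (XO, XY, MULTI_XY, UNKNOWN)

SEXUAL = "sexual"
ASEXUAL = "asexual"
REPRODUCTIVE_MODES = (SEXUAL, ASEXUAL, UNKNOWN)

#: Default logical-name -> CSV-header mapping for karyotype tables.
DEFAULT_DIALECT: Mapping[str, str] = {
    "species": "species",
    "genus": "genus",
    "order": "order",
    "haploid_counts": "haploid_counts",
    "scs": "scs",
    "reproductive_mode": "reproductive_mode",
    "genome_size": "genome_size",
}

_MANDATORY = ("species", "genus", "order", "haploid_counts")


@dataclass(frozen=True)
class KaryotypeRecord:
    """One species' karyotype observation.

    ``haploid_counts`` is a non-empty frozenset of positive integers:
    candidate haploid (autosome or total, depending on the source column)
    chromosome numbers.  Ambiguity is resolved downstream, in inference,
    never at I/O time.
    """

    species: str
    genus: str
    order: str
    haploid_counts: frozenset[int]
    scs: str = UNKNOWN
    reproductive_mode: str = UNKNOWN
    genome_size: float | None = None

    def __post_init__(self) -> None:
        if not self.haploid_counts:
            raise DataError(f"{self.species}: empty haploid count set")
        if any((not isinstance(c, int)) or c < 1 for c in self.haploid_counts):
            raise DataError(
                f"{self.species}: haploid counts must be positive integers, "
                f"got {sorted(self.haploid_counts)}"
            )
        if self.scs not in SCS_STATES:
            raise DataError(f"{self.species}: unknown SCS state {self.scs!r}")
        if self.reproductive_mode not in REPRODUCTIVE_MODES:
            raise DataError(
                f"{self.species}: unknown reproductive mode "
                f"{self.reproductive_mode!r}"
            )
        if self.genome_size is not None and not self.genome_size > 0:
            raise DataError(f"{self.species}: genome size must be positive")

    @property
    def mean_count(self) -> float:
        """Within-species mean over candidate counts."""
        return sum(self.haploid_counts) / len(self.haploid_counts)


@dataclass
class ParseReport:
    """Rows that failed to parse: (1-based row number, message)."""

    entries: list[tuple[int, str]] = field(default_factory=list)

    def add(self, row: int, message: str) -> None:
        self.entries.append((row, message))
        logger.warning("karyotype table row %d: %s", row, message)

    def __len__(self) -> int:
        return len(self.entries)

    def __bool__(self) -> bool:
        return bool(self.entries)


@dataclass
class KaryotypeTable:
    """Parsed karyotype table: records plus the parse report."""

    records: list[KaryotypeRecord]
    report: ParseReport = field(default_factory=ParseReport)

    def __iter__(self) -> Iterator[KaryotypeRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def by_species(self) -> dict[str, KaryotypeRecord]:
        return {r.species: r for r in self.records}


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8", newline="")
    return open(path, "r", encoding="utf-8", newline="")


def _parse_counts(raw: str) -> frozenset[int]:
    parts = [p for chunk in raw.split(";") for p in chunk.split("|")]
    counts = frozenset(int(p.strip()) for p in parts if p.strip())
    if not counts:
        raise ValueError("no counts")
    if any(c < 1 for c in counts):
        raise ValueError(f"non-positive count in {raw!r}")
    return counts


def read_karyotype_table(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> KaryotypeTable:
    """Read a karyotype CSV into records.

    ``dialect`` maps logical column names (the keys of
    :data:`DEFAULT_DIALECT`) to the CSV's header names.  The haploid-count
    field may hold a single integer or a ``;``-delimited candidate list.
    Rows whose counts cannot be parsed are reported (and logged), never
    silently dropped.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    report = ParseReport()
    records: list[KaryotypeRecord] = []
    with _open_text(path) as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for logical in _MANDATORY:
            if cols[logical] not in header:
                raise ConfigurationError(
                    f"karyotype table {path} is missing mandatory column "
                    f"{cols[logical]!r} (for {logical!r})"
                )
        have_scs = cols["scs"] in header
        have_mode = cols["reproductive_mode"] in header
        have_gs = cols["genome_size"] in header
        for i, row in enumerate(reader, start=2):  # row 1 is the header
            try:
                counts = _parse_counts(row[cols["haploid_counts"]] or "")
            except ValueError as exc:
                report.add(i, f"unparseable haploid counts: {exc}")
                continue
            gs_raw = (row.get(cols["genome_size"]) or "").strip() if have_gs else ""
            try:
                genome_size = float(gs_raw) if gs_raw else None
            except ValueError:
                report.add(i, f"unparseable genome size {gs_raw!r}")
                continue
            scs = (row.get(cols["scs"]) or "").strip() if have_scs else ""
            mode = (
                (row.get(cols["reproductive_mode"]) or "").strip()
                if have_mode
                else ""
            )
            try:
                records.append(
                    KaryotypeRecord(
                        species=(row[cols["species"]] or "").strip(),
                        genus=(row[cols["genus"]] or "").strip(),
                        order=(row[cols["order"]] or "").strip(),
                        haploid_counts=counts,
                        scs=scs or UNKNOWN,
                        reproductive_mode=mode or UNKNOWN,
                        genome_size=genome_size,
                    )
                )
            except DataError as exc:
                report.add(i, str(exc))
    return KaryotypeTable(records=records, report=report)


def write_karyotype_table(
    records: Iterable[KaryotypeRecord], path: str | Path
) -> None:
    """Write records to CSV in the default dialect (round-trip safe)."""
    path = Path(path)
    opener = (
        io.TextIOWrapper(gzip.open(path, "wb"), encoding="utf-8", newline="")
        if path.suffix == ".gz"
        else open(path, "w", encoding="utf-8", newline="")
    )
    with opener as fh:
        writer = csv.writer(fh)
        writer.writerow(list(DEFAULT_DIALECT.values()))
        for r in records:
            counts = ";".join(str(c) for c in sorted(r.haploid_counts))
            gs = "" if r.genome_size is None else repr(r.genome_size)
            writer.writerow(
                [r.species, r.genus, r.order, counts, r.scs, r.reproductive_mode, gs]
            )


# ---------------------------------------------------------------------------
# Posterior tree sets
# ---------------------------------------------------------------------------


@dataclass
class PosteriorTreeSet:
    """An ordered posterior sample of rooted trees sharing one tip set."""

    trees: list[dendropy.Tree]
    labels: frozenset[str]

    def __post_init__(self) -> None:
        for i, tree in enumerate(self.trees):
            tips = tip_labels(tree)
            if tips != self.labels:
                diff = sorted(tips.symmetric_difference(self.labels))
                raise DataError(
                    f"tree {i} tip set differs from the shared label set: {diff}"
                )
            if root_depth(tree) <= 0:
                raise DataError(f"tree {i} has zero root depth")

    def __iter__(self) -> Iterator[dendropy.Tree]:
        return iter(self.trees)

    def __len__(self) -> int:
        return len(self.trees)

    def __getitem__(self, i: int) -> dendropy.Tree:
        return self.trees[i]


def tip_labels(tree: dendropy.Tree) -> frozenset[str]:
    """Tip labels, whitespace-stripped (matching is exact and case-sensitive)."""
    return frozenset(leaf.taxon.label.strip() for leaf in tree.leaf_node_iter())


def root_depth(tree: dendropy.Tree) -> float:
    """Maximum root-to-tip path length (the root age for ultrametric trees)."""
    return float(tree.max_distance_from_root())


def read_tree_set(
    paths: str | Path | Sequence[str | Path], format: str = "newick"
) -> PosteriorTreeSet:
    """Read one or more Newick/Nexus files into a posterior tree set.

    All trees are forced rooted; polytomies are resolved to binary with
    zero-length branches (reported in the log).  Tip-label sets must be
    identical across trees; a mismatch raises :class:`DataError` listing
    the symmetric difference.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    if format not in ("newick", "nexus"):
        raise ConfigurationError(f"unknown tree format {format!r}")
    ns = dendropy.TaxonNamespace()
    trees: list[dendropy.Tree] = []
    for path in paths:
        path = Path(path)
        if path.suffix == ".gz":
            with gzip.open(path, "rt", encoding="utf-8") as fh:
                data = fh.read()
            tl = dendropy.TreeList.get(
                data=data, schema=format, taxon_namespace=ns, rooting="force-rooted"
            )
        else:
            tl = dendropy.TreeList.get(
                path=str(path),
                schema=format,
                taxon_namespace=ns,
                rooting="force-rooted",
            )
        trees.extend(tl)
    if not trees:
        raise DataError(f"no trees found in {list(map(str, paths))}")
    label_sets = [tip_labels(t) for t in trees]
    ref = label_sets[0]
    for i, labels in enumerate(label_sets[1:], start=1):
        if labels != ref:
            diff = sorted(ref.symmetric_difference(labels))
            raise DataError(
                f"tree {i} tip labels differ from tree 0; "
                f"symmetric difference: {diff}"
            )
    n_resolved = 0
    for tree in trees:
        poly = [
            nd
            for nd in tree.preorder_node_iter()
            if len(nd.child_nodes()) > 2
        ]
        if poly:
            n_resolved += len(poly)
            tree.resolve_polytomies(limit=2)
            for nd in tree.preorder_node_iter():
                if nd.edge.length is None:
                    nd.edge.length = 0.0
    if n_resolved:
        logger.info("resolved %d polytomies to binary (zero-length branches)", n_resolved)
    return PosteriorTreeSet(trees=trees, labels=ref)


def intersect_tree_and_table(
    tree: dendropy.Tree, table: KaryotypeTable | Iterable[KaryotypeRecord]
) -> tuple[dendropy.Tree, list[KaryotypeRecord]]:
    """Prune tree and table to their common species, reporting the rest.

    Tip-name matching is exact and case-sensitive after stripping
    surrounding whitespace; analysis proceeds on the intersection.
    """
    records = list(table)
    by_species = {r.species: r for r in records}
    tips = tip_labels(tree)
    common = tips & set(by_species)
    if not common:
        raise DataError("no species shared between tree and karyotype table")
    only_tree = sorted(tips - common)
    only_table = sorted(set(by_species) - common)
    if only_tree:
        logger.info("pruning %d tree tips absent from table: %s", len(only_tree), only_tree)
    if only_table:
        logger.info("ignoring %d table species absent from tree: %s", len(only_table), only_table)
    pruned = tree
    if only_tree:
        pruned = tree.extract_tree_with_taxa_labels(labels=common)
    kept = [by_species[s] for s in sorted(common)]
    return pruned, kept


# ---------------------------------------------------------------------------
# Packaged genus-level SCS table fixture
# ---------------------------------------------------------------------------


def table1_fixture():
    """The packaged genus-level mean-autosome-by-SCS table (23 genera).

    Returns a list of :class:`karyorates.scs_analysis.GenusSCSSummary`
    with per-SCS mean autosome numbers and per-genus sample sizes exactly
    as published, ready for :func:`karyorates.scs_analysis.classify_mechanism`
    and :func:`karyorates.scs_analysis.tabulate_mechanisms`.  The published
    classification labels are attached as ``published_label_xo_xy`` /
    ``published_label_to_multixy`` for cross-checking.
    """
    from .scs_analysis import GenusSCSSummary  # local import avoids a cycle

    text = resources.files("karyorates.data").joinpath("table1.csv").read_text()
    summaries = []
    for row in csv.DictReader(io.StringIO(text)):
        means = {}
        for scs, col in ((XO, "mean_xo"), (XY, "mean_xy"), (MULTI_XY, "mean_multixy")):
            if row[col].strip():
                means[scs] = float(row[col])
        summaries.append(
            GenusSCSSummary(
                genus=row["genus"],
                order=row["order"],
                n_total=int(row["n_samples"]),
                mean_autosomes=means,
                published_label_xo_xy=row["label_xo_xy"].strip() or None,
                published_label_to_multixy=row["label_to_multixy"].strip() or None,
            )
        )
    return summaries
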
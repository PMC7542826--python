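"""Genus-level autosome-mean comparison across sex chromosome systems.

Within a genus containing more than one sex chromosome system (SCS),
comparing mean autosome numbers between SCS classes diagnoses the
mechanism behind SCS transitions: an X-autosome fusion removes an
autosome pair, so XY species descended from XO ancestors via fusion
should carry fewer autosomes; a sex-chromosome fission leaves the
autosome count unchanged or (for autosomal fissions) raises it.

The classifier is deliberately asymmetric: any decrease in mean
autosome number is called a fusion, while an increase must reach a
threshold (default 1 autosome — the minimum shift a real fusion/fission
produces) to be called a fission; small increases are "neither".  For
transitions into multi-XY systems the reference mean is the XY class
when present, else XO, and "higher or unchanged" is fission-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .karyodata import MULTI_XY, UNKNOWN, XO, XY, KaryotypeRecord

__all__ = [
    "GenusSCSSummary",
    "summarize_genus",
    "summarize_all_genera",
    "classify_mechanism",
    "MechanismTally",
    "tabulate_mechanisms",
    "summarize_by_order",
]

FUSION = "fusion"
FISSION = "fission"
NEITHER = "neither"


@dataclass
class GenusSCSSummary:
    """Per-genus mean autosome numbers by SCS and mechanism classification."""

    genus: str
    order: str
    n_total: int
    mean_autosomes: dict[str, float]  # SCS -> mean (absent SCS omitted)
    n_species: dict[str, int] = field(default_factory=dict)
    classification_xo_xy: str | None = None  # fusion/fission/neither or None (NA)
    classification_to_multixy: str | None = None
    published_label_xo_xy: str | None = None
    published_label_to_multixy: str | None = None

    @property
    def has_xo_xy_pair(self) -> bool:
        return XO in self.mean_autosomes and XY in self.mean_autosomes

    @property
    def multixy_evaluable(self) -> bool:
        return MULTI_XY in self.mean_autosomes and (
            XO in self.mean_autosomes or XY in self.mean_autosomes
        )


def summarize_genus(
    records: Iterable[KaryotypeRecord], genus: str
) -> GenusSCSSummary:
    """Per-SCS arithmetic mean autosome numbers for one genus.

    Species with ambiguous counts contribute their within-species mean.
    Duplicated identical records are collapsed first (one vote per
    species per SCS), so the summary is invariant to record order and
    duplication.  SCS classes with no species are omitted.
    """
    by_scs: dict[str, dict[str, float]] = {}
    order = ""
    seen = set()
    for r in records:
        if r.genus != genus or r.scs == UNKNOWN:
            continue
        key = (r.species, r.scs, r.haploid_counts)
        if key in seen:
            continue
        seen.add(key)
        order = order or r.order
        by_scs.setdefault(r.scs, {})[r.species] = r.mean_count
    if not by_scs:
        raise DataError(
            f"genus {genus!r}: no records with known SCS and resolved counts"
        )
    means = {scs: float(np.mean(list(vals.values()))) for scs, vals in by_scs.items()}
    n_species = {scs: len(vals) for scs, vals in by_scs.items()}
    return GenusSCSSummary(
        genus=genus,
        order=order,
        n_total=sum(n_species.values()),
        mean_autosomes=means,
        n_species=n_species,
    )


def summarize_all_genera(records: Iterable[KaryotypeRecord]) -> list[GenusSCSSummary]:
    records = list(records)
    genera = sorted({r.genus for r in records if r.scs != UNKNOWN and r.genus})
    return [summarize_genus(records, g) for g in genera]


def classify_mechanism(
    summary: GenusSCSSummary, threshold: float = 1.0
) -> GenusSCSSummary:
    """Attach fusion/fission/neither classifications to a genus summary.

    XO vs XY: a lower XY mean is a fusion signal; an XY mean at least
    ``threshold`` autosomes higher is a fission signal; increases below
    the threshold are "neither".  To multi-XY: a lower multi-XY mean than
    the ancestral pool (XY if present, else XO) indicates fusion; higher
    or unchanged indicates fission.
    """
    cls_xo_xy = None
    if summary.has_xo_xy_pair:
        diff = summary.mean_autosomes[XY] - summary.mean_autosomes[XO]
        if diff < 0:
            cls_xo_xy = FUSION
        elif diff >= threshold:
            cls_xo_xy = FISSION
        else:
            cls_xo_xy = NEITHER
    cls_multi = None
    if summary.multixy_evaluable:
        ref = summary.mean_autosomes.get(XY, summary.mean_autosomes.get(XO))
        cls_multi = FUSION if summary.mean_autosomes[MULTI_XY] < ref else FISSION
    return replace(
        summary,
        classification_xo_xy=cls_xo_xy,
        classification_to_multixy=cls_multi,
    )


@dataclass
class MechanismTally:
    """Counts and percentages of genera per classification, by transition."""

    n_genera: int
    n_xo_xy: int
    xo_xy_counts: dict[str, int]
    n_multixy: int
    multixy_counts: dict[str, int]

    def fraction_xo_xy(self, label: str) -> float:
        return self.xo_xy_counts.get(label, 0) / self.n_xo_xy if self.n_xo_xy else 0.0

    def fraction_multixy(self, label: str) -> float:
        return (
            self.multixy_counts.get(label, 0) / self.n_multixy
            if self.n_multixy
            else 0.0
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for label in (FUSION, FISSION, NEITHER):
            rows.append(
                {
                    "classification": label,
                    "xo_to_xy": self.xo_xy_counts.get(label, 0),
                    "to_multixy": self.multixy_counts.get(label, 0),
                }
            )
        return pd.DataFrame(rows)


def tabulate_mechanisms(summaries: Sequence[GenusSCSSummary]) -> MechanismTally:
    """Tally classified genus summaries by transition type."""
    xo_xy: dict[str, int] = {}
    multi: dict[str, int] = {}
    for s in summaries:
        if s.classification_xo_xy is not None:
            xo_xy[s.classification_xo_xy] = xo_xy.get(s.classification_xo_xy, 0) + 1
        if s.classification_to_multixy is not None:
            multi[s.classification_to_multixy] = (
                multi.get(s.classification_to_multixy, 0) + 1
            )
    return MechanismTally(
        n_genera=len(summaries),
        n_xo_xy=sum(xo_xy.values()),
        xo_xy_counts=xo_xy,
        n_multixy=sum(multi.values()),
        multixy_counts=multi,
    )


def summarize_by_order(records: Iterable[KaryotypeRecord]) -> pd.DataFrame:
    """Per (order, SCS): n, mean and sample variance of chromosome number.

    Variance uses the n-1 denominator and is reported as missing (NaN)
    for single-species cells.
    """
    rows = []
    cells: dict[tuple[str, str], list[float]] = {}
    for r in records:
        if not r.order or r.scs == UNKNOWN:
            continue
        cells.setdefault((r.order, r.scs), []).append(r.mean_count)
    for (order, scs), vals in sorted(cells.items()):
        v = np.asarray(vals)
        rows.append(
            {
                "order": order,
                "scs": scs,
                "n": len(v),
                "mean": float(v.mean()),
                "variance": float(v.var(ddof=1)) if len(v) > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows, columns=["order", "scs", "n", "mean", "variance"])


def format_table(summaries: Sequence[GenusSCSSummary]) -> str:
    """Human-readable genus table in the published layout."""
    lines = [
        f"{'order':<14}{'genus (n)':<24}{'XO':>8}{'XY':>8}{'multiXY':>9}"
        f"  {'XO to XY':<10}{'to multi-XY':<12}"
    ]
    for s in summaries:
        m = s.mean_autosomes
        fmt = lambda x: f"{x:g}" if x is not None else ""
        lines.append(
            f"{s.order:<14}{s.genus + ' (' + str(s.n_total) + ')':<24}"
            f"{fmt(m.get(XO)):>8}{fmt(m.get(XY)):>8}{fmt(m.get(MULTI_XY)):>9}"
            f"  {s.classification_xo_xy or '-':<10}"
            f"{s.classification_to_multixy or '-':<12}"
        )
    return "\n".join(lines)


def summaries_to_dataframe(summaries: Sequence[GenusSCSSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        rows.append(
            {
                "order": s.order,
                "genus": s.genus,
                "n_samples": s.n_total,
                "mean_xo": s.mean_autosomes.get(XO),
                "mean_xy": s.mean_autosomes.get(XY),
                "mean_multixy": s.mean_autosomes.get(MULTI_XY),
                "classification_xo_xy": s.classification_xo_xy,
                "classification_to_multixy": s.classification_to_multixy,
            }
        )
    return pd.DataFrame(rows)
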
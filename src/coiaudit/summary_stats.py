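"""Family-level summaries, dark-taxa correlations and sequencing yields.

The family summary mirrors the reference-library overview table: species
reported in a national checklist, barcode clusters recovered, the
barcoded/reported ratio, the family's body-size interval and mid-range,
and the percentage of "dark" (unnamed) barcoded taxa.  The dark-taxa rate
is tested for a one-sided Pearson correlation against mid-range body size
(expected negative) and against checklist species richness (expected
positive), with and without families whose dark-taxa rate is zero.

Transcriptions of the published campaign tables ship with the package:
``load_family_table`` (families), ``load_cdc_table`` (species split over
multiple clusters) and ``load_bin_sharing_table`` (clusters shared by
several species).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .library_audit import SpeciesAudit, is_binomial

__all__ = [
    "FamilySummary",
    "CorrelationResult",
    "YieldReport",
    "load_family_table",
    "load_cdc_table",
    "load_bin_sharing_table",
    "family_summary",
    "family_summaries_from_table",
    "dark_taxa_correlation",
    "yield_report",
    "split_share_summary",
]


def _data(name: str):
    return resources.files("coiaudit").joinpath("data", name)


def load_family_table() -> pd.DataFrame:
    """Packaged per-family overview (checklist counts, clusters, sizes)."""
    with _data("table1_families.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])


def load_cdc_table() -> pd.DataFrame:
    """Packaged table of species split across >= 2 clusters (percent ISP)."""
    with _data("table2_cdc.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_bin_sharing_table() -> pd.DataFrame:
    """Packaged table of clusters shared by >= 2 named species."""
    with _data("table3_bs.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["NA"])


@dataclass
class FamilySummary:
    """One family row of the library overview."""

    family: str
    infraorder: str | None
    species_reported: int
    n_clusters: int
    size_lo: float
    size_hi: float
    taxa_with_barcode: int
    unnamed_with_barcode: int

    def __post_init__(self) -> None:
        if self.unnamed_with_barcode > self.taxa_with_barcode:
            raise ValueError(
                f"{self.family}: unnamed taxa exceed barcoded taxa"
            )

    @property
    def ratio_barcoded(self) -> float | None:
        if self.species_reported == 0:
            return None
        return 100.0 * self.n_clusters / self.species_reported

    @property
    def size_mid(self) -> float:
        return 0.5 * (self.size_lo + self.size_hi)

    @property
    def pct_dark(self) -> float | None:
        if self.taxa_with_barcode == 0:
            return None
        return 100.0 * self.unnamed_with_barcode / self.taxa_with_barcode

    def to_row(self) -> dict:
        ratio = self.ratio_barcoded
        pct = self.pct_dark
        return {
            "family": self.family,
            "infraorder": self.infraorder,
            "species_reported": self.species_reported,
            "n_clusters": self.n_clusters,
            "ratio_barcoded": None if ratio is None else round(ratio),
            "size_lo": self.size_lo,
            "size_hi": self.size_hi,
            "size_mid": self.size_mid,
            "taxa_with_barcode": self.taxa_with_barcode,
            "unnamed_with_barcode": self.unnamed_with_barcode,
            "pct_dark": None if pct is None else round(pct, 2),
        }


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    direction: str  # "negative" or "positive"

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0:
            raise ValueError("r outside [-1, 1]")
        if self.n < 3:
            raise ValueError("correlation needs n >= 3")


@dataclass(frozen=True)
class YieldReport:
    """Sequencing-yield bookkeeping with percentages of submitted."""

    submitted: int
    recovered: int
    bidirectional_full: int
    unidirectional_ge500: int
    below_500: int
    failed: int

    def __post_init__(self) -> None:
        if self.submitted <= 0:
            raise ValueError("submitted must be positive")
        if self.recovered + self.failed != self.submitted:
            raise ValueError("recovered + failed must equal submitted")
        parts = (self.bidirectional_full + self.unidirectional_ge500
                 + self.below_500)
        if parts != self.recovered:
            raise ValueError("sequence-length classes must sum to recovered")

    def _pct(self, count: int) -> float:
        return round(100.0 * count / self.submitted, 2)

    @property
    def pct_recovered(self) -> float:
        return self._pct(self.recovered)

    @property
    def pct_bidirectional_full(self) -> float:
        return self._pct(self.bidirectional_full)

    @property
    def pct_unidirectional_ge500(self) -> float:
        return self._pct(self.unidirectional_ge500)

    @property
    def pct_below_500(self) -> float:
        return self._pct(self.below_500)

    @property
    def pct_failed(self) -> float:
        return self._pct(self.failed)


def family_summary(
    audits: Sequence[SpeciesAudit],
    clusters_per_family: Mapping[str, int],
    checklist: pd.DataFrame,
) -> list:
    """Family summaries from audit rows plus a checklist.

    ``checklist`` needs columns family, species_reported, size_lo, size_hi
    and optionally infraorder.  A family present in the audit but missing
    from the checklist is an error.  Families in the checklist without
    barcoded taxa get zero counts (and hence an absent dark-taxa rate).
    """
    known = set(checklist["family"])
    audited = {a.family for a in audits if a.family}
    missing = sorted(audited - known)
    if missing:
        raise ValueError(f"families absent from checklist: {missing}")
    rows = []
    for rec in checklist.to_dict("records"):
        fam = rec["family"]
        fam_audits = [a for a in audits if a.family == fam]
        rows.append(FamilySummary(
            family=fam,
            infraorder=rec.get("infraorder"),
            species_reported=int(rec["species_reported"]),
            n_clusters=int(clusters_per_family.get(fam, 0)),
            size_lo=float(rec["size_lo"]),
            size_hi=float(rec["size_hi"]),
            taxa_with_barcode=len(fam_audits),
            unnamed_with_barcode=sum(
                1 for a in fam_audits if not is_binomial(a.species)
            ),
        ))
    return rows


def family_summaries_from_table(table: pd.DataFrame | None = None) -> list:
    """FamilySummary rows from the packaged (or a like-shaped) family table."""
    if table is None:
        table = load_family_table()
    rows = []
    for rec in table.to_dict("records"):
        if pd.isna(rec["taxa_with_barcode"]):
            continue
        rows.append(FamilySummary(
            family=rec["family"],
            infraorder=rec.get("infraorder"),
            species_reported=int(rec["species_reported"]),
            n_clusters=int(rec["n_clusters"]),
            size_lo=float(rec["size_lo"]),
            size_hi=float(rec["size_hi"]),
            taxa_with_barcode=int(rec["taxa_with_barcode"]),
            unnamed_with_barcode=int(rec["unnamed_with_barcode"]),
        ))
    return rows


_DIRECTIONS = {"size_mid": "negative", "species_reported": "positive"}


def dark_taxa_correlation(
    rows: Sequence[FamilySummary],
    covariate: str = "size_mid",
    include_zero_dark: bool = True,
) -> CorrelationResult:
    """One-sided Pearson correlation of the dark-taxa rate with a covariate.

    ``covariate`` is ``"size_mid"`` (tested for a negative correlation) or
    ``"species_reported"`` (positive).  Families without barcoded taxa are
    always excluded; ``include_zero_dark=False`` additionally drops
    families whose dark-taxa rate is exactly zero.
    """
    if covariate not in _DIRECTIONS:
        raise ValueError(f"unknown covariate {covariate!r}")
    direction = _DIRECTIONS[covariate]
    usable = [row for row in rows if row.pct_dark is not None]
    if not include_zero_dark:
        usable = [row for row in usable if row.pct_dark > 0]
    if len(usable) < 3:
        raise ValueError("correlation needs at least 3 usable families")
    x = np.array([getattr(row, covariate) for row in usable], dtype=float)
    y = np.array([row.pct_dark for row in usable], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in correlation input")
    alternative = "less" if direction == "negative" else "greater"
    res = stats.pearsonr(x, y, alternative=alternative)
    return CorrelationResult(
        r=float(res.statistic), p=float(res.pvalue), n=len(usable),
        direction=direction,
    )


def yield_report(
    submitted: int,
    recovered: int,
    bidirectional_full: int,
    unidirectional_ge500: int,
    below_500: int,
) -> YieldReport:
    """Build a YieldReport; ``failed`` is derived as submitted - recovered."""
    return YieldReport(
        submitted=submitted,
        recovered=recovered,
        bidirectional_full=bidirectional_full,
        unidirectional_ge500=unidirectional_ge500,
        below_500=below_500,
        failed=submitted - recovered,
    )


def split_share_summary(
    n_affected_species: int,
    n_named_species: int,
    n_affected_specimens: int,
    n_total_specimens: int,
) -> dict:
    """Species- and specimen-level percentages for a discordance class.

    Species share is printed to 2 decimals, specimen share to 1, matching
    the customary reporting precision.
    """
    if n_named_species <= 0 or n_total_specimens <= 0:
        raise ValueError("totals must be positive")
    return {
        "pct_species": round(100.0 * n_affected_species / n_named_species, 2),
        "pct_specimens": round(100.0 * n_affected_specimens / n_total_specimens, 1),
    }
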
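"""Per-species barcode-gap statistics and cluster-discordance classification.

A named species whose specimens fall into two or more clusters is a
cryptic-diversity candidate (CDC, "split"); a cluster containing two or
more named species is a case of cluster sharing (BS, "merge").  Split
species are banded by their maximum intraspecific divergence (maxISP, in
percent): low (<= 3%), mid (3-6%] and high (> 6%).  Divergences are
reported on the percent scale throughout this module.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from . import distances as _dist
from . import clustering as _clust
from .seqio import SequenceRecord, TAXONOMY_RANKS

__all__ = [
    "SpeciesAudit",
    "ClusterAuditRow",
    "species_stats",
    "classify_discordance",
    "severity_band",
    "band_partition",
    "barcode_gap_flag",
    "interim_name",
    "audit_report",
    "is_binomial",
]

STATUSES = ("concordant", "split", "shared", "split_and_shared", "singleton_data")

BAND_LOW_MAX = 3.0   # percent maxISP, inclusive upper edge of the low band
BAND_MID_MAX = 6.0   # percent maxISP, inclusive upper edge of the mid band

#: Interim names look like "Megaselia sp. BOLD:ACP6151" or
#: "Tachinidae sp. C000123"; a plain Linnean binomial does not contain " sp.".
_INTERIM_RE = re.compile(r"\bsp\.(\s|$)")


def is_binomial(name: str | None) -> bool:
    """True for a plain Linnean binomial, False for interim/absent names."""
    return bool(name) and not _INTERIM_RE.search(name)


@dataclass
class SpeciesAudit:
    """Barcode-gap statistics and discordance status for one species.

    ``mean_isp``/``max_isp``/``nn_dist`` are percent K2P; the intraspecific
    fields are ``None`` for species with a single sequenced member.
    ``cdc_rank`` equals ``n_clusters`` for split species, ``None`` otherwise.
    """

    species: str
    family: str | None
    n_specimens: int
    mean_isp: float | None
    max_isp: float | None
    nn_dist: float | None
    nn_species: str | None
    n_clusters: int = 0
    cluster_ids: tuple = ()
    status: str = "concordant"
    cdc_rank: int | None = None
    band: str = "none"

    def __post_init__(self) -> None:
        if self.mean_isp is not None and self.max_isp is not None:
            if self.mean_isp > self.max_isp + 1e-9:
                raise ValueError(f"{self.species}: mean_isp > max_isp")

    def to_row(self) -> dict:
        return {
            "species": self.species,
            "family": self.family,
            "n_specimens": self.n_specimens,
            "mean_isp": None if self.mean_isp is None else round(self.mean_isp, 4),
            "max_isp": None if self.max_isp is None else round(self.max_isp, 4),
            "nn_dist": None if self.nn_dist is None else round(self.nn_dist, 4),
            "nn_species": self.nn_species,
            "n_clusters": self.n_clusters,
            "status": self.status,
            "band": self.band,
        }


@dataclass
class ClusterAuditRow:
    """One cluster: its member species and the number of named ones (BS rank)."""

    cluster_id: str
    member_species: tuple
    bs_rank: int
    contains_dark: bool

    def __post_init__(self) -> None:
        if self.bs_rank < 1:
            raise ValueError(f"{self.cluster_id}: bs_rank must be >= 1")


def species_stats(
    matrix: _dist.DistanceMatrix,
    species_of: Mapping[str, str],
    family_of: Mapping[str, str] | None = None,
) -> list:
    """Per-species mean/max intraspecific K2P and nearest neighbour (percent).

    Species with a single member in the matrix get ``singleton_data`` status
    and absent intraspecific fields; their nearest neighbour is still
    computed.
    """
    unknown = [rid for rid in matrix.ids if rid not in species_of]
    if unknown:
        raise KeyError(f"records missing from species map: {unknown[:5]}")
    nn = _dist.nearest_neighbor(matrix, species_of)
    labels = np.array([species_of[rid] for rid in matrix.ids])
    audits = []
    for sp in sorted(set(labels)):
        members = np.flatnonzero(labels == sp)
        family = None
        if family_of is not None:
            fams = {family_of.get(matrix.ids[i]) for i in members} - {None}
            family = min(fams) if fams else None
        nn_dist, nn_sp = nn[sp]
        if len(members) < 2:
            audits.append(SpeciesAudit(
                species=sp, family=family, n_specimens=int(len(members)),
                mean_isp=None, max_isp=None,
                nn_dist=100.0 * nn_dist, nn_species=nn_sp,
                status="singleton_data",
            ))
            continue
        sub = matrix.d[np.ix_(members, members)]
        pairs = sub[np.triu_indices_from(sub, k=1)]
        pairs = pairs[np.isfinite(pairs)]
        if pairs.size == 0:
            raise ValueError(f"species {sp!r}: all intraspecific pairs saturated")
        audits.append(SpeciesAudit(
            species=sp, family=family, n_specimens=int(len(members)),
            mean_isp=100.0 * float(pairs.mean()),
            max_isp=100.0 * float(pairs.max()),
            nn_dist=100.0 * nn_dist, nn_species=nn_sp,
        ))
    return audits


def classify_discordance(
    species_of: Mapping[str, str],
    clusters: _clust.ClusterAssignment,
    named: Callable[[str], bool] = is_binomial,
) -> tuple:
    """Split/shared classification of species against a clustering.

    Returns ``(species_status, cluster_rows)`` where ``species_status`` maps
    species -> dict with ``status``, ``n_clusters``, ``cluster_ids`` and
    ``cdc_rank``.  A species spanning >= 2 clusters is split (cdc_rank =
    cluster count); every named species in a cluster holding >= 2 named
    species is shared (the cluster's bs_rank = its named-species count);
    both at once is split_and_shared.  Unnamed (dark) species never create
    sharing conflicts: interim names are cluster-derived and would share by
    construction.
    """
    member_cluster = clusters.member_to_cluster
    missing = [rid for rid in species_of if rid not in member_cluster]
    if missing:
        raise KeyError(f"records missing a cluster: {missing[:5]}")
    sp_clusters: dict = {}
    cluster_species: dict = {cid: set() for cid in clusters.clusters}
    for rid, sp in species_of.items():
        cid = member_cluster[rid]
        sp_clusters.setdefault(sp, set()).add(cid)
        cluster_species[cid].add(sp)

    shared_species: set = set()
    cluster_rows = []
    for cid in sorted(cluster_species):
        species_here = cluster_species[cid]
        named_here = sorted(s for s in species_here if named(s))
        bs_rank = max(len(named_here), 1)
        if len(named_here) >= 2:
            shared_species.update(named_here)
        cluster_rows.append(ClusterAuditRow(
            cluster_id=cid,
            member_species=tuple(sorted(species_here)),
            bs_rank=bs_rank,
            contains_dark=any(not named(s) for s in species_here),
        ))

    species_status: dict = {}
    for sp, cids in sp_clusters.items():
        split = len(cids) >= 2
        shared = sp in shared_species
        if split and shared:
            status = "split_and_shared"
        elif split:
            status = "split"
        elif shared:
            status = "shared"
        else:
            status = "concordant"
        species_status[sp] = {
            "status": status,
            "n_clusters": len(cids),
            "cluster_ids": tuple(sorted(cids)),
            "cdc_rank": len(cids) if split else None,
        }
    return species_status, cluster_rows


def severity_band(max_isp: float | None) -> str:
    """Band a split species by percent maxISP: low <=3, mid (3,6], high >6."""
    if max_isp is None:
        return "none"
    if max_isp <= BAND_LOW_MAX:
        return "low"
    if max_isp <= BAND_MID_MAX:
        return "mid"
    return "high"


def band_partition(max_isps: Iterable[float]) -> tuple:
    """(low, mid, high) tallies of a collection of percent maxISP values."""
    counts = {"low": 0, "mid": 0, "high": 0}
    for value in max_isps:
        counts[severity_band(float(value))] += 1
    return counts["low"], counts["mid"], counts["high"]


def barcode_gap_flag(audit: SpeciesAudit) -> bool:
    """Local barcode gap: maxISP strictly below the nearest-neighbour distance.

    Singleton-data species pass vacuously (no intraspecific pair exists).
    """
    if audit.status == "singleton_data" or audit.max_isp is None:
        return True
    return audit.max_isp < audit.nn_dist


def interim_name(
    members_taxonomy: Sequence[Mapping[str, str]], cluster_id: str
) -> str:
    """Reverse-taxonomy interim name for a cluster.

    If the named members agree on a single binomial, that binomial is
    returned unchanged.  Otherwise the deepest rank on which all members
    with an assignment agree yields ``"<Taxon> sp. <cluster_id>"``.  No
    shared rank at all is an error.
    """
    species_names = {t.get("species") for t in members_taxonomy if t.get("species")}
    binomials = {s for s in species_names if is_binomial(s)}
    if len(binomials) == 1 and len(species_names) == 1:
        return next(iter(binomials))
    for rank in reversed(TAXONOMY_RANKS[:-1]):  # genus, family, order
        values = {t.get(rank) for t in members_taxonomy if t.get(rank)}
        if len(values) == 1:
            return f"{next(iter(values))} sp. {cluster_id}"
    raise ValueError(f"cluster {cluster_id}: members share no taxonomy at any rank")


def audit_report(
    records: Sequence[SequenceRecord],
    min_len: int = 500,
    threshold: float = _clust.SINGLE_LINKAGE_THRESHOLD,
) -> dict:
    """End-to-end library audit: distances, clusters, per-species audit rows
    and a counts summary.

    Unnamed records are first given interim names per cluster so they take
    part in the barcode-gap statistics; the summary percentages, however,
    are over named (binomial) species only, as are split/shared tallies.

    Returns a dict with ``audits`` (list of SpeciesAudit), ``clusters``
    (ClusterAssignment), ``cluster_rows``, ``matrix`` and ``summary``.
    """
    if not records:
        raise ValueError("empty library")
    matrix = _dist.pairwise_matrix(records, min_len=min_len)
    clusters = single_linkage = _clust.single_linkage_clusters(matrix, threshold)
    member_cluster = clusters.member_to_cluster
    by_id = {r.record_id: r for r in records}

    # Reverse taxonomy: name dark records by their cluster.
    species_of: dict = {}
    for cid, member_ids in clusters.clusters.items():
        interim = None
        for rid in member_ids:
            rec = by_id[rid]
            if rec.species:
                species_of[rid] = rec.species
            else:
                if interim is None:
                    interim = interim_name(
                        [by_id[m].taxonomy for m in member_ids
                         if not by_id[m].species], cid)
                species_of[rid] = interim

    family_of = {rid: by_id[rid].family for rid in matrix.ids}
    audits = species_stats(matrix, species_of, family_of)
    statuses, cluster_rows = classify_discordance(species_of, clusters)
    for audit in audits:
        info = statuses[audit.species]
        audit.n_clusters = info["n_clusters"]
        audit.cluster_ids = info["cluster_ids"]
        audit.cdc_rank = info["cdc_rank"]
        if audit.status != "singleton_data":
            audit.status = info["status"]
        if audit.status in ("split", "split_and_shared"):
            audit.band = severity_band(audit.max_isp)

    named_audits = [a for a in audits if is_binomial(a.species)]
    n_named = len(named_audits)
    tally = {status: 0 for status in STATUSES}
    for a in named_audits:
        tally[a.status] += 1
    split_audits = [a for a in named_audits
                    if a.status in ("split", "split_and_shared")]
    low, mid, high = band_partition(
        a.max_isp for a in split_audits if a.max_isp is not None
    )
    summary = {
        "n_species_named": n_named,
        "n_species_total": len(audits),
        **{f"n_{s}": tally[s] for s in STATUSES},
        "pct_split": round(
            100.0 * (tally["split"] + tally["split_and_shared"]) / n_named, 2
        ) if n_named else 0.0,
        "pct_shared": round(
            100.0 * (tally["shared"] + tally["split_and_shared"]) / n_named, 2
        ) if n_named else 0.0,
        "band_low": low,
        "band_mid": mid,
        "band_high": high,
    }
    return {
        "audits": audits,
        "clusters": single_linkage,
        "cluster_rows": cluster_rows,
        "matrix": matrix,
        "summary": summary,
        "species_of": species_of,
    }
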
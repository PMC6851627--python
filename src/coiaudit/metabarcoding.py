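"""Bulk-sample metabarcoding pipeline.

Stages, in order, mirroring a vsearch/cutadapt amplicon workflow:

    merge pairs -> trim primers -> quality filter (expected errors)
    -> dereplicate -> remove chimeras -> cluster OTUs (97% identity)
    -> assign taxonomy by best hit -> filter table (identity & abundance)
    -> merge OTUs to clusters/BINs -> presence-absence

Every stage keeps a read ledger so input counts always reconcile:
pairs in = merged + merge-rejected, merged = trimmed + untrimmed-discarded,
and so on.  The pipeline is deterministic given its input files.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import clustering as _clust
from .seqio import PairedRead, SampleManifest, SequenceRecord, read_fastq_pairs

__all__ = [
    "MergedRead",
    "UniqueSeq",
    "OTUTable",
    "PipelineParams",
    "PipelineResult",
    "merge_pairs",
    "trim_primers",
    "expected_errors",
    "quality_filter",
    "dereplicate",
    "merge_sample_dereps",
    "remove_chimeras",
    "assign_taxonomy",
    "filter_otu_table",
    "merge_otus_to_bins",
    "presence_absence",
    "run_pipeline",
    "reverse_complement",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVN-", "TGCAYRSWMKVHDBN-"
)

#: IUPAC degeneracy sets used when matching primers against reads.
IUPAC_SETS: dict = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class MergedRead:
    """A merged (overlap-assembled) amplicon read with per-base Phred."""

    read_id: str
    sequence: str
    quality: list
    sample_id: str

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"{self.read_id}: seq/qual length mismatch")


@dataclass
class UniqueSeq:
    """A dereplicated sequence with global abundance and sample breakdown."""

    sequence: str
    abundance: int
    samples: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.samples and sum(self.samples.values()) != self.abundance:
            raise ValueError("abundance must equal the sum of sample counts")
        if self.abundance < 1:
            raise ValueError("abundance must be >= 1")


@dataclass
class OTUTable:
    """OTU (or cluster/BIN) x sample read counts plus per-row metadata.

    ``counts``: DataFrame indexed by row id with one integer column per
    sample.  ``meta``: DataFrame on the same index with ``centroid``,
    ``identity`` (percent), ``family``, ``genus``, ``species`` and
    ``bin_id`` columns.
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.meta.index):
            raise ValueError("counts and meta must share an index")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative read count")

    @property
    def total_reads(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_rows(self) -> pd.DataFrame:
        out = self.meta.copy()
        out.insert(0, "otu_id", out.index)
        return pd.concat([out, self.counts], axis=1).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Read merging

def merge_pairs(
    pair: PairedRead,
    min_overlap: int = 40,
    max_mismatch_frac: float = 0.1,
) -> MergedRead | None:
    """Overlap-merge a read pair, or return None (reject) if no overlap
    of at least ``min_overlap`` bases has a mismatch fraction within
    ``max_mismatch_frac``.

    The reverse mate is reverse-complemented; the best overlap is the one
    with the lowest mismatch fraction, ties going to the longest overlap.
    Within the overlap the base with the higher Phred score wins (forward
    wins ties) and the merged Phred is the maximum of the two.
    """
    fwd, rc = pair.forward_seq, reverse_complement(pair.reverse_seq)
    fq = pair.forward_qual
    rq = pair.reverse_qual[::-1]
    max_o = min(len(fwd), len(rc))
    if max_o < min_overlap:
        return None
    best: tuple | None = None  # (mismatch_frac, -overlap, overlap)
    # exact overlaps first: any zero-mismatch overlap beats all others, and
    # among them the longest wins, so a plain string scan settles most reads
    for o in range(max_o, min_overlap - 1, -1):
        if fwd[len(fwd) - o:] == rc[:o]:
            best = (0.0, -o, o)
            break
    if best is None:
        af = np.frombuffer(fwd.encode(), dtype=np.uint8)
        ar = np.frombuffer(rc.encode(), dtype=np.uint8)
        for o in range(min_overlap, max_o + 1):
            mism = int((af[len(af) - o:] != ar[:o]).sum())
            frac = mism / o
            if frac <= max_mismatch_frac:
                cand = (frac, -o, o)
                if best is None or cand < best:
                    best = cand
    if best is None:
        return None
    o = best[2]
    head_len = len(fwd) - o
    merged_seq = list(fwd[:head_len])
    merged_qual = list(fq[:head_len])
    for k in range(o):
        bf, br = fwd[head_len + k], rc[k]
        qf, qr = fq[head_len + k], rq[k]
        if br != bf and qr > qf:
            merged_seq.append(br)
        else:
            merged_seq.append(bf)
        merged_qual.append(max(qf, qr))
    merged_seq.extend(rc[o:])
    merged_qual.extend(rq[o:])
    return MergedRead(
        read_id=pair.read_id,
        sequence="".join(merged_seq),
        quality=merged_qual,
        sample_id=pair.sample_id,
    )


# ---------------------------------------------------------------------------
# Primer trimming

def _primer_matches(window: str, primer: str) -> int:
    return sum(base in IUPAC_SETS.get(code, code)
               for base, code in zip(window, primer))


def trim_primers(
    read: MergedRead,
    fwd_primer: str,
    rev_primer: str,
    min_identity: float = 0.90,
    slack: int = 5,
) -> MergedRead | None:
    """Locate and strip both primers, or return None (discard).

    The forward primer is sought at the 5' end and the reverse-complemented
    reverse primer at the 3' end, each within ``slack`` bases of the read
    boundary.  Detection requires matching positions / primer length >=
    ``min_identity``; IUPAC degeneracies in the primers match their sets.
    """
    if not fwd_primer or not rev_primer:
        raise ValueError("primers must be non-empty")
    seq = read.sequence
    fwd_primer = fwd_primer.upper()
    rc_rev = reverse_complement(rev_primer.upper())
    lf, lr = len(fwd_primer), len(rc_rev)

    best_f: tuple | None = None
    for off in range(0, slack + 1):
        if off + lf > len(seq):
            break
        score = _primer_matches(seq[off:off + lf], fwd_primer)
        if best_f is None or score > best_f[0]:
            best_f = (score, off)
    if best_f is None or best_f[0] / lf < min_identity:
        return None

    best_r: tuple | None = None
    for off in range(0, slack + 1):
        start = len(seq) - lr - off
        if start < 0:
            break
        score = _primer_matches(seq[start:start + lr], rc_rev)
        if best_r is None or score > best_r[0]:
            best_r = (score, off)
    if best_r is None or best_r[0] / lr < min_identity:
        return None

    start = best_f[1] + lf
    end = len(seq) - lr - best_r[1]
    if end <= start:
        return None
    return MergedRead(
        read_id=read.read_id,
        sequence=seq[start:end],
        quality=read.quality[start:end],
        sample_id=read.sample_id,
    )


# ---------------------------------------------------------------------------
# Quality filtering

def expected_errors(quality: Sequence[int]) -> float:
    """Expected number of errors: sum of 10^(-Q/10) over bases."""
    if len(quality) == 0:
        return 0.0
    q = np.asarray(quality, dtype=float)
    return float(np.power(10.0, -q / 10.0).sum())


def quality_filter(
    reads: Iterable[MergedRead], max_ee: float = 1.0
) -> tuple:
    """Split reads into (kept, discarded) by expected errors <= max_ee."""
    kept, discarded = [], []
    for read in reads:
        (kept if expected_errors(read.quality) <= max_ee else discarded).append(read)
    return kept, discarded


# ---------------------------------------------------------------------------
# Dereplication

def dereplicate(reads: Iterable[MergedRead], scope: str = "global"):
    """Collapse exact duplicate sequences, accumulating abundance.

    ``scope="global"`` returns a list of :class:`UniqueSeq` sorted by
    decreasing global abundance (ties: lexicographic sequence) with the
    per-sample breakdown retained.  ``scope="sample"`` returns a dict
    ``sample_id -> list[UniqueSeq]``, each sorted the same way.
    """
    if scope not in ("global", "sample"):
        raise ValueError(f"unknown dereplication scope {scope!r}")
    per_sample: dict = defaultdict(Counter)
    for read in reads:
        per_sample[read.sample_id][read.sequence] += 1
    if scope == "sample":
        return {
            sid: _sorted_uniques({seq: {sid: n} for seq, n in counter.items()})
            for sid, counter in per_sample.items()
        }
    breakdown: dict = defaultdict(dict)
    for sid, counter in per_sample.items():
        for seq, n in counter.items():
            breakdown[seq][sid] = n
    return _sorted_uniques(breakdown)


def _sorted_uniques(breakdown: Mapping[str, Mapping[str, int]]) -> list:
    uniques = [
        UniqueSeq(sequence=seq, abundance=sum(samples.values()),
                  samples=dict(samples))
        for seq, samples in breakdown.items()
    ]
    uniques.sort(key=lambda u: (-u.abundance, u.sequence))
    return uniques


def merge_sample_dereps(per_sample: Mapping[str, Sequence[UniqueSeq]]) -> list:
    """Combine sample-level dereplications into the global dereplication."""
    breakdown: dict = defaultdict(dict)
    for sid, uniques in per_sample.items():
        for u in uniques:
            breakdown[u.sequence][sid] = breakdown[u.sequence].get(sid, 0) \
                + u.abundance
    return _sorted_uniques(breakdown)


# ---------------------------------------------------------------------------
# Chimera removal

def remove_chimeras(
    uniques: Sequence[UniqueSeq],
    min_parent_ratio: float = 2.0,
    identity_threshold: float = 0.99,
) -> tuple:
    """De novo two-parent chimera filter; returns (kept, flagged).

    A unique U is flagged iff two parents A and B exist, each with
    abundance >= ``min_parent_ratio`` x abundance(U), and a crossover point
    c such that U[:c] matches A[:c] and U[c:] matches B[c:] each at >=
    ``identity_threshold``, while no more-abundant unique alone matches U at
    >= the threshold over its full length (such a U is a point-error variant
    of that sequence, not a chimera).  Parents are searched among
    equal-length more-abundant uniques only; the most abundant unique can
    never be flagged.  This is a documented simplification of uchime_denovo matched
    to a single-crossover two-parent chimera model.
    """
    if not uniques:
        return [], []
    order = sorted(uniques, key=lambda u: (-u.abundance, u.sequence))
    by_len: dict = defaultdict(list)
    for u in order:
        by_len[len(u.sequence)].append(u)
    kept, flagged = [], []
    enc_cache: dict = {}

    def enc(seq: str) -> np.ndarray:
        arr = enc_cache.get(seq)
        if arr is None:
            arr = np.frombuffer(seq.encode(), dtype=np.uint8)
            enc_cache[seq] = arr
        return arr

    for u in order:
        # every strictly more-abundant unique of the same length
        others = [
            c for c in by_len[len(u.sequence)]
            if c.abundance > u.abundance and c.sequence != u.sequence
        ]
        if not others:
            kept.append(u)
            continue
        L = len(u.sequence)
        cand_mat = np.stack([enc(c.sequence) for c in others])
        match = cand_mat == enc(u.sequence)            # (n_cand, L)
        overall = match.sum(axis=1) / L
        # a unique explained by any single more-abundant sequence is a
        # variant, never a chimera (self-match exclusion)
        if (overall >= identity_threshold).any():
            kept.append(u)
            continue
        abundances = np.array([c.abundance for c in others], dtype=float)
        eligible = abundances >= min_parent_ratio * u.abundance
        if not eligible.any():
            kept.append(u)
            continue
        prefix = np.cumsum(match[eligible], axis=1).astype(float)  # matches in U[:c]
        total = prefix[:, -1][:, None]
        cols = np.arange(1, L, dtype=float)
        prefix_ok = prefix[:, :-1] / cols >= identity_threshold          # c = 1..L-1
        suffix_ok = (total - prefix[:, :-1]) / (L - cols) >= identity_threshold
        n_pref = prefix_ok.sum(axis=0)
        n_suff = suffix_ok.sum(axis=0)
        both = (n_pref >= 1) & (n_suff >= 1)
        is_chimera = False
        if both.any():
            for c in np.flatnonzero(both):
                pref_idx = np.flatnonzero(prefix_ok[:, c])
                suff_idx = np.flatnonzero(suffix_ok[:, c])
                if len(pref_idx) > 1 or len(suff_idx) > 1 \
                        or pref_idx[0] != suff_idx[0]:
                    is_chimera = True
                    break
        (flagged if is_chimera else kept).append(u)
    return kept, flagged


# ---------------------------------------------------------------------------
# Taxonomy assignment

def assign_taxonomy(
    centroids: Mapping[str, str],
    reference: Sequence[SequenceRecord],
    prefilter: bool = True,
    prefilter_fallback: int = 30,
) -> pd.DataFrame:
    """Best-hit search of OTU centroids against a reference library.

    The best hit maximises semiglobal (terminal-gap-free) identity, the
    Hit-%-ID-style statistic appropriate when a 313-bp minibarcode is
    searched against full-length 658-bp barcodes; ties go to the
    lexicographically smallest reference id.  Taxonomy and cluster id are
    copied from the hit; identity is reported in percent to 2 decimals.

    With ``prefilter`` (default), alignments are restricted to references
    sharing at least half of the centroid's 12-mers — impossible to fail
    for any hit near the reporting thresholds — falling back to the
    ``prefilter_fallback`` references with the highest k-mer sharing when
    no reference passes (low-identity centroids whose exact best-hit value
    is immaterial because the table filter removes them).
    """
    if not reference:
        raise ValueError("empty reference library")
    refs = sorted(reference, key=lambda r: r.record_id)
    ref_kmers = [_clust.kmer_set(r.sequence) for r in refs] if prefilter else None
    rows = []
    for otu_id in sorted(centroids):
        seq = centroids[otu_id]
        if prefilter:
            cent_kmers = _clust.kmer_set(seq)
            shared = [
                _clust.kmer_shared_fraction(cent_kmers, rk) for rk in ref_kmers
            ]
            candidates = [r for r, s in zip(refs, shared)
                          if s >= _clust.KMER_MIN_SHARED]
            if not candidates:
                ranked = sorted(zip(shared, refs),
                                key=lambda t: (-t[0], t[1].record_id))
                candidates = [r for _, r in ranked[:prefilter_fallback]]
        else:
            candidates = refs
        best_ident, best_ref = -1.0, None
        for ref in candidates:
            ident = _clust.semiglobal_identity(seq, ref.sequence)
            if ident > best_ident:
                best_ident, best_ref = ident, ref
        rows.append({
            "otu_id": otu_id,
            "centroid": seq,
            "identity": round(100.0 * best_ident, 2),
            "family": best_ref.taxonomy.get("family"),
            "genus": best_ref.taxonomy.get("genus"),
            "species": best_ref.species,
            "bin_id": best_ref.cluster_id,
            "hit_id": best_ref.record_id,
        })
    return pd.DataFrame(rows).set_index("otu_id")


# ---------------------------------------------------------------------------
# Table filtering and aggregation

def filter_otu_table(
    table: OTUTable,
    min_identity: float = 97.0,
    min_read_frac: float = 1e-4,
    frac_scope: str = "sample",
) -> tuple:
    """Identity and relative-abundance filtering of an OTU table.

    Rows with best-hit identity below ``min_identity`` percent are dropped.
    Then, with ``frac_scope="sample"``, any per-sample count below
    ``min_read_frac`` of that sample's pre-filter total is zeroed;
    ``"global"`` compares against the pre-filter grand total instead.
    All-zero rows are dropped.  Returns (filtered table, removed_reads).
    """
    if frac_scope not in ("sample", "global"):
        raise ValueError(f"unknown frac_scope {frac_scope!r}")
    if table.counts.empty:
        return table, 0
    pre_totals = table.counts.sum(axis=0)
    grand_total = float(pre_totals.sum())
    keep_rows = table.meta["identity"] >= min_identity
    counts = table.counts.loc[keep_rows].copy()
    if frac_scope == "sample":
        thresholds = min_read_frac * pre_totals
        counts = counts.where(counts.ge(thresholds, axis=1), 0)
    else:
        counts = counts.where(counts >= min_read_frac * grand_total, 0)
    nonzero = counts.sum(axis=1) > 0
    counts = counts.loc[nonzero]
    filtered = OTUTable(counts=counts, meta=table.meta.loc[counts.index].copy())
    removed = int(grand_total - counts.to_numpy().sum())
    return filtered, removed


def merge_otus_to_bins(table: OTUTable) -> OTUTable:
    """Merge OTU rows matched to the same cluster/BIN id.

    Counts are summed per sample; the representative identity is the
    maximum and taxonomy comes from the highest-identity row (ties:
    lexicographically smallest OTU id).  Rows without a cluster id keep
    their own OTU id as key.
    """
    if table.counts.empty:
        return table
    keys = table.meta["bin_id"].fillna(pd.Series(table.meta.index,
                                                 index=table.meta.index))
    counts = table.counts.groupby(keys).sum()
    meta_rows = []
    for bin_id, group in table.meta.groupby(keys):
        rep = group.sort_values(
            ["identity"], ascending=False, kind="stable"
        )
        rep = rep.loc[rep["identity"] == rep["identity"].iloc[0]].sort_index()
        row = rep.iloc[0].copy()
        row["bin_id"] = bin_id
        meta_rows.append(row.rename(bin_id))
    meta = pd.DataFrame(meta_rows)
    meta.index.name = table.meta.index.name
    meta = meta.loc[counts.index]
    return OTUTable(counts=counts, meta=meta)


def presence_absence(table: OTUTable) -> pd.DataFrame:
    """Binary (row x sample) matrix: 1 iff the post-filter count is > 0."""
    return (table.counts > 0).astype(int)


# ---------------------------------------------------------------------------
# Orchestration

@dataclass
class PipelineParams:
    """All pipeline thresholds, with the workflow's stated defaults."""

    fwd_primer: str = "GGWACWGGWTGAACWGTWTAYCCYCC"
    rev_primer: str = "TANACYTCNGGRTGNCCRAARAAYCA"
    min_overlap: int = 40
    max_mismatch_frac: float = 0.1
    primer_min_identity: float = 0.90
    max_ee: float = 1.0
    otu_identity: float = 0.97
    assign_min_identity: float = 97.0
    min_read_frac: float = 1e-4
    frac_scope: str = "sample"
    chimera_parent_ratio: float = 2.0
    chimera_identity: float = 0.99


@dataclass
class PipelineResult:
    otu_table: OTUTable
    bin_table: OTUTable
    presence: pd.DataFrame
    ledger: pd.DataFrame
    flagged_chimeras: list


def run_pipeline(
    manifest: Sequence[SampleManifest],
    reference: Sequence[SequenceRecord],
    params: PipelineParams | None = None,
) -> PipelineResult:
    """Run the full bulk-sample pipeline over a manifest of FASTQ pairs."""
    params = params or PipelineParams()
    ledger_rows = []
    all_trimmed: list = []
    for sample in manifest:
        n_pairs = n_merged = n_trimmed = n_kept = 0
        merged_reads = []
        for pair in read_fastq_pairs(
            sample.forward_path, sample.reverse_path, sample.sample_id
        ):
            n_pairs += 1
            merged = merge_pairs(
                pair, min_overlap=params.min_overlap,
                max_mismatch_frac=params.max_mismatch_frac,
            )
            if merged is not None:
                n_merged += 1
                merged_reads.append(merged)
        trimmed_reads = []
        for read in merged_reads:
            trimmed = trim_primers(
                read, params.fwd_primer, params.rev_primer,
                min_identity=params.primer_min_identity,
            )
            if trimmed is not None:
                n_trimmed += 1
                trimmed_reads.append(trimmed)
        kept, _ = quality_filter(trimmed_reads, max_ee=params.max_ee)
        n_kept = len(kept)
        all_trimmed.extend(kept)
        ledger_rows += [
            {"stage": "pairs_in", "sample_id": sample.sample_id, "count": n_pairs},
            {"stage": "merged", "sample_id": sample.sample_id, "count": n_merged},
            {"stage": "merge_rejected", "sample_id": sample.sample_id,
             "count": n_pairs - n_merged},
            {"stage": "trimmed", "sample_id": sample.sample_id, "count": n_trimmed},
            {"stage": "untrimmed_discarded", "sample_id": sample.sample_id,
             "count": n_merged - n_trimmed},
            {"stage": "quality_kept", "sample_id": sample.sample_id, "count": n_kept},
            {"stage": "quality_discarded", "sample_id": sample.sample_id,
             "count": n_trimmed - n_kept},
        ]

    per_sample = dereplicate(all_trimmed, scope="sample")
    uniques = merge_sample_dereps(per_sample)
    kept_uniques, flagged = remove_chimeras(
        uniques, min_parent_ratio=params.chimera_parent_ratio,
        identity_threshold=params.chimera_identity,
    )
    ledger_rows += [
        {"stage": "uniques", "sample_id": "all", "count": len(uniques)},
        {"stage": "chimeras_flagged", "sample_id": "all", "count": len(flagged)},
        {"stage": "uniques_kept", "sample_id": "all", "count": len(kept_uniques)},
    ]

    assignment = _clust.greedy_centroid_cluster(
        [(u.sequence, u.abundance) for u in kept_uniques],
        identity_threshold=params.otu_identity,
        prefilter=True,
    )
    by_seq = {u.sequence: u for u in kept_uniques}
    sample_ids = [s.sample_id for s in manifest]
    count_rows = {}
    for otu_id, member_seqs in assignment.clusters.items():
        tally = Counter()
        for seq in member_seqs:
            tally.update(by_seq[seq].samples)
        count_rows[otu_id] = [tally.get(sid, 0) for sid in sample_ids]
    counts = pd.DataFrame.from_dict(
        count_rows, orient="index", columns=sample_ids
    ).sort_index()
    meta = assign_taxonomy(
        {otu_id: assignment.centroids[otu_id] for otu_id in counts.index},
        reference,
    )
    table = OTUTable(counts=counts, meta=meta.loc[counts.index])
    ledger_rows.append(
        {"stage": "otus", "sample_id": "all", "count": len(counts)}
    )

    filtered, removed = filter_otu_table(
        table, min_identity=params.assign_min_identity,
        min_read_frac=params.min_read_frac, frac_scope=params.frac_scope,
    )
    ledger_rows += [
        {"stage": "otus_after_filter", "sample_id": "all",
         "count": len(filtered.counts)},
        {"stage": "reads_removed_by_filter", "sample_id": "all", "count": removed},
    ]
    bin_table = merge_otus_to_bins(filtered)
    ledger_rows.append(
        {"stage": "bins", "sample_id": "all", "count": len(bin_table.counts)}
    )
    return PipelineResult(
        otu_table=table,
        bin_table=bin_table,
        presence=presence_absence(bin_table),
        ledger=pd.DataFrame(ledger_rows, columns=["stage", "sample_id", "count"]),
        flagged_chimeras=flagged,
    )
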
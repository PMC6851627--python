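"""Readers and writers for the external formats the pipeline touches.

All other modules consume and produce the types defined here.  The FASTA
header dialect couples a sequence to BOLD-workbench-style metadata::

    >record_id|order|family|genus|species|cluster_id

Empty segments are allowed (an unnamed "dark" specimen simply leaves the
species segment blank).  A bare ``>record_id`` header is also accepted.
FASTQ quality strings are always Phred+33; other offsets are rejected, not
auto-detected.  All tabular output is TSV with a fixed, named schema.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "SequenceRecord",
    "PairedRead",
    "SampleManifest",
    "ParseError",
    "TAXONOMY_RANKS",
    "IUPAC_ALPHABET",
    "TABLE_SCHEMAS",
    "read_fasta",
    "write_fasta",
    "read_fastq_pairs",
    "write_fastq",
    "read_manifest",
    "write_manifest",
    "read_table",
    "write_table",
]

TAXONOMY_RANKS = ("order", "family", "genus", "species")

#: IUPAC nucleotide codes plus gap, the only characters a sequence may contain.
IUPAC_ALPHABET = frozenset("ACGTRYSWKMBDHVN-")

PHRED_OFFSET = 33


class ParseError(ValueError):
    """Malformed input file (bad header, mate mismatch, unknown schema...)."""


@dataclass
class SequenceRecord:
    """One COI sequence with its specimen id, taxonomy and cluster id.

    ``taxonomy`` maps rank -> name for the ranks in :data:`TAXONOMY_RANKS`;
    a missing ``species`` entry marks an unnamed ("dark") specimen.
    ``cluster_id`` is a BIN-style identifier ("BOLD:XXXXXXX") or an internal
    cluster label, or ``None`` when the record has not been clustered.
    """

    record_id: str
    sequence: str
    taxonomy: dict = field(default_factory=dict)
    cluster_id: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        if not self.sequence:
            raise ValueError(f"{self.record_id}: sequence must be non-empty")
        bad = set(self.sequence) - IUPAC_ALPHABET
        if bad:
            raise ValueError(
                f"{self.record_id}: non-IUPAC characters in sequence: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def species(self) -> str | None:
        return self.taxonomy.get("species") or None

    @property
    def family(self) -> str | None:
        return self.taxonomy.get("family") or None


@dataclass
class PairedRead:
    """A forward/reverse read pair from one amplicon, Phred scores decoded."""

    read_id: str
    forward_seq: str
    reverse_seq: str
    forward_qual: list
    reverse_qual: list
    sample_id: str

    def __post_init__(self) -> None:
        if len(self.forward_seq) != len(self.forward_qual):
            raise ParseError(f"{self.read_id}: forward seq/qual length mismatch")
        if len(self.reverse_seq) != len(self.reverse_qual):
            raise ParseError(f"{self.read_id}: reverse seq/qual length mismatch")


@dataclass
class SampleManifest:
    """One bulk sample: site, collection window (ISO dates) and mate files."""

    sample_id: str
    site: str
    date_start: str
    date_end: str
    forward_path: str
    reverse_path: str


# ---------------------------------------------------------------------------
# FASTA

def _parse_header(title: str, entry_no: int) -> tuple[str, dict, str | None]:
    parts = title.strip().split("|")
    if len(parts) == 1:
        rid = parts[0].strip()
        if not rid:
            raise ParseError(f"FASTA entry {entry_no}: empty header")
        return rid, {}, None
    if len(parts) != 6:
        raise ParseError(
            f"FASTA entry {entry_no}: header must have 1 or 6 '|'-delimited "
            f"fields (id|order|family|genus|species|cluster_id), got "
            f"{len(parts)}: {title!r}"
        )
    rid = parts[0].strip()
    if not rid:
        raise ParseError(f"FASTA entry {entry_no}: empty record id in {title!r}")
    taxonomy = {
        rank: value.strip()
        for rank, value in zip(TAXONOMY_RANKS, parts[1:5])
        if value.strip()
    }
    cluster = parts[5].strip() or None
    return rid, taxonomy, cluster


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file in the package header dialect.

    Order is preserved; sequences are uppercased.  An empty file yields an
    empty list.  Duplicate record ids raise :class:`ParseError`.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for entry_no, (title, seq) in enumerate(SimpleFastaParser(handle), 1):
            rid, taxonomy, cluster = _parse_header(title, entry_no)
            if rid in seen:
                raise ParseError(f"FASTA entry {entry_no}: duplicate record id {rid!r}")
            seen.add(rid)
            records.append(
                SequenceRecord(rid, seq, taxonomy=taxonomy, cluster_id=cluster)
            )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as handle:
        for rec in records:
            tax = [rec.taxonomy.get(rank, "") for rank in TAXONOMY_RANKS]
            header = "|".join([rec.record_id, *tax, rec.cluster_id or ""])
            handle.write(f">{header}\n{rec.sequence}\n")


# ---------------------------------------------------------------------------
# FASTQ

_MATE_SUFFIXES = ("/1", "/2")


def _strip_mate_suffix(read_id: str) -> str:
    rid = read_id.split()[0]
    for suffix in _MATE_SUFFIXES:
        if rid.endswith(suffix):
            return rid[: -len(suffix)]
    return rid


def _decode_qual(qual: str, read_id: str) -> list:
    scores = [ord(c) - PHRED_OFFSET for c in qual]
    if any(q < 0 for q in scores):
        raise ParseError(f"{read_id}: quality below Phred+33 offset")
    return scores


def read_fastq_pairs(
    path_fwd: str | Path, path_rev: str | Path, sample_id: str
) -> Iterator[PairedRead]:
    """Stream mate pairs from two Phred+33 FASTQ files in file order.

    Mate ids must pair up after stripping ``/1``/``/2`` suffixes; a record
    count or id mismatch raises :class:`ParseError` naming the pair index.
    """
    with open(path_fwd) as fh, open(path_rev) as rh:
        fwd_iter = FastqGeneralIterator(fh)
        rev_iter = FastqGeneralIterator(rh)
        index = 0
        while True:
            fwd = next(fwd_iter, None)
            rev = next(rev_iter, None)
            if fwd is None and rev is None:
                return
            if fwd is None or rev is None:
                raise ParseError(
                    f"{sample_id}: mate files differ in record count at pair {index}"
                )
            (fid, fseq, fqual), (rid, rseq, rqual) = fwd, rev
            fid, rid = _strip_mate_suffix(fid), _strip_mate_suffix(rid)
            if fid != rid:
                raise ParseError(
                    f"{sample_id}: mate ids disagree at pair {index}: {fid!r} vs {rid!r}"
                )
            yield PairedRead(
                read_id=fid,
                forward_seq=fseq.upper(),
                reverse_seq=rseq.upper(),
                forward_qual=_decode_qual(fqual, fid),
                reverse_qual=_decode_qual(rqual, rid),
                sample_id=sample_id,
            )
            index += 1


def write_fastq(
    reads: Iterable[tuple], path: str | Path
) -> None:
    """Write ``(read_id, sequence, qualities)`` triples as Phred+33 FASTQ."""
    with open(path, "w") as handle:
        for read_id, seq, quals in reads:
            qual_str = "".join(chr(q + PHRED_OFFSET) for q in quals)
            handle.write(f"@{read_id}\n{seq}\n+\n{qual_str}\n")


# ---------------------------------------------------------------------------
# Tables

#: Fixed leading columns per named schema.  Schemas flagged wide accept
#: additional per-sample count columns after the fixed block.
TABLE_SCHEMAS: dict = {
    "audit": [
        "species", "family", "n_specimens", "mean_isp", "max_isp",
        "nn_dist", "nn_species", "n_clusters", "status", "band",
    ],
    "cluster_assignment": ["record_id", "cluster_id", "method", "threshold"],
    "otu_table": [
        "otu_id", "bin_id", "identity", "family", "genus", "species", "centroid",
    ],
    "presence_absence": ["bin_id"],
    "family_summary": [
        "family", "infraorder", "species_reported", "n_clusters",
        "ratio_barcoded", "size_lo", "size_hi", "size_mid",
        "taxa_with_barcode", "unnamed_with_barcode", "pct_dark",
    ],
    "ledger": ["stage", "sample_id", "count"],
    "manifest": [
        "sample_id", "site", "date_start", "date_end",
        "forward_path", "reverse_path",
    ],
}

_WIDE_SCHEMAS = {"otu_table", "presence_absence"}


def write_table(rows, path: str | Path, schema_name: str) -> None:
    """Write rows (list of dicts or DataFrame) as TSV under a named schema.

    Column order is deterministic: the schema's fixed columns first, then any
    extra (per-sample) columns in sorted order for wide schemas.
    """
    if schema_name not in TABLE_SCHEMAS:
        raise ParseError(f"unknown table schema {schema_name!r}")
    fixed = TABLE_SCHEMAS[schema_name]
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame(list(rows), columns=None)
    if df.empty:
        df = pd.DataFrame(columns=fixed)
    missing = [c for c in fixed if c not in df.columns]
    if missing:
        raise ParseError(f"schema {schema_name!r}: missing columns {missing}")
    extra = sorted(c for c in df.columns if c not in fixed)
    if extra and schema_name not in _WIDE_SCHEMAS:
        raise ParseError(f"schema {schema_name!r}: unexpected columns {extra}")
    df = df[fixed + extra]
    df.to_csv(path, sep="\t", index=False, na_rep="NA", quoting=csv.QUOTE_NONE)


def read_table(path: str | Path, schema_name: str) -> pd.DataFrame:
    if schema_name not in TABLE_SCHEMAS:
        raise ParseError(f"unknown table schema {schema_name!r}")
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    missing = [c for c in TABLE_SCHEMAS[schema_name] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: schema {schema_name!r} missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# Sample manifests

def read_manifest(path: str | Path) -> list[SampleManifest]:
    df = read_table(path, "manifest")
    samples = [SampleManifest(**row) for row in df.astype(str).to_dict("records")]
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        raise ParseError(f"{path}: duplicate sample ids in manifest")
    return samples


def write_manifest(samples: Sequence[SampleManifest], path: str | Path) -> None:
    rows = [vars(s) for s in samples]
    write_table(pd.DataFrame(rows, columns=TABLE_SCHEMAS["manifest"]), path, "manifest")
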
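"""Pipeline stages: merging, trimming, EE filtering, dereplication,
chimera removal, assignment, table filtering and read accounting."""

import numpy as np
import pytest

from coiaudit.metabarcoding import (
    MergedRead,
    OTUTable,
    UniqueSeq,
    assign_taxonomy,
    dereplicate,
    expected_errors,
    filter_otu_table,
    merge_otus_to_bins,
    merge_pairs,
    merge_sample_dereps,
    presence_absence,
    quality_filter,
    remove_chimeras,
    reverse_complement,
    trim_primers,
)
from coiaudit.seqio import PairedRead, SequenceRecord

import pandas as pd

rng = np.random.default_rng(42)
TEMPLATE_313 = "".join("ACGT"[i] for i in rng.integers(0, 4, size=313))


def _pair_from_template(template, read_len, read_id="r1", q=38):
    fwd = template[:read_len]
    rev = reverse_complement(template)[:read_len]
    return PairedRead(
        read_id=read_id, forward_seq=fwd, reverse_seq=rev,
        forward_qual=[q] * len(fwd), reverse_qual=[q] * len(rev),
        sample_id="S1",
    )


def test_merge_pairs_overlap_arithmetic():
    pair = _pair_from_template(TEMPLATE_313, 200)  # overlap 200+200-313 = 87
    merged = merge_pairs(pair)
    assert merged is not None
    assert len(merged.sequence) == 313
    assert merged.sequence == TEMPLATE_313


def test_merge_pairs_rejects_short_overlap():
    template = TEMPLATE_313 + TEMPLATE_313[:48]  # 361 bp, overlap 39
    assert merge_pairs(_pair_from_template(template, 200)) is None
    template = TEMPLATE_313 + TEMPLATE_313[:47]  # 360 bp, overlap 40
    assert merge_pairs(_pair_from_template(template, 200)) is not None


def test_merge_pairs_identical_full_overlap_and_quality_consensus():
    pair = _pair_from_template(TEMPLATE_313[:100], 100)
    merged = merge_pairs(pair)
    assert merged.sequence == pair.forward_seq

    # disagreeing base: the higher-Phred mate wins, merged Phred is the max
    fwd = TEMPLATE_313[:100]
    rev = reverse_complement(fwd)
    swapped = {"A": "C", "C": "G", "G": "T", "T": "A"}[fwd[50]]
    fwd_bad = fwd[:50] + swapped + fwd[51:]
    pair = PairedRead(
        read_id="q", forward_seq=fwd_bad, reverse_seq=rev,
        forward_qual=[20] * 100, reverse_qual=[38] * 100, sample_id="S1",
    )
    merged = merge_pairs(pair)
    assert merged.sequence == fwd  # reverse mate's base won at position 50
    assert merged.quality[50] == 38


FWD_PRIMER = "GGWACWGGWTGAACWGTWTAYCCYCC"
REV_PRIMER = "TANACYTCNGGRTGNCCRAARAAYCA"


def _amplicon_read(insert, fwd=None, rev=None):
    fwd = fwd if fwd is not None else FWD_PRIMER.replace("W", "A") \
        .replace("Y", "C").replace("N", "G").replace("R", "A")
    rev = rev if rev is not None else REV_PRIMER.replace("W", "A") \
        .replace("Y", "C").replace("N", "G").replace("R", "A")
    seq = fwd + insert + reverse_complement(rev)
    return MergedRead(read_id="m1", sequence=seq, quality=[38] * len(seq),
                      sample_id="S1")


def test_trim_primers_exact_and_degenerate():
    read = _amplicon_read(TEMPLATE_313)
    trimmed = trim_primers(read, FWD_PRIMER, REV_PRIMER)
    assert trimmed is not None
    assert trimmed.sequence == TEMPLATE_313
    assert len(trimmed.quality) == 313


def test_trim_primers_tolerates_one_mismatch_but_not_absence():
    fwd_exact = FWD_PRIMER.replace("W", "A").replace("Y", "C").replace("N", "G")
    mutated = "T" + fwd_exact[1:]  # 25/26 = 96% >= 90%
    read = _amplicon_read(TEMPLATE_313, fwd=mutated)
    assert trim_primers(read, FWD_PRIMER, REV_PRIMER) is not None

    headless = MergedRead(read_id="m2", sequence=TEMPLATE_313,
                          quality=[38] * 313, sample_id="S1")
    assert trim_primers(headless, FWD_PRIMER, REV_PRIMER) is None


def test_expected_errors():
    assert expected_errors([20] * 100) == pytest.approx(1.0)
    assert expected_errors([40] * 10) == pytest.approx(0.001)
    assert expected_errors([]) == 0.0
    kept, discarded = quality_filter([
        MergedRead("a", "A" * 100, [20] * 100, "S1"),   # EE = 1.0, kept
        MergedRead("b", "A" * 101, [20] * 101, "S1"),   # EE > 1.0, discarded
    ])
    assert [r.read_id for r in kept] == ["a"]
    assert [r.read_id for r in discarded] == ["b"]


def _reads(spec):
    """spec: list of (sequence, sample, count) -> MergedRead list."""
    reads = []
    for i, (seq, sample, count) in enumerate(spec):
        for j in range(count):
            reads.append(MergedRead(f"r{i}_{j}", seq, [38] * len(seq), sample))
    return reads


def test_dereplicate_identity_and_sorting():
    reads = _reads([(TEMPLATE_313, "S1", 100)])
    uniques = dereplicate(reads)
    assert len(uniques) == 1
    assert uniques[0].abundance == 100
    assert uniques[0].samples == {"S1": 100}

    other = TEMPLATE_313[:-1] + {"A": "C"}.get(TEMPLATE_313[-1], "A")
    uniques = dereplicate(_reads([(TEMPLATE_313, "S1", 2), (other, "S1", 5)]))
    assert [u.abundance for u in uniques] == [5, 2]  # decreasing abundance


def test_dereplicate_sample_scope_equals_global():
    spec = [
        (TEMPLATE_313, "S1", 4), (TEMPLATE_313, "S2", 3),
        (TEMPLATE_313[::-1], "S1", 2),
    ]
    reads = _reads(spec)
    direct = dereplicate(reads, scope="global")
    via_samples = merge_sample_dereps(dereplicate(reads, scope="sample"))
    assert direct == via_samples
    with pytest.raises(ValueError):
        dereplicate(reads, scope="plate")


def _mutate_at(seq, positions):
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for pos in positions:
        out[pos] = swap[out[pos]]
    return "".join(out)


def test_remove_chimeras_flags_constructed_chimera():
    parent_a = TEMPLATE_313
    parent_b = _mutate_at(TEMPLATE_313, range(0, 313, 12))  # ~8% divergent
    chimera = parent_a[:150] + parent_b[150:]
    uniques = [
        UniqueSeq(parent_a, 50, {"S1": 50}),
        UniqueSeq(parent_b, 40, {"S1": 40}),
        UniqueSeq(chimera, 3, {"S1": 3}),
    ]
    kept, flagged = remove_chimeras(uniques)
    assert [u.sequence for u in flagged] == [chimera]
    assert len(kept) == 2


def test_remove_chimeras_keeps_variants_and_top_unique():
    parent_a = TEMPLATE_313
    variant = _mutate_at(parent_a, [7])  # 99.7% to parent: point-error variant
    parent_b = _mutate_at(TEMPLATE_313, range(0, 313, 12))
    uniques = [
        UniqueSeq(parent_a, 50, {"S1": 50}),
        UniqueSeq(parent_b, 40, {"S1": 40}),
        UniqueSeq(variant, 1, {"S1": 1}),
    ]
    kept, flagged = remove_chimeras(uniques)
    assert flagged == []
    # the most abundant unique has no eligible parents, never flagged
    kept, flagged = remove_chimeras([UniqueSeq(parent_a, 5, {"S1": 5})])
    assert flagged == [] and len(kept) == 1


def _refs():
    return [
        SequenceRecord(
            record_id="REF1", sequence=TEMPLATE_313,
            taxonomy={"family": "Phoridae", "genus": "Megaselia",
                      "species": "Megaselia rufa"},
            cluster_id="BOLD:ACD9573",
        ),
        SequenceRecord(
            record_id="REF2",
            sequence=_mutate_at(TEMPLATE_313, range(0, 313, 12)),
            taxonomy={"family": "Phoridae", "genus": "Megaselia",
                      "species": "Megaselia lutea"},
            cluster_id="BOLD:AAG3351",
        ),
    ]


def test_assign_taxonomy_best_hit_and_percent():
    meta = assign_taxonomy({"OTU000001": TEMPLATE_313}, _refs())
    row = meta.loc["OTU000001"]
    assert row["identity"] == 100.00
    assert row["species"] == "Megaselia rufa"
    assert row["bin_id"] == "BOLD:ACD9573"

    one_off = _mutate_at(TEMPLATE_313, [100])
    meta = assign_taxonomy({"OTU000001": one_off}, _refs())
    assert meta.loc["OTU000001", "identity"] == round(100 * 312 / 313, 2)


def test_assign_taxonomy_tie_breaks_lexicographically():
    refs = _refs()
    twin = SequenceRecord(
        record_id="AREF0", sequence=TEMPLATE_313,
        taxonomy={"family": "Phoridae", "species": "Megaselia alterna"},
        cluster_id="BOLD:XXXX",
    )
    meta = assign_taxonomy({"O1": TEMPLATE_313}, refs + [twin])
    assert meta.loc["O1", "hit_id"] == "AREF0"
    with pytest.raises(ValueError):
        assign_taxonomy({"O1": TEMPLATE_313}, [])


def _table():
    counts = pd.DataFrame(
        {"S1": [40000, 9996, 4], "S2": [0, 10, 0]},
        index=["OTU000001", "OTU000002", "OTU000003"],
    )
    meta = pd.DataFrame({
        "centroid": ["AA", "CC", "GG"],
        "identity": [99.5, 98.0, 96.9],
        "family": ["F1", "F1", "F2"],
        "genus": ["G1", "G2", "G3"],
        "species": ["S a", "S b", "S c"],
        "bin_id": ["B1", "B1", "B2"],
    }, index=counts.index)
    return OTUTable(counts=counts, meta=meta)


def test_filter_otu_table_identity_and_per_sample_fraction():
    table = _table()
    # S1 pre-filter total = 50,000 -> per-sample threshold 5 reads
    filtered, removed = filter_otu_table(table)
    assert list(filtered.counts.index) == ["OTU000001", "OTU000002"]
    assert filtered.counts.loc["OTU000002", "S2"] == 10
    assert removed == 4  # OTU000003: identity 96.9 dropped its 4 reads

    zeroed = _table()
    zeroed.meta.loc["OTU000003", "identity"] = 99.0
    filtered, removed = filter_otu_table(zeroed)
    assert "OTU000003" not in filtered.counts.index  # 4 < 5: zeroed then dropped
    assert removed == 4


def test_filter_otu_table_global_scope_and_empty():
    table = _table()
    filtered, _ = filter_otu_table(table, frac_scope="global")
    # global total 50,010 -> threshold ~5.0 reads everywhere
    assert filtered.counts.loc["OTU000002", "S2"] == 10
    empty = OTUTable(counts=pd.DataFrame(), meta=pd.DataFrame())
    out, removed = filter_otu_table(empty)
    assert out.counts.empty and removed == 0


def test_merge_otus_to_bins_sums_and_conserves():
    table = _table()
    merged = merge_otus_to_bins(table)
    assert merged.counts.loc["B1", "S1"] == 40000 + 9996
    assert merged.meta.loc["B1", "identity"] == 99.5  # max identity
    assert merged.meta.loc["B1", "species"] == "S a"  # highest-identity row
    assert merged.counts.to_numpy().sum() == table.counts.to_numpy().sum()

    distinct = _table()
    distinct.meta["bin_id"] = ["B1", "B2", "B3"]
    merged = merge_otus_to_bins(distinct)
    assert len(merged.counts) == 3


def test_presence_absence():
    table = _table()
    pa = presence_absence(table)
    assert pa.loc["OTU000001", "S1"] == 1
    assert pa.loc["OTU000001", "S2"] == 0
    assert (pa.sum(axis=1) == (table.counts > 0).sum(axis=1)).all()


# ---------------------------------------------------------------------------
# End-to-end accounting on the shared synthetic run

def test_read_ledger_sums_exactly(meta_run):
    ledger = meta_run["result"].ledger
    per_stage = ledger.groupby("stage")["count"].sum()
    assert per_stage["pairs_in"] == \
        per_stage["merged"] + per_stage["merge_rejected"]
    assert per_stage["merged"] == \
        per_stage["trimmed"] + per_stage["untrimmed_discarded"]
    assert per_stage["trimmed"] == \
        per_stage["quality_kept"] + per_stage["quality_discarded"]
    assert per_stage["uniques"] == \
        per_stage["uniques_kept"] + per_stage["chimeras_flagged"]
    n_samples = meta_run["config"].n_samples
    assert per_stage["pairs_in"] == \
        n_samples * meta_run["config"].reads_per_sample
    # per-sample accounting too
    by_sample = ledger.pivot_table(index="sample_id", columns="stage",
                                   values="count", aggfunc="sum")
    samples = by_sample.drop(index="all", errors="ignore")
    assert (samples["pairs_in"] ==
            samples["merged"] + samples["merge_rejected"]).all()


def test_pipeline_is_deterministic(meta_run):
    from coiaudit.metabarcoding import run_pipeline

    result2 = run_pipeline(meta_run["manifest"], meta_run["records"])
    first = meta_run["result"]
    pd.testing.assert_frame_equal(first.bin_table.counts,
                                  result2.bin_table.counts)
    pd.testing.assert_frame_equal(first.ledger, result2.ledger)
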
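"""Synthetic COI reference libraries and Malaise-trap metabarcoding runs.

The generator emulates the statistical structure the audit assumes:

* families of species whose COI sequences diverge ~8% (K2P) between
  species and ~0.5% within species, on a star topology per family;
* a fraction of species carrying a second deep lineage at ~6% (the
  "split" / cryptic-diversity-candidate device);
* pairs of species sharing an ancestral haplotype (the "merge" /
  cluster-sharing device);
* unnamed ("dark") species at a family-specific rate that is higher in
  small-bodied families;
* bulk samples with log-normal species abundances, per-base sequencing
  errors, Phred scores and two-parent single-crossover chimeras.

Substitutions follow a per-site categorical process in which a mutation is
a transition with probability kappa/(kappa+2) — the simplest process whose
K2P estimate is consistent with the configured divergence.  All output is
bit-reproducible for a fixed seed; per-sample streams are derived by
stable hashing so adding a sample does not perturb the others.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqio import (
    SampleManifest,
    SequenceRecord,
    write_fasta,
    write_fastq,
    write_manifest,
)
from .metabarcoding import reverse_complement, IUPAC_SETS

__all__ = [
    "FamilySpec",
    "LibrarySimConfig",
    "MetaSimConfig",
    "GroundTruth",
    "simulate_library",
    "simulate_metabarcoding_run",
    "DEFAULT_FAMILIES",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
# index of the transition partner for A, C, G, T
_TRANSITION = np.array([2, 3, 0, 1])
# the two transversion partners for each base
_TRANSVERSIONS = np.array([[1, 3], [0, 2], [1, 3], [0, 2]])


@dataclass(frozen=True)
class FamilySpec:
    name: str
    genus: str
    n_species: int
    size_range: tuple  # (lo, hi) mm
    dark_fraction: float


#: Default community: eight Diptera families spanning the observed range of
#: body sizes and dark-taxon rates (small-bodied families are darker).
DEFAULT_FAMILIES: tuple = (
    FamilySpec("Cecidomyiidae", "Cecidosoma", 20, (0.5, 3.0), 0.90),
    FamilySpec("Phoridae", "Phorisca", 16, (0.5, 6.0), 0.60),
    FamilySpec("Chironomidae", "Chironella", 14, (1.0, 10.0), 0.65),
    FamilySpec("Sciaridae", "Sciarella", 14, (1.0, 6.0), 0.30),
    FamilySpec("Syrphidae", "Syrphomima", 12, (3.5, 35.0), 0.08),
    FamilySpec("Tachinidae", "Tachinova", 12, (2.0, 20.0), 0.35),
    FamilySpec("Muscidae", "Muscopsis", 6, (2.0, 18.0), 0.40),
    FamilySpec("Tipulidae", "Tipulina", 6, (7.0, 35.0), 0.33),
)


@dataclass(frozen=True)
class LibrarySimConfig:
    """Reference-library simulation parameters.

    Divergence targets are expected pairwise K2P distances
    (substitutions/site).
    """

    seed: int = 0
    families: tuple = DEFAULT_FAMILIES
    haplotypes_per_species: tuple = (3, 5)  # inclusive range
    intraspecific_divergence: float = 0.005
    interspecific_divergence: float = 0.08
    interfamily_divergence: float = 0.05   # extra depth between family ancestors
    split_fraction: float = 0.05
    split_divergence: float = 0.06
    merge_fraction: float = 0.03
    kappa: float = 4.0
    length: int = 658

    def __post_init__(self) -> None:
        for name in ("split_fraction", "merge_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        for spec in self.families:
            if not 0.0 <= spec.dark_fraction <= 1.0:
                raise ValueError(f"{spec.name}: dark_fraction outside [0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if min(self.intraspecific_divergence, self.interspecific_divergence,
               self.split_divergence) < 0:
            raise ValueError("divergence targets must be nonnegative")


@dataclass(frozen=True)
class MetaSimConfig:
    """Metabarcoding-run simulation parameters.

    Defaults mirror a Malaise-trap season: 90 bulk samples and an average
    of ~6,000 read pairs each, a 313-bp minibarcode flanked by degenerate
    primers, log-normal within-sample species abundances and a small
    chimera rate.
    """

    seed: int = 0
    n_samples: int = 90
    reads_per_sample: int = 6000
    abundance_mu: float = 0.0
    abundance_sigma: float = 1.5
    occupancy: float = 0.35
    error_rate: float = 0.002
    chimera_rate: float = 0.02
    quality_mean: float = 35.0
    quality_sd: float = 3.0
    fwd_primer: str = "GGWACWGGWTGAACWGTWTAYCCYCC"
    rev_primer: str = "TANACYTCNGGRTGNCCRAARAAYCA"
    amplicon_start: int = 100
    amplicon_length: int = 313
    read_length: int = 250

    def __post_init__(self) -> None:
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError("occupancy must be in [0, 1]")
        if not 0.0 <= self.chimera_rate <= 1.0:
            raise ValueError("chimera_rate must be in [0, 1]")
        if self.reads_per_sample <= 0:
            raise ValueError("reads_per_sample must be positive")


@dataclass
class GroundTruth:
    """Everything the simulator knows that the pipeline must rediscover."""

    species_lineages: dict = field(default_factory=dict)  # species -> n lineages
    record_species: dict = field(default_factory=dict)    # record id -> species
    split_species: list = field(default_factory=list)
    merged_groups: list = field(default_factory=list)     # list of species tuples
    dark_species: list = field(default_factory=list)
    haplotypes: dict = field(default_factory=dict)        # species -> [sequence]
    sample_species_reads: dict = field(default_factory=dict)  # sample -> {sp: n}
    chimera_read_ids: list = field(default_factory=list)
    read_species: dict = field(default_factory=dict)      # read id -> species


def _mutate(seq: np.ndarray, t: float, kappa: float,
            rng: np.random.Generator) -> np.ndarray:
    """Apply expected ``t`` substitutions/site with ts:tv odds kappa:2."""
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < t)
    if hits.size == 0:
        return out
    is_transition = rng.random(hits.size) < kappa / (kappa + 2.0)
    trans_sites = hits[is_transition]
    out[trans_sites] = _TRANSITION[out[trans_sites]]
    tv_sites = hits[~is_transition]
    picks = rng.integers(0, 2, size=tv_sites.size)
    out[tv_sites] = _TRANSVERSIONS[out[tv_sites], picks]
    return out


def _to_str(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def simulate_library(config: LibrarySimConfig) -> tuple:
    """Simulate a reference library; returns (records, ground_truth)."""
    rng = np.random.default_rng(config.seed)
    root = rng.integers(0, 4, size=config.length)
    n_species_total = sum(f.n_species for f in config.families)

    # plan the species table first so split/merge selection is reproducible
    species_plan = []  # (family_spec, species_name or None, genus, key)
    truth = GroundTruth()
    for spec in config.families:
        for idx in range(spec.n_species):
            dark = rng.random() < spec.dark_fraction
            key = f"{spec.name}:{idx + 1:03d}"
            name = None if dark else f"{spec.genus} simulata{idx + 1:03d}"
            species_plan.append((spec, name, key))
            if dark:
                truth.dark_species.append(key)

    named_idx = [i for i, (_, name, _) in enumerate(species_plan) if name]
    n_split = round(config.split_fraction * n_species_total)
    n_merge_pairs = round(config.merge_fraction * n_species_total)
    if 2 * n_merge_pairs + n_split > len(named_idx):
        raise ValueError(
            "config asks for more split/merged named species than exist"
        )
    pool = set(named_idx)
    split_pick = rng.choice(sorted(pool), size=n_split, replace=False)
    split_set = {int(i) for i in split_pick}
    pool -= split_set
    # merged pairs are congeners: both species of a pair share a family
    by_family: dict = {}
    for i in named_idx:
        by_family.setdefault(species_plan[i][0].name, []).append(i)
    merge_pairs = []
    for _ in range(n_merge_pairs):
        eligible = sorted(
            fam for fam, idxs in by_family.items()
            if sum(1 for i in idxs if i in pool) >= 2
        )
        if not eligible:
            raise ValueError(
                "config asks for more merged pairs than any family can host"
            )
        fam = eligible[int(rng.integers(0, len(eligible)))]
        avail = sorted(i for i in by_family[fam] if i in pool)
        pick = rng.choice(len(avail), size=2, replace=False)
        a, b = avail[int(pick[0])], avail[int(pick[1])]
        pool -= {a, b}
        merge_pairs.append((a, b))
    merge_partner = {}
    for a, b in merge_pairs:
        first, second = (a, b) if a < b else (b, a)
        merge_partner[second] = first

    # family ancestors hang off one root so between-family distances stay
    # inside the K2P domain
    family_anc = {
        spec.name: _mutate(root, config.interfamily_divergence, config.kappa, rng)
        for spec in config.families
    }
    species_anc: dict = {}
    records: list = []
    rec_no = 0
    half_intra = config.intraspecific_divergence / 2.0
    half_inter = config.interspecific_divergence / 2.0
    half_split = config.split_divergence / 2.0
    lo, hi = config.haplotypes_per_species

    for idx, (spec, name, key) in enumerate(species_plan):
        if idx in merge_partner:
            anc = species_anc[merge_partner[idx]]
        else:
            anc = _mutate(family_anc[spec.name], half_inter, config.kappa, rng)
        species_anc[idx] = anc
        n_hap = int(rng.integers(lo, hi + 1))
        if idx in split_set:
            n_hap = max(n_hap, 2)
            lineage_anc = [
                _mutate(anc, half_split, config.kappa, rng),
                _mutate(anc, half_split, config.kappa, rng),
            ]
            lineage_of = [h % 2 for h in range(n_hap)]
            truth.split_species.append(name)
            truth.species_lineages[name or key] = 2
        else:
            lineage_anc = [anc]
            lineage_of = [0] * n_hap
            truth.species_lineages[name or key] = 1
        haplotypes = []
        for h in range(n_hap):
            hap = _mutate(lineage_anc[lineage_of[h]], half_intra, config.kappa, rng)
            haplotypes.append(hap)
            rec_no += 1
            taxonomy = {"order": "Diptera", "family": spec.name,
                        "genus": spec.genus}
            if name:
                taxonomy["species"] = name
            rid = f"SIM{rec_no:06d}"
            records.append(SequenceRecord(
                record_id=rid, sequence=_to_str(hap), taxonomy=taxonomy
            ))
            truth.record_species[rid] = name or key
        truth.haplotypes[name or key] = [_to_str(h) for h in haplotypes]

    truth.merged_groups = [
        tuple(species_plan[i][1] for i in pair) for pair in merge_pairs
    ]
    return records, truth


# ---------------------------------------------------------------------------
# Metabarcoding run

def _realize_primer(primer: str, rng: np.random.Generator) -> str:
    return "".join(
        code if code in "ACGT" else
        IUPAC_SETS[code][rng.integers(0, len(IUPAC_SETS[code]))]
        for code in primer
    )


def _add_errors(seq: np.ndarray, rate: float, rng: np.random.Generator
                ) -> np.ndarray:
    out = seq.copy()
    hits = np.flatnonzero(rng.random(seq.size) < rate)
    if hits.size:
        out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out


def _encode_acgt(seq: str) -> np.ndarray:
    lut = np.full(256, 0, dtype=np.uint8)
    for i, b in enumerate("ACGT"):
        lut[ord(b)] = i
    return lut[np.frombuffer(seq.encode(), dtype=np.uint8)]


def simulate_metabarcoding_run(
    library: Sequence[SequenceRecord],
    truth: GroundTruth,
    config: MetaSimConfig,
    outdir: str | Path,
) -> tuple:
    """Simulate paired-end FASTQ files for bulk samples.

    Writes ``<sample>_R1.fastq``/``_R2.fastq`` plus a manifest TSV into
    ``outdir`` and returns ``(manifest, truth)`` with the truth extended by
    read-level labels.  Each read is a primer-flanked
    ``config.amplicon_length`` window of a species haplotype with per-base
    substitution errors; chimeras recombine two distinct-species parent
    amplicons at a crossover uniform over the middle 60%.
    """
    if not library:
        raise ValueError("empty library")
    species = sorted(truth.haplotypes)
    hap_len = len(truth.haplotypes[species[0]][0])
    window_end = config.amplicon_start + config.amplicon_length
    if window_end > hap_len:
        raise ValueError(
            f"amplicon window [{config.amplicon_start}, {window_end}) exceeds "
            f"haplotype length {hap_len}"
        )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enc_haps = {
        sp: [_encode_acgt(h)[config.amplicon_start:window_end]
             for h in truth.haplotypes[sp]]
        for sp in species
    }
    manifest: list = []
    for s_idx in range(config.n_samples):
        sample_id = f"S{s_idx + 1:03d}"
        stream = np.random.default_rng(
            np.random.SeedSequence([config.seed, zlib.crc32(sample_id.encode())])
        )
        present = np.flatnonzero(stream.random(len(species)) < config.occupancy)
        while present.size == 0:
            present = np.flatnonzero(stream.random(len(species)) < config.occupancy)
        weights = stream.lognormal(
            config.abundance_mu, config.abundance_sigma, size=present.size
        )
        # a present species contributes at least one read; the remainder of
        # the sample's fixed read budget is multinomial over the log-normal
        # weights
        if config.reads_per_sample >= present.size:
            counts = 1 + stream.multinomial(
                config.reads_per_sample - present.size,
                weights / weights.sum(),
            )
        else:
            counts = stream.multinomial(config.reads_per_sample,
                                        weights / weights.sum())
        sample_species = [species[i] for i in present]
        truth.sample_species_reads[sample_id] = {
            sp: int(n) for sp, n in zip(sample_species, counts) if n > 0
        }
        # per-read species choices, shuffled so chimera draws interleave
        read_species = np.repeat(np.arange(present.size), counts)
        stream.shuffle(read_species)
        probs = counts / counts.sum()

        fwd_reads, rev_reads = [], []
        for r_idx, sp_local in enumerate(read_species):
            read_id = f"{sample_id}_R{r_idx + 1:06d}"
            sp = sample_species[sp_local]
            is_chimera = (
                stream.random() < config.chimera_rate and present.size >= 2
            )
            fwd_p = _realize_primer(config.fwd_primer, stream)
            rev_p = _realize_primer(config.rev_primer, stream)
            if is_chimera:
                # parents come from distinct, sequence-distinguishable
                # species: a template switch between near-identical templates
                # yields a read indistinguishable from a normal one, which no
                # two-parent filter could (or should) flag
                ins_a = ins_b = None
                for _ in range(20):
                    a_local = stream.choice(present.size, p=probs)
                    others = np.flatnonzero(np.arange(present.size) != a_local)
                    p_oth = probs[others] / probs[others].sum()
                    b_local = others[stream.choice(others.size, p=p_oth)]
                    hap_a = enc_haps[sample_species[a_local]]
                    hap_b = enc_haps[sample_species[b_local]]
                    cand_a = hap_a[stream.integers(0, len(hap_a))]
                    cand_b = hap_b[stream.integers(0, len(hap_b))]
                    if (cand_a != cand_b).mean() >= 0.02:
                        ins_a, ins_b = cand_a, cand_b
                        break
                if ins_a is None:
                    ins_a, ins_b = cand_a, cand_b
                L = config.amplicon_length
                cross = int(stream.integers(int(0.2 * L), int(0.8 * L)))
                insert = np.concatenate([ins_a[:cross], ins_b[cross:]])
                truth.chimera_read_ids.append(read_id)
                truth.read_species[read_id] = "chimera"
            else:
                haps = enc_haps[sp]
                insert = haps[stream.integers(0, len(haps))]
                truth.read_species[read_id] = sp
            insert = _add_errors(insert, config.error_rate, stream)
            amplicon = (
                fwd_p + _to_str(insert) + reverse_complement(rev_p)
            )
            fwd_seq = amplicon[: config.read_length]
            rev_seq = reverse_complement(amplicon)[: config.read_length]
            quals_f = np.clip(np.rint(stream.normal(
                config.quality_mean, config.quality_sd, len(fwd_seq))), 2, 41
            ).astype(int)
            quals_r = np.clip(np.rint(stream.normal(
                config.quality_mean, config.quality_sd, len(rev_seq))), 2, 41
            ).astype(int)
            fwd_reads.append((read_id, fwd_seq, list(quals_f)))
            rev_reads.append((read_id, rev_seq, list(quals_r)))

        fwd_path = outdir / f"{sample_id}_R1.fastq"
        rev_path = outdir / f"{sample_id}_R2.fastq"
        write_fastq(fwd_reads, fwd_path)
        write_fastq(rev_reads, rev_path)
        manifest.append(SampleManifest(
            sample_id=sample_id, site=f"TRAP{(s_idx % 9) + 1}",
            date_start="2016-05-01", date_end="2016-09-30",
            forward_path=str(fwd_path), reverse_path=str(rev_path),
        ))
    write_manifest(manifest, outdir / "manifest.tsv")
    return manifest, truth


def write_truth_tables(truth: GroundTruth, outdir: str | Path) -> None:
    """Dump ground-truth tables as TSV for inspection."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "truth_species.tsv", "w") as fh:
        fh.write("species\tn_lineages\tdark\tsplit\n")
        for sp in sorted(truth.species_lineages):
            fh.write(
                f"{sp}\t{truth.species_lineages[sp]}\t"
                f"{int(sp in truth.dark_species)}\t"
                f"{int(sp in truth.split_species)}\n"
            )
    with open(outdir / "truth_merges.tsv", "w") as fh:
        fh.write("species_a\tspecies_b\n")
        for group in truth.merged_groups:
            fh.write("\t".join(group) + "\n")
    if truth.read_species:
        with open(outdir / "truth_reads.tsv", "w") as fh:
            fh.write("read_id\tspecies\n")
            for rid in sorted(truth.read_species):
                fh.write(f"{rid}\t{truth.read_species[rid]}\n")
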
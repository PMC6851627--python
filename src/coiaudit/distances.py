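"""Kimura 2-parameter distances, pairwise matrices and nearest neighbours.

The K2P distance for a pair of aligned sequences is

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

where P and Q are the proportions of transition (A<->G, C<->T) and
transversion differences over the n sites at which both sequences carry an
unambiguous base (pairwise deletion of gaps, Ns and ambiguity codes).
Distances are substitutions/site; reporting layers convert to percent.

Matrices honour the reference-library length filter: records with fewer
than ``min_len`` unambiguous bases are excluded (the count is of A/C/G/T
positions, not raw length, so N-padded records cannot pass).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import log
from typing import Mapping, Sequence

import numpy as np

from .seqio import SequenceRecord

__all__ = [
    "PairwiseSiteCounts",
    "DistanceMatrix",
    "SaturatedPairError",
    "NoComparableSitesError",
    "site_counts",
    "k2p",
    "k2p_distance",
    "p_distance",
    "pairwise_matrix",
    "nearest_neighbor",
]

logger = logging.getLogger(__name__)


class SaturatedPairError(ValueError):
    """K2P is undefined: 1-2P-Q <= 0 or 1-2Q <= 0 (saturated pair)."""


class NoComparableSitesError(ValueError):
    """No site carries an unambiguous base in both sequences."""


@dataclass(frozen=True)
class PairwiseSiteCounts:
    """Comparable-site, transition and transversion counts for one pair."""

    n: int
    s: int
    v: int

    def __post_init__(self) -> None:
        if self.s + self.v > self.n:
            raise ValueError("s + v cannot exceed n")

    @property
    def P(self) -> float:
        return self.s / self.n

    @property
    def Q(self) -> float:
        return self.v / self.n


# uint8 code per base: A=0, C=1, G=2, T=3, anything else = invalid.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_INVALID = 255


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def site_counts(seq_a: str, seq_b: str) -> PairwiseSiteCounts:
    """Count comparable sites, transitions and transversions for a pair.

    Positions where either base is not a plain A/C/G/T (gap, N, ambiguity
    code) are excluded from all three counts (pairwise deletion).
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"sequences must be equal length ({len(seq_a)} vs {len(seq_b)})"
        )
    a, b = _encode(seq_a.upper()), _encode(seq_b.upper())
    valid = (a != _INVALID) & (b != _INVALID)
    n = int(valid.sum())
    if n == 0:
        raise NoComparableSitesError("no comparable sites")
    diff = valid & (a != b)
    # A(0)/G(2) are even codes, C(1)/T(3) odd: a same-parity difference is a
    # transition, a cross-parity difference a transversion.
    transition = diff & ((a & 1) == (b & 1))
    s = int(transition.sum())
    v = int(diff.sum()) - s
    return PairwiseSiteCounts(n=n, s=s, v=v)


def k2p(counts: PairwiseSiteCounts) -> float:
    """Kimura 2-parameter distance from site counts (substitutions/site)."""
    P, Q = counts.P, counts.Q
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturatedPairError(
            f"saturated pair: P={P:.4f}, Q={Q:.4f} outside the K2P domain"
        )
    return -0.5 * log(w1) - 0.25 * log(w2)


def k2p_distance(seq_a: str, seq_b: str) -> float:
    return k2p(site_counts(seq_a, seq_b))


def p_distance(counts: PairwiseSiteCounts) -> float:
    return (counts.s + counts.v) / counts.n


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over surviving record ids.

    ``excluded_ids`` lists records dropped by the length filter;
    ``dropped_pairs`` lists saturated pairs whose entries are NaN (only in
    non-strict mode; all other entries are finite).
    """

    ids: list
    d: np.ndarray
    excluded_ids: list = field(default_factory=list)
    dropped_pairs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        self._index = {rid: i for i, rid in enumerate(self.ids)}

    def index(self, record_id: str) -> int:
        return self._index[record_id]

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.d[self._index[id_a], self._index[id_b]])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.d, index=self.ids, columns=self.ids).to_csv(path, sep="\t")


def _unambiguous_length(seq: str) -> int:
    return int((_encode(seq.upper()) != _INVALID).sum())


def pairwise_matrix(
    records: Sequence[SequenceRecord],
    min_len: int = 500,
    strict: bool = False,
) -> DistanceMatrix:
    """All-pairs K2P matrix over position-comparable records.

    Records whose unambiguous-base count falls below ``min_len`` are listed
    in ``excluded_ids`` and omitted.  Saturated pairs raise in strict mode;
    otherwise the entry is NaN, recorded in ``dropped_pairs`` and a warning
    is logged.  Fewer than two surviving records is an error.
    """
    lengths = {len(r.sequence) for r in records}
    if len(lengths) > 1:
        raise ValueError(
            "records are not position-comparable (unequal lengths); align first"
        )
    kept = [r for r in records if _unambiguous_length(r.sequence) >= min_len]
    excluded = [r.record_id for r in records if r.record_id not in
                {k.record_id for k in kept}]
    if len(kept) < 2:
        raise ValueError(
            f"need at least 2 records with >= {min_len} unambiguous bases, "
            f"have {len(kept)}"
        )
    ids = [r.record_id for r in kept]
    enc = np.stack([_encode(r.sequence) for r in kept])
    valid = enc != _INVALID
    parity = enc & 1
    n_rec = len(kept)
    d = np.zeros((n_rec, n_rec), dtype=float)
    dropped: list = []
    for i in range(n_rec - 1):
        both = valid[i] & valid[i + 1:]
        n = both.sum(axis=1).astype(float)
        diff = both & (enc[i] != enc[i + 1:])
        ts = (diff & (parity[i] == parity[i + 1:])).sum(axis=1)
        tv = diff.sum(axis=1) - ts
        with np.errstate(divide="ignore", invalid="ignore"):
            P = ts / n
            Q = tv / n
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            row = np.where(
                (w1 > 0) & (w2 > 0),
                -0.5 * np.log(np.where(w1 > 0, w1, 1.0))
                - 0.25 * np.log(np.where(w2 > 0, w2, 1.0)),
                np.nan,
            )
        row = np.where(n > 0, row, np.nan)
        bad = np.flatnonzero(~np.isfinite(row))
        for j_off in bad:
            pair = (ids[i], ids[i + 1 + j_off])
            if strict:
                raise SaturatedPairError(
                    f"saturated or incomparable pair {pair[0]}/{pair[1]}"
                )
            dropped.append(pair)
            logger.warning("dropping saturated pair %s/%s", *pair)
        d[i, i + 1:] = row
        d[i + 1:, i] = row
    return DistanceMatrix(ids=ids, d=d, excluded_ids=excluded, dropped_pairs=dropped)


def nearest_neighbor(
    matrix: DistanceMatrix, species_of: Mapping[str, str]
) -> dict:
    """Per-species nearest-neighbour distance and species.

    For each species the minimum distance over all (member, non-member)
    pairs; ties broken by the lexicographically smallest neighbour species
    name.  NaN (dropped) pairs are ignored.
    """
    unknown = [rid for rid in matrix.ids if rid not in species_of]
    if unknown:
        raise KeyError(f"records missing from species map: {unknown[:5]}")
    labels = np.array([species_of[rid] for rid in matrix.ids])
    species = sorted(set(labels))
    if len(species) < 2:
        raise ValueError("nearest-neighbour analysis needs at least 2 species")
    result: dict = {}
    for sp in species:
        members = labels == sp
        sub = matrix.d[np.ix_(members, ~members)]
        other_labels = labels[~members]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            per_other = np.nanmin(sub, axis=0)
        finite = np.isfinite(per_other)
        if not finite.any():
            raise ValueError(f"species {sp!r} has no comparable cross-species pair")
        best = per_other[finite].min()
        candidates = other_labels[finite][per_other[finite] == best]
        result[sp] = (float(best), str(min(candidates)))
    return result
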
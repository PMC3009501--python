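"""Conjoint-triad encoding restricted to the predicted surface.

The 20 amino acids are clustered into seven groups by dipole and side-chain
volume:

    1 = {A, G, V}   2 = {I, L, F, P}   3 = {Y, M, T, S}   4 = {H, N, Q, W}
    5 = {R, K}      6 = {D, E}         7 = {C}

(The published group table lists the fourth group's last member with the
nonstandard abbreviation "Tpr"; it is read as tryptophan, W — the only
amino acid otherwise missing from the twenty.)

A conjoint triad is the group triple of three consecutive residues
(343 = 7^3 types). Only triads lying entirely inside the predicted
surface are counted; with the surface set to the whole protein the
encoding reduces exactly to the classic whole-sequence conjoint-triad
vector. A protein pair is the concatenation of its two 343-vectors.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io_formats import SequenceRecord
from .surface import SurfaceAnnotation

#: Table of amino-acid groups (1..7); 0 is the sentinel for unmappable residues.
GROUP_OF = {
    **{aa: 1 for aa in "AGV"},
    **{aa: 2 for aa in "ILFP"},
    **{aa: 3 for aa in "YMTS"},
    **{aa: 4 for aa in "HNQW"},
    **{aa: 5 for aa in "RK"},
    **{aa: 6 for aa in "DE"},
    "C": 7,
}

N_GROUPS = 7
N_TRIAD_TYPES = N_GROUPS**3
PAIR_DIM = 2 * N_TRIAD_TYPES

SENTINEL = 0


@dataclasses.dataclass
class GroupSequence:
    protein_id: str
    groups: np.ndarray  # int array, values in {0..7}; 0 = unmappable

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups, dtype=int)
        if np.any(self.groups < 0) or np.any(self.groups > N_GROUPS):
            raise ValueError("group codes must lie in {0..7}")

    def __len__(self) -> int:
        return len(self.groups)


@dataclasses.dataclass
class TriadVector:
    """343 per-protein triad counts, indexed (g1-1)*49 + (g2-1)*7 + (g3-1)."""

    protein_id: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (N_TRIAD_TYPES,):
            raise ValueError(f"triad vector must have length {N_TRIAD_TYPES}")
        if np.any(self.counts < 0):
            raise ValueError("triad counts must be non-negative")


def triad_index(g1: int, g2: int, g3: int) -> int:
    """Flat index of the triad type (g1, g2, g3), groups in 1..7."""
    return (g1 - 1) * 49 + (g2 - 1) * 7 + (g3 - 1)


def to_group_sequence(seq: SequenceRecord) -> GroupSequence:
    """Per-letter lookup in the 7-group table; unmappable letters -> sentinel."""
    codes = np.array([GROUP_OF.get(aa, SENTINEL) for aa in seq.residues], dtype=int)
    return GroupSequence(protein_id=seq.id, groups=codes)


def count_surface_triads(
    groups: GroupSequence, surface: SurfaceAnnotation
) -> TriadVector:
    """Count triads whose three positions all lie inside the surface.

    Equivalently, a triad is counted iff it fits inside one surface
    segment. Triads containing a sentinel group are skipped.
    """
    if len(groups) != surface.length:
        raise ValueError(
            f"group sequence length {len(groups)} != surface length "
            f"{surface.length}"
        )
    counts = np.zeros(N_TRIAD_TYPES, dtype=int)
    g = groups.groups
    on = surface.mask
    for i in range(len(g) - 2):
        if on[i] and on[i + 1] and on[i + 2]:
            g1, g2, g3 = g[i], g[i + 1], g[i + 2]
            if SENTINEL in (g1, g2, g3):
                continue
            counts[triad_index(g1, g2, g3)] += 1
    return TriadVector(protein_id=groups.protein_id, counts=counts)


def _minmax(v: np.ndarray) -> np.ndarray:
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.zeros_like(v, dtype=float)
    return (v - lo) / (hi - lo)


def encode_pair(
    va: TriadVector, vb: TriadVector, normalize: bool = False
) -> np.ndarray:
    """686-dimensional pair feature: [counts(a) || counts(b)].

    With ``normalize`` each protein's vector is min-max scaled on its own
    range before concatenation (the convention of the whole-sequence
    conjoint-triad predictor this method builds on); raw counts are the
    default.
    """
    a = va.counts.astype(float)
    b = vb.counts.astype(float)
    if normalize:
        a, b = _minmax(a), _minmax(b)
    return np.concatenate([a, b])
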
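"""Glue between the pipeline stages: profile -> RSA -> surface -> features.

These helpers keep the CLI and the evaluation protocols thin; every
scientific decision lives in the stage modules.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .asa_predictor import AsaModel, RsaTrack, predict_rsa
from .io_formats import PairLabel, PairRecord, SequenceRecord
from .profile_encoding import PssmProfile, Pssm2spProfile, build_pssm2sp, rescale_pssm
from .surface import SurfaceAnnotation, SurfaceParams, call_surface, whole_protein_surface
from .triads import TriadVector, count_surface_triads, encode_pair, to_group_sequence


def profile_to_pssm2sp(
    profile: PssmProfile, group_aggregate: str = "mean"
) -> Pssm2spProfile:
    """Rescale a raw PSSM and extend it to the 23-column PSSM-2SP form."""
    return build_pssm2sp(
        rescale_pssm(profile),
        profile.letters,
        protein_id=profile.protein_id,
        group_aggregate=group_aggregate,
    )


def predict_tracks(
    model: AsaModel, profiles: Sequence[PssmProfile]
) -> dict[str, RsaTrack]:
    """Cascade RSA predictions for a batch of proteins, keyed by ID."""
    return {
        p.protein_id: predict_rsa(model, profile_to_pssm2sp(p)) for p in profiles
    }


def call_surfaces(
    tracks: Mapping[str, RsaTrack], params: SurfaceParams
) -> dict[str, SurfaceAnnotation]:
    return {
        pid: call_surface(track.values, params, pid) for pid, track in tracks.items()
    }


def triad_vectors(
    records: Sequence[SequenceRecord],
    surfaces: Mapping[str, SurfaceAnnotation] | None,
) -> dict[str, TriadVector]:
    """Surface-restricted triad vectors; ``surfaces=None`` means the
    whole-sequence baseline (every residue treated as surface)."""
    out = {}
    for rec in records:
        surf = (
            surfaces[rec.id]
            if surfaces is not None
            else whole_protein_surface(rec.id, len(rec))
        )
        out[rec.id] = count_surface_triads(to_group_sequence(rec), surf)
    return out


def pair_features(
    pairs: Sequence[PairRecord],
    vectors: Mapping[str, TriadVector],
    normalize: bool = False,
) -> np.ndarray:
    """686-column feature matrix, one row per pair (id_a half first)."""
    rows = []
    for p in pairs:
        if p.id_a not in vectors or p.id_b not in vectors:
            missing = p.id_a if p.id_a not in vectors else p.id_b
            raise KeyError(f"pair references unknown protein {missing!r}")
        rows.append(encode_pair(vectors[p.id_a], vectors[p.id_b], normalize=normalize))
    return np.vstack(rows)


def pair_labels(pairs: Sequence[PairRecord]) -> np.ndarray:
    """0/1 label vector; unknown labels are rejected."""
    out = np.empty(len(pairs), dtype=int)
    for i, p in enumerate(pairs):
        if p.label is PairLabel.UNKNOWN:
            raise ValueError(f"pair ({p.id_a}, {p.id_b}) has no label")
        out[i] = p.label.value
    return out
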
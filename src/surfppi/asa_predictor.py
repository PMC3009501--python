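"""Two cascading regressions from sequence profiles to relative ASA.

Stage 1 regresses true RSA on windowed PSSM-2SP vectors (253-d at the
default window w1 = 11). Stage 2 then regresses true RSA on a window of
stage-1 *predictions* plus terminal flags and the chain length, exploiting
the spatial correlation of solvent exposure along the chain: buried and
exposed residues come in runs, so neighbouring first-pass predictions
carry information the profile window alone does not.

Epsilon-insensitive kernel regression (sklearn's SVR, RBF kernel) is the
default engine; any object with fit/predict can be plugged in via
``regressor_factory``.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Sequence

import numpy as np
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .profile_encoding import (
    CascadeConfig,
    Pssm2spProfile,
    encode_stage1_windows,
    encode_stage2_vectors,
)

#: Documented defaults of the regression engine.
DEFAULT_REGRESSOR_SETTINGS = {"kernel": "rbf", "C": 1.0, "epsilon": 0.1}


@dataclasses.dataclass
class RsaTrack:
    """Per-residue relative ASA values, clamped to [0, 1]."""

    protein_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("RSA track must be one-dimensional")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError(f"{self.protein_id}: RSA values outside [0, 1]")

    def __len__(self) -> int:
        return len(self.values)


@dataclasses.dataclass
class AsaModel:
    """Trained cascade: both stage regressors plus the window config."""

    stage1: object
    stage2: object
    config: CascadeConfig
    meta: dict

    def __post_init__(self) -> None:
        if self.stage1 is None or self.stage2 is None:
            raise ValueError("both cascade stages must be present")


def _default_factory(settings: dict) -> Callable[[], object]:
    # z-scoring ahead of the RBF kernel keeps the raw sequence-length
    # element of the stage-2 vectors from dominating kernel distances
    merged = {**DEFAULT_REGRESSOR_SETTINGS, **settings}
    return lambda: make_pipeline(StandardScaler(), SVR(**merged))


def train_cascade(
    training: Sequence[tuple[Pssm2spProfile, RsaTrack]],
    config: CascadeConfig | None = None,
    regressor_settings: dict | None = None,
    regressor_factory: Callable[[], object] | None = None,
    out_of_fold: bool = False,
    n_folds: int = 5,
) -> AsaModel:
    """Fit both cascade stages.

    Stage 2 is trained on stage-1 predictions for the training proteins
    themselves (in-sample by default; ``out_of_fold=True`` switches to
    protein-level cross-fitted stage-1 predictions for users worried about
    optimism leaking into stage 2).
    """
    if config is None:
        config = CascadeConfig()
    if regressor_factory is None:
        settings_used: object = {**DEFAULT_REGRESSOR_SETTINGS, **(regressor_settings or {})}
        regressor_factory = _default_factory(regressor_settings or {})
    elif regressor_settings:
        raise ValueError("pass either regressor_settings or regressor_factory")
    else:
        settings_used = "custom"
    if len(training) == 0:
        raise ValueError("no training proteins")
    for p2sp, track in training:
        if len(p2sp) != len(track):
            raise ValueError(
                f"{p2sp.protein_id}: profile length {len(p2sp)} != "
                f"RSA track length {len(track)}"
            )
    if len(training) == 1:
        warnings.warn(
            "training the cascade on a single protein; stage-2 inputs are "
            "in-sample stage-1 predictions",
            UserWarning,
            stacklevel=2,
        )

    X1_per_protein = [encode_stage1_windows(p, config.w1) for p, _ in training]
    y_per_protein = [t.values for _, t in training]
    X1 = np.vstack(X1_per_protein)
    y = np.concatenate(y_per_protein)

    stage1 = regressor_factory()
    stage1.fit(X1, y)

    n = len(training)
    if out_of_fold and n >= 2:
        k = min(n_folds, n)
        fold_of = np.arange(n) % k
        a1_per_protein: list[np.ndarray] = [None] * n  # type: ignore[list-item]
        for f in range(k):
            tr_idx = [i for i in range(n) if fold_of[i] != f]
            te_idx = [i for i in range(n) if fold_of[i] == f]
            reg = regressor_factory()
            reg.fit(
                np.vstack([X1_per_protein[i] for i in tr_idx]),
                np.concatenate([y_per_protein[i] for i in tr_idx]),
            )
            for i in te_idx:
                a1_per_protein[i] = np.clip(reg.predict(X1_per_protein[i]), 0.0, 1.0)
    else:
        a1_per_protein = [
            np.clip(stage1.predict(X1_per_protein[i]), 0.0, 1.0) for i in range(n)
        ]

    X2 = np.vstack(
        [
            encode_stage2_vectors(
                a1_per_protein[i],
                len(training[i][0]),
                config.w2,
                normalize_length=config.normalize_length,
                length_cap=config.length_cap,
            )
            for i in range(n)
        ]
    )
    stage2 = regressor_factory()
    stage2.fit(X2, y)

    return AsaModel(
        stage1=stage1,
        stage2=stage2,
        config=config,
        meta={
            "n_proteins": n,
            "n_residues": int(len(y)),
            "out_of_fold": bool(out_of_fold),
            "regressor_settings": settings_used,
        },
    )


def predict_stage1(model: AsaModel, p2sp: Pssm2spProfile) -> RsaTrack:
    """First-pass RSA predictions only (profile window -> RSA)."""
    X1 = encode_stage1_windows(p2sp, model.config.w1)
    return RsaTrack(
        protein_id=p2sp.protein_id,
        values=np.clip(model.stage1.predict(X1), 0.0, 1.0),
    )


def predict_rsa(model: AsaModel, p2sp: Pssm2spProfile) -> RsaTrack:
    """Full cascade prediction, clamped to [0, 1]; deterministic per model."""
    a1 = predict_stage1(model, p2sp).values
    X2 = encode_stage2_vectors(
        a1,
        len(p2sp),
        model.config.w2,
        normalize_length=model.config.normalize_length,
        length_cap=model.config.length_cap,
    )
    return RsaTrack(
        protein_id=p2sp.protein_id,
        values=np.clip(model.stage2.predict(X2), 0.0, 1.0),
    )
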
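"""PSSM-2SP profile construction and per-residue window encodings.

The solvent-accessibility cascade consumes two encodings built here:

* stage 1 sees, for each residue, a window of ``w1`` consecutive
  23-dimensional PSSM-2SP rows (20 logistic-rescaled substitution scores,
  a terminal flag, and two accumulated group values for the Charged_sel
  {K, D} and Tiny_sel {A, G} residue groups);
* stage 2 sees a window of ``w2`` (predicted RSA, terminal flag) pairs
  followed by the sequence length.

Positions outside the chain contribute a pseudo-terminal row whose
terminal flag is 1 and whose 22 other entries are 0.
"""

from __future__ import annotations

import dataclasses

import numpy as np

#: Fixed 20-column amino-acid order of the substitution-score block.
#: This is the order PSI-BLAST prints in its ASCII matrix output.
PSSM_COLUMNS = "ARNDCQEGHILKMFPSTWYV"

#: Column layout of a PSSM-2SP row.
N_AA = 20
TERMINAL_COL = 20
CHARGED_COL = 21
TINY_COL = 22
PSSM2SP_WIDTH = 23

_K_COL = PSSM_COLUMNS.index("K")
_D_COL = PSSM_COLUMNS.index("D")
_A_COL = PSSM_COLUMNS.index("A")
_G_COL = PSSM_COLUMNS.index("G")


@dataclasses.dataclass
class PssmProfile:
    """Raw per-residue substitution scores for one protein.

    ``raw`` has one row per residue and 20 columns in :data:`PSSM_COLUMNS`
    order; ``letters`` is the residue string the rows are aligned to.
    """

    protein_id: str
    raw: np.ndarray
    letters: str

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 2 or self.raw.shape[1] != N_AA:
            raise ValueError(
                f"PSSM must have {N_AA} columns, got shape {self.raw.shape}"
            )
        if self.raw.shape[0] != len(self.letters):
            raise ValueError(
                f"{self.protein_id}: {self.raw.shape[0]} PSSM rows for "
                f"{len(self.letters)} residues"
            )

    def __len__(self) -> int:
        return self.raw.shape[0]


@dataclasses.dataclass
class Pssm2spProfile:
    """Rescaled 23-column extension of a PSSM (rows in [0, 1])."""

    protein_id: str
    rescaled: np.ndarray

    def __post_init__(self) -> None:
        self.rescaled = np.asarray(self.rescaled, dtype=float)
        if self.rescaled.ndim != 2 or self.rescaled.shape[1] != PSSM2SP_WIDTH:
            raise ValueError(
                f"PSSM-2SP must have {PSSM2SP_WIDTH} columns, got shape "
                f"{self.rescaled.shape}"
            )
        if np.any(self.rescaled < 0) or np.any(self.rescaled > 1):
            raise ValueError("PSSM-2SP entries must lie in [0, 1]")

    def __len__(self) -> int:
        return self.rescaled.shape[0]


@dataclasses.dataclass
class CascadeConfig:
    """Window sizes of the two regression stages.

    ``w1`` (default 11) is the stage-1 profile window; ``w2`` (default 5)
    is the stage-2 accessibility window. Both must be odd. ``group_aggregate``
    selects how the two accumulated group columns combine their member
    columns ("mean" keeps the value in [0, 1]; "sum" is available for
    compatibility experiments). ``normalize_length`` optionally divides the
    stage-2 length element by ``length_cap`` for numeric conditioning.
    """

    w1: int = 11
    w2: int = 5
    group_aggregate: str = "mean"
    normalize_length: bool = False
    length_cap: float = 1000.0

    def __post_init__(self) -> None:
        for name in ("w1", "w2"):
            w = getattr(self, name)
            if w < 1 or w % 2 == 0:
                raise ValueError(f"{name} must be odd and >= 1, got {w}")
        if self.group_aggregate not in ("mean", "sum"):
            raise ValueError("group_aggregate must be 'mean' or 'sum'")

    @property
    def h1(self) -> int:
        return (self.w1 - 1) // 2

    @property
    def h2(self) -> int:
        return (self.w2 - 1) // 2


def rescale_pssm(profile: PssmProfile) -> np.ndarray:
    """Map raw log-odds scores into (0, 1) with the logistic x' = 1/(1+e^-x)."""
    if len(profile) == 0:
        raise ValueError("cannot rescale an empty profile")
    return 1.0 / (1.0 + np.exp(-profile.raw))


def build_pssm2sp(
    rescaled: np.ndarray,
    letters: str,
    protein_id: str = "",
    group_aggregate: str = "mean",
) -> Pssm2spProfile:
    """Extend a rescaled PSSM with a terminal flag and two group columns.

    The terminal flag is 0 for every real residue row (it is only set on
    the pseudo-terminal padding rows added at window-encoding time). The
    Charged_sel column accumulates the rescaled K and D columns and the
    Tiny_sel column the rescaled A and G columns of the same row.
    """
    rescaled = np.asarray(rescaled, dtype=float)
    if rescaled.ndim != 2 or rescaled.shape[1] != N_AA:
        raise ValueError(f"expected an (L, {N_AA}) matrix, got {rescaled.shape}")
    if rescaled.shape[0] != len(letters):
        raise ValueError(
            f"{rescaled.shape[0]} profile rows but {len(letters)} residues"
        )
    if np.any(rescaled < 0) or np.any(rescaled > 1):
        raise ValueError("rescaled PSSM entries must lie in [0, 1]")

    L = rescaled.shape[0]
    out = np.zeros((L, PSSM2SP_WIDTH), dtype=float)
    out[:, :N_AA] = rescaled
    charged = rescaled[:, [_K_COL, _D_COL]]
    tiny = rescaled[:, [_A_COL, _G_COL]]
    if group_aggregate == "mean":
        out[:, CHARGED_COL] = charged.mean(axis=1)
        out[:, TINY_COL] = tiny.mean(axis=1)
    elif group_aggregate == "sum":
        out[:, CHARGED_COL] = charged.sum(axis=1)
        out[:, TINY_COL] = tiny.sum(axis=1)
        # a summed value of two [0,1] columns can exceed 1; rescale into range
        out[:, CHARGED_COL] /= 2.0
        out[:, TINY_COL] /= 2.0
    else:
        raise ValueError("group_aggregate must be 'mean' or 'sum'")
    return Pssm2spProfile(protein_id=protein_id, rescaled=out)


def pseudo_terminal_row() -> np.ndarray:
    """The padding row: terminal flag 1, all 22 other entries 0."""
    row = np.zeros(PSSM2SP_WIDTH)
    row[TERMINAL_COL] = 1.0
    return row


def encode_stage1_windows(p2sp: Pssm2spProfile, w1: int) -> np.ndarray:
    """Per-residue stage-1 feature vectors of length ``23 * w1``.

    Vector ``i`` concatenates the 23-column rows at positions
    ``i-h .. i+h`` (h = (w1-1)/2); positions outside the chain contribute
    the pseudo-terminal row.
    """
    if w1 < 1 or w1 % 2 == 0:
        raise ValueError(f"w1 must be odd and >= 1, got {w1}")
    L = len(p2sp)
    h = (w1 - 1) // 2
    padded = np.vstack(
        [np.tile(pseudo_terminal_row(), (h, 1)), p2sp.rescaled,
         np.tile(pseudo_terminal_row(), (h, 1))]
    )
    windows = np.lib.stride_tricks.sliding_window_view(
        padded, (w1, PSSM2SP_WIDTH)
    )[:, 0]
    return windows.reshape(L, w1 * PSSM2SP_WIDTH).copy()


def encode_stage2_vectors(
    rsa_stage1: np.ndarray,
    L: int,
    w2: int,
    normalize_length: bool = False,
    length_cap: float = 1000.0,
) -> np.ndarray:
    """Per-residue stage-2 vectors of dimension ``2*w2 + 1``.

    For residue ``i`` the vector interleaves (a_j, t_j) over
    ``j = i-h .. i+h``, where a_j is the stage-1 RSA prediction (0 outside
    the chain) and t_j the terminal flag (1 outside the chain), followed by
    the sequence length.
    """
    if w2 < 1 or w2 % 2 == 0:
        raise ValueError(f"w2 must be odd and >= 1, got {w2}")
    rsa_stage1 = np.asarray(rsa_stage1, dtype=float)
    if rsa_stage1.shape != (L,):
        raise ValueError(
            f"stage-1 RSA has shape {rsa_stage1.shape}, expected ({L},)"
        )
    h = (w2 - 1) // 2
    a = np.concatenate([np.zeros(h), rsa_stage1, np.zeros(h)])
    t = np.concatenate([np.ones(h), np.zeros(L), np.ones(h)])
    a_win = np.lib.stride_tricks.sliding_window_view(a, w2)
    t_win = np.lib.stride_tricks.sliding_window_view(t, w2)
    out = np.empty((L, 2 * w2 + 1))
    out[:, 0 : 2 * w2 : 2] = a_win
    out[:, 1 : 2 * w2 : 2] = t_win
    out[:, -1] = L / length_cap if normalize_length else float(L)
    return out
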
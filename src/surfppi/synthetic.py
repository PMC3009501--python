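"""Desk-scale synthetic fixtures with the statistical structure every
pipeline stage assumes.

What is emulated, and why:

* **True RSA** follows a two-state hidden-run process (exposed runs near
  0.7, buried runs near 0.1, geometric run lengths, Gaussian jitter) —
  solvent exposure along real chains comes in runs, which is exactly the
  spatial correlation the second cascade stage exploits.
* **PSSMs** carry (a) an identity signal on the column of the true
  residue and (b) a weak per-position exposure signal: exposed positions
  shift the hydrophilic substitution columns up and the hydrophobic ones
  down, the way surface positions in real alignments tolerate hydrophilic
  substitutions. The per-position signal is deliberately weaker than the
  run structure, so the cascade's second stage has something to recover.
* **Sequences** have a low-complexity hydrophobic/small background (a
  configurable subset of the seven groups) against which charged,
  motif-borne triads stand out, the way interface patches stand out
  against core composition.
* **Interactions** are planted on TRUE surfaces through a recurring
  adhesive motif, mimicking interface patches that recur across binding
  partners. Each dataset draws one template motif over the charged /
  cysteine groups; "adhesive" proteins carry noisy copies of it inside
  exposed runs, while non-adhesive proteins may instead carry decoy
  copies buried deep inside buried runs. A pair is labeled interacting
  when its two TRUE surfaces share more than ``theta`` sticky triad
  types (the template's triads). Because the label rule lives on the
  true surface while the pipeline only sees predicted surfaces,
  ASA-prediction quality mediates PPI performance; and because decoy
  copies are buried, whole-sequence triad encodings cannot tell an
  adhesive protein from a decoy carrier while surface-restricted
  encodings can.

All randomness flows from ``SynthConfig.seed`` through three fixed
sub-streams (template, proteins, interactions).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .io_formats import (
    PairLabel,
    PairRecord,
    RsaTable,
    SequenceRecord,
    write_fasta,
    write_pairs,
    write_pssm,
    write_rsa_table,
)
from .profile_encoding import PSSM_COLUMNS, PssmProfile
from .surface import SurfaceAnnotation, SurfaceParams, call_surface
from .triads import GROUP_OF, count_surface_triads, to_group_sequence, triad_index

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

GROUP_LETTERS = {1: "AGV", 2: "ILFP", 3: "YMTS", 4: "HNQW", 5: "RK", 6: "DE", 7: "C"}

#: +1 for hydrophilic substitution columns, -1 for hydrophobic ones,
#: in PSSM column order. Exposed positions shift scores along +pattern.
EXPOSURE_PATTERN = np.array(
    [+1.0 if aa in set("RNDQEHKST") else -1.0 for aa in PSSM_COLUMNS]
)


@dataclasses.dataclass
class SynthConfig:
    """Generator settings; the defaults are the package's study conditions.

    ``rsa_mode`` selects the true-RSA process: "runs" is the two-state
    hidden-run process; "profile_linear" instead derives a noiseless RSA
    as a clipped linear functional of the (already generated) profile
    window, for regression-recovery experiments.
    """

    seed: int
    n_proteins: int = 40
    length_range: tuple[int, int] = (60, 100)
    # true-RSA process
    rsa_mode: str = "runs"
    exposed_level: float = 0.7
    buried_level: float = 0.1
    mean_run_length: float = 12.0
    rsa_noise_sd: float = 0.08
    linear_gain: float = 8.0
    linear_half_window: int = 2
    # PSSM process
    identity_signal: float = 4.0
    exposure_signal: float = 3.0
    pssm_noise_sd: float = 1.5
    # sequence background: residues drawn uniformly from these groups'
    # letters (hydrophobic/small by default, so the charged adhesive
    # motifs occupy a disjoint region of triad space)
    background_groups: tuple = (1, 2)
    # adhesive-motif interaction process (evaluated on TRUE surfaces)
    motif_length: int = 9
    motif_copies: int = 2
    motif_mutation_rate: float = 0.1
    p_adhesive: float = 0.6
    p_decoy: float = 0.85
    sticky_triads: tuple | None = None  # override for the label rule
    theta: int = 2
    label_noise: float = 0.0
    true_surface_t: float = 0.5
    true_surface_w: int = 9
    true_surface_o: int = 3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_proteins < 2:
            raise ValueError("need at least two proteins")
        lo, hi = self.length_range
        if lo < 10 or hi < lo:
            raise ValueError(f"bad length range {self.length_range}")
        if self.rsa_mode not in ("runs", "profile_linear"):
            raise ValueError("rsa_mode must be 'runs' or 'profile_linear'")
        for name in (
            "rsa_noise_sd",
            "label_noise",
            "true_surface_t",
            "p_adhesive",
            "p_decoy",
            "motif_mutation_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_run_length < 1.0:
            raise ValueError("mean_run_length must be >= 1")
        if self.motif_length < 3:
            raise ValueError("motif_length must be >= 3 (a triad)")
        if not set(self.background_groups) <= set(range(1, 8)):
            raise ValueError("background_groups must be amino-acid groups 1..7")


@dataclasses.dataclass
class SyntheticProtein:
    record: SequenceRecord
    profile: PssmProfile
    rsa: RsaTable  # true RSA
    is_adhesive: bool
    has_decoy: bool
    exposed_states: np.ndarray  # clean two-state exposure (bool per residue)


def _streams(cfg: SynthConfig) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(cfg.seed).spawn(3)  # template, proteins, pairs


def adhesive_template(cfg: SynthConfig) -> str:
    """The dataset's recurring interface motif (deterministic per seed).

    Drawn over the charged groups {R,K} / {D,E} and cysteine — rare
    enough in background sequence that its triads mark adhesive surfaces
    rather than bulk composition.
    """
    rng = np.random.default_rng(_streams(cfg)[0])
    groups = rng.choice([5, 6, 7], size=cfg.motif_length, p=[0.4, 0.4, 0.2])
    return "".join(
        GROUP_LETTERS[g][rng.integers(0, len(GROUP_LETTERS[g]))] for g in groups
    )


def template_triads(cfg: SynthConfig) -> frozenset[int]:
    """Sticky triad types of the label rule: the template's own triads."""
    if cfg.sticky_triads is not None:
        return frozenset(int(t) for t in cfg.sticky_triads)
    tpl = adhesive_template(cfg)
    return frozenset(
        triad_index(GROUP_OF[tpl[i]], GROUP_OF[tpl[i + 1]], GROUP_OF[tpl[i + 2]])
        for i in range(len(tpl) - 2)
    )


def _two_state_rsa(L: int, cfg: SynthConfig, rng: np.random.Generator):
    """Hidden exposed/buried runs + jitter. Returns (values, states)."""
    p_switch = 1.0 / cfg.mean_run_length
    states = np.empty(L, dtype=bool)
    states[0] = rng.random() < 0.5
    flips = rng.random(L - 1) < p_switch if L > 1 else np.empty(0)
    for i in range(1, L):
        states[i] = ~states[i - 1] if flips[i - 1] else states[i - 1]
    values = np.clip(
        np.where(states, cfg.exposed_level, cfg.buried_level)
        + rng.normal(0.0, cfg.rsa_noise_sd, L),
        0.0,
        1.0,
    )
    return values, states


def _plant_motif(
    residues: list[str],
    states: np.ndarray,
    rng: np.random.Generator,
    template: str,
    n_copies: int,
    mutation_rate: float,
    exposed: bool,
    margin: int = 0,
) -> int:
    """Overwrite up to ``n_copies`` non-overlapping stretches that lie
    entirely in the target state with noisy template copies. Returns the
    number of copies actually placed (short chains may lack room).

    ``margin`` additionally requires that many flanking positions to be
    in the target state too; buried (decoy) copies use it to stay clear
    of the surface windows that spill over run boundaries."""
    m = len(template)
    target = states if exposed else ~states
    L = len(residues)
    starts = [
        i
        for i in range(L - m + 1)
        if bool(target[max(0, i - margin) : min(L, i + m + margin)].all())
    ]
    rng.shuffle(starts)
    placed = 0
    used: set[int] = set()
    for start in starts:
        if placed >= n_copies:
            break
        if any(p in used for p in range(start, start + m)):
            continue
        for off, ch in enumerate(template):
            p = start + off
            residues[p] = (
                AA_LETTERS[rng.integers(0, 20)]
                if rng.random() < mutation_rate
                else ch
            )
            used.add(p)
        placed += 1
    return placed


def _linear_profile_rsa(raw: np.ndarray, cfg: SynthConfig) -> np.ndarray:
    """Noiseless RSA: clipped linear functional of the smoothed profile."""
    rescaled = 1.0 / (1.0 + np.exp(-raw))
    z = (rescaled - 0.5) @ EXPOSURE_PATTERN / len(EXPOSURE_PATTERN)
    k = 2 * cfg.linear_half_window + 1
    pad = np.pad(z, cfg.linear_half_window, mode="edge")
    smooth = np.convolve(pad, np.ones(k) / k, mode="valid")
    return np.clip(0.5 + cfg.linear_gain * smooth, 0.0, 1.0)


def gen_proteins(cfg: SynthConfig) -> list[SyntheticProtein]:
    """Sequences, matching PSSMs and true RSA tables.

    Byte-identical across runs with the same config. Adhesive and decoy
    motif copies are planted before the PSSM is built, so profiles always
    reflect the final sequence.
    """
    template = adhesive_template(cfg)
    rng = np.random.default_rng(_streams(cfg)[1])
    proteins: list[SyntheticProtein] = []
    width = len(str(cfg.n_proteins))
    for k in range(cfg.n_proteins):
        pid = f"synth{k:0{width}d}"
        L = int(rng.integers(cfg.length_range[0], cfg.length_range[1] + 1))
        bg = "".join(GROUP_LETTERS[g] for g in cfg.background_groups)
        residues = [bg[i] for i in rng.integers(0, len(bg), L)]

        if cfg.rsa_mode == "runs":
            rsa_values, states = _two_state_rsa(L, cfg, rng)
            exposure = np.where(states, 1.0, -1.0)
        else:
            rsa_values, states = None, np.zeros(L, dtype=bool)
            exposure = np.zeros(L)

        is_adhesive = bool(rng.random() < cfg.p_adhesive)
        # decoys only in non-adhesive proteins: a protein either displays
        # the motif on its surface or harbours it in the core, so motif
        # content alone (the whole-sequence view) cannot separate the two
        has_decoy = bool((not is_adhesive) and rng.random() < cfg.p_decoy)
        if cfg.rsa_mode == "runs":
            if is_adhesive:
                _plant_motif(
                    residues, states, rng, template, cfg.motif_copies,
                    cfg.motif_mutation_rate, exposed=True,
                )
            if has_decoy:
                # keep decoys clear of surface spill-over: a size-w window
                # with >= o surface residues can reach w - o positions into
                # a buried run, and a leaked sticky triad needs 3 covered
                # motif residues in a row
                margin = max(0, cfg.true_surface_w - cfg.true_surface_o - 2)
                _plant_motif(
                    residues, states, rng, template, cfg.motif_copies,
                    cfg.motif_mutation_rate, exposed=False, margin=margin,
                )
        seq = "".join(residues)

        raw = rng.normal(0.0, cfg.pssm_noise_sd, (L, 20))
        col_of = np.array([PSSM_COLUMNS.index(aa) for aa in seq])
        raw[np.arange(L), col_of] += cfg.identity_signal
        raw += (cfg.exposure_signal / 2.0) * exposure[:, None] * EXPOSURE_PATTERN
        raw = np.clip(np.round(raw), -13, 13)

        if cfg.rsa_mode == "profile_linear":
            rsa_values = _linear_profile_rsa(raw, cfg)

        proteins.append(
            SyntheticProtein(
                record=SequenceRecord(id=pid, residues=seq),
                profile=PssmProfile(protein_id=pid, raw=raw, letters=seq),
                rsa=RsaTable(
                    protein_id=pid,
                    rows=[(i + 1, seq[i], float(rsa_values[i])) for i in range(L)],
                ),
                is_adhesive=is_adhesive,
                has_decoy=has_decoy,
                exposed_states=states,
            )
        )
    return proteins


def true_surface(protein: SyntheticProtein, cfg: SynthConfig) -> SurfaceAnnotation:
    """Surface called on the TRUE RSA track with the config's rule."""
    params = SurfaceParams(
        t=cfg.true_surface_t, w=cfg.true_surface_w, o=cfg.true_surface_o
    )
    return call_surface(protein.rsa.values, params, protein.record.id)


def surface_triad_types(protein: SyntheticProtein, cfg: SynthConfig) -> set[int]:
    """Triad types present (count > 0) on the protein's TRUE surface."""
    vec = count_surface_triads(
        to_group_sequence(protein.record), true_surface(protein, cfg)
    )
    return set(np.flatnonzero(vec.counts > 0).tolist())


def gen_interactions(
    proteins: list[SyntheticProtein], cfg: SynthConfig
) -> list[PairRecord]:
    """Label every coupling by the sticky-surface-triad rule, then balance.

    A pair is interacting when the two proteins' TRUE surfaces share more
    than ``theta`` sticky triad types; labels are then flipped with
    probability ``label_noise``; finally negatives (or positives, if in
    excess) are subsampled to a balanced set.
    """
    rng = np.random.default_rng(_streams(cfg)[2])
    sticky = template_triads(cfg)
    types = [surface_triad_types(p, cfg) for p in proteins]

    n = len(proteins)
    couplings = [(i, j) for i in range(n) for j in range(i + 1, n)]
    labels = {
        ij: len(sticky & types[ij[0]] & types[ij[1]]) > cfg.theta for ij in couplings
    }

    rate = sum(labels.values()) / len(couplings)
    if rate < 0.10 or rate > 0.90:
        raise ValueError(
            f"interaction rule yields {rate:.1%} positives; adjust theta, "
            f"p_adhesive or the sticky triad set"
        )

    if cfg.label_noise > 0:
        for ij in couplings:
            if rng.random() < cfg.label_noise:
                labels[ij] = not labels[ij]

    pos = [ij for ij in couplings if labels[ij]]
    neg = [ij for ij in couplings if not labels[ij]]
    k = min(len(pos), len(neg))
    pos = [pos[i] for i in sorted(rng.choice(len(pos), size=k, replace=False))]
    neg = [neg[i] for i in sorted(rng.choice(len(neg), size=k, replace=False))]

    pairs = [
        PairRecord(proteins[i].record.id, proteins[j].record.id, PairLabel.INTERACTING)
        for i, j in pos
    ] + [
        PairRecord(
            proteins[i].record.id, proteins[j].record.id, PairLabel.NON_INTERACTING
        )
        for i, j in neg
    ]
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]


def write_dataset(
    proteins: list[SyntheticProtein],
    pairs: list[PairRecord],
    out_dir,
) -> None:
    """Emit FASTA, per-protein PSSM and RSA files, and the pair list."""
    out = Path(out_dir)
    (out / "pssm").mkdir(parents=True, exist_ok=True)
    (out / "rsa").mkdir(parents=True, exist_ok=True)
    write_fasta([p.record for p in proteins], out / "proteins.fasta")
    for p in proteins:
        write_pssm(p.profile, out / "pssm" / f"{p.record.id}.pssm")
        write_rsa_table(p.rsa, out / "rsa" / f"{p.record.id}.rsa")
    write_pairs(pairs, out / "pairs.tsv")
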
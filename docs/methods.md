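# Methods

This note records the scientific and numerical choices behind
`surfppi`: what each stage assumes, which parameters matter, what the
synthetic generator does and does not emulate, and where the design was
genuinely open.

## Accessibility cascade

Stage 1 regresses true RSA on windowed PSSM-2SP vectors; stage 2
regresses true RSA on a window of stage-1 *predictions* (plus terminal
flags and chain length). The cascade's premise is that solvent exposure
is weakly determined per position but strongly spatially correlated:
buried and exposed residues come in runs, so neighbouring first-pass
predictions carry information the profile window alone does not.

* **Logistic rescaling.** Raw log-odds scores pass through
  x′ = 1/(1 + e^(−x)) with no pre-scaling of x. This is the canonical
  logistic map of integer log-odds into (0, 1).
* **Accumulated group values.** The Charged_sel and Tiny_sel columns are
  the arithmetic mean of the rescaled K/D and A/G columns of the same
  row. The mean (rather than the sum) keeps every PSSM-2SP entry in
  [0, 1]; a `group_aggregate="sum"` switch exists for users who prefer
  the summed convention (rescaled by ½ to preserve the range
  invariant).
* **Terminal handling.** Positions beyond the chain contribute a
  pseudo-terminal row (flag 1, all else 0) in stage 1, and (a = 0,
  t = 1) in stage 2. Using 0 rather than the chain-end prediction for
  out-of-range a values mirrors the stage-1 convention.
* **Regression engine.** Epsilon-insensitive kernel regression (RBF
  kernel, C = 1, ε = 0.1) behind a pluggable fit/predict contract. The
  engine standardizes its inputs internally; without this, the raw
  chain-length element of the stage-2 vectors (scale ~10²) dominates
  RBF distances and the second stage degrades rather than refines. The
  chain length is passed unnormalized at the interface level
  (`normalize_length` divides it by a cap, off by default).
* **Stage-2 training inputs** are in-sample stage-1 predictions.
  Cross-fitted (out-of-fold) cascading is available via a flag but is
  not the default: on the data sizes used here the in-sample optimism
  of stage 1 is small, and in-sample cascading keeps training
  single-pass.
* **Clamping.** Final predictions are clamped to [0, 1]; the regressor
  itself is unconstrained.

## Surface identification

Surface residues satisfy RSA ≥ t (inclusive). Windows are fully
contained in the chain with step 1; a window qualifies with ≥ o surface
residues, and the surface is the union of qualifying windows. A chain
shorter than w is treated as a single full-length window so short
chains are not silently surface-less. Defaults t = 0.3, w = 9 follow
the method's worked illustration; o = 3 is the recommended value (a
stable contact patch needs at least three surface residues). All three
are exposed to the cross-validation grid. The surface is stored both as
a position set and as maximal segments; BED export converts the
internal 1-based inclusive coordinates to 0-based half-open.

An optimized implementation (prefix sums + difference array) is used at
run time; the test suite holds it equal to an explicit
enumerate-every-window reference on a thousand random masks.

## Triad encoding

The seven-group table covers all 20 amino acids; the fourth group is
His, Asn, Gln, Trp. Non-canonical letters (B, Z, X, U, O) map to an
unmappable sentinel and any triad containing the sentinel is skipped. A
triad is counted only when all three positions are inside the surface
(equivalently, inside one segment); with the surface set to the whole
chain the encoding reduces exactly to the classic whole-sequence
conjoint-triad vector, which is the package's baseline ("no surface
information") mode. Pair features are order-dependent
([A ∥ B] ≠ [B ∥ A]); raw counts are the default, with optional
per-protein min–max scaling behind a `normalize` flag. Training-set
symmetrization (adding the mirrored pair) is not performed.

## RVKDE

The estimator family is fixed as: isotropic Gaussian kernels normalized
to unit integral, (√π σᵢ)^(−m) exp(−‖v − sᵢ‖²/σᵢ²); uniform 1/n mixture
weights; per-instance bandwidth σᵢ = c(m, ks) · β · R(sᵢ) with R(sᵢ)
the Euclidean distance to the instance's ks-th nearest same-class
neighbour; and class priors |Sⱼ|/Σ|Sⱼ| multiplying class densities. The
dimension constant c(m, ks) = √π/(ks · Γ(m/2 + 1))^(1/m) comes from the
volume of the m-ball holding the ks neighbours; any positive constant
yields a valid estimator (β can absorb it), and c is configurable. The
kt truncation keeps only the kt instances nearest the query in the
kernel sum while still dividing by n, so kt = "all" recovers the full
estimator and the truncated density increases monotonically to it.

Numerical choices:

* All density evaluation is done in the log domain (log-sum-exp). In
  686 dimensions the unit-integral normalizer underflows double
  precision by hundreds of orders of magnitude; comparing class
  log-likelihoods is exact where comparing likelihoods would tie at
  0.0.
* Features are z-scored with training statistics before any distance
  computation (config-disableable). Raw triad counts put coordinates on
  wildly different scales; zero-variance coordinates are left unscaled.
* Duplicate instances can force R(sᵢ) = 0; bandwidths are floored at
  10⁻¹² with a warning rather than producing a degenerate kernel.
* Exact likelihood ties are resolved to non-interacting — the
  conservative call in an interaction screen.
* In high dimension the σ^(−m) normalizer strongly rewards the class
  with locally smaller bandwidths, so useful β values are well below 1
  (the validation grids here use β ∈ [0.1, 0.5]); β, ks and kt are
  exactly the parameters the evaluation protocol tunes.

## Evaluation protocols

The split protocol draws, per repeat, disjoint train/validation/test
subsets each containing equal numbers of interacting and
non-interacting pairs, grid-searches (surface and classifier)
parameters on validation by F-measure, and reports test metrics;
aggregates are mean ± sample standard deviation over repeats. The
full-scale default subset sizes are 341/175/175 interacting pairs; the
desk-scale runs in the tests and the acceptance script use
60/30/30 interacting pairs (plus matched negatives) over 40-protein
datasets, with 3 repeats — sizes chosen so a full two-encoding
comparison over five datasets completes in well under a minute.
Validation ties break deterministically: higher accuracy, then smaller
w, then lower t, then grid order. Metrics with zero denominators are
reported as explicit `"undefined"` markers and excluded from means with
a count. Negative subsets are resampled fully in every repeat.

The CV protocol is repeated stratified k-fold with per-repeat summed
confusion counts; leave-one-out (folds = n) falls back to unstratified
folds since stratification is impossible there. Both protocols are
bit-reproducible from a single seed via independent spawned
substreams.

## Synthetic data generator

The generator produces the pipeline's full input surface — FASTA,
PSI-BLAST-dialect PSSM files, reference RSA tables, labeled pair
lists — from one seed, with the statistical structure each stage
assumes:

* **True RSA** is a two-state hidden-run process: exposed runs near
  0.7, buried runs near 0.1, geometric run lengths (mean 12), Gaussian
  jitter (sd 0.08), clamped to [0, 1]. The run structure supplies the
  spatial correlation the cascade's second stage exploits.
* **PSSMs** carry an identity signal (+4 on the true residue's column),
  i.i.d. noise (sd 1.5), and a weak exposure signal (±1.5 along a fixed
  hydrophilic-vs-hydrophobic column pattern, by exposure state) — the
  way surface positions in real alignments tolerate hydrophilic
  substitutions. The exposure signal is deliberately weak per position:
  stage 1 alone reaches MAE ≈ 0.08 against a jitter floor of ≈ 0.064,
  leaving room that stage-2 smoothing measurably recovers.
* **Sequences** have a low-complexity hydrophobic/small background
  (letters of groups 1–2 by default, configurable), against which the
  charged adhesive motifs below occupy a disjoint region of triad
  space — mirroring how interface patches stand out against core
  composition. This is the main deliberate departure from uniform
  20-letter sequences: with a uniform background, between-protein
  distances in triad space are dominated by background composition
  noise and no distance-based classifier can resolve the planted
  signal at desk scale.
* **Interactions** follow a shared-surface-patch rule. Each dataset
  draws one 9-residue template motif over the charged/cysteine groups;
  with probability 0.6 a protein is *adhesive* and carries two noisy
  copies (10% per-residue mutation) inside exposed runs; otherwise,
  with probability 0.85, it carries buried *decoy* copies placed with a
  margin that keeps them clear of surface-window spill-over. A pair is
  labeled interacting when its two TRUE surfaces (t = 0.5, w = 9,
  o = 3 on true RSA) share more than θ = 2 sticky triad types (the
  template's own triads), then flipped with the label-noise rate
  (0 by default) and balanced by subsampling. The generator rejects
  configurations whose rule yields under 10% or over 90% positives.

  Two properties of this construction matter. The label rule lives on
  *true* surfaces while the pipeline only sees *predicted* ones, so
  ASA-prediction quality genuinely mediates PPI performance. And decoy
  copies make adhesive and non-adhesive proteins indistinguishable by
  whole-sequence triad content — the whole-sequence baseline is
  systematically confused exactly where the surface-restricted
  encoding is not, which is the mechanism behind the package's central
  directional claim.

What the generator does **not** emulate: evolutionary sequence
structure, realistic amino-acid frequencies, PSI-BLAST search
statistics, continuous ASA distributions (real RSA is not two-state),
structural constraints linking sequence to exposure, or the hub
structure of real interaction networks. Passing tests therefore show
that the pipeline recovers the signal class it targets under its own
assumptions — not that it attains any particular accuracy on real
proteomes, which would require curated interaction sets, database-derived
profiles and structure-derived reference surfaces. In
particular the near-perfect predicted-vs-reference surface overlap on
synthetic data reflects the clean two-state exposure process, not
expected performance on real structures.

## Problem sizes

Default desk-scale conditions: 40 proteins of length 60–100,
balanced pair sets of a few hundred, split subsets of 60/30/30
interacting pairs, 3 repeats, 5 dataset seeds for any cross-seed mean;
the cascade-recovery experiment uses 50 proteins (40 train / 10 test)
in the noiseless profile-determined RSA mode with a tightened
regression tolerance (C = 10, ε = 0.01). The full test suite runs in
about a minute; the acceptance script in under half a minute.

## Known limitations

* The RVKDE normalization constant is parameterized (see above); only
  properties invariant to c are asserted.
* Surface-restricted triad counting is O(L) per protein in pure
  Python; adequate at these scales, vectorizable if ever needed.
* The split protocol's grid search refits the classifier per grid
  point per repeat; feature matrices are cached but models are not.
* Pair features are order-dependent by design; callers who need
  symmetry must symmetrize their pair lists.
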
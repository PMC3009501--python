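# surfppi

Sequence-only prediction of protein–protein interactions (PPIs) with a
predicted protein surface.

Most residues that mediate a physical interaction sit on the protein
surface, yet the most widely used sequence-only PPI encodings count
sequence features over the *whole* chain, core included. `surfppi`
implements a pipeline that keeps the sequence-only setting but restricts
the feature encoding to a surface predicted from sequence alone:

1. **ASA prediction** — two cascading support-vector regressions map a
   PSSM-derived per-residue encoding to relative solvent accessibility
   (RSA ∈ [0, 1]).
2. **Surface identification** — a sliding-window rule turns the RSA
   track into a predicted surface.
3. **Feature encoding** — conjoint-triad counts restricted to the
   predicted surface encode each protein; a pair is the concatenation of
   its two protein vectors.
4. **Classification** — a relaxed variable kernel density estimator
   (RVKDE) classifies pairs as interacting or not.

The package is for computational biologists who want a complete,
retrainable reference implementation of this pipeline — every stage is a
library function with a matching CLI command — plus a synthetic data
generator that makes the whole pipeline testable end to end without any
external database.

## The model

**PSSM-2SP encoding.** Raw PSSM log-odds scores *x* are rescaled with
the logistic function *x′* = 1/(1 + e^(−*x*)). Each residue becomes a
23-dimensional row: the 20 rescaled scores, a terminal flag (0 for real
residues), and two accumulated group values for the Charged_sel {K, D}
and Tiny_sel {A, G} groups (mean of the two named columns). Stage 1 of
the cascade sees a window of *w*₁ = 11 consecutive rows (253 values;
positions beyond the chain contribute a pseudo-terminal row whose flag
is 1 and whose 22 other entries are 0). Stage 2 sees the vector
**v** = (*a*₍ᵢ₋ₕ₎, *t*₍ᵢ₋ₕ₎, …, *a*ᵢ, *t*ᵢ, …, *a*₍ᵢ₊ₕ₎, *t*₍ᵢ₊ₕ₎, *l*)
with *w*₂ = 5: a window of stage-1 RSA predictions *a*ⱼ and terminal
flags *t*ⱼ, plus the chain length *l* — exploiting the fact that
solvent exposure is spatially correlated along the chain.

**Surface rule.** Residues with RSA ≥ *t* are surface residues. Every
length-*w* window (step 1, fully inside the chain) containing at least
*o* surface residues is a surface window; the predicted surface is the
union of all surface windows. Defaults: *t* = 0.3, *w* = 9, *o* = 3,
all meant to be tuned by cross-validation (*o* = 3 is the recommended
setting).

**Conjoint triads.** The 20 amino acids collapse to 7 groups
(1 = AGV, 2 = ILFP, 3 = YMTS, 4 = HNQW, 5 = RK, 6 = DE, 7 = C); a triad
is the group triple of three consecutive residues (343 types). Only
triads lying entirely inside the predicted surface are counted. A pair
is the 686-dimensional concatenation of its two protein vectors.

**RVKDE.** Each training instance **s**ᵢ gets an adaptive Gaussian
kernel with bandwidth σᵢ = c(m, ks) · β · R(**s**ᵢ), where R(**s**ᵢ) is
the distance to its ks-th nearest same-class neighbour and
c(m, ks) = √π / (ks · Γ(m/2 + 1))^(1/m). The class density at a query
**v** averages the kernels
(√π σᵢ)^(−m) · exp(−‖**v** − **s**ᵢ‖² / σᵢ²) of the kt training
instances nearest **v**, divided by the class size n. Classification
picks the class with the larger prior-weighted density, priors being
class fractions; exact ties go to non-interacting.

## Worked example

All inputs here are synthetic (see `surfppi.synthetic`): sequences,
PSI-BLAST-style PSSM files, reference RSA tables, and a labeled pair
list, generated from one seed.

```console
$ surfppi simulate --seed 23 --out-dir data
wrote 40 proteins and 454 pairs (227 interacting) to data

$ surfppi train-asa --fasta data/proteins.fasta --pssm-dir data/pssm \
      --rsa-dir data/rsa -o asa.model
trained on 40 proteins; model saved to asa.model

$ surfppi predict-asa --model asa.model --pssm data/pssm/synth03.pssm -o synth03.rsa
wrote 85 RSA values to synth03.rsa

$ surfppi surface --rsa synth03.rsa -t 0.5 -w 9 -m 3 -o synth03.bed
synth03: 66/85 surface residues in 2 segment(s)
$ cat synth03.bed
synth03	0	23	surface_1
synth03	42	85	surface_2
```

66 of synth03's 85 residues fall in two predicted surface segments
(BED coordinates are 0-based half-open). Featurizing every pair over
the predicted surfaces and running the split protocol — disjoint
train/validation/test subsets with equal interacting and
non-interacting pairs, parameters picked on validation by F-measure —
gives:

```console
$ surfppi featurize --fasta data/proteins.fasta --surface-dir surf \
      --pairs data/pairs.tsv -o features.tsv
wrote 454 pair rows to features.tsv
$ surfppi evaluate --features features.tsv --protocol split \
      --n-train 60 --n-val 30 --n-test 30 --repeats 3 --seed 1 \
      --grid grid.yaml -o report.json
report written to report.json
```

with aggregate test metrics (mean ± sd over 3 repeats):

```
accuracy: 0.800 +/- 0.050
f_measure: 0.799 +/- 0.032
precision: 0.823 +/- 0.110
sensitivity: 0.789 +/- 0.069
specificity: 0.811 +/- 0.158
```

That is: on held-out pairs, four in five calls are correct, and the
balance of precision and sensitivity (the F-measure) sits at 0.80. The
same command with `featurize` run *without* `--surface-dir` gives the
whole-sequence baseline encoding for comparison.

## Layout

| module | role |
| --- | --- |
| `surfppi.io_formats` | FASTA / PSSM / RSA-table / pair-list readers and writers, model archives |
| `surfppi.profile_encoding` | PSSM-2SP construction and both window encodings |
| `surfppi.asa_predictor` | the two-stage RSA regression cascade |
| `surfppi.surface` | surface calling, overlap scoring, BED export |
| `surfppi.triads` | 7-group mapping, surface-restricted triad counts, pair features |
| `surfppi.rvkde` | adaptive-bandwidth density estimation and the pair classifier |
| `surfppi.evaluation` | metrics, split and cross-validation protocols, grid search |
| `surfppi.synthetic` | the synthetic data generator |
| `surfppi.cli` | the `surfppi` command-line interface |

The fixed 20-column amino-acid order of all PSSM matrices is
`A R N D C Q E G H I L K M F P S T W Y V` (`surfppi.PSSM_COLUMNS`).
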
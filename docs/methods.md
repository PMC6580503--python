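# Methods

`kascade` predicts whether a lysine residue in a human protein is an
acetylation site. This note documents the model, the numerical choices, the
synthetic data the package is validated on, and the limits of what those
validations show.

## Problem setting

Experimentally verified acetylation sites are scarce relative to unmodified
lysines — roughly one positive per ten negatives in curated training data.
A candidate site is represented by the 19-residue peptide window centred on
the lysine (9 residues upstream, 9 downstream), padded with `'X'` where the
chain ends early. Coordinates are 1-based throughout. Ambiguous amino-acid
letters (B, Z, J, U, O, `*`) are normalised to `'X'` on input and treated
exactly like padding in every encoder.

## Feature encoding (632 dimensions)

Six descriptor blocks are concatenated in fixed order; every column carries a
registry entry `(encoder, position/lag, property/letter)`.

| block | dims | content |
|------|------|---------|
| PCP  | 72   | 4 physicochemical properties x 18 non-centre positions |
| PSSM | 380  | 19 positions x 20 substitution scores |
| AC   | 8    | 4 properties x lags {1, 2} |
| RC   | 20   | amino-acid frequencies in the window |
| SS   | 133  | 19 positions x 7-bit secondary-structure one-hot |
| ASA  | 19   | per-position accessible surface area (A^2) |

**PCP.** Each AAindex-style property j with per-residue values P_ij is
standardised over the 20 standard amino acids:
`X_ij = (P_ij - mean_j) / sd_j` (population SD). `'X'` carries the raw value
0, i.e. `(0 - mean_j)/sd_j` after standardisation (`x_policy="raw-zero"`;
`"z-zero"` maps it to 0 instead). The centre lysine is excluded from the PCP
block by default (`pcp_include_center=False`) because it is constant across
samples; including it changes the block to 4 x 19 = 76 columns.

**AC (auto-covariation).** For standardised values x_1..x_n across the
window (n = 19, padding included) with window mean m:

    AC(lag, j) = (1 / (n - lag)) * sum_{i=1..n-lag} (x_i - m)(x_{i+lag} - m)

at lags 1 and 2. The test suite checks this against an independent
double-loop implementation at 1e-12 on a thousand random windows.

**PSSM.** PSI-BLAST ASCII PSSM files are parsed; the 20-column integer
log-odds block is used (the percentage block is ignored). Window padding and
in-sequence `'X'` contribute all-zero rows. A missing PSSM for a protein is
either an error or an all-zero block with a warning (`missing_pssm`).

**RC.** Frequencies of the 20 amino acids among the window's non-`'X'`
positions (alphabetical order), so the vector sums to 1. An option
(`rc_count_x` analogue: `count_x=True`) keeps `'X'` in the denominator,
dropping the implicit `'X'` mass from the output.

**SS.** DSSP states H, B, E, G, I, T, S become a 7-bit one-hot per position
with bit order S T I G E B H from most- to least-significant (H -> 0000001,
S -> 1000000); DSSP blank (coil), `'-'` and padding map to 0000000.

**ASA.** Raw per-residue accessible surface area in A^2 (not relative);
padding contributes 0. Annotations come from DSSP files (structure letter +
ACC column) or a plain TSV `protein_id / position / ss / asa`.

## Evaluation metrics

Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total and the Matthews
correlation coefficient, which equals the Pearson correlation of the binary
truth and prediction vectors (an identity the tests verify). A zero factor
in the MCC radical yields MCC = 0 with an explicit degeneracy flag, never
NaN. Precision TP/(TP+FP) is also reported. MCC is the model-selection
criterion throughout because it is the only one of the four that is
informative under heavy class imbalance.

## Two-step feature selection

1. **mRMR ranking.** Features are discretised into 3 bins at mean +/- SD
   (codes -1/0/+1, inclusive bin edges so binary columns survive).  Greedy
   MID ranking: first pick maximises I(f; y); each later pick maximises
   `I(f; y) - mean_{g in S} I(f; g)` (mutual information in nats from the
   joint contingency table). Ties break to the lowest column index. The
   ranking is truncated to the top 300. A Fisher-score ranker
   `(m1-m0)^2/(v1+v0)` is available as an alternative (`ranker="fisher"`).
2. **IFS.** For each prefix of the ranking a balanced RBF-SVM is trained and
   scored by validation MCC; the smallest prefix attaining the maximum wins
   (parsimony on ties). The selected subset size is data-dependent, not a
   constant.

## Cascade of balanced SVM layers

Let PD be the positive rows (M = |PD|) and TND the full negative pool.

1. ND = seeded uniform draw of M negatives from TND; fit scorer S_1 on
   PD vs ND.
2. Score PD and the surviving TND with S_i.
3. Sort PD's decision values descending; T_i = value at 1-based rank
   ceil(q M), q = 0.95 — so at least ceil(q M) positives satisfy
   Deci >= T_i and at most a fraction 1-q is sacrificed per layer.
4. Remove from TND every negative with Deci < T_i; (S_i, T_i) is layer i.
5. Next ND = the M surviving negatives with the lowest scores (the hardest
   ones), ties broken by stable sample index.
6. Stop when a round removes fewer than `stop_frac` (0.05) of the
   *original* |TND|; the triggering layer is retained, since its removals
   must stay accounted for in the negative-pool bookkeeping. Training also
   stops (with a warning) if the surviving pool can no longer fill a
   balanced ND.

Prediction is a short-circuit conjunction: a sample is positive only if its
decision value clears every layer's threshold; the exit layer is recorded
per sample. Two baselines are provided for comparison: a single SVM on the
full imbalanced pool and a single SVM on one balanced undersample.

### Scorer and kernel width

The scorer is an injected interface (`fit` + `decision_function`, larger
means more positive). The default is an RBF SVM (scikit-learn `SVC`, C = 1)
behind a per-layer `StandardScaler`: the descriptor blocks live on wildly
different scales (A^2, integer log-odds, unit variance) and an unscaled RBF
kernel is dominated by the widest block.

The kernel width defaults to `gamma = 0.03 / n_features` on the
standardised inputs rather than the conventional `1 / n_features`. The
threshold rule prices layer thresholds off the *training* positives'
decision values, which is only meaningful if those values generalise. At a
few hundred training samples on 632 dimensions, `gamma = 1/dim` lets the
RBF machine separate the training set outright: training positives pin to
the margin (median decision value 1.0) while held-out positives score far
lower, the 0.95-quantile threshold lands above everything unseen, and the
cascade degenerates to an all-negative predictor. The smoother default
keeps training and held-out score distributions comparable, which is the
regime the threshold rule assumes. Both C and gamma (or the
`gamma_factor`) are configurable, so the conventional width is one option.

## Descriptive site analyses

All analyses return tidy DataFrames (exported as TSV by the CLI), with `'X'`
excluded from every frequency denominator:

* per-position mean +/- standard error of each standardised property, by
  class;
* per-position Shannon entropy (base 2) of amino-acid usage, by class — low
  entropy marks a conserved position; the maximum is log2(20) ~ 4.32 bits;
* per-position, per-residue frequency differences between classes with a
  pooled two-proportion z-test (statsmodels), calling enrichment/depletion
  at a configurable alpha (default 0.05) — the numerical core of a
  two-sample logo, without the graphics;
* secondary-structure state frequencies F_i = N_i/N at the site residue for
  i in {H, B, E, G, I, T, S}, coil reported as the remainder;
* binned site-residue ASA histograms (width 10 A^2 up to 150, final bin
  open-ended), normalised per class.

## Synthetic data generator

The generator is first-class, tested code: it emits a complete bundle
(FASTA, site TSV, per-protein ASCII PSSMs, structure TSV, YAML manifest)
whose class-conditional structure mirrors what is reported for real human
acetylation data. Defaults (the package's study conditions):

* 300 proteins of length 80–300 drawn from UniProt-like background
  amino-acid frequencies; 200 positive and 2000 negative sites (10:1),
  placed one window width apart so planted flank compositions never
  overlap;
* sequence: P(K at +1) = 0.25 in positives (background 0.058), P(K) = 0.12
  at positions +/-2, +/-3, serine multiplied by 0.10 at +1..+4;
* structure: positive site residues strand-enriched (E 0.28 vs 0.18) with
  zero beta-bridge mass; ASA at positive sites ~ N(75, 35) A^2 clipped to
  [0, 220] versus a buried/low mixture (0.35 Exp(8) + 0.65 |N(35, 25)|) at
  negative sites;
* PSSM: per-residue Dirichlet-perturbed background frequencies mixed with a
  one-hot on the true residue (conservation weight 0.25, raised to 0.33
  immediately downstream of positive sites), converted to integer log-odds
  clipped to +/-12.

These effect sizes were set so the classes overlap moderately — a balanced
SVM reaches MCC ~0.3–0.5 on held-out proteins — because that is the regime
the cascade exists for; at these sizes the all-data single SVM also
reproduces the classic imbalance failure (Sn near 0, Sp near 100%).
`GeneratorConfig.null()` gives a no-signal configuration for negative
controls. Identical seeds give byte-identical bundles; splits are always by
protein, so no protein contributes windows to two partitions.

What the generator does **not** emulate: homology between proteins,
realistic PSSM correlation structure along the chain, sequence–structure
coupling (SS states are drawn independently of the residues), multi-chain
proteins, or annotation noise. Passing tests therefore demonstrate that the
implementation is correct and that the method behaves as designed under its
own assumptions — not that the trained models transfer to real proteomes.

## Reproducibility and problem sizes

Every source of randomness flows from explicit integer seeds
(`numpy.random.default_rng`); the CLI derives per-stage sub-seeds from one
global seed, and identical config + seed reproduce byte-identical bundles,
model archives and predictions. The test suite and the acceptance script
run the full pipeline at the default 300-protein / 2200-site scale — large
enough to exhibit the imbalance phenomenology while keeping a complete
multi-seed benchmark in the minutes range on one CPU.

## Known limitations

* The curation pipeline that produced the original human datasets (CD-HIT
  redundancy reduction, PDB matching, resolution filtering) is out of
  scope; real-data use requires the user to supply FASTA/sites/PSSM/DSSP
  inputs produced by the standard external tools.
* The four shipped physicochemical property tables are synthetic
  stand-ins in AAindex1 format; point `aaindex`/`accessions` at a real
  AAindex1 file for production use.
* The per-property screening that originally chose the four properties is
  expressible through the configuration but not automated as a single
  command.
* Thresholds are estimated on training positives; with very small positive
  sets (M below ~50) they remain noisy even with the smooth kernel.
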
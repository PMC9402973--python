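# Methods

## Problem and model

`ionbind` predicts, per residue of a protein chain, whether that residue
binds a metal-ion ligand (Zn²⁺, Cu²⁺, Fe²⁺, Fe³⁺, Co²⁺, Mn²⁺, Ca²⁺, Mg²⁺),
using only sequence-derived information: the amino-acid identity, predicted
secondary structure, relative solvent accessibility (RSA), backbone
dihedrals (φ, ψ), and a predicted intrinsic-disorder score.  Each residue
is classified from the length-L window of (pseudo-)residues centred on it;
L is ligand-specific (Zn 13, Cu 15, Fe²⁺ 9, Fe³⁺ 11, Co 11, Mn 11, Ca 9,
Mg 15).  Chain ends are padded with (L−1)/2 pseudo-residues that occupy a
dedicated *vacancy* category in every annotation track, so every real
residue can be a window centre.

### Discretization

Continuous tracks are discretized with right-closed intervals:

| track    | intervals (category I, II, …)                      | q (incl. vacancy) |
|----------|----------------------------------------------------|---|
| disorder | [0, 0.5], (0.5, 1]                                 | 3 |
| RSA      | (0, 0.2], (0.2, 0.45], (0.45, 0.6], (0.6, 0.85]    | 5 |
| φ        | [−180°, −75°], (−75°, 180°]                        | 3 |
| ψ        | [−180°, 15°], (15°, 135°], (135°, 180°]            | 4 |

RSA = 0 maps into the first interval and RSA > 0.85 clamps into the last so
the map is total; the disorder boundary value 0.5 belongs to the *ordered*
class (closed interval).  Amino acids additionally map onto a charge
alphabet (positive K/R/H, negative D/E, neutral otherwise; q = 4) and a
six-way hydropathy alphabet (strongly hydrophilic R/D/E/N/Q/K, strongly
hydrophobic L/I/V/A/M/F, weakly amphipathic S/T/H/Y/W, and the special
classes P, G and C; q = 7).  Both class tables ship as editable YAML
(`src/ionbind/data/residue_classes.yaml`); the memberships are a documented
assumption, chosen so that cysteine — chemically singular in metal
coordination — keeps its own class.

### Features

Four feature families are computed per fragment and concatenated
(component | conservation | entropy | propensity):

1. **Component information** — within-window relative frequency of every
   category of each track (vacancy included): 21+4+5+3+4+3 = 40 values, or
   37 without disorder.
2. **Site conservation (position weight matrices)** — for each track, two
   L×q log-odds matrices are fitted, one on positive and one on negative
   training fragments, with elements m(i,j) = ln(p(i,j)/p₀(j)) and the
   square-root pseudocount p(i,j) = (n(i,j) + √N/q) / (N + √N), where N is
   the class's fragment count and p₀ the pooled background category
   frequency over the whole training partition (floored at 1/(10·q·total)
   to keep every logarithm finite).  A fragment scores m at its observed
   category per position under both matrices: 2L values per track, six
   tracks (full) or five (basic), i.e. 6·2L or 5·2L values.
3. **Information entropy** — Shannon entropy (bits) of the window's charge
   (q = 4) and hydropathy (q = 7) category distributions: 2 values.
4. **Propensity factors** — Chou–Fasman-style ratios
   F(i,j) = (n(i,j)/N(i)) / (N(j)/N_t) measuring over-representation of the
   central residue's category i among class-j centres; the pair
   (F binding, F non-binding) is emitted for the centre's amino acid,
   charge and hydropathy: 6 values.  Categories unseen in training get the
   neutral factor 1.  The propensity describes the central residue only —
   the one reading consistent with a 6-dimensional block.

Assembled dimensions: 48 + 12L for the full set (L = 13 → 204) and
39 + 10L for the basic set, which omits disorder from the component and
conservation blocks and drops the propensity block entirely (L = 13 → 169).
Features are z-score standardized with parameters fitted on training folds
only (standardization is configurable).

All fitted encoders record the identity set of their training fragments;
the cross-validation harness asserts before scoring that no held-out
fragment contributed to any fitted table or matrix.

### Classifier

A feed-forward network: `hidden_layers` ReLU layers of `hidden_nodes`
units, a sigmoid output, binary cross-entropy loss, Adam optimizer.  The
implementation drives scikit-learn's multilayer perceptron one epoch at a
time so that early stopping can monitor *validation log-loss* on a held-out
stratified split (default 10%): at ~1.5% positive prevalence, accuracy — the
quantity scikit-learn's built-in early stopping watches — is insensitive to
everything that matters.  Training stops after `patience` consecutive
non-improving epochs and restores the best epoch's weights; `patience = 0`
therefore stops at the first non-improving epoch.  A non-finite loss raises
a divergence error carrying the configuration.

Defaults not fixed by the training recipe: learning rate 1e-3, max 200
epochs, patience 10, validation fraction 0.1, L2 weight decay 1e-4 — all
exposed in `NetConfig`.  Class imbalance is left untreated by default (the
operating regime is deliberately high-specificity/low-sensitivity); an
optional `positive_weight` replicates positive training rows
deterministically for applications that need higher recall.  The decision
threshold is stored explicitly (default 0.5).

The grid search enumerates hidden layers {1..8}, nodes {2,4,…,128} and
batch size {2,4,…,128} (392 configurations; a seeded budgeted subset by
default from the CLI), scores each by cross-validated pooled MCC (or Sn),
and breaks ties toward fewer layers, fewer nodes, larger batch.

### Evaluation

Sn, Sp and Acc in percent and MCC, computed from pooled (micro) confusion
counts across folds; per-fold values and their mean are also reported.
Undefined Sn/Sp (empty class) is reported as NaN with a flag, never as 0;
an MCC with zero denominator is 0 with a flag.  Cross-validation is
stratified at the fragment level by default (chain-level grouping
available for stricter generalization estimates); fold assignment is
seeded.  Encoders, scaler and network are refitted per fold on training
fragments only.

## Synthetic data

The generator emulates the statistical structure of a BioLip-style
residue-level dataset without simulating protein structure:

- chain lengths ~ Normal(200, 60) truncated at 50;
- binding fraction 0.015, matching the class imbalance of curated
  metal-site datasets; the per-chain positive count is fixed by stochastic
  rounding, so the realized fraction tracks the target tightly;
- binding residues are planted as clusters of 4 within an 8-residue span,
  mirroring the sequence-local coordination shells of real metal sites
  (e.g. Cys₂His₂ or Cys₄ zinc sites);
- binding residues draw their amino acid with odds 36 on D/E/H/N versus a
  uniform background, which puts ~90% of binding residues in the enriched
  set — the first-shell coordination rate observed in curated metal-site
  data.  The odds are a spec field; the weaker odds-10 setting used in the
  propensity-recovery example is exercised explicitly in tests;
- disorder is a two-component Beta mixture, Beta(8,2) (disordered) and
  Beta(2,8) (ordered); binding residues draw from the high component with
  probability 0.9, non-binding with 0.1, giving
  P(disorder > 0.5) = 0.884 vs 0.116.  This calibration was set by a
  posterior-odds analysis: each binding residue inside a window must carry
  roughly 2 nats of evidence for a typical positive centre to clear the
  prior penalty ln(0.015/0.985) ≈ −4.2 at decision threshold 0.5;
- secondary structure, RSA and dihedrals are label-independent by default,
  keeping feature-ablation experiments interpretable.

What the generator does **not** emulate: realistic amino-acid background
composition, sequence correlation, structural coherence between tracks
(e.g. helix-dependent dihedrals), chain-level redundancy, or multi-segment
binding sites whose coordinating residues are distant in sequence.
Passing the end-to-end tests therefore demonstrates that the pipeline
recovers a planted sequence-local signal under realistic imbalance — not
that it attains any particular performance on real BioLip data.

A separate worked fixture (two 50-residue chains, 100 residues, 20 binding)
has hand-computable counts — e.g. D occurs 10 times, 5 binding, so
F(D, binding) = (5/10)/(20/100) = 2.5 — and serves as the oracle for the
propensity arithmetic.

## Problem sizes and evaluation configuration

The end-to-end checks run at desk scale, chosen as the package's own
standard conditions: ~10,400 fragments (50 chains, ~150 positives) for
signal recovery, which is the smallest size at which the minority class is
reliably learnable, and three-to-five replicates of ~2,500 fragments for
the ablation comparison.  The evaluation network is a
hyper-parameter-optimised setting in the grid's range — 2×16 units, batch
16, weight decay 0.1, max 400 epochs, patience 25 — with `positive_weight=5`
engaged for the signal-recovery run.  On label-shuffled data the same
pipeline yields |MCC| < 0.05, confirming that the recovery is signal, not
leakage.

## Numerical choices and degenerate inputs

- Interval boundary membership is right-closed everywhere, matching the
  discretization tables above exactly.
- 0·log₂0 ≡ 0 in the entropy; entropies are bounded by log₂q.
- The PWM background floor (1/(10·q·total)) only engages for categories
  absent from the training partition; a warning is emitted.
- Fragments from single-residue chains are all padding except the centre.
- Non-canonical residues (X, B, Z, U, J, O) are rejected by default;
  an explicit remap option maps them to the vacancy symbol, which then
  contributes to vacancy counts in every amino-acid-derived track.
- Ties in the grid search are broken deterministically (fewer layers,
  fewer nodes, larger batch).
- All randomness — generator, fold assignment, validation split, weight
  initialisation, minibatch order — is seeded; identical seeds give
  identical results.

## Known limitations

- The network is CPU-bound scikit-learn; no GPU path.
- Chain-level splitting is available but fragment-level stratified
  splitting is the default, which slightly flatters generalization when
  neighbouring (overlapping) windows land in different folds.
- The hydropathy and charge class memberships are configurable assumptions.
- Real upstream predictors (secondary structure, RSA, dihedrals, disorder)
  have correlated errors that the synthetic tracks do not model.
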
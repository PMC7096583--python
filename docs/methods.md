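# Methods

## Problem and representation

`ionbind` classifies individual protein residues as binding or not binding
a given metal ion ligand, using only per-residue sequence-derived
annotations: the amino acid, a three-state secondary structure (H/E/C), and
a relative solvent accessibility (RSA) value. Annotations are inputs — the
package does not predict secondary structure or RSA itself, and it does not
parse structures; chains arrive as FASTA plus a per-residue TSV.

A residue is represented by the length-*L* window centered on it. *L* is
odd and ligand-specific (5–21); shipped defaults are Zn²⁺ 7, Cu²⁺ 13,
Fe²⁺/Fe³⁺ 9, Co²⁺ 11, Ca²⁺ 9, Mg²⁺ 9, Mn²⁺ 7, Na⁺ 9, K⁺ 11. Chains are
padded with (L−1)/2 dummy residues per side so every residue, including
terminal ones, owns a full window. The PAD entry is the vacancy symbol `X`
in the amino-acid channel; the other channels each gain a dedicated PAD
symbol, keeping every channel alphabet closed. An in-chain `X` (unknown
residue) likewise falls back to the PAD/vacancy symbol in the derived
channels, since no category is defined for it.

## Channels

* **WA** — amino-acid identity over the 21-symbol alphabet (20 + `X`).
* **QS** — six hydrophilicity/hydrophobicity groups. Default grouping:
  {A,G}, {V,L,I,P}, {F,W,Y}, {S,T,C,M}, {N,Q,D,E}, {K,R,H}. The pipeline is
  structurally invariant to the specific grouping, and the map is
  overridable in the config; correctness is tested structurally (coverage,
  category count), not against one canonical table.
* **DH** — charge: positive {K,R,H}, negative {D,E}, uncharged otherwise;
  also overridable.
* **SS** — the H/E/C annotation verbatim.
* **SA** — discretized RSA under one of four schemes:
  * `SA_2`: buried (< 0.25) / exposed. The boundary value 0.25 is assigned
    to exposed, consistent with the half-open convention of `SA_V` below.
  * `SA_4`: [0, 0.2], (0.2, 0.45], (0.45, 0.6], (0.6, 0.85] → E/F/G/H
    (left-open, right-closed).
  * `SA_V`: [0, 0.15), [0.15, 0.25), [0.25, 0.35), [0.35, 0.85] → A/B/C/D
    (left-closed, right-open), derived from the shape of the
    class-conditional RSA distributions.
  * `SA_P`: [0, 0.15), [0.15, 0.4), [0.4, 0.5), [0.5, 0.85] → I/K/L/M,
    derived from the distribution peaks.

  Which scheme works best is ligand-specific; shipped defaults are `SA_4`
  for Zn²⁺/Cu²⁺/Fe²⁺/Mg²⁺, `SA_V` for Fe³⁺/Co²⁺/Na⁺/K⁺, `SA_2` for Ca²⁺,
  and `SA_P` for Mn²⁺. Interior breakpoints are configurable per ligand;
  the defaults above are used when no override is given. RSA is accepted in
  [0, 1] at load time but every scheme's support ends at 0.85 (the
  practical ceiling of RSA predictors), so larger values are clamped to
  0.85 at encoding time — counted and logged (one aggregate warning per
  encoding call, per-value detail at DEBUG), never silent.

`rsa_distribution` computes the class-conditional histogram of
center-residue RSA — the statistic that motivates per-ligand
reclassification. Only center residues enter this statistic; window
positions are binned only inside segment encoding.

## Position-weight scoring matrices

Per channel, with alphabet size K (PAD included) and training windows of
one class:

    P_ij = (n_ij + N_i/K) / (2 N_i)

an equal-weight mixture of the empirical symbol frequency at position *i*
and the uniform distribution. This smoothing is exactly normalized (rows
sum to 1) and strictly positive whenever the class has any training data.
Weights are log-odds against a background:

    W_ij = ln(P_ij / P_oj)

The background default is the pooled symbol frequency over every position
of both classes' training windows, smoothed the same way; `uniform`
(P_oj = 1/K) is available as a config option. The logarithm is natural;
tree ensembles are invariant to this positive scale factor, but the base is
fixed for reproducibility.

One matrix pair (positive-trained, negative-trained) is fit per channel.
Scoring concatenates, channel by channel in the fixed order WA, QS, DH, SS,
SA, the L positive-matrix lookups then the L negative-matrix lookups:
2L features per channel, 10L total, named `WA1…WA2L` … `SA1…SA2L`. For the
shipped window lengths this gives 70 (L=7), 90 (L=9), 110 (L=11) and 130
(L=13) features.

## Classifier

Gradient boosting (stage-wise additive trees,
F_m(x) = F_{m−1}(x) + ρ_m h_m(x)) via scikit-learn's
`GradientBoostingClassifier`. The tunable grid spans trees 1–500, minimum
node size 10–50, depth 3–9, shrinkage 0.01–0.1; the default grid is
{50,100,200,500} × {10,30,50} × {3,5,7,9} × {0.01,0.05,0.1}, searched by
stratified inner cross-validation on training data only and refit on the
full training set. Pipeline-scale runs (cross-validation over draws, the
independent test, the CLI) default to a single grid point — 200 trees,
depth 3, node size 10, shrinkage 0.1 — because a 144-point sweep inside
every fold of every draw adds cost without changing the structural
conclusions the package is validated on; pass a larger `GBMConfig` to
sweep. A score of exactly 0.5 classifies positive. Tuning is per ligand
(each profile is trained independently).

## Feature selection

Shadow-feature selection: each iteration appends a column-shuffled copy of
every feature, fits a random forest on the augmented matrix, and credits a
"hit" to every real feature whose importance exceeds the best shadow's.
After `max_iter` iterations (default 30) a two-sided binomial test on each
feature's hit count (null p = 0.5) at level `alpha` (default 0.01) declares
it confirmed (significantly above half) or rejected (significantly below);
unresolved features stay tentative, and the three lists always partition
the input. Constant features are auto-rejected up front with a warning.
The implementation is native and fully seeded rather than bound to an
external package, keeping the pipeline self-contained and deterministic.

## Evaluation protocol

Metrics from the confusion table: Sn, Sp, FPR = 100 − Sp, Acc (all
percentages) and MCC with the standard sum-form denominator
√((TP+FP)(TP+FN)(TN+FP)(TN+FN)); a zero denominator yields MCC = 0 with an
explicit flag instead of an error, so degenerate folds aggregate cleanly.
On any balanced set, Acc = (Sn+Sp)/2 exactly.

Class imbalance is handled by undersampling: a balanced dataset is all
positives plus an equal-count random negative sample, drawn 10 times by
default from independent seeded sub-streams, with metrics averaged over
draws. Cross-validation is stratified 5-fold at segment level (balancing
already operates on segments); a chain-level fold option is not provided,
but the independent test is split at **chain** level — round-half-up of
20% of chains held out — so no chain contributes windows to both sides.
The held-out side keeps its natural imbalance (MCC is the informative
number there); its metrics are averaged over the training draws.

Within every fold and draw, the position-weight matrices are refit from
that fold's training segments only; a structural leakage guard
(`assert_disjoint`) verifies train/test disjointness before any fitting and
records its passage in each result's provenance. Fitting matrices once on
the full dataset would leak test labels into the features.

## Synthetic data generator

The generator emulates the two class-conditional contrasts the method
relies on, with `effect_size` (d) as the single separation dial and d = 2
as the reference condition:

* amino-acid composition — binding residues sample from a distribution in
  which each typical coordinating residue (C, H, D, E by default) has its
  weight multiplied by e^d over a uniform background;
* RSA — binding residues draw from Beta(2, 8) (buried-shifted, mean 0.2),
  non-binding from Beta(2, 3) (mean 0.4); the positive parameters
  interpolate linearly toward the negative ones as d → 0, so d = 0 gives
  exactly exchangeable classes.

Secondary structure follows one first-order Markov chain for both classes
(it carries no signal). Chains default to 50 per corpus, 120–200 residues,
binding fraction 0.05 — about 400 positive windows, a desk-scale problem
size that keeps the full repeated-CV benchmark in tens of seconds.

By default residues are generated independently, so only the window's
center column differs between classes. Because the scoring matrices are
*positional*, the generator also has a **motif mode** that plants fixed
flanking residues around binding sites (C at offsets ±2, H at ±1), giving
the matrices genuine positional conservation to detect; flanks of adjacent
binding sites may overwrite each other. The package's standard
strong-signal benchmark (`strong_signal_config`) is the default corpus with
motif mode on; without positional structure the ceiling of the
center-column-only signal sits near the high 80s in balanced accuracy,
which is a property of that generator condition, not of the pipeline.

What the generator does **not** emulate: real amino-acid background
frequencies, sequence redundancy/homology between chains, coupling between
secondary structure, burial and binding, and BioLip-scale class ratios
(~1:60). Passing tests therefore demonstrate that the machinery is correct
and recovers planted signal of the assumed form — not that any particular
accuracy will transfer to real ligand data.

## Numerical and degenerate-case choices

* Mixture smoothing guarantees P_ij > 0; weight matrices are always finite.
* Probability-matrix rows are validated to sum to 1 within 1e-9.
* Duplicate FASTA headers, annotation gaps, aa mismatches, ss outside
  {H,E,C} and non-numeric RSA are hard errors naming chain and position.
* Non-standard residue letters map to `X` (logged), closing the alphabet
  rather than erroring — padding already requires the symbol.
* `balance_draws` refuses datasets with fewer negatives than positives
  (balancing is meaningless there) with an explanatory message.
* All randomness flows from integer seeds through `numpy` `SeedSequence`
  sub-streams; identical seeds give byte-identical corpora and identical
  chosen hyperparameters, draws and selection reports.

## Known limitations

* Real-data ingestion stops at FASTA + annotation TSV; obtaining binding
  labels and predicted SS/RSA for real proteins is out of scope.
* The hydrophobicity/charge groupings are sensible defaults, not a claim
  about the uniquely correct categorization; override via config when a
  specific table is required.
* The per-ligand `SA_V`/`SA_P` breakpoints shipped as defaults are the
  K⁺-derived regions; other ligands' distribution-specific breakpoints
  should be supplied per ligand via `sa_edges` when known.
* Comparison classifiers (SVM, random forest, neural nets) are not bundled;
  the feature matrices are plain DataFrames, so any scikit-learn estimator
  can be swapped in by the user.
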
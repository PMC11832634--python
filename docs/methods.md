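# Methods

This note documents the models, defaults and numerical choices behind
`tcassign`, and what the synthetic benchmarks do and do not demonstrate.

## Temperature coefficients

Chemical-shift-vs-temperature curves are close to linear over small
ranges but not exactly so, and coherent deviations can also come from
referencing drift between spectra.  `tcassign` therefore never fits a
single global slope: a temperature coefficient is always the
finite-difference slope over one interval,

    TC = 1000 * (delta(T_high) - delta(T_low)) / (T_high - T_low)   [ppb/K],

one per nucleus per consecutive temperature pair (for 5/10/15 °C data:
TC over 5–10 and over 10–15).  Degrees-Celsius differences equal kelvin
differences, so the unit is ppb/K; positive values mean downfield
movement on warming.  A shift missing at either end of an interval makes
that TC missing — it is never imputed.

Peak tracking between two temperatures is a one-to-one assignment that
first maximizes the number of matched peaks and then minimizes the total
cost Σ_d (Δδ_d / gate_d)², with pairs exceeding any per-dimension gate
forbidden (solved with the Hungarian algorithm; a greedy mode exists for
very large lists but is order-dependent and not optimal).  Default gates
are 0.05 ppm (Hᴺ) and 0.5 ppm (N and carbons): generous bounds on how far
an IDP peak moves over a 5 °C step.  When peaks on both sides carry
assignment labels for the same residue, the label overrides distance.

## The classifier

Residue typing is linear discriminant analysis: Gaussian classes with a
shared covariance, which makes the log-posterior linear in the features
and yields calibrated per-type probabilities via a softmax over the
discriminants.  Choices that matter:

- **Standardization.**  Features mix ppm and ppb/K scales; all are
  centered and scaled to unit variance over the pooled training set
  before fitting.  LDA decisions are affine-invariant at λ = 0, so this
  changes nothing mathematically but makes shrinkage meaningful across
  mixed units.
- **Pooled covariance.**  Σ = (1/(N−K)) Σ_k Σ_{i∈k} (x_i−μ_k)(x_i−μ_k)ᵀ.
- **Shrinkage.**  Σ_λ = (1−λ)Σ + λ·D with D = diag(Σ), default λ = 0.05.
  Same-protein training sets are small (often < 10 residues per type), so
  the off-diagonal part of Σ is noisy; mild diagonal shrinkage keeps the
  fit stable without changing well-conditioned problems much.  If a
  diagonal entry of Σ is zero (a feature with no within-class scatter, a
  degenerate case), it is floored at the standardized total variance 1 so
  that any λ > 0 gives a positive-definite matrix.
- **Priors.**  Uniform by default; a "sequence" mode sets π_k
  proportional to the type counts in the protein sequence (excluded types
  removed, renormalized) and a "training" mode uses training counts.
  Uniform is the neutral choice when the query set is not a random draw
  from the sequence (e.g. hand-picked ambiguous systems).
- **min_class_size = 3.**  A class needs ≥ 2 members to contribute
  within-class scatter; 3 adds one sample of margin.  Undersized classes
  are dropped with a warning and recorded on the model.
- **Class exclusion.**  Glycines (obvious from their N/Cα shifts and
  missing Cβ) and prolines (no amide proton, hence invisible in
  HN-rooted experiments) are excluded by default in the CLI; the library
  takes any exclusion list but requires ≥ 2 surviving classes.
- **Missing features.**  A query lacking features of the chosen subset is
  classified by refitting the LDA on exactly its observed features, using
  the training items complete for that reduced subset (cached per feature
  tuple).  This keeps every classification an exact LDA; marginalizing a
  Gaussian would be equivalent only with a shared global standardizer and
  is easier to get subtly wrong, and imputation would fabricate data.
- **Ties** in the ranking are broken by lexicographic class label, so
  results are deterministic.

Feature subsets (i)–(vi) combine the five backbone nuclei with zero, one
or two TC intervals; TC features are included for exactly the nuclei
whose shifts are in the subset (e.g. subset v = 5 shifts + 5 first-interval
TCs = 10 features).

Training from a per-type statistics table (means and sds per feature,
e.g. database-derived) builds the same model with a diagonal covariance
whose per-feature variance is the squared sd averaged over classes;
classes missing any required cell are dropped with a warning.

## Chain mapping

A chain of n sequential unknown systems placed at start s scores
Σ_i log p_i(type(s+i−1)): per-position classifications treated as
independent, no positional weighting.  This is deliberately the simplest
chain-level extension of per-residue typing; a sequence HMM or joint
assignment of all chains is out of scope.  Placements with a
zero-posterior position are inadmissible rather than floored (a
configurable floor exists for noisy posteriors).  Constraints only
filter, never re-weight: proline-flagged boundaries require a proline
immediately outside the chain, terminus flags require the sequence end,
and overlap with already-assigned positions is forbidden by default.
Normalized probabilities are exp(log-score) renormalized over the
admissible placements, computed via a max-shift for stability.

## Spin-system assembly

Roots are (Hᴺ, N) peaks; attached triple-resonance peaks within 0.02 ppm
(Hᴺ) and 0.2 ppm (N) of a root contribute their carbon shift, with the
experiment type deciding the nucleus (C′ from HNCO, Cα from HN(CO)CA,
Cα/Cβ pair from the CBCA-type experiment).  The Cα/Cβ pair is
disambiguated against the HN(CO)CA Cα value (tolerance 0.3 ppm); without
that reference a documented heuristic applies (values below 40 ppm cannot
be Cα; of two candidates in 40–70 ppm the larger is taken as Cα), which
is known to mis-order serine/threonine and is therefore only a fallback.
Competing candidates are recorded as conflicts with the nearest kept.  In
crowded spectra a neighbour's peak can fall within tolerance of a
glycine root and be stored as a spurious Cβ; true peaks always win the
nearest-match because they sit at the root's exact position.

## The synthetic generator

The generator emulates the study design the package targets: one protein,
triple-resonance peak lists at 5/10/15 °C, a labeled (assigned) part used
for training and an unlabeled part to classify and map.

- Per-type features are Gaussian: the shipped statistics table holds
  synthetic, roughly random-coil-like shift means with within-type sds of
  0.10 ppm (Hᴺ), 0.8 ppm (N) and 0.4 ppm (C′/Cα/Cβ), and per-type TC
  means drawn once (fixed internal seed, so the table is a constant)
  around −7 (Hᴺ), −3 (N), −1 (C′) and −0.5 (Cα/Cβ) ppb/K with
  between-type spreads of 1.5/1.5/0.5 ppb/K and within-type sds of
  0.5/0.8/0.3 ppb/K.  These are modelling choices, not literature values.
- Shift(T) is piecewise linear with the drawn per-interval TCs (equal
  across intervals by default; optionally independent), so interval
  slopes computed from the data recover the latent TCs exactly at zero
  noise.  Measurement noise defaults to zero: the within-type sds already
  absorb realistic measurement scatter, and a closed measurement loop is
  what makes the tracking and TC machinery testable bit-exactly.
- Prolines produce no HN-rooted system; glycines have no Cβ; per-nucleus
  missingness (default 0) removes a nucleus's shifts and hence its TCs.
- The default 239-residue benchmark sequence carries 26 prolines and 28
  glycines (a proline/glycine-rich disordered construct) and a
  near-balanced multiset of the other 18 types, so every classifiable
  type has enough residues to train on.  The train/query split is
  stratified by type (per-type rounding of the training fraction) for the
  same reason.
- The shift-degenerate benchmark (`benchmark_statistics`) overwrites the
  shift rows of one member of each chosen pair — by default (E, Q) and
  (F, Y), the two most nearly degenerate pairs in the synthetic table —
  and separates the pair's TC means by 3 within-type sds per nucleus.
  Accuracy there is measured with 30 training and 10 held-out systems per
  class over 20 replicates.

What passing these benchmarks shows: the statistical machinery (tracking,
TC computation, LDA, subset refits, placement ranking) is correct and the
TC information gain works as designed when class-conditional
distributions are Gaussian and stationary.  What it does not show:
performance on real spectra, where peak overlap, exchange broadening,
non-Gaussian tails, assembly errors and temperature-dependent referencing
all degrade the features; real-data validation needs deposited peak
lists and is outside the test suite.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: 200 random classifier
instances (≤ 10 features, ≤ 18 classes) against a brute-force
Gaussian-Bayes oracle (tolerance 1e-8), 500 random ≤ 6-peak matching
instances against exhaustive enumeration, a 150-residue protein for the
TC closed loop (tolerance 1e-9), 20 replicates of the 18-class
degenerate-pair benchmark, and 100 sampled chains of length 3–6 on a
239-residue protein for mapping recovery.  All randomness flows through
explicit integer seeds (`numpy.random.default_rng`); the acceptance
script derives independent substream seeds from its single `--seed` via
`SeedSequence`.

## Known limitations

- Sequential linking (building chains from Cα/Cβ matching) is not
  implemented; chains are inputs.
- The chain score assumes independent per-position posteriors; correlated
  errors (e.g. a systematic referencing offset) violate this.
- The CA/CB fallback heuristic mis-orders Ser/Thr without an HN(CO)CA
  reference.
- Statistics-table training supports only diagonal covariances (a table
  carries no feature correlations).
- The Sparky reader targets the common whitespace export (assignment
  column + one shift column per dimension, optional height).
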
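# Methods

## Problem and scope

`premirscan` detects pre-miRNA hairpins *ab initio*: given only a
nucleotide sequence (a candidate hairpin, or a whole genome), it decides
whether the sequence looks like a microRNA precursor — a stem-loop with
the sequence, structural and thermodynamic signature of real pre-miRNAs —
without using homology or expression evidence. The package implements the
complete workflow: secondary-structure prediction, feature extraction,
balanced Monte-Carlo cross-validated training of per-study classifiers,
consensus/ensemble prediction, rank-based multi-data-set evaluation, and a
sliding-window genome scanner. A synthetic-data module generates every
input the workflows need, so the whole stack builds and tests offline.

## Secondary-structure backends

Two backends share one interface. The default **fallback** is a
Nussinov-style maximum base-pairing dynamic program with:

* allowed pairs {AU, UA, GC, CG, GU, UG};
* minimum terminal loop of 3 unpaired nucleotides;
* deterministic traceback — pairing position *i* with the smallest
  admissible partner is preferred over leaving *i* unpaired, which makes
  folds reproducible byte-for-byte;
* surrogate energy = −(number of base pairs), flagged as a surrogate in
  every result and in the feature schema.

The fallback exists so that structure prediction, hairpin extraction and
structural features never require an external binary. It is *not* a
thermodynamic model: stacking, loop penalties and dangles are ignored, so
its structures have more, shorter helices than an MFE folder would
produce. Tests exploit only the properties it does guarantee (maximum
pairing, loop constraint, determinism), verified against an exhaustive
structure enumeration oracle for sequences up to 14 nt. When the ViennaRNA
`RNAfold` executable is on `PATH`, the **rnafold** backend supplies true
MFE structures with kcal/mol energies; the backend id is recorded in
provenance because structures and thermodynamic features are
backend-dependent.

Suboptimal structures (for the NotBestFold constructor) are produced under
the fallback by re-folding with each optimal-structure pair individually
forbidden and ranking the distinct alternatives by pair count. Full
enumeration of all structures at one pair below the optimum is exponential
in sequence length, so constraint re-folding is used at all lengths; on
short sequences it reproduces what enumeration gives. The thermodynamic
backend delegates to `RNAsubopt`.

The O(n³) DP fill is JIT-compiled with numba when available (a pure-Python
fill is the fallback path); this is what makes folding 500-nt genome
fragments practical.

## Feature registry

73 features in four families, all computed from (sequence, structure,
energy):

* **SEQ** (22): mononucleotide and overlapping dinucleotide frequencies,
  GC fraction, length.
* **TRIPLET** (32): the classic local descriptor — paired/unpaired status
  of three consecutive positions (brackets collapsed to one paired
  symbol) × the centre nucleotide, frequencies normalised by L−2.
* **STRUCT** (13): base-pair count, paired fraction, pair density
  n_bp/L, terminal-loop length, longest stacked-pair run, stem count
  (maximal runs of ≥ 3 consecutive pairs), loop count (maximal unpaired
  runs), AU/GC/GU pair counts and fractions.
* **THERMO** (6): MFE, dG = MFE/L, and the MFEI family
  (MFEI1 = dG/GC% with GC content as a *percentage*, MFEI2 = dG/n_stems,
  MFEI3 = dG/n_loops, MFEI4 = MFE/n_bp). Zero denominators yield 0, and
  the guard is stated in the schema description.

Two probability-family features (mean base-pair probability, positional
entropy) are registered but require a partition-function-capable backend;
requesting them under the shipped backends raises a capability error
rather than silently producing zeros.

The 13 published detection approaches are represented as **study
profiles**: named, ordered selections from the registry with the study's
declared feature count as metadata. The triplet-only selection is an exact
reconstruction; the others are documented approximations (the original
per-study feature lists are not fully recoverable from the literature
survey alone), and `StudyProfile.count_matches` reports whether the
reconstruction size matches the declared count.

## Data-set construction

* **Shuffled** — per-sequence residue permutation (seeded Fisher–Yates).
  The mononucleotide multiset is preserved exactly; a
  dinucleotide-preserving Eulerian-walk shuffle is available as an option
  (`preserve_dinucleotides=True`), since either reading of "shuffling" is
  defensible and they differ for structure-sensitive features.
* **NotBestFold** — sequences unchanged, structures replaced by the best
  suboptimal fold; records with no alternative structure are skipped and
  logged in provenance.
* **FR / BQ / AM** — synthetic sets sampled directly in feature space:
  per feature, values drawn independently and uniformly between the
  min–max, lower–upper quartile, or 40th–60th percentile of an input
  feature matrix; 5000 rows by default. One quantile estimator (linear
  interpolation between order statistics) is shared package-wide because
  quartiles differ across estimators.
* Filters: length within [36, 180] inclusive (the observed span of human
  stem-loops), duplicate-sequence removal keeping the first occurrence,
  and an RPM ≥ 100 expression filter for records carrying read counts.

Every constructed set carries a provenance log (operation, parameters,
seed) sufficient to regenerate it bit-identically.

## Training

Balanced Monte-Carlo cross-validation: at each iteration, 70 % of the
positives and an equal number of negatives (sampled without replacement)
train the classifier; the remaining 30 % of positives plus an equal number
of fresh negatives test it. Train and test never share a record. The split
depends only on (seed, iteration) — substreams are derived by counter —
so every study profile and classifier kind sees identical data at a given
iteration and their scores are directly comparable. Eight measures are
recorded per iteration (recall, precision, sensitivity, specificity,
F-measure, accuracy, Cohen's kappa, Youden's index) together with the raw
confusion counts. The best model per (study, classifier) is the one with
the highest test accuracy; ties break by F-measure, then by earlier
iteration. Classifiers are scikit-learn's decision tree, Gaussian naive
Bayes and SVC with library-default hyperparameters, recorded verbatim in
model provenance. DT and NB are the default prediction pair; SVM models
are persisted like any other.

The modelling surface is Model/Results: `MCCV(...).fit()` returns an
`MCCVResults` with the full metric distributions, best models, failure log
and a `summary()` table; `save_bundle`/`load_bundle` persist the best
models with schema and provenance in a versioned envelope.

## Ensemble prediction

Six schemes over the per-study scores (all scores are positive-class
probabilities in [0, 1]):

* `Consensus_DT`/`Consensus_NB`: majority vote, *miRNA* iff ≥ 7 of the 13
  studies vote positive.
* `Average_DT`/`Average_NB`: mean score, *negative* iff mean < 0.5
  (exactly 0.5 is *miRNA*).
* `ConsensusRule`: *miRNA* if either average > 0.89; else *negative* if
  either average < 0.5; else *candidate*. Both inequalities are strict.
  When both clauses fire simultaneously (one average above 0.89, the
  other below 0.5) the miRNA clause wins by clause order, and the
  decision is flagged `rule_conflict` for audit.
* `ConsensusModel`: an MLP meta-classifier on the score vectors, trained
  with the same balanced Monte-Carlo scheme and selected by accuracy then
  F-measure. Architecture: one hidden layer as wide as the input, early
  stopping, fixed seed. The learning rate (0.05) and early-stopping
  patience (50) are raised above the library defaults: on [0, 1]-scaled
  score inputs at a few hundred samples the default step size plateaus
  the validation score before the loss moves, and the optimiser stops in
  the trivial all-positive state.

Evaluation utilities: TPR/TNR as percent-correct on single-label sets;
per-data-set fractional ranking (average ranks under ties; min-rank
optional) summed into a total rank treating every data set equally; ROC
curves over the full threshold sweep with tied scores grouped, and AUC by
the trapezoidal rule (equal to the Mann–Whitney pair-concordance
statistic, which the tests verify independently). Confidence thresholds
for genome scanning derive from the lower quartile of the scores a
positive control set receives.

## Genome scanning

Chromosomes are cut into 500-nt windows every 250 nt; a trailing fragment
shorter than the window is kept when it is at least the minimum hairpin
length, so chromosome ends stay visible. Every fragment start at a step
multiple is emitted, which makes interior positions covered by two
windows; the redundant suffix hairpins this produces are removed by the
genome-wide duplicate filter. Both strands are folded (T→U; reverse
complement for the template strand). Stem-loop elements are extracted
from each fold: every terminal loop of ≥ 3 unpaired bases is extended
outward through its enclosing helix — across bulges and internal loops —
until the structure branches or ends, and the element is kept if the
extended stem contains ≥ 3 strictly consecutive pairs. Candidates are
length-filtered to [36, 180], deduplicated genome-wide by sequence
(first locus by (chrom, start, strand) kept; duplicate loci listed in the
summary), featurised, scored by the model bundle, labelled by the
ensemble rules, and reported with 0-based half-open BED coordinates.

## Synthetic data

The generators define the study conditions for all tests:

* **Designed stem-loops**: 20-bp GC-only stems with a 6-nt all-A loop
  (46 nt — within the length filter). A GC-only stem folds unambiguously
  under maximum pairing and an A-loop cannot self-pair, so positives are
  guaranteed extractable. Negatives are per-record shuffles: identical
  composition, destroyed complementarity.
* **Separable feature clouds**: unit-variance Gaussians whose means
  differ by `separation` pooled SDs per feature (default 4 — cleanly
  separable; 0 — the no-signal null). Default 10 features.
* **Synthetic genome**: 10 kb uniform-composition chromosome (optional GC
  bias) with 5 planted hairpins at non-overlapping random loci on random
  strands, plus truth intervals in BED form.

What the synthetic data does **not** emulate: real pre-miRNAs have
imperfect stems with bulges and mismatched pairs, biased dinucleotide
composition and a continuum of folding stability; real negatives
(pseudo-hairpins from coding regions) are much harder to separate than
shuffles or Gaussian nulls. Passing tests therefore demonstrate that the
machinery is correct — folding matches its oracle, splits are balanced
and fair, the rules implement their stated boundaries, planted structure
is recovered — not that the shipped profiles reach any particular
accuracy on biological data. Training on real positive/negative sets is
exactly what the loaders and the CLI support, but no biological data is
bundled.

## Numerical and design choices

* Sequence normalisation: uppercase, T→U; ambiguity codes rejected by
  default, with an explicit opt-in policy mapping them to A.
* One quantile estimator everywhere (linear interpolation), so data-set
  quartiles and scan thresholds agree by construction.
* All randomness flows from a single master seed; per-iteration
  substreams are derived by counter so any iteration is reproducible in
  isolation.
* Problem sizes in the test and acceptance workflows (1000-hairpin
  shuffle checks, 30-iteration MCCV runs at n = 1000 per class,
  5-iteration training of the 13-study bundle for the scan, a 10-kb
  planted genome) are chosen so the full verification cycle runs on a
  laptop-class single core in minutes while still exercising every
  contract at realistic dimensionality.
* The fragmentation rule keeps trailing sub-window fragments; the
  alternative (dropping them) blinds the scanner to chromosome ends.
* Model files are joblib envelopes with a JSON header (schema version,
  feature names, metrics, provenance); prediction refuses matrices whose
  column names or order differ from the training schema.

## Known limitations

* The fallback folder's surrogate energies make thermodynamic features
  ordinal rather than physical; mixing backends between training and
  prediction is unsupported (schema provenance records the backend).
* Study profiles are reconstructions, not the original feature code; the
  declared counts are metadata, not a fidelity claim.
* No partition-function features, no pseudoknots, no homology or
  read-mapping evidence, no similarity clustering of scan output (an
  external tool can consume the candidate FASTA for that).
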
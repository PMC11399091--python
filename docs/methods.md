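# Methods

This note documents the statistical procedures quantcore implements, the
conventions and defaults it fixes where the underlying methods leave choices
open, what the synthetic-data generator does and does not emulate, and the
known limitations.

## Scope and data model

quantcore operates entirely on tabular abstractions of a proteomics
experiment: per-engine PSM tables (spectrum reference, peptide, charge,
score, decoy flag, protein accessions, optional precursor intensity), SDRF
experimental-design files, FASTA sequence databases, reporter-ion intensity
matrices, and per-dataset protein/q-value lists.  Everything upstream of
these tables — spectrum processing, database search, feature detection,
retention-time alignment, match-between-runs — is out of scope by design.

## Experimental design (SDRF)

SDRF headers are matched case-insensitively after whitespace normalization.
The required minimum is a `source name` column and one `comment[... data
file ...]` column; everything else is optional with defaults (fraction 1,
technical replicate 1, label "label free sample").  Conditions are the
`factor value[...]` cells joined with `.` in column order — deterministic
and reversible; when no factor column exists the source name stands in.
Biological replicates come from a `characteristics[biological replicate]`
column when present, otherwise each distinct sample receives its own index.
Conflicting factor values across fractions of one sample are rejected rather
than reconciled.  Isobaric labelling schemes are recognised by a channel-set
subset test over the canonical channel tables (iTRAQ 4/8, TMT 6/10/11/16),
preferring the smallest consistent plex so that a plain `TMT126..TMT131` set
resolves to TMT6 and only N/C-split channels force TMT10 and larger.
Acquisition routing: any TMT/iTRAQ label forces the isobaric branch, a
"data-independent" acquisition annotation forces the DIA branch (routing
only), and a run carrying both is an error.

## PSM scoring

**Mixture model.** Scores are modelled as a two-component Gaussian mixture.
EM runs on the target scores only; decoy scores are held out and used to
initialise the incorrect component's mean and variance (the correct
component starts from the upper half of the target scores, mixing weight
0.5).  Including decoys in the likelihood would inflate the incorrect-
component weight, whereas the target population is exactly the mixture the
PEP refers to.  Convergence tolerance is 1e-6 on the log-likelihood, at most
1000 iterations; the log-likelihood is monotone non-decreasing by
construction and this is asserted in the tests.  PEPs are clamped to
[1e-10, 1].  An optional log transform handles right-skewed score scales.

**Consensus.** Candidate peptides for one spectrum are pooled across
engines; a candidate's combined PEP is the arithmetic mean of its per-engine
PEPs over the engines that reported at least one candidate for that
spectrum, with a missing candidate contributing PEP = 1 (maximally
uncertain — a deliberately conservative penalty).  The lowest combined PEP
wins; ties break lexicographically by peptide so output is byte-stable.
This is the similarity-free "average PEP" consensus variant: it needs no
sequence-similarity matrix and is fully deterministic.

**q-values.** FDR at a threshold is `#decoys at-or-above / #targets
at-or-above`, capped at 1, with tied scores sharing the counts of the full
tie block; q-values are the cumulative minimum scanning from the worst score
upward.  The ratio is deliberately D/T (not (D+1)/T).  Peptide-level
q-values collapse PSMs to one best record per modified sequence (lowest PEP,
then higher charge, then lexicographic spectrum reference) before the same
procedure.  Identification filtering uses q ≤ α with α = 0.01 by default.

## Protein inference and picked FDR

Accessions with identical peptide sets are indistinguishable and merge into
one group.  The group score is the minimum peptide PEP (best-peptide
aggregation).  A peptide shared between groups scores every containing group
but is "unique" to none; quantification requires at least two unique
peptides, applied per dataset with all runs pooled.  Picked protein FDR
pairs each target group with its decoy counterpart by stripping the decoy
prefix (`DECOY_` by default) from the accessions; only the better-scoring
member of a pair survives (the target wins ties), unpaired groups survive
unconditionally, and standard target-decoy q-values are computed on the
survivors.  Decoy PSMs are passed through the peptide-level filter so the
protein competition retains its decoy population.

The picked estimator is essentially exact when true proteins score far above
the null (the decoy of a true protein then never survives); at moderate
separation it turns mildly conservative because decoys that beat true
targets survive with no false-target counterpart.  The calibration study in
the test suite therefore uses well-separated true proteins (score separation
6 SD, 6,000 true / 3,000 false targets with paired null decoys), the regime
the estimator is designed for; at smaller separations the bias direction is
conservative, never anti-conservative.

## Quantification

Spectral counts and summed intensities use unique peptides only; fractions
of one sample are summed before aggregation, and a group-sample with no
observed unique-peptide intensity is missing, not zero.  IBAQ divides the
summed intensity by the theoretical peptide count of the group's
representative (first) accession.  The digestion convention is trypsin,
zero missed cleavages, cleavage after K/R but not before P, peptide length
6–30 — the dominant IBAQ convention, exposed as parameters.  riBAQ
(per-sample normalized IBAQ) and log10 IBAQ are derived columns.

Reporter-ion impurity correction solves the channel-impurity linear system
`M x = observed` directly and clips negative components to zero — cheaper
than non-negative least squares and standard practice; matrices with
condition number ≥ 1e8 are rejected.  Within-run normalization equalizes
channel medians by scaling every channel down to the smallest channel
median (factors reported; an all-missing channel keeps factor 1 with a
warning).

## Cross-dataset merging with stand-in decoys

Targets are sorted ascending by nominal q; after the k-th target the
cumulative stand-in decoy count is brought up to `d_k = round_half_up(q_k·k)`
(each decoy carries the target's nominal q), so the decoy/target ratio at
every rank deviates from the nominal q by at most 0.5/k.  Round-half-up is
chosen because it is deterministic and monotone; a 1e-12 guard absorbs
binary-float droop at exact halves.  Merging keeps each target's lowest-q
observation with provenance while every stand-in decoy is retained — each
decoy encodes its source dataset's uncertainty, and deduplicating decoys
would shrink the decoy count anti-conservatively.  Re-estimation assigns
each target the ratio of decoys to targets with nominal q as good or better
(ties count on both sides), capped at 1, monotonized by the standard
worst-to-best cumulative minimum (a `monotonize=False` switch exposes the
raw ratios).  The final build keeps targets with adjusted q strictly below
the threshold (default 0.01); per-dataset identification filters elsewhere
use ≤.  The injection is neutral: it transports nominal q-values into
countable form without improving or worsening their calibration, which the
tests verify on calibrated synthetic inputs.

Expression profiles over the merged build report, per accession and sample
class, the number of datasets observed and the median and unscaled MAD of
log10 IBAQ.

## Formats

The mzTab writer emits a documented subset of mzTab 1.0 (MTD block with
version/mode/type first, then PRT/PEP/PSM sections with their own headers);
columns outside the 1.0 core use the `opt_` prefix rather than new
controlled-vocabulary terms.  Missing values are the literal `null`, floats
are formatted `%.6g`, and row order is fixed (proteins by accession,
peptides by sequence, PSMs by spectrum reference), so identical inputs give
byte-identical files and `read_mztab` is the exact inverse of `write_mztab`.
The MSstats export is the canonical ten-column table; the isobaric dialect
replaces `IsotopeLabelType` with `Channel`.  The Triqler export maps
`searchScore = 1 − PEP` and drops decoys by default.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, not
raw mass spectra:

* **Sequences** are concatenations of tryptic blocks with no proline and no
  internal K/R, so the theoretical digest count equals the block count
  exactly — quantities that depend on the digest are checkable without
  approximation.  Real sequences have missed-cleavage ambiguity the
  generator deliberately avoids.
* **Scores.** Correct PSMs draw from N(Δ, 1) and incorrect/decoy PSMs from
  N(0, 1) (Δ = 3.5 by default, a typical well-separated search); the
  engines of one PSM share a latent normal with loading √ρ, giving pairwise
  correlation ρ (0.5 by default).  Incorrect target PSMs and decoy PSMs are
  generated in equal numbers (0.4 per correct PSM by default) so decoy
  counting estimates the false-match rate among targets.
* **Abundances** are log10-normal across proteins (μ = 2.5, σ = 1.0);
  peptide intensities scatter around the protein abundance with log10
  measurement noise σ = 0.2 and 10% missing-at-random dropout.  Detected
  peptides are a beta-binomial thinning of the theoretical digest (mean 5
  peptides per present protein).
* **Protein q-lists** for merge studies sample true proteins from a shared
  universe (true hits replicate across datasets) while false hits get
  dataset-unique accessions, since spurious identifications rarely recur
  across independent datasets.  Nominal q-values are the oracle tail FDR of
  the generating score mixture — a well-calibrated upstream procedure,
  which is the premise of the neutrality property.  Feeding the merge
  miscalibrated inputs shifts its output by exactly the input bias.

Passing tests on this generator demonstrate the statistical correctness of
the procedures under their stated assumptions; they do not demonstrate
robustness to the pathologies of real data (correlated noise, shared-peptide
networks, systematic missingness, score distributions far from Gaussian).

## Study sizes and numerical conventions

Calibration studies pool discoveries over replicates and compare the
realized false-discovery proportion to the central 95% binomial interval at
the nominal level: PSM level, 100 runs of 3,500 correct / 750 incorrect /
750 decoy PSMs at Δ = 3; picked-protein level, 100 datasets of 6,000 true /
3,000 false targets at Δ = 6; merged build, 200 replicates of three datasets
with 500–2,000 proteins each.  The consensus-gain study uses 25 paired
replicates of a 3-engine design at ρ = 0.5.  Oracle-agreement checks use
1,000 random instances per estimator with up to 200 records and heavy score
ties.  All randomness flows from explicit integer seeds; EM uses tolerance
1e-6, mixture variances are floored at 1e-6 (SD 1e-3), and FDR ratios are
exact rational arithmetic in floating point (no smoothing).

## Known limitations

* Protein inference implements indistinguishability grouping only — no
  parsimony set cover, no subset/subsumable classification, no Bayesian
  scoring.
* The consensus combiner assumes engine PEPs are comparable in scale; it
  does not model engine-specific score reliability.
* Isobaric quantification operates on provided reporter tables; MS2 vs MS3
  extraction and precursor-interference correction are out of scope.
* The stand-in decoy device inherits whatever calibration the per-dataset
  q-values have; it cannot repair miscalibrated inputs.
* The mzTab dialect is a subset; documents from other producers parse only
  if they restrict themselves to the same section/column discipline.
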
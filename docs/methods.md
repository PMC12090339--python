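# Methods

## Scope and model

`fretlearn` treats directed evolution of an enzyme as batch Bayesian
optimization over a small combinatorial sequence space.  A *region* is a set
of P mutable residues (here P = 3, two standard regions: A = 167/169/172
with wild type HLF, B = 217/218/219 with wild type LQE); a *variant* is an
assignment of amino acids to those residues, so the space holds 20³ = 8000
sequences.  Fitness is defined operationally as the initial rate of
substrate cleavage at fixed substrate concentration, normalized to the
wild-type rate, so WT ≡ 1 by construction and a fitness of 4 means
four-fold faster initial cleavage.

## FRET-kinetics scoring

Protease activity is read from a FRET substrate: cleavage separates donor
and acceptor, raising donor (480 nm) emission relative to acceptor (520 nm)
under 430 nm excitation.  For each well,

    ratio(t) = (F480(t) − B480(t)) / (F520(t) − B520(t)),

with B the per-timepoint mean over water-blank wells.  Scoring then:

1. truncates the trace strictly before the first timepoint whose ratio
   reaches the threshold (default 0.55) — the *first-crossing* rule, so a
   noisy dip back below threshold cannot re-admit late, curved points;
2. fits an ordinary least-squares line (free intercept) to each replicate's
   truncated trace; the slope (ratio units/min) estimates the initial rate;
3. normalizes every slope by the WT mean slope and averages over replicates
   (mean ± SD, typically triplicate).

Negative normalized means are clipped to 0 (enzymes have no negative
activity; noise-only wells should score ≈ 0) with the raw slope retained
and a flag recorded.  Replicates whose truncated trace has fewer than two
points (traces starting above threshold) are dropped with a flag.  A free
intercept is used rather than anchoring the line at the first observed
point; the truncation threshold and WT identity are configurable.

**Curvature bias.** Because the ratio follows a saturating curve, an OLS
slope over any finite window underestimates the instantaneous initial rate.
For variants fast enough to cross the threshold during the assay, the
fitted window always spans the same ratio range as WT's, so the bias
cancels in the WT-normalized fitness to within about 1 %.  Variants too
slow to cross (fitness below ≈ 0.5 under default kinetics) are fit over
their full, shallower trace and are *over*-estimated by up to ≈ 6 %.
Rankings are unaffected (the map from true rate to fitted slope is strictly
monotone in the noiseless model), and the 5 % noiseless-recovery guarantee
asserted in the tests applies to the crossing regime the truncation rule is
designed for.

## Surrogate: bootstrapped ensemble as a posterior

Variants are one-hot encoded (20·P binary features, position-major; no
physicochemical information).  The surrogate is an ensemble of k = 5
feed-forward networks, each trained on a random 90 % subsample of the
training data, drawn without replacement and seeded; member i of an
ensemble fit on n records sees floor(0.9·n) rows (44 of the 49 in a
standard first round).  The spread of member predictions stands in for
posterior uncertainty, and a uniformly drawn member is one posterior
sample.

Each member is an MLP with two hidden layers of 32 ReLU units, squared
error loss, trained by L-BFGS with L2 weight decay α = 2×10⁻³.  Full-batch
L-BFGS is the right optimizer at this data scale (tens of records):
stochastic optimizers underfit badly here.  The weight decay is set at the
value that keeps both halves of the ensemble contract healthy — small
enough that members trained on different subsamples still disagree far
from the data (posterior SD at Hamming-distance-3 variants exceeds SD at
training points, averaged over seeds), large enough that predictions on
the ~7950 unmeasured sequences stay in the observed fitness range (on
constant-fitness data every member predicts that constant to within 0.05
over the whole space).  Inputs are binary and targets are already on the
normalized-fitness scale, so no feature or target standardization is
applied.  Inactive (fitness 0) records are kept: a mostly-dead region's
zeros carry real information.  The ensemble class follows the scikit-learn
estimator API and accepts any fit/predict regressor as member prototype.

## Acquisition

Thompson sampling over the enumerated space: for each of the B batch slots,
draw one member uniformly and take the argmax of its prediction over
candidates not yet measured and not already in the batch.  No refit happens
mid-batch — no interim fitness data exists until the whole batch is
assayed — and no hallucinated-observation conditioning is used.  Ties break
toward the lowest enumeration index, so a batch is fully determined by the
sequence of member draws; the member index and predicted fitness behind
each slot are logged for auditability.  The exclusion set contains all
previously measured variants plus the wild type.  A uniform `random_batch`
policy is provided as the baseline for policy-value comparisons.

## Campaign orchestration

Round 1 draws the random library (48 distinct variants by default;
duplicates and the WT triple are redrawn).  Every later round fits the
ensemble on all accumulated records (WT included once with fitness 1) and
proposes the next batch by Thompson sampling.  The canonical replay runs
region A with rounds [48, 10] on a sparse landscape and region B with
[48, 32] on a dense one: 138 measured variants in total, WT uncounted since
it appears on every plate as the normalizer.  Round summaries report mean,
max and SD of fitness plus the fraction of variants with fitness above an
activity threshold (default 0.05 — "active" is operationally any clearly
nonzero rate; the value is configurable and only summaries depend on it).
All randomness flows from a single config seed through a seed tree, so a
completed simulated campaign replays bit-for-bit; artifacts (proposals,
plates, scores, serialized model, summaries) are written one directory per
round.

## Synthetic landscapes

Ground truth is a Potts-like score: per-position fields h_p(a) ~
N(0, 1) plus pairwise couplings J_pq(a, b) ~ N(0, 0.15) (couplings
deliberately weaker than fields: epistasis modulates an additive backbone
rather than drowning it, keeping 49-point learning meaningful while still
requiring simultaneous mutagenesis).  Kinds:

* **sparse** (region-A-like): scores below the 90th percentile (the gate,
  configurable down to 75 %) are set to exactly 0; the WT score is pinned
  at the 98th percentile of the raw distribution so the wild type is active
  and near-optimal in an otherwise mostly-dead space.
* **dense** (region-B-like): scores are shifted so every variant keeps some
  activity, and WT is pinned at the 95th percentile, so ~5 % of the space
  beats the wild type.
* **additive**: couplings zeroed; used as a fully checkable reference.

All kinds are rescaled so WT fitness is exactly 1.  Pinning WT to a fixed
quantile, rather than leaving it at a random draw, makes the qualitative
regimes ("WT near-optimal" vs "WT beatable") hold for every seed instead of
on average.

## Simulated plates

A variant with true fitness f produces the noiseless ratio

    r(t) = r0 + (rmax − r0)(1 − exp(−κ f t)),

a first-order approach to plateau (first-order cleavage at fixed substrate),
with initial slope (rmax − r0)·κ·f — proportional to fitness, which is the
assumption initial-rate scoring rests on.  The two channels are realized as
F520 = blank + S/(1+r) + ε and F480 = blank + S·r/(1+r) + ε with ε ~
N(0, σ) i.i.d. per channel and timepoint; blank wells carry blank + ε.  Any
two-channel decomposition whose blank-subtracted quotient equals r would do;
this one conserves total signal S.

Defaults (all configurable via `KineticParams`): r0 = 0.40, rmax = 0.90,
κ = 0.012 min⁻¹ (WT crosses the 0.55 threshold near minute 30 of a
60-minute assay read every minute), S = 1000 AU, blank = 50 AU, triplicate
wells, 4 blank wells.  The channel noise σ = 10 AU was calibrated by
simulation so that the WT replicate-to-replicate fitness SD is ≈ 0.1,
matching the magnitude of typical triplicate error bars in this kind of
screen; note the noise interacts with truncation (noisy traces cross the
threshold earlier), so this calibration was done empirically rather than
from the linear error-propagation formula, which suggests a larger σ.

**What the simulator does not model:** expression-level variability between
cell-free reactions, gain calibration, edge/evaporation effects, drift and
photobleaching, and any real protease biochemistry.  Passing in-silico
campaign tests therefore shows the *decision loop* works under the stated
statistical structure (triplicates, monotone saturating traces, additive
channel noise, sparse-vs-dense landscape contrast) — not that any
particular wet-lab fitness value would be reproduced.

## Numerical and design choices

* Alphabet order is fixed alphabetical (ACDEFGHIKLMNPQRSTVWY); enumeration
  is lexicographic position-major.  Any fixed order is valid; one is pinned
  so enumeration indices, tie-breaks and one-hot layouts are reproducible.
* Random libraries exclude the WT triple from the draw (it is appended to
  training sets explicitly); libraries are deduplicated by rejection.
* Bootstrap rounding is floor(0.9·n); subsampling is without replacement.
* Non-positive blank-subtracted 520 nm signals mask single timepoints with
  a warning; an all-masked well is unscorable and flagged.
* Problem sizes in tests and the acceptance script match the study design:
  48-variant first rounds, 49-record ensemble fits, 10/32-variant proposal
  batches over the 8000-variant space, 20-seed batteries for the
  statistical properties.

## Known limitations

* Ensembles are serialized with pickle; run directories are therefore not
  portable across library versions (the JSON sidecar records the config).
* The uncertainty of a 5-member bootstrap is a coarse posterior; it is
  sufficient for Thompson sampling but not calibrated in the
  frequentist-coverage sense.
* Landscape "difficulty" (field/coupling scales, gate fraction) is a model
  choice; real epistasis need not be Potts-like.
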
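# Methods

## Diary model and MET scoring

A diary day is a set of timed activity entries over half-open minute
intervals `[start_min, end_min)`, 0-based minutes since midnight.  The
half-open convention makes adjacent bouts non-overlapping and coverage
arithmetic exact.  Bouts are multiples of 5 min (minimal bout 5 min); a
valid day has every one of the 1440 minutes covered by one or two entries.
Validation (`validate_diary`) returns violations as data — gap and overlap
intervals, off-grid bouts, unknown codes, mis-parameterised entries —
rather than raising, so a caller can report all defects at once; scoring an
unvalidated diary is a contract error, and the CLI exits nonzero on any
violation.

Each catalog activity is scored in exactly one mode:

* plain: a single MET value;
* effort-ranked: separate MET values for light/medium/hard effort,
  constrained nondecreasing.  Distinct compendium entries per intensity are
  used rather than multipliers, because the Ainsworth compendium lists
  separate entries per intensity;
* posture-adjustable: MET = f·MET_standing + (1−f)·MET_sitting for
  standing fraction f ∈ [0, 1] — a time-weighted average of the two
  postural states (the instrument collects the ratio on a 0–100% scale but
  no combination rule is standard; the linear rule is the natural
  time-share interpretation).

Where two entries cover the same minute, the minute's MET is their maximum
by default (`overlap_rule="max"`: the dominant activity determines the
minute's intensity); a `mean` rule is available.  Per-minute METs are
classified sedentary (MET ≤ 1.5), light (1.5 < MET < 3.0) or
moderate-to-vigorous (MET ≥ 3.0).  The sedentary boundary is *inclusive*
at 1.5 — the convention governing the tabulated analyses this package
mirrors, although "< 1.5" also circulates; the choice moves only minutes
at exactly 1.5 MET.  The 24-h average MET is the arithmetic mean over all
1440 minutes (not waking minutes only).

The bundled `demo_catalog()` is a ~35-activity demonstration fixture
spanning all 13 activity categories, with MET values sourced from the
public Ainsworth compendium; any user catalog in the documented CSV
dialect may be substituted.

## Accelerometer reduction

Counts are ingested from a plain-text CSV (one counts column, interpreted
as vertical-axis counts — the scale on which the Freedson/Matthews
cut-points are defined) with a constant epoch length dividing 60 s and a
contiguous timestamp sequence.  The recall day is selected by explicit
date, never inferred.  Counts per minute are the sum of the minute's
epochs; a minute containing *any* non-wear epoch is wholly non-wear, which
avoids partial-minute count inflation.  Wear status is an input column
(the study protocol collected wear interruptions by participant report); a
convenience detector (≥ 60 consecutive zero-cpm minutes) exists but is
never applied implicitly.  Cut-points: sedentary < 100 cpm, light
100–1951 cpm, MVPA ≥ 1952 cpm.  Days with fewer than 720 wear minutes
(12 h, 50%) are excluded; kept days are summarised over wear minutes only,
so class minutes always sum to wear minutes.  Counts are never converted
to MET.

## Agreement statistics

All tests are two-sided; reports are read at the 5% level.  No
multiplicity adjustment is applied.

* **Spearman correlation** is computed as the Pearson correlation of
  midranks (average ranks for ties); a constant vector raises an
  undefined-correlation error rather than returning a value.
* **Wilcoxon signed-rank**: zero differences are dropped before ranking
  (classic convention; a Pratt option keeps them in the ranking).  With at
  most 25 nonzero differences the null is enumerated exactly by dynamic
  programming over the 2^n sign patterns — the enumeration conditions on
  the observed |differences|, so tied midranks are handled exactly as
  well.  Beyond 25, the normal approximation uses mean Σr/2 and variance
  Σr²/4 of the midranks (which reduces to n(n+1)(2n+1)/24 minus the usual
  tie term) with a 0.5 continuity correction.  All differences zero
  returns p = 1 with a degenerate flag.  The exact/approximate threshold
  trades runtime against fidelity; at n = 25 the DP grid has ≤ 651 cells,
  so exactness is essentially free there.
* **Wilcoxon rank-sum**: exact by enumeration of all C(n_x+n_y, n_x) rank
  splits up to 12 combined observations (≤ 924 splits); the midrank normal
  approximation with continuity and tie corrections beyond.
* Two-sided p-values are 2·min(P(W ≤ w), P(W ≥ w)) capped at 1, for both
  exact and approximate paths.
* **Median of differences**: the median over participants of a_i − b_i.
  This is deliberately *not* the difference of the medians; both numbers
  appear in reports.  The percent version is the median of 100·(a_i −
  b_i)/b_i over pairs with b_i > 0 (per-pair denominators; printed percent
  differences in the comparison literature are not consistently derivable
  from either convention, so the alternative — median difference over the
  median of b — is available via `percent_denominator="of_medians"`).
* **Bland-Altman**: bias = mean difference; limits of agreement
  bias ± 1.96·SD with the sample (n−1) SD, consistent with ≈95% coverage
  under normality of differences.
* **Stratified comparisons** cut age at 60 years and BMI at 25.0 kg/m²
  (≥ on the upper stratum).  The between-strata test is a rank-sum test on
  the per-participant differences of the two strata.  Participants missing
  a covariate stay in the overall row and drop from that covariate's
  strata only.
* The reliability correlation reported in tables is Spearman's r; a
  two-way random-effects single-measure ICC(2,1) is provided as an
  optional extra.

## Synthetic cohort generator

The generator emulates a paired evaluation study: a true 1440-min schedule
per participant, an accelerometer stream consistent with it, and one or
two recall diaries distorted by misreporting.

* **Schedule**: per-class daily totals drawn normally around means
  (1025, 385, 30) min for sedentary/light/MVPA with SDs (110, 100, 25),
  clipped at 0 and renormalised to 1440; totals are split into bouts around
  typical lengths (60/30/15 min) on the 5-min grid and shuffled into an
  alternating sequence.  The means sit near the accelerometer medians of a
  free-living adult cohort (≈1004/377/30 before renormalisation).
* **Counts**: per-minute counts drawn from truncated normals confined to
  each class's cpm interval (defaults: means 30/650/3000, SDs 30/400/800,
  MVPA capped at 15000 cpm), so the criterion recovers the truth by
  construction — the package evaluates agreement machinery, not cut-point
  estimation.  Setting the SDs to zero gives degenerate class-typical
  emission.  Sub-minute epochs are produced by a count-conserving
  multinomial split and exist to exercise the minute reduction.
* **Misreporting**: each true light bout is independently re-reported as
  an MVPA-coded activity with probability 0.234 or as sedentary with
  probability 0.078.  Against the 385-min mean light schedule these move
  ≈ +90 min into MVPA and ≈ +30 min into sedentary time, i.e. a −120-min
  light / +90-min MVPA reporting bias — the over-reported-exercise /
  under-reported-light pattern characteristic of recall instruments.
  Reported bouts are mapped to concrete catalog activities whose MET falls
  in the reported class, so diary scoring reproduces the intended class
  exactly.
* **Replicates**: the second recall is built from the same truth with
  independent misreport draws.  `boundary_confusion_prob` additionally
  flips a reported bout to an adjacent class; it defaults to 0 so that the
  expected validity transfers are exactly the configured ones, and is the
  knob for degrading test-retest agreement (reliability correlations rise
  toward 1 as it goes to 0).
* **Covariates**: age uniform on 22–70 years, balanced gender, BMI normal
  (26.1, 4.4) clipped to [18.1, 41.2] kg/m².  **Wear**: full 24-h wear by
  default (day-and-night wear protocol); an optional non-wear bout
  injector exists.
* **Reproducibility**: participant *i* uses the substream
  `SeedSequence(seed, spawn_key=(i,))`, so a cohort extends without
  changing existing participants, and a fixed seed reproduces the cohort
  exactly.

What the generator does **not** emulate: within-day autocorrelation of
counts beyond bout structure, magnitude-dependent sedentary misreporting
(real Bland-Altman plots show differences growing with the mean; here the
transfer is proportional to light time only), posture/effort recall
errors, device artefacts, or seasonal and day-of-week variation.  Because
replicate diaries share the truth but re-draw misreporting independently,
simulated test-retest correlations for small-volume classes (MVPA) are
lower than a real instrument's; passing tests demonstrate correctness of
the machinery, not field performance of any instrument.

## Problem sizes and the acceptance run

The default acceptance computation uses a 67-participant cohort with two
recalls each (reliability) whose first 49 participants contribute a kept
accelerometer day (validity) — the sample-size structure of a pilot-scale
evaluation study.  Property checks run at 1000 random diaries/count
series, and oracle-equivalence checks at 200–500 random instances with
exact enumeration sizes n ≤ 12, which keeps brute-force nulls exactly
computable.

## Known limitations

* Exact replication of any historical cohort's p-values is out of scope:
  tie-handling and software conventions differ across implementations and
  the original data are not public.
* The demonstration catalog is a reduced fixture; production use expects a
  full activity catalog in the documented dialect.
* Counts are single-axis by convention; tri-axial vector-magnitude
  cut-points are not implemented.
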
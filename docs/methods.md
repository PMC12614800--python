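# Methods

This note documents the statistical model behind `fearcal`, the parameter
choices that matter, what the synthetic generator does and does not emulate,
and the package's numerical conventions. It states no empirical result that
the test suite does not itself compute.

## Protocol and preprocessing

The 4-day paradigm is encoded as event tables: habituation (5 CS+ / 5 CS−,
alternated), conditioning (5 CS+ each followed by a 2 s / 0.65 mA-class US,
5 interleaved CS−), and two test/extinction sessions (4 CS− then 12 CS+).
Tones last 30 s (200 ms pips at 0.9 Hz); inter-trial intervals are uniform
in 60–90 s with a 2 min pre-stimulus baseline. The US onset is placed one
pip period (1/0.9 s) after CS+ offset — the time of the next expected pip.
Within a session the CS+/CS− order is a deterministic alternation rather
than a per-seed permutation; a randomized presentation order would change
nothing downstream because all analyses index trials per label.

Fluorescence traces are z-scored per cell over the concatenated multi-day
recording (sessions are motion-corrected and extracted as one movie, so a
single mean/sd per cell is the natural scope; per-session z-scoring is
available via `zscore_scope="per_session"`). Constant traces z-score to
zeros with a warning instead of dividing by zero. Binning is a 250 ms mean
(5 samples at 20 Hz); a trailing partial bin is dropped. All intervals are
half-open `[onset, offset)` in seconds and bin `b` covers
`[b·w, (b+1)·w)`.

**AUC.** Because bin values are means over their bin, the exact integral of
the underlying trace over a window is `sum(bins) × bin_width`. We use that
rectangle rule rather than the trapezoid on bin centres: it makes the AUC
exactly linear, exactly additive over disjoint windows, and exactly
height × width for rectangular responses, and it equals the Riemann
integral of the raw 20 Hz trace. One practical caveat, discovered while
validating the generator: event onsets are quantized to the bin grid, so a
short AUC window (e.g. 2 s after US onset) clips a phase-dependent sliver
of the calcium transient's tail, adding deterministic trial-to-trial
variation of a few percent. Windows that contain the full transient (the
10 s post-US window used for clustering features) are immune.

## Responsiveness

Per presentation, the baseline window (30 s pre-CS; 5 s pre-US) is compared
to the evoked window (30 s CS; 2 s US) with a two-sided Wilcoxon rank-sum
test on the 250 ms bins, implemented as the asymptotic Mann-Whitney U with
tie correction (window sizes of 8–120 bins make exact enumeration
pointless). A cell is *responsive* when ≥ 3 presentations reach p < 0.01;
the threshold stays 3 for 4-trial across-day sets, matching the single
stated rule. Direction is the majority sign of the significant trials; an
exact tie falls back to the sign of a caller-supplied statistic (mean AUC)
or the overall sign balance, and is logged.

Two statistical facts shape the design here:

* **Calibration requires bin-scale whiteness.** The rank-sum test assumes
  exchangeable samples. If the noise is autocorrelated at the bin scale,
  adjacent 30 s windows differ by slow noise excursions and the per-trial
  type-I error inflates severely (measured ~0.21 at a bin-lag-1 correlation
  of 0.59). The synthetic noise is therefore AR(1) with coefficient 0.6 at
  20 Hz — correlation time ≈ 0.1 s, comfortably below the 0.25 s analysis
  bin — which restores per-trial type-I ≈ the nominal few percent and a
  null "responsive" rate of ~10⁻⁴ against the exact independent-trial
  binomial bound of 9.85 × 10⁻⁶ for p(≥3 of 5 at α = 0.01). Real
  indicator noise is more autocorrelated than this; on real data the rule's
  false-positive rate is accordingly more permissive than the binomial
  arithmetic suggests.
* **Power scales with the window.** With 120 vs 120 bins, planted
  activations of 3× noise sd are recovered essentially always; the US test
  (8 evoked vs 20 baseline bins) has intrinsically lower power (~80%
  recovery at the same amplitude). Tests assert the ≥ 95% recovery
  guarantee on the CS windows and a correspondingly weaker bound on the US
  window.

**Chance overlap.** The chance level for multi-stimulus responsiveness
models CS+/CS−/US responsiveness as independent per animal, so the chance
fraction of a combination is the product of member marginals times the
product of (1 − marginal) for excluded stimuli, averaged across animals.

**Spatial distances.** Per cell, the mean Euclidean pixel distance to all
other cells responding to the same stimulus; singleton groups are excluded
with a warning. Note that these per-cell values share each group's sampled
geometry, so two-sample tests that assume independent observations (plain
KS) are anti-conservative at any sample size; the calibrated null for "no
spatial clustering" is a label permutation, which is what the tests use.

## Response-archetype clustering

Feature vectors concatenate baselined per-trial (or trial-group-averaged)
response snippets at the 0.25 s analysis bin; traces are already z-scored,
so features are not re-standardized. PCA retains the smallest component set
reaching 80% explained variance; K-means (k-means++, 50 restarts, tol 1e-6,
seeded) runs on the retained scores, and silhouettes are computed on those
scores with Euclidean distance — the space the clustering actually operates
in. The published cluster counts (16 US, 8 conditioning-CS, 10 across-day,
5 extinction-dynamics) are the defaults; with small synthetic cohorts k is
capped at n−1 with a warning.

Cluster merging is traditionally done by visual inspection. Here it is
reproducible: an explicit
raw→merged map (identity by default) followed by semantic labeling — each
merged cluster is named after the archetype template with maximal Pearson
correlation to its mean feature vector. Templates are built through the
same drive → kernel → bin path as the generator, noiselessly, at unit
amplitude. Clusters that map to the same template merge semantically, which
also repairs K-means over-splitting (raw k = 8 against 6 planted archetypes
labels back to the 6 names). Recovery quality is summarized by the adjusted
Rand index against planted labels and degrades monotonically as the evoked
amplitude shrinks.

Cross-labeling flows are raw cell counts (rows = source clusters); the
"flows < 5 cells hidden" rule affects only the display matrix, never the
conserved counts.

## Population vector distance

The US reference vector is the per-cell mean baselined response over
[0, 5) s after shock onset, averaged over the five shocks. Each 250 ms bin
of a 30 s CS response gives a population vector; its Euclidean distance to
the US reference is averaged over bins within the presentation ("30 s
binned responses" read as per-bin vectors; the single-mean-vector reading
is available via `mode="mean_vector"`). Within conditioning, changes are
`100·(d_t − d_1)/d_1` (negative = CS and US representations converging),
summarized as early (pairings 1–2) and late (pairings 4–5) means; the
reference change is exactly 0 by construction and a zero reference distance
is rejected as degenerate. Ablations recompute the whole analysis on the
complement of each named cluster. Across days, per-day PVD uses the first
four CS presentations against the conditioning US vector, normalized to the
habituation distance.

A subtlety the validation accounts for: measured distances are inflated by
noise, `E‖Δ + ε‖ ≈ sqrt(‖Δ‖² + n·σ²)` for n cells, so a planted
convergence rate r yields a late change slightly above −100·(1−r)%. The
recovery test derives this expectation in closed form from the construction
(the planted morph `c_t = c_1 + m_t (u − c_1)` with m reaching 1 − r on
pairings 4–5) and checks the measurement against it within its CI, as well
as against the nominal −100·(1−r) within half a percentage point at the
default noise level.

## Decoding

Datasets are exactly class-balanced: per selected CS presentation a
30-sample block (30 s at 1 s bins, the decoder bin being a 4× aggregation
of the analysis bin), and one baseline block per CS+ presentation taken
from the 30 s immediately before tone onset (ITIs ≥ 60 s keep those windows
stimulus-free). The per-class block count is the smallest CS trial count of
the day. To equalize population size across animals, 37 cells (the smallest
recorded population) are subsampled per iteration, and reported metrics
average 100 iterations.

Multiclass decoding is one-vs-one linear SVMs (C = 1, no further feature
rescaling — traces are z-scored) with majority vote, validated by 10-fold
stratified CV; the confusion matrix aggregates all held-out predictions.
Accuracy is trace/sum of the confusion matrix; per-class precision, recall
and F1 follow the standard identities (zero-division → 0) and are verified
against an independent implementation to 1e-12. Controls: temporally
shuffled labels (chance = 1/#classes for balanced data), responsive-only /
non-responsive-only cell subsets, and a random subset size-matched to the
non-responsive pool.

Cross-day transfer trains a two-way decoder (baseline vs one CS) on the
full session and predicts the other session without retraining, on the
identical cell subsample (cross-day registration is a data-model
invariant). Per-cell absolute weights index each cell's contribution; the
|w(CS+)| vs |w(CS−)| correlation (Pearson by default, Spearman via the
`method` argument — the original statistic is unstated) probes stimulus
selectivity, with a stability control correlating successive refits on
random 90% partitions (200 fits → 100 correlation values).

## Behaviour

Pose tracks (8 labelled body parts, x/y/likelihood per frame) are filtered
by holding the most recent position with likelihood ≥ 0.9 (threshold not
stated in the source protocol; configurable), with leading unconfident
frames back-filled from the first confident one. Immobility requires all
five core points (ear bases, upper/middle spine, tail base) to move less
than the displacement threshold — default 2.0 px/frame, inside the printed
0.7–3.5 calibration range; values outside it warn rather than fail — for at
least 2 s. Bouts intersecting a CS window are flagged and excluded from
neural alignment only; they still count toward CS immobility fractions.

Immobility-aligned activity baselines each bout snippet to the 2 s before
onset (or offset), pools the two extinction sessions into one mean trace
per cell, and integrates 2 s after the event. Cross-session stability is
the per-animal Spearman correlation of per-cell AUCs between sessions,
tested across animals with a one-sample t-test. The discrimination score
DS = (Imm_CS+ − Imm_CS−)/(Imm_CS+ + Imm_CS−) uses the first four CS+ of
test/extinction-1 against the four CS− (balanced counts; an all-12 mode
exists since the trial subset is unstated); DS is undefined (flagged NaN)
when the animal never freezes during either tone. Cluster-prevalence /
behaviour relations use Spearman correlation across ≥ 4 animals.

## Synthetic generator: what it emulates, what it does not

Per cell: `trace = AR(1) noise + (rate drive ∗ calcium kernel)`, then the
standard preprocessing. The kernel is a difference of exponentials (rise
0.1 s, decay 0.6 s — GCaMP6f-like; configurable toward 6s), peak-normalized
for inspection and mass-normalized inside the generator so sustained drives
keep their amplitude in z units. Tone drives follow the 0.9 Hz / 200 ms pip
structure; shock drives are 2 s boxcars ("US off" cells respond in the 2 s
after shock offset instead). Per-trial amplitudes follow the planted
archetype schedule (stable; geometric decay with ratio 0.5; ramps;
first-trial-only; drop-after-trial-2; see
`synth.archetype_amplitude_schedule`). With the 0.5 decay the later trials
of "down" archetypes fall below single-trial detectability — such cells are
recovered through their early trials, as intended by the schedule, but may
fail the ≥ 3-trial responsiveness rule; analyses that first filter by
responsiveness therefore see "down" cells under-represented relative to the
planted mixture. Inhibited archetypes are negative drives: after
z-scoring, suppression of a tonically active interneuron and a negative
deflection are the same observable, so no explicit tonic offset is needed.
Across-day archetypes gate tone responses outside the conditioning day
(tone: both CS, all days; fear: CS+ on test/extinction-1 only; extinction:
CS+ on extinction-2 only; stable: CS+ on all days; "remapped" draws a fresh
random response sign per day per tone — the decoding control). Mixture
defaults follow the cluster sizes reported for the recorded population;
cohort defaults are 9 animals × 58 cells.

Behaviour is a two-state semi-Markov chain (mobile dwell U(5, 20) s, then
an immobile bout of U(2.5, 8) s with probability 0.8): body parts share a
random-walk base whose step is 4 px/frame mobile vs 0.2 px/frame immobile,
with 2% likelihood dropouts that scatter coordinates (so the pose filter is
exercised). State-modulated cells receive a ±1 z drive during immobility
per their planted sign.

Not emulated: photobleaching, neuropil contamination, crosstalk, biophysical
calcium dynamics, frame drops, cross-day registration errors, behavioural
CS-dependence of freezing (planted bouts are independent of tones, so DS
centers on 0), and realistic indicator-noise autocorrelation (see the
calibration note above). A green recovery test therefore establishes that
the analysis logic is correct on data satisfying its assumptions — not that
the statistics are calibrated for arbitrarily autocorrelated in vivo noise.

## Numerical conventions and edge cases

Uniform seeds: every stochastic routine takes a seed or derives child seeds
(< 2³¹) from `numpy.random.SeedSequence`, and two runs with the same config
hash write byte-identical artefacts. Degenerate inputs fail loudly:
zero-variance feature matrices, k outside [2, n], empty cell subsets,
zero reference distances, unbalanced decoder classes, bodies never
confidently tracked. Quantities that are undefined rather than wrong — DS
at 0/0, correlations of constant vectors, s.e.m. of a single observation —
return NaN with a warning and a flag. Group comparisons always report the
non-parametric path (Friedman + Dunn, Mann-Whitney / Wilcoxon with
Bonferroni, chi-square with Yates when an expected count < 5) with
Shapiro-Wilk and Levene screening attached for transparency.

## Known limitations

* The rank-sum responsiveness rule is calibrated only when noise is
  uncorrelated at the bin scale; its real-data false-positive rate depends
  on indicator kinetics.
* Template labeling presumes the template library spans the response types
  present; an unanticipated shape is forced onto its nearest archetype.
* The chance-overlap independence model and the Pearson default for weight
  correlations are package choices where the original computation is
  unstated.
* Short AUC windows interact with bin-grid quantization of event times
  (above); prefer windows that contain the full transient when comparing
  across trials.
* Synthetic cohorts are stationary within sessions; slow drift, arousal
  covariates and cross-day amplitude changes other than the planted gates
  are absent.
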
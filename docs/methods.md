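# Methods

wavepipe reimplements, as a tested pipeline over synthetic ground truth, a
waveform-based candidate cell-type analysis of laminar microcircuits in
primary visual cortex recorded with high-density probes: curation of
spike-sorted waveform templates, graph-based clustering of normalized
waveforms, laminar placement, drifting-grating tuning, interspike-interval
(ISI) bursting, multichannel action-potential propagation, and
cross-correlogram (CCG) connectivity.  This note documents the models,
parameters, numerical choices, and what the synthetic tests do and do not
establish about real recordings.

## Synthetic data generator

The generator produces the inputs the analysis assumes, with known truth
per unit; it is phenomenological, not biophysical.

**Templates.** A unit's somatic waveform is a sum of Gaussian lobes in
continuous time: a narrow trough (SD `max(0.04, 0.15*ttp)` ms), a broader
repolarization peak at the class's trough-to-peak duration `ttp` (SD
`max(0.08, 0.35*ttp)` ms) whose height relative to the trough is the class's
`repolarization_ratio` (default 0.35), and for triphasic classes a
pre-trough peak 0.25 ms early.  Positive-spiking (peak-first) classes are
sign-inverted.  The window is 1.8 ms at 30 kHz (54 samples); the channel
pitch is 20 um.  On a channel at signed distance `d` from the soma
(positive above, i.e. shallower), the waveform is evaluated at `t - v*d`
with `v = v_above` for `d > 0` and `v_below` for `d < 0` (ms/um), and scaled
by `exp(-|d|/lambda)` with space constant `lambda` (default 40 um).  Because
the shape is analytic, the time shift and decay are exact, making the
template a strict oracle for the propagation stage.  Additive white
Gaussian noise (uV) is applied last.

**Spike trains** are renewal processes whose ISI is a mixture: with
probability `burstiness` an ISI is refractory (1 ms) + Gamma(shape 2, scale
2 ms) (mode 2 ms, the short-ISI burst component); otherwise refractory +
exponential, with the exponential mean solved so the mixture mean ISI equals
`1/rate` exactly.  This directly controls the peaked-short-ISI feature the
bursting index measures, without claiming a biophysical burst mechanism.

**Tuning.**  Trial counts are Poisson draws from
`rate(th) = b + (p - b) * exp(kd(cos dth - 1) + ko(cos 2dth - 1))`
over 36 directions (10 deg spacing) x 4 spatial frequencies.  Given the
contrast-form indices used downstream, the concentrations have closed
forms: `kd = atanh(DSI)`, and `ko` from the folded orientation contrast
(preferred vs orthogonal after averaging opposite directions).  A target
OSI below `tanh^2(kd/2)` is impossible — direction tuning alone already
produces that much orientation contrast — and raises an error naming the
bound.  Spatial-frequency tuning is flat (selecting the best SF is the only
SF analysis in scope).

**Coupled pairs.**  A directed pair copies each source spike into the
target with probability `efficacy` at `+delay` (Gaussian jitter, default
0.3 ms) on top of an independent background train; common-input pairs
insert the copies at lag 0; an independent pair is background only.
A 1 ms refractory period is enforced after superposition.

**Default population** (the study conditions for end-to-end runs): six
classes — four negative biphasic (trough-to-peak 0.20-0.70 ms, distinct
repolarization ratios, burstiness 0-0.8, distinct laminar homes and tuning
targets), one triphasic, one positive-spiking concentrated in white matter —
25 units/class, 240 s of spontaneous activity, 5 trials/condition, template
noise 2 uV, three planted coupling edges.  Velocities are 0.001-0.003
ms/um (recovered slopes of trough time vs distance), i.e. conduction at
roughly 0.3-1 m/s.

**What the generator does not emulate:** background correlations between
unpaired units (anesthesia-state co-modulation is configurable in
principle but defaults to none), electrode drift, overlapping spikes and
sorting errors, non-Poisson trial-count dispersion, spatial-frequency
tuning, and biophysical waveform diversity beyond the parameterized lobes.
Passing tests therefore demonstrate that each estimator recovers the
quantity it defines under its own assumptions — not that those assumptions
hold in any particular recording.

## Curation

The max-amplitude (peak-to-trough) channel is the somatic channel (ties go
to the shallower channel).  Polarity: negative if the trough precedes the
dominant peak, positive if the peak precedes the trough; a waveform with
two flanking peaks each >= 25% of the trough magnitude is triphasic and
counted negative, but only when the trough is the dominant extremum —
otherwise a peak-first positive waveform with a shallow after-trough and
noise in its tail is mistaken for triphasic and aligned to the wrong
feature.  Negative waveforms are aligned to the trough and positive ones to
the peak, at sample 18 of 54 (0.6 ms), padding with edge values (flagged)
when the shift leaves the window.  Normalization divides by the maximum
absolute value, pinning one extremum at +-1.  SNR is the somatic
peak-to-trough amplitude over a residual noise SD (supplied, or estimated
from the first 0.2 ms of the window across channels); the default threshold
is 3.  These rules replace the original manual-observer curation with
deterministic equivalents.

## Clustering

UMAP (n_neighbors 20, min_dist 0.2, fixed seed) embeds the normalized
waveforms; community detection runs on the high-dimensional fuzzy neighbor
graph, not the 2-D layout.  Partitions are found with the Leiden refinement
of resolution-parameterized modularity (leidenalg,
RBConfigurationVertexPartition); the reported `modularity_q` is the
standard (resolution-1) Newman modularity of the returned partition,
recomputed directly from the graph by our own formula so tests can check it
against an independent implementation to 1e-9.  The resolution sweep
re-embeds 25 random 80% subsamples and clusters each at every grid value
(0-10 in 0.5 steps by default), recommending the resolution with maximal
mean modularity.  Validation: (i) a five-fold cross-validated
gradient-boosted-tree readout (depth-limited histogram GBT) reported as a
row-normalized confusion matrix and mean per-cluster accuracy; (ii) an
ensemble consensus — edges reweighted by co-assignment frequency over
seeded reruns, then re-partitioned — scored against the primary partition
with the adjusted Rand index (ARI); agreement between partitions is always
plain ARI here.  Cluster names follow field convention: NS-k / BS-k split
at a 0.35 ms trough-to-peak duration, TP-k for triphasic-majority clusters,
numbered by duration rank.

## Laminar placement

Layer boundaries are supplied per session (from CSD + histology; never
computed).  Depths are mapped session-by-session onto the across-session
average boundaries by a piecewise-linear map per layer, so boundaries map
to boundaries and layer membership is exactly preserved; layers are
half-open intervals [top, bottom) with depth increasing downward, and
anything below the deepest gray-matter edge is white matter.  Enrichment of
a cluster in target layers permutes layer labels over units (1,000
shuffles), flagging observations outside the 1st/99th percentiles of the
null; with 1,000 shuffles the attained two-sided floor is P = 0.002.  The
percentile thresholds use order statistics (no interpolation), which makes
the null flag rate at most 1% per side.  Distance from a reference layer is
0 inside it and the gap to the nearest edge outside, summarized as mean
with a normal-approximation 95% CI.

## Tuning metrics

Responsiveness: Wilcoxon signed-rank of stimulus vs baseline rates over
the trials at the best spatial frequency, AND a mean evoked-rate floor of
1 Hz.  DSI = (Rp - Rn)/(Rp + Rn) with the null response 180 deg from
preferred; OSI uses the orthogonal orientation after folding directions
into orientations; both on baseline-subtracted rates floored at 0, with
"selective" conventionally > 0.5.  The preferred direction is the argmax
of a 3-point circularly smoothed curve (ties to the lower angle).
Vector-averaging variants (1 - circular variance on single and doubled
angles) are provided as alternatives; the contrast forms are the default.
Latency is the first PSTH bin (<= 5 ms bins) after onset exceeding baseline
mean + 3 SD for two consecutive bins.  The modulation ratio F1/F0 is the
first-harmonic amplitude at the drift frequency over the mean rate,
computable from spike times or from a sampled rate (the latter is exact
for noiseless rate models; a half-wave-rectified sinusoid gives pi/2).

## ISI and bursting

ISI histograms use 1 ms bins over (0, 100] ms, normalized to probability
(ISIs past 100 ms dropped); units with fewer than 100 ISIs are excluded as
unstable.  PCA is computed across units on the centered probability
vectors; each component's sign is fixed positive at the population's modal
ISI bin (falling back to its largest-magnitude element), which pins the
otherwise arbitrary signs the bursting index depends on.  The bursting
index is the PC1 loading minus the PC3 loading; the PC1-PC3 contrast
emphasizes the peaked short-ISI shape.  Partial correlation regresses both
variables on the covariate and correlates residuals (t test on n-3 df); a
constant covariate falls back to plain Pearson (flagged), and perfect
confounding (no residual variance) reports r = 0.

## Propagation

The analysis window is the soma channel plus five channels above and below
(truncated and flagged at the probe edge).  Per-channel trough/peak times
are measured relative to the soma trough after light 3-point triangular
smoothing — which keeps template noise from pushing a noise-dominated
channel past the acceptance floor (15% of soma amplitude) or displacing an
extremum — and refined by 3-point parabolic interpolation, resolving
delays below one sample (sub-33 us, needed for realistic 0.001-0.003 ms/um
slopes over a +-100 um window).  Cluster trajectories are per-offset means
after one-pass removal of values outside the per-offset 95% interval; an
offset reported by fewer than half the cluster's units is dropped as
unreliable.  Slopes (ms/um) come from OLS of trough time on signed
distance, fit separately above and below the soma with the (0, 0) soma
point anchoring both; the reciprocal is the conduction speed.  The
asymmetry index is the distance of the (above, below) slope pair from the
y = -x line, |a + b|/sqrt(2): zero for symmetric propagation away from the
soma.  Bootstrap inference resamples units within a cluster (500
resamples): SEs, a 95% percentile CI for the below-soma slope (direction
test), and 98% CIs for pairwise asymmetry differences between clusters.
Cluster-mean trajectories feed the regression by default; per-unit slopes
are also computed.

## Connectivity

CCGs use 1 ms bins over +-50 ms.  The raw CCG is normalized by
`N_ref * N_tgt * bin / duration` so two independent Poisson trains have
expectation 1 in every bin (the squared geometric-mean-rate convention).
Interval jitter resamples target spikes uniformly within consecutive 25 ms
windows (200 surrogates); the corrected CCG is raw minus the surrogate
mean, which removes co-modulation slower than the jitter scale and
preserves fine timing.  The noise scale for significance is the per-bin SD
across surrogates pooled (RMS) over bins; a pair is significant when the
corrected peak reaches 7 of these SDs.  A surrogate max-statistic null was
considered and rejected: the SD of a max over ~100 bins is several times
smaller than the per-bin SD, so seven of *those* SDs sits near 3 per-bin
SDs and lets roughly a tenth of independent pairs through; the pointwise
7 SD rule keeps the false-positive rate effectively zero while leaving
planted couplings (efficacy 0.1 at 10 Hz, 600 s) dozens of SDs above the
band.  Peak lag is the argmax; peak width is the full width at half
maximum counted in contiguous bins.  The lead-lag index is
(R - L)/(R + L) over corrected values floored at 0, excluding the lag-0
bin — flooring keeps it in [-1, 1].  Significant pairs with |index| <= 0.3
are classed as common input (auxiliary flags: |peak lag| < 1 ms, width >
4 ms); the rest as putative connections.  Cluster-pair summaries report
median indices with one-sample Wilcoxon signed-rank tests; directed network
edges are emitted for cells significant at P < 0.001, oriented by the
median's sign.  The autocorrelogram of a train excludes spike-self pairs;
a duplicated unit (a distinct array with identical times) keeps its
zero-lag coincidences, as a sorting-split would.

## Resampling utilities

All shuffle tests permute labels with a seeded generator and flag
observations outside order-statistic 1st/99th thresholds; two-sided
permutation p-values carry the attained floor 2/n_shuffles.  Bootstraps
resample with replacement and report the replicate SD as SE plus percentile
CIs.  Chi-square goodness of fit requires expected counts >= 1.  Every
analysis draws randomness from its own seed or generator, so stage order
cannot change results; the pipeline derives per-stage substreams from the
run seed.

## Problem sizes and limitations

Default end-to-end runs use 150 units, 240 s trains, and ~23 CCG pairs;
recovery studies use 600 waveforms (clustering), 200 trains (bursting),
20-unit clusters (propagation), and 200 pairs at 600 s (connectivity) —
sizes chosen so each estimate's sampling error is small against the margins
being tested while a full run stays interactive on one core.  Known
limitations: trough-time tracking on positive-spiking units follows their
minor (after-trough) lobe and is noise-fragile, which is why — as in the
underlying study design — positive units are excluded from the functional
stages after polarity classification; near-floor channels can still emit
spurious extremum times for single units (the cluster stage's trimming and
support rule absorb this); the jitter correction assumes stationarity
within 25 ms windows; and the ensemble-consensus clustering fixes
resolution 1 rather than re-deriving it per run.
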
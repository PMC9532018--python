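# Methods

## Problem and scope

Spike sorters extract single-neuron spike trains from multichannel
extracellular recordings. Their hardest failure mode is the *spike
collision*: two neurons firing within a couple of milliseconds of each
other produce overlapping waveforms in the traces, and whether a sorter
recovers both spikes depends on the time lag between them and on how
similar the two units' templates are. `spikecollide` provides everything
needed to quantify this behaviour without any external sorter: a simulator
with controlled firing rates and pairwise correlations, the standard
ground-truth comparison machinery, collision-specific metrics, and
built-in reference sorters that make the whole pipeline executable and
testable end to end.

## Simulator

### Probe

A planar multi-column layout with staggered (hexagonal) rows. The default
is 32 channels in 3 columns with 18 um x-pitch and 22 um y-pitch, the
geometry of a common 32-channel laboratory probe. Channels are distributed
as evenly as possible over columns (sizes differ by at most one); odd
columns are shifted by half the y-pitch.

### Templates

Real extracellular action potentials arise from detailed biophysics; here
they are replaced by a cheap parametric form with the features that matter
for collision analysis:

* **Temporal kernel** — difference of two Gaussians: a sharp negative
  trough (sd 0.15–0.25 ms) followed by a slower positive after-wave
  (sd 0.6–0.9 ms, delayed 0.6–0.9 ms, relative amplitude 0.30–0.45),
  normalised to a unit trough. Duration 5 ms = 160 samples at 32 kHz.
* **Spatial decay** — Lorentzian attenuation `A / (1 + (d/lambda)^2)` with
  `lambda = 30 um`, `d` the 3-D distance from the unit's soma to each
  channel. Somata are placed uniformly in a 30/20 um margin around the
  probe with a perpendicular offset z in [10, 60] um; peak amplitude A is
  uniform in [30, 200] uV, and a unit whose peak-channel amplitude falls
  below 30 uV is re-drawn (it would not be detectable).
* **Dendritic return lobe** — a positive-polarity copy of the kernel
  (relative amplitude 0.35–0.6, decay constant 1.5 lambda) centred 40–90 um
  from the soma along a random in-plane axis. This emulates return
  currents: when one unit's soma lies near another's dendrite the two
  drive shared channels with opposite polarity, which is what makes
  *negative* pairwise cosine similarities possible.

Template similarity is the cosine of the angle between flattened
(T x C)-dimensional waveforms. The collision analysis needs the similarity
axis populated at both ends, so a placement whose pairwise similarities do
not reach -0.2 and +0.8 is resampled (in practice the first draw almost
always suffices; after 60 draws the widest one is returned with a
warning). Mean similarity decreases with inter-unit distance by
construction (Spearman rho < 0 on every tested draw).

What the generator does **not** model: biophysical cell-type diversity,
electrode surface integration, drift, bursting waveform attenuation.
Passing tests therefore show that the *metrics* behave correctly and that
the template-matching failure modes depend on lag and similarity as
expected — not that any particular real sorter attains a particular score
on tissue data.

### Spike trains

Independent trains are homogeneous Poisson. Correlated trains use a
mixture (mother) process: a mother Poisson process runs at rate `r / c`
and each of the n units copies each mother spike independently with
probability `c`, jittering every copy with zero-mean Gaussian noise
(sd 0.5 ms by default). Each unit's marginal rate is then `r`, the
pairwise spike-count correlation equals `c`, and the expected fraction of
a unit's spikes shared with any other unit is also `c`. The Gaussian
jitter makes the pairwise cross-correlograms carry a Gaussian central
excess (difference of two independent jitters: sd ~0.71 ms, so virtually
all coincidences fall inside the +/-2 ms collision window). At `c = 0`
the construction degenerates exactly to independent Poisson trains.

An alternative instantiation (mother at rate `r`, copy probability `c`,
independent complement at `r(1-c)`) was considered and rejected: its
shared-spike fraction is `c^2`, so the injected "correlation level" would
not be the quantity the correlation parameter claims to control.

Refractory violations are pruned by a greedy time-order scan (the earlier
spike of a violating pair is kept; 4 ms default). Pruning removes a
fraction ~`r * t_ref` of spikes, so trains are topped up with additional
independent Poisson spikes (re-pruned, up to 5 rounds) until the empirical
rate is within 1% of nominal; the configured rates are treated as the
operative levels. Note the interaction with correlations: pruning deletes
each member of a coincidence independently and compensation adds
uncorrelated spikes, so at 15 Hz the realised shared fraction sits ~10–15%
below the injected level. This is inherent to enforcing a refractory
period after injecting correlations, and the unit tests quantify it.

Seeding: a single master seed; per-unit and per-component streams are
derived through `numpy.random.SeedSequence` spawn keys, so trains are
reproducible and unit-wise independent.

### Traces

Linear superposition: each spike adds its unit's template, scaled by an
i.i.d. modulation factor ~ N(1, 0.05) truncated to [0.7, 1.3]
("slight" physiological amplitude variability), with the trough at the
nearest sample (no sub-sample interpolation — at 32 kHz one sample is
0.03 ms, far below the 0.36 ms lag bins). Uncorrelated Gaussian noise
(5 uV default) is added per sample per channel. Traces are generated in
10 s chunks and can be streamed to a float32 memmap, so 30-minute,
32-channel recordings (~7 GB) never need to fit in memory. Noise SD is
estimated per channel by the median absolute deviation scaled to the
Gaussian SD, computed on the first 10 s.

## Ground-truth comparison

Spikes of a ground-truth and a sorted train match when their times differ
by at most 0.4 ms (inclusive, applied in seconds so the convention is
sampling-rate independent). `n_matches` is the size of a maximal
*one-to-one* pairing — the conservative reading that keeps the agreement
score `n_matches / (n_gt + n_sorted - n_matches)` in [0, 1]. The pairing
is computed by a two-pointer sweep over the sorted trains, which is
optimal for this interval-compatibility structure; the tests verify it
against a brute-force maximum-bipartite-matching oracle on random
instances. Hungarian assignment (via `scipy.optimize.linear_sum_assignment`
on the negated score matrix, rows in ground-truth unit order, hence
deterministic) matches units one-to-one; zero-score assignments are
discarded. Matched pairs are labelled per spike (TP/FP/FN), giving
accuracy, precision and recall per unit; unmatched ground-truth units get
all-FN masks and zero metrics.

Sorted units are classified by the first matching rule of: *well
detected* (assigned, accuracy >= 0.8 — inclusive), *false positive*
(unassigned, all scores < 0.2), *redundant* (score >= 0.2 with some
ground-truth unit but never that unit's best match), *overmerged*
(score >= 0.2 with more than one ground-truth unit), *other* (e.g.
assigned with accuracy < 0.8). The rules can overlap; applying them in
this fixed order makes the classes mutually exclusive and deterministic.

## Collision metrics

A synchronous event is a cross-unit spike pair within 2 ms (inclusive).
Events are binned by lag into 11 equal bins over [-2, 2] ms (bin width
4/11 ms). For the pair (i, j) with i < j the lag is `t_j - t_i`; since
that orientation is arbitrary, plotted profiles are symmetrised by
averaging bins at +/-lag. Both spikes of an event contribute, each binned
at the event's lag; a spike participating in k events contributes k times
(the unit of analysis is the event). Collision recall per bin is
recovered-spike count over collided-spike count; empty bins are NaN,
never silent zeros. Profiles are pooled over template-similarity bins
(default edges -0.4 to 1.0 in steps of 0.2) by summing counts, i.e. an
event-weighted average, and integrated over lags the same way to give
recall versus similarity.

The correlogram error metric compares, for every matched ground-truth
pair above a similarity threshold (default 0.5), the ground-truth
cross-correlogram with that of the matched sorted trains: per lag,
`|ccg_gt - ccg_sorted| / mean(ccg_gt)`, the baseline being the mean
ground-truth count over the window (per-bin division would blow up on
near-empty bins). Defaults: +/-10 ms window, 0.5 ms bins — wide enough to
show the flat baseline around the +/-2 ms collision region with stable
counts. Pairs with an empty ground-truth correlogram are skipped and
logged.

A caveat established while validating the degraded oracle: when event
multiplicity is high (many units, high correlation), most collided spikes
participate in several events, so a lag-dependent *per-spike* failure
probability appears mixed across lag bins of the measured profile. The
per-bin expectation is still exactly computable from the event table (the
acceptance tests do so); bin-wise identifiability of a lag step requires a
low-multiplicity regime (few units or low correlation).

## Reference sorters

* **Oracle** — the ground truth renumbered; fixes the top of every metric
  scale and exercises the identity paths.
* **Degraded oracle** — deletes each collided spike with probability
  `p_drop(lag, similarity)` (for a multi-event spike, its
  smallest-|lag| event is used), jitters survivors, injects uniform
  spurious spikes. Used to verify that the collision metrics recover
  known failure probabilities.
* **Greedy template matching** — iterative peeling with the *true*
  templates (no clustering stage, so failures isolate the matching step):
  detect local minima of the channel-wise minimum residual below
  5 estimated-noise-SD; fit every template at +/-2 sample offsets by least
  squares (amplitude clipped to [0.7, 1.3], mirroring the generator's
  modulation truncation; fits with unclipped amplitude outside [0.5, 1.5]
  rejected); accept fits greedily by residual-norm reduction with a
  0.5 ms within-pass exclusion; subtract; repeat up to 6 passes so
  overlapping spikes are peeled once their partner has been removed.
  Fits are evaluated in one BLAS matmul per pass against a zero-padded
  template bank, which keeps a 300 s, 32-channel recording under ~30 s of
  sorting on one core. On noiseless, collision-free recordings the sorter
  is exact (accuracy 1.0 for all units); with collisions its recall drops
  as template similarity rises — the pattern the benchmark exists to
  measure.

## Benchmark grid

The grid crosses firing rates {5, 10, 15} Hz with correlation levels
{0, 10, 20}% and several replicates per condition; the full-scale
profile is 5 replicates of 30-minute recordings (45 runs). Within a
condition the spike-train seed is fixed across replicates while template
and noise seeds vary: replicates share spike times but redraw templates
and positions, which populates the similarity axis without changing the
collision structure. Aggregates report the mean and sample SD (ddof = 1,
conventional for n = 5) of the recall curves over runs. The default
desk-scale profile is 300 s with 2 replicates; tests use 15–300 s
simulations, chosen to keep the full suite in minutes while leaving every
statistical check adequately powered (tolerances are stated per test as
multiples of the relevant standard error).

## Numerical conventions and degenerate inputs

* All windows are inclusive at their boundaries (0.4 ms match, 2 ms
  synchrony).
* Zero-norm templates raise an explicit error rather than propagating
  NaNs; two empty trains score 0 (logged); zero-denominator metrics are 0
  with a warning.
* Zero-duration train generation returns empty trains with a warning;
  `rate * refractory >= 1` is rejected as infeasible.
* Lag-bin assignment uses half-open bins with both extreme boundary
  values clipped into the end bins.
* Correlogram mirror symmetry (`ccg(i,j,l) = ccg(j,i,-l)`) is exact by
  construction (the lower triangle is stored as the reversed upper
  triangle).
* All randomness flows from named `SeedSequence` streams; identical seeds
  give bit-identical outputs everywhere, including traces for a fixed
  chunk size.

## Known limitations

* Parametric templates cover the lag/similarity geometry of collisions
  but not waveform diversity across real cell types; absolute recall
  values are specific to this template family.
* Rates and correlations are homogeneous across units by design.
* The refractory/compensation interaction shifts realised shared-spike
  fractions below the injected correlation at high rates (quantified in
  the tests).
* The greedy sorter is a reference implementation for exercising the
  metrics, not a competitive sorter: no clustering, no drift handling,
  single-channel-peak detection.
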
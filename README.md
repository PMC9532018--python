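# spikecollide

A collision-aware benchmark framework for spike sorting.

Spike sorters turn multichannel extracellular voltage recordings into
per-neuron spike trains. Their characteristic blind spot is the *spike
collision*: two neurons firing within ~2 ms of each other superpose their
waveforms in the traces, and recovery of both spikes depends on the time
lag between them and on how similar the two units' templates are.
`spikecollide` is for developers and evaluators of spike sorting
algorithms who want to measure that behaviour quantitatively. It
provides:

* a **simulator** of ground-truth recordings — a 32-channel, 3-column
  hexagonal probe (18/22 um pitch), parametric spatiotemporal templates
  in uV, Poisson or correlated spike trains (5–15 Hz, 0–20% pairwise
  correlation via a jittered mother process, 4 ms refractory pruning),
  and traces with amplitude modulation plus 5 uV additive Gaussian noise
  at 32 kHz;
* **ground-truth comparison**: spikes matched one-to-one within
  Δ = 0.4 ms; agreement score per unit pair

      score_ij = n_matches / (n_gt_i + n_sorted_j − n_matches),

  Hungarian assignment on the score matrix, per-spike TP/FP/FN labels,
  and per-unit

      accuracy = TP/(TP+FP+FN),  precision = TP/(TP+FP),  recall = TP/(TP+FN),

  with sorted units classified as well detected (accuracy ≥ 0.8), false
  positive (all scores < 0.2), redundant, overmerged, or other;
* **collision metrics**: synchronous events (cross-unit spike pairs
  within 2 ms) binned by lag into 11 bins over [−2, 2] ms; collision
  recall per lag bin, pooled by template cosine similarity and
  integrated over lags; and the lag-wise relative error between
  ground-truth and sorted cross-correlograms;
* **reference sorters** — an oracle, a configurable degraded oracle, and
  a greedy template-matching sorter (iterative peeling with the true
  templates) — so the benchmark runs end to end with no external
  dependencies;
* a **CLI** (`spikecollide simulate | sort | compare | collision |
  correlogram | grid | report`) orchestrating the 3 rates × 3
  correlations × 5 replicates grid of the full-scale benchmark.

## Worked example

Simulate one minute of 20 correlated units, sort it with the built-in
template-matching sorter, and ask how collision recall depends on
template similarity:

```python
import spikecollide as sc

probe     = sc.make_probe()                                   # 32 ch, 3 columns
templates = sc.synthesize_templates(probe, n_units=20, seed=0)
sim       = sc.cosine_similarity(templates)
gt        = sc.generate_correlated(20, rate=10.0, correlation=0.2,
                                   duration=60.0, seed=0)
rec       = sc.assemble_recording(templates, gt, noise_sd=5.0, seed=0)
sorting   = sc.greedy_tm_sorter(rec, templates)

match    = sc.compare_sorting(gt, sorting)
events   = sc.find_synchronous_events(gt)
profiles = sc.collision_recall_by_lag(events, match)
curve    = sc.collision_recall_by_similarity(profiles, sim)
print(curve.round(3).to_string(index=False))
```

Output:

```
 sim_lo  sim_hi  sim_center  recall  n_events
   -0.4    -0.2        -0.3   0.761      5662
   -0.2     0.0        -0.1   0.801     11478
    0.0     0.2         0.1   0.749      6906
    0.2     0.4         0.3   0.770      8428
    0.4     0.6         0.5   0.802      6280
    0.6     0.8         0.7   0.725      3384
    0.8     1.0         0.9   0.583      3210
```

Each row is one template-similarity bin; `recall` is the event-weighted
fraction of collided ground-truth spikes the sorter recovered, integrated
over all lag bins, and `n_events` the number of collided spikes pooled
into the bin. The drop in the last row (0.58 versus ~0.75–0.80 elsewhere)
is the signature the framework exists to measure: collisions between
near-parallel templates are the ones a template-matching sorter fails to
disentangle. The same run reports mean unit accuracy 0.697, precision
0.821, recall 0.808, with 5 of 20 sorted units classified well detected —
on a 60 s recording most units simply accumulate enough collision misses
to fall below the 0.8 accuracy bound.

The full benchmark grid (45 recordings at full scale) runs from the
shell:

```bash
spikecollide grid --full-scale --sorter greedy_tm   # or --dry-run first
spikecollide report --result-dir benchmark_output
```

## Layout

```
src/spikecollide/
  probe_templates.py    probe geometry, parametric templates, cosine similarity
  spike_trains.py       Poisson / mixture-process generators, correlograms
  recording.py          trace assembly, noise estimation, raw binary I/O
  gt_compare.py         agreement scores, Hungarian matching, labels, classes
  collision_metrics.py  synchronous events, collision recall, CCG error
  ref_sorters.py        oracle, degraded oracle, greedy template matching
  bench.py / cli.py     condition grid, aggregation, command line
docs/methods.md         models, parameters, design choices, limitations
```
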
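# dendrosync

Analysis of fiber-photometry recordings of the GnRH neuron dendron — the
converging dendritic projection through which hypothalamic GnRH neurons
drive pituitary LH secretion — together with a calibrated synthetic-data
generator that makes every stage of the analysis verifiable by parameter
recovery.

GnRH dendron calcium activity in freely behaving mice is multi-dimensional:
abrupt **dendron synchronization episodes** (dSEs, ~8–10 min transients)
precede each LH pulse by ~5–6 min; a low-amplitude, higher-frequency
**baseline activity** occurs in clusters of ~20–35 min; and on proestrus a
slow **surge envelope**, composed of ~78-min ultradian oscillations, rises
hours before lights-off and drives the preovulatory LH surge while the dSEs
arrest near its peak.  `dendrosync` implements the full processing chain
for such data:

1. **preprocess** — isosbestic (405 nm) reference subtraction, robust
   single-exponential photobleaching correction, and
   ΔF/F = (F − F_baseline)/F_baseline × 100, for continuous or scheduled
   (5 s on / 10 s off) acquisition;
2. **detect** — prominence-based dSE detection with per-event kinetics:
   rise and decay widths at half maximum ("a" and "b") by interpolated
   crossings, and total duration at 5% of peak amplitude; inter-peak
   interval statistics (mean ± SEM, Fisher–Pearson skewness, both kurtosis
   conventions, Shapiro–Wilk, 10-min histograms) and Kruskal–Wallis/Dunn
   stage comparisons;
3. **deconvolve** — 30-min rolling-average surge extraction with
   onset (>5 pp above the pre-surge level), peak, offset (90% return),
   incline/decline FWHM, and trough-to-trough ultradian segmentation,
   followed by surge subtraction;
4. **residual** — excision of −60/+360 s windows around each dSE,
   residual-peak extraction above baseline, and clustering by the
   >420 s separation rule (durations, intra-cluster frequencies);
5. **align** — LH pulse detection in sparse tail-tip series, dSE→LH
   peak-to-peak lags, and calcium/LH surge concordance.

The synthetic generator (`dendrosync.simulate`) renders two-channel
photometry plus coupled LH for seven profiles — `male`, `metestrus`,
`diestrus`, `proestrus`, `estrus`, `proestrus_surge`, and the
`misplaced_fiber` negative control — with full ground-truth bookkeeping of
every rendered component.  Details of the signal model and all analysis
conventions are in [docs/methods.md](docs/methods.md).

## Worked example

Run the full chain on one simulated 24-h male recording:

```bash
dendrosync run --profile male --duration-h 24 --seed 1 --out runs/male1
```

which prints

```
dendrosync 0.1.0 — profile male, seed 1, 24.0 h
events: 20
mean inter-dSE interval: 68.7 min (n=19, skewness 1.06)
mean event duration: 652 s
baseline clusters: 37 (mean duration 19.7 min, intra-cluster frequency 0.0168 Hz)
dSE→LH lag: 5.7 min over 20 pairs
```

Twenty episodes were detected (all of them match the generator's ground
truth at ±30 s).  The mean event duration of 652 s recovers the generating
kernel's 658 s extent; the mean interval of 68.7 min is one 19-interval
draw from the right-skewed male distribution whose long-run mean is
93.3 min — single recordings scatter widely, which is exactly why the
recovery tests pool several.  Every LH pulse followed its episode, at a
mean lag of 5.7 min against a generative lag of 5.0 min sampled every
5 min.  A proestrus run adds the surge report:

```
dendrosync run --profile proestrus_surge --duration-h 24 --seed 3 --lh-interval-min 180 --out runs/pro3
```

```
dendrosync 0.1.0 — profile proestrus_surge, seed 3, 24.0 h
events: 25
mean inter-dSE interval: 57.3 min (n=24, skewness 4.24)
mean event duration: 443 s
surge: onset-to-peak 5.8 h, amplitude 30.1 dF/F%, 5 oscillations
baseline clusters: 26 (mean duration 16.6 min, intra-cluster frequency 0.0169 Hz)
```

The detector placed the surge onset-to-peak at 5.8 h against a generating
5.9 h, with the surge amplitude (30.1 ΔF/F%) inside the generated 20–40%
band.  The output directory holds the trace, ΔF/F, event table, cluster
table, surge/alignment reports, and a manifest sufficient to re-run
identically.

Each stage is also available separately (`simulate`, `preprocess`,
`detect`, `deconvolve`, `residual`, `align`, `report`) and as plain Python:

```python
import dendrosync as ds

cfg = ds.default_config("male", duration_s=86400, seed=1)
raw, truth = ds.assemble_trace(cfg)
dff = ds.preprocess(raw)
events = ds.detect_dse(dff)
stats = ds.interval_statistics(events.intervals_min)
```

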
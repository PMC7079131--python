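# navclust

Analysis pipelines for studying the supramolecular organization and gating
of the cardiac voltage-gated sodium channel **Nav1.5** (and its modulation
by the auxiliary **β3-subunit**) in heterologous expression systems, with
matched synthetic-data generators. It is written for electrophysiologists
and imaging scientists who want a tested, scriptable re-implementation of
three workflows that are usually spread across vendor software and one-off
scripts:

1. **Whole-cell voltage-clamp kinetics** — peak currents, I/V and reversal
   potential, steady-state Boltzmann gating curves, Hodgkin–Huxley m³h time
   constants, double-exponential decay, and recovery from inactivation:

   *G(t) = Ḡ·[m∞ − (m∞−m₀)e^(−t/τm)]³·[h∞ − (h∞−h₀)e^(−t/τh)] + offset*,
   with *G/Gmax = 1/(1 + exp(±(V−V½)/k))*, *I_P2/I_P1 = 1 − exp(−t/τ)*,
   *t½ = τ·ln 2*, and gating charge *z = RT/(Fk)*.

2. **Single-molecule localization (STORM) statistics** — frame-by-frame 2D
   Gaussian localization with multi-emitter rejection, drift correction by
   cross-correlation, density-based cluster detection (radius, occupancy,
   percent clustered), k-d-tree nearest-neighbor distributions, and the
   two-sample Kolmogorov–Smirnov comparison between conditions.

3. **3D proximity-ligation-assay (PLA) quantification** — triangle-threshold
   segmentation of DAPI/GFP channels, puncta detection by maximum-filter
   local maxima with a noise tolerance, signed Euclidean distance to the
   nuclear mask, and per-cell dot counts and intensities.

Because no raw recordings or images accompany the source study, every
pipeline ships with a seeded generator (`navclust.simulate`) that produces
current families, localization patterns/blinking movies, and three-channel
image stacks with known ground truth — so every estimator is validated by
parameter recovery.

## Worked example

`examples/gating_kinetics.py` simulates five cells under the three clamp
protocols (activation −90…+35 mV, inactivation pre-pulses −140…−50 mV,
recovery intervals 3…72 ms) at 20 pA current noise and runs the full
fitting pipeline:

```text
generator truth: act V1/2 = -42.62 mV, k = 7.28 mV; inact V1/2 = -96.14 mV, k = 7.17 mV; E_Na = 19.58 mV; tau_rec = 7.64 ms

fitted (median of 5 cells, 20 pA current noise):
  reversal potential         18.95 mV
  activation   V1/2, k      -42.14,  7.75 mV
  inactivation V1/2, k      -96.06,  7.17 mV
  recovery tau, t1/2          7.66,  5.31 ms
  gating charge z (act)       3.28 e
  t1/2 / tau                0.6931  (= ln 2)
  tau_m, tau_h at -30 mV      0.66,  3.27 ms  (truth 0.66, 3.28)
```

Every fitted number should be read against the generator truth on the first
line: the Boltzmann midpoints and slopes come back within fractions of a
millivolt, the recovery half-time satisfies t½ = τ·ln 2 exactly, and the
gating charge z ≈ 3.3 elementary charges falls in the 3–4 range expected
for a voltage-sensor transition. The other two examples work the same way:
`examples/storm_clusters.py` recovers a planted 40% clustered fraction and
separates unimodal (6 nm) from bimodal (6 and 12 nm) nearest-neighbor
distributions with a vanishing KS p value; `examples/pla_quantification.py`
detects planted PLA puncta, counts them per GFP-positive cell and
reproduces the 70% membrane-proximal placement.

A thin CLI wraps the same pipelines for shell use:

```bash
navclust simulate-ephys --seed 1 --out out/sim
navclust fit-ephys --input out/sim --seed 1 --out out/fit
```

Each run writes a `manifest.json` (command, seed, parameters, version) that
makes the outputs bit-reproducible.

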
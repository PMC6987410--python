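# hippocal

Analysis pipeline for **longitudinal two-photon calcium imaging of
hippocampal CA1 and dentate gyrus (DG) neurons**, built for chronic
demyelination/remyelination experiments: weekly 200-s recordings of the
red indicator jRGECO1a at 512×512 px / 30 Hz, tracked over ~100 days
while firing rates fall during a cuprizone diet and partially recover
afterwards.  The package also quantifies evoked field EPSPs from
hippocampal slice recordings.

Because chronic in-vivo datasets of this kind are rarely shareable, the
package ships a first-class **synthetic-data generator** that emulates
the recordings with known ground truth — spike trains, fluorescence
traces, rendered movies, and full multi-session cohorts — so every stage
of the analysis is testable end to end.

## What it computes

**Spike inference.**  Fluorescence is converted to ΔF/F₀ with a median
baseline (F₀ = median of F over the recording) and decoded into per-frame
action-potential (AP) counts under a biophysical forward model of the
indicator: latent calcium *c* (in single-AP units) decays as
*c(t+Δt) = c(t)·e^(−Δt/τ)* and each AP adds 1; fluorescence follows a
Hill-type nonlinearity

    ΔF/F(c) = A·c^n                      (c < 1)
    ΔF/F(c) = A·c^n / (1 + γ(c^n − 1))   (c ≥ 1)

with jRGECO1a parameters A = 0.15, τ = 175 ms, n = 1.9, γ = 0.001, and
a multiplicative baseline drift bounded at 3% per recording.  The
decoder finds the MAP spike train by Viterbi dynamic programming over a
discretized (calcium × baseline) lattice: each frame pays a Gaussian
residual cost (y − b·(1+ΔF/F(c)))²/2σ², each spike pays log(1/(νΔt)).
The noise σ is estimated robustly from first differences
(MAD/(0.6745·√2)) and inflated 1.5× for CA1 to suppress false positives.

**Everything around it.**  Frame-pair averaging (30 → 15 Hz), rigid
integer-shift registration, ring-shaped somatic ROIs with a 5×5 nuclear
patch, cytosol/nucleus contrast QC, activity metrics (average rate =
total APs / 200 s; maximal instantaneous rate over 1-s bins; bursts =
≥5 APs within 660 ms), and the longitudinal statistics battery:
Wilcoxon rank-sum (exact for small untied samples), Mann–Kendall trend
test with tie correction, paired *t*, balanced two-way repeated-measures
ANOVA (group × recording day), and one-way ANOVA with Bonferroni
pairwise tests for the slice EPSP data.

## Worked example

Decode a noisy synthetic trace (15 Hz, 200 s, σ = 0.02 ΔF/F) with a
single AP at frame 450, a triplet burst at frames 1200–1201, and one
more AP at frame 2400:

```python
import numpy as np
from hippocal import SpikeTrain, forward_model, compute_dff, infer_spikes
from hippocal.metrics import cell_metrics

rng = np.random.default_rng(0)
counts = np.zeros(3000, dtype=np.int64)
counts[[450, 1200, 1201, 2400]] = [1, 2, 1, 1]
truth = SpikeTrain(counts=counts, frame_rate=15.0)

f = 1000.0 * forward_model(truth) + rng.normal(0, 20.0, 3000)  # raw F
dff = compute_dff(f, frame_rate=15.0)
res = infer_spikes(dff)
m = cell_metrics(res.spikes, cell_id="demo")
```

Output:

```
F0 = 999.1  sigma = 0.0201
true spikes   : {450: 1, 1200: 2, 1201: 1, 2400: 1}
decoded spikes: {450: 1, 1200: 2, 1201: 1, 2400: 1}
average rate = 0.025 Hz   max 1-s rate = 3 Hz   bursts = 0
```

The baseline (999.1 vs. the programmed 1000), noise level (0.0201 vs.
the programmed 0.02) and every AP count — including the two simultaneous
APs at frame 1200, resolved through the supralinear Hill response — are
recovered.  5 APs total / 200 s gives the 0.025 Hz average rate; the
3-AP second is the peak instantaneous rate; no 660-ms window contains
≥5 APs, so no burst is scored.

## Full pipeline

```bash
hippocal run-all --config config.yaml
```

with a config such as

```yaml
outdir: run
seed: 0
compare_days: [[0, 9], [53, 58]]
cohort:
  groups: {cuprizone: cuprizone, control: control}
  mice_per_group: 3
  region: CA1            # CA1 preset: bursty, median ~0.21 Hz, 1.5x noise margin
  cells_per_fov: 100
  duration: 200.0        # seconds per field of view
  frame_rate: 15.0
  mode: traces           # or "movies" to exercise registration/ROI stages
```

This simulates the cohort (the cuprizone timeline scales firing rates
down to 16.5% of baseline by day 53, with a rebound after diet
cessation), infers spikes for every cell, and writes `cell_metrics.csv`,
`session_summary.csv` (medians and quartiles per mouse × day), the
statistics table `stats.csv`, and a `manifest.json` with checksums.
`hippocal recovery` joins the results against the simulated ground truth
(per-session count error, event F1, programmed vs. recovered rate
trajectory).  Subcommands `simulate`, `preprocess`, `extract`, `infer`,
and `metrics` expose the individual stages.

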
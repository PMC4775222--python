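# edgepulse

Quantitative image-analysis tools for **pulsatile assembly of new cell–cell
junctions during epithelial cell intercalation**.

During *Drosophila* germband extension, epithelial cells exchange
neighbours: an interface between anterior and posterior cells contracts to
a multicellular vertex, which then *resolves* by assembling a new interface
between the dorsal and ventral cells. This package implements the
measurement pipeline used to characterise that process in time-lapse
microscopy — and a synthetic-tissue generator that provides exact ground
truth so every stage of the pipeline can be validated end to end:

- **segmentation & tracking** — marker-based watershed on membrane-reporter
  movies, with cell identities propagated between frames by particle image
  velocimetry (PIV);
- **tissue geometry** — shoelace areas, vertex-to-vertex edge lengths,
  interface orientations relative to the anterior–posterior (AP) axis, and
  flanking-junction angles θ₁, θ₂, θ_avg = (θ₁+θ₂)/2;
- **vertex resolution** — onset (first time the nascent edge length *l(t)*
  exceeds 1 µm), resolved/unresolved/collapsed classification, orientation
  150 s after onset, and the mean elongation rate
  `rate(t) = (l(t) − l(t₀)) / (t − t₀)` in µm/min;
- **oscillation analysis** — per-minute rates of change (differences of
  samples 1 min apart), least-squares detrending, FFT period estimation,
  pulse decomposition (signed area under elongation/shortening runs of the
  rate), Pearson correlation, and time-shifted correlation scans
  (±240 s in 10-s steps, Gaussian-smoothed with σ = 10 s);
- **ablation analysis** — instantaneous retraction velocity after laser
  ablation, `v = Δseparation / (t_ablation + t_acquisition)`, a standard
  relative proxy for junctional tension, plus cohort correlations of
  velocity against junction geometry;
- **fluorescence quantification** — apical maximum-intensity projections,
  modal-pixel background subtraction from basal crops, photobleaching
  correction by per-frame mean intensity, junctional and medial traces;
- **reporting statistics** — Student's t-test, Kolmogorov–Smirnov test,
  correlation significance via the t-transformation, mean ± s.e.m.

## Worked example

Generate a synthetic resolving vertex (four cells whose apical areas
oscillate, around a nascent edge that elongates in pulses anti-phase with
the anterior/posterior cells) and run the full signal pipeline:

```python
import numpy as np
from edgepulse import synthetic, oscillation as osc, resolution as res

cfg = synthetic.SyntheticTissueConfig(n_frames=64, dt=10.0, seed=7)
tissue, truth = synthetic.generate_oscillating_tissue(cfg)

edge = tissue.edge
t0 = res.detect_onset(edge)                      # onset: first l(t) > 1 um
status = res.classify_resolution(edge)
rate90 = res.elongation_rate(edge, t0, window=90.0)

length_rate = osc.rate_of_change(osc.TimeSeries(times=edge.times, values=edge.lengths))
period = osc.dominant_period(osc.detrend(length_rate))
pulses = osc.pulse_stats(length_rate)

area_rate = osc.rate_of_change(osc.TimeSeries(times=tissue.times, values=tissue.areas[1]))
n = min(length_rate.rates.size, area_rate.rates.size)
r = osc.correlate(length_rate.rates[:n], area_rate.rates[:n])
curve = osc.shift_scan(length_rate.rates[:n], area_rate.rates[:n], dt=10.0)
```

This prints (formatted):

```
onset t0 = 90 s, status = resolved
elongation rate (90 s window) = 0.205 um/min
dominant period of length-rate signal = 116.0 s
pulses: 1 elongation / 0 shortening, mean elongation = 4896 nm, mean shortening = n/a
net length change = 4.90 um
corr(edge-length rate, anterior-area rate) = -0.85
first correlation min at +10 s, first max at -50 s
```

Reading the output: the nascent edge crosses 1 µm at 90 s and stays above
it, so the vertex is *resolved*. The dominant period of its length-rate
signal is estimated at 116 s — the generating period is 126 s, and the
difference shows the spectral resolution of a 10-minute recording, not an
error. Because this edge elongates strongly on net, its one-minute-lag
rate never reverses sign: the whole recording is a single elongation pulse
and no shortening pulses are detected. The edge-length rate is strongly
anti-correlated with the anterior cell's area rate (r = −0.85), and the
shift scan finds anti-correlation maximal almost immediately (+10 s) while
positive correlation needs a half-period shift (−50 s) — the signature of
junction assembly in anti-phase with neighbour-cell contraction.

A command-line interface wraps the same stages
(`edgepulse simulate|track|resolve|oscillate|ablate|fluor|report`); each
subcommand reads and writes plain CSV/TIFF with a JSON metadata sidecar.

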
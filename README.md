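# chemowave

Single-cell analysis of oscillatory kinase signalling, cell morphology, and
chemotaxis heterogeneity — built around ground-truthed synthetic movies.

Migrating cancer cells in a chemoattractant gradient are strikingly
heterogeneous: seemingly identical cells move at very different speeds and
with very different directionality.  Live-cell kinase translocation
reporters (KTRs) make the underlying signalling visible — the reporter
leaves the nucleus when its kinase (ERK or Akt) is active, so the log2
cytoplasm-to-nucleus intensity ratio (log2 CNR) is a per-cell, per-frame
activity readout.  `chemowave` implements the full computational chain that
connects those readouts to migration:

* **synthetic data** — a generator producing 24 h movies (4-min frames) of
  cells whose ERK/Akt traces superpose short (28–60 min) and long
  (92–124 min) oscillation bands, whose aspect ratio oscillates in
  anti-phase with the long ERK wave, whose nuclear polarization tracks the
  long-wave amplitude, whose speed bursts ~25% about 20 min after each
  elongation peak, and whose mean speed is linear in the short-wave
  amplitude — plus a renderer that turns tracks into 3-channel 16-bit image
  stacks with ground-truth label masks;
* **imaging** — adaptive-threshold nucleus segmentation, nucleus-seeded
  watershed cytoplasm segmentation, log2-CNR quantification, best-fit
  ellipse morphology and nuclear polarization;
* **tracking** — gated Hungarian linking on nuclear positions with an area
  term, gap closing, and mitosis detection with track trimming;
* **oscillation** — moving-average detrending, zero-phase brick-wall
  band-pass decomposition, per-cell band amplitudes (√2 × RMS), and a
  period sweep of amplitude–speed correlations;
* **population statistics** — exact (linear-programming) quantile
  regression at the 20th/50th/80th percentiles with bootstrap inference,
  top-quartile co-occurrence proportions, 1-D earth mover's distance with
  replicate-normalisation, and polar histograms of migration direction;
* **event analysis** — isolation and alignment of aspect-ratio peaks,
  ERK-minimum lags, elongation/ERK-drop differences, and
  polarization-stratified mean speed traces;
* **motility inference** — weak-form least-squares fitting of the
  advection–diffusion equation ∂ρ/∂t = D∇²ρ − v·∇ρ to cell-density fields,
  separating random migration (D) from directed motion (v∥, v⊥), with
  backward elimination of uninformative operators and drug-vs-control
  normalisation D_drug/D_control and [v∥/|v|]_drug / [v∥/|v|]_control.

See `docs/methods.md` for the models, defaults, and numerical choices.

## Worked example

```python
from chemowave import (SynthConfig, generate_tracks, band_amplitude_table,
                       quantile_regress, top_quartile_proportion)
from chemowave.events import collect_events, stratify_by_polarization
from chemowave.vsi import build_density, infer_motility

# a 24 h movie of 200 cells under the default study conditions
cfg = SynthConfig(n_cells=200, rng_seed=1)
tracks, truth = generate_tracks(cfg)

# per-cell band amplitudes and mean speeds; speed ~ short-ERK amplitude
table = band_amplitude_table(tracks, cfg.dt)
fit = quantile_regress(table["erk_short"], table["mean_speed"],
                       taus=(0.5,), n_boot=200, seed=1)[0.5]
prop = top_quartile_proportion(table["mean_speed"], table["erk_short"])

# aspect-ratio peak events and the polarization-gated speed burst
events = collect_events(tracks, cfg.dt)
pol = stratify_by_polarization(events)["polarized"]
i = int(pol["norm_speed"].idxmax())

# population-scale motility from a spreading, drifting cell cloud
cfg_m = SynthConfig(n_cells=2000, D_true=1.0, v_true=(0.05, 0.0),
                    speed_coupling=None, init_distribution="gaussian",
                    boundary="none", rng_seed=1)
tracks_m, _ = generate_tracks(cfg_m)
m = infer_motility(build_density(tracks_m, cfg_m.field_size))

print(f"cells analysed: {len(table)}")
print(f"median-quantile slope, speed ~ short-ERK amplitude: "
      f"{fit.slope:.3f} um/min per log2 unit "
      f"(99% CI {fit.ci99[0]:.3f}..{fit.ci99[1]:.3f})")
print(f"fast cells (>75th pct speed) with high short-ERK amplitude: "
      f"{100 * prop:.1f}%")
print(f"polarized-stratum speed burst: x{pol['norm_speed'].iloc[i]:.2f} "
      f"at +{pol['t_rel_min'].iloc[i]:.0f} min after the aspect-ratio peak")
print(f"population motility: D = {m.D:.3f} um^2/min (true 1.0), "
      f"v_par = {m.v_par:.4f} um/min (true 0.05)")
```

Printed results:

```
cells analysed: 200
median-quantile slope, speed ~ short-ERK amplitude: 1.187 um/min per log2 unit (99% CI 1.178..1.197)
fast cells (>75th pct speed) with high short-ERK amplitude: 96.0%
polarized-stratum speed burst: x1.24 at +16 min after the aspect-ratio peak
population motility: D = 1.061 um^2/min (true 1.0), v_par = 0.0506 um/min (true 0.05)
```

Reading this: the median-quantile slope recovers the generator's
speed–amplitude coupling (true slope 1.2 µm/min per log2 unit), almost all
fast cells have high short-ERK amplitudes because speed is driven by that
amplitude, the stratified event analysis recovers the ~25% speed burst
~20 min after elongation peaks in polarized cells (raised-cosine burst,
so the ±1-frame peak position varies with noise), and the weak-form fit
recovers the diffusivity and drift of the simulated advection–diffusion
motion within a few percent.

## Command line

Every stage is also a CLI subcommand over a YAML run configuration:

```sh
chemowave run -c config.yaml           # simulate → track → ... → report
chemowave simulate -c config.yaml      # or stage by stage
chemowave render -c config.yaml
chemowave segment -c config.yaml
chemowave track -c config.yaml
```

```yaml
# config.yaml
seed: 1
workdir: out
synthetic:
  n_cells: 200
stats:
  n_boot: 200
```

Artifacts (track CSVs with unit headers, amplitude/event tables, TIFF
stacks, JSON stats, a Markdown report) land in `workdir` and are
byte-identical across reruns with the same seed.

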
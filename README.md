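# pinodyn

Quantification of macropinosome dynamics in time-lapse fluorescence
microscopy: how large endocytic vesicles form at membrane ruffles, whether
they seal and mature into endosomes or collapse back to the plasma
membrane, and how reporter proteins are recruited to them over time.

The package targets the analysis around biphasic reporter recruitment —
the pattern shown by the PH/FYVE protein Phafin2, which visits a newly
formed macropinosome twice: a short burst (~40 s) immediately after
scission from the plasma membrane, then a sustained localization minutes
later once the vesicle acquires endosomal identity (PtdIns3P, marked by
2xFYVE probes). It provides, as library functions and a thin `pinodyn`
CLI:

- **`synthetic_data`** — simulators for every data level the analysis
  consumes (per-track intensity tables, rendered multi-channel movies,
  alternating-quench scission traces, two-group cell populations, and
  dextran-uptake endpoint images), each returning a ground-truth record
  so estimators can be validated by parameter recovery.
- **`detection_tracking`** — Laplacian-of-Gaussian vesicle detection with
  local-Otsu area measurement, greedy gated nearest-neighbour linking,
  first-appearance size measurement with the ≥ 0.64 µm² macropinosome
  filter, and counting of newly formed macropinosomes (> 1 µm equivalent
  diameter within a 20 min window).
- **`recruitment_profiles`** — circular-ROI intensity extraction (10 px
  diameter), alignment of every track to its first anchor-channel peak
  (maximum within the first 15 frames), percentile-clipped min–max
  normalization, ensemble mean ± 95% CI (Student-t), first-phase lifetime
  (time above half-maximum) and companion-marker onset/peak timing.
- **`scission_assay`** — sealing-time inference from pH-quench traces
  (pHuji alternately quenched/unquenched every 5 s; a sealed vesicle stops
  responding), with an amplitude-drop gate plus least-squares change-point
  refinement, and sealing-aligned recruitment ensembles.
- **`population_stats`** — success/collapse fate classification
  (sustained endosomal-marker gain on a > 1 µm vesicle), per-cell and
  per-experiment summaries, an exact-arithmetic two-sided Fisher test,
  Student's t / one-way ANOVA with Tukey HSD, and the lipid
  coincidence-enhancement ratio.
- **`uptake_quant`** — per-cell integrated dextran fluorescence
  ((mean in-cell − background) × area) from sum-projected endpoint images
  with membrane-marker segmentation, and high-content dot counting
  (components > 30 px).

## The core computation

For each tracked vesicle, per-channel mean intensities $I_c(t)$ are read
from a circular ROI following the tracked membrane point. Each track is
shifted so that its anchor-channel maximum within the first 15 frames
falls at $t = 0$, normalized per channel to $[0, 1]$ between its 1st and
99th intensity percentiles, and the ensemble is summarized per timepoint
by the mean and Student-t 95% confidence interval over tracks. The
first-phase lifetime is the contiguous time the anchor profile stays above
$\mathrm{baseline} + \tfrac12(\mathrm{peak} - \mathrm{baseline})$, with
crossing times interpolated between frames. Fates are scored per track:
*success* if the endosomal marker exceeds baseline + 3 robust SD for ≥ 3
consecutive frames on a vesicle > 1 µm in diameter, *collapse* if the
track ends without that event, *censored* if the movie ends first; the
per-cell success rate is successes / (successes + collapses).

## Worked example

```python
import numpy as np
import pinodyn as p
from pinodyn.recruitment_profiles import ProfileParams

kin = p.KineticParams()          # 5 s frames, 40 s pulse, 40% success
tracks, truth = p.simulate_track_set(kin, n_tracks=200, duration_frames=80, seed=11)

ens = p.align_tracks(tracks, p.ANCHOR_CHANNEL, ProfileParams())
lifetimes = p.ensemble_lifetimes(ens)
print(f"mean first-phase lifetime: {np.nanmean(lifetimes['lifetime_s']):.1f} s")

outcomes, per_cell = p.classify_outcomes(tracks, p.ENDOSOMAL_CHANNEL,
                                         movie_end_frame=79)
scored = outcomes[outcomes['fate'] != 'censored']
print(f"success rate: {(scored['fate'] == 'success').mean():.2f}")

print(f"Fisher p, [[4,0],[0,4]]: {p.fisher_exact([[4, 0], [0, 4]]):.5f}")
```

prints

```
mean first-phase lifetime: 40.9 s
success rate: 0.41
Fisher p, [[4,0],[0,4]]: 0.02857
```

The lifetime recovers the generator's 40 s pulse width to within one
frame interval; the fate classifier recovers the generator's 40% success
probability; and the Fisher p-value equals the exact enumeration 2/70.

## CLI

```sh
pinodyn simulate --n-tracks 50 --duration-frames 60 --seed 1 --out tracks.csv
pinodyn track movie.tif --channel phafin2 --min-area 0.64 --out tracks.csv
pinodyn profile tracks.csv --anchor phafin2 --roi-diam 10 --window 15 --out ensemble.csv
pinodyn scission traces.csv --half-period 5 --theta 0.25 --out seals.csv
pinodyn stats records.csv
pinodyn uptake dextran.tif membrane.tif --out uptake.csv
```

Movies are TIFF stacks (T×C×Y×X, 16-bit) with a JSON sidecar holding
`pixel_size_um`, `frame_interval_s` and `channel_names`; tracks are CSV
with columns `track_id, frame, t_s, x_px, y_px, area_um2, ch_<name>_mean`,
shared between simulated and real data.

See `docs/methods.md` for the models, parameter choices, and limitations.
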
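# pazquant

Quantification of sub-synaptic protein organization at two model synapses:

* **Cultured hippocampal neurons (STED / confocal):** where does an
  endocytic protein sit relative to the active zone?  Side-view synapses
  are profiled perpendicular to the active-zone marker bar; en-face
  synapses are decomposed into protein clusters around the marker disk;
  confocal fields give bulk synaptic levels inside an Otsu presynaptic
  mask.
* ***Drosophila* larval NMJs (Airyscan-like volumes):** how much protein
  is in a bouton, and how strongly is it polarized to the periactive
  zone (PAZ) — the endocytic membrane domain surrounding each active
  zone?  The NMJ surface is segmented into PAZ units, each split into a
  mesh band and a core, and per-channel enrichment is summarized as a
  log-ratio.

The package is aimed at microscopists and image analysts who need these
measurements as reproducible, scriptable pipelines rather than
point-and-click macros.  Because raw micrographs for such studies are
rarely deposited, `pazquant` ships a synthetic-microscopy generator
(`pazquant.synth`) that renders both scene families with exhaustive
ground truth, so every stage of the pipeline is validated by parameter
recovery.

## The measurements

**Side-view profiles.** For a synapse whose active-zone (AZ) marker
appears as a bar, a 750 nm profile is sampled perpendicular to the bar
(bilinear, one sample per 22.7 nm pixel, averaged across the ROI width),
smoothed with a centered 5-sample rolled average, and aligned so the
marker peak sits at position 0 with positive positions pointing into the
bouton.  Reported per synapse:

* `peak_to_peak_nm` — signed position of the protein maximum relative to
  the marker maximum;
* `window_peak` — protein maximum within the periactive-zone window,
  either ±68 nm around the marker peak or 0…136 nm presynaptic of a
  PSD-95 peak.

Aligned profiles are averaged across synapses and expressed in % of a
reference mean; because per-synapse peak positions jitter, the averaged
trace peaks below 100% even when every individual peak is 100%.

**En-face clusters.** Objects are 8-connected components of a thresholded
protein channel inside an inclusion mask (thresholded vesicle cloud
dilated by 6 px = 136 nm), measured on the original image.  Each object
carries its area, mean, integrated intensity (area × mean), and distance
to the intensity-weighted AZ-marker centroid.

**NMJ boutons.** A 3D mask is built from the normalized sum of reference
channels (Gaussian blur σ = 5 px per slice, auto-threshold, 4 px
erosion); channels are rolling-ball background-subtracted (radius 50 px)
and averaged inside the mask.

**PAZ units.** On a maximum projection of the upper half of the stack, a
composite (e.g. Nwk + Dyn − Brp, mean-normalized, clamped at 0) is
segmented by seeded region growing from automatically detected intensity
minima; units with a mean Euclidean-distance-map score < 7.5 px are
excluded as edge artifacts.  Each unit is split into a 175 nm mesh band
inward from its boundary and a core; per channel,

```
polarization = log2(mean mesh intensity / mean core intensity)
```

with positive values meaning mesh enrichment.  Brp objects are counted
per µm² of NMJ, and units are classified as Brp-containing and/or
Pak-apposed.

**Statistics.** Group comparisons are assumption-gated: Shapiro-Wilk per
group and Levene across groups at α = 0.05 choose between t-test /
one-way ANOVA + Tukey-Kramer and Mann-Whitney U / Kruskal-Wallis +
pairwise Mann-Whitney with Holm correction, all two-sided.  Pearson
colocalization over masked pixels and per-culture normalization to a
reference condition are included.

## Worked example

```python
import numpy as np
from pazquant import ExperimentConfig, synth
from pazquant import sideview as sv
from pazquant.paz import analyze_paz

cfg = ExperimentConfig()

# STED: recover a known 90.8 nm protein offset from a rendered synapse
p = synth.SynthStedParams(n_sideview=1, n_enface=0, field_px=128,
                          protein_offset_nm=90.8, angles_rad=(np.pi / 6,),
                          poisson_scale=0, read_noise_sd=0, seed=1)
field, truth = synth.generate_sted_field(p)
t = truth.sideview[0]
roi = sv.SideViewRoi(t.center_px, t.angle_rad, width_px=11)
prof = sv.align_profile(sv.extract_profile(field, roi, cfg))
print(sv.profile_metrics(prof, cfg).peak_to_peak_nm)   # 90.8

# NMJ: recover a painted 4-fold mesh enrichment as log2(4) = 2
pn = synth.SynthNmjParams(bouton_radius_px=70.0, n_units=16,
                          mesh_enrichment={"nwk": 4.0, "dyn": 2.0},
                          poisson_scale=0, read_noise_sd=0, seed=3)
vol, _ = synth.generate_nmj_volume(pn)
units, brp, summary, labels, proj = analyze_paz(vol, cfg, recipe="fasII")
print(round(summary.mean_polarization["nwk"], 2))      # 1.97
print(round(summary.mean_polarization["dyn"], 2))      # 0.99
```

The first value is the recovered protein offset in nm (exact on the
noise-free scene); the last two are mean mesh/core polarizations over
the analyzed interior units, matching the painted enrichments (log₂ 4 = 2
and log₂ 2 = 1) to about 0.03.

A command-line interface mirrors the library:

```bash
pazquant simulate-nmj --seed 5 --outdir scenes
pazquant nmj-paz --recipe fasII --outdir out scenes/nmj_000.tif
pazquant stats out/table.csv --culture-col culture --reference ctrl
```

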
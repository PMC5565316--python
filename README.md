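# calmito

Analysis pipeline for live imaging of human enteric neurons: calcium-
transient detection from fluorescence time-lapse movies, 3D mitochondrial
morphometry and membrane-potential (TMRE) fluctuation analysis from
confocal stacks, and the paired patient/control statistics used to compare
the two groups — together with a synthetic-data simulator that provides
exact ground truth for every stage.

## Who this is for

Groups doing functional imaging of the enteric nervous system (or any
preparation where hand-drawn neuron ROIs, stimulus-locked Ca²⁺ transients
and locally injected potentiometric dyes are the workflow) who want the
published analysis chain as tested, scriptable, open code rather than a
mixture of proprietary packages, and who need to validate detector
settings against simulations with known truth.

## The analysis in brief

**Calcium.** Movies are registered to the first frame (phase
cross-correlation, subpixel). Each neuron ROI yields a trace normalized to
its pre-stimulus baseline, F/F₀. The intrinsic noise level σ is the SD of
the detrended baseline ratio. A neuron is a **responder** to a stimulus
when its peak within the evaluation window strictly exceeds

    F/F₀ > 1 + 5σ

and its **maximum amplitude** is ΔF/F₀ × 100 (% above baseline). Per
stimulus, the pipeline reports % responders and mean maximum amplitude,
aggregated per subject.

**Mitochondria.** TMRE stacks are background-corrected (scalar,
low-percentile) and bleach-corrected (per-frame rescaling, first frame
brightest). Inside a ganglion mask the pipeline measures: total
supra-threshold mitochondrial volume and its ratio to the mask volume;
mitochondrial density (LoG spot count per 1000 µm³); mean volume of
single mitochondria (26-connected components, watershed-split at spot
seeds); and, for time series, the TMRE fluctuation score of the N=500
brightest tracked spots — the temporal coefficient of variation of each
spot's intensity, in percent.

**Statistics.** Subjects enter as patient/control pairs. Each metric is
compared with a Shapiro–Wilk-gated paired test (exact Wilcoxon signed-rank
for n ≤ 15 pairs), imaging metrics are correlated with clinical covariates
(age, SCOPA-GI, UPDRS-III off, disease duration) by Spearman rank
correlation, and p-values are Bonferroni-corrected within each test
family. 2×2 tables (e.g. gender) use the uncorrected Pearson chi-squared.

## Worked example

```python
from calmito import (
    CalciumSimParams, simulate_calcium_movie, chi2_2x2, dilution_factor,
)
from calmito.calcium import analyze_movie, register_to_first, rois_from_label_mask

# a 20-neuron ganglion, 60% true responders, high-K+ stimulus at 20-30 s
params = CalciumSimParams(n_neurons=20, responder_fraction=0.6, seed=42)
movie, truth = simulate_calcium_movie(params)

reg = register_to_first(movie)
rois = rois_from_label_mask(truth.label_mask)
calls, summaries = analyze_movie(reg.movie, rois)
s = summaries["highK"]
print(f"{s.stimulus}: {s.n_neurons} neurons, {s.pct_responders:.1f}% responders, "
      f"mean max amplitude {s.mean_max_amplitude_pct:.2f}%")
```

prints

```
highK: 20 neurons, 60.0% responders, mean max amplitude 11.63%
```

— the detector recovers all 12 simulated responders (12/20 = 60%); the
amplitude mean is over all 20 neurons (non-responders contribute ~0), so
it sits below the responders' ~20% true amplitudes.

```python
print(chi2_2x2([[4, 11], [11, 4]]))        # gender table, 4:11 vs 11:4 M:F
# chi2 = 6.533, p = 0.0106  (uncorrected Pearson)
print(dilution_factor(150, 6, "nl", "mm3"))   # 40.0   (dye into the biopsy)
print(dilution_factor(150, 500, "nl", "ul"))  # 3333.3 (dye into the bath)
```

## Command line

```sh
calmito simulate-calcium --seed 5 --out sim/          # movie + ROIs + truth
calmito analyze-calcium  --movie sim/movie.ome.tif --rois sim/rois.ome.tif \
                         --protocol protocol.yaml --out results/
calmito simulate-mito    --seed 5 --out simm/
calmito analyze-mito     --stack simm/stack.ome.tif \
                         --mask simm/ganglion_mask.ome.tif --out resultsm/
calmito cohort-stats     --summaries subjects.csv --out cohort.csv
calmito full-run         --out demo/ --seed 7 --pairs 6   # end-to-end fixture
```

Images are TIFF/OME-TIFF (voxel sizes read from OME metadata or given by
flag), protocols are YAML, outputs are CSV/JSON; every output directory
contains the resolved run configuration, and reruns with the same seed are
byte-identical.

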
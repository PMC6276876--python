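# furrowquant

Quantification toolkit for time-lapse fluorescence imaging of epithelial
invagination, built around the measurements used to study basal myosin-II
downregulation during *Drosophila* ventral furrow formation: basal and
apical myosin-II levels from axial intensity profiles, actomyosin-ring
constriction kinetics, 3D cell-shape features from tracked label volumes,
and pulsatile/ratchet apical-constriction statistics — plus a synthetic-data
generator that produces all of these inputs with known ground truth.

It is intended for developmental biologists and image analysts who need a
scriptable, testable reimplementation of these measurements, and for anyone
benchmarking estimators of this kind against controlled synthetic data.

## The measurements

**Basal myosin z-profiles.** A region of interest is subdivided into a grid
of subregions; each subregion's mean intensity per z-slice is computed and
the profiles are averaged (area-weighted).  A Gaussian with constant offset,

&nbsp;&nbsp;&nbsp;&nbsp;I(z) = I₀ + A · exp(−(z − μ)² / 2σ²),

is fitted around the basal-side maximum.  The FWHM (2.355 σ) measures axial
signal spreading (*z-spread*); the *level* is the mean integrated density
per unit area over a 5-slice (5 μm) window centered at μ, above the fitted
offset.  Fold-changes are ratios of levels, each normalized to its initial
value, and level time-courses are summarized by least-squares polynomial
fits with r².

**Ring kinetics.** Contractile actomyosin rings at the cellularization
front are detected in basal projections by a circular Hough transform with
sub-pixel radial refinement.  Diameters are normalized to the mean of the
first time point and fitted with a line; the slope is the constriction
speed.  Tissue compaction is scored as ring density (detections per μm²)
inside versus outside a region mask.

**3D cell shape.** From a label volume, each cell yields per-slice areas
and centroids; derived features are length L = occupied slices × dz, apical
and basal areas (3-slice cap means), the A/B ratio = apical-cap volume /
basal-cap volume (1 = columnar, < 1 = apically constricted wedge), volume
V = Σ area·dz with a CV = 25% outlier filter, and apical anisotropy (axis
ratio of the second-moment ellipse).

**Pulses.** Apical-area traces are reduced to local maxima; the mean
inter-peak time is the pulsation period and the mean area difference
between consecutive peaks is the ratchet extent ΔA (positive = net
constriction per pulse).  Cells ending below half their initial area are
classed as constricting.

**Statistics.** Two-sample pooled t-test; one-way ANOVA with post hoc
Tukey HSD; Cohen's d = |x̄₁ − x̄₂| / s with s the maximal standard
deviation of the analyzed dataset (d ≤ 0.5 low, d ≥ 1 large); boxplot
summaries with type-7 quartiles, 1.5·IQR outliers and
median ± 1.57·IQR/√n notches.

## Worked example

Recover the constriction-speed ratio between an optogenetically activated
and a control ring field, then the basal-level fold-change read out by the
full z-profile pipeline:

```python
from furrowquant import scenarios

ratio, n = scenarios.ring_speed_ratio(seed=1)
print(f"constriction speed ratio: {ratio:.2f} ({n} ring observations)")

fold, _ = scenarios.basal_fold_change(seed=1)
print(f"basal myosin fold at 6 min: {fold:.2f}")

fwhm, _ = scenarios.z_spread_estimate(seed=1)
print(f"z-spread estimate: {fwhm:.2f} um")
```

prints

```
constriction speed ratio: 4.74 (480 ring observations)
basal myosin fold at 6 min: 1.60
z-spread estimate: 3.40 um
```

The first field constricts at 4.8% of its initial diameter per frame and
the control at 1.0%, so the pipeline's slope ratio of ~4.8 means the
detection + normalized-diameter fit recovers the generative kinetics; the
1.60 fold matches the saturating recruitment the myosin channel was
generated with; and a basal layer generated at 3.4 μm axial FWHM is
estimated at 3.40 μm, below the 4 μm spreading bound.

The same stages are scriptable from the shell:

```bash
furrowquant run --config cfg.yaml --out out/          # full pipeline
furrowquant segment stack.tif --pixel-size 0.2 --out labels.tif
furrowquant rings proj.tif --pixel-size 0.2 --rmin 1.5 --rmax 4.5 --out det.csv
furrowquant pulses traces.csv --min-prominence 1.0 --out pulse_stats.csv
furrowquant stats pulse_stats.csv --test anova --groups class \
    --value ratchet_extent --out report.csv
```

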
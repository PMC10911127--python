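# explantkit

Quantification toolkit for axis elongation in zebrafish blastoderm
explants and embryos: explant shape morphometrics, within-clone
dispersal statistics, best-fit-ellipse cell-alignment metrics, and
nuclear pSmad5/pSmad2 signaling-gradient profiles — together with a
synthetic-data generator that produces ground-truth-known fixtures for
every input class, so each analysis stage can be validated without any
microscopy data.

## Who this is for

Blastoderm explants are embryonic cell masses cultured without the yolk
cell; they self-elongate by convergence & extension (C&E), the
gastrulation movement that narrows a tissue mediolaterally while
extending it along the body axis. Quantifying that process from
microscopy requires a pipeline of small, well-defined measurements:
silhouette shape, how labeled cell clones spread, how cells orient
relative to the tissue axis, and how nuclear signaling activity (BMP via
pSmad5, Nodal via pSmad2) is distributed in space. `explantkit`
implements those measurements as a tested library with a thin CLI.

## The measurements

**Clone dispersal.** For a tracked clone, positions are projected along
the imaging (z) axis; at each time point, every cell's mean absolute
separation from all other clone cells is computed parallel and
perpendicular to the extension axis (defined by a stable back anchor and
time-interpolated tip anchors), averaged over cells, and reported
relative to the initial time point:

    D_par(t)  = mean_i mean_{j != i} | (x_i - x_j) . u(t) |,
    fold(t)   = D_par(t) / D_par(t0)

A clone advected by an anisotropic affine flow with endpoint scale
factors (s_par, s_perp) yields exactly those fold changes — the basis of
the parameter-recovery tests.

**Gradient profiles.** Per nucleus, the channel mean is
background-corrected (mean of cytoplasmic spot means, subtracted) and
divided by the DAPI mean, which cancels depth-dependent attenuation
common to both channels. Distances to an operator-defined reference
contour on the high-intensity side are normalized to the sample maximum
and binned at width 0.04 (explants) or 0.02 (embryos, ~two cell
diameters); edge bins covering the outer 4% are excluded, and values are
reported relative to the control group's high-side bin.

**Shape.** Circularity 4πA/P² on the traced (smoothed) boundary
polygon; extension detection via boundary concavities; normalized
extension length along a skeleton midline; geodesic width profiles
(8-connected chamfer distance from a central reference box); domain
length/width ratios and area fractions; embryonic axis-length/height
ratio.

**Alignment.** The cell's orientation is the major-axis angle of the
moment-equivalent ellipse of its traced outline; its deviation from the
mediolateral axis is folded into [0°, 90°], paired optionally with the
nuclear 6-px-circle intensity readout.

**Statistics.** All group comparisons are normality-gated:
D'Agostino–Pearson per group (Shapiro–Wilk for small n), then t-test /
one-way ANOVA or Mann–Whitney / Kruskal–Wallis, with Holm-corrected
pairwise post-hocs after omnibus tests.

## Worked example

```python
from explantkit import dispersal, profiles, synth

# a clone advected by the wild-type-like flow preset (2.02 / 0.88 over 260 min)
table, axis, _ = synth.simulate_clone_flow(synth.wild_type_flow(seed=1))
curves = dispersal.dispersal_curves(table, axis)
fp, fq = dispersal.fold_change(curves, 260.0)
print(f"parallel fold over 260 min:      {fp:.3f}")
print(f"perpendicular fold over 260 min: {fq:.3f}")

# a noisy exponential signaling gradient, decay length 0.2 of the axis
params = synth.GradientParams(profile_shape="exponential", decay_length=0.2,
                              intensity_cv=0.10, seed=1)
nuclei, contour, truth = synth.simulate_gradient_nuclei(params)
nuclei = profiles.distance_to_reference(nuclei, contour)
nuclei = profiles.background_subtract(nuclei,
                                      {"psmad5": truth["background_level"]})
prof = profiles.build_profile(nuclei, bin_width=0.04)
print(f"reported bins: {int(prof.reported.sum())} of {len(prof.values)}")
print(f"fitted decay length: {profiles.fit_exponential_decay(prof):.3f}")
call = profiles.classify_profile(prof)
print(f"profile call: {call.label} (end ratio {call.end_ratio:.1f})")
```

prints

```
parallel fold over 260 min:      2.020
perpendicular fold over 260 min: 0.880
reported bins: 23 of 25
fitted decay length: 0.204
profile call: graded (end ratio 49.7)
```

The fold changes recover the flow preset exactly (the statistic is the
inverse of the construction); the binned profile keeps 23 of 25 bins
after edge exclusion; the decay length re-estimated from the binned
curve is within 2% of the 0.2 ground truth despite 10% intensity noise,
and the profile is called graded rather than radial.

The same operations are available from a shell:

```sh
explantkit synth --kind flow --seed 1 --out tracks.csv
explantkit disperse --tracks tracks.csv --axis tracks.axis.csv \
    --t-end 260 --out curves.csv
```

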
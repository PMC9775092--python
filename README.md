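# cardiomorph

Quantitative analysis pipeline for rodent studies of cardiovascular risk in
nonalcoholic fatty liver disease (NAFLD): cardiomyocyte cross-section
morphometry, liver collagen quantification, atherogenic lipid ratios,
circulating-miRNA relative expression, and the group statistics that tie
them together. A fully seeded synthetic-data generator provides
ground-truthed images and tables for every stage, so the whole pipeline can
be validated end to end without any animal data.

It is written for experimental hepatology/cardiology groups who quantify
diet-induced steatohepatitis models: the typical raw materials are H&E
fields of heart cross-sections, picrosirius-red liver fields, a serum
chemistry panel, and RT-qPCR Ct tables with a cel-miR-39 spike-in.

## The quantities it computes

**Cardiomyocyte irregularity index (CII).** Each cross-sectioned cell is
measured for area plus four dimensionless shape descriptors and scored as

```
CII = aspect − area/box + roundness + radius ratio
```

where *aspect* is the major/minor axis ratio of the moment-equivalent
ellipse, *area/box* the area over the minimum bounding rectangle (π/4 for
an ellipse), *roundness* = perimeter²/(4π·area), and *radius ratio* the
max/min centroid-to-boundary distance. A perfect circle scores
CII = 3 − π/4 ≈ 2.215; every form of irregularity raises the score. Cells
are then gated on the (area, CII) plane against thresholds derived from the
control population into six classes — N (normal), I (irregular), HR/HI
(hypertrophic regular/irregular), AR/AI (atrophic regular/irregular) — and
summarised per animal as class percentages, mean CII, and the coefficient
of variation of area.

**Collagen fraction.** Picrosirius-red fields are reduced to a stained area
fraction (red-dominance rule `R − (G+B)/2` with an Otsu threshold) and a
mean stain intensity, averaged over fields into a per-animal score.

**Atherogenic ratios.** From the serum lipid panel: Castelli's risk index
CRI-I = TC/HDLc, CRI-II = LDLc/HDLc, and the atherogenic coefficient
AC = (TC − HDLc)/HDLc (identically CRI-I − 1).

**miRNA fold changes.** Relative expression by 2^−ΔΔCt, with
ΔCt = Ct(target) − Ct(cel-miR-39) and ΔΔCt referenced to the arithmetic
mean ΔCt of the control group per target.

**Group statistics.** Shapiro–Wilk normality gate on every group; one-way
ANOVA + Tukey HSD when all groups pass, Kruskal–Wallis + Dunn's test
(Holm-adjusted) otherwise; pairwise outcomes rendered as a compact letter
display (groups sharing a letter are not significantly different at α).

## Worked example

```python
from cardiomorph import (PopulationSpec, sample_cell_truth, render_field,
                         measure_cells, derive_thresholds, population_profile,
                         synthetic, MorphClass)

# a healthy reference animal and a hypertrophy-shifted animal
ctrl_spec = PopulationSpec(class_mixture={"N": 1.0}, n_cells=300, seed=1)
sick_spec = PopulationSpec(class_mixture={"N": 0.7, "HR": 0.2, "AR": 0.1},
                           n_cells=300, seed=2)

cells = {}
for name, spec in [("control", ctrl_spec), ("NAFLD", sick_spec)]:
    truths = sample_cell_truth(spec)
    _, mask = render_field(truths, synthetic.RenderConfig(seed=spec.seed))
    cells[name] = measure_cells(mask, pixel_size=spec.pixel_size)

thresholds = derive_thresholds(cells["control"])
profile = population_profile(cells["NAFLD"], thresholds, animal_id="NAFLD_01")
print(f"area band: {thresholds.area_low:.0f}-{thresholds.area_high:.0f} um^2, "
      f"CII cutoff: {thresholds.cii_high:.2f}")
print(f"N: {profile.percents[MorphClass.N]:.1f}%  "
      f"HR: {profile.percents[MorphClass.HR]:.1f}%  "
      f"AR: {profile.percents[MorphClass.AR]:.1f}%  "
      f"mean CII: {profile.mean_cii:.2f}")
```

prints

```
area band: 209-385 um^2, CII cutoff: 3.58
N: 69.3%  HR: 18.0%  AR: 10.0%  mean CII: 2.92
```

i.e. the classifier recovers the simulated 70/20/10 mixture from the
rendered images. The mean CII barely moves (the control population measures
2.91 under the same seed conditions) because this mixture shifts cell *size*,
not shape — shape-shifted mixtures raise it through the irregular classes.

A full simulated study (all modalities, three groups, statistics and a
Table-1-style summary) is one call — `cardiomorph report --seed 5 --out study/`
from the shell, or:

```python
from cardiomorph import run_study
results = run_study(seed=5, out_dir="study")
print(results["summary"].head())
```

The other CLI subcommands (`simulate`, `morphometry`, `collagen`, `ratios`,
`mirna`, `stats`) expose each stage separately for use on real images and
tables; run `cardiomorph --help`.

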
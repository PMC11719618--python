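# filametry

Quantification of the yeast-to-filamentous (pseudohyphal) transition from
whole-colony photomicrographs, with nonparametric dose-response inference.
Built for assays in which yeast colonies — e.g. *Dekkera* (*Brettanomyces*)
species grown on nitrogen-limiting agar — are dosed with quorum-sensing
aromatic alcohols (2-phenylethanol, tryptophol) and the degree of
filamentous outgrowth must be scored objectively across hundreds of colony
images.

## The measurement

Each colony image passes through a six-stage segmentation chain:

1. standardize to a fixed working resolution (2560 × 1920 by default,
   aspect-preserving with background padding),
2. grayscale conversion (Rec.601 luminance, 0.299 R + 0.587 G + 0.114 B),
3. Gaussian smoothing (5 × 5 kernel),
4. binarization (manual intensity threshold or Otsu auto-threshold),
5. filling of enclosed voids left by overlapping/merging filaments,
6. contour extraction: the **outer** boundary enclosing the colony mass
   plus all filamentous protrusions (area *A*<sub>outer</sub>) and the
   **inner** boundary of the central colony mass, isolated by morphological
   opening with a disc structuring element (area *A*<sub>inner</sub>).

The filamentation index is the relative area excess

> *f* = (*A*<sub>outer</sub> − *A*<sub>inner</sub>) / *A*<sub>inner</sub>,

a dimensionless fraction: ≈ 0 for a round colony, ≈ 2 for a strongly
induced pseudohyphal halo.

Downstream, per-group (strain × compound × concentration) screening uses
Iglewicz–Hoaglin modified z-scores *M*ᵢ = 0.6745 (*x*ᵢ − median)/MAD with
exclusion at |*M*ᵢ| > 3.5, and dose-response inference uses the
tie-adjusted Kruskal–Wallis omnibus test followed by Dunn's pairwise
post hoc comparisons,

> *z* = (R̄ᵢ − R̄ⱼ) / √[(N(N+1)/12 − Στ/(12(N−1))) (1/nᵢ + 1/nⱼ)],

with Bonferroni adjustment over the k(k−1)/2 dose pairs.

Because raw colony photographs from published assays are rarely deposited,
the package ships a synthetic-colony generator (`filametry.synthetic`)
that renders whole-colony images with analytically known
*A*<sub>inner</sub>/*A*<sub>outer</sub> ground truth, and simulates
per-group f-measure samples moment-matched to published group means/SDs —
so the entire chain is testable end to end.

## Worked example

```python
import math
from filametry import (ColonySpec, Filament, PipelineConfig, process_image,
                       render_colony, default_designs, simulate_fmeasures,
                       dose_response_report)

# a synthetic colony: 100 px disc plus eight 50 x 10 px filaments
spec = ColonySpec(
    image_width=440, image_height=440, inner_radius=100,
    filaments=tuple(Filament(angle=2 * math.pi * k / 8, length=50, width=10)
                    for k in range(8)),
    noise_sd=4.0, seed=0,
)
image, truth = render_colony(spec)
record = process_image(image, PipelineConfig(resolution=(440, 440)), colony_id="demo")
print(f"true f = {truth.f_true:.3f}")
print(f"measured f = {record.f:.3f}")

# dose-response inference on a simulated five-dose panel
design = default_designs(seed=1)[("D. bruxellensis", "2-phenylethanol")]
report = dose_response_report(simulate_fmeasures(design))
res = report[("D. bruxellensis", "2-phenylethanol")]
kw = res["kw"]
print(f"Kruskal-Wallis: N = {kw.total_n}, chi2({kw.df}) = {kw.chi2:.1f}, p = {kw.p:.3g}")
print(res["dunn"].head(4).round(3).to_string(index=False))
```

prints

```
true f = 0.134
measured f = 0.128
Kruskal-Wallis: N = 419, chi2(4) = 237.9, p = 2.69e-50
 condition_1  condition_2  rank_mean_diff     se       z  p_adj
         0.0         10.0         -31.735 19.929  -1.592    1.0
         0.0         50.0        -123.664 17.180  -7.198    0.0
         0.0        100.0        -232.288 17.820 -13.036    0.0
         0.0        200.0        -205.179 18.955 -10.824    0.0
```

The eight 50 × 10 px spokes add ≈ 4 200 px² to a π·100² ≈ 31 400 px² disc,
hence *f* ≈ 0.13; the pipeline recovers it within a few percent. In the
simulated panel the control vs 10 µM pair shows no effect (adjusted p = 1)
while every contrast against ≥ 50 µM is overwhelming — higher doses carry
higher mean ranks, hence the negative rank-mean differences.

## Command line

```bash
filametry generate --kind images --n 20 --seed 7 --out data/      # synthetic colonies
filametry full-run --manifest data/manifest.csv --out results/    # f + summary + tests
filametry generate --kind values --design db-2pe --out sims/      # simulated f tables
filametry summarize --fmeasures sims/fmeasures.csv --out sums/
filametry infer     --fmeasures sims/fmeasures.csv --out stats/
```

`full-run` emits `fmeasures.csv`, `group_summary.csv`, `exclusion_log.csv`,
`kruskal_wallis.csv`, one `dunn_<compound>.csv` per compound, optional QC
contour overlays (`--qc`), a `run.log`, and a frozen `run_config.json`.
Manifests are CSVs with columns `file, colony_id, strain, compound,
concentration_uM`.

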
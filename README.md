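# mopane

Analysis toolkit for woodland-structure and elephant-impact surveys of
mopane (*Colophospermum mopane*) woodland, the mono-dominant savanna
woodland of semi-arid southern Africa.  Elephants convert tall mopane
woodland to low "hedged" woodland by pollarding (snapping) main stems; the
relict emergent trees that are too thick to snap can still be killed slowly
by bark stripping, which triggers canopy dieback and, eventually,
windthrow.  This package implements the survey formats, estimators and
statistics needed to quantify that process from nested belt-transect field
data, for plant ecologists and protected-area scientists.

## What it computes

* **Crown volume by height layer.**  Each crown is a solid of elliptical
  cross-section defined by the two measured canopy diameters `d1 >= d2`,
  the canopy depth, and one of seven shape archetypes (spheroid, cylinder,
  cones, domes, lens).  The volume between heights `z_lo` and `z_hi` is the
  closed-form integral `V = pi (d1/2)(d2/2) * depth * (F(t_hi) - F(t_lo))`,
  with `F` the antiderivative of the squared radius profile, so per-layer
  volumes sum exactly to the crown total.
* **Damage estimators.**  Canopy loss is scored in nine ordinal percent
  classes (0, 1–5, 6–10, 11–25, 26–50, 51–75, 76–90, 91–99, 100, midpoints
  0, 3, 8, 18, 38, 63, 83, 95, 100).  Plot percentages are weighted means:
  stem cross-sectional area for tree canopy loss, stem circumference for
  bark loss, measured crown volume `V_M` for new shrub loss and the
  reconstructed pre-damage volume `V_R = V_M · 100/(100 − %loss)` for old
  shrub loss, with weights rescaled per hectare across belt widths.
* **Structure and attrition.**  Per-plot densities, canopy volumes and
  species richness; tree height distributions; the partition of a stem
  population by impact category; and the fate classification of a matched
  emergent-tree cohort (intact / lost a main stem / lost completely) with
  the simple per-annum attrition rate `(n_lost/n_cohort)/years × 100`.
* **Inference.**  Paired and Welch t-tests, Pearson chi-square, two-way
  ANOVA with Type II sums of squares, Tukey HSD, Benjamini–Hochberg
  adjustment, binary logistic regression (e.g. pollarding probability
  `logit p = 4.5596 − 10.0834 d` against stem diameter `d` in metres), and
  3-parameter logistic curve fits `y = A/(1 + exp(−k(x − x0)))` for canopy
  dieback against percent debarking and for the height–diameter allometry.
* **Synthetic woodland.**  A seeded generator reproduces the statistical
  structure of surveys under low, intermediate and high elephant-density
  regimes and forward-simulates pollarding, debarking, dieback and
  windthrow, so every stage of the pipeline runs and is testable with no
  external data.

## Worked example

Simulate the high-density regime, apply elephant impacts, resurvey after
eight years and summarise the emergent-tree cohort:

```python
import pandas as pd
from mopane import (regime_config, simulate_plot, apply_elephant_impacts,
                    simulate_resurvey, structure_metrics,
                    classify_emergent_fates, annual_attrition_rate)

cfg = regime_config("high", seed=42)
surveys, truths = [], []
for i in range(cfg.n_plots):
    base = simulate_plot(cfg, f"gnp_p{i+1:02d}")
    impacted = apply_elephant_impacts(base, cfg)
    later, truth = simulate_resurvey(impacted, cfg, years=8)
    surveys.append(impacted)
    truths.append(truth)

m = structure_metrics(surveys[0])
print(f"plot {surveys[0].plot_id}: total canopy volume "
      f"{m.total_canopy_volume:,.0f} m3/ha, live trees "
      f"{m.live_tree_density:.0f} /ha, pollarded stems "
      f"{m.pollarded_stem_density:.0f} /ha")

truth = pd.concat(truths, ignore_index=True)
fates, summary = classify_emergent_fates(truth)
n_lost = sum(f.fate == "lost_completely" for f in fates)
rate = annual_attrition_rate(summary["n_trees"], n_lost, years=8)
print(f"emergent cohort: {summary['n_trees']} trees / {summary['n_stems']} "
      f"stems; {summary['stem_pct']['standing']:.1f}% of stems standing after 8 y")
print(f"annual attrition: {rate:.2f}% per annum")
```

which prints

```
plot gnp_p01: total canopy volume 33,254 m3/ha, live trees 181 /ha, pollarded stems 132 /ha
emergent cohort: 120 trees / 142 stems; 75.4% of stems standing after 8 y
annual attrition: 2.92% per annum
```

The first line is the hedged-woodland structure of one simulated plot: a
large canopy volume held low, with most main stems pollarded.  The last two
lines follow the tall relict trees: about three quarters of their large
stems survive the eight-year interval, and the cohort shrinks by a few
percent per year through debarking-driven windthrow and stem loss.

The same analyses are available from the shell:

```sh
mopane simulate --seed 1 --out fixtures/
mopane structure fixtures/high_p01 fixtures/low_p01 --out results/
mopane attrition --cohort fixtures/high_p01 \
    --resurvey fixtures/high_p01_resurvey --years 8 --out results/
```

## Layout

| module | contents |
| --- | --- |
| `mopane.survey_model` | domain records, transect design, CSV/JSON survey I/O |
| `mopane.canopy_geometry` | shape archetypes, crown/slab volumes, layer profiles |
| `mopane.damage_metrics` | damage scale, `V_R`, weighted percent-damage estimators |
| `mopane.structure_attrition` | structure metrics, height bins, stem impacts, cohort fates |
| `mopane.inference` | t-tests, chi-square, ANOVA, Tukey, BH, GLM and curve fits |
| `mopane.synthetic_woodland` | regime configs, plot simulator, impact/resurvey dynamics |
| `mopane.cli_pipeline` | `mopane` command-line interface |

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations.
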
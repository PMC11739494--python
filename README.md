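# domtrace

Molecular-level groundwater quality from direct-infusion high-resolution
mass spectrometry (DI-HR-MS) of dissolved organic matter (DOM).

Shallow groundwater is purified as water percolates from the soil into
aquifers. When hydroclimatic extremes open fast preferential flow paths,
surface-derived organic molecules reach the groundwater unprocessed. Because
a DOM spectrum contains thousands of molecular features, compositional
similarity between groundwater and soil-seepage DOM is a far more sensitive
indicator of this ingress than bulk dissolved-organic-carbon concentration.
`domtrace` implements the complete analysis chain for long-term monitoring
campaigns — and ships a synthetic-campaign generator with known ground truth
so that every stage can be validated by parameter recovery.

It is written for biogeochemists and hydrogeologists running (or simulating)
DOM monitoring programmes: peak lists in, a quality-trend report out.

## The indicator

For TIC-normalized spectra *u*, *v* aligned on common features, the
percentage similarity is

```
PS = (1 − BC(u, v)) · 100,     BC(u, v) = Σ|uᵢ − vᵢ| / Σ(uᵢ + vᵢ)
```

(for normalized columns, equivalently `PS = 100 · Σ min(uᵢ, vᵢ)`). Each
groundwater sample is referenced against **all** soil-seepage spectra of its
site and the values averaged, buffering against surface heterogeneity. The
quarterly PS series per well is decomposed by STL (seasonal-trend
decomposition by LOESS; period 4, seasonal window 5, trend/seasonal degree
1), piecewise linear slopes are fitted around a drought breakpoint, and
Kendall/Spearman rank statistics quantify trends and the association with
radiocarbon (F¹⁴C) measurements.

Upstream of the indicator sits the spectral cleaning chain — S/N > 10
filtering with Kendrick-defect noise estimation, homologous-series
recalibration to < 1 ppm, 95 %-cumulative blank subtraction, duplicate
replicate intersection, TIC normalization — and CHON₀₋₄S₀₋₁ molecular-formula
assignment. Downstream, assigned formulas are mapped to metabolic pathways,
constrained per well by metagenome-derived pathway presence (MAG profiles),
filtered (≥ 10 formulas or ≥ 25 % of pathway length detected), and screened
for positive rank correlation with PS under Bonferroni control (p < 0.01).

## Worked example

```python
from domtrace.pipeline import RunConfig, run_pipeline
import pandas as pd

report = run_pipeline(RunConfig(seed=1), write_outputs=False)
ps = pd.DataFrame(report["ps_table"])
print("groundwater samples:", len(ps))
print("PS range: %.1f - %.1f" % (ps.mean_ps.min(), ps.mean_ps.max()))
print("assigned intensity fraction: %.3f"
      % report["stages"]["assignment"]["assigned_intensity_fraction_mean"])
for well, entry in report["trend"].items():
    print(f"{well}: STL trend change = {entry['stl']['trend_change']:+.2f} pp")
sig = [r["pathway_id"] for r in report["screen"] if r["significant"]]
print("significant pathways:", sig)
print("planted:", report["stages"]["pathways"]["enriched_truth"])
```

prints

```
groundwater samples: 96
PS range: 58.7 - 71.7
assigned intensity fraction: 0.819
well-1: STL trend change = +8.56 pp
well-2: STL trend change = +6.40 pp
well-3: STL trend change = +8.67 pp
significant pathways: ['pw000', 'pw001', 'pw002', 'pw003', 'pw004', 'pw005']
planted: ['pw000', 'pw001', 'pw002', 'pw003', 'pw004', 'pw005']
```

The default configuration simulates an eight-year campaign (three wells,
quarterly duplicates, recurring seepage references, blanks, a repeated
in-house reference standard) in which the seepage mixing fraction rises from
0.2 towards 0.5 with a step at the July 2018 drought. The PS series recovers
that rise (≈ +7 to +9 percentage points of trend per well), roughly 82 % of
spectral intensity receives a formula, and the Bonferroni screen finds
exactly the six pathways planted as seepage-enriched, with no false
positive.

The same chain is available from the shell:

```
domtrace simulate out/ --seed 1          # synthetic campaign -> peak lists
domtrace run-all --outdir run/ --seed 1  # full pipeline -> report.json
```

plus `preprocess`, `assign`, `similarity`, `trend` and `pathways`
subcommands for stage-wise use on existing peak lists.

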
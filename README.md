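# aquapore

Tools for the quantitative core of an aquaporin functional characterization:

- **Oocyte swelling kinetics** — simulate and estimate the osmotic water
  permeability *P*<sub>f</sub> and apparent solute permeability
  *P*<sub>sol</sub> of *Xenopus* oocytes from silhouette-area time series.
- **Silhouette imaging** — turn grayscale oocyte frames into area time
  series (Otsu threshold, largest component, hole filling).
- **Sequence hallmarks** — annotate aquaporin signatures on cDNA records:
  longest ORF, molecular weight and isoelectric point, NPA boxes, the
  C-terminal motif, Kyte–Doolittle hydropathy segments, ar/R
  selectivity-filter mapping by global alignment, and degenerate in-silico
  PCR.
- **qPCR expression** — relative quantification by the Livak
  2<sup>−ΔΔCt</sup> method with replicate structure and the usual
  screen-then-test group statistics.
- **Synthetic data** — seeded generators for every input class, with
  ground-truth files, so the whole pipeline is testable offline.

## The model

An oocyte transferred to a hypotonic bath swells as water follows the
osmotic gradient. With silhouette area *A* normalized to the first frame,
relative volume is *V*/*V*₀ = (*A*/*A*₀)<sup>3/2</sup> (spherical cell),
and the water permeability is

> *P*<sub>f</sub> = *V*₀ · d(*V*/*V*₀)/d*t* / [*S* · *V*<sub>w</sub> · (Osm<sub>in</sub> − Osm<sub>out</sub>)]

with *V*₀ = 9×10⁻⁴ cm³, *S* = 0.045 cm², *V*<sub>w</sub> = 18 cm³/mol,
Osm<sub>in</sub> = 202 and Osm<sub>out</sub> = 59 mmol/kg by default.  In
an isotonic solute bath the volume gain tracks solute entry and

> *P*<sub>sol</sub> = d(*V*/*V*₀)/d*t* · (*V*₀/*S*).

The forward simulator integrates d*V*/d*t* =
*P*<sub>f</sub>·*S*·*V*<sub>w</sub>·(c<sub>in</sub>(t) − c<sub>out</sub>)
with conserved internal solute; the estimator fits the initial slope of
*V*/*V*₀ by ordinary least squares.  Expression analysis computes
rq = 2<sup>−ΔΔCt</sup> per biological replicate against a configurable
reference gene and calibrator condition.

## Worked example

```python
from aquapore import (AssayConstants, simulate_swelling, estimate_permeability)

constants = AssayConstants()          # standard oocyte assay constants
trace = simulate_swelling(7.77e-3, constants, dt=15, duration=300,
                          noise_sd=0.005, seed=1)
est = estimate_permeability(trace, "pf", constants, window_s=120)
print(f"Pf = {est.value:.3e} cm/s (slope {est.slope:.3e} 1/s, r2 {est.fit_r2:.4f})")
```

prints

```
Pf = 7.163e-03 cm/s (slope 9.218e-04 1/s, r2 0.9786)
```

a Pf within ~8% of the simulated 7.77×10⁻³ cm/s — the small deficit is
the curvature of the swelling curve over the 120-s fit window, plus the
0.5% area noise.  The same workflow is available from the shell:

```sh
aquapore synth swelling --seed 1 --out data/
aquapore estimate data/traces.csv --kind pf --out data/estimates.csv
```

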
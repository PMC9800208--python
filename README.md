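# myocycle

Analysis of myosin motor function from the full suite of standard in vitro
assays, with a matched synthetic-data simulator so every analysis stage is
verifiable by parameter recovery. Built for motor-protein biochemists and
single-molecule biophysicists comparing myosin isoforms (e.g. cardiac
β-MyHC against slower orthologs such as MYH7b).

## What it computes

The chemomechanical cycle of actomyosin is characterized by a small set of
measurable quantities, each with its own assay and model:

| Assay | Model | Parameters |
|---|---|---|
| NADH-coupled ATPase | v = k<sub>cat</sub>[actin]/(K<sub>M</sub>+[actin]) | k<sub>cat</sub>, K<sub>M</sub>, t<sub>cycle</sub>=1/k<sub>cat</sub>, k<sub>cat</sub>/K<sub>M</sub> |
| Stopped-flow, ATP-induced dissociation | k<sub>obs</sub> = K₁k₊₂[ATP]/(1+K₁[ATP]) | K₁k₊₂, k₊₂, 1/K₁ |
| Stopped-flow, ADP competition | k<sub>obs</sub> = k₀/(1+[ADP]/K<sub>ADP</sub>) | K<sub>ADP</sub> |
| mant-ATP single turnover | A·e<sup>−k_slow·t</sup>+(1−A)·e<sup>−k_fast·t</sup>, Y₀=1, plateau=0 | %SRX = 100·A, %DRX, rates |
| Three-bead optical trap | variance/mean-shift event detection; truncated-exponential MLE; time-forward/time-reversed ensemble averages | detachment rate, step size d, substeps d₁, d₂ |
| In vitro motility | Hessian-ridge detection (2–6 px fibers), skeleton pruning, linear-assignment tracking | sliding velocity |
| Markov state models | T = rownorm(C + 1/n); implied timescales −τ/ln λᵢ | π, timescales |

Each module in `myocycle.simkit` generates the corresponding raw data
(plate absorbance traces, fluorescence transients, 20 kHz bead positions,
TIFF movie stacks, state trajectories) from known ground truth with
seeded noise.

## Worked example

Recover Michaelis–Menten parameters from a simulated plate:

```python
from myocycle import atpase, simkit

ds = simkit.make_atpase_plate(
    kcat=0.80, Km=35.9, basal=0.03,
    actin_concs=[10, 15, 20, 30, 45, 60, 80, 100],
    noise_sd=0.001, seed=1)
fit, points, log = atpase.analyze_plate(
    ds.observables["wells"], ds.observables["well_map"],
    ds.observables["standards"], ds.observables["myosin_conc_uM"])
print(f"kcat = {fit.kcat:.3f} 1/s, Km = {fit.Km:.1f} uM, "
      f"t_cycle = {fit.t_cycle:.2f} s")
```

prints

```
kcat = 0.800 1/s, Km = 35.9 uM, t_cycle = 1.25 s
```

i.e. the maximal per-head ATPase rate, the actin concentration at
half-activation, and the implied total cycle time of one head. The same
pattern (simulate → analyze → compare with ground truth) works for every
assay; the command line mirrors it:

```sh
myocycle simulate atpase --seed 3 --out sim/
myocycle atpase --plate sim/plate.csv --standards sim/standards.csv \
    --map sim/well_map.json
myocycle report --d-total 5.3 --t-on 0.01   # predicted sliding velocity
```

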
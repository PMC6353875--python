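# cspfit

NMR chemical-shift-perturbation (CSP) titration analysis for
protein–peptide interactions, built around the study of the EZH2
SRM-SANT1 domain reading the histone H4 tail. For NMR spectroscopists
and structural biologists who have assigned ¹H-¹⁵N HSQC peak lists from
a ligand titration and want, reproducibly and scriptably:

* per-residue normalized CSPs  Δδ = √(ΔδH² + (0.20·ΔδN)²),
* significance classification by the trimmed threshold
  (mean + 1.0/1.5 sample SD after removing the 10% largest Δδ),
* per-residue dissociation constants from the **ligand-depletion**
  isotherm — required at the millimolar protein concentrations of an
  HSQC titration, where the hyperbola is badly biased —

      Δδ = Δδmax · ((L+P+K_d) − √((L+P+K_d)² − 4PL)) / (2P),

* a global K_d with outlier exclusion (≥ 2 SD) and lower-limit
  ("> min K_d") reporting when the titration never saturates,
* mapping of perturbed residues onto construct regions (SRM, linker,
  α1/α2/α3 helices, loops),
* export of ambiguous interaction restraints (AIRs) for data-driven
  docking,
* and a strand-aware "within 150 bp" genomic peak-overlap utility for
  ChIP-seq co-occurrence summaries.

A synthetic-data generator produces titrations from the same forward
model with known ground truth, so the whole pipeline is testable
without any spectrometer data.

## Worked example

Simulate a noiseless titration of a 60-residue construct at
[P] = 0.1 mM, ligand ratios 0–32, true K_d = 0.3 mM, then analyze it:

```sh
cspfit simulate --kd 0.3 --noise-sd 0 --seed 9 --out sim/
cspfit fit --design sim/design.yaml --out fits.tsv
```

which prints

```
Kd = 0.3 +/- 4.48e-15 mM (n=14)
```

i.e. the pipeline identified the significantly perturbed residues,
fitted each one's trajectory, excluded none of substance (the
aggregation retained 14 residues) and recovered the ground-truth
affinity exactly; the per-residue estimates are in `fits.tsv`. The full
pipeline with all tables and a report:

```sh
cat > run.yaml <<EOF
design: sim/design.yaml
outdir: out
EOF
cspfit run --config run.yaml
```

```
Titration analysis: synthetic-protein + synthetic-ligand(kd=0.3mM)
  points: 7  ligand 0-3.2 mM  [P]=0.1 mM
  classified residues: 60 (trimmed 6 for thresholds)
  significance thresholds: 0.0648 / 0.0873 ppm (1.0 / 1.5 SD)
  significant residues passing the 0.02 ppm floor: 15
  result: Kd = 0.3 +/- 4.48e-15 mM (n=14)
```

A titration whose residues move only by noise instead reports
`result: NB (no binding detected)`. Other subcommands: `csp`,
`classify`, `map`, `restraints`, `overlap`, `simulate-beds`
(see `cspfit --help`).

As a library:

```python
from cspfit import read_titration, analyze_series

series = read_titration("sim/design.yaml")
res = analyze_series(series)
print(res["result"], res["global_kd"].describe())
```

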
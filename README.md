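# pbpkflow

Offline, high-throughput physiologically based pharmacokinetic (PBPK) batch
simulation for chemical risk assessment and early drug discovery.

Screening hundreds of compounds through a PBPK simulator normally means
hand-collecting physicochemical and in-vitro PK data for each one, deciding
a pile of modelling assumptions, and clicking through one simulation at a
time. `pbpkflow` automates the whole loop against **local database
snapshots** (no network access required): curation with a fixed source
hierarchy and per-field provenance, a conservative rule-based assumption
engine, a whole-body Monte-Carlo population simulator, and cross-compound
reporting — all driven by a single compound file.

## What it computes

For each compound the pipeline:

1. curates MW, logP, pKa, PSA, HBD and compound characterisation from a
   ChEMBL-like snapshot (falling back to a SusDat-like snapshot for
   compounds absent from it), and fu, blood:plasma ratio (*BP*) and hepatic
   intrinsic clearance (*CL*int) from three httk-style experimental tables,
   reduced by a user-chosen operation (arithmetic/geometric mean, median,
   min, max);
2. applies the assumption rules: ionisation classification from raw pKa
   lists (≤ 2 selected values, clamped to [0, 14]), PSA/HBD defaults and
   caps, *BP* = 0.55 for acids without a measurement, HSA/AGP binding by
   basicity, Henderson–Hasselbalch LogD₇.₄, Kilford fu,hep, and a PSA/HBD
   regression for jejunal permeability *P*eff;
3. predicts fu, *BP*, *V*ss and *K*d for every compound from
   physicochemical data alone (the prediction module), and simulates a
   virtual population (ages 20–55, equal sex ratio) through a
   perfusion-limited whole-body model with

   * tissue:plasma partition coefficients *K*p by Method 1
     (Poulin–Theil–Berezhkovskiy, ionisation-blind) or Methods 2–3
     (Rodgers–Rowland composition equations, ionisation-aware),
   * well-stirred hepatic clearance
     CL_H = Q_H·fu_B·CLu,int / (Q_H + fu_B·CLu,int) when CLint is known,
   * the conservative renal-only fallback CL_R = fu·GFR when it is not,
   * oral (first-order, ka and fa from *P*eff), intravenous (30-s infusion)
     and dermal (single-layer depot) routes;
4. extracts noncompartmental summaries (AUC, AUC∞, Cmax in 10 tissues,
   Tmax, half-life, clearances, fa/fg/fh, accumulation index) per subject,
   aggregates them across the population, and writes one SQLite result
   store per compound plus CSV summary tables and JSON-serialisable plot
   payloads (profiles, relationships, distributions, comparisons).

See `docs/methods.md` for every equation, constant and design choice.

## Worked example

Build a synthetic nine-compound batch (4 data-rich, 4 intermediate, 1
data-poor — the poor compound exists only in the SusDat-like snapshot with
MW and logP) and run it end to end:

```python
from pbpkflow import (FixtureSpec, SimulationConfig, WorkflowConfig,
                      build_snapshot_fixture, run_workflow)

paths, truth = build_snapshot_fixture(FixtureSpec(seed=3), "demo/fixture")
config = WorkflowConfig(
    compound_file=paths.compound_file,
    snapshot=paths.snapshot,
    output_dir="demo/results",
    simulation=SimulationConfig(n_subjects=15, duration_h=48.0,
                                dose=25.0, seed=42),
)
result = run_workflow(config)
print(f"simulated {len(result.simulations)} compounds")
cols = ["code", "cmax_plasma_mean", "cmax_plasma_sd", "half_life_mean",
        "cl_tot_mean", "vss_pred_mean"]
print(result.summary_table[cols].round(2).to_string(index=False))
```

which prints:

```
simulated 9 compounds
code  cmax_plasma_mean  cmax_plasma_sd  half_life_mean  cl_tot_mean  vss_pred_mean
  A1            123.47           16.39          103.37        11.30          21.54
  A2              0.43            0.08           20.18        68.65           6.40
  A3              4.12            0.65           21.65        49.10          12.26
  A4              4.12            0.64            7.64        60.64           0.27
  A5             73.45           11.94            5.94        21.28           1.02
  A6             26.71            3.91           47.68        15.94           8.88
  A7              1.00            0.13           48.11        20.00           5.79
  A8             39.61            6.27           49.50        46.44          72.82
  A9           1103.80          126.73           14.32         2.98           0.79
```

Each row is a population mean (15 virtual subjects) after a single oral
25-mg dose: Cmax in plasma (ng/mL) with its inter-subject SD, terminal
half-life (h), total systemic clearance (L/h) and predicted Vss (L/kg).
A9 is the data-poor compound: with no CLint found anywhere, the pipeline
assumes it cannot be cleared hepatically and applies the renal-only
fallback CL_R = fu·GFR — hence its much lower clearance (2.98 L/h) and
high plasma exposure relative to the hepatically cleared compounds.
`demo/results/` now holds `curated_data.csv`, `predictions.csv`,
`summary.csv` and one SQLite store per compound under `stores/`.

The same batch from the shell:

```bash
pbpkflow fixture --out demo/fixture --seed 3
pbpkflow run --compound-file demo/fixture/compounds.csv \
             --snapshot demo/fixture/snapshot.sqlite \
             --out demo/results --n-subjects 15 --duration-h 48 \
             --dose 25 --seed 42 --explain
```

Real batches replace the fixture with your own compound file
(CSV/XLSX with Code, Compound, InChIKey, SMILES headers, optional
VssMethod/Dose/DoseUnits columns) and a snapshot SQLite built from locally
licensed database dumps (schema in `pbpkflow.data_collection.SNAPSHOT_SCHEMA`);
optional experimental (Code/FU/BP/CLINT) and additional-physchem files
override or supplement the automatic curation.

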
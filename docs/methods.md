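# Methods

This note documents the models, rules and numerical choices behind
`pbpkflow`, in the order the pipeline runs them.

## Scope and model overview

`pbpkflow` is an offline, high-throughput batch pipeline for physiologically
based pharmacokinetic (PBPK) simulation of organic compounds in healthy
adult humans. It automates three stages:

1. **Data collection** — physicochemical properties (MW, logP, pKa, PSA,
   HBD, compound characterisation) and experimental PK parameters (fu, BP
   ratio, CLint) are curated from local SQLite snapshot databases with a
   fixed precedence hierarchy and per-field provenance.
2. **Assumption engine** — a conservative rule set turns the curated record
   into a simulator-ready parameter set (ionisation classification, range
   clamps, binding-protein choice, LogD7.4, fu,hep, Peff).
3. **Simulation and reporting** — a whole-body perfusion-limited ODE model
   is integrated for a Monte-Carlo virtual population; per-subject and
   population PK summaries, plot payloads and per-compound SQLite result
   stores are produced.

Kinetics are linear throughout: no enzyme saturation, no transporters, no
gut-wall metabolism (fg ≡ 1), single dose only.

## Data curation rules

* **Hierarchy.** The ChEMBL-like table is queried first by InChIKey; only
  compounds absent from it fall through to the SusDat-like table (which
  carries MW, logP and CAS/DTXSID identifiers only). A ChEMBL-sourced field
  is never overwritten by a SusDat value.
* **Experimental tables.** CAS/DTXSID are resolved through the SusDat-like
  table; DTXSID match is preferred, CAS is the fallback (the pairing is what
  makes registry matching reliable). Replicate rows within the in-vitro
  table (`chem_phys`) come from a single source and are arithmetic-averaged
  per compound before anything else. A user-chosen operation — arithmetic
  mean, geometric mean, median, minimum or maximum — then reduces the
  per-database fu and CLint values to one number; the sample SD across ≥2
  per-database values is kept. BP is available from one table only, so no
  cross-database operation applies. A geometric mean over values that
  include zero is undefined; the pipeline falls back to the arithmetic mean
  with a warning. Passing `None` as the operation keeps all values and marks
  the table not simulation-ready.
* **User files.** The additional-physchem file either overrides or yields to
  the automatically curated values (one flag), and always fills gaps. The
  experimental file is threshold-filtered (default threshold 0: values ≤ 0
  are discarded), then either wins outright (`mean_flag=False`) or is
  averaged with the httk-derived value (`mean_flag=True`). When exactly one
  database value and one user value are averaged, no SD is reported.
* Systemic clearance (CLsys) is extracted and stored but never consumed.
* A compound-file row carrying a dose but no dose units inherits the
  run-level unit setting.

## Assumption engine

* **Ionisation classification** (no declared type): 0 pKa → neutral; 1 pKa
  → monoprotic acid if < 7 else monoprotic base; 2 pKa → diprotic acid
  (both < 7), diprotic base (both ≥ 7) or ampholyte (one each side); > 2 pKa
  → all > 7 keeps the two largest (diprotic base), all < 7 the two lowest
  (diprotic acid), mixed keeps the two farthest from 7 (equidistant ties
  prefer the larger value, keeping the ampholyte class reachable) and
  re-applies the two-value rules. Selected values are clamped to [0, 14]
  *after* selection. A declared characterisation is honoured and selection
  proceeds within it. The widely circulated description of the two-pKa rule
  inverts the acid/base sides relative to the one-pKa rule; the default here
  is the self-consistent version (acids below 7), with a
  `literal_diprotic_rule` switch for the inverted wording.
* **PSA/HBD**: missing values are assumed 0; PSA is clamped to [0, 300] Å²
  and HBD to [0, 20]. All clamps are idempotent.
* **BP of acids**: acids without a measured BP ratio default to 0.55 — at
  blood pH 7.4 an acid is ionised and excluded from the erythrocytes, and
  the haematocrit:plasma split is 0.45:0.55. Tunable (`bp_acids`), or
  disabled in favour of prediction.
* **Binding protein**: a base with selected pKa above the threshold
  (default 7) binds α1-acid glycoprotein (AGP); everything else binds human
  serum albumin (HSA).
* **LogD7.4** is recomputed from logP and the selected pKa values with the
  Henderson–Hasselbalch correction (two-proton extension for diprotic
  species; zwitterion-free approximation for ampholytes) rather than
  trusting extracted LogD values, for cross-compound consistency; a flag
  restores the extracted value.
* **fu,hep** uses the Kilford hepatocyte-incubation binding regression
  `fu,hep = 1/(1 + 125·VR·10^(0.072 X² + 0.067 X − 1.126))` with
  VR = 0.005 (10⁶ cells/mL); X is logD7.4 for acids/ampholytes and logP for
  bases/neutrals, following that regression's convention.
* **Peff** (human jejunal effective permeability) uses the PSA/HBD
  regression `log10 Peff[cm/s] = −2.546 − 0.011·PSA − 0.278·HBD`. Its
  applicability envelope (16.2 ≤ PSA ≤ 154.4, 60 ≤ MW ≤ 455, HBD ≤ 5) is
  checked and violations produce a "Peff extrapolation" warning on the
  compound.

## Parameter prediction

The prediction module deliberately ignores measured fu/BP so it always
shows the in-silico route:

* **fu** from a logit-linear lipophilicity regression
  `fu = 1/(1 + 10^(0.52·X − 0.20))` (X as in the Kilford convention). The
  coefficients are of the Lobell–Sivarajah family and are stand-ins chosen
  to reproduce typical plasma-binding trends; no printed reference equation
  exists for the proprietary engine being emulated, so all acceptance
  checks on prediction are property-based (monotone in lipophilicity,
  bounded in (0, 1]).
* **BP** from red-cell partitioning of the unionised unbound fraction:
  `BP = (1 − hct) + hct·fu·(f_ni·10^(0.3·logP) + 0.5)` with f_ni the
  neutral-species fraction at pH 7.4. Ionised acids barely enter the cells,
  so their predicted BP approaches 1 − hct from above.
* **Vss** from the tissue-composition Kp model (below) on the reference
  male subject.
* **Kd** by inverting the single-site binding isotherm,
  `Kd = fu·[P]/(1 − fu)`, with plasma protein concentrations
  [HSA] = 646 µM and [AGP] = 22 µM. fu = 1 yields an infinite-dilution
  marker (`inf`), not an exception.

## Tissue partitioning (Vss methods 1–3)

Tissue:plasma partition coefficients use standard human tissue-composition
data (fractional extracellular/intracellular water, neutral lipid, neutral
phospholipid, acidic phospholipid content and tissue:plasma albumin ratios)
collected in one table in `pbpk.py`; the carcass-like "rest" compartment is
muscle-like.

* **Method 1** — Poulin & Theil partitioning with the Berezhkovskiy
  tissue-binding correction; lipophilicity only, pKa never enters.
* **Method 2** — Rodgers & Rowland composition equations. Moderate-to-strong
  bases (pKa ≥ 7) bind acidic phospholipids, with the association constant
  back-calculated from the blood-cell partitioning implied by the compound's
  BP ratio; acids, neutrals and weak bases bind extracellular protein, with
  the residual association back-calculated from fu. Intracellular pH is 7.0
  (7.22 in erythrocytes), plasma pH 7.4. Only the neutral species crosses
  membranes.
* **Method 3** — as Method 2, plus a small fraction
  (`IONIC_MEMBRANE_FACTOR = 0.05`) of the ionised species partitioning into
  membrane lipids. For a neutral compound Methods 2 and 3 are analytically
  identical.

`Vss = (V_plasma + V_cells·E:P + Σ_t V_t·Kp_t)/BW` with
`E:P = (BP − (1 − hct))/hct`; a self-consistency recomputation of this sum
is enforced to < 1e−9 relative.

## Virtual population

Healthy adults aged uniformly 20–55 years, equal male/female probability.
Body weight is lognormal per sex (median 78/65 kg, σ_log 0.15/0.17), height
normal per sex, BSA by Du Bois, haematocrit normal around 0.45 (M) / 0.40
(F). GFR is normal around an age-adjusted mean (115 mL/min/1.73 m² at 20,
−0.4 per year, SD 12, floor 40). Organ volumes scale with body weight and
flows with BSA from the ICRP-style reference bodies in `physiology.py`; the
"rest" flow closes the circuit exactly so that the sum of non-pulmonary
flows equals the cardiac output. A set seed reuses the same subjects for
every compound of a batch; without a seed each compound gets fresh draws.

## Whole-body simulation

Perfusion-limited compartments for lung (in series with the arterial/venous
blood pool, split 1/3 arterial, 2/3 venous), brain, heart, kidney, skin,
muscle, adipose, rest, and the splanchnic organs (gut, spleen, pancreas)
draining through the portal vein into the liver.

* **Clearance switch.** With a CLint value the liver is the only eliminating
  organ: incubation CLint (µL/min/10⁶ cells) is divided by fu,hep and scaled
  by hepatocellularity (99·10⁶ cells/g) and liver weight (density
  1.05 g/mL); elimination in the ODE acts on unbound liver outflow, so the
  well-stirred clearance `CLH = QH·fu_B·CLu,int/(QH + fu_B·CLu,int)`
  (fu_B = fu/BP) emerges, strictly increasing in CLint and bounded by
  hepatic blood flow. Without CLint the compound is conservatively assumed
  to be cleared only renally at `CLR = fu·GFR` (glomerular filtration of
  unbound drug from arterial plasma), with zero hepatic clearance.
* **Oral**: first-order absorption from a lumen depot into the liver via the
  portal route, `ka = 2·Peff/r` with intestinal radius r = 1.75 cm and
  `fa = 1 − exp(−ka·T_SI)` with transit time T_SI = 3.32 h; the unabsorbed
  fraction goes to a sink so mass balance closes. fg ≡ 1;
  fh = 1 − CLH/QH.
* **Intravenous bolus**: a 30-second zero-order infusion into venous blood
  (never an instantaneous impulse).
* **Dermal**: a single-layer formulation depot on the back (60 cm²,
  0.005 cm, 1 g/mL) transferring first-order into the skin compartment at a
  Potts–Guy permeation rate, `log kp[cm/h] = −2.7 + 0.71·logP − 0.0061·MW`,
  divided by the formulation thickness.
* **Dose units**: mg used as-is; mg/kg × body weight; mg·m⁻² × BSA.
  Per-compound dose/units/Vss-method from the compound file override the
  run-level setting.
* **Numerics**: LSODA with rtol 1e−8 / atol 1e−10; output on a uniform
  0.1-h grid. The intravenous route adds a refined sampling window
  (0.002-h steps over the first 0.5 h) so the short infusion peak — and
  hence the AUC — is resolved on the output grid; without it the
  AUC = Dose/CLtot identity is violated by several percent purely through
  sampling. Mass balance (compartments + eliminated + unabsorbed depot =
  dose delivered) holds to < 1e−6 relative at every output time; doubling
  the dose doubles every concentration to integrator tolerance. An
  integration failure is recorded per compound and the batch continues.

## Noncompartmental summaries

AUC uses the linear-up/log-down trapezoid (exact on exponential declines).
The terminal phase is the strictly decreasing positive run at the end of
the profile after the global Tmax; among windows of the last 3..n of those
points the log-linear fit with the highest R² is used (ties keep more
points). R² < 0.9 flags the half-life as unreliable; a non-identifiable
phase (still absorbing, constant profile) leaves half-life and AUC∞
missing rather than fabricated. The accumulation index for the single-dose
run is reported as `1/(1 − exp(−kel·24 h))` by the default dosing-interval
convention. Population tables use the arithmetic mean and sample SD with
pairwise exclusion of missing values and per-parameter counts; SD is
missing at n = 1.

Plot payloads: profiles cap at 30 subjects (seeded subsampling, fixed per
compound); relationship plots report Pearson r and a least-squares line;
distributions use a Gaussian kernel with Silverman bandwidth; comparison
charts order alphanumerically or ascending by value.

## Synthetic snapshots — what they do and do not emulate

The fixture generator plants compounds in three availability tiers
mirroring the nine-compound exemplar batch (4 rich / 4 medium / 1 poor):
rich compounds carry a complete physicochemical record plus fu (two
sources), CLint (two sources, one with replicates) and BP; medium compounds
carry full physchem and CLint only; the poor compound exists only in the
SusDat-like table with MW and logP. The poor tier draws from MW
U[100, 200] and logP U[−0.5, 1.5] — emulating the small hydrophilic
acid-like compound class of the exemplar's data-poor member — so that its
renal-only kinetics reach an identifiable terminal phase within a 48-h run;
a lipophilic deep-distribution compound would leave the qualitative
slower-decline contrast unmeasurable at that duration. Every planted value
is recorded in a truth table for brute-force precedence checks.

What passing tests on these fixtures show: the curation precedence,
assumption rules, clearance switch and reporting machinery behave exactly
as specified, and the ODE engine satisfies its conservation and linearity
invariants. What they do not show: quantitative agreement with any
proprietary simulator or with in-vivo data — the fu/BP/Kd regressions are
published-form stand-ins, the snapshot values are synthetic, and identifier
strings are synthetic stand-ins shaped like InChIKeys/CAS/DTXSIDs.

## Problem sizes used in the shipped checks

The acceptance script runs the nine-compound batch with 10 subjects for
48 h (plus a 5-subject reproducibility pair, a 2-subject IV run of 168 h
for the AUC identity, and a 2-subject dose-linearity pair); the test suite
uses 2–10 subjects per simulation and one 45-subject run for the
profile-subsampling cap. These sizes were chosen so the full pipeline,
including double batch runs, completes in well under a minute on one CPU
while every property is exercised at full model fidelity.

## Known limitations

* Single dose only; no enzyme/transporter interactions; no mechanistic
  kidney or multi-layer dermis model; healthy adults only; human only.
* The fu/BP/Kd prediction constants are documented stand-ins — property
  tests, not value-matching, are the contract.
* The accumulation index is a convention (24-h interval) since no dosing
  schedule exists in a single-dose run.
* Tissue-composition and physiology constants are reference-table values;
  no inter-individual variability is applied to composition, only to
  anatomy, flows and GFR.
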
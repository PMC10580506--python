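# postmeal

Mealtime insulin dosing algorithms, postprandial CGM outcome metrics, a
synthetic meal-response simulator and crossover-trial analysis for
type-1 diabetes research.

## The problem

Carbohydrate counting (CC) is the guideline method for estimating the
mealtime insulin bolus in type-1 diabetes: grams of carbohydrate divided
by the insulin-to-carbohydrate ratio (ICR, estimated with the 500 rule,
ICR = 500/TDD g/U). But dietary fat and protein also raise glucose — with
a delayed, protracted excursion between roughly 1.5 and 6 h after the
meal — and CC ignores them. Fat-protein-unit (FPU) algorithms add insulin
for that load: the original Pankowska equation doses every 100 kcal of
fat/protein like 10 g of carbohydrate; the modified FPU algorithm halves
that demand, treating 200 kcal as one 10-g unit:

```
dose_CC  = carb_g / ICR
dose_FPU = (carb_g + 10 · round(pf_kcal / kcal_per_FPU)) / ICR,   pf_kcal = 4·protein_g + 9·fat_g
```

with `kcal_per_FPU` = 200 (modified) or 100 (Pankowska). Whether the
extra insulin improves 5-h postprandial glycemia without causing
hypoglycemia is the question crossover feeding trials answer: each
subject eats a normal-protein meal (NPM: 53 g carbohydrate, 32 g
protein, 17 g fat → 1 FPU) and a high protein-fat meal (HPFM: 35 g
carbohydrate, 49 g protein, 18.5 g fat → 2 FPU) under each dosing
algorithm, while a flash glucose monitor samples every 15 min for 300
min.

`postmeal` packages that whole pipeline for researchers who want to
prototype, test or reanalyze such designs without clinical data:

* **dosing** — CC, modified FPU and Pankowska boluses, FPU counting,
  dose ratios, pen-increment rounding (`postmeal.dosing`);
* **metrics** — window mean glucose, peak and time-to-peak, total and
  incremental AUC (net or positive-only), time in/above/below range
  (3.9–10 mmol/L), hypoglycemic episode detection, 30-min excursions and
  MAGE (`postmeal.metrics`);
* **simulation** — a seeded four-arm crossover CGM generator with an
  early carbohydrate rise, delayed protein/fat rise, dose-dependent
  insulin lowering, between-subject heterogeneity, AR(1) sensor noise
  and 15-g rescue carbohydrates (`postmeal.simulate`);
* **analysis** — paired t and exact Wilcoxon signed-rank comparisons of
  CC vs FPU within meal type, and an exact discordant-pair test for
  hypoglycemia (`postmeal.analysis`).

## Worked example

Dose the normal-protein meal for a patient with a total daily dose of
31.77 U (ICR = 500/31.77 = 15.74 g/U):

```
$ postmeal dose --meal npm.json --patient patient.json --algorithm fpu
meal: NPM  algorithm: FPU_MODIFIED
carb_equivalent_g: 63.00
fpu_raw: 1.405  fpu_counted: 1
carb_units: 3.368  fpu_units: 0.635
total_units: 4.003
delivered_units: 4.003
```

The meal's 281 kcal of protein and fat count as 1.405 raw FPU, rounded
half-up to 1 FPU, i.e. 10 extra grams of carbohydrate equivalent: the
bolus rises from 3.368 U (plain CC, `--algorithm cc`) to 4.003 U — a 19%
increase for this meal, independent of the patient's ICR.

Simulate a 30-subject crossover trial and compare algorithms:

```
$ postmeal simulate --seed 11 --out sim/
$ postmeal analyze --cgm sim/cgm.csv --out analysis/
$ postmeal trial-report --cgm sim/cgm.csv --manifest sim/manifest.json --out report/
```

`report/comparisons.tsv` lists, per meal type and outcome, the CC and
FPU arm means ± SE, the paired mean difference and its p-value;
`report/hypoglycemia.tsv` counts subjects with at least one reading
below 3.9 mmol/L per arm. Under the shipped calibration the FPU arm
lowers late (240–300 min) glucose after the high protein-fat meal and
shifts its peak earlier, while raising hypoglycemia frequency after the
normal-protein meal — the qualitative behavior such trials report.

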
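# swinegrowth

Post-inflection growth and carcass-trait analysis for pig herds.

Commercial lean-type breeds (e.g. Yorkshire) and indigenous fat-type breeds
(e.g. Qingyu) diverge sharply after the growth inflection point — the age at
which daily weight gain peaks and starts to decline. How muscle area, fat
deposition and meat quality change from that point onward determines both
the economics of feeding and the quality of the pork, so producers want to
know *where* the inflection lies, *when* the growth rate collapses (a proxy
for optimal slaughter age), and *which* traits keep responding to added
body weight versus plateauing.

`swinegrowth` is a library + CLI for exactly that workflow:

* **Growth modelling** — fit the logistic curve y(t) = A/(1 + B·e^(−Kt)) to
  longitudinal body weights (pooled per breed) and derive closed-form
  landmarks: inflection age ln(B)/K, inflection weight A/2, maximum daily
  gain A·K/4, and the maximum-deceleration age [ln B + ln(2+√3)]/K where
  the growth rate declines fastest.
* **Trait trajectories** — fit quadratic or asymptotic (y = a − b·e^(−c·bw))
  trait-versus-weight curves and detect plateaus with a transparent slope
  rule (slope < 10% of the in-range maximum).
* **Trait screening** — 10-kg weight-group binning, one-way ANOVA + Tukey
  HSD per trait, up/down/unchanged trend calls (ANOVA gate × sign of the
  Pearson correlation with body weight), correlation matrices, hierarchical
  clustering and PCA.
* **Relative expression** — 2^−ΔΔCt fold changes from tidy qPCR Ct tables
  (Livak group-mean calibration).
* **Synthetic herds** — a fully parameterized two-breed generator with
  known ground truth for every stage, so the whole pipeline is testable
  without animal data.

## Worked example

Landmarks from published population parameters of a lean breed
(A = 160.493 kg, B = 16.901, K = 0.022/d):

```sh
$ swinegrowth landmarks --params 160.493,16.901,0.022
{
  "inflection_age": 128.5169450807314,
  "inflection_weight": 80.2465,
  "max_daily_gain": 882.7115,
  "max_decel_age": 188.3786676682231,
  "max_decel_weight": 126.57683837652529
}
```

Read: this breed hits its fastest growth at 128.5 days / 80.25 kg, gaining
882.7 g/day at the peak; past 188.4 days (126.6 kg) the daily gain drops
faster than at any other age, so feeding beyond that point buys rapidly
diminishing returns.

Full pipeline on a synthetic herd:

```sh
$ swinegrowth simulate --out-dir sim --seed 11
$ swinegrowth report --weights sim/weights.csv --trait-table sim/traits.csv \
      --qpcr sim/qpcr.csv --out-dir out --seed 11
$ head -3 out/landmarks.csv
breed,n,pcc,A,B,K,P_BW,P_Age,MDG,max_decel_age,max_decel_weight
QYP,126,0.99373,138.023,20.1328,0.0160173,69.0115,187.444,552.69,269.665,108.855
YP,400,0.990692,160.203,16.9564,0.0220476,80.1017,128.388,883.027,188.12,126.349
$ head -5 out/plateaus.csv
breed,trait,model_form,plateau_weight,max_slope,threshold
QYP,LMA,asymptotic,,0.362787,0.1
QYP,IMF,asymptotic,111.439,0.185491,0.1
YP,LMA,asymptotic,128.089,1.99493,0.1
YP,IMF,quadratic,,0.0501594,0.1
```

The fitted curves recover the generating parameters (compare A, B, K with
the defaults above; fitted-vs-observed Pearson correlation ≥ 0.99), the fat
breed's maximum-deceleration age lands at ≈270 days versus ≈188 days for
the lean breed, and the plateau detector flags exactly the saturating
trajectories: lean-breed loin muscle area plateaus near 130 kg, fat-breed
intramuscular fat near 110 kg, while their linearly rising counterparts
yield no plateau. `out/trends.csv` classifies the 28 traits per breed
(here: 10 up / 2 down in the lean breed, 15 up / 5 down in the fat breed,
matching the generator's programmed truth), and `out/fold_changes.csv`
holds the 2^−ΔΔCt table. Every run writes `manifest.json` with the seed,
config hash and per-stage status.

See `docs/methods.md` for the model details, conventions and limitations.

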
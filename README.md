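# lefttrunc

Monte-Carlo quantification of left-truncation bias in pregnancy-cohort
estimates of the placental abruption–perinatal mortality association.

## The problem

Perinatal studies usually open cohort entry at 20 weeks of gestation, because
a clinical abruption diagnosis is rarely possible earlier. But abruption
*onset* and its chief precursor, abnormal placentation, arise around
implantation, and both sharply raise the risk of spontaneous abortion (SAB)
before 20 weeks. Entering the cohort late therefore selectively removes the
highest-risk pregnancies — a depletion of susceptibles — and the association
measured among survivors no longer answers the causal question posed for *all
conceptions*. This package simulates conception cohorts under a fully
specified generative model and measures exactly how much that delayed entry
distorts risks, risk differences (RD) and risk ratios (RR), separately for
normally and abnormally implanted pregnancies.

## The model

Each implanted conceptus carries four binary variables generated in sequence:

| variable | meaning | model |
|---|---|---|
| Z | abnormal placentation | Pr(Z=1) = π_Z |
| X | abruption onset (< 20 wk) | Pr(X=1\|Z) ~ U(0.005, 0.050) if Z=1, U(0.001, 0.020) if Z=0, drawn once per cohort per stratum |
| C | spontaneous abortion | Pr(C=1\|Z,X) = p_C · RR_CZ^Z · RR_CX^X (log-link, no interaction) |
| Y (or S) | perinatal mortality (or stillbirth) | 0 if C=1; else Pr = p_Y · RR_YM^M · RR_YZ^Z with diagnosis M = X |

SAB precludes the outcome, and the diagnosis M is deterministic: missing when
C=1, equal to the onset X when C=0. Each cohort is analysed twice, stratified
by Z:

* **unobserved scope** — the conception cohort: denominators are all
  conceptions per (Z, X) arm, SAB members contribute zero events;
* **observed scope** — entry at 20 weeks: denominators restricted to C=0.

The three bias estimands per stratum are `risk_obs − risk_unobs` per exposure
arm, `RD_obs − RD_unobs`, and `RR_obs / RR_unobs`. Writing q(x,z) for the
survival fraction 1 − Pr(C=1|x,z), the fold bias of the RR is exactly
q(0,z)/q(1,z) — per replicate and in expectation — so every simulated quantity
has a closed form (`lefttrunc.oracle`) against which the Monte-Carlo engine is
tested.

The full design is 80 setups: 10 primary perinatal-mortality setups (a 3×2×2
factorial over RR_CZ ∈ {2,4,6}, RR_CX ∈ {2,4.5}, RR_YZ ∈ {2,4}, minus the two
combinations whose implied Pr(C) exceeds 1), 30 mortality sensitivity setups
(π_Z = 0.2 and/or the alternative outcome pairing p_Y = 0.0120, RR_YM = 9.9),
and 40 stillbirth setups mirroring the first 40.

## Worked example

`examples/04_run_full_study.py` runs the complete primary study — 10 setups ×
200 replicate cohorts × 100,000 conceptuses, under a second via nested
binomial count sampling — and prints:

```
 stratum         quantity  sim_min  sim_max  analytic_min  analytic_max
      -1     sab_fraction   0.0557   0.0763        0.0557        0.0763
       0          rd_bias   0.0115   0.0266        0.0115        0.0263
       0 rr_relative_bias   1.0556   1.2275        1.0556        1.2258
       1          rd_bias   0.0454   0.4380        0.0459        0.4215
       1 rr_relative_bias   1.1238   8.4730        1.1250        8.0000

censoring by spontaneous abortion: 5.6% to 7.6%
normal placentation: RD bias +1% to +3%, RR overestimated 1.1- to 1.2-fold
abnormal placentation: RD bias +5% to +44%, RR overestimated 1.1- to 8.5-fold
```

Reading: between 5.6% and 7.6% of conceptions are censored by SAB depending
on the setup; restricting follow-up to ≥ 20 weeks inflates the
abruption–mortality RD by 1–3 percentage points when placentation is normal
but by up to ~42 points when it is abnormal, and multiplies the RR by up to
~8 — driven entirely by differential survival (q(0,1)=0.80 vs q(1,1)=0.10 in
the most extreme setup). Simulated spans sit on top of the analytic columns
except for the across-replicate *mean* of the RR fold bias, a ratio estimator
whose small exposed-abnormal cell (a few hundred conceptuses) inflates the
mean slightly above its large-cohort limit of 8.0 (see `docs/methods.md`).

The other examples cover the design grid (`01`), a single-cohort analysis
with the saturated log-binomial cross-check (`02`), and the closed-form
expectation tables (`03`). The same pipeline is scriptable from the shell:

```sh
lefttrunc run -f primary --seed 0 --out results/   # CSV bundle (+ figures with --figures)
lefttrunc grid --family all --out design.csv
lefttrunc oracle --family primary --out oracle.csv
lefttrunc compare --results-dir results/ --family primary
```

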
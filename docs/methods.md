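# Methods

## Generative model

The package simulates cohorts of implanted conceptuses with four binary
variables per conceptus, generated in causal order:

1. **Abnormal placentation** Z ~ Bernoulli(π_Z). Default π_Z = 0.1
   (the sensitivity families use 0.2).
2. **Abruption onset** X, the subclinical early event. Its probability is
   drawn once per cohort per stratum: Pr(X=1|Z=1) ~ U(0.005, 0.050) and
   Pr(X=1|Z=0) ~ U(0.001, 0.020). Abnormal placentation is the only cause of
   onset.
3. **Spontaneous abortion** C (< 20 weeks), a log-link (multiplicative) risk
   model: Pr(C=1|Z,X) = p_C · RR_CZ^Z · RR_CX^X, with baseline p_C = 0.05,
   RR_CZ ∈ {2, 4, 6}, RR_CX ∈ {2, 4.5} and no interaction (RR fixed at 1).
4. **Outcome** — perinatal mortality Y (stillbirth ≥ 20 weeks or neonatal
   death ≤ 28 days) or, in the stillbirth families, S alone. Deterministically
   0 when C = 1 (an aborted pregnancy can produce neither stillbirth nor
   neonatal death); otherwise Pr = p_out · RR_M^M · RR_Z^Z with the abruption
   *diagnosis* M equal to the onset X among survivors. Outcome pairings:
   (p_out, RR_M) = (0.0082, 14.5) or (0.0120, 9.9) for mortality and
   (0.0053, 14.5) or (0.0077, 9.9) for stillbirth, with RR_Z ∈ {2, 4}. The
   pairings keep the exposed-survivor baseline risk nearly constant
   (0.0082·14.5 ≈ 0.0120·9.9), so they trade baseline risk against the
   exposure effect rather than changing the exposed stratum's risk level.

The diagnosis M is never stored: it is missing when C = 1 and equals X when
C = 0, so it is recoverable from (X, C) and impossible states cannot be
represented.

### Design grid

The primary grid is the 3×2×2 factorial over (RR_CZ, RR_CX, RR_Z) minus the
two cells with RR_CZ = 6 and RR_CX = 4.5, whose fitted Pr(C=1|Z=1,X=1) =
0.05·6·4.5 = 1.35 is not a probability — leaving 10 setups. The published
design enumerates its setups only in supplementary material that is not
available as text, so this validity-filtered factorial is a reconstruction;
it is consistent with every printed summary we can check (the censoring range
endpoints, the bias spans, and the stated counts of 10/30/40 setups). The
three sensitivity blocks cross the same 10-setup core with π_Z = 0.2 and/or
the alternative outcome pairing; the stillbirth family mirrors all 40
mortality setups with the stillbirth pairings. Setups are ordered ascending
by (RR_CZ, RR_CX, RR_Z) so that setup ids are reproducible; no canonical
ordering is published.

## Sampling strategy

Within every (Z, X, C, outcome) cell conceptuses are exchangeable, so a
cohort is sampled as a chain of binomial splits (Z, then X | Z, then C | Z,X,
then outcome | Z,X,C=0) rather than 100,000 per-subject Bernoulli draws. The
two representations are distributionally identical; the count form makes a
full 80-setup study a sub-second computation. `to_individuals` expands counts
to per-subject records when a flat fixture is wanted.

The uniform abruption probability is drawn **once per cohort per stratum**
(`px_mode="per_cohort"`). The alternative reading — one draw per conceptus —
is marginally equivalent to fixing the probability at the support midpoint,
available as `px_mode="midpoint"`. The choice does not move any expectation
reported here: the marginal censoring proportion is linear in the drawn
probability (so the midpoint is exact for its mean), and the within-stratum
risks, RD and RR do not involve the draw at all. What the per-cohort draw
adds is realistic between-replicate variability, visible in the replicate
distributions.

Reproducibility: a master seed feeds a `numpy.random.SeedSequence` whose
spawn key includes the setup id, and each replicate gets an independent child
stream; the per-replicate seed is recorded in output provenance. Identical
configuration and seed reproduce byte-identical CSVs.

## Estimation

Each cohort is analysed twice per placentation stratum:

* **unobserved scope** (conception cohort): arm denominators are all
  conceptions with that exposure; SAB members count zero events;
* **observed scope** (entry at ≥ 20 weeks): denominators restricted to C = 0,
  exposure read from M (= X on C = 0).

Risks, RD and RR are closed-form cell arithmetic. The log-binomial regression
log Pr(outcome) = α0 + α1·X + α2·Z + α3·XZ is *saturated*, so its MLE equals
those empirical cell risks exactly; the package fits it (statsmodels GLM,
binomial family, log link, started at the closed-form solution) purely as an
equivalence cross-check. Using the closed form as the workhorse avoids the
known convergence fragility of iterative log-link binomial fitting when
fitted risks approach 1 — which happens here, since observed exposed risks
reach 0.47.

Degenerate replicates are flagged, not corrected: a zero denominator flags
every estimand of that stratum/scope, a zero unexposed risk flags the RR, and
zero exposed events flag the RR fold bias (0/0). Flagged values propagate as
NaN; aggregation excludes them and reports the exclusion count. At the design
size (100,000 conceptuses) exclusions are essentially absent; they matter
only for deliberately tiny test cohorts, where a transparent rule beats a
continuity correction.

## Bias estimands and aggregation

Per replicate and stratum: absolute risk bias per arm
(risk_obs − risk_unobs), absolute RD bias (RD_obs − RD_unobs), and relative
RR bias (RR_obs / RR_unobs). Because the two scopes share numerators and the
observed denominator is a subset, risk biases are nonnegative and the fold
bias collapses algebraically to q̂(0,z)/q̂(1,z), the ratio of empirical
survival fractions — an identity the tests assert exactly, replicate by
replicate.

Aggregation reports the across-replicate mean (point summary), median and
2.5–97.5 percentile band per setup, stratum and quantity, with exclusion
counts. Headline rounding: percentages to the nearest integer (censoring to
one decimal), fold biases to one decimal, half away from zero.

## Closed-form expectations

With q(x,z) = 1 − Pr(C=1|x,z) and r(x,z) the survivor outcome risk:
observed risk = r, unobserved risk = q·r, fold bias = q(0,z)/q(1,z) (the
outcome model cancels), RD bias = r(1,z)(1−q(1,z)) − r(0,z)(1−q(0,z)), and
marginal censoring = p_C Σ_z Pr(Z=z)·RR_CZ^z·(1 + (RR_CX − 1)·E[p_X|z]).
By construction stratum-0 quantities are independent of RR_CZ, RR_Z and π_Z,
and the fold bias is independent of the whole outcome model — both asserted
over the grid in tests.

## Numerical and statistical choices

* **Ratio-mean inflation.** The per-replicate fold bias is a ratio estimator;
  its across-replicate mean exceeds the analytic limit by roughly
  (1−q)/(n·q) in the smallest cell (Jensen's inequality). In the most extreme
  setup (RR_CZ=4, RR_CX=4.5) the exposed abnormal cell holds only ~50–500
  conceptuses of which ~10% survive, so at cohort size 100,000 the mean fold
  bias sits near 8.3–8.4 against the limit 8.0, while the median stays close
  to 8.0. Monte-Carlo consistency is therefore tested at 3 empirical standard
  errors for unbiased quantities (censoring, risks, RD, RD bias) and, for the
  fold-bias mean, as convergence at cohort size 10^6 (50 replicates, 2%
  relative tolerance).
* **Problem sizes.** Tests exercise the full published scale (200 replicates
  × 100,000 conceptuses for the primary grid and the stillbirth mirror) —
  seconds of work under count sampling. The reproduction script uses 2,000
  replicates per setup: the quantities it reports are across-replicate means
  whose integer-rounded extrema would otherwise flip on ~8% of seeds (the
  abnormal-stratum minimum RD bias, expectation 4.59%, sits 1.4 standard
  errors from the 4.5% rounding boundary at 200 replicates). Extra replicates
  tighten the measurement of the same estimand; cohort size and all
  generative parameters stay at their design values.
* **Validation vs malformedness.** A parameter set that is syntactically
  sound but implies a fitted probability above 1 is *invalid* (a verdict);
  negative, non-finite or out-of-domain fields are *malformed* (an
  exception). The grid builder applies the validity filter; the simulator
  refuses invalid setups outright.

## What the generator does and does not emulate

The generator reproduces the study's stated world: binary placentation and
abruption states, a single 20-week truncation point, SAB as the only
censoring event, and no induced abortion, no preeclampsia pathway, no direct
onset→diagnosis path independent of SAB. It does not model continuous
gestational age, measurement error in diagnosis, or confounding of the
SAB–outcome relation beyond Z. Passing tests therefore demonstrate the
internal mathematics of left-truncation bias under this mechanism — the
direction and magnitude claims — not the external validity of any particular
parameter value for a real obstetric population.

## Known limitations

* The exact published setup enumeration is reconstructed (see Design grid);
  any discrepancy would shift which setup attains an extremum, not the
  per-setup mathematics.
* The fold-bias *mean* at the design cohort size carries the finite-sample
  inflation described above; quote the median (or a larger cohort) when a
  central value for the ratio is wanted.
* No per-replicate confidence intervals are produced; the study's inferential
  object is the replicate distribution itself.
* The log-binomial cross-check requires events in every (Z, X) cell and is
  undefined otherwise — inherent to log-scale saturated coefficients, and
  flagged rather than patched.
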
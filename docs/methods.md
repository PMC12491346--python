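# Methods

## Decision trees and the effectiveness statistic

Both models are single-time-point diagnostic decision trees over
pretreated pediatric CNS tumor lesions. A strategy rates each lesion
*tumor relapse* or *treatment-related changes* (TRC); the rating is then
confirmed or overturned by neuropathology or clinicoradiological
follow-up. Chance nodes are, per strategy, the rating probability
`p_rated = P(rated relapse)` and two confirmation probabilities
`p_conf_rel = P(confirmed relapse | rated relapse)` and
`p_conf_trc = P(confirmed TRC | rated TRC)`.

The outcome is recall on the confirmed-TRC stratum:

    eff = (1 − p_rated)·p_conf_trc
          / [ p_rated·(1 − p_conf_rel) + (1 − p_rated)·p_conf_trc ].

No closed form for the outcome is printed alongside the trees; this
definition is adopted because it is the unique simple statistic that
simultaneously reproduces every published headline value (100% and 48% in
the two-strategy model, their 52% difference, 90% in the PET-triage
model) from the published node values. Two consequences worth noting:

* `p_conf_rel = 1` forces `eff = 1` independent of the other nodes — the
  combined PET+MRI arm, where all 54 relapse calls were confirmed.
* Consequently the ICER of the two-strategy model is *exactly* invariant
  to the combined arm's rating and TRC-confirmation nodes (N1, N4), which
  the one-way sensitivity analysis confirms.

An effectiveness value outside [0, 1] can only arise when some node value
exceeds 1; such values are tagged `theoretical` and propagated unclamped.
Base-case validation rejects them; sensitivity and Monte Carlo contexts
accept them, because pushing a node whose base value is 1 upward is part
of those analyses.

## Base-case inputs: reconstructed integer counts

The published node values are rounded percentages, which do not reproduce
the cent-level ratios. The canonical inputs are therefore exact count
ratios from reconstructed integer lesion tables:

* 83 lesions / 92 scans: combined reading 54 relapse calls (54 confirmed)
  and 29 TRC calls (21 confirmed TRC, 8 relapse); MRI-alone reading 68
  relapse calls (57 confirmed, 11 TRC) and 15 TRC calls (10 TRC, 5
  relapse). Shared ground truth: 62 relapse, 21 TRC.
* 22 lesions: 10 PET relapse calls (9 confirmed, 1 TRC) and 12 TRC calls
  (9 TRC, 3 relapse).

The test suite re-derives the 83-lesion table by brute-force search over
all integer tables consistent with the rounded percentages, the shared
ground-truth totals, the headline effectiveness values and the cent-level
ICER; the solution is unique. The joint split of the two readings among
confirmed-relapse lesions is *not* identified by these margins (any
agreement count between 49 and 54 works); the fixture uses the
maximum-agreement split, which affects no estimated node, effectiveness
or cost. Which 9 of the 83 lesions carry the second scan is likewise
arbitrary (costs depend only on the 92-scan total); the fixture assigns
them to the first nine lesion ids.

## Costing

Itemized outpatient fee-schedule amounts, summed exactly as decimals:
€1,566.33 per PET scan (6 items incl. €616.00 tracer production) and
€987.80 per MRI scan (8 items). Per-lesion cost = per-scan cost ×
n_scans/n_lesions (92/83, resp. 22/22), kept as an exact rational.
The ICER numerator is the per-lesion cost difference, which equals the
PET scan cost × 92/83 because both strategies share the MRI items.
Exact arithmetic gives ICER = €3,314.5121…; the published €3,314.51 is
matched within €0.05 (its exact intermediate rounding is unknowable).
Display rounding is half-up to whole percents and cents and happens
exactly once, at report time; machine outputs carry full precision.

## One-way deterministic sensitivity analysis

One node is swept over an interval, everything else at base; endpoints
are evaluated through the same base-case code path. Default intervals are
the count-ratio base ±0.15 for nodes with SD 0.08 and ±0.075 for nodes
with SD 0.04 (interval system inherited from adult-glioma
cost-effectiveness work). With these *unrounded* endpoints the published
sensitivity table is reproduced essentially to the cent — including the
theoretical relapse-confirmation row, whose upper endpoint is 1.075
(printed as 108 after rounding) — so the printed interval percentages are
read as rounded displays of `base ± 0.15/0.075`, not as the inputs
themselves. Arbitrary explicit intervals remain supported and the
published rounded endpoints give results inside the package's asserted
tolerances (±1.5 effectiveness points, ±2.5% on ratios).

Tornado rows are ordered by the absolute ratio range (no published
ordering rule exists); by that measure the MRI rating node N2 produces
the widest model-1 bar (€3,308.91) *and* the widest model-2 bar
(€261.06, slightly ahead of N1's €227.81). Undefined endpoints (zero
confirmed-TRC mass) carry explicit markers, never NaN.

## Probabilistic sensitivity analysis

10,000 parameter sets by default. Each node is drawn from
Normal(mean, SD) conditioned on > 0 via rejection — not absolute value or
clipping, so the shape is untouched where the distribution has mass (the
truncated mass is negligible for every bundled parameter). Draws above 1
are kept and flagged theoretical. Node means are the published rounded
percentages (65/82/100/72/84/67 and 46/90/75; SDs 8/8/4/4/4/4 and 8/4/4);
the PET-triage rating mean 46% is the published figure even though the
count ratio is 45.45%. Costs are gamma with mean equal to the model's
per-lesion (incremental) PET cost and CV 0.5, i.e. shape 4, scale
mean/4. Draws are mutually independent; no correlation structure is
published.

Per draw, each strategy's effectiveness and (for the two-strategy model)
the within-draw incremental difference are computed; draws with an
effectiveness denominator within 1e-9 of zero are excluded and counted
(> 1% exclusions aborts). The headline "mean ICER/CER" is the **ratio of
means** — mean cost divided by mean (incremental) effectiveness — which
is the published convention; the mean of per-draw ratios is reported
alongside but is heavy-tailed because the denominator can approach zero.
Percentiles are linear-interpolation order statistics; the SD uses the
n−1 denominator. A fixed seed reproduces the draw table bit for bit
(single `numpy` Generator, nodes drawn in canonical order, cost last).

Mean incremental effectiveness lands near 55% — above the deterministic
52% — because effectiveness is convex in the relapse-confirmation node
around 1; the mean MRI-arm effectiveness lands near 46% (below the
deterministic 47.6%) by the mirror-image concavity in its rating node.
Both shifts are properties of the stated distributions, not calibration.
The published free-text 95% CI strings are internally inconsistent (the
source itself notes its point estimates fall outside them), as is a 90th
percentile printed below the median; neither is modelled or asserted.

## Synthetic cohorts

`generate_cohort` emulates lesion-level data by binomial sampling through
the tree. For the two-strategy model, both readings concern the same
lesion, so a lesion's confirmed diagnosis is a single latent truth: truth
is drawn first (prevalence implied by the tree), then each strategy's
rating conditional on truth, with conditionals back-solved from the node
values via Bayes. Node sets whose two branches imply different
confirmed-TRC prevalences, or whose back-solved conditionals leave
[0, 1], admit no joint distribution and raise an explicit inconsistency
error; `nodes_from_latent` builds guaranteed-consistent node sets from
latent parameters for simulation studies. Generated cohorts are i.i.d.
across lesions with conditionally independent readings — they do not
emulate serial scanning correlation, reader drift, patient-level
clustering (several lesions per patient) or case-mix heterogeneity, so
passing recovery tests demonstrates estimator correctness under the
model's own assumptions, not robustness to those real-data features.

## Numerical and design choices

* Fees: `Decimal`; probabilities/ratios: `Fraction`; Monte Carlo: float64.
* Undefined quantities (no confirmed-TRC mass, |IE| < 1e-9) raise typed
  errors or carry explicit markers — never silent division or NaN.
* Effectiveness denominator tolerance 1e-12 (deterministic) / 1e-9 (PSA).
* Rejection sampling budget: 1000 redraw rounds (only pathological
  mean/SD combinations can exhaust it).
* Problem sizes: parameter-recovery checks run at up to 100,000–200,000
  lesions (binomial SE small enough to detect estimator bias); PSA checks
  run at the production 10,000 draws.

## Known limitations

Single time point, per-lesion perspective: no downstream treatment costs,
discounting, willingness-to-pay thresholds, acceptability curves, or
value-of-information analysis; no currency conversion (German fee
schedule only). Effectiveness is a purely diagnostic quantity — recall on
confirmed-TRC lesions — not a patient outcome. The reconstructed counts
are a model of the published summaries, unique under the published
rounding, but not a substitute for the underlying patient-level data.
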
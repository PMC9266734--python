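# Methods

This note documents the models and estimators implemented in penmark,
the defaults and why they were chosen, what the synthetic cohorts do and
do not emulate, and the package's known limitations.

## 1. CT-scale conventions

CT (cycle threshold) is approximately −log2 of template abundance.
All arithmetic is done on the CT / −ΔCT scale:

* replicate aggregation: arithmetic mean of determined replicate CTs
  (equivalently the geometric mean of abundances). No outlier rejection
  by default; an optional mode drops the replicate farthest from the
  median when the replicate SD exceeds 0.5 cycles.
* detection filter: an mRNA-panel reaction is kept only when CT < 24
  (strictly); the boundary value 24.0 is excluded. The filter is applied
  after aggregation (per-replicate filtering is a plausible alternative
  the data do not distinguish; post-aggregation was chosen as the
  default because the aggregate is the quantity analysed downstream).
  miRNA assays are not filtered by default; the scope is configurable.
* normalisation: −ΔCT(s, t) = mean of the reference CTs in sample s
  minus CT(s, t). Combining references by the arithmetic mean of CTs is
  the geometric mean of their abundances, the standard choice on a log
  scale. Samples missing any reference value are dropped with a warning.
* fold change between groups: FC = 2^(mean −ΔCT in group 1 − mean −ΔCT
  in group 2). FC(1 vs 2) · FC(2 vs 1) = 1 exactly, and adding a
  constant to every CT of a sample cancels in −ΔCT (both are tested as
  properties).

## 2. Reference-gene stability

Candidate endogenous controls are ranked by a two-group
variance-decomposition model of the kind used for data-driven reference
selection in qPCR panels. Within each group g the CT values of the I
candidates form a two-way layout

    z_igj = alpha_ig + b_gj + eps_igj,     eps_igj ~ N(0, sigma²_ig),

with gene effects alpha, sample (loading) effects b, and gene-specific
residual variance. With residuals r_igj = z_igj − mean_j − mean_i +
mean_ij and S_ig = Σ_j r²_igj / (n_g − 1), the expectation
E[S_ig] = sigma²_ig (1 − 2/I) + mean_i sigma²_ig / I yields the
bias-corrected, truncated estimator

    sigmâ²_ig = max( (S_ig − S̄_g/(I−1)) · I/(I−2), 0 ).

The systematic between-group behaviour of candidate i is the doubly
centred gene-by-group deviation d_ig of its group mean. Treating the
true deviations as draws from N(0, gamma²), gamma² is estimated by
moment matching (the raw sum of d² minus its sampling-noise expectation,
truncated at zero), and each d_ig is shrunk by the usual factor
gammâ² / (gammâ² + v_ig) with v_ig = sigmâ²_ig / n_g. The stability
value of a candidate set C (|C| = k) combines bias and noise:

    rho_C = mean_g ( |mean_{i∈C} d̃_ig| + sqrt( (1/k²) Σ_{i∈C} (v_ig + ṽ_ig) ) ),

where ṽ is the posterior variance of the shrunken deviation. Lower is
more stable; a candidate constant in every sample and group scores
exactly 0. Ranking (k = 1) and the default reference pair (k = 2, all
pairs evaluated, ties broken lexicographically) both use rho.
An independent scalar-loop implementation of the same equations serves
as the test oracle; the implementation matches it to 1e-10 on random
instances. Candidates missing in more than 20% of samples are excluded
with a warning; at least 3 usable candidates are required (the I/(I−2)
correction needs I ≥ 3).

The mRNA side selects its reference pair this way from the candidate
controls; the miRNA side uses the panel's fixed endogenous miRNA pair
and is not stability-selected.

## 3. Statistical primitives

All tests are two-sided. Statistics are computed from their defining
formulas; only distribution tail functions come from scipy.

* **t-test**: pooled-variance Student by default ("Student's t-test" as
  conventionally reported); Welch available. Zero pooled variance with
  equal means gives t = 0, p = 1; with unequal means p = 0, flagged
  degenerate.
* **chi-square**: Pearson X² on r × k tables, df = (r−1)(k−1), no
  continuity correction by default — this choice reproduces the printed
  p-values of the motivating cohort report from its printed counts;
  Yates correction is a flag.
* **Fisher exact** (2 × 2): two-sided p sums hypergeometric
  probabilities ≤ the observed one (relative tie tolerance 1e-12);
  verified against exact-rational full enumeration.
* **Mann–Whitney U**: ties counted ½. Exact permutation p (tail
  doubling; the null distribution is symmetric) when both n ≤ 8 and no
  ties; otherwise normal approximation with tie correction and 0.5
  continuity correction.
* **Pearson correlation**: pairwise-complete; p from
  t = r sqrt((n−2)/(1−r²)); fewer than 3 complete pairs or zero
  variance yields an explicitly degenerate (not erroneous) result so
  screens can record and skip it.
* **ROC/AUC**: empirical curve with tied scores traversed as a single
  diagonal segment; the trapezoidal area and the Mann–Whitney identity
  U/(n₁n₂) are both computed and must agree to 1e-12 at construction.
  The AUC is reported as computed plus its flipped value 1 − AUC.
* **Benjamini–Hochberg**: monotone step-up, provided as an opt-in
  (the screening analyses report unadjusted p-values, matching the
  small-panel convention of the motivating study design).

## 4. Pair screen

All gene × miRNA combinations are enumerated (no target-prediction
filtering). Selection keeps pairs with min(p_localized, p_metastatic) ≤
0.1, *inclusive*; because two independent looks are taken, the null
selection rate is 1 − 0.9² = 0.19, and the calibration experiment
checks both the per-group rate (0.10) and the combined rate (0.19).

The pair score defaults to the difference of −ΔCT values — the log2
ratio of gene to miRNA expression. The literal arithmetic quotient
(−ΔCT_gene)/(−ΔCT_miRNA) is implemented as a mode but is not the
default: it is scale-dependent and unstable near zero (samples with
|denominator| < 1e-9 become undefined).

Discrimination ability of a score is orientation-free — a score whose
AUC is a discriminates exactly as well as its negation with 1 − a, and
a planted repression-gain pair (miRNA up, gene pulled down in the
metastatic group) naturally scores *below* 0.5 as computed. The top-pair
flag therefore applies the strict > 0.8 cutoff to the
orientation-corrected AUC max(a, 1 − a), while both raw values are
reported.

Correlation classes use α = 0.05 per group: positive/negative when
significant with that sign, else none; undefined correlations are
"unknown" and excluded from disruption counts. Disrupted = classes
differ; repression-gain = localized ∈ {none, positive} and metastatic
negative.

## 5. Survival screen

* **Median dichotomization**: high ⇔ −ΔCT > median; values equal to the
  median are low, so odd n gives ⌈n/2⌉ low samples. An all-equal marker
  is degenerate and skipped with a reason.
* **Kaplan–Meier**: product-limit estimator; subjects censored exactly
  at an event time remain at risk for that time.
* **Log-rank**: two-group chi-square (df = 1) with the hypergeometric
  variance term. With no tied event times it equals the Cox score test
  at β = 0 (checked numerically). Known property: in very small cohorts
  with heavy censoring the chi-square approximation is anticonservative
  (≈0.06 rejection at nominal 0.05 for 24 subjects with ~50% censoring
  — reproduced identically by reference libraries); the calibration
  experiment therefore uses 50-subject cohorts, where the rate is
  nominal.
* **Cox proportional hazards**: Newton–Raphson maximisation of the
  Breslow partial likelihood (tied event times share a denominator over
  the full risk set), step-halving to guarantee ascent, convergence
  tolerance 1e-8 on the update, at most 50 iterations. Breslow was
  chosen as the default tie method because monthly follow-up times make
  ties routine and it is the simplest consistent choice; the
  implementation matches scikit-survival's Breslow fits to better than
  1e-8 on random tied datasets. Wald HR confidence intervals match the
  (HR, 95% CI) presentation convention. A fitted |β| > 10 is reported
  as `monotone_likelihood` — the regime where a covariate perfectly
  orders the events, the partial likelihood has no interior maximum and
  the Wald interval explodes (the signature of extreme intervals such as
  HR ≈ 115 with CI 0.71–18810 in small single-institution cohorts); the
  estimate and interval are still reported, flagged.
* **Screen**: per marker, KM + unadjusted log-rank on the median split,
  then Cox on the high/low indicator plus adjustment covariates.
  Defaults: cancer-specific survival adjusts for lymph-node metastasis
  and perineural invasion; overall survival is unadjusted. The Cox
  covariate is the dichotomized indicator (matching the high-vs-low
  HR presentation), not continuous −ΔCT.

## 6. Synthetic cohorts

The generator emulates the statistical structure the screens assume:

    CT(s, a, rep) = baseline_a − expression(s, a) + loading_s + tech noise,

with assay baselines ~ N(20, 1) cycles, per-sample loading offsets
~ N(0, 0.5) (removed by reference normalisation), biological −ΔCT noise
0.25 cycles for targets, 0.2 for endogenous controls (stable biology),
and replicate technical noise 0.15 cycles, emitted in triplicate.
Group effects add the planted log2 fold change to the metastatic
samples' latent expression; couplings add slope_group × (miRNA latent
deviation) to a gene's latent expression before replicate noise, so
planted correlations are interpretable; survival times are exponential
with log-hazard linear in designated targets' centred latent expression,
independently exponentially censored (rate set from the target censoring
fraction) and administratively capped at 62 months. OS and CSS are
independent draws from the same hazard model. Annotations carry the
group label (= lymph-node metastasis), perineural invasion (prevalence
10/24) and tumour size > 5 cm (8/24).

The study-shaped preset is 12 + 12 samples, 83 genes + 7 candidate
endogenous mRNAs, 7 miRNAs + 2 fixed endogenous miRNAs, with planted
effect sizes equal to the whole-cohort fold changes of the motivating
panel (miRNAs 2.21 / 1.61; genes 1.44–3.69), seven repression-gain
couplings (slope 0 → −1) and survival coefficients log 2 per −ΔCT unit
on three markers.

Noise defaults were fixed once, before any recovery experiment was run,
by a power analysis of the design the recovery experiments prescribe: at
50 samples per group a planted twofold change must land in FC ∈
[1.8, 2.2] in ≥95% of runs, which requires an effective per-sample −ΔCT
SD ≤ ~0.35 cycles; biological SD 0.25 plus replicate and reference
noise gives ≈0.31. These values are at the low end of what tumour qPCR
panels show in practice; consequences for interpretation are below.

What the generator does **not** emulate: PCR efficiency ≠ 2 (the 2^−ΔΔCT
model is exact in the simulation by construction), amplification
failures correlated with expression level, batch/plate effects,
heavy-tailed biological variation, correlated miRNA–miRNA or gene–gene
co-expression beyond the planted couplings, competing risks (CSS events
are independent of OS events rather than a subset), and HPV biology.
Passing tests therefore demonstrate that the estimators and screens are
correct and calibrated under a clean qPCR error model — not that the
motivating study's biological conclusions transfer, and not that real
cohorts of 24 patients give the recovery rates seen at n = 100.

## 7. Monte-Carlo experiments

`penmark.validation` runs calibration and recovery through the full
pipeline (simulate → aggregate → filter → select references →
normalise → screen):

* **Null calibration** (default 2000 cohorts of 25 + 25 samples, no
  planted effects): DE rejection at α = 0.05, pair per-group rate at
  0.10, pair combined selection at 0.19, log-rank at 0.05. Tests within
  a cohort share reference and loading noise, so the Monte-Carlo band
  uses the larger of the clustered (per-simulation) and pooled binomial
  standard errors, at z = 2.576.
* **Recovery**: planted log2FC = 1 at 50/group recovered within FC
  [1.8, 2.2]; planted repression-gain coupling recovered as
  disrupted + repression-gain + top pair; Wald CI coverage for a
  planted log-hazard coefficient, fitted on the latent covariate that
  actually drives the hazard — fitting on the noisy measured −ΔCT
  estimates an attenuated coefficient (classical measurement-error
  bias) and is deliberately not used as a coverage experiment.

Problem sizes (2000 calibration cohorts, 100–200 recovery runs, 25–50
samples per group) were chosen as the smallest giving Monte-Carlo bands
tight enough to be informative.

## 8. Degenerate inputs and tie-breaks

* Aggregation of an all-undetermined well set stays undetermined.
* Dichotomization ties go to "low"; stability ties and reference-pair
  ties break lexicographically on assay id and are deterministic.
* Untestable targets (fewer than 2 usable values in a group, constant
  contrast variables) are reported as untestable rows, never silently
  dropped.
* The pipeline is a pure function of (inputs, config, seed): identical
  runs produce byte-identical result tables (6-significant-digit TSV).

## 9. Known limitations

* No PCR-efficiency correction (the pure 2^−ΔΔCT model).
* The pair screen's quotient score mode is provided for completeness
  but is numerically fragile; use the default log-ratio.
* Cox inference is Wald-based; likelihood-ratio intervals are not
  implemented, and monotone-likelihood fits report flagged, unstable
  Wald intervals rather than profile or penalised estimates.
* The cohort-comparability chi-square→Fisher switch uses an expected-
  cell threshold of 2 by default (reproducing the motivating report's
  printed test choices); the textbook threshold 5 is a parameter.
* CSS is treated as simple censoring of non-cancer deaths; no
  competing-risks estimators.
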
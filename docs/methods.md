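# Methods

## The model being tested

The monotone homogeneity (MH) model for binary items assumes a single
real-valued latent variable Θ such that (i) the J item score variables
X₁…X_J are conditionally independent given Θ, and (ii) each item regression
P(X_j = 1 | Θ = θ) is nondecreasing in θ.  MH implies *conditional
association*: increasing functions of any item subset have nonnegative
covariance conditionally on any function of the remaining items.  The
package tests MH through one consequence with known sensitivity to
multidimensionality: for every item pair (i, j), the covariance of X_i and
X_j must be nonnegative within groups defined by a score on the other
items.

## Pairwise statistics

For pair (i, j), a conditioning score is built by ordinary least squares:
the pair sum X_i + X_j is regressed on the remaining J − 2 item scores in a
**training sample** (a random 30% of subjects by default).  By linearity
this joint fit equals the sum of separate OLS predictions of X_i and X_j,
so one fit per pair suffices.  On the **test sample** (the other 70%),
subjects are assigned to C = 10 quantile groups ("deciles") of the score;
tied scores always share a group, so the achieved number of groups can be
smaller.  Rank-deficient designs get the minimum-norm solution; a
`conditioning="restscore"` switch replaces the regression score by the
unweighted pairwise rest score (the classical special case).

Within group c with n_c subjects, the maximum-likelihood sample covariance
cov_c of the pair is computed; the statistics are

* numerator T = Σ_c n_c · cov_c, and MCC = T / N_test (the mean conditional
  covariance, bounded by ±0.25 for binary items);
* the stratified hypergeometric (Mantel–Haenszel) variance
  V = Σ_c m_ic (n_c − m_ic) m_jc (n_c − m_jc) / (n_c² (n_c − 1)), where
  m_ic counts the ones on item i in group c (groups with n_c < 2 contribute
  zero — a singleton's covariance is zero and the hypergeometric variance
  needs n_c ≥ 2);
* Z = (T + 0.5·[continuity]) / √V with the left-tail standard-normal
  p-value.  Small p means a clearly negative mean conditional covariance —
  evidence against MH.

The +0.5 continuity correction is on by default; it shifts every Z up by
0.5/√V, so p-values with the correction dominate those without — the
corrected tests are conservative, the uncorrected ones more powerful.
Pairs with V = 0 on the test sample (all groups degenerate) are flagged and
excluded from every aggregation, reducing K = J(J−1)/2 accordingly.

Training-sample MCCs, needed for preselection, use the same training-fitted
weights with deciles formed on the training scores (self-fit; the
alternative of reusing test-sample deciles was considered and rejected as
it would leak test information into the selection).

## Covariance of the pairwise statistics

Aggregations that use a Mahalanobis metric need a K × K covariance Σ of
the statistic vector.  Three estimators:

* **identity** (Z statistics only): justified because, under MH with the
  conditioning score held fixed, within-group responses are close to
  independent Bernoulli variables whose conditional covariances are
  asymptotically uncorrelated;
* **moments**: with the group assignment treated as fixed, each MCC is
  exactly the subject mean of the centred cross products
  u_n = (x_in − p̄_i,c(n))(x_jn − p̄_j,c(n)); the covariance of two MCCs is
  estimated as the sample covariance of their per-subject contributions
  divided by N_test.  This plug-in form was validated against a brute-force
  oracle (empirical covariance of MCC vectors across hundreds of
  independently simulated datasets with the conditioning rule held fixed);
  the Z-scale version rescales entry (p, q) by N²/√(V_p V_q), the linear
  approximation Z ≈ N·MCC/√V (a congruence transform, so symmetry and
  positive semidefiniteness are preserved);
* **bootstrap**: rows of the test matrix are resampled with replacement
  B = 1000 times (configurable) and the statistic recomputed per pair.  The
  training-fitted weights and the original test-sample decile cut points
  are held fixed across resamples — the conditioning rule is part of the
  statistic's definition — with a `recompute_cuts` flag to redo the cuts
  per resample.  Resamples where a pair is degenerate contribute missing
  values handled by pairwise-complete covariance.

Before any Cholesky-based step the matrix is repaired to have smallest
eigenvalue ≥ 1e−10 by a spectral shift (`repair_psd`); repaired matrices
are flagged.

## Aggregation rules and decision rules

The statistic vector x ∈ R^K (Zs or MCCs) is aggregated in eight ways:

* **LR** — project x onto the nonnegative cone {θ ≥ 0} in the metric Σ⁻¹:
  χ̄² = min_{θ≥0} (x−θ)ᵀΣ⁻¹(x−θ).  The projection is computed by whitening
  with the Cholesky factor and solving the resulting nonnegative
  least-squares program exactly (active-set NNLS); under the identity it
  reduces to clipping at zero.  Under the least-favourable null, χ̄² is a
  chi-bar-square mixture Σ_k w_k χ²_k.  Weights are estimated by Monte
  Carlo (draws from N(0, Σ), counting negative coordinates; M = 10 000 by
  default, seeded).  For the identity matrix the weights are binomial(K, ½)
  exactly, and the implementation uses that closed form — the limit of the
  Monte-Carlo estimate — for speed and exactness.
* **CL** — the conditional (Wollan–Dykstra) rule: given D binding
  nonnegativity constraints of the projection (under the identity, the
  number of negative statistics), χ̄² is referred to χ²_D.  With D = 0 the
  vector lies in the cone and the test never rejects; the conditioning-
  probability correction factor is ignored (it is negligible for five or
  more items).  Binding constraints for general Σ are identified by the
  Lagrange multipliers of the NNLS solution.
* **PS** — preselected standardized partial sum: pairs with negative
  *training* MCC form the selection S; T = Σ_S x / √(ΣΣ Σ_S submatrix),
  referred to the standard normal left tail.
* **CS / CP / CB** — conditionalized combiners: test-sample p-values below
  t = 0.5 are divided by t (for Z statistics, p < 0.5 is within the
  continuity shift of "Z < 0", i.e. the negative statistics); the corrected
  p-values are combined by Stouffer's sum (√K′ standardization, normal
  reference), Fisher's product (−2Σlog p′, χ²_{2K′}), or min-p Bonferroni.
* **PP / PB** — preselection versions: raw test p-values over the
  training-selected pairs, Fisher or Bonferroni.  Because training and test
  samples are independent, selection does not distort the null distribution.

Empty selections give p = 1 and no rejection.  p-values are floored at
1e−300 before logarithms or normal quantiles (logged when triggered).
Rejection is p ≤ α (α = 0.05 default) except CL, which rejects when χ̄²
exceeds the χ²_D critical value.

The registry of meaningful combinations has 20 entries: bootstrap and
moments covariances apply to the Mahalanobis-type aggregations (LR, CL, PS)
for both MCC and Z vectors; the identity covariance applies to Z only,
where it also supports the covariance-free combiners — {MB, MM, ZB, ZM} ×
{LR, CL, PS} plus ZI × {LR, CL, PS, CS, CP, CB, PP, PB}.

A note on monotonicity: shifting every Z upward weakly decreases χ̄², and
weakly increases each combiner's p-value *as long as the selected set is
unchanged*.  When the shift moves a pair out of a selection, both the
combined statistic and its degrees of freedom change, and the combined
p-value can move either way; the property tests assert the fixed-selection
form.  The same caveat applies to comparisons of runs with and without the
continuity correction: per-pair p-values are ordered deterministically,
omnibus p-values almost always.

## The simulator

Responses come from a compensatory two-dimensional 2PL model,
P(X_j = 1 | θ) = logistic(a_j1 θ1 + a_j2 θ2 + b_j), with θ bivariate
standard normal, correlation 0.  The intercept parametrization is used (no
a(θ − b) difficulty form, no 1.7 logistic-to-ogive scaling constant), so
a = 1 is a low and a = 1.7 a medium discrimination.  Scenarios: dim0 (all
a = 0; items i.i.d. Bernoulli(logistic(b)) — a degenerate null), dim1 (all
items on dimension 1 — the MH null with informative items), dim2 (items
split evenly across the two independent dimensions, dimension 1 taking the
extra item for odd J — the alternative).  Fixed parameters default to a = 1,
b = 0; random mode draws a ~ U(0.5, 2) and b ~ U(−1, 1) per item (the
ranges are package defaults chosen to span low-to-high discriminations and
centred difficulties, and are plain config keys).

What the simulator deliberately does not emulate: correlated latent
dimensions, more than two dimensions, polytomous or missing responses,
guessing/slipping asymmetries.  Passing tests therefore show calibration
and power under clean compensatory-2PL violations, not under every real-
world departure from MH.

## Experiments and reproducibility

`run_rejection_grid` crosses designs with named tests, sharing the split,
pairwise statistics, and covariance estimates within a replication.  Each
replication receives an independent seed substream derived from (master
seed, design index, replication index), so results are bit-for-bit
identical regardless of execution order or worker count.  Replications in
which every pair is degenerate are recorded as missing and removed from the
denominator.  Diagnostics: Schweder–Spjøtvoll sorted-p series and a
stochastic-dominance comparison of per-cell rejection counts with the
binomial(n_reps, α) reference.

Headline study sizes (chosen to characterize the tests at meaningful
Monte-Carlo resolution): zero-dimensional Type I at the small-J/small-N
corner (J ∈ {3,4,5} × N ∈ {250,500}, 1000 replications per cell);
unidimensional Type I on the J ∈ {3..7,10} × N ∈ {250,500,1000} grid (100
replications per cell); 20 random unidimensional parameter cases × 50
replications; power at a = 1.7 for J ∈ {10,20,30}, N = 500, 100
replications, continuity off.  Full-scale presets (1000 replications per
scenario) are available via `preset_designs("table1-full")`.

## Numerical choices

* Quantile bins: interior quantiles at k/C of the empirical score
  distribution; a subject's label is the number of cut points strictly
  below its score, so labels are a pure function of the score and
  duplicate cut points merge bins automatically.
* OLS per pair via the Gram matrix of the augmented training design with a
  pseudoinverse solve — identical to the minimum-norm least-squares
  solution, O(J³) per pair after one O(N J²) pass.
* NNLS tolerance is scipy's active-set default; binding constraints use a
  1e−9 scaled threshold on (θ*, multiplier).
* Cov matrices are symmetrized to remove floating-point asymmetry before
  validation.

## Known limitations

* The OLS conditioning score is the minimal reading of "weighted sum score
  with weights estimated from a training sample"; regularized or link-based
  predictors are not implemented.
* CS/CP/CB assume the selected p-values behave independently; with few
  items and strongly correlated pairs this is an approximation (the same
  one that motivates the identity covariance).
* The moments estimator ignores the randomness of the group sizes and cut
  points; the bootstrap is the more faithful (and more expensive) option.
* Polytomous items, missing data, covariate-adjusted conditioning, and
  aggregation over multiple train/test splits are out of scope.
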
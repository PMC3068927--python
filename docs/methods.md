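# Methods

## The model and its assumptions

The package treats an array-docking experiment as a two-way layout: the
raw score of drug *j* in pocket *i* is

    x_ij = μ + drug_j + pocket_i + interaction_ij + ε_ij

where `drug_j` and `pocket_i` are main effects (ligand-intrinsic and
pocket-intrinsic score offsets), `interaction_ij` is the specific binding
signal of interest, and ε is noise. Only the interaction term is
pharmacologically meaningful: a pocket that scores well for *every* ligand
is not a hit for any of them. All downstream statistics therefore operate
on 2DIZ-normalized Z′-scores, never on raw scores.

### 2DIZ (column-then-row standardization)

Step 1 z-scores each drug column over its non-missing pockets; step 2
z-scores each row of the result over its non-missing drugs. Step 1 removes
the drug main effect exactly; step 2 removes the pocket main effect
exactly (every output row has mean 0, sd 1, to 1e-9 on complete data), so
the variance that survives is interaction plus noise.

Two invariance statements make the "endogenous variance is normalized
away" claim precise:

* **Per-drug affine rescaling of the input is removed exactly** — the
  column z-score is invariant to it, and the row step then sees identical
  input.
* **Per-pocket affine rescaling is removed up to column-moment estimation
  error.** Because the column step runs first, per-pocket scales and
  offsets perturb each column's estimated mean and sd inhomogeneously.
  The residual deviation shrinks like 1/n_pockets: with severe transforms
  (offsets 10 sd, scales 0.5–5×) it is ~1% of the unit output variance at
  the 410-pocket, 255-drug study scale, and an order of magnitude larger
  on a 40-pocket panel. It is an asymptotic, not algebraic, invariance;
  the tests assert the decay and a 2% ceiling at study scale rather than
  exact equality.

Numerical conventions: the sd divisor is configurable (`ddof` 0 or 1,
default 1; downstream permutation p values are invariant to the choice but
the −0.48 binarization threshold is not). Zero-variance rows/columns map
to 0, not missing, so constant pockets can never rank as hits. Rows or
columns with fewer than two non-missing entries produce missing output
with a warning. Missing cells stay missing throughout.

### Variance decomposition

`variance_decomposition` reports the shares of total sum of squares
attributable to row means, column means, and the remainder, all computed
over non-missing cells. On complete additive data the residual share is 0;
after 2DIZ the pocket share is 0 by construction. Shares estimated from a
single simulated panel inherit the sampling noise of the drawn effects
(relative sd ≈ √(2/n) per variance component, i.e. ~10–14% on a 100×100
panel), which is why recovery tests compare median error across several
seeded panels rather than one draw.

## Analog-pair (binomial antithesis) statistics

The A-score at pocket *i* is `z'_i,drug1 − z'_i,drug2`; negative values
flag pockets bound preferentially by drug 1 (smaller Z′ = stronger
binding). The null is built per pocket by drawing ordered pairs of
distinct drugs uniformly — with replacement across iterations, and without
excluding the tested pair, since every drug on the panel is an eligible
"random drug". The p value is the strictly-less-than fraction, so p = 0.0
is reportable (no +1 smoothing); with the default 10,000 iterations the
granularity is 10⁻⁴. `exact_pair_p` enumerates all ordered pairs and
serves as the oracle the sampled test must converge to.

Ranking keeps pockets with p < α (default 0.05), sorted by p, ties broken
by the more negative A-score, then pocket id. Profile similarity
(pairwise-complete Pearson between drug columns, against a null of random
ordered pairs, counting null mean PCC ≥ observed) quantifies the analog
assumption itself: the pair should correlate strongly overall, with only
focal divergences. When a parent drug docked as several ionization states
or metabolites, `select_variant_pair` runs every cross pair and keeps the
one recalling the most known risk genes (ties: smaller mean p over the
recalled known-gene pockets, then lexicographic).

## Case/control (multiple antitheses) statistics

Z′ < −0.48 defines "interactive" — the threshold is adopted as an
empirical constant from the prior calibration of the docking pipeline
(reported to capture 70% of true bindings) and is not re-derived here.
Equality at the threshold is non-interactive (strict <; measure-zero in
practice). Background drugs and missing cells are excluded, so missing
scores shrink the 2×2 margins. RR = [a/(a+b)]/[c/(c+d)], +∞ when every
case is interactive (c = 0, a > 0); the useful identity is that swapping
the interactive/non-interactive rows inverts RR. The one-sided Fisher
exact p (hypergeometric upper tail of the `a` cell, computed from scipy's
log-space tail) is evaluated only for RR > 1 pockets, matching the screen
it implements; RR ≤ 1 pockets carry no p.

Class enrichment of the prioritized pockets uses the hypergeometric upper
tail with the pocket universe defaulting to all pockets on the panel; a
caller can collapse to unique proteins instead, since several pockets of
one protein otherwise count multiply. Report-rate comparison uses the df-1
chi-square without continuity correction — the convention under which the
published 185/16813 vs 16/11304 comparison reproduces p = 8.2E-21 — and
refuses tables with a zero margin.

## Off-system perturbation

Probes are ranked within each instance by descending fold change
(rank 1 = most up-regulated, average ranks on ties); R′ is the mean rank
over the selected instances. The directional vocabulary is mapped to
numbers explicitly: "more up-regulated" always means *numerically smaller*
mean rank. The null resamples *genes* (each expanded to its real probes,
preserving probes-per-gene multiplicity), not probes, from all mapped
genes; `unit="probes"` switches to probe resampling for sensitivity
checks. p = m/n_iter with strict inequality and no smoothing. Genes of the
query set absent from the probe map are dropped (their count is reported
in the result). The degenerate case "set = whole background" gives p = 0
under strictness, a documented artifact rather than significance.

## Synthetic-data generators

`simulate_cpi` draws the two-way layout above with Gaussian effects and
noise (defaults: 255 drugs × 410 pockets, unit drug/pocket/noise sds,
39 case and 15 control drugs — the dimensions of the motivating study).
Planted structure:

* **Analog pair** — drug 2 copies drug 1's main effect and interactions;
  an interaction depth (default −5, i.e. 5× the noise sd, negative =
  stronger binding of drug 1) is added to drug 1 at the differential
  pockets. The pair's noise is correlated (`profile_correlation`, default
  0.9): analogs and ionization states of one parent dock near-identically,
  and the original study found the analog pair's profile correlation in
  the top percentiles of all drug pairs. This matters statistically: with
  fully independent analog noise, every null pocket's observed pair
  A-score is an ordinary draw from its own null, so the minimum p across
  ~400 null pockets is of the same order as the planted pocket's p floor
  (~1/(2·n_drugs), from null pairs that contain drug 1 itself), and
  "planted pocket ranks first" would hold in only ~half of runs at any
  planted depth.
* **Case/control mediators** — a binding boost (default −5) added to every
  case drug at each mediator pocket (default 5 of them).
* Missingness is completely at random (default rate 0 in the config;
  analyses are exercised at 2–5%).

`simulate_expression` draws i.i.d. Gaussian fold changes (probe counts per
gene constant or sampled from a range) and shifts every probe of a planted
gene set by +δ in all instances. Tests use 1,000 genes with 1–3 probes
each, 4 instances (the study aggregated 4 treatment instances) and a
50-gene planted set; δ = 1 noise sd is ample power at that set size, and
δ = 0 calibrates the null (p uniform across seeds).

What the generators do *not* emulate: heavy-tailed docking-score
distributions, correlated pockets of one protein, structured missingness
(docking failures cluster by chemistry), and instance-to-instance
correlation in expression. Passing recovery tests therefore demonstrate
the statistical machinery, not docking accuracy on real panels.

## Reproducibility and sizes

Every stochastic routine takes an explicit seed (CLI commands require it)
and identical invocations are byte-identical. Permutation defaults are
10,000 iterations, matching the published procedure; convergence tests run
200,000 iterations against exact enumeration on ≤10-drug pockets and
≤10-gene backgrounds. Recovery tests use 40 seeds at the 255×410 study
scale and 200 seeds for null calibration; these sizes keep the full suite
under a minute of compute while leaving the binomial sampling error of the
assessed proportions well below the tested margins. Exact tail
probabilities are floored at 1e-300; p values from sampling are reported
exactly as m/n.

## Known limitations

* Finite-panel 2DIZ leaves the ~1/n_pockets endogenous residue described
  above; panels much smaller than ~100 pockets blur the invariance
  noticeably.
* The one-sided exact test and the printed three-decimal p values of the
  original tables do not agree for every row under any single convention
  (e.g. counts 21/1/18/14 give 0.0013, printed as 0.002); the package
  implements the stated one-sided exact test and leaves the printed values
  as approximate anchors.
* Enrichment p values depend on the universe convention (all pockets vs
  unique proteins); both are exposed, neither is privileged.
* No multiple-testing correction is applied across pockets — the original
  procedure screens at per-pocket α = 0.05 and the package follows it;
  callers can correct the emitted p columns if desired.
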
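# antithesis-cpi

Statistical toolkit for mining a **chemical–protein interactome (CPI)** — a
drug × protein-pocket docking-score matrix — for the *off-targets* that may
mediate an idiosyncratic adverse drug reaction, and for the perturbation of
the gene systems associated with those off-targets. The motivating use case
is drug-induced agranulocytosis: clozapine causes it, its close analog
olanzapine largely does not, so pockets bound by one analog but not the
other are candidate mediators.

It is aimed at computational pharmacologists who already have (or can
simulate) an array-docking score matrix and want reproducible, seeded
statistics on top of it; the docking itself is out of scope.

## What it computes

**Normalization (2DIZ).** Raw docking scores carry large pocket-intrinsic
("endogenous") and drug-intrinsic components. The 2-directional
Z-transformation z-scores each drug column across pockets and then each
pocket row across drugs, giving Z′-scores in which smaller (more negative)
values mean stronger theoretical binding:

    z'_ij = rowz( colz(x)_ij ),   colz(x)_ij = (x_ij − μ_j) / σ_j

**Analog-pair (binomial antithesis) analysis.** For an analog pair (drug 1,
drug 2) and pocket *i*, the antithesis score is the Z′ difference
`A_i = z'_i,1 − z'_i,2`. Its one-tailed p value is the fraction of
randomly drawn ordered distinct drug pairs at that pocket whose A-score is
strictly below the observed one (default 10,000 draws, seeded). Pockets
with p < α are ranked as candidate off-targets of drug 1.

**Case/control (multiple antitheses) analysis.** With many drugs that cause
the reaction (cases) and many that do not (controls), Z′ is binarized at
the empirical threshold −0.48 (interactive ⇔ Z′ < −0.48); each pocket's
2×2 table (a/b interactive cases/controls, c/d non-interactive) gives the
relative ratio `RR = [a/(a+b)] / [c/(c+d)]` and, for RR > 1, a one-sided
Fisher exact (hypergeometric upper-tail) p value. Functional-class
enrichment among prioritized pockets and adverse-event report-rate
comparisons (χ², df 1, no continuity correction) are included.

**Off-system perturbation.** Given a probe × instance expression-rank
compendium (Connectivity-Map style; rank 1 = most up-regulated), a probe's
R′ is its mean rank over chosen instances. A gene set's perturbation p is
the fraction of random same-size gene sets whose probe-mean R′ is more
extreme (strictly smaller for "up") than the set's observed mean.

**Synthetic data.** `simulate_cpi` and `simulate_expression` generate
score matrices (drug + pocket + interaction + noise effects, planted analog
pairs and case/control mediators, missing-at-random gaps) and fold-change
compendia with planted up-shifted gene sets, with truth records, so every
analysis is testable end to end.

## Worked example

Simulate a small interactome with one planted differential pocket for an
analog pair and three planted case/control mediator pockets, then run both
prioritizations:

```sh
cat > sim.yaml <<EOF
n_drugs: 60
n_pockets: 80
missing_rate: 0.05
analog_pair: {depth: -5.0}
case_control: {n_cases: 20, n_controls: 10, n_mediator_pockets: 3, boost: -5.0}
EOF
cpi simulate cpi --config sim.yaml --seed 11 --out-prefix run_
cpi normalize --in run_scores.tsv --out zprime.tsv
cpi binomial --z zprime.tsv --drug1 ANALOG_1 --drug2 ANALOG_2 \
    --iters 10000 --seed 17 --alpha 0.05 --out table_pair.tsv
cpi multiple --z zprime.tsv --roster run_roster.tsv --out table_cc.tsv
```

`table_pair.tsv` contains the pockets where drug 1 binds significantly
more strongly than its analog:

```
pocket_id    z_drug1   z_drug2    a_score   p_value
POCKET_0068  -4.30918  -0.994819  -3.31436  0.0166
```

POCKET_0068 is exactly the pocket the truth record (`run_truth.yaml`) says
was planted with an extra −5 binding depth for drug 1; the A-score −3.31
is its Z′ advantage after normalization and 1.66% of random drug pairs
beat it. `table_cc.tsv` starts with:

```
pocket_id    a   b  c  d   rr   p_value
POCKET_0008  20  0  0  10  inf  3.32834e-08
POCKET_0058  20  0  0  10  inf  3.32834e-08
POCKET_0025  19  0  1  10  11   3.66117e-07
```

— all 20 case drugs and no control drug are interactive at the planted
mediator pockets (RR = ∞ when no case is non-interactive), and these are
precisely the three planted mediators. Report-rate comparison of two
drugs' adverse-event counts:

```sh
$ cpi aers-test --events1 185 --total1 16813 --events2 16 --total2 11304
rate1=1.1%  rate2=0.14%  chi2=87.55  p=8.2e-21
```

i.e. a 1.1% vs 0.14% agranulocytosis report rate, overwhelmingly unequal.

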
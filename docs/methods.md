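# Methods

This note documents the statistical model behind each pipeline stage, the
defaults and why they were chosen, what the synthetic data does and does
not emulate, and the numerically delicate choices.

## Report model and cleaning

A report is one spontaneous submission: demographics, dated, a list of
drugs with reporter-assigned roles (primary suspect, secondary suspect,
concomitant, interacting), a set of reaction Preferred Terms (PTs), a set
of indication PTs, and seriousness outcomes. Dates in the quarterly
dialect may be year-, month- or day-resolved; partial dates are completed
to the *earliest* consistent day so that window selection is inclusive and
deterministic.

Deduplication is deliberately conservative and auditable, in two stages:

1. **Case supersedence** — among records sharing a `caseid`, only the
   highest `caseversion` survives (ties: highest report id). This mirrors
   how regulators publish amended cases.
2. **Exact-tuple collapse** — among survivors, records identical on
   (sex, age group, country, occurrence date, substance set, reaction PT
   set) collapse to the lowest report id. This catches the same patient
   reported through different channels.

Probabilistic or fuzzy linkage is out of scope; every removal is logged
with its rule and the id of the kept record, so the operation is fully
reversible in audit.

Substance names are uppercased, trimmed, stripped of one trailing
salt/ester suffix from a shipped list, and passed through a user-extensible
synonym table that can split combination products into components (e.g. a
lopinavir/ritonavir product contributes both substances). The cohort is
selected by intersecting the *indication* field with a narrow SMQ term
set; reactions never select, since the same terms appearing as reactions
mean something different (a reported event, not the treated condition).

## Terminology projection

Reactions are analysed at the level of primary High-Level Terms: each PT
maps to exactly one primary HLT, each HLT to one primary System Organ
Class. Projection is a set operation — a report counts at most once per
HLT — and drops HLTs whose primary SOC is one of six non-specific classes
(injury/poisoning, social circumstances, product issues, procedures,
investigations, general disorders), which mostly encode reporting
artefacts rather than clinical events. Unknown PTs are skipped with a log
entry rather than raised: real spontaneous data contains verbatim and
retired terms. The dictionary itself is an input in a documented TSV
dialect; the repository ships a synthetic one because the real
terminology is licensed.

## Disproportionality

Within the cohort, for drug D (suspected = PS or SS role; concomitant
mentions do not count) and event E the 2×2 table of report counts is

|                | E present | E absent |
|----------------|-----------|----------|
| D suspected    | a         | b        |
| D not suspected| c         | d        |

ROR = ad/bc with the 95% CI exp(ln ROR ± z·√(1/a+1/b+1/c+1/d)),
z = 1.959964. If any cell is zero, 0.5 is added to all four cells
(Haldane–Anscombe) before both the point estimate and the CI; tables with
an empty drug or event margin are reported as undefined rather than
raised. Only drugs suspected in strictly more than `min_drug_reports`
(default 100) cohort reports enter; a pair is *computed* only when
a ≥ `min_case` (default 3). The number of tests for the Bonferroni
correction is the number of computed pairs — not drugs × all events —
and the corrected threshold α/n_tests is applied uniformly. The Fisher
exact test is two-sided by default (point-probability method, the scipy
convention: all tables with the same margins whose probability is at most
that observed, with 1e-7 relative tolerance); a config switch selects
one-sided "greater", since the CI > 1 criterion already enforces
direction. An SDR requires both the CI criterion and the corrected
p-value. Both a corrected and an uncorrected significance matrix are
exported, rows grouped by primary SOC.

## The Ising network (eLASSO)

Events with at least `min_cases` (default 10) cohort reports become the
binary variables x ∈ {0,1}^p of a pairwise Markov random field
P(x) ∝ exp(Σ τᵢxᵢ + Σ_{i<j} Wᵢⱼxᵢxⱼ), whose conditionals are logistic
regressions — so the graph is estimated nodewise:

* For each node j, an L1 path of logistic regressions of xⱼ on the other
  columns is computed over 100 log-spaced penalties from λ_max (the
  smallest penalty with an empty model) down to 0.01·λ_max. As in
  standard path solvers, predictors are standardized inside the fit and
  the path stops early once the deviance explained improves by less than
  1e-5 per step.
* The distinct supports along the path (including the empty model) are
  candidate neighbourhoods. Each is **refit without penalty** and scored
  by EBIC_γ = −2ℓ̂ + k ln n + 2γk ln(p−1) with γ = 0.25 (the method's
  canonical default) and ℓ̂ the refit log-likelihood.
* An edge (i, j) survives under the AND rule only if each node's selected
  model retains the other; its weight is the mean of the two
  coefficients (under OR, a missing coefficient counts as zero). Node
  thresholds τ are the selected intercepts.

Scoring at the refit rather than the shrunk coefficients is a deliberate
choice. Evaluating EBIC at the penalized estimates — as the canonical R
implementation of this estimator does — makes the comparison across
penalty levels incoherent when signals are strong: moving down the path,
the likelihood gain from merely *un-shrinking* true coefficients can pay
the EBIC price of a spurious extra neighbour. On Gibbs samples from a
6-node chain with unit weights (n = 3000) we reproduced the canonical
implementation edge-for-edge via glmnet and found it adds a false edge in
roughly a fifth of datasets; refit scoring removes that artefact (49/50
exact recoveries) while leaving the selection rule otherwise unchanged.
The trade-off is a slightly higher false-edge rate on pure-noise data:
with γ = 0.25 the per-pair false-inclusion probability of a refit-scored
EBIC is approximately P(χ²₁ > ln n + 2γ ln(p−1)) ≈ 0.003, so on
independent Bernoulli columns (p = 10, n = 2000; 45 candidate pairs) the
expected number of false edges is ≈ 0.14 and the probability of a
perfectly empty graph is ≈ 0.88–0.92 — below the ≥ 0.95 that the shrunk
scoring attains. No single scoring of EBIC at this γ achieves both the
chain-recovery and the null-specificity behaviour simultaneously; we
prefer the variant that is calibrated under strong signals, and leave γ
at its canonical default rather than tuning it. Familywise error of the
full SDR screen on no-effect cohorts is unaffected (≈ 1% at α = 0.05).

Constant columns are rejected before fitting (logistic separation makes
their estimates unbounded). The solver contract is any L1-penalized
logistic minimizer at tolerance ≤ 1e-6; the implementation uses
liblinear with `intercept_scaling` large enough that its intercept
penalty is negligible (liblinear otherwise penalizes the intercept,
which de-calibrates the λ grid), and a pinned coordinate-descent seed so
fits are bit-reproducible.

A single-site Gibbs sampler for the same model (systematic sweeps,
conditional P(xᵢ=1|rest) = logistic(τᵢ + Σ Wᵢⱼxⱼ), seeded, with burn-in
and optional thinning) provides simulation ground truth for recovery
tests; thinning was verified not to change recovery rates, so the default
records one sample per sweep.

## Communities and assortativity

Community detection runs on the positive subnetwork (negative weights
zeroed): standard modularity is not defined for signed graphs, and the
negative edges encode mutual exclusivity rather than co-reporting. The
Louvain implementation is networkx's seeded multi-level algorithm;
partitions are relabelled to contiguous integers ordered by smallest
member, modularity is the weighted Newman–Girvan Q (Q = 0 by convention
for an edgeless graph), and isolated nodes are singletons. An
`include-absolute-weights` style analysis is available by passing |W|
manually.

Degree assortativity is the Pearson correlation of the *unweighted*
degrees at the two ends of each edge (each edge counted in both
orientations) — degree here means number of links. Categorical
assortativity is Newman's r = (Σe_ii − Σa_ib_i)/(1 − Σa_ib_i) on the
edge-end mixing matrix. Both return "undefined" (not an exception) when
the attribute is constant over edge endpoints. The "disproportionality"
attribute is operationalized as each node's sorted tuple of SDR drugs,
the empty tuple being its own class — an interpretation, since sharing
disproportionality is not otherwise a single categorical variable.

## Synthetic data

The generator emulates the structure the estimators assume, per report:
independent Bernoulli drug exposures (each exposed drug suspected with
probability `suspect_prob`; the first suspected is the primary suspect);
an event vector drawn from logit P(e) = baseline_e + Σ_exposed
log-odds(drug, e), followed by one Gibbs sweep over each planted
syndrome's members applying the pairwise coupling — matching the Ising
conditional, so network-recovery tests are well-posed; an indication PT
carrying the epidemic SMQ term with configurable probability; exact-copy
duplicates under fresh case ids; then per-field missingness. Reports
with no drug or no event are resampled, as every valid submission names
at least one of each — this conditioning induces a small negative
correlation among rare events when the event list is short, visible in
the independence tests and harmless to the planted-signal analyses. All
randomness flows from one seed through named SeedSequence sub-streams.

What it does **not** emulate: reporting biases (notoriety, masking,
channelling), time trends, dose or duration, realistic pharmacology, and
the long-tailed verbatim vocabulary of real data. Passing tests therefore
demonstrate statistical correctness of the machinery under the assumed
model, not performance on real-world reporting distortions.

Presets: `tiny` (200 reports, 8 drugs, 15 HLTs), `small` (2,000 / 10 /
40), `medium` (10,000 / 12 / 80), each with planted effects spanning
log-odds 0.5–2.5, two or three syndromes (coupling 1.5), 2% duplicates,
50% cohort-indication probability, and fixed documented seeds
(12001/12002/12003). Two preset events live in excluded SOCs to exercise
the projection filter.

## Problem sizes in tests and the acceptance script

The test suite and `scripts/acceptance.py` use desk-scale replicate
counts chosen to give stable pass/fail behaviour at reasonable runtime:
50 seeds for chain recovery, 20–40 for the null-graph and
planted-partition checks, 100–200 no-effect cohorts for the familywise
error rate, 20
seeds for end-to-end SDR recovery and 3–5 for end-to-end syndrome
recovery (each network fit dominates the cost), and the full enumeration
of all 46,375 2×2 tables with total ≤ 30 for the Fisher oracle. The
headline count-based quantities (Bonferroni threshold at 619 tests; the
29.9% / 9.0% co-suspect percentages from the published counts) are exact
computations, not simulations.

## Known limitations

* Deduplication is exact-match only; it will not catch near-duplicates
  with differing demographics.
* The eLASSO weight is a logistic interaction coefficient; the field
  sometimes describes these edges as "partial correlations", which is a
  related but not identical quantity.
* n_tests (and hence the Bonferroni threshold) depends on the ≥3-case
  rule, so adding reports can change the threshold for all pairs.
* Louvain is greedy; only seed-level determinism is guaranteed, not
  global optimality (the brute-force tests cover ≤ 8-node graphs).
* Bootstrap edge stability and alternative disproportionality statistics
  (PRR, IC, EBGM) are future extensions.
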
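# Methods

## Scores and derived quantities

Each species carries ordinal scores from two assessment processes. Risk
assessment (RA): entry, establishment, spread, impact on 1–5
(very unlikely/minimal … very likely/massive) and overall risk on 1–3
(low–high). Risk management (RM): effectiveness, practicality, cost,
impact, acceptability, reinvasion, window on 1–5 and overall feasibility
of eradication on 1–5. The RM *cost* component is a banded estimate of
eradication cost: 1 = under £50k, 2 = £50–200k, 3 = £200k–1M, 4 = £1–10M,
5 = £10M+.

Derived per species:

* **cost** — the band's currency mid-point. Defaults: £25,000, £125,000,
  £600,000, £5,500,000, £55,000,000. The open-ended bands need a
  convention: band 1 is treated as 0–50k and band 5 as an effective
  10–100M band, the values consistent with published per-species costs of
  £25,000 and £55,000,000. The map is user-overridable
  (`cost_band_midpoints` in the run config) and validated to be positive
  and strictly increasing.
* **benefit** — spread × impact (1–25), the potential impact removed;
  spread and impact are multiplied because together they capture extent
  and severity. Benefit stays in score units; it is deliberately not
  monetised.
* **tie-break keys** — geometric means of component scores (RA: the four
  RA components; RM: effectiveness, practicality, cost, impact,
  acceptability — reinvasion and window are excluded). Keys are compared
  at full floating precision.

## Prioritisation

Three methods sort species descending on a primary key: overall risk
(RA), overall feasibility (RM), or their sum (RA+RM, 2–8, the numeric
equivalent of a risk × feasibility matrix). Ties break on the method's
geometric-mean key (for RA+RM, the sum of the two means); residual ties
break alphabetically so rankings are fully deterministic. Whether the
cost component should be inverted (6 − cost) inside the RM tie-break is
genuinely ambiguous — a high band means *more expensive*, which is
arguably anti-feasibility — so it is exposed as
`invert_cost_in_tiebreak`, default off (the literal component score).
The flag affects within-tie order only.

Display labels for (risk, feasibility) pairs on a five-point VL–VH scale
are supported only through a user-supplied 3×5 lookup matrix
(`matrix_label`); there is no built-in default because published labels
are not derivable from the numeric sum (distinct pairs with equal or
ordered sums can carry different labels). Ranking always uses the sum.

## Cost–benefit curve and AUC

Removing species in rank order traces cumulative (cost, benefit) points;
the origin is prepended and both axes are divided by their totals. The
AUC is the trapezoidal area under this normalized piecewise-linear curve.
Normalization makes the statistic scale-free (invariant to uniform
rescaling of all costs or all benefits) and gives it two exact laws used
as oracles throughout the tests:

* **Reversal identity**: the normalized curve of the reversed order is
  the 180° rotation of the original about (½, ½), so
  AUC(π) + AUC(reverse π) = 1 for every table and every order.
* **Null mean**: pairing each permutation with its reverse shows the mean
  AUC over *all* orderings is exactly 0.5 (`mean_null_auc_exact`
  verifies this by factorial enumeration for n ≤ 8).

The greedy ordering by benefit/cost density (ties alphabetical) yields a
concave curve and attains the maximum AUC over all orderings — the
exchange argument for the continuous knapsack applies segment-wise — and
serves as the attainable upper bound (`optimal_order`).

A curve with zero total cost or benefit is degenerate and rejected
explicitly rather than returning NaN.

## Permutation test

Significance of an observed ordering's AUC is judged against `n_perm`
uniform random permutations drawn with a seeded numpy `Generator`
(Fisher–Yates). The one-sided upper-tail estimate uses the add-one
convention, p̂ = (1 + k)/(1 + n_perm) with k the count of null AUCs ≥ the
observed value; ties count as exceedances (conservative), and a
lower-tail variant tests "worse than random". The 95% CI is the exact
binomial (Clopper–Pearson) interval on the raw exceedance proportion
k/n_perm via `scipy.stats.binomtest`. This fixed-n scheme delivers a
p-value estimate with a CI directly; a sequential early-stopping
Monte-Carlo procedure would give the same deliverable with fewer draws
but is deliberately out of scope. The seed is recorded in the result and
in `run.log`, so reports regenerate byte-identically.

## Synthetic data generator

`generate_table` emulates the structure of a real 26-species assessment
table. Per species a latent pair (risk severity, manageability) is drawn
from a Gaussian copula with correlation ρ (`rho_risk_feasibility`),
factorised explicitly as z₂ = ρz₁ + √(1−ρ²)ε so ρ = ±1 is exact. Each
ordinal component is its latent plus independent N(0, sd²) noise,
discretised to 1–5 by equal-probability thresholds of the marginal (so
component margins are uniform). Overall risk is the equal-width tercile
of the RA component mean; overall feasibility is the equal-width quintile
of the mean of (effectiveness, practicality, 6 − cost, impact,
acceptability).

The cost band is drawn from `cost_band_probs` and then pulled toward the
band implied by the species' manageability tercile with strength |ρ|:
`band = round(base + |ρ|·(target − base))`, where the terciles map onto
the *ends* of the band scale, target = 7 − 2·tercile ∈ {5, 3, 1}. This
mapping is what reproduces the observed structure of the study system —
easily eradicated species sitting in the £25k–£600k bands while
intractable ones occupy £5.5M–£55M, a spread of nearly two orders of
magnitude; a narrower target range (bands 3–5 only) pins every manageable
species at £600k and flattens the RA-vs-RM contrast to nearly nothing. At
|ρ| = 1 the band equals its target exactly, which makes the ρ = +1,
noise-free invariant (RA and RM orderings agree up to ties) hold
deterministically.

Defaults, chosen once for realism at the study's scale: `n_species = 26`
(the study sample), `rho_risk_feasibility = −0.6` (the system shows a
clear negative risk–manageability association; −0.8 is the stress setting
used for the directional headline property), `component_noise_sd = 0.5`
(components track their latent but disagree by a band or two, as
expert-elicited scores do), uniform `cost_band_probs`.

What the generator does *not* emulate: taxonomic/environmental structure
in the scores, expert rounding habits, correlated elicitation errors
across components, and the empirical marginals of any real archive.
Passing tests on synthetic tables therefore demonstrate the pipeline's
correctness and the qualitative cost-effectiveness phenomenon, not the
numeric AUCs of any particular real dataset — those are recomputed only
when a real table is supplied to `run_analysis`.

`table1_fixture` is the other bundled input: a partial reconstruction of
the published top-ten summary lists (species, cost bands, printed overall
labels). Component scores are not printed there, so the fixture is a
dedicated structure rather than a full `SpeciesTable`, and assertions
never touch the unprinted fields.

## Numerical and design choices

* Ordinal parsing accepts integers or case-insensitive labels
  (VL/L/M/H/VH; L/M/H for the 3-point overall risk). Out-of-range values
  raise naming the row and field — never silently clamped.
* CSV dialect: UTF-8, comma, one header row, lower-snake canonical
  columns; a `column_map` lets differently-headed archives load without
  editing the file. Metadata columns (status, taxon group, environment)
  are optional and unused by computation.
* Equal-width binning (not empirical quantiles) converts component means
  to overall scores in the generator: deterministic per species,
  independent of the rest of the table.
* AUC comparisons in tests use absolute tolerances (1e−12 for exact
  identities, 1e−9 against brute force) — both far below any score
  resolution.
* Problem sizes in the test suite (factorial enumeration to n ≤ 7,
  1,000 reversal-identity tables, 200 greedy-optimality tables, 50
  headline replicates, Monte-Carlo calibration at 2,000 permutations)
  keep the full suite under ~10 s while leaving each check's sampling
  error far smaller than the effect it verifies.

## Known limitations

* Cost mid-points inherit the arbitrariness of the open-ended top band;
  conclusions about absolute costs should use the configurable map with
  case-specific estimates.
* Benefit is an ordinal product, not a monetised quantity; AUC compares
  orderings, not welfare.
* The permutation null treats species as exchangeable; it does not
  condition on taxonomic group or environment.
* p-values near the +1/+1 floor (1/(1+n_perm)) are resolution-limited;
  increase `n_perm` for smaller p.
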
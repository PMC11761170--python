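# Methods

This note documents the models, rules and numerical choices behind
`apesoc`, and what the synthetic-data generator does and does not
emulate.

## Data model and node set

The unit of analysis is the *node*: one individual within one group
tenure. Networks are static over the study window, so an individual
that transfers between groups is represented once per tenure (node ids
`X`, `X2`, ...), each tenure age-classed independently. This keeps a
female who dispersed at adulthood an immature in her natal group's
network neighbourhood and an adult female in her new group's, which is
how long-term multi-group studies treat such individuals. Dated records
(events, scans) are routed to the tenure active on the record's date.

Age-sex classes are assigned from the **average age over the
individual's residence window**, computed as the age at the window
midpoint (identical for any residence interval). Defaults: females are
adult above 10 years; males are immature below 8, blackback from 8
onward, and silverback only when the registry records the date the male
was recognised as silverback and that date precedes the window midpoint
— silverback status is observational, not an age cut-off, so an
unflagged old male stays blackback. Thresholds are configurable
(`AgeThresholds`) and an explicit per-row override always wins.
Individuals of unknown sex can only be classed immature (the adult
classes are sex-specific); adults of unknown sex require an override.
Dates are ISO-8601; all intervals are closed-open `[start, end)`.

Behaviour terms collapse to three reporting classes; by default
`submission` is tallied with aggression (it is the complement of an
agonistic interaction), which is overridable through the mapping
argument since tabulation conventions differ between studies.

## Networks

**Interaction counts.** Direction is discarded; cell (i, j) is the
total number of events between the pair. The upper-triangle sum equals
the validated event count, asserted throughout the tests.

**Nearest-neighbour SRI.** The scan design is anchored on silverbacks:
only dyads containing at least one silverback have sampling occasions,
so all other dyads are fixed at 0 rather than treated as missing. For a
sampled dyad, "together" means being the scan's recorded
silverback–nearest-neighbour pair, and the denominator is the number of
scans in which either member was observed — the standard simple-ratio
denominator x + y_A + y_B + y_AB. Scans with no recorded neighbour
still contribute observation occasions to denominators. A
never-observed dyad returns 0 with a warning instead of NaN.
Intergroup dyads with a positive SRI at or below 0.0009 are raised to
0.001 (flooring); intragroup cells are never floored, and flooring
never decreases a value.

**Binarization.** An edge requires interacting *more than once* over
the study (count > 1, threshold exclusive and configurable): a single
event over a multi-year window is treated as noise, not a relationship.

**Expected network.** A prior-knowledge null with binary edges between
every group member and the group's silverback(s) — all of them, in a
multi-male group — plus co-resident mother–offspring pairs and maternal
siblings. The rules are deliberately within-group only, so the null
predicts zero intergroup edges and the observed-vs-expected comparison
directly measures the surplus of (mostly intergroup and peer-peer)
relationships. After a transfer, kin edges do not follow the disperser:
her second-tenure node is linked only through her new group's
silverback. This is a modelling choice; cross-group kin edges can be
added by editing the returned matrix.

## Density and the bootstrapped paired t-test

Density is the proportion of possible dyads holding an edge (binary) or
the mean of all off-diagonal cells (valued; can exceed 1 for count
networks). Both networks in a comparison must share the node set, so
dyad universes match.

The test forms replicate density differences by resampling:

- `node_bootstrap` (default): each replicate draws n nodes with
  replacement and measures the mean off-diagonal cell of the induced
  submatrix of each network, ignoring self-pair positions. This is the
  standard network bootstrap and is robust to node-level dependence,
  at the price of being conservative when dyad values are effectively
  independent.
- `dyad_bootstrap`: replicates jointly resample dyad value *pairs*
  (a_ij, b_ij) with replacement and take the mean paired difference —
  the classic paired bootstrap-t of a mean difference. This route is
  the calibrated one under independent dyads (type-I error at the
  nominal level, verified in the acceptance suite at 500 null
  simulations). The name `edge_permutation` is accepted as an alias
  for interface compatibility; a literal within-matrix permutation of
  dyad values is a no-op for density (a mean over the same cells), so
  the resampling version is what is implemented.

From the replicates: t = observed difference / SD(replicates, ddof 1);
the 95% CI is the replicate 2.5–97.5 percentile band; the two-sided
p-value counts replicates recentred at zero that are at least as
extreme as the observed difference, with the add-one correction
(r + 1)/(N + 1) so 0 is never reported. Default 5,000 iterations.
Output is bit-reproducible for a fixed seed; a self-comparison gives a
difference of exactly 0 and p ≈ 1.

## Simulated removals

A knockout zeroes every row and column of the removed age-sex class
while keeping matrix dimensions, exactly "replacing edges with zeros":
densities before and after are therefore comparable on the same dyad
universe, and density can only decrease. Edge losses are reported on
edge *presence* (counts of nonzero dyads), split intragroup /
intergroup / total, as percentages of the pre-removal edges in each
split (0 where a split had no edges). Weighted losses can be derived
from the attached densities. Each removal result carries the
bootstrap comparison of observed vs. removed density.

Reporting centrality is the leading eigenvector of the weighted
adjacency matrix (optionally restricted to one group's subnetwork),
scaled to a maximum of 1; on a disconnected network mass concentrates
on the dominant component, and an edgeless network yields zeros with a
warning. It is used for node scaling in figures, not for inference.

## Descriptive tables and the model export

Dyad-category tables tabulate interactions (with per-row
play / other-affiliation / aggression percentages) and
nearest-neighbour associations (percent of the grand total), with
conserved subtotals. Percentages are stored unrounded; presentation
rounding is decimal half-up. Per-group descriptives report totals under
both intergroup-attribution conventions (credit both groups / drop
intergroup records), since reported per-group means are convention-
dependent.

The monthly model table counts, per individual and month, total scans
observed and scans whose scanned activity was social (a per-scan flag
column, not inferred from the event stream, since the response is
scan-based). The inclusion filter drops months with fewer than 20
scans, then individuals with fewer than 5 surviving months — in that
order by default; the opposite order can drop different individuals
and is available via the `order` argument. Continuous predictors are
z-scored with the population SD (the transformed column has SD exactly
1) and the means/SDs are exported so raw values reconstruct exactly; a
constant predictor z-scores to zeros and is flagged. The offset is
log(total monthly scans). Fitting the negative-binomial mixed model
itself is intentionally out of scope: the export is handed to standard
mixed-model software.

## The synthetic-data generator

`SimConfig` defaults *are* the emulated study conditions: 4 groups over
96 months; compositions drawn uniformly from 1–2 silverbacks, 2–5
blackbacks, 1–8 adult females and 1–3 immatures, resampled into a
group size of 5–17; per-dyad monthly interaction counts Poisson by
default (negative-binomial via `overdispersion`) with class-pair rates
tuned so category totals approximate the field frequencies (play ≈ 95%
of events, aggression < 1%, intergroup ≈ 2%); behaviour mixes per
category; one scripted female transfer at a month boundary, birth-dated
so she is immature at her natal-tenure midpoint and adult after
dispersal; sinusoidal fruit availability and log-normal rainfall.

Scans pick the silverback (uniformly in a multi-male group), observe
each other member with probability 0.9 (so SRI denominators are
nontrivial), and draw the nearest neighbour class-first: a class is
chosen by the configured propensities (0.48 immature / 0.31 adult
female / 0.20 blackback / 0.01 silverback) among classes present in the
scan, then a member uniformly within the class. Class-first sampling
makes aggregate partner-class shares converge to the propensities
regardless of composition — verified at three sample sizes with
shrinking error. Intergroup nearest neighbours occur at rate 0.002 per
scan. One ScanRecord yields one nearest-neighbour association; the
default of 140 records per group-month emulates the field study's
association volume (≈ 54,000), not its number of scan sessions.

`plant_removal_effect` rescales rates so a class removal loses a target
percentage of a context's edges: dyads incident to the class get a
near-certain edge (p = 0.95), and the shared edge probability of the
remaining dyads is solved in closed form from P(Poisson(μ) ≥ 1) = p
(matching the edge definition used by `removal_impact` on count
matrices), with expected dyad counts estimated by a fixed-seed
Monte-Carlo over the composition distribution. Infeasible targets
(required probability above 1) raise.

Every dataset passes the full validation layer, and the emitted ground
truth (per-dyad counts, per-scan neighbour assignments, expected-edge
list) matches pipeline tabulations *exactly*, for every seed — the
generator and pipeline agree record-for-record, not just statistically.

What the generator does **not** emulate: demographic turnover beyond
the one scripted transfer (no births/deaths mid-study), spatial
structure and home-range geometry, observer effort variation,
autocorrelated behaviour within days, or dyad-level personality
heterogeneity beyond class rates. Passing tests therefore demonstrate
the pipeline's correctness and calibration under the stated sampling
model, not robustness to every field-data pathology.

## Numerical choices and problem sizes

- Matrices are validated (symmetry, zero diagonal, flavor domain) on
  construction; SRI serialisation keeps 12 significant digits, counts
  and binary round-trip exactly.
- Bootstrap replicates are generated in memory-bounded chunks; all
  randomness flows through `numpy.random.default_rng(seed)`.
- The flooring comparison uses a 1e-15 absolute guard so values at the
  threshold boundary are classified stably.
- Test-suite problem sizes are chosen for exhaustive checkability:
  oracle comparisons use ≤ 6-node fixtures; the type-I calibration
  uses 500 null pairs of 30-node networks at 1,000 iterations; planted
  removal recovery uses 20 seeds of a 24-month study; the
  nearest-neighbour share check uses one full-scale (96-month) study.

## Known limitations

- The bootstrap density test is approximate: the node bootstrap is
  conservative for independent dyads, and the dyad bootstrap ignores
  node-level dependence; neither is an exact conditional network test
  (MRQAP / ERGM approaches are out of scope).
- Static networks: no time-sliced or dynamic analysis.
- Half-weight and other association indices are not implemented; the
  SRI is the only index, though `SriComponents` admits extension.
- The expected network is a deliberately simple rule null; richer
  nulls (degree-preserving rewires, kin-distance models) are left to
  the comparison layer's users.
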
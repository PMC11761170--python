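# apesoc

Social-network inference for multi-group wild ape observational data.

`apesoc` turns the two standard behavioural-sampling streams of a
long-term primate field study — **all-occurrence dyadic interaction
records** and **instantaneous group scans** recording the silverback's
nearest neighbour — into analysable social networks, and tests hypotheses
about how connectivity is distributed within and between neighbouring
groups. It was built around the study design of multi-group western
lowland gorilla monitoring (several neighbouring groups followed daily
over years, with occasional intergroup encounters and a female transfer
between groups), but the data model is generic.

## What it computes

Given an individual registry (with group-membership intervals and
maternal pedigree), an interaction event table and a scan table, the
package builds four matrices over the analysis node set (one node per
individual per group tenure — a transferring female appears as an
immature in her natal group and an adult female where she settled):

- **Interaction counts** — bidirectional totals per dyad.
- **Nearest-neighbour associations** — the simple ratio index per dyad,

  SRI(A,B) = x / (x + y_A + y_B + y_AB),

  where x counts scans with A and B recorded as the
  silverback–nearest-neighbour pair and the y's count scans where one or
  both were observed apart. Intergroup SRIs in (0, 0.0009] are floored
  to 0.001 so rare between-group associations survive rounding.
- **Binary observed network** — an edge wherever a dyad interacted more
  than once.
- **Expected network** — a prior-knowledge null: edges between every
  group member and the group's silverback(s), mother–offspring pairs,
  and maternal siblings.

Inference uses **matrix-based bootstrapped paired t-tests of network
density** (node resampling by default, joint dyad resampling as the
calibrated alternative; t = Δdensity / SD of replicate differences, with
percentile CIs and add-one-corrected two-sided p-values) and **simulated
removals** (knockouts) that zero all edges of an age-sex class to
quantify its contribution to intra- and intergroup connectivity.

A seeded synthetic-data generator (`apesoc.synthetic_data`) emulates the
field design — group compositions, play-dominated interaction mixes,
nearest-neighbour class propensities, one between-group transfer — and
emits exact ground truth, so the full pipeline runs and is testable with
no external data.

## Worked example

```python
import tempfile
from apesoc import obs_data, net_build, net_stats, synthetic_data

data_dir, truth = synthetic_data.generate_study(
    synthetic_data.SimConfig(seed=7, scans_per_month=20), tempfile.mkdtemp()
)
registry, events, scans, _ = obs_data.validate_dataset(data_dir)
nodes = obs_data.derive_node_set(registry)

counts = net_build.build_interaction_matrix(events, nodes)
binary = net_build.binarize(counts)            # edge = interacted more than once
expected = net_build.build_expected_network(nodes, registry)

test = net_stats.bootstrap_paired_density_test(binary, expected,
                                               iterations=5000, seed=17)
print(f"observed density {test.density_a:.4f}  expected density {test.density_b:.4f}")
print(f"difference {test.difference:.4f}  T = {test.t_statistic:.2f}  "
      f"95% CI [{test.ci95[0]:.4f}, {test.ci95[1]:.4f}]  P = {test.p_value:.4f}")

removed = net_stats.simulate_class_removal(counts, nodes, "blackback")
impact = net_stats.removal_impact(counts, removed, nodes, seed=17,
                                  removed_class="blackback")
print(f"blackback knockout: intergroup edges lost "
      f"{impact.intergroup_edge_loss_pct:.0f}%")
```

prints

```
observed density 0.1546  expected density 0.0718
difference 0.0827  T = 2.61  95% CI [0.0229, 0.1464]  P = 0.0114
blackback knockout: intergroup edges lost 66%
```

Read: over a simulated 8-year study the observed binary network is about
twice as dense as the rule-built expectation — dyads beyond
silverback-hub and kin relationships interact repeatedly, including
across groups — and the bootstrap rejects equal density. Knocking out
the blackback class erases about two thirds of the between-group edges,
identifying young males as the main intergroup connectors.

The same steps are available from a shell:

```bash
apesoc simulate --out study/ --seed 7
apesoc validate --data-dir study/
apesoc build-networks --data-dir study/ --out nets/
apesoc compare --a nets/observed_binary.csv --b nets/expected_binary.csv --seed 17
apesoc knockout --matrix nets/interaction_counts.csv --nodes nets/nodes.csv --class blackback
apesoc tabulate --data-dir study/ --out tables/
apesoc glmm-export --data-dir study/ --out model_data.csv
```

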
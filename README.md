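# specnet

Group-level correlation-network analysis of athlete performance
variables. For each competition edition, the finalists are split into
medalists (ranks 1–3) and non-medalists (ranks 4–8); six variables (age,
weight, height, BMI, Olympic medal count, reaction time) become the
nodes of a complete weighted graph whose link weights are pairwise
Pearson correlations within the group. Each network is summarized by its
spectral radius (largest eigenvalue of the symmetric connection matrix)
and per-node eigenvector-centrality scores, and the two groups are
compared with one-way ANOVA + Tukey HSD plus a small-sample permutation
test. A latent-factor cohort generator with per-edition calibrated
marginals makes the whole pipeline testable without external data.

## Layout

| module                | purpose                                                       |
|-----------------------|---------------------------------------------------------------|
| `specnet.synthesis`   | synthetic cohorts: latent-factor model, calibrated defaults   |
| `specnet.cohort_io`   | CSV ingest/validation, medal split, node-variable selection   |
| `specnet.network`     | Pearson link weights, connection matrix, exports              |
| `specnet.spectral`    | eigen decomposition, spectral radius, Perron diagnostics      |
| `specnet.comparison`  | ANOVA, Tukey HSD, link-weight/SR comparisons, permutation test|
| `specnet.pipeline`    | end-to-end orchestration, deterministic report artifacts      |
| `specnet.cli`         | `specnet` command-line interface                              |

## CLI

```sh
# generate a synthetic 5-edition cohort (40 athletes) as CSV
specnet synthesize --seed 42 --out cohort.csv

# analyze an existing cohort CSV
specnet analyze --input cohort.csv --weight-mode absolute --out results/

# synthesize + analyze in one step (config file optional)
specnet all --seed 42 --out results/
specnet all --config cfg.yaml --out results/

# summarize an existing run
specnet report --report results/report.json
```

`results/` will contain `report.json`, `sr_table.csv`,
`comparisons.json`, per-network edge lists (CSV + GraphML), labeled
connection matrices, per-node score tables, and `pipeline.log`. Runs are
deterministic given the seed.

Cohort CSV schema (header, order-free, case-insensitive):

```
edition,rank,age,weight_kg,height_cm,bmi,olympic_medals,reaction_time_s[,race_time_s,velocity_ms]
```

## Library example

```python
import specnet

records = specnet.generate_editions(specnet.default_config(seed=42))
medal, rest = specnet.split_by_medal(
    [r for r in records if r.edition_label == "Sydney 2000"]
)
net = specnet.build_network(
    specnet.select_node_variables(medal), medal.variables,
    group_label=medal.group_label,
)
print(specnet.spectral_radius(net))
```

## Notes

- Default link weights are absolute correlations (`|r|`), keeping the
  connection matrix non-negative so Perron–Frobenius guarantees apply to
  the spectral radius; signed weights are retained alongside and a
  signed mode is available.
- Zero-variance variables (e.g. a group where nobody holds a medal)
  yield undefined correlations; those links are kept with weight 0 and
  flagged, so every network in a run shares the same 6-node topology.
- The permutation test re-partitions the 8 athletes into 3/5 groups and
  rebuilds both networks per shuffle; it supplements the ANOVA, whose
  distributional assumptions are fragile at these group sizes.
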
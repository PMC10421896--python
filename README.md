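# fosnet

Correlation-based functional-network analysis of regional immediate-early-gene
expression — from per-animal c-Fos cell counts to brain-wide functional
networks, community structure, hub identification, and permutation-based
between-condition comparison.

## The problem

Counting c-Fos–positive cells ~90 minutes after a behavioural event gives a
per-region snapshot of neural activation.  Beyond asking *which* regions were
more active in one condition than another, one can ask how regions *co-vary*:
if two regions' expression rises and falls together across the animals of a
condition, they are inferred to be functionally coupled.  Thresholding the
resulting inter-regional correlation matrix yields an undirected functional
network per condition whose topology — density, communities, hubs — can be
compared across learning conditions (here: contextual fear conditioning with
the context and shock overlapped, CFC, versus separated by a 5-s interval,
CFC-5s, alongside homecage, context-only and immediate-shock controls, for a
49-region / 9-anatomical-group atlas).

The cohort-level statistics are:

- **Edges.** Pearson r across the animals of a condition, with two-sided
  p from t = r·√(n−2)/√(1−r²), df = n−2.  An edge exists iff r > 0 and
  p < threshold (both p < 0.05 and p < 0.01 networks are built; edges of
  the stricter network are a subset of the laxer one by construction).
- **Edge contrasts.** Fisher z = atanh(r); either the raw difference
  z₁ − z₂ (flagged at |·| ≥ 2) or the standardized two-sample statistic
  (z₁ − z₂)/√(1/(n₁−3) + 1/(n₂−3)) (flagged at 1.96).
- **Mesoscale.** Modularity-optimal communities (seeded multilevel
  heuristic with a deterministic local-moving refinement); per node the
  within-community degree z-score WC and participation coefficient
  PC = 1 − Σₛ(κ_is/k_i)².  Provincial hubs: WC ≥ 1.5 & PC ≤ 0.3;
  connector hubs: PC ≥ 0.8 & WC ≤ 1.5.
- **Centrality hubs.** Weighted degree, eigenvector, betweenness,
  closeness; a node in the top 25% of ≥ 3 measures is a hub; hubs present
  at both p thresholds are *stable* hubs.
- **Inference.** Group-label permutation test: shuffle animals between two
  conditions, rebuild correlations → networks → centralities each time,
  and compare each region's observed centrality difference with its
  resampling distribution.

Because per-animal regional c-Fos datasets are rarely public, the package
ships a synthetic cohort generator that plants condition-specific activation
(multiplicative mean shifts) and coupling (block-structured latent
correlations) so that every stage of the pipeline is testable end to end and
its statistical calibration and recovery can be measured.

## Worked example

```python
import fosnet

# a synthetic 69-animal, 6-condition cohort emulating the study design
expr = fosnet.generate_cohort(fosnet.study_like_spec(seed=11))
design = fosnet.study_design()
norm = fosnet.normalize_to_baseline(expr, design)   # percent of homecage mean

corr = fosnet.correlation_matrix(norm, "CFC-5s")
net = fosnet.build_network(corr, 0.05)
summary = fosnet.graph_summary(net)
print(f"edges: {summary.n_edges}, density: {summary.density:.3f}, "
      f"average degree: {summary.average_degree:.1f}")

part = fosnet.detect_communities(net, seed=0)
print(f"modularity Q = {part.q:.3f} over {len(part.communities)} communities")

hubs = fosnet.identify_hubs(fosnet.centralities(net))
print("hubs:", sorted(hubs.hubs))

cats = fosnet.classify_engagement(fosnet.compare_activation(norm, design), design)
print("target-specific regions:", sorted(cats.index[cats == "target-specific"]))
```

prints

```
edges: 1042, density: 0.886, average degree: 42.5
modularity Q = 0.066 over 3 communities
hubs: ['AD', 'AV', 'BLAp', 'BMEp', 'CEA', 'CENT', 'ECT', 'MEAp', 'MO', 'RSGca', 'VO', 'vCA3']
target-specific regions: ['BLAp', 'DIENT', 'IL', 'LAv', 'MEAa', 'PER', 'PL', 'POR', 'VIENT', 'vCA1', 'vSUB']
```

The CFC-5s-like condition yields a dense network (most region pairs share a
strong cohort-wide activation component, so density is high and Q low — and
varies considerably between cohorts of n = 11), several amygdala nuclei and
thalamic nuclei rank among the centrality hubs, and the per-region contrast
analysis recovers exactly the eleven regions whose activation the generator
planted as specific to that condition.

A command-line interface mirrors the library (`fosnet simulate`,
`activation`, `connectivity`, `network`, `topology`, `permute`, `all`); the
`all` subcommand runs the whole pipeline from a YAML config and writes CSV
tables, GraphML networks and a JSON manifest whose seeds and hashes make the
run exactly reproducible.

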
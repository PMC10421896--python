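# Methods

This note documents the statistical model behind each stage, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions in corner cases.

## Data model and normalization

Expression is an animals × regions table of non-negative c-Fos–positive
cell counts with a condition label per animal.  The shipped atlas has 49
regions in 9 anatomical groups (prefrontal cortex PFC, medial prefrontal
cortex mPFC, retrosplenial cortex RSC, thalamus TAL, amygdala AMY, dorsal
and ventral hippocampus DH/VH, subicular complex SUB, parahippocampal
cortex PHC); it is a plain CSV and fully user-overridable.  Baseline
normalization divides each value by the homecage (HC) group's per-region
mean and multiplies by 100, so the baseline group's means are exactly 100.
Pearson correlations are invariant under this per-region linear rescaling,
so every network result is identical on raw and normalized scales; the
normalized scale only matters for the activation tables.

Missing measurements (e.g. lost posterior tissue) stay `NaN` and propagate
to pairwise-complete correlations with the per-pair n recorded; they are
never silently zeroed.

The default condition design is HC 12, CFC 11, CFC-5s 11, CT 11, CT-5s 12,
US 12 (69 animals).  Sample sizes below 4 are rejected because the
correlation p-value needs df = n − 2 ≥ 2.

## Synthetic cohorts

Per condition the generator draws a latent multivariate normal with a
correlation matrix built as background ρ₀ everywhere, overwritten by ρ
inside designated blocks, optionally with one "hub" region correlated ρ
with every other region.  Positive semi-definiteness is verified by an
eigenvalue check (tolerance 1e−10) before any sampling; the hub coupling
in particular is capped by the Schur-complement bound
ρ ≤ √((1 + (k−2)ρ₀)/(k−1)) ≈ 0.56 for 49 regions at ρ₀ = 0.3 — a single
region simply cannot correlate arbitrarily strongly with 48 mutually
moderately correlated partners.

The latent draw is mapped to counts by a moment-matched lognormal
(default; strictly positive and right-skewed like real counts) or a
zero-clipped normal.  Correlation targets are on the latent scale; the
observed Pearson correlation of lognormals is attenuated by less than
0.01 at the default coefficient of variation (CV) of 0.25, which no
downstream analysis resolves.  Activation effects are multiplicative fold
shifts applied to both mean and SD, preserving the CV as expected for
count-like data.

Defaults: base mean 150 counts, SD 37.5 (CV 0.25).  The study-like spec
plants (a) a 2.5-fold shift in eleven regions for CFC-5s only, (b) a
2.0-fold shift in six regions for both conditioning variants, and (c) an
amygdala-block latent correlation of 0.9 in CFC-5s over a background of
ρ₀ = 0.75.  The high background reproduces the globally dense published
networks (graph density near 0.8 at p < 0.05 with n = 11 implies typical
inter-regional correlations around 0.75): region-level c-Fos counts share
a strong cohort-wide arousal component.  A consequence worth knowing:
with n = 11 the whole correlation matrix is estimated from the same few
animals, so single-cohort network density fluctuates widely between seeds
(roughly 0.6–0.95); only multi-seed averages are stable.

What the generator does *not* emulate: hemispheric structure, spatially
graded (distance-dependent) correlations, heavy-tailed outlier animals,
and count discreteness at low expression.  Tests passing on these cohorts
therefore validate the pipeline's statistics and bookkeeping, not the
biological fidelity of any particular dataset.

## Activation analysis

The omnibus per-region test is a Welch (unequal-variance) one-way ANOVA,
implemented vectorized over regions (Welch's F with Satterthwaite
denominator df), with a label-permutation F as an alternative; pairwise
contrasts are Welch t-tests with a standardized mean difference
(difference of means over pooled SD) as effect size.  Gatekeeping is on
by default: contrasts are evaluated only where the omnibus p < α,
mirroring protected post-hoc practice.  No multiple-testing correction is
applied across the 49 regions by default (matching the unadjusted
reporting convention of this literature); Benjamini–Hochberg is available
by flag.  Regions with zero variance in every group are flagged
undefined, never dropped.

The engagement rule is evaluated per region, first match wins:

1. **target-specific** — the focal condition (CFC-5s) significantly
   exceeds every other condition;
2. **both-conditionings** — CFC and CFC-5s do not differ, each exceeds at
   least one neutral control (US or HC), and each exceeds its respective
   context control (CT / CT-5s) *or* those context controls are
   indistinguishable from the neutral controls;
3. **contextual** — both context-exposure controls significantly exceed
   the baseline (a package-defined rule; the source logic names only the
   first two categories);
4. **other** — some significant contrast but no rule matched;
5. **none**.

A caveat surfaced by simulation: in cohorts where several regions are
genuinely activated by *both* conditionings, chance separation of the two
conditioning groups (probability ≈ α/2 per such region, correlated across
regions when the background correlation is high) occasionally promotes a
co-activated region to target-specific.  This is a property of the
decision rule at α = 0.05, not of the implementation.

## Connectivity and edge contrasts

Correlation p-values use the exact t transform with df = n − 2
(pairwise-complete n under missingness).  The critical |r| at n = 11 is
0.602 (p < 0.05) and 0.735 (p < 0.01).  Edge differences between
conditions are computed in both circulating conventions — the raw Fisher-z
difference flagged at |z₁ − z₂| ≥ 2, and the standardized two-sample
statistic flagged at 1.96, which is the one that actually corresponds to
α = 0.05 and is the default.  The two disagree in general (a raw
difference of 1.96 standardizes to 3.93 at n = 11, 11); outputs label the
mode explicitly.

Anatomical-group summaries average coefficients within a group
(|g|(|g|−1)/2 values), from a group to all others (|g|·(K−|g|)), and
between group pairs (|a|·|b|); undefined coefficients are excluded with a
count.  The per-scope comparison between conditions (Welch t on
Fisher-transformed coefficients, or a coefficient permutation) treats
coefficients as exchangeable units although they share animals; its
p-values are screening heuristics, as in the GZLM-based practice it
replaces, and are labelled as such.

## Networks and graph measures

Networks keep all atlas regions as nodes; edges are significant positive
correlations (strict p < threshold, r > 0), weighted by r and by Fisher z.
Significant negative correlations are counted as a diagnostic but never
become edges.  Shortest-path measures are unweighted ("minimum number of
edges"); weights enter only weighted degree (and optionally eigenvector
and community detection).  Density is reported both over connected nodes
(the convention matching a published 46-connected-node example) and over
all nodes.  Global efficiency averages 1/d over all ordered pairs with
unreachable pairs contributing 0; average path length averages d over
reachable pairs only; maximum eccentricity is the largest finite distance
("regions connected up to k edges" is read as this quantity).

## Communities, roles, centralities, hubs

Community detection maximizes modularity.  Default: networkx multilevel
Louvain, seed-fixed, best of 8 restarts, followed by a deterministic
single-node local-moving refinement (relocate single nodes while Q
improves).  The refinement matters on small graphs, where the coarse
multilevel pass can land in a local optimum; with it, the heuristic
attains the exhaustively enumerated optimum on community-structured
graphs of ≤ 10 nodes in the test suite.  On *unstructured* random graphs
no polynomial heuristic reliably finds the global modularity optimum
(measured ≈ 4–5% miss rate even with 64 restarts); the exhaustive
enumerator (`exhaustive_small`, ≤ 10 non-isolated nodes) exists precisely
to provide ground truth there.  Leading-eigenvector (igraph) is offered
as an alternative.  Community weights default to Fisher z.

WC z-scores use the population SD within each community, with z = 0 when
the SD is 0 (including singleton communities).  The participation
coefficient defaults to the Guimerà–Amaral squared-share form
1 − Σₛ(κ_is/k_i)²; the simple ratio 1 − κ_own/k is kept as a variant
because both phrasings circulate.  Role thresholds: provincial iff
WC ≥ 1.5 and PC ≤ 0.3, connector iff PC ≥ 0.8 and WC ≤ 1.5.

Centralities: weighted degree sums edge r (Fisher z optional);
eigenvector centrality is the principal eigenvector of the weighted
adjacency computed per connected component (each component scaled to
maximum 1; isolated nodes 0); betweenness is unnormalized Brandes on
unweighted paths (computed via igraph for speed; verified against a
layer-DP path-counting oracle); closeness is (reachable nodes)/(sum of
distances to them).  Hub rule: per measure the top floor(N·0.25) nodes by
value (ties broken by value then lexicographic code; ties exactly at the
cutoff expand the list with a logged notice), hub = flagged in ≥ 3 of the
4 measures, stable hub = hub at both thresholds.

## Permutation test

The two conditions' animals are pooled and labels reshuffled without
replacement (sizes preserved), recomputing correlations, networks and
centralities per resample; 1000 resamples by default.  Label assignment
is canonical in the sorted condition names, so swapping the comparison's
direction negates all differences and exchanges the tails exactly.  Three
p-value conventions are emitted per (region, measure, threshold): the
literal resampling frequency with strict ">" (can be exactly 0), the
(count+1)/(n_perm+1) correction, and a tie-aware Monte-Carlo p counting
"≥" with the +1 correction — the convention that is exactly valid under
exchangeability and the one used for calibration statements (ties matter
because betweenness is discrete on sparse graphs).  The directional p
(tail chosen by the observed sign) is convenient for reporting which
group was higher but doubles the nominal one-sided level; calibration
uses the fixed upper tail.

Power at n = 11 per group is modest for single-region effects: at the
strongest PSD-feasible hub coupling (ρ ≈ 0.55 over background 0.3) the
per-region Wdg/Evc rejection rate is ≈ 0.6.  Block-level effects (an
11-region block at ρ = 0.9) are detected essentially always at the block
level, and network-level hub identification of a planted hub region
succeeds in ≈ 100% of seeds — the per-node permutation comparison is the
least powered lens on the same structure.

## Problem sizes used by the test suite and acceptance script

Calibrations use 5000 replicates (edge difference), 45 000 region×rep
nulls (activation omnibus), and 5 cohorts × 200 permutations × 196
region-measure pairs (permutation test).  Recovery scenarios use 100
seeds each at the study's per-condition sample sizes (n = 11–12, 49
regions).  Oracle equivalence covers 200 random weighted graphs of ≤ 12
nodes plus exhaustive-enumeration checks on ≤ 10-node graphs.  These
sizes keep the whole suite in a few minutes while leaving Monte-Carlo
standard errors well inside the asserted tolerance bands.

## Known limitations

- Group-connectivity comparisons treat overlapping correlation
  coefficients as independent observations (screening only).
- Eigenvector centrality across disconnected components has no canonical
  relative scaling; each component is scaled to max 1 independently.
- The exhaustive community oracle is limited to 10 non-isolated nodes
  (Bell-number growth).
- The generator's equicorrelated background makes single-cohort network
  statistics highly variable at n = 11; this mirrors the real situation
  but means point values from any one cohort should not be
  over-interpreted.
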
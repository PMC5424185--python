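# Methods

This note documents the models and procedures behind `sociosurvey`: how
instruments are scored, how sociometric responses become networks, what
the social metrics mean, what the synthetic generator emulates, and the
numerical and design choices made where more than one reasonable option
existed.

## Instrument scoring

An instrument is an ordered list of multiple-choice items; each option
carries a numeric value, and a scoring rule — an arithmetic expression
over item values with `+ − × ÷`, `sum(...)`, `mean(...)`, and literals —
produces the total. `sum(*)` (the default) is the plain sum of all item
values. The grammar is deliberately minimal: no conditionals, no
comparisons. Conditional scoring would need a schema extension, and none
of the bundled instruments requires it.

**Attainable range.** Band tables must cover the attainable total range
exactly, so the range is computed, not declared. When every item
reference occurs exactly once in the expression (true of all sum-type
rules), interval evaluation is exact: each item contributes its own
min/max and the interval combination of `+ − × ÷` is tight for
single-occurrence variables. Expressions that repeat a reference fall
back to exhaustive enumeration over option combinations, refused above
10⁶ combinations. Division by an interval spanning zero is refused.

**Bands.** Score bands are validated as sorted, non-overlapping,
adjacent (`next.lo = prev.hi + 1` on integer scales), and jointly
covering the attainable range — a gapped or overlapping band table is a
definition error, reported with the gap position. AUDIT's bands are the
four published risk zones over 0–40.

**Missing answers.** Policy is an explicit parameter, default `strict`
(any missing item is an error). `prorate` imputes missing items with the
mean value of the answered ones — the standard half-scale convention —
and `omit` scores them at the item minimum, which treats silence as
absence of the behavior and is the right reading for screening items.
Prorated totals are rounded half-up to integer resolution before band
mapping, because band tables are integer ranges. Integer-valued
instruments keep exact integer totals.

**Provisional definitions.** Only AUDIT's full structure (ten items
graded 0–4, items 9–10 taking 0/2/4) and zone table are reproduced from
its published documentation. KIDSCREEN-27 (27 items in five dimensions:
physical well-being, psychological well-being, autonomy & parent
relation, social support & peers, school environment), FAS II, ESTUDES,
and the Spanish self-efficacy adaptation ship with correct item counts
and dimension structure but placeholder wording and simple sum scoring;
they are marked `provisional: true` in their metadata and should be
replaced with normative definitions before substantive use. KIDSCREEN's
official scoring (Rasch-based T-values) is out of scope.

## Sociometric expansion and roster edits

A name-generator template holds a prompt with an `{alter}` placeholder
and a tie-strength scale. Expansion against a roster produces one
generated item per alter, with ids encoding `(template, alter)` so
answers trace back to the named person. One-mode templates exclude the
ego (self-ties are not meaningful in friendship data); two-mode
templates (e.g. drinking venues) keep every entity. Every generated item
offers an implicit "no relation" option with weight 0 — an unanswered or
zero-weight item records no tie. This resolves the ambiguity of whether
per-alter answers are mandatory: they are not, and silence means no
relation.

Roster edits regenerate the affected items and return a change report.
Removal never deletes data: stored answers naming the removed alter are
flagged as orphaned, and destroying them is left to an explicit decision.
Pseudonymization uses HMAC-SHA256 of the value under a user-supplied
salt, truncated to 12 hex characters — deterministic across re-runs with
no state to persist beyond the salt, with collision probability
negligible at survey scales (birthday bound ≈ n²/2⁴⁹).

## Networks

Edges run ego → alter: the namer points to the named, so **popularity**
is in-degree. One edge per (ego, alter, relation); repeated answers are a
validation error upstream. Isolates are kept — a student naming no one
is a finding. Tie weights are the scale weights (1/2/3 on the default
acquaintance/partner/friend scale); `filter_by_level` drops ties below a
relationship level, and `symmetrize` produces undirected networks under
a `mutual` rule (both directions required; weight min or max) or `any`
rule. Reciprocity is the fraction of directed ties returned by the named
party, undefined (signaled) on edgeless networks.

## Social metrics

Geodesics are unweighted throughout: scale weights encode relationship
strength, not distance, so path length is counted in hops.

* **Popularity** — in-degree, raw and divided by n−1.
* **Mediation** — shortest-path betweenness (Brandes accumulation via
  networkx), normalized by (n−1)(n−2) for directed networks and half
  that undirected. Unreachable pairs contribute nothing.
* **Influence** — no standard index is mandated by the problem, so the
  package's documented choice is a damped random-surfer score on
  *reversed* name-edges (damping 0.85, L∞ tolerance 10⁻⁹, dangling mass
  teleported uniformly), normalized to sum to 1. Rationale: in
  name-generator data, being named — especially by well-connected
  namers — is the natural influence proxy; reversing the edges makes the
  surfer flow from namer to named.
* **Communities** — two-phase Louvain modularity maximization at
  resolution 1.0 (classic modularity; the resolution is configurable in
  principle but deliberately not swept). Directed networks are first
  symmetrized with rule `any`, weight max, and the coercion is logged,
  never silent. Edgeless networks get singleton communities with Q
  defined as 0. The returned Q is the modularity of the stored
  partition, re-evaluated from its definition in tests.
* **Personal rankings** — `influencers_for` ranks the ego's named
  alters by global influence; `mediators_for` ranks candidates by
  ego-targeted betweenness (geodesics from every source that end at the
  ego and pass through the candidate, counted via per-source BFS path
  counts multiplied with reverse-BFS counts to the ego). Ties in any
  ranking break by node id, so output is deterministic.
* **Score homophily** — Pearson correlation of a node score across the
  symmetrized edge list with both orientations included (the standard
  attribute-assortativity construction). Zero-variance cases where all
  tied endpoints share one score report 1.0; otherwise undefined
  variance reports no value.

## Longitudinal comparison

Wave alignment builds the union person index with per-wave presence
flags; joiners and leavers are set differences between consecutive
waves. Network diffs report ties gained/lost and Jaccard stability over
the common node set (disjoint node sets are signaled, not defaulted).
Zone-transition matrices count persons per (band at wave a, band at
wave b); persons absent in either wave are excluded from the cells and
visible in the alignment instead — mixing attrition into transitions
would bias the counts. No smoothing or influence-vs-selection inference
is attempted; the module is descriptive.

## Reports

Rendering is slot-filling over an editable phrase catalog
(`data/templates/phrases_en.json`), so identical inputs produce
byte-identical text and every phrase can be audited or translated.
Standings ("among the highest in the group") are quartile cut points
computed within the network: top ≥ 75th percentile, then ≥ 50th, ≥ 25th,
else lowest. Technical index names (betweenness, eigenvector,
modularity, …) never appear in rendered prose — reports are written for
readers with no network-analysis background — and every numeric claim in
the text is mirrored in the section's structured payload. One language
ships; the catalog structure supports others.

## Synthetic studies

The generator emulates a multi-school sociometric deployment: by default
214 students in 9 classrooms (seven of 24, two of 23) across 3 schools,
sex drawn 50/50.

* **Consumption levels.** Each student gets a planted level 0–3
  (none/low/moderate/high) with probabilities (0.40, 0.35, 0.17, 0.08) —
  a right-skewed distribution typical of adolescent screening samples.
  Level-conditional AUDIT totals are normal with means (1, 5, 12, 22)
  and SDs (1.5, 2.5, 3, 4), truncated to 0–40; the level means put the
  bulk of each level in a distinct risk zone.
* **Friendship.** Each ego draws a Poisson(5) out-degree and samples
  distinct alters with selection log-odds `2.0·same_class +
  0.5·same_sex + 1.0·consumption_similarity` (similarity = 1 − level
  gap / 3); softmax is computed stably so a very large boost degenerates
  cleanly to the within-group limit. Tie levels are drawn with
  probabilities (0.2, 0.3, 0.5) over acquaintance/partner/friend.
* **Popularity–consumption coupling.** After the network is drawn, each
  student's consumption latent is tilted by `coupling ×` their
  standardized in-degree (default coupling 1.0). The expected AUDIT
  total follows the latent continuously — level means are linearly
  interpolated and end-slope extrapolated — so the coupling keeps acting
  above the top planted level instead of saturating at its bin.
* **Item decomposition.** A drawn total is decomposed into item answers
  by walking the items with suffix achievable-sum sets, choosing
  uniformly among the options that keep the remainder reachable — exact
  for any option-value structure, including AUDIT's 0/2/4 items.
* **Seeding.** One integer seed spawns an independent generator stream
  per stage (cohort / friendship / responses), so each stage is
  reproducible in isolation.

What the generator does **not** emulate: realistic item-level
correlation structure within instruments (non-AUDIT instruments are
answered uniformly), reciprocity norms (nominations are drawn
independently per ego, so reciprocity sits near the density-driven
baseline rather than the elevated levels real friendship data show),
degree heterogeneity beyond Poisson, and measurement error in
self-reports. Passing pipeline and recovery tests therefore demonstrates
correctness of the machinery and identifiability of the planted effects
at study scale — not that real cohorts look like these.

## Problem sizes and determinism

The test suite verifies metrics against brute-force oracles (explicit
path enumeration, exhaustive search over all set partitions, scripted
power iteration) on graphs of up to 8 nodes, where exhaustive answers
are computable exactly; recovery of planted effect signs is checked over
100 replicated simulations at the default 214-student scale, sizes
chosen so the full suite runs in well under a minute of compute per
module. The acceptance script re-derives its quantities at the same
sizes. All library randomness flows through explicit seeds; pipeline
runs with the same seed produce byte-identical artifact trees (GEXF
output pins its modification-date field to a constant for this reason).

## Known limitations

* Provisional instrument definitions (everything except AUDIT) carry
  placeholder wording and scoring.
* `mediators_for` enumerates per-source BFS counts; on networks far
  larger than a few thousand nodes a targeted Brandes accumulation would
  be preferable.
* Family and venue relations are modeled as roster-based templates like
  any other relation; free-text name generators are not supported.
* Only pairwise wave comparison is provided; no trajectory modeling.
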
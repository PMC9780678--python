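# Methods

This note records what phytoscreen computes, the defaults it ships with
and why, what the synthetic generators emulate, and the numerical choices
a maintainer would want to know.

## The screening model

The pipeline formalizes a common natural-product screening recipe as a
deterministic, auditable computation.

**Curation.** Library entries carry a controlled-vocabulary class tag
(`triacylglycerol`, `diacylglycerol`, `phosphatidylethanolamine`,
`inorganic`, `flavonoid`, `anthocyanin`, `other`). Class filtering is
tag-driven, not substructure-driven: food databases ship ontology classes,
and class deletion is a curatorial decision, so the excluded set is config
(`filters.excluded_classes`), defaulting to the three glycerolipid
classes. Inorganic detection combines the tag with a structural heuristic
— no carbon atom in the parsed molecule — because "inorganic" exports are
named by example (water, salts) rather than by rule. The molecular-weight
cut removes MW strictly below `min_mw` (default 100 Da); an entry at
exactly the cutoff is retained. Unparsable structures are never dropped
silently: they carry `parse_ok=False`, pass through descriptor-dependent
stages untouched, and simply have no descriptor-based rule outcomes later,
so every stage report remains a partition of its input.

**Descriptors.** Seven properties: average-mass MW (drug-likeness rules
are conventionally stated on average masses, not monoisotopic), hydrogen-
bond acceptor and donor counts, rotatable bonds (non-ring single bonds
between non-terminal heavy atoms, amide C–N excluded — RDKit's default),
SSSR ring count, net formal charge, and Crippen atom-contribution logP
(deterministic, no trained model). Salts are reduced first to the fragment
with the most heavy atoms (ties: heavier fragment, then lexicographically
smaller canonical SMILES), so an anthocyanin chloride is scored as its
flavylium cation, which correctly carries fChar = +1. Two acceptor/donor
conventions exist because toolkits disagree: the default counts N+O atoms
as acceptors and N/O atoms bearing ≥ 1 H as donors (water → 1/1); the
`pharmacophore` alternative delegates to RDKit's stricter definitions.
Descriptors are computed on the re-canonicalized molecule so any spelling
of a molecule yields a bit-identical vector (float summation order in the
logP estimate is otherwise visible at the 1e-13 level).

**Cumulative scoring.** The score is a weighted sum of rule indicators.
The shipped default rule set is a *reconstruction* of a conservative
first-pass screen — it restricts size and basic physicochemistry and
requires all toxicity endpoints negative — and is not a published
standard: 100 ≤ MW ≤ 600, nHA ≤ 12, nHD ≤ 7, nRot ≤ 11, nRing ≥ 1,
−1 ≤ fChar ≤ +1, 0 ≤ logP ≤ 5, and each of the eight endpoint
probabilities < 0.5, all unit-weighted. Every threshold is overridable in
a YAML rule file and the active set is echoed into the run report. A rule
whose property is missing becomes `not_evaluable` and leaves the
denominator: the normalized score compares compounds across endpoint
coverage gaps, while the raw score is still reported. Probability
endpoints threshold at 0.5 by default (per-rule configurable). Ranking is
raw score ↓, normalized score ↓, compound id ↑ — the id tie-break makes
the top-k bit-reproducible; boundary ties are logged.

**Consensus voting.** Prediction tools with heterogeneous score semantics
are reduced to per-compound ranks (when only scores are given, ranks are
assigned by descending score, ties by target id). The top-k cutoff
(default 20) marks records rather than dropping them, because the
downstream states distinguish a hit past the cutoff (`hit_beyond_topk`)
from a true miss (`no_hit`); `not_covered` requires a tool manifest.
A manifest with an unknown universe cannot distinguish `no_hit` from
`not_covered`, so the default policy is to refuse; `assume_covered` and
`not_covered` overrides exist and the choice is explicit config. For every
pair the four state counts sum to the number of tools — this conservation
law is the module's core invariant and is property-tested. The network is
bipartite with all compounds and targets present as nodes (isolated nodes
included, keeping node counts deterministic) and edges where votes ≥
`min_votes` (default 1).

**Built-in target fishing.** The offline similarity predictor scores a
target by the maximum Tanimoto similarity between the query and that
target's reference ligands, on hashed circular fingerprints (radius 2,
2048 bits — the standard ECFP4-like setting, configurable). It is
plumbing so the pipeline runs without web services; it does not emulate
any particular external tool's statistics.

**Assay statistics.** `Ratio(%) = 100·F/F0` (scale-invariant by
construction), JC-1 MMP = FI530/FI590, percent-of-control mapping the
control mean to 100%. Group comparisons use a two-sided single-sample
t-test of each treated group against the control mean — the literal
triplicate design the statistics assume — with Welch's two-sample test
available as an alternative and a Bonferroni switch that is off by
default (matching the uncorrected convention of small assay panels).
Degenerate zero-variance groups are split: all values equal to the
reference give (t = 0, p = 1); all equal but different from the reference
are reported as p = 0 with a warning rather than a crash or a silent NaN.
The ThT lag time is the first time the baseline-corrected intensity
(baseline = first sample, plateau = maximum) crosses a fraction of the
dynamic range, linearly interpolated inside the crossing interval. The
10% default is this module's own convention — aggregation papers narrate
lag phases without defining them — and the fraction is exposed. A flat
series returns "no transition" (None), not a number. The estimator is
monotone in the threshold fraction and recovers the analytic crossing of
a generating logistic to within one sampling interval.

## Synthetic data: what it does and does not emulate

The generator produces the *shape* of the problem, not any real dataset:

- a library of `n_compounds` (default 200) with class proportions
  (defaults: 25% flavonoid, 12% anthocyanin, 35% other, 20% glycerolipid
  classes, 8% inorganic) and `n_planted` actives (default 10) whose
  descriptors fall inside every default rule window with a margin and
  whose endpoints are all clearly negative (≤ 0.40);
- decoys that each violate at least one rule by a margin, never at a
  boundary (glycerolipids are oversized and over-flexible, inorganics are
  tiny and ringless, organic decoys draw 1–3 violation modes, including
  positive toxicity endpoints ≥ 0.60). The generator re-scores its own
  output with the real scoring engine and refuses to emit a library
  whose planted set is not identifiable;
- predictor hit lists where a covered true pair enters a tool's top-k
  with probability `sensitivity` (default 0.8), decoy pairs with
  `false_hit_rate`, sub-cutoff appearances with `beyond_topk_rate`, and
  per-target coverage with probability `coverage` — so consensus votes on
  true pairs follow Binomial(n_tools, sensitivity) exactly when coverage
  is 1, giving a closed-form calibration check (6 tools × 0.8 → mean 4.8,
  P(votes ≥ 2) ≈ 0.9984);
- replicate groups (n = 3 by default) as true mean + Gaussian noise, and
  a logistic aggregation curve sampled at 0–96 h (9 points, the typical
  sparse schedule) whose default midpoint/rate place the 10% lag near 6 h.

Descriptor values are *sampled*, not computed from the template SMILES
attached to each record; the templates exist so structure-dependent code
paths (parsing, carbon detection, fingerprints) run on real molecules.
Consequently, passing tests demonstrate the pipeline's bookkeeping,
scoring, voting, and statistics are correct under known ground truth —
they say nothing about real class frequencies, real descriptor
correlations, or real predictor error structure, none of which the
generator attempts to match.

Randomness: one master integer seed; each generator derives an
independent substream keyed by (seed, CRC32 of the generator name,
index), so adding a generator never perturbs existing draws.

## Numerical and design details

- Boundary semantics: MW = `min_mw` is kept by the cascade; `between`
  rules are inclusive on both ends; probability rules use strict `< 0.5`.
- Score ties at the selection boundary are resolved by compound id and
  logged; permutation of the input never changes the selection.
- Stage reports enforce `n_out = n_in − |removed|` at construction, and
  the pipeline report model refuses stage sequences whose counts do not
  chain; the report JSON schema is published at `docs/report_schema.json`.
- Reports record relative artifact paths and no timestamps, so a rerun
  with the same config and seed is byte-identical (report, vote table,
  edge list, GraphML).
- Default problem sizes in tests and the acceptance script (200-compound
  libraries, 20 recovery seeds, 1,000 conservation sets, 2,000
  calibration pairs) were chosen as the smallest sizes at which the
  Monte-Carlo tolerances quoted above are meaningful; everything runs in
  seconds on one CPU.

## Known limitations

- The default rule set is a reconstruction, not a citation; real projects
  should supply their own thresholds (the design intent is precisely that
  the filter is customized per project).
- ADMET endpoint values are ingested, never predicted: the package has no
  QSAR models and does not retrain any external predictor.
- Target identity is a plain accession string; the optional alias mapping
  covers simple renames only, with no organism or isoform resolution.
- `hit_beyond_topk` is only observable when a tool's full list is
  available; with truncated exports, absent targets for covered tools
  degrade to `no_hit` (a coverage warning applies).
- The lag-time estimator assumes a sigmoidal time course with the plateau
  inside the observation window; strongly non-monotone curves (for
  example aggregation followed by disaggregation) are summarized only up
  to their first threshold crossing.
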
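# phytoscreen

Rule-based virtual screening of food-compound libraries, built for the
workflow that takes a raw natural-product export (for example a FooDB-style
table of plant constituents) to a short list of drug-like candidates with
consensus-predicted protein targets — plus the small-sample assay
statistics used to verify hits in vitro.

## What it computes

**Curation cascade.** A compound library is cleaned in three auditable
stages: (1) deletion of excluded ontology classes (glycerolipids such as
triacylglycerols, diacylglycerols, phosphatidylethanolamines); (2) removal
of water and inorganic entries (class tag, or no carbon atom in the parsed
structure); (3) removal of very small molecules (MW < 100 Da by default),
which tend to bind without specificity. Every stage reports
`n_in`, `n_out`, and the removed ids, and the counts chain across stages.

**Cumulative ADMET score.** Each surviving compound *i* is scored against a
rule set R over its seven physicochemical descriptors (MW, nHA, nHD, nRot,
nRing, fChar, logP; computed with RDKit after counter-ion stripping) and
its predicted toxicity endpoints (hERG, H-HT, Ames, ROA, Carcinogenicity,
Respiratory, and the two carcinogenicity/mutagenicity classes):

    S_i = Σ_{r ∈ R} w_r · 1[property_r(i) meets requirement r]

with unit weights by default. Rules whose property is unavailable are
`not_evaluable` and leave the denominator, so `S_i / S_i^max` stays
comparable across coverage gaps. Compounds are ranked by raw score
(ties: normalized score, then compound id) and the top k = 10 retained.

**Consensus target voting.** Ranked hit lists from multiple target
predictors are reduced to per-compound ranks, the first 20 hits per tool
retained, and each (compound, target, tool) triple assigned one of four
states: `hit`, `hit_beyond_topk`, `no_hit`, `not_covered`. The consensus
vote of a pair is its number of `hit` tools; pairs with enough votes become
edges of a bipartite compound–target network (TSV + GraphML export). A
built-in max-Tanimoto similarity predictor (ECFP4-like hashed circular
fingerprints, radius 2 / 2048 bits) lets the stage run fully offline.

**Assay statistics.** Fluorescence ratios `Ratio(%) = 100·F/F0`, the JC-1
mitochondrial-membrane-potential ratio `FI530/FI590`, percent-of-control
normalization, two-sided single-sample t-tests on triplicate groups
(`t = (x̄ − μ₀)/(s/√n)`), and a thioflavin-T lag-time summarizer (first
threshold crossing of the baseline-corrected curve, default 10% of the
dynamic range).

**Synthetic data.** `phytoscreen.synthetic_data` generates libraries with
planted rule-passing actives (every decoy violates ≥ 1 rule by a margin),
simulated predictor outputs with controllable sensitivity / false-hit rate /
coverage, and replicate assay data — all deterministic per seed — so the
whole pipeline is testable without downloads.

## Worked example

Run the bundled 50-compound fixture (5 planted actives, 3 targets, 6
simulated prediction tools):

```
$ phytoscreen screen --config examples/fixture/config.yaml --out-dir out
scored 29 compounds; top 5:
   # 1 C_0002 raw=15/15 normalized=1.000
   # 2 C_0004 raw=15/15 normalized=1.000
   # 3 C_0025 raw=15/15 normalized=1.000
   # 4 C_0027 raw=15/15 normalized=1.000
   # 5 C_0031 raw=15/15 normalized=1.000
```

The cascade ran 50 → 35 → 35 → 29 (15 glycerolipids deleted by class, no
inorganics left after that in this draw, 6 sub-100 Da entries removed); the
five compounds passing all 15 rules (7 physicochemical windows + 8 negative
toxicity endpoints) are exactly the planted actives, and `out/network.tsv`
holds the 15 compound–target edges with their per-tool vote states.
`out/report.json` is the full machine-readable run report (schema in
`docs/report_schema.json`).

Or drive the library directly:

```python
from phytoscreen import (LibraryConfig, generate_library, default_ruleset,
                         evaluate_rules, rank_and_select)

lib = generate_library(LibraryConfig(n_compounds=200, n_planted=10, seed=7))
cards = [evaluate_rules(lib.descriptors.get(r.compound_id),
                        lib.admet[r.compound_id],
                        default_ruleset(), compound_id=r.compound_id)
         for r in lib.compounds]
top10 = rank_and_select(cards, k=10)
assert sorted(c.compound_id for c in top10) == sorted(lib.active_ids)
```

## Layout

- `src/phytoscreen/library_io.py` — library ingestion + curation cascade
- `src/phytoscreen/descriptors.py` — the seven descriptors, salt stripping
- `src/phytoscreen/admet_rules.py` — rule sets, scoring, ranking
- `src/phytoscreen/target_consensus.py` — vote states, networks, target fishing
- `src/phytoscreen/bioassay_stats.py` — ratios, t-tests, lag times
- `src/phytoscreen/synthetic_data.py` — ground-truth generators
- `src/phytoscreen/pipeline.py`, `cli.py` — orchestration and the `phytoscreen` CLI
- `docs/methods.md` — modelling choices, defaults, and limitations
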
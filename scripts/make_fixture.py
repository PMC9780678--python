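"""Regenerate the bundled example fixture under examples/fixture/.

The fixture is a small synthetic screening problem (50 compounds, 5
planted actives, 3 targets, 6 predictor tools) written in the exact file
dialects the pipeline consumes, plus a ground-truth file computed here
from the generator output (not from the pipeline under test).

Run from the repository root:  python scripts/make_fixture.py
"""

from __future__ import annotations

import json
from pathlib import Path

from phytoscreen import admet_rules, library_io, synthetic_data, target_consensus
from phytoscreen import descriptors as descriptors_mod

SEED = 20221209
OUT = Path(__file__).resolve().parent.parent / "examples" / "fixture"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    lib_config = synthetic_data.LibraryConfig(
        n_compounds=50, n_planted=5, n_invalid=1, seed=SEED
    )
    library = synthetic_data.generate_library(lib_config)
    library_io.write_compound_table(library.compounds, OUT / "library.csv")
    descriptors_mod.write_descriptor_csv(library.descriptors, OUT / "descriptors.csv")
    admet_rules.write_admet_table(library.admet, OUT / "admet.csv")

    targets = list(target_consensus.DEFAULT_TARGETS)
    true_pairs = [(cid, t) for cid in library.active_ids for t in targets]
    pred_config = synthetic_data.PredictorSimConfig(
        n_tools=6, sensitivity=0.9, false_hit_rate=0.05, coverage=0.9, topk=20, seed=SEED
    )
    predictions, manifests = synthetic_data.generate_predictions(pred_config, true_pairs)
    pred_entries = []
    for tool in sorted(predictions):
        name = f"predictions_{tool}.tsv"
        target_consensus.write_predictions_tsv(predictions[tool], OUT / name)
        pred_entries.append({"tool_id": tool, "path": name})
    target_consensus.write_manifests_yaml(manifests, OUT / "manifests.yaml")

    config = {
        "seed": SEED,
        "inputs": {
            "library": "library.csv",
            "library_format": "csv",
            "descriptors": "descriptors.csv",
            "admet": "admet.csv",
            "predictions": pred_entries,
            "manifests": "manifests.yaml",
        },
        "filters": {
            "excluded_classes": sorted(library_io.DEFAULT_EXCLUDED_CLASSES),
            "min_mw": 100.0,
        },
        "scoring": {"top_k": 5},
        "targets": {
            "targets_of_interest": targets,
            "top_k": 20,
            "min_votes": 1,
        },
    }
    import yaml

    with open(OUT / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)

    # ground truth straight from the generator output
    covered = {m.tool_id: m.covered_targets for m in manifests}
    hit_pairs = set()
    for tool, records in predictions.items():
        for rec in records:
            if rec.rank <= pred_config.topk and rec.target_id in covered[tool]:
                hit_pairs.add((rec.compound_id, rec.target_id))
    truth = {
        "seed": SEED,
        "active_ids": library.active_ids,
        "n_initial": len(library.compounds),
        "n_after_class": len(library.compounds) - len(library.removed_by_class),
        "n_after_inorganic": len(library.compounds)
        - len(library.removed_by_class)
        - len(library.removed_by_inorganic),
        "n_after_mw": len(library.survivor_ids),
        "removed_by_class": library.removed_by_class,
        "removed_by_inorganic": library.removed_by_inorganic,
        "removed_by_mw": library.removed_by_mw,
        "expected_edges": len(hit_pairs),
        "top_k": 5,
    }
    with open(OUT / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    print(f"fixture written to {OUT}: {len(library.compounds)} compounds, "
          f"{len(library.active_ids)} actives, {truth['expected_edges']} expected edges")


if __name__ == "__main__":
    main()
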
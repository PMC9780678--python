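"""End-to-end screening pipeline driven by a single YAML config.

Stage order: class filter -> inorganic/water filter -> molecular-weight
filter -> descriptor computation (or table load) -> cumulative rule
scoring -> top-k selection -> consensus target aggregation -> network
export.  The run report chains the per-stage counts, echoes the active
rule set, and records only relative artifact paths, so an identical
config and seed reproduce byte-identical outputs.

Inputs come either from files (``inputs:`` block) or from the synthetic
generator (``simulate:`` block); nothing is downloaded.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Sequence

import yaml
from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__
from . import admet_rules, descriptors, library_io, synthetic_data, target_consensus
from .errors import ConfigurationError, DataError, ScreeningError

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "seed",
    "out_dir",
    "simulate",
    "inputs",
    "filters",
    "descriptors",
    "ruleset",
    "scoring",
    "targets",
}


class StageReportModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    stage_name: str
    n_in: int
    n_out: int
    removed_ids: list[str]


class TopCompoundModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    compound_id: str
    raw_score: float
    max_possible: float
    normalized_score: float
    rank: int


class VotePairModel(BaseModel):
    model_config = ConfigDict(extra="forbid")
    compound_id: str
    target_id: str
    votes: int


class ScreeningReport(BaseModel):
    """Validated, fully regenerable run report."""

    model_config = ConfigDict(extra="forbid")
    schema_version: int = 1
    package_version: str
    seed: int
    config: dict[str, Any]
    stages: list[StageReportModel]
    ruleset: list[dict[str, Any]]
    n_scored: int
    top_compounds: list[TopCompoundModel]
    votes: list[VotePairModel] | None = None
    artifacts: dict[str, str]

    @model_validator(mode="after")
    def _stages_chain(self) -> "ScreeningReport":
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if prev.n_out != nxt.n_in:
                raise ValueError(
                    f"stage counts do not chain: {prev.stage_name}.n_out="
                    f"{prev.n_out} != {nxt.stage_name}.n_in={nxt.n_in}"
                )
        return self


def load_config(path: str | Path) -> dict:
    """Load a YAML config; relative input paths resolve against the file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"config {path} must be a mapping")
    base = path.parent
    inputs = cfg.get("inputs")
    if isinstance(inputs, dict):
        for key in ("library", "descriptors", "admet", "manifests"):
            if key in inputs:
                inputs[key] = str((base / inputs[key]).resolve())
        for entry in inputs.get("predictions", []) or []:
            if "path" in entry:
                entry["path"] = str((base / entry["path"]).resolve())
    if "ruleset" in cfg and cfg["ruleset"]:
        cfg["ruleset"] = str((base / cfg["ruleset"]).resolve())
    return cfg


def _validate_config(cfg: dict) -> None:
    unknown = set(cfg) - _KNOWN_KEYS
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    if ("simulate" in cfg) == ("inputs" in cfg):
        raise ConfigurationError("config needs exactly one of 'simulate' or 'inputs'")


def run_screening(
    config: dict | str | Path,
    out_dir: str | Path | None = None,
    seed: int | None = None,
) -> ScreeningReport:
    """Execute the full screening cascade and write artifacts.

    On any stage failure the partially written artifacts are removed and a
    :class:`ScreeningError` naming the stage is raised.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    _validate_config(cfg)
    if seed is not None:
        cfg["seed"] = seed
    run_seed = int(cfg.get("seed", 0))
    out = Path(out_dir if out_dir is not None else cfg.get("out_dir", "phytoscreen_out"))
    out.mkdir(parents=True, exist_ok=True)

    created: list[Path] = []

    def emit(name: str, writer) -> str:
        path = out / name
        path.parent.mkdir(parents=True, exist_ok=True)
        writer(path)
        created.append(path)
        return name

    stage = "setup"
    try:
        artifacts: dict[str, str] = {}

        filters_cfg = dict(cfg.get("filters", {}))
        excluded = set(
            filters_cfg.get("excluded_classes", sorted(library_io.DEFAULT_EXCLUDED_CLASSES))
        )
        min_mw = float(filters_cfg.get("min_mw", 100.0))
        desc_cfg = dict(cfg.get("descriptors", {}))
        convention = desc_cfg.get("hbond_convention", "lipinski")
        scoring_cfg = dict(cfg.get("scoring", {}))
        score_k = int(scoring_cfg.get("top_k", 10))
        targets_cfg = dict(cfg.get("targets", {}))
        targets_of_interest = list(
            targets_cfg.get("targets_of_interest", target_consensus.DEFAULT_TARGETS)
        )
        target_k = int(targets_cfg.get("top_k", 20))
        min_votes = int(targets_cfg.get("min_votes", 1))
        unknown_policy = targets_cfg.get("unknown_universe_policy", "error")

        # ---- gather inputs ------------------------------------------------
        stage = "inputs"
        prediction_sets: dict[str, list[target_consensus.PredictionRecord]] = {}
        manifests: list[target_consensus.ToolManifest] = []
        desc_table: dict[str, descriptors.DescriptorVector] | None = None

        if "simulate" in cfg:
            sim = dict(cfg["simulate"] or {})
            lib_kwargs = dict(sim.get("library", {}))
            lib_config = synthetic_data.LibraryConfig(seed=run_seed, **lib_kwargs)
            library = synthetic_data.generate_library(lib_config)
            records = library.compounds
            desc_table = library.descriptors
            admet = library.admet
            pred_kwargs = dict(sim.get("predictors", {}))
            pred_config = synthetic_data.PredictorSimConfig(seed=run_seed, **pred_kwargs)
            true_pairs = [
                (cid, target) for cid in library.active_ids for target in targets_of_interest
            ]
            prediction_sets, manifests = synthetic_data.generate_predictions(
                pred_config, true_pairs, decoy_targets=sim.get("decoy_targets", ())
            )
            artifacts["input_library"] = emit(
                "inputs/library.csv", lambda p: library_io.write_compound_table(records, p)
            )
            artifacts["input_descriptors"] = emit(
                "inputs/descriptors.csv",
                lambda p: descriptors.write_descriptor_csv(desc_table, p),
            )
            artifacts["input_admet"] = emit(
                "inputs/admet.csv", lambda p: admet_rules.write_admet_table(admet, p)
            )
            for tool in sorted(prediction_sets):
                artifacts[f"input_predictions_{tool}"] = emit(
                    f"inputs/predictions_{tool}.tsv",
                    lambda p, t=tool: target_consensus.write_predictions_tsv(
                        prediction_sets[t], p
                    ),
                )
            artifacts["input_manifests"] = emit(
                "inputs/manifests.yaml",
                lambda p: target_consensus.write_manifests_yaml(manifests, p),
            )
        else:
            inputs = dict(cfg["inputs"] or {})
            records = library_io.read_compound_table(
                inputs["library"], format=inputs.get("library_format")
            )
            admet = admet_rules.load_admet_table(
                inputs["admet"], column_map=inputs.get("admet_column_map")
            )
            if "descriptors" in inputs:
                desc_table = descriptors.read_descriptor_csv(inputs["descriptors"])
            for entry in inputs.get("predictions", []):
                tool_id = entry["tool_id"]
                prediction_sets[tool_id] = target_consensus.load_predictions(
                    entry["path"], tool_id, column_map=entry.get("column_map")
                )
            if "manifests" in inputs:
                manifests = target_consensus.read_manifests_yaml(inputs["manifests"])

        # ---- curation cascade ---------------------------------------------
        stage = "class_filter"
        kept, report_class = library_io.filter_by_class(records, excluded)
        stage = "inorganic_filter"
        kept, report_inorganic = library_io.filter_inorganic(kept)
        stage = "descriptor_computation"
        if desc_table is None:
            desc_table = descriptors.compute_descriptor_table(kept, convention)
        stage = "molecular_weight_filter"
        kept, report_mw = library_io.filter_by_molecular_weight(kept, desc_table, min_mw)
        stage_reports = [report_class, report_inorganic, report_mw]
        artifacts["library_kept"] = emit(
            "library_kept.csv", lambda p: library_io.write_compound_table(kept, p)
        )

        # ---- cumulative scoring -------------------------------------------
        stage = "rule_scoring"
        ruleset_path = cfg.get("ruleset")
        ruleset = (
            admet_rules.load_ruleset(ruleset_path)
            if ruleset_path
            else admet_rules.default_ruleset()
        )
        scorecards = [
            admet_rules.evaluate_rules(
                desc_table.get(rec.compound_id),
                admet.get(rec.compound_id),
                ruleset,
                compound_id=rec.compound_id,
            )
            for rec in kept
        ]
        stage = "top_k_selection"
        selected = admet_rules.rank_and_select(scorecards, k=score_k)
        ordered_cards = sorted(scorecards, key=lambda c: c.rank or 0)
        artifacts["scorecards"] = emit(
            "scorecards.csv",
            lambda p: admet_rules.write_scorecards_csv(ordered_cards, ruleset, p),
        )

        # ---- consensus target voting --------------------------------------
        votes_model: list[VotePairModel] | None = None
        if prediction_sets:
            stage = "target_aggregation"
            selected_ids = {card.compound_id for card in selected}
            all_records: list[target_consensus.PredictionRecord] = []
            for tool in sorted(prediction_sets):
                tool_records = [
                    rec for rec in prediction_sets[tool] if rec.compound_id in selected_ids
                ]
                all_records.extend(target_consensus.apply_topk(tool_records, k=target_k))
            votematrix = target_consensus.assign_vote_states(
                all_records,
                manifests,
                targets_of_interest=targets_of_interest,
                compounds=sorted(selected_ids),
                unknown_universe_policy=unknown_policy,
            )
            stage = "network_export"
            graph = target_consensus.build_network(votematrix, min_votes=min_votes)
            artifacts["votes"] = emit("votes.tsv", lambda p: _write_votes_tsv(votematrix, p))
            artifacts["network_edge_list"] = emit(
                "network.tsv", lambda p: target_consensus.export_edge_list(graph, p)
            )
            artifacts["network_graphml"] = emit(
                "network.graphml", lambda p: target_consensus.export_graphml(graph, p)
            )
            votes_model = [
                VotePairModel(
                    compound_id=c, target_id=t, votes=votematrix.consensus_votes(c, t)
                )
                for c in votematrix.compounds
                for t in votematrix.targets
            ]

        # ---- report --------------------------------------------------------
        stage = "report"
        report = ScreeningReport(
            package_version=__version__,
            seed=run_seed,
            config=_jsonable(cfg),
            stages=[StageReportModel(**r.to_dict()) for r in stage_reports],
            ruleset=[rule.to_dict() for rule in ruleset],
            n_scored=len(scorecards),
            top_compounds=[
                TopCompoundModel(
                    compound_id=card.compound_id,
                    raw_score=card.raw_score,
                    max_possible=card.max_possible,
                    normalized_score=card.normalized_score,
                    rank=card.rank or 0,
                )
                for card in selected
            ],
            votes=votes_model,
            artifacts=artifacts,
        )
        artifacts["report"] = "report.json"
        emit(
            "report.json",
            lambda p: p.write_text(
                json.dumps(report.model_dump(), sort_keys=True, indent=2) + "\n",
                encoding="utf-8",
            ),
        )
        return report
    except ScreeningError:
        _cleanup(created)
        raise
    except Exception as exc:  # attach the failing stage, drop partial outputs
        _cleanup(created)
        raise ScreeningError(f"stage {stage!r} failed: {exc}") from exc


def _write_votes_tsv(votematrix: target_consensus.VoteMatrix, path: Path) -> None:
    import csv

    rows = votematrix.to_rows()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(
            fh,
            fieldnames=["compound_id", "target_id", "votes", *votematrix.tools],
            delimiter="\t",
            lineterminator="\n",
        )
        writer.writeheader()
        writer.writerows(rows)


def _cleanup(paths: Sequence[Path]) -> None:
    for path in paths:
        try:
            path.unlink(missing_ok=True)
        except OSError:  # pragma: no cover
            pass


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    return obj
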
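"""Consensus target prediction across multiple ranked hit lists.

Ligand-based target fishing tools disagree in score semantics, so their
outputs are reduced to per-compound ranks, the first *k* hits per tool
are retained (default 20), and each (compound, target, tool) triple is
assigned one of four vote states:

``hit``
    the tool placed the target within its top-k for this compound;
``hit_beyond_topk``
    the target appears in the tool's list, but past the cutoff;
``no_hit``
    the tool covers the target but did not report it;
``not_covered``
    the target is absent from the tool's prediction universe.

The consensus vote for a (compound, target) pair is the number of tools
voting ``hit``.  Pairs with enough votes become edges of a bipartite
compound-target network (weight = votes, per-tool states annotated).

A built-in similarity predictor (max-Tanimoto over per-target reference
ligands, hashed circular fingerprints) is provided so the stage can run
fully offline; it is plumbing, not a reimplementation of any external
prediction service.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .errors import ConfigurationError, DataError, StructureParseError

logger = logging.getLogger(__name__)

#: Default targets of interest: amyloid precursor protein / A-beta (1-42),
#: acetylcholinesterase, caspase-3.
DEFAULT_TARGETS = ("P05067", "P22303", "P42574")


class VoteState(str, Enum):
    HIT = "hit"
    HIT_BEYOND_TOPK = "hit_beyond_topk"
    NO_HIT = "no_hit"
    NOT_COVERED = "not_covered"


@dataclass(frozen=True)
class PredictionRecord:
    """One ranked prediction from one tool for one compound."""

    tool_id: str
    compound_id: str
    target_id: str
    rank: int
    score: float | None = None
    in_topk: bool = False


@dataclass(frozen=True)
class ToolManifest:
    """Which targets a tool can predict at all.

    ``covered_targets=None`` marks an unknown prediction universe; such a
    tool cannot distinguish ``no_hit`` from ``not_covered`` without an
    explicit policy override.
    """

    tool_id: str
    covered_targets: frozenset[str] | None = None

    def covers(self, target_id: str) -> bool | None:
        if self.covered_targets is None:
            return None
        return target_id in self.covered_targets


@dataclass
class VoteMatrix:
    """Vote states for every (compound, target, tool) triple."""

    compounds: list[str]
    targets: list[str]
    tools: list[str]
    states: dict[tuple[str, str, str], VoteState] = field(default_factory=dict)

    def state(self, compound_id: str, target_id: str, tool_id: str) -> VoteState:
        return self.states[(compound_id, target_id, tool_id)]

    def vote_counts(self, compound_id: str, target_id: str) -> dict[VoteState, int]:
        counts = {s: 0 for s in VoteState}
        for tool in self.tools:
            counts[self.states[(compound_id, target_id, tool)]] += 1
        return counts

    def consensus_votes(self, compound_id: str, target_id: str) -> int:
        return self.vote_counts(compound_id, target_id)[VoteState.HIT]

    def to_rows(self) -> list[dict]:
        """Long-format rows, deterministically ordered."""
        rows = []
        for c in self.compounds:
            for t in self.targets:
                per_tool = {tool: self.states[(c, t, tool)].value for tool in self.tools}
                rows.append(
                    {
                        "compound_id": c,
                        "target_id": t,
                        "votes": self.consensus_votes(c, t),
                        **per_tool,
                    }
                )
        return rows


def load_predictions(
    path: str | Path,
    tool_id: str,
    column_map: Mapping[str, str] | None = None,
    alias_map: Mapping[str, str] | None = None,
) -> list[PredictionRecord]:
    """Load one tool's prediction table (TSV or CSV by suffix).

    Expected columns (remappable via ``column_map``): ``compound_id``,
    ``target_id``, and ``rank`` and/or ``score``.  When ``rank`` is
    absent, ranks are assigned per compound by descending score, ties by
    target_id ascending.  ``alias_map`` normalizes foreign target
    identifiers (gene names, ChEMBL ids) to the canonical accession
    before duplicate checking.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"prediction file not found: {path}")
    cmap = {"compound_id": "compound_id", "target_id": "target_id", "rank": "rank", "score": "score"}
    cmap.update(column_map or {})
    delim = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    raw_rows: list[dict] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delim)
        fields = reader.fieldnames or []
        for key in ("compound_id", "target_id"):
            if cmap[key] not in fields:
                raise ConfigurationError(
                    f"prediction file {path} missing column {cmap[key]!r}"
                )
        has_rank = cmap["rank"] in fields
        has_score = cmap["score"] in fields
        if not has_rank and not has_score:
            raise ConfigurationError(
                f"prediction file {path} needs a rank or score column"
            )
        for row in reader:
            if alias_map:
                tid = row[cmap["target_id"]]
                row[cmap["target_id"]] = alias_map.get(tid, tid)
            raw_rows.append(row)
    if not raw_rows:
        raise DataError(f"prediction file {path} contains no rows")

    seen: set[tuple[str, str]] = set()
    by_compound: dict[str, list[dict]] = {}
    for row in raw_rows:
        pair = (row[cmap["compound_id"]], row[cmap["target_id"]])
        if pair in seen:
            raise DataError(
                f"duplicate prediction for pair {pair} in {path} (tool {tool_id})"
            )
        seen.add(pair)
        by_compound.setdefault(pair[0], []).append(row)

    records: list[PredictionRecord] = []
    for cid in by_compound:
        rows = by_compound[cid]
        if has_rank:
            for row in rows:
                score = float(row[cmap["score"]]) if has_score and row.get(cmap["score"]) else None
                records.append(
                    PredictionRecord(
                        tool_id, cid, row[cmap["target_id"]], int(row[cmap["rank"]]), score
                    )
                )
        else:
            ordered = sorted(
                rows, key=lambda r: (-float(r[cmap["score"]]), r[cmap["target_id"]])
            )
            for rank, row in enumerate(ordered, start=1):
                records.append(
                    PredictionRecord(
                        tool_id, cid, row[cmap["target_id"]], rank, float(row[cmap["score"]])
                    )
                )
    for rec in records:
        if rec.rank < 1:
            raise DataError(f"rank {rec.rank} < 1 for pair ({rec.compound_id}, {rec.target_id})")
    return records


def apply_topk(records: Sequence[PredictionRecord], k: int = 20) -> list[PredictionRecord]:
    """Set ``in_topk`` on every record; nothing is dropped.

    Records beyond the cutoff are needed later to distinguish
    ``hit_beyond_topk`` from ``no_hit``.
    """
    if k <= 0:
        raise ConfigurationError(f"top-k cutoff must be positive, got {k}")
    return [replace(rec, in_topk=rec.rank <= k) for rec in records]


def assign_vote_states(
    records: Sequence[PredictionRecord],
    manifests: Sequence[ToolManifest],
    targets_of_interest: Sequence[str] | None = None,
    compounds: Sequence[str] | None = None,
    unknown_universe_policy: str = "error",
) -> VoteMatrix:
    """Assign the four vote states to every (compound, target, tool) triple.

    ``unknown_universe_policy`` controls tools whose manifest has an
    unknown universe: ``"error"`` (default), ``"assume_covered"`` (absent
    targets become no_hit), or ``"not_covered"``.
    """
    if unknown_universe_policy not in ("error", "assume_covered", "not_covered"):
        raise ConfigurationError(
            f"unknown_universe_policy {unknown_universe_policy!r} not recognised"
        )
    by_tool: dict[str, ToolManifest] = {m.tool_id: m for m in manifests}
    tool_ids = sorted({rec.tool_id for rec in records} | set(by_tool))
    for tool in {rec.tool_id for rec in records}:
        if tool not in by_tool:
            raise ConfigurationError(f"no manifest for tool {tool!r}")
    comp_list = sorted(compounds) if compounds is not None else sorted(
        {rec.compound_id for rec in records}
    )
    targ_list = (
        list(targets_of_interest)
        if targets_of_interest is not None
        else sorted({rec.target_id for rec in records})
    )

    present: dict[tuple[str, str, str], PredictionRecord] = {}
    for rec in records:
        present[(rec.compound_id, rec.target_id, rec.tool_id)] = rec

    states: dict[tuple[str, str, str], VoteState] = {}
    for c in comp_list:
        for t in targ_list:
            for tool in tool_ids:
                covered = by_tool[tool].covers(t)
                rec = present.get((c, t, tool))
                if covered is False:
                    if rec is not None:
                        raise DataError(
                            f"tool {tool!r} predicted target {t!r} outside its manifest"
                        )
                    states[(c, t, tool)] = VoteState.NOT_COVERED
                    continue
                if covered is None and rec is None:
                    if unknown_universe_policy == "error":
                        raise ConfigurationError(
                            f"tool {tool!r} has an unknown target universe; set "
                            "unknown_universe_policy to 'assume_covered' or 'not_covered'"
                        )
                    if unknown_universe_policy == "not_covered":
                        states[(c, t, tool)] = VoteState.NOT_COVERED
                        continue
                if rec is None:
                    states[(c, t, tool)] = VoteState.NO_HIT
                elif rec.in_topk:
                    states[(c, t, tool)] = VoteState.HIT
                else:
                    states[(c, t, tool)] = VoteState.HIT_BEYOND_TOPK
    return VoteMatrix(comp_list, targ_list, tool_ids, states)


def build_network(votematrix: VoteMatrix, min_votes: int = 1) -> nx.Graph:
    """Bipartite compound-target network from a vote matrix.

    Edge present iff consensus votes >= ``min_votes``; edge attributes:
    ``votes`` and a ``states`` string ``tool=state;...`` (per-tool, in
    tool order).  All compounds and targets appear as nodes even when
    isolated, so node counts are deterministic.
    """
    graph = nx.Graph()
    for c in votematrix.compounds:
        graph.add_node(c, bipartite="compound")
    for t in votematrix.targets:
        graph.add_node(t, bipartite="target")
    for c in votematrix.compounds:
        for t in votematrix.targets:
            votes = votematrix.consensus_votes(c, t)
            if votes >= min_votes:
                states = ";".join(
                    f"{tool}={votematrix.state(c, t, tool).value}"
                    for tool in votematrix.tools
                )
                graph.add_edge(c, t, votes=votes, states=states)
    return graph


def export_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Deterministic TSV edge list (compound, target, votes, per-tool states)."""
    edges = []
    for u, v, data in graph.edges(data=True):
        if graph.nodes[u].get("bipartite") == "compound":
            c, t = u, v
        else:
            c, t = v, u
        edges.append((c, t, data["votes"], data.get("states", "")))
    edges.sort()
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["compound_id", "target_id", "votes", "states"])
        writer.writerows(edges)


def export_graphml(graph: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(graph, str(path))


def _fingerprint(smiles: str, radius: int, bits: int):
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=bits)
    return gen.GetFingerprint(mol)


def tanimoto(smiles_a: str, smiles_b: str, radius: int = 2, bits: int = 2048) -> float:
    """Tanimoto similarity of hashed circular fingerprints (ECFP-like)."""
    return DataStructs.TanimotoSimilarity(
        _fingerprint(smiles_a, radius, bits), _fingerprint(smiles_b, radius, bits)
    )


def similarity_target_predictor(
    query_smiles: str,
    reference: Sequence[tuple[str, str]],
    fp_radius: int = 2,
    fp_bits: int = 2048,
    k: int = 20,
) -> list[PredictionRecord]:
    """Rank targets by max Tanimoto similarity of the query to their ligands.

    ``reference`` is a sequence of (smiles, target_id) pairs.  Per target
    the best-matching ligand defines the score; targets are ranked by
    similarity descending, ties by target_id ascending, and the top ``k``
    are returned as records of the ``builtin_sim`` tool (ranked, with
    ``in_topk=True``).
    """
    if not reference:
        raise DataError("similarity predictor needs a non-empty reference set")
    if k <= 0:
        raise ConfigurationError(f"k must be positive, got {k}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=fp_radius, fpSize=fp_bits)
    qmol = Chem.MolFromSmiles(query_smiles)
    if qmol is None:
        raise StructureParseError(query_smiles)
    qfp = gen.GetFingerprint(qmol)
    best: dict[str, float] = {}
    for smiles, target_id in reference:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise StructureParseError(smiles)
        sim = DataStructs.TanimotoSimilarity(qfp, gen.GetFingerprint(mol))
        if sim > best.get(target_id, -1.0):
            best[target_id] = sim
    ordered = sorted(best.items(), key=lambda item: (-item[1], item[0]))
    return [
        PredictionRecord("builtin_sim", "query", target_id, rank, score=sim, in_topk=True)
        for rank, (target_id, sim) in enumerate(ordered[:k], start=1)
    ]


def write_manifests_yaml(manifests: Sequence[ToolManifest], path: str | Path) -> None:
    """Persist tool manifests; an unknown universe is written as null."""
    import yaml

    doc = {
        m.tool_id: (sorted(m.covered_targets) if m.covered_targets is not None else None)
        for m in manifests
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def read_manifests_yaml(path: str | Path) -> list[ToolManifest]:
    import yaml

    path = Path(path)
    if not path.exists():
        raise DataError(f"manifest file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise DataError(f"manifest file {path} must map tool_id to target lists")
    return [
        ToolManifest(tool, frozenset(targets) if targets is not None else None)
        for tool, targets in sorted(doc.items())
    ]


def write_predictions_tsv(records: Iterable[PredictionRecord], path: str | Path) -> None:
    """Write records in the TSV dialect :func:`load_predictions` reads."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["compound_id", "target_id", "rank", "score"])
        for rec in records:
            writer.writerow(
                [rec.compound_id, rec.target_id, rec.rank, "" if rec.score is None else rec.score]
            )
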
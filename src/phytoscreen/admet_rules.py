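"""Cumulative-score drug-likeness screening.

Each compound is checked against a configurable rule set over its seven
physicochemical descriptors and its predicted toxicity endpoints.  A rule
that passes contributes its weight to the compound's raw score; rules
whose property is unavailable (missing endpoint column, unparsable
structure) are marked ``not_evaluable`` and removed from the denominator,
so compounds remain comparable across coverage gaps via the normalized
score.  Compounds are then ranked and the top *k* retained.

The default rule set is a reconstruction of a conservative
natural-product screening recipe — molecular size restricted, basic
physicochemical windows, and all eight toxicity endpoints required
negative — with unit weights.  Every threshold can be overridden from a
YAML rule file; the active rule set is echoed into the run report.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .descriptors import DESCRIPTOR_NAMES, DescriptorVector
from .errors import ConfigurationError, DataError

logger = logging.getLogger(__name__)

#: Toxicity endpoint vocabulary (ADMETlab-style probabilistic predictions;
#: values are probabilities that the compound is positive for the endpoint).
ENDPOINTS = (
    "hERG",
    "H-HT",
    "Ames",
    "ROA",
    "Carcinogenicity",
    "Respiratory",
    "Non-Genotoxic_Carcinogenicity",
    "Genotoxic_Carcinogenicity_Mutagenicity",
)

PASS, FAIL, NOT_EVALUABLE = "pass", "fail", "not_evaluable"

COMPARATORS = ("lt", "le", "gt", "ge", "between", "category_equals")


@dataclass(frozen=True)
class Endpoint:
    """One predicted endpoint value; ``available=False`` when absent."""

    value: float | str | None
    available: bool = True


@dataclass
class AdmetProfile:
    """Per-compound endpoint predictions keyed by endpoint name."""

    compound_id: str
    endpoints: dict[str, Endpoint] = field(default_factory=dict)

    def get(self, name: str) -> Endpoint:
        return self.endpoints.get(name, Endpoint(None, available=False))


@dataclass(frozen=True)
class Rule:
    """One screening rule.

    ``property`` is a descriptor name or endpoint name; ``threshold`` is a
    number for lt/le/gt/ge, a (low, high) pair for ``between`` (inclusive
    on both ends), or a label for ``category_equals``.
    """

    rule_id: str
    property: str
    comparator: str
    threshold: float | str | tuple[float, float]
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.comparator not in COMPARATORS:
            raise ConfigurationError(
                f"rule {self.rule_id!r}: unknown comparator {self.comparator!r}"
            )
        if self.weight < 0:
            raise ConfigurationError(f"rule {self.rule_id!r}: negative weight")
        if self.comparator == "between":
            low, high = self.threshold  # type: ignore[misc]
            if low > high:
                raise ConfigurationError(
                    f"rule {self.rule_id!r}: between requires low <= high"
                )

    def evaluate(self, value: float | str) -> bool:
        if self.comparator == "lt":
            return value < self.threshold  # type: ignore[operator]
        if self.comparator == "le":
            return value <= self.threshold  # type: ignore[operator]
        if self.comparator == "gt":
            return value > self.threshold  # type: ignore[operator]
        if self.comparator == "ge":
            return value >= self.threshold  # type: ignore[operator]
        if self.comparator == "between":
            low, high = self.threshold  # type: ignore[misc]
            return low <= value <= high  # type: ignore[operator]
        return value == self.threshold  # category_equals

    def to_dict(self) -> dict:
        thr = list(self.threshold) if isinstance(self.threshold, tuple) else self.threshold
        return {
            "rule_id": self.rule_id,
            "property": self.property,
            "comparator": self.comparator,
            "threshold": thr,
            "weight": self.weight,
        }


@dataclass
class ScoreCard:
    """Per-compound rule outcomes and cumulative score."""

    compound_id: str
    outcomes: dict[str, str]
    raw_score: float
    max_possible: float
    normalized_score: float
    rank: int | None = None


def default_ruleset() -> list[Rule]:
    """Reconstructed default screening rules (unit weights, overridable).

    Physicochemical windows: 100 <= MW <= 600 Da, nHA <= 12, nHD <= 7,
    nRot <= 11, nRing >= 1, -1 <= fChar <= +1, 0 <= logP <= 5; plus every
    toxicity endpoint predicted negative (probability < 0.5).
    """
    rules = [
        Rule("mw_window", "mw", "between", (100.0, 600.0)),
        Rule("nha_max", "n_ha", "le", 12),
        Rule("nhd_max", "n_hd", "le", 7),
        Rule("nrot_max", "n_rot", "le", 11),
        Rule("nring_min", "n_ring", "ge", 1),
        Rule("fchar_window", "f_char", "between", (-1.0, 1.0)),
        Rule("logp_window", "logp", "between", (0.0, 5.0)),
    ]
    for name in ENDPOINTS:
        rules.append(Rule(f"tox_{name}_negative", name, "lt", 0.5))
    return rules


def load_ruleset(path: str | Path) -> list[Rule]:
    """Load rules from a YAML file with a top-level ``rules:`` list."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"ruleset file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "rules" not in doc:
        raise ConfigurationError(f"ruleset file {path} must contain a 'rules' list")
    rules = []
    for entry in doc["rules"]:
        thr = entry["threshold"]
        if isinstance(thr, list):
            thr = tuple(thr)
        rules.append(
            Rule(
                rule_id=entry["rule_id"],
                property=entry["property"],
                comparator=entry["comparator"],
                threshold=thr,
                weight=float(entry.get("weight", 1.0)),
            )
        )
    if not rules:
        raise ConfigurationError(f"ruleset file {path} defines no rules")
    return rules


def save_ruleset(rules: Sequence[Rule], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"rules": [r.to_dict() for r in rules]}, fh, sort_keys=False)


def load_admet_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> dict[str, AdmetProfile]:
    """Load an ADMETlab-style endpoint table (CSV).

    ``column_map`` maps endpoint names to column names when the export
    uses different headers; endpoints without a column are marked
    unavailable.  Probabilities outside [0, 1] and duplicate compound ids
    are errors.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"ADMET table not found: {path}")
    column_map = dict(column_map or {})
    profiles: dict[str, AdmetProfile] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        fields = reader.fieldnames or []
        if "compound_id" not in fields:
            raise ConfigurationError(f"ADMET table {path} missing 'compound_id' column")
        for name in column_map.values():
            if name not in fields:
                raise ConfigurationError(
                    f"ADMET table {path} missing mapped column {name!r}"
                )
        unknown = [
            c
            for c in fields
            if c != "compound_id" and c not in ENDPOINTS and c not in column_map.values()
        ]
        if unknown:
            raise DataError(f"ADMET table {path} has unknown endpoint columns {unknown}")
        for i, row in enumerate(reader, start=2):
            cid = row["compound_id"]
            if cid in profiles:
                raise DataError(f"duplicate compound_id {cid!r} in ADMET table row {i}")
            endpoints: dict[str, Endpoint] = {}
            for name in ENDPOINTS:
                col = column_map.get(name, name)
                raw = row.get(col)
                if raw is None or raw == "":
                    continue
                value = float(raw)
                if not 0.0 <= value <= 1.0:
                    raise DataError(
                        f"ADMET table row {i}: {name} probability {value} outside [0, 1]"
                    )
                endpoints[name] = Endpoint(value)
            profiles[cid] = AdmetProfile(cid, endpoints)
    if not profiles:
        raise DataError(f"ADMET table {path} contains no rows")
    return profiles


def write_admet_table(profiles: Mapping[str, AdmetProfile], path: str | Path) -> None:
    """Write profiles in the CSV dialect :func:`load_admet_table` reads."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["compound_id", *ENDPOINTS])
        for cid in profiles:
            profile = profiles[cid]
            row = [cid]
            for name in ENDPOINTS:
                ep = profile.get(name)
                row.append("" if not ep.available else ep.value)
            writer.writerow(row)


def _lookup(
    prop: str, descriptors: DescriptorVector | None, profile: AdmetProfile | None
) -> float | str | None:
    """Value of ``prop`` for a compound, or None when not evaluable."""
    if prop in DESCRIPTOR_NAMES:
        return None if descriptors is None else getattr(descriptors, prop)
    if prop in ENDPOINTS:
        if profile is None:
            return None
        ep = profile.get(prop)
        return ep.value if ep.available else None
    raise ConfigurationError(f"rule references unknown property {prop!r}")


def evaluate_rules(
    descriptors: DescriptorVector | None,
    profile: AdmetProfile | None,
    ruleset: Sequence[Rule],
    compound_id: str | None = None,
) -> ScoreCard:
    """Evaluate ``ruleset`` for one compound and build its score card.

    raw_score = sum of weights of passing rules; max_possible = sum of
    weights of evaluable rules; normalized = raw / max (0 when nothing is
    evaluable).
    """
    if not ruleset:
        raise ConfigurationError("empty ruleset")
    cid = compound_id or (profile.compound_id if profile is not None else "")
    outcomes: dict[str, str] = {}
    raw = 0.0
    max_possible = 0.0
    for rule in ruleset:
        value = _lookup(rule.property, descriptors, profile)
        if value is None:
            outcomes[rule.rule_id] = NOT_EVALUABLE
            continue
        max_possible += rule.weight
        if rule.evaluate(value):
            outcomes[rule.rule_id] = PASS
            raw += rule.weight
        else:
            outcomes[rule.rule_id] = FAIL
    normalized = raw / max_possible if max_possible > 0 else 0.0
    return ScoreCard(cid, outcomes, raw, max_possible, normalized)


def rank_and_select(scorecards: Sequence[ScoreCard], k: int = 10) -> list[ScoreCard]:
    """Sort score cards and return the top ``k``.

    Ordering: raw score descending, normalized score descending, then
    compound_id ascending (deterministic tie-break).  Ranks (1-based) are
    assigned on all cards; ties at the selection boundary are logged.
    """
    if k <= 0:
        raise ConfigurationError(f"k must be positive, got {k}")
    if not scorecards:
        raise DataError("no scorecards to rank")
    ordered = sorted(
        scorecards, key=lambda c: (-c.raw_score, -c.normalized_score, c.compound_id)
    )
    for i, card in enumerate(ordered, start=1):
        card.rank = i
    if k < len(ordered):
        last_in, first_out = ordered[k - 1], ordered[k]
        if (last_in.raw_score, last_in.normalized_score) == (
            first_out.raw_score,
            first_out.normalized_score,
        ):
            logger.info(
                "tie at selection boundary k=%d between %s and %s; "
                "resolved by compound_id order",
                k,
                last_in.compound_id,
                first_out.compound_id,
            )
    return list(ordered[:k])


def write_scorecards_csv(
    scorecards: Sequence[ScoreCard], ruleset: Sequence[Rule], path: str | Path
) -> None:
    rule_ids = [r.rule_id for r in ruleset]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["compound_id", *rule_ids, "raw_score", "max_possible", "normalized_score", "rank"]
        )
        for card in scorecards:
            writer.writerow(
                [
                    card.compound_id,
                    *[card.outcomes.get(rid, NOT_EVALUABLE) for rid in rule_ids],
                    card.raw_score,
                    card.max_possible,
                    f"{card.normalized_score:.6f}",
                    card.rank if card.rank is not None else "",
                ]
            )
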
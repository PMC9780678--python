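"""Synthetic benchmark data with known ground truth.

Everything the pipeline consumes — a compound library with class tags, a
descriptor table, ADMET endpoint predictions, multi-tool ranked target
hit lists, and replicate assay readouts — can be generated here so every
stage is testable offline.  Planted actives satisfy every default
screening rule with a margin; every decoy violates at least one rule by
a margin (never at a boundary), so the planted set is identifiable by
construction.  One master integer seed drives independent substreams
keyed by generator name, so adding a generator never perturbs another.

The generator emulates the *shape* of a food-constituent export (class
tags including glycerolipids and inorganics, water-like entries, small
molecules below the MW cutoff) and of consensus target prediction
(per-tool sensitivity, false-hit rate, coverage, top-k rank structure).
It does not attempt to match any real database's class frequencies or
any real predictor's score distributions; descriptor values are sampled,
not computed from the template structures.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import admet_rules
from .admet_rules import AdmetProfile, Endpoint, default_ruleset
from .bioassay_stats import ReplicateGroup, ThTTimeSeries
from .descriptors import DescriptorVector
from .errors import ConfigurationError, DataError
from .library_io import DEFAULT_EXCLUDED_CLASSES, CompoundRecord
from .target_consensus import PredictionRecord, ToolManifest


def _rng(seed: int, name: str, extra: int = 0) -> np.random.Generator:
    """Independent substream for (seed, generator name [, index])."""
    stream = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream, int(extra)]))


# --------------------------------------------------------------------------
# library generator

#: Default class composition of the synthetic library (proportions sum to 1).
DEFAULT_CLASS_MIX: dict[str, float] = {
    "flavonoid": 0.25,
    "anthocyanin": 0.12,
    "other": 0.35,
    "triacylglycerol": 0.10,
    "diacylglycerol": 0.06,
    "phosphatidylethanolamine": 0.04,
    "inorganic": 0.08,
}

# template structures; descriptors are sampled, these keep the records parseable
# and give the inorganic/carbon filter something real to look at.
_ORGANIC_SMILES = (
    "O=C1c2c(O)cc(O)cc2OC(c2ccc(O)c(O)c2)=C1O",  # quercetin-like flavonol
    "COc1cc(-c2[o+]c3cc(O)cc(O)c3cc2OC2OC(CO)C(O)C(O)C2O)cc(OC)c1O",  # anthocyanin glycoside
    "Oc1cc(O)c2c(c1)OC(c1ccc(O)c(O)c1)C(O)C2",  # catechin-like flavanol
    "OCC1OC(Oc2ccccc2)C(O)C(O)C1O",  # phenolic glycoside
    "COc1ccc(C=CC(=O)O)cc1O",  # hydroxycinnamate
    "Oc1ccc(C=Cc2cc(O)cc(O)c2)cc1",  # stilbene
    "CC(C)=CCc1c(O)cc(O)c2c1OC(c1ccc(O)cc1)CC2=O",  # prenyl flavanone
    "O=C(O)c1cc(O)c(O)c(O)c1",  # gallate
)
_LIPID_SMILES = {
    "triacylglycerol": "CCCC(=O)OCC(COC(=O)CCC)OC(=O)CCC",
    "diacylglycerol": "CCCC(=O)OCC(O)COC(=O)CCC",
    "phosphatidylethanolamine": "CCCC(=O)OCC(COP(=O)(O)OCCN)OC(=O)CCC",
}
_INORGANIC_SMILES = ("O", "[Na+].[Cl-]", "[K+].[Cl-]", "O=S(=O)([O-])[O-].[Mg+2]")

#: Sampling windows for planted actives: inside every default rule window
#: with a margin, so no active sits on a boundary.
ACTIVE_WINDOWS: dict[str, tuple[float, float]] = {
    "mw": (150.0, 580.0),
    "n_ha": (1, 12),
    "n_hd": (0, 7),
    "n_rot": (0, 11),
    "n_ring": (1, 5),
    "f_char": (-1, 1),
    "logp": (0.2, 4.8),
}

# violation modes: (descriptor, sampler) — each lands outside the default
# rule window by a clear margin.
_VIOLATIONS: dict[str, tuple[str, tuple[float, float]]] = {
    "mw_low": ("mw", (20.0, 90.0)),
    "mw_high": ("mw", (620.0, 900.0)),
    "nha_high": ("n_ha", (13, 20)),
    "nhd_high": ("n_hd", (8, 12)),
    "nrot_high": ("n_rot", (12, 22)),
    "nring_zero": ("n_ring", (0, 0)),
    "fchar_high": ("f_char", (2, 3)),
    "logp_low": ("logp", (-3.0, -0.5)),
    "logp_high": ("logp", (5.5, 8.0)),
}
_TOX_MODE = "tox_positive"


@dataclass(frozen=True)
class LibraryConfig:
    """Configuration of the synthetic library generator."""

    n_compounds: int = 200
    n_planted: int = 10
    class_mix: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    descriptor_ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    n_invalid: int = 0
    min_mw: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted + self.n_invalid > self.n_compounds:
            raise ConfigurationError("n_planted + n_invalid exceeds n_compounds")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigurationError(f"class_mix proportions sum to {total}, not 1")


@dataclass
class SyntheticLibrary:
    """Generated library plus its ground truth."""

    compounds: list[CompoundRecord]
    descriptors: dict[str, DescriptorVector]
    admet: dict[str, AdmetProfile]
    active_ids: list[str]
    violated_rules: dict[str, list[str]]
    removed_by_class: list[str]
    removed_by_inorganic: list[str]
    removed_by_mw: list[str]
    survivor_ids: list[str]
    config: LibraryConfig


def _active_window(prop: str, ranges: Mapping[str, tuple[float, float]]) -> tuple[float, float]:
    low, high = ACTIVE_WINDOWS[prop]
    if prop in ranges:
        ulow, uhigh = ranges[prop]
        low, high = max(low, ulow), min(high, uhigh)
        if low > high:
            raise ConfigurationError(
                f"descriptor range for {prop!r} excludes the active rule window"
            )
    return low, high


def _sample_active_descriptors(
    rng: np.random.Generator, ranges: Mapping[str, tuple[float, float]]
) -> DescriptorVector:
    def unif(prop: str) -> float:
        low, high = _active_window(prop, ranges)
        return float(rng.uniform(low, high))

    def unif_int(prop: str) -> int:
        low, high = _active_window(prop, ranges)
        return int(rng.integers(int(low), int(high) + 1))

    return DescriptorVector(
        mw=round(unif("mw"), 2),
        n_ha=unif_int("n_ha"),
        n_hd=unif_int("n_hd"),
        n_rot=unif_int("n_rot"),
        n_ring=unif_int("n_ring"),
        f_char=unif_int("f_char"),
        logp=round(unif("logp"), 2),
    )


def _clean_endpoints(rng: np.random.Generator) -> dict[str, Endpoint]:
    return {
        name: Endpoint(round(float(rng.uniform(0.05, 0.40)), 3))
        for name in admet_rules.ENDPOINTS
    }


def _apply_violation(
    vec: DescriptorVector, mode: str, rng: np.random.Generator
) -> DescriptorVector:
    prop, (low, high) = _VIOLATIONS[mode]
    if prop in ("mw", "logp"):
        value: float | int = round(float(rng.uniform(low, high)), 2)
    else:
        value = int(rng.integers(int(low), int(high) + 1))
        if mode == "fchar_high" and rng.random() < 0.5:
            value = -value
    return DescriptorVector(**{**vec.as_dict(), prop: value})  # type: ignore[arg-type]


def generate_library(config: LibraryConfig) -> SyntheticLibrary:
    """Generate a library with ``n_planted`` rule-passing actives.

    Every decoy violates at least one default rule by a margin; entries of
    excluded glycerolipid classes, inorganics, and sub-cutoff molecules
    provide ground truth for the curation cascade.  Deterministic per seed.
    """
    rng = _rng(config.seed, "library")
    n = config.n_compounds
    ids = [f"C_{i + 1:04d}" for i in range(n)]

    planted_idx = set(map(int, rng.choice(n, size=config.n_planted, replace=False)))
    remaining = sorted(set(range(n)) - planted_idx)
    invalid_idx = set(remaining[: config.n_invalid])  # deterministic: first free slots

    classes = sorted(config.class_mix)
    probs = np.array([config.class_mix[c] for c in classes])
    probs = probs / probs.sum()

    compounds: list[CompoundRecord] = []
    descriptors: dict[str, DescriptorVector] = {}
    admet: dict[str, AdmetProfile] = {}
    active_ids: list[str] = []
    violated: dict[str, list[str]] = {}

    ruleset = default_ruleset()

    for i, cid in enumerate(ids):
        if i in planted_idx:
            cls = "anthocyanin" if rng.random() < 0.5 else "flavonoid"
            smiles = _ORGANIC_SMILES[int(rng.integers(len(_ORGANIC_SMILES)))]
            compounds.append(
                CompoundRecord(cid, f"active-{cid}", smiles, cls, source="synthetic")
            )
            descriptors[cid] = _sample_active_descriptors(rng, config.descriptor_ranges)
            admet[cid] = AdmetProfile(cid, _clean_endpoints(rng))
            active_ids.append(cid)
            continue

        if i in invalid_idx:
            endpoints = _clean_endpoints(rng)
            bad = str(rng.choice(admet_rules.ENDPOINTS))
            endpoints[bad] = Endpoint(round(float(rng.uniform(0.60, 0.95)), 3))
            compounds.append(
                CompoundRecord(
                    cid, f"invalid-{cid}", "not_a_molecule", "other",
                    source="synthetic", parse_ok=False,
                )
            )
            admet[cid] = AdmetProfile(cid, endpoints)
            continue

        cls = str(rng.choice(classes, p=probs))
        endpoints = _clean_endpoints(rng)
        if cls in _LIPID_SMILES:
            smiles = _LIPID_SMILES[cls]
            vec = _sample_active_descriptors(rng, {})
            vec = _apply_violation(vec, "mw_high", rng)
            vec = _apply_violation(vec, "nrot_high", rng)
            modes = ["mw_high", "nrot_high"]
        elif cls == "inorganic":
            smiles = _INORGANIC_SMILES[int(rng.integers(len(_INORGANIC_SMILES)))]
            vec = _sample_active_descriptors(rng, {})
            vec = _apply_violation(vec, "mw_low", rng)
            vec = _apply_violation(vec, "nring_zero", rng)
            modes = ["mw_low", "nring_zero"]
        else:
            smiles = _ORGANIC_SMILES[int(rng.integers(len(_ORGANIC_SMILES)))]
            vec = _sample_active_descriptors(rng, {})
            n_modes = 1 + int(rng.binomial(2, 0.3))
            pool = [*(_VIOLATIONS.keys()), _TOX_MODE]
            modes = list(rng.choice(pool, size=n_modes, replace=False))
            for mode in modes:
                if mode == _TOX_MODE:
                    bad = str(rng.choice(admet_rules.ENDPOINTS))
                    endpoints[bad] = Endpoint(round(float(rng.uniform(0.60, 0.95)), 3))
                else:
                    vec = _apply_violation(vec, mode, rng)
        compounds.append(CompoundRecord(cid, f"decoy-{cid}", smiles, cls, source="synthetic"))
        descriptors[cid] = vec
        admet[cid] = AdmetProfile(cid, endpoints)

    # ground-truth cascade (mirrors the curation stage definitions)
    removed_by_class = [
        r.compound_id for r in compounds if r.compound_class in DEFAULT_EXCLUDED_CLASSES
    ]
    after_class = [r for r in compounds if r.compound_id not in set(removed_by_class)]
    removed_by_inorganic = [
        r.compound_id for r in after_class if r.compound_class == "inorganic"
    ]
    after_inorg = [r for r in after_class if r.compound_id not in set(removed_by_inorganic)]
    removed_by_mw = [
        r.compound_id
        for r in after_inorg
        if r.parse_ok and descriptors[r.compound_id].mw < config.min_mw
    ]
    survivors = [
        r.compound_id for r in after_inorg if r.compound_id not in set(removed_by_mw)
    ]

    # verify identifiability by running the actual scoring engine
    full = sum(rule.weight for rule in ruleset)
    for rec in compounds:
        card = admet_rules.evaluate_rules(
            descriptors.get(rec.compound_id), admet[rec.compound_id], ruleset,
            compound_id=rec.compound_id,
        )
        fails = [rid for rid, out in card.outcomes.items() if out == admet_rules.FAIL]
        if rec.compound_id in set(active_ids):
            if fails or card.raw_score != full:
                raise DataError(
                    f"generator bug: planted active {rec.compound_id} fails {fails}"
                )
        else:
            if not fails and card.max_possible == full:
                raise DataError(
                    f"generator bug: decoy {rec.compound_id} violates no rule"
                )
            violated[rec.compound_id] = fails

    return SyntheticLibrary(
        compounds=compounds,
        descriptors=descriptors,
        admet=admet,
        active_ids=active_ids,
        violated_rules=violated,
        removed_by_class=removed_by_class,
        removed_by_inorganic=removed_by_inorganic,
        removed_by_mw=removed_by_mw,
        survivor_ids=survivors,
        config=config,
    )


# --------------------------------------------------------------------------
# predictor simulator

@dataclass(frozen=True)
class PredictorSimConfig:
    """Per-tool behaviour of the simulated target predictors.

    ``sensitivity``: probability a covered true pair appears in a tool's
    top-k; ``false_hit_rate``: probability a covered decoy pair does;
    ``beyond_topk_rate``: probability a covered true pair missing from the
    top-k still appears further down the list; ``coverage``: probability a
    tool covers a given target at all.
    """

    n_tools: int = 6
    sensitivity: float = 0.8
    false_hit_rate: float = 0.05
    coverage: float = 1.0
    topk: int = 20
    beyond_topk_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sensitivity", "false_hit_rate", "coverage", "beyond_topk_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {value}")
        if self.n_tools < 1 or self.topk < 1:
            raise ConfigurationError("n_tools and topk must be >= 1")


def generate_predictions(
    config: PredictorSimConfig,
    true_pairs: Sequence[tuple[str, str]],
    decoy_targets: Sequence[str] = (),
) -> tuple[dict[str, list[PredictionRecord]], list[ToolManifest]]:
    """Simulate ranked hit lists for ``n_tools`` predictors.

    Returns per-tool record lists (ranks collision-free per compound;
    true-pair inclusions land within the top-k) and manifests reflecting
    the sampled coverage.  Deterministic per seed.
    """
    if not true_pairs and not decoy_targets:
        raise DataError("need at least one true pair or decoy target")
    targets = sorted({t for _, t in true_pairs} | set(decoy_targets))
    compounds = sorted({c for c, _ in true_pairs})
    true_by_compound = {
        c: sorted({t for cc, t in true_pairs if cc == c}) for c in compounds
    }

    records: dict[str, list[PredictionRecord]] = {}
    manifests: list[ToolManifest] = []
    for i in range(config.n_tools):
        tool = f"tool_{i + 1}"
        rng = _rng(config.seed, "predictions", i)
        covered = frozenset(t for t in targets if rng.random() < config.coverage)
        manifests.append(ToolManifest(tool, covered))
        tool_records: list[PredictionRecord] = []
        for c in compounds:
            trues = [t for t in true_by_compound[c] if t in covered]
            decoys = [
                t for t in targets
                if t in covered and t not in set(true_by_compound[c])
            ]
            in_topk = [t for t in trues if rng.random() < config.sensitivity]
            in_topk += [t for t in decoys if rng.random() < config.false_hit_rate]
            if len(in_topk) > config.topk:
                raise DataError(
                    f"tool {tool}: {len(in_topk)} hits for {c} exceed topk={config.topk}"
                )
            beyond = [
                t for t in trues
                if t not in set(in_topk) and rng.random() < config.beyond_topk_rate
            ]
            order = list(rng.permutation(len(in_topk)))
            for rank_pos, idx in enumerate(order, start=1):
                tool_records.append(PredictionRecord(tool, c, in_topk[idx], rank_pos))
            order_b = list(rng.permutation(len(beyond)))
            for j, idx in enumerate(order_b):
                tool_records.append(
                    PredictionRecord(tool, c, beyond[idx], config.topk + 1 + j)
                )
        records[tool] = tool_records
    return records, manifests


# --------------------------------------------------------------------------
# assay simulator

@dataclass(frozen=True)
class AssaySimConfig:
    """Replicate-group and aggregation time-course generator settings.

    Group readouts are true mean + Gaussian noise with ``noise_sd``,
    ``n_replicates`` per group (3 by default, matching the triplicate
    design the statistics assume).  The aggregation curve is a logistic
    in time: baseline + amplitude / (1 + exp(-rate * (t - midpoint))).
    """

    group_means: Mapping[str, float] = field(
        default_factory=lambda: {"control": 100.0, "stress": 55.0, "treated": 90.9}
    )
    noise_sd: float = 3.0
    n_replicates: int = 3
    tht_baseline: float = 10.0
    tht_amplitude: float = 90.0
    tht_midpoint: float = 12.0
    tht_rate: float = 0.366
    tht_times: tuple[float, ...] = (0.0, 2.0, 4.0, 6.0, 12.0, 24.0, 48.0, 72.0, 96.0)
    tht_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.tht_noise_sd < 0:
            raise ConfigurationError("noise sd must be non-negative")
        if self.n_replicates < 2:
            raise ConfigurationError("need at least 2 replicates per group")


@dataclass
class AssayData:
    groups: dict[str, ReplicateGroup]
    tht: ThTTimeSeries
    config: AssaySimConfig


def logistic_intensity(
    t: float, baseline: float, amplitude: float, midpoint: float, rate: float
) -> float:
    return baseline + amplitude / (1.0 + np.exp(-rate * (t - midpoint)))


def generate_assay_data(config: AssaySimConfig) -> AssayData:
    """Replicate groups and a logistic aggregation curve; deterministic per seed."""
    rng = _rng(config.seed, "assay")
    groups = {
        label: ReplicateGroup(
            label,
            tuple(
                float(mean + rng.normal(0.0, config.noise_sd))
                if config.noise_sd > 0
                else float(mean)
                for _ in range(config.n_replicates)
            ),
        )
        for label, mean in config.group_means.items()
    }
    intensities = []
    for t in config.tht_times:
        value = logistic_intensity(
            t, config.tht_baseline, config.tht_amplitude, config.tht_midpoint, config.tht_rate
        )
        if config.tht_noise_sd > 0:
            value += float(rng.normal(0.0, config.tht_noise_sd))
        intensities.append(float(value))
    series = ThTTimeSeries(tuple(config.tht_times), tuple(intensities))
    return AssayData(groups=groups, tht=series, config=config)
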
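"""Assay arithmetic and small-sample statistics for the wet-lab readouts.

Fluorescence probes report relative signals: the hydroxyl-radical and
intracellular-ROS readouts use Ratio (%) = 100 * F / F0 against the
untreated (or stressor-only) reference, and the JC-1 mitochondrial
membrane potential readout is the monomer/aggregate intensity ratio
FI530 / FI590.  Group comparisons follow the n = 3 replicate design:
mean +/- SD, percent-of-control normalization, and a two-sided
single-sample t-test of each treated group against the control mean
(Welch's two-sample test is available as an alternative).  A thioflavin-T
time course is summarized by its lag time: the first threshold crossing
of the baseline-corrected intensity (default 10% of the dynamic range),
linearly interpolated between samples.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DataError


@dataclass(frozen=True)
class FluorescenceMeasurement:
    """Signal F against reference F0 (arbitrary units)."""

    F: float
    F0: float


@dataclass(frozen=True)
class Jc1Measurement:
    """JC-1 monomer (530 nm) and aggregate (590 nm) intensities."""

    fi530: float
    fi590: float


@dataclass(frozen=True)
class ReplicateGroup:
    """A labelled set of replicate measurements (n >= 2 for variance use)."""

    label: str
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise DataError(f"replicate group {self.label!r} is empty")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        if self.n < 2:
            raise DataError(f"group {self.label!r}: SD needs n >= 2")
        return float(np.std(self.values, ddof=1))


@dataclass(frozen=True)
class ThTTimeSeries:
    """Thioflavin-T aggregation time course (times in hours)."""

    times: tuple[float, ...]
    intensities: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.times) != len(self.intensities):
            raise DataError("times and intensities differ in length")
        if len(self.times) < 4:
            raise DataError("lag estimation needs at least 4 time points")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise DataError("times must be strictly increasing")


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    note: str = ""


def fluorescence_ratio(m: FluorescenceMeasurement) -> float:
    """Ratio (%) = 100 * F / F0."""
    if m.F0 <= 0:
        raise DataError(f"reference intensity F0 must be positive, got {m.F0}")
    return 100.0 * m.F / m.F0


def mmp_ratio(m: Jc1Measurement) -> float:
    """Mitochondrial membrane potential readout: FI530 / FI590."""
    if m.fi590 <= 0:
        raise DataError(f"aggregate intensity FI590 must be positive, got {m.fi590}")
    return m.fi530 / m.fi590


def percent_of_control(group: ReplicateGroup, control: ReplicateGroup) -> list[float]:
    """Scale values so the control group's mean maps to 100%."""
    cmean = control.mean
    if cmean <= 0:
        raise DataError(f"control group {control.label!r} mean must be positive")
    return [100.0 * v / cmean for v in group.values]


def one_sample_ttest(group: ReplicateGroup, reference_mean: float) -> TTestResult:
    """Two-sided single-sample t-test of a replicate group against a reference.

    t = (mean - ref) / (sd / sqrt(n)), df = n - 1.  Degenerate zero-variance
    groups: all values equal to the reference give (t=0, p=1); all equal but
    different from the reference are reported with p = 0 and a warning.
    """
    if group.n < 2:
        raise DataError(f"group {group.label!r}: t-test needs n >= 2")
    mean = group.mean
    sd = group.sd
    df = group.n - 1
    if sd == 0.0:
        if mean == reference_mean:
            return TTestResult(0.0, df, 1.0, note="zero variance; mean equals reference")
        warnings.warn(
            f"group {group.label!r}: zero variance but mean != reference; "
            "p reported as 0",
            stacklevel=2,
        )
        t = math.inf if mean > reference_mean else -math.inf
        return TTestResult(t, df, 0.0, note="zero variance; degenerate")
    t = (mean - reference_mean) / (sd / math.sqrt(group.n))
    p = 2.0 * float(sps.t.sf(abs(t), df))
    return TTestResult(t, df, p)


def welch_ttest(group_a: ReplicateGroup, group_b: ReplicateGroup) -> TTestResult:
    """Welch two-sample t-test (alternative to the single-sample design)."""
    if group_a.n < 2 or group_b.n < 2:
        raise DataError("Welch test needs n >= 2 in both groups")
    res = sps.ttest_ind(group_a.values, group_b.values, equal_var=False)
    return TTestResult(float(res.statistic), int(round(res.df)), float(res.pvalue))


def tht_lag_time(series: ThTTimeSeries, threshold_fraction: float = 0.1) -> float | None:
    """Lag time of an aggregation time course.

    Baseline = first intensity, plateau = maximum intensity; the lag is
    the first time the baseline-corrected signal crosses
    ``threshold_fraction * (plateau - baseline)``, interpolated linearly
    within the crossing interval.  A flat series (plateau == baseline)
    has no transition and returns None.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise DataError("threshold_fraction must be in (0, 1)")
    y = np.asarray(series.intensities, dtype=float)
    t = np.asarray(series.times, dtype=float)
    baseline = y[0]
    plateau = y.max()
    if plateau <= baseline:
        return None
    threshold = baseline + threshold_fraction * (plateau - baseline)
    if y[0] >= threshold:  # cannot happen for threshold_fraction > 0, kept for safety
        return float(t[0])
    above = np.nonzero(y >= threshold)[0]
    i = int(above[0])
    t0, t1 = t[i - 1], t[i]
    y0, y1 = y[i - 1], y[i]
    return float(t0 + (threshold - y0) / (y1 - y0) * (t1 - t0))


def significance_stars(p: float) -> str:
    """Two-level marking mirroring */** at 0.05/0.01."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def read_long_csv(path: str | Path) -> dict[str, ReplicateGroup]:
    """Read long-format assay data (columns: group, replicate, value)."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"assay file not found: {path}")
    rows: dict[str, list[tuple[str, float]]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for col in ("group", "replicate", "value"):
            if col not in (reader.fieldnames or []):
                raise DataError(f"assay CSV {path} missing column {col!r}")
        for row in reader:
            rows.setdefault(row["group"], []).append((row["replicate"], float(row["value"])))
    if not rows:
        raise DataError(f"assay CSV {path} contains no rows")
    return {
        label: ReplicateGroup(label, tuple(v for _, v in sorted(pairs)))
        for label, pairs in rows.items()
    }


def summarize_groups(
    groups: dict[str, ReplicateGroup],
    control_label: str,
    bonferroni: bool = False,
) -> list[dict]:
    """Per-group summary vs the control: mean, SD, n, percent-of-control,
    single-sample t-test against the control mean, significance stars.

    ``bonferroni=True`` multiplies p-values by the number of treated
    groups (capped at 1); off by default.
    """
    if control_label not in groups:
        raise DataError(f"control group {control_label!r} not present")
    control = groups[control_label]
    treated = [g for g in groups if g != control_label]
    m = max(len(treated), 1)
    out = []
    for label in sorted(groups):
        g = groups[label]
        row: dict = {
            "group": label,
            "n": g.n,
            "mean": g.mean,
            "sd": g.sd if g.n >= 2 else float("nan"),
            "percent_of_control": float(np.mean(percent_of_control(g, control))),
        }
        if label == control_label:
            row.update({"t": float("nan"), "df": None, "p": float("nan"), "stars": ""})
        else:
            res = one_sample_ttest(g, control.mean)
            p = min(res.p * m, 1.0) if bonferroni else res.p
            row.update({"t": res.t, "df": res.df, "p": p, "stars": significance_stars(p)})
        out.append(row)
    return out


def write_summary_csv(summary: Sequence[dict], path: str | Path) -> None:
    cols = ["group", "n", "mean", "sd", "percent_of_control", "t", "df", "p", "stars"]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=cols)
        writer.writeheader()
        for row in summary:
            writer.writerow({c: row.get(c, "") for c in cols})
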
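"""Bland-Altman agreement analysis and study-level summary tables.

Agreement between a reference system (marker-based, "QTM"-like) and a test
system (markerless, "LMC"-like) is quantified per joint and movement with a
standard Bland-Altman analysis of paired per-trial measurements: for pairs
(x_i, y_i) the differences d_i = x_i - y_i (reference minus test, the global
sign convention) and means m_i = (x_i + y_i)/2 give

    bias   = mean(d),
    LoA    = bias +/- 1.96 * sd(d)          (sample sd, n-1),
    CI95   = bias +/- t_{0.975, n-1} sd(d)/sqrt(n),

and a proportional-bias trend is assessed by the Pearson correlation r of
(m_i, d_i) with its two-sided p-value (t transform, n-2 df).  No
repeated-measures correction or multiple-testing adjustment is applied:
each trial contributes one point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InsufficientDataError, ValidationError

#: large-sample limits-of-agreement multiplier
LOA_MULTIPLIER = 1.96


@dataclass
class PairedMeasurements:
    """Positionally paired per-trial values from the two systems."""

    reference_values: np.ndarray   # e.g. QTM, degrees
    test_values: np.ndarray        # e.g. LMC, degrees
    labels: Optional[pd.DataFrame] = None  # subject/trial/joint/task per pair

    def __post_init__(self):
        self.reference_values = np.asarray(self.reference_values, dtype=float)
        self.test_values = np.asarray(self.test_values, dtype=float)
        if self.reference_values.shape != self.test_values.shape:
            raise ValidationError("paired arrays must have equal length")
        if self.reference_values.ndim != 1 or self.reference_values.size < 2:
            raise InsufficientDataError("need >= 2 pairs")
        if self.labels is not None and len(self.labels) != self.reference_values.size:
            raise ValidationError("labels must have one row per pair")

    @property
    def n(self) -> int:
        return int(self.reference_values.size)


@dataclass
class AgreementResult:
    """Bland-Altman estimates for one joint/movement comparison.

    ``r`` is NaN with ``r_defined=False`` when the differences (or means)
    are constant or n < 3; it is never silently reported as 0.
    """

    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci95_bias: Tuple[float, float]
    r: float
    p: float
    r_defined: bool
    sign: str = "reference_minus_test"
    label: Optional[str] = None
    means: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)
    diffs: np.ndarray = field(default_factory=lambda: np.array([]), repr=False)

    def trend(self, alpha: float = 0.05) -> str:
        return trend_interpretation(self, alpha)

    def to_dict(self) -> Dict:
        return {
            "label": self.label, "n": self.n, "bias": self.bias,
            "sd_diff": self.sd_diff, "loa_low": self.loa_low,
            "loa_high": self.loa_high, "ci95_low": self.ci95_bias[0],
            "ci95_high": self.ci95_bias[1], "r": self.r, "p": self.p,
            "r_defined": self.r_defined, "sign": self.sign,
        }

    def summary(self) -> str:
        lines = [
            f"Bland-Altman agreement ({self.sign})"
            + (f" -- {self.label}" if self.label else ""),
            f"  n pairs        : {self.n}",
            f"  bias           : {self.bias:8.3f} deg",
            f"  sd of diffs    : {self.sd_diff:8.3f} deg",
            f"  limits of agr. : [{self.loa_low:.3f}, {self.loa_high:.3f}] deg",
            f"  95% CI of bias : [{self.ci95_bias[0]:.3f}, {self.ci95_bias[1]:.3f}] deg",
        ]
        if self.r_defined:
            lines.append(f"  trend          : r = {self.r:.4f}, P = {self.p:.4f}"
                         f" ({self.trend()})")
        else:
            lines.append("  trend          : r undefined (constant differences or n < 3)")
        return "\n".join(lines)

    def plot_data(self) -> pd.DataFrame:
        """Per-pair means and differences plus the bias/LoA reference lines,
        exported so any plotting front-end can redraw the BA plot."""
        df = pd.DataFrame({"mean": self.means, "difference": self.diffs})
        df["bias"] = self.bias
        df["loa_low"] = self.loa_low
        df["loa_high"] = self.loa_high
        return df


class BlandAltman:
    """Model object for a Bland-Altman comparison of two measurement systems.

    Parameters
    ----------
    pairs
        A :class:`PairedMeasurements`, or build from arrays/DataFrames via
        the constructors.
    sign
        ``"reference_minus_test"`` (default) or ``"test_minus_reference"``.
    """

    def __init__(self, pairs: PairedMeasurements, sign: str = "reference_minus_test",
                 label: Optional[str] = None):
        if sign not in ("reference_minus_test", "test_minus_reference"):
            raise ValidationError(f"unknown sign convention {sign!r}")
        self.pairs = pairs
        self.sign = sign
        self.label = label

    @classmethod
    def from_arrays(cls, reference, test, **kw) -> "BlandAltman":
        return cls(PairedMeasurements(np.asarray(reference), np.asarray(test)), **kw)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, reference_col: str = "reference",
                       test_col: str = "test", **kw) -> "BlandAltman":
        labels = df.drop(columns=[reference_col, test_col])
        pairs = PairedMeasurements(df[reference_col].to_numpy(),
                                   df[test_col].to_numpy(),
                                   labels=labels if len(labels.columns) else None)
        return cls(pairs, **kw)

    def fit(self, loa_multiplier: float = LOA_MULTIPLIER) -> AgreementResult:
        x = self.pairs.reference_values
        y = self.pairs.test_values
        d = x - y if self.sign == "reference_minus_test" else y - x
        m = 0.5 * (x + y)
        n = self.pairs.n
        bias = float(np.mean(d))
        sd = float(np.std(d, ddof=1))
        half = float(stats.t.ppf(0.975, n - 1)) * sd / math.sqrt(n)
        r = float("nan")
        p = float("nan")
        r_defined = False
        if n >= 3 and np.ptp(d) > 0 and np.ptp(m) > 0:
            r, p = stats.pearsonr(m, d)
            r, p = float(r), float(p)
            r_defined = math.isfinite(r)
        return AgreementResult(
            n=n, bias=bias, sd_diff=sd,
            loa_low=bias - loa_multiplier * sd, loa_high=bias + loa_multiplier * sd,
            ci95_bias=(bias - half, bias + half), r=r, p=p, r_defined=r_defined,
            sign=self.sign, label=self.label, means=m, diffs=d,
        )


def bland_altman(pairs: PairedMeasurements, sign: str = "reference_minus_test",
                 label: Optional[str] = None) -> AgreementResult:
    """Functional shorthand for ``BlandAltman(pairs, sign).fit()``."""
    return BlandAltman(pairs, sign=sign, label=label).fit()


def trend_interpretation(result: AgreementResult, alpha: float = 0.05) -> str:
    """``"proportional_bias"`` iff the trend p-value is strictly below alpha."""
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")
    if not result.r_defined:
        return "no_trend"
    return "proportional_bias" if result.p < alpha else "no_trend"


def summarize_segment_lengths(per_subject: pd.DataFrame) -> pd.DataFrame:
    """Across-subject mean +/- sd of per-subject mean segment lengths.

    Expects columns ``subject, system, finger, segment, mean_mm``; systems
    are reported side by side.  A single subject yields sd = 0.
    """
    required = {"subject", "system", "finger", "segment", "mean_mm"}
    missing = required - set(per_subject.columns)
    if missing:
        raise ValidationError(f"missing columns: {sorted(missing)}")
    rows = []
    for (finger, segment), group in per_subject.groupby(["finger", "segment"], sort=False):
        row = {"finger": finger, "segment": segment}
        for system, sub in group.groupby("system", sort=False):
            values = sub["mean_mm"].to_numpy(dtype=float)
            row[f"{system}_mean_mm"] = float(np.mean(values))
            row[f"{system}_sd_mm"] = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
            row[f"{system}_n"] = int(values.size)
        rows.append(row)
    return pd.DataFrame(rows)


def rom_table(rom_records: pd.DataFrame, pooling: str = "mean") -> pd.DataFrame:
    """Study-level ROM comparison table, one row per (task, joint).

    Expects long columns ``task, joint, system, rom`` with systems labelled
    ``reference``/``test``; per-trial ROMs are pooled by ``pooling``
    ("mean" or "median") and the difference column is reference - test.
    Joints present in only one system are omitted with a warning.
    """
    if pooling not in ("mean", "median"):
        raise ValidationError("pooling must be 'mean' or 'median'")
    agg = getattr(np, pooling)
    rows = []
    for (task, joint), group in rom_records.groupby(["task", "joint"], sort=False):
        systems = {s: agg(sub["rom"].to_numpy(dtype=float))
                   for s, sub in group.groupby("system", sort=False)}
        if "reference" not in systems or "test" not in systems:
            import logging
            logging.getLogger(__name__).warning(
                "rom_table: %s/%s present in one system only; row omitted", task, joint)
            continue
        rows.append({
            "task": task, "joint": joint,
            "test_rom": float(systems["test"]),
            "reference_rom": float(systems["reference"]),
            "difference": float(systems["reference"]) - float(systems["test"]),
        })
    return pd.DataFrame(rows)
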
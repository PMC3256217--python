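"""Absolute qPCR quantification with lambda-spike inhibition correction.

Copy numbers are read off dilution-series standard curves
(``Ct = intercept + slope * log10(copies)``, least squares).  Soil
extracts inhibit PCR, so every reaction carries a bacteriophage-lambda
spike of known quantity (1e5 copies/ul); the spike's measured recovery
quantifies inhibition and, when recovery falls below 100%, all other
quantifications in that sample are scaled up proportionally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import LAMBDA_SPIKE_COPIES

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "quantify",
    "spike_recovery",
    "correct_for_inhibition",
    "relative_expression",
    "analyze_qpcr",
]


@dataclass(frozen=True)
class StandardCurve:
    """Fitted dilution-series curve: Ct = intercept + slope * log10(copies)."""

    slope: float
    intercept: float
    r_squared: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency implied by the slope (1.0 = doubling)."""
        return 10.0 ** (-1.0 / self.slope) - 1.0


def fit_standard_curve(dilutions: list[tuple[float, float]]) -> StandardCurve:
    """Least-squares fit of Ct on log10(copies) over >= 3 dilution points.

    The points must span at least two orders of magnitude in copy number.
    """
    if len(dilutions) < 3:
        raise ValueError("need at least 3 dilution points")
    copies = np.array([c for c, _ in dilutions], dtype=float)
    cts = np.array([ct for _, ct in dilutions], dtype=float)
    if (copies <= 0).any():
        raise ValueError("copy numbers must be positive")
    x = np.log10(copies)
    if x.max() - x.min() < 2.0:
        raise ValueError("dilution series must span >= 2 orders of magnitude")
    slope, intercept = np.polyfit(x, cts, 1)
    pred = intercept + slope * x
    ss_res = float(((cts - pred) ** 2).sum())
    ss_tot = float(((cts - cts.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return StandardCurve(slope=float(slope), intercept=float(intercept), r_squared=r2)


def quantify(ct: float, curve: StandardCurve) -> float:
    """Copies implied by a Ct value: ``10 ** ((ct - intercept) / slope)``."""
    if curve.slope == 0:
        raise ValueError("standard curve has zero slope")
    return 10.0 ** ((ct - curve.intercept) / curve.slope)


def spike_recovery(
    measured_spike_copies: float, expected: float = LAMBDA_SPIKE_COPIES
) -> tuple[float, float]:
    """Lambda-spike recovery fraction and inhibition percent.

    Recovery is capped at 1 for inhibition reporting:
    ``inhibition% = max(0, 1 - measured/expected) * 100``.
    """
    if measured_spike_copies <= 0:
        raise ValueError("measured spike copies must be positive")
    recovery = measured_spike_copies / expected
    inhibition_pct = max(0.0, 1.0 - recovery) * 100.0
    return recovery, inhibition_pct


def correct_for_inhibition(raw_copies: float, recovery: float) -> float:
    """Scale a quantification by spike recovery when recovery < 100%.

    Over-recovery (> 1) leaves the value unchanged: correction is only
    applied when the spike came back low.
    """
    if recovery <= 0:
        raise ValueError("recovery must be positive")
    if recovery < 1.0:
        return raw_copies / recovery
    return raw_copies


def relative_expression(component_copies: float, total_copies: float) -> float:
    """Percent of a total accounted for by one component (2 decimals)."""
    if total_copies <= 0:
        raise ValueError("total copies must be positive")
    if component_copies < 0:
        raise ValueError("component copies must be non-negative")
    return round(100.0 * component_copies / total_copies, 2)


def analyze_qpcr(
    table: pd.DataFrame, expected_spike: float = LAMBDA_SPIKE_COPIES
) -> pd.DataFrame:
    """Full analysis of a Ct table: fit curves, quantify, spike-correct.

    ``table`` columns: sample, target, role (standard|unknown|spike), ct,
    known_copies (standards only).  One standard curve is fitted per
    target; each sample's lambda-spike recovery corrects all of its other
    targets.  Returns one row per (sample, target) with raw, recovery,
    inhibition_pct and corrected copies.
    """
    required = {"sample", "target", "role", "ct"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    curves: dict[str, StandardCurve] = {}
    for target, grp in table[table["role"] == "standard"].groupby("target"):
        pts = list(zip(grp["known_copies"], grp["ct"]))
        curves[target] = fit_standard_curve(pts)

    recoveries: dict[str, float] = {}
    for sample, grp in table[table["role"] == "spike"].groupby("sample"):
        target = grp["target"].iloc[0]
        if target not in curves:
            raise ValueError(f"no standard curve for spike target {target!r}")
        measured = quantify(float(grp["ct"].mean()), curves[target])
        recoveries[sample], _ = spike_recovery(measured, expected_spike)

    rows = []
    unknowns = table[table["role"] == "unknown"]
    for (sample, target), grp in unknowns.groupby(["sample", "target"]):
        if target not in curves:
            raise ValueError(f"no standard curve for target {target!r}")
        raw = quantify(float(grp["ct"].mean()), curves[target])
        recovery = recoveries.get(sample, 1.0)
        if math.isnan(recovery):
            recovery = 1.0
        rows.append(
            {
                "sample": sample,
                "target": target,
                "raw_copies": raw,
                "spike_recovery": recovery,
                "inhibition_pct": max(0.0, 1.0 - recovery) * 100.0,
                "corrected_copies": correct_for_inhibition(raw, recovery),
            }
        )
    return pd.DataFrame(rows).sort_values(["sample", "target"]).reset_index(drop=True)
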
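"""Quadratic length/width-ratio calibration curve and seed triage.

The controlled charring experiments show the mean length/width ratio of
grape pips falling with charring temperature.  On the scaled temperature
axis x = (T − 200) / 150 (so x = 0 at 200 °C and x = 1 at 350 °C), an
ordinary least-squares fit of

    r = a·x² + b

to the per-condition mean ratios of the two reference cultivars yields
a ≈ −0.28 and b ≈ 1.44.  Inverting the curve maps a seed of unknown
charring history from its measured ratio to an estimated charring
temperature; seeds whose estimate exceeds a threshold (default 275 °C,
where classification accuracy collapses) are rejected as unsuitable for
variety classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic_seeds import load_reference_means

__all__ = [
    "CharringCurve",
    "SortingDecision",
    "fit_curve",
    "reference_curve",
    "estimate_temperature",
    "sort_seeds",
]

T_ZERO = 200.0
T_ONE = 350.0

REASON_IN_RANGE = "in-range"
REASON_ABOVE_THRESHOLD = "above-threshold"
REASON_CLAMPED = "ratio-above-intercept-clamped"


@dataclass(frozen=True)
class CharringCurve:
    """Fitted coefficients of r = a·x² + b with x = (T − t_zero)/(t_one − t_zero)."""

    a: float
    b: float
    t_zero: float = T_ZERO
    t_one: float = T_ONE
    fit_residual: float = 0.0

    def x_of_temperature(self, temperature_C: float) -> float:
        return (temperature_C - self.t_zero) / (self.t_one - self.t_zero)

    def ratio_at(self, temperature_C: float) -> float:
        """Forward model: the mean L/W ratio expected at a temperature."""
        x = self.x_of_temperature(temperature_C)
        return self.a * x**2 + self.b


@dataclass(frozen=True)
class SortingDecision:
    """Charring-temperature estimate and accept/reject verdict for one seed."""

    seed_id: object
    lw_ratio: float
    x_hat: float
    temperature_hat: float
    accepted: bool
    reason: str
    group: object | None = None


def fit_curve(
    observations: Iterable[tuple[float, float, float]] | pd.DataFrame,
) -> CharringCurve:
    """Least-squares fit of the quadratic ratio-vs-temperature model.

    ``observations`` are (temperature_C, duration_h, mean_lw_ratio) rows —
    typically the per-condition mean ratios at 2 h and 8 h; duration enters
    only through which mean-ratio observations are supplied.  Fresh rows
    (NaN temperature) are excluded.
    """
    if isinstance(observations, pd.DataFrame):
        rows = observations[["temperature_C", "duration_h", "lw_mean"]].itertuples(
            index=False
        )
        obs = [(t, d, r) for t, d, r in rows]
    else:
        obs = list(observations)
    obs = [(t, d, r) for t, d, r in obs if t is not None and np.isfinite(t)]
    if len(obs) < 3:
        raise ValueError("need at least 3 charred observations")
    T = np.array([o[0] for o in obs], dtype=float)
    r = np.array([o[2] for o in obs], dtype=float)
    if np.unique(T).size < 2:
        raise np.linalg.LinAlgError("all observations at one temperature")
    x = (T - T_ZERO) / (T_ONE - T_ZERO)
    A = np.column_stack([x**2, np.ones_like(x)])
    coef, residual, *_ = np.linalg.lstsq(A, r, rcond=None)
    ss = float(residual[0]) if residual.size else float(np.sum((A @ coef - r) ** 2))
    return CharringCurve(a=float(coef[0]), b=float(coef[1]), fit_residual=ss)


def reference_curve() -> CharringCurve:
    """The curve fitted to the 16 packaged per-condition mean ratios."""
    table = load_reference_means()
    return fit_curve(table[table["temperature_C"].notna()])


def estimate_temperature(lw_ratio: float, curve: CharringCurve) -> tuple[float, float]:
    """Invert the curve: measured ratio → (x̂, estimated temperature in °C).

    For r ≤ b the inverse is x̂ = sqrt((b − r)/(−a)); estimates beyond t_one
    are extrapolations of the same branch.  Ratios above the intercept b
    indicate milder-than-calibration charring and clamp to x̂ = 0 (t_zero).
    """
    if not np.isfinite(lw_ratio):
        raise ValueError("lw_ratio must be finite")
    if curve.a >= 0:
        raise ValueError("curve must be decreasing (a < 0)")
    if lw_ratio > curve.b:
        return 0.0, curve.t_zero
    x_hat = float(np.sqrt((curve.b - lw_ratio) / (-curve.a)))
    return x_hat, curve.t_zero + x_hat * (curve.t_one - curve.t_zero)


def sort_seeds(
    morph_table: pd.DataFrame,
    curve: CharringCurve,
    threshold_C: float = 275.0,
) -> tuple[list[SortingDecision], pd.DataFrame]:
    """Triage seeds by estimated charring temperature.

    ``morph_table`` needs an ``lw_ratio`` column (plus optional ``id`` and
    ``group`` provenance columns).  A seed is accepted when its estimated
    temperature is at or below ``threshold_C`` (the boundary counts as
    accepted); ratios above the intercept clamp to t_zero and are accepted.
    Returns the per-seed decisions and an acceptance summary per group.
    """
    decisions: list[SortingDecision] = []
    for _, row in morph_table.iterrows():
        ratio = float(row["lw_ratio"])
        x_hat, t_hat = estimate_temperature(ratio, curve)
        accepted = t_hat <= threshold_C
        if ratio > curve.b:
            reason = REASON_CLAMPED
        elif accepted:
            reason = REASON_IN_RANGE
        else:
            reason = REASON_ABOVE_THRESHOLD
        decisions.append(
            SortingDecision(
                seed_id=row.get("id", None),
                lw_ratio=ratio,
                x_hat=x_hat,
                temperature_hat=t_hat,
                accepted=accepted,
                reason=reason,
                group=row.get("group", None),
            )
        )
    if not decisions:
        return [], pd.DataFrame(
            columns=["group", "n", "n_accepted", "accepted_fraction"]
        )
    df = pd.DataFrame(
        {
            "group": [d.group if d.group is not None else "all" for d in decisions],
            "accepted": [d.accepted for d in decisions],
        }
    )
    summary = (
        df.groupby("group")["accepted"]
        .agg(n="size", n_accepted="sum")
        .reset_index()
    )
    summary["accepted_fraction"] = summary["n_accepted"] / summary["n"]
    total = pd.DataFrame(
        {
            "group": ["all"],
            "n": [len(decisions)],
            "n_accepted": [int(df["accepted"].sum())],
            "accepted_fraction": [float(df["accepted"].mean())],
        }
    )
    if not (summary["group"] == "all").any():
        summary = pd.concat([summary, total], ignore_index=True)
    return decisions, summary
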
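"""Closed-form and small statistical computations on cell-level data.

Cumulative apoptosis from per-hour rates, event-stream rate profiles with
exact Poisson confidence intervals, treated-vs-control outcome
proportions, circular-arc (sagitta) interface curvature and z-stack
volume integration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "OutcomeCounts",
    "cumulative_death_percent",
    "rates_from_events",
    "outcome_proportions",
    "sagitta_curvature",
    "volume_from_z_areas",
]


@dataclass
class OutcomeCounts:
    """Affected/total counts for a treated and a control arm."""

    k_treated: int
    n_treated: int
    k_control: int
    n_control: int

    def __post_init__(self) -> None:
        for k, n in ((self.k_treated, self.n_treated), (self.k_control, self.n_control)):
            if not 0 <= k <= n:
                raise ValueError("counts must satisfy 0 <= k <= n")


def cumulative_death_percent(p_a: float, hours: float) -> float:
    """Percent of cells commencing apoptosis within ``hours``.

    From the per-hour survival probability: 100 * (1 - (1 - p_a)^hours).
    """
    if not 0.0 <= p_a <= 1.0:
        raise ValueError("p_a must be a probability per hour in [0, 1]")
    if hours < 0:
        raise ValueError("duration must be non-negative")
    return 100.0 * (1.0 - (1.0 - p_a) ** hours)


def rates_from_events(
    events: pd.DataFrame,
    exposure_cell_hours,
    n_bins: int = 20,
    event_type: str = "apoptosis",
    conf: float = 0.95,
) -> pd.DataFrame:
    """Per-bin event rates (per cell-hour) with exact Poisson CIs.

    ``exposure_cell_hours`` is either a scalar (same exposure per bin) or a
    length-``n_bins`` array.  The CI uses the chi-square inversion of the
    Poisson count: lower = chi2(alpha/2, 2k)/2, upper =
    chi2(1 - alpha/2, 2k + 2)/2, divided by the exposure (so that the
    upper bound for zero counts is 3.689/exposure at 95%).
    """
    exposure = np.broadcast_to(np.asarray(exposure_cell_hours, dtype=float), (n_bins,))
    if np.any(exposure <= 0):
        raise ValueError("exposure must be positive in every bin")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    sel = events[events["type"] == event_type]
    counts, _ = np.histogram(sel["x"].to_numpy(dtype=float), bins=edges)
    a = 1.0 - conf
    k = counts.astype(float)
    lo = np.where(k > 0, sps.chi2.ppf(a / 2.0, 2.0 * k) / 2.0, 0.0)
    hi = sps.chi2.ppf(1.0 - a / 2.0, 2.0 * k + 2.0) / 2.0
    return pd.DataFrame(
        {
            "x_center": 0.5 * (edges[:-1] + edges[1:]),
            "events": counts,
            "exposure": exposure,
            "rate": k / exposure,
            "rate_lo": lo / exposure,
            "rate_hi": hi / exposure,
        }
    )


def outcome_proportions(counts: OutcomeCounts) -> tuple[float, float, float]:
    """(percent_treated, percent_control, two-sided Fisher exact p).

    Percentages are rounded to one decimal, matching common reporting.
    """
    pct_t = round(100.0 * counts.k_treated / counts.n_treated, 1)
    pct_c = round(100.0 * counts.k_control / counts.n_control, 1)
    table = [
        [counts.k_treated, counts.n_treated - counts.k_treated],
        [counts.k_control, counts.n_control - counts.k_control],
    ]
    _, p = sps.fisher_exact(table, alternative="two-sided")
    return pct_t, pct_c, float(p)


def sagitta_curvature(chord_um: float, deflection_um: float) -> float:
    """Curvature (1/um) of a circular arc from chord length and sagitta.

    The arc through a chord L with maximal deflection h has radius
    R = ((L/2)^2 + h^2) / (2 h); the curvature is 1/R.  A flat interface
    (h = 0) has curvature 0.
    """
    if chord_um <= 0:
        raise ValueError("chord must be positive")
    if deflection_um < 0:
        raise ValueError("deflection must be non-negative")
    if deflection_um == 0:
        return 0.0
    r_arc = ((chord_um / 2.0) ** 2 + deflection_um**2) / (2.0 * deflection_um)
    return 1.0 / r_arc


def volume_from_z_areas(areas_um2, dz_um: float) -> float:
    """Volume (fl) from per-plane cross-section areas: sum(area) * dz."""
    if dz_um <= 0:
        raise ValueError("dz must be positive")
    areas = np.asarray(list(areas_um2), dtype=float)
    if areas.size == 0:
        warnings.warn("empty area list; returning zero volume", stacklevel=2)
        return 0.0
    if np.any(areas < 0):
        raise ValueError("areas must be non-negative")
    return float(areas.sum() * dz_um)
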
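"""Cellular activity kinetics: uptake, partition, clearance, and
time-integrated activity.

The assay's activity model: cells instantly bind a fraction of the added
activity at the start of incubation (measured as %AA per 100,000 cells);
the bound activity splits between a membrane-bound and an internalized
pool at a constant ratio (0.76); during incubation only physical decay
acts; after the radioactive medium is removed the cells release activity
with a mono-exponential biological clearance that plateaus — retention
``r(t) = p + (1 - p) exp(-ln2 t / T_bio)``.  Time-integrated activity
(TIA, in Bq·s) follows in closed form for each experimental phase.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from radiocell.nuclide_data import HOUR

__all__ = [
    "ClearanceModel",
    "PartitionModel",
    "PhaseActivity",
    "bound_activity_per_cell",
    "fit_clearance",
    "time_integrated_activity",
    "FitFailureError",
]

LN2 = math.log(2.0)


class FitFailureError(RuntimeError):
    """Raised when a kinetic fit does not converge."""


@dataclass(frozen=True)
class ClearanceModel:
    """Exponential-plus-plateau biological retention.

    ``retention(t) = plateau_fraction + (1 - plateau_fraction)
    * exp(-ln2 * t / biological_half_life_h)`` — monotone non-increasing
    with r(0) = 1.
    """

    plateau_fraction: float
    biological_half_life_h: float
    plateau_se: float | None = None
    half_life_se: float | None = None
    r_squared: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.plateau_fraction <= 1.0:
            raise ValueError("plateau_fraction must be in [0, 1]")
        if not self.biological_half_life_h > 0:
            raise ValueError("biological_half_life_h must be > 0")

    @property
    def fast_fraction(self) -> float:
        return 1.0 - self.plateau_fraction

    @property
    def biological_lambda_per_s(self) -> float:
        return LN2 / (self.biological_half_life_h * HOUR)

    def retention(self, t_h: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t_h, dtype=float)
        out = self.plateau_fraction + self.fast_fraction * np.exp(
            -LN2 * t / self.biological_half_life_h
        )
        return float(out) if np.ndim(t_h) == 0 else out

    def to_json(self) -> str:
        return json.dumps(
            {
                "plateau_fraction": self.plateau_fraction,
                "biological_half_life_h": self.biological_half_life_h,
                "plateau_se": self.plateau_se,
                "half_life_se": self.half_life_se,
                "r_squared": self.r_squared,
                "degenerate": self.degenerate,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ClearanceModel":
        return cls(**json.loads(text))


@dataclass(frozen=True)
class PartitionModel:
    """Constant membrane-bound to internalized activity partition."""

    membrane_to_internal_ratio: float = 0.76

    def __post_init__(self) -> None:
        if not self.membrane_to_internal_ratio >= 0:
            raise ValueError("ratio must be >= 0")

    @property
    def membrane_fraction(self) -> float:
        r = self.membrane_to_internal_ratio
        return r / (1.0 + r)

    @property
    def internal_fraction(self) -> float:
        return 1.0 / (1.0 + self.membrane_to_internal_ratio)


@dataclass(frozen=True)
class PhaseActivity:
    """Time-integrated activity of one experimental phase."""

    phase: str  # incubation | colony_growth
    a0_per_cell_bq: float
    duration_h: float
    time_integrated_activity_bq_s: float

    def __post_init__(self) -> None:
        if self.phase not in ("incubation", "colony_growth"):
            raise ValueError("phase must be incubation or colony_growth")
        tia = self.time_integrated_activity_bq_s
        if tia < 0:
            raise ValueError("TIA must be >= 0")
        if tia > self.a0_per_cell_bq * self.duration_h * HOUR * (1 + 1e-12):
            raise ValueError("TIA cannot exceed A0 * duration")


def bound_activity_per_cell(
    concentration_bq_per_ml: float,
    volume_ml: float,
    uptake_pct_per_1e5_cells: float,
    n_cells: float,
) -> float:
    """Cell-bound activity (Bq/cell) from the measured uptake.

    Uptake is expressed as percent of added activity per 100,000 cells, so
    total bound activity is ``added x (uptake%/100) x (n_cells / 1e5)`` and
    the per-cell value is that divided by ``n_cells`` — i.e. independent of
    the actual cell number:
    ``A_cell = added_bq x uptake_pct / 100 / 1e5``.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be > 0")
    if min(concentration_bq_per_ml, volume_ml, uptake_pct_per_1e5_cells) < 0:
        raise ValueError("inputs must be >= 0")
    added_bq = concentration_bq_per_ml * volume_ml
    return added_bq * (uptake_pct_per_1e5_cells / 100.0) / 1e5


def fit_clearance(
    times_h: np.ndarray,
    retained_fraction: np.ndarray,
    replicate_errors: np.ndarray | None = None,
) -> ClearanceModel:
    """Least-squares fit of the exponential-plus-plateau retention model.

    ``times_h`` / ``retained_fraction`` may contain replicate measurements
    (repeated time values).  Returns the fitted plateau and biological
    half-life with standard errors and R².  A near-constant series is
    returned with ``degenerate=True`` (half-life unidentifiable).
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(retained_fraction, dtype=float)
    if t.shape != y.shape:
        raise ValueError("times and fractions must have the same shape")
    if len(np.unique(t)) < 4 or 0.0 not in np.unique(t):
        raise ValueError("need >= 4 distinct time points including t = 0")
    if np.any((y < 0) | (y > 1.1)):
        raise ValueError("retained fractions must lie in [0, 1.1]")

    def model(tt, p, half):
        return p + (1.0 - p) * np.exp(-LN2 * tt / half)

    # degenerate flat series: no decaying component to fit
    if np.ptp(y) < 1e-6:
        return ClearanceModel(
            plateau_fraction=float(np.clip(y.mean(), 0, 1)),
            biological_half_life_h=1.0,
            degenerate=True,
            r_squared=1.0,
        )

    sigma = None
    if replicate_errors is not None:
        sigma = np.clip(np.asarray(replicate_errors, dtype=float), 1e-6, None)
    try:
        popt, pcov = curve_fit(
            model,
            t,
            y,
            p0=(max(float(y.min()), 1e-3), 2.0),
            sigma=sigma,
            bounds=([0.0, 1e-3], [1.0, 1e3]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy non-convergence
        raise FitFailureError(f"clearance fit did not converge: {exc}") from exc
    p, half = popt
    perr = np.sqrt(np.diag(pcov))
    resid = y - model(t, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return ClearanceModel(
        plateau_fraction=float(p),
        biological_half_life_h=float(half),
        plateau_se=float(perr[0]),
        half_life_se=float(perr[1]),
        r_squared=r2,
    )


def time_integrated_activity(
    a0_bq: float,
    physical_half_life_h: float,
    clearance: ClearanceModel | None,
    duration_h: float,
) -> float:
    """Closed-form TIA (Bq·s) of ``A(t) = A0 exp(-lambda_p t) r(t)``.

    With no clearance model, r = 1.  ``physical_half_life_h`` may be
    ``inf`` (no decay).
    """
    if a0_bq < 0 or duration_h < 0:
        raise ValueError("A0 and duration must be >= 0")
    lam_p = 0.0 if math.isinf(physical_half_life_h) else LN2 / physical_half_life_h

    def _integral(lam: float, t: float) -> float:
        # integral of exp(-lam u) du from 0 to t, in hours
        if lam == 0.0:
            return t
        return (1.0 - math.exp(-lam * t)) / lam

    if clearance is None:
        hours = _integral(lam_p, duration_h)
    else:
        lam_b = LN2 / clearance.biological_half_life_h
        hours = clearance.plateau_fraction * _integral(lam_p, duration_h) + (
            clearance.fast_fraction
        ) * _integral(lam_p + lam_b, duration_h)
    return a0_bq * hours * HOUR
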
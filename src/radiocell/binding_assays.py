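"""Radioligand uptake quantification and competitive-displacement IC50.

Uptake is measured on a gamma counter: cell-lysate counts are compared to
a standard aliquot representing a known fraction of the added activity,
and expressed as percent of added activity per 100,000 cells
(%AA/100,000 cells).  Displacement assays titrate unlabeled competitor
over ~seven decades; the bound signal is normalized and fitted with a
one-site competition sigmoid on log10 concentration to yield the IC50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["uptake_percent", "IC50Fit", "fit_ic50"]


def uptake_percent(
    lysate_counts: float,
    standard_counts: float,
    standard_fraction_of_added: float,
    cell_count: float,
) -> float:
    """%AA per 100,000 cells from gamma-counter measurements.

    ``standard_counts`` is the signal of an aliquot representing
    ``standard_fraction_of_added`` of the total added activity (e.g. a
    100 uL sample of a 1.5 mL incubation: fraction 1/15).
    """
    if standard_counts <= 0:
        raise ValueError("standard_counts must be > 0")
    if standard_fraction_of_added <= 0 or cell_count <= 0:
        raise ValueError("standard fraction and cell count must be > 0")
    if lysate_counts < 0:
        raise ValueError("lysate_counts must be >= 0")
    added = standard_counts / standard_fraction_of_added
    return 100.0 * (lysate_counts / added) * (1e5 / cell_count)


@dataclass(frozen=True)
class IC50Fit:
    """One-site competition fit on normalized displacement data."""

    ic50_m: float
    ic50_ci95_m: tuple[float, float]
    hill_slope: float
    top: float
    bottom: float
    r_squared: float
    flagged: bool = False
    message: str = ""


def _competition(logc: np.ndarray, top: float, bottom: float,
                 logic50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logc - logic50) * hill))


def fit_ic50(
    concentrations_m: np.ndarray,
    bound_signal: np.ndarray,
    fix_hill: bool = False,
) -> IC50Fit:
    """Least-squares one-site competition fit; returns IC50 with 95% CI.

    ``bound_signal`` is normalized internally so that the mean signal at the
    lowest competitor concentration defines 100%.  Requires >= 6
    concentrations spanning >= 4 decades.  A curve with no resolvable
    displacement, or an IC50 outside the tested range, is returned flagged
    rather than raising.
    """
    c = np.asarray(concentrations_m, dtype=float)
    y = np.asarray(bound_signal, dtype=float)
    if c.shape != y.shape:
        raise ValueError("concentrations and signal must match")
    uniq = np.unique(c)
    if uniq.size < 6:
        raise ValueError("need >= 6 distinct concentrations")
    span = np.log10(uniq.max() / uniq.min())
    if span < 4:
        raise ValueError("concentrations must span >= 4 decades")
    logc = np.log10(c)

    # normalize: mean signal at the lowest concentration = 1
    ref = float(y[c == uniq[0]].mean())
    if ref <= 0:
        raise ValueError("signal at lowest concentration must be > 0")
    yn = y / ref

    if np.ptp(yn) < 0.05:
        return IC50Fit(
            ic50_m=np.nan, ic50_ci95_m=(np.nan, np.nan), hill_slope=np.nan,
            top=float(yn.mean()), bottom=float(yn.mean()), r_squared=0.0,
            flagged=True, message="no displacement resolved (flat curve)",
        )

    mid = 0.5 * (np.log10(uniq.min()) + np.log10(uniq.max()))
    if fix_hill:
        def model(x, top, bottom, logic50):
            return _competition(x, top, bottom, logic50, 1.0)
        p0 = (1.0, float(yn.min()), mid)
        bounds = ([0.0, 0.0, np.log10(uniq.min()) - 2],
                  [2.0, 1.0, np.log10(uniq.max()) + 2])
    else:
        model = _competition
        p0 = (1.0, float(yn.min()), mid, 1.0)
        bounds = ([0.0, 0.0, np.log10(uniq.min()) - 2, 0.2],
                  [2.0, 1.0, np.log10(uniq.max()) + 2, 5.0])
    try:
        popt, pcov = curve_fit(model, logc, yn, p0=p0, bounds=bounds, maxfev=20000)
    except RuntimeError as exc:
        return IC50Fit(
            ic50_m=np.nan, ic50_ci95_m=(np.nan, np.nan), hill_slope=np.nan,
            top=np.nan, bottom=np.nan, r_squared=0.0,
            flagged=True, message=f"fit failed: {exc}",
        )
    if fix_hill:
        top, bottom, logic50 = popt
        hill = 1.0
        i_log = 2
    else:
        top, bottom, logic50, hill = popt
        i_log = 2
    resid = yn - model(logc, *popt)
    ss_tot = float(np.sum((yn - yn.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    se_log = float(np.sqrt(pcov[i_log, i_log]))
    ic50 = 10.0**logic50
    ci = (10.0 ** (logic50 - 1.96 * se_log), 10.0 ** (logic50 + 1.96 * se_log))
    flagged = not (uniq.min() <= ic50 <= uniq.max())
    return IC50Fit(
        ic50_m=float(ic50),
        ic50_ci95_m=(float(ci[0]), float(ci[1])),
        hill_slope=float(hill),
        top=float(top),
        bottom=float(bottom),
        r_squared=r2,
        flagged=flagged,
        message="IC50 outside tested range" if flagged else "",
    )
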
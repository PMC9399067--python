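"""Clonogenic dose-response: survival fractions, radiosensitivity, RBE.

Colony counts (450 cells plated per well, triplicate wells, independent
experiments) are normalized to untreated controls to give survival
fractions with Poisson counting uncertainties.  Survival is modelled as
log-linear in absorbed dose to the nucleus, ``SF = exp(-alpha D)``
(an optional quadratic term is available but off by default, since a pure
linear exponent describes both radioligands here).  The radiosensitivity
``alpha`` is fitted by weighted least squares of ln SF through the origin,
and the relative biological effectiveness for cell killing is the ratio of
the fitted slopes with first-order error propagation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SurvivalPoint",
    "DoseResponseFit",
    "RBEResult",
    "survival_fractions",
    "survival_points_from_table",
    "fit_alpha",
    "plot_dose_response",
    "rbe",
]


@dataclass(frozen=True)
class SurvivalPoint:
    """One dose point of a clonogenic survival curve."""

    dose_gy: float
    mean_colonies: float
    survival_fraction: float
    sd: float
    n_wells: int = 3
    excluded: bool = False
    experiment: int | None = None

    def __post_init__(self) -> None:
        if self.survival_fraction < 0:
            raise ValueError("survival fraction must be >= 0")
        if self.mean_colonies > 0 and not self.sd > 0:
            raise ValueError("sd must be > 0 when colonies were observed")


@dataclass(frozen=True)
class DoseResponseFit:
    """Weighted log-linear fit ``ln SF = -alpha D`` through the origin."""

    alpha_gy_inv: float
    alpha_se_gy_inv: float
    r_squared: float
    n_points: int
    beta_gy2_inv: float = 0.0
    beta_se_gy2_inv: float = 0.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.alpha_gy_inv):
            raise ValueError("alpha must be finite")

    def survival(self, dose_gy: np.ndarray | float) -> np.ndarray | float:
        d = np.asarray(dose_gy, dtype=float)
        return np.exp(-self.alpha_gy_inv * d - self.beta_gy2_inv * d**2)


@dataclass(frozen=True)
class RBEResult:
    """Relative biological effectiveness with propagated standard error."""

    rbe: float
    rbe_se: float

    def __post_init__(self) -> None:
        if not self.rbe > 0:
            raise ValueError("RBE must be > 0")


def survival_fractions(
    doses_gy: np.ndarray,
    colony_counts: np.ndarray,
    untreated_counts: np.ndarray,
    excluded: np.ndarray | None = None,
    experiment: int | None = None,
) -> list[SurvivalPoint]:
    """Normalize colony counts to untreated controls.

    ``colony_counts`` has one row of replicate wells per dose.  SF is the
    ratio of treated to untreated mean counts; its SD assumes Poisson
    statistics of the mean counts, propagated through the ratio:
    ``sd = SF * sqrt(1 / mean(treated) + 1 / mean(untreated))``.  Complete
    kill (zero colonies) yields SF = 0 with a one-sided Poisson upper bound
    stored in ``sd``.
    """
    doses = np.atleast_1d(np.asarray(doses_gy, dtype=float))
    counts = np.atleast_2d(np.asarray(colony_counts, dtype=float))
    ctrl = np.asarray(untreated_counts, dtype=float)
    if counts.shape[0] != doses.size:
        raise ValueError("one row of replicate counts per dose required")
    ctrl_mean = float(ctrl.mean())
    if ctrl_mean <= 0:
        raise ValueError("untreated mean must be > 0 for normalization")
    if excluded is None:
        excluded = np.zeros(doses.size, dtype=bool)

    points = []
    for d, row, exc in zip(doses, counts, np.asarray(excluded, dtype=bool)):
        mean = float(row.mean())
        sf = mean / ctrl_mean
        if mean > 0:
            sd = sf * np.sqrt(1.0 / mean + 1.0 / ctrl_mean)
        else:
            # one-sided 1-sigma Poisson upper bound on the mean count
            sd = 1.84 / len(row) / ctrl_mean
        points.append(
            SurvivalPoint(
                dose_gy=float(d),
                mean_colonies=mean,
                survival_fraction=sf,
                sd=float(sd),
                n_wells=len(row),
                excluded=bool(exc),
                experiment=experiment,
            )
        )
    return points


def survival_points_from_table(table) -> list[SurvivalPoint]:
    """Survival points from a colony-count table.

    The table (``pandas.DataFrame``) needs columns ``dose_gy``,
    ``experiment``, ``replicate`` and ``colonies``; optionally an
    ``excluded`` flag per row.  Each experiment is normalized to its own
    untreated (dose 0) wells, yielding one survival point per experiment
    and dose.
    """
    import pandas as pd  # local: keep module import light

    df = pd.DataFrame(table)
    required = {"dose_gy", "experiment", "replicate", "colonies"}
    if not required <= set(df.columns):
        raise ValueError(f"colony table needs columns {sorted(required)}")
    points: list[SurvivalPoint] = []
    for exp_id, sub in df.groupby("experiment"):
        ctrl = sub.loc[sub["dose_gy"] == 0, "colonies"].to_numpy()
        if ctrl.size == 0:
            raise ValueError("each experiment needs untreated (dose 0) wells")
        treated = sub[sub["dose_gy"] > 0]
        doses = sorted(treated["dose_gy"].unique())
        counts = [
            treated.loc[treated["dose_gy"] == d, "colonies"].to_numpy()
            for d in doses
        ]
        if "excluded" in sub.columns:
            exc = np.array(
                [
                    bool(treated.loc[treated["dose_gy"] == d, "excluded"].any())
                    for d in doses
                ]
            )
        else:
            exc = None
        points.extend(
            survival_fractions(
                np.array(doses), counts, ctrl, exc, experiment=int(exp_id)
            )
        )
    return points


def fit_alpha(
    points: list[SurvivalPoint],
    exclude_flagged: bool = True,
    include_beta: bool = False,
) -> DoseResponseFit:
    """Weighted least-squares fit of ``ln SF = -alpha D`` through the origin.

    Weights are the inverse variances of ln SF derived from the Poisson
    SDs; zero-SF points cannot be log-transformed and are dropped with a
    warning.  The reported standard error combines two components in
    quadrature: the weighted-least-squares error scaled by the reduced
    chi-square (within-experiment counting statistics and scatter), and —
    when points carry experiment labels from two or more independent
    experiments — the between-experiment standard error of per-experiment
    slope estimates.  Survival points within one experiment share its
    untreated control, which correlates them; the between-experiment
    component captures that reproducibility term which the pooled residual
    scatter understates.  R² is computed on the ln scale against the
    zero-intercept model.
    """
    usable = [
        p
        for p in points
        if p.dose_gy > 0 and not (exclude_flagged and p.excluded)
    ]
    dropped = [p for p in usable if p.survival_fraction <= 0]
    if dropped:
        warnings.warn(
            f"{len(dropped)} zero-survival point(s) dropped from ln fit",
            stacklevel=2,
        )
    usable = [p for p in usable if p.survival_fraction > 0]
    if len(usable) < 3:
        raise ValueError("need >= 3 usable points with dose > 0")

    d = np.array([p.dose_gy for p in usable])
    lnsf = np.log([p.survival_fraction for p in usable])
    var_ln = np.array([(p.sd / p.survival_fraction) ** 2 for p in usable])
    w = 1.0 / var_ln

    if include_beta:
        x = np.column_stack([-d, -(d**2)])
    else:
        x = -d[:, None]
    wx = x * w[:, None]
    xtx = x.T @ wx
    coef = np.linalg.solve(xtx, wx.T @ lnsf)
    cov = np.linalg.inv(xtx)
    resid = lnsf - x @ coef
    dof = len(usable) - x.shape[1]
    chi2_red = float((w * resid**2).sum() / dof) if dof > 0 else 1.0
    cov = cov * max(chi2_red, 1.0)
    se = np.sqrt(np.diag(cov))

    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum(lnsf**2))  # zero-intercept null model
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0

    # between-experiment reproducibility component of the slope error
    exps = sorted({p.experiment for p in usable if p.experiment is not None})
    se_between = 0.0
    if not include_beta and len(exps) >= 2:
        slopes = []
        for e in exps:
            idx = np.array([p.experiment == e for p in usable])
            if idx.sum() >= 2:
                we, de, ye = w[idx], d[idx], lnsf[idx]
                slopes.append(float(-np.sum(we * de * ye) / np.sum(we * de * de)))
        if len(slopes) >= 2:
            se_between = float(
                np.std(slopes, ddof=1) / np.sqrt(len(slopes))
            )
    se = np.sqrt(se**2 + np.array([se_between] + [0.0] * (len(se) - 1)) ** 2)

    alpha = float(coef[0])
    beta = float(coef[1]) if include_beta else 0.0
    beta_se = float(se[1]) if include_beta else 0.0
    return DoseResponseFit(
        alpha_gy_inv=alpha,
        alpha_se_gy_inv=float(se[0]),
        r_squared=r2,
        n_points=len(usable),
        beta_gy2_inv=beta,
        beta_se_gy2_inv=beta_se,
    )


def plot_dose_response(
    points: list[SurvivalPoint],
    fit: DoseResponseFit,
    path,
    label: str = "",
) -> None:
    """Export a semilog survival-vs-dose plot with the fitted curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    usable = [p for p in points if p.survival_fraction > 0]
    d = np.array([p.dose_gy for p in usable])
    sf = np.array([p.survival_fraction for p in usable])
    sd = np.array([p.sd for p in usable])
    ax.errorbar(d, sf, yerr=sd, fmt="o", ms=4, capsize=2, label="data")
    grid = np.linspace(0, max(d.max(), 1e-6) * 1.05, 200)
    ax.plot(grid, fit.survival(grid), "-",
            label=f"fit: alpha = {fit.alpha_gy_inv:.3f} /Gy")
    ax.set_yscale("log")
    ax.set_xlabel("absorbed dose to nucleus (Gy)")
    ax.set_ylabel("survival fraction")
    if label:
        ax.set_title(label)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def rbe(fit_test: DoseResponseFit, fit_reference: DoseResponseFit) -> RBEResult:
    """RBE for cell killing: ratio of radiosensitivities alpha_test/alpha_ref
    with first-order (uncorrelated ratio) error propagation."""
    if fit_reference.alpha_gy_inv <= 0:
        raise ValueError("reference alpha must be > 0")
    ratio = fit_test.alpha_gy_inv / fit_reference.alpha_gy_inv
    rel = np.sqrt(
        (fit_test.alpha_se_gy_inv / fit_test.alpha_gy_inv) ** 2
        + (fit_reference.alpha_se_gy_inv / fit_reference.alpha_gy_inv) ** 2
    )
    return RBEResult(rbe=float(ratio), rbe_se=float(ratio * rel))
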
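"""Seeded generators for every input the analysis pipeline consumes.

Each generator emulates one wet-lab assay with the statistical structure
the analysis assumes, so that every stage of the pipeline can be exercised
and validated without measured data:

* clonogenic colony counts: Poisson draws around
  ``450 x PE x exp(-alpha D)`` with lognormal between-experiment
  variability (3 experiments x 3 replicate wells);
* cellular excretion series: exponential-plus-plateau retention on the
  measured time grid {0, 4, 24, 48, 120} h, 2 experiments x triplicate,
  multiplicative Gaussian noise;
* competitive displacement curves and gamma-counter uptake measurements;
* fluorescence image stacks of elliptical nuclei carrying Gaussian foci
  (negative-binomial focus counts to match over-dispersed per-cell
  distributions) and brightfield fields of circular floating cells.

Every function takes a ``seed`` and returns its ground-truth generating
parameters in a metadata dict, enabling parameter-recovery tests.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "gen_clonogenic",
    "gen_excretion",
    "gen_displacement",
    "gen_uptake",
    "gen_foci_images",
    "gen_brightfield",
    "write_with_sidecar",
]

#: default absorbed-dose grids (Gy, average-size cells) for the two
#: radioligands' usable concentration series
DEFAULT_DOSES_GY = {
    "Lu-177": (0.74, 1.48, 2.22, 2.96, 3.70),
    "Ac-225": (0.08, 0.22, 0.41, 0.56, 0.83, 1.12, 1.67),
}
#: generating radiosensitivities (1/Gy)
DEFAULT_ALPHAS = {"Lu-177": 0.16, "Ac-225": 0.67}


def write_with_sidecar(df: pd.DataFrame, path: str | Path, meta: dict) -> None:
    """Write a CSV plus a JSON sidecar holding seed and parameters."""
    path = Path(path)
    df.to_csv(path, index=False)
    path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2))


# ---------------------------------------------------------------------------
# clonogenic assay
# ---------------------------------------------------------------------------
def gen_clonogenic(
    doses_gy: tuple[float, ...],
    alpha_gy_inv: float,
    seed: int,
    plating_efficiency: float = 0.5,
    cells_plated: int = 450,
    n_experiments: int = 3,
    n_replicates: int = 3,
    interexperiment_sigma: float = 0.06,
) -> tuple[pd.DataFrame, dict]:
    """Poisson colony counts from a log-linear survival model.

    Expected colonies per well: ``cells_plated x PE x exp(-alpha D)``
    times a lognormal experiment/condition factor ``exp(N(0, sigma))``
    capturing between-experiment variability (centred on the ln scale so
    the fitted slope is unbiased).  Untreated control wells (D = 0) are
    included per experiment.
    """
    rng = np.random.default_rng(seed)
    rows = []
    all_doses = (0.0,) + tuple(doses_gy)
    for exp in range(1, n_experiments + 1):
        for dose in all_doses:
            mu = cells_plated * plating_efficiency * np.exp(-alpha_gy_inv * dose)
            mu *= np.exp(rng.normal(0.0, interexperiment_sigma))
            counts = rng.poisson(mu, size=n_replicates)
            for rep, cnt in enumerate(counts, start=1):
                rows.append(
                    {
                        "dose_gy": dose,
                        "experiment": exp,
                        "replicate": rep,
                        "colonies": int(cnt),
                    }
                )
    meta = {
        "seed": seed,
        "alpha_gy_inv": alpha_gy_inv,
        "plating_efficiency": plating_efficiency,
        "cells_plated": cells_plated,
        "n_experiments": n_experiments,
        "n_replicates": n_replicates,
        "interexperiment_sigma": interexperiment_sigma,
    }
    return pd.DataFrame(rows), meta


# ---------------------------------------------------------------------------
# excretion / displacement / uptake
# ---------------------------------------------------------------------------
def gen_excretion(
    seed: int,
    plateau: float = 0.41,
    half_life_h: float = 2.3,
    times_h: tuple[float, ...] = (0.0, 4.0, 24.0, 48.0, 120.0),
    n_experiments: int = 2,
    n_replicates: int = 3,
    noise_cv: float = 0.03,
) -> tuple[pd.DataFrame, dict]:
    """Retention series from the exponential-plus-plateau clearance model
    with multiplicative Gaussian noise (t = 0 anchored at 1 before noise)."""
    rng = np.random.default_rng(seed)
    ln2 = np.log(2.0)
    rows = []
    for exp in range(1, n_experiments + 1):
        for t in times_h:
            r = plateau + (1.0 - plateau) * np.exp(-ln2 * t / half_life_h)
            for rep in range(1, n_replicates + 1):
                val = r * (1.0 + rng.normal(0.0, noise_cv))
                rows.append(
                    {
                        "time_h": t,
                        "retained_fraction": float(np.clip(val, 0.0, 1.1)),
                        "experiment": exp,
                        "replicate": rep,
                    }
                )
    meta = {
        "seed": seed,
        "plateau": plateau,
        "half_life_h": half_life_h,
        "noise_cv": noise_cv,
        "times_h": list(times_h),
    }
    return pd.DataFrame(rows), meta


def gen_displacement(
    seed: int,
    ic50_m: float = 1.53e-8,
    hill: float = 1.0,
    bottom: float = 0.03,
    concentrations_m: tuple[float, ...] = tuple(np.geomspace(1e-13, 1e-6, 8)),
    n_experiments: int = 3,
    n_replicates: int = 3,
    noise_cv: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """One-site competitive displacement curves with multiplicative noise."""
    rng = np.random.default_rng(seed)
    rows = []
    logic50 = np.log10(ic50_m)
    for exp in range(1, n_experiments + 1):
        for c in concentrations_m:
            signal = bottom + (1.0 - bottom) / (
                1.0 + 10.0 ** ((np.log10(c) - logic50) * hill)
            )
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "concentration_m": c,
                        "bound_signal": signal * (1.0 + rng.normal(0.0, noise_cv)),
                        "experiment": exp,
                        "replicate": rep,
                    }
                )
    meta = {
        "seed": seed,
        "ic50_m": ic50_m,
        "hill": hill,
        "bottom": bottom,
        "noise_cv": noise_cv,
    }
    return pd.DataFrame(rows), meta


def gen_uptake(
    seed: int,
    uptake_pct_per_1e5_cells: float = 1.87,
    added_counts: float = 1e6,
    standard_fraction: float = 0.1 / 1.5,
    cell_count: float = 750_000.0,
    n_experiments: int = 3,
    n_replicates: int = 3,
    noise_cv: float = 0.03,
) -> tuple[pd.DataFrame, dict]:
    """Gamma-counter uptake measurements: lysate and standard counts.

    The lysate signal corresponds to the generating %AA/100,000 cells
    scaled to the actual cell number; both counts carry multiplicative
    counting noise.
    """
    rng = np.random.default_rng(seed)
    bound_fraction = uptake_pct_per_1e5_cells / 100.0 * (cell_count / 1e5)
    rows = []
    for exp in range(1, n_experiments + 1):
        for rep in range(1, n_replicates + 1):
            lysate = added_counts * bound_fraction * (1 + rng.normal(0, noise_cv))
            standard = added_counts * standard_fraction * (1 + rng.normal(0, noise_cv))
            rows.append(
                {
                    "experiment": exp,
                    "replicate": rep,
                    "lysate_counts": lysate,
                    "standard_counts": standard,
                    "cell_count": cell_count,
                }
            )
    meta = {
        "seed": seed,
        "uptake_pct_per_1e5_cells": uptake_pct_per_1e5_cells,
        "standard_fraction": standard_fraction,
        "cell_count": cell_count,
        "noise_cv": noise_cv,
    }
    return pd.DataFrame(rows), meta


# ---------------------------------------------------------------------------
# images
# ---------------------------------------------------------------------------
def _negative_binomial_counts(
    mean: float, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Integer focus counts with the requested mean and SD (negative
    binomial when over-dispersed, Poisson otherwise; sd = 0 gives exact
    constant counts)."""
    if sd == 0:
        return np.full(n, int(round(mean)))
    var = sd**2
    if var <= mean * (1.0 + 1e-9):
        return rng.poisson(mean, size=n)
    r = mean**2 / (var - mean)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size=n)


def _place_centers(
    n: int,
    shape: tuple[int, int],
    margin: float,
    min_dist: float,
    rng: np.random.Generator,
    max_tries: int = 20000,
) -> np.ndarray:
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n and tries < max_tries:
        tries += 1
        cand = np.array(
            [
                rng.uniform(margin, shape[0] - margin),
                rng.uniform(margin, shape[1] - margin),
            ]
        )
        if all(np.linalg.norm(cand - c) >= min_dist for c in centers):
            centers.append(cand)
    return np.asarray(centers)


def gen_foci_images(
    seed: int,
    n_nuclei: int = 30,
    mean_foci: float = 18.1,
    sd_foci: float = 7.4,
    image_shape: tuple[int, int] = (1024, 1024),
    n_z: int = 3,
    nucleus_axes_px: tuple[float, float] = (36.0, 54.0),
    focus_sigma_px: float = 1.2,
    focus_snr: float = 8.0,
    min_focus_separation_px: float = 5.0,
    background: float = 100.0,
    background_sd: float = 10.0,
    nuclear_signal: float = 800.0,
    noise: bool = True,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, dict]:
    """Synthetic two-channel z-stacks of elliptical nuclei with Gaussian foci.

    Returns ``(nuclear_stack, damage_stack, ground_truth, meta)`` where the
    stacks are (z, y, x) float arrays whose maximum projection carries the
    full 2-D scene, and ``ground_truth`` lists per-nucleus centres, axes and
    true focus counts.  With ``noise=False`` the stacks are exact analytic
    envelopes (for projection tests).

    Foci are placed with a minimum mutual separation
    (``min_focus_separation_px``): a "focus" in the scored assay is by
    definition a resolvable object, so ground-truth counts correspond to
    optically separable foci.  If a crowded nucleus cannot accommodate its
    drawn count, the actually placed number is recorded as truth.
    """
    rng = np.random.default_rng(seed)
    ny, nx = image_shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    a_max = nucleus_axes_px[1]
    centers = _place_centers(
        n_nuclei, image_shape, margin=a_max + 5, min_dist=2.3 * a_max, rng=rng
    )
    counts = _negative_binomial_counts(mean_foci, sd_foci, len(centers), rng)

    nuclear = np.zeros(image_shape)
    damage = np.zeros(image_shape)
    truth_rows = []
    for idx, (cen, n_foci) in enumerate(zip(centers, counts), start=1):
        a = rng.uniform(*nucleus_axes_px)
        b = rng.uniform(*nucleus_axes_px)
        theta = rng.uniform(0, np.pi)
        dy, dx = yy - cen[0], xx - cen[1]
        u = dy * np.cos(theta) + dx * np.sin(theta)
        v = -dy * np.sin(theta) + dx * np.cos(theta)
        inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        nuclear[inside] = nuclear_signal
        # diffuse damage-marker signal within the nucleus
        damage[inside] += 5.0 * background_sd
        # foci uniformly inside a slightly shrunk ellipse, kept resolvable
        amp = focus_snr * background_sd
        placed = 0
        tries = 0
        focus_yx: list[tuple[float, float]] = []
        while placed < n_foci and tries < 200 * max(n_foci, 1):
            tries += 1
            ru, rv = rng.uniform(-0.9, 0.9, 2)
            if (ru**2 + rv**2) > 0.81:
                continue
            fy = cen[0] + (ru * a) * np.cos(theta) - (rv * b) * np.sin(theta)
            fx = cen[1] + (ru * a) * np.sin(theta) + (rv * b) * np.cos(theta)
            if any(
                (fy - py) ** 2 + (fx - px) ** 2 < min_focus_separation_px**2
                for py, px in focus_yx
            ):
                continue
            focus_yx.append((fy, fx))
            # paint the Gaussian only in a +/-5 sigma window
            half = int(np.ceil(5 * focus_sigma_px))
            y0, y1 = max(0, int(fy) - half), min(ny, int(fy) + half + 1)
            x0, x1 = max(0, int(fx) - half), min(nx, int(fx) + half + 1)
            d2 = (yy[y0:y1, x0:x1] - fy) ** 2 + (xx[y0:y1, x0:x1] - fx) ** 2
            damage[y0:y1, x0:x1] += amp * np.exp(-d2 / (2.0 * focus_sigma_px**2))
            placed += 1
        truth_rows.append(
            {
                "nucleus_id": idx,
                "center_y": cen[0],
                "center_x": cen[1],
                "axis_a_px": a,
                "axis_b_px": b,
                "theta_rad": theta,
                "true_foci": int(placed),
            }
        )

    # distribute into z planes; max over z reproduces the 2-D scene
    z_weights = np.linspace(0.5, 1.0, n_z)
    rng.shuffle(z_weights)
    z_weights[rng.integers(0, n_z)] = 1.0
    nuclear_stack = np.stack([nuclear * w for w in z_weights])
    damage_stack = np.stack([damage * w for w in z_weights])
    if noise:
        nuclear_stack = nuclear_stack + rng.normal(
            background, background_sd, nuclear_stack.shape
        )
        damage_stack = damage_stack + rng.normal(
            background, background_sd, damage_stack.shape
        )
    else:
        nuclear_stack = nuclear_stack + background
        damage_stack = damage_stack + background

    meta = {
        "seed": seed,
        "n_nuclei_requested": n_nuclei,
        "n_nuclei_placed": len(centers),
        "mean_foci": mean_foci,
        "sd_foci": sd_foci,
        "focus_snr": focus_snr,
        "focus_sigma_px": focus_sigma_px,
        "noise": noise,
    }
    return nuclear_stack, damage_stack, pd.DataFrame(truth_rows), meta


def gen_brightfield(
    seed: int,
    n_circles: int = 100,
    radius_range_um: tuple[float, float] = (6.0, 11.0),
    pixel_size_um: float = 0.4,
    image_shape: tuple[int, int] = (1400, 1400),
    cell_attenuation: float = 0.6,
    noise_sd: float = 0.0,
) -> tuple[np.ndarray, pd.DataFrame, dict]:
    """Brightfield-like field of dark circular cells on a bright
    background, with ground-truth radii for sizing validation."""
    rng = np.random.default_rng(seed)
    ny, nx = image_shape
    r_max_px = radius_range_um[1] / pixel_size_um
    centers = _place_centers(
        n_circles, image_shape, margin=r_max_px + 4, min_dist=2.4 * r_max_px,
        rng=rng,
    )
    yy, xx = np.mgrid[0:ny, 0:nx]
    image = np.ones(image_shape)
    rows = []
    for idx, cen in enumerate(centers, start=1):
        r_um = rng.uniform(*radius_range_um)
        r_px = r_um / pixel_size_um
        dist = np.sqrt((yy - cen[0]) ** 2 + (xx - cen[1]) ** 2)
        image[dist <= r_px] = 1.0 - cell_attenuation
        rows.append(
            {
                "circle_id": idx,
                "center_y": cen[0],
                "center_x": cen[1],
                "radius_um": r_um,
                "radius_px": r_px,
            }
        )
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, image.shape)
    meta = {
        "seed": seed,
        "n_circles_requested": n_circles,
        "n_circles_placed": len(centers),
        "radius_range_um": list(radius_range_um),
        "pixel_size_um": pixel_size_um,
    }
    return image, pd.DataFrame(rows), meta
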
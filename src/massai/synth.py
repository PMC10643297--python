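"""Synthetic study inputs: landscape rasters, survey tables, known-truth
behavioural coefficients.

The generator emulates the structure of a representative survey of such a
system — 250 households in three input-intensity strata with ~451 plots
nested in them on a 10 m-pixel cultivated landscape — with spatially autocorrelated soil
property maps (Gaussian-filtered white noise; adequate for testing, not a
digital-soil-mapping method) and a decision dataset simulated from known
double-hurdle coefficients so parameter recovery can be verified end to end.

The subsidy coefficients in the truth tables carry the hypothesised signs:
positive on fertilizer adoption and on legume planting (the subsidy package
includes legume seed), negative on manure (subsidised fertilizer crowds out
alternative nutrient sources).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .behaviour import CoefficientTable
from .ecology import Param
from .io import (HOUSEHOLD_COLUMNS, PLOT_COLUMNS, write_ascii_grid,
                 write_coefficients, write_survey)

__all__ = ["gen_landscape", "gen_survey", "gen_behavioural_truth",
           "write_input_dir", "LANDSCAPE_DEFAULTS"]

#: concentration map means/sds (mg kg-1 fine earth) and soil physicals
LANDSCAPE_DEFAULTS = {
    "conc_n": (800.0, 150.0),      # total N
    "conc_p": (300.0, 60.0),       # total P
    "conc_k": (1500.0, 300.0),     # total K
    "conc_soc": (15000.0, 3000.0), # organic C (1.5 %)
    "bulk_density": (1.3, 0.08),
    "coarse_frag": (0.05, 0.03),
    "clay": (20.0, 5.0),
}


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _smooth_field(rng, shape, mean, sd, sigma=6.0, lo=None, hi=None):
    noise = gaussian_filter(rng.normal(size=shape), sigma, mode="reflect")
    s = noise.std()
    field = mean + sd * (noise - noise.mean()) / (s if s > 0 else 1.0)
    if lo is not None or hi is not None:
        field = np.clip(field, lo, hi)
    return field


def gen_landscape(nrows: int = 100, ncols: int = 100, seed=0,
                  cultivated_fraction: float = 0.55, relief: float = 60.0,
                  cellsize: float = 10.0, means=None) -> dict:
    """Generate a coherent synthetic landscape raster set.

    Elevation is a sum of low-frequency harmonics (smooth, so slopes are
    realistic); slope is its gradient magnitude in percent; soil property
    maps are spatially autocorrelated fields around the configured means;
    the cultivated mask covers ``cultivated_fraction`` of the grid as a few
    compact blocks.  Deterministic given the seed.
    """
    rng = _rng(seed)
    means = {**LANDSCAPE_DEFAULTS, **(means or {})}
    y, x = np.mgrid[0:nrows, 0:ncols]
    elev = np.zeros((nrows, ncols))
    for _ in range(6):
        kx, ky = rng.uniform(0.5, 3.0, size=2)
        phase = rng.uniform(0, 2 * np.pi, size=2)
        amp = rng.uniform(0.3, 1.0)
        elev += amp * np.sin(2 * np.pi * kx * x / ncols + phase[0]) \
            * np.sin(2 * np.pi * ky * y / nrows + phase[1])
    elev = relief * (elev - elev.min()) / max(np.ptp(elev), 1e-12)
    gy, gx = np.gradient(elev, cellsize)
    slope = 100.0 * np.hypot(gx, gy)

    out = {"elevation": elev, "slope": slope}
    for name, (mean, sd) in means.items():
        lo = 0.0
        hi = 0.4 if name == "coarse_frag" else None
        out[name] = _smooth_field(rng, (nrows, ncols), mean, sd, lo=lo, hi=hi)

    suit = gaussian_filter(rng.normal(size=(nrows, ncols)), 10.0, mode="reflect")
    thr = np.quantile(suit, 1.0 - cultivated_fraction)
    out["cultivated"] = (suit >= thr).astype(float)
    return out


_TYPE_PROFILES = {
    # farm_type: (income mean, livestock mean, labour mean, education mean,
    #             manure propensity, fert propensity)
    1: dict(income=300.0, livestock=0.5, labour=2.0, education=5.0),
    2: dict(income=600.0, livestock=1.5, labour=2.5, education=7.0),
    3: dict(income=1200.0, livestock=3.0, labour=3.0, education=9.0),
}


def gen_survey(n_households: int = 250, mean_plots_per_hh: float = 1.8,
               seed=0, type_props=(0.40, 0.35, 0.25), landscape=None,
               mean_plot_area_ha: float = 0.10) -> tuple:
    """Generate a survey-like household table with plots nested in it.

    Farm types are drawn with ``type_props``; attribute distributions shift
    upward with input intensity (type 3 richer in income, livestock, labour
    and schooling).  Plots are placed on free cultivated pixels of the
    landscape (generated on the fly if not supplied) with lognormal areas
    around ``mean_plot_area_ha``.

    Returns ``(households, plots, landscape)``.
    """
    rng = _rng(seed)
    if landscape is None:
        landscape = gen_landscape(seed=rng)
    types = rng.choice([1, 2, 3], size=n_households, p=np.asarray(type_props))
    rows = []
    for hid, t in enumerate(types):
        prof = _TYPE_PROFILES[int(t)]
        rows.append({
            "household_id": hid,
            "farm_type": int(t),
            "head_age": float(np.clip(rng.normal(45, 12), 18, 90)),
            "head_gender": int(rng.random() < 0.75),
            "education": float(np.clip(rng.normal(prof["education"], 2.5), 0, 16)),
            "labour": float(np.clip(rng.normal(prof["labour"], 0.7), 0.5, 8)),
            "income": float(rng.lognormal(np.log(prof["income"]), 0.5)),
            "livestock": float(rng.gamma(1.5, prof["livestock"] / 1.5)),
            "group_membership": bool(rng.random() < 0.2 + 0.2 * t),
            "transport_access": bool(rng.random() < 0.1 + 0.15 * t),
            "communication_access": bool(rng.random() < 0.35 + 0.18 * t),
            "sampled": True,
        })
    households = pd.DataFrame(rows, columns=HOUSEHOLD_COLUMNS)

    mask = np.asarray(landscape["cultivated"], dtype=bool)
    free = mask.copy()
    nr, nc = mask.shape
    elev = landscape["elevation"]
    terciles = np.quantile(elev[mask], [1 / 3, 2 / 3]) if mask.any() else (0, 0)
    free_idx = np.flatnonzero(free)
    rng.shuffle(free_idx)
    cursor = 0
    plot_rows = []
    pid = 0
    for hid in range(n_households):
        n_plots = 1 + rng.poisson(max(mean_plots_per_hh - 1.0, 0.0))
        for _ in range(n_plots):
            area = float(np.clip(rng.lognormal(np.log(mean_plot_area_ha), 0.4),
                                 0.01, 1.0))
            npix = max(1, int(round(area / 0.01)))
            seed_px = None
            while cursor < len(free_idx):
                cand = free_idx[cursor]
                cursor += 1
                if free.ravel()[cand]:
                    seed_px = cand
                    break
            if seed_px is None:
                raise ValueError("cultivated mask too small for the requested survey")
            got = _claim(free, seed_px // nc, seed_px % nc, npix)
            r, c = seed_px // nc, seed_px % nc
            legume = float(rng.choice([0.0, 0.2, 0.3], p=[0.6, 0.25, 0.15]))
            plot_rows.append({
                "plot_id": pid, "household_id": hid, "row": r, "col": c,
                "area_ha": got * 0.01,
                "slope": float(landscape["slope"][r, c]),
                "clay": float(landscape["clay"][r, c]),
                "topo_position": int(1 + (elev[r, c] > terciles[0])
                                     + (elev[r, c] > terciles[1])),
                "cultivation_period": float(rng.integers(1, 30)),
                "swc_flag": bool(rng.random() < 0.2),
                "maize_fraction": round(0.9 - legume, 2),
                "legume_fraction": legume,
                "fallow_fraction": 0.0,
                "residue_retained_fraction": float(np.round(rng.beta(2, 2) * 0.6, 3)),
            })
            pid += 1
    plots = pd.DataFrame(plot_rows, columns=PLOT_COLUMNS)
    return households, plots, landscape


def _claim(free, r, c, npix):
    nr, nc = free.shape
    frontier = [(r, c)]
    taken = 0
    while frontier and taken < npix:
        rr, cc = frontier.pop(0)
        if not (0 <= rr < nr and 0 <= cc < nc) or not free[rr, cc]:
            continue
        free[rr, cc] = False
        taken += 1
        frontier.extend([(rr - 1, cc), (rr + 1, cc), (rr, cc - 1), (rr, cc + 1)])
    return max(taken, 1)


def _p(est, half):
    return Param(est, est - half, est + half)


def gen_behavioural_truth(seed=0, n: int = 2000):
    """Known-truth coefficient tables plus a simulated decision dataset.

    The tables drive the full simulator; the decision dataset (fertilizer
    practice) is drawn from the exact double-hurdle process — Bernoulli gate
    at logistic(b1'x), log-normal amounts exp(b2'x + eps) conditional on
    adoption — for parameter-recovery checks.

    Returns ``(tables, decisions)`` with decisions carrying columns const,
    subsidy, education, livestock, adopted, amount.
    """
    rng = _rng(seed)
    tables = {
        "adopt_fert": CoefficientTable("adopt_fert", {
            "const": _p(0.2, 0.3), "subsidy": _p(1.5, 0.5),
            "education": _p(0.05, 0.03), "livestock": _p(0.10, 0.05),
        }, link="logit", bounds=(0.0, 1.0)),
        "qty_fert": CoefficientTable("qty_fert", {
            "const": _p(4.0, 0.2), "subsidy": _p(0.5, 0.2),
            "education": _p(0.02, 0.01), "livestock": _p(0.03, 0.02),
        }, link="log", bounds=(0.0, 300.0)),
        "adopt_manure": CoefficientTable("adopt_manure", {
            "const": _p(-0.3, 0.3), "subsidy": _p(-1.0, 0.4),
            "livestock": _p(0.40, 0.10), "education": _p(0.02, 0.02),
        }, link="logit", bounds=(0.0, 1.0)),
        "qty_manure": CoefficientTable("qty_manure", {
            "const": _p(6.0, 0.3), "livestock": _p(0.15, 0.05),
        }, link="log", bounds=(0.0, 5000.0)),
        "adopt_legume": CoefficientTable("adopt_legume", {
            "const": _p(-0.7, 0.3), "subsidy": _p(0.8, 0.3),
            "education": _p(0.03, 0.02),
        }, link="logit", bounds=(0.0, 1.0)),
        "share_legume": CoefficientTable("share_legume", {
            "const": _p(-1.2, 0.3), "education": _p(0.02, 0.02),
        }, link="logit", bounds=(0.0, 1.0)),
        "adopt_swc": CoefficientTable("adopt_swc", {
            "const": _p(-2.5, 0.3), "slope": _p(0.05, 0.02),
        }, link="logit", bounds=(0.0, 1.0)),
        "yield_maize": CoefficientTable("yield_maize", {
            "const": _p(6.4, 0.2), "fert_kg_ha": _p(0.004, 0.001),
            "manure_kg_ha": _p(0.0002, 0.0001), "stock_n": _p(0.0004, 0.0002),
            "cultivation_period": _p(-0.012, 0.004),
            "farm_type2": _p(0.10, 0.08), "farm_type3": _p(0.25, 0.10),
        }, link="log", bounds=(0.0, 8000.0)),
        "yield_legume": CoefficientTable("yield_legume", {
            "const": _p(5.9, 0.2), "manure_kg_ha": _p(0.0002, 0.0001),
            "stock_n": _p(0.0003, 0.0002), "farm_type3": _p(0.15, 0.10),
        }, link="log", bounds=(0.0, 4000.0)),
    }

    # decision dataset from the exact fertilizer double-hurdle process
    X = pd.DataFrame({
        "const": 1.0,
        "subsidy": rng.uniform(0.0, 0.7, n),
        "education": np.clip(rng.normal(7.0, 3.0, n), 0, 16),
        "livestock": rng.gamma(1.5, 1.0, n),
    })
    b1 = tables["adopt_fert"].estimates()
    b2 = tables["qty_fert"].estimates()
    p = expit(X[b1.index].to_numpy() @ b1.to_numpy())
    adopted = rng.random(n) < p
    amount = np.where(
        adopted,
        np.exp(X[b2.index].to_numpy() @ b2.to_numpy() + rng.normal(0.0, 0.3, n)),
        0.0)
    decisions = X.assign(adopted=adopted, amount=amount, p_true=p)
    return tables, decisions


def write_input_dir(out_dir, nrows: int = 100, ncols: int = 100, seed: int = 0,
                    n_households: int = 250, config_overrides=None) -> Path:
    """Write a complete ready-to-run input directory (rasters, survey,
    coefficient tables, config.yaml) and return its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    landscape = gen_landscape(nrows, ncols, rng)
    households, plots, _ = gen_survey(n_households, seed=rng, landscape=landscape)
    tables, _ = gen_behavioural_truth(rng)
    for name, grid in landscape.items():
        write_ascii_grid(grid, out_dir / f"{name}.asc")
    write_survey(households, plots, out_dir)
    write_coefficients(tables, out_dir / "coefficients.csv")
    cfg = {"input_dir": str(out_dir), "output_dir": str(out_dir / "out"),
           "master_seed": int(seed)}
    cfg.update(config_overrides or {})
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh)
    return out_dir
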
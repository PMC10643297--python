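"""Environment-driven nutrient flows on the cultivated landscape.

This module computes the flows of the nutrient-monitoring ledger that the
environment drives: decomposition of organic inputs and soil organic matter
(IN2 / part of OUT5), biological nitrogen fixation (IN3), sediment
redistribution (OUT3 erosion and IN4 deposition), wet and dry atmospheric
deposition (IN5), leaching (OUT4), gaseous nitrogen losses (OUT5), and crop
removal in grain and residues (OUT1/OUT2) once yields are known.

The functional forms are the standard smallholder nutrient-monitoring
(NUTMON-family) transfer functions: deposition proportional to the square
root of annual rainfall, leaching and gaseous losses as bounded fractions
linear in rainfall and clay, and a multiplicative RUSLE-form erosion model
with an enrichment ratio for sediment nutrient content.  Every coefficient
lives in :class:`EcoCoefficients`, loaded from an editable CSV; the shipped
defaults produce realistic magnitudes (tens of kg ha-1 yr-1) for a Malawi
maize-mixed system but are placeholders that a site study should calibrate.

All amount arguments are kg ha-1 (soil loss in t ha-1) and may be scalars or
numpy arrays broadcast over plots or pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .core import FlowVector, SoilStock, PlotState, stock_to_concentration

__all__ = [
    "Param",
    "EcoCoefficients",
    "load_eco_coefficients",
    "atmospheric_deposition",
    "mineralisation",
    "biological_n_fixation",
    "soil_erosion",
    "erosion_nutrient_loss",
    "d8_routing",
    "sediment_deposition",
    "leaching_loss",
    "gaseous_loss",
    "crop_removal",
]


@dataclass(frozen=True)
class Param:
    """A named coefficient with its point estimate and interval bounds."""

    estimate: float
    lo: float
    hi: float
    units: str = ""

    def __post_init__(self):
        if not (self.lo <= self.estimate <= self.hi):
            raise ValueError("require lo <= estimate <= hi")


class EcoCoefficients:
    """Named ecological coefficients with (estimate, lo, hi) bounds.

    Attribute access returns the *current* value of a coefficient: the point
    estimate, or the realised draw after :meth:`realise` has been called for
    a stochastic replication.
    """

    def __init__(self, params: Mapping[str, Param]):
        self._params = dict(params)
        self._values = {k: p.estimate for k, p in self._params.items()}

    def __getattr__(self, name: str) -> float:
        values = object.__getattribute__(self, "_values")
        if name in values:
            return values[name]
        raise AttributeError(f"no ecological coefficient named {name!r}")

    def __contains__(self, name: str) -> bool:
        return name in self._params

    @property
    def params(self) -> Mapping[str, Param]:
        return dict(self._params)

    def param(self, name: str) -> Param:
        return self._params[name]

    def realise(self, rng: np.random.Generator, how: str = "truncnorm") -> "EcoCoefficients":
        """Return a copy with every coefficient drawn within its bounds.

        ``truncnorm`` draws Normal(estimate, (hi-lo)/(2*1.96)) truncated to
        [lo, hi]; ``uniform`` draws uniformly on [lo, hi].  Degenerate bounds
        (lo == hi) return the estimate.
        """
        from .behaviour import draw_within_bounds  # shared draw rule
        out = EcoCoefficients(self._params)
        for name, p in self._params.items():
            out._values[name] = draw_within_bounds(p.estimate, p.lo, p.hi, rng, how)
        return out

    def with_values(self, **overrides: float) -> "EcoCoefficients":
        out = EcoCoefficients(self._params)
        out._values = dict(self._values)
        for k, v in overrides.items():
            if k not in out._values:
                raise KeyError(f"no ecological coefficient named {k!r}")
            out._values[k] = v
        return out

    def zeroed(self) -> "EcoCoefficients":
        """All-zero coefficients with degenerate bounds (null model: the
        environment does nothing, even under stochastic realisation)."""
        return EcoCoefficients({k: Param(0.0, 0.0, 0.0) for k in self._params})


def load_eco_coefficients(path=None) -> EcoCoefficients:
    """Load coefficients from CSV (columns name, estimate, lo, hi, units);
    with no path, the shipped defaults."""
    if path is None:
        with resources.files("massai.data").joinpath("eco_defaults.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    required = {"name", "estimate", "lo", "hi"}
    if not required.issubset(df.columns):
        raise ValueError(f"coefficient CSV must have columns {sorted(required)}")
    params = {}
    for rec in df.itertuples(index=False):
        params[rec.name] = Param(float(rec.estimate), float(rec.lo), float(rec.hi),
                                 getattr(rec, "units", "") or "")
    return EcoCoefficients(params)


def _asarr(x):
    return np.asarray(x, dtype=float)


def atmospheric_deposition(rain_mm, coeffs: EcoCoefficients) -> FlowVector:
    """Wet + dry deposition from rain and wind: X = a_X * sqrt(rain)."""
    rain = _asarr(rain_mm)
    if np.any(rain < 0):
        raise ValueError("rainfall must be >= 0")
    root = np.sqrt(rain)
    return FlowVector("IN5",
                      n=coeffs.dep_a_n * root,
                      p=coeffs.dep_a_p * root,
                      k=coeffs.dep_a_k * root)


def mineralisation(manure_kg_ha, residue_kg_ha, soc, coeffs: EcoCoefficients):
    """Decomposition of manure, retained residues and soil organic matter.

    Returns ``(FlowVector IN2, soc_loss_c)``: the nutrients released by the
    organic additions (first-year availability fractions) plus the humified
    carbon they add to SOC, and the carbon lost by first-order SOM decay
    (k_soc * SOC), which the caller routes to the gaseous-loss pathway.
    """
    if isinstance(soc, SoilStock):
        soc = soc.soc
    manure = _asarr(manure_kg_ha)
    residue = _asarr(residue_kg_ha)
    soc = _asarr(soc)
    if np.any(manure < 0) or np.any(residue < 0):
        raise ValueError("organic input amounts must be >= 0")
    n = (manure * coeffs.manure_n + residue * coeffs.residue_n) * coeffs.avail_n
    p = (manure * coeffs.manure_p + residue * coeffs.residue_p) * coeffs.avail_p
    k = (manure * coeffs.manure_k + residue * coeffs.residue_k) * coeffs.avail_k
    c = coeffs.humification * (manure * coeffs.manure_c + residue * coeffs.residue_c)
    soc_loss_c = coeffs.k_soc * soc
    return FlowVector("IN2", n=n, p=p, k=k, c=c), soc_loss_c


def biological_n_fixation(legume_biomass_kg_ha, coeffs: EcoCoefficients) -> FlowVector:
    """N fixed by legumes: ndfa * biomass * legume N content."""
    biomass = _asarr(legume_biomass_kg_ha)
    if np.any(biomass < 0):
        raise ValueError("legume biomass must be >= 0")
    return FlowVector("IN3", n=coeffs.ndfa * biomass * coeffs.legume_n_content)


def _ls_factor(slope_pct, coeffs: EcoCoefficients):
    return coeffs.ls_a + coeffs.ls_b * np.power(_asarr(slope_pct), coeffs.ls_exp)


def soil_erosion(plot, coeffs: EcoCoefficients, swc_flag=None):
    """RUSLE-form annual soil loss R*K*LS(slope)*C*P in t ha-1.

    ``plot`` is a :class:`~massai.core.PlotState` or a slope array (percent);
    in the latter case ``swc_flag`` gives the conservation-structure flags.
    The support-practice factor drops below one when SWC structures exist.
    """
    if isinstance(plot, PlotState):
        slope, swc = plot.slope, plot.swc_flag
    else:
        slope = plot
        swc = False if swc_flag is None else swc_flag
    slope = _asarr(slope)
    if np.any(slope < 0):
        raise ValueError("slope must be >= 0")
    p_factor = np.where(np.asarray(swc, dtype=bool),
                        coeffs.swc_practice_p, coeffs.practice_p)
    loss = coeffs.rusle_r * coeffs.rusle_k * _ls_factor(slope, coeffs) \
        * coeffs.cover_c * p_factor
    return float(loss) if loss.ndim == 0 else loss


def erosion_nutrient_loss(soil_loss_t_ha, stock, coeffs: EcoCoefficients) -> FlowVector:
    """Nutrients carried by eroded soil: loss * concentration * enrichment.

    ``stock`` is a SoilStock, or a mapping of nutrient -> stock array with
    keys n, p, k, c (plus rho, cf, depth arrays for the conversion).
    Concentration is the fine-earth concentration of the managed layer
    (mg kg-1 == g t-1, hence the 1e-3 to kg t-1).
    """
    loss = _asarr(soil_loss_t_ha)
    if np.any(loss < 0):
        raise ValueError("soil loss must be >= 0")
    if isinstance(stock, SoilStock):
        pools = {"n": stock.n, "p": stock.p, "k": stock.k, "c": stock.soc}
        rho, cf, depth = stock.rho, stock.cf, stock.depth
    else:
        pools = {nut: stock[nut] for nut in ("n", "p", "k", "c")}
        rho, cf, depth = stock.get("rho", 1.3), stock.get("cf", 0.0), stock.get("depth", 0.10)
    er = {"n": coeffs.er_n, "p": coeffs.er_p, "k": coeffs.er_k, "c": coeffs.er_c}
    comp = {}
    for nut, pool in pools.items():
        conc = stock_to_concentration(pool, rho, cf, depth)  # mg kg-1 = g t-1
        comp[nut] = loss * conc * 1e-3 * er[nut]
    return FlowVector("OUT3", **comp)


def d8_routing(elevation: np.ndarray) -> np.ndarray:
    """Single-direction steepest-descent routing over a grid.

    Returns a flat int array ``flow_to`` with, for each pixel, the flattened
    index of its lowest strictly-lower 8-neighbour, or -1 where the pixel is
    a pit or flat (no receiver).  Strict descent makes the graph acyclic by
    construction; ties break on the lowest neighbour index.
    """
    elev = np.asarray(elevation, dtype=float)
    if elev.ndim != 2:
        raise ValueError("elevation must be a 2-D grid")
    nr, nc = elev.shape
    flow = np.full(nr * nc, -1, dtype=np.int64)
    best_drop = np.zeros(nr * nc)
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    for dr, dc in offsets:
        # neighbour grid shifted by (dr, dc); out-of-bounds masked off
        r0, r1 = max(0, -dr), nr - max(0, dr)
        c0, c1 = max(0, -dc), nc - max(0, dc)
        src = np.zeros((nr, nc), dtype=bool)
        src[r0:r1, c0:c1] = True
        src_idx = np.flatnonzero(src)
        nb_idx = src_idx + dr * nc + dc
        drop = elev.ravel()[src_idx] - elev.ravel()[nb_idx]
        better = drop > best_drop[src_idx] + 1e-12
        tie = np.isclose(drop, best_drop[src_idx]) & (drop > 0) \
            & ((flow[src_idx] == -1) | (nb_idx < flow[src_idx]))
        take = better | tie
        upd = src_idx[take]
        flow[upd] = nb_idx[take]
        best_drop[upd] = drop[take]
    return flow


def _check_acyclic(flow_to: np.ndarray) -> None:
    n = flow_to.size
    colour = np.zeros(n, dtype=np.int8)  # 0 unseen, 1 on path, 2 done
    for start in range(n):
        if colour[start]:
            continue
        path = []
        v = start
        while v != -1 and colour[v] == 0:
            colour[v] = 1
            path.append(v)
            v = int(flow_to[v])
        if v != -1 and colour[v] == 1:
            raise ValueError("routing graph contains a cycle")
        for u in path:
            colour[u] = 2


def sediment_deposition(soil_loss, nutrient_loss: Mapping[str, np.ndarray],
                        flow_to: np.ndarray, coeffs: EcoCoefficients,
                        check: bool = True):
    """Deliver a fraction of eroded soil and nutrients one step downslope.

    Each pixel receives ``sdr`` times the soil (and attached nutrients) eroded
    from pixels routing into it; soil routed off-grid or to a pit is exported
    from the landscape.  Returns ``(soil_deposit, FlowVector IN4)``, both flat
    arrays aligned with ``flow_to``.  Because 0 <= sdr <= 1 and each donor
    routes to at most one receiver, total deposition never exceeds total
    erosion.
    """
    soil_loss = _asarr(soil_loss).ravel()
    flow_to = np.asarray(flow_to)
    if flow_to.shape != soil_loss.shape:
        raise ValueError("flow_to and soil_loss must align")
    if check:
        _check_acyclic(flow_to)
    d = coeffs.sdr
    if not (0 <= d <= 1):
        raise ValueError("sediment delivery ratio must be in [0, 1]")
    has_rx = flow_to >= 0
    soil_dep = np.zeros_like(soil_loss)
    np.add.at(soil_dep, flow_to[has_rx], d * soil_loss[has_rx])
    comp = {}
    for nut in ("n", "p", "k", "c"):
        loss = _asarr(nutrient_loss.get(nut, 0.0))
        loss = np.broadcast_to(loss, soil_loss.shape).ravel()
        dep = np.zeros_like(soil_loss)
        np.add.at(dep, flow_to[has_rx], d * loss[has_rx])
        comp[nut] = dep
    return soil_dep, FlowVector("IN4", **comp)


def _leach_fraction(rain_mm, clay_pct, coeffs: EcoCoefficients):
    rain = _asarr(rain_mm)
    clay = _asarr(clay_pct)
    f = coeffs.leach_rain * (rain / 1000.0) * (1.0 - coeffs.leach_clay * clay / 100.0)
    return np.clip(f, 0.0, 1.0)


def leaching_loss(rain_mm, clay_pct, stock_n, stock_k, fert_n,
                  coeffs: EcoCoefficients) -> FlowVector:
    """Leaching of N and K below the managed layer.

    A bounded fraction f(rain, clay) — increasing in rainfall, decreasing in
    clay — applied to the leachable pools: for N the mineral share of the
    soil pool plus current-year mineral fertilizer N, for K the exchangeable
    share of the soil pool (damped by ``leach_k_factor``).
    """
    f = _leach_fraction(rain_mm, clay_pct, coeffs)
    n_base = coeffs.mineral_n_frac * _asarr(stock_n) + _asarr(fert_n)
    k_base = coeffs.mineral_k_frac * _asarr(stock_k)
    return FlowVector("OUT4", n=f * n_base, k=coeffs.leach_k_factor * f * k_base)


def gaseous_loss(fert_n, mineralised_n, rain_mm, coeffs: EcoCoefficients,
                 soc_loss_c=0.0) -> FlowVector:
    """Denitrification + volatilisation of N, plus SOM-degradation carbon.

    The N component is a bounded fraction (base + rainfall term, clipped to
    [0, 1]) of current-year mineral N inputs (fertilizer plus mineralised
    organic N); the C component is the SOM decay computed by
    :func:`mineralisation` and routed here by the caller.
    """
    g = np.clip(coeffs.gas_base + coeffs.gas_rain * _asarr(rain_mm) / 1000.0, 0.0, 1.0)
    n = g * (_asarr(fert_n) + _asarr(mineralised_n))
    return FlowVector("OUT5", n=n, c=_asarr(soc_loss_c))


def crop_removal(yields: Mapping[str, np.ndarray], residue_retained_fraction,
                 coeffs: EcoCoefficients):
    """Nutrient removal in harvested grain (OUT1) and exported residue (OUT2).

    ``yields`` maps crop name ("maize", "legume") to grain yield kg ha-1.
    Residue biomass is yield * (1/HI - 1); the retained fraction stays on the
    plot and is returned for next year's mineralisation, the rest leaves with
    its nutrients.  Returns ``(OUT1, OUT2, retained_residue_kg_ha)``.
    """
    retain = np.clip(_asarr(residue_retained_fraction), 0.0, 1.0)
    grain = {nut: 0.0 for nut in ("n", "p", "k")}
    residue_biomass = 0.0
    for crop, y in yields.items():
        y = _asarr(y)
        if np.any(y < 0):
            raise ValueError("yield must be >= 0")
        hi = getattr(coeffs, f"hi_{crop}")
        residue_biomass = residue_biomass + (y * (1.0 / hi - 1.0) if hi > 0 else 0.0)
        for nut in grain:
            grain[nut] = grain[nut] + y * getattr(coeffs, f"{crop}_grain_{nut}")
    out1 = FlowVector("OUT1", **grain)
    removed = residue_biomass * (1.0 - retain)
    out2 = FlowVector("OUT2",
                      n=removed * coeffs.residue_n,
                      p=removed * coeffs.residue_p,
                      k=removed * coeffs.residue_k)
    retained = residue_biomass * retain
    return out1, out2, retained
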
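"""Shared domain types, unit conversions and the annual mass-balance update.

The simulator keeps every nutrient ledger in kg per hectare within the managed
soil layer (0-10 cm by default, the hand-hoed ridge layer).  Bulk density,
coarse-fragment fraction and layer depth therefore enter only at the boundary,
when concentration rasters (mg per kg fine earth) are converted to stocks and
back; the annual update itself is a plain sum of inputs minus outputs, which
makes mass conservation exactly testable.

Nutrient bookkeeping conventions:

* phosphorus and potassium are tracked as elemental P and K everywhere inside
  the model; the oxide forms P2O5 / K2O appear only at the fertilizer-product
  interface (bag grades are quoted as N-P2O5-K2O);
* each flow pathway carries only the nutrients of its class (e.g. inorganic
  fertilizer carries N and P, leaching carries N and K, gaseous losses carry
  N and C) — violating components are rejected at construction time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Union

import numpy as np

__all__ = [
    "NUTRIENTS",
    "PATHWAY_NUTRIENTS",
    "IN_PATHWAYS",
    "OUT_PATHWAYS",
    "P2O5_TO_P",
    "K2O_TO_K",
    "FlowVector",
    "SoilStock",
    "PlotState",
    "HouseholdState",
    "FertilizerProduct",
    "FERTILIZER_PRODUCTS",
    "StockUpdate",
    "concentration_to_stock",
    "stock_to_concentration",
    "update_soil_stock",
    "product_to_nutrients",
]

#: nutrient keys used on every ledger: nitrogen, phosphorus, potassium, carbon
NUTRIENTS = ("n", "p", "k", "c")

#: nutrients carried by each flow pathway
PATHWAY_NUTRIENTS: Mapping[str, frozenset] = {
    "IN1": frozenset({"n", "p"}),            # inorganic fertilizer
    "IN2": frozenset({"n", "p", "k", "c"}),  # manure / residue / SOM decomposition
    "IN3": frozenset({"n"}),                 # biological N fixation
    "IN4": frozenset({"n", "p", "k", "c"}),  # sediment deposition
    "IN5": frozenset({"n", "p", "k"}),       # atmospheric deposition
    "OUT1": frozenset({"n", "p", "k"}),      # harvested grain
    "OUT2": frozenset({"n", "p", "k"}),      # removed residues
    "OUT3": frozenset({"n", "p", "k", "c"}), # erosion
    "OUT4": frozenset({"n", "k"}),           # leaching
    "OUT5": frozenset({"n", "c"}),           # gaseous N + SOM-degradation C
}

IN_PATHWAYS = tuple(p for p in PATHWAY_NUTRIENTS if p.startswith("IN"))
OUT_PATHWAYS = tuple(p for p in PATHWAY_NUTRIENTS if p.startswith("OUT"))

#: elemental mass fraction of P in P2O5 and K in K2O
P2O5_TO_P = 0.436
K2O_TO_K = 0.830

Component = Union[float, np.ndarray]


def _nonneg(name: str, value: Component) -> None:
    if np.any(np.asarray(value) < 0):
        raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class FlowVector:
    """One year's nutrient amounts (kg ha-1 yr-1) for one flow pathway.

    Components may be scalars or numpy arrays (one entry per plot/pixel);
    nutrients a pathway does not carry must be zero.
    """

    pathway: str
    n: Component = 0.0
    p: Component = 0.0
    k: Component = 0.0
    c: Component = 0.0

    def __post_init__(self):
        if self.pathway not in PATHWAY_NUTRIENTS:
            raise ValueError(
                f"unknown pathway {self.pathway!r}; expected one of "
                f"{sorted(PATHWAY_NUTRIENTS)}"
            )
        allowed = PATHWAY_NUTRIENTS[self.pathway]
        for nut in NUTRIENTS:
            val = getattr(self, nut)
            _nonneg(f"{self.pathway}.{nut}", val)
            if nut not in allowed and np.any(np.asarray(val) != 0):
                raise ValueError(
                    f"pathway {self.pathway} does not carry nutrient "
                    f"{nut.upper()}"
                )

    def totals(self) -> dict:
        """Sum of each component (collapses array-valued flows)."""
        return {nut: float(np.sum(getattr(self, nut))) for nut in NUTRIENTS}


@dataclass(frozen=True)
class SoilStock:
    """Per-plot (or per-pixel) NPK + SOC pools in the managed soil layer.

    Parameters
    ----------
    n, p, k, soc : float
        Nutrient pools, kg ha-1 within the managed layer.
    rho : float
        Bulk density, t m-3.
    cf : float
        Coarse-fragment volumetric fraction in [0, 1).
    depth : float
        Managed layer thickness in m.  Defaults to 0.10 m, the depth of the
        annually re-made planting ridges where fertilizer and manure are
        placed.
    """

    n: float
    p: float
    k: float
    soc: float
    rho: float = 1.3
    cf: float = 0.0
    depth: float = 0.10

    def __post_init__(self):
        for pool in ("n", "p", "k", "soc"):
            _nonneg(pool, getattr(self, pool))
        if not self.rho > 0:
            raise ValueError("bulk density rho must be > 0")
        if not (0 <= self.cf < 1):
            raise ValueError("coarse-fragment fraction cf must be in [0, 1)")
        if not self.depth > 0:
            raise ValueError("depth must be > 0")

    def pool(self, nutrient: str) -> float:
        return getattr(self, "soc" if nutrient == "c" else nutrient)


@dataclass
class PlotState:
    """A cultivated plot: raster footprint, terrain, management and soil."""

    plot_id: int
    household_id: int
    row: int
    col: int
    area_ha: float
    slope: float                 # percent rise
    clay: float                  # percent
    topo_position: int = 1       # ordinal: 1 valley .. higher = upslope
    cultivation_period: float = 0.0
    swc_flag: bool = False
    maize_fraction: float = 1.0
    legume_fraction: float = 0.0
    fallow_fraction: float = 0.0
    residue_retained_fraction: float = 0.0
    stock: SoilStock | None = None

    def __post_init__(self):
        if not self.area_ha > 0:
            raise ValueError("area_ha must be > 0")
        if self.cultivation_period < 0:
            raise ValueError("cultivation_period must be >= 0")
        for frac in ("maize_fraction", "legume_fraction", "fallow_fraction",
                     "residue_retained_fraction"):
            v = getattr(self, frac)
            if not (0 <= v <= 1):
                raise ValueError(f"{frac} must be in [0, 1]")
        if self.maize_fraction + self.legume_fraction + self.fallow_fraction > 1 + 1e-9:
            raise ValueError("crop allocation fractions must sum to <= 1")


@dataclass
class HouseholdState:
    """A farming household: typology, demographics and endowments."""

    household_id: int
    farm_type: int               # 1 low, 2 medium, 3 high input intensity
    head_age: float
    head_gender: int             # 1 male head, 0 female head
    education: float             # years of schooling of the head
    labour: float                # adult equivalents
    income: float                # currency per year
    livestock: float             # tropical livestock units
    group_membership: bool = False
    transport_access: bool = False
    communication_access: bool = False
    sampled: bool = True

    def __post_init__(self):
        if self.farm_type not in (1, 2, 3):
            raise ValueError("farm_type must be 1, 2 or 3")
        if not self.head_age > 0:
            raise ValueError("head_age must be > 0")


@dataclass(frozen=True)
class FertilizerProduct:
    """A fertilizer grade: mass fractions of N, P2O5 and K2O in the product."""

    name: str
    n_frac: float
    p2o5_frac: float
    k2o_frac: float

    def __post_init__(self):
        fracs = (self.n_frac, self.p2o5_frac, self.k2o_frac)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError("mass fractions must be in [0, 1]")
        if sum(fracs) > 1:
            raise ValueError("mass fractions must sum to <= 1")


#: default grades used in the Malawi maize system (bag label N-P2O5-K2O)
FERTILIZER_PRODUCTS: Mapping[str, FertilizerProduct] = {
    "urea": FertilizerProduct("urea", 0.46, 0.0, 0.0),
    "DAP": FertilizerProduct("DAP", 0.18, 0.46, 0.0),
    "NPK": FertilizerProduct("NPK", 0.23, 0.21, 0.0),
    "CAN": FertilizerProduct("CAN", 0.27, 0.0, 0.0),
    # equal-parts basal NPK + urea top dressing, the usual subsidy package
    "blend": FertilizerProduct("blend", 0.345, 0.105, 0.0),
}


def concentration_to_stock(conc, rho, cf, depth) -> Component:
    """Convert a fine-earth concentration (mg kg-1) to a stock (kg ha-1).

    stock = conc * rho * depth * (1 - cf) * 10

    with rho in t m-3 and depth in m; the factor 10 carries the units
    (mg kg-1) * (t m-3) * m over one hectare into kg ha-1.
    """
    conc = np.asarray(conc, dtype=float)
    _nonneg("concentration", conc)
    if not np.all(np.asarray(rho) > 0):
        raise ValueError("rho must be > 0")
    if not np.all(np.asarray(depth) > 0):
        raise ValueError("depth must be > 0")
    cf_a = np.asarray(cf)
    if np.any(cf_a < 0) or np.any(cf_a >= 1):
        raise ValueError("cf must be in [0, 1)")
    out = conc * np.asarray(rho) * np.asarray(depth) * (1.0 - cf_a) * 10.0
    return float(out) if out.ndim == 0 else out


def stock_to_concentration(stock, rho, cf, depth) -> Component:
    """Inverse of :func:`concentration_to_stock` (kg ha-1 -> mg kg-1)."""
    stock = np.asarray(stock, dtype=float)
    _nonneg("stock", stock)
    out = stock / (np.asarray(rho) * np.asarray(depth) * (1.0 - np.asarray(cf)) * 10.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class StockUpdate:
    """Result of the annual stock update: new stock plus the clipped deficit
    per nutrient (amount by which an outflow exceeded the available pool and
    was therefore not realised)."""

    stock: SoilStock
    clipped: Mapping[str, float]


def update_soil_stock(stock: SoilStock,
                      inflows: Iterable[FlowVector],
                      outflows: Iterable[FlowVector]) -> StockUpdate:
    """Apply one year's mass balance: X_{t+1} = X_t + sum(IN) - sum(OUT).

    Pools are floored at zero; the clipped deficit (the positive magnitude of
    the outflow that could not be realised) is returned so that the exact
    conservation identity

        X_{t+1} - X_t - clipped = sum(IN) - sum(OUT)

    holds for each of N, P, K and SOC.
    """
    inflows = list(inflows)
    outflows = list(outflows)
    for fv in inflows:
        if fv.pathway not in IN_PATHWAYS:
            raise ValueError(f"{fv.pathway} is not an input pathway")
    for fv in outflows:
        if fv.pathway not in OUT_PATHWAYS:
            raise ValueError(f"{fv.pathway} is not an output pathway")

    new_pools = {}
    clipped = {}
    for nut in NUTRIENTS:
        pool = stock.pool(nut)
        balance = sum(float(np.sum(getattr(fv, nut))) for fv in inflows) \
            - sum(float(np.sum(getattr(fv, nut))) for fv in outflows)
        raw = pool + balance
        clipped[nut] = max(0.0, -raw)
        new_pools[nut] = max(0.0, raw)
    new = replace(stock, n=new_pools["n"], p=new_pools["p"], k=new_pools["k"],
                  soc=new_pools["c"])
    return StockUpdate(stock=new, clipped=clipped)


def product_to_nutrients(amount: float,
                         product: Union[str, FertilizerProduct]) -> FlowVector:
    """Convert a fertilizer-product application (kg ha-1) to elemental
    nutrients on the inorganic-fertilizer pathway (IN1).

    N comes straight from the bag N fraction; P2O5 and K2O are converted to
    elemental P (x 0.436) and K (x 0.830).  IN1 carries N and P only, so any
    K in the grade is dropped from the soil ledger (and the default grades
    carry essentially none).
    """
    if isinstance(product, str):
        try:
            product = FERTILIZER_PRODUCTS[product]
        except KeyError:
            raise KeyError(
                f"unknown fertilizer product {product!r}; known grades: "
                f"{sorted(FERTILIZER_PRODUCTS)}"
            ) from None
    if np.any(np.asarray(amount) < 0):
        raise ValueError("amount must be >= 0")
    amount = np.asarray(amount, dtype=float)
    n = amount * product.n_frac
    p = amount * product.p2o5_frac * P2O5_TO_P
    scalar = amount.ndim == 0
    if scalar:
        return FlowVector("IN1", n=float(n), p=float(p))
    return FlowVector("IN1", n=n, p=p)
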
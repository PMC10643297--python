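"""Simulation orchestration: initialise -> simulate -> output.

The engine ties the pieces together.  ``initialise`` loads rasters and
survey tables, converts concentration maps to per-plot stocks, synthesises
the unsampled population when upscaling is requested, claims plot footprints
on the cultivated mask and derives the sediment routing graph.  ``step_year``
advances one growing calendar year through a fixed phase order:

1. progressive update of ageing variables;
2. behavioural decisions per plot (legume -> fertilizer -> manure -> SWC);
3. environment-driven flows (deposition, mineralisation, erosion and its
   downslope delivery, leaching, gaseous losses);
4. crop-yield prediction;
5. nutrient removal in grain and exported residue;
6. the annual mass-balance stock update (floored at zero, deficit logged);
7. recording.

``run_experiment`` runs replications x scenarios.  Each (scenario,
replication) pair owns an independent random generator derived from the
master seed, and coefficient draws happen once per replication, so a single
run's results are bit-identical regardless of which other scenarios are in
the batch.
"""

from __future__ import annotations

import copy
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behaviour, ecology, population, scenario as scenario_mod
from .core import concentration_to_stock, product_to_nutrients, NUTRIENTS
from .io import SimulationConfig, config_hash, read_survey, read_coefficients, read_raster

__all__ = ["World", "SimulationOutput", "initialise", "build_world",
           "step_year", "run_experiment", "run_seed"]

log = logging.getLogger("massai")

#: recorded per-plot mean variables
RECORD_VARIABLES = ("fert_kg_ha", "manure_kg_ha", "maize_yield", "legume_yield",
                    "balance_n", "balance_p", "balance_k", "balance_c",
                    "stock_n", "stock_p", "stock_k", "stock_c")

RASTER_NAMES = ("elevation", "conc_n", "conc_p", "conc_k", "conc_soc",
                "bulk_density", "coarse_frag", "clay", "cultivated")


@dataclass
class World:
    """Initialised simulation state: landscape, agents, models, routing."""

    config: SimulationConfig
    landscape: dict                 # name -> 2-D array
    households: pd.DataFrame
    plots: pd.DataFrame             # includes stock_*, rho, cf columns
    tables: dict                    # behavioural CoefficientTable by model name
    eco: ecology.EcoCoefficients
    flow_to: np.ndarray             # flat D8 receiver index per pixel, -1 none
    owner: np.ndarray               # flat plot index per pixel, -1 unmanaged
    retained_residue: np.ndarray = None  # kg ha-1 carried into next year

    def __post_init__(self):
        if self.retained_residue is None:
            self.retained_residue = np.zeros(len(self.plots))

    def snapshot(self) -> "World":
        """Deep copy of the mutable state for one independent run."""
        return World(self.config, self.landscape,
                     self.households.copy(), self.plots.copy(),
                     self.tables, self.eco, self.flow_to, self.owner,
                     self.retained_residue.copy())

    def summary(self) -> dict:
        return {
            "n_households": int(len(self.households)),
            "n_plots": int(len(self.plots)),
            "cultivated_pixels": int(np.nansum(self.landscape["cultivated"])),
            "mean_stock_n": float(self.plots["stock_n"].mean()),
            "mean_stock_p": float(self.plots["stock_p"].mean()),
            "mean_stock_k": float(self.plots["stock_k"].mean()),
            "mean_stock_c": float(self.plots["stock_c"].mean()),
            "config_hash": config_hash(self.config),
        }


@dataclass
class SimulationOutput:
    """Long-format results plus provenance.

    ``records`` has one row per (scenario, replication, year, farm_type,
    variable) with the over-plot mean; farm_type "all" aggregates the whole
    population.  ``detail`` (optional) carries per-plot-year flows, balances
    and clipped deficits for conservation auditing.
    """

    records: pd.DataFrame
    detail: pd.DataFrame | None
    master_seed: int
    config_hash: str


def run_seed(master_seed: int, scenario_name: str, replication: int) -> np.random.SeedSequence:
    """Independent seed stream for one (scenario, replication) run."""
    h = int.from_bytes(hashlib.sha256(scenario_name.encode()).digest()[:4], "big")
    return np.random.SeedSequence([int(master_seed), h % (2 ** 31), int(replication)])


def _sample_raster(grid, rows, cols, default=np.nan):
    vals = np.asarray(grid)[rows, cols].astype(float)
    return np.where(np.isnan(vals), default, vals)


def build_world(config: SimulationConfig, landscape: dict,
                households: pd.DataFrame, plots: pd.DataFrame,
                tables: dict, eco: ecology.EcoCoefficients | None = None) -> World:
    """Assemble a World from in-memory inputs.

    Handles population upscaling (when ``config.upscale_target_plots`` is
    set), stock initialisation from the concentration rasters, footprint
    claiming and routing.  Deterministic given (config, inputs).
    """
    eco = eco or ecology.load_eco_coefficients()
    missing = [n for n in RASTER_NAMES if n not in landscape]
    if missing:
        raise ValueError(f"landscape is missing raster(s) {missing}")
    mask = np.nan_to_num(np.asarray(landscape["cultivated"], dtype=float)) > 0.5

    rng = np.random.default_rng(np.random.SeedSequence([config.master_seed, 0xB00F]))
    households = households.copy()
    plots = plots.copy()
    if config.upscale_target_plots and config.upscale_target_plots > len(plots):
        factor = config.upscale_target_plots / len(plots)
        target_hh = int(round(len(households) * factor))
        households = population.synthesize_households(households, target_hh, rng)
        plots = population.assign_plots(households, plots, mask, rng)

    nr, nc = mask.shape
    rows = plots["row"].to_numpy(dtype=int)
    cols = plots["col"].to_numpy(dtype=int)
    if (rows < 0).any() or (rows >= nr).any() or (cols < 0).any() or (cols >= nc).any():
        raise ValueError("plot pixel coordinates fall outside the landscape")

    rho = _sample_raster(landscape["bulk_density"], rows, cols, 1.3)
    cf = np.clip(_sample_raster(landscape["coarse_frag"], rows, cols, 0.0), 0.0, 0.999)
    plots["rho"] = rho
    plots["cf"] = cf
    for nut, name in (("n", "conc_n"), ("p", "conc_p"), ("k", "conc_k"),
                      ("c", "conc_soc")):
        conc = _sample_raster(landscape[name], rows, cols, 0.0)
        plots[f"stock_{nut}"] = concentration_to_stock(conc, rho, cf, config.depth)
    plots["slope"] = _sample_raster(
        landscape.get("slope", _derived_slope(landscape["elevation"])),
        rows, cols, plots["slope"].to_numpy(dtype=float))
    plots["clay"] = _sample_raster(landscape["clay"], rows, cols,
                                   plots["clay"].to_numpy(dtype=float))

    owner = _claim_footprints(plots, mask)
    flow_to = ecology.d8_routing(landscape["elevation"])
    return World(config, landscape, households, plots.reset_index(drop=True),
                 tables, eco, flow_to, owner)


def _derived_slope(elevation, cellsize=10.0):
    gy, gx = np.gradient(np.asarray(elevation, dtype=float), cellsize)
    return 100.0 * np.hypot(gx, gy)


def _claim_footprints(plots: pd.DataFrame, mask: np.ndarray) -> np.ndarray:
    """Deterministically grow each plot's contiguous pixel footprint from its
    seed pixel over the cultivated mask; returns flat owner indices."""
    free = mask.copy()
    nr, nc = mask.shape
    owner = np.full(nr * nc, -1, dtype=np.int64)
    for i, rec in enumerate(plots.itertuples(index=False)):
        npix = max(1, int(round(rec.area_ha / 0.01)))
        r, c = int(rec.row), int(rec.col)
        frontier = [(r, c)]
        taken = 0
        while frontier and taken < npix:
            rr, cc = frontier.pop(0)
            if not (0 <= rr < nr and 0 <= cc < nc) or not free[rr, cc]:
                continue
            free[rr, cc] = False
            owner[rr * nc + cc] = i
            taken += 1
            frontier.extend([(rr - 1, cc), (rr + 1, cc), (rr, cc - 1), (rr, cc + 1)])
        if taken == 0:
            # surveyed seed pixel may sit just off the mask: claim it anyway
            rr = min(max(r, 0), nr - 1)
            cc = min(max(c, 0), nc - 1)
            owner[rr * nc + cc] = i
    return owner


def initialise(config: SimulationConfig) -> World:
    """Load every input named by the config and build the World."""
    d = Path(config.input_dir)
    landscape = {}
    for name in RASTER_NAMES + ("slope",):
        found = None
        for ext in (".asc", ".tif", ".tiff"):
            if (d / f"{name}{ext}").exists():
                found = d / f"{name}{ext}"
                break
        if found is None:
            if name == "slope":
                continue  # derived from elevation
            raise FileNotFoundError(f"missing required raster {d / (name + '.asc')}")
        landscape[name], _ = read_raster(found)
    households, plots = read_survey(d)
    tables = read_coefficients(d / "coefficients.csv")
    eco_path = d / "eco_coefficients.csv"
    eco = ecology.load_eco_coefficients(eco_path if eco_path.exists() else None)
    world = build_world(config, landscape, households, plots, tables, eco)
    log.info("initialised world: %s", world.summary())
    return world


def step_year(world: World, year: int, s_t: float, rng: np.random.Generator,
              realised: dict, eco: ecology.EcoCoefficients) -> dict:
    """Advance one growing calendar year; returns per-plot flow ledgers."""
    cfg = world.config
    plots = world.plots
    n_plots = len(plots)

    # 1. progressive update
    if year > 0:
        scenario_mod.progressive_update(world.households, plots,
                                        enabled=cfg.progressive)

    # 2. behavioural decisions
    decisions = behaviour.decide_all(world.households, plots, s_t,
                                     world.tables, rng, realised)
    plots["swc_flag"] = decisions["swc_flag"]

    stock = {nut: plots[f"stock_{nut}"].to_numpy(dtype=float) for nut in NUTRIENTS}
    ins = {nut: np.zeros(n_plots) for nut in NUTRIENTS}
    outs = {nut: np.zeros(n_plots) for nut in NUTRIENTS}

    def add(acc, fv):
        for nut in NUTRIENTS:
            acc[nut] += np.broadcast_to(np.asarray(getattr(fv, nut), dtype=float),
                                        (n_plots,))

    # 3a. fertilizer nutrients (IN1)
    in1 = product_to_nutrients(decisions["fert_kg_ha"].to_numpy(), "blend")
    add(ins, in1)

    # 3b. atmospheric deposition (IN5)
    add(ins, ecology.atmospheric_deposition(cfg.rain_mm, eco))

    # 3c. decomposition of manure + last year's retained residue (IN2), with
    #     the SOM decay carbon routed to the gaseous pathway
    in2, soc_loss_c = ecology.mineralisation(
        decisions["manure_kg_ha"].to_numpy(), world.retained_residue,
        stock["c"], eco)
    add(ins, in2)

    # 3d. erosion (OUT3) and its one-step downslope delivery (IN4)
    soil_loss = ecology.soil_erosion(plots["slope"].to_numpy(dtype=float), eco,
                                     swc_flag=decisions["swc_flag"].to_numpy())
    stock_map = {nut: stock[nut] for nut in NUTRIENTS}
    stock_map.update(rho=plots["rho"].to_numpy(), cf=plots["cf"].to_numpy(),
                     depth=cfg.depth)
    out3 = ecology.erosion_nutrient_loss(soil_loss, stock_map, eco)
    add(outs, out3)

    px_soil, px_nut = _route_sediment(world, soil_loss, out3, eco)
    in4_n = {nut: np.zeros(n_plots) for nut in NUTRIENTS}
    area_px = np.maximum(plots["area_ha"].to_numpy(dtype=float) / 0.01, 1.0)
    for nut in NUTRIENTS:
        np.add.at(in4_n[nut], px_nut["owner"], px_nut[nut])
        in4_n[nut] = in4_n[nut] / (area_px * 0.01)  # pixel mass -> plot kg/ha
    from .core import FlowVector
    in4 = FlowVector("IN4", **in4_n)
    add(ins, in4)

    # 3e. leaching (OUT4)
    out4 = ecology.leaching_loss(cfg.rain_mm, plots["clay"].to_numpy(dtype=float),
                                 stock["n"], stock["k"], in1.n, eco)
    add(outs, out4)

    # 3f. gaseous N + SOM-degradation C (OUT5)
    out5 = ecology.gaseous_loss(in1.n, in2.n, cfg.rain_mm, eco,
                                soc_loss_c=soc_loss_c)
    add(outs, out5)

    # 4. yield prediction on the post-decision context
    ctx = behaviour.assemble_context(world.households, plots, s_t,
                                     legume_planted=(decisions["legume_fraction"] > 0))
    for col in ("fert_kg_ha", "manure_kg_ha", "legume_fraction"):
        ctx[col] = decisions[col].to_numpy()
    for nut in NUTRIENTS:
        ctx[f"stock_{nut}"] = stock[nut]
    maize_yield = np.zeros(n_plots)
    legume_yield = np.zeros(n_plots)
    if "yield_maize" in world.tables:
        maize_yield = behaviour.predict_yield(ctx, world.tables["yield_maize"],
                                              realised.get("yield_maize"))
    if "yield_legume" in world.tables:
        legume_yield = behaviour.predict_yield(ctx, world.tables["yield_legume"],
                                               realised.get("yield_legume"))
    maize_frac = plots["maize_fraction"].to_numpy(dtype=float)
    legume_frac = decisions["legume_fraction"].to_numpy(dtype=float)
    maize_rm = maize_yield * maize_frac
    legume_rm = legume_yield * legume_frac

    # biological N fixation follows from the realised legume biomass (IN3)
    hi_leg = eco.hi_legume
    legume_biomass = legume_rm / hi_leg if hi_leg > 0 else np.zeros(n_plots)
    add(ins, ecology.biological_n_fixation(legume_biomass, eco))

    # 5. crop removal (OUT1 grain, OUT2 exported residue)
    out1, out2, retained = ecology.crop_removal(
        {"maize": maize_rm, "legume": legume_rm},
        decisions["residue_retained_fraction"].to_numpy(), eco)
    add(outs, out1)
    add(outs, out2)
    world.retained_residue = np.broadcast_to(
        np.asarray(retained, dtype=float), (n_plots,)).copy()

    # 6. stock update with non-negativity floor and logged deficit
    balance = {}
    clipped = {}
    for nut in NUTRIENTS:
        balance[nut] = ins[nut] - outs[nut]
        raw = stock[nut] + balance[nut]
        clipped[nut] = np.maximum(0.0, -raw)
        plots[f"stock_{nut}"] = np.maximum(0.0, raw)

    return {
        "decisions": decisions, "maize_yield": maize_rm, "legume_yield": legume_rm,
        "ins": ins, "outs": outs, "balance": balance, "clipped": clipped,
        "stock_before": stock,
        "stock_after": {nut: plots[f"stock_{nut}"].to_numpy() for nut in NUTRIENTS},
        "soil_loss": soil_loss, "soil_deposit_px": px_soil,
    }


def _route_sediment(world: World, soil_loss, out3, eco):
    """Spread plot erosion over footprint pixels, route one D8 step and
    collect receiver-pixel masses (soil t, nutrients kg per pixel)."""
    owner = world.owner
    managed = owner >= 0
    # per-pixel losses: the owning plot's per-ha rate times 0.01 ha
    px_soil_loss = np.zeros(owner.size)
    px_soil_loss[managed] = np.asarray(soil_loss)[owner[managed]] * 0.01
    px_nut_loss = {}
    for nut in NUTRIENTS:
        v = np.zeros(owner.size)
        v[managed] = np.asarray(getattr(out3, nut))[owner[managed]] * 0.01
        px_nut_loss[nut] = v
    soil_dep, in4_px = ecology.sediment_deposition(px_soil_loss, px_nut_loss,
                                                   world.flow_to, eco, check=False)
    rx_owner = np.where(managed, owner, -1)
    keep = rx_owner >= 0
    out = {"owner": rx_owner[keep]}
    for nut in NUTRIENTS:
        out[nut] = np.asarray(getattr(in4_px, nut))[keep]
    return soil_dep, out


def _aggregate(records: list, scen: str, rep: int, year: int,
               plots: pd.DataFrame, step: dict) -> None:
    values = {
        "fert_kg_ha": step["decisions"]["fert_kg_ha"].to_numpy(),
        "manure_kg_ha": step["decisions"]["manure_kg_ha"].to_numpy(),
        "maize_yield": step["maize_yield"],
        "legume_yield": step["legume_yield"],
    }
    for nut in NUTRIENTS:
        values[f"balance_{nut}"] = step["balance"][nut]
        values[f"stock_{nut}"] = step["stock_after"][nut]
    groups = {"all": np.ones(len(plots), dtype=bool)}
    ft = step["farm_type"]
    for t in (1, 2, 3):
        groups[str(t)] = ft == t
    for gname, sel in groups.items():
        if not sel.any():
            continue
        for var, arr in values.items():
            records.append({"scenario": scen, "replication": rep, "year": year,
                            "farm_type": gname, "variable": var,
                            "value": float(np.mean(arr[sel]))})


def run_experiment(world: World, scenarios=None,
                   record_detail: bool | None = None) -> SimulationOutput:
    """Run replications x scenarios from a shared initial world."""
    cfg = world.config
    scenarios = list(scenarios if scenarios is not None else cfg.scenarios)
    record_detail = cfg.record_plot_detail if record_detail is None else record_detail
    ftype_by_hh = dict(zip(world.households["household_id"],
                           world.households["farm_type"]))

    records = []
    detail_rows = []
    for scen in scenarios:
        schedule = scenario_mod.build_schedule(scen, cfg.T, cfg.baseline_share)
        for rep in range(cfg.replications):
            rng = np.random.default_rng(run_seed(cfg.master_seed, scen, rep))
            realised = {name: behaviour.draw_coefficients(t, rng, cfg.coef_draw)
                        for name, t in sorted(world.tables.items())}
            eco = world.eco.realise(rng, cfg.coef_draw)
            w = world.snapshot()
            ft = w.plots["household_id"].map(ftype_by_hh).to_numpy()
            for year in range(cfg.T):
                step = step_year(w, year, schedule.share(year), rng, realised, eco)
                step["farm_type"] = ft
                _aggregate(records, scen, rep, year, w.plots, step)
                if record_detail:
                    for nut in NUTRIENTS:
                        detail_rows.append(pd.DataFrame({
                            "scenario": scen, "replication": rep, "year": year,
                            "plot_id": w.plots["plot_id"].to_numpy(),
                            "nutrient": nut,
                            "stock_before": step["stock_before"][nut],
                            "stock_after": step["stock_after"][nut],
                            "inflow": step["ins"][nut],
                            "outflow": step["outs"][nut],
                            "clipped": step["clipped"][nut],
                        }))
            log.info("finished scenario=%s rep=%d (%d years)", scen, rep, cfg.T)
    detail = pd.concat(detail_rows, ignore_index=True) if detail_rows else None
    return SimulationOutput(pd.DataFrame(records), detail,
                            cfg.master_seed, config_hash(cfg))
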
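"""Raster and table readers/writers plus the run configuration.

Rasters are single-band grids, row-major, 0-based, origin top-left; the
supported on-disk formats are the ESRI ASCII grid (portable, text) and plain
single-band TIFF.  NoData cells round-trip as NaN.  Tables are UTF-8 CSV
with a header row; the column schemas are documented in FORMATS.md.  All
readers reject malformed input rather than coercing it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behaviour import CoefficientTable
from .ecology import Param

__all__ = [
    "read_raster", "write_raster", "read_ascii_grid", "write_ascii_grid",
    "SimulationConfig", "load_config", "config_hash",
    "read_survey", "write_survey", "read_coefficients", "write_coefficients",
    "HOUSEHOLD_COLUMNS", "PLOT_COLUMNS",
]

_ASC_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid; NoData cells become NaN.

    Returns ``(grid, meta)`` with meta holding the georeference header
    (xllcorner, yllcorner, cellsize, nodata_value).
    """
    path = Path(path)
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in _ASC_HEADER_KEYS + ("nodata_value",):
            try:
                meta[parts[0].lower()] = float(parts[1])
            except ValueError:
                raise ValueError(f"{path}:{i + 1}: malformed header value {parts[1]!r}")
        else:
            break
    missing = [k for k in _ASC_HEADER_KEYS if k not in meta]
    if missing:
        raise ValueError(f"{path}:{i + 1}: ASCII grid header missing {missing}")
    ncols, nrows = int(meta["ncols"]), int(meta["nrows"])
    try:
        data = np.loadtxt(lines[i:], dtype=float, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}:{i + 1}: malformed data block: {exc}") from exc
    if data.size != nrows * ncols:
        raise ValueError(
            f"{path}:{i + 1}: expected {nrows}x{ncols} values, got {data.size}")
    grid = data.reshape(nrows, ncols)
    nodata = meta.get("nodata_value")
    if nodata is not None:
        grid = np.where(grid == nodata, np.nan, grid)
    return grid, meta


def write_ascii_grid(grid, path, xllcorner=0.0, yllcorner=0.0, cellsize=10.0,
                     nodata=-9999.0):
    """Write a 2-D grid as an ESRI ASCII grid (NaN -> NoData)."""
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError("grid must be 2-D")
    out = np.where(np.isnan(grid), nodata, grid)
    header = (f"ncols {grid.shape[1]}\nnrows {grid.shape[0]}\n"
              f"xllcorner {xllcorner}\nyllcorner {yllcorner}\n"
              f"cellsize {cellsize}\nnodata_value {nodata}\n")
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_raster(path):
    """Read a raster by extension: .asc ESRI ASCII grid, .tif/.tiff TIFF.

    Returns ``(grid, meta)``; TIFFs carry an empty meta dict.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster not found: {path}")
    if path.suffix.lower() == ".asc":
        return read_ascii_grid(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        return np.asarray(tifffile.imread(path), dtype=float), {}
    raise ValueError(f"unsupported raster format: {path.suffix!r}")


def write_raster(grid, path, **meta):
    path = Path(path)
    if path.suffix.lower() == ".asc":
        write_ascii_grid(grid, path, **meta)
    elif path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, np.asarray(grid, dtype=np.float32))
    else:
        raise ValueError(f"unsupported raster format: {path.suffix!r}")


# --------------------------------------------------------------------------
# configuration

@dataclass
class SimulationConfig:
    """Fully-resolved run configuration (defaults match the study set-up:
    a 20-year horizon, 10 replications, 0.10 m managed layer)."""

    input_dir: str = "."
    output_dir: str = "out"
    scenarios: tuple = ("current",)
    T: int = 20
    replications: int = 10
    master_seed: int = 42
    progressive: bool = True
    rain_mm: float = 900.0
    depth: float = 0.10
    baseline_share: float = 0.28
    coef_draw: str = "truncnorm"
    upscale_target_plots: int | None = None
    record_plot_detail: bool = False
    scenario_custom_path: str | None = None

    def __post_init__(self):
        if self.replications < 1:
            raise ValueError("replications must be >= 1")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if not (0.0 <= self.baseline_share <= 1.0):
            raise ValueError("baseline_share must be in [0, 1]")
        self.scenarios = tuple(self.scenarios)


def config_hash(config: SimulationConfig) -> str:
    """Stable short hash of the resolved configuration (key order free)."""
    blob = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def load_config(path) -> SimulationConfig:
    """Load a YAML config; defaults applied, unknown keys rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return SimulationConfig(**raw)


# --------------------------------------------------------------------------
# survey tables

HOUSEHOLD_COLUMNS = ["household_id", "farm_type", "head_age", "head_gender",
                     "education", "labour", "income", "livestock",
                     "group_membership", "transport_access",
                     "communication_access", "sampled"]

PLOT_COLUMNS = ["plot_id", "household_id", "row", "col", "area_ha", "slope",
                "clay", "topo_position", "cultivation_period", "swc_flag",
                "maize_fraction", "legume_fraction", "fallow_fraction",
                "residue_retained_fraction"]


def read_survey(directory):
    """Read households.csv and plots.csv, validating schema and referential
    integrity (every plot's household must exist)."""
    directory = Path(directory)
    households = pd.read_csv(directory / "households.csv")
    plots = pd.read_csv(directory / "plots.csv")
    for name, df, cols in (("households.csv", households, HOUSEHOLD_COLUMNS),
                           ("plots.csv", plots, PLOT_COLUMNS)):
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValueError(f"{name} missing column(s) {missing}")
    if households["household_id"].duplicated().any():
        raise ValueError("duplicate household_id in households.csv")
    if plots["plot_id"].duplicated().any():
        raise ValueError("duplicate plot_id in plots.csv")
    orphans = set(plots["household_id"]) - set(households["household_id"])
    if orphans:
        raise ValueError(f"plots reference unknown household_id(s): {sorted(orphans)}")
    if not households["farm_type"].isin([1, 2, 3]).all():
        raise ValueError("farm_type must be 1, 2 or 3")
    if (plots["area_ha"] <= 0).any():
        raise ValueError("plot area_ha must be > 0")
    for col in ("maize_fraction", "legume_fraction", "fallow_fraction",
                "residue_retained_fraction"):
        if ((plots[col] < 0) | (plots[col] > 1)).any():
            raise ValueError(f"plots.{col} must lie in [0, 1]")
    for col in ("group_membership", "transport_access", "communication_access",
                "sampled"):
        households[col] = households[col].astype(bool)
    plots["swc_flag"] = plots["swc_flag"].astype(bool)
    return households, plots


def write_survey(households: pd.DataFrame, plots: pd.DataFrame, directory):
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    households[HOUSEHOLD_COLUMNS].to_csv(directory / "households.csv", index=False)
    plots[PLOT_COLUMNS].to_csv(directory / "plots.csv", index=False)


def read_coefficients(path, models_path=None):
    """Read behavioural coefficient tables.

    ``path`` is a CSV with columns model, predictor, estimate, ci_lo, ci_hi;
    ``models_path`` (default: models.csv next to it) declares link and
    outcome bounds per model.  Returns ``{model: CoefficientTable}``.
    """
    path = Path(path)
    coef = pd.read_csv(path)
    need = {"model", "predictor", "estimate", "ci_lo", "ci_hi"}
    if not need.issubset(coef.columns):
        raise ValueError(f"{path}: coefficient CSV must have columns {sorted(need)}")
    bad = coef[coef["ci_lo"] > coef["ci_hi"]]
    if len(bad):
        rows = bad[["model", "predictor"]].to_records(index=False).tolist()
        raise ValueError(f"{path}: ci_lo > ci_hi for {rows}")
    models_path = Path(models_path) if models_path else path.parent / "models.csv"
    models = pd.read_csv(models_path)
    need_m = {"model", "link", "bound_min", "bound_max"}
    if not need_m.issubset(models.columns):
        raise ValueError(f"{models_path}: models CSV must have columns {sorted(need_m)}")
    models = models.set_index("model")
    tables = {}
    for model, grp in coef.groupby("model"):
        if model not in models.index:
            raise ValueError(f"{path}: model {model!r} not declared in {models_path}")
        params = {r.predictor: Param(float(r.estimate), float(r.ci_lo), float(r.ci_hi))
                  for r in grp.itertuples(index=False)}
        row = models.loc[model]
        bmax = float(row["bound_max"])
        tables[model] = CoefficientTable(
            model, params, link=str(row["link"]),
            bounds=(float(row["bound_min"]), np.inf if np.isinf(bmax) or bmax < 0 else bmax))
    return tables


def write_coefficients(tables, path, models_path=None):
    path = Path(path)
    rows, mrows = [], []
    for name, t in tables.items():
        for pred, p in t.coef.items():
            rows.append({"model": name, "predictor": pred, "estimate": p.estimate,
                         "ci_lo": p.lo, "ci_hi": p.hi})
        mrows.append({"model": name, "link": t.link,
                      "bound_min": t.bounds[0], "bound_max": t.bounds[1]})
    pd.DataFrame(rows).to_csv(path, index=False)
    models_path = Path(models_path) if models_path else path.parent / "models.csv"
    pd.DataFrame(mrows).to_csv(models_path, index=False)
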
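"""Synthesis of the unsampled household population and its plots.

A survey covers only a fraction of the landscape (e.g. a 451-plot sample
representing 17.1 % of the cultivated land); the simulator needs every
cultivated pixel managed.  The sampled households are kept verbatim
and the remainder are generated by stratified resampling: synthetic
households are drawn with replacement from the sampled rows of the same farm
type, with continuous attributes jittered by a small Normal kernel so the
synthetic population preserves the empirical joint structure within types
without parametric assumptions.  Synthetic plots inherit their template's
attributes and are placed on unoccupied cultivated pixels by region-growing,
so each plot is a contiguous raster patch and no pixel is assigned twice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["synthesize_households", "upscale_plot_count", "assign_plots"]

#: continuous household attributes jittered during resampling
_JITTER_COLS = ("head_age", "education", "labour", "income", "livestock")


def upscale_plot_count(sampled_plots: int, sampled_fraction: float) -> int:
    """Total plot count implied by the sampled fraction of cultivated land.

    ``round(sampled_plots / sampled_fraction)``; e.g. a 451-plot sample
    covering 17.1 % of the land implies 2,637 plots in total.
    """
    if not (0.0 < sampled_fraction <= 1.0):
        raise ValueError("sampled_fraction must lie in (0, 1]")
    if sampled_plots < 0:
        raise ValueError("sampled_plots must be >= 0")
    return int(round(sampled_plots / sampled_fraction))


def synthesize_households(sample: pd.DataFrame, target_count: int,
                          rng: np.random.Generator,
                          jitter_sd_frac: float = 0.10) -> pd.DataFrame:
    """Grow the household table to ``target_count`` rows.

    Sampled households are returned unchanged (``sampled=True``); synthetic
    ones are resampled within farm type with continuous attributes jittered
    by Normal(0, jitter_sd_frac * within-type sd), clipped to the within-type
    observed range.  The farm-type mix of the synthetic set follows the
    sample's proportions (largest-remainder rounding, so each type's count is
    within one household of exact proportionality).
    """
    if sample.empty:
        raise ValueError("sample must be non-empty")
    if target_count < len(sample):
        raise ValueError("target_count must be >= sample size")
    types = sorted(sample["farm_type"].unique())
    for t in (1, 2, 3):
        if t in types and (sample["farm_type"] == t).sum() == 0:
            raise ValueError(f"empty farm-type stratum {t}")
    n_extra = target_count - len(sample)
    props = sample["farm_type"].value_counts(normalize=True).sort_index()
    exact = props * n_extra
    counts = np.floor(exact).astype(int)
    rem = n_extra - counts.sum()
    for t in exact.sub(counts).sort_values(ascending=False).index[:rem]:
        counts[t] += 1

    next_id = int(sample["household_id"].max()) + 1
    out = [sample.copy()]
    out[0]["sampled"] = True
    for t, k in counts.items():
        if k == 0:
            continue
        stratum = sample[sample["farm_type"] == t]
        picks = stratum.iloc[rng.integers(0, len(stratum), size=k)].copy()
        for col in _JITTER_COLS:
            sd = float(stratum[col].std(ddof=0))
            if jitter_sd_frac > 0 and sd > 0:
                jit = rng.normal(0.0, jitter_sd_frac * sd, size=k)
                picks[col] = np.clip(picks[col] + jit,
                                     stratum[col].min(), stratum[col].max())
        picks["household_id"] = np.arange(next_id, next_id + k)
        picks["sampled"] = False
        next_id += k
        out.append(picks)
    return pd.concat(out, ignore_index=True)


def assign_plots(population: pd.DataFrame, sample_plots: pd.DataFrame,
                 cultivated_mask: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Give every synthetic household plots on the cultivated landscape.

    Sampled plots keep their surveyed pixels.  Each synthetic household
    receives one plot per template plot of a randomly chosen same-type
    sampled household: the plot copies the template's management attributes,
    draws its pixel count from the template area (0.01 ha per pixel), and is
    grown as a contiguous patch from a random free cultivated seed pixel.
    Raises ``ValueError`` with the shortfall when the mask cannot host the
    demanded area.
    """
    mask = np.asarray(cultivated_mask, dtype=bool)
    nr, nc = mask.shape
    free = mask.copy()
    # reserve surveyed footprints first: sampled plots are never moved
    for rec in sample_plots.itertuples(index=False):
        npix = max(1, int(round(rec.area_ha / 0.01)))
        _grow_patch(free, int(rec.row), int(rec.col), npix, claim=True)

    synth_hh = population[~population["sampled"]]
    sample_hh_ids = population.loc[population["sampled"], "household_id"]
    plots_by_hh = {hid: g for hid, g in sample_plots.groupby("household_id")}

    demand_px = 0
    jobs = []  # (household_id, template plot row)
    hh_types = population.set_index("household_id")["farm_type"]
    type_members = {t: [h for h in sample_hh_ids
                        if hh_types[h] == t and h in plots_by_hh]
                    for t in (1, 2, 3)}
    for rec in synth_hh.itertuples(index=False):
        members = type_members.get(int(rec.farm_type)) or list(plots_by_hh)
        donor = members[int(rng.integers(0, len(members)))]
        for tpl in plots_by_hh[donor].itertuples(index=False):
            jobs.append((int(rec.household_id), tpl))
            demand_px += max(1, int(round(tpl.area_ha / 0.01)))
    if demand_px > int(free.sum()):
        raise ValueError(
            f"cultivated mask cannot host synthetic plots: need {demand_px} "
            f"pixels, only {int(free.sum())} free (shortfall "
            f"{demand_px - int(free.sum())})")

    next_pid = int(sample_plots["plot_id"].max()) + 1
    rows = [sample_plots.copy()]
    free_idx = np.flatnonzero(free)
    rng.shuffle(free_idx)
    cursor = 0
    new = []
    for hid, tpl in jobs:
        npix = max(1, int(round(tpl.area_ha / 0.01)))
        seed = None
        while cursor < len(free_idx):
            cand = free_idx[cursor]
            cursor += 1
            if free.ravel()[cand]:
                seed = cand
                break
        if seed is None:
            raise ValueError("ran out of free cultivated pixels while placing plots")
        got = _grow_patch(free, seed // nc, seed % nc, npix, claim=True)
        rec = tpl._asdict()
        rec.update(plot_id=next_pid, household_id=hid,
                   row=seed // nc, col=seed % nc, area_ha=got * 0.01)
        new.append(rec)
        next_pid += 1
    if new:
        rows.append(pd.DataFrame(new))
    return pd.concat(rows, ignore_index=True)


def _grow_patch(free: np.ndarray, r: int, c: int, npix: int, claim: bool) -> int:
    """Region-grow a contiguous patch of up to ``npix`` pixels from (r, c)
    over the free mask, claiming them; returns the number of pixels taken."""
    nr, nc = free.shape
    if not (0 <= r < nr and 0 <= c < nc):
        return 0
    frontier = [(r, c)]
    taken = 0
    seen = set()
    while frontier and taken < npix:
        rr, cc = frontier.pop(0)
        if (rr, cc) in seen or not (0 <= rr < nr and 0 <= cc < nc):
            continue
        seen.add((rr, cc))
        if not free[rr, cc]:
            continue
        if claim:
            free[rr, cc] = False
        taken += 1
        frontier.extend([(rr - 1, cc), (rr + 1, cc), (rr, cc - 1), (rr, cc + 1)])
    return taken
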
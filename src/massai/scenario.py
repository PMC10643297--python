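"""Fertilizer-subsidy policy schedules and yearly progressive state updates.

Four policy spectrums are built in, each a per-year subsidy share (the
fraction of the fertilizer price the farmer does not pay):

* ``current``   — the measured 2016/17 baseline share, held constant (0.28);
* ``reduced``   — a linear ramp from the baseline down to 0.02, whose
  20-year mean is exactly 0.15;
* ``zero``      — subsidy withdrawn after the baseline year;
* ``universal`` — subsidy extended to all farmers at a 0.70 share.

Trajectories are overridable from config or a per-year CSV; only the stated
scenario means are fixed by the policy narrative.

``progressive_update`` applies the between-year drift of the variables that
age naturally (household head age, plot cultivation period); everything else
is held at baseline so scenario differences isolate the policy effect.
Additional update rules (e.g. labour or gender dynamics) can be registered
as hooks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["SCENARIO_NAMES", "ScenarioSchedule", "build_schedule", "progressive_update"]

SCENARIO_NAMES = ("current", "reduced", "zero", "universal")

DEFAULT_BASELINE = 0.28
DEFAULT_HORIZON = 20


@dataclass(frozen=True)
class ScenarioSchedule:
    """A named subsidy-share trajectory s_0..s_{T-1}, each share in [0, 1]."""

    name: str
    s: tuple

    def __post_init__(self):
        if len(self.s) < 1:
            raise ValueError("schedule must cover at least one year")
        if any(not (0.0 <= x <= 1.0) for x in self.s):
            raise ValueError("all subsidy shares must lie in [0, 1]")

    @property
    def T(self) -> int:
        return len(self.s)

    def share(self, year: int) -> float:
        return self.s[year]

    def mean(self) -> float:
        return float(np.mean(self.s))


def build_schedule(name: str, T: int = DEFAULT_HORIZON,
                   baseline_share: float = DEFAULT_BASELINE,
                   custom: Sequence[float] | None = None) -> ScenarioSchedule:
    """Build a subsidy schedule for one of the policy spectrums.

    ``custom`` overrides the built-in trajectory entirely (length-T shares).
    Defaults: current = constant baseline; reduced = linear ramp baseline ->
    0.02 (mean (0.28+0.02)/2 = 0.15 over the default horizon); zero =
    baseline in year 0 then 0; universal = constant 0.70.
    """
    if T < 1:
        raise ValueError("horizon T must be >= 1")
    if custom is not None:
        if len(custom) != T:
            raise ValueError(f"custom schedule must have length {T}")
        return ScenarioSchedule(name, tuple(float(x) for x in custom))
    if name == "current":
        s = np.full(T, baseline_share)
    elif name == "reduced":
        s = np.linspace(baseline_share, 0.02, T) if T > 1 else np.array([0.15])
    elif name == "zero":
        s = np.zeros(T)
        s[0] = baseline_share if T > 1 else 0.0
    elif name == "universal":
        s = np.full(T, 0.70)
    else:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIO_NAMES}")
    return ScenarioSchedule(name, tuple(float(x) for x in s))


def progressive_update(households, plots, enabled: bool = True,
                       hooks: Sequence[Callable] = ()):
    """Advance the progressively changing state variables by one year.

    Head age increases by one for every household; cultivation period by one
    for every cultivated plot.  Registered hooks are called once per tick as
    ``hook(households, plots)`` and may mutate in place (the documented
    extension point for labour / gender update rules).  With the progressive
    switch off, state passes through untouched.

    Returns ``(households, plots)`` (mutated in place for DataFrames).
    """
    if not enabled:
        return households, plots
    households["head_age"] = households["head_age"] + 1
    cultivated = plots["fallow_fraction"] < 1.0
    plots.loc[cultivated, "cultivation_period"] = \
        plots.loc[cultivated, "cultivation_period"] + 1
    for hook in hooks:
        hook(households, plots)
    return households, plots
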
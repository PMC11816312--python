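"""Synthetic study designs and survival datasets with known ground truth.

Emulates the layout of standard bee laboratory tests: geometric
concentration ladders around 1 TU plus a control, grouped replicates of 10
individuals, an early 6-h observation for acute routes followed by daily
observations, horizons of 2-10 days, and nonzero background mortality.
Deaths are drawn from the identical multinomial interval construction used
by the calibration likelihood, so parameter-recovery tests are
well-specified by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import Replicate, SurvivalDataset, Treatment, _LikelihoodEngine
from .exposure import DEFAULT_DT_UNIT, ExposureEvent, Route
from .tktd import DEFAULT_N_STEPS, ModelVariant, TKTDParams

__all__ = ["StudyDesign", "make_design", "simulate_dataset"]


@dataclass
class StudyDesign:
    """Layout of one synthetic study."""

    route: Route
    levels: np.ndarray  # includes the 0 control
    n_replicates: int
    n0: int
    obs_times: np.ndarray  # days, sorted, > 0
    feeding_duration: float  # days; acute oral only
    horizon: float
    unit: str = "TU"

    def __post_init__(self) -> None:
        self.route = Route(self.route)
        self.levels = np.asarray(self.levels, dtype=float)
        self.obs_times = np.asarray(self.obs_times, dtype=float)
        if np.any(self.levels < 0) or 0.0 not in self.levels:
            raise ValueError("levels must be >= 0 and include a 0 control")
        if np.any(np.diff(self.obs_times) <= 0):
            raise ValueError("observation schedule must be sorted")
        if self.n0 < 1 or self.n_replicates < 1:
            raise ValueError("need at least one replicate of one individual")

    def events_for_level(self, level: float) -> list[ExposureEvent]:
        if self.route is Route.ACUTE_CONTACT:
            return [ExposureEvent(self.route, level, 0.0, 0.0, self.unit)]
        if self.route is Route.ACUTE_ORAL:
            return [ExposureEvent(self.route, level, 0.0, self.feeding_duration, self.unit)]
        return [ExposureEvent(self.route, level, 0.0, self.horizon, self.unit)]


def make_design(
    route: Route,
    n_levels: int = 5,
    spacing: float = 2.0,
    n_replicates: int = 3,
    n0: int = 10,
    horizon: float = 10.0,
    feeding_duration: float = 0.25,
    unit: str = "TU",
) -> StudyDesign:
    """Geometric concentration ladder around 1 TU plus control.

    With ``n_levels=5, spacing=2`` the noncontrol levels are
    {0.25, 0.5, 1, 2, 4} TU. The observation schedule is a 6-h timepoint
    (acute routes only) followed by daily observations up to ``horizon``.
    """
    if n_levels < 2:
        raise ValueError("need at least 2 concentration levels")
    if not (2.0 <= horizon <= 10.0):
        raise ValueError("horizon must lie in [2, 10] days")
    route = Route(route)
    exponents = np.arange(n_levels) - (n_levels - 1) / 2.0
    ladder = spacing ** exponents
    levels = np.concatenate([[0.0], ladder])
    daily = np.arange(1.0, horizon + 0.5)
    if route is Route.CHRONIC_ORAL:
        obs = daily
    else:
        obs = np.concatenate([[0.25], daily])
    return StudyDesign(
        route=route,
        levels=levels,
        n_replicates=n_replicates,
        n0=n0,
        obs_times=obs,
        feeding_duration=feeding_duration,
        horizon=horizon,
        unit=unit,
    )


def simulate_dataset(
    design: StudyDesign,
    model: ModelVariant,
    true_params: TKTDParams,
    seed: int = 0,
    dt_unit: float = DEFAULT_DT_UNIT,
    n_steps: int = DEFAULT_N_STEPS,
) -> SurvivalDataset:
    """Draw a survival dataset from the generative model.

    Per replicate, deaths per observation interval are multinomial with
    probabilities ``S(t_{i-1}) - S(t_i)`` induced by the model's survival
    curve -- the same construction the calibration likelihood assumes.
    Identical seeds yield identical datasets.
    """
    rng = np.random.default_rng(seed)
    model = ModelVariant(model)
    treatments = []
    for i, level in enumerate(design.levels):
        label = "control" if level == 0.0 else f"T{i}"
        treatments.append(Treatment(label=label, replicates=[],
                                    events=design.events_for_level(level)))
    # solve all treatments on a shared grid via a throwaway skeleton dataset
    skeleton = SurvivalDataset(
        [Treatment(t.label,
                   [Replicate(design.obs_times, np.full(design.obs_times.shape, design.n0, int),
                              design.n0)],
                   events=t.events)
         for t in treatments],
        metadata={},
    )
    engine = _LikelihoodEngine(model, skeleton, dt_unit=dt_unit, n_steps=n_steps)
    S = engine.survival(true_params)
    dt = engine.t[1] - engine.t[0]
    idx = np.clip(np.round(design.obs_times / dt).astype(int), 0, len(engine.t) - 1)
    for k, tr in enumerate(treatments):
        s = np.clip(S[k, idx], 0.0, 1.0)
        p = np.concatenate([[1.0], s])
        cells = np.append(np.clip(-np.diff(p), 0.0, 1.0), max(s[-1], 0.0))
        cells = cells / cells.sum()
        for _ in range(design.n_replicates):
            deaths = rng.multinomial(design.n0, cells)
            alive = design.n0 - np.cumsum(deaths[:-1])
            tr.replicates.append(Replicate(design.obs_times.copy(), alive, design.n0))
    meta = {
        "study_id": f"synthetic-{design.route.value}-seed{seed}",
        "route": design.route.value,
        "units": design.unit,
        "model": model.value,
        "seed": seed,
    }
    return SurvivalDataset(treatments, metadata=meta)
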
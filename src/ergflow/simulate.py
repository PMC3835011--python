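"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates an acute ocular-perfusion-pressure challenge in
anaesthetised rats: IOP is stepped 10 -> 120 mmHg in 5 mmHg / 3 min
increments while mean arterial pressure is clamped at a high (159),
moderate (104) or low (61 mmHg) level, so OPP = MAP - IOP falls along a
staircase.

Per animal and step the generator produces

* relative blood flow from a piecewise-linear flow–OPP curve with an
  autoregulatory plateau (flat between the plateau anchors, declining
  linearly to zero flow as OPP falls to the zero-flow anchor, rising
  linearly above the plateau), normalised so the reference operating point
  (MAP 93, IOP 10, OPP 83 mmHg) gives exactly 100 %;
* relative vitreal pO2 as the model-implied oxygen consumption of the true
  flow (sensor noise is added after the consumption mapping);
* relative ERG amplitude from the full model (consumption plus mechanical
  stress);

each with additive Gaussian measurement noise truncated at zero.  Group
means with SEM = SD/sqrt(n) are emitted alongside the per-animal records,
matching how the experimental figures summarise cohorts.

The flow–OPP curve exists only in the generator: in the analysis itself
flow is always a measured input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .model import (
    BASELINE_REFERENCE_OPP,
    ModelParams,
    PressureState,
    TABLE1_PARAMS,
    erg_model,
    oxygen_consumption,
)

__all__ = [
    "FlowCurve",
    "NoiseConfig",
    "CohortConfig",
    "MAP_LEVELS",
    "protocol_grid",
    "flow_from_opp",
    "generate_cohort",
]

#: Clamped MAP levels (mmHg) for the high / moderate / low pressure arms.
MAP_LEVELS = {"high": 159.0, "moderate": 104.0, "low": 61.0}


@dataclass(frozen=True)
class FlowCurve:
    """Anchors of the piecewise-linear flow–OPP autoregulation curve.

    The plateau spans MAP 60–100 mmHg at baseline IOP 10, i.e. OPP 50–90
    mmHg.  Flow declines linearly from the lower plateau edge to zero at
    ``zero_flow_opp`` and rises linearly above the upper edge with
    ``rise_slope`` (%/mmHg); the default slope puts the high-pressure arm
    (OPP 149 at baseline) near 200 % flow, the hyperperfusion the
    calibration cohort shows.
    """

    zero_flow_opp: float = 0.0
    plateau_lo: float = 50.0
    plateau_hi: float = 90.0
    plateau_flow: float = 100.0
    rise_slope: float = 1.7

    def __post_init__(self) -> None:
        if not self.zero_flow_opp < self.plateau_lo < self.plateau_hi:
            raise ValueError(
                "flow-curve anchors must satisfy zero_flow_opp < plateau_lo < plateau_hi"
            )
        if self.plateau_flow <= 0:
            raise ValueError("plateau flow must be positive")
        if self.rise_slope < 0:
            raise ValueError("rise slope must be >= 0")


@dataclass(frozen=True)
class NoiseConfig:
    """Per-channel additive Gaussian SD, in percentage points of baseline."""

    flow: float = 8.0
    erg: float = 8.0
    po2: float = 8.0

    def __post_init__(self) -> None:
        if min(self.flow, self.erg, self.po2) < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate one cohort reproducibly."""

    map_level: float = MAP_LEVELS["high"]
    iop_start: float = 10.0
    iop_stop: float = 120.0
    iop_step: float = 5.0
    flow_curve: FlowCurve = field(default_factory=FlowCurve)
    gen_params: ModelParams = TABLE1_PARAMS
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    n_animals: int = 6
    group: str = "high"
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def protocol_grid(config: CohortConfig) -> list[PressureState]:
    """The IOP staircase as ordered pressure states (default 23 steps)."""
    if config.iop_step <= 0:
        raise ValueError("IOP step must be > 0 mmHg")
    iops = np.arange(
        config.iop_start, config.iop_stop + 0.5 * config.iop_step, config.iop_step
    )
    return [PressureState(map=config.map_level, iop=float(i)) for i in iops]


def flow_from_opp(opp, curve: FlowCurve = FlowCurve()):
    """Relative ocular blood flow (% baseline) for a given OPP (mmHg).

    Piecewise linear with an autoregulatory plateau, rescaled so the
    reference operating point (OPP 83 mmHg) returns exactly 100 %.
    """
    opp = np.asarray(opp, dtype=float)

    def unscaled(x):
        x = np.asarray(x, dtype=float)
        below = (x - curve.zero_flow_opp) / (curve.plateau_lo - curve.zero_flow_opp)
        out = np.where(
            x <= curve.zero_flow_opp,
            0.0,
            np.where(
                x < curve.plateau_lo,
                curve.plateau_flow * below,
                np.where(
                    x <= curve.plateau_hi,
                    curve.plateau_flow,
                    curve.plateau_flow + curve.rise_slope * (x - curve.plateau_hi),
                ),
            ),
        )
        return out

    ref = unscaled(BASELINE_REFERENCE_OPP)
    if not ref > 0:
        raise ValueError(
            "flow curve gives non-positive flow at the reference OPP "
            f"({BASELINE_REFERENCE_OPP} mmHg); adjust the anchors"
        )
    return unscaled(opp) * (100.0 / float(ref))


def generate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one cohort; returns (per-animal records, group summary).

    Per-animal frame columns: ``group, animal_id, step, iop_mmHg, map_mmHg,
    flow_pct, erg_pct, po2_pct``.  Summary frame adds per-step means and
    SEMs (``*_sem_pct``; SD/sqrt(n), NaN when n = 1 or noise-free zero
    variance keeps SD at 0).  Byte-identical output for a fixed seed.
    """
    if config.n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    rng = np.random.default_rng(config.seed)
    states = protocol_grid(config)
    iops = np.array([s.iop for s in states])
    opps = np.array([s.opp for s in states])
    true_flow = np.asarray(flow_from_opp(opps, config.flow_curve))
    true_po2 = np.asarray(oxygen_consumption(true_flow, config.gen_params))
    true_erg = np.asarray(erg_model(true_flow, iops, config.gen_params))

    n, k = config.n_animals, len(states)
    noise = config.noise
    flow_obs = np.clip(true_flow + rng.normal(0.0, noise.flow, (n, k)) if noise.flow > 0
                       else np.tile(true_flow, (n, 1)), 0.0, None)
    po2_obs = np.clip(true_po2 + rng.normal(0.0, noise.po2, (n, k)) if noise.po2 > 0
                      else np.tile(true_po2, (n, 1)), 0.0, None)
    erg_obs = np.clip(true_erg + rng.normal(0.0, noise.erg, (n, k)) if noise.erg > 0
                      else np.tile(true_erg, (n, 1)), 0.0, None)

    animals = pd.DataFrame(
        {
            "group": config.group,
            "animal_id": np.repeat(np.arange(1, n + 1), k),
            "step": np.tile(np.arange(1, k + 1), n),
            "iop_mmHg": np.tile(iops, n),
            "map_mmHg": config.map_level,
            "flow_pct": flow_obs.ravel(),
            "erg_pct": erg_obs.ravel(),
            "po2_pct": po2_obs.ravel(),
        }
    )

    def sem(x: np.ndarray) -> np.ndarray:
        if n < 2:
            return np.full(k, np.nan)
        return x.std(axis=0, ddof=1) / np.sqrt(n)

    summary = pd.DataFrame(
        {
            "group": config.group,
            "step": np.arange(1, k + 1),
            "iop_mmHg": iops,
            "map_mmHg": config.map_level,
            "opp_mmHg": opps,
            "n": n,
            "flow_pct": flow_obs.mean(axis=0),
            "flow_sem_pct": sem(flow_obs),
            "erg_pct": erg_obs.mean(axis=0),
            "erg_sem_pct": sem(erg_obs),
            "po2_pct": po2_obs.mean(axis=0),
            "po2_sem_pct": sem(po2_obs),
        }
    )
    return animals, summary
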
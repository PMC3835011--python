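"""Core model of retinal function under perfusion-pressure challenge.

Relative retinal function (ERG b-wave amplitude, % of baseline) is modelled
as the sum of two components:

* **oxygen consumption** — relative blood flow times the oxygen extraction
  ratio (OER).  OER falls exponentially with increasing flow and is pinned
  to onefold at 100 % (baseline) flow, so consumption equals 100 % at
  baseline.
* **IOP mechanical stress (IOP_M)** — a non-vascular, pressure-related
  attenuation of function: zero below a threshold IOP ``t`` and linear with
  slope ``m`` (% ERG per mmHg, negative) above it.

All flow/ERG/pO2/consumption quantities live on a 0–200 % scale where 100
is baseline; OER is a fold change where 1 is baseline.  These conventions
are converted only at module boundaries.

Every function here is pure, stateless and accepts scalars or numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ModelParams",
    "PressureState",
    "TABLE1_PARAMS",
    "BASELINE_REFERENCE_OPP",
    "oer_from_flow",
    "oxygen_consumption",
    "iopm_from_iop",
    "iopm_from_opp",
    "erg_model",
]


@dataclass(frozen=True)
class ModelParams:
    """The four parameters of the retinal-function model.

    Attributes
    ----------
    a:
        OER responsiveness (fold, dimensionless, > 0): the vertical span of
        the exponential OER–flow curve, i.e. the maximum capacity of the
        tissue to modulate oxygen extraction as flow changes.
    b:
        Exponential decay rate of the OER–flow curve (per % blood flow,
        < 0).  The flow increment that halves the exponential term is
        ``-ln(2)/b``.
    t:
        IOP threshold (mmHg, in [10, 120]) above which mechanical stress
        begins to attenuate the ERG.
    m:
        Mechanical-stress slope (% ERG per mmHg, <= 0) above the threshold.
    """

    a: float
    b: float
    t: float
    m: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"OER responsiveness a must be > 0, got {self.a}")
        if not self.b < 0:
            raise ValueError(f"OER decay rate b must be < 0, got {self.b}")
        if not 10.0 <= self.t <= 120.0:
            raise ValueError(f"IOP threshold t must lie in [10, 120] mmHg, got {self.t}")
        if self.m > 0:
            raise ValueError(f"mechanical-stress slope m must be <= 0, got {self.m}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.t, self.m], dtype=float)

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "ModelParams":
        a, b, t, m = (float(x) for x in theta)
        return cls(a=a, b=b, t=t, m=m)


#: Best-fit parameter vector from the high-blood-pressure calibration cohort.
TABLE1_PARAMS = ModelParams(a=4.03, b=-0.019, t=50.0, m=-0.70)

#: OPP (mmHg) of the baseline operating point: MAP 93, IOP 10.
BASELINE_REFERENCE_OPP = 83.0


@dataclass(frozen=True)
class PressureState:
    """MAP and IOP for one protocol step; OPP = MAP - IOP is derived."""

    map: float
    iop: float

    def __post_init__(self) -> None:
        if not self.map > 0:
            raise ValueError(f"MAP must be positive, got {self.map}")
        if self.iop < 0:
            raise ValueError(f"IOP must be non-negative, got {self.iop}")

    @property
    def opp(self) -> float:
        return self.map - self.iop


def _check_flow(flow) -> np.ndarray:
    flow = np.asarray(flow, dtype=float)
    if np.any(flow < 0):
        raise ValueError("relative blood flow must be >= 0 (% of baseline)")
    return flow


def oer_from_flow(flow, params: ModelParams):
    """Oxygen extraction ratio (fold) as a function of relative blood flow.

    ``OER(flow) = a * exp(b * flow) + (1 - a * exp(100 * b))``

    The additive constant pins the curve through the baseline operating
    point (100 % flow, onefold OER); ``a`` is the vertical span and ``b``
    the exponential rate, so with ``a > 0, b < 0`` the OER rises above
    onefold as flow falls (increased extraction buffers ischaemia) and
    drops below onefold during hyperperfusion.

    Parameters
    ----------
    flow:
        Relative blood flow, % of baseline (scalar or array, >= 0).
    params:
        Model parameters; only ``a`` and ``b`` are used.

    Returns
    -------
    OER in fold units (1.0 at ``flow == 100``), same shape as ``flow``.
    """
    flow = _check_flow(flow)
    offset = 1.0 - params.a * np.exp(100.0 * params.b)
    return params.a * np.exp(params.b * flow) + offset


def oxygen_consumption(flow, params: ModelParams):
    """Relative oxygen consumption (% baseline): flow times OER.

    With arterial oxygen content held at its baseline value during an acute
    challenge, consumption reduces to delivery (proportional to flow) times
    the extraction ratio.  Equals 100 at baseline flow and 0 at zero flow.
    """
    flow = _check_flow(flow)
    return flow * oer_from_flow(flow, params)


def iopm_from_iop(iop, params: ModelParams):
    """IOP mechanical stress on neurons, % of baseline ERG (<= 0).

    Two-line hinge: zero for ``iop <= t``, then ``m * (iop - t)`` above the
    threshold.  Continuous at the threshold and non-increasing in IOP.
    """
    iop = np.asarray(iop, dtype=float)
    if np.any(iop < 0):
        raise ValueError("IOP must be >= 0 mmHg")
    return np.where(iop <= params.t, 0.0, params.m * (iop - params.t))


def iopm_from_opp(opp, map_mmHg, params: ModelParams):
    """Mechanical stress expressed against OPP via ``IOP = MAP - OPP``."""
    opp = np.asarray(opp, dtype=float)
    map_mmHg = np.asarray(map_mmHg, dtype=float)
    if np.any(map_mmHg <= 0):
        raise ValueError("MAP must be > 0 mmHg")
    return iopm_from_iop(map_mmHg - opp, params)


def erg_model(flow, iop, params: ModelParams):
    """Predicted relative ERG amplitude (% baseline).

    The sum of relative oxygen consumption and the (non-positive) IOP
    mechanical-stress term, clamped below at 0 % — negative amplitudes are
    unphysical.  Relative blood flow is a *measured* input here; the model
    never predicts flow from pressure (that mapping belongs to the
    synthetic-cohort generator).

    At baseline (flow = 100 %, IOP below threshold) the prediction is
    exactly 100 %.  ``iop`` may be a scalar/array in mmHg or a
    :class:`PressureState`.
    """
    if isinstance(iop, PressureState):
        iop = iop.iop
    cons = oxygen_consumption(flow, params)
    stress = iopm_from_iop(iop, params)
    return np.maximum(cons + stress, 0.0)
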
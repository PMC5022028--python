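"""Clonogenic survival from aberration and break counts.

Lethality channels, combined multiplicatively per condition:

* lethal chromosome aberrations -- dicentrics and large (Giemsa-visible,
  > 3 Mbp) deletions.  With aberrations Poisson-distributed across cells,
  survival is the zero class, ``exp(-N_lethal)``;
* mitotic death -- cells entering mitosis with unrepaired DSBs die with a
  single-exponential probability in the carried break count;
* G1 arrest/apoptosis -- cycling, checkpoint-competent cells escape the
  G1 arrest with probability ``exp(-arrest_sensitivity * N_G1)``.

The mean inactivation dose (MID), the integral of the survival curve over
dose, summarises a whole curve as one radiosensitivity scalar.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .endpoints import aberration_yields
from .parameters import (
    CellPhenotype,
    ExposureScenario,
    ModelParameters,
    Phase,
    Plating,
    initial_dsb_count,
)

__all__ = [
    "SurvivalCurve",
    "survival_g1_noncycling",
    "survival_g2",
    "mitotic_survival",
    "g1_escape",
    "combined_survival",
    "mean_inactivation_dose",
]

logger = logging.getLogger(__name__)


def survival_g1_noncycling(
    dose: float,
    phenotype: CellPhenotype,
    params: ModelParameters | None = None,
) -> float:
    """Survival of non-cycling cells irradiated in G1.

    Death is driven entirely by lethal aberrations scored at complete
    repair: ``S = exp(-(N_dic + N_del>3Mbp))``.
    """
    if params is None:
        params = ModelParameters()
    scenario = ExposureScenario(dose=dose, phase=Phase.G1)
    y = aberration_yields(scenario, phenotype, params, t=float("inf"))
    return math.exp(-(y.n_dicentric + y.n_deletion_visible))


def survival_g2(
    dose: float,
    phenotype: CellPhenotype,
    params: ModelParameters | None = None,
) -> float:
    """Aberration-driven survival for cells irradiated in G2.

    With the genome replicated, structures that block mitosis outright
    (dicentrics, inter-arm exchanges) remain lethal, while a large deletion
    sits on a single chromatid and is inherited by only one daughter; the
    colony fails through deletions only when both daughters draw a lethal
    one.  With per-daughter visible-deletion burden ``m = N_del / 2``:

        S = exp(-(N_dic + N_interarm)) * (1 - (1 - exp(-m))^2)

    Higher-order combinations (several deletions spread across both
    daughters) are neglected.
    """
    if params is None:
        params = ModelParameters()
    scenario = ExposureScenario(dose=dose, phase=Phase.G2)
    y = aberration_yields(scenario, phenotype, params, t=float("inf"))
    m = 0.5 * y.n_deletion_visible
    both_daughters_fail = (1.0 - math.exp(-m)) ** 2
    return math.exp(-(y.n_dicentric + y.n_interarm)) * (1.0 - both_daughters_fail)


def mitotic_survival(n_m: float, params: ModelParameters | None = None) -> float:
    """Probability of surviving mitosis with ``n_m`` unrepaired DSBs."""
    if params is None:
        params = ModelParameters()
    if n_m < 0:
        raise ValueError("break count must be non-negative")
    return math.exp(-params.mitosis_sensitivity * n_m)


def g1_escape(
    n_g1: float,
    phenotype: CellPhenotype,
    params: ModelParameters | None = None,
    cycling: bool = True,
) -> float:
    """Probability of escaping G1 arrest/apoptosis after ``n_g1`` DSBs.

    Only cycling cells with a functional G1 checkpoint trigger the arrest;
    everything else (non-cycling cultures, other phases, p53-type
    checkpoint defects) passes with probability 1.
    """
    if params is None:
        params = ModelParameters()
    if n_g1 < 0:
        raise ValueError("break count must be non-negative")
    if not cycling or not phenotype.g1_checkpoint_competent:
        return 1.0
    return math.exp(-params.arrest_sensitivity * n_g1)


def _checkpoint_escape_breaks(
    n0: float, phenotype: CellPhenotype, params: ModelParameters
) -> float:
    """DSBs carried into mitosis after the G2 damage checkpoint.

    The checkpoint releases once fewer than ``checkpoint_threshold`` breaks
    remain, so cells proceed to mitosis with the residual count at release:
    ``min(N0, threshold)``.
    """
    return min(n0, params.checkpoint_threshold)


@dataclass(frozen=True)
class SurvivalCurve:
    """Surviving fraction on a dose grid for one condition."""

    doses_gy: np.ndarray
    surviving_fraction: np.ndarray
    phase: Phase
    cycling: bool
    plating: Plating
    phenotype_name: str = "generic"

    def __post_init__(self) -> None:
        if len(self.doses_gy) != len(self.surviving_fraction):
            raise ValueError("dose and survival grids must have equal length")


def combined_survival(
    scenario: ExposureScenario,
    phenotype: CellPhenotype,
    params: ModelParameters | None = None,
    doses=None,
) -> SurvivalCurve:
    """Survival over a dose grid for one experimental condition.

    The applicable channels multiply:

    * G1, non-cycling or delayed plating: aberration lethality alone;
    * G1, cycling with immediate plating: aberrations x G1 escape;
    * G2: G2 aberration expression x mitotic death on breaks escaping the
      damage checkpoint;
    * M: mitotic death on every induced break (no repair before anaphase).
    """
    if params is None:
        params = ModelParameters()
    if doses is None:
        doses = np.atleast_1d(np.asarray(scenario.dose, dtype=float))
    doses = np.atleast_1d(np.asarray(doses, dtype=float))
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")

    surv = np.empty_like(doses)
    for i, dose in enumerate(doses):
        n0 = initial_dsb_count(dose, phenotype, scenario.phase, params)
        if scenario.phase is Phase.G1:
            s = survival_g1_noncycling(dose, phenotype, params)
            if scenario.cycling and scenario.plating is Plating.IMMEDIATE:
                s *= g1_escape(n0, phenotype, params, cycling=True)
        elif scenario.phase is Phase.G2:
            s = survival_g2(dose, phenotype, params)
            s *= mitotic_survival(
                _checkpoint_escape_breaks(n0, phenotype, params), params
            )
        elif scenario.phase is Phase.M:
            s = mitotic_survival(n0, params)
        else:  # pragma: no cover - Phase.coerce rejects everything else
            raise ValueError(f"unsupported phase {scenario.phase}")
        surv[i] = s
    return SurvivalCurve(
        doses_gy=doses,
        surviving_fraction=surv,
        phase=scenario.phase,
        cycling=scenario.cycling,
        plating=scenario.plating,
        phenotype_name=phenotype.name,
    )


def mean_inactivation_dose(
    doses_gy,
    surviving_fraction=None,
    tail_warning_level: float = 0.01,
) -> float:
    """Mean inactivation dose: ``int_0^inf S(D) dD`` in Gy.

    Trapezoidal integral over the tabulated curve plus an exponential
    extrapolation of the final segment for the tail beyond the last dose.
    Logs a warning when the curve has not fallen below ``tail_warning_level``
    at its endpoint, where the extrapolated tail dominates the estimate.
    """
    if isinstance(doses_gy, SurvivalCurve):  # allow passing a curve directly
        curve = doses_gy
        doses_gy, surviving_fraction = curve.doses_gy, curve.surviving_fraction
    d = np.asarray(doses_gy, dtype=float)
    s = np.asarray(surviving_fraction, dtype=float)
    if d.ndim != 1 or d.size < 2:
        raise ValueError("need a survival curve with at least two dose points")
    if np.any(np.diff(d) <= 0):
        raise ValueError("doses must be strictly increasing")
    if np.any(s <= 0) or np.any(s > 1.0 + 1e-12):
        raise ValueError("surviving fractions must lie in (0, 1]")
    core = float(np.trapezoid(s, d))
    # exponential tail from the final segment
    if s[-1] < s[-2]:
        k = math.log(s[-2] / s[-1]) / (d[-1] - d[-2])
        tail = s[-1] / k
    else:
        tail = 0.0
        logger.warning(
            "survival curve is non-decreasing at its end; tail ignored"
        )
    if s[-1] > tail_warning_level:
        logger.warning(
            "survival at the last dose point is %.3g (> %.2g); the "
            "extrapolated tail may dominate the MID estimate",
            s[-1],
            tail_warning_level,
        )
    return core + tail
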
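"""Synthetic endpoint data and the joint parameter-fitting harness.

The mechanistic parameters are constrained by fitting one shared parameter
set simultaneously across heterogeneous endpoints: repair (foci)
time-courses, misrepair fractions, chromosome aberration yields versus
dose and time, gene mutation rates, and (in a second, separate stage)
clonogenic survival.  This module provides

* a forward map from a parameter set to every supported endpoint,
* a synthetic-data generator that evaluates the forward model over a
  designed set of experimental conditions and perturbs it with relative
  Gaussian noise (the study conditions used throughout the test suite),
* :func:`joint_fit`, a bounded, multi-start, weighted nonlinear
  least-squares fit over any subset of the parameters, with per-study
  focus-count scaling factors as optional auxiliary parameters, and
* :func:`mid_stratification`, which pairs observed and modelled survival
  curves by condition and summarises agreement of their mean inactivation
  doses by an ordinary least-squares slope and R^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .endpoints import MutationQuery, aberration_yields, gene_mutation_rate, misrepaired_count
from .kinetics import predicted_foci
from .parameters import (
    CellPhenotype,
    DoseRateMode,
    ExposureScenario,
    ModelParameters,
    Phase,
    Plating,
    assign_repair_fractions,
    initial_dsb_count,
)
from .survival import combined_survival, mean_inactivation_dose

__all__ = [
    "ENDPOINT_KINDS",
    "EndpointDataset",
    "FitResult",
    "MIDStratification",
    "default_design",
    "predict_dataset",
    "generate_synthetic_datasets",
    "joint_fit",
    "mid_stratification",
]

logger = logging.getLogger(__name__)

ENDPOINT_KINDS = (
    "foci_timecourse",
    "misrepair_fraction",
    "aberrations_vs_dose",
    "aberrations_vs_time",
    "mutations_vs_dose",
    "survival_vs_dose",
)

# Bounds bracketing the default parameter values by at least an order of
# magnitude: probabilities on [0, 1], rate constants in 1/h, sigma in
# nuclear radii.
PARAMETER_BOUNDS: dict[str, tuple[float, float]] = {
    "lambda_fast": (1e-4, 1e2),
    "lambda_slow": (1e-4, 1e2),
    "lambda_mmej": (1e-4, 1e2),
    "p_complex": (1e-6, 1.0),
    "p_fail": (1e-6, 1.0),
    "sigma": (1e-3, 0.5),
    "mu_nhej": (1e-6, 1.0),
    "mu_mmej": (1e-6, 1.0),
    "nu": (1e-6, 1.0),
    "mitosis_sensitivity": (1e-6, 1.0),
    "arrest_sensitivity": (1e-6, 1.0),
}


@dataclass(frozen=True)
class EndpointDataset:
    """One measured (or synthesised) endpoint series for one condition."""

    kind: str
    phenotype: CellPhenotype
    phase: Phase
    x: np.ndarray
    y: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    sd: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    dose: float = 0.0  # fixed dose for time-resolved kinds
    name: str = ""
    scaling_group: str | None = None  # foci datasets sharing a counting scale
    foci_scaling: float = 1.0
    gene: MutationQuery | None = None
    dose_rate_mode: DoseRateMode = DoseRateMode.ACUTE
    cycling: bool = False
    plating: Plating = Plating.DELAYED

    def __post_init__(self) -> None:
        if self.kind not in ENDPOINT_KINDS:
            raise ValueError(f"unknown endpoint kind {self.kind!r}")
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        object.__setattr__(self, "sd", np.asarray(self.sd, dtype=float))
        if self.y.size and self.y.shape != self.x.shape:
            raise ValueError("y must match x in shape")
        if self.sd.size:
            if self.sd.shape != self.x.shape:
                raise ValueError("sd must match x in shape")
            if np.any(self.sd <= 0):
                raise ValueError("uncertainties must be positive")
        if self.kind == "mutations_vs_dose" and self.gene is None:
            raise ValueError("mutations_vs_dose datasets need a MutationQuery")

    def with_measurements(self, y, sd) -> "EndpointDataset":
        return EndpointDataset(
            kind=self.kind,
            phenotype=self.phenotype,
            phase=self.phase,
            x=self.x,
            y=np.asarray(y, dtype=float),
            sd=np.asarray(sd, dtype=float),
            dose=self.dose,
            name=self.name,
            scaling_group=self.scaling_group,
            foci_scaling=self.foci_scaling,
            gene=self.gene,
            dose_rate_mode=self.dose_rate_mode,
            cycling=self.cycling,
            plating=self.plating,
        )

    def to_frame(self) -> pd.DataFrame:
        """Tabular representation with the documented CSV header."""
        is_time = self.kind in ("foci_timecourse", "aberrations_vs_time")
        return pd.DataFrame(
            {
                "endpoint": self.kind,
                "phenotype_id": self.phenotype.name,
                "phase": self.phase.value,
                "dose_gy": self.dose if is_time else self.x,
                "time_h": self.x if is_time else np.inf,
                "value": self.y,
                "sd": self.sd,
            }
        )


def predict_dataset(
    params: ModelParameters,
    dataset: EndpointDataset,
    foci_scaling: float | None = None,
) -> np.ndarray:
    """Forward-model predictions at the dataset's design points."""
    ph, phase = dataset.phenotype, dataset.phase
    if dataset.kind == "foci_timecourse":
        n0 = initial_dsb_count(dataset.dose, ph, phase, params)
        fractions = assign_repair_fractions(ph, phase, params)
        scale = dataset.foci_scaling if foci_scaling is None else foci_scaling
        return np.asarray(
            predicted_foci(dataset.x, n0, fractions, params, scaling=scale)
        )
    if dataset.kind == "misrepair_fraction":
        out = np.empty_like(dataset.x)
        for i, dose in enumerate(dataset.x):
            scenario = ExposureScenario(
                dose=dose, phase=phase, dose_rate_mode=dataset.dose_rate_mode
            )
            n0 = initial_dsb_count(dose, ph, phase, params)
            mis = misrepaired_count(float("inf"), scenario, ph, params)
            out[i] = mis / n0 if n0 > 0 else 0.0
        return out
    if dataset.kind == "aberrations_vs_dose":
        out = np.empty_like(dataset.x)
        for i, dose in enumerate(dataset.x):
            scenario = ExposureScenario(
                dose=dose, phase=phase, dose_rate_mode=dataset.dose_rate_mode
            )
            out[i] = aberration_yields(scenario, ph, params, t=float("inf")).n_visible
        return out
    if dataset.kind == "aberrations_vs_time":
        scenario = ExposureScenario(
            dose=dataset.dose, phase=phase, dose_rate_mode=dataset.dose_rate_mode
        )
        return np.array(
            [
                aberration_yields(scenario, ph, params, t=t).n_visible
                for t in dataset.x
            ]
        )
    if dataset.kind == "mutations_vs_dose":
        out = np.empty_like(dataset.x)
        for i, dose in enumerate(dataset.x):
            scenario = ExposureScenario(
                dose=dose, phase=phase, dose_rate_mode=dataset.dose_rate_mode
            )
            out[i] = gene_mutation_rate(
                dataset.gene, scenario, ph, params, t=float("inf")
            ).total
        return out
    if dataset.kind == "survival_vs_dose":
        scenario = ExposureScenario(
            dose=0.0,
            phase=phase,
            cycling=dataset.cycling,
            plating=dataset.plating,
        )
        return combined_survival(scenario, ph, params, doses=dataset.x).surviving_fraction
    raise ValueError(f"unknown endpoint kind {dataset.kind!r}")  # pragma: no cover


# --------------------------------------------------------------------------
# study design for synthetic data
# --------------------------------------------------------------------------

_HUMAN = CellPhenotype(name="human_competent")
_HUMAN_NHEJ = CellPhenotype(name="human_nhej_def", nhej_competent=False)
_HUMAN_HR = CellPhenotype(name="human_hr_def", hr_competent=False)
_HAMSTER = CellPhenotype(
    name="hamster", genome_gbp=4.8, n_chromosomes=21, g1_checkpoint_competent=False
)

# Hprt-style assay target.  Neither the gene length nor the largest
# survivable deletion is a model constant; both are experiment inputs, and
# these synthetic placeholder values only define the simulated assay.
_SYNTH_GENE = MutationQuery(gene_bp=34e3, b_max_bp=5.8e6)

_FOCI_TIMES = np.array([0.25, 0.5, 1, 2, 4, 8, 16, 24, 48, 96, 192, 300])
_MISREPAIR_DOSES = np.array([5.0, 10, 20, 40, 60, 80])
_ABERRATION_DOSES = np.array([0.5, 1, 2, 3, 4, 6, 8, 10])
_PCC_TIMES = np.array([0.5, 1, 2, 4, 8, 16, 24])
_MUTATION_DOSES = np.array([1.0, 2, 4, 6, 8, 10])
_SURVIVAL_DOSES = np.array([0.5, 1, 2, 3, 4, 5, 6, 8])


def default_design() -> list[EndpointDataset]:
    """The synthetic study design: conditions mirroring the endpoint mix
    the model is meant to be constrained by (measurements left empty)."""
    design: list[EndpointDataset] = []
    for ph, phase, study, scaling in [
        (_HUMAN, Phase.G1, "study_a", 1.70),
        (_HUMAN_NHEJ, Phase.G1, "study_a", 1.70),
        (_HUMAN, Phase.G2, "study_b", 1.02),
        (_HUMAN_NHEJ, Phase.G2, "study_b", 1.02),
        (_HUMAN_HR, Phase.G2, "study_b", 1.02),
    ]:
        design.append(
            EndpointDataset(
                kind="foci_timecourse",
                phenotype=ph,
                phase=phase,
                x=_FOCI_TIMES,
                dose=2.0,
                name=f"foci_{ph.name}_{phase.value}",
                scaling_group=study,
                foci_scaling=scaling,
            )
        )
    design.append(
        EndpointDataset(
            kind="misrepair_fraction",
            phenotype=_HUMAN,
            phase=Phase.G1,
            x=_MISREPAIR_DOSES,
            name="misrepair_human_G1",
        )
    )
    for ph in (_HUMAN, _HUMAN_NHEJ, _HAMSTER):
        design.append(
            EndpointDataset(
                kind="aberrations_vs_dose",
                phenotype=ph,
                phase=Phase.G1,
                x=_ABERRATION_DOSES,
                name=f"aberrations_{ph.name}_G1",
            )
        )
    for dose in (2.0, 6.0):
        design.append(
            EndpointDataset(
                kind="aberrations_vs_time",
                phenotype=_HUMAN,
                phase=Phase.G2,
                x=_PCC_TIMES,
                dose=dose,
                name=f"pcc_human_G2_{dose:g}Gy",
            )
        )
    design.append(
        EndpointDataset(
            kind="mutations_vs_dose",
            phenotype=_HAMSTER,
            phase=Phase.G1,
            x=_MUTATION_DOSES,
            gene=_SYNTH_GENE,
            name="hprt_hamster_G1",
        )
    )
    return design


def survival_design() -> list[EndpointDataset]:
    """Survival conditions for the second-stage (death-sensitivity) fit."""
    return [
        EndpointDataset(
            kind="survival_vs_dose",
            phenotype=_HUMAN,
            phase=Phase.G1,
            x=_SURVIVAL_DOSES,
            cycling=True,
            plating=Plating.IMMEDIATE,
            name="survival_human_G1_cycling",
        ),
        EndpointDataset(
            kind="survival_vs_dose",
            phenotype=_HUMAN,
            phase=Phase.M,
            x=np.array([0.25, 0.5, 1.0, 1.5, 2.0, 3.0]),
            name="survival_human_M",
        ),
        EndpointDataset(
            kind="survival_vs_dose",
            phenotype=_HAMSTER,
            phase=Phase.G2,
            x=_SURVIVAL_DOSES,
            cycling=True,
            name="survival_hamster_G2",
        ),
    ]


def generate_synthetic_datasets(
    true_params: ModelParameters | None = None,
    design: list[EndpointDataset] | None = None,
    noise_relative: float = 0.05,
    seed: int = 0,
) -> list[EndpointDataset]:
    """Evaluate the forward model over a design and add relative noise.

    Measurements are ``y = model * (1 + noise_relative * N(0,1))`` with
    attached uncertainties ``noise_relative * |model|``, floored at a small
    positive value (5% of the dataset's median magnitude) so that points
    near zero cannot acquire unbounded weight.  Deterministic under
    ``seed``.
    """
    if true_params is None:
        true_params = ModelParameters()
    if design is None:
        design = default_design()
    if not design:
        raise ValueError("design must contain at least one dataset")
    if noise_relative < 0:
        raise ValueError("noise_relative must be non-negative")
    rng = np.random.default_rng(seed)
    out = []
    for ds in design:
        model = predict_dataset(true_params, ds)
        floor = 0.05 * float(np.median(np.abs(model))) + 1e-12
        sd = np.maximum(noise_relative * np.abs(model), noise_relative * floor)
        if noise_relative == 0:
            sd = np.full_like(model, max(floor, 1e-12))
            y = model.copy()
        else:
            y = model * (1.0 + noise_relative * rng.standard_normal(model.shape))
        out.append(ds.with_measurements(y, sd))
    return out


# --------------------------------------------------------------------------
# joint fitting
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    """Outcome of a joint weighted least-squares fit."""

    parameters: ModelParameters
    sd: dict[str, float]
    free_names: tuple[str, ...]
    covariance: np.ndarray
    wrss: float
    n_points: int
    success: bool
    message: str
    foci_scalings: dict[str, float]

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "parameter": name,
                "value": getattr(self.parameters, name),
                "sd": self.sd[name],
            }
            for name in self.free_names
        ]
        for group, value in self.foci_scalings.items():
            rows.append({"parameter": f"foci_scale[{group}]", "value": value,
                         "sd": self.sd.get(f"foci_scale[{group}]", float("nan"))})
        return pd.DataFrame(rows)


def _default_free(datasets: list[EndpointDataset]) -> tuple[str, ...]:
    only_survival = all(ds.kind == "survival_vs_dose" for ds in datasets)
    if only_survival:
        return tuple(ModelParameters.SURVIVAL_FIT_PARAMETERS)
    return tuple(ModelParameters.DNA_FIT_PARAMETERS)


def joint_fit(
    datasets: list[EndpointDataset],
    initial_params: ModelParameters | None = None,
    fixed: tuple[str, ...] = (),
    free: tuple[str, ...] | None = None,
    fit_foci_scalings: bool = False,
    n_starts: int = 5,
    seed: int = 0,
) -> FitResult:
    """Simultaneous weighted nonlinear least squares across endpoints.

    Minimises ``sum(((y - model) / sd)^2)`` over the free parameters
    (by default the nine DNA-repair parameters, or the two death
    sensitivities when only survival data are supplied; any subset may be
    frozen via ``fixed``).  With ``fit_foci_scalings``, one counting-scale
    factor per foci ``scaling_group`` is estimated alongside.  Multi-start:
    the supplied initial point plus ``n_starts - 1`` log-jittered variants,
    keeping the best optimum.  The covariance (and the reported one-sigma
    uncertainties) comes from the Jacobian at the optimum, treating the
    supplied uncertainties as absolute.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    for ds in datasets:
        if not ds.y.size or not ds.sd.size:
            raise ValueError(f"dataset {ds.name!r} carries no measurements")
    if initial_params is None:
        initial_params = ModelParameters()
    if free is None:
        free = _default_free(datasets)
    free = tuple(name for name in free if name not in fixed)
    if not free and not fit_foci_scalings:
        raise ValueError("no free parameters left to fit")
    unknown = [n for n in free if n not in PARAMETER_BOUNDS]
    if unknown:
        raise ValueError(f"cannot fit unknown parameters: {unknown}")

    scale_groups: list[str] = []
    if fit_foci_scalings:
        scale_groups = sorted(
            {
                ds.scaling_group
                for ds in datasets
                if ds.kind == "foci_timecourse" and ds.scaling_group
            }
        )
    names = list(free) + [f"foci_scale[{g}]" for g in scale_groups]

    x0 = np.array(
        [getattr(initial_params, n) for n in free] + [1.0] * len(scale_groups)
    )
    lower = np.array([PARAMETER_BOUNDS[n][0] for n in free] + [0.05] * len(scale_groups))
    upper = np.array([PARAMETER_BOUNDS[n][1] for n in free] + [20.0] * len(scale_groups))

    def residuals(vec: np.ndarray) -> np.ndarray:
        updates = dict(zip(free, vec[: len(free)]))
        scalings = dict(zip(scale_groups, vec[len(free):]))
        try:
            params = initial_params.with_values(**updates)
        except ValueError:
            return np.full(n_points, 1e6)
        chunks = []
        for ds in datasets:
            scaling = None
            if ds.kind == "foci_timecourse" and ds.scaling_group in scalings:
                scaling = scalings[ds.scaling_group]
            pred = predict_dataset(params, ds, foci_scaling=scaling)
            chunks.append((ds.y - pred) / ds.sd)
        return np.concatenate(chunks)

    n_points = int(sum(ds.y.size for ds in datasets))
    rng = np.random.default_rng(seed)
    best = None
    for start in range(max(1, n_starts)):
        if start == 0:
            x_start = x0.copy()
        else:
            jitter = np.exp(rng.normal(0.0, 0.25, size=x0.size))
            x_start = np.clip(x0 * jitter, lower * 1.0001, upper * 0.9999)
        try:
            sol = least_squares(
                residuals,
                x_start,
                bounds=(lower, upper),
                x_scale=np.maximum(np.abs(x0), 1e-4),
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-10,
                max_nfev=400 * x0.size,
            )
        except Exception as exc:  # optimiser blow-up on a bad start
            logger.warning("fit start %d failed: %s", start, exc)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError("all fit starts failed; see log for diagnostics")

    jac = best.jac
    try:
        cov = np.linalg.inv(jac.T @ jac)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jac.T @ jac)
    sd_vec = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    sd = {name: float(v) for name, v in zip(names, sd_vec)}
    values = {name: float(v) for name, v in zip(free, best.x[: len(free)])}
    scalings = {g: float(v) for g, v in zip(scale_groups, best.x[len(free):])}
    success = bool(best.status > 0)
    if not success:
        logger.warning("fit did not converge: %s", best.message)
    return FitResult(
        parameters=initial_params.with_values(**values),
        sd=sd,
        free_names=tuple(free),
        covariance=cov,
        wrss=float(2.0 * best.cost),
        n_points=n_points,
        success=success,
        message=str(best.message),
        foci_scalings=scalings,
    )


# --------------------------------------------------------------------------
# MID stratification
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MIDStratification:
    """Observed-versus-modelled mean inactivation doses across conditions."""

    table: pd.DataFrame
    slope: float
    intercept: float
    r_squared: float


def mid_stratification(
    pred_curves: dict[str, tuple[np.ndarray, np.ndarray]],
    obs_datasets: dict[str, tuple[np.ndarray, np.ndarray]],
) -> MIDStratification:
    """Compare mean inactivation doses of matched survival curves.

    Both mappings are keyed by condition; every observed key must have a
    model counterpart.  Returns the paired MID table plus the ordinary
    least-squares slope, intercept and R^2 of observed on modelled MID.
    """
    missing = sorted(set(obs_datasets) - set(pred_curves))
    if missing:
        raise KeyError(f"no model prediction for conditions: {missing}")
    keys = sorted(obs_datasets)
    if len(keys) < 2:
        raise ValueError("MID comparison needs at least two matched conditions")
    rows = []
    for key in keys:
        d_obs, s_obs = obs_datasets[key]
        d_mod, s_mod = pred_curves[key]
        rows.append(
            {
                "condition": key,
                "mid_observed_gy": mean_inactivation_dose(d_obs, s_obs),
                "mid_model_gy": mean_inactivation_dose(d_mod, s_mod),
            }
        )
    table = pd.DataFrame(rows)
    x = table["mid_model_gy"].to_numpy()
    y = table["mid_observed_gy"].to_numpy()
    slope, intercept = np.polyfit(x, y, 1)
    fitted = slope * x + intercept
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return MIDStratification(
        table=table, slope=float(slope), intercept=float(intercept), r_squared=r2
    )
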
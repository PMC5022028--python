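"""Model parameters, cell phenotype and exposure descriptions.

The mechanistic model is characterised by a single set of constants shared
across all cell lines (the eleven fitted mechanistic parameters plus a small
number of fixed constants), combined with a description of the particular
cell (genome size, chromosome number, repair-pathway defects) and of the
exposure (dose, cell-cycle phase, assay time).  This module holds those
descriptions and the two elementary calculations that combine them: the
initial double-strand-break (DSB) yield and the partition of breaks between
the three repair classes (fast NHEJ, slow HR/complex, very slow MMEJ).
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from enum import Enum

__all__ = [
    "Phase",
    "ModelParameters",
    "CellPhenotype",
    "ExposureScenario",
    "RepairFractions",
    "initial_dsb_count",
    "assign_repair_fractions",
]


class Phase(str, Enum):
    """Cell-cycle phase at the moment of irradiation."""

    G1 = "G1"
    G2 = "G2"
    M = "M"

    @classmethod
    def coerce(cls, value: "Phase | str") -> "Phase":
        if isinstance(value, Phase):
            return value
        try:
            return cls(str(value).upper())
        except ValueError:
            raise ValueError(
                f"unsupported cell-cycle phase {value!r}; expected one of "
                f"{[p.value for p in cls]} (S phase is not modelled)"
            ) from None


@dataclass(frozen=True)
class ModelParameters:
    """Mechanistic model constants.

    The nine DNA-repair parameters (``lambda_fast`` ... ``nu``) and the two
    death sensitivities are fitted quantities; their defaults are the
    reference best-fit values.  The remaining fields are fixed model
    constants (the per-Gbp DSB induction rate, the geometric constants of
    the skew correction, the asymmetric-exchange probability, the
    Giemsa-visibility threshold, the G2 checkpoint-release threshold and
    the foci-appearance lag).

    Units
    -----
    induction_rate          DSB / Gy / Gbp
    lambda_fast/slow/mmej   1 / hour
    p_complex, p_fail       probability
    sigma                   nuclear radii (nucleus radius normalised to 1)
    mu_nhej, mu_mmej, nu    probability
    mitosis_sensitivity     1 / break (death rate per DSB carried into mitosis)
    arrest_sensitivity      1 / break (G1 arrest/apoptosis rate per induced DSB)
    deletion_visibility_bp  base pairs
    checkpoint_threshold    DSB count
    foci_lag_h              hours
    """

    # -- fitted DNA-repair parameters -------------------------------------
    lambda_fast: float = 3.6
    lambda_slow: float = 0.15
    lambda_mmej: float = 0.0084
    p_complex: float = 0.42
    p_fail: float = 0.67
    sigma: float = 0.0428
    mu_nhej: float = 0.985
    mu_mmej: float = 0.465
    nu: float = 0.044
    # -- fitted survival parameters ----------------------------------------
    mitosis_sensitivity: float = 0.014
    arrest_sensitivity: float = 0.0085
    # -- fixed model constants ---------------------------------------------
    induction_rate: float = 5.738
    geom_A: float = 0.757
    geom_B: float = 5.39
    p_asym: float = 0.5
    deletion_visibility_bp: float = 3.0e6
    checkpoint_threshold: float = 20.0
    foci_lag_h: float = 7.5 / 60.0

    DNA_FIT_PARAMETERS = (
        "lambda_fast",
        "lambda_slow",
        "lambda_mmej",
        "p_complex",
        "p_fail",
        "sigma",
        "mu_nhej",
        "mu_mmej",
        "nu",
    )
    SURVIVAL_FIT_PARAMETERS = ("mitosis_sensitivity", "arrest_sensitivity")

    def __post_init__(self) -> None:
        for name in ("p_complex", "p_fail", "mu_nhej", "mu_mmej", "nu", "p_asym"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]; got {value}")
        for name in (
            "lambda_fast",
            "lambda_slow",
            "lambda_mmej",
            "sigma",
            "induction_rate",
        ):
            value = getattr(self, name)
            if value <= 0.0:
                raise ValueError(f"{name} must be positive; got {value}")
        for name in (
            "mitosis_sensitivity",
            "arrest_sensitivity",
            "deletion_visibility_bp",
            "checkpoint_threshold",
            "foci_lag_h",
        ):
            if getattr(self, name) < 0.0:
                raise ValueError(f"{name} must be non-negative")

    def with_values(self, **updates: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **updates)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, values: dict) -> "ModelParameters":
        known = {f.name for f in fields(cls)}
        unknown = set(values) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**values)


@dataclass(frozen=True)
class CellPhenotype:
    """Cell-line description.

    ``genome_gbp`` is the G1 (unreplicated) DNA content in Gbp;
    ``n_chromosomes`` the chromosome count in G1.  Pathway competence flags
    declare whether NHEJ and HR are functional, and
    ``g1_checkpoint_competent`` whether the cell mounts a G1 arrest
    (p53-proficient).  The nucleus radius is normalised to 1; all spatial
    quantities (``sigma``, separations) are expressed in these units.
    """

    genome_gbp: float = 6.1
    n_chromosomes: int = 46
    nhej_competent: bool = True
    hr_competent: bool = True
    g1_checkpoint_competent: bool = True
    nucleus_radius: float = 1.0
    name: str = "generic"

    def __post_init__(self) -> None:
        if self.genome_gbp <= 0:
            raise ValueError("genome_gbp must be positive")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be at least 1")
        if self.nucleus_radius <= 0:
            raise ValueError("nucleus_radius must be positive")

    def dna_content_gbp(self, phase: "Phase | str") -> float:
        """DNA content at a given phase, Gbp.

        G2 and M carry the replicated genome, taken as exactly twice the G1
        content.
        """
        phase = Phase.coerce(phase)
        return self.genome_gbp if phase is Phase.G1 else 2.0 * self.genome_gbp


class DoseRateMode(str, Enum):
    ACUTE = "acute"
    LOW_DOSE_RATE = "low_dose_rate"


class Plating(str, Enum):
    DELAYED = "delayed"
    IMMEDIATE = "immediate"


@dataclass(frozen=True)
class ExposureScenario:
    """A single irradiation condition."""

    dose: float
    phase: Phase = Phase.G1
    assay_time_h: float = float("inf")
    dose_rate_mode: DoseRateMode = DoseRateMode.ACUTE
    plating: Plating = Plating.DELAYED
    cycling: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase", Phase.coerce(self.phase))
        object.__setattr__(self, "dose_rate_mode", DoseRateMode(self.dose_rate_mode))
        object.__setattr__(self, "plating", Plating(self.plating))
        if self.dose < 0:
            raise ValueError(f"dose must be non-negative; got {self.dose}")
        if self.assay_time_h < 0:
            raise ValueError("assay_time_h must be non-negative")


@dataclass(frozen=True)
class RepairFractions:
    """Partition of breaks between the three kinetic repair classes.

    ``p_f`` is the fraction repaired with fast kinetics (simple breaks via
    NHEJ), ``p_s`` with slow kinetics (complex breaks, via HR when available
    and NHEJ otherwise) and ``p_m`` with very slow MMEJ kinetics.  The
    fractions always sum to one.  ``slow_is_hr`` records whether the slow
    class is handled by HR (which repairs with perfect fidelity) in this
    condition.
    """

    p_f: float
    p_s: float
    p_m: float
    slow_is_hr: bool = False

    def __post_init__(self) -> None:
        total = self.p_f + self.p_s + self.p_m
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"repair fractions must sum to 1; got {total}")
        if min(self.p_f, self.p_s, self.p_m) < 0:
            raise ValueError("repair fractions must be non-negative")


def initial_dsb_count(
    dose: float,
    phenotype: CellPhenotype,
    phase: "Phase | str" = Phase.G1,
    params: ModelParameters | None = None,
) -> float:
    """Expected initial DSB yield for an acute exposure.

    The yield is linear in dose and in DNA content, ``N0 = k * D * L`` with
    ``k`` the per-Gbp induction constant (5.738 DSB/Gy/Gbp, fixed from the
    measured ~35 DSB/Gy in 6.1-Gbp human G1 cells).  Cells in G2 or M carry
    the replicated genome and receive twice the G1 yield.  The result is an
    expectation (a real number); integer sampling belongs to the Monte
    Carlo simulator only.
    """
    if params is None:
        params = ModelParameters()
    if dose < 0:
        raise ValueError(f"dose must be non-negative; got {dose}")
    return params.induction_rate * dose * phenotype.dna_content_gbp(phase)


def assign_repair_fractions(
    phenotype: CellPhenotype,
    phase: "Phase | str",
    params: ModelParameters | None = None,
) -> RepairFractions:
    """Partition breaks between fast, slow and MMEJ repair classes.

    Breaks are simple with probability ``1 - p_complex`` (preferring fast
    NHEJ in every phase) or complex with probability ``p_complex``
    (preferring HR in G2 when available, and slow NHEJ otherwise).  When a
    break's preferred pathway is defective, a fraction ``p_fail`` of that
    class fails outright and is diverted to MMEJ; the remainder retains its
    class kinetics (residual activity of the impaired pathway).  The full
    competence-by-phase table follows from applying that single rule to
    both break classes:

    ====================  =======================  =====================
    condition             fast class               slow class
    ====================  =======================  =====================
    competent, G1         (1-pc)                   pc            (NHEJ)
    competent, G2/M       (1-pc)                   pc            (HR)
    NHEJ-def, G1          (1-pc)(1-pfail)          pc (1-pfail)  (NHEJ)
    NHEJ-def, G2/M        (1-pc)(1-pfail)          pc            (HR)
    HR-def, G1            (1-pc)                   pc            (NHEJ)
    HR-def, G2/M          (1-pc)                   pc (1-pfail)  (NHEJ*)
    both def, G1          (1-pc)(1-pfail)          pc (1-pfail)
    both def, G2/M        (1-pc)(1-pfail)          pc (1-pfail)
    ====================  =======================  =====================

    with ``p_m`` the complement in every row.  (*) complex breaks that
    would have used HR fall back to slow NHEJ repair, so their residual
    fidelity is the NHEJ fidelity, not HR's perfect fidelity.
    """
    if params is None:
        params = ModelParameters()
    phase = Phase.coerce(phase)
    pc, pfail = params.p_complex, params.p_fail

    # Fast class: simple breaks always prefer NHEJ.
    p_f = (1.0 - pc) * (1.0 if phenotype.nhej_competent else 1.0 - pfail)

    # Slow class: complex breaks prefer HR in G2/M, slow NHEJ in G1.
    hr_available = phase in (Phase.G2, Phase.M) and phenotype.hr_competent
    if hr_available:
        p_s = pc
        slow_is_hr = True
    else:
        # Complex breaks handled by NHEJ; a NHEJ defect (G1) or the HR
        # defect itself (G2) diverts a p_fail share to MMEJ.
        preferred_ok = (
            phenotype.nhej_competent
            if phase is Phase.G1
            else phenotype.hr_competent and phenotype.nhej_competent
        )
        if phase is not Phase.G1 and not phenotype.hr_competent:
            # HR is the preferred pathway in G2/M: its defect triggers the
            # diversion regardless of NHEJ status.
            preferred_ok = False
        p_s = pc * (1.0 if preferred_ok else 1.0 - pfail)
        slow_is_hr = False

    p_m = 1.0 - p_f - p_s
    # Guard against floating-point drift before the dataclass invariant check.
    if abs(p_m) < 1e-15:
        p_m = 0.0
    return RepairFractions(p_f=p_f, p_s=p_s, p_m=p_m, slow_is_hr=slow_is_hr)
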
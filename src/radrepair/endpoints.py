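"""Observable damage endpoints: misrepair, aberrations and mutations.

The repair kinetics say *when* breaks are repaired; the geometry says how
often a repairing break misrejoins and how far apart the misrejoined ends
were.  This module combines the two into the yields that assays actually
see:

* misrepaired DSBs as a function of time,
* dicentrics (asymmetric inter-chromosome exchanges) and deletions
  (asymmetric intra-chromosome exchanges), with the deletion-size spectrum
  and a visibility threshold (Giemsa resolves deletions above ~3 Mbp),
* inter-arm (centromere-spanning) aberrations, visible in G2 assays,
* gene mutation rates: gene-spanning deletions, intra-gene misrepair, and
  point mutations from imperfect but correctly-targeted rejoining.

Counts are expectations per cell.  In low-dose-rate mode DSBs are too
sparse in time to interact, which is modelled by forcing the pairwise
misrejoining propensity ``eta`` to zero: only the base infidelity of each
repair process remains and every yield becomes linear in dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import geometry as geom
from .kinetics import repaired_increment
from .parameters import (
    CellPhenotype,
    DoseRateMode,
    ExposureScenario,
    ModelParameters,
    Phase,
    RepairFractions,
    assign_repair_fractions,
    initial_dsb_count,
)

__all__ = [
    "AberrationYields",
    "MutationQuery",
    "MutationYields",
    "misrepaired_count",
    "dicentrics_and_deletions",
    "deletions_above",
    "interarm_rate",
    "aberration_yields",
    "gene_mutation_rate",
]

_GBP = 1.0e9


def _class_fidelities(fractions: RepairFractions) -> dict[str, str]:
    """Repair process handling each kinetic class (for fidelity lookup)."""
    return {
        "fast": "NHEJ",
        "slow": "HR" if fractions.slow_is_hr else "NHEJ",
        "mmej": "MMEJ",
    }


def _eta_for(scenario: ExposureScenario, n0: float, phenotype: CellPhenotype,
             params: ModelParameters) -> float:
    if scenario.dose_rate_mode is DoseRateMode.LOW_DOSE_RATE:
        return 0.0
    return geom.eta(n0, params.sigma, phenotype.nucleus_radius, params)


def misrepaired_count(
    t: float,
    scenario: ExposureScenario,
    phenotype: CellPhenotype,
    params: ModelParameters | None = None,
) -> float:
    """Expected number of misrepaired DSBs by time ``t`` (hours).

    Each kinetic class contributes its repaired-by-``t`` count times that
    class's misrepair probability ``1 - P_correct``, where ``P_correct``
    combines the spatial propensity ``eta`` (evaluated at the initial break
    count, which sets the wrong-end field the break saw) with the handling
    process's base fidelity.  HR repairs without error, so a slow class
    routed through HR contributes nothing.
    """
    if params is None:
        params = ModelParameters()
    if t < 0:
        raise ValueError("time must be non-negative")
    n0 = initial_dsb_count(scenario.dose, phenotype, scenario.phase, params)
    if n0 == 0.0:
        return 0.0
    fractions = assign_repair_fractions(phenotype, scenario.phase, params)
    eta_value = _eta_for(scenario, n0, phenotype, params)
    processes = _class_fidelities(fractions)
    total = 0.0
    for cls in ("fast", "slow", "mmej"):
        repaired = repaired_increment(0.0, t, cls, n0, fractions, params)
        p_ok = geom.p_correct(eta_value, processes[cls], params)
        total += repaired * (1.0 - p_ok)
    return total


def dicentrics_and_deletions(
    n_mis: float,
    p_intra_value: float,
    params: ModelParameters | None = None,
) -> tuple[float, float]:
    """Split misrepaired breaks into dicentrics and total deletions.

    Only asymmetric exchanges (probability ``p_asym = 0.5``; rejoining is
    blind to fragment orientation) yield these lesions:

        N_dic = p_asym * (1 - P_intra) * N_mis
        N_del = p_asym * P_intra * N_mis
    """
    if params is None:
        params = ModelParameters()
    if n_mis < 0:
        raise ValueError("n_mis must be non-negative")
    if not 0.0 <= p_intra_value <= 1.0:
        raise ValueError("p_intra_value must lie in [0, 1]")
    n_dic = params.p_asym * (1.0 - p_intra_value) * n_mis
    n_del = params.p_asym * p_intra_value * n_mis
    return n_dic, n_del


def deletions_above(
    size_bp: float,
    n_del_total: float,
    geometry: geom.GeometryContext,
    params: ModelParameters | None = None,
) -> float:
    """Expected deletions larger than ``size_bp``.

    Uses the generalised (separation-truncated) theta over the chromosome
    sub-volume; non-increasing in the threshold, equal to the total at 0.
    """
    if params is None:
        params = ModelParameters()
    if n_del_total < 0:
        raise ValueError("n_del_total must be non-negative")
    return n_del_total * geom.deletion_fraction_above(size_bp, geometry)


def _mean_spanning_integral(
    gene_bp: float,
    b_max_bp: float,
    geometry: geom.GeometryContext,
    n_grid: int = 512,
) -> float:
    """``int_0^{b_max} P(deletion size >= b + g) db`` in base pairs.

    The probability that a deletion whose nearest end sits ``b`` base pairs
    before a gene of length ``g`` spans the whole gene, integrated over all
    admissible offsets.
    """
    if b_max_bp <= 0:
        return 0.0
    b = np.linspace(0.0, b_max_bp, n_grid)
    frac = geom.deletion_fraction_above_many(b + gene_bp, geometry)
    return float(np.trapezoid(frac, b))


@dataclass(frozen=True)
class MutationQuery:
    """A mutation assay target: gene length and survivable-deletion cap."""

    gene_bp: float
    b_max_bp: float

    def __post_init__(self) -> None:
        if self.gene_bp < 0:
            raise ValueError("gene_bp must be non-negative")
        if self.b_max_bp <= 0:
            raise ValueError("b_max_bp must be positive")


@dataclass(frozen=True)
class MutationYields:
    """Expected mutation events per cell, by mechanism."""

    total_deletion: float
    intra_gene: float
    point: float

    @property
    def total(self) -> float:
        return self.total_deletion + self.intra_gene + self.point

    @property
    def point_fraction(self) -> float:
        return self.point / self.total if self.total > 0 else 0.0


def gene_mutation_rate(
    query: MutationQuery,
    scenario: ExposureScenario,
    phenotype: CellPhenotype,
    params: ModelParameters | None = None,
    t: float | None = None,
) -> MutationYields:
    """Expected mutation yields for a single gene.

    Three mechanisms:

    * gene-spanning deletions: for each offset ``b`` up to ``b_max`` (the
      largest deletion compatible with survival) before the gene start, the
      chance a deletion event covers the whole gene, normalised by the
      genome length;
    * intra-gene misrepair: every misrepair event whose break fell inside
      the gene (fraction ``g / L`` of misrepaired breaks);
    * point mutations: correctly rejoined breaks inside the gene mutate it
      with probability ``nu``.
    """
    if params is None:
        params = ModelParameters()
    if t is None:
        t = scenario.assay_time_h
    n0 = initial_dsb_count(scenario.dose, phenotype, scenario.phase, params)
    geometry = geom.GeometryContext.for_cell(phenotype, scenario.phase, params)
    # Breaks are spread over the full (phase-dependent) DNA content, so
    # per-genome normalisations use it; the deletion-size map inside
    # ``geometry`` stays chromatid-level.
    length_bp = phenotype.dna_content_gbp(scenario.phase) * _GBP
    n_mis = misrepaired_count(t, scenario, phenotype, params)
    p_in = geom.p_intra(geometry)
    _, n_del_total = dicentrics_and_deletions(n_mis, p_in, params)

    spanning = _mean_spanning_integral(query.gene_bp, query.b_max_bp, geometry)
    n_total_del = n_del_total * spanning / length_bp
    n_intra = n_mis * query.gene_bp / length_bp
    if math.isinf(t):
        n_repaired = n0
    else:
        fractions = assign_repair_fractions(phenotype, scenario.phase, params)
        from .kinetics import remaining_dsb

        n_repaired = n0 - remaining_dsb(t, n0, fractions, params)
    n_correct = max(0.0, n_repaired - n_mis)
    n_point = params.nu * n_correct * query.gene_bp / length_bp
    return MutationYields(
        total_deletion=n_total_del, intra_gene=n_intra, point=n_point
    )


def interarm_rate(
    scenario: ExposureScenario,
    phenotype: CellPhenotype,
    params: ModelParameters | None = None,
    t: float | None = None,
) -> float:
    """Expected inter-arm (centromere-spanning) aberrations, G2 only.

    The centromere-spanning analogue of the gene-spanning deletion rate
    with a zero-length target (``g = 0``): a deletion spans its
    chromosome's centromere when its start falls within one deletion length
    before it.  Integrating the size-survival function over offsets up to
    the mean chromosome length and normalising by the per-centromere genome
    share ``L / n_c = l_c`` gives the per-deletion spanning probability.
    These structures only become visible against the replicated sister
    chromatid, so the rate is defined for G2 exposures.
    """
    if params is None:
        params = ModelParameters()
    if scenario.phase is not Phase.G2:
        raise ValueError("inter-arm aberrations are modelled for G2 exposures only")
    if t is None:
        t = scenario.assay_time_h
    geometry = geom.GeometryContext.for_cell(phenotype, scenario.phase, params)
    n_mis = misrepaired_count(t, scenario, phenotype, params)
    p_in = geom.p_intra(geometry)
    _, n_del_total = dicentrics_and_deletions(n_mis, p_in, params)
    l_c_bp = geometry.mean_chromosome_gbp * _GBP
    spanning = _mean_spanning_integral(0.0, l_c_bp, geometry)
    return n_del_total * spanning / l_c_bp


@dataclass(frozen=True)
class AberrationYields:
    """Aberration yields for one condition at one assay time."""

    n_misrepaired: float
    n_dicentric: float
    n_deletion_total: float
    n_deletion_visible: float
    n_interarm: float
    visibility_threshold_bp: float

    @property
    def n_visible(self) -> float:
        """Total aberrations a Giemsa/PCC assay resolves."""
        return self.n_dicentric + self.n_deletion_visible + self.n_interarm


def aberration_yields(
    scenario: ExposureScenario,
    phenotype: CellPhenotype,
    params: ModelParameters | None = None,
    t: float | None = None,
) -> AberrationYields:
    """All aberration classes for a condition at time ``t``.

    ``t`` defaults to the scenario assay time; first-mitosis Giemsa assays
    correspond to complete repair (``t = inf``).  Inter-arm events are
    included for G2 exposures only.
    """
    if params is None:
        params = ModelParameters()
    if t is None:
        t = scenario.assay_time_h
    geometry = geom.GeometryContext.for_cell(phenotype, scenario.phase, params)
    n_mis = misrepaired_count(t, scenario, phenotype, params)
    p_in = geom.p_intra(geometry)
    n_dic, n_del = dicentrics_and_deletions(n_mis, p_in, params)
    n_vis = deletions_above(params.deletion_visibility_bp, n_del, geometry, params)
    if scenario.phase is Phase.G2:
        n_ia = interarm_rate(scenario, phenotype, params, t)
    else:
        n_ia = 0.0
    return AberrationYields(
        n_misrepaired=n_mis,
        n_dicentric=n_dic,
        n_deletion_total=n_del,
        n_deletion_visible=n_vis,
        n_interarm=n_ia,
        visibility_threshold_bp=params.deletion_visibility_bp,
    )
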
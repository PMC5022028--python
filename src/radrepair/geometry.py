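"""Analytic spatial misrejoining geometry.

Free DSB ends rejoin at a rate that falls off with their separation ``d``
as a Gaussian, ``zeta(d) = exp(-d^2 / 2 sigma^2)``, where ``sigma`` is the
characteristic rejoining range.  For breaks scattered uniformly through a
spherical nucleus this single assumption fixes, in closed or quadrature
form, everything the endpoint models need:

* ``theta`` -- the expected rejoining rate between two uniformly placed
  ends (the Gaussian kernel averaged over the pair-distance distribution
  of two uniform points in a sphere), optionally truncated at a maximum
  separation;
* ``eta`` -- the integral misrejoining propensity of one break embedded in
  a field of ``n0`` other breaks (wrong-end density x theta, with a skew
  correction ``omega`` for small sigma);
* ``p_intra`` -- the probability that a misrejoining joins ends from the
  same chromosome, with chromosomes idealised as spherical sub-volumes;
* the monotone map between the spatial separation of two misrejoined ends
  and the genomic size of the resulting deletion.

All lengths are expressed in units of the nucleus radius ``R`` (default 1);
the geometry is scale-free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import integrate

from .parameters import CellPhenotype, ModelParameters

__all__ = [
    "GeometryContext",
    "rejoining_kernel",
    "pair_distance_pdf",
    "theta",
    "omega",
    "eta",
    "misrepair_fraction_from_eta",
    "misrepair_fraction_exact",
    "eta_from_misrepair_fraction",
    "p_correct",
    "p_intra",
    "deletion_size_bp",
    "separation_for_deletion_size",
    "deletion_fraction_above",
    "deletion_fraction_above_many",
]

_GBP = 1.0e9  # base pairs per Gbp


@dataclass(frozen=True)
class GeometryContext:
    """Scale-free geometric description of a nucleus and its chromosomes.

    Chromosomes are idealised as ``n_chromosomes`` spherical sub-volumes of
    radius ``r_c = R * n_c**(-1/3)``, so that their total volume equals the
    nucleus volume.  ``genome_gbp`` is the chromatid-level (G1) DNA content
    that sets the separation-to-deletion-size map, and
    ``mean_chromosome_gbp = L / n_c``.
    """

    sigma: float
    nucleus_radius: float = 1.0
    n_chromosomes: int = 46
    genome_gbp: float = 6.1

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.nucleus_radius <= 0:
            raise ValueError("nucleus_radius must be positive")
        if self.n_chromosomes < 1:
            raise ValueError("n_chromosomes must be at least 1")
        if self.genome_gbp <= 0:
            raise ValueError("genome_gbp must be positive")

    @property
    def chromosome_radius(self) -> float:
        return self.nucleus_radius * self.n_chromosomes ** (-1.0 / 3.0)

    @property
    def mean_chromosome_gbp(self) -> float:
        return self.genome_gbp / self.n_chromosomes

    @classmethod
    def for_cell(
        cls,
        phenotype: CellPhenotype,
        phase,
        params: ModelParameters,
    ) -> "GeometryContext":
        """Geometry for a phenotype at a given cell-cycle phase.

        The chromosome count and the genomic length entering the
        separation-to-deletion-size map are kept at their chromatid-level
        (G1) values in every phase: a deletion joins two breaks along one
        DNA molecule, so the spatial-to-genomic conversion uses the
        chromatid's own linear density even after replication.  The larger
        break *number* in G2/M enters through the induced yield, not
        through the geometry.
        """
        del phase  # geometry is chromatid-level in every phase
        return cls(
            sigma=params.sigma,
            nucleus_radius=phenotype.nucleus_radius,
            n_chromosomes=phenotype.n_chromosomes,
            genome_gbp=phenotype.genome_gbp,
        )


def rejoining_kernel(d, sigma: float):
    """Relative rejoining rate between two ends separated by ``d``.

    ``zeta(d) = exp(-d^2 / (2 sigma^2))``: 1 for co-located ends, strictly
    decreasing, vanishing for ``d >> sigma``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("separation must be non-negative")
    out = np.exp(-(d * d) / (2.0 * sigma * sigma))
    return float(out) if out.ndim == 0 else out


def pair_distance_pdf(r, radius: float = 1.0):
    """Density of the distance between two independent uniform points in a
    sphere.

    The standard closed form ``f(r) = 3 r^2/R^3 - 9 r^3/(4 R^4)
    + 3 r^5/(16 R^6)`` on ``0 <= r <= 2R``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    r = np.asarray(r, dtype=float)
    x = r / radius
    out = np.where(
        (x >= 0) & (x <= 2.0),
        (3.0 * x**2 - 2.25 * x**3 + 0.1875 * x**5) / radius,
        0.0,
    )
    return float(out) if out.ndim == 0 else out


@lru_cache(maxsize=4096)
def _theta_cached(sigma: float, radius: float, r_max: float) -> float:
    upper = min(2.0 * radius, r_max)
    if upper <= 0.0:
        return 0.0
    # The integrand is negligible beyond a dozen rejoining ranges; clipping
    # the adaptive quadrature there keeps it well-conditioned for sigma << R.
    effective_upper = min(upper, 14.0 * sigma)
    if effective_upper <= 0.0:
        return 0.0
    value, _ = integrate.quad(
        lambda r: pair_distance_pdf(r, radius) * math.exp(-(r * r) / (2 * sigma**2)),
        0.0,
        effective_upper,
        epsabs=1e-12,
        epsrel=1e-10,
        limit=200,
    )
    return value


def theta(sigma: float, radius: float = 1.0, max_separation: float | None = None) -> float:
    """Expected rejoining rate between two uniform random ends in a sphere.

    ``theta = E[zeta(d)]`` with ``d`` the distance between two independent
    uniform points in a sphere of the given radius.  The generalised form
    truncates the expectation at ``max_separation`` (used for deletion-size
    spectra), so ``theta(...) >= theta(..., max_separation=s)`` and the full
    value is recovered for ``max_separation >= 2 * radius``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if radius <= 0:
        raise ValueError("radius must be positive")
    if max_separation is None:
        max_separation = 2.0 * radius
    if max_separation < 0:
        raise ValueError("max_separation must be non-negative")
    return _theta_cached(float(sigma), float(radius), float(max_separation))


def omega(
    sigma: float,
    n0: float | None = None,
    params: ModelParameters | None = None,
    radius: float = 1.0,
) -> float:
    """Skew correction to the mean-field misrejoining propensity.

    The misrejoining probability of one break is the expectation of
    ``S / (1 + S)`` over the random wrong-end kernel sum ``S``; replacing
    ``S`` by its mean overestimates misrepair because the distribution of
    ``S`` is strongly right-skewed when the rejoining range is small
    (misrepair is then dominated by rare close encounters).  ``omega``
    multiplies the mean-field propensity to absorb that gap:

        omega(sigma) = 1 - (1 - A) * exp(-B * sigma / R)

    which interpolates between a plateau ``A`` in the small-sigma limit and
    1 (no correction) when sigma is comparable to the nucleus radius.  The
    two geometric constants are recovered by matching the analytic model to
    Monte Carlo rejoining simulations (:func:`radrepair.mc.fit_geometry_constants`);
    their defaults are the reference best-fit values A = 0.757, B = 5.39.

    ``n0`` is accepted for interface stability (candidate corrections that
    depend on the break count collapse to sigma-only dependence after
    fitting) but does not enter the adopted form.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if params is None:
        params = ModelParameters()
    A, B = params.geom_A, params.geom_B
    return 1.0 - (1.0 - A) * math.exp(-B * sigma / radius)


def eta(
    n0: float,
    sigma: float | None = None,
    radius: float = 1.0,
    params: ModelParameters | None = None,
) -> float:
    """Integral misrejoining propensity of one break among ``n0`` others.

    ``eta = 2 * n0 * theta * omega``: the first factor is the number of
    wrong free ends competing with the break's own partner (two per other
    DSB), ``theta`` the mean kernel weight of one randomly placed wrong end
    relative to the co-located correct end (weight 1), and ``omega`` the
    small-sigma skew correction.  The misrepair probability implied by
    ``eta`` is ``eta / (1 + eta)`` (:func:`misrepair_fraction_from_eta`).
    """
    if params is None:
        params = ModelParameters()
    if sigma is None:
        sigma = params.sigma
    if n0 < 0:
        raise ValueError("n0 must be non-negative")
    if n0 == 0:
        return 0.0
    return 2.0 * n0 * theta(sigma, radius) * omega(sigma, n0, params, radius)


def misrepair_fraction_from_eta(eta_value: float) -> float:
    """Per-break misrepair probability implied by the propensity ``eta``.

    The break's two co-located ends (joint kernel weight 1) compete with a
    wrong-end field of total weight ``eta``, giving a misrejoining
    probability ``eta / (1 + eta)``.
    """
    if eta_value < 0:
        raise ValueError("eta must be non-negative")
    return eta_value / (1.0 + eta_value)


def eta_from_misrepair_fraction(fraction: float) -> float:
    """Inverse of :func:`misrepair_fraction_from_eta`."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("misrepair fraction must lie in [0, 1)")
    return fraction / (1.0 - fraction)


def _conditional_distance_pdf(r: np.ndarray, a: float) -> np.ndarray:
    """Density of the distance from a fixed point at radius ``a`` to a
    uniform point in the unit sphere.

    ``3 r^2`` while the shell of radius ``r`` lies fully inside the sphere,
    scaled by the inside-cap fraction once it protrudes.
    """
    out = np.zeros_like(r)
    inside = r <= max(1.0 - a, 0.0)
    out[inside] = 3.0 * r[inside] ** 2
    band = (~inside) & (r <= 1.0 + a) & (r > 0)
    if a > 0:
        rb = r[band]
        cos_half = (a * a + rb * rb - 1.0) / (2.0 * a * rb)
        frac = 0.5 * (1.0 - np.clip(cos_half, -1.0, 1.0))
        out[band] = 3.0 * rb**2 * frac
    return out


@lru_cache(maxsize=4096)
def _misrepair_fraction_exact_cached(
    n_other: float, sigma: float, n_t: int, n_a: int, n_r: int
) -> float:
    # Gauss-Legendre nodes for the three nested integrals.
    u_nodes, u_w = np.polynomial.legendre.leggauss(n_t)
    u = 0.5 * (u_nodes + 1.0)  # t = -log u maps (0, inf) -> (0, 1)
    u_w = 0.5 * u_w
    t = -np.log(u)
    a_nodes, a_w = np.polynomial.legendre.leggauss(n_a)
    a = 0.5 * (a_nodes + 1.0)
    a_w = 0.5 * a_w * 3.0 * a**2  # uniform focal radius weight
    psi = np.empty((n_a, n_t))
    for i, ai in enumerate(a):
        upper = min(1.0 + ai, 16.0 * sigma)
        r_nodes, r_w = np.polynomial.legendre.leggauss(n_r)
        r = 0.5 * upper * (r_nodes + 1.0)
        r_w = 0.5 * upper * r_w
        g = _conditional_distance_pdf(r, ai)
        zeta = np.exp(-(r * r) / (2.0 * sigma * sigma))
        # psi_a(t) = E[1 - e^{-t zeta}] restricted to the kernel's support
        psi[i] = ((1.0 - np.exp(-np.outer(t, zeta))) * (g * r_w)).sum(axis=1)
    phi_pow = np.exp(2.0 * n_other * np.log1p(-np.clip(psi, 0.0, 1.0 - 1e-300)))
    inner = (a_w[:, None] * phi_pow).sum(axis=0)
    return float(1.0 - (u_w * inner).sum())


def misrepair_fraction_exact(
    n_other: float,
    sigma: float,
    radius: float = 1.0,
    n_t: int = 96,
    n_a: int = 32,
    n_r: int = 256,
) -> float:
    """Exact mean-field misrepair probability of one break.

    The break's correct channel (weight 1) competes with the kernel-weight
    sum ``S`` of ``2 n_other`` independently, uniformly placed wrong ends,
    so it misrepairs with probability ``E[S / (1 + S)]``.  Using
    ``1/(1+S) = int_0^inf e^{-t(1+S)} dt`` and the independence of end
    positions given the focal position:

        F = 1 - int_0^inf e^-t E_x[ phi_x(t)^(2 n) ] dt,

    with ``phi_x(t)`` the Laplace transform of the kernel weight of one
    uniform end seen from a focal break at radius ``x``.  Evaluated by
    nested fixed-order Gauss-Legendre quadrature; this is the reference
    the Monte Carlo field simulation is tested against, and what the
    closed-form ``eta * omega`` expression approximates.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n_other < 0:
        raise ValueError("n_other must be non-negative")
    if n_other == 0:
        return 0.0
    sigma = sigma / radius  # scale-free
    return _misrepair_fraction_exact_cached(float(n_other), float(sigma), n_t, n_a, n_r)


_PROCESS_FIDELITY = {"NHEJ": "mu_nhej", "MMEJ": "mu_mmej"}


def p_correct(
    eta_value: float,
    process: str,
    params: ModelParameters | None = None,
) -> float:
    """Probability that a break repaired by ``process`` rejoins correctly.

    Homologous recombination uses the sister chromatid as template and is
    taken to always complete successfully (``P = 1``, no spatial term).
    NHEJ and MMEJ combine the spatial misrejoining probability with a
    process-specific base fidelity ``mu_x``:

        P_correct = mu_x / (1 + eta)
    """
    if params is None:
        params = ModelParameters()
    if eta_value < 0:
        raise ValueError("eta must be non-negative")
    key = str(process).upper()
    if key == "HR":
        return 1.0
    try:
        mu = getattr(params, _PROCESS_FIDELITY[key])
    except KeyError:
        raise ValueError(
            f"unknown repair process {process!r}; expected NHEJ, HR or MMEJ"
        ) from None
    return mu / (1.0 + eta_value)


def p_intra(geometry: GeometryContext, sigma: float | None = None) -> float:
    """Probability that a misrejoining is an intra-chromosome event.

    The ratio of the rejoining rate within the break's own chromosome
    sub-volume to the rate across the whole nucleus:

        P_intra = theta(sigma, r_c) / (n_c * theta(sigma, R))

    (the ``1/n_c`` is the fraction of wrong ends resident in the same
    sub-volume).  Equal to 1 for a single chromosome; tends to ``1/n_c``
    when sigma is much larger than the nucleus, where partner choice is
    uniform; approaches 1 again as sigma -> 0, where the partner is almost
    surely a near neighbour in the same territory.
    """
    if sigma is None:
        sigma = geometry.sigma
    num = theta(sigma, geometry.chromosome_radius)
    den = geometry.n_chromosomes * theta(sigma, geometry.nucleus_radius)
    return min(1.0, num / den)


def deletion_size_bp(r_d, genome_gbp: float, radius: float = 1.0):
    """Genomic size of a deletion whose ends were separated by ``r_d``.

    Genomic separation is taken to grow monotonically with spatial
    separation, with the DNA content of the enclosed volume as the measure:
    a separation equal to the chromosome sub-volume radius
    ``r_c = R n_c^{-1/3}`` maps exactly onto one mean chromosome length.

        size(r_d) = L * (r_d / R)^3   (L in Gbp, size returned in bp)
    """
    r_arr = np.asarray(r_d, dtype=float)
    if np.any(r_arr < 0) or np.any(r_arr > 2.0 * radius):
        raise ValueError("separation must lie in [0, 2R]")
    out = genome_gbp * _GBP * (r_arr / radius) ** 3
    return float(out) if out.ndim == 0 else out


def separation_for_deletion_size(size_bp, genome_gbp: float, radius: float = 1.0):
    """Inverse of :func:`deletion_size_bp` (clipped at ``2R``)."""
    s = np.asarray(size_bp, dtype=float)
    if np.any(s < 0):
        raise ValueError("deletion size must be non-negative")
    out = np.minimum(radius * (s / (genome_gbp * _GBP)) ** (1.0 / 3.0), 2.0 * radius)
    return float(out) if out.ndim == 0 else out


@lru_cache(maxsize=1024)
def _theta_cumulative_grid(sigma: float, radius: float, n_grid: int = 4096):
    """Cumulative kernel-weighted pair-distance integral on a fine grid.

    Returns ``(r, C(r))`` with ``C(r) = int_0^r f(x) zeta(x) dx`` evaluated
    by trapezoid on a grid that resolves the kernel scale; used to
    vectorise deletion-size spectra where per-threshold adaptive
    quadrature would be wasteful.
    """
    upper = min(2.0 * radius, 14.0 * sigma)
    r = np.linspace(0.0, upper, n_grid)
    integrand = pair_distance_pdf(r, radius) * np.exp(-(r * r) / (2.0 * sigma**2))
    c = np.concatenate(
        [[0.0], np.cumsum(0.5 * (integrand[1:] + integrand[:-1]) * np.diff(r))]
    )
    return r, c


def deletion_fraction_above_many(
    sizes_bp,
    geometry: "GeometryContext",
    sigma: float | None = None,
) -> np.ndarray:
    """Vectorised :func:`deletion_fraction_above` over many thresholds.

    Interpolates a cached cumulative integral of the kernel-weighted
    pair-distance density over the chromosome sub-volume; agrees with the
    adaptive-quadrature path to a few parts in 1e6.
    """
    if sigma is None:
        sigma = geometry.sigma
    sizes = np.atleast_1d(np.asarray(sizes_bp, dtype=float))
    if np.any(sizes < 0):
        raise ValueError("size thresholds must be non-negative")
    r_c = geometry.chromosome_radius
    grid_r, grid_c = _theta_cumulative_grid(float(sigma), float(r_c))
    full = grid_c[-1]
    if full <= 0.0:
        return np.zeros_like(sizes)
    r_d = separation_for_deletion_size(
        sizes, geometry.genome_gbp, geometry.nucleus_radius
    )
    truncated = np.interp(np.minimum(r_d, grid_r[-1]), grid_r, grid_c)
    return np.clip(1.0 - truncated / full, 0.0, 1.0)


def deletion_fraction_above(
    size_bp: float,
    geometry: GeometryContext,
    sigma: float | None = None,
) -> float:
    """Fraction of intra-chromosome misrejoinings larger than ``size_bp``.

    Deletion-forming ends live in the same chromosome sub-volume, so the
    separation spectrum is the kernel-weighted pair-distance distribution
    over a sphere of radius ``r_c``; the fraction above a genomic size uses
    the generalised (truncated) theta at the corresponding separation:

        frac_above(D) = 1 - theta(sigma, r_c, r_D) / theta(sigma, r_c)
    """
    if sigma is None:
        sigma = geometry.sigma
    if size_bp < 0:
        raise ValueError("size threshold must be non-negative")
    if size_bp == 0:
        return 1.0
    r_d = separation_for_deletion_size(
        size_bp, geometry.genome_gbp, geometry.nucleus_radius
    )
    r_c = geometry.chromosome_radius
    full = theta(sigma, r_c)
    if full == 0.0:
        return 0.0
    truncated = theta(sigma, r_c, max_separation=min(r_d, 2.0 * r_c))
    return max(0.0, 1.0 - truncated / full)
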
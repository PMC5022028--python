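# Methods

`radrepair` implements a mechanistic model of cellular response to sparsely
ionising (low-LET, X-ray-like) radiation: DNA double-strand breaks (DSBs)
are induced in proportion to dose and DNA content, repaired by three
kinetically distinct pathway classes, and occasionally misrejoined with a
probability set by the spatial proximity of competing free ends.  Misrepair
events propagate to chromosome aberrations, gene mutations and clonogenic
survival through a small set of geometric and probabilistic rules.  One
parameter set is shared across all cell lines; everything cell-specific
enters through a phenotype description (genome size, chromosome number,
pathway defects, checkpoint competence) and the exposure conditions.

## DSB induction

DSB yields are linear in dose and DNA content:
`N0 = k · D · L`, with `k = 5.738 DSB/Gy/Gbp` fixed from the measured
~35 DSB/Gy in diploid human (6.1 Gbp) G1 cells.  Cells irradiated in G2 or
M carry the replicated genome and are assigned exactly twice the G1
content.  S phase (partially replicated, heterogeneous content) is not
modelled and is rejected.  `N0` is carried as an expectation throughout the
analytic chain; only the Monte Carlo simulator draws integer realisations.

## Repair kinetics

Breaks are partitioned into three classes repaired with independent
first-order kinetics, so the surviving break count is tri-exponential:

    N(t) = N0 · (p_f e^{-λ_F t} + p_s e^{-λ_S t} + p_m e^{-λ_M t})

Simple breaks (probability `1 - p_c`) prefer fast NHEJ in every phase;
complex breaks (`p_c`) prefer HR in G2/M when available and slow NHEJ
otherwise; MMEJ is a very slow, low-fidelity fallback.  When a break's
preferred pathway is defective, a fraction `p_fail` of that class diverts
to MMEJ and the remainder keeps its class kinetics (residual pathway
activity).  Applying that one rule to both classes in each phase generates
the full competence-by-phase table in
`radrepair.parameters.assign_repair_fractions`; the tabulated worked case
(NHEJ-defective G2: `p_f = (1-p_c)(1-p_fail)`, `p_s = p_c`,
`p_m = (1-p_c) p_fail`) is reproduced exactly.  One consequence worth
stating explicitly: in G2 cells lacking HR, complex breaks fall back to
slow NHEJ, so their residual fidelity is the NHEJ fidelity, not HR's
perfect fidelity.

γH2AX focus counts trail break formation by a 7.5-minute appearance lag.
We evaluate the repair curve at `max(0, t - lag)` — i.e. the predicted
focus count is clamped at `N0` before the lag has elapsed — rather than
shifting the whole curve, and allow one counting-scale factor per study to
absorb inter-laboratory staining differences.

## Misrejoining geometry

Free ends rejoin at a relative rate `ζ(d) = exp(-d²/2σ²)`.  All geometry
is scale-free: the nucleus is a unit sphere and `σ` is expressed in units
of the nuclear radius.

For a break embedded in a field of `N0` other breaks (two free ends each),
the wrong-end kernel-weight sum `S` competes with the break's own
co-located correct partner (weight 1), giving a per-break misrepair
probability `E[S/(1+S)]`.  The package evaluates this expectation along
two independent routes:

* **exact** (`misrepair_fraction_exact`): treating wrong-end positions as
  independent and uniform, `1/(1+S) = ∫ e^{-t(1+S)} dt` turns the
  expectation into
  `F = 1 - ∫₀^∞ e^{-t} E_x[φ_x(t)^{2N0}] dt`,
  where `φ_x(t)` is the Laplace transform of one end's kernel weight
  conditional on the focal break sitting at radius `x`.  The three nested
  integrals (over `t`, `x`, and the conditional pair distance) are done by
  fixed-order Gauss–Legendre quadrature (96 × 32 × 256 nodes), which is
  accurate to well below Monte Carlo resolution at 10⁶ samples;

* **closed form** (`eta`, `omega`): the mean-field propensity
  `η = 2 N0 θ ω` with `F = η/(1+η)`, where
  `θ(σ) = E[ζ(d)]` over the pair-distance density of two uniform points in
  a sphere (the standard closed-form density, integrated adaptively to
  1e-10 absolute tolerance), and
  `ω(σ) = 1 - (1 - A) e^{-Bσ}` corrects for the right-skew of `S` when σ
  is small: misrepair is then dominated by rare close encounters, and
  replacing `S` by its mean overestimates `E[S/(1+S)]`.  In the rare-event
  limit the exact suppression factor is
  `Σ_k (-1)^{k+1} k^{-3/2} ≈ 0.765`, which is why the fitted plateau `A`
  sits just below 0.76; the correction relaxes to 1 as σ grows and `S`
  concentrates.  `A = 0.757` and `B = 5.39` ship as defaults and are
  re-derivable from the package's own Monte Carlo
  (`radrepair.mc.fit_geometry_constants`; the default grid,
  σ ∈ {0.01, 0.02, 0.04, 0.08, 0.15} × N0 ∈ {10, 50, 100, 500} at 5000
  replicates per point, recovers both to within a few per cent).  The
  skew in truth also depends on `N0`; the σ-only form is a deliberate
  compromise that is excellent at experimentally relevant break counts
  (tens to thousands) and leaves residuals of a few per cent at the
  extremes of the fit grid — which is precisely why the `ω` fit carries
  χ²-scaled uncertainties.

Repair fidelity combines the spatial term with a per-process base
fidelity: `P_correct = μ_x / (1 + η)` for NHEJ and MMEJ, and
`P_correct = 1` for HR (template-directed repair from the sister
chromatid is taken to be error-free, with no spatial term).

### Monte Carlo oracle

`simulate_rejoining` realises the rejoining process stochastically and is
the ground truth for the analytic chain.  Three dynamics are available:

* `field` (default): per-break Bernoulli competition against a static
  field of independently placed free ends — exactly the ensemble the
  analytic expressions describe.  Used for the `ω`-constant recovery and
  the analytic-equivalence suite.
* `sequential` and `gillespie`: exclusive pairing cascades in which ends
  are consumed as they join (uniform end pick with kernel-weighted
  partner, and kernel-proportional pair selection, respectively).

The exclusive cascades embody pair-consumption correlations the
mean-field picture ignores: a close wrong pair, once joined, removes two
competitors, and in the rare-misrepair limit their per-break misrepair is
suppressed by `E[ζ/(1+2ζ)]/E[ζ] ≈ 0.64` instead of 0.765 — roughly 16%
below the mean-field ensemble.  Fitting the `ω` constants against a
cascade therefore yields a visibly smaller `A`; the shipped defaults
correspond to the mean-field ensemble, which is also the one the closed
forms are derived from.  Both cascades remain available for sensitivity
analysis and share the placement, classification and scoring machinery.

Chromosome territories are idealised as spheres of radius
`r_c = R · n_c^{-1/3}` centred uniformly in the nucleus; each break picks
a territory and a uniform position inside it.  Because such spheres
necessarily overlap (congruent spheres cannot tile a sphere), a break's
near neighbours are partly drawn from other territories, and the
simulated intra-chromosome fraction sits below the analytic
tiled-territory value at small σ; the two agree in the limits that define
the quantity (→ 1 for one chromosome, → 1/n_c for σ ≫ R) and share the
monotone dependence on `n_c`.  Misrepair partners for classification are
drawn from the kernel over actual break positions, which preserves the
physical co-location of partner ends.

## Aberrations

Misrepaired breaks at time `t` accumulate per class:
`N_mis(t) = Σ_x N0 p_x (1 - e^{-λ_x t}) (1 - P_correct,x)`, with `η`
evaluated at the initial break count (the field a break competes against
is set at induction).  Exchanges are symmetric or asymmetric with equal
probability (`P_asym = 0.5`; rejoining is blind to fragment orientation),
and only asymmetric events produce the scored lesions:

    N_dic = 0.5 · (1 - P_intra) · N_mis      (dicentrics)
    N_del = 0.5 · P_intra · N_mis            (deletions)

`P_intra = θ(σ, r_c) / (n_c · θ(σ, R))` is the ratio of within-chromosome
to whole-nucleus rejoining rates; it approaches 1 both for a single
chromosome and for σ → 0 (the partner is then a near neighbour in the
same territory), and 1/n_c when σ is large.

Deletion sizes follow from a monotone map between the spatial separation
of the misrejoined ends and the genomic span: taking the enclosed DNA as
the measure, `size(r) = L (r/R)³` base pairs.  This is the unique
power-law consistent with the territory model: a separation equal to the
chromosome sub-volume radius maps onto exactly one mean chromosome
length.  The map and the kernel-weighted pair-distance distribution over
the chromosome sub-volume give the deletion-size spectrum; deletions above
the Giemsa visibility threshold (3 Mbp by default) are scored as visible
and lethal.  The map is evaluated at chromatid-level DNA density in every
phase — a deletion joins two breaks along one DNA molecule, so replication
changes the number of targets, not the packing of each.

Inter-arm exchanges (intra-chromosome events spanning the centromere,
visible in G2 against the replicated chromatid) use the same machinery as
gene-spanning deletions with a zero-length target: the per-deletion
spanning probability is `∫₀^{l_c} P(size ≥ b) db / l_c`, with the
centromere taken as a point and `l_c` the mean chromosome length.  The
`1/l_c` normalisation is the per-centromere share of the genome
(`n_c / L`), equivalent to integrating the genome-normalised spanning rate
over all `n_c` centromeres.

In low-dose-rate mode breaks are too sparse in time to interact: `η` is
forced to zero, leaving only base-fidelity misrepair, and every
misrepair-derived yield becomes exactly linear in dose.

## Mutations

For a gene of length `g` with `b_max` the largest deletion compatible
with survival (both experiment inputs — the package deliberately ships no
default for either):

* gene-spanning deletions: `N_del · ∫₀^{b_max} P(size ≥ b + g) db / L`,
  integrating over offsets of the deletion start before the gene;
  survivability enters through the integration limit;
* intra-gene misrepair: every misrepair whose break fell inside the gene,
  `N_mis · g / L`;
* point mutations: correctly rejoined breaks inside the gene mutate it
  with probability `ν`: `ν · N_correct · g / L`.

`L` here is the phase-dependent DNA content over which breaks distribute;
the deletion-size distribution inside the integrand stays
chromatid-level.  The synthetic test assay uses `g = 34 kb` and
`b_max = 5.8 Mbp` as placeholder magnitudes for an Hprt-style selection
assay; they parameterise the simulated experiment, not the model.

## Survival

Poisson-distributed lethal events give zero-class survival per channel;
channels multiply per condition:

* **G1, non-cycling or delayed plating**: lethal aberrations only,
  `S = exp(-(N_dic + N_del>3Mbp))` at complete repair.
* **G1, cycling, immediate plating**: the aberration term times escape
  from G1 arrest, `exp(-φ_arrest · N0)`, applied only in cells with a
  functional G1 checkpoint (CHO-like checkpoint-defective lines skip it).
* **G2**: dicentrics and inter-arm exchanges block mitosis outright;
  a large deletion sits on one chromatid and dooms one daughter, so the
  colony is lost through deletions only when both daughters draw one:
  `S = exp(-(N_dic + N_interarm)) · (1 - (1 - e^{-N_del/2})²)`,
  neglecting higher-order multi-deletion combinations.  Cycling G2 cells
  additionally face mitotic death on the breaks that escape the G2 damage
  checkpoint; since the checkpoint releases when fewer than
  `checkpoint_threshold = 20` breaks remain, they carry
  `min(N0, 20)` breaks into the mitotic term.  This coupling is an
  interpretation (the gate is specified, the hand-off is not).
* **M**: mitotic death on all induced breaks,
  `S = exp(-ψ_mitosis · N_m)`, with no repair before anaphase.

The two death sensitivities use the tabulated best-fit values
(`mitosis_sensitivity = 0.014/break`, `arrest_sensitivity =
0.0085/break`).  The source text and its parameter table swap the symbols
attached to these two numbers; the package binds semantic names to the
tabulated values and ignores the symbols.

The mean inactivation dose is the integral of the survival curve over
dose: trapezoidal on the supplied grid (model curves default to 0.05 Gy
steps; the trapezoid error for typical curvature is ~1e-4 Gy) plus an
exponential extrapolation of the final segment for the tail.  A warning
is logged when the curve has not fallen below 1% at its last point, where
the extrapolated tail dominates.

## Calibration harness and synthetic data

The nine DNA parameters (λ_F, λ_S, λ_M, p_c, p_fail, σ, μ_NHEJ, μ_MMEJ,
ν) are constrained by one simultaneous weighted nonlinear least-squares
fit across endpoint kinds; the two death sensitivities are fitted in a
separate second stage with the DNA model frozen, mirroring the lower
reproducibility of clonogenic data.  The optimiser is bounded
trust-region least squares (`scipy.optimize.least_squares`) with bounds
bracketing the defaults by at least an order of magnitude (probabilities
in [0, 1], rates in [1e-4, 1e2] h⁻¹, σ in [1e-3, 0.5] R), multi-start
with log-jittered initial points (5 by default), and per-study foci
counting scales as optional auxiliary parameters.  Reported uncertainties
are Jacobian-based with the supplied measurement errors treated as
absolute.

The synthetic-data generator evaluates the forward model over a fixed
study design that mirrors the endpoint mix the model is meant to be
constrained by — foci time-courses (0.25–300 h, 2 Gy) for competent,
NHEJ-defective and HR-defective human cells in G1 and G2 with two
study-level counting scales (1.70 and 1.02); misrepair fractions at
5–80 Gy; aberration dose responses (0.5–10 Gy) for human competent,
human NHEJ-defective and hamster-like cells; G2 aberration kinetics at 2
and 6 Gy; Hprt-style mutation yields (1–10 Gy); and survival curves for
the second stage — then perturbs with 5% relative Gaussian noise and
attaches matching uncertainties (floored at 5% of the dataset's median
magnitude so near-zero points cannot acquire unbounded weight).  What the
generator does *not* emulate: inter-laboratory systematic offsets beyond
the foci scale factors, non-Gaussian count statistics at low yields,
cell-cycle heterogeneity within a nominally synchronised population, and
dose-rate structure beyond the acute/negligible dichotomy.  Passing
recovery tests therefore demonstrates identifiability and correctness of
the fitting machinery under the model's own assumptions, not robustness
to the systematics of real literature data.

Parameter-recovery studies (50 repetitions, 5% noise, single-start fits
initialised at the defaults) recover each DNA parameter within ±3
reported SDs in well over 90% of runs; zero-noise fits started from a
strongly perturbed point return to truth to optimiser tolerance.

## Problem sizes and numerical choices

The geometry-constant recovery uses the default 5 × 4 grid at 5000
replicates per point (~2.5 minutes single-core, numba-compiled); the
analytic-equivalence suite uses σ ∈ {0.01, 0.04, 0.1, 0.3} ×
N0 ∈ {10, 100, 1000} at 2000 replicates.  Standard errors in both are
floored at the binomial SE implied by the exact analytic fraction, so
grid points whose expected misrepair count is of order one (σ = 0.01,
N0 = 10) carry sensible weight.  θ integrals use adaptive quadrature
(1e-10 absolute) for scalar calls and a cached 4096-point cumulative
trapezoid for vectorised deletion-spectrum evaluations (the two agree to
a few parts in 1e6); quadrature upper limits are clipped at 14σ–16σ where
the Gaussian kernel has decayed below 1e-40.  Ties and degenerate inputs:
zero-dose scenarios short-circuit to zero yields and unit survival;
kernel-weight underflow in the simulator falls back to nearest-neighbour
selection (the correct σ → 0 limit).

## Known limitations

* Chromosomes are equal-sized spheres: no size distribution, no shape,
  no positional preference; aberration predictions are whole-cell
  averages, not per-chromosome.
* The σ-only skew correction under-represents the N0 dependence of the
  true skew at the extremes of its fit grid (see above).
* Exposure is instantaneous (acute) or interaction-free (low-dose-rate
  limit); finite-duration exposures with intra-exposure repair are out of
  scope.
* The G2 survival expression neglects multi-deletion combinations across
  daughters, and the checkpoint-to-mitosis hand-off is a documented
  interpretation.
* Arrest/apoptosis is a single exponential gate in G1; no senescence or
  signalling dynamics.
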
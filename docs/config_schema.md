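# Config schema

Configs are flat YAML key–value files with up to four sections.  Keys match
the library dataclass fields exactly; unknown keys are rejected with a
field-by-field diagnostic.

## `parameters` — model constants (all optional; defaults are the best-fit set)

| key | meaning | units | default |
|---|---|---|---|
| `lambda_fast` | fast (NHEJ) repair rate | 1/h | 3.6 |
| `lambda_slow` | slow (HR/complex) repair rate | 1/h | 0.15 |
| `lambda_mmej` | MMEJ repair rate | 1/h | 0.0084 |
| `p_complex` | probability a break is complex | — | 0.42 |
| `p_fail` | repair-failure probability on a defective pathway | — | 0.67 |
| `sigma` | misrejoining range | nuclear radii | 0.0428 |
| `mu_nhej` | NHEJ base fidelity | — | 0.985 |
| `mu_mmej` | MMEJ base fidelity | — | 0.465 |
| `nu` | point-mutation probability per correct rejoin in gene | — | 0.044 |
| `mitosis_sensitivity` | mitotic death rate per carried DSB | 1/break | 0.014 |
| `arrest_sensitivity` | G1 arrest/apoptosis rate per induced DSB | 1/break | 0.0085 |
| `induction_rate` | DSB induction constant | DSB/Gy/Gbp | 5.738 |
| `geom_A`, `geom_B` | skew-correction geometric constants | — | 0.757, 5.39 |
| `p_asym` | asymmetric-exchange probability | — | 0.5 |
| `deletion_visibility_bp` | Giemsa visibility/lethality threshold | bp | 3.0e6 |
| `checkpoint_threshold` | G2 checkpoint release level | DSB count | 20 |
| `foci_lag_h` | focus-appearance lag | h | 0.125 |

## `phenotype` — cell description (`genome_gbp` required)

| key | meaning | units | default |
|---|---|---|---|
| `genome_gbp` | G1 DNA content | Gbp | — (required) |
| `n_chromosomes` | chromosome count | — | 46 |
| `nhej_competent` | NHEJ functional | bool | true |
| `hr_competent` | HR functional | bool | true |
| `g1_checkpoint_competent` | G1 arrest functional (p53-type) | bool | true |
| `nucleus_radius` | nucleus radius (normalisation) | R | 1.0 |
| `name` | label used in outputs | — | `generic` |

## `scenario` — exposure conditions

| key | meaning | values / units | default |
|---|---|---|---|
| `dose` | dose for time-resolved commands | Gy | 0 |
| `doses` | dose grid for dose-response commands | `start:stop:step` (inclusive) or list | command default |
| `phase` | phase at irradiation | `G1` / `G2` / `M` | `G1` |
| `assay_time_h` | endpoint time after exposure | h (`.inf` = complete repair) | `.inf` |
| `dose_rate_mode` | `acute` or `low_dose_rate` (no pairwise misrepair) | — | `acute` |
| `plating` | `delayed` or `immediate` (G1 survival) | — | `delayed` |
| `cycling` | cells cycling at exposure | bool | false |

## `mutation_assay` — required by `predict-mutations` and for mutation datasets

| key | meaning | units |
|---|---|---|
| `gene_bp` | target gene length | bp |
| `b_max_bp` | largest deletion compatible with survival | bp |

Both are experiment inputs with no model default; shipped examples mark
them user-supplied.

## `calibrate`-specific keys

| key | meaning |
|---|---|
| `datasets` | list of endpoint CSV paths (header: `dataset, endpoint, phenotype_id, phase, dose_gy, time_h, value, sd[, scaling_group]`) |
| `phenotypes` | mapping phenotype_id → phenotype section (as above) |
| `fixed` | parameter names frozen at their initial values |
| `fit_foci_scalings` | estimate one counting scale per foci `scaling_group` |
| `n_starts` | multi-start count (default 5) |
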
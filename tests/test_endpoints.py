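"""Misrepair, aberration and mutation endpoint yields."""

import numpy as np
import pytest

from radrepair import (
    CellPhenotype,
    ExposureScenario,
    GeometryContext,
    MutationQuery,
    aberration_yields,
    deletions_above,
    dicentrics_and_deletions,
    gene_mutation_rate,
    interarm_rate,
    misrepaired_count,
    p_intra,
)

INF = float("inf")


class TestMisrepairedCount:
    def test_zero_at_time_zero_and_zero_dose(self, human, params):
        sc = ExposureScenario(dose=2.0, phase="G1")
        assert misrepaired_count(0.0, sc, human, params) == 0.0
        sc0 = ExposureScenario(dose=0.0, phase="G1")
        assert misrepaired_count(INF, sc0, human, params) == 0.0

    def test_non_decreasing_in_time(self, human, params):
        sc = ExposureScenario(dose=2.0, phase="G1")
        times = [0.1, 0.5, 1, 4, 24, 200]
        vals = [misrepaired_count(t, sc, human, params) for t in times]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_hr_only_repair_is_error_free(self, params):
        # all breaks complex + HR available and perfect -> no misrepair
        p = params.with_values(p_complex=1.0)
        sc = ExposureScenario(dose=4.0, phase="G2")
        assert misrepaired_count(INF, sc, CellPhenotype(), p) == pytest.approx(0.0)

    def test_low_dose_rate_doubles_linearly(self, human, params):
        sc2 = ExposureScenario(dose=2.0, phase="G1", dose_rate_mode="low_dose_rate")
        sc4 = ExposureScenario(dose=4.0, phase="G1", dose_rate_mode="low_dose_rate")
        m2 = misrepaired_count(INF, sc2, human, params)
        m4 = misrepaired_count(INF, sc4, human, params)
        assert m4 == pytest.approx(2 * m2, rel=1e-12)

    def test_acute_grows_superlinearly(self, human, params):
        sc2 = ExposureScenario(dose=2.0, phase="G1")
        sc4 = ExposureScenario(dose=4.0, phase="G1")
        m2 = misrepaired_count(INF, sc2, human, params)
        m4 = misrepaired_count(INF, sc4, human, params)
        assert m4 > 2 * m2

    def test_low_dose_rate_leaves_base_infidelity(self, human, params):
        # eta = 0 keeps only (1 - mu) per repaired break
        sc = ExposureScenario(dose=1.0, phase="G1", dose_rate_mode="low_dose_rate")
        n0 = 5.738 * 6.1
        expected = n0 * (1 - params.mu_nhej)
        assert misrepaired_count(INF, sc, human, params) == pytest.approx(expected)


class TestDicentricsAndDeletions:
    def test_zero_input(self, params):
        assert dicentrics_and_deletions(0.0, 0.8, params) == (0.0, 0.0)

    def test_single_chromosome_limit(self, params):
        n_dic, n_del = dicentrics_and_deletions(10.0, 1.0, params)
        assert n_dic == 0.0
        assert n_del == pytest.approx(5.0)

    def test_asymmetric_conservation(self, params):
        for n_mis in (0.5, 3.7, 42.0):
            n_dic, n_del = dicentrics_and_deletions(n_mis, 0.857, params)
            assert n_dic + n_del == pytest.approx(0.5 * n_mis, rel=1e-14)


class TestDeletionsAbove:
    def test_threshold_zero_returns_total(self, human, params):
        g = GeometryContext.for_cell(human, "G1", params)
        assert deletions_above(0.0, 7.0, g, params) == pytest.approx(7.0)

    def test_monotone_and_vanishing(self, human, params):
        g = GeometryContext.for_cell(human, "G1", params)
        sizes = np.logspace(5, 9, 20)
        vals = [deletions_above(s, 7.0, g, params) for s in sizes]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))
        assert vals[-1] < 1e-6


class TestAberrationYields:
    def test_conservation_split(self, human, params):
        sc = ExposureScenario(dose=3.0, phase="G1")
        y = aberration_yields(sc, human, params, t=INF)
        assert y.n_dicentric + y.n_deletion_total == pytest.approx(
            params.p_asym * y.n_misrepaired, rel=1e-12
        )
        assert y.n_deletion_visible <= y.n_deletion_total
        assert y.n_interarm == 0.0  # G1 assay

    def test_g2_includes_interarm(self, human, params):
        sc = ExposureScenario(dose=3.0, phase="G2")
        y = aberration_yields(sc, human, params, t=INF)
        assert y.n_interarm > 0
        assert y.n_visible == pytest.approx(
            y.n_dicentric + y.n_deletion_visible + y.n_interarm
        )


class TestInterarm:
    def test_rejected_outside_g2(self, human, params):
        sc = ExposureScenario(dose=2.0, phase="G1")
        with pytest.raises(ValueError, match="G2"):
            interarm_rate(sc, human, params)

    def test_zero_without_misrepair(self, human, params):
        sc = ExposureScenario(dose=0.0, phase="G2")
        assert interarm_rate(sc, human, params, t=INF) == 0.0

    def test_subset_of_deletions(self, human, params):
        sc = ExposureScenario(dose=4.0, phase="G2")
        y = aberration_yields(sc, human, params, t=INF)
        assert 0 < y.n_interarm < y.n_deletion_total


class TestMutations:
    QUERY = MutationQuery(gene_bp=34e3, b_max_bp=5.8e6)  # synthetic assay target

    def test_zero_length_gene_has_no_intra_events(self, human, params):
        sc = ExposureScenario(dose=2.0, phase="G1")
        q = MutationQuery(gene_bp=0.0, b_max_bp=5.8e6)
        m = gene_mutation_rate(q, sc, human, params, t=INF)
        assert m.intra_gene == 0.0
        assert m.point == 0.0
        assert m.total_deletion > 0.0

    def test_point_mutations_scale_with_nu(self, human, params):
        sc = ExposureScenario(dose=2.0, phase="G1")
        m1 = gene_mutation_rate(self.QUERY, sc, human, params, t=INF)
        m2 = gene_mutation_rate(
            self.QUERY, sc, human, params.with_values(nu=2 * params.nu), t=INF
        )
        assert m2.point == pytest.approx(2 * m1.point, rel=1e-12)
        m0 = gene_mutation_rate(
            self.QUERY, sc, human, params.with_values(nu=0.0), t=INF
        )
        assert m0.point == 0.0

    def test_intra_gene_linear_in_gene_length(self, human, params):
        sc = ExposureScenario(dose=2.0, phase="G1")
        m1 = gene_mutation_rate(self.QUERY, sc, human, params, t=INF)
        q2 = MutationQuery(gene_bp=2 * self.QUERY.gene_bp, b_max_bp=self.QUERY.b_max_bp)
        m2 = gene_mutation_rate(q2, sc, human, params, t=INF)
        assert m2.intra_gene == pytest.approx(2 * m1.intra_gene, rel=1e-12)

    def test_all_components_non_negative_and_total(self, human, params):
        sc = ExposureScenario(dose=5.0, phase="G1")
        m = gene_mutation_rate(self.QUERY, sc, human, params, t=INF)
        assert m.total_deletion >= 0 and m.intra_gene >= 0 and m.point >= 0
        assert m.total == pytest.approx(m.total_deletion + m.intra_gene + m.point)
        assert 0 <= m.point_fraction <= 1

    def test_rates_are_rare_events(self, human, params):
        # mutation frequencies should be orders of magnitude below one
        sc = ExposureScenario(dose=2.0, phase="G1")
        m = gene_mutation_rate(self.QUERY, sc, human, params, t=INF)
        assert m.total < 1e-2


def test_intra_inter_split_uses_chromatid_geometry(human, params):
    # the deletion/dicentric split is a chromatid-level geometric quantity
    g1 = GeometryContext.for_cell(human, "G1", params)
    g2 = GeometryContext.for_cell(human, "G2", params)
    assert p_intra(g1) == p_intra(g2)
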
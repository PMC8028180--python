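import numpy as np
import pytest

from arraybridge._codes import AA, AB, BB, MISSING
from arraybridge.classify import (Adjustment, ClassifyConfig, SnpEvidence,
                                  SnpVerdict, apply_adjustments,
                                  classify_all, classify_axiom,
                                  classify_infinium, integrate)
from arraybridge.clusters import ClusterProfile, SubclusterProposal
from arraybridge.io import CallMatrix


def profile(separation=0.4, n_modes=3, cluster_space=0.85, n_classes=3,
            between=0.0):
    counts = {AA: 40.0, AB: 40.0, BB: 40.0}
    stats = {c: {"count": counts[c], "mean": m, "median": m,
                 "q5": m - 0.05, "q95": m + 0.05, "robust_sd": 0.03}
             for c, m in list(zip((AA, AB, BB), (0.05, 0.5, 0.95)))
             [:n_classes]}
    return ClusterProfile("S", stats, n_modes, [], cluster_space,
                          separation, between, 0.0)


def evidence(**kwargs):
    ev = SnpEvidence(snp_id="S")
    ev.inf_profile = kwargs.pop("inf_profile", profile())
    ev.ax_profile = kwargs.pop("ax_profile", profile())
    ev.cross_groups = kwargs.pop("cross_groups", {
        AA: (0.05, 0.0, 0.1), AB: (0.5, 0.44, 0.56), BB: (0.95, 0.9, 1.0)})
    for key, value in kwargs.items():
        setattr(ev, key, value)
    return ev


class TestInfiniumLadder:
    def test_clean_snp_included(self):
        assert classify_infinium(evidence()) == "included"

    def test_monomorphic(self):
        ev = evidence(inf_mono_frac=1.0,
                      inf_profile=profile(n_classes=1, cluster_space=0.05))
        assert classify_infinium(ev) == "Monomorphic"

    def test_poor_clustering_by_separation(self):
        ev = evidence(inf_profile=profile(separation=-0.2))
        assert classify_infinium(ev) == "Poor clustering"

    def test_poor_clustering_wide_single_class_beats_monomorphic(self):
        ev = evidence(inf_mono_frac=1.0,
                      inf_profile=profile(n_classes=1, cluster_space=0.7))
        assert classify_infinium(ev) == "Poor clustering"

    def test_common_null_overlap(self):
        ev = evidence(null_carriers=10)
        assert classify_infinium(ev) == \
            "Overlapping null and homozygous clusters"

    def test_rare_null_stays_included(self):
        ev = evidence(null_carriers=2)
        assert classify_infinium(ev) == "included"

    def test_illogical_segregation(self):
        ev = evidence(inf_inconsistent=3)
        assert classify_infinium(ev) == "Illogical segregation"

    def test_two_errors_tolerated(self):
        ev = evidence(inf_inconsistent=2)
        assert classify_infinium(ev) == "included"

    def test_extra_cluster_with_errors(self):
        ev = evidence(inf_inconsistent=3,
                      inf_profile=profile(n_modes=4))
        assert classify_infinium(ev) == \
            "Extra cluster(s) causing illogical segregation"


class TestAxiomLadder:
    def test_clean_class_a(self):
        cls, adj = classify_axiom(evidence())
        assert cls == "A" and adj == []

    def test_absent_from_axiom_r(self):
        cls, _ = classify_axiom(evidence(on_axiom=False))
        assert cls == "R"

    def test_one_to_two_discordant_d(self):
        for n in (1, 2):
            cls, _ = classify_axiom(evidence(dup_discordant=n))
            assert cls == "D"

    def test_three_discordant_not_d(self):
        cls, _ = classify_axiom(evidence(dup_discordant=3))
        assert cls != "D"

    def test_between_cluster_b_with_adjustment(self):
        ev = evidence(between_frac=0.05,
                      between_members=["i1", "i2", "i3", "i4", "i5"])
        cls, adj = classify_axiom(ev)
        assert cls == "B"
        assert adj[0].action == "set-missing"
        assert len(adj[0].individuals) == 5

    def test_huge_between_fraction_is_j_not_b(self):
        ev = evidence(between_frac=0.2,
                      between_members=[f"i{k}" for k in range(20)])
        cls, _ = classify_axiom(ev)
        assert cls == "J"

    def test_subcluster_proposal_c(self):
        prop = SubclusterProposal("S", ["i1", "i2", "i3"], AA,
                                  supported=True)
        cls, adj = classify_axiom(evidence(subcluster=prop))
        assert cls == "C"
        assert adj[0].action == "recode" and adj[0].new_call == AB

    def test_unsupported_subcluster_not_c(self):
        prop = SubclusterProposal("S", ["i1"], AA, supported=False)
        cls, _ = classify_axiom(evidence(subcluster=prop))
        assert cls == "A"

    def test_poor_separation_j(self):
        cls, _ = classify_axiom(evidence(ax_profile=profile(separation=-0.5)))
        assert cls == "J"

    def test_het_hom_overlap_k(self):
        groups = {AA: (0.05, 0.0, 0.12), AB: (0.18, 0.08, 0.3),
                  BB: (0.95, 0.9, 1.0)}
        cls, _ = classify_axiom(evidence(cross_groups=groups))
        assert cls == "K"

    def test_merged_het_cluster_o(self):
        groups = {AA: (0.05, 0.0, 0.12), AB: (0.06, 0.0, 0.14),
                  BB: (0.95, 0.9, 1.0)}
        cls, _ = classify_axiom(evidence(cross_groups=groups))
        assert cls == "O"

    def test_all_overlap_l(self):
        groups = {AA: (0.3, 0.1, 0.55), AB: (0.5, 0.3, 0.7),
                  BB: (0.6, 0.45, 0.9)}
        cls, _ = classify_axiom(evidence(cross_groups=groups))
        assert cls == "L"

    def test_error_tallies_p(self):
        cls, _ = classify_axiom(evidence(ax_inconsistent=3))
        assert cls == "P"
        cls, _ = classify_axiom(evidence(ax_consistent_individuals=6))
        assert cls == "P"

    def test_rare_resolved_null_g(self):
        cls, _ = classify_axiom(evidence(null_carriers=2,
                                         null_resolved_errors=True))
        assert cls == "G"

    def test_unresolvable_null_q(self):
        cls, _ = classify_axiom(evidence(null_carriers=2,
                                         null_resolved_errors=False))
        assert cls == "Q"

    def test_residual_discordance_m(self):
        cls, _ = classify_axiom(evidence(dup_discordant=7))
        assert cls == "M"

    def test_ladder_totality(self):
        # every evidence combination yields exactly one class
        import itertools
        for disc, inco, null in itertools.product((0, 2, 7), (0, 5),
                                                  (0, 2, 9)):
            ev = evidence(dup_discordant=disc, ax_inconsistent=inco,
                          null_carriers=null)
            cls, _ = classify_axiom(ev)
            assert isinstance(cls, str) and cls


class TestVerdictInvariants:
    def test_compatible_iff_class_a_to_i(self):
        for cls, expected in [("A", True), ("B", True), ("C", True),
                              ("D", True), ("B/G", True), ("J", False),
                              ("M", False), ("R", False), (None, False)]:
            v = SnpVerdict("S", "included", axiom_class=cls)
            assert v.compatible is expected
        v = SnpVerdict("S", "Poor clustering", axiom_class=None)
        assert not v.compatible


class TestApplyAdjustments:
    def _matrix(self):
        calls = np.array([[AA, AB, BB, AA]], dtype=np.int8)
        return CallMatrix(["S0"], ["i1", "i2", "i3", "i4"], calls, "axiom")

    def test_class_a_only_unchanged(self):
        m = self._matrix()
        verdicts = [SnpVerdict("S0", "included", "A")]
        out, log = apply_adjustments(m, verdicts)
        assert np.array_equal(out.calls, m.calls) and log == []

    def test_b_sets_exact_count_missing(self):
        m = self._matrix()
        adj = Adjustment("set-missing", "S0", ("i1", "i3"), MISSING, "b")
        verdicts = [SnpVerdict("S0", "included", "B", adjustments=[adj])]
        out, log = apply_adjustments(m, verdicts)
        assert (out.calls == MISSING).sum() == 2
        assert len(log) == 2

    def test_idempotent(self):
        m = self._matrix()
        adj = Adjustment("recode", "S0", ("i1",), AB, "c")
        verdicts = [SnpVerdict("S0", "included", "C", adjustments=[adj])]
        out1, log1 = apply_adjustments(m, verdicts)
        out2, log2 = apply_adjustments(out1, verdicts)
        assert np.array_equal(out1.calls, out2.calls)
        assert len(log1) == 1 and log2 == []

    def test_unknown_individual_aborts(self):
        m = self._matrix()
        adj = Adjustment("recode", "S0", ("nope",), AB, "c")
        verdicts = [SnpVerdict("S0", "included", "C", adjustments=[adj])]
        with pytest.raises(ValueError, match="unknown individual"):
            apply_adjustments(m, verdicts)


class TestIntegrate:
    def test_disjoint_individuals_column_sum(self):
        a = CallMatrix(["S0"], ["x1", "x2"],
                       np.array([[AA, AB]], dtype=np.int8), "infinium")
        b = CallMatrix(["S0"], ["y1"],
                       np.array([[BB]], dtype=np.int8), "axiom")
        verdicts = [SnpVerdict("S0", "included", "A")]
        out = integrate(a, b, [], verdicts)
        assert out.matrix.n_individuals == 3

    def test_duplicate_consensus(self):
        a = CallMatrix(["S0"], ["x"], np.array([[AB]], dtype=np.int8),
                       "infinium")
        b = CallMatrix(["S0"], ["y"], np.array([[AB]], dtype=np.int8),
                       "axiom")
        verdicts = [SnpVerdict("S0", "included", "A")]
        out = integrate(a, b, [{"x", "y"}], verdicts)
        assert out.matrix.n_individuals == 1
        assert out.matrix.calls[0, 0] == AB
        assert out.conflicts == []

    def test_post_curation_conflict_set_missing_and_logged(self):
        a = CallMatrix(["S0"], ["x"], np.array([[AA]], dtype=np.int8),
                       "infinium")
        b = CallMatrix(["S0"], ["y"], np.array([[BB]], dtype=np.int8),
                       "axiom")
        verdicts = [SnpVerdict("S0", "included", "A")]
        out = integrate(a, b, [{"x", "y"}], verdicts)
        assert out.matrix.calls[0, 0] == MISSING
        assert len(out.conflicts) == 1

    def test_only_compatible_snps_present(self):
        a = CallMatrix(["S0", "S1"], ["x"],
                       np.array([[AA], [BB]], dtype=np.int8), "infinium")
        verdicts = [SnpVerdict("S0", "included", "A"),
                    SnpVerdict("S1", "included", "J")]
        out = integrate(a, None, [], verdicts)
        assert out.matrix.snp_ids == ["S0"]

    def test_maf_excludes_duplicate_members(self):
        a = CallMatrix(["S0"], ["x", "z"],
                       np.array([[BB, AA]], dtype=np.int8), "infinium")
        b = CallMatrix(["S0"], ["y"], np.array([[BB]], dtype=np.int8),
                       "axiom")
        verdicts = [SnpVerdict("S0", "included", "A")]
        out = integrate(a, b, [{"x", "y"}], verdicts)
        # two consensus columns: clone group (BB) + z (AA) -> B freq 0.5
        assert out.maf["S0"] == pytest.approx(0.5)


class TestPipeline:
    def test_class_counts_partition_input(self, scenario):
        res = classify_all(scenario.calls["infinium"],
                           scenario.calls["axiom"],
                           scenario.intensities["infinium"],
                           scenario.intensities["axiom"],
                           scenario.truth.pedigree,
                           scenario.duplicate_pairs,
                           gmap=scenario.truth.gmap)
        assert sum(res.class_counts.values()) == \
            scenario.calls["infinium"].n_snps
        assert len(res.verdicts) == scenario.calls["infinium"].n_snps

    def test_curation_never_increases_discordance_or_errors(self, scenario):
        from arraybridge.concordance import per_snp_discordance
        from arraybridge.mendel import scan_mendelian_errors
        res = classify_all(scenario.calls["infinium"],
                           scenario.calls["axiom"],
                           scenario.intensities["infinium"],
                           scenario.intensities["axiom"],
                           scenario.truth.pedigree,
                           scenario.duplicate_pairs,
                           gmap=scenario.truth.gmap)
        before_d = per_snp_discordance(scenario.duplicate_pairs,
                                       scenario.calls["infinium"],
                                       scenario.calls["axiom"])
        after_d = per_snp_discordance(scenario.duplicate_pairs,
                                      scenario.calls["infinium"],
                                      res.curated_axiom)
        for snp in before_d:
            assert after_d[snp]["n_discordant"] <= \
                before_d[snp]["n_discordant"]
        ped = scenario.truth.pedigree
        before_m = scan_mendelian_errors(scenario.calls["axiom"], ped)
        after_m = scan_mendelian_errors(res.curated_axiom, ped)
        assert after_m.total <= before_m.total
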
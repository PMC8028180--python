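"""Mendelian logic is checked against an independent gamete-enumeration
oracle, and null inference against the simulator's planted truth."""
import itertools

import numpy as np
import pytest

from arraybridge import _codes
from arraybridge._codes import AA, AB, BB, AN, BN, NN, MISSING
from arraybridge.io import CallMatrix, Pedigree
from arraybridge.mendel import (detect_consistent_errors, duo_inconsistent,
                                infer_null_alleles, scan_mendelian_errors,
                                trio_inconsistent)
from arraybridge.synth import (ProbeEffect, SimulationConfig,
                               apply_call_errors, null_scenario,
                               simulate_genotypes)

# --- independent oracle: explicit gamete enumeration -----------------------

_ALLELES = {AA: ("A", "A"), AB: ("A", "B"), BB: ("B", "B"),
            AN: ("A", "N"), BN: ("B", "N"), NN: ("N", "N")}


def oracle_duo(parent, offspring):
    """Inconsistent iff no parental gamete can appear in the offspring."""
    if parent == MISSING or offspring == MISSING:
        return False
    for gamete in _ALLELES[parent]:
        if gamete in _ALLELES[offspring]:
            return False
    return True


def oracle_trio(mother, father, offspring):
    if offspring == MISSING:
        return False
    if mother == MISSING and father == MISSING:
        return False
    if mother == MISSING:
        return oracle_duo(father, offspring)
    if father == MISSING:
        return oracle_duo(mother, offspring)
    target = tuple(sorted(_ALLELES[offspring]))
    for gm in _ALLELES[mother]:
        for gf in _ALLELES[father]:
            if tuple(sorted((gm, gf))) == target:
                return False
    return True


VISIBLE = (AA, AB, BB)
NULL_AWARE = (AA, AB, BB, AN, BN, NN)


class TestDuoTrioLogic:
    def test_duo_examples(self):
        assert duo_inconsistent(AA, BB)
        assert not duo_inconsistent(AA, AB)
        assert not duo_inconsistent(MISSING, BB)

    def test_trio_examples(self):
        assert trio_inconsistent(AA, AA, AB)  # trio-only error
        assert not duo_inconsistent(AA, AB)   # ...neither duo flags it
        for off in (AA, AB, BB):
            assert not trio_inconsistent(AB, AB, off)
        assert not trio_inconsistent(AA, BB, AB)
        assert trio_inconsistent(AA, BB, AA)

    @pytest.mark.parametrize("parent,offspring",
                             list(itertools.product(VISIBLE + (MISSING,),
                                                    repeat=2)))
    def test_duo_matches_oracle_visible(self, parent, offspring):
        assert duo_inconsistent(parent, offspring) == \
            oracle_duo(parent, offspring)

    def test_duo_matches_oracle_null_aware_all_combinations(self):
        for p, o in itertools.product(NULL_AWARE + (MISSING,), repeat=2):
            assert duo_inconsistent(p, o) == oracle_duo(p, o), (p, o)

    def test_trio_matches_oracle_all_27_visible(self):
        for m, f, o in itertools.product(VISIBLE, repeat=3):
            assert trio_inconsistent(m, f, o) == oracle_trio(m, f, o), \
                (m, f, o)

    def test_trio_matches_oracle_all_216_null_aware(self):
        for m, f, o in itertools.product(NULL_AWARE, repeat=3):
            assert trio_inconsistent(m, f, o) == oracle_trio(m, f, o), \
                (m, f, o)

    def test_trio_missing_parent_degrades_to_duo(self):
        for f, o in itertools.product(NULL_AWARE + (MISSING,), repeat=2):
            assert trio_inconsistent(MISSING, f, o) == oracle_duo(f, o) \
                if o != MISSING and f != MISSING else True


class TestScan:
    def test_noise_free_truth_has_zero_errors(self, small_truth):
        scan = scan_mendelian_errors(small_truth.true_genotypes,
                                     small_truth.pedigree)
        assert scan.total == 0
        assert scan.errors == []

    def test_planted_random_errors_within_binomial_envelope(self):
        # oracle: direct simulation of the same error process on the truth
        cfg = SimulationConfig(n_founders=2,
                               families=[("F000", "F001", 200)],
                               n_snps=60, n_linkage_groups=1, seed=31)
        truth = simulate_genotypes(cfg)
        rate = 0.01
        noisy = apply_call_errors(
            CallMatrix(truth.snp_ids, truth.individual_ids,
                       truth.true_genotypes.visible()),
            rate, np.random.default_rng(5))
        scan = scan_mendelian_errors(noisy, truth.pedigree)
        # oracle expectation by direct simulation with independent seeds
        totals = []
        for s in range(20):
            sim = apply_call_errors(
                CallMatrix(truth.snp_ids, truth.individual_ids,
                           truth.true_genotypes.visible()),
                rate, np.random.default_rng(1000 + s))
            totals.append(scan_mendelian_errors(sim, truth.pedigree,
                                                collect_errors=False).total)
        mu, sd = np.mean(totals), np.std(totals)
        assert abs(scan.total - mu) < max(4 * sd, 10)

    def test_individuals_missing_from_matrix_skipped(self, small_truth):
        m = small_truth.true_genotypes
        sub = CallMatrix(m.snp_ids, m.individual_ids[:-5],
                         m.calls[:, :-5])
        scan = scan_mendelian_errors(sub, small_truth.pedigree)
        assert scan.total == 0

    def test_duo_error_evidence_code(self):
        ped = Pedigree({"P": (None, None), "C": ("P", None)})
        m = CallMatrix(["S0"], ["P", "C"],
                       np.array([[AA, BB]], dtype=np.int8))
        scan = scan_mendelian_errors(m, ped)
        assert scan.total == 1
        assert scan.errors[0].evidence == "opposing-homozygote-duo"
        assert scan.per_individual == {"P": 1, "C": 1}


class TestConsistentErrors:
    def _sequence_fixture(self, states, cm=None):
        """Parent AB everywhere, other parent BB, offspring chosen so the
        transmitted state equals ``states``; several siblings carry the
        flank pattern so the parent can be phased."""
        n = len(states)
        snps = [f"S{i}" for i in range(n)]
        import pandas as pd
        from arraybridge.io import GeneticMap
        gmap = GeneticMap(pd.DataFrame({
            "snp_id": snps, "lg": "LG1",
            "cM": cm if cm is not None else np.arange(n, dtype=float),
            "bp": np.arange(n) * 1000 + 1}))
        ped = Pedigree({"P": (None, None), "O": (None, None),
                        **{f"C{k}": ("P", "O") for k in range(6)}})
        # transmitted A -> offspring AB (other parent BB forces state), B -> BB
        def offspring(states_row):
            return [AB if s == 0 else BB for s in states_row]
        cols = {"P": [AB] * n, "O": [BB] * n}
        cols["C0"] = offspring(states)
        for k in range(1, 6):
            cols["C%d" % k] = offspring([states[0]] * n)  # constant siblings
        ids = list(cols)
        calls = np.array([[cols[i][r] for i in ids] for r in range(n)],
                         dtype=np.int8)
        return CallMatrix(snps, ids, calls), ped, gmap

    def test_singleton_flip_flagged(self):
        m, ped, gmap = self._sequence_fixture([0, 0, 0, 1, 0, 0, 0])
        errors = detect_consistent_errors(m, ped, gmap, k_flank=3)
        flagged = [(e.snp_id, e.individuals[0]) for e in errors]
        assert ("S3", "C0") in flagged

    def test_genuine_single_crossover_not_flagged(self):
        m, ped, gmap = self._sequence_fixture([0, 0, 0, 1, 1, 1, 1])
        errors = detect_consistent_errors(m, ped, gmap, k_flank=3)
        assert all(e.individuals[0] != "C0" for e in errors)

    def test_boundary_safety_no_flag_without_flanks(self):
        m, ped, gmap = self._sequence_fixture([0, 0, 1, 0, 0])
        errors = detect_consistent_errors(m, ped, gmap, k_flank=3)
        assert errors == []

    def test_window_limit_respected(self):
        cm = [0.0, 1.0, 2.0, 3.0, 50.0, 51.0, 52.0]
        m, ped, gmap = self._sequence_fixture([0, 0, 0, 1, 0, 0, 0], cm)
        # right flank lies outside the 10 cM window around the flip
        errors = detect_consistent_errors(m, ped, gmap, k_flank=3,
                                          w_cM=10.0)
        assert errors == []

    def test_planted_miscall_found_true_crossovers_explained(self):
        cfg = SimulationConfig(n_founders=4,
                               families=[("F000", "F001", 40)],
                               n_snps=300, n_linkage_groups=2, seed=6)
        truth = simulate_genotypes(cfg)
        m = truth.true_genotypes.copy()
        base = detect_consistent_errors(m, truth.pedigree, truth.gmap)
        # every flag on clean truth is a genuine double crossover in the
        # simulator's transmission record: the transmitted haplotype flips
        # on both sides of the flagged SNP within a short surrounding window
        for err in base:
            child, parent = err.individuals
            origin = truth.origins[(child, parent)]
            row = m.snp_pos(err.snp_id)
            lo, hi = max(row - 30, 0), min(row + 31, len(origin))
            assert (origin[lo:row] != origin[row]).any()
            assert (origin[row + 1:hi] != origin[row]).any()
        # plant one miscall at an informative SNP
        target_row = None
        for i in range(20, 100):
            if m.calls[i, m.ind_pos("F000")] == AB and \
                    m.calls[i, m.ind_pos("P0_000")] == AA:
                target_row = i
                break
        m.calls[target_row, m.ind_pos("P0_000")] = BB
        errors = detect_consistent_errors(m, truth.pedigree, truth.gmap)
        new = [e for e in errors if e not in base]
        assert [(e.snp_id, e.individuals) for e in new] == \
            [(m.snp_ids[target_row], ("P0_000", "F000"))]


@pytest.fixture(scope="module")
def null_ds():
    return null_scenario(seed=5, n_snps=400, n_null_snps=15,
                         n_offspring_per_family=30)


class TestNullInference:

    def test_planted_nulls_recovered_no_false_flags(self, null_ds):
        inf = null_ds.calls["infinium"]
        ni = infer_null_alleles(inf, null_ds.intensities["infinium"],
                                null_ds.truth.pedigree)
        planted = {s for s, l in null_ds.planted.items() if l == "X_NULL"}
        detected = set(ni.per_snp_carriers)
        assert len(planted & detected) / len(planted) >= 0.8
        assert detected <= planted  # zero flags on artifact-free SNPs

    def test_recoding_strictly_decreases_errors(self, null_ds):
        inf = null_ds.calls["infinium"]
        ped = null_ds.truth.pedigree
        before = scan_mendelian_errors(inf, ped).total
        ni = infer_null_alleles(inf, null_ds.intensities["infinium"], ped)
        after = scan_mendelian_errors(ni.matrix, ped).total
        assert after < before

    def test_clean_snp_yields_no_null_calls(self, small_truth):
        from arraybridge.synth import default_infinium, simulate_intensities
        m = CallMatrix(small_truth.snp_ids, small_truth.individual_ids,
                       small_truth.true_genotypes.visible())
        intens = simulate_intensities(small_truth, default_infinium(),
                                      seed=2)
        ni = infer_null_alleles(m, intens, small_truth.pedigree)
        assert ni.null_calls == []

    def test_nn_individuals_recoded_from_missing(self, null_ds):
        inf = null_ds.calls["infinium"]
        truth_calls = null_ds.truth.true_genotypes
        ni = infer_null_alleles(inf, null_ds.intensities["infinium"],
                                null_ds.truth.pedigree)
        nn_calls = [c for c in ni.null_calls if c.recoded_call == NN]
        assert nn_calls
        for call in nn_calls:
            row = truth_calls.snp_pos(call.snp_id)
            col = truth_calls.ind_pos(call.individual)
            assert truth_calls.calls[row, col] == NN  # matches truth

    def test_recodes_consistent_with_visible_calls(self, null_ds):
        inf = null_ds.calls["infinium"]
        ni = infer_null_alleles(inf, null_ds.intensities["infinium"],
                                null_ds.truth.pedigree)
        for call in ni.null_calls:
            if call.recoded_call == NN:
                continue
            visible_before = _codes.visible(np.array(
                [inf.calls[inf.snp_pos(call.snp_id),
                           inf.ind_pos(call.individual)]]))[0]
            expected = AA if call.recoded_call == AN else BB
            assert visible_before == expected
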
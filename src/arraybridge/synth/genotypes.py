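"""Pedigreed diploid genotype simulation with recombination and null alleles."""
from __future__ import annotations

import numpy as np
import pandas as pd

from .. import _codes
from ..io import CallMatrix, GeneticMap, Pedigree
from .config import SimulationConfig, TruthBundle, haldane_recomb_fraction

# haplotype allele codes
ALLELE_A, ALLELE_B, ALLELE_N = 0, 1, 2

# genotype code from sorted allele pair
_PAIR_TO_CODE = {
    (ALLELE_A, ALLELE_A): _codes.AA,
    (ALLELE_A, ALLELE_B): _codes.AB,
    (ALLELE_B, ALLELE_B): _codes.BB,
    (ALLELE_A, ALLELE_N): _codes.AN,
    (ALLELE_B, ALLELE_N): _codes.BN,
    (ALLELE_N, ALLELE_N): _codes.NN,
}


def _generate_map(config: SimulationConfig,
                  rng: np.random.Generator) -> GeneticMap:
    """Place SNPs uniformly at random per LG, then sort by position.

    Physical bp positions are laid out proportionally to cM (1 cM ~ 1 Mb)
    so that map-revision tests have a consistent physical frame.
    """
    n_lg = config.n_linkage_groups
    base = config.n_snps // n_lg
    counts = [base + (1 if i < config.n_snps % n_lg else 0)
              for i in range(n_lg)]
    snp_rows = []
    snp_counter = 0
    for lg_idx, n in enumerate(counts):
        cm = np.sort(rng.uniform(0.0, config.map_length_cM, size=n))
        for pos in cm:
            snp_rows.append({
                "snp_id": f"SNP_{snp_counter:05d}",
                "lg": f"LG{lg_idx + 1}",
                "cM": round(float(pos), 4),
                "bp": int(round(pos * 1e4)) + 1,
            })
            snp_counter += 1
    frame = pd.DataFrame(snp_rows, columns=["snp_id", "lg", "cM", "bp"])
    return GeneticMap(frame)


def _founder_haplotype(p_a: np.ndarray, p_b: np.ndarray, p_n: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    u = rng.random(p_a.shape[0])
    hap = np.full(p_a.shape[0], ALLELE_A, dtype=np.int8)
    hap[u >= p_a] = ALLELE_B
    hap[u >= p_a + p_b] = ALLELE_N
    return hap


def _gamete_origin(lg_slices: list[tuple[slice, np.ndarray]],
                   rng: np.random.Generator, n_snps: int) -> np.ndarray:
    """Which parental haplotype (0/1) is transmitted at each SNP."""
    origin = np.empty(n_snps, dtype=np.int8)
    for sl, rec_fracs in lg_slices:
        n = sl.stop - sl.start
        start = rng.integers(0, 2)
        if n == 1:
            origin[sl] = start
            continue
        crossovers = rng.random(n - 1) < rec_fracs
        states = np.empty(n, dtype=np.int8)
        states[0] = start
        flips = np.cumsum(crossovers) % 2
        states[1:] = (start + flips) % 2
        origin[sl] = states
    return origin


def simulate_genotypes(config: SimulationConfig) -> TruthBundle:
    """Simulate founder and pedigreed genotypes over a random genetic map.

    Founders are drawn from Hardy-Weinberg proportions at a per-SNP MAF
    sampled from ``founder_maf_range``; a null haplotype segregates as a
    third allele N wherever the artifact plan sets a positive null-allele
    frequency.  Gametes recombine per linkage group with crossover
    probability between adjacent SNPs given by Haldane's map function.
    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(config.seed)
    gmap = _generate_map(config, rng)
    snp_ids = gmap.snp_ids()
    n_snps = len(snp_ids)

    # per-SNP allele frequencies
    maf = rng.uniform(*config.founder_maf_range, size=n_snps)
    for snp, value in config.maf_overrides.items():
        maf[snp_ids.index(snp)] = value
    null_freq = np.zeros(n_snps)
    for snp, effect in config.artifact_plan.items():
        if snp not in snp_ids:
            raise ValueError(f"artifact plan references unknown SNP {snp!r}")
        null_freq[snp_ids.index(snp)] = effect.null_allele_frequency
    p_n = null_freq
    p_b = (1.0 - p_n) * maf
    p_a = 1.0 - p_b - p_n

    founders = config.founder_ids()
    offspring = config.offspring_ids()
    individuals = founders + [o for o, _, _ in offspring]
    n_ind = len(individuals)
    ind_index = {ind: i for i, ind in enumerate(individuals)}

    haplotypes = np.empty((n_snps, n_ind, 2), dtype=np.int8)
    for i, _ in enumerate(founders):
        haplotypes[:, i, 0] = _founder_haplotype(p_a, p_b, p_n, rng)
        haplotypes[:, i, 1] = _founder_haplotype(p_a, p_b, p_n, rng)

    # secondary-polymorphism carrier haplotypes, fully linked to the SNP
    poly_carriers: dict[str, np.ndarray] = {}
    for snp, effect in config.artifact_plan.items():
        if effect.secondary_polymorphisms:
            n_poly = len(effect.secondary_polymorphisms)
            flags = np.zeros((n_poly, n_ind, 2), dtype=bool)
            for j, (_, freq) in enumerate(effect.secondary_polymorphisms):
                flags[j, :len(founders), :] = (
                    rng.random((len(founders), 2)) < freq)
            poly_carriers[snp] = flags

    # recombination-fraction cache per LG
    lg_slices: list[tuple[slice, np.ndarray]] = []
    pos = 0
    for _, sub in gmap.per_lg():
        n = len(sub)
        gaps = np.diff(sub["cM"].to_numpy(float))
        lg_slices.append((slice(pos, pos + n),
                          haldane_recomb_fraction(gaps)))
        pos += n

    origins: dict[tuple[str, str], np.ndarray] = {}
    parent_map: dict[str, tuple[str | None, str | None]] = {
        f: (None, None) for f in founders}
    for child, mother, father in offspring:
        ci = ind_index[child]
        parent_map[child] = (mother, father)
        for slot, parent in enumerate((mother, father)):
            pi = ind_index[parent]
            origin = _gamete_origin(lg_slices, rng, n_snps)
            origins[(child, parent)] = origin
            gamete = haplotypes[np.arange(n_snps), pi, origin]
            haplotypes[:, ci, slot] = gamete
            # inherit secondary-polymorphism carrier status with the gamete
            for snp, flags in poly_carriers.items():
                si = ind_index[child]  # same as ci
                row = snp_ids.index(snp)
                flags[:, si, slot] = flags[:, pi, origin[row]]

    pair_lo = np.minimum(haplotypes[:, :, 0], haplotypes[:, :, 1])
    pair_hi = np.maximum(haplotypes[:, :, 0], haplotypes[:, :, 1])
    code_lut = np.zeros((3, 3), dtype=np.int8)
    for (a, b), code in _PAIR_TO_CODE.items():
        code_lut[a, b] = code
    calls = code_lut[pair_lo, pair_hi]

    true_genotypes = CallMatrix(snp_ids, individuals, calls, "truth")
    pedigree = Pedigree(parent_map, clone_groups=[])
    true_classes = {snp: "A" for snp in snp_ids}
    return TruthBundle(true_genotypes=true_genotypes,
                       true_classes=true_classes,
                       pedigree=pedigree, gmap=gmap,
                       haplotypes=haplotypes, origins=origins,
                       poly_carriers=poly_carriers, config=config)
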
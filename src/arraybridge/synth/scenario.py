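"""Canned synthetic scenarios with planted artifact classes.

Every downstream stage is validated against these plants: each SNP gets an
intended verdict class, artifacts are injected at the intensity or call
level, and the truth bundle records what was planted where.

Plant labels:
  A       clean, no adjustment needed
  B       ambiguous between-cluster positions planted in axiom data
  C       heterozygous sub-cluster shifted onto a homozygote (axiom)
  D       one or two discordant duplicate calls planted in axiom data
  J       poor cluster differentiation (axiom noise blow-up)
  K       heterozygous cluster overlapping a homozygote cluster (axiom)
  O       heterozygous cluster fully collapsed onto a homozygote (axiom)
  X_MONO  monomorphic SNP (excluded on the first platform)
  X_POOR  poor clustering on the first platform
  X_NULL  common segregating null allele (overlapping null/hom clusters)
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .. import _codes
from ..io import CallMatrix, IntensityTable
from .config import (PlatformModel, ProbeEffect, SimulationConfig,
                     TruthBundle)
from .calling import apply_call_errors, call_genotypes
from .genotypes import simulate_genotypes
from .intensities import simulate_intensities

_PLATFORM_SEED_OFFSET = {"infinium": 101, "axiom": 202}

COMPATIBLE_PLANTS = ("A", "B", "C", "D")
INCOMPATIBLE_PLANTS = ("J", "K", "O")
EXCLUSION_PLANTS = ("X_MONO", "X_POOR", "X_NULL")


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    truth: TruthBundle
    intensities: dict[str, IntensityTable]
    calls: dict[str, CallMatrix]
    planted: dict[str, str]
    duplicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    d_flip_targets: dict[str, list[str]] = field(default_factory=dict)


def _assign_plants(snp_ids: list[str], counts: dict[str, int],
                   rng: np.random.Generator) -> dict[str, str]:
    total = sum(counts.values())
    if total > len(snp_ids):
        raise ValueError("more plants requested than SNPs available")
    chosen = rng.choice(len(snp_ids), size=total, replace=False)
    labels: dict[str, str] = {s: "A" for s in snp_ids}
    pos = 0
    for label, n in counts.items():
        for k in range(n):
            labels[snp_ids[chosen[pos]]] = label
            pos += 1
    return labels


def default_plant_counts(n_snps: int) -> dict[str, int]:
    """Roughly Table-3-shaped proportions, scaled down."""
    unit = max(n_snps // 15, 1)
    return {"B": unit, "C": unit, "D": unit, "J": unit, "K": unit,
            "O": unit, "X_MONO": unit // 2 + 1, "X_POOR": unit // 2 + 1,
            "X_NULL": unit // 2 + 1}


def build_scenario(seed: int = 0, n_snps: int = 450, n_founders: int = 48,
                   n_offspring_per_family: int = 25, n_families: int = 2,
                   plant_counts: dict[str, int] | None = None,
                   call_error_rate: float = 0.0,
                   null_allele_frequency: float = 0.3) -> SyntheticDataset:
    """Simulate a two-platform dataset with planted artifact classes.

    All individuals are genotyped on both platforms, so every individual is
    its own cross-platform duplicate pair.
    """
    rng = np.random.default_rng(seed)
    families = [(f"F{2 * i:03d}", f"F{2 * i + 1:03d}",
                 n_offspring_per_family) for i in range(n_families)]
    config = SimulationConfig(
        n_founders=n_founders, families=families, n_snps=n_snps,
        n_linkage_groups=3, map_length_cM=120.0,
        call_error_rate=call_error_rate, seed=seed)
    # plants are decided before simulation so null/mono SNPs shape genotypes
    provisional_ids = [f"SNP_{i:05d}" for i in range(n_snps)]
    counts = plant_counts if plant_counts is not None \
        else default_plant_counts(n_snps)
    planted = _assign_plants(provisional_ids, counts, rng)
    for snp, label in planted.items():
        if label == "X_MONO":
            config.maf_overrides[snp] = 0.0
        elif label == "X_NULL":
            config.artifact_plan[snp] = ProbeEffect(
                snp, null_allele_frequency=null_allele_frequency)

    truth = simulate_genotypes(config)
    truth.true_classes.update(planted)

    dataset = SyntheticDataset(config=config, truth=truth, intensities={},
                               calls={}, planted=planted)
    dup_ids = list(truth.individual_ids)
    dataset.duplicate_pairs = [(i, i) for i in dup_ids]

    for platform_name, model in config.platform_models.items():
        intens = simulate_intensities(truth, model, config.artifact_plan,
                                      seed=seed + _PLATFORM_SEED_OFFSET[platform_name])
        intens = _plant_intensity_artifacts(
            intens, truth, planted, model, platform_name,
            np.random.default_rng(seed + 17))
        calls = call_genotypes(intens, model, platform_tag=platform_name)
        calls = apply_call_errors(calls, config.call_error_rate,
                                  np.random.default_rng(seed + 29))
        dataset.intensities[platform_name] = intens
        dataset.calls[platform_name] = calls

    _plant_call_artifacts(dataset, np.random.default_rng(seed + 41))
    return dataset


def _wide(intens: IntensityTable, truth: TruthBundle
          ) -> tuple[np.ndarray, np.ndarray]:
    theta = intens.pivot_theta().reindex(index=truth.snp_ids,
                                         columns=truth.individual_ids)
    r = intens.pivot_r().reindex(index=truth.snp_ids,
                                 columns=truth.individual_ids)
    return theta.to_numpy(float), r.to_numpy(float)


def _rebuild(theta: np.ndarray, r: np.ndarray,
             truth: TruthBundle) -> IntensityTable:
    n_snps, n_ind = theta.shape
    frame = pd.DataFrame({
        "snp_id": np.repeat(truth.snp_ids, n_ind),
        "individual_id": np.tile(truth.individual_ids, n_snps),
        "theta": np.clip(theta, 0.0, 1.0).ravel(),
        "r": np.clip(r, 0.0, None).ravel(),
    })
    return IntensityTable(frame)


def _plant_intensity_artifacts(intens: IntensityTable, truth: TruthBundle,
                               planted: dict[str, str], model: PlatformModel,
                               platform_name: str,
                               rng: np.random.Generator) -> IntensityTable:
    """Inject the geometry-level plants.  Axiom carries the cross-platform
    artifact classes; the first platform carries its own exclusion plants."""
    theta, r = _wide(intens, truth)
    vis = truth.true_genotypes.visible()
    c0, c1, c2 = model.cluster_centers
    snp_row = {s: i for i, s in enumerate(truth.snp_ids)}

    for snp, label in planted.items():
        row = snp_row[snp]
        on_axiom = platform_name == "axiom"
        if label == "B" and on_axiom:
            src = np.flatnonzero(vis[row] == _codes.AA)
            if src.size == 0:
                src = np.flatnonzero(vis[row] != _codes.MISSING)
            take = src[rng.permutation(src.size)[:8]]
            theta[row, take] = rng.normal(0.30, 0.01, take.size)
        elif label == "C" and on_axiom:
            hets = np.flatnonzero(vis[row] == _codes.AB)
            take = hets[rng.permutation(hets.size)[:max(hets.size // 2, 3)]]
            theta[row, take] = rng.normal(0.18, 0.012, take.size)
        elif label == "K" and on_axiom:
            hets = np.flatnonzero(vis[row] == _codes.AB)
            theta[row, hets] = rng.normal(0.14, 0.05, hets.size)
        elif label == "O" and on_axiom:
            hets = np.flatnonzero(vis[row] == _codes.AB)
            theta[row, hets] = rng.normal(c0, 0.02, hets.size)
        elif label == "J" and on_axiom:
            centers = np.select([vis[row] == _codes.AA, vis[row] == _codes.AB,
                                 vis[row] == _codes.BB],
                                [c0, c1, c2], default=c1)
            theta[row] = centers + rng.normal(0.0, 0.12, theta.shape[1])
        elif label == "X_POOR" and platform_name == "infinium":
            centers = np.select([vis[row] == _codes.AA, vis[row] == _codes.AB,
                                 vis[row] == _codes.BB],
                                [c0, c1, c2], default=c1)
            theta[row] = centers + rng.normal(0.0, 0.22, theta.shape[1])
    return _rebuild(theta, r, truth)


def _plant_call_artifacts(dataset: SyntheticDataset,
                          rng: np.random.Generator) -> None:
    """Class D: flip the axiom call of one or two pedigree-unlinked
    individuals to the opposite homozygote."""
    truth = dataset.truth
    ped = truth.pedigree
    linked = {p for duo in ped.duos() for p in duo}
    unlinked = [i for i in truth.individual_ids if i not in linked]
    calls = dataset.calls["axiom"]
    flip_to = {_codes.AA: _codes.BB, _codes.AB: _codes.AA,
               _codes.BB: _codes.AA}
    for snp, label in dataset.planted.items():
        if label != "D":
            continue
        row = calls.snp_pos(snp)
        candidates = [i for i in unlinked
                      if calls.calls[row, calls.ind_pos(i)]
                      in (_codes.AA, _codes.AB, _codes.BB)]
        take = list(rng.choice(candidates, size=min(2, len(candidates)),
                               replace=False))
        for ind in take:
            col = calls.ind_pos(ind)
            calls.calls[row, col] = flip_to[int(calls.calls[row, col])]
        dataset.d_flip_targets[snp] = take


# ---------------------------------------------------------------------------
# focused scenarios for specific analyses
# ---------------------------------------------------------------------------

def null_scenario(seed: int = 0, n_snps: int = 2000, n_null_snps: int = 50,
                  n_offspring_per_family: int = 30, n_families: int = 2,
                  null_allele_frequency: float = 0.3) -> SyntheticDataset:
    """Segregating-null scenario for null-allele recovery checks."""
    counts = {"X_NULL": n_null_snps}
    return build_scenario(seed=seed, n_snps=n_snps, n_founders=40,
                          n_offspring_per_family=n_offspring_per_family,
                          n_families=n_families, plant_counts=counts,
                          null_allele_frequency=null_allele_frequency)


def polymorphism_sweep(seed: int = 0, distances: tuple[int, ...] = (
        1, 2, 3, 5, 8, 12, 18, 25, 35), snps_per_distance: int = 12,
        carrier_frequency: float = 0.5, n_founders: int = 40,
        n_offspring_per_family: int = 20) -> SyntheticDataset:
    """One single secondary polymorphism per SNP at controlled 3'-distance,
    for distance-stratified inclusion/compatibility analyses."""
    n_snps = len(distances) * snps_per_distance + 40  # plus clean controls
    families = [("F000", "F001", n_offspring_per_family),
                ("F002", "F003", n_offspring_per_family)]
    config = SimulationConfig(
        n_founders=n_founders, families=families, n_snps=n_snps,
        n_linkage_groups=2, map_length_cM=120.0, seed=seed)
    snp_ids = [f"SNP_{i:05d}" for i in range(n_snps)]
    planted: dict[str, str] = {}
    idx = 0
    for d in distances:
        for _ in range(snps_per_distance):
            snp = snp_ids[idx]
            config.artifact_plan[snp] = ProbeEffect(
                snp, secondary_polymorphisms=[(d, carrier_frequency)])
            planted[snp] = f"POLY_d{d}"
            idx += 1
    truth = simulate_genotypes(config)
    truth.true_classes.update(planted)
    dataset = SyntheticDataset(config=config, truth=truth, intensities={},
                               calls={}, planted=planted)
    for platform_name, model in config.platform_models.items():
        intens = simulate_intensities(truth, model, config.artifact_plan,
                                      seed=seed + _PLATFORM_SEED_OFFSET[platform_name])
        dataset.intensities[platform_name] = intens
        dataset.calls[platform_name] = call_genotypes(
            intens, model, platform_tag=platform_name)
    dataset.duplicate_pairs = [(i, i) for i in truth.individual_ids]
    return dataset


def paralog_sweep(seed: int = 0, fractions: tuple[float, ...] = (
        0.0, 0.1, 0.2, 0.3, 0.4, 0.5), snps_per_fraction: int = 20,
        n_founders: int = 60) -> tuple[SyntheticDataset, dict[str, float]]:
    """Paralog-signal gradient for cluster-space compression analyses."""
    n_snps = len(fractions) * snps_per_fraction
    config = SimulationConfig(n_founders=n_founders, families=[],
                              n_snps=n_snps, n_linkage_groups=2,
                              map_length_cM=100.0, seed=seed,
                              founder_maf_range=(0.3, 0.5))
    snp_ids = [f"SNP_{i:05d}" for i in range(n_snps)]
    snp_fraction: dict[str, float] = {}
    idx = 0
    for s in fractions:
        for _ in range(snps_per_fraction):
            snp = snp_ids[idx]
            if s > 0:
                config.artifact_plan[snp] = ProbeEffect(
                    snp, paralog_signal_fraction=s)
            snp_fraction[snp] = s
            idx += 1
    truth = simulate_genotypes(config)
    dataset = SyntheticDataset(config=config, truth=truth, intensities={},
                               calls={}, planted={})
    model = config.platform_models["infinium"]
    intens = simulate_intensities(truth, model, config.artifact_plan,
                                  seed=seed + 3)
    dataset.intensities["infinium"] = intens
    dataset.calls["infinium"] = call_genotypes(intens, model,
                                               platform_tag="infinium")
    return dataset, snp_fraction
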
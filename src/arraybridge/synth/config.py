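"""Configuration and truth types for the two-platform array simulator."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..io import CallMatrix, GeneticMap, Pedigree


@dataclass
class PlatformModel:
    """Signal-geometry model for one array platform.

    ``secondary_penalty_lambda`` parameterizes the binding-signal retention
    for a haplotype carrying a secondary polymorphism at distance ``d`` from
    the probe's 3' end: ``retention(d) = 1 - exp(-d / lambda)`` for
    ``d <= probe_len`` and 1 beyond the probe.  A larger lambda makes the
    platform sensitive over more of the probe, which is how the short-probe
    platform is made more vulnerable near the 3' end.
    """

    probe_len: int = 50
    cluster_centers: tuple[float, float, float] = (0.05, 0.5, 0.95)
    theta_sd: tuple[float, float, float] = (0.03, 0.035, 0.03)
    r_mean: float = 1.0
    r_sd: float = 0.06
    null_r_factor: float = 0.04
    secondary_penalty_lambda: float = 3.0

    def __post_init__(self) -> None:
        c = self.cluster_centers
        if not (0.0 <= c[0] < c[1] < c[2] <= 1.0):
            raise ValueError("cluster centers must be strictly increasing in [0,1]")
        if self.probe_len <= 0:
            raise ValueError("probe_len must be positive")
        if self.null_r_factor < 0:
            raise ValueError("null_r_factor must be >= 0")

    def retention(self, d: np.ndarray | float) -> np.ndarray | float:
        """Binding-signal retention for a polymorphism at 3'-distance d."""
        d = np.asarray(d, dtype=float)
        out = 1.0 - np.exp(-d / self.secondary_penalty_lambda)
        out = np.where(d > self.probe_len, 1.0, out)
        return float(out) if out.ndim == 0 else out


def default_infinium() -> PlatformModel:
    return PlatformModel(probe_len=50, secondary_penalty_lambda=3.0)


def default_axiom() -> PlatformModel:
    return PlatformModel(probe_len=35, theta_sd=(0.035, 0.04, 0.035),
                         r_sd=0.08, secondary_penalty_lambda=8.0)


@dataclass
class ProbeEffect:
    """Planted probe-level artifacts for one SNP.

    ``secondary_polymorphisms`` is a list of ``(distance_from_3prime,
    carrier_frequency)`` pairs; carriers lose binding signal on the carrying
    haplotype according to the platform's retention curve.  ``paralog_*``
    model a fixed non-target locus adding constant signal for one allele.
    """

    snp_id: str
    secondary_polymorphisms: list[tuple[int, float]] = field(default_factory=list)
    null_allele_frequency: float = 0.0
    paralog_signal_fraction: float = 0.0
    paralog_allele: str = "A"

    def __post_init__(self) -> None:
        for d, freq in self.secondary_polymorphisms:
            if d < 1:
                raise ValueError("secondary-polymorphism distance must be >= 1")
            if not 0.0 <= freq <= 1.0:
                raise ValueError("carrier frequency outside [0, 1]")
        if not 0.0 <= self.null_allele_frequency <= 1.0:
            raise ValueError("null_allele_frequency outside [0, 1]")
        if not 0.0 <= self.paralog_signal_fraction <= 0.5:
            raise ValueError("paralog_signal_fraction outside [0, 0.5]")
        if self.paralog_allele not in ("A", "B"):
            raise ValueError("paralog_allele must be 'A' or 'B'")


@dataclass
class SimulationConfig:
    n_founders: int = 40
    families: list[tuple[str, str, int]] = field(default_factory=list)
    n_snps: int = 500
    n_linkage_groups: int = 5
    map_length_cM: float = 100.0
    founder_maf_range: tuple[float, float] = (0.1, 0.5)
    platform_models: dict[str, PlatformModel] = field(
        default_factory=lambda: {"infinium": default_infinium(),
                                 "axiom": default_axiom()})
    artifact_plan: dict[str, ProbeEffect] = field(default_factory=dict)
    duplicate_plan: list[str] = field(default_factory=list)
    call_error_rate: float = 0.0
    seed: int = 0
    # per-SNP overrides of the founder minor-allele frequency (e.g. 0.0 to
    # plant a monomorphic SNP); SNP ids are assigned as SNP_00000, SNP_00001..
    maf_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lo, hi = self.founder_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("founder_maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.call_error_rate < 1.0:
            raise ValueError("call_error_rate must lie in [0, 1)")
        if self.n_snps <= 0:
            raise ValueError("need at least one SNP")
        if self.n_founders <= 0:
            raise ValueError("need at least one founder")
        if set(self.platform_models) != {"infinium", "axiom"}:
            raise ValueError("platform_models must key 'infinium' and 'axiom'")
        self._check_family_order()

    def _check_family_order(self) -> None:
        known = {f"F{i:03d}" for i in range(self.n_founders)}
        for fam_idx, (mother, father, n_off) in enumerate(self.families):
            if mother not in known or father not in known:
                raise ValueError(
                    f"family {fam_idx}: parent not among founders or "
                    f"previously generated offspring")
            if n_off < 0:
                raise ValueError("negative offspring count")
            known |= {f"P{fam_idx}_{k:03d}" for k in range(n_off)}

    def founder_ids(self) -> list[str]:
        return [f"F{i:03d}" for i in range(self.n_founders)]

    def offspring_ids(self) -> list[tuple[str, str, str]]:
        """(offspring, mother, father) in generation order."""
        out = []
        for fam_idx, (mother, father, n_off) in enumerate(self.families):
            for k in range(n_off):
                out.append((f"P{fam_idx}_{k:03d}", mother, father))
        return out


def haldane_recomb_fraction(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Map-distance (cM) -> recombination fraction, no interference."""
    d = np.asarray(d_cM, dtype=float)
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


@dataclass
class TruthBundle:
    """Ground truth from :func:`simulate_genotypes`.

    ``haplotypes`` has shape (n_snps, n_individuals, 2) with allele codes
    0=A, 1=B, 2=N.  ``origins[(offspring, parent)]`` gives, per SNP, which
    of the parent's two haplotypes was transmitted (crossover truth).
    ``poly_carriers[snp_id]`` has shape (n_polymorphisms, n_individuals, 2)
    marking haplotypes that carry each planted secondary polymorphism.
    """

    true_genotypes: CallMatrix
    true_classes: dict[str, str]
    pedigree: Pedigree
    gmap: GeneticMap
    haplotypes: np.ndarray
    origins: dict[tuple[str, str], np.ndarray]
    poly_carriers: dict[str, np.ndarray]
    config: SimulationConfig

    @property
    def snp_ids(self) -> list[str]:
        return self.true_genotypes.snp_ids

    @property
    def individual_ids(self) -> list[str]:
        return self.true_genotypes.individual_ids
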
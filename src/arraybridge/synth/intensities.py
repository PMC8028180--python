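"""Allele-signal model producing (Theta, R) cluster-plot coordinates."""
from __future__ import annotations

import numpy as np
import pandas as pd

from ..io import IntensityTable
from .config import PlatformModel, ProbeEffect, TruthBundle
from .genotypes import ALLELE_A, ALLELE_B, ALLELE_N


def _theta_from_signals(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Raw allelic contrast: (2/pi) * arctan(b/a), defined as 0.5 at a=b=0."""
    theta = np.full(a.shape, 0.5)
    nz = (a > 0) | (b > 0)
    theta[nz] = (2.0 / np.pi) * np.arctan2(b[nz], a[nz])
    return theta


def _map_to_centers(theta_raw: np.ndarray,
                    centers: tuple[float, float, float]) -> np.ndarray:
    """Piecewise-linear map sending raw 0 / 0.5 / 1 onto the platform's
    AA / AB / BB cluster centers."""
    c0, c1, c2 = centers
    lo = theta_raw <= 0.5
    out = np.empty_like(theta_raw)
    out[lo] = c0 + (c1 - c0) * (theta_raw[lo] / 0.5)
    out[~lo] = c1 + (c2 - c1) * ((theta_raw[~lo] - 0.5) / 0.5)
    return out


def simulate_intensities(truth: TruthBundle, platform: PlatformModel,
                         effects: dict[str, ProbeEffect] | None = None,
                         seed: int = 0) -> IntensityTable:
    """Evaluate the signal model for every individual x SNP.

    Per haplotype, the carried allele contributes dosage-proportional signal
    to its channel, scaled by the secondary-polymorphism retention of that
    haplotype; N alleles contribute only ``null_r_factor`` (split across
    channels).  A paralogous locus adds a constant ``2 * s`` signal to its
    fixed allele channel.  Theta is the arctan contrast mapped onto the
    platform's cluster centers; R is the mean channel signal scaled by
    ``r_mean``.  Gaussian noise on both axes; deterministic under ``seed``.
    """
    effects = effects or {}
    snp_ids = truth.snp_ids
    snp_set = set(snp_ids)
    for snp in effects:
        if snp not in snp_set:
            raise ValueError(f"effects reference unknown SNP {snp!r}")

    rng = np.random.default_rng(seed)
    individuals = truth.individual_ids
    n_snps, n_ind = len(snp_ids), len(individuals)
    haps = truth.haplotypes

    a_sig = np.zeros((n_snps, n_ind))
    b_sig = np.zeros((n_snps, n_ind))
    for slot in (0, 1):
        alleles = haps[:, :, slot]
        retention = np.ones((n_snps, n_ind))
        for row, snp in enumerate(snp_ids):
            effect = effects.get(snp)
            if effect is None or not effect.secondary_polymorphisms:
                continue
            flags = truth.poly_carriers[snp]
            for j, (d, _) in enumerate(effect.secondary_polymorphisms):
                keep = platform.retention(d)
                retention[row] = np.where(flags[j, :, slot],
                                          retention[row] * keep,
                                          retention[row])
        a_sig += np.where(alleles == ALLELE_A, retention, 0.0)
        b_sig += np.where(alleles == ALLELE_B, retention, 0.0)
        null_part = np.where(alleles == ALLELE_N,
                             platform.null_r_factor / 2.0, 0.0)
        a_sig += null_part / 2.0
        b_sig += null_part / 2.0

    for row, snp in enumerate(snp_ids):
        effect = effects.get(snp)
        if effect is None or effect.paralog_signal_fraction == 0.0:
            continue
        extra = 2.0 * effect.paralog_signal_fraction
        if effect.paralog_allele == "A":
            a_sig[row] += extra
        else:
            b_sig[row] += extra

    theta = _map_to_centers(_theta_from_signals(a_sig, b_sig),
                            platform.cluster_centers)
    # noise SD taken from the nearest cluster center's class
    centers = np.asarray(platform.cluster_centers)
    sds = np.asarray(platform.theta_sd)
    nearest = np.argmin(np.abs(theta[..., None] - centers), axis=-1)
    theta = theta + rng.normal(0.0, 1.0, theta.shape) * sds[nearest]
    theta = np.clip(theta, 0.0, 1.0)

    # multiplicative intensity noise: weak signals stay weak
    r = (a_sig + b_sig) / 2.0 * platform.r_mean
    r = r * (1.0 + rng.normal(0.0, platform.r_sd, r.shape))
    r = np.clip(r, 0.0, None)

    frame = pd.DataFrame({
        "snp_id": np.repeat(snp_ids, n_ind),
        "individual_id": np.tile(individuals, n_snps),
        "theta": theta.ravel(),
        "r": r.ravel(),
    })
    return IntensityTable(frame)
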
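"""Cluster-plot analytics: cluster space, mode detection, between-cluster
calls and heterozygous sub-cluster discovery.

Cluster space is the 5-95% quantile range of observed Theta (linear
interpolation between order statistics), the spread actually available for
genotype clusters after trimming outliers.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import gaussian_kde

from . import _codes
from ._codes import AA, AB, BB

LOW_N = 20  #: below this many Theta values summaries are flagged low-n


@dataclass
class ClusterProfile:
    snp_id: str
    class_stats: dict[int, dict[str, float]]  # call code -> count/mean/q5/q95
    n_modes: int
    mode_positions: list[float]
    cluster_space: float
    separation: float
    between_fraction: float
    low_r_fraction: float
    low_n: bool = False


@dataclass
class SubclusterProposal:
    snp_id: str
    members: list[str]
    from_call: int
    to_call: int = AB
    mode_theta: float = float("nan")
    supported: bool = True
    note: str = ""


def cluster_space(theta_values: np.ndarray) -> float:
    """q95 - q5 of Theta under the linear-interpolation quantile definition.

    Raises on fewer than two values; callers should flag n < 20 as low-n.
    """
    theta = np.asarray(theta_values, dtype=float)
    theta = theta[~np.isnan(theta)]
    if theta.size < 2:
        raise ValueError("cluster space undefined for fewer than 2 values")
    q5, q95 = np.quantile(theta, [0.05, 0.95])
    return float(q95 - q5)


def detect_modes(theta_values: np.ndarray, bandwidth: float | str = "silverman",
                 min_weight: float = 0.02, grid_size: int = 512,
                 max_modes: int = 6) -> list[float]:
    """Local maxima of a kernel density estimate of Theta, keeping only
    modes supported by at least ``min_weight`` of the points (noise guard).
    Deterministic."""
    theta = np.asarray(theta_values, dtype=float)
    theta = theta[~np.isnan(theta)]
    if theta.size < 2 or np.ptp(theta) < 1e-9:
        return [float(np.mean(theta))] if theta.size else []
    kde = gaussian_kde(theta, bw_method=bandwidth)
    grid = np.linspace(0.0, 1.0, grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = list(np.flatnonzero(interior) + 1)
    if dens[0] > dens[1]:
        peaks.insert(0, 0)
    if dens[-1] > dens[-2]:
        peaks.append(grid_size - 1)
    if not peaks:
        return [float(grid[np.argmax(dens)])]
    modes = [float(grid[p]) for p in peaks]
    # weight: fraction of points nearest to each mode
    assign = np.argmin(np.abs(theta[:, None] - np.asarray(modes)[None, :]),
                       axis=1)
    kept = [m for i, m in enumerate(modes)
            if (assign == i).mean() >= min_weight]
    kept.sort()
    return kept[:max_modes] if kept else [float(grid[int(np.argmax(dens))])]


def _robust_sd(values: np.ndarray, floor: float = 0.01) -> float:
    mad = np.median(np.abs(values - np.median(values)))
    return max(1.4826 * float(mad), floor)


def class_theta_stats(theta: np.ndarray, calls: np.ndarray
                      ) -> dict[int, dict[str, float]]:
    stats: dict[int, dict[str, float]] = {}
    vis = _codes.visible(np.asarray(calls, dtype=np.int8))
    for code in (AA, AB, BB):
        sel = theta[(vis == code) & ~np.isnan(theta)]
        if sel.size == 0:
            continue
        stats[code] = {
            "count": float(sel.size),
            "mean": float(np.mean(sel)),
            "median": float(np.median(sel)),
            "q5": float(np.quantile(sel, 0.05)),
            "q95": float(np.quantile(sel, 0.95)),
            "robust_sd": _robust_sd(sel),
        }
    return stats


def between_cluster_fraction(theta: np.ndarray, calls: np.ndarray,
                             band_sd_mult: float = 3.5,
                             sd_cap: float = 0.05
                             ) -> tuple[float, np.ndarray]:
    """Fraction of points lying farther than ``band_sd_mult`` robust SDs
    from every called class's Theta median, plus the outlier mask.

    The robust SD is capped at ``sd_cap``: a batch of errant between-cluster
    points inflates the MAD of whichever class they were called into, which
    would otherwise hide them inside their own band."""
    theta = np.asarray(theta, dtype=float)
    stats = class_theta_stats(theta, calls)
    if not stats:
        return 0.0, np.zeros(theta.shape, dtype=bool)
    ok = ~np.isnan(theta)
    outside = ok.copy()
    for st in stats.values():
        band = band_sd_mult * min(st["robust_sd"], sd_cap)
        outside &= np.abs(theta - st["median"]) > band
    frac = float(outside.sum() / max(ok.sum(), 1))
    return frac, outside


def _separation(stats: dict[int, dict[str, float]],
                band_sd_mult: float = 3.0) -> float:
    """Minimum normalized gap between adjacent class Theta intervals.

    Intervals are median +/- ``band_sd_mult`` robust SDs, so one or two
    errant calls inside a class cannot fake an overlap; classes with fewer
    than five members are too unreliable to define an interval and are
    skipped."""
    present = [stats[c] for c in (AA, AB, BB)
               if c in stats and stats[c]["count"] >= 5]
    if len(present) < 2:
        return float("inf")
    gaps = []
    for left, right in zip(present, present[1:]):
        l_hi = left["median"] + band_sd_mult * left["robust_sd"]
        r_lo = right["median"] - band_sd_mult * right["robust_sd"]
        l_lo = left["median"] - band_sd_mult * left["robust_sd"]
        r_hi = right["median"] + band_sd_mult * right["robust_sd"]
        spread = max(r_hi - l_lo, 1e-9)
        gaps.append((r_lo - l_hi) / spread)
    return float(min(gaps))


def profile_snp(snp_id: str, theta: np.ndarray, r: np.ndarray,
                calls: np.ndarray, r_null_abs: float = 0.1,
                band_sd_mult: float = 3.0) -> ClusterProfile:
    """Full per-SNP cluster profile feeding the classification ladder."""
    theta = np.asarray(theta, dtype=float)
    r = np.asarray(r, dtype=float)
    ok = ~np.isnan(theta)
    stats = class_theta_stats(theta, calls)
    modes = detect_modes(theta[ok]) if ok.sum() >= 2 else []
    space = cluster_space(theta[ok]) if ok.sum() >= 2 else float("nan")
    between, _ = between_cluster_fraction(theta, calls, band_sd_mult)
    r_ok = r[~np.isnan(r)]
    low_r = float((r_ok < r_null_abs * np.median(r_ok)).mean()) \
        if r_ok.size else 0.0
    return ClusterProfile(
        snp_id=snp_id, class_stats=stats, n_modes=len(modes),
        mode_positions=modes, cluster_space=space,
        separation=_separation(stats), between_fraction=between,
        low_r_fraction=low_r, low_n=ok.sum() < LOW_N)


def detect_het_subcluster(snp_id: str, theta: np.ndarray, calls: np.ndarray,
                          individual_ids: Sequence[str],
                          error_individuals: set[str],
                          linked_individuals: set[str],
                          enrich_min: float = 0.5,
                          min_members: int = 3,
                          min_gap: float = 0.03) -> SubclusterProposal | None:
    """Find a Theta mode inside a homozygote-called region that is cleanly
    separated from the main homozygote cluster and whose pedigree-linked
    members are enriched for Mendelian errors; propose recoding it to AB.

    A separated mode without any pedigree-linked member is reported as an
    unsupported mode (no recode).  Returns None when nothing is found.
    """
    theta = np.asarray(theta, dtype=float)
    vis = _codes.visible(np.asarray(calls, dtype=np.int8))
    ids = np.asarray(individual_ids)
    stats = class_theta_stats(theta, calls)
    for hom, direction in ((AA, +1), (BB, -1)):
        sel = (vis == hom) & ~np.isnan(theta)
        if sel.sum() < 2 * min_members:
            continue
        hom_theta = theta[sel]
        modes = detect_modes(hom_theta, min_weight=0.05)
        if len(modes) < 2:
            continue
        # main cluster = mode nearest the extreme; candidate = the other,
        # shifted towards the heterozygous side
        main = modes[0] if direction > 0 else modes[-1]
        candidates = [m for m in modes if m != main and
                      (m - main) * direction > 0]
        if not candidates:
            continue
        cand = candidates[0] if direction > 0 else candidates[-1]
        midpoint = (main + cand) / 2.0
        member_mask = sel & ((theta - midpoint) * direction > 0)
        members = list(ids[member_mask])
        if len(members) < min_members:
            continue
        # clean separation: member range disjoint from the main cluster core
        core = theta[sel & ~member_mask]
        if core.size == 0:
            continue
        core_edge = np.quantile(core, 0.95) if direction > 0 \
            else np.quantile(core, 0.05)
        member_edge = np.min(theta[member_mask]) if direction > 0 \
            else np.max(theta[member_mask])
        if (member_edge - core_edge) * direction < min_gap:
            continue
        linked = [m for m in members if m in linked_individuals]
        if not linked:
            return SubclusterProposal(
                snp_id, members, hom, mode_theta=float(cand),
                supported=False, note="unsupported mode: no pedigree-linked members")
        enriched = sum(1 for m in linked if m in error_individuals)
        if enriched / len(linked) < enrich_min:
            return SubclusterProposal(
                snp_id, members, hom, mode_theta=float(cand),
                supported=False,
                note="mode not enriched for Mendelian errors")
        return SubclusterProposal(snp_id, members, hom,
                                  mode_theta=float(cand), supported=True)
    return None


def detect_cross_subcluster(snp_id: str, theta: np.ndarray,
                            reference_vis: np.ndarray,
                            individual_ids: Sequence[str],
                            min_members: int = 3,
                            min_gap: float = 0.03,
                            min_mode_split: float = 0.12
                            ) -> SubclusterProposal | None:
    """Cross-platform sub-cluster detector.

    Uses a second platform's calls as reference: if the individuals that
    platform calls heterozygous split into two Theta modes here, with one
    mode displaced towards (but cleanly separated from) a homozygote core,
    the displaced members are a miscalled het sub-cluster."""
    theta = np.asarray(theta, dtype=float)
    ids = np.asarray(individual_ids)
    ok = ~np.isnan(theta)
    ab_sel = (reference_vis == AB) & ok
    if ab_sel.sum() < 2 * min_members:
        return None
    modes = detect_modes(theta[ab_sel], min_weight=0.1)
    if len(modes) < 2:
        return None
    for hom, direction in ((AA, +1), (BB, -1)):
        hom_sel = (reference_vis == hom) & ok
        if hom_sel.sum() < 3:
            continue
        cand = modes[0] if direction > 0 else modes[-1]
        far = modes[-1] if direction > 0 else modes[0]
        if (far - cand) * direction < min_mode_split:
            continue
        midpoint = (cand + far) / 2.0
        member_mask = ab_sel & ((midpoint - theta) * direction > 0)
        members = list(ids[member_mask])
        if len(members) < min_members:
            continue
        core = theta[hom_sel]
        core_edge = np.quantile(core, 0.95) if direction > 0 \
            else np.quantile(core, 0.05)
        member_edge = np.min(theta[member_mask]) if direction > 0 \
            else np.max(theta[member_mask])
        if (member_edge - core_edge) * direction < min_gap:
            continue
        return SubclusterProposal(snp_id, members, hom,
                                  mode_theta=float(cand), supported=True,
                                  note="cross-platform reference")
    return None
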
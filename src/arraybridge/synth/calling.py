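"""Emulated automatic genotype calling: per-SNP 1-D Gaussian mixtures."""
from __future__ import annotations

import warnings

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.mixture import GaussianMixture

from .. import _codes
from ..io import CallMatrix, IntensityTable
from .config import PlatformModel

_GENO = (_codes.AA, _codes.AB, _codes.BB)


def _init_means(platform: PlatformModel, k: int) -> np.ndarray:
    c = platform.cluster_centers
    if k == 3:
        means = c
    elif k == 2:
        means = (c[0], c[2])
    else:
        means = (c[1],)
    return np.asarray(means).reshape(-1, 1)


def _fit_mixture(theta: np.ndarray, platform: PlatformModel):
    """BIC-selected 1-3 component mixture, deterministically initialized at
    the platform's cluster centers."""
    x = theta.reshape(-1, 1)
    best = None
    best_bic = np.inf
    max_k = min(3, len(np.unique(np.round(theta, 6))))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for k in range(1, max_k + 1):
            gm = GaussianMixture(n_components=k, covariance_type="spherical",
                                 means_init=_init_means(platform, k),
                                 reg_covar=1e-5, random_state=0, n_init=1,
                                 max_iter=200)
            try:
                gm.fit(x)
            except ValueError:
                continue
            bic = gm.bic(x)
            if bic < best_bic - 1e-9:
                best, best_bic = gm, bic
    return best


def _component_labels(means: np.ndarray, weights: np.ndarray,
                      platform: PlatformModel) -> np.ndarray:
    """Assign genotype labels to mixture components against the platform's
    cluster centers.

    Components claim their nearest center greedily in order of decreasing
    weight (so a degenerate low-weight component can never displace a real
    cluster); ties between components of equal mean are broken by larger
    weight.
    """
    k = len(means)
    order = np.lexsort((means.ravel(), -weights))
    centers = np.asarray(platform.cluster_centers)
    labels = np.empty(k, dtype=np.int8)
    taken: set[int] = set()
    for comp in order:
        prefs = np.argsort(np.abs(centers - means[comp, 0]))
        choice = next((int(p) for p in prefs if int(p) not in taken), None)
        if choice is None:  # more than three components can never happen,
            choice = int(prefs[0])  # but stay safe
        taken.add(choice)
        labels[comp] = _GENO[choice]
    return labels


def call_genotypes(intens: IntensityTable, platform: PlatformModel,
                   p_min: float = 0.9, r_min_frac: float = 0.2,
                   min_component_weight: float = 0.02,
                   platform_tag: str = "merged") -> CallMatrix:
    """Call genotypes from Theta via per-SNP Gaussian-mixture clustering.

    Calls with maximum posterior below ``p_min`` or with R below
    ``r_min_frac`` times the SNP's median R are set to missing.
    Deterministic: mixture initialization is fixed at the platform centers.
    """
    theta_wide = intens.pivot_theta()
    r_wide = intens.pivot_r()
    snp_ids = list(theta_wide.index)
    individuals = list(theta_wide.columns)
    calls = np.full((len(snp_ids), len(individuals)), _codes.MISSING,
                    dtype=np.int8)

    for i, snp in enumerate(snp_ids):
        theta = theta_wide.iloc[i].to_numpy(float)
        r = r_wide.iloc[i].to_numpy(float)
        ok = ~(np.isnan(theta) | np.isnan(r))
        if not ok.any():
            warnings.warn(f"SNP {snp!r} has no intensity data; all missing")
            continue
        gm = _fit_mixture(theta[ok], platform)
        if gm is None:
            continue
        # prune degenerate components before labeling
        keep = gm.weights_ >= min_component_weight
        if not keep.any():
            keep[:] = True
        labels = _component_labels(gm.means_[keep], gm.weights_[keep],
                                   platform)
        post = gm.predict_proba(theta[ok].reshape(-1, 1))[:, keep]
        post = post / np.clip(post.sum(axis=1, keepdims=True), 1e-12, None)
        comp = np.argmax(post, axis=1)
        snp_calls = labels[comp]
        snp_calls[np.max(post, axis=1) < p_min] = _codes.MISSING
        median_r = float(np.median(r[ok]))
        snp_calls[r[ok] < r_min_frac * median_r] = _codes.MISSING
        calls[i, ok] = snp_calls

    return CallMatrix(snp_ids, individuals, calls, platform_tag)


def apply_call_errors(matrix: CallMatrix, rate: float,
                      rng: np.random.Generator) -> CallMatrix:
    """Flip each non-missing call to a different visible call with
    probability ``rate`` (genotype-calling error model)."""
    if rate <= 0:
        return matrix
    out = matrix.copy()
    callable_mask = out.calls != _codes.MISSING
    flip = callable_mask & (rng.random(out.calls.shape) < rate)
    idx = np.argwhere(flip)
    for i, j in idx:
        current = out.calls[i, j]
        choices = [g for g in _GENO if g != _codes.visible(
            np.array([current], dtype=np.int8))[0]]
        out.calls[i, j] = choices[rng.integers(0, len(choices))]
    return out
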
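"""Genetic-map revision against physical coordinates.

SNPs whose genetic order conflicts with their physical order are moved when
the displacement stays within 2 cM and the move does not create spurious
double recombinations; new cM positions come from linear interpolation on
relative physical distance between the nearest concordant flanks, with a
midpoint fallback.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import BlastHit, GeneticMap

MAX_MOVE_CM = 2.0
E_VALUE_MAX = 1.0e-12


@dataclass
class RevisionEntry:
    snp_id: str
    lg: str
    old_cM: float | None
    new_cM: float
    bp: int | None
    method: str  # kept | interpolated | midpoint | placed_new | conflict-kept
    flanks: tuple[str, ...] = ()


@dataclass
class MapRevision:
    revised: GeneticMap
    entries: list[RevisionEntry] = field(default_factory=list)
    skipped_lgs: list[str] = field(default_factory=list)

    def entry(self, snp_id: str) -> RevisionEntry:
        return next(e for e in self.entries if e.snp_id == snp_id)


def select_physical_position(hits: Sequence[BlastHit],
                             expected_subject: str | None = None,
                             flank_interval: tuple[int, int] | None = None,
                             e_max: float = E_VALUE_MAX) -> BlastHit | None:
    """Choose the physical position for one SNP's probe.

    Among hits with E-value strictly below ``e_max``, on the expected
    chromosome, lying within the genetically flanking interval, the hit with
    the lowest E-value wins; None when no hit qualifies.
    """
    eligible = [h for h in hits if h.e_value < e_max]
    if expected_subject is not None:
        eligible = [h for h in eligible if h.subject == expected_subject]
    if flank_interval is not None:
        lo, hi = flank_interval
        eligible = [h for h in eligible if lo <= h.s_lo and h.s_hi <= hi]
    if not eligible:
        return None
    return min(eligible, key=lambda h: h.e_value)


def interpolate_cm(target_bp: float, left: tuple[float, float],
                   right: tuple[float, float]) -> float:
    """Linear interpolation of cM on relative physical distance.

    ``left``/``right`` are (bp, cM) anchors with left.bp < target < right.bp;
    a zero physical span degrades to the midpoint.
    """
    (lbp, lcm), (rbp, rcm) = left, right
    if rbp == lbp:
        return midpoint_cm(lcm, rcm)
    frac = (target_bp - lbp) / (rbp - lbp)
    return lcm + (rcm - lcm) * frac


def midpoint_cm(left_cM: float, right_cM: float) -> float:
    """cM position equidistant between the genetically flanking SNPs."""
    return (left_cM + right_cM) / 2.0


def _anchor_mask(cm: np.ndarray, bp: np.ndarray) -> np.ndarray:
    """Longest increasing subsequence of bp (in cM order): the maximal set
    of SNPs whose genetic and physical orders agree."""
    n = len(bp)
    if n == 0:
        return np.zeros(0, dtype=bool)
    tails: list[int] = []  # indices of LIS tails
    prev = np.full(n, -1)
    tail_vals: list[float] = []
    for i in range(n):
        pos = bisect.bisect_left(tail_vals, bp[i])
        if pos == len(tail_vals):
            tail_vals.append(bp[i])
            tails.append(i)
        else:
            tail_vals[pos] = bp[i]
            tails[pos] = i
        prev[i] = tails[pos - 1] if pos > 0 else -1
    mask = np.zeros(n, dtype=bool)
    k = tails[-1]
    while k >= 0:
        mask[k] = True
        k = prev[k]
    return mask


def revise_map(gmap: GeneticMap,
               positions: Mapping[str, int],
               mendel_hook: Callable[[GeneticMap], int] | None = None,
               max_move_cM: float = MAX_MOVE_CM,
               max_passes: int = 3) -> MapRevision:
    """Reconcile genetic order with physical order, greedily and per LG.

    ``positions`` maps snp_id -> accepted physical bp (from
    :func:`select_physical_position`); unplaced SNPs (NaN cM) are placed
    when they carry an accepted position.  ``mendel_hook`` receives a
    candidate map and returns the Mendelian consistent-error count; moves
    that increase it are rejected.

    Resolution runs up to ``max_passes`` times: a swapped pair where one
    member happens to sit in the concordant anchor set only untangles once
    its partner has been moved.  Idempotent: revising an already-revised
    map is identity.
    """
    revision = _revise_once(gmap, positions, mendel_hook, max_move_cM)
    merged = {e.snp_id: e for e in revision.entries}
    for _ in range(max_passes - 1):
        again = _revise_once(revision.revised, positions, mendel_hook,
                             max_move_cM)
        moved = [e for e in again.entries
                 if e.method in ("interpolated", "midpoint")
                 and abs(e.new_cM - (e.old_cM or e.new_cM)) > 1e-12]
        if not moved:
            break
        for e in again.entries:
            prev = merged.get(e.snp_id)
            if prev is None or e.method != "kept":
                merged[e.snp_id] = e
        revision = again
    return MapRevision(revised=revision.revised,
                       entries=list(merged.values()),
                       skipped_lgs=revision.skipped_lgs)


def _revise_once(gmap: GeneticMap,
                 positions: Mapping[str, int],
                 mendel_hook: Callable[[GeneticMap], int] | None,
                 max_move_cM: float) -> MapRevision:
    entries: list[RevisionEntry] = []
    skipped: list[str] = []
    out_rows: list[dict] = []
    baseline_errors = mendel_hook(gmap) if mendel_hook else 0

    for lg, sub in gmap.per_lg():
        sub = sub.reset_index(drop=True)
        has_cm = sub["cM"].notna()
        placed = sub[has_cm].reset_index(drop=True)
        unplaced = sub[~has_cm].reset_index(drop=True)
        # effective bp: prefer the accepted BLAST position
        eff_bp = np.array([
            float(positions.get(r.snp_id, r.bp))
            if (r.snp_id in positions or not pd.isna(r.bp)) else np.nan
            for r in placed.itertuples()])
        anchored = ~np.isnan(eff_bp)
        if anchored.sum() < 2:
            skipped.append(str(lg))
            for r in placed.itertuples():
                out_rows.append({"snp_id": r.snp_id, "lg": lg, "cM": r.cM,
                                 "bp": r.bp})
                entries.append(RevisionEntry(r.snp_id, str(lg), r.cM, r.cM,
                                             None if pd.isna(r.bp)
                                             else int(r.bp), "kept"))
            continue

        cm = placed["cM"].to_numpy(float)
        new_cm = cm.copy()
        # concordant anchors among bp-known SNPs
        idx_known = np.flatnonzero(anchored)
        mask_lis = _anchor_mask(cm[idx_known], eff_bp[idx_known])
        anchor_idx = idx_known[mask_lis]
        conflict_idx = idx_known[~mask_lis]

        anchor_bp = eff_bp[anchor_idx]
        anchor_cm = cm[anchor_idx]
        anchor_ids = placed["snp_id"].to_numpy()[anchor_idx]

        for i in conflict_idx:
            snp = placed["snp_id"].iloc[i]
            tgt_bp = eff_bp[i]
            method, flanks = "conflict-kept", ()
            proposal = None
            pos = int(np.searchsorted(anchor_bp, tgt_bp))
            if 0 < pos < len(anchor_bp):
                left = (anchor_bp[pos - 1], anchor_cm[pos - 1])
                right = (anchor_bp[pos], anchor_cm[pos])
                proposal = interpolate_cm(tgt_bp, left, right)
                method = "interpolated"
                flanks = (anchor_ids[pos - 1], anchor_ids[pos])
                # fallback ladder: alternative adjacent flank (either side),
                # then midpoint
                if abs(proposal - cm[i]) > max_move_cM and \
                        pos + 1 < len(anchor_bp):
                    alt = interpolate_cm(
                        tgt_bp, left, (anchor_bp[pos + 1], anchor_cm[pos + 1]))
                    if abs(alt - cm[i]) <= max_move_cM:
                        proposal, method = alt, "interpolated"
                        flanks = (anchor_ids[pos - 1], anchor_ids[pos + 1])
                if abs(proposal - cm[i]) > max_move_cM and pos >= 2:
                    alt = interpolate_cm(
                        tgt_bp, (anchor_bp[pos - 2], anchor_cm[pos - 2]),
                        right)
                    if abs(alt - cm[i]) <= max_move_cM:
                        proposal, method = alt, "interpolated"
                        flanks = (anchor_ids[pos - 2], anchor_ids[pos])
                if abs(proposal - cm[i]) > max_move_cM:
                    mid = midpoint_cm(anchor_cm[pos - 1], anchor_cm[pos])
                    if abs(mid - cm[i]) <= max_move_cM:
                        proposal, method = mid, "midpoint"
            elif len(anchor_bp) >= 2:
                # conflict beyond the outermost anchor: linear extrapolation
                # from the two nearest anchors, floored at 0 cM
                if pos == 0:
                    a0, a1 = 0, 1
                else:
                    a0, a1 = len(anchor_bp) - 2, len(anchor_bp) - 1
                span_bp = anchor_bp[a1] - anchor_bp[a0]
                slope = ((anchor_cm[a1] - anchor_cm[a0]) / span_bp
                         if span_bp > 0 else 0.0)
                base = anchor_cm[0] if pos == 0 else anchor_cm[a1]
                ref_bp = anchor_bp[0] if pos == 0 else anchor_bp[a1]
                proposal = max(base + slope * (tgt_bp - ref_bp), 0.0)
                method = "interpolated"
                flanks = (anchor_ids[a0], anchor_ids[a1])
            if proposal is not None and abs(proposal - cm[i]) <= max_move_cM:
                if mendel_hook is not None:
                    trial = new_cm.copy()
                    trial[i] = proposal
                    trial_map = _rebuild(placed, trial, lg)
                    if mendel_hook(trial_map) > baseline_errors:
                        proposal, method = None, "conflict-kept"
            else:
                proposal, method = None, "conflict-kept"
            if proposal is not None:
                new_cm[i] = proposal
            entries.append(RevisionEntry(
                snp, str(lg), float(cm[i]), float(new_cm[i]),
                int(tgt_bp), method, tuple(flanks)))

        for i in anchor_idx:
            entries.append(RevisionEntry(
                placed["snp_id"].iloc[i], str(lg), float(cm[i]),
                float(cm[i]), int(eff_bp[i]), "kept"))
        for i in np.flatnonzero(~anchored):
            entries.append(RevisionEntry(
                placed["snp_id"].iloc[i], str(lg), float(cm[i]),
                float(cm[i]), None, "kept"))

        # place unmapped-but-hit SNPs by interpolation between anchors
        for r in unplaced.itertuples():
            if r.snp_id not in positions:
                continue
            tgt_bp = float(positions[r.snp_id])
            pos = int(np.searchsorted(anchor_bp, tgt_bp))
            if 0 < pos < len(anchor_bp):
                new_pos = interpolate_cm(
                    tgt_bp, (anchor_bp[pos - 1], anchor_cm[pos - 1]),
                    (anchor_bp[pos], anchor_cm[pos]))
                flanks = (anchor_ids[pos - 1], anchor_ids[pos])
            elif pos == 0:
                new_pos = float(anchor_cm[0])
                flanks = (anchor_ids[0],)
            else:
                new_pos = float(anchor_cm[-1])
                flanks = (anchor_ids[-1],)
            entries.append(RevisionEntry(r.snp_id, str(lg), None,
                                         float(new_pos), int(tgt_bp),
                                         "placed_new", tuple(flanks)))
            out_rows.append({"snp_id": r.snp_id, "lg": lg, "cM": new_pos,
                             "bp": int(tgt_bp)})

        for i, r in enumerate(placed.itertuples()):
            out_rows.append({"snp_id": r.snp_id, "lg": lg,
                             "cM": float(new_cm[i]),
                             "bp": (int(eff_bp[i]) if not np.isnan(eff_bp[i])
                                    else r.bp)})

    frame = pd.DataFrame(out_rows, columns=["snp_id", "lg", "cM", "bp"])
    # re-sort within LG by new cM, bp as tiebreak, preserving LG order
    lg_order = {lg: i for i, lg in enumerate(dict.fromkeys(frame["lg"]))}
    frame["_lg_rank"] = frame["lg"].map(lg_order)
    frame = (frame.sort_values(["_lg_rank", "cM", "bp"], kind="stable")
             .drop(columns="_lg_rank").reset_index(drop=True))
    return MapRevision(revised=GeneticMap(frame), entries=entries,
                       skipped_lgs=skipped)


def _rebuild(placed: pd.DataFrame, cm: np.ndarray, lg: str) -> GeneticMap:
    frame = placed.copy()
    frame["cM"] = cm
    frame["lg"] = lg
    frame = frame.sort_values(["cM", "bp"], kind="stable").reset_index(drop=True)
    return GeneticMap(frame[["snp_id", "lg", "cM", "bp"]])
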
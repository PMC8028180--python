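"""Per-SNP verdict engine: fuse concordance, Mendelian, cluster and probe
evidence into inclusion/exclusion categories and cross-platform
compatibility classes, apply the class-specific curation adjustments, and
emit the integrated dataset.

The reference workflow classified SNPs manually from cluster plots; every
quantitative trigger here is an explicit, configurable operationalization of
those visual judgments.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _codes
from ._codes import AA, AB, BB, MISSING
from .clusters import (ClusterProfile, SubclusterProposal,
                       between_cluster_fraction, detect_cross_subcluster,
                       detect_het_subcluster, profile_snp)
from .concordance import per_snp_discordance
from .io import CallMatrix, IntensityTable, Pedigree
from .mendel import (MendelScan, NullInference, infer_null_alleles,
                     scan_mendelian_errors)

COMPATIBLE_CLASSES = frozenset(
    {"A", "B", "C", "D", "E", "F", "G", "H", "I", "B/G"})

EXCLUSION_MONOMORPHIC = "Monomorphic"
EXCLUSION_POOR = "Poor clustering"
EXCLUSION_NULL_OVERLAP = "Overlapping null and homozygous clusters"
EXCLUSION_EXTRA = "Extra cluster(s) causing illogical segregation"
EXCLUSION_ILLOGICAL = "Illogical segregation"


@dataclass
class ClassifyConfig:
    mono_frac: float = 0.99
    sep_min: float = 0.05
    missing_frac_poor: float = 0.30
    poor_space_min: float = 0.40    # wide single-class smear = poor
    between_trigger: float = 0.03
    between_members_min: int = 4
    between_frac_poor: float = 0.12  # beyond this, not salvageable as B
    merge_eps: float = 0.06
    dup_discord_d_max: int = 2
    inconsistent_max: int = 2       # class P: "more than two"
    consistent_max: int = 5         # class P: "more than 5 ... in > 5"
    consistent_individuals_min: int = 5
    rare_null_max: int = 3
    enrich_min: float = 0.5
    founder_lineage: set[str] = field(default_factory=set)  # classes E/H


@dataclass
class Adjustment:
    action: str  # set-missing | recode
    snp_id: str
    individuals: tuple[str, ...]
    new_call: int | None
    reason: str


@dataclass
class SnpVerdict:
    snp_id: str
    infinium_status: str  # "included" | exclusion category
    axiom_class: str | None = None
    adjustments: list[Adjustment] = field(default_factory=list)
    evidence: dict = field(default_factory=dict)

    @property
    def included(self) -> bool:
        return self.infinium_status == "included"

    @property
    def compatible(self) -> bool:
        return self.included and self.axiom_class in COMPATIBLE_CLASSES


@dataclass
class SnpEvidence:
    """Everything the ladders look at for one SNP."""
    snp_id: str
    inf_profile: ClusterProfile | None = None
    ax_profile: ClusterProfile | None = None
    inf_mono_frac: float = 0.0
    inf_missing_frac: float = 0.0
    ax_missing_frac: float = 0.0
    inf_inconsistent: int = 0
    ax_inconsistent: int = 0
    ax_consistent_individuals: int = 0
    null_carriers: int = 0
    null_resolved_errors: bool = False
    dup_discordant: int = 0
    dup_discordant_pairs: list[int] = field(default_factory=list)
    on_axiom: bool = True
    # axiom theta grouped by infinium visible call: code -> (median, q5, q95)
    cross_groups: dict[int, tuple[float, float, float]] = field(
        default_factory=dict)
    subcluster: SubclusterProposal | None = None
    between_frac: float = 0.0
    between_members: list[str] = field(default_factory=list)
    ax_extra_mode: bool = False


# ---------------------------------------------------------------------------
# ladders
# ---------------------------------------------------------------------------

def classify_infinium(ev: SnpEvidence,
                      cfg: ClassifyConfig | None = None) -> str:
    """First-platform inclusion ladder; first match wins.

    Poor clustering is tested before monomorphism: a smeared SNP that the
    caller collapses into a single class would otherwise masquerade as
    monomorphic."""
    cfg = cfg or ClassifyConfig()
    prof = ev.inf_profile
    if prof is not None:
        n_classes = len(prof.class_stats)
        wide_single = (n_classes <= 1
                       and prof.cluster_space > cfg.poor_space_min)
        if (n_classes >= 2 and prof.separation < cfg.sep_min) \
                or ev.inf_missing_frac > cfg.missing_frac_poor \
                or wide_single:
            return EXCLUSION_POOR
    if ev.inf_mono_frac >= cfg.mono_frac:
        return EXCLUSION_MONOMORPHIC
    if ev.null_carriers > cfg.rare_null_max:
        return EXCLUSION_NULL_OVERLAP
    if prof is not None and prof.n_modes > max(len(prof.class_stats), 1) \
            and ev.inf_inconsistent > cfg.inconsistent_max:
        return EXCLUSION_EXTRA
    if ev.inf_inconsistent > cfg.inconsistent_max:
        return EXCLUSION_ILLOGICAL
    return "included"


def classify_axiom(ev: SnpEvidence,
                   cfg: ClassifyConfig | None = None
                   ) -> tuple[str, list[Adjustment]]:
    """Cross-platform compatibility ladder for a SNP already included on the
    first platform.  Every SNP receives exactly one class."""
    cfg = cfg or ClassifyConfig()
    adjustments: list[Adjustment] = []

    if not ev.on_axiom:
        return "R", adjustments

    # resolvable heterozygous sub-cluster (manual recluster emulation);
    # its members are cleanly separated, so test before the overlap classes
    if ev.subcluster is not None and ev.subcluster.supported:
        adjustments.append(Adjustment(
            "recode", ev.snp_id, tuple(ev.subcluster.members), AB,
            "het sub-cluster grouped with homozygous cluster"))
        return "C", adjustments

    # cross-group geometry (axiom Theta grouped by first-platform calls)
    overlap = _group_overlap(ev, cfg)
    if overlap == "merged":
        return "O", adjustments
    if overlap == "all":
        return "L", adjustments
    if overlap == "partial":
        return "K", adjustments

    # axiom-call geometry: unusable clustering.  A between-cluster fraction
    # too large to salvage by setting calls missing also lands here.
    prof = ev.ax_profile
    if prof is not None and (
            (len(prof.class_stats) >= 2 and prof.separation < cfg.sep_min)
            or ev.ax_missing_frac > cfg.missing_frac_poor
            or ev.between_frac > cfg.between_frac_poor):
        return "J", adjustments

    if ev.between_frac >= cfg.between_trigger and \
            len(ev.between_members) >= cfg.between_members_min:
        adjustments.append(Adjustment(
            "set-missing", ev.snp_id, tuple(ev.between_members), MISSING,
            "ambiguous cluster positions between cluster groups"))
        return "B", adjustments

    if ev.ax_extra_mode and ev.ax_inconsistent > cfg.inconsistent_max:
        return "N", adjustments

    if 1 <= ev.dup_discordant <= cfg.dup_discord_d_max:
        return "D", adjustments

    if ev.ax_inconsistent > cfg.inconsistent_max or \
            ev.ax_consistent_individuals > cfg.consistent_individuals_min:
        return "P", adjustments

    if ev.null_carriers > 0:
        if ev.null_carriers <= cfg.rare_null_max and ev.null_resolved_errors:
            return "G", adjustments
        if not ev.null_resolved_errors:
            return "Q", adjustments

    if ev.dup_discordant > cfg.dup_discord_d_max:
        return "M", adjustments  # residual irresolvable discordance

    return "A", adjustments


def _group_overlap(ev: SnpEvidence, cfg: ClassifyConfig) -> str | None:
    """Relationship between axiom Theta groups defined by first-platform
    calls: None, 'partial' (het/hom interval overlap), 'merged' (het median
    inside a hom band: the het cluster is effectively missing) or 'all'."""
    groups = ev.cross_groups
    if AB not in groups or (AA not in groups and BB not in groups):
        return None
    het_med, het_q5, het_q95 = groups[AB]
    overlaps = []
    merged = False
    for hom in (AA, BB):
        if hom not in groups:
            continue
        med, q5, q95 = groups[hom]
        overlap = het_q5 <= q95 and q5 <= het_q95
        overlaps.append(overlap)
        if overlap and abs(het_med - med) < cfg.merge_eps:
            merged = True
    if merged:
        return "merged"
    if all(overlaps) and len(overlaps) == 2:
        return "all"
    if any(overlaps):
        return "partial"
    return None


def _all_groups_overlap(ev: SnpEvidence) -> bool:
    groups = ev.cross_groups
    present = [groups[c] for c in (AA, AB, BB) if c in groups]
    if len(present) < 3:
        return False
    for (m1, lo1, hi1), (m2, lo2, hi2) in zip(present, present[1:]):
        if not (lo1 <= hi2 and lo2 <= hi1):
            return False
    return True


# ---------------------------------------------------------------------------
# evidence assembly
# ---------------------------------------------------------------------------

def build_evidence(snp_id: str,
                   inf_calls: CallMatrix, ax_calls: CallMatrix | None,
                   inf_intens: IntensityTable | None,
                   ax_intens: IntensityTable | None,
                   inf_scan: MendelScan | None,
                   ax_scan: MendelScan | None,
                   ax_consistent_by_snp: Mapping[str, int] | None,
                   null_inf: NullInference | None,
                   discordance: Mapping[str, Mapping[str, object]] | None,
                   ped: Pedigree | None,
                   theta_cache: dict | None = None,
                   cfg: ClassifyConfig | None = None) -> SnpEvidence:
    """Assemble the full evidence record for one SNP."""
    cfg = cfg or ClassifyConfig()
    ev = SnpEvidence(snp_id=snp_id)
    row = inf_calls.snp_row(snp_id)
    vis = _codes.visible(row)
    called = vis != MISSING
    ev.inf_missing_frac = float((~called).mean())
    if called.any():
        counts = np.bincount(vis[called], minlength=3)
        ev.inf_mono_frac = float(counts.max() / called.sum())

    cache = theta_cache if theta_cache is not None else {}

    def wide(platform: str, table: IntensityTable | None):
        if table is None:
            return None
        key = ("wide", platform)
        if key not in cache:
            cache[key] = (table.pivot_theta(), table.pivot_r())
        return cache[key]

    inf_wide = wide("infinium", inf_intens)
    if inf_wide is not None:
        theta_w, r_w = inf_wide
        theta = theta_w.loc[snp_id].reindex(inf_calls.individual_ids) \
                       .to_numpy(float)
        r = r_w.loc[snp_id].reindex(inf_calls.individual_ids).to_numpy(float)
        ev.inf_profile = profile_snp(snp_id, theta, r, row)
    if inf_scan is not None:
        ev.inf_inconsistent = inf_scan.per_snp_inconsistent.get(snp_id, 0)
    if null_inf is not None:
        ev.null_carriers = null_inf.per_snp_carriers.get(snp_id, 0)

    if ax_calls is None or snp_id not in ax_calls._snp_index:
        ev.on_axiom = False
        return ev
    ax_row = ax_calls.snp_row(snp_id)
    ax_vis = _codes.visible(ax_row)
    ev.ax_missing_frac = float((ax_vis == MISSING).mean())

    ax_wide = wide("axiom", ax_intens)
    ax_theta = None
    if ax_wide is not None:
        theta_w, r_w = ax_wide
        ax_theta = theta_w.loc[snp_id].reindex(ax_calls.individual_ids) \
                          .to_numpy(float)
        ax_r = r_w.loc[snp_id].reindex(ax_calls.individual_ids) \
                  .to_numpy(float)
        ev.ax_profile = profile_snp(snp_id, ax_theta, ax_r, ax_row)
        frac, outside = between_cluster_fraction(ax_theta, ax_row)
        ev.between_frac = frac
        ev.between_members = [ind for ind, out in
                              zip(ax_calls.individual_ids, outside) if out]
        n_classes = max(len(ev.ax_profile.class_stats), 1)
        ev.ax_extra_mode = ev.ax_profile.n_modes > n_classes

        # axiom Theta grouped by first-platform call (shared individuals)
        shared = [i for i in ax_calls.individual_ids
                  if i in inf_calls._ind_index]
        if shared:
            inf_idx = [inf_calls.ind_pos(i) for i in shared]
            ax_idx = [ax_calls.ind_pos(i) for i in shared]
            inf_vis_shared = vis[inf_idx]
            theta_shared = ax_theta[ax_idx]
            for code in (AA, AB, BB):
                sel = theta_shared[(inf_vis_shared == code)
                                   & ~np.isnan(theta_shared)]
                if sel.size >= 3:
                    ev.cross_groups[code] = (
                        float(np.median(sel)),
                        float(np.quantile(sel, 0.05)),
                        float(np.quantile(sel, 0.95)))

    if ax_scan is not None:
        ev.ax_inconsistent = ax_scan.per_snp_inconsistent.get(snp_id, 0)
        if ax_theta is not None:
            # support for a het sub-cluster comes from Mendelian errors and
            # from cross-platform discordance: members called heterozygous
            # on the first platform but homozygous on this one
            error_inds = {ind for err in ax_scan.errors
                          if err.snp_id == snp_id
                          for ind in err.individuals}
            linked = {p for duo in ped.duos() for p in duo} \
                if ped is not None else set()
            shared_set = set(ax_calls.individual_ids) \
                & set(inf_calls.individual_ids)
            for ind in shared_set:
                inf_c = vis[inf_calls.ind_pos(ind)]
                ax_c = ax_vis[ax_calls.ind_pos(ind)]
                if inf_c == AB and ax_c in (AA, BB):
                    error_inds.add(ind)
            ev.subcluster = detect_het_subcluster(
                snp_id, ax_theta, ax_row, ax_calls.individual_ids,
                error_inds, linked | shared_set, enrich_min=cfg.enrich_min)
            if (ev.subcluster is None or not ev.subcluster.supported) \
                    and shared_set:
                inf_vis_by_ax = np.array(
                    [vis[inf_calls.ind_pos(i)] if i in shared_set
                     else MISSING for i in ax_calls.individual_ids],
                    dtype=np.int8)
                cross = detect_cross_subcluster(
                    snp_id, ax_theta, inf_vis_by_ax,
                    ax_calls.individual_ids)
                if cross is not None:
                    ev.subcluster = cross
    if ax_consistent_by_snp is not None:
        ev.ax_consistent_individuals = ax_consistent_by_snp.get(snp_id, 0)

    if discordance is not None and snp_id in discordance:
        rec = discordance[snp_id]
        ev.dup_discordant = int(rec["n_discordant"])
        ev.dup_discordant_pairs = list(rec["discordant_pairs"])
    return ev


# ---------------------------------------------------------------------------
# adjustments and integration
# ---------------------------------------------------------------------------

def apply_adjustments(matrix: CallMatrix, verdicts: Sequence[SnpVerdict],
                      dup_pairs: Sequence[tuple[str, str]] | None = None
                      ) -> tuple[CallMatrix, list[Adjustment]]:
    """Apply each verdict's curation actions to a copy of the matrix.

    Class-D verdicts additionally set the discordant duplicate calls to
    missing when ``dup_pairs`` is provided.  Idempotent; every change is
    logged."""
    out = matrix.copy()
    log: list[Adjustment] = []
    for verdict in verdicts:
        if verdict.snp_id not in out._snp_index:
            continue
        row = out.snp_pos(verdict.snp_id)
        for adj in verdict.adjustments:
            for ind in adj.individuals:
                if ind not in out._ind_index:
                    raise ValueError(
                        f"adjustment for unknown individual {ind!r} "
                        f"at SNP {verdict.snp_id!r}")
                col = out.ind_pos(ind)
                new = MISSING if adj.action == "set-missing" else adj.new_call
                if out.calls[row, col] != new:
                    log.append(Adjustment(adj.action, verdict.snp_id, (ind,),
                                          new, adj.reason))
                    out.calls[row, col] = new
        if verdict.axiom_class == "D" and dup_pairs is not None:
            targets = {ind for k in verdict.evidence.get(
                "discordant_pairs", []) for ind in dup_pairs[k]}
            for ind in targets:
                if ind not in out._ind_index:
                    continue
                col = out.ind_pos(ind)
                if out.calls[row, col] != MISSING:
                    log.append(Adjustment("set-missing", verdict.snp_id,
                                          (ind,), MISSING,
                                          "1-2 discordant duplicate calls"))
                    out.calls[row, col] = MISSING
    return out, log


@dataclass
class IntegratedDataset:
    matrix: CallMatrix
    provenance: dict[str, dict]
    maf: dict[str, float]
    conflicts: list[tuple[str, str]]  # (snp, clone-group key) set missing


def integrate(infinium: CallMatrix, axiom: CallMatrix | None,
              clone_groups: Sequence[Iterable[str]],
              verdicts: Sequence[SnpVerdict]) -> IntegratedDataset:
    """Merge curated matrices over compatible SNPs, collapsing each clone
    group to one consensus column (unanimity among non-missing calls, else
    missing and logged)."""
    compatible = [v for v in verdicts if v.compatible]
    snp_ids = [v.snp_id for v in compatible
               if v.snp_id in infinium._snp_index]
    group_of: dict[str, int] = {}
    groups = [set(g) for g in clone_groups]
    for gi, grp in enumerate(groups):
        for member in grp:
            group_of[member] = gi

    columns: list[str] = []
    sources: list[list[tuple[CallMatrix, str]]] = []
    seen_groups: set[int] = set()
    matrices = [m for m in (infinium, axiom) if m is not None]
    column_index: dict[str, int] = {}
    for matrix in matrices:
        for ind in matrix.individual_ids:
            gi = group_of.get(ind)
            if gi is None:
                # same id on both platforms is the same individual: the two
                # platform columns merge into one consensus column
                if ind in column_index:
                    sources[column_index[ind]].append((matrix, ind))
                else:
                    column_index[ind] = len(columns)
                    columns.append(ind)
                    sources.append([(matrix, ind)])
            elif gi not in seen_groups:
                seen_groups.add(gi)
                key = f"G{gi}:{min(groups[gi])}"
                columns.append(key)
                sources.append([(m, member) for m in matrices
                                for member in groups[gi]
                                if member in m._ind_index])
            else:
                key = f"G{gi}:{min(groups[gi])}"
                sources[columns.index(key)].append((matrix, ind))

    calls = np.full((len(snp_ids), len(columns)), MISSING, dtype=np.int8)
    conflicts: list[tuple[str, str]] = []
    for i, snp in enumerate(snp_ids):
        for j, src in enumerate(sources):
            values = set()
            for matrix, ind in src:
                if snp in matrix._snp_index:
                    c = int(matrix.calls[matrix.snp_pos(snp),
                                         matrix.ind_pos(ind)])
                    if c != MISSING:
                        values.add(c)
            if len(values) == 1:
                calls[i, j] = values.pop()
            elif len(values) > 1:
                conflicts.append((snp, columns[j]))

    merged = CallMatrix(snp_ids, columns, calls, "merged")
    # MAF excludes extra clone-group members by construction (one column per
    # clone group)
    maf: dict[str, float] = {}
    vis = merged.visible()
    for i, snp in enumerate(snp_ids):
        row = vis[i]
        called = row != MISSING
        if not called.any():
            maf[snp] = float("nan")
            continue
        n_b = int((row[called] == AB).sum()) + 2 * int((row[called] == BB).sum())
        freq = n_b / (2.0 * called.sum())
        maf[snp] = float(min(freq, 1.0 - freq))

    provenance = {v.snp_id: {"axiom_class": v.axiom_class,
                             "n_adjustments": len(v.adjustments)}
                  for v in compatible}
    return IntegratedDataset(matrix=merged, provenance=provenance, maf=maf,
                             conflicts=conflicts)


# ---------------------------------------------------------------------------
# whole-pipeline driver
# ---------------------------------------------------------------------------

@dataclass
class PipelineResult:
    verdicts: list[SnpVerdict]
    curated_axiom: CallMatrix | None
    integrated: IntegratedDataset
    action_log: list[Adjustment]
    class_counts: dict[str, int]


def classify_all(inf_calls: CallMatrix, ax_calls: CallMatrix | None,
                 inf_intens: IntensityTable | None,
                 ax_intens: IntensityTable | None,
                 ped: Pedigree,
                 dup_pairs: Sequence[tuple[str, str]],
                 gmap=None, cfg: ClassifyConfig | None = None
                 ) -> PipelineResult:
    """Run the full evidence -> verdict -> curation -> integration chain."""
    from .mendel import count_consistent_unrelated, detect_consistent_errors

    cfg = cfg or ClassifyConfig()
    inf_scan = scan_mendelian_errors(inf_calls, ped)
    null_inf = infer_null_alleles(inf_calls, inf_intens, ped)
    inf_scan_post = scan_mendelian_errors(null_inf.matrix, ped)

    ax_scan = scan_mendelian_errors(ax_calls, ped) if ax_calls else None
    ax_consistent: Mapping[str, int] | None = None
    if ax_calls is not None and gmap is not None:
        cons_errors = detect_consistent_errors(ax_calls, ped, gmap)
        ax_consistent = count_consistent_unrelated(cons_errors, ped)

    null_excl: dict[str, set[str]] = {}
    for call in null_inf.null_calls:
        null_excl.setdefault(call.snp_id, set()).add(call.individual)
    discord = per_snp_discordance(dup_pairs, inf_calls, ax_calls,
                                  null_exclude=null_excl) \
        if ax_calls is not None else {}

    cache: dict = {}
    verdicts: list[SnpVerdict] = []
    for snp in inf_calls.snp_ids:
        ev = build_evidence(snp, inf_calls, ax_calls, inf_intens, ax_intens,
                            inf_scan_post, ax_scan, ax_consistent, null_inf,
                            discord, ped, theta_cache=cache, cfg=cfg)
        status = classify_infinium(ev, cfg)
        verdict = SnpVerdict(snp, status)
        verdict.evidence["discordant_pairs"] = ev.dup_discordant_pairs
        if status == "included":
            ax_class, adjustments = classify_axiom(ev, cfg)
            verdict.axiom_class = ax_class
            verdict.adjustments = adjustments
        verdicts.append(verdict)

    curated_ax, log = (apply_adjustments(ax_calls, verdicts, dup_pairs)
                       if ax_calls is not None else (None, []))
    integrated = integrate(inf_calls, curated_ax,
                           clone_groups=_pairs_to_groups(dup_pairs),
                           verdicts=verdicts)
    counts: dict[str, int] = {}
    for v in verdicts:
        key = v.axiom_class if v.included else v.infinium_status
        counts[key] = counts.get(key, 0) + 1
    return PipelineResult(verdicts=verdicts, curated_axiom=curated_ax,
                          integrated=integrated, action_log=log,
                          class_counts=counts)


def _pairs_to_groups(pairs: Sequence[tuple[str, str]]) -> list[set[str]]:
    groups: list[set[str]] = []
    seen: dict[str, int] = {}
    for a, b in pairs:
        ga, gb = seen.get(a), seen.get(b)
        if ga is None and gb is None:
            seen[a] = seen[b] = len(groups)
            groups.append({a, b})
        elif ga is not None and gb is None:
            groups[ga].add(b)
            seen[b] = ga
        elif gb is not None and ga is None:
            groups[gb].add(a)
            seen[a] = gb
        elif ga != gb:
            groups[ga] |= groups[gb]
            for member in groups[gb]:
                seen[member] = ga
            groups[gb] = set()
    return [g for g in groups if len(g) >= 2]
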
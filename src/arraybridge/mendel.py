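"""Mendelian inconsistent/consistent error detection and null-allele
inference over a pedigree.

Duo and trio checks use allele-set logic over genotypes; the null-aware
code space treats N as a transmissible third allele.  The consistent-error
operator flags singleton double-recombinants in map order.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _codes
from ._codes import AA, AB, BB, AN, BN, NN, MISSING, CODE_ALLELES
from .io import CallMatrix, GeneticMap, IntensityTable, Pedigree


@dataclass(frozen=True)
class MendelError:
    kind: str  # "inconsistent" | "consistent"
    snp_id: str
    individuals: tuple[str, ...]
    evidence: str  # opposing-homozygote-duo | impossible-trio | double-recombinant


@dataclass(frozen=True)
class NullCall:
    snp_id: str
    individual: str
    recoded_call: int  # AN, BN or NN
    support: tuple[str, ...]


@dataclass
class MendelScan:
    per_snp_inconsistent: dict[str, int]
    per_individual: dict[str, int]
    errors: list[MendelError]

    @property
    def total(self) -> int:
        return sum(self.per_snp_inconsistent.values())


@dataclass
class NullInference:
    null_calls: list[NullCall]
    matrix: CallMatrix  # recoded copy
    per_snp_carriers: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# duo / trio logic
# ---------------------------------------------------------------------------

def _duo_consistent(parent: int, offspring: int) -> bool:
    p = set(CODE_ALLELES[parent])
    o = set(CODE_ALLELES[offspring])
    return bool(p & o)


def _trio_consistent(mother: int, father: int, offspring: int) -> bool:
    m = set(CODE_ALLELES[mother])
    f = set(CODE_ALLELES[father])
    o1, o2 = CODE_ALLELES[offspring]
    return (o1 in m and o2 in f) or (o2 in m and o1 in f)


def duo_inconsistent(parent_call: int, offspring_call: int) -> bool:
    """True iff the duo is Mendelian impossible (opposing homozygotes in the
    visible space; allele-disjoint in the null-aware space).  Missing calls
    never flag."""
    if parent_call == MISSING or offspring_call == MISSING:
        return False
    return not _duo_consistent(parent_call, offspring_call)


def trio_inconsistent(mother_call: int, father_call: int,
                      offspring_call: int) -> bool:
    """True iff the offspring genotype is impossible under biallelic (or
    null-aware triallelic) transmission from the two parents.  A missing
    parent degrades to duo logic with the other parent."""
    if offspring_call == MISSING:
        return False
    if mother_call == MISSING and father_call == MISSING:
        return False
    if mother_call == MISSING:
        return duo_inconsistent(father_call, offspring_call)
    if father_call == MISSING:
        return duo_inconsistent(mother_call, offspring_call)
    return not _trio_consistent(mother_call, father_call, offspring_call)


# lookup tables indexed by call code + 1 (so MISSING maps to index 0)
_CODES_ALL = (MISSING, AA, AB, BB, AN, BN, NN)
DUO_TABLE = np.zeros((7, 7), dtype=bool)
TRIO_TABLE = np.zeros((7, 7, 7), dtype=bool)
for _p in _CODES_ALL:
    for _o in _CODES_ALL:
        DUO_TABLE[_p + 1, _o + 1] = duo_inconsistent(_p, _o)
for _m in _CODES_ALL:
    for _f in _CODES_ALL:
        for _o in _CODES_ALL:
            TRIO_TABLE[_m + 1, _f + 1, _o + 1] = trio_inconsistent(_m, _f, _o)


# ---------------------------------------------------------------------------
# pedigree-wide scan
# ---------------------------------------------------------------------------

def scan_mendelian_errors(matrix: CallMatrix, ped: Pedigree,
                          collect_errors: bool = True) -> MendelScan:
    """Test every duo and complete trio at every SNP.

    Trio errors are recorded as such only when neither parental duo flags
    on its own; duo errors are recorded per (parent, offspring) link.
    Individuals absent from the matrix are skipped.
    """
    present = set(matrix.individual_ids)
    snp_ids = matrix.snp_ids
    per_snp = np.zeros(matrix.n_snps, dtype=int)
    per_ind: dict[str, int] = {}
    errors: list[MendelError] = []

    trio_offspring = set()
    for mother, father, child in ped.trios():
        if {mother, father, child} <= present:
            trio_offspring.add(child)
            m = matrix.column(mother) + 1
            f = matrix.column(father) + 1
            o = matrix.column(child) + 1
            trio_err = TRIO_TABLE[m, f, o]
            duo_m = DUO_TABLE[m, o]
            duo_f = DUO_TABLE[f, o]
            trio_only = trio_err & ~duo_m & ~duo_f
            for rows, inds, evid in (
                    (duo_m, (mother, child), "opposing-homozygote-duo"),
                    (duo_f, (father, child), "opposing-homozygote-duo"),
                    (trio_only, (mother, father, child), "impossible-trio")):
                n = int(rows.sum())
                if n == 0:
                    continue
                per_snp += rows
                for ind in inds:
                    per_ind[ind] = per_ind.get(ind, 0) + n
                if collect_errors:
                    for row in np.flatnonzero(rows):
                        errors.append(MendelError("inconsistent",
                                                  snp_ids[row], inds, evid))

    for parent, child in ped.duos():
        if child in trio_offspring and \
                all(p is None or p in present
                    for p in ped.parents[child]):
            continue  # handled in the trio loop
        if parent not in present or child not in present:
            continue
        p = matrix.column(parent) + 1
        o = matrix.column(child) + 1
        duo_err = DUO_TABLE[p, o]
        n = int(duo_err.sum())
        if n:
            per_snp += duo_err
            for ind in (parent, child):
                per_ind[ind] = per_ind.get(ind, 0) + n
            if collect_errors:
                for row in np.flatnonzero(duo_err):
                    errors.append(MendelError(
                        "inconsistent", snp_ids[row], (parent, child),
                        "opposing-homozygote-duo"))

    return MendelScan(
        per_snp_inconsistent={s: int(per_snp[i])
                              for i, s in enumerate(snp_ids)},
        per_individual=per_ind, errors=errors)


# ---------------------------------------------------------------------------
# consistent errors: singleton double-recombinants
# ---------------------------------------------------------------------------

def _transmitted_states(parent_calls: np.ndarray, other_calls: np.ndarray,
                        child_calls: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Rows where the allele transmitted by an AB parent is unambiguous,
    and the transmitted state (0 = A, 1 = B)."""
    pv = _codes.visible(parent_calls)
    ov = _codes.visible(other_calls)
    cv = _codes.visible(child_calls)
    informative = pv == AB
    state = np.full(pv.shape, -1, dtype=np.int8)
    state[informative & (cv == AA)] = 0
    state[informative & (cv == BB)] = 1
    het_child = informative & (cv == AB)
    state[het_child & (ov == AA)] = 1
    state[het_child & (ov == BB)] = 0
    ok = state >= 0
    return ok, state


def detect_consistent_errors(matrix: CallMatrix, ped: Pedigree,
                             gmap: GeneticMap, k_flank: int = 3,
                             w_cM: float = 10.0,
                             min_offspring: int = 4) -> list[MendelError]:
    """Flag singleton double-recombinants in parent-offspring transmissions.

    The transmitted-allele sequence of an unphased parent flips whenever the
    parent's phase flips, so raw allele states cannot be scanned directly.
    Each parent is first phased by majority vote across its offspring: for
    adjacent informative SNPs the relative phase is the transmission pattern
    shared by most offspring (most gametes are non-recombinant).  On the
    phase-corrected origin sequences, a state flip at a single SNP flanked on
    both sides by at least ``k_flank`` concordant informative SNPs within
    ``w_cM`` is an implausible double recombination.  Parents with fewer
    than ``min_offspring`` genotyped offspring cannot be phased and are
    skipped.
    """
    present = set(matrix.individual_ids)
    mapped = gmap.frame[gmap.frame["snp_id"].isin(set(matrix.snp_ids))]
    errors: list[MendelError] = []

    offspring_of: dict[str, list[str]] = {}
    for parent, child in ped.duos():
        if parent in present and child in present:
            offspring_of.setdefault(parent, []).append(child)

    for parent, children in offspring_of.items():
        if len(children) < min_offspring:
            continue
        parent_calls = matrix.column(parent)
        # per-offspring raw transmitted states
        state_rows = []
        for child in children:
            mother, father = ped.parents[child]
            other = father if parent == mother else mother
            other_calls = (matrix.column(other) if other in present
                           else np.full(matrix.n_snps, MISSING, np.int8))
            ok, state = _transmitted_states(parent_calls, other_calls,
                                            matrix.column(child))
            state = np.where(ok, state, -1)
            state_rows.append(state)
        states_all = np.stack(state_rows)  # children x snps; -1 unknown

        for _, sub in mapped.groupby("lg", sort=False):
            rows = np.array([matrix.snp_pos(s) for s in sub["snp_id"]])
            cm = sub["cM"].to_numpy(float)
            snps = sub["snp_id"].to_numpy()
            sub_states = states_all[:, rows]
            informative = (sub_states >= 0).any(axis=0) & \
                (_codes.visible(parent_calls[rows]) == AB)
            idx = np.flatnonzero(informative)
            if idx.size < 2 * k_flank + 1:
                continue
            seq = sub_states[:, idx]  # children x informative snps
            # majority-vote relative phase along the chain; a link without
            # enough jointly-informative offspring cannot be phased, so it
            # starts a new segment that singleton detection must not span
            phase = np.zeros(idx.size, dtype=np.int8)
            segment = np.zeros(idx.size, dtype=np.int32)
            min_link = 3
            for i in range(1, idx.size):
                both = (seq[:, i - 1] >= 0) & (seq[:, i] >= 0)
                if both.sum() < min_link:
                    phase[i] = phase[i - 1]
                    segment[i] = segment[i - 1] + 1
                    continue
                segment[i] = segment[i - 1]
                flip_frac = float(np.mean(
                    seq[both, i - 1] != seq[both, i]))
                rel = 1 if flip_frac > 0.5 else 0
                phase[i] = phase[i - 1] ^ rel
            corrected = np.where(seq >= 0, seq ^ phase[None, :], -1)
            positions = cm[idx]
            snp_names = snps[idx]

            for c, child in enumerate(children):
                known = np.flatnonzero(corrected[c] >= 0)
                if known.size < 2 * k_flank + 1:
                    continue
                s = corrected[c][known]
                pos = positions[known]
                names = snp_names[known]
                seg = segment[known]
                for i in range(1, len(s) - 1):
                    if not (s[i] != s[i - 1] and s[i - 1] == s[i + 1]
                            and seg[i - 1] == seg[i] == seg[i + 1]):
                        continue
                    flank = s[i - 1]
                    n_left = 0
                    j = i - 1
                    while j >= 0 and s[j] == flank and seg[j] == seg[i] and \
                            pos[i] - pos[j] <= w_cM:
                        n_left += 1
                        j -= 1
                    n_right = 0
                    j = i + 1
                    while j < len(s) and s[j] == flank and \
                            seg[j] == seg[i] and pos[j] - pos[i] <= w_cM:
                        n_right += 1
                        j += 1
                    if n_left >= k_flank and n_right >= k_flank:
                        errors.append(MendelError(
                            "consistent", str(names[i]), (child, parent),
                            "double-recombinant"))
    return errors


def count_consistent_unrelated(errors: Sequence[MendelError],
                               ped: Pedigree) -> dict[str, int]:
    """Per SNP, the number of distinct offspring with consistent errors."""
    out: dict[str, set[str]] = {}
    for err in errors:
        if err.kind == "consistent":
            out.setdefault(err.snp_id, set()).add(err.individuals[0])
    return {snp: len(inds) for snp, inds in out.items()}


# ---------------------------------------------------------------------------
# null-allele inference
# ---------------------------------------------------------------------------

def infer_null_alleles(matrix: CallMatrix, intens: IntensityTable | None,
                       ped: Pedigree, r_frac: float = 0.75,
                       r_null_abs: float = 0.1, rare_max: int = 3,
                       ambiguous_theta: tuple[float, float] = (0.2, 0.8)
                       ) -> NullInference:
    """Recode opposing-homozygote duos whose members show depressed R as
    null-allele carriers (AN/BN), propagate forced carriers through the
    pedigree, and recode near-zero-R individuals with ambiguous Theta as
    double null (NN).

    Without intensity data the evidence is pedigree-only and recoding is
    limited to propagation from nothing, i.e. empty.
    """
    out = matrix.copy()
    null_calls: dict[tuple[str, str], NullCall] = {}
    snp_ids = matrix.snp_ids

    r_wide = theta_wide = None
    if intens is not None:
        r_wide = intens.pivot_r().reindex(index=snp_ids,
                                          columns=matrix.individual_ids)
        theta_wide = intens.pivot_theta().reindex(index=snp_ids,
                                                  columns=matrix.individual_ids)
        import warnings as _warnings
        r_arr = r_wide.to_numpy(float)
        vis = out.visible()
        called = vis != MISSING
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            overall_med = np.nanmedian(np.where(called, r_arr, np.nan), axis=1)
            cluster_med = {}
            for code in (AA, AB, BB):
                sel = np.where(vis == code, r_arr, np.nan)
                cluster_med[code] = np.nanmedian(sel, axis=1)

    def r_is_low(row: int, col: int, code: int) -> bool:
        if intens is None:
            return True  # pedigree-only mode: lower-confidence evidence
        r_val = r_arr[row, col]
        if np.isnan(r_val):
            return False
        ref = overall_med[row]
        cm = cluster_med[code][row]
        if not np.isnan(cm):
            ref = max(ref, cm)
        return bool(r_val < r_frac * ref)

    def recode(row: int, col: int, support: tuple[str, ...]) -> bool:
        vis_call = _codes.visible(np.array([out.calls[row, col]]))[0]
        new = {AA: AN, BB: BN}.get(int(vis_call))
        if new is None or out.calls[row, col] == new:
            return False
        out.calls[row, col] = new
        ind = matrix.individual_ids[col]
        null_calls[(snp_ids[row], ind)] = NullCall(
            snp_ids[row], ind, new, support)
        return True

    present = set(matrix.individual_ids)
    duos = [(p, c) for p, c in ped.duos()
            if p in present and c in present]

    # pass 1: opposing-homozygote duos with depressed R on both sides
    for parent, child in duos:
        pi, ci = matrix.ind_pos(parent), matrix.ind_pos(child)
        pv = _codes.visible(out.calls[:, pi])
        cv = _codes.visible(out.calls[:, ci])
        opposing = ((pv == AA) & (cv == BB)) | ((pv == BB) & (cv == AA))
        for row in np.flatnonzero(opposing):
            if r_is_low(row, pi, int(pv[row])) and \
                    r_is_low(row, ci, int(cv[row])):
                support = ("opposing-homozygote-duo",) + \
                    (("intensity",) if intens is not None else ())
                recode(row, pi, support)
                recode(row, ci, support)

    def propagate() -> None:
        """Recode N where transmission forces it, to a fixpoint."""
        changed = True
        while changed:
            changed = False
            for parent, child in duos:
                pi, ci = matrix.ind_pos(parent), matrix.ind_pos(child)
                p_calls = out.calls[:, pi]
                c_calls = out.calls[:, ci]
                err = DUO_TABLE[p_calls + 1, c_calls + 1]
                for row in np.flatnonzero(err):
                    p_has_n = int(p_calls[row]) in (AN, BN, NN)
                    c_has_n = int(c_calls[row]) in (AN, BN, NN)
                    if p_has_n and not c_has_n:
                        changed |= recode(row, ci, ("forced-transmission",))
                    elif c_has_n and not p_has_n:
                        changed |= recode(row, pi, ("forced-transmission",))

    # pass 2: propagate N where transmission forces it
    propagate()

    # pass 3: near-zero R with ambiguous Theta -> double null, then a second
    # propagation so that carrier parents of NN individuals get recoded too
    if intens is not None:
        theta_arr = theta_wide.to_numpy(float)
        lo, hi = ambiguous_theta
        low_r = r_arr < r_null_abs * overall_med[:, None]
        ambiguous = (theta_arr > lo) & (theta_arr < hi)
        for row, col in np.argwhere(low_r & ambiguous):
            if out.calls[row, col] != NN:
                out.calls[row, col] = NN
                ind = matrix.individual_ids[col]
                null_calls[(snp_ids[row], ind)] = NullCall(
                    snp_ids[row], ind, NN, ("near-zero-R",))
        propagate()

    carriers: dict[str, int] = {}
    for (snp, _ind) in null_calls:
        carriers[snp] = carriers.get(snp, 0) + 1
    return NullInference(null_calls=list(null_calls.values()), matrix=out,
                         per_snp_carriers=carriers)
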
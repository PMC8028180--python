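"""Duplicate identification, within-platform repeatability and per-SNP
discordance tallies.

Comparisons operate on the visible call space (AN counts as AA, etc.)
because duplicates are identified before null-allele curation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from . import _codes
from .io import CallMatrix

#: below this many jointly-called loci a comparison is considered unreliable
MIN_COMPARED_DEFAULT = 500


@dataclass(frozen=True)
class ConcordanceResult:
    individual_a: str
    individual_b: str
    n_compared: int
    n_concordant: int

    @property
    def fraction(self) -> float:
        if self.n_compared == 0:
            return float("nan")
        return self.n_concordant / self.n_compared

    @property
    def valid(self) -> bool:
        return self.n_compared > 0


@dataclass
class DuplicateReport:
    pairs: list[ConcordanceResult]
    clone_groups: list[set[str]]
    near_misses: list[ConcordanceResult]


@dataclass
class RepeatabilityReport:
    """Per-accession mean percent discordance and the grand mean.

    An accession with k replicates contributes the average over its C(k,2)
    pair values as a single number before the across-accession grand mean.
    """
    per_accession: dict[str, float] = field(default_factory=dict)
    grand_mean_pct: float = float("nan")
    n_pairs: int = 0


def _visible_vectors(calls_a: np.ndarray, calls_b: np.ndarray,
                     null_resolved: bool = False
                     ) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(calls_a, dtype=np.int8)
    b = np.asarray(calls_b, dtype=np.int8)
    if not null_resolved:
        a, b = _codes.visible(a), _codes.visible(b)
    return a, b


def pairwise_concordance(calls_a: np.ndarray, calls_b: np.ndarray,
                         name_a: str = "a", name_b: str = "b",
                         null_resolved: bool = False,
                         exclude: np.ndarray | None = None
                         ) -> ConcordanceResult:
    """Concordance over loci called in both vectors.

    Loci missing in either vector are excluded from the denominator;
    ``exclude`` optionally masks further loci (e.g. confirmed null alleles,
    which are not tallied as cross-platform discordances).
    """
    a, b = _visible_vectors(calls_a, calls_b, null_resolved)
    both = (a != _codes.MISSING) & (b != _codes.MISSING)
    if exclude is not None:
        both &= ~np.asarray(exclude, dtype=bool)
    n_compared = int(both.sum())
    n_concordant = int((a[both] == b[both]).sum())
    return ConcordanceResult(name_a, name_b, n_compared, n_concordant)


def find_duplicates(matrix_a: CallMatrix, matrix_b: CallMatrix,
                    snp_subset: Sequence[str] | None = None,
                    threshold: float = 0.97,
                    min_compared: int = MIN_COMPARED_DEFAULT,
                    near_miss_margin: float = 0.02) -> DuplicateReport:
    """All cross-platform pairs sharing strictly more than ``threshold`` of
    their joint calls, merged into clone groups by transitive closure.

    Pairs in ``[threshold - near_miss_margin, threshold]`` are reported as
    near misses.  The threshold is a strict inequality.
    """
    sub_a = matrix_a.subset_snps(snp_subset) if snp_subset else matrix_a
    sub_b = matrix_b.subset_snps(snp_subset) if snp_subset else matrix_b
    if sub_a.snp_ids != sub_b.snp_ids:
        common = [s for s in sub_a.snp_ids if s in set(sub_b.snp_ids)]
        sub_a, sub_b = sub_a.subset_snps(common), sub_b.subset_snps(common)

    va = _codes.visible(sub_a.calls)  # snps x inds_a
    vb = _codes.visible(sub_b.calls)
    pairs: list[ConcordanceResult] = []
    near: list[ConcordanceResult] = []
    # column-block comparison keeps memory bounded
    for j, ind_b in enumerate(sub_b.individual_ids):
        col = vb[:, j:j + 1]
        both = (va != _codes.MISSING) & (col != _codes.MISSING)
        n_cmp = both.sum(axis=0)
        n_conc = ((va == col) & both).sum(axis=0)
        for i, ind_a in enumerate(sub_a.individual_ids):
            if n_cmp[i] < min_compared:
                continue
            res = ConcordanceResult(ind_a, ind_b, int(n_cmp[i]),
                                    int(n_conc[i]))
            if res.fraction > threshold:
                pairs.append(res)
            elif res.fraction >= threshold - near_miss_margin:
                near.append(res)

    clone_groups = _transitive_closure(
        (p.individual_a, p.individual_b) for p in pairs)
    return DuplicateReport(pairs=pairs, clone_groups=clone_groups,
                           near_misses=near)


def _transitive_closure(edges: Iterable[tuple[str, str]]) -> list[set[str]]:
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        parent.setdefault(a, a)
        parent.setdefault(b, b)
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups: dict[str, set[str]] = {}
    for node in parent:
        groups.setdefault(find(node), set()).add(node)
    return [g for g in groups.values() if len(g) >= 2]


def repeatability(matrix: CallMatrix, clone_groups: Iterable[Iterable[str]],
                  snp_subset: Sequence[str] | None = None,
                  min_compared: int = 1) -> RepeatabilityReport:
    """Percent discordant calls across replicate pairs, averaged first
    within accession (one value per clone group), then across accessions."""
    sub = matrix.subset_snps(snp_subset) if snp_subset else matrix
    per_accession: dict[str, float] = {}
    n_pairs = 0
    for grp in clone_groups:
        members = [m for m in grp if m in sub._ind_index]
        if len(members) < 2:
            continue
        pair_pcts = []
        for a, b in combinations(sorted(members), 2):
            res = pairwise_concordance(sub.column(a), sub.column(b), a, b)
            if res.n_compared >= min_compared:
                pair_pcts.append(100.0 * (1.0 - res.fraction))
                n_pairs += 1
        if pair_pcts:
            per_accession[min(members)] = float(np.mean(pair_pcts))
    grand = float(np.mean(list(per_accession.values()))) \
        if per_accession else float("nan")
    return RepeatabilityReport(per_accession=per_accession,
                               grand_mean_pct=grand, n_pairs=n_pairs)


def per_snp_discordance(pairs: Sequence[tuple[str, str]],
                        matrix_a: CallMatrix, matrix_b: CallMatrix,
                        null_exclude: dict[str, set[str]] | None = None
                        ) -> dict[str, dict[str, int]]:
    """Per-SNP counts of duplicate pairs with discordant calls.

    ``null_exclude`` maps snp_id -> individuals whose confirmed null alleles
    must not be tallied as discordances.  Returns per SNP a dict with
    ``n_discordant``, ``n_informative`` and the discordant pair indices.
    """
    null_exclude = null_exclude or {}
    common = [s for s in matrix_a.snp_ids if s in set(matrix_b.snp_ids)]
    sub_a, sub_b = matrix_a.subset_snps(common), matrix_b.subset_snps(common)
    va, vb = _codes.visible(sub_a.calls), _codes.visible(sub_b.calls)
    n_disc = np.zeros(len(common), dtype=int)
    n_info = np.zeros(len(common), dtype=int)
    disc_pairs: dict[str, list[int]] = {s: [] for s in common}
    for k, (ind_a, ind_b) in enumerate(pairs):
        ca = va[:, sub_a.ind_pos(ind_a)]
        cb = vb[:, sub_b.ind_pos(ind_b)]
        both = (ca != _codes.MISSING) & (cb != _codes.MISSING)
        disc = both & (ca != cb)
        for row in np.flatnonzero(disc):
            snp = common[row]
            excl = null_exclude.get(snp)
            if excl and (ind_a in excl or ind_b in excl):
                disc[row] = False
        n_info += both
        n_disc += disc
        for row in np.flatnonzero(disc):
            disc_pairs[common[row]].append(k)
    return {
        snp: {"n_discordant": int(n_disc[i]),
              "n_informative": int(n_info[i]),
              "discordant_pairs": disc_pairs[snp]}
        for i, snp in enumerate(common)
    }
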
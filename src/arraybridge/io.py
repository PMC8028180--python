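"""Readers and writers for every external format the pipeline touches.

All physical coordinates are 1-based inclusive (BLAST/VCF convention).
Readers validate strictly and raise :class:`FormatError` rather than coerce;
``write -> read`` is the identity on every supported format.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import _codes
from ._codes import MISSING, CODE_TO_STR


class FormatError(ValueError):
    """Malformed external input, with file/line context in the message."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class CallMatrix:
    """SNP x individual biallelic genotype calls.

    ``calls`` is int8 with codes from :mod:`arraybridge._codes`; rows follow
    ``snp_ids``, columns follow ``individual_ids``.
    """

    snp_ids: list[str]
    individual_ids: list[str]
    calls: np.ndarray
    platform_tag: str = "merged"

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.snp_ids), len(self.individual_ids)):
            raise ValueError("call array shape does not match id lists")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("duplicated SNP ids")
        if len(set(self.individual_ids)) != len(self.individual_ids):
            raise ValueError("duplicated individual ids")
        bad = ~np.isin(self.calls, _codes.ALL_CODES)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call code {self.calls[i, j]} at "
                f"SNP {self.snp_ids[i]!r}, individual {self.individual_ids[j]!r}"
            )
        self._snp_index = {s: i for i, s in enumerate(self.snp_ids)}
        self._ind_index = {s: i for i, s in enumerate(self.individual_ids)}

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    def snp_row(self, snp_id: str) -> np.ndarray:
        return self.calls[self._snp_index[snp_id]]

    def column(self, individual_id: str) -> np.ndarray:
        return self.calls[:, self._ind_index[individual_id]]

    def snp_pos(self, snp_id: str) -> int:
        return self._snp_index[snp_id]

    def ind_pos(self, individual_id: str) -> int:
        return self._ind_index[individual_id]

    def visible(self) -> np.ndarray:
        return _codes.visible(self.calls)

    def copy(self) -> "CallMatrix":
        return CallMatrix(list(self.snp_ids), list(self.individual_ids),
                          self.calls.copy(), self.platform_tag)

    def subset_snps(self, snp_subset: Sequence[str]) -> "CallMatrix":
        idx = [self._snp_index[s] for s in snp_subset]
        return CallMatrix(list(snp_subset), list(self.individual_ids),
                          self.calls[idx], self.platform_tag)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.calls, index=self.snp_ids,
                            columns=self.individual_ids)


@dataclass
class IntensityTable:
    """Per (SNP, individual) normalized intensity: Theta in [0,1], R >= 0."""

    frame: pd.DataFrame  # columns: snp_id, individual_id, theta, r

    def __post_init__(self) -> None:
        required = ["snp_id", "individual_id", "theta", "r"]
        if list(self.frame.columns[:4]) != required:
            raise ValueError(f"intensity table needs columns {required}")
        t = self.frame["theta"].to_numpy(float)
        r = self.frame["r"].to_numpy(float)
        if ((t < 0) | (t > 1)).any():
            raise ValueError("theta outside [0, 1]")
        if (r < 0).any():
            raise ValueError("negative R")
        if self.frame.duplicated(["snp_id", "individual_id"]).any():
            raise ValueError("duplicated (snp, individual) intensity record")

    def for_snp(self, snp_id: str) -> pd.DataFrame:
        return self.frame[self.frame["snp_id"] == snp_id]

    def pivot_theta(self) -> pd.DataFrame:
        return self.frame.pivot(index="snp_id", columns="individual_id",
                                values="theta")

    def pivot_r(self) -> pd.DataFrame:
        return self.frame.pivot(index="snp_id", columns="individual_id",
                                values="r")


@dataclass
class Pedigree:
    """Parent map over individuals; ``None`` parent means unknown.

    ``clone_groups`` are sets of accession ids that represent one genotype
    (grafted clones / replicate extractions), to be collapsed downstream.
    """

    parents: dict[str, tuple[str | None, str | None]]
    clone_groups: list[set[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = set(self.parents)
        for ind, (m, f) in self.parents.items():
            for p in (m, f):
                if p is not None and p not in known:
                    raise ValueError(f"parent {p!r} of {ind!r} not in pedigree")
        self._check_acyclic()
        seen: set[str] = set()
        for grp in self.clone_groups:
            if grp & seen:
                raise ValueError("clone groups are not disjoint")
            seen |= grp

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(node: str) -> None:
            state[node] = 1
            for p in self.parents.get(node, (None, None)):
                if p is None:
                    continue
                s = state.get(p)
                if s == 1:
                    raise ValueError(f"pedigree cycle involving {node!r}")
                if s is None:
                    visit(p)
            state[node] = 2

        for n in self.parents:
            if state.get(n) is None:
                visit(n)

    def duos(self) -> list[tuple[str, str]]:
        """All (parent, offspring) links with a known parent."""
        out = []
        for ind, (m, f) in self.parents.items():
            for p in (m, f):
                if p is not None:
                    out.append((p, ind))
        return out

    def trios(self) -> list[tuple[str, str, str]]:
        """All (mother, father, offspring) with both parents known."""
        return [(m, f, ind) for ind, (m, f) in self.parents.items()
                if m is not None and f is not None]

    def individuals(self) -> list[str]:
        return list(self.parents)


@dataclass
class GeneticMap:
    """Per-SNP linkage-group label, cM position and optional physical bp."""

    frame: pd.DataFrame  # columns: snp_id, lg, cM, bp (bp may be NaN)

    def __post_init__(self) -> None:
        required = ["snp_id", "lg", "cM", "bp"]
        if list(self.frame.columns[:4]) != required:
            raise ValueError(f"genetic map needs columns {required}")
        if self.frame["snp_id"].duplicated().any():
            raise ValueError("duplicated SNP id in map")
        if (self.frame["cM"].to_numpy(float) < 0).any():
            raise ValueError("negative cM position")
        for lg, sub in self.frame.groupby("lg", sort=False):
            cm = sub["cM"].to_numpy(float)
            if (np.diff(cm) < 0).any():
                raise ValueError(f"cM not non-decreasing within LG {lg!r}")

    def per_lg(self) -> Iterable[tuple[str, pd.DataFrame]]:
        return self.frame.groupby("lg", sort=False)

    def snp_ids(self) -> list[str]:
        return self.frame["snp_id"].tolist()


@dataclass(frozen=True)
class BlastHit:
    """One row of 12-column tabular alignment output (outfmt 6)."""

    query: str
    subject: str
    pct_identity: float
    length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    @property
    def strand(self) -> str:
        return "+" if self.s_start <= self.s_end else "-"

    @property
    def s_lo(self) -> int:
        return min(self.s_start, self.s_end)

    @property
    def s_hi(self) -> int:
        return max(self.s_start, self.s_end)


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic (post-split) variant over a probe interval."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotypes: tuple[int, ...]  # per-sample alt-allele dosage; -1 = missing
    samples: tuple[str, ...]

    @property
    def n_carriers(self) -> int:
        return int(sum(1 for g in self.genotypes if g > 0))

    @property
    def carrier_fraction(self) -> float:
        called = [g for g in self.genotypes if g >= 0]
        return self.n_carriers / len(called) if called else 0.0

    @property
    def missing_fraction(self) -> float:
        if not self.genotypes:
            return 0.0
        return sum(1 for g in self.genotypes if g < 0) / len(self.genotypes)


# ---------------------------------------------------------------------------
# call matrices
# ---------------------------------------------------------------------------

def read_call_matrix(path: str | Path, platform_tag: str = "merged",
                     dialect: Mapping[str, int] | None = None,
                     sep: str = "\t") -> CallMatrix:
    """Read a SNP x individual call matrix (header row of individual ids).

    ``dialect`` maps call tokens to codes; unknown tokens raise, naming the
    offending row and column.
    """
    path = Path(path)
    tokens = dict(dialect) if dialect is not None else _codes.token_map()
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split(sep)
        if len(header) < 2:
            raise FormatError(f"{path}: header must list individual ids")
        individuals = header[1:]
        snp_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split(sep)
            if len(parts) != len(header):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(header)} columns, "
                    f"got {len(parts)}")
            snp_ids.append(parts[0])
            row = []
            for col, tok in zip(individuals, parts[1:]):
                if tok not in tokens:
                    raise FormatError(
                        f"{path}:{lineno}: unknown call token {tok!r} "
                        f"(SNP {parts[0]!r}, individual {col!r})")
                row.append(tokens[tok])
            rows.append(row)
    calls = (np.array(rows, dtype=np.int8) if rows
             else np.empty((0, len(individuals)), dtype=np.int8))
    try:
        return CallMatrix(snp_ids, individuals, calls, platform_tag)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_call_matrix(matrix: CallMatrix, path: str | Path,
                      sep: str = "\t") -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write(sep.join(["snp_id", *matrix.individual_ids]) + "\n")
        for i, snp in enumerate(matrix.snp_ids):
            toks = [CODE_TO_STR[int(c)] for c in matrix.calls[i]]
            fh.write(sep.join([snp, *toks]) + "\n")


# ---------------------------------------------------------------------------
# intensities
# ---------------------------------------------------------------------------

def read_intensity_table(path: str | Path) -> IntensityTable:
    try:
        frame = pd.read_csv(path, sep="\t",
                            dtype={"snp_id": str, "individual_id": str})
    except Exception as exc:  # pandas raises several parse error types
        raise FormatError(f"{path}: {exc}") from exc
    try:
        return IntensityTable(frame)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_intensity_table(table: IntensityTable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def read_pedigree(path: str | Path,
                  clone_groups_path: str | Path | None = None) -> Pedigree:
    """Read ``id,mother,father`` CSV (empty field = unknown parent).

    ``clone_groups_path`` optionally lists one clone group per line,
    members tab-separated.
    """
    path = Path(path)
    parents: dict[str, tuple[str | None, str | None]] = {}
    with path.open() as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip().lower() for h in header[:3]] != \
                ["id", "mother", "father"]:
            raise FormatError(f"{path}: expected header 'id,mother,father'")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) < 3:
                raise FormatError(f"{path}:{lineno}: expected 3 fields")
            ind, m, f = (x.strip() for x in row[:3])
            if ind in parents:
                raise FormatError(f"{path}:{lineno}: duplicated id {ind!r}")
            parents[ind] = (m or None, f or None)
    groups: list[set[str]] = []
    if clone_groups_path is not None:
        with Path(clone_groups_path).open() as fh:
            for line in fh:
                members = {t for t in line.strip().split("\t") if t}
                if len(members) >= 2:
                    groups.append(members)
    try:
        return Pedigree(parents, groups)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_pedigree(ped: Pedigree, path: str | Path,
                   clone_groups_path: str | Path | None = None) -> None:
    with Path(path).open("w") as fh:
        fh.write("id,mother,father\n")
        for ind, (m, f) in ped.parents.items():
            fh.write(f"{ind},{m or ''},{f or ''}\n")
    if clone_groups_path is not None:
        with Path(clone_groups_path).open("w") as fh:
            for grp in ped.clone_groups:
                fh.write("\t".join(sorted(grp)) + "\n")


# ---------------------------------------------------------------------------
# genetic map
# ---------------------------------------------------------------------------

def read_genetic_map(path: str | Path) -> GeneticMap:
    try:
        frame = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "lg": str})
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    try:
        return GeneticMap(frame)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    frame = gmap.frame.copy()
    frame["bp"] = frame["bp"].astype("Int64")
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BLAST tabular output
# ---------------------------------------------------------------------------

def read_blast_tab(path: str | Path) -> list[BlastHit]:
    """Parse standard 12-column tabular alignment output."""
    path = Path(path)
    hits: list[BlastHit] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            try:
                hit = BlastHit(
                    query=parts[0], subject=parts[1],
                    pct_identity=float(parts[2]), length=int(parts[3]),
                    mismatches=int(parts[4]), gap_opens=int(parts[5]),
                    q_start=int(parts[6]), q_end=int(parts[7]),
                    s_start=int(parts[8]), s_end=int(parts[9]),
                    e_value=float(parts[10]), bit_score=float(parts[11]))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            if hit.e_value < 0:
                raise FormatError(f"{path}:{lineno}: negative E-value")
            if min(hit.q_start, hit.q_end, hit.s_start, hit.s_end) < 1:
                raise FormatError(f"{path}:{lineno}: non-positive coordinate")
            hits.append(hit)
    return hits


def write_blast_tab(hits: Iterable[BlastHit], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for h in hits:
            fh.write("\t".join(str(x) for x in (
                h.query, h.subject, h.pct_identity, h.length, h.mismatches,
                h.gap_opens, h.q_start, h.q_end, h.s_start, h.s_end,
                f"{h.e_value:g}", h.bit_score)) + "\n")


# ---------------------------------------------------------------------------
# VCF over probe intervals
# ---------------------------------------------------------------------------

def read_vcf_probe_variants(
        path: str | Path,
        probe_intervals: Iterable[tuple[str, int, int]]) -> list[VariantRecord]:
    """Return variants overlapping any (chrom, start, end) 1-based inclusive
    interval; multi-allelic records are split into one record per ALT.
    """
    import pysam

    path = Path(path)
    intervals = list(probe_intervals)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(str(chrom), []).append((int(start), int(end)))
    out: list[VariantRecord] = []
    try:
        vcf = pysam.VariantFile(str(path))
    except Exception as exc:
        raise FormatError(f"{path}: {exc}") from exc
    samples = tuple(vcf.header.samples)
    try:
        for rec in vcf:
            spans = by_chrom.get(rec.chrom)
            if spans is None:
                continue
            if not any(lo <= rec.pos <= hi for lo, hi in spans):
                continue
            alts = rec.alts or ()
            for alt_idx, alt in enumerate(alts, start=1):
                doses = []
                for s in samples:
                    gt = rec.samples[s].get("GT", (None,))
                    if gt is None or all(a is None for a in gt):
                        doses.append(-1)
                    else:
                        doses.append(sum(1 for a in gt if a == alt_idx))
                out.append(VariantRecord(rec.chrom, rec.pos, rec.ref or "N",
                                         str(alt), tuple(doses), samples))
    except Exception as exc:
        raise FormatError(f"{path}: malformed VCF record: {exc}") from exc
    finally:
        vcf.close()
    return out
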
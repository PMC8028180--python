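"""Probe-level failure-cause quantification.

Counts off-target alignment hits per E-value stringency, derives probe
intervals and 3'-distances, extracts secondary polymorphisms from variant
panels, and builds the stratified inclusion/compatibility rate tables.

Distance convention: ``d = 1`` is the probe base adjacent to the target SNP
(the 3' terminus); ``d = probe_len`` is the 5' terminus.  An off-by-one here
silently corrupts the distance-stratified analysis, hence it is fixed in one
place (:func:`probe_interval`).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import BlastHit, VariantRecord

DEFAULT_THRESHOLDS = (1.0e-12, 1.0e-14, 1.0e-16)


@dataclass
class ProbeInterval:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    strand: str  # strand the probe anneals to, relative to the reference
    probe_len: int
    truncated: bool = False

    def distance_from_3prime(self, pos: int) -> int | None:
        """d for a reference position inside the interval; None outside."""
        if not (self.start <= pos <= self.end):
            return None
        if self.strand == "+":
            return self.end - pos + 1
        return pos - self.start + 1


@dataclass
class SecondaryPolymorphism:
    chrom: str
    pos: int
    distance_from_3prime: int
    carrier_fraction: float
    missing_fraction: float


@dataclass
class ProbeReport:
    snp_id: str
    probe_len: int
    target_interval: ProbeInterval | None
    hit_counts: dict[float, int] = field(default_factory=dict)
    best_e_value: float = float("inf")
    perfect_match: bool = False
    secondary_polymorphisms: list[SecondaryPolymorphism] = field(
        default_factory=list)

    @property
    def n_secondary(self) -> int:
        return len(self.secondary_polymorphisms)


def count_hits(hits: Sequence[BlastHit], probe_len: int,
               thresholds: Iterable[float] = DEFAULT_THRESHOLDS
               ) -> tuple[dict[float, int], float, bool]:
    """Per threshold t, the number of hits with E < t; plus the best
    E-value and the perfect-match flag.

    Perfect match requires full query coverage, 100% identity and zero
    gaps -- never the E-value, which depends on database size.
    """
    counts = {float(t): sum(1 for h in hits if h.e_value < t)
              for t in thresholds}
    best = min((h.e_value for h in hits), default=float("inf"))
    perfect = any(
        h.pct_identity == 100.0 and h.gap_opens == 0
        and abs(h.q_end - h.q_start) + 1 == probe_len and h.length == probe_len
        for h in hits)
    return counts, best, perfect


def probe_interval(chrom: str, target_pos: int, strand: str,
                   probe_len: int) -> ProbeInterval:
    """Interval of ``probe_len`` reference bases ending adjacent to the
    target SNP on the probe's strand.

    Plus strand: probe covers [pos - probe_len, pos - 1], with d = 1 at
    ``pos - 1``.  Minus strand: probe covers [pos + 1, pos + probe_len] with
    d = 1 at ``pos + 1``.  Intervals running off the chromosome start are
    truncated and flagged.
    """
    if strand == "+":
        start, end = target_pos - probe_len, target_pos - 1
    elif strand == "-":
        start, end = target_pos + 1, target_pos + probe_len
    else:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    truncated = start < 1
    return ProbeInterval(chrom, max(start, 1), end, strand, probe_len,
                         truncated=truncated)


def extract_secondary_polymorphisms(
        variants: Iterable[VariantRecord], interval: ProbeInterval,
        min_carrier_fraction: float = 0.10,
        max_missing_fraction: float = 0.25) -> list[SecondaryPolymorphism]:
    """Filter panel variants over the probe interval to those carried by at
    least 10% of individuals with no more than 25% missing data, attaching
    the 3'-distance.  Indels count once at their 3'-most overlapping
    position."""
    out: list[SecondaryPolymorphism] = []
    for var in variants:
        if var.chrom != interval.chrom:
            continue
        span = max(len(var.ref), 1)
        positions = [p for p in range(var.pos, var.pos + span)
                     if interval.start <= p <= interval.end]
        if not positions:
            continue
        if var.carrier_fraction < min_carrier_fraction:
            continue
        if var.missing_fraction > max_missing_fraction:
            continue
        ds = [interval.distance_from_3prime(p) for p in positions]
        d = min(x for x in ds if x is not None)
        out.append(SecondaryPolymorphism(
            var.chrom, var.pos, int(d), var.carrier_fraction,
            var.missing_fraction))
    return out


def build_probe_report(snp_id: str, hits: Sequence[BlastHit],
                       interval: ProbeInterval | None,
                       variants: Iterable[VariantRecord] = (),
                       probe_len: int = 50,
                       thresholds: Iterable[float] = DEFAULT_THRESHOLDS
                       ) -> ProbeReport:
    counts, best, perfect = count_hits(hits, probe_len, thresholds)
    polys = (extract_secondary_polymorphisms(variants, interval)
             if interval is not None else [])
    return ProbeReport(snp_id=snp_id, probe_len=probe_len,
                       target_interval=interval, hit_counts=counts,
                       best_e_value=best, perfect_match=perfect,
                       secondary_polymorphisms=polys)


# ---------------------------------------------------------------------------
# stratified rate tables
# ---------------------------------------------------------------------------

def _hit_bin(n: int, cap: int = 10) -> str:
    return str(n) if n <= cap else f">{cap}"


def stratified_rates(verdicts: Mapping[str, Mapping[str, object]],
                     reports: Mapping[str, ProbeReport],
                     stratifier: str = "hit_count",
                     threshold: float = 1.0e-12,
                     cluster_space: Mapping[str, float] | None = None,
                     min_stratum: int = 10,
                     hit_bin_cap: int = 10) -> pd.DataFrame:
    """Inclusion and compatibility rates grouped by hit count or by the
    3'-distance of a single secondary polymorphism.

    ``verdicts[snp]`` needs keys ``included`` (bool), ``compatible`` (bool)
    and ``axiom_class`` (str or None).  Compatibility is reported both with
    and without class C counted compatible.  For the distance stratifier,
    probes with more than one secondary polymorphism are excluded.  Strata
    with fewer than ``min_stratum`` SNPs lose their mean-cluster-space value.
    """
    rows = []
    for snp, rep in reports.items():
        v = verdicts.get(snp)
        if v is None:
            continue
        if stratifier == "hit_count":
            key = _hit_bin(rep.hit_counts.get(float(threshold), 0),
                           hit_bin_cap)
        elif stratifier == "polymorphism_distance":
            if rep.n_secondary != 1:
                continue
            key = rep.secondary_polymorphisms[0].distance_from_3prime
        elif stratifier == "polymorphism_count":
            key = rep.n_secondary
        else:
            raise ValueError(f"unknown stratifier {stratifier!r}")
        included = bool(v["included"])
        ax_class = v.get("axiom_class")
        compatible = bool(v.get("compatible", False))
        rows.append({
            "stratum": key,
            "included": included,
            "compatible_with_c": included and compatible,
            "compatible_without_c": included and compatible
            and ax_class != "C",
            "cluster_space": (cluster_space or {}).get(snp, np.nan),
        })
    if not rows:
        return pd.DataFrame(columns=["stratum", "n", "inclusion_rate",
                                     "compatibility_rate",
                                     "compatibility_rate_no_c",
                                     "mean_cluster_space"])
    frame = pd.DataFrame(rows)
    grouped = frame.groupby("stratum", sort=True)
    table = pd.DataFrame({
        "n": grouped.size(),
        "inclusion_rate": grouped["included"].mean(),
        "compatibility_rate": grouped["compatible_with_c"].mean(),
        "compatibility_rate_no_c": grouped["compatible_without_c"].mean(),
        "mean_cluster_space": grouped["cluster_space"].mean(),
    }).reset_index()
    small = table["n"] < min_stratum
    table.loc[small, "mean_cluster_space"] = np.nan
    return table
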
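"""CNV size filtering and cross-platform concordance by reciprocal overlap.

Copy-number variants are handled as 0-based half-open intervals
(BED convention).  Concordance between two callsets — typically
whole-genome-sequencing calls versus chromosomal-microarray (CMA)
calls on the same individuals — is assessed by greedy best
reciprocal-overlap (RO) matching within each sample, RO being the
standard ``min(overlap/len_a, overlap/len_b)`` metric.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CNVCall",
    "ConcordanceReport",
    "filter_cnvs",
    "reciprocal_overlap",
    "match_callsets",
]

DEFAULT_MIN_SIZE = 10_000  # >=10 kb, inclusive
DEFAULT_MIN_RO = 0.5


@dataclass(frozen=True)
class CNVCall:
    """One CNV call: 0-based half-open interval plus dosage and tier."""

    sample_id: str
    chrom: str
    start: int
    end: int
    dosage: str  # "DEL" | "DUP"
    tier: str = "none"  # "pathogenic" | "likely_pathogenic" | "VUS" | "none"
    source: str = "WGS"  # "WGS" | "CMA"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.dosage not in {"DEL", "DUP"}:
            raise ValueError(f"dosage must be DEL or DUP, got {self.dosage!r}")

    @property
    def size(self) -> int:
        return self.end - self.start

    @classmethod
    def from_vcf_coords(cls, sample_id, chrom, pos_1based, end_1based, **kw):
        """Build from 1-based inclusive (VCF-style) coordinates."""
        return cls(sample_id, chrom, pos_1based - 1, end_1based, **kw)


def filter_cnvs(
    calls: Iterable[CNVCall], min_size: int = DEFAULT_MIN_SIZE
) -> list[CNVCall]:
    """Retain calls of size >= ``min_size`` bp (bound inclusive)."""
    return [c for c in calls if c.size >= min_size]


def reciprocal_overlap(a: CNVCall, b: CNVCall) -> float:
    """Reciprocal overlap of two calls; 0 across chromosomes or dosage types."""
    if a.chrom != b.chrom or a.dosage != b.dosage:
        return 0.0
    overlap = min(a.end, b.end) - max(a.start, b.start)
    if overlap <= 0:
        return 0.0
    return min(overlap / a.size, overlap / b.size)


@dataclass(frozen=True)
class ConcordanceReport:
    """Outcome of matching a query (WGS) callset against a truth (CMA) set."""

    matches: tuple[tuple[CNVCall, CNVCall, float], ...]  # (wgs, cma, ro)
    unmatched_wgs: tuple[CNVCall, ...]
    unmatched_cma: tuple[CNVCall, ...]

    @property
    def n_cma(self) -> int:
        return len(self.matches) + len(self.unmatched_cma)

    @property
    def recovery_fraction(self) -> float:
        """Fraction of truth (CMA) calls recovered by the query callset."""
        return len(self.matches) / self.n_cma if self.n_cma else 0.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for wgs, cma, ro in self.matches:
            rows.append(
                {
                    "sample_id": cma.sample_id,
                    "chrom": cma.chrom,
                    "cma_start": cma.start,
                    "cma_end": cma.end,
                    "wgs_start": wgs.start,
                    "wgs_end": wgs.end,
                    "dosage": cma.dosage,
                    "ro": ro,
                    "status": "matched",
                }
            )
        for c in self.unmatched_cma:
            rows.append(
                {
                    "sample_id": c.sample_id,
                    "chrom": c.chrom,
                    "cma_start": c.start,
                    "cma_end": c.end,
                    "wgs_start": pd.NA,
                    "wgs_end": pd.NA,
                    "dosage": c.dosage,
                    "ro": 0.0,
                    "status": "missed",
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "sample_id",
                "chrom",
                "cma_start",
                "cma_end",
                "wgs_start",
                "wgs_end",
                "dosage",
                "ro",
                "status",
            ],
        )


def match_callsets(
    wgs_calls: Sequence[CNVCall],
    cma_calls: Sequence[CNVCall],
    min_ro: float = DEFAULT_MIN_RO,
) -> ConcordanceReport:
    """Greedy best-RO matching of WGS calls to CMA calls within each sample.

    Candidate pairs (same sample) are ranked by descending RO; each call
    participates in at most one match; pairs below ``min_ro`` never match.
    Deterministic: ties broken by input order.
    """
    pairs: list[tuple[float, int, int]] = []
    for i, w in enumerate(wgs_calls):
        for j, c in enumerate(cma_calls):
            if w.sample_id != c.sample_id:
                continue
            ro = reciprocal_overlap(w, c)
            if ro >= min_ro:
                pairs.append((ro, i, j))
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))

    used_w: set[int] = set()
    used_c: set[int] = set()
    matches = []
    for ro, i, j in pairs:
        if i in used_w or j in used_c:
            continue
        used_w.add(i)
        used_c.add(j)
        matches.append((wgs_calls[i], cma_calls[j], ro))

    return ConcordanceReport(
        matches=tuple(matches),
        unmatched_wgs=tuple(
            w for i, w in enumerate(wgs_calls) if i not in used_w
        ),
        unmatched_cma=tuple(
            c for j, c in enumerate(cma_calls) if j not in used_c
        ),
    )
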
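"""Tandem-repeat-expansion (TRE) screening against a locus catalog.

Each catalogued short-tandem-repeat locus carries a normal repeat-count
range and a disease-causing (pathogenic) threshold; a genotype's larger
allele decides the call:

* ``expanded``      — larger allele meets the locus threshold (the
  inequality, >= or >, is per-locus catalog data);
* ``normal``        — larger allele within the normal range;
* ``intermediate``  — in between.

Short-read genotypers systematically underestimate very large
expansions, so calls within a configurable margin below the threshold
are additionally flagged ``near_threshold`` (flag only — a near call is
never promoted to expanded).  Lower-bound genotype estimates such as
">200" are stored as value 201 with a lower-bound marker and classified
at the bound's value.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "TRELocusSpec",
    "TREGenotype",
    "TRECall",
    "classify_tre",
    "screen_cohort",
    "load_catalog",
    "default_catalog",
    "parse_repeat_size",
]

DEFAULT_NEAR_MARGIN = 0.2


@dataclass(frozen=True)
class TRELocusSpec:
    locus_id: str
    gene_symbol: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    motif: str
    normal_min: int
    normal_max: int
    pathogenic_threshold: int
    threshold_inclusive: bool  # True: expanded at >= threshold; False: > threshold

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError(f"{self.locus_id}: empty repeat motif")
        if not (self.normal_min <= self.normal_max < self.pathogenic_threshold):
            raise ValueError(
                f"{self.locus_id}: require normal_min <= normal_max < "
                f"pathogenic_threshold, got {self.normal_min}/"
                f"{self.normal_max}/{self.pathogenic_threshold}"
            )

    def exceeds_threshold(self, repeats: int) -> bool:
        if self.threshold_inclusive:
            return repeats >= self.pathogenic_threshold
        return repeats > self.pathogenic_threshold


@dataclass(frozen=True)
class TREGenotype:
    """Repeat counts of the two alleles at one locus for one sample.

    ``allele2_lower_bound`` marks a ">N"-style estimate: the true size is
    at least ``allele2_repeats``.
    """

    sample_id: str
    locus_id: str
    allele1_repeats: int
    allele2_repeats: int
    allele2_lower_bound: bool = False

    def __post_init__(self) -> None:
        if self.allele1_repeats < 0 or self.allele2_repeats < 0:
            raise ValueError("repeat counts must be >= 0")
        if self.allele1_repeats > self.allele2_repeats:
            raise ValueError(
                "alleles must be ordered: allele1_repeats <= allele2_repeats"
            )

    @property
    def larger_allele(self) -> int:
        return self.allele2_repeats


@dataclass(frozen=True)
class TRECall:
    sample_id: str
    locus_id: str
    category: str  # "normal" | "intermediate" | "expanded"
    near_threshold_flag: bool
    larger_allele: int


def parse_repeat_size(text: str | int) -> tuple[int, bool]:
    """Parse a repeat-size estimate; ">200" -> (201, lower_bound=True)."""
    if isinstance(text, int):
        return text, False
    s = str(text).strip()
    if s.startswith(">"):
        return int(s[1:]) + 1, True
    return int(float(s)), False


def classify_tre(
    genotype: TREGenotype,
    locus: TRELocusSpec,
    near_margin: float = DEFAULT_NEAR_MARGIN,
) -> TRECall:
    """Classify one genotype by its larger allele against the locus rule."""
    if genotype.locus_id != locus.locus_id:
        raise ValueError(
            f"genotype locus {genotype.locus_id!r} does not match "
            f"catalog locus {locus.locus_id!r}"
        )
    larger = genotype.larger_allele
    if locus.exceeds_threshold(larger):
        category = "expanded"
    elif larger <= locus.normal_max:
        category = "normal"
    else:
        category = "intermediate"
    near = (
        category != "expanded"
        and (1.0 - near_margin) * locus.pathogenic_threshold <= larger
    )
    return TRECall(
        sample_id=genotype.sample_id,
        locus_id=genotype.locus_id,
        category=category,
        near_threshold_flag=near,
        larger_allele=larger,
    )


def screen_cohort(
    genotypes: Iterable[TREGenotype],
    catalog: Mapping[str, TRELocusSpec],
    near_margin: float = DEFAULT_NEAR_MARGIN,
) -> tuple[pd.DataFrame, dict]:
    """Classify every genotype; summarise expanded carriers.

    Returns ``(calls, summary)`` where ``calls`` has one row per
    (sample, locus) and ``summary`` counts expanded calls per locus and
    distinct expanded carriers overall.
    """
    calls = []
    for g in genotypes:
        if g.locus_id not in catalog:
            raise KeyError(f"genotype references unknown locus {g.locus_id!r}")
        calls.append(classify_tre(g, catalog[g.locus_id], near_margin))
    frame = pd.DataFrame(
        [
            {
                "sample_id": c.sample_id,
                "locus_id": c.locus_id,
                "category": c.category,
                "near_threshold_flag": c.near_threshold_flag,
                "larger_allele": c.larger_allele,
            }
            for c in calls
        ],
        columns=[
            "sample_id",
            "locus_id",
            "category",
            "near_threshold_flag",
            "larger_allele",
        ],
    )
    expanded = frame[frame["category"] == "expanded"]
    summary = {
        "n_expanded_calls": int(len(expanded)),
        "n_expanded_carriers": int(expanded["sample_id"].nunique()),
        "loci_with_expansions": sorted(expanded["locus_id"].unique().tolist()),
        "expanded_per_locus": expanded.groupby("locus_id")["sample_id"]
        .nunique()
        .to_dict(),
        "n_near_threshold": int(frame["near_threshold_flag"].sum()),
    }
    return frame, summary


def load_catalog(path) -> dict[str, TRELocusSpec]:
    """Load a locus catalog TSV into a dict keyed by locus id.

    Expected columns: locus_id, gene_symbol, chrom, start, end, motif,
    normal_min, normal_max, pathogenic_threshold, threshold_inclusive.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    catalog: dict[str, TRELocusSpec] = {}
    for row in df.itertuples(index=False):
        spec = TRELocusSpec(
            locus_id=str(row.locus_id),
            gene_symbol=str(row.gene_symbol),
            chrom=str(row.chrom),
            start=int(row.start),
            end=int(row.end),
            motif=str(row.motif),
            normal_min=int(row.normal_min),
            normal_max=int(row.normal_max),
            pathogenic_threshold=int(row.pathogenic_threshold),
            threshold_inclusive=bool(row.threshold_inclusive),
        )
        if spec.locus_id in catalog:
            raise ValueError(f"duplicate locus id {spec.locus_id!r}")
        catalog[spec.locus_id] = spec
    return catalog


def default_catalog() -> dict[str, TRELocusSpec]:
    """The bundled 45-locus disease-associated repeat catalog.

    DMPK and ATXN8OS entries follow the published clinical conventions
    exactly (normal 5–35 / pathogenic >=51 CTG, and normal 15–44 /
    pathogenic >110 CTG, respectively); the remaining rows are fixture
    data following published locus conventions and are user-replaceable
    via :func:`load_catalog`.
    """
    ref = resources.files("rarescreen").joinpath("data/tre_catalog.tsv")
    with resources.as_file(ref) as path:
        return load_catalog(path)
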
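"""Per-variant predicates used by the clinical adjudication rules.

Four predicates are housed here, each a direct encoding of a filtering
rule commonly applied when screening rare coding variation in
neurodevelopmental-disorder (NDD) cohorts:

* rarity — the maximum allele frequency across reference population
  panels (ExAC, 1000 Genomes, gnomAD, gnomAD-SV) must be at most 1%;
  a variant absent from every panel is *ultra-rare*;
* loss of function — stop-gains, frameshift indels and splice-site
  variants are presumed LoF;
* missense deleteriousness consensus — a missense variant is deemed
  deleterious when at least 5 of 8 in-silico predictors flag it;
* constraint — the carrier gene must be LoF-intolerant, measured by the
  gnomAD LOEUF score (loss-of-function observed/expected upper bound
  fraction; lower = more constrained).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Optional

__all__ = [
    "LOF_CONSEQUENCES",
    "CONSEQUENCES",
    "VariantRecord",
    "FrequencyProfile",
    "InSilicoProfile",
    "GeneAnnotation",
    "ConsensusConfig",
    "RarityCall",
    "max_population_af",
    "is_lof",
    "missense_consensus",
    "is_constrained",
]

#: Consequence labels accepted on a VariantRecord.
CONSEQUENCES = frozenset(
    {"stopgain", "frameshift", "splice_site", "missense", "synonymous", "other"}
)

#: Consequences presumed to abolish gene product function.
LOF_CONSEQUENCES = frozenset({"stopgain", "frameshift", "splice_site"})

#: Default rarity bound: population-based maximum allele frequency <= 1%.
DEFAULT_AF_CUTOFF = 0.01

#: Default constraint bound on LOEUF (conventional constrained-gene cutoff).
DEFAULT_LOEUF_CUTOFF = 0.35


@dataclass(frozen=True)
class VariantRecord:
    """A single small variant (SNV or indel) carried by one individual."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str  # "SNV" | "indel"
    consequence: str
    gene_symbol: str
    transcript_id: str = ""
    zygosity: str = "het"  # "het" | "hom" | "hemi"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref!r})")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        is_indel = len(self.ref) != len(self.alt)
        if (self.variant_class == "indel") != is_indel:
            raise ValueError(
                f"variant_class {self.variant_class!r} inconsistent with "
                f"alleles {self.ref}>{self.alt}"
            )
        if self.zygosity not in {"het", "hom", "hemi"}:
            raise ValueError(f"unknown zygosity {self.zygosity!r}")


@dataclass(frozen=True)
class FrequencyProfile:
    """Population allele frequencies for one variant; ``None`` = not observed
    in / not reported by that panel."""

    af_exac: Optional[float] = None
    af_1kg: Optional[float] = None
    af_gnomad: Optional[float] = None
    af_gnomad_sv: Optional[float] = None

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{f.name}={v} outside [0, 1]")

    def present(self) -> dict[str, float]:
        return {
            f.name: getattr(self, f.name)
            for f in fields(self)
            if getattr(self, f.name) is not None
        }


@dataclass(frozen=True)
class InSilicoProfile:
    """Scores from the eight in-silico deleteriousness predictors.

    ``None`` marks a predictor that did not score the variant; absent
    scores never count toward the consensus but stay in the denominator.
    """

    cadd: Optional[float] = None
    sift: Optional[float] = None
    polyphen2_hvar: Optional[float] = None
    provean: Optional[float] = None
    mutation_assessor: Optional[float] = None
    mutation_taster: Optional[float] = None
    phylop_mam: Optional[float] = None
    phylop_vert: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("sift", "polyphen2_hvar"):
            v = getattr(self, name)
            if v is not None and not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene-level annotation used for tiering.

    loeuf
        gnomAD LoF observed/expected upper bound fraction; ``None`` when
        the gene has no constraint estimate.
    ndd_associated
        True when the gene sits on an established neurodevelopmental-
        disorder panel (ID / ASD / epilepsy / schizophrenia gene lists).
    """

    symbol: str
    loeuf: Optional[float] = None
    ndd_associated: bool = False
    pathway: str = "other"
    coding_length_kb: float = 1.0
    omim_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.loeuf is not None and self.loeuf < 0:
            raise ValueError(f"loeuf must be >= 0, got {self.loeuf}")
        if self.coding_length_kb <= 0:
            raise ValueError(
                f"coding_length_kb must be > 0, got {self.coding_length_kb}"
            )


@dataclass(frozen=True)
class ConsensusConfig:
    """Predictor thresholds and quorum for the missense consensus.

    Defaults encode: CADD >= 15, SIFT <= 0.05, PolyPhen2-HVAR >= 0.90,
    Provean < -2.5 (strictly), MutationAssessor >= 1.90,
    MutationTaster >= 0.5, PhyloP-mammalian >= 2.30,
    PhyloP-vertebrate >= 4.0; deleterious when >= 5 of 8 pass.
    """

    cadd_min: float = 15.0
    sift_max: float = 0.05
    polyphen2_hvar_min: float = 0.90
    provean_below: float = -2.5
    mutation_assessor_min: float = 1.90
    mutation_taster_min: float = 0.5
    phylop_mam_min: float = 2.30
    phylop_vert_min: float = 4.0
    quorum: int = 5


@dataclass(frozen=True)
class RarityCall:
    max_af: float
    rarity: str  # "ultra_rare" | "rare" | "common"

    @property
    def is_rare(self) -> bool:
        """True for both rare and ultra-rare variants."""
        return self.rarity != "common"


def max_population_af(
    freq: FrequencyProfile, af_cutoff: float = DEFAULT_AF_CUTOFF
) -> RarityCall:
    """Maximum allele frequency over the reference panels, with rarity class.

    Absent panels are ignored; a variant absent from every panel has
    max AF 0 and is *ultra-rare*.  ``rare`` means 0 < max AF <= cutoff,
    ``common`` anything above.
    """
    present = freq.present().values()
    max_af = max(present) if present else 0.0
    if max_af == 0.0:
        rarity = "ultra_rare"
    elif max_af <= af_cutoff:
        rarity = "rare"
    else:
        rarity = "common"
    return RarityCall(max_af=max_af, rarity=rarity)


def is_lof(variant: VariantRecord) -> bool:
    """True iff the consequence is stop-gain, frameshift or splice-site."""
    return variant.consequence in LOF_CONSEQUENCES


def _predictor_verdicts(
    profile: InSilicoProfile, cfg: ConsensusConfig
) -> dict[str, bool]:
    def ok(value: Optional[float], test) -> bool:
        return value is not None and not math.isnan(value) and test(value)

    return {
        "cadd": ok(profile.cadd, lambda v: v >= cfg.cadd_min),
        "sift": ok(profile.sift, lambda v: v <= cfg.sift_max),
        "polyphen2_hvar": ok(
            profile.polyphen2_hvar, lambda v: v >= cfg.polyphen2_hvar_min
        ),
        # Provean is the one strict inequality: deleterious strictly below -2.5
        "provean": ok(profile.provean, lambda v: v < cfg.provean_below),
        "mutation_assessor": ok(
            profile.mutation_assessor, lambda v: v >= cfg.mutation_assessor_min
        ),
        "mutation_taster": ok(
            profile.mutation_taster, lambda v: v >= cfg.mutation_taster_min
        ),
        "phylop_mam": ok(profile.phylop_mam, lambda v: v >= cfg.phylop_mam_min),
        "phylop_vert": ok(profile.phylop_vert, lambda v: v >= cfg.phylop_vert_min),
    }


def missense_consensus(
    profile: InSilicoProfile, config: ConsensusConfig | None = None
) -> tuple[bool, dict[str, bool]]:
    """5-of-8 in-silico deleteriousness consensus for missense variants.

    Returns ``(deleterious, verdicts)`` where ``verdicts`` maps each
    predictor to whether it passed.  An absent score never passes and the
    denominator stays 8: the quorum is absolute, not among present scores.
    """
    cfg = config or ConsensusConfig()
    verdicts = _predictor_verdicts(profile, cfg)
    return sum(verdicts.values()) >= cfg.quorum, verdicts


def is_constrained(
    gene: GeneAnnotation, loeuf_cutoff: float = DEFAULT_LOEUF_CUTOFF
) -> Optional[bool]:
    """LoF-intolerance predicate: LOEUF strictly below the cutoff.

    Returns ``None`` (an explicit "unknown", never a silent False) when
    the gene carries no LOEUF estimate.
    """
    if gene.loeuf is None or (
        isinstance(gene.loeuf, float) and math.isnan(gene.loeuf)
    ):
        return None
    return gene.loeuf < loeuf_cutoff
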
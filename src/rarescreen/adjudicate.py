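"""Clinical tiering of rare variants and per-individual findings accounting.

Combines the predicates in :mod:`rarescreen.filters` into a variant-level
tier, collects per-individual findings across variant classes (CNV,
SNV/indel, tandem-repeat expansion, candidate-gene LoF) into a ledger,
and computes cohort yields (distinct-carrier counts and proportions under
a scope filter, e.g. "individuals without a pathogenic CNV").

Tier rules
----------
clinically_relevant
    rare (max panel AF <= 0.01) AND (LoF, or missense passing the 5-of-8
    consensus) AND constrained gene (LOEUF < cutoff) AND gene on an
    established NDD panel.  Pathogenic and likely-pathogenic calls are
    collapsed into this single tier.
potential_implication (candidate-gene LoF)
    ultra-rare LoF in a constrained gene that is NOT on an NDD panel —
    the research-grade recurrence-candidate stratum.
uncertain
    the rules cannot be evaluated (no gene annotation, or missing LOEUF
    on an otherwise qualifying variant).
none
    everything else (synonymous, common, unconstrained, ...).

Yields count distinct individuals, never variants: one person carrying
two qualifying variants contributes one carrier.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional

import pandas as pd

from .filters import (
    ConsensusConfig,
    DEFAULT_AF_CUTOFF,
    DEFAULT_LOEUF_CUTOFF,
    FrequencyProfile,
    GeneAnnotation,
    InSilicoProfile,
    VariantRecord,
    is_constrained,
    is_lof,
    max_population_af,
    missense_consensus,
)

__all__ = [
    "TIER_CLINICALLY_RELEVANT",
    "TIER_POTENTIAL_IMPLICATION",
    "TIER_UNCERTAIN",
    "TIER_NONE",
    "FINDING_CLASSES",
    "AdjudicationConfig",
    "ClinicalRelevanceCall",
    "IndividualProfile",
    "Finding",
    "FindingsLedger",
    "YieldReport",
    "adjudicate_variant",
    "build_ledger",
    "cohort_yield",
]

TIER_CLINICALLY_RELEVANT = "clinically_relevant"
TIER_POTENTIAL_IMPLICATION = "potential_implication"
TIER_UNCERTAIN = "uncertain"
TIER_NONE = "none"

#: Finding classes are never merged in the ledger.
FINDING_CLASSES = ("CNV", "SNV_indel", "TRE", "candidate_gene_LoF")


@dataclass(frozen=True)
class AdjudicationConfig:
    af_cutoff: float = DEFAULT_AF_CUTOFF
    loeuf_cutoff: float = DEFAULT_LOEUF_CUTOFF
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)


@dataclass(frozen=True)
class ClinicalRelevanceCall:
    tier: str
    rationale: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.tier == TIER_CLINICALLY_RELEVANT:
            need = {"rarity", "constrained", "ndd_panel"}
            if not need <= set(self.rationale) or not (
                "lof" in self.rationale or "consensus_missense" in self.rationale
            ):
                raise ValueError(
                    "clinically_relevant requires rarity, an effect rule "
                    f"and gene evidence; got {self.rationale}"
                )


@dataclass(frozen=True)
class IndividualProfile:
    """Phenotype covariates for one cohort member."""

    sample_id: str
    sex: str = "M"  # "F" | "M"
    aao_class: str = "adult"  # "early" (<18y) | "adult" | "unknown"
    fhx: str = "unknown"  # family history: "yes" | "no" | "unknown"
    id_status: str = "none"  # "none" | "broad_id"
    syndromic: bool = False
    cnv_group: str = "no_rare_cnv"  # "pathogenic_cnv"|"rare_cnv_vus"|"no_rare_cnv"

    def __post_init__(self) -> None:
        checks = {
            "sex": ("F", "M"),
            "aao_class": ("early", "adult", "unknown"),
            "fhx": ("yes", "no", "unknown"),
            "id_status": ("none", "broad_id"),
            "cnv_group": ("pathogenic_cnv", "rare_cnv_vus", "no_rare_cnv"),
        }
        for name, allowed in checks.items():
            if getattr(self, name) not in allowed:
                raise ValueError(f"{name}={getattr(self, name)!r} not in {allowed}")


@dataclass(frozen=True)
class Finding:
    finding_class: str  # one of FINDING_CLASSES
    identifier: str  # gene symbol, locus id, or CNV label
    tier: str

    def __post_init__(self) -> None:
        if self.finding_class not in FINDING_CLASSES:
            raise ValueError(f"unknown finding class {self.finding_class!r}")


class FindingsLedger:
    """Per-individual sets of high-impact findings, keyed by sample id.

    Every cohort member appears, carriers and non-carriers alike, so that
    yield denominators are well defined.
    """

    def __init__(self, sample_ids: Iterable[str]):
        self._findings: dict[str, set[Finding]] = {s: set() for s in sample_ids}

    @property
    def sample_ids(self) -> list[str]:
        return list(self._findings)

    def add(self, sample_id: str, finding: Finding) -> None:
        if sample_id not in self._findings:
            raise KeyError(f"unknown sample id {sample_id!r}")
        self._findings[sample_id].add(finding)

    def findings(self, sample_id: str) -> frozenset[Finding]:
        return frozenset(self._findings[sample_id])

    def carriers(
        self,
        classes: Iterable[str] | None = None,
        tiers: Iterable[str] | None = None,
    ) -> set[str]:
        """Distinct individuals with >= 1 finding in the given classes/tiers."""
        cls = set(classes) if classes is not None else set(FINDING_CLASSES)
        tset = set(tiers) if tiers is not None else None
        return {
            s
            for s, fnds in self._findings.items()
            if any(
                f.finding_class in cls and (tset is None or f.tier in tset)
                for f in fnds
            )
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s,
                "finding_class": f.finding_class,
                "identifier": f.identifier,
                "tier": f.tier,
            }
            for s, fnds in self._findings.items()
            for f in sorted(fnds, key=lambda f: (f.finding_class, f.identifier))
        ]
        return pd.DataFrame(
            rows, columns=["sample_id", "finding_class", "identifier", "tier"]
        )

    def __len__(self) -> int:
        return sum(len(v) for v in self._findings.values())


@dataclass(frozen=True)
class YieldReport:
    n_carriers: int
    denominator: int
    carriers: frozenset[str]

    @property
    def proportion(self) -> float:
        return self.n_carriers / self.denominator


def adjudicate_variant(
    variant: VariantRecord,
    freq: FrequencyProfile,
    scores: Optional[InSilicoProfile],
    gene: Optional[GeneAnnotation],
    config: AdjudicationConfig | None = None,
) -> ClinicalRelevanceCall:
    """Tier one small variant against the clinical adjudication rules."""
    cfg = config or AdjudicationConfig()

    if gene is None:
        return ClinicalRelevanceCall(
            tier=TIER_UNCERTAIN, rationale=("missing_gene_annotation",)
        )

    rarity = max_population_af(freq, af_cutoff=cfg.af_cutoff)
    if rarity.rarity == "common":
        return ClinicalRelevanceCall(tier=TIER_NONE, rationale=("common",))

    rationale: list[str] = ["rarity"]

    lof = is_lof(variant)
    consensus = False
    if variant.consequence == "missense":
        consensus, _ = missense_consensus(
            scores or InSilicoProfile(), cfg.consensus
        )
    if lof:
        rationale.append("lof")
    elif consensus:
        rationale.append("consensus_missense")
    else:
        # synonymous / other / non-deleterious missense
        return ClinicalRelevanceCall(tier=TIER_NONE, rationale=("no_qualifying_effect",))

    constrained = is_constrained(gene, loeuf_cutoff=cfg.loeuf_cutoff)
    if constrained is None:
        return ClinicalRelevanceCall(
            tier=TIER_UNCERTAIN, rationale=tuple(rationale) + ("loeuf_unknown",)
        )
    if not constrained:
        return ClinicalRelevanceCall(tier=TIER_NONE, rationale=("unconstrained",))
    rationale.append("constrained")

    if gene.ndd_associated:
        rationale.append("ndd_panel")
        return ClinicalRelevanceCall(
            tier=TIER_CLINICALLY_RELEVANT, rationale=tuple(rationale)
        )

    # Candidate-gene stratum: ultra-rare LoF in a constrained non-panel gene.
    if lof and rarity.rarity == "ultra_rare":
        return ClinicalRelevanceCall(
            tier=TIER_POTENTIAL_IMPLICATION,
            rationale=tuple(rationale) + ("candidate_gene_lof",),
        )
    return ClinicalRelevanceCall(tier=TIER_NONE, rationale=("no_gene_evidence",))


def build_ledger(
    sample_ids: Iterable[str],
    snv_calls: Iterable[tuple[str, str, ClinicalRelevanceCall]] = (),
    cnv_findings: Iterable[tuple[str, str, str]] = (),
    tre_findings: Iterable[tuple[str, str, str]] = (),
) -> FindingsLedger:
    """Assemble the per-individual multi-class findings ledger.

    Parameters
    ----------
    sample_ids
        The full cohort roster (findings for unknown samples are rejected).
    snv_calls
        ``(sample_id, gene_symbol, call)`` triples from
        :func:`adjudicate_variant`; tiers ``none``/``uncertain`` are
        dropped, ``potential_implication`` becomes a candidate_gene_LoF
        finding, ``clinically_relevant`` an SNV_indel finding.
    cnv_findings, tre_findings
        ``(sample_id, identifier, tier)`` triples; only pathogenic /
        likely-pathogenic CNVs and expanded repeats should be passed.
    """
    ledger = FindingsLedger(sample_ids)
    for sample_id, gene_symbol, call in snv_calls:
        if call.tier == TIER_CLINICALLY_RELEVANT:
            ledger.add(sample_id, Finding("SNV_indel", gene_symbol, call.tier))
        elif call.tier == TIER_POTENTIAL_IMPLICATION:
            ledger.add(
                sample_id, Finding("candidate_gene_LoF", gene_symbol, call.tier)
            )
    for sample_id, ident, tier in cnv_findings:
        ledger.add(sample_id, Finding("CNV", ident, tier))
    for sample_id, ident, tier in tre_findings:
        ledger.add(sample_id, Finding("TRE", ident, tier))
    return ledger


def cohort_yield(
    ledger: FindingsLedger,
    profiles: Mapping[str, IndividualProfile] | None = None,
    scope_filter: Callable[[IndividualProfile], bool] | None = None,
    classes: Iterable[str] | None = None,
    tiers: Iterable[str] | None = None,
) -> YieldReport:
    """Distinct-carrier count and proportion within a phenotype scope.

    The denominator is the number of samples passing ``scope_filter``
    (everyone when no filter is given); carriers are counted within that
    scope only.  An empty denominator is an error, not a NaN.
    """
    samples = set(ledger.sample_ids)
    if scope_filter is not None:
        if profiles is None:
            raise ValueError("scope_filter requires profiles")
        missing = samples - set(profiles)
        if missing:
            raise ValueError(f"profiles missing for samples: {sorted(missing)[:5]}")
        samples = {s for s in samples if scope_filter(profiles[s])}
    if not samples:
        raise ValueError("scope filter leaves an empty denominator")
    carriers = ledger.carriers(classes=classes, tiers=tiers) & samples
    return YieldReport(
        n_carriers=len(carriers),
        denominator=len(samples),
        carriers=frozenset(carriers),
    )
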
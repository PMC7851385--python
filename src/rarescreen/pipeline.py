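"""Stage orchestration: adjudicate → CNV concordance → TRE screen →
gene recurrence → yields → PRS, with a machine-readable summary.

The summary mirrors the multi-class accounting a clinical WGS study
reports: distinct carriers per variant class, their unions inside and
outside the pathogenic-CNV group, and all the derived percentages.
Candidate-gene LoF findings (ultra-rare LoF in constrained non-panel
genes) enter the per-individual ledger only for genes whose recurrence
FDR clears ``candidate_fdr_cutoff`` — recurrent hits are proposed
candidates, isolated ones are not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as rio
from .adjudicate import (
    AdjudicationConfig,
    ClinicalRelevanceCall,
    FindingsLedger,
    IndividualProfile,
    TIER_CLINICALLY_RELEVANT,
    TIER_POTENTIAL_IMPLICATION,
    build_ledger,
    adjudicate_variant,
    cohort_yield,
)
from .burden import bh_adjust, fisher_exact_2x2
from .cnv import CNVCall, DEFAULT_MIN_RO, filter_cnvs, match_callsets
from .filters import FrequencyProfile, GeneAnnotation, InSilicoProfile, VariantRecord
from .prs import PRSWeight, compute_prs, evaluate_prs
from .tre import DEFAULT_NEAR_MARGIN, TREGenotype, default_catalog, screen_cohort

__all__ = ["PipelineConfig", "adjudicate_table", "analyze_cohort", "run_pipeline"]

SCORE_COLS = [
    "cadd", "sift", "polyphen2_hvar", "provean",
    "mutation_assessor", "mutation_taster", "phylop_mam", "phylop_vert",
]


def _gene_map(genes: pd.DataFrame) -> dict[str, GeneAnnotation]:
    out = {}
    for row in genes.itertuples(index=False):
        loeuf = getattr(row, "loeuf", None)
        out[row.symbol] = GeneAnnotation(
            symbol=row.symbol,
            loeuf=None if loeuf is None or pd.isna(loeuf) else float(loeuf),
            ndd_associated=bool(row.ndd_associated),
            pathway=str(getattr(row, "pathway", "other")),
            coding_length_kb=float(getattr(row, "coding_length_kb", 1.0)),
        )
    return out


def adjudicate_table(
    variants: pd.DataFrame,
    frequencies: pd.DataFrame,
    scores: pd.DataFrame,
    genes: pd.DataFrame,
    config: AdjudicationConfig | None = None,
) -> pd.DataFrame:
    """Run the variant-level adjudication over whole tables.

    Returns one row per input variant with its tier and rule codes.
    Frequencies join on (chrom, pos, ref, alt); scores additionally on
    sample_id (score profiles are per observed variant).
    """
    cfg = config or AdjudicationConfig()
    gmap = _gene_map(genes)
    key = ["chrom", "pos", "ref", "alt"]
    merged = variants.merge(frequencies, on=key, how="left")
    if not scores.empty:
        merged = merged.merge(
            scores, on=key + ["sample_id"], how="left", suffixes=("", "_score")
        )
    else:
        for c in SCORE_COLS:
            merged[c] = np.nan

    def _af(v) -> Optional[float]:
        return None if pd.isna(v) else float(v)

    tiers, rationales = [], []
    for row in merged.itertuples(index=False):
        variant = VariantRecord(
            sample_id=row.sample_id,
            chrom=row.chrom,
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            variant_class=row.variant_class,
            consequence=row.consequence,
            gene_symbol=row.gene_symbol,
            transcript_id=row.transcript_id or "",
            zygosity=row.zygosity,
        )
        freq = FrequencyProfile(
            af_exac=_af(getattr(row, "af_exac", None)),
            af_1kg=_af(getattr(row, "af_1kg", None)),
            af_gnomad=_af(getattr(row, "af_gnomad", None)),
            af_gnomad_sv=_af(getattr(row, "af_gnomad_sv", None)),
        )
        profile = None
        if row.consequence == "missense":
            profile = InSilicoProfile(
                **{c: _af(getattr(row, c, None)) for c in SCORE_COLS}
            )
        call = adjudicate_variant(
            variant, freq, profile, gmap.get(row.gene_symbol), cfg
        )
        tiers.append(call.tier)
        rationales.append(",".join(call.rationale))
    out = variants.copy()
    out["tier"] = tiers
    out["rationale"] = rationales
    return out


@dataclass
class CohortAnalysis:
    """All stage outputs plus the flat JSON-able summary."""

    calls: pd.DataFrame
    ledger: FindingsLedger
    tre_calls: Optional[pd.DataFrame]
    recurrence: Optional[pd.DataFrame]
    concordance: Optional[object]
    prs_scores: Optional[pd.DataFrame]
    prs_evaluation: Optional[object]
    summary: dict


def _profiles_from_frame(phenotypes: pd.DataFrame) -> dict[str, IndividualProfile]:
    out = {}
    for row in phenotypes.itertuples(index=False):
        out[row.sample_id] = IndividualProfile(
            sample_id=row.sample_id,
            sex=row.sex,
            aao_class=row.aao_class,
            fhx=row.fhx,
            id_status=row.id_status,
            syndromic=bool(row.syndromic),
            cnv_group=row.cnv_group,
        )
    return out


def analyze_cohort(
    variants: pd.DataFrame,
    frequencies: pd.DataFrame,
    scores: pd.DataFrame,
    genes: pd.DataFrame,
    phenotypes: pd.DataFrame,
    cnvs_wgs: Optional[pd.DataFrame] = None,
    cnvs_cma: Optional[pd.DataFrame] = None,
    tre_genotypes: Optional[pd.DataFrame] = None,
    catalog: Optional[dict] = None,
    recurrence_pvalues: Optional[pd.Series] = None,
    recurrence_m: Optional[int] = None,
    candidate_fdr_cutoff: float = 0.05,
    prs_dosages: Optional[pd.DataFrame] = None,
    prs_weights: Optional[pd.DataFrame] = None,
    config: AdjudicationConfig | None = None,
    min_ro: float = DEFAULT_MIN_RO,
    near_margin: float = DEFAULT_NEAR_MARGIN,
    p_threshold: float = 0.05,
    percentile_cut: float = 0.20,
) -> CohortAnalysis:
    """Run every stage on in-memory tables; the file-based entry point
    :func:`run_pipeline` wraps this.

    Case samples only are used for yield denominators; control samples
    (``is_case == False`` in ``phenotypes``) participate in the PRS
    evaluation as the comparison group.
    """
    cfg = config or AdjudicationConfig()
    cases = phenotypes.loc[phenotypes["is_case"], "sample_id"].tolist()
    if not cases:
        empty = variants.iloc[0:0].copy()
        empty["tier"] = pd.Series(dtype=str)
        empty["rationale"] = pd.Series(dtype=str)
        return CohortAnalysis(
            calls=empty, ledger=FindingsLedger([]), tre_calls=None,
            recurrence=None, concordance=None, prs_scores=None,
            prs_evaluation=None,
            summary={
                "n_cases": 0, "n_pathogenic_cnv_carriers": 0,
                "n_clinrel_snv_carriers": 0, "n_tre_carriers": 0,
                "n_candidate_gene_carriers": 0, "n_non_cnv_class_carriers": 0,
                "n_high_impact_no_pathogenic_cnv": 0,
            },
        )
    case_set = set(cases)
    profiles = _profiles_from_frame(phenotypes)

    # --- stage 1: small-variant adjudication -------------------------------
    case_variants = variants[variants["sample_id"].isin(case_set)]
    calls = adjudicate_table(case_variants, frequencies, scores, genes, cfg)

    # --- stage 2: CNV filtering + cross-platform concordance ---------------
    concordance = None
    cnv_findings: list[tuple[str, str, str]] = []
    if cnvs_wgs is not None and not cnvs_wgs.empty:
        wgs_calls = filter_cnvs(_cnv_objects(cnvs_wgs))
        for c in wgs_calls:
            if c.tier in {"pathogenic", "likely_pathogenic"} and c.sample_id in case_set:
                cnv_findings.append(
                    (c.sample_id, f"{c.chrom}:{c.start}-{c.end}", c.tier)
                )
        if cnvs_cma is not None and not cnvs_cma.empty:
            cma_calls = filter_cnvs(_cnv_objects(cnvs_cma))
            concordance = match_callsets(wgs_calls, cma_calls, min_ro=min_ro)

    # --- stage 3: repeat-expansion screen ----------------------------------
    tre_calls = None
    tre_findings: list[tuple[str, str, str]] = []
    if tre_genotypes is not None and not tre_genotypes.empty:
        cat = catalog or default_catalog()
        genos = [
            TREGenotype(
                sample_id=r.sample_id,
                locus_id=r.locus_id,
                allele1_repeats=int(r.allele1_repeats),
                allele2_repeats=int(r.allele2_repeats),
                allele2_lower_bound=bool(getattr(r, "allele2_lower_bound", False)),
            )
            for r in tre_genotypes.itertuples(index=False)
        ]
        tre_calls, _ = screen_cohort(genos, cat, near_margin)
        expanded = tre_calls[
            (tre_calls["category"] == "expanded")
            & tre_calls["sample_id"].isin(case_set)
        ]
        tre_findings = [
            (r.sample_id, r.locus_id, "expanded")
            for r in expanded.itertuples(index=False)
        ]

    # --- stage 4: gene recurrence and candidate-gene selection -------------
    candidate_calls = calls[calls["tier"] == TIER_POTENTIAL_IMPLICATION]
    recurrence = None
    proposed: set[str] = set()
    if recurrence_pvalues is not None:
        p = recurrence_pvalues.sort_values()
        m = recurrence_m if recurrence_m is not None else len(p)
        fdr = bh_adjust(p.to_numpy(), m=m)
        recurrence = pd.DataFrame(
            {"gene_symbol": p.index, "p_binomial": p.to_numpy(), "fdr": fdr}
        )
        recurrence["rank"] = np.arange(1, len(recurrence) + 1)
        proposed = set(recurrence.loc[recurrence["fdr"] < candidate_fdr_cutoff,
                                      "gene_symbol"])
    elif not candidate_calls.empty:
        carrier_counts = (
            candidate_calls.groupby("gene_symbol")["sample_id"].nunique()
        )
        recurrent = carrier_counts[carrier_counts >= 2]
        # no external null rates: recurrence table needs them, so without
        # p-values we propose genes by recurrence (>=2 carriers) alone
        proposed = set(recurrent.index)

    # --- stage 5: per-individual ledger and yields -------------------------
    snv_triples = []
    for r in calls.itertuples(index=False):
        if r.tier == TIER_CLINICALLY_RELEVANT:
            snv_triples.append(
                (r.sample_id, r.gene_symbol,
                 ClinicalRelevanceCall(r.tier, tuple(r.rationale.split(","))))
            )
        elif r.tier == TIER_POTENTIAL_IMPLICATION and r.gene_symbol in proposed:
            snv_triples.append(
                (r.sample_id, r.gene_symbol,
                 ClinicalRelevanceCall(r.tier, tuple(r.rationale.split(","))))
            )
    ledger = build_ledger(cases, snv_triples, cnv_findings, tre_findings)

    n = len(cases)
    no_path = lambda p: p.cnv_group != "pathogenic_cnv"
    snv_yield = cohort_yield(ledger, classes=["SNV_indel"])
    snv_yield_nopath = cohort_yield(
        ledger, profiles, no_path, classes=["SNV_indel"]
    )
    non_cnv_all = cohort_yield(
        ledger, classes=["SNV_indel", "TRE", "candidate_gene_LoF"]
    )
    non_cnv_nopath = cohort_yield(
        ledger, profiles, no_path, classes=["SNV_indel", "TRE", "candidate_gene_LoF"]
    )
    cnv_carriers = ledger.carriers(classes=["CNV"])

    # rare-CNV-group vs no-rare-CNV contrast on SNV/indel carriers
    rare_group = {
        s for s in cases
        if profiles[s].cnv_group in {"pathogenic_cnv", "rare_cnv_vus"}
    }
    snv_carriers = ledger.carriers(classes=["SNV_indel"])
    a = len(snv_carriers & rare_group)
    b = len(rare_group) - a
    c = len(snv_carriers - rare_group)
    d = n - len(rare_group) - c
    fisher_p = fisher_exact_2x2([[a, b], [c, d]]) if n else None

    # --- stage 6: polygenic-score evaluation -------------------------------
    prs_scores = prs_eval = None
    if prs_dosages is not None and prs_weights is not None:
        weights = [
            PRSWeight(
                snp_id=str(r.snp_id), effect_allele=str(r.effect_allele),
                beta=float(r.beta), p_train=float(r.p_train),
            )
            for r in prs_weights.itertuples(index=False)
        ]
        labels = phenotypes.set_index("sample_id")["is_case"].astype(int)
        try:
            prs_scores, prs_eval = evaluate_prs(
                prs_dosages, weights, labels,
                p_threshold=p_threshold, percentile_cut=percentile_cut,
            )
        except ValueError:
            # degenerate score distribution (tiny panels / single stratum):
            # report scores without the case/control evaluation
            results = compute_prs(prs_dosages, weights, p_threshold)
            prs_scores = pd.DataFrame(
                {
                    "sample_id": [r.sample_id for r in results],
                    "score": [r.score for r in results],
                    "n_snps_used": [r.n_snps_used for r in results],
                }
            )
            prs_eval = None

    summary = {
        "n_cases": n,
        "n_pathogenic_cnv_carriers": len(cnv_carriers),
        "n_clinrel_snv_carriers": snv_yield.n_carriers,
        "pct_clinrel_snv_carriers": round(100 * snv_yield.proportion, 1),
        "n_clinrel_snv_carriers_no_pathogenic_cnv": snv_yield_nopath.n_carriers,
        "n_without_pathogenic_cnv": snv_yield_nopath.denominator,
        "pct_clinrel_snv_no_pathogenic_cnv": round(
            100 * snv_yield_nopath.proportion, 1
        ),
        "n_tre_carriers": len(ledger.carriers(classes=["TRE"])),
        "n_candidate_gene_carriers": len(
            ledger.carriers(classes=["candidate_gene_LoF"])
        ),
        "proposed_candidate_genes": sorted(proposed),
        "n_non_cnv_class_carriers": non_cnv_all.n_carriers,
        "n_high_impact_no_pathogenic_cnv": non_cnv_nopath.n_carriers,
        "pct_high_impact_no_pathogenic_cnv": round(
            100 * non_cnv_nopath.proportion, 1
        ),
        "fisher_rare_cnv_table": [[a, b], [c, d]],
        "fisher_rare_cnv_p": fisher_p,
        "cnv_recovery_pct": (
            round(100 * concordance.recovery_fraction, 1) if concordance else None
        ),
        "prs_nagelkerke_r2": (
            round(prs_eval.nagelkerke_r2, 4) if prs_eval else None
        ),
        "prs_top_percentile_or": (
            round(prs_eval.odds_ratio, 3) if prs_eval else None
        ),
    }
    return CohortAnalysis(
        calls=calls,
        ledger=ledger,
        tre_calls=tre_calls,
        recurrence=recurrence,
        concordance=concordance,
        prs_scores=prs_scores,
        prs_evaluation=prs_eval,
        summary=summary,
    )


def _cnv_objects(frame: pd.DataFrame) -> list[CNVCall]:
    return [
        CNVCall(
            sample_id=r.sample_id, chrom=r.chrom, start=int(r.start),
            end=int(r.end), dosage=r.dosage, tier=r.tier,
            source=getattr(r, "source", "WGS"),
        )
        for r in frame.itertuples(index=False)
    ]


@dataclass
class PipelineConfig:
    """Paths and thresholds for a file-based pipeline run."""

    fixtures_dir: str
    out_dir: str
    af_cutoff: float = 0.01
    loeuf_cutoff: float = 0.35
    min_ro: float = DEFAULT_MIN_RO
    near_margin: float = DEFAULT_NEAR_MARGIN
    p_threshold: float = 0.05
    percentile_cut: float = 0.20
    candidate_fdr_cutoff: float = 0.05
    recurrence_m: Optional[int] = None
    seed: int = 0


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages against a fixture directory; write per-stage TSVs
    plus ``summary.json``; return the summary."""
    from .adjudicate import AdjudicationConfig
    from .filters import ConsensusConfig

    fixtures = rio.read_fixtures(config.fixtures_dir)
    cfg = AdjudicationConfig(
        af_cutoff=config.af_cutoff,
        loeuf_cutoff=config.loeuf_cutoff,
        consensus=ConsensusConfig(),
    )
    result = analyze_cohort(
        fixtures.variants,
        fixtures.frequencies,
        fixtures.scores,
        fixtures.genes,
        fixtures.phenotypes,
        cnvs_wgs=fixtures.cnvs_wgs,
        cnvs_cma=fixtures.cnvs_cma,
        tre_genotypes=fixtures.tre_genotypes,
        prs_dosages=fixtures.prs_dosages,
        prs_weights=fixtures.prs_weights,
        config=cfg,
        min_ro=config.min_ro,
        near_margin=config.near_margin,
        p_threshold=config.p_threshold,
        percentile_cut=config.percentile_cut,
        candidate_fdr_cutoff=config.candidate_fdr_cutoff,
        recurrence_m=config.recurrence_m,
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.calls.to_csv(out / "variant_calls.tsv", sep="\t", index=False)
    result.ledger.to_frame().to_csv(out / "findings_ledger.tsv", sep="\t", index=False)
    if result.tre_calls is not None:
        result.tre_calls.to_csv(out / "tre_calls.tsv", sep="\t", index=False)
    if result.recurrence is not None:
        result.recurrence.to_csv(out / "gene_recurrence.tsv", sep="\t", index=False)
    if result.concordance is not None:
        result.concordance.to_frame().to_csv(
            out / "cnv_concordance.tsv", sep="\t", index=False
        )
    if result.prs_scores is not None:
        result.prs_scores.to_csv(out / "prs_scores.tsv", sep="\t", index=False)
    summary = dict(result.summary)
    summary["thresholds"] = {
        k: getattr(config, k)
        for k in (
            "af_cutoff", "loeuf_cutoff", "min_ro", "near_margin",
            "p_threshold", "percentile_cut", "candidate_fdr_cutoff",
        )
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    return summary
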
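"""Variant tiering rules, the findings ledger and cohort yields."""

import pytest

from rarescreen.adjudicate import (
    ClinicalRelevanceCall,
    Finding,
    FindingsLedger,
    IndividualProfile,
    TIER_CLINICALLY_RELEVANT,
    TIER_NONE,
    TIER_POTENTIAL_IMPLICATION,
    TIER_UNCERTAIN,
    adjudicate_variant,
    build_ledger,
    cohort_yield,
)
from rarescreen.filters import (
    FrequencyProfile,
    GeneAnnotation,
    InSilicoProfile,
    VariantRecord,
)

ULTRA_RARE = FrequencyProfile(af_exac=0.0, af_gnomad=0.0)
PANEL_GENE = GeneAnnotation(symbol="SHANK3", loeuf=0.17, ndd_associated=True)
CANDIDATE_GENE = GeneAnnotation(symbol="ZMYM2", loeuf=0.33, ndd_associated=False)
WEAK_GENE = GeneAnnotation(symbol="TTN", loeuf=1.1, ndd_associated=False)

PASSING_SCORES = InSilicoProfile(
    cadd=30.0, sift=0.0, polyphen2_hvar=0.99, provean=-6.0,
    mutation_assessor=2.6, mutation_taster=1.0, phylop_mam=3.0, phylop_vert=6.0,
)


def _variant(consequence="frameshift", gene="SHANK3", ref="CAG", alt="C"):
    vclass = "indel" if len(ref) != len(alt) else "SNV"
    return VariantRecord(
        sample_id="s1", chrom="chr22", pos=51153434, ref=ref, alt=alt,
        variant_class=vclass, consequence=consequence, gene_symbol=gene,
    )


class TestAdjudicateVariant:
    def test_ultra_rare_frameshift_in_constrained_panel_gene(self):
        call = adjudicate_variant(_variant(), ULTRA_RARE, None, PANEL_GENE)
        assert call.tier == TIER_CLINICALLY_RELEVANT
        assert {"rarity", "lof", "constrained", "ndd_panel"} <= set(call.rationale)

    def test_consensus_missense_in_panel_gene(self):
        call = adjudicate_variant(
            _variant("missense", ref="C", alt="G"), ULTRA_RARE,
            PASSING_SCORES, PANEL_GENE,
        )
        assert call.tier == TIER_CLINICALLY_RELEVANT
        assert "consensus_missense" in call.rationale

    def test_synonymous_is_none_anywhere(self):
        call = adjudicate_variant(
            _variant("synonymous", ref="C", alt="T"), ULTRA_RARE, None, PANEL_GENE
        )
        assert call.tier == TIER_NONE

    def test_candidate_gene_lof_archetype(self):
        call = adjudicate_variant(
            _variant("stopgain", gene="ZMYM2", ref="G", alt="T"),
            ULTRA_RARE, None, CANDIDATE_GENE,
        )
        assert call.tier == TIER_POTENTIAL_IMPLICATION
        assert "candidate_gene_lof" in call.rationale

    def test_rare_but_not_ultra_rare_lof_off_panel_is_none(self):
        call = adjudicate_variant(
            _variant("stopgain", gene="ZMYM2", ref="G", alt="T"),
            FrequencyProfile(af_gnomad=1e-4), None, CANDIDATE_GENE,
        )
        assert call.tier == TIER_NONE

    def test_common_variant_is_none(self):
        call = adjudicate_variant(
            _variant(), FrequencyProfile(af_gnomad=0.05), None, PANEL_GENE
        )
        assert call.tier == TIER_NONE

    def test_unconstrained_gene_is_none(self):
        call = adjudicate_variant(_variant(gene="TTN"), ULTRA_RARE, None, WEAK_GENE)
        assert call.tier == TIER_NONE

    def test_missing_gene_annotation_is_uncertain(self):
        call = adjudicate_variant(_variant(), ULTRA_RARE, None, None)
        assert call.tier == TIER_UNCERTAIN
        assert "missing_gene_annotation" in call.rationale

    def test_missing_loeuf_on_qualifying_lof_is_uncertain(self):
        gene = GeneAnnotation(symbol="X", loeuf=None, ndd_associated=True)
        call = adjudicate_variant(_variant(gene="X"), ULTRA_RARE, None, gene)
        assert call.tier == TIER_UNCERTAIN

    def test_clinically_relevant_rationale_invariant_enforced(self):
        with pytest.raises(ValueError):
            ClinicalRelevanceCall(TIER_CLINICALLY_RELEVANT, ("rarity",))


class TestLedger:
    def test_multi_class_carrier_keeps_all_findings(self):
        # a pathogenic microduplication plus a clinically relevant missense
        ledger = build_ledger(
            ["56", "57"],
            snv_calls=[
                ("56", "SCN1B",
                 ClinicalRelevanceCall(
                     TIER_CLINICALLY_RELEVANT,
                     ("rarity", "consensus_missense", "constrained", "ndd_panel"),
                 ))
            ],
            cnv_findings=[("56", "16p11.2_dup", "pathogenic")],
        )
        assert len(ledger.findings("56")) == 2
        assert ledger.findings("57") == frozenset()

    def test_candidate_and_cnv_classes_never_merge(self):
        ledger = build_ledger(
            ["562"],
            snv_calls=[
                ("562", "ZMYM2",
                 ClinicalRelevanceCall(TIER_POTENTIAL_IMPLICATION, ("rarity",)))
            ],
            cnv_findings=[("562", "NRXN1_del", "pathogenic")],
        )
        classes = {f.finding_class for f in ledger.findings("562")}
        assert classes == {"candidate_gene_LoF", "CNV"}

    def test_unknown_sample_rejected(self):
        ledger = FindingsLedger(["a"])
        with pytest.raises(KeyError):
            ledger.add("b", Finding("TRE", "DMPK", "expanded"))

    def test_none_tier_calls_do_not_enter_ledger(self):
        ledger = build_ledger(
            ["a"],
            snv_calls=[("a", "G", ClinicalRelevanceCall(TIER_NONE, ("common",)))],
        )
        assert len(ledger) == 0


class TestCohortYield:
    def _ledger(self):
        ledger = FindingsLedger([f"s{i}" for i in range(10)])
        for s in ["s0", "s1", "s2"]:
            ledger.add(s, Finding("SNV_indel", "G1", TIER_CLINICALLY_RELEVANT))
        ledger.add("s0", Finding("SNV_indel", "G2", TIER_CLINICALLY_RELEVANT))
        ledger.add("s3", Finding("CNV", "c", "pathogenic"))
        return ledger

    def test_counts_individuals_not_variants(self):
        y = cohort_yield(self._ledger(), classes=["SNV_indel"])
        assert y.n_carriers == 3  # s0 carries two variants, counted once
        assert y.denominator == 10

    def test_scope_filter_changes_denominator_and_carriers(self):
        ledger = self._ledger()
        profiles = {
            s: IndividualProfile(
                sample_id=s,
                cnv_group="pathogenic_cnv" if s == "s0" else "no_rare_cnv",
            )
            for s in ledger.sample_ids
        }
        y = cohort_yield(
            ledger, profiles, lambda p: p.cnv_group != "pathogenic_cnv",
            classes=["SNV_indel"],
        )
        assert (y.n_carriers, y.denominator) == (2, 9)

    def test_empty_ledger_zero_yield(self):
        y = cohort_yield(FindingsLedger(["a", "b"]))
        assert y.n_carriers == 0 and y.proportion == 0.0

    def test_empty_denominator_is_error(self):
        ledger = FindingsLedger(["a"])
        profiles = {"a": IndividualProfile(sample_id="a")}
        with pytest.raises(ValueError):
            cohort_yield(ledger, profiles, lambda p: False)
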
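"""Generator calibration, determinism, spiking rules and ground truth."""

import numpy as np
import pandas as pd
import pytest

from rarescreen.cohortsim import SimulationConfig, generate_cohort
from rarescreen.pipeline import adjudicate_table


def _rare_counts(fixtures, variant_class, samples):
    merged = fixtures.variants.merge(
        fixtures.frequencies, on=["chrom", "pos", "ref", "alt"], how="left"
    )
    max_af = merged[["af_exac", "af_1kg", "af_gnomad", "af_gnomad_sv"]].fillna(
        0.0
    ).max(axis=1)
    rare = merged[(max_af <= 0.01) & (merged["variant_class"] == variant_class)]
    per = rare[rare["sample_id"].isin(set(samples))]
    return per.groupby("sample_id").size().reindex(samples, fill_value=0)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "field, value",
        [
            ("n_cases", 0),
            ("mean_rare_snvs", -1.0),
            ("pathogenic_cnv_prevalence", 1.5),
            ("clinrel_snv_prevalence", -0.1),
            ("af_tail_min", 0.0),
        ],
    )
    def test_offending_field_named_in_error(self, field, value):
        with pytest.raises(ValueError, match=field):
            SimulationConfig(**{field: value})

    def test_overallocated_spikes_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(SimulationConfig(n_cases=4, clinrel_snv_prevalence=1.0))


class TestCalibrationAndDeterminism:
    def test_poisson_means_after_rarity_filter(self, default_cohort):
        """Post-filter per-genome means sit within 3 SE of the configured
        Poisson means across the 259 case genomes."""
        fixtures, _ = default_cohort
        cases = fixtures.phenotypes.loc[
            fixtures.phenotypes["is_case"], "sample_id"
        ].tolist()
        snvs = _rare_counts(fixtures, "SNV", cases)
        se_snv = np.sqrt(271.7 / len(cases))
        assert abs(snvs.mean() - 271.7) < 3 * se_snv
        indels = _rare_counts(fixtures, "indel", cases)
        se_indel = np.sqrt(20.1 / len(cases))
        assert abs(indels.mean() - 20.1) < 3 * se_indel

    def test_common_variants_exist_and_are_filtered(self, default_cohort):
        fixtures, _ = default_cohort
        merged = fixtures.variants.merge(
            fixtures.frequencies, on=["chrom", "pos", "ref", "alt"], how="left"
        )
        max_af = merged[
            ["af_exac", "af_1kg", "af_gnomad", "af_gnomad_sv"]
        ].fillna(0.0).max(axis=1)
        assert (max_af > 0.01).sum() > 0  # the rarity filter has work to do

    def test_same_seed_identical_fixtures(self, small_cohort):
        cfg, (fixtures, _) = small_cohort
        again, _ = generate_cohort(cfg)
        pd.testing.assert_frame_equal(fixtures.variants, again.variants)
        pd.testing.assert_frame_equal(fixtures.prs_dosages, again.prs_dosages)
        pd.testing.assert_frame_equal(fixtures.phenotypes, again.phenotypes)

    def test_different_seed_different_fixtures(self, small_cohort):
        cfg, (fixtures, _) = small_cohort
        import dataclasses

        other, _ = generate_cohort(dataclasses.replace(cfg, seed=cfg.seed + 1))
        assert not fixtures.variants.equals(other.variants)

    def test_zero_prevalence_spiking_leaves_variant_fixtures_unchanged(self):
        import dataclasses

        from rarescreen.cohortsim import spike_in_findings

        cfg = SimulationConfig(
            n_cases=8, n_controls=4, mean_rare_snvs=20, mean_rare_indels=3,
            mean_common_snvs=5, mean_rare_cnvs=1.0, mean_rare_svs=0.5,
            clinrel_snv_prevalence=0.0, pathogenic_cnv_prevalence=0.0,
            tre_carrier_count=0, candidate_gene_carriers=(),
            n_genes=100, n_prs_snps=20, seed=13,
        )
        fixtures, truth = generate_cohort(cfg)
        assert truth.findings == []
        respiked, truth2 = spike_in_findings(fixtures, cfg)
        assert truth2.findings == []
        pd.testing.assert_frame_equal(
            fixtures.variants, respiked.variants
        )
        pd.testing.assert_frame_equal(fixtures.scores, respiked.scores)
        pd.testing.assert_frame_equal(
            fixtures.tre_genotypes.sort_values(
                ["sample_id", "locus_id"], ignore_index=True
            ),
            respiked.tre_genotypes.sort_values(
                ["sample_id", "locus_id"], ignore_index=True
            ),
        )
        assert len(respiked.cnvs_wgs) == len(fixtures.cnvs_wgs)

    def test_minimal_empty_cohort(self):
        cfg = SimulationConfig(
            n_cases=1, n_controls=1,
            mean_rare_snvs=0, mean_rare_indels=0, mean_rare_svs=0,
            mean_rare_cnvs=0, mean_common_snvs=0,
            pathogenic_cnv_prevalence=0, clinrel_snv_prevalence=0,
            tre_carrier_count=0, candidate_gene_carriers=(),
            seed=3,
        )
        fixtures, truth = generate_cohort(cfg)
        assert len(fixtures.variants) == 0
        assert truth.findings == [] and truth.gene_recurrence == {}
        assert len(fixtures.sample_ids) == 2


class TestSpiking:
    def test_deterministic_carrier_counts_at_default_scale(self, default_cohort):
        fixtures, truth = default_cohort
        assert len(truth.samples_with("SNV_indel")) == 11  # round(0.043 * 259)
        assert len(truth.samples_with("TRE")) == 3
        assert len(truth.samples_with("CNV")) == 26  # round(0.10 * 259)
        path = fixtures.cnvs_wgs[fixtures.cnvs_wgs["tier"] == "pathogenic"]
        assert len(path) == 28  # two carriers hold two CNVs each
        assert truth.gene_recurrence and all(
            v >= 2 for v in truth.gene_recurrence.values()
        )

    def test_spiked_tre_alleles_exceed_locus_thresholds(self, default_cohort):
        from rarescreen.tre import default_catalog

        fixtures, truth = default_cohort
        catalog = default_catalog()
        for sample, cls, locus, _ in truth.findings:
            if cls != "TRE":
                continue
            row = fixtures.tre_genotypes[
                (fixtures.tre_genotypes["sample_id"] == sample)
                & (fixtures.tre_genotypes["locus_id"] == locus)
            ].iloc[0]
            assert catalog[locus].exceeds_threshold(int(row["allele2_repeats"]))

    def test_ground_truth_references_existing_samples_and_genes(self, small_cohort):
        _, (fixtures, truth) = small_cohort
        samples = set(fixtures.sample_ids)
        genes = set(fixtures.genes["symbol"])
        loci = set(fixtures.tre_genotypes["locus_id"])
        for sample, cls, ident, _ in truth.findings:
            assert sample in samples
            if cls in {"SNV_indel", "candidate_gene_LoF"}:
                assert ident in genes
            elif cls == "TRE":
                assert ident in loci

    def test_adjudicator_recovers_ground_truth_exactly(self, small_cohort):
        """On noiseless fixtures the tiering has sensitivity = specificity = 1:
        exactly the spiked variants are tiered, nothing else."""
        _, (fixtures, truth) = small_cohort
        calls = adjudicate_table(
            fixtures.variants, fixtures.frequencies, fixtures.scores, fixtures.genes
        )
        clin = calls[calls["tier"] == "clinically_relevant"]
        got = set(zip(clin["sample_id"], clin["gene_symbol"]))
        expected = {
            (s, g) for s, c, g, _ in truth.findings if c == "SNV_indel"
        }
        assert got == expected
        pot = calls[calls["tier"] == "potential_implication"]
        got_cand = set(zip(pot["sample_id"], pot["gene_symbol"]))
        expected_cand = {
            (s, g) for s, c, g, _ in truth.findings if c == "candidate_gene_LoF"
        }
        assert got_cand == expected_cand
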
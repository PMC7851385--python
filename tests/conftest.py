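import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from rarescreen import datasets as ds
from rarescreen.cohortsim import SimulationConfig, generate_cohort
from rarescreen.pipeline import analyze_cohort

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def default_cohort():
    """Full-scale synthetic cohort at the study's default configuration."""
    return generate_cohort(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-case / 6-control cohort for fast structural checks."""
    cfg = SimulationConfig(
        n_cases=30,
        n_controls=10,
        mean_rare_snvs=40.0,
        mean_rare_indels=6.0,
        mean_common_snvs=12.0,
        mean_rare_cnvs=1.5,
        mean_rare_svs=1.0,
        clinrel_snv_prevalence=0.1,
        pathogenic_cnv_prevalence=0.1,
        tre_carrier_count=2,
        candidate_gene_carriers=(2, 2),
        n_genes=300,
        n_prs_snps=60,
        seed=11,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture(scope="session")
def example_bundle():
    """The transcribed published-cohort tables as one dict."""
    variants = pd.concat(
        [ds.example_clinrel_variants(), ds.example_candidate_lof_variants()],
        ignore_index=True,
    ).drop_duplicates(subset=["sample_id", "chrom", "pos", "ref", "alt"])
    wgs, cma = ds.example_cnvs()
    counts, pvalues, m = ds.example_recurrence_pvalues()
    return {
        "variants": variants,
        "frequencies": ds.example_frequencies(),
        "scores": ds.example_missense_scores(),
        "genes": ds.example_gene_annotations(),
        "phenotypes": ds.example_phenotypes(),
        "cnvs_wgs": wgs,
        "cnvs_cma": cma,
        "tre_validated": ds.example_tre_genotypes(validated=True),
        "tre_estimated": ds.example_tre_genotypes(validated=False),
        "recurrence_counts": counts,
        "recurrence_pvalues": pvalues,
        "recurrence_m": m,
    }


@pytest.fixture(scope="session")
def example_analysis(example_bundle):
    """Full pipeline result on the published-cohort example bundle."""
    b = example_bundle
    return analyze_cohort(
        b["variants"],
        b["frequencies"],
        b["scores"],
        b["genes"],
        b["phenotypes"],
        cnvs_wgs=b["cnvs_wgs"],
        cnvs_cma=b["cnvs_cma"],
        tre_genotypes=b["tre_validated"],
        recurrence_pvalues=b["recurrence_pvalues"],
        recurrence_m=b["recurrence_m"],
    )
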
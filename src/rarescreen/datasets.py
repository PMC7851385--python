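"""A worked-example cohort: the findings tables of a published WGS study.

These loaders transcribe, as plain data, the clinically relevant
findings reported for a 259-adult community-based schizophrenia cohort
previously screened by chromosomal microarray (CMA):

* eleven clinically relevant SNVs/indels in ten NDD genes (eight LoF,
  three deleterious missense), two of the carriers also carrying a
  pathogenic 16p11.2 microduplication;
* 28 pathogenic/likely-pathogenic CNVs in 26 individuals;
* three CTG repeat expansions (one *DMPK*, two *ATXN8OS*), one of which
  was under-estimated by short-read genotyping (91 repeats estimated,
  >200 validated);
* four LoF-intolerant genes with recurrent ultra-rare LoF variants
  (*ZMYM2* x3, *GPRIN1* x2, *BRPF1* x2, *DNAJC6* x2) and their
  gene-based recurrence p-values.

Individuals not named in the published tables are synthetic filler with
no findings; gene-level LOEUF and panel annotations are fixture values
chosen to be consistent with the published gene-level claims.  Anything
not printed in the source tables (filler CNV coordinates, CMA
breakpoint jitter) is generated deterministically.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "EXAMPLE_N_CASES",
    "RECURRENCE_M",
    "example_clinrel_variants",
    "example_missense_scores",
    "example_candidate_lof_variants",
    "example_gene_annotations",
    "example_frequencies",
    "example_cnvs",
    "example_tre_genotypes",
    "example_recurrence_pvalues",
    "example_phenotypes",
    "example_roster",
]

EXAMPLE_N_CASES = 259

#: Genome-wide number of screened constrained genes behind the published
#: FDR values (p*m/rank reproduces all four printed FDRs with this m).
RECURRENCE_M = 2944

_PATHOGENIC_CNV_FILLERS = [f"P{i:03d}" for i in range(1, 24)]  # 23 unnamed carriers


def example_clinrel_variants() -> pd.DataFrame:
    """The eleven clinically relevant SNVs/indels (one carrier each)."""
    rows = [
        # sample, gene, consequence, chrom, pos, ref, alt, zygosity
        ("591", "KCNQ5", "stopgain", "chr6", 73904349, "C", "T", "het"),
        ("367", "SCN8A", "frameshift", "chr12", 52115634,
         "GCGTGGTGTCCCTCATCG", "GT", "het"),
        ("592", "CACNA1A", "frameshift", "chr19", 13414644, "CCT", "C", "het"),
        ("567", "SHANK3", "frameshift", "chr22", 51153434, "CAG", "C", "het"),
        ("28", "RYR2", "missense", "chr1", 237954741, "C", "T", "het"),
        ("56", "SCN1B", "missense", "chr19", 35524558, "C", "G", "het"),
        ("55", "SYN1", "missense", "chrX", 47433735, "C", "T", "het"),
        ("573", "MEIS2", "stopgain", "chr15", 37187379, "G", "A", "het"),
        ("625", "BRPF1", "stopgain", "chr3", 9788005, "C", "T", "het"),
        ("609", "BRPF1", "frameshift", "chr3", 9784853, "G", "GA", "het"),
        ("92", "MECP2", "frameshift", "chrX", 153296115, "TGGGGGCA", "T", "het"),
    ]
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "gene_symbol", "consequence", "chrom", "pos",
                 "ref", "alt", "zygosity"],
    )
    df["variant_class"] = np.where(
        df["ref"].str.len() != df["alt"].str.len(), "indel", "SNV"
    )
    df["transcript_id"] = ""
    df["spiked"] = False
    return df[
        ["sample_id", "chrom", "pos", "ref", "alt", "variant_class",
         "consequence", "gene_symbol", "transcript_id", "zygosity", "spiked"]
    ]


def example_candidate_lof_variants() -> pd.DataFrame:
    """Ultra-rare LoF variants in the four recurrence genes (9 variants).

    The two *BRPF1* variants are the same individuals/alleles as in the
    clinically relevant table (that gene is on the NDD panel, so its
    carriers tier as clinically relevant, not as candidate-gene).
    """
    rows = [
        ("562", "ZMYM2", "stopgain", "chr13", 20639938, "G", "T"),
        ("183", "ZMYM2", "frameshift", "chr13", 20649225, "T", "TT"),
        ("291", "ZMYM2", "frameshift", "chr13", 20622456, "CACTG", "C"),
        ("34", "GPRIN1", "frameshift", "chr5", 176036200, "CTTCTG", "C"),
        ("16", "GPRIN1", "frameshift", "chr5", 176037421, "CAC", "C"),
        ("625", "BRPF1", "stopgain", "chr3", 9788005, "C", "T"),
        ("609", "BRPF1", "frameshift", "chr3", 9784853, "G", "GA"),
        ("585", "DNAJC6", "stopgain", "chr1", 65775123, "C", "T"),
        ("26", "DNAJC6", "frameshift", "chr1", 65730988, "GTC", "G"),
    ]
    df = pd.DataFrame(
        rows,
        columns=["sample_id", "gene_symbol", "consequence", "chrom", "pos",
                 "ref", "alt"],
    )
    df["variant_class"] = np.where(
        df["ref"].str.len() != df["alt"].str.len(), "indel", "SNV"
    )
    df["transcript_id"] = ""
    df["zygosity"] = "het"
    df["spiked"] = False
    return df[
        ["sample_id", "chrom", "pos", "ref", "alt", "variant_class",
         "consequence", "gene_symbol", "transcript_id", "zygosity", "spiked"]
    ]


def example_missense_scores() -> pd.DataFrame:
    """In-silico profiles for the three missense variants (fixture values
    passing all eight predictors, consistent with their published
    'deleterious in >=5 of 8' status)."""
    base = {
        "cadd": 29.0, "sift": 0.0, "polyphen2_hvar": 0.99, "provean": -6.0,
        "mutation_assessor": 2.6, "mutation_taster": 1.0,
        "phylop_mam": 2.9, "phylop_vert": 5.8,
    }
    keys = [
        ("28", "chr1", 237954741, "C", "T"),
        ("56", "chr19", 35524558, "C", "G"),
        ("55", "chrX", 47433735, "C", "T"),
    ]
    return pd.DataFrame(
        [{"sample_id": s, "chrom": c, "pos": p, "ref": r, "alt": a, **base}
         for s, c, p, r, a in keys]
    )


def example_gene_annotations() -> pd.DataFrame:
    """Gene table: published LOEUF for the recurrence genes; fixture LOEUF
    (all < 0.35) and NDD-panel membership for the clinical-table genes."""
    rows = [
        # symbol, loeuf, ndd, pathway, coding_kb, omim
        ("KCNQ5", 0.30, True, "synaptic_transmission", 2.7, "607357"),
        ("SCN8A", 0.13, True, "synaptic_transmission", 5.9, "600702"),
        ("CACNA1A", 0.09, True, "synaptic_transmission", 7.5, "601011"),
        ("SHANK3", 0.17, True, "synaptic_transmission", 5.2, "606230"),
        ("RYR2", 0.16, True, "synaptic_transmission", 14.9, "180902"),
        ("SCN1B", 0.26, True, "synaptic_transmission", 0.8, "600235"),
        ("SYN1", 0.21, True, "synaptic_transmission", 2.1, "313440"),
        ("MEIS2", 0.10, True, "gene_expression_regulation", 1.4, "601740"),
        ("BRPF1", 0.18, True, "gene_expression_regulation", 3.6, "602410"),
        ("MECP2", 0.08, True, "gene_expression_regulation", 1.5, "300005"),
        ("ZMYM2", 0.33, False, "gene_expression_regulation", 4.1, "602221"),
        ("GPRIN1", 0.32, False, "synaptic_transmission", 2.3, None),
        ("DNAJC6", 0.22, False, "other", 2.8, None),
    ]
    return pd.DataFrame(
        rows,
        columns=["symbol", "loeuf", "ndd_associated", "pathway",
                 "coding_length_kb", "omim_id"],
    )


def example_frequencies() -> pd.DataFrame:
    """Panel AFs per variant: 0/0 for the ultra-rare rows, the two printed
    non-zero ExAC/gnomAD frequencies for *SCN1B* and *CACNA1A*."""
    variants = pd.concat(
        [example_clinrel_variants(), example_candidate_lof_variants()],
        ignore_index=True,
    ).drop_duplicates(subset=["chrom", "pos", "ref", "alt"])
    out = variants[["chrom", "pos", "ref", "alt"]].copy()
    out["af_exac"] = 0.0
    out["af_1kg"] = np.nan
    out["af_gnomad"] = 0.0
    out["af_gnomad_sv"] = np.nan
    out.loc[out["pos"] == 35524558, ["af_exac", "af_gnomad"]] = [8.24e-6, 4.06e-6]
    out.loc[out["pos"] == 13414644, ["af_exac", "af_gnomad"]] = [0.0, 4.06e-6]
    return out.reset_index(drop=True)


def example_cnvs() -> tuple[pd.DataFrame, pd.DataFrame]:
    """The 28 pathogenic/likely-pathogenic CNVs in 26 carriers.

    Returns ``(wgs_calls, cma_calls)``: the named calls (two 16p11.2
    microduplications, one 2p16.3 *NRXN1* deletion) plus deterministic
    synthetic filler calls; the CMA set repeats each call with <=10%
    breakpoint jitter, emulating the prior microarray platform.
    """
    rng = np.random.default_rng(20_24)
    rows = [
        ("56", "chr16", 29_650_000, 30_200_000, "DUP"),   # 16p11.2
        ("55", "chr16", 29_650_000, 30_200_000, "DUP"),
        ("562", "chr2", 50_145_000, 51_260_000, "DEL"),   # NRXN1, 2p16.3
    ]
    carriers = _PATHOGENIC_CNV_FILLERS
    for i, s in enumerate(carriers):
        n_here = 2 if i < 2 else 1  # 23 carriers, 25 calls -> 28 total
        for _ in range(n_here):
            chrom = f"chr{int(rng.integers(1, 23))}"
            size = int(np.exp(rng.uniform(np.log(100_000), np.log(3_000_000))))
            start = int(rng.integers(1_000_000, 100_000_000))
            rows.append((s, chrom, start, start + size, str(rng.choice(["DEL", "DUP"]))))
    wgs = pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start", "end", "dosage"]
    )
    wgs["tier"] = "pathogenic"
    wgs["source"] = "WGS"
    cma = wgs.copy()
    sizes = (cma["end"] - cma["start"]).to_numpy()
    j1 = (rng.uniform(-0.1, 0.1, size=len(cma)) * sizes).astype(int)
    j2 = (rng.uniform(-0.1, 0.1, size=len(cma)) * sizes).astype(int)
    cma["start"] = cma["start"] + j1
    cma["end"] = cma["end"] + j2
    cma["source"] = "CMA"
    return wgs, cma


def example_tre_genotypes(validated: bool = False) -> pd.DataFrame:
    """Repeat genotypes for the three expansion probands.

    With ``validated=False`` the short-read (ExpansionHunter-style)
    estimates are returned — 97 CTG at *DMPK*, 116 and 91 CTG at
    *ATXN8OS* (the 91 sits below the >110 threshold: an underestimate).
    With ``validated=True`` all three larger alleles are the molecularly
    validated ">200" lower bounds.
    """
    if validated:
        rows = [
            ("72", "DMPK", 9, 201, True),
            ("329", "ATXN8OS", 20, 201, True),
            ("11", "ATXN8OS", 20, 201, True),
        ]
    else:
        rows = [
            ("72", "DMPK", 9, 97, False),
            ("329", "ATXN8OS", 20, 116, False),
            ("11", "ATXN8OS", 20, 91, False),
        ]
    return pd.DataFrame(
        rows,
        columns=["sample_id", "locus_id", "allele1_repeats",
                 "allele2_repeats", "allele2_lower_bound"],
    )


def example_recurrence_pvalues() -> tuple[pd.Series, pd.Series, int]:
    """Published gene-recurrence inputs: carrier counts, binomial
    p-values (the null-rate construction is external) and the
    genome-wide number of screened genes ``m``."""
    counts = pd.Series({"ZMYM2": 3, "GPRIN1": 2, "BRPF1": 2, "DNAJC6": 2})
    pvalues = pd.Series(
        {"ZMYM2": 9.51e-6, "GPRIN1": 9.08e-5, "BRPF1": 3.67e-4, "DNAJC6": 7.39e-4}
    )
    return counts, pvalues, RECURRENCE_M


def example_roster() -> list[str]:
    """All 259 case identifiers (named carriers plus synthetic filler)."""
    named = [
        "591", "367", "592", "567", "28", "56", "55", "573", "625", "609", "92",
        "72", "329", "11",
        "562", "183", "291", "34", "16", "585", "26",
    ]
    roster = list(named) + _PATHOGENIC_CNV_FILLERS
    i = 1
    while len(roster) < EXAMPLE_N_CASES:
        roster.append(f"S{i:03d}")
        i += 1
    return roster


def example_phenotypes() -> pd.DataFrame:
    """Phenotype covariates; CNV-group sizes match the study design
    (26 pathogenic, 136 with any rare CNV, 123 with none)."""
    roster = example_roster()
    pathogenic = {"56", "55", "562"} | set(_PATHOGENIC_CNV_FILLERS)
    named_vus = {"28", "573", "92", "72", "11"}
    fillers = [s for s in roster if s.startswith("S")]
    n_vus_needed = 136 - len(pathogenic) - len(named_vus)
    vus = named_vus | set(fillers[:n_vus_needed])
    female = {"591", "367", "567", "56", "55", "625", "92", "11"}
    broad_id = {"592", "567", "56", "55", "573", "625", "609"}
    syndromic = {"592", "56", "55", "625", "609"}
    rows = []
    for s in roster:
        if s in pathogenic:
            group = "pathogenic_cnv"
        elif s in vus:
            group = "rare_cnv_vus"
        else:
            group = "no_rare_cnv"
        rows.append(
            {
                "sample_id": s,
                "is_case": True,
                "sex": "F" if s in female else "M",
                "aao_class": "adult",
                "fhx": "unknown",
                "id_status": "broad_id" if s in broad_id else "none",
                "syndromic": s in syndromic,
                "cnv_group": group,
            }
        )
    return pd.DataFrame(rows)
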
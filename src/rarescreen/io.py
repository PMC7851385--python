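"""File formats: VCF v4.2, BED, TSV tables and ExpansionHunter-style JSON.

Small variants travel as a sites-style VCF with per-record ``SAMPLE``,
``GENE``, ``CSQ``, ``VCLASS`` and ``ZYG`` INFO keys (one record per
sample-variant pair; the cohort's rare variants are essentially all
singletons, so a genotype-matrix VCF would add hundreds of empty
columns per record).  CNVs travel as BED with three extra columns
(dosage, tier, sample); repeat genotypes as one ExpansionHunter-style
JSON per sample, ``{"LocusResults": {locus: {"Variants": {locus:
{"Genotype": "a/b"}}}}}``, reduced to the consumed fields; everything
else as TSV with documented headers.

Round-trip guarantee: ``read_fixtures(write_fixtures(F)) == F`` on the
canonically sorted bundle.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .cohortsim import SCORE_COLUMNS, VARIANT_KEY, CohortFixtures

__all__ = [
    "write_vcf", "read_vcf", "write_cnv_bed", "read_cnv_bed",
    "write_eh_json", "read_eh_json", "write_fixtures", "read_fixtures",
]

_CHROM_ORDER = {f"chr{i}": i for i in range(1, 23)} | {"chrX": 23, "chrY": 24}

_CONTIG_LINES = "".join(
    f"##contig=<ID=chr{c}>\n" for c in list(range(1, 23)) + ["X", "Y"]
)

VCF_HEADER = f"""\
##fileformat=VCFv4.2
{_CONTIG_LINES}""" + """\
##INFO=<ID=SAMPLE,Number=1,Type=String,Description="Carrier sample id">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=TRANSCRIPT,Number=1,Type=String,Description="Transcript id">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Coding consequence">
##INFO=<ID=VCLASS,Number=1,Type=String,Description="SNV or indel">
##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity">
##INFO=<ID=SPIKED,Number=0,Type=Flag,Description="Simulator spike-in">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _chrom_rank(c: str) -> int:
    return _CHROM_ORDER.get(c, 99)


def write_vcf(variants: pd.DataFrame, path) -> Path:
    """Write the variants table as a sorted VCF v4.2 (1-based positions)."""
    path = Path(path)
    df = variants.copy()
    if not df.empty:
        df["_cr"] = df["chrom"].map(_chrom_rank)
        df = df.sort_values(
            ["_cr", "pos", "ref", "alt", "sample_id"], ignore_index=True
        )
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for row in df.itertuples(index=False):
            info = (
                f"SAMPLE={row.sample_id};GENE={row.gene_symbol};"
                f"TRANSCRIPT={row.transcript_id or '.'};CSQ={row.consequence};"
                f"VCLASS={row.variant_class};ZYG={row.zygosity}"
            )
            if getattr(row, "spiked", False):
                info += ";SPIKED"
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\tPASS\t{info}\n"
            )
    return path


def read_vcf(path) -> pd.DataFrame:
    """Read a VCF written by :func:`write_vcf` back into the table form."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            rows.append(
                {
                    "sample_id": info["SAMPLE"],
                    "chrom": rec.chrom,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "variant_class": info["VCLASS"],
                    "consequence": info["CSQ"],
                    "gene_symbol": info["GENE"],
                    "transcript_id": (
                        "" if info["TRANSCRIPT"] == "." else info["TRANSCRIPT"]
                    ),
                    "zygosity": info["ZYG"],
                    "spiked": "SPIKED" in info,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "chrom", "pos", "ref", "alt", "variant_class",
            "consequence", "gene_symbol", "transcript_id", "zygosity", "spiked",
        ],
    ).astype({"pos": np.int64, "spiked": bool})


_CNV_COLUMNS = ["chrom", "start", "end", "dosage", "tier", "sample_id", "source"]


def write_cnv_bed(cnvs: pd.DataFrame, path) -> Path:
    """BED (0-based half-open) + dosage, tier, sample, source columns."""
    path = Path(path)
    df = cnvs.copy()
    if not df.empty:
        df["_cr"] = df["chrom"].map(_chrom_rank)
        df = df.sort_values(["_cr", "start", "end", "sample_id"]).drop(columns="_cr")
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_CNV_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.dosage}\t"
                f"{row.tier}\t{row.sample_id}\t{row.source}\n"
            )
    return path


def read_cnv_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", names=_CNV_COLUMNS, comment="#",
        dtype={"chrom": str, "start": np.int64, "end": np.int64},
    )
    return df[["sample_id", "chrom", "start", "end", "dosage", "tier", "source"]]


def write_eh_json(tre_genotypes: pd.DataFrame, out_dir) -> Path:
    """One ExpansionHunter-style JSON per sample under ``out_dir``.

    Lower-bound estimates are serialised back to ``">N"`` genotype text.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sample_id, block in tre_genotypes.groupby("sample_id", sort=True):
        locus_results = {}
        for row in block.sort_values("locus_id").itertuples(index=False):
            a2 = (
                f">{row.allele2_repeats - 1}"
                if row.allele2_lower_bound
                else str(row.allele2_repeats)
            )
            locus_results[row.locus_id] = {
                "Variants": {
                    row.locus_id: {"Genotype": f"{row.allele1_repeats}/{a2}"}
                }
            }
        payload = {"SampleParameters": {"SampleId": sample_id},
                   "LocusResults": locus_results}
        with open(out_dir / f"{sample_id}.json", "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
    return out_dir


def read_eh_json(path_or_dir) -> pd.DataFrame:
    """Read one EH-style JSON or a directory of them into the genotype table."""
    p = Path(path_or_dir)
    files = sorted(p.glob("*.json")) if p.is_dir() else [p]
    rows = []
    for f in files:
        payload = json.loads(f.read_text())
        sample_id = payload.get("SampleParameters", {}).get("SampleId", f.stem)
        for locus_id, locus in payload["LocusResults"].items():
            for var in locus["Variants"].values():
                a1_txt, a2_txt = var["Genotype"].split("/")
                lb = a2_txt.startswith(">")
                a2 = int(a2_txt[1:]) + 1 if lb else int(a2_txt)
                rows.append(
                    {
                        "sample_id": sample_id,
                        "locus_id": locus_id,
                        "allele1_repeats": int(a1_txt),
                        "allele2_repeats": a2,
                        "allele2_lower_bound": lb,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "locus_id", "allele1_repeats",
            "allele2_repeats", "allele2_lower_bound",
        ],
    ).astype({"allele1_repeats": np.int64, "allele2_repeats": np.int64,
              "allele2_lower_bound": bool})


_TSV_SPECS = {
    # name -> (attribute, float_format)
    "frequencies": "frequencies",
    "scores": "scores",
    "genes": "genes",
    "svs": "svs",
    "prs_weights": "prs_weights",
    "phenotypes": "phenotypes",
}


def write_fixtures(fixtures: CohortFixtures, out_dir) -> Path:
    """Write the whole bundle under ``out_dir``; see the module docstring."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_vcf(fixtures.variants, out / "variants.vcf")
    write_cnv_bed(fixtures.cnvs_wgs, out / "cnvs_wgs.bed")
    write_cnv_bed(fixtures.cnvs_cma, out / "cnvs_cma.bed")
    write_eh_json(fixtures.tre_genotypes, out / "tre_genotypes")
    for name in _TSV_SPECS:
        getattr(fixtures, name).to_csv(out / f"{name}.tsv", sep="\t", index=False)
    fixtures.prs_dosages.to_csv(out / "prs_dosages.tsv", sep="\t")
    return out


def read_fixtures(in_dir) -> CohortFixtures:
    """Read a bundle written by :func:`write_fixtures`."""
    p = Path(in_dir)
    tsv = {
        name: pd.read_csv(p / f"{name}.tsv", sep="\t", dtype={"chrom": str})
        for name in _TSV_SPECS
    }
    if "syndromic" in tsv["phenotypes"]:
        tsv["phenotypes"]["syndromic"] = tsv["phenotypes"]["syndromic"].astype(bool)
    if "ndd_associated" in tsv["genes"]:
        tsv["genes"]["ndd_associated"] = tsv["genes"]["ndd_associated"].astype(bool)
    dosages = pd.read_csv(p / "prs_dosages.tsv", sep="\t", index_col="sample_id")
    return CohortFixtures(
        variants=read_vcf(p / "variants.vcf"),
        frequencies=tsv["frequencies"],
        scores=tsv["scores"],
        genes=tsv["genes"],
        cnvs_wgs=read_cnv_bed(p / "cnvs_wgs.bed"),
        cnvs_cma=read_cnv_bed(p / "cnvs_cma.bed"),
        svs=tsv["svs"],
        tre_genotypes=read_eh_json(p / "tre_genotypes"),
        prs_weights=tsv["prs_weights"],
        prs_dosages=dosages,
        phenotypes=tsv["phenotypes"],
    )


def canonicalize(fixtures: CohortFixtures) -> CohortFixtures:
    """Sort every table into the canonical order used for round-trip checks."""
    f = fixtures
    return CohortFixtures(
        variants=f.variants.sort_values(
            ["sample_id", "chrom", "pos", "ref", "alt"], ignore_index=True
        ),
        frequencies=f.frequencies.sort_values(VARIANT_KEY, ignore_index=True),
        scores=f.scores.sort_values(
            ["sample_id"] + VARIANT_KEY, ignore_index=True
        )[VARIANT_KEY + ["sample_id"] + SCORE_COLUMNS],
        genes=f.genes.sort_values("symbol", ignore_index=True),
        cnvs_wgs=f.cnvs_wgs.sort_values(
            ["sample_id", "chrom", "start", "end"], ignore_index=True
        ),
        cnvs_cma=f.cnvs_cma.sort_values(
            ["sample_id", "chrom", "start", "end"], ignore_index=True
        ),
        svs=f.svs.sort_values(
            ["sample_id", "chrom", "start", "end"], ignore_index=True
        ),
        tre_genotypes=f.tre_genotypes.sort_values(
            ["sample_id", "locus_id"], ignore_index=True
        ),
        prs_weights=f.prs_weights.sort_values("snp_id", ignore_index=True),
        prs_dosages=f.prs_dosages.sort_index(),
        phenotypes=f.phenotypes.sort_values("sample_id", ignore_index=True),
    )
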
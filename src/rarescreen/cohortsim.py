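"""Synthetic case/control WGS cohort generator with a ground-truth ledger.

Emulates the variant content a clinical WGS pipeline sees *after*
calling and annotation: per-genome rare exonic small variants (Poisson
background calibrated to published per-genome means), in-silico score
profiles, CNV callsets from two platforms, repeat-locus genotypes, a
polygenic-score SNP panel with case enrichment, and phenotype
covariates — plus spiked-in clinically relevant findings recorded in a
:class:`GroundTruth` so every downstream stage can be validated exactly.

Design points that matter for interpretation:

* Per-genome background counts are Poisson with the configured means,
  and those means apply AFTER the rare-exonic filter: common variants
  are generated on top and are meant to be removed by the rarity rule.
* Background population AFs follow a mixture — a point mass at 0
  (ultra-rare) and a log-uniform low-frequency tail up to the rarity
  cutoff — so both rarity strata are populated.
* Background variation is kept out of the clinically actionable gene
  strata (no background missense/LoF in constrained NDD-panel genes, no
  background LoF in constrained genes at all), so on these noiseless
  fixtures the adjudicator's ground-truth sensitivity and specificity
  are exactly 1.
* Carrier counts for spiked classes are deterministic roundings of
  prevalence x n, not Bernoulli draws, so worked-example counts are
  exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .adjudicate import TIER_CLINICALLY_RELEVANT, TIER_POTENTIAL_IMPLICATION
from .filters import DEFAULT_LOEUF_CUTOFF
from .tre import default_catalog

__all__ = ["SimulationConfig", "GroundTruth", "CohortFixtures", "generate_cohort",
           "spike_in_findings"]

_BASES = np.array(["A", "C", "G", "T"])

VARIANT_KEY = ["chrom", "pos", "ref", "alt"]

SCORE_COLUMNS = [
    "cadd", "sift", "polyphen2_hvar", "provean",
    "mutation_assessor", "mutation_taster", "phylop_mam", "phylop_vert",
]

# (fail_low, fail_high, pass_low, pass_high) per predictor; pass ranges sit
# strictly inside the deleterious side of each published threshold.
_SCORE_RANGES = {
    "cadd": (0.0, 14.9, 15.0, 45.0),
    "sift": (0.06, 1.0, 0.0, 0.05),
    "polyphen2_hvar": (0.0, 0.89, 0.90, 1.0),
    "provean": (-2.4, 5.0, -10.0, -2.6),
    "mutation_assessor": (-2.0, 1.8, 1.90, 4.0),
    "mutation_taster": (0.0, 0.49, 0.5, 1.0),
    "phylop_mam": (-1.0, 2.2, 2.30, 4.5),
    "phylop_vert": (-2.0, 3.9, 4.0, 10.0),
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort; defaults encode the study conditions.

    The per-genome means are the published post-filter averages for rare
    exonic variation (271.7 SNVs, 20.1 indels, 2.89 SVs, 3.33 CNVs of
    >=10 kb); 10% of cases carry a pathogenic CNV, 4.3% a clinically
    relevant SNV/indel, and three cases carry a repeat expansion.
    """

    n_cases: int = 259
    n_controls: int = 225
    mean_rare_snvs: float = 271.7
    mean_rare_indels: float = 20.1
    mean_rare_svs: float = 2.89
    mean_rare_cnvs: float = 3.33
    pathogenic_cnv_prevalence: float = 0.10
    clinrel_snv_prevalence: float = 0.043
    tre_carrier_count: int = 3
    # population-AF mixture: point mass at 0, log-uniform tail
    af_zero_fraction: float = 0.60
    af_tail_min: float = 1e-6
    af_tail_max: float = 0.01
    score_pass_probability: float = 1.0
    prs_effect: float = 0.5
    seed: int = 0
    # generator-internal knobs (documented defaults, rarely touched)
    mean_common_snvs: float = 55.0
    cnv_vus_probability: float = 0.22
    candidate_gene_carriers: tuple[int, ...] = (3, 2, 2, 2)
    tre_spike_loci: tuple[str, ...] = ("DMPK", "ATXN8OS", "ATXN8OS")
    n_genes: int = 1200
    ndd_panel_fraction: float = 0.30
    n_prs_snps: int = 300
    carrier_enrichment_odds: float = 3.0
    loeuf_cutoff: float = DEFAULT_LOEUF_CUTOFF

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_controls"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        for name in (
            "mean_rare_snvs", "mean_rare_indels", "mean_rare_svs",
            "mean_rare_cnvs", "mean_common_snvs",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        for name in (
            "pathogenic_cnv_prevalence", "clinrel_snv_prevalence",
            "af_zero_fraction", "score_pass_probability",
            "cnv_vus_probability", "ndd_panel_fraction",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.tre_carrier_count < 0:
            raise ValueError(f"tre_carrier_count must be >= 0, got {self.tre_carrier_count}")
        if not (0 < self.af_tail_min <= self.af_tail_max):
            raise ValueError(
                f"af_tail_min/af_tail_max invalid: {self.af_tail_min}/{self.af_tail_max}"
            )


@dataclass
class GroundTruth:
    """What was spiked where: the oracle for downstream validation."""

    findings: list[tuple[str, str, str, str]] = field(default_factory=list)
    #: (sample_id, finding_class, identifier, intended tier)
    gene_recurrence: dict[str, int] = field(default_factory=dict)

    def samples_with(self, finding_class: str) -> set[str]:
        return {s for s, c, _, _ in self.findings if c == finding_class}


@dataclass
class CohortFixtures:
    """In-memory fixture bundle; see :mod:`rarescreen.io` for file forms."""

    variants: pd.DataFrame
    frequencies: pd.DataFrame
    scores: pd.DataFrame
    genes: pd.DataFrame
    cnvs_wgs: pd.DataFrame
    cnvs_cma: pd.DataFrame
    svs: pd.DataFrame
    tre_genotypes: pd.DataFrame
    prs_weights: pd.DataFrame
    prs_dosages: pd.DataFrame
    phenotypes: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return self.phenotypes["sample_id"].tolist()


# ---------------------------------------------------------------------------
# gene universe

def _make_genes(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_genes
    idx = np.arange(n)
    loeuf = np.round(rng.lognormal(mean=-0.1, sigma=0.55, size=n), 3)
    loeuf = np.clip(loeuf, 0.03, 2.0)
    constrained = loeuf < cfg.loeuf_cutoff
    ndd = np.zeros(n, dtype=bool)
    constrained_idx = np.flatnonzero(constrained)
    n_panel = int(round(cfg.ndd_panel_fraction * constrained_idx.size))
    ndd[constrained_idx[:n_panel]] = True
    coding_length_kb = np.round(np.clip(rng.lognormal(0.6, 0.6, size=n), 0.3, 20.0), 2)
    chrom = np.array([f"chr{(i % 22) + 1}" for i in idx])
    start = 1_000_000 + (idx // 22) * 300_000
    pathway = rng.choice(
        ["synaptic_transmission", "gene_expression_regulation", "other"],
        size=n, p=[0.25, 0.25, 0.5],
    )
    return pd.DataFrame(
        {
            "symbol": [f"GENE{i:04d}" for i in idx],
            "loeuf": loeuf,
            "ndd_associated": ndd,
            "pathway": pathway,
            "coding_length_kb": coding_length_kb,
            "chrom": chrom,
            "start": start,
            "end": start + (coding_length_kb * 1000).astype(int),
        }
    )


# ---------------------------------------------------------------------------
# background variants

def _draw_afs(n: int, cfg: SimulationConfig, rng: np.random.Generator,
              common: bool = False) -> np.ndarray:
    """Max population AF per variant under the configured mixture."""
    if common:
        lo, hi = np.log(cfg.af_tail_max * 1.1), np.log(0.5)
        return np.exp(rng.uniform(lo, hi, size=n))
    af = np.zeros(n)
    tail = rng.random(n) >= cfg.af_zero_fraction
    lo, hi = np.log(cfg.af_tail_min), np.log(cfg.af_tail_max)
    af[tail] = np.exp(rng.uniform(lo, hi, size=int(tail.sum())))
    return af


def _alleles(consequence: np.ndarray, rng: np.random.Generator
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n = consequence.size
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    ref = _BASES[ref_i].astype(object)
    alt = _BASES[alt_i].astype(object)
    vclass = np.full(n, "SNV", dtype=object)
    is_fs = consequence == "frameshift"
    if is_fs.any():
        k = rng.integers(1, 4, size=int(is_fs.sum()))
        pads = np.array(["A", "AT", "ATG"], dtype=object)[k - 1]
        ref[is_fs] = ref[is_fs] + pads  # deletions
        alt[is_fs] = np.array([r[0] for r in ref[is_fs]], dtype=object)
        vclass[is_fs] = "indel"
    return ref, alt, vclass


def _background_variants(
    cfg: SimulationConfig,
    samples: list[str],
    genes: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Background SNV/indel rows plus their frequency profiles."""
    constrained = genes["loeuf"] < cfg.loeuf_cutoff
    panel = constrained & genes["ndd_associated"]
    safe_missense = genes.index[~panel].to_numpy()  # no clin-actionable missense
    safe_lof = genes.index[~constrained].to_numpy()  # no candidate-stratum LoF
    any_gene = genes.index.to_numpy()

    blocks = []
    specs = [
        ("rare_snv", cfg.mean_rare_snvs, False),
        ("rare_indel", cfg.mean_rare_indels, False),
        ("common_snv", cfg.mean_common_snvs, True),
    ]
    for label, mean, common in specs:
        counts = rng.poisson(mean, size=len(samples))
        total = int(counts.sum())
        if total == 0:
            continue
        sample_col = np.repeat(np.array(samples, dtype=object), counts)
        if label == "rare_indel":
            cons = rng.choice(
                ["frameshift", "synonymous", "other"], size=total, p=[0.5, 0.1, 0.4]
            )
            # frameshifts must avoid the constrained stratum; others any gene
            gene_idx = np.where(
                cons == "frameshift",
                rng.choice(safe_lof, size=total),
                rng.choice(any_gene, size=total),
            )
        else:
            cons = rng.choice(
                ["synonymous", "missense", "other", "stopgain", "splice_site"],
                size=total, p=[0.28, 0.40, 0.22, 0.05, 0.05],
            )
            lof_mask = np.isin(cons, ["stopgain", "splice_site"])
            gene_idx = rng.choice(any_gene, size=total)
            gene_idx[lof_mask] = rng.choice(safe_lof, size=int(lof_mask.sum()))
            mis_mask = cons == "missense"
            gene_idx[mis_mask] = rng.choice(safe_missense, size=int(mis_mask.sum()))
        gstart = genes["start"].to_numpy()[gene_idx]
        gend = genes["end"].to_numpy()[gene_idx]
        pos = (gstart + rng.random(total) * (gend - gstart)).astype(np.int64) + 1
        ref, alt, vclass = _alleles(cons, rng)
        if label == "rare_indel":
            # indel block: force indel alleles for non-frameshift rows too
            non_fs = vclass == "SNV"
            if non_fs.any():
                ref[non_fs] = ref[non_fs] + "C"
                vclass[non_fs] = "indel"
        block = pd.DataFrame(
            {
                "sample_id": sample_col,
                "chrom": genes["chrom"].to_numpy()[gene_idx],
                "pos": pos,
                "ref": ref.astype(str),
                "alt": alt.astype(str),
                "variant_class": vclass.astype(str),
                "consequence": cons.astype(str),
                "gene_symbol": genes["symbol"].to_numpy()[gene_idx],
                "transcript_id": "",
                "zygosity": rng.choice(["het", "hom"], size=total, p=[0.95, 0.05]),
                "spiked": False,
            }
        )
        block["max_af_drawn"] = _draw_afs(total, cfg, rng, common=common)
        blocks.append(block)

    if blocks:
        variants = pd.concat(blocks, ignore_index=True)
    else:
        variants = _empty_variants()
    freqs = _frequency_profiles(variants, rng)
    return variants.drop(columns=["max_af_drawn"]), freqs


def _empty_variants() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "sample_id", "chrom", "pos", "ref", "alt", "variant_class",
            "consequence", "gene_symbol", "transcript_id", "zygosity",
            "spiked", "max_af_drawn",
        ]
    ).astype({"pos": np.int64, "spiked": bool, "max_af_drawn": float})


def _frequency_profiles(variants: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    """Panel AF columns per distinct variant key; max over panels equals the
    drawn mixture AF (first occurrence wins for colliding keys)."""
    if variants.empty:
        return pd.DataFrame(
            columns=VARIANT_KEY + ["af_exac", "af_1kg", "af_gnomad", "af_gnomad_sv"]
        )
    uniq = variants.drop_duplicates(subset=VARIANT_KEY)[
        VARIANT_KEY + ["max_af_drawn"]
    ].reset_index(drop=True)
    n = len(uniq)
    max_af = uniq["max_af_drawn"].to_numpy()
    # gnomAD (largest panel) carries the max; ExAC a fraction of it;
    # 1000 Genomes only sees the commoner tail; gnomAD-SV n/a for small variants
    af_gnomad = max_af
    af_exac = np.round(max_af * rng.uniform(0.0, 1.0, size=n), 10)
    af_1kg = np.where(max_af > 5e-3, max_af * rng.uniform(0.0, 1.0, size=n), np.nan)
    out = uniq[VARIANT_KEY].copy()
    out["af_exac"] = af_exac
    out["af_1kg"] = np.round(af_1kg, 10)
    out["af_gnomad"] = np.round(af_gnomad, 10)
    out["af_gnomad_sv"] = np.nan
    return out


def _score_matrix(
    variants: pd.DataFrame, cfg: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """In-silico profiles for every missense variant.

    Background missense rows pass each predictor independently with
    probability 0.25 (so a background consensus pass is possible but the
    affected genes are outside the actionable stratum); spiked rows pass
    all 8 with probability ``score_pass_probability``, else exactly 4.
    """
    mis = variants[variants["consequence"] == "missense"]
    if mis.empty:
        return pd.DataFrame(columns=VARIANT_KEY + ["sample_id"] + SCORE_COLUMNS)
    n = len(mis)
    out = mis[VARIANT_KEY + ["sample_id"]].reset_index(drop=True)
    spiked = mis["spiked"].to_numpy()
    all_pass = np.where(
        spiked, rng.random(n) < cfg.score_pass_probability, False
    )
    for j, col in enumerate(SCORE_COLUMNS):
        flo, fhi, plo, phi = _SCORE_RANGES[col]
        bg_pass = rng.random(n) < 0.25
        spiked_pass = np.where(all_pass, True, j < 4)  # exactly-4 profile fails quorum
        passes = np.where(spiked, spiked_pass, bg_pass)
        vals = np.where(
            passes,
            rng.uniform(plo, phi, size=n),
            rng.uniform(flo, fhi, size=n),
        )
        absent = (~spiked) & (rng.random(n) < 0.10)
        vals = np.where(absent, np.nan, np.round(vals, 3))
        out[col] = vals
    return out


# ---------------------------------------------------------------------------
# CNVs, SVs, repeats, PRS, phenotypes

def _background_cnvs(
    cfg: SimulationConfig, samples: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    counts = rng.poisson(cfg.mean_rare_cnvs, size=len(samples))
    total = int(counts.sum())
    chrom = np.array([f"chr{c}" for c in rng.integers(1, 23, size=total)])
    size = np.exp(rng.uniform(np.log(10_000), np.log(3_000_000), size=total)).astype(
        np.int64
    )
    start = rng.integers(1_000_000, 100_000_000, size=total)
    tier = np.where(rng.random(total) < cfg.cnv_vus_probability, "VUS", "none")
    return pd.DataFrame(
        {
            "sample_id": np.repeat(np.array(samples, dtype=object), counts),
            "chrom": chrom,
            "start": start,
            "end": start + size,
            "dosage": rng.choice(["DEL", "DUP"], size=total),
            "tier": tier,
            "source": "WGS",
        }
    )


def _background_svs(
    cfg: SimulationConfig, samples: list[str], rng: np.random.Generator
) -> pd.DataFrame:
    counts = rng.poisson(cfg.mean_rare_svs, size=len(samples))
    total = int(counts.sum())
    chrom = np.array([f"chr{c}" for c in rng.integers(1, 23, size=total)])
    size = rng.integers(50, 10_000, size=total)
    start = rng.integers(1_000_000, 100_000_000, size=total)
    return pd.DataFrame(
        {
            "sample_id": np.repeat(np.array(samples, dtype=object), counts),
            "chrom": chrom,
            "start": start,
            "end": start + size,
            "svtype": rng.choice(["DEL", "DUP", "INV"], size=total),
            "tier": "none",
        }
    )


def _tre_background(
    samples: list[str], catalog: dict, rng: np.random.Generator
) -> pd.DataFrame:
    loci = sorted(catalog)
    rows = []
    for locus_id in loci:
        spec = catalog[locus_id]
        n = len(samples)
        a = rng.integers(spec.normal_min, spec.normal_max + 1, size=n)
        b = rng.integers(spec.normal_min, spec.normal_max + 1, size=n)
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": samples,
                    "locus_id": locus_id,
                    "allele1_repeats": np.minimum(a, b),
                    "allele2_repeats": np.maximum(a, b),
                    "allele2_lower_bound": False,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _prs_panel(
    cfg: SimulationConfig,
    cases: list[str],
    controls: list[str],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    m = cfg.n_prs_snps
    snp_ids = [f"snp{i:04d}" for i in range(m)]
    beta = rng.normal(0.0, 0.15, size=m)
    p_train = rng.uniform(1e-6, 1.0, size=m)
    maf = rng.uniform(0.10, 0.90, size=m)
    weights = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "effect_allele": rng.choice(list("ACGT"), size=m),
            "beta": np.round(beta, 4),
            "p_train": p_train,
        }
    )
    passing = p_train <= 0.05
    denom = 2.0 * float((beta[passing] ** 2).sum())
    shift = np.zeros(m)
    if denom > 0:
        shift[passing] = cfg.prs_effect * beta[passing] / denom
    f_control = maf
    f_case = np.clip(maf + shift, 0.02, 0.98)
    dos_cases = rng.binomial(2, f_case, size=(len(cases), m)).astype(float)
    dos_controls = rng.binomial(2, f_control, size=(len(controls), m)).astype(float)
    dosages = pd.DataFrame(
        np.vstack([dos_cases, dos_controls]),
        index=pd.Index(cases + controls, name="sample_id"),
        columns=snp_ids,
    )
    return weights, dosages


def _bern(rng, n, p):
    return rng.random(n) < p


def _phenotypes(
    cfg: SimulationConfig,
    cases: list[str],
    controls: list[str],
    carriers: set[str],
    cnv_groups: dict[str, str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    def enriched_p(base: float, enriched: np.ndarray) -> np.ndarray:
        odds = base / (1 - base) * np.where(enriched, cfg.carrier_enrichment_odds, 1.0)
        return odds / (1 + odds)

    samples = cases + controls
    n = len(samples)
    is_case = np.array([s in set(cases) for s in samples])
    is_carrier = np.array([s in carriers for s in samples])
    sex = np.where(_bern(rng, n, enriched_p(0.5, is_carrier)), "F", "M")
    broad_id = _bern(rng, n, enriched_p(0.39, is_carrier)) & is_case
    syndromic = _bern(rng, n, enriched_p(0.20, is_carrier)) & is_case
    fhx = rng.choice(["yes", "no", "unknown"], size=n, p=[0.30, 0.65, 0.05])
    aao = rng.choice(["early", "adult", "unknown"], size=n, p=[0.20, 0.75, 0.05])
    return pd.DataFrame(
        {
            "sample_id": samples,
            "is_case": is_case,
            "sex": sex,
            "aao_class": np.where(is_case, aao, "unknown"),
            "fhx": np.where(is_case, fhx, "unknown"),
            "id_status": np.where(broad_id, "broad_id", "none"),
            "syndromic": syndromic,
            "cnv_group": [cnv_groups.get(s, "no_rare_cnv") for s in samples],
        }
    )


# ---------------------------------------------------------------------------
# spiking

def _check_allocation(cfg: SimulationConfig) -> tuple[int, int, int]:
    n_clinrel = int(round(cfg.clinrel_snv_prevalence * cfg.n_cases))
    n_cnv = int(round(cfg.pathogenic_cnv_prevalence * cfg.n_cases))
    n_candidate = int(sum(cfg.candidate_gene_carriers))
    needed = n_clinrel + cfg.tre_carrier_count + n_candidate
    if n_clinrel > cfg.n_cases or n_cnv > cfg.n_cases:
        raise ValueError("prevalence x n exceeds cohort size")
    if needed > cfg.n_cases:
        raise ValueError(
            f"spike allocation ({needed} carriers) exceeds n_cases={cfg.n_cases}"
        )
    return n_clinrel, n_cnv, n_candidate


def spike_in_findings(
    fixtures: CohortFixtures,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[CohortFixtures, GroundTruth]:
    """Inject carrier findings into a background bundle; record ground truth.

    Carrier counts are deterministic roundings of prevalence x n_cases.
    Spiked variants satisfy, by construction, the tier rules they are
    labelled with (ultra-rare; LoF or all-predictors-passing missense;
    constrained gene; NDD-panel membership for the clinically relevant
    class, non-panel for the candidate-gene class).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    cfg = config
    truth = GroundTruth()
    genes = fixtures.genes
    cases = fixtures.phenotypes.loc[
        fixtures.phenotypes["is_case"], "sample_id"
    ].tolist()

    n_clinrel, n_cnv_carriers, _ = _check_allocation(cfg)
    constrained = genes["loeuf"] < cfg.loeuf_cutoff
    panel_genes = genes[constrained & genes["ndd_associated"]]
    candidate_genes = genes[constrained & ~genes["ndd_associated"]]

    cursor = 0
    new_variant_rows = []
    new_score_rows = []
    new_freq_rows = []

    # --- clinically relevant SNVs/indels -----------------------------------
    archetypes = ["frameshift", "stopgain", "missense"]
    if n_clinrel and panel_genes.empty:
        raise ValueError("no constrained NDD-panel genes available for spiking")
    clinrel_samples = cases[cursor : cursor + n_clinrel]
    cursor += n_clinrel
    for i, sample in enumerate(clinrel_samples):
        gene = panel_genes.iloc[i % len(panel_genes)]
        cons = archetypes[i % 3]
        row, freq_row, score_row = _spiked_variant(sample, gene, cons, cfg, rng)
        new_variant_rows.append(row)
        new_freq_rows.append(freq_row)
        if score_row is not None:
            new_score_rows.append(score_row)
        truth.findings.append(
            (sample, "SNV_indel", gene["symbol"], TIER_CLINICALLY_RELEVANT)
        )

    # --- tandem repeat expansions ------------------------------------------
    tre = fixtures.tre_genotypes.copy()
    catalog = default_catalog()
    tre_samples = cases[cursor : cursor + cfg.tre_carrier_count]
    cursor += cfg.tre_carrier_count
    for i, sample in enumerate(tre_samples):
        locus_id = cfg.tre_spike_loci[i % len(cfg.tre_spike_loci)]
        spec = catalog[locus_id]
        expanded = int(spec.pathogenic_threshold + rng.integers(20, 160))
        mask = (tre["sample_id"] == sample) & (tre["locus_id"] == locus_id)
        tre.loc[mask, "allele2_repeats"] = expanded
        truth.findings.append((sample, "TRE", locus_id, "expanded"))

    # --- candidate-gene ultra-rare LoF recurrence --------------------------
    counts = tuple(cfg.candidate_gene_carriers)
    if counts and candidate_genes.empty:
        raise ValueError("no constrained non-panel genes available for spiking")
    for gi, k in enumerate(counts):
        gene = candidate_genes.iloc[gi % len(candidate_genes)]
        carrier_block = cases[cursor : cursor + k]
        cursor += k
        for sample in carrier_block:
            row, freq_row, _ = _spiked_variant(sample, gene, "stopgain", cfg, rng)
            new_variant_rows.append(row)
            new_freq_rows.append(freq_row)
            truth.findings.append(
                (sample, "candidate_gene_LoF", gene["symbol"], TIER_POTENTIAL_IMPLICATION)
            )
        if carrier_block:
            truth.gene_recurrence[gene["symbol"]] = len(carrier_block)

    # --- pathogenic CNVs (26 carriers / 28 CNVs at default scale) ----------
    cnv_carriers = list(reversed(cases))[:n_cnv_carriers]
    cnv_rows = []
    for i, sample in enumerate(cnv_carriers):
        n_here = 2 if i < 2 and n_cnv_carriers >= 2 else 1
        for j in range(n_here):
            chrom = f"chr{int(rng.integers(1, 23))}"
            size = int(np.exp(rng.uniform(np.log(100_000), np.log(3_000_000))))
            start = int(rng.integers(1_000_000, 100_000_000))
            cnv_rows.append(
                {
                    "sample_id": sample,
                    "chrom": chrom,
                    "start": start,
                    "end": start + size,
                    "dosage": str(rng.choice(["DEL", "DUP"])),
                    "tier": "pathogenic",
                    "source": "WGS",
                }
            )
            truth.findings.append(
                (sample, "CNV", f"{chrom}:{start}-{start + size}", "pathogenic")
            )
    cnvs_wgs = pd.concat(
        [fixtures.cnvs_wgs, pd.DataFrame(cnv_rows, columns=fixtures.cnvs_wgs.columns)],
        ignore_index=True,
    )

    # CMA re-detections of the pathogenic calls, breakpoints jittered <=10%
    cma_rows = []
    for r in cnv_rows:
        size = r["end"] - r["start"]
        j1 = int(rng.uniform(-0.1, 0.1) * size)
        j2 = int(rng.uniform(-0.1, 0.1) * size)
        cma_rows.append(
            {
                **r,
                "start": max(0, r["start"] + j1),
                "end": max(r["start"] + j1 + 1, r["end"] + j2),
                "source": "CMA",
            }
        )
    cnvs_cma = pd.DataFrame(cma_rows, columns=fixtures.cnvs_wgs.columns)

    # --- merge spiked small variants ---------------------------------------
    variants = fixtures.variants
    frequencies = fixtures.frequencies
    scores = fixtures.scores
    if new_variant_rows:
        variants = pd.concat(
            [variants, pd.DataFrame(new_variant_rows)], ignore_index=True
        )
        # spiked rows first so their ultra-rare AF wins any key collision
        frequencies = pd.concat(
            [pd.DataFrame(new_freq_rows), frequencies], ignore_index=True
        ).drop_duplicates(subset=VARIANT_KEY, keep="first")
    if new_score_rows:
        scores = pd.concat([scores, pd.DataFrame(new_score_rows)], ignore_index=True)

    # --- phenotypes ---------------------------------------------------------
    controls = fixtures.phenotypes.loc[
        ~fixtures.phenotypes["is_case"], "sample_id"
    ].tolist()
    carrier_set = set(clinrel_samples) | set(cnv_carriers)
    cnv_groups = {}
    vus_samples = set(cnvs_wgs.loc[cnvs_wgs["tier"] == "VUS", "sample_id"])
    for s in cases + controls:
        if s in set(cnv_carriers):
            cnv_groups[s] = "pathogenic_cnv"
        elif s in vus_samples:
            cnv_groups[s] = "rare_cnv_vus"
        else:
            cnv_groups[s] = "no_rare_cnv"
    phenotypes = _phenotypes(cfg, cases, controls, carrier_set, cnv_groups, rng)

    out = CohortFixtures(
        variants=variants.sort_values(
            ["sample_id", "chrom", "pos", "ref", "alt"], ignore_index=True
        ),
        frequencies=frequencies.sort_values(VARIANT_KEY, ignore_index=True),
        scores=scores.sort_values(
            ["sample_id"] + VARIANT_KEY, ignore_index=True
        ),
        genes=fixtures.genes,
        cnvs_wgs=cnvs_wgs,
        cnvs_cma=cnvs_cma,
        svs=fixtures.svs,
        tre_genotypes=tre,
        prs_weights=fixtures.prs_weights,
        prs_dosages=fixtures.prs_dosages,
        phenotypes=phenotypes,
    )
    return out, truth


def _spiked_variant(sample, gene, consequence, cfg, rng):
    pos = int(rng.integers(gene["start"], gene["end"])) + 1
    if consequence == "frameshift":
        ref, alt, vclass = "CAG", "C", "indel"
    else:
        ref, alt = ("C", "T") if consequence == "stopgain" else ("G", "A")
        vclass = "SNV"
    row = {
        "sample_id": sample,
        "chrom": gene["chrom"],
        "pos": pos,
        "ref": ref,
        "alt": alt,
        "variant_class": vclass,
        "consequence": consequence,
        "gene_symbol": gene["symbol"],
        "transcript_id": "",
        "zygosity": "het",
        "spiked": True,
    }
    freq_row = {
        "chrom": gene["chrom"], "pos": pos, "ref": ref, "alt": alt,
        "af_exac": 0.0, "af_1kg": np.nan, "af_gnomad": 0.0, "af_gnomad_sv": np.nan,
    }
    score_row = None
    if consequence == "missense":
        score_row = {"chrom": gene["chrom"], "pos": pos, "ref": ref, "alt": alt,
                     "sample_id": sample}
        passing = rng.random() < cfg.score_pass_probability
        for j, col in enumerate(SCORE_COLUMNS):
            flo, fhi, plo, phi = _SCORE_RANGES[col]
            ok = True if passing else j < 4
            score_row[col] = round(
                float(rng.uniform(plo, phi) if ok else rng.uniform(flo, fhi)), 3
            )
    return row, freq_row, score_row


# ---------------------------------------------------------------------------
# entry point

def generate_cohort(
    config: SimulationConfig | None = None,
) -> tuple[CohortFixtures, GroundTruth]:
    """Generate the full synthetic cohort bundle plus its ground truth.

    Identical config (including seed) gives byte-identical fixtures once
    written with :func:`rarescreen.io.write_fixtures`.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    cases = [f"SCZ{i + 1:04d}" for i in range(cfg.n_cases)]
    controls = [f"CTL{i + 1:04d}" for i in range(cfg.n_controls)]
    samples = cases + controls

    genes = _make_genes(cfg, rng)
    variants, frequencies = _background_variants(cfg, samples, genes, rng)
    scores = _score_matrix(variants.assign(spiked=False), cfg, rng)
    cnvs = _background_cnvs(cfg, samples, rng)
    svs = _background_svs(cfg, samples, rng)
    tre = _tre_background(samples, default_catalog(), rng)
    weights, dosages = _prs_panel(cfg, cases, controls, rng)
    phenotypes = pd.DataFrame(
        {
            "sample_id": samples,
            "is_case": [s in set(cases) for s in samples],
            "sex": "M",
            "aao_class": "unknown",
            "fhx": "unknown",
            "id_status": "none",
            "syndromic": False,
            "cnv_group": "no_rare_cnv",
        }
    )
    background = CohortFixtures(
        variants=variants,
        frequencies=frequencies,
        scores=scores,
        genes=genes,
        cnvs_wgs=cnvs,
        cnvs_cma=cnvs.iloc[0:0].copy(),
        svs=svs,
        tre_genotypes=tre,
        prs_weights=weights,
        prs_dosages=dosages,
        phenotypes=phenotypes,
    )
    return spike_in_findings(background, cfg, rng)
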
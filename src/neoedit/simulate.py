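"""Synthetic immunoedited cohort generator with known ground truth.

Emulates the genomics of a carcinogen-induced mouse sarcoma cohort: a
synthetic gene space with FABP and MBP gene sets, per-sample somatic
mutations placed uniformly over coding space, binomial read depths, a
clonal/subclonal VAF mixture, chromosome-scale copy-number segments with
a phenotype-linked Myc-region gain, and caliper growth curves.

Immunoediting is the generative mechanism under study: every mutation
whose surrogate-predicted peptides include a strong binder in an FABP
gene is removed before observation with a host-genotype-dependent
probability (high in immunocompetent WT hosts, low or zero in DNGR-1- or
RAG1-deficient hosts).  The observed VCFs are the post-editing variants;
the pre-editing truth is retained for parameter-recovery tests.

Everything is drawn from ``numpy`` generators seeded from the config, so
a (config, seed) pair reproduces outputs byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genemodel import GeneModel, GeneSet, write_gene_models, write_gene_set
from .neoantigen import surrogate_ic50, variant_is_strong
from .variants import SomaticVariant, classify_consequence

CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 20))
CHROM_LEN = 50_000_000
MYC_REGION = ("chr15", 40_000_000, 40_200_000)

_NONSTOP_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
)
_STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Cohort sizes match the sequenced cohort (WT 18, DNGR-1KO 14, RAG1KO
    11).  The default burden of 350-500 mutations per tumor is a 1/10
    scale of the 3,500-5,000 reported for MCA fibrosarcomas, over a
    600-gene coding space; ``paper_scale()`` restores the full burden.
    Editing probabilities are calibration knobs of the generator, not
    measured quantities: they encode the direction of immunoediting
    (strong FABP neoantigens depleted in immunocompetent hosts).
    """

    seed: int = 0
    n_genes: int = 600
    mean_cds_len: int = 1500
    n_fabp: int = 88
    n_mbp: int = 98
    n_wt: int = 18
    n_dngr1ko: int = 14
    n_rag1ko: int = 11
    burden_low: int = 350
    burden_high: int = 500
    editing_prob: dict = field(
        default_factory=lambda: {"WT": 0.8, "DNGR1KO": 0.15, "RAG1KO": 0.0}
    )
    clonal_fraction: float = 0.7
    clonal_beta: tuple = (20.0, 20.0)
    subclonal_beta: tuple = (2.0, 8.0)
    mean_depth: float = 120.0
    indel_fraction: float = 0.10
    decoy_fraction: float = 0.05
    myc_gain_prob: dict = field(
        default_factory=lambda: {"progressor": 0.59, "regressor": 0.19, "unknown": 0.0}
    )
    phenotype_logistic_scale: float = 0.15
    growth_noise_sd: float = 0.05

    def paper_scale(self) -> "SimConfig":
        return replace(self, burden_low=3500, burden_high=5000)

    def cohort_design(self) -> list[tuple[str, str]]:
        design = []
        for genotype, n in (
            ("WT", self.n_wt),
            ("DNGR1KO", self.n_dngr1ko),
            ("RAG1KO", self.n_rag1ko),
        ):
            for i in range(n):
                design.append((f"{genotype}_{i + 1:02d}", genotype))
        return design


@dataclass
class SimSample:
    sample_id: str
    genotype: str
    phenotype: str = "unknown"
    variants: list = field(default_factory=list)  # observed (post-editing)
    segments: list = field(default_factory=list)  # (chrom, start, end, log2)
    growth: list = field(default_factory=list)  # (day, length_mm, width_mm)
    truth: dict = field(default_factory=dict)


@dataclass
class SimCohort:
    config: SimConfig
    gene_models: list
    gene_sets: dict
    samples: list


# ---------------------------------------------------------------------------
# genome


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(len(_NONSTOP_CODONS), size=n_codons - 2)
    stop = _STOP_CODONS[rng.integers(0, 3)]
    return "ATG" + "".join(_NONSTOP_CODONS[i] for i in body) + stop


def simulate_genome(config: SimConfig, rng: np.random.Generator | None = None):
    """Random gene models plus disjoint FABP/MBP gene sets."""
    if config.n_fabp + config.n_mbp > config.n_genes:
        raise ValueError("gene sets larger than the gene space")
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    cursors = {c: 1_000_000 for c in CHROMOSOMES}
    models = []
    for g in range(config.n_genes):
        n_codons = int(
            np.clip(rng.normal(config.mean_cds_len / 3, config.mean_cds_len / 12), 60, None)
        )
        cds = _random_cds(rng, n_codons)
        chrom = CHROMOSOMES[g % len(CHROMOSOMES)]
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 4))
        length = len(cds)
        # split CDS length into exon chunks of >= 30 bp
        if n_exons > 1:
            cuts = np.sort(rng.choice(np.arange(30, length - 30), size=n_exons - 1, replace=False))
            sizes = np.diff(np.concatenate([[0], cuts, [length]]))
            if (sizes < 30).any():
                sizes = np.array([length])
        else:
            sizes = np.array([length])
        start = cursors[chrom] + int(rng.integers(2_000, 10_000))
        intervals = []
        pos = start
        for sz in sizes:
            intervals.append((pos, pos + int(sz)))
            pos += int(sz) + int(rng.integers(200, 2_000))
        cursors[chrom] = pos
        models.append(
            GeneModel(
                gene_id=f"G{g + 1:04d}",
                gene_name=f"Gene{g + 1}",
                chrom=chrom,
                strand=strand,
                cds_intervals=tuple(intervals),
                cds_seq=cds,
            )
        )
    ids = [m.gene_id for m in models]
    picked = rng.choice(len(ids), size=config.n_fabp + config.n_mbp, replace=False)
    fabp_ids = frozenset(ids[i] for i in picked[: config.n_fabp])
    mbp_ids = frozenset(ids[i] for i in picked[config.n_fabp :])
    by_id = {m.gene_id: m for m in models}
    sets = {
        "FABP": GeneSet("FABP", fabp_ids, sum(by_id[i].cds_length for i in fabp_ids)),
        "MBP": GeneSet("MBP", mbp_ids, sum(by_id[i].cds_length for i in mbp_ids)),
    }
    return models, sets


# ---------------------------------------------------------------------------
# per-sample mutations


def _draw_snv(rng, gene: GeneModel):
    fwd = gene.forward_cds
    j = int(rng.integers(0, gene.cds_length))
    ref = fwd[j]
    alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
    return SomaticVariant(
        chrom=gene.chrom, pos=gene.spliced_to_genomic(j), ref=ref, alt=alt
    )


def _draw_indel(rng, gene: GeneModel):
    fwd = gene.forward_cds
    ivs = gene.cds_intervals
    weights = np.array([e - s for s, e in ivs], dtype=float)
    exon = int(rng.choice(len(ivs), p=weights / weights.sum()))
    ex_start_off = sum(e - s for s, e in ivs[:exon])
    ex_len = ivs[exon][1] - ivs[exon][0]
    size = int(rng.choice([1, 2, 3], p=[0.45, 0.30, 0.25]))
    if rng.random() < 0.5 and ex_len > size + 2:  # deletion
        anchor = ex_start_off + int(rng.integers(0, ex_len - size - 1))
        ref = fwd[anchor : anchor + size + 1]
        alt = ref[0]
    else:  # insertion
        anchor = ex_start_off + int(rng.integers(0, ex_len - 1))
        ref = fwd[anchor]
        alt = ref + "".join("ACGT"[i] for i in rng.integers(0, 4, size=size))
    return SomaticVariant(
        chrom=gene.chrom, pos=gene.spliced_to_genomic(anchor), ref=ref, alt=alt
    )


def simulate_sample_variants(
    config: SimConfig,
    genotype: str,
    gene_models: list,
    gene_sets: dict,
    rng: np.random.Generator,
    sample_id: str,
):
    """Generate one sample's somatic variants and per-variant truth.

    Returns (observed_variants, truth_records).  Observed variants are the
    generated set minus edited-out strong-FABP variants; a fraction of
    the remainder are non-PASS decoys.
    """
    lengths = np.array([g.cds_length for g in gene_models], dtype=float)
    weights = lengths / lengths.sum()
    n_mut = int(rng.integers(config.burden_low, config.burden_high + 1))
    gene_idx = rng.choice(len(gene_models), size=n_mut, p=weights)
    fabp, mbp = gene_sets["FABP"], gene_sets["MBP"]
    used: set = set()
    observed, truth = [], []
    for gi in gene_idx:
        gene = gene_models[int(gi)]
        v = None
        for _ in range(5):
            cand = (
                _draw_indel(rng, gene)
                if rng.random() < config.indel_fraction
                else _draw_snv(rng, gene)
            )
            if (cand.chrom, cand.pos) not in used:
                v = cand
                break
        if v is None:
            continue
        used.add((v.chrom, v.pos))
        csq, change = classify_consequence(v, gene)
        v.gene_id, v.consequence, v.protein_change = gene.gene_id, csq, change
        v.sample_id = sample_id
        strong = csq in ("missense", "frameshift_variant") and variant_is_strong(
            v, gene, surrogate_ic50
        )
        in_fabp = gene.gene_id in fabp
        edited = bool(
            strong and in_fabp and rng.random() < config.editing_prob[genotype]
        )
        clonal = rng.random() < config.clonal_fraction
        ab = config.clonal_beta if clonal else config.subclonal_beta
        vaf_true = float(rng.beta(*ab))
        depth = max(1, int(rng.poisson(config.mean_depth)))
        ad_alt = int(rng.binomial(depth, vaf_true))
        v.ad_alt, v.ad_ref = ad_alt, depth - ad_alt
        decoy = bool((not edited) and rng.random() < config.decoy_fraction)
        v.filter_status = "LowEVS" if decoy else "PASS"
        truth.append(
            {
                "variant_id": v.variant_id,
                "gene_id": gene.gene_id,
                "consequence": csq,
                "clone": "clonal" if clonal else "subclonal",
                "vaf_true": round(vaf_true, 5),
                "strong": strong,
                "in_fabp": in_fabp,
                "in_mbp": gene.gene_id in mbp,
                "edited": edited,
                "decoy": decoy,
            }
        )
        if not edited:
            observed.append(v)
    return observed, truth


# ---------------------------------------------------------------------------
# copy number and growth


def simulate_segments(config: SimConfig, rng, myc_gain: bool):
    """Chromosome-scale log2 segments, with an explicit Myc-region segment."""
    segs = []
    for chrom in CHROMOSOMES:
        if chrom == MYC_REGION[0]:
            bounds = [0, MYC_REGION[1], MYC_REGION[2], CHROM_LEN]
        else:
            k = int(rng.integers(2, 6))
            inner = np.sort(rng.integers(1, CHROM_LEN, size=k - 1))
            bounds = [0] + sorted(set(int(b) for b in inner)) + [CHROM_LEN]
        for lo, hi in zip(bounds, bounds[1:]):
            if hi <= lo:
                continue
            u = rng.random()
            if u < 0.05:
                log2 = float(rng.uniform(0.7, 1.3))
            elif u < 0.10:
                log2 = float(-rng.uniform(0.7, 1.3))
            else:
                log2 = float(rng.normal(0.0, 0.12))
            if chrom == MYC_REGION[0] and lo == MYC_REGION[1]:
                log2 = float(rng.uniform(0.8, 1.5)) if myc_gain else float(rng.normal(0.0, 0.12))
            segs.append((chrom, lo, hi, round(log2, 4)))
    return segs


def simulate_growth_curve(
    config: SimConfig, phenotype: str, rng, days=tuple(range(0, 22, 3)), v0: float = 100.0
):
    """Caliper series (day, length_mm, width_mm) under exponential growth.

    Progressors draw a positive Malthusian rate, regressors a negative
    one; unknown phenotype gives a flat curve at the inoculation volume.
    Noise is multiplicative lognormal on volume.
    """
    if phenotype == "progressor":
        rate = float(rng.normal(0.22, 0.04))
    elif phenotype == "regressor":
        rate = float(-abs(rng.normal(0.18, 0.04)))
    else:
        rate = 0.0
    rows = []
    for day in days:
        vol = v0 * np.exp(rate * day)
        if config.growth_noise_sd > 0:
            vol *= float(np.exp(rng.normal(0.0, config.growth_noise_sd)))
        diameter = (2.0 * vol) ** (1.0 / 3.0)  # l = w so that 0.5*l*w^2 = vol
        rows.append((day, round(diameter, 4), round(diameter, 4)))
    return rate, rows


# ---------------------------------------------------------------------------
# cohort


def simulate_cohort(config: SimConfig) -> SimCohort:
    """Generate the full cohort: genome, variants, phenotypes, CNV, growth."""
    gene_models, gene_sets = simulate_genome(config)
    design = config.cohort_design()
    samples = []
    for offset, (sample_id, genotype) in enumerate(design):
        rng = np.random.default_rng([config.seed, 1000 + offset])
        observed, truth = simulate_sample_variants(
            config, genotype, gene_models, gene_sets, rng, sample_id
        )
        pre_fabp = sum(1 for t in truth if t["strong"] and t["in_fabp"])
        post_fabp = sum(
            1 for t in truth if t["strong"] and t["in_fabp"] and not t["edited"]
        )
        pre_mbp = sum(1 for t in truth if t["strong"] and t["in_mbp"])
        strong_total = sum(1 for t in truth if t["strong"] and not t["edited"] and not t["decoy"])
        samples.append(
            SimSample(
                sample_id=sample_id,
                genotype=genotype,
                variants=observed,
                truth={
                    "per_variant": truth,
                    "strong_fabp_pre": pre_fabp,
                    "strong_fabp_post": post_fabp,
                    "strong_mbp_pre": pre_mbp,
                    "strong_mbp_post": pre_mbp,
                    "strong_total_post": strong_total,
                },
            )
        )
    # phenotype: logistic in the observed strong-neoantigen total, so lines
    # retaining more strong neoantigens are more likely to regress on
    # transplantation into immunocompetent recipients
    totals = np.array([s.truth["strong_total_post"] for s in samples], dtype=float)
    center = float(np.median(totals))
    for offset, s in enumerate(samples):
        rng = np.random.default_rng([config.seed, 5000 + offset])
        p_reg = 1.0 / (
            1.0
            + np.exp(-config.phenotype_logistic_scale * (s.truth["strong_total_post"] - center))
        )
        s.phenotype = "regressor" if rng.random() < p_reg else "progressor"
        myc = bool(rng.random() < config.myc_gain_prob[s.phenotype])
        s.truth["myc_gain"] = myc
        s.truth["p_regressor"] = round(float(p_reg), 4)
        s.segments = simulate_segments(config, rng, myc)
        rate, rows = simulate_growth_curve(config, s.phenotype, rng)
        s.truth["growth_rate"] = round(rate, 4)
        s.growth = rows
    return SimCohort(config=config, gene_models=gene_models, gene_sets=gene_sets, samples=samples)


def simulate_expression(config: SimConfig, gene_models, n_lines: int = 6) -> pd.DataFrame:
    """Fragments-per-million matrix for a few representative lines."""
    rng = np.random.default_rng([config.seed, 9000])
    vals = rng.gamma(2.0, 10.0, size=(len(gene_models), n_lines))
    zeros = rng.random(size=vals.shape) < 0.02
    vals[zeros] = 0.0
    return pd.DataFrame(
        np.round(vals, 3),
        index=[g.gene_id for g in gene_models],
        columns=[f"line{i + 1}" for i in range(n_lines)],
    )


# ---------------------------------------------------------------------------
# writers


def write_vcf(variants, path, contig_lengths=None) -> None:
    """Write a Strelka2-style somatic VCF (single TUMOR sample, AD/DP/VAF)."""
    contig_lengths = contig_lengths or {c: CHROM_LEN for c in CHROMOSOMES}
    lines = [
        "##fileformat=VCFv4.2",
        "##source=neoedit-simulate",
        '##FILTER=<ID=LowEVS,Description="Low somatic evidence score">',
        '##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic mutation">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=VAF,Number=1,Type=Float,Description="Variant allele frequency">',
    ]
    for c, ln in contig_lengths.items():
        lines.append(f"##contig=<ID={c},length={ln}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR")
    order = {c: i for i, c in enumerate(contig_lengths)}
    for v in sorted(variants, key=lambda v: (order.get(v.chrom, 99), v.pos)):
        depth = v.ad_ref + v.ad_alt
        vaf = v.ad_alt / depth if depth else 0.0
        lines.append(
            f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\t{v.filter_status}\t"
            f"SOMATIC\tGT:AD:DP:VAF\t0/1:{v.ad_ref},{v.ad_alt}:{depth}:{vaf:.4f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_cohort(cohort: SimCohort, outdir) -> dict:
    """Write the cohort in the formats the pipeline consumes.

    Returns a manifest of the paths written.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_gene_models(cohort.gene_models, out / "genes.fa", out / "genes.tsv")
    for name, gs in cohort.gene_sets.items():
        write_gene_set(gs, out / f"geneset_{name}.tsv")
    meta_rows, growth_rows = [], []
    for s in cohort.samples:
        vcf = out / f"{s.sample_id}.vcf"
        seg = out / f"{s.sample_id}.seg.tsv"
        write_vcf(s.variants, vcf)
        pd.DataFrame(
            [
                {"sample": s.sample_id, "chrom": c, "start": a, "end": b, "log2": l}
                for c, a, b, l in s.segments
            ]
        ).to_csv(seg, sep="\t", index=False)
        meta_rows.append(
            {
                "sample_id": s.sample_id,
                "host_genotype": s.genotype,
                "phenotype": s.phenotype,
                "vcf": vcf.name,
                "seg": seg.name,
            }
        )
        for day, l, w in s.growth:
            growth_rows.append(
                {"sample": s.sample_id, "mouse": 1, "day": day, "length_mm": l, "width_mm": w}
            )
    pd.DataFrame(meta_rows).to_csv(out / "cohort.tsv", sep="\t", index=False)
    pd.DataFrame(growth_rows).to_csv(out / "growth.tsv", sep="\t", index=False)
    simulate_expression(cohort.config, cohort.gene_models).to_csv(
        out / "expression.tsv", sep="\t"
    )
    truth = {
        "config": asdict(cohort.config),
        "samples": {
            s.sample_id: {k: v for k, v in s.truth.items() if k != "per_variant"}
            for s in cohort.samples
        },
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1))
    return {"dir": str(out), "n_samples": len(cohort.samples)}
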
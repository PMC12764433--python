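"""End-to-end cohort analysis: variants -> neoantigens -> statistics -> CNV.

`analyze_cohort` is the in-memory core used both by the CLI `run`
subcommand (which reads a cohort directory from disk) and by simulation
studies that pass generated objects straight through.  Outputs are plain
DataFrames/dicts; `run_pipeline` serializes them as TSV/JSON plus a
reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cnv import (
    CnProfile,
    call_states,
    genome_fractions,
    min_consistency_segmentation,
    read_seg,
    region_gain_fisher,
    region_gain_frequency,
)
from .genemodel import load_cohort_table, load_gene_models, load_gene_set
from .mixture import fit_vaf_mixture
from .neoantigen import call_neoantigens, surrogate_ic50
from .power import power_table
from .simulate import MYC_REGION
from .stats import (
    contingency_2x2,
    fit_malthusian,
    geneset_burden,
    holm_adjust,
    mann_whitney,
    percent,
    tumor_volume,
)
from .variants import (
    GenomeIndex,
    annotate_variants,
    filter_variants,
    read_somatic_vcf,
    summarize_burden,
)

GENOTYPE_PAIRS = (("DNGR1KO", "WT"), ("RAG1KO", "WT"), ("RAG1KO", "DNGR1KO"))


@dataclass
class Thresholds:
    min_alt_reads: int = 5
    min_vaf: float = 0.2
    ic50_candidate: float = 500.0
    ic50_strong: float = 150.0
    log2_gain: float = 0.6
    log2_loss: float = -0.6

    def __post_init__(self):
        if min(self.min_alt_reads, self.min_vaf, self.ic50_candidate, self.ic50_strong, self.log2_gain) <= 0:
            raise ValueError("thresholds must be positive")
        if self.log2_loss >= 0:
            raise ValueError("log2_loss must be negative")


@dataclass
class CohortResults:
    burden_table: pd.DataFrame
    geneset_contrasts: pd.DataFrame
    cnv_fractions: pd.DataFrame
    myc_by_genotype: dict
    myc_by_phenotype: dict
    myc_fisher: object | None
    transplantation: pd.DataFrame
    power_grid: pd.DataFrame
    clonality: pd.DataFrame
    growth: pd.DataFrame | None
    warnings: list = field(default_factory=list)


def analyze_cohort(
    variants_by_sample: dict,
    genotypes: dict,
    phenotypes: dict,
    profiles: list | None,
    gene_models: list,
    gene_sets: dict,
    thresholds: Thresholds | None = None,
    predictor=surrogate_ic50,
    growth_table: pd.DataFrame | None = None,
) -> CohortResults:
    """Run the full analysis over an in-memory cohort.

    ``variants_by_sample`` maps sample_id -> raw SomaticVariant list;
    ``profiles`` is a list of CnProfile (log2 only, states not yet
    called) or None to skip copy-number analysis.
    """
    th = thresholds or Thresholds()
    notices: list[str] = []
    index = GenomeIndex(gene_models)
    scopes = {"all": None, **gene_sets}

    burden_rows, clonality_rows = [], []
    strong_counts: dict[str, dict[str, int]] = {name: {} for name in scopes}
    for sample_id, raw in variants_by_sample.items():
        filt = filter_variants(raw, min_alt_reads=th.min_alt_reads)
        ann = annotate_variants(filt, index)
        candidates = call_neoantigens(
            ann,
            index,
            predictor=predictor,
            ic50_candidate_max=th.ic50_candidate,
            ic50_strong_max=th.ic50_strong,
            min_vaf=th.min_vaf,
        )
        for name, gs in scopes.items():
            strong_counts[name][sample_id] = geneset_burden(candidates, gs)
        vafs = [v.vaf for v in filt]
        clonal_flags = None
        if len(vafs) >= 10 and len(set(vafs)) > 1:
            fit = fit_vaf_mixture(vafs)
            clonal_flags = fit.clonal_labels
            clonality_rows.append(
                {
                    "sample_id": sample_id,
                    "mean_subclonal": round(float(fit.component_means[0]), 4),
                    "mean_clonal": round(float(fit.component_means[1]), 4),
                    "weight_clonal": round(float(fit.component_weights[1]), 4),
                    "n_clonal": int(fit.clonal_labels.sum()),
                    "n_subclonal": int((~fit.clonal_labels).sum()),
                    "converged": bool(fit.converged),
                }
            )
        else:
            notices.append(f"{sample_id}: too few VAFs for mixture modeling")
        s = summarize_burden(ann, sample_id, clonal_flags=clonal_flags)
        burden_rows.append(
            {
                "sample_id": sample_id,
                "host_genotype": genotypes.get(sample_id, "?"),
                "phenotype": phenotypes.get(sample_id, "unknown"),
                "total": s.total,
                "missense": s.missense,
                "synonymous": s.synonymous,
                "truncating": s.truncating,
                "indels": s.indels,
                "clonal": s.clonal_count,
                "subclonal": s.subclonal_count,
                "strong_neoantigens": strong_counts["all"][sample_id],
                "strong_fabp": strong_counts.get("FABP", {}).get(sample_id, 0),
                "strong_mbp": strong_counts.get("MBP", {}).get(sample_id, 0),
            }
        )
    burden_table = pd.DataFrame(burden_rows)

    # gene-set contrasts: 3 scopes x 3 genotype pairs
    contrast_rows = []
    present = set(genotypes.values())
    for name in scopes:
        counts = strong_counts[name]
        for g1, g2 in GENOTYPE_PAIRS:
            if g1 not in present or g2 not in present:
                notices.append(f"contrast {name} {g1} vs {g2} skipped: genotype absent")
                continue
            a = [counts[s] for s, g in genotypes.items() if g == g1 and s in counts]
            b = [counts[s] for s, g in genotypes.items() if g == g2 and s in counts]
            cmp = mann_whitney(a, b, alternative="two-sided")
            contrast_rows.append(
                {
                    "gene_set": name,
                    "group_1": g1,
                    "group_2": g2,
                    "n_1": cmp.n[0],
                    "n_2": cmp.n[1],
                    "median_1": float(pd.Series(a).median()),
                    "median_2": float(pd.Series(b).median()),
                    "u_statistic": cmp.u_statistic,
                    "p_value": cmp.p_value,
                    "method": cmp.method,
                }
            )
    geneset_contrasts = pd.DataFrame(contrast_rows)
    if not geneset_contrasts.empty:
        geneset_contrasts["p_holm"] = holm_adjust(geneset_contrasts["p_value"])

    # copy number
    cnv_rows = []
    myc_by_genotype: dict = {}
    myc_by_phenotype: dict = {}
    myc_fisher = None
    if profiles:
        called = [
            CnProfile(p.sample_id, call_states(p.segments, th.log2_gain, th.log2_loss))
            for p in profiles
        ]
        if len(called) >= 2:
            called = min_consistency_segmentation(called)
        for p in called:
            fg, fl = genome_fractions(p)
            cnv_rows.append(
                {
                    "sample_id": p.sample_id,
                    "fraction_gained": round(fg, 4),
                    "fraction_lost": round(fl, 4),
                }
            )
        myc_by_genotype = region_gain_frequency(
            called, MYC_REGION, {s: g for s, g in genotypes.items()}
        )
        pheno_labels = {
            s: ph for s, ph in phenotypes.items() if ph in ("progressor", "regressor")
        }
        if pheno_labels:
            myc_by_phenotype = region_gain_frequency(called, MYC_REGION, pheno_labels)
            if {"progressor", "regressor"} <= set(myc_by_phenotype):
                myc_fisher = region_gain_fisher(
                    myc_by_phenotype, "progressor", "regressor"
                )
    cnv_fractions = pd.DataFrame(cnv_rows)

    # transplantation phenotype contingency per KO strain vs WT
    transplant_rows = []
    for ko in ("DNGR1KO", "RAG1KO"):
        if ko not in present or "WT" not in present:
            continue
        k_reg = sum(
            1 for s, g in genotypes.items() if g == ko and phenotypes.get(s) == "regressor"
        )
        k_n = sum(1 for g in genotypes.values() if g == ko)
        w_reg = sum(
            1 for s, g in genotypes.items() if g == "WT" and phenotypes.get(s) == "regressor"
        )
        w_n = sum(1 for g in genotypes.values() if g == "WT")
        if min(k_n, w_n) == 0 or k_n == k_reg == 0:
            continue
        res = contingency_2x2(k_reg, k_n - k_reg, w_reg, w_n - w_reg)
        transplant_rows.append(
            {
                "comparison": f"{ko}_vs_WT",
                "regressors_1": k_reg,
                "n_1": k_n,
                "pct_1": percent(k_reg, k_n),
                "regressors_2": w_reg,
                "n_2": w_n,
                "pct_2": percent(w_reg, w_n),
                "odds_ratio": round(res.odds_ratio, 4),
                "ci_low": round(res.ci_low, 4),
                "ci_high": round(res.ci_high, 4),
                "chi2": round(res.chi2, 4),
                "p_one_tailed": res.p_one_tailed,
            }
        )
    transplantation = pd.DataFrame(transplant_rows)

    power_grid = pd.DataFrame(power_table(burdens=(3500, 4000, 4500, 5000), n_values=range(1, 9)))

    growth = None
    if growth_table is not None:
        growth_rows = []
        for sample_id, sub in growth_table.groupby("sample"):
            vols = [tumor_volume(r.length_mm, r.width_mm) for r in sub.itertuples(index=False)]
            fit = fit_malthusian(sub["day"].to_numpy(), vols)
            growth_rows.append(
                {
                    "sample_id": sample_id,
                    "rate_per_day": round(fit.rate_r, 4),
                    "classification": fit.classification,
                }
            )
        growth = pd.DataFrame(growth_rows)

    return CohortResults(
        burden_table=burden_table,
        geneset_contrasts=geneset_contrasts,
        cnv_fractions=cnv_fractions,
        myc_by_genotype=myc_by_genotype,
        myc_by_phenotype=myc_by_phenotype,
        myc_fisher=myc_fisher,
        transplantation=transplantation,
        power_grid=power_grid,
        clonality=pd.DataFrame(clonality_rows),
        growth=growth,
        warnings=notices,
    )


# ---------------------------------------------------------------------------
# file-backed runs


@dataclass
class RunConfig:
    cohort_tsv: str
    gene_fasta: str
    gene_table: str
    gene_sets: dict  # name -> path
    output_dir: str
    growth_tsv: str | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        th = Thresholds(**raw.pop("thresholds", {}))
        return cls(thresholds=th, **raw)


def validate_inputs(cfg: RunConfig) -> list[str]:
    """Collect input problems (empty list means a valid run)."""
    issues = []
    base = Path(cfg.cohort_tsv).parent
    for label, p in (
        ("cohort table", cfg.cohort_tsv),
        ("gene FASTA", cfg.gene_fasta),
        ("gene table", cfg.gene_table),
        *(("gene set " + n, p) for n, p in cfg.gene_sets.items()),
    ):
        if not Path(p).exists():
            issues.append(f"{label} missing: {p}")
    if issues:
        return issues
    try:
        models = load_gene_models(cfg.gene_fasta, cfg.gene_table)
    except ValueError as exc:
        return issues + [f"gene models invalid: {exc}"]
    for name, p in cfg.gene_sets.items():
        try:
            load_gene_set(p, models, name=name)
        except ValueError as exc:
            issues.append(f"gene set {name} invalid: {exc}")
    try:
        samples = load_cohort_table(cfg.cohort_tsv)
    except ValueError as exc:
        return issues + [f"cohort table invalid: {exc}"]
    for s in samples:
        for label, p in (("VCF", s.vcf_path), ("SEG", s.seg_path)):
            if p and not (base / p).exists() and not Path(p).exists():
                issues.append(f"sample {s.sample_id}: {label} missing: {p}")
    return issues


def _resolve(base: Path, p: str) -> Path:
    q = Path(p)
    return q if q.is_absolute() or q.exists() else base / p


def run_pipeline(cfg: RunConfig) -> CohortResults:
    """Load a cohort from disk, analyze it, and write the report bundle."""
    issues = validate_inputs(cfg)
    if issues:
        raise ValueError("invalid inputs:\n" + "\n".join(issues))
    base = Path(cfg.cohort_tsv).parent
    models = load_gene_models(cfg.gene_fasta, cfg.gene_table)
    sets = {n: load_gene_set(p, models, name=n) for n, p in cfg.gene_sets.items()}
    samples = load_cohort_table(cfg.cohort_tsv)
    variants, genotypes, phenotypes, profiles = {}, {}, {}, []
    for s in samples:
        genotypes[s.sample_id] = s.host_genotype
        phenotypes[s.sample_id] = s.phenotype
        try:
            variants[s.sample_id] = read_somatic_vcf(
                _resolve(base, s.vcf_path), sample_id=s.sample_id
            )
            if s.seg_path:
                profiles.append(read_seg(_resolve(base, s.seg_path), sample_id=s.sample_id))
        except Exception as exc:
            raise RuntimeError(f"stage=load sample={s.sample_id}: {exc}") from exc
    growth = None
    if cfg.growth_tsv:
        growth = pd.read_csv(_resolve(base, cfg.growth_tsv), sep="\t")
    results = analyze_cohort(
        variants, genotypes, phenotypes, profiles, models, sets,
        thresholds=cfg.thresholds, growth_table=growth,
    )
    write_report(results, cfg)
    return results


def write_report(results: CohortResults, cfg: RunConfig) -> None:
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results.burden_table.to_csv(out / "burden.tsv", sep="\t", index=False)
    results.geneset_contrasts.to_csv(out / "geneset_contrasts.tsv", sep="\t", index=False)
    results.cnv_fractions.to_csv(out / "cnv_fractions.tsv", sep="\t", index=False)
    results.clonality.to_csv(out / "clonality.tsv", sep="\t", index=False)
    results.transplantation.to_csv(out / "transplantation.tsv", sep="\t", index=False)
    results.power_grid.to_csv(out / "power.tsv", sep="\t", index=False)
    if results.growth is not None:
        results.growth.to_csv(out / "growth_fits.tsv", sep="\t", index=False)
    summary = {
        "myc_by_genotype": {k: list(v) for k, v in results.myc_by_genotype.items()},
        "myc_by_phenotype": {k: list(v) for k, v in results.myc_by_phenotype.items()},
        "myc_fisher_p": None
        if results.myc_fisher is None
        else results.myc_fisher.p_fisher,
        "warnings": results.warnings,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    cfg_dict = asdict(cfg)
    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
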
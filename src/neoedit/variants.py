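"""Somatic variant ingestion, filtering and coding-consequence calling.

Variants come in as Strelka2-style somatic VCFs.  Each record is reduced
to per-ALT :class:`SomaticVariant` objects carrying allelic depths and
VAF; the burden filter keeps PASS calls with at least five alt-supporting
reads.  Consequences are called directly against :class:`GeneModel`
coordinates: SNVs by codon substitution, indels by frame arithmetic, with
a full mutant-CDS rebuild available for frameshift peptide work and for
oracle checks.
"""

from __future__ import annotations

from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass
from itertools import product

import pysam
from Bio.Seq import Seq

from .genemodel import GeneModel, reverse_complement

# codon -> amino acid lookup (standard table), kept as a dict for speed
_CODON_AA = {
    "".join(c): str(Seq("".join(c)).translate()) for c in product("ACGT", repeat=3)
}

CONSEQUENCES = (
    "synonymous",
    "missense",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frameshift_variant",
    "inframe_indel",
    "noncoding",
)
TRUNCATING = {"stop_gained", "stop_lost", "start_lost", "frameshift_variant"}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class SomaticVariant:
    """One somatic mutation (one ALT allele) with depths and annotation."""

    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    filter_status: str = "PASS"
    ad_ref: int = 0
    ad_alt: int = 0
    sample_id: str | None = None
    gene_id: str | None = None
    consequence: str | None = None
    protein_change: tuple | None = None

    @property
    def vaf(self) -> float:
        depth = self.ad_ref + self.ad_alt
        return self.ad_alt / depth if depth > 0 else 0.0

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    @property
    def variant_id(self) -> str:
        return f"{self.chrom}:{self.pos + 1}:{self.ref}>{self.alt}"


@dataclass
class BurdenSummary:
    """Per-sample mutation counts by category.

    Categories are reported independently, not as a partition: frameshift
    indels count in both ``truncating`` and ``indels``.
    """

    sample_id: str
    total: int = 0
    missense: int = 0
    synonymous: int = 0
    truncating: int = 0
    indels: int = 0
    clonal_count: int = 0
    subclonal_count: int = 0


# ---------------------------------------------------------------------------
# VCF reading


def _strelka_tier1_ad(sample, ref: str, alt: str) -> tuple[int, int] | None:
    """Derive (ad_ref, ad_alt) from Strelka2 tier counts when AD is absent.

    SNVs carry AU/CU/GU/TU (tier1, tier2); indels carry TAR/TIR.  Tier-1
    counts are used.
    """
    if len(ref) == 1 and len(alt) == 1:
        keys = {b: f"{b}U" for b in "ACGT"}
        if ref in keys and alt in keys and keys[ref] in sample and keys[alt] in sample:
            r = sample[keys[ref]]
            a = sample[keys[alt]]
            if r is not None and a is not None:
                return int(r[0]), int(a[0])
    if "TAR" in sample and "TIR" in sample:
        tar, tir = sample["TAR"], sample["TIR"]
        if tar is not None and tir is not None:
            return int(tar[0]), int(tir[0])
    return None


def read_somatic_vcf(path, sample_id: str | None = None, tumor_sample: str | None = None) -> list[SomaticVariant]:
    """Read a somatic VCF into per-ALT :class:`SomaticVariant` records.

    Multi-allelic rows are split into one record per ALT.  Allelic depths
    come from the tumor sample's AD field, or from Strelka2 tier counts
    (AU/CU/GU/TU, TAR/TIR) when AD is absent.
    """
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"malformed VCF {path}: {exc}") from exc
    samples = list(vf.header.samples)
    if not samples:
        raise ValueError(f"VCF {path} has no sample columns")
    if tumor_sample is None:
        tumor_sample = "TUMOR" if "TUMOR" in samples else samples[-1]
    out: list[SomaticVariant] = []
    for rec in vf:
        filters = list(rec.filter.keys())
        status = "PASS" if filters == ["PASS"] or not filters else filters[0]
        sample = rec.samples[tumor_sample]
        ad = sample.get("AD")
        for i, alt in enumerate(rec.alts or ()):
            if ad is not None and ad[0] is not None:
                ad_ref, ad_alt = int(ad[0]), int(ad[i + 1])
            else:
                tier = _strelka_tier1_ad(sample, rec.ref, alt)
                if tier is None:
                    raise ValueError(
                        f"{path}: record {rec.chrom}:{rec.pos} lacks AD and tier counts"
                    )
                ad_ref, ad_alt = tier
            out.append(
                SomaticVariant(
                    chrom=rec.chrom,
                    pos=rec.pos - 1,  # VCF is 1-based
                    ref=rec.ref,
                    alt=alt,
                    filter_status=status,
                    ad_ref=ad_ref,
                    ad_alt=ad_alt,
                    sample_id=sample_id,
                )
            )
    vf.close()
    return out


def filter_variants(
    variants: list[SomaticVariant], min_alt_reads: int = 5, require_pass: bool = True
) -> list[SomaticVariant]:
    """Keep PASS variants with at least ``min_alt_reads`` alt-supporting reads.

    Order-preserving and idempotent.
    """
    return [
        v
        for v in variants
        if v.ad_alt >= min_alt_reads and (not require_pass or v.filter_status == "PASS")
    ]


# ---------------------------------------------------------------------------
# consequence calling


class GenomeIndex:
    """Chromosome-bucketed interval lookup from genomic position to genes."""

    def __init__(self, gene_models: list[GeneModel]):
        self.by_id = {g.gene_id: g for g in gene_models}
        buckets: dict[str, list[tuple[int, int, GeneModel]]] = defaultdict(list)
        for g in gene_models:
            s, e = g.span
            buckets[g.chrom].append((s, e, g))
        self._starts: dict[str, list[int]] = {}
        self._genes: dict[str, list[tuple[int, int, GeneModel]]] = {}
        for chrom, items in buckets.items():
            items.sort(key=lambda t: t[0])
            self._genes[chrom] = items
            self._starts[chrom] = [s for s, _, _ in items]

    def overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        items = self._genes.get(chrom)
        if not items:
            return []
        out = []
        # genes are short relative to chromosomes; scan left from the insertion point
        i = bisect_right(self._starts[chrom], end)
        for s, e, g in items[:i]:
            if e > start:
                out.append(g)
        return out


def _affected_positions(variant: SomaticVariant) -> tuple[int, int, str]:
    """Return (start, end, kind) of the genomic bases a variant touches.

    SNV/MNV: the substituted bases.  Deletion: the deleted bases after the
    anchor.  Insertion: the anchor base (insertion occurs after it).
    """
    if len(variant.ref) == len(variant.alt):
        return variant.pos, variant.pos + len(variant.ref), "snv"
    if len(variant.ref) > len(variant.alt):
        return variant.pos + 1, variant.pos + len(variant.ref), "del"
    return variant.pos, variant.pos + 1, "ins"


def build_mutant_cds(gene: GeneModel, variant: SomaticVariant) -> str:
    """Apply a variant to the gene's spliced CDS; return the mutant CDS in
    reading order.

    The variant's edited bases must fall inside the CDS and map to
    contiguous spliced offsets (no exon-boundary-crossing edits).
    """
    fwd = gene.forward_cds
    start, end, kind = _affected_positions(variant)
    if kind == "snv":
        offs = [gene.genomic_to_spliced(p) for p in range(start, end)]
        if any(o is None for o in offs):
            raise ValueError(f"{variant.variant_id}: substitution crosses CDS boundary")
        chars = list(fwd)
        for o, ref_b, alt_b in zip(offs, variant.ref, variant.alt):
            if chars[o] != ref_b:
                raise ValueError(
                    f"{variant.variant_id}: ref allele mismatch with gene {gene.gene_id}"
                )
            chars[o] = alt_b
        mutant_fwd = "".join(chars)
    elif kind == "del":
        offs = [gene.genomic_to_spliced(p) for p in range(start, end)]
        if any(o is None for o in offs):
            raise ValueError(f"{variant.variant_id}: deletion crosses CDS boundary")
        offs_sorted = sorted(offs)
        if offs_sorted != list(range(offs_sorted[0], offs_sorted[-1] + 1)):
            raise ValueError(f"{variant.variant_id}: deletion not contiguous in CDS")
        deleted = "".join(fwd[o] for o in offs)
        if deleted != variant.ref[1:]:
            raise ValueError(
                f"{variant.variant_id}: ref allele mismatch with gene {gene.gene_id}"
            )
        keep = set(offs)
        mutant_fwd = "".join(c for i, c in enumerate(fwd) if i not in keep)
    else:  # insertion after the anchor base
        anchor = gene.genomic_to_spliced(variant.pos)
        if anchor is None:
            raise ValueError(f"{variant.variant_id}: insertion anchor outside CDS")
        if fwd[anchor] != variant.ref[0]:
            raise ValueError(
                f"{variant.variant_id}: ref allele mismatch with gene {gene.gene_id}"
            )
        inserted = variant.alt[1:]
        mutant_fwd = fwd[: anchor + 1] + inserted + fwd[anchor + 1 :]
    return mutant_fwd if gene.strand == "+" else reverse_complement(mutant_fwd)


def translate_until_stop(reading_seq: str) -> str:
    """Translate codons from the start until the first stop (exclusive)."""
    out = []
    for i in range(0, len(reading_seq) - 2, 3):
        aa = _CODON_AA[reading_seq[i : i + 3]]
        if aa == "*":
            break
        out.append(aa)
    return "".join(out)


def classify_consequence(
    variant: SomaticVariant, gene: GeneModel
) -> tuple[str, tuple | None]:
    """Call the coding consequence of a variant on one gene.

    SNVs are classified by wildtype-versus-mutant codon translation;
    indels by the frame of the net CDS length change.  Returns
    ``(consequence, protein_change)`` where protein_change is
    ``(position_1based, wt_aa, mut_aa)`` for substitution classes and
    ``(anchor_position_1based,)`` for indels.
    """
    start, end, kind = _affected_positions(variant)
    if kind == "snv":
        if len(variant.ref) > 1:
            # multi-nucleotide substitutions arrive pre-split by the caller;
            # classify a phased MNV by full rebuild
            return _classify_mnv(variant, gene)
        off = gene.genomic_to_spliced(variant.pos)
        if off is None:
            return "noncoding", None
        fwd = gene.forward_cds
        if fwd[off] != variant.ref:
            raise ValueError(
                f"{variant.variant_id}: ref allele mismatch with gene {gene.gene_id}"
            )
        r_off = gene.spliced_to_reading(off)
        codon_i = r_off // 3
        within = r_off % 3
        wt_codon = gene.cds_seq[3 * codon_i : 3 * codon_i + 3]
        mut_base = (
            variant.alt if gene.strand == "+" else variant.alt.translate(_COMPLEMENT)
        )
        mut_codon = wt_codon[:within] + mut_base + wt_codon[within + 1 :]
        wt_aa = _CODON_AA[wt_codon]
        mut_aa = _CODON_AA[mut_codon]
        if wt_aa == mut_aa:
            return "synonymous", (codon_i + 1, wt_aa, mut_aa)
        if codon_i == 0:
            return "start_lost", (1, wt_aa, mut_aa)
        if wt_aa == "*":
            return "stop_lost", (codon_i + 1, wt_aa, mut_aa)
        if mut_aa == "*":
            return "stop_gained", (codon_i + 1, wt_aa, mut_aa)
        return "missense", (codon_i + 1, wt_aa, mut_aa)
    # indel
    offs = [gene.genomic_to_spliced(p) for p in range(start, end)]
    in_cds = [o for o in offs if o is not None]
    if not in_cds:
        return "noncoding", None
    if kind == "del":
        net = -len(in_cds)
        anchor_off = min(in_cds)
    else:
        net = len(variant.alt) - len(variant.ref)
        anchor_off = in_cds[0]
    r_off = gene.spliced_to_reading(anchor_off)
    anchor_aa = r_off // 3 + 1
    if net % 3 != 0:
        return "frameshift_variant", (anchor_aa,)
    return "inframe_indel", (anchor_aa,)


def _classify_mnv(variant: SomaticVariant, gene: GeneModel) -> tuple[str, tuple | None]:
    offs = [gene.genomic_to_spliced(p) for p in range(variant.pos, variant.pos + len(variant.ref))]
    if all(o is None for o in offs):
        return "noncoding", None
    mutant = translate_until_stop(build_mutant_cds(gene, variant))
    wt = gene.protein_seq
    if mutant == wt:
        return "synonymous", None
    diffs = [i for i, (a, b) in enumerate(zip(wt, mutant)) if a != b]
    if len(mutant) < len(wt) and not diffs:
        return "stop_gained", (len(mutant) + 1, "*", "*")
    i = diffs[0] if diffs else 0
    return "missense", (i + 1, wt[i], mutant[i])


def annotate_variants(
    variants: list[SomaticVariant], index: GenomeIndex
) -> list[SomaticVariant]:
    """Attach gene and consequence annotation.

    A variant overlapping several genes yields one annotated record per
    gene; a variant outside every gene yields one ``noncoding`` record.
    """
    from dataclasses import replace

    out: list[SomaticVariant] = []
    for v in variants:
        start, end, _ = _affected_positions(v)
        genes = index.overlapping(v.chrom, start, end)
        hit = False
        for g in genes:
            csq, change = classify_consequence(v, g)
            if csq == "noncoding":
                continue
            out.append(replace(v, gene_id=g.gene_id, consequence=csq, protein_change=change))
            hit = True
        if not hit:
            out.append(replace(v, gene_id=None, consequence="noncoding", protein_change=None))
    return out


def summarize_burden(
    variants: list[SomaticVariant], sample_id: str = "", clonal_flags=None
) -> BurdenSummary:
    """Count mutation-burden categories over (filtered, annotated) variants.

    Counts are per distinct variant, not per gene annotation: a variant
    annotated against two genes contributes once, with its most severe
    consequence.
    """
    severity_order = (
        "frameshift_variant",
        "stop_gained",
        "stop_lost",
        "start_lost",
        "missense",
        "inframe_indel",
        "synonymous",
        "noncoding",
    )
    severity = {c: i for i, c in enumerate(severity_order)}
    best: dict[str, SomaticVariant] = {}
    for v in variants:
        cur = best.get(v.variant_id)
        rank = severity.get(v.consequence or "noncoding", len(severity))
        if cur is None or rank < severity.get(cur.consequence or "noncoding", len(severity)):
            best[v.variant_id] = v
    s = BurdenSummary(sample_id=sample_id)
    for v in best.values():
        s.total += 1
        if v.consequence == "missense":
            s.missense += 1
        elif v.consequence == "synonymous":
            s.synonymous += 1
        if v.consequence in TRUNCATING:
            s.truncating += 1
        if v.is_indel:
            s.indels += 1
    if clonal_flags is not None:
        s.clonal_count = int(sum(bool(f) for f in clonal_flags))
        s.subclonal_count = int(len(clonal_flags) - s.clonal_count)
    return s
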
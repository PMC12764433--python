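"""Mutant peptide enumeration and MHC class I binding calls.

For each missense variant, every 8-10mer of the mutant protein that
contains the substituted residue is paired with its wildtype window.  For
frameshifts, the mutant CDS is rebuilt and translated in the new frame to
the first stop, and every 8-10mer containing at least one novel residue
is emitted (no wildtype pair exists).  Peptides are scored for H-2Kb and
H-2Db through a pluggable predictor; candidates are kept below 500 nM and
called *strong* below 150 nM, and per-sample burdens count variants (a
variant with several strong peptides counts once).

The bundled predictor is a deterministic motif surrogate, not a
reimplementation of any external tool: it rewards the canonical C57BL/6
anchor preferences (position-5 F/Y for H-2Kb, N for H-2Db; C-terminal
L/M/I/V for both), so only doubly anchored peptides reach 50 nM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable

from .genemodel import GeneModel
from .variants import SomaticVariant, build_mutant_cds, translate_until_stop

ALLELES = ("H2-Kb", "H2-Db")
PEPTIDE_LENGTHS = (8, 9, 10)
IC50_STRONG_NM = 150.0
IC50_CANDIDATE_NM = 500.0

_ANCHOR_MOTIF = {"H2-Kb": frozenset("FY"), "H2-Db": frozenset("N")}
_CTERM_MOTIF = frozenset("LMIV")
_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")

Predictor = Callable[[str, str], float]


@dataclass
class PeptideCandidate:
    sequence: str
    paired_wildtype: str | None
    gene_id: str
    source_variant: str
    allele: str
    ic50_nm: float
    is_strong: bool
    sample_id: str | None = None


def surrogate_ic50(peptide: str, allele: str) -> float:
    """Deterministic motif-anchor IC50 surrogate, in nM.

    Score s = (a + c) / 2 with a = 1 if the position-5 residue matches the
    allele's anchor motif (F/Y for H-2Kb, N for H-2Db) and c = 1 if the
    C-terminal residue is one of L/M/I/V; ic50 = 50000 x 10^(-3 s).  Only
    s = 1 peptides (50 nM) fall under the 150 nM strong threshold.
    """
    if allele not in _ANCHOR_MOTIF:
        raise ValueError(f"unknown allele {allele!r}")
    if not 8 <= len(peptide) <= 10:
        raise ValueError(f"peptide length {len(peptide)} outside 8-10")
    bad = set(peptide) - _AA
    if bad:
        raise ValueError(f"invalid residue letters {sorted(bad)} in {peptide!r}")
    a = 1.0 if peptide[4] in _ANCHOR_MOTIF[allele] else 0.0
    c = 1.0 if peptide[-1] in _CTERM_MOTIF else 0.0
    s = (a + c) / 2.0
    return 50000.0 * 10.0 ** (-3.0 * s)


def enumerate_missense_peptides(
    protein_seq: str,
    mut_pos: int,
    mut_aa: str,
    lengths: Iterable[int] = PEPTIDE_LENGTHS,
) -> list[tuple[str, str]]:
    """All (mutant, wildtype) window pairs covering a missense position.

    ``mut_pos`` is 1-based.  For each length L, every L-window of the
    mutant protein containing the substituted residue is returned with
    the corresponding wildtype window.
    """
    n = len(protein_seq)
    if not 1 <= mut_pos <= n:
        raise ValueError(f"mut_pos {mut_pos} outside protein of length {n}")
    i = mut_pos - 1
    if protein_seq[i] == mut_aa:
        raise ValueError("mutant residue equals wildtype residue")
    mutant = protein_seq[:i] + mut_aa + protein_seq[i + 1 :]
    seen: dict[tuple[int, int], tuple[str, str]] = {}
    for L in sorted(set(lengths)):
        for s in range(max(0, i - L + 1), min(i, n - L) + 1):
            seen[(s, L)] = (mutant[s : s + L], protein_seq[s : s + L])
    return list(seen.values())


def enumerate_frameshift_peptides(
    gene: GeneModel,
    variant: SomaticVariant,
    lengths: Iterable[int] = PEPTIDE_LENGTHS,
) -> list[str]:
    """All 8-10mers of the frameshifted protein containing novel residues.

    The mutant CDS is rebuilt and translated from the start codon in the
    shifted frame until the first stop.  The novel region begins at the
    first residue where the mutant protein diverges from wildtype; every
    window overlapping it is emitted.  A frameshift that stops before
    producing any novel residue yields an empty list with a warning.
    """
    mutant = translate_until_stop(build_mutant_cds(gene, variant))
    wt = gene.protein_seq
    novel_start = None
    for j, aa in enumerate(mutant):
        if j >= len(wt) or wt[j] != aa:
            novel_start = j
            break
    if novel_start is None:
        # immediate stop in the shifted frame; message kept constant so the
        # warning filter deduplicates it across variants
        warnings.warn("frameshift produced no novel residues (immediate stop)")
        return []
    out: list[str] = []
    n = len(mutant)
    for L in sorted(set(lengths)):
        first = max(0, novel_start - L + 1)
        for s in range(first, n - L + 1):
            out.append(mutant[s : s + L])
    return out


def peptides_for_variant(
    variant: SomaticVariant, gene: GeneModel, lengths: Iterable[int] = PEPTIDE_LENGTHS
) -> list[tuple[str, str | None]]:
    """Mutant peptides (with wildtype pair where one exists) for a variant.

    Missense and frameshift variants produce peptides; other classes
    produce none.
    """
    if variant.consequence == "missense":
        pos, _, mut_aa = variant.protein_change
        pairs = enumerate_missense_peptides(gene.protein_seq, pos, mut_aa, lengths)
        return [(m, w) for m, w in pairs]
    if variant.consequence == "frameshift_variant":
        return [(p, None) for p in enumerate_frameshift_peptides(gene, variant, lengths)]
    return []


def variant_is_strong(
    variant: SomaticVariant,
    gene: GeneModel,
    predictor: Predictor = surrogate_ic50,
    ic50_strong_max: float = IC50_STRONG_NM,
) -> bool:
    """Whether any peptide from this variant is strong on either allele."""
    for pep, _ in peptides_for_variant(variant, gene):
        for allele in ALLELES:
            if predictor(pep, allele) < ic50_strong_max:
                return True
    return False


def call_neoantigens(
    variants: list[SomaticVariant],
    gene_index,
    predictor: Predictor = surrogate_ic50,
    ic50_candidate_max: float = IC50_CANDIDATE_NM,
    ic50_strong_max: float = IC50_STRONG_NM,
    min_vaf: float = 0.2,
    expressed_genes: set[str] | None = None,
) -> list[PeptideCandidate]:
    """Score peptides for already-filtered, annotated variants.

    Variants with VAF below ``min_vaf`` are skipped (tumor-DNA VAF gate).
    Candidates are peptides under ``ic50_candidate_max`` on either allele;
    ``is_strong`` marks those under ``ic50_strong_max``.  If
    ``expressed_genes`` is given, candidates are restricted to those genes
    (off by default).
    """
    out: list[PeptideCandidate] = []
    for v in variants:
        if v.vaf < min_vaf or v.gene_id is None:
            continue
        if expressed_genes is not None and v.gene_id not in expressed_genes:
            continue
        gene = gene_index.by_id[v.gene_id]
        for pep, wt in peptides_for_variant(v, gene):
            for allele in ALLELES:
                try:
                    ic50 = float(predictor(pep, allele))
                except Exception as exc:
                    raise RuntimeError(
                        f"predictor failed on peptide {pep!r} ({allele}): {exc}"
                    ) from exc
                if ic50 < ic50_candidate_max:
                    out.append(
                        PeptideCandidate(
                            sequence=pep,
                            paired_wildtype=wt,
                            gene_id=v.gene_id,
                            source_variant=v.variant_id,
                            allele=allele,
                            ic50_nm=ic50,
                            is_strong=ic50 < ic50_strong_max,
                            sample_id=v.sample_id,
                        )
                    )
    return out


def strong_variant_ids(candidates: list[PeptideCandidate]) -> set[str]:
    """Distinct source variants with at least one strong peptide."""
    return {c.source_variant for c in candidates if c.is_strong}


def strong_variant_genes(candidates: list[PeptideCandidate]) -> dict[str, str]:
    """Map strong source variant id -> gene id."""
    return {c.source_variant: c.gene_id for c in candidates if c.is_strong}
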
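"""Gene models, gene sets, cohort metadata and expression tables.

All genomic coordinates are 0-based, half-open internally.  Converters to
and from the 1-based conventions of VCF live at the file boundaries, never
inside the analysis code.

A :class:`GeneModel` holds a gene's spliced coding sequence in *reading
order* (reverse-complemented for minus-strand genes), together with the
genomic CDS intervals that anchor it to the reference.  The coding
sequence includes the terminal stop codon; the stored protein does not.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

HOST_GENOTYPES = ("WT", "DNGR1KO", "RAG1KO")
PHENOTYPES = ("progressor", "regressor", "unknown")

_STOPS = {"TAA", "TAG", "TGA"}


def translate_cds(cds_seq: str, gene_id: str = "?") -> str:
    """Translate a coding sequence, validating frame and stop placement.

    The sequence must be a multiple of 3, contain no internal stop codon,
    and may optionally end with a stop codon (which is stripped from the
    returned protein).
    """
    if len(cds_seq) % 3 != 0:
        raise ValueError(
            f"CDS length {len(cds_seq)} of gene {gene_id} is not a multiple of 3"
        )
    protein = str(Seq(cds_seq).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError(f"internal stop codon in CDS of gene {gene_id}")
    return protein


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass
class GeneModel:
    """A single gene's coding model.

    ``cds_intervals`` are sorted, non-overlapping genomic intervals
    (0-based, half-open).  ``cds_seq`` is the spliced CDS in reading order
    (already reverse-complemented for minus-strand genes) and includes the
    terminal stop codon.
    """

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]
    cds_seq: str
    protein_seq: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")
        ivs = tuple(tuple(iv) for iv in self.cds_intervals)
        if any(e <= s for s, e in ivs):
            raise ValueError(f"gene {self.gene_id}: empty or inverted CDS interval")
        if list(ivs) != sorted(ivs):
            raise ValueError(f"gene {self.gene_id}: CDS intervals not sorted")
        for (_, e0), (s1, _) in zip(ivs, ivs[1:]):
            if s1 < e0:
                raise ValueError(f"gene {self.gene_id}: overlapping CDS intervals")
        if sum(e - s for s, e in ivs) != len(self.cds_seq):
            raise ValueError(
                f"gene {self.gene_id}: CDS interval span does not match sequence length"
            )
        self.cds_intervals = ivs
        derived = translate_cds(self.cds_seq, self.gene_id)
        if self.protein_seq:
            if self.protein_seq != derived:
                raise ValueError(f"gene {self.gene_id}: protein does not match CDS")
        else:
            self.protein_seq = derived
        # forward-strand spliced CDS, used for genomic-coordinate arithmetic
        self._forward = (
            self.cds_seq if self.strand == "+" else reverse_complement(self.cds_seq)
        )

    # -- coordinate arithmetic -------------------------------------------

    @property
    def cds_length(self) -> int:
        return len(self.cds_seq)

    @property
    def forward_cds(self) -> str:
        """Spliced CDS on the forward genomic strand (5'->3' of the reference)."""
        return self._forward

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    def genomic_to_spliced(self, pos: int) -> int | None:
        """Map a genomic position to its offset in ``forward_cds``.

        Returns None for positions outside the CDS (introns, flanks).
        """
        off = 0
        for s, e in self.cds_intervals:
            if s <= pos < e:
                return off + (pos - s)
            off += e - s
        return None

    def spliced_to_genomic(self, off: int) -> int:
        if not 0 <= off < self.cds_length:
            raise IndexError(f"spliced offset {off} outside CDS of {self.gene_id}")
        for s, e in self.cds_intervals:
            if off < e - s:
                return s + off
            off -= e - s
        raise AssertionError("unreachable")

    def spliced_to_reading(self, off: int) -> int:
        """Convert a forward-spliced offset to a reading-order offset."""
        return off if self.strand == "+" else self.cds_length - 1 - off


@dataclass
class GeneSet:
    """A named gene set (e.g. FABP, MBP) with its aggregate CDS footprint."""

    name: str
    member_gene_ids: frozenset[str]
    total_cds_length: int

    def __len__(self) -> int:
        return len(self.member_gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.member_gene_ids


@dataclass
class CohortSample:
    sample_id: str
    host_genotype: str
    phenotype: str = "unknown"
    vcf_path: str | None = None
    seg_path: str | None = None

    def __post_init__(self) -> None:
        if self.host_genotype not in HOST_GENOTYPES:
            raise ValueError(
                f"sample {self.sample_id}: unknown host genotype {self.host_genotype!r}"
            )
        if self.phenotype not in PHENOTYPES:
            raise ValueError(
                f"sample {self.sample_id}: unknown phenotype {self.phenotype!r}"
            )


# ---------------------------------------------------------------------------
# loaders / writers


def _parse_intervals(text: str) -> tuple[tuple[int, int], ...]:
    out = []
    for chunk in str(text).split(";"):
        s, e = chunk.split("-")
        out.append((int(s), int(e)))
    return tuple(out)


def _format_intervals(ivs) -> str:
    return ";".join(f"{s}-{e}" for s, e in ivs)


def load_gene_models(path_fasta, path_table) -> list[GeneModel]:
    """Load gene models from a CDS FASTA plus a gene table TSV.

    The table carries gene_id, gene_name, chrom, strand and the genomic
    CDS intervals as "start-end;start-end" (0-based, half-open).  FASTA
    records are keyed by gene_id and hold the reading-order CDS.
    """
    with open(path_fasta) as fh:
        seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}
    table = pd.read_csv(path_table, sep="\t", dtype=str)
    required = {"gene_id", "gene_name", "chrom", "strand", "cds_intervals"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    models = []
    for row in table.itertuples(index=False):
        if row.gene_id not in seqs:
            raise ValueError(f"gene {row.gene_id} has no FASTA sequence")
        models.append(
            GeneModel(
                gene_id=row.gene_id,
                gene_name=row.gene_name,
                chrom=row.chrom,
                strand=row.strand,
                cds_intervals=_parse_intervals(row.cds_intervals),
                cds_seq=seqs[row.gene_id],
            )
        )
    return models


def write_gene_models(models: list[GeneModel], path_fasta, path_table) -> None:
    with open(path_fasta, "w") as fh:
        for g in models:
            fh.write(f">{g.gene_id}\n")
            for i in range(0, len(g.cds_seq), 60):
                fh.write(g.cds_seq[i : i + 60] + "\n")
    rows = [
        {
            "gene_id": g.gene_id,
            "gene_name": g.gene_name,
            "chrom": g.chrom,
            "strand": g.strand,
            "cds_intervals": _format_intervals(g.cds_intervals),
        }
        for g in models
    ]
    pd.DataFrame(rows).to_csv(path_table, sep="\t", index=False)


def load_gene_set(path_tsv, gene_models: list[GeneModel], name: str | None = None) -> GeneSet:
    """Load a one-id-per-line gene set and resolve it against gene models."""
    by_id = {g.gene_id: g for g in gene_models}
    ids: list[str] = []
    with open(path_tsv) as fh:
        for line in fh:
            token = line.strip()
            if token and not token.startswith("#"):
                ids.append(token)
    unknown = sorted(set(ids) - set(by_id))
    if unknown:
        raise ValueError(f"gene set references unknown genes: {unknown}")
    if len(set(ids)) < len(ids):
        warnings.warn(f"duplicate gene ids in {path_tsv}; deduplicating")
    members = frozenset(ids)
    total = sum(by_id[i].cds_length for i in members)
    return GeneSet(
        name=name or Path(path_tsv).stem, member_gene_ids=members, total_cds_length=total
    )


def write_gene_set(gene_set: GeneSet, path_tsv) -> None:
    with open(path_tsv, "w") as fh:
        for gid in sorted(gene_set.member_gene_ids):
            fh.write(gid + "\n")


def load_cohort_table(path_tsv) -> list[CohortSample]:
    table = pd.read_csv(path_tsv, sep="\t", dtype=str)
    required = {"sample_id", "host_genotype", "phenotype", "vcf", "seg"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if table["sample_id"].duplicated().any():
        dups = table.loc[table["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids in cohort table: {dups}")
    return [
        CohortSample(
            sample_id=r.sample_id,
            host_genotype=r.host_genotype,
            phenotype=r.phenotype,
            vcf_path=r.vcf,
            seg_path=r.seg,
        )
        for r in table.itertuples(index=False)
    ]


def load_expression_matrix(path_tsv) -> pd.DataFrame:
    """Load a genes x samples fragments-per-million matrix."""
    mat = pd.read_csv(path_tsv, sep="\t", index_col=0)
    if mat.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if (mat.to_numpy() < 0).any():
        raise ValueError("expression matrix contains negative values")
    return mat


def common_expressed_genes(expr: pd.DataFrame) -> set[str]:
    """Genes with fragments-per-million strictly above zero in every sample."""
    if expr.empty:
        raise ValueError("expression matrix is empty")
    mask = (expr > 0).all(axis=1)
    return set(expr.index[mask])
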
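import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neoedit.genemodel import GeneModel
from neoedit.neoantigen import (
    call_neoantigens,
    enumerate_frameshift_peptides,
    enumerate_missense_peptides,
    peptides_for_variant,
    surrogate_ic50,
)
from neoedit.variants import GenomeIndex, SomaticVariant, annotate_variants, translate_until_stop, build_mutant_cds

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestSurrogatePredictor:
    def test_doubly_anchored_reference_ligand(self):
        assert surrogate_ic50("SIINFEKL", "H2-Kb") == pytest.approx(50.0)

    def test_single_anchor_is_not_strong(self):
        assert surrogate_ic50("SIINFEKA", "H2-Kb") == pytest.approx(1581.14, abs=0.01)

    def test_no_anchor(self):
        assert surrogate_ic50("AAAAAAAA", "H2-Kb") == pytest.approx(50000.0)

    def test_db_anchor_is_asparagine(self):
        assert surrogate_ic50("SIINFEKL", "H2-Db") == pytest.approx(1581.14, abs=0.01)
        assert surrogate_ic50("SIINFEKL"[:4] + "N" + "FEKL", "H2-Db") == pytest.approx(50.0)

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="invalid residue"):
            surrogate_ic50("SIINFEKX", "H2-Kb")

    @given(
        prefix=st.text(alphabet=AA, min_size=4, max_size=4),
        middle=st.text(alphabet=AA, min_size=2, max_size=4),
    )
    @settings(max_examples=60, deadline=None)
    def test_strength_depends_only_on_anchor_positions(self, prefix, middle):
        pep = prefix + "F" + middle + "L"
        assert surrogate_ic50(pep, "H2-Kb") == pytest.approx(50.0)


class TestMissenseEnumeration:
    def test_interior_mutation_yields_27_windows(self):
        protein = "".join("ACDEFGHIKLMNPQRSTVWY"[i % 20] for i in range(30))
        pairs = enumerate_missense_peptides(protein, 15, "W")
        assert len(pairs) == 27
        for mutant, wildtype in pairs:
            diffs = [i for i, (a, b) in enumerate(zip(mutant, wildtype)) if a != b]
            assert len(diffs) == 1 and mutant[diffs[0]] == "W"

    def test_terminal_mutation_one_window_per_length(self):
        protein = "M" + "A" * 25
        assert len(enumerate_missense_peptides(protein, 1, "T")) == 3

    def test_short_protein_yields_nothing(self):
        assert enumerate_missense_peptides("MAAAAAA", 3, "T") == []

    def test_out_of_range_position_rejected(self):
        with pytest.raises(ValueError, match="outside protein"):
            enumerate_missense_peptides("MAAA" * 5, 40, "T")

    def test_counts_match_brute_force(self, rng):
        """Window counts equal exhaustive enumeration over random cases."""
        for _ in range(300):
            n = int(rng.integers(5, 60))
            protein = "".join(AA[i] for i in rng.integers(0, 20, n))
            pos = int(rng.integers(1, n + 1))
            mut = AA[(AA.index(protein[pos - 1]) + 1) % 20]
            expected = sum(
                1
                for L in (8, 9, 10)
                for s in range(0, n - L + 1)
                if s <= pos - 1 < s + L
            )
            assert len(enumerate_missense_peptides(protein, pos, mut)) == expected


def make_gene(n_codons=40, seed=0):
    rng = np.random.default_rng(seed)
    codons = [
        c
        for c in ("".join(t) for t in __import__("itertools").product("ACGT", repeat=3))
        if c not in ("TAA", "TAG", "TGA")
    ]
    cds = "ATG" + "".join(codons[i] for i in rng.integers(0, len(codons), n_codons - 2)) + "TAA"
    return GeneModel("G1", "g", "chr1", "+", ((0, len(cds)),), cds)


class TestFrameshiftEnumeration:
    def brute_force(self, gene, variant):
        mutant = translate_until_stop(build_mutant_cds(gene, variant))
        wt = gene.protein_seq
        novel = next(
            (j for j, aa in enumerate(mutant) if j >= len(wt) or wt[j] != aa), None
        )
        if novel is None:
            return []
        return [
            mutant[s : s + L]
            for L in (8, 9, 10)
            for s in range(0, len(mutant) - L + 1)
            if s + L > novel
        ]

    def test_matches_brute_force_on_random_frameshifts(self, rng):
        import warnings as _warnings

        checked = 0
        for seed in range(60):
            gene = make_gene(n_codons=int(rng.integers(20, 60)), seed=seed)
            anchor = int(rng.integers(3, gene.cds_length - 6))
            if rng.random() < 0.5:
                ref = gene.cds_seq[anchor : anchor + 2]
                alt = ref[0]
            else:
                ref = gene.cds_seq[anchor]
                alt = ref + "".join("ACGT"[i] for i in rng.integers(0, 4, 1))
            v = SomaticVariant("chr1", anchor, ref, alt, consequence="frameshift_variant")
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                got = enumerate_frameshift_peptides(gene, v)
            assert sorted(got) == sorted(self.brute_force(gene, v))
            checked += 1
        assert checked == 60

    def test_immediate_stop_yields_empty_with_warning(self):
        # inserting T after the first lysine codon makes the shifted frame
        # read TAA immediately: mutant protein MK is a prefix of wildtype
        gene = GeneModel(
            "G1", "g", "chr1", "+", ((0, 36),),
            "ATG" + "AAA" * 10 + "TAA",
        )
        v = SomaticVariant("chr1", 5, "A", "AT", consequence="frameshift_variant")
        assert translate_until_stop(build_mutant_cds(gene, v)) == "MK"
        with pytest.warns(UserWarning, match="no novel residues"):
            assert enumerate_frameshift_peptides(gene, v) == []

    def test_peptides_are_substrings_of_mutant_protein(self, rng):
        gene = make_gene(n_codons=50, seed=99)
        v = SomaticVariant("chr1", 60, gene.cds_seq[60:62], gene.cds_seq[60], consequence="frameshift_variant")
        mutant = translate_until_stop(build_mutant_cds(gene, v))
        for pep in enumerate_frameshift_peptides(gene, v):
            assert pep in mutant


class TestCalling:
    def build_index_and_variant(self, vaf=0.5):
        cds = "ATG" + "GCT" * 40 + "TAA"
        gene = GeneModel("G1", "g", "chr1", "+", ((0, len(cds)),), cds)
        pos = 3 + 19 * 3 + 1  # second base of codon 20: GCT -> GTT (A -> V)
        depth = 100
        ad_alt = int(depth * vaf)
        v = SomaticVariant(
            "chr1", pos, "C", "T", ad_ref=depth - ad_alt, ad_alt=ad_alt, sample_id="s"
        )
        return GenomeIndex([gene]), v

    def test_low_vaf_variant_contributes_nothing(self):
        index, v = self.build_index_and_variant(vaf=0.19)
        ann = annotate_variants([v], index)
        assert call_neoantigens(ann, index) == []

    def test_per_variant_collapse_of_strong_count(self):
        # protein MAAAAAAAA L AA LL AAA...; L10F creates several doubly
        # anchored H2-Kb windows, but the variant-level strong count is one
        protein = list("M" + "A" * 29)
        protein[9] = protein[12] = protein[13] = "L"
        codon = {"M": "ATG", "A": "GCT", "L": "CTT"}
        cds = "".join(codon[aa] for aa in protein) + "TAA"
        gene = GeneModel("G1", "g", "chr1", "+", ((0, len(cds)),), cds)
        index = GenomeIndex([gene])
        v = SomaticVariant("chr1", 27, "C", "T", ad_ref=50, ad_alt=50, sample_id="s")
        ann = annotate_variants([v], index)
        assert ann[0].consequence == "missense" and ann[0].protein_change == (10, "L", "F")
        candidates = call_neoantigens(ann, index)
        strong = [c for c in candidates if c.is_strong]
        assert len(strong) >= 2  # several strong peptides from one variant
        assert len({c.source_variant for c in strong}) == 1

    def test_strong_threshold_monotonicity(self, mini_cohort):
        from neoedit.stats import geneset_burden

        sample = mini_cohort.samples[0]
        index = GenomeIndex(mini_cohort.gene_models)
        ann = annotate_variants(sample.variants, index)
        loose = call_neoantigens(ann, index, ic50_strong_max=150)
        tight = call_neoantigens(ann, index, ic50_strong_max=50)
        assert geneset_burden(tight) <= geneset_burden(loose)

    def test_failing_predictor_is_reported(self):
        index, v = self.build_index_and_variant(vaf=0.5)
        ann = annotate_variants([v], index)

        def broken(peptide, allele):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="predictor failed"):
            call_neoantigens(ann, index, predictor=broken)


def test_missense_peptides_differ_from_wildtype_only_at_mutation(small_genome, rng):
    models, _ = small_genome
    gene = models[0]
    protein = gene.protein_seq
    pos = len(protein) // 2
    wt_aa = protein[pos - 1]
    mut_aa = "W" if wt_aa != "W" else "Y"
    v = SomaticVariant(
        "chr1", 0, "A", "T", consequence="missense", protein_change=(pos, wt_aa, mut_aa)
    )
    for mutant, wildtype in peptides_for_variant(v, gene):
        assert mutant != wildtype
        assert sum(a != b for a, b in zip(mutant, wildtype)) == 1
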
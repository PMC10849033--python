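import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from docknet.io_formats import Atom, Chain, GeneModel, Residue, Structure, VariantRecord
from docknet.synthetic_data import gen_toy_genome, plant_codon_substitution
from docknet.variant_impact import (
    InterfaceResidueSet,
    annotate_substitution,
    classify_ddg,
    find_interface_residues,
    map_variants_to_interfaces,
    summarize_perturbation,
)
from oracles import mrna_diff_annotate


def make_plus_gene(codons, flank="ACGTACGTAC"):
    """Single-exon '+' gene: genome dict, gene model, CDS start offset."""
    cds = "".join(codons)
    chrom_seq = flank + cds + flank
    gene = GeneModel("g1", "chr1", "+", ((len(flank) + 1, len(flank) + len(cds)),))
    return {"chr1": chrom_seq}, gene, len(flank)


class TestAnnotate:
    def test_codon2_tat_to_tgt_is_tyr2cys(self):
        genome, gene, off = make_plus_gene(["ATG", "TAT", "GGT", "TAA"])
        v = VariantRecord("chr1", off + 5, "A", "G")  # middle base of codon 2
        res = annotate_substitution(genome, gene, v)
        assert res.kind == "nonsynonymous"
        assert res.substitution.label == "p.Tyr2Cys"

    def test_wobble_synonymous(self):
        genome, gene, off = make_plus_gene(["ATG", "GCT", "TAA"])
        v = VariantRecord("chr1", off + 6, "T", "C")  # GCT -> GCC, still Ala
        res = annotate_substitution(genome, gene, v)
        assert res.kind == "synonymous"
        assert res.substitution is None

    def test_minus_strand_hand_built(self):
        # mRNA ATG TAT TAA laid on the '-' strand; genomic = its revcomp
        mrna = "ATGTATTAA"
        from docknet.io_formats import reverse_complement

        genomic = reverse_complement(mrna)
        flank = "CCCCC"
        chrom_seq = flank + genomic + flank
        gene = GeneModel("g1", "chr1", "-", ((len(flank) + 1, len(flank) + 9),))
        genome = {"chr1": chrom_seq}
        # codon 2 TAT middle base A->G (mRNA) => genomic T->C on the template;
        # mRNA position 5 is genomic position flank + 9 - 5 + 1
        gpos = len(flank) + 9 - 5 + 1
        ref = chrom_seq[gpos - 1]
        assert ref == "T"
        v = VariantRecord("chr1", gpos, ref, "C")
        res = annotate_substitution(genome, gene, v)
        assert res.kind == "nonsynonymous"
        # oracle cross-check on the same instance
        kind, label = mrna_diff_annotate(genome, gene, v)
        assert (res.kind, res.substitution.label) == (kind, label) == (
            "nonsynonymous", "p.Tyr2Cys")

    def test_reference_mismatch_errors(self):
        genome, gene, off = make_plus_gene(["ATG", "TAT", "TAA"])
        with pytest.raises(ValueError, match="mismatch"):
            annotate_substitution(genome, gene,
                                  VariantRecord("chr1", off + 5, "C", "G"))

    def test_position_outside_gene_is_non_coding(self):
        genome, gene, off = make_plus_gene(["ATG", "TAT", "TAA"])
        v = VariantRecord("chr1", 1, "A", "G")
        assert annotate_substitution(genome, gene, v).kind == "non-coding"

    @pytest.mark.parametrize("strand_seed", [("+", 0), ("-", 1)])
    def test_agrees_with_mrna_diff_oracle(self, strand_seed):
        strand, seed = strand_seed
        genome, genes, variants, _ = gen_toy_genome(80, seed=seed)
        by_id = {g.gene_id: g for g in genes}
        checked = 0
        for v in variants:
            gene = by_id[f"gene{v.chrom[3:]}"]
            if gene.strand != strand:
                continue
            res = annotate_substitution(genome, gene, v)
            kind, label = mrna_diff_annotate(genome, gene, v)
            assert res.kind == kind
            if kind == "nonsynonymous":
                assert res.substitution.label == label
            checked += 1
        assert checked > 50


def two_chain(coords_a, coords_b):
    def chain(cid, coords):
        c = Chain(id=cid)
        for i, xyz in enumerate(coords, start=1):
            c.residues.append(Residue(i, "ALA", [Atom("CA", "C", *xyz)]))
        return c

    return Structure(id="cx", chains=[chain("A", coords_a), chain("B", coords_b)])


class TestInterface:
    def test_far_apart_chains_empty(self):
        s = two_chain([(0, 0, 0), (3, 0, 0)], [(100, 0, 0), (103, 0, 0)])
        iface = find_interface_residues(s)
        assert iface.interface == {"A": set(), "B": set()}

    def test_single_contact_pair(self):
        s = two_chain([(0, 0, 0), (0, 10, 0), (0, 20, 0)],
                      [(4.0, 0, 0), (12, 10, 0), (12, 20, 0)])
        iface = find_interface_residues(s, cutoff=5.5)
        assert iface.interface["A"] == {1}
        assert iface.interface["B"] == {1}

    def test_zero_cutoff_empty(self, half_sphere_complex):
        iface = find_interface_residues(half_sphere_complex, cutoff=0.0)
        assert iface.interface["A"] == set() and iface.interface["B"] == set()

    def test_needs_two_chains(self):
        s = two_chain([(0, 0, 0)], [(1, 0, 0)])
        s.chains.pop()
        with pytest.raises(ValueError, match="2 chains"):
            find_interface_residues(s)

    def test_monotone_in_cutoff(self, half_sphere_complex):
        sizes = []
        for cutoff in (2.0, 4.0, 5.5, 8.0):
            iface = find_interface_residues(half_sphere_complex, cutoff=cutoff)
            sizes.append((len(iface.interface["A"]), len(iface.interface["B"])))
        assert sizes == sorted(sizes)

    def test_hydrogens_ignored(self):
        s = two_chain([(0, 0, 0)], [(20, 0, 0)])
        # an H atom within range must not create an interface
        s.chains[1].residues[0].atoms.append(Atom("H", "H", 3.0, 0, 0))
        iface = find_interface_residues(s, cutoff=5.5)
        assert iface.interface == {"A": set(), "B": set()}


def sub(gene, pos, ref="Tyr", alt="Cys"):
    from docknet.variant_impact import ProteinSubstitution

    return ProteinSubstitution(gene_id=gene, position=pos, ref_residue=ref, alt_residue=alt)


def iface(pair, a_set, b_set, residues=None):
    return InterfaceResidueSet(pair=pair, interface={pair[0]: a_set, pair[1]: b_set},
                               residues=residues)


class TestMapVariants:
    def test_non_interface_no_hit(self):
        hits = map_variants_to_interfaces([sub("P1", 7)], [iface(("P1", "P2"), {3}, {5})])
        assert hits == []

    def test_shared_interface_counts_per_ppi(self):
        interfaces = [iface(("P1", x), {7}, {1}) for x in ("P2", "P3", "P4")]
        hits = map_variants_to_interfaces([sub("P1", 7)], interfaces)
        assert len(hits) == 3

    def test_empty_interfaces(self):
        assert map_variants_to_interfaces([sub("P1", 7)], []) == []

    def test_position_absent_from_structure_skipped(self, caplog):
        import logging

        interfaces = [iface(("P1", "P2"), {7}, {1},
                            residues={"P1": {1, 2, 3}, "P2": {1}})]
        with caplog.at_level(logging.INFO, logger="docknet.variant_impact"):
            hits = map_variants_to_interfaces([sub("P1", 7)], interfaces)
        assert hits == []
        assert "skipped" in caplog.text

    def test_gene_to_protein_mapping(self):
        hits = map_variants_to_interfaces(
            [sub("LOC1", 7)], [iface(("P1", "P2"), {7}, {1})], protein_of={"LOC1": "P1"})
        assert len(hits) == 1


class TestClassifyDdg:
    def test_published_weakening_value(self):
        rec = classify_ddg(dg_ref=-10.0, dg_alt=-8.589)
        assert rec.ddg == pytest.approx(-1.411)
        assert rec.perturbation == "weaken"

    def test_equal_energies_neutral(self):
        assert classify_ddg(-7.0, -7.0).perturbation == "neutral"

    def test_exact_boundary_is_neutral(self):
        assert classify_ddg(-6.0, -7.0).perturbation == "neutral"  # ddG = +1.0
        assert classify_ddg(-7.0, -6.0).perturbation == "neutral"  # ddG = -1.0

    def test_strengthen(self):
        assert classify_ddg(-6.0, -7.5).perturbation == "strengthen"

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_ddg(float("nan"), 0.0)

    @given(st.floats(-20, 20, allow_nan=False), st.floats(-20, 20, allow_nan=False))
    @settings(max_examples=100, deadline=None)
    def test_antisymmetry(self, a, b):
        fwd = classify_ddg(a, b)
        rev = classify_ddg(b, a)
        assert rev.ddg == pytest.approx(-fwd.ddg)
        swap = {"strengthen": "weaken", "weaken": "strengthen", "neutral": "neutral"}
        assert rev.perturbation == swap[fwd.perturbation]


class TestSummarize:
    def test_two_snps_three_ppis_all_strengthen(self):
        records = [classify_ddg(-5.0, -7.0, variant=v, pair=(v, p))
                   for v in ("s1", "s2") for p in ("a", "b", "c")]
        summary = summarize_perturbation(records)
        assert summary["strengthen"] == {"n_variants": 2, "n_pairs": 6}

    def test_all_neutral(self):
        records = [classify_ddg(-5.0, -5.0, variant="s1", pair=("a", "b"))]
        summary = summarize_perturbation(records)
        assert summary["strengthen"]["n_variants"] == 0
        assert summary["weaken"]["n_variants"] == 0
        assert summary["significant_variants_union"] == 0

    def test_snp_in_both_signed_classes(self):
        records = [
            classify_ddg(-5.0, -7.0, variant="s1", pair=("s1", "a")),
            classify_ddg(-7.0, -5.0, variant="s1", pair=("s1", "b")),
        ]
        summary = summarize_perturbation(records)
        assert summary["strengthen"]["n_variants"] == 1
        assert summary["weaken"]["n_variants"] == 1
        assert summary["significant_variants_union"] == 1


class TestPlantedCodon:
    def test_tyr525asn(self):
        # 600-codon gene with TAT planted at codon 525, SNV to AAT
        n_codons = 600
        rng = np.random.default_rng(0)
        codons = ["ATG"] + ["GGT"] * (n_codons - 2) + ["TAA"]
        genome, gene, off = make_plus_gene(codons)
        genome, v = plant_codon_substitution(genome, gene, 525, "TAT", "AAT")
        res = annotate_substitution(genome, gene, v)
        assert res.substitution.label == "p.Tyr525Asn"

    def test_minus_strand_planting(self):
        genome, genes, _, _ = gen_toy_genome(10, seed=42)
        gene = next(g for g in genes if g.strand == "-")
        genome2, v = plant_codon_substitution(genome, gene, 3, "TAT", "TGT")
        res = annotate_substitution(genome2, gene, v)
        assert res.substitution.label == "p.Tyr3Cys"
        kind, label = mrna_diff_annotate(genome2, gene, v)
        assert (kind, label) == ("nonsynonymous", "p.Tyr3Cys")
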
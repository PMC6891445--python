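"""SNP discovery, melting temperatures, and multiplex panel design."""

import numpy as np
import pytest
from Bio.SeqUtils import MeltingTemp as mt

from amomarker.errors import DataError, DesignError, PanelAssemblyError
from amomarker.marker_design import (Primer,
                                     PrimerConstraints,
                                     assemble_multiplex_panel,
                                     design_internal_standard,
                                     design_species_primer,
                                     find_diagnostic_snps, has_3prime_dimer,
                                     primer_tm, read_panel_tsv,
                                     write_panel_tsv)
from amomarker.seq_core import LocusAlignment, SeqRecord, reverse_complement
from amomarker.synthetic_data import (A_LONGILIGULARE, A_VILLOSUM,
                                      A_XANTHIOIDES, INGROUP_SPECIES,
                                      PanelConfig, generate_reference_panel)


def _aln(rows, locus="toy"):
    return LocusAlignment(locus, [
        SeqRecord(f"r{i}", seq, species=sp)
        for i, (sp, seq) in enumerate(rows)])


class TestFindDiagnosticSnps:
    def test_three_species_fixed_column(self):
        aln = _aln([("s1", "AAC"), ("s1", "AAC"),
                    ("s2", "AGC"), ("s2", "AGC"),
                    ("s3", "ATC"), ("s3", "ATC")])
        (snp,) = find_diagnostic_snps(aln, ["s1", "s2", "s3"])
        assert snp.column == 1
        assert snp.alleles == {"s1": "A", "s2": "G", "s3": "T"}
        assert snp.kind == "fixed_interspecific"

    def test_one_vs_rest_discriminates_the_lone_species(self):
        aln = _aln([("s1", "A"), ("s2", "A"), ("s3", "G")])
        (snp,) = find_diagnostic_snps(aln, ["s1", "s2", "s3"])
        assert snp.discriminated_species == "s3"

    def test_identical_alignment_yields_nothing(self):
        aln = _aln([("s1", "ACGT"), ("s2", "ACGT"), ("s3", "ACGT")])
        assert find_diagnostic_snps(aln, ["s1", "s2", "s3"]) == []

    def test_missing_ingroup_species_is_an_error(self):
        aln = _aln([("s1", "ACGT"), ("s2", "ACGT")])
        with pytest.raises(DataError, match="s3"):
            find_diagnostic_snps(aln, ["s1", "s2", "s3"])

    def test_singleton_variant_in_large_species_is_ignored(self):
        # One deviating record out of four looks like amplification noise.
        aln = _aln([("s1", "A"), ("s1", "A"), ("s1", "A"), ("s1", "G"),
                    ("s2", "A"), ("s2", "A")])
        assert find_diagnostic_snps(aln, ["s1", "s2"]) == []

    def test_supported_polymorphism_is_reported(self):
        aln = _aln([("s1", "A"), ("s1", "A"), ("s1", "G"), ("s1", "G"),
                    ("s2", "A"), ("s2", "A")])
        (snp,) = find_diagnostic_snps(aln, ["s1", "s2"])
        assert snp.kind == "intraspecific"
        assert snp.alleles["s1"] == "R"

    def test_two_record_species_disagreement_counts(self):
        # Two accessioned sequences that disagree cannot be noise-filtered.
        aln = _aln([("s1", "A"), ("s1", "G"), ("s2", "A"), ("s2", "A")])
        (snp,) = find_diagnostic_snps(aln, ["s1", "s2"])
        assert snp.kind == "intraspecific"

    def test_shared_gap_is_a_length_variant_allele(self):
        aln = _aln([("s1", "AC"), ("s1", "AC"), ("s2", "A-"), ("s2", "A-")])
        (snp,) = find_diagnostic_snps(aln, ["s1", "s2"])
        assert snp.alleles == {"s1": "C", "s2": "-"}


class TestPlantedRecovery:
    def test_default_panel_recovers_exactly_the_planted_set(
            self, default_panel, its_snps):
        assert sorted(s.column for s in its_snps) == \
            default_panel.planted_columns("ITS")

    def test_alleles_match_the_truth_log(self, default_panel, its_snps):
        truth = {e["column"]: e
                 for e in default_panel.truth["loci"]["ITS"]["planted"]}
        for snp in its_snps:
            entry = truth[snp.column]
            assert snp.kind == entry["kind"]
            assert snp.alleles == entry["alleles"]

    @pytest.mark.parametrize("seed", range(1, 21))
    def test_recovery_across_seeds(self, seed):
        panel = generate_reference_panel(PanelConfig(seed=seed))
        for locus, aln in panel.alignments.items():
            snps = find_diagnostic_snps(aln, INGROUP_SPECIES)
            assert sorted(s.column for s in snps) == \
                panel.planted_columns(locus), (seed, locus)


class TestPrimerTm:
    def test_frozen_nearest_neighbor_values(self):
        # Independent oracle: published-parameter NN calculator at the
        # same salt / strand conditions (values frozen from it).
        assert primer_tm("AAAAAAAAAA") == pytest.approx(12.13, abs=0.05)
        assert primer_tm("GCGCGCATATGCGCATGCAT") == pytest.approx(63.19,
                                                                  abs=0.05)

    @pytest.mark.parametrize("seq", [
        "TGGATGATTGTGAACGTGTCAACA", "GACTCTCGGCAATGGATATCT",
        "ACGTACGTACGTACGTACGT",
    ])
    def test_cross_check_against_reference_calculator(self, seq):
        reference = mt.Tm_NN(seq, nn_table=mt.DNA_NN3, Na=50, dnac1=250,
                             dnac2=250, saltcorr=5)
        assert primer_tm(seq) == pytest.approx(reference, abs=0.1)

    def test_duplex_symmetry(self):
        seq = "TGGATGATTGTGAACGTGTCAACA"
        assert primer_tm(seq) == pytest.approx(
            primer_tm(reverse_complement(seq)), abs=1e-9)

    def test_gc_rich_melts_higher_than_at_rich(self):
        assert primer_tm("GCGCGCGCGCGCGCGCGCGC") > primer_tm(
            "ATATATATATATATATATAT")

    def test_ambiguity_codes_are_an_error(self):
        with pytest.raises(DataError):
            primer_tm("ACGTACGRACGT")

    def test_too_short_is_an_error(self):
        with pytest.raises(DataError):
            primer_tm("ACGTACG")


class TestSpeciesPrimerDesign:
    def test_villosum_marker_is_forward_on_a_planted_anchor(
            self, default_panel, multiplex_panel):
        primer = multiplex_panel.primer("AVF1")
        truth = default_panel.truth["loci"]["ITS"]["planted"]
        anchors = {e["column"]: e for e in truth if "role" in e}
        assert primer.orientation == "forward"
        entry = anchors[primer.anchor_column]
        assert entry["role"] == "avf1_anchor"
        assert primer.seq[-1] == entry["alleles"][A_VILLOSUM]

    def test_longiligulare_marker_is_reverse_in_its2(
            self, default_panel, multiplex_panel):
        primer = multiplex_panel.primer("ALF1")
        geometry = default_panel.its_geometry
        truth = default_panel.truth["loci"]["ITS"]["planted"]
        anchors = {e["column"]: e for e in truth if "role" in e}
        assert primer.orientation == "reverse"
        assert anchors[primer.anchor_column]["role"] == "alf1_anchor"
        its2_start_col = geometry.fivep8S_cols[1]
        assert primer.anchor_column >= its2_start_col

    def test_species_without_discriminating_snp_fails(self):
        aln = _aln([("s1", "ACGTACGTACGTACGTACGTACGTACGTACGT"),
                    ("s2", "ACGTACGTACGTACGTACGTACGTACGTACGT")])
        with pytest.raises((DesignError, DataError)):
            design_species_primer(aln, [], "s1",
                                  is_pair=_fake_is_pair())


def _fake_is_pair():
    isf = Primer("ISF", "ACGTACGTACGTACGTAC", "forward", "toy", 60.0,
                 footprint=(0, 18))
    isr = Primer("ISR", "ACGTACGTACGTACGTAC", "reverse", "toy", 60.0,
                 footprint=(82, 100))
    return isf, isr


class TestInternalStandard:
    def test_footprints_inside_the_conserved_block(self, default_panel,
                                                   multiplex_panel):
        lo, hi = default_panel.its_geometry.fivep8S_cols
        for name in ("ISF", "ISR"):
            primer = multiplex_panel.primer(name)
            assert primer.target_species == frozenset()
            start, end = primer.footprint
            assert lo <= start and end <= hi

    def test_product_is_exactly_the_constraint(self, multiplex_panel):
        assert multiplex_panel.universal_size == 100

    def test_no_conserved_block_is_an_error(self):
        rng = np.random.default_rng(0)
        seqs = ["".join(rng.choice(list("ACGT"), size=120)) for _ in range(3)]
        aln = _aln([("s1", seqs[0]), ("s2", seqs[1]), ("s3", seqs[2])])
        with pytest.raises(DesignError):
            design_internal_standard(aln)


class TestPanelAssembly:
    def test_expected_products(self, multiplex_panel):
        products = multiplex_panel.expected_products
        assert products["universal"] == 100
        assert products[f"{A_LONGILIGULARE}"] == 350
        villosum_key = [k for k in products if "villosum" in k][0]
        assert products[villosum_key] == 270

    def test_size_collision_is_an_error(self, default_panel,
                                        multiplex_panel):
        its = default_panel["ITS"]
        is_pair = (multiplex_panel.primer("ISF"), multiplex_panel.primer("ISR"))
        avf1 = multiplex_panel.primer("AVF1")
        # A second forward primer anchored ten columns downstream yields a
        # product only ten bases shorter than AVF1's.
        fp = (avf1.footprint[0] + 10, avf1.footprint[1] + 10)
        rival = Primer("XVF1", avf1.seq[:len(avf1) - 10] + "ACGTACGTAC",
                       "forward", "ITS", avf1.tm_c,
                       anchor_column=avf1.anchor_column + 10,
                       target_species=frozenset({A_VILLOSUM}),
                       footprint=fp)
        with pytest.raises(PanelAssemblyError, match="differ by"):
            assemble_multiplex_panel([avf1, rival], is_pair, its,
                                     size_resolution=50)

    def test_three_prime_dimer_detection(self):
        a = Primer("A", "ACGTACGTACGTACGTTTAA", "forward", "toy", 60.0)
        b = Primer("B", "CCCCCTTAACCCCCCCCCCC", "forward", "toy", 60.0)
        assert has_3prime_dimer(a, b)       # TTAA 3' end anneals inside b
        c = Primer("C", "CCCCCGGGGGCCCCCGGGGG", "forward", "toy", 60.0)
        assert not has_3prime_dimer(a, c)

    def test_design_is_deterministic(self, default_panel, its_snps,
                                     multiplex_panel):
        its = default_panel["ITS"]
        constraints = PrimerConstraints()
        is_pair = design_internal_standard(its, constraints)
        avf1 = design_species_primer(
            its, its_snps, A_VILLOSUM, constraints,
            target_species={A_VILLOSUM, A_XANTHIOIDES},
            is_pair=is_pair, name="AVF1")
        alf1 = design_species_primer(its, its_snps, A_LONGILIGULARE,
                                     constraints, is_pair=is_pair,
                                     name="ALF1")
        rebuilt = assemble_multiplex_panel([avf1, alf1], is_pair, its)
        assert {p.name: p.seq for p in rebuilt.primers} == \
               {p.name: p.seq for p in multiplex_panel.primers}
        assert rebuilt.expected_products == multiplex_panel.expected_products

    def test_panel_tsv_round_trip(self, multiplex_panel, tmp_path):
        path = tmp_path / "panel.tsv"
        write_panel_tsv(multiplex_panel, path)
        back = read_panel_tsv(path)
        assert back.expected_products == multiplex_panel.expected_products
        assert [(p.name, p.seq, p.orientation) for p in back.primers] == \
               [(p.name, p.seq, p.orientation)
                for p in multiplex_panel.primers]
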
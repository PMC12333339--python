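"""Extended-FASTA / HELM / BILN parsing, emission, and conversion laws."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bitterspace.notation import (
    Connection,
    NotationError,
    PeptideSequence,
    Site,
    convert,
    parse_biln,
    parse_fasta_extended,
    parse_helm,
    three_to_one,
    write_biln,
    write_fasta_extended,
    write_helm,
)

canonical_seqs = st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=25)


class TestFastaExtended:
    @pytest.mark.parametrize(
        "text, chains",
        [
            ("GF", [["G", "F"]]),
            ("(D)-L", [["dL"]]),
            ("RRPPPFFF", [["R", "R", "P", "P", "P", "F", "F", "F"]]),
            ("[pGlu]GF", [["pGlu", "G", "F"]]),
            ("VV[OMe]", [["V", "V", "OMe"]]),
            ("F[Nle]G", [["F", "Nle", "G"]]),
            ("W(D)-FW", [["W", "dF", "W"]]),
        ],
    )
    def test_chains(self, lib, text, chains):
        assert parse_fasta_extended(text, lib).chains == chains

    def test_cyclo_wrapper_adds_head_to_tail_bond(self, lib):
        p = parse_fasta_extended("cyclo(APG)", lib)
        assert p.chains == [["A", "P", "G"]]
        assert p.connections[0].normalized() == Connection(
            Site(0, 1, "R1"), Site(0, 3, "R2")
        ).normalized()

    def test_gamma_prefix_builds_side_chain_linkage(self, lib):
        p = parse_fasta_extended("gE-V", lib)
        assert p.chains == [["E"], ["V"]]
        assert p == parse_fasta_extended("γE-V", lib)  # γE- alias
        (conn,) = p.connections
        assert {conn.a, conn.b} == {Site(0, 1, "R3"), Site(1, 1, "R1")}

    @pytest.mark.parametrize("bad", ["", "GxF", "G[Foo]F", "G[", "(D)-B"])
    def test_bad_tokens_report_position(self, lib, bad):
        with pytest.raises(NotationError):
            parse_fasta_extended(bad, lib)


class TestHelm:
    def test_simple_polymer(self, lib):
        assert parse_helm("PEPTIDE1{G.F}$$$$", lib).chains == [["G", "F"]]

    def test_cyclization_connection(self, lib):
        p = parse_helm("PEPTIDE1{A.P.G}$PEPTIDE1,PEPTIDE1,3:R2-1:R1$$$", lib)
        assert p == parse_fasta_extended("cyclo(APG)", lib)

    def test_multi_character_ids_bracketed(self, lib):
        p = parse_helm("PEPTIDE1{[pGlu].G.[Nle]}$$$$", lib)
        assert p.chains == [["pGlu", "G", "Nle"]]

    def test_out_of_bounds_connection_rejected(self, lib):
        with pytest.raises(NotationError, match="residue 5"):
            parse_helm("PEPTIDE1{A.P.G}$PEPTIDE1,PEPTIDE1,5:R2-1:R1$$$", lib)

    def test_dangling_polymer_reference_rejected(self, lib):
        with pytest.raises(NotationError, match="undefined polymer"):
            parse_helm("PEPTIDE1{A.P.G}$PEPTIDE1,PEPTIDE9,3:R2-1:R1$$$", lib)

    def test_unknown_monomer_rejected(self, lib):
        with pytest.raises(Exception, match="Xyz"):
            parse_helm("PEPTIDE1{[Xyz].G}$$$$", lib)

    @pytest.mark.parametrize(
        "chains, expected",
        [([["G", "F"]], "PEPTIDE1{G.F}$$$$"), ([["W", "W", "W"]], "PEPTIDE1{W.W.W}$$$$")],
    )
    def test_write_simple(self, chains, expected):
        assert write_helm(PeptideSequence(chains=chains)) == expected

    def test_write_cyclic_has_connection_section(self, lib):
        s = write_helm(parse_fasta_extended("cyclo(APG)", lib))
        assert s.split("$")[1] != ""

    def test_v2_suffix_accepted(self, lib):
        assert parse_helm("PEPTIDE1{G.F}$$$$V2.0", lib).chains == [["G", "F"]]


class TestBiln:
    def test_simple_chain(self, lib):
        assert parse_biln("G-F", lib).chains == [["G", "F"]]
        assert write_biln(PeptideSequence(chains=[["G", "F"]])) == "G-F"

    def test_d_monomer_emitted_as_plain_id(self, lib):
        assert write_biln(parse_fasta_extended("(D)-L", lib)) == "dL"

    def test_cyclic_bond_index_appears_exactly_twice(self, lib):
        s = write_biln(parse_fasta_extended("cyclo(APG)", lib))
        assert s.count("(1,") == 2

    def test_unpaired_bond_index_rejected(self, lib):
        with pytest.raises(NotationError, match="pair"):
            parse_biln("A(1,2)-P-G", lib)

    def test_legacy_r_labelled_bonds_accepted(self, lib):
        assert parse_biln("A(1,R1)-P-G(1,R2)", lib) == parse_biln("A(1,1)-P-G(1,2)", lib)


class TestConvert:
    @pytest.mark.parametrize(
        "s, src, dst, expected",
        [
            ("PEPTIDE1{G.F}$$$$", "helm", "biln", "G-F"),
            ("G-F", "biln", "helm", "PEPTIDE1{G.F}$$$$"),
            ("GF", "fasta", "helm", "PEPTIDE1{G.F}$$$$"),
        ],
    )
    def test_examples(self, lib, s, src, dst, expected):
        assert convert(s, src, dst, lib) == expected

    def test_same_notation_rejected(self, lib):
        with pytest.raises(NotationError):
            convert("GF", "fasta", "fasta", lib)

    @settings(max_examples=60, deadline=None)
    @given(seq=canonical_seqs)
    def test_round_trip_law_canonical(self, lib, seq):
        # convert(convert(s, A->B), B->A) parses equal to s, for all pairs
        p = parse_fasta_extended(seq, lib)
        helm = convert(seq, "fasta", "helm", lib)
        biln = convert(helm, "helm", "biln", lib)
        assert parse_biln(biln, lib) == p
        assert convert(biln, "biln", "fasta", lib) == seq

    @pytest.mark.parametrize(
        "fasta",
        ["cyclo(GPFPV)", "gE-CG", "gD-F", "[pGlu]QG", "[Lac]FF", "VV[OMe]",
         "F[Nva]G", "(D)-W(D)-F", "[Orn]K", "[M(O)]P", "[pS]A"],
    )
    def test_round_trip_modified(self, lib, fasta):
        p = parse_fasta_extended(fasta, lib)
        assert parse_helm(write_helm(p), lib) == p
        assert parse_biln(write_biln(p), lib) == p
        assert parse_fasta_extended(write_fasta_extended(p, lib), lib) == p


class TestThreeToOne:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("Gly-Phe", "GF"),
            ("Arg-Arg-Pro-Pro-Pro-Phe-Phe-Phe", "RRPPPFFF"),
            ("trp trp", "WW"),
        ],
    )
    def test_examples(self, text, expected):
        assert three_to_one(text) == expected

    def test_residue_count_preserved(self):
        assert len(three_to_one("Ala-Gly-Ser-Thr")) == 4

    @pytest.mark.parametrize("bad", ["Xyz", "Gly-Xyz", ""])
    def test_unknown_triplet_rejected(self, bad):
        with pytest.raises(NotationError):
            three_to_one(bad)


class TestNotationConsistency:
    @settings(max_examples=40, deadline=None)
    @given(seq=canonical_seqs)
    def test_all_entry_notations_agree(self, lib, seq):
        # the same peptide entered via any notation yields one PeptideSequence
        helm = write_helm(PeptideSequence(chains=[list(seq)]))
        biln = "-".join(seq)
        assert parse_fasta_extended(seq, lib) == parse_helm(helm, lib) == parse_biln(biln, lib)

    def test_three_letter_path_matches_fasta_path(self, lib):
        via_three = three_to_one("Arg-Arg-Pro-Pro-Pro-Phe-Phe-Phe")
        assert parse_fasta_extended(via_three, lib) == parse_fasta_extended("RRPPPFFF", lib)

    def test_connection_reuse_rejected(self, lib):
        p = PeptideSequence(
            chains=[["A", "P", "G"]],
            connections=[
                Connection(Site(0, 3, "R2"), Site(0, 1, "R1")),
                Connection(Site(0, 3, "R2"), Site(0, 2, "R1")),
            ],
        )
        with pytest.raises(NotationError, match="more than one"):
            p.validate(lib)
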
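"""Record I/O and the two-part analysis: splits, distributions, space
points, enrichment, BTT bands, receptor coverage, correlations, plots."""

import pytest

from bitterspace.dataset import (
    AXES_LOGP_MW,
    AXES_Q_LENGTH,
    DatasetError,
    PeptideRecord,
    SpacePoint,
    aa_composition,
    btt_summary,
    correlation_report,
    export_space_plot,
    length_distribution,
    load_tas2r_reference,
    read_records,
    receptor_coverage,
    space_points,
    split_canonical,
    threshold_enrichment,
    write_records,
)


def rec(id_, fasta, taste="bitter", **kw):
    return PeptideRecord(id=id_, fasta=fasta, taste=taste, **kw)


@pytest.fixture()
def mixed_records():
    return [
        rec("a", "GF"),
        rec("b", "GG", taste="nonbitter"),
        rec("c", "GGG", taste="nonbitter"),
        rec("d", "cyclo(GPFPV)", canonical=False, mod_group=2),
        rec("e", "gE-V", taste="nonbitter", canonical=False, mod_group=5),
    ]


class TestRecordIO:
    def test_round_trip(self, tmp_path, mixed_records):
        path = tmp_path / "records.tsv"
        write_records(mixed_records, path)
        assert read_records(path) == mixed_records

    def test_round_trip_preserves_optional_fields(self, tmp_path):
        records = [
            rec("x", "WW", btt=0.25, receptors=("TAS2R1", "TAS2R4"),
                conflict=True, source="plant", references="ref 12"),
        ]
        path = tmp_path / "r.tsv"
        write_records(records, path)
        assert read_records(path) == records

    def test_missing_mandatory_column(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("id\tfasta\n1\tGF\n")
        with pytest.raises(DatasetError, match="mandatory"):
            read_records(path)

    def test_invariant_violations_reported_with_row_numbers(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "id\tfasta\tcanonical\ttaste\tmod_group\tbtt_mmol_L\n"
            "ok\tGF\t1\tbitter\t1\t\n"
            "bad\tGG\t1\tnonbitter\t1\t5\n"
        )
        with pytest.raises(DatasetError, match="row 3"):
            read_records(path)

    def test_unknown_columns_preserved(self, tmp_path):
        path = tmp_path / "extra.tsv"
        path.write_text(
            "id\tfasta\tcanonical\ttaste\tmod_group\tpanel\n"
            "p1\tGF\t1\tbitter\t1\tmunich\n"
        )
        (record,) = read_records(path)
        assert record.extra["panel"] == "munich"


class TestRecordInvariants:
    def test_btt_on_nonbitter_flagged(self):
        assert rec("x", "GG", taste="nonbitter", btt=5.0).validate()

    def test_canonical_iff_group_one(self):
        assert rec("x", "GF", mod_group=2).validate()
        assert rec("x", "cyclo(GPF)", canonical=False, mod_group=1).validate()

    def test_unknown_receptor_flagged(self):
        assert rec("x", "GF", receptors=("TAS2R99",)).validate()

    def test_valid_record_has_no_problems(self):
        assert rec("x", "GF", btt=1.0, receptors=("TAS2R1",)).validate() == []


class TestSplitAndDistributions:
    def test_split_partitions_preserving_order(self, mixed_records):
        canonical, modified = split_canonical(mixed_records)
        assert [r.id for r in canonical] == ["a", "b", "c"]
        assert [r.id for r in modified] == ["d", "e"]
        assert len(canonical) + len(modified) == len(mixed_records)

    def test_split_all_canonical(self):
        records = [rec("a", "GF"), rec("b", "FF")]
        assert split_canonical(records) == (records, [])

    def test_length_distribution_counts(self, mixed_records):
        table = length_distribution(split_canonical(mixed_records)[0])
        got = {
            (row["length"], row["taste"]): row["count"]
            for row in table.to_dict(orient="records")
        }
        assert got == {(2, "bitter"): 1, (2, "nonbitter"): 1, (3, "nonbitter"): 1}
        assert table["count"].sum() == 3

    def test_length_distribution_empty(self):
        assert length_distribution([]).empty

    def test_aa_composition_counts_residues(self):
        table = aa_composition([rec("p", "PP")])
        assert table.to_dict(orient="records") == [
            {"residue": "P", "taste": "bitter", "count": 2}
        ]

    def test_aa_composition_octapeptide(self):
        table = aa_composition([rec("r8", "RRPPPFFF")])
        counts = dict(zip(table["residue"], table["count"]))
        assert counts == {"R": 2, "P": 3, "F": 3}
        assert table["count"].sum() == 8  # conserves residue totals

    def test_aa_composition_order_invariant(self, mixed_records):
        canonical, _ = split_canonical(mixed_records)
        a = aa_composition(canonical)
        b = aa_composition(list(reversed(canonical)))
        assert a.equals(b)

    def test_aa_composition_filter_applied_before_counting(self):
        records = [rec("short", "FF"), rec("long", "F" * 20)]
        table = aa_composition(records, filter=lambda r: len(r.fasta) <= 13)
        assert table["count"].sum() == 2


class TestSpacePoints:
    def test_q_length_plane_worked_values(self):
        points, excl = space_points([rec("gf", "GF"), rec("ww", "WW")], AXES_Q_LENGTH)
        assert not excl
        by_id = {p.id: (p.x, p.y) for p in points}
        assert by_id["gf"] == (1325.0, 2.0)
        assert by_id["ww"] == (3000.0, 2.0)

    def test_modified_record_excluded_from_q_plane_with_reason(self, lib, mixed_records):
        points, excl = space_points(mixed_records, AXES_Q_LENGTH, lib)
        assert len(points) == 3 and len(excl) == 2
        assert {rid for rid, _ in excl} == {"d", "e"}
        assert all(reason for _, reason in excl)

    def test_modified_records_live_on_logp_mw_plane(self, lib, mixed_records):
        points, excl = space_points(mixed_records, AXES_LOGP_MW, lib)
        assert len(points) == 5 and not excl


class TestEnrichment:
    def test_three_point_fixture_brute_force(self):
        points = [
            SpacePoint("a", 2151, 8, AXES_Q_LENGTH, "bitter", 1),
            SpacePoint("b", 275, 2, AXES_Q_LENGTH, "nonbitter", 1),
            SpacePoint("c", 1325, 2, AXES_Q_LENGTH, "bitter", 1),
        ]
        summary = threshold_enrichment(points, 1400.0)
        assert (summary.bitter_above, summary.nonbitter_above,
                summary.bitter_below, summary.nonbitter_below) == (1, 0, 1, 1)
        assert summary.total == 3

    def test_threshold_below_everything(self):
        points = [SpacePoint(str(i), q, 2, AXES_Q_LENGTH, "bitter", 1)
                  for i, q in enumerate([100, 500, 900])]
        summary = threshold_enrichment(points, -1e9)
        assert summary.bitter_above == 3 and summary.bitter_below == 0

    def test_conservation_with_unlabelled_points(self):
        points = [
            SpacePoint("a", 2000, 2, AXES_Q_LENGTH, "bitter", 1),
            SpacePoint("b", 100, 2, AXES_Q_LENGTH, "not_tested", 1),
        ]
        summary = threshold_enrichment(points, 1400.0)
        assert summary.excluded == 1 and summary.total == 2

    def test_mixed_axes_rejected(self):
        points = [
            SpacePoint("a", 1, 1, AXES_Q_LENGTH, "bitter", 1),
            SpacePoint("b", 1, 1, AXES_LOGP_MW, "bitter", 1),
        ]
        with pytest.raises(DatasetError, match="mix"):
            threshold_enrichment(points, 0.0)


class TestBttSummary:
    def test_extremes_carry_record_ids(self):
        records = [
            rec("rrpppfff", "RRPPPFFF", btt=0.002),
            rec("ge", "GE", btt=403.0),
            rec("gf", "GF", btt=519.0),
        ]
        summary = btt_summary(records)
        assert summary["min"]["id"] == "rrpppfff"
        assert summary["max"]["id"] == "gf"
        assert summary["max"]["btt_mmol_L"] == 519.0

    def test_band_counts_sum_to_btt_bearing_records(self, default_dataset):
        summary = btt_summary(default_dataset)
        assert summary["bands"]["count"].sum() == summary["n"]

    def test_single_band_occupancy(self):
        records = [rec(f"r{i}", "FF", btt=v) for i, v in enumerate([2.0, 3.0, 9.9])]
        bands = btt_summary(records)["bands"]
        assert bands.loc[bands["band_mmol_L"] == "1.0-10.0", "count"].item() == 3
        assert bands["count"].sum() == 3


class TestReceptorCoverage:
    def test_reference_table_maximum_is_tas2r1(self):
        table = receptor_coverage(reference=load_tas2r_reference())
        assert table.iloc[0]["receptor"] == "TAS2R1"

    def test_universal_agonist_counts_once_per_receptor(self):
        www = rec("www", "WWW",
                  receptors=("TAS2R1", "TAS2R4", "TAS2R14", "TAS2R39", "TAS2R46"))
        table = receptor_coverage([www])
        assert table["peptide_count"].sum() == 5

    def test_empty_annotations_give_all_zero(self):
        table = receptor_coverage([rec("a", "GF")])
        assert (table["peptide_count"] == 0).all()

    def test_unknown_receptor_is_an_error(self):
        # construction does not validate; coverage must still refuse the id
        bad = rec("x", "GF", receptors=("TAS2R99",))
        with pytest.raises(DatasetError, match="TAS2R99"):
            receptor_coverage([bad])


class TestCorrelation:
    def test_perfectly_linear(self):
        pairs = [(x, 2 * x + 1) for x in range(5)]
        anti = [(x, -x) for x in range(5)]
        r_a, r_b, comparison = correlation_report(pairs, anti)
        assert r_a == pytest.approx(1.0)
        assert r_b == pytest.approx(-1.0)
        assert comparison == "first stronger"

    def test_zero_variance_is_an_error(self):
        with pytest.raises(DatasetError, match="zero variance"):
            correlation_report([(1, 1), (1, 2), (1, 3)], [(0, 0), (1, 1), (2, 2)])

    def test_too_few_pairs(self):
        with pytest.raises(DatasetError, match="3"):
            correlation_report([(0, 0), (1, 1)], [(0, 0), (1, 1), (2, 2)])


class TestPlots:
    def test_taste_plot_written_with_legend(self, tmp_path):
        points = [
            SpacePoint("a", 2151, 8, AXES_Q_LENGTH, "bitter", 1),
            SpacePoint("b", 275, 2, AXES_Q_LENGTH, "nonbitter", 1),
            SpacePoint("c", 1325, 2, AXES_Q_LENGTH, "bitter", 1),
        ]
        out = tmp_path / "space.png"
        export_space_plot(points, out, color_by="taste")
        assert out.exists() and out.stat().st_size > 0

    def test_btt_coloring_without_btt_values_names_field(self, tmp_path):
        points = [SpacePoint("a", 1.0, 75.0, AXES_LOGP_MW, "bitter", 1)]
        with pytest.raises(DatasetError, match="btt"):
            export_space_plot(points, tmp_path / "x.png", color_by="btt")

    def test_mod_group_coloring_on_mixed_set(self, tmp_path):
        points = [SpacePoint(str(g), 0.1 * g, 100.0 * g, AXES_LOGP_MW, "bitter", g)
                  for g in range(1, 8)]
        out = tmp_path / "groups.png"
        export_space_plot(points, out, color_by="mod_group")
        assert out.exists()
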
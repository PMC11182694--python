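"""IO, validation and harmonization of summary statistics and LD matrices."""

import math

import numpy as np
import pytest

from dtmr.sumstats import (
    LDMatrix,
    harmonize,
    read_ld,
    read_sumstats,
    write_ld,
    write_sumstats,
)


class TestReadSumstats:
    def test_well_formed_file_parses_every_row(self, sumstats_file):
        path = sumstats_file(
            [
                ["rs1", 1, 100, "A", "G", 0.2, 0.1, 0.01, 1e-10, 1000],
                ["rs2", 1, 200, "C", "T", 0.3, -0.2, 0.02, 1e-8, 1000],
                ["rs3", 1, 300, "a", "g", 0.4, 0.05, 0.01, 0.5, 1000],
            ]
        )
        report = []
        records = read_sumstats(path, trait="protein", report=report)
        assert len(records) == 3
        assert report == []
        assert records[2].variant.effect_allele == "A"  # upper-cased
        assert all(r.trait == "protein" for r in records)

    def test_zero_se_row_rejected_with_line_number(self, sumstats_file):
        path = sumstats_file(
            [
                ["rs1", 1, 100, "A", "G", 0.2, 0.1, 0.01, 1e-10, 1000],
                ["rs2", 1, 200, "C", "T", 0.3, -0.2, 0.0, 1e-8, 1000],
                ["rs3", 1, 300, "G", "T", 0.4, 0.05, 0.01, 0.5, 1000],
            ]
        )
        report = []
        records = read_sumstats(path, trait="t", report=report)
        assert len(records) == 2
        assert len(report) == 1
        assert ":3:" in report[0]  # header is line 1, rs2 is line 3

    def test_published_instrument_row_round_trips(self, sumstats_file):
        # ANGPTL4 p.E40K missense variant and the APOC3 splice-donor PTV,
        # with their per-allele TG effects
        path = sumstats_file(
            [
                ["rs116843064", 19, 8364439, "A", "G", 0.024, -0.21, 0.009, 3.2e-127, 344278],
                ["rs138326449", 11, 116830638, "A", "G", 0.002, -0.86, 0.032, 3.4e-157, 344278],
            ]
        )
        records = read_sumstats(path, trait="TG")
        by_id = {r.variant.id: r for r in records}
        assert by_id["rs116843064"].beta == -0.21
        assert by_id["rs116843064"].pvalue == 3.2e-127
        assert by_id["rs138326449"].variant.pos == 116830638
        assert by_id["rs138326449"].beta == -0.86

    def test_missing_mandatory_column_names_it(self, sumstats_file):
        path = sumstats_file(
            [["rs1", 1, 100, "A", "G", 0.2, 0.1, 0.01, 1e-10, 1000]],
            header=["id", "chrom", "pos", "effect_allele", "other_allele",
                    "eaf", "beta", "stderr", "pvalue", "n"],
        )
        with pytest.raises(ValueError, match="'se'"):
            read_sumstats(path, trait="t")

    def test_non_numeric_beta_rejected_not_fatal(self, sumstats_file):
        path = sumstats_file(
            [
                ["rs1", 1, 100, "A", "G", 0.2, "NA", 0.01, 1e-10, 1000],
                ["rs2", 1, 200, "C", "T", 0.3, -0.2, 0.02, 1e-8, 1000],
            ]
        )
        records = read_sumstats(path, trait="t")
        assert [r.variant.id for r in records] == ["rs2"]

    def test_duplicate_id_rejected_as_multiallelic(self, sumstats_file):
        path = sumstats_file(
            [
                ["rs1", 1, 100, "A", "G", 0.2, 0.1, 0.01, 1e-10, 1000],
                ["rs1", 1, 100, "A", "C", 0.1, 0.2, 0.01, 1e-10, 1000],
            ]
        )
        report = []
        records = read_sumstats(path, trait="t", report=report)
        assert len(records) == 1 and len(report) == 1

    def test_comma_delimited_autodetected(self, sumstats_file):
        path = sumstats_file(
            [["rs1", 1, 100, "A", "G", 0.2, 0.1, 0.01, 1e-10, 1000]],
            sep=",", name="sumstats.csv",
        )
        assert len(read_sumstats(path, trait="t")) == 1

    def test_write_read_round_trip_preserves_numbers(self, tmp_path, make_record):
        rng = np.random.default_rng(42)
        records = [
            make_record(
                vid=f"rs{i}", pos=100 + i,
                beta=float(rng.normal()), se=float(rng.uniform(0.001, 1.0)),
                pvalue=float(rng.uniform(1e-300, 1.0)), eaf=float(rng.uniform(0, 1)),
            )
            for i in range(20)
        ]
        path = tmp_path / "out.tsv"
        write_sumstats(records, path)
        back = read_sumstats(path, trait="protein")
        assert len(back) == len(records)
        for a, b in zip(records, back):
            assert b.beta == pytest.approx(a.beta, rel=1e-11)
            assert b.se == pytest.approx(a.se, rel=1e-11)
            assert b.pvalue == pytest.approx(a.pvalue, rel=1e-11)
            assert b.variant.eaf == pytest.approx(a.variant.eaf, rel=1e-11)


class TestLDMatrix:
    def test_identity_accepted(self, tmp_path):
        ld = LDMatrix(["a", "b", "c"], np.eye(3))
        assert np.allclose(ld.r, np.eye(3))

    def test_symmetric_entry_accepted(self):
        r = np.array([[1.0, 0.7], [0.7, 1.0]])
        ld = LDMatrix(["a", "b"], r)
        assert ld.pairwise_r("a", "b") == pytest.approx(0.7)

    @pytest.mark.parametrize(
        "bad",
        [
            np.array([[1.0, 1.2], [1.2, 1.0]]),  # |r| > 1
            np.array([[1.0, 0.2], [0.5, 1.0]]),  # asymmetric
            np.array([[1.0, np.nan], [np.nan, 1.0]]),  # NaN
        ],
    )
    def test_invalid_matrices_rejected(self, bad):
        with pytest.raises(ValueError):
            LDMatrix(["a", "b"], bad)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            LDMatrix(["a", "b"], np.ones((2, 3)))

    def test_non_psd_input_is_conditioned(self):
        # three mutually correlated at 0.9/-0.9 is not PSD
        r = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(r).min() < 0
        ld = LDMatrix(["a", "b", "c"], r)
        assert np.linalg.eigvalsh(ld.r).min() >= 0
        assert np.allclose(np.diag(ld.r), 1.0)
        assert np.allclose(ld.r, ld.r.T)

    def test_file_round_trip_is_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((6, 4))
        r = np.corrcoef(x)
        ld = LDMatrix([f"v{i}" for i in range(6)], r)
        path = tmp_path / "ld.tsv"
        write_ld(ld, path)
        back = read_ld(path)
        assert back.variant_ids == ld.variant_ids
        assert np.allclose(back.r, ld.r, atol=1e-10)

    def test_subset_preserves_order_and_values(self):
        r = np.array([[1.0, 0.5, 0.2], [0.5, 1.0, 0.1], [0.2, 0.1, 1.0]])
        ld = LDMatrix(["a", "b", "c"], r)
        sub = ld.subset(["c", "a"])
        assert sub.variant_ids == ["c", "a"]
        assert sub.pairwise_r("c", "a") == pytest.approx(0.2)


class TestHarmonize:
    def test_swapped_alleles_negate_beta(self, make_record):
        exposure = [make_record(vid="rs1", ea="A", oa="G", beta=0.5)]
        outcome = [make_record(vid="rs1", ea="G", oa="A", beta=-0.3, eaf=0.75, trait="out")]
        result = harmonize(exposure, outcome)
        assert len(result) == 1
        pair = result.pairs[0]
        assert pair.outcome.beta == pytest.approx(0.3)
        assert pair.outcome.variant.effect_allele == "A"
        assert pair.outcome.variant.eaf == pytest.approx(0.25)

    def test_ambiguous_palindrome_dropped(self, make_record):
        exposure = [
            make_record(vid="rs1", ea="A", oa="T", eaf=0.50),
            make_record(vid="rs2", ea="C", oa="G", eaf=0.30),
        ]
        outcome = [
            make_record(vid="rs1", ea="A", oa="T", eaf=0.50, trait="out"),
            make_record(vid="rs2", ea="C", oa="G", eaf=0.30, trait="out"),
        ]
        result = harmonize(exposure, outcome, palindrome_eaf_window=0.08)
        assert result.variant_ids == ["rs2"]
        assert any("palindromic" in line for line in result.log)

    def test_strand_flip_resolved_by_complement(self, make_record):
        exposure = [make_record(vid="rs1", ea="A", oa="G", beta=0.5)]
        outcome = [make_record(vid="rs1", ea="T", oa="C", beta=0.2, trait="out")]
        result = harmonize(exposure, outcome)
        assert result.pairs[0].outcome.beta == pytest.approx(0.2)
        assert result.pairs[0].outcome.variant.effect_allele == "A"

    def test_incompatible_alleles_dropped(self, make_record):
        exposure = [
            make_record(vid="rs1", ea="A", oa="G"),
            make_record(vid="rs2", ea="A", oa="G"),
        ]
        outcome = [
            make_record(vid="rs1", ea="A", oa="C", trait="out"),
            make_record(vid="rs2", ea="A", oa="G", trait="out"),
        ]
        result = harmonize(exposure, outcome)
        assert result.variant_ids == ["rs2"]

    def test_zero_shared_variants_is_hard_error(self, make_record):
        with pytest.raises(ValueError, match="zero shared"):
            harmonize([make_record(vid="rs1")], [make_record(vid="rs2", trait="out")])

    def test_harmonization_is_idempotent(self, make_record):
        rng = np.random.default_rng(7)
        # outcome pairs are the identity, swap, strand-flip, strand+swap of an
        # A/G exposure variant, plus one unambiguous palindrome
        cases = [
            (("A", "G"), ("A", "G")),
            (("A", "G"), ("G", "A")),
            (("A", "G"), ("T", "C")),
            (("A", "G"), ("C", "T")),
            (("A", "T"), ("A", "T")),
        ]
        exposure, outcome = [], []
        for i, ((xea, xoa), (ea, oa)) in enumerate(cases):
            eaf = float(rng.uniform(0.05, 0.35))  # outside the palindrome window
            exposure.append(make_record(vid=f"rs{i}", ea=xea, oa=xoa, eaf=eaf,
                                        beta=float(rng.normal())))
            outcome.append(make_record(vid=f"rs{i}", ea=ea, oa=oa, eaf=eaf,
                                       beta=float(rng.normal()), trait="out"))
        once = harmonize(exposure, outcome)
        twice = harmonize(
            [p.exposure for p in once.pairs], [p.outcome for p in once.pairs]
        )
        assert twice.variant_ids == once.variant_ids
        for p1, p2 in zip(once.pairs, twice.pairs):
            assert p2.outcome.beta == p1.outcome.beta
            assert p2.outcome.variant.effect_allele == p1.outcome.variant.effect_allele
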
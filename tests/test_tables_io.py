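"""I/O readers, validation, notation pre-pass and bundled fixtures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import cholscreen as cs
from cholscreen.errors import FormatError, ValidationError


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestHaplotypeReader:
    def test_bundled_table_shape_and_calls(self, study):
        t = study.haplotypes
        assert len(t.genes) == 22
        assert t.strains == ["B6", "BXD51", "BXD73", "BXD2"]
        assert t.call("Aldh7a1", "BXD2") == "D2"
        assert t.call("Chkb", "B6") == "H"
        # gene symbols match case-insensitively but are stored as read
        assert t.call("slc44a1", "BXD51") == "D2"
        assert "Slc44a1" in t.genes

    def test_minimal_one_by_one_table(self, tmp_path):
        p = _write(tmp_path, "h.tsv", "gene\tB6\nCept1\tB6\n")
        t = cs.read_haplotype_table(p)
        assert t.genes == ["Cept1"] and t.call("Cept1", "B6") == "B6"

    def test_unknown_code_rejected_with_location(self, tmp_path):
        p = _write(tmp_path, "h.tsv", "gene\tS1\tS2\nCept1\tB6\tX2\n")
        with pytest.raises(ValidationError, match="X2.*Cept1.*S2"):
            cs.read_haplotype_table(p)

    def test_codes_as_first_row_means_missing_header(self, tmp_path):
        p = _write(tmp_path, "h.tsv", "Cept1\tB6\tD2\nChka\tB6\tB6\n")
        with pytest.raises(FormatError, match="header"):
            cs.read_haplotype_table(p)

    def test_nv_must_fill_the_whole_row(self, tmp_path):
        p = _write(tmp_path, "h.tsv", "gene\tS1\tS2\nChat\tNV\tB6\n")
        with pytest.raises(ValidationError, match="NV"):
            cs.read_haplotype_table(p)


class TestProteomeReader:
    def test_bundled_table_missing_strain(self, study):
        t = study.proteome
        assert len(t.genes) == 5
        assert t.abundance("Slc44a1", "BXD73") == 12.9
        assert all(np.isnan(t.abundance(g, "BXD2")) for g in t.genes)

    def test_header_only_gives_zero_genes(self, tmp_path):
        p = _write(tmp_path, "p.tsv", "gene\tS1\tS2\n")
        assert cs.read_proteome_table(p).genes == []

    def test_comma_decimal_rejected(self, tmp_path):
        p = _write(tmp_path, "p.csv", 'gene,S1,S2\nCept1,"12,7",16\n')
        with pytest.raises(FormatError, match="12,7"):
            cs.read_proteome_table(p, dialect="csv")

    @pytest.mark.parametrize("token", ["n/a", "N/A", ""])
    def test_missing_tokens(self, tmp_path, token):
        p = _write(tmp_path, "p.tsv", f"gene\tS1\tS2\nCept1\t16.4\t{token}\n")
        t = cs.read_proteome_table(p)
        assert t.abundance("Cept1", "S1") == 16.4
        assert np.isnan(t.abundance("Cept1", "S2"))

    def test_roundtrip_preserves_cells_and_missing(self, tmp_path, study):
        out = tmp_path / "rt.tsv"
        study.proteome.frame.to_csv(out, sep="\t", na_rep="n/a")
        again = cs.read_proteome_table(out)
        pd.testing.assert_frame_equal(again.frame, study.proteome.frame)


class TestCellDeathReader:
    HEADER = "strain\tregion\ttreatment\tcholine_dose\tlitter_id\tlitter_mean\n"

    def test_single_row(self, tmp_path):
        p = _write(tmp_path, "c.tsv",
                   self.HEADER + "B6\tbrainstem\tETOH\t0\tL1\t12.5\n")
        (obs,) = cs.read_celldeath_table(p)
        assert obs.strain == "B6" and obs.litter_mean == 12.5
        assert obs.choline_dose == 0.0

    def test_duplicate_key_rejected(self, tmp_path):
        row = "B6\tbrainstem\tETOH\t0\tL1\t12.5\n"
        p = _write(tmp_path, "c.tsv", self.HEADER + row + row)
        with pytest.raises(ValidationError, match="duplicate"):
            cs.read_celldeath_table(p)

    def test_negative_mean_rejected(self, tmp_path):
        p = _write(tmp_path, "c.tsv",
                   self.HEADER + "B6\tbrainstem\tETOH\t0\tL1\t-1\n")
        with pytest.raises(ValidationError, match="negative"):
            cs.read_celldeath_table(p)

    def test_unusual_dose_flagged_not_rejected(self, tmp_path, caplog):
        p = _write(tmp_path, "c.tsv",
                   self.HEADER + "B6\tbrainstem\tETOH\t75\tL1\t12.5\n")
        with caplog.at_level("WARNING"):
            (obs,) = cs.read_celldeath_table(p)
        assert obs.choline_dose == 75.0
        assert "unusual choline dose" in caplog.text

    def test_write_read_roundtrip(self, tmp_path):
        obs = [
            cs.CellDeathObservation("B6", "forebrain", "MD", 100.0, f"L{i}", v)
            for i, v in enumerate([18.0, 21.5, 19.25])
        ]
        out = tmp_path / "c.tsv"
        cs.write_celldeath_table(obs, out)
        assert cs.read_celldeath_table(out) == obs


class TestGwasReader:
    def test_bundled_tables_row_counts(self, study):
        assert len(study.snp_tables["Cept1"]) == 53
        assert len(study.snp_tables["Slc44a1"]) == 78

    @pytest.mark.parametrize("raw, expected", [
        ("3.01 × 10^−2^", 0.0301),   # published unicode markup
        ("3.01 x 10^-2", 0.0301),
        ("4.94e-2", 0.0494),
        ("0.05", 0.05),
    ])
    def test_p_value_notations(self, tmp_path, raw, expected):
        p = _write(tmp_path, "g.tsv",
                   f"variant\tphenotype\tp_value\nrs1\tsome trait\t{raw}\n")
        (rec,) = cs.read_gwas_table(p)
        assert rec.p_value == pytest.approx(expected, rel=1e-12)
        assert rec.category is None

    def test_p_above_one_rejected(self, tmp_path):
        p = _write(tmp_path, "g.tsv",
                   "variant\tphenotype\tp_value\nrs1\ttrait\t1.5\n")
        with pytest.raises(ValidationError, match="outside"):
            cs.read_gwas_table(p)

    @pytest.mark.parametrize("raw", [
        "3.01 × 10^−2^", "1.82 × 10^−19^", "0.05", "5e-8",
    ])
    def test_notation_prepass_is_idempotent(self, raw):
        once = cs.normalize_scientific(raw)
        assert cs.normalize_scientific(once) == once


class TestFunnelReportWriter:
    def _report(self):
        return cs.FunnelReport(
            stages=[cs.StageResult("s1", "crit", ["Cept1", "Slc44a1"],
                                   {"Bhmt": "no variation"})],
            final_candidates=["Cept1", "Slc44a1"],
        )

    @pytest.mark.parametrize("fmt", ["tsv", "json", "markdown"])
    def test_empty_report_renders(self, fmt):
        text = cs.render_report(cs.FunnelReport(), fmt)
        assert text  # valid output with zero stage blocks

    @pytest.mark.parametrize("fmt", ["tsv", "json", "markdown"])
    def test_written_twice_is_byte_identical(self, tmp_path, fmt):
        a, b = tmp_path / "a.out", tmp_path / "b.out"
        cs.write_funnel_report(self._report(), a, fmt)
        cs.write_funnel_report(self._report(), b, fmt)
        assert a.read_bytes() == b.read_bytes()

    def test_final_candidates_line(self, tmp_path):
        out = tmp_path / "r.tsv"
        cs.write_funnel_report(self._report(), out)
        assert "Cept1,Slc44a1" in out.read_text()


class TestCorrelationGridFixture:
    def test_cells_match_published_grid(self, study):
        g = study.correlations
        assert g.at["Cept1", ("brainstem", 100)] == 0.996
        assert g.at["Slc44a1", ("forebrain", 100)] == 0.521
        assert g.at["Aldh7a1", ("brainstem", 100)] == 0.085
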
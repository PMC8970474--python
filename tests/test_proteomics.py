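"""Two-bait enrichment: ratio arithmetic, orientation, GST normalisation,
quantification filters, quadrant classification, enriched-set selection."""

import math

import numpy as np
import pandas as pd
import pytest

from psdnano import proteomics as prot
from psdnano import simulate


def peptide_frame(rows):
    return pd.DataFrame(rows, columns=["protein", "peptide", "replicate", "ratio", "intensity"])


class TestProteinRatio:
    def test_intensity_weighted_average(self):
        peps = peptide_frame([("P", "p1", "A", 2.0, 1.0), ("P", "p2", "A", 4.0, 3.0)])
        ratio, n = prot.protein_ratio(peps)
        assert ratio == pytest.approx(3.5)
        assert n == 2

    def test_single_peptide_is_its_own_ratio(self):
        ratio, n = prot.protein_ratio(peptide_frame([("P", "p1", "A", 1.7, 9.0)]))
        assert ratio == pytest.approx(1.7) and n == 1

    def test_equal_intensities_give_arithmetic_mean(self):
        peps = peptide_frame([("P", f"p{i}", "A", r, 5.0) for i, r in enumerate((1.0, 2.0, 6.0))])
        assert prot.protein_ratio(peps)[0] == pytest.approx(3.0)

    def test_scale_invariance_in_intensity(self):
        peps = peptide_frame([("P", "p1", "A", 2.0, 1.0), ("P", "p2", "A", 4.0, 3.0)])
        scaled = peps.assign(intensity=peps.intensity * 1e6)
        assert prot.protein_ratio(peps)[0] == pytest.approx(prot.protein_ratio(scaled)[0])

    def test_zero_intensity_rejected(self):
        with pytest.raises(ValueError, match="intensity"):
            prot.protein_ratio(peptide_frame([("P", "p1", "A", 2.0, 0.0)]))


class TestOrientation:
    def test_replicate_b_inverted(self):
        assert prot.orient_ratio(0.25, "B") == pytest.approx(4.0)

    def test_replicate_a_identity(self):
        assert prot.orient_ratio(4.0, "A") == pytest.approx(4.0)

    def test_double_inversion_is_identity(self):
        assert prot.orient_ratio(prot.orient_ratio(0.4, "B"), "B") == pytest.approx(0.4)

    def test_unknown_replicate_rejected(self):
        with pytest.raises(ValueError, match="replicate"):
            prot.orient_ratio(1.0, "C")


class TestGSTNormalisation:
    @staticmethod
    def two_protein_table(gst_a=0.7, gst_b=1.0 / 0.7):
        rows = []
        for rep, inv in (("A", False), ("B", True)):
            for protein, oriented in (("P", 3.5), ("GST", 0.7)):
                raw = 1.0 / oriented if inv else oriented
                rows.append((protein, f"{protein}_{rep}", rep, raw, 10.0))
        return peptide_frame(rows)

    def test_ratio_divided_by_gst(self):
        table = prot.compute_protein_table(self.two_protein_table())
        row = table[table.protein == "P"].iloc[0]
        assert row.ratio_A == pytest.approx(5.0)
        assert row.ratio_B == pytest.approx(5.0)

    def test_gst_self_normalises_to_one(self):
        table = prot.compute_protein_table(self.two_protein_table())
        row = table[table.protein == "GST"].iloc[0]
        assert row.ratio_A == pytest.approx(1.0)
        assert row.ratio_B == pytest.approx(1.0)

    def test_missing_gst_names_replicate(self):
        peps = peptide_frame([("P", "p", "A", 2.0, 1.0), ("P", "p", "B", 0.5, 1.0),
                              ("GST", "g", "A", 1.0, 1.0)])
        with pytest.raises(ValueError, match="replicate B"):
            prot.compute_protein_table(peps)


class TestGeometricSD:
    def test_worked_example_ratios_two_and_eight(self):
        # ln 2, ln 8: sample SD = (ln 8 - ln 2)/sqrt(2) = 0.980, exp = 2.66
        assert prot.geometric_sd(np.array([2.0, 8.0])) == pytest.approx(2.665, abs=0.01)

    def test_equal_ratios_give_one(self):
        assert prot.geometric_sd(np.array([3.0, 3.0])) == 1.0

    def test_dispersed_protein_removed_by_filter(self):
        table = pd.DataFrame({
            "protein": ["P", "Q"],
            "ratio_A": [2.0, 2.0], "ratio_B": [8.0, 2.0],
            "n_peptides_A": [3, 3], "n_peptides_B": [3, 3],
            "geometric_sd": [prot.geometric_sd(np.array([2.0, 8.0])), 1.0],
        })
        table["quadrant"] = "PSD95-enriched"
        table["mpp2_fold_enrichment"] = 0.5
        table["psd95_fold_enrichment"] = 2.0
        kept = prot.apply_quant_filters(table)
        assert list(kept.protein) == ["Q"]

    def test_single_replicate_protein_removed(self):
        peps = peptide_frame([
            ("P", "p1", "A", 2.0, 1.0), ("P", "p2", "A", 2.0, 1.0),
            ("GST", "g1", "A", 1.0, 1.0), ("GST", "g2", "A", 1.0, 1.0),
            ("GST", "g1", "B", 1.0, 1.0), ("GST", "g2", "B", 1.0, 1.0),
        ])
        table = prot.analyze_peptide_table(peps)
        assert "P" not in set(table.protein)


class TestQuadrants:
    @pytest.mark.parametrize("a,b,expected", [
        (5.0, 4.2, prot.QUAD_PSD95),
        (0.10, 0.08, prot.QUAD_MPP2),
        (1.2, 0.8, prot.QUAD_NONE),
    ])
    def test_classification(self, a, b, expected):
        quad, _, _ = prot.classify_quadrant(a, b)
        assert quad == expected

    def test_mpp2_fold_uses_weaker_replicate(self):
        quad, fold_mpp2, _ = prot.classify_quadrant(0.10, 0.08)
        assert quad == prot.QUAD_MPP2
        assert fold_mpp2 == pytest.approx(10.0)

    def test_nonpositive_ratio_rejected(self):
        with pytest.raises(ValueError):
            prot.classify_quadrant(-1.0, 2.0)


class TestSelection:
    @staticmethod
    def table_with_folds(folds):
        rows = []
        for i, fold in enumerate(folds):
            rows.append({"protein": f"P{i}", "ratio_A": 1.0 / fold, "ratio_B": 1.0 / fold,
                         "n_peptides_A": 3, "n_peptides_B": 3, "geometric_sd": 1.0})
        table = pd.DataFrame(rows)
        quad, fm, fp = zip(*(prot.classify_quadrant(a, b)
                             for a, b in zip(table.ratio_A, table.ratio_B)))
        return table.assign(quadrant=quad, mpp2_fold_enrichment=fm, psd95_fold_enrichment=fp)

    def test_strict_sevenfold_boundary(self):
        table = self.table_with_folds([10.0, 7.0, 6.0])
        selected = prot.select_enriched(table, "MPP2", 7.0)
        assert list(selected.protein) == ["P0"]

    def test_planted_set_recovered_end_to_end(self):
        config = simulate.study_peptide_config(seed=21, noise_sd=0.05)
        peptides, truth = simulate.simulate_peptide_table(config, seed=22)
        table = prot.analyze_peptide_table(peptides)
        selected = set(prot.select_enriched(table, "MPP2", 7.0).protein)
        planted = {p for p, e in truth.enriched.items()
                   if e and truth.true_ratio[p] < 1.0}
        assert selected == planted

    def test_label_swap_symmetry(self):
        config = simulate.PeptideTableConfig(
            true_log2_ratios={"P1": 3.2, "P2": -3.5, "P3": 0.1},
            peptide_log_ratio_noise_sd=0.0)
        peptides, _ = simulate.simulate_peptide_table(config, seed=5)
        normal = prot.analyze_peptide_table(peptides)
        swapped_peps = peptides.assign(
            replicate=peptides.replicate.map({"A": "B", "B": "A"}),
            ratio=1.0 / peptides.ratio)
        swapped = prot.analyze_peptide_table(swapped_peps)
        merged = normal.merge(swapped, on="protein", suffixes=("_n", "_s"))
        np.testing.assert_allclose(merged.ratio_A_n, merged.ratio_A_s)
        np.testing.assert_allclose(merged.ratio_B_n, merged.ratio_B_s)


class TestProteinSheetReader:
    def test_tsv_round_trip(self, tmp_path):
        path = tmp_path / "sheet.tsv"
        pd.DataFrame({
            "Accession": ["P1", "P2"],
            "Ratio A": [5.0, 0.1], "Ratio B": [4.0, 0.12],
        }).to_csv(path, sep="\t", index=False)
        table = prot.read_protein_sheet(
            path, {"Accession": "protein", "Ratio A": "ratio_A", "Ratio B": "ratio_B"})
        assert list(table.quadrant) == [prot.QUAD_PSD95, prot.QUAD_MPP2]

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "sheet.tsv"
        pd.DataFrame({"Accession": ["P1"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="not found"):
            prot.read_protein_sheet(path, {"Accession": "protein", "Ratio A": "ratio_A"})
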
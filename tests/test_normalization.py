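"""Reference alignment, delta-Ct arithmetic, stability scoring and cutoff."""

import io
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import gpcrprofile as gp
from gpcrprofile import normalization, qpcr_io


def _matrix_from_ct(table: dict[str, dict[str, float]], category="GPCR") -> gp.MeanCtMatrix:
    """Build a MeanCtMatrix directly from {gene: {cell: ct}}."""
    rows = []
    for gene, cells in table.items():
        for cell, ct in cells.items():
            sentinel = ct >= 40.0
            rows.append((gene, cell, ct, 0.0, 2, sentinel, False))
    data = pd.DataFrame(
        rows,
        columns=["gene_symbol", "cell_type", "mean_ct", "sd_ct",
                 "n_replicates", "all_sentinel", "mixed_detection"],
    )
    catalog = pd.DataFrame(
        {"assay_id": [f"A{i}" for i in range(len(table))],
         "gene_symbol": list(table), "category": category},
    )
    return gp.MeanCtMatrix(data=data, catalog=catalog)


class TestDeltaCtArithmetic:
    def test_published_exemplar_folds(self):
        # LPHN2 in TG1: Ct 24.00 vs reference 21.12 -> dCt 2.88, fold 7.36
        # F2R in OB1:   Ct 24.30 -> dCt 3.18, fold 9.06
        matrix = _matrix_from_ct(
            {"LPHN2": {"TG1": 24.0}, "F2R": {"OB1": 24.3},
             "RPLP0": {"TG1": 21.12, "OB1": 21.12}}
        )
        ref = gp.build_reference(matrix, grand_mean_ct=21.12)
        prof = gp.normalize(matrix, ref)
        lphn2 = prof.lookup("LPHN2", "TG1")
        assert lphn2["delta_ct"] == pytest.approx(2.88)
        assert round(lphn2["fold_below_ref"], 2) == 7.36
        assert round(prof.lookup("F2R", "OB1")["fold_below_ref"], 2) == 9.06

    def test_ratio_over_reference_at_ct_31_2(self):
        # GPR56 in astrocytes: Ct 31.2 -> ratio over the reference 0.0009
        matrix = _matrix_from_ct({"GPR56": {"HA": 31.2}, "RPLP0": {"HA": 21.12}})
        prof = gp.normalize(matrix, gp.build_reference(matrix, grand_mean_ct=21.12))
        ratio = prof.lookup("GPR56", "HA")["ratio_over_ref"]
        assert float(f"{ratio:.1g}") == 0.0009

    def test_gene_at_reference_ct_is_identity(self):
        matrix = _matrix_from_ct({"X": {"TG1": 21.12}, "RPLP0": {"TG1": 21.12}})
        prof = gp.normalize(matrix, gp.build_reference(matrix, grand_mean_ct=21.12))
        row = prof.lookup("X", "TG1")
        assert row["delta_ct"] == pytest.approx(0.0)
        assert row["fold_below_ref"] == pytest.approx(1.0)
        assert row["ratio_over_ref"] == pytest.approx(1.0)

    def test_cross_sample_alignment_shift_and_inverse(self):
        # the reference is 0.5 cycles late in OB1: every OB1 Ct shifts by -0.5
        matrix = _matrix_from_ct(
            {"X": {"TG1": 25.0, "OB1": 25.0},
             "RPLP0": {"TG1": 21.12, "OB1": 21.62}}
        )
        ref = gp.build_reference(matrix, grand_mean_ct=21.12)
        prof = gp.normalize(matrix, ref)
        assert prof.lookup("X", "OB1")["ct"] == pytest.approx(24.5)
        assert prof.lookup("X", "TG1")["ct"] == pytest.approx(25.0)
        # un-normalize: adding the shift back recovers the raw Ct exactly
        raw = prof.lookup("X", "OB1")["ct"] + ref.shift("OB1")
        assert raw == pytest.approx(25.0)

    def test_sentinel_genes_keep_sentinel_units_and_fail_cutoff(self):
        matrix = _matrix_from_ct({"X": {"TG1": 40.0}, "RPLP0": {"TG1": 21.0}})
        prof = gp.normalize(matrix, gp.build_reference(matrix))
        row = prof.lookup("X", "TG1")
        assert row["ct"] == 40.0
        assert not row["above_cutoff"]
        assert row["units"] == pytest.approx(gp.expression_units(40.0))

    def test_sentinel_reference_is_unusable(self):
        matrix = _matrix_from_ct({"X": {"TG1": 25.0}, "RPLP0": {"TG1": 40.0}})
        with pytest.raises(normalization.UnusableReferenceError):
            gp.normalize(matrix, gp.build_reference(matrix))


class TestUnitsAndCutoff:
    def test_units_at_cutoff_round_to_329(self):
        assert round(gp.expression_units(31.5)) == 329

    def test_units_monotone_decreasing_in_ct(self):
        cts = np.linspace(15, 40, 200)
        units = [gp.expression_units(c) for c in cts]
        assert all(a > b for a, b in zip(units, units[1:]))

    def test_fold_identity_invariant(self):
        matrix = _matrix_from_ct(
            {"X": {"TG1": 24.0}, "Y": {"TG1": 33.3}, "RPLP0": {"TG1": 21.12}}
        )
        prof = gp.normalize(matrix, gp.build_reference(matrix, grand_mean_ct=21.12))
        prod = prof.data["fold_below_ref"] * prof.data["ratio_over_ref"]
        assert np.allclose(prod, 1.0, atol=1e-12)

    def test_cutoff_inclusive_and_union(self):
        matrix = _matrix_from_ct(
            {"AT": {"TG1": 31.5, "OB1": 35.0},
             "OVER": {"TG1": 32.0, "OB1": 33.0},
             "RPLP0": {"TG1": 21.12, "OB1": 21.12}}
        )
        prof = gp.normalize(matrix, gp.build_reference(matrix, grand_mean_ct=21.12))
        result = gp.filter_expressed(prof)
        assert "AT" in result.per_cell_type["TG1"]  # Ct exactly 31.5 retained
        assert "AT" not in result.per_cell_type["OB1"]
        assert "OVER" not in result.union
        assert result.counts == {"TG1": 2, "OB1": 1}  # reference included

    def test_all_sentinel_genes_give_empty_union(self):
        matrix = _matrix_from_ct(
            {"X": {"TG1": 40.0}, "Y": {"TG1": 40.0}, "RPLP0": {"TG1": 21.12}}
        )
        prof = gp.normalize(matrix, gp.build_reference(matrix), genes=["X", "Y"])
        assert gp.filter_expressed(prof).union == frozenset()

    @pytest.mark.parametrize(
        "ct, expected",
        [(31.5, 1.0), (21.12, 2 ** 10.38), (40.0, 2 ** -8.5)],
    )
    def test_relative_fold_over_cutoff(self, ct, expected):
        assert gp.relative_fold_over_cutoff(ct) == pytest.approx(expected)


class TestStability:
    def test_constant_offset_profiles_have_zero_m(self):
        matrix = _matrix_from_ct(
            {"A": {"c1": 20.0, "c2": 22.0, "c3": 24.0},
             "B": {"c1": 21.0, "c2": 23.0, "c3": 25.0}},
            category="housekeeping",
        )
        M = gp.compute_stability(matrix, ["A", "B"])
        assert M["A"] == pytest.approx(0.0, abs=1e-12)
        assert M["B"] == pytest.approx(0.0, abs=1e-12)

    def test_three_candidate_hand_computed_values(self):
        # B is a constant offset of A (V_AB = 0); C deviates:
        # V_AC = sd(0, 1, -1) = 1, V_BC = sd(-0.5, 0.5, -1.5) = 1
        # M_A = M_B = 0.5, M_C = 1.0  (frozen manual pairwise-sd oracle)
        matrix = _matrix_from_ct(
            {"A": {"c1": 20.0, "c2": 21.0, "c3": 22.0},
             "B": {"c1": 20.5, "c2": 21.5, "c3": 22.5},
             "C": {"c1": 20.0, "c2": 22.0, "c3": 21.0}},
            category="housekeeping",
        )
        M = gp.compute_stability(matrix, ["A", "B", "C"])
        assert M["A"] == pytest.approx(0.5)
        assert M["B"] == pytest.approx(0.5)
        assert M["C"] == pytest.approx(1.0)

    @given(perm=st.permutations(["c1", "c2", "c3", "c4"]))
    def test_m_invariant_to_cell_type_order(self, perm):
        base = {"c1": 20.0, "c2": 22.0, "c3": 21.0, "c4": 23.0}
        other = {"c1": 20.5, "c2": 21.0, "c3": 23.0, "c4": 22.0}
        matrix = _matrix_from_ct(
            {"A": {c: base[c] for c in perm}, "B": {c: other[c] for c in perm}},
            category="housekeeping",
        )
        M = gp.compute_stability(matrix, ["A", "B"])
        expected = np.std(
            [other[c] - base[c] for c in ["c1", "c2", "c3", "c4"]], ddof=1
        )
        assert M["A"] == pytest.approx(expected)

    def test_too_few_candidates_or_cell_types_rejected(self):
        matrix = _matrix_from_ct(
            {"A": {"c1": 20.0, "c2": 21.0}, "B": {"c1": 20.0}},
            category="housekeeping",
        )
        with pytest.raises(normalization.NormalizationError):
            gp.compute_stability(matrix, ["A"])
        with pytest.raises(normalization.NormalizationError):
            gp.compute_stability(matrix, ["A", "B"])
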
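import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitoproteoscope.core_io import GroupDesign, QuantMatrix, ValidationError
from mitoproteoscope.differential import (
    classify_volcano,
    differential_test,
    subset_mito,
    volcano_table,
)
from mitoproteoscope.synthetic import default_design, generate_annotations


# --- independent textbook oracle -------------------------------------------


def oracle_t_test(a, b, equal_var=True):
    """Closed-form two-sample t-test (pooled or Welch), written from the
    textbook formulas; only the t CDF comes from scipy."""
    a = [x for x in a if not math.isnan(x)]
    b = [x for x in b if not math.isnan(x)]
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    if equal_var:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = (ma - mb) / se
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def make_matrix(rows: dict[str, list[float]], design: GroupDesign) -> QuantMatrix:
    data = pd.DataFrame.from_dict(rows, orient="index", columns=list(design.all_samples))
    return QuantMatrix(data=data, scale="log2")


DESIGN_3V5 = default_design()


class TestDifferentialTest:
    def test_identical_groups_null(self):
        matrix = make_matrix({"P1": [3.0] * 8}, DESIGN_3V5)
        result = differential_test(matrix, DESIGN_3V5)
        assert result.loc["P1", "log2_diff"] == 0
        assert result.loc["P1", "p_value"] == pytest.approx(1.0)
        assert classify_volcano(result).loc["P1", "class"] == "ns"

    def test_valid_value_filter(self):
        rows = {"P1": [5.0, math.nan, math.nan, 3.0, 3.1, 3.0, 3.2, 3.0]}
        result = differential_test(make_matrix(rows, DESIGN_3V5), DESIGN_3V5)
        assert result.loc["P1", "class"] == "filtered"
        assert math.isnan(result.loc["P1", "p_value"])

    @pytest.mark.parametrize("variant", ["student", "welch"])
    def test_matches_closed_form_oracle(self, variant):
        patient = [4.0, 4.2, 4.1]
        control = [3.0, 3.1, 2.9, 3.0, 3.2]
        result = differential_test(
            make_matrix({"P1": patient + control}, DESIGN_3V5), DESIGN_3V5, variant
        )
        t_exp, p_exp = oracle_t_test(patient, control, equal_var=(variant == "student"))
        assert result.loc["P1", "t_statistic"] == pytest.approx(t_exp, rel=1e-12)
        assert result.loc["P1", "p_value"] == pytest.approx(p_exp, rel=1e-12)
        assert result.loc["P1", "log2_diff"] == pytest.approx(
            np.mean(patient) - np.mean(control)
        )

    def test_oracle_equivalence_on_synthetic_matrix(self, seed42_dataset):
        """Every tested protein's t and p match the textbook formulas."""
        matrix, _ = seed42_dataset
        log2 = np.log2(matrix.data)
        result = differential_test(
            QuantMatrix(data=log2, scale="log2"), DESIGN_3V5
        )
        rng = np.random.default_rng(0)
        tested = result[result["class"] != "filtered"]
        for acc in rng.choice(tested.index, size=200, replace=False):
            row = log2.loc[acc]
            t_exp, p_exp = oracle_t_test(row.iloc[:3].tolist(), row.iloc[3:].tolist())
            assert result.loc[acc, "t_statistic"] == pytest.approx(t_exp, rel=1e-10)
            assert result.loc[acc, "p_value"] == pytest.approx(p_exp, rel=1e-10)

    def test_filter_exact_over_all_missingness_patterns(self):
        """class == filtered exactly when min(valid counts) < 2 (brute force
        over all 2^8 missingness patterns of the 3+5 design)."""
        base = [4.0, 4.2, 4.1, 3.0, 3.1, 2.9, 3.0, 3.2]
        rows = {}
        for bits in itertools.product([0, 1], repeat=8):
            key = "P" + "".join(map(str, bits))
            rows[key] = [math.nan if b else v for b, v in zip(bits, base)]
        result = differential_test(make_matrix(rows, DESIGN_3V5), DESIGN_3V5)
        for key, bits in zip(rows, itertools.product([0, 1], repeat=8)):
            n_pat = 3 - sum(bits[:3])
            n_ctl = 5 - sum(bits[3:])
            expected = "filtered" if min(n_pat, n_ctl) < 2 else "ns"
            assert result.loc[key, "class"] == expected, key

    def test_group_swap_negates_diff_preserves_p(self, seed42_dataset):
        matrix, _ = seed42_dataset
        log2 = QuantMatrix(data=np.log2(matrix.data), scale="log2")
        swapped = GroupDesign(DESIGN_3V5.control_samples, DESIGN_3V5.patient_samples)
        fwd = differential_test(log2, DESIGN_3V5)
        rev = differential_test(log2, swapped)
        tested = fwd["class"] != "filtered"
        np.testing.assert_allclose(
            fwd.loc[tested, "log2_diff"], -rev.loc[tested, "log2_diff"], rtol=1e-12
        )
        np.testing.assert_allclose(
            fwd.loc[tested, "p_value"], rev.loc[tested, "p_value"], rtol=1e-9
        )

    def test_tiny_group_rejected(self):
        design = GroupDesign(("p1",), ("c1", "c2"))
        data = pd.DataFrame({"p1": [1.0], "c1": [1.0], "c2": [1.0]}, index=["P1"])
        with pytest.raises(ValidationError, match=">= 2 samples"):
            differential_test(QuantMatrix(data=data, scale="log2"), design)

    def test_power_on_planted_effects(self, seed42_dataset, seed42_diff):
        """>= 90% of proteins with true |effect| = 1.5 and no missingness are
        classified significant (recovery against generator truth)."""
        matrix, truth = seed42_dataset
        complete = matrix.data.notna().all(axis=1)
        planted = truth[
            (truth["true_log2_effect"].abs() == 1.5)
            & truth["accession"].isin(complete[complete].index)
        ]["accession"]
        classes = seed42_diff.loc[planted, "class"]
        assert (classes.isin(["down", "up"])).mean() >= 0.90


class TestClassifyVolcano:
    @pytest.mark.parametrize(
        "diff,p,expected",
        [
            (-1.0, 0.05, "down"),   # boundary inclusive
            (1.0, 0.05, "up"),
            (-2.0, 0.2, "ns"),      # big change, weak evidence
            (-0.5, 0.001, "ns"),    # strong evidence, small change
        ],
    )
    def test_boundary_geometry(self, diff, p, expected):
        frame = pd.DataFrame(
            {"log2_diff": [diff], "p_value": [p], "class": ["ns"]}, index=["P1"]
        )
        assert classify_volcano(frame).loc["P1", "class"] == expected

    def test_nonpositive_thresholds_rejected(self):
        frame = pd.DataFrame(
            {"log2_diff": [0.0], "p_value": [1.0], "class": ["ns"]}, index=["P1"]
        )
        with pytest.raises(ValidationError):
            classify_volcano(frame, fc_log2=0)
        with pytest.raises(ValidationError):
            classify_volcano(frame, p_max=-0.1)


class TestSubsetMito:
    def test_subset_and_idempotence(self, seed42_diff, complex_defs):
        annotations = generate_annotations(2000, complex_defs, seed=1)
        sub = subset_mito(seed42_diff, annotations)
        assert set(sub.index) <= annotations.mito_accessions
        assert len(sub) == sum(
            seed42_diff.index.isin(annotations.mito_accessions)
        )
        pd.testing.assert_frame_equal(subset_mito(sub, annotations), sub)
        # classes unchanged by subsetting
        assert (sub["class"] == seed42_diff.loc[sub.index, "class"]).all()

    def test_empty_intersection_warns(self, seed42_diff):
        from mitoproteoscope.core_io import AnnotationSet

        with pytest.warns(UserWarning):
            sub = subset_mito(seed42_diff, AnnotationSet(mito_accessions=frozenset({"ZZZ"})))
        assert sub.empty


class TestVolcanoTable:
    @pytest.mark.parametrize("p,y", [(0.05, 1.301), (1.0, 0.0), (0.001, 3.0)])
    def test_y_axis_values(self, p, y):
        frame = pd.DataFrame(
            {"log2_diff": [0.0], "p_value": [p], "class": ["ns"]}, index=["P1"]
        )
        table = volcano_table(frame)
        assert table.loc["P1", "y"] == pytest.approx(y, abs=5e-4)

    def test_significance_line_constants(self, seed42_diff):
        table = volcano_table(seed42_diff)
        assert table.attrs["x_lines"] == (-1.0, 1.0)
        assert table.attrs["y_line"] == pytest.approx(1.301, abs=5e-4)
        filtered = seed42_diff["class"] == "filtered"
        assert table.loc[filtered, "y"].isna().all()
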
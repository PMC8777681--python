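import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitoproteoscope.assays import (
    compare_growth,
    compare_intensity,
    normalize_growth,
    quantify_image,
    sidak_correct,
)
from mitoproteoscope.core_io import ValidationError
from mitoproteoscope.synthetic import (
    ImageDesign,
    generate_growth_plate,
    generate_intensity_image,
)


def toy_plate(day0: float, day2: float, blank: float = 100.0) -> pd.DataFrame:
    rows = []
    for day, rfu in [(0, day0), (2, day2)]:
        rows.append(
            {"well": "w1", "cell_line": "L", "condition": "galactose",
             "day": day, "rfu_raw": rfu, "is_blank": False}
        )
        rows.append(
            {"well": "b1", "cell_line": "blank", "condition": "galactose",
             "day": day, "rfu_raw": blank, "is_blank": True}
        )
    return pd.DataFrame(rows)


class TestNormalizeGrowth:
    def test_hand_computed_toy(self):
        """blank 100; 300 at day 0 and 500 at day 2 -> growth 2.0."""
        out = normalize_growth(toy_plate(300.0, 500.0))
        cells = out[~out["is_blank"]].set_index("day")
        assert cells.loc[0, "growth_norm"] == pytest.approx(1.0)
        assert cells.loc[2, "growth_norm"] == pytest.approx(2.0)

    def test_zero_denominator_errors(self):
        with pytest.raises(ValidationError, match="denominator"):
            normalize_growth(toy_plate(100.0, 500.0))  # well equals blank at day 0

    def test_invariant_to_plate_wide_offset(self):
        """Adding any constant to all wells of a plate-day cancels in
        blank subtraction."""
        plate = generate_growth_plate(noise_sd=3.0, seed=5)
        shifted = plate.copy()
        offsets = {(c, d): o for (c, d), o in zip(
            plate.groupby(["condition", "day"]).groups,
            np.random.default_rng(0).uniform(-50, 50, size=plate.groupby(["condition", "day"]).ngroups),
        )}
        shifted["rfu_raw"] = [
            r + offsets[(c, d)]
            for r, c, d in zip(plate["rfu_raw"], plate["condition"], plate["day"])
        ]
        a = normalize_growth(plate)
        b = normalize_growth(shifted)
        np.testing.assert_allclose(
            a["growth_norm"].dropna(), b["growth_norm"].dropna(), rtol=1e-9
        )

    def test_per_well_normalization_is_one_at_day0(self):
        plate = generate_growth_plate(noise_sd=3.0, seed=5)
        out = normalize_growth(plate, per_well=True)
        day0 = out[(out["day"] == 0) & (~out["is_blank"])]
        np.testing.assert_allclose(day0["growth_norm"], 1.0)

    def test_missing_blank_errors(self):
        plate = toy_plate(300.0, 500.0)
        with pytest.raises(ValidationError, match="blank"):
            normalize_growth(plate[~plate["is_blank"]])


class TestCompareGrowth:
    def _normalized(self, params, noise_sd=15.0, seed=0):
        plate = generate_growth_plate(growth_params=params, noise_sd=noise_sd, seed=seed)
        return normalize_growth(plate)

    def test_identical_lines_line_effect_near_one(self):
        """Copying one line's data onto another gives line SS = 0, p = 1."""
        growth = self._normalized({}, noise_sd=10.0, seed=1)
        sub = growth[growth["condition"] == "glucose"].copy()
        clone = sub[sub["cell_line"] == "patient"].copy()
        clone["cell_line"] = "mirror"
        clone["well"] = clone["well"] + "_m"
        report = compare_growth(pd.concat([sub, clone]), "patient", "mirror", "glucose")
        assert report["p_line"] > 0.99

    def test_halved_rate_detected(self):
        params = {
            ("patient", "galactose"): (0.5, 1000.0),
            ("control_A", "galactose"): (1.0, 1000.0),
        }
        report = compare_growth(
            self._normalized(params), "patient", "control_A", "galactose"
        )
        assert report["p_line"] < 1e-6
        final = report["per_day"].iloc[-1]
        assert final["mean_diff"] < 0  # patient grows less

    def test_permuted_labels_give_uniform_p(self):
        """Under random label permutation the line-effect p is ~Uniform(0,1)
        (KS check over 200 permutations)."""
        growth = self._normalized({}, noise_sd=25.0, seed=3)
        sub = growth[
            (growth["condition"] == "glucose")
            & growth["cell_line"].isin(["patient", "control_A"])
        ].copy()
        wells = sorted(sub["well"].unique())
        rng = np.random.default_rng(3)
        p_values = []
        for _ in range(200):
            labels = dict(zip(wells, rng.permutation(
                ["patient"] * (len(wells) // 2) + ["control_A"] * (len(wells) // 2)
            )))
            permuted = sub.copy()
            permuted["cell_line"] = permuted["well"].map(labels)
            report = compare_growth(permuted, "patient", "control_A", "glucose")
            p_values.append(report["p_line"])
        ks = stats.kstest(p_values, "uniform")
        assert ks.pvalue > 0.01

    def test_many_to_one_dunnett(self):
        params = {("patient", "galactose"): (0.4, 1000.0)}
        report = compare_growth(
            self._normalized(params), "patient", ["control_A", "control_B"], "galactose"
        )
        assert set(report["per_day"]["comparator"]) == {"control_A", "control_B"}
        assert (report["per_day"]["p_corrected"] <= 1).all()

    def test_unbalanced_design_rejected(self):
        growth = self._normalized({})
        sub = growth[growth["condition"] == "glucose"]
        broken = sub[~((sub["cell_line"] == "patient") & (sub["day"] == 2))]
        with pytest.raises(ValidationError, match="unbalanced"):
            compare_growth(broken, "patient", "control_A", "glucose")


class TestQuantifyImage:
    def test_constant_image_empty_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            table = quantify_image(np.full((64, 64), 7.0))
        assert table.empty

    def test_noiseless_disc_recovers_planted_intensity(self):
        """One disc at 200 on background 20: one mask, mean corrected
        intensity 180 +/- 1."""
        design = ImageDesign(n_cells=1, intensity={"g": 200.0}, background=20.0,
                             noise_sd=0.0)
        image, masks = generate_intensity_image(design, "g", seed=4)
        table = quantify_image(image)
        assert len(table) == 1
        assert abs(table.iloc[0]["mean_intensity"] - 180.0) <= 1.0
        assert table.iloc[0]["area_px"] == masks[0].sum()

    def test_mask_count_equals_planted_blob_count(self):
        design = ImageDesign(n_cells=6, noise_sd=0.0)
        image, masks = generate_intensity_image(design, "control", seed=8)
        table = quantify_image(image)
        assert len(table) == len(masks)

    def test_min_area_suppresses_small_components(self):
        img = np.full((64, 64), 10.0)
        img[10:12, 10:12] = 200.0  # 4-px speck
        with pytest.warns(UserWarning, match="50 px"):
            table = quantify_image(img, min_area=50)
        assert table.empty

    def test_two_group_ratio_recovered(self):
        """Patient cells at ~2x control intensity: group mean ratio in
        [1.8, 2.2] after background correction."""
        design = ImageDesign(noise_sd=3.0)
        tables = []
        for group, seeds in [("patient", (0, 1, 2)), ("control", (3, 4, 5))]:
            for s in seeds:
                image, _ = generate_intensity_image(design, group, seed=s)
                tables.append(quantify_image(image, cell_line=group, image_id=f"{group}{s}"))
        table = pd.concat(tables, ignore_index=True)
        means = table.groupby("cell_line")["mean_intensity"].mean()
        ratio = means["patient"] / means["control"]
        assert 1.8 <= ratio <= 2.2


class TestCompareIntensity:
    def make_table(self, means, n=10, sd=5.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for group, mu in means.items():
            for i, v in enumerate(rng.normal(mu, sd, size=n)):
                rows.append({"cell_line": group, "mean_intensity": v,
                             "image_id": group, "cell_index": i, "area_px": 100})
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self):
        table = self.make_table({"a": 100.0, "b": 100.0, "c": 100.0})
        report = compare_intensity(table)
        assert report["p_overall"] > 0.05

    def test_matches_textbook_anova(self):
        table = self.make_table({"a": 100.0, "b": 140.0, "c": 100.0})
        report = compare_intensity(table)
        groups = [g["mean_intensity"].to_numpy() for _, g in table.groupby("cell_line")]
        f_exp, p_exp = stats.f_oneway(*groups)
        assert report["f_statistic"] == pytest.approx(f_exp, rel=1e-8)
        assert report["p_overall"] == pytest.approx(p_exp, rel=1e-8)

    def test_sidak_closed_form(self):
        assert sidak_correct(0.02, 3) == pytest.approx(1 - (1 - 0.02) ** 3, rel=1e-12)
        table = self.make_table({"a": 100.0, "b": 130.0})
        report = compare_intensity(table)
        row = report["pairwise"].iloc[0]
        assert row["p_sidak"] == pytest.approx(sidak_correct(row["p_raw"], 1))

    def test_type_i_rate_calibrated(self):
        """3 equal-mean groups over 200 simulations: rejection rate at
        alpha 0.05 within [0.02, 0.08]."""
        rng = np.random.default_rng(12)
        rejections = 0
        for _ in range(200):
            table = pd.DataFrame({
                "cell_line": np.repeat(["a", "b", "c"], 10),
                "mean_intensity": rng.normal(100, 10, size=30),
            })
            if compare_intensity(table)["p_overall"] <= 0.05:
                rejections += 1
        assert 0.02 <= rejections / 200 <= 0.08

    def test_small_group_rejected(self):
        table = self.make_table({"a": 100.0, "b": 100.0}, n=2)
        with pytest.raises(ValidationError, match="< 3"):
            compare_intensity(table)
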
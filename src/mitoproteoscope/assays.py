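"""Cell-phenotype assay quantification: galactose growth stress and
masked fluorescence intensity.

Growth: daily resazurin relative-fluorescence (RFU) readings are blanked by
subtracting the plate-and-day mean of the media-only wells, then expressed
relative to the same line-and-condition mean at day 0, giving a dimensionless
growth index that equals 1 at day 0.  A mitochondrial defect shows up as a
depressed index under galactose (glucose-free) medium, worsened by azide.

Imaging: a micrograph is background-corrected by subtracting a low quantile
of its pixels, thresholded (Otsu) into whole-cell masks, and each retained
mask's mean corrected intensity is reported — the superoxide readout.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm

from .core_io import ValidationError

DEFAULT_BACKGROUND_QUANTILE = 0.10
DEFAULT_MIN_AREA = 50


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------


def normalize_growth(growth: pd.DataFrame, per_well: bool = False) -> pd.DataFrame:
    """Blank-subtract and day-0-normalize a long-format growth table.

    Expects columns ``well, cell_line, condition, day, rfu_raw, is_blank``.
    Adds ``rfu_blanked`` (raw minus the mean of the same condition's blank
    wells on the same day) and ``growth_norm`` (blanked RFU relative to the
    day-0 mean of the same line and condition; with ``per_well=True``,
    relative to the same well's own day-0 reading).
    """
    required = {"well", "cell_line", "condition", "day", "rfu_raw", "is_blank"}
    missing = required - set(growth.columns)
    if missing:
        raise ValidationError(f"growth table missing columns: {sorted(missing)}")
    out = growth.copy()
    blanks = out[out["is_blank"]]
    if blanks.empty:
        raise ValidationError("no blank (media-only) wells in the table")
    blank_mean = blanks.groupby(["condition", "day"])["rfu_raw"].mean()
    keys = pd.MultiIndex.from_frame(out[["condition", "day"]])
    if not keys.isin(blank_mean.index).all():
        raise ValidationError("some condition/day has no blank well")
    out["rfu_blanked"] = out["rfu_raw"].to_numpy() - blank_mean.loc[keys].to_numpy()

    cells = out[~out["is_blank"]]
    if per_well:
        day0 = cells[cells["day"] == 0].set_index("well")["rfu_blanked"]
        denom = cells["well"].map(day0)
    else:
        day0 = (
            cells[cells["day"] == 0]
            .groupby(["cell_line", "condition"])["rfu_blanked"]
            .mean()
        )
        denom = pd.Series(
            day0.loc[
                pd.MultiIndex.from_frame(cells[["cell_line", "condition"]])
            ].to_numpy(),
            index=cells.index,
        )
    if (denom <= 0).any():
        bad = cells.loc[denom.index[denom <= 0], ["cell_line", "condition"]]
        raise ValidationError(
            "non-positive day-0 denominator for "
            f"{sorted(set(map(tuple, bad.to_numpy())))}"
        )
    out["growth_norm"] = np.nan
    out.loc[cells.index, "growth_norm"] = cells["rfu_blanked"] / denom
    return out


def compare_growth(
    growth: pd.DataFrame,
    line_a: str,
    line_b: str | list[str],
    condition: str,
) -> dict:
    """Compare growth curves of ``line_a`` against comparator line(s).

    Runs a two-factor fixed-effects ANOVA (line, day, interaction) on
    ``growth_norm`` and per-day contrasts of ``line_a`` vs each comparator.
    With a single comparator the per-day contrasts are Welch t-tests with
    Sidak correction over days; with several comparators, Dunnett's
    many-to-one test is applied per day with ``line_a`` as the reference.

    Returns a dict with ``anova`` (the ANOVA table), ``per_day`` (a
    DataFrame of per-day mean differences and corrected p-values) and the
    headline ``p_line`` / ``p_interaction``.
    """
    comparators = [line_b] if isinstance(line_b, str) else list(line_b)
    lines = [line_a] + comparators
    data = growth[
        (growth["condition"] == condition)
        & (growth["cell_line"].isin(lines))
        & (~growth["is_blank"])
    ].copy()
    if data.empty:
        raise ValidationError(f"no data for lines {lines} under {condition!r}")
    if "growth_norm" not in data or data["growth_norm"].isna().any():
        raise ValidationError("run normalize_growth first")
    counts = data.groupby(["cell_line", "day"]).size()
    if (counts < 2).any():
        raise ValidationError("need >= 2 replicate wells per line and day")
    expected_cells = len(lines) * data["day"].nunique()
    if len(counts) != expected_cells:
        raise ValidationError("unbalanced design: some line/day cell is empty")

    model = ols(
        "growth_norm ~ C(cell_line) * C(day)",
        data=data.rename(columns={"cell_line": "cell_line", "day": "day"}),
    ).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = anova_lm(model, typ=2)

    days = sorted(data["day"].unique())
    per_day_rows = []
    for day in days:
        ref = data[(data["cell_line"] == line_a) & (data["day"] == day)][
            "growth_norm"
        ].to_numpy()
        others = [
            data[(data["cell_line"] == line) & (data["day"] == day)][
                "growth_norm"
            ].to_numpy()
            for line in comparators
        ]
        if len(comparators) == 1:
            t = stats.ttest_ind(ref, others[0], equal_var=False)
            raw = [float(t.pvalue)]
            # Sidak over the family of days
            corrected = [sidak_correct(raw[0], len(days))]
        else:
            d = stats.dunnett(*others, control=ref)
            raw = list(map(float, np.atleast_1d(d.pvalue)))
            corrected = raw  # Dunnett is already family-corrected per day
        for line, other, p_raw, p_corr in zip(comparators, others, raw, corrected):
            per_day_rows.append(
                {
                    "day": day,
                    "comparator": line,
                    "mean_diff": float(np.mean(ref) - np.mean(other)),
                    "p_raw": p_raw,
                    "p_corrected": min(p_corr, 1.0),
                }
            )
    return {
        "anova": table,
        "p_line": float(table.loc["C(cell_line)", "PR(>F)"]),
        "p_day": float(table.loc["C(day)", "PR(>F)"]),
        "p_interaction": float(table.loc["C(cell_line):C(day)", "PR(>F)"]),
        "per_day": pd.DataFrame(per_day_rows),
    }


# ---------------------------------------------------------------------------
# imaging
# ---------------------------------------------------------------------------


def quantify_image(
    image: np.ndarray,
    background_quantile: float = DEFAULT_BACKGROUND_QUANTILE,
    mask_method: str = "otsu",
    min_area: int = DEFAULT_MIN_AREA,
    image_id: str = "image",
    cell_line: str = "",
) -> pd.DataFrame:
    """Background-correct, mask, and measure a single-channel image.

    The image is corrected by subtracting its ``background_quantile``
    quantile (floored at 0), thresholded globally (Otsu) on the corrected
    pixels, and connected components of at least ``min_area`` pixels become
    cells.  Returns one row per retained mask with its area and mean
    corrected intensity; an empty table (with a warning) if nothing passes.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValidationError("quantify_image expects a single-channel 2-D image")
    if mask_method != "otsu":
        raise ValidationError(f"unknown mask_method {mask_method!r}")
    corrected = image - np.quantile(image, background_quantile)
    np.clip(corrected, 0, None, out=corrected)
    if np.allclose(corrected, 0):
        warnings.warn(f"{image_id}: image is constant; no masks", stacklevel=2)
        return _empty_mask_table()
    threshold = threshold_otsu(corrected)
    labels = label(corrected > threshold)
    rows = []
    for idx, region in enumerate(regionprops(labels, intensity_image=corrected)):
        if region.area < min_area:
            continue
        rows.append(
            {
                "image_id": image_id,
                "cell_line": cell_line,
                "cell_index": idx,
                "area_px": int(region.area),
                "mean_intensity": float(region.intensity_mean),
            }
        )
    if not rows:
        warnings.warn(f"{image_id}: no component >= {min_area} px", stacklevel=2)
        return _empty_mask_table()
    return pd.DataFrame(rows)


def _empty_mask_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["image_id", "cell_line", "cell_index", "area_px", "mean_intensity"]
    )


def sidak_correct(p: float, m: int) -> float:
    """Sidak correction of one of ``m`` independent contrasts."""
    return float(1.0 - (1.0 - p) ** m)


def compare_intensity(
    table: pd.DataFrame,
    group_col: str = "cell_line",
    value_col: str = "mean_intensity",
) -> dict:
    """One-way ANOVA over mask intensities with Sidak-corrected pairwise contrasts.

    Requires >= 2 groups with >= 3 masks each.  Returns the overall F-test
    and a DataFrame of all pairwise Welch contrasts with raw and
    Sidak-corrected p-values.
    """
    groups = {g: sub[value_col].to_numpy(dtype=float) for g, sub in table.groupby(group_col)}
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups")
    small = [g for g, v in groups.items() if v.size < 3]
    if small:
        raise ValidationError(f"groups with < 3 masks: {small}")
    names = sorted(groups)
    f_stat, f_p = stats.f_oneway(*(groups[g] for g in names))
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1:]]
    rows = []
    for a, b in pairs:
        t = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "mean_a": float(np.mean(groups[a])),
                "mean_b": float(np.mean(groups[b])),
                "p_raw": float(t.pvalue),
                "p_sidak": sidak_correct(float(t.pvalue), len(pairs)),
            }
        )
    return {
        "f_statistic": float(f_stat),
        "p_overall": float(f_p),
        "group_means": {g: float(np.mean(v)) for g, v in groups.items()},
        "pairwise": pd.DataFrame(rows),
    }
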
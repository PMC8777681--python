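"""Per-protein two-group differential abundance with volcano classification.

Each protein is tested patient vs control on its non-missing log2 values with
a two-sample t-test, after requiring at least two valid values in each group
(the valid-value filter).  Classification follows the volcano geometry:
a protein is "down"/"up" when |log2 difference| >= 1 (two-fold) AND the raw
two-sided p <= 0.05, both comparisons inclusive.  No per-protein multiple
testing correction is applied — significance here is the raw p threshold;
FDR control enters only at the enrichment stage.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AnnotationSet, GroupDesign, QuantMatrix, ValidationError

#: minimum non-missing values per group for a protein to be tested
MIN_VALID_PER_GROUP = 2

#: volcano defaults: two-fold change, raw p 0.05
DEFAULT_FC_LOG2 = 1.0
DEFAULT_P_MAX = 0.05

RESULT_COLUMNS = [
    "mean_log2_patient",
    "mean_log2_control",
    "log2_diff",
    "t_statistic",
    "p_value",
    "n_valid_patient",
    "n_valid_control",
    "class",
]


def differential_test(
    matrix: QuantMatrix,
    design: GroupDesign,
    variant: str = "student",
) -> pd.DataFrame:
    """Two-sample t-test per protein on log2 values.

    Parameters
    ----------
    matrix
        Must be log2-scaled (use :func:`~mitoproteoscope.core_io.log2_transform`).
    variant
        ``"student"`` (pooled-variance, the default of the upstream
        quantification software) or ``"welch"``.

    Returns
    -------
    DataFrame indexed by accession with group means, ``log2_diff``
    (patient minus control), ``t_statistic``, ``p_value``, valid counts and a
    ``class`` column.  Proteins with fewer than two valid values in either
    group get class ``"filtered"`` and NaN statistics; all others start as
    ``"ns"`` until :func:`classify_volcano` assigns down/up.
    """
    if matrix.scale != "log2":
        raise ValidationError("differential_test requires a log2-scaled matrix")
    if variant not in ("student", "welch"):
        raise ValidationError(f"unknown t-test variant {variant!r}")
    design.check_against(matrix)
    if len(design.patient_samples) < 2 or len(design.control_samples) < 2:
        raise ValidationError("each group needs >= 2 samples for a t-test")

    pat = matrix.data[list(design.patient_samples)].to_numpy(dtype=float)
    ctl = matrix.data[list(design.control_samples)].to_numpy(dtype=float)
    n_pat = (~np.isnan(pat)).sum(axis=1)
    n_ctl = (~np.isnan(ctl)).sum(axis=1)
    testable = (n_pat >= MIN_VALID_PER_GROUP) & (n_ctl >= MIN_VALID_PER_GROUP)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_pat = np.nanmean(pat, axis=1)
        mean_ctl = np.nanmean(ctl, axis=1)
        t_stat, p_val = stats.ttest_ind(
            pat, ctl, axis=1, equal_var=(variant == "student"), nan_policy="omit"
        )
    t_stat = np.asarray(t_stat, dtype=float)
    p_val = np.asarray(p_val, dtype=float)
    # degenerate zero-variance proteins: identical groups are a clean null
    # (t = 0, p = 1); separated constant groups are infinitely significant
    degenerate = testable & ~np.isfinite(p_val)
    if degenerate.any():
        diff = mean_pat - mean_ctl
        zero = degenerate & (diff == 0)
        apart = degenerate & (diff != 0)
        t_stat[zero], p_val[zero] = 0.0, 1.0
        t_stat[apart] = np.sign(diff[apart]) * np.inf
        p_val[apart] = 0.0
    t_stat[~testable] = np.nan
    p_val[~testable] = np.nan
    mean_pat[n_pat == 0] = np.nan
    mean_ctl[n_ctl == 0] = np.nan

    result = pd.DataFrame(
        {
            "mean_log2_patient": mean_pat,
            "mean_log2_control": mean_ctl,
            "log2_diff": mean_pat - mean_ctl,
            "t_statistic": t_stat,
            "p_value": p_val,
            "n_valid_patient": n_pat,
            "n_valid_control": n_ctl,
            "class": np.where(testable, "ns", "filtered"),
        },
        index=matrix.data.index.copy(),
    )
    result.attrs["variant"] = variant
    return result


def classify_volcano(
    result: pd.DataFrame,
    fc_log2: float = DEFAULT_FC_LOG2,
    p_max: float = DEFAULT_P_MAX,
) -> pd.DataFrame:
    """Assign down/up/ns classes by the inclusive volcano rule.

    ``down``: log2_diff <= -fc_log2 and p <= p_max; ``up`` symmetric;
    boundary values count as significant.  Filtered rows stay filtered.
    """
    if fc_log2 <= 0 or p_max <= 0:
        raise ValidationError("volcano thresholds must be > 0")
    out = result.copy()
    tested = out["class"] != "filtered"
    sig = tested & (out["p_value"] <= p_max)
    down = sig & (out["log2_diff"] <= -fc_log2)
    up = sig & (out["log2_diff"] >= fc_log2)
    out.loc[tested, "class"] = "ns"
    out.loc[down, "class"] = "down"
    out.loc[up, "class"] = "up"
    out.attrs.update(result.attrs)
    out.attrs["fc_log2"] = fc_log2
    out.attrs["p_max"] = p_max
    out.attrs["n_down"] = int(down.sum())
    out.attrs["n_up"] = int(up.sum())
    return out


def subset_mito(result: pd.DataFrame, annotations: AnnotationSet) -> pd.DataFrame:
    """Restrict a differential table to mitochondrially annotated proteins."""
    keep = result.index.isin(annotations.mito_accessions)
    if not keep.any():
        warnings.warn(
            "no proteins in the result are mitochondrially annotated",
            stacklevel=2,
        )
    out = result.loc[keep].copy()
    out.attrs.update(result.attrs)
    return out


def volcano_table(result: pd.DataFrame) -> pd.DataFrame:
    """Plot-ready volcano coordinates: x = log2_diff, y = -log10 p.

    ``y`` is NaN for filtered rows.  The significance-line constants are
    emitted in ``attrs`` (``x_lines`` at +/- the fold-change threshold,
    ``y_line`` at -log10 of the p threshold, e.g. 1.301 for p = 0.05).
    """
    fc = result.attrs.get("fc_log2", DEFAULT_FC_LOG2)
    p_max = result.attrs.get("p_max", DEFAULT_P_MAX)
    out = pd.DataFrame(
        {
            "x": result["log2_diff"],
            "y": -np.log10(result["p_value"]),
            "class": result["class"],
        },
        index=result.index,
    )
    out.attrs["x_lines"] = (-fc, fc)
    out.attrs["y_line"] = float(-np.log10(p_max))
    return out
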
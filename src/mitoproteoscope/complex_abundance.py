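"""Relative complex abundance (RCA) and structure painting.

RCA summarises a protein complex in one number: for each quantified,
unfiltered subunit i take its patient-minus-control log2 difference d_i; the
complex ratio is the mean of the d_i mapped to the percent scale
(2**mean x 100, i.e. the geometric mean of subunit ratios), with a 95%
confidence interval from the t distribution on n-1 degrees of freedom over
the subunit differences, and a significance p from the one-sample t-test of
{d_i} against 0 — algebraically identical to the paired t-test of
per-subunit patient vs control means.  A healthy complex sits at 100%.

Structure painting writes each mapped chain's protein log2 difference into
the per-atom B-factor (isotropic displacement) column of a mmCIF/PDB file,
clipped to a palette range, so any structure viewer can colour the complex
by abundance change.
"""

from __future__ import annotations

import math
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd
from scipy import stats

from .core_io import ComplexDefinition, ParseError, ValidationError, _read_table

#: significance stars, per the conventional caption map
STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def stars_for_p(p: float) -> str:
    if not np.isfinite(p):
        return "na"
    for threshold, label in STAR_THRESHOLDS:
        if p <= threshold:
            return label
    return "ns"


def rca(
    result: pd.DataFrame,
    complex_defs: list[ComplexDefinition],
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Relative complex abundance per complex definition.

    Parameters
    ----------
    result
        Differential table from :func:`~mitoproteoscope.differential.differential_test`
        (subunits with class ``"filtered"`` are excluded — the same
        valid-value rule as the per-protein stage).
    ci_level
        Confidence level for the t-based interval over subunit differences.

    Returns
    -------
    One row per complex: subunit accounting (``n_members`` defined,
    ``n_subunits_used`` quantified and unfiltered), ``mean_log2_ratio``,
    ``sd_log2``, ``ratio_percent`` with ``ci_low_percent``/``ci_high_percent``,
    the paired-test ``paired_p`` and its ``stars``.  Complexes with fewer
    than two usable subunits carry the point ratio only (CI and p are NaN).
    A complex whose subunit differences are all identical is degenerate
    (sd 0): the CI collapses to the point and p is clamped to 0 with
    ``degenerate_sd=True``.
    """
    if not 0 < ci_level < 1:
        raise ValidationError("ci_level must be in (0, 1)")
    usable = result[result["class"] != "filtered"]
    rows = []
    for d in complex_defs:
        members = sorted(d.member_accessions)
        present = usable.index.intersection(members)
        diffs = usable.loc[present, "log2_diff"].to_numpy(dtype=float)
        diffs = diffs[np.isfinite(diffs)]
        n = diffs.size
        row = {
            "complex_id": d.complex_id,
            "n_members": len(members),
            "n_subunits_used": n,
            "mean_log2_ratio": np.nan,
            "sd_log2": np.nan,
            "ratio_percent": np.nan,
            "ci_low_percent": np.nan,
            "ci_high_percent": np.nan,
            "paired_p": np.nan,
            "stars": "na",
            "degenerate_sd": False,
        }
        if n >= 1:
            mean = float(np.mean(diffs))
            row["mean_log2_ratio"] = mean
            row["ratio_percent"] = 2.0**mean * 100.0
        if n >= 2:
            sd = float(np.std(diffs, ddof=1))
            row["sd_log2"] = sd
            if sd == 0.0:
                row["ci_low_percent"] = row["ci_high_percent"] = row["ratio_percent"]
                row["paired_p"] = 0.0 if mean != 0.0 else 1.0
                row["degenerate_sd"] = True
            else:
                tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df=n - 1)
                half = tcrit * sd / math.sqrt(n)
                row["ci_low_percent"] = 2.0 ** (mean - half) * 100.0
                row["ci_high_percent"] = 2.0 ** (mean + half) * 100.0
                row["paired_p"] = float(stats.ttest_1samp(diffs, 0.0).pvalue)
            row["stars"] = stars_for_p(row["paired_p"])
        rows.append(row)
    out = pd.DataFrame(rows).set_index("complex_id")
    out.attrs["ci_level"] = ci_level
    return out


# ---------------------------------------------------------------------------
# structure painting
# ---------------------------------------------------------------------------


def read_chain_map(path: str | Path) -> dict[str, str]:
    """Read a two-column chain/accession TSV."""
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: need columns chain, accession")
    chain_col, acc_col = raw.columns[:2]
    mapping: dict[str, str] = {}
    for _, row in raw.iterrows():
        if row[chain_col] in mapping:
            raise ParseError(f"{path}: duplicate chain {row[chain_col]!r}")
        mapping[row[chain_col]] = row[acc_col]
    return mapping


def paint_structure(
    result: pd.DataFrame,
    structure_path: str | Path,
    chain_map: dict[str, str],
    palette_range: tuple[float, float] = (-2.0, 2.0),
    out_path: str | Path | None = None,
    sentinel: float = 0.0,
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Write per-protein log2 differences into a structure's B-factor column.

    Every atom of a chain mapped to a quantified, unfiltered protein receives
    that protein's ``log2_diff`` clipped to ``palette_range``; atoms of
    unmapped chains receive ``sentinel``.  Chains listed in ``chain_map`` but
    absent from the structure are an error; mapped chains whose accession is
    missing from (or filtered in) the differential table are reported
    unmapped.

    Returns the per-residue table (chain, residue number, painted value,
    mapped flag) and an {chain: reason} report of unmapped chains.
    """
    lo, hi = palette_range
    if not lo < hi:
        raise ValidationError("palette_range must be (lo, hi) with lo < hi")
    structure = gemmi.read_structure(str(structure_path))
    model = structure[0]
    chain_names = {chain.name for chain in model}
    missing = sorted(set(chain_map) - chain_names)
    if missing:
        raise ValidationError(
            f"chains in map absent from structure: {missing} "
            f"(structure has {sorted(chain_names)})"
        )

    usable = result[result["class"] != "filtered"]
    records = []
    unmapped: dict[str, str] = {}
    for chain in model:
        accession = chain_map.get(chain.name)
        if accession is None:
            value, mapped = sentinel, False
            unmapped[chain.name] = "not in chain map"
        elif accession not in result.index:
            value, mapped = sentinel, False
            unmapped[chain.name] = f"accession {accession!r} not quantified"
        elif accession not in usable.index:
            value, mapped = sentinel, False
            unmapped[chain.name] = f"accession {accession!r} filtered"
        else:
            value = float(np.clip(usable.loc[accession, "log2_diff"], lo, hi))
            mapped = True
        for residue in chain:
            for atom in residue:
                atom.b_iso = value
            records.append(
                {
                    "chain": chain.name,
                    "residue": residue.seqid.num,
                    "value": value,
                    "mapped": mapped,
                }
            )

    if out_path is not None:
        out_path = Path(out_path)
        structure.setup_entities()
        if out_path.suffix.lower() == ".cif":
            structure.make_mmcif_document().write_file(str(out_path))
        else:
            structure.write_pdb(str(out_path))
    return pd.DataFrame(records), unmapped
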
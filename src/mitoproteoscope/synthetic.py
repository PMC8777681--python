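"""Synthetic inputs with the statistical structure the analysis assumes.

The generators emulate the study's four raw inputs so every downstream stage
is testable offline: (1) a ~5000-protein log-normal DIA abundance matrix for
3 patient replicates vs 5 singleton controls, with configurable per-complex
depletion, extra random up/down proteins and missing values; (2) flat
annotation sets over the same protein universe; (3) resazurin plate-reader
growth tables; (4) grayscale fluorescence images with disc-shaped cells.

Everything is driven by an explicit integer seed and is bit-reproducible:
identical seeds give identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    AnnotationSet,
    ComplexDefinition,
    GroupDesign,
    QuantMatrix,
    ValidationError,
    default_complex_definitions,
)

# ---------------------------------------------------------------------------
# profiles / designs
# ---------------------------------------------------------------------------


@dataclass
class DiseaseProfile:
    """What the disease does to the proteome, in generator terms.

    ``complex_scalings`` multiplies the linear patient-group mean of every
    member of the named complex (e.g. ``{"CI": 0.70}`` depletes complex I to
    70% of control).  Complexes not named keep factor 1.0.  ``n_extra_down`` /
    ``n_extra_up`` additional non-complex proteins receive a +/-
    ``extra_effect_log2`` shift, emulating the broader proteome response.
    ``replicate_cv`` is the multiplicative within-group coefficient of
    variation; ``missing_rate`` the overall fraction of missing cells.

    The defaults are the package's reference disease fixture: complex I at
    70%, mitoribosome LSU at 60% and SSU at 75% of control, 200 extra down /
    60 extra up proteins at 1.5 log2 units, 5% missingness, 15% CV.
    """

    complex_scalings: dict[str, float] = field(
        default_factory=lambda: {"CI": 0.70, "LSU": 0.60, "SSU": 0.75}
    )
    n_extra_down: int = 200
    n_extra_up: int = 60
    extra_effect_log2: float = 1.5
    missing_rate: float = 0.05
    replicate_cv: float = 0.15

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.complex_scalings.values()):
            raise ValidationError("complex scaling factors must be > 0")
        if self.n_extra_down < 0 or self.n_extra_up < 0:
            raise ValidationError("extra-protein counts must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.replicate_cv < 0:
            raise ValidationError("replicate_cv must be >= 0")


def null_profile() -> DiseaseProfile:
    """A profile with no effects at all (for calibration runs)."""
    return DiseaseProfile(
        complex_scalings={}, n_extra_down=0, n_extra_up=0, missing_rate=0.0
    )


def default_design() -> GroupDesign:
    """3 patient replicates vs 5 singleton controls."""
    return GroupDesign(
        patient_samples=("patient_1", "patient_2", "patient_3"),
        control_samples=tuple(f"control_{i}" for i in range(1, 6)),
    )


@dataclass
class PlateDesign:
    """Layout of a resazurin growth plate."""

    cell_lines: tuple[str, ...] = ("patient", "control_A", "control_B")
    conditions: tuple[str, ...] = ("glucose", "galactose", "galactose+azide")
    days: tuple[int, ...] = (0, 1, 2, 3, 4)
    wells_per_line: int = 6
    n_blank_wells: int = 3

    def __post_init__(self) -> None:
        if self.n_blank_wells < 1:
            raise ValidationError("need >= 1 blank well per plate")
        if list(self.days) != sorted(self.days) or self.days[0] != 0:
            raise ValidationError("days must be ascending and start at 0")


@dataclass
class ImageDesign:
    """Layout of a synthetic fluorescence micrograph."""

    shape: tuple[int, int] = (256, 256)
    n_cells: int = 8
    cell_radius: int = 14
    intensity: dict[str, float] = field(
        default_factory=lambda: {"patient": 400.0, "control": 200.0}
    )
    background: float = 20.0
    noise_sd: float = 4.0

    def __post_init__(self) -> None:
        if any(v <= self.background for v in self.intensity.values()):
            raise ValidationError("cell intensities must exceed the background")


# ---------------------------------------------------------------------------
# quant matrix
# ---------------------------------------------------------------------------

#: baseline log2 abundance distribution — a typical MS2 dynamic-range
#: stand-in; only relative quantities matter downstream.
BASELINE_LOG2_MEAN = 20.0
BASELINE_LOG2_SD = 2.0


def protein_universe(
    n_proteins: int, complex_defs: list[ComplexDefinition]
) -> list[str]:
    """The synthetic accession universe: complex members first, then fillers."""
    members: list[str] = []
    seen: set[str] = set()
    for d in complex_defs:
        for acc in sorted(d.member_accessions):
            if acc not in seen:
                members.append(acc)
                seen.add(acc)
    if n_proteins < len(members):
        raise ValidationError(
            f"n_proteins={n_proteins} < {len(members)} complex members"
        )
    fillers = [f"SYN{i:05d}" for i in range(n_proteins - len(members))]
    return members + fillers


def generate_quant_matrix(
    n_proteins: int,
    design: GroupDesign | None = None,
    profile: DiseaseProfile | None = None,
    seed: int = 0,
    complex_defs: list[ComplexDefinition] | None = None,
    mnar: bool = False,
    mnar_quantile: float = 0.25,
) -> tuple[QuantMatrix, pd.DataFrame]:
    """Generate a linear-scale quant matrix plus its ground-truth table.

    Per-protein baseline log2 means are drawn Normal(20, 2).  The patient
    group's linear mean is multiplied by the profile factor of the protein's
    complex (1.0 if none) and by ``2**(+/-extra_effect_log2)`` for the
    sampled extra proteins (complex members are excluded from the extra
    pool).  Within-group noise is multiplicative log-normal with the stated
    CV.  Missingness is injected uniformly at ``missing_rate`` (missing at
    random); with ``mnar=True`` cells in the lowest ``mnar_quantile`` of
    abundance are three times as likely to drop out, at the same overall
    rate, emulating low-abundance dropout.

    Returns the matrix and a truth table with one row per protein:
    ``accession``, ``true_log2_effect`` (patient minus control) and
    ``complex_id`` ("" for proteins outside any complex).
    """
    design = design or default_design()
    profile = profile or DiseaseProfile()
    complex_defs = complex_defs if complex_defs is not None else default_complex_definitions()
    known = {d.complex_id for d in complex_defs}
    unknown = set(profile.complex_scalings) - known
    if unknown:
        raise ValidationError(
            f"profile references complexes absent from definitions: {sorted(unknown)}"
        )

    rng = np.random.default_rng(seed)
    proteins = protein_universe(n_proteins, complex_defs)
    acc_to_complex: dict[str, str] = {}
    for d in complex_defs:
        for acc in d.member_accessions:
            acc_to_complex.setdefault(acc, d.complex_id)

    baseline_log2 = rng.normal(BASELINE_LOG2_MEAN, BASELINE_LOG2_SD, size=n_proteins)

    effect_log2 = np.zeros(n_proteins)
    complex_ids = np.array([acc_to_complex.get(p, "") for p in proteins], dtype=object)
    for i, p in enumerate(proteins):
        cid = acc_to_complex.get(p)
        if cid is not None and cid in profile.complex_scalings:
            effect_log2[i] = math.log2(profile.complex_scalings[cid])

    non_complex = np.array(
        [i for i, p in enumerate(proteins) if p not in acc_to_complex]
    )
    n_extra = profile.n_extra_down + profile.n_extra_up
    if n_extra > len(non_complex):
        raise ValidationError("not enough non-complex proteins for the extra pool")
    if n_extra:
        extra = rng.choice(non_complex, size=n_extra, replace=False)
        effect_log2[extra[: profile.n_extra_down]] = -profile.extra_effect_log2
        effect_log2[extra[profile.n_extra_down:]] = profile.extra_effect_log2

    n_pat = len(design.patient_samples)
    n_ctl = len(design.control_samples)
    n_samples = n_pat + n_ctl
    # multiplicative log-normal noise with E[factor] = 1 at the stated CV
    sigma = math.sqrt(math.log(1.0 + profile.replicate_cv**2))
    noise = rng.normal(-0.5 * sigma**2, sigma, size=(n_proteins, n_samples))
    mean_log2 = np.tile(baseline_log2[:, None], (1, n_samples)).astype(float)
    mean_log2[:, :n_pat] += effect_log2[:, None]
    values = np.exp2(mean_log2) * np.exp(noise)

    if profile.missing_rate > 0:
        if mnar:
            q = np.quantile(values, mnar_quantile)
            low = values < q
            rate_low = min(3.0 * profile.missing_rate, 0.9)
            rate_high = max(
                (profile.missing_rate - mnar_quantile * rate_low)
                / (1.0 - mnar_quantile),
                0.0,
            )
            p_miss = np.where(low, rate_low, rate_high)
        else:
            p_miss = np.full(values.shape, profile.missing_rate)
        values[rng.random(values.shape) < p_miss] = np.nan

    data = pd.DataFrame(
        values,
        index=pd.Index(proteins, name="accession"),
        columns=list(design.all_samples),
    )
    truth = pd.DataFrame(
        {
            "accession": proteins,
            "true_log2_effect": effect_log2,
            "complex_id": complex_ids,
        }
    )
    return QuantMatrix(data=data, scale="linear"), truth


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def generate_annotations(
    n_proteins: int,
    complex_defs: list[ComplexDefinition] | None = None,
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (10, 40),
    seed: int = 0,
    mito_extra_fraction: float = 0.05,
) -> AnnotationSet:
    """Random flat terms over the synthetic universe, plus the complexes.

    Every complex is also emitted as a term with identical membership, so
    enrichment can rediscover planted complexes among the random decoys.
    The mitochondrial set contains all complex members plus a random
    ``mito_extra_fraction`` of the remaining universe (MitoCarta-style).
    """
    complex_defs = complex_defs if complex_defs is not None else default_complex_definitions()
    rng = np.random.default_rng(seed)
    proteins = np.array(protein_universe(n_proteins, complex_defs), dtype=object)
    lo, hi = term_size_range
    if lo < 1:
        raise ValidationError("term sizes must be >= 1")
    if hi > n_proteins:
        raise ValidationError("term_size_range exceeds the protein universe")

    membership: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        term = f"TERM{i:04d}"
        membership[term] = frozenset(rng.choice(proteins, size=size, replace=False))
        names[term] = f"random term {i}"
    for d in complex_defs:
        membership[d.complex_id] = frozenset(d.member_accessions)
        names[d.complex_id] = f"complex {d.complex_id}"

    complex_members = {acc for d in complex_defs for acc in d.member_accessions}
    rest = np.array(sorted(set(proteins) - complex_members), dtype=object)
    n_extra = int(round(mito_extra_fraction * len(rest)))
    extra = rng.choice(rest, size=n_extra, replace=False) if n_extra else []
    mito = frozenset(complex_members) | frozenset(extra)
    return AnnotationSet(
        mito_accessions=mito, term_membership=membership, term_names=names
    )


# ---------------------------------------------------------------------------
# growth plates
# ---------------------------------------------------------------------------


def generate_growth_plate(
    design: PlateDesign | None = None,
    growth_params: dict[tuple[str, str], tuple[float, float]] | None = None,
    blank_rfu: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a resazurin plate: RFU = blank + capacity*logistic(rate*day).

    ``growth_params`` maps (cell line, condition) to (rate, capacity); any
    pair not listed defaults to rate 1.0, capacity 1000.  Blank (media-only)
    wells read ``blank_rfu`` plus noise.  Returns a long-format table with
    columns well, cell_line, condition, day, rfu_raw, is_blank.
    """
    design = design or PlateDesign()
    growth_params = growth_params or {}
    rng = np.random.default_rng(seed)
    rows: list[dict] = []
    for condition in design.conditions:
        for line in design.cell_lines:
            rate, capacity = growth_params.get((line, condition), (1.0, 1000.0))
            if capacity <= 0:
                raise ValidationError(
                    f"capacity must be > 0 for ({line}, {condition})"
                )
            for w in range(design.wells_per_line):
                well = f"{line}|{condition}|w{w}"
                for day in design.days:
                    signal = capacity / (1.0 + math.exp(-rate * day))
                    rows.append(
                        {
                            "well": well,
                            "cell_line": line,
                            "condition": condition,
                            "day": int(day),
                            "rfu_raw": blank_rfu + signal + rng.normal(0, noise_sd),
                            "is_blank": False,
                        }
                    )
        for b in range(design.n_blank_wells):
            well = f"blank|{condition}|w{b}"
            for day in design.days:
                rows.append(
                    {
                        "well": well,
                        "cell_line": "blank",
                        "condition": condition,
                        "day": int(day),
                        "rfu_raw": blank_rfu + rng.normal(0, noise_sd),
                        "is_blank": True,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# intensity images
# ---------------------------------------------------------------------------


def generate_intensity_image(
    design: ImageDesign | None = None,
    group: str = "control",
    seed: int = 0,
    max_tries: int = 2000,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """A constant background with non-overlapping disc 'cells' plus noise.

    Returns the float image and one boolean truth mask per placed cell.
    Raises after ``max_tries`` failed placements.
    """
    design = design or ImageDesign()
    if group not in design.intensity:
        raise ValidationError(f"unknown group {group!r}")
    rng = np.random.default_rng(seed)
    h, w = design.shape
    r = design.cell_radius
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.full((h, w), design.background, dtype=float)
    masks: list[np.ndarray] = []
    centers: list[tuple[int, int]] = []
    tries = 0
    while len(masks) < design.n_cells:
        tries += 1
        if tries > max_tries:
            raise ValidationError(
                f"could not place {design.n_cells} cells of radius {r} "
                f"in a {h}x{w} image after {max_tries} tries"
            )
        cy = int(rng.integers(r, h - r))
        cx = int(rng.integers(r, w - r))
        if any((cy - y) ** 2 + (cx - x) ** 2 < (2 * r + 2) ** 2 for y, x in centers):
            continue
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        img[mask] = design.intensity[group]
        masks.append(mask)
        centers.append((cy, cx))
    if design.noise_sd > 0:
        img = img + rng.normal(0, design.noise_sd, size=img.shape)
    return np.clip(img, 0, None), masks
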
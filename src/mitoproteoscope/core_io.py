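"""Domain containers and tab-separated readers/writers shared by every stage.

The pipeline's substrate is a protein x sample abundance matrix as exported by
DIA search software (linear MS2-style quantities, missing cells allowed),
together with a two-group sample design, flat annotation sets (mitochondrial
membership, term membership), and protein-complex definitions.

All tables are UTF-8, tab-separated, with a mandatory header row.  Files
written by this package start with a comment line ``# mitoproteoscope vX``
which is ignored on read.  Missing values are written as empty cells and
``""``, ``"NA"`` and ``"NaN"`` are accepted on read (common exporter
dialects).  Accession matching everywhere is exact string equality; no
isoform stripping is attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__

COMMENT_HEADER = f"# mitoproteoscope v{__version__}"

#: canonical OXPHOS / mitoribosome complex identifiers; user-defined ids are
#: also accepted by ComplexDefinition.
KNOWN_COMPLEXES = ("CI", "CII", "CIII", "CIV", "CV", "LSU", "SSU")

_MISSING_TOKENS = ("", "NA", "NaN", "nan")


class ParseError(ValueError):
    """A table could not be parsed; message names the offending row/column."""


class ValidationError(ValueError):
    """A parsed table violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class QuantMatrix:
    """Protein x sample abundance matrix.

    Parameters
    ----------
    data
        DataFrame indexed by unique protein accessions with unique sample-id
        columns.  NaN encodes a missing quantification.
    scale
        ``"linear"`` (raw MS2-style quantities, all non-missing values > 0)
        or ``"log2"``.  The transform is recorded exactly once so it cannot
        be applied twice.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValidationError(f"unknown scale {self.scale!r}")
        idx = self.data.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate protein accession {dup!r}")
        cols = self.data.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValidationError(f"duplicate sample id {dup!r}")
        values = self.data.to_numpy(dtype=float)
        if self.scale == "linear" and np.any(values[np.isfinite(values)] <= 0):
            r, c = np.argwhere(np.isfinite(values) & (values <= 0))[0]
            raise ValidationError(
                f"linear abundance must be > 0; offending cell "
                f"({idx[r]!r}, {cols[c]!r}) = {values[r, c]}"
            )

    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_missing(self) -> int:
        return int(self.data.isna().sum().sum())


@dataclass(frozen=True)
class GroupDesign:
    """Assignment of samples to the patient and control groups."""

    patient_samples: tuple[str, ...]
    control_samples: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.patient_samples or not self.control_samples:
            raise ValidationError("both groups must be non-empty")
        overlap = set(self.patient_samples) & set(self.control_samples)
        if overlap:
            raise ValidationError(f"samples in both groups: {sorted(overlap)}")

    @property
    def all_samples(self) -> tuple[str, ...]:
        return self.patient_samples + self.control_samples

    def check_against(self, matrix: QuantMatrix) -> None:
        unknown = set(self.all_samples) - set(matrix.sample_ids)
        if unknown:
            raise ValidationError(f"design samples absent from matrix: {sorted(unknown)}")


@dataclass
class AnnotationSet:
    """Flat annotation sets: mitochondrial membership and term membership."""

    mito_accessions: frozenset[str] = frozenset()
    term_membership: dict[str, frozenset[str]] = field(default_factory=dict)
    term_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, members in self.term_membership.items():
            if not members:
                raise ValidationError(f"term {term!r} has no members")


@dataclass(frozen=True)
class ComplexDefinition:
    """A named protein complex (e.g. OXPHOS CI or the mitoribosome LSU)."""

    complex_id: str
    member_accessions: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_accessions:
            raise ValidationError(f"complex {self.complex_id!r} has no members")


# ---------------------------------------------------------------------------
# quant matrix IO
# ---------------------------------------------------------------------------


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    return pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype=str,
        keep_default_na=False,
        encoding="utf-8",
    )


def read_quant_matrix(path: str | Path, scale: str = "linear") -> QuantMatrix:
    """Read a wide TSV (first column = accession, header = sample ids)."""
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: need an accession column plus >=1 sample column")
    acc_col = raw.columns[0]
    accessions = raw[acc_col].astype(str)
    dup = accessions[accessions.duplicated()]
    if not dup.empty:
        raise ParseError(f"{path}: duplicate accession {dup.iloc[0]!r}")

    def parse_cell(cell: str, acc: str, sample: str) -> float:
        if cell in _MISSING_TOKENS:
            return math.nan
        try:
            return float(cell)
        except ValueError:
            raise ParseError(
                f"{path}: non-numeric value {cell!r} at row {acc!r}, column {sample!r}"
            ) from None

    samples = list(raw.columns[1:])
    values = {
        sample: [
            parse_cell(cell, acc, sample)
            for acc, cell in zip(accessions, raw[sample])
        ]
        for sample in samples
    }
    data = pd.DataFrame(values, index=pd.Index(accessions, name="accession"))
    return QuantMatrix(data=data, scale=scale)


def write_quant_matrix(matrix: QuantMatrix, path: str | Path) -> None:
    """Write a wide TSV; round-trips finite values bit-identically."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(COMMENT_HEADER + "\n")
        fh.write("accession\t" + "\t".join(matrix.sample_ids) + "\n")
        for acc, row in matrix.data.iterrows():
            cells = ["" if math.isnan(v) else repr(float(v)) for v in row]
            fh.write(str(acc) + "\t" + "\t".join(cells) + "\n")


def log2_transform(matrix: QuantMatrix) -> QuantMatrix:
    """Log2-transform a linear matrix; missing stays missing.

    Guards against a double transform: a matrix already on the log2 scale is
    rejected rather than silently transformed again.
    """
    if matrix.scale != "linear":
        raise ValidationError("matrix is already log2-scaled (double-transform guard)")
    return QuantMatrix(data=np.log2(matrix.data), scale="log2")


# ---------------------------------------------------------------------------
# design / annotation / complex IO
# ---------------------------------------------------------------------------


def read_design(path: str | Path) -> GroupDesign:
    """Read a two-column sample/group TSV; groups must be patient|control."""
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: need columns sample, group")
    sample_col, group_col = raw.columns[:2]
    patients, controls = [], []
    for _, row in raw.iterrows():
        group = row[group_col].strip().lower()
        if group == "patient":
            patients.append(row[sample_col])
        elif group == "control":
            controls.append(row[sample_col])
        else:
            raise ParseError(
                f"{path}: unknown group {row[group_col]!r} for sample "
                f"{row[sample_col]!r} (expected patient|control)"
            )
    return GroupDesign(tuple(patients), tuple(controls))


def write_design(design: GroupDesign, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(COMMENT_HEADER + "\nsample\tgroup\n")
        for s in design.patient_samples:
            fh.write(f"{s}\tpatient\n")
        for s in design.control_samples:
            fh.write(f"{s}\tcontrol\n")


def read_annotations(
    term_path: str | Path | None = None,
    mito_path: str | Path | None = None,
) -> AnnotationSet:
    """Read annotation tables.

    ``term_path``: two-column accession/term TSV (optional third column with a
    human-readable term name).  ``mito_path``: one-column accession list of
    mitochondrially localized proteins (MitoCarta-style).
    """
    mito: frozenset[str] = frozenset()
    membership: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    if mito_path is not None:
        raw = _read_table(mito_path)
        mito = frozenset(raw[raw.columns[0]].astype(str))
    if term_path is not None:
        raw = _read_table(term_path)
        if raw.shape[1] < 2:
            raise ParseError(f"{term_path}: need columns accession, term")
        acc_col, term_col = raw.columns[:2]
        name_col = raw.columns[2] if raw.shape[1] > 2 else None
        for _, row in raw.iterrows():
            term = row[term_col]
            membership.setdefault(term, set()).add(row[acc_col])
            if name_col is not None and row[name_col]:
                names[term] = row[name_col]
    return AnnotationSet(
        mito_accessions=mito,
        term_membership={t: frozenset(m) for t, m in membership.items()},
        term_names=names,
    )


def write_annotations(annotations: AnnotationSet, term_path: str | Path,
                      mito_path: str | Path | None = None) -> None:
    with Path(term_path).open("w", encoding="utf-8") as fh:
        fh.write(COMMENT_HEADER + "\naccession\tterm\tname\n")
        for term in sorted(annotations.term_membership):
            name = annotations.term_names.get(term, "")
            for acc in sorted(annotations.term_membership[term]):
                fh.write(f"{acc}\t{term}\t{name}\n")
    if mito_path is not None:
        with Path(mito_path).open("w", encoding="utf-8") as fh:
            fh.write(COMMENT_HEADER + "\naccession\n")
            for acc in sorted(annotations.mito_accessions):
                fh.write(acc + "\n")


def read_complex_definitions(path: str | Path) -> list[ComplexDefinition]:
    """Read a two-column accession/complex TSV."""
    raw = _read_table(path)
    if raw.shape[1] < 2:
        raise ParseError(f"{path}: need columns accession, complex")
    acc_col, cpx_col = raw.columns[:2]
    members: dict[str, set[str]] = {}
    order: list[str] = []
    for _, row in raw.iterrows():
        cid = row[cpx_col]
        if cid not in members:
            members[cid] = set()
            order.append(cid)
        members[cid].add(row[acc_col])
    return [ComplexDefinition(cid, frozenset(members[cid])) for cid in order]


def write_complex_definitions(defs: list[ComplexDefinition], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write(COMMENT_HEADER + "\naccession\tcomplex\n")
        for d in defs:
            for acc in sorted(d.member_accessions):
                fh.write(f"{acc}\t{d.complex_id}\n")


def default_complex_definitions() -> list[ComplexDefinition]:
    """The bundled OXPHOS CI-CV + mitoribosome LSU/SSU definitions.

    Gene content is configuration, not code: the TSV under
    ``mitoproteoscope/data`` can be edited or replaced by the user.
    """
    path = Path(__file__).parent / "data" / "oxphos_mitoribosome_complexes.tsv"
    return read_complex_definitions(path)
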
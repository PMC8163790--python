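"""Domain types and file readers/writers shared by all pipeline stages.

The pipeline's contract starts at integrated peak areas: a long-format
transition table with one row per sample x peptide carrying the light
(endogenous) and heavy (spiked internal standard) peak areas.  Raw
chromatograms, peak integration and vendor formats are out of scope.

All tabular outputs are plain CSV/TSV with a one-line ``#`` provenance
header naming the tool version; readers skip comment lines.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__

ROLES = frozenset({"study", "pooled_reference", "calibration_standard", "curve_qc"})
#: roles whose rows must carry a nominal (known, spiked) concentration
ROLES_WITH_NOMINAL = frozenset({"calibration_standard", "curve_qc"})

CENSOR_FLAGS = ("in_range", "below_lloq", "above_uloq", "missing")

TRANSITION_COLUMNS = [
    "sample_id",
    "protein_id",
    "peptide_id",
    "light_area",
    "heavy_area",
    "plate_id",
    "role",
    "nominal_conc",
]


class FormatError(ValueError):
    """Malformed input file (missing column, bad shape, bad line)."""


class ValidationError(ValueError):
    """Well-formed file whose content violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransitionRecord:
    """One light/heavy peak-area measurement for one peptide in one sample."""

    sample_id: str
    protein_id: str
    peptide_id: str
    light_area: float
    heavy_area: float
    plate_id: str
    role: str
    nominal_conc: float | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(f"unknown role {self.role!r}")
        if not self.heavy_area > 0:
            raise ValidationError(
                f"heavy_area must be > 0, got {self.heavy_area!r} "
                f"(sample {self.sample_id}, peptide {self.peptide_id})"
            )
        if self.light_area < 0:
            raise ValidationError(
                f"light_area must be >= 0, got {self.light_area!r}"
            )
        needs_nominal = self.role in ROLES_WITH_NOMINAL
        has_nominal = self.nominal_conc is not None and not (
            isinstance(self.nominal_conc, float) and math.isnan(self.nominal_conc)
        )
        if needs_nominal and not has_nominal:
            raise ValidationError(
                f"role {self.role!r} requires nominal_conc "
                f"(sample {self.sample_id}, peptide {self.peptide_id})"
            )
        if not needs_nominal and has_nominal:
            raise ValidationError(
                f"role {self.role!r} must not carry nominal_conc "
                f"(sample {self.sample_id})"
            )

    @property
    def ratio(self) -> float:
        """Endogenous/heavy (light/heavy) peak-area ratio."""
        return self.light_area / self.heavy_area


@dataclass(frozen=True)
class AssayDefinition:
    """One validated MRM assay: protein, surrogate peptide and its range.

    By convention the heavy internal standard is spiked at 100x the assay
    LLOQ and the calibration curve spans 1-1000x LLOQ, so ``heavy_spike``
    and ``uloq`` default accordingly.
    """

    protein_id: str
    peptide_id: str
    lloq: float
    heavy_spike: float | None = None
    uloq: float | None = None

    def __post_init__(self) -> None:
        if not self.lloq > 0:
            raise ValidationError(f"lloq must be > 0 for {self.protein_id}")
        if self.heavy_spike is None:
            object.__setattr__(self, "heavy_spike", 100.0 * self.lloq)
        if self.uloq is None:
            object.__setattr__(self, "uloq", 1000.0 * self.lloq)
        if not (self.lloq < self.heavy_spike < self.uloq):
            raise ValidationError(
                f"require lloq < heavy_spike < uloq for {self.protein_id}: "
                f"{self.lloq}, {self.heavy_spike}, {self.uloq}"
            )


@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    strain: str
    zygosity: str  # HOM | HET | WT
    sex: str  # F | M
    plate_id: str

    def __post_init__(self) -> None:
        if self.zygosity not in ("HOM", "HET", "WT"):
            raise ValidationError(f"bad zygosity {self.zygosity!r}")
        if self.sex not in ("F", "M"):
            raise ValidationError(f"bad sex {self.sex!r}")


@dataclass
class ConcentrationMatrix:
    """Samples x proteins grid of concentrations (fmol/uL) with censor flags.

    ``values`` holds the uncensored back-calculated number even when the
    flag records ``below_lloq``/``above_uloq``; a NaN value always pairs
    with flag ``missing`` and vice versa.
    """

    values: pd.DataFrame
    flags: pd.DataFrame

    def __post_init__(self) -> None:
        v, f = self.values, self.flags
        if v.shape != f.shape or list(v.index) != list(f.index) or list(
            v.columns
        ) != list(f.columns):
            raise ValidationError("values and flags grids are not congruent")
        bad = set(np.unique(f.to_numpy())) - set(CENSOR_FLAGS)
        if bad:
            raise ValidationError(f"unknown censor flags {sorted(bad)}")
        miss_v = v.isna().to_numpy()
        miss_f = (f == "missing").to_numpy()
        if not np.array_equal(miss_v, miss_f):
            raise ValidationError("value missing iff flag == 'missing' violated")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def proteins(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "ConcentrationMatrix":
        return ConcentrationMatrix(self.values.copy(), self.flags.copy())


@dataclass(frozen=True)
class PanelDefinition:
    """A named set of marker proteins (e.g. erythrocyte contaminants)."""

    name: str
    member_protein_ids: frozenset[str]
    origin: str  # erythrocyte | platelet | user

    def __post_init__(self) -> None:
        if not self.member_protein_ids:
            raise ValidationError(f"panel {self.name!r} is empty")
        if self.origin not in ("erythrocyte", "platelet", "user"):
            raise ValidationError(f"bad panel origin {self.origin!r}")


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    sets: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for s in self.sets.values():
            if not s.members:
                raise ValidationError(f"gene set {s.name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_table(path: str | Path, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, comment="#", dtype=str, keep_default_na=False)


def _require_columns(df: pd.DataFrame, needed: Sequence[str], path: str | Path) -> None:
    for col in needed:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")


def read_assay_table(path: str | Path) -> list[AssayDefinition]:
    """Read the assay-definition CSV (protein, peptide, LLOQ, optional spike/ULOQ)."""
    df = _read_table(path, ",")
    _require_columns(df, ["protein_id", "peptide_id", "lloq"], path)
    out = []
    for i, row in df.iterrows():
        out.append(
            AssayDefinition(
                protein_id=row["protein_id"],
                peptide_id=row["peptide_id"],
                lloq=float(row["lloq"]),
                heavy_spike=float(row["heavy_spike"])
                if "heavy_spike" in df.columns and row["heavy_spike"] != ""
                else None,
                uloq=float(row["uloq"])
                if "uloq" in df.columns and row["uloq"] != ""
                else None,
            )
        )
    seen: dict[str, str] = {}
    for a in out:
        if a.protein_id in seen and seen[a.protein_id] != a.peptide_id:
            raise ValidationError(
                f"{path}: protein {a.protein_id} maps to multiple surrogate "
                "peptides; one surrogate per protein is required"
            )
        seen[a.protein_id] = a.peptide_id
    return out


def write_assay_table(assays: Iterable[AssayDefinition], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(a) for a in assays])
    _write_with_header(df, path, sep=",")


def read_transition_table(
    path: str | Path, assay_definitions: Iterable[AssayDefinition]
) -> list[TransitionRecord]:
    """Read a long-format transition TSV and validate against the assays.

    Every (protein, peptide) pair must match a known assay; one surrogate
    peptide per protein is enforced.  Errors cite the offending column or
    row number (1-based, excluding the header).
    """
    df = _read_table(path, "\t")
    _require_columns(df, TRANSITION_COLUMNS[:-1], path)  # nominal_conc may be absent
    if "nominal_conc" not in df.columns:
        df["nominal_conc"] = ""
    by_protein = {a.protein_id: a for a in assay_definitions}
    records: list[TransitionRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        assay = by_protein.get(row.protein_id)
        if assay is None:
            raise ValidationError(f"{path}: row {i}: unknown protein {row.protein_id!r}")
        if row.peptide_id != assay.peptide_id:
            raise ValidationError(
                f"{path}: row {i}: peptide {row.peptide_id!r} does not match "
                f"assay surrogate {assay.peptide_id!r} for {row.protein_id}"
            )
        try:
            records.append(
                TransitionRecord(
                    sample_id=row.sample_id,
                    protein_id=row.protein_id,
                    peptide_id=row.peptide_id,
                    light_area=float(row.light_area),
                    heavy_area=float(row.heavy_area),
                    plate_id=row.plate_id,
                    role=row.role,
                    nominal_conc=float(row.nominal_conc)
                    if row.nominal_conc != ""
                    else None,
                )
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return records


def records_to_frame(records: Iterable[TransitionRecord]) -> pd.DataFrame:
    """Long DataFrame view of transition records (vectorised pipeline input)."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    if df.empty:
        df = pd.DataFrame(columns=TRANSITION_COLUMNS)
    return df


def write_transition_table(frame: pd.DataFrame, path: str | Path) -> None:
    df = frame.copy()
    _write_with_header(df[TRANSITION_COLUMNS], path, sep="\t")


def _fmt(x: float) -> str:
    return "" if pd.isna(x) else format(float(x), ".12g")


def _write_with_header(df: pd.DataFrame, path: str | Path, sep: str) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# proteotype v{__version__}\n")
        df.to_csv(fh, sep=sep, index=False, float_format="%.12g")


def write_concentration_matrix(matrix: ConcentrationMatrix, path: str | Path) -> None:
    """Write a matrix as wide CSV: value columns, then a parallel flag block.

    Flag columns carry the ``::flag`` suffix; missing values are empty
    cells paired with flag ``missing``.  Values print with 12 significant
    digits so write-then-read is the identity.
    """
    v, f = matrix.values, matrix.flags
    flag_block = f.copy()
    flag_block.columns = [f"{p}::flag" for p in f.columns]
    out = pd.concat([v.map(_fmt), flag_block], axis=1)
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            f"# proteotype v{__version__} concentration matrix; fmol/uL; "
            "columns '<protein>::flag' hold censor flags "
            "(in_range|below_lloq|above_uloq|missing)\n"
        )
        out.to_csv(fh, index_label="sample_id")


def read_concentration_matrix(path: str | Path) -> ConcentrationMatrix:
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing column 'sample_id'")
    df = df.set_index("sample_id")
    flag_cols = [c for c in df.columns if c.endswith("::flag")]
    value_cols = [c for c in df.columns if not c.endswith("::flag")]
    if [f"{c}::flag" for c in value_cols] != flag_cols:
        raise FormatError(f"{path}: value and flag column blocks do not match")
    values = df[value_cols].mask(df[value_cols] == "").astype(float)
    flags = df[flag_cols].copy()
    flags.columns = value_cols
    values.index.name = None
    flags.index.name = None
    try:
        return ConcentrationMatrix(values, flags)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_annotation_table(path: str | Path) -> list[SampleAnnotation]:
    df = _read_table(path, ",")
    _require_columns(df, ["sample_id", "strain", "zygosity", "sex", "plate_id"], path)
    return [
        SampleAnnotation(
            row.sample_id, row.strain, row.zygosity, row.sex, row.plate_id
        )
        for row in df.itertuples(index=False)
    ]


def write_annotation_table(
    annotations: Iterable[SampleAnnotation], path: str | Path
) -> None:
    df = pd.DataFrame([dataclasses.asdict(a) for a in annotations])
    _write_with_header(df, path, sep=",")


def annotations_to_frame(annotations: Iterable[SampleAnnotation]) -> pd.DataFrame:
    return pd.DataFrame([dataclasses.asdict(a) for a in annotations]).set_index(
        "sample_id"
    )


def read_panels(path: str | Path) -> list[PanelDefinition]:
    """Read a plain-text panel file: ``protein_id<TAB>origin`` per line."""
    members: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{path}: line {lineno}: expected 'protein_id<TAB>origin'"
                )
            pid, origin = parts
            members.setdefault(origin, set()).add(pid)
    return [
        PanelDefinition(name=origin, member_protein_ids=frozenset(ids), origin=origin)
        for origin, ids in sorted(members.items())
    ]


def write_panels(panels: Iterable[PanelDefinition], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# proteotype v{__version__} contamination panels\n")
        for panel in panels:
            for pid in sorted(panel.member_protein_ids):
                fh.write(f"{pid}\t{panel.origin}\n")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated name, description, members."""
    sets: dict[str, GeneSet] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT lines need >= 3 tab-separated fields"
                )
            name, desc, *members = parts
            members = [m for m in members if m]
            if not members:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} is empty")
            sets[name] = GeneSet(name, desc, frozenset(members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in collection.sets.values():
            fh.write("\t".join([s.name, s.description, *sorted(s.members)]) + "\n")


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    """Clinical phenotyping table: sample_id index, numeric test columns."""
    df = pd.read_csv(path, comment="#")
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing column 'sample_id'")
    return df.set_index("sample_id").astype(float)


def read_id_map(path: str | Path) -> dict[str, str]:
    """Two-column ortholog/identifier map: source_id, target_id."""
    df = _read_table(path, ",")
    _require_columns(df, ["source_id", "target_id"], path)
    return dict(zip(df["source_id"], df["target_id"]))
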
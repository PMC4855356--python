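"""Domain types and I/O for descriptor tables, XYZ files and trained models.

A *descriptor table* is a CSV with one row per molecular complex: an ``id``
column, an interaction ``class`` column (``h_bonded``, ``dispersion``,
``mixed``, ``halogen`` or ``unknown``), a mandatory ``dft_nci`` column — the
DFT-computed non-covalent interaction energy in kcal/mol, the model's primary
descriptor — an optional reference column (default ``ref_nci``, the
CCSD(T)/CBS-quality benchmark energy), and any number of additional numeric
descriptor columns.

All variables (descriptors and, when requested, the target) are min–max
scaled to [-1, 1] before modelling; :class:`NormalizationMap` records the
per-variable ranges so every reported energy can be mapped back to kcal/mol.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

MODEL_FORMAT_TAG = "deltanci-grnn-model"
MODEL_FORMAT_VERSION = 1

#: Variable key under which the regression target (the reference NCI) is
#: stored inside a NormalizationMap.
TARGET_KEY = "reference_nci"

PRIMARY_DESCRIPTOR = "dft_nci"


class SchemaError(ValueError):
    """A required column or variable is missing or mis-declared."""


class TableParseError(ValueError):
    """A cell could not be parsed as the declared type."""


class IntegrityError(ValueError):
    """The table violates a dataset invariant (duplicate ids, missing ref)."""


class XYZFormatError(ValueError):
    """An XYZ file does not follow the two-header-line convention."""


class ElementLookupError(KeyError):
    """An element symbol is outside the shipped valence table."""


class ModelFormatError(ValueError):
    """A model file has an unknown or incompatible format tag/version."""


class DatabaseTag(str, Enum):
    S22 = "S22"
    S66 = "S66"
    X40 = "X40"
    SYNTHETIC = "synthetic"
    OTHER = "other"


class InteractionClass(str, Enum):
    H_BONDED = "h_bonded"
    DISPERSION = "dispersion"
    MIXED = "mixed"
    HALOGEN = "halogen"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, token: str) -> "InteractionClass":
        try:
            return cls(str(token).strip().lower())
        except ValueError:
            raise TableParseError(
                f"unknown interaction class {token!r}; expected one of "
                f"{[c.value for c in cls]}"
            ) from None


# Main-group valence-electron counts (group valence), H through I.
VALENCE_ELECTRONS: Mapping[str, int] = {
    "H": 1, "He": 2,
    "Li": 1, "Be": 2, "B": 3, "C": 4, "N": 5, "O": 6, "F": 7, "Ne": 8,
    "Na": 1, "Mg": 2, "Al": 3, "Si": 4, "P": 5, "S": 6, "Cl": 7, "Ar": 8,
    "K": 1, "Ca": 2, "Ga": 3, "Ge": 4, "As": 5, "Se": 6, "Br": 7, "Kr": 8,
    "Rb": 1, "Sr": 2, "In": 3, "Sn": 4, "Sb": 5, "Te": 6, "I": 7, "Xe": 8,
}


@dataclass
class MoleculeRecord:
    """One molecular complex: descriptors, class label, reference energy."""

    id: str
    interaction_class: InteractionClass = InteractionClass.UNKNOWN
    database_tag: DatabaseTag = DatabaseTag.OTHER
    descriptors: dict[str, float] = field(default_factory=dict)
    reference_nci: float | None = None

    def __post_init__(self) -> None:
        if PRIMARY_DESCRIPTOR not in self.descriptors:
            raise SchemaError(
                f"record {self.id!r} lacks the primary descriptor "
                f"{PRIMARY_DESCRIPTOR!r}"
            )
        for name, value in self.descriptors.items():
            if not np.isfinite(value):
                raise IntegrityError(
                    f"record {self.id!r}: descriptor {name!r} is not finite"
                )


@dataclass
class Dataset:
    """Ordered collection of records sharing one descriptor schema."""

    records: list[MoleculeRecord]
    descriptor_names: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise IntegrityError(f"duplicate record id {dup!r}")
        for r in self.records:
            if list(r.descriptors) != list(self.descriptor_names):
                raise SchemaError(
                    f"record {r.id!r} descriptors "
                    f"{list(r.descriptors)} != schema {self.descriptor_names}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def X(self) -> np.ndarray:
        """Descriptor matrix, one row per record, columns in schema order."""
        return np.array(
            [[r.descriptors[n] for n in self.descriptor_names]
             for r in self.records],
            dtype=float,
        ).reshape(len(self.records), len(self.descriptor_names))

    @property
    def y(self) -> np.ndarray:
        """Reference NCI vector (kcal/mol); raises if any record lacks it."""
        vals = [r.reference_nci for r in self.records]
        if any(v is None for v in vals):
            missing = [r.id for r in self.records if r.reference_nci is None]
            raise IntegrityError(
                f"records without reference_nci: {missing[:5]}"
            )
        return np.asarray(vals, dtype=float)

    @property
    def has_reference(self) -> bool:
        return all(r.reference_nci is not None for r in self.records)

    def subset(self, ids: Iterable[str]) -> "Dataset":
        """Rows for ``ids``, in the order given."""
        by_id = {r.id: r for r in self.records}
        try:
            recs = [by_id[i] for i in ids]
        except KeyError as e:
            raise IntegrityError(f"unknown record id {e.args[0]!r}") from None
        return Dataset(recs, list(self.descriptor_names), self.provenance)

    def column(self, name: str) -> np.ndarray:
        if name not in self.descriptor_names:
            raise SchemaError(f"unknown descriptor {name!r}")
        return np.asarray(
            [r.descriptors[name] for r in self.records], dtype=float
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row: dict[str, object] = {
                "id": r.id,
                "class": r.interaction_class.value,
            }
            row.update(r.descriptors)
            if r.reference_nci is not None:
                row["ref_nci"] = r.reference_nci
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class TableSchema:
    """Column-role map for :func:`read_descriptor_table`."""

    id_column: str = "id"
    class_column: str = "class"
    reference_column: str = "ref_nci"
    reference_required: bool = False
    database_tag: DatabaseTag = DatabaseTag.OTHER


def read_descriptor_table(
    path: str | Path, schema: TableSchema | None = None
) -> Dataset:
    """Read a descriptor CSV into a :class:`Dataset`, preserving row order.

    Every column other than id/class/reference is treated as a numeric
    descriptor. A missing reference cell is an :class:`IntegrityError` when
    the schema marks the reference required; otherwise the record simply has
    no ``reference_nci``.
    """
    schema = schema or TableSchema()
    path = Path(path)
    df = pd.read_csv(
        path, dtype={schema.id_column: str}, float_precision="round_trip"
    )
    for col in (schema.id_column, schema.class_column, PRIMARY_DESCRIPTOR):
        if col not in df.columns:
            raise SchemaError(f"{path.name}: missing mandatory column {col!r}")
    has_ref = schema.reference_column in df.columns
    if schema.reference_required and not has_ref:
        raise SchemaError(
            f"{path.name}: missing required reference column "
            f"{schema.reference_column!r}"
        )
    desc_cols = [
        c for c in df.columns
        if c not in (schema.id_column, schema.class_column,
                     schema.reference_column)
    ]
    records = []
    for idx, row in df.iterrows():
        descriptors: dict[str, float] = {}
        for c in desc_cols:
            try:
                v = float(row[c])
            except (TypeError, ValueError):
                raise TableParseError(
                    f"{path.name}: non-numeric value {row[c]!r} "
                    f"at row {idx}, column {c!r}"
                ) from None
            if not np.isfinite(v):
                raise TableParseError(
                    f"{path.name}: non-finite value at row {idx}, "
                    f"column {c!r}"
                )
            descriptors[c] = v
        ref: float | None = None
        if has_ref:
            raw = row[schema.reference_column]
            if pd.isna(raw):
                if schema.reference_required:
                    raise IntegrityError(
                        f"{path.name}: missing reference value at row {idx} "
                        f"(id {row[schema.id_column]!r})"
                    )
            else:
                ref = float(raw)
        records.append(
            MoleculeRecord(
                id=str(row[schema.id_column]),
                interaction_class=InteractionClass.parse(
                    row[schema.class_column]
                ),
                database_tag=schema.database_tag,
                descriptors=descriptors,
                reference_nci=ref,
            )
        )
    return Dataset(records, desc_cols, provenance=str(path))


def write_descriptor_table(dataset: Dataset, path: str | Path) -> None:
    """Write ``dataset`` as a descriptor CSV (the dialect read back above)."""
    df = dataset.to_frame()
    # keep ref_nci last, descriptors in schema order
    cols = ["id", "class", *dataset.descriptor_names]
    if "ref_nci" in df.columns:
        cols.append("ref_nci")
    df.to_csv(path, index=False, columns=cols)


def read_xyz(path: str | Path) -> list[tuple[str, float, float, float]]:
    """Parse a standard two-header-line XYZ file into (element, x, y, z)."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise XYZFormatError(f"{path}: empty file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise XYZFormatError(f"{path}: first line is not an atom count") from None
    body = [ln for ln in lines[2:] if ln.strip()]
    if len(body) != n:
        raise XYZFormatError(
            f"{path}: count line says {n} atoms but {len(body)} rows found"
        )
    atoms = []
    for ln in body:
        parts = ln.split()
        if len(parts) < 4:
            raise XYZFormatError(f"{path}: malformed atom line {ln!r}")
        sym = parts[0].capitalize()
        try:
            xyz = tuple(float(p) for p in parts[1:4])
        except ValueError:
            raise XYZFormatError(
                f"{path}: non-numeric coordinate in line {ln!r}"
            ) from None
        atoms.append((sym, *xyz))
    return atoms


def constitutional_descriptors(xyz_path: str | Path) -> tuple[int, int]:
    """Atom count and total valence-electron count of an XYZ structure.

    Valence electrons follow the main-group valence convention
    (H=1, C=4, N=5, O=6, halogens=7, ...).
    """
    atoms = read_xyz(xyz_path)
    n_ve = 0
    for sym, *_ in atoms:
        if sym not in VALENCE_ELECTRONS:
            raise ElementLookupError(
                f"element {sym!r} not in the valence table"
            )
        n_ve += VALENCE_ELECTRONS[sym]
    return len(atoms), n_ve


@dataclass
class NormalizationMap:
    """Per-variable min/max for the affine map onto [-1, 1].

    ``x -> 2*(x - min)/(max - min) - 1``. Variables with zero range are
    flagged in ``constant_variables`` and mapped to 0 (kept, not dropped, so
    column indices stay stable). Values outside the fitted range transform
    outside [-1, 1]; no clipping, so kernel distances stay meaningful for
    extrapolating queries.
    """

    ranges: dict[str, tuple[float, float]]
    constant_variables: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, (lo, hi) in self.ranges.items():
            if hi < lo:
                raise ValueError(f"variable {name!r}: max {hi} < min {lo}")

    def apply_value(self, name: str, value):
        if name not in self.ranges:
            raise SchemaError(f"variable {name!r} not in normalization map")
        lo, hi = self.ranges[name]
        if hi == lo:
            return np.zeros_like(np.asarray(value, dtype=float))
        return 2.0 * (np.asarray(value, dtype=float) - lo) / (hi - lo) - 1.0

    def invert_value(self, name: str, value):
        if name not in self.ranges:
            raise SchemaError(f"variable {name!r} not in normalization map")
        lo, hi = self.ranges[name]
        if hi == lo:
            return np.full_like(np.asarray(value, dtype=float), lo)
        return (np.asarray(value, dtype=float) + 1.0) * (hi - lo) / 2.0 + lo

    def transform_matrix(
        self, X: np.ndarray, names: Sequence[str]
    ) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty_like(X)
        for j, name in enumerate(names):
            out[:, j] = self.apply_value(name, X[:, j])
        return out

    def apply_target(self, y):
        return self.apply_value(TARGET_KEY, y)

    def invert_target(self, y):
        return self.invert_value(TARGET_KEY, y)

    def to_dict(self) -> dict:
        return {
            "ranges": {k: list(v) for k, v in self.ranges.items()},
            "constant_variables": list(self.constant_variables),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "NormalizationMap":
        return cls(
            ranges={k: (float(v[0]), float(v[1]))
                    for k, v in d["ranges"].items()},
            constant_variables=list(d.get("constant_variables", [])),
        )


def fit_normalization(
    data: Dataset, include_target: bool = True
) -> NormalizationMap:
    """Record per-variable min/max on ``data`` for the [-1, 1] scaling."""
    if len(data) == 0:
        raise IntegrityError("cannot fit normalization on an empty dataset")
    ranges: dict[str, tuple[float, float]] = {}
    constant: list[str] = []
    X = data.X
    for j, name in enumerate(data.descriptor_names):
        lo, hi = float(X[:, j].min()), float(X[:, j].max())
        ranges[name] = (lo, hi)
        if lo == hi:
            constant.append(name)
    if include_target:
        y = data.y
        lo, hi = float(y.min()), float(y.max())
        ranges[TARGET_KEY] = (lo, hi)
        if lo == hi:
            constant.append(TARGET_KEY)
    return NormalizationMap(ranges, constant)


def apply_normalization(nmap: NormalizationMap, data: Dataset) -> Dataset:
    """Return a new Dataset with descriptors (and target) mapped by ``nmap``."""
    records = []
    for r in data.records:
        desc = {
            n: float(nmap.apply_value(n, np.asarray(v)))
            for n, v in r.descriptors.items()
        }
        ref = r.reference_nci
        if ref is not None and TARGET_KEY in nmap.ranges:
            ref = float(nmap.apply_target(np.asarray(ref)))
        records.append(
            MoleculeRecord(
                id=r.id,
                interaction_class=r.interaction_class,
                database_tag=r.database_tag,
                descriptors=desc,
                reference_nci=ref,
            )
        )
    return Dataset(records, list(data.descriptor_names), data.provenance)


def invert_target(nmap: NormalizationMap, value):
    """Map a normalized target value back to kcal/mol."""
    return nmap.invert_target(value)


def save_model(model, path: str | Path) -> None:
    """Serialize a trained GRNN model as versioned structured text (JSON)."""
    payload = {
        "format": MODEL_FORMAT_TAG,
        "version": MODEL_FORMAT_VERSION,
        "descriptor_names": list(model.descriptor_names),
        "sigma": float(model.sigma),
        "patterns": np.asarray(model.patterns).tolist(),
        "targets": np.asarray(model.targets).tolist(),
        "normalization": model.normalization.to_dict(),
        "training_meta": model.training_meta,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_model(path: str | Path):
    """Load a model written by :func:`save_model`."""
    from .grnn import GRNNModel  # local import to avoid a cycle

    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ModelFormatError(f"{path}: not a model file ({e})") from None
    if payload.get("format") != MODEL_FORMAT_TAG:
        raise ModelFormatError(
            f"{path}: format tag {payload.get('format')!r} != "
            f"{MODEL_FORMAT_TAG!r}"
        )
    if payload.get("version") != MODEL_FORMAT_VERSION:
        raise ModelFormatError(
            f"{path}: unsupported model version {payload.get('version')!r}"
        )
    for key in ("descriptor_names", "sigma", "patterns", "targets",
                "normalization"):
        if key not in payload:
            raise ModelFormatError(f"{path}: missing field {key!r}")
    return GRNNModel(
        descriptor_names=list(payload["descriptor_names"]),
        patterns=np.asarray(payload["patterns"], dtype=float),
        targets=np.asarray(payload["targets"], dtype=float),
        sigma=float(payload["sigma"]),
        normalization=NormalizationMap.from_dict(payload["normalization"]),
        training_meta=payload.get("training_meta", {}),
    )
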
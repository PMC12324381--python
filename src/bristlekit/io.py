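"""Tabular I/O for the bristle-pattern pipeline.

Three artifact kinds move between stages as delimited text:

* centroid tables — one row per bristle precursor cell, coordinates in
  microns, either a plain ``x_um,y_um`` layout or the standard ImageJ
  "Results" export (columns ``X``, ``Y``; an unnamed leading index column
  and extra measurement columns are tolerated);
* cohort manifests — which centroid file belongs to which tissue/group,
  with tissue areas and an optional pairing table mapping each mutant
  group to its control;
* feature tables — one row of global pattern features per tissue.

Coordinates are microns throughout; no pixel/micron conversion happens
here (calibration belongs to the upstream image processing). Duplicate
coordinate pairs are legal — two cells can land on coincident centroids —
so downstream distance code must tolerate zero distances.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
import pandas as pd

__all__ = [
    "PointPattern",
    "ManifestEntry",
    "GroupRole",
    "CohortManifest",
    "CentroidFormatError",
    "ManifestError",
    "read_centroid_table",
    "write_centroid_table",
    "read_manifest",
    "load_cohort",
    "write_feature_table",
    "read_feature_table",
    "FEATURE_TABLE_COLUMNS",
]

#: Column order of the per-tissue feature table.
FEATURE_TABLE_COLUMNS = [
    "pattern_id", "group", "n_points", "eps_opt", "minpts_opt",
    "RSA", "CN", "OP", "CQ", "CSV",
]


class CentroidFormatError(ValueError):
    """A centroid table is malformed (missing column, non-numeric cell)."""


class ManifestError(ValueError):
    """A cohort manifest violates its invariants."""


@dataclass
class PointPattern:
    """One tissue's bristle-cell centroids plus its area and group label.

    Attributes
    ----------
    pattern_id : str
        Unique identifier of the tissue (one heminotum).
    group : str
        Genotype / condition label, e.g. ``"control-White"``.
    points : (n, 2) ndarray of float
        Centroid coordinates in microns, in source-row order. Row order
        is part of the contract: deterministic cluster numbering
        downstream depends on it.
    tissue_area : float
        Tissue area in square microns; strictly positive.
    """

    pattern_id: str
    group: str
    points: np.ndarray
    tissue_area: float

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.size == 0:
            pts = pts.reshape(0, 2)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        if not np.isfinite(pts).all():
            raise ValueError("points must be finite")
        self.points = pts
        if not (self.tissue_area > 0):
            raise ValueError(
                f"tissue_area must be > 0, got {self.tissue_area!r}"
            )

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class ManifestEntry:
    pattern_id: str
    group: str
    tissue_area: float
    centroid_file: Path


@dataclass(frozen=True)
class GroupRole:
    """Role of a group: ``control`` or ``mutant`` with its paired control."""

    role: Literal["control", "mutant"]
    control_group: str | None = None


@dataclass
class CohortManifest:
    """Validated cohort manifest: entries plus the mutant→control pairing."""

    entries: list[ManifestEntry]
    role_map: dict[str, GroupRole] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [e.pattern_id for e in self.entries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ManifestError(f"duplicate pattern_id(s): {sorted(dupes)}")
        for e in self.entries:
            if not (e.tissue_area > 0):
                raise ManifestError(
                    f"pattern {e.pattern_id!r}: tissue_area must be > 0"
                )
        for group, gr in self.role_map.items():
            if gr.role == "mutant":
                ctrl = gr.control_group
                if not ctrl:
                    raise ManifestError(
                        f"mutant group {group!r} has no paired control"
                    )
                ctrl_role = self.role_map.get(ctrl)
                if ctrl_role is None or ctrl_role.role != "control":
                    raise ManifestError(
                        f"mutant group {group!r} pairs to {ctrl!r}, "
                        "which is not declared as a control"
                    )

    @property
    def pairing(self) -> dict[str, str]:
        """Mapping mutant group → its paired control group."""
        return {
            g: gr.control_group
            for g, gr in self.role_map.items()
            if gr.role == "mutant" and gr.control_group
        }

    @property
    def control_groups(self) -> list[str]:
        return [g for g, gr in self.role_map.items() if gr.role == "control"]


def _read_delimited(path: os.PathLike | str) -> pd.DataFrame:
    # sep=None sniffs comma vs tab, covering both export conventions
    return pd.read_csv(path, sep=None, engine="python")


def read_centroid_table(
    path: os.PathLike | str,
    dialect: Literal["plain_xy", "imagej_results"] = "plain_xy",
) -> np.ndarray:
    """Read a centroid table and return the (n, 2) coordinate array.

    ``plain_xy`` expects columns ``x_um``, ``y_um``; ``imagej_results``
    expects the ImageJ Results columns ``X``, ``Y`` (micron-calibrated)
    and ignores any other columns, including the unnamed row index.
    Row order is preserved; duplicates are not removed. An empty table
    yields an empty array, not an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"centroid table not found: {path}")
    if dialect == "plain_xy":
        cols = ("x_um", "y_um")
    elif dialect == "imagej_results":
        cols = ("X", "Y")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_delimited(path)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise CentroidFormatError(
            f"{path}: missing required column(s) {missing} "
            f"for dialect {dialect!r}"
        )
    if len(df) == 0:
        return np.empty((0, 2), dtype=float)
    sub = df.loc[:, list(cols)]
    coerced = sub.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna()
    if bad.to_numpy().any():
        row = int(np.argwhere(bad.to_numpy().any(axis=1))[0][0])
        raise CentroidFormatError(
            f"{path}: non-numeric or missing coordinate in data row {row}"
        )
    return coerced.to_numpy(dtype=float)


def write_centroid_table(points: np.ndarray, path: os.PathLike | str) -> None:
    """Write coordinates as a plain ``x_um,y_um`` CSV (full precision)."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    df = pd.DataFrame(pts, columns=["x_um", "y_um"])
    df.to_csv(path, index=False, float_format="%.12g")


def read_manifest(
    path: os.PathLike | str,
    pairing_path: os.PathLike | str | None = None,
) -> CohortManifest:
    """Read a cohort manifest (and its pairing table, if present).

    The manifest is a CSV with header ``pattern_id,group,tissue_area_um2,
    centroid_file``; relative centroid paths resolve against the manifest
    location. The pairing table (``group,role,control_group``) is read
    from *pairing_path*, defaulting to ``pairing.csv`` next to the
    manifest when that file exists. Centroid files are NOT touched here:
    a missing file surfaces only when the pattern is actually loaded.
    """
    path = Path(path)
    df = _read_delimited(path)
    required = ["pattern_id", "group", "tissue_area_um2", "centroid_file"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ManifestError(f"{path}: missing manifest column(s) {missing}")
    base = path.parent
    entries = []
    for _, row in df.iterrows():
        area = pd.to_numeric(row["tissue_area_um2"], errors="coerce")
        if pd.isna(area):
            raise ManifestError(
                f"{path}: non-numeric tissue_area_um2 for "
                f"pattern {row['pattern_id']!r}"
            )
        cf = Path(str(row["centroid_file"]))
        if not cf.is_absolute():
            cf = base / cf
        entries.append(
            ManifestEntry(
                pattern_id=str(row["pattern_id"]),
                group=str(row["group"]),
                tissue_area=float(area),
                centroid_file=cf,
            )
        )

    role_map: dict[str, GroupRole] = {}
    if pairing_path is None:
        default = base / "pairing.csv"
        pairing_path = default if default.exists() else None
    if pairing_path is not None:
        pdf = _read_delimited(pairing_path)
        preq = ["group", "role", "control_group"]
        pmissing = [c for c in preq if c not in pdf.columns]
        if pmissing:
            raise ManifestError(
                f"{pairing_path}: missing pairing column(s) {pmissing}"
            )
        for _, row in pdf.iterrows():
            role = str(row["role"])
            if role not in ("control", "mutant"):
                raise ManifestError(
                    f"{pairing_path}: role must be control|mutant, "
                    f"got {role!r}"
                )
            ctrl = row["control_group"]
            ctrl = None if pd.isna(ctrl) or str(ctrl) == "" else str(ctrl)
            role_map[str(row["group"])] = GroupRole(role=role, control_group=ctrl)
    return CohortManifest(entries=entries, role_map=role_map)


def load_cohort(
    manifest: CohortManifest,
    dialect: Literal["plain_xy", "imagej_results"] = "plain_xy",
) -> Iterator[PointPattern]:
    """Yield the cohort's patterns in manifest order (lazy file access)."""
    for e in manifest.entries:
        points = read_centroid_table(e.centroid_file, dialect=dialect)
        yield PointPattern(
            pattern_id=e.pattern_id,
            group=e.group,
            points=points,
            tissue_area=e.tissue_area,
        )


def write_feature_table(features: pd.DataFrame, path: os.PathLike | str) -> None:
    """Write the per-tissue feature table (one row per pattern).

    Columns: pattern_id, group, n_points, eps_opt, minpts_opt, RSA, CN,
    OP, CQ, CSV. Floats are written at 12 significant digits so the
    table round-trips well below 1e-9. Refuses an empty cohort.
    """
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in features.columns]
    if missing:
        raise ValueError(f"feature table missing column(s) {missing}")
    if len(features) == 0:
        raise ValueError("refusing to write an empty feature table")
    features.loc[:, FEATURE_TABLE_COLUMNS].to_csv(
        path, index=False, float_format="%.12g"
    )


def read_feature_table(path: os.PathLike | str) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    df = _read_delimited(path)
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: not a feature table, missing {missing}")
    return df
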
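"""Readers, writers and validation for labelled 3-D marker data.

Conventions used throughout the package:

* world frame: right-handed, vertical axis = +z, units of millimetres;
* marker trajectories are sampled uniformly (100 Hz in a typical optical
  motion-capture setup);
* untracked (gapped) frames are kept explicit in a boolean mask and are
  never interpolated — downstream stride aggregation drops strides that
  contain gaps in the markers it needs.

The marker set covers the dorsal midline of the horse (head, withers,
thoracic/lumbar spine, sacrum) plus a pelvic triad (tuber sacrale and both
tubera coxae).  Thirteen anatomical *roles* are defined; a
:class:`MarkerConfig` maps each role to the label used in a given file.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "MARKER_ROLES",
    "CONDITIONS",
    "DAYS",
    "PATHS",
    "SURFACES",
    "FormatError",
    "EmptyInputError",
    "MarkerConfig",
    "MarkerFrameSeries",
    "MarkerSetReport",
    "condition_label",
    "read_trajectories",
    "write_trajectories_tsv",
    "validate_marker_set",
    "read_measurement_table",
    "write_measurement_table",
]

#: Anatomical roles every trial must provide.  ``head_ref`` is the lowest of
#: the three head markers; the withers carry a central marker flanked by two
#: lateral ones; the pelvic triad is tuber sacrale + left/right tuber coxae;
#: the remaining markers sit over the dorsal spinous processes.
MARKER_ROLES: tuple[str, ...] = (
    "head_ref",
    "withers_mid",
    "withers_left",
    "withers_right",
    "tuber_sacrale",
    "tuber_coxae_left",
    "tuber_coxae_right",
    "T12",
    "T15",
    "T18",
    "L3",
    "L5",
    "S5",
)

DAYS = ("day1", "day2", "recheck")
PATHS = ("straight", "lunge_left", "lunge_right")
SURFACES = ("hard", "soft")

#: The four path-surface combinations measured in a trot-up protocol.
#: Circles (lunge) are only ridden on the soft surface.
CONDITIONS = ("hard_straight", "soft_straight", "soft_left", "soft_right")


class FormatError(ValueError):
    """A file could not be parsed in the requested format."""


class EmptyInputError(ValueError):
    """A trajectory file contained no frames."""


def condition_label(path: str, surface: str) -> str:
    """Map a (path, surface) pair to its condition label.

    >>> condition_label("straight", "hard")
    'hard_straight'
    >>> condition_label("lunge_left", "soft")
    'soft_left'
    """
    if path == "straight":
        return f"{surface}_straight"
    if path == "lunge_left":
        return "soft_left"
    if path == "lunge_right":
        return "soft_right"
    raise ValueError(f"unknown path {path!r}")


# ---------------------------------------------------------------------------
# Marker configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerConfig:
    """Role -> marker-label mapping.

    All thirteen roles in :data:`MARKER_ROLES` must be mapped and the labels
    must be unique.
    """

    roles: Mapping[str, str]

    def __post_init__(self) -> None:
        missing = [r for r in MARKER_ROLES if r not in self.roles]
        if missing:
            raise ValueError(f"marker config missing roles: {missing}")
        unknown = [r for r in self.roles if r not in MARKER_ROLES]
        if unknown:
            raise ValueError(f"marker config has unknown roles: {unknown}")
        labels = list(self.roles.values())
        if len(set(labels)) != len(labels):
            raise ValueError("marker labels must be unique")
        object.__setattr__(self, "roles", dict(self.roles))

    def label(self, role: str) -> str:
        return self.roles[role]

    @classmethod
    def identity(cls) -> "MarkerConfig":
        """Config where every label equals its role name (the simulator's)."""
        return cls({r: r for r in MARKER_ROLES})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MarkerConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, Mapping):
            raise FormatError(f"{path}: expected a mapping of role: label")
        return cls(dict(data))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dict(self.roles), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Marker trajectories
# ---------------------------------------------------------------------------


@dataclass
class MarkerFrameSeries:
    """Time-indexed 3-D positions for named markers at a fixed sampling rate.

    Parameters
    ----------
    sampling_rate
        Frames per second, > 0.
    positions
        Mapping label -> ``(n_frames, 3)`` float array, millimetres,
        right-handed world frame with +z up.  Gapped frames may hold NaN.
    gap_mask
        Mapping label -> ``(n_frames,)`` boolean array; ``True`` marks an
        untracked frame.  If omitted, gaps are inferred from NaNs.
    """

    sampling_rate: float
    positions: dict[str, np.ndarray]
    gap_mask: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be > 0")
        if not self.positions:
            raise EmptyInputError("no markers")
        lengths = {len(p) for p in self.positions.values()}
        if len(lengths) != 1:
            raise ValueError("all markers must have the same frame count")
        n = lengths.pop()
        if n == 0:
            raise EmptyInputError("zero frames")
        for label, pos in self.positions.items():
            pos = np.asarray(pos, dtype=float)
            if pos.shape != (n, 3):
                raise ValueError(f"marker {label!r}: expected shape ({n}, 3)")
            self.positions[label] = pos
            mask = self.gap_mask.get(label)
            if mask is None:
                mask = ~np.isfinite(pos).all(axis=1)
            else:
                mask = np.asarray(mask, dtype=bool)
                if mask.shape != (n,):
                    raise ValueError(f"gap mask for {label!r}: expected shape ({n},)")
            self.gap_mask[label] = mask
            if not np.isfinite(pos[~mask]).all():
                raise ValueError(f"marker {label!r}: non-finite position outside gaps")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.positions.values())))

    @property
    def duration(self) -> float:
        """Trial duration in seconds (n_frames / sampling_rate)."""
        return self.n_frames / self.sampling_rate

    @property
    def labels(self) -> list[str]:
        return list(self.positions)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.sampling_rate

    def marker(self, label: str) -> np.ndarray:
        return self.positions[label]

    def gaps(self, label: str) -> np.ndarray:
        return self.gap_mask[label]


# ---------------------------------------------------------------------------
# Trajectory file formats
# ---------------------------------------------------------------------------

_RATE_KEY = "# sampling_rate_hz"


def write_trajectories_tsv(series: MarkerFrameSeries, path: str | Path) -> None:
    """Write a :class:`MarkerFrameSeries` in the package's TSV dialect.

    Line 1 carries the sampling rate; the header row has one ``<label>_X/_Y/_Z``
    column triple per marker; gapped frames are written as empty fields.
    """
    labels = series.labels
    cols: dict[str, np.ndarray] = {"frame": np.arange(series.n_frames)}
    for label in labels:
        pos = series.positions[label].copy()
        pos[series.gap_mask[label]] = np.nan
        for j, ax in enumerate("XYZ"):
            cols[f"{label}_{ax}"] = pos[:, j]
    df = pd.DataFrame(cols)
    with open(path, "w") as fh:
        fh.write(f"{_RATE_KEY}\t{series.sampling_rate!r}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="")


def _read_tsv(path: Path) -> MarkerFrameSeries:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith(_RATE_KEY):
            raise FormatError(f"{path}: missing '{_RATE_KEY}' header line")
        try:
            rate = float(first.split("\t")[1])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: unreadable sampling rate") from exc
        body = fh.read()
    try:
        # round_trip parsing keeps write->read bit-exact
        df = pd.read_csv(io.StringIO(body), sep="\t",
                         float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"{path}: {exc}") from exc
    if df.empty:
        raise EmptyInputError(f"{path}: zero frames")
    labels: list[str] = []
    for col in df.columns:
        if col.endswith("_X"):
            labels.append(col[:-2])
    if not labels:
        raise FormatError(f"{path}: no <label>_X/_Y/_Z columns found")
    positions = {}
    for label in labels:
        try:
            arr = df[[f"{label}_X", f"{label}_Y", f"{label}_Z"]].to_numpy(float)
        except KeyError as exc:
            raise FormatError(f"{path}: incomplete XYZ triple for {label!r}") from exc
        positions[label] = arr
    return MarkerFrameSeries(sampling_rate=rate, positions=positions)


def _read_c3d(path: Path) -> MarkerFrameSeries:
    try:
        import ezc3d
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading C3D files requires the optional 'ezc3d' package "
            "(pip install equispine[c3d]); the TSV dialect needs no extras"
        ) from exc
    c3d = ezc3d.c3d(str(path))
    pts = c3d["data"]["points"]  # (4, n_markers, n_frames)
    labels = [s.strip() for s in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    if pts.shape[2] == 0:
        raise EmptyInputError(f"{path}: zero frames")
    positions = {}
    for i, label in enumerate(labels):
        positions[label] = pts[:3, i, :].T.astype(float)
    return MarkerFrameSeries(sampling_rate=rate, positions=positions)


def read_trajectories(path: str | Path, format: str | None = None) -> MarkerFrameSeries:
    """Read labelled marker trajectories from ``path``.

    Parameters
    ----------
    path
        Input file.
    format
        ``"tsv"`` or ``"c3d"``; inferred from the suffix when ``None``.

    Untracked frames are flagged in the gap mask, never interpolated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "c3d" if path.suffix.lower() == ".c3d" else "tsv"
    if format == "tsv":
        return _read_tsv(path)
    if format == "c3d":
        return _read_c3d(path)
    raise ValueError(f"unknown trajectory format {format!r}")


# ---------------------------------------------------------------------------
# Marker-set validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MarkerSetReport:
    """Outcome of :func:`validate_marker_set` (report, not exception)."""

    missing_roles: tuple[str, ...]
    gap_fractions: Mapping[str, float]  # role -> fraction of gapped frames
    gap_threshold: float
    passed: bool

    def failures(self) -> list[str]:
        out = [f"role {r!r} not present in file" for r in self.missing_roles]
        for role, frac in self.gap_fractions.items():
            if frac > self.gap_threshold:
                out.append(f"role {role!r}: gap fraction {frac:.2f} exceeds "
                           f"threshold {self.gap_threshold:.2f}")
        return out


def validate_marker_set(
    series: MarkerFrameSeries,
    config: MarkerConfig,
    gap_threshold: float = 0.05,
) -> MarkerSetReport:
    """Check that all 13 roles are present and adequately tracked.

    Pure function: the series is not modified.  Passes iff every role maps to
    a marker in the file and each such marker's gap fraction is at or below
    ``gap_threshold``.
    """
    missing = []
    fractions: dict[str, float] = {}
    for role in MARKER_ROLES:
        label = config.label(role)
        if label not in series.positions:
            missing.append(role)
            continue
        fractions[role] = float(series.gap_mask[label].mean())
    passed = not missing and all(f <= gap_threshold for f in fractions.values())
    return MarkerSetReport(
        missing_roles=tuple(missing),
        gap_fractions=fractions,
        gap_threshold=gap_threshold,
        passed=passed,
    )


# ---------------------------------------------------------------------------
# Measurement-mean tables
# ---------------------------------------------------------------------------

#: Identifier columns of a measurement-mean table; remaining columns are
#: kinematic parameters (one measurement mean each).
ID_COLUMNS = ("horse", "day", "measurement_no", "path", "surface", "n_strides")

_DAY_ALIASES = {1: "day1", 2: "day2", 3: "recheck", "1": "day1", "2": "day2",
                "3": "recheck", "day1": "day1", "day2": "day2",
                "recheck": "recheck"}


def _normalise_records(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in ("horse", "day", "measurement_no", "path", "surface"):
        if col not in df.columns:
            raise FormatError(f"measurement table missing column {col!r}")
    df["day"] = df["day"].map(lambda v: _DAY_ALIASES.get(v, v))
    bad_day = ~df["day"].isin(DAYS)
    if bad_day.any():
        raise FormatError(f"unknown day values: {sorted(df.loc[bad_day, 'day'].unique())}")
    bad_path = ~df["path"].isin(PATHS)
    if bad_path.any():
        raise FormatError(f"unknown path values: {sorted(df.loc[bad_path, 'path'].unique())}")
    bad_surface = ~df["surface"].isin(SURFACES)
    if bad_surface.any():
        raise FormatError(
            f"unknown surface values: {sorted(df.loc[bad_surface, 'surface'].unique())}")
    df["measurement_no"] = df["measurement_no"].astype(int)
    if ((df["measurement_no"] < 1) | (df["measurement_no"] > 12)).any():
        raise FormatError("measurement_no must be in 1..12")
    # No hard-surface circles exist in the protocol.
    lunge_hard = df["path"].str.startswith("lunge") & (df["surface"] == "hard")
    if lunge_hard.any():
        raise FormatError("lunge records must be on soft surface (no hard circles)")
    if "n_strides" in df.columns:
        if (df["n_strides"].fillna(0) < 0).any():
            raise FormatError("n_strides must be >= 0")
    df["condition"] = [condition_label(p, s) for p, s in zip(df["path"], df["surface"])]
    return df


def read_measurement_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a measurement-mean table (CSV or XLSX).

    One row per horse x day x measurement number x path x surface; one column
    per kinematic parameter.  ``column_map`` renames file columns to the
    package's names (``{"file column": "package name"}``) before validation.
    A ``condition`` column with the path-surface label is added.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=dict(column_map))
    return _normalise_records(df)


def write_measurement_table(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def parameter_columns(records: pd.DataFrame) -> list[str]:
    """Kinematic-parameter columns of a measurement table (non-identifier)."""
    skip = set(ID_COLUMNS) | {"condition"}
    return [c for c in records.columns if c not in skip]
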
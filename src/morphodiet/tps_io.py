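"""Reading and writing landmark data (TPS dialect) and specimen isotope tables.

The TPS format is the plain-text landmark exchange format written by the tpsDig
family of digitizing tools.  A record starts with ``LM=<n>`` (number of fixed
anatomical landmarks) followed by ``n`` coordinate lines, optionally a
``CURVES=<c>`` section whose ``POINTS=<k>`` blocks hold outline semi-landmarks,
and trailing key lines such as ``ID=``, ``SCALE=`` and ``IMAGE=``.  Curve
points are appended after the fixed landmarks in index order.  3-D records
(``LM3=``) are rejected.

Isotope tables are plain CSV with required columns
``specimen_id, taxon, phase, d13C, d15N`` and optional
``dental_stage, M3_length, site, status``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LandmarkConfiguration",
    "IsotopeRecord",
    "TPSParseError",
    "DimensionalityError",
    "IsotopeValidationError",
    "read_tps",
    "write_tps",
    "read_isotope_csv",
    "records_to_frame",
]


class TPSParseError(ValueError):
    """Raised when a TPS file violates the LM=/POINTS/CURVES conventions."""


class DimensionalityError(TPSParseError):
    """Raised for 3-D records (LM3=) or coordinate lines with != 2 values."""


class IsotopeValidationError(ValueError):
    """Raised when mandatory isotope values are missing or non-numeric."""


@dataclass
class LandmarkConfiguration:
    """One specimen's ordered 2-D point configuration with landmark roles.

    ``points`` holds fixed anatomical landmarks and outline semi-landmarks in
    a single ordered array; ``fixed_indices`` and ``semi_indices`` partition
    the row indices.  Semi-landmark indices must be consecutive along the
    outline.  Coordinates are kept in native digitizing units (the optional
    image ``scale`` has already been applied by :func:`read_tps`).
    """

    specimen_id: str
    points: np.ndarray
    fixed_indices: tuple[int, ...] = ()
    semi_indices: tuple[int, ...] = ()
    scale: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise DimensionalityError(
                f"{self.specimen_id}: points must be an (n, 2) array, "
                f"got shape {self.points.shape}"
            )
        n = self.points.shape[0]
        if n < 3:
            raise ValueError(f"{self.specimen_id}: need at least 3 points, got {n}")
        if not np.all(np.isfinite(self.points)):
            raise ValueError(f"{self.specimen_id}: non-finite coordinates")
        if not self.fixed_indices and not self.semi_indices:
            self.fixed_indices = tuple(range(n))
        self.fixed_indices = tuple(int(i) for i in self.fixed_indices)
        self.semi_indices = tuple(int(i) for i in self.semi_indices)
        union = sorted(self.fixed_indices + self.semi_indices)
        if union != list(range(n)):
            raise ValueError(
                f"{self.specimen_id}: fixed_indices and semi_indices must "
                f"partition 0..{n - 1}"
            )
        if self.semi_indices:
            s = list(self.semi_indices)
            if s != list(range(min(s), min(s) + len(s))):
                raise ValueError(
                    f"{self.specimen_id}: semi-landmark indices must be "
                    "consecutive along the outline"
                )

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    def copy(self) -> "LandmarkConfiguration":
        return LandmarkConfiguration(
            specimen_id=self.specimen_id,
            points=self.points.copy(),
            fixed_indices=self.fixed_indices,
            semi_indices=self.semi_indices,
            scale=self.scale,
            meta=dict(self.meta),
        )


@dataclass
class IsotopeRecord:
    """Bone-collagen stable isotope measurements for one specimen.

    δ13C is reported in ‰ relative to VPDB, δ15N in ‰ relative to AIR.
    ``dental_stage`` is the eruption/wear stage used for the weaning filter;
    ``M3_length`` is the third lower molar length in mm when measurable.
    """

    specimen_id: str
    taxon: str
    phase: str
    d13C: float
    d15N: float
    dental_stage: int | None = None
    M3_length: float | None = None
    site: str | None = None
    status: str | None = None

    def __post_init__(self) -> None:
        for name in ("d13C", "d15N"):
            v = getattr(self, name)
            if v is not None and not math.isfinite(v):
                raise IsotopeValidationError(
                    f"{self.specimen_id}: non-finite {name} value"
                )


# ---------------------------------------------------------------------------
# TPS reading/writing
# ---------------------------------------------------------------------------

_KEY_PREFIXES = ("ID=", "SCALE=", "IMAGE=", "COMMENT=", "VARIABLES=")


def _parse_coord(line: str, lineno: int) -> tuple[float, float]:
    parts = line.split()
    if len(parts) == 3:
        raise DimensionalityError(
            f"line {lineno}: 3-D coordinate found; only 2-D records supported"
        )
    if len(parts) != 2:
        raise TPSParseError(
            f"line {lineno}: expected 2 coordinates, got {len(parts)}: {line!r}"
        )
    try:
        return float(parts[0]), float(parts[1])
    except ValueError as exc:
        raise TPSParseError(f"line {lineno}: non-numeric coordinate: {line!r}") from exc


def _parse_count(line: str, key: str, lineno: int) -> int:
    try:
        value = int(line.split("=", 1)[1].strip())
    except (IndexError, ValueError) as exc:
        raise TPSParseError(f"line {lineno}: malformed {key} count line: {line!r}") from exc
    if value < 0:
        raise TPSParseError(f"line {lineno}: negative {key} count")
    return value


def read_tps(
    path: str | Path,
    sidecar: str | Path | Mapping[str, Mapping] | None = None,
) -> list[LandmarkConfiguration]:
    """Read a TPS file into a list of :class:`LandmarkConfiguration`.

    ``SCALE=`` lines are applied multiplicatively to the coordinates and the
    factor is retained on the configuration.  Semi-landmark roles come from
    CURVES blocks; when a record has no curves, roles (and site/phase/taxon/
    status metadata) may be supplied through ``sidecar`` — either a mapping or
    a path to a JSON file keyed by specimen id.  By default all points are
    fixed landmarks.  Point and record order are never changed.
    """
    path = Path(path)
    if sidecar is not None and not isinstance(sidecar, Mapping):
        with open(sidecar, "r", encoding="utf-8") as fh:
            sidecar = json.load(fh)

    lines = path.read_text(encoding="utf-8").splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    n_lines = len(lines)

    def current(idx: int) -> str:
        return lines[idx].strip()

    while i < n_lines:
        line = current(i)
        if not line:
            i += 1
            continue
        upper = line.upper()
        if upper.startswith("LM3="):
            raise DimensionalityError(
                f"line {i + 1}: 3-D record (LM3=) not supported"
            )
        if not upper.startswith("LM="):
            raise TPSParseError(f"line {i + 1}: expected LM= record header, got {line!r}")
        n_fixed = _parse_count(line, "LM", i + 1)
        i += 1
        fixed_pts = []
        for _ in range(n_fixed):
            if i >= n_lines:
                raise TPSParseError(f"line {i + 1}: unexpected end of file in LM block")
            fixed_pts.append(_parse_coord(current(i), i + 1))
            i += 1

        curve_pts: list[tuple[float, float]] = []
        specimen_id: str | None = None
        scale: float | None = None
        meta: dict = {}
        while i < n_lines:
            line = current(i)
            if not line:
                i += 1
                continue
            upper = line.upper()
            if upper.startswith(("LM=", "LM3=")):
                break
            if upper.startswith("CURVES="):
                n_curves = _parse_count(line, "CURVES", i + 1)
                i += 1
                for _ in range(n_curves):
                    if i >= n_lines or not current(i).upper().startswith("POINTS="):
                        raise TPSParseError(
                            f"line {i + 1}: expected POINTS= line inside CURVES block"
                        )
                    n_pts = _parse_count(current(i), "POINTS", i + 1)
                    i += 1
                    for _ in range(n_pts):
                        if i >= n_lines:
                            raise TPSParseError(
                                f"line {i + 1}: unexpected end of file in POINTS block"
                            )
                        curve_pts.append(_parse_coord(current(i), i + 1))
                        i += 1
            elif upper.startswith("ID="):
                specimen_id = line.split("=", 1)[1].strip()
                i += 1
            elif upper.startswith("SCALE="):
                try:
                    scale = float(line.split("=", 1)[1])
                except ValueError as exc:
                    raise TPSParseError(f"line {i + 1}: malformed SCALE line") from exc
                i += 1
            elif upper.startswith(("IMAGE=", "COMMENT=", "VARIABLES=")):
                key, _, value = line.partition("=")
                meta[key.lower()] = value.strip()
                i += 1
            else:
                raise TPSParseError(f"line {i + 1}: unexpected line in record: {line!r}")

        if specimen_id is None:
            specimen_id = f"spec{len(configs)}"
        pts = np.array(fixed_pts + curve_pts, dtype=float)
        if scale is not None:
            pts = pts * scale
        fixed_idx = tuple(range(n_fixed))
        semi_idx = tuple(range(n_fixed, n_fixed + len(curve_pts)))

        if sidecar is not None and specimen_id in sidecar:
            entry = dict(sidecar[specimen_id])
            if not semi_idx and "semi_indices" in entry:
                semi_idx = tuple(int(j) for j in entry.pop("semi_indices"))
                fixed_idx = tuple(
                    j for j in range(pts.shape[0]) if j not in set(semi_idx)
                )
            else:
                entry.pop("semi_indices", None)
            meta.update(entry)

        configs.append(
            LandmarkConfiguration(
                specimen_id=specimen_id,
                points=pts,
                fixed_indices=fixed_idx,
                semi_indices=semi_idx,
                scale=scale,
                meta=meta,
            )
        )
    return configs


def write_tps(configs: Sequence[LandmarkConfiguration], path: str | Path) -> Path:
    """Write configurations to a TPS file re-readable by :func:`read_tps`.

    Fixed landmarks go in the LM block, semi-landmarks into a single CURVES
    block (they must occupy the trailing index block), and coordinates are
    divided back out by ``scale`` when one is set, so that read(write(x))
    round-trips.  Field order is deterministic.
    """
    if not configs:
        raise ValueError("write_tps: empty configuration list")
    path = Path(path)
    out: list[str] = []
    for cfg in configs:
        n = cfg.n_points
        semis = cfg.semi_indices
        if semis and list(semis) != list(range(n - len(semis), n)):
            raise ValueError(
                f"{cfg.specimen_id}: semi-landmarks must occupy the trailing "
                "index block to be representable as a CURVES section"
            )
        pts = cfg.points if cfg.scale is None else cfg.points / cfg.scale
        n_fixed = n - len(semis)
        out.append(f"LM={n_fixed}")
        for x, y in pts[:n_fixed]:
            out.append(f"{x:.17g} {y:.17g}")
        if semis:
            out.append("CURVES=1")
            out.append(f"POINTS={len(semis)}")
            for x, y in pts[n_fixed:]:
                out.append(f"{x:.17g} {y:.17g}")
        if "image" in cfg.meta:
            out.append(f"IMAGE={cfg.meta['image']}")
        out.append(f"ID={cfg.specimen_id}")
        if cfg.scale is not None:
            out.append(f"SCALE={cfg.scale:.17g}")
    path.write_text("\n".join(out) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# Isotope CSV
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ["specimen_id", "taxon", "phase", "d13C", "d15N"]
_OPTIONAL_COLS = ["dental_stage", "M3_length", "site", "status"]


def read_isotope_csv(path: str | Path, on_missing: str = "error") -> list[IsotopeRecord]:
    """Read an isotope table (CSV) into :class:`IsotopeRecord` rows.

    ``on_missing`` controls rows whose mandatory δ13C/δ15N is empty:
    ``"error"`` raises, ``"drop"`` silently removes them, ``"keep"`` keeps
    them with NaN replaced by None is not allowed — they are dropped with a
    flag in the record count.  Non-numeric δ values always raise, naming the
    offending specimen ids.
    """
    if on_missing not in {"error", "drop"}:
        raise ValueError("on_missing must be 'error' or 'drop'")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    missing_cols = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing_cols:
        raise IsotopeValidationError(f"missing required columns: {missing_cols}")
    if df.empty:
        return []

    def _clean(s: pd.Series) -> pd.Series:
        # tolerate unicode minus signs from spreadsheet exports
        return s.str.strip().str.replace("−", "-", regex=False)

    records: list[IsotopeRecord] = []
    bad_numeric: list[str] = []
    missing_rows: list[str] = []
    for col in ("d13C", "d15N"):
        df[col] = _clean(df[col].astype("string"))
    for _, row in df.iterrows():
        sid = (row["specimen_id"] or "").strip()
        values: dict[str, float] = {}
        skip = False
        for col in ("d13C", "d15N"):
            raw = row[col]
            if raw is pd.NA or raw is None or raw == "":
                missing_rows.append(sid)
                skip = True
                break
            try:
                values[col] = float(raw)
            except ValueError:
                bad_numeric.append(sid)
                skip = True
                break
        if skip:
            continue

        def _opt_float(col: str) -> float | None:
            if col not in df.columns:
                return None
            raw = row[col]
            if pd.isna(raw) or str(raw).strip() == "":
                return None
            return float(str(raw).replace("−", "-"))

        def _opt_str(col: str) -> str | None:
            if col not in df.columns or pd.isna(row[col]):
                return None
            return str(row[col]).strip()

        stage = _opt_float("dental_stage")
        records.append(
            IsotopeRecord(
                specimen_id=sid,
                taxon=(row["taxon"] or "").strip(),
                phase=(row["phase"] or "").strip(),
                d13C=values["d13C"],
                d15N=values["d15N"],
                dental_stage=None if stage is None else int(stage),
                M3_length=_opt_float("M3_length"),
                site=_opt_str("site"),
                status=_opt_str("status"),
            )
        )
    if bad_numeric:
        raise IsotopeValidationError(
            f"non-numeric delta values for specimens: {sorted(set(bad_numeric))}"
        )
    if missing_rows and on_missing == "error":
        raise IsotopeValidationError(
            f"missing mandatory delta values for specimens: {sorted(set(missing_rows))}"
        )
    return records


def records_to_frame(records: Iterable[IsotopeRecord]) -> pd.DataFrame:
    """Tabulate isotope records as a DataFrame (columns in canonical order)."""
    rows = [
        {
            "specimen_id": r.specimen_id,
            "taxon": r.taxon,
            "phase": r.phase,
            "d13C": r.d13C,
            "d15N": r.d15N,
            "dental_stage": r.dental_stage,
            "M3_length": r.M3_length,
            "site": r.site,
            "status": r.status,
        }
        for r in records
    ]
    return pd.DataFrame(rows, columns=_REQUIRED_COLS + _OPTIONAL_COLS)
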
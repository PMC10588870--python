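"""Tabular I/O for leaf records, cluster datasheets and per-plant totals.

All data files are plain CSV (comma separator, UTF-8, header row, ``.``
decimal).  Lengths are centimetres and areas cm² everywhere on disk; inches
exist only inside :class:`palmleaf.scoring_board.BoardSpec`.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "LeafRecord",
    "RunConfig",
    "LeafTableError",
    "read_leaf_table",
    "write_leaf_table",
    "read_totals",
    "write_totals",
    "load_field_totals",
    "load_greenhouse_totals",
]

#: CSV columns of the canonical leaf table, in order.
LEAF_COLUMNS = [
    "plant_id",
    "leaf_id",
    "L_cm",
    "W_cm",
    "LA_cm2",
    "cluster_key",
    "is_representative",
    "source",
]

VALID_SOURCES = ("image", "manual", "synthetic")


class LeafTableError(ValueError):
    """Raised when a leaf CSV has missing columns or malformed rows."""


@dataclass
class LeafRecord:
    """One leaf's morphological descriptors and (optionally) its area.

    Parameters
    ----------
    plant_id, leaf_id
        Identity of the leaf within the experiment.
    L, W
        Leaf length and width in cm: the two point-to-point spans used by
        the allometric models (L along the leaf's main axis, W across it).
    LA
        Measured one-sided leaf area in cm², when available.
    cluster_key
        Scoring-board cell ``(L_cell, W_cell)`` in inches, assigned by
        :func:`palmleaf.scoring_board.assign_cluster`.
    is_representative
        Whether this leaf was sampled as its cluster's representative.
    source
        Provenance of the measurements: ``image``, ``manual`` or
        ``synthetic``.
    """

    plant_id: str
    leaf_id: str
    L: float
    W: float
    LA: float | None = None
    cluster_key: tuple[float, float] | None = None
    is_representative: bool = False
    source: str = "manual"

    def __post_init__(self) -> None:
        if not (self.L > 0 and self.W > 0):
            raise ValueError(
                f"leaf {self.plant_id}/{self.leaf_id}: L and W must be > 0 "
                f"(got L={self.L}, W={self.W})"
            )
        if self.LA is not None and not self.LA > 0:
            raise ValueError(
                f"leaf {self.plant_id}/{self.leaf_id}: LA must be > 0 when present"
            )
        if self.source not in VALID_SOURCES:
            raise ValueError(f"unknown source {self.source!r}")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (see :mod:`palmleaf.cli`)."""

    out_dir: Path = Path(".")
    seed: int = 0
    ppcm: float | None = None
    marker_cm: float | None = None
    board: "object | None" = None  # BoardSpec; default built lazily
    model: str = "builtin:model4"
    k_representatives: int = 2
    log_level: str = "INFO"

    def config_hash(self) -> str:
        """Stable hash of the configuration, recorded in run logs."""
        payload = {
            k: (str(v) if isinstance(v, Path) else
                dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# leaf tables
# ---------------------------------------------------------------------------

def _format_cluster_key(key: tuple[float, float] | None) -> str:
    if key is None:
        return ""
    parts = []
    for v in key:
        parts.append("overflow" if math.isinf(v) else format(v, "g"))
    return "x".join(parts)


def _parse_cluster_key(text: str) -> tuple[float, float] | None:
    if not text:
        return None
    parts = text.split("x")
    if len(parts) != 2:
        raise ValueError(f"bad cluster key {text!r}")
    return tuple(math.inf if p == "overflow" else float(p) for p in parts)


def write_leaf_table(records: Iterable[LeafRecord], path: str | Path) -> None:
    """Write leaf records to CSV in the canonical column order."""
    rows = []
    for r in records:
        rows.append(
            {
                "plant_id": r.plant_id,
                "leaf_id": r.leaf_id,
                "L_cm": repr(float(r.L)),
                "W_cm": repr(float(r.W)),
                "LA_cm2": "" if r.LA is None else repr(float(r.LA)),
                "cluster_key": _format_cluster_key(r.cluster_key),
                "is_representative": int(bool(r.is_representative)),
                "source": r.source,
            }
        )
    pd.DataFrame(rows, columns=LEAF_COLUMNS).to_csv(path, index=False)


def read_leaf_table(path: str | Path) -> list[LeafRecord]:
    """Read a leaf CSV, reporting malformed rows with their line numbers.

    Raises
    ------
    LeafTableError
        If required columns are missing, or any row has non-numeric or
        non-positive dimensions.  The message lists every bad row as
        ``line N: reason`` (line 1 is the header).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"plant_id", "leaf_id", "L_cm", "W_cm"}
    missing = required - set(df.columns)
    if missing:
        raise LeafTableError(f"{path}: missing required columns {sorted(missing)}")

    records: list[LeafRecord] = []
    problems: list[str] = []
    for i, row in df.iterrows():
        line = i + 2  # header occupies line 1
        try:
            la_text = row.get("LA_cm2", "")
            records.append(
                LeafRecord(
                    plant_id=str(row["plant_id"]),
                    leaf_id=str(row["leaf_id"]),
                    L=float(row["L_cm"]),
                    W=float(row["W_cm"]),
                    LA=float(la_text) if la_text != "" else None,
                    cluster_key=_parse_cluster_key(str(row.get("cluster_key", ""))),
                    is_representative=str(row.get("is_representative", "0"))
                    in ("1", "True", "true"),
                    source=str(row.get("source", "manual")) or "manual",
                )
            )
        except (ValueError, TypeError) as exc:
            problems.append(f"line {line}: {exc}")
    if problems:
        raise LeafTableError(f"{path}: {len(problems)} malformed row(s); " + "; ".join(problems))
    return records


# ---------------------------------------------------------------------------
# per-plant totals
# ---------------------------------------------------------------------------

def write_totals(totals: "pd.Series | dict", path: str | Path, column: str = "total_LA") -> None:
    """Write a per-plant totals vector as a two-column CSV keyed by plant_id."""
    s = pd.Series(totals)
    s.rename_axis("plant_id").rename(column).to_csv(path)


def read_totals(path: str | Path, column: str | None = None) -> pd.Series:
    """Read a per-plant totals CSV into a Series indexed by plant_id."""
    df = pd.read_csv(path, dtype={0: str})
    df = df.set_index(df.columns[0])
    col = column if column is not None else df.columns[0]
    return df[col].astype(float)


# ---------------------------------------------------------------------------
# bundled validation datasets (printed per-plant totals)
# ---------------------------------------------------------------------------

def _load_bundled(name: str) -> pd.DataFrame:
    with resources.files("palmleaf.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh, dtype={"plant_id": str})


def load_field_totals() -> pd.DataFrame:
    """Per-plant total leaf area of nine field-grown cassava plants.

    Columns ``total_photo_clustered`` (image-based measurement with
    scoring-board clustering, M1), ``total_meter_clustered`` (leaf-area
    meter with clustering, M2) and ``total_meter_all`` (meter on every
    leaf, M3), as published.  Totals are the printed per-plant numbers and
    are used as given for method comparison.
    """
    return _load_bundled("field_plant_totals.csv")


def load_greenhouse_totals() -> pd.DataFrame:
    """Per-plant totals for six greenhouse plants: hybrid estimate
    (clustering + LA = 0.42·L·W) versus the image-based measurement."""
    return _load_bundled("greenhouse_plant_totals.csv")
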
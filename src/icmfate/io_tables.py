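"""Per-nucleus feature tables: reading, lineage normalisation, result output.

Input tables are CSV/TSV files with one row per segmented nucleus carrying a
specimen identifier, a nucleus identifier, the 3D centroid in micrometres and
either NANOG/GATA6 fluorescence intensities, a lineage label, or both.
Column names vary between sources, so reading goes through a semantic
column map; a default profile for deposited embryo-style tables is built in.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Canonical lineage labels. EPI = NANOG+/GATA6−, PRE = NANOG−/GATA6+.
LINEAGES = ("TE", "DN", "DP", "EPI", "PRE")

# Fixed synonym dictionary; keys are labels after _canon_key().
_LINEAGE_SYNONYMS = {
    "TE": "TE",
    "DN": "DN",
    "DP": "DP",
    "EPI": "EPI",
    "EPIBLAST": "EPI",
    "N+G-": "EPI",
    "NANOG+GATA6-": "EPI",
    "PRE": "PRE",
    "PRE(EMPTY)": "PRE",
    "PRIMITIVEENDODERM": "PRE",
    "N-G+": "PRE",
    "NANOG-GATA6+": "PRE",
}

#: Default semantic→column profile for deposited embryo-style tables.
DEFAULT_EMBRYO_COLUMNS = {
    "specimen_id": "Embryo_ID",
    "nucleus_id": "Cell_ID",
    "x": "X",
    "y": "Y",
    "z": "Z",
    "nanog": "NANOG",
    "gata6": "GATA6",
    "lineage": "Identity",
}


class TableFormatError(ValueError):
    """Raised when an input table violates the expected schema."""


def _canon_key(label: str) -> str:
    # Case/punctuation-insensitive: strip spaces, slashes, underscores and
    # normalise unicode minus signs before lookup.
    s = str(label).strip().upper()
    for ch in (" ", "/", "_", "."):
        s = s.replace(ch, "")
    return s.replace("−", "-").replace("–", "-")


def normalize_lineage(label: str) -> str:
    """Map a raw lineage string onto the canonical set {TE, DN, DP, EPI, PRE}.

    Unknown labels raise rather than being dropped: they usually signal a
    schema mismatch, not a new cell type.
    """
    key = _canon_key(label)
    try:
        return _LINEAGE_SYNONYMS[key]
    except KeyError:
        raise TableFormatError(f"unknown lineage label: {label!r}") from None


@dataclass
class NucleusRecord:
    """One segmented nucleus.

    Coordinates are centroids in µm; intensities are background-subtracted
    fluorescence in arbitrary units (non-negative). ``lineage`` is one of
    ``LINEAGES`` or ``None`` when only intensities are available.
    """

    specimen_id: str
    nucleus_id: str
    x: float
    y: float
    z: float
    nanog: float | None = None
    gata6: float | None = None
    lineage: str | None = None

    def __post_init__(self) -> None:
        for name in ("x", "y", "z"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite coordinate {name} in nucleus {self.nucleus_id}")
        for name in ("nanog", "gata6"):
            v = getattr(self, name)
            if v is not None and (not np.isfinite(v) or v < 0):
                raise ValueError(f"invalid {name} intensity {v!r} in nucleus {self.nucleus_id}")
        if self.lineage is not None and self.lineage not in LINEAGES:
            raise ValueError(f"lineage {self.lineage!r} not in {LINEAGES}")

    @property
    def position(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class SpecimenTable:
    """All nuclei of one specimen (organoid or embryo), in input order."""

    specimen_id: str
    records: list[NucleusRecord]
    specimen_kind: str = "organoid"  # or "embryo"
    age_label: str | None = None
    #: generator ground truth (synthetic specimens only); never read by the
    #: analysis path, only by tests and recovery checks.
    ground_truth: list[str] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError(f"specimen {self.specimen_id}: empty record set")
        ids = [r.nucleus_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError(f"specimen {self.specimen_id}: duplicate nucleus ids")
        for r in self.records:
            if r.specimen_id != self.specimen_id:
                raise ValueError(
                    f"record {r.nucleus_id} belongs to {r.specimen_id}, not {self.specimen_id}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def nucleus_ids(self) -> list[str]:
        return [r.nucleus_id for r in self.records]

    @property
    def positions(self) -> np.ndarray:
        """(n, 3) centroid array in µm, record order."""
        return np.array([[r.x, r.y, r.z] for r in self.records], dtype=float)

    @property
    def nanog(self) -> np.ndarray:
        if any(r.nanog is None for r in self.records):
            raise ValueError(f"specimen {self.specimen_id}: missing NANOG intensities")
        return np.array([r.nanog for r in self.records], dtype=float)

    @property
    def gata6(self) -> np.ndarray:
        if any(r.gata6 is None for r in self.records):
            raise ValueError(f"specimen {self.specimen_id}: missing GATA6 intensities")
        return np.array([r.gata6 for r in self.records], dtype=float)

    @property
    def lineages(self) -> list[str]:
        missing = [r.nucleus_id for r in self.records if r.lineage is None]
        if missing:
            raise ValueError(
                f"specimen {self.specimen_id}: records without lineage label: {missing[:5]}"
            )
        return [r.lineage for r in self.records]

    @property
    def has_lineage(self) -> bool:
        return all(r.lineage is not None for r in self.records)

    @property
    def has_intensities(self) -> bool:
        return all(r.nanog is not None and r.gata6 is not None for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "specimen_id": [r.specimen_id for r in self.records],
                "nucleus_id": [r.nucleus_id for r in self.records],
                "x": [r.x for r in self.records],
                "y": [r.y for r in self.records],
                "z": [r.z for r in self.records],
                "nanog": [r.nanog for r in self.records],
                "gata6": [r.gata6 for r in self.records],
                "lineage": [r.lineage for r in self.records],
            }
        )


def read_nucleus_table(
    path: str | os.PathLike,
    column_map: Mapping[str, str] | None = None,
    specimen_kind: str = "embryo",
) -> list[SpecimenTable]:
    """Read a per-nucleus CSV/TSV into one :class:`SpecimenTable` per specimen.

    Parameters
    ----------
    path:
        Header-bearing CSV or TSV file (delimiter sniffed from the extension,
        ``.tsv``/``.txt`` → tab, otherwise comma).
    column_map:
        Mapping from semantic field names (``specimen_id``, ``nucleus_id``,
        ``x``, ``y``, ``z`` and optionally ``nanog``, ``gata6``, ``lineage``)
        to column names in the file. Defaults to the deposited-embryo profile.
    specimen_kind:
        ``"embryo"`` or ``"organoid"``; recorded on each table.

    At least one of the intensity pair or the lineage column must be mapped
    and present. Lineage strings are normalised to the canonical label set;
    unknown strings raise. Row order within a specimen is preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    cmap = dict(column_map) if column_map is not None else dict(DEFAULT_EMBRYO_COLUMNS)

    required = ("specimen_id", "nucleus_id", "x", "y", "z")
    for sem in required:
        if sem not in cmap:
            raise TableFormatError(f"column_map lacks required field {sem!r}")

    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    for sem in required:
        if cmap[sem] not in df.columns:
            raise TableFormatError(f"missing mapped column {cmap[sem]!r} (field {sem!r})")

    has_intens = (
        "nanog" in cmap
        and "gata6" in cmap
        and cmap["nanog"] in df.columns
        and cmap["gata6"] in df.columns
    )
    has_lineage = "lineage" in cmap and cmap["lineage"] in df.columns
    if not has_intens and not has_lineage:
        raise TableFormatError("table has neither intensity columns nor a lineage column")

    def _num(col: str, row_idx: int, value: str, allow_none: bool = False) -> float | None:
        if allow_none and (value is None or (isinstance(value, float) and np.isnan(value)) or value == ""):
            return None
        try:
            return float(value)
        except (TypeError, ValueError):
            raise TableFormatError(
                f"non-numeric value {value!r} in column {col!r} at row {row_idx}"
            ) from None

    tables: dict[str, list[NucleusRecord]] = {}
    order: list[str] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        row = dict(zip(df.columns, row))
        sid = str(row[cmap["specimen_id"]])
        rec = NucleusRecord(
            specimen_id=sid,
            nucleus_id=str(row[cmap["nucleus_id"]]),
            x=_num(cmap["x"], idx, row[cmap["x"]]),
            y=_num(cmap["y"], idx, row[cmap["y"]]),
            z=_num(cmap["z"], idx, row[cmap["z"]]),
            nanog=_num(cmap["nanog"], idx, row[cmap["nanog"]], allow_none=True) if has_intens else None,
            gata6=_num(cmap["gata6"], idx, row[cmap["gata6"]], allow_none=True) if has_intens else None,
            lineage=(
                normalize_lineage(row[cmap["lineage"]])
                if has_lineage and row[cmap["lineage"]] not in (None, "")
                and not (isinstance(row[cmap["lineage"]], float) and np.isnan(row[cmap["lineage"]]))
                else None
            ),
        )
        if sid not in tables:
            tables[sid] = []
            order.append(sid)
        tables[sid].append(rec)

    return [
        SpecimenTable(specimen_id=sid, records=tables[sid], specimen_kind=specimen_kind)
        for sid in order
    ]


def write_nucleus_table(tables: Sequence[SpecimenTable], path: str | os.PathLike) -> Path:
    """Write specimens back to one CSV in the default embryo dialect."""
    path = Path(path)
    frames = [t.to_frame() for t in tables]
    df = pd.concat(frames, ignore_index=True)
    df = df.rename(columns=DEFAULT_EMBRYO_COLUMNS)
    df.to_csv(path, index=False)
    return path


def filter_icm(table: SpecimenTable) -> SpecimenTable:
    """Drop trophectoderm (TE) cells, keeping the inner cell mass.

    Every record must carry a lineage label; organoid tables without TE
    labels pass through unchanged. Idempotent.
    """
    kept = []
    for r in table.records:
        if r.lineage is None:
            raise ValueError(
                f"specimen {table.specimen_id}: record {r.nucleus_id} has no lineage label"
            )
        if r.lineage != "TE":
            kept.append(r)
    if not kept:
        raise ValueError(f"specimen {table.specimen_id}: no ICM cells after TE removal")
    gt = None
    if table.ground_truth is not None:
        gt = [g for r, g in zip(table.records, table.ground_truth) if r.lineage != "TE"]
    return SpecimenTable(
        specimen_id=table.specimen_id,
        records=kept,
        specimen_kind=table.specimen_kind,
        age_label=table.age_label,
        ground_truth=gt,
    )


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | os.PathLike) -> dict[str, Path]:
    """Write named result tables as TSV files with ≥6 significant digits.

    Column order is taken from each DataFrame as-is (callers construct them
    deterministically); an empty frame yields a header-only file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False, float_format="%.8g")
        written[name] = p
    return written


def read_result_table(path: str | os.PathLike) -> pd.DataFrame:
    """Read back a TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
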
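"""Minimal GenePix ATF dialect I/O.

Reads GAL array layouts and GPR per-spot result files (tab-separated
Axon Text File 1.0), and assembles a set of per-sample spot tables into a
spot-level cohort matrix keyed by ``(feature_id, replicate)`` x sample.

The dialect is intentionally narrow: the eight columns below are required
for GPR (five for GAL); any additional columns found in real exports are
ignored. Flags are recorded verbatim and acted upon downstream, never here.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError

GAL_COLUMNS = ("Block", "Column", "Row", "Name", "ID")
GPR_COLUMNS = GAL_COLUMNS + ("F635 Median", "B635 Median", "Flags")

Position = tuple[int, int, int]  # (block, row, column)


@dataclass(frozen=True)
class SpotRecord:
    """One quantified spot as read from a GPR data row."""

    block: int
    column: int
    row: int
    name: str
    id: str
    fg_median: float
    bg_median: float
    flag: int = 0

    @property
    def position(self) -> Position:
        return (self.block, self.row, self.column)


@dataclass
class ArrayLayout:
    """Spot layout of one array lot: feature identities and their
    (possibly duplicated) physical positions."""

    feature_ids: list[str]
    spot_map: dict[str, list[Position]]
    names: dict[str, str] = field(default_factory=dict)
    lot_id: str = ""

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_spots(self) -> int:
        return sum(len(v) for v in self.spot_map.values())

    def position_index(self) -> dict[Position, tuple[str, int]]:
        """Map each physical position to ``(feature_id, replicate_index)``."""
        out: dict[Position, tuple[str, int]] = {}
        for fid in self.feature_ids:
            for rep, pos in enumerate(self.spot_map[fid]):
                out[pos] = (fid, rep)
        return out

    def validate(self) -> None:
        if set(self.feature_ids) != set(self.spot_map):
            raise IntegrityError("feature_ids and spot_map disagree")
        seen: set[Position] = set()
        for fid in self.feature_ids:
            positions = self.spot_map[fid]
            if not positions:
                raise IntegrityError(f"feature {fid!r} maps to no spots")
            for pos in positions:
                if pos in seen:
                    raise IntegrityError(f"position {pos} mapped twice")
                seen.add(pos)


@dataclass
class SpotTable:
    """All spot records of a single hybridized array (one sample)."""

    sample_id: str
    records: list[SpotRecord]
    group: str | None = None  # "ALS" | "NDC", supplied by the sample sheet


@dataclass
class SpotCohort:
    """Spot-level cohort: aligned foreground/background/flag matrices with
    rows indexed by ``(feature_id, replicate)`` and columns by sample id."""

    fg: pd.DataFrame
    bg: pd.DataFrame
    flag: pd.DataFrame
    groups: pd.Series  # index: sample_id, values in {"ALS", "NDC"}
    layout: ArrayLayout | None = None

    @property
    def n_samples(self) -> int:
        return self.fg.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(dict.fromkeys(self.fg.index.get_level_values(0)))


def _read_atf(path: str | Path, required: Sequence[str]) -> tuple[pd.DataFrame, list[str]]:
    """Parse an ATF file, returning the data frame (all columns, as strings)
    and the list of optional header records."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("ATF"):
            raise FormatError(f"{path.name}: not an ATF file (missing 'ATF' signature)")
        counts = fh.readline().rstrip("\n").split("\t")
        try:
            n_optional = int(counts[0])
        except (ValueError, IndexError) as exc:
            raise FormatError(f"{path.name}: malformed ATF header-count line") from exc
        optional = [fh.readline().rstrip("\n").strip('"') for _ in range(n_optional)]
        body = fh.read()
    df = pd.read_csv(io.StringIO(body), sep="\t", dtype=str, keep_default_na=False)
    df.columns = [c.strip('"') for c in df.columns]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path.name}: required column {col!r} is missing")
    return df, optional


def _numeric(df: pd.DataFrame, col: str, path_name: str, as_int: bool = False) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{path_name}: non-numeric value {df[col].iloc[row]!r} in column "
            f"{col!r} at data row {row + 1}"
        )
    if as_int:
        return vals.to_numpy().astype(int)
    # numpy's strtod is round-trip exact; pandas' parser can drop the last ulp
    return df[col].to_numpy(dtype="U32").astype(float)


def read_gal(path: str | Path) -> ArrayLayout:
    """Read a GAL layout file.

    Spots sharing the same ID are grouped into one feature with multiple
    replicate positions. Feature order follows first appearance in the file.
    """
    path = Path(path)
    df, optional = _read_atf(path, GAL_COLUMNS)
    block = _numeric(df, "Block", path.name, as_int=True)
    row = _numeric(df, "Row", path.name, as_int=True)
    col = _numeric(df, "Column", path.name, as_int=True)
    ids = df["ID"].tolist()
    names = df["Name"].tolist()

    lot_id = ""
    for rec in optional:
        if rec.startswith("LotID="):
            lot_id = rec.split("=", 1)[1]

    spot_map: dict[str, list[Position]] = {}
    feature_names: dict[str, str] = {}
    seen: set[Position] = set()
    for b, r, c, fid, name in zip(block, row, col, ids, names):
        pos = (int(b), int(r), int(c))
        if pos in seen:
            raise IntegrityError(f"{path.name}: duplicate spot position {pos}")
        seen.add(pos)
        spot_map.setdefault(fid, []).append(pos)
        feature_names.setdefault(fid, name)

    layout = ArrayLayout(
        feature_ids=list(spot_map), spot_map=spot_map, names=feature_names, lot_id=lot_id
    )
    layout.validate()
    return layout


def read_gpr(
    path: str | Path,
    layout: ArrayLayout,
    sample_id: str | None = None,
    group: str | None = None,
) -> SpotTable:
    """Read a GPR results file against a known layout.

    The reader is non-destructive: flagged spots are kept with their flag.
    Group labels never come from the file itself.
    """
    path = Path(path)
    df, _ = _read_atf(path, GPR_COLUMNS)
    block = _numeric(df, "Block", path.name, as_int=True)
    row = _numeric(df, "Row", path.name, as_int=True)
    col = _numeric(df, "Column", path.name, as_int=True)
    fg = _numeric(df, "F635 Median", path.name)
    bg = _numeric(df, "B635 Median", path.name)
    flags = _numeric(df, "Flags", path.name, as_int=True)

    pos_index = layout.position_index()
    records: list[SpotRecord] = []
    for i in range(len(df)):
        pos = (int(block[i]), int(row[i]), int(col[i]))
        if pos not in pos_index:
            raise IntegrityError(f"{path.name}: position {pos} absent from layout")
        fid = pos_index[pos][0]
        if df["ID"].iloc[i] != fid:
            raise IntegrityError(
                f"{path.name}: ID {df['ID'].iloc[i]!r} at {pos} does not match "
                f"layout ID {fid!r}"
            )
        records.append(
            SpotRecord(
                block=pos[0],
                column=pos[2],
                row=pos[1],
                name=df["Name"].iloc[i],
                id=fid,
                fg_median=float(fg[i]),
                bg_median=float(bg[i]),
                flag=int(flags[i]),
            )
        )
    return SpotTable(sample_id=sample_id or path.stem, records=records, group=group)


def _fmt(x: float) -> str:
    """Shortest decimal text that round-trips to the same float."""
    return repr(int(x)) if float(x).is_integer() else repr(float(x))


def write_gpr(table: SpotTable, path: str | Path) -> Path:
    """Write a SpotTable as a minimal ATF 1.0 GPR file, re-readable by
    :func:`read_gpr` with identical record content."""
    if not table.records:
        raise ValueError("cannot write a GPR with no records")
    path = Path(path)
    lines = ["ATF\t1.0", f"1\t{len(GPR_COLUMNS)}", f'"SampleID={table.sample_id}"']
    lines.append("\t".join(GPR_COLUMNS))
    for rec in table.records:
        lines.append(
            "\t".join(
                (
                    str(rec.block),
                    str(rec.column),
                    str(rec.row),
                    rec.name,
                    rec.id,
                    _fmt(rec.fg_median),
                    _fmt(rec.bg_median),
                    str(rec.flag),
                )
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def write_gal(layout: ArrayLayout, path: str | Path) -> Path:
    """Write an ArrayLayout as a minimal ATF 1.0 GAL file."""
    path = Path(path)
    lines = ["ATF\t1.0", f"1\t{len(GAL_COLUMNS)}", f'"LotID={layout.lot_id}"']
    lines.append("\t".join(GAL_COLUMNS))
    for fid in layout.feature_ids:
        for b, r, c in layout.spot_map[fid]:
            lines.append("\t".join((str(b), str(c), str(r), layout.names.get(fid, fid), fid)))
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


def read_sample_sheet(path: str | Path) -> dict[str, str]:
    """Read a two-column (sample_id, group) tab-separated sample sheet.
    A header line 'sample_id<TAB>group' is permitted and skipped."""
    path = Path(path)
    mapping: dict[str, str] = {}
    for line_no, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"{path.name}: line {line_no} is not two tab-separated fields")
        sid, grp = parts[0].strip(), parts[1].strip()
        if line_no == 1 and (sid, grp) == ("sample_id", "group"):
            continue
        if grp not in ("ALS", "NDC"):
            raise FormatError(f"{path.name}: unknown group {grp!r} on line {line_no}")
        mapping[sid] = grp
    return mapping


def assemble_cohort(tables: Iterable[SpotTable], layout: ArrayLayout) -> SpotCohort:
    """Align per-sample spot tables into the spot-level cohort matrices.

    Rows are ordered by layout feature order, replicates within feature;
    columns are ALS samples first, then NDC, each sorted by sample id.
    """
    tables = list(tables)
    if not tables:
        raise ValueError("no spot tables given")
    for t in tables:
        if t.group not in ("ALS", "NDC"):
            raise IntegrityError(f"sample {t.sample_id!r} has no valid group label")
    tables.sort(key=lambda t: (t.group != "ALS", t.sample_id))

    pos_index = layout.position_index()
    index_rows = [
        (fid, rep) for fid in layout.feature_ids for rep in range(len(layout.spot_map[fid]))
    ]
    row_of = {key: i for i, key in enumerate(index_rows)}
    n_rows, n_cols = len(index_rows), len(tables)

    fg = np.empty((n_rows, n_cols))
    bg = np.empty((n_rows, n_cols))
    flag = np.zeros((n_rows, n_cols), dtype=int)
    for j, table in enumerate(tables):
        filled = np.zeros(n_rows, dtype=bool)
        for rec in table.records:
            key = pos_index.get(rec.position)
            if key is None:
                raise IntegrityError(
                    f"sample {table.sample_id!r}: position {rec.position} not in layout"
                )
            i = row_of[key]
            fg[i, j] = rec.fg_median
            bg[i, j] = rec.bg_median
            flag[i, j] = rec.flag
            filled[i] = True
        if not filled.all():
            missing = index_rows[int(np.flatnonzero(~filled)[0])]
            raise IntegrityError(
                f"sample {table.sample_id!r}: missing spot for feature "
                f"{missing[0]!r} replicate {missing[1]}"
            )

    mindex = pd.MultiIndex.from_tuples(index_rows, names=["feature_id", "replicate"])
    sample_ids = [t.sample_id for t in tables]
    groups = pd.Series([t.group for t in tables], index=sample_ids, name="group")
    return SpotCohort(
        fg=pd.DataFrame(fg, index=mindex, columns=sample_ids),
        bg=pd.DataFrame(bg, index=mindex, columns=sample_ids),
        flag=pd.DataFrame(flag, index=mindex, columns=sample_ids),
        groups=groups,
        layout=layout,
    )
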
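"""Data model for 384-well drug-screen measurements.

A screen is a tidy table of per-well records (one measured value per
plate/well/readout/timepoint).  Treatment wells carry one or two drugs with
doses in micromolar; vehicle wells define the per-plate baseline.  Wells that
belong to a pairwise 5x5 dose matrix name both drugs, with the partner dose
set to 0 on the single-agent edges, so every matrix cell is attributable to
exactly one drug pair.  Wells of the broad-range single-drug screen leave
``drug_b`` empty.
"""

from __future__ import annotations

import itertools
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError, RecordError, SchemaError

logger = logging.getLogger(__name__)

PLATE_ROWS = "ABCDEFGHIJKLMNOP"  # 16 rows
PLATE_COLS = 24
_WELL_RE = re.compile(r"^([A-P])([0-9]{1,2})$")

CULTURE_FORMATS = ("2D", "3D")
ROLES = ("treatment", "vehicle", "positive_control")
READOUTS = ("viability", "confluency", "spheroid_size", "celltox", "nucview")

#: Canonical column order of the tidy on-disk format.
COLUMNS = (
    "plate_id", "well", "cell_line", "culture_format", "role",
    "drug_a", "dose_a", "drug_b", "dose_b",
    "readout", "timepoint", "tech_rep", "bio_rep", "value",
)

#: Relative tolerance used when matching doses to grid positions.
DOSE_RTOL = 1e-9


def parse_well(well: str) -> tuple[int, int]:
    """Parse a well label like ``"B07"`` into 0-based (row, column) indices."""
    m = _WELL_RE.match(str(well).strip())
    if not m:
        raise RecordError(f"invalid 384-well coordinate {well!r}")
    row = PLATE_ROWS.index(m.group(1))
    col = int(m.group(2))
    if not 1 <= col <= PLATE_COLS:
        raise RecordError(f"well column out of range in {well!r}")
    return row, col - 1


def well_name(row: int, col: int) -> str:
    return f"{PLATE_ROWS[row]}{col + 1:02d}"


@dataclass(frozen=True)
class WellRecord:
    """One measured well: identity, treatment, replicate structure, raw value."""

    plate_id: str
    well: str
    cell_line: str
    culture_format: str
    role: str
    drug_a: str
    dose_a: float
    drug_b: str
    dose_b: float
    readout: str
    timepoint: float
    tech_rep: int
    bio_rep: int
    value: float

    def __post_init__(self) -> None:
        parse_well(self.well)
        if self.culture_format not in CULTURE_FORMATS:
            raise RecordError(f"unknown culture format {self.culture_format!r}")
        if self.role not in ROLES:
            raise RecordError(f"unknown well role {self.role!r}")
        if self.readout not in READOUTS:
            raise RecordError(f"unknown readout {self.readout!r}")
        if self.dose_a < 0 or self.dose_b < 0:
            raise RecordError("doses must be nonnegative")
        if self.value < 0:
            raise RecordError("raw signal must be nonnegative")
        if self.timepoint < 0:
            raise RecordError("timepoint must be nonnegative")
        if self.tech_rep < 1 or self.bio_rep < 1:
            raise RecordError("replicate indices are 1-based")
        if self.role == "vehicle" and (self.dose_a != 0 or self.dose_b != 0):
            raise RecordError("vehicle wells must carry zero doses")
        if self.role == "treatment":
            if not self.drug_a and not self.drug_b:
                raise RecordError("treatment wells must name at least one drug")
            if not self.drug_b and self.dose_a <= 0:
                raise RecordError("single-agent treatment wells need one nonzero dose")


class ScreenDataset:
    """A collection of well records held as a tidy :class:`pandas.DataFrame`.

    The frame is validated on construction; ``(plate_id, well, readout,
    timepoint)`` must uniquely identify a record.
    """

    def __init__(self, records: pd.DataFrame | Iterable[WellRecord]):
        if not isinstance(records, pd.DataFrame):
            records = pd.DataFrame([r.__dict__ for r in records], columns=COLUMNS)
        df = records.copy()
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        df = df[list(COLUMNS)].reset_index(drop=True)
        for col in ("drug_a", "drug_b"):
            df[col] = df[col].fillna("").astype(str)
            df.loc[df[col].isin(("nan", "None")), col] = ""
        for col, dtype in (("dose_a", float), ("dose_b", float), ("value", float),
                           ("timepoint", float), ("tech_rep", int), ("bio_rep", int)):
            try:
                df[col] = df[col].astype(dtype)
            except (TypeError, ValueError) as exc:
                bad = pd.to_numeric(df[col], errors="coerce").isna()
                line = int(df.index[bad][0]) + 2  # header + 1-based
                raise RecordError(f"unparsable {col!r} near line {line}: {exc}") from exc
        self._validate(df)
        self.records = df

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        for well in df["well"].unique():
            parse_well(well)
        for col, allowed in (("culture_format", CULTURE_FORMATS), ("role", ROLES),
                             ("readout", READOUTS)):
            bad = set(df[col].unique()) - set(allowed)
            if bad:
                raise RecordError(f"unknown {col} value(s): {sorted(bad)}")
        if (df[["dose_a", "dose_b", "value", "timepoint"]] < 0).any().any():
            raise RecordError("doses, values and timepoints must be nonnegative")
        veh = df["role"] == "vehicle"
        if ((df.loc[veh, "dose_a"] != 0) | (df.loc[veh, "dose_b"] != 0)).any():
            raise RecordError("vehicle wells must carry zero doses")
        key = df[["plate_id", "well", "readout", "timepoint"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise RecordError(
                f"duplicate record key plate={dup.plate_id} well={dup.well} "
                f"readout={dup.readout} t={dup.timepoint}")

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ScreenDataset):
            return NotImplemented
        return self.records.equals(other.records)

    def __iter__(self) -> Iterator[WellRecord]:
        for row in self.records.itertuples(index=False):
            yield WellRecord(**row._asdict())

    @property
    def drug_panel(self) -> list[str]:
        """Distinct treatment drug names, sorted."""
        treat = self.records[self.records["role"] == "treatment"]
        names = set(treat["drug_a"]) | set(treat["drug_b"])
        names.discard("")
        return sorted(names)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def read_screen_csv(path) -> ScreenDataset:
    """Read a tidy per-well CSV into a validated :class:`ScreenDataset`."""
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s): {', '.join(missing)}")
    return ScreenDataset(df)


def write_screen_csv(dataset: ScreenDataset, path) -> None:
    dataset.to_csv(path)


def enumerate_pairs(drug_panel: Sequence[str]) -> list[tuple[str, str]]:
    """All unordered drug pairs of a panel, lexicographically ordered.

    For ``n`` distinct drugs this yields n*(n-1)/2 pairs, each once, with
    the two members of every pair themselves in lexicographic order.
    """
    panel = list(drug_panel)
    if len(set(panel)) != len(panel):
        dupes = sorted({d for d in panel if panel.count(d) > 1})
        raise DesignError(f"duplicate drug name(s): {dupes}")
    if len(panel) < 2:
        raise DesignError("need at least 2 drugs to form pairs")
    return list(itertools.combinations(sorted(panel), 2))


def _dose_axis(nonzero: Iterable[float]) -> np.ndarray:
    """Build the ascending dose axis [0, d1..dk], de-duplicated at DOSE_RTOL."""
    doses: list[float] = []
    for d in sorted(set(float(x) for x in nonzero)):
        if not doses or not np.isclose(d, doses[-1], rtol=DOSE_RTOL, atol=0.0):
            doses.append(d)
    return np.asarray([0.0] + doses)


def _dose_index(axis: np.ndarray, dose: float) -> int:
    hits = np.flatnonzero(np.isclose(axis, dose, rtol=DOSE_RTOL, atol=1e-300))
    if dose == 0.0:
        return 0
    if len(hits) != 1:
        raise DesignError(f"dose {dose} does not match the axis {axis}")
    return int(hits[0])


@dataclass
class DoseMatrix:
    """Grid of normalized responses for one (cell line, format, pair, readout, bio rep).

    ``response[i][j]`` is the mean normalized response (vehicle = 1) over
    technical replicates at dose ``doses_a[i]`` of ``drug_a`` combined with
    ``doses_b[j]`` of ``drug_b``; row/column 0 are the single-agent edges and
    ``response[0][0]`` the vehicle baseline.  Missing cells are NaN with
    ``n_tech`` 0.
    """

    cell_line: str
    culture_format: str
    drug_a: str
    drug_b: str
    doses_a: np.ndarray
    doses_b: np.ndarray
    readout: str
    bio_rep: int
    response: np.ndarray
    n_tech: np.ndarray

    @property
    def pair(self) -> tuple[str, str]:
        return (self.drug_a, self.drug_b)

    def transpose(self) -> "DoseMatrix":
        """Swap the two drugs (rows <-> columns)."""
        return DoseMatrix(
            cell_line=self.cell_line, culture_format=self.culture_format,
            drug_a=self.drug_b, drug_b=self.drug_a,
            doses_a=self.doses_b.copy(), doses_b=self.doses_a.copy(),
            readout=self.readout, bio_rep=self.bio_rep,
            response=self.response.T.copy(), n_tech=self.n_tech.T.copy())


def assemble_dose_matrices(normalized: pd.DataFrame, readout: str,
                           bio_rep: int) -> list[DoseMatrix]:
    """Assemble per-pair dose matrices from a table of normalized wells.

    ``normalized`` is a records frame (see :data:`COLUMNS`) with an extra
    ``norm_value`` column.  Only combination-screen wells (both drugs named)
    of the requested readout and biological replicate are gridded; single-agent
    edges are the rows with a partner dose of 0, and the vehicle corner is
    filled from the vehicle wells of the same cell line / format / replicate.
    Cells with no contributing technical replicate are flagged missing (NaN)
    and a warning is logged; the matrix is still returned.
    """
    if "norm_value" not in normalized.columns:
        raise SchemaError("normalized table lacks a 'norm_value' column")
    sel = normalized[
        (normalized["readout"] == readout)
        & (normalized["bio_rep"] == bio_rep)
    ]
    combo = sel[(sel["role"] == "treatment") & (sel["drug_a"] != "")
                & (sel["drug_b"] != "")]
    vehicle = sel[sel["role"] == "vehicle"]
    matrices: list[DoseMatrix] = []
    group_cols = ["cell_line", "culture_format", "drug_a", "drug_b"]
    for (cell_line, fmt, a, b), grp in sorted(
            combo.groupby(group_cols, sort=False),
            key=lambda kv: kv[0]):
        axis_a = _dose_axis(grp.loc[grp["dose_a"] > 0, "dose_a"])
        axis_b = _dose_axis(grp.loc[grp["dose_b"] > 0, "dose_b"])
        shape = (len(axis_a), len(axis_b))
        total = np.zeros(shape)
        count = np.zeros(shape, dtype=int)
        for row in grp.itertuples(index=False):
            i = _dose_index(axis_a, row.dose_a)
            j = _dose_index(axis_b, row.dose_b)
            total[i, j] += row.norm_value
            count[i, j] += 1
        with np.errstate(invalid="ignore"):
            response = np.where(count > 0, total / np.maximum(count, 1), np.nan)
        veh = vehicle[(vehicle["cell_line"] == cell_line)
                      & (vehicle["culture_format"] == fmt)]
        if len(veh):
            response[0, 0] = float(veh["norm_value"].mean())
            count[0, 0] = len(veh)
        else:
            response[0, 0] = np.nan
        if (count == 0).any():
            n_missing = int((count == 0).sum())
            logger.warning(
                "%s/%s %s+%s readout=%s bio_rep=%d: %d grid cell(s) have no "
                "technical replicates; flagged missing",
                cell_line, fmt, a, b, readout, bio_rep, n_missing)
        matrices.append(DoseMatrix(
            cell_line=cell_line, culture_format=fmt, drug_a=a, drug_b=b,
            doses_a=axis_a, doses_b=axis_b, readout=readout, bio_rep=bio_rep,
            response=response, n_tech=count))
    return matrices
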
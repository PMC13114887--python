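"""Domain types, tabular I/O and quality control for CBMN scoring data.

The unit of observation is one scored culture: a donor's blood sample,
processed on one culture day (an "experiment"), treated with a substance
before or after a gamma exposure, in which micronuclei (MN) were counted in a
known number of binucleated cells (BC).  Frequencies are conventionally
expressed per 500 BC.  The cytokinesis-block proliferation index (CBPI)
quality gate keeps cultures whose proliferation was adequate for scoring.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, asdict, fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import FormatError, MissingGroupError, ValidationError

logger = logging.getLogger(__name__)

TIMINGS = ("none", "pre", "post")
SOLVENTS = ("aqueous", "dmso", "undiluted")

#: columns a scoring table must provide (after column-name mapping)
MANDATORY_COLUMNS = (
    "donor_id",
    "experiment_id",
    "substance",
    "timing",
    "solvent",
    "dose_mGy",
    "n_bc_scored",
    "mn_count",
)
OPTIONAL_COLUMNS = ("n_mono", "n_bi", "n_multi")

#: minimum BC per condition recommended for scoring; enforced as a warning
MIN_BC_PER_CONDITION = 3000

CBPI_LOW, CBPI_HIGH = 1.3, 1.7


@dataclass(frozen=True)
class CultureRecord:
    """One scored culture.

    ``timing`` is ``"none"`` for control arms (untreated, irradiated or not),
    ``"pre"``/``"post"`` for substance administration relative to exposure.
    ``dose_mGy`` of 0 is permitted with any timing (unirradiated arms).
    """

    donor_id: str
    experiment_id: str
    substance: str
    timing: str
    solvent: str
    dose_mGy: float
    n_bc_scored: int
    mn_count: int
    n_mono: int | None = None
    n_bi: int | None = None
    n_multi: int | None = None

    def __post_init__(self) -> None:
        if self.timing not in TIMINGS:
            raise ValidationError(f"unknown timing {self.timing!r}; expected one of {TIMINGS}")
        if self.solvent not in SOLVENTS:
            raise ValidationError(f"unknown solvent {self.solvent!r}; expected one of {SOLVENTS}")
        if self.dose_mGy < 0:
            raise ValidationError(f"dose_mGy must be non-negative, got {self.dose_mGy}")
        if self.n_bc_scored < 1:
            raise ValidationError(f"n_bc_scored must be >= 1, got {self.n_bc_scored}")
        if self.mn_count < 0:
            raise ValidationError(f"mn_count must be non-negative, got {self.mn_count}")
        tallies = (self.n_mono, self.n_bi, self.n_multi)
        if any(t is not None for t in tallies):
            if any(t is None for t in tallies):
                raise ValidationError("CBPI tallies must be given all together or not at all")
            if any(t < 0 for t in tallies):  # type: ignore[operator]
                raise ValidationError("CBPI tallies must be non-negative")
            if sum(tallies) < 1:  # type: ignore[arg-type]
                raise ValidationError("CBPI tallies must total at least one cell")

    @property
    def frequency_per_500(self) -> float:
        return mn_frequency_per_500(self.mn_count, self.n_bc_scored)

    @property
    def cbpi_value(self) -> float | None:
        if self.n_mono is None:
            return None
        return cbpi(self.n_mono, self.n_bi, self.n_multi)  # type: ignore[arg-type]


@dataclass(frozen=True)
class FrequencyPer500BC:
    """MN frequency normalized to 500 binucleated cells, with optional SE."""

    value: float
    se: float | None = None

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValidationError(f"frequency must be non-negative, got {self.value}")
        if self.se is not None and self.se < 0:
            raise ValidationError(f"standard error must be non-negative, got {self.se}")

    def __float__(self) -> float:
        return float(self.value)


def mn_frequency_per_500(mn_count: int, n_bc_scored: int) -> float:
    """Rescale an MN count to the MN/500 BC convention.

    Exact rational scaling ``mn_count * 500 / n_bc_scored``; no rounding.
    """
    if n_bc_scored < 1:
        raise ValidationError("frequency undefined: n_bc_scored must be >= 1")
    if mn_count < 0:
        raise ValidationError(f"mn_count must be non-negative, got {mn_count}")
    return mn_count * 500 / n_bc_scored


def cbpi(n_mono: int, n_bi: int, n_multi: int) -> float:
    """Cytokinesis-block proliferation index (M1 + 2 M2 + 3 M3+) / N.

    1.0 means no cell divided; 3.0 means every cell passed two divisions.
    """
    total = n_mono + n_bi + n_multi
    if min(n_mono, n_bi, n_multi) < 0:
        raise ValidationError("CBPI tallies must be non-negative")
    if total < 1:
        raise ValidationError("CBPI undefined: all tallies zero")
    return (n_mono + 2 * n_bi + 3 * n_multi) / total


def cbpi_quality_flag(cbpi_value: float) -> str:
    """Return ``"pass"`` iff CBPI lies in the quality window [1.3, 1.7].

    Bounds are inclusive so that a control culture at exactly 1.7 passes.
    The flag travels with downstream summaries; data are never dropped.
    """
    return "pass" if CBPI_LOW <= cbpi_value <= CBPI_HIGH else "fail"


def records_to_frame(records: Iterable[CultureRecord]) -> pd.DataFrame:
    """Tabulate records; adds derived ``freq_per_500`` and ``cbpi`` columns."""
    rows = [asdict(r) for r in records]
    df = pd.DataFrame(rows, columns=[f.name for f in fields(CultureRecord)])
    if len(df):
        df["freq_per_500"] = df["mn_count"] * 500 / df["n_bc_scored"]
        df["cbpi"] = [r.cbpi_value for r in records] if rows else []
    else:
        df["freq_per_500"] = pd.Series(dtype=float)
        df["cbpi"] = pd.Series(dtype=float)
    return df


def read_scoring_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> list[CultureRecord]:
    """Read a delimited scoring table into validated records.

    ``column_map`` maps canonical field names to the file's header names
    (e.g. ``{"donor_id": "Donor"}``); unmapped fields use their own names.
    Unknown columns are tolerated and reported to the module logger.  A
    missing mandatory column raises :class:`FormatError`; an invalid value
    raises :class:`ValidationError` citing the offending row.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"scoring table not found: {path}")
    column_map = dict(column_map or {})
    header_for = {field: column_map.get(field, field) for field in MANDATORY_COLUMNS + OPTIONAL_COLUMNS}

    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = reader.fieldnames or []
        for field in MANDATORY_COLUMNS:
            if header_for[field] not in header:
                raise FormatError(f"missing mandatory column {header_for[field]!r} in {path.name}")
        known = {header_for[f] for f in MANDATORY_COLUMNS + OPTIONAL_COLUMNS}
        unknown = [c for c in header if c not in known]
        if unknown:
            logger.warning("%s: ignoring unknown columns %s", path.name, unknown)

        records: list[CultureRecord] = []
        for lineno, row in enumerate(reader, start=2):
            try:
                kwargs: dict = {
                    "donor_id": row[header_for["donor_id"]].strip(),
                    "experiment_id": row[header_for["experiment_id"]].strip(),
                    "substance": row[header_for["substance"]].strip(),
                    "timing": row[header_for["timing"]].strip(),
                    "solvent": row[header_for["solvent"]].strip(),
                    "dose_mGy": float(row[header_for["dose_mGy"]]),
                    "n_bc_scored": int(row[header_for["n_bc_scored"]]),
                    "mn_count": int(row[header_for["mn_count"]]),
                }
                for opt in OPTIONAL_COLUMNS:
                    raw = row.get(header_for[opt])
                    kwargs[opt] = int(raw) if raw not in (None, "") else None
                records.append(CultureRecord(**kwargs))
            except (ValueError, ValidationError) as exc:
                raise ValidationError(f"{path.name} line {lineno}: {exc}") from exc
    return records


def write_scoring_table(records: Sequence[CultureRecord], path: str | Path, delimiter: str = ",") -> None:
    """Write records back to a delimited file; inverse of :func:`read_scoring_table`."""
    path = Path(path)
    cols = [f.name for f in fields(CultureRecord)]
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(cols)
        for r in records:
            d = asdict(r)
            writer.writerow(["" if d[c] is None else d[c] for c in cols])


def summarize_condition(
    records: Sequence[CultureRecord],
    grouping: Sequence[str] = ("substance", "timing", "dose_mGy"),
    require: Sequence[tuple] | None = None,
) -> pd.DataFrame:
    """Per-condition mean and SE of MN/500 BC across cultures.

    The replication unit is the (donor, experiment) culture; SE is the sample
    SD over cultures divided by sqrt(n).  Where CBPI tallies are present the
    mean CBPI and its quality flag are attached.  Conditions with fewer than
    :data:`MIN_BC_PER_CONDITION` total BC scored are flagged, not dropped.

    ``require`` is an optional list of group-key tuples that must be present;
    a missing one raises :class:`MissingGroupError` naming the key.
    """
    if not records:
        raise MissingGroupError("no records to summarize")
    df = records_to_frame(records)
    for key in grouping:
        if key not in df.columns:
            raise MissingGroupError(f"grouping key {key!r} is not a record field")

    rows = []
    for key, grp in df.groupby(list(grouping), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        freqs = grp["freq_per_500"]
        n = len(freqs)
        mean = freqs.mean()
        se = freqs.std(ddof=1) / math.sqrt(n) if n > 1 else float("nan")
        total_bc = int(grp["n_bc_scored"].sum())
        cbpi_mean = grp["cbpi"].mean() if grp["cbpi"].notna().any() else None
        row = dict(zip(grouping, key))
        row.update(
            n=n,
            mean_mn_per_500=mean,
            se_mn_per_500=se,
            total_bc=total_bc,
            bc_sufficient=total_bc >= MIN_BC_PER_CONDITION,
            cbpi=cbpi_mean,
            cbpi_flag=cbpi_quality_flag(cbpi_mean) if cbpi_mean is not None else None,
        )
        rows.append(row)
        if total_bc < MIN_BC_PER_CONDITION:
            logger.warning("condition %s: only %d BC scored (< %d recommended)", key, total_bc, MIN_BC_PER_CONDITION)

    out = pd.DataFrame(rows)
    if require:
        have = {tuple(r[k] for k in grouping) for r in rows}
        for want in require:
            if tuple(want) not in have:
                raise MissingGroupError(f"required condition {want!r} absent from data")
    return out
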
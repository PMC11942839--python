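"""Life-table domain types and delimited-text I/O.

The canonical unit is one reared individual (:class:`DevRecord`).  Because
published thermal-biology studies usually report only cell means (temperature,
mean development time, n), a secondary *group-mean* input mode is accepted and
expanded into n identical pseudo-records flagged as aggregated.

Temperatures are degrees Celsius throughout; no unit conversion is ever
performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "DevRecord",
    "RateObservation",
    "TemperatureSeries",
    "LifetableParseError",
    "RowError",
    "ReadResult",
    "DEFAULT_COLUMNS",
    "read_lifetable",
    "write_lifetable",
    "expand_group_means",
    "read_mean_lifetable",
    "rates_from_records",
    "weighted_mean_observations",
    "non_developing_temperatures",
    "read_temperature_series",
    "table1_fixture_path",
]

SEXES = ("female", "male", "unknown")

#: default CSV header -> field mapping
DEFAULT_COLUMNS: Mapping[str, str] = {
    "species": "species",
    "sex": "sex",
    "temperature": "temperature_C",
    "dev_time": "dev_time_days",
    "emerged": "emerged",
    "replicate": "replicate",
}

_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f"}


class LifetableParseError(ValueError):
    """Fatal file-level problem (missing file, missing required column)."""


@dataclass(frozen=True)
class RowError:
    """One rejected input row, reported with its 1-based data row number."""

    row: int
    message: str


@dataclass(frozen=True)
class DevRecord:
    """One reared individual: egg-to-adult development under a constant T.

    ``dev_time`` is present if and only if the individual emerged, and is
    strictly positive (days).  ``aggregated`` marks pseudo-records expanded
    from a group mean rather than observed individuals.
    """

    species: str
    sex: str
    temperature: float
    dev_time: float | None
    emerged: bool
    replicate: int = 1
    aggregated: bool = False

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not math.isfinite(self.temperature):
            raise ValueError("temperature must be finite")
        if self.emerged:
            if self.dev_time is None:
                raise ValueError("emerged record requires dev_time")
            if not (self.dev_time > 0) or not math.isfinite(self.dev_time):
                raise ValueError("dev_time must be finite and > 0")
        elif self.dev_time is not None:
            raise ValueError("non-emerged record must not carry dev_time")
        if self.replicate < 1:
            raise ValueError("replicate identifier must be >= 1")


@dataclass(frozen=True)
class RateObservation:
    """(temperature °C, development rate 1/day) pair feeding the model fits.

    ``weight`` carries the cell n when observations originate from group
    means; individual observations have weight 1.
    """

    temperature: float
    rate: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("development rate must be >= 0")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")


@dataclass(frozen=True)
class TemperatureSeries:
    """Daily mean temperature series for degree-day accumulation.

    ``day_index`` starts at 1 and increases without gaps; ``dates`` is an
    optional parallel list of calendar labels.
    """

    t_mean: tuple[float, ...]
    day_index: tuple[int, ...] = ()
    dates: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not self.day_index:
            object.__setattr__(
                self, "day_index", tuple(range(1, len(self.t_mean) + 1))
            )
        if len(self.day_index) != len(self.t_mean):
            raise ValueError("day_index and t_mean lengths differ")
        expected = tuple(range(self.day_index[0], self.day_index[0] + len(self.t_mean))) if self.t_mean else ()
        if self.day_index != expected or (self.t_mean and self.day_index[0] < 1):
            raise ValueError("day_index must start >= 1, strictly increasing, no gaps")
        if self.dates is not None and len(self.dates) != len(self.t_mean):
            raise ValueError("dates length differs from series length")

    def __len__(self) -> int:
        return len(self.t_mean)


@dataclass
class ReadResult:
    """Parsed life table: valid records plus per-row rejection report."""

    records: list[DevRecord]
    errors: list[RowError] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _parse_bool(raw: object) -> bool:
    s = str(raw).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValueError(f"cannot interpret {raw!r} as boolean")


def read_lifetable(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> ReadResult:
    """Read a per-individual life-table CSV into validated records.

    Parameters
    ----------
    path
        CSV file with a header row; UTF-8, ``.`` decimal separator.
    columns
        Field -> column-name mapping; defaults to :data:`DEFAULT_COLUMNS`.
        ``replicate`` is optional in the file (defaults to 1).

    Returns
    -------
    ReadResult
        Valid :class:`DevRecord` rows and a list of :class:`RowError` for the
        rejected ones (non-numeric values, invariant violations).

    Raises
    ------
    LifetableParseError
        If the file is missing or a required column is absent.
    """
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    path = Path(path)
    if not path.exists():
        raise LifetableParseError(f"life-table file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    required = [cols[k] for k in ("species", "sex", "temperature", "dev_time", "emerged")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LifetableParseError(
            f"missing required column(s) {missing} in {path} (found {list(df.columns)})"
        )
    has_rep = cols["replicate"] in df.columns

    records: list[DevRecord] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        row = dict(zip(df.columns, row))
        try:
            emerged = _parse_bool(row[cols["emerged"]])
            raw_dt = str(row[cols["dev_time"]]).strip()
            dev_time = float(raw_dt) if raw_dt else None
            rec = DevRecord(
                species=str(row[cols["species"]]).strip(),
                sex=str(row[cols["sex"]]).strip().lower(),
                temperature=float(row[cols["temperature"]]),
                dev_time=dev_time,
                emerged=emerged,
                replicate=int(row[cols["replicate"]]) if has_rep else 1,
            )
        except (ValueError, KeyError) as exc:
            errors.append(RowError(row=i, message=str(exc)))
            continue
        records.append(rec)
    return ReadResult(records=records, errors=errors)


def write_lifetable(
    records: Iterable[DevRecord],
    path: str | Path,
    columns: Mapping[str, str] | None = None,
    header_comment: str | None = None,
) -> None:
    """Write records as a life-table CSV (inverse of :func:`read_lifetable`)."""
    cols = dict(DEFAULT_COLUMNS)
    if columns:
        cols.update(columns)
    df = pd.DataFrame(
        {
            cols["species"]: [r.species for r in records],
            cols["sex"]: [r.sex for r in records],
            cols["temperature"]: [r.temperature for r in records],
            cols["dev_time"]: [r.dev_time if r.dev_time is not None else "" for r in records],
            cols["emerged"]: [str(r.emerged).lower() for r in records],
            cols["replicate"]: [r.replicate for r in records],
        }
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def expand_group_means(
    species: str,
    sex: str,
    temperature: float,
    mean_dev_time: float | None,
    n: int,
) -> list[DevRecord]:
    """Expand one group-mean cell into n identical aggregated pseudo-records.

    A cell with no emergence (``mean_dev_time`` None) expands to n
    non-emerged records.
    """
    if n < 1:
        raise ValueError("group size n must be >= 1")
    emerged = mean_dev_time is not None
    return [
        DevRecord(
            species=species,
            sex=sex,
            temperature=temperature,
            dev_time=mean_dev_time,
            emerged=emerged,
            replicate=i + 1,
            aggregated=True,
        )
        for i in range(n)
    ]


def read_mean_lifetable(path: str | Path) -> ReadResult:
    """Read a group-mean life table (columns ``species,sex,temperature_C,
    mean_dev_time_days,n``) and expand each cell via
    :func:`expand_group_means`.

    An empty ``mean_dev_time_days`` cell means no emergence at that
    temperature (recorded as n non-emerged rows).
    """
    path = Path(path)
    if not path.exists():
        raise LifetableParseError(f"life-table file not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False, comment="#")
    required = ["species", "sex", "temperature_C", "mean_dev_time_days", "n"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise LifetableParseError(f"missing required column(s) {missing} in {path}")
    records: list[DevRecord] = []
    errors: list[RowError] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            raw = str(row["mean_dev_time_days"]).strip()
            mean_dt = float(raw) if raw else None
            cell = expand_group_means(
                species=str(row["species"]).strip(),
                sex=str(row["sex"]).strip().lower(),
                temperature=float(row["temperature_C"]),
                mean_dev_time=mean_dt,
                n=int(row["n"]),
            )
        except ValueError as exc:
            errors.append(RowError(row=i, message=str(exc)))
            continue
        records.extend(cell)
    return ReadResult(records=records, errors=errors)


def rates_from_records(
    records: Iterable[DevRecord],
) -> tuple[list[RateObservation], int]:
    """Convert emerged records to (T, 1/dev_time) observations.

    Non-emerged records are excluded; the second return value is their count.
    Rates keep full floating precision (no rounding).
    """
    obs: list[RateObservation] = []
    excluded = 0
    for rec in records:
        if not rec.emerged:
            excluded += 1
            continue
        assert rec.dev_time is not None
        obs.append(RateObservation(temperature=rec.temperature, rate=1.0 / rec.dev_time))
    return obs, excluded


def weighted_mean_observations(
    records: Iterable[DevRecord],
) -> list[RateObservation]:
    """Collapse emerged records to one mean-rate observation per temperature,
    weighted by the cell count n.

    This is the fitting unit used for published tables that report only cell
    means: expanded pseudo-records (or raw individuals) at each temperature
    become a single observation with weight equal to the number of
    individuals behind it.
    """
    by_t: dict[float, list[float]] = {}
    for rec in records:
        if rec.emerged:
            assert rec.dev_time is not None
            by_t.setdefault(rec.temperature, []).append(1.0 / rec.dev_time)
    out = []
    for t, rs in sorted(by_t.items()):
        # expanded pseudo-records are identical; keep their rate bit-exact
        rate = rs[0] if all(r == rs[0] for r in rs) else math.fsum(rs) / len(rs)
        out.append(RateObservation(temperature=t, rate=rate, weight=len(rs)))
    return out


def non_developing_temperatures(records: Iterable[DevRecord]) -> list[float]:
    """Temperatures at which no individual emerged (kept out of the fits).

    These enter reports as metadata; they never contribute zero-rate
    observations, which would bias both rate models.
    """
    seen: dict[float, bool] = {}
    for rec in records:
        seen[rec.temperature] = seen.get(rec.temperature, False) or rec.emerged
    return sorted(t for t, any_emerged in seen.items() if not any_emerged)


def read_temperature_series(path: str | Path) -> TemperatureSeries:
    """Read a daily temperature-series CSV.

    Accepts either ``day,t_mean_C`` or ``date,t_min_C,t_max_C`` (daily mean
    computed as the min/max midpoint).
    """
    path = Path(path)
    if not path.exists():
        raise LifetableParseError(f"temperature series not found: {path}")
    df = pd.read_csv(path, comment="#")
    if {"day", "t_mean_C"}.issubset(df.columns):
        if df["t_mean_C"].isna().any() or len(df) == 0:
            raise LifetableParseError(f"malformed temperature series: {path}")
        return TemperatureSeries(
            t_mean=tuple(float(x) for x in df["t_mean_C"]),
            day_index=tuple(int(d) for d in df["day"]),
        )
    if {"date", "t_min_C", "t_max_C"}.issubset(df.columns):
        if df[["t_min_C", "t_max_C"]].isna().any().any() or len(df) == 0:
            raise LifetableParseError(f"malformed temperature series: {path}")
        mid = (df["t_min_C"].astype(float) + df["t_max_C"].astype(float)) / 2.0
        return TemperatureSeries(
            t_mean=tuple(mid), dates=tuple(str(d) for d in df["date"])
        )
    raise LifetableParseError(
        f"temperature series {path} needs columns day,t_mean_C or date,t_min_C,t_max_C"
    )


def table1_fixture_path() -> Path:
    """Path of the packaged mean development-time fixture (2 species x 2
    sexes x 5 temperatures, n = 50 per cell; empty cells = no emergence)."""
    return Path(__file__).parent / "data" / "mean_dev_times.csv"
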
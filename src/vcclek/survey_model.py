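"""Interview data model, validation, and active-decade derivation.

The survey elicits, per fisher, demographic data, fishing gears, up to three
target species, coded decline drivers, and — per decade of activity — a
categorical catch-trend score together with the percentage the fisher assigns
to that score.  Five scores are used: major decline (MD), decline (D),
stable (S), increase (I) and major increase (MI).

Decades covered are the 1980s through the 2010s; the 2020s are structurally
excluded from the analysis (the survey design leaves them out to avoid
pandemic-era bias).  Activity before 1980 is tracked as a separate flag
because the virtual-catch cascade anchors such fishers at the pre-1980s
baseline.

The on-disk interview table is a delimited text file with one row per fisher
and response stratum (``response_for`` is ``overall`` or a species name);
fisher-level fields repeat across a fisher's rows.  See
:data:`DEFAULT_SCHEMA` for column names.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

#: Analysis decades, in chronological order.  The 2020s are deliberately absent.
DECADES: tuple[str, ...] = ("1980s", "1990s", "2000s", "2010s")

#: Pseudo-decade label for careers that started before 1980.
PRE_BASELINE = "pre1980s"

_DECADE_START = {d: int(d[:4]) for d in DECADES}


def decade_start(decade: str) -> int:
    """First calendar year of an analysis decade, e.g. ``"1990s"`` -> 1990."""
    return _DECADE_START[decade]


class TrendScore(enum.Enum):
    """Categorical catch-trend perception for one decade."""

    MD = "MD"
    D = "D"
    S = "S"
    I = "I"  # noqa: E741 - the field's own label
    MI = "MI"

    @property
    def sign(self) -> int:
        """-1 for declines, 0 for stable, +1 for increases."""
        if self in (TrendScore.MD, TrendScore.D):
            return -1
        if self is TrendScore.S:
            return 0
        return 1


@dataclass(frozen=True)
class TrendResponse:
    """One (decade, score, perceived percentage) elicitation.

    ``perceived_pct`` is the percentage the fisher attaches to the score
    (e.g. "decline" meaning a 25 % drop).  It must lie in [0, 100]: a decline
    cannot remove more than the whole catch.  For stable scores it is
    irrelevant and may be ``None``.
    """

    decade: str
    score: TrendScore
    perceived_pct: float | None = None

    def __post_init__(self) -> None:
        if self.decade not in DECADES:
            raise ValueError(f"unknown decade {self.decade!r}")
        if self.perceived_pct is not None and not 0.0 <= self.perceived_pct <= 100.0:
            raise ValueError(
                f"perceived_pct {self.perceived_pct} outside [0, 100]"
            )


@dataclass
class InterviewRecord:
    """One fisher's interview: demographics, gears, species and responses.

    ``responses`` maps a stratum key — ``"overall"`` or a species name — to
    the fisher's chronologically ordered trend responses for that stratum.
    """

    fisher_id: str
    village: str
    port_id: str
    interview_year: int
    age: int
    experience: int
    gears: frozenset[str] = frozenset()
    species: tuple[str, ...] = ()
    responses: dict[str, tuple[TrendResponse, ...]] = field(default_factory=dict)
    consented: bool = True
    drivers: tuple[str, ...] = ()

    def validate(self) -> None:
        if self.experience < 0:
            raise ValueError(f"{self.fisher_id}: negative experience")
        if self.age < self.experience:
            raise ValueError(f"{self.fisher_id}: age {self.age} < experience {self.experience}")
        if len(self.species) > 3:
            raise ValueError(f"{self.fisher_id}: more than three target species")
        for stratum, resps in self.responses.items():
            decs = [r.decade for r in resps]
            if sorted(decs, key=decade_start) != decs or len(set(decs)) != len(decs):
                raise ValueError(
                    f"{self.fisher_id}/{stratum}: responses not in unique decade order"
                )


class ActiveDecades(NamedTuple):
    """Decades a career overlaps, plus whether it began before 1980."""

    decades: frozenset[str]
    pre1980s: bool

    @property
    def entry_decade(self) -> str:
        """Earliest anchor: :data:`PRE_BASELINE` or the first active decade."""
        if self.pre1980s:
            return PRE_BASELINE
        return min(self.decades, key=decade_start)


def active_decades(interview_year: int, experience: int) -> ActiveDecades:
    """Decades whose calendar interval intersects the fisher's career.

    The career interval is ``[interview_year - experience, interview_year]``;
    a decade counts as active on any partial overlap.  Activity in the 2020s
    is ignored by design, and a start before 1980 is reported via the
    ``pre1980s`` flag rather than as a decade.
    """
    if experience < 0:
        raise ValueError("experience must be non-negative")
    if experience > interview_year - 1900:
        raise ValueError("career would start before 1900")
    start = interview_year - experience
    out = frozenset(
        d for d in DECADES
        if decade_start(d) <= interview_year and decade_start(d) + 9 >= start
    )
    return ActiveDecades(out, pre1980s=start < 1980)


# ---------------------------------------------------------------------------
# Port registry

@dataclass(frozen=True)
class Port:
    port_id: str
    name: str
    lon: float
    lat: float

    def __post_init__(self) -> None:
        if not -180.0 <= self.lon <= 180.0 or not -90.0 <= self.lat <= 90.0:
            raise ValueError(f"port {self.port_id}: coordinates out of bounds")


@dataclass
class PortRegistry:
    """Lookup of port-of-origin points (WGS84 lon/lat) keyed by port id."""

    ports: dict[str, Port] = field(default_factory=dict)

    def __getitem__(self, port_id: str) -> Port:
        try:
            return self.ports[port_id]
        except KeyError:
            raise KeyError(f"unknown port_id {port_id!r}") from None

    def __contains__(self, port_id: str) -> bool:
        return port_id in self.ports

    def add(self, port: Port) -> None:
        self.ports[port.port_id] = port

    @classmethod
    def from_csv(cls, path: str | Path) -> "PortRegistry":
        reg = cls()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                reg.add(Port(row["port_id"], row["name"],
                             float(row["lon"]), float(row["lat"])))
        return reg

    @classmethod
    def from_geojson(cls, path: str | Path) -> "PortRegistry":
        reg = cls()
        with open(path) as fh:
            fc = json.load(fh)
        for feat in fc["features"]:
            lon, lat = feat["geometry"]["coordinates"][:2]
            props = feat["properties"]
            reg.add(Port(str(props["port_id"]), props.get("name", ""), lon, lat))
        return reg

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["port_id", "name", "lon", "lat"])
            for p in self.ports.values():
                w.writerow([p.port_id, p.name, repr(p.lon), repr(p.lat)])


# ---------------------------------------------------------------------------
# Interview table I/O

#: Default column names of the interview table.
DEFAULT_SCHEMA: dict[str, str] = {
    "fisher_id": "fisher_id",
    "village": "village",
    "port_id": "port_id",
    "interview_year": "interview_year",
    "age": "age",
    "experience": "experience",
    "consented": "consented",
    "gears": "gears",          # ';'-separated labels
    "species": "species",      # ';'-separated, up to three
    "drivers": "drivers",      # ';'-separated coded labels
    "response_for": "response_for",  # 'overall' or a species name
    # per-decade: score_1980s, pct_1980s, ...
}

_REQUIRED = ["fisher_id", "village", "port_id", "interview_year",
             "age", "experience", "consented"]

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n"}


class Rejection(NamedTuple):
    line: int
    fisher_id: str
    reason: str


class LoadResult(NamedTuple):
    records: list[InterviewRecord]
    rejections: list[Rejection]


def _split(cell: str | None) -> tuple[str, ...]:
    if not cell:
        return ()
    return tuple(s.strip() for s in cell.split(";") if s.strip())


def _parse_bool(cell: str) -> bool:
    low = cell.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"unparseable boolean {cell!r}")


def _parse_responses(row: Mapping[str, str], schema: Mapping[str, str]
                     ) -> tuple[TrendResponse, ...]:
    out = []
    for dec in DECADES:
        raw = (row.get(f"score_{dec}") or "").strip()
        if not raw:
            continue
        try:
            score = TrendScore(raw)
        except ValueError:
            raise ValueError(f"unknown trend score {raw!r} for {dec}") from None
        pct_raw = (row.get(f"pct_{dec}") or "").strip()
        pct = float(pct_raw) if pct_raw else None
        if score is not TrendScore.S and pct is None:
            raise ValueError(f"missing perceived percentage for {score.value} in {dec}")
        if pct is not None and not 0.0 <= pct <= 100.0:
            raise ValueError(f"perceived percentage {pct} outside [0, 100] in {dec}")
        out.append(TrendResponse(dec, score, pct))
    return tuple(out)


def load_interviews(path: str | Path,
                    schema: Mapping[str, str] | None = None) -> LoadResult:
    """Read and validate an interview table.

    Rows sharing a ``fisher_id`` are merged into one record (each row carries
    one response stratum).  Invalid rows are reported per line with a reason
    instead of aborting the load; a missing required column is a
    configuration error and raises immediately.
    """
    schema = dict(DEFAULT_SCHEMA, **(schema or {}))
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: dict[str, InterviewRecord] = {}
    order: list[str] = []
    rejections: list[Rejection] = []
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        missing = [schema[c] for c in _REQUIRED if schema[c] not in header]
        if missing:
            raise KeyError(f"missing required column(s): {missing}")
        for lineno, row in enumerate(reader, start=2):
            fid = (row.get(schema["fisher_id"]) or "").strip()
            try:
                stratum = (row.get(schema["response_for"]) or "overall").strip() or "overall"
                responses = _parse_responses(row, schema)
                if fid in records:
                    rec = records[fid]
                    if stratum in rec.responses:
                        raise ValueError(f"duplicate response stratum {stratum!r}")
                    if responses:
                        rec.responses[stratum] = responses
                    continue
                rec = InterviewRecord(
                    fisher_id=fid,
                    village=row[schema["village"]].strip(),
                    port_id=row[schema["port_id"]].strip(),
                    interview_year=int(row[schema["interview_year"]]),
                    age=int(row[schema["age"]]),
                    experience=int(row[schema["experience"]]),
                    gears=frozenset(_split(row.get(schema["gears"]))),
                    species=_split(row.get(schema["species"])),
                    consented=_parse_bool(row[schema["consented"]]),
                    drivers=_split(row.get(schema["drivers"])),
                )
                if responses:
                    rec.responses[stratum] = responses
                rec.validate()
            except (ValueError, KeyError) as exc:
                rejections.append(Rejection(lineno, fid, str(exc)))
                continue
            records[fid] = rec
            order.append(fid)
    return LoadResult([records[f] for f in order], rejections)


def write_interviews(records: Iterable[InterviewRecord], path: str | Path) -> None:
    """Write records in the table layout :func:`load_interviews` reads."""
    cols = list(DEFAULT_SCHEMA.values())
    for dec in DECADES:
        cols += [f"score_{dec}", f"pct_{dec}"]
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=cols)
        w.writeheader()
        for rec in records:
            base = {
                "fisher_id": rec.fisher_id,
                "village": rec.village,
                "port_id": rec.port_id,
                "interview_year": rec.interview_year,
                "age": rec.age,
                "experience": rec.experience,
                "consented": str(rec.consented).lower(),
                "gears": ";".join(sorted(rec.gears)),
                "species": ";".join(rec.species),
                "drivers": ";".join(rec.drivers),
            }
            strata = rec.responses or {"overall": ()}
            for stratum, resps in strata.items():
                row = dict(base, response_for=stratum)
                for r in resps:
                    row[f"score_{r.decade}"] = r.score.value
                    if r.perceived_pct is not None:
                        row[f"pct_{r.decade}"] = repr(r.perceived_pct)
                w.writerow(row)


class FilterResult(NamedTuple):
    retained: list[InterviewRecord]
    removed: dict[str, int]


def filter_eligible(records: Sequence[InterviewRecord],
                    min_experience: int = 5,
                    inclusive: bool = True) -> FilterResult:
    """Keep consenting fishers with enough experience for decadal recall.

    The experience threshold is inclusive by default (fishers with exactly
    ``min_experience`` years are retained, matching the survey's observed
    experience minima); ``inclusive=False`` applies a strict ``>`` cut.
    Removal counts are reported per reason, counting each record once
    (non-consent takes precedence).
    """
    retained: list[InterviewRecord] = []
    removed = {"not_consented": 0, "insufficient_experience": 0}
    for rec in records:
        if not rec.consented:
            removed["not_consented"] += 1
        elif (rec.experience >= min_experience if inclusive
              else rec.experience > min_experience):
            retained.append(rec)
        else:
            removed["insufficient_experience"] += 1
    return FilterResult(retained, removed)
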
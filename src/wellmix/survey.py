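"""Curated survey of pipette-mixing stroke counts in 96-well protocols.

The packaged fixture transcribes stroke-count instructions ("pipette up and
down N times") collected from lab-forum posts, vendor kit documents, and
peer-reviewed protocol papers that use a 96-well plate and give an explicit
count.  Curation rules: entries listing two counts are split into separate
records; entries giving only a pipetting volume are excluded; a protocol
served at two URLs is counted once; the one "couple of times" instruction is
read as 2.  Ranges are reduced to their midpoint, so normalized counts can
be half-integers (e.g. "2 - 3" -> 2.5).  The curated dataset holds 42
protocol instances.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import EmptyDatasetError, StrokeCountParseError, SurveyFormatError

__all__ = [
    "SurveyRecord",
    "SurveySummary",
    "normalize_stroke_count",
    "load_survey",
    "packaged_fixture_path",
    "survey_summary",
    "write_survey",
]

_RANGE_RE = re.compile(r"^\s*(\d+)\s*[-–—]\s*(\d+)\s*$")
_INT_RE = re.compile(r"^\s*(\d+)\s*$")
_COUPLE = "couple of times"


@dataclass(frozen=True)
class SurveyRecord:
    """One curated protocol instance."""

    source: str
    raw_count_text: str
    normalized_count: float
    volume_pct: float | None = None

    def __post_init__(self) -> None:
        if self.normalized_count < 1:
            raise SurveyFormatError(
                f"normalized_count must be >= 1, got {self.normalized_count} "
                f"({self.source!r})"
            )
        if self.volume_pct is not None and not (0 < self.volume_pct <= 100):
            raise SurveyFormatError(
                f"volume_pct must be in (0, 100], got {self.volume_pct} "
                f"({self.source!r})"
            )


@dataclass(frozen=True)
class SurveySummary:
    """Descriptive statistics of the normalized stroke counts.

    ``histogram`` maps each distinct half-integer-resolved count to its
    frequency (sorted by count value); mode ties break toward the smaller
    value.
    """

    n_records: int
    min_count: float
    max_count: float
    mode_count: float
    histogram: tuple[tuple[float, int], ...] = field(default=())

    def to_json(self, **kwargs) -> str:
        return json.dumps(
            {
                "n_records": self.n_records,
                "min_count": self.min_count,
                "max_count": self.max_count,
                "mode_count": self.mode_count,
                "histogram": [list(pair) for pair in self.histogram],
            },
            **kwargs,
        )


def normalize_stroke_count(raw_count_text: str) -> float:
    """Reduce a raw stroke-count expression to a single number of strokes.

    An integer maps to itself, a range "a - b" (hyphen or dash) to its
    midpoint, and the literal phrase "couple of times" to 2.  Anything else
    raises :class:`StrokeCountParseError`.
    """
    text = raw_count_text.strip()
    if text.lower() == _COUPLE:
        return 2.0
    m = _INT_RE.match(text)
    if m:
        return float(m.group(1))
    m = _RANGE_RE.match(text)
    if m:
        return (float(m.group(1)) + float(m.group(2))) / 2.0
    raise StrokeCountParseError(f"cannot parse stroke count {raw_count_text!r}")


def packaged_fixture_path() -> Path:
    """Path of the packaged survey fixture CSV."""
    return Path(resources.files("wellmix").joinpath("data/survey_strokes.csv"))


def load_survey(path: str | Path | None = None) -> list[SurveyRecord]:
    """Load survey records from a CSV fixture (packaged one by default).

    Expected columns: ``source, raw_count_text, normalized_count,
    volume_pct`` (volume blank when unreported).  Each row's stored
    normalized count is checked against re-normalizing the raw text; any
    inconsistency or parse failure is reported with its line number.
    """
    path = packaged_fixture_path() if path is None else Path(path)
    try:
        df = pd.read_csv(path, dtype={"raw_count_text": str, "source": str})
    except pd.errors.EmptyDataError:
        return []
    except (pd.errors.ParserError, OSError) as exc:
        raise SurveyFormatError(f"cannot read survey fixture {path}: {exc}") from exc

    required = {"source", "raw_count_text", "normalized_count", "volume_pct"}
    missing = required - set(df.columns)
    if missing:
        raise SurveyFormatError(
            f"survey fixture {path} lacks columns {sorted(missing)}"
        )

    records = []
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        try:
            normalized = normalize_stroke_count(row.raw_count_text)
        except StrokeCountParseError as exc:
            raise SurveyFormatError(f"{path} line {line}: {exc}") from exc
        if abs(normalized - float(row.normalized_count)) > 1e-12:
            raise SurveyFormatError(
                f"{path} line {line}: stored normalized_count "
                f"{row.normalized_count} disagrees with raw text "
                f"{row.raw_count_text!r} (-> {normalized})"
            )
        volume = None if pd.isna(row.volume_pct) else float(row.volume_pct)
        records.append(
            SurveyRecord(
                source=str(row.source),
                raw_count_text=str(row.raw_count_text),
                normalized_count=normalized,
                volume_pct=volume,
            )
        )
    return records


def write_survey(records: Iterable[SurveyRecord], path: str | Path) -> None:
    """Write records back to the CSV fixture format (round-trip safe)."""
    df = pd.DataFrame(
        [
            {
                "source": r.source,
                "raw_count_text": r.raw_count_text,
                "normalized_count": r.normalized_count,
                "volume_pct": r.volume_pct,
            }
            for r in records
        ],
        columns=["source", "raw_count_text", "normalized_count", "volume_pct"],
    )
    df.to_csv(path, index=False)


def survey_summary(records: Sequence[SurveyRecord]) -> SurveySummary:
    """Min/max/mode and frequency histogram of the normalized counts."""
    if not records:
        raise EmptyDatasetError("survey summary requires at least one record")
    counts = [r.normalized_count for r in records]
    freq = Counter(counts)
    # mode: highest frequency, ties toward the smaller count
    mode = min(sorted(freq), key=lambda v: (-freq[v], v))
    histogram = tuple(sorted(freq.items()))
    return SurveySummary(
        n_records=len(records),
        min_count=min(counts),
        max_count=max(counts),
        mode_count=mode,
        histogram=histogram,
    )
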
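"""Read/write segmented copy-number calls (IGV SEG dialect) and clinical tables.

SEG files, as emitted by conumee-style methylation-array CNV pipelines, are
tab-separated with a header: sample ID, chromosome, start, end, optionally a
probe count, and the segment-mean log2 copy-ratio.  On disk SEG coordinates
are conventionally 1-based closed; internally everything is 0-based
half-open, converted at the I/O boundary according to the declared basis.

The segment mean is interpreted directly as a log2 copy-ratio; no
re-centering is applied at I/O time.  Overlapping segments within one sample
are allowed here (some pipelines emit them) and resolved during arm-fraction
computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from armloss.genome import normalize_chrom

__all__ = [
    "CnvSegment",
    "SubjectRecord",
    "SchemaError",
    "ParseError",
    "ValidationError",
    "read_seg",
    "write_seg",
    "read_clinical",
    "clinical_to_frame",
    "MC_LABELS",
]

MC_LABELS = ("Ben-1", "Ben-2", "Ben-3", "Int-A", "Int-B", "Mal")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ParseError(ValueError):
    """A row could not be parsed; the message names the line number."""


class ValidationError(ValueError):
    """A parsed value violates a data-model invariant."""


@dataclass(frozen=True)
class CnvSegment:
    """One segmented interval with log2 copy-ratio for one sample.

    Coordinates are 0-based half-open.
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    log2_ratio: float
    n_probes: int | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValidationError(
                f"segment {self.sample_id} {self.chrom}:[{self.start},{self.end}): "
                "start must be < end"
            )
        if not math.isfinite(self.log2_ratio):
            raise ValidationError(
                f"segment {self.sample_id} {self.chrom}:[{self.start},{self.end}): "
                f"non-finite log2 ratio {self.log2_ratio!r}"
            )
        if self.n_probes is not None and self.n_probes <= 0:
            raise ValidationError(f"n_probes must be positive, got {self.n_probes}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SubjectRecord:
    """Clinical/survival row for one subject.

    time: recurrence-free time in years; event: 1 = recurrence observed,
    0 = censored; mc_class: one of the six epigenetic methylation classes.
    """

    sample_id: str
    time: float
    event: int
    who_grade: int | None = None
    mc_class: str | None = None
    cohort: str = "unspecified"

    def __post_init__(self) -> None:
        if self.time < 0 or not math.isfinite(self.time):
            raise ValidationError(f"{self.sample_id}: time must be finite and >= 0, got {self.time}")
        if self.event not in (0, 1):
            raise ValidationError(f"{self.sample_id}: event must be 0 or 1, got {self.event!r}")
        if self.who_grade is not None and self.who_grade not in (1, 2, 3):
            raise ValidationError(
                f"{self.sample_id}: who_grade must be in {{1,2,3}}, got {self.who_grade!r}"
            )
        if self.mc_class is not None and self.mc_class not in MC_LABELS:
            raise ValidationError(
                f"{self.sample_id}: unknown methylation class {self.mc_class!r}; "
                f"permitted labels: {', '.join(MC_LABELS)}"
            )


_SEG_COLUMN_ALIASES = {
    "sample_id": ("id", "sample", "sample_id", "samplename", "sampleid"),
    "chrom": ("chrom", "chromosome", "chr"),
    "start": ("loc.start", "start", "loc_start", "chromstart"),
    "end": ("loc.end", "end", "loc_end", "chromend"),
    "n_probes": ("num.mark", "num_mark", "num.probes", "nummark", "n_probes"),
    "log2_ratio": ("seg.mean", "seg_mean", "segmean", "mean", "log2", "seg.median"),
}


def _match_columns(header: Sequence[str], path: Path) -> dict[str, int]:
    lowered = [h.strip().lower() for h in header]
    mapping: dict[str, int] = {}
    for field, aliases in _SEG_COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                mapping[field] = lowered.index(alias)
                break
    missing = [f for f in ("sample_id", "chrom", "start", "end", "log2_ratio") if f not in mapping]
    if missing:
        raise SchemaError(
            f"{path}: missing required SEG column(s) {missing}; header was {list(header)}"
        )
    return mapping


def read_seg(path: str | Path, basis: str = "1-closed") -> list[CnvSegment]:
    """Read an IGV-dialect SEG file into validated CnvSegments.

    basis: coordinate convention of the file, '1-closed' (IGV/DNAcopy
    default) or '0-half-open'.  Output coordinates are always 0-based
    half-open.  Row order is preserved.
    """
    if basis not in ("1-closed", "0-half-open"):
        raise ValueError(f"unknown coordinate basis {basis!r}")
    path = Path(path)
    offset = 1 if basis == "1-closed" else 0
    segments: list[CnvSegment] = []
    with path.open() as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise SchemaError(f"{path}: empty file, expected a SEG header line")
        cols = _match_columns(header_line.rstrip("\n").split("\t"), path)
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            try:
                start = int(fields[cols["start"]]) - offset
                end = int(fields[cols["end"]])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: unparseable coordinates") from exc
            try:
                log2 = float(fields[cols["log2_ratio"]])
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric segment mean") from exc
            n_probes: int | None = None
            if "n_probes" in cols and cols["n_probes"] < len(fields):
                token = fields[cols["n_probes"]].strip()
                if token:
                    try:
                        n_probes = int(token)
                    except ValueError as exc:
                        raise ParseError(f"{path}:{lineno}: non-integer probe count") from exc
            try:
                segments.append(
                    CnvSegment(
                        sample_id=fields[cols["sample_id"]].strip(),
                        chrom=normalize_chrom(fields[cols["chrom"]]),
                        start=start,
                        end=end,
                        log2_ratio=log2,
                        n_probes=n_probes,
                    )
                )
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return segments


def write_seg(
    segments: Iterable[CnvSegment], path: str | Path, basis: str = "1-closed"
) -> None:
    """Write segments as an IGV-dialect SEG file in the declared basis."""
    if basis not in ("1-closed", "0-half-open"):
        raise ValueError(f"unknown coordinate basis {basis!r}")
    offset = 1 if basis == "1-closed" else 0
    path = Path(path)
    with path.open("w") as fh:
        fh.write("ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n")
        for seg in segments:
            probes = "" if seg.n_probes is None else str(seg.n_probes)
            # str() gives the shortest exact float repr, so the round trip is lossless
            fh.write(
                f"{seg.sample_id}\t{seg.chrom}\t{seg.start + offset}\t{seg.end}"
                f"\t{probes}\t{seg.log2_ratio!s}\n"
            )


def read_clinical(path: str | Path, time_unit: str = "years") -> list[SubjectRecord]:
    """Read a clinical table (TSV or CSV, header required) into SubjectRecords.

    Required columns: sample_id, time, event.  Optional: who_grade,
    mc_class, cohort.  time_unit='months' divides times by 12 on ingest;
    internally times are always in years.
    """
    if time_unit not in ("years", "months"):
        raise ValueError(f"time_unit must be 'years' or 'months', got {time_unit!r}")
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [str(c).strip().lower() for c in df.columns]
    required = {"sample_id", "time", "event"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise SchemaError(f"{path}: missing required clinical column(s) {missing}")
    scale = 1.0 / 12.0 if time_unit == "months" else 1.0
    records: list[SubjectRecord] = []
    for idx, row in df.iterrows():
        try:
            time = float(row["time"]) * scale
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: row {idx}: non-numeric time {row['time']!r}") from exc
        event_raw = row["event"]
        try:
            event_f = float(event_raw)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"{path}: row {idx}: non-numeric event {event_raw!r}") from exc
        if event_f not in (0.0, 1.0):
            raise ValidationError(f"{path}: row {idx}: event must be 0 or 1, got {event_raw!r}")
        grade = None
        if "who_grade" in df.columns and pd.notna(row["who_grade"]):
            grade = int(row["who_grade"])
        mc = None
        if "mc_class" in df.columns and pd.notna(row["mc_class"]):
            mc = str(row["mc_class"]).strip()
        cohort = "unspecified"
        if "cohort" in df.columns and pd.notna(row["cohort"]):
            cohort = str(row["cohort"]).strip()
        try:
            records.append(
                SubjectRecord(
                    sample_id=str(row["sample_id"]).strip(),
                    time=time,
                    event=int(event_f),
                    who_grade=grade,
                    mc_class=mc,
                    cohort=cohort,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from exc
    return records


def clinical_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Tabulate SubjectRecords as a DataFrame (one row per subject)."""
    rows = list(records)
    return pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in rows],
            "time": [r.time for r in rows],
            "event": [r.event for r in rows],
            "who_grade": [r.who_grade for r in rows],
            "mc_class": [r.mc_class for r in rows],
            "cohort": [r.cohort for r in rows],
        }
    )
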
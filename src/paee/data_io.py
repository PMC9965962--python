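"""Delimited-text readers and writers for every on-disk artifact.

Dialects (all comma-separated, UTF-8, dot decimal):

* cohort: CSV with header ``participant_id,sex_code,age,weight,height``
  (sex coded 0 = girl, 1 = boy; weight kg; height m).
* isotope records: one CSV holding all participants, one row per urine
  sample, with the dose columns repeated on each row.
* epoch streams: an ActiGraph-CSV-export-like file with ``#``-prefixed
  metadata header lines (epoch length declared as ``# epoch_s: 15``)
  followed by ``timestamp,axis1,axis2,axis3`` rows.
* results/reports: JSON written from dataclasses, lossless for floats.

Readers validate strictly and name the offending row; they never
silently drop rows.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .accelerometry import EpochStream
from .dlw_energy import IsotopeRecord, IsotopeSample

__all__ = [
    "CohortValidationError",
    "EpochFormatError",
    "read_cohort",
    "write_cohort",
    "read_isotope_records",
    "write_isotope_records",
    "read_epoch_stream",
    "write_epoch_stream",
    "write_results",
    "read_results",
]

COHORT_COLUMNS = ["participant_id", "sex_code", "age", "weight", "height"]
SAMPLE_LABELS = ("baseline", "post4h", "day10")
_TS_FORMAT = "%Y-%m-%d %H:%M:%S"


class CohortValidationError(ValueError):
    pass


class EpochFormatError(ValueError):
    pass


def read_cohort(path) -> pd.DataFrame:
    """Read and validate a cohort table; row order is preserved."""
    frame = pd.read_csv(path, dtype={"participant_id": str})
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortValidationError(f"missing columns: {missing}")
    frame = frame[COHORT_COLUMNS].copy()
    dupes = frame["participant_id"][frame["participant_id"].duplicated()]
    if len(dupes):
        raise CohortValidationError(
            f"duplicate participant_id {dupes.iloc[0]!r}"
        )
    for row in frame.itertuples():
        label = f"row {row.Index + 2}"  # 1-based with header line
        if row.sex_code not in (0, 1):
            raise CohortValidationError(
                f"{label}: sex_code {row.sex_code!r} not in {{0, 1}}"
            )
        if not row.weight > 0:
            raise CohortValidationError(f"{label}: non-positive weight")
        if not row.height > 0:
            raise CohortValidationError(f"{label}: non-positive height")
        if row.age < 0:
            raise CohortValidationError(f"{label}: negative age")
    frame["sex_code"] = frame["sex_code"].astype(int)
    return frame


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def write_isotope_records(records: dict[str, IsotopeRecord], path) -> None:
    """Write all isotope records as one long-format CSV."""
    rows = []
    for pid, rec in records.items():
        for label in SAMPLE_LABELS:
            sample: IsotopeSample | None = getattr(rec, label)
            if sample is None:
                continue
            rows.append(
                {
                    "participant_id": pid,
                    "dose_2h_g": rec.dose_2h_g,
                    "dose_18o_g": rec.dose_18o_g,
                    "dose_enrichment_2h": rec.dose_enrichment_2h,
                    "dose_enrichment_18o": rec.dose_enrichment_18o,
                    "sample_label": label,
                    "time_h": sample.time_h,
                    "e_2h_ppm": sample.e_2h_ppm,
                    "e_18o_ppm": sample.e_18o_ppm,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.10g")


def read_isotope_records(path) -> dict[str, IsotopeRecord]:
    """Read the long-format isotope CSV back into records.

    A participant may legitimately lack a sample row (incomplete
    collection); duplicated sample labels are an error.
    """
    frame = pd.read_csv(path, dtype={"participant_id": str})
    records: dict[str, IsotopeRecord] = {}
    for pid, group in frame.groupby("participant_id", sort=False):
        if group["sample_label"].duplicated().any():
            raise ValueError(f"participant {pid}: duplicated sample label")
        samples: dict[str, IsotopeSample] = {}
        for row in group.itertuples(index=False):
            if row.sample_label not in SAMPLE_LABELS:
                raise ValueError(
                    f"participant {pid}: unknown sample label {row.sample_label!r}"
                )
            samples[row.sample_label] = IsotopeSample(
                time_h=float(row.time_h),
                e_2h_ppm=float(row.e_2h_ppm),
                e_18o_ppm=float(row.e_18o_ppm),
            )
        first = group.iloc[0]
        records[pid] = IsotopeRecord(
            participant_id=pid,
            dose_2h_g=float(first["dose_2h_g"]),
            dose_18o_g=float(first["dose_18o_g"]),
            dose_enrichment_2h=float(first["dose_enrichment_2h"]),
            dose_enrichment_18o=float(first["dose_enrichment_18o"]),
            baseline=samples.get("baseline"),
            post4h=samples.get("post4h"),
            day10=samples.get("day10"),
        )
    return records


def write_epoch_stream(
    stream: EpochStream, path, participant_id: str = ""
) -> None:
    """Write an ActiGraph-CSV-export-like epoch file (10 header lines)."""
    header = [
        "# ActiGraph-style epoch export (synthetic)",
        "# device: wGT3X-BT",
        f"# participant_id: {participant_id}",
        f"# start: {stream.start.strftime(_TS_FORMAT)}",
        f"# epoch_s: {stream.epoch_s}",
        f"# n_epochs: {len(stream)}",
        "# axes: axis1,axis2,axis3",
        "# units: counts/epoch",
        "# timezone: local wall-clock",
        "# ---",
    ]
    timestamps = stream.timestamps().strftime(_TS_FORMAT)
    with open(path, "w", encoding="utf-8") as handle:
        handle.write("\n".join(header) + "\n")
        handle.write("timestamp,axis1,axis2,axis3\n")
        counts = stream.counts
        for i in range(len(stream)):
            handle.write(
                f"{timestamps[i]},{counts[i, 0]},{counts[i, 1]},{counts[i, 2]}\n"
            )


def read_epoch_stream(path, epoch_s: int | None = None) -> EpochStream:
    """Read an epoch file; timestamp gaps are rejected, not imputed.

    ``epoch_s`` overrides the header-declared epoch length and must be
    one of 1, 15 or 60 seconds.
    """
    path = Path(path)
    header_epoch = None
    n_header = 0
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            if not line.startswith("#"):
                break
            n_header += 1
            if line[1:].strip().startswith("epoch_s:"):
                header_epoch = int(line.split(":", 1)[1])
    if epoch_s is None:
        epoch_s = header_epoch
    if epoch_s is None:
        raise EpochFormatError("epoch length neither in header nor supplied")
    if epoch_s not in (1, 15, 60):
        raise EpochFormatError(f"unsupported epoch length {epoch_s}s")

    frame = pd.read_csv(path, skiprows=n_header)
    expected = ["timestamp", "axis1", "axis2", "axis3"]
    if list(frame.columns) != expected:
        raise EpochFormatError(f"expected columns {expected}")
    if len(frame) == 0:
        raise EpochFormatError("no epoch rows")
    times = pd.to_datetime(frame["timestamp"], format=_TS_FORMAT)
    deltas = times.diff().dt.total_seconds().to_numpy()[1:]
    bad = np.flatnonzero(deltas != epoch_s)
    if len(bad):
        # +2 for the column-header line, +n_header for metadata, 1-based
        line_no = int(bad[0]) + 2 + n_header + 1
        raise EpochFormatError(
            f"timestamp step of {deltas[bad[0]]:.0f}s (expected {epoch_s}s) "
            f"at line {line_no}"
        )
    counts = frame[["axis1", "axis2", "axis3"]].to_numpy()
    if (counts < 0).any():
        raise EpochFormatError("negative counts")
    return EpochStream(
        start=times.iloc[0].to_pydatetime(), epoch_s=epoch_s, counts=counts
    )


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            "__type__": type(obj).__name__,
            **{
                f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)
            },
        }
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return {"__frame__": obj.to_dict(orient="list")}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (dt.date, dt.datetime)):
        return obj.isoformat()
    return obj


def write_results(report: Any, path) -> None:
    """Serialize a result dataclass (or nested structure) as JSON text.

    Floats use ``repr`` precision, so a write-then-read round trip is
    the identity well beyond 6 significant digits.
    """
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(_jsonable(report), handle, indent=1)
        handle.write("\n")


def read_results(path) -> Any:
    with open(path, encoding="utf-8") as handle:
        return json.load(handle)
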
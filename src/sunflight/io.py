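"""Cohort containers, CSV serialisation and flight-discard rules.

On-disk dialect
---------------
A cohort is a manifest CSV plus one trace CSV per flight.

* manifest columns: ``fly_id,group,flight_type,flight_index,n_stops,
  stop_intervals,path`` where ``path`` is relative to the data directory and
  ``stop_intervals`` encodes intervals as ``start:end`` pairs joined by
  ``;`` (empty when none).
* trace columns: ``t_s,heading_deg`` -- UTF-8, '.' decimal, header required,
  values written to 6 decimal places (the declared round-trip precision).

QC rules
--------
Flights in which the fly stopped flying more than once are discarded; then
all flights of any fly that did not complete both 5-minute sun flights are
discarded ("completed" meaning duration >= completeness_fraction x the
nominal trial duration).  Heading-distribution analyses additionally require
a per-flight vector strength strictly above a minimum threshold (0.2).
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .circstats import FlightSummary, HeadingTrace

MANIFEST_COLUMNS = [
    "fly_id",
    "group",
    "flight_type",
    "flight_index",
    "n_stops",
    "stop_intervals",
    "path",
]

#: Nominal trial duration (seconds): two 5-minute sun flights per fly.
TRIAL_DURATION_S = 300.0
#: Fraction of the nominal duration a flight must reach to count as complete.
DEFAULT_COMPLETENESS_FRACTION = 0.95
#: Minimum vector strength for a flight to enter heading analyses (strict >).
DEFAULT_VS_THRESHOLD = 0.2
#: Number of sun flights each fly must complete.
REQUIRED_SUN_FLIGHTS = 2


@dataclass
class FlyRecord:
    """One fly: identifier, group label and its flights."""

    fly_id: str
    group: str
    flights: list = field(default_factory=list)

    def __post_init__(self):
        keys = [(f.flight_type, f.flight_index) for f in self.flights]
        if len(keys) != len(set(keys)):
            raise ValueError(
                f"fly {self.fly_id!r}: duplicate (flight_type, flight_index)"
            )

    def sun_flights(self):
        return [f for f in self.flights if f.flight_type == "sun"]


@dataclass
class Cohort:
    """Flies grouped by genotype/treatment label."""

    groups: dict = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self):
        seen = set()
        for label, flies in self.groups.items():
            for fly in flies:
                if fly.fly_id in seen:
                    raise ValueError(f"duplicate fly_id {fly.fly_id!r} in cohort")
                seen.add(fly.fly_id)
                if fly.group != label:
                    raise ValueError(
                        f"fly {fly.fly_id!r} has group {fly.group!r} "
                        f"but is listed under {label!r}"
                    )

    @property
    def n_flies(self) -> int:
        return sum(len(flies) for flies in self.groups.values())

    @property
    def n_flights(self) -> int:
        return sum(len(f.flights) for f in self.iter_flies())

    def iter_flies(self):
        for flies in self.groups.values():
            yield from flies

    def iter_flights(self):
        for fly in self.iter_flies():
            yield from fly.flights


def _encode_intervals(intervals) -> str:
    return ";".join(f"{a:.6f}:{b:.6f}" for a, b in intervals)


def _decode_intervals(text) -> list:
    if text is None or (isinstance(text, float) and np.isnan(text)) or text == "":
        return []
    out = []
    for item in str(text).split(";"):
        a, b = item.split(":")
        out.append((float(a), float(b)))
    return out


def _trace_filename(trace: HeadingTrace) -> str:
    return f"{trace.fly_id}_{trace.flight_type}_{trace.flight_index}.csv"


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write a cohort as ``manifest.csv`` + per-flight trace CSVs.

    Output ordering is deterministic: rows sorted by (group, fly_id,
    flight_type, flight_index).  Returns the manifest path.
    """
    out_dir = Path(out_dir)
    traces_dir = out_dir / "traces"
    traces_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    flights = sorted(
        cohort.iter_flights(),
        key=lambda f: (f.group, f.fly_id, f.flight_type, f.flight_index),
    )
    for trace in flights:
        rel = os.path.join("traces", _trace_filename(trace))
        df = pd.DataFrame({"t_s": trace.t, "heading_deg": trace.heading})
        df.to_csv(out_dir / rel, index=False, float_format="%.6f")
        rows.append(
            {
                "fly_id": trace.fly_id,
                "group": trace.group,
                "flight_type": trace.flight_type,
                "flight_index": trace.flight_index,
                "n_stops": trace.n_stops,
                "stop_intervals": _encode_intervals(trace.stop_intervals),
                "path": rel,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_cohort(manifest_path, data_dir=None) -> Cohort:
    """Read a cohort from a manifest CSV.

    ``data_dir`` defaults to the manifest's directory.  Angle values are
    wrapped to (-180, 180] on load.  Missing trace files, malformed rows and
    duplicate (fly, flight_type, flight_index) keys raise errors naming the
    offending record.
    """
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    data_dir = Path(data_dir) if data_dir is not None else manifest_path.parent
    df = pd.read_csv(manifest_path, dtype={"fly_id": str, "group": str})
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns and c != "stop_intervals"]
    if missing:
        raise ValueError(f"manifest {manifest_path} missing columns: {missing}")

    seen_keys = set()
    flies: dict = {}
    order: list = []
    for i, row in df.iterrows():
        key = (row["fly_id"], row["flight_type"], int(row["flight_index"]))
        if key in seen_keys:
            raise ValueError(f"duplicate flight key {key} in manifest row {i}")
        seen_keys.add(key)
        trace_path = data_dir / row["path"]
        if not trace_path.exists():
            raise FileNotFoundError(
                f"trace file for {key} not found: {trace_path}"
            )
        tdf = pd.read_csv(trace_path)
        if "t_s" not in tdf.columns or "heading_deg" not in tdf.columns:
            raise ValueError(f"trace file {trace_path} lacks t_s/heading_deg columns")
        try:
            trace = HeadingTrace(
                fly_id=str(row["fly_id"]),
                group=str(row["group"]),
                flight_type=str(row["flight_type"]),
                flight_index=int(row["flight_index"]),
                t=tdf["t_s"].to_numpy(),
                heading=tdf["heading_deg"].to_numpy(),
                n_stops=int(row["n_stops"]),
                stop_intervals=_decode_intervals(row.get("stop_intervals")),
            )
        except ValueError as exc:
            raise ValueError(f"malformed flight {key}: {exc}") from exc
        if trace.fly_id not in flies:
            flies[trace.fly_id] = FlyRecord(trace.fly_id, trace.group, [])
            order.append(trace.fly_id)
        elif flies[trace.fly_id].group != trace.group:
            raise ValueError(
                f"fly {trace.fly_id!r} listed under two groups: "
                f"{flies[trace.fly_id].group!r} and {trace.group!r}"
            )
        flies[trace.fly_id].flights.append(trace)

    groups: dict = {}
    for fly_id in order:
        fly = flies[fly_id]
        fly.__post_init__()  # re-check flight-key uniqueness after filling
        groups.setdefault(fly.group, []).append(fly)
    return Cohort(groups=groups, provenance=f"read from {manifest_path}")


@dataclass
class QCReport:
    """Per-rule discard accounting from :func:`apply_qc`.

    ``flights_in == flights_out + discarded_stop_rule + discarded_incomplete``
    overall and per group.
    """

    flights_in: int
    flights_out: int
    discarded_stop_rule: int
    discarded_incomplete: int
    flies_in: int
    flies_out: int
    per_group: dict = field(default_factory=dict)

    def to_text(self) -> str:
        lines = ["group\tflights_in\tflights_out\tdiscarded_stop\tdiscarded_incomplete"]
        for g, d in sorted(self.per_group.items()):
            lines.append(
                f"{g}\t{d['flights_in']}\t{d['flights_out']}"
                f"\t{d['discarded_stop_rule']}\t{d['discarded_incomplete']}"
            )
        lines.append(
            f"TOTAL\t{self.flights_in}\t{self.flights_out}"
            f"\t{self.discarded_stop_rule}\t{self.discarded_incomplete}"
        )
        return "\n".join(lines)


def apply_qc(
    cohort: Cohort,
    completeness_fraction: float = DEFAULT_COMPLETENESS_FRACTION,
    trial_duration_s: float = TRIAL_DURATION_S,
):
    """Apply the flight-discard rules; returns (filtered cohort, QCReport).

    Rule order: first discard flights with more than one stop; then discard
    all remaining flights of any fly lacking ``REQUIRED_SUN_FLIGHTS``
    completed sun flights.  Idempotent; an empty result is allowed.
    """
    min_duration = completeness_fraction * trial_duration_s
    per_group: dict = {}
    groups_out: dict = {}
    flies_in = flies_out = 0
    for label, flies in cohort.groups.items():
        acc = per_group.setdefault(
            label,
            {
                "flights_in": 0,
                "flights_out": 0,
                "discarded_stop_rule": 0,
                "discarded_incomplete": 0,
            },
        )
        kept_flies = []
        for fly in flies:
            flies_in += 1
            acc["flights_in"] += len(fly.flights)
            after_stop = [f for f in fly.flights if f.n_stops <= 1]
            acc["discarded_stop_rule"] += len(fly.flights) - len(after_stop)
            completed_sun = [
                f
                for f in after_stop
                if f.flight_type == "sun" and f.duration_s >= min_duration
            ]
            if len(completed_sun) >= REQUIRED_SUN_FLIGHTS:
                acc["flights_out"] += len(after_stop)
                kept_flies.append(FlyRecord(fly.fly_id, fly.group, after_stop))
                flies_out += 1
            else:
                acc["discarded_incomplete"] += len(after_stop)
        if kept_flies:
            groups_out[label] = kept_flies
    report = QCReport(
        flights_in=sum(d["flights_in"] for d in per_group.values()),
        flights_out=sum(d["flights_out"] for d in per_group.values()),
        discarded_stop_rule=sum(d["discarded_stop_rule"] for d in per_group.values()),
        discarded_incomplete=sum(d["discarded_incomplete"] for d in per_group.values()),
        flies_in=flies_in,
        flies_out=flies_out,
        per_group=per_group,
    )
    return Cohort(groups=groups_out, provenance=cohort.provenance), report


def select_heading_flights(summaries, threshold: float = DEFAULT_VS_THRESHOLD):
    """Keep flights whose vector strength is strictly above ``threshold``.

    This is the gate for heading-distribution analyses and confidence
    intervals: a flight with no directional consistency has a meaningless
    mean heading.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    return [s for s in summaries if s.vector_strength > threshold]


def summarize_cohort(cohort: Cohort, flight_type=None, exclude_stops=False):
    """FlightSummary list for every flight (optionally one flight type)."""
    from .circstats import summarize_flight

    out = []
    for trace in cohort.iter_flights():
        if flight_type is not None and trace.flight_type != flight_type:
            continue
        out.append(summarize_flight(trace, exclude_stops=exclude_stops))
    return out


def summaries_to_frame(summaries) -> pd.DataFrame:
    """Tabulate FlightSummary objects as a DataFrame (stable column order)."""
    return pd.DataFrame(
        [
            {
                "fly_id": s.fly_id,
                "group": s.group,
                "flight_type": s.flight_type,
                "flight_index": s.flight_index,
                "mean_heading": s.mean_heading,
                "vector_strength": s.vector_strength,
                "abs_mean_heading": s.abs_mean_heading,
                "n_samples": s.n_samples,
                "duration_s": s.duration_s,
                "n_stops": s.n_stops,
            }
            for s in summaries
        ]
    )
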
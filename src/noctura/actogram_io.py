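"""Reading, validating, re-binning and light-annotating activity-monitor data.

The raw substrate of every downstream phenotype is a per-fly vector of beam-break
counts in fixed-width time bins.  Two input dialects are supported:

* ``dam42`` — the 42-column tab-delimited text emitted by DAMSystem3-style
  *Drosophila* activity monitors (index, date, time, status, six metadata
  columns, then 32 channel counts; one row per time bin).
* ``tidy_csv`` — a long-format CSV with columns ``fly_id``, ``datetime``
  (ISO-8601), ``count`` and optionally ``light_flag``.

Light annotation labels every bin ``L``/``D`` under a light:dark cycle and
``subjL``/``subjD`` ("subjective" day/night) once the lights stay off, by
projecting the prior LD schedule forward at fixed clock times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LIGHT_LABELS = ("L", "D", "subjL", "subjD")
NIGHT_LABELS = frozenset({"D", "subjD"})
DAY_LABELS = frozenset({"L", "subjL"})

_DAM_N_FIELDS = 42
_DAM_FIRST_CHANNEL_FIELD = 10  # 0-based; fields 10..41 are channels 1..32
_DAM_STATUS_FIELD = 3
_DAM_VALID_STATUS = 1


class ActogramParseError(ValueError):
    """Raised when a monitor file violates the expected layout."""


@dataclass
class ActivitySeries:
    """One fly's contiguous, fixed-width activity-count series.

    Parameters
    ----------
    fly_id
        Identifier, e.g. ``"M1C01"`` (monitor 1, channel 1).
    t0
        Timestamp of the *start* of the first bin.
    bin_minutes
        Bin width in minutes; must divide 1440 (a whole day).
    counts
        Non-negative integer counts, one per bin.
    light_flags
        Optional per-bin label in {L, D, subjL, subjD}.
    """

    fly_id: str
    t0: pd.Timestamp
    bin_minutes: int
    counts: np.ndarray
    light_flags: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t0 = pd.Timestamp(self.t0)
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D sequence")
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.allclose(as_int, self.counts):
                raise ValueError("counts must be integral")
            self.counts = as_int
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.bin_minutes <= 0 or 1440 % self.bin_minutes != 0:
            raise ValueError("bin_minutes must be a positive divisor of 1440")
        if self.light_flags is not None:
            self.light_flags = np.asarray(self.light_flags, dtype=object)
            if self.light_flags.shape != self.counts.shape:
                raise ValueError("light_flags length must equal counts length")
            bad = set(self.light_flags) - set(LIGHT_LABELS)
            if bad:
                raise ValueError(f"unknown light flags: {sorted(bad)}")

    # -- derived geometry ---------------------------------------------------
    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    @property
    def bins_per_day(self) -> int:
        return 1440 // self.bin_minutes

    @property
    def times(self) -> pd.DatetimeIndex:
        return self.t0 + pd.to_timedelta(
            np.arange(self.n_bins) * self.bin_minutes, unit="m"
        )

    @property
    def duration_hours(self) -> float:
        return self.n_bins * self.bin_minutes / 60.0

    def slice_bins(self, start: int, stop: int | None = None) -> "ActivitySeries":
        """Return a new series covering bins ``start:stop``."""
        sl = slice(start, stop)
        flags = None if self.light_flags is None else self.light_flags[sl]
        return ActivitySeries(
            fly_id=self.fly_id,
            t0=self.t0 + pd.Timedelta(minutes=start * self.bin_minutes),
            bin_minutes=self.bin_minutes,
            counts=self.counts[sl].copy(),
            light_flags=flags,
        )


@dataclass
class LightRegime:
    """A light schedule: an LD cycle, optionally followed by constant darkness.

    ``lights_on_hour`` is the clock hour of lights-on (ZT0); the photoperiod is
    the number of lit hours per 24.  After ``dd_start`` the lights stay off and
    day/night become *subjective*, defined by projecting the same schedule
    forward on clock time.
    """

    lights_on_hour: float = 8.0
    photoperiod_hours: float = 12.0
    dd_start: pd.Timestamp | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.photoperiod_hours <= 24.0:
            raise ValueError("photoperiod_hours must be in [0, 24]")
        if not 0.0 <= self.lights_on_hour < 24.0:
            raise ValueError("lights_on_hour must be in [0, 24)")
        if self.dd_start is not None:
            self.dd_start = pd.Timestamp(self.dd_start)

    def zt(self, when: pd.Timestamp) -> float:
        """Zeitgeber time (hours since lights-on, mod 24) of a clock time."""
        when = pd.Timestamp(when)
        clock_h = when.hour + when.minute / 60.0 + when.second / 3600.0
        return (clock_h - self.lights_on_hour) % 24.0


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _parse_dam_lines(lines: Iterable[str], monitor_id: int) -> tuple[
    list[pd.Timestamp], np.ndarray, int
]:
    """Parse dam42 rows -> (timestamps, counts[n_rows, 32], n_dropped)."""
    stamps: list[pd.Timestamp] = []
    rows: list[list[int]] = []
    n_dropped = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.rstrip("\r\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != _DAM_N_FIELDS:
            raise ActogramParseError(
                f"line {lineno}: expected {_DAM_N_FIELDS} tab-separated fields, "
                f"got {len(fields)}"
            )
        try:
            status = int(fields[_DAM_STATUS_FIELD])
        except ValueError as exc:
            raise ActogramParseError(f"line {lineno}: bad status field") from exc
        if status != _DAM_VALID_STATUS:
            n_dropped += 1
            logger.warning(
                "monitor M%d line %d: status %d != 1, row dropped",
                monitor_id, lineno, status,
            )
            continue
        try:
            stamp = pd.to_datetime(
                f"{fields[1]} {fields[2]}", format="%d %b %y %H:%M:%S"
            )
        except ValueError as exc:
            raise ActogramParseError(
                f"line {lineno}: cannot parse timestamp {fields[1]!r} {fields[2]!r}"
            ) from exc
        try:
            counts = [int(v) for v in fields[_DAM_FIRST_CHANNEL_FIELD:]]
        except ValueError as exc:
            raise ActogramParseError(f"line {lineno}: non-integer count") from exc
        stamps.append(stamp)
        rows.append(counts)
    if not rows:
        raise ActogramParseError("no records")
    return stamps, np.asarray(rows, dtype=np.int64), n_dropped


def _regularise(
    stamps: Sequence[pd.Timestamp], counts: np.ndarray, label: str
) -> tuple[pd.Timestamp, int, np.ndarray]:
    """Check monotonicity, infer the bin width and zero-fill gaps.

    Returns (t0, bin_minutes, counts) with counts possibly gap-filled
    (rows of zeros where bins were missing; each fill is logged).
    """
    stamps = pd.DatetimeIndex(stamps)
    if len(stamps) == 1:
        return stamps[0], 1, counts
    diffs = np.diff(stamps.asi8) / 60e9  # minutes
    if (diffs <= 0).any():
        raise ActogramParseError(f"{label}: non-monotone timestamps")
    bin_minutes = int(round(diffs.min()))
    if bin_minutes <= 0 or not np.allclose(diffs % bin_minutes, 0, atol=1e-6):
        raise ActogramParseError(
            f"{label}: irregular bin spacing (inferred {bin_minutes} min)"
        )
    steps = np.round(diffs / bin_minutes).astype(int)
    n_missing = int((steps - 1).sum())
    if n_missing == 0:
        return stamps[0], bin_minutes, counts
    logger.warning("%s: %d missing bins zero-filled", label, n_missing)
    n_total = int(steps.sum()) + 1
    filled = np.zeros((n_total, counts.shape[1]) if counts.ndim == 2 else n_total,
                      dtype=np.int64)
    pos = np.concatenate([[0], np.cumsum(steps)])
    filled[pos] = counts
    return stamps[0], bin_minutes, filled


def read_dam_monitor(
    path: str | Path, dialect: str = "dam42", monitor_id: int | None = None
) -> list[ActivitySeries]:
    """Read an activity-monitor file into one :class:`ActivitySeries` per fly.

    ``dialect`` is ``"dam42"`` (32-channel DAM text) or ``"tidy_csv"``.
    Rows with a status code other than 1 are dropped (and logged); gaps left
    by dropped or missing bins are zero-filled and logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "dam42":
        if monitor_id is None:
            digits = "".join(ch for ch in path.stem if ch.isdigit())
            monitor_id = int(digits) if digits else 1
        with open(path) as fh:
            stamps, rows, _ = _parse_dam_lines(fh, monitor_id)
        t0, bin_minutes, rows = _regularise(stamps, rows, str(path))
        return [
            ActivitySeries(
                fly_id=f"M{monitor_id}C{ch + 1:02d}",
                t0=t0,
                bin_minutes=bin_minutes,
                counts=rows[:, ch],
            )
            for ch in range(rows.shape[1])
        ]
    if dialect == "tidy_csv":
        df = pd.read_csv(path)
        required = {"fly_id", "datetime", "count"}
        missing = required - set(df.columns)
        if missing:
            raise ActogramParseError(f"tidy_csv missing columns: {sorted(missing)}")
        if df.empty:
            raise ActogramParseError("no records")
        df["datetime"] = pd.to_datetime(df["datetime"])
        out: list[ActivitySeries] = []
        for fly_id, sub in df.groupby("fly_id", sort=True):
            sub = sub.sort_values("datetime")
            t0, bin_minutes, counts = _regularise(
                sub["datetime"].tolist(),
                sub["count"].to_numpy(dtype=np.int64),
                f"{path}:{fly_id}",
            )
            flags = None
            if "light_flag" in sub.columns and sub["light_flag"].notna().all():
                if len(sub) == len(counts):  # no gap-fill: flags still aligned
                    flags = sub["light_flag"].to_numpy(dtype=object)
            out.append(
                ActivitySeries(
                    fly_id=str(fly_id), t0=t0, bin_minutes=bin_minutes,
                    counts=counts, light_flags=flags,
                )
            )
        return out
    raise ValueError(f"unknown dialect {dialect!r}")


def write_tidy_csv(series: Iterable[ActivitySeries], path: str | Path) -> None:
    """Write series to the tidy CSV dialect (with light_flag when present)."""
    frames = []
    for s in series:
        df = pd.DataFrame(
            {
                "fly_id": s.fly_id,
                "datetime": s.times,
                "count": s.counts,
            }
        )
        if s.light_flags is not None:
            df["light_flag"] = s.light_flags
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_dam_file(
    series: Sequence[ActivitySeries], path: str | Path, monitor_id: int = 1
) -> None:
    """Write up to 32 equally-binned, aligned series as a dam42 monitor file."""
    if not series:
        raise ValueError("no series to write")
    if len(series) > 32:
        raise ValueError("a DAM monitor has 32 channels")
    ref = series[0]
    for s in series[1:]:
        if s.n_bins != ref.n_bins or s.bin_minutes != ref.bin_minutes or s.t0 != ref.t0:
            raise ValueError("all series must share t0, bin width and length")
    mat = np.zeros((ref.n_bins, 32), dtype=np.int64)
    for ch, s in enumerate(series):
        mat[:, ch] = s.counts
    with open(path, "w") as fh:
        for i, ts in enumerate(ref.times):
            meta = ["0"] * 6
            row = [
                str(i + 1),
                ts.strftime("%d %b %y").lstrip("0"),
                ts.strftime("%H:%M:%S"),
                "1",
                *meta,
                *(str(v) for v in mat[i]),
            ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# re-binning and light annotation
# ---------------------------------------------------------------------------

def rebin(series: ActivitySeries, target_minutes: int) -> ActivitySeries:
    """Sum counts into wider bins; total activity is conserved.

    ``target_minutes`` must be a multiple of the current bin width.  A trailing
    partial window is dropped (and logged).  Light flags survive only if every
    window is homogeneous; otherwise they are dropped with a warning
    (re-annotate after re-binning instead).
    """
    if target_minutes % series.bin_minutes != 0:
        raise ValueError(
            f"target {target_minutes} min is not a multiple of "
            f"{series.bin_minutes} min bins"
        )
    factor = target_minutes // series.bin_minutes
    if factor == 1:
        return replace(series, counts=series.counts.copy())
    n_whole = series.n_bins // factor
    dropped = series.n_bins - n_whole * factor
    if dropped:
        logger.warning(
            "%s: dropping %d trailing bin(s) in rebin to %d min",
            series.fly_id, dropped, target_minutes,
        )
    if n_whole == 0:
        raise ValueError("series shorter than one target bin")
    counts = series.counts[: n_whole * factor].reshape(n_whole, factor).sum(axis=1)
    flags = None
    if series.light_flags is not None:
        fmat = series.light_flags[: n_whole * factor].reshape(n_whole, factor)
        if all(len(set(row)) == 1 for row in fmat):
            flags = fmat[:, 0].copy()
        else:
            logger.warning(
                "%s: light flags mix within rebinned windows; flags dropped",
                series.fly_id,
            )
    return ActivitySeries(
        fly_id=series.fly_id,
        t0=series.t0,
        bin_minutes=target_minutes,
        counts=counts,
        light_flags=flags,
    )


def annotate_light(series: ActivitySeries, regime: LightRegime) -> ActivitySeries:
    """Label every bin L/D (or subjL/subjD after ``regime.dd_start``).

    Bins must align with the schedule's light transitions; a bin straddling
    lights-on or lights-off raises with advice to re-bin.
    """
    pp = regime.photoperiod_hours
    if pp == 0.0:
        raise ValueError(
            "no subjective reference: photoperiod 0 with no LD history; "
            "provide the prior LD schedule and dd_start instead"
        )
    if regime.dd_start is not None:
        off_min = (regime.dd_start - series.t0) / pd.Timedelta(minutes=1)
        if off_min % series.bin_minutes != 0:
            raise ValueError("dd_start does not align to a bin boundary")
    bin_h = series.bin_minutes / 60.0
    flags = np.empty(series.n_bins, dtype=object)
    for i, ts in enumerate(series.times):
        zt = regime.zt(ts)
        # a light transition (ZT0 or ZT=pp) strictly inside the bin is an error
        for boundary in (0.0, pp):
            into = (boundary - zt) % 24.0
            if 1e-9 < into < bin_h - 1e-9:
                raise ValueError(
                    f"bin starting {ts} straddles a light transition; "
                    "re-bin to align with the schedule"
                )
        lit = zt < pp - 1e-9 or zt < 1e-9 or zt > 24.0 - 1e-9
        subjective = regime.dd_start is not None and ts >= regime.dd_start
        if lit:
            flags[i] = "subjL" if subjective else "L"
        else:
            flags[i] = "subjD" if subjective else "D"
    return replace(series, counts=series.counts.copy(), light_flags=flags)
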
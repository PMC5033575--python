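"""Data containers, file I/O and preprocessing for movement signals.

The long-format table of functional samples has columns
``participant, repetition, condition, time, value`` with one row per
observed time point; an empty value field marks a missing observation
(e.g. an occluded motion-capture marker).  Raw 3-D tracks are stored as
``t, x, y, z`` tables at a fixed sampling rate.

Preprocessing follows the standard motion-capture pipeline: acceleration
profiles are obtained by central finite differences of the speed (velocity
magnitude), movements are mapped to percentual time (onset -> 0,
offset -> 1) by a threshold rule, and whole datasets are affinely rescaled
so the global value span is 1 and the global time span is [0, 1] -- with a
single common scaling shared by all experimental conditions so that
amplitudes remain comparable across conditions.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .bases import SplineBasis, bspline_design
from .exceptions import (
    DegenerateDataError,
    DomainError,
    FormatError,
    LengthError,
    OnsetDetectionError,
    RankError,
    ValidationError,
)

__all__ = [
    "FunctionalSample",
    "TrajectorySample",
    "RawTrack",
    "ScaleRecord",
    "read_functional_table",
    "write_functional_table",
    "read_raw_track",
    "write_raw_track",
    "compute_acceleration",
    "to_percentual_time",
    "rescale_dataset",
    "invert_rescaling",
    "resample_path",
    "read_trajectory_table",
    "write_trajectory_table",
]

_COLUMNS = ["participant", "repetition", "condition", "time", "value"]


@dataclass
class FunctionalSample:
    """One repetition's observed signal y_ij(t_k) with identifiers.

    ``times`` must be strictly increasing; ``values`` must be finite
    wherever ``missing_mask`` is False.  Masked entries are ignored by all
    model computations.
    """

    participant_id: int
    repetition_id: int
    condition_id: str
    times: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if not (len(self.times) == len(self.values) == len(self.missing_mask)):
            raise ValidationError("times, values and missing_mask must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"times must be strictly increasing within sample "
                f"({self.participant_id}, {self.repetition_id}, {self.condition_id!r})"
            )
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValidationError("values must be finite wherever not masked")

    @property
    def n_observed(self) -> int:
        return int(np.sum(~self.missing_mask))

    def observed(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) restricted to non-missing entries."""
        keep = ~self.missing_mask
        return self.times[keep], self.values[keep]


@dataclass
class TrajectorySample:
    """An aligned spatial path represented by 30 equidistant sample points
    (in percentual warped time), with participant/repetition/height labels."""

    participant_id: int
    repetition_id: int
    height_level: int
    distance_cm: float
    path: np.ndarray

    def __post_init__(self) -> None:
        self.path = np.asarray(self.path, dtype=float)
        if self.path.shape != (30, 3):
            raise ValidationError(f"path must be 30x3, got {self.path.shape}")
        if not np.all(np.isfinite(self.path)):
            raise ValidationError("path entries must be finite")
        if self.height_level not in (1, 2, 3):
            raise ValidationError("height_level must be 1, 2 or 3")


@dataclass
class RawTrack:
    """A raw motion-capture track: T x 3 positions (cm) at a fixed rate."""

    sample_rate_hz: float
    positions: np.ndarray
    timestamps: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError("positions must be a T x 3 matrix")
        if len(self.timestamps) != len(self.positions):
            raise ValidationError("timestamps and positions must have equal length")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValidationError("timestamps must be strictly increasing")


# ---------------------------------------------------------------------------
# Long-table I/O


def _samples_to_frame(samples: Iterable[FunctionalSample]) -> pd.DataFrame:
    rows = []
    for s in samples:
        vals = s.values.astype(object)
        vals[s.missing_mask] = np.nan
        rows.append(
            pd.DataFrame(
                {
                    "participant": s.participant_id,
                    "repetition": s.repetition_id,
                    "condition": s.condition_id,
                    "time": s.times,
                    "value": vals,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_functional_table(samples: Sequence[FunctionalSample], path, format: str = "csv") -> None:
    """Write samples as a long table (CSV or JSON records)."""
    df = _samples_to_frame(samples)
    path = Path(path)
    if format == "csv":
        # %.17g guarantees bit-exact float round-trips through text
        df = df.assign(
            time=df["time"].map(lambda x: f"{x:.17g}"),
            value=df["value"].map(
                lambda v: "" if (isinstance(v, float) and np.isnan(v)) else f"{v:.17g}"
            ),
        )
        df.to_csv(path, index=False)
    elif format == "json":
        records = df.to_dict(orient="records")
        for rec in records:
            v = rec["value"]
            if isinstance(v, float) and np.isnan(v):
                rec["value"] = None
        path.write_text(json.dumps(records))
    else:
        raise FormatError(f"unknown format {format!r}")


def read_functional_table(path, format: str = "csv") -> list[FunctionalSample]:
    """Read a long table into one :class:`FunctionalSample` per
    (participant, repetition, condition) group.

    Rows with an empty/absent value field become masked entries.  Duplicate
    (participant, repetition, condition, time) rows raise a
    :class:`ValidationError`; a missing column raises :class:`FormatError`.
    """
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path, float_precision="round_trip")
    elif format == "json":
        df = pd.DataFrame(json.loads(path.read_text()))
    else:
        raise FormatError(f"unknown format {format!r}")
    missing_cols = [c for c in _COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"missing required column(s): {missing_cols}")
    if df.duplicated(subset=["participant", "repetition", "condition", "time"]).any():
        raise ValidationError("duplicated (participant, repetition, condition, time) rows")
    samples = []
    for (pid, rid, cid), grp in df.groupby(["participant", "repetition", "condition"], sort=True):
        grp = grp.sort_values("time")
        values = pd.to_numeric(grp["value"], errors="coerce").to_numpy(dtype=float)
        mask = ~np.isfinite(values)
        values = np.where(mask, 0.0, values)
        samples.append(
            FunctionalSample(
                participant_id=int(pid),
                repetition_id=int(rid),
                condition_id=str(cid),
                times=grp["time"].to_numpy(dtype=float),
                values=values,
                missing_mask=mask,
            )
        )
    return samples


def write_raw_track(track: RawTrack, path) -> None:
    df = pd.DataFrame(
        {
            "t": track.timestamps,
            "x": track.positions[:, 0],
            "y": track.positions[:, 1],
            "z": track.positions[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_raw_track(path, sample_rate_hz: float | None = None) -> RawTrack:
    """Read a t,x,y,z CSV; the rate is inferred from timestamps if omitted."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("t", "x", "y", "z") if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")
    ts = df["t"].to_numpy(dtype=float)
    if sample_rate_hz is None:
        sample_rate_hz = 1.0 / float(np.median(np.diff(ts)))
    return RawTrack(
        sample_rate_hz=sample_rate_hz,
        positions=df[["x", "y", "z"]].to_numpy(dtype=float),
        timestamps=ts,
    )


def write_trajectory_table(trajectories: Sequence[TrajectorySample], path) -> None:
    rows = []
    for tr in trajectories:
        for k in range(30):
            rows.append(
                (
                    tr.participant_id,
                    tr.repetition_id,
                    tr.height_level,
                    tr.distance_cm,
                    k + 1,
                    tr.path[k, 0],
                    tr.path[k, 1],
                    tr.path[k, 2],
                )
            )
    pd.DataFrame(
        rows,
        columns=["participant", "repetition", "height", "distance", "time_index", "x", "y", "z"],
    ).to_csv(path, index=False, float_format="%.17g")


def read_trajectory_table(path) -> list[TrajectorySample]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = ["participant", "repetition", "height", "distance", "time_index", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")
    out = []
    for (pid, rid, h, d), grp in df.groupby(["participant", "repetition", "height", "distance"], sort=True):
        grp = grp.sort_values("time_index")
        out.append(
            TrajectorySample(
                participant_id=int(pid),
                repetition_id=int(rid),
                height_level=int(h),
                distance_cm=float(d),
                path=grp[["x", "y", "z"]].to_numpy(dtype=float),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Preprocessing


def compute_acceleration(track: RawTrack) -> FunctionalSample:
    """Acceleration profile from finite differences of the speed.

    The speed (velocity magnitude) is computed by central differences of the
    positions at the T-2 interior time points; its time derivative is then
    taken by finite differences over those points (one-sided at the two ends
    so the length stays T-2).  Only the speed magnitude enters, so the
    result is invariant to rigid translations and rotations of the track.
    """
    p = track.positions
    t = track.timestamps
    if len(t) < 3:
        raise LengthError("at least 3 time points are needed for acceleration")
    vel = (p[2:] - p[:-2]) / (t[2:] - t[:-2])[:, None]
    speed = np.linalg.norm(vel, axis=1)
    t_mid = t[1:-1]
    acc = np.gradient(speed, t_mid)
    return FunctionalSample(
        participant_id=0,
        repetition_id=0,
        condition_id="",
        times=t_mid,
        values=acc,
        missing_mask=np.zeros(len(t_mid), dtype=bool),
    )


@dataclass(frozen=True)
class OnsetRule:
    """Threshold rule for movement onset/offset detection.

    ``kind = "fraction_of_peak"``: the movement spans the first through last
    time at which |value| reaches ``fraction`` of the peak |value|.
    ``kind = "first_sample"``: the full recorded span is used.
    """

    kind: str = "fraction_of_peak"
    fraction: float = 0.05


def to_percentual_time(sample: FunctionalSample, onset_rule: OnsetRule | None = None) -> FunctionalSample:
    """Linearly rescale time so onset maps to 0 and offset to 1.

    Observations outside [onset, offset] are dropped.  A flat signal has no
    detectable onset under the fraction-of-peak rule and raises
    :class:`OnsetDetectionError`.
    """
    rule = onset_rule or OnsetRule()
    t, v = sample.times, sample.values
    keepable = ~sample.missing_mask
    if rule.kind == "first_sample":
        onset, offset = t[0], t[-1]
    elif rule.kind == "fraction_of_peak":
        mag = np.abs(np.where(keepable, v, 0.0))
        peak = mag.max() if mag.size else 0.0
        if peak <= 0:
            raise OnsetDetectionError("flat signal: no onset detectable")
        above = np.nonzero(mag >= rule.fraction * peak)[0]
        onset, offset = t[above[0]], t[above[-1]]
    else:
        raise DomainError(f"unknown onset rule kind {rule.kind!r}")
    if offset <= onset:
        raise OnsetDetectionError("degenerate movement span")
    inside = (t >= onset) & (t <= offset)
    return FunctionalSample(
        participant_id=sample.participant_id,
        repetition_id=sample.repetition_id,
        condition_id=sample.condition_id,
        times=(t[inside] - onset) / (offset - onset),
        values=sample.values[inside],
        missing_mask=sample.missing_mask[inside],
    )


@dataclass(frozen=True)
class ScaleRecord:
    """Affine rescaling applied to a dataset; allows exact inversion."""

    value_min: float
    value_span: float
    time_min: float
    time_span: float

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self)))

    @classmethod
    def from_json(cls, path) -> "ScaleRecord":
        return cls(**json.loads(Path(path).read_text()))


def rescale_dataset(
    samples: Sequence[FunctionalSample],
) -> tuple[list[FunctionalSample], ScaleRecord]:
    """Apply one common affine rescaling to all samples (all conditions)
    so the global value span has length 1 and times lie in [0, 1]."""
    all_vals = np.concatenate([s.values[~s.missing_mask] for s in samples])
    all_times = np.concatenate([s.times for s in samples])
    if all_vals.size == 0:
        raise DegenerateDataError("no unmasked values in dataset")
    vmin, vmax = float(all_vals.min()), float(all_vals.max())
    tmin, tmax = float(all_times.min()), float(all_times.max())
    if vmax <= vmin:
        raise DegenerateDataError("zero value span: cannot rescale")
    tspan = tmax - tmin if tmax > tmin else 1.0
    record = ScaleRecord(vmin, vmax - vmin, tmin, tspan)
    out = []
    for s in samples:
        out.append(
            FunctionalSample(
                participant_id=s.participant_id,
                repetition_id=s.repetition_id,
                condition_id=s.condition_id,
                times=(s.times - tmin) / tspan,
                values=(s.values - vmin) / (vmax - vmin),
                missing_mask=s.missing_mask.copy(),
            )
        )
    return out, record


def invert_rescaling(sample: FunctionalSample, record: ScaleRecord) -> FunctionalSample:
    """Undo :func:`rescale_dataset` for one sample."""
    return FunctionalSample(
        participant_id=sample.participant_id,
        repetition_id=sample.repetition_id,
        condition_id=sample.condition_id,
        times=sample.times * record.time_span + record.time_min,
        values=sample.values * record.value_span + record.value_min,
        missing_mask=sample.missing_mask.copy(),
    )


# ---------------------------------------------------------------------------
# Path resampling for the factor model


def resample_path(
    track: RawTrack,
    warp: Callable[[np.ndarray], np.ndarray] | None = None,
    *,
    participant_id: int = 0,
    repetition_id: int = 0,
    height_level: int = 1,
    distance_cm: float = 0.0,
    n_points: int = 30,
    n_knots: int = 10,
) -> TrajectorySample:
    """Smooth each coordinate with a cubic spline (10 equidistant knots in
    warped percentual time) and evaluate at 30 equidistant warped-time
    points.

    ``warp`` maps percentual time to warped percentual time (the repetition's
    predicted warp); ``None`` means the identity.  The track's timestamps are
    first normalized to [0, 1].
    """
    t = track.timestamps
    s = (t - t[0]) / (t[-1] - t[0])
    if warp is not None:
        s = np.asarray(warp(s), dtype=float)
        if np.any(np.diff(s) <= 0) or abs(s[0]) > 1e-12 or abs(s[-1] - 1.0) > 1e-12:
            raise DomainError("warp must be an increasing homeomorphism of [0, 1]")
        s = np.clip(s, 0.0, 1.0)
    basis = SplineBasis(n_knots)
    design = bspline_design(basis, s)
    if len(s) < basis.n_basis or np.linalg.matrix_rank(design) < basis.n_basis:
        raise RankError(
            f"track too short/ill-spread for a {n_knots}-knot cubic spline fit"
        )
    coef, *_ = np.linalg.lstsq(design, track.positions, rcond=None)
    grid = np.linspace(0.0, 1.0, n_points)
    path = bspline_design(basis, grid) @ coef
    return TrajectorySample(
        participant_id=participant_id,
        repetition_id=repetition_id,
        height_level=height_level,
        distance_cm=distance_cm,
        path=path,
    )
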
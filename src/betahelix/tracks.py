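"""Cell-migration statistics from 2-D time-lapse tracks.

Per-track descriptors (net and total displacement, persistence = net/total,
mean velocity) and the ensemble mean-squared displacement MSD(τ) with its
anomalous-diffusion exponent α (MSD ∝ τ^α): α ≈ 1 is diffusive, 1 < α < 2
superdiffusive (persistent migration), α = 2 ballistic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DomainError, InsufficientDataError, ResampleRequiredError

TRACK_COLUMNS = ["track_id", "t_min", "x_um", "y_um"]


@dataclass(frozen=True)
class TrackSet:
    """Time-stamped 2-D positions grouped by cell: id -> (n, 3) [t, x, y]."""

    tracks: dict[object, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for tid, arr in self.tracks.items():
            a = np.asarray(arr, dtype=float)
            if a.ndim != 2 or a.shape[1] != 3:
                raise DomainError(f"track {tid!r} must be an (n, 3) [t, x, y] array")
            if len(a) < 2:
                raise DomainError(f"track {tid!r} needs at least 2 points")
            if not np.all(np.diff(a[:, 0]) > 0):
                raise DomainError(f"track {tid!r} times must be strictly increasing")
            clean[tid] = a
        if not clean:
            raise DomainError("empty track set")
        object.__setattr__(self, "tracks", clean)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TrackSet":
        missing = [c for c in TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise DomainError(f"track table missing columns {missing}")
        tracks = {
            tid: g.sort_values("t_min")[["t_min", "x_um", "y_um"]].to_numpy()
            for tid, g in df.groupby("track_id")
        }
        return cls(tracks)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrackSet":
        return cls.from_dataframe(pd.read_csv(path))

    def to_dataframe(self) -> pd.DataFrame:
        frames = [
            pd.DataFrame(
                {"track_id": tid, "t_min": a[:, 0], "x_um": a[:, 1], "y_um": a[:, 2]}
            )
            for tid, a in self.tracks.items()
        ]
        return pd.concat(frames, ignore_index=True)


def per_track_metrics(ts: TrackSet) -> pd.DataFrame:
    """Net/total displacement, persistence, mean velocity and duration.

    Persistence = net displacement / total path ∈ [0, 1]; a stationary track
    (zero total path) is flagged rather than errored, with NaN persistence.
    """
    rows = []
    for tid, a in ts.tracks.items():
        xy = a[:, 1:]
        steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
        total = float(steps.sum())
        net = float(np.linalg.norm(xy[-1] - xy[0]))
        duration = float(a[-1, 0] - a[0, 0])
        stationary = total == 0.0
        rows.append(
            {
                "track_id": tid,
                "net_um": net,
                "total_um": total,
                "persistence": np.nan if stationary else net / total,
                "mean_velocity_um_min": np.nan if duration == 0 else total / duration,
                "duration_min": duration,
                "stationary": stationary,
            }
        )
    return pd.DataFrame(rows).set_index("track_id")


def _common_dt(ts: TrackSet) -> float:
    dts = np.concatenate([np.diff(a[:, 0]) for a in ts.tracks.values()])
    dt = float(dts[0])
    if not np.allclose(dts, dt, rtol=1e-6):
        raise ResampleRequiredError("tracks are not on a common time step")
    return dt


def ensemble_msd_alpha(
    ts: TrackSet,
    max_lag_fraction: float = 0.25,
    overlapping: bool = True,
) -> dict:
    """Ensemble MSD(τ) and the anomalous exponent α.

    Each track is time-averaged first (overlapping windows by default), then
    the per-track curves are ensemble-averaged.  α is the log–log slope of
    MSD versus lag over [2nd lag point, max_lag_fraction × shortest track].
    """
    tracks = list(ts.tracks.values())
    if len(tracks) < 3 or any(len(a) < 8 for a in tracks):
        raise InsufficientDataError("MSD needs >= 3 tracks of >= 8 points")
    dt = _common_dt(ts)
    n_min = min(len(a) for a in tracks)
    max_lag = max(2, int(np.floor(max_lag_fraction * n_min)))
    lags = np.arange(1, min(max_lag, n_min - 1) + 1)
    msd = np.zeros(len(lags))
    for j, m in enumerate(lags):
        per_track = []
        for a in tracks:
            xy = a[:, 1:]
            if overlapping:
                disp = xy[m:] - xy[:-m]
            else:
                disp = xy[m::m] - xy[:-m:m] if len(xy) > m else xy[:0]
            if len(disp):
                per_track.append(np.mean(np.sum(disp**2, axis=1)))
        msd[j] = np.mean(per_track)
    taus = lags * dt
    fit_mask = slice(1, None)  # from the 2nd lag point
    slope, intercept = np.polyfit(np.log(taus[fit_mask]), np.log(msd[fit_mask]), 1)
    alpha = float(slope)
    regime = (
        "ballistic" if alpha > 1.9
        else "superdiffusive" if alpha > 1.1
        else "diffusive" if alpha > 0.9
        else "subdiffusive"
    )
    table = pd.DataFrame({"lag_min": taus, "msd_um2": msd})
    return {
        "msd": table,
        "alpha": alpha,
        "regime": regime,
        "fit_lags_min": (float(taus[1]), float(taus[-1])),
    }
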
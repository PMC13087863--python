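"""Melting-temperature calling from temperature-ramp trajectory observables.

A candidate's triple helix is simulated under a linear temperature ramp
(320 K start, 1 K/ns by default) and denaturation is detected from two
per-frame observables: the radius of gyration of the most collapsed of the
three strands, and the three inter-strand central-residue distances.  The
melt temperature Tm is the ramp temperature at the onset of the first
sustained event:

* collapse   - min-over-strands Rg < 1.25 nm for at least 200 ps;
* dissociation - any pair distance >= 2 nm for at least 200 ps.

A trajectory with no sustained event is censored at its final frame.
Replicate calls (six per sequence by default) are aggregated into a mean Tm
and its standard error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    AllCensored,
    EmptyTrajectory,
    IrregularSpacing,
    NegativeTime,
)

DEFAULT_T0_K = 320.0
DEFAULT_RAMP_RATE_K_PER_NS = 1.0
DEFAULT_RG_THRESHOLD_NM = 1.25
DEFAULT_DIST_THRESHOLD_NM = 2.0
DEFAULT_SUSTAIN_PS = 200.0


@dataclass
class TrajectoryObservables:
    """Per-frame observables of one temperature-ramp replicate.

    ``rg_per_strand`` has shape (3, n_frames) in nm, ``pair_distances`` the
    strand pairs (1-2, 1-3, 2-3) with the same shape.  ``frame_times`` is in
    ns with uniform spacing.
    """

    frame_times: np.ndarray
    rg_per_strand: np.ndarray
    pair_distances: np.ndarray
    T0: float = DEFAULT_T0_K
    ramp_rate: float = DEFAULT_RAMP_RATE_K_PER_NS
    replicate_id: int = 0

    def __post_init__(self):
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.rg_per_strand = np.atleast_2d(np.asarray(self.rg_per_strand, float))
        self.pair_distances = np.atleast_2d(np.asarray(self.pair_distances, float))
        n = self.frame_times.size
        if n == 0:
            raise EmptyTrajectory("trajectory has no frames")
        if self.rg_per_strand.shape[1] != n or self.pair_distances.shape[1] != n:
            raise IrregularSpacing("observable series lengths differ")
        if n > 1:
            dts = np.diff(self.frame_times)
            if dts.min() <= 0 or not np.allclose(dts, dts[0], rtol=1e-6):
                raise IrregularSpacing("frame times must be uniformly spaced")

    @property
    def frame_spacing_ns(self) -> float:
        if self.frame_times.size < 2:
            return 0.0
        return float(self.frame_times[1] - self.frame_times[0])


@dataclass(frozen=True)
class MeltCall:
    """Outcome of melt detection for one replicate."""

    Tm: float | None  # K; None when censored
    event: str  # "collapse" | "dissociation" | "censored"
    event_time: float  # ns (final frame time when censored)


@dataclass(frozen=True)
class TmEstimate:
    mean_Tm: float
    se_Tm: float
    n_replicates: int
    n_censored: int = 0
    replicate_Tms: tuple = field(default_factory=tuple)


def ramp_temperature(t_ns: float, T0: float = DEFAULT_T0_K,
                     rate: float = DEFAULT_RAMP_RATE_K_PER_NS) -> float:
    """Instantaneous ramp temperature ``T0 + rate * t``."""
    t = np.asarray(t_ns, dtype=float)
    if np.any(t < 0):
        raise NegativeTime("ramp time must be nonnegative")
    out = T0 + rate * t
    return float(out) if out.ndim == 0 else out


def _first_sustained_onset(mask: np.ndarray, min_frames: int) -> int | None:
    """Index of the first frame starting a run of >= min_frames True values."""
    if not mask.any():
        return None
    idx = np.flatnonzero(mask)
    # split into contiguous runs
    splits = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], splits + 1])
    ends = np.concatenate([splits, [idx.size - 1]])
    for s, e in zip(starts, ends):
        if e - s + 1 >= min_frames:
            return int(idx[s])
    return None


def detect_melt(
    traj: TrajectoryObservables,
    rg_threshold: float = DEFAULT_RG_THRESHOLD_NM,
    dist_threshold: float = DEFAULT_DIST_THRESHOLD_NM,
    sustain_ps: float = DEFAULT_SUSTAIN_PS,
) -> MeltCall:
    """Call the melt event for one replicate trajectory.

    A run must span ``sustain_ps`` of contiguous frames to count; Tm is
    assigned at the run's first frame (excursion onset).  The earlier of a
    collapse or dissociation onset wins; exact ties go to collapse.
    """
    dt_ns = traj.frame_spacing_ns
    if dt_ns <= 0:
        raise EmptyTrajectory("need at least two frames to detect a melt event")
    sustain_ns = sustain_ps / 1000.0
    if sustain_ns < dt_ns:
        raise IrregularSpacing("sustain window shorter than the frame spacing")
    min_frames = int(np.ceil(sustain_ns / dt_ns))

    min_rg = traj.rg_per_strand.min(axis=0)
    max_dist = traj.pair_distances.max(axis=0)
    i_col = _first_sustained_onset(min_rg < rg_threshold, min_frames)
    i_dis = _first_sustained_onset(max_dist >= dist_threshold, min_frames)

    if i_col is None and i_dis is None:
        return MeltCall(None, "censored", float(traj.frame_times[-1]))
    if i_dis is None or (i_col is not None and i_col <= i_dis):
        i, event = i_col, "collapse"
    else:
        i, event = i_dis, "dissociation"
    t = float(traj.frame_times[i])
    return MeltCall(ramp_temperature(t, traj.T0, traj.ramp_rate), event, t)


def aggregate_replicates(calls: list[MeltCall]) -> TmEstimate:
    """Mean and standard error of the non-censored replicate Tm values.

    A single replicate gets ``se = 0`` by convention; downstream consumers
    (the GPR surrogate) apply a noise floor before using the SE as a noise
    level.  Raises :class:`AllCensored` when no replicate melted.
    """
    tms = [c.Tm for c in calls if c.event != "censored"]
    n_censored = len(calls) - len(tms)
    if not tms:
        raise AllCensored("no replicate produced a melt event")
    arr = np.asarray(tms, dtype=float)
    se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
    return TmEstimate(
        mean_Tm=float(arr.mean()),
        se_Tm=se,
        n_replicates=arr.size,
        n_censored=n_censored,
        replicate_Tms=tuple(float(x) for x in arr),
    )
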
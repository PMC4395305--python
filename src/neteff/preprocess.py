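"""Temporal preprocessing of node x frame BOLD-like matrices.

Implements the cleanup chain applied to each subject's time series before
network construction: band-pass filtering, nuisance regression, and
motion scrubbing based on framewise displacement (FD) and DVARS.

Conventions
-----------
* A :class:`TimeSeriesMatrix` is nodes (rows) by frames (columns), with a
  fixed sampling interval ``tr`` in seconds and per-frame provenance ids.
* FD follows the Power convention: summed absolute frame-to-frame
  translations (mm) plus rotations (radians) scaled by a sphere radius
  (default 50 mm).
* DVARS is the root-mean-square frame-to-frame signal change across
  nodes, expressed as a percentage of the mean signal.  Because band-pass
  filtering removes the DC component, callers may supply the pre-filter
  grand mean as ``reference_mean``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "TimeSeriesMatrix",
    "ScrubReport",
    "UnusableSubjectError",
    "MOTION_COLUMNS",
    "bandpass_filter",
    "regress_nuisance",
    "compute_fd",
    "compute_dvars",
    "scrub",
    "read_timeseries_tsv",
    "write_timeseries_tsv",
    "read_motion_tsv",
    "write_motion_tsv",
]

#: Column order of a rigid-body motion table: translations in mm, rotations
#: in radians.
MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")

#: Rotation-to-displacement conversion radius in mm (surface of a 50 mm
#: sphere, the conventional head-size approximation).
DEFAULT_ROTATION_RADIUS_MM = 50.0


class UnusableSubjectError(RuntimeError):
    """Raised when scrubbing would remove every frame of a subject."""


@dataclass
class TimeSeriesMatrix:
    """Node x frame numeric matrix with sampling interval and provenance.

    Parameters
    ----------
    values : ndarray, shape (n_nodes, n_frames)
        Signal values in arbitrary BOLD-like units.
    tr : float
        Sampling interval (repetition time) in seconds.
    frame_ids : ndarray of int, optional
        Original frame indices; defaults to ``0..n_frames-1``.  Preserved
        through scrubbing so removed frames remain identifiable.
    """

    values: np.ndarray
    tr: float
    frame_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (nodes x frames) array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("time series contains non-finite values")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")
        if self.frame_ids is None:
            self.frame_ids = np.arange(self.values.shape[1])
        self.frame_ids = np.asarray(self.frame_ids, dtype=int)
        if self.frame_ids.shape != (self.values.shape[1],):
            raise ValueError("frame_ids length must equal the frame count")
        if self.values.shape[1] > 1 and not np.all(np.diff(self.frame_ids) > 0):
            raise ValueError("frame_ids must be strictly increasing")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


@dataclass
class ScrubReport:
    """Outcome of motion scrubbing for one subject/condition.

    ``fd`` and ``dvars`` have one entry per frame-to-frame transition
    (length ``n_frames - 1``); ``removed_frames`` holds the frame ids of
    the frames that terminated an offending transition.
    """

    fd: np.ndarray
    dvars: np.ndarray
    removed_frames: list[int]
    n_removed: int

    def __post_init__(self) -> None:
        self.fd = np.asarray(self.fd, dtype=float)
        self.dvars = np.asarray(self.dvars, dtype=float)
        if self.n_removed != len(self.removed_frames):
            raise ValueError("n_removed must equal len(removed_frames)")
        if np.any(self.fd < 0) or np.any(self.dvars < 0):
            raise ValueError("FD and DVARS must be non-negative")

    def to_dict(self) -> dict:
        return {
            "fd": self.fd.tolist(),
            "dvars": self.dvars.tolist(),
            "removed_frames": [int(i) for i in self.removed_frames],
            "n_removed": int(self.n_removed),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def bandpass_filter(
    ts: TimeSeriesMatrix,
    low_hz: float = 0.009,
    high_hz: float = 0.08,
    order: int = 2,
) -> TimeSeriesMatrix:
    """Zero-phase Butterworth band-pass filter applied node-wise.

    The per-node mean (DC component) is removed before filtering, and the
    filter is applied forward-backward (``sosfiltfilt``) so correlations
    between nodes are not distorted by phase lag.  With ``low_hz == 0``
    the filter degenerates to a low-pass (mean still removed).
    """
    nyquist = 1.0 / (2.0 * ts.tr)
    if not 0.0 <= low_hz < high_hz:
        raise ValueError(f"need 0 <= low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz >= nyquist:
        raise ValueError(
            f"high_hz={high_hz} must be below the Nyquist frequency {nyquist}"
        )
    if low_hz == 0.0:
        sos = signal.butter(order, high_hz, btype="lowpass", fs=1.0 / ts.tr, output="sos")
    else:
        sos = signal.butter(
            order, [low_hz, high_hz], btype="bandpass", fs=1.0 / ts.tr, output="sos"
        )
    demeaned = ts.values - ts.values.mean(axis=1, keepdims=True)
    filtered = signal.sosfiltfilt(sos, demeaned, axis=1)
    return TimeSeriesMatrix(filtered, tr=ts.tr, frame_ids=ts.frame_ids.copy())


def regress_nuisance(
    ts: TimeSeriesMatrix, regressors: np.ndarray, add_intercept: bool = True
) -> TimeSeriesMatrix:
    """Project nuisance signals out of every node's series.

    Each node's residual is orthogonal to every regressor column.  An
    intercept column is included by default, so the residuals are also
    mean-free.  A rank-deficient regressor matrix is handled by the
    least-norm solution with a warning.
    """
    reg = np.atleast_2d(np.asarray(regressors, dtype=float))
    if reg.shape[0] != ts.n_frames:
        if reg.shape[1] == ts.n_frames:
            reg = reg.T
        else:
            raise ValueError(
                f"regressors have {reg.shape[0]} rows but the series has "
                f"{ts.n_frames} frames"
            )
    if reg.shape[1] < 1:
        raise ValueError("need at least one regressor column")
    design = np.column_stack([np.ones(ts.n_frames), reg]) if add_intercept else reg
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn(
            "nuisance regressor matrix is rank deficient; using the "
            "least-norm solution",
            RuntimeWarning,
            stacklevel=2,
        )
    beta, *_ = np.linalg.lstsq(design, ts.values.T, rcond=None)
    resid = ts.values.T - design @ beta
    return TimeSeriesMatrix(resid.T, tr=ts.tr, frame_ids=ts.frame_ids.copy())


def _motion_array(motion) -> np.ndarray:
    if isinstance(motion, pd.DataFrame):
        arr = motion.loc[:, list(MOTION_COLUMNS)].to_numpy(dtype=float)
    else:
        arr = np.asarray(motion, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 6:
        raise ValueError("motion table must have 6 columns (3 trans mm, 3 rot rad)")
    if not np.all(np.isfinite(arr)):
        raise ValueError("motion parameters contain non-finite values")
    return arr


def compute_fd(motion, rotation_radius: float = DEFAULT_ROTATION_RADIUS_MM) -> np.ndarray:
    """Framewise displacement in mm for each frame-to-frame transition.

    ``FD_t = sum |d trans_i| + radius * sum |d rot_j|``; rotations are
    converted to arc length on a sphere of ``rotation_radius`` mm.
    """
    arr = _motion_array(motion)
    if arr.shape[0] < 2:
        raise ValueError("need at least 2 frames to compute FD")
    deltas = np.abs(np.diff(arr, axis=0))
    return deltas[:, :3].sum(axis=1) + rotation_radius * deltas[:, 3:].sum(axis=1)


def compute_dvars(ts: TimeSeriesMatrix, reference_mean: float | None = None) -> np.ndarray:
    """DVARS per transition, as percent of the mean signal.

    ``DVARS_t`` is the RMS over nodes of the frame-to-frame signal change,
    divided by the grand mean signal and scaled to percent.  When the
    series has been demeaned (e.g. after filtering), pass the pre-filter
    grand mean as ``reference_mean``.
    """
    if ts.n_frames < 2:
        raise ValueError("need at least 2 frames to compute DVARS")
    ref = float(np.mean(ts.values)) if reference_mean is None else float(reference_mean)
    if abs(ref) < 1e-12:
        raise ValueError(
            "mean signal is ~0; supply reference_mean (e.g. the pre-filter "
            "grand mean) to express DVARS as a percentage"
        )
    diffs = np.diff(ts.values, axis=1)
    rms = np.sqrt(np.mean(diffs**2, axis=0))
    return 100.0 * rms / abs(ref)


def scrub(
    ts: TimeSeriesMatrix,
    motion,
    fd_thresh: float = 0.5,
    dvars_thresh: float = 0.5,
    rotation_radius: float = DEFAULT_ROTATION_RADIUS_MM,
    reference_mean: float | None = None,
    extend_before: int = 0,
    extend_after: int = 0,
) -> tuple[TimeSeriesMatrix, ScrubReport]:
    """Remove frames with excessive motion (FD) or signal change (DVARS).

    A frame is removed when it terminates a transition with
    ``FD > fd_thresh`` (mm) OR ``DVARS > dvars_thresh`` (%).  Only
    transitions between consecutive acquisitions (``frame_ids`` differing
    by 1) are evaluated, so scrubbing already-scrubbed data removes
    nothing.  ``extend_before``/``extend_after`` optionally widen each
    removal to neighboring frames (default 0: only the offending frame).
    """
    if fd_thresh <= 0 or dvars_thresh <= 0:
        raise ValueError("scrub thresholds must be positive")
    arr = _motion_array(motion)
    if arr.shape[0] != ts.n_frames:
        raise ValueError(
            f"motion table has {arr.shape[0]} frames but the series has {ts.n_frames}"
        )
    fd = compute_fd(arr, rotation_radius=rotation_radius)
    dvars = compute_dvars(ts, reference_mean=reference_mean)
    contiguous = np.diff(ts.frame_ids) == 1
    bad_transition = contiguous & ((fd > fd_thresh) | (dvars > dvars_thresh))
    bad = np.zeros(ts.n_frames, dtype=bool)
    bad[1:] = bad_transition
    if extend_before or extend_after:
        core = np.flatnonzero(bad)
        for pos in core:
            lo = max(0, pos - extend_before)
            hi = min(ts.n_frames, pos + extend_after + 1)
            bad[lo:hi] = True
    keep = ~bad
    if not keep.any():
        raise UnusableSubjectError("scrubbing removed every frame")
    removed = [int(i) for i in ts.frame_ids[bad]]
    report = ScrubReport(fd=fd, dvars=dvars, removed_frames=removed, n_removed=len(removed))
    clean = TimeSeriesMatrix(
        ts.values[:, keep], tr=ts.tr, frame_ids=ts.frame_ids[keep]
    )
    return clean, report


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------

def write_timeseries_tsv(ts: TimeSeriesMatrix, path) -> None:
    """Write a nodes x frames matrix as TSV; columns named by frame id."""
    df = pd.DataFrame(ts.values, columns=[f"f{i}" for i in ts.frame_ids])
    df.to_csv(path, sep="\t", index=False)


def read_timeseries_tsv(path, tr: float) -> TimeSeriesMatrix:
    df = pd.read_csv(path, sep="\t")
    frame_ids = [int(str(c).lstrip("f")) for c in df.columns]
    return TimeSeriesMatrix(df.to_numpy(dtype=float), tr=tr, frame_ids=np.array(frame_ids))


def write_motion_tsv(motion: pd.DataFrame, path) -> None:
    motion.loc[:, list(MOTION_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_motion_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(MOTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"motion table missing columns: {sorted(missing)}")
    return df
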
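"""Frame-wise displacement and scan-level motion exclusion rules.

Two rules are applied: a mean-FD threshold (scans with mean frame-wise
displacement at or above the cutoff are dropped, default 0.25 mm) and a
gross-motion rule (any translation exceeding a 2 mm peak-to-peak range, or
any rotation exceeding 2 degrees peak-to-peak).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: rotational lever arm converting radians to mm of surface displacement
DEFAULT_ROTATION_RADIUS_MM = 50.0


@dataclass
class QcDecision:
    scan_id: str
    mean_fd: float
    max_range: np.ndarray  # peak-to-peak per parameter (mm / degrees)
    included: bool
    rule_triggered: str  # 'fd_threshold', 'gross_motion' or 'none'


def framewise_displacement(
    motion: np.ndarray, radius: float = DEFAULT_ROTATION_RADIUS_MM
) -> np.ndarray:
    """Power-style frame-wise displacement in mm.

    FD_t = |dx| + |dy| + |dz| + radius * (|dpitch| + |dyaw| + |droll|) with
    rotations in radians converted to arc length on a sphere of the given
    radius. FD of the first frame is 0.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion must be a (T, 6) array: 3 translations + 3 rotations")
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 frames")
    if not np.all(np.isfinite(motion)):
        raise ValueError("non-finite motion parameters")
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + radius * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def scan_fd_summary(motion: np.ndarray, how: str = "mean", radius: float = DEFAULT_ROTATION_RADIUS_MM) -> float:
    """Scalar FD summary per scan: mean (default), median or max."""
    fd = framewise_displacement(motion, radius=radius)
    if how == "mean":
        return float(fd.mean())
    if how == "median":
        return float(np.median(fd))
    if how == "max":
        return float(fd.max())
    raise ValueError(f"unknown FD summary {how!r}")


def fd_scan_filter(
    summaries: dict[str, float], threshold: float = 0.25
) -> tuple[set[str], dict]:
    """Retain scans whose FD summary is strictly below the threshold.

    Returns the retained scan ids and a summary dict with the counts of
    removed scans (mirroring cohort-level removal reporting).
    """
    kept = {sid for sid, fd in summaries.items() if fd < threshold}
    removed = sorted(set(summaries) - kept)
    return kept, {
        "n_scans": len(summaries),
        "n_removed": len(removed),
        "removed": removed,
        "threshold": threshold,
    }


def gross_motion_filter(motion: np.ndarray, limit: float = 2.0) -> bool:
    """True (included) unless any parameter's peak-to-peak range exceeds the limit.

    Translations are compared in mm, rotations in degrees (a limit of 2
    radians would be physically implausible).
    """
    motion = np.asarray(motion, dtype=float)
    if not np.all(np.isfinite(motion)):
        raise ValueError("non-finite motion parameters")
    rng = motion.max(axis=0) - motion.min(axis=0)
    trans_ok = np.all(rng[:3] <= limit)
    rot_ok = np.all(np.degrees(rng[3:]) <= limit)
    return bool(trans_ok and rot_ok)


def qc_decision(
    scan_id: str,
    motion: np.ndarray,
    fd_threshold: float = 0.25,
    gross_limit: float = 2.0,
    fd_summary: str = "mean",
) -> QcDecision:
    """Combined decision: gross-motion rule first, then the FD threshold."""
    mean_fd = scan_fd_summary(motion, how=fd_summary)
    rng = motion.max(axis=0) - motion.min(axis=0)
    rng = np.concatenate([rng[:3], np.degrees(rng[3:])])
    if not gross_motion_filter(motion, limit=gross_limit):
        return QcDecision(scan_id, mean_fd, rng, False, "gross_motion")
    if mean_fd >= fd_threshold:
        return QcDecision(scan_id, mean_fd, rng, False, "fd_threshold")
    return QcDecision(scan_id, mean_fd, rng, True, "none")


def read_motion_file(path) -> np.ndarray:
    """Read a plain-text motion file: one frame per line, 6 columns
    (translations in mm, rotations in radians)."""
    motion = np.loadtxt(path, ndmin=2)
    if motion.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns, found {motion.shape[1]}")
    return motion
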
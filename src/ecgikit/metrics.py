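"""Reconstruction error (RDMS) and threshold-based ischemic lesion detection.

RDMS (relative difference measure star) is the Euclidean distance between the
unit-normalised true and reconstructed potential patterns; it is scale
invariant, zero for perfect (positively scaled) agreement, and bounded by 2
(antipodal patterns).  Computed spatially (one value per timestep, over
nodes) or temporally (one per node, over timesteps).

Lesion detection thresholds the epicardial map at one timestep:
``w_threshold = w_mean - Q (w_mean - w_min)`` with threshold factor Q
(default 0.4); a mesh element whose mean vertex potential falls strictly
below the threshold is classified ischemic.  Detection quality is reported
as traffic-light areas relative to the true lesion area: correctly ischemic
(CI), incorrectly healthy (IH, the missed part) and incorrectly ischemic
(II, false detections anywhere on the ventricle); CI + IH = 100 by
construction and II may exceed 100 when over-detection is large.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import LesionSpec, TriangleMesh
from .sources import PotentialField

DEFAULT_Q = 0.4


@dataclass
class RDMSSummary:
    per_timestep: np.ndarray
    mean: float
    sd: float
    mode: str


@dataclass
class DetectionReport:
    threshold: float
    q_factor: float
    detected_elements: np.ndarray
    ci_pct: float
    ih_pct: float
    ii_pct: float
    detection_time: float


# ---------------------------------------------------------------------------
# RDMS
# ---------------------------------------------------------------------------


def rdms(x, x_hat, root: bool = True) -> float:
    """Distance between unit-normalised vectors.

    With ``root=True`` (the conventional definition) this is
    ``|| x/||x|| - x_hat/||x_hat|| ||``, in [0, 2].  ``root=False`` returns
    the squared form for comparison.
    """
    x = np.asarray(x, dtype=float).ravel()
    x_hat = np.asarray(x_hat, dtype=float).ravel()
    if x.shape != x_hat.shape:
        raise ValueError("inputs must have equal length")
    nx, nh = np.linalg.norm(x), np.linalg.norm(x_hat)
    if nx == 0.0 or nh == 0.0:
        raise ValueError("RDMS undefined for a zero-norm input")
    s = float(np.sum((x / nx - x_hat / nh) ** 2))
    return float(np.sqrt(s)) if root else s


def rdms_summary(
    x: PotentialField, x_hat: PotentialField, mode: str = "spatial", root: bool = True
) -> RDMSSummary:
    """Per-timestep (spatial) or per-node (temporal) RDMS with mean and sd.

    Zero-norm columns/rows are flagged, excluded and reported with a warning
    rather than poisoning the summary.
    """
    if x.values.shape != x_hat.values.shape:
        raise ValueError("fields must have matching shapes")
    if mode not in ("spatial", "temporal"):
        raise ValueError("mode must be 'spatial' or 'temporal'")
    a = x.values if mode == "spatial" else x.values.T
    b = x_hat.values if mode == "spatial" else x_hat.values.T
    n = a.shape[1]
    out = np.full(n, np.nan)
    skipped = 0
    for j in range(n):
        try:
            out[j] = rdms(a[:, j], b[:, j], root=root)
        except ValueError:
            skipped += 1
    if skipped:
        warnings.warn(f"{skipped} zero-norm slice(s) excluded from RDMS summary", stacklevel=2)
    valid = out[~np.isnan(out)]
    return RDMSSummary(
        per_timestep=out,
        mean=float(valid.mean()) if valid.size else float("nan"),
        sd=float(valid.std(ddof=0)) if valid.size else float("nan"),
        mode=mode,
    )


# ---------------------------------------------------------------------------
# Threshold detection
# ---------------------------------------------------------------------------


def detection_threshold(w, q: float) -> float:
    """``w_mean - q (w_mean - w_min)`` over one timestep's node potentials."""
    w = np.asarray(w, dtype=float).ravel()
    if w.size == 0:
        raise ValueError("empty potential vector")
    w_bar = float(w.mean())
    w_min = float(w.min())
    return w_bar - q * (w_bar - w_min)


def contrast_timestep(field: PotentialField, window: tuple | None = None) -> int:
    """Index of the timestep maximising the mean-to-minimum potential range.

    ``window`` optionally restricts the search to times (ms) in
    ``[t_lo, t_hi]`` — e.g. the plateau phase after full activation, where a
    depressed ischemic zone is the spatial minimum.
    """
    v = field.values
    contrast = v.mean(axis=0) - v.min(axis=0)
    if window is not None:
        t = field.times
        mask = (t >= window[0]) & (t <= window[1])
        if mask.any():
            idx = np.flatnonzero(mask)
            return int(idx[np.argmax(contrast[idx])])
    return int(np.argmax(contrast))


def detect_ischemia(
    field: PotentialField,
    heart: TriangleMesh,
    q: float = DEFAULT_Q,
    t_detect: float | None = None,
    window: tuple | None = None,
) -> DetectionReport:
    """Per-face ischemia classification on an epicardial field.

    A face's potential is the unweighted mean of its three vertex values at
    the detection timestep; the face is ischemic iff strictly below the
    threshold computed from the node potentials at that timestep.  With
    ``t_detect=None`` the timestep with maximum spatial contrast
    (mean minus minimum) is used — where the lesion is most visible —
    optionally restricted to a time ``window`` (ms), e.g. the plateau phase
    after full activation so the wavefront itself is not mistaken for a
    lesion.  Percentages in the returned report are left at NaN until scored
    against a real lesion mask by :func:`traffic_light`.
    """
    idx = (field.time_index(t_detect) if t_detect is not None
           else contrast_timestep(field, window=window))
    w = field.values[:, idx]
    thr = detection_threshold(w, q)
    face_pot = w[heart.faces].mean(axis=1)
    detected = face_pot < thr
    return DetectionReport(
        threshold=thr,
        q_factor=q,
        detected_elements=detected,
        ci_pct=float("nan"),
        ih_pct=float("nan"),
        ii_pct=float("nan"),
        detection_time=float(field.t0 + idx * field.dt),
    )


def real_lesion_mask(heart: TriangleMesh, lesion: LesionSpec) -> np.ndarray:
    """Faces whose centroid lies within the lesion radius of its centre."""
    d = np.linalg.norm(heart.face_centroids() - lesion.centre, axis=1)
    return d <= lesion.radius


def traffic_light(
    real_mask: np.ndarray, detected_mask: np.ndarray, heart: TriangleMesh
) -> tuple[float, float, float]:
    """(CI, IH, II) percentages of the true lesion area.

    CI: lesion area correctly detected; IH: lesion area missed; II: healthy
    area falsely detected, also relative to the true lesion area.
    """
    real_mask = np.asarray(real_mask, dtype=bool)
    detected_mask = np.asarray(detected_mask, dtype=bool)
    if real_mask.shape != detected_mask.shape:
        raise ValueError("masks must have the same length")
    areas = heart.face_areas()
    real_area = float(areas[real_mask].sum())
    if real_area == 0.0:
        raise ValueError("real lesion area is zero")
    ci = float(areas[real_mask & detected_mask].sum()) / real_area * 100.0
    ih = float(areas[real_mask & ~detected_mask].sum()) / real_area * 100.0
    ii = float(areas[~real_mask & detected_mask].sum()) / real_area * 100.0
    return ci, ih, ii


def score_detection(
    report: DetectionReport, real_mask: np.ndarray, heart: TriangleMesh
) -> DetectionReport:
    """Fill a detection report's CI/IH/II fields against the true mask."""
    ci, ih, ii = traffic_light(real_mask, report.detected_elements, heart)
    report.ci_pct, report.ih_pct, report.ii_pct = ci, ih, ii
    return report


def traffic_light_labels(real_mask: np.ndarray, detected_mask: np.ndarray) -> np.ndarray:
    """Per-face labels: 0 true-negative, 1 CI, 2 IH, 3 II (for visualisation)."""
    real_mask = np.asarray(real_mask, dtype=bool)
    detected_mask = np.asarray(detected_mask, dtype=bool)
    labels = np.zeros(real_mask.shape, dtype=int)
    labels[real_mask & detected_mask] = 1
    labels[real_mask & ~detected_mask] = 2
    labels[~real_mask & detected_mask] = 3
    return labels
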
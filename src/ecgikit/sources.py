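"""Synthetic epicardial action-potential sources with ischemic remodelling.

This module stands in for a biophysically detailed ventricular excitation
model.  It produces epicardial potential fields from three phenomenological
ingredients:

* a template action potential (AP) waveform parameterised by resting
  potential, peak potential, duration at 90% repolarisation (APD90) and
  upstroke duration;
* an activation map obtained from graph-geodesic distances to a set of pacing
  nodes at a fixed conduction velocity;
* a two-zone ischemic lesion in which the AP parameters are interpolated
  linearly between healthy and central-ischemic values by the lesion ramp
  weight (APD 274 -> 150 ms, resting potential depolarised by 0 -> +18 mV and
  upstroke slowed up to 3x at full weight, so a mid-ramp node approximates
  the border-zone electrophysiology of 228 ms / +10 mV).

Gaussian measurement noise at a prescribed signal-to-noise ratio can be added
to any field.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.optimize import brentq
from scipy.sparse.csgraph import dijkstra

from .geometry import LesionSpec, TriangleMesh, lesion_zones

# healthy ventricular AP summary values (mV, ms)
HEALTHY_RESTING_MV = -85.0
HEALTHY_PEAK_MV = 20.0
HEALTHY_APD_MS = 274.0
HEALTHY_UPSTROKE_MS = 5.0

# central ischemic zone remodelling at full ramp weight
ISCHEMIC_APD_MS = 150.0
ISCHEMIC_RESTING_SHIFT_MV = 18.0
ISCHEMIC_UPSTROKE_FACTOR = 3.0


@dataclass(frozen=True)
class APTemplate:
    """Summary parameters of a phenomenological action potential."""

    resting_potential: float = HEALTHY_RESTING_MV
    peak_potential: float = HEALTHY_PEAK_MV
    apd: float = HEALTHY_APD_MS
    upstroke_duration: float = HEALTHY_UPSTROKE_MS

    def __post_init__(self) -> None:
        if self.peak_potential <= self.resting_potential:
            raise ValueError("peak potential must exceed resting potential")
        if not (self.apd > self.upstroke_duration > 0):
            raise ValueError("require apd > upstroke_duration > 0")


def healthy_template() -> APTemplate:
    return APTemplate()


def ischemic_template(weight: float) -> APTemplate:
    """Template with remodelling interpolated linearly by ramp weight in [0, 1]."""
    w = float(np.clip(weight, 0.0, 1.0))
    return APTemplate(
        resting_potential=HEALTHY_RESTING_MV + w * ISCHEMIC_RESTING_SHIFT_MV,
        peak_potential=HEALTHY_PEAK_MV,
        apd=HEALTHY_APD_MS + w * (ISCHEMIC_APD_MS - HEALTHY_APD_MS),
        upstroke_duration=HEALTHY_UPSTROKE_MS * (1.0 + w * (ISCHEMIC_UPSTROKE_FACTOR - 1.0)),
    )


@dataclass
class ActivationMap:
    """Per-heart-node activation times in ms."""

    activation_time: np.ndarray

    def __post_init__(self) -> None:
        self.activation_time = np.asarray(self.activation_time, dtype=float)
        if np.any(~np.isfinite(self.activation_time)) or np.any(self.activation_time < 0):
            raise ValueError("activation times must be finite and non-negative")


@dataclass
class PotentialField:
    """Node x time matrix of potentials (mV) with a uniform time step (ms)."""

    values: np.ndarray
    dt: float = 1.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("values must be a (nodes, timesteps>=1) matrix")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("potential values must be finite")

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n_steps)

    def time_index(self, t: float) -> int:
        """Index of the sample closest to time ``t`` (ms)."""
        i = int(round((t - self.t0) / self.dt))
        if not (0 <= i < self.n_steps):
            raise ValueError(f"time {t} ms outside the field timeline")
        return i

    # -- delimited-text serialisation (matrix file + JSON metadata sidecar) --

    def save(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.values, delimiter="\t")
        Path(str(path) + ".meta.json").write_text(
            json.dumps({"dt": self.dt, "t0": self.t0}) + "\n"
        )

    @classmethod
    def load(cls, path: str | Path) -> "PotentialField":
        path = Path(path)
        values = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
        meta_path = Path(str(path) + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(values, dt=float(meta.get("dt", 1.0)), t0=float(meta.get("t0", 0.0)))


# ---------------------------------------------------------------------------
# AP waveform
# ---------------------------------------------------------------------------


def _repolarisation_centre(template: APTemplate, width: float) -> float:
    """Locate the repolarisation sigmoid centre so the waveform crosses 10% of
    the resting-to-peak range (i.e. 90% repolarisation) exactly at t = apd."""
    t_up, apd = template.upstroke_duration, template.apd
    droop = 0.1 / (apd - t_up)  # plateau decays ~10% of amplitude over the APD

    def f(tc: float) -> float:
        p = 1.0 - droop * (apd - t_up)
        r = 1.0 / (1.0 + np.exp((apd - tc) / width))
        r0 = 1.0 / (1.0 + np.exp((t_up - tc) / width))
        return p * r / r0 - 0.1

    lo, hi = t_up + 1e-9, apd + 20.0 * width
    return brentq(f, lo, hi, xtol=1e-10)


def ap_waveform(template: APTemplate, t: float | np.ndarray) -> np.ndarray:
    """Evaluate the phenomenological AP at times ``t`` (ms since activation).

    Pre-activation samples (t < 0) return the resting potential exactly; the
    upstroke is a monotone smoothstep reaching the peak at
    ``upstroke_duration``; afterwards a mildly decaying plateau multiplied by
    a sigmoidal repolarisation returns the trace to 10% of the amplitude
    above resting at ``t = apd`` (the APD90 definition).
    """
    t = np.asarray(t, dtype=float)
    rest, amp = template.resting_potential, template.peak_potential - template.resting_potential
    t_up, apd = template.upstroke_duration, template.apd
    width = max((apd - t_up) / 25.0, 1.0)
    tc = _repolarisation_centre(template, width)
    droop = 0.1 / (apd - t_up)
    r0 = 1.0 / (1.0 + np.exp((t_up - tc) / width))

    f = np.zeros_like(t)
    up = (t >= 0) & (t < t_up)
    tau = t[up] / t_up
    f[up] = tau * tau * (3.0 - 2.0 * tau)
    after = t >= t_up
    p = 1.0 - droop * (t[after] - t_up)
    r = 1.0 / (1.0 + np.exp((t[after] - tc) / width))
    f[after] = np.maximum(p, 0.0) * r / r0
    return rest + amp * f


# ---------------------------------------------------------------------------
# Activation map
# ---------------------------------------------------------------------------


def activation_map(
    heart: TriangleMesh, pacing_nodes, conduction_velocity: float = 2.0
) -> ActivationMap:
    """Activation times from graph-geodesic distance to the nearest pacing node.

    ``conduction_velocity`` is in mm/ms (default 2.0, a typical apparent
    epicardial spread speed, so the whole surface activates within ~100 ms).
    """
    pacing_nodes = np.atleast_1d(np.asarray(pacing_nodes, dtype=int))
    if pacing_nodes.size == 0:
        raise ValueError("at least one pacing node is required")
    if conduction_velocity <= 0:
        raise ValueError("conduction velocity must be positive")
    e = heart.edges()
    w = np.linalg.norm(heart.vertices[e[:, 0]] - heart.vertices[e[:, 1]], axis=1)
    n = heart.n_vertices
    g = sp.csr_matrix((np.r_[w, w], (np.r_[e[:, 0], e[:, 1]], np.r_[e[:, 1], e[:, 0]])), shape=(n, n))
    dist = dijkstra(g, directed=False, indices=pacing_nodes).min(axis=0)
    return ActivationMap(dist / conduction_velocity)


# ---------------------------------------------------------------------------
# Epicardial field synthesis
# ---------------------------------------------------------------------------


def epicardial_field(
    heart: TriangleMesh,
    lesion: LesionSpec | None,
    act: ActivationMap,
    timeline: tuple[float, float, int] = (0.0, 1.0, 400),
) -> PotentialField:
    """Synthesise the epicardial potential field over a timeline.

    ``timeline`` is ``(t0, dt, n_steps)`` in ms.  Each node's trace is the AP
    waveform with parameters interpolated between healthy and
    central-ischemic values by the node's lesion ramp weight, shifted by its
    activation time.  With ``lesion=None`` the healthy template is used
    everywhere.
    """
    t0, dt, n_steps = timeline
    times = t0 + dt * np.arange(int(n_steps))
    if times[-1] - times[0] < HEALTHY_APD_MS:
        raise ValueError("timeline must span at least one full APD")
    if lesion is None:
        weights = np.zeros(heart.n_vertices)
    else:
        _, weights = lesion_zones(heart, lesion)
    max_act = float(act.activation_time.max())
    if times[-1] < max_act + HEALTHY_APD_MS:
        warnings.warn(
            "timeline shorter than latest activation + APD; repolarisation truncated",
            stacklevel=2,
        )

    values = np.empty((heart.n_vertices, len(times)))
    # evaluate one waveform per distinct ramp weight (few in practice)
    uniq, inverse = np.unique(np.round(weights, 9), return_inverse=True)
    for k, w in enumerate(uniq):
        template = ischemic_template(w) if w > 0 else healthy_template()
        nodes = np.flatnonzero(inverse == k)
        shifted = times[None, :] - act.activation_time[nodes, None]
        values[nodes] = ap_waveform(template, shifted)
    return PotentialField(values, dt=dt, t0=t0)


# ---------------------------------------------------------------------------
# Measurement noise
# ---------------------------------------------------------------------------


def add_gaussian_noise(field: PotentialField, snr_db: float, seed: int) -> PotentialField:
    """Add zero-mean Gaussian noise at a prescribed global SNR (dB).

    The noise variance is ``signal_power / 10**(snr_db / 10)`` where the
    signal power is the mean squared value over all nodes and timesteps.
    Deterministic for a fixed seed.
    """
    if not np.isfinite(snr_db):
        raise ValueError("snr_db must be finite")
    power = float(np.mean(field.values**2))
    if power == 0.0:
        raise ValueError("SNR undefined for an all-zero field")
    sigma = np.sqrt(power / 10.0 ** (snr_db / 10.0))
    rng = np.random.default_rng(seed)
    noisy = field.values + rng.normal(0.0, sigma, size=field.values.shape)
    return replace(field, values=noisy)
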
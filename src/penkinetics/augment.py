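"""Physics-based pathology operators for sim-to-real augmentation.

Two deterministic, transparent operators emulate the motor signature of
early cognitive-motor impairment:

* **Tremor injection** — additive white Gaussian noise on the acceleration
  and jerk channels, with standard deviation expressed relative to the
  channel amplitude (max - min).  Severity sigma is drawn uniformly from a
  configured range, spanning mild physiological to pronounced pathological
  tremor.
* **Bradykinesia time-warping** — resampling through a smooth, strictly
  monotone warping function built by cubic-spline interpolation through
  randomly perturbed knot points.  Local stretches simulate hesitation,
  local compressions rushed segments; the order of motor events is strictly
  preserved.

The per-class policy applies tremor + strong warping to the impaired class
and mild warping only to controls, so a classifier cannot key on the mere
presence of augmentation artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy.interpolate import CubicSpline, PchipInterpolator

from penkinetics.features import NOISE_CHANNELS, FeatureTensor
from penkinetics.recording import RawRecording


@dataclass
class AugmentationParams:
    """Per-class pathology operator configuration.

    ``sigma_range`` is the tremor noise std relative to channel amplitude;
    ``n_knots`` the number of interior warp knots K; the knot jitters are the
    std of knot displacement relative to the knot spacing T/(K+1), with the
    control-class ("mild") jitter at a quarter of the impaired-class strength
    by default.
    """

    sigma_range: tuple = (0.01, 0.05)
    noise_channels: tuple = NOISE_CHANNELS
    n_knots: int = 8
    ad_knot_jitter: float = 0.2
    cn_knot_jitter: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.sigma_range
        if not 0 <= lo <= hi:
            raise ValueError("sigma_range must satisfy 0 <= low <= high")
        if self.n_knots < 1:
            raise ValueError("n_knots must be >= 1")
        if self.ad_knot_jitter < 0 or self.cn_knot_jitter < 0:
            raise ValueError("knot jitters must be non-negative")
        if self.cn_knot_jitter > self.ad_knot_jitter:
            raise ValueError("control-class jitter must not exceed impaired-class jitter")


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def inject_tremor(x: np.ndarray, sigma_rel: float, seed=0) -> np.ndarray:
    """Add white Gaussian tremor noise scaled to the signal amplitude.

    Noise std is ``sigma_rel * (max - min)`` per channel; constant channels
    (zero amplitude) are left untouched, and ``sigma_rel = 0`` is an exact
    identity.  Works on (n,) or (n, k) arrays, channels along axis 1.
    """
    if sigma_rel < 0:
        raise ValueError("sigma_rel must be non-negative")
    arr = np.asarray(x, dtype=float)
    if sigma_rel == 0:
        return arr.copy()
    rng = _as_rng(seed)
    amp = arr.max(axis=0, keepdims=True) - arr.min(axis=0, keepdims=True)
    noise = rng.normal(0.0, 1.0, size=arr.shape) * (sigma_rel * amp)
    return arr + noise


def build_warp(T: int, K: int = 8, jitter: float = 0.2, seed=0) -> np.ndarray:
    """Monotone warping function tau over the index grid [0, T-1].

    K interior knots are placed evenly over the time axis and their ordinates
    displaced by Normal(0, (jitter * T / (K+1))^2); endpoints stay pinned so
    ``tau(0) = 0`` and ``tau(T-1) = T-1`` exactly.  A cubic spline through the
    knots gives a smooth map; because unconstrained splines through jittered
    knots can overshoot, knot ordinates are first projected onto the
    increasing cone (pool-adjacent-violators) and, if the evaluated grid
    still contains a non-positive increment, the fit falls back to a
    monotone cubic (PCHIP) with a final cumulative-maximum repair.  The
    returned grid is strictly increasing for every seed.
    """
    if T < 4:
        raise ValueError("build_warp requires T >= 4")
    if K < 1:
        raise ValueError("K must be >= 1")
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    rng = _as_rng(seed)
    knots_x = np.linspace(0.0, T - 1.0, K + 2)
    knots_y = knots_x.copy()
    if jitter > 0:
        knots_y[1:-1] += rng.normal(0.0, jitter * T / (K + 1), size=K)
        knots_y = _isotonic_increasing(knots_y)
        # restore pinned endpoints after projection
        knots_y = knots_y - knots_y[0]
        knots_y = knots_y * (T - 1.0) / knots_y[-1]
    grid = np.arange(T, dtype=float)
    tau = CubicSpline(knots_x, knots_y)(grid)
    if np.any(np.diff(tau) <= 0):
        tau = PchipInterpolator(knots_x, knots_y)(grid)
    if np.any(np.diff(tau) <= 0):
        # last-resort repair: cumulative max plus a vanishing ramp, re-pinned
        tau = np.maximum.accumulate(tau) + 1e-9 * grid
        tau = tau - tau[0]
        tau = tau * (T - 1.0) / tau[-1]
    tau[0] = 0.0
    tau[-1] = T - 1.0
    return np.clip(tau, 0.0, T - 1.0)


def _isotonic_increasing(y: np.ndarray) -> np.ndarray:
    """Project onto non-decreasing sequences (PAV), then strictify."""
    from sklearn.isotonic import IsotonicRegression
    iso = IsotonicRegression(increasing=True)
    z = iso.fit_transform(np.arange(len(y)), y)
    # break exact ties so the spline sees strictly increasing ordinates
    eps = 1e-6 * max(float(y[-1] - y[0]), 1.0)
    return z + eps * np.arange(len(z))


def time_warp(x: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Resample a series through a warp: out(t) = x(tau(t)), linear interp.

    ``tau`` indexes fractional sample positions of ``x``; length is
    preserved and, because tau is monotone, the order of any two motor
    events is preserved.  Works on (n,) or (n, k) arrays.
    """
    arr = np.asarray(x, dtype=float)
    n = arr.shape[0]
    tau = np.asarray(tau, dtype=float)
    if len(tau) != n:
        raise ValueError("tau length must match the series length")
    if tau.min() < 0 or tau.max() > n - 1:
        raise ValueError("tau indexes outside the series range")
    base = np.arange(n, dtype=float)
    if arr.ndim == 1:
        return np.interp(tau, base, arr)
    return np.stack([np.interp(tau, base, arr[:, j]) for j in range(arr.shape[1])], axis=1)


def augment_recording(rec: RawRecording, params: AugmentationParams,
                      rng=None, severity: Optional[str] = None) -> RawRecording:
    """Apply the class policy to a raw recording (pre-featurization mode).

    Impaired (AD) recordings receive tremor noise on the acceleration
    channels (jerk does not exist yet at this stage) plus strong warping;
    control (CN) recordings receive mild warping only.  ``severity``
    overrides the class read from ``rec.label``.
    """
    params.validate()
    rng = _as_rng(params.seed if rng is None else rng)
    sev = severity or rec.label
    out = rec.copy()
    n = rec.n_samples
    if sev == "AD":
        sigma = float(rng.uniform(*params.sigma_range))
        out.accel = inject_tremor(out.accel, sigma, seed=rng)
        jitter = params.ad_knot_jitter
    else:
        jitter = params.cn_knot_jitter
    if jitter > 0:
        tau = build_warp(n, params.n_knots, jitter, seed=rng)
        out.accel = time_warp(out.accel, tau)
        out.gyro = time_warp(out.gyro, tau)
        if out.mag is not None:
            out.mag = time_warp(out.mag, tau)
    return out


def augment_tensor(ft: FeatureTensor, params: AugmentationParams,
                   rng=None, severity: Optional[str] = None) -> FeatureTensor:
    """Apply the class policy to an assembled feature tensor.

    Tremor noise goes to the configured noise channels (acceleration and
    jerk by default); warping resamples all 18 channels through a shared
    tau restricted to the unpadded region so zero padding stays in place.
    """
    params.validate()
    rng = _as_rng(params.seed if rng is None else rng)
    sev = severity or ft.label
    out = ft.copy()
    n = ft.valid_length
    if sev == "AD":
        sigma = float(rng.uniform(*params.sigma_range))
        idx = [ft.channel_names.index(c) for c in params.noise_channels]
        out.values[:n, idx] = inject_tremor(out.values[:n, idx], sigma, seed=rng)
        jitter = params.ad_knot_jitter
    else:
        jitter = params.cn_knot_jitter
    if jitter > 0 and n >= 4:
        tau = build_warp(n, params.n_knots, jitter, seed=rng)
        out.values[:n] = time_warp(out.values[:n], tau)
    return out


def apply_policy(cohort: Sequence[Union[RawRecording, FeatureTensor]],
                 params: AugmentationParams, seed: int = 0) -> list:
    """Augment a labelled cohort under the per-class policy.

    Dispatches per item to the recording- or tensor-level operator; labels
    and counts are unchanged and per-item seeds derive reproducibly from the
    master ``seed``.
    """
    params.validate()
    children = np.random.SeedSequence(seed).spawn(len(cohort))
    out = []
    for item, ss in zip(cohort, children):
        rng = np.random.default_rng(ss)
        if isinstance(item, RawRecording):
            out.append(augment_recording(item, params, rng=rng))
        elif isinstance(item, FeatureTensor):
            out.append(augment_tensor(item, params, rng=rng))
        else:
            raise TypeError(f"cannot augment items of type {type(item).__name__}")
    return out
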
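"""Cleaning and orientation of raw ADV bursts.

The processing chain mirrors standard ADV practice for shallow tidal flows:

1. split each component into a zero-phase low-pass "mean" and a residual
   turbulent fluctuation (``decompose``),
2. remove spikes from the fluctuations with phase-space thresholding
   (``despike``),
3. rotate the frame into streamline coordinates so the burst-mean transverse
   and vertical velocities and the v'w' covariance vanish
   (``estimate_rotation_angles`` / ``apply_rotation`` / ``rotate_profile``).
"""
from __future__ import annotations

import dataclasses
import math
from typing import Dict, Iterable, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import signal

from .types import DecomposedBurst, RotationAngles, SpikeMask, VelocityBurst

__all__ = [
    "decompose",
    "despike",
    "despike_burst",
    "estimate_rotation_angles",
    "apply_rotation",
    "rotate_profile",
    "burst_summary",
    "process_burst",
    "process_profile",
    "rotation_matrix",
    "misalignment_matrix",
]

COMPONENTS = ("u", "v", "w")


# ---------------------------------------------------------------------------
# rotations
# ---------------------------------------------------------------------------

def _plane_rotation(theta_deg: float, i: int, j: int) -> np.ndarray:
    """Rotation in the (axis_i, axis_j) plane: x_i' = x_i c + x_j s."""
    th = math.radians(theta_deg)
    r = np.eye(3)
    c, s = math.cos(th), math.sin(th)
    r[i, i] = c
    r[i, j] = s
    r[j, i] = -s
    r[j, j] = c
    return r


def rotation_matrix(angles: Union[RotationAngles, Sequence[float]]) -> np.ndarray:
    """Streamline rotation: x-y plane first, then x-z, then roll about x."""
    if isinstance(angles, RotationAngles):
        a, b, c = angles.as_tuple()
    else:
        a, b, c = angles
    return _plane_rotation(c, 1, 2) @ _plane_rotation(b, 0, 2) @ _plane_rotation(a, 0, 1)


def misalignment_matrix(angles: Sequence[float]) -> np.ndarray:
    """Sensor-misalignment transform that the streamline rotation inverts.

    Built so that a burst misaligned by ``angles`` yields estimated streamline
    angles equal to ``-angles`` exactly (the plane rotations are applied in
    the reverse order of :func:`rotation_matrix`).
    """
    a, b, c = angles
    return _plane_rotation(a, 0, 1) @ _plane_rotation(b, 0, 2) @ _plane_rotation(c, 1, 2)


def _principal_roll_angle_deg(var_v: float, var_w: float, cov_vw: float) -> float:
    """Roll about x (degrees, in (-45, 45]) that zeroes cov(v, w)."""
    if var_v == var_w == 0.0 or (cov_vw == 0.0 and var_v == var_w):
        return 0.0
    psi = 0.5 * math.degrees(math.atan2(2.0 * cov_vw, var_v - var_w))
    while psi > 45.0:
        psi -= 90.0
    while psi <= -45.0:
        psi += 90.0
    return psi


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

def decompose(burst: VelocityBurst, cutoff: float = 0.1, order: int = 4) -> DecomposedBurst:
    """Split each component into a low-pass mean series and fluctuations.

    The mean is the zero-phase (forward-backward Butterworth) low-pass of the
    component, so the split introduces no phase shift and ``mean + fluct``
    reconstructs the input exactly because the fluctuation is defined as the
    residual.

    Parameters
    ----------
    cutoff : float
        Low-pass cutoff in Hz; must be below the Nyquist frequency, and the
        burst must span at least ten filter time constants (10 / (2 pi cutoff)
        seconds) so the mean series is meaningful.
    """
    fs = burst.sample_rate
    if cutoff >= fs / 2:
        raise ValueError(f"cutoff {cutoff} Hz must be below Nyquist ({fs / 2} Hz)")
    duration = len(burst) / fs
    if duration < 10.0 / (2.0 * math.pi * cutoff):
        raise ValueError("burst shorter than ten filter time constants at this cutoff")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    means = {}
    flucts = {}
    for name in COMPONENTS:
        x = getattr(burst, name)
        m = signal.sosfiltfilt(sos, x)
        means[name] = m
        flucts[name] = x - m
    return DecomposedBurst(
        t=burst.t,
        sample_rate=fs,
        mean_u=means["u"],
        mean_v=means["v"],
        mean_w=means["w"],
        fluct_u=flucts["u"],
        fluct_v=flucts["v"],
        fluct_w=flucts["w"],
        cutoff=cutoff,
        elevation=burst.elevation,
        location=burst.location,
        profile_id=burst.profile_id,
        truth=burst.truth,
    )


# ---------------------------------------------------------------------------
# despiking
# ---------------------------------------------------------------------------

def _robust_sd(x: np.ndarray) -> float:
    # MAD scaled to the SD of a Gaussian; spikes barely move it.
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def _phase_space_outliers(y: np.ndarray, lam: float) -> np.ndarray:
    """Boolean mask of points outside any of the three threshold ellipses."""
    d1 = np.gradient(y)
    d2 = np.gradient(d1)
    s0, s1, s2 = _robust_sd(y), _robust_sd(d1), _robust_sd(d2)
    eps = np.finfo(float).tiny
    bad = np.zeros(y.shape, dtype=bool)
    # (y, d1) and (d1, d2): axis-aligned ellipses (the pairs are uncorrelated
    # for a stationary series).
    bad |= (y / max(lam * s0, eps)) ** 2 + (d1 / max(lam * s1, eps)) ** 2 > 1.0
    bad |= (d1 / max(lam * s1, eps)) ** 2 + (d2 / max(lam * s2, eps)) ** 2 > 1.0
    # (y, d2): correlated pair, rotate by the principal angle.
    denom = float(np.sum(y * y))
    theta = math.atan2(float(np.sum(y * d2)), denom) if denom > 0 else 0.0
    ct, st = math.cos(theta), math.sin(theta)
    a2 = (lam * s0) ** 2 * ct**2 + (lam * s2) ** 2 * st**2
    b2 = (lam * s0) ** 2 * st**2 + (lam * s2) ** 2 * ct**2
    xr = y * ct + d2 * st
    zr = -y * st + d2 * ct
    bad |= xr**2 / max(a2, eps) + zr**2 / max(b2, eps) > 1.0
    return bad


def _interpolate_over(x: np.ndarray, bad: np.ndarray) -> np.ndarray:
    """Linear interpolation across flagged runs; edges take nearest good value."""
    y = x.copy()
    good = ~bad
    if bad.any():
        if not good.any():
            raise ValueError("all samples flagged as spikes")
        idx = np.arange(len(x))
        y[bad] = np.interp(idx[bad], idx[good], x[good])
    return y


def despike(
    fluct: np.ndarray,
    max_iter: int = 20,
    revalidate: bool = True,
) -> Tuple[np.ndarray, SpikeMask]:
    """Phase-space threshold despiking of one fluctuating series.

    Builds the (x, dx, d2x) phase space, thresholds each 2-d projection with
    the universal ellipse lambda = sqrt(2 ln n) robust SDs (the x-d2x
    projection rotated by its principal angle), replaces flagged points by
    linear interpolation, and iterates until no new spikes appear or the
    good-point count stops changing (capped at ``max_iter``).

    A re-validation pass then restores any flagged sample whose violation is
    not attributable to its own value: the central-difference coordinates of a
    point depend only on its neighbours, so a large spike casts collateral
    flags onto perfectly good samples (and a good sample sitting between two
    sharply differing neighbours can violate no matter what value it holds).
    A flag is kept only if the sample's amplitude alone exceeds the threshold
    or if restoring it creates a violation the cleaned series does not already
    have; restored samples are exempt from re-flagging, and detection and
    re-validation alternate to a fixpoint, so a second despike pass flags
    nothing new.

    Returns the cleaned series and a :class:`SpikeMask`.
    """
    x = np.asarray(fluct, dtype=float)
    if x.ndim != 1 or len(x) < 100:
        raise ValueError("despike expects a 1-d series of length >= 100")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values present; screen NaN/inf before despiking")
    flagged, iterations = _despike_pass(x, max_iter, revalidate)
    # idempotence by construction: points that still look bad in the cleaned
    # context are absorbed until a rerun on the output would flag nothing
    for _ in range(8):
        clean = _interpolate_over(x, flagged)
        extra, _ = _despike_pass(clean, max_iter, revalidate)
        if not extra.any():
            break
        flagged |= extra
    clean = _interpolate_over(x, flagged)
    idx = np.flatnonzero(flagged)
    return clean, SpikeMask(
        indices=idx, iterations=max(iterations, 1), replaced_values=clean[idx]
    )


def _despike_pass(x: np.ndarray, max_iter: int, revalidate: bool):
    """One full detect / replace / re-validate convergence on a series."""
    n = len(x)
    lam = math.sqrt(2.0 * math.log(n))
    flagged = np.zeros(n, dtype=bool)
    exempt = np.zeros(n, dtype=bool)  # restored samples deemed good for good
    iterations = 0
    guard = 0
    # every sample can be flagged and exempted at most once, so the
    # alternation terminates; the guard is a hard stop well beyond that
    while guard < 20 * max_iter:
        guard += 1
        y = _interpolate_over(x, flagged)
        bad = _phase_space_outliers(y, lam)
        new = bad & ~flagged & ~exempt
        if new.any():
            iterations += 1
            flagged |= new
            continue
        if not revalidate or not flagged.any():
            break
        vio_y = bad
        med = np.median(y)
        s0 = _robust_sd(y)
        keep = flagged.copy()
        for i in np.flatnonzero(flagged):
            if abs(x[i] - med) > lam * s0:
                continue  # amplitude alone convicts the sample
            z = y.copy()
            z[i] = x[i]
            lo, hi = max(i - 3, 0), min(i + 4, n)
            vio_z = _phase_space_outliers(z, lam)[lo:hi]
            if not (vio_z & ~vio_y[lo:hi]).any():
                keep[i] = False
        if np.array_equal(keep, flagged):
            break
        exempt |= flagged & ~keep
        flagged = keep
    return flagged, iterations


def despike_burst(
    dec: DecomposedBurst, max_iter: int = 20
) -> Tuple[DecomposedBurst, Dict[str, SpikeMask]]:
    """Despike each fluctuating component of a decomposed burst."""
    masks: Dict[str, SpikeMask] = {}
    clean = dataclasses.replace(dec)
    for name in COMPONENTS:
        cleaned, mask = despike(getattr(dec, f"fluct_{name}"), max_iter=max_iter)
        setattr(clean, f"fluct_{name}", cleaned)
        masks[name] = mask
    return clean, masks


# ---------------------------------------------------------------------------
# streamline rotation
# ---------------------------------------------------------------------------

def _totals(burst: Union[VelocityBurst, DecomposedBurst]) -> np.ndarray:
    if isinstance(burst, DecomposedBurst):
        return np.vstack([burst.total(c) for c in COMPONENTS])
    return burst.components()


def estimate_rotation_angles(
    burst: Union[VelocityBurst, DecomposedBurst],
    min_speed: float = 1e-4,
) -> RotationAngles:
    """Angles of the three-step streamline rotation for one burst.

    theta_xy zeroes the burst-mean transverse velocity, theta_xz the
    burst-mean vertical velocity (after the first rotation), and theta_cross
    is the roll about the streamwise axis zeroing the covariance of the
    burst-demeaned transverse and vertical series. Applying all three via
    :func:`apply_rotation` therefore leaves v-bar, w-bar and v'w' at zero to
    machine precision.
    """
    xyz = _totals(burst)
    ubar, vbar, wbar = xyz.mean(axis=1)
    if math.hypot(ubar, vbar) < min_speed:
        raise ValueError("indeterminate streamline direction: mean horizontal speed below floor")
    theta_xy = math.degrees(math.atan2(vbar, ubar))
    xyz1 = _plane_rotation(theta_xy, 0, 1) @ xyz
    u1 = xyz1[0].mean()
    theta_xz = math.degrees(math.atan2(xyz1[2].mean(), u1))
    xyz2 = _plane_rotation(theta_xz, 0, 2) @ xyz1
    v2 = xyz2[1] - xyz2[1].mean()
    w2 = xyz2[2] - xyz2[2].mean()
    n = v2.size
    theta_cross = _principal_roll_angle_deg(
        float(v2 @ v2) / n, float(w2 @ w2) / n, float(v2 @ w2) / n
    )
    elev = (burst.elevation,) if burst.elevation is not None else None
    return RotationAngles(theta_xy, theta_xz, theta_cross, source_elevations=elev)


def apply_rotation(burst, angles: Union[RotationAngles, Sequence[float]]):
    """Rotate a burst (or decomposed burst) into the frame given by ``angles``.

    The transform is orthogonal, so per-sample speed magnitude is preserved.
    For a :class:`DecomposedBurst` the mean and fluctuation triplets are
    rotated with the same matrix — the low-pass filter is linear, so the
    decomposition commutes with a static rotation.
    """
    r = rotation_matrix(angles)
    if isinstance(burst, DecomposedBurst):
        means = r @ burst.means()
        flucts = r @ burst.flucts()
        out = dataclasses.replace(burst)
        for k, name in enumerate(COMPONENTS):
            setattr(out, f"mean_{name}", means[k])
            setattr(out, f"fluct_{name}", flucts[k])
        return out
    if isinstance(burst, VelocityBurst):
        uvw = r @ burst.components()
        return dataclasses.replace(burst, u=uvw[0], v=uvw[1], w=uvw[2])
    raise TypeError("apply_rotation expects a VelocityBurst or DecomposedBurst")


def rotate_profile(
    profile: Sequence[DecomposedBurst],
) -> Tuple[List[DecomposedBurst], RotationAngles]:
    """Rotate every burst of a vertical profile with profile-level angles.

    Near the bed the flow is three-dimensional, so the angles are estimated
    only at the two highest elevations (where the flow is assumed
    two-dimensional), averaged arithmetically per angle, and the averaged
    rotation is applied to all elevations of the profile (rigid sensor frame).
    """
    bursts = list(profile)
    if len(bursts) < 2:
        raise ValueError("rotate_profile needs at least two elevations")
    if any(b.elevation is None for b in bursts):
        raise ValueError("every burst in a profile needs an elevation")
    ordered = sorted(bursts, key=lambda b: b.elevation, reverse=True)
    top_two = ordered[:2]
    ests = [estimate_rotation_angles(b) for b in top_two]
    angles = RotationAngles(
        theta_xy=float(np.mean([e.theta_xy for e in ests])),
        theta_xz=float(np.mean([e.theta_xz for e in ests])),
        theta_cross=float(np.mean([e.theta_cross for e in ests])),
        source_elevations=tuple(b.elevation for b in top_two),
    )
    return [apply_rotation(b, angles) for b in bursts], angles


# ---------------------------------------------------------------------------
# summaries and convenience pipelines
# ---------------------------------------------------------------------------

def burst_summary(
    burst: Union[VelocityBurst, DecomposedBurst],
    decomposed: Optional[DecomposedBurst] = None,
    masks: Optional[Dict[str, SpikeMask]] = None,
    angles: Optional[RotationAngles] = None,
) -> dict:
    """Per-burst row of mean velocities and fluctuation (co)variances.

    This is the record behind vertical profiles of mean velocity: burst
    averages of each component (the low-pass mean series plus the
    fluctuation, whose average is ~0) and variances/covariance of the
    fluctuations, with elevation and location carried along.
    """
    dec = decomposed if decomposed is not None else burst
    if not isinstance(dec, DecomposedBurst):
        raise TypeError("burst_summary needs a DecomposedBurst (pass one or decompose first)")
    fl = dec.flucts()
    fl = fl - fl.mean(axis=1, keepdims=True)
    n = fl.shape[1]
    row = {
        "profile_id": dec.profile_id,
        "location": dec.location,
        "elevation_cmab": dec.elevation,
        "u_mean": float(dec.total("u").mean()),
        "v_mean": float(dec.total("v").mean()),
        "w_mean": float(dec.total("w").mean()),
        "var_u": float(fl[0] @ fl[0]) / n,
        "var_v": float(fl[1] @ fl[1]) / n,
        "var_w": float(fl[2] @ fl[2]) / n,
        "cov_vw": float(fl[1] @ fl[2]) / n,
        "n_spikes": int(sum(m.n_spikes for m in masks.values())) if masks else 0,
    }
    if angles is not None:
        row.update(
            theta_xy=angles.theta_xy,
            theta_xz=angles.theta_xz,
            theta_cross=angles.theta_cross,
        )
    return row


def process_burst(
    burst: VelocityBurst,
    cutoff: float = 0.1,
    rotate: bool = True,
    max_iter: int = 20,
) -> Tuple[DecomposedBurst, Dict[str, SpikeMask], Optional[RotationAngles]]:
    """Decompose, despike and (optionally) streamline-rotate a single burst."""
    dec = decompose(burst, cutoff=cutoff)
    clean, masks = despike_burst(dec, max_iter=max_iter)
    angles = None
    if rotate:
        angles = estimate_rotation_angles(clean)
        clean = apply_rotation(clean, angles)
    return clean, masks, angles


def process_profile(
    bursts: Sequence[VelocityBurst],
    cutoff: float = 0.1,
    max_iter: int = 20,
):
    """Full cleaning chain for a vertical profile.

    Returns (rotated decomposed bursts, per-burst spike masks, profile angles).
    """
    cleaned = []
    all_masks = []
    for b in bursts:
        dec = decompose(b, cutoff=cutoff)
        clean, masks = despike_burst(dec, max_iter=max_iter)
        cleaned.append(clean)
        all_masks.append(masks)
    rotated, angles = rotate_profile(cleaned)
    return rotated, all_masks, angles
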
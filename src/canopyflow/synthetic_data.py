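"""Synthetic ADV bursts and behavioural count tables with known ground truth.

The burst generator emulates the field measurement scheme — 25 Hz,
four-minute bursts at elevations within and above an artificial seagrass
canopy — by random-phase spectral synthesis against the inertial-subrange
model spectra, then layering on the instrument artefacts the processing
chain must undo: a mean current, a low-frequency wave oscillation, white
sensor noise, isolated spikes, and a rigid sensor-frame misalignment.

The count generator emulates the camera-deployment design: replicate
artificial seagrass units (ASUs) each filmed from four positions for a fixed
number of observed minutes on one tidal phase, with AR(1) temporal
correlation in the latent log-intensity, overdispersed abundance counts, and
a binomial water-column split.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from scipy.special import expit

from .adv_processing import misalignment_matrix, _plane_rotation, _principal_roll_angle_deg
from .spectral_dissipation import model_spectrum
from .types import (
    CAMERA_POSITIONS,
    BurstTruth,
    CountSimParams,
    TurbSimParams,
    VelocityBurst,
)

__all__ = [
    "simulate_adv_burst",
    "simulate_profile",
    "simulate_counts",
    "model_frequency_spectrum",
]

_COMPONENTS = ("u", "v", "w")


def model_frequency_spectrum(
    component: str, params: TurbSimParams, f: np.ndarray
) -> np.ndarray:
    """Target one-sided frequency spectrum of the synthesized turbulence.

    The inertial-subrange wavenumber model mapped to frequency at the burst's
    advection speed, truncated to zero below ``spectrum_floor_hz``.
    """
    f = np.asarray(f, dtype=float)
    s = np.zeros_like(f)
    if params.epsilon <= 0:
        return s
    band = f >= params.spectrum_floor_hz
    k = 2.0 * math.pi * f[band] / params.mean_speed
    s[band] = model_spectrum(component, params.epsilon, k) * (
        2.0 * math.pi / params.mean_speed
    )
    return s


def _synthesize_turbulence(params: TurbSimParams, rng: np.random.Generator) -> np.ndarray:
    """Random-phase synthesis of the three fluctuating components.

    Spectral amplitudes are set deterministically from the model spectrum
    (so the realized variance equals the band integral exactly, by Parseval)
    and phases are independent and uniform per frequency bin and component.
    """
    n = params.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / params.sample_rate)
    df = params.sample_rate / n
    out = np.zeros((3, n))
    if params.epsilon <= 0:
        return out
    for row, comp in enumerate(_COMPONENTS):
        s = model_frequency_spectrum(comp, params, freqs)
        amp = np.sqrt(s * params.sample_rate * n / 2.0)
        if n % 2 == 0 and freqs[-1] > 0:
            # the Nyquist bin of a one-sided PSD carries no factor of two
            amp[-1] = math.sqrt(s[-1] * params.sample_rate * n)
        phases = rng.uniform(0.0, 2.0 * math.pi, size=freqs.size)
        spec = amp * np.exp(1j * phases)
        spec[0] = 0.0
        if n % 2 == 0:
            spec[-1] = spec[-1].real  # Nyquist coefficient must be real
        out[row] = np.fft.irfft(spec, n=n)
    # Orthogonalize the transverse/vertical pair so the aligned frame is an
    # exact ground truth: remove the (sampling-noise) v-w covariance with the
    # principal-axis roll. The angle is tiny; variances barely move.
    v, w = out[1], out[2]
    var_v, var_w = float(v @ v) / n, float(w @ w) / n
    if var_v + var_w > 0:
        psi = _principal_roll_angle_deg(var_v, var_w, float(v @ w) / n)
        rot = _plane_rotation(psi, 1, 2)
        out[1:] = rot[1:, 1:] @ out[1:]
    return out


def simulate_adv_burst(
    params: TurbSimParams,
    elevation: Optional[float] = None,
    location: Optional[str] = None,
    profile_id: Optional[str] = None,
) -> VelocityBurst:
    """Simulate one ADV burst with recorded ground truth.

    Construction order: spectral synthesis of the fluctuations; mean current
    and wave oscillation added to u; white noise added to every component;
    spikes injected per component at recorded indices; finally the whole
    triplet is rotated by the misalignment angles.
    """
    n = params.n_samples
    rng = np.random.default_rng(params.seed)
    t = np.arange(n) / params.sample_rate
    xyz = _synthesize_turbulence(params, rng)

    xyz[0] += params.mean_speed
    if params.wave_amp != 0.0:
        phase = rng.uniform(0.0, 2.0 * math.pi)
        xyz[0] += params.wave_amp * np.sin(2.0 * math.pi * params.wave_freq * t + phase)

    fluct_sd = []
    for row in range(3):
        sd = params.noise_sd[row]
        noise = rng.normal(0.0, sd, size=n) if sd > 0 else 0.0
        xyz[row] = xyz[row] + noise
        base = xyz[row] - (params.mean_speed if row == 0 else 0.0)
        fluct_sd.append(float(np.std(base - base.mean())))

    spike_indices: Dict[str, np.ndarray] = {}
    n_spikes = int(round(params.spike_rate * n))
    for row, comp in enumerate(_COMPONENTS):
        if n_spikes == 0:
            spike_indices[comp] = np.empty(0, dtype=int)
            continue
        if fluct_sd[row] == 0.0:
            raise ValueError(
                f"cannot scale spikes for component {comp}: zero fluctuation SD"
            )
        idx = np.sort(rng.choice(n, size=n_spikes, replace=False))
        signs = rng.choice([-1.0, 1.0], size=n_spikes)
        xyz[row, idx] += signs * params.spike_amplitude * fluct_sd[row]
        spike_indices[comp] = idx

    xyz = misalignment_matrix(params.angles) @ xyz
    return VelocityBurst(
        t=t,
        u=xyz[0],
        v=xyz[1],
        w=xyz[2],
        sample_rate=params.sample_rate,
        elevation=elevation,
        location=location,
        profile_id=profile_id,
        truth=BurstTruth(params=params, spike_indices=spike_indices),
    )


def simulate_profile(
    params_by_elevation: Union[Mapping[float, TurbSimParams], Iterable[Tuple[float, TurbSimParams]]],
    location: Optional[str] = None,
    profile_id: Optional[str] = None,
    seed: Optional[int] = None,
    share_angles: bool = True,
) -> List[VelocityBurst]:
    """One burst per elevation, sharing a profile identifier.

    By default every burst gets the misalignment angles of the highest
    elevation's parameters (the sensors share a rigid frame). If ``seed`` is
    given, per-burst seeds are derived from it deterministically and override
    the per-elevation seeds.
    """
    if isinstance(params_by_elevation, Mapping):
        items = list(params_by_elevation.items())
    else:
        items = list(params_by_elevation)
    if not items:
        raise ValueError("params_by_elevation must not be empty")
    elevations = [e for e, _ in items]
    if len(set(elevations)) != len(elevations):
        raise ValueError("elevations must be distinct")
    items = sorted(items, key=lambda kv: kv[0])

    if seed is not None:
        children = np.random.SeedSequence(seed).spawn(len(items))
        sub_seeds = [int(c.generate_state(1)[0] % 2**31) for c in children]
        items = [
            (elev, dataclasses.replace(p, seed=s))
            for (elev, p), s in zip(items, sub_seeds)
        ]
    if share_angles:
        frame_angles = items[-1][1].angles  # highest elevation
        items = [(elev, dataclasses.replace(p, angles=frame_angles)) for elev, p in items]
    if profile_id is None:
        profile_id = f"profile-{items[0][1].seed}"
    return [
        simulate_adv_burst(p, elevation=elev, location=location, profile_id=profile_id)
        for elev, p in items
    ]


def _draw_counts(mu: np.ndarray, dispersion: float, rng: np.random.Generator) -> np.ndarray:
    """Counts with mean mu and variance dispersion * mu (gamma-mixed Poisson)."""
    if dispersion == 1.0:
        return rng.poisson(mu)
    shape = mu / (dispersion - 1.0)
    lam = rng.gamma(shape=shape, scale=dispersion - 1.0)
    return rng.poisson(lam)


def _ar1(n: int, phi: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series with marginal SD sigma."""
    if sigma == 0.0 or n == 0:
        return np.zeros(n)
    e = np.empty(n)
    e[0] = rng.normal(0.0, sigma)
    innov_sd = sigma * math.sqrt(1.0 - phi**2)
    shocks = rng.normal(0.0, innov_sd, size=n - 1) if n > 1 else []
    for i in range(1, n):
        e[i] = phi * e[i - 1] + shocks[i - 1]
    return e


def simulate_counts(params: CountSimParams) -> pd.DataFrame:
    """Per-minute fish-count table across ASUs, positions and tides.

    Per (ASU, camera position) series: latent log-intensity
    beta0 + beta_pos + beta_tide * flood + AR(1) noise; abundance drawn from
    the overdispersed count law (variance = dispersion * mean); water-column
    count binomial out of abundance with logit probability
    gamma0 + gamma_pos + gamma_tide * flood. Tide is fixed per deployment:
    the first ``n_flood`` ASUs are filmed on flood tide, the rest on ebb.
    """
    rng = np.random.default_rng(params.seed)
    m = params.minutes_per_deployment
    rows = []
    n_flood = params.resolved_n_flood
    for asu in range(params.n_asu):
        tide = "flood" if asu < n_flood else "ebb"
        flood = 1.0 if tide == "flood" else 0.0
        # a smooth tidal-scale velocity trace shared by the ASU's cameras
        vel_phase = rng.uniform(0.0, 2.0 * math.pi)
        minutes = np.arange(m)
        velocity = params.velocity_mean + params.velocity_range * np.sin(
            2.0 * math.pi * minutes / max(m, 2) + vel_phase
        )
        for j, pos in enumerate(CAMERA_POSITIONS):
            latent = _ar1(m, params.phi_ar, params.sigma_ar, rng)
            log_mu = params.beta0 + params.beta_pos[j] + params.beta_tide * flood + latent
            mu = np.exp(log_mu)
            abundance = _draw_counts(mu, params.dispersion, rng)
            eta = params.gamma0 + params.gamma_pos[j] + params.gamma_tide * flood
            p = float(expit(eta))
            watercolumn = rng.binomial(abundance, p)
            for i in range(m):
                rows.append(
                    {
                        "asu_id": asu + 1,
                        "camera_position": pos,
                        "tide": tide,
                        "minute_index": int(minutes[i]),
                        "abundance": int(abundance[i]),
                        "watercolumn_count": int(watercolumn[i]),
                        "velocity": float(velocity[i]),
                        "visibility_ok": True,
                    }
                )
    table = pd.DataFrame(rows)
    assert (table["watercolumn_count"] <= table["abundance"]).all()
    return table
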
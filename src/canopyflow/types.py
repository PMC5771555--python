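"""Shared domain containers.

Velocity containers hold SI units throughout (m s^-1, seconds, Hz);
elevations are centimetres above the seabed (cmab); rotation angles are
degrees; dissipation is m^2 s^-3.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Tuple

import numpy as np

#: Camera positions relative to the tidal current, in canonical order.
CAMERA_POSITIONS: Tuple[str, ...] = (
    "down-current 1 m",
    "down-current edge",
    "up-current edge",
    "up-current 1 m",
)

#: Tidal phases.
TIDES: Tuple[str, ...] = ("flood", "ebb")

#: ADV measurement locations relative to the artificial canopy patch.
LOCATIONS: Tuple[str, ...] = ("A", "B", "C")


def _as_triplet(value) -> Tuple[float, float, float]:
    """Broadcast a scalar to a per-component (u, v, w) triplet."""
    if np.isscalar(value):
        return (float(value),) * 3
    out = tuple(float(x) for x in value)
    if len(out) != 3:
        raise ValueError("expected a scalar or a length-3 sequence")
    return out


@dataclass(frozen=True)
class TurbSimParams:
    """Ground-truth parameters for one synthetic ADV burst.

    Parameters
    ----------
    epsilon : float
        Turbulence kinetic-energy dissipation rate (m^2 s^-3, >= 0).
    mean_speed : float
        Mean streamwise current speed u-bar (m s^-1, >= 0). Must be positive
        whenever ``epsilon`` is, because the frozen-turbulence mapping between
        frequency and wavenumber is otherwise undefined.
    sample_rate, duration : float
        Sampling rate (Hz) and burst length (s); their product must be an
        integer sample count. Defaults follow the 25 Hz x 4 min burst scheme.
    noise_sd : float or (float, float, float)
        Instrument white-noise SD per component (m s^-1). The vertical beam
        geometry of an ADV gives w a markedly lower noise floor, hence the
        anisotropic default.
    spike_rate : float
        Fraction of samples replaced by spikes, in [0, 0.05], per component.
    spike_amplitude : float
        Spike offset in multiples of the component's fluctuation SD (>= 4).
    angles : (float, float, float)
        Sensor misalignment (theta_xy, theta_xz, theta_roll) in degrees.
    wave_amp, wave_freq : float
        Amplitude (m s^-1) and frequency (Hz) of a non-turbulent wave-band
        oscillation added to u; keep ``wave_freq`` below the decomposition
        cutoff so the low-pass mean absorbs it.
    spectrum_floor_hz : float
        Low-frequency truncation of the synthesized turbulence spectrum;
        turbulence and the wave term stay separable across this bound.
    seed : int
        Seed for the burst's random generator.
    """

    epsilon: float = 1e-5
    mean_speed: float = 0.2
    sample_rate: float = 25.0
    duration: float = 240.0
    noise_sd: object = (0.002, 0.002, 0.0005)
    spike_rate: float = 0.005
    spike_amplitude: float = 8.0
    angles: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    wave_amp: float = 0.0
    wave_freq: float = 0.05
    spectrum_floor_hz: float = 0.1
    seed: int = 0

    def __post_init__(self):
        n = self.sample_rate * self.duration
        if abs(n - round(n)) > 1e-9 or round(n) < 2:
            raise ValueError("sample_rate * duration must be an integer sample count >= 2")
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.epsilon > 0 and self.mean_speed <= 0:
            raise ValueError(
                "mean_speed must be positive when epsilon > 0 "
                "(Taylor frozen-turbulence conversion undefined at U = 0)"
            )
        if not 0.0 <= self.spike_rate <= 0.05:
            raise ValueError("spike_rate must lie in [0, 0.05]")
        if self.spike_rate > 0 and self.spike_amplitude < 4:
            raise ValueError("spike_amplitude must be >= 4 fluctuation SDs")
        object.__setattr__(self, "noise_sd", _as_triplet(self.noise_sd))
        object.__setattr__(self, "angles", _as_triplet(self.angles))

    @property
    def n_samples(self) -> int:
        return int(round(self.sample_rate * self.duration))


@dataclass(frozen=True)
class BurstTruth:
    """Ground truth attached to a simulated burst."""

    params: TurbSimParams
    spike_indices: Mapping[str, np.ndarray]


@dataclass
class VelocityBurst:
    """One ADV burst: time base plus the three velocity components.

    u is streamwise (positive down-current), v transverse, w vertical and
    positive away from the seabed.
    """

    t: np.ndarray
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    sample_rate: float
    elevation: Optional[float] = None  # cmab
    location: Optional[str] = None  # in LOCATIONS
    profile_id: Optional[str] = None
    truth: Optional[BurstTruth] = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        for name in ("u", "v", "w"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != self.t.shape:
                raise ValueError(f"component {name} length differs from t")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0) or not np.allclose(dt, 1.0 / self.sample_rate, rtol=1e-6, atol=1e-12):
                raise ValueError("t must increase at a fixed step of 1/sample_rate")
        if self.location is not None and self.location not in LOCATIONS:
            raise ValueError(f"location must be one of {LOCATIONS}")

    def __len__(self) -> int:
        return len(self.t)

    def components(self) -> np.ndarray:
        """Return a (3, n) array of (u, v, w)."""
        return np.vstack([self.u, self.v, self.w])


@dataclass
class DecomposedBurst:
    """Low-pass mean / fluctuation split of a burst, per component.

    ``mean_* + fluct_*`` reconstructs the input exactly by construction.
    """

    t: np.ndarray
    sample_rate: float
    mean_u: np.ndarray
    mean_v: np.ndarray
    mean_w: np.ndarray
    fluct_u: np.ndarray
    fluct_v: np.ndarray
    fluct_w: np.ndarray
    cutoff: float
    elevation: Optional[float] = None
    location: Optional[str] = None
    profile_id: Optional[str] = None
    truth: Optional[BurstTruth] = None

    def total(self, component: str) -> np.ndarray:
        return getattr(self, f"mean_{component}") + getattr(self, f"fluct_{component}")

    def means(self) -> np.ndarray:
        return np.vstack([self.mean_u, self.mean_v, self.mean_w])

    def flucts(self) -> np.ndarray:
        return np.vstack([self.fluct_u, self.fluct_v, self.fluct_w])


@dataclass
class SpikeMask:
    """Outcome of phase-space despiking one series."""

    indices: np.ndarray  # flagged sample indices, sorted
    iterations: int
    replaced_values: np.ndarray  # interpolated values, aligned with indices

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        self.replaced_values = np.asarray(self.replaced_values, dtype=float)
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")

    @property
    def n_spikes(self) -> int:
        return int(self.indices.size)


@dataclass(frozen=True)
class RotationAngles:
    """Streamline-frame rotation angles in degrees.

    theta_xy zeroes the burst-mean transverse velocity, theta_xz then zeroes
    the burst-mean vertical velocity, and theta_cross is the roll about the
    streamwise axis that zeroes the v'w' covariance.
    """

    theta_xy: float
    theta_xz: float
    theta_cross: float
    source_elevations: Optional[Tuple[float, ...]] = None

    def __post_init__(self):
        for name in ("theta_xy", "theta_xz", "theta_cross"):
            val = getattr(self, name)
            if not np.isfinite(val) or abs(val) >= 90.0:
                raise ValueError(f"{name} must be finite with |angle| < 90 degrees")

    def as_tuple(self) -> Tuple[float, float, float]:
        return (self.theta_xy, self.theta_xz, self.theta_cross)


@dataclass
class Spectrum:
    """One-sided spectral density of one velocity component.

    In the frequency domain the abscissa is Hz and density is
    (m^2 s^-2)/Hz; in the wavenumber domain the abscissa is angular
    wavenumber (rad m^-1) and density (m^2 s^-2)/(rad m^-1). ``U`` stores the
    eddy advection speed used for the Taylor conversion.
    """

    abscissa: np.ndarray
    density: np.ndarray
    component: str
    domain: str  # "frequency" | "wavenumber"
    U: Optional[float] = None

    def __post_init__(self):
        self.abscissa = np.asarray(self.abscissa, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.domain not in ("frequency", "wavenumber"):
            raise ValueError("domain must be 'frequency' or 'wavenumber'")
        if self.abscissa.ndim != 1 or self.abscissa.shape != self.density.shape:
            raise ValueError("abscissa and density must be matching 1-d arrays")
        if np.any(self.abscissa <= 0) or np.any(np.diff(self.abscissa) <= 0):
            raise ValueError("abscissa must be strictly increasing and positive")
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        if self.component not in ("u", "v", "w"):
            raise ValueError("component must be one of u, v, w")

    def integrated(self) -> float:
        """Trapezoid integral of the density — the variance it accounts for."""
        return float(np.trapezoid(self.density, self.abscissa))


@dataclass
class DissipationEstimate:
    """Inertial-subrange dissipation estimate for one burst."""

    epsilon: float
    component: str
    fit_band: Tuple[float, float]  # (k_min, k_max), rad m^-1
    alpha1: float
    n_bins_used: int
    goodness: float  # RMS log-residual of the -5/3 fit
    slope: Optional[float] = None  # diagnostic log-log slope
    elevation: Optional[float] = None
    location: Optional[str] = None
    profile_id: Optional[str] = None

    def __post_init__(self):
        if not self.epsilon > 0:
            raise ValueError("epsilon must be positive")
        if not self.fit_band[0] < self.fit_band[1]:
            raise ValueError("fit_band must be an increasing (k_min, k_max) pair")


@dataclass(frozen=True)
class CountSimParams:
    """Ground truth for the behavioural count generator.

    The generator mirrors the field design: ``n_asu`` replicate canopy patches
    each filmed once from the four camera positions, one count per observed
    minute, tide direction fixed within a deployment. Effects are on the log
    scale for abundance and the logit scale for the water-column proportion;
    ``beta_pos``/``gamma_pos`` align with :data:`CAMERA_POSITIONS`.
    """

    n_asu: int = 10
    minutes_per_deployment: int = 23
    beta0: float = float(np.log(5.0))
    beta_pos: Tuple[float, float, float, float] = (0.4, 0.0, -0.4, 0.0)
    beta_tide: float = 0.2
    phi_ar: float = 0.6
    sigma_ar: float = 0.4
    dispersion: float = 2.0
    gamma0: float = -0.5
    gamma_pos: Tuple[float, float, float, float] = (0.3, -0.3, 0.0, 0.8)
    gamma_tide: float = 0.5
    n_flood: Optional[int] = None  # default: ~60% of deployments on flood tide
    velocity_mean: float = 20.0  # cm s^-1, tidal scale of the site
    velocity_range: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if self.n_asu < 1 or self.minutes_per_deployment < 1:
            raise ValueError("n_asu and minutes_per_deployment must be >= 1")
        if not -1.0 < self.phi_ar < 1.0:
            raise ValueError("phi_ar must lie in (-1, 1)")
        if self.sigma_ar < 0:
            raise ValueError("sigma_ar must be >= 0")
        if self.dispersion < 1.0:
            raise ValueError("dispersion (variance inflation) must be >= 1")
        if self.n_flood is not None and not 0 <= self.n_flood <= self.n_asu:
            raise ValueError("n_flood must lie in [0, n_asu]")
        if len(self.beta_pos) != 4 or len(self.gamma_pos) != 4:
            raise ValueError("beta_pos and gamma_pos must have one entry per camera position")

    @property
    def resolved_n_flood(self) -> int:
        if self.n_flood is None:
            return int(round(0.6 * self.n_asu))
        return int(self.n_flood)


@dataclass
class GlmResult:
    """Fitted GLM with its analysis-of-deviance term table.

    ``terms`` columns: term, df, statistic, statistic_type ("F" or "chi2"), p.
    ``contrasts`` is populated by :func:`canopyflow.behaviour_stats.tukey_pairwise`.
    """

    family: str  # "quasipoisson" | "binomial"
    terms: "pd.DataFrame"
    dispersion: float
    coefficients: "pd.DataFrame"
    fit: object  # statsmodels GLMResults of the full model
    design_info: object
    data: "pd.DataFrame"
    test_type: str = "sequential"
    contrasts: Optional["pd.DataFrame"] = None


# Imported late to keep module import light for annotations only.
import pandas as pd  # noqa: E402  (used in annotations above)
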
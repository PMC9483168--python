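"""Phasor transform of TCSPC decay images.

The phasor approach maps each pixel's photon-arrival histogram ``I_k`` to a point

    g = sum_k I_k cos(n w t_k) / sum_k I_k,
    s = sum_k I_k sin(n w t_k) / sum_k I_k,

with ``t_k`` the time-bin centers, ``w = 2 pi f_rep`` the laser angular frequency and
``n`` the harmonic. Mono-exponential decays land on the universal semicircle
``(g - 1/2)^2 + s^2 = 1/4``; mixtures of two species lie on the chord joining the two
pure-species points, which is what makes the free/bound NAD(P)H decomposition a linear
projection downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import AcquisitionConfig
from .errors import CalibrationError, ConfigError, DomainError


@dataclass(frozen=True)
class TCSPCImage:
    """Per-pixel time-binned photon counts with acquisition metadata.

    Attributes
    ----------
    counts : ndarray, shape (rows, cols, K)
        Non-negative integer photon counts per pixel and time bin.
    acquisition : AcquisitionConfig
        Repetition rate, bin count and harmonic; ``K * bin_width`` spans one period.
    true_fraction : ndarray or None
        Ground-truth free-NAD(P)H fraction per pixel, present only for synthetic
        images (used by recovery tests, never by the analysis itself).
    """

    counts: np.ndarray
    acquisition: AcquisitionConfig
    true_fraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 3:
            raise ConfigError("counts must be a (rows, cols, K) array")
        if c.shape[2] != self.acquisition.n_time_bins:
            raise ConfigError(
                f"counts have {c.shape[2]} time bins but acquisition declares "
                f"{self.acquisition.n_time_bins}"
            )
        if not np.issubdtype(c.dtype, np.integer):
            raise ConfigError("counts must be integer-typed")
        if c.size and c.min() < 0:
            raise ConfigError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    @property
    def intensity(self) -> np.ndarray:
        """Per-pixel total photon count."""
        return self.counts.sum(axis=2)


@dataclass(frozen=True)
class PhasorMap:
    """Per-pixel phasor coordinates at one harmonic.

    ``valid_mask`` marks pixels with enough photons for analysis; ``g``/``s`` are
    finite wherever the mask is true and zero elsewhere.
    """

    g: np.ndarray
    s: np.ndarray
    intensity: np.ndarray
    harmonic: int
    omega: float  # fundamental angular frequency, rad/ns
    valid_mask: np.ndarray

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


@dataclass(frozen=True)
class CalibrationReference:
    """Measured phasor of a reference fluorophore with known mono-exponential lifetime."""

    g_measured: float
    s_measured: float
    tau_ref_ns: float

    def __post_init__(self) -> None:
        if self.tau_ref_ns < 0:
            raise DomainError("reference lifetime must be non-negative")
        if np.hypot(self.g_measured, self.s_measured) == 0.0:
            raise CalibrationError("measured reference phasor has zero magnitude")


def bin_centers(acquisition: AcquisitionConfig) -> np.ndarray:
    """Time-bin centers t_k = (k + 1/2) T / K in ns."""
    K = acquisition.n_time_bins
    return (np.arange(K) + 0.5) * (acquisition.period_ns / K)


def theoretical_phasor(
    tau_ns: float, harmonic: int = 1, omega: float | None = None,
    acquisition: AcquisitionConfig | None = None,
) -> tuple[float, float]:
    """Closed-form phasor of a mono-exponential decay.

    For lifetime tau at effective frequency ``n w`` the continuous-time phasor is

        g = 1 / (1 + (n w tau)^2),   s = n w tau / (1 + (n w tau)^2),

    a point on the universal semicircle. This holds exactly for the *wrapped*
    (periodic) exponential as well, which is why it serves as the oracle for the
    simulated decays.
    """
    if tau_ns < 0:
        raise DomainError(f"lifetime must be non-negative, got {tau_ns}")
    if omega is None:
        if acquisition is None:
            raise ConfigError("provide either omega or an acquisition config")
        omega = acquisition.omega
    if harmonic < 1:
        raise ConfigError("harmonic must be a positive integer")
    wt = harmonic * omega * tau_ns
    denom = 1.0 + wt * wt
    return 1.0 / denom, wt / denom


def phasor_transform(image: TCSPCImage, harmonic: int | None = None) -> PhasorMap:
    """Compute per-pixel (g, s) phasor coordinates of a TCSPC image.

    Zero-photon pixels (empty background) are flagged invalid rather than raising;
    their coordinates are set to zero.
    """
    acq = image.acquisition
    if harmonic is None:
        harmonic = acq.harmonic
    if harmonic < 1:
        raise ConfigError("harmonic must be a positive integer")
    if acq.n_time_bins < 2:
        raise ConfigError("phasor transform needs at least 2 time bins")

    t = bin_centers(acq)
    phase = harmonic * acq.omega * t
    counts = image.counts.astype(np.float64)
    intensity = counts.sum(axis=2)

    with np.errstate(invalid="ignore", divide="ignore"):
        g = counts @ np.cos(phase) / intensity
        s = counts @ np.sin(phase) / intensity
    valid = intensity > 0
    g = np.where(valid, g, 0.0)
    s = np.where(valid, s, 0.0)
    return PhasorMap(
        g=g, s=s, intensity=intensity, harmonic=harmonic, omega=acq.omega,
        valid_mask=valid,
    )


def calibrate(pmap: PhasorMap, ref: CalibrationReference) -> PhasorMap:
    """Correct instrument phase/modulation using a reference of known lifetime.

    Phasors are treated as complex numbers ``g + i s``; every pixel is multiplied by
    ``theoretical(tau_ref) / measured_ref``, which rotates and rescales the plot so
    the reference lands on its semicircle position. Intensity and mask are unchanged.
    """
    meas = complex(ref.g_measured, ref.s_measured)
    if abs(meas) == 0.0:
        raise CalibrationError("measured reference phasor has zero magnitude")
    g_th, s_th = theoretical_phasor(ref.tau_ref_ns, pmap.harmonic, pmap.omega)
    factor = complex(g_th, s_th) / meas
    z = (pmap.g + 1j * pmap.s) * factor
    return replace(pmap, g=z.real, s=z.imag)


def apply_threshold(pmap: PhasorMap, min_photons: int) -> PhasorMap:
    """Mark pixels with fewer than ``min_photons`` total photons invalid.

    Coordinates are left untouched; only the validity mask changes.
    """
    if min_photons < 0:
        raise ConfigError("min_photons must be >= 0")
    return replace(pmap, valid_mask=pmap.intensity >= min_photons)


def median_filter_phasor(pmap: PhasorMap, size: int = 3) -> PhasorMap:
    """Optional spatial median filter of g and s (off by default in the pipeline)."""
    from scipy.ndimage import median_filter

    return replace(
        pmap,
        g=median_filter(pmap.g, size=size),
        s=median_filter(pmap.s, size=size),
    )
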
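"""Synthetic TCSPC FLIM experiments with known free/bound NAD(P)H composition.

The generator emulates the statistical structure the drug-response scoring relies on:

* per-pixel decays are intensity-weighted mixtures of two wrapped (periodic)
  exponentials — the free (short-lifetime) and enzyme-bound (long-lifetime)
  NAD(P)H species — with Poisson photon noise;
* replicate images of one arm vary around an arm-level mean free fraction
  (``replicate_sd``), and pixels within a replicate vary around the replicate
  mean (``pixel_sd``), mirroring the 6-12 repeated acquisitions per arm;
* a responsive treated arm has a *lower* mean free fraction than its control,
  i.e. a shift toward bound NAD(P)H / oxidative metabolism.

Photon sampling uses the Poissonization identity: a Poisson-distributed total count
with i.i.d. arrival times from the mixture density is distributionally identical to
independent Poisson counts per time bin with mean ``N * p_k``, where ``p_k`` is the
exact bin-integrated mixture probability. Bins are sampled directly.

Every image carries its ground-truth fraction field (``TCSPCImage.true_fraction``)
so recovery accuracy can be measured; the analysis pipeline never reads it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .config import TIMEPOINTS, AcquisitionConfig, ComponentPair
from .errors import ConfigError, DomainError
from .phasor import TCSPCImage


def wrapped_exponential_bin_probabilities(
    tau_ns: float, acquisition: AcquisitionConfig
) -> np.ndarray:
    """Exact per-bin probabilities of a wrapped exponential decay on [0, T).

    The wrapped density is ``exp(-t/tau) / (tau (1 - exp(-T/tau)))``; integrating
    over bin ``[a, b)`` gives ``(exp(-a/tau) - exp(-b/tau)) / (1 - exp(-T/tau))``.
    The wrapped form preserves the closed-form semicircle phasor of the species,
    which is what makes the simulator checkable against ``theoretical_phasor``.
    """
    if tau_ns <= 0:
        raise DomainError("lifetime must be strictly positive")
    T = acquisition.period_ns
    edges = np.linspace(0.0, T, acquisition.n_time_bins + 1)
    cdf = -np.expm1(-edges / tau_ns)  # 1 - exp(-t/tau), numerically stable
    p = np.diff(cdf) / cdf[-1]
    return p


def mixture_bin_probabilities(
    f_free: float, components: ComponentPair, acquisition: AcquisitionConfig
) -> np.ndarray:
    """Per-bin probabilities of the two-species mixture at free fraction ``f_free``."""
    if not np.isfinite(f_free) or not 0.0 <= f_free <= 1.0:
        raise DomainError(f"free fraction must be a finite value in [0, 1], got {f_free}")
    p_free = wrapped_exponential_bin_probabilities(components.tau_free, acquisition)
    p_bound = wrapped_exponential_bin_probabilities(components.tau_bound, acquisition)
    return f_free * p_free + (1.0 - f_free) * p_bound


def _gaussian_irf_kernel(acquisition: AcquisitionConfig, t0_ns: float, sigma_ns: float) -> np.ndarray:
    """Discretized wrapped-Gaussian IRF, circularly convolved with decay probabilities."""
    t = (np.arange(acquisition.n_time_bins) + 0.5) * acquisition.bin_width_ns
    T = acquisition.period_ns
    # wrap a few periods so the kernel is periodic on [0, T)
    k = np.zeros_like(t)
    for m in (-1, 0, 1):
        k += np.exp(-0.5 * ((t - t0_ns + m * T) / sigma_ns) ** 2)
    return k / k.sum()


def apply_irf(probabilities: np.ndarray, acquisition: AcquisitionConfig,
              t0_ns: float, sigma_ns: float) -> np.ndarray:
    """Circularly convolve bin probabilities with a Gaussian instrument response.

    Optional; used only to exercise phasor calibration. The default pipeline
    simulates an ideal (delta) IRF.
    """
    if sigma_ns <= 0:
        raise ConfigError("IRF width must be positive")
    kernel = _gaussian_irf_kernel(acquisition, t0_ns, sigma_ns)
    out = np.fft.irfft(np.fft.rfft(probabilities) * np.fft.rfft(kernel),
                       n=probabilities.shape[-1])
    return np.clip(out, 0.0, None)


def simulate_pixel_decay(
    f_free: float,
    components: ComponentPair,
    photons: float,
    acquisition: AcquisitionConfig,
    seed: int | np.random.Generator | None = None,
    irf: tuple[float, float] | None = None,
) -> np.ndarray:
    """Simulate one pixel's time-binned photon histogram.

    Parameters
    ----------
    f_free : float in [0, 1]
        Intensity fraction contributed by the free species.
    photons : float
        Expected total photon count; the realized total is Poisson-distributed.
    seed : int, Generator or None
        Fixed seed gives bitwise-identical output.
    irf : (t0_ns, sigma_ns), optional
        Gaussian instrument-response shift/broadening (calibration exercises only).
    """
    if photons < 0:
        raise DomainError("expected photon count must be >= 0")
    if acquisition.n_time_bins < 1:
        raise ConfigError("need at least one time bin")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = mixture_bin_probabilities(f_free, components, acquisition)
    if irf is not None:
        p = apply_irf(p, acquisition, *irf)
    return rng.poisson(photons * p).astype(np.int64)


@dataclass(frozen=True)
class SimArmSpec:
    """Generative specification of one experimental arm (control or treated).

    ``mean_free_fraction`` is the arm-level mean free-NAD(P)H intensity fraction;
    replicate means scatter around it with ``replicate_sd`` and pixels scatter
    around their replicate mean with ``pixel_sd`` (Gaussian, clamped to [0, 1]).
    """

    mean_free_fraction: float
    pixel_sd: float = 0.1
    replicate_sd: float = 0.02
    n_replicates: int = 8
    image_shape: tuple[int, int] = (32, 32)
    photons_per_pixel: float = 5000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_free_fraction <= 1.0:
            raise DomainError("mean_free_fraction must lie in [0, 1]")
        if self.pixel_sd < 0 or self.replicate_sd < 0:
            raise ConfigError("spread parameters must be >= 0")
        if self.n_replicates < 2:
            raise ConfigError("need at least 2 replicates per arm")
        if min(self.image_shape) < 1:
            raise ConfigError("image_shape must have at least one pixel per axis")
        if self.photons_per_pixel < 0:
            raise DomainError("photons_per_pixel must be >= 0")


@dataclass(frozen=True)
class SimExperimentSpec:
    """Full multi-timepoint experiment: one control spec, one treated spec per timepoint."""

    control: SimArmSpec
    treated: Mapping[str, SimArmSpec]
    components: ComponentPair = field(default_factory=ComponentPair)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)

    def __post_init__(self) -> None:
        if set(self.treated) != set(TIMEPOINTS):
            missing = set(TIMEPOINTS) - set(self.treated)
            extra = set(self.treated) - set(TIMEPOINTS)
            raise ConfigError(
                f"treated arms must cover exactly {TIMEPOINTS}; "
                f"missing {sorted(missing)}, unknown {sorted(extra)}"
            )
        if self.acquisition.n_time_bins < 64:
            raise ConfigError("experiment simulation requires at least 64 time bins")


@dataclass(frozen=True)
class SimulatedExperiment:
    """Bundle of simulated replicate images, directly consumable by the scorer."""

    timepoints: dict[str, tuple[list[TCSPCImage], list[TCSPCImage]]]
    spec: SimExperimentSpec

    def arms(self, timepoint: str) -> tuple[list[TCSPCImage], list[TCSPCImage]]:
        """(control images, treated images) for one timepoint label."""
        return self.timepoints[timepoint]


def simulate_replicate_image(
    arm: SimArmSpec,
    components: ComponentPair,
    acquisition: AcquisitionConfig,
    rng: np.random.Generator | None = None,
) -> TCSPCImage:
    """Simulate a single replicate image of an arm.

    A replicate-level mean fraction is drawn first, then per-pixel fractions around
    it; the ground-truth fraction field is retained on the returned image.
    """
    if rng is None:
        rng = np.random.default_rng(arm.seed)
    rep_mean = rng.normal(arm.mean_free_fraction, arm.replicate_sd)
    fractions = rng.normal(rep_mean, arm.pixel_sd, size=arm.image_shape)
    fractions = np.clip(fractions, 0.0, 1.0)

    p_free = wrapped_exponential_bin_probabilities(components.tau_free, acquisition)
    p_bound = wrapped_exponential_bin_probabilities(components.tau_bound, acquisition)
    flat = fractions.reshape(-1, 1)
    means = arm.photons_per_pixel * (flat * p_free + (1.0 - flat) * p_bound)
    counts = rng.poisson(means).astype(np.int64)
    counts = counts.reshape(*arm.image_shape, acquisition.n_time_bins)
    return TCSPCImage(counts=counts, acquisition=acquisition, true_fraction=fractions)


def simulate_arm(
    arm: SimArmSpec,
    components: ComponentPair,
    acquisition: AcquisitionConfig,
    seed_seq: np.random.SeedSequence | None = None,
) -> list[TCSPCImage]:
    """Simulate all ``n_replicates`` images of one arm, reproducibly under its seed."""
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(arm.seed)
    children = seed_seq.spawn(arm.n_replicates)
    return [
        simulate_replicate_image(arm, components, acquisition, np.random.default_rng(c))
        for c in children
    ]


def simulate_experiment(spec: SimExperimentSpec) -> SimulatedExperiment:
    """Simulate control and treated replicate sets for all three timepoints.

    Control acquisitions are re-simulated at every timepoint from the single control
    spec (fresh replicates, as in repeated imaging sessions). Fully deterministic
    under the arm seeds.
    """
    timepoints: dict[str, tuple[list[TCSPCImage], list[TCSPCImage]]] = {}
    for tp_idx, tp in enumerate(TIMEPOINTS):
        treated_arm = spec.treated[tp]
        ctrl_ss = np.random.SeedSequence([spec.control.seed, tp_idx, 0])
        trt_ss = np.random.SeedSequence([treated_arm.seed, tp_idx, 1])
        controls = simulate_arm(spec.control, spec.components, spec.acquisition, ctrl_ss)
        treateds = simulate_arm(treated_arm, spec.components, spec.acquisition, trt_ss)
        timepoints[tp] = (controls, treateds)
    return SimulatedExperiment(timepoints=timepoints, spec=spec)


def shifted_experiment_spec(
    base_free_fraction: float = 0.6,
    shift: float = 0.0,
    *,
    pixel_sd: float = 0.1,
    replicate_sd: float = 0.02,
    n_replicates: int = 8,
    image_shape: tuple[int, int] = (32, 32),
    photons_per_pixel: float = 5000.0,
    seed: int = 0,
    components: ComponentPair | None = None,
    acquisition: AcquisitionConfig | None = None,
    shifts_by_timepoint: Mapping[str, float] | None = None,
) -> SimExperimentSpec:
    """Convenience builder: control at ``base_free_fraction``, treated shifted toward bound.

    ``shift`` (or per-timepoint ``shifts_by_timepoint``) is subtracted from the
    control mean free fraction; a positive shift emulates a responsive tumor.
    """
    shifts = dict(shifts_by_timepoint) if shifts_by_timepoint else {t: shift for t in TIMEPOINTS}
    common = dict(
        pixel_sd=pixel_sd, replicate_sd=replicate_sd, n_replicates=n_replicates,
        image_shape=image_shape, photons_per_pixel=photons_per_pixel,
    )
    control = SimArmSpec(mean_free_fraction=base_free_fraction, seed=seed, **common)
    treated = {
        tp: SimArmSpec(
            mean_free_fraction=float(np.clip(base_free_fraction - shifts.get(tp, 0.0), 0, 1)),
            seed=seed + 1 + i,
            **common,
        )
        for i, tp in enumerate(TIMEPOINTS)
    }
    return SimExperimentSpec(
        control=control, treated=treated,
        components=components or ComponentPair(),
        acquisition=acquisition or AcquisitionConfig(),
    )
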
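"""Run configuration: every numeric constant the pipeline uses, in one serializable object.

The defaults encode the assay's published procedure (125 curve segments, per-segment
Student's t-test at alpha = 0.05, timepoint weights 1/2/3 for 24/48/72 h, responder-class
boundaries at 5/20/50 %DR) together with acquisition and fluorophore parameters that are
instrument-dependent and therefore configurable (repetition rate, time-bin count,
NAD(P)H component lifetimes).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import IO, Any

import yaml

from .errors import ConfigError

#: Supported treatment timepoint labels, in chronological order.
TIMEPOINTS: tuple[str, ...] = ("24h", "48h", "72h")

#: Timepoint weights for the final weighted-average %DR. 72 h carries the most
#: weight because it is the standard time at which cells reach metabolic adaptation.
DEFAULT_WEIGHTS: dict[str, float] = {"24h": 1.0, "48h": 2.0, "72h": 3.0}

#: Responder classes in order of increasing response.
RESPONDER_CLASSES: tuple[str, ...] = ("NR", "LR", "MR", "HR")


@dataclass(frozen=True)
class ComponentPair:
    """Lifetimes (ns) of the two NAD(P)H species.

    Free NAD(P)H is the short-lifetime species, enzyme-bound the long-lifetime one.
    Defaults are common literature values for free / enzyme-bound NAD(P)H.
    """

    tau_free: float = 0.4
    tau_bound: float = 3.4

    def __post_init__(self) -> None:
        if not (self.tau_free > 0 and self.tau_bound > 0):
            raise ConfigError("component lifetimes must be strictly positive")
        if not self.tau_bound > self.tau_free:
            raise ConfigError(
                f"tau_bound ({self.tau_bound} ns) must exceed tau_free ({self.tau_free} ns)"
            )


@dataclass(frozen=True)
class AcquisitionConfig:
    """Pulsed-laser acquisition parameters.

    Attributes
    ----------
    repetition_rate_mhz : float
        Laser repetition rate in MHz; the laser period is ``T = 1e3 / rate`` ns.
    n_time_bins : int
        Number K of TCSPC time bins spanning one laser period.
    harmonic : int
        Harmonic of the repetition frequency at which phasors are computed.
    """

    repetition_rate_mhz: float = 80.0
    n_time_bins: int = 256
    harmonic: int = 1

    def __post_init__(self) -> None:
        if self.repetition_rate_mhz <= 0:
            raise ConfigError("repetition rate must be positive")
        if self.n_time_bins < 1:
            raise ConfigError("need at least one time bin")
        if self.harmonic < 1:
            raise ConfigError("harmonic must be a positive integer")

    @property
    def period_ns(self) -> float:
        """Laser period T in ns."""
        return 1e3 / self.repetition_rate_mhz

    @property
    def bin_width_ns(self) -> float:
        return self.period_ns / self.n_time_bins

    @property
    def omega(self) -> float:
        """Fundamental angular frequency in rad/ns."""
        return 2.0 * 3.141592653589793 * self.repetition_rate_mhz * 1e-3


@dataclass(frozen=True)
class AnalysisConfig:
    """Scoring parameters: thresholds, segmentation, test level, weights, class bounds."""

    min_photons: int = 50
    n_bins: int = 125
    alpha: float = 0.05
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    class_thresholds: tuple[float, float, float] = (5.0, 20.0, 50.0)
    fdr_correction: bool = False
    median_filter: bool = False

    def __post_init__(self) -> None:
        if self.min_photons < 0:
            raise ConfigError("min_photons must be >= 0")
        if self.n_bins < 1:
            raise ConfigError("n_bins must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must lie in (0, 1)")
        t = self.class_thresholds
        if not (0 < t[0] < t[1] < t[2] <= 100):
            raise ConfigError("class thresholds must be strictly increasing in (0, 100]")
        if any(w <= 0 for w in self.weights.values()):
            raise ConfigError("timepoint weights must be positive")
        unknown = set(self.weights) - set(TIMEPOINTS)
        if unknown:
            raise ConfigError(f"unknown timepoint labels in weights: {sorted(unknown)}")


@dataclass(frozen=True)
class RunConfig:
    """Complete pipeline configuration."""

    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    components: ComponentPair = field(default_factory=ComponentPair)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["analysis"]["class_thresholds"] = list(self.analysis.class_thresholds)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        try:
            analysis = dict(d.get("analysis", {}))
            if "class_thresholds" in analysis:
                analysis["class_thresholds"] = tuple(analysis["class_thresholds"])
            return cls(
                acquisition=AcquisitionConfig(**d.get("acquisition", {})),
                components=ComponentPair(**d.get("components", {})),
                analysis=AnalysisConfig(**analysis),
                seed=int(d.get("seed", 0)),
            )
        except TypeError as exc:  # unknown keys
            raise ConfigError(str(exc)) from exc

    def dump(self, stream: IO[str]) -> None:
        yaml.safe_dump(self.to_dict(), stream, sort_keys=True)

    @classmethod
    def load(cls, stream: IO[str]) -> "RunConfig":
        data = yaml.safe_load(stream)
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)
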
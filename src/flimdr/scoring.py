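"""Drug-response scoring: per-segment t-tests, %DR, weighted final score, classes.

For one timepoint the treated and control arms each contribute 6-12 replicate
fractional distribution curves. Each of the (default 125) curve segments is compared
across arms with a two-sided two-sample Student's t-test (pooled variance) on the
replicate heights; segments with p < alpha are significant. No multiple-testing
correction is applied by default — each segment is reported at its nominal level —
though Benjamini-Hochberg can be switched on for exploratory use.

The percentage of drug response is computed on the TREATED mean curve only:

    %DR = 100 * (mass in significant segments) / (total curve mass),

the unit segment base cancelling from numerator and denominator. Per-timepoint %DR
values are combined as a weighted average (weights 1/2/3 for 24/48/72 h; 72 h
dominates because it is the standard time of metabolic adaptation) and the final
value is stratified into Non/Low/Medium/High Responder at 5/20/50.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import TIMEPOINTS, AnalysisConfig, RunConfig
from .errors import (
    ConfigError,
    DomainError,
    EmptyImageError,
    InsufficientReplicatesError,
)
from .fractions import (
    FractionalDistribution,
    ReplicateCurves,
    build_distribution,
    free_fraction_map,
    mean_distribution,
)
from .phasor import (
    CalibrationReference,
    TCSPCImage,
    apply_threshold,
    calibrate,
    median_filter_phasor,
    phasor_transform,
    theoretical_phasor,
)


@dataclass(frozen=True)
class TimepointScore:
    """Per-segment statistics and %DR for one control-vs-treated comparison."""

    timepoint: str
    p_values: np.ndarray
    significant_mask: np.ndarray
    pct_dr: float
    n_control: int
    n_treated: int
    control_curves: ReplicateCurves | None = None
    treated_curves: ReplicateCurves | None = None


@dataclass(frozen=True)
class CaseAssessment:
    """Final weighted %DR and responder annotation for one case."""

    pct_dr_by_timepoint: dict[str, float]
    weights: dict[str, float]
    final_pct_dr: float
    responder_class: str
    responder_binary: str


def per_bin_ttest(
    control: np.ndarray, treated: np.ndarray, alpha: float = 0.05,
    fdr_correction: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided pooled-variance t-test of each curve segment across replicates.

    Parameters
    ----------
    control, treated : ndarray, shape (n_replicates, n_bins)
        Per-replicate segment heights for each arm.

    Returns
    -------
    p_values, significant_mask
        Degenerate segments (zero variance in both arms) get p = 1 when the arm
        means agree and p = 0 when they differ, the limits of the t-statistic.
    """
    control = np.atleast_2d(np.asarray(control, dtype=float))
    treated = np.atleast_2d(np.asarray(treated, dtype=float))
    if control.shape[0] < 2 or treated.shape[0] < 2:
        raise InsufficientReplicatesError(
            f"need >= 2 replicates per arm, got {control.shape[0]} control "
            f"and {treated.shape[0]} treated"
        )
    if control.shape[1] != treated.shape[1]:
        raise ConfigError("control and treated have different segment counts")

    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(control, treated, axis=0, equal_var=True)
        p = np.asarray(res.pvalue, dtype=float)

    # degenerate = every replicate identical within each arm (exact constancy,
    # robust to float fuzz in the variance)
    degenerate = (control == control[0]).all(axis=0) & (treated == treated[0]).all(axis=0)
    equal_means = control[0] == treated[0]
    p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
    p = np.where(np.isnan(p), 1.0, p)

    if fdr_correction:
        from statsmodels.stats.multitest import multipletests

        _, p, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p, p < alpha


def percent_dr(treated_mean: FractionalDistribution, significant_mask: np.ndarray) -> float:
    """%DR = 100 * significant-area / total-area of the treated mean curve."""
    mask = np.asarray(significant_mask, dtype=bool)
    if mask.shape[0] != treated_mean.n_bins:
        raise ConfigError("significance mask length does not match segment count")
    total = float(treated_mean.heights.sum())
    if total == 0.0:
        raise EmptyImageError("treated mean curve has zero total area")
    return 100.0 * float(treated_mean.heights[mask].sum()) / total


def weighted_final(pct_dr_by_timepoint: dict[str, float],
                   weights: dict[str, float] | None = None) -> float:
    """Weighted average of per-timepoint %DR values.

    Missing timepoints drop out of both numerator and denominator; the 72 h value
    must be present (it anchors the assessment).
    """
    if not pct_dr_by_timepoint:
        raise ConfigError("no timepoint %DR values supplied")
    unknown = set(pct_dr_by_timepoint) - set(TIMEPOINTS)
    if unknown:
        raise ConfigError(f"unknown timepoint labels: {sorted(unknown)}")
    if "72h" not in pct_dr_by_timepoint:
        raise ConfigError("the 72h %DR is required for the final score")
    if weights is None:
        weights = {"24h": 1.0, "48h": 2.0, "72h": 3.0}
    num = sum(weights[t] * v for t, v in pct_dr_by_timepoint.items())
    den = sum(weights[t] for t in pct_dr_by_timepoint)
    return num / den


def stratify(final_pct_dr: float,
             thresholds: tuple[float, float, float] = (5.0, 20.0, 50.0)) -> tuple[str, str]:
    """Map a final %DR to (responder class, binary annotation).

    NR: %DR < 5; LR: 5 <= %DR < 20; MR: 20 <= %DR < 50; HR: %DR >= 50.
    Binary annotation is Non-Resp for NR and Resp otherwise.
    """
    if not np.isfinite(final_pct_dr) or not 0.0 <= final_pct_dr <= 100.0:
        raise DomainError(f"final %DR must lie in [0, 100], got {final_pct_dr}")
    t1, t2, t3 = thresholds
    if final_pct_dr < t1:
        cls = "NR"
    elif final_pct_dr < t2:
        cls = "LR"
    elif final_pct_dr < t3:
        cls = "MR"
    else:
        cls = "HR"
    return cls, ("Non-Resp" if cls == "NR" else "Resp")


def _arm_curves(
    images: list[TCSPCImage],
    config: RunConfig,
    calibration: CalibrationReference | None = None,
) -> ReplicateCurves:
    """Phasor -> threshold -> (calibrate) -> fraction -> distribution per replicate, then average."""
    acq = config.acquisition
    an = config.analysis
    free_ref = theoretical_phasor(config.components.tau_free, acq.harmonic, acq.omega)
    bound_ref = theoretical_phasor(config.components.tau_bound, acq.harmonic, acq.omega)
    curves = []
    for img in images:
        pmap = phasor_transform(img, acq.harmonic)
        pmap = apply_threshold(pmap, an.min_photons)
        if calibration is not None:
            pmap = calibrate(pmap, calibration)
        if an.median_filter:
            pmap = median_filter_phasor(pmap)
        fimg = free_fraction_map(pmap, free_ref, bound_ref)
        curves.append(build_distribution(fimg, an.n_bins))
    return mean_distribution(curves)


def score_timepoint(
    control_images: list[TCSPCImage],
    treated_images: list[TCSPCImage],
    config: RunConfig,
    timepoint: str = "72h",
    calibration: CalibrationReference | None = None,
) -> TimepointScore:
    """Full comparison of one timepoint's control vs treated replicate images."""
    if timepoint not in TIMEPOINTS:
        raise ConfigError(f"unknown timepoint label {timepoint!r}")
    if len(control_images) < 2 or len(treated_images) < 2:
        raise InsufficientReplicatesError("need >= 2 replicate images per arm")
    control = _arm_curves(control_images, config, calibration)
    treated = _arm_curves(treated_images, config, calibration)
    p, sig = per_bin_ttest(
        control.replicate_heights, treated.replicate_heights,
        alpha=config.analysis.alpha, fdr_correction=config.analysis.fdr_correction,
    )
    pct = percent_dr(treated.mean, sig)
    return TimepointScore(
        timepoint=timepoint, p_values=p, significant_mask=sig, pct_dr=pct,
        n_control=len(control_images), n_treated=len(treated_images),
        control_curves=control, treated_curves=treated,
    )


def assess_case(scores: list[TimepointScore], config: RunConfig | None = None) -> CaseAssessment:
    """Combine per-timepoint scores into the final weighted %DR and responder class."""
    if not scores:
        raise ConfigError("no timepoint scores supplied")
    labels = [s.timepoint for s in scores]
    if len(set(labels)) != len(labels):
        raise ConfigError(f"duplicate timepoint labels: {labels}")
    analysis = config.analysis if config is not None else AnalysisConfig()
    by_tp = {s.timepoint: s.pct_dr for s in scores}
    final = weighted_final(by_tp, analysis.weights)
    cls, binary = stratify(final, analysis.class_thresholds)
    return CaseAssessment(
        pct_dr_by_timepoint=by_tp,
        weights={t: analysis.weights[t] for t in by_tp},
        final_pct_dr=final,
        responder_class=cls,
        responder_binary=binary,
    )
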
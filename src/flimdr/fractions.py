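"""Free/bound NAD(P)H fraction maps and fractional distribution curves.

A pixel's phasor is projected orthogonally onto the chord joining the pure-free and
pure-bound reference phasors; the projection parameter is the fractional intensity
of free NAD(P)H (1 at the free endpoint, 0 at the bound endpoint), clamped to [0, 1]
since photon noise scatters phasors symmetrically off the chord.

Each image is then summarized as a normalized histogram of its valid pixels' free
fractions over (by default) 125 uniform segments of [0, 1] — the fractional
distribution curve. Low bins = bound-rich / oxidative metabolism; a treated curve
shifting toward lower bins is the responsive drug signature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, EmptyImageError, InsufficientReplicatesError
from .phasor import PhasorMap


@dataclass(frozen=True)
class FractionImage:
    """Per-pixel free-NAD(P)H fractional intensity in [0, 1], with validity mask."""

    f_free: np.ndarray
    valid_mask: np.ndarray


@dataclass(frozen=True)
class FractionalDistribution:
    """Normalized histogram of per-pixel free fraction for one image.

    ``heights`` sum to 1 over the ``n_bins`` uniform segments of [0, 1];
    segments are half-open except the last, which includes f = 1.
    """

    heights: np.ndarray
    bin_edges: np.ndarray
    n_pixels: int

    @property
    def n_bins(self) -> int:
        return len(self.heights)

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mean_fraction(self) -> float:
        """Mass-weighted mean free fraction of the curve."""
        return float(np.dot(self.heights, self.bin_centers))


def free_fraction_map(
    pmap: PhasorMap,
    free_ref: tuple[float, float],
    bound_ref: tuple[float, float],
) -> FractionImage:
    """Project each valid pixel's phasor onto the free-bound chord.

    ``f_free = <P - P_bound, P_free - P_bound> / |P_free - P_bound|^2``, clamped.
    """
    pf = np.asarray(free_ref, dtype=float)
    pb = np.asarray(bound_ref, dtype=float)
    chord = pf - pb
    norm2 = float(chord @ chord)
    if norm2 == 0.0:
        raise ConfigError("free and bound reference phasors coincide")
    t = ((pmap.g - pb[0]) * chord[0] + (pmap.s - pb[1]) * chord[1]) / norm2
    f = np.clip(np.where(pmap.valid_mask, t, 0.0), 0.0, 1.0)
    return FractionImage(f_free=f, valid_mask=pmap.valid_mask)


def build_distribution(fimg: FractionImage, n_bins: int = 125) -> FractionalDistribution:
    """Histogram the valid pixels' free fractions into ``n_bins`` uniform segments.

    Heights are normalized to unit total mass, so downstream curve areas are mass
    fractions. Raises if no pixel is valid (e.g. everything below the photon
    threshold).
    """
    if n_bins < 1:
        raise ConfigError("n_bins must be >= 1")
    values = fimg.f_free[fimg.valid_mask]
    if values.size == 0:
        raise EmptyImageError("no valid pixels to histogram")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # np.histogram uses half-open bins with the last bin closed, matching the
    # conservation requirement that f = 1 is counted.
    counts, _ = np.histogram(values, bins=edges)
    return FractionalDistribution(
        heights=counts / values.size, bin_edges=edges, n_pixels=int(values.size)
    )


@dataclass(frozen=True)
class ReplicateCurves:
    """Mean curve, per-bin sample SD, and the stacked per-replicate heights."""

    mean: FractionalDistribution
    sd: np.ndarray
    replicate_heights: np.ndarray  # (n_replicates, n_bins)

    @property
    def n_replicates(self) -> int:
        return self.replicate_heights.shape[0]


def mean_distribution(replicates: list[FractionalDistribution]) -> ReplicateCurves:
    """Average replicate distribution curves bin-by-bin.

    Returns the arithmetic mean curve, per-bin sample standard deviation (ddof=1)
    and the per-replicate height matrix the t-test consumes.
    """
    if len(replicates) < 2:
        raise InsufficientReplicatesError(
            f"need at least 2 replicate curves, got {len(replicates)}"
        )
    n_bins = replicates[0].n_bins
    if any(r.n_bins != n_bins for r in replicates):
        raise ConfigError("replicate curves have mismatched bin counts")
    if any(not np.array_equal(r.bin_edges, replicates[0].bin_edges) for r in replicates):
        raise ConfigError("replicate curves have mismatched bin edges")
    heights = np.stack([r.heights for r in replicates])
    mean = FractionalDistribution(
        heights=heights.mean(axis=0),
        bin_edges=replicates[0].bin_edges.copy(),
        n_pixels=int(sum(r.n_pixels for r in replicates)),
    )
    return ReplicateCurves(
        mean=mean, sd=heights.std(axis=0, ddof=1), replicate_heights=heights
    )
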
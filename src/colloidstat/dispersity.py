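"""Size-distribution statistics: number- vs intensity-weighted means,
DLS-style z-average and PDI, NTA-style D10/D50/D90 and Span.

Number weighting reflects particle counting (NTA); intensity weighting uses
the Rayleigh d⁶ proxy for scattered light (DLS).  The PDI is computed from
cumulant-style moments of the decay-rate distribution (Γ ∝ 1/d) under
intensity weights, which is exact in the no-noise limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

PDI_MONODISPERSE_LIMIT = 0.2
SPAN_MONODISPERSE_LIMIT = 1.0


@dataclass(frozen=True)
class SizeDistributionSummary:
    mean_number_weighted: float
    mean_intensity_weighted: float
    z_average: float
    d10: float
    d50: float
    d90: float
    pdi: float
    span: float


def _as_arrays(diameters, weights=None):
    d = np.asarray(diameters, dtype=float)
    if d.size == 0:
        raise ValueError("empty population")
    if np.any(d <= 0):
        raise ValueError("diameters must be > 0")
    if weights is None:
        w = np.ones_like(d)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != d.shape or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("invalid weights")
    return d, w


def weighted_percentiles(
    diameters: Sequence[float],
    quantiles: Sequence[float],
    weights: Sequence[float] | None = None,
) -> np.ndarray:
    """Percentiles of the number-weighted cumulative diameter distribution.

    Linear interpolation between adjacent ranked values; ties broken by
    stable ordering.
    """
    d, w = _as_arrays(diameters, weights)
    q = np.asarray(quantiles, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("quantiles must lie in (0, 1)")
    order = np.argsort(d, kind="stable")
    d, w = d[order], w[order]
    cw = np.cumsum(w)
    # midpoint convention: each ranked particle sits at the centre of its mass
    grid = (cw - 0.5 * w) / cw[-1]
    return np.interp(q, grid, d)


def span(d10: float, d50: float, d90: float) -> float:
    """Distribution width (D90 − D10)/D50; 0 for a monodisperse sample."""
    if d50 <= 0:
        raise ValueError("d50 must be > 0")
    if d10 > d90:
        raise ValueError("d10 must not exceed d90")
    return (d90 - d10) / d50


def intensity_weights(diameters: Sequence[float]) -> np.ndarray:
    """Rayleigh scattering weights ∝ d⁶, normalised to sum to 1."""
    d = np.asarray(diameters, dtype=float)
    if d.size == 0 or np.any(d <= 0):
        raise ValueError("diameters must be a non-empty positive array")
    w = (d / d.max()) ** 6  # scale before the 6th power to avoid overflow
    return w / w.sum()


def number_weighted_mean(diameters, weights=None) -> float:
    d, w = _as_arrays(diameters, weights)
    return float(np.average(d, weights=w))


def intensity_weighted_mean(diameters, weights=None) -> float:
    d, w = _as_arrays(diameters, weights)
    iw = w * (d / d.max()) ** 6
    return float(np.average(d, weights=iw))


def z_average_and_pdi(diameters, weights=None) -> tuple[float, float]:
    """DLS cumulant-style z-average and polydispersity index.

    z-average = Σnᵢdᵢ⁶ / Σnᵢdᵢ⁵ (intensity-weighted harmonic-style mean).
    PDI = μ₂/Γ̄² with decay rate Γᵢ ∝ 1/dᵢ averaged under intensity
    weights nᵢdᵢ⁶; zero iff the sample is monodisperse.
    """
    d, w = _as_arrays(diameters, weights)
    s = d / d.max()
    iw = w * s**6
    iw = iw / iw.sum()
    z = 1.0 / np.average(1.0 / d, weights=iw)
    gamma = 1.0 / d  # decay rate up to a positive constant; PDI is scale-free
    gbar = np.average(gamma, weights=iw)
    mu2 = np.average((gamma - gbar) ** 2, weights=iw)
    return float(z), float(mu2 / gbar**2)


def classify_dispersity(pdi: float, span_value: float) -> str:
    """``"monodisperse"`` iff PDI < 0.2 and Span < 1, else ``"polydisperse"``."""
    if pdi < 0 or span_value < 0:
        raise ValueError("pdi and span must be >= 0")
    if pdi < PDI_MONODISPERSE_LIMIT and span_value < SPAN_MONODISPERSE_LIMIT:
        return "monodisperse"
    return "polydisperse"


def summarize(diameters, weights=None) -> SizeDistributionSummary:
    """All size statistics for one particle population."""
    d10, d50, d90 = weighted_percentiles(diameters, [0.1, 0.5, 0.9], weights)
    z, pdi = z_average_and_pdi(diameters, weights)
    return SizeDistributionSummary(
        mean_number_weighted=number_weighted_mean(diameters, weights),
        mean_intensity_weighted=intensity_weighted_mean(diameters, weights),
        z_average=z,
        d10=float(d10),
        d50=float(d50),
        d90=float(d90),
        pdi=pdi,
        span=span(float(d10), float(d50), float(d90)),
    )
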
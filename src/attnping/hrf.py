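"""Canonical double-gamma hemodynamic response function.

The HRF links a (brief) neural event to the BOLD time course it evokes.
The double-gamma form has a positive response peaking ~6 s after the event
and a smaller, later undershoot; it is the standard shape used by SPM-style
analysis packages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import gamma as _gamma_dist


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF parameters (all in seconds unless noted).

    peak_delay / undershoot_delay are the gamma shape parameters of the
    positive lobe and the undershoot; dispersions are their scales;
    undershoot_ratio is the peak/undershoot amplitude ratio (1/6 gives the
    familiar mild undershoot). duration bounds the kernel support.
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0


def hrf_kernel(tr: float, params: HRFParams | None = None, oversample: int = 1) -> np.ndarray:
    """Sample the double-gamma HRF on a TR grid, normalized to unit peak.

    Parameters
    ----------
    tr : sampling interval in seconds (must be positive).
    params : HRF shape parameters; defaults are the canonical ones.
    oversample : internal oversampling factor (kept for API symmetry;
        sampling is at the volume grid for this package's use).
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    p = params or HRFParams()
    t = np.arange(0.0, p.duration + 1e-9, tr / oversample)
    pos = _gamma_dist.pdf(t, p.peak_delay / p.peak_dispersion, scale=p.peak_dispersion)
    neg = _gamma_dist.pdf(
        t, p.undershoot_delay / p.undershoot_dispersion, scale=p.undershoot_dispersion
    )
    h = pos - p.undershoot_ratio * neg
    peak = np.max(np.abs(h))
    if peak == 0:
        raise ValueError("degenerate HRF parameters produced a flat kernel")
    return h / peak


def add_event(
    series: np.ndarray,
    onset: float,
    amplitude: np.ndarray | float,
    tr: float,
    params: HRFParams | None = None,
) -> None:
    """Add amplitude * HRF(t - onset) to ``series`` in place.

    ``series`` is (n_samples,) or (n_samples, n_voxels); ``amplitude`` a
    scalar or per-voxel vector. Sample i sits at time i * tr (sample-onset
    convention). The event onset need not be on the sample grid: the kernel
    is evaluated at the sample times relative to the onset.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    p = params or HRFParams()
    n = series.shape[0]
    times = np.arange(n) * tr - onset
    support = (times >= 0) & (times <= p.duration)
    if not support.any():
        return
    kern = hrf_kernel(tr, p)
    # sample the kernel at the (possibly fractional) lags of the run grid
    lag = times[support]
    grid = np.arange(kern.size) * tr
    vals = np.interp(lag, grid, kern)
    if series.ndim == 1:
        series[support] += np.asarray(amplitude) * vals
    else:
        series[support, :] += np.outer(vals, np.atleast_1d(amplitude))
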
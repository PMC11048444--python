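"""Canonical double-gamma haemodynamic response function.

The BOLD response to a brief neural event is modelled as the difference of two
gamma densities: a positive lobe peaking ~6 s after the event and a slower
undershoot peaking ~16 s, scaled to 1/6 of the peak.  This is the standard
shape used throughout task and resting-state fMRI modelling.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["double_gamma_hrf"]


def double_gamma_hrf(
    tr: float,
    duration: float = 32.0,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Sample the double-gamma HRF at one value per repetition time.

    Parameters
    ----------
    tr : float
        Repetition time in seconds (sampling interval).
    duration : float
        Total kernel length in seconds.
    peak_delay, undershoot_delay : float
        Shape parameters (seconds to peak) of the positive and undershoot
        gamma lobes, with unit scale.
    undershoot_ratio : float
        Relative amplitude of the undershoot lobe.

    Returns
    -------
    ndarray
        Kernel normalised to unit peak.
    """
    if tr <= 0:
        raise ValueError("tr must be positive")
    if duration <= tr:
        raise ValueError("duration must exceed one TR")
    t = np.arange(0.0, duration, tr)
    h = stats.gamma.pdf(t, peak_delay) - undershoot_ratio * stats.gamma.pdf(
        t, undershoot_delay
    )
    return h / h.max()
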
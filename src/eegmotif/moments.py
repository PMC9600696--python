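"""Statistical feature generator: 14 moments of a 1-D signal.

The moment set follows the common wavelet-feature convention: simple order
statistics and dispersion measures plus four entropy-style quantities
computed on squared sample values.

Conventions (all configurable):

* sample variance uses divisor ``n - 1`` (``ddof=1``);
* natural logarithm throughout;
* Shannon entropy is ``-sum(x_i^2 * ln(x_i^2))`` with ``0*ln(0) := 0``
  (unnormalised, as is usual for wavelet subband energies);
* sure entropy with threshold ``eps`` is
  ``n - #{i : |x_i| <= eps} + sum(min(x_i^2, eps^2))``;
* log-energy entropy is ``sum(ln(x_i^2))`` with zero samples contributing
  ``ln(delta^2)`` for a small floor ``delta``;
* threshold entropy is the count ``#{i : |x_i| > eps}``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["STAT_NAMES", "N_STATS", "statistical_features"]

STAT_NAMES = [
    "maximum",
    "minimum",
    "average",
    "variance",
    "std",
    "median",
    "range",
    "rms",
    "energy",
    "shannon_entropy",
    "sure_entropy",
    "log_energy_entropy",
    "threshold_entropy",
    "mean_abs_deviation",
]
N_STATS = len(STAT_NAMES)


def statistical_features(
    signal: np.ndarray,
    eps: float = 0.2,
    delta: float = 1e-12,
    ddof: int = 1,
) -> np.ndarray:
    """The 14 statistical moments of a signal, in :data:`STAT_NAMES` order.

    Parameters
    ----------
    signal : array-like, length >= 2, finite
    eps : threshold used by the sure and threshold entropies
    delta : floor replacing zero samples inside the log-energy entropy
    ddof : variance divisor is ``n - ddof``
    """
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("need a 1-D signal with at least 2 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    n = x.size
    x2 = x * x
    mean = float(np.mean(x))
    var = float(np.var(x, ddof=ddof))
    energy = float(np.sum(x2))

    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(x2 > 0.0, np.log(np.where(x2 > 0.0, x2, 1.0)), 0.0)
    shannon = float(-np.sum(x2 * logs))
    small = np.abs(x) <= eps
    sure = float(n - int(np.sum(small)) + np.sum(np.minimum(x2, eps * eps)))
    log_energy = float(np.sum(np.where(x2 > 0.0, logs, np.log(delta * delta))))
    threshold = float(np.sum(np.abs(x) > eps))

    return np.array(
        [
            float(np.max(x)),
            float(np.min(x)),
            mean,
            var,
            float(np.sqrt(var)),
            float(np.median(x)),
            float(np.max(x) - np.min(x)),
            float(np.sqrt(energy / n)),
            energy,
            shannon,
            sure,
            log_energy,
            threshold,
            float(np.mean(np.abs(x - mean))),
        ]
    )
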
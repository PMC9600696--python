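"""Tunable Q-factor wavelet transform (TQWT).

The TQWT is an iterated two-channel perfect-reconstruction filter bank
defined directly in the frequency domain.  It is parameterised by a quality
factor ``Q`` (centre frequency over bandwidth of the band-pass filters), a
redundancy ``r`` (oversampling rate of the resulting frame) and a level
count ``J``.  Each analysis stage splits the current low-pass signal into a
low-pass branch of length ``2*round(alpha*n/2)`` and a high-pass branch of
length ``2*round(beta*n/2)``, where ``beta = 2/(Q+1)`` and
``alpha = 1 - beta/r``.  Iterating ``J`` times yields ``J`` detail subbands
plus one final scaling (low-pass) subband.

The transition between pass band and stop band uses the Daubechies-type
function ``theta(w) = 0.5*(1 + cos w) * sqrt(2 - cos w)`` for
``0 <= w <= pi``, which satisfies ``theta(w)**2 + theta(pi - w)**2 = 1`` and
hence gives an exactly energy-preserving (Parseval) and perfectly
invertible filter bank.

All subband lengths are computed from the *original* signal length via
powers of ``alpha``/``beta`` (round half up), so the decomposition is
deterministic across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TQWTParams",
    "SubbandSet",
    "max_levels",
    "tqwt_analyze",
    "tqwt_synthesize",
]


@dataclass(frozen=True)
class TQWTParams:
    """Parameters of the tunable Q-factor wavelet transform.

    Attributes
    ----------
    Q : float
        Quality factor, >= 1.  Higher Q gives more oscillatory wavelets.
    r : float
        Redundancy (oversampling) factor, > 1.
    J : int
        Number of decomposition levels; the transform returns ``J + 1``
        subbands (J details + final scaling band).
    """

    Q: float = 4.0
    r: float = 3.0
    J: int = 17

    def __post_init__(self) -> None:
        if self.Q < 1:
            raise ValueError(f"Q must be >= 1, got {self.Q}")
        if self.r <= 1:
            raise ValueError(f"r must be > 1, got {self.r}")
        if self.J < 1:
            raise ValueError(f"J must be >= 1, got {self.J}")

    @property
    def beta(self) -> float:
        """High-pass scaling factor, 2/(Q+1)."""
        return 2.0 / (self.Q + 1.0)

    @property
    def alpha(self) -> float:
        """Low-pass scaling factor, 1 - beta/r."""
        return 1.0 - self.beta / self.r


@dataclass
class SubbandSet:
    """Ordered TQWT subbands of one signal.

    ``subbands[0] .. subbands[J-1]`` are the detail (high-pass) outputs of
    stages 1..J, ``subbands[J]`` is the final scaling (low-pass) band.
    ``n`` is the original signal length before any padding; ``padded`` marks
    whether one zero was appended to make the length even.
    """

    subbands: list[np.ndarray]
    params: TQWTParams
    n: int
    padded: bool = False

    def __len__(self) -> int:
        return len(self.subbands)

    def __iter__(self):
        return iter(self.subbands)

    def __getitem__(self, i: int) -> np.ndarray:
        return self.subbands[i]

    def energy(self) -> float:
        return float(sum(np.sum(b * b) for b in self.subbands))


def _round_half_up_even(x: float) -> int:
    """2 * round(x/2) with deterministic half-up rounding."""
    return 2 * int(math.floor(x / 2.0 + 0.5))


def max_levels(n: int, Q: float = 4.0, r: float = 3.0) -> int:
    """Largest usable level count for a length-``n`` signal.

    The filter bank requires every subband to keep at least 8 samples,
    which bounds J by ``floor(log(beta*n/8) / log(1/alpha))``.
    """
    p = TQWTParams(Q=Q, r=r, J=1)
    if n < 8:
        raise ValueError("signal too short for any TQWT level")
    arg = p.beta * n / 8.0
    if arg <= 1.0:
        raise ValueError("signal too short for any TQWT level")
    return int(math.floor(math.log(arg) / math.log(1.0 / p.alpha)))


def _stage_lengths(n: int, params: TQWTParams) -> list[tuple[int, int]]:
    """(low-pass, high-pass) output lengths of stages 1..J, from original n."""
    a, b = params.alpha, params.beta
    out = []
    for j in range(1, params.J + 1):
        n0 = _round_half_up_even(a**j * n)
        n1 = _round_half_up_even(a ** (j - 1) * b * n)
        out.append((n0, n1))
    return out


def _theta(v: np.ndarray) -> np.ndarray:
    """Daubechies transition function on [0, pi]."""
    return 0.5 * (1.0 + np.cos(v)) * np.sqrt(2.0 - np.cos(v))


def _transition(T: int) -> np.ndarray:
    v = np.arange(1, T + 1) * (np.pi / (T + 1))
    return _theta(v)


def _afb(Xh: np.ndarray, m: int, n0: int, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """One analysis stage on a half-spectrum (rfft) of even length m."""
    P = (m - n1) // 2
    T = (n0 + n1 - m) // 2 - 1
    if T < 0 or P < 0:
        raise ValueError("inconsistent subband lengths for analysis stage")
    tr = _transition(T)
    V0 = np.zeros(n0 // 2 + 1, dtype=complex)
    V1 = np.zeros(n1 // 2 + 1, dtype=complex)
    V0[: P + 1] = Xh[: P + 1]
    V0[P + 1 : P + T + 1] = Xh[P + 1 : P + T + 1] * tr
    # V0[n0//2] stays 0 (low-pass filter vanishes at its Nyquist)
    V1[1 : T + 1] = Xh[P + 1 : P + T + 1] * tr[::-1]
    V1[T + 1 :] = Xh[P + T + 1 : m // 2 + 1]
    return V0, V1


def _sfb(V0: np.ndarray, V1: np.ndarray, m: int, n0: int, n1: int) -> np.ndarray:
    """Inverse of :func:`_afb`; returns the half-spectrum of length m//2+1."""
    P = (m - n1) // 2
    T = (n0 + n1 - m) // 2 - 1
    tr = _transition(T)
    Xh = np.zeros(m // 2 + 1, dtype=complex)
    Xh[: P + 1] = V0[: P + 1]
    Xh[P + 1 : P + T + 1] = V0[P + 1 : P + T + 1] * tr + V1[1 : T + 1] * tr[::-1]
    Xh[P + T + 1 :] = V1[T + 1 : n1 // 2 + 1]
    return Xh


def tqwt_analyze(signal: np.ndarray, params: TQWTParams | None = None) -> SubbandSet:
    """Decompose a 1-D signal into ``J`` detail subbands plus a scaling band.

    Odd-length inputs are zero-padded by one sample (recorded on the
    returned :class:`SubbandSet`).  Raises if ``params.J`` exceeds
    :func:`max_levels` for this signal length.
    """
    params = params or TQWTParams()
    x = np.asarray(signal, dtype=float)
    if x.ndim != 1:
        raise ValueError("tqwt_analyze expects a 1-D signal")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    n_orig = x.size
    padded = False
    if x.size % 2 == 1:
        x = np.append(x, 0.0)
        padded = True
    n = x.size
    jmax = max_levels(n, params.Q, params.r)
    if params.J > jmax:
        raise ValueError(
            f"J={params.J} exceeds the maximum of {jmax} levels for a "
            f"length-{n} signal at Q={params.Q}, r={params.r}"
        )
    lengths = _stage_lengths(n, params)
    Xh = np.fft.rfft(x, norm="ortho")
    m = n
    details: list[np.ndarray] = []
    for n0, n1 in lengths:
        Xh, V1 = _afb(Xh, m, n0, n1)
        details.append(np.fft.irfft(V1, n=n1, norm="ortho"))
        m = n0
    scaling = np.fft.irfft(Xh, n=m, norm="ortho")
    return SubbandSet(subbands=details + [scaling], params=params, n=n_orig, padded=padded)


def tqwt_synthesize(subbands: SubbandSet) -> np.ndarray:
    """Reconstruct the original signal from its TQWT subbands."""
    params = subbands.params
    n = subbands.n + (1 if subbands.padded else 0)
    if len(subbands.subbands) != params.J + 1:
        raise ValueError(
            f"expected {params.J + 1} subbands, got {len(subbands.subbands)}"
        )
    lengths = _stage_lengths(n, params)
    for (n0, n1), band in zip(lengths, subbands.subbands):
        if band.size != n1:
            raise ValueError(
                f"detail subband length {band.size} inconsistent with expected {n1}"
            )
    if subbands.subbands[-1].size != lengths[-1][0]:
        raise ValueError("scaling subband length inconsistent with parameters")
    Xh = np.fft.rfft(np.asarray(subbands.subbands[-1], dtype=float), norm="ortho")
    for j in range(params.J - 1, -1, -1):
        n0, n1 = lengths[j]
        m = lengths[j - 1][0] if j > 0 else n
        V1 = np.fft.rfft(np.asarray(subbands.subbands[j], dtype=float), norm="ortho")
        Xh = _sfb(Xh, V1, m, n0, n1)
    x = np.fft.irfft(Xh, n=n, norm="ortho")
    if subbands.padded:
        x = x[:-1]
    return x
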
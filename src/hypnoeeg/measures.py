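"""Per-segment hypnotic-depth measures.

Two information-theoretic measures and a set of spectral measures:

* **LZc** — Lempel-Ziv complexity: the signal is binarized across its median
  and parsed by the LZ76 exhaustive-history algorithm into the minimal
  sequence of non-redundant words; the word count c(n) is normalized as
  ``c(n) * log2(n) / n`` so that periodic signals score near 0 and
  i.i.d. noise near 1.
* **PE** — permutation entropy: the Shannon entropy of the distribution of
  ordinal (rank) patterns of m=5 consecutive points (delay 1), normalized by
  ``log(m!)`` to [0, 1].
* **Alpha power** — the time-averaged squared magnitude of the analytic
  (Hilbert) signal of the 8-12 Hz bandpassed segment, in uV^2.
* **Welch spectrum** — Hann windows of 4.5 s with 50% overlap within each
  15 s segment, scaled so that the summed powers approximate the signal
  variance (Parseval-consistent); from it total power (< 30 Hz), the 95%
  spectral edge frequency, and band powers (delta/theta/alpha/beta).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as _sig

__all__ = [
    "BANDS",
    "PSD",
    "OrdinalPatternDistribution",
    "binarize_median",
    "lz76_count",
    "lzc",
    "ordinal_patterns",
    "permutation_entropy",
    "pattern_duration_ms",
    "alpha_power_hilbert",
    "welch_psd",
    "total_power",
    "sef95",
    "band_power",
]

#: frequency bands in Hz, [lo, hi)
BANDS = {"delta": (0.5, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 12.0), "beta": (12.0, 25.0)}

#: upper frequency bound for total power and SEF95
FMAX_HZ = 30.0


# ---------------------------------------------------------------------------
# Lempel-Ziv complexity


def binarize_median(samples) -> np.ndarray:
    """Binarize a signal across its median (1 above, 0 at or below)."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples to binarize")
    return (x > np.median(x)).astype(np.uint8)


def lz76_count(symbols) -> int:
    """LZ76 exhaustive-history word count c(n) of a binary sequence.

    The sequence is parsed left to right into words; each word is the
    shortest extension of the current position that cannot be copied from
    anywhere earlier in the sequence (overlap with the word's own start is
    allowed, as in the exhaustive history).  A trailing word that remains
    copyable up to the end still counts.
    """
    if isinstance(symbols, str):
        if set(symbols) - {"0", "1"}:
            raise ValueError("sequence must be binary")
        s = symbols.encode()
    else:
        a = np.asarray(symbols)
        if a.size and not np.isin(a, (0, 1)).all():
            raise ValueError("sequence must be binary")
        s = a.astype(np.uint8).tobytes()  # bytes.find is C-level
    n = len(s)
    if n == 0:
        raise ValueError("empty sequence")
    c = 0
    p = 0
    while p < n:
        length = 1
        j = -1  # start of the last known copy of the current word (j < p)
        # grow the candidate word while it is reproducible from s[0 : p+length-1]
        while p + length <= n:
            if j >= 0 and s[j + length - 1] == s[p + length - 1]:
                length += 1  # the previous copy extends; skip the search
                continue
            j = s.find(s[p : p + length], 0, p + length - 1)
            if j == -1:
                break
            length += 1
        c += 1
        p += length
    return c


def lzc(samples) -> float:
    """Normalized Lempel-Ziv complexity ``c(n) * log2(n) / n``."""
    sym = binarize_median(samples)
    n = sym.size
    return lz76_count(sym) * math.log2(n) / n


# ---------------------------------------------------------------------------
# permutation entropy


@dataclass
class OrdinalPatternDistribution:
    """Occurrence counts of ordinal patterns (rank orderings) of the signal."""

    m: int
    tau: int
    counts: dict  # pattern tuple -> count
    total: int

    def probabilities(self) -> np.ndarray:
        return np.array(list(self.counts.values()), dtype=float) / self.total


def ordinal_patterns(samples, m: int = 5, tau: int = 1) -> OrdinalPatternDistribution:
    """Count ordinal patterns of ``m`` points with embedding delay ``tau``.

    Each window (x[i], x[i+tau], ..., x[i+(m-1)tau]) is mapped to the
    permutation that sorts it ascending; ties rank the earlier point lower
    (stable sort).  Only the induced distribution matters for the entropy.
    """
    x = np.asarray(samples, dtype=float)
    n = x.size
    span = (m - 1) * tau
    if n < span + 1:
        raise ValueError(f"need at least {span + 1} samples for m={m}, tau={tau}")
    idx = np.arange(n - span)[:, None] + np.arange(m)[None, :] * tau
    windows = x[idx]
    pats = np.argsort(windows, axis=1, kind="stable")
    # encode each permutation as an integer in base m for fast counting
    code = pats @ (m ** np.arange(m))
    uniq, cnt = np.unique(code, return_counts=True)
    counts = {}
    for u, c in zip(uniq, cnt):
        digits = []
        v = int(u)
        for _ in range(m):
            digits.append(v % m)
            v //= m
        counts[tuple(digits)] = int(c)
    return OrdinalPatternDistribution(m=m, tau=tau, counts=counts, total=int(n - span))


def permutation_entropy(dist: OrdinalPatternDistribution) -> float:
    """Shannon entropy of the ordinal-pattern distribution, normalized to [0, 1]."""
    if dist.total < 1:
        raise ValueError("empty pattern distribution")
    p = dist.probabilities()
    p = p[p > 0]
    h = -np.sum(p * np.log(p))
    return float(h / math.log(math.factorial(dist.m)))


def pattern_duration_ms(m: int, fs: float, tau: int = 1) -> float:
    """Duration in milliseconds spanned by one ordinal pattern of m samples."""
    return 1000.0 * (1 + (m - 1) * tau) / fs


# ---------------------------------------------------------------------------
# spectral measures


def alpha_power_hilbert(samples, fs: float, edge_trim_s: float = 0.5) -> float:
    """Mean squared magnitude of the analytic signal (uV^2).

    Expects the 8-12 Hz bandpassed segment.  ``edge_trim_s`` seconds are
    discarded at each end before averaging to suppress Hilbert edge effects.
    For a pure in-band sinusoid of amplitude A this returns A^2.
    """
    x = np.asarray(samples, dtype=float)
    env2 = np.abs(_sig.hilbert(x)) ** 2
    trim = int(round(edge_trim_s * fs))
    if 2 * trim >= x.size:
        raise ValueError("segment shorter than twice the edge trim")
    return float(env2[trim : x.size - trim].mean())


@dataclass
class PSD:
    """A one-sided power spectrum: per-bin powers (uV^2), Parseval-consistent."""

    freqs: np.ndarray
    powers: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.powers = np.asarray(self.powers, dtype=float)
        if self.freqs.size != self.powers.size:
            raise ValueError("freqs and powers must have the same length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.powers < -1e-12):
            raise ValueError("powers must be nonnegative")


def welch_psd(samples, fs: float, window_s: float = 4.5, overlap: float = 0.5) -> PSD:
    """Welch spectrum with Hann windows (4.5 s, 50% overlap) of a raw segment.

    Powers are per-bin (density times bin width) so that their sum
    approximates the signal variance.
    """
    x = np.asarray(samples, dtype=float)
    nperseg = int(round(window_s * fs))
    if x.size < nperseg:
        raise ValueError(f"segment of {x.size} samples shorter than one {window_s} s window")
    freqs, pxx = _sig.welch(
        x, fs=fs, window="hann", nperseg=nperseg,
        noverlap=int(nperseg * overlap), detrend="constant",
    )
    df = freqs[1] - freqs[0]
    return PSD(freqs=freqs, powers=pxx * df)


def total_power(psd: PSD, fmax_hz: float = FMAX_HZ) -> float:
    """Sum of spectral powers at frequencies below ``fmax_hz`` (uV^2)."""
    return float(psd.powers[psd.freqs < fmax_hz].sum())


def sef95(psd: PSD, fmax_hz: float = FMAX_HZ, fraction: float = 0.95) -> float:
    """Spectral edge frequency: lowest f with cumulative power >= 95% of total.

    Computed within the sub-``fmax_hz`` range; NaN when that range holds no
    power.
    """
    sel = psd.freqs < fmax_hz
    p = psd.powers[sel]
    f = psd.freqs[sel]
    tot = p.sum()
    if tot <= 0:
        return float("nan")
    csum = np.cumsum(p)
    return float(f[np.searchsorted(csum, fraction * tot)])


def band_power(psd: PSD, lo_hz: float, hi_hz: float) -> float:
    """Sum of spectral powers over [lo_hz, hi_hz) (uV^2)."""
    if not lo_hz < hi_hz:
        raise ValueError(f"inverted band bounds ({lo_hz}, {hi_hz})")
    sel = (psd.freqs >= lo_hz) & (psd.freqs < hi_hz)
    return float(psd.powers[sel].sum())
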
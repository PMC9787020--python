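"""Detrended fluctuation analysis (DFA) with a multiplicative window schedule.

DFA estimates the scaling exponent ``alpha`` of long-range temporal
correlation in a fluctuation series.  The procedure: subtract the series
mean and integrate (the *profile*), tile the profile with windows of
geometrically increasing size, detrend each window with a least-squares
polynomial fit, average the residual standard deviation per window size,
and regress log fluctuation on log window size.  The slope is ``alpha``:

* ``alpha ~ 0.5``  — uncorrelated (white-noise) fluctuations
* ``alpha < 0.5``  — antipersistent fluctuations
* ``alpha ~ 1.0``  — 1/f (pink) structure, moderately persistent
* ``alpha ~ 1.5``  — Brownian, highly persistent

Window schedule: sizes start at ``min_window`` samples and grow by a
constant multiplicative factor (default 1.2), each rounded to the nearest
integer and deduplicated, up to (exclusive) ``max_window_fraction`` of the
series length.  Windows are placed with 50% overlap by default.

The per-window-size statistic defaults to the arithmetic mean of the
per-window residual SDs (``"mean_sd"``); the more common root-mean-square
convention is available as ``"rms"``.  The two agree closely for the
stationary series handled here.

The module also provides seeded reference noise generators (white, pink,
brown, antipersistent) used for calibrating the estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DFAConfig",
    "DFAResult",
    "InsufficientLengthError",
    "profile",
    "window_schedule",
    "fluctuation",
    "dfa_alpha",
    "generate_noise",
    "MIN_SERIES_LENGTH",
]

#: Shortest series accepted by :func:`dfa_alpha`.  Below this the largest
#: admissible window does not strictly exceed the smallest, so no slope
#: can be fit.
MIN_SERIES_LENGTH = 50

NOISE_KINDS = ("white", "pink", "brown", "antipersistent")


class InsufficientLengthError(ValueError):
    """Series too short for the requested window schedule."""


@dataclass(frozen=True)
class DFAConfig:
    """Parameters of the DFA window schedule and detrending.

    Attributes
    ----------
    min_window:
        Smallest window size in samples (5 samples = 1 s at 5 Hz).
    growth:
        Multiplicative factor between successive window sizes.
    overlap_fraction:
        Fractional overlap between adjacent windows of the same size.
    max_window_fraction:
        Windows must be strictly smaller than this fraction of the series
        length.
    detrend_order:
        Degree of the least-squares detrending polynomial.
    fluctuation_stat:
        ``"mean_sd"`` (mean of per-window residual SDs, the default) or
        ``"rms"`` (root-mean-square of per-window residual SDs).
    """

    min_window: int = 5
    growth: float = 1.2
    overlap_fraction: float = 0.5
    max_window_fraction: float = 0.10
    detrend_order: int = 1
    fluctuation_stat: str = "mean_sd"

    def __post_init__(self) -> None:
        if not self.growth > 1:
            raise ValueError("growth must be > 1")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if not 0 < self.max_window_fraction <= 1:
            raise ValueError("max_window_fraction must be in (0, 1]")
        if self.min_window <= self.detrend_order + 1:
            raise ValueError("min_window must exceed detrend_order + 1")
        if self.fluctuation_stat not in ("mean_sd", "rms"):
            raise ValueError("fluctuation_stat must be 'mean_sd' or 'rms'")


@dataclass
class DFAResult:
    """Outcome of a DFA fit."""

    alpha: float
    window_sizes: np.ndarray
    fluctuations: np.ndarray
    fit_r2: float
    n: int
    intercept: float = field(default=float("nan"))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"DFAResult(alpha={self.alpha:.4f}, r2={self.fit_r2:.4f}, "
            f"n={self.n}, windows={len(self.window_sizes)})"
        )


def profile(series: np.ndarray) -> np.ndarray:
    """Mean-centered cumulative sum of a series.

    ``Y_k = sum_{i<=k} (x_i - mean(x))``; the final value is zero up to
    rounding.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile requires a 1-D series of length >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    return np.cumsum(x - x.mean())


def window_schedule(n: int, config: DFAConfig | None = None) -> np.ndarray:
    """Geometric window-size schedule for a series of length ``n``.

    Sizes are ``min_window * growth**k`` rounded to the nearest integer,
    deduplicated, and kept while strictly below
    ``n * max_window_fraction``.  At least two distinct sizes are required
    to fit a slope.
    """
    config = config or DFAConfig()
    limit = n * config.max_window_fraction
    sizes: list[int] = []
    k = 0
    while True:
        w_exact = config.min_window * config.growth**k
        w = int(np.floor(w_exact + 0.5))
        if w >= limit:
            break
        if not sizes or w != sizes[-1]:
            sizes.append(w)
        k += 1
        if k > 10_000:  # pragma: no cover - defensive
            break
    if len(sizes) < 2:
        raise InsufficientLengthError(
            f"insufficient length for DFA: n={n} admits {len(sizes)} window "
            f"size(s) below {limit:.1f}; need at least 2"
        )
    return np.asarray(sizes, dtype=int)


def fluctuation(
    profile_series: np.ndarray,
    window: int,
    detrend_order: int = 1,
    overlap_fraction: float = 0.5,
    stat: str = "mean_sd",
) -> float:
    """Average detrended fluctuation of the profile at one window size.

    Windows of length ``window`` are placed with the given fractional
    overlap (step ``floor(w * (1 - overlap))``, at least 1); a trailing
    partial window is discarded.  Within each window the residual SD after
    a least-squares polynomial fit of degree ``detrend_order`` is taken,
    and the per-window SDs are combined with ``stat``.
    """
    prof = np.asarray(profile_series, dtype=float)
    n = prof.size
    w = int(window)
    if w > n:
        raise ValueError(f"window {w} exceeds profile length {n}")
    step = max(1, int(np.floor(w * (1.0 - overlap_fraction))))
    starts = np.arange(0, n - w + 1, step)
    if starts.size == 0:  # pragma: no cover - guarded by w <= n
        raise ValueError("no windows fit the profile")
    segments = prof[starts[:, None] + np.arange(w)]
    # Orthonormal basis of the polynomial design; residual = (I - QQ')y.
    design = np.vander(np.arange(w, dtype=float), detrend_order + 1)
    q, _ = np.linalg.qr(design)
    residuals = segments - (segments @ q) @ q.T
    sds = residuals.std(axis=1)
    if stat == "mean_sd":
        return float(sds.mean())
    if stat == "rms":
        return float(np.sqrt(np.mean(sds**2)))
    raise ValueError("stat must be 'mean_sd' or 'rms'")


def dfa_alpha(series: np.ndarray, config: DFAConfig | None = None) -> DFAResult:
    """Full DFA of a fluctuation series.

    Raises
    ------
    InsufficientLengthError
        If the series is shorter than :data:`MIN_SERIES_LENGTH` or admits
        fewer than two window sizes.
    ValueError
        For constant or non-finite input (zero fluctuation has no
        log-log slope).
    """
    config = config or DFAConfig()
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if x.size < MIN_SERIES_LENGTH:
        raise InsufficientLengthError(
            f"insufficient length for DFA: n={x.size} < {MIN_SERIES_LENGTH}"
        )
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if np.ptp(x) == 0:
        raise ValueError("constant series has zero fluctuation at every scale")

    prof = profile(x)
    sizes = window_schedule(x.size, config)
    flucts = np.array(
        [
            fluctuation(
                prof,
                w,
                detrend_order=config.detrend_order,
                overlap_fraction=config.overlap_fraction,
                stat=config.fluctuation_stat,
            )
            for w in sizes
        ]
    )
    if np.any(flucts <= 0):
        raise ValueError("zero fluctuation encountered; series is locally constant")

    logw = np.log10(sizes)
    logf = np.log10(flucts)
    slope, intercept = np.polyfit(logw, logf, 1)
    r2 = float(np.corrcoef(logw, logf)[0, 1] ** 2)
    return DFAResult(
        alpha=float(slope),
        window_sizes=sizes,
        fluctuations=flucts,
        fit_r2=r2,
        n=int(x.size),
        intercept=float(intercept),
    )


def generate_noise(kind: str, n: int, seed: int) -> np.ndarray:
    """Seeded reference noise for DFA calibration.

    * ``white`` — iid standard Gaussian.
    * ``brown`` — cumulative sum of white noise drawn with the same seed
      (``brown(s) == cumsum(white(s))``).
    * ``pink`` — spectral synthesis: the rFFT of white noise is scaled by
      ``f**-0.5`` (DC removed), inverted, and standardized to unit
      variance, giving a 1/f power spectrum.
    * ``antipersistent`` — first differences of ``n + 1`` white samples.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    if kind == "white":
        return rng.standard_normal(n)
    if kind == "brown":
        return np.cumsum(rng.standard_normal(n))
    if kind == "antipersistent":
        return np.diff(rng.standard_normal(n + 1))
    if kind == "pink":
        white = rng.standard_normal(n)
        spectrum = np.fft.rfft(white)
        freqs = np.fft.rfftfreq(n)
        scale = np.zeros_like(freqs)
        scale[1:] = freqs[1:] ** -0.5
        x = np.fft.irfft(spectrum * scale, n)
        return (x - x.mean()) / x.std()
    raise ValueError(f"unknown noise kind {kind!r}; choose from {NOISE_KINDS}")
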
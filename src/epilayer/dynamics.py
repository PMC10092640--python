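"""Monolayer fluidity from live movies.

The fluidity readout is an image autocorrelation: every frame is
normalized to zero mean and unit SD, and the correlation strength at lag
``T_k = k * frame_interval`` is the average over all frame pairs separated
by k of the pixel-averaged elementwise product of the two normalized
frames,

    C(T_k) = 1/(N-k) * sum_t [ 1/M^2 * sum_ij  I_t(i,j) * I_{t+k}(i,j) ]

with I the normalized frames.  C runs from -1 (perfectly anticorrelated)
through 0 (uncorrelated) to 1 (perfectly correlated); C(0) = 1 by
construction.  Fitting C(t) to an exponential decay exp(-lambda t) over
positive lags gives the correlation half-life ln 2 / lambda: the time for
cells within the field to decorrelate, short in fluid (Immature) layers
and long in glass-like (Mature) ones.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

logger = logging.getLogger("epilayer")


@dataclass
class Movie:
    """A 2D time-lapse: frames of equal shape at a fixed time interval."""

    frames: np.ndarray  # (N, M, M') float array
    frame_interval_min: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("movie frames must form a 3D (time, y, x) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a movie needs at least 2 frames")
        if not (self.frame_interval_min > 0):
            raise ValueError("frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class CorrelationCurve:
    """Correlation strength vs correlation time, with an optional decay fit."""

    correlation_time_min: np.ndarray
    correlation_strength: np.ndarray
    half_life_min: float | None = None

    def __post_init__(self) -> None:
        self.correlation_time_min = np.asarray(self.correlation_time_min, dtype=float)
        self.correlation_strength = np.asarray(self.correlation_strength, dtype=float)


def normalize_frame(frame: np.ndarray) -> np.ndarray:
    """Subtract the mean pixel intensity and divide by the (population) SD."""
    frame = np.asarray(frame, dtype=float)
    sd = frame.std()
    if sd == 0:
        raise ValueError("zero variance: constant frame cannot be normalized")
    return (frame - frame.mean()) / sd


def gaussian_blur(movie: Movie, sigma_px: float) -> Movie:
    """Optional preprocessing: per-frame Gaussian blur (sigma in pixels)."""
    blurred = np.stack(
        [ndimage.gaussian_filter(f, sigma_px) for f in movie.frames]
    )
    return Movie(frames=blurred, frame_interval_min=movie.frame_interval_min)


def autocorrelation(movie: Movie) -> CorrelationCurve:
    """Correlation strength at every lag 0 .. N-1 of the movie."""
    normalized = np.stack([normalize_frame(f) for f in movie.frames])
    n = movie.n_frames
    m2 = normalized[0].size
    strengths = np.empty(n)
    for k in range(n):
        pair_means = [
            float(np.sum(normalized[t] * normalized[t + k])) / m2
            for t in range(n - k)
        ]
        strengths[k] = np.mean(pair_means)
    lags = np.arange(n) * movie.frame_interval_min
    return CorrelationCurve(correlation_time_min=lags, correlation_strength=strengths)


def fit_half_life(curve: CorrelationCurve) -> float:
    """Half-life of the exponential decay fitted to positive lags.

    Least squares of C(t) = exp(-lambda t) on the linear scale (the curve
    may be near 0 or slightly negative at long lags, so a log-linear fit
    is not used).  A non-decaying curve (lambda <= 0) is flagged and the
    half-life reported as infinite.
    """
    positive = curve.correlation_time_min > 0
    t = curve.correlation_time_min[positive]
    c = curve.correlation_strength[positive]
    if t.size < 4:
        raise ValueError("half-life fit needs at least 4 positive lags")

    def model(t, lam):
        return np.exp(-lam * t)

    # moment-based start: lambda from the first sub-1/e crossing if any
    below = np.nonzero(c < np.exp(-1))[0]
    lam0 = 1.0 / t[below[0]] if below.size else 1.0 / t[-1]
    try:
        popt, _ = optimize.curve_fit(model, t, c, p0=[max(lam0, 1e-9)], maxfev=10000)
        lam = float(popt[0])
    except RuntimeError:
        lam = 0.0
    if lam <= 0 or lam * t[-1] < 1e-8:
        # no measurable decay over the whole movie
        logger.warning("non-decaying correlation curve: half-life is infinite")
        return float("inf")
    return float(np.log(2) / lam)


def analyze_movie(movie: Movie, blur_sigma_px: float | None = None) -> CorrelationCurve:
    """Autocorrelation plus half-life fit (optionally blurring first)."""
    if blur_sigma_px:
        movie = gaussian_blur(movie, blur_sigma_px)
    curve = autocorrelation(movie)
    try:
        curve.half_life_min = fit_half_life(curve)
    except ValueError:
        curve.half_life_min = None
    return curve
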
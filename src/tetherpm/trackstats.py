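"""Track-level observables of confined particle motion.

Operates identically on simulated and experimental position tracks: vibration
amplitude (positional SD with fixed-marker correction), 2D position-maps,
positional autocorrelation, mean-squared displacement with multi-start
averaging, the confinement exponent alpha from a log-log power-law fit
MSD(t) = A * t^alpha, and the ordinary least-squares / Pearson analysis used
to relate adhesion forces to vibration amplitudes across strains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DataError, InvalidArgumentError

#: Published single-bacterium-probe AFM adhesion forces (nN) and vibration
#: amplitudes (nm) for eight non-motile coccal strains adhering to glass.
#: Consumed directly by the cross-strain linear-correlation analysis.
ADHESION_VIBRATION_DATA: dict[str, tuple[float, float]] = {
    "S. aureus ATCC12600": (1.1, 25.0),
    "S. aureus NCTC8325-4": (1.4, 17.0),
    "S. epidermidis ATCC35983": (0.8, 78.0),
    "S. epidermidis ATCC35984": (1.5, 21.0),
    "S. mutans LT11": (1.8, 6.0),
    "S. mutans IB03987": (0.6, 95.0),
    "S. salivarius HB7": (1.1, 94.0),
    "S. salivarius HBC-12": (1.0, 69.0),
}

#: Default MSD estimator parameters: 1000 lags (16.7 s at 60 Hz) averaged over
#: 10 starting positions spaced 100 frames apart.
MSD_N_LAGS = 1000
MSD_N_STARTS = 10
MSD_START_SPACING = 100

#: Default power-law fit windows (s): the long-time confinement exponent is
#: reported both for t > 1 s and for t > 5 s; the short-time diffusive check
#: uses the first half second.
ALPHA_WINDOW_T1 = (1.0, math.inf)
ALPHA_WINDOW_T5 = (5.0, math.inf)
ALPHA_WINDOW_INITIAL = (0.0, 0.5)


@dataclass
class PositionTrack:
    """Uniformly sampled 2D positions in nm."""

    times: np.ndarray  # s
    x: np.ndarray  # nm
    y: np.ndarray  # nm
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.times.size == self.x.size == self.y.size):
            raise DataError("times, x and y must have equal length")
        if self.times.size < 2:
            raise DataError("a track needs at least 2 frames")
        if not (
            np.all(np.isfinite(self.times))
            and np.all(np.isfinite(self.x))
            and np.all(np.isfinite(self.y))
        ):
            raise DataError("track contains non-finite values")
        dt = np.diff(self.times)
        if dt.size and (np.abs(dt - dt[0]) > 1e-6).any():
            raise DataError("track frame spacing is not uniform (tolerance 1e-6 s)")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    @property
    def frame_interval(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass
class PositionMap:
    bin_edges_x: np.ndarray  # nm
    bin_edges_y: np.ndarray  # nm
    counts: np.ndarray  # (nx, ny) occupancy


@dataclass
class AutocorrCurve:
    lags: np.ndarray  # s
    values: np.ndarray  # dimensionless R(h)


@dataclass
class MSDCurve:
    lags: np.ndarray  # s (lag 0 included)
    values: np.ndarray  # nm^2
    n_starts: int
    n_lags: int


@dataclass
class PowerLawFit:
    """MSD(t) = A * t^alpha fitted by OLS on log-log axes inside a window."""

    A: float  # nm^2 s^-alpha
    alpha: float
    window: tuple[float, float]  # s
    r_squared: float


@dataclass
class LinearFit:
    slope: float
    intercept: float
    r_squared: float
    p_two_tailed: float


def vibration_amplitude(track: PositionTrack, marker_amplitude: float = 0.0) -> float:
    """Positional SD of the track (nm), corrected for a fixed marker.

    Amplitude = mean of the per-axis population standard deviations about the
    track mean, minus the co-recorded fixed-marker amplitude (linear
    subtraction, floored at zero).  For circular position-maps this reduces to
    the single-axis SD.
    """
    if track.n_frames < 2:
        raise DataError("vibration amplitude needs at least 2 frames")
    sd = 0.5 * (np.std(track.x) + np.std(track.y))
    return max(0.0, float(sd) - marker_amplitude)


def position_map(track: PositionTrack, bin_width: float) -> PositionMap:
    """2D occupancy histogram centered on the track mean."""
    if bin_width <= 0:
        raise InvalidArgumentError("bin_width must be positive")

    def edges(values: np.ndarray) -> np.ndarray:
        center = values.mean()
        half = max(np.max(np.abs(values - center)), 0.0)
        n_half = int(math.floor(half / bin_width + 0.5)) + 1
        return center + bin_width * (np.arange(-n_half, n_half + 1) - 0.5)

    ex, ey = edges(track.x), edges(track.y)
    counts, _, _ = np.histogram2d(track.x, track.y, bins=(ex, ey))
    return PositionMap(bin_edges_x=ex, bin_edges_y=ey, counts=counts)


def autocorrelation(track: PositionTrack, axis: str = "x") -> AutocorrCurve:
    """Biased positional autocorrelation R(h) of one coordinate.

    ``R(h) = sum_{n=0}^{N-h-1} x(n) x(n+h) / sum_{n=0}^{N-1} x(n)^2`` with
    ``x`` the position relative to the track mean.  The biased normalization
    guarantees |R(h)| <= 1.  Lags are multiples of the frame interval.
    """
    if axis not in ("x", "y"):
        raise InvalidArgumentError("axis must be 'x' or 'y'")
    x = (track.x if axis == "x" else track.y).astype(float)
    x = x - x.mean()
    denom = float(np.dot(x, x))
    if denom <= 0.0:
        raise DataError("autocorrelation undefined for a zero-variance track")
    n = x.size
    full = np.correlate(x, x, mode="full")
    values = full[n - 1 :] / denom
    lags = np.arange(n) * track.frame_interval
    return AutocorrCurve(lags=lags, values=values)


def autocorrelation_half_time(curve: AutocorrCurve) -> float:
    """Smallest lag at which R first falls to 0.5 (linear interpolation).

    Returns +inf when the autocorrelation never loses half its value inside
    the measured lag range.
    """
    r = curve.values
    below = np.nonzero(r <= 0.5)[0]
    if below.size == 0:
        return math.inf
    i = int(below[0])
    if i == 0:
        return float(curve.lags[0])
    t0, t1 = curve.lags[i - 1], curve.lags[i]
    r0, r1 = r[i - 1], r[i]
    if r0 == r1:
        return float(t1)
    return float(t0 + (r0 - 0.5) / (r0 - r1) * (t1 - t0))


def msd(
    track: PositionTrack,
    n_lags: int = MSD_N_LAGS,
    n_starts: int = MSD_N_STARTS,
    start_spacing: int = MSD_START_SPACING,
) -> MSDCurve:
    """Lag-resolved 2D mean-squared displacement (nm^2).

    ``MSD(i) = (1/M) sum_k |r(j_k + i) - r(j_k)|^2`` with starting frames
    ``j_k = (k-1) * start_spacing``.  The default 1000 lags / 10 starts spaced
    100 frames apart need ``(M-1)*spacing + N + 1`` frames.
    """
    needed = (n_starts - 1) * start_spacing + n_lags + 1
    if track.n_frames < needed:
        raise DataError(
            f"track too short for MSD: {track.n_frames} frames < {needed} required"
        )
    r = np.column_stack([track.x, track.y])
    starts = np.arange(n_starts) * start_spacing
    lags = np.arange(n_lags + 1)
    # displacement of r[j+i] from each start j, vectorized over starts
    disp = r[starts[:, None] + lags[None, :], :] - r[starts, None, :]
    values = np.mean(np.sum(disp**2, axis=2), axis=0)
    return MSDCurve(
        lags=lags * track.frame_interval,
        values=values,
        n_starts=n_starts,
        n_lags=n_lags,
    )


def msd_ensemble(curves: list[MSDCurve]) -> MSDCurve:
    """Pointwise mean of per-track MSD curves (equal lag axes required)."""
    if not curves:
        raise DataError("need at least one MSD curve")
    ref = curves[0]
    for c in curves[1:]:
        if c.lags.size != ref.lags.size or np.abs(c.lags - ref.lags).max() > 1e-9:
            raise DataError("MSD curves have mismatched lag axes (frame intervals)")
    values = np.mean([c.values for c in curves], axis=0)
    return MSDCurve(
        lags=ref.lags.copy(), values=values, n_starts=ref.n_starts, n_lags=ref.n_lags
    )


def fit_power_law(curve: MSDCurve, window: tuple[float, float]) -> PowerLawFit:
    """OLS straight line on (log t, log MSD) restricted to t in (t_min, t_max]."""
    t_min, t_max = window
    mask = (curve.lags > t_min) & (curve.lags <= t_max) & (curve.lags > 0)
    if int(mask.sum()) < 3:
        raise DataError("power-law fit needs at least 3 lags inside the window")
    values = curve.values[mask]
    if np.any(values <= 0):
        raise DataError("power-law fit undefined for non-positive MSD values")
    logt = np.log(curve.lags[mask])
    logm = np.log(values)
    res = stats.linregress(logt, logm)
    return PowerLawFit(
        A=float(np.exp(res.intercept)),
        alpha=float(res.slope),
        window=(float(t_min), float(t_max)),
        r_squared=float(res.rvalue**2),
    )


def pearson_linear_fit(x: "np.ndarray | list", y: "np.ndarray | list") -> LinearFit:
    """OLS of y on x with the two-tailed Pearson significance test.

    ``r_squared`` is the squared Pearson correlation; ``p_two_tailed`` comes
    from the t-test on r with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise DataError("x and y must have equal length")
    if x.size < 3:
        raise DataError("linear fit needs at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("linear fit undefined for zero-variance input")
    res = stats.linregress(x, y)
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_two_tailed=float(res.pvalue),
    )


def adhesion_vs_amplitude_fit(
    data: dict[str, tuple[float, float]] | None = None,
) -> LinearFit:
    """Cross-strain OLS of vibration amplitude (nm) on adhesion force (nN)."""
    pairs = list((data or ADHESION_VIBRATION_DATA).values())
    forces = [p[0] for p in pairs]
    amplitudes = [p[1] for p in pairs]
    return pearson_linear_fit(forces, amplitudes)


def track_summary(
    track: PositionTrack,
    marker_amplitude: float = 0.0,
    msd_lags: int = MSD_N_LAGS,
    msd_starts: int = MSD_N_STARTS,
    msd_spacing: int = MSD_START_SPACING,
) -> dict:
    """Per-track summary: amplitude, autocorrelation half-time, alpha values."""
    out: dict[str, float | str] = {"label": track.label, "n_frames": track.n_frames}
    out["vibration_amplitude_nm"] = vibration_amplitude(track, marker_amplitude)
    try:
        curve = autocorrelation(track)
        out["autocorrelation_half_time_s"] = autocorrelation_half_time(curve)
    except DataError:
        out["autocorrelation_half_time_s"] = math.nan
    try:
        m = msd(track, n_lags=msd_lags, n_starts=msd_starts, start_spacing=msd_spacing)
        for name, window in (
            ("alpha_t_gt_1s", ALPHA_WINDOW_T1),
            ("alpha_t_gt_5s", ALPHA_WINDOW_T5),
            ("alpha_initial", ALPHA_WINDOW_INITIAL),
        ):
            try:
                out[name] = fit_power_law(m, window).alpha
            except DataError:
                out[name] = math.nan
    except DataError:
        out["alpha_t_gt_1s"] = out["alpha_t_gt_5s"] = out["alpha_initial"] = math.nan
    return out
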
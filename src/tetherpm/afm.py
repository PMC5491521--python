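"""Force-distance-curve metrics for single-bacterium contact probe AFM.

Retract-curve observables: adhesion force (strongest attractive force during
retraction), adhesion peaks (local minima marking rupture of individual
tethers), rupture length (separation at which the entire bond has detached)
and adhesion energy (area of the adhesive well).  A synthetic multi-tether
rupture-curve generator provides ground-truth curves for validation: each
tether is a Hookean spring that engages at its attachment offset and snaps
once loaded past its rupture force.

Sign convention: attractive (adhesive) forces are stored negative; all derived
metrics are reported as positive magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .errors import DataError, InvalidArgumentError

#: Instrument noise floor (nN) applied to the peak-prominence threshold so
#: that noiseless synthetic curves still get a finite detection threshold.
NOISE_FLOOR_NN = 1e-3

DEFAULT_MIN_PROMINENCE = 3.0  # multiples of the baseline noise SD


@dataclass(frozen=True)
class CantileverCalibration:
    """Optical-lever calibration: F_n = alpha_s * V_n * K_n."""

    deflection_sensitivity: float  # alpha_s, m/V
    stiffness: float  # K_n, N/m
    photodiode_voltage: float  # V_n, V

    def __post_init__(self) -> None:
        if self.deflection_sensitivity <= 0 or self.stiffness <= 0:
            raise InvalidArgumentError(
                "deflection sensitivity and stiffness must be positive"
            )


@dataclass
class ForceDistanceCurve:
    """Approach/retract force (nN) versus probe-surface separation (nm)."""

    separation: np.ndarray  # nm
    force: np.ndarray  # nN; negative = attractive
    segment: np.ndarray  # array of 'approach' / 'retract' per point

    def __post_init__(self) -> None:
        self.separation = np.asarray(self.separation, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.segment = np.asarray(self.segment)
        if not (self.separation.size == self.force.size == self.segment.size):
            raise DataError("separation, force and segment must have equal length")
        if not np.all(np.isfinite(self.separation)) or not np.all(np.isfinite(self.force)):
            raise DataError("force-distance curve contains non-finite values")

    def retract(self) -> tuple[np.ndarray, np.ndarray]:
        """(separation, force) of the retract segment, sorted by separation."""
        mask = self.segment == "retract"
        if not mask.any():
            raise DataError("curve has no retract segment")
        s = self.separation[mask]
        f = self.force[mask]
        order = np.argsort(s, kind="stable")
        return s[order], f[order]


@dataclass
class RetractAnalysis:
    adhesion_force: float  # nN, positive magnitude
    peaks: list[tuple[float, float]]  # (separation nm, force nN at the minimum)
    rupture_length: float  # nm
    adhesion_energy: float  # J, positive magnitude
    adhesion_energy_kbt: float  # same, in units of kT
    baseline: float  # nN
    noise_sd: float  # nN


@dataclass
class SyntheticCurveLedger:
    """Ground truth for a generated multi-tether curve."""

    rupture_separations: list[float]  # nm, per tether
    rupture_forces: list[float]  # nN, per tether
    total_energy: float  # J, sum of 1/2 k dx^2 over tethers
    n_tethers: int = 0
    extras: dict = field(default_factory=dict)


def normal_force(cal: CantileverCalibration) -> float:
    """Applied normal force (N) from the optical-lever calibration."""
    return cal.deflection_sensitivity * cal.photodiode_voltage * cal.stiffness


def estimate_baseline(curve: ForceDistanceCurve) -> tuple[float, float]:
    """Robust zero-force baseline from the far-separation retract tail.

    Baseline = median force of the final 10% of retract points (by
    separation); noise SD = 1.4826 * MAD of the same tail.
    """
    s, f = curve.retract()
    n_tail = max(int(round(0.1 * f.size)), 0)
    tail = f[-n_tail:] if n_tail else f[:0]
    if tail.size < 5:
        raise DataError("retract tail too short to estimate a baseline (< 5 points)")
    baseline = float(np.median(tail))
    noise_sd = float(1.4826 * np.median(np.abs(tail - baseline)))
    return baseline, noise_sd


def adhesion_force(curve: ForceDistanceCurve, baseline: float | None = None) -> float:
    """Magnitude (nN) of the strongest attractive force during retraction."""
    _, f = curve.retract()
    if baseline is None:
        baseline, _ = estimate_baseline(curve)
    return max(0.0, float(-(f - baseline).min()))


def _threshold(noise_sd: float, min_prominence: float) -> float:
    return min_prominence * max(noise_sd, NOISE_FLOOR_NN)


#: Boxcar width (samples) used to smooth the retract trace before event
#: detection.  Rupture peaks sit on ramps many samples wide and survive the
#: smoothing essentially unchanged, while single-sample noise excursions are
#: attenuated by sqrt(window) and no longer reach the 3-sigma threshold.
SMOOTH_WINDOW = 5


def _boxcar(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1 or values.size < window:
        return values
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(values, pad, mode="edge")
    return np.convolve(padded, kernel, mode="valid")[: values.size]


def detect_adhesion_peaks(
    curve: ForceDistanceCurve,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    baseline: float | None = None,
    noise_sd: float | None = None,
) -> list[tuple[float, float]]:
    """Local minima of the retract force marking individual tether ruptures.

    The baseline-subtracted retract trace is boxcar-smoothed, candidate
    minima must dip below ``baseline - min_prominence * noise_sd`` with at
    least that prominence, and each detection is snapped to the deepest raw
    sample in its neighborhood.  Returned as (separation nm, force nN)
    ordered by separation; may be empty.
    """
    s, f = curve.retract()
    if baseline is None or noise_sd is None:
        est_base, est_noise = estimate_baseline(curve)
        baseline = est_base if baseline is None else baseline
        noise_sd = est_noise if noise_sd is None else noise_sd
    thr = _threshold(noise_sd, min_prominence)
    inverted = -(f - baseline)  # adhesive well becomes positive peaks
    smooth = _boxcar(inverted, SMOOTH_WINDOW)
    idx, _ = find_peaks(smooth, height=thr, prominence=thr)
    # a curve ending mid-well (deepest point at the first retract sample)
    # is still a rupture event even though find_peaks needs interior points
    if smooth.size >= 2 and smooth[0] >= thr and smooth[0] > smooth[1]:
        idx = np.concatenate([[0], idx])
    peaks = []
    half = SMOOTH_WINDOW // 2
    for j in sorted(int(i) for i in idx):
        lo, hi = max(0, j - half), min(inverted.size, j + half + 1)
        snapped = lo + int(np.argmax(inverted[lo:hi]))
        peaks.append((float(s[snapped]), float(f[snapped])))
    return peaks


def rupture_length(
    curve: ForceDistanceCurve,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    peaks: list[tuple[float, float]] | None = None,
    baseline: float | None = None,
    noise_sd: float | None = None,
) -> float:
    """Separation (nm) at which the entire bond has detached.

    Taken as the first retract sample after the final adhesion peak at which
    the baseline-subtracted force has returned to within the peak-detection
    threshold of zero.  Returns 0.0 when no adhesion peak exists.
    """
    s, f = curve.retract()
    if baseline is None or noise_sd is None:
        est_base, est_noise = estimate_baseline(curve)
        baseline = est_base if baseline is None else baseline
        noise_sd = est_noise if noise_sd is None else noise_sd
    if peaks is None:
        peaks = detect_adhesion_peaks(
            curve, min_prominence, baseline=baseline, noise_sd=noise_sd
        )
    if not peaks:
        return 0.0
    last_sep = peaks[-1][0]
    thr = _threshold(noise_sd, min_prominence)
    after = np.nonzero(s >= last_sep)[0]
    for i in after:
        if -(f[i] - baseline) <= thr:
            return float(s[i])
    return float(s[-1])


def adhesion_energy(
    curve: ForceDistanceCurve,
    baseline: float | None = None,
    upper_separation: float | None = None,
    temperature: float = 298.0,
) -> tuple[float, float]:
    """Area (J) of the adhesive well under the retract curve, and in kT.

    Trapezoidal integral of ``max(0, -(force - baseline))`` over separation
    from contact (minimum separation) up to the rupture length (or the full
    retract range when no rupture length is given).
    """
    s, f = curve.retract()
    if baseline is None:
        baseline, _ = estimate_baseline(curve)
    well = np.clip(-(f - baseline), 0.0, None)
    if upper_separation is not None:
        mask = s <= upper_separation
        s, well = s[mask], well[mask]
    if s.size < 2:
        return 0.0, 0.0
    energy_nn_nm = float(np.trapezoid(well, s))
    energy_j = energy_nn_nm * 1e-18  # nN * nm = 1e-18 J
    kbt = 1.380649e-23 * temperature
    return energy_j, energy_j / kbt


def analyze_retract(
    curve: ForceDistanceCurve,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    temperature: float = 298.0,
) -> RetractAnalysis:
    """Full retract-curve analysis bundle."""
    baseline, noise_sd = estimate_baseline(curve)
    peaks = detect_adhesion_peaks(
        curve, min_prominence, baseline=baseline, noise_sd=noise_sd
    )
    rl = rupture_length(
        curve, min_prominence, peaks=peaks, baseline=baseline, noise_sd=noise_sd
    )
    upper = rl if peaks else None
    energy_j, energy_kbt = adhesion_energy(
        curve, baseline=baseline, upper_separation=upper, temperature=temperature
    )
    return RetractAnalysis(
        adhesion_force=adhesion_force(curve, baseline=baseline),
        peaks=peaks,
        rupture_length=rl,
        adhesion_energy=energy_j,
        adhesion_energy_kbt=energy_kbt,
        baseline=baseline,
        noise_sd=noise_sd,
    )


def synth_fd_curve(
    n_tethers: int,
    k: float,
    rupture_forces: "list[float] | np.ndarray",
    attachment_offsets: "list[float] | np.ndarray",
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    sample_spacing: float = 0.25,
    tail_fraction: float = 0.3,
) -> tuple[ForceDistanceCurve, SyntheticCurveLedger]:
    """Synthetic retract curve from parallel Hookean tethers.

    Tether ``i`` (spring constant ``k`` in N/m = nN/nm) engages once the
    separation exceeds ``attachment_offsets[i]`` (nm) and contributes force
    ``-k (s - o_i)`` until the load crosses ``rupture_forces[i]`` (N), where
    it snaps to zero.  Gaussian noise of SD ``noise_sd`` (nN) is added, and a
    flat approach segment is included.  Returns the curve and a ground-truth
    ledger (per-tether rupture separations and the analytic elastic energy
    ``sum_i F_i^2 / 2k``).
    """
    rupture_forces = np.asarray(rupture_forces, dtype=float)
    attachment_offsets = np.asarray(attachment_offsets, dtype=float)
    if rupture_forces.size != n_tethers or attachment_offsets.size != n_tethers:
        raise InvalidArgumentError(
            "rupture_forces and attachment_offsets must each have n_tethers entries"
        )
    if n_tethers and (np.any(rupture_forces <= 0) or np.any(attachment_offsets < 0)):
        raise InvalidArgumentError("rupture forces must be positive, offsets >= 0")
    rng = rng or np.random.default_rng()
    k_nn_nm = k * 1e9 / 1e9  # N/m == nN/nm numerically
    f_nn = rupture_forces * 1e9
    if n_tethers:
        rupture_seps = attachment_offsets + f_nn / k_nn_nm
        s_max = float(rupture_seps.max()) * (1.0 + tail_fraction) + 10.0
    else:
        rupture_seps = np.empty(0)
        s_max = 100.0
    s = np.arange(0.0, s_max + sample_spacing, sample_spacing)
    force = np.zeros_like(s)
    for o, s_rup in zip(attachment_offsets, rupture_seps):
        engaged = (s > o) & (s <= s_rup + 1e-12)
        force[engaged] -= k_nn_nm * (s[engaged] - o)
    deepest = float(-force.min()) if s.size else 0.0
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, size=s.size)
    approach = np.zeros_like(s)
    if noise_sd > 0:
        approach = approach + rng.normal(0.0, noise_sd, size=s.size)
    separation = np.concatenate([s[::-1], s])
    forces = np.concatenate([approach[::-1], force])
    segment = np.array(["approach"] * s.size + ["retract"] * s.size)
    curve = ForceDistanceCurve(separation=separation, force=forces, segment=segment)
    total_energy = float(np.sum((rupture_forces**2) / (2.0 * k))) if n_tethers else 0.0
    ledger = SyntheticCurveLedger(
        rupture_separations=[float(v) for v in rupture_seps],
        rupture_forces=[float(v) for v in f_nn],
        total_energy=total_energy,
        n_tethers=n_tethers,
        extras={
            "sample_spacing": sample_spacing,
            "k_nN_per_nm": k_nn_nm,
            "deepest_force_nN": deepest,
        },
    )
    return curve, ledger
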
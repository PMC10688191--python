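"""Angular densities of states and the 14-feature switch descriptor.

A DoS is the normalized histogram of one three-atom angle over all pooled
trajectory frames, on equal-width bins spanning [0, pi].  A residue angle
is a *switch* when its DoS is bimodal with no populated intermediate
state between the two modes.  The feature vector summarizes mode
structure (counts, locations, heights, widths, valley depth, mass split)
plus distribution shape (variance, skewness, bimodality coefficient) and
feeds the supervised switch classifiers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
from scipy.signal import find_peaks

from .geometry import AngleSeries

__all__ = [
    "AngleDoS",
    "Mode",
    "ModeSet",
    "DoSFeatureVector",
    "SwitchLabel",
    "FEATURE_NAMES",
    "build_dos",
    "smooth_dos",
    "find_modes",
    "extract_features",
    "heuristic_label",
]

#: defaults, overridable through every public function below
DEFAULT_N_BINS = 90          # 2 degrees per bin over [0, pi]
DEFAULT_SMOOTH_WINDOW = 5    # bins, centered moving average
DEFAULT_MIN_PROMINENCE = 0.05   # fraction of the tallest bin
DEFAULT_MIN_SEPARATION_BINS = 5
DEFAULT_VALLEY_RATIO_MAX = 0.5  # heuristic label: valley / minor peak
DEFAULT_MINOR_MASS_MIN = 0.05   # heuristic label: minor-side mass floor


@dataclass
class AngleDoS:
    """Normalized histogram of one angle series over [0, pi]."""

    bin_edges: np.ndarray
    mass: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.mass.size != self.bin_edges.size - 1:
            raise ValueError("mass must have one entry per bin")
        if self.n_frames < 1:
            raise ValueError("a DoS needs at least one source frame")
        if abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError("DoS mass must sum to 1")

    @property
    def n_bins(self) -> int:
        return self.mass.size

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])


@dataclass(frozen=True)
class Mode:
    """One local maximum of a DoS."""

    location: float   # bin center, radians
    height: float     # mass in the peak bin
    mass: float       # mass of the basin belonging to this mode
    fwhm: float       # full width at half maximum, radians
    bin: int


@dataclass(frozen=True)
class ModeSet:
    modes: tuple[Mode, ...]          # sorted by height desc, ties by lower bin
    valley_height: float             # min mass between the two tallest modes
    valley_bin: int                  # -1 when fewer than two modes

    @property
    def n_modes(self) -> int:
        return len(self.modes)


@dataclass(frozen=True)
class SwitchLabel:
    """Binary switch annotation: 1 = bimodal with no intermediate state."""

    value: int
    source: str  # manual | synthetic_truth | heuristic

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise ValueError("switch label must be 0 or 1")
        if self.source not in ("manual", "synthetic_truth", "heuristic"):
            raise ValueError(f"unknown label source {self.source!r}")


FEATURE_NAMES: tuple[str, ...] = (
    "n_modes",
    "major_mode_loc",
    "minor_mode_loc",
    "mode_separation",
    "major_height",
    "minor_height",
    "height_ratio",
    "valley_ratio",
    "minor_mass_fraction",
    "major_fwhm",
    "minor_fwhm",
    "sample_variance",
    "sample_skewness",
    "bimodality_coefficient",
)


@dataclass(frozen=True)
class DoSFeatureVector:
    n_modes: float
    major_mode_loc: float
    minor_mode_loc: float
    mode_separation: float
    major_height: float
    minor_height: float
    height_ratio: float
    valley_ratio: float
    minor_mass_fraction: float
    major_fwhm: float
    minor_fwhm: float
    sample_variance: float
    sample_skewness: float
    bimodality_coefficient: float

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not math.isfinite(v):
                raise ValueError(f"feature {f.name} is not finite: {v}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in FEATURE_NAMES}


# ---------------------------------------------------------------------------
# Histogram construction and smoothing
# ---------------------------------------------------------------------------

def build_dos(series: AngleSeries | np.ndarray, n_bins: int = DEFAULT_N_BINS) -> AngleDoS:
    """Bin an angle series into a normalized DoS on [0, pi].

    Values exactly at pi fall in the last bin (numpy's closed right edge).
    """
    values = series.values if isinstance(series, AngleSeries) else np.asarray(series, float)
    if values.size == 0:
        raise ValueError("cannot build a DoS from an empty series")
    if n_bins < 2:
        raise ValueError("n_bins must be at least 2")
    edges = np.linspace(0.0, math.pi, n_bins + 1)
    counts, _ = np.histogram(values, bins=edges)
    return AngleDoS(edges, counts / counts.sum(), n_frames=values.size)


def smooth_dos(dos: AngleDoS, window: int = DEFAULT_SMOOTH_WINDOW) -> AngleDoS:
    """Centered moving average with reflective ends; total mass preserved."""
    if window % 2 == 0 or window < 1:
        raise ValueError("smoothing window must be odd and >= 1")
    if window == 1:
        return AngleDoS(dos.bin_edges.copy(), dos.mass.copy(), dos.n_frames)
    half = window // 2
    padded = np.r_[dos.mass[half - 1 :: -1] if half else [], dos.mass, dos.mass[: -half - 1 : -1]]
    kernel = np.full(window, 1.0 / window)
    sm = np.convolve(padded, kernel, mode="valid")
    sm /= sm.sum()  # guard against float drift; reflection preserves mass
    return AngleDoS(dos.bin_edges.copy(), sm, dos.n_frames)


# ---------------------------------------------------------------------------
# Mode detection
# ---------------------------------------------------------------------------

def find_modes(
    dos: AngleDoS,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation_bins: int = DEFAULT_MIN_SEPARATION_BINS,
) -> ModeSet:
    """Detect DoS modes: prominent local maxima at least ``min_separation_bins`` apart.

    Prominence is measured as a fraction of the tallest bin.  Modes are
    returned sorted by height descending, ties broken by lower bin index.
    """
    m = dos.mass
    padded = np.r_[0.0, m, 0.0]  # zero pad so edge bins can be maxima
    prom = max(min_prominence * m.max(), 1e-15)
    peaks, _ = find_peaks(padded, prominence=prom, distance=max(1, min_separation_bins))
    peaks = peaks - 1

    if peaks.size == 0:  # degenerate flat input
        peaks = np.array([int(np.argmax(m))])

    order = sorted(range(peaks.size), key=lambda i: (-m[peaks[i]], peaks[i]))
    peaks_by_height = peaks[order]

    # basin boundaries: minimum between consecutive peaks in bin order
    by_bin = np.sort(peaks)
    cuts = [0]
    for p, q in zip(by_bin, by_bin[1:]):
        cuts.append(p + int(np.argmin(m[p : q + 1])))
    cuts.append(m.size)
    basin_mass = {
        int(p): float(m[lo:hi].sum()) for p, lo, hi in zip(by_bin, cuts[:-1], cuts[1:])
    }

    centers = dos.bin_centers
    width = dos.bin_width
    modes = tuple(
        Mode(
            location=float(centers[p]),
            height=float(m[p]),
            mass=basin_mass[int(p)],
            fwhm=_fwhm(m, int(p), width),
            bin=int(p),
        )
        for p in peaks_by_height
    )

    if len(modes) >= 2:
        b0, b1 = sorted((modes[0].bin, modes[1].bin))
        vb = b0 + int(np.argmin(m[b0 : b1 + 1]))
        return ModeSet(modes, float(m[vb]), int(vb))
    return ModeSet(modes, 0.0, -1)


def _fwhm(mass: np.ndarray, peak: int, bin_width: float) -> float:
    """Full width at half maximum around one peak, linearly interpolated."""
    half = mass[peak] / 2.0
    left = 0.0
    i = peak
    while i > 0 and mass[i - 1] >= half:
        i -= 1
    if i == 0 and mass[0] >= half:
        left = float(peak)  # clipped at the edge
    else:
        # crossing between bins i-1 and i
        left = (peak - i) + (half - mass[i]) / (mass[i - 1] - mass[i]) if i > 0 else float(peak)
        left = min(max(left, 0.0), float(peak))
    right = 0.0
    j = peak
    n = mass.size
    while j < n - 1 and mass[j + 1] >= half:
        j += 1
    if j == n - 1 and mass[n - 1] >= half:
        right = float(n - 1 - peak)
    else:
        right = (j - peak) + (half - mass[j]) / (mass[j + 1] - mass[j]) if j < n - 1 else float(n - 1 - peak)
        right = min(max(right, 0.0), float(n - 1 - peak))
    return (left + right) * bin_width


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def extract_features(
    dos: AngleDoS,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation_bins: int = DEFAULT_MIN_SEPARATION_BINS,
) -> DoSFeatureVector:
    """Compute the 14-feature descriptor from the smoothed DoS.

    Single-mode densities take sentinel values for the minor-mode block:
    zero separation, zero minor height/width/mass, and the minor location
    pinned to the major location.
    """
    sm = smooth_dos(dos, smooth_window)
    ms = find_modes(sm, min_prominence, min_separation_bins)

    centers = sm.bin_centers
    w = sm.mass
    mu = float(np.sum(w * centers))
    var = float(np.sum(w * (centers - mu) ** 2))
    if var > 1e-18:
        skew = float(np.sum(w * (centers - mu) ** 3) / var**1.5)
        kurt = float(np.sum(w * (centers - mu) ** 4) / var**2)
        bc = (skew**2 + 1.0) / kurt
    else:
        skew, bc = 0.0, 0.0

    major = ms.modes[0]
    if ms.n_modes >= 2:
        minor = ms.modes[1]
        lo_bin = min(major.bin, minor.bin)
        minor_side_mass = min(major.mass, minor.mass)
        # basins of the top-two modes may not exhaust the mass when a third
        # mode exists; clamp to the invariant range [0, 0.5]
        minor_side_mass = min(max(minor_side_mass, 0.0), 0.5)
        return DoSFeatureVector(
            n_modes=float(ms.n_modes),
            major_mode_loc=major.location,
            minor_mode_loc=minor.location,
            mode_separation=abs(major.location - minor.location),
            major_height=major.height,
            minor_height=minor.height,
            height_ratio=minor.height / major.height if major.height > 0 else 0.0,
            valley_ratio=ms.valley_height / minor.height if minor.height > 0 else 0.0,
            minor_mass_fraction=minor_side_mass,
            major_fwhm=major.fwhm,
            minor_fwhm=minor.fwhm,
            sample_variance=var,
            sample_skewness=skew,
            bimodality_coefficient=bc,
        )
    return DoSFeatureVector(
        n_modes=float(ms.n_modes),
        major_mode_loc=major.location,
        minor_mode_loc=major.location,
        mode_separation=0.0,
        major_height=major.height,
        minor_height=0.0,
        height_ratio=0.0,
        valley_ratio=0.0,
        minor_mass_fraction=0.0,
        major_fwhm=major.fwhm,
        minor_fwhm=0.0,
        sample_variance=var,
        sample_skewness=skew,
        bimodality_coefficient=bc,
    )


def heuristic_label(
    dos: AngleDoS,
    valley_ratio_max: float = DEFAULT_VALLEY_RATIO_MAX,
    minor_mass_min: float = DEFAULT_MINOR_MASS_MIN,
    smooth_window: int = DEFAULT_SMOOTH_WINDOW,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    min_separation_bins: int = DEFAULT_MIN_SEPARATION_BINS,
) -> SwitchLabel:
    """Rule-based switch call: exactly two modes, an empty valley, and a
    non-negligible minor state.  A labeling aid, not the trained classifier.
    """
    fv = extract_features(dos, smooth_window, min_prominence, min_separation_bins)
    is_switch = (
        fv.n_modes == 2.0
        and fv.valley_ratio < valley_ratio_max
        and fv.minor_mass_fraction > minor_mass_min
    )
    return SwitchLabel(int(is_switch), "heuristic")
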
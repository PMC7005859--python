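"""DIA isolation schemes, XIC extraction, peak groups and pseudo-DDA spectra.

The DIA run model is deliberately simple: a run is a time-ordered list of
centroided :class:`SpectrumRecord` objects, MS1 scans interleaved with one
MS2 scan per isolation window. Extraction slices those scans into
chromatograms; peak-group detection finds co-eluting fragment apexes;
3D feature detection plus precursor-fragment grouping turns a library-free
DIA run into pseudo-DDA spectra (the directDIA route).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter
from scipy.stats import pearsonr

__all__ = [
    "IsolationWindow", "SpectrumRecord", "Chromatogram", "PeakGroup",
    "Feature3D", "PseudoSpectrum", "WindowObservation",
    "build_window_scheme", "assign_windows", "extract_xic",
    "detect_peak_groups", "detect_3d_features", "build_pseudo_spectra",
    "window_diagnostics",
]


@dataclass(frozen=True)
class IsolationWindow:
    index: int
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if self.upper <= self.lower:
            raise ValueError("window upper bound must exceed lower bound")

    @property
    def center(self) -> float:
        return 0.5 * (self.lower + self.upper)

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, mz: float) -> bool:
        # closed on both ends so a 1-Da overlap region double-assigns
        return self.lower <= mz <= self.upper


@dataclass
class SpectrumRecord:
    """One centroided scan: parallel (m/z, intensity) arrays, rt in seconds."""

    ms_level: int
    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    window: IsolationWindow | None = None

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must be parallel")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            order = np.argsort(self.mz)
            self.mz, self.intensity = self.mz[order], self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity")
        if self.ms_level == 2 and self.window is None:
            raise ValueError("MS2 scan requires an isolation window")


@dataclass
class Chromatogram:
    target_mz: float
    tolerance_ppm: float
    rt: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.rt = np.asarray(self.rt, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.rt.shape != self.intensity.shape:
            raise ValueError("rt grid and intensities must be parallel")
        if self.rt.size > 1 and not np.all(np.diff(self.rt) > 0):
            raise ValueError("rt grid must be strictly increasing")


@dataclass
class PeakGroup:
    apex_rt: float
    left_rt: float
    right_rt: float
    fragment_areas: dict[int, float]           # xic index -> integrated area
    consensus_profile: np.ndarray              # summed trace over boundary grid
    rt_grid: np.ndarray
    quality_score: float

    def __post_init__(self) -> None:
        if not self.left_rt < self.apex_rt < self.right_rt:
            raise ValueError("apex must lie strictly inside boundaries")


@dataclass
class Feature3D:
    mz: float
    rt_start: float
    rt_end: float
    apex_intensity: float
    scan_indices: list[int] = field(default_factory=list)
    intensities: list[float] = field(default_factory=list)


@dataclass
class PseudoSpectrum:
    precursor: Feature3D
    fragment_mz: np.ndarray
    fragment_intensity: np.ndarray
    window_index: int


def build_window_scheme(start: float, width: float, overlap: float,
                        count: int) -> list[IsolationWindow]:
    """Sequential isolation windows; window i covers start + i*(width-overlap)
    to that plus width. The benchmark instrument method is 48 windows of
    14 Da with 1 Da overlap starting at 350 m/z."""
    if overlap >= width:
        raise ValueError("overlap must be smaller than window width")
    if overlap < 0 or count < 1:
        raise ValueError("overlap must be >= 0 and count >= 1")
    step = width - overlap
    return [IsolationWindow(i, start + i * step, start + i * step + width)
            for i in range(count)]


def assign_windows(mz: float, scheme: list[IsolationWindow]) -> set[int]:
    """Indices of all windows whose closed interval contains mz (two in an
    overlap region, empty if out of range)."""
    if not scheme:
        raise ValueError("empty window scheme")
    return {w.index for w in scheme if w.contains(mz)}


def _match_intensity(scan: SpectrumRecord, target_mz: float, tol_ppm: float) -> float:
    tol = target_mz * tol_ppm * 1e-6
    lo = np.searchsorted(scan.mz, target_mz - tol, side="left")
    hi = np.searchsorted(scan.mz, target_mz + tol, side="right")
    return float(scan.intensity[lo:hi].sum())


def extract_xic(run: list[SpectrumRecord], target_mz: float, tolerance_ppm: float = 20.0,
                window_index: int | None = None,
                rt_range: tuple[float, float] | None = None) -> Chromatogram:
    """Extracted ion chromatogram of one target m/z.

    With a window index, only MS2 scans of that window contribute (one grid
    point per scan); with ``window_index=None`` the MS1 scans are used.
    Scans with no matching peak contribute intensity 0, never a gap.
    """
    if window_index is None:
        scans = [s for s in run if s.ms_level == 1]
    else:
        scans = [s for s in run if s.ms_level == 2 and s.window is not None
                 and s.window.index == window_index]
        if not scans:
            raise ValueError(f"no MS2 scans for window {window_index}")
    if rt_range is not None:
        scans = [s for s in scans if rt_range[0] <= s.rt <= rt_range[1]]
    rt = np.array([s.rt for s in scans])
    inten = np.array([_match_intensity(s, target_mz, tolerance_ppm) for s in scans])
    return Chromatogram(target_mz, tolerance_ppm, rt, inten)


def _smooth(trace: np.ndarray, window: int = 5, order: int = 2) -> np.ndarray:
    if trace.size < window:
        return trace.copy()
    return np.clip(savgol_filter(trace, window, order), 0.0, None)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    if a.size < 2 or np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(pearsonr(a, b)[0])


def spectral_contrast_angle(a: np.ndarray, b: np.ndarray) -> float:
    """1 - 2*theta/pi for the angle theta between two nonnegative intensity
    vectors; 1 for identical relative intensities, 0 for orthogonal."""
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    cos = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(1.0 - 2.0 * np.arccos(cos) / np.pi)


def detect_peak_groups(xics: list[Chromatogram],
                       library_intensities: np.ndarray | None = None,
                       noise_floor_frac: float = 0.05) -> list[PeakGroup]:
    """Candidate peak groups on the summed fragment trace.

    Apexes are local maxima of the Savitzky-Golay-smoothed summed trace above
    ``noise_floor_frac`` of its maximum; boundaries extend to the nearest
    flanking minima. The quality score blends how well integrated fragment
    areas match the library's relative intensities (spectral contrast angle)
    with the mean pairwise Pearson correlation of the fragment traces —
    co-elution plus library agreement.
    """
    if not xics:
        raise ValueError("need at least one chromatogram")
    grid = xics[0].rt
    for x in xics[1:]:
        if x.rt.shape != grid.shape or not np.allclose(x.rt, grid):
            raise ValueError("chromatograms must share a common rt grid")
    traces = np.vstack([x.intensity for x in xics])
    summed = _smooth(traces.sum(axis=0))
    if summed.max() <= 0:
        return []
    floor = noise_floor_frac * summed.max()

    apexes = [i for i in range(1, len(summed) - 1)
              if summed[i] >= summed[i - 1] and summed[i] > summed[i + 1]
              and summed[i] > floor]
    groups: list[PeakGroup] = []
    for apex in apexes:
        left = apex
        while left > 0 and summed[left - 1] < summed[left]:
            left -= 1
        right = apex
        while right < len(summed) - 1 and summed[right + 1] < summed[right]:
            right += 1
        # plateau apexes can leave a boundary on the apex sample; widen by one
        if left == apex and left > 0:
            left -= 1
        if right == apex and right < len(summed) - 1:
            right += 1
        if right - left < 2:
            continue
        sl = slice(left, right + 1)
        areas = {i: float(np.trapezoid(traces[i, sl], grid[sl])) for i in range(len(xics))}
        area_vec = np.array([areas[i] for i in range(len(xics))])
        if library_intensities is not None:
            sca = spectral_contrast_angle(area_vec, np.asarray(library_intensities, float))
        else:
            sca = 1.0
        sub = traces[:, sl]
        active = [i for i in range(len(xics)) if sub[i].max() > 0]
        if len(active) >= 2:
            cors = [_pearson(sub[i], sub[j]) for k, i in enumerate(active)
                    for j in active[k + 1:]]
            mean_cor = float(np.mean(cors))
        else:
            mean_cor = 1.0 if active else 0.0
        groups.append(PeakGroup(
            apex_rt=float(grid[apex]), left_rt=float(grid[left]), right_rt=float(grid[right]),
            fragment_areas=areas, consensus_profile=summed[sl].copy(), rt_grid=grid[sl].copy(),
            quality_score=0.5 * sca + 0.5 * mean_cor))
    groups.sort(key=lambda g: (-g.quality_score, g.apex_rt))
    return groups


def detect_3d_features(ms1_scans: list[SpectrumRecord], tolerance_ppm: float = 10.0,
                       intensity_threshold: float = 0.0, gap_limit: int = 1,
                       min_span: int = 3) -> list[Feature3D]:
    """Connect per-scan centroid peaks into 3D (m/z, rt, intensity) features.

    Peaks above the intensity threshold in consecutive MS1 scans are linked
    when within the ppm tolerance, allowing up to ``gap_limit`` missing
    scans; chains spanning fewer than ``min_span`` scans are dropped.
    """
    scans = [s for s in ms1_scans if s.ms_level == 1]
    open_chains: list[dict] = []   # {'mz', 'scans', 'intens', 'rts', 'last'}
    closed: list[dict] = []

    for si, scan in enumerate(scans):
        mask = scan.intensity > intensity_threshold
        peaks = list(zip(scan.mz[mask], scan.intensity[mask]))
        used = set()
        still_open = []
        for chain in open_chains:
            if si - chain["last"] > gap_limit + 1:
                closed.append(chain)
                continue
            tol = chain["mz"] * tolerance_ppm * 1e-6
            best, best_d = None, tol
            for pi, (mz, inten) in enumerate(peaks):
                if pi in used:
                    continue
                d = abs(mz - chain["mz"])
                if d <= best_d:
                    best, best_d = pi, d
            if best is not None:
                mz, inten = peaks[best]
                used.add(best)
                chain["mz"] = 0.5 * (chain["mz"] + mz)
                chain["scans"].append(si)
                chain["intens"].append(inten)
                chain["rts"].append(scan.rt)
                chain["last"] = si
            still_open.append(chain)
        open_chains = still_open
        for pi, (mz, inten) in enumerate(peaks):
            if pi not in used:
                open_chains.append({"mz": mz, "scans": [si], "intens": [inten],
                                    "rts": [scan.rt], "last": si})
    closed.extend(open_chains)

    features = []
    for chain in closed:
        if len(chain["scans"]) < min_span:
            continue
        features.append(Feature3D(
            mz=float(chain["mz"]), rt_start=float(chain["rts"][0]),
            rt_end=float(chain["rts"][-1]),
            apex_intensity=float(max(chain["intens"])),
            scan_indices=chain["scans"], intensities=chain["intens"]))
    features.sort(key=lambda f: (f.rt_start, f.mz))
    return features


def build_pseudo_spectra(features: list[Feature3D], run: list[SpectrumRecord],
                         scheme: list[IsolationWindow], tolerance_ppm: float = 20.0,
                         r_min: float = 0.8) -> list[PseudoSpectrum]:
    """Pseudo-DDA spectra: fragments co-eluting with each 3D precursor feature.

    For every feature, fragment XICs are extracted in its isolation window
    over its rt span; peaks whose trace correlates with the feature's MS1
    elution profile at Pearson r >= ``r_min`` become pseudo-spectrum peaks at
    their apex intensity. A fragment m/z claimed by several overlapping
    features goes to the one with which it correlates best.
    """
    # candidate fragment m/z per window: union of peak m/z, clustered at tol
    claims: dict[tuple[int, int], tuple[int, float, float]] = {}
    frag_cache: dict[tuple[int, int], tuple[float, float]] = {}

    for fi, feat in enumerate(features):
        windows = assign_windows(feat.mz, scheme)
        profile = np.asarray(feat.intensities, float)
        for wi in windows:
            scans = [s for s in run if s.ms_level == 2 and s.window is not None
                     and s.window.index == wi
                     and feat.rt_start <= s.rt <= feat.rt_end]
            if len(scans) < 3:
                continue
            all_mz = np.sort(np.concatenate([s.mz for s in scans])) if scans else np.array([])
            # cluster peak m/z to candidate fragment targets
            targets: list[float] = []
            for mz in all_mz:
                if targets and (mz - targets[-1]) <= targets[-1] * tolerance_ppm * 1e-6:
                    continue
                targets.append(float(mz))
            for tmz in targets:
                trace = np.array([_match_intensity(s, tmz, tolerance_ppm) for s in scans])
                if trace.max() <= 0:
                    continue
                n = min(len(trace), len(profile))
                r = _pearson(trace[:n], profile[:n])
                if r < r_min:
                    continue
                key = (wi, int(round(tmz * 1e4)))
                prev = claims.get(key)
                if prev is None or r > prev[1]:
                    claims[key] = (fi, r, float(trace.max()))
                    frag_cache[key] = (tmz, float(trace.max()))

    by_feature: dict[int, list[tuple[float, float]]] = {}
    windows_of: dict[int, int] = {}
    for key, (fi, _r, apex) in claims.items():
        tmz, _ = frag_cache[key]
        by_feature.setdefault(fi, []).append((tmz, apex))
        windows_of[fi] = key[0]

    out = []
    for fi, peaks in sorted(by_feature.items()):
        peaks.sort()
        mz = np.array([p[0] for p in peaks])
        inten = np.array([p[1] for p in peaks])
        out.append(PseudoSpectrum(precursor=features[fi], fragment_mz=mz,
                                  fragment_intensity=inten, window_index=windows_of[fi]))
    return out


@dataclass(frozen=True)
class WindowObservation:
    """One precursor seen in two half-window-shifted schemes: once near the
    window center, once near an edge."""

    mz: float
    window: IsolationWindow
    intensity_center: float
    intensity_extreme: float


def window_diagnostics(observations: list[WindowObservation]) -> list[tuple[float, float]]:
    """(transmission, centerness) per precursor.

    Transmission is the extreme-position intensity over the center-position
    intensity of the same precursor; centerness is the precursor's distance
    from the window center over the half window width (0 at center, 1 at the
    edge). Observations with zero center intensity are skipped.
    """
    out = []
    for obs in observations:
        if obs.intensity_center == 0:
            import warnings
            warnings.warn(f"precursor {obs.mz:.4f}: zero center intensity, skipped")
            continue
        transmission = obs.intensity_extreme / obs.intensity_center
        centerness = abs(obs.mz - obs.window.center) / (obs.window.width / 2.0)
        out.append((float(transmission), float(centerness)))
    return out
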
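"""Weighted fragment evidence and fractional phosphosite confidences.

The localization score works per precursor and per detected peak group:

1. every positional isomer of the precursor is enumerated;
2. the union of their theoretical fragment masses is deduplicated, and each
   unique mass is annotated per candidate as confirming, refuting or neutral;
3. each unique mass is looked up in the run — its XIC over the peak-group
   boundaries yields an observed flag, an intensity component, a mass-accuracy
   component, an XIC-shape correlation against the group consensus profile and
   (optionally) an isotope-pattern component; the fragment weight is the
   product of the clamped components, so any failing aspect vetoes the
   fragment, and fragments whose elution shape does not track the consensus
   are removed outright as interference;
4. each candidate scores the sum of its observed confirming weights minus its
   observed refuting weights (floored at zero), and candidate scores are
   normalized to fractional confidences;
5. per-residue site confidences sum the fractions of all candidates placing a
   phospho on that residue; residues at or above the Class I threshold
   (0.75 with a spectral library, 0.99 library-free) are accepted calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import chem
from .dia_extraction import PeakGroup, SpectrumRecord, extract_xic, _pearson
from .peptide_model import (ModifiedPeptide, SiteCandidate, UniqueMass,
                            enumerate_site_candidates,
                            site_determining_fragment_sets)

__all__ = [
    "LocalizationConfig", "FragmentEvidence", "CandidateScore",
    "SiteConfidenceTable", "score_fragment_evidence", "score_candidates",
    "site_confidences", "localize_precursor",
]

CLASS1_THRESHOLD = 0.75          # library-based analysis
CLASS1_THRESHOLD_LIBFREE = 0.99  # directDIA (library-free) analysis


@dataclass(frozen=True)
class LocalizationConfig:
    tolerance_ppm: float = 20.0
    sigma_ppm: float = 10.0       # mass-accuracy Gaussian width
    r_min: float = 0.25           # interference-removal correlation cutoff
    noise_floor_frac: float = 0.01  # of the strongest fragment apex in the group
    intensity_decades: float = 3.0  # dynamic range of the log-intensity component
    use_isotopes: bool = True
    combination: str = "product"  # 'product' | 'mean'
    fragment_charges: tuple[int, ...] = (1, 2)
    neutral_losses_as_evidence: bool = False


@dataclass
class FragmentEvidence:
    unique_mass: UniqueMass
    observed: bool
    intensity_component: float = 0.0
    mass_accuracy_component: float = 0.0
    xic_correlation_component: float = 0.0
    isotope_component: float = 1.0
    weight: float = 0.0


@dataclass
class CandidateScore:
    candidate: SiteCandidate
    raw_score: float
    fractional_confidence: float


@dataclass
class SiteConfidenceTable:
    """Per-residue localization confidences for one precursor.

    Residue confidences sum to the phospho count; a residue belonging to no
    candidate has confidence 0.
    """

    confidences: dict[int, float]
    threshold: float = CLASS1_THRESHOLD
    class1_positions: tuple[int, ...] = field(default=())

    def __post_init__(self) -> None:
        self.class1_positions = tuple(sorted(
            pos for pos, c in self.confidences.items() if c >= self.threshold))


def _combine(components: list[float], strategy: str) -> float:
    clamped = [min(max(c, 0.0), 1.0) for c in components]
    if strategy == "mean":
        return float(np.mean(clamped))
    return float(np.prod(clamped))


def _observed_centroid(scan: SpectrumRecord, target_mz: float, tol_ppm: float) -> float | None:
    tol = target_mz * tol_ppm * 1e-6
    lo = np.searchsorted(scan.mz, target_mz - tol, side="left")
    hi = np.searchsorted(scan.mz, target_mz + tol, side="right")
    if hi <= lo or scan.intensity[lo:hi].sum() == 0:
        return None
    return float(np.average(scan.mz[lo:hi], weights=scan.intensity[lo:hi]))


def score_fragment_evidence(unique_masses: list[UniqueMass], peak_group: PeakGroup,
                            run: list[SpectrumRecord], window_index: int,
                            config: LocalizationConfig = LocalizationConfig(),
                            precursor_neutral_mass: float | None = None,
                            ) -> list[FragmentEvidence]:
    """Score every unique fragment mass against the run inside one peak group.

    Components (each in [0, 1] after clamping):

    * intensity — ``1 + log10(apex / max_apex) / decades``: 1 for the
      strongest fragment, 0 for anything ``decades`` orders of magnitude
      down. A pure function of the intensity ratio, so globally rescaling the
      run leaves it unchanged.
    * mass accuracy — ``exp(-(ppm / sigma)^2 / 2)`` of the intensity-weighted
      observed centroid at the apex scan.
    * XIC correlation — Pearson r of the fragment trace against the group's
      consensus profile; traces below ``r_min`` are interference and their
      weight is forced to 0.
    * isotope (optional) — agreement of the observed M+1/M+0 ratio with the
      averagine expectation at the fragment's mass.

    The fragment weight is the product (or mean) of the clamped components;
    unobserved fragments weigh 0.
    """
    if not unique_masses:
        raise ValueError("empty unique-mass table")

    scans = [s for s in run if s.ms_level == 2 and s.window is not None
             and s.window.index == window_index
             and peak_group.left_rt <= s.rt <= peak_group.right_rt]
    rt_range = (peak_group.left_rt, peak_group.right_rt)

    traces = []
    for um in unique_masses:
        xic = extract_xic(run, um.mz, config.tolerance_ppm, window_index, rt_range)
        traces.append(xic.intensity)
    apexes = np.array([t.max() if t.size else 0.0 for t in traces])
    max_apex = apexes.max() if apexes.size else 0.0
    floor = config.noise_floor_frac * max_apex

    evidence = []
    for um, trace, apex in zip(unique_masses, traces, apexes):
        ev = FragmentEvidence(unique_mass=um, observed=bool(apex > floor and apex > 0))
        if not ev.observed:
            evidence.append(ev)
            continue
        # intensity: scale-invariant log-ratio over a fixed dynamic range
        ev.intensity_component = float(np.clip(
            1.0 + np.log10(apex / max_apex) / config.intensity_decades, 0.0, 1.0))
        # mass accuracy at the apex scan
        apex_scan = scans[int(np.argmax(trace))] if scans else None
        ppm = 0.0
        if apex_scan is not None:
            cen = _observed_centroid(apex_scan, um.mz, config.tolerance_ppm)
            if cen is not None:
                ppm = (cen - um.mz) / um.mz * 1e6
        ev.mass_accuracy_component = float(np.exp(-0.5 * (ppm / config.sigma_ppm) ** 2))
        # elution-shape agreement with the group consensus
        n = min(trace.size, peak_group.consensus_profile.size)
        r = _pearson(trace[:n], peak_group.consensus_profile[:n])
        ev.xic_correlation_component = r
        if r < config.r_min:
            ev.weight = 0.0   # systematic interference removal
            evidence.append(ev)
            continue
        if config.use_isotopes and apex_scan is not None:
            ev.isotope_component = _isotope_similarity(apex_scan, um.mz, config)
        components = [ev.intensity_component, ev.mass_accuracy_component,
                      ev.xic_correlation_component, ev.isotope_component]
        ev.weight = _combine(components, config.combination)
        evidence.append(ev)
    return evidence


def _isotope_similarity(scan: SpectrumRecord, mz: float, config: LocalizationConfig,
                        assumed_charge: int = 1) -> float:
    """Compare the observed M+1/M+0 ratio to the averagine expectation."""
    neutral = (mz - chem.PROTON) * assumed_charge
    if neutral <= 0:
        return 1.0
    envelope = chem.isotope_envelope(neutral, assumed_charge)
    expected = envelope.relative_abundances[1] / envelope.relative_abundances[0]
    from .dia_extraction import _match_intensity
    m0 = _match_intensity(scan, mz, config.tolerance_ppm)
    m1 = _match_intensity(scan, mz + chem.NEUTRON / assumed_charge, config.tolerance_ppm)
    if m0 <= 0:
        return 1.0
    if m1 <= 0:
        return 1.0   # isotope peak may be below noise; do not veto
    observed = m1 / m0
    return float(np.clip(np.exp(-abs(np.log(observed / expected))), 0.0, 1.0))


def score_candidates(evidence: list[FragmentEvidence],
                     candidates: list[SiteCandidate]) -> list[CandidateScore]:
    """Sum confirming weights minus refuting weights per candidate, floor at
    zero, normalize to fractional confidences. With no usable evidence the
    confidences fall back to uniform."""
    raw = np.zeros(len(candidates))
    for ev in evidence:
        if not ev.observed or ev.weight <= 0:
            continue
        for ci, role in enumerate(ev.unique_mass.roles):
            if role == "confirming":
                raw[ci] += ev.weight
            elif role == "refuting":
                raw[ci] -= ev.weight
    floored = np.maximum(raw, 0.0)
    total = floored.sum()
    if total > 0:
        fractions = floored / total
    else:
        fractions = np.full(len(candidates), 1.0 / len(candidates))
    return [CandidateScore(c, float(r), float(f))
            for c, r, f in zip(candidates, raw, fractions)]


def site_confidences(candidate_scores: list[CandidateScore],
                     threshold: float = CLASS1_THRESHOLD) -> SiteConfidenceTable:
    """Per-residue confidence = sum of fractional confidences of every
    candidate placing a phospho on that residue."""
    conf: dict[int, float] = {}
    if candidate_scores:
        for pos in candidate_scores[0].candidate.parent.candidate_residues:
            conf[pos] = 0.0
    for cs in candidate_scores:
        for pos in cs.candidate.phospho_positions:
            conf[pos] = conf.get(pos, 0.0) + cs.fractional_confidence
    return SiteConfidenceTable(confidences=conf, threshold=threshold)


@dataclass
class LocalizationResult:
    peptide: ModifiedPeptide
    charge: int
    best_candidate: SiteCandidate | None
    candidate_scores: list[CandidateScore]
    site_table: SiteConfidenceTable
    peak_group: PeakGroup | None
    quantity: float

    def probability_string(self) -> str:
        probs = {pos: round(c, 4) for pos, c in self.site_table.confidences.items() if c > 0}
        out = []
        for i, aa in enumerate(self.peptide.sequence, start=1):
            out.append(aa)
            if i in probs:
                out.append(f"({probs[i]:g})")
        return "".join(out)


def localize_precursor(peptide: ModifiedPeptide, charge: int, run: list[SpectrumRecord],
                       scheme, library_intensities: dict[str, float] | None = None,
                       config: LocalizationConfig = LocalizationConfig(),
                       threshold: float = CLASS1_THRESHOLD) -> LocalizationResult:
    """Full per-precursor pipeline: enumerate isomers, detect the best peak
    group on the union of unique fragment masses, score evidence, and return
    per-residue confidences plus the summed fragment quantity."""
    from .dia_extraction import assign_windows, detect_peak_groups

    candidates = enumerate_site_candidates(peptide)
    unique = site_determining_fragment_sets(
        candidates, charges=config.fragment_charges,
        neutral_losses=config.neutral_losses_as_evidence)
    windows = sorted(assign_windows(peptide.mz(charge), scheme))
    if not windows:
        raise ValueError(f"precursor m/z {peptide.mz(charge):.3f} outside window scheme")
    window_index = windows[0]

    xics = [extract_xic(run, um.mz, config.tolerance_ppm, window_index) for um in unique]
    lib = None
    if library_intensities is not None:
        lib = np.array([max((library_intensities.get(lab, 0.0) for lab in um.labels),
                            default=0.0) for um in unique])
    groups = detect_peak_groups(xics, lib)
    if not groups:
        table = site_confidences(score_candidates([], candidates), threshold)
        return LocalizationResult(peptide, charge, None, [], table, None, 0.0)
    group = groups[0]
    evidence = score_fragment_evidence(unique, group, run, window_index, config,
                                       precursor_neutral_mass=peptide.neutral_mass())
    scores = score_candidates(evidence, candidates)
    table = site_confidences(scores, threshold)
    best = max(scores, key=lambda s: s.fractional_confidence).candidate
    quantity = float(sum(group.fragment_areas.values()))
    return LocalizationResult(peptide, charge, best, scores, table, group, quantity)
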
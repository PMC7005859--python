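"""Window schemes, XIC extraction, peak groups, 3D features, pseudo-spectra."""

import numpy as np
import pytest

from phosphodia.dia_extraction import (Chromatogram, IsolationWindow,
                                       SpectrumRecord, WindowObservation,
                                       assign_windows, build_pseudo_spectra,
                                       build_window_scheme, detect_3d_features,
                                       detect_peak_groups, extract_xic,
                                       window_diagnostics)


class TestWindowScheme:
    def test_benchmark_scheme_boundaries(self, benchmark_scheme):
        assert (benchmark_scheme[0].lower, benchmark_scheme[0].upper) == (350.0, 364.0)
        assert (benchmark_scheme[1].lower, benchmark_scheme[1].upper) == (363.0, 377.0)
        assert benchmark_scheme[-1].upper == 975.0

    def test_zero_overlap_shares_single_point(self):
        scheme = build_window_scheme(400.0, 10.0, 0.0, 3)
        assert scheme[0].upper == scheme[1].lower

    def test_overlap_must_be_below_width(self):
        with pytest.raises(ValueError):
            build_window_scheme(350.0, 14.0, 14.0, 10)

    @pytest.mark.parametrize("mz,expected", [
        (363.5, {0, 1}),   # in the 1-Da overlap region
        (355.0, {0}),
        (349.0, set()),
    ])
    def test_assign_windows(self, benchmark_scheme, mz, expected):
        assert assign_windows(mz, benchmark_scheme) == expected


def _scan(rt, peaks, window=None):
    mz = np.array([p[0] for p in peaks])
    inten = np.array([p[1] for p in peaks])
    return SpectrumRecord(2 if window else 1, rt, mz, inten, window=window)


class TestXIC:
    @pytest.fixture
    def tiny_run(self):
        w = IsolationWindow(0, 495.0, 509.0)
        return [
            _scan(1.0, [(500.000, 100.0)], w),
            _scan(2.0, [(500.000, 200.0), (500.005, 50.0)], w),
            _scan(3.0, [], w),
        ]

    def test_exact_match(self, tiny_run):
        xic = extract_xic(tiny_run, 500.000, 20.0, 0)
        assert xic.intensity[0] == 100.0

    def test_outside_tolerance_is_zero(self, tiny_run):
        xic = extract_xic(tiny_run, 500.02, 20.0, 0)  # 40 ppm away
        assert np.all(xic.intensity == 0.0)

    def test_peaks_within_tolerance_summed(self, tiny_run):
        xic = extract_xic(tiny_run, 500.000, 20.0, 0)
        assert xic.intensity[1] == 250.0

    def test_absent_signal_yields_zero_not_gap(self, tiny_run):
        xic = extract_xic(tiny_run, 500.000, 20.0, 0)
        assert xic.rt.size == 3 and xic.intensity[2] == 0.0

    def test_missing_window_errors(self, tiny_run):
        with pytest.raises(ValueError, match="window 7"):
            extract_xic(tiny_run, 500.0, 20.0, 7)

    def test_extraction_is_linear(self, tiny_run):
        xic1 = extract_xic(tiny_run, 500.000, 20.0, 0)
        scaled = [SpectrumRecord(s.ms_level, s.rt, s.mz, s.intensity * 3.0, s.window)
                  for s in tiny_run]
        xic3 = extract_xic(scaled, 500.000, 20.0, 0)
        assert np.allclose(xic3.intensity, 3.0 * xic1.intensity)


def _gaussian_xics(apexes, grid=None, sigma=4.0, n_fragments=3):
    grid = np.arange(60.0, 141.0, 2.0) if grid is None else grid
    xics = []
    for k in range(n_fragments):
        trace = np.zeros_like(grid)
        for apex, height in apexes:
            trace += height * (1 - 0.1 * k) * np.exp(-0.5 * ((grid - apex) / sigma) ** 2)
        xics.append(Chromatogram(500.0 + k, 20.0, grid, trace))
    return grid, xics


class TestPeakGroups:
    def test_single_gaussian_apex_recovered(self):
        grid, xics = _gaussian_xics([(100.0, 1000.0)])
        groups = detect_peak_groups(xics)
        assert len(groups) == 1
        assert abs(groups[0].apex_rt - 100.0) <= np.diff(grid)[0]

    def test_two_separated_gaussians_two_groups(self):
        _, xics = _gaussian_xics([(80.0, 1000.0), (125.0, 800.0)])
        groups = detect_peak_groups(xics)
        assert len(groups) == 2

    def test_all_zero_input_empty(self):
        grid = np.arange(0.0, 50.0, 2.0)
        xics = [Chromatogram(500.0, 20.0, grid, np.zeros_like(grid))]
        assert detect_peak_groups(xics) == []

    def test_apex_within_one_step_for_fine_grids(self):
        """Noiseless Gaussian apex is localized to one grid step whenever the
        grid is finer than sigma/2."""
        sigma = 6.0
        for step in (0.5, 1.0, 2.0):
            grid = np.arange(50.0, 151.0, step)
            _, xics = _gaussian_xics([(99.7, 500.0)], grid=grid, sigma=sigma)
            groups = detect_peak_groups(xics)
            assert groups and abs(groups[0].apex_rt - 99.7) <= step

    def test_library_agreement_raises_score(self):
        _, xics = _gaussian_xics([(100.0, 1000.0)])
        areas_like = np.array([1.0, 0.9, 0.8])
        good = detect_peak_groups(xics, areas_like)[0].quality_score
        bad = detect_peak_groups(xics, np.array([0.0, 0.0, 1.0]))[0].quality_score
        assert good > bad


class TestFeature3D:
    def _ms1(self, rts, mz=500.0, heights=None):
        heights = heights or [100.0] * len(rts)
        return [_scan(rt, [(mz, h)]) for rt, h in zip(rts, heights)]

    def test_five_consecutive_scans_one_feature(self):
        scans = self._ms1([1, 2, 3, 4, 5])
        feats = detect_3d_features(scans)
        assert len(feats) == 1
        assert len(feats[0].scan_indices) == 5

    def test_two_scan_gap_splits(self):
        scans = [_scan(t, [(500.0, 100.0)]) for t in (1, 2, 3)]
        scans += [_scan(t, []) for t in (4, 5)]
        scans += [_scan(t, [(500.0, 100.0)]) for t in (6, 7, 8)]
        feats = detect_3d_features(scans, gap_limit=1, min_span=3)
        assert len(feats) == 2

    def test_below_threshold_is_empty(self):
        scans = self._ms1([1, 2, 3, 4], heights=[5.0] * 4)
        assert detect_3d_features(scans, intensity_threshold=10.0) == []

    def test_short_chains_dropped(self):
        scans = self._ms1([1, 2])
        assert detect_3d_features(scans, min_span=3) == []


class TestPseudoSpectra:
    def _co_eluting_run(self, frag_mz, shape, window, extra=None):
        run = []
        for i, rt in enumerate(range(1, len(shape) + 1)):
            run.append(_scan(float(rt), [(400.0, 1000.0 * shape[i])]))
            peaks = [(mz, 100.0 * shape[i]) for mz in frag_mz]
            if extra:
                peaks += extra(i)
            run.append(_scan(float(rt), sorted(peaks), window))
        return run

    def test_five_co_eluting_fragments(self):
        w = IsolationWindow(0, 395.0, 409.0)
        shape = [0.1, 0.5, 1.0, 0.5, 0.1]
        frag_mz = [200.0, 300.0, 400.5, 500.0, 600.0]
        run = self._co_eluting_run(frag_mz, shape, w)
        feats = detect_3d_features([s for s in run if s.ms_level == 1])
        spectra = build_pseudo_spectra(feats, run, [w])
        assert len(spectra) == 1
        assert np.allclose(spectra[0].fragment_mz, frag_mz)

    def test_constant_interference_excluded(self):
        w = IsolationWindow(0, 395.0, 409.0)
        shape = [0.1, 0.5, 1.0, 0.5, 0.1]
        run = self._co_eluting_run([200.0, 300.0], shape, w,
                                   extra=lambda i: [(700.0, 500.0)])
        feats = detect_3d_features([s for s in run if s.ms_level == 1])
        spectra = build_pseudo_spectra(feats, run, [w])
        assert 700.0 not in spectra[0].fragment_mz

    def test_two_precursors_disjoint_fragments(self):
        w = IsolationWindow(0, 395.0, 409.0)
        shape_a = np.exp(-0.5 * ((np.arange(10) - 3) / 1.0) ** 2)
        shape_b = np.exp(-0.5 * ((np.arange(10) - 7) / 1.0) ** 2)
        run = []
        for i in range(10):
            run.append(_scan(float(i), [(398.0, 1000 * shape_a[i] + 1e-9),
                                        (402.0, 800 * shape_b[i] + 1e-9)]))
            peaks = [(mz, 100 * shape_a[i] + 1e-12) for mz in (210.0, 310.0)]
            peaks += [(mz, 90 * shape_b[i] + 1e-12) for mz in (510.0, 610.0)]
            run.append(_scan(float(i), sorted(peaks), w))
        feats = detect_3d_features([s for s in run if s.ms_level == 1],
                                   intensity_threshold=1e-6)
        spectra = build_pseudo_spectra(feats, run, [w])
        assert len(spectra) == 2
        sets = [set(np.round(s.fragment_mz, 3)) for s in spectra]
        assert sets[0].isdisjoint(sets[1])
        assert sets[0] | sets[1] == {210.0, 310.0, 510.0, 610.0}

    def test_single_analyte_reproduces_generative_fragments(self, single_analyte_run):
        """Library-free pseudo-spectrum generation on a one-peptide synthetic
        run recovers the generative fragment m/z list exactly and relative
        intensities up to a common scale."""
        config, run, truth, library = single_analyte_run
        scheme = config.scheme()
        ms1 = [s for s in run if s.ms_level == 1]
        feats = detect_3d_features(ms1, intensity_threshold=1.0)
        spectra = build_pseudo_spectra(feats, run, scheme)
        assert len(spectra) >= 1
        spec = max(spectra, key=lambda s: s.fragment_mz.size)
        lib = library[(truth.sequence[0], 2)]
        from phosphodia.peptide_model import (ModifiedPeptide, SiteCandidate,
                                              theoretical_fragments)
        cand = SiteCandidate(ModifiedPeptide(truth.sequence[0], 1), (3,))
        ions = theoretical_fragments(cand, charges=(1,))
        expected = {round(i.mz, 4): lib[i.label] for i in ions}
        got = dict(zip(np.round(spec.fragment_mz, 4), spec.fragment_intensity))
        assert set(got) == set(expected)
        scale = [got[mz] / expected[mz] for mz in expected]
        assert np.allclose(scale, scale[0], rtol=1e-6)


class TestWindowDiagnostics:
    def test_definitions(self):
        w = IsolationWindow(0, 350.0, 364.0)
        obs = [
            WindowObservation(357.0, w, 1000.0, 500.0),   # at center
            WindowObservation(364.0, w, 1000.0, 800.0),   # at edge
        ]
        pairs = window_diagnostics(obs)
        assert pairs[0] == (0.5, 0.0)
        assert pairs[1] == (0.8, 1.0)

    def test_zero_center_intensity_skipped_with_warning(self):
        w = IsolationWindow(0, 350.0, 364.0)
        with pytest.warns(UserWarning):
            pairs = window_diagnostics([WindowObservation(357.0, w, 0.0, 10.0)])
        assert pairs == []
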
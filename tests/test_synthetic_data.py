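import numpy as np
import pytest

from urinemet.synthetic_data import (
    CohortSpec,
    MetabolitePeak,
    build_template_library,
    render_multiplet,
    simulate_cohort,
)

from conftest import MARKER_DIRECTIONS, MARKER_PEAKS


class TestTemplateLibrary:
    def test_marker_panel_complete(self, library):
        by_name = {t.name: t for t in library}
        for name, peaks in MARKER_PEAKS.items():
            got = [(p.center, p.multiplicity) for p in by_name[name].peaks]
            assert got == peaks, name
            assert by_name[name].direction == MARKER_DIRECTIONS[name]

    def test_creatine_is_a_single_singlet(self, library):
        creatine = next(t for t in library if t.name == "creatine")
        assert len(creatine.peaks) == 1
        assert creatine.peaks[0].center == 3.04
        assert creatine.peaks[0].multiplicity == "singlet"

    def test_glycerol_three_multiplets_down(self, library):
        glycerol = next(t for t in library if t.name == "glycerol")
        assert [p.center for p in glycerol.peaks] == [3.57, 3.66, 3.78]
        assert all(p.multiplicity == "multiplet" for p in glycerol.peaks)
        assert glycerol.direction == "down"

    def test_relative_areas_sum_to_one(self, library):
        for tpl in library:
            assert sum(p.relative_area for p in tpl.peaks) == pytest.approx(1.0)

    def test_tsp_reference_present(self, library):
        tsp = next(t for t in library if t.name == "tsp")
        assert tsp.peaks[0].center == 0.0
        assert tsp.direction == "none"

    def test_background_metabolites_avoid_marker_centers(self, library):
        marker_centers = [
            p.center for t in library if t.direction != "none" for p in t.peaks
        ]
        background = [t for t in library if t.direction == "none" and t.name != "tsp"]
        assert len(background) >= 3
        for tpl in background:
            for p in tpl.peaks:
                assert all(abs(p.center - c) > 0.02 for c in marker_centers), tpl.name


class TestRenderMultiplet:
    AXIS = np.linspace(-0.5, 13.5, 2**17)  # fine grid for numeric checks

    def test_zero_amplitude_is_zero(self):
        pk = MetabolitePeak(center=3.0, multiplicity="singlet")
        assert not render_multiplet(pk, 0.0, self.AXIS).any()

    def test_doublet_splitting_matches_j_over_frequency(self):
        pk = MetabolitePeak(center=1.49, multiplicity="doublet", j_coupling=7.0)
        y = render_multiplet(pk, 1.0, self.AXIS, linewidth=0.0015,
                             spectrometer_freq=500.13)
        # locate the two maxima numerically
        local_max = (y[1:-1] > y[:-2]) & (y[1:-1] > y[2:])
        peaks_ppm = self.AXIS[1:-1][local_max & (y[1:-1] > 0.1 * y.max())]
        assert peaks_ppm.size == 2
        sep = peaks_ppm.max() - peaks_ppm.min()
        assert sep == pytest.approx(7.0 / 500.13, rel=0.05)

    def test_triplet_line_areas_1_2_1(self):
        # wide splitting relative to the linewidth so per-line windows
        # capture each Lorentzian's tails almost completely
        j = 50.0
        pk = MetabolitePeak(center=7.0, multiplicity="triplet", j_coupling=j)
        y = render_multiplet(pk, 1.0, self.AXIS, linewidth=0.0008)
        j_ppm = j / 500.13
        # integrate each line over a half-splitting-wide window
        areas = []
        for c in (7.0 - j_ppm, 7.0, 7.0 + j_ppm):
            m = np.abs(self.AXIS - c) < j_ppm / 2
            areas.append(np.trapezoid(y[m], self.AXIS[m]))
        assert areas[1] / areas[0] == pytest.approx(2.0, rel=0.01)
        assert areas[2] / areas[0] == pytest.approx(1.0, rel=0.01)

    @pytest.mark.parametrize("mult,j", [("singlet", 0.0), ("doublet", 7.2),
                                        ("triplet", 6.6), ("multiplet", 7.8)])
    def test_integral_equals_amplitude(self, mult, j):
        pk = MetabolitePeak(center=6.5, multiplicity=mult, j_coupling=j)
        y = render_multiplet(pk, 2.5, self.AXIS, linewidth=0.0015)
        assert np.trapezoid(y, self.AXIS) == pytest.approx(2.5, rel=0.02)

    def test_linearity_in_amplitude(self):
        pk = MetabolitePeak(center=5.0, multiplicity="doublet", j_coupling=7.0)
        y1 = render_multiplet(pk, 1.0, self.AXIS)
        y2 = render_multiplet(pk, 2.0, self.AXIS)
        assert np.trapezoid(y2, self.AXIS) == pytest.approx(
            2.0 * np.trapezoid(y1, self.AXIS), rel=0.01)

    def test_non_monotone_axis_rejected(self):
        pk = MetabolitePeak(center=1.0, multiplicity="singlet")
        with pytest.raises(ValueError):
            render_multiplet(pk, 1.0, np.array([0.0, 1.0, 0.5]))


class TestCohortSimulation:
    def test_same_seed_bit_identical(self):
        spec = CohortSpec(n_control=3, n_case=3, n_points=1024, seed=9)
        a = simulate_cohort(spec)
        b = simulate_cohort(spec)
        assert np.array_equal(a.true_concentrations, b.true_concentrations)
        for sa, sb in zip(a.spectra, b.spectra):
            assert np.array_equal(sa.intensity, sb.intensity)

    def test_different_seeds_differ(self):
        a = simulate_cohort(CohortSpec(n_control=3, n_case=3, n_points=1024, seed=1))
        b = simulate_cohort(CohortSpec(n_control=3, n_case=3, n_points=1024, seed=2))
        assert not np.array_equal(a.spectra[0].intensity, b.spectra[0].intensity)

    def test_null_effect_gives_unit_ratio(self):
        spec = CohortSpec(n_control=100, n_case=100, effect_log2fc=0.0,
                          n_points=512, noise_sd=0.0, seed=5)
        c = simulate_cohort(spec)
        case = np.array(c.labels) == "case"
        ratio = c.true_concentrations[case].mean(0) / c.true_concentrations[~case].mean(0)
        assert np.allclose(ratio, 1.0, atol=0.15)

    def test_down_marker_concentration_halves(self):
        spec = CohortSpec(n_control=250, n_case=250, effect_log2fc=1.0,
                          n_points=512, noise_sd=0.0, seed=11)
        c = simulate_cohort(spec)
        j = c.metabolite_names.index("glycerol")
        case = np.array(c.labels) == "case"
        ratio = c.true_concentrations[case, j].mean() / c.true_concentrations[~case, j].mean()
        assert ratio == pytest.approx(0.5, rel=0.1)

    def test_signal_present_at_every_marker_shift(self, small_cohort):
        # multiplet lines sit at +-J/2 etc. around the printed centre, so
        # look for signal anywhere within a small window around each shift
        s = small_cohort.spectra[0]
        tsp_height = 2.0 / (np.pi * small_cohort.spec.linewidth)
        noise_sd_abs = small_cohort.spec.noise_sd * tsp_height
        for peaks in MARKER_PEAKS.values():
            for center, _ in peaks:
                w = np.abs(s.ppm - center) < 0.02
                assert s.intensity[w].max() > 3 * noise_sd_abs, center

    def test_water_band_dominates_water_region(self, small_cohort):
        s = small_cohort.spectra[0]
        inside = (s.ppm >= 4.62) & (s.ppm <= 5.15)
        assert s.intensity[inside].max() > 10 * np.median(s.intensity)

    def test_creatine_creatinine_anticorrelated(self):
        spec = CohortSpec(n_control=300, n_case=2, n_points=512, seed=3)
        c = simulate_cohort(spec)
        ctrl = np.array(c.labels) == "control"
        i = c.metabolite_names.index("creatine")
        j = c.metabolite_names.index("creatinine")
        r = np.corrcoef(np.log(c.true_concentrations[ctrl, i]),
                        np.log(c.true_concentrations[ctrl, j]))[0, 1]
        assert r < -0.2

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            CohortSpec(n_control=1, n_case=5)
        with pytest.raises(ValueError):
            CohortSpec(axis_min=0.5)  # TSP at 0 must lie on the axis
        with pytest.raises(ValueError):
            CohortSpec(linewidth=0.0)


def test_write_cohort_roundtrip(tmp_path, small_cohort):
    from urinemet.synthetic_data import write_cohort
    from urinemet.spectral_processing import read_spectra_csv

    paths = write_cohort(small_cohort, tmp_path)
    spectra = read_spectra_csv(paths["spectra"])
    assert len(spectra) == len(small_cohort.spectra)
    assert np.allclose(spectra[0].intensity, small_cohort.spectra[0].intensity)
    meta = paths["metadata"].read_text().splitlines()
    assert meta[0] == "sample_id\tgroup\tstage"
    assert len(meta) == len(small_cohort.spectra) + 1
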
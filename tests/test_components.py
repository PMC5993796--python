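"""Lifetime histograms, Gaussian decomposition, pairs, and metabolic ratios."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from flim4.components import (
    ComponentSet,
    GaussianComponent,
    LifetimeHistogram,
    PAIR_CYTO,
    PAIR_MITO,
    UNCLASSIFIED,
    classify_pairs,
    component_intensities,
    fit_gaussians,
    free_to_bound,
    lifetime_histogram,
    mcr,
    redox_image,
    select_peak_count,
)
from flim4.decay import FitImage


def _fit_image(meta, tau1, tau2, photons, intensity1, intensity2):
    """Assemble a FitImage from parameter arrays (QC everywhere)."""
    tau1 = np.asarray(tau1, dtype=float)
    shape = tau1.shape
    ones = np.ones(shape, dtype=bool)
    return FitImage(
        tau1=tau1,
        tau2=np.asarray(tau2, dtype=float),
        intensity1=np.asarray(intensity1, dtype=float),
        intensity2=np.asarray(intensity2, dtype=float),
        offset=np.zeros(shape),
        chi2=np.ones(shape),
        photons=np.asarray(photons, dtype=float),
        foreground_mask=ones,
        qc_mask=ones.copy(),
        meta=meta,
    )


DEFAULT_COMPS = ComponentSet(
    components=(
        GaussianComponent(a=1.0, b=0.5, c=0.08),
        GaussianComponent(a=1.0, b=1.0, c=0.12),
        GaussianComponent(a=1.0, b=2.3, c=0.2),
        GaussianComponent(a=1.0, b=3.7, c=0.3),
    )
)


class TestHistogram:
    def test_single_pixel_splits_intensity_by_fraction(self, meta):
        # photons 900 split 1/3 : 2/3 across (0.5, 2.3) ns
        fit = _fit_image(meta, [[0.5]], [[2.3]], [[900.0]], [[100.0]], [[200.0]])
        hist = lifetime_histogram(fit)

        def weight_near(tau):
            sel = np.abs(hist.bin_centers - tau) <= hist.bin_width
            return hist.weights[sel].sum()

        assert weight_near(0.5) == pytest.approx(300.0)
        assert weight_near(2.3) == pytest.approx(600.0)
        assert hist.total_weight == pytest.approx(900.0)

    def test_mono_exponential_image_fills_one_bin_pair(self, meta):
        n = 8
        fit = _fit_image(
            meta,
            np.full((n, n), 1.0),
            np.full((n, n), 1.0),
            np.full((n, n), 500.0),
            np.full((n, n), 1.0),
            np.full((n, n), 0.0),
        )
        hist = lifetime_histogram(fit)
        assert (hist.weights > 0).sum() == 1

    def test_weight_conservation(self, adipocyte_fit):
        fit, _ = adipocyte_fit
        hist = lifetime_histogram(fit)
        assert hist.total_weight == pytest.approx(fit.photons[fit.qc_mask].sum())

    def test_empty_mask_gives_empty_histogram(self, meta):
        fit = _fit_image(meta, [[0.5]], [[2.3]], [[900.0]], [[1.0]], [[2.0]])
        fit.qc_mask[:] = False
        assert lifetime_histogram(fit).total_weight == 0.0


class TestGaussianFit:
    @staticmethod
    def _hist_from_components(comps, lo=0.0, hi=6.0, width=0.05):
        edges = np.arange(lo, hi + width / 2, width)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return LifetimeHistogram(bin_centers=centers, weights=comps(centers))

    def test_exact_gaussian_self_fit(self):
        truth = ComponentSet(components=(GaussianComponent(a=100.0, b=1.0, c=0.1),))
        hist = self._hist_from_components(truth)
        fitted = fit_gaussians(hist, 1)
        g = fitted.components[0]
        assert g.a == pytest.approx(100.0, rel=1e-3)
        assert g.b == pytest.approx(1.0, abs=1e-3)
        assert g.c == pytest.approx(0.1, rel=1e-3)

    def test_two_separated_gaussians_conserve_area(self):
        truth = ComponentSet(
            components=(
                GaussianComponent(a=500.0, b=1.0, c=0.15),
                GaussianComponent(a=300.0, b=3.5, c=0.25),
            )
        )
        hist = self._hist_from_components(truth)
        fitted = fit_gaussians(hist, 2)
        assert fitted.areas == pytest.approx(truth.areas, rel=0.01)
        assert fitted.areas.sum() == pytest.approx(truth.areas.sum(), rel=0.01)
        assert fitted.centers == pytest.approx([1.0, 3.5], abs=0.01)

    def test_overlapping_request_flagged_degenerate(self):
        truth = ComponentSet(components=(GaussianComponent(a=100.0, b=2.0, c=0.3),))
        hist = self._hist_from_components(truth)
        fitted = fit_gaussians(hist, 3)
        assert fitted.degenerate

    def test_empty_histogram_rejected(self):
        hist = LifetimeHistogram(
            bin_centers=np.linspace(0.1, 5, 50), weights=np.zeros(50)
        )
        with pytest.raises(ValueError):
            fit_gaussians(hist, 2)

    def test_area_identity(self):
        g = GaussianComponent(a=10.0, b=1.0, c=0.2)
        assert g.area == pytest.approx(10.0 * 0.2 * np.sqrt(2 * np.pi))


class TestPeakCountSelection:
    def test_mono_modal_histogram_reports_candidate_floor(self):
        comps = ComponentSet(components=(GaussianComponent(a=100.0, b=2.0, c=0.3),))
        hist = TestGaussianFit._hist_from_components(comps)
        assert select_peak_count(hist) == 2  # floor of {2, 3, 4}
        assert fit_gaussians(hist, 2).degenerate

    def test_four_well_separated_modes_report_four(self):
        hist = TestGaussianFit._hist_from_components(DEFAULT_COMPS)
        assert select_peak_count(hist) == 4

    def test_two_modes_report_two(self):
        comps = ComponentSet(
            components=(
                GaussianComponent(a=80.0, b=0.8, c=0.15),
                GaussianComponent(a=60.0, b=3.0, c=0.4),
            )
        )
        hist = TestGaussianFit._hist_from_components(comps)
        assert select_peak_count(hist) == 2
        assert select_peak_count(hist, method="bic") == 2


class TestPairClassification:
    def test_known_pairs_and_tie(self, meta):
        fit = _fit_image(
            meta,
            [[0.5, 1.0, 0.75]],
            [[2.3, 3.7, 3.0]],
            [[500.0] * 3],
            [[1.0] * 3],
            [[1.0] * 3],
        )
        labels = classify_pairs(fit, DEFAULT_COMPS)
        assert labels[0, 0] == PAIR_MITO  # (0.5, 2.3)
        assert labels[0, 1] == PAIR_CYTO  # (1.0, 3.7)

    def test_exact_tie_is_unclassified(self, meta):
        sym = ComponentSet(
            components=(
                GaussianComponent(a=1.0, b=0.5, c=0.1),
                GaussianComponent(a=1.0, b=1.5, c=0.1),
                GaussianComponent(a=1.0, b=2.0, c=0.2),
                GaussianComponent(a=1.0, b=3.0, c=0.2),
            )
        )
        fit = _fit_image(meta, [[1.0]], [[2.5]], [[500.0]], [[1.0]], [[1.0]])
        assert classify_pairs(fit, sym)[0, 0] == UNCLASSIFIED

    def test_requires_four_components(self, meta):
        fit = _fit_image(meta, [[0.5]], [[2.3]], [[500.0]], [[1.0]], [[1.0]])
        three = ComponentSet(components=DEFAULT_COMPS.components[:3])
        with pytest.raises(ValueError):
            classify_pairs(fit, three)


class TestComponentIntensities:
    def test_pure_mito_image_leaves_cyto_components_empty(self, meta):
        n = 4
        fit = _fit_image(
            meta,
            np.full((n, n), 0.5),
            np.full((n, n), 2.3),
            np.full((n, n), 600.0),
            np.full((n, n), 1.0),
            np.full((n, n), 2.0),
        )
        totals = component_intensities(fit, DEFAULT_COMPS)
        assert totals[1] == 0.0 and totals[3] == 0.0
        assert totals.sum() == pytest.approx(600.0 * n * n)

    def test_half_and_half_image_is_symmetric(self, meta):
        tau1 = np.array([[0.5, 1.0]])
        tau2 = np.array([[2.3, 3.7]])
        fit = _fit_image(meta, tau1, tau2, [[500.0, 500.0]], [[1.0, 1.0]], [[1.0, 1.0]])
        totals = component_intensities(fit, DEFAULT_COMPS)
        assert totals[0] + totals[2] == pytest.approx(totals[1] + totals[3])

    def test_totals_conserve_histogram_weight(self, adipocyte_fit):
        fit, _ = adipocyte_fit
        hist = lifetime_histogram(fit)
        comps = fit_gaussians(hist, 4)
        totals = component_intensities(fit, comps)
        assert totals.sum() == pytest.approx(hist.total_weight)


class TestMCR:
    def test_symmetry_gives_one(self):
        assert mcr(np.array([100.0, 100.0, 100.0, 100.0])) == 1.0

    def test_arithmetic(self):
        assert mcr(np.array([300.0, 100.0, 300.0, 100.0])) == 3.0

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            mcr(np.array([1.0, 0.0, 1.0, 0.0]))

    @given(
        base=st.tuples(*[st.floats(min_value=1.0, max_value=1e3)] * 4),
        factor=st.floats(min_value=1.01, max_value=5.0),
    )
    def test_monotone_in_compartment_scaling(self, base, factor):
        """MCR strictly increases in any mitochondrial intensity and
        strictly decreases in any cytoplasmic intensity."""
        base = np.asarray(base)
        up_mito = base * np.array([factor, 1, 1, 1])
        up_cyto = base * np.array([1, factor, 1, 1])
        assert mcr(up_mito) > mcr(base) > mcr(up_cyto)


class TestFreeToBound:
    def test_constant_amplitude_ratio(self, meta):
        # alpha1/alpha2 = (I1/tau1)/(I2/tau2); choose I so the ratio is 2
        n = 3
        fit = _fit_image(
            meta,
            np.full((n, n), 0.5),
            np.full((n, n), 2.0),
            np.full((n, n), 500.0),
            np.full((n, n), 1.0),  # alpha1 = 1/0.5 = 2
            np.full((n, n), 2.0),  # alpha2 = 2/2.0 = 1
        )
        assert free_to_bound(fit) == pytest.approx(2.0)

    def test_no_qc_pixels_raises(self, meta):
        fit = _fit_image(meta, [[0.5]], [[2.0]], [[500.0]], [[1.0]], [[1.0]])
        fit.qc_mask[:] = False
        with pytest.raises(ValueError):
            free_to_bound(fit)


class TestRedox:
    def test_equal_channels_give_half(self):
        fad = np.full((8, 8), 50.0)
        nadh = np.full((8, 8), 50.0)
        ratio, mean = redox_image(fad, nadh)
        assert np.allclose(ratio, 0.5)
        assert mean == pytest.approx(0.5)

    def test_zero_fad_gives_zero(self):
        ratio, mean = redox_image(np.zeros((4, 4)), np.ones((4, 4)))
        assert mean == 0.0

    def test_zero_denominator_masked(self):
        fad = np.array([[0.0, 1.0]])
        nadh = np.array([[0.0, 1.0]])
        ratio, mean = redox_image(fad, nadh)
        assert np.isnan(ratio[0, 0]) and ratio[0, 1] == 0.5

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            redox_image(np.zeros((2, 2)), np.zeros((3, 3)))


def test_pair_classification_accuracy_against_ground_truth(adipocyte_fit):
    """Pixels of (nearly) pure compartments must classify to their pair with
    >= 90% accuracy on the default geometry."""
    fit, geom = adipocyte_fit
    hist = lifetime_histogram(fit)
    comps = fit_gaussians(hist, 4)
    labels = classify_pairs(fit, comps)
    qc = fit.qc_mask
    mito_true = qc & (geom.mito_fraction > 0.95)
    cyto_true = qc & (geom.mito_fraction < 0.02) & geom.cell_mask
    mito_acc = (labels[mito_true] == PAIR_MITO).mean()
    cyto_acc = (labels[cyto_true] == PAIR_CYTO).mean()
    assert mito_acc >= 0.9
    assert cyto_acc >= 0.9
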
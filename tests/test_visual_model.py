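"""Quantum catches, Weber fractions and the receptor-noise JND metric."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from camonorm.spectra import Spectrum, StandardGrid
from camonorm.visual_model import (SINGLE_CONES, DiscriminabilityCategory,
                                   QuantumCatchVector, ReceptorSet,
                                   WeberVector, achromatic_jnd, chromatic_jnd,
                                   discriminability, discriminability_category,
                                   greenness_chromatic, quantum_catch,
                                   weber_fractions)

GRID = StandardGrid()


def boxcar_receptors(lo=500.0, hi=600.0) -> ReceptorSet:
    wl = GRID.wavelengths
    box = ((wl >= lo) & (wl <= hi)).astype(float)
    sens = {c: Spectrum(wl, box, name=c) for c in SINGLE_CONES}
    sens["DD"] = Spectrum(wl, box, name="DD")
    return ReceptorSet(sens)


def jnd_oracle(qa, qb, e):
    """Independent route: norm of the log-catch difference projected
    orthogonally to the intensity direction in noise-whitened space."""
    df = np.log(np.asarray(qa) / np.asarray(qb))
    inv = 1.0 / np.asarray(e) ** 2
    quad = df @ (inv * df) - (inv @ df) ** 2 / inv.sum()
    return np.sqrt(max(quad, 0.0))


def qcv(values, dd=None) -> QuantumCatchVector:
    c = dict(zip(SINGLE_CONES, values))
    if dd is not None:
        c["DD"] = dd
    return QuantumCatchVector(c)


class TestQuantumCatch:
    def test_boxcar_closed_form(self, flat_spectrum):
        q = quantum_catch(flat_spectrum(1.0), flat_spectrum(1.0),
                          boxcar_receptors())
        # 101 grid points of height 1 inside [500, 600], step 1 nm
        for c in SINGLE_CONES:
            assert q[c] == pytest.approx(101.0)

    def test_zero_reflectance_errors(self, flat_spectrum):
        with pytest.raises(ValueError, match="zero quantum catch"):
            quantum_catch(flat_spectrum(0.0), flat_spectrum(1.0),
                          boxcar_receptors())

    def test_floor_option_replaces_zero_catch(self, flat_spectrum, grid):
        wl = grid.wavelengths
        rs = boxcar_receptors()
        # UV band moved so the stimulus leaves it completely dark
        rs.sensitivities["UV"] = Spectrum(
            wl, ((wl >= 310) & (wl <= 330)).astype(float), name="UV")
        refl = Spectrum(wl, ((wl >= 500) & (wl <= 600)).astype(float))
        with pytest.raises(ValueError, match="floor"):
            quantum_catch(refl, flat_spectrum(1.0), rs)
        q = quantum_catch(refl, flat_spectrum(1.0), rs, floor=True)
        assert all(v > 0 for v in q.catches.values())
        assert q["UV"] == pytest.approx(1e-6 * q["SW"])

    def test_matches_termwise_accumulation(self, receptors, rng, grid):
        refl = Spectrum(grid.wavelengths, rng.uniform(0, 1, len(grid)))
        ill = Spectrum(grid.wavelengths, rng.uniform(0.1, 2, len(grid)))
        q = quantum_catch(refl, ill, receptors, grid=grid)
        for c, sens in receptors.sensitivities.items():
            acc = 0.0
            for r, i, s in zip(refl.values, ill.values, sens.values):
                acc += r * i * s * grid.step
            assert q[c] == pytest.approx(acc, abs=1e-12 * max(acc, 1))

    def test_bilinear_in_reflectance_and_illuminant(self, receptors, rng, grid):
        r = Spectrum(grid.wavelengths, rng.uniform(0, 1, len(grid)))
        i = Spectrum(grid.wavelengths, rng.uniform(0.1, 1, len(grid)))
        q1 = quantum_catch(r, i, receptors, grid=grid)
        q2 = quantum_catch(r.copy_with(2.0 * r.values), i, receptors, grid=grid)
        q3 = quantum_catch(r, i.copy_with(3.0 * i.values), receptors, grid=grid)
        for c in SINGLE_CONES:
            assert q2[c] == pytest.approx(2.0 * q1[c])
            assert q3[c] == pytest.approx(3.0 * q1[c])


class TestWeberFractions:
    def test_reference_cone_gets_base_fraction(self, receptors):
        w = weber_fractions(receptors)
        assert w["LW"] == pytest.approx(0.05)

    def test_density_quarter_doubles_noise(self, receptors, grid):
        rs = ReceptorSet(receptors.sensitivities,
                         densities={"UV": 0.25, "SW": 0.5, "MW": 0.75,
                                    "LW": 1.0})
        assert weber_fractions(rs)["UV"] == pytest.approx(0.10)

    def test_uv_density_value(self, receptors):
        w = weber_fractions(receptors)
        assert w["UV"] == pytest.approx(0.05 / np.sqrt(0.3704), abs=1e-5)
        assert w["UV"] == pytest.approx(0.08215, abs=1e-4)

    def test_invalid_density_rejected(self, receptors):
        with pytest.raises(ValueError, match="density"):
            ReceptorSet(receptors.sensitivities,
                        densities={"UV": 0.0, "SW": 0.5, "MW": 0.7, "LW": 1.0})


class TestChromaticJnd:
    W_EQUAL = WeberVector({c: 0.05 for c in SINGLE_CONES})

    def test_identity(self):
        a = qcv([1.0, 2.0, 3.0, 4.0])
        assert chromatic_jnd(a, a, self.W_EQUAL) == 0.0

    def test_intensity_invariance(self):
        a = qcv([1.0, 2.0, 3.0, 4.0])
        b = qcv([2.5, 5.0, 7.5, 10.0])
        assert chromatic_jnd(a, b, self.W_EQUAL) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_sqrt3_over_2(self):
        a = qcv([1.0, 1.0, 1.0, 1.0])
        b = qcv([1.0, 1.0, 1.0, np.exp(-0.05)])
        ds = chromatic_jnd(a, b, self.W_EQUAL)
        assert ds == pytest.approx(np.sqrt(3) / 2, abs=1e-12)

    def test_matches_whitened_projection_oracle(self, rng):
        e = np.array([0.0821, 0.0593, 0.0502, 0.05])
        w = WeberVector(dict(zip(SINGLE_CONES, e)))
        for _ in range(200):
            qa = rng.uniform(0.1, 10, 4)
            qb = rng.uniform(0.1, 10, 4)
            ours = chromatic_jnd(qcv(qa), qcv(qb), w)
            assert ours == pytest.approx(jnd_oracle(qa, qb, e), abs=1e-10)

    def test_symmetry(self, rng):
        w = weber_fractions_default()
        qa, qb = rng.uniform(0.1, 5, 4), rng.uniform(0.1, 5, 4)
        assert chromatic_jnd(qcv(qa), qcv(qb), w) == pytest.approx(
            chromatic_jnd(qcv(qb), qcv(qa), w), abs=1e-12)

    def test_monotone_in_single_log_contrast(self):
        w = self.W_EQUAL
        prev = -1.0
        for d in np.linspace(0, 1, 20):
            b = qcv([1.0, 1.0, 1.0, np.exp(d)])
            ds = chromatic_jnd(qcv([1.0] * 4), b, w)
            assert ds >= prev
            prev = ds

    def test_nonpositive_catch_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            chromatic_jnd(qcv([0.0, 1, 1, 1]), qcv([1, 1, 1, 1]), self.W_EQUAL)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(hst.lists(hst.floats(0.1, 10), min_size=12, max_size=12))
    def test_triangle_inequality_property(self, vals):
        w = self.W_EQUAL
        a, b, c = (qcv(vals[i:i + 4]) for i in (0, 4, 8))
        ab = chromatic_jnd(a, b, w)
        bc = chromatic_jnd(b, c, w)
        ac = chromatic_jnd(a, c, w)
        assert ac <= ab + bc + 1e-9


def weber_fractions_default() -> WeberVector:
    e = {c: 0.05 / np.sqrt(d) for c, d in
         zip(SINGLE_CONES, (0.3704, 0.7111, 0.9926, 1.0))}
    return WeberVector(e)


class TestAchromaticJnd:
    def test_equal_catches_zero(self):
        a = qcv([1, 1, 1, 1], dd=2.0)
        assert achromatic_jnd(a, a, dd_weber=0.05) == 0.0

    def test_definitional_unit(self):
        a = qcv([1, 1, 1, 1], dd=np.exp(0.05))
        b = qcv([1, 1, 1, 1], dd=1.0)
        assert achromatic_jnd(a, b, dd_weber=0.05) == pytest.approx(1.0)

    def test_doubling_gives_ln2_over_weber(self):
        a = qcv([1, 1, 1, 1], dd=2.0)
        b = qcv([1, 1, 1, 1], dd=1.0)
        assert achromatic_jnd(a, b, dd_weber=0.05) == pytest.approx(
            np.log(2) / 0.05)

    def test_missing_dd_catch_errors(self):
        a = qcv([1, 1, 1, 1])
        with pytest.raises(KeyError, match="DD"):
            achromatic_jnd(a, a, dd_weber=0.05)


class TestCategories:
    @pytest.mark.parametrize("jnd,expected", [
        (0.5, DiscriminabilityCategory.INDISCRIMINABLE),
        (2.0, DiscriminabilityCategory.GOOD_CONDITIONS_ONLY),
        (13.9, DiscriminabilityCategory.DISCRIMINABLE),
        (1.0, DiscriminabilityCategory.GOOD_CONDITIONS_ONLY),
        (3.0, DiscriminabilityCategory.GOOD_CONDITIONS_ONLY),
        (3.0001, DiscriminabilityCategory.DISCRIMINABLE),
    ])
    def test_threshold_rule(self, jnd, expected):
        assert discriminability_category(jnd) is expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            discriminability_category(-0.1)

    def test_discriminability_bundles_both_channels(self, receptors,
                                                    flat_spectrum, grid):
        ill = flat_spectrum(1.0)
        a = quantum_catch(flat_spectrum(0.2), ill, receptors, grid=grid)
        b = quantum_catch(flat_spectrum(0.6), ill, receptors, grid=grid)
        res = discriminability(a, b, receptors)
        assert res.chromatic_jnd == pytest.approx(0.0, abs=1e-9)
        assert res.achromatic_jnd == pytest.approx(np.log(3) / 0.05)
        assert res.achromatic_category is DiscriminabilityCategory.DISCRIMINABLE


class TestGreenness:
    def test_equal_catches_half(self):
        assert greenness_chromatic(qcv([1, 1, 2.0, 2.0])) == 0.5

    def test_three_to_one(self):
        assert greenness_chromatic(qcv([1, 1, 3.0, 1.0])) == 0.75

    def test_limit_small_mw(self):
        assert greenness_chromatic(qcv([1, 1, 1e-12, 1.0])) < 1e-11

    def test_strictly_increasing_in_mw(self):
        vals = [greenness_chromatic(qcv([1, 1, m, 2.0]))
                for m in np.linspace(0.1, 5, 25)]
        assert np.all(np.diff(vals) > 0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            greenness_chromatic(qcv([1, 1, 0.0, 0.0]))
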
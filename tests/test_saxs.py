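"""Form factors and forward intensity prediction (Debye and Monte Carlo)."""

import numpy as np
import pytest

import foldsaxs as fs
from foldsaxs.elements import ATOMIC_NUMBER
from foldsaxs.saxs import SolventModel

TABLE = fs.load_default_table()


class TestFormFactors:
    def test_f0_equals_c_plus_sum_a_and_matches_atomic_number(self):
        for element in TABLE.elements:
            entry = TABLE.entry(element)
            f0 = float(fs.atomic_form_factor(element, 0.0, TABLE))
            assert f0 == pytest.approx(entry.c + sum(entry.a), abs=1e-12)
            assert f0 == pytest.approx(ATOMIC_NUMBER[element], abs=0.2)

    def test_carbon_f0_close_to_six(self):
        assert float(fs.atomic_form_factor("C", 0.0, TABLE)) == pytest.approx(6.0, abs=0.2)

    @pytest.mark.parametrize("element", ["C", "N", "O"])
    def test_strictly_decreasing_on_low_q(self, element):
        q = np.linspace(0.0, 1.0, 500)
        f = fs.atomic_form_factor(element, q, TABLE)
        assert np.all(np.diff(f) < 0)

    def test_unknown_element_lists_available(self):
        with pytest.raises(fs.ValidationError, match="available"):
            fs.atomic_form_factor("Xx", 0.1, TABLE)

    def test_bad_table_entry_rejected(self):
        table = fs.FormFactorTable()
        with pytest.raises(fs.ValidationError):
            table.add("C", [1, 1, 1, 1], [1, 1, 1, 1], 10.0)  # f(0)=14, not ~6


class TestEffectiveFormFactor:
    def test_zero_density_equals_vacuum(self):
        q = np.linspace(0.0, 0.5, 20)
        solvent = SolventModel(electron_density=0.0, mode="excluded_volume")
        np.testing.assert_allclose(
            fs.effective_form_factor("C", q, TABLE, solvent),
            fs.atomic_form_factor("C", q, TABLE),
        )

    def test_excluded_volume_at_q0_subtracts_rho_v(self):
        solvent = SolventModel(mode="excluded_volume")  # water, 334 e/nm³
        v_c = TABLE.entry("C").v_disp_nm3
        f0 = float(fs.atomic_form_factor("C", 0.0, TABLE))
        expected = f0 - 334.0 * v_c
        assert float(fs.effective_form_factor("C", 0.0, TABLE, solvent)) == pytest.approx(expected)
        assert expected < f0

    def test_hydrogen_contrast_is_negative_in_water(self):
        # V_H > f_H(0)/rho_s: hydrogen scatters below the water background
        solvent = SolventModel(mode="excluded_volume")
        assert float(fs.effective_form_factor("H", 0.0, TABLE, solvent)) < 0

    def test_missing_volume_errors_in_excluded_mode(self):
        solvent = SolventModel(mode="excluded_volume")
        with pytest.raises(fs.ValidationError, match="displaced volume"):
            fs.effective_form_factor("Na", 0.1, TABLE, solvent)


@pytest.fixture(scope="module")
def two_atom_model():
    return fs.rigid_reference_shapes("two_points", distance=0.5, element="C")


@pytest.fixture(scope="module")
def ten_atom_model():
    return fs.rigid_reference_shapes("gaussian_blob", n_beads=10, rg=0.6, seed=4)


class TestDebyeIntensity:
    def test_single_atom_is_f_squared(self):
        model = fs.rigid_reference_shapes("two_points", distance=0.5).with_coordinates(
            np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        )
        single = fs.MolecularModel([model.atoms[0]], np.zeros((1, 3)))
        q = np.linspace(0.0, 0.6, 25)
        curve = fs.debye_intensity(single, q, TABLE)
        np.testing.assert_allclose(
            curve.intensity, fs.atomic_form_factor("C", q, TABLE) ** 2, rtol=1e-12
        )

    def test_two_atoms_match_closed_form(self, two_atom_model):
        q = np.linspace(0.01, 0.8, 40)
        r_angstrom = 5.0
        f = fs.atomic_form_factor("C", q, TABLE)
        expected = 2 * f**2 * (1 + np.sin(q * r_angstrom) / (q * r_angstrom))
        curve = fs.debye_intensity(two_atom_model, q, TABLE)
        np.testing.assert_allclose(curve.intensity, expected, rtol=1e-9)

    def test_q0_limit_is_total_f0_squared(self, ten_atom_model):
        curve = fs.debye_intensity(ten_atom_model, [0.0], TABLE)
        f0_sum = sum(
            float(fs.atomic_form_factor(el, 0.0, TABLE)) for el in ten_atom_model.elements()
        )
        assert curve.intensity[0] == pytest.approx(f0_sum**2, rel=1e-9)

    def test_vacuum_intensity_positive(self, ten_atom_model):
        q = np.linspace(0.0, 1.0, 60)
        assert np.all(fs.debye_intensity(ten_atom_model, q, TABLE).intensity > 0)


class TestOrientationalAverage:
    def test_single_atom_exact_regardless_of_directions(self):
        single = fs.MolecularModel(
            [fs.rigid_reference_shapes("two_points", distance=1.0).atoms[0]],
            np.array([[0.3, -0.2, 0.1]]),
        )
        q = np.linspace(0.05, 0.5, 10)
        curve = fs.orientational_average_intensity(single, q, TABLE, n_vectors=7)
        np.testing.assert_allclose(
            curve.intensity, fs.atomic_form_factor("C", q, TABLE) ** 2, rtol=1e-10
        )

    def test_random_sampler_matches_debye_within_3_stderr(self, two_atom_model):
        q = np.linspace(0.02, 0.8, 25)
        mc = fs.orientational_average_intensity(
            two_atom_model, q, TABLE, n_vectors=10_000, seed=123, sampling="random"
        )
        exact = fs.debye_intensity(two_atom_model, q, TABLE)
        assert np.all(np.abs(mc.intensity - exact.intensity) <= 3 * mc.sigma)

    def test_same_seed_reproduces_curve_exactly(self, ten_atom_model):
        q = np.linspace(0.05, 0.5, 8)
        kwargs = dict(n_vectors=200, seed=9, sampling="random")
        a = fs.orientational_average_intensity(ten_atom_model, q, TABLE, **kwargs)
        b = fs.orientational_average_intensity(ten_atom_model, q, TABLE, **kwargs)
        np.testing.assert_array_equal(a.intensity, b.intensity)

    def test_fibonacci_default_agrees_within_5pct_rms_at_500_vectors(self, ten_atom_model):
        q = np.linspace(0.01, 0.5, 30)
        mc = fs.orientational_average_intensity(ten_atom_model, q, TABLE, n_vectors=500)
        exact = fs.debye_intensity(ten_atom_model, q, TABLE)
        rel = (mc.intensity - exact.intensity) / exact.intensity
        assert np.sqrt((rel**2).mean()) < 0.05


class TestEnsembleIntensity:
    def _traj(self, frames):
        model = fs.rigid_reference_shapes("rod", n_beads=4, spacing=0.3)
        return fs.TrajectoryFrames(model.with_coordinates(frames[0]), frames, 0.1)

    def test_identical_frames_equal_single_frame(self):
        model = fs.rigid_reference_shapes("rod", n_beads=4, spacing=0.3)
        traj = self._traj([model.coordinates] * 3)
        q = np.linspace(0.01, 0.5, 15)
        ensemble = fs.ensemble_intensity(traj, q, TABLE)
        single = fs.debye_intensity(model, q, TABLE)
        np.testing.assert_allclose(ensemble.intensity, single.intensity, rtol=1e-12)

    def test_two_frames_give_arithmetic_mean(self):
        model = fs.rigid_reference_shapes("rod", n_beads=4, spacing=0.3)
        stretched = model.coordinates * 1.8
        traj = self._traj([model.coordinates, stretched])
        q = np.linspace(0.01, 0.5, 15)
        ensemble = fs.ensemble_intensity(traj, q, TABLE)
        a = fs.debye_intensity(model, q, TABLE).intensity
        b = fs.debye_intensity(model.with_coordinates(stretched), q, TABLE).intensity
        np.testing.assert_allclose(ensemble.intensity, (a + b) / 2, rtol=1e-12)

    def test_compact_ensemble_normalized_kratky_exceeds_extended_at_high_q(
        self, two_state_system
    ):
        # smaller Rg decays slower: the folded ensemble's I(0)-normalised
        # Kratky curve lies above the unfolded one at the high-q end
        curves = two_state_system["curves"]
        normed = {
            name: fs.kratky_transform(c).intensity / c.intensity[0]
            for name, c in curves.items()
        }
        assert normed["fc"][-1] > normed["uf"][-1]
        # and the unfolded (extended) curve keeps rising across the grid
        assert np.argmax(normed["uf"]) >= len(normed["uf"]) - 2

    def test_empty_after_striding_rejected(self):
        model = fs.rigid_reference_shapes("rod", n_beads=4, spacing=0.3)
        traj = self._traj([model.coordinates])
        with pytest.raises(fs.ValidationError):
            fs.ensemble_intensity(traj, [0.1], TABLE, stride=0)
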
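import numpy as np
import pytest
import tifffile
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from dissolvox import (
    Compound,
    TabletSpec,
    VoxelMatrix,
    compound_masses,
    cylinder_mask,
    desirability_score,
    image_porosity,
    read_tiff_stack,
    recovery_report,
    write_tiff_stack,
)
from dissolvox.voxel_matrix import (
    TiffFormatError,
    UnknownLabelError,
    linear_ramp_desirability,
    round_half_up,
)

LABELS = [0, 1, 31, 200]
LABEL_MAP = {0: "air", 1: "compound", 31: "compound", 200: "medium"}


def make_matrix(labels, edge=0.028):
    return VoxelMatrix(np.asarray(labels, dtype=np.uint8), edge, LABEL_MAP)


class TestTiffRoundTrip:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        arrays(
            np.uint8,
            st.tuples(
                st.integers(1, 4), st.integers(1, 6), st.integers(1, 6)
            ),
            elements=st.sampled_from(LABELS),
        )
    )
    def test_round_trip_is_bit_exact(self, tmp_path_factory, labels):
        path = tmp_path_factory.mktemp("tiff") / "m.tif"
        matrix = make_matrix(labels)
        write_tiff_stack(matrix, path)
        back = read_tiff_stack(path, LABEL_MAP)
        assert np.array_equal(back.labels, matrix.labels)
        assert back.n_slices == matrix.labels.shape[0]

    def test_all_air_stack(self, tmp_path):
        path = tmp_path / "air.tif"
        write_tiff_stack(make_matrix(np.zeros((2, 3, 3))), path)
        m = read_tiff_stack(path, LABEL_MAP)
        assert m.n_slices == 2 and np.all(m.labels == 0)

    def test_directory_of_numbered_slices(self, tmp_path):
        ref = np.arange(18, dtype=np.uint8).reshape(2, 3, 3) % 2
        for i in range(2):
            tifffile.imwrite(tmp_path / f"slice_{i:03d}.tif", ref[i])
        m = read_tiff_stack(tmp_path, LABEL_MAP)
        assert np.array_equal(m.labels, ref)

    def test_unknown_grey_value_names_value_and_slice(self, tmp_path):
        data = np.zeros((3, 2, 2), dtype=np.uint8)
        data[1, 0, 0] = 77
        tifffile.imwrite(tmp_path / "bad.tif", data, photometric="minisblack")
        with pytest.raises(UnknownLabelError, match="77.*slice 1"):
            read_tiff_stack(tmp_path / "bad.tif", LABEL_MAP)

    def test_non_8bit_input_rejected(self, tmp_path):
        tifffile.imwrite(tmp_path / "b16.tif", np.zeros((2, 2, 2), dtype=np.uint16))
        with pytest.raises(TiffFormatError):
            read_tiff_stack(tmp_path / "b16.tif", LABEL_MAP)


class TestCompoundMasses:
    def test_empty_matrix_all_masses_zero(self, compounds):
        masses = compound_masses(make_matrix(np.zeros((2, 2, 2))), compounds)
        assert all(m == 0.0 for m in masses.values())

    def test_unit_arithmetic_mm_kg_m3_to_mg(self, api):
        # 1e6 voxels of edge 0.028 mm at 1447.2 kg/m^3 -> ~31.77 mg
        labels = np.ones((100, 100, 100), dtype=np.uint8)
        masses = compound_masses(make_matrix(labels), [api])
        assert masses[1] == pytest.approx(1e6 * 0.028**3 * 1.4472, rel=1e-12)
        assert masses[1] == pytest.approx(31.77, abs=0.01)

    def test_doubling_edge_multiplies_masses_by_eight(self, compounds, rng):
        labels = rng.choice([0, 1, 31], size=(5, 6, 6)).astype(np.uint8)
        m1 = compound_masses(make_matrix(labels, 0.028), compounds)
        m2 = compound_masses(make_matrix(labels, 0.056), compounds)
        for g in m1:
            assert m2[g] == pytest.approx(8 * m1[g], rel=1e-12)

    def test_additive_over_disjoint_partition(self, compounds, rng):
        labels = rng.choice([0, 1, 31], size=(6, 6, 6)).astype(np.uint8)
        whole = compound_masses(make_matrix(labels), compounds)
        top = compound_masses(make_matrix(labels[:3]), compounds)
        bottom = compound_masses(make_matrix(labels[3:]), compounds)
        for g in whole:
            assert whole[g] == pytest.approx(top[g] + bottom[g], rel=1e-12)

    def test_missing_compound_raises(self):
        with pytest.raises(KeyError):
            compound_masses(make_matrix(np.ones((2, 2, 2))), [])


class TestImagePorosity:
    def test_all_air_is_100(self):
        assert image_porosity(make_matrix(np.zeros((2, 2, 2)))) == 100.0

    def test_no_air_is_0(self):
        assert image_porosity(make_matrix(np.ones((2, 2, 2)))) == 0.0

    def test_known_fraction(self):
        labels = np.zeros((2, 2, 2), dtype=np.uint8)
        labels[0] = 1  # half solid
        assert image_porosity(make_matrix(labels)) == pytest.approx(50.0)

    def test_cylindrical_region(self):
        shape = (4, 11, 11)
        mask = cylinder_mask(shape, 1.0, 9.0, 4.0)
        labels = np.zeros(shape, dtype=np.uint8)
        labels[mask] = 31  # solid cylinder in an air bounding box
        assert image_porosity(make_matrix(labels, 1.0), region=mask) == 0.0
        assert image_porosity(make_matrix(labels, 1.0)) > 0.0


class TestRecoveryReport:
    def _spec(self, api_mg, ex_mg):
        return TabletSpec(
            diameter=11.28, height=3.5, total_mass=api_mg + ex_mg,
            api_mass=api_mg, excipient_mass=ex_mg,
        )

    def test_identical_masses_give_100_everywhere(self, compounds, api, excipient):
        labels = np.zeros((10, 12, 12), dtype=np.uint8)
        labels[:, :6] = 1
        labels[:, 6:] = 31
        m = make_matrix(labels)
        masses = compound_masses(m, compounds)
        report = recovery_report(m, compounds, self._spec(masses[1], masses[31]))
        for value in report.recoveries().values():
            assert value == pytest.approx(100.0, rel=1e-12)
        assert report.desirability == pytest.approx(1.0)

    def test_total_recovery_is_mass_weighted_combination(self, compounds, rng):
        labels = rng.choice([0, 1, 31], size=(8, 8, 8)).astype(np.uint8)
        m = make_matrix(labels)
        real = self._spec(30.0, 50.0)
        rep = recovery_report(m, compounds, real)
        w_api = real.api_mass / (real.api_mass + real.excipient_mass)
        expected = w_api * rep.recovery_api + (1 - w_api) * rep.recovery_excipient
        assert rep.recovery_total == pytest.approx(expected, rel=1e-12)

    def test_zero_real_mass_rejected(self):
        with pytest.raises(ValueError):
            TabletSpec(diameter=11.28, height=3.5, total_mass=100.0,
                       api_mass=0.0, excipient_mass=100.0)


class TestDesirability:
    def test_all_ones(self):
        assert desirability_score([1.0] * 6) == 1.0

    def test_zero_annihilates(self):
        assert desirability_score([1, 1, 0, 1, 1, 1]) == 0.0

    def test_closed_form_single_half(self):
        assert desirability_score([1, 1, 1, 1, 1, 0.5]) == pytest.approx(
            0.5 ** (1 / 6), rel=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6), st.randoms())
    def test_permutation_invariant(self, values, random):
        shuffled = list(values)
        random.shuffle(shuffled)
        assert desirability_score(values) == pytest.approx(
            desirability_score(shuffled), rel=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 0.99), min_size=2, max_size=6),
           st.integers(0, 5), st.floats(0.001, 0.2))
    def test_monotone_in_each_component(self, values, idx, bump):
        idx = idx % len(values)
        raised = list(values)
        raised[idx] = min(1.0, raised[idx] + bump)
        assert desirability_score(raised) >= desirability_score(values)

    def test_ramp_mapping(self):
        assert linear_ramp_desirability(100.0) == 1.0
        assert linear_ramp_desirability(75.0) == 0.0
        assert linear_ramp_desirability(87.5) == pytest.approx(0.5)


def test_round_half_up_matches_printed_precision():
    assert round_half_up(84.3499, 1) == 84.3
    assert round_half_up(99.85, 1) == 99.9
    assert round_half_up(98.25, 1) == 98.3
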
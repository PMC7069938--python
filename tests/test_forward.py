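"""Forward-model assembly: delay law, column oracle, windowing, diagnostics.

The central correctness property: every column of the matrix built by
delay-shifting a single PSF record must equal the directly synthesized RF of
a unit source at that column's grid point.
"""

import numpy as np
import pytest

from sparsebeam import (
    PA,
    US_PLANEWAVE,
    PSFRecord,
    SourceSet,
    build_matrix,
    delay_law,
    make_grid,
    make_linear_probe,
    model_diagnostics,
    select_elements,
    synthesize_rf,
    vectorize_rf,
)
from sparsebeam.forward import ForwardModel


@pytest.fixture(scope="module")
def small_model(small_probe, pulse, small_grid):
    subset = select_elements(small_probe, 16, "all")
    rf = synthesize_rf(
        SourceSet(positions=[(0.0, 5e-3)], amplitudes=[1.0]),
        small_probe, subset, pulse, PA, 1500.0,
        t_start=2.9e-6, n_samples=128,
    )
    psf = PSFRecord(rf=rf, source_position=(0.0, 5e-3))
    return build_matrix(psf, small_grid, subset, 1500.0)


class TestDelayLaw:
    @pytest.mark.parametrize("modality", [PA, US_PLANEWAVE])
    def test_identity_at_the_psf_source(self, modality):
        dt = delay_law((1e-3, 15e-3), (1e-3, 15e-3), (0.0, 0.0),
                       1500.0, modality)
        assert dt == 0.0

    def test_pa_lateral_offset_hand_value(self):
        # element at origin, source on-axis at 15 mm, point 1 mm off-axis:
        # dt = (sqrt(1e-6 + 2.25e-4) - 0.015) / 1500  (evaluated in mpmath)
        dt = delay_law((1e-3, 15e-3), (0.0, 15e-3), (0.0, 0.0), 1500.0, PA)
        assert dt == pytest.approx(2.21973705e-8, rel=1e-6)

    def test_planewave_axial_offset_doubles(self):
        # a point 0.1 mm deeper: emission delay + return-path delay add
        dt = delay_law((0.0, 15.1e-3), (0.0, 15e-3), (0.0, 0.0),
                       1500.0, US_PLANEWAVE)
        assert dt == pytest.approx(2e-4 / 1500.0, rel=1e-9)
        dt_pa = delay_law((0.0, 15.1e-3), (0.0, 15e-3), (0.0, 0.0),
                          1500.0, PA)
        assert dt_pa == pytest.approx(1e-4 / 1500.0, rel=1e-9)


class TestBuildMatrix:
    def test_column_at_psf_source_is_the_psf(self, small_model, small_probe,
                                             pulse, small_grid):
        p = small_grid.point_index(*small_grid.nearest_cell(0.0, 5e-3))
        subset = select_elements(small_probe, 16, "all")
        rf = synthesize_rf(
            SourceSet(positions=[(0.0, 5e-3)], amplitudes=[1.0]),
            small_probe, subset, pulse, PA, 1500.0,
            t_start=2.9e-6, n_samples=128,
        )
        psf_vec = vectorize_rf(small_model, rf)
        np.testing.assert_allclose(small_model.matrix[:, p], psf_vec,
                                   atol=1e-12)

    @pytest.mark.parametrize("modality", [PA, US_PLANEWAVE])
    def test_every_column_matches_synthesized_point_response(
            self, small_probe, pulse, small_grid, modality):
        """The module's core oracle: columns vs direct synthesis, < 1e-6."""
        subset = select_elements(small_probe, 16, "all")
        t_start = 2.9e-6 if modality == PA else 6.2e-6
        rf = synthesize_rf(
            SourceSet(positions=[(0.0, 5e-3)], amplitudes=[1.0]),
            small_probe, subset, pulse, modality, 1500.0,
            t_start=t_start, n_samples=128,
        )
        psf = PSFRecord(rf=rf, source_position=(0.0, 5e-3))
        model = build_matrix(psf, small_grid, subset, 1500.0)
        for p in range(small_grid.n_points):
            x, z = small_grid.point_xz(p)
            direct = synthesize_rf(
                SourceSet(positions=[(x, z)], amplitudes=[1.0]),
                small_probe, subset, pulse, modality, 1500.0,
                t_start=t_start, n_samples=128,
            )
            S = vectorize_rf(model, direct)
            err = np.linalg.norm(model.matrix[:, p] - S) / np.linalg.norm(S)
            assert err < 1e-6

    def test_replica_row_count_is_4608(self, engine):
        # 128 elements x 36 time samples per element
        model = engine.assets(128)["model"]
        assert model.m == 4608
        assert model.n == 793

    def test_subset_restriction_commutes_with_assembly(
            self, small_probe, pulse, small_grid):
        full = select_elements(small_probe, 16, "all")
        rf = synthesize_rf(
            SourceSet(positions=[(0.0, 5e-3)], amplitudes=[1.0]),
            small_probe, full, pulse, PA, 1500.0,
            t_start=2.9e-6, n_samples=128,
        )
        psf = PSFRecord(rf=rf, source_position=(0.0, 5e-3))
        sub = select_elements(small_probe, 5, "regular_with_endpoints")
        model_full = build_matrix(psf, small_grid, full, 1500.0,
                                  n_window_samples=48)
        model_sub = build_matrix(psf, small_grid, sub, 1500.0,
                                 n_window_samples=48)
        rows = []
        pos = {int(e): i for i, e in enumerate(full.indices)}
        for e in sub.indices:
            k = pos[int(e)]
            rows.extend(range(k * 48, (k + 1) * 48))
        np.testing.assert_allclose(model_full.matrix[rows], model_sub.matrix,
                                   atol=1e-12)

    def test_column_energy_conserved(self, small_model):
        norms = np.linalg.norm(small_model.matrix, axis=0)
        ref = norms[small_model.grid.point_index(
            *small_model.grid.nearest_cell(0.0, 5e-3))]
        # small grid, well-contained pulse: truncation budget ~0
        assert np.all(norms > 0.999 * ref)
        assert np.all(norms < 1.001 * ref)

    def test_single_point_grid_gives_single_column(self, small_probe, pulse):
        subset = select_elements(small_probe, 16, "all")
        rf = synthesize_rf(
            SourceSet(positions=[(0.0, 5e-3)], amplitudes=[1.0]),
            small_probe, subset, pulse, PA, 1500.0,
            t_start=2.9e-6, n_samples=128,
        )
        psf = PSFRecord(rf=rf, source_position=(0.0, 5e-3))
        grid = make_grid(0.0, 0.0, 5e-3, 5e-3, 12.5e-6)
        model = build_matrix(psf, grid, subset, 1500.0)
        assert model.matrix.shape == (128 * 16, 1)
        np.testing.assert_allclose(
            model.matrix[:, 0], vectorize_rf(model, rf), atol=1e-12)

    def test_psf_single_peak_validation(self, small_model, small_probe,
                                        pulse):
        subset = select_elements(small_probe, 16, "all")
        good = synthesize_rf(
            SourceSet(positions=[(0.0, 5e-3)], amplitudes=[1.0]),
            small_probe, subset, pulse, PA, 1500.0,
            t_start=2.9e-6, n_samples=256,
        )
        assert PSFRecord(rf=good, source_position=(0.0, 5e-3)
                         ).validate_single_peak()
        double = synthesize_rf(
            SourceSet(positions=[(0.0, 5e-3), (0.0, 5.5e-3)],
                      amplitudes=[1.0, 1.0]),
            small_probe, subset, pulse, PA, 1500.0,
            t_start=2.9e-6, n_samples=256,
        )
        assert not PSFRecord(rf=double, source_position=(0.0, 5e-3)
                             ).validate_single_peak()


class TestDiagnostics:
    def _wrap(self, A):
        """Minimal ForwardModel carrying only what diagnostics needs."""
        grid = make_grid(0, (A.shape[1] - 1) * 12.5e-6, 0, 0, 12.5e-6)
        probe = make_linear_probe(2, 100e-6)
        subset = select_elements(probe, 2, "all")
        return ForwardModel(
            matrix=A, grid=grid, probe=probe, subset=subset,
            window_starts=np.zeros(2, int),
            n_window_samples=A.shape[0] // 2, sampling_rate=62.5e6,
            t0=0.0, source_position=(0.0, 0.0), modality=PA, c=1500.0,
        )

    def test_orthonormal_columns(self):
        A = np.eye(6)[:, :4]
        d = model_diagnostics(self._wrap(A))
        assert d["rank"] == 4
        assert d["mutual_coherence"] == pytest.approx(0.0, abs=1e-12)
        assert not d["underdetermined"]

    def test_duplicated_column_drops_rank(self):
        rng = np.random.default_rng(0)
        A = rng.standard_normal((8, 4))
        A[:, 3] = A[:, 0]
        d = model_diagnostics(self._wrap(A))
        assert d["rank"] < 4
        assert d["underdetermined"]
        assert d["mutual_coherence"] == pytest.approx(1.0)

    def test_replica_model_is_underdetermined(self, engine):
        # the qualitative regime of the full-array configuration: more grid
        # unknowns (793) than independent data directions
        d = model_diagnostics(engine.assets(128)["model"])
        assert d["underdetermined"]
        assert d["rank"] < 793
        assert 300 < d["rank"] < 400  # same regime as the measured system
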
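"""Tracker contracts: turn bound, amplitude gating, ACT termination,
reproducibility, and the plain-text streamline round-trip."""

import numpy as np
import pytest
from scipy import ndimage

from lingtract.exceptions import InputError, ParameterError
from lingtract.io import VolumeGrid
from lingtract.seeds import SeedRegion, build_seed
from lingtract.tracking import (
    OrientationField,
    TractMap,
    TrackingParams,
    binarize,
    load_streamlines,
    max_turn_angle,
    save_streamlines,
    track,
)
from tests.conftest import build_corridor


class TestMaxTurnAngle:
    def test_step_equals_radius_gives_60_degrees(self):
        assert max_turn_angle(1.0, 1.0) == pytest.approx(60.0)

    def test_straight_line_limit(self):
        assert max_turn_angle(1.0, 1e9) == pytest.approx(0.0, abs=1e-6)

    def test_degenerate_half_step_radius(self):
        assert max_turn_angle(1.0, 0.5) == pytest.approx(180.0)

    def test_radius_below_half_step_rejected(self):
        with pytest.raises(ParameterError):
            max_turn_angle(1.0, 0.4)
        with pytest.raises(ParameterError):
            TrackingParams(step_mm=2.0, min_curvature_radius_mm=0.5)


def corridor_params(**kw):
    defaults = dict(n_streamlines=200, max_steps=60, seed=1)
    defaults.update(kw)
    return TrackingParams(**defaults)


class TestTrack:
    def test_streamlines_confined_to_corridor(self, corridor):
        tissue, field, seed = corridor
        tm = track(seed, field, tissue, corridor_params())
        assert tm.n_accepted > 0
        outside = tissue.labels.data == 0
        assert tm.probability[outside].max() == 0.0

    def test_zero_dispersion_is_a_single_polyline(self, corridor):
        tissue, field, seed = corridor
        tm = track(seed, field, tissue, corridor_params(dispersion_deg=0.0))
        assert tm.n_accepted == tm.n_attempted
        first = tm.streamlines[0]
        for line in tm.streamlines[1:]:
            assert np.array_equal(line, first)
        on = tm.probability[tm.probability > 0]
        assert np.all(on == 1.0)

    def test_low_amplitude_wall_blocks_propagation(self, walled_corridor):
        tissue, field, seed = walled_corridor
        tm = track(seed, field, tissue, corridor_params())
        assert tm.probability[29:, :, :].max() == 0.0

    def test_reachability_matches_voxel_graph_oracle(self, walled_corridor):
        tissue, field, seed = walled_corridor
        params = corridor_params()
        tm = track(seed, field, tissue, params)
        # oracle: 26-connected components of trackable voxels with
        # amplitude >= threshold; visited voxels must stay in the
        # component(s) containing seed voxels
        passable = (tissue.labels.data != 0) & (
            field.amplitude >= params.min_fod_amplitude
        )
        comp, _ = ndimage.label(passable, structure=np.ones((3, 3, 3)))
        seed_labels = set(comp[seed.voxels[:, 0], seed.voxels[:, 1], seed.voxels[:, 2]])
        visited = np.argwhere(tm.visit_counts > 0)
        got = set(comp[visited[:, 0], visited[:, 1], visited[:, 2]])
        assert got <= seed_labels

    def test_curvature_contract_on_stored_polylines(self, phantom):
        tissue, field, _, peak = phantom[0], phantom[1], phantom[2], phantom[2]
        seed = build_seed(peak, tissue, k=60)
        params = TrackingParams(n_streamlines=300, seed=3)
        tm = track(seed, field, tissue, params)
        assert tm.n_accepted > 0
        for line in tm.streamlines:
            steps = np.diff(line, axis=0)
            norms = np.linalg.norm(steps, axis=1)
            assert np.allclose(norms, params.step_mm, atol=1e-9)
            cosang = np.sum(steps[1:] * steps[:-1], axis=1) / (norms[1:] * norms[:-1])
            angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            assert (angles <= params.max_turn_deg + 1e-6).all()

    def test_amplitude_contract_on_stored_polylines(self, phantom):
        tissue, field, peak = phantom[0], phantom[1], phantom[2]
        seed = build_seed(peak, tissue, k=60)
        params = TrackingParams(n_streamlines=300, seed=4)
        tm = track(seed, field, tissue, params)
        grid = field.grid
        for line in tm.streamlines:
            vox = np.rint(np.atleast_2d(grid.world_to_voxel(line))).astype(int)
            amps = field.amplitude[vox[:, 0], vox[:, 1], vox[:, 2]]
            assert (amps >= params.min_fod_amplitude).all()

    def test_reproducible_bit_exact(self, corridor):
        tissue, field, seed = corridor
        a = track(seed, field, tissue, corridor_params(seed=9))
        b = track(seed, field, tissue, corridor_params(seed=9))
        assert np.array_equal(a.probability, b.probability)
        assert a.n_accepted == b.n_accepted
        assert all(np.array_equal(x, y) for x, y in zip(a.streamlines, b.streamlines))

    def test_mass_conservation(self, corridor):
        tissue, field, seed = corridor
        tm = track(seed, field, tissue, corridor_params(seed=2))
        grid = field.grid
        total = 0
        for line in tm.streamlines:
            vox = np.rint(np.atleast_2d(grid.world_to_voxel(line))).astype(int)
            total += len(np.unique(vox, axis=0))
        assert tm.visit_counts.sum() == total

    def test_zero_accepted_is_flagged_not_raised(self, corridor):
        tissue, field, _ = corridor
        dead_seed = SeedRegion(np.array([[20, 9, 9]]), "left", "picture_naming")
        tm = track(dead_seed, field, tissue, corridor_params())
        assert tm.n_accepted == 0
        assert tm.probability.max() == 0.0

    def test_grid_mismatch_rejected(self, corridor):
        tissue, field, seed = corridor
        other = OrientationField(
            direction=field.direction[:-1],
            amplitude=field.amplitude[:-1],
            affine=field.affine,
        )
        with pytest.raises(InputError):
            track(seed, other, tissue, corridor_params())


class TestBinarize:
    def _map(self, value):
        prob = np.zeros((3, 3, 3))
        prob[1, 1, 1] = value
        return TractMap(probability=prob, affine=np.eye(4), n_accepted=10, n_attempted=10)

    def test_threshold_is_inclusive(self):
        assert not binarize(self._map(0.009), 0.01).any()
        assert binarize(self._map(0.01), 0.01)[1, 1, 1]

    def test_all_zero_map_gives_empty_mask(self):
        assert not binarize(self._map(0.0), 0.01).any()

    @pytest.mark.parametrize("bad", [0.0, -0.1, 1.5])
    def test_threshold_domain(self, bad):
        with pytest.raises(ParameterError):
            binarize(self._map(0.5), bad)


class TestStreamlineIO:
    def test_round_trip_bit_exact(self, tmp_path, corridor):
        tissue, field, seed = corridor
        tm = track(seed, field, tissue, corridor_params(seed=5))
        path = tmp_path / "tracts.txt"
        save_streamlines(tm.streamlines, path)
        back = load_streamlines(path)
        assert len(back) == len(tm.streamlines)
        for a, b in zip(tm.streamlines, back):
            assert np.array_equal(a, b)

    def test_wrong_header_rejected(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("not a streamline file\n")
        with pytest.raises(InputError):
            load_streamlines(p)
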
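import numpy as np
import pandas as pd
import pytest

from btbcul3.structure_io import write_multi_model, write_structure
from btbcul3.synthetic_data import (
    SyntheticComplexSpec,
    SyntheticTrajectorySpec,
    make_cn_complex,
    make_trajectory,
)
from btbcul3.trajectory import (
    TrajectoryEnsemble,
    pair_distance_series,
    parse_pair_spec,
    plateau_detect,
    read_trajectory,
    rmsd_timeseries,
    rmsf,
)

from oracles import apply_rigid_to_model, rigid_transform


@pytest.fixture(scope="module")
def topo():
    model, _ = make_cn_complex(
        SyntheticComplexSpec(n_fold=2, subunit_size=20, partner=False, seed=0)
    )
    return model


def _frame_models(topology, frames):
    import copy

    models = []
    for k in range(len(frames)):
        m = copy.deepcopy(topology)
        i = 0
        for res in m.residues():
            for atom in res.atoms:
                atom.coords = frames[k, i]
                i += 1
        models.append(m)
    return models


class TestReadTrajectory:
    def test_single_frame_identical_to_topology(self, tmp_path, topo):
        tp = tmp_path / "topo.pdb"
        fp = tmp_path / "frames.pdb"
        write_structure(topo, tp)
        write_multi_model([topo], fp)
        traj = read_trajectory(tp, fp, source="synthetic")
        assert traj.n_frames == 1
        assert np.abs(traj.frames[0] - traj.topology.coords()).max() <= 1e-3

    def test_jitter_fixture_round_trips(self, tmp_path, topo):
        ens, _ = make_trajectory(
            SyntheticTrajectorySpec(n_frames=5, sigma=0.3, seed=4), topo
        )
        tp, fp = tmp_path / "t.pdb", tmp_path / "f.pdb"
        write_structure(topo, tp)
        write_multi_model(_frame_models(topo, ens.frames), fp)
        traj = read_trajectory(tp, fp, dt=1.0, source="synthetic")
        assert traj.n_frames == 5
        assert np.abs(traj.frames - ens.frames).max() <= 1e-3

    def test_atom_count_mismatch_names_frame(self, tmp_path, topo):
        import copy

        tp, fp = tmp_path / "t.pdb", tmp_path / "f.pdb"
        write_structure(topo, tp)
        broken = copy.deepcopy(topo)
        broken.chains["A"][0].atoms.pop()
        write_multi_model([topo, broken], fp)
        with pytest.raises(ValueError, match="frame 1"):
            read_trajectory(tp, fp, source="synthetic")

    def test_times_strictly_increasing(self, topo):
        frames = np.repeat(topo.coords()[None], 3, axis=0)
        with pytest.raises(ValueError, match="increasing"):
            TrajectoryEnsemble(topo, frames, np.array([0.0, 0.0, 1.0]), {})


class TestRmsd:
    def test_static_trajectory_is_zero(self, topo):
        frames = np.repeat(topo.coords()[None], 8, axis=0)
        traj = TrajectoryEnsemble(topo, frames, np.arange(8.0), {})
        assert np.allclose(rmsd_timeseries(traj), 0.0, atol=1e-12)

    def test_rigidly_rotated_frames_fit_to_zero(self, topo, rng):
        ref = topo.coords()
        frames = [ref]
        for _ in range(6):
            rot, trans = rigid_transform(rng)
            frames.append(ref @ rot.T + trans)
        traj = TrajectoryEnsemble(topo, np.array(frames), np.arange(7.0), {})
        assert rmsd_timeseries(traj).max() < 1e-9

    def test_jitter_matches_isotropic_closed_form(self, topo):
        """Against the noiseless reference, E[RMSD] = sqrt(3) * sigma."""
        sigma = 0.4
        ens, _ = make_trajectory(
            SyntheticTrajectorySpec(n_frames=60, sigma=sigma, seed=9), topo
        )
        series = rmsd_timeseries(ens, reference=topo)
        assert series.mean() == pytest.approx(np.sqrt(3) * sigma, rel=0.05)

    def test_mdanalysis_oracle_agreement(self, topo, rng):
        mda = pytest.importorskip("MDAnalysis")
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        ref = topo.coords()
        rot, trans = rigid_transform(rng)
        frame = (ref + rng.normal(scale=0.5, size=ref.shape)) @ rot.T + trans
        traj = TrajectoryEnsemble(topo, np.array([ref, frame]), np.arange(2.0), {})
        ours = rmsd_timeseries(traj).iloc[1]
        theirs = mda_rmsd(frame, ref, center=True, superposition=True)
        assert ours == pytest.approx(theirs, abs=1e-6)

    def test_empty_selection_rejected(self, topo):
        frames = np.repeat(topo.coords()[None], 3, axis=0)
        traj = TrajectoryEnsemble(topo, frames, np.arange(3.0), {})
        with pytest.raises((KeyError, ValueError)):
            rmsd_timeseries(traj, fit_selection="nonexistent")

    def test_statistics_invariant_under_global_rigid_motion(self, topo, rng):
        ens, _ = make_trajectory(
            SyntheticTrajectorySpec(n_frames=30, sigma=0.5, seed=2), topo
        )
        base_rmsd = rmsd_timeseries(ens, reference=topo)
        base_rmsf = rmsf(ens)
        rot, trans = rigid_transform(rng)
        moved_frames = ens.frames @ rot.T + trans
        moved_topo = apply_rigid_to_model(topo, rot, trans)
        moved = TrajectoryEnsemble(moved_topo, moved_frames, ens.times, {})
        assert np.allclose(rmsd_timeseries(moved, reference=moved_topo), base_rmsd, atol=1e-9)
        assert np.allclose(rmsf(moved), base_rmsf, atol=1e-9)


class TestRmsf:
    def test_static_trajectory_is_zero(self, topo):
        frames = np.repeat(topo.coords()[None], 12, axis=0)
        traj = TrajectoryEnsemble(topo, frames, np.arange(12.0), {})
        assert np.allclose(rmsf(traj), 0.0, atol=1e-12)

    def test_isotropic_closed_form(self, topo):
        sigma = 0.5
        ens, man = make_trajectory(
            SyntheticTrajectorySpec(n_frames=2000, sigma=sigma, seed=5), topo
        )
        values = rmsf(ens)
        assert values.mean() == pytest.approx(man["expected_rmsf"]["uniform"], rel=0.05)

    def test_two_tier_profile_rank_order(self, topo):
        profile = {}
        core, tail = [], []
        for res in topo.residues():
            key = (res.chain_id, res.seq_number)
            if res.seq_number <= 10:
                profile[key] = 0.3
                core.append(key)
            else:
                profile[key] = 1.5
                tail.append(key)
        ens, _ = make_trajectory(
            SyntheticTrajectorySpec(n_frames=400, sigma=0.0, sigma_profile=profile, seed=6),
            topo,
        )
        values = rmsf(ens)
        assert values.loc[core].max() < values.loc[tail].min()

    def test_window_needs_ten_frames(self, topo):
        frames = np.repeat(topo.coords()[None], 30, axis=0)
        traj = TrajectoryEnsemble(topo, frames, np.arange(30.0), {})
        with pytest.raises(ValueError, match=">= 10"):
            rmsf(traj, window=(0.0, 5.0))

    def test_window_outside_range_rejected(self, topo):
        frames = np.repeat(topo.coords()[None], 30, axis=0)
        traj = TrajectoryEnsemble(topo, frames, np.arange(30.0), {})
        with pytest.raises(ValueError, match="outside"):
            rmsf(traj, window=(100.0, 200.0))


class TestPairDistances:
    def test_identical_atom_specs_rejected(self, topo):
        frames = topo.coords()[None]
        traj = TrajectoryEnsemble(topo, frames, np.array([0.0]), {})
        with pytest.raises(ValueError, match="same atom"):
            pair_distance_series(traj, [(("A", 1, "CA"), ("A", 1, "CA"))])

    def test_static_fixture_constant_distance(self, topo):
        frames = np.repeat(topo.coords()[None], 4, axis=0)
        traj = TrajectoryEnsemble(topo, frames, np.arange(4.0), {})
        a = topo.chains["A"][0].atom("CA").coords
        b = topo.chains["B"][0].atom("CA").coords
        expected = float(np.linalg.norm(a - b))
        df = pair_distance_series(traj, [(("A", 1, "CA"), ("B", 1, "CA"))])
        assert np.allclose(df.iloc[:, 0], expected)

    def test_jitter_series_stays_in_band(self, topo):
        sigma = 0.3
        ens, _ = make_trajectory(
            SyntheticTrajectorySpec(n_frames=300, sigma=sigma, seed=8), topo
        )
        a = topo.chains["A"][0].atom("CA").coords
        b = topo.chains["B"][0].atom("CA").coords
        ref_d = float(np.linalg.norm(a - b))
        df = pair_distance_series(ens, [(("A", 1, "CA"), ("B", 1, "CA"))])
        # both endpoints jittered: displacement variance 2 * 3 sigma^2
        assert abs(df.iloc[:, 0].mean() - ref_d) < 3 * np.sqrt(6) * sigma / np.sqrt(300) + 0.05

    def test_unresolvable_atom_named(self, topo):
        frames = topo.coords()[None]
        traj = TrajectoryEnsemble(topo, frames, np.array([0.0]), {})
        with pytest.raises(KeyError, match="Q:5:ZZ"):
            pair_distance_series(traj, ["Q:5:ZZ-A:1:CA"])

    def test_spec_mini_language(self):
        a, b = parse_pair_spec("A:84:NH2-B:121:OD2")
        assert a == ("A", 84, "NH2")
        assert b == ("B", 121, "OD2")
        with pytest.raises(ValueError):
            parse_pair_spec("garbage")


class TestPlateau:
    def test_constant_series_onset_zero(self):
        t = np.arange(0.0, 41.0, 2.0)
        assert plateau_detect(pd.Series(np.ones_like(t), index=t)) == 0.0

    def test_ramp_then_flat_onset_at_ramp_end(self):
        t = np.arange(0.0, 41.0, 2.0)
        v = np.where(t < 20.0, 0.15 * t, 3.0)
        onset = plateau_detect(pd.Series(v, index=t), window_span=10.0, tol=0.2)
        assert onset == 20.0

    def test_unbounded_ramp_never_plateaus(self):
        t = np.arange(0.0, 41.0, 1.0)
        assert plateau_detect(pd.Series(0.5 * t, index=t), tol=1.0) is None

    @pytest.mark.parametrize("pair", [(0.2, 0.5), (0.5, 1.0), (1.0, 2.0)])
    def test_monotone_in_tolerance(self, pair):
        rng = np.random.default_rng(3)
        t = np.arange(0.0, 60.0, 1.0)
        v = np.where(t < 25, 0.2 * t, 5.0) + rng.normal(scale=0.2, size=len(t))
        series = pd.Series(v, index=t)
        tight = plateau_detect(series, tol=pair[0])
        loose = plateau_detect(series, tol=pair[1])
        if tight is not None:
            assert loose is not None and loose <= tight

    def test_series_must_cover_two_windows(self):
        t = np.arange(0.0, 15.0, 1.0)
        with pytest.raises(ValueError, match="spans"):
            plateau_detect(pd.Series(np.ones_like(t), index=t), window_span=10.0)
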
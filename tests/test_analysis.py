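"""Stationary points, minimax paths, and barrier bookkeeping."""

import itertools

import numpy as np
import pytest

import pmfkit as pk
from pmfkit.analysis import EnergyProfile, ProfileState


def grid_fes(values, mask=None, range1=(0.0, 1.0), range2=(0.0, 1.0)):
    values = np.asarray(values, dtype=float)
    if mask is None:
        mask = np.zeros_like(values, dtype=bool)
    grid = pk.GridSpec(range1=range1, range2=range2, bins1=values.shape[0], bins2=values.shape[1])
    return pk.FES(values=values, mask=np.asarray(mask, dtype=bool), grid=grid, temperature=300.0)


class TestFindMinima:
    def test_harmonic_well_has_one_minimum_at_center(self):
        surf = pk.make_surface("harmonic_well", curvature=2.0)
        grid = pk.GridSpec((-2, 2), (-2, 2), 41, 41)
        minima = pk.find_minima(pk.fes_from_surface(surf, grid))
        assert len(minima) == 1
        assert minima[0].index == (20, 20)
        assert minima[0].best_position == pytest.approx((0.0, 0.0), abs=1e-9)

    def test_double_well_has_two_minima_at_the_wells(self, double_well):
        grid = pk.GridSpec((-2, 2), (1, 3), 60, 60)
        minima = pk.find_minima(pk.fes_from_surface(double_well, grid))
        assert len(minima) == 2
        got = sorted(m.best_position[0] for m in minima)
        assert got == pytest.approx([-1.0, 1.0], abs=0.01)

    def test_tilted_plane_minimum_at_lowest_corner(self):
        x = np.arange(8)[:, None] + 0.5 * np.arange(8)[None, :]
        minima = pk.find_minima(grid_fes(x))
        assert len(minima) == 1
        assert minima[0].index == (0, 0)

    def test_plateau_resolved_to_lowest_index(self):
        v = np.full((5, 5), 5.0)
        v[2, 2] = v[2, 3] = 1.0  # two-cell flat bottom
        minima = pk.find_minima(grid_fes(v))
        assert len(minima) == 1
        assert minima[0].index == (2, 2)

    def test_masked_fes_rejected(self):
        v = np.zeros((5, 5))
        with pytest.raises(ValueError, match="3x3 unmasked"):
            pk.find_minima(grid_fes(v, mask=np.ones((5, 5))))


class TestFindSaddles:
    def test_double_well_single_saddle_energy(self, double_well):
        grid = pk.GridSpec((-2, 2), (1, 3), 60, 60)
        fes = pk.fes_from_surface(double_well, grid)
        saddles = pk.find_saddles(fes)
        assert len(saddles) == 1
        deeper = min(m.best_energy for m in pk.find_minima(fes))
        assert saddles[0].best_energy - deeper == pytest.approx(13.8, abs=0.3)

    def test_harmonic_well_has_no_saddles(self):
        surf = pk.make_surface("harmonic_well", curvature=2.0)
        grid = pk.GridSpec((-2, 2), (-2, 2), 41, 41)
        assert pk.find_saddles(pk.fes_from_surface(surf, grid)) == []

    def test_muller_brown_saddles_match_oracle_within_one_cell(self, muller_brown, mb_oracle):
        grid = pk.GridSpec(muller_brown.domain[0], muller_brown.domain[1], 120, 120)
        fes = pk.fes_from_surface(muller_brown, grid)
        saddles = pk.find_saddles(fes)
        cell = np.array(grid.widths)
        assert len(saddles) == len(mb_oracle["saddles"])
        for ox, oy, oe in mb_oracle["saddles"]:
            nearest = min(saddles, key=lambda s: np.hypot(s.best_position[0] - ox,
                                                          s.best_position[1] - oy))
            assert abs(nearest.best_position[0] - ox) <= cell[0]
            assert abs(nearest.best_position[1] - oy) <= cell[1]
            assert nearest.best_energy == pytest.approx(oe, abs=0.3)


class TestMfep:
    def test_double_well_path_max_equals_saddle(self, double_well):
        grid = pk.GridSpec((-2, 2), (1, 3), 60, 60)
        fes = pk.fes_from_surface(double_well, grid)
        a, b = pk.main_basins(fes)
        path = pk.mfep(fes, a, b)
        saddle = pk.find_saddles(fes)[0]
        assert path.max_energy == pytest.approx(saddle.energy, abs=1e-12)
        # the path's top coincides with the saddle node within one cell
        top = path.nodes[path.barrier_index]
        assert max(abs(top[0] - saddle.index[0]), abs(top[1] - saddle.index[1])) <= 1

    def test_identical_endpoints_give_single_node(self):
        fes = grid_fes(np.zeros((5, 5)))
        m = pk.find_minima(grid_fes(np.arange(25.0).reshape(5, 5)))[0]
        path = pk.mfep(fes, m, m)
        assert len(path.nodes) == 1 and path.barrier == 0.0

    def test_corridor_gap_is_used(self):
        # a wall of high energy with one gap: the path must thread the gap
        v = np.zeros((5, 5))
        v[:, 2] = 10.0
        v[3, 2] = 2.0
        fes = grid_fes(v)
        a = pk.StationaryPoint(index=(2, 0), position=(0, 0), energy=0.0, kind="minimum")
        b = pk.StationaryPoint(index=(2, 4), position=(0, 0), energy=0.0, kind="minimum")
        path = pk.mfep(fes, a, b)
        assert path.max_energy == 2.0
        assert (3, 2) in path.nodes

    def test_masked_endpoint_rejected(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, 0] = True
        fes = grid_fes(np.zeros((5, 5)), mask=mask)
        a = pk.StationaryPoint(index=(0, 0), position=(0, 0), energy=0.0, kind="minimum")
        b = pk.StationaryPoint(index=(4, 4), position=(0, 0), energy=0.0, kind="minimum")
        with pytest.raises(ValueError, match="masked"):
            pk.mfep(fes, a, b)

    def test_no_route_through_full_mask_wall(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[:, 2] = True
        fes = grid_fes(np.zeros((5, 5)), mask=mask)
        a = pk.StationaryPoint(index=(2, 0), position=(0, 0), energy=0.0, kind="minimum")
        b = pk.StationaryPoint(index=(2, 4), position=(0, 0), energy=0.0, kind="minimum")
        with pytest.raises(ValueError, match="no unmasked path"):
            pk.mfep(fes, a, b)

    @pytest.mark.parametrize("seed", range(6))
    def test_minimax_optimality_against_threshold_oracle(self, seed):
        # independent oracle: the minimax value is the smallest threshold t
        # for which start and goal lie in one connected component of the
        # sub-grid {v <= t} (flood fill per candidate threshold)
        from scipy import ndimage

        rng = np.random.default_rng(seed)
        v = rng.uniform(0, 10, (6, 6))
        fes = grid_fes(v)
        start, goal = (0, 0), (5, 5)
        brute = np.inf
        for t in np.unique(v):
            labels, _ = ndimage.label(v <= t, structure=np.ones((3, 3), dtype=int))
            if labels[start] and labels[start] == labels[goal]:
                brute = t
                break
        a = pk.StationaryPoint(index=start, position=(0, 0), energy=float(v[start]), kind="minimum")
        b = pk.StationaryPoint(index=goal, position=(0, 0), energy=float(v[goal]), kind="minimum")
        path = pk.mfep(fes, a, b)
        assert path.max_energy == pytest.approx(brute, abs=1e-12)


def four_step_profile():
    """A 4-step mechanism built so the two conventions disagree on the
    rate-limiting step: TS2 is highest from RS, TS4 highest from its own
    intermediate."""
    return EnergyProfile(
        states=[
            ProfileState("RS", 0.0, "min"),
            ProfileState("TS1", 13.8, "ts"),
            ProfileState("TI1", 11.5, "min"),
            ProfileState("TS2", 16.1, "ts"),
            ProfileState("INT2", -2.0, "min"),
            ProfileState("TS3", 6.3, "ts"),
            ProfileState("TI2", 1.0, "min"),
            ProfileState("TS4", 14.9, "ts"),
            ProfileState("PS", -8.0, "min"),
        ],
        name="mechanism",
    )


class TestBarriers:
    def test_hand_computed_example(self):
        prof = EnergyProfile(states=[
            ProfileState("RS", 0.0, "min"),
            ProfileState("TS1", 5.0, "ts"),
            ProfileState("TI1", 2.0, "min"),
            ProfileState("TS2", 6.0, "ts"),
        ])
        table = pk.barriers(prof).set_index("label")
        assert table.loc["TS2", "dG_rel_prev"] == 4.0
        assert table.loc["TS2", "dG_rel_RS"] == 6.0
        assert table.attrs["rate_limiting_rel_RS"] == "TS2"
        assert table.attrs["rate_limiting_rel_prev"] == "TS1"

    def test_four_step_table_equals_hand_computation(self):
        table = pk.barriers(four_step_profile()).set_index("label")
        expected_rel_rs = {"RS": 0.0, "TS1": 13.8, "TI1": 11.5, "TS2": 16.1,
                          "INT2": -2.0, "TS3": 6.3, "TI2": 1.0, "TS4": 14.9, "PS": -8.0}
        expected_rel_prev = {"TS1": 13.8, "TS2": 4.6, "TS3": 8.3, "TS4": 13.9}
        for label, v in expected_rel_rs.items():
            assert table.loc[label, "dG_rel_RS"] == pytest.approx(v, abs=1e-12)
        for label, v in expected_rel_prev.items():
            assert table.loc[label, "dG_rel_prev"] == pytest.approx(v, abs=1e-12)
        # the conventions disagree, as they can for a real mechanism
        assert table.attrs["rate_limiting_rel_RS"] == "TS2"
        assert table.attrs["rate_limiting_rel_prev"] == "TS4"

    def test_rs_only_profile_has_no_barriers(self):
        table = pk.barriers(EnergyProfile(states=[ProfileState("RS", 0.0, "min")]))
        assert (table["kind"] == "ts").sum() == 0

    def test_missing_rs_rejected(self):
        prof = EnergyProfile(states=[ProfileState("A", 0.0, "min")])
        with pytest.raises(ValueError, match="no RS"):
            pk.barriers(prof)

    def test_ts_identity_links_the_two_conventions(self):
        # rel_RS(TS) - rel_prev(TS) = rel_RS(preceding intermediate), exactly
        table = pk.barriers(four_step_profile()).set_index("label")
        prev_min = {"TS1": "RS", "TS2": "TI1", "TS3": "INT2", "TS4": "TI2"}
        for ts, m in prev_min.items():
            assert (table.loc[ts, "dG_rel_RS"] - table.loc[ts, "dG_rel_prev"]
                    ) == pytest.approx(table.loc[m, "dG_rel_RS"], abs=1e-12)

    def test_constant_shift_changes_no_barrier(self):
        base = pk.barriers(four_step_profile())
        shifted = pk.barriers(four_step_profile().shifted(100.0))
        np.testing.assert_allclose(shifted["dG_rel_RS"], base["dG_rel_RS"], atol=1e-10)
        np.testing.assert_allclose(
            shifted["dG_rel_prev"].dropna(), base["dG_rel_prev"].dropna(), atol=1e-10
        )


class TestAssembleProfile:
    def test_shift_cancellation_at_shared_state(self):
        s1 = EnergyProfile(states=[ProfileState("RS", 0.0, "min"),
                                   ProfileState("TS1", 5.0, "ts"),
                                   ProfileState("TI1", 2.0, "min")], name="step1")
        # step 2 measured from its own zero, offset by 3 from step 1's scale
        s2 = EnergyProfile(states=[ProfileState("TI1", -1.0, "min"),
                                   ProfileState("TS2", 4.0, "ts"),
                                   ProfileState("PS", -3.0, "min")], name="step2")
        combined = pk.assemble_profile([s1, s2])
        assert combined.energy_of("TI1") == 2.0
        assert combined.energy_of("TS2") == pytest.approx(7.0)
        assert combined.energy_of("PS") == pytest.approx(0.0)

    def test_single_step_is_unchanged(self):
        s1 = four_step_profile()
        assert pk.assemble_profile([s1]).states == s1.states

    def test_master_profile_split_and_reassembled(self):
        master = four_step_profile()
        rng = np.random.default_rng(8)
        steps = []
        labels = master.labels
        for k in range(0, 8, 2):
            chunk = master.states[k : k + 3]
            shift = float(rng.uniform(-20, 20))
            steps.append(EnergyProfile(
                states=[ProfileState(s.label, s.energy + shift, s.kind) for s in chunk],
                name=f"step{k}",
            ))
        rebuilt = pk.assemble_profile(steps)
        assert rebuilt.labels == labels
        for lab in labels:
            assert rebuilt.energy_of(lab) - rebuilt.energy_of("RS") == pytest.approx(
                master.energy_of(lab), abs=1e-6
            )

    def test_missing_shared_state_rejected(self):
        s1 = EnergyProfile(states=[ProfileState("RS", 0.0, "min")])
        s2 = EnergyProfile(states=[ProfileState("PS", 0.0, "min")])
        with pytest.raises(ValueError, match="shares no state"):
            pk.assemble_profile([s1, s2])

    def test_inconsistent_duplicate_labels_rejected(self):
        s1 = EnergyProfile(states=[ProfileState("RS", 0.0, "min"),
                                   ProfileState("TI1", 2.0, "min")])
        s2 = EnergyProfile(states=[ProfileState("RS", 0.0, "min"),
                                   ProfileState("TI1", 3.0, "min")])
        with pytest.raises(ValueError, match="inconsistent duplicate"):
            pk.assemble_profile([s1, s2])

    def test_profile_from_fes_recovers_step_states(self, double_well):
        grid = pk.GridSpec((-2, 2), (1, 3), 60, 60)
        fes = pk.fes_from_surface(double_well, grid)
        prof = pk.profile_from_fes(fes, labels=("RS", "TS1", "TI1"))
        assert prof.labels == ["RS", "TS1", "TI1"]
        table = pk.barriers(prof).set_index("label")
        assert table.loc["TS1", "dG_rel_RS"] == pytest.approx(13.8, abs=0.2)
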
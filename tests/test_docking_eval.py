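import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from miaqsar.docking_eval import (
    ActivityEnergyPoint,
    EnergyDecomposition,
    PoseRMSDSet,
    activity_energy_fit,
    check_energy_table,
    docking_accuracy,
    pose_rmsd,
    total_binding_energy,
)

# Published decomposition table for the triketone/HPPD redocking study
# (kcal/mol): electrostatic, vdW, internal, torsional terms plus the reported
# ΔG_bind total.
ENERGY_TABLE = [
    EnergyDecomposition("B9", -2.24, -7.55, -0.41, 1.79, reported_total=-7.99),
    EnergyDecomposition("A7", -1.68, -8.33, -0.63, 0.89, reported_total=-9.12),
    EnergyDecomposition("B1", -2.32, -7.73, -0.05, 1.49, reported_total=-8.56),
    EnergyDecomposition("P1", -1.48, -9.58, -1.39, 1.49, reported_total=-9.57),
    EnergyDecomposition("Mesotrione Cryst.", -2.81, -3.97, -1.06, 1.49, reported_total=-6.36),
    EnergyDecomposition("Mesotrione 69th", -2.05, -6.01, -2.15, 1.49, reported_total=-6.56),
]


class TestPoseRmsd:
    def test_identical_coordinates_give_zero(self, rng):
        a = rng.normal(size=(7, 3))
        assert pose_rmsd(a, a) == 0.0

    def test_three_four_five_displacement(self):
        assert pose_rmsd([[0.0, 0.0, 0.0]], [[3.0, 4.0, 0.0]]) == pytest.approx(5.0)

    def test_matches_per_atom_loop_oracle(self, rng):
        a = rng.normal(size=(12, 3))
        b = rng.normal(size=(12, 3))
        total = sum(sum((ai - bi) ** 2 for ai, bi in zip(ra, rb)) for ra, rb in zip(a, b))
        assert pose_rmsd(a, b) == pytest.approx(math.sqrt(total / 12), abs=1e-12)

    def test_length_mismatch_is_error(self):
        with pytest.raises(ValueError, match="differ"):
            pose_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))


class TestDockingAccuracy:
    def test_redocking_worked_example(self):
        """83 poses within 2 A and 17 in (2, 3] out of 100 score DA = 0.915."""
        rmsds = np.concatenate([np.full(83, 1.2), np.full(17, 2.6)])
        assert docking_accuracy(PoseRMSDSet(rmsds)) == pytest.approx(0.915, abs=1e-12)

    def test_all_within_lower_limit_scores_one(self):
        assert docking_accuracy(PoseRMSDSet(np.full(10, 0.5))) == 1.0

    def test_all_beyond_upper_limit_scores_zero(self):
        assert docking_accuracy(PoseRMSDSet(np.full(10, 4.5))) == 0.0

    def test_limits_are_closed_intervals(self):
        assert docking_accuracy(PoseRMSDSet(np.array([2.0]))) == 1.0
        assert docking_accuracy(PoseRMSDSet(np.array([3.0]))) == 0.5

    def test_empty_pose_set_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            docking_accuracy(PoseRMSDSet(np.array([])))

    def test_invalid_limits_rejected(self):
        with pytest.raises(ValueError, match="l < h"):
            PoseRMSDSet(np.array([1.0]), l=3.0, h=2.0)

    @given(st.lists(st.floats(0.0, 6.0), min_size=1, max_size=30), st.data())
    def test_improving_any_pose_never_lowers_da(self, rmsds, data):
        base = docking_accuracy(PoseRMSDSet(np.array(rmsds)))
        i = data.draw(st.integers(0, len(rmsds) - 1))
        factor = data.draw(st.floats(0.0, 1.0))
        improved = list(rmsds)
        improved[i] = rmsds[i] * factor
        assert docking_accuracy(PoseRMSDSet(np.array(improved))) >= base - 1e-12

    def test_invariant_to_pose_ordering(self, rng):
        rmsds = rng.uniform(0, 5, 40)
        shuffled = rng.permutation(rmsds)
        assert docking_accuracy(PoseRMSDSet(rmsds)) == docking_accuracy(PoseRMSDSet(shuffled))


class TestEnergyTotals:
    def test_interaction_sum_excludes_internal_energy(self):
        d = EnergyDecomposition("P1", -1.48, -9.58, -1.39, 1.49, reported_total=-9.57)
        total, consistent = total_binding_energy(d)
        assert total == pytest.approx(-9.57, abs=1e-12)
        assert consistent is True

    def test_published_table_flags_only_the_crystal_row(self):
        table = check_energy_table(ENERGY_TABLE)
        flags = dict(zip(table["name"], table["consistent"]))
        assert flags["Mesotrione Cryst."] is False
        for name in ("B9", "A7", "B1", "P1", "Mesotrione 69th"):
            assert flags[name] is True
        cryst = table[table["name"] == "Mesotrione Cryst."].iloc[0]
        assert cryst["computed_total"] == pytest.approx(-5.29, abs=1e-12)

    def test_all_zero_terms_total_zero(self):
        total, consistent = total_binding_energy(EnergyDecomposition("z", 0, 0, 0, 0))
        assert total == 0.0
        assert consistent is None

    def test_total_is_linear_in_each_term(self, rng):
        base = EnergyDecomposition("b", -1.0, -5.0, -0.5, 1.0)
        t0, _ = total_binding_energy(base)
        for term in ("electrostatic", "vdw", "torsional"):
            bumped = EnergyDecomposition(
                "b",
                base.electrostatic + (1.0 if term == "electrostatic" else 0.0),
                base.vdw + (1.0 if term == "vdw" else 0.0),
                base.internal,
                base.torsional + (1.0 if term == "torsional" else 0.0),
            )
            assert total_binding_energy(bumped)[0] == pytest.approx(t0 + 1.0)
        # internal term must not contribute
        bumped = EnergyDecomposition("b", base.electrostatic, base.vdw, base.internal + 5.0, base.torsional)
        assert total_binding_energy(bumped)[0] == pytest.approx(t0)

    def test_missing_term_is_error(self):
        with pytest.raises(ValueError, match="missing"):
            total_binding_energy(EnergyDecomposition("x", math.nan, -5.0, 0.0, 1.0))


class TestActivityEnergyFit:
    def _points(self, energies, means, spread):
        return [
            ActivityEnergyPoint(f"c{i}", e, (m - spread, m, m + spread))
            for i, (e, m) in enumerate(zip(energies, means))
        ]

    def test_linear_group_means_give_zero_lack_of_fit(self):
        energies = [-9.0, -8.0, -7.0, -6.0]
        means = [-0.25 * e + 5.6 for e in energies]
        fit = activity_energy_fit(self._points(energies, means, spread=0.1))
        assert fit.lof_f == pytest.approx(0.0, abs=1e-10)
        assert fit.lof_p == pytest.approx(1.0, abs=1e-6)
        assert fit.slope == pytest.approx(-0.25, abs=1e-10)
        assert fit.intercept == pytest.approx(5.6, abs=1e-10)

    def test_exactly_collinear_data_has_unit_r2(self):
        energies = [-9.0, -8.0, -7.0]
        means = [2.0 * e + 1.0 for e in energies]
        fit = activity_energy_fit(self._points(energies, means, spread=0.0))
        assert fit.r2 == pytest.approx(1.0, abs=1e-10)
        assert fit.max_studentized_residual == pytest.approx(0.0, abs=1e-6)

    def test_matches_closed_form_least_squares_oracle(self, rng):
        energies = list(rng.uniform(-10, -5, 6))
        points = [
            ActivityEnergyPoint(f"c{i}", e, tuple(rng.normal(7.0, 0.3, 3)))
            for i, e in enumerate(energies)
        ]
        x = np.repeat(energies, 3)
        y = np.concatenate([p.pki_replicates for p in points])
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        r2 = 1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
        fit = activity_energy_fit(points)
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.r2 == pytest.approx(r2, abs=1e-10)

    def test_lack_of_fit_matches_partition_oracle(self, rng):
        energies = [-9.0, -8.0, -7.5, -6.0]
        points = [
            ActivityEnergyPoint(f"c{i}", e, tuple(7.0 + rng.normal(0, 0.2, 3)))
            for i, e in enumerate(energies)
        ]
        fit = activity_energy_fit(points)
        x = np.repeat(energies, 3)
        y = np.concatenate([p.pki_replicates for p in points])
        slope = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        resid = y - (y.mean() - slope * x.mean()) - slope * x
        ss_res = np.sum(resid**2)
        ss_pe = sum(
            np.sum((np.array(p.pki_replicates) - np.mean(p.pki_replicates)) ** 2) for p in points
        )
        k, n = 4, 12
        f_oracle = ((ss_res - ss_pe) / (k - 2)) / (ss_pe / (n - k))
        assert fit.lof_f == pytest.approx(f_oracle, abs=1e-8)

    def test_fewer_than_three_distinct_energies_is_error(self):
        points = self._points([-9.0, -9.0, -8.0], [7.0, 7.0, 7.2], 0.1)
        with pytest.raises(ValueError, match="distinct"):
            activity_energy_fit(points)

    def test_replicate_count_enforced(self):
        with pytest.raises(ValueError, match="3"):
            ActivityEnergyPoint("c", -8.0, (7.0, 7.1))
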
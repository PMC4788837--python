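import numpy as np
import pytest

from qaleplan import dose_metrics as dm
from qaleplan import moea_planner as mo


def tiny_config(**overrides):
    defaults = dict(population=6, generations=3)
    defaults.update(overrides)
    return mo.PlannerConfig(**defaults)


def random_criteria(rng, n):
    out = []
    for _ in range(n):
        out.append(mo.CriteriaVector(
            names=mo.CRITERIA_NAMES,
            values=np.concatenate([rng.uniform(50, 90, 2), rng.uniform(0, 1, 3)]),
            higher_better=mo.CRITERIA_HIGHER))
    return out


class TestInnerSolve:
    def test_feasible_uniform_target_nearly_achieved(self, small_phantom):
        cfg = tiny_config()
        gene = mo.Gene(weights=np.array([1.0, 0.0, 0.0, 0.0]),
                       targets=np.array([10.0, 0.0, 0.0, 0.0]))
        plan = mo.inner_solve(gene, small_phantom, cfg)
        ptv = small_phantom.structure_doses(plan.dose, "ptv")
        assert np.sqrt(plan.objective_value / ptv.size) < 0.6  # RMS deviation, Gy

    def test_weighted_sum_degeneracy(self, small_phantom):
        cfg = tiny_config()
        lone = mo.Gene(weights=np.array([1.0, 0.0, 0.0, 0.0]),
                       targets=np.array([40.0, 0.0, 0.0, 0.0]))
        scaled = mo.Gene(weights=np.array([7.5, 0.0, 0.0, 0.0]),
                         targets=np.array([40.0, 0.0, 0.0, 0.0]))
        a = mo.inner_solve(lone, small_phantom, cfg, tol=1e-14, max_iter=3000)
        b = mo.inner_solve(scaled, small_phantom, cfg, tol=1e-14, max_iter=3000)
        # the minimizer is unique only on the optimized structure: compare there,
        # plus the scale-normalized optimum
        np.testing.assert_allclose(small_phantom.structure_doses(a.dose, "ptv"),
                                   small_phantom.structure_doses(b.dose, "ptv"),
                                   atol=0.05)
        assert b.objective_value / 7.5 == pytest.approx(a.objective_value, abs=1e-8)

    def test_matches_generic_nnls_on_two_sided_problem(self, small_phantom):
        """Dual route: with only two-sided objectives the problem is a
        non-negative least-squares, solvable independently by scipy."""
        from scipy.optimize import nnls

        cfg = mo.PlannerConfig(objectives=(
            mo.ObjectiveSpec("ptv", one_sided=False),
            mo.ObjectiveSpec("rectum", one_sided=False),
        ), population=2, generations=1)
        gene = mo.Gene(weights=np.array([1.0, 2.0]),
                       targets=np.array([60.0, 5.0]))
        plan = mo.inner_solve(gene, small_phantom, cfg, tol=1e-12, max_iter=2000)
        rows, rhs = [], []
        for w, spec, t in zip(gene.weights, cfg.objectives, gene.targets):
            idx = small_phantom.masks[spec.structure].reshape(-1)
            rows.append(np.sqrt(w) * small_phantom.influence[idx])
            rhs.append(np.sqrt(w) * np.full(idx.sum(), t))
        A = np.vstack(rows)
        b = np.concatenate(rhs)
        x_ref, _ = nnls(A, b)
        obj_ref = float(((A @ x_ref - b) ** 2).sum())
        assert plan.objective_value == pytest.approx(obj_ref, rel=1e-5)

    def test_gene_length_checked(self, small_phantom):
        with pytest.raises(ValueError):
            mo.inner_solve(mo.Gene(weights=np.array([1.0]),
                                   targets=np.array([60.0])),
                           small_phantom, tiny_config())


class TestDecisionCriteria:
    def test_zero_fluence_floor(self, small_phantom):
        plan = mo.Plan(fluence=np.zeros(small_phantom.influence.shape[1]),
                       dose=np.zeros(small_phantom.influence.shape[0]),
                       objective_value=0.0, converged=True)
        crit = mo.decision_criteria(plan, small_phantom, tiny_config())
        vals = dict(zip(crit.names, crit.values))
        assert vals["ptv_d95"] == 0.0
        assert vals["cold_spot"] == 1.0
        # zero-dose NTCP floor is the lower probit tail, identical per organ
        calib = tiny_config().calibration
        from scipy.stats import norm
        assert vals["ntcp_rectum"] == pytest.approx(
            norm.cdf(-1 / calib.ntcp["rectum"].m), abs=1e-12)

    def test_round_trip_through_dvh_files(self, small_phantom, tmp_path):
        cfg = tiny_config()
        gene = mo.Gene(weights=np.array([1.0, 0.5, 0.5, 0.1]),
                       targets=np.array([76.0, 20.0, 20.0, 10.0]))
        plan = mo.inner_solve(gene, small_phantom, cfg)
        crit = mo.decision_criteria(plan, small_phantom, cfg)
        ptv = small_phantom.structure_doses(plan.dose, "ptv")
        dvh = dm.build_cumulative_dvh(ptv, structure_name="ptv")
        path = tmp_path / "ptv.csv"
        dm.write_dvh_csv(dvh, path)
        back = dm.read_dvh_csv(path, structure_name="ptv")
        assert dm.dose_at_volume(back, 0.95) == pytest.approx(
            dict(zip(crit.names, crit.values))["ptv_d95"])

    def test_missing_structure_rejected(self, small_phantom):
        phantom = mo.Phantom(nx=small_phantom.nx, ny=small_phantom.ny,
                             spacing_mm=small_phantom.spacing_mm,
                             masks={"ptv": small_phantom.masks["ptv"]},
                             influence=small_phantom.influence)
        plan = mo.Plan(fluence=np.zeros(phantom.influence.shape[1]),
                       dose=np.zeros(phantom.influence.shape[0]),
                       objective_value=0.0, converged=True)
        with pytest.raises(KeyError):
            mo.decision_criteria(plan, phantom, tiny_config())


class TestDominance:
    def _vec(self, values):
        return mo.CriteriaVector(names=mo.CRITERIA_NAMES,
                                 values=np.asarray(values, dtype=float),
                                 higher_better=mo.CRITERIA_HIGHER)

    def test_identical_vectors_do_not_dominate(self):
        a = self._vec([76, 77, 0.05, 0.03, 0.01])
        assert not mo.dominates(a, a)

    def test_strictly_better_everywhere(self):
        a = self._vec([77, 78, 0.04, 0.02, 0.005])
        b = self._vec([76, 77, 0.05, 0.03, 0.010])
        assert mo.dominates(a, b) and not mo.dominates(b, a)

    def test_mixed_neither_dominates(self):
        a = self._vec([77, 77, 0.05, 0.05, 0.01])
        b = self._vec([76, 77, 0.05, 0.03, 0.01])
        assert not mo.dominates(a, b) and not mo.dominates(b, a)

    def test_mismatched_criteria_rejected(self):
        a = self._vec([76, 77, 0.05, 0.03, 0.01])
        b = mo.CriteriaVector(names=("x",), values=np.array([1.0]),
                              higher_better=(True,))
        with pytest.raises(ValueError):
            mo.dominates(a, b)


class TestArchive:
    def _entry(self, crit):
        return mo.ArchiveEntry(gene=mo.Gene(np.array([1.0]), np.array([0.0])),
                               plan=mo.Plan(np.zeros(1), np.zeros(1), 0.0, True),
                               criteria=crit)

    def test_matches_brute_force_filter(self, rng):
        candidates = random_criteria(rng, 200)
        archive = mo.ParetoArchive()
        for c in candidates:
            mo.update_archive(archive, self._entry(c))
        brute = [c for c in candidates
                 if not any(mo.dominates(o, c) for o in candidates)]
        got = sorted(tuple(e.criteria.values) for e in archive.entries)
        want = sorted(tuple(c.values) for c in brute)
        assert got == want

    def test_dominated_candidate_rejected(self, rng):
        strong = random_criteria(rng, 1)[0]
        weak = mo.CriteriaVector(names=strong.names,
                                 values=strong.values +
                                 np.where(np.array(strong.higher_better), -1.0, 0.1),
                                 higher_better=strong.higher_better)
        archive = mo.ParetoArchive()
        mo.update_archive(archive, self._entry(strong))
        mo.update_archive(archive, self._entry(weak))
        assert len(archive.entries) == 1

    def test_candidate_evicts_all_dominated(self):
        vecs = [np.array([70.0, 72, 0.5, 0.4, 0.5]),  # mutually non-dominated
                np.array([72.0, 70, 0.4, 0.5, 0.5]),
                np.array([90.0, 90, 0.0, 0.0, 0.0])]
        archive = mo.ParetoArchive()
        for v in vecs[:2]:
            mo.update_archive(archive, self._entry(mo.CriteriaVector(
                mo.CRITERIA_NAMES, v, mo.CRITERIA_HIGHER)))
        assert len(archive.entries) == 2
        mo.update_archive(archive, self._entry(mo.CriteriaVector(
            mo.CRITERIA_NAMES, vecs[2], mo.CRITERIA_HIGHER)))
        assert len(archive.entries) == 1


class TestHypervolume:
    def test_single_point_box(self):
        c = mo.CriteriaVector(("a", "b"), np.array([1.0, 0.5]), (False, False))
        assert mo.hypervolume([c], (2.0, 1.0)) == pytest.approx(0.5)

    def test_union_of_two_boxes(self):
        # min-form points (1, 0.5) and (0.5, 1): union vs ref (2,2)
        a = mo.CriteriaVector(("a", "b"), np.array([1.0, 0.5]), (False, False))
        b = mo.CriteriaVector(("a", "b"), np.array([0.5, 1.0]), (False, False))
        want = 1.0 * 1.5 + 1.5 * 1.0 - 1.0 * 1.0
        assert mo.hypervolume([a, b], (2.0, 2.0)) == pytest.approx(want)

    def test_dominated_point_adds_nothing(self):
        a = mo.CriteriaVector(("a", "b"), np.array([0.5, 0.5]), (False, False))
        b = mo.CriteriaVector(("a", "b"), np.array([0.8, 0.8]), (False, False))
        assert mo.hypervolume([a, b], (2.0, 2.0)) == pytest.approx(
            mo.hypervolume([a], (2.0, 2.0)))


class TestEvolve:
    def test_seed_reproducible(self, small_phantom):
        cfg = tiny_config()
        arch1, hist1 = mo.evolve(small_phantom, cfg, seed=5)
        arch2, hist2 = mo.evolve(small_phantom, cfg, seed=5)
        assert hist1 == hist2
        assert len(arch1.entries) == len(arch2.entries)
        for a, b in zip(arch1.entries, arch2.entries):
            np.testing.assert_array_equal(a.criteria.values, b.criteria.values)

    def test_archive_has_no_dominated_pair(self, small_phantom):
        arch, _ = mo.evolve(small_phantom, tiny_config(), seed=2)
        for a in arch.entries:
            for b in arch.entries:
                if a is not b:
                    assert not mo.dominates(a.criteria, b.criteria)

    def test_hypervolume_non_decreasing(self, small_phantom):
        _, hist = mo.evolve(small_phantom, tiny_config(generations=5), seed=4)
        hv = [h["hypervolume"] for h in hist]
        assert np.all(np.diff(hv) >= -1e-9)

    def test_population_floor(self, small_phantom):
        with pytest.raises(ValueError):
            mo.evolve(small_phantom, tiny_config(population=1), seed=0)

    def test_constraint_gate_keeps_infeasible_out(self, small_phantom):
        cfg = tiny_config(d95_constraint=5.0, generations=2)
        arch, _ = mo.evolve(small_phantom, cfg, seed=6)
        for e in arch.entries:
            vals = dict(zip(e.criteria.names, e.criteria.values))
            assert vals["ptv_d95"] >= 5.0
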
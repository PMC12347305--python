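import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from torsionfold.energy import (EnergySystem, evaluate_energy,
                                nonbonded_pair_energy, torsion_energy)
from torsionfold.errors import DomainError, NumericError
from torsionfold.geometry import Atom, AtomModel, PeptideSystem, TorsionState
from torsionfold.io_formats import EnergyParameterSet


def toy_params(a=1.0, b=2.0, q=0.0, eps=2.0, hbond=None, torsions=None):
    classes = {"X": q, "Y": q, "H": q, "O": q}
    pairs = {frozenset(p): (a, b) for p in
             [("X", "X"), ("X", "Y"), ("Y", "Y"), ("H", "O"), ("H", "H"),
              ("O", "O"), ("X", "H"), ("X", "O"), ("Y", "H"), ("Y", "O")]}
    return EnergyParameterSet(
        pair_params=pairs, hbond_params=hbond or {}, charges=classes,
        dielectric=eps, coulomb_constant=332.0,
        torsion_params=torsions or {"phi": (1.0, 1, 1)})


class TestPairEnergy:
    def test_lj_at_unit_distance(self):
        lj, elec, hb = nonbonded_pair_energy("X", "Y", 1.0, toy_params(a=1, b=2))
        assert lj == -1.0 and elec == 0.0 and hb == 0.0

    def test_coulomb_scaling(self):
        p = toy_params(a=0, b=0, q=1.0, eps=2.0)
        _, elec, _ = nonbonded_pair_energy("X", "Y", 166.0, p)
        assert elec == pytest.approx(1.0)

    def test_hbond_replaces_lj(self):
        p = toy_params(a=5, b=7, hbond={("H", "O"): (1.0, 2.0)})
        lj, _, hb = nonbonded_pair_energy("H", "O", 1.0, p)
        assert hb == -1.0
        assert lj == 0.0  # 12-6 superseded for the flagged pair

    def test_hbond_additive_mode_keeps_lj(self):
        p = toy_params(a=5, b=7, hbond={("H", "O"): (1.0, 2.0)})
        lj, _, hb = nonbonded_pair_energy("H", "O", 1.0, p, hbond_mode="additive")
        assert hb == -1.0 and lj == -2.0

    def test_nonpositive_distance_rejected(self):
        with pytest.raises(DomainError):
            nonbonded_pair_energy("X", "Y", 0.0, toy_params())

    def test_lj_minimum_location_and_depth(self):
        # r* = (2A/B)^(1/6), depth -B^2/(4A): for A=1, B=2 the minimum is -1 at r=1
        p = toy_params(a=1, b=2)
        r = np.linspace(0.8, 2.0, 20001)
        e = np.array([nonbonded_pair_energy("X", "Y", ri, p)[0] for ri in r])
        k = e.argmin()
        assert r[k] == pytest.approx(1.0, abs=1e-3)
        assert e[k] == pytest.approx(-1.0, abs=1e-6)

    def test_all_terms_vanish_at_long_range(self):
        p = toy_params(a=1, b=1, q=1.0, hbond={("H", "O"): (1.0, 1.0)})
        lj, elec, hb = nonbonded_pair_energy("H", "O", 1e3, p)
        assert abs(lj) < 1e-9 and abs(elec) < 1.0 and abs(hb) < 1e-9


class TestTorsionEnergy:
    @pytest.mark.parametrize("u,k,sign,angle,expected", [
        (1.0, 1, 1, 180.0, 0.0),
        (1.0, 1, 1, 0.0, 2.0),
        (2.0, 3, -1, 60.0, 4.0),   # 2 (1 - cos 180)
    ])
    def test_single_angle(self, u, k, sign, angle, expected):
        torsions = {"phi": (u, k, sign), "psi": (0.0, 1, 1),
                    "omega": (0.0, 1, 1), "chi": (0.0, 1, 1)}
        p = toy_params(torsions=torsions)
        state = TorsionState("G", [angle], [0.0], [180.0], [np.array([])])
        assert torsion_energy(state, p) == pytest.approx(expected, abs=1e-12)


class TestEvaluateEnergy:
    def test_two_atom_model_reduces_to_pair_energy(self):
        p = toy_params(a=1, b=2, q=1.0)
        model = AtomModel(atoms=[
            Atom("A1", 1, "X", 1.0, (0.0, 0.0, 0.0)),
            Atom("A2", 1, "Y", 1.0, (1.5, 0.0, 0.0))], bonds=[])
        torsions = {"phi": (0.0, 1, 1), "psi": (0.0, 1, 1),
                    "omega": (0.0, 1, 1), "chi": (0.0, 1, 1)}
        p = toy_params(a=1, b=2, q=1.0, torsions=torsions)
        state = TorsionState("G", [0.0], [0.0], [180.0], [np.array([])])
        bd = evaluate_energy(model, state, p)
        lj, elec, hb = nonbonded_pair_energy("X", "Y", 1.5, p)
        assert bd.total == pytest.approx(lj + elec + hb)

    def test_total_is_sum_of_components(self, params):
        system = PeptideSystem("GAG")
        bd = EnergySystem(system, params).breakdown(TorsionState.extended("GAG"))
        assert bd.total == bd.lj + bd.electrostatic + bd.hbond + bd.torsion

    def test_rigid_motion_leaves_breakdown_unchanged(self, params, rng):
        system = PeptideSystem("GAGA")
        state = TorsionState.from_flat("GAGA", rng.uniform(-180, 180, system.n_variables))
        model = system.build_model(state, params.charges)
        bd1 = evaluate_energy(model, state, params)
        rot = Rotation.from_rotvec([0.3, -1.2, 0.7]).as_matrix()
        moved = AtomModel(atoms=[
            Atom(a.name, a.residue_index, a.atom_class, a.charge,
                 tuple(rot @ np.asarray(a.xyz) + np.array([5.0, -3.0, 2.0])),
                 a.res_name)
            for a in model.atoms], bonds=model.bonds)
        bd2 = evaluate_energy(moved, state, params)
        assert bd2.total == pytest.approx(bd1.total, rel=1e-9)

    def test_fast_and_reference_paths_agree(self, params, rng):
        """The vectorized evaluator must match the per-pair reference sum."""
        system = PeptideSystem("AKG")
        state = TorsionState.from_flat("AKG", rng.uniform(-180, 180, system.n_variables))
        fast = EnergySystem(system, params).breakdown(state)
        slow = evaluate_energy(system.build_model(state, params.charges), state, params)
        assert fast.total == pytest.approx(slow.total, rel=1e-9)
        assert fast.lj == pytest.approx(slow.lj, rel=1e-9)
        assert fast.hbond == pytest.approx(slow.hbond, rel=1e-9)

    def test_energy_is_bit_reproducible(self, params, rng):
        system = PeptideSystem("GAGAGA")
        es = EnergySystem(system, params)
        vec = rng.uniform(-180, 180, system.n_variables)
        assert es(vec) == es(vec.copy())

    def test_overlapping_atoms_named_in_error(self):
        model = AtomModel(atoms=[
            Atom("A1", 1, "X", 0.0, (0.0, 0.0, 0.0)),
            Atom("A2", 2, "Y", 0.0, (0.0, 0.0, 1e-9))], bonds=[])
        state = TorsionState("G", [0.0], [0.0], [180.0], [np.array([])])
        with pytest.raises(NumericError, match="A1/1.*A2/2"):
            evaluate_energy(model, state, toy_params())
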
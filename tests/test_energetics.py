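import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gridpocket import (
    Atom,
    EnergyParams,
    GridSpec,
    PairParams,
    ProteinStructure,
    combine_pair,
    coulomb_channel,
    hbond_channel,
    lj_12_6,
    lj_12_10,
    vdw_channel,
)
from gridpocket.energetics import COULOMB_K, PROBE_OH
from gridpocket.forcefield import AtomTypeParams

from oracles import coulomb_bruteforce, hbond_bruteforce, vdw_bruteforce


def _atom(pos, atom_type="C", charge=0.0, radius=2.0, serial=1):
    return Atom(
        serial=serial,
        name=atom_type,
        element=atom_type[0],
        position=np.asarray(pos, float),
        partial_charge=charge,
        vdw_radius=radius,
        atom_type=atom_type,
    )


class TestCombinePair:
    def test_equal_types(self):
        p = combine_pair(
            AtomTypeParams(0.15, 1.75, 1.75), AtomTypeParams(0.15, 1.75, 1.75)
        )
        assert p.epsilon == pytest.approx(0.15)
        assert p.r0 == pytest.approx(3.5)

    def test_geometric_mean_epsilon(self):
        p = combine_pair(AtomTypeParams(0.25, 1.0, 1.0), AtomTypeParams(0.09, 1.0, 1.0))
        assert p.epsilon == pytest.approx(0.15)

    def test_zero_epsilon_zeroes_coefficients(self):
        p = combine_pair(AtomTypeParams(0.0, 1.0, 1.0), AtomTypeParams(0.2, 1.0, 1.0))
        assert p.epsilon == 0 and p.A == 0 and p.B == 0 and p.C == 0 and p.D == 0

    def test_coefficient_identities(self):
        p = PairParams(epsilon=0.3, r0=2.5)
        assert p.A == pytest.approx(0.3 * 2.5**12)
        assert p.B == pytest.approx(2 * 0.3 * 2.5**6)
        assert p.C == pytest.approx(5 * 0.3 * 2.5**12)
        assert p.D == pytest.approx(6 * 0.3 * 2.5**10)


class TestLennardJones:
    def test_12_6_minimum_at_r0(self):
        p = PairParams(epsilon=0.15, r0=3.5)
        assert lj_12_6(3.5, p) == pytest.approx(-0.15)

    def test_12_6_beyond_cutoff_is_zero(self):
        p = PairParams(epsilon=0.15, r0=3.5)
        assert lj_12_6(9.0, p, cutoff=8.0) == 0.0

    def test_12_6_at_twice_r0(self):
        p = PairParams(epsilon=0.15, r0=3.5)
        assert lj_12_6(7.0, p) == pytest.approx(-(127 / 4096) * 0.15, rel=1e-12)

    def test_12_10_oxygen_well(self):
        p = PairParams(epsilon=5.0, r0=1.9)
        assert lj_12_10(1.9, p) == pytest.approx(-5.0)

    def test_12_10_beyond_cutoff_is_zero(self):
        assert lj_12_10(8.5, PairParams(5.0, 1.9)) == 0.0

    @pytest.mark.parametrize("fn", [lj_12_6, lj_12_10])
    def test_nonpositive_distance_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(0.0, PairParams(1.0, 2.0))

    @given(
        eps=st.floats(0.01, 10.0),
        r0=st.floats(1.0, 4.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_both_potentials_minimize_at_r0_with_depth_eps(self, eps, r0):
        p = PairParams(epsilon=eps, r0=r0)
        r = np.linspace(0.8 * r0, 1.4 * r0, 2001)
        for fn in (lj_12_6, lj_12_10):
            e = fn(r, p, cutoff=np.inf)
            i = int(np.argmin(e))
            assert r[i] == pytest.approx(r0, rel=2e-3)
            assert e[i] == pytest.approx(-eps, rel=1e-4)


def _grid(origin=(0, 0, 0), shape=(10, 10, 10)):
    return GridSpec(origin=origin, shape=shape)


class TestVdwChannel:
    def test_zero_outside_cutoff(self, forcefield):
        protein = ProteinStructure([_atom((50, 5, 5))], id="far")
        grid = vdw_channel(protein, _grid(), forcefield=forcefield)
        assert np.all(grid.values == 0.0)

    def test_single_pair_minimum(self, forcefield):
        # voxel center (0.5,0.5,0.5); atom r0 C-C = 4.0 away along x
        protein = ProteinStructure([_atom((4.5, 0.5, 0.5))], id="one")
        grid = vdw_channel(protein, _grid(), forcefield=forcefield)
        assert grid.values[0, 0, 0] == pytest.approx(-0.15, rel=1e-9)

    def test_matches_bruteforce(self, forcefield, rng):
        atoms = [
            _atom(rng.uniform(2, 12, 3), atom_type=t, serial=i)
            for i, t in enumerate(rng.choice(["C", "N", "OA"], size=20))
        ]
        protein = ProteinStructure(atoms, id="rand")
        spec = _grid(shape=(14, 14, 14))
        grid = vdw_channel(protein, spec, forcefield=forcefield)
        probe = forcefield.get("C")
        pairs = []
        for a in atoms:
            p = combine_pair(probe, forcefield.get(a.atom_type))
            pairs.append((p.A, p.B))
        ref = vdw_bruteforce([a.position for a in atoms], pairs, spec.origin, spec.shape)
        np.testing.assert_allclose(grid.values, ref, rtol=1e-9, atol=1e-12)


class TestHbondChannel:
    def test_no_capable_atom_in_range_gives_zero(self, forcefield):
        protein = ProteinStructure([_atom((5, 5, 5), atom_type="C")], id="apolar")
        grid = hbond_channel(protein, _grid(), forcefield=forcefield)
        assert np.all(grid.values == 0.0)

    def test_max_abs_selection_keeps_attractive_candidate(self, forcefield):
        # candidates of both signs at one voxel: the largest |E| wins
        protein = ProteinStructure(
            [_atom((2.4, 0.5, 0.5), atom_type="OA", serial=1),
             _atom((0.5, 1.6, 0.5), atom_type="OA", serial=2)],
            id="two",
        )
        grid = hbond_channel(protein, _grid(), forcefield=forcefield)
        candidates = []
        for off in ((0.0, 0.0, 0.0), (0.96, 0.0, 0.0)):
            for a in protein.atoms:
                pairw = forcefield.hbond_pair("HD" if off[0] else "OA", a.atom_type)
                if pairw is None:
                    continue
                p = PairParams(*pairw)
                r = np.linalg.norm(np.array([0.5, 0.5, 0.5]) + off - a.position)
                candidates.append(p.C / r**12 - p.D / r**10)
        expected = max(candidates, key=abs)
        assert grid.values[0, 0, 0] == pytest.approx(expected, rel=1e-9)

    def test_matches_bruteforce(self, forcefield, rng):
        types = rng.choice(["C", "N", "OA", "HD"], size=25)
        atoms = [
            _atom(rng.uniform(2, 12, 3), atom_type=t, serial=i)
            for i, t in enumerate(types)
        ]
        protein = ProteinStructure(atoms, id="rand")
        spec = _grid(shape=(14, 14, 14))
        grid = hbond_channel(protein, spec, forcefield=forcefield)
        probe_offsets = [np.asarray(a[1]) for a in PROBE_OH.atoms]
        entries = []
        for a in atoms:
            if a.atom_type not in forcefield.hbond_capable:
                continue
            per_probe = {}
            for pi, (ptype, _off, _q) in enumerate(PROBE_OH.atoms):
                well = forcefield.hbond_pair(ptype, a.atom_type)
                if well is not None:
                    p = PairParams(*well)
                    per_probe[pi] = (p.C, p.D)
            if per_probe:
                entries.append((a.position, per_probe))
        ref = hbond_bruteforce(probe_offsets, entries, spec.origin, spec.shape)
        np.testing.assert_allclose(grid.values, ref, rtol=1e-9, atol=1e-12)


class TestCoulombChannel:
    def test_unit_charge_at_unit_distance_gives_K(self):
        protein = ProteinStructure([_atom((1.5, 0.5, 0.5), charge=1.0)], id="q")
        grid = coulomb_channel(protein, _grid())
        assert grid.values[0, 0, 0] == pytest.approx(COULOMB_K)

    def test_inverse_square_form(self):
        protein = ProteinStructure([_atom((2.5, 0.5, 0.5), charge=-0.5)], id="q")
        grid = coulomb_channel(protein, _grid())
        assert grid.values[0, 0, 0] == pytest.approx(COULOMB_K * (-0.5) / 4.0)

    def test_mirrored_charges_cancel(self):
        protein = ProteinStructure(
            [_atom((3.5, 0.5, 0.5), charge=0.4, serial=1),
             _atom((-2.5, 0.5, 0.5), charge=-0.4, serial=2)],
            id="dipole",
        )
        grid = coulomb_channel(protein, _grid())
        assert grid.values[0, 0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_charges_warns_and_returns_zero(self, caplog):
        protein = ProteinStructure([_atom((5, 5, 5))], id="neutral")
        with caplog.at_level("WARNING"):
            grid = coulomb_channel(protein, _grid())
        assert np.all(grid.values == 0.0)
        assert any("zero" in r.message for r in caplog.records)

    def test_matches_bruteforce(self, rng):
        atoms = [
            _atom(rng.uniform(2, 12, 3), charge=float(q), serial=i)
            for i, q in enumerate(rng.normal(0, 0.3, 20))
        ]
        protein = ProteinStructure(atoms, id="rand")
        spec = _grid(shape=(14, 14, 14))
        grid = coulomb_channel(protein, spec)
        ref = coulomb_bruteforce(
            [a.position for a in atoms], [a.partial_charge for a in atoms],
            spec.origin, spec.shape, COULOMB_K,
        )
        np.testing.assert_allclose(grid.values, ref, rtol=1e-9, atol=1e-12)

    def test_exponent_one_option(self):
        protein = ProteinStructure([_atom((2.5, 0.5, 0.5), charge=1.0)], id="q")
        grid = coulomb_channel(protein, _grid(), EnergyParams(coulomb_exponent=1))
        assert grid.values[0, 0, 0] == pytest.approx(COULOMB_K / 2.0)


class TestTranslationEquivariance:
    def test_channels_follow_the_grid(self, forcefield, rng):
        atoms = [
            _atom(rng.uniform(2, 10, 3), atom_type=t, charge=float(q), serial=i)
            for i, (t, q) in enumerate(
                zip(rng.choice(["C", "OA", "N"], 12), rng.normal(0, 0.2, 12))
            )
        ]
        shift = np.array([3.25, -1.5, 2.0])
        shifted = [
            _atom(a.position + shift, atom_type=a.atom_type, charge=a.partial_charge, serial=a.serial)
            for a in atoms
        ]
        spec = _grid(shape=(12, 12, 12))
        spec2 = GridSpec(origin=tuple(np.array(spec.origin) + shift), shape=spec.shape)
        for fn in (
            lambda p, s: vdw_channel(p, s, forcefield=forcefield),
            lambda p, s: hbond_channel(p, s, forcefield=forcefield),
            lambda p, s: coulomb_channel(p, s),
        ):
            a = fn(ProteinStructure(atoms, id="a"), spec).values
            b = fn(ProteinStructure(shifted, id="b"), spec2).values
            np.testing.assert_allclose(a, b, rtol=1e-9, atol=1e-12)
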
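"""Backbone geometry: PDB round trips, Cβ construction, dihedrals, SS8."""

import numpy as np
import pytest
from scipy.optimize import fsolve, minimize

from peptox.backbone import (
    assign_ss8,
    compute_dihedrals,
    dihedral,
    impute_cbeta,
    rank_by_plddt,
    read_pdb,
    write_pdb,
    CB_BOND_LENGTH,
)
from peptox.errors import (
    ChainNotFound,
    DegenerateGeometry,
    EmptyEnsemble,
    MalformedStructure,
)
from peptox.simulate import (
    BackboneSpec,
    build_backbone_from_dihedrals,
    make_structure_preset,
)
from conftest import random_rotation


def make_backbone(L=5, seed=0, sequence=None):
    rng = np.random.default_rng(seed)
    seq = sequence or "".join(rng.choice(list("ACDEFG"), L))
    spec = BackboneSpec(
        sequence=seq,
        phi=rng.uniform(-170, 170, L),
        psi=rng.uniform(-170, 170, L),
        omega=np.full(L, 180.0),
        seed=seed,
    )
    return build_backbone_from_dihedrals(spec)


class TestReadWritePdb:
    def test_empty_file_is_malformed(self, tmp_path):
        p = tmp_path / "empty.pdb"
        p.write_text("HEADER    NOTHING\nEND\n")
        with pytest.raises(MalformedStructure):
            read_pdb(p)

    def test_round_trip_within_pdb_precision(self, tmp_path):
        s = make_backbone(L=3, seed=1)
        path = tmp_path / "bb.pdb"
        write_pdb(s, path)
        r = read_pdb(path)
        assert r.sequence == s.sequence
        for name in ("coords_N", "coords_CA", "coords_C"):
            np.testing.assert_allclose(
                getattr(r, name), getattr(s, name), atol=1e-3
            )

    def test_uniform_bfactor_becomes_plddt(self, tmp_path):
        s = make_backbone(L=4, seed=2)
        s.plddt[:] = 90.0
        path = tmp_path / "bb.pdb"
        write_pdb(s, path)
        assert read_pdb(path).mean_plddt == pytest.approx(90.0)

    def test_missing_chain(self, tmp_path):
        s = make_backbone(L=3, seed=3)
        path = tmp_path / "bb.pdb"
        write_pdb(s, path)
        with pytest.raises(ChainNotFound):
            read_pdb(path, chain="Z")


class TestImputeCbeta:
    def test_recorded_cbeta_untouched(self):
        s = make_backbone(L=4, seed=4, sequence="AAAA")
        out = impute_cbeta(s)
        np.testing.assert_array_equal(out.coords_CB, s.coords_CB)
        assert not out.cb_imputed.any()

    def test_glycine_matches_brute_force_oracle(self):
        s = make_backbone(L=4, seed=5, sequence="AGAA")
        out = impute_cbeta(s)
        i = 1  # the glycine
        assert out.cb_imputed[i]
        cb = out.coords_CB[i]
        assert np.linalg.norm(cb - s.coords_CA[i]) == pytest.approx(
            CB_BOND_LENGTH, abs=1e-6
        )
        # oracle: numerically solve for the unit direction making the
        # tetrahedral angle with both Ca->N and Ca->C, then pick the
        # solution on the L-chirality side
        n1 = s.coords_N[i] - s.coords_CA[i]
        n1 /= np.linalg.norm(n1)
        n2 = s.coords_C[i] - s.coords_CA[i]
        n2 /= np.linalg.norm(n2)
        target = -1.0 / 3.0

        def equations(u):
            return [u @ n1 - target, u @ n2 - target, u @ u - 1.0]

        def objective(u):
            u = u / np.linalg.norm(u)
            return (u @ n1 - target) ** 2 + (u @ n2 - target) ** 2

        best = None
        for trial in range(20):
            rng = np.random.default_rng(trial)
            res = minimize(objective, rng.normal(size=3))
            u = fsolve(equations, res.x / np.linalg.norm(res.x), xtol=1e-13)
            u = u / np.linalg.norm(u)
            if (np.max(np.abs(equations(u))) < 1e-10
                    and u @ np.cross(n1, n2) > 0):
                best = u
                break
        assert best is not None
        oracle = s.coords_CA[i] + CB_BOND_LENGTH * best
        np.testing.assert_allclose(cb, oracle, atol=1e-6)

    def test_missing_alanine_cb_gets_flagged(self):
        s = make_backbone(L=3, seed=6, sequence="AAA")
        s.coords_CB[1] = np.nan
        out = impute_cbeta(s)
        assert out.cb_imputed[1] and not out.cb_imputed[0]
        assert np.all(np.isfinite(out.coords_CB))

    def test_idempotent(self):
        s = make_backbone(L=5, seed=7, sequence="GAGAG")
        once = impute_cbeta(s)
        twice = impute_cbeta(once)
        np.testing.assert_array_equal(once.coords_CB, twice.coords_CB)
        np.testing.assert_array_equal(once.cb_imputed, twice.cb_imputed)


class TestDihedrals:
    def test_sign_convention_quarter_turn(self):
        pts = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)]
        assert np.degrees(dihedral(*pts)) == pytest.approx(90.0)

        # independent atan2 oracle (praxeolitic projection formulation)
        def oracle(p0, p1, p2, p3):
            p0, p1, p2, p3 = [np.asarray(p, dtype=float)
                              for p in (p0, p1, p2, p3)]
            b0 = -(p1 - p0)
            b1 = (p2 - p1) / np.linalg.norm(p2 - p1)
            b2 = p3 - p2
            v = b0 - (b0 @ b1) * b1
            w = b2 - (b2 @ b1) * b1
            return np.arctan2(np.cross(b1, v) @ w, v @ w)

        assert np.degrees(oracle(*pts)) == pytest.approx(90.0)
        rng = np.random.default_rng(0)
        for _ in range(20):
            quad = rng.normal(size=(4, 3))
            assert dihedral(*quad) == pytest.approx(oracle(*quad), abs=1e-9)

    def test_internal_coordinate_round_trip(self):
        L = 10
        spec = BackboneSpec(
            sequence="A" * L,
            phi=np.full(L, -57.0),
            psi=np.full(L, -47.0),
            omega=np.full(L, 180.0),
        )
        d = compute_dihedrals(build_backbone_from_dihedrals(spec))
        np.testing.assert_allclose(np.degrees(d.phi[1:]), -57.0, atol=1e-6)
        np.testing.assert_allclose(np.degrees(d.psi[:-1]), -47.0, atol=1e-6)
        np.testing.assert_allclose(
            np.abs(np.degrees(d.omega[:-1])), 180.0, atol=1e-6
        )

    def test_terminal_angles_masked(self):
        d = compute_dihedrals(make_backbone(L=4, seed=8))
        assert not d.phi_defined[0]
        assert not d.psi_defined[-1] and not d.omega_defined[-1]
        assert d.phi_defined[1:].all()

    def test_collinear_atoms_raise(self):
        with pytest.raises(DegenerateGeometry):
            dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))

    def test_rigid_motion_invariance(self):
        s = make_backbone(L=6, seed=9)
        rng = np.random.default_rng(1)
        moved = s.transformed(random_rotation(rng), rng.normal(size=3) * 10)
        d0 = compute_dihedrals(s)
        d1 = compute_dihedrals(moved)
        np.testing.assert_allclose(d0.phi[1:], d1.phi[1:], atol=1e-9)
        np.testing.assert_allclose(d0.psi[:-1], d1.psi[:-1], atol=1e-9)
        np.testing.assert_array_equal(assign_ss8(s, d0), assign_ss8(moved, d1))


class TestAssignSS8:
    def test_ideal_helix_interior_is_H(self, helix12):
        labels = assign_ss8(helix12, compute_dihedrals(helix12))
        assert (labels[1:-1] == 0).all()  # H

    def test_ideal_strand_run_is_E(self, strand12):
        labels = assign_ss8(strand12, compute_dihedrals(strand12))
        assert (labels[1:-1] == 3).all()  # E

    def test_coil_defaults_to_C(self):
        s = make_structure_preset("coil", 5, seed=5)
        labels = assign_ss8(s, compute_dihedrals(s))
        assert (labels == 7).all()  # C

    def test_short_helical_run_stays_coil(self):
        # three helical residues flanked by coil: below the >=4 run rule
        L = 9
        rng = np.random.default_rng(2)
        phi = rng.uniform(40, 140, L)
        psi = rng.uniform(-170, 170, L)
        phi[3:6], psi[3:6] = -57.0, -47.0
        spec = BackboneSpec(sequence="A" * L, phi=phi, psi=psi,
                            omega=np.full(L, 180.0))
        s = build_backbone_from_dihedrals(spec)
        labels = assign_ss8(s, compute_dihedrals(s))
        assert (labels == 7).all()


def test_external_ss8_label_table(tmp_path):
    from peptox.backbone import read_ss8_table

    path = tmp_path / "labels.tsv"
    path.write_text("# id\tss8\npep1\tHHHHCC\npep2\tEEETSC\n")
    labels = read_ss8_table(path)
    assert list(labels["pep1"]) == [0, 0, 0, 0, 7, 7]
    assert list(labels["pep2"]) == [3, 3, 3, 5, 6, 7]


class TestRankByPlddt:
    def _with_plddt(self, value, seed):
        s = make_backbone(L=3, seed=seed)
        s.plddt[:] = value
        return s

    def test_single_structure(self):
        s = self._with_plddt(80, 0)
        assert rank_by_plddt([s]) == [s]

    def test_descending_order(self):
        lo, hi = self._with_plddt(70, 1), self._with_plddt(90, 2)
        assert rank_by_plddt([lo, hi]) == [hi, lo]

    def test_stable_on_ties(self):
        structures = [self._with_plddt(85, i) for i in range(4)]
        expected = sorted(structures, key=lambda s: -s.mean_plddt)
        assert rank_by_plddt(structures) == expected == structures

    def test_empty_ensemble(self):
        with pytest.raises(EmptyEnsemble):
            rank_by_plddt([])
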
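"""Conformer generation: torsion sampling, chain building, pools,
side-chain resampling."""

import numpy as np
import pytest

from sahens.conformers import (
    COIL_BASINS,
    DihedralSet,
    HelicityProfile,
    build_conformer,
    count_clashes,
    generate_pool,
    resample_sidechains,
    sample_dihedrals,
)
from sahens.geometry import bond_angle, dihedral, fit_plane, place_atom
from sahens.sequence import DREBRIN_SAH_SEQUENCE
from tests.conftest import uniform_dihedrals

BACKBONE = ("N", "CA", "C", "O")


def measured_phi_psi(conf, i):
    phi = dihedral(conf.atom_coord(i - 1, "C"), conf.atom_coord(i, "N"),
                   conf.atom_coord(i, "CA"), conf.atom_coord(i, "C"))
    psi = dihedral(conf.atom_coord(i, "N"), conf.atom_coord(i, "CA"),
                   conf.atom_coord(i, "C"), conf.atom_coord(i + 1, "N"))
    return phi, psi


class TestGeometryPrimitives:
    def test_place_atom_round_trips_torsion(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b, c = rng.normal(size=(3, 3))
            bond, ang, tor = rng.uniform(0.1, 0.2), rng.uniform(60, 150), \
                rng.uniform(-179, 179)
            d = place_atom(a, b, c, bond, ang, tor)
            assert dihedral(a, b, c, d) == pytest.approx(tor, abs=1e-8)
            assert bond_angle(b, c, d) == pytest.approx(ang, abs=1e-8)
            assert np.linalg.norm(d - c) == pytest.approx(bond, abs=1e-12)

    def test_fit_plane_recovers_exact_plane(self):
        rng = np.random.default_rng(1)
        pts = np.c_[rng.normal(size=(10, 2)), np.zeros(10)]
        centroid, normal = fit_plane(pts)
        assert abs(normal[2]) == pytest.approx(1.0)
        assert centroid[2] == pytest.approx(0.0, abs=1e-12)


class TestSampleDihedrals:
    def test_forced_helix_is_inside_basin(self):
        prof = HelicityProfile.uniform(30, 1.0)
        d = sample_dihedrals("A" * 30, prof, seed=0)
        assert np.all(np.abs(d.phi[1:] + 63.0) < 3 * 7.0 + 1e-9)
        assert np.all(np.abs(d.psi + 42.0) < 3 * 7.0 + 1e-9)

    def test_zero_profile_matches_coil_basin_mass(self):
        """Helical-basin occupancy of profile-0 draws equals the coil
        mixture's own basin mass (alphaR component)."""
        prof = HelicityProfile.uniform(1, 0.0)
        rng_draws = [sample_dihedrals("A", prof, seed=s) for s in range(10000)]
        phi = np.array([d.psi[0] for d in rng_draws])  # psi defined at res 0
        # oracle: direct draw from the coil mixture
        rng = np.random.default_rng(123)
        weights = np.array([b[2] for b in COIL_BASINS])
        weights = weights / weights.sum()
        comp = rng.choice(len(COIL_BASINS), size=10000, p=weights)
        oracle_psi = np.array([
            np.random.default_rng(7 + i).normal(COIL_BASINS[c][0][1],
                                                COIL_BASINS[c][1][1])
            for i, c in enumerate(comp)
        ])
        in_basin = np.mean(np.abs(phi + 42.0) < 21.0)
        oracle = np.mean(np.abs(oracle_psi + 42.0) < 21.0)
        assert in_basin == pytest.approx(oracle, abs=0.02)

    def test_fixed_seed_is_deterministic(self):
        prof = HelicityProfile.uniform(74, 0.5)
        d1 = sample_dihedrals(DREBRIN_SAH_SEQUENCE, prof, seed=42)
        d2 = sample_dihedrals(DREBRIN_SAH_SEQUENCE, prof, seed=42)
        np.testing.assert_array_equal(d1.psi, d2.psi)
        np.testing.assert_array_equal(d1.phi[1:], d2.phi[1:])
        for c1, c2 in zip(d1.chis, d2.chis):
            np.testing.assert_array_equal(c1, c2)

    def test_profile_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            sample_dihedrals("AAAA", HelicityProfile.uniform(3, 0.5), seed=0)

    def test_no_cis_by_default(self):
        prof = HelicityProfile.uniform(74, 0.5)
        for s in range(5):
            d = sample_dihedrals(DREBRIN_SAH_SEQUENCE, prof, seed=s)
            assert not d.has_cis()

    def test_cis_rate_produces_cis_bonds(self):
        prof = HelicityProfile.uniform(74, 0.5)
        d = sample_dihedrals(DREBRIN_SAH_SEQUENCE, prof, seed=0, cis_rate=0.3)
        assert d.has_cis()


class TestBuildConformer:
    def test_alpha_helix_pitch_geometry(self, ideal_helix):
        ca = ideal_helix.ca_coords()
        d_i4 = np.linalg.norm(ca[4:] - ca[:-4], axis=1)
        assert np.allclose(d_i4, 0.62, atol=0.05)

    def test_extended_chain_rise(self, extended_chain):
        ca = extended_chain.ca_coords()
        assert np.linalg.norm(ca[-1] - ca[0]) == pytest.approx(9 * 0.363, rel=0.05)

    def test_single_residue_has_no_peptide_bond(self):
        conf = build_conformer("A", uniform_dihedrals(1, -60.0, -40.0))
        assert conf.n_residues == 1
        assert set(conf.atom_names) == {"N", "CA", "C", "O", "CB"}

    def test_built_torsions_match_requested(self):
        prof = HelicityProfile.uniform(20, 0.5)
        d = sample_dihedrals("A" * 20, prof, seed=3)
        conf = build_conformer("A" * 20, d)
        for i in (5, 10, 15):
            phi, psi = measured_phi_psi(conf, i)
            assert phi == pytest.approx(d.phi[i], abs=1e-6)
            assert psi == pytest.approx(d.psi[i], abs=1e-6)

    def test_backbone_bond_geometry_audit(self, small_pool):
        """All backbone bond lengths within 10% of ideal on every member."""
        ideals = {("N", "CA"): 0.1458, ("CA", "C"): 0.1525, ("C", "O"): 0.1231}
        for conf in small_pool:
            for (a, b), ideal in ideals.items():
                pa = conf.backbone_coords(a)
                pb = conf.backbone_coords(b)
                d = np.linalg.norm(pa - pb, axis=1)
                assert np.all(np.abs(d - ideal) < 0.1 * ideal)
            # peptide bonds
            c = conf.backbone_coords("C")[:-1]
            n_next = conf.backbone_coords("N")[1:]
            d = np.linalg.norm(c - n_next, axis=1)
            assert np.all(np.abs(d - 0.1329) < 0.1 * 0.1329)

    def test_sidechains_respect_requested_chi1(self):
        prof = HelicityProfile.uniform(10, 0.0)
        d = sample_dihedrals("K" * 10, prof, seed=1)
        conf = build_conformer("K" * 10, d)
        for i in range(10):
            chi1 = dihedral(conf.atom_coord(i, "N"), conf.atom_coord(i, "CA"),
                            conf.atom_coord(i, "CB"), conf.atom_coord(i, "CG"))
            assert chi1 == pytest.approx(d.chis[i][0], abs=1e-6)


class TestGeneratePool:
    def test_pool_size_is_seeds_times_variants(self):
        prof = HelicityProfile.uniform(20, 0.8)
        pool = generate_pool("A" * 20, prof, 5, 6, seed=0)
        assert len(pool) == 30  # mirrors the 5000 x 6 = 30,000 bookkeeping

    def test_single_seed_single_variant_is_self_consistent(self):
        prof = HelicityProfile.uniform(20, 0.8)
        pool = generate_pool("A" * 20, prof, 1, 1, seed=5)
        assert len(pool) == 1
        # the stored torsions regenerate the stored coordinates exactly
        rebuilt = build_conformer("A" * 20, pool[0].dihedrals)
        np.testing.assert_allclose(pool[0].backbone_coords("CA"),
                                   rebuilt.backbone_coords("CA"), atol=1e-9)

    def test_variants_share_sequence_but_differ_in_coordinates(self):
        prof = HelicityProfile.uniform(30, 0.6)
        pool = generate_pool("A" * 30, prof, 1, 4, seed=2)
        assert len({m.sequence for m in pool}) == 1
        assert len({m.provenance["stage"] for m in pool}) == 1
        for i in range(len(pool)):
            for j in range(i + 1, len(pool)):
                assert not np.allclose(pool[i].coords, pool[j].coords)

    def test_determinism_under_fixed_seed(self):
        prof = HelicityProfile.uniform(20, 0.7)
        p1 = generate_pool("A" * 20, prof, 3, 2, seed=9)
        p2 = generate_pool("A" * 20, prof, 3, 2, seed=9)
        for a, b in zip(p1, p2):
            np.testing.assert_array_equal(a.coords, b.coords)

    def test_unflagged_members_are_clash_free(self, small_pool):
        for conf in small_pool:
            if not conf.clash_flag:
                n, _ = count_clashes(conf)
                assert n == 0

    def test_rejects_bad_counts(self):
        prof = HelicityProfile.uniform(5, 0.5)
        with pytest.raises(ValueError):
            generate_pool("AAAAA", prof, 0, 1, seed=0)


class TestResampleSidechains:
    @pytest.fixture(scope="class")
    def parent(self):
        prof = HelicityProfile.uniform(74, 0.8)
        return generate_pool(DREBRIN_SAH_SEQUENCE, prof, 1, 1, seed=7)[0]

    def test_default_returns_41_snapshots(self, parent):
        ens = resample_sidechains(parent, seed=0)
        assert len(ens) == 41

    def test_backbone_is_bitwise_frozen(self, parent):
        ens = resample_sidechains(parent, 10, seed=1)
        mask = np.isin(parent.atom_names, BACKBONE)
        for snap in ens:
            np.testing.assert_array_equal(parent.coords[mask], snap.coords[mask])

    def test_arg_chi1_occupies_multiple_rotamer_wells(self, parent):
        ens = resample_sidechains(parent, 41, seed=2)
        arg_positions = [i for i, a in enumerate(parent.sequence) if a == "R"]
        wells_seen = set()
        for i in arg_positions[:5]:
            chi1 = np.array([snap.dihedrals.chis[i][0] for snap in ens])
            wells = np.argmin(np.abs(
                ((chi1[:, None] - np.array([-60.0, 180.0, 60.0]) + 180) % 360)
                - 180), axis=1)
            wells_seen.update(wells.tolist())
        assert len(wells_seen) >= 2

    def test_determinism(self, parent):
        e1 = resample_sidechains(parent, 5, seed=3)
        e2 = resample_sidechains(parent, 5, seed=3)
        for a, b in zip(e1, e2):
            np.testing.assert_array_equal(a.coords, b.coords)
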
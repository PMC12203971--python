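"""Geometric interaction detectors: salt bridges, cation-pi, edge-to-face."""

import numpy as np
import pytest

from sahens.analysis import (
    AnalysisThresholds,
    InteractionRecord,
    cation_pi,
    edge_to_face,
    interaction_matrix,
    salt_bridges,
)
from sahens.conformers import Conformer, Ensemble, HelicityProfile, generate_pool
from sahens.geometry import fit_plane
from sahens.sequence import DREBRIN_SAH_SEQUENCE

ONE = {"GLU": "E", "ARG": "R", "LYS": "K", "ASP": "D", "PHE": "F",
       "TRP": "W", "TYR": "Y", "GLY": "G", "ALA": "A"}


def make_conformer(residues):
    """Hand-placed conformer from [(res3, {atom_name: xyz-nm}), ...]."""
    res_names, atom_res, atom_names, coords = [], [], [], []
    for i, (res3, atoms) in enumerate(residues):
        res_names.append(res3)
        for name, xyz in atoms.items():
            atom_res.append(i)
            atom_names.append(name)
            coords.append(xyz)
    return Conformer(
        sequence="".join(ONE[r] for r in res_names),
        res_names=np.array(res_names),
        atom_res_index=np.array(atom_res, dtype=np.int32),
        atom_names=np.array(atom_names),
        elements=np.array([n[0] for n in atom_names]),
        coords=np.array(coords, dtype=float),
        provenance={"uid": "fixture"},
    )


def hexagon(center, radius=0.14, z=0.0):
    """Six ring atoms in the z=... plane around center."""
    pts = {}
    for k, name in enumerate(["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]):
        ang = np.pi / 3 * k
        pts[name] = np.array([center[0] + radius * np.cos(ang),
                              center[1] + radius * np.sin(ang), z])
    return pts


GAP = {"GLY": {"CA": np.array([5.0, 5.0, 5.0])}}  # spacer residue far away


class TestSaltBridges:
    def pair(self, d):
        """Glu and Arg with closest O-N distance d (nm), spaced i,i+4."""
        glu = {"OE1": np.array([0.0, 0.0, 0.0]),
               "OE2": np.array([0.1, 0.0, 0.0])}
        arg = {"NE": np.array([0.0, d, 0.0]),
               "NH1": np.array([0.1, d + 0.1, 0.0]),
               "NH2": np.array([-0.1, d + 0.1, 0.0])}
        spacers = [("GLY", {"CA": np.array([9.0, 9.0, 9.0 + i])}) for i in range(3)]
        return make_conformer([("GLU", glu)] + spacers + [("ARG", arg)])

    def test_contact_below_cutoff_detected(self):
        recs = salt_bridges(self.pair(0.35))
        assert len(recs) == 1
        rec = recs[0]
        assert rec.kind == "salt_bridge"
        assert rec.orientation == "acidic_toward_N"
        assert rec.spacing_class == "i4"

    def test_contact_beyond_cutoff_ignored(self):
        assert salt_bridges(self.pair(0.45)) == []

    def test_detector_matches_brute_force_on_generated_conformers(self):
        """Detector equals an independent all-pairs scan on real chains."""
        pool = generate_pool(DREBRIN_SAH_SEQUENCE,
                             HelicityProfile.uniform(74, 0.8), 5, 1, seed=31)
        acid = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
        base = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}
        for conf in pool:
            expected = set()
            for i in range(conf.n_residues):
                for j in range(conf.n_residues):
                    if conf.res_names[i] in acid and conf.res_names[j] in base:
                        dmin = min(
                            np.linalg.norm(conf.atom_coord(i, a) -
                                           conf.atom_coord(j, b))
                            for a in acid[conf.res_names[i]]
                            for b in base[conf.res_names[j]])
                        if dmin < 0.4:
                            expected.add((i, j))
            got = {(r.res_i, r.res_j) for r in salt_bridges(conf)}
            assert got == expected


class TestCationPi:
    def stack(self, height, second_offset=0.1):
        """Phe ring in the xy-plane with an Arg guanidinium above it."""
        phe = hexagon((0.0, 0.0))
        arg = {"CZ": np.array([0.0, 0.0, height]),
               "NE": np.array([second_offset, 0.0, height])}
        spacers = [("GLY", {"CA": np.array([9.0, 9.0, 9.0 + i])}) for i in range(2)]
        return make_conformer([("PHE", phe)] + spacers + [("ARG", arg)])

    def test_stacked_cation_detected(self):
        recs = cation_pi(self.stack(0.4))
        assert len(recs) == 1
        assert recs[0].spacing_class == "i3"
        assert recs[0].orientation == "aromatic_toward_N"

    def test_distant_cation_ignored(self):
        assert cation_pi(self.stack(0.7)) == []

    def test_all_five_distances_must_pass(self):
        # plane distance fine but ring-edge atoms too far: shift laterally
        phe = hexagon((0.0, 0.0))
        arg = {"CZ": np.array([0.75, 0.0, 0.1]),
               "NE": np.array([0.8, 0.0, 0.1])}
        conf = make_conformer([("PHE", phe), ("ARG", arg)])
        assert cation_pi(conf) == []

    def test_detector_matches_brute_force_on_generated_conformers(self):
        pool = generate_pool(DREBRIN_SAH_SEQUENCE,
                             HelicityProfile.uniform(74, 0.5), 4, 1, seed=37)
        ring_atoms = {"PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
                      "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
                      "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")}
        for conf in pool:
            expected = set()
            for i in range(conf.n_residues):
                ri = conf.res_names[i]
                if ri not in ring_atoms:
                    continue
                ring = np.array([conf.atom_coord(i, a) for a in ring_atoms[ri]])
                centroid, normal = fit_plane(ring)
                p3 = conf.atom_coord(i, "CD1")
                p4 = conf.atom_coord(i, "CH2" if ri == "TRP" else "CD2")
                p5 = conf.atom_coord(i, "CE2" if ri == "TRP" else "CZ")
                for j in range(conf.n_residues):
                    rj = conf.res_names[j]
                    if rj not in ("ARG", "LYS"):
                        continue
                    cat = conf.atom_coord(j, "CZ" if rj == "ARG" else "NZ")
                    sec = conf.atom_coord(j, "NE" if rj == "ARG" else "CE")
                    ds = [abs(np.dot(cat - centroid, normal)),
                          abs(np.dot(sec - centroid, normal)),
                          np.linalg.norm(p3 - cat),
                          np.linalg.norm(p4 - cat),
                          np.linalg.norm(p5 - cat)]
                    if max(ds) < 0.6:
                        expected.add((i, j))
            got = {(r.res_i, r.res_j) for r in cation_pi(conf)}
            assert got == expected


class TestEdgeToFace:
    def t_stack(self, gap, coplanar=False):
        """Trp indole in the xy-plane; Phe ring edge-on above (or coplanar
        far away)."""
        trp = {}
        names = ["CG", "CD1", "NE1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"]
        for k, name in enumerate(names):
            ang = 2 * np.pi * k / len(names)
            trp[name] = np.array([0.22 * np.cos(ang), 0.22 * np.sin(ang), 0.0])
        if coplanar:
            phe = hexagon((gap, 0.0), z=0.0)
        else:
            phe = {k: np.array([v[0], v[2], gap + v[1] + 0.14])
                   for k, v in hexagon((0.0, 0.0)).items()}
        return make_conformer([("PHE", phe), ("GLY", dict(GAP["GLY"])), ("TRP", trp)])

    def test_perpendicular_stack_detected(self):
        recs = edge_to_face(self.t_stack(0.45))
        assert len(recs) == 1
        assert recs[0].kind == "edge_to_face"

    def test_coplanar_distant_ring_ignored(self):
        assert edge_to_face(self.t_stack(1.0, coplanar=True)) == []


class TestInteractionMatrix:
    def test_single_conformer_single_bridge(self):
        conf = TestSaltBridges().pair(0.35)
        mat = interaction_matrix(Ensemble([conf], "t"), kind="salt_bridge")
        assert mat.count(0, 4) == 1

    def test_duplicated_conformer_counts_multiply(self):
        conf = TestSaltBridges().pair(0.35)
        mat = interaction_matrix(Ensemble([conf] * 60, "t"), kind="salt_bridge")
        assert mat.count(0, 4) == 60
        assert mat.partner_counts()[0] == 60

    def test_designed_i4_ladder_dominates_spacing_classes(self):
        """Several hand-placed E/R pairs at i,i+4 plus one long-range pair:
        the i4 class dominates the spacing breakdown."""
        residues = []
        for k in range(3):
            base = np.array([2.0 * k, 0.0, 0.0])
            residues.append(("GLU", {"OE1": base, "OE2": base + [0.05, 0, 0]}))
            residues.extend([("GLY", {"CA": base + [9, 9, 9 + i]}) for i in range(3)])
            residues.append(("ARG", {"NE": base + [0.0, 0.3, 0.0],
                                     "NH1": base + [0.05, 0.35, 0],
                                     "NH2": base + [-0.05, 0.35, 0]}))
        mat = interaction_matrix(
            Ensemble([make_conformer(residues)], "t"), kind="salt_bridge")
        assert mat.spacing_counts.get("i4", 0) >= 3
        assert mat.spacing_counts.get("i4", 0) > mat.spacing_counts.get("other", 0)

    def test_orientation_counts_sum_to_total(self, small_pool):
        mat = interaction_matrix(small_pool, kind="salt_bridge")
        assert sum(mat.orientation_counts.values()) == sum(mat.counts.values())
        assert sum(mat.spacing_counts.values()) == sum(mat.counts.values())

    def test_detection_invariant_under_rigid_motion(self, small_pool):
        from sahens.geometry import rotate_about_axis
        conf = small_pool[0]
        moved = conf.copy()
        moved.coords = rotate_about_axis(
            conf.coords + np.array([1.0, -2.0, 0.5]),
            np.array([0.3, 0.3, 0.3]), np.array([1.0, 2.0, 3.0]), 73.0)
        for detector in (salt_bridges, cation_pi, edge_to_face):
            a = {(r.res_i, r.res_j) for r in detector(conf)}
            b = {(r.res_i, r.res_j) for r in detector(moved)}
            assert a == b


def test_interaction_record_validates_spacing():
    with pytest.raises(ValueError):
        InteractionRecord("salt_bridge", 1, 5, "GLU", "ARG",
                          "acidic_toward_N", "i3")
    with pytest.raises(ValueError):
        InteractionRecord("salt_bridge", 2, 2, "GLU", "ARG",
                          "acidic_toward_N", "other")
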
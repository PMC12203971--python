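"""All-atom conformer generation for helix-biased disordered chains.

The generator mirrors a statistical-coil pipeline with regional helicity
bias: backbone torsions are drawn per residue either from a tight alpha-
helical basin (with probability given by a per-residue helicity profile)
or from a residue-independent mixture of coil basins (beta / PPII / alphaR
/ alphaL).  Chains are grown with ideal covalent geometry (NeRF), side
chains are attached from ideal residue templates (CCD geometry via
biotite) and rotated to sampled chi angles, and clashes are relieved by
small torsion perturbations.  A side-chain Monte-Carlo resampler with the
backbone held fixed stands in for backbone-restrained MD.

Internal units: nm and degrees.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.spatial import cKDTree

from ._residue_data import CHI_DEFINITIONS, ONE_TO_THREE, chi_well_priors
from .geometry import dihedral, frame_from_three_points
from .sequence import ConstructSequence

logger = logging.getLogger(__name__)

__all__ = [
    "HelicityProfile",
    "DihedralSet",
    "Conformer",
    "Ensemble",
    "sample_dihedrals",
    "build_conformer",
    "generate_pool",
    "resample_sidechains",
    "count_clashes",
    "HELICAL_BASIN",
    "COIL_BASINS",
]

# Ideal backbone covalent geometry (nm / degrees).
BOND_N_CA = 0.1458
BOND_CA_C = 0.1525
BOND_C_N = 0.1329
BOND_C_O = 0.1231
BOND_N_H = 0.098
ANGLE_N_CA_C = 111.0
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8

# (phi, psi) means and sigma of the helical basin.
HELICAL_BASIN = ((-63.0, -42.0), 7.0)

# Residue-independent coil mixture: (phi, psi) mean, (sigma_phi, sigma_psi),
# weight.  The alphaR component gives the coil ensemble its intrinsic
# helical-basin mass.
COIL_BASINS = [
    ((-120.0, 135.0), (25.0, 25.0), 0.32),  # beta
    ((-75.0, 150.0), (15.0, 20.0), 0.35),   # PPII
    ((-65.0, -40.0), (12.0, 12.0), 0.20),   # alphaR
    ((60.0, 45.0), (12.0, 12.0), 0.13),     # alphaL
]

DEFAULT_CLASH_CUTOFF = 0.2  # nm between non-bonded heavy atoms
DEFAULT_RETRY_BUDGET = 50


def _wrap_angle(a):
    """Wrap angles to (-180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = ((a + 180.0) % 360.0) - 180.0
    return np.where(wrapped == -180.0, 180.0, wrapped)


@dataclass(frozen=True)
class HelicityProfile:
    """Per-residue probability of drawing the helical basin."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("profile must be one-dimensional")
        if np.any((vals < 0.0) | (vals > 1.0)):
            raise ValueError("profile values must lie in [0, 1]")
        object.__setattr__(self, "values", vals)

    def __len__(self):
        return len(self.values)

    @classmethod
    def uniform(cls, n: int, p: float) -> "HelicityProfile":
        return cls(np.full(n, float(p)))

    @classmethod
    def from_regions(cls, n: int, baseline: float,
                     regions: list[tuple[int, int, float]]) -> "HelicityProfile":
        """Build from (first, last, probability) 1-based inclusive spans."""
        vals = np.full(n, float(baseline))
        for first, last, p in regions:
            vals[first - 1:last] = p
        return cls(vals)


@dataclass
class DihedralSet:
    """Backbone (phi, psi, omega) and side-chain chi torsions in degrees.

    ``omega[i]`` is the CA(i-1)-C(i-1)-N(i)-CA(i) torsion; ``phi[0]`` and
    ``omega[0]`` are NaN.
    """

    phi: np.ndarray
    psi: np.ndarray
    omega: np.ndarray
    chis: list[np.ndarray]

    def __post_init__(self):
        n = len(self.phi)
        if not (len(self.psi) == len(self.omega) == len(self.chis) == n):
            raise ValueError("inconsistent residue counts in DihedralSet")

    def __len__(self):
        return len(self.phi)

    def has_cis(self, tol_deg: float = 30.0) -> bool:
        om = self.omega[1:]
        return bool(np.any(np.abs(np.abs(om) - 180.0) > tol_deg))

    def copy(self) -> "DihedralSet":
        return DihedralSet(self.phi.copy(), self.psi.copy(), self.omega.copy(),
                           [c.copy() for c in self.chis])


@dataclass
class Conformer:
    """One all-atom chain conformation (coordinates in nm)."""

    sequence: str
    res_names: np.ndarray          # (n_res,) three-letter codes
    atom_res_index: np.ndarray     # (n_atoms,) 0-based residue index
    atom_names: np.ndarray         # (n_atoms,)
    elements: np.ndarray           # (n_atoms,)
    coords: np.ndarray             # (n_atoms, 3) nm
    dihedrals: DihedralSet | None = None
    provenance: dict = field(default_factory=dict)
    clash_flag: bool = False
    _index: dict = field(default=None, repr=False, compare=False)

    @property
    def n_residues(self) -> int:
        return len(self.res_names)

    def _atom_lookup(self):
        if self._index is None:
            self._index = {
                (int(r), n): i
                for i, (r, n) in enumerate(zip(self.atom_res_index, self.atom_names))
            }
        return self._index

    def atom_index(self, res_index: int, atom_name: str):
        """Flat index of an atom, or None if absent (0-based residue)."""
        return self._atom_lookup().get((res_index, atom_name))

    def atom_coord(self, res_index: int, atom_name: str) -> np.ndarray:
        idx = self.atom_index(res_index, atom_name)
        if idx is None:
            raise KeyError(f"no atom {atom_name} in residue {res_index + 1}")
        return self.coords[idx]

    def backbone_coords(self, atom_name: str) -> np.ndarray:
        """(n_res, 3) coordinates of one backbone atom type; NaN if absent."""
        out = np.full((self.n_residues, 3), np.nan)
        mask = self.atom_names == atom_name
        out[self.atom_res_index[mask]] = self.coords[mask]
        return out

    def ca_coords(self) -> np.ndarray:
        return self.backbone_coords("CA")

    @property
    def heavy_mask(self) -> np.ndarray:
        return self.elements != "H"

    def copy(self) -> "Conformer":
        return Conformer(
            self.sequence, self.res_names, self.atom_res_index,
            self.atom_names, self.elements, self.coords.copy(),
            self.dihedrals.copy() if self.dihedrals is not None else None,
            dict(self.provenance), self.clash_flag,
        )


@dataclass
class Ensemble:
    """Ordered, uniformly weighted collection of same-sequence conformers."""

    members: list
    stage: str = "initial_pool"

    def __post_init__(self):
        if len(self.members) < 1:
            raise ValueError("an ensemble needs at least one member")
        seqs = {m.sequence for m in self.members}
        if len(seqs) != 1:
            raise ValueError("all ensemble members must share one sequence")

    @property
    def sequence(self) -> str:
        return self.members[0].sequence

    def __len__(self):
        return len(self.members)

    def __getitem__(self, i):
        return self.members[i]

    def __iter__(self):
        return iter(self.members)

    def subset(self, indices, stage: str | None = None) -> "Ensemble":
        return Ensemble([self.members[i] for i in indices], stage or self.stage)

    @staticmethod
    def concatenate(ensembles, stage: str) -> "Ensemble":
        members = [m for e in ensembles for m in e.members]
        return Ensemble(members, stage)


# ---------------------------------------------------------------------------
# Torsion sampling
# ---------------------------------------------------------------------------

def _sample_coil(rng) -> tuple[float, float]:
    weights = np.array([b[2] for b in COIL_BASINS])
    k = rng.choice(len(COIL_BASINS), p=weights / weights.sum())
    (mphi, mpsi), (sphi, spsi), _ = COIL_BASINS[k]
    return rng.normal(mphi, sphi), rng.normal(mpsi, spsi)


@lru_cache(maxsize=32)
def _chi_prior_cumulative(res3: str):
    """Per-chi (wells, cumulative weights, sigma) with weights normalized."""
    out = []
    for wells, w, sigma in chi_well_priors(res3):
        if wells is None:
            out.append(None)
        else:
            cum = np.cumsum(np.asarray(w, dtype=float))
            out.append((wells, tuple(cum / cum[-1]), sigma))
    return tuple(out)


def _sample_chis(res3: str, rng) -> np.ndarray:
    priors = _chi_prior_cumulative(res3)
    if not priors:
        return np.empty(0)
    chis = np.empty(len(priors))
    for k, prior in enumerate(priors):
        if prior is None:
            chis[k] = rng.random() * 360.0 - 180.0
        else:
            wells, cum, sigma = prior
            u = rng.random()
            j = 0
            while cum[j] < u:
                j += 1
            chis[k] = wells[j] + sigma * rng.standard_normal()
    return _wrap_angle(chis)


def sample_dihedrals(seq: ConstructSequence | str, profile: HelicityProfile,
                     seed=None, cis_rate: float = 0.0) -> DihedralSet:
    """Draw one backbone + side-chain torsion set.

    Per residue, with probability ``profile[i]`` (phi, psi) comes from the
    helical basin, otherwise from the coil mixture.  Omega is trans
    (180 +- 5 deg) except for cis bonds drawn at ``cis_rate``.
    """
    residues = seq.residues if isinstance(seq, ConstructSequence) else seq
    n = len(residues)
    if len(profile) != n:
        raise ValueError(
            f"profile length {len(profile)} does not match sequence length {n}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    (hphi, hpsi), hsig = HELICAL_BASIN
    phi = np.empty(n)
    psi = np.empty(n)
    for i in range(n):
        if rng.random() < profile.values[i]:
            phi[i], psi[i] = rng.normal(hphi, hsig), rng.normal(hpsi, hsig)
        else:
            phi[i], psi[i] = _sample_coil(rng)
    omega = rng.normal(180.0, 5.0, size=n)
    if cis_rate > 0.0:
        cis = rng.random(n) < cis_rate
        omega[cis] = rng.normal(0.0, 5.0, size=int(cis.sum()))
    phi = _wrap_angle(phi)
    psi = _wrap_angle(psi)
    omega = _wrap_angle(omega)
    phi[0] = np.nan
    omega[0] = np.nan
    chis = [_sample_chis(ONE_TO_THREE[aa], rng) for aa in residues]
    return DihedralSet(phi, psi, omega, chis)


# ---------------------------------------------------------------------------
# Side-chain templates (ideal CCD geometry, expressed in a backbone frame)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=32)
def _sidechain_template(res3: str):
    """Ideal side-chain heavy atoms of one residue type.

    Returns (side_names, local_coords, chi_specs).  ``local_coords`` are nm
    offsets from CA expressed in the N/CA/C backbone frame.  Each chi spec
    is (b_ref, c_ref, rotate_mask, theta0) where b_ref/c_ref locate the
    rotatable-bond atoms (either a backbone tag or a side-atom index) and
    ``theta0`` is the template's own value of that torsion — rigid
    placement preserves internal torsions, so at build time each chi only
    needs a single axis rotation by (target - theta0).
    """
    import biotite.structure.info as struc_info

    arr = struc_info.residue(res3)
    heavy = arr[(arr.element != "H") & (arr.atom_name != "OXT")]
    names = list(heavy.atom_name)
    coords = heavy.coord.astype(float) / 10.0  # Angstrom -> nm
    idx = {nm: i for i, nm in enumerate(names)}
    frame = frame_from_three_points(coords[idx["N"]], coords[idx["CA"]], coords[idx["C"]])
    backbone = {"N", "CA", "C", "O"}
    side_names = [nm for nm in names if nm not in backbone]
    side_pos = {nm: i for i, nm in enumerate(side_names)}
    side_idx = [idx[nm] for nm in side_names]
    local = (coords[side_idx] - coords[idx["CA"]]) @ frame.T

    # Bond graph over heavy atoms, for chi-rotation distal sets.
    bonds = heavy.bonds.as_array()[:, :2]
    adjacency = {i: set() for i in range(len(names))}
    for a, b in bonds:
        adjacency[int(a)].add(int(b))
        adjacency[int(b)].add(int(a))

    def _ref(nm):
        return ("bb", nm) if nm in backbone else ("side", side_pos[nm])

    chi_specs = []
    for quad in CHI_DEFINITIONS.get(res3, []):
        b_name, c_name = quad[1], quad[2]
        start = idx[c_name]
        blocked = idx[b_name]
        seen = {blocked, start}
        stack = [start]
        distal = set()
        while stack:
            cur = stack.pop()
            for nb in adjacency[cur]:
                if nb not in seen:
                    seen.add(nb)
                    distal.add(nb)
                    stack.append(nb)
        mask = np.array([idx[nm] in distal for nm in side_names])
        theta0 = dihedral(*(coords[idx[nm]] for nm in quad))
        chi_specs.append((_ref(b_name), _ref(c_name), mask, theta0))
    return side_names, local, chi_specs


def _scalar_frame(p0, p1, p2):
    """Scalar-math equivalent of geometry.frame_from_three_points."""
    ux, uy, uz = p0[0] - p1[0], p0[1] - p1[1], p0[2] - p1[2]
    vx, vy, vz = p2[0] - p1[0], p2[1] - p1[1], p2[2] - p1[2]
    nu = math.sqrt(ux * ux + uy * uy + uz * uz)
    e1x, e1y, e1z = ux / nu, uy / nu, uz / nu
    wx = uy * vz - uz * vy
    wy = uz * vx - ux * vz
    wz = ux * vy - uy * vx
    nw = math.sqrt(wx * wx + wy * wy + wz * wz)
    e3x, e3y, e3z = wx / nw, wy / nw, wz / nw
    e2x = e3y * e1z - e3z * e1y
    e2y = e3z * e1x - e3x * e1z
    e2z = e3x * e1y - e3y * e1x
    return np.array([[e1x, e1y, e1z], [e2x, e2y, e2z], [e3x, e3y, e3z]])


def _rotation_matrix(axis, angle_deg):
    """3x3 rotation about a (non-unit) axis vector, scalar Rodrigues."""
    kx, ky, kz = float(axis[0]), float(axis[1]), float(axis[2])
    nk = math.sqrt(kx * kx + ky * ky + kz * kz)
    kx, ky, kz = kx / nk, ky / nk, kz / nk
    t = math.radians(angle_deg)
    c, s = math.cos(t), math.sin(t)
    ic = 1.0 - c
    return np.array([
        [c + kx * kx * ic, kx * ky * ic - kz * s, kx * kz * ic + ky * s],
        [ky * kx * ic + kz * s, c + ky * ky * ic, ky * kz * ic - kx * s],
        [kz * kx * ic - ky * s, kz * ky * ic + kx * s, c + kz * kz * ic],
    ])


def _place_sidechain(res3: str, n_xyz, ca_xyz, c_xyz, chis):
    """Global side-chain heavy-atom coordinates for one residue."""
    side_names, local, chi_specs = _sidechain_template(res3)
    if not side_names:
        return [], np.empty((0, 3))
    frame = _scalar_frame(n_xyz, ca_xyz, c_xyz)
    coords = ca_xyz + local @ frame
    bb = {"N": n_xyz, "CA": ca_xyz, "C": c_xyz}

    def _coord(ref):
        kind, key = ref
        return bb[key] if kind == "bb" else coords[key]

    for k, (b_ref, c_ref, mask, theta0) in enumerate(chi_specs):
        if k >= len(chis):
            break
        b = np.asarray(_coord(b_ref), dtype=float)
        c = _coord(c_ref)
        rot = _rotation_matrix((c[0] - b[0], c[1] - b[1], c[2] - b[2]),
                               chis[k] - theta0)
        coords[mask] = (coords[mask] - b) @ rot.T + b
    return side_names, coords


# ---------------------------------------------------------------------------
# Chain construction
# ---------------------------------------------------------------------------

def _fast_place(a, b, c, bond, angle_deg, dihedral_deg):
    """Scalar-math NeRF placement (hot path; mirrors geometry.place_atom)."""
    ang = math.radians(angle_deg)
    tor = math.radians(dihedral_deg)
    bcx, bcy, bcz = c[0] - b[0], c[1] - b[1], c[2] - b[2]
    nb = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx, bcy, bcz = bcx / nb, bcy / nb, bcz / nb
    abx, aby, abz = b[0] - a[0], b[1] - a[1], b[2] - a[2]
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    nn = math.sqrt(nx * nx + ny * ny + nz * nz)
    nx, ny, nz = nx / nn, ny / nn, nz / nn
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    d0 = -bond * math.cos(ang)
    d1 = bond * math.sin(ang) * math.cos(tor)
    d2 = bond * math.sin(ang) * math.sin(tor)
    return (c[0] + d0 * bcx + d1 * mx + d2 * nx,
            c[1] + d0 * bcy + d1 * my + d2 * ny,
            c[2] + d0 * bcz + d1 * mz + d2 * nz)


def build_conformer(seq: ConstructSequence | str, dih: DihedralSet,
                    provenance: dict | None = None) -> Conformer:
    """Grow an all-atom chain from torsions with ideal covalent geometry.

    Backbone N/CA/C are placed by NeRF chain growth, carbonyl O in the
    peptide plane, amide H geometrically (absent for Pro and residue 1);
    side-chain heavy atoms come from ideal templates rotated to the chi
    angles.  No clash relief is attempted here (see :func:`generate_pool`).
    """
    residues = seq.residues if isinstance(seq, ConstructSequence) else seq
    n = len(residues)
    if len(dih) != n:
        raise ValueError("DihedralSet length does not match sequence")

    N = [None] * n
    CA = [None] * n
    C = [None] * n
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (BOND_N_CA, 0.0, 0.0)
    ang = math.radians(ANGLE_N_CA_C)
    C[0] = (CA[0][0] - BOND_CA_C * math.cos(ang),
            BOND_CA_C * math.sin(ang), 0.0)
    psi = dih.psi
    phi = dih.phi
    omega = dih.omega
    for i in range(1, n):
        N[i] = _fast_place(N[i - 1], CA[i - 1], C[i - 1],
                           BOND_C_N, ANGLE_CA_C_N, psi[i - 1])
        CA[i] = _fast_place(CA[i - 1], C[i - 1], N[i],
                            BOND_N_CA, ANGLE_C_N_CA, omega[i])
        C[i] = _fast_place(C[i - 1], N[i], CA[i],
                           BOND_CA_C, ANGLE_N_CA_C, phi[i])

    res_names = np.array([ONE_TO_THREE[aa] for aa in residues])
    atom_res, atom_names, elements, coords = [], [], [], []

    for i in range(n):
        res3 = res_names[i]
        entries = [("N", "N", N[i]), ("CA", "C", CA[i]), ("C", "C", C[i])]
        # carbonyl O anti to the next amide nitrogen (torsion psi - 180)
        o_xyz = _fast_place(N[i], CA[i], C[i], BOND_C_O, ANGLE_CA_C_O,
                            psi[i] - 180.0)
        entries.append(("O", "O", o_xyz))
        if i > 0 and res3 != "PRO":
            ni = np.asarray(N[i])
            u = np.asarray(CA[i]) - ni
            v = np.asarray(C[i - 1]) - ni
            bis = u / np.linalg.norm(u) + v / np.linalg.norm(v)
            h_xyz = ni - BOND_N_H * bis / np.linalg.norm(bis)
            entries.append(("H", "H", h_xyz))
        side_names, side_coords = _place_sidechain(
            res3, np.asarray(N[i]), np.asarray(CA[i]), np.asarray(C[i]),
            dih.chis[i])
        for nm, xyz in zip(side_names, side_coords):
            entries.append((nm, nm[0], xyz))
        for nm, el, xyz in entries:
            atom_res.append(i)
            atom_names.append(nm)
            elements.append(el)
            coords.append(xyz)

    conf = Conformer(
        sequence=residues,
        res_names=res_names,
        atom_res_index=np.asarray(atom_res, dtype=np.int32),
        atom_names=np.asarray(atom_names),
        elements=np.asarray(elements),
        coords=np.asarray(coords),
        dihedrals=dih,
        provenance=dict(provenance or {}),
    )
    return conf


_BACKBONE_NAMES = ("C", "CA", "H", "N", "O")


def _clash_pairs(conf: Conformer, cutoff: float = DEFAULT_CLASH_CUTOFF):
    """Flat-index pairs of clashing non-bonded heavy atoms.

    A clash is a heavy-atom pair closer than ``cutoff`` in different
    residues, except backbone-backbone pairs of adjacent residues (these
    are covalently linked through the peptide bond).
    """
    heavy_idx = np.where(conf.heavy_mask)[0]
    coords = conf.coords[heavy_idx]
    res_idx = conf.atom_res_index[heavy_idx]
    is_bb = np.isin(conf.atom_names[heavy_idx], _BACKBONE_NAMES)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return np.empty((0, 2), dtype=int)
    sep = np.abs(res_idx[pairs[:, 0]] - res_idx[pairs[:, 1]])
    bb_bb = is_bb[pairs[:, 0]] & is_bb[pairs[:, 1]]
    keep = (sep >= 2) | ((sep == 1) & ~bb_bb)
    return heavy_idx[pairs[keep]]


def count_clashes(conf: Conformer, cutoff: float = DEFAULT_CLASH_CUTOFF):
    """Number of clashing heavy-atom pairs and the residues involved."""
    pairs = _clash_pairs(conf, cutoff)
    if len(pairs) == 0:
        return 0, np.empty(0, dtype=int)
    residues = np.unique(conf.atom_res_index[pairs.ravel()])
    return len(pairs), residues


def _sidechain_atom_indices(conf: Conformer):
    """Per-residue flat indices of side-chain heavy atoms."""
    side = ~np.isin(conf.atom_names, _BACKBONE_NAMES)
    return [np.where(side & (conf.atom_res_index == i))[0]
            for i in range(conf.n_residues)]


def _redraw_sidechain(conf: Conformer, i: int, rng, side_idx) -> np.ndarray | None:
    """Redraw residue ``i``'s chi set and re-place its side chain in place."""
    if not len(side_idx[i]):
        return None
    res3 = conf.res_names[i]
    chis = _sample_chis(res3, rng)
    _, side_coords = _place_sidechain(
        res3, conf.atom_coord(i, "N"), conf.atom_coord(i, "CA"),
        conf.atom_coord(i, "C"), chis)
    conf.coords[side_idx[i]] = side_coords
    if conf.dihedrals is not None:
        conf.dihedrals.chis[i] = chis
    return chis


def _optimize_sidechain(conf: Conformer, i: int, rng, side_idx,
                        cutoff: float, n_trials: int = 12) -> int:
    """Greedy rotamer search for residue ``i`` against the current structure.

    Proposes up to ``n_trials`` chi sets and keeps the one with the fewest
    heavy-atom contacts below ``cutoff`` to other residues (the incumbent
    side chain competes too).  Returns the remaining contact count.
    """
    if not len(side_idx[i]) or len(CHI_DEFINITIONS.get(conf.res_names[i], [])) == 0:
        return 0
    res3 = conf.res_names[i]
    heavy = conf.heavy_mask & (conf.atom_res_index != i)
    others = conf.coords[heavy]
    n_bb, ca, c_at = (conf.atom_coord(i, "N"), conf.atom_coord(i, "CA"),
                      conf.atom_coord(i, "C"))
    cut2 = cutoff * cutoff

    def _score(side_coords):
        diff = side_coords[:, None, :] - others[None, :, :]
        return int(np.sum(np.einsum("ijk,ijk->ij", diff, diff) < cut2))

    best_chis = conf.dihedrals.chis[i] if conf.dihedrals is not None else None
    best_coords = conf.coords[side_idx[i]]
    best_score = _score(best_coords)
    for _ in range(n_trials):
        if best_score == 0:
            break
        chis = _sample_chis(res3, rng)
        _, side_coords = _place_sidechain(res3, n_bb, ca, c_at, chis)
        score = _score(side_coords)
        if score < best_score:
            best_score, best_coords, best_chis = score, side_coords, chis
    conf.coords[side_idx[i]] = best_coords
    if conf.dihedrals is not None and best_chis is not None:
        conf.dihedrals.chis[i] = best_chis
    return best_score


def _rigid_atom_mask(conf: Conformer) -> np.ndarray:
    """Atoms whose position cannot change under chi resampling.

    Backbone atoms, CB, and the whole side chain of residues without
    sampled chi angles (Gly/Ala/Pro).  A clash between two rigid atoms can
    only be relieved by redrawing backbone torsions.
    """
    rigid = np.isin(conf.atom_names, _BACKBONE_NAMES) | (conf.atom_names == "CB")
    no_chi = np.array([len(CHI_DEFINITIONS.get(r, [])) == 0 for r in conf.res_names])
    rigid |= no_chi[conf.atom_res_index]
    return rigid


def _draw_phipsi(p_helix: float, rng):
    """One (phi, psi) draw: helical basin with probability ``p_helix``."""
    (hphi, hpsi), hsig = HELICAL_BASIN
    if rng.random() < p_helix:
        return rng.normal(hphi, hsig), rng.normal(hpsi, hsig)
    return _sample_coil(rng)


def _build_relaxed(seq, dih, rng, provenance, clash_cutoff, retry_budget,
                   profile: HelicityProfile | None = None):
    """Build a conformer and relieve steric clashes.

    Side-chain clashes are relieved by redrawing the offending residues'
    rotamers in place.  Backbone self-intersections (possible when a coil
    interruption folds the chain back onto itself) are relieved by
    redrawing the clashing residues' (phi, psi) from their basin
    distribution and rebuilding, accepting moves that do not increase the
    clash count.  A conformer still clashing after the retry budget is
    returned flagged, never silently dropped.
    """
    conf = build_conformer(seq, dih, provenance)
    side_idx = _sidechain_atom_indices(conf)
    rigid = _rigid_atom_mask(conf)

    def _counts(c):
        pairs = _clash_pairs(c, clash_cutoff)
        n_rigid = int(np.sum(rigid[pairs[:, 0]] & rigid[pairs[:, 1]])) if len(pairs) else 0
        return pairs, n_rigid

    pairs, n_rigid = _counts(conf)
    stall = 0
    for _ in range(retry_budget):
        if len(pairs) == 0:
            break
        # escalate to backbone redraw for rigid-rigid clashes, or when
        # rotamer moves stop helping (a compacted backbone can leave no
        # clash-free rotamer at all)
        if n_rigid > 0 or stall >= 3:
            rigid_pairs = pairs[rigid[pairs[:, 0]] & rigid[pairs[:, 1]]]
            source = rigid_pairs if len(rigid_pairs) else pairs
            trial = conf.dihedrals.copy()
            # pivot move: a fold-back bringing residues i and j together is
            # relieved by redrawing a torsion somewhere on the arc between
            # them, not necessarily at the contact itself
            redo = set()
            for i, j in source[:3]:
                ri = int(conf.atom_res_index[i])
                rj = int(conf.atom_res_index[j])
                lo, hi = min(ri, rj), max(ri, rj)
                redo.add(int(rng.integers(lo, hi + 1)) if hi > lo else lo)
                redo.update((ri, rj))
            for r in redo:
                p = float(profile.values[r]) if profile is not None else 0.5
                # a clash the helical basin cannot resolve (e.g. a proline
                # ring against the preceding turn's carbonyl) is relieved
                # by letting the residue fall out of the helix locally
                p *= 0.5 ** stall
                phi, psi = _draw_phipsi(p, rng)
                if r > 0:
                    trial.phi[r] = _wrap_angle(phi)
                trial.psi[r] = _wrap_angle(psi)
            cand = build_conformer(seq, trial, provenance)
            cand_pairs, cand_rigid = _counts(cand)
            # rigid clashes are what backbone moves must fix; rotamer
            # clashes introduced by the rebuild get cleaned up below
            if (cand_rigid, len(cand_pairs)) <= (n_rigid, len(pairs)):
                conf, pairs, n_rigid = cand, cand_pairs, cand_rigid
                side_idx = _sidechain_atom_indices(conf)
                stall = 0
            else:
                stall += 1
        else:
            for r in np.unique(conf.atom_res_index[pairs.ravel()]):
                _optimize_sidechain(conf, r, rng, side_idx, clash_cutoff)
            new_pairs, n_rigid = _counts(conf)
            stall = stall + 1 if len(new_pairs) >= len(pairs) else 0
            pairs = new_pairs
    conf.clash_flag = len(pairs) > 0
    return conf


def generate_pool(seq: ConstructSequence | str, profile: HelicityProfile,
                  n_seeds: int, variants_per_seed: int, seed=None,
                  cis_rate: float = 0.0,
                  jitter_deg: float = 5.0,
                  clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
                  retry_budget: int = DEFAULT_RETRY_BUDGET,
                  stage: str = "initial_pool") -> Ensemble:
    """Build a pool of ``n_seeds * variants_per_seed`` conformers.

    Each seed torsion draw yields one as-built conformer plus jittered,
    clash-relaxed copies (torsion perturbations of at most ``jitter_deg``
    followed by clash relief), a surrogate for short vacuum-MD
    diversification of each generated structure.
    """
    if n_seeds < 1 or variants_per_seed < 1:
        raise ValueError("n_seeds and variants_per_seed must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    members = []
    uid = 0
    for s in range(n_seeds):
        dih = sample_dihedrals(seq, profile, rng, cis_rate=cis_rate)
        for v in range(variants_per_seed):
            prov = {"stage": stage, "seed_index": s, "variant": v,
                    "uid": f"{stage}:{uid}"}
            if v == 0:
                conf = _build_relaxed(seq, dih, rng, prov, clash_cutoff,
                                      retry_budget, profile)
            else:
                jit = dih.copy()
                jit.phi[1:] = _wrap_angle(
                    jit.phi[1:] + rng.uniform(-jitter_deg, jitter_deg, len(jit.phi) - 1))
                jit.psi[:] = _wrap_angle(
                    jit.psi + rng.uniform(-jitter_deg, jitter_deg, len(jit.psi)))
                conf = _build_relaxed(seq, jit, rng, prov, clash_cutoff,
                                      retry_budget, profile)
            members.append(conf)
            uid += 1
    return Ensemble(members, stage)


def resample_sidechains(conf: Conformer, n_snapshots: int = 41, seed=None,
                        clash_cutoff: float = DEFAULT_CLASH_CUTOFF,
                        max_rounds: int = 20) -> Ensemble:
    """Monte-Carlo side-chain resampling with the backbone frozen.

    Every snapshot keeps the backbone heavy atoms (N, CA, C, O) bitwise
    identical to the parent and redraws all side-chain chi angles from the
    rotamer-well priors, with hard-sphere clash rejection: residues whose
    new side chain clashes are redrawn for up to ``max_rounds`` rounds and
    a snapshot that cannot be made clash-free is dropped with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = conf.n_residues
    rigid = _rigid_atom_mask(conf)
    parent_pairs = _clash_pairs(conf, clash_cutoff)
    parent_pairs = parent_pairs[~(rigid[parent_pairs[:, 0]] & rigid[parent_pairs[:, 1]])]
    base_pairs = set(map(tuple, parent_pairs))

    members = []
    dropped = 0
    for snap in range(n_snapshots):
        trial = conf.copy()
        side_idx = _sidechain_atom_indices(trial)
        for i in range(n):
            _redraw_sidechain(trial, i, rng, side_idx)
        def _fixable_pairs():
            pairs = _clash_pairs(trial, clash_cutoff)
            # only rotamer-fixable clashes are the resampler's to resolve;
            # rigid-rigid contacts are a property of the fixed backbone,
            # and contacts already present in the parent are its baseline
            pairs = pairs[~(rigid[pairs[:, 0]] & rigid[pairs[:, 1]])]
            if base_pairs:
                keep = [k for k, p in enumerate(map(tuple, pairs))
                        if p not in base_pairs]
                pairs = pairs[keep] if len(keep) < len(pairs) else pairs
            return pairs

        ok = False
        for _ in range(max_rounds):
            pairs = _fixable_pairs()
            if len(pairs) == 0:
                ok = True
                break
            for r in np.unique(trial.atom_res_index[pairs.ravel()]):
                _optimize_sidechain(trial, r, rng, side_idx, clash_cutoff)
        if not ok:
            # fall back toward the parent's (clash-free) rotamers for the
            # residues that could not be re-packed
            for _ in range(conf.n_residues):
                pairs = _fixable_pairs()
                if len(pairs) == 0:
                    ok = True
                    break
                for r in np.unique(trial.atom_res_index[pairs.ravel()]):
                    if len(side_idx[r]):
                        trial.coords[side_idx[r]] = conf.coords[side_idx[r]]
                        if trial.dihedrals is not None and conf.dihedrals is not None:
                            trial.dihedrals.chis[r] = conf.dihedrals.chis[r].copy()
        if not ok:
            dropped += 1
            continue
        trial.provenance = {
            **conf.provenance, "stage": "sidechain_resample",
            "parent": conf.provenance.get("uid"), "snapshot": snap,
            "uid": f"{conf.provenance.get('uid')}/sc{snap}",
        }
        members.append(trial)
    if dropped:
        warnings.warn(
            f"side-chain resampling dropped {dropped} of {n_snapshots} "
            "snapshots (clash-rejection starvation)", stacklevel=2)
        logger.warning("resample_sidechains: %d/%d snapshots dropped",
                       dropped, n_snapshots)
    return Ensemble(members, "sidechain_resample")
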
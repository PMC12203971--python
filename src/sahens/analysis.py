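"""Ensemble structural characterization.

Secondary-structure assignment (Kabsch-Sander hydrogen-bond patterns,
averaged over the ensemble into per-residue state probabilities), geometric
detection of salt bridges, cation-pi and edge-to-face aromatic contacts,
occurrence bookkeeping across an ensemble, and a superposition-free
conformational PCA on Calpha distance matrices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA

from .conformers import Conformer, Ensemble
from .geometry import fit_plane

logger = logging.getLogger(__name__)

__all__ = [
    "SSProfile",
    "AnalysisThresholds",
    "InteractionRecord",
    "InteractionMatrix",
    "dssp_assign",
    "ensemble_ss",
    "helix_indicator",
    "export_ss_logo",
    "salt_bridges",
    "cation_pi",
    "edge_to_face",
    "interaction_matrix",
    "pca_conformers",
]

SS_STATES = ("H", "G", "I", "E", "B", "T", "S", "C")

# Kabsch-Sander electrostatic H-bond model: q1*q2*332 kcal/mol/Angstrom
# with partial charges 0.42 and 0.20; bond accepted below -0.5 kcal/mol.
_KS_COUPLING = 0.42 * 0.20 * 332.0  # = 27.888
_KS_CUTOFF = -0.5
_CHAIN_BREAK_NM = 0.25  # C(i)-N(i+1) beyond this is a chain break


@dataclass(frozen=True)
class AnalysisThresholds:
    """Geometric contact criteria (nm)."""

    salt_bridge_cutoff: float = 0.4
    cation_pi_cutoff: float = 0.6
    edge_to_face_cutoff: float = 0.5

    def __post_init__(self):
        if min(self.salt_bridge_cutoff, self.cation_pi_cutoff,
               self.edge_to_face_cutoff) <= 0:
            raise ValueError("all thresholds must be positive")


@dataclass(frozen=True)
class InteractionRecord:
    """One detected residue-pair contact in one conformer.

    Residue indices are 0-based construct positions; ``spacing_class``
    groups the sequence separation into the helical-face classes i+/-3 and
    i+/-4 versus everything else.
    """

    kind: str                  # salt_bridge | cation_pi | edge_to_face
    res_i: int
    res_j: int
    type_i: str
    type_j: str
    orientation: str
    spacing_class: str
    conformer_uid: str | None = None

    def __post_init__(self):
        if self.res_i == self.res_j:
            raise ValueError("contact requires two distinct residues")
        sep = abs(self.res_i - self.res_j)
        expected = "i3" if sep == 3 else ("i4" if sep == 4 else "other")
        if self.spacing_class != expected:
            raise ValueError("spacing class inconsistent with residue indices")


def _spacing_class(i: int, j: int) -> str:
    sep = abs(i - j)
    return "i3" if sep == 3 else ("i4" if sep == 4 else "other")


@dataclass
class SSProfile:
    """Per-residue secondary-structure state probabilities."""

    probabilities: pd.DataFrame  # index: residue number (1-based), cols SS_STATES

    def __post_init__(self):
        sums = self.probabilities.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("state probabilities must sum to 1 per residue")

    @property
    def helicity(self) -> np.ndarray:
        """P(H): alpha-helix probability per residue."""
        return self.probabilities["H"].to_numpy()

    @property
    def helicity_combined(self) -> np.ndarray:
        """P(H) + P(G) + P(I): any-helix probability per residue."""
        return self.probabilities[["H", "G", "I"]].sum(axis=1).to_numpy()

    def helicity_percent(self) -> np.ndarray:
        return 100.0 * self.helicity

    def high_helicity_segments(self, threshold: float = 0.85):
        """Maximal runs of residues at or above ``threshold`` helicity.

        Returns 1-based inclusive (first, last) spans.
        """
        above = self.helicity >= threshold
        spans = []
        start = None
        for k, flag in enumerate(above):
            if flag and start is None:
                start = k
            elif not flag and start is not None:
                spans.append((start + 1, k))
                start = None
        if start is not None:
            spans.append((start + 1, len(above)))
        return spans


# ---------------------------------------------------------------------------
# Kabsch-Sander secondary structure
# ---------------------------------------------------------------------------

def _hbond_matrix(conf: Conformer):
    """Boolean matrix B[i, j]: N-H of residue i donates to C=O of residue j."""
    n = conf.n_residues
    N = conf.backbone_coords("N")
    C = conf.backbone_coords("C")
    O = conf.backbone_coords("O")
    H = conf.backbone_coords("H")
    # geometric amide H if the builder did not provide one (e.g. read-in
    # structures without protons); prolines and residue 1 have no donor
    have_h = ~np.isnan(H[:, 0])

    def _dist(A, B_):
        return np.sqrt(np.sum((A[:, None, :] - B_[None, :, :]) ** 2, axis=-1))

    # distances in Angstrom for the Kabsch-Sander energy
    r_on = _dist(N, O) * 10.0
    r_cn = _dist(N, C) * 10.0
    r_oh = _dist(H, O) * 10.0
    r_ch = _dist(H, C) * 10.0
    with np.errstate(divide="ignore", invalid="ignore"):
        energy = _KS_COUPLING * (1.0 / r_on + 1.0 / r_ch
                                 - 1.0 / r_oh - 1.0 / r_cn)
    bonds = energy < _KS_CUTOFF
    bonds &= have_h[:, None]
    idx = np.arange(n)
    sep = np.abs(idx[:, None] - idx[None, :])
    bonds &= sep >= 2  # no self or neighbour bonds
    bonds &= ~np.isnan(energy)
    return bonds


def chain_breaks(conf: Conformer) -> np.ndarray:
    """Indices i where the C(i)-N(i+1) peptide bond is broken."""
    C = conf.backbone_coords("C")
    N = conf.backbone_coords("N")
    d = np.linalg.norm(C[:-1] - N[1:], axis=1)
    return np.where(d > _CHAIN_BREAK_NM)[0]


def dssp_assign(conf: Conformer) -> np.ndarray:
    """Kabsch-Sander 8-state secondary-structure labels.

    Hydrogen bonds follow the electrostatic criterion
    E = 27.888 (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) < -0.5 kcal/mol;
    helices (G/H/I) require two consecutive n-turns, strands (E/B) come
    from parallel or antiparallel bridge ladders, remaining turn and bend
    residues are T and S, everything else C.  Residues flanking a chain
    break are left unassigned (C) for the helix patterns crossing the
    break.
    """
    n = conf.n_residues
    hb = _hbond_matrix(conf)  # hb[donor, acceptor]

    def turn(i, k):
        """n-turn at i: C=O(i) accepts from N-H(i+k)."""
        return i + k < n and hb[i + k, i]

    labels = np.full(n, "C", dtype="<U1")

    # bridges
    para = np.zeros((n, n), dtype=bool)
    anti = np.zeros((n, n), dtype=bool)
    for i in range(1, n - 1):
        for j in range(i + 3, n - 1):
            if (hb[j, i - 1] and hb[i + 1, j]) or (hb[i, j - 1] and hb[j + 1, i]):
                para[i, j] = para[j, i] = True
            if (hb[j, i] and hb[i, j]) or (hb[j + 1, i - 1] and hb[i + 1, j - 1]):
                anti[i, j] = anti[j, i] = True
    bridge = para | anti
    in_ladder = np.zeros(n, dtype=bool)
    is_bridge = bridge.any(axis=1)
    # ladders: two consecutive bridges of the same kind
    for mat in (para, anti):
        for i in range(n - 1):
            for j in np.where(mat[i])[0]:
                if i + 1 < n and (mat[i + 1, j + 1] if j + 1 < n else False):
                    in_ladder[[i, i + 1, j]] = True
                    if j + 1 < n:
                        in_ladder[j + 1] = True
                if i + 1 < n and j - 1 >= 0 and mat[i + 1, j - 1]:
                    in_ladder[[i, i + 1, j, j - 1]] = True

    # helices: two consecutive n-turns; priority H > E > G > I
    def mark_helix(k, symbol):
        for i in range(1, n - k + 1):
            if turn(i - 1, k) and turn(i, k):
                for r in range(i, i + k):
                    if symbol == "H" or labels[r] == "C":
                        labels[r] = symbol

    mark_helix(4, "H")
    for i in range(n):
        if labels[i] == "C" and in_ladder[i]:
            labels[i] = "E"
        elif labels[i] == "C" and is_bridge[i]:
            labels[i] = "B"
    mark_helix(3, "G")
    mark_helix(5, "I")

    # turns: residues inside any n-turn
    for i in range(n):
        if labels[i] != "C":
            continue
        covered = False
        for k in (3, 4, 5):
            for s in range(max(0, i - k + 1), i):
                if turn(s, k) and s < i < s + k:
                    covered = True
        if covered:
            labels[i] = "T"

    # bends: kappa angle CA(i-2), CA(i), CA(i+2) > 70 degrees
    ca = conf.ca_coords()
    for i in range(2, n - 2):
        if labels[i] != "C":
            continue
        u = ca[i] - ca[i - 2]
        v = ca[i + 2] - ca[i]
        cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        if np.degrees(np.arccos(np.clip(cosang, -1, 1))) > 70.0:
            labels[i] = "S"

    for b in chain_breaks(conf):
        labels[b] = "C"
        if b + 1 < n:
            labels[b + 1] = "C"
    return labels


def helix_indicator(conf: Conformer) -> np.ndarray:
    """Boolean per-residue alpha-helix ('H') indicator."""
    return dssp_assign(conf) == "H"


def ensemble_ss(ens: Ensemble) -> SSProfile:
    """Per-residue state frequencies across an ensemble."""
    n = ens[0].n_residues
    counts = np.zeros((n, len(SS_STATES)))
    lookup = {s: k for k, s in enumerate(SS_STATES)}
    for conf in ens:
        labels = dssp_assign(conf)
        for i, lab in enumerate(labels):
            counts[i, lookup[lab]] += 1
    probs = counts / len(ens)
    df = pd.DataFrame(probs, columns=list(SS_STATES),
                      index=pd.RangeIndex(1, n + 1, name="residue"))
    return SSProfile(df)


def export_ss_logo(profile: SSProfile, n_rows: int = 100) -> tuple[pd.DataFrame, list[str]]:
    """Logo inputs: per-residue state percentages and a pseudo-alignment.

    The pseudo-alignment has ``n_rows`` sequences over the secondary-
    structure alphabet, apportioned per residue to the state probabilities
    by largest remainder, so external logo tools reproduce the profile.
    """
    probs = profile.probabilities
    percents = probs * 100.0
    n_res = len(probs)
    columns = []
    for _, row in probs.iterrows():
        target = row.to_numpy() * n_rows
        base = np.floor(target).astype(int)
        short = n_rows - base.sum()
        if short > 0:
            order = np.argsort(-(target - base))
            base[order[:short]] += 1
        col = []
        for state, count in zip(probs.columns, base):
            col.extend([state] * count)
        columns.append(col)
    rows = ["".join(columns[i][r] for i in range(n_res)) for r in range(n_rows)]
    return percents, rows


# ---------------------------------------------------------------------------
# Interaction detectors
# ---------------------------------------------------------------------------

_ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_BASIC_ATOMS = {"ARG": ("NE", "NH1", "NH2"), "LYS": ("NZ",)}
_AROMATIC_RING = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    # Trp: the six-membered ring defines the plane
    "TRP": ("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}
_TRP_FULL_RING = ("CG", "CD1", "NE1", "CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2")


def _residues_of(conf, names):
    return [i for i in range(conf.n_residues) if conf.res_names[i] in names]


def _atoms(conf, i, names):
    out = []
    for nm in names:
        idx = conf.atom_index(i, nm)
        if idx is None:
            return None
        out.append(conf.coords[idx])
    return np.asarray(out)


def salt_bridges(conf: Conformer,
                 thresholds: AnalysisThresholds = AnalysisThresholds()
                 ) -> list[InteractionRecord]:
    """Barlow-Thornton ion pairs.

    A bridge is any Asp/Glu - Arg/Lys pair with a side-chain O to
    side-chain N distance below the cutoff (default 0.4 nm).  Orientation
    records whether the acidic partner lies toward the N- or C-terminus;
    every simultaneous multi-partner contact is reported.
    """
    records = []
    uid = conf.provenance.get("uid")
    for i in _residues_of(conf, _ACIDIC_ATOMS):
        ox = _atoms(conf, i, _ACIDIC_ATOMS[conf.res_names[i]])
        if ox is None:
            logger.warning("residue %d missing carboxylate atoms; skipped", i + 1)
            continue
        for j in _residues_of(conf, _BASIC_ATOMS):
            nx = _atoms(conf, j, _BASIC_ATOMS[conf.res_names[j]])
            if nx is None:
                logger.warning("residue %d missing amine atoms; skipped", j + 1)
                continue
            dmin = np.min(np.linalg.norm(ox[:, None, :] - nx[None, :, :], axis=-1))
            if dmin < thresholds.salt_bridge_cutoff:
                records.append(InteractionRecord(
                    kind="salt_bridge", res_i=i, res_j=j,
                    type_i=conf.res_names[i], type_j=conf.res_names[j],
                    orientation="acidic_toward_N" if i < j else "acidic_toward_C",
                    spacing_class=_spacing_class(i, j),
                    conformer_uid=uid,
                ))
    return records


def _plane_distance(points, centroid, normal):
    return np.abs((points - centroid) @ normal)


def cation_pi(conf: Conformer,
              thresholds: AnalysisThresholds = AnalysisThresholds()
              ) -> list[InteractionRecord]:
    """Five-distance geometric cation-pi criterion.

    For every Phe/Tyr/Trp - Arg/Lys pair the following must all fall below
    the cutoff (default 0.6 nm): (1) ring plane to Arg Czeta / Lys Nzeta,
    (2) ring plane to Arg Nepsilon / Lys Cepsilon, (3) ring Cdelta1 to the
    cation atom, (4) ring Cdelta2 (Trp: Ceta2) to the cation atom, (5)
    ring Czeta (Trp: Cepsilon2) to the cation atom.  The Trp plane is the
    least-squares plane of its six-membered ring.
    """
    records = []
    uid = conf.provenance.get("uid")
    cutoff = thresholds.cation_pi_cutoff
    for i in _residues_of(conf, _AROMATIC_RING):
        res3 = conf.res_names[i]
        ring = _atoms(conf, i, _AROMATIC_RING[res3])
        if res3 == "TRP":
            probe_names = ("CD1", "CH2", "CE2")
        else:
            probe_names = ("CD1", "CD2", "CZ")
        probes = _atoms(conf, i, probe_names)
        if ring is None or probes is None:
            logger.warning("residue %d missing ring atoms; skipped", i + 1)
            continue
        centroid, normal = fit_plane(ring)
        for j in _residues_of(conf, _BASIC_ATOMS):
            basic3 = conf.res_names[j]
            names = ("CZ", "NE") if basic3 == "ARG" else ("NZ", "CE")
            cat = _atoms(conf, j, names)
            if cat is None:
                logger.warning("residue %d missing cation atoms; skipped", j + 1)
                continue
            cation_atom, second_atom = cat
            d1 = float(_plane_distance(cation_atom[None], centroid, normal)[0])
            d2 = float(_plane_distance(second_atom[None], centroid, normal)[0])
            d3, d4, d5 = np.linalg.norm(probes - cation_atom, axis=1)
            if max(d1, d2, d3, d4, d5) < cutoff:
                records.append(InteractionRecord(
                    kind="cation_pi", res_i=i, res_j=j,
                    type_i=res3, type_j=basic3,
                    orientation="aromatic_toward_N" if i < j else "aromatic_toward_C",
                    spacing_class=_spacing_class(i, j),
                    conformer_uid=uid,
                ))
    return records


def edge_to_face(conf: Conformer,
                 thresholds: AnalysisThresholds = AnalysisThresholds()
                 ) -> list[InteractionRecord]:
    """Phenyl-edge to indole-plane aromatic contacts.

    Detected when any carbon of a Phe/Tyr phenyl ring lies within the
    cutoff (default 0.5 nm) of the Trp indole least-squares plane and its
    in-plane projection falls inside the ring extent (largest in-plane
    atom radius plus 0.05 nm), which excludes coplanar but laterally
    distant rings.
    """
    records = []
    uid = conf.provenance.get("uid")
    trps = [i for i in range(conf.n_residues) if conf.res_names[i] == "TRP"]
    phes = [i for i in range(conf.n_residues) if conf.res_names[i] in ("PHE", "TYR")]
    for j in trps:
        indole = _atoms(conf, j, _TRP_FULL_RING)
        if indole is None:
            logger.warning("residue %d missing indole atoms; skipped", j + 1)
            continue
        centroid, normal = fit_plane(indole)
        in_plane = indole - np.outer((indole - centroid) @ normal, normal) - centroid
        extent = np.max(np.linalg.norm(in_plane, axis=1)) + 0.05
        for i in phes:
            phenyl = _atoms(conf, i, _AROMATIC_RING[conf.res_names[i]])
            if phenyl is None:
                continue
            dist = _plane_distance(phenyl, centroid, normal)
            proj = phenyl - np.outer((phenyl - centroid) @ normal, normal) - centroid
            lateral = np.linalg.norm(proj, axis=1)
            if np.any((dist < thresholds.edge_to_face_cutoff) & (lateral <= extent)):
                records.append(InteractionRecord(
                    kind="edge_to_face", res_i=i, res_j=j,
                    type_i=conf.res_names[i], type_j="TRP",
                    orientation="aromatic_toward_N" if i < j else "aromatic_toward_C",
                    spacing_class=_spacing_class(i, j),
                    conformer_uid=uid,
                ))
    return records


@dataclass
class InteractionMatrix:
    """Occurrence counts of residue-pair contacts across an ensemble."""

    kind: str
    counts: dict = field(default_factory=dict)       # (res_i, res_j) -> count
    orientation_counts: dict = field(default_factory=dict)
    spacing_counts: dict = field(default_factory=dict)
    n_conformers: int = 0

    def count(self, i: int, j: int) -> int:
        return self.counts.get((min(i, j), max(i, j)), 0)

    def partner_counts(self) -> dict:
        """Total contacts each residue participates in (can exceed the
        number of conformers when a residue has simultaneous partners)."""
        out = {}
        for (i, j), c in self.counts.items():
            out[i] = out.get(i, 0) + c
            out[j] = out.get(j, 0) + c
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"res_i": i + 1, "res_j": j + 1, "count": c}
            for (i, j), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(rows, columns=["res_i", "res_j", "count"])


_DETECTORS = {
    "salt_bridge": salt_bridges,
    "cation_pi": cation_pi,
    "edge_to_face": edge_to_face,
}


def interaction_matrix(ens: Ensemble,
                       thresholds: AnalysisThresholds = AnalysisThresholds(),
                       kind: str = "salt_bridge") -> InteractionMatrix:
    """Count per-pair contact occurrences of one kind over an ensemble."""
    detector = _DETECTORS[kind]
    mat = InteractionMatrix(kind=kind, n_conformers=len(ens))
    for conf in ens:
        for rec in detector(conf, thresholds):
            key = (min(rec.res_i, rec.res_j), max(rec.res_i, rec.res_j))
            mat.counts[key] = mat.counts.get(key, 0) + 1
            mat.orientation_counts[rec.orientation] = (
                mat.orientation_counts.get(rec.orientation, 0) + 1)
            mat.spacing_counts[rec.spacing_class] = (
                mat.spacing_counts.get(rec.spacing_class, 0) + 1)
    return mat


# ---------------------------------------------------------------------------
# Conformational PCA
# ---------------------------------------------------------------------------

def pca_conformers(pool: Ensemble, selected: Ensemble | None = None,
                   n_components: int = 5):
    """PCA of the pool's Calpha-Calpha distance matrices.

    Superposition-free: each conformer is represented by its condensed
    Calpha distance matrix.  Selected conformers are projected into the
    pool's principal-component space.  Returns (pool projections,
    selected projections or None, explained variance ratios).
    """
    if len(pool) < 3:
        raise ValueError("PCA needs at least 3 conformers in the pool")
    n_res = pool[0].n_residues
    for e in (pool, selected) if selected is not None else (pool,):
        for c in e:
            if c.n_residues != n_res:
                raise ValueError("heterogeneous residue counts")
    X = np.stack([pdist(c.ca_coords()) for c in pool])
    n_comp = min(n_components, len(pool) - 1, X.shape[1])
    pca = PCA(n_components=n_comp)
    pool_proj = pca.fit_transform(X)
    sel_proj = None
    if selected is not None:
        Xs = np.stack([pdist(c.ca_coords()) for c in selected])
        sel_proj = pca.transform(Xs)
    return pool_proj, sel_proj, pca.explained_variance_ratio_
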
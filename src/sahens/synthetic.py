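"""Synthetic ground truth and pseudo-experimental observables.

Emulates the study conditions for a 74-residue low-complexity charged
single-alpha-helix construct: a ground-truth ensemble generated from a
prescribed per-residue helicity profile (disordered 8-residue expression
tag, high-helicity core, asymmetric taper that falls off more steeply
toward the C-terminus), noisy Calpha/Cbeta/Halpha chemical shifts, and a
noisy SAXS curve whose relative error grows with angle.  The decoy pool
mixes scaled, flattened and reversed profiles so that it spans compact to
extended shapes and contains look-alikes that match the global dimensions
but not the local helicity pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .conformers import (
    Conformer,
    Ensemble,
    HelicityProfile,
    sample_dihedrals,
)
from .conformers import _build_relaxed  # clash relief reused for pool members
from .forward import SAXSCurve, ShiftTable, coil_shift_table, debye_curve, predict_shifts
from .sequence import DREBRIN_SAH_SEQUENCE

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticScenario",
    "default_helicity_profile",
    "make_truth",
    "observe",
]


def default_helicity_profile(n: int = 74) -> HelicityProfile:
    """Asymmetric high-helicity profile for the 74-residue construct.

    Residues 1-8 (expression-tag remnant) are disordered; helicity rises
    over a long N-side ramp to a high-probability core and drops steeply
    over the last handful of residues, so the taper is asymmetric with
    the sharper transition toward the C-terminus.
    """
    p = np.full(n, 0.95)
    p[:8] = 0.10                                  # disordered tag
    ramp = np.linspace(0.35, 0.95, 18)            # shallow N-side rise
    p[8:8 + len(ramp)] = ramp
    core_hi = slice(37, 59)                       # residues 38-59
    p[core_hi] = 0.97
    tail = np.linspace(0.9, 0.15, 6)              # steep C-side fall
    p[n - len(tail):] = tail
    return HelicityProfile(p[:n])


@dataclass
class SyntheticScenario:
    """Study conditions for the synthetic experiments.

    Sizes default to the scaled-down pipeline (pool 2000, draw 500, five
    repeats, final 60); the full-scale settings remain reachable through
    the same fields.
    """

    sequence: str = DREBRIN_SAH_SEQUENCE
    profile: HelicityProfile | None = None
    truth_min_end_to_end: float = 9.0   # nm; truth emulates the extended state
    truth_size: int = 60
    pool_size: int = 2000
    n_truth_adjacent: int = 400
    draw_size: int = 500
    repeats: int = 5
    per_repeat_size: int = 60
    final_size: int = 60
    snapshots_per_member: int = 10
    shift_sigma: dict = field(default_factory=lambda: {"CA": 0.3, "CB": 0.3, "HA": 0.05})
    saxs_rel_sigma: tuple = (0.02, 0.15)
    s_min: float = 0.1
    s_max: float = 3.0
    n_s: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.profile is None:
            self.profile = default_helicity_profile(len(self.sequence))
        if len(self.profile) != len(self.sequence):
            raise ValueError("profile length must match the sequence")
        if min(self.shift_sigma.values()) <= 0 or min(self.saxs_rel_sigma) <= 0:
            raise ValueError("noise widths must be positive")

    @property
    def s_grid(self) -> np.ndarray:
        return np.linspace(self.s_min, self.s_max, self.n_s)


def _build_from_profile(seq: str, profile: HelicityProfile, rng,
                        stage: str, uid: str) -> Conformer:
    dih = sample_dihedrals(seq, profile, rng)
    return _build_relaxed(seq, dih, rng, {"stage": stage, "uid": uid},
                          clash_cutoff=0.2, retry_budget=50, profile=profile)


def make_truth(scenario: SyntheticScenario, seed=None
               ) -> tuple[Ensemble, Ensemble]:
    """Ground-truth ensemble and decoy pool.

    The truth ensemble is generated from the scenario's helicity profile
    and conditioned on the extended state (terminal Calpha separation of
    at least ``truth_min_end_to_end``), emulating an SAH that is helical
    AND extended rather than a kinked helix bundle.  The pool contains
    truth-adjacent members (fresh, unconditioned draws from the same
    profile) plus decoy families spanning compact to extended shapes:
    uniformly scaled profiles, flat profiles, the reversed profile (same
    mean helicity, wrong local pattern), kinked multi-block helices
    (compact), and rigid full-length helices (maximally extended).
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    seq = scenario.sequence
    n = len(seq)
    profile = scenario.profile

    def _e2e(conf):
        ca = conf.ca_coords()
        return float(np.linalg.norm(ca[-1] - ca[0]))

    truth_members = []
    attempts = 0
    while len(truth_members) < scenario.truth_size and attempts < 50 * scenario.truth_size:
        conf = _build_from_profile(seq, profile, rng, "truth",
                                   f"truth:{len(truth_members)}")
        attempts += 1
        if _e2e(conf) >= scenario.truth_min_end_to_end:
            truth_members.append(conf)
    if len(truth_members) < scenario.truth_size:
        raise RuntimeError("could not generate enough extended truth members")
    truth = Ensemble(truth_members, stage="truth")

    n_pool = scenario.pool_size
    n_adj = min(scenario.n_truth_adjacent, n_pool)
    n_rest = n_pool - n_adj
    shares = {"scaled": 0.15, "flat": 0.2, "rev": 0.15, "blocky": 0.3}
    counts = {fam: int(n_rest * w) for fam, w in shares.items()}
    counts["full"] = n_rest - sum(counts.values())

    def _blocky_profile():
        """Helical blocks broken by short coil stretches: kinked bundles."""
        p = np.zeros(n)
        i = 0
        while i < n:
            block = int(rng.integers(5, 9))
            p[i:i + block] = 0.97
            i += block + int(rng.integers(3, 7))
        return HelicityProfile(p)

    reversed_profile = HelicityProfile(profile.values[::-1].copy())
    family_profiles = {
        "adj": lambda: profile,
        "scaled": lambda: HelicityProfile(profile.values * rng.uniform(0.1, 1.0)),
        "flat": lambda: HelicityProfile.uniform(n, rng.uniform(0.0, 0.6)),
        "rev": lambda: reversed_profile,
        "blocky": _blocky_profile,
        "full": lambda: HelicityProfile.uniform(n, 1.0),
    }
    members = []
    k = 0
    for fam in ("adj", "scaled", "flat", "rev", "blocky", "full"):
        for _ in range(n_adj if fam == "adj" else counts[fam]):
            members.append(_build_from_profile(
                seq, family_profiles[fam](), rng, "decoy_pool",
                f"pool:{fam}:{k}"))
            k += 1
    pool = Ensemble(members, stage="decoy_pool")
    logger.info("synthetic truth %d (acceptance %.2f) + pool %d "
                "(adjacent %d, families %s)", len(truth),
                scenario.truth_size / max(attempts, 1), len(pool), n_adj, counts)
    return truth, pool


def observe(truth: Ensemble, scenario: SyntheticScenario, seed=None,
            noise: bool = True) -> tuple[ShiftTable, SAXSCurve]:
    """Noisy pseudo-experimental observables from the truth ensemble.

    Shifts: two-state forward prediction plus independent Gaussian noise
    per nucleus.  SAXS: ensemble Debye curve on the scenario s grid with
    relative noise growing linearly from the low- to the high-angle end;
    the curve's sigma column carries the generating widths.
    """
    rng = np.random.default_rng(scenario.seed + 1 if seed is None else seed)
    coil = coil_shift_table(truth.sequence)
    pred = predict_shifts(truth, coil)
    data = pred.data.copy()
    if noise:
        sig = data["nucleus"].map(scenario.shift_sigma).to_numpy()
        data["value"] = data["value"] + rng.normal(0.0, sig)
        data["sigma"] = sig
    obs_shifts = ShiftTable(data)

    curve = debye_curve(truth, scenario.s_grid, granularity="ca")
    lo, hi = scenario.saxs_rel_sigma
    rel = lo + (hi - lo) * (curve.s - curve.s[0]) / (curve.s[-1] - curve.s[0])
    sigma = rel * curve.I
    intensity = curve.I + rng.normal(0.0, sigma) if noise else curve.I.copy()
    obs_saxs = SAXSCurve(curve.s, intensity, sigma=sigma)
    return obs_shifts, obs_saxs
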
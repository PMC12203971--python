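"""Multi-stage sub-ensemble selection against chemical shifts and SAXS.

The selection objective is a weighted sum of the ensemble shift RMSD and
the SAXS reduced chi-square, each normalized by its full-pool value so
the weights are scale-free.  Sub-ensembles grow by forward greedy search
(ensemble-averaged predictions recomputed at every candidate size), the
random-draw / select / union protocol mirrors repeated selection from a
large pool, and the final ensemble is selected from a side-chain-
resampled secondary pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .analysis import helix_indicator
from .conformers import Ensemble, resample_sidechains
from .forward import SAXSCurve, ShiftTable, debye_curve

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionObjective",
    "SelectionResult",
    "PrecomputedObservables",
    "greedy_select",
    "repeated_subset_protocol",
    "build_secondary_pool",
    "final_select",
]


@dataclass
class SelectionObjective:
    """Weights and pool-level normalization of the joint objective.

    O(subset) = w_shift * RMSD/RMSD0 + w_saxs * chi2/chi2_0.  A zero
    weight drops the corresponding observable (e.g. SAXS-only selection).
    """

    weight_shift: float = 1.0
    weight_saxs: float = 1.0
    rmsd0: float | None = None
    chi20: float | None = None

    def __post_init__(self):
        if self.weight_shift < 0 or self.weight_saxs < 0:
            raise ValueError("weights must be non-negative")
        if self.weight_shift == 0 and self.weight_saxs == 0:
            raise ValueError("at least one weight must be positive")


@dataclass
class SelectionResult:
    """Indices into the pool plus the per-stage scores."""

    indices: list
    stage: str
    rmsd: float | None
    secondary_correlation: float | None
    chi2: float | None
    objective: float
    objective_trace: list = field(default_factory=list)

    def __len__(self):
        return len(self.indices)


class PrecomputedObservables:
    """Per-conformer forward predictions for fast subset evaluation.

    Rows of ``shift_matrix`` are per-conformer predicted shifts on the
    observed (residue, nucleus) grid; rows of ``saxs_matrix`` are
    per-conformer Debye curves on the observed s grid.
    """

    def __init__(self, pool: Ensemble, obs_shifts: ShiftTable | None,
                 obs_saxs: SAXSCurve | None, coil: ShiftTable | None = None,
                 helix_offsets: dict | None = None,
                 granularity: str = "ca"):
        from ._residue_data import HELIX_SHIFT_OFFSETS
        from .forward import coil_shift_table

        self.pool = pool
        self.obs_shifts = obs_shifts
        self.obs_saxs = obs_saxs
        self.coil = coil if coil is not None else coil_shift_table(pool.sequence)
        offsets = dict(HELIX_SHIFT_OFFSETS)
        if helix_offsets:
            offsets.update(helix_offsets)

        self.offsets = offsets
        self.granularity = granularity
        self.helix_matrix = None
        self.shift_matrix = None
        self.obs_shift_values = None
        if obs_shifts is not None:
            helix = np.stack([helix_indicator(c) for c in pool])  # (n_conf, n_res)
            self.helix_matrix = helix
            coil_s = self.coil.series()
            obs_s = obs_shifts.series()
            common = obs_s.index.intersection(coil_s.index)
            if len(common) < 3:
                raise ValueError("need at least 3 observed shifts with coil reference")
            self.shift_index = common
            residues = common.get_level_values("residue").to_numpy() - 1
            nuclei = common.get_level_values("nucleus").to_numpy()
            off = np.array([offsets[n] for n in nuclei])
            base = coil_s.loc[common].to_numpy()
            self.shift_matrix = base[None, :] + helix[:, residues] * off[None, :]
            self.obs_shift_values = obs_s.loc[common].to_numpy()

        self.saxs_matrix = None
        if obs_saxs is not None:
            self.saxs_matrix = np.stack([
                debye_curve(c, obs_saxs.s, granularity=granularity).I
                for c in pool
            ])
            self.saxs_iv = 1.0 / obs_saxs.sigma ** 2
            self.obs_I = obs_saxs.I

    def rebind(self, obs_shifts: ShiftTable | None = None,
               obs_saxs: SAXSCurve | None = None) -> "PrecomputedObservables":
        """New instance with fresh observations, reusing the per-conformer
        forward matrices (valid for observations on the same residue/
        nucleus set and s grid)."""
        new = object.__new__(PrecomputedObservables)
        new.__dict__.update(self.__dict__)
        if obs_shifts is not None:
            obs_s = obs_shifts.series()
            if not self.shift_index.isin(obs_s.index).all():
                raise ValueError("rebind requires the same observed shift set")
            new.obs_shifts = obs_shifts
            new.obs_shift_values = obs_s.loc[self.shift_index].to_numpy()
        if obs_saxs is not None:
            if len(obs_saxs.s) != self.saxs_matrix.shape[1]:
                raise ValueError("rebind requires the same s grid")
            new.obs_saxs = obs_saxs
            new.saxs_iv = 1.0 / obs_saxs.sigma ** 2
            new.obs_I = obs_saxs.I
        return new

    def rmsd_of_mean(self, mean_pred: np.ndarray) -> float:
        return float(np.sqrt(np.mean((mean_pred - self.obs_shift_values) ** 2)))

    def chi2_of_mean(self, mean_curve: np.ndarray) -> float:
        iv = self.saxs_iv
        c = np.sum(mean_curve * self.obs_I * iv) / np.sum(mean_curve ** 2 * iv)
        resid = (c * mean_curve - self.obs_I) * np.sqrt(iv)
        return float(np.sum(resid ** 2) / max(len(self.obs_I) - 1, 1))

    def pool_scores(self):
        """Objective components of the full pool (normalization constants)."""
        rmsd0 = chi20 = None
        if self.shift_matrix is not None:
            rmsd0 = self.rmsd_of_mean(self.shift_matrix.mean(axis=0))
        if self.saxs_matrix is not None:
            chi20 = self.chi2_of_mean(self.saxs_matrix.mean(axis=0))
        return rmsd0, chi20


def _subset_scores(pre: PrecomputedObservables, indices) -> tuple:
    rmsd = chi2 = None
    if pre.shift_matrix is not None:
        rmsd = pre.rmsd_of_mean(pre.shift_matrix[indices].mean(axis=0))
    if pre.saxs_matrix is not None:
        chi2 = pre.chi2_of_mean(pre.saxs_matrix[indices].mean(axis=0))
    return rmsd, chi2


def _secondary_correlation(pre: PrecomputedObservables, indices) -> float | None:
    """Pooled Pearson r between predicted and observed secondary shifts."""
    if pre.shift_matrix is None:
        return None
    coil_vals = pre.coil.series().loc[pre.shift_index].to_numpy()
    pred = pre.shift_matrix[indices].mean(axis=0) - coil_vals
    obs = pre.obs_shift_values - coil_vals
    if np.std(pred) == 0 or np.std(obs) == 0:
        return np.nan
    return float(np.corrcoef(pred, obs)[0, 1])


def greedy_select(pool: Ensemble, obs_shifts: ShiftTable | None,
                  obs_saxs: SAXSCurve | None,
                  objective: SelectionObjective | None = None,
                  target_size: int = 60, patience: int = 10,
                  precomputed: PrecomputedObservables | None = None,
                  candidate_indices=None,
                  stage: str = "selected") -> SelectionResult:
    """Forward greedy sub-ensemble growth.

    Starts from the best single conformer under the normalized joint
    objective and adds, at every step, the candidate minimizing the
    objective of the grown ensemble (ties break to the lower index).
    Growth stops at ``target_size`` or once the objective has failed to
    improve on its best value for ``patience`` consecutive additions; the
    best prefix is kept and then refined by exchange sweeps (replacing a
    member with a non-member whenever that lowers the objective), which
    removes most of plain forward-greedy's suboptimality.
    """
    if obs_shifts is None and obs_saxs is None:
        raise ValueError("at least one observable must be supplied")
    pre = precomputed or PrecomputedObservables(pool, obs_shifts, obs_saxs)
    objective = objective or SelectionObjective()
    cand = (np.arange(len(pool)) if candidate_indices is None
            else np.asarray(candidate_indices, dtype=int))
    if target_size < 1 or target_size > len(cand):
        raise ValueError("target_size must be between 1 and the candidate count")

    rmsd0, chi20 = objective.rmsd0, objective.chi20
    if (rmsd0 is None or chi20 is None):
        p_rmsd0, p_chi20 = pre.pool_scores()
        rmsd0 = rmsd0 if rmsd0 is not None else p_rmsd0
        chi20 = chi20 if chi20 is not None else p_chi20

    w_s = objective.weight_shift
    w_x = objective.weight_saxs
    use_shift = pre.shift_matrix is not None and w_s > 0
    use_saxs = pre.saxs_matrix is not None and w_x > 0

    def _objective_vec(sum_shift, sum_saxs, k):
        """Objective for current sums grown by each candidate (vectorized)."""
        total = np.zeros(len(cand))
        if use_shift:
            mean_pred = (sum_shift + pre.shift_matrix[cand]) / k
            rmsd = np.sqrt(np.mean((mean_pred - pre.obs_shift_values) ** 2, axis=1))
            total += w_s * rmsd / rmsd0
        if use_saxs:
            mean_curve = (sum_saxs + pre.saxs_matrix[cand]) / k
            iv = pre.saxs_iv
            num = mean_curve @ (pre.obs_I * iv)
            den = np.sum(mean_curve ** 2 * iv[None, :], axis=1)
            c = num / den
            resid = (c[:, None] * mean_curve - pre.obs_I[None, :]) * np.sqrt(iv)[None, :]
            chi2 = np.sum(resid ** 2, axis=1) / max(len(pre.obs_I) - 1, 1)
            total += w_x * chi2 / chi20
        return total

    n_obs_shift = pre.shift_matrix.shape[1] if use_shift else 0
    n_obs_saxs = pre.saxs_matrix.shape[1] if use_saxs else 0
    sum_shift = np.zeros(n_obs_shift)
    sum_saxs = np.zeros(n_obs_saxs)
    selected = []
    remaining = np.ones(len(cand), dtype=bool)
    trace = []
    best_obj = np.inf
    best_len = 0
    since_best = 0

    while len(selected) < target_size and remaining.any():
        obj = _objective_vec(sum_shift, sum_saxs, len(selected) + 1)
        obj[~remaining] = np.inf
        pick = int(np.argmin(obj))
        selected.append(int(cand[pick]))
        remaining[pick] = False
        if use_shift:
            sum_shift = sum_shift + pre.shift_matrix[cand[pick]]
        if use_saxs:
            sum_saxs = sum_saxs + pre.saxs_matrix[cand[pick]]
        current = float(obj[pick])
        trace.append(current)
        if current <= best_obj + 1e-12:
            # improvement or tie: ties extend the prefix (a pool of
            # identical conformers fills the target with the first indices)
            best_obj = min(best_obj, current)
            best_len = len(selected)
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    selected = selected[:best_len]
    trace = trace[:best_len]

    # exchange refinement: swap one member for one candidate while the
    # objective improves (deterministic, first-improvement per position)
    if use_shift:
        sum_shift = pre.shift_matrix[selected].sum(axis=0)
    if use_saxs:
        sum_saxs = pre.saxs_matrix[selected].sum(axis=0)
    k = len(selected)
    in_set = np.zeros(len(pool), dtype=bool)
    in_set[selected] = True
    current_obj = best_obj
    for _ in range(5):  # sweeps
        improved = False
        for pos in range(k):
            i = selected[pos]
            base_shift = sum_shift - pre.shift_matrix[i] if use_shift else sum_shift
            base_saxs = sum_saxs - pre.saxs_matrix[i] if use_saxs else sum_saxs
            obj = _objective_vec(base_shift, base_saxs, k)
            blocked = in_set[cand].copy()
            blocked[cand == i] = False
            obj[blocked] = np.inf
            pick = int(np.argmin(obj))
            j = int(cand[pick])
            if j != i and obj[pick] < current_obj - 1e-12:
                selected[pos] = j
                in_set[i] = False
                in_set[j] = True
                if use_shift:
                    sum_shift = base_shift + pre.shift_matrix[j]
                if use_saxs:
                    sum_saxs = base_saxs + pre.saxs_matrix[j]
                current_obj = float(obj[pick])
                improved = True
        if not improved:
            break
    if current_obj < best_obj:
        best_obj = current_obj
        trace = trace + [current_obj]

    rmsd, chi2 = _subset_scores(pre, selected)
    sec_corr = _secondary_correlation(pre, selected)
    return SelectionResult(indices=selected, stage=stage, rmsd=rmsd,
                           secondary_correlation=sec_corr, chi2=chi2,
                           objective=best_obj, objective_trace=trace)


def repeated_subset_protocol(pool: Ensemble, obs_shifts, obs_saxs,
                             objective: SelectionObjective | None = None,
                             draw_size: int = 5000, repeats: int = 5,
                             per_repeat_size: int = 60, seed=None,
                             precomputed: PrecomputedObservables | None = None
                             ) -> Ensemble:
    """Draw / select / union protocol.

    Each repeat draws ``draw_size`` pool members without replacement
    (draws are independent across repeats) and greedily selects a
    sub-ensemble; the deduplicated union of all selections (by conformer
    identity tag) becomes the next stage's input.
    """
    if draw_size > len(pool):
        raise ValueError("draw_size exceeds the pool size")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pre = precomputed or PrecomputedObservables(pool, obs_shifts, obs_saxs)
    chosen = {}
    for rep in range(repeats):
        draw = rng.choice(len(pool), size=draw_size, replace=False)
        draw.sort()
        result = greedy_select(pool, obs_shifts, obs_saxs, objective,
                               target_size=per_repeat_size,
                               precomputed=pre, candidate_indices=draw,
                               stage=f"repeat_{rep}")
        logger.info("repeat %d: selected %d members (objective %.4f)",
                    rep, len(result), result.objective)
        for idx in result.indices:
            uid = pool[idx].provenance.get("uid", idx)
            chosen.setdefault(uid, idx)
    indices = sorted(chosen.values())
    return pool.subset(indices, stage="union")


def build_secondary_pool(union: Ensemble, snapshots_per_member: int = 41,
                         seed=None, exclude_cis: bool = True) -> Ensemble:
    """Side-chain-resampled secondary pool.

    Every union member contributes ``snapshots_per_member`` conformers
    with its backbone frozen and side chains re-packed; members with cis
    peptide bonds are excluded beforehand.
    """
    if len(union) < 1:
        raise ValueError("empty union")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    members = []
    for conf in union:
        if exclude_cis and conf.dihedrals is not None and conf.dihedrals.has_cis():
            logger.info("excluding cis-containing conformer %s",
                        conf.provenance.get("uid"))
            continue
        ens = resample_sidechains(conf, snapshots_per_member, rng)
        members.extend(ens.members)
    return Ensemble(members, stage="secondary_pool")


def final_select(secondary: Ensemble, obs_shifts, obs_saxs,
                 objective: SelectionObjective | None = None,
                 final_size: int = 60,
                 precomputed: PrecomputedObservables | None = None
                 ) -> SelectionResult:
    """Final ensemble selection from the secondary pool (default 60)."""
    return greedy_select(secondary, obs_shifts, obs_saxs, objective,
                         target_size=final_size, precomputed=precomputed,
                         stage="final")
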
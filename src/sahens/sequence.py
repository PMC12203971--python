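"""Sequence bookkeeping and circular-dichroism arithmetic.

Covers the construct-level quantities used to characterize a single-alpha-
helix (SAH) construct: average molecular mass of the chain, mean residue
weight (MRW), mean residue ellipticity (MRE) and a clearly labelled
two-state helicity approximation from MRE at 222 nm.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._residue_data import AVERAGE_RESIDUE_MASS, WATER_MASS

__all__ = [
    "ConstructSequence",
    "CDRecord",
    "DREBRIN_SAH_SEQUENCE",
    "DREBRIN_SAH",
    "sequence_mass",
    "mean_residue_weight",
    "mre_from_ellipticity",
    "ellipticity_from_mre",
    "approx_helicity_from_mre",
]

# 74-residue Drebrin SAH construct: an 8-residue expression-tag remnant
# (gshmkdpm) followed by the native SAH segment.  Construct position + 164
# gives full-protein (UniProt Q16643) numbering.
DREBRIN_SAH_SEQUENCE = (
    "GSHMKDPM"
    "KRINREQFWE" "QAKKEEELRKE" "EERKKALDER"
    "LRFEQERMEQ" "ERQEQEERER" "RYREREQQIE" "EHRRK"
)


@dataclass(frozen=True)
class ConstructSequence:
    """A one-letter protein sequence with construct bookkeeping.

    Parameters
    ----------
    residues : str
        One-letter amino-acid string (20 standard residues).
    linker_length : int
        Number of non-native N-terminal residues (expression-tag remnant).
    numbering_offset : int
        Added to a construct position to obtain full-protein numbering.
    """

    residues: str
    linker_length: int = 0
    numbering_offset: int = 0

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValueError("sequence must contain at least one residue")
        if self.linker_length >= len(self.residues):
            raise ValueError("linker_length must be smaller than the sequence length")
        for pos, aa in enumerate(self.residues, start=1):
            if aa not in AVERAGE_RESIDUE_MASS:
                raise ValueError(
                    f"unknown residue letter {aa!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    def full_protein_number(self, construct_position: int) -> int:
        """Map a 1-based construct position to full-protein numbering."""
        return construct_position + self.numbering_offset


DREBRIN_SAH = ConstructSequence(
    DREBRIN_SAH_SEQUENCE, linker_length=8, numbering_offset=164
)


@dataclass(frozen=True)
class CDRecord:
    """One column of a CD summary table.

    ``helicity_fraction`` is externally supplied (e.g. from a spectral
    deconvolution program); it is carried, never derived here.
    """

    n_residues: int
    concentration: float        # molar
    path_length: float          # cm
    mw: float                   # Da
    mrw: float                  # Da per residue
    mre_222: float              # deg dmol^-1 cm^2
    helicity_fraction: float

    def __post_init__(self):
        if abs(self.mrw - self.mw / self.n_residues) > 0.01:
            raise ValueError("mrw inconsistent with mw / n_residues")
        if not 0.0 <= self.helicity_fraction <= 1.0:
            raise ValueError("helicity_fraction must lie in [0, 1]")


def sequence_mass(seq: ConstructSequence | str) -> float:
    """Average-isotopic molecular mass of the chain in Da.

    Sum of average residue masses plus one water (equivalently, free
    amino-acid masses minus ``n - 1`` condensation waters).
    """
    residues = seq.residues if isinstance(seq, ConstructSequence) else seq
    if not residues:
        raise ValueError("empty sequence")
    total = WATER_MASS
    for pos, aa in enumerate(residues, start=1):
        try:
            total += AVERAGE_RESIDUE_MASS[aa]
        except KeyError:
            raise ValueError(f"unknown residue letter {aa!r} at position {pos}") from None
    return round(total, 2)


def mean_residue_weight(mw: float, n: int) -> float:
    """MRW = MW / n, reported to two decimals (Da per residue)."""
    if n < 1:
        raise ValueError("residue count must be >= 1")
    return round(mw / n, 2)


def mre_from_ellipticity(
    theta_mdeg: float, conc_mg_ml: float, path_cm: float, n: int, mw: float
) -> float:
    """Mean residue ellipticity in deg dmol^-1 cm^2.

    MRE = theta[mdeg] * MRW / (10 * path[cm] * conc[mg/ml]).
    """
    if conc_mg_ml <= 0 or path_cm <= 0:
        raise ValueError("concentration and path length must be positive")
    mrw = mw / n
    return theta_mdeg * mrw / (10.0 * path_cm * conc_mg_ml)


def ellipticity_from_mre(
    mre: float, conc_mg_ml: float, path_cm: float, n: int, mw: float
) -> float:
    """Algebraic inverse of :func:`mre_from_ellipticity` (mdeg)."""
    if conc_mg_ml <= 0 or path_cm <= 0:
        raise ValueError("concentration and path length must be positive")
    mrw = mw / n
    return mre * 10.0 * path_cm * conc_mg_ml / mrw


def approx_helicity_from_mre(mre_222: float, n: int) -> float:
    """Crude two-state helicity estimate from MRE at 222 nm.

    Uses the textbook limits MRE_helix = -39500 * (1 - 2.57 / n) and
    MRE_coil = 640 deg dmol^-1 cm^2.  This is a labelled approximation for
    orientation only; published helicity percentages normally come from
    spectral deconvolution and will not be reproduced exactly.
    """
    if n < 3:
        raise ValueError("chain too short for the two-state estimate")
    mre_helix = -39500.0 * (1.0 - 2.57 / n)
    mre_coil = 640.0
    frac = (mre_222 - mre_coil) / (mre_helix - mre_coil)
    return float(min(1.0, max(0.0, frac)))
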
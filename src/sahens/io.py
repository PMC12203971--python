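"""Standard-format I/O.

Multi-model PDB ensembles (Angstrom on disk, nm in memory, one MODEL per
conformer), 3-column SAXS ``.dat`` text profiles (s in nm^-1), chemical-
shift tables as TSV, and a lenient reader for an NMR-STAR chemical-shift
loop (Comp_index_ID / Atom_ID / Val columns).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from ._residue_data import THREE_TO_ONE
from .conformers import Conformer, Ensemble
from .forward import SAXSCurve, ShiftTable, SUPPORTED_NUCLEI

logger = logging.getLogger(__name__)

__all__ = [
    "write_pdb_ensemble",
    "read_pdb_ensemble",
    "write_saxs_dat",
    "read_saxs_dat",
    "write_shift_table",
    "read_shift_table",
    "read_star_shifts",
]


def write_pdb_ensemble(ens: Ensemble | Conformer, path,
                       numbering_offset: int = 0) -> None:
    """Write an ensemble as a multi-model PDB file (coordinates in A)."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    members = ens.members if isinstance(ens, Ensemble) else [ens]
    arrays = []
    for conf in members:
        n_atoms = len(conf.coords)
        arr = struc.AtomArray(n_atoms)
        arr.coord = conf.coords * 10.0
        arr.atom_name = conf.atom_names
        arr.res_id = conf.atom_res_index + 1 + numbering_offset
        arr.res_name = conf.res_names[conf.atom_res_index]
        arr.element = conf.elements
        arr.chain_id = np.full(n_atoms, "A")
        arr.hetero = np.zeros(n_atoms, dtype=bool)
        arrays.append(arr)
    stack = struc.stack(arrays)
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


def read_pdb_ensemble(path, stage: str = "loaded") -> Ensemble:
    """Read a multi-model PDB file into an Ensemble (coordinates in nm)."""
    import biotite.structure.io.pdb as pdb

    pdb_file = pdb.PDBFile.read(str(path))
    try:
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:
        raise ValueError(
            f"inconsistent models in {path}: {exc}") from exc
    if stack.stack_depth() == 0:
        raise ValueError(f"no models found in {path}")
    template = stack[0]
    res_ids, res_starts = np.unique(template.res_id, return_index=True)
    res_names = template.res_name[np.sort(res_starts)]
    try:
        sequence = "".join(THREE_TO_ONE[r] for r in res_names)
    except KeyError as exc:
        raise ValueError(f"non-standard residue in {path}: {exc}") from exc
    id_to_index = {rid: k for k, rid in enumerate(sorted(res_ids))}
    atom_res_index = np.array([id_to_index[r] for r in template.res_id],
                              dtype=np.int32)
    members = []
    for m in range(stack.stack_depth()):
        arr = stack[m]
        members.append(Conformer(
            sequence=sequence,
            res_names=np.asarray(res_names),
            atom_res_index=atom_res_index,
            atom_names=np.asarray(template.atom_name),
            elements=np.asarray(template.element),
            coords=np.asarray(arr.coord, dtype=float) / 10.0,
            provenance={"stage": stage, "uid": f"{Path(path).stem}:{m}"},
        ))
    return Ensemble(members, stage=stage)


def write_saxs_dat(curve: SAXSCurve, path, header: str = "") -> None:
    """3-column whitespace text: s [nm^-1], I, sigma."""
    sigma = curve.sigma if curve.sigma is not None else np.zeros(len(curve))
    with open(path, "w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# s[nm^-1]  I  sigma\n")
        for s, i, e in zip(curve.s, curve.I, sigma):
            fh.write(f"{s:.6e} {i:.6e} {e:.6e}\n")


def read_saxs_dat(path) -> SAXSCurve:
    """Read a 3-column SAXS profile; '#' lines are comments."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = text.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least 2 columns")
            try:
                vals = [float(p) for p in parts[:3]]
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed number") from None
            rows.append(vals)
    if not rows:
        raise ValueError(f"{path}: no data lines")
    arr = np.array([r + [0.0] * (3 - len(r)) for r in rows])
    s, intensity, sigma = arr[:, 0], arr[:, 1], arr[:, 2]
    if np.any(np.diff(s) <= 0):
        raise ValueError(f"{path}: s column must be strictly increasing")
    has_sigma = np.any(sigma > 0)
    if has_sigma and np.any(sigma <= 0):
        raise ValueError(f"{path}: nonpositive sigma")
    return SAXSCurve(s, intensity, sigma=sigma if has_sigma else None)


def write_shift_table(table: ShiftTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_shift_table(path) -> ShiftTable:
    """TSV with columns residue, nucleus, value (extras preserved)."""
    df = pd.read_csv(path, sep="\t")
    return ShiftTable(df)


def read_star_shifts(path) -> ShiftTable:
    """Lenient NMR-STAR chemical-shift-loop reader.

    Finds a ``loop_`` whose tags include Comp_index_ID, Atom_ID and Val
    (any ``_Atom_chem_shift``-style prefix) and extracts CA/CB/HA shifts.
    Unsupported nuclei are skipped.
    """
    lines = Path(path).read_text().splitlines()
    records = []
    i = 0
    n = len(lines)
    while i < n:
        if lines[i].strip() != "loop_":
            i += 1
            continue
        i += 1
        tags = []
        while i < n and lines[i].strip().startswith("_"):
            tags.append(lines[i].strip().split(".")[-1])
            i += 1
        wanted = {"Comp_index_ID", "Atom_ID", "Val"}
        if not wanted.issubset(tags):
            continue
        col = {t: k for k, t in enumerate(tags)}
        while i < n:
            text = lines[i].strip()
            if not text:
                i += 1
                continue
            if text == "stop_" or text.startswith(("loop_", "_", "#", "save_")):
                break
            parts = text.split()
            if len(parts) >= len(tags):
                try:
                    res = int(parts[col["Comp_index_ID"]])
                    nucleus = parts[col["Atom_ID"]]
                    val = float(parts[col["Val"]])
                except ValueError:
                    raise ValueError(
                        f"{path}:{i + 1}: malformed chemical-shift row") from None
                if nucleus in SUPPORTED_NUCLEI:
                    records.append((res, nucleus, val))
                else:
                    logger.debug("skipping nucleus %s", nucleus)
            i += 1
    if not records:
        raise ValueError(f"{path}: no chemical-shift loop found")
    return ShiftTable.from_records(records)
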
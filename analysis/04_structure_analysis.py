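#!/usr/bin/env python
"""Structural characterization of the selected ensemble.

Reads the final ensemble written by 02_select_ensemble.py and reports
per-residue helicity (with high-helicity segments), the residue-pair
interaction matrices (salt bridges, cation-pi, edge-to-face) with their
orientation and helical-face spacing breakdown, and the distance-PCA
placement of the selection.
"""

from pathlib import Path

from sahens.analysis import AnalysisThresholds, ensemble_ss, interaction_matrix
from sahens.io import read_pdb_ensemble

RESULTS = Path("results")


def main():
    path = RESULTS / "pipeline" / "selected_ensemble.pdb"
    if not path.exists():
        raise SystemExit("run analysis/02_select_ensemble.py first")
    selected = read_pdb_ensemble(path, stage="selected")
    profile = ensemble_ss(selected)

    segments = profile.high_helicity_segments(0.85)
    print(f"selected ensemble: {len(selected)} conformers")
    print("segments with >= 85% helicity:",
          ", ".join(f"{a}-{b}" for a, b in segments) or "none")
    segments90 = profile.high_helicity_segments(0.90)
    print("segments with >= 90% helicity:",
          ", ".join(f"{a}-{b}" for a, b in segments90) or "none")

    thresholds = AnalysisThresholds()
    with open(RESULTS / "04_interaction_summary.tsv", "w") as fh:
        fh.write("kind\tpairs\ttotal\ti3\ti4\tother\t"
                 "acidic_or_aromatic_toward_N\ttoward_C\n")
        for kind in ("salt_bridge", "cation_pi", "edge_to_face"):
            mat = interaction_matrix(selected, thresholds, kind=kind)
            sp = mat.spacing_counts
            oc = mat.orientation_counts
            toward_n = sum(v for k, v in oc.items() if k.endswith("_N"))
            toward_c = sum(v for k, v in oc.items() if k.endswith("_C"))
            fh.write(f"{kind}\t{len(mat.counts)}\t{sum(mat.counts.values())}\t"
                     f"{sp.get('i3', 0)}\t{sp.get('i4', 0)}\t"
                     f"{sp.get('other', 0)}\t{toward_n}\t{toward_c}\n")
            print(f"{kind}: {sum(mat.counts.values())} contacts over "
                  f"{len(mat.counts)} pairs "
                  f"(i3 {sp.get('i3', 0)}, i4 {sp.get('i4', 0)}, "
                  f"other {sp.get('other', 0)})")
    print("wrote results/04_interaction_summary.tsv")


if __name__ == "__main__":
    main()
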
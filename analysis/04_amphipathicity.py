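#!/usr/bin/env python
"""Helical-wheel and hydrophobic-moment screen of the targeting peptide.

The membrane-targeting peptide MFSKQAKS is short, lysine-rich and, on a
helical wheel, does not segregate hydrophobic from polar faces; its
hydrophobic moment is far below that of a textbook amphipathic helix.
This negative result motivates the non-helical, electrostatics-plus-
insertion binding mode probed by the trajectory analyses.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import bactomts as b

RESULTS = Path(__file__).resolve().parents[1] / "results"

PEPTIDES = {
    "MTS_wt": "MFSKQAKS",
    "MTS_K4S_K7S": "MFSSQASS",
    "MTS_F2Y": "MYSKQAKS",
    "amphipathic_reference": "LKLLKKLLKKLKKLLKKL",
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = ["name\tsequence\tmu_H\tmean_h"]
    for name, seq in PEPTIDES.items():
        mu, mean_h = b.hydrophobic_moment(seq)
        rows.append(f"{name}\t{seq}\t{mu:.4f}\t{mean_h:.4f}")
        print(f"[muH] {name:24s} {seq:20s} muH={mu:.3f} <h>={mean_h:+.3f}")
    (RESULTS / "amphipathicity.tsv").write_text("\n".join(rows) + "\n")

    layout = b.helical_wheel("MFSKQAKS")
    wheel_rows = ["position\tresidue\tangle_deg\tclass"]
    for r in layout.to_rows():
        wheel_rows.append(f"{r['position']}\t{r['residue']}"
                          f"\t{r['angle_deg']:.0f}\t{r['class']}")
    (RESULTS / "wheel_mts.tsv").write_text("\n".join(wheel_rows) + "\n")
    print("[wheel] MFSKQAKS wheel written; basic residues K4/K7 sit at "
          "300/240 degrees — no contiguous hydrophobic face")


if __name__ == "__main__":
    main()
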
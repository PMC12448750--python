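"""Helical-wheel layout, residue classification and hydrophobic moments.

An alpha-helix advances ~100 degrees of wheel angle per residue, so residue
i sits at ((i - 1) * 100) mod 360 degrees. The hydrophobic moment is the
classical vector sum

    muH = | sum_n h_n (cos(delta n), sin(delta n)) | / N

on a named hydrophobicity scale (Eisenberg consensus by default); a high
muH flags amphipathic helices. This is the package's amphipathicity
screen; the bactofilin targeting peptide is expected to score low,
matching its non-amphipathic, extended binding mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import HYDROPHOBICITY_SCALES, RESIDUE_CLASSES


def residue_class(aa: str) -> str:
    """Physico-chemical class of a residue: hydrophobic {ACFILMVWY},
    basic {KRH}, acidic {DE}, uncharged-polar {STNQG}, special {P}."""
    a = aa.upper()
    for cls, members in RESIDUE_CLASSES.items():
        if a in members:
            return cls
    raise ValueError(f"unknown amino acid {aa!r}")


@dataclass
class WheelLayout:
    sequence: str
    angles_deg: np.ndarray
    classes: list[str]

    def to_rows(self) -> list[dict]:
        return [{"position": i + 1, "residue": aa,
                 "angle_deg": float(self.angles_deg[i]),
                 "class": self.classes[i]}
                for i, aa in enumerate(self.sequence)]


def helical_wheel(sequence: str, delta: float = 100.0) -> WheelLayout:
    """Wheel angles ((i-1)*delta mod 360) and residue classes."""
    seq = sequence.upper()
    n = len(seq)
    angles = np.mod((np.arange(n)) * delta, 360.0)
    return WheelLayout(sequence=seq, angles_deg=angles,
                       classes=[residue_class(a) for a in seq])


def hydrophobic_moment(sequence: str, delta: float = 100.0,
                       scale: str = "eisenberg-consensus",
                       ) -> tuple[float, float]:
    """Normalized hydrophobic moment muH and mean hydrophobicity <h>."""
    seq = sequence.upper()
    if not seq:
        raise ValueError("sequence must be non-empty")
    table = HYDROPHOBICITY_SCALES[scale]
    h = np.array([table[a] for a in seq])
    ang = np.deg2rad(np.arange(len(seq)) * delta)
    vec = np.array([(h * np.cos(ang)).sum(), (h * np.sin(ang)).sum()])
    mu_h = float(np.sqrt((vec * vec).sum()) / len(seq))
    return mu_h, float(h.mean())
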
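"""Readers and writers for the plain-text formats used across the package.

Formats
-------
FASTA           wrapped at 60 columns (Biopython-backed).
Taxonomy TSV    columns ``seq_id  superkingdom  phylum  species``.
Topology TSV    columns ``atom_id mol_id mol_type res_index atom_name heavy
                charge_e sigma_nm epsilon_kJmol mass_amu``.
Trajectory      extended-XYZ dialect: per frame a line with the atom count,
                a comment line ``box <Lx> <Ly> <Lz> time_ps <t>``, then
                ``atom_id x y z`` in nm with a fixed atom order.
Sensorgram CSV  columns ``time_s,signal,concentration_M,phase``.
Track CSV       columns ``track_id,frame,t_s,x_um,y_um``.

All numeric output uses fixed formats so identical data yields
byte-identical files.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

TAXONOMY_COLUMNS = ["seq_id", "superkingdom", "phylum", "species"]
TOPOLOGY_COLUMNS = ["atom_id", "mol_id", "mol_type", "res_index", "atom_name",
                    "heavy", "charge_e", "sigma_nm", "epsilon_kJmol",
                    "mass_amu"]


# ---------------------------------------------------------------- sequences

def write_fasta(records: list[tuple[str, str]], path: str | Path) -> None:
    """Write ``(id, sequence)`` pairs as 60-column-wrapped FASTA."""
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    with open(path, "w") as fh:
        SeqIO.write(seqs, fh, "fasta")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    return [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]


def write_taxonomy(table: pd.DataFrame, path: str | Path) -> None:
    table[TAXONOMY_COLUMNS].to_csv(path, sep="\t", index=False)


def read_taxonomy(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(TAXONOMY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"taxonomy table missing columns: {sorted(missing)}")
    return df


# ----------------------------------------------------------------- topology

@dataclass
class Topology:
    """Typed pseudo-atom table for the surrogate membrane system."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(TOPOLOGY_COLUMNS) - set(self.table.columns)
        if missing:
            raise ValueError(f"topology missing columns: {sorted(missing)}")

    @property
    def n_atoms(self) -> int:
        return len(self.table)

    @property
    def atom_ids(self) -> np.ndarray:
        return self.table["atom_id"].to_numpy()

    @property
    def mol_ids(self) -> np.ndarray:
        return self.table["mol_id"].to_numpy()

    @property
    def mol_types(self) -> np.ndarray:
        return self.table["mol_type"].to_numpy()

    @property
    def res_index(self) -> np.ndarray:
        return self.table["res_index"].to_numpy()

    @property
    def heavy(self) -> np.ndarray:
        return self.table["heavy"].to_numpy().astype(bool)

    @property
    def charges(self) -> np.ndarray:
        return self.table["charge_e"].to_numpy(dtype=float)

    @property
    def sigma(self) -> np.ndarray:
        return self.table["sigma_nm"].to_numpy(dtype=float)

    @property
    def epsilon(self) -> np.ndarray:
        return self.table["epsilon_kJmol"].to_numpy(dtype=float)

    @property
    def masses(self) -> np.ndarray:
        return self.table["mass_amu"].to_numpy(dtype=float)

    def lipid_mask(self) -> np.ndarray:
        return np.isin(self.mol_types, ["GLY", "PG", "DAG"])

    def peptide_mask(self) -> np.ndarray:
        return self.mol_types == "PEPTIDE"

    def to_tsv(self, path: str | Path) -> None:
        df = self.table.copy()
        df["heavy"] = df["heavy"].astype(int)
        for col, fmt in (("charge_e", "%.4f"), ("sigma_nm", "%.4f"),
                         ("epsilon_kJmol", "%.4f"), ("mass_amu", "%.2f")):
            df[col] = df[col].map(lambda v, f=fmt: f % v)
        df[TOPOLOGY_COLUMNS].to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Topology":
        df = pd.read_csv(path, sep="\t")
        df["heavy"] = df["heavy"].astype(bool)
        return cls(df)


# --------------------------------------------------------------- trajectory

@dataclass
class Trajectory:
    """Per-frame coordinates with orthorhombic boxes, fixed atom order."""

    atom_ids: np.ndarray            # (n_atoms,)
    coords: np.ndarray              # (n_frames, n_atoms, 3) nm
    boxes: np.ndarray               # (n_frames, 3) nm
    times: np.ndarray               # (n_frames,) ps

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def to_xyz(self, path: str | Path) -> None:
        buf = _io.StringIO()
        for f in range(self.n_frames):
            lx, ly, lz = self.boxes[f]
            buf.write(f"{self.n_atoms}\n")
            buf.write(f"box {lx:.6f} {ly:.6f} {lz:.6f} time_ps "
                      f"{self.times[f]:.3f}\n")
            for a in range(self.n_atoms):
                x, y, z = self.coords[f, a]
                buf.write(f"{self.atom_ids[a]} {x:.6f} {y:.6f} {z:.6f}\n")
        Path(path).write_text(buf.getvalue())

    @classmethod
    def from_xyz(cls, path: str | Path) -> "Trajectory":
        lines = Path(path).read_text().splitlines()
        coords, boxes, times = [], [], []
        atom_ids: list[int] | None = None
        i = 0
        while i < len(lines):
            if not lines[i].strip():
                i += 1
                continue
            n = int(lines[i])
            hdr = lines[i + 1].split()
            if hdr[0] != "box" or hdr[4] != "time_ps":
                raise ValueError(f"malformed frame header: {lines[i + 1]!r}")
            boxes.append([float(hdr[1]), float(hdr[2]), float(hdr[3])])
            times.append(float(hdr[5]))
            ids, xyz = [], []
            for j in range(n):
                parts = lines[i + 2 + j].split()
                ids.append(int(parts[0]))
                xyz.append([float(parts[1]), float(parts[2]), float(parts[3])])
            if atom_ids is None:
                atom_ids = ids
            elif ids != atom_ids:
                raise ValueError("atom order changed between frames")
            coords.append(xyz)
            i += 2 + n
        return cls(np.array(atom_ids), np.array(coords), np.array(boxes),
                   np.array(times))


# --------------------------------------------------------------- timeseries

@dataclass
class SensorgramSet:
    """Association/dissociation biosensor curves at several concentrations.

    ``data`` has columns time_s (phase-relative), signal, concentration_M,
    phase in {assoc, dissoc}.
    """

    data: pd.DataFrame
    t_assoc: float = field(default=0.0)

    def concentrations(self) -> np.ndarray:
        return np.sort(self.data["concentration_M"].unique())

    def to_csv(self, path: str | Path) -> None:
        df = self.data.copy()
        df["time_s"] = df["time_s"].map(lambda v: "%.6f" % v)
        df["signal"] = df["signal"].map(lambda v: "%.8f" % v)
        df["concentration_M"] = df["concentration_M"].map(lambda v: "%.6e" % v)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SensorgramSet":
        df = pd.read_csv(path)
        t_assoc = float(df.loc[df["phase"] == "assoc", "time_s"].max())
        return cls(df, t_assoc=t_assoc)


@dataclass
class TrackSet:
    """2D single-particle tracks; columns track_id, frame, t_s, x_um, y_um."""

    data: pd.DataFrame
    dt: float

    def to_csv(self, path: str | Path) -> None:
        df = self.data.copy()
        for col in ("t_s", "x_um", "y_um"):
            df[col] = df[col].map(lambda v: "%.6f" % v)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TrackSet":
        df = pd.read_csv(path)
        t = np.sort(df["t_s"].unique())
        dt = float(np.min(np.diff(t))) if len(t) > 1 else 0.0
        return cls(df, dt=dt)
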
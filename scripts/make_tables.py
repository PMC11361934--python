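"""One-off generator for the bundled per-residue scale tables in src/tcrh/tables/.

Well-characterised scales (Kidera, Z, VHSE, Cruciani, MS-WHIM, Eisenberg,
Kyte-Doolittle, Boman, residue masses, EMBOSS pKa) are literature transcriptions.
The rarer descriptor families (BLOSUM indices, FASGAI, PCP, Physical, ProtFP,
Sneath, SVGER, ST-, T-scales) are synthetic reconstructions: standardized,
seeded mixtures of measured residue properties chosen to preserve each family's
documented dimensionality and semantics. Those files carry a `.synthetic.`
marker in their name and say so in their header.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

AA = list("ACDEFGHIKLMNPQRSTVWY")
OUT = Path(__file__).resolve().parents[1] / "src" / "tcrh" / "tables"
OUT.mkdir(parents=True, exist_ok=True)

# ---------------------------------------------------------------- transcribed
KIDERA = {  # 10 Kidera factors
    "A": [-1.56, -1.67, -0.97, -0.27, -0.93, -0.78, -0.20, -0.08, 0.21, -0.48],
    "C": [0.12, -0.89, 0.45, -1.05, -0.71, 2.41, 1.52, -0.69, 1.13, 1.10],
    "D": [0.58, -0.22, -1.58, 0.81, -0.92, 0.15, -1.52, 0.47, 0.76, 0.70],
    "E": [-1.45, 0.19, -1.61, 1.17, -1.31, 0.40, 0.04, 0.38, -0.35, -0.12],
    "F": [-0.21, 0.98, -0.36, -1.43, 0.22, -0.81, 0.67, 1.10, 1.71, -0.44],
    "G": [1.46, -1.96, -0.23, -0.16, 0.10, -0.11, 1.32, 2.36, -1.66, 0.46],
    "H": [-0.41, 0.52, -0.28, 0.28, 1.61, 1.01, -1.85, 0.47, 1.13, 1.63],
    "I": [-0.73, -0.16, 1.79, -0.77, -0.54, 0.03, -0.83, 0.51, 0.66, -1.78],
    "K": [-0.34, 0.82, -0.23, 1.70, 1.54, -1.62, 1.15, -0.08, -0.48, 0.60],
    "L": [-1.04, 0.00, -0.24, -1.10, -0.55, -2.05, 0.96, -0.76, 0.45, 0.93],
    "M": [-1.40, 0.18, -0.42, -0.73, 2.00, 1.52, 0.26, 0.11, -1.27, 0.27],
    "N": [1.14, -0.07, -0.12, 0.81, 0.18, 0.37, -0.09, 1.23, 1.10, -1.73],
    "P": [2.06, -0.33, -1.15, -0.75, 0.88, -0.45, 0.30, -2.30, 0.74, -0.28],
    "Q": [-0.47, 0.24, 0.07, 1.10, 1.10, 0.59, 0.84, -0.71, -0.03, -2.33],
    "R": [0.22, 1.27, 1.37, 1.87, -1.70, 0.46, 0.92, -0.39, 0.23, 0.93],
    "S": [0.81, -1.08, 0.16, 0.42, -0.21, -0.43, -1.89, -1.15, -0.97, -0.23],
    "T": [0.26, -0.70, 1.21, 0.63, -0.10, 0.21, 0.24, -1.15, -0.56, 0.19],
    "V": [-0.74, -0.71, 2.04, -0.40, 0.50, -0.81, -1.07, 0.06, -0.46, 0.65],
    "W": [0.30, 2.10, -0.72, -1.57, -1.16, 0.57, -0.48, -0.40, -2.30, -0.60],
    "Y": [1.38, 1.48, 0.80, -0.56, 0.00, -0.68, -0.31, 1.03, -0.05, 0.53],
}
ZSCALES = {  # Sandberg 5 z-scales
    "A": [0.24, -2.32, 0.60, -0.14, 1.30],
    "C": [0.84, -1.67, 3.71, 0.18, -2.65],
    "D": [3.98, 0.93, 1.93, -2.46, 0.75],
    "E": [3.11, 0.26, -0.11, -0.34, -0.25],
    "F": [-4.22, 1.94, 1.06, 0.54, -0.62],
    "G": [2.05, -4.06, 0.36, -0.82, -0.38],
    "H": [2.47, 1.95, 0.26, 3.90, 0.09],
    "I": [-3.89, -1.73, -1.71, -0.84, 0.26],
    "K": [2.29, 0.89, -2.49, 1.49, 0.31],
    "L": [-4.28, -1.30, -1.49, -0.72, 0.84],
    "M": [-2.85, -0.22, 0.47, 1.94, -0.98],
    "N": [3.05, 1.62, 1.04, -1.15, 1.61],
    "P": [-1.66, 0.27, 1.84, 0.70, 2.00],
    "Q": [1.75, 0.50, -1.44, -1.34, 0.66],
    "R": [3.52, 2.50, -3.50, 1.99, -0.17],
    "S": [2.39, -1.07, 1.15, -1.39, 0.67],
    "T": [0.75, -2.18, -1.12, -1.46, -0.40],
    "V": [-2.59, -2.64, -1.54, -0.85, -0.02],
    "W": [-4.36, 3.94, 0.59, 3.44, -1.59],
    "Y": [-2.54, 2.44, 0.43, 0.04, -1.47],
}
VHSE = {  # 8 VHSE scales
    "A": [0.15, -1.11, -1.35, -0.92, 0.02, -0.91, 0.36, -0.48],
    "C": [0.18, -1.67, -0.46, -0.21, 0.00, 1.20, -1.61, -0.19],
    "D": [-1.15, 0.67, -0.41, -0.01, -2.68, 1.31, 0.03, 0.56],
    "E": [-1.18, 0.40, 0.10, 0.36, -2.16, -0.17, 0.91, 0.02],
    "F": [1.52, 0.61, 0.96, -0.16, 0.25, 0.28, -1.33, -0.20],
    "G": [-0.20, -1.53, -2.63, 2.28, -0.53, -1.18, 2.01, -1.34],
    "H": [-0.43, -0.25, 0.37, 0.19, 0.51, 1.28, 0.93, 0.65],
    "I": [1.27, -0.14, 0.30, -1.80, 0.30, -1.61, -0.16, -0.13],
    "K": [-1.17, 0.70, 0.70, 0.80, 1.64, 0.67, 1.63, 0.13],
    "L": [1.36, 0.07, 0.26, -0.80, 0.22, -1.37, 0.08, -0.62],
    "M": [1.01, -0.53, 0.43, 0.00, 0.23, 0.10, -0.86, -0.68],
    "N": [-0.99, 0.00, -0.37, 0.69, -0.55, 0.85, 0.73, -0.80],
    "P": [0.22, -0.17, -0.50, 0.05, -0.01, -1.34, -0.19, 3.56],
    "Q": [-0.96, 0.12, 0.18, 0.16, 0.09, 0.42, -0.20, -0.41],
    "R": [-1.47, 1.45, 1.24, 1.27, 1.55, 1.47, 1.30, 0.83],
    "S": [-0.67, -0.86, -1.07, -0.41, -0.32, 0.27, -0.64, 0.11],
    "T": [-0.34, -0.51, -0.55, -1.06, -0.06, -0.01, -0.79, 0.39],
    "V": [0.76, -0.92, -0.17, -1.91, 0.22, -1.40, -0.24, -0.03],
    "W": [1.50, 2.06, 1.79, 0.75, 0.75, -0.13, -1.01, -0.85],
    "Y": [0.61, 1.60, 1.17, 0.73, 0.53, 0.25, -0.96, -0.52],
}
CRUCIANI = {  # PP1 polarity/hydrophilicity, PP2 H-bond donor, PP3 H-bond acceptor
    "A": [-0.96, -0.76, 0.31],
    "C": [-0.55, -0.47, 0.19],
    "D": [0.82, -0.89, -0.94],
    "E": [0.94, -0.54, -0.99],
    "F": [-0.85, 0.48, -0.58],
    "G": [-0.88, -1.00, 0.49],
    "H": [0.67, -0.11, 0.37],
    "I": [-0.94, -0.05, -0.18],
    "K": [0.60, 0.10, 1.00],
    "L": [-0.90, 0.03, -0.24],
    "M": [-0.82, 0.03, -0.08],
    "N": [0.82, -0.57, 0.02],
    "P": [-0.81, -0.44, -0.18],
    "Q": [0.78, -0.30, -0.38],
    "R": [0.80, 0.63, 0.99],
    "S": [0.41, -0.97, 0.37],
    "T": [0.40, -0.64, 0.27],
    "V": [-0.90, -0.22, -0.15],
    "W": [-0.60, 1.00, -0.48],
    "Y": [-0.58, 0.82, -0.41],
}
MSWHIM = {  # 3 MS-WHIM scores
    "A": [-0.73, 0.20, -0.62],
    "C": [-0.66, 0.26, -0.27],
    "D": [0.11, -1.00, -0.96],
    "E": [0.24, -0.39, -0.04],
    "F": [0.76, 0.85, -0.34],
    "G": [-0.31, -0.28, -0.75],
    "H": [0.84, 0.67, -0.78],
    "I": [-0.91, 0.83, -0.25],
    "K": [-0.51, 0.08, 0.70],
    "L": [-0.74, 0.72, -0.16],
    "M": [-0.70, 1.00, -0.32],
    "N": [0.14, 0.20, -0.66],
    "P": [-0.43, 0.73, -0.60],
    "Q": [0.30, 1.00, -0.30],
    "R": [-0.22, 0.27, 1.00],
    "S": [-0.80, 0.61, -1.00],
    "T": [-0.58, 0.85, -0.89],
    "V": [-1.00, 0.79, -0.58],
    "W": [1.00, 0.98, -0.47],
    "Y": [0.97, 0.66, -0.23],
}
EISENBERG = {  # consensus normalized hydrophobicity
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8, "G": -0.4,
    "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8, "M": 1.9, "N": -3.5,
    "P": -1.6, "Q": -3.5, "R": -4.5, "S": -0.8, "T": -0.7, "V": 4.2,
    "W": -0.9, "Y": -1.3,
}
BOMAN = {  # per-residue solubility contribution, hydrophilic positive
    "A": -1.81, "C": -1.28, "D": 8.72, "E": 6.81, "F": -2.98, "G": -0.94,
    "H": 4.66, "I": -4.92, "K": 5.55, "L": -4.92, "M": -2.35, "N": 6.64,
    "P": 0.0, "Q": 5.54, "R": 14.92, "S": 3.40, "T": 2.57, "V": -4.04,
    "W": -2.33, "Y": 0.14,
}
MASSES = {  # average residue (monomer minus water) masses, Da
    "A": 71.0788, "C": 103.1388, "D": 115.0886, "E": 129.1155, "F": 147.1766,
    "G": 57.0519, "H": 137.1411, "I": 113.1594, "K": 128.1741, "L": 113.1594,
    "M": 131.1926, "N": 114.1038, "P": 97.1167, "Q": 128.1307, "R": 156.1875,
    "S": 87.0782, "T": 101.1051, "V": 99.1326, "W": 186.2132, "Y": 163.1760,
}

# --------------------------------------------------- synthetic reconstructions
# Base measured residue properties used to build the synthetic stand-in scales.
VOLUME = {  # residue volume, A^3
    "A": 88.6, "C": 108.5, "D": 111.1, "E": 138.4, "F": 189.9, "G": 60.1,
    "H": 153.2, "I": 166.7, "K": 168.6, "L": 166.7, "M": 162.9, "N": 114.1,
    "P": 112.7, "Q": 143.8, "R": 173.4, "S": 89.0, "T": 116.1, "V": 140.0,
    "W": 227.8, "Y": 193.6,
}
POLARITY = {  # Grantham polarity
    "A": 8.1, "C": 5.5, "D": 13.0, "E": 12.3, "F": 5.2, "G": 9.0,
    "H": 10.4, "I": 5.2, "K": 11.3, "L": 4.9, "M": 5.7, "N": 11.6,
    "P": 8.0, "Q": 10.5, "R": 10.5, "S": 9.2, "T": 8.6, "V": 5.9,
    "W": 5.4, "Y": 6.2,
}
CHARGE7 = {a: 0.0 for a in AA} | {"K": 1.0, "R": 1.0, "H": 0.1, "D": -1.0, "E": -1.0}
FLEX = {  # normalized B-factor-like flexibility
    "A": 0.36, "C": 0.35, "D": 0.51, "E": 0.50, "F": 0.31, "G": 0.54,
    "H": 0.32, "I": 0.46, "K": 0.47, "L": 0.37, "M": 0.30, "N": 0.46,
    "P": 0.51, "Q": 0.49, "R": 0.53, "S": 0.51, "T": 0.44, "V": 0.39,
    "W": 0.31, "Y": 0.42,
}
AROMATIC = {a: 0.0 for a in AA} | {"F": 1.0, "W": 1.0, "Y": 1.0, "H": 0.5}
BRANCH = {a: 0.0 for a in AA} | {"I": 1.0, "L": 1.0, "V": 1.0, "T": 0.5}


def _std(d: dict) -> np.ndarray:
    v = np.array([d[a] for a in AA], float)
    return (v - v.mean()) / v.std()


BASE = {
    "hydro": _std(KYTE_DOOLITTLE),
    "volume": _std(VOLUME),
    "mass": _std(MASSES),
    "polarity": _std(POLARITY),
    "charge": _std(CHARGE7),
    "flex": _std(FLEX),
    "aromatic": _std(AROMATIC),
    "branch": _std(BRANCH),
}


def synth_family(name: str, primaries: list[str], seed: int) -> dict:
    """Seeded standardized mixtures: one dominant measured property per
    dimension plus small loadings on the others, rounded to 2 dp."""
    rng = np.random.default_rng(seed)
    keys = list(BASE)
    cols = []
    for p in primaries:
        load = 0.3 * rng.normal(size=len(keys))
        col = BASE[p].copy()
        for k, w in zip(keys, load):
            if k != p:
                col = col + w * BASE[k]
        col = (col - col.mean()) / col.std()
        cols.append(np.round(col, 2))
    mat = np.column_stack(cols)
    return {a: list(mat[i]) for i, a in enumerate(AA)}


FASGAI = {  # hand-constructed stand-in: F1 hydrophobicity, F2 alpha/turn,
    # F3 bulkiness, F4 composition, F5 flexibility, F6 electronic
    "A": [-0.59, 1.04, -1.14, 0.25, 0.66, -0.18],
    "C": [0.59, -0.42, -0.49, 2.60, -0.53, 0.36],
    "D": [-1.29, -0.48, -0.58, -0.52, 0.77, -1.74],
    "E": [-1.31, 0.60, -0.11, -0.72, 0.43, -1.60],
    "F": [1.59, -0.49, 1.27, -0.29, -0.66, 0.45],
    "G": [-1.05, -1.60, -1.96, 0.30, 1.57, -0.09],
    "H": [0.05, -0.24, 0.56, 0.26, -0.39, 0.77],
    "I": [1.56, 0.17, 0.35, -0.53, -0.83, 0.08],
    "K": [-1.17, 0.74, 0.45, -0.29, 0.73, 1.41],
    "L": [1.46, 0.52, 0.33, -0.44, -0.52, 0.04],
    "M": [1.12, 0.36, 0.29, 0.65, -0.58, 0.20],
    "N": [-0.91, -0.86, -0.44, -0.21, 0.83, -0.56],
    "P": [-0.58, -2.18, -0.60, -0.16, 1.64, -0.06],
    "Q": [-0.82, 0.52, 0.04, -0.41, 0.36, -0.38],
    "R": [-0.93, 0.46, 0.88, -0.29, 0.38, 1.96],
    "S": [-0.84, -0.74, -1.00, 0.19, 0.96, -0.25],
    "T": [-0.49, -0.55, -0.52, -0.10, 0.40, -0.19],
    "V": [1.24, -0.02, -0.09, -0.46, -0.70, -0.01],
    "W": [1.82, -0.17, 2.07, 0.34, -1.02, 0.75],
    "Y": [1.05, -0.40, 1.34, -0.11, -0.74, 0.59],
}

SYNTH = {
    "blosum_indices": synth_family(
        "blosum",
        ["hydro", "volume", "polarity", "charge", "aromatic",
         "flex", "mass", "hydro", "polarity", "volume"], 101),
    "pcp": synth_family("pcp", ["hydro", "volume", "polarity", "charge", "flex"], 102),
    "protfp": synth_family(
        "protfp",
        ["hydro", "volume", "charge", "polarity", "flex", "aromatic", "mass", "hydro"], 103),
    "sneath": synth_family("sneath", ["volume", "polarity", "hydro", "flex"], 104),
    "svger": synth_family(
        "svger",
        ["volume", "mass", "branch", "volume", "flex", "mass",
         "mass", "branch", "volume", "branch", "aromatic"], 105),
    "st_scales": synth_family(
        "st_scales",
        ["volume", "hydro", "polarity", "mass", "branch", "charge", "flex", "aromatic"], 106),
    "t_scales": synth_family("t_scales", ["mass", "branch", "aromatic", "volume", "flex"], 107),
}
PHYSICAL = {a: [round(float(_std(VOLUME)[i]), 2), round(float(-_std(KYTE_DOOLITTLE)[i]), 2)]
            for i, a in enumerate(AA)}  # PD1 volume, PD2 hydrophilicity


def write_table(fname: str, header: list[str], cols: list[str], data: dict) -> None:
    path = OUT / fname
    lines = [f"# {h}" for h in header]
    lines.append("residue," + ",".join(cols))
    for a in AA:
        row = data[a] if isinstance(data[a], list) else [data[a]]
        lines.append(a + "," + ",".join(f"{v:g}" for v in row))
    path.write_text("\n".join(lines) + "\n")


TRANSCRIBED_NOTE = "Transcribed from the descriptor literature; see docs/methods.md for provenance."
SYNTH_NOTE = ("SYNTHETIC stand-in: seeded mixture of measured residue properties "
              "preserving the family's documented dimensionality and semantics; "
              "not the original published values. See docs/methods.md.")

write_table("kidera.csv",
            ["Kidera factors KF1-KF10 (Kidera et al. 1985).", TRANSCRIBED_NOTE],
            [f"KF{i}" for i in range(1, 11)], KIDERA)
write_table("zscales.csv",
            ["Z-scales Z1-Z5 (Sandberg et al. 1998).", TRANSCRIBED_NOTE],
            [f"Z{i}" for i in range(1, 6)], ZSCALES)
write_table("vhse.csv",
            ["VHSE scales 1-8 (Mei et al. 2005).", TRANSCRIBED_NOTE],
            [f"VHSE{i}" for i in range(1, 9)], VHSE)
write_table("cruciani.csv",
            ["Cruciani properties PP1-PP3 (Cruciani et al. 2004).", TRANSCRIBED_NOTE],
            [f"PP{i}" for i in range(1, 4)], CRUCIANI)
write_table("mswhim.csv",
            ["MS-WHIM scores 1-3 (Zaliani & Gancia 1999).", TRANSCRIBED_NOTE],
            [f"MSWHIM{i}" for i in range(1, 4)], MSWHIM)
write_table("fasgai.synthetic.csv",
            ["FASGAI vectors F1-F6 (Liang & Li 2007).", SYNTH_NOTE],
            [f"F{i}" for i in range(1, 7)], FASGAI)
write_table("physical.synthetic.csv",
            ["Physical descriptors PD1 (volume), PD2 (hydrophilicity).", SYNTH_NOTE],
            ["PD1", "PD2"], PHYSICAL)
write_table("blosum_indices.synthetic.csv",
            ["BLOSUM indices 1-10 (VARIMAX components of BLOSUM62).", SYNTH_NOTE],
            [f"BLOSUM{i}" for i in range(1, 11)], SYNTH["blosum_indices"])
write_table("pcp.synthetic.csv",
            ["PCP descriptors 1-5 (multidimensional scaling of physicochemical properties).",
             SYNTH_NOTE],
            [f"PCP{i}" for i in range(1, 6)], SYNTH["pcp"])
write_table("protfp.synthetic.csv",
            ["ProtFP descriptors 1-8 (PCA of AAindex entries).", SYNTH_NOTE],
            [f"ProtFP{i}" for i in range(1, 9)], SYNTH["protfp"])
write_table("sneath.synthetic.csv",
            ["Sneath vectors SV1-SV4 (PCA of binary residue traits).", SYNTH_NOTE],
            [f"SV{i}" for i in range(1, 5)], SYNTH["sneath"])
write_table("svger.synthetic.csv",
            ["SVGER descriptors 1-11 (geometrical/eigenvalue/Randic PCA).", SYNTH_NOTE],
            [f"SVGER{i}" for i in range(1, 12)], SYNTH["svger"])
write_table("st_scales.synthetic.csv",
            ["ST-scales ST1-ST8 (Yang et al. 2010).", SYNTH_NOTE],
            [f"ST{i}" for i in range(1, 9)], SYNTH["st_scales"])
write_table("t_scales.synthetic.csv",
            ["T-scales T1-T5 (topological descriptors).", SYNTH_NOTE],
            [f"T{i}" for i in range(1, 6)], SYNTH["t_scales"])
write_table("eisenberg.csv",
            ["Eisenberg consensus normalized hydrophobicity.", TRANSCRIBED_NOTE],
            ["value"], EISENBERG)
write_table("kyte_doolittle.csv",
            ["Kyte-Doolittle hydropathy.", TRANSCRIBED_NOTE],
            ["value"], KYTE_DOOLITTLE)
write_table("boman.csv",
            ["Boman per-residue solubility contributions (hydrophilic positive);"
             " P set to 0.0 by convention (absent from the source data).",
             TRANSCRIBED_NOTE],
            ["value"], BOMAN)
write_table("masses.csv",
            ["Average residue masses (Da); peptide mass = sum + 18.0153 (water).",
             TRANSCRIBED_NOTE],
            ["value"], MASSES)

# EMBOSS pKa set
pka = OUT / "pka_emboss.csv"
pka.write_text(
    "# EMBOSS pKa set; sign +1 = basic (protonated below pKa), -1 = acidic.\n"
    "group,pka,sign\n"
    "n_term,8.6,1\nc_term,3.6,-1\n"
    "C,8.5,-1\nD,3.9,-1\nE,4.1,-1\nY,10.1,-1\n"
    "H,6.5,1\nK,10.8,1\nR,12.5,1\n")

# checksum manifest over the csv payloads
manifest = {}
for f in sorted(OUT.glob("*.csv")):
    manifest[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
(OUT / "checksums.json").write_text(json.dumps(manifest, indent=1) + "\n")
print("wrote", len(manifest), "tables ->", OUT)
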
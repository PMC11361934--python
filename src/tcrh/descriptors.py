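"""Whole-sequence physicochemical descriptors for peptides.

Each CDR3β or epitope sequence is summarised by 96 numerical descriptors:
88 family descriptors (per-residue scale tables averaged over the sequence,
14 published families) plus 8 closed-form scalar indices (Boman index, net
charge at pH 7, hydrophobic moment, mean hydrophobicity, instability index,
isoelectric point, average molecular weight, and m/z at unit charge).

Scale tables are shipped as versioned CSV package data with a sha256
manifest; per-residue values are looked up from those tables only, so every
descriptor here is reproducible by brute-force table arithmetic.
"""
from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, field
from functools import cache
from importlib import resources

import numpy as np
import pandas as pd
from Bio.SeqUtils.ProtParamData import DIWV  # Guruprasad dipeptide weights

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(ALPHABET)}

WATER_MASS = 18.0153  # Da
PROTON_MASS = 1.00728  # Da

#: family -> (column prefix file, expected dimensionality), canonical order
FAMILY_FILES = {
    "blosum": ("blosum_indices.synthetic.csv", 10),
    "cruciani": ("cruciani.csv", 3),
    "fasgai": ("fasgai.synthetic.csv", 6),
    "kidera": ("kidera.csv", 10),
    "mswhim": ("mswhim.csv", 3),
    "pcp": ("pcp.synthetic.csv", 5),
    "physical": ("physical.synthetic.csv", 2),
    "protfp": ("protfp.synthetic.csv", 8),
    "sneath": ("sneath.synthetic.csv", 4),
    "svger": ("svger.synthetic.csv", 11),
    "st": ("st_scales.synthetic.csv", 8),
    "t": ("t_scales.synthetic.csv", 5),
    "vhse": ("vhse.csv", 8),
    "z": ("zscales.csv", 5),
}
FAMILY_ORDER = list(FAMILY_FILES)

SCALAR_NAMES = [
    "boman", "charge", "hydrophobic_moment", "hydrophobicity",
    "instability_index", "isoelectric_point", "molecular_weight", "mz",
]


class SequenceError(ValueError):
    """Raised for sequences outside the 20-letter amino-acid alphabet."""


def validate_sequence(raw: str) -> str:
    """Uppercase, strip whitespace and check the 20-letter alphabet.

    Returns the normalized sequence; raises :class:`SequenceError` naming the
    first offending character and its (1-based) position otherwise.
    """
    if raw is None:
        raise SequenceError("sequence is None")
    seq = "".join(str(raw).split()).upper()
    if not seq:
        raise SequenceError("empty sequence")
    for pos, ch in enumerate(seq, start=1):
        if ch not in _AA_INDEX:
            raise SequenceError(
                f"non-standard residue {ch!r} at position {pos} in {seq!r}")
    return seq


# --------------------------------------------------------------------------
# bundled tables
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaleTable:
    """A named per-residue lookup: one real value per standard amino acid."""

    name: str
    values: dict = field(repr=False)

    def __post_init__(self):
        if set(self.values) != set(ALPHABET):
            raise ValueError(f"scale {self.name!r} must cover exactly the 20 residues")

    @property
    def array(self) -> np.ndarray:
        return np.array([self.values[a] for a in ALPHABET], dtype=float)


@dataclass(frozen=True)
class AcidDissociationSet:
    """pKa values for the termini and ionizable side chains (D,E,C,Y,H,K,R)."""

    n_term: float
    c_term: float
    side: dict  # residue -> pKa
    source: str = ""

    def __post_init__(self):
        for v in [self.n_term, self.c_term, *self.side.values()]:
            if not 0.0 < v < 14.0:
                raise ValueError(f"pKa {v} outside (0, 14)")


def _read_table_csv(fname: str) -> pd.DataFrame:
    ref = resources.files("tcrh.tables") / fname
    with ref.open("rb") as fh:
        payload = fh.read()
    manifest = json.loads((resources.files("tcrh.tables") / "checksums.json").read_text())
    digest = hashlib.sha256(payload).hexdigest()
    if manifest.get(fname) != digest:
        raise RuntimeError(f"scale table {fname} fails its checksum")
    from io import BytesIO
    return pd.read_csv(BytesIO(payload), comment="#").set_index("residue")


@cache
def load_family(family: str) -> tuple[ScaleTable, ...]:
    """Ordered per-dimension scale tables of one descriptor family."""
    if family not in FAMILY_FILES:
        raise KeyError(f"unknown descriptor family {family!r}")
    fname, ndim = FAMILY_FILES[family]
    df = _read_table_csv(fname)
    if df.shape != (20, ndim):
        raise RuntimeError(f"{fname}: expected 20x{ndim}, got {df.shape}")
    return tuple(ScaleTable(col, df[col].to_dict()) for col in df.columns)


@cache
def load_scale(name: str) -> ScaleTable:
    """A single-valued per-residue scale (eisenberg, kyte_doolittle, boman, masses)."""
    df = _read_table_csv(f"{name}.csv")
    return ScaleTable(name, df["value"].to_dict())


def _load_pkas() -> AcidDissociationSet:
    ref = resources.files("tcrh.tables") / "pka_emboss.csv"
    df = pd.read_csv(ref.open("r"), comment="#")
    by_group = df.set_index("group")["pka"]
    side = {g: float(by_group[g]) for g in by_group.index if g not in ("n_term", "c_term")}
    return AcidDissociationSet(float(by_group["n_term"]), float(by_group["c_term"]),
                               side, source="EMBOSS")


EMBOSS_PKAS = _load_pkas()

#: canonical 96 descriptor names: family dimensions in family order, scalars last
FEATURE_NAMES: list[str] = [
    t.name for fam in FAMILY_ORDER for t in load_family(fam)
] + list(SCALAR_NAMES)
assert len(FEATURE_NAMES) == 96


@cache
def _family_matrix(family: str) -> np.ndarray:
    """(n_dims, 20) array of the family's scale values in alphabet order."""
    return np.vstack([t.array for t in load_family(family)])


def _indices(seq: str) -> np.ndarray:
    return np.fromiter((_AA_INDEX[a] for a in seq), dtype=np.intp, count=len(seq))


# --------------------------------------------------------------------------
# descriptor operations
# --------------------------------------------------------------------------

def scale_average(seq: str, table: ScaleTable) -> float:
    """Arithmetic mean of the per-residue table values over the sequence."""
    idx = _indices(validate_sequence(seq))
    return float(table.array[idx].mean())


def family_descriptors(seq: str, family: str) -> np.ndarray:
    """Per-dimension scale averages for one descriptor family."""
    idx = _indices(validate_sequence(seq))
    return _family_matrix(family)[:, idx].mean(axis=1)


def boman(seq: str) -> float:
    """Boman index: summed per-residue solubility values divided by length."""
    return scale_average(seq, load_scale("boman"))


def net_charge(seq: str, pH: float = 7.0,
               pkas: AcidDissociationSet = EMBOSS_PKAS) -> float:
    """Henderson-Hasselbalch net charge of the peptide at the given pH.

    Positive groups (N-terminus, K, R, H side chains) each contribute
    ``1/(1 + 10^(pH - pKa))``; negative groups (C-terminus, D, E, C, Y)
    contribute ``-1/(1 + 10^(pKa - pH))``.
    """
    seq = validate_sequence(seq)
    if not 0.0 <= pH <= 14.0:
        raise ValueError("pH outside [0, 14]")
    pos = {"K", "R", "H"} & set(pkas.side)
    neg = {"D", "E", "C", "Y"} & set(pkas.side)
    q = 1.0 / (1.0 + 10.0 ** (pH - pkas.n_term))
    q -= 1.0 / (1.0 + 10.0 ** (pkas.c_term - pH))
    for a in seq:
        if a in pos:
            q += 1.0 / (1.0 + 10.0 ** (pH - pkas.side[a]))
        elif a in neg:
            q -= 1.0 / (1.0 + 10.0 ** (pkas.side[a] - pH))
    return q


def isoelectric_point(seq: str, pkas: AcidDissociationSet = EMBOSS_PKAS,
                      tol: float = 1e-4) -> float:
    """pH at which the net charge is zero, found by bisection on [0, 14].

    The net charge is strictly decreasing in pH and is positive at pH 0 and
    negative at pH 14 for any peptide with free termini, so the zero crossing
    is bracketed; bisection stops when the bracket is narrower than ``tol``.
    """
    seq = validate_sequence(seq)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(seq, mid, pkas) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def hydrophobicity(seq: str, scale_name: str = "kyte_doolittle") -> float:
    """Mean per-residue hydrophobicity on a named bundled scale."""
    return scale_average(seq, load_scale(scale_name))


def hydrophobic_moment(seq: str, angle_deg: float = 100.0, window: int = 11) -> float:
    """Maximum Eisenberg hydrophobic moment over sliding windows.

    For a window of N residues with Eisenberg hydrophobicities h_i,
    ``muH = sqrt((sum h_i sin(i*delta))^2 + (sum h_i cos(i*delta))^2) / N``
    with delta the helical angle in radians and i = 0..N-1; the effective
    window is ``min(window, len(seq))`` and the maximum over all windows is
    returned.
    """
    seq = validate_sequence(seq)
    if window < 1:
        raise ValueError("window must be >= 1")
    h = load_scale("eisenberg").array[_indices(seq)]
    n = min(window, len(seq))
    delta = math.radians(angle_deg)
    phases = np.arange(n) * delta
    sin, cos = np.sin(phases), np.cos(phases)
    best = 0.0
    for start in range(len(seq) - n + 1):
        w = h[start:start + n]
        mu = math.hypot(float(w @ sin), float(w @ cos)) / n
        best = max(best, mu)
    return best


def instability_index(seq: str) -> float:
    """Guruprasad instability index: (10/L) * sum of dipeptide weights.

    Length-1 sequences have no dipeptide; they return 0.0 with a warning.
    """
    seq = validate_sequence(seq)
    if len(seq) == 1:
        warnings.warn("instability_index of a length-1 sequence is 0 by convention",
                      stacklevel=2)
        return 0.0
    total = sum(DIWV[a][b] for a, b in zip(seq, seq[1:]))
    return 10.0 / len(seq) * total


def molecular_weight(seq: str) -> float:
    """Average molecular weight in daltons (residue masses plus one water)."""
    seq = validate_sequence(seq)
    masses = load_scale("masses").array
    return float(masses[_indices(seq)].sum()) + WATER_MASS


def mass_over_charge(seq: str, z: int = 1) -> float:
    """m/z of the peptide: (M + z * proton mass) / z for charge state z >= 1."""
    if z < 1:
        raise ValueError("charge state z must be >= 1")
    return (molecular_weight(seq) + z * PROTON_MASS) / z


def feature_vector(seq: str) -> pd.Series:
    """All 96 descriptors of one sequence, named, in canonical order."""
    seq = validate_sequence(seq)
    values = np.concatenate(
        [family_descriptors(seq, fam) for fam in FAMILY_ORDER]
        + [np.array([
            boman(seq),
            net_charge(seq, 7.0),
            hydrophobic_moment(seq),
            hydrophobicity(seq),
            instability_index(seq) if len(seq) > 1 else 0.0,
            isoelectric_point(seq),
            molecular_weight(seq),
            mass_over_charge(seq),
        ])])
    if not np.all(np.isfinite(values)):
        raise RuntimeError(f"non-finite descriptor for {seq!r}")
    return pd.Series(values, index=FEATURE_NAMES, name=seq)


def featurize_pair(epitope: str, cdr3b: str) -> pd.Series:
    """192 named descriptors: epitope block (``epi_``) then CDR3β (``cdr_``)."""
    e = feature_vector(epitope)
    c = feature_vector(cdr3b)
    return pd.concat([e.add_prefix("epi_"), c.add_prefix("cdr_")])


PAIR_FEATURE_NAMES: list[str] = (
    [f"epi_{n}" for n in FEATURE_NAMES] + [f"cdr_{n}" for n in FEATURE_NAMES])


def featurize_pairs(epitopes, cdr3bs) -> pd.DataFrame:
    """Vectorized 192-column feature matrix for aligned sequence pairs.

    Unique sequences are featurized once and broadcast, which matters because
    binding tables reuse few epitopes across many TCRs.
    """
    epitopes = list(epitopes)
    cdr3bs = list(cdr3bs)
    if len(epitopes) != len(cdr3bs):
        raise ValueError("epitopes and cdr3bs must have equal length")
    uniq = {s: feature_vector(s).to_numpy()
            for s in dict.fromkeys(epitopes + cdr3bs)}
    epi = np.vstack([uniq[s] for s in epitopes])
    cdr = np.vstack([uniq[s] for s in cdr3bs])
    return pd.DataFrame(np.hstack([epi, cdr]), columns=PAIR_FEATURE_NAMES)
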
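"""Rigid Calpha superposition of two protein structures.

Coordinates are read from PDB-format files (gemmi does the parsing); one
Calpha per residue is kept, choosing the highest-occupancy alternate
location (ties go to altloc 'A').  Residues are paired across structures by
residue number — point mutations are allowed, so residue codes may differ —
and the optimal least-squares rotation comes from the Kabsch algorithm
(SVD with determinant correction), reported with the post-fit RMSD in
angstroms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "CaRecord",
    "CaModel",
    "SuperpositionResult",
    "read_ca",
    "pair_by_residue",
    "kabsch_superpose",
    "superpose_files",
]

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class CaRecord:
    resnum: int
    code: str  # one-letter, 'X' for nonstandard
    xyz: tuple[float, float, float]
    occupancy: float


@dataclass
class CaModel:
    chain: str
    residues: list[CaRecord]

    def __post_init__(self) -> None:
        nums = [r.resnum for r in self.residues]
        if len(set(nums)) != len(nums):
            raise ValueError("duplicate residue numbers in chain")

    def coords(self) -> np.ndarray:
        return np.array([r.xyz for r in self.residues])


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # applied after rotation
    rmsd: float
    n_pairs: int
    paired_residues: list[int]
    unpaired_a: list[int]
    unpaired_b: list[int]

    def to_dict(self) -> dict:
        return {
            "rmsd_A": self.rmsd,
            "n_pairs": self.n_pairs,
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "unpaired_first": self.unpaired_a,
            "unpaired_second": self.unpaired_b,
        }


def read_ca(
    path: str | Path,
    chain: str | None = None,
    min_occupancy: float = 0.0,
) -> CaModel:
    """One Calpha per residue from a PDB file.

    ``chain=None`` takes the first chain of the first model.  Alternate
    locations keep the highest occupancy (ties: altloc 'A'); residues whose
    Calpha occupancy falls below ``min_occupancy`` or that lack a Calpha are
    skipped with a warning.
    """
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models")
    model = st[0]
    if chain is None:
        ch = model[0]
    else:
        ch = model.find_chain(chain)
        if ch is None:
            raise ValueError(f"{path}: no chain {chain!r}")
    residues = []
    skipped = 0
    for res in ch:
        cas = [a for a in res if a.name == "CA" and a.element.name == "C"]
        if not cas:
            if res.name in _THREE_TO_ONE:
                skipped += 1
            continue
        cas.sort(key=lambda a: (-a.occ, a.altloc or "A"))
        ca = cas[0]
        if ca.occ < min_occupancy:
            skipped += 1
            continue
        residues.append(
            CaRecord(
                resnum=res.seqid.num,
                code=_THREE_TO_ONE.get(res.name, "X"),
                xyz=(ca.pos.x, ca.pos.y, ca.pos.z),
                occupancy=ca.occ,
            )
        )
    if not residues:
        raise ValueError(f"{path}: no Calpha atoms found")
    if skipped:
        warnings.warn(
            f"{path}: skipped {skipped} residue(s) without usable Calpha",
            stacklevel=2,
        )
    return CaModel(chain=ch.name, residues=residues)


def pair_by_residue(
    a: CaModel, b: CaModel
) -> tuple[np.ndarray, np.ndarray, list[int], list[int], list[int]]:
    """Pair Calphas on matching residue numbers.

    Returns (coords_a, coords_b, paired numbers, unpaired in a, unpaired
    in b); residue codes are allowed to differ (point mutations).
    """
    in_a = {r.resnum: r for r in a.residues}
    in_b = {r.resnum: r for r in b.residues}
    shared = sorted(set(in_a) & set(in_b))
    if not shared:
        raise ValueError("no residues with matching numbers")
    xa = np.array([in_a[n].xyz for n in shared])
    xb = np.array([in_b[n].xyz for n in shared])
    only_a = sorted(set(in_a) - set(in_b))
    only_b = sorted(set(in_b) - set(in_a))
    return xa, xb, shared, only_a, only_b


def kabsch_superpose(
    xa: np.ndarray,
    xb: np.ndarray,
    paired_residues: list[int] | None = None,
    unpaired_a: list[int] | None = None,
    unpaired_b: list[int] | None = None,
) -> SuperpositionResult:
    """Least-squares rigid superposition of xb onto xa (Kabsch/SVD).

    The returned transform maps a point p of the second set to
    ``rotation @ p + translation``; rmsd is over the transformed pairs.
    """
    xa = np.asarray(xa, dtype=float)
    xb = np.asarray(xb, dtype=float)
    if xa.shape != xb.shape or xa.ndim != 2 or xa.shape[1] != 3:
        raise ValueError("need two equal-length Nx3 coordinate arrays")
    n = len(xa)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    ca = xa.mean(axis=0)
    cb = xb.mean(axis=0)
    A = xa - ca
    B = xb - cb
    if np.linalg.matrix_rank(B, tol=1e-9) < 2 or np.linalg.matrix_rank(A, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) configuration")
    H = B.T @ A
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    moved = (R @ xb.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - xa) ** 2, axis=1))))
    return SuperpositionResult(
        rotation=R,
        translation=t,
        rmsd=rmsd,
        n_pairs=n,
        paired_residues=list(paired_residues or []),
        unpaired_a=list(unpaired_a or []),
        unpaired_b=list(unpaired_b or []),
    )


def superpose_files(
    path_a: str | Path,
    path_b: str | Path,
    chain_a: str | None = None,
    chain_b: str | None = None,
    min_occupancy: float = 0.0,
) -> SuperpositionResult:
    """Read two PDB files, pair Calphas by residue number and superpose."""
    a = read_ca(path_a, chain_a, min_occupancy)
    b = read_ca(path_b, chain_b, min_occupancy)
    xa, xb, shared, only_a, only_b = pair_by_residue(a, b)
    return kabsch_superpose(xa, xb, shared, only_a, only_b)
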
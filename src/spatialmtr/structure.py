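"""Structure models, spherical residue windows, and B-factor painting.

A residue's spatial neighborhood is the set of residues whose C-alpha atoms
lie within a fixed radius of its own C-alpha.  C-alpha is used as the
residue proxy because it is the only atom guaranteed present in every
modeled residue; the boundary is inclusive (distance <= radius) and the
center residue always belongs to its own window.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import gemmi
import numpy as np
from scipy.spatial import cKDTree

from .errors import EmptyModelError, IntegrityError, StructureFormatError

logger = logging.getLogger(__name__)

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: canonical three-letter names, used when writing synthetic models
AA_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "X": "UNK",
}


@dataclass(frozen=True)
class Residue3D:
    """One residue of a structure model.

    Parameters
    ----------
    index : int
        1-based position in the canonical protein sequence.
    aa : str
        One-letter amino acid code, or ``'X'`` for non-standard residues.
    ca_coord : numpy.ndarray
        C-alpha coordinates in Angstrom, shape ``(3,)``.
    plddt : float
        Per-residue confidence on the 0-100 scale (read from the B-factor
        field of the C-alpha atom for AlphaFold-style models).
    """

    index: int
    aa: str
    ca_coord: np.ndarray
    plddt: float

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError(f"residue index must be >= 1, got {self.index}")
        if self.aa not in AA_ALPHABET and self.aa != "X":
            raise ValueError(f"unknown amino acid code {self.aa!r}")
        coord = np.asarray(self.ca_coord, dtype=float)
        if coord.shape != (3,):
            raise ValueError("ca_coord must be a 3-vector")
        object.__setattr__(self, "ca_coord", coord)
        if not 0.0 <= self.plddt <= 100.0:
            raise ValueError(f"plddt {self.plddt} outside [0, 100]")


@dataclass
class ProteinModel:
    """An ordered single-chain structure model."""

    protein_id: str
    residues: list[Residue3D]
    source_path: str = ""

    def __post_init__(self) -> None:
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise IntegrityError(
                f"residue indices not strictly increasing in {self.protein_id}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def indices(self) -> list[int]:
        return [r.index for r in self.residues]

    @property
    def sequence(self) -> str:
        return "".join(r.aa for r in self.residues)

    @property
    def coords(self) -> np.ndarray:
        """C-alpha coordinates as an ``(n, 3)`` array, model order."""
        return np.array([r.ca_coord for r in self.residues], dtype=float)

    @property
    def plddt(self) -> np.ndarray:
        return np.array([r.plddt for r in self.residues], dtype=float)

    def mean_plddt(self) -> float:
        return float(self.plddt.mean())

    def residue(self, index: int) -> Residue3D:
        for r in self.residues:
            if r.index == index:
                return r
        raise KeyError(index)


@dataclass
class WindowIndex:
    """Spherical windows at one radius: center index -> member indices."""

    radius: float
    members: dict[int, frozenset[int]] = field(default_factory=dict)

    def sizes(self) -> list[int]:
        return [len(m) for m in self.members.values()]


_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
}


def _one_letter(name: str) -> str:
    info = gemmi.find_tabulated_residue(name)
    if info is not None:
        code = info.one_letter_code.upper()
        if code in AA_ALPHABET:
            return code
    return "X"


def load_structure(
    path: str | Path,
    format: str | None = None,
    chain: str | None = None,
) -> ProteinModel:
    """Read a PDB or mmCIF file into a :class:`ProteinModel`.

    One chain is selected (``chain`` by name, else the first chain that
    contains a C-alpha atom).  Per-residue confidence (pLDDT) is taken from
    the B-factor of each C-alpha.  Residues without a C-alpha are skipped
    with a warning and take no part in any window.

    Raises
    ------
    StructureFormatError
        If the file cannot be parsed.
    EmptyModelError
        If the selected chain has no C-alpha atoms.
    IntegrityError
        If two residues in the chain share a sequence number.
    """
    path = Path(path)
    if format is not None and format not in _FORMATS:
        raise ValueError(f"format must be one of {sorted(_FORMATS)}")
    try:
        if format is None:
            st = gemmi.read_structure(str(path))
        else:
            st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyModelError(f"{path}: no models in file")
    model = st[0]

    picked = None
    if chain is not None:
        for ch in model:
            if ch.name == chain:
                picked = ch
                break
        if picked is None:
            raise EmptyModelError(f"{path}: chain {chain!r} not found")
    else:
        for ch in model:
            if any(res.find_atom("CA", "*") is not None for res in ch):
                picked = ch
                break
        if picked is None:
            raise EmptyModelError(f"{path}: no chain with C-alpha atoms")

    residues: list[Residue3D] = []
    seen: set[int] = set()
    skipped = 0
    for res in picked:
        ca = res.find_atom("CA", "*")
        if ca is None:
            skipped += 1
            continue
        num = res.seqid.num
        if num in seen:
            raise IntegrityError(
                f"{path}: duplicate residue number {num} in chain {picked.name}"
            )
        seen.add(num)
        residues.append(
            Residue3D(
                index=num,
                aa=_one_letter(res.name),
                ca_coord=np.array([ca.pos.x, ca.pos.y, ca.pos.z]),
                plddt=ca.b_iso,
            )
        )
    if skipped:
        logger.warning(
            "%s: skipped %d residue(s) without C-alpha in chain %s",
            path, skipped, picked.name,
        )
    if not residues:
        raise EmptyModelError(f"{path}: chain {picked.name} has no C-alpha atoms")
    residues.sort(key=lambda r: r.index)
    return ProteinModel(
        protein_id=path.stem, residues=residues, source_path=str(path)
    )


def select_best_model(models: Sequence[ProteinModel]) -> ProteinModel:
    """Pick the model with the highest mean pLDDT (ties: first occurrence).

    All candidate models must share length and sequence — they are expected
    to be alternative predictions of the same protein.
    """
    if not models:
        raise ValueError("no models given")
    ref = models[0]
    for m in models[1:]:
        if len(m) != len(ref) or m.sequence != ref.sequence:
            raise IntegrityError(
                f"model {m.protein_id} sequence differs from {ref.protein_id}"
            )
    means = [m.mean_plddt() for m in models]
    return models[int(np.argmax(means))]


def build_windows(model: ProteinModel, radius: float) -> WindowIndex:
    """Spherical windows: all residues with C-alpha within ``radius`` Angstrom.

    Membership is symmetric and boundary-inclusive; the center residue is
    always a member of its own window.
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if len(model) == 0:
        raise EmptyModelError("empty model")
    coords = model.coords
    idx = model.indices
    tree = cKDTree(coords)
    neighborhoods = tree.query_ball_point(coords, r=radius)
    members = {
        idx[i]: frozenset(idx[j] for j in neigh)
        for i, neigh in enumerate(neighborhoods)
    }
    return WindowIndex(radius=radius, members=members)


def window_size_stats(windows: WindowIndex) -> dict:
    """Mean/median/histogram of the number of residues each window captures."""
    sizes = windows.sizes()
    if not sizes:
        raise ValueError("empty window index")
    hist: dict[int, int] = {}
    for s in sizes:
        hist[s] = hist.get(s, 0) + 1
    return {
        "mean": float(np.mean(sizes)),
        "median": float(np.median(sizes)),
        "histogram": dict(sorted(hist.items())),
    }


def write_model_pdb(model: ProteinModel, path: str | Path) -> None:
    """Write a C-alpha-only PDB file for a (typically synthetic) model."""
    st = gemmi.Structure()
    st.name = model.protein_id
    gm = gemmi.Model("1")
    ch = gemmi.Chain("A")
    for r in model.residues:
        res = gemmi.Residue()
        res.name = AA_THREE.get(r.aa, "UNK")
        res.seqid = gemmi.SeqId(r.index, " ")
        at = gemmi.Atom()
        at.name = "CA"
        at.element = gemmi.Element("C")
        at.pos = gemmi.Position(*r.ca_coord)
        at.occ = 1.0
        at.b_iso = r.plddt
        res.add_atom(at)
        ch.add_residue(res)
    gm.add_chain(ch)
    st.add_model(gm)
    st.setup_entities()
    st.write_pdb(str(path))


INVALID_BFACTOR = 999.99  # out-of-band on both the pLDDT and MTR scales


def paint_pdb(
    in_path: str | Path,
    values: Mapping[int, float],
    out_path: str | Path,
    sentinel: float = INVALID_BFACTOR,
) -> None:
    """Copy a PDB file, substituting a per-residue value into the B-factor
    column (%6.2f) of every atom.

    Residues absent from ``values`` (e.g. with no valid score) are painted
    with ``sentinel``.  Only ATOM/HETATM records are touched.
    """
    out_lines: list[str] = []
    with open(in_path) as fh:
        for line in fh:
            if line.startswith(("ATOM  ", "HETATM")):
                try:
                    resnum = int(line[22:26])
                except ValueError as exc:
                    raise StructureFormatError(
                        f"{in_path}: bad residue number field in {line!r}"
                    ) from exc
                value = values.get(resnum, sentinel)
                if not math.isfinite(value):
                    value = sentinel
                line = line[:60] + f"{value:6.2f}" + line[66:]
            out_lines.append(line)
    with open(out_path, "w") as fh:
        fh.writelines(out_lines)
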
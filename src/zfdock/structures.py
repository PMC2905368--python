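"""Coordinate hierarchy for protein-DNA docking work.

A light chain->residue->atom hierarchy tailored to what restraint design and
model evaluation need: heavy-atom coordinates, 1-based PDB numbering, a
protein/DNA role per chain, and zinc-finger domain annotations.  PDB reading
and writing are delegated to gemmi; this module only converts to and from the
validated in-memory form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "ZincFingerDomain",
    "PDBError",
    "AnnotationError",
    "read_pdb",
    "write_pdb",
    "merge_and_renumber_dna",
    "annotate_zinc_fingers",
]

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V",
}

# PDB v3 deoxynucleotide names plus legacy single-letter forms.
DNA_RESIDUES = {"DA", "DC", "DG", "DT", "A", "C", "G", "T", "ADE", "CYT", "GUA", "THY"}

DNA_ONE_LETTER = {
    "DA": "A", "DC": "C", "DG": "G", "DT": "T",
    "A": "A", "C": "C", "G": "G", "T": "T",
    "ADE": "A", "CYT": "C", "GUA": "G", "THY": "T",
}


class PDBError(ValueError):
    """Unreadable, empty or inconsistent coordinate input."""


class AnnotationError(ValueError):
    """Domain annotation could not satisfy the request."""


@dataclass
class Atom:
    name: str
    element: str
    coords: np.ndarray
    serial: int = 0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise PDBError(f"atom {self.name!r}: coordinates must be a finite 3-vector")
        if not self.name:
            raise PDBError("atom name must be non-empty")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass
class Residue:
    name: str
    seq_id: int
    kind: str  # "protein" | "dna" | "het"
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise KeyError(f"{self.name}{self.seq_id} has no atom {name!r}")

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.heavy_atoms()], dtype=float).reshape(-1, 3)

    @property
    def one_letter(self) -> str:
        if self.kind == "protein":
            return THREE_TO_ONE.get(self.name, "X")
        return DNA_ONE_LETTER.get(self.name, "N")


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)
    role: str = "protein"  # "protein" | "dna"

    def __post_init__(self) -> None:
        self._check()

    def _check(self) -> None:
        ids = [r.seq_id for r in self.residues]
        if len(set(ids)) != len(ids):
            raise PDBError(f"chain {self.id}: duplicate residue seq_ids")
        if ids != sorted(ids):
            self.residues.sort(key=lambda r: r.seq_id)

    def residue(self, seq_id: int) -> Residue:
        for r in self.residues:
            if r.seq_id == seq_id:
                return r
        raise KeyError(f"chain {self.id} has no residue {seq_id}")

    @property
    def sequence(self) -> str:
        return "".join(r.one_letter for r in self.residues if r.kind in ("protein", "dna"))

    def polymer_residues(self) -> list[Residue]:
        return [r for r in self.residues if r.kind in ("protein", "dna")]

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Structure:
    chains: list[Chain] = field(default_factory=list)
    model_id: int = 1
    source: str = ""

    def __post_init__(self) -> None:
        if not self.chains:
            raise PDBError("structure must contain at least one chain")
        ids = [c.id for c in self.chains]
        if len(set(ids)) != len(ids):
            raise PDBError("chain ids must be unique")

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r}")

    def chains_with_role(self, role: str) -> list[Chain]:
        return [c for c in self.chains if c.role == role]

    def iter_atoms(self) -> Iterator[tuple[Chain, Residue, Atom]]:
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield c, r, a

    def heavy_coords(self) -> np.ndarray:
        pts = [a.coords for _, _, a in self.iter_atoms() if a.is_heavy]
        return np.array(pts, dtype=float).reshape(-1, 3)

    def copy(self) -> "Structure":
        chains = [
            Chain(
                id=c.id,
                residues=[
                    Residue(
                        name=r.name,
                        seq_id=r.seq_id,
                        kind=r.kind,
                        atoms=[Atom(a.name, a.element, a.coords.copy(), a.serial) for a in r.atoms],
                    )
                    for r in c.residues
                ],
                role=c.role,
            )
            for c in self.chains
        ]
        return Structure(chains=chains, model_id=self.model_id, source=self.source)

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a rigidly transformed copy (x -> R x + t)."""
        out = self.copy()
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        for _, _, a in out.iter_atoms():
            a.coords = R @ a.coords + t
        return out


@dataclass
class ZincFingerDomain:
    """One Cys2His2 finger: zinc ligands, span, and recognition-helix mapping.

    helix_positions maps the canonical DNA-contacting positions (-1, +1 ... +6,
    counted from the first helix residue = +1) to residue seq_ids.
    """

    index: int
    span: tuple[int, int]
    zn_ligands: tuple[int, int, int, int]
    helix_span: tuple[int, int]
    helix_positions: dict[int, int]

    def __post_init__(self) -> None:
        lo, hi = self.span
        c1, c2, h1, h2 = self.zn_ligands
        if not (lo <= c1 < c2 < h1 < h2 <= hi):
            raise AnnotationError(f"finger {self.index}: zinc ligands must be ordered C,C,H,H within span")
        vals = list(self.helix_positions.values())
        if len(set(vals)) != len(vals):
            raise AnnotationError(f"finger {self.index}: helix position mapping must be injective")

    def contains(self, seq_id: int) -> bool:
        return self.span[0] <= seq_id <= self.span[1]


def _residue_kind(name: str) -> str:
    name = name.strip().upper()
    if name in AMINO_ACIDS:
        return "protein"
    if name in DNA_RESIDUES:
        return "dna"
    return "het"


def _chain_role(residues: list[Residue]) -> str:
    n_prot = sum(1 for r in residues if r.kind == "protein")
    n_dna = sum(1 for r in residues if r.kind == "dna")
    return "dna" if n_dna > n_prot else "protein"


def read_pdb(path: str | Path) -> Structure:
    """Read a PDB file into a Structure (model 1 only).

    Alternate locations collapse to the highest-occupancy conformer (tie: first
    encountered).  HETATM records (e.g. zinc ions) are kept as single-atom
    residues of kind "het".
    """
    path = Path(path)
    if not path.exists():
        raise PDBError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise PDBError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise PDBError(f"{path}: no coordinate records")
    model = st[0]
    chains: list[Chain] = []
    for gchain in model:
        residues: list[Residue] = []
        for gres in gchain:
            # altloc collapse: per atom name keep highest occupancy, tie -> first
            best: dict[str, gemmi.Atom] = {}
            for ga in gres:
                prev = best.get(ga.name)
                if prev is None or ga.occ > prev.occ:
                    best[ga.name] = ga
            atoms = [
                Atom(
                    name=ga.name,
                    element=ga.element.name,
                    coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    serial=ga.serial,
                )
                for ga in best.values()
            ]
            if not atoms:
                continue
            residues.append(
                Residue(name=gres.name.strip(), seq_id=gres.seqid.num, kind=_residue_kind(gres.name), atoms=atoms)
            )
        if residues:
            chains.append(Chain(id=gchain.name, residues=residues, role=_chain_role(residues)))
    if not chains or not any(r.kind != "het" for c in chains for r in c.residues):
        raise PDBError(f"{path}: no ATOM records")
    return Structure(chains=chains, model_id=1, source=str(path))


def write_pdb(s: Structure, path: str | Path) -> Path:
    """Write standard ATOM/HETATM records, preserving residue numbering."""
    for c in s.chains:
        if not c.residues:
            raise PDBError(f"chain {c.id} is empty")
    st = gemmi.Structure()
    st.name = "zfdock"
    model = gemmi.Model("1")
    for c in s.chains:
        gchain = gemmi.Chain(c.id)
        for r in c.residues:
            gres = gemmi.Residue()
            gres.name = r.name
            gres.seqid = gemmi.SeqId(r.seq_id, " ")
            gres.het_flag = "H" if r.kind == "het" else "A"
            for a in r.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = 1.0
                gres.add_atom(ga)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    st.write_pdb(str(path))
    return path


def merge_and_renumber_dna(strand_a: Chain, strand_b: Chain) -> tuple[Chain, dict[tuple[str, int], int]]:
    """Merge two complementary DNA strands into one renumbered chain.

    Residues are renumbered 1..2n: strand A 5'->3' first, then strand B 5'->3'.
    Returns the merged chain and the (old chain id, old seq_id) -> new seq_id map.
    Base i (strand A) pairs base 2n - i + 1 (strand B read 3'->5').
    """
    from .bdna import wc_complement

    for strand in (strand_a, strand_b):
        if strand.role != "dna":
            raise PDBError(f"chain {strand.id} is not a DNA chain")
    a_res = strand_a.polymer_residues()
    b_res = strand_b.polymer_residues()
    if len(a_res) != len(b_res):
        raise PDBError(
            f"strands have unequal lengths ({len(a_res)} vs {len(b_res)})"
        )
    seq_a = "".join(r.one_letter for r in a_res)
    seq_b = "".join(r.one_letter for r in b_res)
    expected = wc_complement(seq_a)
    if seq_b != expected:
        for i, (got, want) in enumerate(zip(seq_b, expected)):
            if got != want:
                raise PDBError(
                    f"strands are not complementary: strand {strand_b.id} position {i + 1} "
                    f"is {got}, expected {want} to pair strand {strand_a.id}"
                )
    mapping: dict[tuple[str, int], int] = {}
    merged: list[Residue] = []
    new_id = 0
    for strand, res_list in ((strand_a, a_res), (strand_b, b_res)):
        for r in res_list:
            new_id += 1
            mapping[(strand.id, r.seq_id)] = new_id
            merged.append(
                Residue(
                    name=r.name,
                    seq_id=new_id,
                    kind="dna",
                    atoms=[Atom(a.name, a.element, a.coords.copy(), a.serial) for a in r.atoms],
                )
            )
    return Chain(id=strand_a.id, residues=merged, role="dna"), mapping


# Cys2His2 motif: C-x(2,4)-C-x(12)-H-x(3,5)-H
_ZF_MOTIF = re.compile(r"C(.{2,4})C(.{12})H(.{3,5})H")

# Offset from the second zinc-ligating Cys to the first recognition-helix
# residue (+1).  +7 places position -1 on the arginine of the RSD motif in
# classical fingers; overridable for unusual architectures.
HELIX_START_OFFSET = 7

# Canonical base-contacting helix positions reported for Cys2His2 fingers.
CANONICAL_POSITIONS = (-1, 1, 2, 3, 5, 6)


def annotate_zinc_fingers(
    chain: Chain,
    min_domains: int = 0,
    helix_start_offset: int = HELIX_START_OFFSET,
) -> list[ZincFingerDomain]:
    """Scan a protein chain for Cys2His2 zinc-finger motifs.

    Fingers are located with the C-x(2,4)-C-x(12)-H-x(3,5)-H pattern and
    returned N->C.  The recognition helix is placed ``helix_start_offset``
    residues after the second Cys; canonical position -1 is the residue
    immediately preceding the helix start.
    """
    if chain.role != "protein":
        raise AnnotationError(f"chain {chain.id} is not a protein chain")
    residues = chain.polymer_residues()
    seq = "".join(r.one_letter for r in residues)
    domains: list[ZincFingerDomain] = []
    pos = 0
    while True:
        m = _ZF_MOTIF.search(seq, pos)
        if m is None:
            break
        i0 = m.start()  # first Cys, 0-based in seq
        c2_off = 1 + len(m.group(1))
        h1_off = c2_off + 1 + len(m.group(2))
        h2_off = h1_off + 1 + len(m.group(3))
        idx = len(domains) + 1
        ids = [r.seq_id for r in residues]
        c1, c2 = ids[i0], ids[i0 + c2_off]
        h1, h2 = ids[i0 + h1_off], ids[i0 + h2_off]
        helix_start_i = i0 + c2_off + helix_start_offset
        helix_end_i = min(i0 + h2_off, len(residues) - 1)
        if helix_start_i >= len(residues):
            pos = m.start() + 1
            continue
        helix_span = (ids[helix_start_i], ids[helix_end_i])
        helix_positions: dict[int, int] = {}
        for p in CANONICAL_POSITIONS:
            j = helix_start_i + (p - 1 if p > 0 else -1)
            if 0 <= j < len(residues):
                helix_positions[p] = ids[j]
        span = (ids[max(i0 - 2, 0)], ids[min(i0 + h2_off + 2, len(residues) - 1)])
        domains.append(
            ZincFingerDomain(
                index=idx,
                span=span,
                zn_ligands=(c1, c2, h1, h2),
                helix_span=helix_span,
                helix_positions=helix_positions,
            )
        )
        pos = m.end()
    if min_domains and len(domains) < min_domains:
        raise AnnotationError(
            f"found {len(domains)} Cys2His2 motifs, {min_domains} requested; "
            f"scan of {len(seq)}-residue sequence with pattern {_ZF_MOTIF.pattern}"
        )
    return domains


def structure_from_chains(chains: Iterable[Chain], source: str = "") -> Structure:
    return Structure(chains=list(chains), source=source)
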
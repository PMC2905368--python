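"""Ambiguous interaction restraints (AIRs) for protein-DNA docking.

An AIR ties one active protein residue to one or more DNA bases (plus, in
non-pairwise mode, solvent-exposed neighbour residues/bases) through an
effective distance with an upper bound, typically 2 Angstrom.  The effective
distance aggregates every heavy-atom cross pair with an r^-6 sum,

    d_eff = ( sum_mn d_mn^-6 )^(-1/6)

so that a single close atom pair satisfies the restraint; d_eff never exceeds
the minimum pairwise distance.  Violations are penalised with a flat-bottom
harmonic, E_AIR = k * sum_i max(0, d_eff,i - bound_i)^2.

Restraint sets are grouped per zinc-finger domain and written to a CNS-style
``assign`` restraint table consumed by data-driven docking engines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .structures import Atom, Chain, Structure, ZincFingerDomain

__all__ = [
    "AIR",
    "AIRSet",
    "EffectiveDistance",
    "RestraintError",
    "build_pairwise_airs",
    "select_two_per_domain",
    "expand_non_pairwise",
    "write_tbl",
    "read_tbl",
    "effective_distance",
    "air_energy",
]

DEFAULT_UPPER_BOUND = 2.0  # Angstrom
DEFAULT_FORCE_CONSTANT = 50.0  # kcal mol^-1 A^-2


class RestraintError(ValueError):
    pass


@dataclass(frozen=True)
class AIR:
    domain_index: int
    active_protein: int
    active_dna: tuple[int, ...]
    passive_protein: frozenset[int] = frozenset()
    passive_dna: frozenset[int] = frozenset()
    upper_bound: float = DEFAULT_UPPER_BOUND

    def __post_init__(self) -> None:
        if not self.active_dna:
            raise RestraintError("AIR needs at least one active DNA base")
        if self.upper_bound <= 0:
            raise RestraintError("upper bound must be positive")
        if self.active_protein in self.passive_protein or set(self.active_dna) & self.passive_dna:
            raise RestraintError("passive selections must be disjoint from active ones")


@dataclass
class AIRSet:
    airs: list[AIR] = field(default_factory=list)
    mode: str = "pairwise"  # "pairwise" | "non-pairwise"
    label: str = ""

    def __post_init__(self) -> None:
        if self.mode == "pairwise":
            for a in self.airs:
                if len(a.active_dna) != 1 or a.passive_protein or a.passive_dna:
                    raise RestraintError(
                        "pairwise mode requires exactly one active base and empty passive sets"
                    )

    def __len__(self) -> int:
        return len(self.airs)

    def per_domain_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for a in self.airs:
            counts[a.domain_index] = counts.get(a.domain_index, 0) + 1
        return dict(sorted(counts.items()))

    def __add__(self, other: "AIRSet") -> "AIRSet":
        mode = self.mode if self.mode == other.mode else "non-pairwise"
        return AIRSet(airs=self.airs + other.airs, mode=mode, label=f"{self.label}+{other.label}")


@dataclass(frozen=True)
class EffectiveDistance:
    value: float
    n_pairs: int


def build_pairwise_airs(
    pairs: Iterable[tuple[int, int, int]],
    bound: float = DEFAULT_UPPER_BOUND,
    label: str = "",
) -> AIRSet:
    """One pairwise AIR per (domain_index, protein seq_id, base seq_id) triple.

    Duplicate bases across entries are legitimate (a base may partner several
    residues); entries are kept positionally.
    """
    airs = [
        AIR(domain_index=d, active_protein=p, active_dna=(b,), upper_bound=bound)
        for d, p, b in pairs
    ]
    return AIRSet(airs=airs, mode="pairwise", label=label)


def select_two_per_domain(
    interactions: Iterable[tuple[int, int, int]],
    domains: Sequence[ZincFingerDomain],
    bound: float = DEFAULT_UPPER_BOUND,
) -> AIRSet:
    """Pick two pairwise AIRs per finger: one at each end of the recognition helix.

    Candidates are split at the helix midpoint; within the N-terminal half the
    residue closest to helix position -1 is taken, within the C-terminal half
    the residue closest to position +6 (ties break toward the smaller seq_id).
    A domain whose candidates all sit on one half of the helix cannot anchor
    both helix ends and raises, instructing the user to supply another
    candidate pair.
    """
    by_domain: dict[int, list[tuple[int, int]]] = {}
    for d, p, b in interactions:
        by_domain.setdefault(d, []).append((p, b))
    chosen: list[AIR] = []
    for dom in domains:
        cands = by_domain.get(dom.index, [])
        if not cands:
            raise RestraintError(f"finger {dom.index}: no candidate interactions")
        n_anchor = dom.helix_positions.get(-1, dom.helix_span[0] - 1)
        c_anchor = dom.helix_positions.get(6, dom.helix_span[1])
        mid = (n_anchor + c_anchor) / 2.0
        n_half = [c for c in cands if c[0] <= mid]
        c_half = [c for c in cands if c[0] > mid]
        if not n_half or not c_half:
            raise RestraintError(
                f"finger {dom.index}: all candidates fall on one half of the recognition "
                f"helix; choose another AIR pair covering both helix ends"
            )
        pick_n = min(n_half, key=lambda c: (abs(c[0] - n_anchor), c[0]))
        pick_c = min(c_half, key=lambda c: (abs(c[0] - c_anchor), c[0]))
        for p, b in (pick_n, pick_c):
            chosen.append(AIR(domain_index=dom.index, active_protein=p, active_dna=(b,), upper_bound=bound))
    return AIRSet(airs=chosen, mode="pairwise", label="two-per-domain")


def expand_non_pairwise(
    pairs: Iterable[tuple[int, int, int]],
    protein: Structure,
    dna: Structure,
    sasa_threshold: float = 0.15,
    neighbor_cutoff: float = 6.5,
    bound: float = DEFAULT_UPPER_BOUND,
    label: str = "non-pairwise",
) -> AIRSet:
    """Expand active pairs with passive surface neighbours.

    Passive residues/bases are those within ``neighbor_cutoff`` (heavy-atom
    minimum distance) of an active residue/base of the same molecule and with
    relative solvent accessibility >= ``sasa_threshold``.  Each AIR keeps its
    active protein residue and gains the passive bases neighbouring its active
    bases; passive protein neighbours are recorded on the AIR for restraint
    bookkeeping in the inverse direction.
    """
    from .modeleval import relative_sasa

    pairs = list(pairs)
    if not pairs:
        return AIRSet(airs=[], mode="non-pairwise", label=label)
    prot_chain = protein.chains_with_role("protein")[0]
    dna_chain = dna.chains_with_role("dna")[0]
    rel_prot = relative_sasa(protein)
    rel_dna = relative_sasa(dna)

    def _neighbors(chain: Chain, active_ids: set[int], rel: dict[int, float]) -> frozenset[int]:
        active_coords = np.vstack(
            [chain.residue(i).heavy_coords() for i in active_ids]
        )
        out = set()
        for r in chain.polymer_residues():
            if r.seq_id in active_ids:
                continue
            if rel.get(r.seq_id, 0.0) < sasa_threshold:
                continue
            d = np.linalg.norm(r.heavy_coords()[:, None, :] - active_coords[None, :, :], axis=-1)
            if d.min() <= neighbor_cutoff:
                out.add(r.seq_id)
        return frozenset(out)

    active_prot = {p for _, p, _ in pairs}
    active_dna = {b for _, _, b in pairs}
    passive_prot = _neighbors(prot_chain, active_prot, rel_prot)
    passive_dna = _neighbors(dna_chain, active_dna, rel_dna)
    airs = [
        AIR(
            domain_index=d,
            active_protein=p,
            active_dna=(b,),
            passive_protein=passive_prot,
            passive_dna=passive_dna,
            upper_bound=bound,
        )
        for d, p, b in pairs
    ]
    return AIRSet(airs=airs, mode="non-pairwise", label=label)


def _fmt_selection(segid: str, resids: Sequence[int]) -> str:
    if len(resids) == 1:
        return f"(segid {segid} and resid {resids[0]})"
    inner = " or ".join(f"(segid {segid} and resid {r})" for r in resids)
    return f"({inner})"


def write_tbl(
    air_set: AIRSet,
    path: str | Path,
    protein_segid: str = "A",
    dna_segid: str = "B",
) -> Path:
    """Write a CNS/HADDOCK-style ``assign`` restraint table.

    The distance triple encodes the upper bound u as ``u u 0.0`` (target u,
    minus u, plus 0): only separations beyond the bound are penalised.  Output
    is byte-stable for a fixed AIRSet.
    """
    path = Path(path)
    lines = [f"! zfdock AIR restraints label={air_set.label or '-'} mode={air_set.mode}"]
    for a in air_set.airs:
        dna_ids = sorted(set(a.active_dna) | a.passive_dna)
        sel_p = _fmt_selection(protein_segid, [a.active_protein])
        sel_d = _fmt_selection(dna_segid, dna_ids)
        comment = (
            f"! finger={a.domain_index} "
            f"active_dna={','.join(str(b) for b in a.active_dna)}"
        )
        if a.passive_protein:
            comment += f" passive_prot={','.join(str(p) for p in sorted(a.passive_protein))}"
        lines.append(
            f"assign {sel_p} {sel_d} {a.upper_bound:.1f} {a.upper_bound:.1f} 0.0 {comment}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


_BALANCED = r"\((?:[^()]|\([^()]*\))*\)"
_ASSIGN_RE = re.compile(
    rf"assign\s+(?P<selp>{_BALANCED})\s+(?P<seld>{_BALANCED})\s+"
    r"(?P<d>[\d.]+)\s+(?P<dminus>[\d.]+)\s+(?P<dplus>[\d.]+)\s*"
    r"!\s*finger=(?P<finger>\d+)\s+active_dna=(?P<act>[\d,]+)"
    r"(?:\s+passive_prot=(?P<pasp>[\d,]+))?"
)


def read_tbl(path: str | Path) -> AIRSet:
    """Parse a restraint table written by :func:`write_tbl` (inverse round-trip)."""
    text = Path(path).read_text()
    header = text.splitlines()[0] if text else ""
    m = re.search(r"label=(\S+)\s+mode=(\S+)", header)
    label = m.group(1) if m else "-"
    mode = m.group(2) if m else "pairwise"
    if label == "-":
        label = ""
    airs = []
    for am in _ASSIGN_RE.finditer(text):
        resid_p = [int(x) for x in re.findall(r"resid\s+(\d+)", am.group("selp"))]
        resid_d = [int(x) for x in re.findall(r"resid\s+(\d+)", am.group("seld"))]
        active_dna = tuple(int(x) for x in am.group("act").split(","))
        passive_dna = frozenset(resid_d) - set(active_dna)
        pasp = am.group("pasp")
        passive_prot = frozenset(int(x) for x in pasp.split(",")) if pasp else frozenset()
        airs.append(
            AIR(
                domain_index=int(am.group("finger")),
                active_protein=resid_p[0],
                active_dna=active_dna,
                passive_protein=passive_prot,
                passive_dna=passive_dna,
                upper_bound=float(am.group("d")),
            )
        )
    if not airs and "assign" in text:
        raise RestraintError(f"{path}: assign records present but none parsable")
    return AIRSet(airs=airs, mode=mode, label=label)


def effective_distance(
    atoms_a: Sequence[Atom] | np.ndarray,
    atoms_b: Sequence[Atom] | np.ndarray,
    exponent: float = 6.0,
) -> EffectiveDistance:
    """r^-6-summed effective distance between two atom sets.

    Always bounded above by the minimum pairwise distance; the exponent is
    configurable for sensitivity checks but defaults to the conventional 6.
    """
    def _coords(atoms) -> np.ndarray:
        if isinstance(atoms, np.ndarray):
            return np.asarray(atoms, dtype=float)
        atoms = list(atoms)
        if atoms and isinstance(atoms[0], Atom):
            return np.array([a.coords for a in atoms], dtype=float)
        return np.asarray(atoms, dtype=float)

    xa = _coords(atoms_a)
    xb = _coords(atoms_b)
    if xa.size == 0 or xb.size == 0:
        raise RestraintError("both atom sets must be non-empty")
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
    if np.any(d == 0.0):
        raise RestraintError("coincident atoms (zero distance) in effective-distance sum")
    value = float(np.sum(d ** (-exponent)) ** (-1.0 / exponent))
    return EffectiveDistance(value=value, n_pairs=int(d.size))


def air_energy(
    air_set: AIRSet,
    model: Structure,
    k: float = DEFAULT_FORCE_CONSTANT,
) -> tuple[float, list[dict]]:
    """Flat-bottom harmonic restraint energy of a model, with per-AIR violations.

    Returns (E_AIR, records); each record carries the AIR identity, its
    effective distance and the violation delta = max(0, d_eff - bound).
    E_AIR = k * sum delta^2, additive over AIRs.
    """
    prot_chains = model.chains_with_role("protein")
    dna_chains = model.chains_with_role("dna")
    if not prot_chains or not dna_chains:
        raise RestraintError("model must contain one protein and one DNA chain")
    prot, dna = prot_chains[0], dna_chains[0]
    total = 0.0
    records = []
    for a in air_set.airs:
        try:
            atoms_p = prot.residue(a.active_protein).heavy_atoms()
            dna_ids = sorted(set(a.active_dna) | a.passive_dna)
            atoms_d = [at for b in dna_ids for at in dna.residue(b).heavy_atoms()]
        except KeyError as exc:
            raise RestraintError(
                f"AIR finger {a.domain_index} residue {a.active_protein} -> bases "
                f"{a.active_dna}: {exc}"
            ) from exc
        eff = effective_distance(atoms_p, atoms_d)
        delta = max(0.0, eff.value - a.upper_bound)
        total += k * delta**2
        records.append(
            {
                "domain_index": a.domain_index,
                "protein_res": a.active_protein,
                "dna_bases": a.active_dna,
                "d_eff": eff.value,
                "violation": delta,
            }
        )
    return total, records
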
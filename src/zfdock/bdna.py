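"""Canonical (fiber-style) B-DNA duplex construction.

A duplex is assembled by placing ideal heavy-atom nucleotide templates into a
base-pair reference frame and propagating that frame along the global z axis
with a fixed helical twist and rise.  The frame is chosen so that the midpoint
of the paired C1' atoms lies exactly on the construction axis, which makes z
the exact helical axis of every duplex built here — convenient both for
restraint-geometry analysis and for validating the axis-fitting code against
a known ground truth.

Template coordinates come from the chemical-component dictionary bundled with
biotite (ideal geometry, heavy atoms only); sugar pucker is whatever the ideal
component carries, and no sequence-dependent step parameters are applied: the
product is deliberately canonical, not a deformed-DNA model.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .structures import Atom, Chain, Residue, Structure, merge_and_renumber_dna

__all__ = [
    "FiberParameters",
    "wc_complement",
    "build_bdna_duplex",
    "measure_step_parameters",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Glycosidic nitrogen and ring atoms per base type.
_GLYCOSIDIC = {"A": "N9", "G": "N9", "C": "N1", "T": "N1"}
_RING = {
    "A": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "G": ["N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"],
    "C": ["N1", "C2", "N3", "C4", "C5", "C6"],
    "T": ["N1", "C2", "N3", "C4", "C5", "C6"],
}
# Watson-Crick central hydrogen-bond atoms (purine N1 ... pyrimidine N3).
_WC_ATOM = {"A": "N1", "G": "N1", "C": "N3", "T": "N3"}

# Base-pair frame targets; strand 2 is generated by the dyad (x, -y, -z).
# C1' of strand 1 sits exactly here, so the paired-C1' midpoint is the frame
# origin and the construction axis (z) is the exact helix axis.
_C1_TARGET = np.array([0.0, 5.346, 0.0])
# Approximate in-plane targets for the central Watson-Crick hydrogen-bond
# atoms (purine N1, pyrimidine N3); fine placement is calibrated numerically.
_WC_TARGET = {
    "A": np.array([1.811, 0.532, 0.0]),
    "G": np.array([1.811, 0.532, 0.0]),
    "C": np.array([1.811, 2.368, 0.0]),
    "T": np.array([1.811, 2.368, 0.0]),
}


@dataclass(frozen=True)
class FiberParameters:
    """Helical parameters of the canonical build.

    twist: degrees of right-handed rotation per base-pair step.
    rise:  axial translation per step, in Angstrom.
    """

    twist: float = 36.0
    rise: float = 3.38
    template_set: str = "ccd-ideal"

    def __post_init__(self) -> None:
        if not 0.0 < self.twist < 60.0:
            raise ValueError(f"twist {self.twist} out of range (0, 60) degrees")
        if not 2.0 < self.rise < 5.0:
            raise ValueError(f"rise {self.rise} out of range (2, 5) Angstrom")


def wc_complement(seq: str) -> str:
    """Reverse complement (5'->3') of a DNA sequence."""
    seq = seq.upper()
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"non-ACGT characters in sequence: {sorted(bad)}")
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


@lru_cache(maxsize=None)
def _ccd_nucleotide(base: str) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Ideal heavy-atom nucleotide (names, elements, coords) for base A/C/G/T."""
    import biotite.structure.info as info

    res = info.residue("D" + base)
    keep = (res.element != "H") & (res.atom_name != "OP3")
    names = tuple(res.atom_name[keep])
    elements = tuple(res.element[keep])
    coords = np.array(res.coord[keep], dtype=float)
    return names, elements, coords


def _place_in_pair_frame(base: str, flip: bool) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Rigidly place an ideal nucleotide so C1' hits the frame target.

    The base plane is aligned with z = 0; ``flip`` selects which face points
    along +z.
    """
    names, elements, coords = _ccd_nucleotide(base)
    name_idx = {n: i for i, n in enumerate(names)}
    c1 = coords[name_idx["C1'"]]
    wc = coords[name_idx[_WC_ATOM[base]]]
    ring = coords[[name_idx[a] for a in _RING[base]]]
    # source frame: C1' -> WC-edge direction + ring normal
    e1 = wc - c1
    e1 /= np.linalg.norm(e1)
    centered = ring - ring.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    n = vt[2]
    if flip:
        n = -n
    e3 = n - (n @ e1) * e1
    e3 /= np.linalg.norm(e3)
    e2 = np.cross(e3, e1)
    src = np.stack([e1, e2, e3], axis=1)
    # target frame: WC edge toward its nominal spot, base plane in z = 0
    t1 = _WC_TARGET[base] - _C1_TARGET
    t1 = t1 / np.linalg.norm(t1)
    t3 = np.array([0.0, 0.0, 1.0])
    t3 = t3 - (t3 @ t1) * t1
    t3 /= np.linalg.norm(t3)
    t2 = np.cross(t3, t1)
    tgt = np.stack([t1, t2, t3], axis=1)
    rot = tgt @ src.T
    placed = (coords - c1) @ rot.T + _C1_TARGET
    return names, elements, placed


_DYAD = np.diag([1.0, -1.0, -1.0])


def _base_atom_idx(names: tuple[str, ...], base: str) -> list[int]:
    ring_and_subs = set(_RING[base]) | {"N1", "C2", "N3", "C4", "C5", "C6", "N7", "C8", "N9",
                                        "O2", "N2", "O4", "N4", "O6", "N6", "C7"}
    return [i for i, n in enumerate(names) if n in ring_and_subs]


def _rot_inplane(coords: np.ndarray, pivot: np.ndarray, deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return (coords - pivot) @ R.T + pivot


@lru_cache(maxsize=None)
def _pair_templates() -> dict[str, tuple[tuple[str, ...], tuple[str, ...], np.ndarray]]:
    """Base templates in the pair frame, pairing geometry calibrated.

    For each Watson-Crick pair: (1) the face of each partner (ring-normal
    sign) and (2) a small in-plane rotation of each base about its fixed C1'
    are chosen deterministically so that, after the pyrimidine partner is
    dyad-transformed, the central hydrogen-bond atoms (purine N1, pyrimidine
    N3) meet at ~2.9 A without steric overlap of the two bases.  C1' stays
    exactly on its frame target throughout.
    """
    templates: dict[str, tuple[tuple[str, ...], tuple[str, ...], np.ndarray]] = {}
    grid = np.arange(-25.0, 25.01, 1.0)
    for pu, py in (("A", "T"), ("G", "C")):
        best = None
        for flip_pu in (False, True):
            for flip_py in (False, True):
                tp = _place_in_pair_frame(pu, flip_pu)
                tq = _place_in_pair_frame(py, flip_py)
                ip = tp[0].index(_WC_ATOM[pu])
                iq = tq[0].index(_WC_ATOM[py])
                base_p = _base_atom_idx(tp[0], pu)
                base_q = _base_atom_idx(tq[0], py)
                for a_pu in grid:
                    cp = _rot_inplane(tp[2], _C1_TARGET, a_pu)
                    for a_py in grid:
                        cq = _rot_inplane(tq[2], _C1_TARGET, a_py)
                        cq_d = cq @ _DYAD.T
                        hb = np.linalg.norm(cp[ip] - cq_d[iq])
                        dmat = np.linalg.norm(
                            cp[base_p][:, None, :] - cq_d[base_q][None, :, :], axis=-1
                        )
                        clash = np.maximum(0.0, 2.7 - dmat).sum()
                        score = (hb - 2.9) ** 2 + 10.0 * clash**2 + 1e-4 * (a_pu**2 + a_py**2)
                        if best is None or score < best[0]:
                            best = (score, (tp[0], tp[1], cp), (tq[0], tq[1], cq))
        assert best is not None
        templates[pu] = _calibrate_backbone(best[1], pu)
        templates[py] = _calibrate_backbone(best[2], py)
    return templates


def _calibrate_backbone(
    template: tuple[tuple[str, ...], tuple[str, ...], np.ndarray], base: str
) -> tuple[tuple[str, ...], tuple[str, ...], np.ndarray]:
    """Set the glycosidic torsion so the backbone tracks the helix.

    The sugar-phosphate moiety is rotated about the C1'->glycosidic-N bond
    (base and C1' fixed) to bring O3' of one step close to P of the next
    (bonded continuity ~1.6 A) without steric overlap between stacked
    nucleotides.  Purely geometric, deterministic grid search.
    """
    names, elements, coords = template
    idx = {n: i for i, n in enumerate(names)}
    c1 = coords[idx["C1'"]]
    axis = coords[idx[_GLYCOSIDIC[base]]] - c1
    axis = axis / np.linalg.norm(axis)
    base_atoms = set(_base_atom_idx(names, base))
    backbone = [i for i in range(len(names)) if i not in base_atoms and names[i] != "C1'"]
    step_rot = _rot_z(36.0)
    step_t = np.array([0.0, 0.0, 3.38])
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    best = None
    for beta in np.arange(0.0, 360.0, 2.0):
        th = np.deg2rad(beta)
        R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
        trial = coords.copy()
        trial[backbone] = (coords[backbone] - c1) @ R.T + c1
        nxt = trial @ step_rot.T + step_t
        d_o3p = np.linalg.norm(trial[idx["O3'"]] - nxt[idx["P"]])
        dmat = np.linalg.norm(trial[:, None, :] - nxt[None, :, :], axis=-1)
        dmat[idx["O3'"], idx["P"]] = np.inf  # the bonded pair
        clash = np.maximum(0.0, 2.2 - dmat).sum()
        score = (d_o3p - 1.6) ** 2 + 10.0 * clash**2
        if best is None or score < best[0]:
            best = (score, trial)
    assert best is not None
    return names, elements, best[1]


def _rot_z(deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def build_bdna_duplex(
    seq: str,
    params: FiberParameters | None = None,
    chain_id: str = "D",
) -> Structure:
    """Build an all-heavy-atom canonical B-DNA duplex from a sequence.

    Strand 1 carries ``seq`` 5'->3'; strand 2 is its Watson-Crick complement.
    The two strands are merged into a single chain renumbered 1..2n (strand 1
    first, then strand 2 5'->3'), so base i pairs base 2n - i + 1.  The
    helical axis of construction is the global z axis.
    """
    params = params or FiberParameters()
    seq = seq.upper()
    comp = wc_complement(seq)  # 5'->3' of strand 2
    n = len(seq)
    if n < 2:
        raise ValueError("duplex needs at least 2 base pairs")
    templates = _pair_templates()

    def _residues(bases: str, steps: list[int], dyad: bool) -> list[Residue]:
        out = []
        for local_i, (base, step) in enumerate(zip(bases, steps), start=1):
            names, elements, coords = templates[base]
            xyz = coords @ _DYAD.T if dyad else coords
            rot = _rot_z(step * params.twist)
            xyz = xyz @ rot.T + np.array([0.0, 0.0, step * params.rise])
            atoms = [Atom(nm, el, c) for nm, el, c in zip(names, elements, xyz)]
            out.append(Residue(name="D" + base, seq_id=local_i, kind="dna", atoms=atoms))
        return out

    strand1 = Chain(id="X", residues=_residues(seq, list(range(n)), dyad=False), role="dna")
    # strand 2 residue j (5'->3') pairs strand 1 residue n-1-j, hence sits at that step
    strand2 = Chain(id="Y", residues=_residues(comp, [n - 1 - j for j in range(n)], dyad=True), role="dna")
    merged, _ = merge_and_renumber_dna(strand1, strand2)
    merged.id = chain_id
    return Structure(chains=[merged], source=f"bdna:{seq}")


def duplex_pairing(chain: Chain) -> list[tuple[Residue, Residue]]:
    """Base pairs of a merged duplex chain (i pairs 2n - i + 1), validated."""
    res = chain.polymer_residues()
    if len(res) % 2:
        raise ValueError(f"chain {chain.id}: odd residue count {len(res)}, not a merged duplex")
    n = len(res) // 2
    pairs = []
    for i in range(n):
        a, b = res[i], res[2 * n - 1 - i]
        if _COMPLEMENT.get(a.one_letter) != b.one_letter:
            raise ValueError(
                f"bases {a.name}{a.seq_id} and {b.name}{b.seq_id} are not Watson-Crick complementary"
            )
        pairs.append((a, b))
    return pairs


def measure_step_parameters(duplex: Structure) -> pd.DataFrame:
    """Per-step helical twist and rise of a merged duplex.

    Rise is the axial separation of successive paired-C1' midpoints along the
    least-squares helix axis; twist is the rotation of the C1'-C1' vector
    about that axis.  A step whose rise exceeds 1.5x the median is flagged as
    a gap.
    """
    from .axisgeom import fit_helix_axis

    dna_chains = duplex.chains_with_role("dna")
    if len(dna_chains) != 1:
        raise ValueError("expected exactly one merged DNA chain")
    pairs = duplex_pairing(dna_chains[0])
    axis = fit_helix_axis(duplex)
    d = axis.direction
    mids, vecs = [], []
    for a, b in pairs:
        ca, cb = a.atom("C1'").coords, b.atom("C1'").coords
        mids.append((ca + cb) / 2.0)
        vecs.append(cb - ca)
    rows = []
    for i in range(len(pairs) - 1):
        rise = float((mids[i + 1] - mids[i]) @ d)
        u = vecs[i] - (vecs[i] @ d) * d
        v = vecs[i + 1] - (vecs[i + 1] @ d) * d
        cosang = (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
        sinang = np.cross(u, v) @ d / (np.linalg.norm(u) * np.linalg.norm(v))
        twist = float(np.degrees(np.arctan2(sinang, cosang)))
        rows.append({"step": i + 1, "twist": twist, "rise": rise})
    table = pd.DataFrame(rows)
    med = table["rise"].abs().median()
    table["gap"] = table["rise"].abs() > 1.5 * med
    return table
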
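"""Evaluation of docked protein-DNA complex models.

Implements the standard post-docking quality measures for a zinc-finger-DNA
ensemble: residue-nucleotide contact enumeration (5 A heavy-atom criterion),
fraction of native contacts (F_nat), interface RMSD after least-squares
superposition, solvent-accessible and buried surface area, wrap-around
classification about the DNA helix axis, docking-score parsing/re-ranking,
and the score-versus-restraint-energy population table.

Everything operates on heavy atoms; hydrogens and heteroatoms (zinc ions) are
excluded from every metric.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import re

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .axisgeom import HelixAxis, circular_span
from .structures import Residue, Structure, ZincFingerDomain

__all__ = [
    "ContactSet",
    "ScoreRecord",
    "EvaluationReport",
    "WrapConfig",
    "enumerate_contacts",
    "fnat",
    "kabsch_superpose",
    "irmsd",
    "sasa",
    "relative_sasa",
    "bsa",
    "classify_wrap_around",
    "parse_haddock_scores",
    "rescore_and_rank",
    "population_table",
]

CONTACT_CUTOFF = 5.0  # Angstrom, heavy-atom residue-nucleotide contact criterion

# Heavy-atom van der Waals radii (Angstrom) used for surface areas.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80}
PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960

# Docking-score component weights used for re-ranking when no pre-computed
# score is available (water-refinement stage convention; BSA unweighted).
DEFAULT_SCORE_WEIGHTS = {"e_vdw": 0.2, "e_elec": 1.0, "e_desolv": 1.0, "e_air": 0.1, "bsa": 0.0}


@dataclass(frozen=True)
class ContactSet:
    pairs: frozenset[tuple[int, int]]  # (protein seq_id, dna seq_id)
    cutoff: float = CONTACT_CUTOFF

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class ScoreRecord:
    model_id: str
    e_elec: float | None = None
    e_vdw: float | None = None
    e_desolv: float | None = None
    e_air: float | None = None
    bsa: float | None = None
    haddock_score: float | None = None
    source: str = "parsed"

    @property
    def e_inter(self) -> float | None:
        if self.e_elec is None or self.e_vdw is None:
            return None
        return self.e_elec + self.e_vdw


@dataclass
class EvaluationReport:
    model_id: str
    wrap_around: bool
    coverage: float
    e_air: float
    fnat: float | None = None
    irmsd: float | None = None
    bsa: float | None = None
    rank: int | None = None


@dataclass
class WrapConfig:
    min_coverage: float = 180.0  # deg of azimuth the interface must span
    gap_tol: float = 120.0  # azimuthal gaps smaller than this are bridged
    contact_cutoff: float = CONTACT_CUTOFF


def _split_complex(model: Structure) -> tuple:
    prot = model.chains_with_role("protein")
    dna = model.chains_with_role("dna")
    if len(prot) != 1 or len(dna) != 1:
        raise ValueError(
            f"expected exactly one protein and one DNA chain, found "
            f"{len(prot)} protein / {len(dna)} DNA"
        )
    return prot[0], dna[0]


def _heavy_atom_table(chain) -> tuple[np.ndarray, np.ndarray]:
    """(coords, residue seq_ids) over heavy atoms of polymer residues."""
    coords, ids = [], []
    for r in chain.polymer_residues():
        for a in r.heavy_atoms():
            coords.append(a.coords)
            ids.append(r.seq_id)
    return np.array(coords, dtype=float).reshape(-1, 3), np.array(ids, dtype=int)


def enumerate_contacts(model: Structure, cutoff: float = CONTACT_CUTOFF) -> ContactSet:
    """Residue-nucleotide pairs with any heavy-atom cross distance <= cutoff."""
    prot, dna = _split_complex(model)
    xp, idp = _heavy_atom_table(prot)
    xd, idd = _heavy_atom_table(dna)
    if len(xp) == 0 or len(xd) == 0:
        return ContactSet(pairs=frozenset(), cutoff=cutoff)
    tree = cKDTree(xd)
    pairs = set()
    hits = tree.query_ball_point(xp, cutoff)
    for ip, neigh in enumerate(hits):
        for jd in neigh:
            pairs.add((int(idp[ip]), int(idd[jd])))
    return ContactSet(pairs=frozenset(pairs), cutoff=cutoff)


def fnat(model: Structure, reference: Structure, cutoff: float = CONTACT_CUTOFF) -> float:
    """Fraction of the reference's residue-nucleotide contacts present in the model."""
    native = enumerate_contacts(reference, cutoff)
    if len(native) == 0:
        raise ValueError("reference structure has no protein-DNA contacts; F_nat undefined")
    found = enumerate_contacts(model, cutoff)
    return len(native.pairs & found.pairs) / len(native)


def kabsch_superpose(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of A onto B.

    Returns (R, t, rmsd) with R a proper rotation (det = +1) minimising
    ||R a + t - b||; the McLachlan and Kabsch solutions coincide.
    """
    A = np.asarray(coords_a, dtype=float)
    B = np.asarray(coords_b, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must be matched (n, 3) arrays")
    if len(A) < 3:
        raise ValueError("need at least 3 points for superposition")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    if S[1] < 1e-10:
        raise ValueError("degenerate (collinear) point set; superposition ill-defined")
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cb - R @ ca
    diff = (A - ca) @ R.T - (B - cb)
    rmsd = float(np.sqrt(np.mean(np.sum(diff**2, axis=-1))))
    return R, t, rmsd


def _interface_residues(reference: Structure, cutoff: float) -> set[tuple[str, int]]:
    prot, dna = _split_complex(reference)
    xp, idp = _heavy_atom_table(prot)
    xd, idd = _heavy_atom_table(dna)
    tree_d = cKDTree(xd)
    tree_p = cKDTree(xp)
    iface: set[tuple[str, int]] = set()
    for ip, neigh in enumerate(tree_d.query_ball_point(xp, cutoff)):
        if neigh:
            iface.add(("protein", int(idp[ip])))
            for jd in neigh:
                iface.add(("dna", int(idd[jd])))
    return iface


def irmsd(
    model: Structure,
    reference: Structure,
    interface_cutoff: float = 10.0,
) -> float:
    """Heavy-atom interface RMSD of a model against the reference complex.

    Interface residues/nucleotides are taken from the reference (any heavy
    atom within ``interface_cutoff`` of the partner molecule); the shared
    heavy atoms are superposed and the RMSD reported.
    """
    iface = _interface_residues(reference, interface_cutoff)
    if not iface:
        raise ValueError("reference has an empty interface at this cutoff")
    ref_prot, ref_dna = _split_complex(reference)
    mod_prot, mod_dna = _split_complex(model)
    ref_xyz, mod_xyz = [], []
    for role, seq_id in sorted(iface):
        ref_chain = ref_prot if role == "protein" else ref_dna
        mod_chain = mod_prot if role == "protein" else mod_dna
        try:
            mres = mod_chain.residue(seq_id)
        except KeyError:
            continue
        rres = ref_chain.residue(seq_id)
        mod_atoms = {a.name: a for a in mres.heavy_atoms()}
        for a in rres.heavy_atoms():
            if a.name in mod_atoms:
                ref_xyz.append(a.coords)
                mod_xyz.append(mod_atoms[a.name].coords)
    if len(ref_xyz) < 3:
        raise ValueError("fewer than 3 shared interface heavy atoms")
    _, _, rmsd = kabsch_superpose(np.array(mod_xyz), np.array(ref_xyz))
    return rmsd


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)], axis=1
    )


def _sasa_atoms(
    coords: np.ndarray, elements: list[str], probe: float, n_points: int
) -> np.ndarray:
    unknown = sorted({e for e in elements if e.upper() not in VDW_RADII})
    if unknown:
        raise ValueError(f"no van der Waals radius for element(s): {unknown}")
    radii = np.array([VDW_RADII[e.upper()] for e in elements]) + probe
    sphere = _sphere_points(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    areas = np.zeros(len(coords))
    for i, (c, r) in enumerate(zip(coords, radii)):
        pts = c + r * sphere
        neigh = [j for j in tree.query_ball_point(c, r + rmax) if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neigh:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= radii[j]
        areas[i] = 4.0 * np.pi * r**2 * accessible.sum() / n_points
    return areas


def _structure_atoms(s: Structure) -> tuple[np.ndarray, list[str], list[tuple[str, int]]]:
    coords, elements, owners = [], [], []
    for c in s.chains:
        for r in c.polymer_residues():
            for a in r.heavy_atoms():
                coords.append(a.coords)
                elements.append(a.element)
                owners.append((c.id, r.seq_id))
    return np.array(coords, dtype=float).reshape(-1, 3), elements, owners


def sasa(
    s: Structure, probe: float = PROBE_RADIUS, n_points: int = N_SPHERE_POINTS
) -> float:
    """Solvent-accessible surface area (A^2), Shrake-Rupley sphere sampling.

    Deterministic for a fixed configuration: a golden-spiral point set of
    ``n_points`` per atom and the fixed heavy-atom radius table VDW_RADII.
    """
    coords, elements, _ = _structure_atoms(s)
    if len(coords) == 0:
        raise ValueError("no heavy atoms with assignable radii")
    return float(_sasa_atoms(coords, elements, probe, n_points).sum())


def relative_sasa(
    s: Structure, probe: float = PROBE_RADIUS, n_points: int = N_SPHERE_POINTS
) -> dict[int, float]:
    """Per-residue accessibility relative to the same residue fully exposed.

    The denominator is the residue's own SASA computed in isolation with the
    identical algorithm, so the ratio is self-consistent and needs no external
    reference table.  Keyed by residue seq_id (first polymer chain).
    """
    coords, elements, owners = _structure_atoms(s)
    areas = _sasa_atoms(coords, elements, probe, n_points)
    rel: dict[int, float] = {}
    by_res: dict[tuple[str, int], list[int]] = {}
    for i, o in enumerate(owners):
        by_res.setdefault(o, []).append(i)
    for (chain_id, seq_id), idx in by_res.items():
        alone = _sasa_atoms(coords[idx], [elements[i] for i in idx], probe, n_points)
        denom = alone.sum()
        rel[seq_id] = float(areas[idx].sum() / denom) if denom > 0 else 0.0
    return rel


def bsa(complex_model: Structure, probe: float = PROBE_RADIUS, n_points: int = N_SPHERE_POINTS) -> float:
    """Buried surface area: SASA(protein) + SASA(DNA) - SASA(complex)."""
    prot, dna = _split_complex(complex_model)
    s_prot = sasa(Structure(chains=[prot], source="bsa:protein"), probe, n_points)
    s_dna = sasa(Structure(chains=[dna], source="bsa:dna"), probe, n_points)
    s_both = sasa(Structure(chains=[prot, dna], source="bsa:complex"), probe, n_points)
    return s_prot + s_dna - s_both


def _coverage(azimuths: np.ndarray, gap_tol: float) -> float:
    """Azimuthal extent of the occupied arc after bridging gaps < gap_tol."""
    if len(azimuths) == 0:
        return 0.0
    if len(azimuths) == 1:
        return 0.0
    az = np.sort(np.asarray(azimuths) % 360.0)
    gaps = np.diff(np.concatenate([az, [az[0] + 360.0]]))
    big = gaps[gaps >= gap_tol]
    if len(big) == 0:
        return 360.0
    return float(360.0 - big.sum())


def classify_wrap_around(
    model: Structure,
    axis: HelixAxis,
    domains: list[ZincFingerDomain] | list[tuple[int, int]],
    config: WrapConfig | None = None,
) -> tuple[bool, float]:
    """Operational wrap-around test: interface azimuth coverage + per-domain contact.

    Interface protein residues (any heavy atom within the contact cutoff of
    DNA) are projected about the DNA axis; coverage is the azimuthal extent of
    the occupied arc after bridging gaps narrower than ``gap_tol``.  A model
    wraps if coverage >= ``min_coverage`` and every domain touches the DNA.
    Returns (wrap_around, coverage in degrees).
    """
    config = config or WrapConfig()
    spans = [d.span if isinstance(d, ZincFingerDomain) else tuple(d) for d in domains]
    contacts = enumerate_contacts(model, config.contact_cutoff)
    if len(contacts) == 0:
        return False, 0.0
    prot, _ = _split_complex(model)
    iface_ids = sorted({p for p, _ in contacts.pairs})
    azimuths = []
    for seq_id in iface_ids:
        res = prot.residue(seq_id)
        try:
            ca = res.atom("CA")
        except KeyError:
            continue
        az, _ = axis.azimuth_radius(ca.coords)
        azimuths.append(az)
    coverage = _coverage(np.array(azimuths), config.gap_tol)
    per_domain = [
        any(lo <= p <= hi for p, _ in contacts.pairs) for lo, hi in spans
    ]
    wrap = bool(coverage >= config.min_coverage and all(per_domain))
    return wrap, coverage


_REMARK_KEYS = {
    "evdw": "e_vdw",
    "eelec": "e_elec",
    "edesolv": "e_desolv",
    "eair": "e_air",
    "bsa": "bsa",
    "haddockscore": "haddock_score",
    "haddock-score": "haddock_score",
}

_FILELIST_RE = re.compile(r'"(?P<name>[^"]+)"\s*\{\s*(?P<score>-?[\d.eE+]+)\s*\}')
_REMARK_KV_RE = re.compile(r"([A-Za-z-]+)\s*=\s*(-?[\d.eE+]+)")


def _parse_model_pdb_remarks(path: Path) -> ScoreRecord | None:
    rec = ScoreRecord(model_id=path.stem)
    seen = False
    for line in path.read_text().splitlines():
        if not line.startswith("REMARK"):
            if line.startswith(("ATOM", "HETATM")):
                break
            continue
        for key, val in _REMARK_KV_RE.findall(line):
            attr = _REMARK_KEYS.get(key.lower())
            if attr:
                setattr(rec, attr, float(val))
                seen = True
    return rec if seen else None


def parse_haddock_scores(dir_or_file: str | Path) -> list[ScoreRecord]:
    """Read docking-engine score output.

    Two dialects are recognised: a ``file.list`` of ``"model.pdb" { score }``
    entries (order preserved), or per-model PDB files whose REMARK lines carry
    ``key=value`` energy components (Evdw, Eelec, Edesolv, Eair, BSA,
    HADDOCKscore).  Missing components stay absent, never zero.
    """
    p = Path(dir_or_file)
    records: list[ScoreRecord] = []
    if p.is_dir():
        filelist = p / "file.list"
        if filelist.exists():
            records.extend(parse_haddock_scores(filelist))
        pdbs = sorted(q for q in p.glob("*.pdb"))
        by_id = {r.model_id: r for r in records}
        for q in pdbs:
            rec = _parse_model_pdb_remarks(q)
            if rec is None:
                continue
            if rec.model_id in by_id:
                base = by_id[rec.model_id]
                for f in ("e_elec", "e_vdw", "e_desolv", "e_air", "bsa", "haddock_score"):
                    if getattr(base, f) is None:
                        setattr(base, f, getattr(rec, f))
            else:
                records.append(rec)
    elif p.suffix == ".pdb":
        rec = _parse_model_pdb_remarks(p)
        if rec:
            records.append(rec)
    elif p.exists():
        for m in _FILELIST_RE.finditer(p.read_text()):
            # entries look like "PREVIT:complex_1w.pdb"; the tag is not part of the id
            name = Path(m.group("name").split(":")[-1]).stem
            records.append(ScoreRecord(model_id=name, haddock_score=float(m.group("score"))))
    else:
        raise FileNotFoundError(p)
    if not records:
        raise ValueError(f"no parsable score records under {p}")
    return records


def rescore_and_rank(
    records: list[ScoreRecord],
    weights: dict[str, float] | None = None,
    n: int = 10,
) -> list[tuple[ScoreRecord, float]]:
    """Rank models by (weighted) docking score, ascending; return the top n.

    With ``weights=None`` the pre-computed parsed score is used.  The sort is
    stable, so equal scores keep their input order.
    """
    scored = []
    for rec in records:
        if weights is None:
            if rec.haddock_score is None:
                raise ValueError(f"model {rec.model_id}: no pre-computed score to rank by")
            scored.append((rec, rec.haddock_score))
        else:
            total = 0.0
            for comp, w in weights.items():
                if w == 0.0:
                    continue
                val = getattr(rec, comp, None)
                if val is None:
                    raise ValueError(f"model {rec.model_id}: missing component {comp} under nonzero weight")
                total += w * val
            scored.append((rec, total))
    ranked = sorted(scored, key=lambda rs: rs[1])
    return ranked[: max(0, n)] if n < len(ranked) else ranked


def population_table(
    records: list[ScoreRecord],
    e_air: dict[str, float],
    gap_min: float = 25.0,
) -> tuple[pd.DataFrame, list[dict]]:
    """Join per-model restraint energies with docking scores; cluster E_AIR.

    Populations are 1-D clusters of E_AIR obtained by splitting the sorted
    values at gaps larger than ``gap_min`` (kcal/mol).  Returns the joined
    table and a list of populations with count and bounds.
    """
    if not records:
        raise ValueError("no score records")
    missing = [r.model_id for r in records if r.model_id not in e_air]
    extra = set(e_air) - {r.model_id for r in records}
    if missing or extra:
        raise ValueError(f"model id mismatch: missing e_air for {missing}, unmatched {sorted(extra)}")
    rows = [
        {
            "model_id": r.model_id,
            "e_air": e_air[r.model_id],
            "score": r.haddock_score,
        }
        for r in records
    ]
    table = pd.DataFrame(rows)
    vals = np.sort(table["e_air"].to_numpy(dtype=float))
    populations = []
    start = 0
    for i in range(1, len(vals) + 1):
        if i == len(vals) or vals[i] - vals[i - 1] > gap_min:
            chunk = vals[start:i]
            populations.append(
                {"count": int(len(chunk)), "lo": float(chunk.min()), "hi": float(chunk.max())}
            )
            start = i
    return table, populations
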
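"""Synthetic wrapped/unwrapped protein-DNA complexes with known ground truth.

Every evaluation metric in this package is purely coordinate-based, so the
test fixtures do not need real zinc-finger folds: each "finger" is a
geometric mini-helix of pseudo-residues (CA/CB/CG backbone stub plus a tip
oxygen) placed around a canonical B-DNA duplex at a prescribed azimuth.  The
tip atom of every residue is set a fixed gap away from its nearest DNA heavy
atom, which guarantees (a) a residue-nucleotide contact at the 5 A criterion
and (b) a satisfied pairwise restraint (effective distance <= gap < 2 A) on
the generating complex.  Rotating one domain about the DNA axis produces the
classic mismatched decoy: the protein no longer wraps and the rotated
domain's restraints are violated.

All generators are seed-deterministic and return machine-readable ground
truth (domain spans, target bases, true contacts, true axis).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .axisgeom import HelixAxis, fit_helix_axis
from .bdna import FiberParameters, build_bdna_duplex
from .modeleval import ContactSet, enumerate_contacts
from .structures import Atom, Chain, Residue, Structure, ZincFingerDomain

__all__ = [
    "DecoyConfig",
    "WrappedTruth",
    "make_wrapped_complex",
    "make_mismatched_decoy",
    "perturb_coordinates",
    "make_toy_interaction_table",
]

RESIDUES_PER_DOMAIN = 8
HELIX_RISE_PER_RESIDUE = 1.5  # A along the DNA axis
AZIMUTH_SLOPE = 5.0  # deg of azimuth per residue: each finger spans ~35 deg
CONTACT_GAP = 1.9  # A from tip atom to its nearest DNA heavy atom
STUB_SPACING = 1.4  # A between successive stub atoms along the outward radial


@dataclass(frozen=True)
class DecoyConfig:
    seq: str = "AGGGGCGGGGCC"
    n_domains: int = 3
    azimuths: tuple[float, ...] = (0.0, 120.0, 240.0)
    contact_offset: float = 0.0  # added to CONTACT_GAP
    noise_sigma: float = 0.0
    seed: int = 0
    twist: float = 36.0
    rise: float = 3.38

    def __post_init__(self) -> None:
        if len(self.azimuths) != self.n_domains:
            raise ValueError(
                f"{self.n_domains} domains but {len(self.azimuths)} azimuths"
            )


@dataclass
class WrappedTruth:
    cfg: DecoyConfig
    domains: list[ZincFingerDomain]
    target_bases: dict[tuple[int, int], int]  # (domain_index, protein seq_id) -> base seq_id
    axis: HelixAxis
    contacts: ContactSet

    def true_pairs(self) -> list[tuple[int, int, int]]:
        return [(d, p, b) for (d, p), b in sorted(self.target_bases.items())]

    def to_json(self, path: str | Path) -> Path:
        payload = {
            "cfg": asdict(self.cfg),
            "domains": [
                {
                    "index": d.index,
                    "span": list(d.span),
                    "zn_ligands": list(d.zn_ligands),
                    "helix_span": list(d.helix_span),
                    "helix_positions": {str(k): v for k, v in d.helix_positions.items()},
                }
                for d in self.domains
            ],
            "target_bases": [[d, p, b] for (d, p), b in sorted(self.target_bases.items())],
            "axis": {
                "point": self.axis.point.tolist(),
                "direction": self.axis.direction.tolist(),
            },
            "contacts": sorted(list(p) for p in self.contacts.pairs),
        }
        path = Path(path)
        path.write_text(json.dumps(payload, indent=1))
        return path


def _pseudo_domain(index: int, start_id: int) -> ZincFingerDomain:
    end_id = start_id + RESIDUES_PER_DOMAIN - 1
    positions = {-1: start_id}
    for p in (1, 2, 3, 5, 6):
        positions[p] = start_id + p
    return ZincFingerDomain(
        index=index,
        span=(start_id, end_id),
        zn_ligands=(start_id, start_id + 1, end_id - 1, end_id),
        helix_span=(start_id + 1, end_id),
        helix_positions=positions,
    )


def make_wrapped_complex(cfg: DecoyConfig | None = None) -> tuple[Structure, WrappedTruth]:
    """Canonical B-DNA plus a pseudo-protein wrapping it at the given azimuths."""
    cfg = cfg or DecoyConfig()
    dna_struct = build_bdna_duplex(cfg.seq, FiberParameters(twist=cfg.twist, rise=cfg.rise), chain_id="D")
    dna_chain = dna_struct.chains[0]
    dna_xyz, dna_owner = [], []
    for r in dna_chain.polymer_residues():
        for a in r.heavy_atoms():
            dna_xyz.append(a.coords)
            dna_owner.append(r.seq_id)
    dna_xyz = np.array(dna_xyz)
    dna_owner = np.array(dna_owner)

    n = len(cfg.seq)
    z_total = (n - 1) * cfg.rise
    z_centers = np.linspace(0.22 * z_total, 0.78 * z_total, cfg.n_domains)
    gap = CONTACT_GAP + cfg.contact_offset

    residues: list[Residue] = []
    domains: list[ZincFingerDomain] = []
    target_bases: dict[tuple[int, int], int] = {}
    for k, (az0, zc) in enumerate(zip(cfg.azimuths, z_centers), start=1):
        start_id = (k - 1) * (RESIDUES_PER_DOMAIN + 2) + 1
        dom = _pseudo_domain(k, start_id)
        domains.append(dom)
        for j in range(RESIDUES_PER_DOMAIN):
            frac = j - (RESIDUES_PER_DOMAIN - 1) / 2.0
            az = np.deg2rad(az0 + frac * AZIMUTH_SLOPE)
            zj = zc + frac * HELIX_RISE_PER_RESIDUE
            u = np.array([np.cos(az), np.sin(az), 0.0])
            anchor = 11.0 * u + np.array([0.0, 0.0, zj])
            nearest = int(np.argmin(np.linalg.norm(dna_xyz - anchor, axis=1)))
            tip = dna_xyz[nearest] + gap * u
            seq_id = start_id + j
            atoms = [
                Atom("OD1", "O", tip),
                Atom("CG", "C", tip + STUB_SPACING * u),
                Atom("CB", "C", tip + 2 * STUB_SPACING * u),
                Atom("CA", "C", tip + 3 * STUB_SPACING * u),
            ]
            residues.append(Residue(name="ALA", seq_id=seq_id, kind="protein", atoms=atoms))
            target_bases[(k, seq_id)] = int(dna_owner[nearest])

    protein = Chain(id="A", residues=residues, role="protein")
    complex_structure = Structure(chains=[protein, dna_chain], source="fixture:wrapped")
    if cfg.noise_sigma > 0:
        complex_structure = perturb_coordinates(complex_structure, cfg.noise_sigma, cfg.seed)
    axis = fit_helix_axis(complex_structure)
    contacts = enumerate_contacts(complex_structure)
    truth = WrappedTruth(
        cfg=cfg, domains=domains, target_bases=target_bases, axis=axis, contacts=contacts
    )
    return complex_structure, truth


def make_mismatched_decoy(
    base: Structure,
    truth: WrappedTruth,
    domain: int,
    rotation: float,
    seed: int = 0,
) -> Structure:
    """Rigidly rotate one domain about the DNA axis; other domains untouched.

    This reproduces the classic mismatched-restraint situation: one finger's
    restraint geometry no longer matches its target bases and the protein
    cannot wrap around the DNA.
    """
    spans = {d.index: d.span for d in truth.domains}
    if domain not in spans:
        raise ValueError(f"no domain {domain}; have {sorted(spans)}")
    lo, hi = spans[domain]
    out = base.copy()
    th = np.deg2rad(rotation)
    d = truth.axis.direction
    p0 = truth.axis.point
    # rotation about the DNA axis via Rodrigues' formula
    K = np.array([[0, -d[2], d[1]], [d[2], 0, -d[0]], [-d[1], d[0], 0]])
    R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    prot = out.chains_with_role("protein")[0]
    for r in prot.residues:
        if lo <= r.seq_id <= hi:
            for a in r.atoms:
                a.coords = R @ (a.coords - p0) + p0
    return out


def perturb_coordinates(s: Structure, sigma: float, seed: int = 0) -> Structure:
    """Seeded i.i.d. Gaussian displacement of every heavy atom."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    out = s.copy()
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    for _, _, a in out.iter_atoms():
        if a.is_heavy:
            a.coords = a.coords + rng.normal(0.0, sigma, size=3)
    return out


def make_toy_interaction_table(truth: WrappedTruth) -> pd.DataFrame:
    """Per-domain residue-base candidate table drawn from the true contacts.

    Columns: domain, protein_res, dna_base, helix_position (canonical label
    where the residue carries one, else blank).
    """
    rows = []
    pos_label = {}
    for d in truth.domains:
        for p, sid in d.helix_positions.items():
            pos_label[(d.index, sid)] = p
    for (dom, res), base in sorted(truth.target_bases.items()):
        rows.append(
            {
                "domain": dom,
                "protein_res": res,
                "dna_base": base,
                "helix_position": pos_label.get((dom, res), ""),
            }
        )
    return pd.DataFrame(rows)
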
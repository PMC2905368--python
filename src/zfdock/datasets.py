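"""Reference inputs for the Zif268/Sp1 zinc-finger docking workflow.

The Zif268 DNA-binding domain (three classical Cys2His2 fingers) is the
standard benchmark for zinc-finger-DNA docking; the residue numbering here
starts at 1 on the 90-residue domain construct so that the published
interaction tables (e.g. R18/S19 in finger 1, R46/D48 in finger 2,
R74/D76/R80 in finger 3) resolve directly.  The DNA site numbering refers to
the merged, consecutively renumbered duplex chain (strand 1 then strand 2,
both 5'->3').

Three restraint sets of increasing parsimony are provided for Zif268:

* set i   - the complete interface (hydrogen bonds + van der Waals contacts):
            7, 5 and 6 pairwise AIRs in fingers 1-3 (18 total);
* set ii  - sequence-specific hydrogen bonds only (2, 3, 2 AIRs);
* set iii - two AIRs per finger, one at each end of the recognition helix
            (6 total) - the minimal balanced set.
"""

from __future__ import annotations

import re

from .structures import Chain, Residue, AnnotationError

__all__ = [
    "SP1_SITE",
    "ZIF268_SEQUENCE",
    "ZIF268_AIR_SETS",
    "zif268_air_pairs",
    "parse_residue_label",
    "protein_chain_from_sequence",
]

# Consensus Sp1 binding site, 5'->3'.
SP1_SITE = "AGGGGCGGGGCC"

# Zif268 DNA-binding domain, numbering from 1.
ZIF268_SEQUENCE = (
    "MERPYACPVESCDRRFSRSDELTRHIRIHTGQKPFQCRICMRNFSRSDHLTTHIRTHTGEKPF"
    "ACDICGRKFARSDERKRHTKIHLRQKD"
)

# Pairwise AIR sets: per finger, positional (residue, base) pairs.
# Duplicate bases are intentional: one base may partner several residues.
ZIF268_AIR_SETS: dict[str, dict[int, list[tuple[str, str]]]] = {
    "i": {
        1: [("R18", "G10"), ("S19", "T13"), ("D20", "T13"), ("E21", "G8"),
            ("R24", "G8"), ("I28", "G6"), ("H25", "G7")],
        2: [("R46", "G7"), ("D48", "C17"), ("H49", "G6"), ("H53", "G4"),
            ("T56", "C3")],
        3: [("R74", "G4"), ("S75", "C18"), ("D76", "A20"), ("E77", "G2"),
            ("K79", "C19"), ("R80", "G2")],
    },
    "ii": {
        1: [("R18", "G10"), ("R24", "G8")],
        2: [("R46", "G7"), ("D48", "C17"), ("H49", "G6")],
        3: [("R74", "G4"), ("R80", "G2")],
    },
    "iii": {
        1: [("S19", "T13"), ("I28", "G6")],
        2: [("D48", "C17"), ("T56", "C3")],
        3: [("D76", "A20"), ("R80", "G2")],
    },
}

_LABEL_RE = re.compile(r"^([A-Za-z])(\d+)$")


def parse_residue_label(label: str) -> tuple[str, int]:
    """Split a one-letter residue/base label like ``S19`` or ``G10``."""
    m = _LABEL_RE.match(label.strip())
    if not m:
        raise ValueError(f"unparsable residue label {label!r}")
    return m.group(1).upper(), int(m.group(2))


def zif268_air_pairs(set_name: str) -> list[tuple[int, int, int]]:
    """(domain, protein seq_id, base seq_id) triples for a named AIR set."""
    try:
        data = ZIF268_AIR_SETS[set_name.strip().lower().strip("()")]
    except KeyError as exc:
        raise KeyError(f"unknown AIR set {set_name!r}; have i, ii, iii") from exc
    out = []
    for dom in sorted(data):
        for res_label, base_label in data[dom]:
            _, res_id = parse_residue_label(res_label)
            _, base_id = parse_residue_label(base_label)
            out.append((dom, res_id, base_id))
    return out


ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}


def protein_chain_from_sequence(seq: str, chain_id: str = "A", start: int = 1) -> Chain:
    """Coordinate-free protein chain (sequence only), for domain annotation."""
    residues = []
    for i, aa in enumerate(seq.upper()):
        if aa not in ONE_TO_THREE:
            raise AnnotationError(f"unknown amino acid {aa!r} at position {i + start}")
        residues.append(Residue(name=ONE_TO_THREE[aa], seq_id=start + i, kind="protein", atoms=[]))
    return Chain(id=chain_id, residues=residues, role="protein")
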
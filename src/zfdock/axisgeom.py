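"""DNA helix-axis geometry and the AIR projection view.

The DNA helix axis is the reference frame for judging how restraints are
distributed over the three zinc-finger domains.  Restraint residues are
projected onto the plane perpendicular to the axis; the resulting azimuths
show at a glance whether an AIR set covers the DNA all around (a prerequisite
for a wrap-around binding mode) or piles up on one side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .structures import Chain, Residue, Structure, ZincFingerDomain
from .restraints import AIRSet

__all__ = [
    "HelixAxis",
    "ProjectionView",
    "BalanceReport",
    "BalanceConfig",
    "fit_helix_axis",
    "project_residues",
    "project_airs",
    "assess_distribution",
    "circular_span",
]


@dataclass
class HelixAxis:
    point: np.ndarray  # centroid on the axis
    direction: np.ndarray  # unit vector, 5'->3' of strand 1
    rms_residual: float
    reference: np.ndarray = field(default=None)  # azimuth zero, unit, perpendicular to direction

    def __post_init__(self) -> None:
        self.point = np.asarray(self.point, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if not np.isclose(norm, 1.0, atol=1e-8):
            self.direction = self.direction / norm
        if self.reference is None:
            # deterministic perpendicular fallback
            trial = np.array([1.0, 0.0, 0.0])
            if abs(trial @ self.direction) > 0.9:
                trial = np.array([0.0, 1.0, 0.0])
            ref = trial - (trial @ self.direction) * self.direction
            self.reference = ref / np.linalg.norm(ref)
        else:
            ref = np.asarray(self.reference, dtype=float)
            ref = ref - (ref @ self.direction) * self.direction
            self.reference = ref / np.linalg.norm(ref)

    def azimuth_radius(self, xyz: np.ndarray) -> tuple[float, float]:
        """Azimuth (degrees in [0, 360)) and radial distance of a point."""
        w = np.asarray(xyz, dtype=float) - self.point
        w_perp = w - (w @ self.direction) * self.direction
        r = float(np.linalg.norm(w_perp))
        if r < 1e-9:
            return 0.0, 0.0
        y_axis = np.cross(self.direction, self.reference)
        az = np.degrees(np.arctan2(w_perp @ y_axis, w_perp @ self.reference)) % 360.0
        return float(az), r


@dataclass
class ProjectionView:
    # (azimuth deg, radial distance A, domain_index, residue seq_id)
    points: list[tuple[float, float, int, int]]

    def azimuths(self) -> np.ndarray:
        return np.array([p[0] for p in self.points], dtype=float)

    def for_domain(self, domain_index: int) -> list[tuple[float, float, int, int]]:
        return [p for p in self.points if p[2] == domain_index]


@dataclass
class BalanceConfig:
    cluster_halfwidth: float = 60.0  # max deviation from the domain circular mean, deg
    min_span: float = 120.0  # minimum azimuthal span of the whole set, deg


@dataclass
class BalanceReport:
    per_domain_counts: dict[int, int]
    per_domain_azimuth_spread: dict[int, float]
    balanced: bool
    offenders: list[tuple[int, int]]  # (domain_index, residue seq_id)
    one_sided: bool
    total_span: float


def fit_helix_axis(duplex: Structure) -> HelixAxis:
    """Least-squares 3-D line through the paired-C1' midpoints of a duplex.

    Direction is oriented 5'->3' along strand 1.  The azimuth reference vector
    is the perpendicular component of (first midpoint -> first-strand C1' of
    the first base pair) — arbitrary but fixed.
    """
    from .bdna import duplex_pairing

    dna_chains = duplex.chains_with_role("dna")
    if not dna_chains:
        raise ValueError("structure has no DNA chain")
    pairs = duplex_pairing(dna_chains[0])
    if len(pairs) < 4:
        raise ValueError(f"need >= 4 base pairs to fit a helix axis, got {len(pairs)}")
    mids = []
    for a, b in pairs:
        mids.append((a.atom("C1'").coords + b.atom("C1'").coords) / 2.0)
    mids = np.array(mids)
    centroid = mids.mean(axis=0)
    centered = mids - centroid
    _, _, vt = np.linalg.svd(centered)
    direction = vt[0]
    if direction @ (mids[-1] - mids[0]) < 0:
        direction = -direction
    perp = centered - np.outer(centered @ direction, direction)
    rms = float(np.sqrt(np.mean(np.sum(perp**2, axis=-1))))
    ref = pairs[0][0].atom("C1'").coords - mids[0]
    ref_perp = ref - (ref @ direction) * direction
    if np.linalg.norm(ref_perp) < 1e-6:
        ref_perp = None  # degenerate; HelixAxis picks a fallback
    return HelixAxis(point=centroid, direction=direction, rms_residual=rms, reference=ref_perp)


def project_residues(
    residues: list[tuple[int, Residue]],
    axis: HelixAxis,
    atom_name: str = "CA",
) -> ProjectionView:
    """Project residues onto the plane perpendicular to the axis.

    ``residues`` is a list of (domain_index, residue); each protein residue is
    represented by its C-alpha.
    """
    points = []
    for domain_index, res in residues:
        try:
            ca = res.atom(atom_name)
        except KeyError as exc:
            raise ValueError(f"residue {res.name}{res.seq_id} lacks {atom_name}") from exc
        az, r = axis.azimuth_radius(ca.coords)
        points.append((az, r, domain_index, res.seq_id))
    return ProjectionView(points=points)


def project_airs(air_set: AIRSet, protein_chain: Chain, axis: HelixAxis) -> ProjectionView:
    """Projection view of the AIR residues (one dot per AIR)."""
    residues = [(a.domain_index, protein_chain.residue(a.active_protein)) for a in air_set.airs]
    return project_residues(residues, axis)


def _circular_mean(deg: np.ndarray) -> float:
    rad = np.deg2rad(deg)
    return float(np.degrees(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))) % 360.0)


def _circular_dev(deg: np.ndarray, center: float) -> np.ndarray:
    d = (deg - center + 180.0) % 360.0 - 180.0
    return np.abs(d)


def circular_span(deg: np.ndarray) -> float:
    """Extent of the smallest arc containing all azimuths (360 - largest gap)."""
    deg = np.sort(np.asarray(deg, dtype=float) % 360.0)
    if len(deg) < 2:
        return 0.0
    gaps = np.diff(np.concatenate([deg, [deg[0] + 360.0]]))
    return float(360.0 - gaps.max())


def assess_distribution(
    air_set: AIRSet,
    view: ProjectionView,
    config: BalanceConfig | None = None,
) -> BalanceReport:
    """Judge whether an AIR set is geometrically balanced across the domains.

    Balanced means: equal AIR counts in every domain, every dot within
    ``cluster_halfwidth`` of its domain's circular-mean azimuth, and the whole
    set spanning at least ``min_span`` of azimuth (a set confined to one side
    of the DNA cannot pull the protein around it).
    """
    config = config or BalanceConfig()
    if not air_set.airs:
        raise ValueError("empty AIR set")
    if len(view.points) != len(air_set.airs):
        raise ValueError("projection view does not cover the AIR set")
    counts = air_set.per_domain_counts()
    spreads: dict[int, float] = {}
    offenders: list[tuple[int, int]] = []
    for dom in sorted(counts):
        pts = view.for_domain(dom)
        az = np.array([p[0] for p in pts])
        spreads[dom] = circular_span(az)
        center = _circular_mean(az)
        dev = _circular_dev(az, center)
        for p, d in zip(pts, dev):
            if d > config.cluster_halfwidth:
                offenders.append((dom, p[3]))
    total_span = circular_span(view.azimuths())
    one_sided = total_span < config.min_span
    equal_counts = len(set(counts.values())) == 1
    balanced = equal_counts and not offenders and not one_sided
    return BalanceReport(
        per_domain_counts=counts,
        per_domain_azimuth_spread=spreads,
        balanced=balanced,
        offenders=offenders,
        one_sided=one_sided,
        total_span=total_span,
    )
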
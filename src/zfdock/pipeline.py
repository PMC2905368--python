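"""Stepwise modelling pipeline around an external docking engine.

The workflow has four steps: (1) select two restraints per finger, (2) check
their geometric distribution about the DNA axis (prescreen), (3) dock with an
external engine (not wrapped here — the pipeline emits engine-ready restraint
files and consumes engine output), (4) evaluate the resulting ensemble
(wrap-around tally, restraint-energy populations, top-N analysis).  Steps 2
and 3 both have a back-loop: an unbalanced restraint set, or an ensemble with
few wrap-around models and a thin low-energy population, sends the user back
to step 1 to choose another restraint pair.

Exit-code convention for the CLI wrappers: 0 ok, 1 back-loop (choose another
AIR pair), 2 hard error.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .axisgeom import BalanceConfig, BalanceReport, assess_distribution, fit_helix_axis, project_airs
from .bdna import FiberParameters, build_bdna_duplex
from .modeleval import (
    ScoreRecord,
    WrapConfig,
    bsa,
    classify_wrap_around,
    fnat,
    irmsd,
    parse_haddock_scores,
    population_table,
    rescore_and_rank,
)
from .restraints import (
    AIRSet,
    air_energy,
    build_pairwise_airs,
    read_tbl,
    select_two_per_domain,
    write_tbl,
)
from .structures import Structure, ZincFingerDomain, annotate_zinc_fingers, read_pdb

__all__ = ["PipelineConfig", "BackLoop", "cmd_prescreen", "cmd_evaluate", "cmd_report"]

# Ensemble convention of the docking protocol: rigid-body models generated,
# best fraction kept for refinement and analysis.
RIGID_BODY_MODELS = 1000
REFINE_FRACTION = 0.2


class BackLoop(RuntimeError):
    """Flowchart back-loop: the restraint set should be re-chosen."""


@dataclass
class PipelineConfig:
    protein: str | None = None
    dna: str | None = None
    sequence: str | None = None
    table: str | None = None
    airs: str | None = None
    truth: str | None = None
    models_dir: str | None = None
    reference: str | None = None
    out_tbl: str | None = None
    report: str | None = None
    out_dir: str | None = None
    two_per_domain: bool = False
    bound: float = 2.0
    twist: float = 36.0
    rise: float = 3.38
    balance: BalanceConfig = field(default_factory=BalanceConfig)
    wrap: WrapConfig = field(default_factory=WrapConfig)
    score_weights: dict | None = None
    top_n: int = 10
    seed: int = 0
    warn_wrap_fraction: float = 0.5
    rigid_body_models: int = RIGID_BODY_MODELS
    refine_fraction: float = REFINE_FRACTION

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")

    def ensemble_size(self) -> int:
        """Number of refined structures analysed per docking run."""
        return int(round(self.rigid_body_models * self.refine_fraction))

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _load_pairs(path: str | Path) -> list[tuple[int, int, int]]:
    tab = pd.read_csv(path, sep="\t")
    required = {"domain", "protein_res", "dna_base"}
    if not required <= set(tab.columns):
        raise ValueError(f"{path}: interaction table needs columns {sorted(required)}")
    return [
        (int(r.domain), int(r.protein_res), int(r.dna_base)) for r in tab.itertuples()
    ]


def _domains_from_json(path: str | Path) -> list[ZincFingerDomain]:
    payload = json.loads(Path(path).read_text())
    return [
        ZincFingerDomain(
            index=d["index"],
            span=tuple(d["span"]),
            zn_ligands=tuple(d["zn_ligands"]),
            helix_span=tuple(d["helix_span"]),
            helix_positions={int(k): v for k, v in d["helix_positions"].items()},
        )
        for d in payload["domains"]
    ]


def _domains_from_airs(air_set: AIRSet) -> list[tuple[int, int]]:
    """Fallback domain spans derived from the restraints themselves."""
    spans = {}
    for a in air_set.airs:
        lo, hi = spans.get(a.domain_index, (a.active_protein, a.active_protein))
        spans[a.domain_index] = (min(lo, a.active_protein), max(hi, a.active_protein))
    return [(lo - 2, hi + 2) for _, (lo, hi) in sorted(spans.items())]


def _resolve_domains(cfg: PipelineConfig, protein: Structure | None) -> list[ZincFingerDomain] | None:
    if cfg.truth:
        return _domains_from_json(cfg.truth)
    if protein is not None:
        try:
            doms = annotate_zinc_fingers(protein.chains_with_role("protein")[0])
            if doms:
                return doms
        except Exception:
            pass
    return None


def cmd_prescreen(cfg: PipelineConfig) -> tuple[BalanceReport, AIRSet]:
    """Build the restraint set and vet its geometric distribution (steps 1-2).

    Raises :class:`BackLoop` on an unbalanced set, naming the offending
    fingers, so a CLI wrapper can exit with the back-loop code.
    """
    if cfg.airs:
        air_set = read_tbl(cfg.airs)
    elif cfg.table:
        pairs = _load_pairs(cfg.table)
        protein = read_pdb(cfg.protein) if cfg.protein else None
        if cfg.two_per_domain:
            domains = _resolve_domains(cfg, protein)
            if domains is None:
                raise ValueError("two-per-domain selection needs --truth or an annotatable protein")
            air_set = select_two_per_domain(pairs, domains, bound=cfg.bound)
        else:
            air_set = build_pairwise_airs(pairs, bound=cfg.bound, label="from-table")
    else:
        raise ValueError("prescreen needs --airs or --table")
    if cfg.dna:
        dna = read_pdb(cfg.dna)
    elif cfg.sequence:
        dna = build_bdna_duplex(cfg.sequence, FiberParameters(twist=cfg.twist, rise=cfg.rise))
    else:
        raise ValueError("prescreen needs --dna or --seq")
    if not cfg.protein:
        raise ValueError("prescreen needs --protein for the projection view")
    protein = read_pdb(cfg.protein)
    axis = fit_helix_axis(dna)
    view = project_airs(air_set, protein.chains_with_role("protein")[0], axis)
    report = assess_distribution(air_set, view, cfg.balance)
    if cfg.report:
        Path(cfg.report).write_text(
            json.dumps(
                {
                    "config_hash": cfg.config_hash(),
                    "balanced": report.balanced,
                    "one_sided": report.one_sided,
                    "total_span": report.total_span,
                    "per_domain_counts": report.per_domain_counts,
                    "per_domain_azimuth_spread": report.per_domain_azimuth_spread,
                    "offenders": report.offenders,
                },
                indent=1,
            )
        )
    if not report.balanced:
        bad = sorted({d for d, _ in report.offenders})
        detail = []
        if len(set(report.per_domain_counts.values())) > 1:
            detail.append(f"unequal AIR counts {report.per_domain_counts}")
        if bad:
            detail.append(f"AIRs out of the domain cluster in finger(s) {bad}")
        if report.one_sided:
            detail.append(
                f"AIRs located on one side of the DNA (span {report.total_span:.0f} deg)"
            )
        raise BackLoop(
            "unbalanced AIR distribution: " + "; ".join(detail) + "; choose another AIR pair"
        )
    if cfg.out_tbl:
        write_tbl(air_set, cfg.out_tbl)
    return report, air_set


def cmd_evaluate(cfg: PipelineConfig) -> dict:
    """Evaluate a docked ensemble (steps 3-4): wrap tally, E_AIR, top-N table.

    Writes report.tsv, populations.tsv and summary.json to ``cfg.out_dir``.
    iRMSD / F_nat columns appear only when a reference complex is given.
    Raises :class:`BackLoop` when both the wrap-around tally and the
    low-E_AIR population are small.
    """
    if not cfg.models_dir:
        raise ValueError("evaluate needs --models")
    model_paths = sorted(Path(cfg.models_dir).glob("*.pdb"))
    if not model_paths:
        raise ValueError(f"no model PDBs in {cfg.models_dir}")
    if not cfg.airs:
        raise ValueError("evaluate needs --airs")
    air_set = read_tbl(cfg.airs)
    domains = None
    if cfg.truth:
        domains = _domains_from_json(cfg.truth)
    reference = read_pdb(cfg.reference) if cfg.reference else None

    rows = []
    e_air_by_id: dict[str, float] = {}
    models: dict[str, Structure] = {}
    for p in model_paths:
        model = read_pdb(p)
        models[p.stem] = model
        axis = fit_helix_axis(model)
        doms = domains if domains is not None else _domains_from_airs(air_set)
        e_air, _ = air_energy(air_set, model)
        wrap, coverage = classify_wrap_around(model, axis, doms, cfg.wrap)
        row = {
            "model_id": p.stem,
            "wrap_around": wrap,
            "coverage": round(coverage, 1),
            "e_air": e_air,
        }
        if reference is not None:
            row["fnat"] = fnat(model, reference)
            row["irmsd"] = irmsd(model, reference)
        rows.append(row)
        e_air_by_id[p.stem] = e_air

    try:
        records = parse_haddock_scores(cfg.models_dir)
        score_source = "parsed"
    except (ValueError, FileNotFoundError):
        records = [
            ScoreRecord(model_id=mid, e_air=e, haddock_score=e, source="recomputed")
            for mid, e in e_air_by_id.items()
        ]
        score_source = "recomputed(e_air)"
    known = set(e_air_by_id)
    records = [r for r in records if r.model_id in known]
    ranked = rescore_and_rank(records, weights=cfg.score_weights, n=cfg.top_n)
    rank_of = {rec.model_id: i + 1 for i, (rec, _) in enumerate(ranked)}
    pop_tab, populations = population_table(records, e_air_by_id)

    table = pd.DataFrame(rows)
    table["rank"] = [rank_of.get(mid, pd.NA) for mid in table["model_id"]]
    top_ids = [rec.model_id for rec, _ in ranked]
    bsa_by_id = {mid: bsa(models[mid]) for mid in top_ids}
    table["bsa"] = [round(bsa_by_id[m], 2) if m in bsa_by_id else pd.NA for m in table["model_id"]]

    n_wrap = int(table["wrap_around"].sum())
    n_total = len(table)
    low_pop = min(populations, key=lambda p: p["lo"])
    low_frac = low_pop["count"] / n_total
    summary = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_models": n_total,
        "wrap_tally": f"{n_wrap}/{n_total}",
        "wrap_fraction": n_wrap / n_total,
        "low_e_air_population_fraction": low_frac,
        "populations": populations,
        "score_source": score_source,
        "top_models": top_ids,
        "reference_given": reference is not None,
    }
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        table.to_csv(out / "report.tsv", sep="\t", index=False)
        pop_tab.to_csv(out / "populations.tsv", sep="\t", index=False)
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
    if summary["wrap_fraction"] < cfg.warn_wrap_fraction and low_frac < cfg.warn_wrap_fraction:
        raise BackLoop(
            f"only {n_wrap}/{n_total} wrap-around models and a thin low-E_AIR population "
            f"({low_pop['count']}/{n_total}); go back to the first step and choose another AIR pair"
        )
    return summary


def cmd_report(cfg: PipelineConfig) -> str:
    """Merge evaluation outputs into a human-readable summary (deterministic)."""
    if not cfg.out_dir:
        raise ValueError("report needs --evaluation directory")
    out = Path(cfg.out_dir)
    try:
        summary = json.loads((out / "summary.json").read_text())
        table = pd.read_csv(out / "report.tsv", sep="\t")
    except FileNotFoundError as exc:
        raise ValueError(f"missing evaluation output: {exc}") from exc
    except (json.JSONDecodeError, pd.errors.ParserError) as exc:
        raise ValueError(f"corrupted evaluation output under {out}: {exc}") from exc
    lines = [
        f"zfdock {summary['version']} evaluation summary (config {summary['config_hash']}, seed {summary['seed']})",
        f"models analysed : {summary['n_models']}",
        f"wrap-around     : {summary['wrap_tally']}",
        f"E_AIR populations: "
        + ", ".join(f"{p['count']} in [{p['lo']:.1f}, {p['hi']:.1f}]" for p in summary["populations"]),
        f"score source    : {summary['score_source']}",
        "top models by score:",
    ]
    ranked = table.dropna(subset=["rank"]).sort_values("rank")
    for r in ranked.itertuples():
        extra = ""
        if "fnat" in table.columns and not pd.isna(r.fnat):
            extra = f"  fnat={r.fnat:.2f} irmsd={r.irmsd:.2f}"
        lines.append(
            f"  #{int(r.rank):2d} {r.model_id}  e_air={r.e_air:.2f} wrap={bool(r.wrap_around)}{extra}"
        )
    return "\n".join(lines)
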
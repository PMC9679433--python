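"""One-shot analysis pipeline: collapse -> diversity -> AMOVA -> PCoA ->
sharing -> broodstock matching -> contribution, with file outputs.

The stages run in the order a stocking-assessment study would report them:
pre-stocking population structure first (pooled per site), then the
post-stocking haplotype-sharing and broodstock-matching evidence.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from . import __version__
from .amova import AmovaResult, amova_phipt, pairwise_phipt
from .ordination import PcoaResult, pcoa
from .popgen import (
    DiversitySummary,
    collapse,
    collapse_haplotypes,
    divergence_matrix,
    diversity_summaries,
    pairwise_distances,
)
from .seqio import BoundDataset
from .stocking import (
    BroodstockMatchReport,
    ContributionEstimate,
    SharingReport,
    estimate_contribution,
    match_broodstock,
    sharing_between,
    temporal_sharing_profile,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Knobs of a full analysis run (all reproducibility-relevant state)."""

    seed: int = 0
    alpha: float = 0.05
    n_perm: int = 999
    distance_mode: str = "pairwise-deletion"
    background_aggregation: str = "mean"

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "seed": self.seed, "alpha": self.alpha, "n_perm": self.n_perm,
            "distance_mode": self.distance_mode,
            "background_aggregation": self.background_aggregation,
            "version": __version__,
        }


@dataclass
class AnalysisReport:
    """All results of one pipeline run."""

    config: RunConfig
    diversity: list[DiversitySummary]
    divergence: pd.DataFrame
    amova: AmovaResult | None
    phipt: pd.DataFrame | None
    pcoa: PcoaResult
    sharing: dict[str, SharingReport]
    sharing_between: pd.DataFrame
    contributions: dict[str, ContributionEstimate] = field(default_factory=dict)
    broodstock_matches: dict[str, BroodstockMatchReport] = field(default_factory=dict)

    def dossier(self) -> dict:
        """Combined per-site stocking dossier (JSON-serializable)."""
        return {
            "config": self.config.to_dict(),
            "sharing": {s: r.to_dict() for s, r in self.sharing.items()},
            "contributions": {s: c.to_dict() for s, c in self.contributions.items()},
            "broodstock_matches": {
                s: m.to_dict() for s, m in self.broodstock_matches.items()
            },
            "amova": self.amova.to_dict() if self.amova else None,
        }


def run_analysis(data: BoundDataset, config: RunConfig | None = None) -> AnalysisReport:
    """Run the full pipeline on a bound dataset."""
    config = config or RunConfig()
    meta = data.meta.df

    # --- pre-stocking structure, pooled per site (plus broodstock as a pop)
    pre_ids = list(meta.index[meta["stocking_epoch"] == "pre"])
    pre = data.subset(pre_ids)
    pre_sites = pre.group_ids("site")
    amova_res = phipt = None
    diversity: list[DiversitySummary] = []
    divergence = pd.DataFrame()
    if len(pre_sites) >= 2 and all(len(v) >= 2 for v in pre_sites.values()):
        logger.info("pre-stocking structure over %d sites", len(pre_sites))
        diversity = diversity_summaries(pre, by="site")
        divergence = divergence_matrix(pre, by="site")
        dm_pre = pairwise_distances(pre.seqs, mode=config.distance_mode)
        site_of = meta["site"].to_dict()
        amova_res = amova_phipt(dm_pre, {i: site_of[i] for i in dm_pre.ids},
                                n_perm=config.n_perm, seed=config.seed)
        phipt = pairwise_phipt(dm_pre, {i: site_of[i] for i in dm_pre.ids},
                               n_perm=config.n_perm, seed=config.seed)

    # --- ordination over everything
    dm_all = pairwise_distances(data.seqs, mode=config.distance_mode)
    pcoa_res = pcoa(dm_all)

    # --- sharing and stocking signal over all estuary samples
    estuary_sites = sorted(meta.loc[meta["role"] == "estuary", "site"].unique())
    sharing = {s: temporal_sharing_profile(data, s) for s in estuary_sites}
    tables = collapse_haplotypes(
        data.subset(list(meta.index[meta["role"] == "estuary"])), "site"
    )
    between = sharing_between(tables)

    treatments = meta.drop_duplicates("site").set_index("site")["site_treatment"]
    stocked = [s for s in estuary_sites if treatments.get(s) == "stocked"]
    references = [s for s in estuary_sites if treatments.get(s) == "reference"]
    contributions = {}
    if stocked and references:
        ref_reports = [sharing[s] for s in references]
        for s in stocked:
            contributions[s] = estimate_contribution(
                sharing[s], ref_reports, aggregation=config.background_aggregation
            )

    # --- broodstock matching
    brood_ids = list(meta.index[meta["role"] == "broodstock"])
    matches = {}
    if brood_ids:
        brood_table = collapse(data.seqs.subset(brood_ids), label="broodstock")
        epochs = meta["stocking_epoch"].to_dict()
        for table in tables:
            matches[table.label] = match_broodstock(table, brood_table, epochs)

    return AnalysisReport(
        config=config, diversity=diversity, divergence=divergence,
        amova=amova_res, phipt=phipt, pcoa=pcoa_res, sharing=sharing,
        sharing_between=between, contributions=contributions,
        broodstock_matches=matches,
    )


# ---------------------------------------------------------------------------
# output

def _diversity_frame(summaries: list[DiversitySummary]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "population": s.label, "n": s.n, "n_haplotypes": s.n_haplotypes,
            "haplotype_diversity": s.h, "nucleotide_diversity": s.pi,
            "n_polymorphic_sites": s.n_polymorphic_sites,
            "n_private_alleles": s.n_private_alleles,
            "mean_n_alleles_per_site": s.mean_n_alleles_per_site,
        }
        for s in summaries
    ])


def write_report(report: AnalysisReport, data: BoundDataset, outdir) -> dict[str, str]:
    """Write all pipeline outputs (CSV/JSON/PNG) into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def save_csv(name: str, frame: pd.DataFrame, **kw) -> None:
        p = outdir / name
        frame.to_csv(p, **kw)
        paths[name] = str(p)

    if report.diversity:
        save_csv("diversity.csv", _diversity_frame(report.diversity), index=False)
    if not report.divergence.empty:
        save_csv("divergence_pct.csv", report.divergence.round(4))
    if report.phipt is not None:
        # PhiPT below the diagonal, permutation p above — one square table
        save_csv("phipt_pairwise.csv", report.phipt.round(4))
    if report.amova is not None:
        p = outdir / "amova.json"
        p.write_text(json.dumps(report.amova.to_dict(), indent=2))
        paths["amova.json"] = str(p)

    save_csv("sharing_between_sites.csv", report.sharing_between)
    dossier = report.dossier()
    p = outdir / "stocking_dossier.json"
    p.write_text(json.dumps(dossier, indent=2))
    paths["stocking_dossier.json"] = str(p)

    coords = report.pcoa.frame()
    coords.insert(0, "site", data.meta.df.loc[coords.index, "site"])
    save_csv("pcoa_coordinates.csv", coords.iloc[:, : 1 + min(4, report.pcoa.n_axes)],
             index_label="sample_id")
    paths["pcoa.png"] = str(_plot_pcoa(report.pcoa, data, outdir / "pcoa.png"))
    paths["sharing.png"] = str(_plot_sharing(report.sharing, outdir / "sharing.png"))

    p = outdir / "summary.txt"
    p.write_text(_summary_text(report))
    paths["summary.txt"] = str(p)
    return paths


def _plot_pcoa(res: PcoaResult, data: BoundDataset, path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 5))
    sites = data.meta.df.loc[res.ids, "site"]
    y = res.coordinates[:, 1] if res.n_axes > 1 else 0 * res.coordinates[:, 0]
    for site in sorted(sites.unique()):
        mask = (sites == site).to_numpy()
        ax.scatter(res.coordinates[mask, 0], y[mask], s=12, alpha=0.6, label=site)
    pct = res.pct_variance_explained
    ax.set_xlabel(f"PCo1 ({pct[0]:.1f}%)")
    ax.set_ylabel(f"PCo2 ({pct[1]:.1f}%)" if len(pct) > 1 else "PCo2")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def _plot_sharing(sharing: dict[str, SharingReport], path) -> Path:
    fig, ax = plt.subplots(figsize=(6, 4))
    sites = list(sharing)
    ax.bar(sites, [sharing[s].pct_sharing for s in sites], color="tab:blue")
    ax.set_ylabel("% of animals sharing a haplotype")
    ax.tick_params(axis="x", rotation=30)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def _summary_text(report: AnalysisReport) -> str:
    lines = [f"haplostock {__version__} analysis summary", ""]
    if report.diversity:
        lines.append("Pre-stocking diversity (pooled per site):")
        for s in report.diversity:
            lines.append(
                f"  {s.label}: n={s.n}, {s.n_haplotypes} haplotypes, "
                f"h={s.h:.3f}, pi={100 * s.pi:.2f}%, "
                f"{s.n_polymorphic_sites} polymorphic sites"
            )
        lines.append("")
    if report.amova is not None:
        a = report.amova
        lines.append(
            f"AMOVA: PhiPT={a.phi_pt:.3f} (p={a.p_value:.3f}, "
            f"{a.n_permutations} permutations); "
            f"{a.pct_among:.1f}% of variance among populations"
        )
        lines.append("")
    lines.append("Haplotype sharing within sites:")
    for s, rep in report.sharing.items():
        lines.append(
            f"  {s}: {rep.n_sharing_samples}/{rep.n_samples} sharing "
            f"({rep.pct_sharing:.1f}%), {rep.n_shared_groups} shared groups"
        )
    if report.contributions:
        lines.append("")
        lines.append("Background-corrected stocking contribution (upper bound):")
        for s, c in report.contributions.items():
            lines.append(
                f"  {s}: raw {c.raw_shared_pct:.1f}% - background "
                f"{c.background_pct:.1f}% -> {c.corrected_contribution_pct:.1f}%"
            )
    if report.broodstock_matches:
        lines.append("")
        lines.append("Broodstock haplotype matches:")
        for s, m in report.broodstock_matches.items():
            lines.append(
                f"  {s}: {m.n_matching_samples}/{m.n_samples} "
                f"({m.match_pct:.1f}%)"
            )
    return "\n".join(lines) + "\n"
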
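"""Haplotype sharing as a kinship proxy and stocking-contribution estimation.

In a large panmictic stock with a hypervariable maternal marker, nearly every
wild individual carries a unique haplotype, so two animals at one site with
the identical haplotype are most plausibly maternal siblings. Hatchery
cohorts descend from few dams, so released animals arrive in large maternal
families; an excess of within-site haplotype sharing over the background
level measured at unstocked reference sites is therefore a signal of hatchery
origin, and (after background correction) an upper bound on the hatchery
contribution. Exact haplotype matches to sampled broodstock provide a second,
direct line of evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import EmptyBroodstockError, NoReferencesError
from .popgen import HaplotypeTable
from .seqio import BoundDataset


@dataclass
class SharingReport:
    """Within-group haplotype-sharing statistics.

    An individual "shares" when its haplotype is carried by >= 2 individuals
    in the group; a "shared group" is one such haplotype (a putative maternal
    family).
    """

    site: str
    n_samples: int
    n_haplotypes: int
    n_shared_groups: int
    n_sharing_samples: int
    pct_unique: float
    cohorts: list["SharingReport"] | None = field(default=None, repr=False)

    @property
    def pct_sharing(self) -> float:
        return 100.0 - self.pct_unique

    def to_dict(self) -> dict:
        d = {
            "site": self.site, "n_samples": self.n_samples,
            "n_haplotypes": self.n_haplotypes,
            "n_shared_groups": self.n_shared_groups,
            "n_sharing_samples": self.n_sharing_samples,
            "pct_unique": self.pct_unique, "pct_sharing": self.pct_sharing,
        }
        if self.cohorts is not None:
            d["cohorts"] = [c.to_dict() for c in self.cohorts]
        return d


def sharing_within(table: HaplotypeTable) -> SharingReport:
    """Sharing statistics of one haplotype table."""
    counts = table.counts
    n = int(counts.sum())
    shared = counts >= 2
    n_sharing = int(counts[shared].sum())
    return SharingReport(
        site=table.label, n_samples=n, n_haplotypes=table.n_haplotypes,
        n_shared_groups=int(shared.sum()), n_sharing_samples=n_sharing,
        pct_unique=100.0 * (1.0 - n_sharing / n) if n else 100.0,
    )


def sharing_between(tables: list[HaplotypeTable]) -> pd.DataFrame:
    """Counts of distinct haplotypes shared between each pair of groups."""
    labels = [t.label for t in tables]
    sets = [t.haplotype_set() for t in tables]
    out = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for i, (li, si) in enumerate(zip(labels, sets)):
        out.loc[li, li] = len(si)
        for lj, sj in zip(labels[i + 1:], sets[i + 1:]):
            shared = len(si & sj)
            out.loc[li, lj] = out.loc[lj, li] = shared
    return out


def temporal_sharing_profile(data: BoundDataset, site: str,
                             window: str = "trip") -> SharingReport:
    """Per-collection-time sharing within one site.

    Sharing is evaluated against all samples from the site (a cohort member
    counts as sharing when its haplotype occurs >= 2 times site-wide), with
    membership grouped per collection trip (``window='trip'``) or per
    calendar month (``window='month'``). The returned report carries the
    site-wide statistics with the per-cohort series in ``cohorts``.
    """
    from .popgen import collapse

    meta = data.meta.df
    ids = list(meta.index[(meta["site"] == site) & (meta["role"] == "estuary")])
    if not ids:
        raise KeyError(f"no estuary samples at site {site!r}")
    sub = data.subset(ids)
    table = collapse(sub.seqs, label=site)
    site_counts: dict[str, int] = {}
    hap_of: dict[str, str] = {}
    for hap, members in zip(table.haplotypes, table.members):
        site_counts[hap] = len(members)
        for sid in members:
            hap_of[sid] = hap

    dates = sub.meta.df["collection_date"]
    if window == "month":
        labels = dates.dt.strftime("%Y-%m")
    else:
        labels = dates.dt.strftime("%Y-%m-%d")
    cohorts = []
    for label, members in sorted(labels.groupby(labels).groups.items()):
        member_ids = list(members)
        haps = {hap_of[i] for i in member_ids}
        sharing = [i for i in member_ids if site_counts[hap_of[i]] >= 2]
        shared_groups = {hap_of[i] for i in sharing}
        n = len(member_ids)
        cohorts.append(SharingReport(
            site=f"{site}:{label}", n_samples=n, n_haplotypes=len(haps),
            n_shared_groups=len(shared_groups), n_sharing_samples=len(sharing),
            pct_unique=100.0 * (1.0 - len(sharing) / n),
        ))
    report = sharing_within(table)
    report.cohorts = cohorts
    return report


@dataclass
class ContributionEstimate:
    """Background-corrected stocking-contribution estimate for one site.

    The corrected percentage is an *upper bound* on the hatchery contribution
    under the sibship assumption: wild background sharing is subtracted, but
    hatchery families represented by a single sampled individual are
    invisible to a sharing-based estimator.
    """

    site: str
    raw_shared_pct: float
    background_pct: float
    corrected_contribution_pct: float
    interpretation: str = "upper-bound"
    background_aggregation: str = "mean"

    def to_dict(self) -> dict:
        return {
            "site": self.site, "raw_shared_pct": self.raw_shared_pct,
            "background_pct": self.background_pct,
            "corrected_contribution_pct": self.corrected_contribution_pct,
            "interpretation": self.interpretation,
            "background_aggregation": self.background_aggregation,
        }


def estimate_contribution(stocked: SharingReport, references: list[SharingReport],
                          aggregation: str = "mean") -> ContributionEstimate:
    """Background-corrected contribution: stocked sharing minus reference sharing.

    ``aggregation`` chooses how reference-site sharing percentages are
    combined into a single background level (mean by default; min and max
    give the optimistic and conservative variants). The result is truncated
    at zero.
    """
    if not references:
        raise NoReferencesError("at least one reference-site report required")
    ref_pcts = [r.pct_sharing for r in references]
    if aggregation == "mean":
        background = sum(ref_pcts) / len(ref_pcts)
    elif aggregation == "min":
        background = min(ref_pcts)
    elif aggregation == "max":
        background = max(ref_pcts)
    else:
        raise ValueError(f"unknown background aggregation {aggregation!r}")
    raw = stocked.pct_sharing
    return ContributionEstimate(
        site=stocked.site, raw_shared_pct=raw, background_pct=background,
        corrected_contribution_pct=max(0.0, raw - background),
        background_aggregation=aggregation,
    )


@dataclass
class BroodstockMatchReport:
    """Exact haplotype matches between a site sample and hatchery broodstock."""

    site: str
    n_samples: int
    n_matching_samples: int
    match_pct: float
    matched_haplotypes: list[str]
    #: per stocking-epoch breakdown {epoch: (n_matching, n_samples)}
    by_epoch: dict[str, tuple[int, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "site": self.site, "n_samples": self.n_samples,
            "n_matching_samples": self.n_matching_samples,
            "match_pct": self.match_pct,
            "n_matched_haplotypes": len(self.matched_haplotypes),
            "by_epoch": {k: {"n_matching": v[0], "n_samples": v[1]}
                         for k, v in self.by_epoch.items()},
        }


def match_broodstock(site_table: HaplotypeTable, broodstock_table: HaplotypeTable,
                     epochs: dict[str, str] | None = None) -> BroodstockMatchReport:
    """Count site individuals whose haplotype exactly matches a broodstock one.

    ``epochs`` optionally maps sample ids to a stocking epoch (pre/post) for
    the per-epoch breakdown.
    """
    if broodstock_table.n == 0:
        raise EmptyBroodstockError("broodstock haplotype table is empty")
    brood = broodstock_table.haplotype_set()
    matched_haps, matching_ids = [], []
    for hap, members in zip(site_table.haplotypes, site_table.members):
        if hap in brood:
            matched_haps.append(hap)
            matching_ids.extend(members)
    n = site_table.n
    by_epoch: dict[str, tuple[int, int]] = {}
    if epochs is not None:
        all_ids = [sid for members in site_table.members for sid in members]
        matching = set(matching_ids)
        for epoch in sorted({epochs[i] for i in all_ids if i in epochs}):
            ids_e = [i for i in all_ids if epochs.get(i) == epoch]
            by_epoch[epoch] = (sum(1 for i in ids_e if i in matching), len(ids_e))
    return BroodstockMatchReport(
        site=site_table.label, n_samples=n, n_matching_samples=len(matching_ids),
        match_pct=100.0 * len(matching_ids) / n if n else 0.0,
        matched_haplotypes=matched_haps, by_epoch=by_epoch,
    )


def kinship_groups(table: HaplotypeTable) -> list[list[str]]:
    """Putative maternal families: member lists of haplotypes carried >= 2 times.

    Identical-by-state wild haplotypes inflate these groups at the background
    sharing rate, so group membership is suggestive, not proof, of sibship.
    Singleton haplotypes are excluded. Groups are ordered largest first.
    """
    groups = [list(m) for m in table.members if len(m) >= 2]
    groups.sort(key=len, reverse=True)
    return groups
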
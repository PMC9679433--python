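"""Haplotype collapsing, pairwise distances, and diversity statistics.

Core quantities for a haploid, maternally inherited marker:

* haplotype collapsing by exact string identity over all aligned columns;
* pairwise nucleotide-difference counts with pairwise deletion of columns
  that are missing (N or gap) in either sequence;
* Nei's unbiased haplotype (gene) diversity h = n/(n-1) * (1 - sum p_i^2);
* nucleotide diversity pi = mean over unordered pairs of the per-pair
  per-comparable-site difference proportion;
* per-population allelic pattern statistics (polymorphic sites, private
  alleles, mean alleles per site) and the chi-square / ANOVA comparisons of
  those counts across populations with Bonferroni-corrected pairwise tests.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    DegenerateCountsError,
    EmptyInputError,
    NoComparablePairsError,
    SinglePopulationError,
    TooFewSamplesError,
)
from .seqio import AlignedSeqSet, BoundDataset


# ---------------------------------------------------------------------------
# haplotype tables

@dataclass
class HaplotypeTable:
    """Distinct haplotypes within a group, with their member sample ids.

    Haplotype identity is exact string equality over all aligned columns
    (N and gaps included), so member lists are disjoint and exhaustive.
    """

    label: str
    haplotypes: list[str]
    members: list[list[str]]

    @property
    def n(self) -> int:
        """Number of samples in the group."""
        return sum(len(m) for m in self.members)

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def counts(self) -> np.ndarray:
        return np.array([len(m) for m in self.members], dtype=int)

    def haplotype_set(self) -> set[str]:
        return set(self.haplotypes)


def collapse(seqs: AlignedSeqSet, label: str = "all") -> HaplotypeTable:
    """Collapse an alignment to distinct haplotypes (exact-match identity)."""
    by_hap: dict[str, list[str]] = {}
    for i, sid in enumerate(seqs.ids):
        by_hap.setdefault(seqs.sequence(i), []).append(sid)
    haps = list(by_hap)
    return HaplotypeTable(label=label, haplotypes=haps, members=[by_hap[h] for h in haps])


def collapse_haplotypes(data: BoundDataset, group_by: str = "site") -> list[HaplotypeTable]:
    """One haplotype table per group of a bound dataset.

    ``group_by`` may be ``all``, ``site``, ``site_cohort`` or any metadata
    column. Haplotypes are ordered by first occurrence within each group.
    """
    if data.n == 0:
        raise EmptyInputError("empty dataset")
    return [
        collapse(data.seqs.subset(ids), label=label)
        for label, ids in data.group_ids(group_by).items()
    ]


# ---------------------------------------------------------------------------
# distances

@dataclass
class DistanceMatrix:
    """Pairwise nucleotide-difference counts with per-pair comparable sites.

    ``d[i, j]`` counts aligned columns where both sequences carry a definite
    base (A/C/G/T) and the bases differ; columns with N or a gap in either
    sequence are excluded pair-by-pair (pairwise deletion), and the number of
    retained columns is recorded in ``comparable[i, j]``.
    """

    ids: list[str]
    d: np.ndarray
    comparable: np.ndarray

    @property
    def n(self) -> int:
        return len(self.ids)

    def per_site(self) -> np.ndarray:
        """Per-pair per-site difference proportions (diagonal zero).

        Raises :class:`NoComparablePairsError` if any off-diagonal pair has
        zero comparable sites.
        """
        comp = self.comparable.astype(float)
        zero = (comp == 0) & ~np.eye(self.n, dtype=bool)
        if zero.any():
            i, j = np.argwhere(zero)[0]
            raise NoComparablePairsError(
                f"no comparable sites between {self.ids[i]!r} and {self.ids[j]!r}"
            )
        np.fill_diagonal(comp, 1.0)  # avoid 0/0 on the diagonal
        return self.d / comp

    def subset(self, ids: list[str]) -> "DistanceMatrix":
        index = {sid: i for i, sid in enumerate(self.ids)}
        rows = np.array([index[i] for i in ids])
        return DistanceMatrix(
            ids=list(ids), d=self.d[np.ix_(rows, rows)],
            comparable=self.comparable[np.ix_(rows, rows)],
        )


def pairwise_distances(seqs: AlignedSeqSet, mode: str = "pairwise-deletion") -> DistanceMatrix:
    """Pairwise nucleotide-difference matrix.

    ``mode='pairwise-deletion'`` (default) excludes missing columns pair by
    pair; ``mode='complete-deletion'`` first drops every column with a
    missing value in *any* sequence, so all pairs are compared over the same
    columns.
    """
    if seqs.n < 2:
        raise TooFewSamplesError("need at least 2 sequences for distances")
    codes = seqs.codes()
    valid = codes >= 0
    if mode == "complete-deletion":
        keep = valid.all(axis=0)
        codes = codes[:, keep]
        valid = valid[:, keep]
    elif mode != "pairwise-deletion":
        raise ValueError(f"unknown distance mode {mode!r}")
    n = seqs.n
    d = np.zeros((n, n), dtype=np.int64)
    comp = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = valid[i] & valid
        d[i] = ((codes[i] != codes) & both).sum(axis=1)
        comp[i] = both.sum(axis=1)
    return DistanceMatrix(ids=list(seqs.ids), d=d, comparable=comp)


# ---------------------------------------------------------------------------
# diversity statistics

def haplotype_diversity(table: HaplotypeTable) -> float:
    """Nei's unbiased gene diversity h = n/(n-1) * (1 - sum p_i^2)."""
    n = table.n
    if n < 2:
        raise TooFewSamplesError(f"haplotype diversity needs n >= 2, got {n}")
    p = table.counts / n
    return float(n / (n - 1) * (1.0 - np.sum(p**2)))


def nucleotide_diversity(dm: DistanceMatrix) -> float:
    """Mean per-site difference proportion over unordered sequence pairs."""
    if dm.n < 2:
        raise TooFewSamplesError("nucleotide diversity needs n >= 2")
    ps = dm.per_site()
    iu = np.triu_indices(dm.n, k=1)
    return float(ps[iu].mean())


@dataclass
class DiversitySummary:
    """Per-population diversity summary (one row of a comparison table)."""

    label: str
    n: int
    n_haplotypes: int
    h: float
    pi: float
    n_polymorphic_sites: int
    n_private_alleles: int
    mean_n_alleles_per_site: float
    #: distinct non-missing bases per aligned column (used by the ANOVA)
    per_site_allele_counts: np.ndarray | None = field(default=None, repr=False)


def site_allele_stats(data: BoundDataset, by: str = "site") -> dict[str, dict]:
    """Allelic pattern statistics per population.

    For each population: a polymorphic site is a column with >= 2 distinct
    non-missing bases within that population; a private allele is a
    (position, base) pair observed in exactly one population; the mean number
    of alleles per site averages the count of distinct non-missing bases over
    all columns. Requires >= 2 populations (private alleles are otherwise
    undefined).
    """
    groups = data.group_ids(by)
    if len(groups) < 2:
        raise SinglePopulationError("private alleles need >= 2 populations")
    codes = data.seqs.codes()
    index = {sid: i for i, sid in enumerate(data.seqs.ids)}
    # presence[pop] has shape (4, L): base b observed at column c in pop
    presence: dict[str, np.ndarray] = {}
    for label, ids in groups.items():
        sub = codes[[index[i] for i in ids]]
        pres = np.stack([(sub == b).any(axis=0) for b in range(4)])
        presence[label] = pres
    total_occurrences = sum(p.astype(int) for p in presence.values())
    out: dict[str, dict] = {}
    for label, pres in presence.items():
        n_alleles = pres.sum(axis=0)  # per column
        private = pres & (total_occurrences == 1)
        out[label] = {
            "n_polymorphic_sites": int((n_alleles >= 2).sum()),
            "n_private_alleles": int(private.sum()),
            "mean_n_alleles_per_site": float(n_alleles.mean()),
            "per_site_allele_counts": n_alleles.astype(float),
        }
    return out


def diversity_summaries(data: BoundDataset, by: str = "site") -> list[DiversitySummary]:
    """Full per-population diversity summaries (h, pi, allelic patterns)."""
    allele = site_allele_stats(data, by=by)
    out = []
    for table, (label, ids) in zip(collapse_haplotypes(data, by), data.group_ids(by).items()):
        dm = pairwise_distances(data.seqs.subset(ids))
        st = allele[label]
        out.append(DiversitySummary(
            label=label, n=table.n, n_haplotypes=table.n_haplotypes,
            h=haplotype_diversity(table), pi=nucleotide_diversity(dm),
            n_polymorphic_sites=st["n_polymorphic_sites"],
            n_private_alleles=st["n_private_alleles"],
            mean_n_alleles_per_site=st["mean_n_alleles_per_site"],
            per_site_allele_counts=st["per_site_allele_counts"],
        ))
    return out


# ---------------------------------------------------------------------------
# divergence table

def divergence_matrix(data: BoundDataset, by: str = "site") -> pd.DataFrame:
    """Mean percent sequence divergence within (diagonal) and between groups.

    Raw mean pairwise per-site difference x 100, with no within-group
    correction (gross, not net, divergence). Populations with n < 2 get NaN
    on the diagonal.
    """
    groups = data.group_ids(by)
    dm = pairwise_distances(data.seqs)
    ps = dm.per_site()
    index = {sid: i for i, sid in enumerate(dm.ids)}
    labels = list(groups)
    out = pd.DataFrame(np.nan, index=labels, columns=labels)
    rows = {g: np.array([index[i] for i in ids]) for g, ids in groups.items()}
    for g in labels:
        r = rows[g]
        if len(r) >= 2:
            iu = np.triu_indices(len(r), k=1)
            out.loc[g, g] = 100.0 * ps[np.ix_(r, r)][iu].mean()
    for g1, g2 in itertools.combinations(labels, 2):
        val = 100.0 * ps[np.ix_(rows[g1], rows[g2])].mean()
        out.loc[g1, g2] = out.loc[g2, g1] = val
    return out


# ---------------------------------------------------------------------------
# count comparisons across populations

@dataclass
class CountComparison:
    """One test comparing a count (or mean) across populations."""

    metric: str
    statistic: float
    df: float
    p_value: float
    pairwise: pd.DataFrame  # columns: group1, group2, statistic, p_raw, p_adj, significant
    letters: dict[str, str]  # homogeneous-group letters per population


@dataclass
class SiteCountReport:
    """Chi-square / ANOVA comparisons of allelic-pattern counts across sites."""

    comparisons: dict[str, CountComparison]
    alpha: float


def _bonferroni(p_values: list[float]) -> list[float]:
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]


def _homogeneous_letters(labels: list[str], sig_pairs: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display via the insert-and-absorb algorithm.

    Two populations share a letter iff they are not significantly different
    (directly); starts from one letter covering everything and splits it on
    each significant pair, absorbing letter sets contained in others.
    """
    letter_sets: list[set[str]] = [set(labels)]
    for a, b in sig_pairs:
        for s in list(letter_sets):
            if a in s and b in s:
                letter_sets.remove(s)
                for new in (s - {a}, s - {b}):
                    if new and not any(new <= other for other in letter_sets):
                        letter_sets.append(new)
                        letter_sets = [
                            x for x in letter_sets if not (x < new)
                        ]
    # stable ordering: by first member in input label order
    order = {lab: i for i, lab in enumerate(labels)}
    letter_sets.sort(key=lambda s: min(order[x] for x in s))
    out = {lab: "" for lab in labels}
    for letter, s in zip(string.ascii_lowercase, letter_sets):
        for lab in labels:
            if lab in s:
                out[lab] += letter
    return out


def _chi_square_comparison(metric: str, labels: list[str], counts: np.ndarray,
                           alpha: float) -> CountComparison:
    """Goodness-of-fit against equal expected counts, with pairwise tests."""
    if counts.sum() == 0:
        raise DegenerateCountsError(f"all {metric} counts are zero")
    stat, p = sps.chisquare(counts)
    rows, raw = [], []
    for (l1, c1), (l2, c2) in itertools.combinations(zip(labels, counts), 2):
        if c1 + c2 == 0:
            s2, p2 = 0.0, 1.0
        else:
            s2, p2 = sps.chisquare([c1, c2])
        rows.append((l1, l2, float(s2)))
        raw.append(float(p2))
    adj = _bonferroni(raw)
    pairwise = pd.DataFrame(
        [(l1, l2, s, pr, pa, pa < alpha) for (l1, l2, s), pr, pa in zip(rows, raw, adj)],
        columns=["group1", "group2", "statistic", "p_raw", "p_adj", "significant"],
    )
    sig = {(r.group1, r.group2) for r in pairwise.itertuples() if r.significant}
    return CountComparison(
        metric=metric, statistic=float(stat), df=float(len(counts) - 1),
        p_value=float(p), pairwise=pairwise,
        letters=_homogeneous_letters(labels, sig),
    )


def _anova_comparison(metric: str, labels: list[str], samples: list[np.ndarray],
                      alpha: float) -> CountComparison:
    """One-way ANOVA with Bonferroni-corrected pairwise t-tests."""
    if all(np.ptp(s) == 0 for s in samples) and len({s.mean() for s in samples}) == 1:
        stat, p, dof = 0.0, 1.0, float(len(samples) - 1)
    else:
        stat, p = sps.f_oneway(*samples)
        dof = float(len(samples) - 1)
    rows, raw = [], []
    for (l1, s1), (l2, s2) in itertools.combinations(zip(labels, samples), 2):
        if np.ptp(s1) == 0 and np.ptp(s2) == 0 and s1.mean() == s2.mean():
            t, pt = 0.0, 1.0
        else:
            t, pt = sps.ttest_ind(s1, s2)
        rows.append((l1, l2, float(t)))
        raw.append(float(pt))
    adj = _bonferroni(raw)
    pairwise = pd.DataFrame(
        [(l1, l2, s, pr, pa, pa < alpha) for (l1, l2, s), pr, pa in zip(rows, raw, adj)],
        columns=["group1", "group2", "statistic", "p_raw", "p_adj", "significant"],
    )
    sig = {(r.group1, r.group2) for r in pairwise.itertuples() if r.significant}
    return CountComparison(
        metric=metric, statistic=float(stat), df=dof, p_value=float(p),
        pairwise=pairwise, letters=_homogeneous_letters(labels, sig),
    )


def compare_site_counts(summaries: list[DiversitySummary], alpha: float = 0.05) -> SiteCountReport:
    """Compare allelic-pattern statistics across populations.

    Haplotype counts, private-allele counts and polymorphic-locus counts are
    compared with chi-square goodness-of-fit tests against equal expected
    counts; the mean number of alleles per site is compared with a one-way
    ANOVA over per-column allele counts. Pairwise comparisons are
    Bonferroni-corrected and summarized as homogeneous-group letters (groups
    sharing a letter are not significantly different).
    """
    if len(summaries) < 2:
        raise SinglePopulationError("count comparison needs >= 2 populations")
    labels = [s.label for s in summaries]
    comparisons = {}
    for metric, attr in [("n_haplotypes", "n_haplotypes"),
                         ("n_private_alleles", "n_private_alleles"),
                         ("n_polymorphic_sites", "n_polymorphic_sites")]:
        counts = np.array([getattr(s, attr) for s in summaries], dtype=float)
        comparisons[metric] = _chi_square_comparison(metric, labels, counts, alpha)
    if all(s.per_site_allele_counts is not None for s in summaries):
        comparisons["mean_n_alleles_per_site"] = _anova_comparison(
            "mean_n_alleles_per_site", labels,
            [s.per_site_allele_counts for s in summaries], alpha,
        )
    return SiteCountReport(comparisons=comparisons, alpha=alpha)
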
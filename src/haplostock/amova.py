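"""One-level analysis of molecular variance (AMOVA) and PhiPT.

PhiPT is an F_ST analogue for haploid (or binary) data: the among-population
fraction of total molecular variance obtained by partitioning squared
inter-individual distances. With N samples in k populations of sizes n_g:

    SS_total  = (1/N) * sum_{i<j} d_ij^2
    SS_within = sum_g (1/n_g) * sum_{i<j in g} d_ij^2
    SS_among  = SS_total - SS_within
    MS_among  = SS_among / (k - 1),   MS_within = SS_within / (N - k)
    sigma2_w  = MS_within
    sigma2_a  = (MS_among - MS_within) / n0,  n0 = (N - sum n_g^2 / N) / (k - 1)
    PhiPT     = max(0, sigma2_a / (sigma2_a + sigma2_w))

Significance is assessed by permuting individual labels among populations
(group sizes fixed); the one-tailed p-value is
(1 + #{permuted PhiPT >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    BadPermutationCountError,
    SingletonAllGroupsError,
    TooFewSamplesError,
)
from .popgen import DistanceMatrix
from .seqio import BoundDataset


@dataclass
class AmovaResult:
    """Variance partition, PhiPT and permutation significance."""

    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    var_among: float          #: sigma^2_a, truncated at 0
    var_within: float         #: sigma^2_w
    var_among_raw: float      #: sigma^2_a before truncation (may be negative)
    phi_pt: float             #: max(0, sigma^2_a / (sigma^2_a + sigma^2_w))
    pct_among: float
    pct_within: float
    p_value: float | None
    n_permutations: int

    @property
    def ss_total(self) -> float:
        return self.ss_among + self.ss_within

    def to_dict(self) -> dict:
        return {
            "ss_among": self.ss_among, "ss_within": self.ss_within,
            "df_among": self.df_among, "df_within": self.df_within,
            "var_among": self.var_among, "var_within": self.var_within,
            "var_among_raw": self.var_among_raw, "phi_pt": self.phi_pt,
            "pct_among": self.pct_among, "pct_within": self.pct_within,
            "p_value": self.p_value, "n_permutations": self.n_permutations,
        }


def _group_indices(ids: list[str], groups) -> list[np.ndarray]:
    """Resolve a per-sample label mapping/sequence into index arrays."""
    if isinstance(groups, dict):
        labels = [groups[i] for i in ids]
    else:
        labels = list(groups)
        if len(labels) != len(ids):
            raise ValueError("group labels must align with distance-matrix ids")
    order = sorted(set(labels), key=str)
    return [np.flatnonzero(np.array([l == g for l in labels])) for g in order]


def _ss_partition(d2: np.ndarray, idx_groups: list[np.ndarray]) -> tuple[float, float]:
    """(SS_among, SS_within) from a squared-distance matrix and group indices."""
    n_total = sum(len(g) for g in idx_groups)
    ss_total = d2.sum() / (2.0 * n_total)
    ss_within = 0.0
    for g in idx_groups:
        ss_within += d2[np.ix_(g, g)].sum() / (2.0 * len(g))
    return ss_total - ss_within, ss_within


def _phi_from_partition(d2: np.ndarray, idx_groups: list[np.ndarray]) -> tuple[float, dict]:
    k = len(idx_groups)
    sizes = np.array([len(g) for g in idx_groups], dtype=float)
    n_total = int(sizes.sum())
    df_among, df_within = k - 1, n_total - k
    ss_among, ss_within = _ss_partition(d2, idx_groups)
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (n_total - (sizes**2).sum() / n_total) / df_among
    var_among_raw = (ms_among - ms_within) / n0
    var_within = ms_within
    var_among = max(0.0, var_among_raw)
    total = var_among + var_within
    phi = var_among / total if total > 0 else 0.0
    return phi, {
        "ss_among": ss_among, "ss_within": ss_within,
        "df_among": df_among, "df_within": df_within,
        "var_among": var_among, "var_among_raw": var_among_raw,
        "var_within": var_within,
    }


def amova_phipt(dm: DistanceMatrix, groups, n_perm: int = 999,
                seed: int | np.random.SeedSequence | None = None) -> AmovaResult:
    """One-level AMOVA on squared pairwise distances with a permutation test.

    Parameters
    ----------
    dm : DistanceMatrix
        Pairwise nucleotide-difference counts.
    groups : mapping sample_id -> label, or sequence of labels aligned to dm.ids
        Population assignment; >= 2 populations required.
    n_perm : int
        Number of label permutations for the p-value; 0 skips the test.
    seed : int, SeedSequence or None
        Seeds the permutation stream; required for reproducibility.
    """
    if n_perm < 0:
        raise BadPermutationCountError(f"n_perm must be >= 0, got {n_perm}")
    idx_groups = _group_indices(dm.ids, groups)
    if len(idx_groups) < 2:
        raise TooFewSamplesError("AMOVA needs >= 2 populations")
    n_total = sum(len(g) for g in idx_groups)
    if n_total < 3:
        raise TooFewSamplesError("AMOVA needs >= 3 samples")
    if n_total == len(idx_groups):
        raise SingletonAllGroupsError("every group is a singleton; df_within = 0")

    d2 = dm.d.astype(float) ** 2
    phi_obs, parts = _phi_from_partition(d2, idx_groups)

    p_value = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        sizes = [len(g) for g in idx_groups]
        bounds = np.cumsum(sizes)[:-1]
        n_ge = 0
        for _ in range(n_perm):
            perm = rng.permutation(n_total)
            perm_groups = np.split(perm, bounds)
            phi_p, _ = _phi_from_partition(d2, perm_groups)
            if phi_p >= phi_obs - 1e-12:
                n_ge += 1
        p_value = (1 + n_ge) / (1 + n_perm)

    total = parts["var_among"] + parts["var_within"]
    pct_among = 100.0 * parts["var_among"] / total if total > 0 else 0.0
    return AmovaResult(
        ss_among=parts["ss_among"], ss_within=parts["ss_within"],
        df_among=parts["df_among"], df_within=parts["df_within"],
        var_among=parts["var_among"], var_within=parts["var_within"],
        var_among_raw=parts["var_among_raw"], phi_pt=phi_obs,
        pct_among=pct_among, pct_within=100.0 - pct_among,
        p_value=p_value, n_permutations=n_perm,
    )


def pairwise_phipt(dm: DistanceMatrix, groups, n_perm: int = 999,
                   seed: int | None = None) -> pd.DataFrame:
    """All-pairs PhiPT: PhiPT below the diagonal, permutation p above.

    Each population pair is analyzed independently on its sub-matrix, with an
    independent permutation stream spawned from ``seed`` so the result does
    not depend on the order pairs are visited.
    """
    if isinstance(groups, dict):
        labels = [groups[i] for i in dm.ids]
    else:
        labels = list(groups)
    order = sorted(set(labels), key=str)
    out = pd.DataFrame(np.nan, index=order, columns=order, dtype=float)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(order) * (len(order) - 1) // 2)
    label_arr = np.array(labels, dtype=object)
    for child, (g1, g2) in zip(children, itertools.combinations(order, 2)):
        mask = (label_arr == g1) | (label_arr == g2)
        ids = [i for i, m in zip(dm.ids, mask) if m]
        sub = dm.subset(ids)
        sub_labels = label_arr[mask]
        res = amova_phipt(sub, list(sub_labels), n_perm=n_perm, seed=child)
        out.loc[g2, g1] = res.phi_pt          # lower triangle: PhiPT
        out.loc[g1, g2] = res.p_value         # upper triangle: p-value
    return out


@dataclass
class TemporalScanResult:
    """Pairwise PhiPT across site x collection-trip cohorts."""

    matrix: pd.DataFrame
    n_comparisons: int
    n_significant: int
    alpha: float
    cohort_sizes: dict[str, int]

    @property
    def significant_fraction(self) -> float:
        return self.n_significant / self.n_comparisons if self.n_comparisons else 0.0


def temporal_phipt_scan(data: BoundDataset, n_perm: int = 999, seed: int | None = None,
                        alpha: float = 0.05, min_cohort_size: int = 2,
                        epoch: str | None = None) -> TemporalScanResult:
    """Pairwise PhiPT across all site x collection-trip cohorts.

    Supports the temporal-pooling decision: when the fraction of significant
    cohort pairs is close to the test level alpha (the chance expectation),
    temporal samples within a site may be pooled. ``epoch='pre'`` restricts
    the scan to pre-stocking collections.
    """
    meta = data.meta.df
    keep = meta.index if epoch is None else meta.index[meta["stocking_epoch"] == epoch]
    sub = data.subset(list(keep))
    cohorts = {c: ids for c, ids in sub.group_ids("site_cohort").items()
               if len(ids) >= min_cohort_size}
    if len(cohorts) < 2:
        raise TooFewSamplesError("temporal scan needs >= 2 cohorts")
    ids = [i for c in cohorts.values() for i in c]
    labels = {i: c for c, members in cohorts.items() for i in members}
    from .popgen import pairwise_distances

    dm = pairwise_distances(sub.seqs.subset(ids))
    matrix = pairwise_phipt(dm, labels, n_perm=n_perm, seed=seed)
    order = list(matrix.index)
    n_comp = len(order) * (len(order) - 1) // 2
    n_sig = sum(
        1 for g1, g2 in itertools.combinations(order, 2)
        if pd.notna(matrix.loc[g1, g2]) and matrix.loc[g1, g2] < alpha
    )
    return TemporalScanResult(
        matrix=matrix, n_comparisons=n_comp, n_significant=n_sig, alpha=alpha,
        cohort_sizes={c: len(v) for c, v in cohorts.items()},
    )
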
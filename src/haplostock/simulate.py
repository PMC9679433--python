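"""Seeded simulator of mtDNA control-region datasets with family structure.

The generator emulates the statistical features the stocking-signal analysis
relies on, without a coalescent model:

* a large panmictic wild haplotype pool built column-by-column so that the
  expected mean pairwise per-site divergence equals ``target_pi`` over the
  designated fraction of polymorphic columns — two random wild draws are
  nearly always distinct, and the residual collision rate (finite pool)
  produces the background sharing seen at unstocked reference sites;
* hatchery cohorts descended from few dams with skewed family sizes
  (lognormal fecundity by default); offspring inherit the dam haplotype
  exactly, since the marker is maternally inherited and release-to-recapture
  spans months, not generations;
* estuary time series mixing wild recruits with hatchery families at a
  per-cohort hatchery fraction m (m = 0 at reference sites, m = 1 in a
  closed lagoon shortly after release, declining after it re-opens).

Everything is driven by a single ``numpy`` Generator seeded from the config,
so identical configs produce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import InfeasibleConfigError
from .seqio import (
    AlignedSeqSet,
    BoundDataset,
    SampleFrame,
    bind,
    build_sample_frame,
    write_alignment,
)

_BASES = np.array(list("ACGT"))


@dataclass
class ReleaseSpec:
    """One stocking release event at a site."""

    date: str
    count: int


@dataclass
class CohortSpec:
    """One collection trip: date, sample size and true hatchery fraction."""

    date: str
    n: int
    hatchery_fraction: float = 0.0


@dataclass
class SiteSpec:
    """A sampled estuary: stocked or reference, with its collection trips."""

    name: str
    treatment: str  # "stocked" | "reference"
    cohorts: list[CohortSpec]
    releases: list[ReleaseSpec] = field(default_factory=list)
    closed: bool = False  # intermittently-closed lagoon (no natural recruits)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic mtCR dataset.

    Defaults describe a hypervariable ~716 bp control-region fragment:
    ~41% of columns polymorphic, mean pairwise divergence 2.3% per site, a
    wild pool large enough that reference-site sharing stays at the ~1-2%
    background level, and a hatchery whose releases stem from few dams with
    lognormally skewed fecundity.
    """

    seed: int = 0
    length: int = 716
    target_pi: float = 0.023
    polymorphic_fraction: float = 294 / 716
    wild_pool_size: int = 12000
    n_dams: int = 46                  #: wild-caught spawners held in the hatchery
    n_broodstock_sampled: int = 46    #: dams genotyped as the broodstock sample
    n_families: int = 9               #: dams contributing offspring per stocked site
    family_size_law: str = "lognormal"  # "lognormal" | "equal"
    family_sigma: float = 1.0
    background_sharing_target: float = 1.5  #: percent, reference-site sharing
    hatchery_site_name: str = "Hatchery"
    broodstock_date: str = "2015-11-01"
    sites: list[SiteSpec] = field(default_factory=list)

    # -- validation --------------------------------------------------------

    @property
    def n_polymorphic_columns(self) -> int:
        return int(np.ceil(self.polymorphic_fraction * self.length))

    def per_column_heterozygosity(self) -> float:
        """Target probability that two random draws differ at one variable column."""
        return self.target_pi * self.length / self.n_polymorphic_columns

    def validate(self) -> None:
        if self.length < 1:
            raise InfeasibleConfigError("alignment length must be >= 1")
        if not 0.0 <= self.polymorphic_fraction <= 1.0:
            raise InfeasibleConfigError("polymorphic_fraction must be in [0, 1]")
        if self.target_pi < 0:
            raise InfeasibleConfigError("target_pi must be >= 0")
        if self.target_pi > 0 and self.n_polymorphic_columns == 0:
            raise InfeasibleConfigError("target_pi > 0 needs polymorphic columns")
        # with at most 4 equifrequent alleles per column the per-column
        # heterozygosity cannot exceed 3/4
        if self.target_pi > 0 and self.per_column_heterozygosity() > 0.75:
            raise InfeasibleConfigError(
                f"target_pi={self.target_pi} unreachable with polymorphic "
                f"fraction {self.polymorphic_fraction}: per-column "
                f"heterozygosity {self.per_column_heterozygosity():.3f} > 0.75"
            )
        if self.background_sharing_target > 0 and (
            self.wild_pool_size < 100.0 / self.background_sharing_target
        ):
            raise InfeasibleConfigError(
                "wild pool too small: two random draws collide more often "
                "than the background sharing target"
            )
        if self.n_families < 1 or self.n_families > self.n_dams:
            raise InfeasibleConfigError("need 1 <= n_families <= n_dams")
        if self.n_broodstock_sampled > self.n_dams:
            raise InfeasibleConfigError("cannot sample more broodstock than dams")
        if self.wild_pool_size <= self.n_dams:
            raise InfeasibleConfigError("wild pool must exceed the number of dams")
        if self.family_size_law not in ("lognormal", "equal"):
            raise InfeasibleConfigError(f"unknown family_size_law {self.family_size_law!r}")
        for site in self.sites:
            if site.treatment not in ("stocked", "reference"):
                raise InfeasibleConfigError(f"unknown treatment {site.treatment!r}")
            for cohort in site.cohorts:
                if not 0.0 <= cohort.hatchery_fraction <= 1.0:
                    raise InfeasibleConfigError("hatchery_fraction must be in [0, 1]")
                if site.treatment == "reference" and cohort.hatchery_fraction > 0:
                    raise InfeasibleConfigError(
                        f"reference site {site.name!r} has hatchery_fraction > 0"
                    )

    # -- (de)serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        sites = [
            SiteSpec(
                name=s["name"], treatment=s["treatment"],
                cohorts=[CohortSpec(**c) for c in s["cohorts"]],
                releases=[ReleaseSpec(**r) for r in s.get("releases", [])],
                closed=s.get("closed", False),
            )
            for s in d.pop("sites", [])
        ]
        return cls(sites=sites, **d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# wild pool

def _make_pool(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Distinct wild haplotypes as an integer-coded (W, L) matrix.

    Variable columns use two alleles (ancestral major plus one minor) when
    the per-column target heterozygosity allows (h <= 1/2), otherwise one
    major and three equifrequent minors (feasible up to h = 3/4); minor
    frequencies solve 2q(1-q) = h, resp. 6q - 12q^2 = h, so the expected
    mean pairwise per-site divergence equals target_pi by construction.
    """
    L, W = cfg.length, cfg.wild_pool_size
    n_var = cfg.n_polymorphic_columns if cfg.target_pi > 0 else 0
    ancestral = rng.integers(0, 4, size=L, dtype=np.int8)
    pool = np.tile(ancestral, (W, 1))
    if n_var:
        het = cfg.per_column_heterozygosity()
        var_idx = np.sort(rng.choice(L, size=n_var, replace=False))
        if het <= 0.5:
            q = (1.0 - np.sqrt(1.0 - 2.0 * het)) / 2.0
            minor_p = np.array([q])
        else:
            q = (3.0 - np.sqrt(9.0 - 12.0 * het)) / 12.0
            minor_p = np.array([q, q, q])
        for col in var_idx:
            major = ancestral[col]
            minors = np.array([b for b in range(4) if b != major], dtype=np.int8)
            probs = np.zeros(4)
            probs[major] = 1.0 - minor_p.sum()
            probs[minors[: len(minor_p)]] = minor_p
            pool[:, col] = rng.choice(4, size=W, p=probs).astype(np.int8)
    # enforce distinctness: redraw duplicate rows on the variable columns
    if n_var:
        seen: dict[bytes, int] = {}
        dup_rows = []
        for i in range(W):
            key = pool[i, var_idx].tobytes()
            if key in seen:
                dup_rows.append(i)
            else:
                seen[key] = i
        while dup_rows:
            still = []
            for i in dup_rows:
                for col in var_idx:
                    major = ancestral[col]
                    minors = np.array([b for b in range(4) if b != major], dtype=np.int8)
                    probs = np.zeros(4)
                    probs[major] = 1.0 - minor_p.sum()
                    probs[minors[: len(minor_p)]] = minor_p
                    pool[i, col] = rng.choice(4, p=probs)
                key = pool[i, var_idx].tobytes()
                if key in seen:
                    still.append(i)
                else:
                    seen[key] = i
            dup_rows = still
    elif W > 1 and cfg.target_pi == 0:
        pass  # identical haplotypes are intended when target_pi = 0
    return pool


def _codes_to_seqset(codes: np.ndarray, ids: list[str]) -> AlignedSeqSet:
    return AlignedSeqSet(ids=ids, matrix=_BASES[codes])


def simulate_wild_pool(cfg: SimulationConfig,
                       rng: np.random.Generator | None = None) -> AlignedSeqSet:
    """The wild haplotype pool as an alignment (one record per haplotype)."""
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pool = _make_pool(cfg, rng)
    ids = [f"hap{i:05d}" for i in range(pool.shape[0])]
    return _codes_to_seqset(pool, ids)


# ---------------------------------------------------------------------------
# hatchery families

def _family_weights(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.family_size_law == "equal":
        w = np.ones(cfg.n_families)
    else:
        w = rng.lognormal(mean=0.0, sigma=cfg.family_sigma, size=cfg.n_families)
    return w / w.sum()


def simulate_hatchery_cohort(cfg: SimulationConfig, n: int = 250,
                             rng: np.random.Generator | None = None,
                             pool: np.ndarray | None = None,
                             ) -> tuple[AlignedSeqSet, np.ndarray]:
    """A hatchery offspring cohort and its true maternal-family labels.

    Draws ``n_families`` dam haplotypes from the wild pool, assigns the ``n``
    offspring to dams according to the family-size law, and gives each
    offspring its dam's haplotype exactly (matroclinous inheritance, no
    mutation over a single release season). Returns the cohort alignment and
    an integer family label per offspring.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if pool is None:
        pool = _make_pool(cfg, rng)
    dam_rows = rng.choice(pool.shape[0], size=cfg.n_families, replace=False)
    weights = _family_weights(cfg, rng)
    families = rng.choice(cfg.n_families, size=n, p=weights)
    codes = pool[dam_rows[families]]
    ids = [f"off{i:04d}" for i in range(n)]
    return _codes_to_seqset(codes, ids), families


# ---------------------------------------------------------------------------
# estuary time series

@dataclass
class SimulatedDataset:
    """A full synthetic study: bound dataset plus per-sample ground truth."""

    data: BoundDataset
    truth: pd.DataFrame  # sample_id, origin, family, pool_index
    config: SimulationConfig

    def write(self, outdir) -> dict[str, str]:
        """Write FASTA + metadata CSV + release-calendar CSV + truth CSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "fasta": outdir / "alignment.fasta",
            "metadata": outdir / "metadata.csv",
            "calendar": outdir / "release_calendar.csv",
            "truth": outdir / "truth.csv",
        }
        write_alignment(self.data.seqs, paths["fasta"])
        meta = self.data.meta.df.reset_index()[
            ["sample_id", "site", "collection_date", "role"]
        ].copy()
        meta["collection_date"] = pd.to_datetime(meta["collection_date"]).dt.strftime("%Y-%m-%d")
        meta.to_csv(paths["metadata"], index=False)
        cal = self.data.release_calendar.copy()
        cal["release_date"] = pd.to_datetime(cal["release_date"]).dt.strftime("%Y-%m-%d")
        cal.to_csv(paths["calendar"], index=False)
        self.truth.to_csv(paths["truth"], index=False)
        return {k: str(v) for k, v in paths.items()}


def simulate_estuary_timeseries(cfg: SimulationConfig) -> SimulatedDataset:
    """Simulate the full multi-site sampling design.

    Per cohort, each sampled individual is hatchery-origin with the cohort's
    hatchery fraction (drawing a dam by family weight) and otherwise a
    uniform draw from the non-dam wild pool (dams are physically removed
    from the wild, so broodstock matches at reference sites can only be
    false positives — which the finite pool makes impossible here by
    construction). Broodstock are a subset of the dams.
    """
    cfg.validate()
    if not cfg.sites:
        raise InfeasibleConfigError("no sites configured")
    rng = np.random.default_rng(cfg.seed)
    pool = _make_pool(cfg, rng)
    W = pool.shape[0]
    dam_rows = rng.choice(W, size=cfg.n_dams, replace=False)
    wild_rows = np.setdiff1d(np.arange(W), dam_rows)

    rows = []  # (sample_id, site, date, role, origin, family, pool_index)
    for site in cfg.sites:
        counter = 0
        if site.treatment == "stocked":
            fam_dams = rng.choice(dam_rows, size=cfg.n_families, replace=False)
            fam_weights = _family_weights(cfg, rng)
        for cohort in site.cohorts:
            m = cohort.hatchery_fraction
            for _ in range(cohort.n):
                sid = f"{site.name}_{counter:04d}"
                counter += 1
                if m > 0 and rng.random() < m:
                    fam = int(rng.choice(cfg.n_families, p=fam_weights))
                    rows.append((sid, site.name, cohort.date, "estuary",
                                 "hatchery", f"dam{fam_dams[fam]:05d}",
                                 int(fam_dams[fam])))
                else:
                    idx = int(wild_rows[rng.integers(len(wild_rows))])
                    rows.append((sid, site.name, cohort.date, "estuary",
                                 "wild", "", idx))
    if cfg.n_broodstock_sampled:
        sampled = rng.choice(dam_rows, size=cfg.n_broodstock_sampled, replace=False)
        for k, idx in enumerate(sampled):
            rows.append((f"Brood_{k:03d}", cfg.hatchery_site_name,
                         cfg.broodstock_date, "broodstock",
                         "broodstock", f"dam{idx:05d}", int(idx)))

    frame = pd.DataFrame(
        rows, columns=["sample_id", "site", "collection_date", "role",
                       "origin", "family", "pool_index"],
    )
    seqs = _codes_to_seqset(
        pool[frame["pool_index"].to_numpy()], list(frame["sample_id"])
    )
    cal_rows = []
    for site in cfg.sites:
        if site.releases:
            for rel in site.releases:
                cal_rows.append((site.name, rel.date, rel.count))
        else:
            # reference sites appear with a zero-count row so they are known
            cal_rows.append((site.name, site.cohorts[0].date, 0))
    calendar = pd.DataFrame(cal_rows, columns=["site", "release_date", "count"])
    calendar["release_date"] = pd.to_datetime(calendar["release_date"])
    meta = build_sample_frame(
        frame[["sample_id", "site", "collection_date", "role"]], calendar
    )
    data = bind(seqs, meta, calendar)
    truth = frame[["sample_id", "origin", "family", "pool_index"]]
    return SimulatedDataset(data=data, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# canned scenarios

def default_scenario(seed: int = 0) -> SimulationConfig:
    """The reference study design: two stocked and two reference estuaries.

    Mirrors a two-season release program monitored over ~2 years: reference
    estuaries (never stocked), an ocean-open stocked estuary where hatchery
    recruits are diluted by natural recruitment, and a closed lagoon where
    all early post-release samples are hatchery-origin, with the fraction
    declining after the lagoon re-opens to the sea. Sample sizes per site
    follow the monitoring design (168-253 per estuary plus 46 broodstock).
    """
    pre = lambda d, n: CohortSpec(date=d, n=n, hatchery_fraction=0.0)
    return SimulationConfig(
        seed=seed,
        sites=[
            SiteSpec(
                name="Durras", treatment="reference",
                cohorts=[pre("2014-10-15", 25), pre("2014-11-15", 26),
                         pre("2015-01-15", 20), pre("2015-04-15", 20),
                         pre("2015-07-15", 20), pre("2015-11-15", 20),
                         pre("2016-03-15", 20), pre("2016-08-15", 17)],
            ),
            SiteSpec(
                name="Corunna", treatment="reference",
                cohorts=[pre("2014-10-15", 25), pre("2014-11-15", 25),
                         pre("2015-01-15", 20), pre("2015-04-15", 20),
                         pre("2015-07-15", 20), pre("2015-11-15", 20),
                         pre("2016-03-15", 20), pre("2016-08-15", 20)],
            ),
            SiteSpec(
                name="Tabourie", treatment="stocked",
                releases=[ReleaseSpec("2014-12-15", 260_000),
                          ReleaseSpec("2015-12-15", 1_305_000)],
                cohorts=[pre("2014-10-15", 25), pre("2014-11-15", 25),
                         CohortSpec("2015-02-15", 30, 0.08),
                         CohortSpec("2015-05-15", 30, 0.08),
                         CohortSpec("2015-09-15", 30, 0.08),
                         CohortSpec("2016-01-15", 32, 0.08),
                         CohortSpec("2016-05-15", 31, 0.08),
                         CohortSpec("2016-09-15", 31, 0.08)],
            ),
            SiteSpec(
                name="Wallagoot", treatment="stocked", closed=True,
                releases=[ReleaseSpec("2014-12-15", 726_000),
                          ReleaseSpec("2015-12-15", 3_501_000)],
                # closed to the sea until Oct 2015: early cohorts are pure
                # hatchery; the fraction halves per trip after re-opening
                cohorts=[CohortSpec("2015-01-15", 40, 1.0),
                         CohortSpec("2015-03-15", 45, 1.0),
                         CohortSpec("2015-05-15", 30, 1.0),
                         CohortSpec("2015-12-20", 46, 0.5),
                         CohortSpec("2016-03-15", 46, 0.25),
                         CohortSpec("2016-08-15", 46, 0.125)],
            ),
        ],
    )


def mixture_scenario(m: float, seed: int = 0, n_stocked: int = 250,
                     n_reference: int = 170, n_cohorts: int = 5,
                     closed: bool = True) -> SimulationConfig:
    """A single stocked site at hatchery fraction ``m`` plus two references.

    Used for parameter-recovery experiments: the stocked site's cohorts all
    carry the same true hatchery fraction, so the background-corrected
    sharing estimate can be compared against the expected sharing implied by
    the family-size law.
    """
    per = [n_stocked // n_cohorts] * n_cohorts
    per[-1] += n_stocked - sum(per)
    dates = [f"2015-{month:02d}-15" for month in range(1, n_cohorts + 1)]
    stocked = SiteSpec(
        name="StockedLake", treatment="stocked", closed=closed,
        releases=[ReleaseSpec("2014-12-15", 500_000)],
        cohorts=[CohortSpec(d, n, m) for d, n in zip(dates, per)],
    )
    refs = [
        SiteSpec(
            name=name, treatment="reference",
            cohorts=[CohortSpec("2014-10-15", n_reference // 2, 0.0),
                     CohortSpec("2015-06-15", n_reference - n_reference // 2, 0.0)],
        )
        for name in ("RefA", "RefB")
    ]
    return SimulationConfig(seed=seed, sites=refs + [stocked])


def expected_sharing_pct(cfg: SimulationConfig, n: int, m: float,
                         rng: np.random.Generator, n_rep: int = 400) -> float:
    """Expected percent of individuals sharing a haplotype in a mixed sample.

    Monte-Carlo expectation computed directly from the generator's counting
    laws (family weights, multinomial assignment, uniform wild-pool draws)
    without building any sequences — an independent oracle for the sharing
    statistics. A hatchery individual shares when >= 2 sampled individuals
    carry its dam's haplotype; a wild individual shares only via a pool
    collision.
    """
    W_eff = cfg.wild_pool_size - cfg.n_dams
    total = 0.0
    for _ in range(n_rep):
        h = rng.binomial(n, m)
        counts = np.zeros(0, dtype=int)
        if h:
            weights = _family_weights(cfg, rng)
            counts = rng.multinomial(h, weights)
        wild = rng.integers(0, W_eff, size=n - h)
        _, wild_counts = np.unique(wild, return_counts=True)
        n_sharing = int(counts[counts >= 2].sum()) + int(
            wild_counts[wild_counts >= 2].sum()
        )
        total += n_sharing / n
    return 100.0 * total / n_rep
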
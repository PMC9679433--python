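"""Reading, validating and binding aligned mtDNA sequences and sample metadata.

The analysis operates on an aligned haploid marker (here, the mitochondrial
control region). Alignment itself is an upstream step performed with standard
tools; this module only validates that input sequences have equal length and a
clean alphabet, and joins them to per-sample metadata (site, collection date,
role) and the per-site stocking release calendar.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import (
    DuplicateSampleIdError,
    EmptyInputError,
    IdMismatchError,
    IllegalCharacterError,
    MissingColumnError,
    RaggedAlignmentError,
    UnknownSiteError,
    UnparseableDateError,
)

logger = logging.getLogger(__name__)

#: canonical single-character alphabet after normalization
ALPHABET = ("A", "C", "G", "T", "N", "-")

#: IUPAC ambiguity codes collapsed to N (a single missing-data symbol)
_AMBIGUITY = set("RYSWKMBDHV")

#: integer codes used for distance computations; -1 marks missing (N or gap)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": -1, "-": -1}


@dataclass
class AlignedSeqSet:
    """An aligned set of haploid sequences keyed by sample id.

    Attributes
    ----------
    ids : list of str
        Ordered, unique sample identifiers (FASTA record ids).
    matrix : ndarray of shape (n, length), dtype '<U1'
        Uppercase character matrix over the alphabet {A, C, G, T, N, -}.
    """

    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype="<U1")
        if self.matrix.ndim != 2:
            raise RaggedAlignmentError("sequence matrix must be 2-dimensional")
        if len(self.ids) != self.matrix.shape[0]:
            raise ValueError("ids and matrix row count differ")
        if len(set(self.ids)) != len(self.ids):
            dupes = {i for i in self.ids if self.ids.count(i) > 1}
            raise DuplicateSampleIdError(f"duplicate sequence ids: {sorted(dupes)}")
        if any(not i for i in self.ids):
            raise ValueError("empty sample id")
        bad = set(np.unique(self.matrix)) - set(ALPHABET)
        if bad:
            raise IllegalCharacterError(f"illegal characters after normalization: {sorted(bad)}")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        """Alignment length in bp."""
        return self.matrix.shape[1]

    @classmethod
    def from_strings(cls, ids: Iterable[str], seqs: Iterable[str]) -> "AlignedSeqSet":
        """Build from raw sequence strings, normalizing case and ambiguity codes."""
        ids = list(ids)
        seqs = [normalize_sequence(s, sid) for sid, s in zip(ids, seqs)]
        if not seqs:
            raise EmptyInputError("no sequences provided")
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise RaggedAlignmentError(f"unequal aligned lengths: {sorted(lengths)}")
        matrix = np.array([list(s) for s in seqs], dtype="<U1")
        return cls(ids=ids, matrix=matrix)

    def sequence(self, i: int) -> str:
        """Return row ``i`` as a plain string."""
        return "".join(self.matrix[i])

    def sequences(self) -> list[str]:
        return ["".join(row) for row in self.matrix]

    def codes(self) -> np.ndarray:
        """Integer-coded matrix: A,C,G,T -> 0..3; N and gap -> -1 (missing)."""
        out = np.empty(self.matrix.shape, dtype=np.int8)
        for ch, code in _CODE.items():
            out[self.matrix == ch] = code
        return out

    def subset(self, ids: Iterable[str]) -> "AlignedSeqSet":
        """Row subset in the given id order."""
        index = {sid: i for i, sid in enumerate(self.ids)}
        ids = list(ids)
        missing = [i for i in ids if i not in index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        rows = [index[i] for i in ids]
        return AlignedSeqSet(ids=ids, matrix=self.matrix[rows])


def normalize_sequence(seq: str, sample_id: str = "?") -> str:
    """Uppercase a sequence and collapse IUPAC ambiguity codes to N.

    Symbols outside the IUPAC nucleotide alphabet raise
    :class:`IllegalCharacterError`; ambiguity codes other than N are converted
    to N with a logged warning, since downstream statistics use a single
    missing-data symbol.
    """
    up = seq.upper()
    out = []
    n_ambiguous = 0
    for ch in up:
        if ch in "ACGTN-":
            out.append(ch)
        elif ch in _AMBIGUITY:
            out.append("N")
            n_ambiguous += 1
        else:
            raise IllegalCharacterError(f"illegal character {ch!r} in sequence {sample_id!r}")
    if n_ambiguous:
        logger.warning(
            "sequence %s: %d IUPAC ambiguity code(s) converted to N", sample_id, n_ambiguous
        )
    return "".join(out)


def read_alignment(path) -> AlignedSeqSet:
    """Read an aligned FASTA file into an :class:`AlignedSeqSet`.

    All records must have identical length (the input is an alignment, not a
    read set). Lowercase letters are uppercased and ambiguity codes collapsed
    to N.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise DuplicateSampleIdError(f"duplicate FASTA ids: {dupes}")
    return AlignedSeqSet.from_strings(ids, [str(r.seq) for r in records])


def write_alignment(seqs: AlignedSeqSet, path) -> None:
    """Write an alignment as single-line-per-record FASTA."""
    records = [
        SeqRecord(Seq(seqs.sequence(i)), id=sid, description="")
        for i, sid in enumerate(seqs.ids)
    ]
    SeqIO.write(records, str(path), "fasta-2line")


# ---------------------------------------------------------------------------
# metadata

_REQUIRED_COLUMNS = ("sample_id", "site", "collection_date", "role")
_ROLES = {"estuary", "broodstock"}


@dataclass
class SampleFrame:
    """Per-sample metadata table.

    ``df`` is indexed by sample_id with columns ``site``, ``collection_date``
    (datetime), ``role`` (estuary | broodstock), ``site_treatment``
    (stocked | reference | hatchery) and ``stocking_epoch`` (pre | post,
    relative to the first release at the sample's site).
    """

    df: pd.DataFrame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    def sites(self, role: str | None = "estuary") -> list[str]:
        sub = self.df if role is None else self.df[self.df["role"] == role]
        return sorted(sub["site"].unique())

    def subset(self, ids: Iterable[str]) -> "SampleFrame":
        return SampleFrame(self.df.loc[list(ids)])


def _parse_dates(series: pd.Series, what: str) -> pd.Series:
    try:
        return pd.to_datetime(series, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise UnparseableDateError(f"unparseable {what} date: {exc}") from exc


def read_release_calendar(path) -> pd.DataFrame:
    """Read the per-site release calendar CSV (site, release_date, count).

    Reference sites appear with count 0; the set of sites in the calendar
    defines the known estuaries.
    """
    cal = pd.read_csv(path)
    missing = {"site", "release_date", "count"} - set(cal.columns)
    if missing:
        raise MissingColumnError(f"release calendar missing columns: {sorted(missing)}")
    cal = cal.copy()
    cal["release_date"] = _parse_dates(cal["release_date"], "release")
    cal["count"] = cal["count"].astype(int)
    return cal


def first_release_dates(calendar: pd.DataFrame) -> dict[str, pd.Timestamp]:
    """First actual (count > 0) release date per stocked site."""
    actual = calendar[calendar["count"] > 0]
    return actual.groupby("site")["release_date"].min().to_dict()


def build_sample_frame(meta: pd.DataFrame, calendar: pd.DataFrame) -> SampleFrame:
    """Validate a raw metadata table and derive per-sample fields.

    ``meta`` needs columns sample_id, site, collection_date, role (dates may
    be strings or datetimes). ``site_treatment`` is hatchery for broodstock,
    stocked for sites with at least one non-zero release, reference otherwise.
    ``stocking_epoch`` is pre when the collection date is strictly earlier
    than the site's first release (reference sites and broodstock are always
    pre). Estuary sites absent from the calendar are rejected.
    """
    present = set(meta.columns)
    if meta.index.name == "sample_id":
        present.add("sample_id")
    missing = set(_REQUIRED_COLUMNS) - present
    if missing:
        raise MissingColumnError(f"metadata missing columns: {sorted(missing)}")
    meta = meta.copy()
    if meta.index.name != "sample_id":
        if meta["sample_id"].duplicated().any():
            dupes = sorted(meta.loc[meta["sample_id"].duplicated(), "sample_id"].unique())
            raise DuplicateSampleIdError(f"duplicate sample ids in metadata: {dupes}")
        meta = meta.set_index("sample_id")
    elif meta.index.duplicated().any():
        raise DuplicateSampleIdError("duplicate sample ids in metadata")
    bad_roles = set(meta["role"]) - _ROLES
    if bad_roles:
        raise MissingColumnError(f"unknown role values: {sorted(bad_roles)}")
    if not pd.api.types.is_datetime64_any_dtype(meta["collection_date"]):
        meta["collection_date"] = _parse_dates(meta["collection_date"], "collection")

    known_sites = set(calendar["site"])
    first_release = first_release_dates(calendar)

    estuary = meta["role"] == "estuary"
    unknown = sorted(set(meta.loc[estuary, "site"]) - known_sites)
    if unknown:
        raise UnknownSiteError(f"estuary sites absent from release calendar: {unknown}")

    treatment = pd.Series("reference", index=meta.index)
    treatment[meta["site"].isin(first_release)] = "stocked"
    treatment[~estuary] = "hatchery"
    meta["site_treatment"] = treatment

    epoch = pd.Series("pre", index=meta.index)
    for site, date in first_release.items():
        at_site = estuary & (meta["site"] == site)
        epoch[at_site & (meta["collection_date"] >= date)] = "post"
    meta["stocking_epoch"] = epoch
    return SampleFrame(meta)


def read_metadata(path, release_calendar_path) -> tuple[SampleFrame, pd.DataFrame]:
    """Read sample metadata and the release calendar; derive per-sample fields.

    See :func:`build_sample_frame` for the derivation rules.
    """
    meta = pd.read_csv(path, dtype={"sample_id": str})
    calendar = read_release_calendar(release_calendar_path)
    return build_sample_frame(meta, calendar), calendar


# ---------------------------------------------------------------------------
# binding

@dataclass
class BoundDataset:
    """Sequences, metadata and the release calendar joined on sample id.

    Metadata rows are re-ordered to follow the sequence order, so positional
    indexing is consistent across the two.
    """

    seqs: AlignedSeqSet
    meta: SampleFrame
    release_calendar: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["site", "release_date", "count"])
    )

    @property
    def n(self) -> int:
        return self.seqs.n

    def cohort_labels(self) -> pd.Series:
        """site × collection-trip label per sample, e.g. ``Durras:2014-10-15``."""
        df = self.meta.df
        return df["site"] + ":" + df["collection_date"].dt.strftime("%Y-%m-%d")

    def group_ids(self, by: str) -> dict[str, list[str]]:
        """Partition sample ids by a grouping key.

        Supported keys: ``all``, ``site``, ``site_cohort``, or any metadata
        column name. Groups are returned in sorted label order and are
        disjoint and exhaustive.
        """
        from .errors import UnknownGroupKeyError

        df = self.meta.df
        if by == "all":
            return {"all": list(df.index)}
        if by == "site_cohort":
            labels = self.cohort_labels()
        elif by in df.columns:
            labels = df[by]
        else:
            raise UnknownGroupKeyError(f"unknown grouping key {by!r}")
        return {
            str(label): list(sub.index)
            for label, sub in sorted(df.groupby(labels, sort=True), key=lambda kv: str(kv[0]))
        }

    def subset(self, ids: Iterable[str]) -> "BoundDataset":
        ids = list(ids)
        return BoundDataset(
            seqs=self.seqs.subset(ids),
            meta=self.meta.subset(ids),
            release_calendar=self.release_calendar,
        )


def bind(seqs: AlignedSeqSet, meta: SampleFrame,
         release_calendar: pd.DataFrame | None = None) -> BoundDataset:
    """Join sequences and metadata into a :class:`BoundDataset`.

    The two id sets must coincide; otherwise :class:`IdMismatchError` reports
    both one-sided differences.
    """
    seq_ids = set(seqs.ids)
    meta_ids = set(meta.df.index)
    if seq_ids != meta_ids:
        raise IdMismatchError(seq_ids - meta_ids, meta_ids - seq_ids)
    meta = SampleFrame(meta.df.loc[seqs.ids])
    if release_calendar is None:
        release_calendar = pd.DataFrame(columns=["site", "release_date", "count"])
    return BoundDataset(seqs=seqs, meta=meta, release_calendar=release_calendar)
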
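"""Exception hierarchy for haplostock.

All package-specific failures derive from :class:`HaplostockError` so callers
(and the CLI) can distinguish analysis errors from programming errors.
"""


class HaplostockError(Exception):
    """Base class for all haplostock errors."""


# --- sequence / metadata input -------------------------------------------

class RaggedAlignmentError(HaplostockError):
    """Input FASTA records do not all have the same aligned length."""


class EmptyInputError(HaplostockError):
    """An input file or dataset contained no usable records."""


class IllegalCharacterError(HaplostockError):
    """A sequence contains a symbol outside the IUPAC nucleotide alphabet."""


class MissingColumnError(HaplostockError):
    """A required metadata column is absent."""


class DuplicateSampleIdError(HaplostockError):
    """The same sample identifier appears more than once."""


class UnparseableDateError(HaplostockError):
    """A collection or release date could not be parsed as ISO-8601."""


class UnknownSiteError(HaplostockError):
    """A sample references a site absent from the release calendar."""


class IdMismatchError(HaplostockError):
    """Sequence and metadata sample-id sets differ.

    Carries the two one-sided difference lists so the caller can report
    exactly which ids are missing from which input.
    """

    def __init__(self, only_in_seqs, only_in_meta):
        self.only_in_seqs = sorted(only_in_seqs)
        self.only_in_meta = sorted(only_in_meta)
        super().__init__(
            f"sample ids do not match: {len(self.only_in_seqs)} only in "
            f"sequences {self.only_in_seqs[:5]}..., {len(self.only_in_meta)} "
            f"only in metadata {self.only_in_meta[:5]}..."
        )


# --- statistics ------------------------------------------------------------

class UnknownGroupKeyError(HaplostockError):
    """Grouping key is not one of the supported keys or metadata columns."""


class TooFewSamplesError(HaplostockError):
    """A statistic requiring n >= 2 was requested on fewer samples."""


class NoComparablePairsError(HaplostockError):
    """Some sequence pair has zero mutually non-missing sites."""


class SinglePopulationError(HaplostockError):
    """Private alleles are undefined with fewer than two populations."""


class DegenerateCountsError(HaplostockError):
    """All observed counts are zero; the test statistic is undefined."""


class SingletonAllGroupsError(HaplostockError):
    """Every group has a single member, so within-group variance is undefined."""


class BadPermutationCountError(HaplostockError):
    """Number of permutations must be a positive integer."""


# --- stocking signal -------------------------------------------------------

class NoReferencesError(HaplostockError):
    """Contribution estimation requires at least one reference site."""


class EmptyBroodstockError(HaplostockError):
    """Broodstock haplotype table is empty."""


# --- simulation ------------------------------------------------------------

class InfeasibleConfigError(HaplostockError):
    """Simulation parameters are mutually inconsistent or out of range."""
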
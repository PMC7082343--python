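"""Curation of a *nifH* reference sequence database.

Raw candidate records (e.g. keyword-harvested nitrogenase reductase entries
from a public nucleotide archive) are reduced to a usable reference set by
three filters: (1) drop sequences from unidentified organisms, (2) drop
sequences shorter than 200 bp or longer than 1 kb, and (3) drop sequences not
flanked by start and stop codons.  Amplicon-side, a simple length window
(330-370 bp for *nifH*) removes off-target merges.

Records carry a ranked taxonomic lineage (domain..species) used downstream for
conserved-rank host inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

#: Canonical rank order, shallow to deep.
RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

#: Organism-name substrings that mark a record as taxonomically anonymous,
#: following common NCBI naming conventions for environmental sequences.
UNIDENTIFIED_TOKENS = (
    "uncultured",
    "unidentified",
    "unclassified",
    "environmental sample",
    "metagenome",
)

#: Bacterial start codons (alternative starts are common in nifH).
START_CODONS = frozenset({"ATG", "GTG", "TTG"})
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

_IUPAC_NT = frozenset("ACGTUNRYSWKMBDHV")
_GAP_CHARS = frozenset("-.")

# Filter identifiers, in application order.
FILTER_MALFORMED = "malformed"
FILTER_UNIDENTIFIED = "unidentified"
FILTER_LENGTH = "length"
FILTER_CODON_FLANKS = "codon_flanks"


def ungapped(sequence: str) -> str:
    """Sequence with alignment gap characters removed, uppercased."""
    return "".join(c for c in sequence.upper() if c not in _GAP_CHARS)


@dataclass(frozen=True)
class RawRecord:
    """One candidate reference sequence prior to curation.

    ``lineage`` is an ordered tuple of ``(rank, name)`` pairs, ranks drawn
    from :data:`RANKS`, strictly ordered shallow to deep; ranks may be absent.
    """

    id: str
    sequence: str
    organism_name: str = ""
    lineage: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        last = -1
        for rank, _ in self.lineage:
            if rank not in _RANK_INDEX:
                raise ValueError(f"record {self.id!r}: unknown rank {rank!r}")
            idx = _RANK_INDEX[rank]
            if idx <= last:
                raise ValueError(
                    f"record {self.id!r}: lineage ranks not strictly ordered"
                )
            last = idx

    def rank_name(self, rank: str) -> str | None:
        for r, name in self.lineage:
            if r == rank:
                return name
        return None

    def ungapped_sequence(self) -> str:
        return ungapped(self.sequence)


@dataclass(frozen=True)
class ReferenceRecord(RawRecord):
    """A curated reference record, annotated with the filters it passed."""

    passed_filters: tuple[str, ...] = ()


def is_malformed(sequence: str) -> bool:
    """True if the ungapped sequence contains non-IUPAC nucleotide codes."""
    return any(c not in _IUPAC_NT for c in ungapped(sequence))


def is_identified(record: RawRecord) -> bool:
    """Whether the source organism is taxonomically identified.

    A record counts as unidentified if its organism name matches any of the
    anonymous-sequence naming conventions, or if its lineage carries no
    genus-rank entry.
    """
    name = record.organism_name.lower()
    if any(tok in name for tok in UNIDENTIFIED_TOKENS):
        return False
    return record.rank_name("genus") is not None


def has_codon_flanks(sequence: str) -> bool:
    """True if the sequence starts with a start codon, ends with a stop codon,
    and closes the reading frame (length divisible by 3)."""
    seq = ungapped(sequence)
    if len(seq) < 6 or len(seq) % 3 != 0:
        return False
    return seq[:3] in START_CODONS and seq[-3:] in STOP_CODONS


@dataclass
class CurationResult:
    """Outcome of :func:`curate_references`."""

    kept: list[ReferenceRecord]
    #: rejection counts keyed by first failing filter
    rejections: dict[str, int]
    #: per-record outcome: id -> "kept" or the first failing filter
    outcomes: dict[str, str] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.kept) + sum(self.rejections.values())


def curate_references(
    records: Iterable[RawRecord],
    min_len: int = 200,
    max_len: int = 1000,
    require_identified: bool = True,
    require_codon_flanks: bool = True,
) -> CurationResult:
    """Apply the three reference-database filters, in order.

    Filters are attributed in the order unidentified -> length -> codon
    flanks; a malformed sequence (non-IUPAC characters) is rejected at the
    record level before any filter.  Lengths are computed on the ungapped
    sequence; both length bounds are inclusive.

    Returns kept records (order preserving) plus rejection counts that
    partition the rejected set by first failing filter.
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept: list[ReferenceRecord] = []
    rejections = {
        FILTER_MALFORMED: 0,
        FILTER_UNIDENTIFIED: 0,
        FILTER_LENGTH: 0,
        FILTER_CODON_FLANKS: 0,
    }
    outcomes: dict[str, str] = {}
    for rec in records:
        reason = _first_failure(
            rec, min_len, max_len, require_identified, require_codon_flanks
        )
        if reason is None:
            passed = [FILTER_LENGTH]
            if require_identified:
                passed.insert(0, FILTER_UNIDENTIFIED)
            if require_codon_flanks:
                passed.append(FILTER_CODON_FLANKS)
            kept.append(
                ReferenceRecord(
                    id=rec.id,
                    sequence=rec.sequence,
                    organism_name=rec.organism_name,
                    lineage=rec.lineage,
                    passed_filters=tuple(passed),
                )
            )
            outcomes[rec.id] = "kept"
        else:
            rejections[reason] += 1
            outcomes[rec.id] = reason
    return CurationResult(kept=kept, rejections=rejections, outcomes=outcomes)


def _first_failure(
    rec: RawRecord,
    min_len: int,
    max_len: int,
    require_identified: bool,
    require_codon_flanks: bool,
) -> str | None:
    if is_malformed(rec.sequence):
        return FILTER_MALFORMED
    if require_identified and not is_identified(rec):
        return FILTER_UNIDENTIFIED
    n = len(rec.ungapped_sequence())
    if n < min_len or n > max_len:
        return FILTER_LENGTH
    if require_codon_flanks and not has_codon_flanks(rec.sequence):
        return FILTER_CODON_FLANKS
    return None


def filter_amplicon_lengths(
    queries: Sequence, lo: int = 330, hi: int = 370
) -> list:
    """Keep query sequences whose ungapped length falls in [lo, hi].

    ``queries`` may be plain sequence strings or ``(id, sequence)`` pairs;
    the kept items are returned unchanged, order preserved.
    """
    if lo > hi:
        raise ValueError(f"length window misconfigured: lo {lo} > hi {hi}")
    kept = []
    for item in queries:
        seq = item if isinstance(item, str) else item[1]
        if lo <= len(ungapped(seq)) <= hi:
            kept.append(item)
    return kept
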
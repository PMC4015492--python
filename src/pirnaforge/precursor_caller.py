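"""Assign library reads to piRNA loci and separate mature from precursor species.

A read is assigned to a locus iff it matches the genome exactly on the locus
strand, covers the locus 5'U, and its 5' end lies at or upstream of the 5'U.
Species calls:

* ``mature``: 5' extension 0 and read length equal to the mature length.
* ``precursor_candidate``: read longer than the mature length, with a 5'
  extension of at most 10 nt and total length at most 45 nt (capped
  precursors carry a 2-nt 5' extension and peak at 28-29 nt; degradation
  fragments beyond those guards are excluded from precursor profiles).
* ``other_locus_overlap``: assigned but outside the guards above.
* ``unassigned``: no exact locus-anchored match.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .io_formats import GenomeSequence, Library, PiRNALocus, revcomp

MAX_EXT5_PRECURSOR = 10
MAX_LEN_PRECURSOR = 45
MAX_EXT5_SEARCH = 15  # upstream reach of the locus-anchored match window
ANCHOR_LEN = 15  # seed length for the exact-match index (min read length)


@dataclass
class ReadAlignment:
    """An exact match of one library sequence to one locus."""

    sequence: str
    count: int
    locus_id: str | None
    five_prime_ext: int
    three_prime_ext: int
    read_length: int
    species_call: str
    multi: bool = False


@dataclass
class ExtensionProfile:
    """Count-weighted 5'-extension and read-length histograms for one library."""

    ext_counts: Counter = field(default_factory=Counter)
    len_counts: Counter = field(default_factory=Counter)
    ext_unique: Counter = field(default_factory=Counter)
    len_unique: Counter = field(default_factory=Counter)
    label: str = ""

    @property
    def total(self) -> int:
        return sum(self.len_counts.values())

    @property
    def modal_ext(self) -> int | None:
        return _weighted_mode(self.ext_counts)

    @property
    def modal_length(self) -> int | None:
        return _weighted_mode(self.len_counts)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for key, counter, unique in (
            ("five_prime_ext", self.ext_counts, self.ext_unique),
            ("read_length", self.len_counts, self.len_unique),
        ):
            for value in sorted(counter):
                rows.append(
                    {"metric": key, "value": value, "reads": counter[value],
                     "unique_sequences": unique[value]}
                )
        return pd.DataFrame(rows, columns=["metric", "value", "reads",
                                           "unique_sequences"])


def _weighted_mode(counter: Counter) -> int | None:
    """Count-weighted mode; ties broken toward the smaller value."""
    if not counter:
        return None
    best_count = max(counter.values())
    return min(v for v, c in counter.items() if c == best_count)


def _species_call(ext5: int, length: int, mature_length: int) -> str:
    if ext5 == 0 and length == mature_length:
        return "mature"
    if length > mature_length and ext5 <= MAX_EXT5_PRECURSOR and \
            length <= MAX_LEN_PRECURSOR:
        return "precursor_candidate"
    return "other_locus_overlap"


def _build_anchor_index(
    genome: dict[str, GenomeSequence], loci: list[PiRNALocus]
) -> dict[str, list[PiRNALocus]]:
    """Map the first ANCHOR_LEN nt of each mature sequence to its loci."""
    index: dict[str, list[PiRNALocus]] = {}
    for locus in loci:
        anchor = locus.mature_seq[:ANCHOR_LEN]
        index.setdefault(anchor, []).append(locus)
    return index


def _matches_genome(
    genome: dict[str, GenomeSequence], locus: PiRNALocus, read: str, ext5: int
) -> bool:
    """Exact genome match of ``read`` placed with its 5' end ext5 nt upstream
    of the locus 5'U, on the locus strand."""
    chrom = genome[locus.chrom].seq
    n = len(read)
    if locus.strand == "+":
        start = locus.start - ext5
        if start < 0 or start + n > len(chrom):
            return False
        return chrom[start:start + n] == read
    start5 = locus.start + ext5
    lo = start5 - n + 1
    if lo < 0 or start5 + 1 > len(chrom):
        return False
    return revcomp(chrom[lo:start5 + 1]) == read


def assign_reads(
    library: Library,
    genome: dict[str, GenomeSequence],
    loci: list[PiRNALocus],
) -> list[ReadAlignment]:
    """Assign every library read to matching loci by exact genome match.

    Returns one :class:`ReadAlignment` per (read, locus) match, with
    ``multi=True`` when a read matches several loci, plus one ``unassigned``
    record per unmatched read.  Matching is anchored to the locus (5'
    extensions up to MAX_EXT5_SEARCH are considered) rather than running a
    whole-genome alignment.
    """
    index = _build_anchor_index(genome, loci)
    alignments: list[ReadAlignment] = []
    for seq in sorted(library.reads):
        count = library.reads[seq]
        hits: list[tuple[PiRNALocus, int]] = []
        max_ext = min(MAX_EXT5_SEARCH, len(seq) - ANCHOR_LEN)
        for ext5 in range(0, max_ext + 1):
            candidates = index.get(seq[ext5:ext5 + ANCHOR_LEN])
            if not candidates:
                continue
            for locus in candidates:
                if len(seq) - ext5 < 1:  # must cover the 5'U
                    continue
                if _matches_genome(genome, locus, seq, ext5):
                    hits.append((locus, ext5))
        if not hits:
            alignments.append(
                ReadAlignment(seq, count, None, -1, 0, len(seq), "unassigned")
            )
            continue
        multi = len(hits) > 1
        for locus, ext5 in hits:
            ext3 = len(seq) - locus.mature_length - ext5
            alignments.append(
                ReadAlignment(
                    sequence=seq,
                    count=count,
                    locus_id=locus.locus_id,
                    five_prime_ext=ext5,
                    three_prime_ext=ext3,
                    read_length=len(seq),
                    species_call=_species_call(ext5, len(seq),
                                               locus.mature_length),
                    multi=multi,
                )
            )
    return alignments


def conservation_ledger(alignments: list[ReadAlignment]) -> dict[str, int]:
    """Per-class read totals with each read counted once (multi deduped).

    The sum over classes equals the library total.
    """
    seen: set[str] = set()
    ledger: Counter = Counter()
    for aln in alignments:
        if aln.sequence in seen:
            continue
        seen.add(aln.sequence)
        ledger[aln.species_call] += aln.count
    return dict(ledger)


def extension_profile(
    alignments: list[ReadAlignment],
    species: tuple[str, ...] = ("mature", "precursor_candidate"),
    loci_filter: set[str] | None = None,
    label: str = "",
) -> ExtensionProfile:
    """Count-weighted 5'-extension / length histograms over selected species.

    Multi-locus reads contribute once to the global histograms (their first
    qualifying alignment is used).  ``loci_filter`` restricts to reads
    assigned to the given loci (e.g. one motif class).  An empty selection
    is a valid, empty profile.
    """
    profile = ExtensionProfile(label=label)
    seen: set[str] = set()
    for aln in alignments:
        if aln.species_call not in species:
            continue
        if loci_filter is not None and aln.locus_id not in loci_filter:
            continue
        if aln.sequence in seen:
            continue
        seen.add(aln.sequence)
        profile.ext_counts[aln.five_prime_ext] += aln.count
        profile.len_counts[aln.read_length] += aln.count
        profile.ext_unique[aln.five_prime_ext] += 1
        profile.len_unique[aln.read_length] += 1
    return profile


def per_locus_counts(alignments: list[ReadAlignment]) -> pd.DataFrame:
    """Mature / precursor read counts per locus (multi reads counted toward
    every matching locus, flagged in the ``multi_reads`` column)."""
    rows: dict[str, dict[str, int]] = {}
    for aln in alignments:
        if aln.locus_id is None:
            continue
        rec = rows.setdefault(
            aln.locus_id,
            {"mature": 0, "precursor_candidate": 0, "other_locus_overlap": 0,
             "multi_reads": 0},
        )
        if aln.species_call in rec:
            rec[aln.species_call] += aln.count
        if aln.multi:
            rec["multi_reads"] += aln.count
    frame = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    frame.index.name = "locus_id"
    return frame.sort_index()


def compare_protocols(
    alignments_by_protocol: dict[str, list[ReadAlignment]],
    background_fraction: float = 0.05,
) -> pd.DataFrame:
    """Per-protocol mature/precursor composition with the qualitative contract.

    Expected structure: capRNA libraries are depleted of mature piRNAs,
    untreated (5'-monophosphate-dependent) libraries lack capped precursors,
    and TAP-treated libraries contain both.  ``contract_ok`` records whether
    each protocol matches its expectation (fractions of assigned reads,
    threshold 2x the background fraction).
    """
    rows = []
    thresh = 2 * background_fraction
    for protocol, alignments in alignments_by_protocol.items():
        ledger = conservation_ledger(alignments)
        mature = ledger.get("mature", 0)
        prec = ledger.get("precursor_candidate", 0)
        assigned = mature + prec + ledger.get("other_locus_overlap", 0)
        mature_frac = mature / assigned if assigned else 0.0
        prec_frac = prec / assigned if assigned else 0.0
        profile = extension_profile(alignments)
        if protocol == "capRNA":
            ok = mature_frac < thresh
        elif protocol == "untreated":
            ok = prec_frac < thresh
        elif protocol == "TAP":
            ok = mature_frac >= thresh and prec_frac >= thresh
        else:
            ok = True
        rows.append(
            {
                "protocol": protocol,
                "mature_reads": mature,
                "precursor_reads": prec,
                "assigned_reads": assigned,
                "mature_fraction": mature_frac,
                "precursor_fraction": prec_frac,
                "modal_length": profile.modal_length,
                "contract_ok": ok,
            }
        )
    return pd.DataFrame(rows).set_index("protocol")
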
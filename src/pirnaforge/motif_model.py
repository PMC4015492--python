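"""Ruby-motif scoring: core PWM construction, locus scoring, classification.

The Ruby motif is an 8-nt core (consensus CTGTTTCA) found ~40 bp upstream of
the mature piRNA 5'U, separated from it by an A/T-rich spacer.  A locus's
motif score is the maximum log2-odds of the core PWM over placements whose
core 3' end lies 30-50 bp upstream of the 5'U; loci scoring strictly above
the cutoff (default 7 bits) are classified motif-dependent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GenomeSequence, PiRNALocus, revcomp

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
RUBY_CORE = "CTGTTTCA"
DEFAULT_WINDOW = (30, 50)
DEFAULT_CUTOFF = 7.0


@dataclass
class PWM:
    """Position probability matrix over the motif core, with background.

    ``probs`` has shape (4, width) with rows in A,C,G,T order.  Scores are
    log2-odds against ``background`` and are reported in bits.
    """

    probs: np.ndarray
    background: np.ndarray
    pseudocount: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[0] != 4:
            raise ValueError("probs must have shape (4, width)")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("each PWM column must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if (self.probs <= 0).any() or (self.background <= 0).any():
            raise ValueError("zero probability in PWM; use a pseudocount > 0")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log2(self.probs / self.background[:, None])

    def score_kmer(self, kmer: str) -> float:
        """log2-odds of one width-length string (no placement search)."""
        if len(kmer) != self.width:
            raise ValueError(f"kmer length {len(kmer)} != PWM width {self.width}")
        lo = self.log_odds
        return float(sum(lo[_BASE_INDEX[b], i] for i, b in enumerate(kmer)))

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    def consensus_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.probs, index=list(BASES))


@dataclass
class MotifScore:
    """Best core placement for one locus: score in bits plus its offset.

    ``offset`` is the distance in bp from the core 3' end to the mature 5'U
    (canonically ~40 bp upstream).
    """

    score: float
    offset: int
    window: tuple[int, int]

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError("motif score must be finite")


def build_pwm(
    upstream_cores: list[str],
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> PWM:
    """Estimate the core PWM from aligned width-length training strings.

    probs[b, i] = (count[b, i] + pseudocount) / (n + 4 * pseudocount).
    Background defaults to uniform 0.25.
    """
    if not upstream_cores:
        raise ValueError("no training sequences")
    width = len(upstream_cores[0])
    counts = np.zeros((4, width))
    for seq in upstream_cores:
        if len(seq) != width:
            raise ValueError(
                f"training sequence {seq!r} has length {len(seq)}, expected {width}"
            )
        for i, b in enumerate(seq):
            counts[_BASE_INDEX[b], i] += 1
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if pseudocount == 0 and (counts == 0).any():
        raise ValueError(
            "pseudocount 0 with an unobserved base; scores would be infinite"
        )
    n = len(upstream_cores)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    return PWM(probs=probs, background=bg, pseudocount=pseudocount)


def pwm_to_tsv(pwm: PWM, path) -> None:
    pwm.to_frame().to_csv(path, sep="\t", header=False, float_format="%.8g")


def pwm_from_tsv(path) -> PWM:
    """Load a PWM from a TSV of 4 rows (A,C,G,T) x width probability columns."""
    frame = pd.read_csv(path, sep="\t", header=None, index_col=0)
    if list(frame.index) != list(BASES):
        raise ValueError("PWM file must have rows A, C, G, T in order")
    return PWM(probs=frame.to_numpy(float), background=np.full(4, 0.25),
               pseudocount=0.0)


def upstream_region(
    genome: dict[str, GenomeSequence], locus: PiRNALocus, length: int
) -> str:
    """Strand-aware upstream sequence ending immediately before the 5'U.

    The returned string reads 5'->3' on the locus strand; its last character
    is the base 1 bp upstream of the mature 5' nucleotide.  Truncated at the
    chromosome boundary.
    """
    chrom = genome[locus.chrom].seq
    if locus.strand == "+":
        lo = max(0, locus.start - length)
        return chrom[lo:locus.start]
    hi = min(len(chrom), locus.start + 1 + length)
    return revcomp(chrom[locus.start + 1:hi])


def score_locus(
    genome: dict[str, GenomeSequence],
    locus: PiRNALocus,
    pwm: PWM,
    window: tuple[int, int] = DEFAULT_WINDOW,
    preferred_offset: int = 40,
) -> MotifScore:
    """Score a locus: max log2-odds over core placements in the offset window.

    Offset d means the core's 3'-end base sits d bp upstream of the 5'U, so
    the core occupies upstream offsets [d+width-1 .. d].  Ties are broken
    toward ``preferred_offset`` (the canonical ~40 bp), then the smaller
    offset.  A locus too close to a chromosome end is scored over the
    placements that fit, with a warning; no placement at all is an error.
    """
    min_off, max_off = window
    if not 1 <= min_off <= max_off:
        raise ValueError("window must satisfy 1 <= min <= max")
    need = max_off + pwm.width - 1
    region = upstream_region(genome, locus, need)
    best: tuple[float, int] | None = None
    truncated = False
    for d in range(min_off, max_off + 1):
        # core spans region[-(d + width - 1) : len(region) - d + 1]
        hi = len(region) - d + 1
        lo = hi - pwm.width
        if lo < 0:
            truncated = True
            continue
        kmer = region[lo:hi]
        if "N" in kmer:
            continue
        score = pwm.score_kmer(kmer)
        if (
            best is None
            or score > best[0] + 1e-12
            or (
                abs(score - best[0]) <= 1e-12
                and _tie_key(d, preferred_offset) < _tie_key(best[1], preferred_offset)
            )
        ):
            best = (score, d)
    if best is None:
        raise ValueError(
            f"locus {locus.locus_id}: no scorable core placement in window {window}"
        )
    if truncated:
        warnings.warn(
            f"locus {locus.locus_id}: upstream window truncated at chromosome end",
            stacklevel=2,
        )
    return MotifScore(score=best[0], offset=best[1], window=window)


def _tie_key(offset: int, preferred: int) -> tuple[int, int]:
    return (abs(offset - preferred), offset)


def classify_locus(ms: MotifScore | float, cutoff: float = DEFAULT_CUTOFF) -> str:
    """Two-class call: strictly greater than the cutoff -> motif_dependent."""
    score = ms.score if isinstance(ms, MotifScore) else float(ms)
    return "motif_dependent" if score > cutoff else "motif_independent"


def extract_training_cores(
    genome: dict[str, GenomeSequence],
    loci: list[PiRNALocus],
    window: tuple[int, int] = DEFAULT_WINDOW,
    seed_consensus: str = RUBY_CORE,
) -> list[str]:
    """Pull one core-width string per training locus for PWM estimation.

    For each locus the window placement whose string best matches the seed
    consensus (fewest mismatches, ties toward the canonical offset) is
    extracted.  This bootstraps the matrix from data without any
    generator-side knowledge of where cores were planted.
    """
    width = len(seed_consensus)
    cores = []
    for locus in loci:
        region = upstream_region(genome, locus, window[1] + width - 1)
        best: tuple[int, tuple[int, int], str] | None = None
        for d in range(window[0], window[1] + 1):
            hi = len(region) - d + 1
            lo = hi - width
            if lo < 0:
                continue
            kmer = region[lo:hi]
            if "N" in kmer:
                continue
            mm = sum(a != b for a, b in zip(kmer, seed_consensus))
            key = (mm, _tie_key(d, 40))
            if best is None or key < (best[0], best[1]):
                best = (mm, _tie_key(d, 40), kmer)
        if best is not None:
            cores.append(best[2])
    if not cores:
        raise ValueError("no usable training loci")
    return cores


def score_histogram(scores: list[float], binwidth: float = 5.0) -> pd.Series:
    """Bin unique-sequence motif scores into windows of the given width.

    Bins are [k*w, (k+1)*w) and are indexed by their midpoint, mirroring the
    field's convention of plotting counts against the window midpoint.
    Empty input yields an empty histogram.
    """
    if binwidth <= 0:
        raise ValueError("binwidth must be > 0")
    if len(scores) == 0:
        return pd.Series(dtype=int, name="count")
    arr = np.asarray(scores, dtype=float)
    k = np.floor(arr / binwidth).astype(int)
    lo, hi = k.min(), k.max()
    index = np.arange(lo, hi + 1)
    counts = np.bincount(k - lo, minlength=len(index))
    midpoints = (index + 0.5) * binwidth
    return pd.Series(counts, index=midpoints, name="count")


def count_modes(hist: pd.Series) -> int:
    """Number of local maxima in a binned histogram (bimodality summary).

    Runs of equal counts are compressed before peak detection so a plateau
    counts as a single mode; zero-count bins separate modes.
    """
    values = [int(v) for v in hist.values]
    compressed: list[int] = []
    for v in values:
        if not compressed or compressed[-1] != v:
            compressed.append(v)
    n = len(compressed)
    modes = 0
    for i, v in enumerate(compressed):
        if v == 0:
            continue
        left = compressed[i - 1] if i > 0 else 0
        right = compressed[i + 1] if i < n - 1 else 0
        if v > left and v > right:
            modes += 1
    return modes
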
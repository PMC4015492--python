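"""Seed-controlled generator of genomes, piRNA loci, small-RNA libraries,
22G-RNA libraries, and expression matrices, with a truth set for recovery
scoring.

The generator encodes the structural model of C. elegans piRNA biogenesis:

* Motif-dependent loci carry the 8-nt Ruby core (CTGTTTCA) whose 3' end sits
  ~40 bp upstream of the mature 5'U, separated by an A/T-rich spacer;
  motif-independent loci have no core within 60 bp upstream.
* Mature piRNAs are exact 21-mers starting with a 5'U.  Capped precursors
  begin 2 nt upstream of the mature 5'U and have lengths peaking at
  28-29 nt (drawn over 26-36 nt).
* Genotype effects: prg-1 loses mature piRNAs of both classes but keeps
  precursors; prde-1 loses motif-dependent mature piRNAs AND precursors
  while motif-independent species persist (mature slightly increased).
* Cloning protocols: untreated (5'-monophosphate) libraries exclude capped
  species; TAP libraries include them; capRNA libraries contain only capped
  species (mature excluded).  A background fraction of random genomic
  slices (15-35 nt) is present in every library.
* 22G-RNAs are 22-nt antisense slices of target-gene bodies with a 5'G,
  depleted per genotype class; target genes are up-regulated on the
  expression array in the genotypes where their 22Gs are lost.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GeneInterval,
    GenomeSequence,
    Library,
    PiRNALocus,
    revcomp,
)

BASES = np.frombuffer(b"ACGT", dtype="S1")
RUBY_CORE = "CTGTTTCA"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

DEFAULT_PRECURSOR_LEN_PROBS: dict[int, float] = {
    26: 0.05, 27: 0.10, 28: 0.22, 29: 0.22, 30: 0.14, 31: 0.09,
    32: 0.07, 33: 0.05, 34: 0.03, 35: 0.02, 36: 0.01,
}

# per-class multipliers: {genotype: {class: {"mature": m, "precursor": p}}}
DEFAULT_GENOTYPE_EFFECTS: dict[str, dict[str, dict[str, float]]] = {
    "wild_type": {
        "motif_dependent": {"mature": 1.0, "precursor": 1.0},
        "motif_independent": {"mature": 1.0, "precursor": 1.0},
    },
    "prg1": {
        "motif_dependent": {"mature": 0.0, "precursor": 1.0},
        "motif_independent": {"mature": 0.0, "precursor": 1.0},
    },
    "prde1": {
        "motif_dependent": {"mature": 0.0, "precursor": 0.0},
        "motif_independent": {"mature": 1.25, "precursor": 1.0},
    },
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults encode the structural facts the model states (2-nt precursor
    extension, 28-29 nt precursor length mode, Ruby core ~40 bp upstream
    with an A/T-rich spacer, genotype-class effects); remaining values are
    chosen as realistic desk-scale conditions and documented in the methods
    note.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_len: int = 200_000
    n_motif_loci: int = 300
    n_nonmotif_loci: int = 60
    mature_length: int = 21
    motif_offset_mean: int = 40
    motif_offset_jitter: int = 2
    spacer_at_fraction: float = 0.75
    precursor_ext5: int = 2
    precursor_len_probs: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PRECURSOR_LEN_PROBS))
    precursor_mature_ratio: float = 0.15
    library_depth: int = 200_000
    genotype_effects: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=lambda: {
            g: {c: dict(v) for c, v in d.items()}
            for g, d in DEFAULT_GENOTYPE_EFFECTS.items()
        })
    background_fraction: float = 0.05
    abundance_sigma: float = 1.0
    # target genes / 22G / expression stage
    n_target_genes: int = 60  # split equally shared / prg1-only / untargeted
    gene_length: int = 1000
    g22_sites_mean: int = 25
    g22_depletion: float = 0.1
    g22_prg1_only_weight: float = 0.5
    # fraction of the wild-type 22G library that maps to the target genes;
    # the remainder emulates the genome-wide 22G pool, which keeps RPM
    # normalization from inflating unaltered genes when targets are lost
    g22_target_fraction: float = 0.2
    expr_effect_log2: float = 2.5
    expr_noise_sd: float = 0.4
    expr_baseline_mean: float = 8.0
    expr_baseline_sd: float = 1.5
    n_reps: int = 3

    def validate(self) -> None:
        if self.library_depth <= 0:
            raise ValueError("library_depth must be > 0")
        for p in (self.spacer_at_fraction, self.background_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.precursor_len_probs.values()) - 1.0) > 1e-9:
            raise ValueError("precursor_len_probs must sum to 1")
        for g, classes in self.genotype_effects.items():
            for c, mult in classes.items():
                if mult["mature"] < 0 or mult["precursor"] < 0:
                    raise ValueError(f"negative multiplier for {g}/{c}")
        if self.n_chrom < 1:
            raise ValueError("need at least one chromosome")
        min_len = 150 * (self.n_motif_loci + self.n_nonmotif_loci)
        if self.locus_region_len < min_len:
            raise ValueError(
                f"chrom_len {self.chrom_len} too short for "
                f"{self.n_motif_loci + self.n_nonmotif_loci} loci "
                f"(need >= {min_len} of locus space)"
            )

    @property
    def locus_region_len(self) -> int:
        """Length of the chromosome region available for piRNA loci (genes
        take the final third when there is only one chromosome)."""
        if self.n_chrom > 1:
            return self.chrom_len
        return (self.chrom_len * 2) // 3 - 200


@dataclass
class TruthSet:
    """Generator-side ground truth for recovery scoring.

    ``read_origins[sample_id]`` maps each emitted unique sequence to its
    origin counts; origin strings are ``mature:<locus>``,
    ``precursor:<locus>`` (capped species), ``g22:<gene>``, or
    ``background``.  The sum of origin counts equals the library total for
    every generated library.
    """

    config: SimConfig
    genome: dict[str, GenomeSequence] = field(default_factory=dict)
    loci: list[PiRNALocus] = field(default_factory=list)
    locus_classes: dict[str, str] = field(default_factory=dict)
    locus_abundance: dict[str, float] = field(default_factory=dict)
    planted_offsets: dict[str, int] = field(default_factory=dict)
    genes: list[GeneInterval] = field(default_factory=list)
    gene_classes: dict[str, str] = field(default_factory=dict)
    gene_weights: dict[str, float] = field(default_factory=dict)
    g22_sites: dict[str, list[int]] = field(default_factory=dict)
    target_sites: dict[str, tuple[str, int, int]] = field(default_factory=dict)
    read_origins: dict[str, dict[str, dict[str, int]]] = field(
        default_factory=dict)

    def origin_total(self, sample_id: str) -> int:
        return sum(
            c for origins in self.read_origins[sample_id].values()
            for c in origins.values()
        )

    def origins_to_frame(self, sample_id: str) -> pd.DataFrame:
        rows = [
            {"sequence": seq, "origin": origin, "count": count}
            for seq, origins in sorted(self.read_origins[sample_id].items())
            for origin, count in sorted(origins.items())
        ]
        return pd.DataFrame(rows, columns=["sequence", "origin", "count"])


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible child RNG of the top-level seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed,
                               spawn_key=(zlib.crc32(name.encode()),))
    )


# ---------------------------------------------------------------------------
# Genome and locus generation
# ---------------------------------------------------------------------------

def _write_frame(arr: np.ndarray, anchor: int, strand: str, rel: int,
                 base: str) -> None:
    """Write one base in locus coordinates (rel=0 is the 5'U; negative rel
    is upstream).  Minus-strand loci store the complement."""
    if strand == "+":
        arr[anchor + rel] = base.encode()
    else:
        arr[anchor - rel] = _COMPLEMENT[base].encode()


def _read_frame(arr: np.ndarray, anchor: int, strand: str, rel_start: int,
                length: int) -> str:
    """Read ``length`` bases 5'->3' on the locus strand starting at rel_start."""
    if strand == "+":
        sub = arr[anchor + rel_start:anchor + rel_start + length]
        return sub.tobytes().decode()
    sub = arr[anchor - rel_start - length + 1:anchor - rel_start + 1]
    return revcomp(sub.tobytes().decode())


def _offset_probs(mean: int, jitter: int) -> tuple[np.ndarray, np.ndarray]:
    """Triangular offset distribution centred on the canonical ~40 bp."""
    offsets = np.arange(mean - jitter, mean + jitter + 1)
    weights = (jitter + 1 - np.abs(offsets - mean)).astype(float)
    return offsets, weights / weights.sum()


def generate_genome(config: SimConfig) -> tuple[
        dict[str, GenomeSequence], list[PiRNALocus], TruthSet]:
    """Generate the genome, piRNA loci, target genes, and truth set.

    piRNA loci are placed non-overlapping on both strands of the first
    chromosome (the piRNA-cluster chromosome); target genes occupy the last
    chromosome.  Motif-dependent loci have the Ruby core planted with its 3'
    end at a jittered offset upstream of the forced 5'U and an A/T-rich
    spacer in between; motif-independent loci are guaranteed core-free
    within 60 bp upstream.
    """
    config.validate()
    rng = substream(config.seed, "genome")
    chrom_names = ["chrIV"] + [f"chr{i}" for i in range(2, config.n_chrom + 1)]
    arrays = {
        name: rng.choice(BASES, size=config.chrom_len).copy()
        for name in chrom_names
    }
    truth = TruthSet(config=config)

    n_loci = config.n_motif_loci + config.n_nonmotif_loci
    slot = 150
    locus_chrom = chrom_names[0]
    arr = arrays[locus_chrom]
    n_slots = config.locus_region_len // slot
    slots = rng.choice(n_slots, size=n_loci, replace=False)
    classes = np.array(
        ["motif_dependent"] * config.n_motif_loci
        + ["motif_independent"] * config.n_nonmotif_loci
    )
    rng.shuffle(classes)
    offsets, offset_p = _offset_probs(config.motif_offset_mean,
                                      config.motif_offset_jitter)

    loci: list[PiRNALocus] = []
    for i, (slot_i, cls) in enumerate(zip(np.sort(slots), classes)):
        cls = str(cls)
        anchor = int(slot_i) * slot + 70 + int(rng.integers(0, 11))
        strand = "+" if rng.random() < 0.5 else "-"
        locus_id = f"21ur-{i + 1}"
        _write_frame(arr, anchor, strand, 0, "T")  # force the 5'U (T on DNA)
        if cls == "motif_dependent":
            d = int(rng.choice(offsets, p=offset_p))
            for j, base in enumerate(RUBY_CORE):
                _write_frame(arr, anchor, strand, -(d + 7) + j, base)
            # A/T-rich spacer between the core 3' end and the 5'U
            for rel in range(-(d - 1), 0):
                if rng.random() < config.spacer_at_fraction:
                    base = "A" if rng.random() < 0.5 else "T"
                else:
                    base = "C" if rng.random() < 0.5 else "G"
                _write_frame(arr, anchor, strand, rel, base)
            truth.planted_offsets[locus_id] = d
        else:
            # resample upstream bases until no core within 60 bp
            for _ in range(100):
                window = _read_frame(arr, anchor, strand, -60, 60)
                if RUBY_CORE not in window:
                    break
                pos = window.index(RUBY_CORE)
                for j in range(8):
                    new = str(rng.choice(BASES).decode())
                    _write_frame(arr, anchor, strand, -60 + pos + j, new)
            else:  # pragma: no cover - astronomically unlikely
                raise RuntimeError("could not clear upstream core")
        mature_seq = _read_frame(arr, anchor, strand, 0, config.mature_length)
        loci.append(
            PiRNALocus(
                locus_id=locus_id, chrom=locus_chrom, start=anchor,
                strand=strand, mature_length=config.mature_length,
                mature_seq=mature_seq, class_label="unscored",
            )
        )
        truth.locus_classes[locus_id] = cls
        truth.locus_abundance[locus_id] = float(
            rng.lognormal(mean=0.0, sigma=config.abundance_sigma))

    _place_genes(config, rng, arrays, chrom_names, truth, loci)

    # re-read mature sequences: gene planting never touches the locus
    # chromosome unless n_chrom == 1, in which case regions are disjoint,
    # but refresh defensively so locus invariants hold by construction
    for locus in loci:
        locus.mature_seq = _read_frame(
            arrays[locus.chrom], locus.start, locus.strand, 0,
            locus.mature_length)

    genome = {
        name: GenomeSequence(name, a.tobytes().decode())
        for name, a in arrays.items()
    }
    truth.genome = genome
    truth.loci = loci
    return genome, loci, truth


def _mutate_site(rng: np.random.Generator, site: str, n_mm: int) -> str:
    chars = list(site)
    positions = rng.choice(len(chars), size=n_mm, replace=False)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != chars[p]]
        chars[p] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


def _place_genes(config, rng, arrays, chrom_names, truth, loci) -> None:
    """Place target genes, plant piRNA complementary sites, and fix the
    genomic bases that make the planned 22G reads start with a 5'G."""
    n = config.n_target_genes
    if n == 0:
        return
    gene_chrom = chrom_names[-1]
    arr = arrays[gene_chrom]
    gap = config.gene_length + 100
    region_start = 0
    if len(chrom_names) == 1:
        region_start = (config.chrom_len * 2) // 3  # keep clear of loci
    max_genes = (config.chrom_len - region_start) // gap
    if n > max_genes:
        raise ValueError(f"chromosome too short for {n} genes")
    n_shared = n // 3
    n_prg1_only = n // 3
    gene_classes = (
        ["shared_target"] * n_shared
        + ["prg1_only_target"] * n_prg1_only
        + ["untargeted"] * (n - n_shared - n_prg1_only)
    )
    md_loci = [l for l in loci if truth.locus_classes[l.locus_id] ==
               "motif_dependent"]
    mi_loci = [l for l in loci if truth.locus_classes[l.locus_id] ==
               "motif_independent"]
    for i, cls in enumerate(gene_classes):
        start = region_start + i * gap + 50
        end = start + config.gene_length
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"gene-{i + 1}"
        gene = GeneInterval(gene_id, gene_chrom, start, end, strand)
        truth.genes.append(gene)
        truth.gene_classes[gene_id] = cls
        weight = float(rng.lognormal(0.0, 0.5))
        if cls == "prg1_only_target":
            weight *= config.g22_prg1_only_weight
        truth.gene_weights[gene_id] = weight

        site_window: tuple[int, int] | None = None
        if cls != "untargeted":
            # plant an antisense piRNA complementary site (<=3 mismatches):
            # shared targets take a motif-dependent piRNA, prg1-only targets
            # a motif-independent one (their piRNAs persist in prde-1)
            pool = md_loci if cls == "shared_target" else mi_loci
            locus = pool[int(rng.integers(0, len(pool)))]
            n_mm = int(rng.integers(0, 4))
            site = _mutate_site(rng, revcomp(locus.mature_seq), n_mm)
            pos = int(rng.integers(50, config.gene_length - 80))
            # write the site into the transcript (gene-strand) frame
            for j, base in enumerate(site):
                if strand == "+":
                    arr[start + pos + j] = base.encode()
                else:
                    arr[end - 1 - pos - j] = _COMPLEMENT[base].encode()
            truth.target_sites[gene_id] = (locus.locus_id, pos, n_mm)
            g_lo = start + pos if strand == "+" else end - pos - len(site)
            site_window = (g_lo, g_lo + len(site))

        # 22G start sites: genomic start of each antisense 22-mer; force the
        # base that becomes the read's 5' nucleotide to G
        n_sites = 5 + int(rng.poisson(config.g22_sites_mean))
        if site_window is not None:
            centre = (site_window[0] + site_window[1]) // 2
            lo = max(start, centre - 120)
            hi = min(end - 22, centre + 120)
        else:
            lo, hi = start, end - 22
        sites = sorted(
            int(s) for s in rng.choice(np.arange(lo, hi), size=n_sites,
                                       replace=False)
        )
        kept = []
        for s in sites:
            five_prime_pos = s + 21 if strand == "+" else s
            if site_window and site_window[0] <= five_prime_pos < site_window[1]:
                continue  # do not disturb the planted complementary site
            arr[five_prime_pos] = b"C" if strand == "+" else b"G"
            kept.append(s)
        truth.g22_sites[gene_id] = kept


# ---------------------------------------------------------------------------
# Small-RNA library generation
# ---------------------------------------------------------------------------

def _background_species(
    rng: np.random.Generator,
    genome: dict[str, GenomeSequence],
    n_species: int,
    len_range: tuple[int, int] = (15, 35),
) -> list[str]:
    """Random genomic slices emulating degradation background."""
    chroms = list(genome)
    seqs = []
    for _ in range(n_species):
        chrom = genome[chroms[int(rng.integers(0, len(chroms)))]].seq
        length = int(rng.integers(len_range[0], len_range[1] + 1))
        pos = int(rng.integers(0, len(chrom) - length))
        s = chrom[pos:pos + length]
        if rng.random() < 0.5:
            s = revcomp(s)
        seqs.append(s)
    return seqs


def generate_library(
    truth: TruthSet,
    genotype: str,
    protocol: str,
    depth: int | None = None,
    seed: int | None = None,
    sample_id: str | None = None,
) -> Library:
    """Draw one collapsed small-RNA library for a genotype/protocol.

    Expected per-species abundances combine the per-locus base abundance,
    the precursor:mature ratio and length distribution, the genotype-class
    multipliers, and the protocol filter; counts are drawn multinomially at
    the requested depth.  Origins are appended to ``truth.read_origins``.
    """
    config = truth.config
    if genotype not in config.genotype_effects:
        raise ValueError(f"unknown genotype {genotype!r}")
    if protocol not in ("untreated", "TAP", "capRNA"):
        raise ValueError(f"unknown protocol {protocol!r}")
    depth = config.library_depth if depth is None else depth
    if depth <= 0:
        raise ValueError("depth must be > 0")
    seed = config.seed if seed is None else seed
    sample_id = sample_id or f"{genotype}_{protocol}"
    rng = substream(seed, f"library:{sample_id}")

    mature_in = protocol in ("untreated", "TAP")
    precursor_in = protocol in ("TAP", "capRNA")

    species: list[tuple[str, str, float]] = []  # (sequence, origin, weight)
    arr_cache = {
        name: np.frombuffer(g.seq.encode(), dtype="S1")
        for name, g in truth.genome.items()
    }
    for locus in truth.loci:
        cls = truth.locus_classes[locus.locus_id]
        ab = truth.locus_abundance[locus.locus_id]
        eff = config.genotype_effects[genotype][cls]
        if mature_in and eff["mature"] > 0:
            species.append(
                (locus.mature_seq, f"mature:{locus.locus_id}",
                 ab * eff["mature"])
            )
        if precursor_in and eff["precursor"] > 0:
            arr = arr_cache[locus.chrom]
            for length, p in config.precursor_len_probs.items():
                seq = _read_frame(arr, locus.start, locus.strand,
                                  -config.precursor_ext5, length)
                species.append(
                    (seq, f"precursor:{locus.locus_id}",
                     ab * config.precursor_mature_ratio * p
                     * eff["precursor"])
                )

    signal = sum(w for _, _, w in species)
    bf = config.background_fraction
    if signal > 0 and bf > 0:
        bg_weight_total = signal * bf / (1 - bf)
    else:
        bg_weight_total = 1.0 if signal == 0 else 0.0
    if bg_weight_total > 0:
        bg = _background_species(rng, truth.genome, n_species=2000)
        w = bg_weight_total / len(bg)
        species.extend((s, "background", w) for s in bg)

    weights = np.array([w for _, _, w in species])
    counts = rng.multinomial(depth, weights / weights.sum())

    reads: dict[str, int] = {}
    origins: dict[str, dict[str, int]] = {}
    for (seq, origin, _w), count in zip(species, counts):
        if count == 0:
            continue
        reads[seq] = reads.get(seq, 0) + int(count)
        origins.setdefault(seq, {})
        origins[seq][origin] = origins[seq].get(origin, 0) + int(count)
    truth.read_origins[sample_id] = origins
    return Library(sample_id=sample_id, genotype=genotype, protocol=protocol,
                   reads=reads)


# ---------------------------------------------------------------------------
# 22G-RNA libraries and expression matrix
# ---------------------------------------------------------------------------

def _g22_multiplier(config: SimConfig, genotype: str, gene_class: str) -> float:
    if gene_class == "shared_target" and genotype.startswith(("prg1", "prde1")):
        return config.g22_depletion
    if gene_class == "prg1_only_target" and genotype.startswith("prg1"):
        return config.g22_depletion
    return 1.0


def _gene_is_up(genotype: str, gene_class: str) -> bool:
    """A target gene is de-repressed wherever its 22G silencing is lost."""
    if gene_class == "shared_target":
        return genotype.startswith(("prg1", "prde1"))
    if gene_class == "prg1_only_target":
        return genotype.startswith("prg1")
    return False


def generate_22g_and_expression(
    truth: TruthSet,
    genotypes: tuple[str, ...] = ("wild_type", "prg1", "prde1"),
    n_reps: int | None = None,
    seed: int | None = None,
    depth: int | None = None,
) -> tuple[dict[str, Library], ExpressionMatrix]:
    """Per-genotype 22G libraries plus a replicated log2 expression matrix.

    22G reads are 22-nt antisense slices of gene bodies with a forced 5'G
    (the forcing is done in the genome at generation time so reads match it
    exactly); per-gene abundance is scaled by the genotype-class depletion.
    Expression: targets gain ``expr_effect_log2`` in the genotypes where
    their 22Gs are lost, with i.i.d. Gaussian noise on every sample.
    """
    config = truth.config
    n_reps = config.n_reps if n_reps is None else n_reps
    if n_reps < 2:
        raise ValueError("need >= 2 replicates per genotype")
    seed = config.seed if seed is None else seed
    depth = config.library_depth if depth is None else depth
    if "wild_type" not in genotypes:
        raise ValueError("genotypes must include wild_type")

    arr_cache = {
        name: np.frombuffer(g.seq.encode(), dtype="S1")
        for name, g in truth.genome.items()
    }
    libraries: dict[str, Library] = {}
    # the genome-wide 22G pool is anchored to the wild-type target signal so
    # genotype depletion shrinks the target share instead of renormalizing it
    signal_wt = sum(truth.gene_weights[g.gene_id] for g in truth.genes
                    if truth.g22_sites[g.gene_id])
    f = config.g22_target_fraction
    for genotype in genotypes:
        rng = substream(seed, f"g22:{genotype}")
        species: list[tuple[str, str, float]] = []
        for gene in truth.genes:
            cls = truth.gene_classes[gene.gene_id]
            mult = _g22_multiplier(config, genotype, cls)
            if mult == 0:
                continue
            sites = truth.g22_sites[gene.gene_id]
            if not sites:
                continue
            w = truth.gene_weights[gene.gene_id] * mult / len(sites)
            arr = arr_cache[gene.chrom]
            for s in sites:
                window = arr[s:s + 22].tobytes().decode()
                read = revcomp(window) if gene.strand == "+" else window
                species.append((read, f"g22:{gene.gene_id}", w))
        bg_total = signal_wt * (1 - f) / f if signal_wt > 0 else 1.0
        bg = _background_species(rng, truth.genome, n_species=4000,
                                 len_range=(18, 26))
        species.extend((b, "background", bg_total / len(bg)) for b in bg)
        weights = np.array([w for _, _, w in species])
        counts = rng.multinomial(depth, weights / weights.sum())
        reads: dict[str, int] = {}
        origins: dict[str, dict[str, int]] = {}
        for (seq, origin, _w), count in zip(species, counts):
            if count == 0:
                continue
            reads[seq] = reads.get(seq, 0) + int(count)
            origins.setdefault(seq, {})
            origins[seq][origin] = origins[seq].get(origin, 0) + int(count)
        sample_id = f"{genotype}_22g"
        truth.read_origins[sample_id] = origins
        libraries[sample_id] = Library(
            sample_id=sample_id, genotype=genotype, protocol="untreated",
            reads=reads)

    rng = substream(seed, "expression")
    gene_ids = [g.gene_id for g in truth.genes]
    baselines = rng.normal(config.expr_baseline_mean, config.expr_baseline_sd,
                           size=len(gene_ids))
    columns, genotype_labels, data = [], [], []
    for genotype in genotypes:
        for rep in range(1, n_reps + 1):
            columns.append(f"{genotype}_rep{rep}")
            genotype_labels.append(genotype)
            effects = np.array([
                config.expr_effect_log2
                if _gene_is_up(genotype, truth.gene_classes[g]) else 0.0
                for g in gene_ids
            ])
            noise = rng.normal(0.0, config.expr_noise_sd, size=len(gene_ids))
            data.append(baselines + effects + noise)
    values = pd.DataFrame(np.column_stack(data), index=gene_ids,
                          columns=columns)
    values.index.name = "gene"
    reps: dict[str, int] = {}
    replicate = []
    for g in genotype_labels:
        reps[g] = reps.get(g, 0) + 1
        replicate.append(reps[g])
    samples = pd.DataFrame({
        "sample_id": columns, "genotype": genotype_labels,
        "replicate": replicate,
    })
    return libraries, ExpressionMatrix(values=values, samples=samples)


def scaled_config(seed: int = 0, **overrides) -> SimConfig:
    """A reduced configuration for fast exploratory runs and unit tests."""
    defaults = dict(
        seed=seed, chrom_len=40_000, n_motif_loci=60, n_nonmotif_loci=15,
        library_depth=30_000, n_target_genes=18,
    )
    defaults.update(overrides)
    return SimConfig(**defaults)
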
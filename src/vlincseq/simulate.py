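"""Synthetic genomes, annotations and SMS-like reads with known truth.

The generator emulates the salient properties of single-molecule cDNA
sequencing of cellular RNA: short trimmed reads (25-55 nt, mean ~34), a
deletion-dominant per-base error process, occasional leading-T homopolymer
artifacts from the dA-tailing chemistry, a category mixture over
ribosomal / mitochondrial / exonic / intronic / intergenic origins, and
gene-desert regions harbouring planted high-density transcribed domains of
at least 50 kb (the ground truth for the vlinc caller). Ribosomal and
mitochondrial reads originate from decoy contigs named ``rDNA`` and
``chrM`` so the exclusion filter is exercisable.

Every read is emitted together with its true placement as a gapped
tag/reference alignment, so the scoring formula downstream is auditable
base by base. All sampling flows through one ``numpy`` generator seeded
from the config: a seed fully determines the dataset.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import intervals as iv
from .models import AlignedRead, AlignmentBlock, Category, TranscriptModel

BASES = "ACGT"
_BASE_CODES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: Fixed category order used for multinomial draws.
CATEGORY_ORDER = (
    Category.RIBOSOMAL,
    Category.MITOCHONDRIAL,
    Category.EXONIC,
    Category.INTRONIC,
    Category.INTERGENIC,
)

#: Sampling slack (bp) kept between a read start and its segment end so the
#: genomic footprint (tag length + deletions) always fits.
_FOOTPRINT_SLACK = 16


@dataclass(frozen=True)
class VlincSpec:
    """Planted intergenic domain specification."""

    count: int = 3
    length_range: Tuple[int, int] = (60_000, 300_000)
    #: Per-bp read density inside a domain relative to intergenic background.
    multiplier: float = 50.0
    min_separation: int = 30_000

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("vlinc count must be >= 0")
        if self.length_range[0] < 50_000:
            raise ValueError("vlinc lengths must be >= 50,000 bp")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("bad vlinc length range")
        if self.multiplier <= 0:
            raise ValueError("density multiplier must be positive")


def _default_mixture() -> Dict[Category, float]:
    # A RiboMinus-like human sample: residual rRNA plus mtRNA, and an
    # informative pool of ~45% exonic / 40% intronic / 15% intergenic.
    return {
        Category.RIBOSOMAL: 0.20,
        Category.MITOCHONDRIAL: 0.05,
        Category.EXONIC: 0.34,
        Category.INTRONIC: 0.30,
        Category.INTERGENIC: 0.11,
    }


@dataclass
class SyntheticConfig:
    """All knobs of the synthetic study, with realistic defaults."""

    seed: int
    chrom_sizes: Dict[str, int]
    n_genes: int = 20
    exons_per_gene: Tuple[int, int] = (3, 8)
    exon_length: Tuple[int, int] = (100, 400)
    intron_length: Tuple[int, int] = (500, 5_000)
    #: Leading fraction of each chromosome where genes may be placed; the
    #: remainder is a gene desert reserved for vlinc planting.
    gene_space_fraction: float = 0.4
    read_length: Tuple[int, int] = (25, 55)
    read_length_mean: float = 34.0
    n_reads: int = 100_000
    mixture: Dict[Category, float] = field(default_factory=_default_mixture)
    error_rate: float = 0.04
    deletion_fraction: float = 0.7
    leading_t_rate: float = 0.15
    leading_t_mean: float = 3.0
    multimap_rate: float = 0.0
    vlinc_spec: VlincSpec = field(default_factory=VlincSpec)
    rdna_size: int = 8_000
    chrm_size: int = 16_000

    def __post_init__(self) -> None:
        self.mixture = {Category(k): float(v) for k, v in self.mixture.items()}
        for cat in CATEGORY_ORDER:
            self.mixture.setdefault(cat, 0.0)
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture fractions sum to {total}, not 1")
        if any(v < 0 for v in self.mixture.values()):
            raise ValueError("mixture fractions must be non-negative")
        if not self.chrom_sizes:
            raise ValueError("chrom_sizes must be non-empty")
        if any(n <= 0 for n in self.chrom_sizes.values()):
            raise ValueError("all chromosome lengths must be positive")
        if not (0 < self.gene_space_fraction < 1):
            raise ValueError("gene_space_fraction must be in (0, 1)")
        lo, hi = self.read_length
        if not (0 < lo <= self.read_length_mean <= hi):
            raise ValueError("read_length_mean must lie within read_length range")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if not (0 <= self.deletion_fraction <= 1):
            raise ValueError("deletion_fraction must be in [0, 1]")

    @property
    def mixture_probs(self) -> np.ndarray:
        return np.array([self.mixture[c] for c in CATEGORY_ORDER], dtype=float)


def config_from_key_values(kv: Dict[str, str]) -> "SyntheticConfig":
    """Build a config from a flat key-value mapping (text config dialect).

    Recognized keys: seed; chrom_sizes ("chr1:1000000,chr2:500000");
    mixture ("exonic:0.4,intronic:0.35,intergenic:0.25"); n_genes; n_reads;
    error_rate; deletion_fraction; leading_t_rate; gene_space_fraction;
    multimap_rate; vlinc_count; vlinc_min_length; vlinc_max_length;
    vlinc_multiplier. Seed is mandatory.
    """
    if "seed" not in kv:
        raise ValueError("config must set a seed")
    if "chrom_sizes" not in kv:
        raise ValueError("config must set chrom_sizes")
    chrom_sizes = {}
    for item in kv["chrom_sizes"].split(","):
        name, _, size = item.strip().partition(":")
        chrom_sizes[name] = int(size)
    kwargs: Dict[str, object] = {"seed": int(kv["seed"]), "chrom_sizes": chrom_sizes}
    if "mixture" in kv:
        mixture = {}
        for item in kv["mixture"].split(","):
            name, _, frac = item.strip().partition(":")
            mixture[Category(name)] = float(frac)
        kwargs["mixture"] = mixture
    for key, conv in (
        ("n_genes", int), ("n_reads", int), ("error_rate", float),
        ("deletion_fraction", float), ("leading_t_rate", float),
        ("gene_space_fraction", float), ("multimap_rate", float),
    ):
        if key in kv:
            kwargs[key] = conv(kv[key])
    if any(k.startswith("vlinc_") for k in kv):
        spec = VlincSpec(
            count=int(kv.get("vlinc_count", VlincSpec.count)),
            length_range=(
                int(kv.get("vlinc_min_length", VlincSpec.length_range[0])),
                int(kv.get("vlinc_max_length", VlincSpec.length_range[1])),
            ),
            multiplier=float(kv.get("vlinc_multiplier", VlincSpec.multiplier)),
        )
        kwargs["vlinc_spec"] = spec
    return SyntheticConfig(**kwargs)  # type: ignore[arg-type]


@dataclass
class SimulatedReads:
    """Read set plus ground truth."""

    placements: List[AlignedRead]
    raw_sequences: Dict[str, str]
    truth: pd.DataFrame  # read_id, category, chrom, start, end


@dataclass
class SimulatedDataset:
    config: SyntheticConfig
    genome: Dict[str, str]
    transcripts: List[TranscriptModel]
    vlincs: List[Tuple[str, int, int]]
    reads: SimulatedReads


def _random_sequence(n: int, rng: np.random.Generator) -> str:
    codes = rng.integers(0, 4, size=n, dtype=np.uint8)
    return bytes(_BASE_CODES[codes]).decode("ascii")


def generate_genome(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> Dict[str, str]:
    """Random nuclear chromosomes plus the rDNA and chrM decoy contigs."""
    rng = rng or np.random.default_rng(config.seed)
    genome = {
        name: _random_sequence(size, rng)
        for name, size in config.chrom_sizes.items()
    }
    genome["rDNA"] = _random_sequence(config.rdna_size, rng)
    genome["chrM"] = _random_sequence(config.chrm_size, rng)
    return genome


def _gene_counts_per_chrom(config: SyntheticConfig) -> Dict[str, int]:
    """Largest-remainder apportionment of genes by chromosome size."""
    names = list(config.chrom_sizes)
    sizes = np.array([config.chrom_sizes[n] for n in names], dtype=float)
    quota = config.n_genes * sizes / sizes.sum()
    counts = np.floor(quota).astype(int)
    remainder = config.n_genes - int(counts.sum())
    for i in np.argsort(-(quota - counts))[:remainder]:
        counts[i] += 1
    return dict(zip(names, counts))


def generate_annotation(
    config: SyntheticConfig, rng: Optional[np.random.Generator] = None
) -> List[TranscriptModel]:
    """Place non-overlapping multi-exon transcripts in the genic region.

    Genes occupy only the leading ``gene_space_fraction`` of each
    chromosome; the rest is a designated gene desert left annotation-free
    for vlinc planting. Raises if the requested genes cannot fit.
    """
    rng = rng or np.random.default_rng(config.seed)
    counts = _gene_counts_per_chrom(config)
    transcripts: List[TranscriptModel] = []
    gene_no = 0
    for chrom, size in config.chrom_sizes.items():
        region_end = int(size * config.gene_space_fraction)
        pos = int(rng.integers(1_000, 5_000))
        for _ in range(counts[chrom]):
            gene_no += 1
            n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            ex_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, n_ex)
            in_lens = rng.integers(config.intron_length[0], config.intron_length[1] + 1, max(n_ex - 1, 0))
            starts, ends = [], []
            cursor = pos
            for i, el in enumerate(ex_lens):
                starts.append(cursor)
                cursor += int(el)
                ends.append(cursor)
                if i < len(in_lens):
                    cursor += int(in_lens[i])
            if cursor > region_end:
                raise ValueError(
                    f"requested genes cannot fit: gene {gene_no} exceeds the "
                    f"genic region of {chrom} ({region_end} bp)"
                )
            strand = "+" if rng.random() < 0.5 else "-"
            transcripts.append(
                TranscriptModel(
                    transcript_id=f"gene_{gene_no}",
                    chrom=chrom,
                    strand=strand,
                    start=starts[0],
                    end=ends[-1],
                    exon_starts=tuple(starts),
                    exon_ends=tuple(ends),
                )
            )
            pos = cursor + int(rng.integers(2_000, 20_000))
    return transcripts


def plant_vlincs(
    annotation: Sequence[TranscriptModel],
    config: SyntheticConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[Tuple[str, int, int]]:
    """Reserve disjoint >=50 kb domains in the gene deserts.

    Domains never overlap any transcript span and are separated by at least
    ``min_separation``. Raises when the deserts cannot host the request.
    """
    rng = rng or np.random.default_rng(config.seed)
    spec = config.vlinc_spec
    if spec.count == 0:
        return []
    gene_spans: Dict[str, List[Tuple[int, int]]] = {}
    for t in annotation:
        gene_spans.setdefault(t.chrom, []).append((t.start, t.end))
    cursors: Dict[str, Tuple[int, int]] = {}
    for chrom, size in config.chrom_sizes.items():
        desert_start = int(size * config.gene_space_fraction) + 50_000
        desert_end = size - 50_000
        if desert_end > desert_start:
            cursors[chrom] = (desert_start, desert_end)
    planted: List[Tuple[str, int, int]] = []
    for _ in range(spec.count):
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        placed = False
        for chrom in list(cursors):
            start, limit = cursors[chrom]
            if start + length <= limit:
                planted.append((chrom, start, start + length))
                gap = int(rng.integers(spec.min_separation, 3 * spec.min_separation))
                cursors[chrom] = (start + length + gap, limit)
                placed = True
                break
        if not placed:
            raise ValueError("insufficient intergenic space to plant vlinc domains")
    for chrom, s, e in planted:
        for gs, ge in gene_spans.get(chrom, ()):
            if s < ge and gs < e:  # pragma: no cover - defensive
                raise AssertionError("planted domain overlaps a gene span")
    return planted


def _choose_sub(refbase: str, u: float, forbid_t: bool = False) -> str:
    alts = [b for b in BASES if b != refbase and not (forbid_t and b == "T")]
    return alts[int(u * len(alts)) % len(alts)]


def _synthesize_read(
    seq: str,
    start: int,
    length: int,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> Tuple[str, str, str, int]:
    """Copy ``length`` tag bases from ``seq[start:]`` applying the error model.

    Returns (tag, gapped tag, gapped ref, footprint end). The first tag base
    is always an error-free copy so that leading-T trimming downstream can
    never consume genuine sequence (read starts are sampled on non-T bases).
    """
    us = rng.random(length + _FOOTPRINT_SLACK)
    ui = 0
    tag: List[str] = []
    tag_g: List[str] = []
    ref_g: List[str] = []
    pos = start
    while len(tag) < length:
        if ui >= len(us):  # rare top-up when many deletions occurred
            us = rng.random(length)
            ui = 0
        refbase = seq[pos]
        if not tag:  # first tag base: forced exact copy
            tag.append(refbase)
            tag_g.append(refbase)
            ref_g.append(refbase)
            pos += 1
            continue
        u = us[ui]
        ui += 1
        if u < config.error_rate:
            if u / config.error_rate < config.deletion_fraction:
                tag_g.append("-")  # deleted reference base
                ref_g.append(refbase)
                pos += 1
                continue
            if ui >= len(us):
                us = rng.random(length)
                ui = 0
            sub = _choose_sub(refbase, us[ui])
            ui += 1
            tag.append(sub)
            tag_g.append(sub)
            ref_g.append(refbase)
            pos += 1
        else:
            tag.append(refbase)
            tag_g.append(refbase)
            ref_g.append(refbase)
            pos += 1
    return "".join(tag), "".join(tag_g), "".join(ref_g), pos


def _sample_length(config: SyntheticConfig, rng: np.random.Generator) -> int:
    """Trimmed read length: min + truncated geometric, mean ~read_length_mean."""
    lo, hi = config.read_length
    p = 1.0 / (config.read_length_mean - lo + 1.0)
    k = int(rng.geometric(p)) - 1
    return lo + min(k, hi - lo)


def _sample_start(
    seq: str, lo: int, hi: int, length: int, rng: np.random.Generator
) -> int:
    """Uniform start in [lo, hi - length - slack] landing on a non-T base."""
    span = hi - lo - length - _FOOTPRINT_SLACK
    if span <= 0:
        raise ValueError("segment too short to host a read")
    for _ in range(100):
        start = lo + int(rng.integers(0, span + 1))
        if seq[start] != "T":
            return start
    while start < lo + span and seq[start] == "T":  # pathological T run
        start += 1
    return start


class _IntergenicSampler:
    """Weighted sampler over intergenic segments.

    Segments inside planted vlinc domains carry ``multiplier`` weight per
    base so the within-domain read density is elevated by that factor over
    the intergenic background.
    """

    def __init__(
        self,
        config: SyntheticConfig,
        annotation: Sequence[TranscriptModel],
        vlincs: Sequence[Tuple[str, int, int]],
    ) -> None:
        min_len = config.read_length[1] + _FOOTPRINT_SLACK + 8
        self.segments: List[Tuple[str, int, int]] = []
        weights: List[float] = []
        vl_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
        for chrom, s, e in vlincs:
            vl_by_chrom.setdefault(chrom, []).append((s, e))
        for chrom, size in config.chrom_sizes.items():
            genic = iv.merge(
                (t.start - 100, t.end + 100)
                for t in annotation
                if t.chrom == chrom
            )
            inter = iv.subtract([(100, size - 100)], genic)
            vl = vl_by_chrom.get(chrom, [])
            hot = iv.intersect(inter, vl)
            cold = iv.subtract(inter, vl)
            for s, e in hot:
                if e - s >= min_len:
                    self.segments.append((chrom, s, e))
                    weights.append((e - s) * config.vlinc_spec.multiplier)
            for s, e in cold:
                if e - s >= min_len:
                    self.segments.append((chrom, s, e))
                    weights.append(float(e - s))
        if not self.segments:
            raise ValueError("no intergenic space available for read sampling")
        w = np.array(weights, dtype=float)
        self.cum = np.cumsum(w / w.sum())

    def draw(self, rng: np.random.Generator) -> Tuple[str, int, int]:
        idx = int(np.searchsorted(self.cum, rng.random(), side="right"))
        return self.segments[min(idx, len(self.segments) - 1)]


def generate_reads(
    annotation: Sequence[TranscriptModel],
    genome: Dict[str, str],
    config: SyntheticConfig,
    vlincs: Sequence[Tuple[str, int, int]] = (),
    rng: Optional[np.random.Generator] = None,
) -> SimulatedReads:
    """Draw reads from the category mixture with true placements attached."""
    rng = rng or np.random.default_rng(config.seed)
    probs = config.mixture_probs
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("mixture fractions must sum to 1")
    counts = rng.multinomial(config.n_reads, probs)

    exon_pool: List[Tuple[str, int, int]] = []
    intron_pool: List[Tuple[str, int, int]] = []
    for t in annotation:
        exon_pool.extend((t.chrom, s, e) for s, e in t.exons)
        intron_pool.extend((t.chrom, s, e) for s, e in t.introns)

    def _pool_sampler(pool: List[Tuple[str, int, int]]):
        w = np.array([e - s for _, s, e in pool], dtype=float)
        cum = np.cumsum(w / w.sum())

        def draw() -> Tuple[str, int, int]:
            idx = int(np.searchsorted(cum, rng.random(), side="right"))
            return pool[min(idx, len(pool) - 1)]

        return draw

    needs_genic = counts[2] > 0 or counts[3] > 0
    if needs_genic and not exon_pool:
        raise ValueError("mixture requests genic reads but annotation is empty")
    draw_exon = _pool_sampler(exon_pool) if exon_pool else None
    draw_intron = _pool_sampler(intron_pool) if intron_pool else None
    if counts[3] > 0 and draw_intron is None:
        raise ValueError("mixture requests intronic reads but no transcript has introns")
    intergenic = (
        _IntergenicSampler(config, annotation, vlincs) if counts[4] > 0 else None
    )

    placements: List[AlignedRead] = []
    raw_sequences: Dict[str, str] = {}
    truth_rows: List[Tuple[str, str, str, int, int]] = []
    read_no = 0
    for cat, n_cat in zip(CATEGORY_ORDER, counts):
        for _ in range(int(n_cat)):
            read_no += 1
            rid = f"read_{read_no:07d}"
            length = _sample_length(config, rng)
            if cat is Category.RIBOSOMAL:
                chrom, lo, hi = "rDNA", 0, config.rdna_size
            elif cat is Category.MITOCHONDRIAL:
                chrom, lo, hi = "chrM", 0, config.chrm_size
            elif cat is Category.EXONIC:
                chrom, lo, hi = draw_exon()
            elif cat is Category.INTRONIC:
                chrom, lo, hi = draw_intron()
            else:
                chrom, lo, hi = intergenic.draw(rng)
            seq = genome[chrom]
            start = _sample_start(seq, lo, hi, length, rng)
            tag, tag_g, ref_g, end = _synthesize_read(seq, start, length, config, rng)
            raw = tag
            if rng.random() < config.leading_t_rate:
                k = int(rng.geometric(1.0 / config.leading_t_mean))
                raw = "T" * k + tag
            raw_sequences[rid] = raw
            placements.append(
                AlignedRead(rid, chrom, start, AlignmentBlock(tag_g, ref_g))
            )
            truth_rows.append((rid, cat.value, chrom, start, end))

    if config.multimap_rate > 0:
        nuclear = list(config.chrom_sizes)
        for read in list(placements):
            if rng.random() < config.multimap_rate:
                c = nuclear[int(rng.integers(len(nuclear)))]
                limit = config.chrom_sizes[c] - read.block.ref_length
                s = int(rng.integers(0, max(limit, 1)))
                # An exact-repeat decoy: identical alignment elsewhere ties
                # the best score, so the unique-best filter drops the read.
                placements.append(AlignedRead(read.read_id, c, s, read.block))

    truth = pd.DataFrame(
        truth_rows, columns=["read_id", "category", "chrom", "start", "end"]
    )
    return SimulatedReads(placements, raw_sequences, truth)


def simulate(config: SyntheticConfig) -> SimulatedDataset:
    """Full deterministic study: genome, annotation, planted domains, reads."""
    rng = np.random.default_rng(config.seed)
    genome = generate_genome(config, rng)
    transcripts = generate_annotation(config, rng)
    vlincs = (
        plant_vlincs(transcripts, config, rng)
        if config.vlinc_spec.count > 0
        else []
    )
    reads = generate_reads(transcripts, genome, config, vlincs, rng)
    return SimulatedDataset(config, genome, transcripts, vlincs, reads)
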
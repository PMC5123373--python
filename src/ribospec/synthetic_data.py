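"""Synthetic transcriptome and ribosome-profiling fixtures with known truth.

The generator emulates the two signal classes the classifier must
separate: translated regions, whose P-sites are drawn per codon with
frame probabilities (p, (1-p)/2, (1-p)/2) so a periodicity parameter
p = 1/3 means no frame preference and p = 1 a perfect tri-nucleotide
signal; and untranslated regions with uniform P-site placement.  Read
lengths follow a configurable mix peaked at 28-30 nt for coding-style
reads (cycloheximide libraries) and a flatter mix for non-coding
transcripts.  Every fixture (GTF, SAM, truth table) is a plain-text file,
deterministic under the seed.

Reads are emitted as single-block alignments positioned so the inferred
P-site (5' end + 12 nt) lands exactly on the drawn exonic position; a
read body may overhang an exon end, but the P-site never does, so the
truth count vectors are recovered exactly by the coverage extractor.

Also provides the biased length-resampling utility used for robustness
analysis: reads are resampled with weight exp(b * |length - 28.5|), so
b = 0 reproduces the population mix and increasing b progressively
flattens the 28-30 nt enrichment toward a uniform length distribution.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pysam

from .annotation_coverage import TranscriptModel

#: read-length mix typical of a cycloheximide-treated footprint library
CODING_LENGTH_MIX = {26: 0.02, 27: 0.06, 28: 0.30, 29: 0.32, 30: 0.20, 31: 0.07, 32: 0.03}
#: flatter mix for non-coding transcripts (fragments not ribosome-protected
#: in a codon-stepping complex show broader size selection)
NONCODING_LENGTH_MIX = {26: 0.10, 27: 0.12, 28: 0.18, 29: 0.18, 30: 0.15, 31: 0.14, 32: 0.13}

_PSITE_OFFSET = 12


@dataclass
class SimConfig:
    """Study conditions for fixture generation.

    Defaults describe a realistic desk-scale experiment: a notional
    library of 5e7 mapped reads, transcript abundance FPKM ~
    LogNormal(ln 8, 1.5), and frame fidelity p = 0.85 as seen in good
    cycloheximide libraries.
    """

    n_coding: int = 20
    n_noncoding: int = 20
    cds_codons_range: tuple[int, int] = (120, 400)
    utr5_range: tuple[int, int] = (60, 200)
    utr3_range: tuple[int, int] = (60, 300)
    noncoding_length_range: tuple[int, int] = (400, 1500)
    multi_exon_fraction: float = 0.5
    max_exons: int = 4
    intron_range: tuple[int, int] = (60, 500)
    fpkm_log_mu: float = math.log(8.0)
    fpkm_log_sigma: float = 1.5
    total_mapped_reads: int = 50_000_000
    periodicity: float = 0.85
    length_mix: dict[int, float] = field(default_factory=lambda: dict(CODING_LENGTH_MIX))
    noncoding_length_mix: dict[int, float] = field(
        default_factory=lambda: dict(NONCODING_LENGTH_MIX)
    )
    bias: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 / 3 - 1e-9 <= self.periodicity <= 1.0):
            raise ValueError("periodicity must lie in [1/3, 1]")
        for mix in (self.length_mix, self.noncoding_length_mix):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("length mix probabilities must sum to 1")
        if self.cds_codons_range[0] * 3 < 60:
            raise ValueError("CDS must be at least 60 nt")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=str)


@dataclass
class TruthRegion:
    transcript_id: str
    region: str
    translated: bool
    true_p: float
    true_fpkm: float
    n_reads: int
    counts: np.ndarray


@dataclass
class TruthTable:
    """Ground truth for every simulated scored region."""

    regions: list[TruthRegion]
    seed: int

    def counts_of(self, transcript_id: str) -> np.ndarray:
        for r in self.regions:
            if r.transcript_id == transcript_id:
                return r.counts
        raise KeyError(transcript_id)

    def write_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# seed={self.seed}\n")
            fh.write(
                "transcript_id\tregion\ttranslated\ttrue_p\ttrue_fpkm\tn_reads\n"
            )
            for r in self.regions:
                fh.write(
                    f"{r.transcript_id}\t{r.region}\t{int(r.translated)}\t"
                    f"{r.true_p:.4f}\t{r.true_fpkm:.4f}\t{r.n_reads}\n"
                )


@dataclass
class Transcriptome:
    models: list[TranscriptModel]
    chrom_sizes: dict[str, int]
    gtf_path: str | None = None


@dataclass
class ReadSet:
    """In-memory footprint set over one region (transcript coordinates)."""

    positions: np.ndarray  # P-site position in region space
    lengths: np.ndarray

    def __len__(self) -> int:
        return int(self.positions.size)

    def length_histogram(self) -> dict[int, int]:
        lengths, counts = np.unique(self.lengths, return_counts=True)
        return {int(l): int(c) for l, c in zip(lengths, counts)}


# ---------------------------------------------------------------------------
# transcriptome
# ---------------------------------------------------------------------------

def _split_length(rng, total: int, n_parts: int, minimum: int = 40) -> list[int]:
    """Partition total nt into n_parts pieces, each >= minimum."""
    if n_parts * minimum > total:
        n_parts = max(1, total // minimum)
    if n_parts == 1:
        return [total]
    cuts = np.sort(rng.choice(total - n_parts * minimum + 1, n_parts - 1, replace=True))
    sizes = np.diff(np.concatenate([[0], cuts, [total - n_parts * minimum]]))
    return [int(s) + minimum for s in sizes]


def simulate_transcriptome(cfg: SimConfig, gtf_path: str | None = None) -> Transcriptome:
    """Lay out coding and non-coding transcripts on two chromosomes.

    Coding transcripts carry 5'UTR/CDS/3'UTR structure (CDS a multiple of
    3); about half of all transcripts are multi-exon.  Deterministic under
    cfg.seed; writing the GTF twice from the same config is byte-identical.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 0]))
    cursors = {"chrS1": 1000, "chrS2": 1000}
    chroms = list(cursors)
    models: list[TranscriptModel] = []
    specs = [("protein_coding", i) for i in range(cfg.n_coding)] + [
        ("lincRNA", i) for i in range(cfg.n_noncoding)
    ]
    for k, (biotype, i) in enumerate(specs):
        chrom = chroms[k % len(chroms)]
        if biotype == "protein_coding":
            n_codons = int(rng.integers(*cfg.cds_codons_range))
            u5 = int(rng.integers(*cfg.utr5_range))
            u3 = int(rng.integers(*cfg.utr3_range))
            tx_len = u5 + 3 * n_codons + u3
            tid = f"SIMC{i:05d}"
        else:
            tx_len = int(rng.integers(*cfg.noncoding_length_range))
            u5 = u3 = 0
            tid = f"SIMN{i:05d}"
        multi = rng.random() < cfg.multi_exon_fraction
        n_exons = int(rng.integers(2, cfg.max_exons + 1)) if multi else 1
        exon_lens = _split_length(rng, tx_len, n_exons)
        strand = "+" if rng.random() < 0.5 else "-"
        start = cursors[chrom] + int(rng.integers(500, 2000))
        exons, pos = [], start
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el
            if j < len(exon_lens) - 1:
                pos += int(rng.integers(*cfg.intron_range))
        cursors[chrom] = pos

        cds_intervals: list[tuple[int, int]] = []
        if biotype == "protein_coding":
            # transcript-space CDS interval [u5, u5 + 3*n_codons) mapped to genome
            coords = np.concatenate([np.arange(s, e) for s, e in exons])
            if strand == "-":
                coords = coords[::-1]
            cds_coords = np.sort(coords[u5 : u5 + 3 * n_codons])
            breaks = np.flatnonzero(np.diff(cds_coords) != 1) + 1
            for run in np.split(cds_coords, breaks):
                cds_intervals.append((int(run[0]), int(run[-1]) + 1))
        models.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=tid.replace("SIM", "GENE"),
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds=cds_intervals,
                biotype=biotype,
            )
        )
    chrom_sizes = {c: cursors[c] + 2000 for c in chroms}
    tr = Transcriptome(models, chrom_sizes, gtf_path)
    if gtf_path is not None:
        write_gtf(tr, gtf_path)
    return tr


def write_gtf(tr: Transcriptome, path: str) -> None:
    """Write GENCODE-dialect GTF (1-based closed coordinates)."""
    lines = ["##provider: ribospec synthetic fixture\n"]
    for m in sorted(tr.models, key=lambda m: (m.chrom, m.span[0], m.transcript_id)):
        attrs = (
            f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
            f'transcript_biotype "{m.biotype}";'
        )
        s, e = m.span
        lines.append(
            f"{m.chrom}\tribospec\ttranscript\t{s + 1}\t{e}\t.\t{m.strand}\t.\t{attrs}\n"
        )
        for xs, xe in m.exons:
            lines.append(
                f"{m.chrom}\tribospec\texon\t{xs + 1}\t{xe}\t.\t{m.strand}\t.\t{attrs}\n"
            )
        for cs, ce in m.cds:
            lines.append(
                f"{m.chrom}\tribospec\tCDS\t{cs + 1}\t{ce}\t.\t{m.strand}\t.\t{attrs}\n"
            )
    with open(path, "w") as fh:
        fh.writelines(lines)


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def draw_region_reads(
    rng, region_len: int, n_reads: int, translated: bool, p: float, mix: dict[int, float]
) -> ReadSet:
    if translated:
        n_codons = region_len // 3
        codons = rng.integers(0, n_codons, n_reads)
        frames = rng.choice(3, n_reads, p=[p, (1 - p) / 2, (1 - p) / 2])
        positions = codons * 3 + frames
    else:
        positions = rng.integers(0, region_len, n_reads)
    lengths = rng.choice(
        np.fromiter(mix.keys(), dtype=int),
        n_reads,
        p=np.fromiter(mix.values(), dtype=float),
    )
    return ReadSet(positions.astype(np.int64), lengths.astype(np.int64))


def simulate_ribo_reads(
    cfg: SimConfig,
    transcriptome: Transcriptome,
    sam_path: str | None = None,
    truth_path: str | None = None,
) -> tuple[TruthTable, dict[str, ReadSet]]:
    """Draw footprints per region and (optionally) write a SAM fixture.

    Scored region: CDS for protein-coding transcripts, full transcript
    otherwise.  Expected read counts follow the FPKM invariant against
    the notional library size: n = Poisson(fpkm * len * total / 1e9).
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    truth_regions: list[TruthRegion] = []
    readsets: dict[str, ReadSet] = {}
    alignments: list[tuple[str, int, bool, int, str]] = []

    for m in transcriptome.models:
        translated = m.biotype == "protein_coding"
        region = "CDS" if translated else "full"
        coords = m.region_coords(region)
        region_len = coords.size
        fpkm = float(rng.lognormal(cfg.fpkm_log_mu, cfg.fpkm_log_sigma))
        lam = fpkm * region_len * cfg.total_mapped_reads / 1e9
        n_reads = int(rng.poisson(lam))
        mix = cfg.length_mix if translated else cfg.noncoding_length_mix
        rs = draw_region_reads(
            rng, region_len, n_reads, translated, cfg.periodicity, mix
        )
        readsets[m.transcript_id] = rs
        counts = np.bincount(rs.positions, minlength=region_len)[:region_len]
        truth_regions.append(
            TruthRegion(
                m.transcript_id, region, translated,
                cfg.periodicity if translated else 1 / 3,
                fpkm, n_reads, counts.astype(np.int64),
            )
        )
        g = coords[rs.positions]
        for gpos, length in zip(g, rs.lengths):
            if m.strand == "+":
                start = int(gpos) - _PSITE_OFFSET
            else:
                start = int(gpos) - int(length) + 1 + _PSITE_OFFSET
            alignments.append((m.chrom, start, m.strand == "-", int(length), m.transcript_id))

    truth = TruthTable(truth_regions, cfg.seed)
    if truth_path is not None:
        truth.write_tsv(truth_path)
    if sam_path is not None:
        write_sam(alignments, transcriptome.chrom_sizes, sam_path)
    return truth, readsets


def write_sam(
    alignments: list[tuple[str, int, bool, int, str]],
    chrom_sizes: dict[str, int],
    path: str,
) -> None:
    """Write coordinate-sorted single-block alignments as plain SAM."""
    chroms = sorted(chrom_sizes)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": int(chrom_sizes[c])} for c in chroms],
    }
    tid_of = {c: i for i, c in enumerate(chroms)}
    ordered = sorted(enumerate(alignments), key=lambda kv: (tid_of[kv[1][0]], kv[1][1]))
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for serial, (chrom, start, reverse, length, origin) in ordered:
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"{origin}.r{serial:07d}"
            a.flag = 16 if reverse else 0
            a.reference_id = tid_of[chrom]
            a.reference_start = start
            a.mapping_quality = 255
            a.cigarstring = f"{length}M"
            a.query_sequence = "A" * length
            out.write(a)


def sam_to_indexed_bam(sam_path: str, bam_path: str) -> str:
    """Convert a coordinate-sorted SAM fixture to an indexed BAM."""
    pysam.sort("-o", bam_path, sam_path)
    pysam.index(bam_path)
    return bam_path


# ---------------------------------------------------------------------------
# biased length resampling
# ---------------------------------------------------------------------------

def biased_resample(
    reads: ReadSet,
    bias: float,
    n_sample: int,
    n_trials: int,
    seed: int,
) -> list[ReadSet]:
    """Resample read subsets with a length-dependent weight.

    Each trial draws ``n_sample`` reads without replacement with weight
    proportional to exp(bias * |length - 28.5|); bias 0 is uniform
    sampling, larger bias progressively flattens the 28-30 nt enrichment
    toward a uniform length distribution.  Sampling uses the Gumbel
    top-k trick so 10^3 trials over 10^5-read populations stay fast.
    Deterministic under the seed.
    """
    if len(reads) == 0:
        raise ValueError("read population is empty")
    if n_sample > len(reads):
        raise ValueError("n_sample exceeds the population size")
    rng = np.random.default_rng(seed)
    logw = bias * np.abs(reads.lengths.astype(float) - 28.5)
    out = []
    for _ in range(n_trials):
        keys = logw + rng.gumbel(size=logw.size)
        idx = np.argpartition(-keys, n_sample - 1)[:n_sample]
        idx.sort()
        out.append(ReadSet(reads.positions[idx], reads.lengths[idx]))
    return out
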
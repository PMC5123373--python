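"""Transcript models, GTF parsing, P-site assignment and per-region coverage.

A transcript is represented by its exon (and optionally CDS) intervals in
genomic coordinates (0-based, half-open, as in BAM).  Scored regions —
``5UTR``, ``CDS``, ``3UTR`` and ``full`` — are ordered coordinate sets in
transcript orientation: index 0 is always the 5' end, so on minus-strand
transcripts genomic coordinates descend along the region.

Ribosome footprints are reduced to a single inferred P-site position per
read (5' end + a length-dependent offset), and a region's coverage profile
is the tally of P-sites over its coordinate set.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pysam

log = logging.getLogger(__name__)

#: biotypes treated as protein-coding for calibration and filtering
CODING_BIOTYPES = frozenset({"protein_coding"})

#: community-standard cycloheximide P-site offset (+12 nt from the 5' end)
#: for ribosome-protected fragments of 26-32 nt
DEFAULT_OFFSETS: dict[int, int] = {n: 12 for n in range(26, 33)}

REGION_NAMES = ("5UTR", "CDS", "3UTR", "full")

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')
_BIOTYPE_KEYS = ("transcript_biotype", "transcript_type", "gene_biotype", "gene_type")


class GtfParseError(ValueError):
    """Raised for a malformed GTF line; message names the line number."""


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` and ``cds`` are lists of (start, end) genomic intervals,
    0-based half-open, sorted in ascending genomic order regardless of
    strand.  Transcript orientation is applied when coordinate sets are
    materialised via :meth:`region_coords`.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        self.cds = sorted((int(s), int(e)) for s, e in self.cds)
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if s1 < e0:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons {(s0, e0)} and {(s1, e1)}"
                )

    # -- geometry ---------------------------------------------------------

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end) of the transcript footprint."""
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds) or self.biotype in CODING_BIOTYPES

    def exonic_coords(self) -> np.ndarray:
        """Genomic coordinates of every exonic base, 5'->3'."""
        coords = np.concatenate([np.arange(s, e) for s, e in self.exons])
        if self.strand == "-":
            coords = coords[::-1]
        return coords

    def region_coords(self, region: str = "full") -> np.ndarray:
        """Ordered genomic coordinate set C for a named sub-region."""
        coords = self.exonic_coords()
        if region == "full":
            return coords
        if region not in REGION_NAMES:
            raise ValueError(f"unknown region {region!r}")
        if not self.cds:
            return coords[:0]
        in_cds = np.zeros(coords.size, dtype=bool)
        for s, e in self.cds:
            in_cds |= (coords >= s) & (coords < e)
        if region == "CDS":
            return coords[in_cds]
        idx = np.flatnonzero(in_cds)
        if region == "5UTR":
            return coords[: idx[0]]
        return coords[idx[-1] + 1 :]  # 3UTR

    def region_length(self, region: str = "full") -> int:
        return int(self.region_coords(region).size)


@dataclass
class PSiteProfile:
    """Per-position P-site counts over a region's coordinate set."""

    transcript_id: str
    region: str
    counts: np.ndarray
    length_histogram: dict[int, int] = field(default_factory=dict)
    skipped: int = 0  # reads dropped for want of a P-site offset

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())


@dataclass
class AbundanceRecord:
    transcript_id: str
    region: str
    read_count: int
    region_length_nt: int
    fpkm: float


# ---------------------------------------------------------------------------
# GTF parsing
# ---------------------------------------------------------------------------

def parse_annotation(
    gtf_path: str,
    biotype_filter: set[str] | None = None,
) -> list[TranscriptModel]:
    """Parse a GENCODE-dialect GTF into :class:`TranscriptModel` objects.

    Only ``exon`` and ``CDS`` features are consumed; coordinates are
    converted from GTF's 1-based closed convention to 0-based half-open.
    Minus-strand orientation is handled downstream (coordinate sets are
    materialised 5'->3'), so exon storage order is always genomic.

    Parameters
    ----------
    gtf_path
        Path to an uncompressed GTF file.
    biotype_filter
        If given, only transcripts whose biotype is in this set are kept.

    Raises
    ------
    GtfParseError
        For a structurally malformed line, naming its line number.
    """
    exons: dict[str, list[tuple[int, int]]] = {}
    cds: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, dict[str, str]] = {}
    order: list[str] = []

    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise GtfParseError(
                    f"{gtf_path}: malformed GTF line {lineno}: "
                    f"expected 9 tab-separated fields, got {len(fields)}"
                )
            feature = fields[2]
            if feature not in ("exon", "CDS"):
                continue
            try:
                start = int(fields[3]) - 1
                end = int(fields[4])
            except ValueError as exc:
                raise GtfParseError(
                    f"{gtf_path}: malformed GTF line {lineno}: non-numeric coordinates"
                ) from exc
            if fields[6] not in ("+", "-"):
                raise GtfParseError(
                    f"{gtf_path}: malformed GTF line {lineno}: bad strand {fields[6]!r}"
                )
            attrs = dict(_ATTR_RE.findall(fields[8]))
            tid = attrs.get("transcript_id")
            if not tid:
                raise GtfParseError(
                    f"{gtf_path}: malformed GTF line {lineno}: missing transcript_id"
                )
            if tid not in meta:
                order.append(tid)
                biotype = next(
                    (attrs[k] for k in _BIOTYPE_KEYS if k in attrs), "unknown"
                )
                meta[tid] = {
                    "gene_id": attrs.get("gene_id", tid),
                    "chrom": fields[0],
                    "strand": fields[6],
                    "biotype": biotype,
                }
            if feature == "exon":
                exons.setdefault(tid, []).append((start, end))
            else:
                cds.setdefault(tid, []).append((start, end))

    models: list[TranscriptModel] = []
    for tid in order:
        if tid not in exons:
            log.warning("transcript %s has zero exon features; skipped", tid)
            continue
        m = meta[tid]
        model = TranscriptModel(
            transcript_id=tid,
            gene_id=m["gene_id"],
            chrom=m["chrom"],
            strand=m["strand"],
            exons=exons[tid],
            cds=cds.get(tid, []),
            biotype=m["biotype"],
        )
        if biotype_filter is not None and model.biotype not in biotype_filter:
            continue
        models.append(model)
    return models


# ---------------------------------------------------------------------------
# P-site assignment and coverage
# ---------------------------------------------------------------------------

def adjust_to_psite(
    read: pysam.AlignedSegment,
    offset_table: dict[int, int] = DEFAULT_OFFSETS,
    default_offset: int | None = None,
) -> int | None:
    """Genomic coordinate of a read's inferred P-site, or None if the
    read length has no offset (caller tallies the skip).

    On the plus strand the P-site is the 5' end (reference_start) plus the
    offset; on the minus strand the 5' end is the high coordinate, so the
    P-site is reference_end - 1 - offset.
    """
    length = read.query_length or read.infer_query_length()
    offset = offset_table.get(length, default_offset)
    if offset is None:
        return None
    if read.is_reverse:
        return read.reference_end - 1 - offset
    return read.reference_start + offset


def extract_psite_profile(
    bam: str | pysam.AlignmentFile,
    transcript: TranscriptModel,
    region: str = "full",
    offset_table: dict[int, int] = DEFAULT_OFFSETS,
    default_offset: int | None = None,
    min_mapq: int = 0,
) -> PSiteProfile:
    """Tally P-site-adjusted read positions over a region's coordinate set.

    Only primary, mapped, strand-matched alignments are counted; a read
    contributes iff its P-site coordinate is a member of the region's
    coordinate set (a P-site in an intron or outside the region is ignored).
    """
    own = isinstance(bam, str)
    handle = pysam.AlignmentFile(bam) if own else bam
    try:
        coords = transcript.region_coords(region)
        counts = np.zeros(coords.size, dtype=np.int64)
        profile = PSiteProfile(transcript.transcript_id, region, counts)
        if coords.size == 0:
            return profile
        if transcript.chrom not in handle.references:
            log.warning(
                "chromosome %s absent from alignment header; empty profile for %s",
                transcript.chrom,
                transcript.transcript_id,
            )
            return profile
        index = {int(g): i for i, g in enumerate(coords)}
        lo, hi = int(coords.min()), int(coords.max()) + 1
        want_reverse = transcript.strand == "-"
        # pad the fetch window so reads whose body starts outside the region
        # but whose P-site falls inside are still seen
        pad = 50
        for read in handle.fetch(transcript.chrom, max(0, lo - pad), hi + pad):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            if read.is_reverse != want_reverse:
                continue
            psite = adjust_to_psite(read, offset_table, default_offset)
            if psite is None:
                profile.skipped += 1
                continue
            i = index.get(psite)
            if i is None:
                continue
            counts[i] += 1
            length = read.query_length or read.infer_query_length()
            profile.length_histogram[length] = (
                profile.length_histogram.get(length, 0) + 1
            )
        return profile
    finally:
        if own:
            handle.close()


def compute_fpkm(profile: PSiteProfile, total_mapped_reads: int) -> AbundanceRecord:
    """Fragments per kilobase of region per million mapped reads.

    fpkm = read_count * 1e9 / (region_length_nt * total_mapped_reads)
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    n = profile.total_reads
    length = int(profile.counts.size)
    fpkm = 0.0 if length == 0 else n * 1e9 / (length * total_mapped_reads)
    return AbundanceRecord(profile.transcript_id, profile.region, n, length, fpkm)


def filter_conflicting_transcripts(
    models: list[TranscriptModel],
    flank: int = 0,
) -> list[TranscriptModel]:
    """Drop transcripts whose genomic span conflicts with a transcript of
    the opposite biotype class (coding vs non-coding).

    A conflict is overlap of the two spans after extending each side by
    ``flank`` nt, on either strand (antisense overlap counts).  Both
    members of a conflicting pair are removed; same-class overlaps (e.g.
    two isoforms of one gene) are retained.
    """
    def klass(m: TranscriptModel) -> str:
        return "coding" if m.is_coding else "noncoding"

    doomed: set[str] = set()
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    for group in by_chrom.values():
        for i, a in enumerate(group):
            for b in group[i + 1 :]:
                if klass(a) == klass(b):
                    continue
                (as_, ae), (bs, be) = a.span, b.span
                if as_ < be + flank and bs < ae + flank:
                    doomed.add(a.transcript_id)
                    doomed.add(b.transcript_id)
    removed = [m.transcript_id for m in models if m.transcript_id in doomed]
    if removed:
        log.info("removed %d conflicting transcripts: %s", len(removed), removed)
    return [m for m in models if m.transcript_id not in doomed]
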
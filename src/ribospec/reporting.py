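"""Pipeline orchestration, ROC/AUC benchmarking and output writers.

The pipeline runs annotation parsing, conflict filtering, P-site
coverage, coherence scoring, FDR calibration, classification and the
comparator metrics, chunked by chromosome; chunk results are merged in a
fixed (chrom, start, transcript_id) order so serial and parallel runs
produce identical output.
"""

from __future__ import annotations

import json
import logging
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from sklearn.metrics import roc_auc_score, roc_curve

from . import annotation_coverage as ac
from . import classification as cls
from . import comparators as cmp
from . import spectre_core as core

log = logging.getLogger(__name__)

DEFAULT_FPKM_CUTOFFS = (0.5, 1.0, 3.0, 5.0, 10.0)

RESULT_COLUMNS = [
    "transcript_id", "gene_id", "chrom", "start", "end", "strand", "biotype",
    "region", "length", "read_count", "fpkm", "spectre_score", "posterior",
    "translated", "reason", "floss", "floss_outlier", "orfscore",
]


@dataclass
class RunConfig:
    """Everything a pipeline run needs; serialized alongside every run."""

    bam: str
    gtf: str
    out_dir: str
    offsets: dict[int, int] = field(default_factory=lambda: dict(ac.DEFAULT_OFFSETS))
    default_offset: int | None = None
    window: core.WindowSpec = field(default_factory=core.WindowSpec)
    region_mode: str = "auto"  # auto: CDS for coding, full otherwise
    fpkm_cutoff: float = 5.0
    fdr: float = 0.05
    filter_conflicts: bool = True
    flank: int = 0
    min_mapq: int = 0
    calibration_min: int = 50
    floss_range: tuple[int, int] = cmp.DEFAULT_LENGTH_RANGE
    comparators: bool = True
    write_tracks: bool = False
    workers: int = 1
    seed: int = 0
    #: FPKM denominator override: library size in mapped reads.  By default
    #: FPKM uses the BAM's own mapped-read total; when the alignment file is
    #: a subset of a larger library (e.g. a simulated slice of a notional
    #: 5e7-read experiment), pass the full library size here so abundances
    #: are on the intended scale.
    total_mapped_override: int | None = None


@dataclass
class RocResult:
    fpkm_cutoff: float | None
    auc: float
    curve: list[tuple[float, float]]
    n_pos: int
    n_neg: int


def roc_auc(scores, labels, fpkm_cutoff: float | None = None) -> RocResult:
    """ROC curve and AUC for a scored, binary-labelled set.

    AUC is the rank statistic (Mann-Whitney U / (n_pos * n_neg), midrank
    ties); the curve comes from a full threshold sweep.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    keep = np.isfinite(s)
    s, y = s[keep], y[keep]
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    return RocResult(
        fpkm_cutoff, float(roc_auc_score(y, s)),
        list(zip(fpr.tolist(), tpr.tolist())), n_pos, n_neg,
    )


def benchmark_over_cutoffs(
    table: pd.DataFrame,
    cutoffs=DEFAULT_FPKM_CUTOFFS,
    metrics=("spectre_score", "orfscore", "floss"),
    truth_column: str | None = None,
) -> pd.DataFrame:
    """One ROC per metric per abundance cutoff, as a tidy frame.

    Two labelling modes mirror the two ground truths available.  On real
    libraries translation status is unknown, so the label is the
    abundance proxy fpkm >= cutoff over all regions.  On simulated data
    (``truth_column`` given) the label is the simulator's ground truth
    and the cutoff instead acts as the evaluation's inclusion floor:
    only regions with fpkm >= cutoff enter the ROC, matching how
    benchmarks in this field always restrict to minimally covered
    regions.  FLOSS is negated before ranking (low distance =
    coding-like).  Single-class cells are reported with AUC = NaN.
    """
    rows = []
    for cutoff in cutoffs:
        if truth_column is not None:
            in_eval = table["fpkm"] >= cutoff
            labels = table[truth_column].astype(int)
        else:
            in_eval = pd.Series(True, index=table.index)
            labels = (table["fpkm"] >= cutoff).astype(int)
        for metric in metrics:
            scores = table[metric].astype(float)
            if metric == "floss":
                scores = -scores
            keep = np.isfinite(scores) & in_eval
            try:
                res = roc_auc(scores[keep], labels[keep], cutoff)
                rows.append(
                    dict(metric=metric, fpkm_cutoff=cutoff, auc=res.auc,
                         n_pos=res.n_pos, n_neg=res.n_neg)
                )
            except ValueError:
                rows.append(
                    dict(metric=metric, fpkm_cutoff=cutoff, auc=np.nan,
                         n_pos=int(labels[keep].sum()),
                         n_neg=int((1 - labels[keep]).sum()))
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _pick_region(model: ac.TranscriptModel, mode: str) -> str:
    if mode == "auto":
        return "CDS" if model.cds else "full"
    return mode


def _score_chromosome(args) -> list[dict]:
    """Worker: score every transcript of one chromosome."""
    (bam_path, models, cfg) = args
    rows = []
    with pysam.AlignmentFile(bam_path) as bam:
        for m in models:
            region = _pick_region(m, cfg.region_mode)
            profile = ac.extract_psite_profile(
                bam, m, region, cfg.offsets, cfg.default_offset, cfg.min_mapq
            )
            row = dict(
                transcript_id=m.transcript_id, gene_id=m.gene_id, chrom=m.chrom,
                start=m.span[0], end=m.span[1], strand=m.strand, biotype=m.biotype,
                region=region, length=int(profile.counts.size),
                read_count=profile.total_reads,
                length_histogram=profile.length_histogram,
            )
            sc = core.score_counts(
                profile.counts, cfg.window,
                transcript_id=m.transcript_id, region=region,
            )
            row["spectre_score"] = sc.score
            row["reason"] = sc.reason
            row["_windows"] = (sc.window_starts, sc.window_values)
            if cfg.comparators:
                fc = cmp.frame_counts(profile.counts)
                row["orfscore"] = cmp.orfscore(fc)
            rows.append(row)
    return rows


def run_pipeline(cfg: RunConfig) -> pd.DataFrame:
    """Execute the full classification pipeline; returns the main table
    and writes results.tsv, calibration.json and a run manifest to
    cfg.out_dir (plus per-window bedGraph tracks when requested)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if not Path(cfg.bam).exists():
        raise FileNotFoundError(cfg.bam)
    if not (Path(cfg.bam + ".bai").exists() or Path(cfg.bam).with_suffix(".bam.bai").exists()
            or Path(str(cfg.bam) + ".csi").exists()):
        raise FileNotFoundError(
            f"alignment index not found for {cfg.bam}; run samtools index first"
        )

    models = ac.parse_annotation(cfg.gtf)
    if cfg.filter_conflicts:
        models = ac.filter_conflicting_transcripts(models, cfg.flank)
    model_index = {m.transcript_id: m for m in models}

    with pysam.AlignmentFile(cfg.bam) as bam:
        total_mapped = sum(
            1 for r in bam.fetch(until_eof=True)
            if not (r.is_unmapped or r.is_secondary or r.is_supplementary)
        )
    if total_mapped == 0:
        raise ValueError(f"no mapped reads in {cfg.bam}")
    fpkm_denominator = cfg.total_mapped_override or total_mapped

    by_chrom: dict[str, list] = {}
    for m in models:
        by_chrom.setdefault(m.chrom, []).append(m)
    chunks = [(cfg.bam, by_chrom[c], cfg) for c in sorted(by_chrom)]
    if cfg.workers > 1:
        with ProcessPoolExecutor(max_workers=cfg.workers) as pool:
            chunk_rows = list(pool.map(_score_chromosome, chunks))
    else:
        chunk_rows = [_score_chromosome(c) for c in chunks]
    rows = [r for chunk in chunk_rows for r in chunk]
    rows.sort(key=lambda r: (r["chrom"], r["start"], r["transcript_id"]))

    for r in rows:
        r["fpkm"] = (
            r["read_count"] * 1e9 / (r["length"] * fpkm_denominator)
            if r["length"] else 0.0
        )

    if cfg.comparators:
        coding_profiles = [
            ac.PSiteProfile(r["transcript_id"], r["region"],
                            np.zeros(1), r["length_histogram"])
            for r in rows
            if r["biotype"] in ac.CODING_BIOTYPES and r["length_histogram"]
        ]
        if coding_profiles:
            ref = cmp.floss_reference(coding_profiles, cfg.floss_range)
            for r in rows:
                dist = cmp.LengthDistribution.from_histogram(
                    r["length_histogram"], cfg.floss_range
                )
                r["floss"] = cmp.floss_score(dist, ref)
            fence_pts = [
                (r["read_count"], r["floss"])
                for r in rows
                if r["biotype"] in ac.CODING_BIOTYPES and r["floss"] is not None
            ]
            fence = cmp.floss_outlier_cutoff(fence_pts) if len(fence_pts) >= 5 else None
            for r in rows:
                r["floss_outlier"] = (
                    fence.is_outlier(r["read_count"], r["floss"])
                    if fence is not None and r["floss"] is not None
                    else None
                )

    calibration = None
    try:
        calibration = cls.build_calibration(
            [(r["transcript_id"], r["spectre_score"], r["fpkm"], r["biotype"])
             for r in rows if r["spectre_score"] is not None],
            cfg.fpkm_cutoff, cfg.fdr, cfg.calibration_min,
        )
    except cls.CalibrationError as exc:
        log.warning("calibration skipped: %s", exc)

    if calibration is not None:
        calls = cls.classify(
            [dict(transcript_id=r["transcript_id"], region=r["region"],
                  score=r["spectre_score"], fpkm=r["fpkm"], reason=r["reason"])
             for r in rows],
            calibration,
        )
        for r, call in zip(rows, calls):
            r["posterior"] = call.posterior
            r["translated"] = call.translated
        (out / "calibration.json").write_text(
            json.dumps(calibration.summary(), indent=2) + "\n"
        )

    if cfg.write_tracks and calibration is not None:
        _write_tracks(rows, model_index, calibration, cfg, out / "windows.bedGraph")

    table = pd.DataFrame(
        [{k: r.get(k) for k in RESULT_COLUMNS} for r in rows],
        columns=RESULT_COLUMNS,
    )
    write_results_tsv(table, out / "results.tsv")
    manifest = asdict(cfg)
    manifest["window"] = asdict(cfg.window)
    manifest["total_mapped_reads"] = total_mapped
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return table


def _write_tracks(rows, model_index, calibration, cfg, path) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based half-open (bedGraph)\n")
        fh.write('track type=bedGraph name="windowed posterior"\n')
        for r in rows:
            m = model_index[r["transcript_id"]]
            starts, values = r["_windows"]
            if len(values) == 0:
                continue
            sc = core.SpectreScore(
                r["spectre_score"], starts, values, len(values),
                transcript_id=r["transcript_id"], region=r["region"],
            )
            posts = cls.posterior_probability(np.clip(values, 0, 1), calibration)
            sc = core.SpectreScore(r["spectre_score"], starts, posts, len(values))
            for chrom, lo, hi, value in core.window_track(sc, m, r["region"], cfg.window):
                fh.write(f"{chrom}\t{lo}\t{hi}\t{value:.6f}\n")


def write_results_tsv(table: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write("# ribospec results; genomic coordinates 0-based half-open\n")
        table.to_csv(fh, sep="\t", index=False, float_format="%.6f")
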
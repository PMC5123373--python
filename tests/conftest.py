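"""Shared fixtures: simulated libraries run through the full pipeline."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import pytest

from ribospec import reporting
from ribospec import synthetic_data as synth


@dataclass
class FixtureRun:
    """One simulated library scored end to end."""

    cfg: synth.SimConfig
    out_dir: Path
    gtf: Path
    sam: Path
    bam: Path
    truth: synth.TruthTable
    table: pd.DataFrame  # results merged with truth columns

    @property
    def calibration(self) -> dict:
        return json.loads((self.out_dir / "calibration.json").read_text())


def run_fixture(
    base_dir: Path,
    seed: int,
    n_coding: int = 100,
    n_noncoding: int = 100,
    **sim_kwargs,
) -> FixtureRun:
    """Simulate a library, score it with the pipeline, merge in truth."""
    d = base_dir / f"fix_seed{seed}_{n_coding}_{n_noncoding}"
    d.mkdir(parents=True, exist_ok=True)
    cfg = synth.SimConfig(
        n_coding=n_coding, n_noncoding=n_noncoding, seed=seed, **sim_kwargs
    )
    gtf, sam, bam = d / "f.gtf", d / "f.sam", d / "f.bam"
    tr = synth.simulate_transcriptome(cfg, str(gtf))
    truth, _ = synth.simulate_ribo_reads(cfg, tr, str(sam), str(d / "truth.tsv"))
    synth.sam_to_indexed_bam(str(sam), str(bam))
    rc = reporting.RunConfig(
        bam=str(bam), gtf=str(gtf), out_dir=str(d / "out"),
        filter_conflicts=False,
        total_mapped_override=cfg.total_mapped_reads,
    )
    table = reporting.run_pipeline(rc)
    tt = pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "truth_translated": int(r.translated),
                "true_p": r.true_p,
                "true_fpkm": r.true_fpkm,
            }
            for r in truth.regions
        ]
    )
    table = table.merge(tt, on="transcript_id")
    return FixtureRun(cfg, d / "out", gtf, sam, bam, truth, table)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory) -> Path:
    return tmp_path_factory.mktemp("fixtures")


@pytest.fixture(scope="session")
def default_run(fixture_dir) -> FixtureRun:
    """The default study-condition library (seed 1) scored end to end."""
    return run_fixture(fixture_dir, seed=1)


@pytest.fixture(scope="session")
def small_transcriptome(fixture_dir):
    """A small annotated transcriptome with reads, for unit-level checks."""
    d = fixture_dir / "small"
    d.mkdir(exist_ok=True)
    cfg = synth.SimConfig(n_coding=10, n_noncoding=10, seed=42)
    tr = synth.simulate_transcriptome(cfg, str(d / "f.gtf"))
    truth, readsets = synth.simulate_ribo_reads(cfg, tr, str(d / "f.sam"))
    synth.sam_to_indexed_bam(str(d / "f.sam"), str(d / "f.bam"))
    return cfg, tr, truth, readsets, d
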
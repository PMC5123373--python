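"""FDR-calibrated translation calls and posterior probabilities.

Score distributions are stratified by abundance: regions of
protein-coding transcripts at or above an FPKM cutoff form the "active"
sample, regions below the cutoff form the empirical null.  The call
threshold is the (1 - fdr) quantile of the null score distribution, and
the posterior that a region is translated comes from smoothed density
estimates of the two samples combined with the sample-size prior:

    P(active | s) = f_a(s) * pi / (f_a(s) * pi + f_n(s) * (1 - pi))

Densities are Gaussian KDEs fit on the logit of the (bounded) scores and
Jacobian-corrected back to score space, floored at a small epsilon so the
ratio is always defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .annotation_coverage import CODING_BIOTYPES

_EPS = 1e-10
_CLIP = 1e-6


class CalibrationError(ValueError):
    """Raised when either score partition is too small to calibrate."""


class _LogitKDE:
    """Gaussian KDE on logit-transformed scores in (0, 1).

    Degenerate samples (zero variance after clipping) fall back to a
    narrow fixed-bandwidth Gaussian so density queries stay finite.
    """

    def __init__(self, scores: np.ndarray, bandwidth=None) -> None:
        s = np.clip(np.asarray(scores, dtype=float), _CLIP, 1 - _CLIP)
        self._z = np.log(s / (1 - s))
        if np.std(self._z) < 1e-12:
            self._kde = None
            self._mu = float(np.mean(self._z))
            self._bw = 0.05
        else:
            self._kde = gaussian_kde(self._z, bw_method=bandwidth)

    def pdf(self, scores: np.ndarray) -> np.ndarray:
        s = np.clip(np.asarray(scores, dtype=float), _CLIP, 1 - _CLIP)
        z = np.log(s / (1 - s))
        if self._kde is None:
            dens = np.exp(-0.5 * ((z - self._mu) / self._bw) ** 2) / (
                self._bw * np.sqrt(2 * np.pi)
            )
        else:
            dens = self._kde(np.atleast_1d(z))
        return dens / (s * (1 - s))  # Jacobian of the logit


@dataclass
class ScoreCalibration:
    """Active/null score samples, FDR threshold and posterior machinery."""

    fpkm_cutoff: float
    fdr: float
    threshold: float
    prior_active: float
    active_scores: np.ndarray
    null_scores: np.ndarray
    _kde_active: _LogitKDE = field(repr=False)
    _kde_null: _LogitKDE = field(repr=False)

    def summary(self) -> dict:
        return {
            "fpkm_cutoff": self.fpkm_cutoff,
            "fdr": self.fdr,
            "threshold": self.threshold,
            "prior_active": self.prior_active,
            "n_active": int(self.active_scores.size),
            "n_null": int(self.null_scores.size),
        }


@dataclass
class TranslationCall:
    transcript_id: str
    region: str
    score: float | None
    fpkm: float
    posterior: float | None
    translated: bool
    threshold_used: float
    reason: str | None = None


def build_calibration(
    scores: Iterable[tuple[str, float, float, str]],
    fpkm_cutoff: float = 5.0,
    fdr: float = 0.05,
    min_sample: int = 50,
    coding_biotypes: frozenset[str] = CODING_BIOTYPES,
    null_biotype_mode: bool = False,
    bandwidth=None,
) -> ScoreCalibration:
    """Partition (region_id, score, fpkm, biotype) records and calibrate.

    Active: protein-coding regions with fpkm >= cutoff.  Null: regions
    with fpkm < cutoff, or — with ``null_biotype_mode`` — all scored
    non-coding regions regardless of abundance.  The threshold is the
    empirical (1 - fdr) quantile of the null sample; it depends on the
    null alone.
    """
    if not 0 < fdr < 1:
        raise ValueError("fdr must be in (0, 1)")
    active, null = [], []
    for _rid, score, fpkm, biotype in scores:
        if score is None or not np.isfinite(score):
            continue
        coding = biotype in coding_biotypes
        if coding and fpkm >= fpkm_cutoff:
            active.append(score)
        if null_biotype_mode:
            if not coding:
                null.append(score)
        elif fpkm < fpkm_cutoff:
            null.append(score)
    if len(active) < min_sample or len(null) < min_sample:
        raise CalibrationError(
            f"calibration needs >= {min_sample} scores on each side of the "
            f"FPKM cutoff (got {len(active)} active, {len(null)} null); "
            f"choose a different fpkm_cutoff"
        )
    active_arr = np.asarray(active, dtype=float)
    null_arr = np.asarray(null, dtype=float)
    threshold = float(np.quantile(null_arr, 1 - fdr))
    prior = len(active) / (len(active) + len(null))
    return ScoreCalibration(
        fpkm_cutoff=fpkm_cutoff,
        fdr=fdr,
        threshold=threshold,
        prior_active=prior,
        active_scores=active_arr,
        null_scores=null_arr,
        _kde_active=_LogitKDE(active_arr, bandwidth),
        _kde_null=_LogitKDE(null_arr, bandwidth),
    )


def posterior_probability(score, cal: ScoreCalibration):
    """Posterior probability of active translation at a score (scalar or
    array), from the calibrated density ratio and prior."""
    scalar = np.ndim(score) == 0
    arr = np.atleast_1d(np.asarray(score, dtype=float))
    if np.any((arr < 0) | (arr > 1)):
        raise ValueError("scores must lie in [0, 1]")
    fa = np.maximum(cal._kde_active.pdf(arr), _EPS)
    fn = np.maximum(cal._kde_null.pdf(arr), _EPS)
    pi = cal.prior_active
    post = fa * pi / (fa * pi + fn * (1 - pi))
    return float(post[0]) if scalar else post


def classify(
    scored: Sequence,
    cal: ScoreCalibration,
) -> list[TranslationCall]:
    """One TranslationCall per scored region.

    ``scored`` holds records with attributes or keys (transcript_id,
    region, score, fpkm, reason).  A region is called translated iff its
    score is at or above the threshold (boundary inclusive); unscorable
    regions are emitted untranslated with their reason and no posterior.
    """
    calls = []
    for rec in scored:
        get = rec.get if isinstance(rec, dict) else lambda k, r=rec: getattr(r, k, None)
        score = get("score")
        reason = get("reason")
        if score is None or not np.isfinite(score):
            calls.append(
                TranslationCall(
                    get("transcript_id"), get("region"), None, get("fpkm"),
                    None, False, cal.threshold, reason or "unscorable",
                )
            )
            continue
        calls.append(
            TranslationCall(
                get("transcript_id"), get("region"), float(score), get("fpkm"),
                posterior_probability(float(score), cal),
                bool(score >= cal.threshold), cal.threshold, None,
            )
        )
    return calls
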
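"""Contaminant screening and low-abundance culling.

Decontamination follows the prevalence logic: an ASV seen more often in
negative controls than in true samples is a reagent-contamination suspect.
Each ASV is scored with the one-sided p-value of a 2×2 presence/absence
test (chi-square, with Fisher's exact test whenever an expected cell count
falls below 5) against the alternative "more prevalent in negatives"; small
scores mean contamination and ASVs scoring below the threshold are dropped.

Culling removes low-read samples, then low-read ASVs, iterating the ordered
pass until stable so the result is a fixed point (re-culling changes
nothing).  Thresholds are explicit; :func:`suggest_break_threshold` is an
advisory diagnostic that locates the largest gap in log-transformed read
totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import CountTable


@dataclass
class ContaminantReport:
    asv_id: str
    prevalence_in_negatives: float
    prevalence_in_samples: float
    score: float
    flagged: bool


def _prevalence_score(n_neg_present: int, n_neg: int, n_true_present: int, n_true: int) -> float:
    """One-sided p for 'more prevalent in negatives' on the 2×2 presence table."""
    a, b = n_neg_present, n_neg - n_neg_present
    c, d = n_true_present, n_true - n_true_present
    table = np.array([[a, b], [c, d]], dtype=float)
    total = table.sum()
    expected = np.outer(table.sum(1), table.sum(0)) / total
    if (expected < 5).any() or (table.sum(1) == 0).any() or (table.sum(0) == 0).any():
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        return float(p)
    _, p_two, _, _ = stats.chi2_contingency(table, correction=False)
    if a / n_neg > c / n_true:
        return float(p_two / 2.0)
    return float(1.0 - p_two / 2.0)


def decontam_prevalence(
    table: CountTable, samples: pd.DataFrame, threshold: float = 0.5
) -> tuple[list[ContaminantReport], CountTable]:
    """Score every ASV and return (reports, table with flagged ASVs removed)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    meta = samples.set_index("sample_id").loc[table.sample_ids]
    is_neg = (meta["compartment"] == "negative_control").to_numpy()
    n_neg, n_true = int(is_neg.sum()), int((~is_neg).sum())
    if n_neg == 0:
        raise ValueError(
            "no negative-control samples: skip decontamination for this table"
        )
    if n_true == 0:
        raise ValueError("no true samples present")
    present = table.counts > 0
    neg_hits = present[is_neg].sum(axis=0)
    true_hits = present[~is_neg].sum(axis=0)
    reports = []
    for j, asv in enumerate(table.asv_ids):
        score = _prevalence_score(int(neg_hits[j]), n_neg, int(true_hits[j]), n_true)
        reports.append(
            ContaminantReport(
                asv_id=asv,
                prevalence_in_negatives=neg_hits[j] / n_neg,
                prevalence_in_samples=true_hits[j] / n_true,
                score=score,
                flagged=score < threshold,
            )
        )
    keep = np.array([not r.flagged for r in reports])
    return reports, table.select_asvs(keep)


def cull(table: CountTable, min_sample_reads: int, min_asv_reads: int) -> CountTable:
    """Drop samples with total reads ≤ ``min_sample_reads``, then ASVs with
    total reads ≤ ``min_asv_reads``; repeat until stable (idempotent)."""
    if min_sample_reads < 0 or min_asv_reads < 0:
        raise ValueError("cull thresholds must be non-negative")
    current = table
    while True:
        keep_samples = current.sample_totals() > min_sample_reads
        if not keep_samples.any():
            raise ValueError("culling removed every sample")
        nxt = current.select_samples(keep_samples)
        nxt = nxt.select_asvs(nxt.asv_totals() > min_asv_reads)
        if nxt.shape == current.shape:
            return nxt
        current = nxt


@dataclass
class BreakSuggestion:
    """Advisory cull threshold from the largest log-scale gap.

    ``threshold`` is the geometric midpoint of the gap: totals ≤ threshold
    fall below the break.  ``low_confidence`` is set when the winning gap
    does not clearly dominate the others (no obvious bimodality).
    """

    threshold: float
    gap_low: float
    gap_high: float
    low_confidence: bool


def suggest_break_threshold(totals) -> BreakSuggestion:
    totals = np.asarray(list(totals), dtype=float)
    if totals.size < 5:
        raise ValueError("need at least 5 totals to locate a break")
    if (totals <= 0).any():
        raise ValueError("totals must be positive (log scale)")
    srt = np.sort(totals)
    logs = np.log(srt)
    gaps = np.diff(logs)
    # only breaks whose lower endpoint sits in the lower half of the
    # distribution separate a low-read cluster worth culling
    cand = gaps[: totals.size // 2 + 1]
    # ties (within fp tolerance) break toward the smallest threshold
    best = int(np.flatnonzero(cand >= cand.max() - 1e-9)[0])
    gap_low, gap_high = srt[best], srt[best + 1]
    med = float(np.median(gaps)) if gaps.size else 0.0
    dominant = med > 0 and cand[best] > 2.0 * med
    threshold = math.sqrt(gap_low * gap_high)
    return BreakSuggestion(
        threshold=threshold,
        gap_low=float(gap_low),
        gap_high=float(gap_high),
        low_confidence=not dominant,
    )


def reports_to_frame(reports: list[ContaminantReport]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in reports])
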
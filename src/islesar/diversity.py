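"""Alpha diversity, sampling sufficiency, evenness and compartment overlap.

Observed ASV richness is the alpha metric (accumulation curves are expected
to saturate, so extrapolated estimators are deliberately excluded).
Evenness is the Hill number of order 1 — the exponential of Shannon
entropy, an effective species number sensitive to both rare and common
taxa.  Rarefaction uses the analytic hypergeometric interpolation
``E[S(m)] = S_obs − Σ_i C(N−N_i, m)/C(N, m)`` evaluated in log space.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .core import CountTable


# ---------------------------------------------------------------------------
# richness
# ---------------------------------------------------------------------------

def observed_richness(
    table: CountTable,
    samples: pd.DataFrame | None = None,
    group_by: str = "sample",
) -> pd.Series:
    """ASVs with count > 0 per unit.

    ``group_by="sample"`` counts per sample; ``"island_compartment"`` pools
    replicate samples of each (island, compartment) by summation first and
    needs ``samples`` metadata.
    """
    if table.shape[0] == 0:
        raise ValueError("empty table")
    if group_by == "sample":
        vals = (table.counts > 0).sum(axis=1)
        return pd.Series(vals, index=table.sample_ids, name="richness")
    if group_by != "island_compartment":
        raise ValueError(f"unknown group_by {group_by!r}")
    if samples is None:
        raise ValueError("island_compartment grouping requires sample metadata")
    pooled = pooled_counts(table, samples)
    vals = (pooled > 0).sum(axis=1)
    vals.name = "richness"
    return vals


def pooled_counts(
    table: CountTable, samples: pd.DataFrame, by: tuple[str, ...] = ("island_id", "compartment")
) -> pd.DataFrame:
    """Sum replicate samples into grouped count vectors (rows = groups)."""
    meta = samples.set_index("sample_id").loc[table.sample_ids]
    frame = pd.DataFrame(table.counts, index=table.sample_ids, columns=table.asv_ids)
    pooled = frame.groupby([meta[k].to_numpy() for k in by]).sum()
    pooled.index.names = list(by)
    return pooled


# ---------------------------------------------------------------------------
# rarefaction / accumulation
# ---------------------------------------------------------------------------

@dataclass
class AccumulationCurve:
    depths: np.ndarray
    expected_richness: np.ndarray
    asymptote_reached: bool
    final_slope: float


def rarefaction_curve(
    counts, depths, asymptote_tol: float = 1e-3
) -> AccumulationCurve:
    """Analytic rarefaction of one pooled count vector on a depth grid.

    The expected richness at depth ``m`` is
    ``S_obs − Σ_i C(N−N_i, m)/C(N, m)`` (hypergeometric interpolation); the
    binomial ratio is evaluated with log-gamma for numerical safety.  The
    asymptote flag compares the mean slope over the final 10 % of the grid
    against ``asymptote_tol`` (species gained per read).
    """
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("empty count vector")
    n_total = int(counts.sum())
    depths = np.asarray(sorted(int(d) for d in depths), dtype=np.int64)
    if depths.size == 0 or depths[0] < 1:
        raise ValueError("depths must be positive integers")
    if depths[-1] > n_total:
        raise ValueError(
            f"depth {depths[-1]} exceeds total reads {n_total}: no extrapolation"
        )
    s_obs = counts.size
    exp_rich = np.empty(depths.size)
    for k, m in enumerate(depths):
        rem = n_total - counts  # N - N_i
        ok = rem >= m
        # log C(N-Ni, m) - log C(N, m)
        log_ratio = (
            gammaln(rem[ok] + 1)
            - gammaln(rem[ok] - m + 1)
            - gammaln(n_total + 1)
            + gammaln(n_total - m + 1)
        )
        exp_rich[k] = s_obs - np.exp(log_ratio).sum()
    tail = max(2, int(np.ceil(depths.size * 0.1)))
    d_tail, s_tail = depths[-tail:], exp_rich[-tail:]
    final_slope = float((s_tail[-1] - s_tail[0]) / max(1, d_tail[-1] - d_tail[0]))
    return AccumulationCurve(
        depths=depths,
        expected_richness=exp_rich,
        asymptote_reached=final_slope < asymptote_tol,
        final_slope=final_slope,
    )


# ---------------------------------------------------------------------------
# evenness
# ---------------------------------------------------------------------------

def hill_q1(counts) -> float:
    """Hill number of order 1: exp(Shannon entropy), natural log."""
    counts = np.asarray(counts, dtype=float)
    counts = counts[counts > 0]
    if counts.size == 0:
        raise ValueError("all-zero count vector")
    p = counts / counts.sum()
    return float(np.exp(-(p * np.log(p)).sum()))


@dataclass
class RegressionFit:
    """Simple OLS fit of y on x: slope, intercept, R², two-sided slope p."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    n: int


def simple_ols(x, y) -> RegressionFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    if np.ptp(y) == 0:
        # constant response: flat line, no variance explained
        return RegressionFit(
            slope=0.0, intercept=float(y[0]), r_squared=0.0,
            p_value=1.0, stderr=0.0, n=int(x.size),
        )
    res = stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        stderr=float(res.stderr),
        n=int(x.size),
    )


def evenness_vs_size(
    records: pd.DataFrame, islands: pd.DataFrame, size_field: str
) -> RegressionFit:
    """OLS of q=1 evenness on log island size.

    ``records`` needs columns island_id and q1; a significant slope is the
    signature of disproportionate effects on the SAR (evenness changing
    with area rather than richness alone).
    """
    merged = records.merge(islands[["island_id", size_field]], on="island_id")
    return simple_ols(np.log(merged[size_field].to_numpy(float)), merged["q1"].to_numpy(float))


# ---------------------------------------------------------------------------
# compartment overlap (Venn regions)
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    """Exclusive Venn-region counts over pooled compartment presence sets."""

    compartments: list[str]
    regions: dict[frozenset, int]
    presence: dict[str, set]

    def union_size(self) -> int:
        out: set = set()
        for s in self.presence.values():
            out |= s
        return len(out)

    def fraction_shared(self, a: str, b: str) -> float:
        """|A ∩ B| / |A| — e.g. the share of host ASVs also found free-living."""
        if not self.presence[a]:
            return float("nan")
        return len(self.presence[a] & self.presence[b]) / len(self.presence[a])


def compartment_overlap(table: CountTable, samples: pd.DataFrame) -> OverlapResult:
    meta = samples.set_index("sample_id").loc[table.sample_ids]
    comps = [c for c in meta["compartment"].unique() if c != "negative_control"]
    if len(comps) < 2:
        raise ValueError("need at least two compartments")
    presence: dict[str, set] = {}
    asv = np.asarray(table.asv_ids)
    for c in comps:
        mask = (meta["compartment"] == c).to_numpy()
        present = table.counts[mask].sum(axis=0) > 0
        presence[c] = set(asv[present])
    regions: dict[frozenset, int] = {}
    for r in range(1, len(comps) + 1):
        for inside in combinations(comps, r):
            region = set.intersection(*(presence[c] for c in inside))
            for c in comps:
                if c not in inside:
                    region -= presence[c]
            regions[frozenset(inside)] = len(region)
    return OverlapResult(compartments=list(comps), regions=regions, presence=presence)


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    f_statistic: float
    p_value: float
    tukey: pd.DataFrame


def richness_anova(values, groups) -> AnovaResult:
    """One-way ANOVA on richness with Tukey HSD pairwise comparisons."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if labels.size < 2:
        raise ValueError("need at least two groups")
    split = [values[groups == g] for g in labels]
    if min(len(s) for s in split) < 2:
        raise ValueError("need at least two observations per group")
    with np.errstate(invalid="ignore", divide="ignore"):
        f, p = stats.f_oneway(*split)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    hsd = pairwise_tukeyhsd(values, groups)
    frame = pd.DataFrame(
        hsd.summary().data[1:], columns=[str(c) for c in hsd.summary().data[0]]
    )
    return AnovaResult(f_statistic=float(f), p_value=float(p), tukey=frame)
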
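"""Null-model inference for community assembly.

Three tools:

* **RC-Bray** — abundance-weighted Raup–Crick turnover.  For each sample
  pair, null communities preserve each sample's observed richness (species
  drawn without replacement with probability proportional to occurrence
  frequency across the metacommunity) and observed read total (one read
  per drawn species, remainder multinomial over metacommunity relative
  abundances).  The observed Bray–Curtis is located within the null
  distribution and rescaled to [−1, 1]; values above +0.95 indicate
  deterministic divergence (environmental filtering / dispersal limitation
  with drift), below −0.95 homogenizing dispersal, and the middle band
  drift alone.

* **NODF** — nestedness by overlap and decreasing fill, over all row pairs
  and all column pairs, in [0, 100].

* **quasiswap / curveball** — randomizations of a binary matrix preserving
  both row and column totals, used to build nestedness null distributions
  (oecosimu-style z and permutation p via :func:`null_compare`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import random_table

from .core import CountTable

COMPARTMENT_ORDER = ("detritus", "water", "invertebrate")


# ---------------------------------------------------------------------------
# RC-Bray
# ---------------------------------------------------------------------------

@dataclass
class RCBrayMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, NaN diagonal, entries in [-1, 1]
    reps: int
    seed: int | None

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def fraction_beyond(self, cutoff: float = 0.95) -> float:
        v = self.condensed()
        return float((np.abs(v) > cutoff).mean())


def rc_bray(
    table: CountTable,
    reps: int = 999,
    seed: int | np.random.Generator | None = None,
) -> RCBrayMatrix:
    """Abundance-weighted Raup–Crick Bray–Curtis over all sample pairs.

    The metacommunity is every sample in ``table``: occurrence frequencies
    weight which species enter a null sample, metacommunity relative
    abundances weight how reads are spread over them.
    """
    counts = table.counts
    n, p = counts.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("zero-read samples present")
    presence = counts > 0
    richness = presence.sum(axis=1)
    occ = presence.sum(axis=0).astype(float)
    n_occupied = int((occ > 0).sum())
    if (richness > n_occupied).any():
        raise ValueError("sample richness exceeds the occupied species pool")
    occ_w = occ / occ.sum()
    relab = counts.sum(axis=0) / counts.sum()
    obs = squareform(pdist(counts.astype(float), metric="braycurtis"))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def null_sample(n_sp: int, n_reads: int) -> np.ndarray:
        chosen = rng.choice(p, size=n_sp, replace=False, p=occ_w)
        w = relab[chosen]
        if w.sum() == 0:
            w = np.ones(n_sp)
        vec = np.zeros(p)
        vec[chosen] = 1 + rng.multinomial(n_reads - n_sp, w / w.sum())
        return vec

    values = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            lt = eq = 0
            for _ in range(reps):
                a = null_sample(int(richness[i]), int(totals[i]))
                b = null_sample(int(richness[j]), int(totals[j]))
                bc = np.abs(a - b).sum() / (a + b).sum()
                if bc < obs[i, j] - 1e-12:
                    lt += 1
                elif abs(bc - obs[i, j]) <= 1e-12:
                    eq += 1
            rc = (lt + 0.5 * eq) / reps
            values[i, j] = values[j, i] = 2.0 * (rc - 0.5)
    return RCBrayMatrix(
        ids=list(table.sample_ids),
        values=values,
        reps=reps,
        seed=seed if isinstance(seed, int) else None,
    )


# ---------------------------------------------------------------------------
# compartment presence-absence matrix
# ---------------------------------------------------------------------------

def build_compartment_matrix(
    table: CountTable, samples: pd.DataFrame
) -> tuple[np.ndarray, list[str], list[str]]:
    """Pooled presence/absence matrix (compartments × ASVs).

    Rows ordered detritus, water, invertebrate; empty compartments dropped
    with a warning; all-zero ASV columns removed.
    """
    meta = samples.set_index("sample_id").loc[table.sample_ids]
    rows, row_ids = [], []
    for comp in COMPARTMENT_ORDER:
        mask = (meta["compartment"] == comp).to_numpy()
        if not mask.any():
            continue
        pooled = table.counts[mask].sum(axis=0) > 0
        if not pooled.any():
            import warnings

            warnings.warn(f"compartment {comp!r} has no reads; dropped", stacklevel=2)
            continue
        rows.append(pooled.astype(np.int64))
        row_ids.append(comp)
    if len(rows) < 2:
        raise ValueError("need at least two non-empty compartments")
    mat = np.vstack(rows)
    keep = mat.sum(axis=0) > 0
    asv_ids = [a for a, k in zip(table.asv_ids, keep) if k]
    return mat[:, keep], row_ids, asv_ids


# ---------------------------------------------------------------------------
# NODF
# ---------------------------------------------------------------------------

def _check_binary(matrix: np.ndarray) -> np.ndarray:
    m = np.asarray(matrix)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("matrix must be binary (0/1)")
    return m.astype(np.int64)


def _paired_nestedness_sum(m: np.ndarray) -> tuple[float, int]:
    """Sum of paired-overlap terms over all row pairs of ``m``.

    Rows sharing an identical 0/1 pattern contribute identically (and
    equal-fill pairs contribute zero), so the pair sum is evaluated over
    unique patterns with multiplicities — exact, but O(P²) in the number
    of distinct patterns instead of O(R²) rows.
    """
    n_rows = m.shape[0]
    n_pairs = n_rows * (n_rows - 1) // 2
    dim = m.shape[1]
    if dim <= 62:
        # patterns fit in an int64: dedupe on packed codes (much faster)
        codes = m.astype(np.int64) @ (np.int64(1) << np.arange(dim, dtype=np.int64))
        ucodes, counts = np.unique(codes, return_counts=True)
        uniq = ((ucodes[:, None] >> np.arange(dim, dtype=np.int64)) & 1).astype(np.int64)
    else:
        uniq, counts = np.unique(m, axis=0, return_counts=True)
    fills = uniq.sum(axis=1)
    overlap = (uniq @ uniq.T).astype(float)
    fi = fills[:, None]
    fj = fills[None, :]
    denom = np.maximum(np.minimum(fi, fj), 1)
    term = np.where((fi != fj) & (np.minimum(fi, fj) > 0), 100.0 * overlap / denom, 0.0)
    weight = counts[:, None] * counts[None, :]
    total = float((term * weight).sum()) / 2.0  # each unordered pair counted twice
    return total, n_pairs


def nodf(matrix) -> float:
    """NODF nestedness in [0, 100].

    For each pair with strictly decreasing fill, the paired term is
    100·|overlap|/fill_smaller; equal fills contribute zero.  Row-pair and
    column-pair terms are averaged over all R(R−1)/2 + C(C−1)/2 pairs.
    """
    m = _check_binary(matrix)
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    row_sum, row_pairs = _paired_nestedness_sum(m)
    col_sum, col_pairs = _paired_nestedness_sum(m.T)
    return (row_sum + col_sum) / (row_pairs + col_pairs)


# ---------------------------------------------------------------------------
# margin-preserving randomization
# ---------------------------------------------------------------------------

def _reduce_to_binary(m: np.ndarray, rng: np.random.Generator, max_iter: int) -> np.ndarray | None:
    """Apply margin-preserving 2×2 moves until no cell exceeds 1.

    A move picks a cell above 1 and shifts one unit into a 2×2 exchange
    that lowers the total excess ``Σ max(0, m−1)``; candidate columns are
    drawn preferentially from the zero entries of the donor row, which is
    where excess-lowering exchanges live.
    """
    m = m.astype(np.int64).copy()
    r, c = m.shape
    it = 0
    while True:
        big = np.argwhere(m > 1)
        if len(big) == 0:
            return m
        i, j = (int(v) for v in big[rng.integers(len(big))])
        zl = np.flatnonzero(m[i] == 0)
        moved = False
        for trial in range(500):
            it += 1
            if it > max_iter:
                return None
            if zl.size and rng.random() < 0.9:
                l = int(zl[rng.integers(zl.size)])
            else:
                l = int(rng.integers(c - 1))
                l += l >= j
            k = int(rng.integers(r - 1))
            k += k >= i
            if m[k, l] == 0:
                continue
            delta = (
                -1
                - (1 if m[k, l] > 1 else 0)
                + (1 if m[i, l] >= 1 else 0)
                + (1 if m[k, j] >= 1 else 0)
            )
            # accept strict improvements; after many failures also accept
            # excess-neutral moves to walk out of local traps
            if delta < 0 or (delta == 0 and trial > 100):
                m[i, j] -= 1
                m[k, l] -= 1
                m[i, l] += 1
                m[k, j] += 1
                moved = True
                break
        if not moved:
            return None


def _checkerboard_mix(m: np.ndarray, rng: np.random.Generator, trades: int) -> np.ndarray:
    """Random checkerboard (2×2 swap) walk; symmetric proposals, so the
    stationary distribution is uniform on the margin class."""
    r, c = m.shape
    ii = rng.integers(r, size=trades)
    kk = rng.integers(r, size=trades)
    jj = rng.integers(c, size=trades)
    ll = rng.integers(c, size=trades)
    for t in range(trades):
        i, k, j, l = ii[t], kk[t], jj[t], ll[t]
        if i == k or j == l:
            continue
        a, b, cc, d = m[i, j], m[i, l], m[k, j], m[k, l]
        if a == 1 and d == 1 and b == 0 and cc == 0:
            m[i, j] = m[k, l] = 0
            m[i, l] = m[k, j] = 1
        elif a == 0 and d == 0 and b == 1 and cc == 1:
            m[i, j] = m[k, l] = 1
            m[i, l] = m[k, j] = 0
    return m


def _curveball(m: np.ndarray, rng: np.random.Generator, trades: int) -> np.ndarray:
    """Curveball randomization: repeated trades of row-unique species."""
    m = m.copy()
    r = m.shape[0]
    for _ in range(trades):
        r1, r2 = rng.choice(r, size=2, replace=False)
        a = np.flatnonzero(m[r1] & ~m[r2].astype(bool))
        b = np.flatnonzero(m[r2] & ~m[r1].astype(bool))
        if a.size == 0 or b.size == 0:
            continue
        pool = np.concatenate([a, b])
        rng.shuffle(pool)
        new_a, new_b = pool[: a.size], pool[a.size :]
        m[r1, a] = 0
        m[r2, b] = 0
        m[r1, new_a] = 1
        m[r2, new_b] = 1
    return m


def _exact_three_row_sampler(m: np.ndarray):
    """Exact uniform sampler over binary matrices with the margins of a
    3-row matrix.

    With three rows, a matrix is determined by the row-subset occupying
    each column; columns of fill 3 (and 0) are forced, so the class is
    parametrized by how fill-2 columns split over {AB, AC, BC} and fill-1
    columns over {A, B, C} — two free counts once margins are imposed.
    The number of matrices with a given split is a product of multinomial
    coefficients, which gives the exact distribution of the split; a draw
    samples the split and then assigns columns by random permutation.
    """
    colf = m.sum(axis=0)
    c3 = np.flatnonzero(colf == 3)
    c2 = np.flatnonzero(colf == 2)
    c1 = np.flatnonzero(colf == 1)
    n3, n2, n1 = len(c3), len(c2), len(c1)
    ra, rb, rc = (int(v) for v in m.sum(axis=1))
    from scipy.special import gammaln

    # x = #{A,C} fill-2 columns, y = #{B,C}; everything else follows
    xmax = rc - n3
    xg, yg = np.meshgrid(np.arange(xmax + 1), np.arange(xmax + 1), indexing="ij")
    x, y = xg.ravel(), yg.ravel()
    n_ab = n2 - x - y
    n_a = ra - n3 - n_ab - x
    n_b = rb - n3 - n_ab - y
    n_c = rc - n3 - x - y
    ok = (n_ab >= 0) & (n_a >= 0) & (n_b >= 0) & (n_c >= 0)
    x, y, n_ab, n_a, n_b, n_c = (v[ok] for v in (x, y, n_ab, n_a, n_b, n_c))
    logw = (
        gammaln(n2 + 1) - gammaln(n_ab + 1) - gammaln(x + 1) - gammaln(y + 1)
        + gammaln(n1 + 1) - gammaln(n_a + 1) - gammaln(n_b + 1) - gammaln(n_c + 1)
    )
    w = np.exp(logw - logw.max())
    cdf = np.cumsum(w / w.sum())
    splits = np.column_stack([x, y, n_ab, n_a, n_b, n_c])

    def draw(rng: np.random.Generator) -> np.ndarray:
        xi, yi, ab, a, b, _ = splits[int(np.searchsorted(cdf, rng.random()))]
        out = np.zeros_like(m)
        out[:, c3] = 1
        p2 = rng.permutation(c2)
        out[0, p2[: ab + xi]] = 1
        out[1, np.concatenate([p2[:ab], p2[ab + xi :]])] = 1
        out[2, p2[ab:]] = 1
        p1 = rng.permutation(c1)
        out[0, p1[:a]] = 1
        out[1, p1[a : a + b]] = 1
        out[2, p1[a + b :]] = 1
        return out

    return draw


def quasiswap(
    matrix,
    seed: int | np.random.Generator | None = None,
    method: str = "quasiswap",
    mix_trades: int = 1000,
    max_retries: int = 20,
) -> np.ndarray:
    """Randomize a binary matrix preserving exact row and column totals.

    ``quasiswap``: matrices with three rows (or columns) are drawn exactly
    uniformly from the margin class via :func:`_exact_three_row_sampler`;
    otherwise start from a random integer contingency table with the
    target margins (Patefield algorithm), reduce cells above 1 with
    margin-preserving 2×2 moves, then mix with ``mix_trades`` checkerboard
    swap attempts.  ``curveball``: pairwise row trades (burn-in
    ``mix_trades``) starting from the observed matrix.
    """
    m = _check_binary(matrix)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if method == "curveball":
        return _curveball(m, rng, max(mix_trades, 1000))
    if method != "quasiswap":
        raise ValueError(f"unknown method {method!r}")
    if m.shape[0] == 3:
        return _exact_three_row_sampler(m)(rng)
    if m.shape[1] == 3:
        return _exact_three_row_sampler(m.T)(rng).T
    rows, cols = m.sum(axis=1), m.sum(axis=0)
    budget = 200 * max(1, int(np.maximum(m - 1, 0).sum()) + m.size)
    for _ in range(max_retries):
        start = random_table(rows, cols).rvs(random_state=rng)
        reduced = _reduce_to_binary(np.asarray(start), rng, max_iter=budget)
        if reduced is not None:
            return _checkerboard_mix(reduced, rng, mix_trades)
    raise RuntimeError("could not reconstruct a binary matrix with the given margins")


# ---------------------------------------------------------------------------
# oecosimu-style comparison
# ---------------------------------------------------------------------------

@dataclass
class NestednessResult:
    observed: float
    null_mean: float
    null_sd: float
    z: float
    p_value: float
    n_null: int


def null_compare(
    observed: float,
    statistic: Callable[[np.ndarray], float],
    matrix,
    n_null: int = 1000,
    seed: int | np.random.Generator | None = None,
    method: str = "quasiswap",
    mix_trades: int = 1000,
) -> NestednessResult:
    """Locate an observed statistic within a margin-preserving null.

    z = (obs − mean_null)/sd_null; two-sided p = 2·min(P_low, P_high) with
    P = (count + 1)/(n_null + 1), capped at 1.
    """
    if n_null < 99:
        raise ValueError("need at least 99 null matrices")
    m = _check_binary(matrix)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nulls = np.empty(n_null)
    if method == "quasiswap" and m.shape[0] == 3:
        # build the exact sampler once; each draw is then O(columns)
        draw = _exact_three_row_sampler(m)
        for k in range(n_null):
            nulls[k] = statistic(draw(rng))
    else:
        for k in range(n_null):
            nulls[k] = statistic(quasiswap(m, seed=rng, method=method, mix_trades=mix_trades))
    mean, sd = float(nulls.mean()), float(nulls.std(ddof=1))
    z = (observed - mean) / sd if sd > 0 else float("nan")
    tol = 1e-9
    p_high = ((nulls >= observed - tol).sum() + 1) / (n_null + 1)
    p_low = ((nulls <= observed + tol).sum() + 1) / (n_null + 1)
    p = min(1.0, 2.0 * min(p_low, p_high))
    return NestednessResult(
        observed=float(observed),
        null_mean=mean,
        null_sd=sd,
        z=z,
        p_value=float(p),
        n_null=n_null,
    )
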
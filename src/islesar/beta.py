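"""Spatial turnover: Bray–Curtis dissimilarity, Mantel tests against island
size, composition-vs-size regressions with island-level bootstrap, and
within-island multivariate dispersion.

The Mantel test correlates the unfolded upper triangles of two distance
matrices with Spearman's rank correlation; the null permutes object labels
of one matrix (rows and columns jointly).  Beta dispersion embeds the
dissimilarity matrix by principal coordinates and measures each sample's
distance to its group centroid with the negative-eigenvalue correction
(squared distances along negative axes subtract, clamped at zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .core import CountTable, DistanceMatrix
from .diversity import RegressionFit, simple_ols
from .sar import BootstrapSlopes


def bray_curtis(table: CountTable) -> DistanceMatrix:
    """Pairwise Bray–Curtis dissimilarities ``Σ|x−y| / Σ(x+y)`` on raw counts."""
    totals = table.sample_totals()
    if (totals == 0).any():
        bad = [s for s, t in zip(table.sample_ids, totals) if t == 0]
        raise ValueError(f"zero-read samples (drop upstream): {', '.join(bad)}")
    vals = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(list(table.sample_ids), vals)


def size_distance(
    islands: pd.DataFrame, size_field: str, scale: str = "log"
) -> DistanceMatrix:
    """Pairwise island-size distances, |log A_i − log A_j| by default."""
    sizes = islands[size_field].to_numpy(float)
    if (sizes <= 0).any():
        raise ValueError("island sizes must be positive")
    v = np.log(sizes) if scale == "log" else sizes
    vals = np.abs(v[:, None] - v[None, :])
    return DistanceMatrix(list(islands["island_id"]), vals)


@dataclass
class MantelResult:
    r: float
    p_value: float
    n_perm: int
    seed: int | None


def _triangle_ranks(values: np.ndarray, iu) -> np.ndarray:
    return stats.rankdata(values[iu])


def mantel_spearman(
    d_comm: DistanceMatrix,
    d_size: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = None,
) -> MantelResult:
    """Mantel test with Spearman correlation, one-sided (greater).

    p = (#{r_perm ≥ r_obs} + 1) / (n_perm + 1).
    """
    if set(d_comm.ids) != set(d_size.ids):
        raise ValueError("distance matrices must share ids")
    n = len(d_comm.ids)
    if n < 4:
        raise ValueError("need at least 4 objects")
    d2 = d_size.reorder(d_comm.ids)
    iu = np.triu_indices(n, k=1)
    a, b = d_comm.values, d2.values
    if np.ptp(a[iu]) == 0 or np.ptp(b[iu]) == 0:
        raise ValueError("constant distance triangle: Mantel r undefined")
    rb = _triangle_ranks(b, iu)
    rb = (rb - rb.mean()) / rb.std()

    def corr(mat: np.ndarray) -> float:
        ra = _triangle_ranks(mat, iu)
        sd = ra.std()
        if sd == 0:
            return 0.0
        return float(((ra - ra.mean()) / sd * rb).mean())

    r_obs = corr(a)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if corr(a[np.ix_(perm, perm)]) >= r_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return MantelResult(
        r=r_obs, p_value=p, n_perm=n_perm, seed=seed if isinstance(seed, int) else None
    )


@dataclass
class CompositionSizeFit:
    fit: RegressionFit
    slopes: BootstrapSlopes


def composition_size_regression(
    d_comm: DistanceMatrix,
    d_size: DistanceMatrix,
    b: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> CompositionSizeFit:
    """OLS of pairwise dissimilarity on pairwise size distance, with an
    island-level bootstrap of the slope.

    Resampling islands (not pairs) and rebuilding both triangles respects
    the dependence among entries sharing an island; resampled self-pairs
    are excluded as degenerate (0, 0) points.
    """
    if set(d_comm.ids) != set(d_size.ids):
        raise ValueError("distance matrices must share ids")
    d2 = d_size.reorder(d_comm.ids)
    n = len(d_comm.ids)
    iu = np.triu_indices(n, k=1)
    x, y = d2.values[iu], d_comm.values[iu]
    if np.ptp(x) == 0:
        raise ValueError("constant size distances")
    fit = simple_ols(x, y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    slopes = np.empty(b)
    n_redrawn = 0
    i = 0
    while i < b:
        take = rng.integers(0, n, size=n)
        ii, jj = np.meshgrid(take, take, indexing="ij")
        mask = np.triu(np.ones((n, n), dtype=bool), k=1) & (ii != jj)
        xs, ys = d2.values[ii[mask], jj[mask]], d_comm.values[ii[mask], jj[mask]]
        if xs.size < 3 or np.ptp(xs) == 0:
            n_redrawn += 1
            continue
        mx, my = xs.mean(), ys.mean()
        slopes[i] = ((xs - mx) * (ys - my)).sum() / ((xs - mx) ** 2).sum()
        i += 1
    boot = BootstrapSlopes(
        slopes=slopes,
        b=b,
        seed=seed if isinstance(seed, int) else None,
        n_redrawn=n_redrawn,
    )
    return CompositionSizeFit(fit=fit, slopes=boot)


@dataclass
class DispersionResult:
    """Per-sample distance to its group (island) centroid in PCoA space."""

    sample_ids: list[str]
    groups: list[str]
    distances: np.ndarray
    n_negative_eigenvalues: int
    min_eigenvalue: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.sample_ids, "group": self.groups, "distance": self.distances}
        )


def beta_dispersion(d: DistanceMatrix, groups) -> DispersionResult:
    """Distance of each sample to its group centroid.

    The dissimilarity matrix is embedded by principal coordinates (Gower
    double centering).  For a sample x in group g,
    ``dist² = ||x−c||²_pos − ||x−c||²_neg`` over the positive- and
    negative-eigenvalue axes, clamped at zero before the square root.
    """
    groups = [str(g) for g in groups]
    if len(groups) != len(d.ids):
        raise ValueError("one group label per object required")
    n = len(d.ids)
    a = -0.5 * d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    g = (g + g.T) / 2.0
    eigval, eigvec = np.linalg.eigh(g)
    keep = np.abs(eigval) > 1e-10 * max(1.0, np.abs(eigval).max())
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    coords = eigvec * np.sqrt(np.abs(eigval))
    pos = eigval > 0
    distances = np.zeros(n)
    labels = np.asarray(groups)
    for glab in pd.unique(labels):
        members = np.flatnonzero(labels == glab)
        if members.size == 1:
            distances[members[0]] = 0.0
            continue
        centroid = coords[members].mean(axis=0)
        delta = coords[members] - centroid
        d2_pos = (delta[:, pos] ** 2).sum(axis=1)
        d2_neg = (delta[:, ~pos] ** 2).sum(axis=1)
        distances[members] = np.sqrt(np.clip(d2_pos - d2_neg, 0.0, None))
    return DispersionResult(
        sample_ids=list(d.ids),
        groups=groups,
        distances=distances,
        n_negative_eigenvalues=int((eigval < 0).sum()),
        min_eigenvalue=float(eigval.min()) if eigval.size else 0.0,
    )


def dispersion_vs_size(
    disp: DispersionResult, islands: pd.DataFrame, size_field: str
) -> RegressionFit:
    """OLS of per-sample centroid distance on log island size."""
    frame = disp.to_frame().merge(
        islands[["island_id", size_field]], left_on="group", right_on="island_id"
    )
    counts = frame.groupby("island_id")["sample_id"].count()
    if (counts >= 2).sum() < 3:
        raise ValueError("need >= 3 islands with >= 2 samples each")
    return simple_ols(np.log(frame[size_field].to_numpy(float)), frame["distance"].to_numpy(float))
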
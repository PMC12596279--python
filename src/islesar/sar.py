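"""Power-law species–area relationships and bootstrap slope inference.

The SAR is fitted as ``log S = log c + z log A`` by ordinary least squares
(natural logs throughout; the exponent z is base-invariant).  Uncertainty
on z comes from a joint case bootstrap — resampling (richness, area) pairs
with replacement — and slope distributions from different habitats are
compared with Welch's t-test, Benjamini–Hochberg corrected across the
comparison family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diversity import RegressionFit, simple_ols


@dataclass
class SARFit:
    """One Table-1-style SAR row: z (slope), log c (intercept), R², p."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    stderr: float
    n: int
    p_adjusted: float | None = None
    compartment: str | None = None
    locus: str | None = None
    size_field: str | None = None

    @property
    def z_score(self) -> float | None:
        """The SAR exponent, reported only for significant fits (α = 0.05)."""
        p = self.p_adjusted if self.p_adjusted is not None else self.p_value
        return self.slope if p <= 0.05 else None


def fit_sar(richness, sizes, **labels) -> SARFit:
    """OLS of log richness on log island size."""
    richness = np.asarray(richness, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if richness.size < 3:
        raise ValueError("need at least 3 islands")
    if (richness <= 0).any():
        raise ValueError(
            "zero richness present: drop those islands or apply an explicit "
            "offset before fitting (no silent +1 is applied)"
        )
    if (sizes <= 0).any():
        raise ValueError("island sizes must be positive")
    fit: RegressionFit = simple_ols(np.log(sizes), np.log(richness))
    return SARFit(
        slope=fit.slope,
        intercept=fit.intercept,
        r_squared=fit.r_squared,
        p_value=fit.p_value,
        stderr=fit.stderr,
        n=fit.n,
        **labels,
    )


@dataclass
class BootstrapSlopes:
    slopes: np.ndarray
    b: int
    seed: int | None
    n_redrawn: int = 0

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        return (
            float(np.quantile(self.slopes, lo)),
            float(np.quantile(self.slopes, 1.0 - lo)),
        )


def _batch_slopes(x: np.ndarray, y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Vectorized OLS slopes for each row of resample indices."""
    xs, ys = x[idx], y[idx]
    mx = xs.mean(axis=1, keepdims=True)
    my = ys.mean(axis=1, keepdims=True)
    sxx = ((xs - mx) ** 2).sum(axis=1)
    sxy = ((xs - mx) * (ys - my)).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return sxy / sxx


def bootstrap_slopes(
    richness, sizes, b: int = 1000, seed: int | np.random.Generator | None = None
) -> BootstrapSlopes:
    """Case bootstrap of the SAR slope.

    (S, A) pairs are resampled jointly with replacement to the original n,
    the log-log OLS refitted, and the slope recorded, B times.  Degenerate
    resamples (zero size variance) are redrawn and counted.
    """
    if b < 2:
        raise ValueError("need at least 2 bootstrap replicates")
    richness = np.asarray(richness, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if richness.size < 3:
        raise ValueError("need at least 3 islands")
    if (richness <= 0).any() or (sizes <= 0).any():
        raise ValueError("richness and sizes must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x, y = np.log(sizes), np.log(richness)
    n = x.size
    idx = rng.integers(0, n, size=(b, n))
    slopes = _batch_slopes(x, y, idx)
    n_redrawn = 0
    bad = ~np.isfinite(slopes)
    while bad.any():
        n_redrawn += int(bad.sum())
        idx = rng.integers(0, n, size=(int(bad.sum()), n))
        slopes[bad] = _batch_slopes(x, y, idx)
        bad = ~np.isfinite(slopes)
    return BootstrapSlopes(
        slopes=slopes,
        b=b,
        seed=seed if isinstance(seed, int) else None,
        n_redrawn=n_redrawn,
    )


@dataclass
class SlopeComparison:
    label_a: str
    label_b: str
    t: float
    df: float
    p_value: float
    p_adjusted: float | None = None


def compare_slopes(
    a: BootstrapSlopes, b: BootstrapSlopes, label_a: str = "a", label_b: str = "b"
) -> SlopeComparison:
    """Welch two-sample t-test between two bootstrap slope distributions."""
    xa, xb = a.slopes, b.slopes
    va, vb = xa.var(ddof=1), xb.var(ddof=1)
    if va == 0 and vb == 0:
        return SlopeComparison(label_a, label_b, float("nan"), float("nan"), float("nan"))
    na, nb = xa.size, xb.size
    t, p = stats.ttest_ind(xa, xb, equal_var=False)
    se2a, se2b = va / na, vb / nb
    df = (se2a + se2b) ** 2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
    return SlopeComparison(label_a, label_b, float(t), float(df), float(p))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def adjust_family(fits: list[SARFit]) -> list[SARFit]:
    """BH-correct a family of SAR fits in place (all fits of one run)."""
    adj = bh_adjust([f.p_value for f in fits])
    for f, q in zip(fits, adj):
        f.p_adjusted = float(q)
    return fits


def adjust_comparisons(comparisons: list[SlopeComparison]) -> list[SlopeComparison]:
    """BH-correct a family of slope comparisons (undefined t's excluded)."""
    defined = [c for c in comparisons if np.isfinite(c.p_value)]
    if defined:
        adj = bh_adjust([c.p_value for c in defined])
        for c, q in zip(defined, adj):
            c.p_adjusted = float(q)
    return comparisons
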
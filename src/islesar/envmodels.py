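"""Environmental-predictor modelling for island richness.

Two tools: greedy stepwise multiple regression minimizing
``AIC = n·ln(RSS/n) + 2k`` (the conventional linear-model stepwise
criterion, with k counting the intercept and the additive constant dropped
consistently), and the LMG decomposition of the full model's R² into
per-predictor shares by averaging each predictor's incremental R² over all
orderings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

# default candidate sets: physical predictors shared by both island-size
# panels, plus detritus- or water-specific chemistry
COMMON_PREDICTORS = (
    "diameter_cm",
    "height_cm",
    "complexity",
    "invertebrate_number",
    "log_invertebrate_weight",
)
DETRITUS_PREDICTORS = COMMON_PREDICTORS + ("percent_carbon", "percent_nitrogen")
WATER_PREDICTORS = COMMON_PREDICTORS + (
    "dissolved_oxygen_mg_l",
    "pH",
    "temperature_C",
    "nitrate_conc",
)


def candidate_matrix(islands: pd.DataFrame, predictors) -> pd.DataFrame:
    """Assemble a candidate predictor matrix, deriving log invertebrate weight."""
    frame = islands.copy()
    if "log_invertebrate_weight" in predictors:
        w = frame["invertebrate_weight_mg"].astype(float)
        frame["log_invertebrate_weight"] = np.log(w.where(w > 0))
    return frame.set_index("island_id")[list(predictors)]


def _rss(y: np.ndarray, x: np.ndarray) -> float:
    """Residual sum of squares of y on [1, x]."""
    design = np.column_stack([np.ones(y.size), x]) if x.size else np.ones((y.size, 1))
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return float(resid @ resid)


def _aic(y: np.ndarray, x: np.ndarray) -> float:
    n = y.size
    rss = max(_rss(y, x), 1e-300)
    k = 1 + (x.shape[1] if x.ndim == 2 else 0)
    return n * math.log(rss / n) + 2 * k


@dataclass
class StepwiseModel:
    response: str
    selected: list[str]
    coefficients: dict[str, float]
    coefficient_p: dict[str, float]
    aic: float
    r_squared: float
    n: int
    n_dropped_incomplete: int
    trace: list[tuple[int, str, float]] = field(default_factory=list)


def _check_collinear(frame: pd.DataFrame) -> None:
    x = frame.to_numpy(float)
    std = x.std(axis=0, ddof=0)
    if (std == 0).any():
        bad = [c for c, s in zip(frame.columns, std) if s == 0]
        raise ValueError(f"constant candidate predictors: {', '.join(bad)}")
    z = (x - x.mean(0)) / std
    corr = np.corrcoef(z, rowvar=False)
    if corr.ndim == 2:
        iu = np.triu_indices(corr.shape[0], k=1)
        hits = np.where(np.abs(corr[iu]) > 1 - 1e-10)[0]
        if hits.size:
            i, j = iu[0][hits[0]], iu[1][hits[0]]
            raise ValueError(
                f"collinear candidates: {frame.columns[i]!r} and {frame.columns[j]!r}"
            )
    cond = np.linalg.cond(z)
    if cond > 1e8:
        raise ValueError(f"candidate matrix ill-conditioned (condition number {cond:.3g})")


def step_aic(
    response: pd.Series | np.ndarray,
    candidates: pd.DataFrame,
    direction: str = "both",
    response_label: str = "response",
) -> StepwiseModel:
    """Greedy stepwise selection minimizing AIC.

    ``both``/``backward`` start from the full model, ``forward`` from the
    intercept-only model; at every step the single add or drop giving the
    largest AIC decrease is taken, stopping when no move improves.
    Incomplete cases (any NaN in response or candidates) are dropped first.
    """
    if direction not in ("both", "forward", "backward"):
        raise ValueError(f"unknown direction {direction!r}")
    y_raw = np.asarray(response, dtype=float)
    data = candidates.copy()
    data["_y"] = y_raw
    complete = data.dropna()
    n_dropped = len(data) - len(complete)
    y = complete["_y"].to_numpy()
    frame = complete.drop(columns="_y")
    names = list(frame.columns)
    k_full = len(names)
    if y.size <= k_full + 2:
        raise ValueError(
            f"need n > k+2 complete cases for the full model (n={y.size}, k={k_full})"
        )
    _check_collinear(frame)
    x_all = frame.to_numpy(float)

    current = set(names) if direction in ("both", "backward") else set()
    cols = {name: i for i, name in enumerate(names)}

    def aic_of(subset) -> float:
        idx = [cols[s] for s in sorted(subset)]
        return _aic(y, x_all[:, idx] if idx else np.empty((y.size, 0)))

    trace: list[tuple[int, str, float]] = []
    step_no = 0
    current_aic = aic_of(current)
    trace.append((step_no, "start", current_aic))
    allow_add = direction in ("both", "forward")
    allow_drop = direction in ("both", "backward")
    while True:
        best_move, best_aic = None, current_aic
        if allow_add:
            for name in names:
                if name not in current:
                    a = aic_of(current | {name})
                    if a < best_aic - 1e-12:
                        best_move, best_aic = ("add", name), a
        if allow_drop:
            for name in list(current):
                a = aic_of(current - {name})
                if a < best_aic - 1e-12:
                    best_move, best_aic = ("drop", name), a
        if best_move is None:
            break
        action, name = best_move
        current = current | {name} if action == "add" else current - {name}
        current_aic = best_aic
        step_no += 1
        trace.append((step_no, f"{action} {name}", current_aic))

    selected = sorted(current)
    idx = [cols[s] for s in selected]
    x_sel = x_all[:, idx] if idx else np.empty((y.size, 0))
    design = np.column_stack([np.ones(y.size), x_sel])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 0.0
    dof = y.size - design.shape[1]
    if dof > 0 and rss > 0:
        sigma2 = rss / dof
        cov = sigma2 * np.linalg.inv(design.T @ design)
        se = np.sqrt(np.diag(cov))
        tvals = coef / se
        pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    else:
        pvals = np.full(design.shape[1], np.nan)
    labels = ["(intercept)"] + selected
    return StepwiseModel(
        response=response_label,
        selected=selected,
        coefficients=dict(zip(labels, map(float, coef))),
        coefficient_p=dict(zip(labels, map(float, pvals))),
        aic=current_aic,
        r_squared=r2,
        n=int(y.size),
        n_dropped_incomplete=n_dropped,
        trace=trace,
    )


# ---------------------------------------------------------------------------
# LMG relative importance
# ---------------------------------------------------------------------------

@dataclass
class RelativeImportance:
    shares: dict[str, float]
    full_r_squared: float


def lmg_importance(response, predictors: pd.DataFrame) -> RelativeImportance:
    """LMG decomposition of R² into per-predictor shares.

    Each predictor's share is the average over all k! orderings of its
    incremental R² when added; computed via the subset formulation with
    weights |S|!(k−|S|−1)!/k! over the 2^(k−1) subsets not containing the
    predictor.  Shares sum to the full-model R² exactly.
    """
    y = np.asarray(response, dtype=float)
    frame = predictors.dropna()
    if len(frame) != len(predictors) or np.isnan(y).any():
        raise ValueError("lmg_importance requires complete cases")
    names = list(frame.columns)
    k = len(names)
    if k > 10:
        raise ValueError("more than 10 predictors: enumerate a subset instead")
    if k == 0:
        raise ValueError("need at least one predictor")
    _check_collinear(frame)
    x = frame.to_numpy(float)
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("response has zero variance")

    r2_cache: dict[frozenset, float] = {}

    def r2_of(subset: frozenset) -> float:
        if subset not in r2_cache:
            idx = sorted(subset)
            r2_cache[subset] = 1.0 - _rss(y, x[:, idx]) / tss
        return r2_cache[subset]

    fact = [math.factorial(i) for i in range(k + 1)]
    shares = {}
    others = list(range(k))
    for i in range(k):
        rest = [j for j in others if j != i]
        total = 0.0
        for r in range(k):
            w = fact[r] * fact[k - r - 1] / fact[k]
            for s in combinations(rest, r):
                sub = frozenset(s)
                total += w * (r2_of(sub | {i}) - r2_of(sub))
        shares[names[i]] = total
    return RelativeImportance(shares=shares, full_r_squared=r2_of(frozenset(range(k))))
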
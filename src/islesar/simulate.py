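"""Synthetic island-metacommunity generator.

Emulates the statistical structure a bromeliad-island amplicon survey is
expected to show: ~32 phytotelm islands whose detrital habitat spans a
250-fold size range (90-fold for water), per-island replicate samples in
three compartments (detritus, water, invertebrate hosts), power-law
species–area structure ``log S = log c + z log A + ε`` carried by community
richness, host filtering that makes invertebrate communities nested subsets
of the free-living pool, an island-size-correlated pH gradient, and
reagent contaminants shared with negative-control samples.

Read depth is decoupled from the richness signal: every community member is
guaranteed at least one read, and the remaining depth is multinomial over
the member relative abundances.  This mirrors surveys whose accumulation
curves saturate, so observed richness equals true community richness in the
deep-sampling regime.

All randomness flows from ``SyntheticConfig.seed`` through a single
``numpy.random.Generator``; there is no hidden global state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .core import AnalysisBundle, CountTable, join_metadata

COMMUNITY_COMPARTMENTS = ("detritus", "water", "invertebrate")


@dataclass
class SyntheticConfig:
    """Study-condition parameters for one simulated island metacommunity."""

    n_islands: int = 32
    detritus_fold_range: float = 250.0
    water_fold_range: float = 90.0
    #: SAR exponents z per compartment; defaults follow the fungal regime
    #: (positive detrital and aquatic slopes, flat host communities).
    sar_exponent_by_compartment: Mapping[str, float] = field(
        default_factory=lambda: {"detritus": 0.12, "water": 0.10, "invertebrate": 0.0}
    )
    sar_intercept_by_compartment: Mapping[str, float] = field(
        default_factory=lambda: {"detritus": 3.95, "water": 3.25, "invertebrate": 2.96}
    )
    pool_size: int = 4000
    pool_abundance_meanlog: float = 0.0
    pool_abundance_sdlog: float = 1.5
    #: sd of per-island lognormal species affinities; drives between-island
    #: turnover (large values -> islands share few taxa, as real phytotelm
    #: communities do)
    island_affinity_sd: float = 2.0
    host_filter_strength: float = 0.3
    #: fraction of each host community drawn from the admissible pool at
    #: large (host specialists / vertically acquired taxa); the remainder is
    #: acquired from the island's own detrital community, which is what
    #: nests hosts inside their local environment.  Kept small: at synthetic
    #: community sizes a large specialist share drowns the nestedness signal
    #: that real, much larger tables retain.
    host_specialist_fraction: float = 0.05
    replicates_per_island: Mapping[str, int] = field(
        default_factory=lambda: {"detritus": 2, "water": 2, "invertebrate": 1}
    )
    sequencing_depth_mean: int = 10000
    sequencing_depth_dispersion: float = 8.0
    contaminant_count: int = 10
    n_negatives: int = 6
    ph_size_slope: float = -0.15
    ph_noise_sd: float = 0.2
    noise_sd_log_richness: float = 0.5
    locus: str = "18S"
    detritus_min_mg: float = 100.0
    water_min_ml: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.detritus_fold_range <= 1 or self.water_fold_range <= 1:
            raise ValueError("fold ranges must exceed 1")
        if not 0.0 <= self.host_filter_strength <= 1.0:
            raise ValueError("host_filter_strength must lie in [0, 1]")
        for z in self.sar_exponent_by_compartment.values():
            if not math.isfinite(z):
                raise ValueError("SAR exponents must be finite")
        if self.contaminant_count > self.pool_size:
            raise ValueError("contaminant_count must not exceed pool_size")
        if self.noise_sd_log_richness < 0:
            raise ValueError("noise_sd_log_richness must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class RegionalPool:
    """Species pool with rank-ordered relative abundances.

    ``host_admissible`` indexes the fraction of the pool that invertebrate
    hosts can recruit from (the host-filter); it is fixed per metacommunity.
    """

    asv_ids: list[str]
    abundances: np.ndarray
    host_admissible: np.ndarray  # integer indices into the pool


def generate_islands(config: SyntheticConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-island size measures and environmental covariates.

    Sizes are log-uniform with the extremes pinned so the realized fold
    range equals the configured one exactly.  pH tracks log water volume
    with slope ``ph_size_slope``; the remaining covariates are independent
    of size so that size effects and covariate effects are separable
    downstream.
    """
    if config.n_islands < 3:
        raise ValueError("need at least 3 islands for any regression")
    rng = config.rng() if rng is None else rng
    n = config.n_islands

    def _log_uniform(lo: float, fold: float) -> np.ndarray:
        logs = np.empty(n)
        logs[0], logs[-1] = math.log(lo), math.log(lo * fold)
        logs[1:-1] = rng.uniform(logs[0], logs[-1], size=n - 2)
        return np.exp(rng.permutation(logs))

    detritus = _log_uniform(config.detritus_min_mg, config.detritus_fold_range)
    water = _log_uniform(config.water_min_ml, config.water_fold_range)
    log_wv = np.log(water)
    ph = 6.5 + config.ph_size_slope * (log_wv - log_wv.mean())
    if config.ph_noise_sd > 0:
        ph = ph + rng.normal(0, config.ph_noise_sd, n)
    islands = pd.DataFrame(
        {
            "island_id": [f"isl{i:02d}" for i in range(1, n + 1)],
            "detritus_weight_mg": detritus,
            "water_volume_ml": water,
            "diameter_cm": np.clip(rng.normal(40, 10, n), 8, None),
            "height_cm": np.clip(rng.normal(30, 8, n), 5, None),
            "complexity": rng.poisson(25, n) + 1,
            "invertebrate_number": rng.poisson(4, n),
            "invertebrate_weight_mg": rng.gamma(2.0, 15.0, n),
            "pH": ph,
            "temperature_C": rng.normal(25, 1.5, n),
            "dissolved_oxygen_mg_l": np.clip(rng.normal(4.0, 1.0, n), 0.2, None),
            "nitrate_conc": rng.lognormal(-1.0, 0.5, n),
            "percent_carbon": rng.normal(45, 5, n),
            "percent_nitrogen": np.clip(rng.normal(1.5, 0.3, n), 0.1, None),
        }
    )
    return islands


def generate_regional_pool(config: SyntheticConfig, rng: np.random.Generator | None = None) -> RegionalPool:
    """Lognormal rank-abundance pool, normalized and sorted descending."""
    if config.pool_size < 2:
        raise ValueError("pool_size must be at least 2")
    rng = config.rng() if rng is None else rng
    raw = rng.lognormal(config.pool_abundance_meanlog, config.pool_abundance_sdlog, config.pool_size)
    if config.pool_abundance_sdlog == 0:
        raw = np.full(config.pool_size, 1.0)
    ab = np.sort(raw)[::-1]
    ab = ab / ab.sum()
    n_host = max(1, int(round(config.host_filter_strength * config.pool_size)))
    host_admissible = np.sort(rng.choice(config.pool_size, size=n_host, replace=False))
    ids = [f"asv{i:05d}" for i in range(1, config.pool_size + 1)]
    return RegionalPool(ids, ab, host_admissible)


def _size_for(compartment: str, island: pd.Series) -> float:
    # detritus communities scale with detrital mass; aquatic and
    # host-associated communities with standing water volume
    return float(
        island["detritus_weight_mg"] if compartment == "detritus" else island["water_volume_ml"]
    )


def target_richness(
    island: pd.Series, compartment: str, config: SyntheticConfig, rng: np.random.Generator
) -> int:
    """Realize ``S* = round(exp(log c + z log A + N(0, σ)))``, clamped to ≥ 1."""
    z = config.sar_exponent_by_compartment[compartment]
    logc = config.sar_intercept_by_compartment[compartment]
    eps = rng.normal(0.0, config.noise_sd_log_richness) if config.noise_sd_log_richness else 0.0
    return max(1, int(round(math.exp(logc + z * math.log(_size_for(compartment, island)) + eps))))


def generate_community(
    island: pd.Series,
    compartment: str,
    pool: RegionalPool,
    config: SyntheticConfig,
    rng: np.random.Generator,
    affinity: np.ndarray | None = None,
    local_environment: np.ndarray | None = None,
):
    """Realize one island × compartment community.

    ``affinity`` is the island's per-species habitat-suitability multiplier
    (shared across its compartments; drives between-island turnover).
    For invertebrate hosts, ``local_environment`` gives the pool indices of
    the island's own free-living (detrital) community: most host taxa are
    acquired from it (restricted to the admissible host fraction), the
    ``host_specialist_fraction`` remainder from the admissible pool at
    large.  This is what makes host communities nested within their local
    environment.

    Returns ``(counts, meta_rows, members)`` where ``counts`` is a
    replicates × pool_size integer matrix, ``meta_rows`` the matching sample
    metadata records and ``members`` the pool indices of the community.
    """
    if compartment == "negative_control":
        raise ValueError("negative controls are generated by generate_negatives")
    weights = pool.abundances if affinity is None else pool.abundances * affinity
    s_star = target_richness(island, compartment, config, rng)

    def _draw(candidates: np.ndarray, k: int, exclude: np.ndarray | None = None) -> np.ndarray:
        if exclude is not None and exclude.size:
            candidates = np.setdiff1d(candidates, exclude)
        k = min(k, candidates.size)
        if k <= 0:
            return np.empty(0, dtype=np.int64)
        w = weights[candidates]
        return rng.choice(candidates, size=k, replace=False, p=w / w.sum())

    if compartment != "invertebrate":
        members = _draw(np.arange(len(pool.asv_ids)), s_star)
    else:
        admissible = pool.host_admissible
        local = (
            np.intersect1d(local_environment, admissible)
            if local_environment is not None
            else admissible
        )
        n_env = int(round(s_star * (1.0 - config.host_specialist_fraction)))
        env_members = _draw(local, n_env)
        spec_members = _draw(admissible, s_star - env_members.size, exclude=env_members)
        members = np.concatenate([env_members, spec_members])
        if members.size < s_star:
            import warnings

            warnings.warn(
                f"target richness {s_star} exceeds admissible pool "
                f"({admissible.size}) for {island['island_id']}/{compartment}; clamping",
                stacklevel=2,
            )
    s_star = members.size
    p_members = weights[members] / weights[members].sum()

    n_rep = config.replicates_per_island.get(compartment, 1)
    counts = np.zeros((n_rep, len(pool.asv_ids)), dtype=np.int64)
    meta_rows = []
    for rep in range(1, n_rep + 1):
        lam = rng.gamma(
            config.sequencing_depth_dispersion,
            config.sequencing_depth_mean / config.sequencing_depth_dispersion,
        )
        depth = max(s_star, int(rng.poisson(lam)))
        reads = np.ones(s_star, dtype=np.int64)
        reads += rng.multinomial(depth - s_star, p_members)
        counts[rep - 1, members] = reads
        meta_rows.append(
            {
                "sample_id": f"{island['island_id']}_{compartment}_r{rep}",
                "island_id": island["island_id"],
                "compartment": compartment,
                "locus": config.locus,
                "replicate_index": rep,
            }
        )
    return counts, meta_rows, members


def generate_negatives(config: SyntheticConfig, pool: RegionalPool, rng: np.random.Generator):
    """Negative-control samples plus the ground-truth contaminant registry.

    Contaminants are reagent-borne ASVs with dedicated ids (disjoint from
    the ecological pool).  Each contaminant is planted in at least
    three-quarters of the negatives (so prevalence-based screening has
    signal) and later sprinkled into true samples at low prevalence.
    """
    n_neg, n_cont = config.n_negatives, config.contaminant_count
    contaminant_ids = [f"contam{i:03d}" for i in range(1, n_cont + 1)]
    counts = np.zeros((n_neg, n_cont), dtype=np.int64)
    for j in range(n_cont):
        k = max(1, math.ceil(0.75 * n_neg)) if n_neg else 0
        hit = rng.choice(n_neg, size=k, replace=False) if n_neg else []
        counts[hit, j] = rng.poisson(50, size=len(hit)) + 1
    meta_rows = [
        {
            "sample_id": f"neg{r:02d}",
            "island_id": "",
            "compartment": "negative_control",
            "locus": config.locus,
            "replicate_index": r,
        }
        for r in range(1, n_neg + 1)
    ]
    return counts, meta_rows, contaminant_ids


@dataclass
class SimulatedDataset:
    bundle: AnalysisBundle
    truth: dict

    @property
    def table(self) -> CountTable:
        return self.bundle.table

    @property
    def samples(self) -> pd.DataFrame:
        return self.bundle.samples

    @property
    def islands(self) -> pd.DataFrame:
        return self.bundle.islands


def simulate_dataset(config: SyntheticConfig, rng: np.random.Generator | None = None) -> SimulatedDataset:
    """Generate a full metacommunity: islands, communities, negatives, truth."""
    rng = config.rng() if rng is None else rng
    islands = generate_islands(config, rng)
    pool = generate_regional_pool(config, rng)

    blocks, meta_rows, members_by_island = [], [], {}
    for _, island in islands.iterrows():
        if config.island_affinity_sd > 0:
            affinity = np.exp(rng.normal(0.0, config.island_affinity_sd, len(pool.asv_ids)))
        else:
            affinity = None
        local_env: np.ndarray | None = None
        for compartment in COMMUNITY_COMPARTMENTS:
            if config.replicates_per_island.get(compartment, 0) < 1:
                continue
            counts, rows, members = generate_community(
                island, compartment, pool, config, rng,
                affinity=affinity, local_environment=local_env,
            )
            if compartment == "detritus":
                local_env = members
            blocks.append(counts)
            meta_rows.extend(rows)
            members_by_island[(island["island_id"], compartment)] = members
    community = np.vstack(blocks) if blocks else np.zeros((0, len(pool.asv_ids)), dtype=np.int64)

    neg_counts, neg_rows, contaminant_ids = generate_negatives(config, pool, rng)
    # sprinkle contaminants into true samples at low prevalence / low depth
    n_true = community.shape[0]
    cont_true = np.zeros((n_true, len(contaminant_ids)), dtype=np.int64)
    for j in range(len(contaminant_ids)):
        hit = rng.random(n_true) < 0.3
        cont_true[hit, j] = rng.poisson(5, size=int(hit.sum())) + 1

    counts = np.block(
        [
            [community, cont_true],
            [np.zeros((neg_counts.shape[0], community.shape[1]), dtype=np.int64), neg_counts],
        ]
    )
    asv_ids = pool.asv_ids + contaminant_ids
    sample_ids = [r["sample_id"] for r in meta_rows + neg_rows]
    table = CountTable(counts, sample_ids, asv_ids)
    # observed tables carry only detected ASVs
    seen = table.asv_totals() > 0
    table = table.select_asvs(seen)
    samples = pd.DataFrame(meta_rows + neg_rows)
    bundle = join_metadata(table, samples, islands)
    truth = {
        "sar_exponent_by_compartment": dict(config.sar_exponent_by_compartment),
        "sar_intercept_by_compartment": dict(config.sar_intercept_by_compartment),
        "contaminants": contaminant_ids,
        "host_admissible": [pool.asv_ids[i] for i in pool.host_admissible],
        "config": asdict(config),
    }
    return SimulatedDataset(bundle, truth)


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> None:
    """Emit counts.tsv, samples.tsv, islands.tsv and truth.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.table.to_frame().to_csv(out / "counts.tsv", sep="\t", index_label="sample_id")
    dataset.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
    dataset.islands.to_csv(out / "islands.tsv", sep="\t", index=False)
    with open(out / "truth.json", "w") as fh:
        json.dump(dataset.truth, fh, indent=2, sort_keys=True, default=str)
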
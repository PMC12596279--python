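"""Config-driven end-to-end runs with machine-readable reports.

``run_pipeline`` executes qc → diversity → sar → envmodel → beta →
nullmodels on either a simulated metacommunity or user-supplied TSVs, and
writes every stage's outputs as TSV/JSON under the output directory plus a
manifest recording the package version, master seed and config hash.

Determinism contract: a single master seed spawns per-stage child seeds
keyed by stage name (CRC-32 of the name), so toggling one stage never
shifts another stage's random stream, and a rerun with the same seed is
byte-identical.  No timestamps are written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import (
    AnalysisBundle,
    join_metadata,
    read_count_table,
    read_island_metadata,
    read_sample_metadata,
)
from .simulate import SyntheticConfig, simulate_dataset, write_dataset
from . import beta as beta_mod
from . import diversity as div_mod
from . import envmodels as env_mod
from . import nullmodels as null_mod
from . import qc as qc_mod
from . import sar as sar_mod

log = logging.getLogger("islesar")

ALL_STAGES = ("qc", "diversity", "sar", "envmodel", "beta", "nullmodels")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """One pipeline run: exactly one of ``simulate`` or ``input``."""

    seed: int = 0
    simulate: SyntheticConfig | None = None
    input: dict | None = None  # paths: counts, samples, islands
    stages: tuple[str, ...] = ALL_STAGES
    decontam: bool = True
    decontam_threshold: float = 0.5
    min_sample_reads: int = 300
    min_asv_reads: int = 3
    sar_bootstrap: int = 1000
    mantel_permutations: int = 999
    beta_bootstrap: int = 200
    rc_reps: int = 199
    rc_max_islands: int = 12
    nodf_nulls: int = 1000

    def __post_init__(self):
        if (self.simulate is None) == (self.input is None):
            raise ValueError("exactly one of 'simulate' or 'input' must be set")
        for s in self.stages:
            if s not in ALL_STAGES:
                raise ValueError(f"unknown stage {s!r}")
        for name in ("sar_bootstrap", "mantel_permutations", "beta_bootstrap", "rc_reps", "nodf_nulls"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = SyntheticConfig(**sim)
        stages = tuple(raw.pop("stages", ALL_STAGES))
        return cls(simulate=sim, stages=stages, **raw)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["stages"] = list(self.stages)
        return out


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Child generator keyed by stage name; independent of other stages."""
    key = zlib.crc32(stage.encode())
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) % 2**31, key]))


def _write_json(obj, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, frozenset):
        return sorted(x)
    return str(x)


def _write_tsv(frame: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep="\t", index=index, float_format="%.10g")


def _load_bundle(config: RunConfig, outdir: Path) -> tuple[AnalysisBundle, dict | None]:
    if config.simulate is not None:
        sim_cfg = dataclasses.replace(config.simulate, seed=config.seed)
        dataset = simulate_dataset(sim_cfg, rng=stage_rng(config.seed, "simulate"))
        write_dataset(dataset, outdir / "data")
        return dataset.bundle, dataset.truth
    paths = config.input
    table = read_count_table(paths["counts"])
    samples = read_sample_metadata(paths["samples"])
    islands = read_island_metadata(paths["islands"])
    return join_metadata(table, samples, islands), None


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_qc(bundle: AnalysisBundle, config: RunConfig, out: Path) -> AnalysisBundle:
    table = bundle.table
    summary: dict = {"samples_in": table.shape[0], "asvs_in": table.shape[1]}
    if config.decontam and (bundle.samples["compartment"] == "negative_control").any():
        reports, table = qc_mod.decontam_prevalence(
            table, bundle.samples, threshold=config.decontam_threshold
        )
        _write_tsv(qc_mod.reports_to_frame(reports), out / "qc" / "contaminants.tsv")
        summary["asvs_flagged"] = int(sum(r.flagged for r in reports))
    # drop the controls once decontamination has used them
    keep = bundle.samples["compartment"] != "negative_control"
    table = table.select_samples(
        [s for s, k in zip(bundle.samples["sample_id"], keep) if k and s in table.sample_ids]
    )
    table = qc_mod.cull(table, config.min_sample_reads, config.min_asv_reads)
    summary["samples_out"], summary["asvs_out"] = table.shape
    _write_json(summary, out / "qc" / "summary.json")
    samples = bundle.samples[bundle.samples["sample_id"].isin(table.sample_ids)].reset_index(drop=True)
    log.info("qc: %s", summary)
    return AnalysisBundle(table, samples, bundle.islands)


def _stage_diversity(bundle: AnalysisBundle, config: RunConfig, out: Path) -> dict:
    pooled = div_mod.pooled_counts(bundle.table, bundle.samples)
    rows = []
    for (island, comp), vec in pooled.iterrows():
        arr = vec.to_numpy()
        rows.append(
            {
                "island_id": island,
                "compartment": comp,
                "richness": int((arr > 0).sum()),
                "q1": div_mod.hill_q1(arr),
            }
        )
    per_island = pd.DataFrame(rows)
    _write_tsv(per_island, out / "diversity" / "richness.tsv")

    overlap = div_mod.compartment_overlap(bundle.table, bundle.samples)
    overlap_json = {
        "regions": {"+".join(sorted(k)): v for k, v in overlap.regions.items()},
        "union": overlap.union_size(),
    }
    if "invertebrate" in overlap.presence:
        free = overlap.presence.get("detritus", set()) | overlap.presence.get("water", set())
        hosts = overlap.presence["invertebrate"]
        overlap_json["fraction_free_living_in_hosts"] = (
            len(free & hosts) / len(free) if free else float("nan")
        )
        overlap_json["fraction_hosts_in_free_living"] = (
            len(hosts & free) / len(hosts) if hosts else float("nan")
        )
    _write_json(overlap_json, out / "diversity" / "overlap.json")

    anova = div_mod.richness_anova(per_island["richness"], per_island["compartment"])
    _write_json(
        {
            "f_statistic": anova.f_statistic,
            "p_value": anova.p_value,
            "significant": bool(anova.p_value <= 0.05),
        },
        out / "diversity" / "anova.json",
    )
    _write_tsv(anova.tukey, out / "diversity" / "tukey.tsv")

    ev_rows = []
    for comp, size_field in (
        ("detritus", "detritus_weight_mg"),
        ("water", "water_volume_ml"),
        ("invertebrate", "water_volume_ml"),
    ):
        sub = per_island[per_island["compartment"] == comp]
        if len(sub) < 3:
            continue
        fit = div_mod.evenness_vs_size(sub, bundle.islands, size_field)
        ev_rows.append(
            {
                "compartment": comp,
                "size_field": size_field,
                "slope": fit.slope,
                "r_squared": fit.r_squared,
                "p_value": fit.p_value,
                "significant": fit.p_value <= 0.05,
            }
        )
    _write_tsv(pd.DataFrame(ev_rows), out / "diversity" / "evenness_vs_size.tsv")
    return {"per_island": per_island}


SAR_SPECS = (
    ("detritus", "detritus_weight_mg"),
    ("water", "water_volume_ml"),
    ("invertebrate", "detritus_weight_mg"),
    ("invertebrate", "water_volume_ml"),
)


def _stage_sar(per_island: pd.DataFrame, bundle: AnalysisBundle, config: RunConfig, out: Path, rng) -> None:
    sizes = bundle.islands.set_index("island_id")
    locus = bundle.samples["locus"].iloc[0] if len(bundle.samples) else "NA"
    fits, boots, labels = [], [], []
    for comp, size_field in SAR_SPECS:
        sub = per_island[(per_island["compartment"] == comp) & (per_island["richness"] > 0)]
        if len(sub) < 3:
            continue
        area = sizes.loc[sub["island_id"], size_field].to_numpy(float)
        fit = sar_mod.fit_sar(
            sub["richness"].to_numpy(float),
            area,
            compartment=comp,
            locus=locus,
            size_field=size_field,
        )
        fits.append(fit)
        boots.append(sar_mod.bootstrap_slopes(sub["richness"], area, b=config.sar_bootstrap, seed=rng))
        labels.append(f"{comp}({size_field})")
    sar_mod.adjust_family(fits)
    table1 = pd.DataFrame(
        {
            "compartment": [f.compartment for f in fits],
            "locus": [f.locus for f in fits],
            "size_field": [f.size_field for f in fits],
            "r_squared": [f.r_squared for f in fits],
            "p_value": [f.p_value for f in fits],
            "p_adjusted": [f.p_adjusted for f in fits],
            "slope": [f.slope for f in fits],
            "intercept": [f.intercept for f in fits],
            "z_score": [f.z_score for f in fits],
            "n": [f.n for f in fits],
        }
    )
    _write_tsv(table1, out / "sar" / "sar_fits.tsv")
    comparisons = []
    for i in range(len(boots)):
        for j in range(i + 1, len(boots)):
            comparisons.append(
                sar_mod.compare_slopes(boots[i], boots[j], labels[i], labels[j])
            )
    sar_mod.adjust_comparisons(comparisons)
    _write_tsv(
        pd.DataFrame([c.__dict__ for c in comparisons]), out / "sar" / "slope_comparisons.tsv"
    )


def _stage_envmodel(per_island: pd.DataFrame, bundle: AnalysisBundle, config: RunConfig, out: Path) -> None:
    panels = {
        "detritus": env_mod.DETRITUS_PREDICTORS,
        "water": env_mod.WATER_PREDICTORS,
        "invertebrate": env_mod.WATER_PREDICTORS,
    }
    model_rows, importance_rows = [], []
    for comp, predictors in panels.items():
        sub = per_island[(per_island["compartment"] == comp) & (per_island["richness"] > 0)]
        if len(sub) < len(predictors) + 3:
            continue
        cand = env_mod.candidate_matrix(bundle.islands, predictors).loc[sub["island_id"]]
        y = np.log(sub["richness"].to_numpy(float))
        model = env_mod.step_aic(y, cand, response_label=f"log_richness[{comp}]")
        for term, coef in model.coefficients.items():
            p = model.coefficient_p[term]
            model_rows.append(
                {
                    "compartment": comp,
                    "term": term,
                    "coefficient": coef,
                    "p_value": p,
                    "stars": "***" if p <= 0.001 else "**" if p <= 0.01 else "*" if p <= 0.05 else "",
                    "r_squared": model.r_squared,
                    "aic": model.aic,
                    "n": model.n,
                }
            )
        if model.selected:
            imp = env_mod.lmg_importance(y, cand[model.selected])
            for name, share in imp.shares.items():
                importance_rows.append(
                    {"compartment": comp, "predictor": name, "lmg_share": share,
                     "full_r_squared": imp.full_r_squared}
                )
    _write_tsv(pd.DataFrame(model_rows), out / "envmodel" / "models.tsv")
    _write_tsv(pd.DataFrame(importance_rows), out / "envmodel" / "importance.tsv")


def _stage_beta(per_island_counts: pd.DataFrame, bundle: AnalysisBundle, config: RunConfig, out: Path, rng) -> None:
    sizes = bundle.islands
    mantel_rows, reg_rows = [], []
    for comp, size_field in SAR_SPECS:
        pooled = per_island_counts.xs(comp, level="compartment")
        pooled = pooled[pooled.sum(axis=1) > 0]
        if len(pooled) < 4:
            continue
        from .core import CountTable

        tbl = CountTable(pooled.to_numpy(), list(pooled.index), list(pooled.columns))
        d_comm = beta_mod.bray_curtis(tbl)
        isl = sizes[sizes["island_id"].isin(pooled.index)]
        d_size = beta_mod.size_distance(isl, size_field)
        mr = beta_mod.mantel_spearman(d_comm, d_size, n_perm=config.mantel_permutations, seed=rng)
        mantel_rows.append(
            {
                "compartment": comp,
                "size_field": size_field,
                "r": mr.r,
                "p_value": mr.p_value,
                "n_perm": mr.n_perm,
                "significant": mr.p_value <= 0.05,
            }
        )
        cs = beta_mod.composition_size_regression(d_comm, d_size, b=config.beta_bootstrap, seed=rng)
        reg_rows.append(
            {
                "compartment": comp,
                "size_field": size_field,
                "slope": cs.fit.slope,
                "r_squared": cs.fit.r_squared,
                "p_value": cs.fit.p_value,
                "boot_slope_mean": float(cs.slopes.slopes.mean()),
                "boot_slope_sd": float(cs.slopes.slopes.std(ddof=1)),
            }
        )
    _write_tsv(pd.DataFrame(mantel_rows), out / "beta" / "mantel.tsv")
    _write_tsv(pd.DataFrame(reg_rows), out / "beta" / "composition_size_regression.tsv")

    # within-island dispersion for free-living compartments with replication
    disp_rows, disp_fits = [], []
    for comp, size_field in (("detritus", "detritus_weight_mg"), ("water", "water_volume_ml")):
        mask = (bundle.samples["compartment"] == comp).to_numpy()
        if mask.sum() < 6:
            continue
        sub_tbl = bundle.table.select_samples(mask).drop_empty()
        meta = bundle.samples.set_index("sample_id").loc[sub_tbl.sample_ids]
        if meta.groupby("island_id").size().max() < 2:
            continue
        d = beta_mod.bray_curtis(sub_tbl)
        disp = beta_mod.beta_dispersion(d, list(meta["island_id"]))
        frame = disp.to_frame()
        frame.insert(0, "compartment", comp)
        disp_rows.append(frame)
        try:
            fit = beta_mod.dispersion_vs_size(disp, bundle.islands, size_field)
        except ValueError:
            continue
        disp_fits.append(
            {
                "compartment": comp,
                "size_field": size_field,
                "slope": fit.slope,
                "r_squared": fit.r_squared,
                "p_value": fit.p_value,
                "significant": fit.p_value <= 0.05,
            }
        )
    if disp_rows:
        _write_tsv(pd.concat(disp_rows, ignore_index=True), out / "beta" / "dispersion.tsv")
    _write_tsv(pd.DataFrame(disp_fits), out / "beta" / "dispersion_vs_size.tsv")


def _stage_nullmodels(per_island_counts: pd.DataFrame, bundle: AnalysisBundle, config: RunConfig, out: Path, rng) -> None:
    mat, row_ids, _ = null_mod.build_compartment_matrix(bundle.table, bundle.samples)
    observed = null_mod.nodf(mat)
    res = null_mod.null_compare(
        observed, null_mod.nodf, mat, n_null=config.nodf_nulls, seed=rng
    )
    _write_json(
        {
            "rows": row_ids,
            "nodf_observed": res.observed,
            "null_mean": res.null_mean,
            "null_sd": res.null_sd,
            "z": res.z,
            "p_value": res.p_value,
            "n_null": res.n_null,
            "significant": bool(res.p_value <= 0.05),
        },
        out / "nullmodels" / "nestedness.json",
    )

    rc_summary = {}
    for comp in ("detritus", "water", "invertebrate"):
        try:
            pooled = per_island_counts.xs(comp, level="compartment")
        except KeyError:
            continue
        pooled = pooled[pooled.sum(axis=1) > 0]
        pooled = pooled.iloc[: config.rc_max_islands]
        if len(pooled) < 2:
            continue
        from .core import CountTable

        tbl = CountTable(pooled.to_numpy(), list(pooled.index), list(pooled.columns))
        rc = null_mod.rc_bray(tbl, reps=config.rc_reps, seed=rng)
        frame = pd.DataFrame(rc.values, index=rc.ids, columns=rc.ids)
        _write_tsv(frame, out / "nullmodels" / f"rc_bray_{comp}.tsv", index=True)
        rc_summary[comp] = {
            "n_islands": len(rc.ids),
            "reps": rc.reps,
            "fraction_above_0.95": float((rc.condensed() > 0.95).mean()),
            "fraction_below_-0.95": float((rc.condensed() < -0.95).mean()),
        }
    _write_json(rc_summary, out / "nullmodels" / "rc_bray_summary.json")


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the configured stages; returns the output directory.

    A stage failure aborts the run with the stage name; outputs of earlier
    stages are retained.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle, truth = _load_bundle(config, out)

    cfg_dict = config.to_dict()
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True, default=_jsonable).encode()
    ).hexdigest()
    manifest = {
        "islesar_version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_sha256": cfg_hash,
        "stages": list(config.stages),
        "report_schema": 1,
    }
    _write_json(manifest, out / "manifest.json")

    per_island = None
    pooled = None
    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        rng = stage_rng(config.seed, stage)
        try:
            if stage == "qc":
                bundle = _stage_qc(bundle, config, out)
            elif stage == "diversity":
                per_island = _stage_diversity(bundle, config, out)["per_island"]
            elif stage == "sar":
                if per_island is None:
                    per_island = _stage_diversity(bundle, config, out)["per_island"]
                _stage_sar(per_island, bundle, config, out, rng)
            elif stage == "envmodel":
                if per_island is None:
                    per_island = _stage_diversity(bundle, config, out)["per_island"]
                _stage_envmodel(per_island, bundle, config, out)
            elif stage == "beta":
                pooled = div_mod.pooled_counts(bundle.table, bundle.samples)
                _stage_beta(pooled, bundle, config, out, rng)
            elif stage == "nullmodels":
                if pooled is None:
                    pooled = div_mod.pooled_counts(bundle.table, bundle.samples)
                _stage_nullmodels(pooled, bundle, config, out, rng)
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc

    if truth is not None and per_island is not None and "sar" in config.stages:
        fits = pd.read_csv(out / "sar" / "sar_fits.tsv", sep="\t")
        comp_z = truth["sar_exponent_by_compartment"]
        rows = []
        for _, r in fits.iterrows():
            rows.append(
                {
                    "compartment": r["compartment"],
                    "size_field": r["size_field"],
                    "fitted_slope": r["slope"],
                    "true_z": comp_z.get(r["compartment"]),
                }
            )
        _write_json({"sar": rows}, out / "truth_vs_fit.json")
    return out
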
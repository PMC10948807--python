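"""End-to-end orchestration: simulate/load -> filter -> dissimilarity ->
lineages -> detection -> classification -> pair enumeration -> effects.

One global seed deterministically derives a seed per stage (stage-name
hashing), so identical configs yield identical summaries and any stage can
be reproduced in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FilterConfig, SimulationConfig
from .dissimilarity import (
    NoAntimodeError,
    NoReplicatesError,
    call_clonal_lineages,
    detect_antimode,
    pairwise_dissimilarity,
    replicate_dissimilarity,
)
from .effects import differing_snps, effect_table, go_weighting, occurrence_spectrum, summarise_effects
from .genotypes import apply_filters, collapse_replicates, load_meta, load_vcf
from .igv import (
    association_test,
    classify_colonies,
    colony_max_distance,
    enumerate_intra_colonial_pairs,
    evaluate_filter_grid,
    igv_curve,
    surface_correlation,
)
from .simulate import simulate_dataset, write_dataset

log = logging.getLogger("coraligv")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.blake2s(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2 ** 31)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    out_dir: str
    simulate: SimulationConfig | None = None
    vcf: str | None = None
    meta: str | None = None
    gff: str | None = None
    fasta: str | None = None
    gene2go: str | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    grid: list[FilterConfig] | None = None
    seed: int = 0
    antimode_bin_width: float = 0.25
    min_go_count: int = 50
    write_simulated: bool = True
    log_level: str = "INFO"

    def validate(self) -> None:
        if (self.simulate is None) == (self.vcf is None):
            raise ValueError("provide exactly one of 'simulate' config or 'vcf' path")
        if self.vcf is not None and self.meta is None:
            raise ValueError("'meta' path required with 'vcf'")
        self.filters.validate()
        if self.simulate is not None:
            self.simulate.validate()

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "simulate" in raw and raw["simulate"] is not None:
            raw["simulate"] = SimulationConfig.from_dict(raw["simulate"])
        if "filters" in raw and isinstance(raw["filters"], dict):
            raw["filters"] = FilterConfig(**raw["filters"])
        if raw.get("grid"):
            raw["grid"] = [FilterConfig(**g) for g in raw["grid"]]
        cfg = cls(**raw)
        cfg.validate()
        return cfg


@dataclass
class RunReport:
    summary: dict
    paths: dict[str, str]
    classification: object = None
    dissimilarity: object = None


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage and write per-stage outputs plus a summary."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = config.out_dir
    os.makedirs(out, exist_ok=True)
    paths: dict[str, str] = {}
    summary: dict = {"seed": config.seed}

    def _path(name: str) -> str:
        paths[name] = os.path.join(out, name)
        return paths[name]

    # ---- stage: input -----------------------------------------------------
    stage = "input"
    try:
        gene2go = None
        annotation = None
        if config.simulate is not None:
            sim_cfg = config.simulate
            if sim_cfg.seed == 0 and config.seed != 0:
                from dataclasses import replace
                sim_cfg = replace(sim_cfg, seed=stage_seed(config.seed, "simulate"))
            dataset = simulate_dataset(sim_cfg)
            if config.write_simulated:
                data_dir = os.path.join(out, "dataset")
                paths.update(write_dataset(dataset, data_dir))
            gm, meta = dataset.genotypes, dataset.meta
            annotation, gene2go = dataset.annotation, dataset.gene2go
            summary["truth_categories"] = dataset.truth.category_counts()
            truth = dataset.truth
        else:
            gm = load_vcf(config.vcf)
            meta = load_meta(config.meta)
            truth = None
            if config.gff and config.fasta:
                from .annotation import load_annotation
                annotation = load_annotation(config.gff, config.fasta)
            if config.gene2go:
                gene2go = pd.read_csv(config.gene2go, sep="\t")
        log.info("input: %d samples x %d sites", gm.n_samples, gm.n_sites)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- stage: filter ----------------------------------------------------
    stage = "filter"
    try:
        report: dict = {}
        filtered = apply_filters(gm, config.filters, report=report)
        summary["n_snp"] = filtered.n_sites
        summary["filter_report"] = report
        log.info("filter: %d sites retained", filtered.n_sites)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- stage: dissimilarity --------------------------------------------
    stage = "dissimilarity"
    try:
        D = pairwise_dissimilarity(filtered)
        D.to_long().to_csv(_path("pairs.tsv"), sep="\t", index=False)
        try:
            rep = replicate_dissimilarity(D, meta)
            summary["delta_rep"] = rep.delta_rep
            summary["delta_rep_se"] = rep.se
        except NoReplicatesError:
            summary["delta_rep"] = None
            summary["delta_rep_se"] = None
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- stage: lineages --------------------------------------------------
    stage = "lineages"
    try:
        collapsed_meta = collapse_replicates(meta)
        Dc = D.subset([s for s in D.sample_ids
                       if s in set(collapsed_meta["sample_id"])])
        vals = Dc.condensed()
        vals = vals[np.isfinite(vals)]
        try:
            clone_gap = detect_antimode(vals, bin_width=config.antimode_bin_width,
                                        which="first")
            clone_threshold = clone_gap.midpoint
        except NoAntimodeError:
            clone_gap = None
            clone_threshold = 1.0
            log.warning("no antimode in pairwise distribution; clone threshold 1.0%%")
        lineages = call_clonal_lineages(Dc, clone_threshold)
        lineages.rename_axis("sample_id").reset_index().to_csv(
            _path("lineages.tsv"), sep="\t", index=False)
        summary["clone_threshold"] = clone_threshold
        summary["n_lineages"] = int(lineages.nunique())
        lin_by_colony = collapsed_meta.merge(
            lineages.rename("lineage").rename_axis("sample_id").reset_index(),
            on="sample_id")
        multi = (lin_by_colony.groupby("colony_id")["lineage"].nunique() > 1)
        multi_lineage_colonies = sorted(multi[multi].index)
        summary["n_multi_lineage_colonies"] = len(multi_lineage_colonies)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- stage: filter grid (optional) -----------------------------------
    if config.grid:
        stage = "filter_grid"
        try:
            grid_df = evaluate_filter_grid(gm, meta, config.grid,
                                           drop_chimeric_nubbins=multi_lineage_colonies)
            grid_df.to_csv(_path("filter_grid.tsv"), sep="\t", index=False)
            summary["grid_rows"] = len(grid_df)
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

    # ---- stage: detection -------------------------------------------------
    stage = "detection"
    try:
        from .igv import detect_igv_threshold

        t_err, fit, _gap = detect_igv_threshold(
            vals, bin_width=config.antimode_bin_width,
            seed=stage_seed(config.seed, "gmm"))
        fit_bound = _gap.lower
        summary["gmm"] = {
            "weights": fit.weights, "means": fit.means, "sds": fit.sds,
            "n_points": fit.n_points, "fit_upper_bound": fit_bound,
            "intersection": t_err,
            "intersection_between_means": fit.intersection_between_means,
        }
        summary["t_err"] = t_err
        with open(_path("gmm_report.json"), "w") as fh:
            json.dump(summary["gmm"], fh, indent=2, default=_json_default)
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- stage: classification -------------------------------------------
    stage = "classification"
    try:
        maxima = colony_max_distance(D, meta)
        curve = igv_curve(maxima["max_percent_diff"])
        curve.as_frame().to_csv(_path("igv_curve.tsv"), sep="\t", index=False)
        summary["t50"] = curve.t50
        classification = classify_colonies(
            maxima, t_err, pairwise_values=vals,
            bin_width=config.antimode_bin_width)
        classification.table.to_csv(_path("classification.tsv"), sep="\t", index=False)
        summary["colony_categories"] = classification.counts()
        gap = classification.chimera_gap
        summary["chimera_gap"] = None if gap is None else [gap.lower, gap.upper]
        log.info("classification: %s", summary["colony_categories"])
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- stage: pairs and tests ------------------------------------------
    stage = "pair_enumeration"
    try:
        pair_set = enumerate_intra_colonial_pairs(classification, D, meta)
        pair_set.to_csv(_path("pair_enumeration.tsv"), sep="\t", index=False)
        summary["n_chimeric_pairs"] = int((pair_set["pair_type"] == "chimeric").sum())
        summary["n_mosaic_pairs"] = int((pair_set["pair_type"] == "mosaic").sum())

        tests: dict = {}
        for grouping in ("site_label", "species_group"):
            try:
                res = association_test(classification, meta, grouping,
                                       seed=stage_seed(config.seed, f"fisher:{grouping}"))
                tests[grouping] = {"p": res.p_value, "method": res.method}
            except ValueError as exc:
                tests[grouping] = {"p": None, "note": str(exc)}
        for label, ptype in (("chimeric", "chimeric"), ("mosaic", "mosaic")):
            sub = pair_set[pair_set["pair_type"] == ptype]
            try:
                r2, p = surface_correlation(meta, D, sub)
                tests[f"surface_{label}"] = {"r_squared": r2, "p": p}
            except ValueError as exc:
                tests[f"surface_{label}"] = {"r_squared": None, "note": str(exc)}
        summary["tests"] = tests
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    # ---- stage: characterisation -----------------------------------------
    stage = "characterisation"
    try:
        if annotation is not None:
            eff_summaries = {}
            for ptype in ("chimeric", "mosaic"):
                sub = pair_set[pair_set["pair_type"] == ptype]
                diffs = differing_snps(filtered, sub)
                effs = effect_table(filtered, diffs, annotation)
                effs.to_csv(_path(f"effects_{ptype}.tsv"), sep="\t", index=False)
                occurrence_spectrum(diffs).to_csv(
                    _path(f"occurrence_{ptype}.tsv"), sep="\t", index=False)
                eff_summaries[ptype] = summarise_effects(effs)
                if gene2go is not None and not effs.empty:
                    go = go_weighting(effs, gene2go, min_count=config.min_go_count)
                    go.to_csv(_path(f"go_weights_{ptype}.tsv"), sep="\t", index=False)
                    go[go["retained"]][["go_id", "weight"]].to_csv(
                        _path(f"go_revigo_{ptype}.tsv"), sep="\t",
                        index=False, header=False)
            summary["effects"] = eff_summaries
        else:
            summary["effects"] = None
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc

    with open(_path("summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=_json_default, sort_keys=True)
    flat = pd.json_normalize(summary, sep=".").T.reset_index()
    flat.columns = ["key", "value"]
    flat.to_csv(_path("summary.tsv"), sep="\t", index=False)
    return RunReport(summary=summary, paths=paths,
                     classification=classification, dissimilarity=D)
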
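"""End-to-end orchestration: simulate/load -> calibrate -> call -> annotate ->
differential -> SELECT, with per-stage logging and a machine-readable summary.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .benchmark import (
    GridSpec,
    ThresholdSet,
    apply_thresholds,
    classify_known_sites,
    detection_summary,
    grid_search,
    landscape_frame,
    outcomes_frame,
)
from .differential import (
    compare_conditions,
    compute_delta_esb,
    delta_frame,
    ms_correlation,
    shared_frame,
)
from .io_formats import (
    MOD_SYMBOLS,
    SiteRecord,
    read_assay_tables,
    read_gene_models,
    read_known_sites,
    read_site_table,
)
from .regions import (
    annotate_regions,
    biotype_proportions,
    merge_regions,
    metagene_positions,
    write_metagene_table,
    write_regions_bed,
)
from .select_qpcr import select_classify, select_frame
from .synthetic import SimConfig, simulate_all, write_simulation

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs, thresholds/grid and knobs for one pipeline run.

    Exactly one of ``thresholds`` / ``grid`` drives the thresholding stage;
    a grid triggers the calibration search, a fixed set skips it.
    """

    out_dir: str | Path = "modcal_out"
    seed: int = 0
    simulate: bool = True
    sim: SimConfig | None = None
    # input paths (ignored when simulate=True)
    sites_a_path: str | None = None
    sites_b_path: str | None = None
    known_path: str | None = None
    gff_path: str | None = None
    utr_bed_path: str | None = None
    ms_path: str | None = None
    ct_path: str | None = None
    site_dialect: str = "modcal"
    # analysis knobs
    thresholds: ThresholdSet | None = None
    grid: GridSpec | None = field(default_factory=GridSpec)
    min_depth: int = 20
    tolerance: int = 10
    precision_floor: float = 0.85
    offset_window: int = 10
    condition_a: str = "37C"
    condition_b: str = "45C"
    select_ref: str = "IVT"

    def __post_init__(self) -> None:
        if (self.thresholds is None) == (self.grid is None):
            raise ValueError("exactly one of thresholds / grid must be supplied")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a flat key-value config file."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        threshold_keys = {"esb_test_min", "esb_control_max", "oddr_min", "padj_max"}
        if threshold_keys & raw.keys():
            missing = threshold_keys - raw.keys()
            if missing:
                raise ValueError(f"incomplete threshold set in config: missing {missing}")
            kwargs["thresholds"] = ThresholdSet(
                **{k: float(raw.pop(k)) for k in threshold_keys}
            )
            kwargs["grid"] = None
        for key in ("out_dir", "seed", "simulate", "sites_a_path", "sites_b_path",
                    "known_path", "gff_path", "utr_bed_path", "ms_path", "ct_path",
                    "site_dialect", "min_depth", "tolerance", "precision_floor",
                    "offset_window", "condition_a", "condition_b", "select_ref"):
            if key in raw:
                kwargs[key] = raw.pop(key)
        sim_keys = {k: v for k, v in raw.items() if k.startswith("sim_")}
        if sim_keys:
            kwargs["sim"] = SimConfig(
                **{k[len("sim_"):]: v for k, v in sim_keys.items()}
            )
        return cls(**kwargs)


def depth_by_molecule(sites: Sequence[SiteRecord]) -> dict[str, int]:
    """Per-molecule read depth (maximum per-position depth reported)."""
    depths: dict[str, int] = {}
    for s in sites:
        if s.depth > depths.get(s.molecule_id, -1):
            depths[s.molecule_id] = s.depth
    return depths


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full chain and write every intermediate table plus a
    ``summary.json``; any stage failure aborts with a stage-named error and
    partial outputs are retained."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("modcal")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> Path:
    logger.info(
        "modcal %s | numpy %s | pandas %s | seed %d",
        __version__, np.__version__, pd.__version__, config.seed,
    )
    logger.info("config: %s", config)
    summary: dict = {"version": __version__, "seed": config.seed}

    # --- inputs -----------------------------------------------------------
    @_stage("simulate")
    def stage_simulate():
        sim_cfg = config.sim or SimConfig(seed=config.seed)
        result = simulate_all(sim_cfg)
        write_simulation(result, out / "inputs")
        return result

    @_stage("load")
    def stage_load():
        sites_a = read_site_table(config.sites_a_path, config.site_dialect)
        sites_b = read_site_table(config.sites_b_path, config.site_dialect)
        known = read_known_sites(config.known_path)
        models = read_gene_models(config.gff_path, config.utr_bed_path)
        ms, ct = read_assay_tables(config.ms_path, config.ct_path)
        return sites_a, sites_b, known, models, ms, ct

    if config.simulate:
        sim = stage_simulate()
        sites_a, sites_b = sim.sites_a, sim.sites_b
        known = sim.truth.known_sites
        models = sim.truth.models
        ms, ct = sim.ms, sim.ct
        depths_a, depths_b = dict(sim.truth.depth_a), dict(sim.truth.depth_b)
    else:
        sites_a, sites_b, known, models, ms, ct = stage_load()
        depths_a = depth_by_molecule(sites_a)
        depths_b = depth_by_molecule(sites_b)

    # --- threshold calibration on the tRNA/rRNA benchmark set -------------
    @_stage("benchmark")
    def stage_benchmark():
        bench_mols = {m.molecule_id for m in models if m.biotype in ("tRNA", "rRNA")}
        bench_sites = [s for s in sites_a if s.molecule_id in bench_mols]
        best, landscape = grid_search(
            bench_sites, known, config.grid,
            precision_floor=config.precision_floor, tolerance=config.tolerance,
        )
        landscape_frame(landscape).to_csv(out / "pr_landscape.tsv", sep="\t",
                                          index=False)
        return best, landscape

    if config.grid is not None:
        best, landscape = stage_benchmark()
        if best is None:
            raise RuntimeError(
                "stage 'benchmark' failed: no threshold combination reaches "
                f"the precision floor {config.precision_floor}"
            )
        thresholds = best
        feasible = [
            p for p in landscape
            if not math.isnan(p.precision) and p.precision >= config.precision_floor
        ]
        chosen = [p for p in landscape if p.thresholds == best][0]
        summary["calibration"] = {
            "selected": vars(best),
            "precision": chosen.precision,
            "recall": chosen.recall,
            "combinations": len(landscape),
            "feasible": len(feasible),
        }
    else:
        thresholds = config.thresholds
        summary["calibration"] = {"selected": vars(thresholds), "combinations": 0}

    # --- thresholding ------------------------------------------------------
    @_stage("threshold")
    def stage_threshold():
        called_a = apply_thresholds(sites_a, thresholds)
        called_b = apply_thresholds(sites_b, thresholds)
        for name, called in (("called_a.tsv", called_a), ("called_b.tsv", called_b)):
            pd.DataFrame(sorted(called), columns=["molecule", "position"]).to_csv(
                out / name, sep="\t", index=False
            )
        return called_a, called_b

    called_a, called_b = stage_threshold()
    summary["called"] = {"a": len(called_a), "b": len(called_b)}

    # --- known-site classification -----------------------------------------
    @_stage("classify")
    def stage_classify():
        outcomes = classify_known_sites(
            called_a, known, depths_a, min_depth=config.min_depth,
            offset_window=config.offset_window,
        )
        outcomes_frame(outcomes).to_csv(out / "detection_outcomes.tsv", sep="\t",
                                        index=False)
        return outcomes

    outcomes = stage_classify()
    det = detection_summary(outcomes)
    det["categories"].to_csv(out / "detection_summary.tsv", sep="\t", index=False)
    summary["detection"] = {
        "categories": dict(zip(det["categories"]["category"],
                               [int(c) for c in det["categories"]["count"]])),
        "recall": det["recall"],
    }

    # --- regions and annotation --------------------------------------------
    @_stage("annotate")
    def stage_annotate():
        esb_a = {(s.molecule_id, s.position): s.esb_test for s in sites_a}
        esb_b = {(s.molecule_id, s.position): s.esb_test for s in sites_b}
        regions_a = annotate_regions(merge_regions(called_a, esb_a), models)
        regions_b = annotate_regions(merge_regions(called_b, esb_b), models)
        write_regions_bed(regions_a, out / "regions_a.bed")
        write_regions_bed(regions_b, out / "regions_b.bed")
        novel = {"CDS", "UTR5", "UTR3", "ncRNA", "intergenic"}
        props = {}
        for cond, regs in (("a", regions_a), ("b", regions_b)):
            outside = [r for r in regs if r.biotype in novel]
            df = biotype_proportions(outside) if outside else pd.DataFrame(
                columns=["biotype", "count", "percent"]
            )
            df.to_csv(out / f"biotype_proportions_{cond}.tsv", sep="\t", index=False)
            props[cond] = df
        mrna_regions = [r for r in regions_a if r.biotype in ("UTR5", "CDS", "UTR3")]
        write_metagene_table(metagene_positions(mrna_regions, models),
                             out / "metagene_a.tsv")
        return regions_a, regions_b, props

    regions_a, regions_b, props = stage_annotate()
    summary["biotype_proportions"] = {
        cond: dict(zip(df["biotype"], [float(p) for p in df["percent"]]))
        for cond, df in props.items()
    }
    summary["regions"] = {"a": len(regions_a), "b": len(regions_b)}

    # --- differential -------------------------------------------------------
    @_stage("differential")
    def stage_differential():
        delta = compute_delta_esb(sites_a, sites_b, called_a, called_b)
        delta_frame(delta).to_csv(out / "delta_esb.tsv", sep="\t", index=False)
        biotype_by_site: dict[tuple[str, int], str] = {}
        for regs in (regions_a, regions_b):
            for r in regs:
                for p in range(r.start, r.end + 1):
                    biotype_by_site.setdefault((r.molecule_id, p), r.biotype)
        statuses, shared_summary = compare_conditions(
            called_a, called_b, depths_a, depths_b, min_depth=config.min_depth,
            delta_records=delta, biotype_by_site=biotype_by_site,
        )
        shared_frame(statuses).to_csv(out / "shared_status.tsv", sep="\t", index=False)
        # only types the error-based caller can see belong in the MS pairing
        mod_names = {
            (k.molecule_id, k.position): MOD_SYMBOLS[k.mod_symbol][0]
            for k in known
            if k.mod_symbol in MOD_SYMBOLS and k.detectable is not False
        }
        try:
            rho, pval, paired = ms_correlation(
                delta, ms, mod_names,
                condition_a=config.condition_a, condition_b=config.condition_b,
            )
            paired.to_csv(out / "ms_pairs.tsv", sep="\t", index=False)
            corr = {"rho": rho, "p": pval, "n_types": len(paired)}
        except ValueError as exc:
            logger.warning("MS correlation unavailable: %s", exc)
            corr = {"rho": None, "p": None, "n_types": 0}
        return shared_summary, corr

    shared_summary, corr = stage_differential()
    summary["shared"] = shared_summary
    summary["ms_correlation"] = corr

    # --- SELECT --------------------------------------------------------------
    @_stage("select")
    def stage_select():
        results = select_classify(ct, ref_type=config.select_ref)
        select_frame(results).to_csv(out / "select_results.tsv", sep="\t", index=False)
        return results

    select_results = stage_select()
    summary["select"] = {
        "assays": len(select_results),
        "modified": sum(r.classified_modified for r in select_results),
    }

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    logger.info("pipeline complete: %s", out)
    return out
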
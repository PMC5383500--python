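"""Reproducible end-to-end runs: configuration, staging, outputs, report.

A run executes simulate (optional) → preprocess → pools → scans →
predictions → grid → validation, writing every table as CSV plus a
plain-text report.  All stochastic stages draw from seeds derived
deterministically from the top-level seed, and the configuration is
archived verbatim into the output directory, so re-running a config
reproduces every output byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import inference, simulate as sim
from .distances import NN, SIZE_GRID
from .models import coefficient_table
from .tables import TableError, actual_establishment, build_habitat_pool, preprocess_traits, read_tables

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "pools", "scan", "predict", "grid", "validate", "report")


class StageError(RuntimeError):
    """An error tagged with the pipeline stage that raised it."""

    def __init__(self, stage, exc):
        super().__init__(f"[{stage}] {exc}")
        self.stage = stage


@dataclass
class RunConfig:
    """Everything needed to reproduce a run."""

    seed: int = 0
    outdir: str = "run"
    simulation: sim.SimulationConfig | None = None
    inputs: dict | None = None            # paths: traits, regional, occurrences, ...
    trait_kinds: dict = field(default_factory=dict)
    log_traits: tuple = ()
    sizes: tuple = SIZE_GRID
    schemes: tuple = ("none",)
    basis: str = "per-trait"
    subset: str = "all"                   # "all" | "native"
    min_sites: int = 2
    focal_site: str | None = None
    re_prediction: str = "plot"
    n_quad: int = 15
    verbosity: int = 1

    def __post_init__(self):
        if self.simulation is None and not self.inputs:
            raise TableError("config needs either a simulation block or input paths")
        if self.inputs and "traits" in self.inputs and not self.trait_kinds:
            # kinds default to continuous inside read_tables; explicit list not forced
            pass
        if self.subset not in ("all", "native"):
            raise TableError(f"unknown subset {self.subset!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "simulation" in raw and raw["simulation"] is not None:
            simraw = dict(raw["simulation"])
            for key in ("env_optimum", "biotic_mode"):
                if key in simraw:
                    simraw[key] = tuple(simraw[key])
            raw["simulation"] = sim.SimulationConfig(**simraw)
        for key in ("sizes", "schemes", "log_traits"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        if "sizes" in raw:
            raw["sizes"] = tuple(
                NN if (isinstance(s, str) and s.lower() == "nn") else float(s)
                for s in raw["sizes"]
            )
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        if self.simulation is not None:
            data["simulation"] = dataclasses.asdict(self.simulation)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


def _size_label(s):
    return "NN" if s == NN else s


def run(config: RunConfig, until: str = "report") -> Path:
    """Execute the pipeline, stopping after stage ``until``; returns the
    run directory.  Partial outputs are preserved on failure."""
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    log_lines = []

    def checkpoint(stage, t0):
        log_lines.append(f"{stage}: {time.perf_counter() - t0:.2f}s")
        (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
        return STAGES.index(stage) >= STAGES.index(until)

    stage = "simulate"
    try:
        t0 = time.perf_counter()
        if config.simulation is not None:
            assembly = sim.simulate_assembly(config.simulation, config.seed)
            sim.write_csvs(assembly, outdir / "data")
            traits = assembly.traits
            pool = assembly.pool
            community = assembly.community
            colonists = assembly.colonists
            focal_site = pool.focal_site
        else:
            assembly = None
        if checkpoint(stage, t0):
            return outdir

        stage = "preprocess"
        t0 = time.perf_counter()
        if assembly is None:
            paths = dict(config.inputs)
            raw_traits, regional, occ, community, colonists, report = read_tables(
                paths["traits"], paths["regional"], paths["occurrences"],
                paths.get("community"), paths.get("colonists"),
                trait_kinds=config.trait_kinds or None,
                log_traits=config.log_traits,
            )
            traits = preprocess_traits(raw_traits, config.log_traits,
                                       modeling_species=regional)
        if checkpoint(stage, t0):
            return outdir

        stage = "pools"
        t0 = time.perf_counter()
        if assembly is None:
            focal_site = config.focal_site or occ.sites[0]
            pool = build_habitat_pool(occ, regional, focal_site,
                                      min_sites=config.min_sites)
            # in field data the focal occupancy list and the plot records may
            # differ; plot species absent from the pool are reported
            stray = set(community.records["species_id"]) - set(pool.pool_species)
            if stray:
                logger.warning("%d community species outside the pool", len(stray))
        pool.table.to_csv(outdir / "pools.csv")
        if checkpoint(stage, t0):
            return outdir

        stage = "scan"
        t0 = time.perf_counter()
        kinds = traits.kinds if hasattr(traits, "kinds") else {}
        env_scan = inference.scan_env(
            pool, traits.values, sizes=config.sizes, schemes=config.schemes,
            basis=config.basis, trait_kinds=kinds,
        )
        biotic_scan = inference.scan_biotic(
            pool, community, traits.values, sizes=config.sizes,
            schemes=config.schemes, basis=config.basis, n_quad=config.n_quad,
        )
        scan_table = pd.concat(
            [env_scan.table.assign(filter="environmental"),
             biotic_scan.table.assign(filter="biotic")],
            ignore_index=True,
        )[["filter", "size", "scheme", "aicc", "delta_aicc", "converged",
           "degenerate", "selected"]]
        scan_table.to_csv(outdir / "scan.csv", index=False)
        models_blob = {
            "environmental": env_scan.selected_model.to_dict(),
            "biotic": biotic_scan.selected_model.to_dict(),
        }
        (outdir / "models.json").write_text(json.dumps(models_blob, indent=2))
        coefficient_table({
            f"env {_size_label(env_scan.selected[0])}/{env_scan.selected[1]}":
                env_scan.selected_model,
            f"biotic {_size_label(biotic_scan.selected[0])}/{biotic_scan.selected[1]}":
                biotic_scan.selected_model,
        }).to_csv(outdir / "coefficients.csv")
        if checkpoint(stage, t0):
            return outdir

        stage = "predict"
        t0 = time.perf_counter()
        colonist_species = colonists.species
        predictions = inference.predict_establishment(
            env_scan.selected_model, biotic_scan.selected_model,
            pool, traits.values, community, colonist_species,
            center=biotic_scan.center, basis=config.basis,
            re_prediction=config.re_prediction,
            site_id=community.records["site_id"].iloc[0],
        )
        predictions.to_csv(outdir / "predictions.csv", index=False)
        if checkpoint(stage, t0):
            return outdir

        stage = "grid"
        t0 = time.perf_counter()
        actual = actual_establishment(colonists)
        sites = colonists.records.groupby("species_id")["site_id"].first()
        subset_species = colonists.native_species() if config.subset == "native" else None
        rows = []
        for scheme in config.schemes:
            grid = inference.prediction_grid(
                env_scan, biotic_scan, pool, traits.values, community,
                colonist_species, actual, sites, scheme=scheme,
                subset_species=subset_species, subset_label=config.subset,
                basis=config.basis, re_prediction=config.re_prediction,
                site_id=community.records["site_id"].iloc[0],
            )
            long = grid.stack(future_stack=True).rename("adj_r2").reset_index()
            long.insert(2, "scheme", scheme)
            long.insert(3, "subset", config.subset)
            rows.append(long)
        grid_long = pd.concat(rows, ignore_index=True)
        grid_long.to_csv(outdir / "grid.csv", index=False)
        if checkpoint(stage, t0):
            return outdir

        stage = "validate"
        t0 = time.perf_counter()
        pred = predictions.set_index("species_id")["p_overall"]
        results = {}
        results["all"] = inference.validate(pred, actual, sites, subset_label="all")
        natives = colonists.native_species()
        if 2 < len(natives) < len(colonist_species):
            results["native_only"] = inference.validate(
                pred, actual, sites, subset_species=natives,
                subset_label="native_only",
            )
        (outdir / "validation.json").write_text(
            json.dumps({k: dataclasses.asdict(v) for k, v in results.items()}, indent=2)
        )
        if checkpoint(stage, t0):
            return outdir

        stage = "report"
        t0 = time.perf_counter()
        (outdir / "report.txt").write_text(make_report(outdir))
        checkpoint(stage, t0)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc
    return outdir


def make_report(rundir) -> str:
    """Human-readable run summary: selected models, ΔAICc ranking,
    coefficient table and validation statistics."""
    rundir = Path(rundir)
    if not rundir.is_dir() or not (rundir / "config.yaml").exists():
        raise TableError(f"{rundir} is not a run directory")
    lines = ["darkneighbors run report", "=" * 40, ""]
    partial = False

    scan_path = rundir / "scan.csv"
    if scan_path.exists():
        scan = pd.read_csv(scan_path)
        for filt in ("environmental", "biotic"):
            sub = scan[scan["filter"] == filt]
            lines.append(f"{filt} filter: {len(sub)} candidate model(s)")
            sel = sub[sub["selected"] == True]  # noqa: E712
            if len(sel):
                row = sel.iloc[0]
                lines.append(
                    f"  selected: size={row['size']} scheme={row['scheme']} "
                    f"AICc={row['aicc']:.2f}"
                )
            degen = sub[sub["degenerate"].notna() & (sub["degenerate"] != "")]
            for _, row in degen.iterrows():
                lines.append(
                    f"  flags size={row['size']} scheme={row['scheme']}: "
                    f"{row['degenerate']}"
                )
            lines.append("  dAICc ranking (best first):")
            for _, row in sub.sort_values("aicc").head(12).iterrows():
                lines.append(
                    f"    size={row['size']:>4} scheme={row['scheme']:<13} "
                    f"dAICc={row['delta_aicc']:+.2f}"
                )
            lines.append("")
    else:
        partial = True

    coef_path = rundir / "coefficients.csv"
    if coef_path.exists():
        lines.append("standardized coefficients (selected models):")
        lines.append(pd.read_csv(coef_path, index_col=0).round(3).to_string())
        lines.append("")
    else:
        partial = True

    val_path = rundir / "validation.json"
    if val_path.exists():
        results = json.loads(val_path.read_text())
        for label, res in results.items():
            lines.append(
                f"validation ({label}): slope={res['slope']:.3f} "
                f"t={res['slope_t']:.2f} p={res['slope_p']:.4g} "
                f"adj R2={res['adj_r2']:.3f} n={res['n']}"
            )
            if res.get("note"):
                lines.append(f"  note: {res['note']}")
        lines.append("")
    else:
        partial = True

    grid_path = rundir / "grid.csv"
    if grid_path.exists():
        grid = pd.read_csv(grid_path)
        best = grid.loc[grid["adj_r2"].idxmax()] if grid["adj_r2"].notna().any() else None
        if best is not None:
            lines.append(
                f"grid maximum adj R2={best['adj_r2']:.3f} at env={best['env_size']} "
                f"biotic={best['biotic_size']} ({best['scheme']}, {best['subset']})"
            )
    else:
        partial = True

    if partial:
        lines.append("")
        lines.append("NOTE: incomplete run; some sections are missing.")
    return "\n".join(lines) + "\n"
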
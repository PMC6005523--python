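"""End-to-end orchestration of the seasonal diet analysis.

One config drives the whole workflow: load (or simulate) a stomach table,
tally the sampling design, test the empty-stomach pattern, contrast wet vs
dry diets (ANOSIM + SIMPER), estimate per-season diet breadth with the
dispersion test, ordinate with NMDS, and test pairwise dietary overlap
against the bootstrap null.  Every stage writes a CSV; a JSON manifest
records outputs, stage seeds and wall times.

Seeding: a single top-level seed; stage i uses ``seed + 1000 * i`` (stages
are numbered in execution order), so any stage can be re-run in isolation
with the same randomness.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_data import (
    StomachTable,
    build_community_matrix,
    empty_stomach_counts,
    empty_stomach_summary,
    read_stomach_table,
    tally_by,
)
from .dissimilarity import bray_curtis
from .dispersion import dispersion_by_season
from .group_tests import GroupLabels, anosim, chi_square_independence, simper
from .ordination import nmds
from .overlap import overlap_summary
from .simulate import SimConfig, generate

__all__ = ["RunConfig", "run_pipeline", "STAGES"]

STAGES = ("tallies", "empty_chisq", "anosim", "simper", "dispersion", "nmds",
          "overlap")


@dataclass
class RunConfig:
    """Configuration of one full pipeline run.

    Exactly one of ``input_path`` / ``sim`` must be set.  ``season_pair``
    is the two-season contrast for ANOSIM/SIMPER (wet vs dry by default:
    the full six-pair sweep would demand multiplicity adjustments).
    """

    seed: int
    output_dir: str | Path
    input_path: str | Path | None = None
    sim: SimConfig | None = None
    stages: tuple[str, ...] = STAGES
    anosim_level: str = "item"
    simper_level: str = "category"
    dispersion_level: str = "item"
    overlap_level: str = "item"
    season_pair: tuple[str, str] = ("wet", "dry")
    n_perm: int = 1000
    n_boot: int = 1000
    nmds_k: int = 2
    nmds_starts: int = 20

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.sim is None):
            raise ValueError("exactly one of input_path / sim must be given")
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "sim" in raw and raw["sim"] is not None:
            sim = raw.pop("sim")
            if "seasons" in sim:
                sim["seasons"] = tuple(sim["seasons"])
            if "category_sizes" in sim:
                sim["category_sizes"] = tuple(sim["category_sizes"])
            raw["sim"] = SimConfig(**sim)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "season_pair" in raw:
            raw["season_pair"] = tuple(raw["season_pair"])
        return cls(**raw)


def _stage_seed(seed: int, stage: str) -> int:
    return (seed + 1000 * STAGES.index(stage)) % (2**31)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages; return (and write) the run manifest.

    A stage failure aborts the run with the stage name and cause; outputs
    already written are listed in the manifest as partial.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "outputs": [],
        "partial": False,
    }

    if config.input_path is not None:
        table = read_stomach_table(config.input_path)
        manifest["input"] = str(config.input_path)
    else:
        table, _truth = generate(config.sim)
        manifest["input"] = f"simulated (sim seed {config.sim.seed})"

    def record(stage: str, seed: int, t0: float, paths: list[Path], extra=None):
        entry = {
            "seed": seed,
            "wall_time_s": round(time.perf_counter() - t0, 3),
            "outputs": [str(p) for p in paths],
        }
        if extra:
            entry["summary"] = extra
        manifest["stages"][stage] = entry
        manifest["outputs"] += [str(p) for p in paths]
        log_lines.append(
            f"{stage}: {entry['wall_time_s']}s seed={seed} -> "
            + ", ".join(p.name for p in paths)
        )

    current = "setup"
    try:
        if "tallies" in config.stages:
            current = "tallies"
            t0 = time.perf_counter()
            loc = tally_by(table, "species", "location").to_frame()
            sea = tally_by(table, "species", "season").to_frame()
            p = outdir / "table1.csv"
            combined = pd.concat({"locations": loc, "seasons": sea}, axis=1)
            combined.to_csv(p)
            record(current, _stage_seed(config.seed, current), t0, [p],
                   {"total_specimens": int(loc.values.sum())})

        if "empty_chisq" in config.stages:
            current = "empty_chisq"
            t0 = time.perf_counter()
            prop = empty_stomach_summary(table)
            p1 = outdir / "empty_stomach.csv"
            prop.to_csv(p1)
            res = chi_square_independence(empty_stomach_counts(table))
            p2 = outdir / "empty_chisq.csv"
            res.summary().to_csv(p2, index=False)
            record(current, _stage_seed(config.seed, current), t0, [p1, p2],
                   {"chi2": res.statistic, "df": res.df, "p": res.p_value})

        wetdry = None
        if {"anosim", "simper"} & set(config.stages):
            keep = set(config.season_pair)
            recs = [r for r in table.records if r.season in keep]
            wetdry = StomachTable(recs, table.item_vocabulary,
                                  table.category_map, table.seasons)

        if "anosim" in config.stages:
            current = "anosim"
            t0 = time.perf_counter()
            rows = []
            sseed = _stage_seed(config.seed, current)
            for si, sp in enumerate(table.species_levels):
                sub = StomachTable(
                    [r for r in wetdry.records if r.species == sp],
                    table.item_vocabulary, table.category_map, table.seasons)
                m = build_community_matrix(sub, level=config.anosim_level)
                res = anosim(bray_curtis(m),
                             GroupLabels(m.unit_labels["season"].to_numpy()),
                             n_perm=config.n_perm, seed=sseed + si)
                rows.append({"species": sp, "R": res.R, "p_value": res.p_value,
                             "n_perm": res.n_perm, "seed": res.seed})
            p = outdir / "anosim.csv"
            pd.DataFrame(rows).to_csv(p, index=False)
            record(current, sseed, t0, [p])

        if "simper" in config.stages:
            current = "simper"
            t0 = time.perf_counter()
            frames = []
            sseed = _stage_seed(config.seed, current)
            for si, sp in enumerate(table.species_levels):
                sub = StomachTable(
                    [r for r in wetdry.records if r.species == sp],
                    table.item_vocabulary, table.category_map, table.seasons)
                m = build_community_matrix(sub, level=config.simper_level)
                res = simper(m, GroupLabels(m.unit_labels["season"].to_numpy()),
                             n_perm=config.n_perm, seed=sseed + si)
                df = res.to_frame()
                df.insert(0, "species", sp)
                frames.append(df)
            p = outdir / "simper.csv"
            pd.concat(frames, ignore_index=True).to_csv(p, index=False)
            record(current, sseed, t0, [p])

        if "dispersion" in config.stages:
            current = "dispersion"
            t0 = time.perf_counter()
            sseed = _stage_seed(config.seed, current)
            breadth, _ = dispersion_by_season(
                table, level=config.dispersion_level,
                n_perm=config.n_perm, seed=sseed)
            p = outdir / "dispersion.csv"
            breadth.to_csv(p, index=False)
            record(current, sseed, t0, [p])

        if "nmds" in config.stages:
            current = "nmds"
            t0 = time.perf_counter()
            sseed = _stage_seed(config.seed, current)
            m = build_community_matrix(table, level="item")
            res = nmds(bray_curtis(m), k=config.nmds_k,
                       n_starts=config.nmds_starts, seed=sseed)
            p = outdir / "nmds_coords.csv"
            res.to_frame(m.unit_labels).to_csv(p, index=False)
            record(current, sseed, t0, [p],
                   {"stress": res.stress, "converged": res.converged})

        if "overlap" in config.stages:
            current = "overlap"
            t0 = time.perf_counter()
            sseed = _stage_seed(config.seed, current)
            df = overlap_summary(table, n_boot=config.n_boot,
                                 level=config.overlap_level, seed=sseed)
            p = outdir / "overlap.csv"
            df.to_csv(p, index=False)
            record(current, sseed, t0, [p])
    except Exception as exc:
        manifest["partial"] = True
        manifest["failed_stage"] = current
        manifest["error"] = str(exc)
        _write_manifest(outdir, manifest, log_lines)
        raise StageError(current, exc) from exc

    _write_manifest(outdir, manifest, log_lines)
    return manifest


def _write_manifest(outdir: Path, manifest: dict, log_lines: list[str]) -> None:
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
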
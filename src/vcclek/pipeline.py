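"""End-to-end orchestration: load -> filter -> VCC -> aggregate -> spatial.

:func:`run_pipeline` executes the full reconstruction from files on disk and
writes every table, fit and raster together with a manifest (parameter
values, per-stage record counts, SHA-256 digest of every output) sufficient
to reproduce and audit the run.  Any stage error aborts the run and removes
partial outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from vcclek import __version__
from vcclek.sampling_design import load_population_sources, sampling_effort_table
from vcclek.survey_model import (
    DECADES,
    PRE_BASELINE,
    PortRegistry,
    filter_eligible,
    load_interviews,
)
from vcclek.spatial_analysis import (
    GridSpec,
    decadal_distance_summary,
    load_fishing_grounds,
    normalize_surface,
    rasterize_effort,
    vcc_surface,
    write_ascii_grid,
)
from vcclek.vcc_engine import (
    build_trajectories,
    cohort_aggregate,
    driver_frequency_ranking,
    fit_decadal_trend,
    relative_change,
)


@dataclass
class PipelineConfig:
    """Inputs, thresholds and toggles for one reconstruction run."""

    interviews: str | Path
    output_dir: str | Path
    polygons: str | Path | None = None
    ports: str | Path | None = None
    population_sources: str | Path | None = None
    cell_size: float = 0.01
    min_experience: int = 5
    core_threshold: float = 0.6
    baseline_weighting: bool = True
    normalization_mode: str = "symmetric4"   # symmetric4 | minmax_affine
    precision_e: float = 0.10
    seed: int = 0

    def validate(self) -> None:
        for name in ("interviews", "polygons", "ports", "population_sources"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        if not 0.0 < self.core_threshold <= 1.0:
            raise ValueError("core_threshold must lie in (0, 1]")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for diagnostics."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.output_dir)
    fresh = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    manifest: dict = {
        "version": __version__,
        "parameters": {
            k: (str(v) if isinstance(v, Path) else v)
            for k, v in dataclasses.asdict(config).items()
        },
        "stages": {},
    }

    def emit(name: str, path: Path) -> None:
        outputs.append(path)

    try:
        # --- sampling design (optional) ----------------------------------
        if config.population_sources is not None:
            stage = "sampling_design"
            try:
                sources = load_population_sources(config.population_sources)
                table = sampling_effort_table(sources, config.precision_e)
                p = outdir / "sampling_effort.csv"
                table.to_csv(p, index=False)
                emit(stage, p)
                manifest["stages"][stage] = {"villages": len(table)}
            except Exception as exc:
                raise StageError(stage, exc) from exc

        # --- load and filter ----------------------------------------------
        stage = "load_interviews"
        try:
            loaded = load_interviews(config.interviews)
            manifest["stages"][stage] = {
                "rows_loaded": len(loaded.records),
                "rows_rejected": len(loaded.rejections),
                "rejections": [f"line {r.line}: {r.reason}"
                               for r in loaded.rejections[:50]],
            }
        except Exception as exc:
            raise StageError(stage, exc) from exc

        stage = "filter_eligible"
        try:
            filtered = filter_eligible(loaded.records, config.min_experience)
            manifest["stages"][stage] = {
                "retained": len(filtered.retained),
                "removed": filtered.removed,
            }
        except Exception as exc:
            raise StageError(stage, exc) from exc
        records = filtered.retained

        # --- VCC ----------------------------------------------------------
        stage = "vcc"
        try:
            trajectories = build_trajectories(
                records, "overall",
                baseline_weighting=config.baseline_weighting)
            traj_rows = [
                {"fisher_id": t.fisher_id, "stratum": t.stratum,
                 "decade": dec, "vcc": val, "baseline": t.baseline}
                for t in trajectories for dec, val in t.values.items()
            ]
            p = outdir / "trajectories.csv"
            pd.DataFrame(traj_rows).to_csv(p, index=False)
            emit(stage, p)

            agg = cohort_aggregate(trajectories)
            agg_rows = [{"stratum": agg.stratum, "decade": d, "mean": m,
                         "sd": s, "n": n}
                        for d, (m, s, n) in agg.stats.items()]
            p = outdir / "decadal_aggregate.csv"
            pd.DataFrame(agg_rows).to_csv(p, index=False)
            emit(stage, p)

            fit = fit_decadal_trend(agg, include_baseline=True)
            p = outdir / "trend_fit.json"
            with open(p, "w") as fh:
                json.dump({"stratum": agg.stratum,
                           "coefficients": list(fit.coefficients),
                           "domain": list(fit.domain)}, fh, indent=2)
            emit(stage, p)

            changes = []
            seq = [(PRE_BASELINE, 1.0)] + [(d, agg.stats[d][0])
                                           for d in DECADES if d in agg.stats]
            for (d0, v0), (d1, v1) in zip(seq[:-1], seq[1:]):
                changes.append({"from": d0, "to": d1,
                                "relative_change_pct": relative_change(v1, v0)})
            if len(seq) > 2:
                changes.append({"from": seq[0][0], "to": seq[-1][0],
                                "relative_change_pct":
                                    relative_change(seq[-1][1], seq[0][1])})
            p = outdir / "relative_changes.csv"
            pd.DataFrame(changes).to_csv(p, index=False)
            emit(stage, p)

            drivers = driver_frequency_ranking(records)
            p = outdir / "driver_ranking.csv"
            pd.DataFrame(drivers, columns=["driver", "n_fishers"]).to_csv(
                p, index=False)
            emit(stage, p)
            manifest["stages"][stage] = {
                "trajectories": len(trajectories),
                "baseline_weighting": config.baseline_weighting,
                "decadal_means": {d: agg.stats[d][0] for d in agg.stats},
            }
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # --- spatial (optional) -------------------------------------------
        if config.polygons is not None and config.ports is not None:
            stage = "spatial"
            try:
                grounds = load_fishing_grounds(config.polygons)
                ports = PortRegistry.from_csv(config.ports)
                vcc_by_key = {(t.fisher_id, d): v
                              for t in trajectories
                              for d, v in t.values.items()}
                kept = []
                for g in grounds:
                    key = (g.fisher_id, g.decade)
                    if key in vcc_by_key:
                        g.vcc_value = vcc_by_key[key]
                        kept.append(g)
                spec = GridSpec.covering(kept, config.cell_size)

                effort_all = rasterize_effort(kept, spec)
                p = outdir / "effort_all.asc"
                write_ascii_grid(normalize_surface(effort_all, "unit"), p)
                emit(stage, p)
                for dec in DECADES:
                    dec_grounds = [g for g in kept if g.decade == dec]
                    if not dec_grounds:
                        continue
                    eff = normalize_surface(
                        rasterize_effort(dec_grounds, spec), "unit")
                    p = outdir / f"effort_{dec}.asc"
                    write_ascii_grid(eff, p)
                    emit(stage, p)
                    surf = vcc_surface(dec_grounds, spec, dec, normalized=True)
                    p = outdir / f"vcc_{dec}.asc"
                    write_ascii_grid(surf, p)
                    emit(stage, p)

                dist = decadal_distance_summary(kept, ports)
                p = outdir / "distance_summary.csv"
                dist.to_csv(p, index=False)
                emit(stage, p)
                overall = dist[(dist.village == "ALL") & (dist.decade == "all")]
                manifest["stages"][stage] = {
                    "grounds": len(kept),
                    "grounds_without_vcc": len(grounds) - len(kept),
                    "grid": {"n_cols": spec.n_cols, "n_rows": spec.n_rows,
                             "cell_size": spec.cell_size},
                    "overall_mean_distance_km":
                        float(overall.mean_km.iloc[0]),
                }
            except Exception as exc:
                raise StageError(stage, exc) from exc

        manifest["outputs"] = {str(p.relative_to(outdir)): _sha256(p)
                               for p in outputs}
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        return manifest
    except StageError:
        # remove partial outputs; leave pre-existing directories in place
        if fresh:
            shutil.rmtree(outdir, ignore_errors=True)
        else:
            for p in outputs:
                p.unlink(missing_ok=True)
        raise
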
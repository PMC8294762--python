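"""End-to-end orchestration: simulation → DE → shift, plus assay quantifiers.

A run is described by a :class:`RunConfig` (deserializable from YAML with
strict key checking), executes its selected stages in dependency order under
one global seed, writes every artifact into the output directory, and records
a manifest (tool version, config hash, per-stage seeds and files). The global
seed fans out to per-stage seeds through a hash of the stage name, so a
single stage re-run sees the same random stream regardless of stage order.

The default synthetic run mirrors a two-contrast translatome experiment:
contrast A plants a depletion of the target-gene subset (the
mutant-mislocalization condition), contrast B plants no target effect (the
knockout condition); both are tested, compared gene-by-gene via signed
z-scores, and each is subjected to the target-vs-nontarget cumulative-shift
test. Droplet, kinetics and axon stages quantify simulated assay data against
their planted truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from ribodrop import __version__ as _version
from ribodrop import de as de_mod
from ribodrop import droplets as drop_mod
from ribodrop import io, kinetics, puncta, shift, sim
from ribodrop._utils import stage_seed
from ribodrop.errors import ConfigError, RibodropError

logger = logging.getLogger("ribodrop")

ALL_STAGES = ("counts", "de", "shift", "droplets", "kinetics", "axon")


@dataclasses.dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    counts_a: dict = dataclasses.field(default_factory=dict)
    counts_b: dict = dataclasses.field(default_factory=lambda: {"target_log2fc": 0.0})
    de: dict = dataclasses.field(default_factory=dict)
    shift: dict = dataclasses.field(default_factory=dict)
    droplets: dict = dataclasses.field(default_factory=dict)
    kinetics: dict = dataclasses.field(default_factory=dict)
    axon: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigError(f"stages: unknown stage names {sorted(unknown)}")
        self.stages = tuple(self.stages)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["stages"] = list(self.stages)
        return out


def _config_hash(cfg: RunConfig) -> str:
    canonical = json.dumps(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _build(cls, overrides: dict, seed: int):
    try:
        return cls(seed=seed, **overrides)
    except TypeError as exc:
        raise ConfigError(f"{cls.__name__}: {exc}") from exc


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "tool": "ribodrop",
        "version": _version,
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    state: dict[str, Any] = {}
    try:
        for stage in [s for s in ALL_STAGES if s in config.stages]:
            t0 = time.perf_counter()
            seed = stage_seed(config.seed, stage)
            logger.info("stage=%s seed=%d starting", stage, seed)
            files = _STAGE_RUNNERS[stage](config, seed, outdir, state)
            elapsed = time.perf_counter() - t0
            logger.info("stage=%s seed=%d elapsed=%.2fs", stage, seed, elapsed)
            manifest["stages"][stage] = {"seed": seed, "files": files,
                                         "elapsed_s": round(elapsed, 3)}
        manifest["status"] = "ok"
    except RibodropError as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        io.write_json(manifest, outdir / "manifest.json")
        raise RibodropError(f"stage {stage!r} failed: {exc}") from exc
    io.write_json(manifest, outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------


def _run_counts(config: RunConfig, seed: int, outdir: Path, state: dict) -> list[str]:
    files = []
    for tag, overrides in (("a", config.counts_a), ("b", config.counts_b)):
        cfg = _build(sim.SimCountConfig, overrides, stage_seed(seed, f"contrast_{tag}"))
        cm, truth = sim.simulate_counts(cfg)
        state[f"counts_{tag}"], state[f"truth_{tag}"] = cm, truth
        io.write_counts(cm, outdir / f"counts_{tag}.tsv", outdir / f"design_{tag}.tsv")
        io.write_table(truth, outdir / f"truth_{tag}.tsv")
        files += [f"counts_{tag}.tsv", f"design_{tag}.tsv", f"truth_{tag}.tsv"]
    return files


def _run_de(config: RunConfig, seed: int, outdir: Path, state: dict) -> list[str]:
    if "counts_a" not in state:
        raise ConfigError("stages: 'de' requires the 'counts' stage")
    files = []
    for tag in ("a", "b"):
        table = de_mod.nb_wald_test(state[f"counts_{tag}"], **config.de)
        state[f"de_{tag}"] = table
        io.write_table(table, outdir / f"de_{tag}.tsv")
        files.append(f"de_{tag}.tsv")
    comparison = de_mod.compare_contrasts(state["de_a"], state["de_b"])
    state["comparison"] = comparison
    io.write_table(comparison["genes"], outdir / "contrast_genes.tsv")
    io.write_json(
        {"pearson_r": comparison["pearson_r"], "pearson_p": comparison["pearson_p"],
         "class_counts": comparison["class_counts"]},
        outdir / "contrast_comparison.json",
    )
    return files + ["contrast_genes.tsv", "contrast_comparison.json"]


def _run_shift(config: RunConfig, seed: int, outdir: Path, state: dict) -> list[str]:
    if "de_a" not in state:
        raise ConfigError("stages: 'shift' requires the 'de' stage")
    params = dict(config.shift)
    window = shift.ExpressionWindow(**params.pop("window", {}))
    alpha = params.pop("alpha", 0.05)
    if params:
        raise ConfigError(f"shift: unknown keys {sorted(params)}")
    files = []
    for tag in ("a", "b"):
        targets = set(state[f"truth_{tag}"].loc[state[f"truth_{tag}"]["is_target"], "gene"])
        result, curves = shift.cumulative_shift(state[f"de_{tag}"], targets, window, alpha)
        state[f"shift_{tag}"] = result
        io.write_json(result.to_dict(), outdir / f"shift_{tag}.json")
        for name, curve in curves.items():
            io.write_table(curve, outdir / f"ecdf_{tag}_{name}.tsv")
        files += [f"shift_{tag}.json", f"ecdf_{tag}_targets.tsv", f"ecdf_{tag}_nontargets.tsv"]
    return files


def _run_droplets(config: RunConfig, seed: int, outdir: Path, state: dict) -> list[str]:
    params = dict(config.droplets)
    analysis = params.pop("analysis", {})
    cfg = _build(sim.SimDropletConfig, params, seed)
    raster, planted = sim.simulate_droplet_field(cfg)
    table, result = drop_mod.quantify_partition(raster, seed=stage_seed(seed, "roi"), **analysis)
    io.write_table(planted, outdir / "droplets_planted.tsv")
    io.write_table(table, outdir / "droplets_measured.tsv")
    io.write_json(result.to_dict(), outdir / "droplets_enrichment.json")
    state["droplets"] = (planted, table, result)
    return ["droplets_planted.tsv", "droplets_measured.tsv", "droplets_enrichment.json"]


def _run_kinetics(config: RunConfig, seed: int, outdir: Path, state: dict) -> list[str]:
    params = dict(config.kinetics)
    n_reps = params.pop("n_replicates", 3)
    conditions = params.pop("conditions", {"buffer": 1.0, "condensate": 0.27})
    assay = params.get("assay", "turbidity")
    rows = []
    for condition, scale in conditions.items():
        for rep in range(n_reps):
            cfg = _build(
                sim.SimKineticConfig, params, stage_seed(seed, f"{condition}:{rep}")
            )
            cfg.initial_rate = cfg.initial_rate * scale
            series = sim.simulate_kinetics(cfg, condition=condition)
            for t, s in zip(series.time_min, series.signal):
                rows.append({"condition": condition, "replicate": rep,
                             "time_min": t, "signal": s})
    plate = pd.DataFrame(rows)
    io.write_table(plate, outdir / "plate.tsv")
    mode = "turbidity" if assay == "turbidity" else "translation"
    rates = kinetics.fit_plate(plate, mode=mode)
    io.write_table(rates, outdir / "rates.tsv")
    summary = kinetics.normalize_rates(rates, control="buffer")
    io.write_table(summary, outdir / "rates_normalized.tsv")
    state["kinetics"] = (plate, rates, summary)
    return ["plate.tsv", "rates.tsv", "rates_normalized.tsv"]


def _run_axon(config: RunConfig, seed: int, outdir: Path, state: dict) -> list[str]:
    params = dict(config.axon)
    n_axons = params.pop("n_axons", 5)
    gate = params.pop("size_gate", puncta.DEFAULT_SIZE_GATE)
    rows = []
    for i in range(n_axons):
        cfg = _build(sim.SimAxonConfig, params, stage_seed(seed, f"axon:{i}"))
        raster, planted = sim.simulate_axon_image(cfg)
        detected, labels = puncta.detect_puncta(raster["ch1"], raster.pixel_size_um)
        detected = puncta.size_gate(detected, *gate)
        axis_y = cfg.corridor_width_um / 2.0 + 2.0
        polyline = np.array([[0.0, axis_y], [cfg.axon_length_um, axis_y]])
        density = puncta.linear_density(
            detected, polyline, cfg.corridor_width_um, raster.pixel_size_um
        )
        mask2 = drop_mod.otsu_mask(raster["ch2"])
        classified = puncta.classify_all_overlaps(detected, labels, mask2)
        frac = classified["overlap_class"].value_counts(normalize=True)
        rows.append(
            {"axon": i, "density_per_100um": density,
             "n_puncta": len(detected),
             "frac_full": float(frac.get("full", 0.0)),
             "frac_partial": float(frac.get("partial", 0.0)),
             "frac_negative": float(frac.get("negative", 0.0))}
        )
    table = pd.DataFrame(rows)
    io.write_table(table, outdir / "axon_puncta.tsv")
    state["axon"] = table
    return ["axon_puncta.tsv"]


_STAGE_RUNNERS = {
    "counts": _run_counts,
    "de": _run_de,
    "shift": _run_shift,
    "droplets": _run_droplets,
    "kinetics": _run_kinetics,
    "axon": _run_axon,
}
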
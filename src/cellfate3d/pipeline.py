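"""Batch orchestration: configuration, per-position analysis, parallel runs.

The unit of work is one (well, position): all of its channel stacks are
read, illumination-corrected, thresholded (one threshold per channel stack,
estimated from the central slices), segmented, and reduced to pixel areas.
Positions are analyzed independently — a pure function of the input files
and the configuration — so they can run across processes; results are merged
in sorted key order, making the output byte-identical for any worker count.

A results directory contains the full audit trail: the per-image areas CSV
(every number in the scores table is recomputable from it), the threshold
decision per stack, the per-treatment scores CSV, a config snapshot, and a
run log.  Positions that fail (unreadable files, shape mismatches) are
quarantined with their error message; the run continues.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, UserError
from .image_io import (
    ChannelRole, DatasetManifest, ImageStack, PlateLayout, StackKey,
    discover_dataset, read_stack, write_scores_table, DEFAULT_FILENAME_REGEX,
)
from .preprocess import CorrectionParams, correct_illumination
from .quantify import ChannelAreas, coloc_fraction, dead_area, measure_areas
from .scores import (
    ImageRatio, Orientation, proliferation_ratio, treatment_scores, viability_ratio,
)
from .threshold import (
    DEFAULT_CENTRAL_FRACTION, DEFAULT_N_BINS, DEFAULT_SIGNAL_FOLD,
    ThresholdDecision, estimate_stack_threshold, segment_foreground,
)

__all__ = [
    "ThresholdSettings", "ScoreSettings", "RunConfig", "PositionResult",
    "analyze_position", "analyze_stacks", "run_pipeline", "load_config",
]

log = logging.getLogger(__name__)


@dataclass
class ThresholdSettings:
    method: str = "yen"   # or "robust_background"
    signal_fold: float = DEFAULT_SIGNAL_FOLD
    central_fraction: float = DEFAULT_CENTRAL_FRACTION
    n_bins: int = DEFAULT_N_BINS

    def __post_init__(self) -> None:
        if self.method not in ("yen", "robust_background"):
            raise ConfigError(f"unknown threshold method {self.method!r}")
        if not 0 < self.central_fraction <= 1:
            raise ConfigError("central_fraction must be in (0, 1]")
        if self.n_bins < 2:
            raise ConfigError("n_bins must be >= 2")


@dataclass
class ScoreSettings:
    orientation: Orientation = Orientation.EDU_OVER_HOECHST
    pseudocount: int = 1
    coculture: bool = False
    subtract_mode: str = "intersection"

    def __post_init__(self) -> None:
        self.orientation = Orientation(self.orientation)
        if self.pseudocount < 1:
            raise ConfigError("pseudocount must be >= 1")
        if self.subtract_mode not in ("intersection", "raw"):
            raise ConfigError(f"unknown subtract_mode {self.subtract_mode!r}")


@dataclass
class RunConfig:
    """Validated run configuration; serialized verbatim into the results dir."""

    input_dir: Path
    output_dir: Path
    naming_config: dict[ChannelRole, str]
    layout: PlateLayout
    correction: CorrectionParams = field(default_factory=CorrectionParams)
    thresholds: ThresholdSettings = field(default_factory=ThresholdSettings)
    score_settings: ScoreSettings = field(default_factory=ScoreSettings)
    filename_regex: str = DEFAULT_FILENAME_REGEX
    n_workers: int = 1

    def __post_init__(self) -> None:
        self.input_dir = Path(self.input_dir)
        self.output_dir = Path(self.output_dir)
        self.naming_config = {ChannelRole(r): str(t) for r, t in self.naming_config.items()}
        if ChannelRole.NUCLEAR not in self.naming_config:
            raise ConfigError("a nuclear channel token is mandatory for any scoring run")
        if self.n_workers < 1:
            raise ConfigError("n_workers must be >= 1")

    def to_dict(self) -> dict:
        d = {
            "input_dir": str(self.input_dir),
            "output_dir": str(self.output_dir),
            "channels": {str(r): t for r, t in self.naming_config.items()},
            "wells": dict(self.layout.assignments),
            "control": self.layout.control_label,
            "illumination": {
                "sigma_px": self.correction.sigma_px,
                "enabled": self.correction.enabled,
            },
            "threshold": dataclasses.asdict(self.thresholds),
            "scores": {
                "orientation": self.score_settings.orientation.value,
                "pseudocount": self.score_settings.pseudocount,
                "coculture": self.score_settings.coculture,
                "subtract_mode": self.score_settings.subtract_mode,
            },
            "filename_regex": self.filename_regex,
            "n_workers": self.n_workers,
        }
        return d


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Build a ``RunConfig`` from a YAML file (CLI flags may override)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    try:
        layout = PlateLayout.from_dict(raw)
        cfg = dict(
            input_dir=raw.get("input_dir", "."),
            output_dir=raw.get("output_dir", "results"),
            naming_config=raw["channels"],
            layout=layout,
            correction=CorrectionParams(**raw.get("illumination", {})),
            thresholds=ThresholdSettings(**raw.get("threshold", {})),
            score_settings=ScoreSettings(**raw.get("scores", {})),
            filename_regex=raw.get("filename_regex", DEFAULT_FILENAME_REGEX),
            n_workers=int(raw.get("n_workers", 1)),
        )
    except KeyError as e:
        raise ConfigError(f"{path}: missing required key {e}") from None
    except TypeError as e:
        raise ConfigError(f"{path}: {e}") from None
    cfg.update(overrides)
    return RunConfig(**cfg)


@dataclass
class PositionResult:
    """Areas plus threshold decisions for one (well, position)."""

    well: str
    position: int
    areas: ChannelAreas
    decisions: dict[ChannelRole, ThresholdDecision]

    @property
    def nuclear_has_signal(self) -> bool:
        d = self.decisions.get(ChannelRole.NUCLEAR)
        return bool(d is not None and d.has_signal)


def _analyze_channel_stacks(
    well: str,
    position: int,
    stacks: Mapping[ChannelRole, ImageStack],
    config: RunConfig,
) -> PositionResult:
    masks: dict[ChannelRole, np.ndarray] = {}
    decisions: dict[ChannelRole, ThresholdDecision] = {}
    for role in sorted(stacks, key=lambda r: r.value):
        stack = stacks[role]
        corrected = np.stack([
            correct_illumination(p, config.correction) for p in stack.planes
        ])
        decision = estimate_stack_threshold(
            corrected,
            central_fraction=config.thresholds.central_fraction,
            n_bins=config.thresholds.n_bins,
            signal_fold=config.thresholds.signal_fold,
            method=config.thresholds.method,
        )
        decisions[role] = decision
        masks[role] = np.stack([segment_foreground(p, decision) for p in corrected])
    areas = measure_areas(masks, well=well, position=position)
    return PositionResult(well=well, position=position, areas=areas, decisions=decisions)


def analyze_position(
    well: str,
    position: int,
    manifest: DatasetManifest,
    config: RunConfig,
) -> PositionResult:
    """Analyze one (well, position) from its files: the unit of parallelism.

    Pure function of the input files and the configuration — no shared
    mutable state.
    """
    stacks = {
        key.channel: read_stack(key, manifest)
        for key in manifest.stacks
        if key.well == well and key.position == position
    }
    if ChannelRole.NUCLEAR not in stacks:
        raise UserError(f"position {well}/{position}: nuclear channel stack missing")
    return _analyze_channel_stacks(well, position, stacks, config)


def analyze_stacks(
    stacks: Mapping[StackKey, ImageStack], config: RunConfig
) -> list[PositionResult]:
    """In-memory variant of the batch run (used by simulations and tests)."""
    by_pos: dict[tuple[str, int], dict[ChannelRole, ImageStack]] = {}
    for key, stack in stacks.items():
        by_pos.setdefault((key.well, key.position), {})[key.channel] = stack
    return [
        _analyze_channel_stacks(well, pos, chans, config)
        for (well, pos), chans in sorted(by_pos.items())
    ]


def compute_ratios(
    results: Sequence[PositionResult], config: RunConfig
) -> list[ImageRatio]:
    """Per-image log-ratios from analyzed positions.

    Positions whose *nuclear* channel had no signal are excluded (no cells
    found there); absent signal on a marker channel contributes 0 px and the
    image stays in.
    """
    ss = config.score_settings
    ratios: list[ImageRatio] = []
    for res in results:
        if not res.nuclear_has_signal:
            log.info("excluding %s/p%d: no nuclear signal", res.well, res.position)
            continue
        has_death = (
            ChannelRole.DEAD_MEMBRANE in res.areas.area
            or ChannelRole.DEAD_APOPTOTIC in res.areas.area
        )
        if has_death:
            ratios.append(viability_ratio(
                res.areas, pseudocount=ss.pseudocount,
                coculture=ss.coculture, subtract_mode=ss.subtract_mode,
            ))
        if ChannelRole.PROLIFERATION in res.areas.area:
            ratios.append(proliferation_ratio(
                res.areas, orientation=ss.orientation, pseudocount=ss.pseudocount,
            ))
    return ratios


def areas_table(results: Sequence[PositionResult]) -> pd.DataFrame:
    """Per-image intermediate table: the auditable unit of the pipeline."""
    rows = []
    for res in sorted(results, key=lambda r: (r.well, r.position)):
        row: dict = {"well": res.well, "position": res.position}
        for role in ChannelRole:
            if role in res.areas.area:
                row[f"area_{role}"] = res.areas.area[role]
        for pair, count in sorted(res.areas.intersections.items(),
                                  key=lambda kv: sorted(str(r) for r in kv[0])):
            a, b = sorted(pair, key=lambda r: r.value)
            row[f"intersect_{a}_{b}"] = count
        if (ChannelRole.DEAD_MEMBRANE in res.areas.area
                or ChannelRole.DEAD_APOPTOTIC in res.areas.area):
            row["dead_px"] = dead_area(res.areas)
        if ChannelRole.LINEAGE_GFP in res.areas.area:
            frac = coloc_fraction(res.areas, ChannelRole.LINEAGE_GFP, ChannelRole.NUCLEAR)
            row["gfp_in_hoechst"] = math.nan if frac is None else frac
        for role, d in sorted(res.decisions.items(), key=lambda kv: kv[0].value):
            row[f"threshold_{role}"] = d.threshold
            row[f"has_signal_{role}"] = d.has_signal
            row[f"background_{role}"] = d.background_mean
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Discover, analyze (parallel over positions), score, and write results.

    Returns the results directory.  Output files: ``areas.csv`` (per image),
    ``scores.csv`` (per treatment), ``thresholds.json`` (decision audit),
    ``config.yaml`` (snapshot), ``quarantine.csv`` (failed positions, if
    any), ``rejected_files.csv`` (unassignable TIFFs, if any), ``run.log``.
    """
    out = config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root_logger = logging.getLogger("cellfate3d")
    root_logger.addHandler(handler)
    try:
        return _run(config, out)
    finally:
        root_logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> Path:
    from . import __version__

    log.info("cellfate3d %s starting", __version__)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    manifest = discover_dataset(config.input_dir, config.naming_config,
                                filename_regex=config.filename_regex)
    if manifest.rejects:
        pd.DataFrame(
            [(str(p), reason) for p, reason in manifest.rejects],
            columns=["file", "reason"],
        ).to_csv(out / "rejected_files.csv", index=False, lineterminator="\n")
        log.warning("%d files could not be assigned; see rejected_files.csv",
                    len(manifest.rejects))

    positions = manifest.positions()
    control_wells = {
        w for w, t in config.layout.assignments.items()
        if t == config.layout.control_label
    }
    if not control_wells & {w for w, _ in positions}:
        raise UserError(
            f"no images found for any control well "
            f"({config.layout.control_label!r}); cannot normalize"
        )
    for well, _ in positions:
        config.layout.treatment(well)  # fail fast on unassigned wells

    def _safe(well: str, pos: int):
        try:
            return analyze_position(well, pos, manifest, config), None
        except Exception as e:  # noqa: BLE001 — quarantine, keep the run alive
            return None, f"{type(e).__name__}: {e}"

    outcomes = joblib.Parallel(n_jobs=config.n_workers, prefer="processes")(
        joblib.delayed(_safe)(well, pos) for well, pos in positions
    )
    results = [r for r, _ in outcomes if r is not None]
    quarantined = [
        (well, pos, err)
        for (well, pos), (r, err) in zip(positions, outcomes) if r is None
    ]
    if quarantined:
        pd.DataFrame(quarantined, columns=["well", "position", "error"]).to_csv(
            out / "quarantine.csv", index=False, lineterminator="\n")
        log.warning("%d positions quarantined; see quarantine.csv", len(quarantined))
    if not results:
        raise UserError("every position failed; nothing to score")

    results.sort(key=lambda r: (r.well, r.position))
    areas_table(results).to_csv(out / "areas.csv", index=False,
                                float_format="%.10g", lineterminator="\n")
    with open(out / "thresholds.json", "w") as fh:
        json.dump(
            {
                f"{res.well}/p{res.position}/{role}": {
                    "threshold": d.threshold if math.isfinite(d.threshold) else "inf",
                    "has_signal": d.has_signal,
                    "background_mean": d.background_mean,
                    "fold_over_background": d.fold_over_background,
                    "central_slices_used": d.central_slices_used,
                    "method": d.method,
                }
                for res in results
                for role, d in sorted(res.decisions.items(), key=lambda kv: kv[0].value)
            },
            fh, indent=2, sort_keys=True,
        )

    ratios = compute_ratios(results, config)
    if ratios:
        scores = treatment_scores(ratios, config.layout)
        write_scores_table(scores, out / "scores.csv")
    else:
        log.warning("no scorable images (no nuclear signal anywhere?)")
    log.info("done: %d positions analyzed, %d quarantined",
             len(results), len(quarantined))
    return out


def scores_from_results_dir(results_dir: str | Path) -> pd.DataFrame:
    """Reload the scores table written by ``run_pipeline``."""
    return pd.read_csv(Path(results_dir) / "scores.csv")
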
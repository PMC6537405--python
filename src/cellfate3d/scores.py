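"""Per-image log-ratios and vehicle-normalized treatment scores.

Each image (one well/position) yields ln(numerator px / denominator px + 1):
nuclear over overlap-corrected dead pixels for viability, EdU over nuclear
for proliferation.  Per-treatment scores are the mean of these log-ratios
over a treatment's images divided by the mean over the vehicle (DMSO)
control's images, so the control scores exactly 1.  A zero denominator is
replaced by an integer pseudocount (default 1 px), negligible against
realistic areas of 1e3-1e6 px.

The proliferation ratio's orientation deserves a note: the assay description
reads "Hoechst to EdU", but a proliferation score that *falls* as S-phase is
suppressed requires EdU in the numerator once normalized, and published
dose-response plots fall with dose.  The default is therefore
``edu_over_hoechst``; the literal ``hoechst_over_edu`` orientation is
available and its use is logged.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import UserError
from .image_io import ChannelRole, PlateLayout
from .quantify import ChannelAreas, coculture_areas, dead_area

__all__ = [
    "Metric", "Orientation", "ImageRatio", "TreatmentScore", "image_log_ratio",
    "viability_ratio", "proliferation_ratio", "treatment_scores",
]

log = logging.getLogger(__name__)


class Metric(str, enum.Enum):
    VIABILITY = "viability"
    PROLIFERATION = "proliferation"

    def __str__(self) -> str:
        return self.value


class Orientation(str, enum.Enum):
    """Which channel is the numerator of the proliferation ratio."""

    EDU_OVER_HOECHST = "edu_over_hoechst"
    HOECHST_OVER_EDU = "hoechst_over_edu"


@dataclass
class ImageRatio:
    """One image's log(ratio + 1) for one metric."""

    well: str
    position: int
    metric: Metric
    numerator_px: int
    denominator_px: int
    log_ratio: float


@dataclass
class TreatmentScore:
    """Vehicle-normalized score for one treatment and metric."""

    treatment: str
    metric: Metric
    score: float
    sem: float
    n_images: int
    n_positions: int


def image_log_ratio(numerator_px: int, denominator_px: int, pseudocount: int = 1) -> float:
    """ln(numerator / max(denominator, pseudocount) + 1)."""
    if numerator_px < 0 or denominator_px < 0:
        raise ValueError("pixel counts must be >= 0")
    if pseudocount < 1:
        raise ValueError("pseudocount must be >= 1")
    return math.log(numerator_px / max(denominator_px, pseudocount) + 1.0)


def viability_ratio(
    areas: ChannelAreas, pseudocount: int = 1, coculture: bool = False,
    subtract_mode: str = "intersection",
) -> ImageRatio:
    """Viability log-ratio: nuclear px over overlap-corrected dead px.

    In co-culture mode the GFP lineage is deconvolved out first: numerator is
    the GFP-free nuclear area, denominator the GFP-free EtHd area.
    """
    if ChannelRole.NUCLEAR not in areas.area:
        raise UserError("nuclear channel missing; it is mandatory for scoring")
    if coculture:
        cc = coculture_areas(areas, subtract_mode=subtract_mode)
        num, den = cc.hoechst_target, cc.ethd_target
    else:
        num, den = areas.area[ChannelRole.NUCLEAR], dead_area(areas)
    return ImageRatio(
        well=areas.well, position=areas.position, metric=Metric.VIABILITY,
        numerator_px=num, denominator_px=den,
        log_ratio=image_log_ratio(num, den, pseudocount),
    )


def proliferation_ratio(
    areas: ChannelAreas,
    orientation: Orientation | str = Orientation.EDU_OVER_HOECHST,
    pseudocount: int = 1,
) -> ImageRatio:
    """Proliferation log-ratio between the EdU and nuclear areas."""
    orientation = Orientation(orientation)
    if ChannelRole.PROLIFERATION not in areas.area:
        raise UserError("proliferation (EdU) channel missing")
    if ChannelRole.NUCLEAR not in areas.area:
        raise UserError("nuclear channel missing; it is mandatory for scoring")
    edu = areas.area[ChannelRole.PROLIFERATION]
    hoechst = areas.area[ChannelRole.NUCLEAR]
    if orientation is Orientation.EDU_OVER_HOECHST:
        num, den = edu, hoechst
    else:
        log.info("using literal hoechst_over_edu proliferation orientation")
        num, den = hoechst, edu
    return ImageRatio(
        well=areas.well, position=areas.position, metric=Metric.PROLIFERATION,
        numerator_px=num, denominator_px=den,
        log_ratio=image_log_ratio(num, den, pseudocount),
    )


def treatment_scores(
    ratios: Iterable[ImageRatio], layout: PlateLayout
) -> list[TreatmentScore]:
    """Average per-image log-ratios by treatment and normalize to the control.

    score(T) = mean(log_ratio | T) / mean(log_ratio | control), per metric;
    the control scores exactly 1.  SEM is the per-image SD/sqrt(n) of T
    scaled by the control mean (the control mean is treated as a constant).
    Images where the nuclear channel had no signal must already have been
    excluded upstream (no cells found); zero signal on a marker channel
    simply contributes 0 px and stays in.

    Raises
    ------
    UserError
        If, for some metric, the control has no image or a zero mean.
    """
    groups: dict[tuple[str, Metric], list[ImageRatio]] = {}
    for r in ratios:
        if not math.isfinite(r.log_ratio):
            raise UserError(f"non-finite log-ratio for well {r.well} position {r.position}")
        groups.setdefault((layout.treatment(r.well), r.metric), []).append(r)

    metrics = sorted({m for _, m in groups}, key=str)
    out: list[TreatmentScore] = []
    for metric in metrics:
        control = groups.get((layout.control_label, metric))
        if not control:
            raise UserError(f"control treatment has no images for metric {metric}")
        control_mean = float(np.mean([r.log_ratio for r in control]))
        if control_mean == 0:
            raise UserError(f"control has no signal for metric {metric} (mean log-ratio 0)")
        for (treatment, m), imgs in sorted(groups.items(), key=lambda kv: (kv[0][0], str(kv[0][1]))):
            if m is not metric:
                continue
            vals = np.array([r.log_ratio for r in imgs], dtype=float)
            n = len(vals)
            sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
            out.append(TreatmentScore(
                treatment=treatment, metric=metric,
                score=1.0 if treatment == layout.control_label
                else float(vals.mean()) / control_mean,
                sem=(sd / math.sqrt(n)) / abs(control_mean),
                n_images=n,
                n_positions=len({(r.well, r.position) for r in imgs}),
            ))
    return out


def plot_scores(
    scores: Sequence[TreatmentScore], out_path, treatment_order: Sequence[str] | None = None
):
    """Bar plot of scores with SEM error bars, one panel per metric (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = sorted({s.metric for s in scores}, key=str)
    fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 3), squeeze=False)
    for ax, metric in zip(axes[0], metrics):
        rows = [s for s in scores if s.metric == metric]
        order = treatment_order or sorted({s.treatment for s in rows})
        by_t = {s.treatment: s for s in rows}
        vals = [by_t[t].score for t in order if t in by_t]
        errs = [by_t[t].sem for t in order if t in by_t]
        labels = [t for t in order if t in by_t]
        ax.bar(range(len(vals)), vals, yerr=errs, capsize=3)
        ax.set_xticks(range(len(labels)), labels, rotation=45, ha="right")
        ax.set_ylabel(f"{metric} score (control = 1)")
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path
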
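"""End-to-end pipeline: read tracks → forest → traits → pairs → H² report.

Every intermediate artifact (trait table, pair sets, estimate table, census)
is written to the output directory so any number in the final report can be
re-derived from the emitted files; the log records the exclusion waterfall
at each filtering step.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import heritability as h2
from . import io as tio
from . import traits as tr
from .errors import PipelineError, ValidationError

log = logging.getLogger("clonalherit")


@dataclass
class RunConfig:
    tracks_path: str
    lineage_path: str
    out_dir: str
    dialect: str = "csv"  # csv | mdf
    microns_per_pixel: float = 1.0
    frame_interval_min: float = tio.DEFAULT_FRAME_INTERVAL_MIN
    n_frames: int = tio.DEFAULT_N_FRAMES
    sister_mode: str = "first"
    cousin_mode: str = "branch"
    relationships: tuple[str, ...] = h2.RELATIONSHIPS
    traits: tuple[str, ...] = h2.TRAITS
    line: str = "input"
    overwrite: bool = False
    make_plots: bool = False

    def __post_init__(self) -> None:
        if self.dialect not in ("csv", "mdf"):
            raise ValidationError(f"unknown dialect {self.dialect!r}; use csv or mdf")
        for p in (self.tracks_path, self.lineage_path):
            if not Path(p).exists():
                raise ValidationError(f"input path does not exist: {p}")


def _mode_for(rc: RunConfig, relationship: str) -> Optional[str]:
    if relationship == "sister_sister":
        return rc.sister_mode
    if relationship == "cousin_cousin":
        return rc.cousin_mode
    return None


def plot_pairs(ps: h2.PairSet, est: h2.H2Estimate, path) -> None:
    """Scatter of one pair set with the fitted regression line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x, y = ps.arrays()
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(x, y, s=12, alpha=0.6, edgecolors="none")
    if len(x):
        xs = [x.min(), x.max()]
        ax.plot(xs, [est.intercept + est.slope * v for v in xs], color="C3")
    ax.set_xlabel(f"{ps.trait} (x)")
    ax.set_ylabel(f"{ps.trait} (y)")
    ax.set_title(f"{ps.relationship}: H² = {est.slope:.2f}{est.stars()}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(rc: RunConfig) -> dict:
    """Execute the full analysis and write all artifacts; returns the summary."""
    out = Path(rc.out_dir)
    if out.exists() and any(out.iterdir()) and not rc.overwrite:
        raise ValidationError(
            f"output directory {out} is not empty; pass overwrite to replace"
        )
    out.mkdir(parents=True, exist_ok=True)

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(name, exc) from exc

    reader = tio.read_track_csv if rc.dialect == "csv" else tio.read_mdf
    ts = stage(
        "read", reader, rc.tracks_path, rc.lineage_path,
        microns_per_pixel=rc.microns_per_pixel,
        frame_interval_min=rc.frame_interval_min,
        n_frames=rc.n_frames,
    )
    log.info("read: %d cells", len(ts.cells))
    if not ts.cells:
        raise PipelineError("forest", ValidationError("no cells in input"))

    forest = stage("forest", tio.build_forest, ts)
    log.info("forest: %d families", len(forest.families))

    tt = stage("traits", tr.compute_traits, forest, ts)
    tt.to_csv(out / "traits.csv")
    census = stage("census", tr.family_census, tt, forest)
    n_excluded = census.n_cells_tracked - census.n_complete_cells
    log.info(
        "traits: %d cells tracked; %d complete, %d excluded (%s)",
        census.n_cells_tracked, census.n_complete_cells, n_excluded,
        ", ".join(f"{k}={v}" for k, v in sorted(census.excluded_by_reason.items())),
    )
    log.info(
        "census: %d/%d families cousin-eligible; %d usable cells (%.1f%% of tracked)",
        census.n_eligible_families, census.n_families,
        census.n_usable_cells, 100.0 * census.usable_fraction,
    )
    (out / "census.json").write_text(json.dumps(census.to_dict(), indent=2) + "\n")

    estimates: list[h2.H2Estimate] = []
    pair_counts: dict[str, int] = {}
    for trait in rc.traits:
        for rel in rc.relationships:
            ps = stage(
                f"pairs[{rel}/{trait}]", h2.enumerate_pairs,
                forest, tt, rel, trait, _mode_for(rc, rel),
            )
            ps.to_dataframe().to_csv(out / f"pairs_{rel}_{trait}.csv", index=False)
            pair_counts[f"{rel}/{trait}"] = ps.n_pairs
            log.info("pairs %s/%s: %d", rel, trait, ps.n_pairs)
            try:
                est = stage(f"estimate[{rel}/{trait}]", h2.estimate_h2, ps)
            except PipelineError as exc:
                if isinstance(exc.cause, ValidationError):
                    log.warning("estimate %s/%s skipped: %s", rel, trait, exc.cause)
                    continue
                raise
            estimates.append(est)
            if rc.make_plots:
                plot_pairs(ps, est, out / f"pairs_{rel}_{trait}.png")

    aux: dict[str, object] = {}
    for name, fn in (
        ("speed_generation_correlation", lambda: h2.speed_generation_correlation(tt)),
        ("well_effect", lambda: h2.well_effect_test(tt)),
        ("family_size_speed", lambda: h2.family_size_speed_test(tt, forest)),
        ("offscreen_speed", lambda: h2.offscreen_speed_test(tt)),
    ):
        try:
            aux[name] = fn()
        except ValidationError as exc:
            aux[name] = {"skipped": str(exc)}

    h2.estimates_frame(estimates).to_csv(out / "estimates.csv", index=False)
    report = h2.report_frame(estimates, tt, census, line=rc.line)
    report.to_csv(out / "report.csv", index=False)
    (out / "report.txt").write_text(h2.format_report(report) + "\n")

    summary = {
        "n_cells_tracked": census.n_cells_tracked,
        "n_complete_cells": census.n_complete_cells,
        "excluded_by_reason": census.excluded_by_reason,
        "n_families": census.n_families,
        "n_eligible_families": census.n_eligible_families,
        "n_usable_cells": census.n_usable_cells,
        "usable_fraction": census.usable_fraction,
        "pair_counts": pair_counts,
        "estimates": [
            {
                "relationship": e.relationship, "trait": e.trait,
                "slope": e.slope, "slope_se": e.slope_se, "p_value": e.p_value,
                "r_squared": e.r_squared, "n_pairs": e.n_pairs,
            }
            for e in estimates
        ],
        "auxiliary_tests": aux,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    return summary
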
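"""Broad-sense heritability from trait regressions between clonal relatives.

H² is estimated as the slope of an ordinary least-squares regression of trait
values between related cells — Cov(x, y)/Var(x) — a clonal adaptation of
parent–offspring regression.  Three relationships are supported:

* ``sister_sister`` — daughters of the same division.  Their similarity mixes
  stable lineage factors with transient cytoplasmic sharing.
* ``mother_daughter`` — x is the mother's trait, y the mean over her complete
  daughters.
* ``cousin_cousin`` — granddaughters of the same cell through different
  daughters; they never shared cytoplasm, so their regression isolates stably
  inherited variation.

Where a cell has multiple tracked daughters or cousins, their mean value is
used.  Only cells observed for a complete cell cycle contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    InsufficientDataError,
)
from .io import LineageForest, LineageNode
from .traits import CellTraits, TraitTable

RELATIONSHIPS = ("sister_sister", "mother_daughter", "cousin_cousin")
TRAITS = ("speed", "generation_time")

SISTER_MODES = ("first", "double_entry")
COUSIN_MODES = ("branch", "focal")


@dataclass
class PairSet:
    """(x, y) trait pairs for one relationship, ready for regression."""

    relationship: str
    trait: str
    mode: str
    pairs: list[tuple[float, float, str]]  # (x, y, family_id)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.array([p[0] for p in self.pairs], dtype=float)
        y = np.array([p[1] for p in self.pairs], dtype=float)
        return x, y

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.relationship, self.trait, fam, x, y) for x, y, fam in self.pairs],
            columns=["relationship", "trait", "family_id", "x", "y"],
        )


@dataclass
class H2Estimate:
    """OLS slope (the H² estimate) with its inference summary."""

    relationship: str
    trait: str
    slope: float
    intercept: float
    slope_se: float
    t_statistic: float
    p_value: float
    r_squared: float
    n_pairs: int
    df: int

    def stars(self) -> str:
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""


def _trait_value(row: CellTraits, trait: str) -> float:
    if trait == "speed":
        return row.speed
    if trait == "generation_time":
        return row.generation_time
    raise ConfigurationError(f"unknown trait {trait!r}; allowed: {TRAITS}")


def _complete_children(node: LineageNode, cell_map: dict[str, CellTraits]):
    return [
        c for c in node.children
        if c.cell_id in cell_map and cell_map[c.cell_id].complete
    ]


def enumerate_pairs(
    forest: LineageForest,
    tt: TraitTable,
    relationship: str,
    trait: str,
    mode: str | None = None,
) -> PairSet:
    """Build the (x, y) pair set for one relationship × trait.

    Modes
    -----
    sister_sister : ``first`` (default) — x is the first-tracked sister
        (lower cell id), one point per dyad; ``double_entry`` — each dyad is
        entered in both orientations (inference then counts dyads, not rows).
    mother_daughter : single policy — one point per complete mother with at
        least one complete daughter, y the mean of her complete daughters.
    cousin_cousin : ``branch`` (default) — one point per grandmother with
        complete cells in both granddaughter branches, x and y the branch
        means (no cell is reused across points); ``focal`` — one point per
        complete granddaughter, y the mean of her complete cousins.
    """
    if relationship not in RELATIONSHIPS:
        raise ConfigurationError(
            f"unknown relationship {relationship!r}; allowed: {RELATIONSHIPS}"
        )
    if trait not in TRAITS:
        raise ConfigurationError(f"unknown trait {trait!r}; allowed: {TRAITS}")
    cell_map = tt.by_cell()
    pairs: list[tuple[float, float, str]] = []

    if relationship == "sister_sister":
        mode = mode or "first"
        if mode not in SISTER_MODES:
            raise ConfigurationError(
                f"unknown sister mode {mode!r}; allowed: {SISTER_MODES}"
            )
        for family_id, node in forest.iter_cells():
            kids = _complete_children(node, cell_map)
            if len(kids) != 2:
                continue
            a, b = sorted(kids, key=lambda n: n.cell_id)
            xa = _trait_value(cell_map[a.cell_id], trait)
            xb = _trait_value(cell_map[b.cell_id], trait)
            pairs.append((xa, xb, family_id))
            if mode == "double_entry":
                pairs.append((xb, xa, family_id))

    elif relationship == "mother_daughter":
        mode = mode or "mean_daughters"
        if mode != "mean_daughters":
            raise ConfigurationError(
                "mother_daughter supports only mode 'mean_daughters'"
            )
        for family_id, node in forest.iter_cells():
            mother_row = cell_map.get(node.cell_id)
            if mother_row is None or not mother_row.complete:
                continue
            kids = _complete_children(node, cell_map)
            if not kids:
                continue
            x = _trait_value(mother_row, trait)
            y = float(
                np.mean([_trait_value(cell_map[k.cell_id], trait) for k in kids])
            )
            pairs.append((x, y, family_id))

    else:  # cousin_cousin
        mode = mode or "branch"
        if mode not in COUSIN_MODES:
            raise ConfigurationError(
                f"unknown cousin mode {mode!r}; allowed: {COUSIN_MODES}"
            )
        for family_id, node in forest.iter_cells():
            if len(node.children) != 2:
                continue
            branch_a = _complete_children(node.children[0], cell_map)
            branch_b = _complete_children(node.children[1], cell_map)
            if not branch_a or not branch_b:
                continue
            va = [_trait_value(cell_map[c.cell_id], trait) for c in branch_a]
            vb = [_trait_value(cell_map[c.cell_id], trait) for c in branch_b]
            if mode == "branch":
                pairs.append((float(np.mean(va)), float(np.mean(vb)), family_id))
            else:  # focal: one point per granddaughter vs mean of her cousins
                for x in va:
                    pairs.append((x, float(np.mean(vb)), family_id))
                for x in vb:
                    pairs.append((x, float(np.mean(va)), family_id))

    return PairSet(relationship=relationship, trait=trait, mode=mode, pairs=pairs)


def estimate_h2(ps: PairSet) -> H2Estimate:
    """OLS fit of y on x; the slope is the H² estimate.

    Under double-entry sister pairing every dyad appears twice, so the
    t-test degrees of freedom are counted on unique dyads (n/2 − 2) and the
    slope standard error is rescaled accordingly.
    """
    x, y = ps.arrays()
    n_units = ps.n_pairs // 2 if ps.mode == "double_entry" else ps.n_pairs
    if n_units < 3:
        raise InsufficientDataError(
            f"{ps.relationship}/{ps.trait}: {n_units} pairs; need at least 3"
        )
    if np.ptp(x) == 0:
        raise DegenerateDataError(
            f"{ps.relationship}/{ps.trait}: Var(x) = 0, slope undefined"
        )
    fit = stats.linregress(x, y)
    slope, intercept = float(fit.slope), float(fit.intercept)
    r2 = float(fit.rvalue) ** 2
    if ps.mode == "double_entry":
        df = n_units - 2
        resid = y - (intercept + slope * x)
        sxx = float(np.sum((x - x.mean()) ** 2))
        se = float(np.sqrt(np.sum(resid**2) / df / sxx))
    else:
        df = len(x) - 2
        se = float(fit.stderr)
    if se > 0:
        t = slope / se
        p = 2.0 * float(stats.t.sf(abs(t), df))
    else:  # perfect fit
        t = float("inf") if slope != 0 else 0.0
        p = 0.0 if slope != 0 else 1.0
    return H2Estimate(
        relationship=ps.relationship,
        trait=ps.trait,
        slope=slope,
        intercept=intercept,
        slope_se=se,
        t_statistic=t,
        p_value=p,
        r_squared=r2,
        n_pairs=ps.n_pairs,
        df=df,
    )


# ---------------------------------------------------------------------------
# Auxiliary checks reported alongside the heritability table


def speed_generation_correlation(tt: TraitTable) -> tuple[float, float]:
    """Spearman rank correlation between speed and generation time (complete cells)."""
    rows = tt.complete_rows()
    if len(rows) < 3:
        raise InsufficientDataError("need at least 3 complete cells")
    speed = [r.speed for r in rows]
    gt = [r.generation_time for r in rows]
    rho, p = stats.spearmanr(speed, gt)
    return float(rho), float(p)


def well_effect_test(tt: TraitTable) -> tuple[float, float]:
    """Kruskal–Wallis test of complete-cell speeds grouped by well."""
    groups: dict[str, list[float]] = {}
    for r in tt.complete_rows():
        groups.setdefault(r.well_id, []).append(r.speed)
    if len(groups) < 2:
        raise InsufficientDataError("need at least 2 wells with complete cells")
    h, p = stats.kruskal(*groups.values())
    return float(h), float(p)


def family_size_speed_test(tt: TraitTable, forest: LineageForest) -> list[dict]:
    """Pairwise Welch t-tests of speed between family-size classes.

    Family size is the number of complete cells in the family; every observed
    size class is compared against every other.
    """
    complete = {r.cell_id: r for r in tt.complete_rows()}
    by_size: dict[int, list[float]] = {}
    for root in forest.families:
        members = [complete[n.cell_id] for n in root.walk() if n.cell_id in complete]
        if not members:
            continue
        by_size.setdefault(len(members), []).extend(r.speed for r in members)
    sizes = sorted(by_size)
    if len(sizes) < 2:
        raise InsufficientDataError("need at least 2 family-size classes")
    records = []
    for i, sa in enumerate(sizes):
        for sb in sizes[i + 1:]:
            res = stats.ttest_ind(by_size[sa], by_size[sb], equal_var=False)
            records.append(
                {
                    "size_a": sa,
                    "size_b": sb,
                    "n_a": len(by_size[sa]),
                    "n_b": len(by_size[sb]),
                    "t": float(res.statistic),
                    "df": float(res.df),
                    "p_value": float(res.pvalue),
                }
            )
    return records


def offscreen_speed_test(tt: TraitTable) -> dict:
    """Welch t-test: partial speeds of off-screen cells vs complete-cell speeds.

    A clear difference would indicate that fast cells are preferentially lost
    off-screen, biasing the trait sample.
    """
    complete = [r.speed for r in tt.complete_rows()]
    offscreen = [
        r.speed
        for r in tt.rows
        if r.exclusion_reason == "off_screen" and np.isfinite(r.speed)
    ]
    if not complete or not offscreen:
        raise InsufficientDataError("need both off-screen and complete cells")
    res = stats.ttest_ind(offscreen, complete, equal_var=False)
    return {
        "n_offscreen": len(offscreen),
        "n_complete": len(complete),
        "t": float(res.statistic),
        "df": float(res.df),
        "p_value": float(res.pvalue),
    }


# ---------------------------------------------------------------------------
# Reporting


def _fmt_cell(est: H2Estimate | None) -> str:
    if est is None:
        return "—"
    return f"{est.slope:.2f}{est.stars()} ({est.r_squared:.2f})"


def report_frame(
    estimates: list[H2Estimate],
    tt: TraitTable | None = None,
    census=None,
    line: str = "simulated",
) -> pd.DataFrame:
    """One-row summary table: family count, mean ± SD per trait, H² (R²) per
    relationship × trait with significance stars (* p<0.05, ** p<0.01,
    *** p<0.001)."""
    if not estimates:
        raise InsufficientDataError("need at least one estimate")
    by_key = {(e.relationship, e.trait): e for e in estimates}
    row: dict[str, object] = {"cell_line": line}
    if census is not None:
        row["n_families"] = census.n_eligible_families
    if tt is not None:
        rows = tt.complete_rows()
        sp = np.array([r.speed for r in rows], dtype=float)
        gt = np.array([r.generation_time for r in rows], dtype=float)
        # Per-cell SD over complete cells (ddof=1), as labelled in the docs.
        row["mean_speed"] = f"{sp.mean():.2f} ± {sp.std(ddof=1):.2f}" if len(sp) > 1 else ""
        row["mean_generation_time"] = (
            f"{gt.mean():.2f} ± {gt.std(ddof=1):.2f}" if len(gt) > 1 else ""
        )
    for trait in TRAITS:
        for rel in ("sister_sister", "mother_daughter", "cousin_cousin"):
            row[f"{trait}:{rel}"] = _fmt_cell(by_key.get((rel, trait)))
    return pd.DataFrame([row])


def estimates_frame(estimates: list[H2Estimate]) -> pd.DataFrame:
    """Full numeric estimate table (one row per relationship × trait)."""
    return pd.DataFrame(
        [
            {
                "relationship": e.relationship,
                "trait": e.trait,
                "slope": e.slope,
                "intercept": e.intercept,
                "slope_se": e.slope_se,
                "t_statistic": e.t_statistic,
                "p_value": e.p_value,
                "r_squared": e.r_squared,
                "n_pairs": e.n_pairs,
                "df": e.df,
            }
            for e in estimates
        ]
    )


def format_report(df: pd.DataFrame) -> str:
    """Plain-text rendering of the report table."""
    return df.to_string(index=False)
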
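"""Synthetic lineage-tracking data with known heritable structure.

The trait model is additive Gaussian on a binary pedigree.  For a trait z of
cell c in family f:

    z_c = mu + g_c + s_c + u_c

* ``g`` — stable heritable component, transmitted mother→daughter as an
  AR(1): g_d = a·g_m + δ, δ ~ N(0, σ_δ²).  Founders draw g from the
  stationary distribution N(0, σ_g²) with σ_g² = σ_δ²/(1 − a²), so the
  g-variance is constant across generations.
* ``s`` — sister-shared transient component: one draw N(0, σ_s²) per
  division, given to both daughters (partitioned cytoplasm, local signals).
* ``u`` — independent environmental noise N(0, σ_u²) per cell.

Draws are truncated below at a positive floor (speeds must be positive,
generation times at least two frame intervals); default regimes keep the
floor ≥ 3σ from the mean so this affects well under 0.1% of draws.

With σ_z² = σ_g² + σ_s² + σ_u², the expected regression slopes are

    mother–daughter  a·σ_g²/σ_z²
    sister–sister    (a²·σ_g² + σ_s²)/σ_z²
    cousin–cousin    a⁴·σ_g²/σ_z²

(the cousin form holds exactly when the regressor is a single cell, i.e. the
focal pairing mode; branch means shrink Var(x) and raise the slope).

Tracks are realised as persistent random walks sampled on the frame grid:
every step has length exactly speed × frame_interval, so the polyline
curvilinear speed recovers the generating trait exactly; the heading evolves
by wrapped-normal increments with SD 1/√turning_kappa.

Reproducibility: trait and censoring draws are family-major rows of single
block draws from spawn-keyed generator streams, so raising ``n_founders``
appends families without perturbing earlier ones; each trajectory has a
per-cell substream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import yaml

from .errors import ConfigurationError
from .io import CellTrack, LineageForest, LineageNode, TrackPoint, TrackSet
from .traits import CellTraits, TraitTable

RELATIONSHIPS = ("sister_sister", "mother_daughter", "cousin_cousin")


@dataclass(frozen=True)
class TraitParams:
    """Generative parameters for one trait.

    mu : trait mean (µm h⁻¹ for speed, hours for generation time)
    a : mother→daughter transmission coefficient, 0 ≤ a < 1
    sigma_delta : innovation SD of the heritable component
    sigma_s : sister-shared transient SD
    sigma_u : independent environmental SD
    floor : lower truncation bound
    """

    mu: float
    a: float
    sigma_delta: float
    sigma_s: float
    sigma_u: float
    floor: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.a < 1.0):
            raise ConfigurationError(
                f"transmission coefficient a={self.a} must lie in [0, 1) "
                "for a finite stationary heritable variance"
            )
        for name in ("sigma_delta", "sigma_s", "sigma_u"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")

    @property
    def sigma_g2(self) -> float:
        """Stationary variance of the heritable component."""
        return self.sigma_delta**2 / (1.0 - self.a**2)

    @property
    def sigma_z2(self) -> float:
        """Total (phenotypic) trait variance."""
        return self.sigma_g2 + self.sigma_s**2 + self.sigma_u**2

    @classmethod
    def from_variances(
        cls, mu: float, a: float, sigma_g2: float, sigma_s2: float,
        sigma_u2: float, floor: float,
    ) -> "TraitParams":
        """Parameterise by stationary variances instead of the innovation SD."""
        return cls(
            mu=mu,
            a=a,
            sigma_delta=math.sqrt(sigma_g2 * (1.0 - a**2)),
            sigma_s=math.sqrt(sigma_s2),
            sigma_u=math.sqrt(sigma_u2),
            floor=floor,
        )

    def expected_slopes(self) -> dict[str, float]:
        """Closed-form regression slopes implied by these parameters."""
        sz2 = self.sigma_z2
        if sz2 == 0:
            return {rel: 0.0 for rel in RELATIONSHIPS}
        sg2 = self.sigma_g2
        return {
            "mother_daughter": self.a * sg2 / sz2,
            "sister_sister": (self.a**2 * sg2 + self.sigma_s**2) / sz2,
            "cousin_cousin": self.a**4 * sg2 / sz2,
        }


def _default_speed() -> TraitParams:
    # Fibrosarcoma-like motility: mean 37.55, SD 10.03 µm/h, strongly
    # heritable (half the variance in the stable lineage component).
    return TraitParams.from_variances(
        mu=37.55, a=0.9, sigma_g2=50.30, sigma_s2=21.64, sigma_u2=28.6609,
        floor=0.5,
    )


def _default_generation_time() -> TraitParams:
    # Generation time: mean 14.22, SD 4.15 h; similarity confined to sisters
    # (no stable heritable component), as expected for a fitness-coupled
    # trait under directional selection.
    return TraitParams.from_variances(
        mu=14.22, a=0.0, sigma_g2=0.0, sigma_s2=7.75, sigma_u2=9.4725,
        floor=2.0 * 20.0 / 60.0,
    )


@dataclass
class SimConfig:
    """Full simulation configuration; defaults mirror the study design
    (20-min frames over 72 h, 6 wells × 5 fields, ~110 families)."""

    n_founders: int = 110
    n_generations: int = 3
    frame_interval_min: float = 20.0
    total_hours: float = 72.0
    microns_per_pixel: float = 0.65
    n_wells: int = 6
    n_fields: int = 5
    speed: TraitParams = field(default_factory=_default_speed)
    generation_time: TraitParams = field(default_factory=_default_generation_time)
    turning_kappa: float = 5.0
    p_offscreen: float = 0.05
    p_death: float = 0.01
    u_correlation: float = 0.0  # couples the u components of the two traits
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 1 or self.n_generations < 1:
            raise ConfigurationError("need at least one founder and one generation")
        if not -1.0 <= self.u_correlation <= 1.0:
            raise ConfigurationError("u_correlation must lie in [-1, 1]")
        if self.generation_time.floor < 2 * self.frame_interval_min / 60.0:
            raise ConfigurationError(
                "generation-time floor must be at least two frame intervals"
            )

    @property
    def n_frames(self) -> int:
        return int(round(self.total_hours * 60.0 / self.frame_interval_min)) + 1

    # -- flat key-value (YAML) round trip -----------------------------------

    _TRAIT_KEYS = ("mu", "a", "sigma_delta", "sigma_s", "sigma_u", "floor")
    _TOP_KEYS = (
        "n_founders", "n_generations", "frame_interval_min", "total_hours",
        "microns_per_pixel", "n_wells", "n_fields", "turning_kappa",
        "p_offscreen", "p_death", "u_correlation", "seed",
    )

    def to_dict(self) -> dict:
        out = {k: getattr(self, k) for k in self._TOP_KEYS}
        for prefix, tp in (("speed", self.speed), ("generation_time", self.generation_time)):
            for k in self._TRAIT_KEYS:
                out[f"{prefix}_{k}"] = getattr(tp, k)
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        kwargs = {}
        for prefix in ("speed", "generation_time"):
            tkw = {}
            for k in cls._TRAIT_KEYS:
                key = f"{prefix}_{k}"
                if key in d:
                    tkw[k] = float(d.pop(key))
            if tkw:
                base = _default_speed() if prefix == "speed" else _default_generation_time()
                kwargs[prefix] = replace(base, **tkw)
        unknown = set(d) - set(cls._TOP_KEYS)
        if unknown:
            raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
        kwargs.update(d)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Pedigree-level trait simulation


def _cell_id(founder_idx: int, gen: int, j: int) -> str:
    cid = f"F{founder_idx:05d}"
    for bit in range(gen - 1, -1, -1):
        cid += f".{(j >> bit) & 1}"
    return cid


@dataclass
class GroundTruth:
    """Latent components, realized traits and pedigree for a simulated run.

    ``components[trait][name]`` is a list of per-generation arrays of shape
    (n_founders, 2**gen); ``expected_slopes[trait][relationship]`` holds the
    closed-form slopes implied by the configuration.
    """

    config: SimConfig
    components: dict[str, dict[str, list[np.ndarray]]]
    expected_slopes: dict[str, dict[str, float]]

    @property
    def n_generations(self) -> int:
        return self.config.n_generations

    def trait_values(self, trait: str, gen: int) -> np.ndarray:
        return self.components[trait]["z"][gen]

    def well_field(self, founder_idx: int) -> tuple[str, str]:
        combo = founder_idx % (self.config.n_wells * self.config.n_fields)
        return f"W{combo // self.config.n_fields + 1}", f"P{combo % self.config.n_fields + 1}"

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for fam in range(self.config.n_founders):
            for gen in range(self.n_generations):
                for j in range(2**gen):
                    rec = {
                        "family_id": f"F{fam:05d}",
                        "cell_id": _cell_id(fam, gen, j),
                        "generation": gen,
                    }
                    for trait in ("speed", "generation_time"):
                        comp = self.components[trait]
                        for name in ("g", "s", "u", "z"):
                            rec[f"{trait}_{name}"] = comp[name][gen][fam, j]
                    rows.append(rec)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    # Fast conversion to analysis inputs (no tracks, no censoring): every
    # non-founder cell is complete; founders are excluded as unobserved births.
    def to_forest(self) -> LineageForest:
        def grow(fam: int, gen: int, j: int) -> LineageNode:
            node = LineageNode(cell_id=_cell_id(fam, gen, j), generation=gen)
            if gen + 1 < self.n_generations:
                node.children = [grow(fam, gen + 1, 2 * j), grow(fam, gen + 1, 2 * j + 1)]
            return node

        return LineageForest(families=[grow(f, 0, 0) for f in range(self.config.n_founders)])

    def to_trait_table(self) -> TraitTable:
        rows = []
        sp = self.components["speed"]["z"]
        gt = self.components["generation_time"]["z"]
        for fam in range(self.config.n_founders):
            well, fld = self.well_field(fam)
            for gen in range(self.n_generations):
                for j in range(2**gen):
                    speed = float(sp[gen][fam, j])
                    gtime = float(gt[gen][fam, j])
                    complete = gen >= 1
                    rows.append(
                        CellTraits(
                            cell_id=_cell_id(fam, gen, j),
                            family_id=f"F{fam:05d}",
                            well_id=well,
                            field_id=fld,
                            generation=gen,
                            generation_time=gtime if complete else float("nan"),
                            speed=speed,
                            path_length=speed * gtime,
                            net_displacement=float("nan"),
                            complete=complete,
                            exclusion_reason="none" if complete else "founder",
                        )
                    )
        rows.sort(key=lambda r: (r.family_id, r.generation, r.cell_id))
        return TraitTable(
            rows=rows,
            frame_interval=self.config.frame_interval_min,
            scale=self.config.microns_per_pixel,
        )


def _simulate_one_trait(
    cfg: SimConfig, tp: TraitParams, block: np.ndarray
) -> dict[str, list[np.ndarray]]:
    """Generate g/s/u/z arrays per generation from a family-major normal block."""
    n, G = cfg.n_founders, cfg.n_generations
    col = 0

    def take(k: int) -> np.ndarray:
        nonlocal col
        out = block[:, col:col + k]
        col += k
        return out

    g: list[np.ndarray] = []
    s: list[np.ndarray] = []
    u: list[np.ndarray] = []
    sigma_g = math.sqrt(tp.sigma_g2)
    for gen in range(G):
        k = 2**gen
        if gen == 0:
            g.append(sigma_g * take(1))
            s.append(np.zeros((n, 1)))
        else:
            delta = tp.sigma_delta * take(k)
            g.append(tp.a * np.repeat(g[gen - 1], 2, axis=1) + delta)
            shared = tp.sigma_s * take(k // 2)
            s.append(np.repeat(shared, 2, axis=1))
        u.append(tp.sigma_u * take(k))
    z = [np.maximum(tp.mu + g[i] + s[i] + u[i], tp.floor) for i in range(G)]
    return {"g": g, "s": s, "u": u, "z": z}


def _block_width(cfg: SimConfig) -> int:
    G = cfg.n_generations
    n_cells = 2**G - 1
    n_innov = n_cells  # one g-draw per cell (founder stationary draw included)
    n_shared = sum(2 ** (gen - 1) for gen in range(1, G))
    return n_innov + n_shared + n_cells  # + one u per cell


def simulate_pedigree_traits(cfg: SimConfig) -> GroundTruth:
    """Draw latent components and realized traits for every cell of every family."""
    width = _block_width(cfg)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(0,)))
    block = rng.standard_normal((cfg.n_founders, 2 * width))
    speed = _simulate_one_trait(cfg, cfg.speed, block[:, :width])
    gen_time = _simulate_one_trait(cfg, cfg.generation_time, block[:, width:])
    if cfg.u_correlation != 0.0:
        rho = cfg.u_correlation
        scale = math.sqrt(1.0 - rho**2)
        tp = cfg.generation_time
        u_new = []
        for gen in range(cfg.n_generations):
            u_sp_std = (
                speed["u"][gen] / cfg.speed.sigma_u
                if cfg.speed.sigma_u > 0
                else np.zeros_like(speed["u"][gen])
            )
            u_gt_std = (
                gen_time["u"][gen] / tp.sigma_u
                if tp.sigma_u > 0
                else np.zeros_like(gen_time["u"][gen])
            )
            u_new.append(tp.sigma_u * (rho * u_sp_std + scale * u_gt_std))
        gen_time["u"] = u_new
        gen_time["z"] = [
            np.maximum(tp.mu + gen_time["g"][i] + gen_time["s"][i] + u_new[i], tp.floor)
            for i in range(cfg.n_generations)
        ]
    return GroundTruth(
        config=cfg,
        components={"speed": speed, "generation_time": gen_time},
        expected_slopes={
            "speed": cfg.speed.expected_slopes(),
            "generation_time": cfg.generation_time.expected_slopes(),
        },
    )


# ---------------------------------------------------------------------------
# Trajectory realisation


def simulate_trajectory(
    speed: float,
    generation_time: float,
    cfg: SimConfig,
    rng: np.random.Generator,
    start_xy: tuple[float, float] = (0.0, 0.0),
    start_frame: int = 0,
) -> list[TrackPoint]:
    """Persistent random walk on the frame grid.

    Each of the ``round(generation_time / frame_interval)`` steps has length
    exactly ``speed × frame_interval`` (in pixels via the configured scale),
    so the polyline curvilinear speed equals ``speed``.  Heading increments
    are N(0, 1/turning_kappa); ``turning_kappa = inf`` gives a straight
    (ballistic) track, ``turning_kappa = 0`` independent uniform headings.
    """
    if speed < 0 or generation_time <= 0:
        raise ConfigurationError("speed and generation_time must be positive")
    interval_h = cfg.frame_interval_min / 60.0
    n_steps = int(round(generation_time / interval_h))
    if n_steps < 1:
        raise ConfigurationError(
            f"generation time {generation_time} h shorter than one frame interval"
        )
    step_px = speed * interval_h / cfg.microns_per_pixel
    theta0 = rng.uniform(-math.pi, math.pi)
    if math.isinf(cfg.turning_kappa):
        headings = np.full(n_steps, theta0)
    elif cfg.turning_kappa <= 0.0:
        headings = rng.uniform(-math.pi, math.pi, size=n_steps)
    else:
        increments = rng.normal(0.0, 1.0 / math.sqrt(cfg.turning_kappa), size=n_steps)
        increments[0] = 0.0
        headings = theta0 + np.cumsum(increments)
    x = start_xy[0] + np.concatenate([[0.0], np.cumsum(step_px * np.cos(headings))])
    y = start_xy[1] + np.concatenate([[0.0], np.cumsum(step_px * np.sin(headings))])
    return [
        TrackPoint(frame=start_frame + i, x=float(x[i]), y=float(y[i]))
        for i in range(n_steps + 1)
    ]


# ---------------------------------------------------------------------------
# Full track-set assembly


def simulate_trackset(cfg: SimConfig) -> tuple[TrackSet, GroundTruth]:
    """Realise the pedigree traits as tracks with censoring and recording limits.

    Division anchoring matches the traits module: a daughter's first frame
    (and position) is her mother's last.  Censoring: with probability
    ``p_offscreen`` (then ``p_death``) a non-founder cell's track is truncated
    at a uniformly drawn interior frame and its descendants are dropped;
    cells whose division falls after the last frame are censored by the end
    of the recording.
    """
    gt = simulate_pedigree_traits(cfg)
    n_frames = cfg.n_frames
    n_cells_per_family = 2**cfg.n_generations - 1
    censor_rng = np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(1,)))
    censor = censor_rng.uniform(size=(cfg.n_founders, 3 * n_cells_per_family))
    interval_h = cfg.frame_interval_min / 60.0
    cells: dict[str, CellTrack] = {}

    def linear_index(gen: int, j: int) -> int:
        return 2**gen - 1 + j

    def place(fam: int, gen: int, j: int, birth_frame: int,
              start_xy: tuple[float, float], mother_id: Optional[str],
              well: str, fld: str) -> None:
        if birth_frame >= n_frames - 1:
            return  # born too late to be observed moving
        cid = _cell_id(fam, gen, j)
        z_speed = float(gt.components["speed"]["z"][gen][fam, j])
        z_gt = float(gt.components["generation_time"]["z"][gen][fam, j])
        traj_rng = np.random.default_rng(
            np.random.SeedSequence(cfg.seed, spawn_key=(2, fam, linear_index(gen, j)))
        )
        points = simulate_trajectory(
            z_speed, z_gt, cfg, traj_rng, start_xy=start_xy, start_frame=birth_frame
        )
        n_steps = len(points) - 1
        division_frame = birth_frame + n_steps
        ci = linear_index(gen, j)
        u_off, u_death, u_cut = censor[fam, 3 * ci], censor[fam, 3 * ci + 1], censor[fam, 3 * ci + 2]
        fate = "divided"
        if gen > 0 and u_off < cfg.p_offscreen:
            fate = "off_screen"
        elif gen > 0 and u_death < cfg.p_death:
            fate = "died"
        if fate != "divided":
            cut = birth_frame + 1 + (int(u_cut * (n_steps - 1)) if n_steps >= 2 else 0)
            points = points[: cut - birth_frame + 1]
        if points[-1].frame > n_frames - 1:
            # recording ended first: observationally this cell is censored
            points = points[: n_frames - birth_frame]
            fate = "censored_at_end"
        cells[cid] = CellTrack(
            cell_id=cid, points=points, mother_id=mother_id, fate=fate,
            well_id=well, field_id=fld,
        )
        if fate == "divided" and gen + 1 < cfg.n_generations:
            end_xy = (points[-1].x, points[-1].y)
            for child_j in (2 * j, 2 * j + 1):
                place(fam, gen + 1, child_j, division_frame, end_xy, cid, well, fld)

    for fam in range(cfg.n_founders):
        well, fld = gt.well_field(fam)
        # founders start on a coarse grid so fields do not overlap visually
        origin = (200.0 * (fam % 25), 200.0 * (fam // 25))
        place(fam, 0, 0, 0, origin, None, well, fld)

    ts = TrackSet(
        cells=cells,
        frame_interval=cfg.frame_interval_min,
        scale=cfg.microns_per_pixel,
        n_frames=n_frames,
    )
    return ts, gt
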
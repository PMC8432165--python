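"""End-to-end, seeded reproductions of the model's environmental experiments.

Each experiment is a deterministic pipeline: build arena(s), simulate
foraging, TD-learn the successor matrix over BVC features, derive place or
grid maps, and reduce them to the population statistics of interest
(gridness, ellipticity, field-rate variability, half-arena SAC similarity,
orientation uniformity, barrier-duplication fractions, hairpin arm
correlations).  Summaries are plain dicts backed by per-cell tables so
every headline number is recomputable from saved output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import baseline as bl
from .bvc import BVCPopulation, FeatureMap, feature_map, make_population
from .cells import grid_maps, place_maps, sr_eigenmodes
from .fields import (
    arm_correlation_matrix,
    barrier_duplication,
    detect_fields,
    field_size_comparison,
    hairpin_arm_masks,
)
from .geometry import (
    Environment,
    build_environment,
    default_barrier,
    equal_area_split_x,
    insert_barrier,
    scale_environment,
)
from .gridmetrics import (
    ellipticity,
    grid_orientation,
    gridness,
    kl_uniform,
    peak_cv,
    sac,
    sac_correlation,
    shuffled_gridness_threshold,
)
from .motion import MotionParams, simulate_trajectory
from .sr import SuccessorMatrix, learn_sr

EXPERIMENTS = (
    "openfield_cells",
    "stretch",
    "barrier",
    "square_vs_trapezoid",
    "square_vs_circle_orientation",
    "hairpin",
)


@dataclass(frozen=True)
class ExperimentConfig:
    experiment: str = "openfield_cells"
    duration: float = 2400.0          # s per learning phase (40 simulated min)
    gamma: float = 0.99
    alpha_M: float = 0.01
    bin_size: float = 0.02
    seed: int = 0
    motion: MotionParams = field(default_factory=MotionParams)
    population: BVCPopulation | None = None
    n_shuffles: int = 200
    shuffle_percentile: float = 95.0

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    def pop(self) -> BVCPopulation:
        return self.population or make_population()


@dataclass
class RunSummary:
    experiment: str
    summary: dict
    tables: dict[str, pd.DataFrame]
    provenance: dict

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        doc = {"experiment": self.experiment, "summary": self.summary,
               "provenance": self.provenance}
        (out / "summary.json").write_text(json.dumps(doc, indent=1, default=float))
        for name, df in self.tables.items():
            df.to_csv(out / f"{name}.csv", index=False)


def _nanstd(values) -> float:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    return float(v.std(ddof=1)) if v.size >= 2 else float("nan")


def _rng_seeds(seed: int, n: int) -> list[int]:
    """Independent 31-bit phase seeds derived from the run seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def train_model(
    env: Environment,
    cfg: ExperimentConfig,
    *,
    seed: int,
    fmap: FeatureMap | None = None,
    M0: SuccessorMatrix | None = None,
):
    """Simulate foraging in ``env`` and TD-learn the SR over its features."""
    if fmap is None:
        fmap = feature_map(cfg.pop(), env)
    traj = simulate_trajectory(env, cfg.duration, cfg.motion, seed=seed)
    sm = learn_sr(fmap, traj, gamma=cfg.gamma, alpha_M=cfg.alpha_M, M0=M0)
    return fmap, traj, sm


def _mode_stats(sm: SuccessorMatrix, fmap: FeatureMap) -> pd.DataFrame:
    """Per-eigenmode gridness / ellipticity / CV / orientation table."""
    modes = sr_eigenmodes(sm, fmap)
    rows = []
    for mode, gm in zip(modes, grid_maps(modes, fmap)):
        if gm.is_degenerate:
            rows.append({"mode": mode.index, "eigenvalue": mode.eigenvalue,
                         "degenerate": True, "gridness": np.nan,
                         "ellipticity": np.nan, "cv": np.nan,
                         "orientation": np.nan})
            continue
        acg = sac(gm)
        rows.append({
            "mode": mode.index,
            "eigenvalue": mode.eigenvalue,
            "degenerate": False,
            "gridness": gridness(acg),
            "ellipticity": ellipticity(acg),
            "cv": peak_cv(gm),
            "orientation": grid_orientation(acg),
        })
    return pd.DataFrame(rows)


def _classify_grid_cells(sm, fmap, cfg: ExperimentConfig, seed: int):
    """(mode table with is_grid_cell column, threshold)."""
    modes = sr_eigenmodes(sm, fmap)
    maps = grid_maps(modes, fmap)
    thr = shuffled_gridness_threshold(
        modes, fmap, n_shuffles=cfg.n_shuffles,
        percentile=cfg.shuffle_percentile, seed=seed,
    )
    table = _mode_stats(sm, fmap)
    table["is_grid_cell"] = table["gridness"] > thr
    return modes, maps, table, thr


# ---------------------------------------------------------------------------
# Experiments
# ---------------------------------------------------------------------------

def run_openfield_cells(cfg: ExperimentConfig) -> RunSummary:
    """Open 1 m square: place-field shape and the grid-mode statistics that
    contrast the feature-based SR with the tabular baseline."""
    seeds = _rng_seeds(cfg.seed, 2)
    env = build_environment("square", bin_size=cfg.bin_size)
    fmap, _, sm = train_model(env, cfg, seed=seeds[0])

    pmaps = place_maps(sm, fmap)
    field_counts = []
    for m in pmaps:
        field_counts.append(len(detect_fields(m)) if not m.is_degenerate else 0)
    field_counts = np.array(field_counts)
    active = field_counts > 0
    frac_unimodal = float((field_counts[active] == 1).mean()) if active.any() else 0.0

    mode_table = _mode_stats(sm, fmap)

    # tabular grid-world baselines in the same arena, 160 leading modes:
    # the random-walk closed form, and the TD-learned parity variant that
    # sees the same kind of 40-minute experience as the feature model
    traj_b = simulate_trajectory(env, cfg.duration, cfg.motion, seed=seeds[1])
    baselines = {
        "closed_form": bl.tabular_sr(env),
        "td": bl.tabular_sr_td(env, traj_b, gamma=cfg.gamma, alpha=cfg.alpha_M),
    }
    tab_tables = {}
    for variant, tab in baselines.items():
        rows = []
        for mode in bl.baseline_eigenmodes(tab)[: sm.n]:
            gm = bl.baseline_grid_map(tab, mode)
            if gm.is_degenerate:
                continue
            acg = sac(gm, min_overlap=10)
            rows.append({"mode": mode.index, "gridness": gridness(acg),
                         "ellipticity": ellipticity(acg), "cv": peak_cv(gm)})
        tab_tables[variant] = pd.DataFrame(rows)
    tab_table = tab_tables["closed_form"]

    summary = {
        "frac_place_maps_unimodal": frac_unimodal,
        "n_place_maps_active": int(active.sum()),
        "mean_gridness": float(np.nanmean(mode_table["gridness"])),
        "sd_gridness": _nanstd(mode_table["gridness"]),
        "mean_ellipticity": float(np.nanmean(mode_table["ellipticity"])),
        "sd_ellipticity": _nanstd(mode_table["ellipticity"]),
        "mean_cv": float(np.nanmean(mode_table["cv"])),
        "sd_cv": _nanstd(mode_table["cv"]),
        "baseline_mean_gridness": float(np.nanmean(tab_table["gridness"])),
        "baseline_mean_ellipticity": float(np.nanmean(tab_table["ellipticity"])),
        "baseline_mean_cv": float(np.nanmean(tab_table["cv"])),
        "baseline_td_mean_gridness": float(np.nanmean(tab_tables["td"]["gridness"])),
        "baseline_td_mean_ellipticity": float(np.nanmean(tab_tables["td"]["ellipticity"])),
        "baseline_td_mean_cv": float(np.nanmean(tab_tables["td"]["cv"])),
    }
    tables = {
        "modes": mode_table,
        "baseline_modes": tab_table,
        "baseline_td_modes": tab_tables["td"],
        "place_fields": pd.DataFrame({"cell": np.arange(sm.n), "n_fields": field_counts}),
    }
    return RunSummary("openfield_cells", summary, tables, _provenance(cfg, seeds))


def run_stretch(cfg: ExperimentConfig) -> RunSummary:
    """Four-box stretch family: fixed-SR place maps deform affinely with the
    arena and per-cell field sizes stay correlated across arenas."""
    seeds = _rng_seeds(cfg.seed, 1)
    base = build_environment("square", bin_size=cfg.bin_size)
    fmap, _, sm = train_model(base, cfg, seed=seeds[0])
    factors = {"1x1": (1.0, 1.0), "2x1": (2.0, 1.0), "1x2": (1.0, 2.0), "2x2": (2.0, 2.0)}
    maps_by_env = {}
    envs = {}
    for name, (fx, fy) in factors.items():
        env = base if (fx, fy) == (1.0, 1.0) else scale_environment(base, fx, fy)
        envs[name] = env
        fm = fmap if env is base else feature_map(cfg.pop(), env, gain=fmap.gain)
        maps_by_env[name] = place_maps(sm, fm)

    areas, corr = field_size_comparison(maps_by_env)

    # affine prediction of centroid displacement from 1x1 to each arena
    affine_rows = []
    base_fields = [detect_fields(m) for m in maps_by_env["1x1"]]
    for name, (fx, fy) in factors.items():
        if name == "1x1":
            continue
        pred, obs = [], []
        for cell, m in enumerate(maps_by_env[name]):
            if not base_fields[cell]:
                continue
            flds = detect_fields(m)
            if not flds:
                continue
            b = max(base_fields[cell], key=lambda f: f.area)
            s = max(flds, key=lambda f: f.area)
            pred.append([b.centroid.x * fx, b.centroid.y * fy])
            obs.append([s.centroid.x, s.centroid.y])
        pred, obs = np.array(pred), np.array(obs)
        r = float(np.corrcoef(pred.ravel(), obs.ravel())[0, 1]) if len(pred) > 2 else np.nan
        mean_ratio = float(np.nanmean(
            np.where(areas["1x1"] > 0, areas[name] / np.where(areas["1x1"] > 0, areas["1x1"], 1),
                     np.nan)))
        affine_rows.append({"arena": name, "affine_centroid_corr": r,
                            "mean_area_ratio": mean_ratio,
                            "arena_area_ratio": fx * fy})
    affine_table = pd.DataFrame(affine_rows)
    area_table = pd.DataFrame({f"area_{k}": v for k, v in areas.items()})
    area_table.insert(0, "cell", np.arange(sm.n))

    summary = {
        "area_correlations": {f"{a}|{b}": v for (a, b), v in corr.items()},
        "min_area_correlation": float(np.nanmin(list(corr.values()))),
        "mean_area_correlation": float(np.nanmean(list(corr.values()))),
    }
    for row in affine_rows:
        summary[f"affine_centroid_corr_{row['arena']}"] = row["affine_centroid_corr"]
        summary[f"mean_area_ratio_{row['arena']}"] = row["mean_area_ratio"]
    return RunSummary("stretch", summary, {"areas": area_table, "affine": affine_table},
                      _provenance(cfg, seeds))


def run_barrier(cfg: ExperimentConfig) -> RunSummary:
    """Barrier insertion: immediate field duplication with an unchanged SR,
    partial loss of duplicates after relearning, reversion after removal.
    The tabular baseline is checked for its zero immediate response."""
    seeds = _rng_seeds(cfg.seed, 2)
    env = build_environment("square", bin_size=cfg.bin_size)
    fmap, _, sm = train_model(env, cfg, seed=seeds[0])
    barrier = default_barrier(env)
    env_b = insert_barrier(env, barrier)
    fmap_b = feature_map(cfg.pop(), env_b, gain=fmap.gain)

    maps_before = place_maps(sm, fmap)
    maps_after = place_maps(sm, fmap_b)  # same SR, new geometry
    records = [
        barrier_duplication(mb, ma, barrier, cell=i)
        for i, (mb, ma) in enumerate(zip(maps_before, maps_after))
    ]
    dup_idx = [r.cell for r in records if r.duplicated]

    # relearning with the barrier present (continual learning from sm)
    _, _, sm2 = train_model(env_b, cfg, seed=seeds[1], fmap=fmap_b, M0=sm)
    maps_relearned = place_maps(sm2, fmap_b)
    lost, persisted = [], []
    for r in records:
        if not r.duplicated:
            continue
        n_now = len(detect_fields(maps_relearned[r.cell]))
        (lost if n_now <= r.fields_before else persisted).append(r.cell)

    # barrier removal: original geometry, updated SR
    maps_removed = place_maps(sm2, fmap)
    reverted = []
    for r in records:
        n_rem = len(detect_fields(maps_removed[r.cell]))
        if n_rem == r.fields_before:
            reverted.append(r.cell)

    # tabular baseline: maps derive from M alone, so insertion without
    # relearning cannot change them
    tab = bl.tabular_sr(env)
    tab_places, _ = bl.baseline_maps(tab, n_modes=0)
    baseline_changed = 0  # structural: same M, same state grid => same maps
    for s in range(0, tab.n_states, max(1, tab.n_states // 20)):
        m = bl.baseline_place_map(tab, s)
        if not np.allclose(m.values, tab_places[s].values):
            baseline_changed += 1

    n = sm.n
    n_dup = len(dup_idx)
    table = pd.DataFrame([
        {"cell": r.cell, "fields_before": r.fields_before,
         "fields_after": r.fields_after_insertion, "duplicated": r.duplicated,
         "lost_after_relearn": r.cell in lost,
         "reverted_after_removal": r.cell in reverted}
        for r in records
    ])
    summary = {
        "n_cells": n,
        "n_duplicated": n_dup,
        "pct_duplicated": 100.0 * n_dup / n,
        "n_lost": len(lost),
        "pct_lost_of_duplicated": (100.0 * len(lost) / n_dup) if n_dup else float("nan"),
        "pct_persisted_of_duplicated": (100.0 * len(persisted) / n_dup) if n_dup else float("nan"),
        "frac_reverted": float(np.mean(table["reverted_after_removal"])),
        "sr_change_during_insertion": 0.0,  # maps_after used sm unchanged
        "baseline_cells_changed_immediately": baseline_changed,
    }
    return RunSummary("barrier", summary, {"duplication": table}, _provenance(cfg, seeds))


def equal_area_half_masks(env: Environment) -> tuple[np.ndarray, np.ndarray]:
    """Bin masks of the two equal-area halves split by a vertical line."""
    xsplit = equal_area_split_x(env)
    xs, _ = env.bin_centers()
    inside = env.bin_mask()
    left = inside & (xs <= xsplit)[None, :]
    right = inside & (xs > xsplit)[None, :]
    return left, right


def _half_sac_stats(maps, left: np.ndarray, right: np.ndarray) -> pd.DataFrame:
    rows = []
    for k, gm in enumerate(maps):
        if gm.is_degenerate:
            continue
        try:
            sac_l = sac(gm.restrict(left))
            sac_r = sac(gm.restrict(right))
        except ValueError:
            continue
        rows.append({
            "mode": k,
            "half_sac_corr": sac_correlation(sac_l, sac_r),
            "gridness_left": gridness(sac_l),
            "gridness_right": gridness(sac_r),
        })
    return pd.DataFrame(rows)


def run_square_vs_trapezoid(cfg: ExperimentConfig) -> RunSummary:
    """Independent learning in square and trapezoid arenas; compares
    half-arena SAC similarity and grid regularity (full arena, and broad vs
    narrow trapezoid halves for the classified grid cells)."""
    seeds = _rng_seeds(cfg.seed, 4)
    out_tables = {}
    summary = {}
    per_env = {}
    for idx, name in enumerate(("square", "trapezoid")):
        env = build_environment(name, bin_size=cfg.bin_size)
        fmap, _, sm = train_model(env, cfg, seed=seeds[idx])
        modes, maps, table, thr = _classify_grid_cells(sm, fmap, cfg, seeds[2 + idx])
        left, right = equal_area_half_masks(env)
        halves = _half_sac_stats(maps, left, right)
        table = table.merge(halves, on="mode", how="left")
        out_tables[f"{name}_modes"] = table
        gc = table[table["is_grid_cell"]]
        per_env[name] = (table, gc)
        summary[f"{name}_gridness_threshold"] = thr
        summary[f"{name}_n_grid_cells"] = int(table["is_grid_cell"].sum())
        summary[f"{name}_mean_half_sac_corr"] = float(np.nanmean(table["half_sac_corr"]))
        summary[f"{name}_sd_half_sac_corr"] = _nanstd(table["half_sac_corr"])
        summary[f"{name}_grid_cell_mean_gridness"] = float(np.nanmean(gc["gridness"]))
        summary[f"{name}_grid_cell_sd_gridness"] = _nanstd(gc["gridness"])
        # left half is the broad end of the trapezoid preset
        summary[f"{name}_grid_cell_mean_gridness_left"] = float(np.nanmean(gc["gridness_left"]))
        summary[f"{name}_grid_cell_mean_gridness_right"] = float(np.nanmean(gc["gridness_right"]))
    summary["trapezoid_grid_cell_mean_gridness_broad"] = summary[
        "trapezoid_grid_cell_mean_gridness_left"]
    summary["trapezoid_grid_cell_mean_gridness_narrow"] = summary[
        "trapezoid_grid_cell_mean_gridness_right"]
    return RunSummary("square_vs_trapezoid", summary, out_tables, _provenance(cfg, seeds))


def run_square_vs_circle_orientation(cfg: ExperimentConfig) -> RunSummary:
    """Grid-axis orientation distributions: polarized (wall-aligned) in the
    square, near-uniform in the circle, quantified by D_KL from uniform."""
    seeds = _rng_seeds(cfg.seed, 4)
    tables = {}
    summary = {}
    for idx, name in enumerate(("square", "circle")):
        env = build_environment(name, bin_size=cfg.bin_size)
        fmap, _, sm = train_model(env, cfg, seed=seeds[idx])
        _, _, table, thr = _classify_grid_cells(sm, fmap, cfg, seeds[2 + idx])
        tables[f"{name}_modes"] = table
        gc = table[table["is_grid_cell"]]
        ori_gc = gc["orientation"].to_numpy()
        ori_gc = ori_gc[np.isfinite(ori_gc)]
        ori_all = table["orientation"].to_numpy()
        ori_all = ori_all[np.isfinite(ori_all)]
        summary[f"{name}_n_grid_cells"] = int(len(gc))
        summary[f"{name}_gridness_threshold"] = thr
        # headline statistic over every mode's axis orientation; a 20-bin
        # histogram needs ~10^2 samples for its bias floor to sit below the
        # effect size, which a dozen classified cells cannot provide
        summary[f"{name}_kl_uniform"] = kl_uniform(ori_all) if ori_all.size else float("nan")
        summary[f"{name}_kl_uniform_grid_cells"] = (
            kl_uniform(ori_gc) if ori_gc.size else float("nan")
        )
    return RunSummary("square_vs_circle_orientation", summary, tables,
                      _provenance(cfg, seeds))


def run_hairpin(cfg: ExperimentConfig) -> RunSummary:
    """Hairpin maze: eigenmode maps fragment into submaps that repeat across
    alternating arms, giving a checkerboard arm-correlation matrix."""
    seeds = _rng_seeds(cfg.seed, 1)
    env = build_environment("hairpin", bin_size=cfg.bin_size)
    fmap, _, sm = train_model(env, cfg, seed=seeds[0])
    modes = sr_eigenmodes(sm, fmap)
    maps = grid_maps(modes, fmap)
    arms = hairpin_arm_masks(env)
    n_arms = len(arms)
    same, opposite = [], []
    mats = []
    for gm in maps:
        if gm.is_degenerate:
            continue
        C = arm_correlation_matrix(gm, arms)
        mats.append(C)
        for i in range(n_arms):
            for j in range(i + 1, n_arms):
                if not np.isfinite(C[i, j]):
                    continue
                (same if (i - j) % 2 == 0 else opposite).append(C[i, j])
    mean_mat = np.nanmean(np.stack(mats), axis=0) if mats else np.full((n_arms, n_arms), np.nan)
    summary = {
        "n_arms": n_arms,
        "mean_corr_same_parity": float(np.mean(same)) if same else float("nan"),
        "mean_corr_opposite_parity": float(np.mean(opposite)) if opposite else float("nan"),
        "checkerboard_contrast": float(np.mean(same) - np.mean(opposite))
        if same and opposite else float("nan"),
    }
    table = pd.DataFrame(mean_mat,
                         columns=[f"arm{j}" for j in range(n_arms)])
    return RunSummary("hairpin", summary, {"mean_arm_correlation": table},
                      _provenance(cfg, seeds))


_RUNNERS = {
    "openfield_cells": run_openfield_cells,
    "stretch": run_stretch,
    "barrier": run_barrier,
    "square_vs_trapezoid": run_square_vs_trapezoid,
    "square_vs_circle_orientation": run_square_vs_circle_orientation,
    "hairpin": run_hairpin,
}


def _provenance(cfg: ExperimentConfig, seeds) -> dict:
    pop = cfg.pop()
    return {
        "seed": cfg.seed,
        "phase_seeds": list(map(int, seeds)),
        "duration_s": cfg.duration,
        "gamma": cfg.gamma,
        "alpha_M": cfg.alpha_M,
        "bin_size": cfg.bin_size,
        "n_bvcs": pop.n,
        "beta": pop.beta,
        "xi": pop.xi,
    }


def run_experiment(cfg: ExperimentConfig, out_dir: str | Path | None = None) -> RunSummary:
    """Run one named experiment; optionally save its tables and summary."""
    result = _RUNNERS[cfg.experiment](cfg)
    if out_dir is not None:
        result.save(out_dir)
    return result


def load_config(path: str | Path) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML document.

    Recognised keys mirror the dataclass fields; ``motion`` and
    ``population`` may be nested mappings of their constructor arguments.
    """
    import yaml

    doc = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key in ("experiment", "duration", "gamma", "alpha_M", "bin_size", "seed",
                "n_shuffles", "shuffle_percentile"):
        if key in doc:
            kwargs[key] = doc[key]
    if "motion" in doc:
        kwargs["motion"] = MotionParams(**doc["motion"])
    if "population" in doc:
        kwargs["population"] = make_population(**doc["population"])
    return ExperimentConfig(**kwargs)
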
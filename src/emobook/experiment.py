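"""Run orchestration: single runs, partner-selectivity sweeps, calibration.

A :class:`RunSummary` condenses one run into per-agent measures, dyadic
matrices and group statistics.  The sweep replicates the main experiment
design (one run per (LPS, replicate) pair with derived seeds); calibration
searches the base behavior weights until group-level behavioral
frequencies fall within one standard deviation of empirical macaque data.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import space, stats
from .config import ModelConfig, default_config
from .observation import RunRecord
from .simulation import Simulation

# group measures compared against empirical data during calibration
CALIBRATION_MEASURES = ("grooming_given_min_h", "grooming_received_min_h",
                        "pct_time_grooming", "groom_bout_duration_min",
                        "approach_rate_per_h", "attack_rate_per_h",
                        "aggressive_signal_rate_per_h",
                        "movement_bout_distance_m", "pct_time_scanning")

DEFAULT_TUNABLES = ("gg_prob", "afs_prob", "app_prob", "att_prob",
                    "ags_prob", "le_prob", "ss_prob", "av_prob",
                    "rndw_prob", "rest_prob", "stop_chance",
                    "rest_schedule_mean", "scan_mid", "scan_slope")


@dataclass
class RunSummary:
    """Averaged outcome of one simulation run."""
    lps: float
    seed: int
    agents: pd.DataFrame
    matrices: dict[str, np.ndarray]
    group: dict[str, float]
    rank_contrast: dict[str, tuple[float, float]]   # (subordinate, dominant)
    dyad_contrast: dict[str, tuple[float, float]]   # (similar, distant)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.agents.to_csv(directory / "agents.csv")
        for name, m in self.matrices.items():
            pd.DataFrame(m).to_csv(directory / f"matrix_{name}.csv")
        rows = [{"measure": k, "value": v} for k, v in self.group.items()]
        pd.DataFrame(rows).to_csv(directory / "group.csv", index=False)


def _pooled_mean(list_of_lists) -> float:
    pooled = [v for sub in list_of_lists for v in sub]
    return float(np.mean(pooled)) if pooled else float("nan")


def summarize(record: RunRecord, cfg: ModelConfig, seed: int) -> RunSummary:
    """Reduce a :class:`RunRecord` to individual, dyadic and group measures."""
    from .config import dominance_vector
    n = cfg.n_agents
    dom = dominance_vector(n)
    rm = record.rate_matrices
    gm = record.groom_minutes

    agents = pd.DataFrame({
        "dom": dom,
        "groom_given_min_h": gm.sum(axis=1),
        "groom_received_min_h": gm.sum(axis=0),
        "pct_grooming": record.pct_grooming,
        "pct_scanning": record.pct_scanning,
        "pct_moving": record.pct_moving,
        "arousal": record.arousal_mean,
        "anxiety": record.anxiety_mean,
        "satisfaction": record.satisfaction_mean,
        "like_given": record.like_mean.sum(axis=1) / (n - 1),
        "like_received": record.like_mean.sum(axis=0) / (n - 1),
        "proximity_score": record.proximity.sum(axis=1),
        "groom_bout_min": [float(np.mean(b)) if b else np.nan
                           for b in record.groom_bouts],
        "move_bout_m": [float(np.mean(b)) if b else np.nan
                        for b in record.move_bout_distances],
    })
    for beh in rm:
        agents[f"{beh}_given_per_h"] = rm[beh].sum(axis=1)
        agents[f"{beh}_received_per_h"] = rm[beh].sum(axis=0)

    matrices = dict(rm)
    matrices["groom_min_h"] = gm
    matrices["like"] = record.like_mean
    matrices["proximity"] = record.proximity
    from .attitudes import fear_matrix
    matrices["fear"] = fear_matrix(dom)

    group: dict[str, float] = {
        "grooming_given_min_h": float(agents.groom_given_min_h.mean()),
        "grooming_received_min_h": float(agents.groom_received_min_h.mean()),
        "pct_time_grooming": float(agents.pct_grooming.mean()),
        "groom_bout_duration_min": _pooled_mean(record.groom_bouts),
        "approach_rate_per_h":
            float(agents[f"{space.APPROACH}_given_per_h"].mean()),
        "attack_rate_per_h":
            float(agents[f"{space.ATTACK}_given_per_h"].mean()),
        "aggressive_signal_rate_per_h":
            float(agents[f"{space.AGGRESSIVE_SIGNAL}_given_per_h"].mean()),
        "movement_bout_distance_m":
            _pooled_mean(record.move_bout_distances),
        "pct_time_scanning": float(agents.pct_scanning.mean()),
        "pct_time_moving": float(agents.pct_moving.mean()),
        "n_samples": float(record.n_samples),
    }
    if gm.sum() > 0:
        group["updown_groom"] = stats.updown_index(gm, dom)
        group["hstar_groom"] = stats.group_shannon_evenness(gm)
        group["tau_rw_groom"] = stats.tau_rw(gm)
    for beh in (space.APPROACH, space.ATTACK, space.AGGRESSIVE_SIGNAL,
                space.AFFILIATIVE_SIGNAL):
        if rm[beh].sum() > 0:
            group[f"updown_{beh}"] = stats.updown_index(rm[beh], dom)
    group["tau_rw_like"] = stats.tau_rw(record.like_mean)
    if rm[space.APPROACH].sum() > 0:
        group["tau_rw_approach"] = stats.tau_rw(rm[space.APPROACH])

    rank_contrast = {
        col: stats.rank_split_means(agents[col].to_numpy(), dom)
        for col in agents.columns if col != "dom"
    }
    dyad_contrast = {name: stats.dyad_split_means(m, dom)
                     for name, m in matrices.items()}
    return RunSummary(cfg.lps, seed, agents, matrices, group,
                      rank_contrast, dyad_contrast)


def run_simulation(cfg: ModelConfig, seed: int | None = None,
                   record_events: bool = False
                   ) -> RunSummary:
    """Execute one full run (stabilization + recorded period)."""
    sim = Simulation(cfg, seed=seed, record_events=record_events)
    record = sim.run()
    out = summarize(record, cfg, cfg.rng_seed if seed is None else seed)
    if record_events:
        out.group["n_events"] = float(len(sim.event_log))
    return out


def scaled_config(cfg: ModelConfig | None = None,
                  stabilization_weeks: float = 1.0,
                  recorded_weeks: float = 4.0) -> ModelConfig:
    """A shortened variant of a configuration for quick experiments: by
    default one week of stabilization plus four recorded weeks."""
    cfg = dataclasses.replace(cfg or default_config())
    week = cfg.day_minutes * cfg.week_days
    cfg.stabilization_minutes = stabilization_weeks * week
    cfg.run_minutes = recorded_weeks * week
    cfg.record_last_minutes = cfg.run_minutes
    cfg.validate()
    return cfg


DEFAULT_LPS_VALUES = (0.0, 0.5, 0.9, 0.95, 0.99)


def run_sweep(lps_values=DEFAULT_LPS_VALUES, n_replicates: int = 10,
              base_seed: int = 0, cfg: ModelConfig | None = None,
              ) -> tuple[pd.DataFrame, list[RunSummary]]:
    """One run per (LPS, replicate) with seeds base_seed + run index.

    Returns a tidy per-run table (group measures plus rank/dyad contrast
    columns) and the underlying :class:`RunSummary` objects.
    """
    cfg = cfg or default_config()
    rows = []
    summaries = []
    idx = 0
    for lps in lps_values:
        if not 0.0 <= lps <= 1.0:
            raise ValueError("lps values must lie in [0, 1]")
        for rep in range(n_replicates):
            c = dataclasses.replace(cfg, lps=float(lps))
            seed = base_seed + idx
            summ = run_simulation(c, seed=seed)
            summaries.append(summ)
            row = {"lps": float(lps), "replicate": rep, "seed": seed}
            row.update(summ.group)
            for k, (sub, domi) in summ.rank_contrast.items():
                row[f"sub_{k}"] = sub
                row[f"dom_{k}"] = domi
            for k, (simi, dist) in summ.dyad_contrast.items():
                row[f"similar_{k}"] = simi
                row[f"distant_{k}"] = dist
            rows.append(row)
            idx += 1
    return pd.DataFrame(rows), summaries


def sweep_contrast_table(table: pd.DataFrame, measures: list[str],
                         kind: str = "rank") -> pd.DataFrame:
    """Paired t-test contrasts per LPS level for the given measures.

    ``kind`` selects subordinate-vs-dominant ('rank', columns sub_/dom_) or
    similar-vs-distant dyad contrasts ('dyad', columns similar_/distant_).
    """
    a_pre, b_pre = (("sub_", "dom_") if kind == "rank"
                    else ("similar_", "distant_"))
    rows = []
    for lps, grp in table.groupby("lps"):
        for m in measures:
            t, p, direction = stats.paired_t(grp[a_pre + m], grp[b_pre + m])
            rows.append({"lps": lps, "measure": m, "t": t, "p": p,
                         "direction": direction})
    return pd.DataFrame(rows)


def empirical_targets() -> dict[str, tuple[float, float]]:
    """Empirical group-level behavioral frequencies (mean, SD) surveyed
    from the macaque literature; the calibration reference."""
    path = importlib.resources.files("emobook") / "data" \
        / "empirical_targets.csv"
    df = pd.read_csv(str(path))
    return {r.measure: (float(r["mean"]), float(r.sd))
            for _, r in df.iterrows()}


def calibration_residuals(group: dict[str, float],
                          targets: dict[str, tuple[float, float]]
                          ) -> pd.DataFrame:
    rows = []
    for m, (mean, sd) in targets.items():
        value = group.get(m, float("nan"))
        rows.append({"measure": m, "target_mean": mean, "target_sd": sd,
                     "model": value, "z": abs(value - mean) / sd})
    return pd.DataFrame(rows)


def _evaluate(cfg: ModelConfig, targets, seeds) -> tuple[float, pd.DataFrame]:
    groups = []
    for s in seeds:
        groups.append(run_simulation(cfg, seed=int(s)).group)
    mean_group = {k: float(np.mean([g.get(k, np.nan) for g in groups]))
                  for k in CALIBRATION_MEASURES}
    res = calibration_residuals(mean_group, targets)
    return float(res.z.max()), res


def calibrate(targets: dict[str, tuple[float, float]] | None = None,
              tunables: tuple[str, ...] = DEFAULT_TUNABLES,
              budget: int = 20, cfg: ModelConfig | None = None,
              seed: int = 0, n_eval_runs: int = 2,
              stabilization_weeks: float = 1.0, recorded_weeks: float = 2.0,
              ) -> tuple[ModelConfig, pd.DataFrame]:
    """Seeded random search over base behavior weights and bout parameters.

    Candidate configurations are scored on short runs; the search stops as
    soon as every target lies within one empirical SD, or when the budget
    (number of evaluated configurations) is exhausted, in which case the
    best configuration found is returned together with its residual table.
    """
    targets = targets or empirical_targets()
    cfg = cfg or default_config()
    eval_cfg = scaled_config(cfg, stabilization_weeks, recorded_weeks)
    rng = np.random.default_rng(seed)
    seeds = rng.integers(0, 2**31 - 1, size=n_eval_runs)
    best_cfg = cfg
    best_score, best_res = _evaluate(eval_cfg, targets, seeds)
    if best_score <= 1.0 or not tunables:
        return best_cfg, best_res
    for _ in range(budget - 1):
        cand = dataclasses.replace(eval_cfg)
        for name in tunables:
            factor = float(np.exp(rng.normal(0.0, 0.25)))
            setattr(cand, name, getattr(eval_cfg, name) * factor)
        cand.stop_chance = min(cand.stop_chance, 0.95)
        try:
            cand.validate()
        except ValueError:
            continue
        score, res = _evaluate(cand, targets, seeds)
        if score < best_score:
            best_score, best_res = score, res
            best_cfg = dataclasses.replace(
                cfg, **{name: getattr(cand, name) for name in tunables})
        if best_score <= 1.0:
            break
    return best_cfg, best_res
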
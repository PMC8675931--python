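"""Scripted in-silico experiments: ablations, sweeps, variability."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis as _an
from .network import NetworkConfig
from .simulate import integrate, simulate_single_unit

__all__ = [
    "ExperimentSpec",
    "EXPERIMENT_NAMES",
    "intrinsic_frequencies",
    "run_ablation",
    "run_sweep",
    "run_variability",
    "run_experiment",
    "metrics_frame",
    "write_outputs",
]

EXPERIMENT_NAMES = (
    "default",        # full default chain
    "ablation",       # electrical-only / messenger-only / both
    "g_sweep",        # ICC-ICC conductance sweep
    "pip3_sweep",     # IP3 permeability sweep
    "pca_sweep",      # Ca2+ permeability sweep
    "variability",    # seeded coupling-strength variability
    "intrinsic",      # uncoupled per-cell frequencies along the gradient
    "gcoup_sweep",    # ICC->SM conductance sweep
)

#: Default sweep grids: a factor of two above and below the default coupling
#: values, and two orders of magnitude each way for the (insensitive) Ca2+
#: permeability.
SWEEP_GRIDS = {
    "g_icc_icc": tuple(np.geomspace(0.35, 1.4, 7).round(6)),
    "p_ip3": tuple(np.geomspace(4.0, 16.0, 7).round(6)),
    "p_ca": (0.008, 0.08, 0.8, 8.0, 80.0),
    "g_coup": (0.0, 0.05, 0.125, 0.25, 0.5, 1.0),
}

VARIABILITY_LEVELS = (0.2, 0.5, 1.0)
DEFAULT_SEEDS = (1, 2, 3, 4, 5)


@dataclass
class ExperimentSpec:
    """Fully determined description of one experiment run."""

    name: str
    overrides: dict = field(default_factory=dict)
    seeds: tuple = DEFAULT_SEEDS
    duration_s: float = 900.0
    out_dir: str | None = None


def metrics_frame(metrics: _an.EntrainmentMetrics) -> pd.DataFrame:
    """Per-cell metrics table."""
    n = metrics.n_units
    return pd.DataFrame({
        "cell": np.arange(1, n + 1),
        "period_mean_s": metrics.period_mean,
        "period_sd_s": metrics.period_sd,
        "period_valid": metrics.period_valid,
        "relative_lag_mean_s": metrics.relative_lag_mean,
        "relative_lag_sd_s": metrics.relative_lag_sd,
        "entrained": metrics.entrained,
        "v_min_mV": metrics.v_min,
    })


def write_outputs(out_dir, name: str, result, metrics) -> Path:
    """Persist one run: config copy, trajectory container, metrics CSV and a
    machine-readable summary."""
    out = Path(out_dir) / name
    out.mkdir(parents=True, exist_ok=True)
    result.config.to_yaml(out / "config.yaml")
    result.save(out / "trajectories.h5")
    metrics_frame(metrics).to_csv(out / "metrics.csv", index=False)
    summary = {
        "total_lag_mean_s": metrics.total_lag_mean,
        "total_lag_sd_s": metrics.total_lag_sd,
        "velocity_cm_s": metrics.velocity_cm_s,
        "entrainment_range": metrics.entrainment_range,
        "period_cell1_s": float(metrics.period_mean[0]),
        "period_last_cell_s": float(metrics.period_mean[-1]),
        "v_min_mean_mV": float(np.mean(metrics.v_min)),
        "discarded_cycles": metrics.discarded_cycles,
    }
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    return out


def _run_and_measure(cfg: NetworkConfig, duration_s: float,
                     transient_s: float = 300.0):
    result = integrate(cfg, duration_s=duration_s)
    metrics = _an.compute_metrics(result.time, result.v_sm,
                                  length_cm=cfg.length_cm,
                                  transient_s=transient_s)
    return result, metrics


def intrinsic_frequencies(config: NetworkConfig | None = None,
                          duration_s: float = 900.0,
                          transient_s: float = 300.0):
    """Uncoupled oscillation frequency (cpm) of each cell along the
    innervation gradient.  Returns (betas, frequencies_cpm)."""
    cfg = config if config is not None else NetworkConfig()
    from .network import beta_gradient

    betas = beta_gradient(cfg)
    freqs = np.empty(cfg.n_units)
    for i, b in enumerate(betas):
        res = simulate_single_unit(float(b), icc_params=cfg.icc_params,
                                   sm_params=cfg.sm_params,
                                   duration_s=duration_s)
        keep = res.time >= transient_s
        pk = _an.detect_peaks(res.time[keep], res.v_icc[keep, 0])
        freqs[i] = 60.0 / np.diff(pk).mean() if pk.size >= 3 else np.nan
    return betas, freqs


def run_ablation(config: NetworkConfig | None = None,
                 duration_s: float = 900.0, out_dir=None) -> dict:
    """Electrical-only, messenger-only and fully coupled chains.

    Electrical-only disables both second-messenger exchanges; messenger-only
    disables ICC-ICC electrical coupling.  Returns a dict of
    ``{condition: {"result", "metrics"}}``.
    """
    base = config if config is not None else NetworkConfig()
    conditions = {
        "electrical_only": base.replace(enable_ca=False, enable_ip3=False),
        "messenger_only": base.replace(enable_electrical=False),
        "both": base.replace(),
    }
    out = {}
    for name, cfg in conditions.items():
        result, metrics = _run_and_measure(cfg, duration_s)
        out[name] = {"result": result, "metrics": metrics}
        if out_dir is not None:
            write_outputs(out_dir, f"ablation_{name}", result, metrics)
    return out


def run_sweep(parameter: str, values=None,
              config: NetworkConfig | None = None,
              duration_s: float = 900.0, out_dir=None) -> dict:
    """Sweep one coupling parameter and summarize entrainment per value.

    Returns ``{"table": DataFrame, "fit": dict | None}``.  The
    double-exponential total-lag fit is attempted only over fully entrained
    networks and only for the conductance/IP3-permeability sweeps; partially
    entrained values are flagged in the table and excluded.
    """
    if parameter not in SWEEP_GRIDS:
        raise ValueError(f"unknown sweep parameter {parameter!r}; "
                         f"choose from {sorted(SWEEP_GRIDS)}")
    base = config if config is not None else NetworkConfig()
    values = SWEEP_GRIDS[parameter] if values is None else tuple(values)
    rows = []
    for v in values:
        cfg = base.replace(**{parameter: float(v)})
        result, metrics = _run_and_measure(cfg, duration_s)
        rows.append({
            "value": float(v),
            "total_lag_mean_s": metrics.total_lag_mean,
            "total_lag_sd_s": metrics.total_lag_sd,
            "period_last_cell_s": float(metrics.period_mean[-1]),
            "period_cell1_s": float(metrics.period_mean[0]),
            "entrainment_range": metrics.entrainment_range,
            "fully_entrained": metrics.entrainment_range == cfg.n_units,
            "sm_amplitude_mV": float(np.ptp(result.v_sm[result.time >= 300.0],
                                            axis=0).mean()),
        })
        if out_dir is not None:
            write_outputs(out_dir, f"sweep_{parameter}_{v:g}", result, metrics)
    table = pd.DataFrame(rows)
    fit = None
    if parameter in ("g_icc_icc", "p_ip3"):
        ok = table[table["fully_entrained"]]
        if len(ok) >= 5:
            try:
                fit = _an.fit_lag_vs_coupling(ok["value"].to_numpy(),
                                              ok["total_lag_mean_s"].to_numpy())
            except RuntimeError:
                fit = None
    return {"table": table, "fit": fit}


def run_variability(levels=VARIABILITY_LEVELS, with_ip3_exchange: bool = True,
                    seeds=DEFAULT_SEEDS, config: NetworkConfig | None = None,
                    duration_s: float = 900.0, out_dir=None) -> pd.DataFrame:
    """Seeded coupling-variability replicates.

    With IP3 exchange, both the per-junction conductances and IP3
    permeabilities are drawn; without it, IP3 exchange is disabled and only
    the conductances vary.
    """
    base = config if config is not None else NetworkConfig()
    if not with_ip3_exchange:
        base = base.replace(enable_ip3=False)
    rows = []
    for v in levels:
        for seed in seeds:
            cfg = base.replace(variability=float(v), seed=int(seed))
            result, metrics = _run_and_measure(cfg, duration_s)
            rows.append({
                "variability": float(v),
                "seed": int(seed),
                "with_ip3_exchange": bool(with_ip3_exchange),
                "total_lag_mean_s": metrics.total_lag_mean,
                "total_lag_sd_s": metrics.total_lag_sd,
                "entrainment_range": metrics.entrainment_range,
                "fully_entrained": metrics.entrainment_range == cfg.n_units,
            })
            if out_dir is not None:
                write_outputs(out_dir, f"variability_v{v:g}_seed{seed}",
                              result, metrics)
    return pd.DataFrame(rows)


def run_experiment(spec: ExperimentSpec) -> dict:
    """Dispatch one named experiment.  Unknown names raise with the list of
    available experiments."""
    if spec.name not in EXPERIMENT_NAMES:
        raise ValueError(f"unknown experiment {spec.name!r}; available: "
                         f"{', '.join(EXPERIMENT_NAMES)}")
    cfg = NetworkConfig(**spec.overrides) if spec.overrides else NetworkConfig()
    if spec.name == "default":
        result, metrics = _run_and_measure(cfg, spec.duration_s)
        if spec.out_dir is not None:
            write_outputs(spec.out_dir, "default", result, metrics)
        return {"result": result, "metrics": metrics}
    if spec.name == "ablation":
        return run_ablation(cfg, spec.duration_s, out_dir=spec.out_dir)
    if spec.name == "g_sweep":
        return run_sweep("g_icc_icc", config=cfg, duration_s=spec.duration_s,
                         out_dir=spec.out_dir)
    if spec.name == "pip3_sweep":
        return run_sweep("p_ip3", config=cfg, duration_s=spec.duration_s,
                         out_dir=spec.out_dir)
    if spec.name == "pca_sweep":
        return run_sweep("p_ca", config=cfg, duration_s=spec.duration_s,
                         out_dir=spec.out_dir)
    if spec.name == "gcoup_sweep":
        return run_sweep("g_coup", config=cfg, duration_s=spec.duration_s,
                         out_dir=spec.out_dir)
    if spec.name == "variability":
        table = run_variability(seeds=spec.seeds, config=cfg,
                                duration_s=spec.duration_s,
                                out_dir=spec.out_dir)
        return {"table": table}
    if spec.name == "intrinsic":
        betas, freqs = intrinsic_frequencies(cfg, duration_s=spec.duration_s)
        slope, intercept, r2 = _an.fit_frequency_beta(freqs, betas)
        out = {"betas": betas, "frequencies_cpm": freqs,
               "fit": {"slope": slope, "intercept": intercept, "r2": r2}}
        if spec.out_dir is not None:
            outp = Path(spec.out_dir)
            outp.mkdir(parents=True, exist_ok=True)
            pd.DataFrame({"beta": betas, "frequency_cpm": freqs}).to_csv(
                outp / "intrinsic_frequencies.csv", index=False)
            with open(outp / "intrinsic_fit.json", "w") as fh:
                json.dump(out["fit"], fh, indent=2)
        return out
    raise AssertionError("unreachable")
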
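"""Config-driven sweep experiments and fixture generation.

Ties the simulators, the bifurcation analysis, the rate theory and the
iterative predictions into reproducible, file-producing experiments.  Every
figure-class analysis of the underlying study has a named configuration in
:data:`NAMED_CONFIGS`; experiments are deterministic, and rerunning an
identical configuration reproduces identical output files.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fixed_points import bifurcation_diagram
from .hh import analyze_spike_train, fi_curve, hh_spike_times, isi_return_map
from .iterative import iterate
from .params import PROVENANCE, ModelParameters, default_parameters, load_parameters
from .qif import simulate_qif
from .theory import firing_rate, gain, mu_star

__all__ = ["ExperimentConfig", "NAMED_CONFIGS", "run_experiment", "generate_fixtures"]


@dataclass
class ExperimentConfig:
    """One reproducible sweep experiment.

    ``seed`` exists for interface stability (all algorithms here are
    deterministic); ``param_overrides`` are applied on top of the packaged
    default set or a parameter file.
    """

    sweep: str                       # fi | bifurcation | theory | iterative | returnmap
    model: str = "hh"                # hh | qif
    mu_min: float = 0.0
    mu_max: float = 30.0
    mu_step: float = 0.5
    mu_values: list | None = None    # overrides the min/max/step grid
    gca_values: list = field(default_factory=lambda: [0.0, 0.2, 0.4, 0.6])
    reset_mode: str | None = None
    param_file: str | None = None
    param_overrides: dict = field(default_factory=dict)
    dt: float = 0.01
    duration: float = 3000.0
    n_discard: int = 20
    seed: int = 0
    name: str = "experiment"

    def mu_grid(self) -> np.ndarray:
        if self.mu_values is not None:
            return np.asarray(self.mu_values, dtype=float)
        return np.arange(self.mu_min, self.mu_max + 0.5 * self.mu_step, self.mu_step)

    def parameters(self) -> ModelParameters:
        p = load_parameters(self.param_file) if self.param_file else default_parameters()
        if self.reset_mode:
            p = p.with_(reset_mode=self.reset_mode)
        if self.param_overrides:
            p = p.with_(**self.param_overrides)
        return p

    def validate(self) -> None:
        if self.sweep not in ("fi", "bifurcation", "theory", "iterative", "returnmap"):
            raise ValueError(f"unknown sweep type {self.sweep!r}")
        if self.model not in ("hh", "qif"):
            raise ValueError(f"unknown model {self.model!r}")
        if len(self.mu_grid()) == 0:
            raise ValueError("empty mu grid")
        if self.param_file and not Path(self.param_file).exists():
            raise ValueError(f"parameter file not found: {self.param_file}")

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _qif_fi(p: ModelParameters, mu_grid, duration, dt, n_discard) -> pd.DataFrame:
    rows = []
    for mu in mu_grid:
        _, seq = simulate_qif(p, mu, duration, dt, n_discard=n_discard)
        kept = seq.isis[n_discard:] if len(seq.isis) > n_discard else np.array([])
        rows.append(
            {
                "mu": mu,
                "rate_mean": float(np.mean(1000.0 / kept)) if len(kept) else 0.0,
                "n_distinct": len(seq.distinct_isis),
                "rate_values": [1000.0 / v for v in seq.distinct_isis],
                "pattern": seq.pattern,
                "period": seq.period,
            }
        )
    return pd.DataFrame(rows)


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> dict:
    """Execute a sweep and write CSV/JSON outputs plus a manifest.

    Returns the manifest dictionary (also written as manifest.json); the
    manifest records the config, its hash, the package version and the
    parameter provenance table, making runs auditable and idempotent.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    p = config.parameters()
    mu_grid = config.mu_grid()
    files: list[str] = []
    extra: dict = {}

    if config.sweep == "fi":
        for gca in config.gca_values:
            q = p.with_(gCa=gca)
            if config.model == "hh":
                df = fi_curve(q, mu_grid, config.duration, config.dt, config.n_discard)
            else:
                df = _qif_fi(q, mu_grid, config.duration, config.dt, config.n_discard)
            df["rate_values"] = df["rate_values"].apply(json.dumps)
            fn = out / f"{config.name}_fi_gca{gca:g}.csv"
            df.to_csv(fn, index=False)
            files.append(fn.name)
    elif config.sweep == "bifurcation":
        for gca in config.gca_values:
            q = p.with_(gCa=gca)
            diag = bifurcation_diagram(config.model, q, mu_grid)
            fn = out / f"{config.name}_bif_gca{gca:g}.csv"
            diag.to_frame().to_csv(fn, index=False)
            files.append(fn.name)
            extra[f"gca{gca:g}"] = {
                "onset_type": diag.onset_type,
                "onset_mu": diag.onset_mu,
                "subthreshold_annihilation_mu": diag.subthreshold_annihilation_mu,
            }
    elif config.sweep == "theory":
        for gca in config.gca_values:
            q = p.with_(gCa=gca, reset_mode="fixed_reset")
            res = firing_rate(mu_grid, q)
            g = gain(res, q)
            df = res.table.merge(g, on="mu")
            df["mu_star"] = res.mu_star
            fn = out / f"{config.name}_theory_gca{gca:g}.csv"
            df.to_csv(fn, index=False)
            files.append(fn.name)
            extra[f"gca{gca:g}"] = {"mu_star": res.mu_star}
    elif config.sweep == "iterative":
        for gca in config.gca_values:
            q = p.with_(gCa=gca)
            rows = []
            for mu in mu_grid:
                s = iterate(mu, q, n_transient=config.n_discard)
                rows.append(
                    {"mu": mu, "pattern": s.pattern, "period": s.period,
                     "mean_rate": s.mean_rate, "sd_rate": s.sd_rate,
                     "isis": json.dumps(list(np.round(s.retained_isis, 6)))}
                )
            fn = out / f"{config.name}_iterative_gca{gca:g}.csv"
            pd.DataFrame(rows).to_csv(fn, index=False)
            files.append(fn.name)
    elif config.sweep == "returnmap":
        for gca in config.gca_values:
            q = p.with_(gCa=gca)
            rows = []
            for mu in mu_grid:
                if config.model == "hh":
                    spikes = hh_spike_times(q, mu, config.duration, config.dt)
                    seq = analyze_spike_train(spikes, n_discard=config.n_discard)
                else:
                    _, seq = simulate_qif(q, mu, config.duration, config.dt,
                                          n_discard=config.n_discard)
                isis = seq.isis[config.n_discard:]
                if len(isis) >= 2:
                    pairs, mean_isi = isi_return_map(isis)
                    for a, b in pairs:
                        rows.append({"mu": mu, "isi_k": a, "isi_k1": b,
                                     "mean_isi": mean_isi, "pattern": seq.pattern})
            fn = out / f"{config.name}_returnmap_gca{gca:g}.csv"
            pd.DataFrame(rows).to_csv(fn, index=False)
            files.append(fn.name)

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.digest(),
        "files": files,
        "provenance": PROVENANCE,
        **({"results": extra} if extra else {}),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


#: figure-class experiment configurations (one per analysis of the study)
NAMED_CONFIGS: dict[str, ExperimentConfig] = {
    "hh-fi": ExperimentConfig(sweep="fi", model="hh", name="hh-fi"),
    "hh-returnmap-burst": ExperimentConfig(
        sweep="returnmap", model="hh", mu_values=[18.0, 19.0, 22.0, 22.5],
        gca_values=[0.6], duration=5000.0, name="hh-returnmap-burst"),
    "hh-bifurcation": ExperimentConfig(
        sweep="bifurcation", model="hh", mu_step=1.0, gca_values=[0.0, 0.2, 0.4, 0.6],
        name="hh-bifurcation"),
    "qif-bifurcation": ExperimentConfig(
        sweep="bifurcation", model="qif", mu_step=1.0, gca_values=[0.0, 0.1, 0.15, 0.2],
        name="qif-bifurcation"),
    "qif-fi-waveform": ExperimentConfig(
        sweep="fi", model="qif", reset_mode="spike_waveform",
        gca_values=[0.0, 0.1, 0.15, 0.2], name="qif-fi-waveform"),
    "qif-returnmap-burst": ExperimentConfig(
        sweep="returnmap", model="qif", reset_mode="spike_waveform",
        mu_values=[10.0, 11.0, 12.5, 14.0], gca_values=[0.2], duration=5000.0,
        name="qif-returnmap-burst"),
    "qif-fi-fixed-delta": ExperimentConfig(
        sweep="fi", model="qif", reset_mode="fixed_delta",
        gca_values=[0.0, 0.1, 0.15, 0.2], name="qif-fi-fixed-delta"),
    "qif-fi-fixed-reset": ExperimentConfig(
        sweep="fi", model="qif", reset_mode="fixed_reset",
        gca_values=[0.05, 0.1, 0.15, 0.2], name="qif-fi-fixed-reset"),
    "theory-intervals": ExperimentConfig(
        sweep="theory", model="qif", mu_min=1.0, mu_max=16.0, mu_step=0.25,
        gca_values=[0.2], name="theory-intervals"),
    "theory-rate-gain": ExperimentConfig(
        sweep="theory", model="qif", mu_min=0.5, mu_max=20.0, mu_step=0.25,
        gca_values=[0.05, 0.1, 0.15, 0.2], name="theory-rate-gain"),
    "iterative-fi": ExperimentConfig(
        sweep="iterative", model="qif", mu_min=2.0, mu_max=40.0, mu_step=0.5,
        gca_values=[0.0, 0.1, 0.15, 0.2], name="iterative-fi"),
    "iterative-returnmap": ExperimentConfig(
        sweep="iterative", model="qif", mu_min=18.0, mu_max=23.0, mu_step=0.1,
        gca_values=[0.2], name="iterative-returnmap"),
}


def generate_fixtures(tier: str, out_dir: str | Path) -> dict:
    """Produce the reference tables the test suite and examples consume.

    ``fast`` regenerates the HH burst-region return maps (the printed
    example biases), a short QIF f-I sweep and one theory sweep in about a
    minute; ``full`` runs every named configuration.  Output is
    deterministic, so fixtures regenerate identically.
    """
    out = Path(out_dir)
    if tier == "fast":
        names = ["hh-returnmap-burst", "qif-fi-fixed-reset", "theory-intervals"]
    elif tier == "full":
        names = list(NAMED_CONFIGS)
    else:
        raise ValueError("tier must be 'fast' or 'full'")
    manifests = {}
    for name in names:
        cfg = NAMED_CONFIGS[name]
        manifests[name] = run_experiment(cfg, out / name)
    index = {name: m["config_hash"] for name, m in manifests.items()}
    (out / "fixtures.json").write_text(json.dumps(index, indent=2))
    return manifests
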
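"""End-to-end synthetic experiments: generative gel physics -> AFM measurement
-> distribution-type classification.

The baseline experiment closes the loop the individual modules leave open:
a spatially correlated exponent field generates a log-normal elasticity
map, each pixel's true modulus drives a synthetic Hertz force curve, the
curves are inverted back to moduli, and the fitted map is classified. The
M1/M2 contrast pairs an intact map with a patch-degraded copy of the same
underlying field and compares the fitted moduli between the two (verdicts
plus a Mann-Whitney U test), reproducing the logic of a
degradation-signature experiment on a simplified tissue.

Reproducibility: every stage draws from a generator derived from the global
seed by a fixed counter-based splitting rule, so a report is a pure
function of its configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as gio
from .distributions import classify_distribution, compare_groups
from .errors import DomainError, StageError
from .gel import (
    ElasticityMap,
    PercolationParams,
    decorrelated_indices,
    degrade_map,
    elasticity_from_percolation,
    sample_exponent_field,
)
from .hertz import ProbeSpec, fit_hertz, generate_force_curve
from .lattice import build_lattice, effective_modulus, estimate_critical_exponent
from .processes import KineticSpec, RecursionSpec, simulate_kinetics, simulate_recursion

__all__ = [
    "ExperimentConfig",
    "ExperimentReport",
    "run_experiment",
    "generate_fixtures",
    "fit_map_from_curves",
]

SCENARIOS = ("gel_baseline", "m2_like", "m1_like", "process_demo", "lattice_demo")

# Fixed stage ids for the counter-based seed-splitting rule.
_STAGE_IDS = {
    "field": 0,
    "curves": 1,
    "degrade": 2,
    "curves_degraded": 3,
    "processes": 4,
    "lattice": 5,
    "fixtures": 6,
}


def stage_rng(global_seed: int, stage: str) -> np.random.Generator:
    """Generator for a named stage, derived from the global seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=global_seed, spawn_key=(_STAGE_IDS[stage],))
    )


@dataclass
class ExperimentConfig:
    """Complete parameterization of one synthetic experiment."""

    scenario: str = "gel_baseline"
    seed: int = 0
    alpha: float = 0.05
    out_dir: str | None = None

    # exponent field / percolation map
    map_shape: tuple[int, int] = (96, 96)
    f_mean: float = 2.0
    f_sd: float = 0.2
    correlation_length_px: float = 1.5
    pixel_size_m: float = 5e-6
    p: float = 0.447
    p_c: float = 0.347
    prefactor_Pa: float = 3e4

    # measurement model
    probe_radius_m: float = 5e-6
    poisson_ratio: float = 0.5
    spring_constant_N_per_m: float = 0.01
    setpoint_N: float = 2e-9
    noise_sd_N: float = 5e-11
    n_points_per_curve: int = 128
    fit_curves: bool = True

    # degradation (m1_like)
    degrade_fraction: float = 0.3
    degrade_severity: float = 5.0
    patch_radius_px: int = 3

    # generative processes demo
    recursion_noise_sd: float = 0.05
    recursion_steps: int = 200
    additive_x0: float = 30.0
    additive_noise_sd: float = 1.0
    additive_steps: int = 100
    n_replicates: int = 800
    kinetics_a_bar: float = 0.5
    kinetics_noise_sd: float = 0.3
    kinetics_dt: float = 0.01
    kinetics_steps: int = 100

    # lattice demo
    lattice_side: int = 14
    lattice_p_values: tuple[float, ...] = (0.55, 0.6, 0.65, 0.7, 0.75, 0.8, 0.85)
    lattice_seeds_per_p: int = 3
    lattice_regimes: tuple[tuple[float, float], ...] = ((1.0, 1.0), (1.0, 0.02))

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise DomainError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        self.map_shape = tuple(int(v) for v in self.map_shape)
        self.lattice_p_values = tuple(float(v) for v in self.lattice_p_values)
        self.lattice_regimes = tuple(
            (float(a), float(b)) for a, b in self.lattice_regimes
        )

    @property
    def probe(self) -> ProbeSpec:
        return ProbeSpec(
            radius_m=self.probe_radius_m,
            poisson_ratio=self.poisson_ratio,
            spring_constant_N_per_m=self.spring_constant_N_per_m,
        )

    @property
    def percolation(self) -> PercolationParams:
        return PercolationParams(p=self.p, p_c=self.p_c, prefactor_Pa=self.prefactor_Pa)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ExperimentReport:
    """Deterministic record of an experiment: config, per-stage results, provenance."""

    config: dict
    results: dict
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"config": self.config, "results": self.results, "provenance": self.provenance},
            sort_keys=True,
            indent=2,
        )

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path


def fit_map_from_curves(
    true_moduli_Pa: np.ndarray,
    probe: ProbeSpec,
    noise_sd_N: float,
    n_points: int,
    rng: np.random.Generator,
    setpoint_N: float = 2e-9,
) -> np.ndarray:
    """Synthesize one force curve per modulus and fit each back to a modulus."""
    flat_true = np.asarray(true_moduli_Pa, dtype=float).ravel()
    fitted = np.empty_like(flat_true)
    for i, e_true in enumerate(flat_true):
        curve = generate_force_curve(
            e_true,
            probe=probe,
            noise_sd_N=noise_sd_N,
            n_points=n_points,
            setpoint_N=setpoint_N,
            seed=rng,
        )
        fitted[i] = fit_hertz(curve).youngs_modulus_Pa
    return fitted.reshape(np.asarray(true_moduli_Pa).shape)


def _sample_result(true_vals, fitted_vals, verdict) -> dict:
    rel_err = np.abs(fitted_vals - true_vals) / true_vals
    return {
        "classification": verdict.classification,
        "shapiro_p_log": verdict.shapiro_p_log,
        "shapiro_p_linear": verdict.shapiro_p_linear,
        "ks_p_lognormal": verdict.ks_p_lognormal,
        "mean_Pa": float(fitted_vals.mean()),
        "sd_Pa": float(fitted_vals.std(ddof=1)),
        "median_rel_error": float(np.median(rel_err)),
        "n_pixels": int(fitted_vals.size),
    }


def _run_gel(config: ExperimentConfig, degraded: bool) -> dict:
    """Field -> map -> (degrade) -> per-pixel curves -> fits -> verdicts.

    Measurement and classification operate on a decorrelated (strided)
    subsample of pixels: the normality tests assume independent
    observations, and the subsample is what a spatially thinned
    force-volume scan would record.
    """
    try:
        fld = sample_exponent_field(
            shape=config.map_shape,
            f_mean=config.f_mean,
            f_sd=config.f_sd,
            correlation_length_px=config.correlation_length_px,
            pixel_size_m=config.pixel_size_m,
            seed=stage_rng(config.seed, "field"),
        )
        base_map = elasticity_from_percolation(fld, config.percolation)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise StageError("field", exc) from exc

    rows, cols = decorrelated_indices(
        config.map_shape, config.correlation_length_px, stage_rng(config.seed, "field")
    )

    out: dict = {}
    maps = {"m2": base_map}
    if degraded:
        try:
            maps["m1"] = degrade_map(
                base_map,
                mode="patch_degradation",
                fraction=config.degrade_fraction,
                severity=config.degrade_severity,
                patch_radius_px=config.patch_radius_px,
                seed=stage_rng(config.seed, "degrade"),
            )
        except Exception as exc:  # noqa: BLE001
            raise StageError("degrade", exc) from exc

    fitted = {}
    for name, true_map in maps.items():
        stage = "curves" if name == "m2" else "curves_degraded"
        true_vals = true_map.moduli_Pa[rows, cols].ravel()
        try:
            if config.fit_curves:
                fit_vals = fit_map_from_curves(
                    true_vals,
                    config.probe,
                    config.noise_sd_N,
                    config.n_points_per_curve,
                    stage_rng(config.seed, stage),
                    setpoint_N=config.setpoint_N,
                )
            else:
                fit_vals = true_vals
            verdict = classify_distribution(fit_vals, alpha=config.alpha, seed=config.seed)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError(stage, exc) from exc
        fitted[name] = fit_vals
        out[name] = _sample_result(true_vals, fit_vals, verdict)

    if degraded:
        comp = compare_groups(fitted["m2"], fitted["m1"])
        out["comparison"] = {
            "u_statistic": comp.u_statistic,
            "p_value": comp.p_value,
            "summary": comp.summary(),
        }
    return out


def _run_processes(config: ExperimentConfig) -> dict:
    rng = stage_rng(config.seed, "processes")
    mult = simulate_recursion(
        RecursionSpec(
            x0=1.0,
            n_steps=config.recursion_steps,
            noise_sd=config.recursion_noise_sd,
            mode="multiplicative",
        ),
        n_replicates=config.n_replicates,
        seed=rng,
    )
    add = simulate_recursion(
        RecursionSpec(
            x0=config.additive_x0,
            n_steps=config.additive_steps,
            noise_sd=config.additive_noise_sd,
            mode="additive",
        ),
        n_replicates=config.n_replicates,
        seed=rng,
    )
    kin = simulate_kinetics(
        KineticSpec(
            c0=1.0,
            a_bar=config.kinetics_a_bar,
            noise_sd=config.kinetics_noise_sd,
            dt=config.kinetics_dt,
            n_steps=config.kinetics_steps,
        ),
        n_replicates=config.n_replicates,
        seed=rng,
    )

    def _verdict(values):
        pos = values[values > 0]
        v = classify_distribution(pos, alpha=config.alpha, seed=config.seed)
        return {
            "classification": v.classification,
            "shapiro_p_log": v.shapiro_p_log,
            "shapiro_p_linear": v.shapiro_p_linear,
            "ks_p_lognormal": v.ks_p_lognormal,
            "n_used": int(pos.size),
        }

    return {
        "multiplicative": {**_verdict(mult.values), "n_excluded": mult.n_excluded},
        "additive": _verdict(add.values),
        "kinetics": _verdict(kin.values),
    }


def _run_lattice(config: ExperimentConfig) -> dict:
    rng = stage_rng(config.seed, "lattice")
    out = {}
    for alpha, beta in config.lattice_regimes:
        samples = []
        for p in config.lattice_p_values:
            moduli = []
            for _ in range(config.lattice_seeds_per_p):
                net = build_lattice(
                    dimension=2,
                    side_length=config.lattice_side,
                    p=p,
                    alpha=alpha,
                    beta=beta,
                    seed=rng,
                )
                moduli.append(effective_modulus(net))
            mean_mod = float(np.mean(moduli))
            if mean_mod > 0:
                samples.append((p, mean_mod))
        est = estimate_critical_exponent(samples, p_c=config.p_c)
        lo, hi = est.confidence_interval()
        out[f"alpha={alpha:g}_beta={beta:g}"] = {
            "exponent": est.exponent,
            "stderr": est.stderr,
            "ci95": [lo, hi],
            "n_points": est.n,
        }
    return out


def run_experiment(config: ExperimentConfig) -> ExperimentReport:
    """Run one scenario end to end; deterministic for a fixed config."""
    if config.scenario in ("gel_baseline", "m2_like"):
        results = {config.scenario: _run_gel(config, degraded=False)}
    elif config.scenario == "m1_like":
        results = {"m1_like": _run_gel(config, degraded=True)}
    elif config.scenario == "process_demo":
        results = {"process_demo": _run_processes(config)}
    else:
        results = {"lattice_demo": _run_lattice(config)}

    report = ExperimentReport(
        config=config.to_dict(),
        results=results,
        provenance={"seed": config.seed, "package": "gelsig", "version": "0.1.0"},
    )
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.write(out / f"report_{config.scenario}_seed{config.seed}.json")
    return report


def generate_fixtures(kind: str, seed: int, out_dir) -> list[Path]:
    """Write small plain-text fixtures with ground truth in JSON sidecars."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = stage_rng(seed, "fixtures")
    written: list[Path] = []

    if kind == "force_curves":
        probe = ProbeSpec()
        for e in (100.0, 300.0, 1000.0):
            for noise, tag in ((0.0, "clean"), (5e-11, "noisy")):
                curve = generate_force_curve(
                    e, probe=probe, noise_sd_N=noise, n_points=64, seed=rng
                )
                written.append(
                    gio.write_force_curve(curve, out / f"curve_E{int(e)}_{tag}.csv")
                )
    elif kind == "maps":
        fld = sample_exponent_field(shape=(16, 16), seed=rng)
        base = elasticity_from_percolation(fld)
        degraded = degrade_map(base, seed=rng)
        written.append(gio.write_field(fld, out / "exponent_field.tsv"))
        written.append(gio.write_map(base, out / "map_baseline.tsv"))
        written.append(gio.write_map(degraded, out / "map_degraded.tsv"))
    elif kind == "ensembles":
        for mode in ("additive", "multiplicative"):
            spec = RecursionSpec(x0=30.0 if mode == "additive" else 1.0, mode=mode)
            ens = simulate_recursion(spec, n_replicates=256, seed=rng)
            written.append(
                gio.write_ensemble(
                    ens.values,
                    out / f"ensemble_{mode}.csv",
                    {"spec": asdict(spec), "seed": seed, "n_excluded": ens.n_excluded},
                )
            )
    elif kind == "lattices":
        for p, tag in ((1.0, "full"), (0.5, "diluted")):
            net = build_lattice(dimension=2, side_length=6, p=p, seed=rng)
            payload = {
                "dimension": net.dimension,
                "side_length": net.side_length,
                "p": net.p,
                "alpha": net.alpha,
                "beta": net.beta,
                "bonds": [
                    [int(a), int(b), int(e)]
                    for (a, b), e in zip(net.bonds, net.occupancy)
                ],
            }
            path = out / f"lattice_{tag}.json"
            path.write_text(json.dumps(payload, indent=2, sort_keys=True))
            written.append(path)
    else:
        raise DomainError(
            f"unknown fixture kind {kind!r}; choose force_curves|maps|ensembles|lattices"
        )
    return written
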
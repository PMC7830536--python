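"""Recursive and kinetic noise processes: when normal vs log-normal laws emerge.

Two discrete recursions contrast the central-limit mechanisms:

  additive        X_{j+1} = X_j + R_j          ->  X_n normal
  multiplicative  X_{j+1} = X_j (1 + R_j)      ->  log X_n approx normal

with R_j i.i.d. Gaussian. The multiplicative recursion is the small-noise
log-sum argument: log X_n = log X_0 + sum log(1 + R_j) ~ log X_0 + sum R_j.
The kinetic analogue is geometric growth with a fluctuating rate,
d log c / dt = a_bar + delta(t), integrated by Euler-Maruyama on the log so
concentrations stay positive by construction. A standardized-sum CLT demo
rounds out the picture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError

__all__ = [
    "RecursionSpec",
    "KineticSpec",
    "RecursionEnsemble",
    "KineticEnsemble",
    "CLTDemoResult",
    "simulate_recursion",
    "simulate_kinetics",
    "clt_demo",
]


@dataclass(frozen=True)
class RecursionSpec:
    """Parameters of an additive or multiplicative Gaussian recursion."""

    x0: float = 1.0
    n_steps: int = 100
    noise_sd: float = 0.05
    mode: str = "multiplicative"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("additive", "multiplicative"):
            raise DomainError(f"mode must be additive|multiplicative, got {self.mode!r}")
        if self.n_steps < 1:
            raise DomainError("n_steps must be >= 1")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")
        if self.mode == "multiplicative" and self.noise_sd >= 1.0 / 3.0:
            raise DomainError(
                "multiplicative noise_sd must be < 1/3 so 1 + R_j stays "
                "positive with overwhelming probability"
            )


@dataclass(frozen=True)
class KineticSpec:
    """Geometric kinetics d log c = (a_bar + delta(t)) dt with white noise delta."""

    c0: float = 1.0
    a_bar: float = 0.5
    noise_sd: float = 0.3
    dt: float = 0.01
    n_steps: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.c0 > 0:
            raise DomainError("c0 must be strictly positive")
        if not self.dt > 0:
            raise DomainError("dt must be strictly positive")
        if self.n_steps < 1:
            raise DomainError("n_steps must be >= 1")
        if self.noise_sd < 0:
            raise DomainError("noise_sd must be >= 0")


@dataclass
class RecursionEnsemble:
    """Terminal values X_n across replicates, with exclusion diagnostics.

    Multiplicative trajectories whose factor 1 + R_j ever becomes
    non-positive are excluded (and counted) rather than reflected, keeping
    the product recursion literal.
    """

    values: np.ndarray
    spec: RecursionSpec
    n_requested: int
    n_excluded: int


@dataclass
class KineticEnsemble:
    """Terminal concentrations c(t_end) across replicates."""

    values: np.ndarray
    spec: KineticSpec
    t_end: float


def simulate_recursion(
    spec: RecursionSpec,
    n_replicates: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> RecursionEnsemble:
    """Simulate terminal values of the recursion for an ensemble of replicates.

    ``seed`` overrides ``spec.seed`` when given.
    """
    if n_replicates < 1:
        raise DomainError("n_replicates must be >= 1")
    if seed is None:
        seed = spec.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if spec.noise_sd == 0:
        values = np.full(n_replicates, float(spec.x0))
        return RecursionEnsemble(values, spec, n_replicates, 0)

    steps = rng.normal(0.0, spec.noise_sd, size=(n_replicates, spec.n_steps))
    if spec.mode == "additive":
        values = spec.x0 + steps.sum(axis=1)
        return RecursionEnsemble(values, spec, n_replicates, 0)

    factors = 1.0 + steps
    valid = np.all(factors > 0, axis=1)
    values = spec.x0 * np.exp(np.log(factors[valid]).sum(axis=1))
    return RecursionEnsemble(values, spec, n_replicates, int((~valid).sum()))


def simulate_kinetics(
    spec: KineticSpec,
    n_replicates: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> KineticEnsemble:
    """Euler-Maruyama ensemble of c(t_end) for the log-space kinetics.

    Noise increments are N(0, noise_sd^2 dt) so the integrated fluctuation
    has variance noise_sd^2 t; with noise_sd = 0 the scheme reproduces
    c0 exp(a_bar t) exactly (the drift integrates exactly on the log scale).
    """
    if n_replicates < 1:
        raise DomainError("n_replicates must be >= 1")
    if seed is None:
        seed = spec.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    t_end = spec.dt * spec.n_steps
    log_c = np.full(n_replicates, np.log(spec.c0)) + spec.a_bar * t_end
    if spec.noise_sd > 0:
        increments = rng.normal(
            0.0, spec.noise_sd * np.sqrt(spec.dt), size=(n_replicates, spec.n_steps)
        )
        log_c = log_c + increments.sum(axis=1)
    return KineticEnsemble(np.exp(log_c), spec, t_end)


_FAMILIES = {
    "normal": (lambda rng, size: rng.standard_normal(size), 0.0, 1.0),
    "bernoulli": (lambda rng, size: rng.random(size) < 0.5, 0.5, 0.25),
    "uniform": (lambda rng, size: rng.random(size), 0.5, 1.0 / 12.0),
    "exponential": (lambda rng, size: rng.exponential(1.0, size), 1.0, 1.0),
    "lognormal_skewed": (
        lambda rng, size: rng.lognormal(0.0, 1.5, size),
        float(np.exp(1.5**2 / 2)),
        float((np.exp(1.5**2) - 1) * np.exp(1.5**2)),
    ),
    "constant": (lambda rng, size: np.ones(size), 1.0, 0.0),
}


@dataclass
class CLTDemoResult:
    """Standardized-sum ensemble with a Shapiro-Wilk normality verdict."""

    samples: np.ndarray
    family: str
    n_summands: int
    shapiro_W: float
    shapiro_p: float
    normal: bool


def clt_demo(
    distribution_family: str = "bernoulli",
    n_summands: int = 1000,
    n_replicates: int = 1000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
) -> CLTDemoResult:
    """Standardize sums of i.i.d. draws and test the ensemble for normality.

    Returns samples of sum(X_j - E X_j)/sqrt(n sigma^2); for finite-variance
    families these converge in law to N(0, 1).
    """
    if distribution_family not in _FAMILIES:
        raise DomainError(
            f"unknown family {distribution_family!r}; choose from {sorted(_FAMILIES)}"
        )
    if n_summands < 1 or n_replicates < 8:
        raise DomainError("need n_summands >= 1 and n_replicates >= 8")
    sampler, mean, var = _FAMILIES[distribution_family]
    if var == 0:
        raise DomainError("zero-variance family is degenerate for the CLT")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = sampler(rng, (n_replicates, n_summands)).astype(float)
    sums = (draws - mean).sum(axis=1) / np.sqrt(n_summands * var)
    W, p = stats.shapiro(sums)
    return CLTDemoResult(
        samples=sums,
        family=distribution_family,
        n_summands=n_summands,
        shapiro_W=float(W),
        shapiro_p=float(p),
        normal=bool(p > alpha),
    )
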
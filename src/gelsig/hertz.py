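"""Hertzian contact mechanics for spherical-probe AFM indentation.

Forward model, synthetic force-curve generation, and inversion of curves to
Young's moduli. The contact model is the classical Hertz relation for a
rigid sphere of radius ``R`` indenting an incompressible elastic half-space:

    F = 4 sqrt(R) E / (3 (1 - nu^2)) * delta^(3/2)

with ``delta`` the indentation depth and ``nu`` the sample Poisson ratio.
Adhesion is assumed negligible relative to the force setpoint, and
indentation is kept well below the probe radius so the parabolic
approximation of the sphere holds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import DomainError, FitFailureError, HertzValidityWarning, NoContactError

__all__ = [
    "ProbeSpec",
    "ForceCurve",
    "HertzFit",
    "hertz_force",
    "hertz_prefactor",
    "generate_force_curve",
    "fit_hertz",
]


@dataclass(frozen=True)
class ProbeSpec:
    """Spherical AFM probe: bead radius, sample Poisson ratio, cantilever stiffness.

    Defaults correspond to a 5 um borosilicate bead on a soft cantilever
    (nominal 0.01 N/m) indenting an incompressible gel (nu = 0.5).
    """

    radius_m: float = 5e-6
    poisson_ratio: float = 0.5
    spring_constant_N_per_m: float = 0.01

    def __post_init__(self) -> None:
        if not self.radius_m > 0:
            raise DomainError(f"probe radius must be positive, got {self.radius_m}")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise DomainError(
                f"Poisson ratio must lie in [0, 0.5], got {self.poisson_ratio}"
            )
        if not self.spring_constant_N_per_m > 0:
            raise DomainError("spring constant must be positive")


def hertz_prefactor(youngs_modulus_Pa: float, probe: ProbeSpec) -> float:
    """Return C such that F = C * delta^(3/2) for the given modulus and probe."""
    if youngs_modulus_Pa < 0:
        raise DomainError(f"Young's modulus must be >= 0, got {youngs_modulus_Pa}")
    nu = probe.poisson_ratio
    return 4.0 * np.sqrt(probe.radius_m) * youngs_modulus_Pa / (3.0 * (1.0 - nu**2))


def hertz_force(youngs_modulus_Pa, indentation_m, probe: ProbeSpec = ProbeSpec()):
    """Hertz contact force (N) for indentation depth ``indentation_m`` (m).

    Accepts scalar or array indentation; zero indentation gives zero force.
    Negative modulus or indentation is a domain error.
    """
    delta = np.asarray(indentation_m, dtype=float)
    if np.any(delta < 0):
        raise DomainError("indentation must be non-negative")
    force = hertz_prefactor(youngs_modulus_Pa, probe) * delta**1.5
    return force if delta.ndim else float(force)


@dataclass
class ForceCurve:
    """One indentation event: force vs tip-sample separation plus probe metadata.

    ``separation_m`` is strictly monotone (time-ordered): increasing for a
    retraction curve, decreasing for an approach. Indentation is implicit,
    delta = max(contact_point - separation, 0).
    """

    separation_m: np.ndarray
    force_N: np.ndarray
    direction: str = "retraction"
    probe: ProbeSpec = field(default_factory=ProbeSpec)
    setpoint_N: float = 2e-9
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.separation_m = np.asarray(self.separation_m, dtype=float)
        self.force_N = np.asarray(self.force_N, dtype=float)
        if self.direction not in ("approach", "retraction"):
            raise DomainError(f"direction must be approach|retraction, got {self.direction!r}")
        if self.separation_m.shape != self.force_N.shape:
            raise DomainError("separation and force arrays must have equal length")
        if self.separation_m.size < 8:
            raise DomainError("a force curve needs at least 8 samples")
        diffs = np.diff(self.separation_m)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise DomainError("separation must be strictly monotone")
        if self.force_N.max() > self.setpoint_N * 1.5:
            raise DomainError(
                "maximum force exceeds 1.5x the setpoint; curve is not physical"
            )

    def __len__(self) -> int:
        return int(self.separation_m.size)


@dataclass(frozen=True)
class HertzFit:
    """Result of inverting a force curve with the Hertz model."""

    youngs_modulus_Pa: float
    contact_point_m: float
    baseline_N: float
    rss: float
    n_contact_points: int

    def __post_init__(self) -> None:
        if not self.youngs_modulus_Pa > 0:
            raise DomainError("fitted modulus must be strictly positive")
        if self.n_contact_points < 4:
            raise DomainError("a Hertz fit needs at least 4 contact samples")
        if self.rss < 0:
            raise DomainError("residual sum of squares cannot be negative")


def generate_force_curve(
    youngs_modulus_Pa: float,
    probe: ProbeSpec = ProbeSpec(),
    contact_point_m: float = 0.0,
    baseline_N: float = 0.0,
    noise_sd_N: float = 0.0,
    n_points: int = 256,
    max_indentation_m: float | None = None,
    setpoint_N: float = 2e-9,
    direction: str = "retraction",
    seed: int | np.random.Generator | None = None,
) -> ForceCurve:
    """Synthesize a force curve for a sample of known modulus.

    The separation axis spans symmetric in- and out-of-contact ranges around
    the contact point. When ``max_indentation_m`` is None the depth is chosen
    so the peak Hertz force equals the setpoint, clipped to 0.4 R to respect
    the small-indentation validity of the model. Noise is additive i.i.d.
    Gaussian on force. The true modulus and generation parameters are stored
    in ``metadata`` so round-trip tests can use them as ground truth.
    """
    if not youngs_modulus_Pa > 0:
        raise DomainError("modulus must be strictly positive for curve generation")
    if noise_sd_N < 0:
        raise DomainError("noise standard deviation must be >= 0")
    if n_points < 16:
        raise DomainError("need at least 16 samples per synthetic curve")

    pref = hertz_prefactor(youngs_modulus_Pa, probe)
    if max_indentation_m is None:
        depth = min((setpoint_N / pref) ** (2.0 / 3.0), 0.4 * probe.radius_m)
    else:
        depth = float(max_indentation_m)
        if depth <= 0:
            raise DomainError("max indentation must be positive")
        if depth > probe.radius_m / 2:
            warnings.warn(
                "max indentation exceeds half the probe radius; the Hertz "
                "small-indentation approximation is unreliable",
                HertzValidityWarning,
                stacklevel=2,
            )

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    separation = np.linspace(contact_point_m - depth, contact_point_m + depth, n_points)
    delta = np.clip(contact_point_m - separation, 0.0, None)
    force = baseline_N + pref * delta**1.5
    if noise_sd_N > 0:
        force = force + rng.normal(0.0, noise_sd_N, size=n_points)
    if direction == "approach":
        separation = separation[::-1]
        force = force[::-1]

    return ForceCurve(
        separation_m=separation,
        force_N=force,
        direction=direction,
        probe=probe,
        setpoint_N=setpoint_N,
        metadata={
            "true_youngs_modulus_Pa": float(youngs_modulus_Pa),
            "contact_point_m": float(contact_point_m),
            "baseline_N": float(baseline_N),
            "noise_sd_N": float(noise_sd_N),
            "max_indentation_m": float(depth),
            "seed": None if isinstance(seed, np.random.Generator) else seed,
        },
    )


def _profiled_rss(cp: np.ndarray, s: np.ndarray, f: np.ndarray):
    """RSS of F ~ b + c*max(cp - s, 0)^1.5, (b, c) profiled out in closed form.

    ``cp`` may be an array of candidate contact points; returns (rss, b, c)
    arrays of the same shape. Candidates whose optimal amplitude is
    non-positive are assigned infinite RSS.
    """
    cp = np.atleast_1d(np.asarray(cp, dtype=float))
    x = np.clip(cp[:, None] - s[None, :], 0.0, None) ** 1.5
    n = s.size
    sx = x.sum(axis=1)
    sxx = np.einsum("ij,ij->i", x, x)
    sf = f.sum()
    sxf = x @ f
    denom = n * sxx - sx**2
    with np.errstate(divide="ignore", invalid="ignore"):
        c = (n * sxf - sx * sf) / denom
        b = (sf - c * sx) / n
        rss = (f @ f) - b * sf - c * sxf
    bad = (denom <= 0) | ~np.isfinite(rss) | (c <= 0)
    rss = np.where(bad, np.inf, np.maximum(rss, 0.0))
    return rss, b, c


def fit_hertz(curve: ForceCurve, n_grid: int = 96) -> HertzFit:
    """Invert a force curve to a Young's modulus by least squares.

    Jointly estimates (modulus, contact point, baseline) on the delta^(3/2)
    model. The baseline and Hertz amplitude enter linearly and are profiled
    out in closed form; the contact point is located on a coarse grid and
    refined by bounded scalar minimization. The fit is invariant to adding a
    constant force offset and to rigid shifts of the separation axis.
    """
    order = np.argsort(curve.separation_m)
    s = curve.separation_m[order]
    f = curve.force_N[order]
    n = s.size

    # Baseline and noise floor from the out-of-contact quarter (largest separations).
    far = f[-max(n // 4, 4):]
    b0 = float(np.median(far))
    mad = 1.4826 * float(np.median(np.abs(far - b0)))
    span = f.max() - b0
    if span <= 0:
        raise NoContactError("force never rises above the baseline")

    # Smooth with a short moving average and threshold against the noise
    # floor of the *smoothed* trace, so soft samples whose peak force sits
    # near the raw noise level are still detected.
    w = max(3, n // 16)
    kernel = np.ones(w) / w
    f_smooth = np.convolve(f, kernel, mode="same")
    threshold = b0 + max(3.0 * mad / np.sqrt(w), 1e-3 * span)
    above = np.nonzero(f_smooth > threshold)[0]
    if above.size == 0:
        raise NoContactError("no samples above the contact detection threshold")

    lo_i, hi_i = 4, n - 3  # keep >=4 contact points and some non-contact points
    if lo_i >= hi_i:
        raise NoContactError("curve too short to bracket a contact point")
    candidates = np.linspace(s[lo_i], s[hi_i], n_grid)
    rss, _, _ = _profiled_rss(candidates, s, f)
    if not np.isfinite(rss).any():
        raise NoContactError("no candidate contact point yields a positive modulus")
    best = int(np.argmin(rss))
    h = candidates[1] - candidates[0]
    lo = max(candidates[best] - h, s[lo_i])
    hi = min(candidates[best] + h, s[hi_i])

    res = minimize_scalar(
        lambda cp: float(_profiled_rss(cp, s, f)[0][0]),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": max((s[-1] - s[0]) * 1e-9, 1e-16)},
    )
    if not res.success:
        raise FitFailureError(f"contact-point refinement failed: {res.message}")
    cp = float(res.x)
    rss_v, b_v, c_v = _profiled_rss(cp, s, f)
    rss_f, baseline, amplitude = float(rss_v[0]), float(b_v[0]), float(c_v[0])
    if not np.isfinite(rss_f) or amplitude <= 0:
        raise NoContactError("refined fit has non-positive Hertz amplitude")

    modulus = amplitude / hertz_prefactor(1.0, curve.probe)
    n_contact = int(np.count_nonzero(s < cp))
    if n_contact < 4:
        raise NoContactError("fewer than 4 samples in the contact region")
    return HertzFit(
        youngs_modulus_Pa=modulus,
        contact_point_m=cp,
        baseline_N=baseline,
        rss=rss_f,
        n_contact_points=n_contact,
    )
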
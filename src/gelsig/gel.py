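"""Generative physics of gel elasticity.

A polymeric gel near the sol-gel transition has an elastic modulus that
vanishes as a power law of the distance to the percolation threshold,

    E = A |p - p_c|^f,

with a critical exponent ``f`` that is only weakly universal: it depends on
microscopic details such as the bond stretching/bending stiffness ratio.
Swelling of a biopolymer network heterogeneously bends and stretches bonds,
so ``f`` acquires a smooth spatial dependence and, by the central limit
behaviour of many local contributions, a Gaussian law. Taking logs,

    log E = log A + f log|p - p_c|,

i.e. the log-modulus is an affine image of a Gaussian field: the modulus is
exactly log-normal. This module builds those fields and maps, the
node-density (rubber elasticity) relation E ~ c k T Q^(-1/3), and
degradation perturbations that destroy log-normality (emulating
matrix-degrading, pro-inflammatory macrophage activity) or preserve it
(uniform softening, the negative control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.constants import k as BOLTZMANN_K
from scipy.ndimage import gaussian_filter

from .errors import DomainError, FieldDegeneracyWarning, SingularThresholdError

__all__ = [
    "NodeDensityState",
    "PercolationParams",
    "ExponentField",
    "ElasticityMap",
    "modulus_from_density",
    "sample_exponent_field",
    "elasticity_from_percolation",
    "degrade_map",
    "decorrelated_indices",
    "decorrelated_subsample",
]


@dataclass(frozen=True)
class NodeDensityState:
    """Node density c (m^-3), temperature T (K) and swelling ratio Q of a gel."""

    concentration: float
    temperature_K: float
    swelling_ratio: float

    def __post_init__(self) -> None:
        for name in ("concentration", "temperature_K", "swelling_ratio"):
            if not getattr(self, name) > 0:
                raise DomainError(f"{name} must be strictly positive")


def modulus_from_density(state: NodeDensityState) -> float:
    """Rubber-elasticity estimate of the modulus, E = c k T Q^(-1/3) (Pa)."""
    return (
        state.concentration
        * BOLTZMANN_K
        * state.temperature_K
        * state.swelling_ratio ** (-1.0 / 3.0)
    )


@dataclass(frozen=True)
class PercolationParams:
    """Bond fraction p, critical threshold p_c and amplitude A of E = A|p-p_c|^f.

    Defaults: p_c = 0.347 (2D triangular bond percolation), p chosen so
    |p - p_c| = 0.1, and A fixed so the median modulus at f = 2 is 300 Pa,
    the order of magnitude measured on collagen scaffolds.
    """

    p: float = 0.447
    p_c: float = 0.347
    prefactor_Pa: float = 3e4

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0 and 0.0 < self.p_c < 1.0):
            raise DomainError("p and p_c must lie in (0, 1)")
        if self.p == self.p_c:
            raise SingularThresholdError("p equals the percolation threshold")
        if not self.prefactor_Pa > 0:
            raise DomainError("prefactor must be strictly positive")

    @property
    def log_distance(self) -> float:
        """log|p - p_c|; strictly negative since |p - p_c| < 1."""
        return float(np.log(abs(self.p - self.p_c)))


@dataclass
class ExponentField:
    """Stationary Gaussian realization of the critical exponent f on a 2D grid."""

    values: np.ndarray
    f_mean: float
    f_sd: float
    correlation_length_px: float
    pixel_size_m: float = 5e-6
    seed: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise DomainError("exponent field must be a 2D grid")
        if not np.all(np.isfinite(self.values)):
            raise DomainError("exponent field must be finite")
        if self.f_sd < 0:
            raise DomainError("f_sd must be >= 0")
        if self.correlation_length_px < 1:
            raise DomainError(
                "correlation length must be at least one pixel (inhomogeneity "
                "scale must exceed the node spacing)"
            )


@dataclass
class ElasticityMap:
    """2D grid of Young's moduli (Pa) with pixel spacing and provenance."""

    moduli_Pa: np.ndarray
    pixel_size_m: float = 5e-6
    provenance: str = "percolation_simulation"
    metadata: dict = field(default_factory=dict)
    degraded_mask: np.ndarray | None = None

    _PROVENANCES = ("percolation_simulation", "degraded_simulation", "fitted_from_curves")

    def __post_init__(self) -> None:
        self.moduli_Pa = np.asarray(self.moduli_Pa, dtype=float)
        if self.moduli_Pa.ndim != 2:
            raise DomainError("elasticity map must be a 2D grid")
        if not np.all(np.isfinite(self.moduli_Pa)) or np.any(self.moduli_Pa <= 0):
            raise DomainError("all moduli must be strictly positive and finite")
        if self.provenance not in self._PROVENANCES:
            raise DomainError(f"unknown provenance {self.provenance!r}")

    @property
    def shape(self):
        return self.moduli_Pa.shape


def sample_exponent_field(
    shape: tuple[int, int] = (64, 64),
    f_mean: float = 2.0,
    f_sd: float = 0.2,
    correlation_length_px: float = 1.5,
    pixel_size_m: float = 5e-6,
    seed: int | np.random.Generator | None = None,
) -> ExponentField:
    """Sample a spatially correlated Gaussian exponent field.

    Construction: white Gaussian noise convolved with a periodic Gaussian
    kernel of width ``correlation_length_px``, then rescaled by the exact
    kernel norm so the marginal law is N(f_mean, f_sd^2) — the smoothing is
    linear, so joint Gaussianity and the marginal are exact, not asymptotic.
    """
    shape = tuple(int(v) for v in shape)
    if len(shape) != 2 or min(shape) < 4:
        raise DomainError("field shape must be 2D and at least 4x4")
    if f_sd < 0:
        raise DomainError("f_sd must be >= 0")
    if correlation_length_px < 1:
        raise DomainError("correlation length must be >= 1 pixel")
    if correlation_length_px >= min(shape) / 2:
        warnings.warn(
            "correlation length is >= half the grid; the field degenerates "
            "toward a constant",
            FieldDegeneracyWarning,
            stacklevel=2,
        )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if f_sd == 0:
        values = np.full(shape, f_mean, dtype=float)
    else:
        white = rng.standard_normal(shape)
        smooth = gaussian_filter(white, sigma=correlation_length_px, mode="wrap")
        # Exact variance of the smoothed field = sum of squared kernel weights.
        impulse = np.zeros(shape)
        impulse[0, 0] = 1.0
        kernel = gaussian_filter(impulse, sigma=correlation_length_px, mode="wrap")
        norm = np.sqrt(np.sum(kernel**2))
        values = f_mean + f_sd * smooth / norm
    return ExponentField(
        values=values,
        f_mean=f_mean,
        f_sd=f_sd,
        correlation_length_px=correlation_length_px,
        pixel_size_m=pixel_size_m,
        seed=None if isinstance(seed, np.random.Generator) else seed,
    )


def elasticity_from_percolation(
    exponent_field: ExponentField, params: PercolationParams = PercolationParams()
) -> ElasticityMap:
    """Map an exponent field to moduli via log E = log A + f log|p - p_c|.

    Because the log-modulus is an affine function of a Gaussian field, the
    resulting moduli have exactly log-normal marginals with
    mean(log E) = log A + f_mean log|p - p_c| and
    sd(log E) = f_sd |log|p - p_c||.
    """
    if abs(params.p - params.p_c) >= 1.0:
        raise DomainError("|p - p_c| must be < 1 so that log|p - p_c| < 0")
    log_e = np.log(params.prefactor_Pa) + exponent_field.values * params.log_distance
    return ElasticityMap(
        moduli_Pa=np.exp(log_e),
        pixel_size_m=exponent_field.pixel_size_m,
        provenance="percolation_simulation",
        metadata={
            "p": params.p,
            "p_c": params.p_c,
            "prefactor_Pa": params.prefactor_Pa,
            "f_mean": exponent_field.f_mean,
            "f_sd": exponent_field.f_sd,
            "correlation_length_px": exponent_field.correlation_length_px,
            "seed": exponent_field.seed,
        },
    )


def decorrelated_indices(
    shape: tuple[int, int],
    correlation_length_px: float,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Grid indices of a spatially thinned (approximately independent) subsample.

    i.i.d.-based tests (Shapiro-Wilk, KS) over-reject on spatially correlated
    fields, so distribution verdicts are taken on a strided subsample with
    stride 4x the correlation length (pair correlation < 2% for a Gaussian
    kernel) and a seeded random phase. Returns (row_idx, col_idx) open grids
    suitable for fancy indexing.
    """
    stride = max(int(np.ceil(4.0 * correlation_length_px)), 1)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    i0 = int(rng.integers(0, stride))
    j0 = int(rng.integers(0, stride))
    rows = np.arange(i0, shape[0], stride)
    cols = np.arange(j0, shape[1], stride)
    return rows[:, None], cols[None, :]


def decorrelated_subsample(
    values: np.ndarray,
    correlation_length_px: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Flattened, approximately independent subsample of a correlated 2D field."""
    rows, cols = decorrelated_indices(values.shape, correlation_length_px, seed)
    return np.asarray(values)[rows, cols].ravel()


def _disk_mask(shape, centers, radius):
    """Boolean union of disks of given radius at integer centers."""
    rows = np.arange(shape[0])[:, None]
    cols = np.arange(shape[1])[None, :]
    mask = np.zeros(shape, dtype=bool)
    for r0, c0 in centers:
        mask |= (rows - r0) ** 2 + (cols - c0) ** 2 <= radius**2
    return mask


def degrade_map(
    emap: ElasticityMap,
    mode: str = "patch_degradation",
    fraction: float = 0.3,
    severity: float = 5.0,
    patch_radius_px: int = 3,
    seed: int | np.random.Generator | None = None,
) -> ElasticityMap:
    """Perturb an elasticity map, emulating enzymatic matrix degradation.

    ``patch_degradation`` divides the modulus by ``severity`` inside randomly
    placed disks until at least ``fraction`` of pixels is covered, producing
    a two-component mixture on the log scale that destroys log-normality for
    sufficient fraction and severity. ``global_softening`` divides every
    pixel by ``severity``; a pure log-location shift that preserves
    log-normality (negative control). The boolean degradation mask is kept
    as ground truth on the returned map.
    """
    if mode not in ("patch_degradation", "global_softening"):
        raise DomainError(f"unknown degradation mode {mode!r}")
    if not 0.0 <= fraction <= 1.0:
        raise DomainError("fraction must lie in [0, 1]")
    if not severity > 0:
        raise DomainError("severity must be strictly positive")

    meta = dict(emap.metadata)
    meta.update({"degrade_mode": mode, "fraction": fraction, "severity": severity})

    if mode == "global_softening":
        return ElasticityMap(
            moduli_Pa=emap.moduli_Pa / severity,
            pixel_size_m=emap.pixel_size_m,
            provenance="degraded_simulation",
            metadata=meta,
            degraded_mask=np.ones(emap.shape, dtype=bool),
        )

    if fraction == 0.0:
        return replace(
            emap,
            moduli_Pa=emap.moduli_Pa.copy(),
            metadata=dict(emap.metadata),
            degraded_mask=np.zeros(emap.shape, dtype=bool),
        )

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if patch_radius_px < 1:
        raise DomainError("patch radius must be >= 1 pixel")
    mask = np.zeros(emap.shape, dtype=bool)
    max_patches = 100 * int(np.ceil(fraction * mask.size / max(patch_radius_px**2, 1)))
    for _ in range(max(max_patches, 1000)):
        if mask.mean() >= fraction:
            break
        center = (rng.integers(0, emap.shape[0]), rng.integers(0, emap.shape[1]))
        mask |= _disk_mask(emap.shape, [center], patch_radius_px)

    moduli = np.where(mask, emap.moduli_Pa / severity, emap.moduli_Pa)
    meta["achieved_fraction"] = float(mask.mean())
    return ElasticityMap(
        moduli_Pa=moduli,
        pixel_size_m=emap.pixel_size_m,
        provenance="degraded_simulation",
        metadata=meta,
        degraded_mask=mask,
    )
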
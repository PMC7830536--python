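"""Distribution-type classification of elasticity samples and group comparison.

The classification mirrors standard practice in force-volume AFM analysis:
a sample is called log-normal when a Shapiro-Wilk test on the log scale AND
a Kolmogorov-Smirnov test against a fitted log-normal on the linear scale
both fail to reject; otherwise normal when Shapiro-Wilk on the linear scale
fails to reject; otherwise neither. Because the log-normal parameters are
estimated from the same sample, the naive KS p-value is conservative; the
default uses a Monte-Carlo (Lilliefors-type) null so rejection rates are
calibrated. The naive p-value remains available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DomainError, InsufficientSampleError, InsufficientVarianceError

__all__ = [
    "DistributionVerdict",
    "GroupComparison",
    "MapSummary",
    "classify_distribution",
    "compare_groups",
    "summarize_map",
    "plot_map_histograms",
]


@dataclass(frozen=True)
class DistributionVerdict:
    """Test statistics, p-values and the three-way distribution classification."""

    shapiro_W_log: float
    shapiro_p_log: float
    ks_D_lognormal: float
    ks_p_lognormal: float
    shapiro_p_linear: float
    alpha: float
    classification: str  # {log-normal, normal, neither}
    n: int

    def __post_init__(self) -> None:
        for name in ("shapiro_p_log", "ks_p_lognormal", "shapiro_p_linear"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.ks_D_lognormal <= 1.0:
            raise DomainError("KS D must lie in [0, 1]")
        if self.classification not in ("log-normal", "normal", "neither"):
            raise DomainError(f"unknown classification {self.classification!r}")


@dataclass(frozen=True)
class GroupComparison:
    """Mann-Whitney U comparison of two elasticity samples, with mean +/- sd."""

    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int

    def summary(self, unit: str = "Pa") -> str:
        return (
            f"group A: {self.mean_a:.1f} +/- {self.sd_a:.1f} {unit} (n={self.n_a}); "
            f"group B: {self.mean_b:.1f} +/- {self.sd_b:.1f} {unit} (n={self.n_b}); "
            f"Mann-Whitney U={self.u_statistic:.1f}, p={self.p_value:.3g}"
        )


def _ks_statistic_standardized(z_sorted: np.ndarray) -> np.ndarray:
    """KS D for rows of sorted standardized values against the standard normal."""
    if z_sorted.ndim == 1:
        z_sorted = z_sorted[None, :]
    n = z_sorted.shape[1]
    cdf = stats.norm.cdf(z_sorted)
    i = np.arange(1, n + 1)
    d_plus = (i / n - cdf).max(axis=1)
    d_minus = (cdf - (i - 1) / n).max(axis=1)
    return np.maximum(d_plus, d_minus)


def _lilliefors_null(n: int, n_resamples: int, rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo null of the KS D with location/scale fitted per resample.

    The fitted-normal KS statistic is pivotal in the location-scale family,
    so the null can be simulated from the standard normal regardless of the
    estimated parameters.
    """
    sims = rng.standard_normal((n_resamples, n))
    mu = sims.mean(axis=1, keepdims=True)
    sd = sims.std(axis=1, ddof=1, keepdims=True)
    return _ks_statistic_standardized(np.sort((sims - mu) / sd, axis=1))


def classify_distribution(
    sample,
    alpha: float = 0.05,
    ks_mode: str = "monte_carlo",
    n_resamples: int = 500,
    seed: int | np.random.Generator | None = 0,
) -> DistributionVerdict:
    """Classify a positive sample as log-normal, normal, or neither.

    Decision rule (log-normal takes priority): log-normal iff Shapiro-Wilk
    on the log scale and KS against the fitted log-normal both have
    p > alpha; else normal iff Shapiro-Wilk on the linear scale has
    p > alpha; else neither. ``ks_mode`` selects the Monte-Carlo
    (Lilliefors-type) null (default) or the naive KS p-value.
    """
    x = np.asarray(sample, dtype=float).ravel()
    if x.size < 20:
        raise InsufficientSampleError(f"need at least 20 observations, got {x.size}")
    if np.any(~np.isfinite(x)) or np.any(x <= 0):
        raise DomainError("sample must be finite and strictly positive (log required)")
    if np.std(x) == 0:
        raise InsufficientVarianceError("sample is constant; tests are undefined")
    if ks_mode not in ("monte_carlo", "naive"):
        raise DomainError(f"ks_mode must be monte_carlo|naive, got {ks_mode!r}")

    log_x = np.log(x)
    W_log, p_log = stats.shapiro(log_x)
    _, p_lin = stats.shapiro(x)

    mu = float(log_x.mean())
    sd = float(log_x.std(ddof=1))
    # KS of the sample against the fitted log-normal equals KS of log(x)
    # against the fitted normal (monotone transform preserves the ECDF gap).
    z = np.sort((log_x - mu) / sd)
    D = float(_ks_statistic_standardized(z)[0])
    if ks_mode == "naive":
        ks_p = float(stats.kstest(x, stats.lognorm(s=sd, scale=np.exp(mu)).cdf).pvalue)
    else:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        null = _lilliefors_null(x.size, n_resamples, rng)
        ks_p = float((1 + np.sum(null >= D)) / (n_resamples + 1))

    if p_log > alpha and ks_p > alpha:
        label = "log-normal"
    elif p_lin > alpha:
        label = "normal"
    else:
        label = "neither"
    return DistributionVerdict(
        shapiro_W_log=float(W_log),
        shapiro_p_log=float(p_log),
        ks_D_lognormal=D,
        ks_p_lognormal=ks_p,
        shapiro_p_linear=float(p_lin),
        alpha=alpha,
        classification=label,
        n=int(x.size),
    )


def compare_groups(sample_a, sample_b) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison with tie handling."""
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size < 8 or b.size < 8:
        raise InsufficientSampleError("both groups need at least 8 observations")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupComparison(
        mean_a=float(a.mean()),
        sd_a=float(a.std(ddof=1)),
        mean_b=float(b.mean()),
        sd_b=float(b.std(ddof=1)),
        u_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n_a=int(a.size),
        n_b=int(b.size),
    )


@dataclass
class MapSummary:
    """Publication-style summary of an elasticity map."""

    verdict: DistributionVerdict
    mean_Pa: float
    sd_Pa: float
    n: int
    linear_bin_edges: np.ndarray
    linear_counts: np.ndarray
    log_bin_edges: np.ndarray
    log_counts: np.ndarray


def summarize_map(emap, alpha: float = 0.05, subsample_seed=0, **classify_kwargs) -> MapSummary:
    """Flatten an elasticity map, classify its distribution, and bin histograms.

    When the map records a spatial correlation length in its metadata the
    verdict is computed on a decorrelated (strided) subsample, since the
    normality tests assume independent observations; the histograms always
    use the full map. Binning is Freedman-Diaconis on both the linear and
    the log scale, mirroring the usual linear/log panel pair of
    force-volume reports.
    """
    from .gel import decorrelated_subsample  # local import to avoid a cycle

    values = np.asarray(emap.moduli_Pa, dtype=float).ravel()
    corr = emap.metadata.get("correlation_length_px") if hasattr(emap, "metadata") else None
    if corr is not None and corr > 0:
        test_values = decorrelated_subsample(
            np.asarray(emap.moduli_Pa, dtype=float), corr, seed=subsample_seed
        )
    else:
        test_values = values
    verdict = classify_distribution(test_values, alpha=alpha, **classify_kwargs)
    lin_counts, lin_edges = np.histogram(values, bins="fd")
    log_counts, log_edges = np.histogram(np.log10(values), bins="fd")
    return MapSummary(
        verdict=verdict,
        mean_Pa=float(values.mean()),
        sd_Pa=float(values.std(ddof=1)),
        n=int(values.size),
        linear_bin_edges=lin_edges,
        linear_counts=lin_counts,
        log_bin_edges=log_edges,
        log_counts=log_counts,
    )


def plot_map_histograms(summary: MapSummary, path) -> None:
    """Two-panel histogram figure (linear and log10 scale) for a map summary.

    Mirrors the usual linear/log presentation of force-volume elasticity
    distributions, annotated with the classification verdict.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_lin, ax_log) = plt.subplots(1, 2, figsize=(9, 3.5))
    ax_lin.stairs(summary.linear_counts, summary.linear_bin_edges, fill=True,
                  color="steelblue")
    ax_lin.set_xlabel("E (Pa)")
    ax_lin.set_ylabel("count")
    ax_lin.set_title(f"linear scale (mean {summary.mean_Pa:.0f} "
                     f"$\\pm$ {summary.sd_Pa:.0f} Pa)")
    ax_log.stairs(summary.log_counts, summary.log_bin_edges, fill=True,
                  color="indianred")
    ax_log.set_xlabel("log10 E (Pa)")
    ax_log.set_title(f"log scale — verdict: {summary.verdict.classification}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
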
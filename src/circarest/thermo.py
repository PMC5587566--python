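"""Temperature threshold detection for the afternoon resting period.

Above a threshold temperature the afternoon break duration T_break starts
growing with the daily maximum temperature theta, while below it the two
are essentially unrelated.  The (theta, T_break) scatter of one city-year
is split into two clusters with normalised-cut (Shi-Malik) spectral
clustering on an RBF similarity graph; both coordinates are standardised
first (raw units, degC vs hours, would dominate the kernel) and the kernel
scale defaults to the 5th percentile of the pairwise distances — local
enough that two separated regimes are not bridged by the graph, yet global
enough to keep a continuous seasonal cloud connected.  The threshold theta* is
read off as the midpoint between the 95th percentile of theta in the cold
cluster and the 5th percentile in the warm cluster (robust to a few
mislabelled points); if those cross, the median of the overlap region is
used.  An alternative read-off (minimum theta of the warm cluster) is
available behind the ``rule`` flag.  Pearson correlations are then computed
separately below and above theta*.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist
from sklearn.cluster import SpectralClustering
from sklearn.metrics import silhouette_score

__all__ = [
    "ThermalClustering",
    "cluster_two_regimes",
    "threshold_temperature",
    "regime_correlations",
    "thermal_analysis",
    "kernel_scale_sweep",
]

MIN_POINTS = 30

#: Low-confidence guard: a normalised-cut split of a single isotropic
#: Gaussian cloud scores a silhouette of ~0.31-0.35, so splits below 0.35
#: are flagged; splinter cuts (a tiny cluster shaved off the edge of one
#: cloud) can score higher, so extreme imbalance is flagged as well.
LOW_CONFIDENCE_SILHOUETTE = 0.35
MIN_CLUSTER_FRACTION = 0.05

#: Pairwise-distance quantile defining the RBF kernel scale.
KERNEL_SCALE_QUANTILE = 0.05


@dataclass
class ThermalClustering:
    theta: np.ndarray
    t_break: np.ndarray
    days: np.ndarray
    labels: np.ndarray  # 0 = cold, 1 = warm
    theta_star: float
    silhouette: float
    low_confidence: bool
    r_below: float
    p_below: float
    r_above: float
    p_above: float

    @property
    def n_cold(self) -> int:
        return int(np.sum(self.labels == 0))

    @property
    def n_warm(self) -> int:
        return int(np.sum(self.labels == 1))


def cluster_two_regimes(
    theta, t_break, seed: int = 0, scale_factor: float = 1.0
) -> tuple[np.ndarray, float]:
    """Two-cluster spectral clustering of the standardised (theta, T_break) cloud.

    Returns ``(labels, silhouette)`` with label 0 for the cluster of lower
    mean temperature (cold) and 1 for the warmer one.  ``scale_factor``
    multiplies the quantile-based kernel scale (used by the sensitivity
    sweep).  Requires at least ``MIN_POINTS`` points; an all-identical
    cloud raises ``ValueError``.
    """
    theta = np.asarray(theta, dtype=float)
    t_break = np.asarray(t_break, dtype=float)
    if theta.size < MIN_POINTS:
        raise ValueError(f"need at least {MIN_POINTS} points, got {theta.size}")
    X = np.column_stack([theta, t_break])
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        if np.all(sd == 0):
            raise ValueError("all points identical; clustering is degenerate")
        sd = np.where(sd == 0, 1.0, sd)
    Z = (X - X.mean(axis=0)) / sd
    scale = float(np.quantile(pdist(Z), KERNEL_SCALE_QUANTILE)) * scale_factor
    if scale <= 0:
        raise ValueError("degenerate point cloud (zero median distance)")
    gamma = 1.0 / (2.0 * scale**2)
    model = SpectralClustering(
        n_clusters=2,
        affinity="rbf",
        gamma=gamma,
        assign_labels="kmeans",
        random_state=seed,
        n_init=10,
    )
    raw = model.fit_predict(Z)
    # orient labels: 0 = lower mean temperature
    mean0 = theta[raw == 0].mean() if np.any(raw == 0) else np.inf
    mean1 = theta[raw == 1].mean() if np.any(raw == 1) else np.inf
    labels = raw if mean0 <= mean1 else 1 - raw
    sil = float(silhouette_score(Z, labels)) if len(set(labels)) == 2 else -1.0
    return labels, sil


def threshold_temperature(theta, labels, rule: str = "percentile") -> float:
    """Read the threshold temperature off a two-cluster labelling.

    ``percentile`` (default): midpoint between the cold cluster's 95th
    theta percentile and the warm cluster's 5th; when they cross, the
    median theta of the overlap region.  ``min-warm``: minimum theta of the
    warm cluster.
    """
    theta = np.asarray(theta, dtype=float)
    labels = np.asarray(labels)
    cold = theta[labels == 0]
    warm = theta[labels == 1]
    if cold.size == 0 or warm.size == 0:
        raise ValueError("both clusters must be non-empty")
    if rule == "min-warm":
        return float(warm.min())
    if rule != "percentile":
        raise ValueError(f"unknown rule {rule!r}")
    hi_cold = float(np.percentile(cold, 95))
    lo_warm = float(np.percentile(warm, 5))
    if hi_cold <= lo_warm:
        return 0.5 * (hi_cold + lo_warm)
    overlap = theta[(theta >= lo_warm) & (theta <= hi_cold)]
    if overlap.size == 0:
        return 0.5 * (hi_cold + lo_warm)
    return float(np.median(overlap))


def regime_correlations(
    theta, t_break, theta_star: float
) -> tuple[float, float, float, float]:
    """Pearson (r, p) of T_break vs theta below (theta < theta*) and above.

    A regime with fewer than 3 points yields NaNs for its side.
    """
    theta = np.asarray(theta, dtype=float)
    t_break = np.asarray(t_break, dtype=float)
    ok = np.isfinite(theta) & np.isfinite(t_break)
    theta, t_break = theta[ok], t_break[ok]
    out = []
    for mask in (theta < theta_star, theta >= theta_star):
        if mask.sum() < 3 or np.ptp(theta[mask]) == 0 or np.ptp(t_break[mask]) == 0:
            out.extend([float("nan"), float("nan")])
        else:
            r, p = stats.pearsonr(theta[mask], t_break[mask])
            out.extend([float(r), float(p)])
    return tuple(out)  # type: ignore[return-value]


def kernel_scale_sweep(
    theta, t_break, seed: int = 0, factors=(0.5, 1.0, 2.0)
) -> dict[float, float]:
    """Label stability of the two-regime split across kernel scales.

    For each scale factor, reports the fraction of points whose label
    agrees with the default-scale clustering (after the cold/warm
    orientation).  A sensitivity diagnostic, not a core output.
    """
    ref, _ = cluster_two_regimes(theta, t_break, seed=seed, scale_factor=1.0)
    out = {}
    for f in factors:
        lab, _ = cluster_two_regimes(theta, t_break, seed=seed, scale_factor=f)
        out[float(f)] = float(np.mean(lab == ref))
    return out


def thermal_analysis(
    theta, t_break, days=None, seed: int = 0, rule: str = "percentile"
) -> ThermalClustering:
    """Cluster, threshold and regime-correlate one city-year of points.

    Non-finite points are dropped first (days excluded upstream arrive as
    NaN).
    """
    theta = np.asarray(theta, dtype=float)
    t_break = np.asarray(t_break, dtype=float)
    if days is None:
        days = np.arange(1, theta.size + 1)
    days = np.asarray(days)
    ok = np.isfinite(theta) & np.isfinite(t_break)
    theta, t_break, days = theta[ok], t_break[ok], days[ok]
    labels, sil = cluster_two_regimes(theta, t_break, seed=seed)
    theta_star = threshold_temperature(theta, labels, rule=rule)
    r_b, p_b, r_a, p_a = regime_correlations(theta, t_break, theta_star)
    balance = min(np.mean(labels == 0), np.mean(labels == 1))
    low_conf = bool(sil < LOW_CONFIDENCE_SILHOUETTE or balance < MIN_CLUSTER_FRACTION)
    return ThermalClustering(
        theta=theta,
        t_break=t_break,
        days=days,
        labels=labels,
        theta_star=theta_star,
        silhouette=sil,
        low_confidence=low_conf,
        r_below=r_b,
        p_below=p_b,
        r_above=r_a,
        p_above=p_a,
    )
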
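"""Developmental trends of branch-point flux partitioning.

Flux distributions computed per internode (FBA for the wild type, MOMA for
transgenic lines) are summarized as partitioning ratios — each flux leaving
a branch-point metabolite divided by the total flux entering it — and the
resulting internode series are classified into five categories:
monotonically increasing/decreasing, increasing/decreasing with minor
variations, or essentially unchanged.  The arrow categories are qualitative
in origin; the numeric thresholds used here are package defaults exposed in
:class:`TrendConfig`.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .fba import FluxDistribution
from .network import PathwayNetwork

__all__ = [
    "PartitionSeries",
    "TrendCategory",
    "TrendConfig",
    "FluxCorrelation",
    "branch_definitions",
    "partition_ratios",
    "classify_trend",
    "pairwise_flux_correlation",
]


class TrendCategory(enum.Enum):
    MONO_UP = "↑↑"
    UP_MINOR = "↑"
    UNCHANGED = "—"
    DOWN_MINOR = "↓"
    MONO_DOWN = "↓↓"


@dataclass(frozen=True)
class TrendConfig:
    """Thresholds for the arrow classifier.

    ``unchanged_rel_range``: series whose total range is below this fraction
    of the mean magnitude count as unchanged.  ``spearman_cutoff``: minimum
    |Spearman rho| for a non-monotone series to count as a minor trend.
    """

    unchanged_rel_range: float = 0.05
    spearman_cutoff: float = 0.6
    #: series whose magnitude never exceeds this are solver noise around zero
    absolute_floor: float = 1e-9


@dataclass(frozen=True)
class PartitionSeries:
    branch_point: str
    ratio_id: str
    internodes: tuple[str, ...]
    #: One fraction per internode; None marks an undefined ratio (no flux
    #: entering the branch point).
    values: tuple[float | None, ...]


@dataclass(frozen=True)
class FluxCorrelation:
    flux_pair: tuple[str, str]
    pearson_rho: float | None
    n_points: int


def branch_definitions(net: PathwayNetwork) -> dict[str, tuple[tuple[str, ...], tuple[str, ...]]]:
    """Branch points of a network: internal metabolites with >= 2 consuming
    reactions, mapped to (entering reaction ids, outgoing reaction ids)."""
    out = {}
    for m in net.internal_metabolites:
        consumers = net.consumers(m.id)
        if len(consumers) >= 2:
            out[m.id] = (net.producers(m.id), consumers)
    return out


def partition_ratios(
    flux_distributions_by_internode: dict[str, FluxDistribution],
    net: PathwayNetwork,
    branch_defs: dict[str, tuple[tuple[str, ...], tuple[str, ...]]] | None = None,
    *,
    zero_tol: float = 1e-12,
) -> list[PartitionSeries]:
    """Per-branch-point partition fractions across internodes.

    Each outgoing flux is normalized by the total flux entering the branch
    point, so the outgoing fractions at a branch sum to one for any
    mass-balanced distribution.
    """
    if branch_defs is None:
        branch_defs = branch_definitions(net)
    internodes = tuple(flux_distributions_by_internode.keys())
    series: list[PartitionSeries] = []
    for mid, (entering, outgoing) in branch_defs.items():
        for rid in outgoing:
            vals: list[float | None] = []
            for key in internodes:
                dist = flux_distributions_by_internode[key]
                total_in = sum(dist[e] for e in entering)
                vals.append(dist[rid] / total_in if total_in > zero_tol else None)
            series.append(
                PartitionSeries(
                    branch_point=mid,
                    ratio_id=f"{rid}/{mid}",
                    internodes=internodes,
                    values=tuple(vals),
                )
            )
    return series


def classify_trend(series, config: TrendConfig | None = None) -> TrendCategory:
    """Classify an ordered internode series into one of five categories.

    Strictly monotone series are MONO_UP / MONO_DOWN; series whose relative
    range is negligible are UNCHANGED; otherwise the sign of a sufficiently
    strong Spearman rank correlation against internode order decides a minor
    trend, and weak correlations fall back to UNCHANGED.
    """
    cfg = config or TrendConfig()
    x = np.asarray([v for v in series], dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points to classify a trend")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if np.max(np.abs(x)) <= cfg.absolute_floor:
        return TrendCategory.UNCHANGED

    diffs = np.diff(x)
    if np.all(diffs > 0):
        return TrendCategory.MONO_UP
    if np.all(diffs < 0):
        return TrendCategory.MONO_DOWN

    scale = np.mean(np.abs(x))
    if scale == 0 or (x.max() - x.min()) / scale < cfg.unchanged_rel_range:
        return TrendCategory.UNCHANGED

    rho = stats.spearmanr(np.arange(x.size), x).statistic
    if np.isnan(rho) or abs(rho) < cfg.spearman_cutoff:
        return TrendCategory.UNCHANGED
    return TrendCategory.UP_MINOR if rho > 0 else TrendCategory.DOWN_MINOR


def pairwise_flux_correlation(
    distributions, flux_a: str, flux_b: str
) -> FluxCorrelation:
    """Pearson correlation of two fluxes across a pool of distributions
    (e.g. all internodes of all non-CCoAOMT lines for the v13--v14 check)."""
    dists = list(distributions)
    if len(dists) < 3:
        raise ValueError("need at least 3 distributions")
    a = np.array([d[flux_a] for d in dists])
    b = np.array([d[flux_b] for d in dists])
    # solver round-off makes nominally constant fluxes vary at ~1e-15
    def _constant(x):
        return np.std(x) <= 1e-10 * max(1.0, float(np.max(np.abs(x))))

    if _constant(a) or _constant(b):
        return FluxCorrelation((flux_a, flux_b), None, len(dists))
    rho = float(stats.pearsonr(a, b).statistic)
    return FluxCorrelation((flux_a, flux_b), rho, len(dists))
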
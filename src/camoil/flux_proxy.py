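"""Relative enzyme-activity proxies from fatty-acid pool time courses.

Given the pathway topology (every enzyme feeds a fixed set of fatty-acid
product pools), the week-over-week change in the summed content of an
enzyme's pool is a relative proxy for its in-planta activity during that
week: if all 18C/20C KASII-derived species together gained 1.5 % dry mass
between two samplings, net KASII-routed synthesis outpaced turnover by that
amount.  The proxy is expressed in % dry mass per week and is deliberately
relative — no conversion to molar flux is attempted.

`synchrony` summarizes how concerted the six proxies fluctuate as the mean
pairwise Pearson correlation of their delta series, optionally restricted
to a window of weeks; this quantifies the "synchronized fluctuation" of
fatty-acid synthesis enzymes during rapid oil accumulation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import InsufficientDataError, RegistryError
from .fame_quant import FATimeCourse
from .species_registry import DEFAULT_REGISTRY, SpeciesRegistry

__all__ = ["EnzymeProxySeries", "SynchronyReport", "pool_content", "proxy_series", "synchrony"]


@dataclass(frozen=True)
class EnzymeProxySeries:
    """Week-indexed activity-proxy deltas for one enzyme in one cultivar.

    ``weeks[i]`` labels the interval ending at that week; ``delta[i]`` is the
    pool-content change over the interval in % dry mass per week (changes
    across a sampling gap are divided by the gap length).
    """

    cultivar: str
    enzyme: str
    weeks: tuple[int, ...]
    delta: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.weeks) != len(self.delta):
            raise ValueError("weeks and delta must have equal length")


@dataclass(frozen=True)
class SynchronyReport:
    cultivar: str
    pairwise_r: dict[tuple[str, str], float | None]
    mean_r: float
    window: tuple[int, int] | None = None

    def r(self, a: str, b: str) -> float | None:
        return self.pairwise_r.get((a, b), self.pairwise_r.get((b, a)))


def _pool_series(
    tc: FATimeCourse, enzyme: str, registry: SpeciesRegistry
) -> "np.ndarray":
    pool = registry.get_pool(enzyme)
    means = tc.replicate_means()
    missing = pool - set(means.columns)
    if missing:
        warnings.warn(
            f"{tc.cultivar}: species {sorted(missing)} absent from time course; "
            "treated as zero content",
            stacklevel=3,
        )
    present = [sp for sp in pool if sp in means.columns]
    if not present:
        return np.zeros(len(means.index))
    return means[present].sum(axis=1).to_numpy()


def pool_content(
    tc: FATimeCourse,
    enzyme: str,
    week: int,
    registry: SpeciesRegistry = DEFAULT_REGISTRY,
) -> float:
    """Replicate-mean summed content of the enzyme's pool at one week (% dry mass)."""
    weeks = tc.weeks
    if week not in weeks:
        raise LookupError(f"week {week} not sampled in {tc.cultivar}")
    series = _pool_series(tc, enzyme, registry)
    return float(series[weeks.index(week)])


def proxy_series(
    tc: FATimeCourse,
    enzyme: str,
    registry: SpeciesRegistry = DEFAULT_REGISTRY,
) -> EnzymeProxySeries:
    """Weekly activity proxy: consecutive differences of the pool series.

    Deltas across a multi-week sampling gap are normalized per week of gap,
    so a missed sampling does not inflate apparent activity.
    """
    weeks = tc.weeks
    if len(weeks) < 2:
        raise InsufficientDataError("proxy series needs at least two sampled weeks")
    series = _pool_series(tc, enzyme, registry)
    gaps = np.diff(weeks)
    delta = np.diff(series) / gaps
    return EnzymeProxySeries(
        cultivar=tc.cultivar,
        enzyme=enzyme,
        weeks=tuple(int(w) for w in weeks[1:]),
        delta=tuple(float(d) for d in delta),
    )


def proxy_series_bootstrap(
    tc: FATimeCourse,
    enzyme: str,
    n_boot: int = 200,
    rng: np.random.Generator | None = None,
    registry: SpeciesRegistry = DEFAULT_REGISTRY,
) -> dict[int, tuple[float, float]]:
    """Optional uncertainty for the proxy deltas by resampling replicates.

    Replicates are resampled with replacement within each week; returns
    interval-end week -> (bootstrap mean, bootstrap SD) of the delta.
    """
    rng = rng if rng is not None else np.random.default_rng()
    pool = registry.get_pool(enzyme)
    present = [sp for sp in tc.species if sp in pool]
    weeks = tc.weeks
    gaps = np.diff(weeks)
    # week x replicate matrix of pool sums
    pools = (
        tc.data[tc.data["species"].isin(present)]
        .groupby(["week", "replicate"])["content_pct"]
        .sum()
        .unstack("replicate")
        .loc[weeks]
        .to_numpy()
    )
    n_rep = pools.shape[1]
    draws = np.empty((n_boot, len(weeks) - 1))
    for b in range(n_boot):
        idx = rng.integers(n_rep, size=(len(weeks), n_rep))
        means = np.take_along_axis(pools, idx, axis=1).mean(axis=1)
        draws[b] = np.diff(means) / gaps
    return {
        int(w): (float(draws[:, i].mean()), float(draws[:, i].std(ddof=1)))
        for i, w in enumerate(weeks[1:])
    }


def all_proxy_series(
    tc: FATimeCourse, registry: SpeciesRegistry = DEFAULT_REGISTRY
) -> list[EnzymeProxySeries]:
    return [proxy_series(tc, e, registry) for e in registry.enzymes]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    return float((xc * yc).sum() / denom)


def synchrony(
    series: list[EnzymeProxySeries],
    window: tuple[int, int] | None = None,
) -> SynchronyReport:
    """Mean pairwise Pearson correlation between enzyme proxy delta series.

    Pairs involving a zero-variance series (typically FAD3 when 18:3 is
    flat) are recorded as missing (None) instead of propagating NaN, and
    excluded from ``mean_r``.
    """
    if len(series) < 2:
        raise InsufficientDataError("synchrony needs at least two proxy series")
    weeks = series[0].weeks
    if any(s.weeks != weeks for s in series[1:]):
        raise InsufficientDataError("proxy series must share the same interval labels")
    cultivar = series[0].cultivar
    if window is not None:
        lo, hi = window
        keep = [i for i, w in enumerate(weeks) if lo <= w <= hi]
        if len(keep) < 2:
            raise InsufficientDataError("window covers fewer than two intervals")
    else:
        keep = list(range(len(weeks)))

    vectors = {s.enzyme: np.asarray(s.delta)[keep] for s in series}
    pairwise: dict[tuple[str, str], float | None] = {}
    rs = []
    for a, b in itertools.combinations(vectors, 2):
        va, vb = vectors[a], vectors[b]
        if np.ptp(va) == 0 or np.ptp(vb) == 0:
            pairwise[(a, b)] = None
            continue
        r = _pearson(va, vb)
        pairwise[(a, b)] = r
        rs.append(r)
    mean_r = float(np.mean(rs)) if rs else float("nan")
    return SynchronyReport(cultivar=cultivar, pairwise_r=pairwise, mean_r=mean_r, window=window)
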
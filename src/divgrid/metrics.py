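"""Summary statistics: richness, range size, turnover, Δr, tree balance.

Δr is the change in net diversification between the two halves of a run:
``r1`` over [t_start, T/2], ``r2`` over [T/2, T], each the log-change in
lineage count, and ``Δr = r2 − r1``.  Zero under constant-rate growth,
negative for a slowdown.  Two conventions are supported: per-unit-time rates
(each half's log-change divided by its duration, the default) and bare
log-changes; the two differ only by the factor 1/(T/2) when the halves are
equal.  The full-tree variant counts species alive at each anchor; the
reconstructed variant counts lineages ancestral to the extant species.

Tree imbalance uses Sackin's index under the Yule-expectation normalization
of Blum & François: S = (S_raw − E_Yule[S_n]) / n with
E_Yule[S_n] = 2 n Σ_{j=2..n} 1/j, so a pure-birth process has S ≈ 0 and
larger values mean greater imbalance.  Undefined values (extinct clade,
n < 2 tips, bins without speciations) propagate as NaN, never as zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .sim_core import EventRecord, RunResult
from .phylogeny import LineageTree, PhyloTree, build_full_tree

__all__ = [
    "delta_r",
    "delta_r_full",
    "delta_r_reconstructed",
    "sackin_normalized",
    "yule_expected_sackin",
    "turnover_series",
    "range_and_age_summary",
    "MetricsSummary",
    "compute_summary",
]


def delta_r(
    ltt: Callable[[float], float],
    T: float,
    t_start: float = 0.0,
    normalize: bool = True,
) -> float:
    """Δr from a lineage-count function evaluated at t_start, T/2 and T.

    Returns NaN if any anchor count is zero (clade extinct).
    """
    n0 = float(ltt(t_start))
    n1 = float(ltt(T / 2.0))
    n2 = float(ltt(T))
    if n0 <= 0 or n1 <= 0 or n2 <= 0:
        return math.nan
    r1 = math.log(n1) - math.log(n0)
    r2 = math.log(n2) - math.log(n1)
    if normalize:
        r1 /= T / 2.0 - t_start
        r2 /= T / 2.0
    return r2 - r1


def delta_r_full(tree: LineageTree, normalize: bool = True) -> float:
    """Δr from true richness through time (species alive at each anchor)."""
    return delta_r(tree.lineages_alive_at, tree.present, normalize=normalize)


def delta_r_reconstructed(
    tree: Union[LineageTree, PhyloTree], normalize: bool = True
) -> float:
    """Δr from the reconstructed tree's lineages-through-time curve."""
    phylo = tree.reconstructed() if isinstance(tree, LineageTree) else tree
    if phylo.is_empty:
        return math.nan
    return delta_r(phylo.lineages_at, phylo.present, normalize=normalize)


def yule_expected_sackin(n: int) -> float:
    """E[S_raw] for a Yule tree with n tips: 2n * sum_{j=2..n} 1/j."""
    return 2.0 * n * sum(1.0 / j for j in range(2, n + 1))


def sackin_normalized(tree: PhyloTree) -> float:
    """Yule-normalized Sackin imbalance; NaN for trees with < 2 tips.

    Topology-only: S_raw is the sum over tips of the number of internal
    nodes on the root-to-tip path, so branch lengths are irrelevant.
    """
    depths = tree.tip_depths()
    n = len(depths)
    if n < 2:
        return math.nan
    return (sum(depths) - yule_expected_sackin(n)) / n


def turnover_series(
    source: Union[LineageTree, Sequence[EventRecord]],
    bin_width: float = 1.0,
    duration: Optional[float] = None,
    include_pseudo: bool = True,
) -> np.ndarray:
    """Evolutionary turnover per time bin: species extinctions / speciations.

    Bins with zero speciation events yield NaN.  ``include_pseudo`` controls
    whether parental pseudoextinctions at speciation enter the numerator.
    """
    tree = source if isinstance(source, LineageTree) else build_full_tree(source, duration)
    T = tree.present if duration is None else duration
    edges = np.arange(0.0, T + bin_width, bin_width)
    if edges[-1] < T:
        edges = np.append(edges, T)
    spec_times = tree.origin[1:]  # the founding is not a speciation event
    ext_mask = ~np.isnan(tree.extinction)
    if not include_pseudo:
        ext_mask &= ~tree.pseudo
    ext_times = tree.extinction[ext_mask]
    n_spec, _ = np.histogram(spec_times, bins=edges)
    n_ext, _ = np.histogram(ext_times, bins=edges)
    out = np.full(len(n_spec), np.nan)
    nz = n_spec > 0
    out[nz] = n_ext[nz] / n_spec[nz]
    return out


def range_and_age_summary(
    result: RunResult, tree: Optional[LineageTree] = None
) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-extant-species range sizes and ages, plus range-size skewness.

    Range size is the number of occupied cells; age is T minus origination
    time.  Skewness is NaN when fewer than 3 species survive.
    """
    if tree is None:
        tree = LineageTree.from_run(result)
    ranges = result.range_sizes()
    ages = tree.ages()
    # skewness is undefined for < 3 species or a degenerate distribution
    if len(ranges) >= 3 and ranges.min() != ranges.max():
        skew = float(stats.skew(ranges))
    else:
        skew = math.nan
    return ranges, ages, skew


@dataclass
class MetricsSummary:
    """Per-run metric bundle (NaN marks undefined values)."""

    final_richness: int
    mean_local_richness: float
    range_sizes: np.ndarray
    mean_range_size: float
    range_skewness: float
    ages: np.ndarray
    delta_r_full: float
    delta_r_reconstructed: float
    sackin: float
    turnover: np.ndarray
    richness_series: np.ndarray
    survived: bool

    def scalar_dict(self) -> dict:
        return {
            "final_richness": self.final_richness,
            "mean_local_richness": self.mean_local_richness,
            "mean_range_size": self.mean_range_size,
            "range_skewness": self.range_skewness,
            "delta_r_full": self.delta_r_full,
            "delta_r_reconstructed": self.delta_r_reconstructed,
            "sackin": self.sackin,
            "survived": float(self.survived),
        }


def compute_summary(result: RunResult, normalize_delta_r: bool = True) -> MetricsSummary:
    """All per-run metrics from a finished replicate."""
    tree = LineageTree.from_run(result)
    survived = not result.extinct
    ranges, ages, skew = range_and_age_summary(result, tree)
    n_extant = len(tree.extant_ids())
    mean_local = result.population_series[-1] / result.params.area if survived else 0.0
    if survived:
        recon = tree.reconstructed()
        dr_rec = delta_r_reconstructed(recon, normalize=normalize_delta_r)
        dr_full = delta_r_full(tree, normalize=normalize_delta_r)
        sackin = sackin_normalized(recon)
    else:
        dr_rec = dr_full = sackin = math.nan
    return MetricsSummary(
        final_richness=n_extant,
        mean_local_richness=float(mean_local),
        range_sizes=ranges,
        mean_range_size=float(ranges.mean()) if len(ranges) else math.nan,
        range_skewness=skew,
        ages=ages,
        delta_r_full=dr_full,
        delta_r_reconstructed=dr_rec,
        sackin=sackin,
        turnover=turnover_series(tree),
        richness_series=result.richness_series,
        survived=survived,
    )
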
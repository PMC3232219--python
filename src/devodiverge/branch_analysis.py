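"""Expression-distance trees and lineage branch-length statistics.

For each gene, the fitted trajectories of the three species are interpolated
on a common transformed-age grid and pairwise Euclidean distances between
the curves are computed.  For three taxa the neighbor-joining/additive
decomposition of those distances into per-lineage branch lengths is closed
form:

    b_H = (d_HC + d_HM - d_CM) / 2
    b_C = (d_HC + d_CM - d_HM) / 2
    b_M = (d_HM + d_CM - d_HC) / 2

The log2 human/chimpanzee branch-length ratio R = log2(b_H / b_C) summarizes
lineage asymmetry; R > 0 means human-accelerated divergence.  For pattern
(type III) analyses the curves are mean-centered on the grid first, so
constitutive level differences do not contribute.  Gene-set summaries use
the Wilcoxon signed-rank test of median R = 0 and percentile-bootstrap
confidence intervals of the median.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from ._stats import binomial_upper_tail, wilcoxon_signed_rank
from .trajectory_fit import AgeGrid, TrajectoryModel, interpolate

#: Raw NJ branches can come out negative on noisy distances; they are clamped
#: here (and flagged) because log2 of a non-positive branch is undefined.
DEFAULT_BRANCH_FLOOR = 1e-6


@dataclass
class BranchTree:
    """Per-gene three-taxon distances, branch lengths, and the log2 H/C ratio."""

    feature_id: str
    d_HC: float
    d_HM: float
    d_CM: float
    b_H: float
    b_C: float
    b_M: float
    R: float
    clamped: tuple[bool, bool, bool]  # (H, C, M)

    @property
    def ratio_usable(self) -> bool:
        """True when neither ingroup branch had to be clamped."""
        return not (self.clamped[0] or self.clamped[1])

    @property
    def tree_size(self) -> float:
        return self.b_H + self.b_C + self.b_M


@dataclass
class RatioSummary:
    gene_set: str
    n: int
    n_excluded: int
    median_R: float
    wilcoxon_p: float
    ci95: tuple[float, float]
    n_boot: int
    seed: Optional[int]


def trajectory_distance(
    mA: TrajectoryModel,
    mB: TrajectoryModel,
    grid: AgeGrid,
    remove_mean: bool = False,
) -> float:
    """Euclidean distance between two interpolated trajectories.

    With ``remove_mean`` each curve is centered to mean zero over the grid
    first, leaving only shape differences (mandatory for type III analyses).
    """
    if mA.feature_id != mB.feature_id:
        raise ValueError(
            f"feature mismatch: {mA.feature_id!r} vs {mB.feature_id!r}"
        )
    vA = interpolate(mA, grid)
    vB = interpolate(mB, grid)
    if remove_mean:
        vA = vA - vA.mean()
        vB = vB - vB.mean()
    return float(np.linalg.norm(vA - vB))


def nj_three_taxon(
    d_HC: float, d_HM: float, d_CM: float, floor: float = DEFAULT_BRANCH_FLOOR
) -> tuple[float, float, float, tuple[bool, bool, bool]]:
    """Exact additive (NJ) branch lengths for three taxa, clamped at ``floor``."""
    if min(d_HC, d_HM, d_CM) < 0:
        raise ValueError("distances must be >= 0")
    raw = (
        (d_HC + d_HM - d_CM) / 2.0,
        (d_HC + d_CM - d_HM) / 2.0,
        (d_HM + d_CM - d_HC) / 2.0,
    )
    clamped = tuple(b < floor for b in raw)
    b_H, b_C, b_M = (max(b, floor) for b in raw)
    return b_H, b_C, b_M, clamped  # type: ignore[return-value]


def build_branch_trees(
    models: Mapping[str, Mapping[str, TrajectoryModel]],
    grid: AgeGrid,
    species_order: Sequence[str] = ("human", "chimpanzee", "macaque"),
    remove_mean: bool = False,
    floor: float = DEFAULT_BRANCH_FLOOR,
    features: Optional[Sequence[str]] = None,
) -> list[BranchTree]:
    """Distances, branch lengths and R for every feature in ``models``.

    ``models[feature][species]`` as produced by
    :func:`devodiverge.trajectory_fit.fit_species_trajectories`.
    """
    h, c, m = species_order
    if features is None:
        features = list(models)
    trees = []
    for fid in features:
        ms = models[fid]
        d_HC = trajectory_distance(ms[h], ms[c], grid, remove_mean)
        d_HM = trajectory_distance(ms[h], ms[m], grid, remove_mean)
        d_CM = trajectory_distance(ms[c], ms[m], grid, remove_mean)
        b_H, b_C, b_M, clamped = nj_three_taxon(d_HC, d_HM, d_CM, floor)
        trees.append(
            BranchTree(
                feature_id=fid,
                d_HC=d_HC,
                d_HM=d_HM,
                d_CM=d_CM,
                b_H=b_H,
                b_C=b_C,
                b_M=b_M,
                R=float(np.log2(b_H / b_C)),
                clamped=clamped,
            )
        )
    return trees


def bootstrap_median_ci(
    values: np.ndarray,
    n_boot: int = 1000,
    seed: Optional[int] = None,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap CI of the median, resampling with replacement."""
    rng = np.random.default_rng(seed)
    n = len(values)
    idx = rng.integers(0, n, size=(n_boot, n))
    medians = np.median(values[idx], axis=1)
    lo = (1.0 - level) / 2.0
    return (
        float(np.quantile(medians, lo)),
        float(np.quantile(medians, 1.0 - lo)),
    )


def branch_ratio_stats(
    trees: Sequence[BranchTree],
    n_boot: int = 1000,
    seed: Optional[int] = None,
    gene_set: str = "",
) -> RatioSummary:
    """Median R, Wilcoxon signed-rank p (median 0), and bootstrap CI.

    Genes where either ingroup branch was clamped to the floor are excluded
    from the ratio distribution (and counted), since their log ratio reflects
    the floor rather than the data.  No magnitude truncation is applied to
    the retained ratios.
    """
    usable = [t for t in trees if t.ratio_usable]
    n_excluded = len(trees) - len(usable)
    if len(usable) < 3:
        raise ValueError(
            f"need >= 3 genes with both ingroup branches above the floor, "
            f"got {len(usable)}"
        )
    R = np.array([t.R for t in usable])
    median, p = wilcoxon_signed_rank(R, alternative="two-sided")
    ci = bootstrap_median_ci(R, n_boot=n_boot, seed=seed)
    return RatioSummary(
        gene_set=gene_set,
        n=len(usable),
        n_excluded=n_excluded,
        median_R=median,
        wilcoxon_p=p,
        ci95=ci,
        n_boot=n_boot,
        seed=seed,
    )


def species_specific_calls(
    p_diff: Mapping[tuple[str, str], float],
    alpha: float = 0.001,
    species_order: Sequence[str] = ("human", "chimpanzee", "macaque"),
) -> str:
    """Assign divergence to one lineage from the three pairwise ANCOVA p-values.

    A gene is species-specific when exactly the two pairs involving that
    species are significant; all three significant is "unspecific"; any other
    configuration is "none".
    """
    h, c, m = species_order
    pairs = [(h, c), (h, m), (c, m)]
    norm: dict[frozenset, float] = {}
    for key, p in p_diff.items():
        norm[frozenset(key)] = p
    missing = [pr for pr in pairs if frozenset(pr) not in norm]
    if missing:
        raise ValueError(f"missing p-values for pairs: {missing}")
    sig = {pr: norm[frozenset(pr)] < alpha for pr in pairs}
    if all(sig.values()):
        return "unspecific"
    for sp in (h, c, m):
        involving = [pr for pr in pairs if sp in pr]
        other = [pr for pr in pairs if sp not in pr]
        if all(sig[pr] for pr in involving) and not any(sig[pr] for pr in other):
            return sp
    return "none"


def lineage_binomial_test(
    trees: Optional[Sequence[BranchTree]] = None,
    paired_distances: Optional[Sequence[tuple[float, float]]] = None,
) -> tuple[float, float]:
    """Binary lineage coding: is human-outgroup divergence the larger one?

    Each gene is coded 1 when its human-outgroup distance exceeds its
    chimpanzee-outgroup distance (ties dropped); returns the proportion of 1s
    and the one-sided exact binomial p against 0.5.
    """
    if paired_distances is None:
        if trees is None:
            raise ValueError("provide trees or paired distances")
        paired_distances = [(t.d_HM, t.d_CM) for t in trees]
    codes = [1 if hm > cm else 0 for hm, cm in paired_distances if hm != cm]
    if not codes:
        raise ValueError("no genes left after dropping ties")
    k, n = sum(codes), len(codes)
    return k / n, binomial_upper_tail(k, n, 0.5)
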
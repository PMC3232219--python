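"""Trans-regulator screen: target enrichment plus correlation-excess testing.

Candidate regulators (miRNAs, or TFs with the correlation sign flipped) of a
focal gene set are called in two stages:

1. target enrichment — a one-sided hypergeometric test of whether the
   regulator's predicted targets are over-represented in the focal set
   relative to a background set (the other divergent gene types).
2. correlation excess — among regulators passing stage 1, a one-sided
   binomial test of whether an excess of their in-set targets shows strong
   negative Pearson correlation (r < -0.75 by default) with the regulator's
   expression trajectory, against a background rate taken from the
   non-enriched regulators.

Correlations are computed from fitted trajectories in two modes: "profile"
concatenates the three species' interpolated curves; "species_diff"
concatenates the three pairwise between-species difference curves, isolating
divergence from shared age effects.  A permutation null (reassigning
focal/background labels over genes) gives the expected number of enriched
regulators by chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from ._stats import binomial_upper_tail, hypergeom_upper_tail
from .core_model import TargetTable
from .trajectory_fit import AgeGrid, TrajectoryModel, interpolate

SPECIES_DEFAULT = ("human", "chimpanzee", "macaque")
NEGATIVE_CUTOFF = -0.75  # screen-stage correlation cutoff
STRONG_CUTOFF = 0.9  # |r| cutoff for the excess-distribution analysis


@dataclass
class RegulatorScreenResult:
    regulator_id: str
    n_targets_in_set: int
    n_targets_background: int
    p_enrich: float
    neg_frequency: float
    background_frequency: float
    p_binomial: float
    candidate: bool
    enriched: bool
    flagged_degenerate: bool = False


@dataclass
class ScreenPermutation:
    """Null expectation for the number of enriched regulators."""

    observed_enriched: int
    expected_enriched: float
    p_empirical: float
    n_perm: int
    seed: Optional[int]


@dataclass
class CorrelationExcess:
    bin_edges: np.ndarray
    observed_excess: np.ndarray  # per-bin target density minus non-target density
    permuted_excess: np.ndarray  # (n_perm, n_bins)
    n_perm: int


def target_enrichment(
    regulator: str,
    focal_set: Iterable[str],
    background_set: Iterable[str],
    targets: TargetTable,
) -> tuple[float, int, int]:
    """Hypergeometric upper-tail p for target overlap with the focal set.

    Returns (p, n_targets_in_focal, n_targets_in_background).  The universe
    is focal ∪ background; the caller restricts both to expressed genes.
    """
    focal = set(focal_set)
    background = set(background_set) - focal
    universe = focal | background
    tset = targets.targets_of(regulator) & universe
    k = len(tset & focal)
    K = len(tset)
    if K == 0:
        warnings.warn(
            f"regulator {regulator!r} has no targets in the universe; p = 1",
            UserWarning,
        )
        return 1.0, 0, 0
    p = hypergeom_upper_tail(k, len(universe), K, len(focal))
    return p, k, K - k


def profile_correlations(
    reg_models: Mapping[str, TrajectoryModel],
    target_models: Mapping[str, Mapping[str, TrajectoryModel]],
    grid: AgeGrid,
    mode: Literal["profile", "species_diff"] = "profile",
    species_order: Sequence[str] = SPECIES_DEFAULT,
) -> dict[str, float]:
    """Pearson r between a regulator's and each target's trajectory vectors.

    "profile": concatenate the three species' interpolated curves (3G points).
    "species_diff": concatenate the three pairwise difference curves
    (H-C, H-M, C-M at the grid points), which is invariant to adding the same
    curve to all species.  Zero-variance vectors yield NaN.
    """
    reg_vec = _stack_curves(reg_models, grid, mode, species_order)
    out: dict[str, float] = {}
    for tid, tmods in target_models.items():
        tvec = _stack_curves(tmods, grid, mode, species_order)
        out[tid] = _pearson_or_nan(reg_vec, tvec)
    return out


def _stack_curves(
    models: Mapping[str, TrajectoryModel],
    grid: AgeGrid,
    mode: str,
    species_order: Sequence[str],
) -> np.ndarray:
    curves = [interpolate(models[sp], grid) for sp in species_order]
    if mode == "profile":
        return np.concatenate(curves)
    if mode == "species_diff":
        a, b, c = curves
        return np.concatenate([a - b, a - c, b - c])
    raise ValueError(f"unknown mode {mode!r}")


def _pearson_or_nan(u: np.ndarray, v: np.ndarray) -> float:
    su, sv = np.std(u), np.std(v)
    if su <= 1e-12 or sv <= 1e-12:
        return np.nan
    return float(np.corrcoef(u, v)[0, 1])


def negative_excess_test(
    enriched: Sequence[str],
    non_enriched: Sequence[str],
    correlations: Mapping[str, Mapping[str, float]],
    cutoff: float = NEGATIVE_CUTOFF,
    tail: Literal["negative", "positive"] = "negative",
    background_mode: Literal["per_regulator", "pooled"] = "per_regulator",
) -> dict[str, tuple[float, float, float]]:
    """Binomial test of excess strong correlations for each enriched regulator.

    ``correlations[regulator][target]`` holds in-set target correlations.
    The background success rate is the mean, over non-enriched regulators, of
    their fraction of in-set targets beyond the cutoff ("per_regulator"); the
    "pooled" option pools all non-enriched targets instead.  For TFs pass
    tail="positive" with a positive cutoff.  Returns
    {regulator: (p_binomial, frequency, background_rate)}.
    """

    def frac_beyond(reg: str) -> tuple[int, int]:
        rs = [r for r in correlations.get(reg, {}).values() if not np.isnan(r)]
        if tail == "negative":
            hits = sum(r < cutoff for r in rs)
        else:
            hits = sum(r > cutoff for r in rs)
        return hits, len(rs)

    per_reg = []
    pooled_hits = pooled_n = 0
    for reg in non_enriched:
        hits, n = frac_beyond(reg)
        if n > 0:
            per_reg.append(hits / n)
            pooled_hits += hits
            pooled_n += n
    if background_mode == "per_regulator":
        background = float(np.mean(per_reg)) if per_reg else 0.0
    else:
        background = pooled_hits / pooled_n if pooled_n else 0.0

    out: dict[str, tuple[float, float, float]] = {}
    for reg in enriched:
        hits, n = frac_beyond(reg)
        if n == 0:
            continue  # no in-set targets with a defined correlation
        if background <= 0.0:
            p = 0.0 if hits > 0 else 1.0
            if hits > 0:
                warnings.warn(
                    "background rate is 0 with nonzero observed count; p = 0",
                    UserWarning,
                )
        else:
            p = binomial_upper_tail(hits, n, background)
        out[reg] = (p, hits / n, background)
    return out


def screen_candidates(
    regulators: Sequence[str],
    focal_set: Iterable[str],
    background_set: Iterable[str],
    models: Mapping[str, Mapping[str, TrajectoryModel]],
    grid: AgeGrid,
    targets: TargetTable,
    alpha_enrich: float = 0.05,
    alpha_binom: float = 0.05,
    cutoff: float = NEGATIVE_CUTOFF,
    tail: Literal["negative", "positive"] = "negative",
    mode: Literal["profile", "species_diff"] = "profile",
    n_perm: int = 1000,
    seed: Optional[int] = None,
    species_order: Sequence[str] = SPECIES_DEFAULT,
    background_mode: Literal["per_regulator", "pooled"] = "per_regulator",
) -> tuple[list[RegulatorScreenResult], Optional[ScreenPermutation]]:
    """Run the full two-stage screen over all regulators.

    ``models`` must contain trajectories for every regulator and for every
    focal gene (regulator trajectories typically come from a miRNA dataset
    sharing the sample metadata).  With n_perm = 0 the permutation
    expectation is omitted but candidate flags are still computed.
    """
    if len(regulators) < 2:
        raise ValueError("need at least 2 regulators to screen")
    focal = sorted(set(focal_set))
    background = sorted(set(background_set) - set(focal))

    enrich_p: dict[str, float] = {}
    counts: dict[str, tuple[int, int]] = {}
    for reg in regulators:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            p, k_in, k_bg = target_enrichment(reg, focal, background, targets)
        enrich_p[reg] = p
        counts[reg] = (k_in, k_bg)
    enriched = [r for r in regulators if enrich_p[r] < alpha_enrich]
    non_enriched = [r for r in regulators if r not in set(enriched)]

    # correlations of each regulator with its in-focal-set targets
    focal_in_models = [g for g in focal if g in models]
    correlations: dict[str, dict[str, float]] = {}
    for reg in regulators:
        tgts = [g for g in targets.targets_of(reg) if g in focal_in_models]
        if not tgts or reg not in models:
            correlations[reg] = {}
            continue
        correlations[reg] = profile_correlations(
            models[reg],
            {g: models[g] for g in tgts},
            grid,
            mode=mode,
            species_order=species_order,
        )

    excess = negative_excess_test(
        enriched, non_enriched, correlations, cutoff, tail, background_mode
    )

    results = []
    for reg in regulators:
        k_in, k_bg = counts[reg]
        is_enriched = reg in set(enriched)
        p_binom, freq, bg_rate = excess.get(reg, (np.nan, np.nan, np.nan))
        candidate = bool(
            is_enriched and not np.isnan(p_binom) and p_binom < alpha_binom
        )
        results.append(
            RegulatorScreenResult(
                regulator_id=reg,
                n_targets_in_set=k_in,
                n_targets_background=k_bg,
                p_enrich=enrich_p[reg],
                neg_frequency=freq,
                background_frequency=bg_rate,
                p_binomial=p_binom,
                candidate=candidate,
                enriched=is_enriched,
                flagged_degenerate=bool(bg_rate == 0.0 and freq > 0),
            )
        )

    permutation = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        universe = np.array(focal + background)
        n_focal = len(focal)
        target_sets = {
            reg: targets.targets_of(reg) & set(universe) for reg in regulators
        }
        perm_counts = np.empty(n_perm, dtype=int)
        M = len(universe)
        for it in range(n_perm):
            perm = rng.permutation(M)
            pseudo_focal = set(universe[perm[:n_focal]])
            n_enriched = 0
            for reg in regulators:
                tset = target_sets[reg]
                K = len(tset)
                if K == 0:
                    continue
                k = len(tset & pseudo_focal)
                if hypergeom_upper_tail(k, M, K, n_focal) < alpha_enrich:
                    n_enriched += 1
            perm_counts[it] = n_enriched
        observed = len(enriched)
        permutation = ScreenPermutation(
            observed_enriched=observed,
            expected_enriched=float(perm_counts.mean()),
            p_empirical=float((1 + np.sum(perm_counts >= observed)) / (1 + n_perm)),
            n_perm=n_perm,
            seed=seed,
        )
    return results, permutation


def correlation_excess_distribution(
    target_correlations: Sequence[float],
    nontarget_correlations: Sequence[float],
    bin_edges: Optional[np.ndarray] = None,
    n_perm: int = 100,
    seed: Optional[int] = None,
) -> CorrelationExcess:
    """Per-bin excess of target-pair correlation density over non-target density.

    Densities are per-bin probability masses (each class sums to 1), so the
    excess sums to 0 across bins.  The permutation null resamples non-target
    pairs as pseudo-target sets of matched size and differences them against
    the remaining non-target pairs.
    """
    tc = np.asarray([r for r in target_correlations if not np.isnan(r)])
    nc = np.asarray([r for r in nontarget_correlations if not np.isnan(r)])
    if len(tc) == 0 or len(nc) == 0:
        raise ValueError("need both target and non-target correlations")
    if bin_edges is None:
        bin_edges = np.linspace(-1.0, 1.0, 21)
    bin_edges = np.asarray(bin_edges, dtype=float)
    if len(bin_edges) < 3:
        raise ValueError("need at least 2 bins")

    def density(vals: np.ndarray) -> np.ndarray:
        h, _ = np.histogram(vals, bins=bin_edges)
        return h / max(len(vals), 1)

    observed = density(tc) - density(nc)
    rng = np.random.default_rng(seed)
    n_t = min(len(tc), len(nc) - 1) if len(nc) > 1 else 1
    permuted = np.empty((n_perm, len(bin_edges) - 1))
    for it in range(n_perm):
        idx = rng.permutation(len(nc))
        pseudo = nc[idx[:n_t]]
        rest = nc[idx[n_t:]] if len(nc) > n_t else nc
        permuted[it] = density(pseudo) - density(rest)
    return CorrelationExcess(
        bin_edges=bin_edges,
        observed_excess=observed,
        permuted_excess=permuted,
        n_perm=n_perm,
    )


def transfection_inhibition_test(
    effect_sizes: Mapping[str, float],
    target_set: Iterable[str],
    other_set: Iterable[str],
) -> float:
    """One-sided rank-sum test that target effect sizes are shifted downward.

    ``effect_sizes`` are per-gene transfected-minus-control log2 expression
    differences (mean over cell lines when two are given, computed upstream).
    """
    targets = [effect_sizes[g] for g in target_set if g in effect_sizes]
    others = [effect_sizes[g] for g in other_set if g in effect_sizes]
    if not targets:
        raise ValueError("empty target set")
    if not others:
        raise ValueError("empty comparison set")
    res = stats.mannwhitneyu(targets, others, alternative="less")
    return float(res.pvalue)
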
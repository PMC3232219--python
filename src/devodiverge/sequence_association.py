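"""Associations between expression divergence and sequence scores.

Expression divergence per gene and lineage is the corresponding NJ branch
length ("total" = tree size, the sum of branches).  Sequence divergence comes
in as precomputed per-gene scores: pan-mammalian conservation means per
region class (sign-flipped to divergence), species-specific mutation counts,
binding-site densities, and coding divergence.  Associations are Spearman
rank correlations; binding-site density is first adjusted for overall
conservation by taking OLS residuals.  Two preprocessing helpers mirror the
robustness procedures used with such data: subsampling gene sets to equalize
mean-expression distributions, and trimming the upper tail of mutation
estimates (alignment artifacts inflate the extremes).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._stats import spearman


@dataclass
class AssociationResult:
    lineage: str  # species name or "total"
    region_class: str  # promoter, 3'UTR, enhancer class, coding
    rho: float
    p: float
    n: int
    flagged: bool = False  # constant input, rho undefined


def expression_sequence_correlation(
    expr_divergence: Mapping[str, float] | pd.Series,
    seq_scores: Mapping[str, float] | pd.Series,
    lineage: str = "",
    region_class: str = "",
    negate_scores: bool = False,
) -> AssociationResult:
    """Spearman correlation between expression and sequence divergence.

    Set ``negate_scores`` when the sequence column is a conservation score:
    sequence divergence is then its negative.  Only genes with both values
    present enter; p is the exact permutation p for n <= 9 and tie-corrected
    otherwise.
    """
    ed = pd.Series(expr_divergence, dtype=float)
    ss = pd.Series(seq_scores, dtype=float)
    common = ed.dropna().index.intersection(ss.dropna().index)
    if len(common) < 5:
        raise ValueError(f"need >= 5 complete pairs, got {len(common)}")
    x = ed[common].to_numpy()
    y = ss[common].to_numpy()
    if negate_scores:
        y = -y
    rho, p = spearman(x, y)
    if math.isnan(rho):
        warnings.warn("constant vector; rho undefined", UserWarning)
        return AssociationResult(lineage, region_class, np.nan, np.nan, len(common), True)
    return AssociationResult(lineage, region_class, rho, p, len(common))


def conservation_adjusted_density(
    bs_density: Mapping[str, float] | pd.Series,
    conservation: Mapping[str, float] | pd.Series,
) -> pd.Series:
    """OLS residuals of binding-site density on conservation, per gene.

    Removes the overall effect of sequence conservation on binding-site
    density before set contrasts (which reuse the specificity-contrast
    machinery with a median statistic).  With constant conservation the
    regression is degenerate and the mean-centered density is returned with a
    warning.
    """
    dens = pd.Series(bs_density, dtype=float)
    cons = pd.Series(conservation, dtype=float)
    common = dens.dropna().index.intersection(cons.dropna().index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 complete pairs, got {len(common)}")
    y = dens[common].to_numpy()
    x = cons[common].to_numpy()
    if np.ptp(x) <= 1e-12:
        warnings.warn(
            "constant conservation; returning mean-centered density", UserWarning
        )
        return pd.Series(y - y.mean(), index=common)
    X = np.column_stack([np.ones_like(x), x])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    return pd.Series(y - X @ beta, index=common)


def equalize_expression_distributions(
    sets: Mapping[str, Sequence[str]],
    mean_expression: Mapping[str, float] | pd.Series,
    n_bins: int = 10,
    seed: Optional[int] = None,
) -> dict[str, list[str]]:
    """Subsample gene sets so their mean-expression histograms match.

    Equal-width bins over the pooled expression range; within each bin every
    set is randomly downsampled to the minimum per-bin count across sets.
    Output sets therefore have identical per-bin counts.
    """
    if len(sets) < 2:
        raise ValueError("need >= 2 gene sets")
    expr = pd.Series(mean_expression, dtype=float)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate(
        [expr[[g for g in genes if g in expr.index]].to_numpy() for genes in sets.values()]
    )
    if len(pooled) == 0:
        raise ValueError("no genes with expression values")
    edges = np.linspace(pooled.min(), pooled.max(), n_bins + 1)
    edges[-1] = np.nextafter(edges[-1], np.inf)  # include the max in the last bin

    binned: dict[str, dict[int, list[str]]] = {}
    for name, genes in sets.items():
        gs = [g for g in genes if g in expr.index]
        bins = np.digitize(expr[gs].to_numpy(), edges) - 1
        d: dict[int, list[str]] = {}
        for g, b in zip(gs, bins):
            d.setdefault(int(b), []).append(g)
        binned[name] = d

    out: dict[str, list[str]] = {name: [] for name in sets}
    for b in range(n_bins):
        counts = [len(binned[name].get(b, [])) for name in sets]
        take = min(counts)
        if take == 0:
            continue  # bin empty in at least one set; skipped
        for name in sets:
            members = binned[name][b]
            chosen = rng.choice(len(members), size=take, replace=False)
            out[name].extend(members[i] for i in sorted(chosen))
    if all(len(v) == 0 for v in out.values()):
        raise ValueError(
            "equalization emptied every set; the expression ranges may be "
            "disjoint — try wider bins"
        )
    return out


def trim_mutation_estimates(
    values: Sequence[float] | pd.Series, fraction: float = 0.05
) -> np.ndarray | pd.Series:
    """Drop the upper ``fraction`` of mutation estimates.

    Removes the ceil(fraction * n) largest values; ties at the cutoff are
    broken by stable input order (later entries removed first).  Order of the
    retained values is preserved.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must be in [0, 1)")
    is_series = isinstance(values, pd.Series)
    arr = np.asarray(values, dtype=float)
    m = math.ceil(fraction * len(arr))
    if m == 0:
        return values.copy() if is_series else arr.copy()
    order = np.argsort(arr, kind="stable")
    keep = np.sort(order[:-m])
    if is_series:
        return values.iloc[keep]
    return arr[keep]
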
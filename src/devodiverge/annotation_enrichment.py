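"""Functional-category enrichment and cell-type/expression-breadth contrasts."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._stats import hypergeom_upper_tail
from .branch_analysis import bootstrap_median_ci
from .core_model import GeneSetAnnotation


@dataclass
class EnrichmentRow:
    category_id: str
    category_name: str
    n_test: int
    n_other: int
    p_raw: float
    p_bonferroni: float


@dataclass
class SpecificityContrast:
    gene_set: str
    metric: str
    mean_relative: float
    ci95: tuple[float, float]
    n_set: int
    n_boot: int
    seed: Optional[int]
    coverage_ok: bool  # metric defined for >= 80% of the set


def functional_enrichment(
    test_set: Iterable[str],
    background_set: Iterable[str],
    annotation: GeneSetAnnotation,
) -> list[EnrichmentRow]:
    """One-sided hypergeometric enrichment per category, Bonferroni-corrected.

    The universe is test ∪ background (background excludes test genes, the
    "Test"/"Other" convention); only categories with at least one test-set
    member are tested, and the Bonferroni factor is the number of categories
    actually tested.  Rows come back sorted by raw p.
    """
    test = set(test_set)
    if not test:
        raise ValueError("empty test set")
    background = set(background_set) - test
    universe = test | background

    rows = []
    for cid, (name, members) in annotation.categories.items():
        members_u = members & universe
        k = len(members_u & test)
        if k == 0:
            continue
        p = hypergeom_upper_tail(k, len(universe), len(members_u), len(test))
        rows.append((cid, name, k, len(members_u) - k, p))
    if not rows:
        warnings.warn("annotation has no overlap with the test set", UserWarning)
        return []
    m = len(rows)
    out = [
        EnrichmentRow(cid, name, k, other, p, min(1.0, p * m))
        for cid, name, k, other, p in rows
    ]
    out.sort(key=lambda r: r.p_raw)
    return out


def enrichment_table(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "category": [r.category_id for r in rows],
            "name": [r.category_name for r in rows],
            "n_test": [r.n_test for r in rows],
            "n_other": [r.n_other for r in rows],
            "p_raw": [r.p_raw for r in rows],
            "p_bonferroni": [r.p_bonferroni for r in rows],
        }
    )


def specificity_contrast(
    gene_set: Iterable[str],
    all_expressed: Iterable[str],
    metric: Mapping[str, float],
    n_boot: int = 1000,
    seed: Optional[int] = None,
    statistic: str = "mean",
    gene_set_id: str = "",
    metric_name: str = "",
) -> SpecificityContrast:
    """Set mean (or median) of a per-gene metric, relative to all expressed genes.

    The metric is, e.g., expression breadth (number of cell types expressing
    the gene) or a 0/1 neuron-/glia-specificity membership.  The CI is a
    percentile bootstrap over set genes.
    """
    gene_set = list(gene_set)
    all_expressed = list(all_expressed)
    set_vals = np.array([metric[g] for g in gene_set if g in metric], dtype=float)
    bg_vals = np.array([metric[g] for g in all_expressed if g in metric], dtype=float)
    if len(set_vals) == 0:
        raise ValueError("metric undefined for every gene in the set")
    coverage_ok = len(set_vals) >= 0.8 * len(gene_set)

    stat = np.mean if statistic == "mean" else np.median
    ref = float(stat(bg_vals))
    rel = float(stat(set_vals)) - ref

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(set_vals), size=(n_boot, len(set_vals)))
    boots = (
        np.mean(set_vals[idx], axis=1)
        if statistic == "mean"
        else np.median(set_vals[idx], axis=1)
    ) - ref
    ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
    return SpecificityContrast(
        gene_set=gene_set_id,
        metric=metric_name,
        mean_relative=rel,
        ci95=ci,
        n_set=len(set_vals),
        n_boot=n_boot,
        seed=seed,
        coverage_ok=coverage_ok,
    )
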
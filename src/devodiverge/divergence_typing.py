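"""Significance tests for expression divergence and the type I/II/III classification.

Three nested F-tests drive the typing of every gene:

* age test (per species): does expression change with transformed age?
  Polynomial family vs. intercept-only model.
* differential-expression test (per species pair, ANCOVA): do the two species
  share one trajectory?  Shared polynomial vs. per-species polynomials.
* pattern test (per species pair): after subtracting each species' own mean
  expression, do trajectory *shapes* differ?  Shared shape plus per-species
  intercepts vs. per-species polynomials — sensitive only to shape.

All tests compare the full polynomial family at the configured maximum
degree (capped by sample support), so the null distribution of each p-value
is exactly F and the tests are exactly calibrated.  Degree *selection*
(adjusted R^2 or forward F) is reserved for the trajectory models used in
distances and interpolation.

Genes are typed from the p-values:

* type I — constitutive divergence among constant genes: age test p > 0.01 in
  all species, differential-expression p < 0.001 in at least one pair.
* type II — constitutive divergence among developmental genes: age test
  p < 0.001 in at least one species, differential-expression p < 0.001 in at
  least one pair, pattern p > 0.01 in all pairs.
* type III — developmental remodeling: age test p < 0.001 in at least one
  species and some pair with both differential-expression and pattern
  p < 0.001.

The significance (0.001) and constancy/absence (0.01) bands are deliberately
non-exhaustive; genes falling between them stay unclassified ("none").
False-discovery rates are estimated by permuting ages within species (age
test) or species labels within a pair (ANCOVA tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_model import ExpressionDataset, species_pairs
from .trajectory_fit import (
    AgeTransform,
    FitConfig,
    polynomial_rss,
    transform_age,
)

Pair = tuple[str, str]


class DegenerateFitWarning(UserWarning):
    """Zero residual variance where the model has nonzero df."""


@dataclass
class DivergenceCall:
    feature_id: str
    p_age: dict[str, float]
    p_diff: dict[Pair, float]
    p_pattern: dict[Pair, float]
    dtype: str = "none"


@dataclass(frozen=True)
class TypingThresholds:
    """Default p-value bands used to assign divergence types."""

    age_sig: float = 0.001
    age_const: float = 0.01
    diff_sig: float = 0.001
    pattern_sig: float = 0.001
    pattern_absent: float = 0.01


@dataclass
class FdrEstimate:
    observed_significant: int
    mean_permuted_significant: float
    fdr: float  # NaN with defined=False when nothing is observed
    n_permutations: int
    seed: Optional[int]
    defined: bool = True


# ---------------------------------------------------------------------------
# F-test machinery
# ---------------------------------------------------------------------------

def _nested_f_p(
    rss_reduced: float, rss_full: float, df_num: int, df_den: int, scale: float
) -> float:
    """p-value of the nested-model F-test, with degenerate-fit handling."""
    if df_num < 1 or df_den < 1:
        raise ValueError("not enough residual degrees of freedom for the F-test")
    eps = 1e-12 * max(1.0, scale)
    if rss_full <= eps:
        if rss_reduced - rss_full <= eps:
            return 1.0
        warnings.warn(
            "zero residual variance with nonzero model df; p set to 0",
            DegenerateFitWarning,
        )
        return 0.0
    f = ((rss_reduced - rss_full) / df_num) / (rss_full / df_den)
    return float(stats.f.sf(max(f, 0.0), df_num, df_den))


def _family_degree(max_degree: int, *xs: np.ndarray) -> int:
    """Degree of the polynomial family supportable by every species' design."""
    d = max_degree
    for x in xs:
        d = min(d, len(np.unique(x)) - 1)
    return max(d, 0)


def age_test(x, y, fit_cfg: FitConfig = FitConfig()) -> float:
    """F-test of the polynomial age family against the intercept-only model."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("age test needs at least 4 samples")
    d = _family_degree(fit_cfg.max_degree, x)
    d = min(d, n - 2)
    if d < 1:
        return 1.0
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = polynomial_rss(x, y, d)
    return _nested_f_p(tss, rss, d, n - d - 1, scale=tss)


def diff_expr_test(xA, yA, xB, yB, fit_cfg: FitConfig = FitConfig()) -> float:
    """ANCOVA F-test: one shared trajectory vs. per-species trajectories."""
    xA, yA, xB, yB = (np.asarray(v, dtype=float) for v in (xA, yA, xB, yB))
    nA, nB = len(xA), len(xB)
    if nA < 4 or nB < 4:
        raise ValueError("differential-expression test needs >= 4 samples per species")
    d = _family_degree(fit_cfg.max_degree, xA, xB)
    d = max(d, 1) if len(np.unique(np.r_[xA, xB])) > 1 else 0
    d = min(d, (nA + nB - 3) // 2)
    x_pool = np.r_[xA, xB]
    y_pool = np.r_[yA, yB]
    rss_reduced = polynomial_rss(x_pool, y_pool, d)
    rss_full = polynomial_rss(xA, yA, d) + polynomial_rss(xB, yB, d)
    df_den = nA + nB - 2 * (d + 1)
    scale = float(np.sum((y_pool - y_pool.mean()) ** 2))
    return _nested_f_p(rss_reduced, rss_full, d + 1, df_den, scale=scale)


def pattern_test(xA, yA, xB, yB, fit_cfg: FitConfig = FitConfig()) -> float:
    """Shape-only ANCOVA on per-species mean-centered data.

    Constitutive (mean) differences are subtracted per species before
    testing, and the reduced model keeps per-species intercepts, so the
    p-value responds only to trajectory-shape divergence and is invariant to
    any per-species constant shift.
    """
    xA, yA, xB, yB = (np.asarray(v, dtype=float) for v in (xA, yA, xB, yB))
    nA, nB = len(xA), len(xB)
    if nA < 4 or nB < 4:
        raise ValueError("pattern test needs >= 4 samples per species")
    yA = yA - yA.mean()
    yB = yB - yB.mean()
    d = _family_degree(fit_cfg.max_degree, xA, xB)
    d = max(d, 1) if len(np.unique(np.r_[xA, xB])) > 1 else 0
    d = min(d, (nA + nB - 3) // 2)
    if d < 1:
        return 1.0
    # reduced: shared shape terms + per-species intercepts
    x_pool = np.r_[xA, xB]
    y_pool = np.r_[yA, yB]
    shape = np.vander(x_pool, d + 1, increasing=True)[:, 1:]
    dummies = np.zeros((nA + nB, 2))
    dummies[:nA, 0] = 1.0
    dummies[nA:, 1] = 1.0
    X_red = np.hstack([dummies, shape])
    beta, _, _, _ = np.linalg.lstsq(X_red, y_pool, rcond=None)
    resid = y_pool - X_red @ beta
    rss_reduced = float(resid @ resid)
    rss_full = polynomial_rss(xA, yA, d) + polynomial_rss(xB, yB, d)
    df_den = nA + nB - 2 * (d + 1)
    scale = float(np.sum((y_pool - y_pool.mean()) ** 2))
    return _nested_f_p(rss_reduced, rss_full, d, df_den, scale=scale)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_types(
    call: DivergenceCall, thresholds: TypingThresholds = TypingThresholds()
) -> str:
    """Assign a divergence type from the stored p-values (pure function)."""
    th = thresholds
    for label, mapping in (
        ("p_age", call.p_age),
        ("p_diff", call.p_diff),
        ("p_pattern", call.p_pattern),
    ):
        if not mapping or any(p is None or np.isnan(p) for p in mapping.values()):
            raise ValueError(f"missing {label} values for {call.feature_id!r}")

    age_all_constant = all(p > th.age_const for p in call.p_age.values())
    age_some_sig = min(call.p_age.values()) < th.age_sig
    diff_some_sig = min(call.p_diff.values()) < th.diff_sig
    pattern_all_absent = all(p > th.pattern_absent for p in call.p_pattern.values())
    joint_pair = any(
        call.p_diff[pair] < th.diff_sig and call.p_pattern[pair] < th.pattern_sig
        for pair in call.p_diff
        if pair in call.p_pattern
    )

    if age_all_constant and diff_some_sig:
        return "I"
    if age_some_sig and diff_some_sig and pattern_all_absent:
        return "II"
    if age_some_sig and joint_pair:
        return "III"
    return "none"


def classify_dataset(
    dataset: ExpressionDataset,
    transform: AgeTransform,
    fit_cfg: FitConfig = FitConfig(),
    thresholds: TypingThresholds = TypingThresholds(),
    features: Optional[Sequence[str]] = None,
) -> tuple[list[DivergenceCall], pd.DataFrame]:
    """Run all three tests on every feature and type each gene.

    Returns the calls and a tidy table (one row per feature) with columns
    ``p_age.<species>``, ``p_diff.<A>-<B>``, ``p_pattern.<A>-<B>`` and
    ``dtype``.
    """
    if features is None:
        features = dataset.feature_ids
    present = [sp for sp in dataset.species_order if dataset.species_columns(sp)]
    xs = {sp: transform_age(dataset.species_ages(sp), sp, transform) for sp in present}
    cols = {sp: dataset.species_columns(sp) for sp in present}
    pairs = [p for p in species_pairs(dataset.species_order) if set(p) <= set(present)]

    calls: list[DivergenceCall] = []
    rows = []
    for fid in features:
        row = dataset.values.loc[fid]
        ys = {sp: row[cols[sp]].to_numpy(dtype=float) for sp in present}
        p_age = {sp: age_test(xs[sp], ys[sp], fit_cfg) for sp in present}
        p_diff = {
            pr: diff_expr_test(xs[pr[0]], ys[pr[0]], xs[pr[1]], ys[pr[1]], fit_cfg)
            for pr in pairs
        }
        p_pattern = {
            pr: pattern_test(xs[pr[0]], ys[pr[0]], xs[pr[1]], ys[pr[1]], fit_cfg)
            for pr in pairs
        }
        call = DivergenceCall(fid, p_age, p_diff, p_pattern)
        call.dtype = classify_types(call, thresholds)
        calls.append(call)
        rec: dict[str, object] = {"feature_id": fid}
        rec.update({f"p_age.{sp}": p_age[sp] for sp in present})
        rec.update({f"p_diff.{a}-{b}": p_diff[(a, b)] for a, b in pairs})
        rec.update({f"p_pattern.{a}-{b}": p_pattern[(a, b)] for a, b in pairs})
        rec["dtype"] = call.dtype
        rows.append(rec)
    return calls, pd.DataFrame(rows).set_index("feature_id")


# ---------------------------------------------------------------------------
# Permutation FDR
# ---------------------------------------------------------------------------

def _min_p_per_feature(
    values: pd.DataFrame,
    xs: dict[str, np.ndarray],
    cols: dict[str, list[str]],
    pairs: Sequence[Pair],
    test: str,
    fit_cfg: FitConfig,
) -> np.ndarray:
    out = np.empty(len(values))
    for i, fid in enumerate(values.index):
        row = values.loc[fid]
        if test == "age":
            p = min(
                age_test(xs[sp], row[cols[sp]].to_numpy(dtype=float), fit_cfg)
                for sp in xs
            )
        else:
            fn = diff_expr_test if test == "diff" else pattern_test
            p = min(
                fn(
                    xs[a],
                    row[cols[a]].to_numpy(dtype=float),
                    xs[b],
                    row[cols[b]].to_numpy(dtype=float),
                    fit_cfg,
                )
                for a, b in pairs
            )
        out[i] = p
    return out


def permutation_fdr(
    dataset: ExpressionDataset,
    transform: AgeTransform,
    test: Literal["age", "diff", "pattern"] = "age",
    alpha: float = 0.001,
    n_perm: int = 1000,
    seed: Optional[int] = None,
    fit_cfg: FitConfig = FitConfig(),
    features: Optional[Sequence[str]] = None,
) -> FdrEstimate:
    """Estimate the FDR of a test at ``alpha`` by label permutation.

    The age test permutes individuals' ages within each species; the
    differential-expression and pattern tests permute species identity within
    each species pair (group sizes preserved).  The FDR is the mean number of
    significant features across permutations divided by the observed number.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if test not in ("age", "diff", "pattern"):
        raise ValueError(f"unknown test {test!r}")
    rng = np.random.default_rng(seed)
    if features is None:
        features = dataset.feature_ids
    values = dataset.values.loc[list(features)]
    present = [sp for sp in dataset.species_order if dataset.species_columns(sp)]
    xs = {sp: transform_age(dataset.species_ages(sp), sp, transform) for sp in present}
    cols = {sp: dataset.species_columns(sp) for sp in present}
    pairs = [p for p in species_pairs(dataset.species_order) if set(p) <= set(present)]

    observed_p = _min_p_per_feature(values, xs, cols, pairs, test, fit_cfg)
    observed = int(np.sum(observed_p < alpha))

    counts = np.empty(n_perm)
    for it in range(n_perm):
        if test == "age":
            perm_xs = {sp: rng.permutation(xs[sp]) for sp in xs}
            n_sig = 0
            for fid in values.index:
                row = values.loc[fid]
                p = min(
                    age_test(perm_xs[sp], row[cols[sp]].to_numpy(dtype=float), fit_cfg)
                    for sp in perm_xs
                )
                n_sig += p < alpha
        else:
            # shuffle species identity within each pair; every sample keeps
            # its own age, only the species label moves
            fn = diff_expr_test if test == "diff" else pattern_test
            splits: dict[Pair, tuple[np.ndarray, list[str], np.ndarray, list[str]]] = {}
            for a, b in pairs:
                pooled_x = np.r_[xs[a], xs[b]]
                pooled_cols = cols[a] + cols[b]
                idx = rng.permutation(len(pooled_cols))
                ia, ib = idx[: len(cols[a])], idx[len(cols[a]) :]
                splits[(a, b)] = (
                    pooled_x[ia],
                    [pooled_cols[i] for i in ia],
                    pooled_x[ib],
                    [pooled_cols[i] for i in ib],
                )
            n_sig = 0
            for fid in values.index:
                row = values.loc[fid]
                p = min(
                    fn(
                        xa,
                        row[ca].to_numpy(dtype=float),
                        xb,
                        row[cb].to_numpy(dtype=float),
                        fit_cfg,
                    )
                    for xa, ca, xb, cb in splits.values()
                )
                n_sig += p < alpha
        counts[it] = n_sig

    mean_perm = float(counts.mean())
    if observed == 0:
        return FdrEstimate(0, mean_perm, np.nan, n_perm, seed, defined=False)
    return FdrEstimate(observed, mean_perm, mean_perm / observed, n_perm, seed)
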
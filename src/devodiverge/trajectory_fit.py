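"""Age transformation, polynomial trajectory fitting, and common-grid interpolation.

Expression changes with age are modeled per gene and species as ordinary
least-squares polynomials in transformed age.  Age is transformed to a
log2 scale after adding a per-species offset (defaulting to gestation
length, so age 0 = birth stays finite), or through a monotone piecewise
linear life-history landmark map onto a reference species' timeline.
Fitted trajectories are compared between species on a shared grid spanning
the overlap of the species' transformed-age ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy import stats

from .core_model import SampleRecord

#: Default per-species additive age offsets, in days (gestation lengths).
DEFAULT_OFFSETS = {"human": 280.0, "chimpanzee": 224.0, "macaque": 165.0}


class AgeTransformError(ValueError):
    pass


@dataclass(frozen=True)
class AgeTransform:
    """Maps chronological age (days since birth) to the modeling scale.

    mode="log2_offset": x = log2(age + offset_species).
    mode="life_history": age is first mapped onto the reference species'
    timeline through a piecewise-linear interpolation of landmark pairs
    (own-species age -> reference age), then log2(+offset_reference).
    """

    mode: Literal["log2_offset", "life_history"] = "log2_offset"
    offsets: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OFFSETS)
    )
    landmark_map: Optional[Mapping[str, Sequence[tuple[float, float]]]] = None
    reference: str = "human"

    def __post_init__(self) -> None:
        for sp, off in self.offsets.items():
            if off <= 0:
                raise AgeTransformError(f"offset for {sp!r} must be > 0")
        if self.mode == "life_history":
            if self.landmark_map is None:
                raise AgeTransformError("life_history mode needs landmark_map")
            for sp, pairs in self.landmark_map.items():
                own = [p[0] for p in pairs]
                ref = [p[1] for p in pairs]
                if len(pairs) < 2 or np.any(np.diff(own) <= 0) or np.any(
                    np.diff(ref) <= 0
                ):
                    raise AgeTransformError(
                        f"landmark map for {sp!r} must be strictly increasing "
                        "in both coordinates with >= 2 landmarks"
                    )


def transform_age(age_days: float, species: str, t: AgeTransform) -> float:
    """Transform one age; vectorized over array input."""
    age = np.asarray(age_days, dtype=float)
    if np.any(age < 0):
        raise AgeTransformError("age must be >= 0")
    if t.mode == "log2_offset":
        if species not in t.offsets:
            raise AgeTransformError(f"no age offset configured for {species!r}")
        out = np.log2(age + t.offsets[species])
    else:
        assert t.landmark_map is not None
        if species not in t.landmark_map:
            raise AgeTransformError(f"no landmark map for species {species!r}")
        pairs = t.landmark_map[species]
        own = np.array([p[0] for p in pairs], dtype=float)
        ref = np.array([p[1] for p in pairs], dtype=float)
        mapped = _interp_extrap(age, own, ref)
        if t.reference not in t.offsets:
            raise AgeTransformError(
                f"no age offset configured for reference {t.reference!r}"
            )
        out = np.log2(mapped + t.offsets[t.reference])
    return float(out) if np.ndim(age_days) == 0 else out


def _interp_extrap(x: np.ndarray, xp: np.ndarray, fp: np.ndarray) -> np.ndarray:
    """np.interp with linear extrapolation beyond the landmark range."""
    y = np.interp(x, xp, fp)
    lo = x < xp[0]
    hi = x > xp[-1]
    if np.any(lo):
        slope = (fp[1] - fp[0]) / (xp[1] - xp[0])
        y = np.where(lo, fp[0] + slope * (x - xp[0]), y)
    if np.any(hi):
        slope = (fp[-1] - fp[-2]) / (xp[-1] - xp[-2])
        y = np.where(hi, fp[-1] + slope * (x - xp[-1]), y)
    return y


@dataclass(frozen=True)
class FitConfig:
    """Polynomial family and degree-selection rule for trajectory fits."""

    max_degree: int = 3
    selection: Literal["adjR2", "ftest"] = "adjR2"
    ftest_alpha: float = 0.05


@dataclass
class TrajectoryModel:
    """A per-gene per-species polynomial trajectory on transformed age."""

    feature_id: str
    species: str
    degree: int
    coefficients: np.ndarray  # beta_0 .. beta_d, ascending powers
    n: int
    rss: float
    df_resid: int

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return npoly.polyval(x, self.coefficients)


def _ols_poly(x: np.ndarray, y: np.ndarray, degree: int) -> tuple[np.ndarray, float]:
    """Least-squares polynomial coefficients (ascending) and residual SS."""
    X = np.vander(x, degree + 1, increasing=True)
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def polynomial_rss(x: np.ndarray, y: np.ndarray, degree: int) -> float:
    """Residual sum of squares of the degree-d OLS polynomial fit."""
    return _ols_poly(x, y, degree)[1]


def fit_trajectory(
    x: np.ndarray,
    y: np.ndarray,
    max_degree: int = 3,
    selection: Literal["adjR2", "ftest"] = "adjR2",
    feature_id: str = "",
    species: str = "",
    ftest_alpha: float = 0.05,
) -> TrajectoryModel:
    """Fit polynomials of degree 0..max_degree and select one.

    selection="adjR2" keeps the degree maximizing adjusted R^2 (degree 0 has
    adjusted R^2 = 0 by convention); "ftest" adds terms by forward nested
    F-tests at ``ftest_alpha``.  The degree is capped at (#distinct x - 1)
    when x contains duplicates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n != len(y):
        raise ValueError("x and y length mismatch")
    n_distinct = len(np.unique(x))
    cap = min(max_degree, n_distinct - 1 if n_distinct > 1 else 0)
    cap = max(cap, 0)
    if n < cap + 2:
        raise ValueError(f"need at least {cap + 2} samples for degree {cap}")

    fits = {d: _ols_poly(x, y, d) for d in range(cap + 1)}
    tss = float(np.sum((y - y.mean()) ** 2))
    eps = 1e-12 * max(1.0, tss)

    if selection == "adjR2":
        best_d, best_adj = 0, 0.0
        for d in range(1, cap + 1):
            rss = fits[d][1]
            df = n - (d + 1)
            if df < 1 or tss <= 0:
                continue
            adj = 1.0 - (rss / df) / (tss / (n - 1))
            if adj > best_adj + 1e-12:
                best_d, best_adj = d, adj
        degree = best_d
    elif selection == "ftest":
        degree = 0
        for d in range(1, cap + 1):
            rss_lo, rss_hi = fits[d - 1][1], fits[d][1]
            df_hi = n - (d + 1)
            if df_hi < 1:
                break
            if rss_hi <= eps:  # lower-degree model already (near) exact
                if rss_lo > rss_hi + eps:
                    degree = d
                continue
            f = (rss_lo - rss_hi) / (rss_hi / df_hi)
            p = stats.f.sf(f, 1, df_hi)
            if p < ftest_alpha:
                degree = d
            else:
                break
    else:
        raise ValueError(f"unknown selection rule {selection!r}")

    beta, rss = fits[degree]
    return TrajectoryModel(
        feature_id=feature_id,
        species=species,
        degree=degree,
        coefficients=beta,
        n=n,
        rss=rss,
        df_resid=n - (degree + 1),
    )


@dataclass(frozen=True)
class AgeGrid:
    """Equally spaced transformed-age points inside the species overlap."""

    points: np.ndarray
    span: tuple[float, float]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if len(pts) < 2 or np.any(np.diff(pts) <= 0):
            raise ValueError("grid needs >= 2 strictly increasing points")

    def __len__(self) -> int:
        return len(self.points)


def common_age_grid(
    samples: Sequence[SampleRecord], t: AgeTransform, G: int = 20
) -> AgeGrid:
    """Grid over the intersection of per-species transformed-age ranges."""
    by_species: dict[str, list[float]] = {}
    for s in samples:
        by_species.setdefault(s.species, []).append(
            transform_age(s.age_days, s.species, t)
        )
    for sp, xs in by_species.items():
        if len(xs) < 2:
            raise ValueError(f"species {sp!r} has fewer than 2 samples")
    lo = max(min(xs) for xs in by_species.values())
    hi = min(max(xs) for xs in by_species.values())
    if lo >= hi:
        raise ValueError(
            "species transformed-age ranges do not overlap; consider the "
            "life_history age transform"
        )
    return AgeGrid(points=np.linspace(lo, hi, G), span=(lo, hi))


def interpolate(model: TrajectoryModel, grid: AgeGrid) -> np.ndarray:
    """Evaluate the fitted polynomial at every grid point."""
    return np.asarray(model.predict(grid.points), dtype=float)


def fit_species_trajectories(
    dataset,
    transform: AgeTransform,
    fit_cfg: FitConfig = FitConfig(),
    features: Optional[Sequence[str]] = None,
) -> dict[str, dict[str, TrajectoryModel]]:
    """Fit one trajectory per (feature, species) over a dataset.

    Returns ``models[feature_id][species]``.
    """
    if features is None:
        features = dataset.feature_ids
    xs = {
        sp: transform_age(dataset.species_ages(sp), sp, transform)
        for sp in dataset.species_order
        if dataset.species_columns(sp)
    }
    cols = {sp: dataset.species_columns(sp) for sp in xs}
    out: dict[str, dict[str, TrajectoryModel]] = {}
    values = dataset.values
    for fid in features:
        row = values.loc[fid]
        out[fid] = {
            sp: fit_trajectory(
                xs[sp],
                row[cols[sp]].to_numpy(dtype=float),
                max_degree=fit_cfg.max_degree,
                selection=fit_cfg.selection,
                feature_id=fid,
                species=sp,
                ftest_alpha=fit_cfg.ftest_alpha,
            )
            for sp in xs
        }
    return out


def smoothing_curve(x: np.ndarray, y: np.ndarray, grid_x: np.ndarray) -> np.ndarray:
    """Natural cubic smoothing spline evaluated on grid_x (plotting aid only).

    All statistics and distances in this package use the selected polynomial;
    this helper exists solely to draw figure-style curves.
    """
    from scipy.interpolate import UnivariateSpline

    order = np.argsort(x)
    xs, ys = np.asarray(x)[order], np.asarray(y)[order]
    # collapse duplicate x by averaging, as splines need strictly increasing x
    ux, inv = np.unique(xs, return_inverse=True)
    uy = np.bincount(inv, weights=ys) / np.bincount(inv)
    k = min(3, len(ux) - 1)
    spl = UnivariateSpline(ux, uy, k=k, s=len(ux) * np.var(uy) * 0.05)
    return spl(grid_x)
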
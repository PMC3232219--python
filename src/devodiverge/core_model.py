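"""Domain containers, TSV readers/writers, detection filtering, quantile normalization.

Expression data are log2 intensities in a genes x samples matrix, with a
sample-metadata table carrying species, brain region and age (days since
birth).  All downstream analyses (trajectory fitting, divergence typing,
branch statistics, the regulator screen) consume the :class:`ExpressionDataset`
built here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_SPECIES_ORDER = ("human", "chimpanzee", "macaque")


class DataValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class SampleRecord:
    """One profiled individual/tissue sample.

    ``age_days`` counts days since birth (newborns are 0); gestation is
    handled later by the age transform, not here.
    """

    sample_id: str
    species: str
    region: str
    age_days: float
    batch: Optional[str] = None
    quality: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.age_days) or self.age_days < 0:
            raise DataValidationError(
                f"sample {self.sample_id!r}: age_days must be finite and >= 0, "
                f"got {self.age_days!r}"
            )


@dataclass
class ExpressionDataset:
    """Log2 expression matrix plus aligned sample metadata.

    ``values`` has feature ids as the index and sample ids as columns, in the
    metadata order.  ``species_order`` fixes the ingroup pair (first two) and
    the outgroup (last).
    """

    values: pd.DataFrame
    samples: list[SampleRecord]
    feature_type: str = "mRNA"
    species_order: tuple[str, ...] = DEFAULT_SPECIES_ORDER

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise DataValidationError(f"duplicate sample ids: {dupes}")
        if list(self.values.columns) != ids:
            raise DataValidationError(
                "matrix columns do not match metadata sample order"
            )
        if self.values.index.has_duplicates:
            dupes = sorted(self.values.index[self.values.index.duplicated()])
            raise DataValidationError(f"duplicate feature ids: {dupes[:10]}")
        unknown = sorted(
            {s.species for s in self.samples} - set(self.species_order)
        )
        if unknown:
            raise DataValidationError(
                f"species {unknown} not in configured set {self.species_order}"
            )

    # -- conveniences -----------------------------------------------------
    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "species": [s.species for s in self.samples],
                "region": [s.region for s in self.samples],
                "age_days": [s.age_days for s in self.samples],
                "batch": [s.batch for s in self.samples],
                "quality": [s.quality for s in self.samples],
            }
        )

    def species_samples(self, species: str) -> list[SampleRecord]:
        return [s for s in self.samples if s.species == species]

    def species_columns(self, species: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.species == species]

    def species_values(self, feature_id: str, species: str) -> np.ndarray:
        cols = self.species_columns(species)
        return self.values.loc[feature_id, cols].to_numpy(dtype=float)

    def species_ages(self, species: str) -> np.ndarray:
        return np.array(
            [s.age_days for s in self.samples if s.species == species], dtype=float
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionDataset":
        keep = set(sample_ids)
        samples = [s for s in self.samples if s.sample_id in keep]
        cols = [s.sample_id for s in samples]
        return ExpressionDataset(
            self.values[cols].copy(), samples, self.feature_type, self.species_order
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "ExpressionDataset":
        return ExpressionDataset(
            self.values.loc[list(feature_ids)].copy(),
            list(self.samples),
            self.feature_type,
            self.species_order,
        )


@dataclass
class TargetTable:
    """Regulator -> predicted target sets, with optional context-like scores."""

    pairs: dict[str, set[str]]
    scores: Optional[dict[tuple[str, str], float]] = None

    def __post_init__(self) -> None:
        for reg, targets in self.pairs.items():
            if not targets:
                raise DataValidationError(f"regulator {reg!r} has no targets")

    @property
    def regulators(self) -> list[str]:
        return sorted(self.pairs)

    def targets_of(self, regulator: str) -> set[str]:
        return self.pairs[regulator]


@dataclass
class GeneSetAnnotation:
    """Flat functional categories (KEGG/GO-like): id -> (name, member set)."""

    categories: dict[str, tuple[str, set[str]]]

    def __post_init__(self) -> None:
        for cid, (_, members) in self.categories.items():
            if not members:
                raise DataValidationError(f"category {cid!r} is empty")

    def members(self, category_id: str) -> set[str]:
        return self.categories[category_id][1]


#: Sequence scores are a plain DataFrame indexed by feature id with named
#: numeric columns (conservation means, per-lineage mutation counts,
#: binding-site densities, coding divergence); NaN marks missing values.
SequenceScoreTable = pd.DataFrame


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_expression_dataset(
    matrix_path: str | Path,
    metadata_path: str | Path,
    feature_type: str = "mRNA",
    species_order: tuple[str, ...] = DEFAULT_SPECIES_ORDER,
) -> ExpressionDataset:
    """Read a tab-separated expression matrix and its sample metadata.

    The matrix has a header row of sample ids and a first column of feature
    ids.  Metadata columns: sample_id, species, region, age_days (batch,
    quality optional).  Columns are reordered to metadata order, which is
    authoritative.
    """
    matrix = pd.read_csv(
        matrix_path, sep="\t", index_col=0, float_precision="round_trip"
    )
    meta = pd.read_csv(
        metadata_path, sep="\t", dtype={"sample_id": str},
        float_precision="round_trip",
    )
    required = {"sample_id", "species", "region", "age_days"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise DataValidationError(
            f"metadata is missing columns: {sorted(missing_cols)}"
        )
    matrix.columns = matrix.columns.astype(str)
    meta_ids = list(meta["sample_id"])
    orphans_meta = sorted(set(meta_ids) - set(matrix.columns))
    orphans_matrix = sorted(set(matrix.columns) - set(meta_ids))
    if orphans_meta or orphans_matrix:
        raise DataValidationError(
            "sample ids do not match between matrix and metadata; "
            f"in metadata only: {orphans_meta}; in matrix only: {orphans_matrix}"
        )
    if matrix.index.has_duplicates:
        dupes = sorted(matrix.index[matrix.index.duplicated()])
        raise DataValidationError(f"duplicate feature ids in matrix: {dupes[:10]}")
    non_numeric = matrix.columns[
        [not pd.api.types.is_numeric_dtype(t) for t in matrix.dtypes]
    ]
    if len(non_numeric):
        col = non_numeric[0]
        coerced = pd.to_numeric(matrix[col], errors="coerce")
        bad_rows = matrix.index[coerced.isna() & matrix[col].notna()]
        row = bad_rows[0] if len(bad_rows) else "?"
        raise DataValidationError(
            f"non-numeric expression value at row {row!r}, column {col!r}"
        )
    samples = [
        SampleRecord(
            sample_id=str(r.sample_id),
            species=str(r.species),
            region=str(r.region),
            age_days=float(r.age_days),
            batch=None if pd.isna(getattr(r, "batch", np.nan)) else str(r.batch),
            quality=None
            if pd.isna(getattr(r, "quality", np.nan))
            else float(r.quality),
        )
        for r in meta.itertuples(index=False)
    ]
    matrix = matrix[meta_ids].astype(float)
    return ExpressionDataset(matrix, samples, feature_type, species_order)


def write_expression_dataset(
    dataset: ExpressionDataset,
    matrix_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write the matrix and metadata in the formats `read_expression_dataset` accepts.

    Values are written with full float repr so a write/read round trip is
    bit-exact.
    """
    dataset.values.to_csv(
        matrix_path, sep="\t", index_label="feature_id", float_format=None
    )
    meta = dataset.metadata
    meta.to_csv(metadata_path, sep="\t", index=False)


def read_target_table(path: str | Path) -> TargetTable:
    """Read a regulator/target TSV (columns regulator_id, target_id[, score]).

    A TargetScan-style context-score export works as long as those two columns
    are present.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"regulator_id", "target_id"} <= set(df.columns):
        raise DataValidationError(
            "target table needs columns regulator_id and target_id"
        )
    if df.duplicated(["regulator_id", "target_id"]).any():
        dup = df[df.duplicated(["regulator_id", "target_id"])].iloc[0]
        raise DataValidationError(
            f"duplicate pair ({dup.regulator_id!r}, {dup.target_id!r})"
        )
    pairs: dict[str, set[str]] = {}
    for reg, sub in df.groupby("regulator_id"):
        pairs[str(reg)] = set(sub["target_id"])
    scores = None
    if "score" in df.columns:
        scores = {
            (str(r), str(t)): float(s)
            for r, t, s in zip(df.regulator_id, df.target_id, df.score)
            if not pd.isna(s)
        }
    return TargetTable(pairs, scores)


def write_target_table(table: TargetTable, path: str | Path) -> None:
    rows = []
    for reg in table.regulators:
        for tgt in sorted(table.pairs[reg]):
            score = (
                table.scores.get((reg, tgt)) if table.scores is not None else None
            )
            rows.append({"regulator_id": reg, "target_id": tgt, "score": score})
    df = pd.DataFrame(rows)
    if table.scores is None and "score" in df.columns:
        df = df.drop(columns=["score"])
    df.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> GeneSetAnnotation:
    """Read category memberships (category_id, category_name, target_id rows)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    need = {"category_id", "category_name", "target_id"}
    if not need <= set(df.columns):
        raise DataValidationError(f"annotation needs columns {sorted(need)}")
    categories: dict[str, tuple[str, set[str]]] = {}
    for cid, sub in df.groupby("category_id"):
        names = sub["category_name"].unique()
        categories[str(cid)] = (str(names[0]), set(sub["target_id"]))
    return GeneSetAnnotation(categories)


def write_annotation(annotation: GeneSetAnnotation, path: str | Path) -> None:
    rows = [
        {"category_id": cid, "category_name": name, "target_id": gid}
        for cid, (name, members) in sorted(annotation.categories.items())
        for gid in sorted(members)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sequence_scores(path: str | Path) -> SequenceScoreTable:
    df = pd.read_csv(
        path, sep="\t", index_col="feature_id", float_precision="round_trip"
    )
    return df.astype(float)


def write_sequence_scores(table: SequenceScoreTable, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="feature_id")


# ---------------------------------------------------------------------------
# Normalization and detection filtering
# ---------------------------------------------------------------------------

def quantile_normalize(dataset: ExpressionDataset) -> ExpressionDataset:
    """Quantile-normalize columns to a common distribution.

    The reference distribution is the per-rank mean over columns; ties within
    a column receive the mean of the reference values at their tied ranks, so
    the output is invariant to the order of tied entries and the procedure is
    idempotent.
    """
    values = dataset.values
    if values.isna().any().any():
        raise DataValidationError("missing values present; filter or impute first")
    if values.shape[1] < 2:
        warnings.warn("single-column dataset returned unchanged", UserWarning)
        return dataset
    arr = values.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = reference
        # average the reference over tied ranks
        ser = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = ser.to_numpy()
    normed = pd.DataFrame(out, index=values.index, columns=values.columns)
    return ExpressionDataset(
        normed, list(dataset.samples), dataset.feature_type, dataset.species_order
    )


def filter_detected(
    dataset: ExpressionDataset,
    detection_threshold: Optional[float] = None,
    min_fraction_per_species: float = 0.5,
    min_detected_per_sample: int = 0,
) -> ExpressionDataset:
    """Drop poorly hybridized samples, then undetected features.

    A feature is called detected in a sample when its value exceeds
    ``detection_threshold``.  First, samples whose detected-feature count does
    not exceed ``min_detected_per_sample`` are dropped; then only features
    detected in strictly more than ``min_fraction_per_species`` of the
    retained samples in *every* species are kept.  The default threshold is
    the matrix's 25th percentile, a stand-in used when the platform's own
    detection call is unavailable.
    """
    if detection_threshold is None:
        detection_threshold = float(np.percentile(dataset.values.to_numpy(), 25))
    detected = dataset.values > detection_threshold

    per_sample = detected.sum(axis=0)
    keep_samples = [
        s.sample_id
        for s in dataset.samples
        if per_sample[s.sample_id] > min_detected_per_sample
    ]
    if not keep_samples:
        raise DataValidationError(
            f"all samples dropped at min_detected_per_sample={min_detected_per_sample}"
        )
    ds = dataset.subset_samples(keep_samples)

    detected = ds.values > detection_threshold
    keep = pd.Series(True, index=ds.values.index)
    present_species = {s.species for s in ds.samples}
    for sp in ds.species_order:
        if sp not in present_species:
            continue
        cols = ds.species_columns(sp)
        frac = detected[cols].mean(axis=1)
        keep &= frac > min_fraction_per_species
    if not keep.any():
        raise DataValidationError("all features dropped by detection filtering")
    return ds.subset_features(list(ds.values.index[keep]))


def species_pairs(species_order: Sequence[str]) -> list[tuple[str, str]]:
    """All ordered species pairs, ingroup pair first: (A,B), (A,C), (B,C)."""
    a, b, c = species_order
    return [(a, b), (a, c), (b, c)]
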
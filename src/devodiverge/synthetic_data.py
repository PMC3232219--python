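"""Synthetic three-species developmental expression data with known ground truth.

The generator emulates a cross-species postnatal brain expression study:
log2 intensities for two hominids plus an outgroup (human, chimpanzee,
macaque by default), individuals sampled densely in early life (log-uniform
ages), and per-gene polynomial expression-age trajectories.  Implanted
structure mirrors the divergence taxonomy the pipeline detects:

* null genes — flat, no species differences;
* type I — flat trajectories with per-species constant shifts;
* type II — a shared age trajectory plus constant shifts;
* type III — a shared trajectory plus a mean-free shape perturbation on the
  ingroup lineages.  The perturbation lies along one remodeling axis per
  gene, with the human lineage displaced k times as far as the chimpanzee
  lineage and in the opposite direction, so the three pairwise curve
  distances are exactly tree-additive and the NJ branch lengths identify the
  implanted per-lineage magnitudes (median 2^R recovers k by construction).

Regulators (miRNA-like features measured on the same individuals) come in
two kinds: coupled regulators are themselves type III and their target genes
express ``-coupling`` times the regulator's signal (so regulator-target
correlations are strongly negative); decoys have ordinary trajectories and
random target sets.  Sequence scores, functional categories and a
target-prediction table are emitted alongside, with configurable couplings
to the implanted divergence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .core_model import (
    DEFAULT_SPECIES_ORDER,
    ExpressionDataset,
    GeneSetAnnotation,
    SampleRecord,
    TargetTable,
    write_annotation,
    write_expression_dataset,
    write_sequence_scores,
    write_target_table,
)
from .trajectory_fit import DEFAULT_OFFSETS, AgeTransform, transform_age

DEFAULT_AGE_RANGES = {
    "human": (0.0, 90 * 365.0),
    "chimpanzee": (0.0, 45 * 365.0),
    "macaque": (0.0, 28 * 365.0),
}


@dataclass
class SyntheticConfig:
    """Study conditions for one simulated dataset.

    Effect sizes are in log2-expression units.  ``human_acceleration`` is the
    multiplier on the human lineage's trajectory-shape displacement for
    type III genes; the default matches the magnitude of human-lineage
    acceleration the pipeline is meant to resolve in prefrontal cortex.
    """

    n_type1: int = 200
    n_type2: int = 200
    n_type3: int = 200
    n_null: int = 200
    n_coupled: int = 3
    n_decoy: int = 50
    targets_per_regulator: int = 15
    decoy_targets: int = 15
    n_per_species: int = 15
    age_ranges: dict = field(default_factory=lambda: dict(DEFAULT_AGE_RANGES))
    noise_sd: float = 0.1
    shift_sd: float = 1.0
    age_effect: float = 1.0
    remodel_effect: float = 0.5
    human_acceleration: float = 5.2
    coupling: float = 0.8
    seq_coupling: float = 0.3
    detection_floor: float = 4.0
    baseline_range: tuple[float, float] = (6.0, 12.0)
    region: str = "PFC"
    species_order: tuple[str, ...] = DEFAULT_SPECIES_ORDER
    seed: int = 0

    def validate(self) -> None:
        counts = (
            self.n_type1,
            self.n_type2,
            self.n_type3,
            self.n_null,
            self.n_coupled,
            self.n_decoy,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.human_acceleration < 1:
            raise ValueError("human_acceleration must be >= 1")
        if self.n_coupled * self.targets_per_regulator > self.n_type3:
            raise ValueError(
                "more coupled targets than type III genes: "
                f"{self.n_coupled} x {self.targets_per_regulator} > {self.n_type3}"
            )
        if self.n_per_species < 4:
            raise ValueError("need >= 4 samples per species")


@dataclass
class SyntheticTruth:
    """Ground truth emitted with every simulated dataset."""

    genes: pd.DataFrame  # feature_id, dtype, lineage, acceleration, effect, coupled_regulator
    regulators: pd.DataFrame  # regulator_id, coupled, n_targets


@dataclass
class SyntheticBundle:
    expression: ExpressionDataset
    regulator_expression: Optional[ExpressionDataset]
    targets: Optional[TargetTable]
    annotation: Optional[GeneSetAnnotation]
    seqscores: pd.DataFrame
    truth: SyntheticTruth
    transform: AgeTransform
    config: SyntheticConfig


def _random_shape(
    rng: np.random.Generator, span: tuple[float, float], grid: np.ndarray
) -> np.ndarray:
    """Random degree<=3 polynomial (ascending coeffs), mean-free and RMS 1 on grid.

    Coefficients are drawn on the age span rescaled to [-1, 1] and converted
    back, so shape complexity does not depend on the span's units.
    """
    lo, hi = span
    c = rng.normal(0.0, [0.0, 1.0, 0.6, 0.3])
    # polynomial in s = (2x - lo - hi) / (hi - lo); expand into powers of x
    a = 2.0 / (hi - lo)
    b = -(lo + hi) / (hi - lo)
    # s = a*x + b;  c0 + c1 s + c2 s^2 + c3 s^3 -> coefficients in x
    coeffs = np.zeros(4)
    s_pow = np.zeros((4, 4))  # s^k as polynomial in x
    s_pow[0, 0] = 1.0
    for k in range(1, 4):
        # multiply s^(k-1) by (a x + b)
        s_pow[k, 1:] += a * s_pow[k - 1, :3]
        s_pow[k, :] += b * s_pow[k - 1, :]
    for k in range(4):
        coeffs += c[k] * s_pow[k]
    vals = np.polynomial.polynomial.polyval(grid, coeffs)
    coeffs[0] -= vals.mean()
    rms = float(np.sqrt(np.mean((vals - vals.mean()) ** 2)))
    if rms < 1e-9:  # all-zero draw; fall back to a plain linear ramp
        coeffs = np.array([0.0, a, 0.0, 0.0])
        vals = np.polynomial.polynomial.polyval(grid, coeffs)
        coeffs[0] -= vals.mean()
        rms = float(np.sqrt(np.mean((vals - vals.mean()) ** 2)))
    return coeffs / rms


def _polyval(coeffs: np.ndarray, x: np.ndarray) -> np.ndarray:
    return np.polynomial.polynomial.polyval(x, coeffs)


def generate_dataset(cfg: SyntheticConfig) -> SyntheticBundle:
    """Simulate the full study bundle deterministically from ``cfg.seed``."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    species = list(cfg.species_order)
    transform = AgeTransform(mode="log2_offset", offsets=dict(DEFAULT_OFFSETS))

    # --- samples: log-uniform ages, dense in early life --------------------
    samples: list[SampleRecord] = []
    xs: dict[str, np.ndarray] = {}
    for sp in species:
        lo_d, hi_d = cfg.age_ranges[sp]
        off = transform.offsets[sp]
        u = rng.uniform(math.log2(lo_d + off), math.log2(hi_d + off), cfg.n_per_species)
        u.sort()
        ages = np.clip(2.0**u - off, 0.0, None)
        for i, age in enumerate(ages):
            samples.append(
                SampleRecord(
                    sample_id=f"{sp[:2]}{i + 1:02d}",
                    species=sp,
                    region=cfg.region,
                    age_days=float(age),
                )
            )
        xs[sp] = transform_age(ages, sp, transform)

    span = (
        max(x.min() for x in xs.values()),
        min(x.max() for x in xs.values()),
    )
    norm_grid = np.linspace(span[0], span[1], 101)

    # --- regulators --------------------------------------------------------
    n_reg = cfg.n_coupled + cfg.n_decoy
    reg_ids = [f"mir-{i + 1:03d}" for i in range(n_reg)]
    coupled_ids = reg_ids[: cfg.n_coupled]
    reg_signals: dict[str, dict[str, np.ndarray]] = {}
    reg_levels: dict[str, float] = {}
    reg_effects: dict[str, float] = {}
    for i, rid in enumerate(reg_ids):
        level = rng.uniform(*cfg.baseline_range)
        shifts = rng.normal(0.0, cfg.shift_sd, len(species))
        base = _random_shape(rng, span, norm_grid)
        coupled = rid in coupled_ids
        if coupled:
            axis = _random_shape(rng, span, norm_grid)
            e = cfg.remodel_effect * rng.uniform(0.7, 1.3)
            reg_effects[rid] = e
        reg_levels[rid] = level
        sig = {}
        for j, sp in enumerate(species):
            y = level + shifts[j] + cfg.age_effect * _polyval(base, xs[sp])
            if coupled:
                if sp == species[0]:  # accelerated ingroup lineage
                    y = y + cfg.human_acceleration * e * _polyval(axis, xs[sp])
                elif sp == species[1]:
                    y = y - e * _polyval(axis, xs[sp])
            sig[sp] = y
        reg_signals[rid] = sig

    # --- genes -------------------------------------------------------------
    n_genes = cfg.n_type1 + cfg.n_type2 + cfg.n_type3 + cfg.n_null
    gene_ids = [f"g{i + 1:04d}" for i in range(n_genes)]
    dtypes = (
        ["I"] * cfg.n_type1
        + ["II"] * cfg.n_type2
        + ["III"] * cfg.n_type3
        + ["null"] * cfg.n_null
    )
    type3_start = cfg.n_type1 + cfg.n_type2
    # the first blocks of type III genes are the coupled regulators' targets
    coupled_target_map: dict[str, str] = {}
    pos = type3_start
    for rid in coupled_ids:
        for _ in range(cfg.targets_per_regulator):
            coupled_target_map[gene_ids[pos]] = rid
            pos += 1

    gene_signals: dict[str, dict[str, np.ndarray]] = {}
    truth_rows = []
    for gid, dtype in zip(gene_ids, dtypes):
        level = rng.uniform(*cfg.baseline_range)
        row = {
            "feature_id": gid,
            "dtype": dtype,
            "lineage": "",
            "acceleration": np.nan,
            "effect": np.nan,
            "coupled_regulator": "",
        }
        if gid in coupled_target_map:
            rid = coupled_target_map[gid]
            sig = {
                sp: level
                - cfg.coupling * (reg_signals[rid][sp] - reg_levels[rid])
                for sp in species
            }
            row.update(
                lineage=species[0],
                acceleration=cfg.human_acceleration,
                effect=cfg.coupling * reg_effects[rid],
                coupled_regulator=rid,
            )
        else:
            shifts = (
                rng.normal(0.0, cfg.shift_sd, len(species))
                if dtype != "null"
                else np.zeros(len(species))
            )
            sig = {sp: np.full_like(xs[sp], level) + shifts[j] for j, sp in enumerate(species)}
            if dtype in ("II", "III"):
                base = _random_shape(rng, span, norm_grid)
                for sp in species:
                    sig[sp] = sig[sp] + cfg.age_effect * _polyval(base, xs[sp])
            if dtype == "III":
                axis = _random_shape(rng, span, norm_grid)
                e = cfg.remodel_effect * rng.uniform(0.7, 1.3)
                k = cfg.human_acceleration
                sig[species[0]] = sig[species[0]] + k * e * _polyval(axis, xs[species[0]])
                sig[species[1]] = sig[species[1]] - e * _polyval(axis, xs[species[1]])
                row.update(lineage=species[0], acceleration=k, effect=e)
        gene_signals[gid] = sig
        truth_rows.append(row)

    # --- assemble matrices with iid Gaussian noise -------------------------
    col_ids = [s.sample_id for s in samples]
    sp_cols = {sp: [s.sample_id for s in samples if s.species == sp] for sp in species}

    def build_matrix(ids, signals):
        mat = np.empty((len(ids), len(col_ids)))
        col_index = {c: i for i, c in enumerate(col_ids)}
        for r, fid in enumerate(ids):
            for sp in species:
                idx = [col_index[c] for c in sp_cols[sp]]
                mat[r, idx] = signals[fid][sp]
        mat += rng.normal(0.0, cfg.noise_sd, mat.shape)
        return pd.DataFrame(mat, index=ids, columns=col_ids)

    expr = ExpressionDataset(
        build_matrix(gene_ids, gene_signals),
        list(samples),
        feature_type="mRNA",
        species_order=cfg.species_order,
    )
    reg_expr = None
    if n_reg:
        reg_expr = ExpressionDataset(
            build_matrix(reg_ids, reg_signals),
            list(samples),
            feature_type="miRNA",
            species_order=cfg.species_order,
        )

    # --- target table ------------------------------------------------------
    targets = None
    if n_reg:
        pairs: dict[str, set[str]] = {}
        scores: dict[tuple[str, str], float] = {}
        for rid in coupled_ids:
            tgts = {g for g, r in coupled_target_map.items() if r == rid}
            pairs[rid] = tgts
        for rid in reg_ids[cfg.n_coupled :]:
            chosen = rng.choice(n_genes, size=min(cfg.decoy_targets, n_genes), replace=False)
            pairs[rid] = {gene_ids[i] for i in chosen}
        for rid, tgts in pairs.items():
            for g in tgts:
                scores[(rid, g)] = float(np.round(-rng.uniform(0.05, 0.6), 3))
        targets = TargetTable(pairs, scores)

    # --- annotation --------------------------------------------------------
    annotation = None
    if n_genes >= 50:
        categories: dict[str, tuple[str, set[str]]] = {}
        type3_ids = [g for g, d in zip(gene_ids, dtypes) if d == "III"]
        for c in range(15):
            size = int(rng.integers(25, 60))
            members = {gene_ids[i] for i in rng.choice(n_genes, size=size, replace=False)}
            categories[f"cat{c + 1:02d}"] = (f"pathway {c + 1}", members)
        if type3_ids:
            n_neuro = min(40, len(type3_ids))
            n_from_t3 = int(round(0.7 * n_neuro))
            picked = set(
                np.array(type3_ids)[
                    rng.choice(len(type3_ids), size=n_from_t3, replace=False)
                ]
            )
            rest = [g for g in gene_ids if g not in picked]
            picked |= {
                rest[i]
                for i in rng.choice(len(rest), size=n_neuro - n_from_t3, replace=False)
            }
            categories["neuro"] = ("neuron-related", picked)
        annotation = GeneSetAnnotation(categories)

    # --- sequence scores ---------------------------------------------------
    is_t3 = np.array([d == "III" for d in dtypes])
    effects = np.array([r["effect"] for r in truth_rows], dtype=float)
    # latent divergence rank per gene: implanted effect size for type III
    # genes (all lineage magnitudes scale with it), noise for the rest
    z_div = rng.normal(0.0, 1.0, n_genes)
    has_e = is_t3 & np.isfinite(effects) & (effects > 0)
    if has_e.sum() >= 2:
        log_e = np.log(effects[has_e])
        z_div[has_e] = (log_e - log_e.mean()) / max(log_e.std(), 1e-9)

    def mutation_counts(rho: float) -> np.ndarray:
        latent = rho * z_div + math.sqrt(max(1.0 - rho**2, 0.0)) * rng.normal(
            0.0, 1.0, n_genes
        )
        return np.round(10.0 * np.exp(0.5 * latent)).astype(float)

    prom_cons = np.clip(rng.normal(0.5, 0.15, n_genes) + 0.15 * is_t3, 0.0, 1.0)
    utr_cons = np.clip(rng.normal(0.45, 0.15, n_genes) + 0.15 * is_t3, 0.0, 1.0)
    enh_cons = np.clip(rng.normal(0.4, 0.15, n_genes) + 0.1 * is_t3, 0.0, 1.0)
    seq = pd.DataFrame(
        {
            "promoter_conservation": prom_cons,
            "utr3_conservation": utr_cons,
            "enhancer_conservation": enh_cons,
            "coding_divergence": np.clip(
                rng.normal(0.15, 0.08, n_genes) - 0.05 * is_t3, 0.0, None
            ),
            "mut_human": mutation_counts(-cfg.seq_coupling),
            "mut_chimpanzee": mutation_counts(+cfg.seq_coupling),
            "mut_macaque": mutation_counts(+cfg.seq_coupling),
            "tfbs_density": np.clip(
                2.0 + 3.0 * prom_cons + 0.5 * is_t3 + rng.normal(0, 0.3, n_genes),
                0.0,
                None,
            ),
            "mirna_bs_density": np.clip(
                2.0 + 3.0 * utr_cons + 0.5 * is_t3 + rng.normal(0, 0.3, n_genes),
                0.0,
                None,
            ),
        },
        index=pd.Index(gene_ids, name="feature_id"),
    )
    # sprinkle explicit missing values into the conservation columns
    n_missing = int(0.02 * n_genes)
    if n_missing:
        for col in ("promoter_conservation", "utr3_conservation"):
            rows = rng.choice(n_genes, size=n_missing, replace=False)
            seq.iloc[rows, seq.columns.get_loc(col)] = np.nan

    truth = SyntheticTruth(
        genes=pd.DataFrame(truth_rows).set_index("feature_id"),
        regulators=pd.DataFrame(
            {
                "regulator_id": reg_ids,
                "coupled": [rid in coupled_ids for rid in reg_ids],
                "n_targets": [len(targets.pairs[rid]) if targets else 0 for rid in reg_ids],
            }
        ).set_index("regulator_id"),
    )
    return SyntheticBundle(
        expression=expr,
        regulator_expression=reg_expr,
        targets=targets,
        annotation=annotation,
        seqscores=seq,
        truth=truth,
        transform=transform,
        config=cfg,
    )


def write_dataset(bundle: SyntheticBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write every bundle component as TSV; re-reading reproduces the objects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["matrix"] = out / "matrix.tsv"
    paths["meta"] = out / "meta.tsv"
    write_expression_dataset(bundle.expression, paths["matrix"], paths["meta"])
    if bundle.regulator_expression is not None:
        paths["mirna_matrix"] = out / "mirna_matrix.tsv"
        bundle.regulator_expression.values.to_csv(
            paths["mirna_matrix"], sep="\t", index_label="feature_id"
        )
    if bundle.targets is not None:
        paths["targets"] = out / "targets.tsv"
        write_target_table(bundle.targets, paths["targets"])
    if bundle.annotation is not None:
        paths["annotation"] = out / "annotation.tsv"
        write_annotation(bundle.annotation, paths["annotation"])
    paths["seqscores"] = out / "seqscores.tsv"
    write_sequence_scores(bundle.seqscores, paths["seqscores"])
    paths["truth"] = out / "truth.tsv"
    bundle.truth.genes.to_csv(paths["truth"], sep="\t")
    paths["truth_regulators"] = out / "truth_regulators.tsv"
    bundle.truth.regulators.to_csv(paths["truth_regulators"], sep="\t")
    return paths
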
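"""Synthetic cohort generator with planted ground truth.

Every input the pipeline consumes is emulated here — a bilateral spherical
parcellation, a positively skewed two-timepoint trait, an age-dependent
spatially smooth regional MT matrix with a trait effect planted in chosen
regions, a spatially autocorrelated regions×genes expression matrix with a
planted component aligned to the true trait–MT map, enriched annotation
lists with a matched differential-expression table, and a protein-interaction
edge list containing a planted dense module.

Spatial smoothness is produced by a squared-exponential Gaussian-process
kernel over inter-centroid distance on the unit sphere.  The kernel is
evaluated on chordal (straight-line) distance, which is positive definite on
the sphere by restriction from R^3; for the length scales used here the
chordal and great-circle metrics are nearly identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from srmtx.config import GroundTruth, SyntheticConfig, stream_rng
from srmtx.exceptions import InvalidConfigError
from srmtx import io

log = logging.getLogger(__name__)

# Regional MT field hyper-parameters (MT expressed in saturation units of
# magnitude ~1): spatially smooth intercept-at-14 and per-year slope fields.
MT14_MEAN, MT14_SD = 1.0, 0.06
DMT_MEAN, DMT_SD = 0.010, 0.005


@dataclass
class SyntheticDataset:
    """In-memory bundle of all generated inputs plus their ground truth."""

    subjects: pd.DataFrame
    trait: pd.DataFrame
    mt: pd.DataFrame
    centroids: pd.DataFrame
    expression: pd.DataFrame
    genesets: dict[str, set[str]]
    de_tables: dict[str, pd.DataFrame]
    ppi_edges: pd.DataFrame
    truth: GroundTruth


# ---------------------------------------------------------------------------
# parcellation


def generate_parcellation(n_per_hemi: int, seed: int) -> pd.DataFrame:
    """Random bilateral parcellation: region name, hemisphere, unit centroid.

    Left-hemisphere centroids are drawn uniformly on the x<0 half of the unit
    sphere; right-hemisphere centroids are their sagittal mirror (x -> -x),
    as in a symmetric cortical atlas.
    """
    if n_per_hemi < 2:
        raise InvalidConfigError("n_per_hemi must be >= 2")
    rng = stream_rng(seed, "parcellation")
    v = rng.standard_normal((n_per_hemi, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    v[:, 0] = -np.abs(v[:, 0])  # left hemisphere: x < 0
    left = pd.DataFrame(
        {
            "region": [f"L_reg{i:02d}" for i in range(n_per_hemi)],
            "hemisphere": "L",
            "x": v[:, 0],
            "y": v[:, 1],
            "z": v[:, 2],
        }
    )
    right = left.copy()
    right["region"] = [f"R_reg{i:02d}" for i in range(n_per_hemi)]
    right["hemisphere"] = "R"
    right["x"] = -left["x"]
    return pd.concat([left, right], ignore_index=True)


def spherical_covariance(
    centroids: np.ndarray, length_scale: float, jitter: float = 1e-10
) -> np.ndarray:
    """Squared-exponential covariance over chordal distance on the sphere."""
    d2 = np.sum((centroids[:, None, :] - centroids[None, :, :]) ** 2, axis=-1)
    k = np.exp(-0.5 * d2 / length_scale**2)
    return k + jitter * np.eye(len(centroids))


def sample_smooth_fields(
    centroids: np.ndarray,
    length_scale: float,
    rng: np.random.Generator,
    n_fields: int = 1,
) -> np.ndarray:
    """Draw ``n_fields`` zero-mean unit-variance smooth fields (regions × fields)."""
    cov = spherical_covariance(centroids, length_scale)
    chol = np.linalg.cholesky(cov)
    return chol @ rng.standard_normal((len(centroids), n_fields))


# ---------------------------------------------------------------------------
# subjects and trait


def generate_subjects(
    n_subjects: int, age_range: tuple[float, float], seed: int
) -> pd.DataFrame:
    """Subject covariate table: age, sex, site, SES, brain volume, Euler number."""
    if n_subjects < 3:
        raise InvalidConfigError("n_subjects must be >= 3")
    rng = stream_rng(seed, "subjects")
    lo, hi = age_range
    ages = rng.uniform(lo, hi, n_subjects)
    sex = rng.choice(["F", "M"], n_subjects)
    site = rng.choice(["site1", "site2", "site3"], n_subjects)
    ses = rng.normal(0.0, 1.0, n_subjects)
    tbv = rng.normal(1.2e6, 1.0e5, n_subjects)
    # Euler numbers: even, negative, more negative = worse surface quality
    euler = -2 * rng.poisson(30, n_subjects)
    return pd.DataFrame(
        {
            "subject_id": [f"sub{i:04d}" for i in range(n_subjects)],
            "age": ages,
            "sex": sex,
            "site": site,
            "ses": ses,
            "total_brain_volume": tbv,
            "euler_number": euler,
        }
    )


def generate_trait_scores(
    n_subjects: int,
    trait_skew_params: tuple[float, float] | float,
    seed: int,
    timepoint_noise_sd: float = 0.03,
) -> pd.DataFrame:
    """Two-timepoint endorsement-rate scores on [0, 1].

    A latent trait T is drawn from a Beta distribution (or a point mass when
    a single float is given); the two assessments are T ± d with a symmetric,
    range-respecting measurement perturbation d, so their mean equals T
    exactly — the latent trait used for planting effects downstream.
    """
    if n_subjects < 3:
        raise InvalidConfigError("n_subjects must be >= 3")
    rng = stream_rng(seed, "trait")
    if isinstance(trait_skew_params, (int, float)):
        value = float(trait_skew_params)
        if not (0.0 <= value <= 1.0):
            raise InvalidConfigError("degenerate trait value must lie in [0, 1]")
        latent = np.full(n_subjects, value)
        timepoint_noise_sd = 0.0  # a true point mass: both assessments exact
    else:
        a, b = trait_skew_params
        if a <= 0 or b <= 0:
            raise InvalidConfigError("Beta shape parameters must be positive")
        latent = rng.beta(a, b, n_subjects)
    d = rng.normal(0.0, timepoint_noise_sd, n_subjects)
    bound = np.minimum(latent, 1.0 - latent)
    d = np.clip(d, -bound, bound)
    return pd.DataFrame(
        {
            "subject_id": [f"sub{i:04d}" for i in range(n_subjects)],
            "score_t1": latent + d,
            "score_t2": latent - d,
            "true_trait": latent,
        }
    )


# ---------------------------------------------------------------------------
# regional MT


def generate_mt_matrix(
    subjects: pd.DataFrame,
    centroids: pd.DataFrame,
    trait: pd.DataFrame,
    srm_regions: Sequence[int],
    srm_effect_r: float,
    noise_sd: float,
    spatial_length_scale: float,
    seed: int,
    background_effect_sd: float = 0.0,
) -> tuple[pd.DataFrame, dict]:
    """Subjects×regions MT matrix with a planted trait effect.

    MT[i, j] = a_j + b_j (age_i − 14) + β_j √T_i + ε_ij, with spatially smooth
    intercept a_j (MT at age 14) and slope b_j fields.  The target residual
    trait correlation is ``srm_effect_r`` in ``srm_regions``; with
    ``background_effect_sd`` > 0 the remaining regions carry a smooth,
    zero-mean background correlation field of that amplitude, emulating the
    spatially continuous trait–MT maps seen in cortical data, where the
    "significant" regions are the peaks of a smooth field rather than spikes
    in a sea of exact zeros.  β_j is scaled from the sample s.d. of √T so the
    age-residualized correlation matches the per-region target in
    expectation.

    The returned truth dict records ``true_srm_map`` — the per-region target
    correlation — alongside the planted regions and age-model fields.
    """
    n_regions = len(centroids)
    srm_regions = sorted(int(r) for r in srm_regions)
    if any(not (0 <= r < n_regions) for r in srm_regions):
        raise InvalidConfigError("srm_regions must index rows of the parcellation")
    has_effect = (srm_regions and srm_effect_r > 0) or background_effect_sd > 0
    if has_effect and noise_sd <= 0:
        raise InvalidConfigError(
            f"srm_effect_r={srm_effect_r} is unreachable with noise_sd=0: "
            "the residual correlation would be 1 in every planted region"
        )
    rng = stream_rng(seed, "mt")
    xyz = centroids[["x", "y", "z"]].to_numpy()
    fields = sample_smooth_fields(xyz, spatial_length_scale, rng, 3)
    a = MT14_MEAN + MT14_SD * fields[:, 0]
    b = DMT_MEAN + DMT_SD * fields[:, 1]

    # per-region target residual correlations
    r_target = np.zeros(n_regions)
    if background_effect_sd > 0:
        r_target = np.clip(
            background_effect_sd * fields[:, 2], -0.9 * srm_effect_r
            if srm_effect_r > 0 else -0.5, 0.9 * srm_effect_r
            if srm_effect_r > 0 else 0.5,
        )
    if srm_regions and srm_effect_r > 0:
        r_target[srm_regions] = srm_effect_r

    ages = subjects["age"].to_numpy()
    latent = trait["true_trait"].to_numpy()
    s = np.sqrt(latent)
    s_sd = s.std(ddof=1)
    beta = np.zeros(n_regions)
    if has_effect:
        if s_sd <= 0:
            raise InvalidConfigError(
                "trait is constant: planted effect size is undefined"
            )
        beta = r_target * noise_sd / (s_sd * np.sqrt(1.0 - r_target**2))

    mt = (
        a[None, :]
        + b[None, :] * (ages - 14.0)[:, None]
        + beta[None, :] * s[:, None]
        + noise_sd * rng.standard_normal((len(subjects), n_regions))
    )
    mt_df = pd.DataFrame(
        mt, index=subjects["subject_id"].to_numpy(), columns=centroids["region"]
    )
    mt_df.index.name = "subject_id"
    truth = {
        "true_srm_regions": list(centroids["region"].iloc[srm_regions]),
        "true_srm_map": r_target.tolist(),
        "age_model_truth": {
            r: (float(ai), float(bi))
            for r, ai, bi in zip(centroids["region"], a, b)
        },
        "beta": {r: float(bj) for r, bj in zip(centroids["region"], beta)},
    }
    return mt_df, truth


# ---------------------------------------------------------------------------
# expression


def generate_expression(
    centroids: pd.DataFrame,
    n_genes: int,
    true_srm_map: np.ndarray,
    planted_gene_fraction: float,
    spatial_length_scale: float,
    noise_sd: float,
    seed: int,
) -> tuple[pd.DataFrame, dict]:
    """Regions×genes expression with a planted component along the true map.

    Planted genes have regional profiles loading (±1) on the standardized
    true trait–MT map plus a spatially correlated noise field; the remaining
    genes are pure spatially correlated noise.  Gene-level baselines shift
    profiles to realistic positive expression levels.
    """
    if n_genes < 10:
        raise InvalidConfigError("n_genes must be >= 10")
    n_planted = int(round(planted_gene_fraction * n_genes))
    if n_planted < 2:
        raise InvalidConfigError(
            "planted_gene_fraction * n_genes must yield at least 2 planted genes"
        )
    n_regions = len(centroids)
    true_srm_map = np.asarray(true_srm_map, dtype=float)
    if true_srm_map.shape != (n_regions,):
        raise InvalidConfigError("true_srm_map must have one value per region")
    map_sd = true_srm_map.std()
    if map_sd <= 0:
        raise InvalidConfigError("true_srm_map is constant; nothing to plant")
    zmap = (true_srm_map - true_srm_map.mean()) / map_sd

    rng = stream_rng(seed, "expression")
    genes = [f"G{i:05d}" for i in range(n_genes)]
    n_pos = n_planted // 2 + n_planted % 2
    loadings = np.zeros(n_genes)
    loadings[:n_pos] = 1.0
    loadings[n_pos:n_planted] = -1.0

    xyz = centroids[["x", "y", "z"]].to_numpy()
    noise = sample_smooth_fields(xyz, spatial_length_scale, rng, n_genes)
    baseline = rng.normal(5.0, 1.0, n_genes)
    values = baseline[None, :] + loadings[None, :] * zmap[:, None] + noise_sd * noise
    expr = pd.DataFrame(values, index=centroids["region"].to_numpy(), columns=genes)
    expr.index.name = "region"
    truth = {
        "true_positive_genes": genes[:n_pos],
        "true_negative_genes": genes[n_pos:n_planted],
        "true_loadings": {g: float(l) for g, l in zip(genes, loadings)},
    }
    return expr, truth


# ---------------------------------------------------------------------------
# annotations, differential expression, PPI


def _weighted_subset(
    universe: Sequence[str],
    favored: set[str],
    odds: float,
    size: int,
    rng: np.random.Generator,
) -> set[str]:
    """Size-``size`` subset over-sampling ``favored`` at the given odds.

    Weighted sampling without replacement via exponential sort keys
    (Efraimidis–Spirakis); ``odds=inf`` selects favored genes first, so the
    infinite-odds limit is contained in the favored set.
    """
    universe = list(universe)
    w = np.where([g in favored for g in universe], float(odds), 1.0)
    keys = rng.exponential(1.0, len(universe))
    with np.errstate(divide="ignore"):
        keys = keys / w
    order = np.lexsort((universe, keys))  # deterministic at tied keys
    return {universe[i] for i in order[:size]}


def generate_annotations_and_ppi(
    universe: Sequence[str],
    true_positive_genes: Sequence[str],
    true_negative_genes: Sequence[str],
    enrichment_odds: float,
    annotation_size: int,
    de_effect: float,
    background_density: float,
    module_density: float,
    module_size: int,
    seed: int,
) -> tuple[dict[str, set[str]], dict[str, pd.DataFrame], pd.DataFrame, list[str]]:
    """Enriched annotation lists, DE tables, and a PPI edge list.

    Returns ``(genesets, de_tables, edges, module_genes)``:

    * ``downregulated_like`` over-samples the planted positive genes and
      ``upregulated_like`` the planted negative genes, at ``enrichment_odds``;
      cell-type-like lists mimic the same asymmetry (an interneuron-like list
      tracking positive genes, an astrocyte-like list tracking negative ones)
      plus two unenriched controls.
    * DE tables (two correlated disorder tables and one unrelated control)
      assign log-fold-changes anti-aligned with the planted loadings, so
      planted-positive genes look transcriptionally downregulated.
    * The PPI edge list is an Erdős–Rényi background at
      ``background_density`` plus a denser planted module (``module_density``)
      on ``module_size`` genes drawn from the planted positive set.
    """
    if not (0.0 <= background_density <= 1.0 and 0.0 <= module_density <= 1.0):
        raise InvalidConfigError("densities must lie in [0, 1]")
    if enrichment_odds <= 1.0:
        raise InvalidConfigError("enrichment_odds must be > 1 for enriched lists")
    rng = stream_rng(seed, "annotations")
    universe = list(universe)
    pos, neg = set(true_positive_genes), set(true_negative_genes)

    genesets: dict[str, set[str]] = {
        "downregulated_like": _weighted_subset(
            universe, pos, enrichment_odds, annotation_size, rng
        ),
        "upregulated_like": _weighted_subset(
            universe, neg, enrichment_odds, annotation_size, rng
        ),
        "interneuron_like": _weighted_subset(
            universe, pos, enrichment_odds, annotation_size, rng
        ),
        "astrocyte_like": _weighted_subset(
            universe, neg, enrichment_odds, annotation_size, rng
        ),
        "oligodendrocyte_like": _weighted_subset(
            universe, set(), np.inf, annotation_size, rng
        ),
        "microglia_like": _weighted_subset(
            universe, set(), np.inf, annotation_size, rng
        ),
    }

    loadings = np.array(
        [1.0 if g in pos else -1.0 if g in neg else 0.0 for g in universe]
    )
    de_tables: dict[str, pd.DataFrame] = {}
    for name in ("disorder_a", "disorder_b"):
        logfc = -de_effect * loadings + rng.normal(0.0, 1.0, len(universe))
        de_tables[name] = pd.DataFrame(
            {
                "gene": universe,
                "logFC": logfc,
                "sig_down": [g in genesets["downregulated_like"] for g in universe],
                "sig_up": [g in genesets["upregulated_like"] for g in universe],
            }
        )
    de_tables["unrelated"] = pd.DataFrame(
        {
            "gene": universe,
            "logFC": rng.normal(0.0, 1.0, len(universe)),
            "sig_down": False,
            "sig_up": False,
        }
    )

    ppi_rng = stream_rng(seed, "ppi")
    # The downstream edge test targets genes that are both positively weighted
    # and in the downregulated-like list, so the dense module is planted inside
    # that intersection (falling back to the full positive set if it is small).
    pool = sorted(pos & genesets["downregulated_like"])
    if len(pool) < max(2, module_size // 2):
        pool = sorted(pos)
    module_size = min(module_size, len(pool))
    module_genes = sorted(
        ppi_rng.choice(pool, size=module_size, replace=False).tolist()
    )
    n = len(universe)
    iu, ju = np.triu_indices(n, k=1)
    keep = ppi_rng.random(len(iu)) < background_density
    module_idx = np.flatnonzero(np.isin(universe, module_genes))
    in_module = np.isin(iu, module_idx) & np.isin(ju, module_idx)
    keep_module = ppi_rng.random(len(iu)) < module_density
    keep = np.where(in_module, keep_module, keep)
    edges = pd.DataFrame(
        {
            "gene_a": np.asarray(universe, dtype=object)[iu[keep]],
            "gene_b": np.asarray(universe, dtype=object)[ju[keep]],
        }
    )
    return genesets, de_tables, edges, module_genes


# ---------------------------------------------------------------------------
# full dataset


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate every pipeline input for ``config``, with ground truth."""
    seed = config.seed
    centroids = generate_parcellation(config.n_regions_per_hemisphere, seed)
    subjects = generate_subjects(config.n_subjects, config.age_range, seed)
    trait = generate_trait_scores(
        config.n_subjects,
        config.trait_skew_params,
        seed,
        timepoint_noise_sd=config.trait_timepoint_noise_sd,
    )
    if config.srm_regions is not None:
        srm_regions = list(config.srm_regions)
    else:
        plant_rng = stream_rng(seed, "plant")
        srm_regions = sorted(
            plant_rng.choice(config.n_regions, config.n_srm_regions, replace=False)
        )
    mt, mt_truth = generate_mt_matrix(
        subjects,
        centroids,
        trait,
        srm_regions,
        config.srm_effect_r,
        config.mt_noise_sd,
        config.spatial_length_scale,
        seed,
        background_effect_sd=config.srm_background_sd,
    )
    # true trait–MT correlation map: expected residual correlation per region
    true_map = np.asarray(mt_truth["true_srm_map"])
    expr, expr_truth = generate_expression(
        centroids,
        config.n_genes,
        true_map,
        config.planted_gene_fraction,
        config.spatial_length_scale,
        config.expression_noise_sd,
        seed,
    )
    genesets, de_tables, edges, module_genes = generate_annotations_and_ppi(
        list(expr.columns),
        expr_truth["true_positive_genes"],
        expr_truth["true_negative_genes"],
        config.enrichment_odds,
        config.annotation_size,
        config.de_effect,
        config.ppi_background_density,
        config.ppi_module_density,
        config.ppi_module_size,
        seed,
    )
    truth = GroundTruth(
        true_srm_regions=mt_truth["true_srm_regions"],
        true_positive_genes=expr_truth["true_positive_genes"],
        true_negative_genes=expr_truth["true_negative_genes"],
        true_module_genes=module_genes,
        age_model_truth=mt_truth["age_model_truth"],
        true_loadings=expr_truth["true_loadings"],
    )
    return SyntheticDataset(
        subjects=subjects,
        trait=trait,
        mt=mt,
        centroids=centroids,
        expression=expr,
        genesets=genesets,
        de_tables=de_tables,
        ppi_edges=edges,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write all inputs as plain-text files; returns name -> path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _write(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        paths[name] = str(path)

    _write("subjects.tsv", lambda p: dataset.subjects.to_csv(p, sep="\t", index=False))
    _write("trait.tsv", lambda p: dataset.trait.to_csv(p, sep="\t", index=False))
    _write("mt_matrix.tsv", lambda p: dataset.mt.to_csv(p, sep="\t"))
    _write("centroids.csv", lambda p: dataset.centroids.to_csv(p, index=False))
    _write("expression.tsv", lambda p: dataset.expression.to_csv(p, sep="\t"))
    _write("genesets.gmt", lambda p: io.write_gmt(dataset.genesets, p))
    for name, table in dataset.de_tables.items():
        _write(f"de_{name}.tsv", lambda p, t=table: t.to_csv(p, sep="\t", index=False))
    _write(
        "ppi_edges.tsv", lambda p: dataset.ppi_edges.to_csv(p, sep="\t", index=False)
    )
    _write(
        "ground_truth.json",
        lambda p: Path(p).write_text(json.dumps(dataset.truth.to_dict(), indent=1)),
    )
    log.info("wrote %d synthetic inputs to %s", len(paths), outdir)
    return paths
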
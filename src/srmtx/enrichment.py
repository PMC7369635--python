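"""Gene-set enrichment by random relabeling, and weight–DE correlations.

Enrichment of a target gene list (e.g. the significantly weighted PLS1
genes) in an annotation list is tested by repeatedly drawing random gene
sets of the same size from the analysis universe — the genes that entered
the PLS — and comparing the observed overlap to that null (upper tail,
+1-smoothed empirical p).  As the number of relabelings grows this p
converges to the hypergeometric upper tail, which serves as the oracle in
the test suite.

Gene-level convergence with case-control differential expression is
measured as the Spearman correlation between PLS1 weights and reported
log-fold-changes, Bonferroni-adjusted across disorder tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from srmtx.exceptions import DegenerateInputError, InvalidConfigError

log = logging.getLogger(__name__)

_CHUNK = 500  # permutations per vectorized block


@dataclass
class EnrichmentResult:
    target: str
    annotation: str
    n_target: int
    n_annotation: int
    observed: int
    null_mean: float
    null_sd: float
    p: float
    n_perm: int


def relabeling_enrichment(
    target,
    annotation,
    universe,
    n_perm: int = 10000,
    seed: int = 0,
    target_name: str = "target",
    annotation_name: str = "annotation",
) -> EnrichmentResult:
    """Permutation enrichment of ``annotation`` in ``target`` over ``universe``.

    Null: overlap of the annotation with uniform random subsets of the
    universe of size |target| (without replacement);
    p = (1 + #{null ≥ observed}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise InvalidConfigError("n_perm must be >= 100")
    universe = sorted(set(universe))
    uset = set(universe)
    target = set(target) & uset
    annotation = set(annotation) & uset
    if not target or not annotation:
        raise DegenerateInputError(
            "target or annotation empty after mapping to the universe"
        )
    n, k = len(universe), len(target)
    observed = len(target & annotation)
    mask = np.fromiter((g in annotation for g in universe), bool, count=n)
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm, dtype=np.int64)
    done = 0
    while done < n_perm:
        m = min(_CHUNK, n_perm - done)
        keys = rng.random((m, n))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        null[done : done + m] = mask[idx].sum(axis=1)
        done += m
    p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return EnrichmentResult(
        target=target_name,
        annotation=annotation_name,
        n_target=k,
        n_annotation=len(annotation),
        observed=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)),
        p=float(p),
        n_perm=n_perm,
    )


def celltype_enrichment(
    target_lists: dict[str, set[str] | list[str]],
    celltype_sets: dict[str, set[str] | list[str]],
    universe,
    n_perm: int = 10000,
    seed: int = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Relabeling enrichment per (target list × cell type), FDR per target.

    BH-FDR is applied within the family of cell types separately for each
    target list, mirroring how cell-class enrichment tables are corrected.
    """
    from statsmodels.stats.multitest import multipletests

    if not celltype_sets:
        raise InvalidConfigError("need at least one cell-type list")
    rows = []
    rng = np.random.default_rng(seed)
    for tname in sorted(target_lists):
        for cname in sorted(celltype_sets):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            res = relabeling_enrichment(
                target_lists[tname],
                celltype_sets[cname],
                universe,
                n_perm=n_perm,
                seed=sub_seed,
                target_name=tname,
                annotation_name=cname,
            )
            rows.append(res)
    out = pd.DataFrame([r.__dict__ for r in rows])
    out["q"] = np.nan
    for tname in out["target"].unique():
        fam = out["target"] == tname
        out.loc[fam, "q"] = multipletests(
            out.loc[fam, "p"], alpha=alpha, method="fdr_bh"
        )[1]
    return out


def weight_de_correlation(
    weights: pd.Series,
    de_tables: dict[str, pd.DataFrame],
    min_genes: int = 8,
) -> pd.DataFrame:
    """Spearman correlation of PLS1 weights with DE log-fold-changes.

    One row per disorder table (columns ``gene`` and ``logFC``); p-values
    are Bonferroni-adjusted across the supplied tables.
    """
    rows = []
    for name in sorted(de_tables):
        table = de_tables[name]
        de = table.set_index("gene")["logFC"]
        common = weights.index.intersection(de.index)
        if len(common) < min_genes:
            raise DegenerateInputError(
                f"only {len(common)} genes shared with DE table {name!r} "
                f"(need >= {min_genes})"
            )
        rho, p = stats.spearmanr(weights.loc[common], de.loc[common])
        rows.append((name, len(common), float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["disorder", "n", "rho", "p"])
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out
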
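"""Cohort-wise MES comparisons and alpha-diversity tests.

For each disease cohort, metabolites are screened (exchanged in ≥ 50
individuals of the healthy∪disease pool, ≥ 15 of them diseased; water
and oxygen excluded as trivially universal), tested with a two-group
Kruskal–Wallis test against the healthy population, Bonferroni-corrected
within the disease's own test family, and the significant *reductions*
ranked by the healthy-minus-disease MES difference.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from mescore.mes_core import matrix_to_wide

DEFAULT_EXCLUDE = frozenset({"h2o", "o2"})

RESULT_COLUMNS = [
    "metabolite_id", "disease", "n_healthy", "n_disease", "H", "df", "p",
    "threshold", "direction", "delta", "significant",
]


def kruskal_2group(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-group Kruskal–Wallis (df = 1); H = 0, p = 1 on a degenerate pooled sample."""
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(x, y)
    return float(H), float(p)


def filter_metabolites(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    disease: str,
    min_total: int = 50,
    min_diseased: int = 15,
    exclude: frozenset[str] = DEFAULT_EXCLUDE,
) -> set[str]:
    """Metabolites testable for one disease-vs-healthy comparison.

    Keeps metabolites with MES > 0 in at least ``min_total`` individuals of
    the pooled healthy+disease samples, at least ``min_diseased`` of them
    diseased, minus the exclusion set.
    """
    if disease not in set(metadata["cohort"]):
        raise ValueError(f"unknown disease label: {disease!r}")
    pool = metadata.index[metadata["cohort"].isin(["healthy", disease])]
    sub = matrix[matrix["sample_id"].isin(set(pool)) & (matrix["mes"] > 0)]
    diseased = set(metadata.index[metadata["cohort"] == disease])
    counts = sub.groupby("metabolite_id")["sample_id"].agg(
        total="nunique",
        diseased=lambda s: s[s.isin(diseased)].nunique(),
    )
    keep = counts[(counts["total"] >= min_total) & (counts["diseased"] >= min_diseased)]
    return set(keep.index) - set(exclude)


def test_mes_difference(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    disease: str,
    metabolites: set[str],
    alpha: float = 0.05,
    direction_stat: str = "mean",
    one_sided_mode: str = "gate",
    zero_fill: bool = True,
) -> pd.DataFrame:
    """Kruskal–Wallis MES comparison for one disease vs healthy.

    The Bonferroni threshold is ``alpha`` divided by the number of
    metabolites in this disease's family.  A one-sided reading of the
    two-group test is realized either by gating significance on the
    observed direction (``gate``, default) or by halving the two-sided p
    in the observed direction (``halve``); the choice is recorded in
    output headers by the CLI.
    """
    if not metabolites:
        raise ValueError("empty metabolite set")
    if direction_stat not in {"mean", "median"}:
        raise ValueError(f"unknown direction_stat: {direction_stat!r}")
    if one_sided_mode not in {"gate", "halve"}:
        raise ValueError(f"unknown one_sided_mode: {one_sided_mode!r}")

    healthy = metadata.index[metadata["cohort"] == "healthy"]
    diseased = metadata.index[metadata["cohort"] == disease]
    if len(healthy) == 0 or len(diseased) == 0:
        raise ValueError("both the healthy and the disease cohort must be nonempty")
    wide = matrix_to_wide(
        matrix, samples=list(healthy) + list(diseased), zero_fill=zero_fill
    )
    threshold = alpha / len(metabolites)
    stat = np.mean if direction_stat == "mean" else np.median

    rows = []
    for met in sorted(metabolites):
        if met not in wide.columns:
            x = np.zeros(len(healthy))
            y = np.zeros(len(diseased))
        else:
            x = wide.loc[healthy, met].dropna().to_numpy()
            y = wide.loc[diseased, met].dropna().to_numpy()
        if len(x) < 2 or len(y) < 2:
            warnings.warn(
                f"metabolite {met!r}: a group has <2 samples; test skipped",
                stacklevel=2,
            )
            continue
        H, p = kruskal_2group(x, y)
        delta = float(stat(x) - stat(y))
        direction = "reduced" if delta > 0 else "increased"
        if one_sided_mode == "halve":
            p = p / 2.0 if delta > 0 else 1.0 - p / 2.0
            significant = p < threshold
        else:
            significant = (p < threshold) and (direction == "reduced")
        rows.append(
            (met, disease, len(x), len(y), H, 1, p, threshold, direction,
             delta, significant)
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def rank_losses(results: pd.DataFrame, k: int = 5) -> pd.DataFrame:
    """Top-k significant cross-feeding losses per disease.

    Keeps only significant reductions, sorts by delta (healthy − disease
    mean MES) descending with lexicographic tie-break, and returns at
    most ``k`` rows per disease.
    """
    if results.empty:
        return results.copy()
    kept = results[results["significant"] & (results["direction"] == "reduced")]
    kept = kept.sort_values(
        ["disease", "delta", "metabolite_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return kept.groupby("disease", group_keys=False).head(k).reset_index(drop=True)


def alpha_diversity(abundance: pd.DataFrame) -> pd.DataFrame:
    """Species richness S and Shannon index H′ (nats) per sample.

    S counts taxa with abundance > 0; H′ = −Σ aᵢ·ln aᵢ over nonzero
    abundances.  An empty sample yields S = 0, H′ = 0 and a warning.
    """
    values = abundance.to_numpy(dtype=float)
    richness = (values > 0).sum(axis=1)
    if (richness == 0).any():
        warnings.warn("sample(s) with no taxa present; S = 0, H' = 0", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(values > 0, values * np.log(values), 0.0)
    shannon = -plogp.sum(axis=1)
    return pd.DataFrame(
        {"richness": richness, "shannon": shannon}, index=abundance.index
    )


def compare_alpha(alpha_div: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon rank-sum of each alpha-diversity index, per disease vs healthy.

    p-values are Holm-adjusted within each index's family of diseases.
    """
    healthy = metadata.index[metadata["cohort"] == "healthy"]
    diseases = sorted(set(metadata["cohort"]) - {"healthy"})
    if len(healthy) == 0 or not diseases:
        raise ValueError("need a healthy cohort and at least one disease cohort")
    rows = []
    for index_name in ("richness", "shannon"):
        pvals = []
        for disease in diseases:
            dis = metadata.index[metadata["cohort"] == disease]
            x = alpha_div.loc[alpha_div.index.intersection(healthy), index_name]
            y = alpha_div.loc[alpha_div.index.intersection(dis), index_name]
            stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
            rows.append([index_name, disease, len(x), len(y), float(stat), float(p)])
            pvals.append(p)
        adjusted = multipletests(pvals, method="holm")[1]
        for offset, p_adj in enumerate(adjusted):
            rows[len(rows) - len(diseases) + offset].append(float(p_adj))
    return pd.DataFrame(
        rows, columns=["index", "disease", "n_healthy", "n_disease", "U", "p", "p_holm"]
    )
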
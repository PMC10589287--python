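"""Cohort tests for gene prevalence and abundance, diversity-adjusted.

Gene hits are per-taxon copy counts (e.g., from an HMM survey of
H₂S-cycling genes).  Per sample a gene is summarized either by
*prevalence* — the number of present taxa carrying at least one copy —
or by *abundance* — Σ copy count × relative abundance.  Each gene is
tested with a linear model of log(value + offset) on a disease
indicator plus species richness, Bonferroni-corrected over the genes
passing the filters within that mode.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

GENE_RESULT_COLUMNS = [
    "gene_id", "mode", "coefficient", "p", "threshold", "significant",
    "enriched_in", "n_samples", "n_samples_with_gene",
]


def gene_sample_matrix(
    gene_hits: pd.DataFrame, abundance: pd.DataFrame, mode: str
) -> pd.DataFrame:
    """Per-sample gene values (sample × gene).

    ``gene_hits`` is long-form with columns ``taxon_id``, ``gene_id``,
    ``copies`` (nonnegative integers).  Taxa not present in the abundance
    table are skipped with a warning.
    """
    if mode not in {"prevalence", "abundance"}:
        raise ValueError(f"unknown mode: {mode!r}")
    if (gene_hits["copies"] < 0).any():
        raise ValueError("gene copy counts must be nonnegative")
    known = gene_hits[gene_hits["taxon_id"].isin(abundance.columns)]
    n_skipped = gene_hits["taxon_id"].nunique() - known["taxon_id"].nunique()
    if n_skipped:
        warnings.warn(
            f"{n_skipped} taxon id(s) in gene hits unresolvable against the "
            "abundance table; skipped",
            stacklevel=2,
        )
    copies = (
        known[known["copies"] > 0]
        .pivot_table(index="taxon_id", columns="gene_id", values="copies", fill_value=0)
        .reindex(abundance.columns, fill_value=0)
    )
    ab = abundance.to_numpy(dtype=float)
    if mode == "prevalence":
        carriers = (copies.to_numpy() > 0).astype(float)
        values = (ab > 0).astype(float) @ carriers
    else:
        values = ab @ copies.to_numpy(dtype=float)
    return pd.DataFrame(values, index=abundance.index, columns=copies.columns)


def test_genes(
    values: pd.DataFrame,
    metadata: pd.DataFrame,
    alpha_div: pd.DataFrame,
    disease: str,
    mode: str,
    min_species: int = 100,
    min_samples_with_gene: int = 10,
    offset: float = 0.1,
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Diversity-adjusted cohort test for every gene in a sample × gene matrix.

    Samples need at least ``min_species`` species; genes must be observed
    (value > 0) in at least ``min_samples_with_gene`` retained samples.
    The response is log(value + offset); the disease coefficient's
    two-sided t-test p is compared against alpha divided by the number of
    genes tested in this mode.  Returns (results, skipped_genes).
    """
    common = values.index.intersection(metadata.index).intersection(alpha_div.index)
    keep = common[alpha_div.loc[common, "richness"] >= min_species]
    vals = values.loc[keep]
    meta = metadata.loc[keep]
    pool = meta["cohort"].isin(["healthy", disease])
    vals, meta = vals.loc[pool], meta.loc[pool]
    richness = alpha_div.loc[vals.index, "richness"].to_numpy(dtype=float)
    is_disease = (meta["cohort"] == disease).to_numpy(dtype=float)

    observed = (vals > 0).sum(axis=0)
    tested = [g for g in vals.columns if observed[g] >= min_samples_with_gene]
    skipped = [g for g in vals.columns if g not in tested]
    if not tested:
        return pd.DataFrame(columns=GENE_RESULT_COLUMNS), skipped

    threshold = alpha / len(tested)
    X = sm.add_constant(np.column_stack([is_disease, richness]), has_constant="add")
    rows = []
    for gene in tested:
        response = np.log(vals[gene].to_numpy(dtype=float) + offset)
        fit = sm.OLS(response, X).fit()
        coef, p = float(fit.params[1]), float(fit.pvalues[1])
        rows.append(
            [gene, mode, coef, p, threshold, p < threshold,
             disease if coef > 0 else "healthy",
             int(len(vals)), int(observed[gene])]
        )
    return pd.DataFrame(rows, columns=GENE_RESULT_COLUMNS), skipped
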
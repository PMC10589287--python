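"""Abundance-weighted flux attribution for one focal metabolite.

Generalizes the case-study machinery used to dissect hydrogen sulfide in
Crohn's disease: per-sample production/consumption totals (flux ×
relative abundance), producer:consumer count and flux ratios, cohort
balancing by seeded down-sampling, Kruskal–Wallis comparisons with
direction gating, diversity-adjusted linear models, and per-species
weighted-flux deltas that rank the key producers and consumers.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from mescore.cohort_stats import kruskal_2group
from mescore.producer_consumer import lookup_abundance

TOTALS_COLUMNS = [
    "sample_id", "production", "consumption", "P", "C",
    "ratio_counts", "ratio_flux", "excess",
    "log2_production", "log2_consumption",
]

KEY_SPECIES_COLUMNS = [
    "taxon_id", "role", "weighted_sum_a", "weighted_sum_b", "delta", "rank",
]


def log2_with_offset(values: np.ndarray, offset: float | None = None) -> np.ndarray:
    """log₂ with a pseudo-offset for zeros.

    When ``offset`` is None it defaults to half the smallest nonzero value
    observed, applied only to exact zeros; strictly positive data are
    transformed as-is.
    """
    values = np.asarray(values, dtype=float)
    if offset is None:
        nonzero = values[values > 0]
        offset = 0.5 * nonzero.min() if nonzero.size else 1.0
    shifted = np.where(values > 0, values, offset)
    return np.log2(shifted)


def sample_totals(
    records: pd.DataFrame,
    abundance: pd.DataFrame,
    metabolite_id: str,
    tolerance: float = 1e-6,
    log2_offset: float | None = None,
) -> pd.DataFrame:
    """Per-sample abundance-weighted flux totals for one metabolite.

    production = Σ export·abundance, consumption = Σ import·abundance;
    ratios (P/C and production/consumption) are NaN-flagged where the
    denominator is zero and excluded from downstream ratio tests.
    """
    sub = records[records["metabolite_id"] == metabolite_id].copy()
    if sub.empty:
        raise ValueError(f"no flux records for metabolite {metabolite_id!r}")
    sub["weighted"] = sub["flux"].to_numpy() * lookup_abundance(sub, abundance)
    qualifying = sub["flux"] > tolerance

    def per_direction(direction, col, agg):
        mask = (sub["direction"] == direction) & (qualifying if agg == "nunique" else True)
        part = sub[mask]
        if agg == "nunique":
            return part.groupby("sample_id")["taxon_id"].nunique().rename(col)
        return part.groupby("sample_id")["weighted"].sum().rename(col)

    samples = sorted(sub["sample_id"].unique())
    out = pd.DataFrame(index=pd.Index(samples, name="sample_id"))
    out["production"] = per_direction("export", "production", "sum")
    out["consumption"] = per_direction("import", "consumption", "sum")
    out["P"] = per_direction("export", "P", "nunique")
    out["C"] = per_direction("import", "C", "nunique")
    out = out.fillna(0.0)
    out[["P", "C"]] = out[["P", "C"]].astype(int)

    with np.errstate(divide="ignore", invalid="ignore"):
        out["ratio_counts"] = np.where(out["C"] > 0, out["P"] / out["C"], np.nan)
        out["ratio_flux"] = np.where(
            out["consumption"] > 0, out["production"] / out["consumption"], np.nan
        )
    n_undef = int(out["ratio_flux"].isna().sum() + out["ratio_counts"].isna().sum())
    if n_undef:
        warnings.warn(
            f"{n_undef} undefined ratio value(s) (zero denominator) flagged as NaN",
            stacklevel=2,
        )
    signed = sub["weighted"].to_numpy() * np.where(
        sub["direction"].to_numpy() == "export", 1.0, -1.0
    )
    out["excess"] = (
        pd.Series(signed).groupby(sub["sample_id"].to_numpy()).sum().reindex(out.index)
    )
    out["log2_production"] = log2_with_offset(out["production"].to_numpy(), log2_offset)
    out["log2_consumption"] = log2_with_offset(out["consumption"].to_numpy(), log2_offset)
    return out.reset_index()[TOTALS_COLUMNS]


def compare_totals(
    totals: pd.DataFrame,
    metadata: pd.DataFrame,
    cohorts: tuple[str, str],
    quantities: tuple[str, ...] = (
        "P", "C", "log2_production", "log2_consumption",
        "ratio_counts", "ratio_flux", "excess",
    ),
) -> pd.DataFrame:
    """Kruskal–Wallis (df = 1) per quantity between two cohorts.

    Direction is reported relative to the first cohort (``reduced`` means
    the second cohort's mean is lower).  Undefined (NaN) ratio values are
    dropped pairwise with a warning from :func:`sample_totals`.
    """
    a, b = cohorts
    indexed = totals.set_index("sample_id")
    rows = []
    for quantity in quantities:
        x = indexed.loc[indexed.index.isin(metadata.index[metadata["cohort"] == a]), quantity].dropna()
        y = indexed.loc[indexed.index.isin(metadata.index[metadata["cohort"] == b]), quantity].dropna()
        if len(x) < 2 or len(y) < 2:
            warnings.warn(f"quantity {quantity!r}: a cohort has <2 samples; skipped",
                          stacklevel=2)
            continue
        H, p = kruskal_2group(x.to_numpy(), y.to_numpy())
        delta = float(x.mean() - y.mean())
        rows.append([quantity, a, b, len(x), len(y), H, 1, p,
                     "reduced" if delta > 0 else "increased", delta])
    return pd.DataFrame(
        rows,
        columns=["quantity", "cohort_a", "cohort_b", "n_a", "n_b", "H", "df", "p",
                 "direction", "delta"],
    )


def balance_cohorts(
    metadata: pd.DataFrame, cohorts: tuple[str, str], seed: int
) -> pd.DataFrame:
    """Down-sample the larger cohort to the smaller one's size, seeded.

    Returns the balanced metadata subset (only the two cohorts), with the
    excluded samples chosen without replacement by the seeded generator so
    reruns are reproducible.
    """
    a, b = cohorts
    sub = metadata[metadata["cohort"].isin([a, b])]
    ids_a = list(sub.index[sub["cohort"] == a])
    ids_b = list(sub.index[sub["cohort"] == b])
    if not ids_a or not ids_b:
        raise ValueError(f"cohort(s) empty among {cohorts}")
    rng = np.random.default_rng(seed)
    target = min(len(ids_a), len(ids_b))
    keep_a = sorted(rng.choice(ids_a, size=target, replace=False)) if len(ids_a) > target else ids_a
    keep_b = sorted(rng.choice(ids_b, size=target, replace=False)) if len(ids_b) > target else ids_b
    return sub.loc[list(keep_a) + list(keep_b)]


def weighted_flux_sums(
    records: pd.DataFrame,
    abundance: pd.DataFrame,
    samples,
    metabolite_id: str,
) -> pd.DataFrame:
    """Σ over samples of flux × relative abundance, per taxon and role."""
    sub = records[
        (records["metabolite_id"] == metabolite_id)
        & records["sample_id"].isin(set(samples))
    ].copy()
    sub["weighted"] = sub["flux"].to_numpy() * lookup_abundance(sub, abundance)
    sub["role"] = np.where(sub["direction"] == "export", "producer", "consumer")
    return (
        sub.groupby(["taxon_id", "role"])["weighted"].sum().rename("weighted_sum").reset_index()
    )


def key_species(
    records: pd.DataFrame,
    abundance: pd.DataFrame,
    metadata: pd.DataFrame,
    metabolite_id: str,
    cohorts: tuple[str, str],
    top_n: int = 10,
    seed: int = 0,
    balance: bool = True,
) -> pd.DataFrame:
    """Rank species by their cohort shift in weighted flux of one metabolite.

    Cohorts are balanced to equal size first (seeded) so weighted sums are
    comparable.  With cohort A the reference (healthy) and B the disease,
    producers are ranked by *increase* in B (delta = sum_A − sum_B
    ascending) and consumers by *decrease* in B (delta descending) —
    the species driving the disease-associated imbalance.  A taxon absent
    from one cohort contributes a weighted sum of 0 there.
    """
    meta = balance_cohorts(metadata, cohorts, seed) if balance else metadata[
        metadata["cohort"].isin(cohorts)
    ]
    a, b = cohorts
    sums = {}
    for label in cohorts:
        samples = meta.index[meta["cohort"] == label]
        sums[label] = weighted_flux_sums(records, abundance, samples, metabolite_id)
    merged = pd.merge(
        sums[a], sums[b], on=["taxon_id", "role"], how="outer",
        suffixes=("_a", "_b"),
    ).fillna(0.0)
    merged["delta"] = merged["weighted_sum_a"] - merged["weighted_sum_b"]
    parts = []
    for role, ascending in (("producer", True), ("consumer", False)):
        part = merged[merged["role"] == role].sort_values(
            ["delta", "taxon_id"], ascending=[ascending, True], kind="mergesort"
        ).reset_index(drop=True)
        part["rank"] = np.arange(1, len(part) + 1)
        parts.append(part.head(top_n) if top_n is not None else part)
    return pd.concat(parts, ignore_index=True)[KEY_SPECIES_COLUMNS]


def exchange_graph(key: pd.DataFrame, metabolite_id: str) -> pd.DataFrame:
    """Edge list (taxon → metabolite) for graph import, weight = |delta|."""
    edges = key.copy()
    edges["source"] = np.where(edges["role"] == "producer", edges["taxon_id"], metabolite_id)
    edges["target"] = np.where(edges["role"] == "producer", metabolite_id, edges["taxon_id"])
    edges["weight"] = edges["delta"].abs()
    return edges[["source", "target", "role", "weight"]]


def confounder_model(
    response: pd.Series,
    metadata: pd.DataFrame,
    alpha_div: pd.DataFrame,
    disease: str,
    min_species: int = 99,
) -> dict:
    """Diversity-adjusted linear model for a disease effect.

    OLS of the response on a disease indicator plus species richness,
    restricted to samples with at least ``min_species`` species (nesting
    the comparison inside the richness range shared by both cohorts).
    Returns the disease coefficient, its two-sided t-test p, and the
    number of samples retained.
    """
    common = response.index.intersection(metadata.index).intersection(alpha_div.index)
    richness = alpha_div.loc[common, "richness"]
    keep = common[richness >= min_species]
    meta = metadata.loc[keep]
    is_disease = (meta["cohort"] == disease).to_numpy(dtype=float)
    n_disease, n_healthy = int(is_disease.sum()), int((1 - is_disease).sum())
    if n_disease < 3 or n_healthy < 3:
        raise ValueError(
            f"fewer than 3 samples per cohort after the ≥{min_species}-species filter "
            f"(healthy={n_healthy}, {disease}={n_disease})"
        )
    X = sm.add_constant(
        np.column_stack([is_disease, alpha_div.loc[keep, "richness"].to_numpy()]),
        has_constant="add",
    )
    fit = sm.OLS(response.loc[keep].to_numpy(dtype=float), X).fit()
    return {
        "disease_coef": float(fit.params[1]),
        "disease_p": float(fit.pvalues[1]),
        "richness_coef": float(fit.params[2]),
        "n_samples": int(len(keep)),
        "n_healthy": n_healthy,
        "n_disease": n_disease,
    }
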
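"""Do producer and consumer diversity scale differently with richness?

For every metabolite, each sample contributes two observations — its
producer count and its consumer count — regressed on species richness
with a category interaction:

    count ~ richness + category + richness:category

A significant interaction term means the per-richness-unit slope differs
between roles; metabolites are classified ``consumer_steeper``,
``producer_steeper`` or ``no_difference`` at the Bonferroni-corrected
family threshold (alpha over the number of metabolites actually fitted).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm

from mescore.errors import ReferentialError

LONG_COLUMNS = ["sample_id", "metabolite_id", "category", "count", "richness"]
FIT_COLUMNS = [
    "metabolite_id", "n_samples", "slope_producers", "slope_consumers",
    "interaction_p", "threshold", "classification",
]


def build_long_table(sets: pd.DataFrame, alpha_div: pd.DataFrame) -> pd.DataFrame:
    """Two rows (producer count, consumer count) per (sample, metabolite)."""
    if sets.empty:
        return pd.DataFrame(columns=LONG_COLUMNS)
    missing = sorted(set(sets["sample_id"]) - set(alpha_div.index))
    if missing:
        raise ReferentialError(f"richness unavailable for sample(s): {missing[:5]}")
    richness = alpha_div.loc[sets["sample_id"], "richness"].to_numpy()
    frames = []
    for category, col in (("producer", "P"), ("consumer", "C")):
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": sets["sample_id"],
                    "metabolite_id": sets["metabolite_id"],
                    "category": category,
                    "count": sets[col].to_numpy(),
                    "richness": richness,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _fit_one(obs: pd.DataFrame, log_link: bool = False):
    """count ~ richness * category (producer = reference level).

    OLS by default; ``log_link`` switches to a Poisson GLM with log link,
    the textbook choice for count responses (slopes are then on the log
    scale).
    """
    is_consumer = (obs["category"] == "consumer").to_numpy(dtype=float)
    richness = obs["richness"].to_numpy(dtype=float)
    X = sm.add_constant(
        np.column_stack([richness, is_consumer, richness * is_consumer]),
        has_constant="add",
    )
    y = obs["count"].to_numpy(dtype=float)
    if log_link:
        fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    else:
        fit = sm.OLS(y, X).fit()
    slope_prod = float(fit.params[1])
    slope_cons = float(fit.params[1] + fit.params[3])
    interaction_p = float(fit.pvalues[3])
    return slope_prod, slope_cons, interaction_p


def fit_interactions(
    long_table: pd.DataFrame,
    min_samples: int = 50,
    alpha: float = 0.05,
    log_link: bool = False,
) -> pd.DataFrame:
    """Fit the slope-interaction model for every eligible metabolite.

    Metabolites exchanged in fewer than ``min_samples`` distinct samples
    are skipped with a warning; the Bonferroni threshold is recomputed
    from the number actually fitted.
    """
    fits, skipped = [], []
    for met, obs in long_table.groupby("metabolite_id", sort=True):
        n = obs["sample_id"].nunique()
        if n < min_samples:
            skipped.append(met)
            continue
        if obs["richness"].nunique() < 2:
            warnings.warn(
                f"metabolite {met!r}: richness is constant; fit degenerate, skipped",
                stacklevel=2,
            )
            continue
        slope_prod, slope_cons, p = _fit_one(obs, log_link=log_link)
        fits.append([met, n, slope_prod, slope_cons, p])
    if skipped:
        warnings.warn(
            f"{len(skipped)} metabolite(s) below the {min_samples}-sample filter",
            stacklevel=2,
        )
    out = pd.DataFrame(
        fits, columns=["metabolite_id", "n_samples", "slope_producers",
                       "slope_consumers", "interaction_p"]
    )
    if out.empty:
        out["threshold"] = []
        out["classification"] = []
        return out[FIT_COLUMNS]
    threshold = alpha / len(out)
    out["threshold"] = threshold
    steeper = np.where(
        out["slope_consumers"] > out["slope_producers"],
        "consumer_steeper",
        "producer_steeper",
    )
    out["classification"] = np.where(
        out["interaction_p"] < threshold, steeper, "no_difference"
    )
    return out[FIT_COLUMNS]


def classify_all(fits: pd.DataFrame) -> dict[str, float]:
    """Fractions of consumer-steeper / producer-steeper / no-difference fits."""
    if fits.empty:
        raise ValueError("no fitted metabolites to classify")
    counts = fits["classification"].value_counts()
    n = len(fits)
    return {
        "consumer_steeper": counts.get("consumer_steeper", 0) / n,
        "producer_steeper": counts.get("producer_steeper", 0) / n,
        "no_difference": counts.get("no_difference", 0) / n,
    }
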
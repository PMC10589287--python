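"""The Metabolite Exchange Score.

MES is the harmonic mean of the number of producer species P and
consumer species C of a metabolite within one sample's community:

    MES = 2·P·C / (P + C)

The score is zero whenever a metabolite is only produced or only
consumed — no exchange can occur without both partners — and for
P, C ≥ 1 it lies between min(P, C) and max(P, C), closer to the
smaller count, so it rewards balanced redundancy on both sides of
the exchange.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from mescore.errors import ReferentialError

MATRIX_COLUMNS = ["sample_id", "metabolite_id", "mes"]


def mes(P: int, C: int) -> float:
    """Harmonic-mean exchange score of producer and consumer counts.

    >>> mes(3, 6)
    4.0
    >>> mes(7, 0)
    0.0
    """
    if P < 0 or C < 0:
        raise ValueError("producer and consumer counts must be nonnegative")
    if P == 0 or C == 0:
        return 0.0
    return 2.0 * P * C / (P + C)


def mes_matrix(sets: pd.DataFrame) -> pd.DataFrame:
    """Score every (sample, metabolite) entry of a producer/consumer table.

    Entries absent from ``sets`` stay absent here; whether they are later
    treated as zero is the cohort summariser's decision.
    """
    if sets.empty:
        return pd.DataFrame(columns=MATRIX_COLUMNS)
    P = sets["P"].to_numpy(dtype=float)
    C = sets["C"].to_numpy(dtype=float)
    denom = P + C
    score = np.divide(2.0 * P * C, denom, out=np.zeros_like(denom), where=denom > 0)
    out = sets[["sample_id", "metabolite_id"]].copy()
    out["mes"] = score
    return out


def matrix_to_wide(
    matrix: pd.DataFrame, samples=None, zero_fill: bool = True
) -> pd.DataFrame:
    """Pivot the long MES table to sample × metabolite.

    With ``zero_fill`` (default) metabolites missing from a sample score 0
    — the defined MES of an unexchanged metabolite; otherwise they stay NaN
    and drop out of summaries sample-wise.
    """
    wide = matrix.pivot(index="sample_id", columns="metabolite_id", values="mes")
    if samples is not None:
        wide = wide.reindex(list(samples))
    if zero_fill:
        wide = wide.fillna(0.0)
    return wide


def summarize_cohort(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    cohort: str,
    k: int = 15,
    zero_fill: bool = True,
) -> pd.DataFrame:
    """Rank metabolites by mean MES over one cohort's samples.

    Returns the top ``k`` metabolites as a DataFrame with columns
    ``metabolite_id``, ``cohort``, ``n``, ``mean_mes``, ``sd_mes``,
    ``rank``; ties on the mean break lexicographically by metabolite id.
    """
    if cohort not in set(metadata["cohort"]):
        raise ValueError(f"unknown cohort label: {cohort!r}")
    samples = metadata.index[metadata["cohort"] == cohort]
    wide = matrix_to_wide(matrix, samples=samples, zero_fill=zero_fill)
    if wide.empty or wide.shape[1] == 0:
        raise ReferentialError(f"no MES entries for cohort {cohort!r}")
    summary = pd.DataFrame(
        {
            "metabolite_id": wide.columns,
            "cohort": cohort,
            "n": wide.notna().sum(axis=0).to_numpy(),
            "mean_mes": wide.mean(axis=0, skipna=True).to_numpy(),
            "sd_mes": wide.std(axis=0, ddof=1, skipna=True).to_numpy(),
        }
    )
    summary = summary.sort_values(
        ["mean_mes", "metabolite_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    summary["rank"] = np.arange(1, len(summary) + 1)
    return summary.head(k)
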
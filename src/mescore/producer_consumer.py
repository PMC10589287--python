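"""Producer/consumer set extraction and community net export.

A taxon is a *producer* of a metabolite in a sample if its export flux
exceeds the calling tolerance, and a *consumer* if its import flux does.
A taxon with both qualifying records counts once in each set — community
metabolic models routinely predict dual-role species whose realized role
depends on community context.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

SETS_COLUMNS = ["sample_id", "metabolite_id", "P", "C", "producers", "consumers"]

#: fluxes at or below this magnitude are solver noise, not exchange
DEFAULT_TOLERANCE = 1e-6


def extract_sets(records: pd.DataFrame, tolerance: float = DEFAULT_TOLERANCE) -> pd.DataFrame:
    """Build per-(sample, metabolite) producer and consumer taxa sets.

    Parameters
    ----------
    records
        Canonical flux records (see :mod:`mescore.flux_io`).
    tolerance
        Minimum flux magnitude (mmol·gDW⁻¹·h⁻¹) for a record to count as
        a real exchange; must be ≥ 0.

    Returns
    -------
    DataFrame with columns ``sample_id``, ``metabolite_id``, ``P``, ``C``,
    ``producers``, ``consumers`` (the last two are sorted tuples of taxon
    ids).  (sample, metabolite) pairs with no qualifying record are absent
    — distinguishable downstream from an exchanged metabolite with P=C=0.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be nonnegative")
    kept = records[records["flux"] > tolerance]
    if kept.empty:
        return pd.DataFrame(columns=SETS_COLUMNS)

    grouped = (
        kept.groupby(["sample_id", "metabolite_id", "direction"], sort=True)["taxon_id"]
        .agg(lambda t: tuple(sorted(set(t))))
        .unstack("direction")
    )
    for col in ("import", "export"):
        if col not in grouped.columns:
            grouped[col] = None
    empty: tuple = ()
    producers = grouped["export"].apply(lambda t: t if isinstance(t, tuple) else empty)
    consumers = grouped["import"].apply(lambda t: t if isinstance(t, tuple) else empty)
    out = pd.DataFrame(
        {
            "P": producers.apply(len),
            "C": consumers.apply(len),
            "producers": producers,
            "consumers": consumers,
        }
    ).reset_index()
    return out[SETS_COLUMNS]


def sets_to_tsv_frame(sets: pd.DataFrame) -> pd.DataFrame:
    """Flatten taxa tuples to ';'-joined strings for TSV output."""
    out = sets.copy()
    out["producers"] = out["producers"].apply(";".join)
    out["consumers"] = out["consumers"].apply(";".join)
    return out


def excess_to_medium(
    records: pd.DataFrame, metabolite_id: str, abundance: pd.DataFrame
) -> pd.Series:
    """Abundance-weighted net community export of one metabolite, per sample.

    Net export Σ(export flux × abundance) − Σ(import flux × abundance)
    estimates the metabolite the community releases to the medium in
    excess of what its own members recapture; negative values mean net
    uptake from the medium.
    """
    sub = records[records["metabolite_id"] == metabolite_id]
    if sub.empty:
        warnings.warn(f"no flux records for metabolite {metabolite_id!r}", stacklevel=2)
        return pd.Series(dtype=float, name="excess")
    weights = lookup_abundance(sub, abundance)
    signed = sub["flux"].to_numpy() * weights * np.where(
        sub["direction"].to_numpy() == "export", 1.0, -1.0
    )
    out = pd.Series(signed, name="excess").groupby(sub["sample_id"].to_numpy()).sum()
    out.index.name = "sample_id"
    return out


def lookup_abundance(records: pd.DataFrame, abundance: pd.DataFrame) -> np.ndarray:
    """Relative abundance of each record's taxon in its sample.

    Raises :class:`~mescore.errors.ReferentialError` for taxa with flux
    records but no abundance column.
    """
    from mescore.errors import ReferentialError

    missing = sorted(set(records["taxon_id"]) - set(abundance.columns))
    if missing:
        raise ReferentialError(
            f"taxa in flux records absent from abundance table: {missing[:5]}"
        )
    idx = pd.MultiIndex.from_frame(records[["sample_id", "taxon_id"]])
    stacked = abundance.stack()
    return stacked.reindex(idx, fill_value=0.0).to_numpy(dtype=float)
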
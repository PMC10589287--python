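"""Tabular input/output and identifier canonicalization.

All tables travel as pandas DataFrames with fixed column names:

* flux records  — ``sample_id``, ``taxon_id``, ``metabolite_id``,
  ``direction`` (``import``/``export``), ``flux`` (nonnegative magnitude,
  mmol·gDW⁻¹·h⁻¹).  Sign conventions from upstream community-FBA outputs
  are resolved at read time: a negative signed flux is an import.
* abundance     — wide, index ``sample_id``, one column per taxon,
  rows renormalized to sum to 1.
* metadata      — index ``sample_id``, columns ``cohort`` and
  (optionally) ``study_id``.
"""

from __future__ import annotations

import re
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from mescore.errors import IntegrityError, ReferentialError, SchemaError

FLUX_COLUMNS = ["sample_id", "taxon_id", "metabolite_id", "direction", "flux"]
FLUX_KEY = ["sample_id", "taxon_id", "metabolite_id", "direction"]

_EX_PREFIX = re.compile(r"^ex_", re.IGNORECASE)
_E_SUFFIX = re.compile(r"(_e|\(e\)|\[e\])$", re.IGNORECASE)


def normalize_metabolite_id(raw: str) -> str:
    """Canonicalize a metabolite or exchange-reaction identifier.

    Strips a leading exchange prefix (``EX_``), a trailing extracellular
    compartment token (``_e``, ``(e)``, ``[e]``) and lowercases, so that
    BiGG-style exchange-reaction ids and bare metabolite names collapse
    to one key.  Idempotent.

    >>> normalize_metabolite_id("EX_h2s_e")
    'h2s'
    """
    if not raw or not str(raw).strip():
        raise ValueError("empty metabolite identifier")
    out = str(raw).strip()
    out = _EX_PREFIX.sub("", out)
    out = _E_SUFFIX.sub("", out)
    return out.lower()


def _read_tabular(path: str | Path) -> pd.DataFrame:
    """Read a headered TSV/CSV, sniffing the delimiter, skipping '#' comments."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input table not found: {path}")
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab", ".txt"} else ","
    return pd.read_csv(path, sep=sep, comment="#", dtype={"sample_id": str})


def _require_columns(df: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def read_flux_table(path: str | Path, dialect: str = "long_signed") -> pd.DataFrame:
    """Read a long-form exchange-flux table into canonical records.

    Parameters
    ----------
    path
        TSV/CSV with one row per (sample, taxon, reaction/metabolite[, direction]).
    dialect
        ``long_signed`` — one signed ``flux`` column, negative = import;
        ``long_directional`` — nonnegative ``flux`` plus a ``direction`` column.
    """
    if dialect not in {"long_signed", "long_directional"}:
        raise ValueError(f"unknown flux dialect: {dialect!r}")
    df = _read_tabular(path)
    # accept either a raw reaction id or an already-canonical metabolite column
    met_col = "reaction" if "reaction" in df.columns else "metabolite"
    taxon_col = "taxon" if "taxon" in df.columns else "taxon_id"
    base = ["sample_id", taxon_col, met_col, "flux"]
    if dialect == "long_directional":
        base.append("direction")
    _require_columns(df, base, f"flux table ({dialect})")

    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"].astype(str),
            "taxon_id": df[taxon_col].astype(str),
            "metabolite_id": [normalize_metabolite_id(m) for m in df[met_col]],
        }
    )
    flux = pd.to_numeric(df["flux"], errors="raise").to_numpy(dtype=float)
    if dialect == "long_signed":
        out["direction"] = np.where(flux < 0, "import", "export")
        out["flux"] = np.abs(flux)
    else:
        direction = df["direction"].astype(str).str.lower()
        bad = sorted(set(direction) - {"import", "export"})
        if bad:
            raise SchemaError(f"flux table: unknown direction value(s) {bad}")
        if (flux < 0).any():
            raise SchemaError(
                "flux table (long_directional): flux magnitudes must be nonnegative"
            )
        out["direction"] = direction.to_numpy()
        out["flux"] = flux
    assert (out["flux"] >= 0).all()

    dup = out.duplicated(subset=FLUX_KEY)
    if dup.any():
        first = out.loc[dup.idxmax(), FLUX_KEY].tolist()
        raise IntegrityError(
            f"duplicate flux record key {tuple(first)}; "
            "(sample, taxon, metabolite, direction) must be unique"
        )
    return out[FLUX_COLUMNS].reset_index(drop=True)


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Read a sample × taxon relative-abundance matrix and renormalize rows.

    The first column is the sample id; remaining columns are taxa.  Rows
    whose raw sum deviates from 1 by more than 1% trigger a warning; all
    rows are renormalized to sum exactly to 1.
    """
    df = _read_tabular(path)
    if df.columns[0] != "sample_id":
        raise SchemaError("abundance table: first column must be 'sample_id'")
    df = df.set_index("sample_id")
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError("abundance table contains negative values")
    return renormalize_abundance(pd.DataFrame(values, index=df.index, columns=df.columns))


def renormalize_abundance(ab: pd.DataFrame, warn_tol: float = 0.01) -> pd.DataFrame:
    """Renormalize each sample's abundances to sum to 1 (warn if off by >1%)."""
    totals = ab.sum(axis=1)
    if (totals <= 0).any():
        empty = list(ab.index[totals <= 0])
        raise ValueError(f"sample(s) with zero total abundance: {empty}")
    off = (totals - 1.0).abs() > warn_tol
    if off.any():
        warnings.warn(
            f"{int(off.sum())} sample(s) had raw abundance sums deviating from 1 "
            "by >1%; renormalized",
            stacklevel=2,
        )
    return ab.div(totals, axis=0)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (``sample_id``, ``cohort``[, ``study_id``])."""
    df = _read_tabular(path)
    _require_columns(df, ["sample_id", "cohort"], "metadata table")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise IntegrityError(f"duplicate sample_id in metadata: {dup!r}")
    out = df.set_index("sample_id")
    out["cohort"] = out["cohort"].astype(str)
    return out


def read_gene_hits(path: str | Path) -> pd.DataFrame:
    """Read a long-form gene-hit table (``taxon_id``, ``gene_id``, ``copies``)."""
    df = _read_tabular(path)
    _require_columns(df, ["taxon_id", "gene_id", "copies"], "gene-hit table")
    if (df["copies"] < 0).any():
        raise ValueError("gene copy counts must be nonnegative")
    return df[["taxon_id", "gene_id", "copies"]]


def check_samples_covered(samples, metadata: pd.DataFrame) -> None:
    """Raise if any sample id is absent from the metadata table."""
    missing = sorted(set(map(str, samples)) - set(metadata.index))
    if missing:
        raise ReferentialError(
            f"sample(s) present in data but absent from metadata: {missing}"
        )


def write_table(
    df: pd.DataFrame,
    path: str | Path,
    parameters: dict | None = None,
    index: bool = False,
    float_format: str | None = "%.6g",
) -> None:
    """Write a result table as TSV with a header comment.

    The comment records the tool version and the parameters that produced
    the table, so every output is self-describing.  Scores are printed
    with 6 significant digits by default; pass ``float_format=None`` for
    full (round-trippable) precision, used for generated data files.
    """
    from mescore import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# mescore {__version__}"]
    for key, val in (parameters or {}).items():
        lines.append(f"# {key}={val}")
    body = df.to_csv(sep="\t", index=index, float_format=float_format)
    path.write_text("\n".join(lines) + "\n" + body)
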
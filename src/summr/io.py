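"""Reading and writing GWAS summary-statistic tables and MR result tables.

Real summary-statistic exports have no universal header convention, so
reading is driven by a *column map* (field name -> column header).  Presets
are shipped for the common portals; all are user-overridable.
"""

from __future__ import annotations

import json
import sys
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ConfigurationError, InputError, MRResult, SummaryStats, SUMMARY_COLUMNS,
    VALID_ALLELES,
)

MANDATORY_FIELDS = ("rsid", "effect_allele", "other_allele", "beta", "se", "pvalue")
OPTIONAL_FIELDS = ("eaf", "n", "chrom", "pos")

#: identity map over the canonical column names
DEFAULT_COLUMN_MAP: dict[str, str] = {f: f for f in SUMMARY_COLUMNS}

#: best-effort presets for the public portals this package is pointed at;
#: real exports vary by release, so these are overridable defaults only.
COLUMN_MAP_PRESETS: dict[str, dict[str, str]] = {
    "default": dict(DEFAULT_COLUMN_MAP),
    "ssgac": {
        "rsid": "MarkerName", "effect_allele": "A1", "other_allele": "A2",
        "eaf": "EAF", "beta": "Beta", "se": "SE", "pvalue": "Pval",
        "chrom": "CHR", "pos": "POS",
    },
    "ieu": {
        "rsid": "SNP", "effect_allele": "effect_allele",
        "other_allele": "other_allele", "eaf": "eaf", "beta": "beta",
        "se": "se", "pvalue": "pval", "n": "samplesize",
        "chrom": "chr", "pos": "position",
    },
    "ipsych": {
        "rsid": "SNP", "effect_allele": "A1", "other_allele": "A2",
        "eaf": "FRQ_A", "beta": "BETA", "se": "SE", "pvalue": "P",
        "chrom": "CHR", "pos": "BP",
    },
}

_TINY_P = np.nextafter(0.0, 1.0)


def resolve_column_map(column_map: str | Mapping[str, str] | None) -> dict[str, str]:
    if column_map is None:
        return dict(DEFAULT_COLUMN_MAP)
    if isinstance(column_map, str):
        try:
            return dict(COLUMN_MAP_PRESETS[column_map])
        except KeyError:
            raise ConfigurationError(
                f"unknown column-map preset {column_map!r}; "
                f"known: {sorted(COLUMN_MAP_PRESETS)}") from None
    return dict(column_map)


def read_summary_table(path, column_map: str | Mapping[str, str] | None = None,
                       trait_meta: Mapping[str, str] | None = None,
                       sep: str | None = None) -> SummaryStats:
    """Read a delimited summary-statistics table into a :class:`SummaryStats`.

    Rows failing the per-field invariants (invalid alleles, se <= 0, p
    outside (0, 1], eaf outside [0, 1]) are dropped and tallied in the
    returned object's ``parse_log``.  p-values of exactly 0 are clamped to
    the smallest positive float with a warning (some GWAS exports underflow).

    Parameters
    ----------
    column_map
        Field -> column-header mapping, a preset name
        (``"ssgac"``, ``"ieu"``, ``"ipsych"``) or None for canonical headers.
    trait_meta
        Keys ``trait_name``, ``trait_type``, ``unit``.
    sep
        Field delimiter; None sniffs tab/comma/whitespace.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"summary-statistics file not found: {path}")
    cmap = resolve_column_map(column_map)
    meta = dict(trait_meta or {})

    raw = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    missing = [f for f in MANDATORY_FIELDS
               if cmap.get(f) is None or cmap.get(f) not in raw.columns]
    if missing:
        raise ConfigurationError(
            f"mandatory column(s) missing from {path.name}: "
            + ", ".join(f"{f} (mapped to {cmap.get(f)!r})" for f in missing))

    tab = pd.DataFrame()
    for f in MANDATORY_FIELDS + OPTIONAL_FIELDS:
        col = cmap.get(f)
        tab[f] = raw[col] if col in raw.columns else np.nan

    n_input = len(tab)
    tab["rsid"] = tab["rsid"].astype(str)
    tab["effect_allele"] = tab["effect_allele"].astype(str).str.upper()
    tab["other_allele"] = tab["other_allele"].astype(str).str.upper()
    for f in ("beta", "se", "pvalue", "eaf", "n", "pos"):
        tab[f] = pd.to_numeric(tab[f], errors="coerce")

    n_zero_p = int((tab["pvalue"] == 0).sum())
    if n_zero_p:
        warnings.warn(
            f"{n_zero_p} p-value(s) of 0 clamped to {_TINY_P:g} (underflow)",
            stacklevel=2)
        tab.loc[tab["pvalue"] == 0, "pvalue"] = _TINY_P

    bad_allele = (~tab["effect_allele"].isin(VALID_ALLELES)
                  | ~tab["other_allele"].isin(VALID_ALLELES)
                  | (tab["effect_allele"] == tab["other_allele"]))
    bad_se = ~(tab["se"] > 0)
    bad_beta = ~np.isfinite(tab["beta"])
    bad_p = ~((tab["pvalue"] > 0) & (tab["pvalue"] <= 1))
    bad_eaf = tab["eaf"].notna() & ~((tab["eaf"] >= 0) & (tab["eaf"] <= 1))
    bad_n = tab["n"].notna() & ~(tab["n"] > 0)
    invalid = bad_allele | bad_se | bad_beta | bad_p | bad_eaf | bad_n

    tally = {
        "n_input": n_input,
        "n_kept": int((~invalid).sum()),
        "n_dropped": int(invalid.sum()),
        "dropped_allele": int(bad_allele.sum()),
        "dropped_se": int((bad_se & ~bad_allele).sum()),
        "dropped_beta": int((bad_beta & ~bad_allele & ~bad_se).sum()),
        "dropped_pvalue": int((bad_p & ~bad_allele & ~bad_se & ~bad_beta).sum()),
        "dropped_eaf": int((bad_eaf & ~bad_allele & ~bad_se & ~bad_beta & ~bad_p).sum()),
        "dropped_n": int((bad_n & ~bad_allele & ~bad_se & ~bad_beta & ~bad_p
                          & ~bad_eaf).sum()),
        "p_clamped": n_zero_p,
    }
    tab = tab[~invalid].reset_index(drop=True)
    if tab.empty:
        raise InputError(f"no parseable rows in {path.name}")

    stats = SummaryStats(
        trait_name=meta.get("trait_name", path.stem),
        table=tab,
        trait_type=meta.get("trait_type", "continuous"),
        unit=meta.get("unit", ""),
        parse_log=tally,
    )
    return stats


def write_summary_table(stats: SummaryStats, path,
                        column_map: str | Mapping[str, str] | None = None,
                        sep: str = "\t") -> None:
    """Write a SummaryStats back to disk under a column map (round-trippable)."""
    cmap = resolve_column_map(column_map)
    out = stats.table.copy()
    out = out.rename(columns={f: c for f, c in cmap.items() if f in out.columns})
    out.to_csv(path, sep=sep, index=False)


def write_results_table(results: Sequence[MRResult], path,
                        precision: int = 3, sep: str = "\t") -> None:
    """Write MR results as a table of odds ratios with 95% CIs.

    Columns: exposure, outcome, method, nSNP, OR, OR_LCI, OR_UCI, pvalue.
    OR columns are exp-transformed estimates rounded to ``precision``
    decimals.  Continuous outcomes are written as-is on the beta scale with
    a ``beta_scale`` note column instead of exponentiation.
    """
    if not results:
        raise InputError("no results to write")
    rows = []
    for r in results:
        if r.outcome_type == "binary":
            o, lo, hi = r.odds_ratio()
        else:
            o, lo, hi = r.estimate, r.ci_low, r.ci_high
        rows.append({
            "exposure": r.exposure, "outcome": r.outcome, "method": r.method,
            "nSNP": r.n_snps,
            "OR": round(o, precision), "OR_LCI": round(lo, precision),
            "OR_UCI": round(hi, precision),
            "pvalue": r.pvalue,
            "scale": "OR" if r.outcome_type == "binary" else "beta",
        })
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)


def write_run_metadata(metadata: Mapping, path) -> None:
    """JSON sidecar with thresholds, seeds and per-stage SNP counts."""
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        return str(o)

    with open(path, "w") as fh:
        json.dump(metadata, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
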
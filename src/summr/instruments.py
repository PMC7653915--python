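"""Instrument selection and strength.

Instruments are genome-wide-significant SNPs (default P < 5e-8), pruned to
mutual independence by greedy LD clumping (default r2 < 0.001 within a
10,000 kb window).  Strength is summarised by per-SNP F = (beta/se)^2, the
mean F with its 95% CI lower bound, and the instrument variance explained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import HarmonizedSet, InputError, SummaryStats

GWS_P = 5e-8


# ---------------------------------------------------------------------------
# LD providers
# ---------------------------------------------------------------------------

class LDProvider:
    """Pairwise r-squared lookup interface."""

    def r2(self, rsid1: str, rsid2: str) -> float:  # pragma: no cover - interface
        raise NotImplementedError


class IndependentLD(LDProvider):
    """All pairs independent (r2 = 0): for pre-clumped or simulated SNPs."""

    def r2(self, rsid1: str, rsid2: str) -> float:
        return 0.0


class MatrixLD(LDProvider):
    """r-squared lookups backed by a user-supplied pairwise table."""

    def __init__(self, r2_map: Mapping[tuple[str, str], float]):
        self._map = dict(r2_map)

    def r2(self, rsid1: str, rsid2: str) -> float:
        if rsid1 == rsid2:
            return 1.0
        for key in ((rsid1, rsid2), (rsid2, rsid1)):
            if key in self._map:
                return float(self._map[key])
        raise InputError(f"LD provider has no r2 for pair ({rsid1}, {rsid2})")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "MatrixLD":
        """Square matrix with rsid index/columns, or long (rsid1, rsid2, r2)."""
        if set(map(str.lower, df.columns[:3])) >= {"rsid1", "rsid2", "r2"}:
            cols = {c.lower(): c for c in df.columns}
            pairs = {(str(a), str(b)): float(v) for a, b, v in
                     zip(df[cols["rsid1"]], df[cols["rsid2"]], df[cols["r2"]])}
            return cls(pairs)
        pairs = {}
        for i in df.index:
            for j in df.columns:
                pairs[(str(i), str(j))] = float(df.loc[i, j])
        return cls(pairs)

    @classmethod
    def from_square_tsv(cls, path) -> "MatrixLD":
        return cls.from_dataframe(pd.read_csv(path, sep="\t", index_col=0))

    @classmethod
    def from_long_tsv(cls, path) -> "MatrixLD":
        return cls.from_dataframe(pd.read_csv(path, sep="\t"))


# ---------------------------------------------------------------------------
# Selection and clumping
# ---------------------------------------------------------------------------

def select_gws(stats: SummaryStats, p_threshold: float = GWS_P) -> SummaryStats:
    """SNPs associated strictly below the genome-wide significance threshold."""
    if len(stats) == 0:
        raise InputError("empty summary statistics")
    tab = stats.table[stats.table["pvalue"] < p_threshold].reset_index(drop=True)
    return SummaryStats(stats.trait_name, tab, stats.trait_type, stats.unit)


def _in_window(row_a, row_b, window_kb: float) -> bool:
    # without coordinates every pair is treated as in-window (conservative)
    if pd.isna(row_a["chrom"]) or pd.isna(row_b["chrom"]):
        return True
    if str(row_a["chrom"]) != str(row_b["chrom"]):
        return False
    if pd.isna(row_a["pos"]) or pd.isna(row_b["pos"]):
        return True
    return abs(float(row_a["pos"]) - float(row_b["pos"])) <= window_kb * 1000.0


def greedy_ld_clump(stats: SummaryStats, ld: LDProvider | None = None,
                    r2_threshold: float = 0.001,
                    window_kb: float = 10_000) -> SummaryStats:
    """Greedy p-value-ordered LD pruning.

    Repeatedly keep the remaining SNP with the lowest p-value and discard
    remaining SNPs correlated with it above ``r2_threshold`` within
    ``window_kb``.  Ties on p are broken by lexicographic rsid order, so
    the result is invariant to input row order.
    """
    if ld is None:
        ld = IndependentLD()
    tab = stats.table.sort_values(["pvalue", "rsid"], kind="mergesort")
    remaining = list(tab.index)
    rows = {i: tab.loc[i] for i in remaining}
    kept: list = []
    while remaining:
        lead = remaining.pop(0)
        kept.append(lead)
        lead_row = rows[lead]
        survivors = []
        for i in remaining:
            if _in_window(lead_row, rows[i], window_kb):
                if ld.r2(lead_row["rsid"], rows[i]["rsid"]) > r2_threshold:
                    continue
            survivors.append(i)
        remaining = survivors
    out = stats.table.loc[sorted(kept)].reset_index(drop=True)
    return SummaryStats(stats.trait_name, out, stats.trait_type, stats.unit)


# ---------------------------------------------------------------------------
# Instrument strength
# ---------------------------------------------------------------------------

@dataclass
class InstrumentSet:
    """A selected, clumped instrument panel with strength statistics."""

    snps: SummaryStats
    p_threshold: float
    r2_threshold: float
    window_kb: float
    per_snp_f: dict[str, float] = field(default_factory=dict)
    mean_f: float | None = None
    mean_f_lci: float | None = None
    r2_explained: float | None = None

    def __post_init__(self) -> None:
        bad = self.snps.table[self.snps.table["pvalue"] >= self.p_threshold]
        if len(bad):
            raise InputError("instrument set contains sub-threshold SNPs")


def instrument_strength(h: HarmonizedSet | SummaryStats, exposure: int = 0,
                        ci_method: str = "normal", n_boot: int = 2000,
                        seed: int | None = None):
    """Per-SNP F statistics and the mean F with its 95% CI lower bound.

    F_j = (beta_j / se_j)^2 on the exposure associations; the variance
    explained is sum_j F_j / (F_j + n_j - 2) when sample sizes are known.
    ``ci_method`` is ``"normal"`` (mean - 1.96 * SD/sqrt(k)) or
    ``"bootstrap"`` (percentile bootstrap of the mean).

    Returns ``(per_snp_f, mean_f, mean_f_lci, r2_explained)``.
    """
    if isinstance(h, SummaryStats):
        rsids = h.rsids
        beta = h.table["beta"].to_numpy(float)
        se = h.table["se"].to_numpy(float)
        n = h.table["n"].to_numpy(float)
    else:
        rsids = h.rsids
        beta = h.exposure_beta[:, exposure]
        se = h.exposure_se[:, exposure]
        n = (h.exposure_n[:, exposure] if h.exposure_n is not None
             else np.full(len(rsids), np.nan))
    k = len(rsids)
    if k < 2:
        raise InputError("instrument strength CI needs >= 2 SNPs")
    f = (beta / se) ** 2
    mean_f = float(np.mean(f))
    if ci_method == "normal":
        lci = mean_f - 1.96 * float(np.std(f, ddof=1)) / np.sqrt(k)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        means = rng.choice(f, size=(n_boot, k), replace=True).mean(axis=1)
        lci = float(np.percentile(means, 2.5))
    else:
        raise InputError(f"unknown ci_method {ci_method!r}")
    if np.all(np.isfinite(n)) and np.all(n > 2):
        r2 = float(np.sum(f / (f + n - 2.0)))
    else:
        r2 = None
    per_snp = dict(zip(rsids, map(float, f)))
    return per_snp, mean_f, float(lci), r2


def build_instruments(stats: SummaryStats, p_threshold: float = GWS_P,
                      ld: LDProvider | None = None, r2_threshold: float = 0.001,
                      window_kb: float = 10_000) -> InstrumentSet:
    """Select GWS SNPs, clump them, and attach strength statistics."""
    sel = select_gws(stats, p_threshold)
    clumped = greedy_ld_clump(sel, ld, r2_threshold, window_kb)
    inst = InstrumentSet(clumped, p_threshold, r2_threshold, window_kb)
    if len(clumped) >= 2:
        per_snp, mean_f, lci, r2 = instrument_strength(clumped)
        inst.per_snp_f, inst.mean_f, inst.mean_f_lci, inst.r2_explained = (
            per_snp, mean_f, lci, r2)
    return inst
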
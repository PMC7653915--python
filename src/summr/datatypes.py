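"""Core containers for summary-statistic Mendelian randomization.

The package operates entirely on GWAS summary statistics: per-SNP additive
effect sizes (beta), their standard errors, allele labels, allele
frequencies, p-values and sample sizes.  Three containers carry the data
through an analysis:

* :class:`SummaryStats` — one trait's table of per-SNP associations.
* :class:`HarmonizedSet` — exposure and outcome effects aligned to a common
  effect allele per SNP, the input to every estimator.
* :class:`MRResult` — one estimator's output (point estimate on the
  log-odds-per-exposure-unit scale for binary outcomes, SE, CI, p,
  heterogeneity and pleiotropy statistics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _st

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column order of a summary-statistics table
SUMMARY_COLUMNS = [
    "rsid", "effect_allele", "other_allele", "eaf",
    "beta", "se", "pvalue", "n", "chrom", "pos",
]

# Harmonization action labels -------------------------------------------------
ACTION_KEPT = "kept"
ACTION_SIGN_FLIPPED = "sign_flipped"
ACTION_STRAND_COMPLEMENTED = "strand_complemented"
DROP_PALINDROMIC = "dropped:palindromic_intermediate_af"
DROP_MISMATCH = "dropped:allele_mismatch"
DROP_MISSING = "dropped:missing_in_source"
KEPT_ACTIONS = (ACTION_KEPT, ACTION_SIGN_FLIPPED, ACTION_STRAND_COMPLEMENTED)


class SummrError(Exception):
    """Base error for this package."""


class ConfigurationError(SummrError):
    """A column map, threshold or study configuration is invalid."""


class InputError(SummrError):
    """Input data cannot support the requested operation."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's association record for one trait."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float | None = None
    n: float | None = None
    chrom: str | None = None
    pos: int | None = None

    def is_valid(self) -> bool:
        if self.effect_allele not in VALID_ALLELES:
            return False
        if self.other_allele not in VALID_ALLELES:
            return False
        if self.effect_allele == self.other_allele:
            return False
        if not (self.se > 0 and math.isfinite(self.se)):
            return False
        if not math.isfinite(self.beta):
            return False
        if not (0 < self.pvalue <= 1):
            return False
        if self.eaf is not None and not math.isnan(self.eaf):
            if not (0 <= self.eaf <= 1):
                return False
        if self.n is not None and not math.isnan(self.n) and self.n <= 0:
            return False
        return True


@dataclass
class SummaryStats:
    """A trait's full set of per-SNP associations plus trait metadata.

    Parameters
    ----------
    trait_name : str
        Human-readable trait label.
    trait_type : {"continuous", "binary"}
        Measurement scale; betas of binary traits are log odds ratios.
    unit : str
        Free-text description of one exposure unit (e.g. "SD of years of
        schooling").
    table : pandas.DataFrame
        One row per SNP with the columns of :data:`SUMMARY_COLUMNS`
        (missing optional columns are added as NaN).  rsids must be unique.
    """

    trait_name: str
    table: pd.DataFrame
    trait_type: str = "continuous"
    unit: str = ""
    parse_log: dict | None = None

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ConfigurationError(
                f"trait_type must be 'continuous' or 'binary', got {self.trait_type!r}")
        tab = self.table.copy()
        for col in SUMMARY_COLUMNS:
            if col not in tab.columns:
                tab[col] = np.nan
        tab = tab[SUMMARY_COLUMNS].reset_index(drop=True)
        if tab["rsid"].duplicated().any():
            dups = tab.loc[tab["rsid"].duplicated(), "rsid"].tolist()
            raise InputError(f"duplicate rsids in {self.trait_name!r}: {dups[:5]}")
        self.table = tab

    # -- container protocol ------------------------------------------------
    def __len__(self) -> int:
        return len(self.table)

    def __contains__(self, rsid: str) -> bool:
        return rsid in set(self.table["rsid"])

    @property
    def rsids(self) -> list[str]:
        return self.table["rsid"].tolist()

    def record(self, rsid: str) -> VariantAssociation:
        row = self.table.loc[self.table["rsid"] == rsid]
        if row.empty:
            raise KeyError(rsid)
        r = row.iloc[0]
        return VariantAssociation(
            rsid=r["rsid"], effect_allele=r["effect_allele"],
            other_allele=r["other_allele"], beta=float(r["beta"]),
            se=float(r["se"]), pvalue=float(r["pvalue"]),
            eaf=None if pd.isna(r["eaf"]) else float(r["eaf"]),
            n=None if pd.isna(r["n"]) else float(r["n"]),
            chrom=None if pd.isna(r["chrom"]) else str(r["chrom"]),
            pos=None if pd.isna(r["pos"]) else int(r["pos"]),
        )

    def subset(self, rsids: Iterable[str]) -> "SummaryStats":
        keep = set(rsids)
        tab = self.table[self.table["rsid"].isin(keep)].reset_index(drop=True)
        return SummaryStats(self.trait_name, tab, self.trait_type, self.unit)

    @classmethod
    def from_records(cls, trait_name: str, records: Sequence[VariantAssociation],
                     trait_type: str = "continuous", unit: str = "") -> "SummaryStats":
        tab = pd.DataFrame([r.__dict__ for r in records])
        return cls(trait_name, tab, trait_type, unit)


@dataclass
class HarmonizedSet:
    """Exposure(s) and outcome effects aligned to a common effect allele.

    Rows correspond to retained SNPs in ``rsids`` order; ``actions`` holds
    one entry per *candidate* SNP (retained and dropped), so the audit trail
    conserves counts: kept + dropped = candidates considered.
    """

    rsids: list[str]
    exposure_names: list[str]
    exposure_beta: np.ndarray        # (k, p)
    exposure_se: np.ndarray          # (k, p)
    outcome_beta: np.ndarray         # (k,)
    outcome_se: np.ndarray           # (k,)
    actions: dict[str, str]
    eaf: np.ndarray | None = None    # (k,) aligned effect-allele frequency
    exposure_n: np.ndarray | None = None   # (k, p)
    outcome_n: np.ndarray | None = None    # (k,)
    outcome_name: str = "outcome"
    outcome_type: str = "binary"

    def __post_init__(self) -> None:
        self.exposure_beta = np.atleast_2d(np.asarray(self.exposure_beta, float))
        self.exposure_se = np.atleast_2d(np.asarray(self.exposure_se, float))
        if self.exposure_beta.shape[0] == 1 and len(self.rsids) > 1:
            self.exposure_beta = self.exposure_beta.T
            self.exposure_se = self.exposure_se.T
        self.outcome_beta = np.asarray(self.outcome_beta, float).ravel()
        self.outcome_se = np.asarray(self.outcome_se, float).ravel()
        k = len(self.rsids)
        if not (self.exposure_beta.shape[0] == self.exposure_se.shape[0]
                == self.outcome_beta.shape[0] == self.outcome_se.shape[0] == k):
            raise InputError("harmonized matrices have inconsistent row counts")
        if self.eaf is not None:
            self.eaf = np.asarray(self.eaf, float).ravel()
        for rsid in self.rsids:
            act = self.actions.get(rsid)
            if act not in KEPT_ACTIONS:
                raise InputError(f"retained SNP {rsid} lacks a kept-action record")

    # -- accessors ---------------------------------------------------------
    @property
    def n_snps(self) -> int:
        return len(self.rsids)

    @property
    def n_exposures(self) -> int:
        return self.exposure_beta.shape[1]

    @property
    def bx(self) -> np.ndarray:
        """Single-exposure betas (first column)."""
        return self.exposure_beta[:, 0]

    @property
    def bx_se(self) -> np.ndarray:
        return self.exposure_se[:, 0]

    @property
    def by(self) -> np.ndarray:
        return self.outcome_beta

    @property
    def by_se(self) -> np.ndarray:
        return self.outcome_se

    def action_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for act in self.actions.values():
            out[act] = out.get(act, 0) + 1
        return out

    def subset(self, rsids: Iterable[str]) -> "HarmonizedSet":
        keep = [r for r in self.rsids if r in set(rsids)]
        idx = [self.rsids.index(r) for r in keep]
        return HarmonizedSet(
            rsids=keep,
            exposure_names=list(self.exposure_names),
            exposure_beta=self.exposure_beta[idx],
            exposure_se=self.exposure_se[idx],
            outcome_beta=self.outcome_beta[idx],
            outcome_se=self.outcome_se[idx],
            actions={r: self.actions[r] for r in keep},
            eaf=None if self.eaf is None else self.eaf[idx],
            exposure_n=None if self.exposure_n is None else self.exposure_n[idx],
            outcome_n=None if self.outcome_n is None else self.outcome_n[idx],
            outcome_name=self.outcome_name,
            outcome_type=self.outcome_type,
        )

    def drop(self, rsids: Iterable[str]) -> "HarmonizedSet":
        gone = set(rsids)
        return self.subset([r for r in self.rsids if r not in gone])

    def to_frame(self) -> pd.DataFrame:
        cols = {"rsid": self.rsids}
        for j, name in enumerate(self.exposure_names):
            cols[f"beta_{name}"] = self.exposure_beta[:, j]
            cols[f"se_{name}"] = self.exposure_se[:, j]
        cols["beta_outcome"] = self.outcome_beta
        cols["se_outcome"] = self.outcome_se
        if self.eaf is not None:
            cols["eaf"] = self.eaf
        cols["action"] = [self.actions[r] for r in self.rsids]
        return pd.DataFrame(cols)

    def action_log(self) -> pd.DataFrame:
        """Full per-candidate audit table (rsid, action) including drops."""
        return pd.DataFrame(
            {"rsid": list(self.actions), "action": list(self.actions.values())}
        )

    def write_action_log(self, path) -> None:
        self.action_log().to_csv(path, sep="\t", index=False)


@dataclass
class MRResult:
    """One MR estimator's output.

    ``estimate`` is on the scale of the outcome betas per unit of exposure —
    log odds per exposure unit when the outcome is binary.  Heterogeneity
    (Cochran Q) and the Egger intercept triple are attached where the method
    provides them.
    """

    method: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snps: int
    exposure: str = ""
    outcome: str = ""
    outcome_type: str = "binary"
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    q_statistic: float | None = None
    q_df: int | None = None
    q_p: float | None = None
    notes: str = ""

    def __post_init__(self) -> None:
        if self.n_snps >= 2 and not self.se > 0:
            raise InputError("MRResult with >=2 SNPs must have positive SE")
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise InputError("CI must bracket the estimate")

    def odds_ratio(self) -> tuple[float, float, float]:
        """Exponentiate estimate and CI bounds (binary outcomes only)."""
        if self.outcome_type != "binary":
            raise InputError(
                "odds ratios are only defined for binary (log-odds) outcomes; "
                "report beta for continuous outcomes")
        return (math.exp(self.estimate), math.exp(self.ci_low), math.exp(self.ci_high))

    def summary(self) -> str:
        lines = [
            f"{self.method} MR: {self.exposure or 'exposure'} -> "
            f"{self.outcome or 'outcome'}  (k = {self.n_snps} SNPs)",
            f"  estimate {self.estimate:+.4f}  se {self.se:.4f}  "
            f"95% CI [{self.ci_low:+.4f}, {self.ci_high:+.4f}]  p = {self.pvalue:.3g}",
        ]
        if self.outcome_type == "binary":
            o, lo, hi = self.odds_ratio()
            lines.append(f"  OR {o:.3f}  95% CI [{lo:.3f}, {hi:.3f}]")
        if self.intercept is not None:
            lines.append(
                f"  intercept {self.intercept:+.4g} (se {self.intercept_se:.3g}, "
                f"p = {self.intercept_p:.3g})")
        if self.q_statistic is not None:
            lines.append(
                f"  Cochran Q {self.q_statistic:.2f} on {self.q_df} df "
                f"(p = {self.q_p:.3g})")
        if self.notes:
            lines.append(f"  notes: {self.notes}")
        return "\n".join(lines)


def normal_ci_result(method: str, estimate: float, se: float, n_snps: int,
                     **kw) -> MRResult:
    """Assemble an MRResult with a Wald 95% CI and two-sided normal p."""
    if se > 0:
        z = estimate / se
        p = 2.0 * _st.norm.sf(abs(z))
    else:
        p = 1.0 if estimate == 0 else 0.0
    return MRResult(
        method=method, estimate=float(estimate), se=float(se),
        ci_low=float(estimate - 1.96 * se), ci_high=float(estimate + 1.96 * se),
        pvalue=float(p), n_snps=int(n_snps), **kw)
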
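"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the structure a two-sample MR analysis assumes:
independent (pre-clumped) SNPs instrumenting an exposure measured in SD
units, a binary outcome whose per-allele effects are log odds ratios, and
summary-level sampling noise driven by allele frequency and sample size.
Horizontal pleiotropy (balanced or directional), gross outlier SNPs and a
two-exposure mediation structure can all be switched on, so every estimator
and diagnostic in the package can be exercised against known truth.

All randomness flows from a single integer seed; per-trait sampling noise
uses independently spawned streams, giving the two-sample independence the
estimators assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _st

from .datatypes import ConfigurationError, InputError, SummaryStats

_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]
_NONPAL_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                 ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]
_TINY_P = np.nextafter(0.0, 1.0)


@dataclass(frozen=True)
class MediationSpec:
    """Exposure B acts on the outcome only through exposure A.

    ``lam`` is the loading of B's SNP effects onto A (per-SD scale);
    ``theta_a`` is A's causal effect on the outcome (log odds per SD of A);
    B has zero direct effect by construction.  ``a_specific_variance`` is
    the instrument variance in A not shared with B.
    """

    lam: float = 0.66
    theta_a: float = -0.646
    n_a: int = 766_345
    a_specific_variance: float = 0.06


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters of a synthetic dataset, kept for recovery tests.

    Defaults mirror the motivating study design: ~224 independent
    instruments explaining ~10% of variance in an educational-attainment-
    scale exposure (sample size 766,345), acting on a binary outcome with
    a hospital-register-scale sample (50,264) with true effect
    ln(0.524) ≈ -0.646 log odds per exposure SD.
    """

    m_snps: int = 224
    theta: float = -0.646
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    pleiotropy_fraction: float = 1.0
    outlier_ids: frozenset = frozenset()
    outlier_alpha: float = 0.15
    mediation: MediationSpec | None = None
    n_exposure: int = 766_345
    n_outcome: int = 50_264
    case_fraction: float = 0.12
    variance_explained: float = 0.10
    palindromic_fraction: float = 0.20
    seed: int = 0

    def validate(self) -> None:
        if self.m_snps < 2:
            raise ConfigurationError("m_snps must be >= 2")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ConfigurationError("sample sizes must be positive")
        if self.pleiotropy_sd < 0:
            raise ConfigurationError("pleiotropy_sd must be >= 0")
        if not (0 <= self.pleiotropy_fraction <= 1):
            raise ConfigurationError("pleiotropy_fraction must be in [0, 1]")
        if not (0 < self.case_fraction < 1):
            raise ConfigurationError("case_fraction must be in (0, 1)")
        if not (0 < self.variance_explained < 1):
            raise ConfigurationError("variance_explained must be in (0, 1)")
        if not (0 <= self.palindromic_fraction <= 1):
            raise ConfigurationError("palindromic_fraction must be in [0, 1]")
        if self.mediation is not None and not (-1 <= self.mediation.lam <= 1):
            raise ConfigurationError("mediation loading lam must be in [-1, 1]")


def _rsids(m: int, prefix: str) -> list[str]:
    return [f"{prefix}{j + 1:05d}" for j in range(m)]


def _draw_architecture(truth: SimulationTruth, rng: np.random.Generator,
                       prefix: str):
    """Allele frequencies, allele labels and per-allele true exposure effects."""
    m = truth.m_snps
    f = rng.uniform(0.05, 0.95, m)
    pal = rng.random(m) < truth.palindromic_fraction
    pal_idx = rng.integers(0, len(_PALINDROMIC_PAIRS), m)
    non_idx = rng.integers(0, len(_NONPAL_PAIRS), m)
    ea = np.where(pal, [p[0] for p in np.array(_PALINDROMIC_PAIRS)[pal_idx]],
                  [p[0] for p in np.array(_NONPAL_PAIRS)[non_idx]])
    oa = np.where(pal, [p[1] for p in np.array(_PALINDROMIC_PAIRS)[pal_idx]],
                  [p[1] for p in np.array(_NONPAL_PAIRS)[non_idx]])
    # per-allele effect scaled so the set explains variance_explained on
    # average: per-SNP r2 = 2 f (1-f) b^2 = variance_explained / m
    u = rng.standard_normal(m)
    b = u * np.sqrt(truth.variance_explained / m / (2.0 * f * (1.0 - f)))
    return _rsids(m, prefix), f, ea, oa, b


def _pleiotropy(truth: SimulationTruth, rng: np.random.Generator,
                rsids: Sequence[str]) -> np.ndarray:
    alpha = rng.normal(truth.pleiotropy_mean, truth.pleiotropy_sd, truth.m_snps)
    if truth.pleiotropy_fraction < 1.0:
        affected = rng.random(truth.m_snps) < truth.pleiotropy_fraction
        alpha = np.where(affected, alpha, 0.0)
    if truth.outlier_ids:
        unknown = set(truth.outlier_ids) - set(rsids)
        if unknown:
            raise ConfigurationError(f"outlier_ids not among simulated rsids: {sorted(unknown)}")
        mask = np.isin(rsids, list(truth.outlier_ids))
        alpha = alpha + mask * truth.outlier_alpha
    return alpha


def _observe(true_beta: np.ndarray, f: np.ndarray, n: float,
             rng: np.random.Generator):
    """Observed beta/se/p for one sample: se = (2 f (1-f) n)^(-1/2).

    For a binary trait, pass the effective sample size n * v * (1 - v)
    (logistic-regression information with case fraction v) so log-odds SEs
    carry the precision a case/control GWAS actually has.
    """
    se = 1.0 / np.sqrt(2.0 * f * (1.0 - f) * n)
    beta = true_beta + rng.standard_normal(len(f)) * se
    p = 2.0 * _st.norm.sf(np.abs(beta / se))
    p = np.clip(p, _TINY_P, 1.0)
    return beta, se, p


def _as_stats(name: str, trait_type: str, unit: str, rsids, ea, oa, f,
              beta, se, p, n: int) -> SummaryStats:
    import pandas as pd

    tab = pd.DataFrame({
        "rsid": rsids, "effect_allele": ea, "other_allele": oa,
        "eaf": f, "beta": beta, "se": se, "pvalue": p,
        "n": float(n),
    })
    return SummaryStats(name, tab, trait_type, unit)


def simulate_two_sample(truth: SimulationTruth, rsid_prefix: str = "rs",
                        exposure_name: str = "exposure",
                        outcome_name: str = "outcome"
                        ) -> tuple[SummaryStats, SummaryStats]:
    """Simulate exposure and outcome summary statistics from two samples.

    True outcome effects are ``theta * b_j + alpha_j`` with pleiotropy
    ``alpha_j ~ N(pleiotropy_mean, pleiotropy_sd^2)`` (inflated by
    ``outlier_alpha`` for ``outlier_ids``).  Observation noise is
    independent between the two samples.  Deterministic given the seed.
    """
    truth.validate()
    ss = np.random.SeedSequence(truth.seed)
    s_arch, s_plei, s_exp, s_out = ss.spawn(4)
    rsids, f, ea, oa, b = _draw_architecture(truth, np.random.default_rng(s_arch),
                                             rsid_prefix)
    alpha = _pleiotropy(truth, np.random.default_rng(s_plei), rsids)
    # directional pleiotropy acts on the exposure-increasing allele: apply
    # alpha in the orientation of the SNP's exposure effect, so a nonzero
    # pleiotropy_mean is genuinely directional rather than self-cancelling
    by_true = truth.theta * b + np.sign(b) * alpha

    v = truth.case_fraction
    n_out_eff = truth.n_outcome * v * (1.0 - v)
    bx, sx, px = _observe(b, f, truth.n_exposure, np.random.default_rng(s_exp))
    by, sy, py = _observe(by_true, f, n_out_eff, np.random.default_rng(s_out))

    exposure = _as_stats(exposure_name, "continuous", "SD", rsids, ea, oa, f,
                         bx, sx, px, truth.n_exposure)
    outcome = _as_stats(outcome_name, "binary", "log-odds", rsids, ea, oa, f,
                        by, sy, py, truth.n_outcome)
    return exposure, outcome


def simulate_mediation_triplet(truth: SimulationTruth, rsid_prefix: str = "rs",
                               names: tuple[str, str, str] = ("A", "B", "outcome")
                               ) -> tuple[SummaryStats, SummaryStats, SummaryStats]:
    """Simulate exposures A and B plus an outcome where B acts only via A.

    SNP effects on B are drawn as in :func:`simulate_two_sample`; effects on
    A are ``lam * b_B + e`` with independent A-specific effects ``e``;
    outcome effects are ``theta_a * b_A`` (B has zero direct effect).  The
    three traits are observed in non-overlapping pseudo-samples.
    """
    truth.validate()
    if truth.mediation is None:
        raise ConfigurationError("simulate_mediation_triplet requires a mediation spec")
    med = truth.mediation
    ss = np.random.SeedSequence(truth.seed)
    s_arch, s_aspec, s_plei, s_a, s_b, s_out = ss.spawn(6)
    rsids, f, ea, oa, b_B = _draw_architecture(truth, np.random.default_rng(s_arch),
                                               rsid_prefix)
    rng_a = np.random.default_rng(s_aspec)
    e = rng_a.standard_normal(truth.m_snps) * np.sqrt(
        med.a_specific_variance / truth.m_snps / (2.0 * f * (1.0 - f)))
    b_A = med.lam * b_B + e
    alpha = _pleiotropy(truth, np.random.default_rng(s_plei), rsids)
    by_true = med.theta_a * b_A + np.sign(b_A) * alpha

    v = truth.case_fraction
    bA, sA, pA = _observe(b_A, f, med.n_a, np.random.default_rng(s_a))
    bB, sB, pB = _observe(b_B, f, truth.n_exposure, np.random.default_rng(s_b))
    bY, sY, pY = _observe(by_true, f, truth.n_outcome * v * (1.0 - v),
                          np.random.default_rng(s_out))

    A = _as_stats(names[0], "continuous", "SD", rsids, ea, oa, f, bA, sA, pA, med.n_a)
    B = _as_stats(names[1], "continuous", "SD", rsids, ea, oa, f, bB, sB, pB,
                  truth.n_exposure)
    Y = _as_stats(names[2], "binary", "log-odds", rsids, ea, oa, f, bY, sY, pY,
                  truth.n_outcome)
    return A, B, Y


def inject_outliers(exposure: SummaryStats, outcome: SummaryStats,
                    ids: Iterable[str], alpha_size: float) -> SummaryStats:
    """Add a pleiotropic offset to the named SNPs' outcome betas.

    Returns a new outcome SummaryStats; p-values of modified rows are
    recomputed from the shifted beta and unchanged SE.
    """
    ids = list(ids)
    shared = set(exposure.rsids) & set(outcome.rsids)
    unknown = set(ids) - shared
    if unknown:
        raise InputError(f"outlier rsids not shared by both traits: {sorted(unknown)}")
    tab = outcome.table.copy()
    mask = tab["rsid"].isin(ids)
    tab.loc[mask, "beta"] = tab.loc[mask, "beta"] + alpha_size
    z = np.abs(tab.loc[mask, "beta"] / tab.loc[mask, "se"])
    tab.loc[mask, "pvalue"] = np.clip(2.0 * _st.norm.sf(z), _TINY_P, 1.0)
    return SummaryStats(outcome.trait_name, tab, outcome.trait_type, outcome.unit)


def simulate_bidirectional(truth_forward: SimulationTruth,
                           truth_reverse: SimulationTruth,
                           names: tuple[str, str] = ("A", "B")
                           ) -> tuple[SummaryStats, SummaryStats]:
    """Two traits each with its own instrument set, for bidirectional MR.

    ``truth_forward`` governs A's instrument architecture, the A -> B causal
    effect (its ``theta``), and both sample sizes: trait A is measured as a
    continuous trait in a sample of ``n_exposure``; trait B as a binary
    trait in a sample of ``n_outcome`` with ``case_fraction`` cases.
    ``truth_reverse`` contributes B's instrument architecture (``m_snps``,
    ``variance_explained``) and the B -> A effect (its ``theta``; 0 for a
    one-way relationship); its sample-size fields are unused.

    Each trait is observed once, in its own sample, across *all* SNPs —
    both its own instruments and the other trait's — so instruments can be
    re-selected per direction exactly as with real per-trait GWAS files.
    """
    truth_forward.validate()
    truth_reverse.validate()
    ss = np.random.SeedSequence(truth_forward.seed)
    s_arch_a, s_plei_a, s_obs_a, s_obs_b = ss.spawn(4)
    s_arch_b, s_plei_b = np.random.SeedSequence(truth_reverse.seed).spawn(2)

    rsA, fA, eaA, oaA, bA = _draw_architecture(
        truth_forward, np.random.default_rng(s_arch_a), "rsA")
    rsB, fB, eaB, oaB, bB = _draw_architecture(
        truth_reverse, np.random.default_rng(s_arch_b), "rsB")
    alpha_f = _pleiotropy(truth_forward, np.random.default_rng(s_plei_a), rsA)
    alpha_r = _pleiotropy(truth_reverse, np.random.default_rng(s_plei_b), rsB)

    rsids = list(rsA) + list(rsB)
    f = np.concatenate([fA, fB])
    ea = np.concatenate([eaA, eaB])
    oa = np.concatenate([oaA, oaB])
    true_on_a = np.concatenate([bA, truth_reverse.theta * bB
                                + np.sign(bB) * alpha_r])
    true_on_b = np.concatenate([truth_forward.theta * bA
                                + np.sign(bA) * alpha_f, bB])

    v = truth_forward.case_fraction
    betaA, seA, pA = _observe(true_on_a, f, truth_forward.n_exposure,
                              np.random.default_rng(s_obs_a))
    betaB, seB, pB = _observe(true_on_b, f,
                              truth_forward.n_outcome * v * (1.0 - v),
                              np.random.default_rng(s_obs_b))
    A = _as_stats(names[0], "continuous", "SD", rsids, ea, oa, f,
                  betaA, seA, pA, truth_forward.n_exposure)
    B = _as_stats(names[1], "binary", "log-odds", rsids, ea, oa, f,
                  betaB, seB, pB, truth_forward.n_outcome)
    return A, B
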
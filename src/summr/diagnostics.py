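"""Heterogeneity, pleiotropy, outlier and directionality diagnostics.

* :func:`cochran_q` — heterogeneity of per-SNP causal estimates around a
  fitted effect; excess heterogeneity suggests pleiotropy.
* :func:`egger_intercept_test` — average directional pleiotropy.
* :func:`mr_presso` — simulation-based global and per-SNP outlier test on
  leave-one-out weighted residual sums of squares (works for single- and
  multi-exposure harmonized sets; the multivariable case uses the same
  leave-one-out scheme with the MVMR-IVW fit as its engine).
* :func:`remove_outliers_and_rerun` — prune flagged SNPs, re-estimate,
  and retest heterogeneity.
* :func:`steiger_direction` — compares instrument variance explained in
  exposure vs outcome to verify the assumed causal direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as _st

from .datatypes import HarmonizedSet, InputError, MRResult, SummaryStats
from .mvmr import MultivariableMR
from .svmr import SingleVariableMR


def cochran_q(h: HarmonizedSet, estimate: float) -> tuple[float, int, float]:
    """Cochran Q of outcome betas around ``estimate * bx``; df = k - 1."""
    if h.n_snps < 2:
        raise InputError("Cochran Q needs >= 2 SNPs")
    w = 1.0 / h.by_se ** 2
    q = float(np.sum(w * (h.by - estimate * h.bx) ** 2))
    df = h.n_snps - 1
    return q, df, float(_st.chi2.sf(q, df))


def egger_intercept_test(h: HarmonizedSet) -> tuple[float, float, float]:
    """Egger intercept, its SE and p — the average-pleiotropy test."""
    res = SingleVariableMR(h).fit_egger()
    return res.intercept, res.intercept_se, res.intercept_p


# ---------------------------------------------------------------------------
# MR-PRESSO
# ---------------------------------------------------------------------------

@dataclass
class PressoResult:
    """MR-PRESSO global and per-SNP outlier test output."""

    observed_rss: float
    global_p: float
    per_snp_p: dict[str, float]
    outliers: list[str]
    n_sim: int
    seed: int | None
    outlier_threshold: float = 0.10

    def __post_init__(self) -> None:
        lo = 1.0 / (self.n_sim + 1)
        if not (lo <= self.global_p <= 1.0):
            raise InputError("global_p outside its attainable range")


def _reorder(h: HarmonizedSet, order: list[str]) -> HarmonizedSet:
    idx = [h.rsids.index(r) for r in order]
    return HarmonizedSet(
        rsids=order, exposure_names=list(h.exposure_names),
        exposure_beta=h.exposure_beta[idx], exposure_se=h.exposure_se[idx],
        outcome_beta=h.outcome_beta[idx], outcome_se=h.outcome_se[idx],
        actions={r: h.actions[r] for r in order},
        eaf=None if h.eaf is None else h.eaf[idx],
        exposure_n=None if h.exposure_n is None else h.exposure_n[idx],
        outcome_n=None if h.outcome_n is None else h.outcome_n[idx],
        outcome_name=h.outcome_name, outcome_type=h.outcome_type)


def _loo_fit(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out fixed-effect IVW estimates, vectorized via totals."""
    a = np.sum(w * bx * by)
    b = np.sum(w * bx ** 2)
    return (a - w * bx * by) / (b - w * bx ** 2)


def _loo_fit_multi(X: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out MVMR-IVW fitted values for each left-out SNP."""
    k, p = X.shape
    Xw = X * w[:, None]
    A = X.T @ Xw
    b = Xw.T @ by
    fitted = np.empty(k)
    for j in range(k):
        Aj = A - w[j] * np.outer(X[j], X[j])
        bj = b - w[j] * X[j] * by[j]
        fitted[j] = X[j] @ np.linalg.solve(Aj, bj)
    return fitted


def mr_presso(h: HarmonizedSet, n_sim: int = 1000,
              outlier_threshold: float = 0.10,
              seed: int | None = None) -> PressoResult:
    """Pleiotropy residual sum and outlier test.

    For each SNP j the model is fitted leaving j out; the observed weighted
    residual sum of squares is compared against ``n_sim`` parametric
    simulations of the summary data under the fitted model.  p-values use
    the add-one rule ``(1 + #{sim >= obs}) / (n_sim + 1)``, so the smallest
    attainable p is 1/(n_sim + 1).  Deterministic given the seed.
    """
    k = h.n_snps
    if k < 4:
        raise InputError("MR-PRESSO needs >= 4 SNPs")
    # canonical rsid order so the result is invariant to input SNP order
    h = _reorder(h, sorted(h.rsids))
    multi = h.n_exposures > 1
    by, by_se = h.by, h.by_se
    w = 1.0 / by_se ** 2
    rng = np.random.default_rng(seed)

    if multi:
        X = h.exposure_beta
        fitted = _loo_fit_multi(X, by, w)
    else:
        bx = h.bx
        est_loo = _loo_fit(bx, by, w)
        fitted = est_loo * bx
    resid = by - fitted
    obs_contrib = w * resid ** 2
    observed_rss = float(np.sum(obs_contrib))

    bx_se_mat = h.exposure_se
    bx_mat = h.exposure_beta
    sim_contrib = np.empty((n_sim, k))
    for s in range(n_sim):
        by_s = fitted + rng.standard_normal(k) * by_se
        X_s = bx_mat + rng.standard_normal(bx_mat.shape) * bx_se_mat
        if multi:
            fit_s = _loo_fit_multi(X_s, by_s, w)
        else:
            bx_s = X_s[:, 0]
            fit_s = _loo_fit(bx_s, by_s, w) * bx_s
        sim_contrib[s] = w * (by_s - fit_s) ** 2

    sim_rss = sim_contrib.sum(axis=1)
    global_p = float((1 + np.sum(sim_rss >= observed_rss)) / (n_sim + 1))
    per_snp = (1 + (sim_contrib >= obs_contrib[None, :]).sum(axis=0)) / (n_sim + 1)
    per_snp_p = dict(zip(h.rsids, map(float, per_snp)))
    outliers = [r for r, p in per_snp_p.items() if p < outlier_threshold]
    return PressoResult(observed_rss, global_p, per_snp_p, outliers,
                        n_sim, seed, outlier_threshold)


def remove_outliers_and_rerun(h: HarmonizedSet, presso: PressoResult,
                              estimator: str = "ivw", **fit_kw
                              ) -> tuple[HarmonizedSet, MRResult | list[MRResult]]:
    """Drop MR-PRESSO outliers, re-estimate, and retest heterogeneity.

    ``estimator`` is a fit method name ('ivw', 'egger', 'weighted_median',
    'weighted_mode'); multi-exposure sets dispatch to MVMR.  The re-fit
    result's notes record whether removing outliers resolved the
    heterogeneity (Q p-value above 0.05 after pruning).
    """
    missing = set(presso.outliers) - set(h.rsids)
    if missing:
        raise InputError(f"presso outliers not in harmonized set: {sorted(missing)}")
    pruned = h.drop(presso.outliers)
    min_needed = (pruned.n_exposures + 2 if pruned.n_exposures > 1
                  else {"ivw": 2}.get(estimator, 3))
    if pruned.n_snps < min_needed:
        raise InputError(
            f"pruning left {pruned.n_snps} SNPs, below the minimum "
            f"{min_needed} for {estimator}")
    if pruned.n_exposures > 1:
        result = MultivariableMR(pruned).fit(estimator, **fit_kw)
        q_note = f"post-pruning Q p = {result[0].q_p:.3g}" if result[0].q_p else ""
        for r in result:
            r.notes = (r.notes + "; " if r.notes else "") + \
                f"{len(presso.outliers)} outlier(s) removed; {q_note}"
        return pruned, result
    result = SingleVariableMR(pruned).fit(estimator, **fit_kw)
    q, df, q_p = cochran_q(pruned, result.estimate)
    if result.q_statistic is None:
        result.q_statistic, result.q_df, result.q_p = q, df, q_p
    resolved = "resolved" if q_p > 0.05 else "not resolved"
    result.notes = (result.notes + "; " if result.notes else "") + \
        f"{len(presso.outliers)} outlier(s) removed; heterogeneity {resolved} " \
        f"(Q p = {q_p:.3g})"
    return pruned, result


# ---------------------------------------------------------------------------
# Steiger directionality
# ---------------------------------------------------------------------------

@dataclass
class SteigerResult:
    r2_exposure: float
    r2_outcome: float
    direction_ok: bool
    pvalue: float
    note: str = ""


def _instrument_r2(stats: SummaryStats, rsids: list[str]) -> tuple[float, float]:
    tab = stats.table.set_index("rsid")
    missing = [r for r in rsids if r not in tab.index]
    if missing:
        raise InputError(f"rsids missing from {stats.trait_name!r}: {missing[:5]}")
    sub = tab.loc[rsids]
    n = sub["n"].to_numpy(float)
    if np.any(~np.isfinite(n)):
        raise InputError(f"sample sizes missing in {stats.trait_name!r}; "
                         "Steiger test needs per-SNP n")
    z2 = (sub["beta"].to_numpy(float) / sub["se"].to_numpy(float)) ** 2
    r2 = float(np.sum(z2 / (z2 + n)))
    return r2, float(np.median(n))


def steiger_direction(exposure_stats: SummaryStats, outcome_stats: SummaryStats,
                      h: HarmonizedSet) -> SteigerResult:
    """Does the instrument explain more variance in exposure than outcome?

    Per-SNP variance explained is approximated from summary data as
    z^2/(z^2 + n) and summed over the harmonized SNPs; the two sums are
    compared with a normal test on the difference of Fisher-z-transformed
    correlations using the two independent sample sizes.  For binary
    traits this is an observed-scale approximation.
    """
    r2_x, n_x = _instrument_r2(exposure_stats, h.rsids)
    r2_y, n_y = _instrument_r2(outcome_stats, h.rsids)
    r_x, r_y = np.sqrt(min(r2_x, 1.0 - 1e-12)), np.sqrt(min(r2_y, 1.0 - 1e-12))
    z = (np.arctanh(r_x) - np.arctanh(r_y)) / np.sqrt(
        1.0 / (n_x - 3.0) + 1.0 / (n_y - 3.0))
    p = float(2.0 * _st.norm.sf(abs(z)))
    note = ""
    if "binary" in (exposure_stats.trait_type, outcome_stats.trait_type):
        note = "observed-scale z-based r2 approximation for binary trait(s)"
    return SteigerResult(r2_x, r2_y, bool(r2_x > r2_y), p, note)


def diagnostic_report(q: tuple[float, int, float],
                      egger_intercept: tuple[float, float, float],
                      presso: PressoResult | None,
                      steiger: SteigerResult | None) -> dict:
    """Flat dict for the per-analysis diagnostics TSV."""
    rep = {
        "Q": q[0], "Q_df": q[1], "Q_p": q[2],
        "egger_intercept": egger_intercept[0],
        "egger_intercept_se": egger_intercept[1],
        "egger_intercept_p": egger_intercept[2],
    }
    if presso is not None:
        rep.update(presso_global_p=presso.global_p,
                   n_outliers=len(presso.outliers))
    if steiger is not None:
        rep.update(steiger_r2_exposure=steiger.r2_exposure,
                   steiger_r2_outcome=steiger.r2_outcome,
                   steiger_direction=steiger.direction_ok,
                   steiger_p=steiger.pvalue)
    return rep
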
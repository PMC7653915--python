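"""Multivariable MR: simultaneous direct effects of several exposures.

:class:`MultivariableMR` regresses outcome betas on the matrix of exposure
betas (weights 1/se_y^2) with the intercept set to zero (IVW) or free
(MVMR-Egger).  Each coefficient is the direct effect of that exposure
conditional on the others — the quantity that distinguishes a genuinely
causal exposure from one acting only through a correlated co-exposure.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _st

from ._wls import weighted_least_squares
from .datatypes import HarmonizedSet, InputError, MRResult, normal_ci_result
from .svmr import SingleVariableMR


class MultivariableMR:
    """Multi-exposure MR model over a jointly harmonized SNP set."""

    def __init__(self, harmonized: HarmonizedSet):
        self.h = harmonized

    def fit(self, method: str = "ivw", **kw) -> list[MRResult]:
        if method == "ivw":
            return self.fit_ivw(**kw)
        if method == "egger":
            return self.fit_egger(**kw)
        raise InputError(f"unknown method {method!r}; choose 'ivw' or 'egger'")

    def fit_ivw(self, effects_model: str = "multiplicative_random"
                ) -> list[MRResult]:
        """Weighted regression through the origin; one MRResult per exposure.

        SNP count must be at least the exposure count plus two.  With a
        single exposure this reduces exactly to single-variable IVW.
        """
        h = self.h
        p = h.n_exposures
        if h.n_snps < p + 2:
            raise InputError(f"MVMR-IVW needs >= {p + 2} SNPs for {p} exposures")
        w = 1.0 / h.by_se ** 2
        params, se, q, df, sigma = weighted_least_squares(
            h.exposure_beta, h.by, w, effects_model)
        q_p = float(_st.chi2.sf(q, df))
        out = []
        for j, name in enumerate(h.exposure_names):
            res = normal_ci_result(
                "mvmr_ivw", params[j], se[j], h.n_snps, exposure=name,
                outcome=h.outcome_name, outcome_type=h.outcome_type,
                notes=f"direct effect conditional on "
                      f"{[n for i, n in enumerate(h.exposure_names) if i != j]}; "
                      f"sigma = {sigma:.3f}")
            res.q_statistic, res.q_df, res.q_p = q, df, q_p
            out.append(res)
        return out

    def fit_egger(self, reference_exposure: int = 0,
                  effects_model: str = "multiplicative_random"
                  ) -> list[MRResult]:
        """MVMR-Egger: free intercept after orienting on a reference exposure.

        Rows are sign-oriented so the reference exposure's betas are
        non-negative (all exposure columns and the outcome flipped
        together per SNP); the intercept and its test are attached to each
        returned result.
        """
        h = self.h
        p = h.n_exposures
        if h.n_snps < p + 3:
            raise InputError(f"MVMR-Egger needs >= {p + 3} SNPs for {p} exposures")
        if not (0 <= reference_exposure < p):
            raise InputError(f"reference_exposure {reference_exposure} out of range")
        flip = np.where(h.exposure_beta[:, reference_exposure] < 0, -1.0, 1.0)
        X = h.exposure_beta * flip[:, None]
        by = h.by * flip
        w = 1.0 / h.by_se ** 2
        Xi = np.column_stack([np.ones(h.n_snps), X])
        params, se, q, df, sigma = weighted_least_squares(Xi, by, w, effects_model)
        intercept, i_se = float(params[0]), float(se[0])
        i_p = float(2.0 * _st.norm.sf(abs(intercept / i_se)))
        q_p = float(_st.chi2.sf(q, df))
        out = []
        for j, name in enumerate(h.exposure_names):
            res = normal_ci_result(
                "mvmr_egger", params[j + 1], se[j + 1], h.n_snps, exposure=name,
                outcome=h.outcome_name, outcome_type=h.outcome_type,
                notes=f"oriented on {h.exposure_names[reference_exposure]!r}; "
                      f"sigma = {sigma:.3f}")
            res.intercept, res.intercept_se, res.intercept_p = intercept, i_se, i_p
            res.q_statistic, res.q_df, res.q_p = q, df, q_p
            out.append(res)
        return out


def mvmr_ivw(h: HarmonizedSet,
             effects_model: str = "multiplicative_random") -> list[MRResult]:
    return MultivariableMR(h).fit_ivw(effects_model)


def mvmr_egger(h: HarmonizedSet, reference_exposure: int = 0,
               effects_model: str = "multiplicative_random") -> list[MRResult]:
    return MultivariableMR(h).fit_egger(reference_exposure, effects_model)
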
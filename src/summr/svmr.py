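"""Single-variable MR estimators.

:class:`SingleVariableMR` is a model object built from a
:class:`~summr.datatypes.HarmonizedSet`; its ``fit`` methods return
:class:`~summr.datatypes.MRResult` objects.  Four estimators are provided,
differing in which instruments they allow to be invalid:

* **IVW** — inverse-variance weighted regression of outcome betas on
  exposure betas through the origin; unbiased only under balanced
  pleiotropy.
* **MR-Egger** — the same regression with a free intercept; the intercept
  estimates the average directional pleiotropic effect.
* **Weighted median** — the inverse-variance-weighted median of per-SNP
  Wald ratios; consistent when under half of the weight is on invalid
  instruments.
* **Weighted mode** — the mode of the kernel-smoothed weighted Wald-ratio
  density; consistent when the largest cluster of SNPs is valid.

Module-level functions (:func:`ivw`, :func:`egger`, ...) are thin wrappers
over the model class.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as _st

from ._wls import weighted_least_squares
from .datatypes import HarmonizedSet, InputError, MRResult, normal_ci_result
from .harmonize import harmonize_pair
from .instruments import greedy_ld_clump, select_gws


def wald_ratio(bx: float, bx_se: float, by: float, by_se: float,
               exposure: str = "", outcome: str = "",
               outcome_type: str = "binary") -> MRResult:
    """Single-SNP causal estimate by/bx with first-order SE |by_se/bx|."""
    if bx == 0:
        raise InputError("Wald ratio undefined for bx = 0")
    est = by / bx
    se = abs(by_se / bx)
    return normal_ci_result("wald_ratio", est, se, 1, exposure=exposure,
                            outcome=outcome, outcome_type=outcome_type)


class SingleVariableMR:
    """Single-exposure MR model over a harmonized SNP set."""

    def __init__(self, harmonized: HarmonizedSet):
        if harmonized.n_exposures != 1:
            raise InputError(
                "SingleVariableMR takes a single-exposure HarmonizedSet; "
                "use MultivariableMR for several exposures")
        self.h = harmonized

    @classmethod
    def from_summary_stats(cls, exposure, outcome, p_threshold: float = 5e-8,
                           ld=None, r2_threshold: float = 0.001,
                           window_kb: float = 10_000,
                           af_window=(0.42, 0.58)) -> "SingleVariableMR":
        """Select instruments, clump, harmonize, and build the model."""
        inst = greedy_ld_clump(select_gws(exposure, p_threshold), ld,
                               r2_threshold, window_kb)
        return cls(harmonize_pair(inst, outcome, af_window))

    # -- shared pieces -----------------------------------------------------
    @property
    def _names(self) -> dict:
        return dict(exposure=self.h.exposure_names[0],
                    outcome=self.h.outcome_name,
                    outcome_type=self.h.outcome_type)

    def _ratios(self):
        bx, by = self.h.bx, self.h.by
        if np.any(bx == 0):
            raise InputError("zero exposure beta: Wald ratio undefined")
        ratios = by / bx
        weights = bx ** 2 / self.h.by_se ** 2  # 1 / var(ratio), first order
        return ratios, weights

    # -- estimators --------------------------------------------------------
    def fit(self, method: str = "ivw", **kw) -> MRResult:
        dispatch = {
            "ivw": self.fit_ivw, "egger": self.fit_egger,
            "weighted_median": self.fit_weighted_median,
            "weighted_mode": self.fit_weighted_mode,
        }
        try:
            return dispatch[method](**kw)
        except KeyError:
            raise InputError(f"unknown method {method!r}; "
                             f"choose from {sorted(dispatch)}") from None

    def fit_all(self, n_boot: int = 1000, seed: int | None = None
                ) -> dict[str, MRResult]:
        return {
            "ivw": self.fit_ivw(),
            "egger": self.fit_egger(),
            "weighted_median": self.fit_weighted_median(n_boot=n_boot, seed=seed),
            "weighted_mode": self.fit_weighted_mode(n_boot=n_boot, seed=seed),
        }

    def fit_ivw(self, effects_model: str = "multiplicative_random") -> MRResult:
        h = self.h
        if h.n_snps < 2:
            raise InputError("IVW needs >= 2 SNPs; use wald_ratio for one")
        w = 1.0 / h.by_se ** 2
        params, se, q, df, sigma = weighted_least_squares(
            h.bx[:, None], h.by, w, effects_model)
        notes = (f"multiplicative random effects, sigma = {sigma:.3f}"
                 if effects_model == "multiplicative_random" else "fixed effects")
        res = normal_ci_result("ivw", params[0], se[0], h.n_snps,
                               notes=notes, **self._names)
        res.q_statistic, res.q_df, res.q_p = q, df, float(_st.chi2.sf(q, df))
        return res

    def fit_egger(self, effects_model: str = "multiplicative_random") -> MRResult:
        h = self.h
        if h.n_snps < 3:
            raise InputError("MR-Egger needs >= 3 SNPs")
        # orient rows so exposure betas are non-negative (InSIDE convention)
        flip = np.where(h.bx < 0, -1.0, 1.0)
        bx, by = h.bx * flip, h.by * flip
        w = 1.0 / h.by_se ** 2
        X = np.column_stack([np.ones_like(bx), bx])
        params, se, q, df, sigma = weighted_least_squares(X, by, w, effects_model)
        res = normal_ci_result("egger", params[1], se[1], h.n_snps,
                               notes=f"sigma = {sigma:.3f}", **self._names)
        z0 = params[0] / se[0]
        res.intercept, res.intercept_se = float(params[0]), float(se[0])
        res.intercept_p = float(2.0 * _st.norm.sf(abs(z0)))
        res.q_statistic, res.q_df, res.q_p = q, df, float(_st.chi2.sf(q, df))
        return res

    def fit_weighted_median(self, n_boot: int = 1000,
                            seed: int | None = None) -> MRResult:
        h = self.h
        if h.n_snps < 3:
            raise InputError("weighted median needs >= 3 SNPs")
        ratios, weights = self._ratios()
        est = _weighted_median(ratios, weights)
        boots = self._bootstrap_ratio_estimator(_weighted_median_rows,
                                                n_boot, seed)
        se = float(np.std(boots, ddof=1))
        return normal_ci_result("weighted_median", est, se, h.n_snps,
                                notes=f"parametric bootstrap SE, B = {n_boot}",
                                **self._names)

    def fit_weighted_mode(self, phi: float = 1.0, n_boot: int = 1000,
                          seed: int | None = None) -> MRResult:
        h = self.h
        if h.n_snps < 3:
            raise InputError("weighted mode needs >= 3 SNPs")
        ratios, weights = self._ratios()
        est = _weighted_mode(ratios, weights, phi)
        boots = self._bootstrap_ratio_estimator(
            lambda R, W: np.array([_weighted_mode(r, w, phi)
                                   for r, w in zip(R, W)]),
            n_boot, seed)
        se = float(np.std(boots, ddof=1))
        return normal_ci_result("weighted_mode", est, se, h.n_snps,
                                notes=f"phi = {phi}, bootstrap B = {n_boot}",
                                **self._names)

    def _bootstrap_ratio_estimator(self, estimator_rows, n_boot: int,
                                   seed: int | None) -> np.ndarray:
        """Parametric bootstrap: redraw bx, by from their SEs, re-estimate."""
        h = self.h
        rng = np.random.default_rng(seed)
        k = h.n_snps
        bxs = h.bx + rng.standard_normal((n_boot, k)) * h.bx_se
        bys = h.by + rng.standard_normal((n_boot, k)) * h.by_se
        bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)
        R = bys / bxs
        W = bxs ** 2 / h.by_se ** 2
        return np.asarray(estimator_rows(R, W), float)


# ---------------------------------------------------------------------------
# ratio-based estimator internals
# ---------------------------------------------------------------------------

def _weighted_median_rows(R: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Row-wise weighted median by interpolation at cumulative weight 0.5."""
    idx = np.argsort(R, axis=-1)
    r = np.take_along_axis(R, idx, -1)
    w = np.take_along_axis(W, idx, -1)
    cw = np.cumsum(w, -1)
    p = (cw - 0.5 * w) / cw[..., -1:]
    k = R.shape[-1]
    j = np.clip((p < 0.5).sum(-1), 1, k - 1)
    rows = np.arange(R.shape[0])
    p0, p1 = p[rows, j - 1], p[rows, j]
    r0, r1 = r[rows, j - 1], r[rows, j]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(p1 > p0, (0.5 - p0) / (p1 - p0), 0.0)
    return r0 + np.clip(t, 0.0, 1.0) * (r1 - r0)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    return float(_weighted_median_rows(ratios[None, :], weights[None, :])[0])


def _weighted_mode(ratios: np.ndarray, weights: np.ndarray,
                   phi: float = 1.0, n_grid: int = 512) -> float:
    """Argmax of the weighted Gaussian-kernel density of the Wald ratios.

    Bandwidth is phi times the modified Silverman rule
    0.9 * min(SD, 1.4826 * MAD) * k^(-1/5); grid spans the ratios plus
    three bandwidths; ties resolve to the smallest grid value.
    """
    r = np.asarray(ratios, float)
    if np.ptp(r) == 0:
        return float(r[0])
    sd = float(np.std(r, ddof=1))
    mad = float(np.median(np.abs(r - np.median(r)))) * 1.4826
    sig = min(sd, mad) if mad > 0 else sd
    h = phi * 0.9 * sig * len(r) ** (-0.2)
    if h <= 0:
        return float(np.median(r))
    grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, n_grid)
    dens = (weights[:, None]
            * np.exp(-0.5 * ((grid[None, :] - r[:, None]) / h) ** 2)).sum(0)
    return float(grid[np.argmax(dens)])


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def ivw(h: HarmonizedSet, effects_model: str = "multiplicative_random") -> MRResult:
    return SingleVariableMR(h).fit_ivw(effects_model)


def egger(h: HarmonizedSet, effects_model: str = "multiplicative_random") -> MRResult:
    return SingleVariableMR(h).fit_egger(effects_model)


def weighted_median(h: HarmonizedSet, n_boot: int = 1000,
                    seed: int | None = None) -> MRResult:
    return SingleVariableMR(h).fit_weighted_median(n_boot=n_boot, seed=seed)


def weighted_mode(h: HarmonizedSet, phi: float = 1.0, n_boot: int = 1000,
                  seed: int | None = None) -> MRResult:
    return SingleVariableMR(h).fit_weighted_mode(phi=phi, n_boot=n_boot, seed=seed)


def as_odds_ratio(r: MRResult) -> tuple[float, float, float]:
    """Exponentiate a log-odds MRResult to (OR, OR_LCI, OR_UCI)."""
    return r.odds_ratio()
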
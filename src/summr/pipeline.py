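"""Study orchestration: full single-variable and multivariable MR batteries.

`run_svmr_analysis` executes the complete chain for one exposure-outcome
pair — instrument selection, LD clumping, harmonization, the four
single-variable estimators, the diagnostic battery, and the
outlier-pruned re-run — and returns a bundle whose primary reported
result is the outlier-pruned IVW estimate (unpruned results are always
retained alongside).  `run_mvmr_analysis` does the analogous chain on a
union instrument panel for several exposures; `run_bidirectional` runs a
pair of traits in both directions with instruments re-selected per
direction.  `StudyConfig` drives batch runs from a YAML/JSON file.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as _io
from .datatypes import (ConfigurationError, HarmonizedSet, InputError,
                        MRResult, SummaryStats, SummrError)
from .diagnostics import (PressoResult, SteigerResult, cochran_q,
                          diagnostic_report, egger_intercept_test, mr_presso,
                          remove_outliers_and_rerun, steiger_direction)
from .harmonize import DEFAULT_AF_WINDOW, harmonize_multi, harmonize_pair
from .instruments import (LDProvider, greedy_ld_clump, instrument_strength,
                          select_gws)
from .mvmr import MultivariableMR
from .svmr import SingleVariableMR


@dataclass
class Thresholds:
    """Analysis thresholds; defaults follow the study design this package
    reimplements (GWS selection, clumping, outlier pruning, decision flags)."""

    gws_p: float = 5e-8
    clump_r2: float = 0.001
    clump_window_kb: float = 10_000
    palindrome_af_window: tuple[float, float] = DEFAULT_AF_WINDOW
    presso_outlier_p: float = 0.10
    presso_prune_gate_p: float = 0.05
    presso_global_flag_p: float = 0.01
    egger_intercept_flag_p: float = 0.01
    steiger_p: float = 0.01
    alpha: float = 0.025
    presso_n_sim: int = 1000
    n_boot: int = 1000

    def validate(self) -> None:
        for name in ("gws_p", "presso_outlier_p", "presso_prune_gate_p",
                     "presso_global_flag_p",
                     "egger_intercept_flag_p", "steiger_p", "alpha"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ConfigurationError(f"threshold {name} = {v} outside (0, 1]")
        if not (0 <= self.clump_r2 <= 1):
            raise ConfigurationError("clump_r2 outside [0, 1]")
        lo, hi = self.palindrome_af_window
        if not (0 < lo < hi < 1):
            raise ConfigurationError("palindrome_af_window must satisfy 0 < lo < hi < 1")
        if self.presso_n_sim < 1 or self.n_boot < 1:
            raise ConfigurationError("simulation counts must be positive")


@dataclass
class DecisionFlags:
    """The four decision criteria applied to a completed SVMR bundle."""

    sign_agreement: bool
    ivw_significant: bool
    no_pleiotropy: bool
    direction_ok: bool

    @property
    def overall(self) -> bool:
        return (self.sign_agreement and self.ivw_significant
                and self.no_pleiotropy and self.direction_ok)


@dataclass
class SVMRBundle:
    exposure: str
    outcome: str
    counts: dict
    harmonized: HarmonizedSet
    strength: dict
    results: dict[str, MRResult]
    presso: PressoResult
    pruned: HarmonizedSet
    pruned_results: dict[str, MRResult]
    steiger: SteigerResult
    flags: DecisionFlags | None = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int | None = None

    @property
    def primary(self) -> MRResult:
        """Headline estimate: outlier-pruned IVW."""
        return self.pruned_results["ivw"]

    def all_results(self) -> list[MRResult]:
        out = []
        for tag, d in (("", self.results), ("pruned_", self.pruned_results)):
            for name, r in d.items():
                r2 = dataclasses.replace(r, method=tag + r.method)
                out.append(r2)
        return out


@dataclass
class MVMRBundle:
    exposures: list[str]
    outcome: str
    counts: dict
    harmonized: HarmonizedSet
    results: list[MRResult]
    egger_results: list[MRResult]
    presso: PressoResult
    pruned: HarmonizedSet
    pruned_results: list[MRResult]
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int | None = None

    @property
    def primary(self) -> list[MRResult]:
        return self.pruned_results


def _child_seeds(seed: int | None, n: int) -> list[int]:
    rng = np.random.default_rng(seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, n)]


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, SummrError):
                raise type(exc)(f"[stage: {name}] {exc}") from exc
            return False
    return _Ctx()


def run_svmr_analysis(exposure: SummaryStats, outcome: SummaryStats,
                      thresholds: Thresholds | None = None,
                      ld: LDProvider | None = None,
                      seed: int | None = None) -> SVMRBundle:
    """Full single-variable MR battery for one exposure-outcome pair."""
    t = thresholds or Thresholds()
    t.validate()
    s_presso, s_boot = _child_seeds(seed, 2)
    counts: dict = {"n_exposure_input": len(exposure)}

    with _stage("select_gws"):
        gws = select_gws(exposure, t.gws_p)
        counts["n_gws"] = len(gws)
    with _stage("clump"):
        inst = greedy_ld_clump(gws, ld, t.clump_r2, t.clump_window_kb)
        counts["n_clumped"] = len(inst)
        counts["n_clump_removed"] = counts["n_gws"] - counts["n_clumped"]
    with _stage("harmonize"):
        h = harmonize_pair(inst, outcome, t.palindrome_af_window)
        counts.update({f"harmonize_{k}": v for k, v in h.action_counts().items()})
        counts["n_harmonized"] = h.n_snps
    with _stage("instrument_strength"):
        per_f, mean_f, lci, r2 = instrument_strength(h)
        strength = {"mean_f": mean_f, "mean_f_lci": lci, "r2_explained": r2,
                    "min_f": min(per_f.values())}
    with _stage("estimators"):
        model = SingleVariableMR(h)
        results = model.fit_all(n_boot=t.n_boot, seed=s_boot)
    with _stage("diagnostics"):
        presso = mr_presso(h, n_sim=t.presso_n_sim,
                           outlier_threshold=t.presso_outlier_p, seed=s_presso)
        steiger = steiger_direction(exposure, outcome, h)
    with _stage("outlier_pruned_rerun"):
        # prune only when the global test indicates pleiotropic bias;
        # removing chance-flagged SNPs from a homogeneous set shrinks the
        # heterogeneity estimate and makes the re-fit anti-conservative
        if presso.outliers and presso.global_p < t.presso_prune_gate_p:
            pruned, _ = remove_outliers_and_rerun(h, presso, "ivw")
            pruned_results = SingleVariableMR(pruned).fit_all(
                n_boot=t.n_boot, seed=s_boot)
            counts["n_outliers_removed"] = len(presso.outliers)
        else:
            pruned, pruned_results = h, results
            counts["n_outliers_removed"] = 0
        counts["n_pruned"] = pruned.n_snps

    bundle = SVMRBundle(
        exposure=exposure.trait_name, outcome=outcome.trait_name,
        counts=counts, harmonized=h, strength=strength, results=results,
        presso=presso, pruned=pruned, pruned_results=pruned_results,
        steiger=steiger, thresholds=t, seed=seed)
    bundle.flags = evaluate_decision_criteria(bundle)
    return bundle


def evaluate_decision_criteria(bundle: SVMRBundle,
                               thresholds: Thresholds | None = None
                               ) -> DecisionFlags:
    """Apply the four decision criteria to a completed SVMR bundle.

    (1) all four estimators agree in sign; (2) IVW p below alpha;
    (3) no pleiotropy indication (MR-PRESSO global p and Egger intercept p
    both above their flag thresholds); (4) Steiger supports the assumed
    direction at its threshold.  The primary (outlier-pruned) results are
    used throughout.
    """
    t = thresholds or bundle.thresholds
    res = bundle.pruned_results
    signs = {np.sign(r.estimate) for r in res.values()}
    sign_agreement = len(signs) == 1
    ivw_significant = res["ivw"].pvalue < t.alpha
    no_pleiotropy = (bundle.presso.global_p > t.presso_global_flag_p
                     and res["egger"].intercept_p > t.egger_intercept_flag_p)
    direction_ok = (bundle.steiger.direction_ok
                    and bundle.steiger.pvalue < t.steiger_p)
    return DecisionFlags(sign_agreement, ivw_significant, no_pleiotropy,
                         direction_ok)


def run_bidirectional(trait_a: SummaryStats, trait_b: SummaryStats,
                      thresholds: Thresholds | None = None,
                      ld: LDProvider | None = None,
                      seed: int | None = None) -> tuple[SVMRBundle, SVMRBundle]:
    """Run A -> B and B -> A with instruments re-selected per direction."""
    s_f, s_r = _child_seeds(seed, 2)
    forward = run_svmr_analysis(trait_a, trait_b, thresholds, ld, seed=s_f)
    reverse = run_svmr_analysis(trait_b, trait_a, thresholds, ld, seed=s_r)
    return forward, reverse


def run_mvmr_analysis(exposures: Sequence[SummaryStats], outcome: SummaryStats,
                      thresholds: Thresholds | None = None,
                      ld: LDProvider | None = None,
                      seed: int | None = None,
                      reference_exposure: int = 0):
    """Multivariable MR battery on the union instrument panel.

    The panel is the union of each exposure's genome-wide-significant,
    clumped SNPs; union SNPs missing from any source are dropped during
    harmonization.  A single exposure delegates to
    :func:`run_svmr_analysis` with a logged note.
    """
    if len(exposures) == 1:
        bundle = run_svmr_analysis(exposures[0], outcome, thresholds, ld, seed)
        bundle.counts["note"] = "single exposure: delegated to SVMR"
        return bundle
    t = thresholds or Thresholds()
    t.validate()
    (s_presso,) = _child_seeds(seed, 1)
    counts: dict = {}

    with _stage("select_and_clump_union"):
        union: list[str] = []
        seen: set[str] = set()
        for e in exposures:
            inst = greedy_ld_clump(select_gws(e, t.gws_p), ld,
                                   t.clump_r2, t.clump_window_kb)
            counts[f"n_instruments_{e.trait_name}"] = len(inst)
            for r in inst.rsids:
                if r not in seen:
                    union.append(r)
                    seen.add(r)
        counts["n_union"] = len(union)
    with _stage("harmonize_multi"):
        h = harmonize_multi(exposures, outcome, t.palindrome_af_window,
                            instruments=union)
        counts.update({f"harmonize_{k}": v for k, v in h.action_counts().items()})
        counts["n_harmonized"] = h.n_snps
    with _stage("mvmr_estimators"):
        model = MultivariableMR(h)
        results = model.fit_ivw()
        egger_results = model.fit_egger(reference_exposure=reference_exposure)
    with _stage("mvmr_presso"):
        presso = mr_presso(h, n_sim=t.presso_n_sim,
                           outlier_threshold=t.presso_outlier_p, seed=s_presso)
    with _stage("outlier_pruned_rerun"):
        if presso.outliers and presso.global_p < t.presso_prune_gate_p:
            pruned, pruned_results = remove_outliers_and_rerun(h, presso, "ivw")
            counts["n_outliers_removed"] = len(presso.outliers)
        else:
            pruned, pruned_results = h, results
            counts["n_outliers_removed"] = 0
        counts["n_pruned"] = pruned.n_snps

    return MVMRBundle(
        exposures=[e.trait_name for e in exposures],
        outcome=outcome.trait_name, counts=counts, harmonized=h,
        results=results, egger_results=egger_results, presso=presso,
        pruned=pruned, pruned_results=pruned_results, thresholds=t, seed=seed)


# ---------------------------------------------------------------------------
# config-driven studies
# ---------------------------------------------------------------------------

@dataclass
class DatasetSpec:
    path: str
    column_map: str | Mapping[str, str] | None = None
    trait_type: str = "continuous"
    unit: str = ""


@dataclass
class AnalysisSpec:
    kind: str                      # svmr | mvmr | bidirectional
    exposures: list[str]
    outcome: str
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("svmr", "mvmr", "bidirectional"):
            raise ConfigurationError(f"unknown analysis kind {self.kind!r}")
        if not self.name:
            self.name = f"{self.kind}:{'+'.join(self.exposures)}->{self.outcome}"


@dataclass
class StudyConfig:
    datasets: dict[str, DatasetSpec]
    analyses: list[AnalysisSpec]
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int | None = None

    def validate(self) -> None:
        self.thresholds.validate()
        for a in self.analyses:
            for name in [*a.exposures, a.outcome]:
                if name not in self.datasets:
                    raise ConfigurationError(
                        f"analysis {a.name!r} references undefined dataset {name!r}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        datasets = {name: DatasetSpec(**spec) if not isinstance(spec, DatasetSpec)
                    else spec for name, spec in d.get("datasets", {}).items()}
        analyses = [AnalysisSpec(**a) if not isinstance(a, AnalysisSpec) else a
                    for a in d.get("analyses", [])]
        thr = d.get("thresholds", {})
        if isinstance(thr, Mapping):
            thr = dict(thr)
            if "palindrome_af_window" in thr:
                thr["palindrome_af_window"] = tuple(thr["palindrome_af_window"])
            thr = Thresholds(**thr)
        cfg = cls(datasets=datasets, analyses=analyses, thresholds=thr,
                  seed=d.get("seed"))
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def load_dataset(name: str, spec: DatasetSpec, base_dir: Path | None = None
                 ) -> SummaryStats:
    path = Path(spec.path)
    if base_dir is not None and not path.is_absolute():
        path = base_dir / path
    return _io.read_summary_table(
        path, column_map=spec.column_map,
        trait_meta={"trait_name": name, "trait_type": spec.trait_type,
                    "unit": spec.unit})


def run_study(config: StudyConfig, out_dir, base_dir=None) -> dict:
    """Execute every analysis in the config; write result tables and metadata.

    Outputs under ``out_dir``: ``results.tsv`` (unpruned + pruned estimates
    for every analysis), ``diagnostics.tsv``, one harmonization action log
    per analysis, and ``run_metadata.json`` with thresholds, seeds and
    per-stage SNP counts.
    """
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    base_dir = Path(base_dir) if base_dir is not None else None
    data = {name: load_dataset(name, spec, base_dir)
            for name, spec in config.datasets.items()}

    all_results: list[MRResult] = []
    diag_rows = []
    meta: dict = {"seed": config.seed,
                  "thresholds": dataclasses.asdict(config.thresholds),
                  "analyses": {}}
    seeds = _child_seeds(config.seed, max(1, len(config.analyses)))

    for a, a_seed in zip(config.analyses, seeds):
        t = config.thresholds
        if a.kind == "svmr":
            b = run_svmr_analysis(data[a.exposures[0]], data[a.outcome], t,
                                  seed=a_seed)
            bundles = [("", b)]
        elif a.kind == "bidirectional":
            fwd, rev = run_bidirectional(data[a.exposures[0]], data[a.outcome],
                                         t, seed=a_seed)
            bundles = [("forward", fwd), ("reverse", rev)]
        else:
            b = run_mvmr_analysis([data[e] for e in a.exposures],
                                  data[a.outcome], t, seed=a_seed)
            bundles = [("", b)]

        for tag, b in bundles:
            label = a.name + (f" ({tag})" if tag else "")
            if isinstance(b, SVMRBundle):
                all_results.extend(b.all_results())
                q = (b.results["ivw"].q_statistic, b.results["ivw"].q_df,
                     b.results["ivw"].q_p)
                eg = (b.results["egger"].intercept,
                      b.results["egger"].intercept_se,
                      b.results["egger"].intercept_p)
                row = {"analysis": label,
                       **diagnostic_report(q, eg, b.presso, b.steiger)}
                row.update({f"flag_{k}": v for k, v in
                            dataclasses.asdict(b.flags).items()})
                row["flag_overall"] = b.flags.overall
                diag_rows.append(row)
            else:
                all_results.extend(b.results + b.pruned_results)
                r0 = b.results[0]
                e0 = b.egger_results[0]
                diag_rows.append({
                    "analysis": label,
                    "Q": r0.q_statistic, "Q_df": r0.q_df, "Q_p": r0.q_p,
                    "egger_intercept": e0.intercept,
                    "egger_intercept_se": e0.intercept_se,
                    "egger_intercept_p": e0.intercept_p,
                    "presso_global_p": b.presso.global_p,
                    "n_outliers": len(b.presso.outliers),
                })
            safe = label.replace("/", "_").replace(" ", "_").replace(":", "_")
            b.harmonized.write_action_log(out_dir / f"actions_{safe}.tsv")
            meta["analyses"][label] = {"counts": b.counts, "seed": a_seed}

    _io.write_results_table(all_results, out_dir / "results.tsv")
    pd.DataFrame(diag_rows).to_csv(out_dir / "diagnostics.tsv", sep="\t",
                                   index=False)
    _io.write_run_metadata(meta, out_dir / "run_metadata.json")
    return meta
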
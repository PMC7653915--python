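import numpy as np
import pandas as pd
import pytest

from summr.datatypes import HarmonizedSet, SummaryStats


def _make_harmonized(bx, bx_se, by, by_se, rsids=None, n_x=None, n_y=None,
                     outcome_type="binary"):
    bx = np.atleast_2d(np.asarray(bx, float))
    if bx.shape[0] == 1:
        bx = bx.T
    bx_se = np.atleast_2d(np.asarray(bx_se, float))
    if bx_se.shape[0] == 1:
        bx_se = bx_se.T
    k, p = bx.shape
    if rsids is None:
        rsids = [f"rs{i + 1:04d}" for i in range(k)]
    return HarmonizedSet(
        rsids=list(rsids),
        exposure_names=[f"X{j + 1}" for j in range(p)],
        exposure_beta=bx, exposure_se=bx_se,
        outcome_beta=np.asarray(by, float), outcome_se=np.asarray(by_se, float),
        actions={r: "kept" for r in rsids},
        exposure_n=None if n_x is None else np.full((k, p), float(n_x)),
        outcome_n=None if n_y is None else np.full(k, float(n_y)),
        outcome_type=outcome_type,
    )


@pytest.fixture
def make_harmonized():
    """Factory for small hand-specified harmonized sets."""
    return _make_harmonized


def _make_stats(rows, name="trait", trait_type="continuous", **meta):
    """rows: list of dicts with at least rsid/effect_allele/other_allele/
    beta/se/pvalue."""
    tab = pd.DataFrame(rows)
    return SummaryStats(name, tab, trait_type, meta.get("unit", ""))


@pytest.fixture
def make_stats():
    return _make_stats


@pytest.fixture
def snp_row():
    """A well-formed association row; override fields as needed."""
    def _row(**kw):
        row = dict(rsid="rs1", effect_allele="A", other_allele="G", eaf=0.3,
                   beta=0.1, se=0.01, pvalue=1e-9, n=10_000.0)
        row.update(kw)
        return row
    return _row
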
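import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from summr.datatypes import InputError, SummaryStats
from summr.harmonize import harmonize_multi, harmonize_pair
from summr.simulate import MediationSpec, SimulationTruth, simulate_mediation_triplet


def _row(rsid, ea, oa, beta, eaf=0.3, se=0.01, pvalue=1e-9, n=1e5):
    return dict(rsid=rsid, effect_allele=ea, other_allele=oa, beta=beta,
                eaf=eaf, se=se, pvalue=pvalue, n=n)


class TestHarmonizePair:
    def test_swapped_alleles_flip_sign(self, make_stats):
        exp = make_stats([_row("rs1", "A", "G", 0.1)])
        out = make_stats([_row("rs1", "G", "A", -0.05, eaf=0.7)])
        h = harmonize_pair(exp, out)
        assert h.actions["rs1"] == "sign_flipped"
        assert np.isclose(h.by[0], 0.05)

    def test_palindromic_intermediate_af_dropped(self, make_stats):
        exp = make_stats([_row("rs1", "A", "T", 0.1, eaf=0.3)])
        out = make_stats([_row("rs1", "A", "T", 0.05, eaf=0.50)])
        h = harmonize_pair(exp, out)
        assert h.actions["rs1"] == "dropped:palindromic_intermediate_af"
        assert h.n_snps == 0

    def test_strand_complement_then_kept(self, make_stats):
        exp = make_stats([_row("rs1", "A", "G", 0.1, eaf=0.3)])
        out = make_stats([_row("rs1", "T", "C", 0.05, eaf=0.3)])
        h = harmonize_pair(exp, out)
        assert h.actions["rs1"] == "strand_complemented"
        assert np.isclose(h.by[0], 0.05)

    def test_palindrome_oriented_by_concordant_frequency(self, make_stats):
        exp = make_stats([_row("rs1", "A", "T", 0.1, eaf=0.2)])
        out = make_stats([_row("rs1", "A", "T", 0.05, eaf=0.25)])
        h = harmonize_pair(exp, out)
        assert h.actions["rs1"] == "kept"
        # discordant frequency: reported from the other strand
        out2 = make_stats([_row("rs1", "A", "T", 0.05, eaf=0.75)])
        h2 = harmonize_pair(exp, out2)
        assert h2.actions["rs1"] == "strand_complemented"
        assert np.isclose(h2.by[0], -0.05)

    def test_palindrome_with_missing_eaf_dropped(self, make_stats):
        exp = make_stats([_row("rs1", "A", "T", 0.1, eaf=0.2)])
        out = make_stats([_row("rs1", "A", "T", 0.05, eaf=np.nan)])
        h = harmonize_pair(exp, out)
        assert h.actions["rs1"] == "dropped:palindromic_intermediate_af"

    def test_allele_mismatch_dropped(self, make_stats):
        exp = make_stats([_row("rs1", "A", "G", 0.1)])
        out = make_stats([_row("rs1", "A", "C", 0.05)])
        assert harmonize_pair(exp, out).actions["rs1"] == "dropped:allele_mismatch"

    def test_missing_in_outcome_dropped(self, make_stats):
        exp = make_stats([_row("rs1", "A", "G", 0.1), _row("rs2", "A", "G", 0.1)])
        out = make_stats([_row("rs1", "A", "G", 0.05)])
        h = harmonize_pair(exp, out)
        assert h.actions["rs2"] == "dropped:missing_in_source"

    def test_empty_intersection_errors(self, make_stats):
        exp = make_stats([_row("rs1", "A", "G", 0.1)])
        out = make_stats([_row("rs2", "A", "G", 0.1)])
        with pytest.raises(InputError, match="shared"):
            harmonize_pair(exp, out)

    def test_conservation_of_counts(self, make_stats):
        exp = make_stats([_row(f"rs{i}", "A", "G", 0.1) for i in range(6)])
        out = make_stats([_row(f"rs{i}", "A", "G", 0.05) for i in range(4)]
                         + [_row("rs4", "A", "C", 0.05)])
        h = harmonize_pair(exp, out)
        counts = h.action_counts()
        assert sum(counts.values()) == len(exp)
        assert h.n_snps + sum(v for k, v in counts.items()
                              if k.startswith("dropped")) == len(exp)

    def test_idempotence(self, make_stats):
        exp = make_stats([_row("rs1", "A", "G", 0.1, eaf=0.3),
                          _row("rs2", "C", "T", -0.2, eaf=0.6),
                          _row("rs3", "A", "T", 0.15, eaf=0.2)])
        out = make_stats([_row("rs1", "G", "A", -0.05, eaf=0.7),
                          _row("rs2", "T", "C", 0.07, eaf=0.4),
                          _row("rs3", "T", "A", 0.04, eaf=0.81)])
        h1 = harmonize_pair(exp, out)
        # rebuild the outcome from the harmonized (aligned) records
        aligned = make_stats(
            [_row(r, exp.record(r).effect_allele, exp.record(r).other_allele,
                  float(h1.by[i]), eaf=float(h1.eaf[i]))
             for i, r in enumerate(h1.rsids)])
        h2 = harmonize_pair(exp.subset(h1.rsids), aligned)
        assert h2.rsids == h1.rsids
        np.testing.assert_allclose(h2.by, h1.by)
        assert all(h2.actions[r] == "kept" for r in h2.rsids)

    @given(flip=st.lists(st.booleans(), min_size=3, max_size=3))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_allele_flip_equivalence(self, flip):
        # swapping an outcome record's alleles while negating its beta and
        # mirroring its eaf is a pure re-encoding: harmonization output is
        # identical
        exp = SummaryStats("exp", __import__("pandas").DataFrame(
            [_row("rs1", "A", "G", 0.1, eaf=0.3),
             _row("rs2", "C", "T", -0.2, eaf=0.6),
             _row("rs3", "A", "T", 0.15, eaf=0.2)]))
        base = [_row("rs1", "A", "G", 0.05, eaf=0.3),
                _row("rs2", "C", "T", 0.07, eaf=0.6),
                _row("rs3", "A", "T", 0.04, eaf=0.19)]
        flipped = []
        for r, fl in zip(base, flip):
            r = dict(r)
            if fl:
                r["effect_allele"], r["other_allele"] = (r["other_allele"],
                                                         r["effect_allele"])
                r["beta"] = -r["beta"]
                r["eaf"] = 1 - r["eaf"]
            flipped.append(r)
        import pandas as pd

        h1 = harmonize_pair(exp, SummaryStats("out", pd.DataFrame(base)))
        h2 = harmonize_pair(exp, SummaryStats("out", pd.DataFrame(flipped)))
        assert h1.rsids == h2.rsids
        np.testing.assert_allclose(h1.by, h2.by)
        np.testing.assert_allclose(h1.eaf, h2.eaf)


class TestHarmonizeMulti:
    def test_union_row_count_no_palindromes(self, make_stats):
        e1 = make_stats([_row("rs1", "A", "G", 0.1), _row("rs2", "C", "T", 0.2)])
        e2 = make_stats([_row("rs1", "A", "G", 0.05), _row("rs2", "C", "T", 0.1)])
        out = make_stats([_row("rs1", "A", "G", 0.01), _row("rs2", "C", "T", 0.02)])
        h = harmonize_multi([e1, e2], out)
        assert h.n_snps == 2
        assert h.exposure_beta.shape == (2, 2)

    def test_missing_from_one_exposure_dropped(self, make_stats):
        e1 = make_stats([_row("rs1", "A", "G", 0.1), _row("rs2", "C", "T", 0.2)])
        e2 = make_stats([_row("rs1", "A", "G", 0.05)])
        out = make_stats([_row("rs1", "A", "G", 0.01), _row("rs2", "C", "T", 0.02)])
        h = harmonize_multi([e1, e2], out)
        assert h.actions["rs2"] == "dropped:missing_in_source"
        assert h.rsids == ["rs1"]

    def test_alignment_against_first_exposure(self, make_stats):
        e1 = make_stats([_row("rs1", "A", "G", 0.1)] * 1
                        + [_row("rs2", "C", "T", 0.2)])
        e2 = make_stats([_row("rs1", "G", "A", -0.05, eaf=0.7),
                         _row("rs2", "C", "T", 0.1)])
        out = make_stats([_row("rs1", "A", "G", 0.01),
                          _row("rs2", "T", "C", -0.02, eaf=0.7)])
        h = harmonize_multi([e1, e2], out)
        np.testing.assert_allclose(h.exposure_beta[:, 1], [0.05, 0.1])
        np.testing.assert_allclose(h.by, [0.01, 0.02])

    def test_requires_two_exposures(self, make_stats):
        e1 = make_stats([_row("rs1", "A", "G", 0.1)])
        with pytest.raises(InputError):
            harmonize_multi([e1], e1)

    def test_mediation_triplet_harmonizes_completely(self):
        t = SimulationTruth(m_snps=40, seed=4, palindromic_fraction=0.0,
                            mediation=MediationSpec())
        A, B, Y = simulate_mediation_triplet(t)
        h = harmonize_multi([A, B], Y)
        # simulator emits complete, consistently oriented files
        assert h.n_snps == 40
        assert all(a == "kept" for a in h.actions.values())


class TestHarmonizationFixture:
    """A crafted 10-SNP panel covering every harmonization path."""

    @pytest.fixture
    def panel(self, make_stats):
        exp = make_stats([
            _row("rs01", "A", "G", 0.10, eaf=0.30),   # identical -> kept
            _row("rs02", "C", "T", 0.12, eaf=0.60),   # swapped -> sign flip
            _row("rs03", "A", "G", 0.08, eaf=0.20),   # strand complement
            _row("rs04", "C", "T", 0.05, eaf=0.70),   # complement + swap
            _row("rs05", "A", "T", 0.07, eaf=0.20),   # palindrome, concordant
            _row("rs06", "C", "G", 0.06, eaf=0.50),   # palindrome, intermediate
            _row("rs07", "A", "T", 0.04, eaf=0.10),   # palindrome, outcome int.
            _row("rs08", "A", "G", 0.09, eaf=0.40),   # mismatched alleles
            _row("rs09", "G", "T", 0.11, eaf=0.55),   # missing in outcome
            _row("rs10", "A", "C", 0.03, eaf=0.25),   # identical -> kept
        ])
        out = make_stats([
            _row("rs01", "A", "G", 0.010, eaf=0.30),
            _row("rs02", "T", "C", -0.020, eaf=0.40),
            _row("rs03", "T", "C", 0.030, eaf=0.20),
            _row("rs04", "A", "G", -0.040, eaf=0.30),
            _row("rs05", "A", "T", 0.050, eaf=0.25),
            _row("rs06", "C", "G", 0.060, eaf=0.50),
            _row("rs07", "A", "T", 0.070, eaf=0.45),
            _row("rs08", "A", "C", 0.080, eaf=0.40),
            _row("rs10", "A", "C", 0.090, eaf=0.25),
        ])
        return exp, out

    def test_expected_per_reason_counts(self, panel):
        h = harmonize_pair(*panel)
        counts = h.action_counts()
        assert counts == {
            "kept": 3,                                   # rs01, rs05, rs10
            "sign_flipped": 1,                           # rs02
            "strand_complemented": 2,                    # rs03, rs04
            "dropped:palindromic_intermediate_af": 2,    # rs06, rs07
            "dropped:allele_mismatch": 1,                # rs08
            "dropped:missing_in_source": 1,              # rs09
        }
        np.testing.assert_allclose(
            h.by, [0.010, 0.020, 0.030, 0.040, 0.050, 0.090])

    def test_fixture_idempotent(self, panel, make_stats):
        exp, out = panel
        h1 = harmonize_pair(exp, out)
        aligned = make_stats(
            [_row(r, exp.record(r).effect_allele, exp.record(r).other_allele,
                  float(h1.by[i]), eaf=float(h1.eaf[i]))
             for i, r in enumerate(h1.rsids)])
        h2 = harmonize_pair(exp.subset(h1.rsids), aligned)
        assert h2.action_counts() == {"kept": h1.n_snps}
        np.testing.assert_allclose(h2.by, h1.by)
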
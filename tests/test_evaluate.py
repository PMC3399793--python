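"""Evaluation framework: deltas, ratios, strata, matrices, attenuation."""

import math

import numpy as np
import pytest

import grsim
from grsim import (
    delta_ld,
    delta_maf,
    median_delta_matrix,
    phi_dichotomized,
    sd_se_ratio,
    stratified_deltas,
)
from grsim.evaluate import DeltaSummary
from grsim.ld import se_dprime

from conftest import panel_from_columns


def panel_with_counts(counts, n=100):
    """Panel whose sites have the given allele-1 counts out of n."""
    cols = [[1] * c + [0] * (n - c) for c in counts]
    return panel_from_columns(cols)


def pair_panel(n, n11, n1, n2):
    """Two-site panel with n11 joint carriers and n1/n2 marginal counts."""
    a = [1] * n11 + [1] * (n1 - n11) + [0] * (n - n1)
    b = [1] * n11 + [0] * (n1 - n11) + [1] * (n2 - n11) + [0] * (n - n1 - n2 + n11)
    return panel_from_columns([a, b])


class TestDeltaSummary:
    def test_quantiles_match_sort_oracle(self):
        """Summary quantiles agree with manual type-7 interpolation on the
        sorted sample."""
        rng = np.random.default_rng(21)
        v = rng.normal(size=37)
        s = DeltaSummary.from_values(v)
        srt = np.sort(v)

        def q7(p):
            h = (len(srt) - 1) * p
            lo = int(math.floor(h))
            return srt[lo] + (h - lo) * (srt[min(lo + 1, len(srt) - 1)] - srt[lo])

        assert s.q1 == pytest.approx(q7(0.25), abs=1e-12)
        assert s.median == pytest.approx(q7(0.5), abs=1e-12)
        assert s.q3 == pytest.approx(q7(0.75), abs=1e-12)
        assert s.sd == pytest.approx(np.std(v, ddof=1), abs=1e-12)
        assert s.min <= s.q1 <= s.median <= s.q3 <= s.max


class TestDeltaMaf:
    def test_identical_replicates_zero(self, small_panel):
        res = delta_maf(small_panel, [small_panel] * 4)
        assert (res.deltas == 0).all()
        assert res.summary.sd == 0.0 and res.summary.mean == 0.0

    def test_hand_enumeration(self):
        """2 sites x 2 replicates with MAFs {0.30->0.25, 0.10->0.10} and
        {0.30->0.35, 0.10->0.12}: deltas {-0.05, 0, 0.05, 0.02}."""
        original = panel_with_counts([30, 10])
        rep1 = panel_with_counts([25, 10])
        rep2 = panel_with_counts([35, 12])
        res = delta_maf(original, [rep1, rep2])
        assert sorted(res.deltas) == pytest.approx([-0.05, 0.0, 0.02, 0.05])
        assert res.summary.mean == pytest.approx(0.005)

    def test_alignment_error(self, small_panel):
        other = small_panel.subset_sites(range(small_panel.n_sites - 1))
        with pytest.raises(ValueError, match="site list"):
            delta_maf(small_panel, [other])


class TestDeltaLd:
    def test_identical_replicates_zero(self, small_panel):
        for measure in ("Dprime", "r2"):
            res = delta_ld(small_panel, [small_panel] * 3, measure)
            assert (res.deltas == 0).all()

    def test_hand_ld_computation(self):
        """Original pair at D' = 1, replicate at D' = 0.9: delta = -0.1."""
        original = pair_panel(40, 10, 20, 10)   # p11 = p_b -> D' = 1
        replicate = pair_panel(40, 19, 20, 20)  # D = .475-.25, Dmax = .25
        assert grsim.pair_ld(original, 0, 1).Dprime == 1.0
        assert grsim.pair_ld(replicate, 0, 1).Dprime == pytest.approx(0.9)
        res = delta_ld(original, [replicate], "Dprime")
        assert res.deltas == pytest.approx([-0.1])

    def test_monoallelic_pair_counting(self):
        """A replicate with one monoallelic site among 3 sites contributes
        only the 1 unaffected pair; N = 3 (R - 1) + 1."""
        rng = np.random.default_rng(4)
        original = panel_from_columns(rng.integers(0, 2, (3, 20)))
        mono = original.alleles.copy()
        mono[2] = 0
        bad_rep = original.with_alleles(mono)
        R = 4
        res = delta_ld(original, [original] * (R - 1) + [bad_rep], "Dprime")
        assert res.summary.n == 3 * (R - 1) + 1


class TestSdSeRatio:
    def test_identical_replicates_zero_ratio(self, small_panel):
        for measure in ("Dprime", "r"):
            rs = sd_se_ratio(small_panel, [small_panel] * 3, measure)
            assert rs.median == 0.0 and rs.q1 == 0.0 and rs.q3 == 0.0

    def test_hand_arithmetic(self):
        """Pair with replicate D' values {0.5, 0.7}: ratio = SD / SE =
        0.1414.. / se_dprime(original)."""
        original = pair_panel(40, 16, 20, 20)   # D' = 0.6, SE defined
        rep1 = pair_panel(40, 15, 20, 20)       # D' = 0.5
        rep2 = pair_panel(40, 17, 20, 20)       # D' = 0.7
        assert grsim.pair_ld(rep1, 0, 1).Dprime == pytest.approx(0.5)
        assert grsim.pair_ld(rep2, 0, 1).Dprime == pytest.approx(0.7)
        rs = sd_se_ratio(original, [rep1, rep2], "Dprime")
        expected_sd = np.std([0.5, 0.7], ddof=1)
        assert expected_sd == pytest.approx(0.1414, abs=2e-4)
        assert rs.median == pytest.approx(
            expected_sd / se_dprime(original, 0, 1)
        )

    def test_undefined_se_excluded_and_counted(self):
        """|D'| = 1 pairs have no asymptotic SE and are excluded from the
        D' ratio summary but counted."""
        original = pair_panel(40, 10, 20, 10)  # D' = 1 -> SE undefined
        rep = pair_panel(40, 12, 20, 12)
        rs = sd_se_ratio(original, [rep, rep], "Dprime")
        assert rs.n_pairs == 0 and rs.n_excluded == 1

    def test_needs_two_replicates(self, small_panel):
        with pytest.raises(ValueError, match="two replicates"):
            sd_se_ratio(small_panel, [small_panel])


class TestStratified:
    def test_all_original_bins_zero(self, small_panel):
        rep = stratified_deltas(small_panel, [small_panel] * 2, "r2")
        for s in (*rep.ld_bins.values(), *rep.maf_bins.values()):
            assert s.n == 0 or (s.mean == 0.0 and s.sd == 0.0)

    def test_binning_keyed_by_original(self):
        """A pair with original D' = 0.85 lands in the >= 0.8 stratum no
        matter what the replicates show."""
        n = 400
        original = pair_panel(n, 188, 200, 200)
        dp0 = grsim.pair_ld(original, 0, 1).Dprime
        assert dp0 == pytest.approx(0.88)
        weak = pair_panel(n, 104, 200, 200)  # D' = 0.04
        rep = stratified_deltas(original, [weak], "Dprime")
        high = rep.ld_bins[">=0.8"]
        assert high.n == 1
        assert high.mean == pytest.approx(
            grsim.pair_ld(weak, 0, 1).Dprime - dp0
        )
        assert rep.ld_bins["<=0.2"].n == 0

    def test_maf_bins_require_both_sites(self):
        """MAF strata include a pair only when BOTH sites fall in the bin."""
        original = panel_with_counts([5, 20, 40])  # mafs .05, .20, .40
        rep = stratified_deltas(original, [original], "r2")
        assert rep.maf_bins["<=0.1"].n == 0  # only one rare site
        assert rep.maf_bins["0.1-0.3"].n == 0
        assert rep.maf_bins[">=0.3"].n == 0


class TestMedianDeltaMatrix:
    def test_identical_replicates_zero_matrix(self, small_panel):
        med = median_delta_matrix(small_panel, [small_panel] * 3, "Dprime")
        iu, ju = np.triu_indices(small_panel.n_sites, k=1)
        assert np.nanmax(np.abs(med[iu, ju])) == 0.0

    def test_hand_median(self):
        """Replicate D' values {0.8, 0.9, 1.0} against original 1.0 give a
        median delta of -0.1, symmetrically placed."""
        n = 40
        original = pair_panel(n, 10, 20, 10)
        reps = [
            pair_panel(n, 18, 20, 20),  # D' = 0.8
            pair_panel(n, 19, 20, 20),  # D' = 0.9
            pair_panel(n, 20, 20, 20),  # D' = 1.0
        ]
        med = median_delta_matrix(original, reps, "Dprime")
        assert med[0, 1] == pytest.approx(-0.1)
        assert med[0, 1] == med[1, 0]

    def test_symmetry_random(self, small_panel, gr_mini):
        panel, gmap = gr_mini
        reps = [
            grsim.simulate_resample(
                panel, gmap, grsim.ResampleConfig(n_haplotypes_out=100, seed=s)
            )
            for s in range(3)
        ]
        med = median_delta_matrix(panel, reps, "r2")
        assert np.array_equal(med, med.T, equal_nan=True)


class TestPhiDichotomized:
    def test_zero_rho(self):
        assert phi_dichotomized(0.0, 0.7, -1.1) == pytest.approx(0.0, abs=1e-14)

    def test_sheppard_closed_form(self):
        assert phi_dichotomized(0.5, 0.0, 0.0) == pytest.approx(
            1.0 / 3.0, abs=1e-12
        )

    def test_monte_carlo_oracle_unequal_cuts(self):
        """rho = 0.9 with cuts (0, 1.5) against a 10^7-draw simulation."""
        rho, c1, c2 = 0.9, 0.0, 1.5
        rng = np.random.default_rng(12)
        total = 10_000_000
        chunk = 1_000_000
        s11 = s1 = s2 = 0
        for _ in range(total // chunk):
            x = rng.standard_normal(chunk)
            y = rho * x + math.sqrt(1 - rho**2) * rng.standard_normal(chunk)
            a = x <= c1
            b = y <= c2
            s11 += int((a & b).sum())
            s1 += int(a.sum())
            s2 += int(b.sum())
        p1, p2, p11 = s1 / total, s2 / total, s11 / total
        mc_phi = (p11 - p1 * p2) / math.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
        se = 3.0 / math.sqrt(total)
        assert phi_dichotomized(rho, c1, c2) == pytest.approx(mc_phi, abs=3 * se)

    def test_odd_and_monotone_in_rho(self):
        vals = [phi_dichotomized(r, 0.0, 0.0) for r in np.arange(-0.9, 0.95, 0.1)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        for r in (0.2, 0.5, 0.8):
            assert phi_dichotomized(-r, 0.0, 0.0) == pytest.approx(
                -phi_dichotomized(r, 0.0, 0.0), abs=1e-12
            )

    def test_domain_error(self):
        with pytest.raises(ValueError):
            phi_dichotomized(1.0, 0.0, 0.0)
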
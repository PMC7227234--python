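"""ancestry: Weir-Cockerham FST, AIM selection, admixture EM, f4/f4n."""

import numpy as np
import pytest

from ovipop.ancestry import (
    FstRule,
    admixture_em,
    f4_stat,
    f4n_profile,
    fst_overall,
    fst_per_snp,
    jackknife_sd,
    select_aims,
)
from ovipop.distances import FreqTable, pool_freqs
from ovipop.simulate import PopSpec, SimConfig, simulate_annotated


def _ft(pops, freqs, counts=None):
    freqs = np.asarray(freqs, dtype=float)
    if counts is None:
        counts = np.full(freqs.shape, 100, dtype=int)
    n = freqs.shape[1]
    return FreqTable(pops, [f"snp{i}" for i in range(n)], freqs, counts)


def _wc_oracle(p1, n1_dip, p2, n2_dip):
    """Independently coded textbook two-population Weir-Cockerham FST
    (alleles as sampling units), scalar arithmetic throughout."""
    n1, n2 = 2 * n1_dip, 2 * n2_dip
    r = 2
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
    a = (nbar / nc) * (
        s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r) / (nbar - 1)
    )
    b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r)
    return a / (a + b)


class TestWeirCockerham:
    def test_equal_frequencies_nonpositive(self):
        ft = _ft(["A", "B"], [[0.4, 0.25], [0.4, 0.25]])
        fst = fst_per_snp(ft, "A", "B")
        assert (fst <= 0).all()

    def test_fixed_difference_approaches_one(self):
        ft = _ft(["A", "B"], [[1.0], [0.0]],
                 counts=np.array([[20000], [20000]]))
        fst = fst_per_snp(ft, "A", "B")
        assert fst[0] == pytest.approx(1.0, abs=1e-3)

    def test_matches_independent_oracle(self, rng):
        p1 = rng.uniform(0.02, 0.98, 200)
        p2 = rng.uniform(0.02, 0.98, 200)
        n1 = rng.integers(10, 80, 200)
        n2 = rng.integers(10, 80, 200)
        ft = _ft(["A", "B"], np.array([p1, p2]),
                 counts=np.array([2 * n1, 2 * n2]))
        fst = fst_per_snp(ft, "A", "B")
        oracle = np.array(
            [_wc_oracle(p1[j], n1[j], p2[j], n2[j]) for j in range(200)]
        )
        np.testing.assert_allclose(fst, oracle, atol=1e-10)

    def test_ungenotyped_population_propagates_missing(self):
        ft = _ft(["A", "B"], [[0.5, np.nan], [0.2, 0.3]],
                 counts=np.array([[40, 0], [40, 40]]))
        fst = fst_per_snp(ft, "A", "B")
        assert np.isnan(fst[1]) and not np.isnan(fst[0])

    def test_balding_nichols_pair_tracks_expectation(self):
        """Two populations at drift F from a shared ancestor: the
        multi-locus Weir-Cockerham estimate (ratio of summed variance
        components) is unbiased for the pairwise coancestry, which under
        independent drift equals F."""
        f = 0.1
        cfg = SimConfig(
            populations=[
                PopSpec("ROOT"),
                PopSpec("A", parent="ROOT", fst=f, n=50),
                PopSpec("B", parent="ROOT", fst=f, n=50),
            ],
            n_snps=20_000,
            seed=42,
        )
        ann, _ = simulate_annotated(cfg)
        ft = pool_freqs(ann)
        assert fst_overall(ft, "A", "B") == pytest.approx(f, abs=0.02)


class TestSelectAims:
    def _three_pop_ft(self, rng, n=200):
        f = rng.uniform(0.1, 0.9, (3, n))
        return _ft(["AMF", "mEMF", "PRMS"], f)

    def test_paper_style_thresholds_pass_and_fail(self):
        # one SNP passing all three clauses, one failing the "< 0.1" clause
        ft = _ft(
            ["AMF", "mEMF", "PRMS"],
            [[0.95, 0.9], [0.05, 0.05], [0.06, 0.45]],
        )
        rules = [
            FstRule("AMF", "PRMS", ">", 0.5),
            FstRule("mEMF", "AMF", ">", 0.5),
            FstRule("mEMF", "PRMS", "<", 0.1),
        ]
        panel = select_aims(ft, rules, name="AMF")
        assert panel.snp_ids == ["snp0"]

    def test_count_floor_excludes_undersampled_snp(self):
        counts = np.full((2, 2), 84)
        counts[0, 1] = 80  # below the ">40 of 42" floor
        ft = _ft(["AMF", "PRMS"], [[0.95, 0.95], [0.05, 0.05]], counts)
        panel = select_aims(
            ft, [FstRule("AMF", "PRMS", ">", 0.5)], count_floors={"AMF": 82}
        )
        assert panel.snp_ids == ["snp0"]

    def test_unknown_population_rejected(self, rng):
        ft = self._three_pop_ft(rng)
        with pytest.raises(ValueError, match="unknown population"):
            select_aims(ft, [FstRule("AMF", "nope", ">", 0.5)])

    def test_implanted_markers_recovered_exactly(self, rng):
        """50 engineered source-specific SNPs among 5000 neutral ones are
        selected exactly, verified against a brute-force evaluation."""
        n = 5050
        base = rng.uniform(0.3, 0.7, n)
        f_amf = base.copy()
        f_memf = base + rng.normal(0, 0.02, n)
        f_prms = base + rng.normal(0, 0.02, n)
        implant = rng.choice(n, 50, replace=False)
        f_amf[implant] = 0.97
        f_memf[implant] = 0.03
        f_prms[implant] = 0.05
        freqs = np.clip(np.array([f_amf, f_memf, f_prms]), 0.01, 0.99)
        ft = _ft(["AMF", "mEMF", "PRMS"], freqs)
        rules = [
            FstRule("AMF", "PRMS", ">", 0.5),
            FstRule("mEMF", "AMF", ">", 0.5),
            FstRule("mEMF", "PRMS", "<", 0.1),
        ]
        panel = select_aims(ft, rules, name="AMF")

        brute = []
        for j in range(n):
            ok = True
            for rule in rules:
                i_a = ft.pops.index(rule.pop_a)
                i_b = ft.pops.index(rule.pop_b)
                v = _wc_oracle(freqs[i_a, j], 25, freqs[i_b, j], 25)
                ok &= (v > rule.threshold) if rule.op == ">" else (v < rule.threshold)
            if ok:
                brute.append(f"snp{j}")
        assert panel.snp_ids == brute
        assert set(panel.snp_ids) == {f"snp{j}" for j in implant}

    def test_relaxing_thresholds_never_shrinks_panel(self, rng):
        ft = self._three_pop_ft(rng, n=500)
        strict = select_aims(ft, [FstRule("AMF", "PRMS", ">", 0.3)])
        relaxed = select_aims(ft, [FstRule("AMF", "PRMS", ">", 0.2)])
        assert set(strict.snp_ids) <= set(relaxed.snp_ids)


def _reference_ann(seed=3, fst=0.1, n_snps=2000, with_f1=True):
    pops = [
        PopSpec("ROOT"),
        PopSpec("A", parent="ROOT", fst=fst, n=20),
        PopSpec("B", parent="ROOT", fst=fst, n=20),
    ]
    if with_f1:
        pops.append(PopSpec("F1", admix={"A": 0.5, "B": 0.5}, n=10))
    return simulate_annotated(SimConfig(populations=pops, n_snps=n_snps, seed=seed))


class TestAdmixtureEM:
    def test_supervised_recovers_pure_and_hybrid(self):
        ann, _ = _reference_ann()
        refs = {
            s: b for s, b in zip(ann.gm.samples, ann.breeds()) if b in ("A", "B")
        }
        qm = admixture_em(ann.gm, k=2, mode="supervised",
                          reference_assignments=refs, seed=1)
        qf = qm.to_frame()
        pure = qf.loc[[s for s in qf.index if s.startswith("A_")], "A"]
        hyb = qf.loc[[s for s in qf.index if s.startswith("F1_")], "A"]
        assert (pure >= 0.95).all()
        assert hyb.mean() == pytest.approx(0.5, abs=0.05)

    def test_loglik_monotone_nondecreasing(self):
        ann, _ = _reference_ann(seed=5, n_snps=800)
        qm = admixture_em(ann.gm, k=2, mode="unsupervised", seed=2,
                          max_iter=300, n_starts=2)
        trace = np.array(qm.loglik_trace)
        assert (np.diff(trace) >= -1e-6 * np.abs(trace[:-1])).all()
        assert (np.abs(qm.q.sum(axis=1) - 1) < 1e-6).all()

    def test_identical_clusters_flagged_degenerate(self):
        ann, _ = _reference_ann(seed=7, fst=0.0, n_snps=500, with_f1=False)
        refs = {
            s: b for s, b in zip(ann.gm.samples, ann.breeds()) if b in ("A", "B")
        }
        qm = admixture_em(ann.gm, k=2, mode="supervised",
                          reference_assignments=refs, seed=3, max_iter=50)
        assert qm.degenerate

    def test_unsupervised_separates_populations(self):
        ann, _ = _reference_ann(seed=9, n_snps=1000, with_f1=False)
        qm = admixture_em(ann.gm, k=2, mode="unsupervised", seed=4,
                          max_iter=300, n_starts=2)
        qf = qm.to_frame()
        a_major = qf.iloc[:20, 0].mean()
        b_major = qf.iloc[20:, 0].mean()
        assert abs(a_major - b_major) > 0.8  # clusters align with populations


class TestF4:
    def test_equal_sources_give_zero(self):
        ft = _ft(["s1", "s2", "r", "x"],
                 [[0.3, 0.6], [0.3, 0.6], [0.2, 0.8], [0.9, 0.1]])
        assert f4_stat(ft, "s1", "s2", "r", "x") == 0.0

    def test_x_equals_ref_gives_zero(self):
        ft = _ft(["s1", "s2", "r"],
                 [[0.3, 0.6], [0.8, 0.1], [0.2, 0.8]])
        assert f4_stat(ft, "s1", "s2", "r", "r") == 0.0

    def test_single_snp_arithmetic(self):
        ft = _ft(["s1", "s2", "r", "x"], [[0.9], [0.1], [0.8], [0.2]])
        assert f4_stat(ft, "s1", "s2", "r", "x") == pytest.approx(0.48)

    def test_antisymmetry(self, rng):
        f = rng.uniform(0.05, 0.95, (4, 300))
        ft = _ft(["s1", "s2", "r", "x"], f)
        base = f4_stat(ft, "s1", "s2", "r", "x")
        assert f4_stat(ft, "s2", "s1", "r", "x") == pytest.approx(-base)
        assert f4_stat(ft, "s1", "s2", "x", "r") == pytest.approx(-base)


class TestF4n:
    def _cline_ft(self, alpha, seed=1, n_snps=5000):
        pops = [
            PopSpec("WILD", fst=0.1),
            PopSpec("AMF", parent="WILD", fst=0.12, n=25),
            PopSpec("EMF", parent="WILD", fst=0.12, n=25),
            PopSpec("DOM", fst=0.05),
            PopSpec("PRMS", parent="DOM", fst=0.05, n=25),
            PopSpec("BKG", parent="DOM", fst=0.05),
        ]
        if alpha == 0:
            pops.append(PopSpec("X", parent="BKG", fst=0.0, n=25))
        else:
            pops.append(PopSpec("X", admix={"BKG": 1 - alpha, "EMF": alpha}, n=25))
        ann, _ = simulate_annotated(
            SimConfig(populations=pops, n_snps=n_snps, seed=seed)
        )
        return pool_freqs(ann)

    def test_source_scores_one_and_ref_scores_zero(self):
        ft = self._cline_ft(0.2, seed=2, n_snps=1000)
        res = {r.test_pop: r for r in
               f4n_profile(ft, "AMF", "EMF", "PRMS", ["EMF", "PRMS"], n_blocks=20)}
        assert res["EMF"].f4n == 1.0
        assert res["PRMS"].f4n == 0.0

    def test_recovers_admixture_fraction(self):
        ft = self._cline_ft(0.30, seed=3)
        (res,) = f4n_profile(ft, "AMF", "EMF", "PRMS", ["X"], n_blocks=50)
        assert res.f4n == pytest.approx(0.30, abs=0.07)
        assert res.ci_low <= res.f4n <= res.ci_high

    def test_linear_in_admixture_proportion(self):
        from scipy.stats import linregress

        alphas = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5]
        est = []
        for i, a in enumerate(alphas):
            ft = self._cline_ft(a, seed=100 + i, n_snps=4000)
            (res,) = f4n_profile(ft, "AMF", "EMF", "PRMS", ["X"], n_blocks=40)
            est.append(res.f4n)
        fit = linregress(alphas, est)
        assert fit.slope == pytest.approx(1.0, abs=0.1)
        assert fit.intercept == pytest.approx(0.0, abs=0.03)

    def test_undifferentiated_sources_rejected(self):
        ft = _ft(["s1", "s2", "r", "x"],
                 [[0.3, 0.6], [0.3, 0.6], [0.2, 0.8], [0.9, 0.1]])
        with pytest.raises(ValueError, match="not differentiated"):
            f4n_profile(ft, "s1", "s2", "r", ["x"], n_blocks=10)


class TestJackknife:
    def test_constant_contributions_zero_sd(self):
        num = np.full(1000, 0.3)
        den = np.full(1000, 0.6)
        assert jackknife_sd(num, den, n_blocks=100) == 0.0

    def test_too_many_blocks_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            jackknife_sd(np.ones(50), np.ones(50), n_blocks=100)

    def test_matches_naive_delete_block_computation(self, rng):
        num = rng.normal(0.1, 0.3, 500)
        den = rng.normal(0.5, 0.1, 500)
        nb = 20
        sd = jackknife_sd(num, den, n_blocks=nb)
        bounds = np.linspace(0, 500, nb + 1).astype(int)
        thetas = []
        for b in range(nb):
            keep = np.ones(500, dtype=bool)
            keep[bounds[b]:bounds[b + 1]] = False
            thetas.append(num[keep].sum() / den[keep].sum())
        thetas = np.array(thetas)
        expect = np.sqrt((nb - 1) / nb * ((thetas - thetas.mean()) ** 2).sum())
        assert sd == pytest.approx(expect, rel=1e-12)
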
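import numpy as np
import pytest
from dataclasses import replace

from coloctools import (
    coloc_abf,
    coloc_signals,
    conditional_summary,
    label_comparison,
    mask_log_abf,
    stepwise_signals,
)
from coloctools import simulate as sim
from coloctools.sumstats import LDMatrix, RegionSummary
from conftest import pick_independent_pair


def sim_with_ld(panel, truth, N=5000, seed=0):
    d1, d2, tr, (G1, Y1), (G2, Y2) = sim.simulate_trait_pair(
        panel, N, N, truth, seed=seed, return_genotypes=True
    )
    ld1 = sim.genotype_ld(G1, panel.snp_ids)
    ld2 = sim.genotype_ld(G2, panel.snp_ids)
    return d1, d2, ld1, ld2, (G1, Y1), (G2, Y2)


class TestConditionalSummary:
    def test_orthogonal_conditioning_snp_leaves_betas(self, panel):
        """Conditioning on an LD-independent SNP does not move other effects."""
        rng = np.random.default_rng(21)
        a, b = pick_independent_pair(panel, rng)
        truth = sim.SimTruth("custom", causal1=[a], beta1=[1.0])
        d1, _, ld1, _, _, _ = sim_with_ld(panel, truth, seed=22)
        # make b exactly orthogonal to everything in the LD matrix
        idx = {s: i for i, s in enumerate(ld1.snp_ids)}
        r = ld1.r.copy()
        r[idx[b], :] = 0.0
        r[:, idx[b]] = 0.0
        r[idx[b], idx[b]] = 1.0
        ld_orth = LDMatrix(ld1.snp_ids, r)
        out = conditional_summary(d1, ld_orth, [b])
        keep = [s for s in d1.snp_ids if s != b]
        base = d1.subset(keep)
        np.testing.assert_allclose(out.beta, base.beta, atol=1e-10)
        # varbeta shifts only at O(1/N) via the joint-fit residual df
        np.testing.assert_allclose(out.varbeta, base.varbeta, rtol=5e-3)

    def test_agrees_with_exact_joint_regression(self, panel):
        """Summary-level conditioning reproduces the joint least-squares fit
        of each target SNP plus the conditioning SNP on raw genotypes."""
        rng = np.random.default_rng(23)
        a, b = pick_independent_pair(panel, rng)
        truth = sim.SimTruth("custom", causal1=[a, b], beta1=[1.0, 0.5])
        d1, _, ld1, _, (G1, Y1), _ = sim_with_ld(panel, truth, seed=24)
        out = conditional_summary(d1, ld1, [a])
        ja = list(panel.snp_ids).index(a)
        N = G1.shape[0]
        idx_out = {s: i for i, s in enumerate(out.snp_ids)}
        r2_to_a = ld1.r2()[ja]
        worst = 0.0
        for s in out.snp_ids[::5]:
            j = list(panel.snp_ids).index(s)
            if r2_to_a[j] >= 0.9:
                continue
            X = np.column_stack([np.ones(N), G1[:, j], G1[:, ja]])
            coef, *_ = np.linalg.lstsq(X, Y1, rcond=None)
            rss = Y1 @ Y1 - coef @ (X.T @ Y1)
            cov = rss / (N - 3) * np.linalg.inv(X.T @ X)
            k = idx_out[s]
            worst = max(worst, abs(out.beta[k] - coef[1]) / np.sqrt(cov[1, 1]))
            assert out.varbeta[k] == pytest.approx(cov[1, 1], rel=1e-6)
        assert worst < 1e-8

    def test_collinear_conditioning_set_rejected(self, panel, panel_ld):
        # two SNPs from the same block with r2 >= 0.9 if available, else build one
        r2 = panel_ld.r2()
        iu = np.triu_indices(panel_ld.nsnps, k=1)
        k = int(np.argmax(r2[iu]))
        a = str(panel_ld.snp_ids[iu[0][k]])
        b = str(panel_ld.snp_ids[iu[1][k]])
        r = panel_ld.r.copy()
        ia, ib = iu[0][k], iu[1][k]
        r[ia, ib] = r[ib, ia] = 0.99
        ld = LDMatrix(panel_ld.snp_ids, r)
        d = RegionSummary(
            panel.snp_ids,
            beta=np.zeros(panel.nsnps),
            varbeta=np.full(panel.nsnps, 1e-3),
            maf=np.maximum(panel.maf, 0.01),
            n_samples=1000,
            sd_trait=1.0,
        )
        with pytest.raises(ValueError, match=f"{a}|{b}"):
            conditional_summary(d, ld, [a, b])

    def test_unsigned_input_refused(self, panel, panel_ld):
        d = RegionSummary(
            panel.snp_ids,
            beta=np.zeros(panel.nsnps),
            varbeta=np.full(panel.nsnps, 1e-3),
            n_samples=1000,
            signed=False,
        )
        with pytest.raises(ValueError, match="unsigned|signed"):
            conditional_summary(d, panel_ld, [str(panel.snp_ids[0])])

    def test_collinear_targets_zeroed(self, panel):
        rng = np.random.default_rng(25)
        a, _ = pick_independent_pair(panel, rng)
        truth = sim.SimTruth("custom", causal1=[a], beta1=[1.0])
        d1, _, ld1, _, _, _ = sim_with_ld(panel, truth, seed=26)
        out = conditional_summary(d1, ld1, [a])
        ja = list(ld1.snp_ids).index(a)
        r2 = ld1.r2()[ja]
        idx_out = {s: i for i, s in enumerate(out.snp_ids)}
        hits = [s for s in out.snp_ids if r2[list(ld1.snp_ids).index(s)] >= 0.9]
        for s in hits:
            assert out.beta[idx_out[s]] == 0.0


class TestStepwise:
    def test_no_signal_empty(self, panel, panel_ld):
        d1, _, _ = sim.simulate_trait_pair(panel, 2000, 2000, sim.SimTruth("H0"), seed=30)
        sig = stepwise_signals(d1, panel_ld, "mask")
        assert len(sig) == 0

    def test_single_causal_single_lead(self, panel):
        rng = np.random.default_rng(31)
        a, _ = pick_independent_pair(panel, rng)
        truth = sim.SimTruth("custom", causal1=[a], beta1=[1.0])
        d1, _, ld1, _, _, _ = sim_with_ld(panel, truth, seed=32)
        for method in ("mask", "cond"):
            sig = stepwise_signals(d1, ld1, method)
            assert len(sig) == 1
            # the lead is the most significant SNP
            assert sig.lead_ids[0] == str(d1.snp_ids[int(np.argmax(np.abs(d1.z)))])

    @pytest.mark.parametrize("method", ["mask", "cond"])
    def test_two_independent_causals_two_leads(self, panel, method):
        rng = np.random.default_rng(33)
        a, b = pick_independent_pair(panel, rng)
        truth = sim.SimTruth("custom", causal1=[a, b], beta1=[1.0, 0.8])
        d1, _, ld1, _, _, _ = sim_with_ld(panel, truth, seed=34)
        sig = stepwise_signals(d1, ld1, method)
        assert len(sig) == 2
        idx = {s: i for i, s in enumerate(ld1.snp_ids)}
        r2 = ld1.r2()
        tags = set()
        for lead in sig.lead_ids:
            vals = {c: r2[idx[lead], idx[c]] for c in (a, b)}
            best = max(vals, key=vals.get)
            assert vals[best] > 0.8
            tags.add(best)
        assert tags == {a, b}

    def test_max_signals_cap(self, panel):
        rng = np.random.default_rng(35)
        a, b = pick_independent_pair(panel, rng)
        truth = sim.SimTruth("custom", causal1=[a, b], beta1=[1.0, 0.8])
        d1, _, ld1, _, _, _ = sim_with_ld(panel, truth, seed=36)
        sig = stepwise_signals(d1, ld1, "mask", max_signals=1)
        assert len(sig) == 1

    def test_mask_leads_mutually_independent(self, panel):
        rng = np.random.default_rng(37)
        a, b = pick_independent_pair(panel, rng)
        truth = sim.SimTruth("custom", causal1=[a, b], beta1=[1.2, 1.0])
        d1, _, ld1, _, _, _ = sim_with_ld(panel, truth, seed=38)
        sig = stepwise_signals(d1, ld1, "mask", r2_threshold=0.01)
        idx = {s: i for i, s in enumerate(ld1.snp_ids)}
        for i, x in enumerate(sig.lead_ids):
            for y in sig.lead_ids[i + 1:]:
                assert ld1.r2()[idx[x], idx[y]] < 0.01


class TestMasking:
    def test_empty_mask_is_identity(self, panel_ld):
        labf = np.linspace(-1, 5, panel_ld.nsnps)
        np.testing.assert_array_equal(mask_log_abf(labf, panel_ld, []), labf)

    def test_mask_everything_zeroes_vector(self, panel_ld):
        labf = np.linspace(-1, 5, panel_ld.nsnps)
        out = mask_log_abf(labf, panel_ld, list(panel_ld.snp_ids), r2_threshold=0.0)
        np.testing.assert_array_equal(out, np.zeros_like(labf))

    def test_minimal_mask_zeroes_only_lead(self, panel_ld):
        # orthogonalise one SNP so only itself is within r2 of the mask
        idx = 7
        r = panel_ld.r.copy()
        r[idx, :] = 0.0
        r[:, idx] = 0.0
        r[idx, idx] = 1.0
        ld = LDMatrix(panel_ld.snp_ids, r)
        labf = np.ones(ld.nsnps)
        out = mask_log_abf(labf, ld, [str(ld.snp_ids[idx])], r2_threshold=0.01)
        assert out[idx] == 0.0
        assert (out[np.arange(ld.nsnps) != idx] == 1.0).all()

    def test_unknown_lead(self, panel_ld):
        with pytest.raises(KeyError):
            mask_log_abf(np.zeros(panel_ld.nsnps), panel_ld, ["nope"])


class TestColocSignals:
    def test_one_signal_each_equals_plain_coloc(self, panel):
        rng = np.random.default_rng(40)
        a, _ = pick_independent_pair(panel, rng)
        truth = sim.SimTruth("H4", causal1=[a], beta1=[1.0], causal2=[a], beta2=[1.0])
        d1, d2, ld1, ld2, _, _ = sim_with_ld(panel, truth, seed=41)
        rows = coloc_signals(d1, d2, ld1, ld2, "cond", "cond")
        assert len(rows) == 1
        plain = coloc_abf(d1, d2)
        np.testing.assert_allclose(rows[0].pp, plain.pp, atol=1e-12)

    def test_two_by_one_leads_two_rows(self, panel):
        rng = np.random.default_rng(42)
        a, b = pick_independent_pair(panel, rng)
        truth = sim.SimTruth(
            "custom", causal1=[a, b], beta1=[1.0, 0.8], causal2=[b], beta2=[1.0]
        )
        d1, d2, ld1, ld2, _, _ = sim_with_ld(panel, truth, seed=43)
        rows = coloc_signals(d1, d2, ld1, ld2, "cond", "cond")
        assert len(rows) == 2
        assert all(r.lead2 == rows[0].lead2 for r in rows)

    def test_secondary_shared_signal_found_by_cond_not_single(self, panel):
        """Trait 1 has causals {A (primary), B}; trait 2 has {B}.  A single
        comparison tracks A vs B (H3) and misses the shared secondary signal;
        conditioning adds a B-vs-B comparison with H4 maximal."""
        rng = np.random.default_rng(44)
        a, b = pick_independent_pair(panel, rng)
        truth = sim.SimTruth(
            "custom", causal1=[a, b], beta1=[1.0, 0.5], causal2=[b], beta2=[1.0]
        )
        d1, d2, ld1, ld2, _, _ = sim_with_ld(panel, truth, seed=45)
        single = coloc_signals(d1, d2, ld1, ld2, "single", "single")
        assert len(single) == 1
        assert single[0].pp[4] < 0.5
        cond = coloc_signals(d1, d2, ld1, ld2, "cond", "cond")
        labelled = {
            (
                label_comparison(r.lead1, r.lead2, [a, b], ld1).trait1_hit,
                label_comparison(r.lead1, r.lead2, [a, b], ld1).trait2_hit,
            ): r
            for r in cond
        }
        assert (b, b) in labelled
        assert labelled[(b, b)].best_hypothesis() == "H4"

    def test_hybrid_cond_mask(self, panel):
        rng = np.random.default_rng(46)
        a, b = pick_independent_pair(panel, rng)
        truth = sim.SimTruth(
            "custom", causal1=[a, b], beta1=[1.0, 0.5], causal2=[b], beta2=[1.0]
        )
        d1, d2, ld1, ld2, _, _ = sim_with_ld(panel, truth, seed=47)
        rows = coloc_signals(d1, d2, ld1, ld2, "cond", "mask")
        assert len(rows) >= 2
        assert any(r.best_hypothesis() == "H4" for r in rows)

    def test_cond_mode_requires_signed(self, panel, panel_ld):
        d = RegionSummary(
            panel.snp_ids,
            beta=np.abs(np.random.default_rng(0).normal(0, 0.2, panel.nsnps)),
            varbeta=np.full(panel.nsnps, 1e-3),
            n_samples=1000,
            signed=False,
        )
        with pytest.raises(ValueError, match="signed"):
            coloc_signals(d, d, panel_ld, panel_ld, "cond", "single")

    def test_mask_agrees_with_cond_when_causals_independent(self, panel):
        """With causal variants in linkage equilibrium, masking approximates
        conditioning: mean |Δ PP.H4| over matched comparisons stays < 0.1."""
        root = np.random.SeedSequence(48)
        diffs = []
        for ss in root.spawn(200):
            rng = np.random.default_rng(ss)
            a, b = pick_independent_pair(panel, rng)
            truth = sim.SimTruth(
                "custom", causal1=[a, b], beta1=[1.0, 0.6], causal2=[b], beta2=[1.0]
            )
            d1, d2, ld1, ld2, _, _ = sim_with_ld(
                panel, truth, N=2000, seed=ss.spawn(1)[0]
            )
            def labelled(rows):
                out = {}
                for r in rows:
                    lab = label_comparison(r.lead1, r.lead2, [a, b], ld1)
                    out[(lab.trait1_hit, lab.trait2_hit)] = float(r.pp[4])
                return out

            lc = labelled(coloc_signals(d1, d2, ld1, ld2, "cond", "cond"))
            lm = labelled(coloc_signals(d1, d2, ld1, ld2, "mask", "mask"))
            for key in set(lc) & set(lm):
                diffs.append(abs(lc[key] - lm[key]))
        assert len(diffs) > 100
        assert np.mean(diffs) < 0.1


class TestLabels:
    def test_tags_by_max_r2(self, panel, panel_ld):
        rng = np.random.default_rng(50)
        a, b = pick_independent_pair(panel, rng)
        lab = label_comparison(a, b, [a, b], panel_ld)
        assert lab.trait1_hit == a and lab.trait2_hit == b  # r2 = 1 with itself

    def test_question_mark_when_no_strong_ld(self, panel_ld):
        # find a SNP with r2 < 0.8 to a chosen causal
        r2 = panel_ld.r2()
        a = 0
        far = int(np.argmin(r2[a]))
        lab = label_comparison(
            panel_ld.snp_ids[far], panel_ld.snp_ids[a], [str(panel_ld.snp_ids[a])], panel_ld
        )
        assert lab.trait1_hit == "?"
        assert lab.trait2_hit == str(panel_ld.snp_ids[a])

    def test_unknown_ids(self, panel_ld):
        with pytest.raises(KeyError):
            label_comparison("nope", panel_ld.snp_ids[0], [panel_ld.snp_ids[1]], panel_ld)
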
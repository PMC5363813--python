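import numpy as np
import pandas as pd
import pytest

import stemdist as sd
from conftest import make_expr


def dv_from(values, sample_ids, label="hESC"):
    # the regression only sees centered distances, so shifting to >= 0 is free
    v = np.asarray(values, float)
    if v.min() < 0:
        v = v - v.min()
    return sd.DistanceVector(sample_ids, v, "euclidean", label, 10)


def cohort_distance(sim, mask_fraction=1.0):
    ref = sd.reference_centroid(sim.reference, "hESC")
    mask = sd.filter_by_retained_fraction(sim.cohort.expression, mask_fraction)
    return sd.stem_cell_distances(sim.cohort.expression, ref, mask, "pearson")


class TestPerGeneAssociation:
    def test_perfect_fit_gene(self, rng):
        d = np.array([1.0, 2, 3, 4, 5])
        x = (d - d.mean()) / d.std(ddof=1)  # standardized copy of the distances
        em = make_expr(np.vstack([x, rng.normal(size=5)]))
        out = sd.per_gene_association(em, dv_from(d, em.sample_ids), "c0")
        row = out[out.gene_id == "g0"].iloc[0]
        assert row.beta == pytest.approx(d.std(ddof=1), abs=1e-10)
        assert row.se == pytest.approx(0.0, abs=1e-6)

    def test_closed_form_least_squares(self):
        x = np.array([-1.2649110640673518, -0.6324555320336759, 0.0,
                      0.6324555320336759, 1.2649110640673518])
        d = np.array([1.0, 2, 3, 4, 5])
        em = make_expr(x[None, :] * 2 + 7)  # affine copy; standardization undoes it
        out = sd.per_gene_association(em, dv_from(d, em.sample_ids), "c0")
        beta_oracle = np.sum(x * (d - d.mean())) / np.sum(x * x)
        assert out.iloc[0].beta == pytest.approx(beta_oracle, abs=1e-10)

    def test_null_gene_rarely_significant(self):
        # |beta/se| is t-distributed under the null: P(|t| < 2) ~ 0.95 at 198 df
        n_rep = 100
        hits = 0
        for seed in range(n_rep):
            rng = np.random.default_rng(500 + seed)
            em = make_expr(rng.normal(size=(1, 200)))
            d = rng.normal(size=200)
            out = sd.per_gene_association(em, dv_from(d, em.sample_ids), "c0")
            hits += abs(out.iloc[0].beta / out.iloc[0].se) < 2
        assert hits >= 0.9 * n_rep

    def test_zero_variance_genes_excluded(self, rng):
        em = make_expr(np.vstack([np.full(6, 3.0), rng.normal(size=6)]))
        out = sd.per_gene_association(em, dv_from(rng.normal(size=6), em.sample_ids), "c0")
        assert list(out.gene_id) == ["g1"]

    def test_too_few_samples_error(self, rng):
        em = make_expr(rng.normal(size=(2, 3)))
        with pytest.raises(ValueError, match="4 samples"):
            sd.per_gene_association(em, dv_from(np.arange(3.0), em.sample_ids), "c0")


class TestPooling:
    def _assoc(self, genes, betas, ses, cohort):
        return pd.DataFrame(
            {"gene_id": genes, "cohort": cohort, "beta": betas, "se": ses, "n": 10}
        )

    def test_single_cohort_identity(self):
        a = self._assoc(["g1", "g2"], [0.5, -1.0], [0.1, 0.2], "c0")
        out = sd.pool_fixed_effects([a]).set_index("gene_id")
        assert out.loc["g1", "pooled_beta"] == pytest.approx(0.5)
        assert out.loc["g2", "pooled_se"] == pytest.approx(0.2)

    def test_equal_se_pooling_is_mean_and_sqrt2(self):
        a = self._assoc(["g"], [1.0], [0.3], "c0")
        b = self._assoc(["g"], [2.0], [0.3], "c1")
        out = sd.pool_fixed_effects([a, b]).iloc[0]
        assert out.pooled_beta == pytest.approx(1.5)
        assert out.pooled_se == pytest.approx(0.3 / np.sqrt(2))

    def test_hand_computed_inverse_variance_weights(self):
        a = self._assoc(["g"], [1.0], [0.1], "c0")
        b = self._assoc(["g"], [3.0], [1.0], "c1")
        out = sd.pool_fixed_effects([a, b]).iloc[0]
        assert out.pooled_beta == pytest.approx((100 * 1 + 1 * 3) / 101.0, abs=1e-9)

    def test_k_identical_cohorts_shrink_se(self):
        frames = [self._assoc(["g"], [0.7], [0.25], f"c{k}") for k in range(4)]
        out = sd.pool_fixed_effects(frames).iloc[0]
        assert out.pooled_beta == pytest.approx(0.7)
        assert out.pooled_se == pytest.approx(0.25 / 2.0)

    def test_strict_mode_drops_incomplete_genes(self):
        a = self._assoc(["g1", "g2"], [1.0, 1.0], [0.1, 0.1], "c0")
        b = self._assoc(["g1"], [2.0], [0.1], "c1")
        strict = sd.pool_fixed_effects([a, b], strict=True)
        loose = sd.pool_fixed_effects([a, b], strict=False)
        assert list(strict.gene_id) == ["g1"]
        assert set(loose.gene_id) == {"g1", "g2"}

    def test_nonpositive_se_errors(self):
        a = self._assoc(["g"], [1.0], [0.0], "c0")
        with pytest.raises(ValueError, match="standard error"):
            sd.pool_fixed_effects([a])


class TestBuildSignature:
    def _pooled(self, n, rng):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "pooled_beta": rng.normal(size=n),
                "pooled_se": rng.uniform(0.05, 0.2, n),
            }
        ).assign(z=lambda df: df.pooled_beta / df.pooled_se)

    def test_k_all_is_reordering(self, rng):
        pooled = self._pooled(20, rng)
        sig = sd.build_signature(pooled, 20, "hESC")
        assert set(sig.entries.gene_id) == set(pooled.gene_id)
        az = sig.entries.z.abs().to_numpy()
        assert (az[:-1] >= az[1:]).all()

    def test_k1_picks_max_abs_z(self, rng):
        pooled = self._pooled(15, rng)
        sig = sd.build_signature(pooled, 1, "hESC")
        assert sig.entries.iloc[0].gene_id == pooled.loc[pooled.z.abs().idxmax(), "gene_id"]

    def test_k_too_large_errors(self, rng):
        with pytest.raises(ValueError, match="only"):
            sd.build_signature(self._pooled(5, rng), 6, "hESC")

    def test_round_trip(self, tmp_path, rng):
        sig = sd.build_signature(self._pooled(10, rng), 5, "hESC")
        sig.write(tmp_path / "sig.tsv")
        back = sd.read_signature(tmp_path / "sig.tsv", "hESC")
        pd.testing.assert_frame_equal(
            back.entries[["gene_id", "pooled_beta", "z"]],
            sig.entries[["gene_id", "pooled_beta", "z"]],
        )


class TestRiskScore:
    def _sig(self, genes, betas):
        df = pd.DataFrame(
            {"gene_id": genes, "pooled_beta": betas, "pooled_se": 0.1}
        ).assign(z=lambda d: d.pooled_beta / d.pooled_se, rank=np.arange(1, len(genes) + 1))
        return sd.Signature(df, "hESC")

    def test_single_gene_score_is_standardized_expression(self, rng):
        em = make_expr(rng.normal(size=(3, 8)))
        sig = self._sig(["g1"], [1.0])
        x = em.values[1]
        expected = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(sd.signature_risk_score(em, sig), expected, atol=1e-10)

    def test_negating_weights_negates_scores(self, rng):
        em = make_expr(rng.normal(size=(4, 10)))
        genes = ["g0", "g2", "g3"]
        betas = [0.5, -1.0, 2.0]
        s1 = sd.signature_risk_score(em, self._sig(genes, betas))
        s2 = sd.signature_risk_score(em, self._sig(genes, [-b for b in betas]))
        np.testing.assert_allclose(s2, -s1, atol=1e-10)

    def test_gene_order_invariance(self, rng):
        em = make_expr(rng.normal(size=(5, 12)))
        s1 = sd.signature_risk_score(em, self._sig(["g0", "g3"], [1.0, -2.0]))
        s2 = sd.signature_risk_score(em, self._sig(["g3", "g0"], [-2.0, 1.0]))
        np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_missing_genes_dropped_with_warning(self, rng):
        em = make_expr(rng.normal(size=(2, 6)))
        sig = self._sig(["g0", "nope"], [1.0, 5.0])
        with pytest.warns(UserWarning, match="absent"):
            sd.signature_risk_score(em, sig)

    def test_no_overlap_errors(self, rng):
        em = make_expr(rng.normal(size=(2, 6)))
        with pytest.raises(ValueError, match="no signature gene"):
            sd.signature_risk_score(em, self._sig(["x", "y"], [1.0, 1.0]))

    def test_score_tracks_distance_on_planted_cohort(self, default_sim):
        dv = cohort_distance(default_sim)
        assoc = sd.per_gene_association(default_sim.cohort.expression, dv, "c0")
        pooled = sd.pool_fixed_effects([assoc])
        n_planted = int(default_sim.truth.diff_flags.sum())
        sig = sd.build_signature(pooled, n_planted, "hESC")
        scores = sd.signature_risk_score(default_sim.cohort.expression, sig, top_k=n_planted)
        r = np.corrcoef(scores, dv.distances)[0, 1]
        assert r >= 0.9


class TestMultiCohortRecovery:
    def test_planted_genes_recovered_in_top_ranks(self):
        cfg = sd.SyntheticConfig(
            n_genes=2000, frac_diff_genes=0.025, fixed_effect_magnitude=True, seed=0
        )
        sims = sd.simulate_multi_cohort(cfg, n_cohorts=4, seed=31)
        truth_genes = {
            sims[0].cohort.expression.gene_ids[i]
            for i in np.flatnonzero(sims[0].truth.diff_flags)
        }
        assocs = []
        for sim in sims:
            mask = sd.FilterMask(
                [sim.cohort.expression.gene_ids[i]
                 for i in np.flatnonzero(sim.truth.diff_flags)],
                c=0.0, retained_fraction=cfg.frac_diff_genes,
            )
            ref = sd.reference_centroid(sim.reference, "hESC")
            dv = sd.stem_cell_distances(sim.cohort.expression, ref, mask, "pearson")
            assocs.append(sd.per_gene_association(sim.cohort.expression, dv, sim.cohort.name))
        pooled = sd.pool_fixed_effects(assocs)
        sig = sd.build_signature(pooled, 50, "hESC")
        assert len(truth_genes & set(sig.entries.gene_id)) >= 45
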
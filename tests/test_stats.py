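import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from smdiv.stats import (
    DEFAULT_PAIRING,
    bray_curtis,
    bray_curtis_matrix,
    correlate_differential,
    fit_differential,
    nmds,
    shepard_correlation,
)


class TestBrayCurtis:
    def test_identical_nonzero_vectors(self):
        assert bray_curtis([3, 1, 2], [3, 1, 2]) == 0.0

    def test_disjoint_supports(self):
        assert bray_curtis([5, 0, 0], [0, 2, 1]) == 1.0

    def test_hand_worked_example(self):
        assert bray_curtis([1, 1, 0], [0, 1, 1]) == pytest.approx(0.5)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    def test_semimetric_properties(self, rng):
        for _ in range(50):
            x = rng.integers(0, 10, size=8)
            y = rng.integers(0, 10, size=8)
            if x.sum() == 0 or y.sum() == 0:
                continue
            d = bray_curtis(x, y)
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(bray_curtis(y, x))


class TestNmds:
    def line_dissimilarity(self, n=8):
        x = np.arange(n, dtype=float)[:, None]
        return np.abs(x - x.T)

    def test_monotone_line_embeds_with_negligible_stress(self):
        res = nmds(self.line_dissimilarity(), seed=0)
        assert res.stress < 1e-3
        # rank-preserving, not linear: the line may bend, so only a strong
        # (not perfect) Shepard correlation is guaranteed
        assert res.shepard_r > 0.95

    def test_duplicate_samples_coincide(self):
        base = self.line_dissimilarity(5)
        idx = [0, 1, 2, 3, 4, 0]  # sample 0 duplicated
        D = base[np.ix_(idx, idx)]
        res = nmds(D, seed=0)
        a, b = res.coordinates.iloc[0], res.coordinates.iloc[-1]
        span = np.linalg.norm(np.ptp(res.coordinates.values, axis=0))
        assert np.linalg.norm(a - b) < 0.05 * span

    def test_seeded_determinism(self, rng):
        D = rng.random((6, 6))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0)
        r1 = nmds(D, seed=3)
        r2 = nmds(D, seed=3)
        assert r1.stress == r2.stress
        assert np.allclose(r1.coordinates, r2.coordinates)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            nmds(np.zeros((2, 2)))


class TestShepard:
    def test_perfect_embedding_correlates_one(self):
        X = np.array([[0.0, 0], [1, 0], [3, 0]])
        D = np.abs(X[:, 0][:, None] - X[:, 0][None, :])
        assert shepard_correlation(D, X) == pytest.approx(1.0)

    def test_anti_ordered_configuration_negative(self):
        # dissimilarities reversed relative to the embedded distances
        X = np.array([[0.0, 0], [1, 0], [3, 0]])
        D = np.array([[0, 3.0, 1.0], [3.0, 0, 2.0], [1.0, 2.0, 0]])
        assert shepard_correlation(D, X) < 0

    def test_bounded(self, rng):
        for _ in range(20):
            X = rng.random((5, 2))
            D = rng.random((5, 5))
            D = (D + D.T) / 2
            np.fill_diagonal(D, 0)
            assert -1.0 <= shepard_correlation(D, X) <= 1.0


def nb_counts(rng, mu, alpha, size):
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + mu), size=size)


class TestFitDifferential:
    def metadata(self, reps=3):
        rows = []
        for site in ("P1", "P2", "P3"):
            for stage in ("emergence", "senescence"):
                for k in range(1, reps + 1):
                    rows.append(
                        {"sample_id": f"{site}_{stage[:3]}_{k}", "site": site,
                         "stage": stage, "replicate": k}
                    )
        return pd.DataFrame(rows)

    def test_single_level_factor_rejected(self, rng):
        meta = self.metadata().assign(stage="emergence")
        meta["sample_id"] = [f"s{i}" for i in range(len(meta))]
        table = pd.DataFrame(
            nb_counts(rng, 30.0, 0.4, (4, len(meta))),
            index=[f"o{i}" for i in range(4)],
            columns=meta["sample_id"],
        )
        with pytest.raises(ValueError, match="single level"):
            fit_differential(table, meta, ("stage",), n_boot=9, seed=0)

    def test_matches_statsmodels_nb_glm_at_fixed_dispersion(self, rng):
        """Our batched IRLS agrees with statsmodels GLM (NB family with the
        same dispersion) on coefficients and log-likelihood."""
        from smdiv.stats import _design, _estimate_alpha, _irls_nb

        meta = self.metadata()
        y = nb_counts(rng, 40.0, 0.5, len(meta)).astype(float)
        X, _ = _design(meta, ("site", "stage"))
        alpha = _estimate_alpha(X, y[:, None])
        beta, ll, conv = _irls_nb(X, y[:, None], alpha)
        ref = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=float(alpha[0]))
        ).fit()
        assert conv[0]
        assert np.allclose(beta[:, 0], ref.params, atol=1e-5)
        assert ll[0] == pytest.approx(ref.llf, abs=1e-4)

    def test_dispersion_close_to_statsmodels_ml(self, rng):
        from smdiv.stats import _design, _estimate_alpha

        meta = self.metadata(reps=5)
        y = nb_counts(rng, 60.0, 0.7, len(meta)).astype(float)
        X, _ = _design(meta, ("site",))
        alpha = _estimate_alpha(X, y[:, None])[0]
        ref = sm.NegativeBinomial(y, X).fit(disp=0, maxiter=200)
        assert alpha == pytest.approx(ref.params[-1], rel=0.15, abs=0.05)

    def test_planted_stage_effect_ranks_high(self, rng):
        """OTUs with a planted 4-fold stage effect are enriched among the
        smallest p-values (AUC > 0.8 against the planted truth)."""
        meta = self.metadata()
        stage_vec = (meta["stage"] == "senescence").to_numpy(float)
        m = 20
        truth = np.zeros(m, dtype=bool)
        truth[: m // 5] = True  # 20% of OTUs shifted 4-fold
        Y = np.empty((m, len(meta)))
        for j in range(m):
            mu = 40.0 * (4.0 ** (stage_vec * truth[j]))
            Y[j] = nb_counts(rng, mu, 0.3, len(meta))
        table = pd.DataFrame(Y.astype(int), index=[f"o{j}" for j in range(m)],
                             columns=meta["sample_id"])
        res = fit_differential(table, meta, ("site", "stage"), n_boot=99, seed=2)
        p = res.per_otu["p_stage"].to_numpy()
        from scipy.stats import rankdata

        ranks = rankdata(-p)  # small p -> high rank
        auc = (ranks[truth].sum() - truth.sum() * (truth.sum() + 1) / 2) / (
            truth.sum() * (~truth).sum()
        )
        assert auc > 0.8
        assert res.multivariate["stage"]["p"] <= 0.05

    def test_bootstrap_p_in_unit_interval_and_deterministic(self, rng):
        meta = self.metadata(reps=2)
        table = pd.DataFrame(
            nb_counts(rng, 30.0, 0.4, (4, len(meta))),
            index=[f"o{i}" for i in range(4)],
            columns=meta["sample_id"],
        )
        r1 = fit_differential(table, meta, ("site", "stage"), n_boot=49, seed=7)
        r2 = fit_differential(table, meta, ("site", "stage"), n_boot=49, seed=7)
        for f in ("site", "stage"):
            assert 0.0 < r1.multivariate[f]["p"] <= 1.0
            assert r1.multivariate[f]["p"] == r2.multivariate[f]["p"]
        assert r1.fitted.shape == table.shape
        assert r1.residuals.shape == table.shape


class TestCorrelateDifferential:
    def build(self, rng, track=True):
        meta_samples = [f"s{i}" for i in range(9)]
        base = rng.integers(5, 50, size=9).astype(float)
        sm_table = pd.DataFrame(
            {s: [base[i], rng.integers(1, 40)] for i, s in enumerate(meta_samples)},
            index=["sm1", "sm2"],
        )
        marker_row = base if track else (base.max() + base.min() - base)
        marker_table = pd.DataFrame(
            {s: [marker_row[i], rng.integers(1, 40)] for i, s in enumerate(meta_samples)},
            index=["m1", "m2"],
        )
        tax = pd.DataFrame(
            {"otu": ["m1", "m2"], "phylum": ["Firmicutes", "Bacteroidetes"],
             "genus": ["Bacillus", "Flavobacterium"]}
        )

        class FakeResult:
            def __init__(self, idx):
                self.per_otu = pd.DataFrame({"p_site": [0.01] * len(idx)}, index=idx)

        return (
            FakeResult(sm_table.index), FakeResult(marker_table.index),
            sm_table, marker_table, tax,
        )

    def test_tracking_otu_gives_rho_one(self, rng):
        smr, mr, smt, mt, tax = self.build(rng, track=True)
        df = correlate_differential(smr, mr, smt, mt, tax, "ACP",
                                    min_genus_abundance=0.0)
        row = df[(df.marker_otu == "m1") & (df.sm_otu == "sm1")]
        assert row["rho"].iloc[0] == pytest.approx(1.0)

    def test_reversed_ranks_give_rho_minus_one(self, rng):
        smr, mr, smt, mt, tax = self.build(rng, track=False)
        df = correlate_differential(smr, mr, smt, mt, tax, "ACP",
                                    min_genus_abundance=0.0)
        row = df[(df.marker_otu == "m1") & (df.sm_otu == "sm1")]
        assert row["rho"].iloc[0] == pytest.approx(-1.0)

    def test_pairing_rule_excludes_disallowed_phylum(self, rng):
        smr, mr, smt, mt, tax = self.build(rng)
        df = correlate_differential(smr, mr, smt, mt, tax, "ACP",
                                    min_genus_abundance=0.0)
        # Bacteroidetes marker OTU m2 may not pair with ACP-derived genes
        assert "m2" not in set(df["marker_otu"])
        assert DEFAULT_PAIRING["ACP"] == {"Firmicutes"}

    def test_too_few_shared_samples_rejected(self, rng):
        smr, mr, smt, mt, tax = self.build(rng)
        with pytest.raises(ValueError, match="shared samples"):
            correlate_differential(smr, mr, smt.iloc[:, :2], mt.iloc[:, :2],
                                   tax, "ACP")


def test_bray_curtis_matrix_square_and_hollow(rng):
    table = pd.DataFrame(rng.integers(0, 20, size=(6, 4)),
                         columns=[f"s{i}" for i in range(4)])
    D = bray_curtis_matrix(table)
    assert np.allclose(D.values, D.values.T)
    assert np.allclose(np.diag(D.values), 0.0)
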
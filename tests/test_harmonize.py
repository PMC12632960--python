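"""ComBat correctness: closed forms, independent EB oracle, reference
implementation agreement, covariate preservation."""

import subprocess
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from reactage import harmonize as hz
from reactage import synthetic as syn
from reactage.features import FeatureTable


def _table(X, site, age=None, sex=None, meta=None):
    n, G = X.shape
    rng = np.random.default_rng(0)
    subjects = pd.Index([f"s{i}" for i in range(n)], name="subject")
    if meta is None:
        meta = syn.make_feature_meta(G)
    return FeatureTable(
        values=pd.DataFrame(X, index=subjects, columns=meta.index),
        feature_meta=meta,
        covariates=pd.DataFrame(
            {
                "age": rng.uniform(18, 90, n) if age is None else age,
                "sex": rng.integers(0, 2, n).astype(float) if sex is None else sex,
                "site": site,
            },
            index=subjects,
        ),
    )


# ---------------------------------------------------------------------------
# independent loop-based oracle for the location/scale EB model
# ---------------------------------------------------------------------------


def _eb_oracle(X, batch, cov, conv=1e-4):
    """Per-feature-loop reimplementation of ComBat with parametric EB."""
    levels = sorted(set(batch))
    n, G = X.shape
    D = np.zeros((n, len(levels) + cov.shape[1]))
    for i, lv in enumerate(levels):
        D[:, i] = batch == lv
    D[:, len(levels):] = cov
    B = np.linalg.solve(D.T @ D, D.T @ X)
    n_i = np.array([(batch == lv).sum() for lv in levels], dtype=float)
    grand = np.zeros(G)
    for i in range(len(levels)):
        grand += (n_i[i] / n) * B[i]
    resid = X - D @ B
    vp = np.array([np.mean(resid[:, g] ** 2) for g in range(G)])
    stand = grand + cov @ B[len(levels):]
    s = (X - stand) / np.sqrt(vp)

    g_star = np.zeros((len(levels), G))
    d_star = np.zeros((len(levels), G))
    for i, lv in enumerate(levels):
        si = s[batch == lv]
        g_hat = np.array([si[:, g].mean() for g in range(G)])
        d_hat = np.array([si[:, g].var(ddof=1) for g in range(G)])
        g_bar, t2 = g_hat.mean(), g_hat.var(ddof=1)
        m, s2 = d_hat.mean(), d_hat.var(ddof=1)
        a = (2 * s2 + m**2) / s2
        b = (m * s2 + m**3) / s2
        nb = si.shape[0]
        g_old, d_old = g_hat.copy(), d_hat.copy()
        change = 1.0
        while change > conv:
            g_new = np.empty(G)
            d_new = np.empty(G)
            for g in range(G):
                g_new[g] = (t2 * nb * g_hat[g] + d_old[g] * g_bar) / (t2 * nb + d_old[g])
                sum2 = ((si[:, g] - g_new[g]) ** 2).sum()
                d_new[g] = (0.5 * sum2 + b) / (nb / 2 + a - 1)
            change = max(
                np.max(np.abs(g_new - g_old) / g_old),
                np.max(np.abs(d_new - d_old) / d_old),
            )
            g_old, d_old = g_new, d_new
        g_star[i], d_star[i] = g_old, d_old

    adj = s.copy()
    for i, lv in enumerate(levels):
        rows = batch == lv
        adj[rows] = (adj[rows] - g_star[i]) / np.sqrt(d_star[i])
    return g_star, d_star, adj * np.sqrt(vp) + stand


def _planted_cohort(seed, G=240, n_per=30, shift_sd=0.3, shift_mean=1.5):
    rng = np.random.default_rng(seed)
    shift_b = rng.normal(shift_mean, shift_sd, G)
    cfg = syn.SimulationConfig(
        sites=(("a", n_per), ("b", n_per)),
        beta_age=0.0,
        beta_sex=0.0,
        site_shift={"a": 0.0, "b": shift_b},
        site_scale={"a": 1.0, "b": 1.0},
        noise_sd=1.0,
        seed=seed,
    )
    table, truth = syn.make_cohort(cfg, syn.make_feature_meta(G))
    return table, shift_b


class TestPartitionSubgroups:
    def test_transporter_by_parcel_set_gives_27_groups(self):
        meta = syn.make_feature_meta(270)  # cycles 3 blocks x 9 parcel sets
        assert hz.partition_subgroups(meta).nunique() == 27

    def test_identical_metadata_gives_one_group(self):
        meta = pd.DataFrame(
            {"block": "DAT", "group": "Vis", "nature": "connectivity"},
            index=pd.Index([f"f{i}" for i in range(5)], name="feature"),
        )
        assert hz.partition_subgroups(meta).nunique() == 1

    def test_structural_groups_follow_declared_file_nature_pairs(self):
        meta = syn.make_structural_block(4, seed=0).feature_meta
        expected = meta.groupby(["group", "nature"]).ngroups
        assert hz.partition_subgroups(meta).nunique() == expected == 12

    def test_unknown_block_is_an_error(self):
        meta = pd.DataFrame(
            {"block": "XXX", "group": "g", "nature": None},
            index=pd.Index(["f0"], name="feature"),
        )
        with pytest.raises(ValueError, match="unknown block"):
            hz.partition_subgroups(meta)


class TestCombatClosedForms:
    def test_single_batch_is_identity(self):
        rng = np.random.default_rng(1)
        table = _table(rng.standard_normal((20, 6)), site=["only"] * 20)
        model = hz.fit_combat(table, eb=False)
        adj = hz.apply_combat(model, table)
        assert np.abs(adj.values.to_numpy() - table.values.to_numpy()).max() <= 1e-10

    def test_pure_mean_shift_equalized_to_pooled_mean(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 8))
        X[30:] += 3.0
        site = np.array(["a"] * 30 + ["b"] * 30)
        table = _table(X, site=site)
        model = hz.fit_combat(table, covariate_keys=(), eb=False)
        adj = hz.apply_combat(model, table).values.to_numpy()
        pooled = adj.mean(axis=0)
        assert np.abs(adj[:30].mean(axis=0) - pooled).max() <= 1e-10
        assert np.abs(adj[30:].mean(axis=0) - pooled).max() <= 1e-10

    def test_no_eb_no_covariates_moments_equalized(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((90, 10))
        X[:40] = X[:40] * 1.8 + 2.0
        site = np.array(["a"] * 40 + ["b"] * 50)
        table = _table(X, site=site)
        model = hz.fit_combat(table, covariate_keys=(), eb=False)
        adj = hz.apply_combat(model, table).values.to_numpy()
        pooled_mean = adj.mean(axis=0)
        for rows in (slice(0, 40), slice(40, 90)):
            assert np.abs(adj[rows].mean(axis=0) - pooled_mean).max() <= 1e-8
            assert np.abs(adj[rows].var(axis=0, ddof=1) - model.var_pooled).max() <= 1e-8

    def test_refit_after_adjustment_finds_no_location_effect(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((80, 6))
        X[40:] = X[40:] * 1.5 + 2.5
        site = np.array(["a"] * 40 + ["b"] * 40)
        adj = hz.apply_combat(
            hz.fit_combat(_table(X, site=site), covariate_keys=(), eb=False),
            _table(X, site=site),
        )
        refit = hz.fit_combat(adj, covariate_keys=(), eb=False)
        assert np.abs(refit.gamma_star).max() <= 1e-8
        # scale effects are equalized across batches exactly
        assert np.abs(refit.delta_star_sq[0] - refit.delta_star_sq[1]).max() <= 1e-8

    def test_zero_within_batch_variance_is_an_error(self):
        X = np.random.default_rng(5).standard_normal((20, 3))
        X[:10, 0] = 7.0
        with pytest.raises(ValueError, match="zero within-batch variance"):
            hz.fit_combat(_table(X, site=["a"] * 10 + ["b"] * 10), covariate_keys=(), eb=False)

    def test_confounded_covariate_is_an_error(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((20, 3))
        site = ["a"] * 10 + ["b"] * 10
        sex = np.r_[np.zeros(10), np.ones(10)]  # identical to batch
        with pytest.raises(ValueError, match="confounded"):
            hz.fit_combat(_table(X, site=site, sex=sex), covariate_keys=("sex",), eb=False)


class TestEmpiricalBayes:
    def test_matches_independent_iterative_oracle(self):
        table, _ = _planted_cohort(seed=11)
        model = hz.fit_combat(table, eb=True)
        adj = hz.apply_combat(model, table)
        cov = table.covariates[["age", "sex"]].to_numpy(float)
        g_star, d_star, adj_oracle = _eb_oracle(
            table.values.to_numpy(), table.covariates["site"].to_numpy(), cov
        )
        assert np.abs(model.gamma_star - g_star).max() <= 1e-6
        assert np.abs(model.delta_star_sq - d_star).max() <= 1e-6
        assert np.abs(adj.values.to_numpy() - adj_oracle).max() <= 1e-6

    def test_estimates_shrink_toward_subgroup_prior_mean(self):
        table, _ = _planted_cohort(seed=12)
        model = hz.fit_combat(table, eb=True)
        # recompute the raw per-feature estimates from the stored standardization
        X = table.values.to_numpy(float)
        cov = table.covariates[["age", "sex"]].to_numpy(float)
        s = (X - (model.grand_mean + cov @ model.beta)) / np.sqrt(model.var_pooled)
        site = table.covariates["site"].to_numpy()
        for i, lv in enumerate(model.batch_levels):
            g_hat = s[site == lv].mean(axis=0)
            g_bar = g_hat.mean()
            assert (np.abs(model.gamma_star[i] - g_bar) <= np.abs(g_hat - g_bar) + 1e-12).all()

    def test_matches_reference_combat_implementation(self, tmp_path):
        """Adjusted values agree with sva::ComBat (parametric EB) to 1e-6."""
        rng = np.random.default_rng(42)
        n, G = 40, 60
        site = np.array(["A"] * 20 + ["B"] * 20)
        age = rng.uniform(18, 90, n)
        sex = rng.integers(0, 2, n).astype(float)
        X = (
            rng.normal(0, 1, (n, G))
            + 0.05 * age[:, None]
            + (site == "B")[:, None] * rng.normal(1.0, 0.3, G)
        )
        table = _table(X, site=site, age=age, sex=sex)
        adj = hz.apply_combat(hz.fit_combat(table, eb=True), table)

        pd.DataFrame(X.T).to_csv(tmp_path / "dat.csv")
        (tmp_path / "batch.txt").write_text("\n".join(site))
        pd.DataFrame({"age": age, "sex": sex}).to_csv(tmp_path / "mod.csv")
        script = tmp_path / "combat.R"
        script.write_text(
            'suppressMessages(library(sva))\n'
            'args <- commandArgs(trailingOnly=TRUE)\n'
            'dat <- as.matrix(read.csv(file.path(args[1], "dat.csv"), row.names=1))\n'
            'batch <- scan(file.path(args[1], "batch.txt"), what=character(), quiet=TRUE)\n'
            'mod <- cbind(1, as.matrix(read.csv(file.path(args[1], "mod.csv"), row.names=1)))\n'
            'out <- ComBat(dat=dat, batch=batch, mod=mod, par.prior=TRUE)\n'
            'write.csv(out, file.path(args[1], "out.csv"))\n'
        )
        subprocess.run(
            ["Rscript", str(script), str(tmp_path)], check=True, capture_output=True
        )
        ref = pd.read_csv(tmp_path / "out.csv", index_col=0).to_numpy().T
        assert np.abs(adj.values.to_numpy() - ref).max() <= 1e-6

    def test_eb_beats_per_feature_estimates_when_favorable(self):
        """Small batches, many exchangeable features: EB shift estimates have
        lower RMSE against the planted batch shift than raw per-feature ones."""
        table, shift_b = _planted_cohort(seed=13, G=300, n_per=10)
        cbi = hz.fit_combat(table, eb=False)
        cbe = hz.fit_combat(table, eb=True)

        def est_shift(model):
            return (model.gamma_star[1] - model.gamma_star[0]) * np.sqrt(model.var_pooled)

        rmse_cbi = np.sqrt(np.mean((est_shift(cbi) - shift_b) ** 2))
        rmse_cbe = np.sqrt(np.mean((est_shift(cbe) - shift_b) ** 2))
        assert rmse_cbe < rmse_cbi


class TestHarmonizeStrategies:
    def test_none_is_bit_identical(self):
        table, _ = _planted_cohort(seed=14, G=12, n_per=10)
        out = hz.harmonize(table, "none")
        pd.testing.assert_frame_equal(out.values, table.values)

    def test_cbi_removes_planted_shift(self):
        table, _ = _planted_cohort(seed=15, G=20, n_per=50)
        out = hz.harmonize(table, "cbi")
        site = table.covariates["site"]
        gap = (
            out.values[site == "b"].mean(axis=0) - out.values[site == "a"].mean(axis=0)
        )
        raw_gap = (
            table.values[site == "b"].mean(axis=0)
            - table.values[site == "a"].mean(axis=0)
        )
        assert np.abs(gap).max() < 0.2 and np.abs(raw_gap).mean() > 1.0

    def test_cbe_preserves_column_order_and_is_order_invariant(self):
        table, _ = _planted_cohort(seed=16, G=54, n_per=20)
        out = hz.harmonize(table, "cbe")
        assert list(out.values.columns) == list(table.values.columns)
        perm = np.random.default_rng(0).permutation(table.n_features)
        shuffled = FeatureTable(
            table.values.iloc[:, perm],
            table.feature_meta.iloc[perm],
            table.covariates,
        )
        out_shuffled = hz.harmonize(shuffled, "cbe")
        pd.testing.assert_frame_equal(
            out_shuffled.values[out.values.columns], out.values
        )

    def test_age_slope_preserved_after_adjustment(self):
        cfg = syn.SimulationConfig(
            sites=(("a", 200), ("b", 200)),
            beta_age=0.5,
            site_shift={"a": 0.0, "b": 2.0},
            site_scale={"a": 1.0, "b": 1.5},
            noise_sd=1.0,
            seed=17,
        )
        table, _ = syn.make_cohort(cfg, syn.make_feature_meta(6))
        out = hz.harmonize(table, "cbi")
        age = table.covariates["age"].to_numpy()
        slope = np.polyfit(age, out.values.iloc[:, 0].to_numpy(), 1)[0]
        assert abs(slope - 0.5) <= 0.1

    def test_site_not_decodable_after_adjustment(self):
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import cross_val_score

        cfg = syn.SimulationConfig(
            sites=(("a", 200), ("b", 200)),
            beta_age=0.0,
            beta_sex=0.0,
            site_shift={"a": 0.0, "b": 1.0},
            site_scale={"a": 1.0, "b": 1.3},
            noise_sd=1.0,
            seed=18,
        )
        table, _ = syn.make_cohort(cfg, syn.make_feature_meta(20))
        out = hz.harmonize(table, "cbi")
        y = (table.covariates["site"] == "b").to_numpy()
        acc = cross_val_score(
            LogisticRegression(max_iter=2000), out.values.to_numpy(), y, cv=5
        ).mean()
        assert acc <= 0.55

    def test_unseen_batch_level_is_an_error(self):
        table, _ = _planted_cohort(seed=19, G=10, n_per=10)
        model = hz.fit_combat(table, eb=False)
        other = table.copy()
        other.covariates.loc[other.covariates.index[0], "site"] = "zz"
        with pytest.raises(ValueError, match="unseen"):
            hz.apply_combat(model, other)

    def test_model_json_roundtrip(self, tmp_path):
        table, _ = _planted_cohort(seed=20, G=10, n_per=10)
        model = hz.fit_combat(table, eb=False)
        hz.save_model(model, tmp_path / "m.json")
        back = hz.load_model(tmp_path / "m.json")
        adj1 = hz.apply_combat(model, table).values.to_numpy()
        adj2 = hz.apply_combat(back, table).values.to_numpy()
        assert np.allclose(adj1, adj2)
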
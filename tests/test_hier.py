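"""Hierarchical posterior: gradients, density composition, diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import revlearn as rl
from revlearn import _kernels
from revlearn.diagnostics import psis_loo, split_rhat
from revlearn.hier import CellPosterior, PriorSpec
from revlearn.models import negative_log_likelihood


def random_cell(rng, S=4, T=12):
    choices = rng.integers(0, 2, (S, T)).astype(np.int8)
    outcomes = rng.integers(0, 2, (S, T)).astype(np.int8)
    return choices, outcomes


class TestKernels:
    def test_rp_kernel_matches_reference_nll(self):
        rng = np.random.default_rng(1)
        choices, outcomes = random_cell(rng)
        ap, an = rng.random(4), rng.random(4)
        be = 5 * rng.random(4)
        nll, _ = _kernels.rp_nll_grad(choices, outcomes, ap, an, be, 0.5)
        for s in range(4):
            frame = pd.DataFrame(
                {"choice": np.where(choices[s] == 0, "A", "B"), "outcome": outcomes[s]}
            )
            ref = negative_log_likelihood(frame, rl.RLParams(ap[s], an[s], be[s]), "RP")
            assert nll[s] == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("model", ["RP", "EWA"])
    def test_kernel_gradients_match_finite_differences(self, model):
        rng = np.random.default_rng(2)
        choices, outcomes = random_cell(rng, S=3, T=15)
        theta = np.column_stack([0.2 + 0.6 * rng.random(3)] * 2 + [1 + 3 * rng.random(3)])
        kern = _kernels.rp_nll_grad if model == "RP" else _kernels.ewa_nll_grad
        nll0, grad = kern(choices, outcomes, theta[:, 0], theta[:, 1], theta[:, 2], 0.5)
        eps = 1e-6
        for k in range(3):
            bumped = theta.copy()
            bumped[:, k] += eps
            nll1, _ = kern(choices, outcomes, bumped[:, 0], bumped[:, 1], bumped[:, 2], 0.5)
            fd = (nll1 - nll0) / eps
            assert np.allclose(grad[:, k], fd, atol=1e-4)

    def test_ewa_kernel_matches_stepwise_update(self):
        # one subject, checked against the dataclass-level EWA recursion
        rng = np.random.default_rng(3)
        choices, outcomes = random_cell(rng, S=1, T=10)
        params = rl.RLParams(beta=2.0, phi=0.85, rho=0.7)
        nll = _kernels.ewa_nll(
            choices, outcomes, np.array([0.85]), np.array([0.7]), np.array([2.0]), 0.5
        )
        frame = pd.DataFrame(
            {"choice": np.where(choices[0] == 0, "A", "B"), "outcome": outcomes[0]}
        )
        ref = negative_log_likelihood(frame, params, "EWA")
        assert nll[0] == pytest.approx(ref, abs=1e-12)


class TestCellPosterior:
    def make_posterior(self, model="RP", S=4, T=12, seed=4):
        rng = np.random.default_rng(seed)
        choices, outcomes = random_cell(rng, S, T)
        return CellPosterior(choices=choices, outcomes=outcomes, model=model), rng

    @pytest.mark.parametrize("model", ["RP", "RW", "EWA"])
    def test_density_gradient_matches_finite_differences(self, model):
        post, rng = self.make_posterior(model)
        theta = 0.3 * rng.standard_normal(post.dim)
        lp0, grad = post.logp_grad(theta)
        eps = 1e-6
        for i in range(post.dim):
            t1 = theta.copy()
            t1[i] += eps
            fd = (post.logp(t1) - lp0) / eps
            assert grad[i] == pytest.approx(fd, abs=2e-4, rel=1e-3)

    def test_density_composes_prior_plus_subject_likelihoods(self):
        # brute-force composition: hyperpriors + z prior + sum of NLLs from
        # the reference likelihood path
        post, rng = self.make_posterior("RP")
        theta = 0.3 * rng.standard_normal(post.dim)
        mu, eta, z = post.unpack(theta)
        sigma = np.exp(eta)
        lp = sps.norm.logpdf(mu).sum() - 3 * math.log(math.sqrt(2 * math.pi))
        # half-normal kernel + jacobian, dropping constants as the class does
        lp = -0.5 * np.sum(mu**2)
        lp += np.sum(-0.5 * (sigma / 0.2) ** 2 + eta)
        lp += -0.5 * np.sum(z**2)
        nat = post.natives(theta)
        for s in range(post.S):
            frame = pd.DataFrame(
                {
                    "choice": np.where(post.choices[s] == 0, "A", "B"),
                    "outcome": post.outcomes[s],
                }
            )
            lp -= negative_log_likelihood(
                frame, rl.RLParams(nat[s, 0], nat[s, 1], nat[s, 2]), "RP"
            )
        assert post.logp(theta) == pytest.approx(lp, abs=1e-9)

    def test_natives_respect_ranges(self):
        post, rng = self.make_posterior("RP")
        for _ in range(20):
            nat = post.natives(2.0 * rng.standard_normal(post.dim))
            assert (nat[:, :2] >= 0).all() and (nat[:, :2] <= 1).all()
            assert (nat[:, 2] >= 0).all() and (nat[:, 2] <= 10).all()

    def test_single_subject_rejected(self):
        rng = np.random.default_rng(0)
        choices, outcomes = random_cell(rng, S=1)
        with pytest.raises(ValueError, match="2 subjects"):
            CellPosterior(choices=choices, outcomes=outcomes)


def rhat_oracle(draws):
    """Textbook split-R-hat, written independently of the package."""
    m, n = draws.shape
    half = n // 2
    chains = [draws[i, :half] for i in range(m)] + [draws[i, half : 2 * half] for i in range(m)]
    chains = np.asarray(chains)
    W = np.mean([c.var(ddof=1) for c in chains])
    means = chains.mean(axis=1)
    B = half * means.var(ddof=1)
    var_plus = (half - 1) / half * W + B / half
    return math.sqrt(var_plus / W)


class TestSplitRhat:
    def test_well_mixed_chains_near_one(self):
        rng = np.random.default_rng(5)
        draws = rng.standard_normal((4, 2000))
        assert split_rhat(draws) == pytest.approx(1.0, abs=0.02)

    def test_offset_chains_flagged(self):
        rng = np.random.default_rng(6)
        draws = rng.standard_normal((2, 500)) + np.array([[0.0], [10.0]])
        assert split_rhat(draws) > 1.1

    def test_matches_textbook_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            draws = rng.standard_normal((4, 100)) * rng.random() + rng.random()
            assert split_rhat(draws) == pytest.approx(rhat_oracle(draws), abs=1e-10)

    def test_matches_arviz_split_rhat(self):
        import arviz as az

        rng = np.random.default_rng(8)
        draws = rng.standard_normal((4, 200))
        ref = float(az.rhat(az.convert_to_dataset(draws), method="split")["x"].values)
        assert split_rhat(draws) == pytest.approx(ref, abs=1e-8)

    def test_constant_draws_return_sentinel(self):
        assert math.isnan(split_rhat(np.ones((2, 10))))

    def test_too_few_chains_rejected(self):
        with pytest.raises(ValueError, match="2 chains"):
            split_rhat(np.zeros((1, 10)))


class TestPsisLoo:
    def test_identical_matrices_tie(self):
        rng = np.random.default_rng(9)
        ll = -np.abs(rng.standard_normal((2, 100, 8))) - 1.0
        a = psis_loo(ll)
        b = psis_loo(ll.copy())
        assert a.looic == pytest.approx(b.looic, abs=1e-9)
        assert a.looic == pytest.approx(-2.0 * a.elpd_loo, abs=1e-9)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(10)
        ll = -np.abs(rng.standard_normal((2, 100, 8))) - 1.0
        perm = rng.permutation(8)
        assert psis_loo(ll).looic == pytest.approx(psis_loo(ll[:, :, perm]).looic, abs=1e-8)

    def test_degenerate_draw_count_rejected(self):
        with pytest.raises(ValueError, match="100"):
            psis_loo(-np.ones((1, 1, 5)))

    def test_nonfinite_rejected(self):
        ll = -np.ones((1, 200, 5))
        ll[0, 0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            psis_loo(ll)


class TestFit:
    def test_fixed_seed_fits_are_bit_identical(self, small_cell):
        cfg = rl.FitConfig(chains=2, warmup=60, draws=40, seed=3)
        a = rl.fit_hierarchical(small_cell, "RP", config=cfg)
        b = rl.fit_hierarchical(small_cell, "RP", config=cfg)
        assert np.array_equal(a.mu, b.mu)
        assert np.array_equal(a.subject_params, b.subject_params)

    def test_converged_small_fit(self, small_fit):
        assert small_fit.max_rhat(group_level_only=True) < 1.1

    def test_posterior_covers_generating_group_means(self, small_fit):
        # the small_cell fixture draws subjects around (0.35, 0.25, 4.0)
        iv = small_fit.group_native_interval()
        for name, true in [("alpha_pos", 0.35), ("alpha_neg", 0.25), ("beta", 4.0)]:
            lo, hi = iv[name]
            assert lo - 0.1 < true < hi + 0.1

    def test_equal_alpha_data_shows_overlapping_rates(self):
        rng = np.random.default_rng(20)
        rows = []
        for s in range(12):
            a = float(np.clip(rng.normal(0.4, 0.08), 0.05, 0.95))
            be = float(np.clip(rng.normal(3.5, 0.8), 0.5, 9))
            sched = rl.make_schedule(rl.stable_design(), seed=3000 + s)
            rows.append(
                rl.simulate_choices(
                    sched, rl.RLParams(a, a, be), "RP", seed=4000 + s,
                    subject=f"e{s}", group="OT", context="stable",
                )
            )
        data = pd.concat(rows, ignore_index=True)
        fit = rl.fit_hierarchical(
            data, "RP", config=rl.FitConfig(chains=2, warmup=300, draws=300, seed=5)
        )
        diff = fit.subject_params[..., 0] - fit.subject_params[..., 1]
        lo, hi = np.percentile(diff.mean(axis=-1), [2.5, 97.5])
        assert lo < 0 < hi

    def test_save_load_round_trip(self, small_fit, tmp_path):
        small_fit.save(tmp_path / "fit")
        back = rl.PosteriorFit.load(tmp_path / "fit")
        assert np.allclose(back.mu, small_fit.mu)
        assert back.data_hash == small_fit.data_hash
        assert back.loo().looic == pytest.approx(small_fit.loo().looic, abs=1e-6)

    def test_mismatched_data_comparison_rejected(self, small_fit, small_cell):
        other = small_cell.copy()
        other.loc[0, "outcome"] = 1 - other.loc[0, "outcome"]
        fit2 = rl.fit_hierarchical(
            other, "RW", config=rl.FitConfig(chains=2, warmup=60, draws=40, seed=3)
        )
        with pytest.raises(ValueError, match="different data"):
            rl.compare_models([small_fit, fit2])

    def test_single_model_comparison_degenerates(self, small_fit):
        comp = rl.compare_models([small_fit])
        assert comp.table.shape == (1, 1)

    def test_identical_fits_tie(self, small_fit):
        import copy

        twin = copy.deepcopy(small_fit)
        twin.model = "RW"
        comp = rl.compare_models([small_fit, twin])
        assert comp.winners[list(comp.winners)[0]] is None


class TestPosteriorPredictive:
    def test_zero_beta_gives_flat_chance_curve(self, small_fit):
        import copy

        flat = copy.deepcopy(small_fit)
        flat.subject_params = flat.subject_params.copy()
        flat.subject_params[..., 2] = 0.0
        sched = rl.make_schedule(rl.stable_design(), seed=0)
        acc = rl.posterior_predictive_accuracy(flat, sched, n_draws=100, seed=1)
        assert abs(acc.mean() - 0.5) < 0.02
        assert acc.std() < 0.05

    def test_self_consistency_with_generating_agents(self, small_fit, small_cell):
        sched = rl.make_schedule(rl.stable_design(), seed=123)
        acc = rl.posterior_predictive_accuracy(small_fit, sched, n_draws=150, seed=2)
        # empirical accuracy of the generating cohort on its own schedules
        emp = []
        for s, grp in small_cell.groupby("subject"):
            sid = int(s[1:])
            emp.append(rl.choice_accuracy(grp, rl.make_schedule(rl.stable_design(), seed=1000 + sid)))
        assert abs(acc.mean() - np.mean(emp)) < 0.05

    def test_accuracy_dips_after_reversals(self, small_cell):
        rng = np.random.default_rng(33)
        rows = []
        for s in range(12):
            params = rl.RLParams(
                float(np.clip(rng.normal(0.7, 0.1), 0.1, 0.95)),
                float(np.clip(rng.normal(0.6, 0.1), 0.1, 0.95)),
                float(np.clip(rng.normal(3.0, 0.7), 0.5, 9)),
            )
            sched = rl.make_schedule(rl.volatile_design(), seed=6000 + s)
            rows.append(
                rl.simulate_choices(sched, params, "RP", seed=7000 + s,
                                    subject=f"v{s}", group="OT", context="volatile")
            )
        data = pd.concat(rows, ignore_index=True)
        fit = rl.fit_hierarchical(
            data, "RP", config=rl.FitConfig(chains=2, warmup=250, draws=250, seed=9)
        )
        sched = rl.make_schedule(rl.volatile_design(), seed=77)
        acc = rl.posterior_predictive_accuracy(fit, sched, n_draws=150, seed=3)
        pts = rl.reversal_points(sched)
        pre = np.mean([acc[p - 5 : p].mean() for p in pts])
        post = np.mean([acc[p : p + 5].mean() for p in pts])
        assert post < pre
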
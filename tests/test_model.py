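"""Joint likelihood, posterior inference, EM and rewiring statistics."""

from dataclasses import replace

import numpy as np
import pytest

from tnevo.ctmc import RateParams, enumerate_leaf_configs, leaf_config_probability
from tnevo.expression import ExpressionParams, expr_loglik
from tnevo.model import (
    GroupPosterior,
    ModelParams,
    OrthologGroup,
    RewiringReport,
    affinity_by_conservation,
    classify_conservation,
    dataset_loglik,
    em_fit,
    group_loglik,
    group_posterior,
    groups_from_windows,
    infer_states,
    prediction_accuracy,
    rewiring_rate,
)
from tnevo.motif import SequenceModelParams, scan_window, seq_loglik
from tnevo.phylo import Phylogeny


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def random_params(rng, species, k=3, weight=1.0):
    theta = lambda: rng.dirichlet(np.ones(k) * 3)
    return ModelParams(
        rates=RateParams(
            lam=float(rng.uniform(0.1, 2)),
            mu=float(rng.uniform(0.1, 2)),
            pi_root=float(rng.uniform(0.1, 0.9)),
        ),
        seq=SequenceModelParams(q=float(rng.uniform(0.001, 0.05))),
        expr=ExpressionParams(
            theta0={sp: theta() for sp in species}, theta1={sp: theta() for sp in species}
        ),
        weight=weight,
    )


def random_group(rng, species, pssm, params, gid="g"):
    k = params.expr.k(species[0])
    scans = {
        sp: scan_window(rand_seq(rng, int(rng.integers(30, 120))), pssm, params.seq, seq_id=sp)
        for sp in species
    }
    return OrthologGroup(
        group_id=gid,
        genes={sp: f"{gid}_{sp}" for sp in species},
        scans=scans,
        labels={sp: int(rng.integers(1, k + 1)) for sp in species},
    )


def brute_group_loglik(group, tree, params):
    """Direct summation over all leaf configurations."""
    total = 0.0
    for cfg in enumerate_leaf_configs(tree.leaves):
        prior = leaf_config_probability(tree, params.rates, cfg)
        emis = 0.0
        for sp in tree.leaves:
            z = cfg[sp]
            if params.use_sequence:
                emis += seq_loglik(group.scans[sp], z, params.seq)
            emis += params.weight * expr_loglik(group.labels[sp], z, params.expr, sp)
        total += prior * np.exp(emis)
    return np.log(total)


class TestGroupLoglik:
    def test_matches_bruteforce_on_random_toys(self, tree3, sharp_pssm):
        rng = np.random.default_rng(21)
        species = tree3.leaves
        for i in range(100):
            params = random_params(rng, species, weight=float(rng.choice([0.0, 0.5, 1.0, 2.0])))
            group = random_group(rng, species, sharp_pssm, params, gid=f"g{i}")
            fast = group_loglik(group, tree3, params)
            slow = brute_group_loglik(group, tree3, params)
            assert fast == pytest.approx(slow, rel=1e-10)

    def test_weight_zero_ignores_expression(self, tree3, sharp_pssm):
        rng = np.random.default_rng(22)
        species = tree3.leaves
        params = random_params(rng, species, weight=0.0)
        group = random_group(rng, species, sharp_pssm, params)
        other_theta = random_params(rng, species, weight=0.0)
        swapped = replace(params, expr=other_theta.expr)
        assert group_loglik(group, tree3, params) == pytest.approx(
            group_loglik(group, tree3, swapped)
        )

    def test_uninformative_data_flat_in_theta(self, tree3, sharp_pssm):
        # no motif hits, tiny q, theta0 == theta1: changing theta pairs together
        # cannot change the likelihood
        rng = np.random.default_rng(23)
        species = tree3.leaves
        th = {sp: np.array([0.3, 0.3, 0.4]) for sp in species}
        seq = SequenceModelParams(q=1e-9, threshold=2.0)
        params = ModelParams(
            rates=RateParams(0.5, 0.5, 0.5),
            seq=seq,
            expr=ExpressionParams(theta0=dict(th), theta1=dict(th)),
            weight=1.0,
        )
        group = random_group(rng, species, sharp_pssm, params)
        th2 = {sp: np.array([0.5, 0.25, 0.25]) for sp in species}
        params2 = replace(params, expr=ExpressionParams(theta0=dict(th2), theta1=dict(th2)))
        # emission ratio is ~0 in both, so posterior-relevant difference vanishes
        d1 = group_loglik(group, tree3, params) - sum(
            np.log(th[sp][group.labels[sp] - 1]) for sp in species
        )
        d2 = group_loglik(group, tree3, params2) - sum(
            np.log(th2[sp][group.labels[sp] - 1]) for sp in species
        )
        assert d1 == pytest.approx(d2, abs=1e-6)

    def test_missing_species_rejected(self, tree3, sharp_pssm):
        rng = np.random.default_rng(24)
        params = random_params(rng, tree3.leaves)
        group = random_group(rng, ["A", "B"], sharp_pssm, params)
        with pytest.raises(ValueError):
            group_loglik(group, tree3, params)


class TestGroupPosterior:
    def test_flat_emissions_recover_prior(self, tree3, sharp_pssm):
        rng = np.random.default_rng(25)
        species = tree3.leaves
        th = {sp: np.full(3, 1 / 3) for sp in species}
        params = ModelParams(
            rates=RateParams(0.4, 0.8, 0.35),
            seq=SequenceModelParams(q=1e-9, threshold=2.0),  # no hits callable
            expr=ExpressionParams(theta0=dict(th), theta1=dict(th)),
            weight=1.0,
        )
        group = random_group(rng, species, sharp_pssm, params)
        assert all(s.n_motifs == 0 for s in group.scans.values())
        post = group_posterior(group, tree3, params)
        for i, cfg in enumerate(enumerate_leaf_configs(species)):
            prior = leaf_config_probability(tree3, params.rates, cfg)
            assert post.posterior[i] == pytest.approx(prior, rel=1e-6)

    def test_posterior_sums_to_one(self, tree3, sharp_pssm):
        rng = np.random.default_rng(26)
        params = random_params(rng, tree3.leaves)
        group = random_group(rng, tree3.leaves, sharp_pssm, params)
        post = group_posterior(group, tree3, params)
        assert post.posterior.sum() == pytest.approx(1.0, abs=1e-9)

    def test_strong_signal_maps_to_all_ones(self, tree3, sharp_pssm):
        rng = np.random.default_rng(27)
        species = tree3.leaves
        params = ModelParams(
            rates=RateParams(0.3, 0.7, 0.3),
            seq=SequenceModelParams(q=0.01, threshold=0.9),
            expr=ExpressionParams(
                theta0={sp: np.array([0.98, 0.01, 0.01]) for sp in species},
                theta1={sp: np.array([0.01, 0.98, 0.01]) for sp in species},
            ),
            weight=1.0,
        )
        cons = sharp_pssm.consensus()
        scans = {
            sp: scan_window(
                rand_seq(rng, 30) + cons + rand_seq(rng, 20) + cons + rand_seq(rng, 30),
                sharp_pssm,
                params.seq,
                seq_id=sp,
            )
            for sp in species
        }
        group = OrthologGroup(
            group_id="strong",
            genes={sp: sp for sp in species},
            scans=scans,
            labels={sp: 2 for sp in species},
        )
        post = group_posterior(group, tree3, params)
        assert post.map_config == {sp: 1 for sp in species}
        assert all(post.marginal[sp] > 0.95 for sp in species)

    def test_map_agrees_with_exhaustive_argmax(self, tree3, sharp_pssm):
        rng = np.random.default_rng(28)
        species = tree3.leaves
        for i in range(100):
            params = random_params(rng, species)
            group = random_group(rng, species, sharp_pssm, params, gid=f"g{i}")
            post = group_posterior(group, tree3, params)
            # exhaustive: evaluate joint for each config directly
            joint = []
            for cfg in enumerate_leaf_configs(species):
                prior = leaf_config_probability(tree3, params.rates, cfg)
                emis = sum(
                    seq_loglik(group.scans[sp], cfg[sp], params.seq)
                    + params.weight * expr_loglik(group.labels[sp], cfg[sp], params.expr, sp)
                    for sp in species
                )
                joint.append(np.log(prior) + emis)
            best = int(np.argmax(joint))
            expected = enumerate_leaf_configs(species)[best]
            assert post.map_config == expected

    def test_theta1_label_flip_raises_own_marginal_only(self, tree3, sharp_pssm):
        rng = np.random.default_rng(29)
        species = tree3.leaves
        params = ModelParams(
            rates=RateParams(0.5, 0.5, 0.5),
            seq=SequenceModelParams(q=0.005),
            expr=ExpressionParams(
                theta0={sp: np.array([0.6, 0.2, 0.2]) for sp in species},
                theta1={sp: np.array([0.1, 0.8, 0.1]) for sp in species},
            ),
            weight=1.0,
        )
        group = random_group(rng, species, sharp_pssm, params)
        group = replace(group, labels={sp: 1 for sp in species})
        flipped = replace(group, labels={**group.labels, "A": 2})
        before = group_posterior(group, tree3, params)
        after = group_posterior(flipped, tree3, params)
        assert after.marginal["A"] > before.marginal["A"]


class TestEmFit:
    def test_trace_monotone_and_self_consistent_at_truth(self, strong_dataset, strong_groups):
        from tnevo.simulate import _default_init

        tree = strong_dataset.scenario.tree
        truth_params = ModelParams(
            rates=strong_dataset.scenario.rates,
            seq=SequenceModelParams(q=strong_dataset.scenario.q_true),
            expr=strong_dataset.expr_truth,
            weight=1.0,
        )
        fit = em_fit(strong_groups, tree, truth_params, max_iter=20, tol=1e-9)
        trace = np.array(fit.trace)
        assert np.all(np.diff(trace) >= -1e-8)
        # initialized at truth: parameters should barely move in one step
        one = em_fit(strong_groups, tree, truth_params, max_iter=1, tol=0)
        assert one.params.seq.q == pytest.approx(truth_params.seq.q, abs=0.02)
        tv = 0.5 * np.abs(
            one.params.expr.theta1["speciesA"] - truth_params.expr.theta1["speciesA"]
        ).sum()
        assert tv < 0.1

    def test_needs_two_groups(self, tree3, sharp_pssm):
        rng = np.random.default_rng(30)
        params = random_params(rng, tree3.leaves)
        group = random_group(rng, tree3.leaves, sharp_pssm, params)
        with pytest.raises(ValueError):
            em_fit([group], tree3, params)

    def test_fixed_blocks_do_not_move(self, strong_dataset, strong_groups):
        from tnevo.simulate import _default_init

        tree = strong_dataset.scenario.tree
        init = _default_init(strong_dataset, weight=1.0)
        fit = em_fit(
            strong_groups, tree, init, max_iter=5, tol=0, fixed={"rates", "q"}
        )
        assert fit.params.rates == init.rates
        assert fit.params.seq.q == init.seq.q


class TestConservationCategories:
    @pytest.mark.parametrize(
        "cfg,expected",
        [
            ({"A": 1, "B": 1, "C": 1}, "conserved_all"),
            ({"A": 1, "B": 0, "C": 0}, "species_specific(A)"),
            ({"A": 0, "B": 0, "C": 0}, "non_target"),
            ({"A": 1, "B": 1, "C": 0}, "conserved_partial(C)"),
        ],
    )
    def test_three_species_categories(self, cfg, expected):
        assert classify_conservation(cfg) == expected

    def test_rewiring_from_category_counts(self):
        report = RewiringReport.from_counts({"conserved_all": 823, "mixed": 666})
        assert report.rate * 100 == pytest.approx(44.7, abs=0.05)

    def test_all_conserved_rate_zero(self):
        configs = [{"A": 1, "B": 1, "C": 1}] * 5
        assert rewiring_rate(configs).rate == 0.0

    def test_any_link_denominator(self):
        configs = [{"A": 1, "B": 1, "C": 1}] * 2 + [{"A": 1, "B": 0, "C": 0}] * 2
        report = rewiring_rate(configs, denominator="groups_with_any_link")
        assert report.rate == pytest.approx(0.5)

    def test_species_specific_addition_increases_rate(self):
        conserved = [{"A": 1, "B": 1, "C": 1}] * 10
        base = rewiring_rate(conserved).rate
        more = rewiring_rate(conserved + [{"A": 1, "B": 0, "C": 0}]).rate
        assert more > base

    def test_zero_denominator_undefined(self):
        with pytest.raises(ValueError):
            rewiring_rate([{"A": 0, "B": 0}], denominator="groups_with_any_link")


class TestPredictionAccuracy:
    def test_perfect_and_partial(self):
        truth = [{"A": 1, "B": 0, "C": 1}, {"A": 0, "B": 0, "C": 0}]
        assert prediction_accuracy(truth, truth) == 1.0
        predicted = [{"A": 1, "B": 0, "C": 1}, {"A": 1, "B": 0, "C": 0}]
        assert prediction_accuracy(predicted, truth) == pytest.approx(5 / 6)

    def test_invariant_to_group_order(self):
        truth = [{"A": 1, "B": 0}, {"A": 0, "B": 1}]
        pred = [{"A": 1, "B": 1}, {"A": 0, "B": 1}]
        acc1 = prediction_accuracy(pred, truth)
        acc2 = prediction_accuracy(pred[::-1], truth[::-1])
        assert acc1 == acc2

    def test_missing_truth_rejected(self):
        with pytest.raises(ValueError):
            prediction_accuracy([{"A": 1, "B": 0}], [{"A": 1}])


class TestAffinityByConservation:
    def test_identical_sequences_give_zero_means(self, sharp_pssm, seq_params):
        rng = np.random.default_rng(31)
        seq = rand_seq(rng, 1000)
        sequences = {sp: [seq, seq] for sp in ("A", "B", "C")}
        configs = [{"A": 1, "B": 1, "C": 1}, {"A": 0, "B": 0, "C": 0}]
        table = affinity_by_conservation(sequences, configs, sharp_pssm, seq_params)
        assert (table["mean"].abs() < 1e-12).all()

    def test_category_means_match_hand_computation(self, sharp_pssm):
        rng = np.random.default_rng(32)
        params = SequenceModelParams(q=0.01, threshold=0.9)
        from tnevo.motif import binding_affinity, interspecies_affinity_difference

        seqs = {sp: [rand_seq(rng, 1000)] for sp in ("A", "B", "C")}
        table = affinity_by_conservation(
            seqs, [{"A": 1, "B": 1, "C": 1}], sharp_pssm, params
        )
        affs = [binding_affinity(seqs[sp][0], sharp_pssm, params) for sp in ("A", "B", "C")]
        assert table.loc["conserved_all", "mean"] == pytest.approx(
            interspecies_affinity_difference(affs)
        )
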
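"""Constrained-projection deconvolution, NRBC scan, density comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cordmeth import (
    beta_to_m,
    density_comparison,
    estimate_composition,
    nrbc_ewas,
    nrbc_hypomethylated_cpgs,
    select_discriminating_cpgs,
)
from cordmeth.containers import BetaMatrix, CellComposition, ReferenceProfile


def _beta_from_array(arr, cpg_ids=None, sample_ids=None):
    cpg_ids = cpg_ids or [f"cg{i}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"S{j}" for j in range(arr.shape[1])]
    return BetaMatrix(values=pd.DataFrame(arr, index=cpg_ids, columns=sample_ids))


class TestSelectDiscriminating:
    def _reference_samples(self, seed=0):
        """3 cell types x 3 replicates; one perfect marker per type."""
        rng = np.random.default_rng(seed)
        n_cpgs = 50
        labels = ["A"] * 3 + ["B"] * 3 + ["C"] * 3
        base = rng.uniform(0.4, 0.6, size=(n_cpgs, 9))
        base[0, :3] = 0.95  # marker for A
        base[1, 3:6] = 0.95  # marker for B
        base[2, 6:9] = 0.05  # (hypo) marker for C
        df = pd.DataFrame(
            base,
            index=[f"cg{i}" for i in range(n_cpgs)],
            columns=[f"R{j}" for j in range(9)],
        )
        return df, pd.Series(labels, index=df.columns)

    def test_perfect_markers_selected(self):
        samples, labels = self._reference_samples()
        ref = select_discriminating_cpgs(samples, labels, per_type=2)
        assert "cg0" in ref.discriminating_cpgs["A"]
        assert "cg1" in ref.discriminating_cpgs["B"]
        assert "cg2" in ref.discriminating_cpgs["C"]

    def test_t_statistics_match_brute_force(self):
        samples, labels = self._reference_samples(seed=1)
        X = samples.to_numpy()
        in_a = (labels == "A").to_numpy()
        expected_t = stats.ttest_ind(
            X[:, in_a], X[:, ~in_a], axis=1, equal_var=True
        ).statistic
        # brute-force per-CpG two-sample pooled-variance t as oracle
        a, b = X[:, in_a], X[:, ~in_a]
        na, nb = a.shape[1], b.shape[1]
        sp2 = ((na - 1) * a.var(axis=1, ddof=1) + (nb - 1) * b.var(axis=1, ddof=1)) / (
            na + nb - 2
        )
        oracle_t = (a.mean(axis=1) - b.mean(axis=1)) / np.sqrt(
            sp2 * (1 / na + 1 / nb)
        )
        assert np.allclose(expected_t, oracle_t)

    def test_constructed_markers_outrank_background(self):
        # no NRBC hypo-shift here: that component plants additional real
        # (if weaker) NRBC markers that may legitimately enter the ranking
        from cordmeth import generate_reference_profiles

        reference = generate_reference_profiles(1500, seed=1,
                                                nrbc_hypo_fraction=0.0)
        rng = np.random.default_rng(2)
        means = reference.means
        cols, labels = [], []
        for t in means.columns:
            for r in range(2):
                cols.append(
                    np.clip(means[t] + rng.normal(0, 0.01, len(means)), 0, 1)
                )
                labels.append(t)
        samples = pd.DataFrame(
            np.column_stack(cols), index=means.index,
            columns=[f"R{i}" for i in range(len(cols))],
        )
        ref = select_discriminating_cpgs(
            samples, pd.Series(labels, index=samples.columns), per_type=100
        )
        for t in means.columns:
            constructed = set(reference.discriminating_cpgs[t])
            selected = set(ref.discriminating_cpgs[t])
            assert constructed == selected

    def test_too_few_replicates_rejected(self):
        samples, labels = self._reference_samples()
        with pytest.raises(ValueError):
            select_discriminating_cpgs(samples.iloc[:, [0, 3, 6]],
                                       labels[[0, 3, 6]])


class TestEstimateComposition:
    def test_pure_type_sample(self, small_reference):
        ref = small_reference
        y = ref.means[["CD4T"]].copy()
        y.columns = ["S0"]
        comp = estimate_composition(BetaMatrix(values=y), ref)
        frac = comp.fractions.iloc[0]
        assert frac["CD4T"] == pytest.approx(1.0, abs=1e-8)
        assert frac.drop("CD4T").abs().max() < 1e-8

    def test_even_two_type_mixture(self, small_reference):
        ref = small_reference
        mix = 0.5 * ref.means["B"] + 0.5 * ref.means["NK"]
        comp = estimate_composition(
            _beta_from_array(mix.to_numpy()[:, None], cpg_ids=list(ref.means.index)),
            ref,
        )
        frac = comp.fractions.iloc[0]
        assert frac["B"] == pytest.approx(0.5, abs=1e-6)
        assert frac["NK"] == pytest.approx(0.5, abs=1e-6)

    def test_matches_grid_search_on_two_types(self, small_reference):
        """Exhaustive 0.01-step grid as the optimisation oracle."""
        ref = small_reference
        rng = np.random.default_rng(3)
        two = ReferenceProfile(
            means=ref.means[["CD8T", "Gran"]].iloc[:200],
            discriminating_cpgs={
                "CD8T": list(ref.means.index[:200]),
                "Gran": list(ref.means.index[:200]),
            },
        )
        R = two.means.to_numpy()
        w_true = np.array([0.3, 0.6])
        y = R @ w_true + rng.normal(0, 0.02, 200)
        y = np.clip(y, 0, 1)
        comp = estimate_composition(
            _beta_from_array(y[:, None], cpg_ids=list(two.means.index)), two
        )
        grid = np.arange(0.0, 1.2001, 0.01)
        best, best_sse = None, np.inf
        for w1 in grid:
            for w2 in grid:
                sse = ((y - R @ [w1, w2]) ** 2).sum()
                if sse < best_sse:
                    best, best_sse = (w1, w2), sse
        assert np.abs(comp.fractions.iloc[0].to_numpy() - best).max() <= 0.01

    def test_duplicating_basis_rows_leaves_weights_unchanged(
        self, small_reference
    ):
        ref = small_reference
        rng = np.random.default_rng(4)
        w = rng.dirichlet(np.ones(7))
        y = ref.means.to_numpy() @ w
        beta = _beta_from_array(y[:, None], cpg_ids=list(ref.means.index))
        comp1 = estimate_composition(beta, ref)

        basis = ref.basis_cpgs()
        dup_means = pd.concat(
            [ref.means, ref.means.loc[basis].set_axis([f"{c}_dup" for c in basis])]
        )
        dup_disc = {
            t: cpgs + [f"{c}_dup" for c in cpgs]
            for t, cpgs in ref.discriminating_cpgs.items()
        }
        dup_ref = ReferenceProfile(means=dup_means, discriminating_cpgs=dup_disc)
        dup_vals = pd.concat(
            [beta.values, beta.values.loc[basis].set_axis([f"{c}_dup" for c in basis])]
        )
        comp2 = estimate_composition(BetaMatrix(values=dup_vals), dup_ref)
        assert np.abs(
            comp1.fractions.to_numpy() - comp2.fractions.to_numpy()
        ).max() < 1e-8

    def test_noiseless_cohort_recovered_exactly(
        self, noiseless_cohort, small_reference
    ):
        beta, _, truth = noiseless_cohort
        comp = estimate_composition(beta, small_reference)
        err = np.abs(
            comp.fractions.to_numpy() - truth.true_cell_fractions.to_numpy()
        )
        assert err.max() < 1e-6

    def test_default_noise_cohort_recovered_closely(
        self, small_cohort, small_reference
    ):
        beta, _, truth = small_cohort
        comp = estimate_composition(beta, small_reference)
        err = np.abs(
            comp.fractions.to_numpy() - truth.true_cell_fractions.to_numpy()
        ).mean()
        assert err < 0.02

    def test_rank_deficient_reference_rejected(self, small_reference):
        ref = small_reference
        means = ref.means.copy()
        means["NRBC"] = means["Gran"]  # duplicate column
        bad = ReferenceProfile(means=means,
                               discriminating_cpgs=ref.discriminating_cpgs)
        beta = _beta_from_array(
            means["Gran"].to_numpy()[:, None], cpg_ids=list(means.index)
        )
        with pytest.raises(ValueError, match="rank"):
            estimate_composition(beta, bad)


class TestNrbcEwas:
    def test_hypomethylation_component_enriched(
        self, small_cohort, small_reference
    ):
        beta, sheet, truth = small_cohort
        comp = estimate_composition(beta, small_reference)
        m = beta_to_m(beta)
        res = nrbc_ewas(m, comp, sheet, exclude_bpd=True)
        hypo = set(truth.nrbc_hypo_cpg_ids)
        sig = set(res.index[res["significant"]])
        table = [
            [len(hypo & sig), len(hypo - sig)],
            [len(sig - hypo), len(set(res.index) - hypo - sig)],
        ]
        odds, p = stats.fisher_exact(table, alternative="greater")
        assert odds > 1
        assert p < 0.01

    def test_constant_nrbc_yields_no_hits(self, small_cohort):
        beta, sheet, _ = small_cohort
        comp = CellComposition(
            fractions=pd.DataFrame(
                1.0 / 7, index=beta.sample_ids,
                columns=["CD8T", "CD4T", "B", "NK", "Mono", "Gran", "NRBC"],
            ),
            residual_norm=pd.Series(0.0, index=beta.sample_ids),
        )
        res = nrbc_ewas(beta_to_m(beta), comp, sheet)
        assert res["significant"].sum() == 0

    def test_permuted_nrbc_controls_false_positives(
        self, small_cohort, small_reference
    ):
        beta, sheet, _ = small_cohort
        comp = estimate_composition(beta, small_reference)
        m = beta_to_m(beta)
        rng = np.random.default_rng(11)
        for _ in range(20):
            perm = comp.fractions.sample(
                frac=1.0, random_state=rng.integers(2**31)
            ).set_axis(comp.fractions.index)
            pcomp = CellComposition(
                fractions=perm, residual_norm=comp.residual_norm
            )
            res = nrbc_ewas(m, pcomp, sheet)
            assert res["significant"].sum() <= 1


class TestDensityComparison:
    def test_identical_groups_identical_densities(self):
        rng = np.random.default_rng(5)
        col = rng.uniform(0.05, 0.95, 300)
        arr = np.tile(col[:, None], (1, 10))  # all samples identical
        beta = _beta_from_array(arr)
        comp = CellComposition(
            fractions=pd.DataFrame(
                {"NRBC": np.linspace(0.1, 0.9, 10)}, index=beta.sample_ids
            ),
            residual_norm=pd.Series(0.0, index=beta.sample_ids),
        )
        summ = density_comparison(beta, comp, k=3)
        assert np.allclose(summ.density_high, summ.density_low)
        assert summ.frac_methylated_high == summ.frac_methylated_low

    def test_high_nrbc_group_loses_methylated_mass(
        self, small_cohort, small_reference
    ):
        beta, _, _ = small_cohort
        comp = estimate_composition(beta, small_reference)
        summ = density_comparison(beta, comp, k=10)
        assert summ.frac_methylated_high < summ.frac_methylated_low

    def test_k_one_allowed_and_k_too_large_rejected(self, small_cohort,
                                                    small_reference):
        beta, _, _ = small_cohort
        comp = estimate_composition(beta, small_reference)
        summ = density_comparison(beta, comp, k=1)
        assert len(summ.high_samples) == 1
        with pytest.raises(ValueError):
            density_comparison(beta, comp, k=beta.n_samples)
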
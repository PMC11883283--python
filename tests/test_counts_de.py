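"""TMM normalization, pooled dispersion, NB exact test — with brute-force oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import heartregen as hr
from heartregen.counts_de import (
    CountExperiment,
    SampleInfo,
    exact_test_pvalue,
    nb_exact_test,
    regeneration_contrast,
    tmm_factors,
)


def _exp_from_matrix(counts, n_rep=None):
    """Wrap a plain matrix as a WT-only experiment (uninjured vs regenerating)."""
    counts = np.asarray(counts)
    n = counts.shape[1]
    half = n // 2
    samples = []
    for j in range(n):
        cond = "uninjured" if j < half else "regenerating"
        samples.append(SampleInfo(f"s{j}", "WT", cond, j))
    genes = [f"g{i}" for i in range(counts.shape[0])]
    return CountExperiment(counts, genes, samples)


# ---------------------------------------------------------------------------
# TMM

def brute_force_tmm(counts, ref_j, logratio_trim=0.30, abs_expr_trim=0.05):
    """Independent TMM re-computation with explicit sorting (no rank tricks)."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    log2f = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_j:
            continue
        yo, yr = counts[:, j], counts[:, ref_j]
        keep = (yo > 0) & (yr > 0)
        po, pr = yo[keep] / lib[j], yr[keep] / lib[ref_j]
        m = np.log2(po / pr)
        a = 0.5 * np.log2(po * pr)
        w = (lib[j] - yo[keep]) / (lib[j] * yo[keep]) + (
            lib[ref_j] - yr[keep]
        ) / (lib[ref_j] * yr[keep])
        n = len(m)
        lo_m = np.floor(n * logratio_trim / 2.0) + 1
        hi_m = n + 1 - lo_m
        lo_a = np.floor(n * abs_expr_trim / 2.0) + 1
        hi_a = n + 1 - lo_a
        rm = stats.rankdata(m)
        ra = stats.rankdata(a)
        sel = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        log2f[j] = np.sum(m[sel] / w[sel]) / np.sum(1.0 / w[sel])
    return 2.0 ** (log2f - log2f.mean())


class TestTMM:
    def test_identical_samples_give_unit_factors(self):
        counts = np.tile([[10], [20], [30], [5]], (1, 2))
        exp = _exp_from_matrix(counts)
        nf = tmm_factors(exp)
        assert nf.factors == pytest.approx([1.0, 1.0])

    def test_pure_depth_difference_gives_unit_factors(self):
        base = np.array([[10], [20], [30], [5], [100], [7]])
        counts = np.hstack([base, 2 * base])
        nf = tmm_factors(_exp_from_matrix(counts))
        assert nf.factors == pytest.approx([1.0, 1.0], abs=1e-10)

    def test_matches_brute_force_reference(self, rng):
        counts = rng.integers(1, 2000, size=(60, 4))
        exp = _exp_from_matrix(counts)
        nf = tmm_factors(exp, reference="s0")
        expected = brute_force_tmm(counts, ref_j=0)
        assert nf.factors == pytest.approx(expected, abs=1e-10)

    def test_doubling_one_sample_leaves_factor_nearly_invariant(self, rng):
        # M- and A-values are depth-invariant; only the precision weights
        # shift (the doubled sample's binomial variance term halves while
        # the reference's term does not), so invariance is approximate.
        means = np.exp(rng.normal(4.5, 1.0, size=80))
        counts = rng.poisson(means[:, None], size=(80, 3)) + 1
        doubled = counts.copy()
        doubled[:, 1] *= 2
        f1 = tmm_factors(_exp_from_matrix(counts), reference="s0").factors
        f2 = tmm_factors(_exp_from_matrix(doubled), reference="s0").factors
        assert f1 == pytest.approx(f2, abs=5e-3)

    def test_geometric_mean_is_one(self, small_experiment):
        exp, _ = small_experiment
        nf = tmm_factors(exp)
        assert np.mean(np.log(nf.factors)) == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# dispersion

class TestCommonDispersion:
    def test_poisson_counts_estimate_near_zero(self):
        cfg = hr.SimulationConfig(seed=3, n_genes=500, frac_responsive=0.0, dispersion=0.0)
        exp, _ = hr.simulate_count_experiment(cfg)
        assert hr.common_dispersion(exp) <= 0.01

    def test_nb_dispersion_recovered(self):
        cfg = hr.SimulationConfig(
            seed=4, n_genes=2000, n_replicates=4, frac_responsive=0.0, dispersion=0.1
        )
        exp, _ = hr.simulate_count_experiment(cfg)
        assert 0.05 <= hr.common_dispersion(exp) <= 0.2

    def test_constant_matrix_gives_zero(self):
        counts = np.full((10, 4), 7)
        assert hr.common_dispersion(_exp_from_matrix(counts)) == 0.0

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError):
            hr.common_dispersion(_exp_from_matrix(np.zeros((5, 4), dtype=int)))


# ---------------------------------------------------------------------------
# exact test

def brute_force_exact_p(z_a, z_b, n_a, n_b, phi):
    """Oracle via scipy's NB pmf: enumerate the conditional distribution."""
    t = z_a + z_b
    z = np.arange(t + 1)
    if phi == 0.0:
        pmf = stats.binom.pmf(z, t, n_a / (n_a + n_b))
    else:
        # NB size r, arbitrary success prob (cancels after normalization)
        r_a, r_b = n_a / phi, n_b / phi
        p0 = 0.3
        pmf = stats.nbinom.pmf(z, r_a, p0) * stats.nbinom.pmf(t - z, r_b, p0)
        pmf = pmf / pmf.sum()
    obs = pmf[z_a]
    return min(1.0, pmf[pmf <= obs * (1 + 1e-9)].sum())


class TestNBExactTest:
    def test_symmetric_split_gives_p_one(self):
        assert exact_test_pvalue(5, 5, 3, 3, 0.1) == pytest.approx(1.0)

    def test_poisson_limit_closed_form(self):
        # totals 0 vs 10, equal sizes, phi=0: two-sided binomial tail 2*(1/2)^10
        p = exact_test_pvalue(0, 10, 3, 3, 0.0)
        assert p == pytest.approx(2 * 0.5**10)

    @pytest.mark.parametrize("phi", [0.0, 0.05, 0.4])
    def test_matches_enumeration_oracle(self, phi, rng):
        for _ in range(20):
            z_a = int(rng.integers(0, 60))
            z_b = int(rng.integers(0, 60))
            n_a = int(rng.integers(2, 5))
            n_b = int(rng.integers(2, 5))
            ours = exact_test_pvalue(z_a, z_b, n_a, n_b, phi)
            assert ours == pytest.approx(
                brute_force_exact_p(z_a, z_b, n_a, n_b, phi), abs=1e-10
            )

    def test_null_midp_values_uniform(self, null_experiment):
        exp = null_experiment
        nf = tmm_factors(exp)
        phi = hr.common_dispersion(exp, factors=nf)
        table = nb_exact_test(exp, nf, phi, regeneration_contrast(exp, "WT"), midp=True)
        ks = stats.kstest(table["p_value"], "uniform")
        assert ks.pvalue > 0.01

    def test_null_plain_pvalues_conservative_not_inflated(self, null_experiment):
        # the plain exact p stochastically dominates uniform (discrete
        # statistic), so its rejection rate must not exceed the level
        exp = null_experiment
        nf = tmm_factors(exp)
        phi = hr.common_dispersion(exp, factors=nf)
        table = nb_exact_test(exp, nf, phi, regeneration_contrast(exp, "WT"))
        assert (table["p_value"] < 0.05).mean() <= 0.06

    def test_midp_never_exceeds_plain_p(self, rng):
        for _ in range(20):
            za, zb = int(rng.integers(0, 40)), int(rng.integers(0, 40))
            plain = exact_test_pvalue(za, zb, 3, 3, 0.1)
            mid = exact_test_pvalue(za, zb, 3, 3, 0.1, midp=True)
            assert mid <= plain + 1e-12

    def test_log2fc_sign_flips_with_contrast(self, small_experiment):
        exp, _ = small_experiment
        nf = tmm_factors(exp)
        a, b = regeneration_contrast(exp, "WT")
        t1 = nb_exact_test(exp, nf, 0.1, (a, b))
        t2 = nb_exact_test(exp, nf, 0.1, (b, a))
        assert t1["log2FC"].to_numpy() == pytest.approx(-t2["log2FC"].to_numpy())
        assert t1["p_value"].to_numpy() == pytest.approx(t2["p_value"].to_numpy())

    def test_zero_count_genes_excluded(self):
        counts = np.array([[0, 0, 0, 0], [5, 6, 7, 8]])
        exp = _exp_from_matrix(counts)
        nf = tmm_factors(exp)
        table = nb_exact_test(exp, nf, 0.0, regeneration_contrast(exp, "WT"))
        assert list(table.index) == ["g1"]

    def test_doubling_a_sample_leaves_log2fc_nearly_invariant(self, rng):
        counts = rng.poisson(100, size=(50, 6))
        exp = _exp_from_matrix(counts)
        doubled = counts.copy()
        doubled[:, 0] *= 2
        exp2 = _exp_from_matrix(doubled)
        t1 = nb_exact_test(exp, tmm_factors(exp, "s1"), 0.1, regeneration_contrast(exp, "WT"))
        t2 = nb_exact_test(exp2, tmm_factors(exp2, "s1"), 0.1, regeneration_contrast(exp2, "WT"))
        # depth cancels in CPM; the residual wiggle comes from the TMM
        # weight shift (see the TMM doubling test)
        assert t1["log2FC"].to_numpy() == pytest.approx(t2["log2FC"].to_numpy(), abs=5e-3)


class TestCountExperimentIO:
    def test_tsv_round_trip(self, tmp_path, small_experiment):
        exp, _ = small_experiment
        cpath = tmp_path / "counts.tsv"
        dpath = tmp_path / "design.tsv"
        pd.DataFrame(
            exp.counts, index=pd.Index(exp.genes, name="gene"), columns=exp.sample_ids
        ).to_csv(cpath, sep="\t")
        pd.DataFrame(
            [
                {"sample_id": s.sample_id, "genotype": s.genotype,
                 "condition": s.condition, "replicate": s.replicate}
                for s in exp.samples
            ]
        ).to_csv(dpath, sep="\t", index=False)
        loaded = hr.counts_de.load_count_experiment(cpath, dpath)
        assert np.array_equal(loaded.counts, exp.counts)
        assert loaded.genes == exp.genes

    def test_missing_design_column_named(self, tmp_path):
        (tmp_path / "d.tsv").write_text("sample_id\tgenotype\ns1\tWT\n")
        with pytest.raises(ValueError, match="condition"):
            hr.counts_de.read_design_tsv(tmp_path / "d.tsv")

    def test_rejects_negative_and_duplicate_genes(self):
        with pytest.raises(ValueError):
            _exp_from_matrix(np.array([[-1, 2], [3, 4]]))
        with pytest.raises(ValueError, match="unique"):
            CountExperiment(
                np.ones((2, 2), dtype=int),
                ["g", "g"],
                [SampleInfo("a", "WT", "uninjured", 1), SampleInfo("b", "WT", "regenerating", 1)],
            )
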
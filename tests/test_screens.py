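import numpy as np
import pandas as pd
import pytest

from opsccrna.screens import (
    correlation_matrix,
    correlation_screen,
    deconvolve,
    deconvolve_samples,
    spearman,
)
from opsccrna.synthetic import SimulationConfig, gen_counts, gen_signature_mixtures


def spearman_rho_oracle(x, y):
    """Mid-rank Pearson formula written independently (explicit averaging of
    tied ranks, explicit covariance)."""

    def midranks(v):
        v = np.asarray(v, float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j + 1 < len(v) and sorted_v[j + 1] == sorted_v[i]:
                j += 1
            ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
            i = j + 1
        return ranks

    rx, ry = midranks(x), midranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


class TestSpearman:
    def test_monotone_perfect(self):
        rho, _ = spearman([1, 2, 3], [10, 20, 30])
        assert rho == pytest.approx(1.0)

    def test_hand_example_minus_half(self):
        rho, _ = spearman([1, 2, 3], [3, 1, 2])
        assert rho == pytest.approx(-0.5)

    def test_ties_match_bruteforce_midrank_oracle(self):
        rng = np.random.default_rng(51)
        for _ in range(50):
            x = rng.integers(0, 5, 20).astype(float)  # heavy ties
            y = rng.integers(0, 5, 20).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rho, _ = spearman(x, y, exact=False)
            assert rho == pytest.approx(spearman_rho_oracle(x, y), abs=1e-12)

    def test_pairwise_complete_drops_nan(self):
        rho, _ = spearman([1, 2, 3, 4, np.nan], [1, 2, 3, 4, 100], exact=False)
        assert rho == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_exact_permutation_p_small_n(self):
        # perfect concordance of 4: only 2 of 24 orderings tie the extreme
        _, p = spearman([1, 2, 3, 4], [5, 6, 7, 8], exact=True)
        assert p == pytest.approx(2 / 24)


class TestCorrelationScreen:
    def anchor_partners(self):
        rng = np.random.default_rng(52)
        samples = [f"s{i}" for i in range(30)]
        anchor = pd.Series(rng.normal(size=30), index=samples)
        partners = pd.DataFrame(
            {
                "self": anchor,
                "noise": rng.normal(size=30),
                "anti": -anchor + rng.normal(0, 0.1, 30),
            }
        ).T
        partners.columns = samples
        return anchor, partners

    def test_self_partner_flagged_positive(self):
        anchor, partners = self.anchor_partners()
        out = correlation_screen(anchor, partners, direction="positive")
        assert out.loc["self", "rho"] == pytest.approx(1.0)
        assert bool(out.loc["self", "relevant"])

    def test_negative_mode_excludes_positive(self):
        anchor, partners = self.anchor_partners()
        out = correlation_screen(anchor, partners, direction="negative")
        assert not out.loc["self", "relevant"]
        assert out.loc["anti", "relevant"]

    def test_sorted_by_rho_descending(self):
        anchor, partners = self.anchor_partners()
        out = correlation_screen(anchor, partners, direction="both")
        assert list(out["rho"]) == sorted(out["rho"], reverse=True)

    def test_planted_hub_partners_flagged_background_quiet(self):
        """Copula-planted partners pass the rho > 0.4 screen; background
        genes are flagged at under 10%."""
        cfg = SimulationConfig(n_genes=400, n_samples_per_group=(30, 30), seed=3)
        cm, truth = gen_counts(cfg)
        expr = pd.DataFrame(cm.counts, index=cm.gene_ids, columns=cm.sample_ids).astype(float)
        anchor = expr.loc[truth.hub_gene]
        partners = expr.drop(index=truth.hub_gene)
        out = correlation_screen(anchor, partners, direction="positive")
        for partner in truth.partner_rhos:
            assert out.loc[partner, "relevant"]
        background = out.drop(index=list(truth.partner_rhos))
        assert background["relevant"].mean() < 0.10

    def test_flags_invariant_under_monotone_transforms(self):
        anchor, partners = self.anchor_partners()
        base = correlation_screen(anchor, partners, direction="both")
        transformed = correlation_screen(np.exp(anchor / 2), partners, direction="both")
        pd.testing.assert_series_equal(base["relevant"], transformed["relevant"])
        ranked = partners.rank(axis=1)
        transformed2 = correlation_screen(anchor, ranked, direction="both")
        pd.testing.assert_series_equal(base["relevant"], transformed2["relevant"])


class TestCorrelationMatrix:
    def matrix(self):
        rng = np.random.default_rng(53)
        return pd.DataFrame(
            rng.normal(size=(4, 20)),
            index=list("wxyz"),
            columns=[f"s{i}" for i in range(20)],
        )

    def test_symmetric_unit_diagonal(self):
        rho, _ = correlation_matrix(self.matrix())
        pd.testing.assert_frame_equal(rho, rho.T)
        np.testing.assert_allclose(np.diag(rho), 1.0)

    def test_off_diagonal_consistent_with_spearman(self):
        m = self.matrix().iloc[:2]
        rho, p = correlation_matrix(m)
        r_ref, p_ref = spearman(m.iloc[0], m.iloc[1], exact=False)
        assert rho.iloc[0, 1] == pytest.approx(r_ref)
        assert p.iloc[0, 1] == pytest.approx(p_ref)

    def test_gene_permutation_permutes_rows(self):
        m = self.matrix()
        rho, _ = correlation_matrix(m)
        rho_p, _ = correlation_matrix(m.loc[list("zxwy")])
        pd.testing.assert_frame_equal(rho_p, rho.loc[list("zxwy"), list("zxwy")])

    def test_constant_gene_marked_undefined(self):
        m = self.matrix()
        m.loc["w"] = 5.0
        rho, _ = correlation_matrix(m)
        assert rho.loc["w", "x"] != rho.loc["w", "x"]  # NaN
        assert rho.loc["x", "y"] == rho.loc["x", "y"]


class TestDeconvolution:
    def test_pure_column_recovers_unit_vector(self, default_config):
        sig, _, _ = gen_signature_mixtures(default_config)
        res = deconvolve(sig["typeB"], sig)
        assert res.fractions["typeB"] == pytest.approx(1.0, abs=1e-6)
        assert res.fractions.drop("typeB").abs().max() < 1e-6

    def test_two_type_mixture_recovered(self, default_config):
        sig, _, _ = gen_signature_mixtures(default_config)
        mix = 0.3 * sig["typeA"] + 0.7 * sig["typeB"]
        res = deconvolve(mix, sig)
        assert res.fractions["typeA"] == pytest.approx(0.3, abs=1e-6)
        assert res.fractions["typeB"] == pytest.approx(0.7, abs=1e-6)

    def test_unmodeled_half_reported_as_other(self, default_config):
        """Half the mixture from a profile outside the signature's span
        lands in the 'other' remainder."""
        sig, mix, frac = gen_signature_mixtures(default_config)
        res = deconvolve_samples(mix.T, sig)
        np.testing.assert_allclose(
            res["other"], 1.0 - frac.sum(axis=1), atol=1e-6
        )

    def test_noiseless_mixtures_mae_below_1e6(self, default_config):
        sig, mix, frac = gen_signature_mixtures(default_config)
        res = deconvolve_samples(mix.T, sig)
        mae = np.abs(res[frac.columns].to_numpy() - frac.to_numpy()).mean()
        assert mae < 1e-6

    def test_dense_random_signature_full_mixtures_recovered(self, default_config):
        sig, mix, frac = gen_signature_mixtures(default_config, full_sum=True)
        res = deconvolve_samples(mix.T, sig)
        assert np.abs(res[frac.columns].to_numpy() - frac.to_numpy()).mean() < 1e-6

    def test_scale_invariance(self, default_config):
        sig, mix, _ = gen_signature_mixtures(default_config)
        r1 = deconvolve(mix.iloc[0], sig)
        r2 = deconvolve(mix.iloc[0] * 37.5, sig)
        pd.testing.assert_series_equal(r1.fractions, r2.fractions)

    def test_fractions_nonnegative_sum_below_one(self, default_config):
        sig, mix, _ = gen_signature_mixtures(default_config, noise_sd=5.0)
        res = deconvolve_samples(mix.T, sig)
        fr = res.drop(columns="other")
        assert (fr.to_numpy() >= 0).all()
        assert (fr.sum(axis=1) <= 1 + 1e-9).all()

    def test_missing_marker_rejected(self, default_config):
        sig, mix, _ = gen_signature_mixtures(default_config)
        with pytest.raises(ValueError, match="marker"):
            deconvolve(mix.iloc[0].drop(sig.index[0]), sig)
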
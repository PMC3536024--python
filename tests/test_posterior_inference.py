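"""Decision rules: high/low, Bayesian t, indicator differential, variability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import isobayes as ib
from isobayes.gene_models import nearest_rank_percentile


def make_samples(gene_id, iso_ids, sample_ids, beta, indicator, tau=None, tau0=None,
                 n_segments=3):
    """Assemble PosteriorSamples from (draws, s, L) arrays as one chain x two."""
    beta = np.asarray(beta, dtype=float)
    indicator = np.asarray(indicator, dtype=np.int8)
    D, s, L = beta.shape
    half = D // 2
    tau = np.ones((D, L)) if tau is None else np.asarray(tau, dtype=float)
    tau0 = np.ones((D, s)) if tau0 is None else np.asarray(tau0, dtype=float)

    def split(a):
        return np.stack([a[:half], a[half : 2 * half]])

    return ib.PosteriorSamples(
        gene_id=gene_id, isoform_ids=list(iso_ids), sample_ids=list(sample_ids),
        n_segments=n_segments, beta=split(beta), indicator=split(indicator),
        tau=split(tau), tau0=split(tau0), burn_in=0, thin=1, seed=0,
    )


def _summary_frame(n=100, rng=None):
    rng = rng or np.random.default_rng(0)
    means = rng.gamma(2.0, 3.0, n)
    return pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n)],
            "isoform_id": [f"g{i}.1" for i in range(n)],
            "sample_id": "S1",
            "presence_prob": 0.9,
            "expr_mean": means,
            "expr_sd": 0.5,
            "ppi_2.5": means - 1.2,
            "ppi_5": means - 1.0,
            "ppi_95": means + 1.0,
            "ppi_97.5": means + 1.2,
            "n_segments": 3,
        }
    )


class TestCallHighLow:
    def test_matches_direct_recomputation(self):
        summ = _summary_frame(100)
        out = ib.call_high_low(summ)
        lo = nearest_rank_percentile(summ.expr_mean, 10)
        hi = nearest_rank_percentile(summ.expr_mean, 90)
        expected = np.where(
            summ.ppi_95 < lo, "low", np.where(summ.ppi_5 > hi, "high", "none")
        )
        assert (out["call"].to_numpy() == expected).all()

    def test_zero_ppi_isoform_called_low(self):
        summ = _summary_frame(50)
        summ.loc[0, ["ppi_2.5", "ppi_5", "ppi_95", "ppi_97.5", "expr_mean"]] = 0.0
        out = ib.call_high_low(summ)
        assert out.loc[0, "call"] == "low"

    def test_dominant_isoform_called_high(self):
        summ = _summary_frame(50)
        top = summ.expr_mean.max()
        summ.loc[1, ["ppi_5", "ppi_95", "ppi_97.5"]] = [top + 1, top + 3, top + 4]
        out = ib.call_high_low(summ)
        assert out.loc[1, "call"] == "high"

    def test_mutual_exclusivity(self):
        out = ib.call_high_low(_summary_frame(200, np.random.default_rng(5)))
        assert set(out["call"]) <= {"high", "low", "none"}

    def test_too_few_isoforms_raise(self):
        with pytest.raises(ValueError):
            ib.call_high_low(_summary_frame(1))


class TestBayesianT:
    def _fits(self, rng=None, D=1000):
        rng = rng or np.random.default_rng(0)
        beta = np.stack(
            [np.column_stack([rng.normal(8, 0.5, D), rng.normal(2, 0.5, D)])], axis=1
        )  # (D, 1, 2)
        ind = np.ones_like(beta, dtype=np.int8)
        tau = np.full((D, 2), 4.0)
        return make_samples("g1", ["g1.1"], ["A", "B"], beta, ind, tau=tau)

    def test_same_sample_gives_zero(self):
        s = self._fits()
        t = ib.bayesian_t(s, "g1.1", ("A", "A"))
        assert np.allclose(t.draws, 0.0)

    def test_antisymmetric_in_pair(self):
        s = self._fits()
        ab = ib.bayesian_t(s, "g1.1", ("A", "B"))
        ba = ib.bayesian_t(s, "g1.1", ("B", "A"))
        assert np.allclose(ab.draws, -ba.draws)

    def test_matches_direct_draw_arithmetic(self):
        s = self._fits()
        t = ib.bayesian_t(s, "g1.1", ("A", "B"))
        bstar = s.pooled("beta_star")
        tau = s.pooled("tau")
        m = s.n_segments
        expected = (bstar[:, 0, 0] - bstar[:, 0, 1]) / np.sqrt(
            1 / (m * tau[:, 0]) + 1 / (m * tau[:, 1])
        )
        assert np.allclose(t.draws, expected)

    def test_scale_invariance_of_r1(self):
        """Jointly rescaling expressions and noise SDs (tau -> tau/c^2) leaves
        every t draw, hence the zero-in-PPI verdict, unchanged."""
        rng = np.random.default_rng(1)
        D = 800
        beta = rng.gamma(4, 1, (D, 1, 2))
        ind = np.ones_like(beta, dtype=np.int8)
        tau = np.full((D, 2), 2.0)
        c = 7.0
        s1 = make_samples("g", ["i"], ["A", "B"], beta, ind, tau=tau)
        s2 = make_samples("g", ["i"], ["A", "B"], beta * c, ind, tau=tau / c**2)
        t1 = ib.bayesian_t(s1, "i", ("A", "B"))
        t2 = ib.bayesian_t(s2, "i", ("A", "B"))
        assert np.allclose(t1.draws, t2.draws)


class TestDifferentialCalls:
    def _population(self, n_genes=30, seed=0, effect_genes=(0,)):
        rng = np.random.default_rng(seed)
        fits = {}
        D = 600
        for g in range(n_genes):
            if g in effect_genes:
                a, b = rng.normal(10, 0.3, D), np.zeros(D)
                ind = np.stack([np.column_stack([np.ones(D), np.zeros(D)])], 1).astype(np.int8)
            else:
                base = rng.normal(5, 0.3, D)
                a, b = base, base + rng.normal(0, 0.05, D)
                ind = np.ones((D, 1, 2), dtype=np.int8)
            beta = np.stack([np.column_stack([a, np.abs(b)])], axis=1)
            tau = np.full((D, 2), 1.0)
            fits[f"g{g}"] = make_samples(f"g{g}", [f"g{g}.1"], ["T", "C"], beta, ind, tau=tau)
        return fits

    def test_strong_effect_called_up_by_r1(self):
        fits = self._population()
        calls = ib.differential_calls(fits, ("T", "C"))
        r1 = calls[calls.rule == "R1-ppi-zero"].set_index("gene_id")
        assert r1.loc["g0", "verdict"] == "up"
        assert r1.loc["g0", "ppi_lo"] > 0

    def test_r3_only_for_multi_segment(self):
        fits = self._population()
        for f in fits.values():
            f.n_segments = 1
        calls = ib.differential_calls(fits, ("T", "C"))
        assert "R3-t-critical" not in set(calls.rule)

    def test_r3_uses_exon_count_critical_value(self):
        fits = self._population()
        calls = ib.differential_calls(fits, ("T", "C"))
        r3 = calls[calls.rule == "R3-t-critical"].set_index("gene_id")
        crit = stats.t.ppf(0.975, df=2 * (3 - 1))
        for gid, row in r3.iterrows():
            assert (abs(row.t_mean) > crit) == (row.verdict != "none")

    def test_r2_thresholds_are_mean_t_deciles(self):
        fits = self._population()
        calls = ib.differential_calls(fits, ("T", "C"))
        means = calls[calls.rule == "R1-ppi-zero"]["t_mean"].to_numpy()
        ref = calls.attrs["t_mean_percentiles"]
        assert ref["lo"] == nearest_rank_percentile(means, 10)
        assert ref["hi"] == nearest_rank_percentile(means, 90)


class TestIndicatorDifferential:
    def _samples_with_presence(self, p1, p2, D=1000):
        ind = np.zeros((D, 1, 2), dtype=np.int8)
        ind[: int(round(p1 * D)), 0, 0] = 1
        ind[: int(round(p2 * D)), 0, 1] = 1
        beta = np.full((D, 1, 2), 5.0)
        return make_samples("g", ["i"], ["A", "B"], beta, ind)

    def test_confident_asymmetry_is_differential(self):
        s = self._samples_with_presence(0.99, 0.01)
        assert ib.indicator_differential(s, "i", ("A", "B")) == "up"

    def test_middling_presence_is_none(self):
        s = self._samples_with_presence(0.6, 0.4)
        assert ib.indicator_differential(s, "i", ("A", "B")) == "none"

    def test_grid_sweep_matches_rule(self):
        conf = 0.95
        for p1 in np.linspace(0, 1, 11):
            for p2 in np.linspace(0, 1, 11):
                s = self._samples_with_presence(p1, p2)
                got = ib.indicator_differential(s, "i", ("A", "B"), conf)
                pres = s.presence_prob()
                q1, q2 = float(pres[0, 0]), float(pres[0, 1])
                if q1 >= conf and q2 <= 1 - conf:
                    expected = "up"
                elif q2 >= conf and q1 <= 1 - conf:
                    expected = "down"
                else:
                    expected = "none"
                assert got == expected


class TestVariability:
    def _fits_with_variances(self, variances):
        fits = {}
        D = 10
        for i, v in enumerate(variances):
            tau0 = np.full((D, 1), 1.0 / v)
            beta = np.full((D, 1, 1), 1.0)
            ind = np.ones_like(beta, dtype=np.int8)
            fits[f"g{i}"] = make_samples(
                f"g{i}", [f"g{i}.1"], ["S1"], beta, ind, tau0=tau0
            )
        return fits

    def test_known_values_classified_by_nearest_rank(self):
        vals = np.arange(1.0, 101.0)
        res = ib.variability_classify(self._fits_with_variances(vals))
        thr = res["thresholds"]
        assert thr == {"p35": 35.0, "p65": 65.0, "p90": 90.0}
        table = res["table"].set_index("variability")["class"]
        assert (table.loc[: 34.0] == "low").all()
        assert (table.loc[35.0:65.0] == "mid").all()
        assert (table.loc[66.0:90.0] == "moderate").all()
        assert (table.loc[91.0:] == "high").all()

    def test_constant_values_no_extreme_classes(self):
        res = ib.variability_classify(self._fits_with_variances(np.full(20, 3.0)))
        assert set(res["table"]["class"]) == {"mid"}
        assert res["gamma_fit"] is None

    def test_gamma_mle_recovers_shape(self):
        rng = np.random.default_rng(4)
        vals = rng.gamma(2.0, 1.0, 1000)
        res = ib.variability_classify(self._fits_with_variances(vals))
        assert res["gamma_fit"]["shape"] == pytest.approx(2.0, rel=0.2)
        qq = res["qq"]
        slope = np.polyfit(qq["theoretical"], qq["observed"], 1)[0]
        assert slope == pytest.approx(1.0, abs=0.15)
        # tail exceedance is near the nominal tail probability by construction
        assert res["tail_exceedance"] == pytest.approx(0.05, abs=0.02)


class TestOverlapTable:
    def _labels(self, assignment):
        rows = []
        for cond, calls in assignment.items():
            for iso, call in calls.items():
                rows.append(
                    {"gene_id": iso.split(".")[0], "isoform_id": iso, "sample_id": cond, "call": call}
                )
        return pd.DataFrame(rows)

    def test_identical_conditions_full_overlap(self):
        calls = {f"g{i}.1": ("high" if i < 4 else "low") for i in range(10)}
        labels = self._labels({"A": calls, "B": calls})
        out = ib.pairwise_overlap_table(labels)
        assert out.loc["A", "B"] == 4  # common high
        assert out.loc["B", "A"] == 6  # common low
        assert out.loc["total", "A"] == 4 and out.loc["A", "total"] == 6

    def test_disjoint_conditions_zero_overlap(self):
        a = {f"g{i}.1": "high" for i in range(5)}
        b = {f"h{i}.1": "high" for i in range(5)}
        labels = self._labels({"A": a, "B": b})
        out = ib.pairwise_overlap_table(labels)
        assert out.loc["A", "B"] == 0

    def test_random_labels_match_set_oracle(self):
        rng = np.random.default_rng(6)
        conds = ["A", "B", "C"]
        assignment = {
            c: {f"g{i}.1": rng.choice(["high", "low", "none"]) for i in range(40)}
            for c in conds
        }
        labels = self._labels(assignment)
        out = ib.pairwise_overlap_table(labels)
        for i, ci in enumerate(conds):
            for j, cj in enumerate(conds):
                if i == j:
                    continue
                kind = "high" if i < j else "low"
                expect = len(
                    {k for k, v in assignment[ci].items() if v == kind}
                    & {k for k, v in assignment[cj].items() if v == kind}
                )
                assert out.loc[ci, cj] == expect


class TestGeneLevelSummary:
    def test_single_isoform_equals_isoform_summary(self):
        rng = np.random.default_rng(0)
        D = 1000
        beta = rng.gamma(5, 1, (D, 1, 1))
        ind = np.ones_like(beta, dtype=np.int8)
        s = make_samples("g", ["i"], ["S1"], beta, ind)
        gene = ib.gene_level_summary(s)
        iso = ib.isoform_summaries([s])
        assert gene["expr_mean"].iloc[0] == pytest.approx(iso["expr_mean"].iloc[0])

    def test_two_isoforms_add_drawwise(self):
        rng = np.random.default_rng(1)
        D = 2000
        beta = np.concatenate(
            [rng.normal(3, 0.2, (D, 1, 1)), rng.normal(4, 0.2, (D, 1, 1))], axis=1
        )
        ind = np.ones_like(beta, dtype=np.int8)
        s = make_samples("g", ["a", "b"], ["S1"], np.abs(beta), ind)
        gene = ib.gene_level_summary(s)
        assert gene["expr_mean"].iloc[0] == pytest.approx(7.0, abs=0.05)

    def test_absent_gene_near_zero(self):
        D = 100
        beta = np.full((D, 2, 1), 5.0)
        ind = np.zeros_like(beta, dtype=np.int8)
        s = make_samples("g", ["a", "b"], ["S1"], beta, ind)
        gene = ib.gene_level_summary(s)
        assert gene["expr_mean"].iloc[0] == 0.0
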
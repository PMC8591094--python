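import numpy as np
import pandas as pd
import pytest

from subnetmark.data_io import ClinicalTable, ValidationError
from subnetmark.scoring import SubnetworkScoreMatrix
from subnetmark.survival import (
    CRC15_RISK_BETAS,
    RiskModel,
    cox_fit,
    external_validation,
    km_logrank,
    risk_score,
    stratify_median,
)
from subnetmark.synthetic import SyntheticSpec, gen_survival

from _oracles import logrank_by_hand


def _clinical(times, events, index=None):
    index = index or [f"P{i}" for i in range(len(times))]
    return ClinicalTable(
        pd.DataFrame({"time": times, "event": events}, index=pd.Index(index, name="sample"))
    )


def _simulate_cox(beta, n, censor_rate, seed, covariate="binary"):
    """Exponential survival with one covariate; uniform censoring."""
    from subnetmark.synthetic import _censor_horizon

    rng = np.random.default_rng(seed)
    if covariate == "binary":
        x = rng.integers(0, 2, n).astype(float)
    else:
        x = rng.normal(0.0, 1.0, n)
    hazard = 0.05 * np.exp(beta * x)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        upper = _censor_horizon(hazard, censor_rate)
        c = rng.uniform(0, upper, n)
        time, event = np.minimum(t_event, c), (t_event <= c).astype(int)
    else:
        time, event = t_event, np.ones(n, dtype=int)
    clin = _clinical(time, event)
    design = pd.DataFrame({"x": x}, index=clin.data.index)
    return clin, design


class TestCoxFit:
    def test_recovers_binary_effect(self):
        clin, design = _simulate_cox(beta=0.7, n=300, censor_rate=0.2, seed=0)
        fit = cox_fit(clin, design)[0]
        assert 0.5 <= fit.beta <= 0.9
        assert fit.hr == pytest.approx(np.exp(fit.beta), rel=1e-9)
        assert fit.ci95[0] <= fit.hr <= fit.ci95[1]

    def test_constant_covariate_rejected(self):
        clin, design = _simulate_cox(beta=0.0, n=50, censor_rate=0.0, seed=1)
        design["x"] = 1.0
        with pytest.raises(ValidationError, match="constant"):
            cox_fit(clin, design)

    def test_null_covariate_small_and_insignificant(self):
        """Independent covariate: |beta| < 0.25 and p > 0.05 in >= 90% of reps."""
        ok = 0
        n_reps = 40
        for seed in range(n_reps):
            clin, design = _simulate_cox(
                beta=0.0, n=300, censor_rate=0.2, seed=seed, covariate="normal"
            )
            fit = cox_fit(clin, design)[0]
            ok += abs(fit.beta) < 0.25 and fit.p_value > 0.05
        assert ok / n_reps >= 0.9

    def test_zero_events_rejected(self):
        clin = _clinical([1.0, 2.0, 3.0], [0, 0, 0])
        design = pd.DataFrame({"x": [0.0, 1.0, 0.0]}, index=clin.data.index)
        with pytest.raises(ValidationError, match="no events"):
            cox_fit(clin, design)

    def test_univariate_mode_fits_each_alone(self):
        clin, design = _simulate_cox(beta=0.5, n=200, censor_rate=0.1, seed=3)
        rng = np.random.default_rng(4)
        design["y"] = rng.normal(0, 1, len(design))
        fits = cox_fit(clin, design, mode="univariate")
        assert [f.covariate for f in fits] == ["x", "y"]
        assert all(f.model_tag == "univariate" for f in fits)


class TestRiskScore:
    def test_zero_scores_give_zero(self):
        scores = SubnetworkScoreMatrix(
            pd.DataFrame(np.zeros((3, 4)), index=[1, 2, 3])
        )
        model = RiskModel([1, 2, 3], [0.5, -1.0, 2.0], 0.0)
        assert (risk_score(scores, model) == 0).all()

    def test_reference_15_coefficient_model_on_unit_scores(self):
        """All scores 1 under the published 15-subnetwork colorectal model
        sums its betas: -5.4."""
        expected = sum(CRC15_RISK_BETAS)  # independent summation
        scores = SubnetworkScoreMatrix(
            pd.DataFrame(np.ones((15, 2)), index=range(1, 16), columns=["A", "B"])
        )
        model = RiskModel(list(range(1, 16)), list(CRC15_RISK_BETAS), 0.0)
        out = risk_score(scores, model)
        assert out["A"] == pytest.approx(expected, abs=1e-12)
        assert out["A"] == pytest.approx(-5.4, abs=1e-9)

    def test_linearity(self):
        rng = np.random.default_rng(0)
        frame = pd.DataFrame(rng.normal(0, 1, (4, 6)), index=[1, 2, 3, 4])
        scores = SubnetworkScoreMatrix(frame)
        doubled = SubnetworkScoreMatrix(2 * frame)
        model = RiskModel([1, 2, 3, 4], [0.3, -0.7, 1.1, 0.0], 0.0)
        assert np.allclose(
            risk_score(doubled, model), 2 * risk_score(scores, model), atol=1e-12
        )

    def test_row_order_irrelevant_when_ids_align(self):
        rng = np.random.default_rng(1)
        frame = pd.DataFrame(rng.normal(0, 1, (3, 5)), index=[1, 2, 3])
        model = RiskModel([1, 2, 3], [0.5, -0.5, 1.0], 0.0)
        shuffled = SubnetworkScoreMatrix(frame.loc[[3, 1, 2]])
        assert np.allclose(
            risk_score(SubnetworkScoreMatrix(frame), model),
            risk_score(shuffled, model),
            atol=1e-12,
        )

    def test_missing_subnetwork_named(self):
        scores = SubnetworkScoreMatrix(pd.DataFrame(np.ones((2, 2)), index=[1, 2]))
        with pytest.raises(ValidationError, match="3"):
            risk_score(scores, RiskModel([1, 2, 3], [1.0, 1.0, 1.0], 0.0))


class TestStratifyMedian:
    def test_even_split(self):
        groups, threshold = stratify_median(pd.Series([1, 2, 3, 4], index=list("abcd")))
        assert threshold == 2.5
        assert groups == {"a": "low", "b": "low", "c": "high", "d": "high"}

    def test_sample_at_median_goes_low(self):
        groups, _ = stratify_median(pd.Series([1, 2, 3], index=list("abc")))
        assert groups["b"] == "low"

    def test_degenerate_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            stratify_median(pd.Series([5.0, 5.0, 5.0]))


class TestKMLogrank:
    def test_identical_groups_null(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 0, 1]
        clin = _clinical(times + times, events + events)
        groups = {f"P{i}": ("high" if i < 4 else "low") for i in range(8)}
        km = km_logrank(clin, groups)
        assert km.chi_square == pytest.approx(0.0, abs=1e-9)
        assert km.p_value == pytest.approx(1.0, abs=1e-9)

    def test_product_limit_by_hand(self):
        clin = _clinical([1.0, 2.0, 5.0, 6.0], [1, 1, 1, 1])
        groups = {"P0": "high", "P1": "high", "P2": "low", "P3": "low"}
        km = km_logrank(clin, groups)
        high = km.curves["high"].set_index("time")["survival"]
        assert high.loc[1.0] == pytest.approx(0.5)
        assert high.loc[2.0] == pytest.approx(0.0)

    def test_km_equals_empirical_survival_without_censoring(self):
        rng = np.random.default_rng(2)
        times = rng.exponential(10, 40)
        clin = _clinical(times, [1] * 40)
        groups = {f"P{i}": ("high" if i < 20 else "low") for i in range(40)}
        km = km_logrank(clin, groups)
        for name, rows in km.curves.items():
            member_times = np.sort(
                [times[i] for i in range(40) if groups[f"P{i}"] == name]
            )
            for _, row in rows.iterrows():
                empirical = np.mean(member_times > row["time"])
                assert row["survival"] == pytest.approx(empirical, abs=1e-12)

    def test_matches_bruteforce_logrank_on_random_data(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(4, 30))
            times = np.round(rng.exponential(5, n), 1) + 0.1
            events = rng.integers(0, 2, n)
            if events.sum() == 0:
                continue
            split = n // 2
            groups = {f"P{i}": ("high" if i < split else "low") for i in range(n)}
            clin = _clinical(times, events)
            km = km_logrank(clin, groups)
            ref = logrank_by_hand(
                times[:split], events[:split], times[split:], events[split:]
            )
            assert km.chi_square == pytest.approx(ref, abs=1e-6)

    def test_power_under_true_hazard_ratio(self):
        rng = np.random.default_rng(4)
        t1 = rng.exponential(1.0, 100)   # hazard 1
        t2 = rng.exponential(3.0, 100)   # hazard 1/3, HR = 3 between groups
        clin = _clinical(np.concatenate([t1, t2]), [1] * 200)
        groups = {f"P{i}": ("high" if i < 100 else "low") for i in range(200)}
        assert km_logrank(clin, groups).p_value < 0.05

    def test_empty_group_rejected(self):
        clin = _clinical([1.0, 2.0], [1, 1])
        with pytest.raises(ValidationError, match="two non-empty groups"):
            km_logrank(clin, {"P0": "high", "P1": "high"})


class TestExternalValidation:
    def _scores_and_clinical(self, beta, n, seed):
        rng = np.random.default_rng(seed)
        frame = pd.DataFrame(
            rng.normal(0, 1, (3, n)),
            index=[1, 2, 3],
            columns=[f"P{i}" for i in range(n)],
        )
        scores = SubnetworkScoreMatrix(frame)
        model = RiskModel([1, 2, 3], [1.0, 0.8, -0.6], 0.0)
        risk = risk_score(scores, model)
        spec = SyntheticSpec(rng_seed=seed, survival_beta=beta, censor_rate=0.2)
        return scores, model, gen_survival(risk, spec)

    def test_same_hazard_model_validates(self):
        scores, model, clinical = self._scores_and_clinical(beta=1.2, n=200, seed=5)
        km = external_validation(scores, model, clinical)
        assert km.p_value < 0.05

    def test_permuted_survival_times_null(self):
        """With survival independent of risk, p is non-significant most of the
        time and spreads over (0, 1)."""
        pvals = []
        for seed in range(20):
            scores, model, clinical = self._scores_and_clinical(beta=0.0, n=80, seed=seed)
            pvals.append(external_validation(scores, model, clinical).p_value)
        assert np.mean(np.array(pvals) < 0.05) <= 0.2
        assert np.ptp(pvals) > 0.3

    def test_all_zero_betas_cannot_stratify(self):
        scores, _, clinical = self._scores_and_clinical(beta=1.0, n=50, seed=6)
        zero_model = RiskModel([1, 2, 3], [0.0, 0.0, 0.0], 0.0)
        with pytest.raises(ValidationError, match="degenerate"):
            external_validation(scores, zero_model, clinical)
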
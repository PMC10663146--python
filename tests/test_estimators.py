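"""Pooled logistic regression and the two curve estimators."""

import numpy as np
import pandas as pd
import pytest

from weighttte import (
    PooledLogisticModel,
    apply_exclusions,
    default_params,
    expand_person_periods,
    fit_pooled_logistic,
    gformula_incidence,
    ipw_weighted_km,
    method_spec,
    simulate_cohort,
)
from _oracles import newton_logistic


@pytest.fixture(scope="module")
def null_fit3(null_cohort):
    model = PooledLogisticModel.from_cohort(null_cohort, "3")
    return model.fit()


def _records_subset(cohort, method, max_records):
    spec = method_spec(method)
    sub, _ = apply_exclusions(cohort, spec)
    pp = expand_person_periods(sub, spec)
    keep_ids = []
    total = 0
    for sid, cnt in pp.groupby("id", sort=True).size().items():
        if total + cnt > max_records:
            break
        keep_ids.append(sid)
        total += cnt
    return pp[pp["id"].isin(keep_ids)].reset_index(drop=True)


@pytest.mark.parametrize("method", ["1", "2", "3"])
def test_coefficients_match_newton_oracle(method):
    """Implementation vs written-out Newton-Raphson, <= 500 records, 1e-6."""
    # a short study (3 intervals, higher hazard) keeps every interval
    # populated with events inside the 500-record budget
    params = default_params().replace(
        n_subjects=180, n_intervals=3, baseline_hazard_logits=(-3.5,) * 3
    )
    cohort = simulate_cohort(params, seed=29)
    records = _records_subset(cohort, method, 500)
    assert len(records) <= 500
    model = PooledLogisticModel(records, method_spec(method))
    fit = model.fit()
    assert fit.converged
    beta = newton_logistic(model.exog, model.endog)
    np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-6)


def test_hand_built_person_periods_against_oracle():
    """20 handwritten records, coefficients to 1e-8."""
    from weighttte.emulation import MethodSpec

    # 11 subjects; 3 and 9 fail in interval 1 (one record each), 4 and 10
    # in interval 2; everyone else is event-free with two records
    sid      = [1, 1, 2, 2, 3, 4, 4, 5, 5, 6, 6, 7, 7, 8, 8, 9, 10, 10, 11, 11]
    interval = [1, 2, 1, 2, 1, 1, 2, 1, 2, 1, 2, 1, 2, 1, 2, 1, 1, 2, 1, 2]
    event    = [0, 0, 0, 0, 1, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 1, 0, 1, 0, 0]
    loss     = {1: 1, 2: 1, 3: 1, 10: 1}
    gain     = {4: 1, 5: 1, 6: 1, 11: 1}
    smoking  = {1: 1, 3: 1, 5: 1, 8: 1, 10: 1}
    records = pd.DataFrame(
        {
            "id": sid,
            "interval": interval,
            "event": event,
            "exposure_loss": [loss.get(s, 0) for s in sid],
            "exposure_gain": [gain.get(s, 0) for s in sid],
            "smoking0": [smoking.get(s, 0) for s in sid],
        }
    )
    spec = MethodSpec(
        name="method1",
        time_zero="enrolment",
        exclude_first_interval_cvd=False,
        exclude_first_interval_chronic=False,
        covariate_set=("smoking0",),
        first_modelled_interval=1,
    )
    model = PooledLogisticModel(records, spec)
    fit = model.fit()
    beta = newton_logistic(model.exog, model.endog, tol=1e-14)
    np.testing.assert_allclose(fit.params.to_numpy(), beta, atol=1e-8)


def test_null_confounding_recovers_truth(null_fit3):
    assert null_fit3.converged and not null_fit3.separation_flag
    assert abs(null_fit3.coef_loss - 0.0) < 3 * null_fit3.se_loss
    assert abs(null_fit3.coef_gain - 0.3) < 3 * null_fit3.se_gain
    lo, hi = null_fit3.ci_loss
    assert lo < null_fit3.coef_loss < hi
    np.testing.assert_allclose(
        hi - null_fit3.coef_loss, 1.959964 * null_fit3.se_loss, rtol=1e-12
    )


def test_fit_result_bookkeeping(null_fit3, null_cohort):
    sub, _ = apply_exclusions(null_cohort, method_spec("3"))
    assert null_fit3.n_subjects == sub.n
    assert null_fit3.n_events <= null_fit3.n_subjects
    assert null_fit3.n_records > null_fit3.n_subjects
    s = null_fit3.summary()
    assert "exposure_loss" in s and "exposure_gain" in s


def test_zero_events_is_an_error(make_cohort):
    cohort = make_cohort([{} for _ in range(5)])
    pp = expand_person_periods(cohort, method_spec("1"))
    with pytest.raises(ValueError, match="events"):
        fit_pooled_logistic(pp, method_spec("1"))


def test_separation_is_flagged(make_cohort):
    # smoking0 perfectly predicts the event
    rows = []
    for i in range(30):
        smoking = int(i < 10)
        rows.append(
            {"smoking0": smoking, "event_interval": 2 if smoking else pd.NA,
             "change_category": "loss" if i % 2 else "maintain"}
        )
    cohort = make_cohort(rows)
    pp = expand_person_periods(cohort, method_spec("1"))
    fit = fit_pooled_logistic(pp, method_spec("1"))
    assert fit.separation_flag


def test_cox_concordance(default_cohort):
    """Pooled-logistic exposure coefficients track a Cox fit on the same data."""
    from lifelines import CoxPHFitter

    spec = method_spec("3")
    sub, _ = apply_exclusions(default_cohort, spec)
    fit = PooledLogisticModel.from_cohort(default_cohort, spec).fit()

    df = sub.subjects
    ev = df["event_interval"].to_numpy(dtype=float)
    observed = ~np.isnan(ev)
    data = pd.DataFrame(
        {
            "duration": np.where(observed, ev, default_cohort.params.n_intervals),
            "event": observed.astype(int),
            "loss": (df["change_category"] == "loss").astype(int),
            "gain": (df["change_category"] == "gain").astype(int),
        }
    )
    for c in spec.covariate_set:
        data[c] = df[c].to_numpy()
    cph = CoxPHFitter()
    cph.fit(data, duration_col="duration", event_col="event")
    assert abs(cph.params_["loss"] - fit.coef_loss) < 0.02
    assert abs(cph.params_["gain"] - fit.coef_gain) < 0.02


# --- curves -----------------------------------------------------------------

def test_gformula_single_interval_recovers_group_rates():
    """With one interval and no covariates the standardized risk equals the
    observed event rate per exposure group (saturated logistic MLE)."""
    n = 150
    rows = []
    for g, k in (("maintain", 30), ("loss", 52), ("gain", 45)):
        for i in range(n):
            rows.append({"group": g, "event": int(i < k)})
    df = pd.DataFrame(rows)
    records = pd.DataFrame(
        {
            "id": np.arange(len(df)),
            "interval": 1,
            "event": df["event"],
            "exposure_loss": (df["group"] == "loss").astype(int),
            "exposure_gain": (df["group"] == "gain").astype(int),
        }
    )
    spec = method_spec("1").__class__(
        name="method1",
        time_zero="enrolment",
        exclude_first_interval_cvd=False,
        exclude_first_interval_chronic=False,
        covariate_set=(),
        first_modelled_interval=1,
    )
    curves = gformula_incidence(records, spec, interval_length=2.0)
    by_group = {c.group: c for c in curves}
    assert by_group["maintain"].risk[-1] == pytest.approx(30 / n, abs=1e-8)
    assert by_group["loss"].risk[-1] == pytest.approx(52 / n, abs=1e-8)
    assert by_group["gain"].risk[-1] == pytest.approx(45 / n, abs=1e-8)


def test_gformula_null_model_gives_identical_curves(null_fit3):
    """Forcing the exposure coefficients to zero removes all group contrast."""
    fit = null_fit3
    params = fit.params.copy()
    params["exposure_loss"] = 0.0
    params["exposure_gain"] = 0.0
    import dataclasses

    forced = dataclasses.replace(fit, params=params)
    curves = forced.gformula_curves(interval_length=2.0)
    risks = np.array([c.risk for c in curves])
    assert np.allclose(risks[0], risks[1]) and np.allclose(risks[1], risks[2])


def test_curve_invariants_and_baseline_period(default_cohort):
    spec = method_spec("3")
    sub, _ = apply_exclusions(default_cohort, spec)
    records = expand_person_periods(sub, spec)
    for curves in (
        gformula_incidence(records, spec, interval_length=2.0),
        ipw_weighted_km(sub, spec),
    ):
        for c in curves:
            assert c.risk[0] == 0.0
            assert np.all(np.diff(c.risk) >= -1e-12)
            assert c.times[0] == 0.0 and c.times[-1] == 20.0
            assert c.risk_at(2.0) == 0.0  # structural baseline period


def test_stabilized_weights_center_on_one(default_cohort):
    spec = method_spec("3")
    sub, _ = apply_exclusions(default_cohort, spec)
    curves = ipw_weighted_km(sub, spec)
    for c in curves:
        assert 0.9 <= c.weight_mean <= 1.1
        assert c.weight_max is not None and c.weight_max >= c.weight_mean


def test_ipw_equals_unweighted_km_under_randomization(null_cohort):
    from lifelines import KaplanMeierFitter

    spec = method_spec("3")
    sub, _ = apply_exclusions(null_cohort, spec)
    curves = {c.group: c for c in ipw_weighted_km(sub, spec)}
    df = sub.subjects
    ev = df["event_interval"].to_numpy(dtype=float)
    observed = ~np.isnan(ev)
    durations = np.where(observed, ev, 10) * 2.0
    for group, c in curves.items():
        mask = df["change_category"].to_numpy() == group
        kmf = KaplanMeierFitter()
        kmf.fit(durations[mask], event_observed=observed[mask], timeline=c.times)
        plain = 1.0 - kmf.survival_function_at_times(c.times).to_numpy()
        assert np.max(np.abs(plain - c.risk)) < 0.005


def test_gformula_calibrates_to_empirical_risk(default_cohort):
    """Correctly specified model: standardized maintenance risk matches the
    empirical 20-year risk among maintainers."""
    spec = method_spec("3")
    sub, _ = apply_exclusions(default_cohort, spec)
    records = expand_person_periods(sub, spec)
    curves = {c.group: c for c in gformula_incidence(records, spec, interval_length=2.0)}
    df = sub.subjects
    maint = df[df["change_category"] == "maintain"]
    empirical = maint["event_interval"].notna().mean()
    assert abs(curves["maintain"].risk[-1] - empirical) < 0.02
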
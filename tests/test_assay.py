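import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from pgalbind.assay import (
    CalibrationCurve,
    DoseResponse,
    inhibition_percent,
    inhibition_table,
    linear_calibration,
    load_ros_table,
    probit_ic50,
    quantify,
    simulate_dose_response,
)

DOSES = np.geomspace(0.02, 1.5, 8)


def test_dose_response_validation():
    with pytest.raises(ValueError, match="increasing"):
        DoseResponse([1.0, 1.0, 2.0], [0.1, 0.2, 0.3])
    with pytest.raises(ValueError, match="positive"):
        DoseResponse([-1.0, 1.0, 2.0], [0.1, 0.2, 0.3])
    with pytest.raises(ValueError, match="fractions"):
        DoseResponse([1.0, 2.0, 3.0], [0.1, 0.2, 1.3])


def test_noiseless_probit_recovery():
    data = simulate_dose_response(0.165, slope=2.2, doses=DOSES)
    res = probit_ic50(data)
    assert res.ic50 == pytest.approx(0.165, rel=0.01)
    assert res.beta1 == pytest.approx(2.2, rel=0.01)
    assert not res.extrapolated
    assert "IC50" in res.summary()


def test_symmetric_data_ic50_at_midpoint():
    # responses exactly symmetric about 0.5 at c* = 1.0
    c = np.array([0.25, 0.5, 1.0, 2.0, 4.0])
    p = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
    res = probit_ic50(DoseResponse(c, p))
    assert res.ic50 == pytest.approx(1.0, rel=1e-6)


def test_probit_scale_equivariance():
    data = simulate_dose_response(0.165, 2.2, DOSES)
    scaled = DoseResponse(data.concentrations * 37.0, data.responses)
    r1 = probit_ic50(data)
    r2 = probit_ic50(scaled)
    assert r2.ic50 == pytest.approx(37.0 * r1.ic50, rel=1e-8)


def test_binomial_noise_median_bias_small():
    rng = np.random.default_rng(11)
    estimates = []
    for _ in range(200):
        d = simulate_dose_response(0.165, 2.2, DOSES, n_replicates=4, rng=rng)
        try:
            estimates.append(probit_ic50(d).ic50)
        except (RuntimeError, ValueError):
            continue
    med = np.median(estimates)
    assert abs(med - 0.165) / 0.165 < 0.05


def test_flat_data_is_degenerate():
    with pytest.raises(ValueError, match="flat"):
        probit_ic50(DoseResponse([1.0, 2.0, 4.0], [0.5, 0.5, 0.5]))


def test_extrapolation_flagged():
    data = simulate_dose_response(50.0, 2.2, DOSES)  # IC50 far above range
    with pytest.warns(UserWarning, match="extrapolation"):
        res = probit_ic50(data)
    assert res.extrapolated


def test_logit_link_option():
    data = simulate_dose_response(0.165, 2.2, DOSES)
    res = probit_ic50(data, link="logit")
    assert res.ic50 == pytest.approx(0.165, rel=0.1)


# --- calibration -----------------------------------------------------------

def test_identity_line_quantification():
    curve = linear_calibration([0.0, 1.0], [0.0, 1.0])
    assert float(quantify(curve, 0.5)) == pytest.approx(0.5)


def test_exact_inversion_of_affine_line():
    curve = linear_calibration([0.0, 1.0, 2.0], [1.0, 3.0, 5.0])  # y = 2x + 1
    assert curve.slope == pytest.approx(2.0)
    assert curve.r_squared == pytest.approx(1.0)
    assert float(quantify(curve, 5.0)) == pytest.approx(2.0)


def test_noiseless_standards_self_quantify_exactly():
    x = np.array([0.0, 100.0, 250.0, 500.0])
    y = 0.004 * x + 0.02
    curve = linear_calibration(x, y)
    np.testing.assert_allclose(quantify(curve, y), x, atol=1e-9)


def test_zero_slope_quantification_error():
    curve = CalibrationCurve(0.0, 1.0, 0.0)
    with pytest.raises(ZeroDivisionError):
        quantify(curve, 2.0)


def test_ols_slope_coverage():
    """True slope inside +-3 SE in >= 95% of seeded noisy calibrations."""
    rng = np.random.default_rng(5)
    x = np.linspace(0.0, 500.0, 6)
    hits = 0
    n_sim = 1000
    for _ in range(n_sim):
        y = 0.004 * x + 0.02 + rng.normal(0.0, 0.05, size=x.size)
        res = stats.linregress(x, y)
        if abs(res.slope - 0.004) <= 3.0 * res.stderr:
            hits += 1
    assert hits / n_sim >= 0.95


# --- ROS inhibition --------------------------------------------------------

@pytest.mark.parametrize("control,treated,expected_rounded", [
    (62.1, 33.4, 46),
    (62.1, 22.82, 63),
    (62.1, 26.31, 58),
])
def test_inhibition_matches_reported_reductions(control, treated, expected_rounded):
    assert round(inhibition_percent(control, treated)) == expected_rounded


def test_inhibition_identity_and_undefined():
    assert inhibition_percent(40.0, 40.0) == 0.0
    with pytest.raises(ZeroDivisionError):
        inhibition_percent(0.0, 10.0)


@given(control=st.floats(1.0, 100.0),
       t1=st.floats(0.0, 100.0), t2=st.floats(0.0, 100.0))
@settings(max_examples=100, deadline=None)
def test_inhibition_antitone_and_bounded(control, t1, t2):
    lo, hi = sorted((t1, t2))
    assert inhibition_percent(control, lo) >= inhibition_percent(control, hi)
    assert inhibition_percent(control, lo) <= 100.0 + 1e-9  # fp roundoff


def test_inhibition_table_thresholds():
    tab = inhibition_table(load_ros_table())
    at48 = tab[tab.timepoint_h == 48]
    pgal_rows = at48[at48.treatment.str.startswith(("PGAL",))]
    assert (pgal_rows.inhibition_percent > 70.0).all()
    his24 = tab[(tab.timepoint_h == 24) & tab.treatment.str.startswith("His")]
    assert (his24.inhibition_percent < 10.0).all()


def test_inhibition_table_requires_control():
    import pandas as pd

    t = pd.DataFrame({"treatment": ["X"], "timepoint_h": [24],
                      "percent_positive": [10.0]})
    with pytest.raises(ValueError, match="control"):
        inhibition_table(t)


def test_control_only_table_is_empty():
    import pandas as pd

    t = pd.DataFrame({"treatment": ["Control"], "timepoint_h": [24],
                      "percent_positive": [50.0]})
    assert len(inhibition_table(t)) == 0
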
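"""Decay kinetics: net decay, conversions, partition, half-lives, split."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mzdecay import (
    SimConfig,
    compute_kinetics,
    fraction_remaining,
    half_life,
    maternal_zygotic_split,
    net_decay,
    partition_early_late,
    percent_reduction,
    percent_remaining,
    simulate_dataset,
    summarize_replicates,
)
from mzdecay.simulate import CLASS_IV, CLASS_V
from conftest import exponential_truth, render


def _profiles_from(rows: dict) -> pd.DataFrame:
    """Profile table from {gene: {cond: median}} mappings."""
    conds = ["U1", "U2", "U3", "E1", "E2", "E3"]
    data = {}
    for cond in conds:
        data[f"median_{cond}"] = [rows[g].get(cond, np.nan) for g in rows]
    return pd.DataFrame(data, index=list(rows))


def test_net_decay_is_late_minus_u1():
    prof = _profiles_from({"g": dict(U1=10.0, U2=9.0, U3=8.5, E1=10.0, E2=9.0, E3=8.7)})
    assert net_decay(prof, "E3").iloc[0] == pytest.approx(-1.3)
    assert net_decay(prof, "U3").iloc[0] == pytest.approx(-1.5)
    flat = _profiles_from({"g": {c: 10.0 for c in ("U1", "U2", "U3", "E1", "E2", "E3")}})
    assert net_decay(flat, "E3").iloc[0] == 0.0


def test_fraction_conversions_match_reported_equivalences():
    # a net decay of -1 halves the signal; -5.8 leaves under 2%
    assert fraction_remaining(-1.0) == pytest.approx(0.5)
    assert percent_reduction(-1.0) == pytest.approx(50.0)
    assert fraction_remaining(0.0) == 1.0
    assert fraction_remaining(-5.8) == pytest.approx(0.0179, abs=2e-4)
    assert fraction_remaining(-5.8) < 0.02
    assert percent_remaining(-1.3) == pytest.approx(40.0, abs=1.5)


def test_partition_components_sum_to_series_change():
    prof = _profiles_from({"g": dict(U1=9.0, U2=8.0, U3=7.0, E1=10.0, E2=9.5, E3=7.0)})
    part = partition_early_late(prof, "E")
    assert part["early_decay"].iloc[0] == pytest.approx(-0.5)
    assert part["late_decay"].iloc[0] == pytest.approx(-2.5)
    flat = _profiles_from({"g": {c: 4.2 for c in ("U1", "U2", "U3", "E1", "E2", "E3")}})
    assert partition_early_late(flat, "U").iloc[0].tolist() == [0.0, 0.0]


def test_exclusively_zygotic_decay_is_late():
    # zygotic machinery only acts after its onset (post-t2), so class IV
    # cohorts show no early decay in embryos and clear late decay
    cfg = SimConfig(n_genes_per_class={CLASS_IV: 150}, noise_sd=0.2, seed=23)
    matrix, _ = simulate_dataset(cfg)
    prof = summarize_replicates(matrix, detection_threshold=5.0)
    part = partition_early_late(prof, "E")
    assert abs(part["early_decay"].median()) < 0.1
    assert part["late_decay"].median() < -0.5


@pytest.mark.parametrize(
    "l2_t2, l2_t3, expected_thalf",
    [
        (10.0, 9.0, 60.0),  # one log2 unit per hour halves each hour
        (10.0, 8.0, 30.0),
        (8.0, 8.0, math.inf),
        (8.0, 9.0, math.inf),  # apparent gain: censored, not clipped
    ],
)
def test_half_life_closed_forms(l2_t2, l2_t3, expected_thalf):
    k, t_half = half_life(l2_t2, l2_t3, dt_min=60.0)
    assert t_half == expected_thalf or t_half == pytest.approx(expected_thalf)
    if math.isfinite(t_half):
        assert t_half == pytest.approx(math.log(2) / k)
        # cross-check against numerically solving 2^(-t/tau) = X(t3)/X(t2)
        ratio = 2.0 ** (l2_t3 - l2_t2)
        tau = -60.0 / math.log2(ratio)
        assert t_half == pytest.approx(tau)
    else:
        assert k <= 0


def test_half_life_requires_positive_dt():
    with pytest.raises(ValueError, match="dt_min"):
        half_life(10.0, 9.0, dt_min=0.0)


@given(
    drop1=st.floats(0.01, 6.0),
    extra=st.floats(0.01, 3.0),
)
@settings(max_examples=50, deadline=None)
def test_half_life_strictly_decreasing_in_drop(drop1, extra):
    _, t1 = half_life(10.0, 10.0 - drop1)
    _, t2 = half_life(10.0, 10.0 - drop1 - extra)
    assert t2 < t1


def test_noise_free_half_life_recovery_is_exact():
    truth = exponential_truth([30.0, 60.0, 120.0])
    matrix = render(truth, noise_sd=0.0, seed=0)
    prof = summarize_replicates(matrix, detection_threshold=5.0)
    _, t_half = half_life(prof["median_U2"].to_numpy(), prof["median_U3"].to_numpy())
    assert np.allclose(t_half, [30.0, 60.0, 120.0], rtol=1e-12)


def test_maternal_zygotic_split_arithmetic():
    prof = _profiles_from({"g": dict(U1=10.0, U2=9.0, U3=8.0, E1=10.0, E2=9.0, E3=7.0)})
    split = maternal_zygotic_split(prof)
    assert split["maternal_component"].iloc[0] == pytest.approx(-2.0)
    assert split["zygotic_component"].iloc[0] == pytest.approx(-1.0)
    flat_u = _profiles_from({"g": dict(U1=9.0, U2=9.0, U3=9.0, E1=9.0, E2=9.0, E3=7.5)})
    split2 = maternal_zygotic_split(flat_u)
    assert split2.iloc[0].tolist() == pytest.approx([0.0, -1.5])


def test_mixed_decay_cohort_is_maternally_dominated_when_rates_say_so():
    cfg = SimConfig(
        n_genes_per_class={CLASS_V: 150},
        noise_sd=0.2,
        seed=29,
        maternal_drop_range=(1.5, 3.0),
        zygotic_drop_range=(0.5, 1.2),
    )
    matrix, _ = simulate_dataset(cfg)
    prof = summarize_replicates(matrix, detection_threshold=5.0)
    split = maternal_zygotic_split(prof)
    dominant = split["maternal_component"].abs() > split["zygotic_component"].abs()
    assert dominant.mean() > 0.5


def test_additivity_invariants_hold_exactly_on_noisy_data(noisy_sim):
    _, matrix, _ = noisy_sim
    prof = summarize_replicates(matrix, detection_threshold=5.0)
    for series in ("U", "E"):
        part = partition_early_late(prof, series)
        series_net = prof[f"median_{series}3"] - prof[f"median_{series}1"]
        resid = (part["early_decay"] + part["late_decay"] - series_net).abs()
        assert resid.max() < 1e-9
    split = maternal_zygotic_split(prof)
    resid = (
        split["maternal_component"] + split["zygotic_component"]
        - (prof["median_E3"] - prof["median_U1"])
    ).abs()
    assert resid.max() < 1e-9


def test_compute_kinetics_routes_series_by_class(noisy_sim):
    _, matrix, truth = noisy_sim
    prof = summarize_replicates(matrix, detection_threshold=5.0)
    labels = truth.set_index("gene_id")["class_label"]
    kin = compute_kinetics(prof, labels)
    routed = kin.join(labels)
    assert (routed.loc[routed["class_label"].isin(["II", "III"]), "series_used"] == "U").all()
    assert (routed.loc[routed["class_label"].isin(["IV", "V"]), "series_used"] == "E").all()
    finite = np.isfinite(kin["half_life_min"])
    assert np.allclose(
        kin.loc[finite, "half_life_min"], math.log(2) / kin.loc[finite, "k"]
    )
    assert (kin.loc[~finite, "k"] <= 0).all()
    assert kin["censored"].equals(kin["k"] <= 0)


def test_half_life_recovery_under_noise_is_reasonable():
    hls = np.repeat([30.0, 60.0, 120.0], 100)
    truth = exponential_truth(hls)
    matrix = render(truth, noise_sd=0.2, seed=19)
    prof = summarize_replicates(matrix, detection_threshold=5.0)
    _, t_half = half_life(prof["median_U2"].to_numpy(), prof["median_U3"].to_numpy())
    rel = np.abs(t_half - hls) / hls
    assert np.median(rel) < 0.15
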
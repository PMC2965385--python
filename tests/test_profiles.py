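"""Replicate summaries, significance calls and sample QC clustering."""

import numpy as np
import pandas as pd
import pytest

from mzdecay import (
    SimConfig,
    cluster_samples,
    flag_significant_change,
    sample_distances,
    simulate_dataset,
    summarize_replicates,
)
from mzdecay.matrix import ExpressionMatrix
from mzdecay.profiles import replicate_groups_recovered
from mzdecay.simulate import CLASS_I, CLASS_II


def _tiny_matrix(u_rows, e_rows=None, n_rep=4):
    """Matrix with identical replicate values per condition from given rows."""
    e_rows = e_rows if e_rows is not None else u_rows
    genes = [f"g{i}" for i in range(len(u_rows))]
    cols, data, design = [], [], []
    for series, rows in (("U", u_rows), ("E", e_rows)):
        for tp in (1, 2, 3):
            for rep in range(1, n_rep + 1):
                name = f"{series}{tp}_rep{rep}"
                cols.append(name)
                design.append({"sample": name, "series": series, "timepoint": tp, "replicate": rep})
                data.append([row[tp - 1] for row in rows])
    values = pd.DataFrame(np.array(data).T, index=genes, columns=cols)
    return ExpressionMatrix(values, pd.DataFrame(design).set_index("sample"))


def test_median_and_sem_of_four_replicates():
    reps = np.array([1.0, 2.0, 3.0, 4.0])
    values = pd.DataFrame(
        {f"{s}{t}_rep{r}": [reps[r - 1]] for s in "UE" for t in (1, 2, 3) for r in (1, 2, 3, 4)},
        index=["g0"],
    )
    design = pd.DataFrame(
        [
            {"sample": f"{s}{t}_rep{r}", "series": s, "timepoint": t, "replicate": r}
            for s in "UE" for t in (1, 2, 3) for r in (1, 2, 3, 4)
        ]
    ).set_index("sample")
    prof = summarize_replicates(ExpressionMatrix(values, design), detection_threshold=0.0)
    assert prof.loc["g0", "median_U1"] == pytest.approx(2.5)
    assert prof.loc["g0", "sem_U1"] == pytest.approx(np.std(reps, ddof=1) / 2, abs=1e-9)
    assert prof.loc["g0", "sem_U1"] == pytest.approx(0.6455, abs=5e-4)


def test_single_replicate_sem_is_zero_by_convention():
    cfg = SimConfig(n_genes_per_class={CLASS_I: 3}, n_replicates=1, noise_sd=0.0, seed=0)
    matrix, _ = simulate_dataset(cfg)
    prof = summarize_replicates(matrix, detection_threshold=0.0)
    assert (prof.filter(like="sem_") == 0).all().all()


def test_medians_track_simulated_truth_within_noise():
    cfg = SimConfig(n_genes_per_class={CLASS_I: 1000}, noise_sd=0.2, seed=31)
    matrix, truth = simulate_dataset(cfg)
    prof = summarize_replicates(matrix, detection_threshold=5.0)
    mad = (prof["median_U1"].to_numpy() - truth["maternal_level_log2"].to_numpy())
    assert np.mean(np.abs(mad)) < 0.2


def test_detection_uses_threshold():
    m = _tiny_matrix([(6.0, 6.0, 6.0), (4.0, 4.0, 4.0)])
    prof = summarize_replicates(m, detection_threshold=5.0)
    assert prof["detected_U1"].tolist() == [True, False]


def test_duplicated_samples_have_zero_correlation_distance():
    rng = np.random.default_rng(0)
    base = rng.normal(size=50)
    m = _tiny_matrix([tuple(x) for x in rng.normal(8, 1, size=(50, 3))])
    values = m.values.copy()
    values["U1_rep2"] = values["U1_rep1"]  # exact duplicate
    d = sample_distances(values)
    assert d.loc["U1_rep1", "U1_rep2"] == pytest.approx(0.0, abs=1e-12)


def test_anticorrelated_samples_have_distance_two():
    x = np.linspace(0, 1, 30)
    values = pd.DataFrame({"a": x, "b": -x + 1})
    d = sample_distances(values)
    assert d.loc["a", "b"] == pytest.approx(2.0)


def _separable_qc_matrix(noise_sd=0.2, n_rep=4, seed=0):
    """24 samples whose six conditions carry orthogonal gene-block
    signatures: the well-posed setting for replicate-group QC."""
    rng = np.random.default_rng(seed)
    n_genes = 600
    cols, design, data = [], [], []
    for ci, (series, tp) in enumerate([(s, t) for s in "UE" for t in (1, 2, 3)]):
        signal = np.full(n_genes, 8.0)
        signal[100 * ci : 100 * (ci + 1)] += 2.0
        for rep in range(1, n_rep + 1):
            name = f"{series}{tp}_rep{rep}"
            cols.append(name)
            design.append({"sample": name, "series": series, "timepoint": tp, "replicate": rep})
            data.append(signal + rng.normal(0, noise_sd, n_genes))
    values = pd.DataFrame(
        np.column_stack(data), index=[f"g{i}" for i in range(n_genes)], columns=cols
    )
    return ExpressionMatrix(values, pd.DataFrame(design).set_index("sample"))


def test_clustering_recovers_replicate_groups_when_conditions_are_separable():
    matrix = _separable_qc_matrix()
    clustering = cluster_samples(matrix, k=6)
    assert clustering.excluded == []
    assert replicate_groups_recovered(matrix, clustering)


def test_decay_sim_clustering_separates_start_and_end_states(noisy_sim):
    # pre-onset samples (U1/E1) and late embryos (E3) carry opposite
    # deviation signatures; no 4-way cluster may mix them
    _, matrix, _ = noisy_sim
    clustering = cluster_samples(matrix, k=4)
    design = matrix.design.loc[clustering.labels.index]
    start = clustering.labels[(design["timepoint"] == 1)]
    end = clustering.labels[(design["series"] == "E") & (design["timepoint"] == 3)]
    assert set(start) & set(end) == set()


def test_clustering_invariant_to_sample_order():
    matrix = _separable_qc_matrix(seed=5)
    rng = np.random.default_rng(3)
    perm = rng.permutation(list(matrix.values.columns))
    shuffled = ExpressionMatrix(matrix.values[perm], matrix.design)
    labels_a = cluster_samples(matrix, k=6).labels
    labels_b = cluster_samples(shuffled, k=6).labels
    # same partition: co-membership must agree for every sample pair
    pa = {s: labels_a[s] for s in labels_a.index}
    pb = {s: labels_b[s] for s in labels_b.index}
    samples = list(labels_a.index)
    for i, s1 in enumerate(samples):
        for s2 in samples[i + 1:]:
            assert (pa[s1] == pa[s2]) == (pb[s1] == pb[s2])


def test_zero_variance_sample_excluded_with_warning(noisy_sim):
    _, matrix, _ = noisy_sim
    values = matrix.values.copy()
    values["U1_rep1"] = 5.0
    degenerate = ExpressionMatrix(values, matrix.design)
    with pytest.warns(UserWarning, match="zero-variance"):
        clustering = cluster_samples(degenerate, k=6)
    assert clustering.excluded == ["U1_rep1"]
    assert "U1_rep1" not in clustering.labels.index


def test_identical_conditions_are_never_flagged():
    m = _tiny_matrix([(8.0, 8.0, 8.0)] * 5)
    # add distinct replicate values so variance is nonzero but equal
    values = m.values.copy()
    for s in values.columns:
        values[s] = values[s] + [0.1, -0.1, 0.05, -0.05, 0.0]
    m2 = ExpressionMatrix(values, m.design)
    table = flag_significant_change(m2, ("U", 3), ("U", 1), direction="less")
    assert (table["p"] >= 0.5).all()
    assert not table["flag"].any()


def test_power_on_two_log2_maternal_drop():
    cfg = SimConfig(n_genes_per_class={CLASS_II: 200}, noise_sd=0.2, seed=13,
                    maternal_drop_range=(2.0, 2.0))
    matrix, _ = simulate_dataset(cfg)
    table = flag_significant_change(matrix, ("U", 3), ("U", 1), direction="less", fdr=0.1)
    assert table["flag"].mean() >= 0.95


def test_false_positive_rate_controlled_on_stable_genes():
    cfg = SimConfig(n_genes_per_class={CLASS_I: 400}, noise_sd=0.2, seed=17)
    matrix, _ = simulate_dataset(cfg)
    table = flag_significant_change(matrix, ("U", 3), ("U", 1), direction="less", fdr=0.1)
    assert table["flag"].mean() <= 0.10


def test_bh_flags_are_subset_of_raw_p_flags(noisy_sim):
    _, matrix, _ = noisy_sim
    table = flag_significant_change(matrix, ("U", 3), ("U", 1), direction="less", fdr=0.1)
    raw = table["p"] <= 0.1
    assert (table["q"] >= table["p"] - 1e-15).all()
    assert not (table["flag"] & ~raw).any()


def test_unknown_direction_rejected(noisy_sim):
    _, matrix, _ = noisy_sim
    with pytest.raises(ValueError, match="direction"):
        flag_significant_change(matrix, ("U", 3), ("U", 1), direction="down")
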
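"""Statistical engine vs closed-form oracles; aggregation and summary table."""

import numpy as np
import pytest
from scipy import stats as sps

from csfflow import (
    CohortSpec,
    UnsynchronizedError,
    VelocityWaveform,
    anova_tukey,
    build_table1,
    generate_cohort,
    group_mean_waveform,
    paired_t,
    peak_velocities,
    summarize_group,
    synchronize_cohort,
    unpaired_t,
)
from csfflow.stats import csf_tonsil_anova, format_table1, peak_samples
from conftest import noiseless_spec


# ---------------------------------------------------------------------------
# closed-form oracles (textbook formulas; only distribution CDFs from scipy)
# ---------------------------------------------------------------------------

def oracle_unpaired_t(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    df = na + nb - 2
    return t, df, 2 * sps.t.sf(abs(t), df)


def oracle_paired_t(pairs):
    d = np.asarray([p[0] - p[1] for p in pairs], float)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
    df = d.size - 1
    return t, df, 2 * sps.t.sf(abs(t), df)


def oracle_anova(groups):
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb, dfw = len(groups) - 1, all_vals.size - len(groups)
    f = (ssb / dfb) / (ssw / dfw)
    return f, (dfb, dfw), sps.f.sf(f, dfb, dfw)


def oracle_tukey_p(groups, i, j):
    k = len(groups)
    dfw = sum(g.size for g in groups) - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in groups) / dfw
    gi, gj = groups[i], groups[j]
    se = np.sqrt(msw / 2 * (1 / gi.size + 1 / gj.size))
    q = abs(gi.mean() - gj.mean()) / se
    return sps.studentized_range.sf(q, k, dfw)


UNPAIRED_FIXTURES = [
    ([1.0, 2.0, 3.0], [2.0, 3.0, 4.0]),
    ([0.3, 0.5, 0.4, 0.6], [0.2, 0.1, 0.3]),
    ([0.76, 0.5, 1.2, 0.9, 0.33], [0.31, 0.2, 0.45, 0.28]),
]

PAIRED_FIXTURES = [
    [(1.0, 2.0), (2.0, 4.0), (3.0, 5.0)],
    [(0.9, 0.3), (0.7, 0.4), (1.2, 0.2), (0.5, 0.5)],
]

ANOVA_FIXTURES = [
    [[1.0, 2.0, 3.0], [2.0, 3.0, 4.0], [6.0, 7.0, 8.0]],
    [[0.3, 0.4, 0.2, 0.35], [2.2, 2.9, 1.8], [0.7, 0.9, 0.6, 0.8, 0.75]],
]


@pytest.mark.parametrize("a,b", UNPAIRED_FIXTURES)
def test_unpaired_t_matches_closed_form(a, b):
    res = unpaired_t(a, b)
    t, df, p = oracle_unpaired_t(a, b)
    assert res.statistic == pytest.approx(t, rel=1e-9)
    assert res.df == df
    assert res.p_value == pytest.approx(p, rel=1e-9)


def test_unpaired_t_hand_value():
    res = unpaired_t([1, 2, 3], [2, 3, 4])
    assert res.statistic == pytest.approx(-np.sqrt(1.5), rel=1e-12)  # -1.224744...
    assert res.df == 4


@pytest.mark.parametrize("pairs", PAIRED_FIXTURES)
def test_paired_t_matches_closed_form(pairs):
    res = paired_t(pairs)
    t, df, p = oracle_paired_t(pairs)
    assert res.statistic == pytest.approx(t, rel=1e-9)
    assert res.df == df
    assert res.p_value == pytest.approx(p, rel=1e-9)


def test_paired_t_hand_value():
    # diffs [-1, -2, -2]: mean -5/3, sd 1/sqrt(3) -> t = -5
    res = paired_t([(1, 2), (2, 4), (3, 5)])
    assert res.statistic == pytest.approx(-5.0, rel=1e-12)
    assert res.df == 2


@pytest.mark.parametrize("groups", ANOVA_FIXTURES)
def test_anova_and_tukey_match_closed_form(groups):
    arrays = [np.asarray(g) for g in groups]
    labels = [f"g{i}" for i in range(len(groups))]
    anova, pairs = anova_tukey(dict(zip(labels, arrays)))
    f, df, p = oracle_anova(arrays)
    assert anova.statistic == pytest.approx(f, rel=1e-9)
    assert anova.df == df
    assert anova.p_value == pytest.approx(p, rel=1e-9)
    idx = {lbl: i for i, lbl in enumerate(labels)}
    for pair in pairs:
        i, j = idx[pair.comparison[0]], idx[pair.comparison[1]]
        assert pair.p_value == pytest.approx(oracle_tukey_p(arrays, i, j), rel=1e-6)


def test_anova_hand_value():
    # SSB=42 (df 2), SSW=6 (df 6) -> F = 21
    anova, _ = anova_tukey({"a": [1, 2, 3], "b": [2, 3, 4], "c": [6, 7, 8]})
    assert anova.statistic == pytest.approx(21.0, rel=1e-12)


def test_two_group_anova_equals_squared_t(rng):
    a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 9)
    anova, _ = anova_tukey({"a": a, "b": b})
    t = unpaired_t(a, b)
    assert anova.statistic == pytest.approx(t.statistic**2, rel=1e-9)
    assert anova.p_value == pytest.approx(t.p_value, rel=1e-9)


def test_tukey_p_never_below_unadjusted_pairwise_p(rng):
    groups = {f"g{i}": rng.normal(i * 0.2, 1, 8) for i in range(3)}
    _, pairs = anova_tukey(groups)
    for pair in pairs:
        raw = unpaired_t(groups[pair.comparison[0]], groups[pair.comparison[1]])
        assert pair.p_value >= raw.p_value - 1e-12


def test_degenerate_inputs():
    same = [1.0, 1.0, 1.0]
    res = unpaired_t(same, same)
    assert res.statistic == 0.0 and res.p_value == 1.0 and res.degenerate
    res = unpaired_t(same, [2.0, 2.0, 2.0])
    assert res.p_value == 0.0 and res.degenerate
    res = paired_t([(1.0, 1.0), (2.0, 2.0)])
    assert res.statistic == 0.0 and res.p_value == 1.0
    anova, pairs = anova_tukey({"a": same, "b": same, "c": same})
    assert anova.statistic == 0.0 and anova.p_value == 1.0
    assert all(p.p_value == 1.0 for p in pairs)


def test_welch_option_differs_under_heteroscedasticity():
    a = [1.0, 1.1, 0.9, 1.05, 0.95]
    b = [2.0, 4.0, 0.5, 3.5, 1.0, 2.5]
    pooled = unpaired_t(a, b)
    welch = unpaired_t(a, b, welch=True)
    assert welch.df != pooled.df


# ---------------------------------------------------------------------------
# peaks, group means, bands
# ---------------------------------------------------------------------------

def test_peak_velocities_extrema():
    assert peak_velocities(VelocityWaveform("tonsil", np.zeros(50))) == (0.0, 0.0)
    values = np.zeros(50)
    values[3], values[10] = -1.0, 2.0
    assert peak_velocities(VelocityWaveform("tonsil", values)) == (2.0, -1.0)


def test_group_mean_band_closed_form_two_sessions():
    """Two sessions at 1.0 and 3.0: mean 2.0, half-width t(0.975,1)*sd/sqrt(2)."""
    spec = noiseless_spec(n_control=2, n_preop=0, n_postop=0)
    sessions = synchronize_cohort(generate_cohort(spec)[0])
    sessions = [
        sessions[0].replace(waveforms={**sessions[0].waveforms,
                                       "tonsil": VelocityWaveform("tonsil", np.full(50, 1.0))}),
        sessions[1].replace(waveforms={**sessions[1].waveforms,
                                       "tonsil": VelocityWaveform("tonsil", np.full(50, 3.0))}),
    ]
    gw = group_mean_waveform(sessions, "tonsil")
    t975 = 12.7062047361747  # t quantile, df=1
    assert np.allclose(gw.mean, 2.0)
    assert np.allclose(gw.upper - gw.mean, t975 * np.sqrt(2.0) / np.sqrt(2.0), rtol=1e-10)
    assert np.all(gw.lower <= gw.mean) and np.all(gw.mean <= gw.upper)


def test_identical_sessions_have_zero_band_width():
    spec = noiseless_spec(n_control=4, n_preop=0, n_postop=0)
    sessions = synchronize_cohort(generate_cohort(spec)[0])
    gw = group_mean_waveform(sessions, "ventral_sa")
    assert np.allclose(gw.upper, gw.lower)
    assert np.allclose(gw.mean, sessions[0].waveforms["ventral_sa"].values)


def test_band_coverage_is_calibrated():
    """Monte-Carlo: the 95% band covers the true waveform ~95% of the time.

    Amplitude spread is switched off so per-bin errors are the i.i.d.
    measurement noise; the truth is the noiseless synchronized template.
    Coverage is recorded at a rest-phase bin (early diastole), where the
    waveform is flat and a one-bin trigger jitter cannot bias the value,
    over 200 replicate cohorts.
    """
    truth_spec = noiseless_spec(n_control=1, n_preop=0, n_postop=0)
    true_wave = synchronize_cohort(generate_cohort(truth_spec)[0])[0].waveforms["tonsil"].values
    hits = 0
    reps = 200
    b = 0  # rest phase: template is zero in a neighbourhood of this bin
    assert true_wave[b] == 0.0
    for r in range(reps):
        spec = noiseless_spec(n_control=10, n_preop=0, n_postop=0, noise_sd=0.05, seed=3000 + r)
        sessions = synchronize_cohort(generate_cohort(spec)[0])
        gw = group_mean_waveform(sessions, "tonsil")
        hits += bool(gw.lower[b] <= true_wave[b] <= gw.upper[b])
    # binomial(200, 0.95): 3 sigma is about +/-0.046
    assert 0.90 <= hits / reps <= 0.995


def test_group_operations_require_synchronized_sessions():
    sessions, _ = generate_cohort(noiseless_spec(n_control=3, n_preop=0, n_postop=0))
    with pytest.raises(UnsynchronizedError):
        group_mean_waveform(sessions, "tonsil")
    with pytest.raises(UnsynchronizedError):
        build_table1(sessions)


# ---------------------------------------------------------------------------
# summary table
# ---------------------------------------------------------------------------

def test_table_rows_and_equal_groups_give_p_one():
    spec = noiseless_spec()
    table_equal = {k: spec.amplitude_table[("control", k[1])] for k in spec.amplitude_table}
    rostral_equal = {g: spec.cord_rostral_table["control"] for g in ("control", "preop", "postop")}
    eq_spec = noiseless_spec(amplitude_table=table_equal, cord_rostral_table=rostral_equal)
    sessions = synchronize_cohort(generate_cohort(eq_spec)[0])
    table = build_table1(sessions)
    assert list(table.index) == [
        "tonsil", "ventral_sa", "dorsal_sa", "syrinx", "cord_rostral", "cord_caudal", "medulla",
    ]
    assert np.all(table["p_control_vs_preop"] == 1.0)
    assert np.all(table["p_preop_vs_postop"] == 1.0)
    assert not table["sig_control_vs_preop"].any()


def test_table_on_study_sized_cohort(synced_study_cohort):
    _, synced, _ = synced_study_cohort
    table = build_table1(synced)
    assert (table["preop_n"] == 17).all()
    assert (table["postop_n"] == 18).all()
    assert (table["control_n"] == 21).all()
    # cord rostral peaks are negative, caudal peaks positive
    assert table.loc["cord_rostral", "preop_mean"] < 0 < table.loc["cord_caudal", "preop_mean"]
    text = format_table1(table)
    assert "tonsil" in text and "p(c vs pre)" in text


def test_paired_comparison_excludes_unpaired_subject(synced_study_cohort):
    _, synced, _ = synced_study_cohort
    preop = [s for s in synced if s.group_label == "preop"]
    postop = [s for s in synced if s.group_label == "postop"]
    from csfflow.stats import _paired_peaks

    pairs = _paired_peaks(preop, postop, "tonsil", "caudal")
    assert len(pairs) == 17  # patient-017 has no preoperative session


def test_empty_group_marks_row_unavailable():
    spec = CohortSpec(n_control=4, n_preop=4, n_postop=0, seed=2)
    synced = synchronize_cohort(generate_cohort(spec)[0])
    table = build_table1(synced)
    assert np.isnan(table.loc["tonsil", "postop_mean"])
    assert np.isnan(table.loc["tonsil", "p_preop_vs_postop"])


def test_csf_tonsil_anova_detects_velocity_differences(synced_study_cohort):
    _, synced, _ = synced_study_cohort
    anova, pairs = csf_tonsil_anova(synced, "preop")
    assert anova.comparison == ("tonsil", "dorsal_sa", "ventral_sa")
    assert anova.statistic > 0 and anova.p_value < 0.05
    assert len(pairs) == 3


def test_summarize_group_collects_peaks_and_waveforms(synced_study_cohort):
    _, synced, _ = synced_study_cohort
    summary = summarize_group(synced, "preop")
    assert summary.n_sessions == 17
    assert set(summary.waveforms) == {"tonsil", "cord", "ventral_sa", "dorsal_sa", "syrinx", "medulla"}
    mean, sd = summary.peak_caudal["tonsil"]
    peaks = peak_samples([s for s in synced if s.group_label == "preop"], "tonsil")
    assert mean == pytest.approx(peaks.mean()) and sd == pytest.approx(peaks.std(ddof=1))
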
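import shutil

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from rivalry.survival import (
    ReportDataset,
    fit_cox_mixed,
    proportionality_check,
    read_reports,
    records_from_reports,
    screen_subjects,
    synth_reports,
)

HAVE_R = shutil.which("Rscript") is not None


def _dataset(rows, blocks=None):
    reports = pd.DataFrame(
        rows,
        columns=["subject", "block", "T_frame_ms", "block_duration_ms",
                 "report_time_ms"],
    )
    if blocks is None:
        blocks = reports[
            ["subject", "block", "T_frame_ms", "block_duration_ms"]
        ].drop_duplicates()
    return ReportDataset(reports=reports, blocks=blocks)


def test_record_construction_from_report_times():
    ds = _dataset([("A", 0, 300.0, 3000.0, 1200.0), ("A", 0, 300.0, 3000.0, 2400.0)])
    rec = records_from_reports(ds)
    assert rec["T_D_frames"].tolist() == [4, 4, 2]
    assert rec["censored"].tolist() == [False, False, True]
    assert rec["epoch"].tolist() == [1, 2, 3]


def test_empty_block_yields_single_censored_record():
    blocks = pd.DataFrame(
        [("A", 0, 300.0, 3000.0)],
        columns=["subject", "block", "T_frame_ms", "block_duration_ms"],
    )
    ds = _dataset([], blocks=blocks)
    rec = records_from_reports(ds)
    assert len(rec) == 1
    assert rec.iloc[0]["T_D_frames"] == 10 and rec.iloc[0]["censored"]


@settings(derandomize=True, max_examples=60)
@given(
    times=st.lists(
        st.floats(1.0, 299_000.0), min_size=0, max_size=40, unique=True
    ),
    T_frame=st.sampled_from([300.0, 350.0, 450.0]),
)
def test_censoring_conserves_block_length(times, T_frame):
    """Total duration (censored + uncensored) equals the block length in
    frames up to per-interval rounding."""
    rows = [("A", 0, T_frame, 300_000.0, t) for t in sorted(times)]
    blocks = pd.DataFrame(
        [("A", 0, T_frame, 300_000.0)],
        columns=["subject", "block", "T_frame_ms", "block_duration_ms"],
    )
    rec = records_from_reports(_dataset(rows, blocks))
    total = rec["T_D_frames"].sum()
    n_intervals = len(rec)
    assert abs(total - 300_000.0 / T_frame) <= 0.5 * n_intervals + 1


def test_screening_drops_inadequate_subject():
    """Sixteen subjects, one with fewer than two switches anywhere:
    fifteen remain."""
    rows = []
    for s in range(16):
        subj = f"S{s:02d}"
        n_reports = 1 if s == 7 else 8
        for b in range(2):
            for k in range(n_reports):
                rows.append((subj, b, 300.0, 60_000.0, 5_000.0 * (k + 1)))
    rec = records_from_reports(_dataset(rows))
    kept, excl = screen_subjects(rec)
    assert kept["subject"].nunique() == 15
    assert "S07" not in set(kept["subject"])
    assert (excl["subject"] == "S07").sum() >= 1


def test_screening_is_identity_when_all_pass():
    ds = synth_reports(n_subjects=4, seed=3)
    rec = records_from_reports(ds)
    kept, excl = screen_subjects(rec)
    assert len(kept) == len(rec)
    assert excl.empty


def test_synth_reports_seed_deterministic():
    a = synth_reports(n_subjects=3, seed=9).reports
    b = synth_reports(n_subjects=3, seed=9).reports
    pd.testing.assert_frame_equal(a, b)
    c = synth_reports(n_subjects=3, seed=10).reports
    assert not a.equals(c)


def test_null_durations_are_exponential():
    ds = synth_reports(
        n_subjects=25,
        blocks=((300, 30), (300, 30)),
        tframe_log_hr=0.0,
        epoch_log_hr=0.0,
        frailty_variance=0.0,
        baseline_mean_frames=30.0,
        seed=5,
    )
    d = ds.reports.sort_values(["subject", "block", "report_time_ms"])
    gaps = (
        d.groupby(["subject", "block"])["report_time_ms"].diff().dropna().to_numpy()
    )
    first = d.groupby(["subject", "block"])["report_time_ms"].first().to_numpy()
    frames = np.concatenate([gaps, first]) / 300.0
    assert len(frames) >= 10_000
    p = stats.kstest(frames, "expon", args=(0, frames.mean())).pvalue
    assert p > 0.01


def test_negative_tframe_coefficient_lengthens_durations():
    common = dict(n_subjects=6, epoch_log_hr=0.0, frailty_variance=0.0, seed=2)
    ds = synth_reports(tframe_log_hr=np.log(0.99), **common)
    rec = records_from_reports(ds)
    means = rec[~rec.censored].groupby("T_frame_ms")["T_D_frames"].mean()
    assert means.loc[300.0] < means.loc[450.0]


def test_fit_requires_two_covariate_values_and_events():
    ds = synth_reports(n_subjects=4, blocks=((300, 3),), seed=1)
    rec = records_from_reports(ds)
    with pytest.raises(ValueError, match="covariate"):
        fit_cox_mixed(rec, "T_frame", backend="lifelines")
    none_events = rec.copy()
    none_events["censored"] = True
    with pytest.raises(ValueError, match="events"):
        fit_cox_mixed(none_events, "epoch", backend="lifelines")


@pytest.mark.parametrize("backend", ["lifelines"] + (["r"] if HAVE_R else []))
def test_fit_recovers_known_coefficient(backend):
    log_hr = np.log(0.99)
    ds = synth_reports(
        n_subjects=10,
        blocks=((300, 3), (350, 3), (400, 3), (450, 3)),
        tframe_log_hr=log_hr,
        epoch_log_hr=0.0,
        frailty_variance=0.02,
        seed=17,
    )
    rec = records_from_reports(ds)
    fit = fit_cox_mixed(rec, "T_frame", backend=backend)
    assert fit.hazard_ratio > 0
    assert fit.n_events <= fit.n_samples
    assert abs(fit.coef - log_hr) <= 2 * fit.se
    if backend == "r":
        assert fit.random_effect_variance >= 0
        assert fit.frailty_by_subject


@pytest.mark.skipif(not HAVE_R, reason="Rscript not on PATH")
def test_proportionality_check_passes_under_proportional_hazards():
    ds = synth_reports(n_subjects=10, seed=23)
    rec = records_from_reports(ds)
    fit = fit_cox_mixed(rec, "T_frame", backend="r")
    p = proportionality_check(fit, rec)
    assert p > 0.05


def _time_varying_dataset(seed, beta_early=0.25, t_break=6.0):
    """Oracle generator with a coefficient that reverses after t_break
    frames: a strong proportional-hazards violation."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(16):
        subj = f"S{s:02d}"
        for b, T in enumerate((300.0, 450.0)):
            x = (T - 375.0) / 75.0
            t = 0.0
            while True:
                lam1 = np.exp(beta_early * x) / 12.0
                lam2 = np.exp(-beta_early * x) / 12.0
                u = rng.exponential(1.0 / lam1)
                if u > t_break:
                    u = t_break + rng.exponential(1.0 / lam2)
                t_next = t + u * T
                if t_next >= 150_000.0:
                    break
                rows.append((subj, b, T, 150_000.0, t_next))
                t = t_next
    return _dataset(rows)


def test_proportionality_check_detects_time_varying_effect():
    hits = 0
    n_rep = 6
    for seed in range(n_rep):
        rec = records_from_reports(_time_varying_dataset(seed))
        fit = fit_cox_mixed(rec, "T_frame",
                            backend="r" if HAVE_R else "lifelines")
        if proportionality_check(fit, rec) < 0.05:
            hits += 1
    assert hits > n_rep / 2


def test_proportionality_check_rejects_single_covariate_value():
    ds = synth_reports(n_subjects=4, blocks=((300, 3),), seed=1)
    rec = records_from_reports(ds)
    fit_stub = fit_cox_mixed(
        records_from_reports(synth_reports(n_subjects=4, seed=0)),
        "T_frame",
        backend="lifelines",
    )
    with pytest.raises(ValueError, match="covariate"):
        proportionality_check(fit_stub, rec)


def test_read_reports_with_column_mapping(tmp_path):
    df = pd.DataFrame(
        {
            "subj": ["A", "A"],
            "blk": [0, 0],
            "period": [300.0, 300.0],
            "dur": [3000.0, 3000.0],
            "rt": [900.0, 2100.0],
        }
    )
    path = tmp_path / "deposit.csv"
    df.to_csv(path, index=False)
    ds = read_reports(
        path,
        column_map={
            "subj": "subject",
            "blk": "block",
            "period": "T_frame_ms",
            "dur": "block_duration_ms",
            "rt": "report_time_ms",
        },
    )
    assert ds.provenance == "deposited"
    rec = records_from_reports(ds)
    assert rec["T_D_frames"].tolist() == [3, 4, 3]


def test_report_times_must_increase():
    with pytest.raises(ValueError, match="increase"):
        _dataset(
            [("A", 0, 300.0, 3000.0, 1200.0), ("A", 0, 300.0, 3000.0, 1200.0)]
        )
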
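"""Replicate discovery, estpost parsing, burn-in/thin arithmetic, traces."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinekit.posterior import (
    PosteriorSamples,
    combine_bgc_output,
    discover_replicates,
    parse_estpost_file,
    retained_indices,
    trace_stats,
)


def _touch(d, *names):
    for n in names:
        (d / n).write_text("0.0\n")


def test_discover_groups_and_sorts_by_replicate(tmp_path):
    _touch(tmp_path, "run_stat_alpha_2", "run_stat_alpha_1",
           "run_stat_beta_1", "run_stat_beta_2")
    groups = discover_replicates(tmp_path, "run")
    assert sorted(groups) == ["alpha", "beta"]
    assert [p.name for p in groups["alpha"]] == ["run_stat_alpha_1", "run_stat_alpha_2"]


def test_discover_parses_zero_padded_replicate(tmp_path):
    _touch(tmp_path, "run_stat_alpha_01", "run_stat_beta_01")
    groups = discover_replicates(tmp_path, "run")
    assert len(groups["alpha"]) == 1


def test_discover_unequal_alpha_beta_replicates_errors(tmp_path):
    _touch(tmp_path, "run_stat_alpha_1", "run_stat_alpha_2", "run_stat_beta_1")
    with pytest.raises(ValueError, match="replicate"):
        discover_replicates(tmp_path, "run")


def test_discover_passes_unknown_params_with_warning(tmp_path, caplog):
    _touch(tmp_path, "run_stat_rho_1")
    with caplog.at_level("WARNING"):
        groups = discover_replicates(tmp_path, "run")
    assert "rho" in groups


def test_parse_entities_as_rows_transposes(tmp_path):
    f = tmp_path / "f"
    f.write_text("0.1,0.2,0.3\n-0.1,0.0,0.1\n")
    mat = parse_estpost_file(f, orientation="entities_as_rows")
    assert mat.shape == (3, 2)
    assert np.allclose(mat[:, 0], [0.1, 0.2, 0.3])


def test_parse_single_row_lnl(tmp_path):
    f = tmp_path / "f"
    f.write_text("1.0,2.0,3.0\n")
    assert parse_estpost_file(f).shape == (3, 1)


def test_parse_ragged_rows_error_names_row(tmp_path):
    f = tmp_path / "f"
    f.write_text("0.1,0.2\n0.3\n")
    with pytest.raises(ValueError, match="row 2"):
        parse_estpost_file(f)


def test_parse_non_numeric_cell_rejected(tmp_path):
    f = tmp_path / "f"
    f.write_text("0.1,abc\n")
    with pytest.raises(ValueError, match="non-numeric"):
        parse_estpost_file(f)


# ------------------------------------------------------ burn-in / thinning

def _write_replicates(tmp_path, n_draws, n_rep, n_entities=3):
    files = []
    for r in range(n_rep):
        f = tmp_path / f"rep{r}"
        rows = []
        for e in range(n_entities):
            rows.append(",".join(str(float(1000 * r + i)) for i in range(n_draws)))
        f.write_text("\n".join(rows) + "\n")
        files.append(f)
    return files


def test_worked_thinning_case_two_reps_1000_draws(tmp_path):
    files = _write_replicates(tmp_path, 1000, 2)
    ps = combine_bgc_output(files, burnin=200, thin=2)
    assert ps.n_draws == 800
    assert (ps.replicate_of_sample == 0).sum() == 400
    # retained draws are burnin-anchored: indices 200, 202, ...
    assert ps.samples[0, 0] == 200.0
    assert ps.samples[1, 0] == 202.0


def test_no_burnin_no_thin_is_plain_concatenation(tmp_path):
    files = _write_replicates(tmp_path, 50, 3)
    ps = combine_bgc_output(files, burnin=0, thin=1)
    assert ps.n_draws == 150
    assert np.allclose(ps.samples[:, 0], np.concatenate(
        [1000 * r + np.arange(50.0) for r in range(3)]))


def test_burnin_at_last_draw_keeps_one(tmp_path):
    files = _write_replicates(tmp_path, 1000, 1)
    ps = combine_bgc_output(files, burnin=999, thin=1)
    assert ps.n_draws == 1


def test_burnin_exceeding_replicate_length_names_file(tmp_path):
    files = _write_replicates(tmp_path, 10, 1)
    with pytest.raises(ValueError, match="rep0"):
        combine_bgc_output(files, burnin=10)


@settings(deadline=None, max_examples=200, derandomize=True)
@given(
    s=st.integers(1, 50),
    burnin=st.integers(0, 49),
    thin=st.integers(1, 10),
)
def test_retained_count_matches_brute_force_enumeration(s, burnin, thin):
    if burnin >= s:
        burnin = s - 1
    brute = [i for i in range(s) if i >= burnin and (i - burnin) % thin == 0]
    idx = retained_indices(s, burnin, thin)
    assert list(idx) == brute
    assert len(idx) == int(np.ceil((s - burnin) / thin))


def test_recombining_with_no_burnin_is_idempotent(tmp_path):
    files = _write_replicates(tmp_path, 100, 2)
    ps = combine_bgc_output(files, burnin=20, thin=3)
    again = np.vstack([ps.samples[idx][retained_indices(len(idx), 0, 1)]
                       for idx in ps.replicate_slices()])
    assert np.array_equal(again, ps.samples)


def test_thin_then_concat_equals_concat_then_blockwise_thin(tmp_path):
    files = _write_replicates(tmp_path, 60, 2)
    ps = combine_bgc_output(files, burnin=10, thin=4)
    blocks = []
    for r, f in enumerate(files):
        full = combine_bgc_output([f], burnin=0, thin=1)
        blocks.append(full.samples[retained_indices(full.n_draws, 10, 4)])
    assert np.array_equal(np.vstack(blocks), ps.samples)


# ------------------------------------------------------------- trace stats

def _ps(samples_by_rep):
    samples = np.vstack([np.atleast_2d(s).T if np.asarray(s).ndim == 1 else s
                         for s in samples_by_rep])
    rep = np.concatenate([np.full(len(s), r) for r, s in enumerate(samples_by_rep)])
    return PosteriorSamples("alpha", samples, rep, 0, 1,
                            [len(s) for s in samples_by_rep])


def test_constant_trace_has_zero_variance_and_autocorr():
    ps = _ps([np.full(10, 3.0)])
    _, summary = trace_stats(ps)
    assert summary.loc[0, "variance"] == 0.0
    assert summary.loc[0, "lag1_autocorr"] == 0.0


def test_per_replicate_means_are_separated():
    ps = _ps([np.zeros(100), np.full(100, 10.0)])
    _, summary = trace_stats(ps)
    assert summary.loc[summary.replicate == 0, "mean"].iloc[0] == 0.0
    assert summary.loc[summary.replicate == 1, "mean"].iloc[0] == 10.0


def test_ar1_trace_recovers_its_coefficient():
    rng = np.random.default_rng(7)
    n, phi_true = 10_000, 0.5
    x = np.empty(n)
    x[0] = rng.normal()
    for t in range(1, n):
        x[t] = phi_true * x[t - 1] + rng.normal() * np.sqrt(1 - phi_true**2)
    _, summary = trace_stats(_ps([x]))
    assert summary.loc[0, "lag1_autocorr"] == pytest.approx(0.5, abs=0.05)
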
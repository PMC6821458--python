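"""Model/Results interface, serialization, spiking input path, and CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

from glmcfc import AnalysisConfig, CFCModel, ConditionCFCModel
from glmcfc.cli import main
from glmcfc.simulate import simulate_spiking, simulate_two_condition


def test_results_structure_and_summary(pac_results):
    res = pac_results
    assert set(res.fits) == {"phi", "alow", "joint"}
    assert res.r_pac >= 0 and res.r_aac >= 0
    text = res.summary()
    assert "R_PAC" in text and "R_AAC" in text and "spline control points: 10" in text
    d = res.to_dict()
    json.dumps(d)  # serializable
    assert len(d["fits"]["joint"]["beta"]) == 13


def test_significance_updates_result(pac_results):
    ps = pac_results.significance(("r_pac",), n_surrogates=20, seed=5)
    assert pac_results.result.p_pac == ps["r_pac"]
    assert 0.0005 <= ps["r_pac"] <= 1.0


def test_model_requires_signal_or_decomposition():
    with pytest.raises(ValueError, match="decomposition"):
        CFCModel()


def test_from_decomposition_no_double_trim(pac_decomposition):
    m = CFCModel.from_decomposition(pac_decomposition, trim=False)
    assert len(m.decomposition) == len(pac_decomposition)


def test_config_echoed(pac_results):
    cfg = pac_results.to_dict()["config"]
    assert cfg["n_alow_grid"] == 640 and cfg["n_phi_grid"] == 100
    assert cfg["alow_quantiles"] == [0.05, 0.95]
    assert cfg["n_surrogates"] == 1000 and cfg["n_bootstrap"] == 10000


def test_spiking_detected_by_rpac_not_mi():
    """Amplitude-dependent preferred phase: the GLM statistic sees coupling
    the phase-binned index misses."""
    detected = 0
    mis = []
    for seed in (0, 1, 2):
        sim = simulate_spiking(duration=20.0, seed=seed)
        model = CFCModel.from_phase_amplitude(sim.a_high, sim.phi_low,
                                              sim.a_low, sim.fs)
        res = model.fit()
        ps = res.significance(("r_pac",), n_surrogates=40, seed=seed)
        detected += ps["r_pac"] < 0.05
        mis.append(res.modulation_index().mi)
    assert detected >= 2
    assert np.median(mis) < 0.01


def test_condition_model_end_to_end():
    sim = simulate_two_condition("step_pac", duration=24.0, seed=21)
    res = ConditionCFCModel(sim.v, sim.condition, sim.fs).fit()
    assert len(res.fit_full.beta) == 24 and len(res.fit_amp.beta) == 14
    p = res.significance(n_surrogates=40, seed=2)
    assert res.result.p == p
    assert "R_PAC,condition" in res.summary()
    with pytest.raises(ValueError, match="condition indicator"):
        ConditionCFCModel(sim.v, None, sim.fs)


# ---------------------------------------------------------------------------
# command-line interface

def test_cli_simulate_analyze_roundtrip(tmp_path):
    runner = CliRunner()
    csv = tmp_path / "sim.csv"
    r = runner.invoke(main, ["simulate", "--scenario", "pac", "--i-pac", "1.0",
                             "--duration", "8", "--seed", "5",
                             "--out", str(csv)])
    assert r.exit_code == 0, r.output
    assert csv.exists() and csv.with_suffix(".csv.json").exists()
    data = np.loadtxt(csv, delimiter=",", skiprows=1)
    assert data.shape[1] == 2 and len(data) == 8000

    # the analyze command consumes a single-column file
    volts = tmp_path / "v.csv"
    np.savetxt(volts, data[:, 1])
    out = tmp_path / "report.json"
    args = ["analyze", str(volts), "--fs", "1000", "--n-surrogates", "10",
            "--n-bootstrap", "20", "--seed", "1", "--out", str(out)]
    r = runner.invoke(main, args)
    assert r.exit_code == 0, r.output
    rep = json.loads(out.read_text())
    assert {"r_pac", "r_aac", "p_values", "mi", "config", "seed"} <= set(rep)

    # byte-identical on rerun with the same seed
    out2 = tmp_path / "report2.json"
    r = runner.invoke(main, args[:-1] + [str(out2)])
    assert r.exit_code == 0
    assert out.read_text() == out2.read_text()


def test_cli_analyze_condition(tmp_path):
    runner = CliRunner()
    sim = simulate_two_condition("step_pac", duration=12.0, seed=3)
    path = tmp_path / "cond.csv"
    np.savetxt(path, np.column_stack([sim.v, sim.condition]), delimiter=",")
    out = tmp_path / "cond.json"
    r = runner.invoke(main, ["analyze-condition", str(path), "--fs", "1000",
                             "--n-surrogates", "10", "--seed", "2",
                             "--out", str(out)])
    assert r.exit_code == 0, r.output
    rep = json.loads(out.read_text())
    assert "r_pac_condition" in rep
    assert len(rep["fits"]["joint+condition"]["beta"]) == 24
    assert len(rep["fits"]["alow+condition"]["beta"]) == 14


def test_cli_study_runs(tmp_path):
    runner = CliRunner()
    out = tmp_path / "study.json"
    r = runner.invoke(main, ["study", "--scenario", "pac", "--n-runs", "2",
                             "--n-surrogates", "8", "--duration", "8",
                             "--seed", "4", "--out", str(out)])
    assert r.exit_code == 0, r.output
    rep = json.loads(out.read_text())
    assert "detection_rates" in rep and rep["n_runs"] == 2


def test_cli_bad_input_fails_cleanly(tmp_path):
    bad = tmp_path / "bad.csv"
    bad.write_text("not,numbers\n")
    runner = CliRunner()
    r = runner.invoke(main, ["analyze", str(bad), "--fs", "1000"])
    assert r.exit_code != 0
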
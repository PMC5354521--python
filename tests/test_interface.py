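"""Tabular I/O, config parsing, pipeline runs, and the CLI surface."""

import json

import pandas as pd
import pytest
from click.testing import CliRunner

from cellenergetics import cli, io, pipeline
from cellenergetics.errors import ConfigurationError, SchemaError


def _write(path, text):
    path.write_text(text)
    return path


def test_species_table_round_trip(tmp_path):
    frame = pd.DataFrame(
        {
            "species": ["a", "b"],
            "group": ["bacteria", "eukaryote"],
            "cell_volume_um3": [1.0, 44.0],
            "division_time_h": [0.5, 2.5],
        }
    )
    path = tmp_path / "t.tsv"
    io.write_species_table(frame, path)
    loaded = io.read_species_table(path)
    pd.testing.assert_frame_equal(loaded.frame, frame)
    assert loaded.rejected == []


def test_empty_file_and_missing_columns_are_schema_errors(tmp_path):
    with pytest.raises(SchemaError):
        io.read_species_table(_write(tmp_path / "empty.tsv", ""))
    with pytest.raises(SchemaError, match="cell_volume_um3"):
        io.read_species_table(_write(tmp_path / "nocol.tsv", "species\na\n"))


def test_missing_cell_is_flagged_not_rejected(tmp_path):
    path = _write(
        tmp_path / "m.tsv",
        "species\tcell_volume_um3\tdivision_time_h\na\t1.0\t\nb\t2.0\t3.0\n",
    )
    table = io.read_species_table(path)
    assert len(table) == 2
    assert ("a", "division_time_h") in table.missing_cells()


def test_unparseable_and_negative_rows_rejected_with_row_numbers(tmp_path):
    path = _write(
        tmp_path / "bad.tsv",
        "species\tcell_volume_um3\na\tfast\nb\t2.0\nc\t-1.0\n",
    )
    with pytest.warns(UserWarning, match="rejected"):
        table = io.read_species_table(path)
    assert list(table.frame["species"]) == ["b"]
    assert any("row 2" in msg for msg in table.rejected)
    assert any("row 4" in msg for msg in table.rejected)


def test_duplicate_species_labels_rejected(tmp_path):
    path = _write(tmp_path / "dup.tsv", "species\tcell_volume_um3\na\t1\na\t2\n")
    with pytest.raises(SchemaError, match="duplicate"):
        io.read_species_table(path)


def test_read_lipid_composition(tmp_path):
    path = _write(
        tmp_path / "lipids.tsv",
        "name\tdomain\tchain_length\tunsaturations\tfraction\ttotal_cost_override\treduced_cost_override\n"
        "PG\tbacteria\t16\t0\t0.8\t\t\n"
        "cardiolipin\teukaryote\t18\t2\t0.2\t640\t240\n",
    )
    comp = io.read_lipid_composition(path)
    from cellenergetics import mean_membrane_cost

    assert mean_membrane_cost(comp) == pytest.approx(0.8 * 320 + 0.2 * 640)


def test_read_config(tmp_path):
    path = _write(
        tmp_path / "cfg.txt",
        "# comment\nseed = 3\nsd_log10 = 0.15\ngroup = eukaryote\n",
    )
    cfg = io.read_config(path)
    assert cfg == {"seed": 3, "sd_log10": 0.15, "group": "eukaryote"}
    with pytest.raises(SchemaError):
        io.read_config(_write(tmp_path / "bad.txt", "seed 3\n"))


def test_pipeline_runs_and_reproduces_mito_cost_figure(tmp_path):
    bundle = pipeline.run_pipeline({"seed": 11, "n_species": 20}, tmp_path / "out")
    # the ~15% mitochondrial membrane share of the growth budget at V=1
    assert bundle.budget["mito_membrane_relative_cost"] == pytest.approx(0.15, abs=0.005)
    report = json.loads(bundle.report_path.read_text())
    assert set(report) == {"fits", "budget", "membrane_apportionment"}
    assert report["fits"]["mito_total_um2"]["exponent"] == pytest.approx(0.99, abs=0.15)
    assert bundle.log_path.exists()
    assert "seed = 11" in bundle.log_path.read_text()


def test_pipeline_rerun_is_byte_identical(tmp_path):
    cfg = {"seed": 5, "n_species": 15, "group": "bacteria"}
    b1 = pipeline.run_pipeline(cfg, tmp_path / "r1")
    b2 = pipeline.run_pipeline(cfg, tmp_path / "r2")
    assert b1.report_path.read_bytes() == b2.report_path.read_bytes()
    assert b1.species_table_path.read_bytes() == b2.species_table_path.read_bytes()


def test_pipeline_requires_seed(tmp_path):
    with pytest.raises(ConfigurationError, match="seed"):
        pipeline.run_pipeline({}, tmp_path)


def test_cli_lipid_cost_and_combine():
    runner = CliRunner()
    res = runner.invoke(cli.main, ["lipid-cost", "-l", "16", "-u", "0", "--domain", "bacteria"])
    assert res.exit_code == 0
    assert json.loads(res.output)["cost_atp"] == 320.0
    res = runner.invoke(cli.main, ["combine", "0.97", "0.04", "divide", "-0.17", "0.11"])
    assert res.exit_code == 0
    out = json.loads(res.output)
    assert out["exponent"] == pytest.approx(1.14)
    assert round(out["se"], 2) == 0.12


def test_cli_simulate_then_fit(tmp_path):
    runner = CliRunner()
    table_path = tmp_path / "species.tsv"
    res = runner.invoke(
        cli.main,
        ["simulate", "--seed", "2", "--group", "eukaryote", "--n", "30",
         "--sd-log10", "0", "--out", str(table_path)],
    )
    assert res.exit_code == 0, res.output
    res = runner.invoke(
        cli.main,
        ["fit", "--input", str(table_path), "--x", "cell_volume_um3", "--y", "ribosomes_per_cell"],
    )
    assert res.exit_code == 0, res.output
    fit = json.loads(res.output)
    assert fit["exponent"] == pytest.approx(0.82, rel=1e-9)
    assert fit["coefficient"] == pytest.approx(7586.0, rel=1e-9)


def test_cli_run_pipeline(tmp_path):
    cfg = tmp_path / "cfg.txt"
    cfg.write_text("seed = 4\nn_species = 12\n")
    runner = CliRunner()
    res = runner.invoke(cli.main, ["run", "--config", str(cfg), "--outdir", str(tmp_path / "out")])
    assert res.exit_code == 0, res.output
    assert (tmp_path / "out" / "report.json").exists()
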
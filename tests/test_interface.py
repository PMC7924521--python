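import json
import warnings

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import intervalscore as ics
from _data import separable_xy
from intervalscore.cli import main


@pytest.fixture(scope="module")
def fitted(tmp_path_factory):
    """Fit a small model through the CLI and keep the artifacts around."""
    root = tmp_path_factory.mktemp("cli")
    X, y = separable_xy(250, seed=2)
    df = pd.DataFrame(X, columns=["marker"])
    df["outcome"] = np.where(y > 0, 1, 0)
    data = root / "train.csv"
    df.to_csv(data, index=False)
    cfg = root / "config.yaml"
    cfg.write_text(
        "var_types: [continuous]\nmethod: lp\ncv_folds: 4\n"
        "weight_grid: [-1, 1, 5]\ngamma_grid: [1, 10]\nseed: 0\n"
    )
    model_path = root / "model.json"
    runner = CliRunner()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = runner.invoke(main, [
            "fit", "--data", str(data), "--label-col", "outcome",
            "--config", str(cfg), "--out", str(model_path),
        ])
    assert res.exit_code == 0, res.output
    return root, data, model_path, X, y


def test_fit_minimal_defaults_all_main_effects(tmp_path):
    rng = np.random.default_rng(3)
    X = rng.uniform(size=(150, 2))
    y = np.where(X[:, 0] > 0.5, 1, 0)
    df = pd.DataFrame(X, columns=["a", "b"])
    df["label"] = y
    data = tmp_path / "d.csv"
    df.to_csv(data, index=False)
    out = tmp_path / "m.json"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = CliRunner().invoke(main, [
            "fit", "--data", str(data), "--label-col", "label",
            "--choose-weight", "-1", "--out", str(out),
        ])
    assert res.exit_code == 0, res.output
    model = ics.ScoreModel.from_json(out)
    assert model.n_variables >= 1


def test_missing_label_column_errors(tmp_path):
    data = tmp_path / "d.csv"
    pd.DataFrame({"a": [1.0, 2.0]}).to_csv(data, index=False)
    res = CliRunner().invoke(main, [
        "fit", "--data", str(data), "--label-col", "nope", "--out",
        str(tmp_path / "m.json"),
    ])
    assert res.exit_code != 0
    assert "nope" in res.output


def test_predict_round_trip_matches_library(fitted, tmp_path):
    root, data, model_path, X, y = fitted
    out = tmp_path / "pred.csv"
    res = CliRunner().invoke(main, [
        "predict", "--model", str(model_path), "--data", str(data),
        "--out", str(out),
    ])
    assert res.exit_code == 0, res.output
    pred = pd.read_csv(out)
    assert list(pred.columns) == ["row_id", "score", "risk", "predicted_class"]
    model = ics.ScoreModel.from_json(model_path)
    scores, risks, cls = model.apply(X)
    assert np.array_equal(pred["score"].to_numpy(), scores)
    assert np.allclose(pred["risk"].to_numpy(), risks)
    assert np.array_equal(pred["predicted_class"].to_numpy(dtype=float), cls)


def test_predict_single_row_and_permuted_columns(fitted, tmp_path):
    root, data, model_path, X, y = fitted
    df = pd.read_csv(data)
    one = tmp_path / "one.csv"
    # permute columns; header-driven mapping must restore order
    df[df.columns[::-1]].head(1).to_csv(one, index=False)
    out = tmp_path / "pred1.csv"
    res = CliRunner().invoke(main, [
        "predict", "--model", str(model_path), "--data", str(one),
        "--out", str(out),
    ])
    assert res.exit_code == 0, res.output
    pred = pd.read_csv(out)
    model = ics.ScoreModel.from_json(model_path)
    s, r, c = model.apply(X[:1])
    assert pred["score"].iloc[0] == s[0]


def test_assess_reports_metrics(fitted, tmp_path):
    root, data, model_path, X, y = fitted
    report = tmp_path / "rep.json"
    res = CliRunner().invoke(main, [
        "assess", "--model", str(model_path), "--data", str(data),
        "--label-col", "outcome", "--report", str(report),
    ])
    assert res.exit_code == 0, res.output
    assert "AUC" in res.output
    rep = json.loads(report.read_text())
    assert rep["auc"] == pytest.approx(1.0, abs=1e-9)
    assert rep["accuracy"] == pytest.approx(1.0, abs=1e-9)


class TestRender:
    def test_txt_contains_every_threshold_point_and_risk(self, fitted):
        *_, model_path, X, y = fitted
        model = ics.ScoreModel.from_json(model_path)
        doc = ics.render_scorecard(model, format="txt")
        for e in model.effects:
            for tau in e.margins[0].thresholds:
                assert f"{tau:.4g}" in doc
            for p in np.asarray(e.points).ravel():
                assert f"{int(p):+d}" in doc
        for s, r in model.risk_table.items():
            assert f"score {s:+d}" in doc
            assert f"{r * 100:.1f}%" in doc

    def test_intercept_only_model_renders_risk_strip(self):
        model = ics.ScoreModel(
            method="lp", effects=[], b0=0.0, b1=0.0,
            risk_table={0: 0.4}, label_map={"negative": 0.0, "positive": 1.0},
        )
        doc = ics.render_scorecard(model, format="txt")
        assert "risk profile" in doc and "40.0%" in doc
        svg = ics.render_scorecard(model, format="svg")
        assert svg.startswith("<svg") and "rect" in svg

    def test_svg_equal_points_share_fill(self):
        vb = ics.VariableBinning("continuous", np.array([0.5]), None, 2)
        model = ics.ScoreModel(
            method="lp",
            effects=[
                ics.EffectPoints("u", "main", (1,), [vb], np.array([0, 2])),
                ics.EffectPoints("v", "main", (2,), [vb], np.array([2, 0])),
            ],
            b0=0.0, b1=1.0,
            risk_table={s: 0.5 for s in range(5)},
            label_map={"negative": 0.0, "positive": 1.0},
        )
        svg = ics.render_scorecard(model, format="svg")
        effect_part = svg.split("risk profile")[0]  # exclude the risk strip
        fills = {}
        import re
        for rect, label in re.findall(
            r'<rect[^>]*fill="(#\w+)"[^>]*/>\s*<text[^>]*>([+-]\d+)</text>',
            effect_part,
        ):
            fills.setdefault(label, set()).add(rect)
        assert fills["+2"] and fills["+0"]
        assert all(len(v) == 1 for v in fills.values())
        assert svg.count("<rect") >= 4

    def test_three_interval_effect_renders_cells_and_thresholds(self):
        vb = ics.VariableBinning("continuous", np.array([0.3, 0.7]), None, 3)
        model = ics.ScoreModel(
            method="lp",
            effects=[ics.EffectPoints("m", "main", (1,), [vb], np.array([0, 1, 3]))],
            b0=0.0, b1=1.0,
            risk_table={s: 0.5 for s in range(4)},
            label_map={"negative": 0.0, "positive": 1.0},
        )
        txt = ics.render_scorecard(model, format="txt")
        assert "0.3" in txt and "0.7" in txt
        svg = ics.render_scorecard(model, format="svg")
        assert svg.count('height="36"') >= 3
        assert "0.3" in svg and "0.7" in svg

    def test_grayscale_maps_magnitude(self):
        vb = ics.VariableBinning("continuous", np.array([0.5]), None, 2)
        model = ics.ScoreModel(
            method="lp",
            effects=[ics.EffectPoints("m", "main", (1,), [vb], np.array([-2, 2]))],
            b0=0.0, b1=1.0,
            risk_table={s: 0.5 for s in range(-2, 3)},
            label_map={"negative": 0.0, "positive": 1.0},
        )
        svg = ics.render_scorecard(model, format="svg", grayscale=True)
        import re
        fills = re.findall(r'fill="(#\w+)"', svg)
        # |+2| and |-2| share the same gray
        assert fills[0] == fills[1]
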
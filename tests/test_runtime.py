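"""Training loop, pretraining, checkpointing, prediction, CLI consistency."""

import json

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from lnpfusion import chemio, runtime, splits, synthgen
from lnpfusion.cli import main as cli_main
from lnpfusion.runtime import RunConfig

TINY = dict(width=16, layers_3d=1, n_heads=2, n_kernels=4, state_dim=4,
            batch_size=8, lr=3e-3)


@pytest.fixture(scope="module")
def tiny_setup():
    lib = synthgen.generate_library(n_heads=6, n_tails=4, seed=21)
    lib = synthgen.assign_labels(lib, seed=22)
    split = splits.scaffold_split(lib.records, seed=0)
    return lib.records, split


class TestTrain:
    def test_smoke_run_writes_loadable_checkpoint(self, tiny_setup, tmp_path):
        records, split = tiny_setup
        cfg = RunConfig.desk(**TINY, epochs=2, seed=0)
        result = runtime.train(cfg, records, split)
        assert len(result.log) == 2
        path = tmp_path / "ck.npz"
        runtime.save_checkpoint(result.checkpoint, path)
        loaded = runtime.load_checkpoint(path)
        model = runtime.model_from_checkpoint(loaded)
        rec = records[0]
        pred = model.predict_label(chemio.featurize_3d(rec, seed=0), chemio.tokenize(rec))
        assert np.isfinite(pred)

    def test_loss_decreases_with_training(self, tiny_setup):
        """Median over 3 seeds: epoch-10 training loss below epoch-1 loss."""
        records, split = tiny_setup
        firsts, lasts = [], []
        for seed in (0, 1, 2):
            cfg = RunConfig.desk(**TINY, epochs=10, seed=seed)
            log = runtime.train(cfg, records, split).log
            firsts.append(log[0]["train_loss"])
            lasts.append(log[9]["train_loss"])
        assert np.median(lasts) < np.median(firsts)

    def test_same_config_and_seed_reproduce_metric_log(self, tiny_setup):
        records, split = tiny_setup
        cfg = RunConfig.desk(**TINY, epochs=2, seed=7)
        log_a = runtime.train(cfg, records, split).log
        log_b = runtime.train(cfg, records, split).log
        assert log_a == log_b

    def test_artifacts_embed_config_hash_and_seed(self, tiny_setup):
        records, split = tiny_setup
        cfg = RunConfig.desk(**TINY, epochs=1, seed=3)
        result = runtime.train(cfg, records, split)
        assert result.checkpoint["config_hash"] == cfg.hash()
        assert all(row["config_hash"] == cfg.hash() for row in result.log)
        assert all(row["seed"] == 3 for row in result.log)

    def test_unlabelled_training_molecule_rejected(self, tiny_setup):
        records, split = tiny_setup
        broken = [
            chemio.LipidRecord(r.id, r.smiles, None if i == 0 else r.label)
            for i, r in enumerate(records)
        ]
        with pytest.raises(ValueError):
            runtime.train(RunConfig.desk(**TINY, epochs=1), broken, split)


class TestPretrain:
    @pytest.fixture(scope="class")
    def corpus(self):
        lib = synthgen.generate_library(n_heads=4, n_tails=2, seed=31)
        return [r.smiles for r in lib.records]

    def test_masked_type_accuracy_above_chance(self, corpus):
        cfg = RunConfig.desk(**TINY, epochs=1, seed=0)
        ckpt = runtime.pretrain(cfg, corpus[:6], n_steps=25)
        acc = runtime.masked_type_accuracy(ckpt, corpus[6:], seed=1)
        assert acc > 1.0 / 30.0

    def test_pretraining_reduces_its_own_objective(self, corpus):
        cfg = RunConfig.desk(**TINY, epochs=1, seed=0)
        ckpt = runtime.pretrain(cfg, corpus[:6], n_steps=25)
        log = ckpt["log"]
        assert log[-1]["total"] < log[0]["total"]

    def test_loading_pretrained_encoder_changes_initial_training_loss(self, tiny_setup, corpus):
        records, split = tiny_setup
        cfg = RunConfig.desk(**TINY, epochs=1, seed=0)
        ckpt = runtime.pretrain(cfg, corpus[:4], n_steps=10)
        cold = runtime.train(cfg, records, split).log[0]["train_loss"]
        warm = runtime.train(cfg, records, split, init_state=ckpt["state"]).log[0]["train_loss"]
        assert cold != warm

    def test_zero_mask_rate_warns_and_zeroes_type_loss(self, corpus):
        cfg = RunConfig.desk(**TINY, epochs=1, seed=0, mask_rate=0.0)
        with pytest.warns(UserWarning):
            ckpt = runtime.pretrain(cfg, corpus[:3], n_steps=2)
        assert all(row["type_ce"] == 0.0 for row in ckpt["log"])


class TestPredictAndCLI:
    @pytest.fixture(scope="class")
    def trained(self, tiny_setup, tmp_path_factory):
        records, split = tiny_setup
        cfg = RunConfig.desk(**TINY, epochs=3, seed=0)
        result = runtime.train(cfg, records, split)
        path = tmp_path_factory.mktemp("ckpt") / "model.npz"
        runtime.save_checkpoint(result.checkpoint, path)
        return records, path, result

    def test_one_prediction_per_input_row_in_order(self, trained):
        records, path, _ = trained
        ckpt = runtime.load_checkpoint(path)
        df = runtime.predict(ckpt, records[:5])
        assert list(df["id"]) == [r.id for r in records[:5]]
        assert df["prediction"].notna().all()

    def test_repeated_invocation_identical(self, trained):
        records, path, _ = trained
        ckpt = runtime.load_checkpoint(path)
        a = runtime.predict(ckpt, records[:4])["prediction"].to_numpy()
        b = runtime.predict(ckpt, records[:4])["prediction"].to_numpy()
        assert np.array_equal(a, b)

    def test_cli_predict_matches_in_process_forward_rank_order(self, trained, tmp_path):
        records, path, _ = trained
        subset = records[:5]
        csv = tmp_path / "in.csv"
        csv.write_text(
            "id,smiles,label,cell_line\n"
            + "\n".join(f"{r.id},{r.smiles},{r.label},Hela" for r in subset)
            + "\n"
        )
        out = tmp_path / "pred.csv"
        runner = CliRunner()
        res = runner.invoke(
            cli_main,
            ["predict", str(csv), "--checkpoint", str(path), "--out", str(out)],
        )
        assert res.exit_code == 0, res.output
        import pandas as pd

        cli_preds = pd.read_csv(out)["prediction"].to_numpy()
        api_preds = runtime.predict(runtime.load_checkpoint(path), subset)[
            "prediction"
        ].to_numpy()
        assert np.array_equal(np.argsort(cli_preds), np.argsort(api_preds))

    def test_cli_explain_emits_per_atom_scores(self, trained, tmp_path):
        records, path, _ = trained
        csv = tmp_path / "in.csv"
        rec = records[0]
        csv.write_text(f"id,smiles,label,cell_line\n{rec.id},{rec.smiles},{rec.label},Hela\n")
        out = tmp_path / "scores.csv"
        res = CliRunner().invoke(
            cli_main, ["explain", str(csv), "--checkpoint", str(path), "--out", str(out)]
        )
        assert res.exit_code == 0, res.output
        import pandas as pd

        df = pd.read_csv(out)
        n_atoms = chemio.featurize_3d(rec, seed=0).n_atoms
        assert len(df) == n_atoms
        assert ((df["score"] > 0) & (df["score"] < 1)).all()

    def test_cli_simulate_split_cliffs_roundtrip(self, tmp_path):
        runner = CliRunner()
        lib_csv = tmp_path / "lib.csv"
        res = runner.invoke(
            cli_main,
            ["simulate", "--n-heads", "6", "--n-tails", "4", "--cliff-pairs", "2",
             "--seed", "5", "--out", str(lib_csv)],
        )
        assert res.exit_code == 0, res.output
        split_csv = tmp_path / "split.csv"
        res = runner.invoke(
            cli_main, ["split", str(lib_csv), "--method", "scaffold", "--out", str(split_csv)]
        )
        assert res.exit_code == 0, res.output
        cliff_json = tmp_path / "cliffs.json"
        res = runner.invoke(cli_main, ["cliffs", str(lib_csv), "--out", str(cliff_json)])
        assert res.exit_code == 0, res.output
        report = json.loads(cliff_json.read_text())
        assert "Hela" in report and report["Hela"]["n_cliff_pairs"] >= 2
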
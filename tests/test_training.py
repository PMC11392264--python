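"""Schedule, training-loop bookkeeping, checkpoints, and the CLI surface."""

import csv

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from polypseg.cli import main as cli_main
from polypseg.exceptions import DivergenceError
from polypseg.losses import LossConfig
from polypseg.network import DLGRAFENet, NetworkConfig
from polypseg.synthetic import SyntheticSpec, generate_dataset
from polypseg.training import (
    TrainConfig,
    evaluate_checkpoint,
    evaluate_model,
    load_checkpoint,
    lr_at_epoch,
    predict_probabilities,
    predict_to_dir,
    save_checkpoint,
    train,
)
from polypseg import image_io

TINY_NET = dict(filters=(8, 8, 16, 16, 32), input_size=64,
                decoder_widths=(16, 16, 8, 8), efe_reduction=2,
                ssia_mid_channels=8, head_width=8)


def tiny_train_config(**kw):
    defaults = dict(batch_size=2, epochs=2, seed=0,
                    network=NetworkConfig(**TINY_NET),
                    validate_every_epoch=False, out_dir="unused")
    defaults.update(kw)
    return TrainConfig(**defaults)


class TestSchedule:
    def test_endpoints_match_the_recipe(self):
        cfg = tiny_train_config(epochs=200)
        assert lr_at_epoch(cfg, 0) == pytest.approx(1e-4)
        assert lr_at_epoch(cfg, 199) == pytest.approx(1e-5)

    def test_cosine_midpoint_is_the_mean(self):
        cfg = tiny_train_config(epochs=201)
        assert lr_at_epoch(cfg, 100) == pytest.approx(5.5e-5)

    def test_monotone_decay(self):
        cfg = tiny_train_config(epochs=50)
        rates = [lr_at_epoch(cfg, e) for e in range(50)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_out_of_range_epoch_rejected(self):
        cfg = tiny_train_config(epochs=10)
        with pytest.raises(ValueError):
            lr_at_epoch(cfg, 10)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            tiny_train_config(min_lr=1e-3)
        with pytest.raises(ValueError):
            tiny_train_config(batch_size=0)


@pytest.fixture(scope="module")
def tiny_dataset(tmp_path_factory):
    root = tmp_path_factory.mktemp("data")
    spec = SyntheticSpec(image_size=64, seed=0)
    generate_dataset(spec, 4, root)
    return root


class TestTrainLoop:
    def test_one_epoch_bookkeeping(self, tiny_dataset, tmp_path):
        cfg = tiny_train_config(
            epochs=1, out_dir=str(tmp_path / "run"),
            train_images=str(tiny_dataset / "images"),
            train_masks=str(tiny_dataset / "masks"),
            val_images=str(tiny_dataset / "images"),
            val_masks=str(tiny_dataset / "masks"),
            validate_every_epoch=True)
        result = train(cfg)
        assert len(result.history) == 1
        assert result.best_checkpoint.exists()
        assert result.last_checkpoint.exists()
        with open(result.history_csv) as fh:
            rows = list(csv.DictReader(fh))
        assert len(rows) == 1
        assert float(rows[0]["val_dsc"]) >= 0.0

    def test_seeded_runs_reproduce_loss_trajectory(self, small_batch, tmp_path):
        images, masks = small_batch
        losses = []
        for run in ("a", "b"):
            cfg = tiny_train_config(epochs=1, out_dir=str(tmp_path / run))
            result = train(cfg, data=(images, masks))
            losses.append(result.history[0]["loss"])
        assert losses[0] == pytest.approx(losses[1], rel=1e-5)

    def test_local_component_zero_iff_disabled(self, small_batch, tmp_path):
        images, masks = small_batch
        on = train(tiny_train_config(epochs=1, out_dir=str(tmp_path / "on")),
                   data=(images, masks))
        off_cfg = tiny_train_config(
            epochs=1, out_dir=str(tmp_path / "off"),
            loss=LossConfig(lambda_local=0.0))
        off = train(off_cfg, data=(images, masks))
        assert on.history[0]["loss_local"] > 0.0
        assert off.history[0]["loss_local"] == 0.0

    def test_use_local_loss_switch_zeroes_component(self, small_batch, tmp_path):
        cfg = tiny_train_config(
            epochs=1, out_dir=str(tmp_path / "sw"),
            network=NetworkConfig(**TINY_NET, use_local_loss=False))
        result = train(cfg, data=small_batch)
        assert result.history[0]["loss_local"] == 0.0

    def test_divergence_guard(self, small_batch, tmp_path, monkeypatch):
        import polypseg.training as train_mod
        monkeypatch.setattr(
            train_mod, "total_loss",
            lambda out, q, cfg: (out.prediction, {"total": float("nan"),
                                                  "global": 0.0, "local": 0.0}))
        with pytest.raises(DivergenceError):
            train(tiny_train_config(epochs=1, out_dir=str(tmp_path / "div")),
                  data=small_batch)


class TestCheckpoints:
    def test_save_load_round_trip(self, tmp_path, small_batch):
        net = DLGRAFENet(NetworkConfig(**TINY_NET), seed=3)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, net)
        restored = load_checkpoint(path)
        images, _ = small_batch
        np.testing.assert_allclose(
            predict_probabilities(net, images),
            predict_probabilities(restored, images), atol=1e-7)

    def test_unknown_schema_rejected(self, tmp_path):
        import json
        meta = np.frombuffer(json.dumps({"schema": "other"}).encode(), dtype=np.uint8)
        np.savez(tmp_path / "bad.npz", __meta__=meta)
        with pytest.raises(ValueError):
            load_checkpoint(tmp_path / "bad.npz")


class TestEvaluation:
    def test_perfect_oracle_predictor_scores_one(self, tiny_dataset):
        manifest = image_io.list_pairs(tiny_dataset / "images",
                                       tiny_dataset / "masks")
        _, masks = image_io.load_batch(manifest, 64)

        def oracle(images):
            return masks[:, None].astype(np.float32)

        summary, rows, _ = evaluate_model(oracle, manifest, 64)
        assert summary.dsc == 1.0 and summary.iou == 1.0
        assert len(rows) == len(manifest)

    def test_all_background_dataset_uses_empty_convention(self, tmp_path):
        spec = SyntheticSpec(image_size=64, n_lesions_range=(0, 0), seed=2)
        generate_dataset(spec, 2, tmp_path)
        manifest = image_io.list_pairs(tmp_path / "images", tmp_path / "masks")
        summary, _, _ = evaluate_model(
            lambda images: np.zeros((len(images), 1, 64, 64), dtype=np.float32),
            manifest, 64)
        assert summary.dsc == 1.0  # empty prediction vs empty mask

    def test_evaluate_checkpoint_agrees_with_direct_metrics(self, tiny_dataset,
                                                            tmp_path):
        from polypseg.metrics import evaluate_dataset
        net = DLGRAFENet(NetworkConfig(**TINY_NET), seed=4)
        ckpt = tmp_path / "m.npz"
        save_checkpoint(ckpt, net)
        out_csv = tmp_path / "metrics.csv"
        summary = evaluate_checkpoint(ckpt, tiny_dataset / "images",
                                      tiny_dataset / "masks", out_csv,
                                      pr_csv=tmp_path / "pr.csv")
        manifest = image_io.list_pairs(tiny_dataset / "images",
                                       tiny_dataset / "masks")
        images, masks = image_io.load_batch(manifest, 64)
        probs = predict_probabilities(net, images)
        direct, _ = evaluate_dataset(list(probs[:, 0]), list(masks))
        assert summary.dsc == pytest.approx(direct.dsc, abs=1e-9)
        with open(out_csv) as fh:
            rows = list(csv.DictReader(fh))
        assert rows[-1]["identifier"] == "summary"
        assert (tmp_path / "pr.csv").exists()


class TestPredict:
    def test_masks_written_with_matching_stems_and_idempotent(self, tiny_dataset,
                                                              tmp_path):
        net = DLGRAFENet(NetworkConfig(**TINY_NET), seed=5)
        ckpt = tmp_path / "m.npz"
        save_checkpoint(ckpt, net)
        out_a = tmp_path / "a"
        out_b = tmp_path / "b"
        stems = predict_to_dir(ckpt, tiny_dataset / "images", out_a)
        assert len(stems) == 4
        for stem in stems:
            assert (out_a / f"{stem}.png").exists()
        predict_to_dir(ckpt, tiny_dataset / "images", out_b)
        for stem in stems:
            assert (out_a / f"{stem}.png").read_bytes() == \
                (out_b / f"{stem}.png").read_bytes()


class TestCLI:
    def test_synth_and_train_round_trip(self, tmp_path):
        runner = CliRunner()
        data_dir = tmp_path / "data"
        res = runner.invoke(cli_main, ["synth", "--out", str(data_dir),
                                       "--n", "2", "--size", "64", "--seed", "1"])
        assert res.exit_code == 0, res.output
        cfg = {
            "batch_size": 2, "epochs": 1, "seed": 0,
            "network": {**TINY_NET, "filters": list(TINY_NET["filters"]),
                        "decoder_widths": list(TINY_NET["decoder_widths"])},
            "train_images": str(data_dir / "images"),
            "train_masks": str(data_dir / "masks"),
            "out_dir": str(tmp_path / "run"),
            "validate_every_epoch": False,
        }
        cfg_path = tmp_path / "cfg.yaml"
        cfg_path.write_text(yaml.safe_dump(cfg))
        res = runner.invoke(cli_main, ["train", "--config", str(cfg_path)])
        assert res.exit_code == 0, res.output
        ckpt = tmp_path / "run" / "last.npz"
        assert ckpt.exists()
        res = runner.invoke(cli_main, [
            "evaluate", "--ckpt", str(ckpt),
            "--images", str(data_dir / "images"),
            "--masks", str(data_dir / "masks"),
            "--out", str(tmp_path / "metrics.csv")])
        assert res.exit_code == 0, res.output
        assert "DSC=" in res.output
        res = runner.invoke(cli_main, [
            "predict", "--ckpt", str(ckpt),
            "--images", str(data_dir / "images"),
            "--out", str(tmp_path / "preds")])
        assert res.exit_code == 0, res.output
        assert len(list((tmp_path / "preds").glob("*.png"))) == 2
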
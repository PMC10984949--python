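"""Command-line entry point: simulate / train / eval / ablate / project.

Runs are driven by a YAML config with sections ``data``, ``encoder``,
``loss``, ``episodes``, ``meta``, ``eval`` and ``synthetic`` plus a global
``seed`` and ``output_dir``; unknown keys are rejected before any compute.
Outputs: CSV + JSON-split synthetic families, ``.npz`` checkpoints,
JSON-lines per-step metrics (including the raw and clipped hard-negative
fraction), JSON evaluation reports and PNG projections. Every command is
deterministic under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from pathlib import Path

import click
import yaml

from .analysis import plot_projection
from .chem_io import read_task_split, read_task_table, write_task_split, write_task_table
from .encoder import EncoderConfig
from .losses import LossConfig
from .metatrain import MetaConfig, ablation_variant
from .model import FewShotGraphModel
from .synthetic_data import SyntheticSpec, generate_family, preset_spec

_SECTIONS = ("data", "encoder", "loss", "episodes", "meta", "eval",
             "synthetic", "seed", "output_dir")


class RunConfig:
    """Validated run configuration assembled from YAML."""

    def __init__(self, raw: dict):
        unknown = set(raw) - set(_SECTIONS)
        if unknown:
            raise click.ClickException(f"unknown config sections: {sorted(unknown)}")
        self.seed = int(raw.get("seed", 0))
        self.output_dir = Path(raw.get("output_dir", "runs"))
        self.data = raw.get("data", {})
        try:
            self.encoder = EncoderConfig(**raw.get("encoder", {}))
            self.loss = LossConfig(**raw.get("loss", {}))
            self.meta = MetaConfig(**raw.get("meta", {}))
        except (TypeError, ValueError) as exc:
            raise click.ClickException(f"invalid config: {exc}") from exc
        episodes = dict(raw.get("episodes", {}))
        self.k_shot = int(episodes.pop("k_shot", 10))
        self.query_size = episodes.pop("query_size", 32)
        if episodes:
            raise click.ClickException(f"unknown episode keys: {sorted(episodes)}")
        ev = dict(raw.get("eval", {}))
        self.eval_runs = int(ev.pop("runs", self.meta.runs))
        if ev:
            raise click.ClickException(f"unknown eval keys: {sorted(ev)}")
        self.synthetic = raw.get("synthetic", {})

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def model(self) -> FewShotGraphModel:
        if "table_csv" not in self.data or "split_json" not in self.data:
            raise click.ClickException(
                "config data section needs table_csv and split_json"
            )
        return FewShotGraphModel.from_files(
            self.data["table_csv"], self.data["split_json"],
            encoder_config=self.encoder, loss_config=self.loss,
            meta_config=self.meta, k_shot=self.k_shot,
            query_size=self.query_size,
        )


@click.group()
def main():
    """Few-shot molecular property prediction toolkit."""


_config_opt = click.option("--config", "config_path", required=True,
                           type=click.Path(exists=True), help="YAML run config.")


@main.command()
@_config_opt
@click.option("--preset", type=click.Choice(["imbalanced", "balanced"]),
              default=None, help="Stock imbalance profile overriding the config.")
def simulate(config_path, preset):
    """Materialize a synthetic motif-labelled task family (CSV + split JSON)."""
    cfg = RunConfig.load(config_path)
    syn = dict(cfg.synthetic)
    syn.setdefault("seed", cfg.seed)
    try:
        if preset:
            spec = preset_spec(preset, **syn)
        else:
            spec = SyntheticSpec(**syn)
        fam = generate_family(spec)
    except (TypeError, ValueError) as exc:
        raise click.ClickException(f"infeasible synthetic spec: {exc}") from exc
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    write_task_table(fam.table, cfg.output_dir / "tasks.csv")
    write_task_split(fam.split, cfg.output_dir / "split.json")
    for task in fam.table.task_names:
        labels = [labels[task] for _, labels in fam.table.records
                  if labels[task] is not None]
        n_pos = sum(labels)
        click.echo(f"{task}: {len(labels)} molecules, {n_pos} positive "
                   f"({n_pos / len(labels):.1%})")
    click.echo(f"wrote {cfg.output_dir / 'tasks.csv'} and "
               f"{cfg.output_dir / 'split.json'}")


@main.command()
@_config_opt
def train(config_path):
    """Meta-train the encoder; write checkpoint and per-step metrics."""
    cfg = RunConfig.load(config_path)
    res = cfg.model().fit(seed=cfg.seed)
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    ckpt = cfg.output_dir / "encoder.npz"
    res.save(ckpt)
    with open(cfg.output_dir / "metrics.jsonl", "w") as fh:
        for row in res.metrics:
            fh.write(json.dumps(row) + "\n")
    click.echo(res.summary())
    click.echo(f"checkpoint: {ckpt}")


@main.command(name="eval")
@_config_opt
@click.option("--checkpoint", required=True, type=click.Path(exists=True))
def evaluate(config_path, checkpoint):
    """Meta-test a trained encoder; emit the AUC report as JSON."""
    cfg = RunConfig.load(config_path)
    cfg.encoder = dataclasses.replace(cfg.encoder, checkpoint_path=checkpoint)
    model = cfg.model()
    from .losses import TrainingClock
    from .model import FewShotGraphResults
    res = FewShotGraphResults(model, model.init_params(cfg.seed), [],
                              TrainingClock(), cfg.seed)
    report = res.evaluate(runs=cfg.eval_runs)
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    out = cfg.output_dir / "eval_report.json"
    out.write_text(report.to_json())
    click.echo(f"mean AUC {report.mean_auc:.4f} ± {report.std_auc:.4f} "
               f"over {report.runs} runs")
    click.echo(f"wrote {out}")


@main.command()
@_config_opt
def ablate(config_path):
    """Train + evaluate the full, no-contrastive and no-dynamic variants."""
    cfg = RunConfig.load(config_path)
    rows = {}
    for variant in ("full", "wc", "wd"):
        loss_cfg = ablation_variant(variant, base=cfg.loss)
        model = FewShotGraphModel.from_files(
            cfg.data["table_csv"], cfg.data["split_json"],
            encoder_config=cfg.encoder, loss_config=loss_cfg,
            meta_config=cfg.meta, k_shot=cfg.k_shot, query_size=cfg.query_size,
        )
        res = model.fit(seed=cfg.seed)
        report = res.evaluate(runs=cfg.eval_runs)
        rows[variant] = {"mean_auc": report.mean_auc, "std_auc": report.std_auc}
        click.echo(f"{variant:<5} AUC {report.mean_auc:.4f} ± {report.std_auc:.4f}")
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    out = cfg.output_dir / "ablation.json"
    out.write_text(json.dumps(rows, indent=2))
    click.echo(f"wrote {out}")


@main.command()
@_config_opt
@click.option("--checkpoint", required=True, type=click.Path(exists=True))
def project(config_path, checkpoint):
    """2-D PCA projection + silhouette for every meta-test task."""
    cfg = RunConfig.load(config_path)
    cfg.encoder = dataclasses.replace(cfg.encoder, checkpoint_path=checkpoint)
    model = cfg.model()
    from .losses import TrainingClock
    from .model import FewShotGraphResults
    res = FewShotGraphResults(model, model.init_params(cfg.seed), [],
                              TrainingClock(), cfg.seed)
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    scores = {}
    for task in model.split.test_tasks:
        result, score = res.project_task(task, seed=cfg.seed)
        scores[task] = score
        plot_projection(result, cfg.output_dir / f"projection_{task}.png",
                        title=f"{task} (silhouette {score:.3f})")
        click.echo(f"{task}: silhouette {score:.4f}")
    (cfg.output_dir / "separation.json").write_text(json.dumps(scores, indent=2))


if __name__ == "__main__":
    sys.exit(main())
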
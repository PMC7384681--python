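"""End-to-end orchestration: synthetic data (or normalized input) -> split ->
lambda selection -> production ensemble -> EC50 estimation -> combination
screens -> ranked target lists, with a manifest for reproducibility.

Every stage writes plain-text artifacts (TSV/JSON) into the run directory;
rerunning with the same configuration reproduces all outputs bit-identically
because every random choice is seeded from the config.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import read_response_dataset
from .design import write_design_tsv
from .inference import FitConfig, fit_ensemble
from .io_utils import atomic_write_text
from .perturbation import (
    combinatorial_screen,
    estimate_ec50_map,
    rank_targets,
)
from .selection import select_lambda, split_dataset
from .synthetic import (
    GroundTruthSpec,
    demo_design,
    generate_ground_truth,
    simulate_dataset,
)


@dataclass
class SyntheticConfig:
    n_molec: int = 10
    n_phen: int = 2
    n_drug: int = 4
    edge_density: float = 0.10
    drug_target_count: int = 3
    noise_sd: float = 0.05
    include_control: bool = False


@dataclass
class PipelineConfig:
    """Strict-schema configuration of a full run."""

    out_dir: str = "perturbnet_run"
    seed: int = 0
    dataset_path: str | None = None
    design_path: str | None = None
    control_label: str | None = None
    synthetic: SyntheticConfig | None = field(default_factory=SyntheticConfig)
    lambda_grid: list[float] = field(default_factory=lambda: [0.0, 1.0, 3.0])
    n_restarts: int = 4
    n_ensemble: int = 8
    criterion: str = "bic"
    max_iterations: int = 1500
    learning_rate: float = 0.01
    fit_step_h: float = 0.2
    screen_step_h: float = 0.05
    top_unique: int = 20
    fallback_dose: float = 1.0
    keep_models: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        allowed = {f.name for f in fields(cls)}
        unknown = set(d) - allowed
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if d.get("synthetic") is not None:
            syn = d["synthetic"]
            syn_allowed = {f.name for f in fields(SyntheticConfig)}
            bad = set(syn) - syn_allowed
            if bad:
                raise ValueError(f"unknown synthetic config key(s): {sorted(bad)}")
            d["synthetic"] = SyntheticConfig(**syn)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        return asdict(self)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Stage failures abort with the stage name; artifacts written so far are
    left in place.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "package_version": __version__,
        "stages": {},
    }
    stage = "load-data"
    t0 = time.monotonic()
    try:
        if config.dataset_path is not None:
            dataset = read_response_dataset(
                config.dataset_path, config.design_path, config.control_label
            )
            truth = None
        else:
            syn = config.synthetic or SyntheticConfig()
            truth = generate_ground_truth(
                GroundTruthSpec(
                    n_molec=syn.n_molec,
                    n_phen=syn.n_phen,
                    n_drug=syn.n_drug,
                    edge_density=syn.edge_density,
                    drug_target_count=syn.drug_target_count,
                    seed=config.seed,
                )
            )
            design = demo_design(syn.n_drug, include_control=syn.include_control)
            dataset = simulate_dataset(
                truth, design, noise_sd=syn.noise_sd, seed=config.seed + 1
            )
            truth.to_json(out / "ground_truth.json")
            write_design_tsv(design, truth.drug_names, out / "design.tsv")
        dataset.to_tsv(out / "dataset.tsv")
        _mark(manifest, stage, t0)

        stage = "split"
        t0 = time.monotonic()
        split = split_dataset(dataset, seed=config.seed + 2)
        atomic_write_text(
            out / "split.json",
            json.dumps(
                {
                    "train": split.train,
                    "validation": split.validation,
                    "test": split.test,
                    "balanced": split.balanced,
                },
                indent=1,
            ),
        )
        _mark(manifest, stage, t0)

        stage = "select-lambda"
        t0 = time.monotonic()
        fit_cfg = FitConfig(
            learning_rate=config.learning_rate,
            max_iterations=config.max_iterations,
            step_h=config.fit_step_h,
        )
        report = select_lambda(
            dataset,
            lambda_grid=config.lambda_grid,
            n_restarts=config.n_restarts,
            seed=config.seed + 3,
            config=fit_cfg,
            criterion=config.criterion,
            split=split,
        )
        atomic_write_text(
            out / "selection.json", json.dumps(report.to_dict(), indent=1)
        )
        pd.DataFrame(
            {
                "lambda": report.lambda_grid,
                "mean_bic": report.mean_bic,
                "mean_train_rss": report.mean_train_rss,
                "mean_validation_rss": report.mean_validation_rss,
                "mean_validation_pearson": report.mean_validation_pearson,
                "mean_n_nonzero_w": report.mean_n_nonzero_w,
            }
        ).to_csv(out / "selection.tsv", sep="\t", index=False)
        _mark(manifest, stage, t0)

        stage = "fit-ensemble"
        t0 = time.monotonic()
        ensemble = fit_ensemble(
            dataset,
            report.lambda_star,
            config.n_ensemble,
            base_seed=config.seed + 10_000,
            config=fit_cfg,
        )
        models_dir = out / "models"
        if config.keep_models:
            models_dir.mkdir(exist_ok=True)
            index = []
            for i, r in enumerate(ensemble):
                name = f"model_{i:03d}.json"
                r.params.to_json(models_dir / name)
                index.append(
                    {
                        "file": name,
                        "seed": r.seed,
                        "rss_train": r.rss_train,
                        "n_nonzero_w": r.n_nonzero_w,
                    }
                )
            atomic_write_text(
                models_dir / "index.json", json.dumps(index, indent=1)
            )
        _mark(manifest, stage, t0)

        stage = "screen"
        t0 = time.monotonic()
        params_list = [r.params for r in ensemble]
        ranked_paths = {}
        for phenotype in params_list[0].phenotype_names:
            ec50, fits = estimate_ec50_map(
                params_list, phenotype, step_h=config.screen_step_h
            )
            pd.DataFrame(
                {
                    "node": list(fits),
                    "e1": [fits[n].e1 for n in fits],
                    "ec50": [fits[n].ec50 for n in fits],
                    "hill_n": [fits[n].hill_n for n in fits],
                    "no_effect": [fits[n].no_effect for n in fits],
                }
            ).to_csv(out / f"ec50_{phenotype}.tsv", sep="\t", index=False)
            screen = combinatorial_screen(
                params_list,
                ec50,
                phenotype,
                fallback_dose=config.fallback_dose,
                step_h=config.screen_step_h,
            )
            pd.DataFrame(
                screen.matrix, index=screen.nodes, columns=screen.nodes
            ).to_csv(out / f"screen_{phenotype}.tsv", sep="\t")
            ranked = rank_targets(screen, top_unique=config.top_unique)
            rp = out / f"ranked_{phenotype}.tsv"
            pd.DataFrame(
                {
                    "rank": np.arange(1, len(ranked) + 1),
                    "node_a": [r.node_a for r in ranked],
                    "node_b": [r.node_b for r in ranked],
                    "effect": [r.effect for r in ranked],
                }
            ).to_csv(rp, sep="\t", index=False)
            ranked_paths[phenotype] = rp.name
        _mark(manifest, stage, t0)
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        atomic_write_text(out / "manifest.json", json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest["lambda_star"] = report.lambda_star
    manifest["ranked_lists"] = ranked_paths
    atomic_write_text(out / "manifest.json", json.dumps(manifest, indent=1))
    return out


def _mark(manifest: dict, stage: str, t0: float) -> None:
    manifest["stages"][stage] = {"seconds": round(time.monotonic() - t0, 3)}
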
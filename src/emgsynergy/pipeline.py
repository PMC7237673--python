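"""End-to-end pipeline: configuration, simulation, and the full method
comparison (simulate → preprocess → select K → fit → score → group stats).

`RunConfig` collects every tunable parameter with the defaults used
throughout (band-pass 30–400 Hz, envelope cut-off 6 Hz, 200 time points,
K = 3 compared over candidates 2–6 at an 85% VAF threshold, KS level 0.05)
and round-trips through YAML.  `simulate_dataset` writes a synthetic study
to disk (conditions × subjects × trials, one CSV+JSON pair per trial plus a
manifest); `run_pipeline` consumes such a directory and writes scores.csv,
anova.json, selected_k.json and a figure summarising VAF, occurrence of
agreement and maximum dissimilarity per method and condition.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import io as eio
from .evaluation import group_comparison, score_dataset, scores_to_frame, select_num_synergies
from .factorization import METHODS
from .preprocessing import process_trial
from .synthetic import SPEED_CONDITIONS, generate_raw_trial

__all__ = ["RunConfig", "simulate_dataset", "run_pipeline", "plot_method_comparison"]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """All pipeline parameters in one serialisable record."""

    input_dir: str = "results/trials"
    output_dir: str = "results/run"
    bandpass_low_hz: float = 30.0
    bandpass_high_hz: float = 400.0
    envelope_cutoff_hz: float = 6.0
    n_points: int = 200
    K: int = 3
    K_range: tuple[int, int] = (2, 6)
    vaf_threshold: float = 0.85
    alpha: float = 0.05
    seed: int = 0
    methods: tuple[str, ...] = METHODS
    select_k: bool = True
    make_figures: bool = True

    def validate(self) -> None:
        if not (0 < self.bandpass_low_hz < self.bandpass_high_hz):
            raise ValueError("invalid band-pass corner frequencies")
        if self.envelope_cutoff_hz <= 0:
            raise ValueError("envelope cut-off must be positive")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if not (1 <= self.K_range[0] <= self.K_range[1]):
            raise ValueError("invalid K_range")
        if not (0 < self.vaf_threshold <= 1):
            raise ValueError("vaf_threshold must be in (0, 1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        unknown = set(m.upper() for m in self.methods) - set(METHODS)
        if unknown or not self.methods:
            raise ValueError(f"methods must be a non-empty subset of {METHODS}")

    def to_yaml(self, path: Path | str) -> None:
        d = dataclasses.asdict(self)
        d["K_range"] = list(self.K_range)
        d["methods"] = list(self.methods)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["K_range"] = tuple(d.get("K_range", (2, 6)))
        d["methods"] = tuple(d.get("methods", METHODS))
        cfg = cls(**d)
        cfg.validate()
        return cfg


def _trial_seed(master: int, condition: str, subject: int, trial: int) -> int:
    """Deterministic per-trial seed derived from the master seed (< 2^31)."""
    order = list(SPEED_CONDITIONS)
    key = (order.index(condition), subject, trial)
    ss = np.random.SeedSequence(entropy=master, spawn_key=key)
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def simulate_dataset(
    out_dir: Path | str,
    conditions: list[str] | None = None,
    n_subjects: int = 2,
    n_trials: int = 3,
    seed: int = 0,
    n_channels: int = 10,
    fs: float = 1500.0,
) -> dict:
    """Write a synthetic study to disk and return its manifest.

    One CSV+JSON trial pair per (condition, subject, trial); the manifest
    records the per-trial seeds so any file can be regenerated in isolation.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    conditions = conditions or list(SPEED_CONDITIONS)
    entries = []
    if n_trials == 0:
        logger.warning("n_trials=0: writing an empty manifest")
    for cond in conditions:
        for subj in range(1, n_subjects + 1):
            for tr in range(1, n_trials + 1):
                tseed = _trial_seed(seed, cond, subj, tr)
                trial = generate_raw_trial(cond, n_channels=n_channels, fs=fs, seed=tseed)
                stem = out_dir / f"{cond}_s{subj:02d}_t{tr:02d}"
                eio.write_trial(trial, stem)
                entries.append(
                    {"stem": stem.name, "condition": cond, "subject": f"s{subj:02d}",
                     "trial": f"t{tr:02d}", "seed": tseed}
                )
    manifest = {"master_seed": seed, "fs_hz": fs, "n_channels": n_channels,
                "trials": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def plot_method_comparison(scores_df, path: Path | str) -> None:
    """Bar chart (mean ± sd per method and condition) of the three metrics."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    metrics = [("vaf", "VAF"), ("agreement_pct", "occurrence of agreement (%)"),
               ("d_max", "maximum dissimilarity D")]
    conditions = list(scores_df["condition"].unique())
    methods = sorted(scores_df["method"].unique())
    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6))
    width = 0.8 / len(methods)
    for ax, (col, title) in zip(axes, metrics):
        for j, m in enumerate(methods):
            sub = scores_df[scores_df["method"] == m]
            means = [sub[sub["condition"] == c][col].mean() for c in conditions]
            sds = [sub[sub["condition"] == c][col].std() for c in conditions]
            xs = np.arange(len(conditions)) + j * width
            ax.bar(xs, means, width=width, yerr=sds, capsize=2, label=m)
        ax.set_xticks(np.arange(len(conditions)) + 0.4 - width / 2)
        ax.set_xticklabels(conditions, rotation=20, fontsize=8)
        ax.set_title(title, fontsize=10)
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> Path:
    """Run the full comparison on a simulated-trial directory.

    Returns the output directory containing scores.csv, anova.json,
    selected_k.json, config.yaml and (optionally) the summary figure.
    """
    config.validate()
    in_dir = Path(config.input_dir)
    manifest_path = in_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json under {in_dir}; run simulate first")
    manifest = json.loads(manifest_path.read_text())
    if not manifest["trials"]:
        raise FileNotFoundError(f"manifest under {in_dir} lists no trials")

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")

    logger.info("preprocessing %d trials (band-pass %g-%g Hz, envelope %g Hz, %d points)",
                len(manifest["trials"]), config.bandpass_low_hz, config.bandpass_high_hz,
                config.envelope_cutoff_hz, config.n_points)
    trials, conditions, subjects, trial_ids, seeds = [], [], [], [], []
    for entry in manifest["trials"]:
        raw = eio.read_trial(in_dir / entry["stem"])
        act = process_trial(
            raw,
            bandpass_low_hz=config.bandpass_low_hz,
            bandpass_high_hz=config.bandpass_high_hz,
            envelope_cutoff_hz=config.envelope_cutoff_hz,
            n_points=config.n_points,
        )
        trials.append(act)
        conditions.append(entry["condition"])
        subjects.append(entry["subject"])
        trial_ids.append(entry["stem"])
        seeds.append(entry["seed"])

    methods = tuple(m.upper() for m in config.methods)
    if config.select_k:
        K = select_num_synergies(
            trials[0], methods, range(config.K_range[0], config.K_range[1] + 1),
            threshold=config.vaf_threshold, seed=config.seed,
        )
        logger.info("selected K=%d (VAF > %.0f%% for all methods)", K,
                    100 * config.vaf_threshold)
    else:
        K = config.K
    (out_dir / "selected_k.json").write_text(json.dumps({"K": K}))

    scores = score_dataset(trials, methods, K=K, seeds=seeds, conditions=conditions,
                           subjects=subjects, trial_ids=trial_ids, alpha=config.alpha)
    df = scores_to_frame(scores)
    df.to_csv(out_dir / "scores.csv", index=False)

    anova = {}
    if len(methods) >= 2 and df["subject"].nunique() >= 2:
        for metric in ("vaf", "agreement_pct", "d_max"):
            anova[metric] = group_comparison(df, metric)
    (out_dir / "anova.json").write_text(json.dumps(anova, indent=2))

    if config.make_figures:
        plot_method_comparison(df, out_dir / "method_comparison.svg")
    logger.info("wrote %s (%d score rows)", out_dir, len(df))
    return out_dir
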
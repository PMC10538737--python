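"""Run orchestration: importance tables, paired evaluations, calibration
studies, and JSON manifests sufficient to replay any run exactly."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CohortTable, read_cohort, read_feature_config, split_data
from .evaluation import EvalReport, evaluate_split
from .importance import ImportanceResult, run_permfit, select_important
from .simulate import SyntheticSpec, make_null_cohort, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "permfit_report",
    "evaluation_report",
    "calibration_study",
    "load_cohort_from_config",
]


@dataclass
class RunConfig:
    """Everything needed to replay a run."""

    command: str                      # permfit | evaluate | simulate | calibration-study
    learner_kind: str = "logistic"
    input_path: str | None = None     # cohort CSV/XLSX
    meta_path: str | None = None      # feature config YAML/JSON
    alpha: float = 0.05
    n_perm: int = 100
    val_fraction: float = 0.2
    test_n: int | None = None
    seed: int = 0
    out_dir: str = "permfit_out"
    learner_configs: dict = field(default_factory=dict)

    def validate(self):
        if self.command not in ("permfit", "evaluate", "simulate", "calibration-study"):
            raise ValueError(f"unknown command {self.command!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


def load_cohort_from_config(config: RunConfig) -> CohortTable:
    if config.input_path is None or config.meta_path is None:
        raise ValueError("input_path and meta_path are required to load a cohort")
    metas, outcome, positive = read_feature_config(config.meta_path)
    return read_cohort(config.input_path, metas, outcome, positive)


def _versions() -> dict:
    import sklearn
    from . import __version__
    return {"permfit": __version__, "numpy": np.__version__, "sklearn": sklearn.__version__}


def _write_manifest(path: Path, config: RunConfig, extra: dict):
    manifest = {"config": asdict(config), "versions": _versions(),
                "rng": "numpy PCG64 (default_rng)", **extra}
    path.write_text(json.dumps(manifest, indent=2, default=str))


def results_table(results: list[ImportanceResult], method: str) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "method": method,
            "feature": [r.feature for r in results],
            "score": [r.score for r in results],
            "se": [r.se for r in results],
            "z": [r.z for r in results],
            "p_value": [r.p_value for r in results],
            "display_p": [r.display_p for r in results],
        }
    )


def permfit_report(
    cohort: CohortTable, config: RunConfig, out_dir: str | Path | None = None
) -> tuple[list[ImportanceResult], pd.DataFrame]:
    """Run the feature-identification procedure and write the importance
    table (TSV) plus a replayable manifest (JSON)."""
    config.validate()
    results = run_permfit(
        cohort, config.learner_kind, config.learner_configs,
        val_fraction=config.val_fraction, alpha=config.alpha,
        n_perm=config.n_perm, seed=config.seed,
    )
    table = results_table(results, f"PermFIT-{config.learner_kind}")
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "importance.tsv", sep="\t", index=False, float_format="%.10g")
    selected = select_important(results, config.alpha)
    _write_manifest(out / "manifest.json", config, {"selected_features": selected})
    logger.info("permfit: %d/%d features significant at alpha=%g",
                len(selected), len(results), config.alpha)
    return results, table


def evaluation_report(
    cohort: CohortTable, config: RunConfig, out_dir: str | Path | None = None
) -> dict[str, EvalReport]:
    """All-features vs PermFIT-selected-features comparison on one shared
    held-out test split.

    Features are selected by running the importance procedure on the
    training rows only, then both models are refitted on those rows and
    scored on the identical test rows.
    """
    config.validate()
    split = split_data(
        cohort,
        test_n=config.test_n or max(1, int(round(cohort.n / 11))),
        seed=config.seed, stratified=True,
    )
    train = cohort.subset_rows(split.train_idx)
    results = run_permfit(
        train, config.learner_kind, config.learner_configs,
        val_fraction=config.val_fraction, alpha=config.alpha,
        n_perm=config.n_perm, seed=config.seed,
    )
    selected = select_important(results, config.alpha)
    reports = {
        "all_features": evaluate_split(
            cohort, split, config.learner_kind, None,
            config.learner_configs, seed=config.seed),
    }
    if selected:
        reports["selected_features"] = evaluate_split(
            cohort, split, config.learner_kind, selected,
            config.learner_configs, seed=config.seed)
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {k: v.to_dict() for k, v in reports.items()}
    payload["selected"] = selected
    (out / "evaluation.json").write_text(json.dumps(payload, indent=2))
    _write_manifest(out / "manifest.json", config, {
        "selected_features": selected,
        "test_idx": split.test_idx.tolist(),
    })
    return reports


def calibration_study(
    base_spec: SyntheticSpec,
    n_replicates: int,
    scenario: str = "null",
    learner_kind: str = "logistic",
    alpha: float = 0.05,
    n_perm: int = 50,
    seed: int = 0,
    learner_configs: dict | None = None,
) -> pd.DataFrame:
    """Repeated-simulation rejection rates per feature with binomial CIs.

    scenario "null": all signal coefficients zeroed (type-I error);
    scenario "signal": the spec as given (power on its signal features).
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    if n_replicates < 100:
        logger.warning("calibration with %d replicates is noisy; >=100 recommended",
                       n_replicates)
    ss = np.random.SeedSequence(seed).spawn(n_replicates)
    rejections = None
    features = None
    for r, child in enumerate(ss):
        rep_seed = int(child.generate_state(1)[0] % 2**31)
        from dataclasses import replace
        spec = replace(base_spec, seed=rep_seed)
        sim = make_null_cohort(spec) if scenario == "null" else simulate_cohort(spec)
        results = run_permfit(
            sim.table, learner_kind, learner_configs,
            alpha=alpha, n_perm=n_perm, seed=rep_seed,
        )
        if rejections is None:
            features = [res.feature for res in results]
            rejections = np.zeros(len(features))
        rejections += np.array([res.p_value < alpha for res in results], dtype=float)
    rate = rejections / n_replicates
    half = 1.96 * np.sqrt(rate * (1 - rate) / n_replicates)
    return pd.DataFrame(
        {
            "feature": features,
            "is_signal": [f in base_spec.signal_features and scenario != "null"
                          for f in features],
            "rejection_rate": rate,
            "ci_low": np.clip(rate - half, 0, 1),
            "ci_high": np.clip(rate + half, 0, 1),
            "n_replicates": n_replicates,
        }
    )
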
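"""End-to-end pipeline orchestration and result assembly.

Sequences the analysis stages — per-block filtering, imputation and alr
transformation; one standardization of the joined dataset; discriminant
and regression CMV plus a permutation null; consensus selection; and the
Bayesian per-metabolite line-difference estimation — into a single
reproducible run with serializable artifacts.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bayes as bayes_mod
from .cmv import CmvConfig, CmvResult, consensus_selection, permutation_cmv, run_cmv
from .preprocess import ProcessedBlocks, process_blocks
from .synth import MetabolomePanel


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed to reproduce a full run bit-for-bit."""

    cmv: CmvConfig = field(default_factory=CmvConfig)
    max_zero_frac: float = 0.10
    impute_trees: int = 100
    impute_max_iter: int = 10
    n_permutations: int = 1
    mcmc_draws: int = 50_000
    mcmc_burn_in: int = 10_000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cmv_raw = raw.pop("cmv", {})
        return cls(cmv=CmvConfig(**cmv_raw), **raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class PipelineRun:
    config: PipelineConfig
    processed: ProcessedBlocks
    cmv_da: CmvResult
    cmv_pls: CmvResult
    permuted_da: list[CmvResult]
    permuted_pls: list[CmvResult]
    consensus: pd.Index
    posterior: pd.DataFrame | None
    provenance: dict


def standardize(data: pd.DataFrame) -> pd.DataFrame:
    """Center and unit-scale every column (one global pass, as the models
    expect); zero-variance columns are left centered only."""
    sd = data.std(axis=0, ddof=1).replace(0.0, 1.0)
    return (data - data.mean(axis=0)) / sd


def misclassification_table(cmv_result: CmvResult) -> pd.DataFrame:
    """Row-normalized 2x2 percentage table of true vs predicted class,
    pooled over the held-out predictions of all models. Rows sum to 100."""
    counts = cmv_result.pooled_confusion()
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise ValueError("a true class has no pooled test predictions")
    return 100.0 * counts.div(totals, axis=0)


def _hash_frame(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(df, index=True).to_numpy().tobytes())
    return h.hexdigest()[:16]


def run_pipeline(panel: MetabolomePanel, config: PipelineConfig | None = None) -> PipelineRun:
    """Execute the complete analysis chain on one metabolome panel."""
    config = config or PipelineConfig()
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(c.generate_state(1)[0] % (2**31 - 1)) for c in ss.spawn(5)]
    impute_seed, cmv_seed, perm_seed, mcmc_seed, _ = seeds

    processed = process_blocks(
        panel.split_blocks(),
        max_zero_frac=config.max_zero_frac,
        impute_seed=impute_seed,
        n_estimators=config.impute_trees,
        max_iter=config.impute_max_iter,
    )
    X = standardize(processed.data)
    line = processed.samples["line"]
    imf = processed.samples["imf"]

    cmv_config = replace(config.cmv, seed=cmv_seed)
    cmv_da = run_cmv(X, line, "discriminant", cmv_config)
    cmv_pls = run_cmv(X, imf, "regression", cmv_config, strata=line.to_numpy())

    perm_config = replace(config.cmv, seed=perm_seed)
    permuted_da = permutation_cmv(X, line, "discriminant", perm_config, config.n_permutations)
    permuted_pls = permutation_cmv(
        X, imf, "regression", perm_config, config.n_permutations, strata=line.to_numpy()
    )

    consensus = consensus_selection(cmv_da.tally, cmv_pls.tally, cmv_config)
    posterior = None
    if len(consensus):
        posterior = bayes_mod.fit_all_selected(
            processed.data,
            processed.samples,
            consensus,
            n_draws=config.mcmc_draws,
            burn_in=config.mcmc_burn_in,
            seed=mcmc_seed,
        )

    provenance = {
        "seed": config.seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "abundance_hash": _hash_frame(panel.abundance),
        "metadata_hash": _hash_frame(panel.samples),
    }
    return PipelineRun(
        config=config,
        processed=processed,
        cmv_da=cmv_da,
        cmv_pls=cmv_pls,
        permuted_da=permuted_da,
        permuted_pls=permuted_pls,
        consensus=consensus,
        posterior=posterior,
        provenance=provenance,
    )


def write_run(run: PipelineRun, out_dir: str | Path) -> None:
    """Serialize the run: tallies, per-model metrics, summary JSON, posterior."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    threshold = run.config.cmv.selection_frequency * run.config.cmv.n_models
    tally = pd.DataFrame(
        {
            "tally_da": run.cmv_da.tally,
            "tally_pls": run.cmv_pls.tally,
        }
    )
    tally["selected"] = (tally["tally_da"] > threshold) & (tally["tally_pls"] > threshold)
    tally.to_csv(out / "tally.csv", index_label="metabolite_id")

    metrics = []
    for result in (run.cmv_da, run.cmv_pls):
        for rec in result.records:
            metrics.append(
                {
                    "mode": result.mode,
                    "iteration": rec.iteration,
                    "fold": rec.fold,
                    "n_components": rec.n_components,
                    "n_selected": len(rec.selected),
                    "q2": rec.q2,
                    "excluded": rec.excluded,
                }
            )
    pd.DataFrame(metrics).to_csv(out / "model_metrics.csv", index=False)

    if run.posterior is not None:
        run.posterior.to_csv(out / "posterior_summary.csv")

    summary = {
        "config": run.config.to_dict(),
        "provenance": run.provenance,
        "n_models": run.cmv_da.n_models,
        "consensus_size": int(len(run.consensus)),
        "consensus": list(run.consensus),
        "misclassification_true": misclassification_table(run.cmv_da).round(4).to_dict(),
        "misclassification_permuted": misclassification_table(run.permuted_da[0])
        .round(4)
        .to_dict(),
        "q2_mean_true": float(np.mean(run.cmv_pls.q2_distribution)),
        "q2_mean_permuted": float(np.mean(run.permuted_pls[0].q2_distribution)),
        "references": {
            block: res.reference_id for block, res in run.processed.alr_results.items()
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))


def plot_q2_distribution(cmv_result: CmvResult, path: str | Path) -> None:
    """Histogram of the per-model test-set Q^2 values."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.hist(cmv_result.q2_distribution, bins=20, color="#4477aa", edgecolor="white")
    ax.set_xlabel("Q$^2$ (held-out)")
    ax.set_ylabel("models")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_tally(cmv_result: CmvResult, path: str | Path, top: int = 40) -> None:
    """Bar chart of the most frequently selected metabolites."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    tally = cmv_result.tally.sort_values(ascending=False).head(top)
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.bar(range(len(tally)), tally.to_numpy(), color="#4477aa")
    ax.set_xticks(range(len(tally)))
    ax.set_xticklabels(tally.index, rotation=90, fontsize=5)
    ax.set_ylabel("models selecting")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
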
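"""Zero filtering and iterative random-forest imputation.

Untargeted LC-MS intensities contain zeros where a compound was not
detected. Metabolites that are mostly undetected in both lines carry no
usable signal and are dropped; the remaining zeros are treated as missing
values and imputed with an iterative random-forest scheme (missForest
style) so the log-ratio transformation downstream receives strictly
positive data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .synth import MetabolomePanel


@dataclass
class FilterReport:
    kept: pd.Index
    removed: pd.Index
    zero_frac_by_line: pd.DataFrame  # columns H, L

    def __post_init__(self) -> None:
        if len(self.kept.intersection(self.removed)):
            raise ValueError("kept and removed metabolite sets overlap")


def filter_by_missingness(
    panel: MetabolomePanel, max_zero_frac: float = 0.10
) -> tuple[MetabolomePanel, FilterReport]:
    """Drop metabolites undetected too often in both lines.

    A metabolite is kept iff its zero fraction is strictly below
    ``max_zero_frac`` in at least one line, i.e.
    ``min(frac_zero_H, frac_zero_L) < max_zero_frac``. Zeros in kept
    metabolites are left in place for imputation.
    """
    if not 0.0 < max_zero_frac <= 1.0:
        raise ValueError("max_zero_frac must lie in (0, 1]")
    line = panel.line_of
    fracs = {}
    for ln in ("H", "L"):
        rows = panel.abundance.loc[line == ln]
        if rows.empty:
            raise ValueError(f"line {ln} has no samples")
        fracs[ln] = (rows == 0).mean(axis=0)
    zero_frac = pd.DataFrame(fracs)
    keep_mask = zero_frac.min(axis=1) < max_zero_frac
    kept = panel.abundance.columns[keep_mask]
    removed = panel.abundance.columns[~keep_mask]
    report = FilterReport(kept=kept, removed=removed, zero_frac_by_line=zero_frac)
    return panel.subset_metabolites(kept), report


def impute_random_forest(
    panel: MetabolomePanel,
    seed: int = 0,
    max_iter: int = 10,
    n_estimators: int = 100,
) -> MetabolomePanel:
    """Impute zeros by iterative random-forest regression (missForest).

    Columns are initialized with the median of their observed values and
    then cycled in order of increasing missingness; each column with
    missing cells is regressed on all other columns with a random forest
    and its missing cells replaced by the forest's predictions. Iteration
    stops when the normalized change in imputed values increases (the
    previous iterate is returned) or after ``max_iter`` sweeps, with a
    warning. Observed values are never modified, and imputed values are
    floored at half the column's minimum observed value so every entry
    stays strictly positive for the log-ratio step.
    """
    values = panel.abundance.to_numpy(copy=True)
    mask = values == 0
    if not mask.any():
        return panel

    if mask.all(axis=0).any():
        bad = panel.abundance.columns[mask.all(axis=0)].tolist()
        raise ValueError(f"fully-missing metabolites (should have been filtered): {bad}")

    n, p = values.shape
    col_min_obs = np.array(
        [values[~mask[:, j], j].min() for j in range(p)]
    )
    # initialization: column medians of observed values
    for j in range(p):
        if mask[:, j].any():
            values[mask[:, j], j] = np.median(values[~mask[:, j], j])

    order = np.argsort(mask.sum(axis=0))
    order = [j for j in order if mask[:, j].any()]

    rng = np.random.default_rng(seed)
    prev_diff = np.inf
    previous = values.copy()
    converged = False
    for _ in range(max_iter):
        previous = values.copy()
        for j in order:
            obs = ~mask[:, j]
            others = np.delete(np.arange(p), j)
            rf = RandomForestRegressor(
                n_estimators=n_estimators,
                random_state=int(rng.integers(0, 2**31 - 1)),
                n_jobs=1,
            )
            rf.fit(values[obs][:, others], values[obs, j])
            pred = rf.predict(values[mask[:, j]][:, others])
            values[mask[:, j], j] = np.maximum(pred, 0.5 * col_min_obs[j])
        num = ((values - previous)[mask] ** 2).sum()
        den = (values[mask] ** 2).sum()
        diff = num / den if den > 0 else 0.0
        if diff >= prev_diff:
            values = previous  # stopping rule: change in imputed values rose
            converged = True
            break
        prev_diff = diff
    if not converged:
        warnings.warn(
            "random-forest imputation reached max_iter without the "
            "missForest stopping criterion triggering",
            RuntimeWarning,
            stacklevel=2,
        )

    abundance = pd.DataFrame(values, index=panel.abundance.index, columns=panel.abundance.columns)
    return MetabolomePanel(
        abundance=abundance,
        samples=panel.samples.copy(),
        blocks=panel.blocks.copy(),
        truth=None if panel.truth is None else panel.truth.copy(),
        original=None if panel.original is None else panel.original.copy(),
    )


@dataclass
class ProcessedBlocks:
    """Joined log-ratio data plus per-block processing diagnostics."""

    data: pd.DataFrame  # samples x (sum_b (J_b - 1)) alr-transformed values
    samples: pd.DataFrame
    filter_reports: dict
    alr_results: dict
    block_of: pd.Series  # transformed column -> acquisition block


def process_blocks(
    panels: list[MetabolomePanel] | dict[str, MetabolomePanel],
    max_zero_frac: float = 0.10,
    impute_seed: int = 0,
    n_estimators: int = 100,
    max_iter: int = 10,
) -> ProcessedBlocks:
    """Filter, impute and alr-transform each block, then join columns.

    Processing runs separately per acquisition block; each block loses one
    column to its alr reference, so the joined width is
    ``sum_b (kept_b - 1)``. All blocks must share the same sample set.
    """
    from .compositional import select_alr_reference

    if isinstance(panels, dict):
        items = list(panels.items())
    else:
        items = [(str(pnl.blocks.iloc[0]), pnl) for pnl in panels]
    if not items:
        raise ValueError("no blocks given")

    ref_index = items[0][1].abundance.index
    for name, pnl in items[1:]:
        if not pnl.abundance.index.equals(ref_index):
            raise ValueError(f"block {name!r} has a different sample set")

    pieces, reports, alr_results, provenance = [], {}, {}, []
    for name, pnl in items:
        filtered, report = filter_by_missingness(pnl, max_zero_frac=max_zero_frac)
        reports[name] = report
        imputed = impute_random_forest(
            filtered, seed=impute_seed, max_iter=max_iter, n_estimators=n_estimators
        )
        alr = select_alr_reference(imputed.abundance)
        alr_results[name] = alr
        pieces.append(alr.transformed)
        provenance.extend([name] * alr.transformed.shape[1])

    data = pd.concat(pieces, axis=1)
    if data.columns.duplicated().any():
        raise ValueError("duplicate metabolite identifiers across blocks")
    block_of = pd.Series(provenance, index=data.columns, name="block")
    return ProcessedBlocks(
        data=data,
        samples=items[0][1].samples.copy(),
        filter_reports=reports,
        alr_results=alr_results,
        block_of=block_of,
    )
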
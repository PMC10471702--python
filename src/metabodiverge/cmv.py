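"""Cross model validation (CMV) with embedded variable selection.

CMV is a nested cross-validation: an outer CV measures predictive
performance on samples never touched during modelling, while an inner CV
inside each training partition picks the number of PLS components and
provides the jackknife segments for coefficient confidence intervals.
Variable selection (VIP >= threshold AND 95% CI excluding zero) happens
strictly inside the training partition; the reduced model is then refit
and evaluated on the held-out outer fold. Repeating the outer split over
many iterations yields a per-metabolite selection tally, a permutation
null calibrates the whole procedure, and metabolites selected in more
than a fixed fraction of both the discriminant (line) and regression
(IMF) models form the consensus set.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pls import coefficient_ci, fit_pls, q2_statistic

MODES = ("discriminant", "regression")


@dataclass(frozen=True)
class CmvConfig:
    """Tuning knobs of the CMV procedure (defaults follow the study design)."""

    outer_folds: int = 8
    inner_folds: int = 7
    iterations: int = 20
    vip_threshold: float = 0.8
    ci_level: float = 0.95
    selection_frequency: float = 0.8
    q2_exclusion: float = 0.4
    max_components: int = 10
    fold_standardize: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("outer_folds and inner_folds must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        for name in ("vip_threshold", "ci_level", "selection_frequency"):
            v = getattr(self, name)
            if not 0.0 <= v <= (1.0 if name != "vip_threshold" else np.inf):
                raise ValueError(f"{name} out of range")
        if self.max_components < 1:
            raise ValueError("max_components must be >= 1")

    @property
    def n_models(self) -> int:
        return self.outer_folds * self.iterations


@dataclass
class ModelRecord:
    """One outer-fold model: its selection and held-out predictions."""

    iteration: int
    fold: int
    n_components: int
    selected: list[str]
    test_ids: list[str]
    y_true: np.ndarray
    y_pred: np.ndarray
    q2: float | None = None  # regression mode only
    excluded: bool = False  # regression models with poor test Q2


@dataclass
class CmvResult:
    mode: str
    config: CmvConfig
    metabolites: pd.Index
    records: list[ModelRecord]
    tally: pd.Series
    classes: tuple | None = None  # (label0, label1) in discriminant mode

    @property
    def n_models(self) -> int:
        return len(self.records)

    @property
    def excluded_models(self) -> list[tuple[int, int]]:
        return [(r.iteration, r.fold) for r in self.records if r.excluded]

    @property
    def q2_distribution(self) -> list[float]:
        return [r.q2 for r in self.records if r.q2 is not None]

    def pooled_confusion(self) -> pd.DataFrame:
        """Counts of (true class, predicted class) pooled over all models."""
        if self.mode != "discriminant":
            raise ValueError("confusion counts require a discriminant-mode result")
        labels = list(self.classes)
        counts = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
        for rec in self.records:
            for yt, yp in zip(rec.y_true, rec.y_pred):
                counts.loc[yt, yp] += 1
        return counts

    @property
    def average_misclassification(self) -> float:
        """Pooled percent of held-out samples assigned to the wrong class."""
        counts = self.pooled_confusion()
        total = counts.to_numpy().sum()
        off = total - np.trace(counts.to_numpy())
        return 100.0 * off / total


def stratified_folds(
    n: int, n_folds: int, rng: np.random.Generator, strata=None
) -> list[np.ndarray]:
    """Partition samples into folds of near-equal size, balanced per stratum.

    Samples are shuffled within each stratum and dealt round-robin, so
    with 24 samples per line and 8 folds every fold holds exactly 3 of
    each line. Fold sizes differ by at most one overall.
    """
    if strata is None:
        strata = np.zeros(n, dtype=int)
    strata = np.asarray(strata)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    offset = 0
    for value in pd.unique(strata):
        members = rng.permutation(np.flatnonzero(strata == value))
        for i, idx in enumerate(members):
            folds[(offset + i) % n_folds].append(int(idx))
        offset += len(members)
    sizes = [len(f) for f in folds]
    if min(sizes) < 2:
        raise ValueError(f"fold of size {min(sizes)} < 2; fewer folds needed")
    return [np.asarray(sorted(f)) for f in folds]


def _inner_select_components(
    X: np.ndarray,
    y: np.ndarray,
    discriminant: bool,
    inner_folds: int,
    max_components: int,
    rng: np.random.Generator,
) -> tuple[int, list[np.ndarray]]:
    """Pick the component count by inner CV with a one-standard-error rule.

    Per inner fold the model is fit once at the maximum component count;
    held-out error (misclassification rate or MSEP) is read off for every
    truncation. The chosen count is the smallest whose mean error is
    within one standard error of the best mean error.
    """
    n = X.shape[0]
    perm = rng.permutation(n)
    segments = [perm[k::inner_folds] for k in range(inner_folds)]
    min_train = n - max(len(s) for s in segments)
    amax = int(min(max_components, X.shape[1], min_train - 1))
    amax = max(amax, 1)

    errors = np.full((len(segments), amax), np.nan)
    for i, seg in enumerate(segments):
        train = np.setdiff1d(np.arange(n), seg)
        if discriminant and len(np.unique(y[train])) < 2:
            continue  # degenerate inner split; skip fold
        model = fit_pls(X[train], y[train], amax)
        for a in range(1, amax + 1):
            pred = model.predict(X[seg], min(a, model.n_components))
            if discriminant:
                errors[i, a - 1] = float(np.mean((pred >= 0.5) != (y[seg] >= 0.5)))
            else:
                errors[i, a - 1] = float(np.mean((y[seg] - pred) ** 2))

    mean_err = np.nanmean(errors, axis=0)
    m_eff = np.sum(~np.isnan(errors), axis=0)
    se_err = np.nanstd(errors, axis=0, ddof=1) / np.sqrt(np.maximum(m_eff, 1))
    best = int(np.nanargmin(mean_err))
    threshold = mean_err[best] + (se_err[best] if np.isfinite(se_err[best]) else 0.0)
    chosen = int(np.flatnonzero(mean_err <= threshold)[0]) + 1
    return chosen, segments


def _fit_one_model(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    Xte: np.ndarray,
    discriminant: bool,
    config: CmvConfig,
    rng: np.random.Generator,
    columns: pd.Index,
) -> tuple[list[str], np.ndarray, int]:
    """Train-side CMV body: optimize, select variables, refit, predict."""
    a, segments = _inner_select_components(
        Xtr, ytr, discriminant, config.inner_folds, config.max_components, rng
    )
    model = fit_pls(Xtr, ytr, a)
    a = model.n_components
    ci, _ = coefficient_ci(
        Xtr, ytr, a, inner_folds=config.inner_folds,
        level=config.ci_level, segments=segments,
    )
    excludes_zero = (ci[:, 0] > 0) | (ci[:, 1] < 0)
    sel_mask = (model.vip >= config.vip_threshold) & excludes_zero
    selected = list(columns[sel_mask])

    if not selected:
        # no variable survives: fall back to the training mean / majority vote
        pred = np.full(Xte.shape[0], float(ytr.mean()))
        return selected, pred, 0

    Xtr_sel = Xtr[:, sel_mask]
    a2, _ = _inner_select_components(
        Xtr_sel, ytr, discriminant, config.inner_folds,
        min(config.max_components, Xtr_sel.shape[1]), rng,
    )
    final = fit_pls(Xtr_sel, ytr, a2)
    pred = final.predict(Xte[:, sel_mask])
    return selected, pred, final.n_components


def run_cmv(
    X: pd.DataFrame,
    response,
    mode: str,
    config: CmvConfig,
    strata=None,
) -> CmvResult:
    """Run the full cross-model-validation procedure.

    ``X`` is the (already standardized) samples x metabolites matrix. In
    discriminant mode ``response`` holds the two class labels and outer
    folds are stratified by them; in regression mode ``response`` is the
    continuous phenotype and ``strata`` (e.g. the line labels) may be
    supplied to balance folds. Every sample lands in the test set exactly
    once per iteration, giving ``iterations * outer_folds`` models.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    discriminant = mode == "discriminant"

    if isinstance(X, pd.DataFrame):
        columns = X.columns
        sample_ids = list(X.index.astype(str))
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        columns = pd.Index([f"m{j}" for j in range(Xv.shape[1])])
        sample_ids = [str(i) for i in range(Xv.shape[0])]
    n = Xv.shape[0]

    response = np.asarray(pd.Series(response).to_numpy())
    classes = None
    if discriminant:
        uniq = sorted(pd.unique(response))
        if len(uniq) != 2:
            raise ValueError("discriminant mode needs exactly two classes")
        classes = (uniq[0], uniq[1])
        y = (response == uniq[1]).astype(float)
        if strata is None:
            strata = response
    else:
        y = response.astype(float)

    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    records: list[ModelRecord] = []
    tally = pd.Series(0, index=columns, dtype=int)

    for it in range(config.iterations):
        folds = stratified_folds(n, config.outer_folds, rng, strata)
        for k, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(n), test_idx)
            Xtr, Xte = Xv[train_idx], Xv[test_idx]
            ytr = y[train_idx]
            if config.fold_standardize:
                mu = Xtr.mean(axis=0)
                sd = Xtr.std(axis=0, ddof=1)
                sd = np.where(sd < 1e-12, 1.0, sd)
                Xtr = (Xtr - mu) / sd
                Xte = (Xte - mu) / sd
            selected, pred, ncomp = _fit_one_model(
                Xtr, ytr, Xte, discriminant, config, rng, columns
            )

            if discriminant:
                y_true = response[test_idx]
                y_pred = np.asarray(classes)[(pred >= 0.5).astype(int)]
                rec = ModelRecord(
                    iteration=it, fold=k, n_components=ncomp, selected=selected,
                    test_ids=[sample_ids[i] for i in test_idx],
                    y_true=y_true, y_pred=y_pred,
                )
                if selected:
                    tally[selected] += 1
            else:
                q2 = q2_statistic(y[test_idx], pred, float(ytr.mean()))
                excluded = q2 < config.q2_exclusion
                rec = ModelRecord(
                    iteration=it, fold=k, n_components=ncomp, selected=selected,
                    test_ids=[sample_ids[i] for i in test_idx],
                    y_true=y[test_idx], y_pred=pred, q2=q2, excluded=excluded,
                )
                if selected and not excluded:
                    tally[selected] += 1
            records.append(rec)

    return CmvResult(
        mode=mode, config=config, metabolites=columns,
        records=records, tally=tally, classes=classes,
    )


def consensus_selection(
    tally_da: pd.Series, tally_pls: pd.Series, config: CmvConfig
) -> pd.Index:
    """Metabolites selected in more than ``selection_frequency`` of the
    models of *both* the discriminant and the regression analyses.

    With 160 models per mode and an 0.8 frequency the cut is a tally
    strictly greater than 128 in each mode independently.
    """
    if not tally_da.index.equals(tally_pls.index):
        raise ValueError("tallies cover different metabolite universes")
    threshold = config.selection_frequency * config.n_models
    hits_da = tally_da.index[tally_da > threshold]
    hits_pls = tally_pls.index[tally_pls > threshold]
    return hits_da.intersection(hits_pls)


def permutation_cmv(
    X: pd.DataFrame,
    response,
    mode: str,
    config: CmvConfig,
    n_permutations: int = 1,
    strata=None,
) -> list[CmvResult]:
    """CMV under the permutation null: shuffle the response, rerun everything.

    Each permutation draws a fresh uniform shuffle of the dependent
    variable and executes the identical CMV; no tally-based selection is
    meaningful under the null, but the performance metrics calibrate what
    the true-data models must beat.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    master = np.random.SeedSequence(config.seed).spawn(n_permutations)
    response = pd.Series(response).to_numpy()
    results = []
    for perm_ss in master:
        rng = np.random.default_rng(perm_ss)
        permuted = rng.permutation(response)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub_config = replace(config, seed=sub_seed)
        sub_strata = permuted if (mode == "discriminant" and strata is None) else strata
        results.append(run_cmv(X, permuted, mode, sub_config, strata=sub_strata))
    return results
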
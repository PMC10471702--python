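"""Additive log-ratio (alr) transformation with data-driven reference choice.

Untargeted metabolomic intensities are relative, so the information sits
in ratios between parts: the panel is treated as compositional. The alr
transformation ``ln(x_j / x_ref) = ln(x_j) - ln(x_ref)`` maps a J-part
composition to J-1 unconstrained coordinates. The reference part is
chosen so that (1) the alr sample geometry reproduces the geometry of the
full set of pairwise log-ratios, measured by the Procrustes correlation,
and (2) its own log abundance has low variance, ensuring variation in the
ratios is driven by the numerators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class AlrResult:
    """Chosen alr reference, its diagnostics, and the transformed matrix."""

    reference_id: str
    procrustes_corr: float
    reference_log_variance: float
    transformed: pd.DataFrame
    diagnostics: pd.DataFrame  # per candidate: procrustes_corr, log_variance, screened


def _check_positive(matrix: pd.DataFrame) -> None:
    if (matrix.values <= 0).any():
        raise ValueError("alr requires strictly positive abundances")


def alr_transform(matrix: pd.DataFrame, reference_id: str) -> pd.DataFrame:
    """Log-ratio of every metabolite against the reference metabolite.

    Returns a samples x (J-1) frame; the reference column is consumed.
    """
    _check_positive(matrix)
    if reference_id not in matrix.columns:
        raise KeyError(f"unknown reference metabolite {reference_id!r}")
    log_x = np.log(matrix)
    out = log_x.drop(columns=reference_id).sub(log_x[reference_id], axis=0)
    return out


def pairwise_logratio_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """All J(J-1)/2 pairwise log-ratios; the full-geometry configuration.

    Quadratic in J — meant for oracle checks and small panels. The sample
    geometry it spans equals the centred-log-ratio (clr) geometry up to
    rotation and a sqrt(J) scale.
    """
    _check_positive(matrix)
    log_x = np.log(matrix.to_numpy())
    cols = matrix.columns
    data, names = [], []
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            data.append(log_x[:, a] - log_x[:, b])
            names.append(f"{cols[a]}/{cols[b]}")
    return pd.DataFrame(np.column_stack(data), index=matrix.index, columns=names)


def clr_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Centred log-ratio: log abundance minus the per-sample log mean."""
    _check_positive(matrix)
    log_x = np.log(matrix)
    return log_x.sub(log_x.mean(axis=1), axis=0)


def _configuration_scores(config: np.ndarray) -> np.ndarray:
    """Column-centred principal-coordinate scores of a sample configuration."""
    centred = config - config.mean(axis=0, keepdims=True)
    # economy SVD: the scores U*S carry the full inter-sample geometry
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    return u * s


def procrustes_correlation(full_geometry, alr_geometry) -> float:
    """Procrustes correlation between two sample configurations.

    Both configurations are column-centred; the correlation is the nuclear
    norm of the cross-product of their principal-coordinate scores divided
    by the geometric mean of their total variances — the cosine similarity
    of the configurations after optimal translation, rotation and scaling.
    Always in [0, 1]; 1 means the geometries match exactly.
    """
    a = np.asarray(full_geometry, dtype=float)
    b = np.asarray(alr_geometry, dtype=float)
    if a.ndim != 2 or b.ndim != 2:
        raise ValueError("configurations must be 2-D (samples x coordinates)")
    if a.shape[0] != b.shape[0]:
        raise ValueError("configurations must share the same samples")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 samples for a Procrustes comparison")
    sa = _configuration_scores(a)
    sb = _configuration_scores(b)
    na = np.linalg.norm(sa)
    nb = np.linalg.norm(sb)
    if na == 0.0 or nb == 0.0:
        raise ValueError("degenerate (zero-variance) configuration")
    cross = sa.T @ sb
    corr = np.linalg.svd(cross, compute_uv=False).sum() / (na * nb)
    return float(min(corr, 1.0))


def select_alr_reference(
    matrix: pd.DataFrame, variance_quantile: float = 0.5
) -> AlrResult:
    """Scan every metabolite as candidate alr reference and pick the best.

    Candidates whose log-abundance variance falls below the panel's
    ``variance_quantile`` (default: median) pass the low-variance screen;
    among those, the one maximizing the Procrustes correlation between its
    alr geometry and the full pairwise-log-ratio geometry is selected.
    Ties break toward lower variance, then lexicographic identifier. The
    full candidate table is returned for diagnostics.

    The full-set geometry is represented by the clr configuration, which
    spans the same sample geometry as the complete pairwise log-ratio
    matrix up to rotation and scale (to which the Procrustes correlation
    is invariant).
    """
    _check_positive(matrix)
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 metabolites")
    if matrix.shape[0] < 3:
        raise ValueError("need at least 3 samples")

    log_x = np.log(matrix)
    log_var = log_x.var(axis=0, ddof=1)
    cutoff = float(log_var.quantile(variance_quantile))
    screened = log_var < cutoff
    if not screened.any():
        # all variances tied at the cutoff (e.g. two metabolites): keep all
        screened = pd.Series(True, index=log_var.index)

    full_scores = _configuration_scores(clr_transform(matrix).to_numpy())

    records = []
    for met in matrix.columns:
        alr = alr_transform(matrix, met)
        try:
            corr = procrustes_correlation(full_scores, alr.to_numpy())
        except ValueError:
            corr = np.nan
        records.append(
            {
                "metabolite_id": met,
                "procrustes_corr": corr,
                "log_variance": float(log_var[met]),
                "screened": bool(screened[met]),
            }
        )
    diagnostics = pd.DataFrame(records).set_index("metabolite_id")

    pool = diagnostics[diagnostics["screened"] & diagnostics["procrustes_corr"].notna()]
    if pool.empty:
        raise ValueError("all candidate references are degenerate")
    best = pool.sort_values(
        by=["procrustes_corr", "log_variance"],
        ascending=[False, True],
        kind="mergesort",  # stable: remaining ties fall back to lexicographic order
    )
    best = best.loc[best.index.sort_values()].sort_values(
        by=["procrustes_corr", "log_variance"], ascending=[False, True], kind="mergesort"
    )
    reference_id = str(best.index[0])

    return AlrResult(
        reference_id=reference_id,
        procrustes_corr=float(diagnostics.loc[reference_id, "procrustes_corr"]),
        reference_log_variance=float(diagnostics.loc[reference_id, "log_variance"]),
        transformed=alr_transform(matrix, reference_id),
        diagnostics=diagnostics,
    )
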
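"""Contrast construction: fold changes and regularized t-test p-values.

The fold change of gene *g* is ``log2(mean treated / mean control)`` on the
natural scale, or equivalently the difference of group means when the
matrix is already log2 (the usual gcrma output).

P-values come from a Bayesian-regularized two-group t-test in the Cyber-T
style: the per-probe sample variance is shrunk toward a background variance
estimated from probes of similar overall expression level.  At small group
sizes (2-3 arrays per side are common) the raw per-probe variance is a very
noisy estimate; borrowing strength from the local expression window
stabilizes the denominator of t and suppresses false positives driven by
accidentally tiny variances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ContrastRecord, ExpressionMatrix, GroupDefinition, ValidationError

logger = logging.getLogger(__name__)

#: smallest reportable p-value; exact zeros are never emitted
P_FLOOR = np.nextafter(0.0, 1.0)


@dataclass
class BayesTConfig:
    """Hyperparameters of the regularized t-test.

    window_size
        Number of probes (odd) in the sliding window, ordered by mean
        expression, over which the background variance is averaged.
    prior_df
        Pseudo-observations v0 backing the background variance; 0 recovers
        the classical pooled-variance t-test exactly.
    paired
        Use the paired statistic on (treated - control) differences; group
        sizes must match and samples pair by list order.
    """

    window_size: int = 101
    prior_df: float = 10.0
    paired: bool = False

    def __post_init__(self) -> None:
        if self.window_size < 3 or self.window_size % 2 == 0:
            raise ValidationError(f"window_size must be odd and >= 3, got {self.window_size}")
        if self.prior_df < 0:
            raise ValidationError(f"prior_df must be >= 0, got {self.prior_df}")


def compute_fold_change(matrix: ExpressionMatrix, groups: GroupDefinition) -> pd.Series:
    """Per-probe log2 fold change (treated over control), indexed in matrix probe order.

    On the linear scale a non-positive group mean makes the ratio undefined;
    such probes are set missing (NaN) and logged, never zero-filled.
    """
    groups.validate_against(matrix)
    ctrl = matrix.values[:, matrix.sample_index(groups.control_samples)]
    trt = matrix.values[:, matrix.sample_index(groups.treated_samples)]
    mean_c = ctrl.mean(axis=1)
    mean_t = trt.mean(axis=1)
    if matrix.scale == "linear":
        bad = (mean_c <= 0) | (mean_t <= 0)
        if bad.any():
            logger.warning(
                "%s: %d probes with non-positive group mean set to missing",
                groups.contrast_id,
                int(bad.sum()),
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            fold = np.log2(mean_t / mean_c)
        fold[bad] = np.nan
    else:
        fold = mean_t - mean_c
    return pd.Series(fold, index=matrix.probe_ids, name=groups.contrast_id)


def _clamped_window_mean(sorted_values: np.ndarray, window: int) -> np.ndarray:
    """Mean of ``sorted_values`` over a length-``window`` window centred on each
    position, clamped at the edges (edge positions reuse the first/last full
    window rather than a shrunken one)."""
    n = len(sorted_values)
    if n <= window:
        return np.full(n, sorted_values.mean() if n else np.nan)
    half = window // 2
    cs = np.concatenate(([0.0], np.cumsum(sorted_values)))
    starts = np.clip(np.arange(n) - half, 0, n - window)
    return (cs[starts + window] - cs[starts]) / window


def _background_variance(s2: np.ndarray, rank_order: np.ndarray, window: int) -> np.ndarray:
    """Average the per-probe variances ``s2`` over expression-rank windows."""
    inverse = np.empty_like(rank_order)
    inverse[rank_order] = np.arange(len(rank_order))
    smoothed_sorted = _clamped_window_mean(s2[rank_order], window)
    return smoothed_sorted[inverse]


def _two_tailed_p(t: np.ndarray, df: float) -> np.ndarray:
    return 2.0 * stats.t.sf(np.abs(t), df)


def bayes_t_statistics(
    matrix: ExpressionMatrix, groups: GroupDefinition, cfg: BayesTConfig | None = None
) -> tuple[pd.Series, pd.Series]:
    """Regularized t-statistics and two-tailed p-values, indexed by probe.

    Probes whose statistic is undefined (zero posterior variance with
    prior_df = 0 and zero difference information) carry NaN.
    """
    cfg = cfg or BayesTConfig()
    groups.validate_against(matrix)
    if groups.n_control < 2 or groups.n_treated < 2:
        raise ValidationError(f"{groups.contrast_id}: need >=2 samples per group for the t-test")
    values = matrix.values
    if matrix.scale == "linear":
        if np.any(values <= 0):
            raise ValidationError("linear-scale values must be positive for log transform")
        values = np.log2(values)
    ctrl = values[:, matrix.sample_index(groups.control_samples)]
    trt = values[:, matrix.sample_index(groups.treated_samples)]
    n_c, n_t = ctrl.shape[1], trt.shape[1]
    v0, w = cfg.prior_df, cfg.window_size
    # probes ranked by mean expression over every array in the contrast
    overall_mean = np.hstack([ctrl, trt]).mean(axis=1)
    rank_order = np.argsort(overall_mean, kind="stable")

    if cfg.paired:
        if n_c != n_t:
            raise ValidationError(
                f"{groups.contrast_id}: paired test needs equal group sizes ({n_c} vs {n_t})"
            )
        diff = trt - ctrl
        mean_d = diff.mean(axis=1)
        s2 = diff.var(axis=1, ddof=1)
        s0 = _background_variance(s2, rank_order, w)
        post = (v0 * s0 + (n_c - 1) * s2) / (v0 + n_c - 1)
        df = v0 + n_c - 1
        denom2 = post / n_c
        num = mean_d
    else:
        s2_c = ctrl.var(axis=1, ddof=1)
        s2_t = trt.var(axis=1, ddof=1)
        s0_c = _background_variance(s2_c, rank_order, w)
        s0_t = _background_variance(s2_t, rank_order, w)
        df = 2 * v0 + n_c + n_t - 2
        # pooled posterior variance: reduces to the classical pooled s_p^2 at v0 = 0
        sp2 = (v0 * s0_c + (n_c - 1) * s2_c + v0 * s0_t + (n_t - 1) * s2_t) / df
        denom2 = sp2 * (1.0 / n_c + 1.0 / n_t)
        num = trt.mean(axis=1) - ctrl.mean(axis=1)

    t = np.full(len(num), np.nan)
    ok = denom2 > 0
    t[ok] = num[ok] / np.sqrt(denom2[ok])
    # zero variance with a zero difference is 0/0: undefined, left missing
    p = np.full(len(num), np.nan)
    p[ok] = np.maximum(_two_tailed_p(t[ok], df), P_FLOOR)
    degenerate = (~ok) & (num != 0)
    if degenerate.any():
        logger.warning(
            "%s: %d probes with zero posterior variance flagged missing",
            groups.contrast_id,
            int((~ok).sum()),
        )
    index = pd.Index(matrix.probe_ids, name="probe_id")
    return (
        pd.Series(t, index=index, name="t"),
        pd.Series(p, index=index, name="pvalue"),
    )


def bayes_t_test(
    matrix: ExpressionMatrix, groups: GroupDefinition, cfg: BayesTConfig | None = None
) -> pd.Series:
    """Two-tailed p-values of the regularized t-test (see bayes_t_statistics)."""
    return bayes_t_statistics(matrix, groups, cfg)[1]


def build_contrast(
    matrix: ExpressionMatrix,
    groups: GroupDefinition,
    cfg: BayesTConfig | None = None,
    study_title: str = "",
) -> ContrastRecord:
    """Assemble one ContrastRecord: fold changes, p-values and metadata.

    Enforces the inclusion rule of at least two control and two treated
    arrays; thinner designs are rejected by name.
    """
    if groups.n_control < 2 or groups.n_treated < 2:
        raise ValidationError(
            f"contrast {groups.contrast_id!r} rejected: a minimum of two control and two "
            f"treated arrays is required (got {groups.n_control} control, "
            f"{groups.n_treated} treated)"
        )
    fold = compute_fold_change(matrix, groups)
    pvalue = bayes_t_test(matrix, groups, cfg)
    return ContrastRecord(
        contrast_id=groups.contrast_id,
        study_title=study_title or groups.description,
        n_control=groups.n_control,
        n_treated=groups.n_treated,
        design=groups.description,
        fold=fold,
        pvalue=pvalue,
    )
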
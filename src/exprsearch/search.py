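"""Signature and gene-list searches over a contrast database.

Two statistical query modes:

* profile search — Pearson correlation between a query signature (probe,
  log2 fold) and every contrast's fold values on the shared probes, ranked
  by signed r descending and truncated to the top-N (default 30);
* probe-list search — per contrast, a two-tailed t-test asking whether the
  listed genes are collectively up- or downregulated, with
  Benjamini-Hochberg q-values across all contrasts tested and a p < alpha
  filter (default 0.05).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import ContrastDatabase, EmptyResultError, Signature, ValidationError

logger = logging.getLogger(__name__)

_P_FLOOR = np.nextafter(0.0, 1.0)


@dataclass
class SearchConfig:
    """Knobs of the two statistical searches.

    top_n: number of correlation hits returned (the classic top-30).
    alpha: p-value cutoff for the probe-list search.
    min_overlap: minimum shared probes for a correlation to be computed;
        Pearson r on fewer than 3 points is degenerate.
    gene_list_mode: "one_sample" tests the listed genes' folds against 0
        within each contrast; "background" is a Welch t against the same
        genes' folds pooled over all other contrasts.
    """

    top_n: int = 30
    alpha: float = 0.05
    min_overlap: int = 3
    gene_list_mode: str = "one_sample"

    def __post_init__(self) -> None:
        if self.top_n < 1:
            raise ValidationError(f"top_n must be >= 1, got {self.top_n}")
        if not (0 < self.alpha < 1):
            raise ValidationError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.min_overlap < 3:
            raise ValidationError(f"min_overlap must be >= 3, got {self.min_overlap}")
        if self.gene_list_mode not in ("one_sample", "background"):
            raise ValidationError(f"unknown gene_list_mode {self.gene_list_mode!r}")


@dataclass
class CorrelationHit:
    contrast_id: str
    pearson_r: float
    study_title: str
    rank: int
    n_overlap: int = 0


@dataclass
class TTestHit:
    contrast_id: str
    p_value: float
    q_value: float
    t_statistic: float
    study_title: str
    n_probes: int = 0


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    q_(i) = min_{j>=i} p_(j) * m / j on the sorted p-values, clipped at 1
    and mapped back to input order; tied p-values receive equal q.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValidationError("bh_fdr expects a 1-d vector of p-values")
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = math.sqrt(float(xc @ xc) * float(yc @ yc))
    if denom == 0.0:
        return math.nan
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def profile_search(
    query: Signature, db: ContrastDatabase, cfg: SearchConfig | None = None
) -> list[CorrelationHit]:
    """Rank contrasts by Pearson correlation with the query signature.

    For each contrast the correlation uses only query probes present in the
    database and non-missing in that contrast; contrasts with fewer than
    ``min_overlap`` usable probes, or zero variance on either side, are
    excluded.  Results are sorted by signed r descending (ties broken by
    contrast id) and truncated to ``top_n``.
    """
    cfg = cfg or SearchConfig()
    universe = set(db.probe_universe)
    matched = [p for p in query.probe_ids if p in universe]
    unmatched = [p for p in query.probe_ids if p not in universe]
    if len(matched) < cfg.min_overlap:
        raise EmptyResultError(
            f"only {len(matched)} query probes found in the database "
            f"(need >= {cfg.min_overlap}); unmatched: {unmatched}",
            unmatched=unmatched,
        )
    if unmatched:
        logger.info("profile search: %d query probes not in database: %s", len(unmatched), unmatched)
    qfold = dict(query.entries)
    x_all = np.array([qfold[p] for p in matched])
    sub = db.fold_table.loc[matched]
    scored: list[CorrelationHit] = []
    for cid in sub.columns:
        y = sub[cid].to_numpy()
        ok = ~np.isnan(y)
        if ok.sum() < cfg.min_overlap:
            logger.debug("profile search: %s skipped (overlap %d)", cid, int(ok.sum()))
            continue
        r = _pearson(x_all[ok], y[ok])
        if math.isnan(r):
            logger.debug("profile search: %s skipped (zero variance)", cid)
            continue
        scored.append(
            CorrelationHit(
                contrast_id=cid,
                pearson_r=r,
                study_title=db.study_title(cid),
                rank=0,
                n_overlap=int(ok.sum()),
            )
        )
    scored.sort(key=lambda h: (-h.pearson_r, h.contrast_id))
    hits = scored[: cfg.top_n]
    for i, h in enumerate(hits, 1):
        h.rank = i
    return hits


def _one_sample_t(x: np.ndarray) -> tuple[float, float, float]:
    """t, p, df of the one-sample two-tailed t-test against mean 0."""
    k = len(x)
    mean = x.mean()
    sd = x.std(ddof=1)
    df = k - 1
    if sd == 0.0:
        if mean == 0.0:
            return 0.0, 1.0, df
        return math.copysign(math.inf, mean), _P_FLOOR, df
    t = mean / (sd / math.sqrt(k))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), max(float(p), _P_FLOOR), df


def probe_list_search(
    probes: list[str], db: ContrastDatabase, cfg: SearchConfig | None = None
) -> list[TTestHit]:
    """Find contrasts on which the listed genes move together.

    In ``one_sample`` mode the listed probes' fold values in each contrast
    are t-tested against 0; in ``background`` mode they are Welch-compared
    with the same probes' folds pooled across all other contrasts.  The
    sign of t reports the direction (positive = collectively upregulated).
    q-values are computed over every contrast actually tested; only hits
    with p < alpha are returned, sorted by p ascending.
    """
    cfg = cfg or SearchConfig()
    universe = set(db.probe_universe)
    matched = [p for p in probes if p in universe]
    unmatched = [p for p in probes if p not in universe]
    if len(matched) < 2:
        raise EmptyResultError(
            f"only {len(matched)} listed probes found in the database (need >= 2); "
            f"unmatched: {unmatched}",
            unmatched=unmatched,
        )
    sub = db.fold_table.loc[matched]
    tested: list[tuple[str, float, float, int]] = []
    for cid in sub.columns:
        x = sub[cid].to_numpy()
        x = x[~np.isnan(x)]
        if len(x) < 2:
            logger.info("probe-list search: %s skipped (%d usable probes)", cid, len(x))
            continue
        if cfg.gene_list_mode == "one_sample":
            t, p, _ = _one_sample_t(x)
        else:
            background = sub.drop(columns=cid).to_numpy().ravel()
            background = background[~np.isnan(background)]
            if len(background) < 2:
                logger.info("probe-list search: %s skipped (no background)", cid)
                continue
            t, p = stats.ttest_ind(x, background, equal_var=False)
            t, p = float(t), max(float(p), _P_FLOOR)
        tested.append((cid, p, t, len(x)))
    if not tested:
        raise EmptyResultError("no contrast had enough non-missing values for the listed probes")
    logger.info("probe-list search: BH correction over m = %d contrasts tested", len(tested))
    q = bh_fdr([p for _, p, _, _ in tested])
    hits = [
        TTestHit(
            contrast_id=cid,
            p_value=p,
            q_value=float(qi),
            t_statistic=t,
            study_title=db.study_title(cid),
            n_probes=k,
        )
        for (cid, p, t, k), qi in zip(tested, q)
        if p < cfg.alpha
    ]
    hits.sort(key=lambda h: (h.p_value, h.contrast_id))
    return hits


# display rounding used by the TSV writers: r to 8 decimals, p/q to 5, t to 4
def format_correlation_hits(hits: list[CorrelationHit]) -> list[str]:
    lines = ["contrast_id\tpearson_r\tstudy_title"]
    lines += [f"{h.contrast_id}\t{h.pearson_r:.8f}\t{h.study_title}" for h in hits]
    return lines


def format_ttest_hits(hits: list[TTestHit]) -> list[str]:
    lines = ["contrast_id\tp_value\tq_value\tt_statistic\tstudy_title"]
    lines += [
        f"{h.contrast_id}\t{h.p_value:.5f}\t{h.q_value:.5f}\t{h.t_statistic:.4f}\t{h.study_title}"
        for h in hits
    ]
    return lines
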
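"""Per-gene two-group differential-expression statistics.

Implements the statistic panel the distance-synthesis objective draws on —
ordinary t, SAM (t with a stabilizing fudge factor), fold change, empirical-Bayes
moderated t and F, and the B-statistic (log posterior odds of differential
expression) — plus the Wilcoxon-Mann-Whitney p-value that feeds the Fisher
meta-score.  All statistics are oriented small-group minus large-group.

Scalar functions operate on two 1-D sample vectors; :func:`compute_stat_matrix`
and :func:`batch_stat_values` evaluate the panel genome-wide, the latter for
many group relabelings at once (the permutation workload), using closed-form
group moments so the cost per relabeling is a pair of matrix products.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import special, stats

from .core import ExpressionStudy, GroupSplit

__all__ = [
    "ALL_STATS",
    "SIGNED_STATS",
    "StatMatrix",
    "ModerationPriors",
    "wmw_pvalue",
    "wmw_pvalues",
    "ordinary_t",
    "fold_change",
    "estimate_sam_s0",
    "sam_stat",
    "estimate_eb_priors",
    "moderated_t",
    "b_stat",
    "compute_stat_matrix",
    "batch_stat_values",
]

#: Statistic vocabulary, in canonical order.
ALL_STATS: tuple[str, ...] = ("t", "SAM", "FC", "B", "modT", "modF")

#: Statistics whose sign encodes direction; folding replaces them by |value|.
SIGNED_STATS: frozenset[str] = frozenset({"t", "SAM", "FC", "modT"})

# Guards for degenerate genes.
_SE_FLOOR = 1e-12  # standard-error floor before division in t-type statistics
_PRIOR_DF_CAP = 1e6  # prior df when log-variances show no excess spread
_B_FLOOR = -1e4  # clamp for the log posterior odds as de_proportion -> 0
_WMW_EXACT_MAX_N = 12  # exact rank-sum enumeration up to this pooled n


@dataclass(frozen=True)
class StatMatrix:
    """Genome-wide values of the selected statistics for one study, one split."""

    values: np.ndarray  # (I, J)
    stat_names: tuple[str, ...]
    study_id: str
    threshold_q: float
    folded: bool

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "stat_names", tuple(self.stat_names))
        if values.ndim != 2 or values.shape[1] != len(self.stat_names):
            raise ValueError("values must be (I, J) with J == len(stat_names)")
        if not 1 <= len(self.stat_names) <= 6:
            raise ValueError("between 1 and 6 statistics are supported")
        unknown = set(self.stat_names) - set(ALL_STATS)
        if unknown:
            raise ValueError(f"unknown statistic name(s): {sorted(unknown)}")
        if np.any(~np.isfinite(values)):
            raise ValueError("StatMatrix contains non-finite entries")
        if self.folded:
            for j, name in enumerate(self.stat_names):
                if name in SIGNED_STATS and np.any(values[:, j] < 0):
                    raise ValueError(f"folded column {name!r} has negative entries")

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.stat_names.index(name)]


@dataclass(frozen=True)
class ModerationPriors:
    """Empirical-Bayes hyperparameters for variance moderation and the B-statistic.

    ``prior_df`` / ``prior_var`` describe the scaled-inverse-chi-square prior
    on gene variances (estimated by moment matching on log sample variances);
    ``de_proportion`` is the prior probability a gene is differentially
    expressed, and ``effect_var_scale`` the ratio of the prior variance of a
    true effect to its sampling variance (the variance-inflation ratio minus
    one in the B-statistic).  Note the SAM fudge factor is a separate quantity
    (the ``s0`` argument of :func:`sam_stat`), not ``prior_var``.
    """

    prior_df: float
    prior_var: float
    de_proportion: float = 0.01
    effect_var_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.prior_df < 0:
            raise ValueError("prior_df must be >= 0")
        if self.prior_df > 0 and self.prior_var <= 0:
            raise ValueError("prior_var must be > 0")
        if not 0 < self.de_proportion < 1:
            raise ValueError("de_proportion must be in (0, 1)")
        if self.effect_var_scale <= 0:
            raise ValueError("effect_var_scale must be > 0")


# ---------------------------------------------------------------------------
# scalar statistics
# ---------------------------------------------------------------------------


def wmw_pvalue(x_small: np.ndarray, x_large: np.ndarray) -> float:
    """Two-sided Wilcoxon-Mann-Whitney p-value, small vs large group.

    Exact enumeration of the rank-sum distribution when the pooled sample has
    at most 12 observations and no ties; otherwise the normal approximation
    with tie and continuity corrections.
    """
    x_small = np.asarray(x_small, dtype=float)
    x_large = np.asarray(x_large, dtype=float)
    if x_small.size == 0 or x_large.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x_small, x_large])
    if pooled.size <= _WMW_EXACT_MAX_N and np.unique(pooled).size == pooled.size:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x_small, x_large, alternative="two-sided", method=method
    )
    return float(min(res.pvalue, 1.0))


def wmw_pvalues(expression: np.ndarray, small_mask: np.ndarray) -> np.ndarray:
    """Row-wise WMW p-values for a features x samples matrix.

    Applies the same exact/approximate switchover as :func:`wmw_pvalue`; for
    pooled n > 12 the whole matrix is tested in one vectorized call.
    """
    X = np.asarray(expression, dtype=float)
    mask = np.asarray(small_mask, dtype=bool)
    xs, xl = X[:, mask], X[:, ~mask]
    if X.shape[1] > _WMW_EXACT_MAX_N:
        res = stats.mannwhitneyu(
            xs, xl, alternative="two-sided", method="asymptotic", axis=1
        )
        return np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
    return np.array([wmw_pvalue(a, b) for a, b in zip(xs, xl)])


def _pooled_se(x_small: np.ndarray, x_large: np.ndarray) -> tuple[float, float, int]:
    n1, n2 = len(x_small), len(x_large)
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs >= 2 observations")
    df = n1 + n2 - 2
    ss = (n1 - 1) * np.var(x_small, ddof=1) + (n2 - 1) * np.var(x_large, ddof=1)
    pooled_var = ss / df
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    return float(se), float(pooled_var), df


def ordinary_t(x_small: np.ndarray, x_large: np.ndarray) -> float:
    """Pooled-variance two-sample t statistic (small minus large); 0/0 -> 0."""
    x_small = np.asarray(x_small, dtype=float)
    x_large = np.asarray(x_large, dtype=float)
    se, _, _ = _pooled_se(x_small, x_large)
    diff = float(np.mean(x_small) - np.mean(x_large))
    if se < _SE_FLOOR:
        return 0.0 if diff == 0.0 else diff / _SE_FLOOR
    return diff / se


def fold_change(x_small: np.ndarray, x_large: np.ndarray) -> float:
    """Difference of group means (the log-scale fold change), small minus large."""
    if len(x_small) == 0 or len(x_large) == 0:
        raise ValueError("both groups must be non-empty")
    return float(np.mean(x_small) - np.mean(x_large))


def sam_stat(x_small: np.ndarray, x_large: np.ndarray, s0: float) -> float:
    """SAM statistic: mean difference over (standard error + fudge factor s0)."""
    x_small = np.asarray(x_small, dtype=float)
    x_large = np.asarray(x_large, dtype=float)
    if s0 < 0:
        raise ValueError("s0 must be >= 0")
    se, _, _ = _pooled_se(x_small, x_large)
    diff = float(np.mean(x_small) - np.mean(x_large))
    denom = se + s0
    if denom < _SE_FLOOR:
        return 0.0 if diff == 0.0 else diff / _SE_FLOOR
    return diff / denom


def estimate_sam_s0(
    per_gene_means_diff: np.ndarray,
    per_gene_se: np.ndarray,
    n_bins: int = 10,
    percentile_step: int = 5,
) -> float:
    """Select the SAM fudge factor from the standard-error distribution.

    Candidates are the percentiles {0, 5, ..., 100} of the per-gene standard
    errors; the winner minimizes the coefficient of variation of the median
    absolute deviation of the SAM statistic across ``n_bins`` se-quantile bins
    (the published SAM recipe).  A small positive floor is enforced so genes
    with zero standard error never divide by zero.
    """
    diff = np.asarray(per_gene_means_diff, dtype=float)
    se = np.asarray(per_gene_se, dtype=float)
    if diff.shape != se.shape or diff.ndim != 1:
        raise ValueError("diff and se must be 1-D vectors of equal length")
    if np.any(se < 0):
        raise ValueError("standard errors must be >= 0")
    floor = 1e-8 * max(float(np.median(se)), 1.0)
    if diff.size < 2:
        return max(float(se[0]) if se.size else 0.0, floor)

    candidates = np.percentile(se, np.arange(0, 101, percentile_step))
    order = np.argsort(se, kind="stable")
    k = min(n_bins, diff.size)

    if diff.size % k == 0:
        # equal se-quantile bins: evaluate every candidate in two median calls
        denom = np.maximum(se[order][None, :] + candidates[:, None], _SE_FLOOR)
        dr = (diff[order][None, :] / denom).reshape(len(candidates), k, -1)
        med = np.median(dr, axis=2, keepdims=True)
        mads = np.median(np.abs(dr - med), axis=2)  # (n_candidates, k)
        m = mads.mean(axis=1)
        sd = mads.std(axis=1, ddof=1) if k > 1 else np.zeros(len(candidates))
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(m > 0, sd / m, np.where(sd == 0, 0.0, np.inf))
        return max(float(candidates[int(np.argmin(cv))]), floor)

    bins = np.array_split(order, k)
    best_cv, best_s0 = np.inf, float(candidates[0])
    for s0 in candidates:
        d = diff / np.maximum(se + s0, _SE_FLOOR)
        mads = np.array(
            [np.median(np.abs(d[b] - np.median(d[b]))) for b in bins if b.size]
        )
        m = mads.mean()
        sd = mads.std(ddof=1) if mads.size > 1 else 0.0
        cv = 0.0 if (m == 0 and sd == 0) else (np.inf if m == 0 else sd / m)
        if cv < best_cv - 1e-15:
            best_cv, best_s0 = cv, float(s0)
    return max(best_s0, floor)


def _fit_scaled_inv_chisq(variances: np.ndarray, residual_df: int) -> tuple[np.ndarray, np.ndarray]:
    """Moment-match log sample variances to a scaled-inverse-chi-square prior.

    Works column-wise on a (I,) or (I, B) array of per-gene sample variances;
    returns (prior_df, prior_var) arrays of shape () or (B,).  Columns whose
    log-variance spread does not exceed the chi-square-implied spread get
    prior_df at the cap (effectively a common variance across genes).
    """
    v = np.atleast_2d(np.asarray(variances, dtype=float).T).T  # (I, B)
    df = float(residual_df)
    z = np.log(np.maximum(v, 1e-300))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean(axis=0)
    evar = e.var(axis=0, ddof=1)
    rhs = evar - special.polygamma(1, df / 2.0)

    x = np.full(rhs.shape, _PRIOR_DF_CAP / 2.0)
    degenerate = evar < 1e-12  # no gene-to-gene spread at all: the common
    solvable = rhs > 0         # variance is the only consistent prior scale
    if np.any(solvable):
        r = rhs[solvable]
        xs = 0.5 + 1.0 / r  # trigamma(x) ~ 1/x + 1/(2x^2) inversion start
        for _ in range(50):
            f = special.polygamma(1, xs) - r
            fp = special.polygamma(2, xs)
            step = f / fp
            xs_new = np.clip(xs - step, 1e-8, _PRIOR_DF_CAP / 2.0)
            if np.max(np.abs(xs_new - xs)) < 1e-12:
                xs = xs_new
                break
            xs = xs_new
        x[solvable] = xs
    prior_df = np.minimum(2.0 * x, _PRIOR_DF_CAP)
    prior_var = np.exp(emean + special.digamma(x) - np.log(x))
    prior_var = np.where(degenerate, np.exp(z.mean(axis=0)), prior_var)
    return np.squeeze(prior_df), np.squeeze(prior_var)


def estimate_eb_priors(per_gene_var: np.ndarray, residual_df: int) -> ModerationPriors:
    """Estimate the variance prior (df and scale) from genome-wide sample variances.

    Falls back to no moderation (``prior_df = 0``) with a warning when fewer
    than two genes carry a positive variance.
    """
    v = np.asarray(per_gene_var, dtype=float)
    usable = v[np.isfinite(v) & (v > 0)]
    if usable.size < 2:
        warnings.warn(
            "fewer than 2 genes with positive variance; moderation disabled",
            RuntimeWarning,
            stacklevel=2,
        )
        return ModerationPriors(prior_df=0.0, prior_var=1.0)
    prior_df, prior_var = _fit_scaled_inv_chisq(usable, residual_df)
    return ModerationPriors(prior_df=float(prior_df), prior_var=float(prior_var))


def moderated_t(
    x_small: np.ndarray, x_large: np.ndarray, priors: ModerationPriors
) -> tuple[float, float]:
    """Empirical-Bayes moderated t and F for one gene.

    The posterior variance shrinks the gene's pooled variance toward the prior
    scale by prior_df pseudo-observations; with two groups the moderated F is
    the square of the moderated t.
    """
    x_small = np.asarray(x_small, dtype=float)
    x_large = np.asarray(x_large, dtype=float)
    se, pooled_var, df = _pooled_se(x_small, x_large)
    n1, n2 = len(x_small), len(x_large)
    diff = float(np.mean(x_small) - np.mean(x_large))
    d0 = priors.prior_df
    s2_post = (d0 * priors.prior_var + df * pooled_var) / (d0 + df) if (d0 + df) > 0 else 0.0
    denom = np.sqrt(max(s2_post, 0.0) * (1.0 / n1 + 1.0 / n2))
    if denom < _SE_FLOOR:
        mod_t = 0.0 if diff == 0.0 else diff / _SE_FLOOR
    else:
        mod_t = diff / denom
    return float(mod_t), float(mod_t) ** 2


def b_stat(
    mod_t: float | np.ndarray,
    total_df: float,
    priors: ModerationPriors,
    floor: float = _B_FLOOR,
) -> float | np.ndarray:
    """Log posterior odds of differential expression given a moderated t.

    Under the hierarchical two-component model a true effect inflates the
    sampling variance of the moderated t by the factor
    ``r = 1 + effect_var_scale``, giving

        B = log(p / (1 - p)) - log(r) / 2
            + (total_df + 1) / 2 * log((t^2 + total_df) / (t^2 / r + total_df))

    which is symmetric in t and strictly increasing in |t|.  ``total_df`` is
    the moderated residual df (residual df + prior df).  The result is clamped
    below at ``floor`` so a vanishing prior DE proportion stays finite.
    """
    t2 = np.square(np.asarray(mod_t, dtype=float))
    p = priors.de_proportion
    r = 1.0 + priors.effect_var_scale
    d = min(float(total_df), _PRIOR_DF_CAP)
    kernel = (d + 1.0) / 2.0 * np.log((t2 + d) / (t2 / r + d))
    out = np.log(p / (1.0 - p)) - 0.5 * np.log(r) + kernel
    out = np.maximum(out, floor)
    return float(out) if np.isscalar(mod_t) else out


# ---------------------------------------------------------------------------
# genome-wide (batched) evaluation
# ---------------------------------------------------------------------------


def _batch_moments(X: np.ndarray, masks: np.ndarray):
    """Group means and pooled variances for B small-group masks at once.

    X is (I, n); masks is (B, n) boolean.  Returns (diff, se, pooled_var, df)
    with gene-by-mask arrays of shape (I, B).  One matrix product per moment
    makes the permutation workload cheap.
    """
    n = X.shape[1]
    n1 = masks.sum(axis=1).astype(float)  # (B,)
    n2 = n - n1
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("each group needs >= 2 samples in every mask")
    M = masks.T.astype(float)  # (n, B)
    X2 = X * X
    S1 = X @ M  # (I, B)
    Q1 = X2 @ M
    S = X.sum(axis=1, keepdims=True)
    Q = X2.sum(axis=1, keepdims=True)
    mean1 = S1 / n1
    mean2 = (S - S1) / n2
    ss1 = np.maximum(Q1 - n1 * mean1**2, 0.0)
    ss2 = np.maximum((Q - Q1) - n2 * mean2**2, 0.0)
    df = n - 2
    pooled_var = (ss1 + ss2) / df
    diff = mean1 - mean2
    se = np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    return diff, se, pooled_var, df


def batch_stat_values(
    expression: np.ndarray,
    small_masks: np.ndarray,
    stat_names: Sequence[str] = ALL_STATS,
    fold: bool = True,
) -> np.ndarray:
    """Evaluate the statistic panel for each of B group relabelings.

    Returns an array of shape (B, I, J).  The SAM fudge factor and the
    empirical-Bayes hyperparameters are re-estimated independently for every
    relabeling, exactly as for the observed labeling, so permutation extreme
    points are calibrated like the observed one.
    """
    X = np.asarray(expression, dtype=float)
    masks = np.atleast_2d(np.asarray(small_masks, dtype=bool))
    stat_names = tuple(stat_names)
    unknown = set(stat_names) - set(ALL_STATS)
    if unknown:
        raise ValueError(f"unknown statistic name(s): {sorted(unknown)}")

    diff, se, pooled_var, df = _batch_moments(X, masks)
    B_count, I = masks.shape[0], X.shape[0]
    need_mod = bool({"modT", "modF", "B"} & set(stat_names))

    se_safe = np.maximum(se, _SE_FLOOR)
    out = np.empty((B_count, I, len(stat_names)), dtype=float)

    if need_mod:
        prior_df, prior_var = _fit_scaled_inv_chisq(pooled_var, df)
        prior_df = np.atleast_1d(prior_df)
        prior_var = np.atleast_1d(prior_var)
        n1 = masks.sum(axis=1).astype(float)
        n2 = masks.shape[1] - n1
        c = 1.0 / n1 + 1.0 / n2
        s2_post = (prior_df * prior_var + df * pooled_var) / (prior_df + df)
        mod_t = diff / np.maximum(np.sqrt(s2_post * c), _SE_FLOOR)

    for j, name in enumerate(stat_names):
        if name == "t":
            vals = diff / se_safe
        elif name == "FC":
            vals = diff
        elif name == "SAM":
            vals = np.empty_like(diff)
            for b in range(B_count):
                s0 = estimate_sam_s0(diff[:, b], se[:, b])
                vals[:, b] = diff[:, b] / np.maximum(se[:, b] + s0, _SE_FLOOR)
        elif name == "modT":
            vals = mod_t
        elif name == "modF":
            vals = mod_t**2
        elif name == "B":
            vals = np.empty_like(diff)
            for b in range(B_count):
                v0 = max(float(np.percentile(mod_t[:, b] ** 2, 90)) - 1.0, 0.1)
                pri = ModerationPriors(
                    prior_df=float(prior_df[b]),
                    prior_var=float(prior_var[b]),
                    effect_var_scale=v0,
                )
                vals[:, b] = b_stat(mod_t[:, b], df + prior_df[b], pri)
        if fold and name in SIGNED_STATS:
            vals = np.abs(vals)
        out[:, :, j] = vals.T
    return out


def compute_stat_matrix(
    study: ExpressionStudy,
    split: GroupSplit,
    stat_names: Sequence[str] = ALL_STATS,
    fold: bool = True,
) -> StatMatrix:
    """Genome-wide statistic panel for one study at one threshold.

    The SAM fudge factor and the moderation priors are estimated once from
    this study/split, then applied to every gene.  With ``fold`` (the default)
    the signed statistics t, SAM, FC and modT are replaced by their absolute
    values, so "larger = more differentially expressed" holds for every column
    — the orientation the extreme-point distance synthesis requires.
    """
    if not split.valid:
        raise ValueError(
            f"invalid split at q={split.threshold_q:g} for study "
            f"{study.study_id!r}: groups {split.n_small}/{split.n_large} "
            f"below min_group={split.min_group}"
        )
    values = batch_stat_values(
        study.expression, split.small_mask[None, :], stat_names, fold=fold
    )[0]
    return StatMatrix(
        values=values,
        stat_names=tuple(stat_names),
        study_id=study.study_id,
        threshold_q=split.threshold_q,
        folded=fold,
    )
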
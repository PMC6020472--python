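"""Per-dataset two-group differential expression.

The meta-analysis needs, for every gene in every study, a p-value and a
direction of change.  The workhorse here is a moderated t-test: the
per-gene residual variance is shrunk toward a common prior variance
estimated empirically across all genes, which stabilizes the statistic
at the small group sizes typical of treatment-vs-control expression
studies.  The prior is a scaled inverse-chi-square distribution whose
parameters (d0 degrees of freedom, s0^2 scale) are obtained by moment
matching on the log variances, and the moderated variance is

    s~_g^2 = (d0 * s0^2 + df_g * s_g^2) / (d0 + df_g)

with the moderated t referred to a t distribution on d0 + df_g degrees
of freedom.  A Welch test is available as an unmoderated fallback, and
a simple fold-change filter covers the proteome-style comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping

import numpy as np
from scipy import special, stats

from .expr_io import GROUP_CONTROL, GROUP_TREATED, ExpressionDataset

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_ZERO = "zero"

#: d0 above this is treated as infinite (complete shrinkage to s0^2)
D0_CAP = 1e6


@dataclass(frozen=True)
class DEResult:
    """Differential-expression record for one gene.

    ``log2fc`` is treated mean minus control mean on the log2 scale;
    ``direction`` is the sign of ``log2fc`` (``zero`` for an exact tie).
    """

    gene: str
    log2fc: float
    t_stat: float
    p_value: float
    direction: str


def _direction(log2fc: float) -> str:
    if log2fc > 0:
        return DIRECTION_UP
    if log2fc < 0:
        return DIRECTION_DOWN
    return DIRECTION_ZERO


def _group_matrices(dataset: ExpressionDataset) -> tuple[np.ndarray, np.ndarray]:
    ctrl = dataset.samples_in_group(GROUP_CONTROL)
    trt = dataset.samples_in_group(GROUP_TREATED)
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError(
            f"{dataset.dataset_id}: need >=2 samples per group "
            f"(control={len(ctrl)}, treated={len(trt)})"
        )
    return (
        dataset.data[ctrl].to_numpy(dtype=float),
        dataset.data[trt].to_numpy(dtype=float),
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0.

    Newton iteration on the monotone decreasing trigamma function with a
    bisection safeguard; tolerance 1e-8.  Large x (small y) corresponds
    to a tight (nearly infinite-df) variance prior.
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    # trigamma(x) ~ 1/x + 1/(2x^2); start from the 1/x approximation
    x = 0.5 + 1.0 / y
    lo, hi = 1e-12, 1e12
    for _ in range(100):
        f = special.polygamma(1, x) - y
        if f > 0:
            lo = max(lo, x)
        else:
            hi = min(hi, x)
        step = f / special.polygamma(2, x)  # f' = polygamma(2) < 0
        x_new = x - step
        if not (lo < x_new < hi):
            x_new = 0.5 * (lo + hi)
        if abs(x_new - x) < 1e-8 * max(1.0, abs(x)):
            return x_new
        x = x_new
    return x


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to residual variances.

    Works on the log scale: for s2 ~ s0^2 * chisq_d0 scaling, the
    statistic z = log(s2) has known mean/variance expressible through
    digamma/trigamma functions, so matching the empirical mean and
    variance of z yields (d0, s0^2).  Returns ``(inf, s0^2)`` when the
    observed spread of log variances is no larger than expected from the
    residual degrees of freedom alone.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        # not enough information to fit a prior
        return 0.0, float(s2[ok].mean()) if ok.any() else 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if e_var <= 0:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
        return d0, s0_sq
    half_d0 = _trigamma_inverse(e_var)
    d0 = 2.0 * half_d0
    if d0 > D0_CAP:
        return np.inf, float(np.exp(e_mean))
    s0_sq = float(np.exp(e_mean + special.digamma(half_d0) - np.log(half_d0)))
    return d0, s0_sq


def moderated_two_group_test(dataset: ExpressionDataset) -> list[DEResult]:
    """Empirical-Bayes moderated t-test of treated vs. control samples.

    Requires a log2-scale matrix with at least two samples per group.
    With a single gene the prior cannot be estimated and the statistic
    reduces to the ordinary pooled-variance t-test.
    """
    ctrl, trt = _group_matrices(dataset)
    n1, n2 = ctrl.shape[1], trt.shape[1]
    df_res = n1 + n2 - 2

    diff = trt.mean(axis=1) - ctrl.mean(axis=1)
    ss = ((ctrl - ctrl.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (trt - trt.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / df_res

    if len(diff) >= 2:
        d0, s0_sq = estimate_variance_prior(s2, df_res)
    else:
        d0, s0_sq = 0.0, 0.0

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_sq + df_res * s2) / (d0 + df_res)
        df_total = d0 + df_res

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = np.where(se > 0, diff / se, np.where(diff == 0, 0.0, np.inf * np.sign(diff)))
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t_stat))
    else:
        p = 2.0 * stats.t.sf(np.abs(t_stat), df_total)
    p = np.clip(p, np.finfo(float).tiny, 1.0)

    return [
        DEResult(
            gene=g,
            log2fc=float(diff[i]),
            t_stat=float(t_stat[i]),
            p_value=float(p[i]),
            direction=_direction(float(diff[i])),
        )
        for i, g in enumerate(dataset.genes)
    ]


def welch_two_group_test(dataset: ExpressionDataset) -> list[DEResult]:
    """Welch's unequal-variance t-test (Satterthwaite df), per gene."""
    ctrl, trt = _group_matrices(dataset)
    t_stat, p = stats.ttest_ind(trt, ctrl, axis=1, equal_var=False)
    diff = trt.mean(axis=1) - ctrl.mean(axis=1)
    t_stat = np.where(np.isnan(t_stat), 0.0, t_stat)
    p = np.where(np.isnan(p), 1.0, p)
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    return [
        DEResult(
            gene=g,
            log2fc=float(diff[i]),
            t_stat=float(t_stat[i]),
            p_value=float(p[i]),
            direction=_direction(float(diff[i])),
        )
        for i, g in enumerate(dataset.genes)
    ]


def fold_change_filter(
    values_before: Mapping[str, float],
    values_after: Mapping[str, float],
    fold: float = 2.0,
    one_sided_policy: Literal["assign", "drop"] = "assign",
) -> tuple[set[str], set[str]]:
    """Split proteins into increased / decreased sets by fold change.

    A protein is *increased* when after/before strictly exceeds ``fold``
    and *decreased* when before/after does.  Proteins detected on only
    one side are, under the default policy, assigned to the side where
    they were detected (only-after -> increased, only-before ->
    decreased); ``drop`` discards them instead.
    """
    if fold < 1:
        raise ValueError("fold must be >= 1")
    for name, vals in (("before", values_before), ("after", values_after)):
        non_pos = [p for p, v in vals.items() if v <= 0]
        if non_pos:
            raise ValueError(f"non-positive abundance in '{name}': {non_pos}")
    increased: set[str] = set()
    decreased: set[str] = set()
    for p in set(values_before) | set(values_after):
        if p in values_before and p in values_after:
            ratio = values_after[p] / values_before[p]
            if ratio > fold:
                increased.add(p)
            elif 1.0 / ratio > fold:
                decreased.add(p)
        elif one_sided_policy == "assign":
            if p in values_after:
                increased.add(p)
            else:
                decreased.add(p)
    return increased, decreased


def write_de_results(results: Iterable[DEResult], path) -> None:
    """Write DE records as ``gene<TAB>log2fc<TAB>t<TAB>p<TAB>direction``."""
    with open(path, "w") as fh:
        fh.write("gene\tlog2fc\tt\tp\tdirection\n")
        for r in results:
            fh.write(
                f"{r.gene}\t{r.log2fc:.6g}\t{r.t_stat:.6g}\t"
                f"{r.p_value:.6g}\t{r.direction}\n"
            )
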
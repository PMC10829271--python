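"""Goodness-of-fit and benchmarking diagnostics.

Randomized quantile residuals (RQRs) map each discrete count observation
through the fitted NB distribution function to a standard-normal scale:
r_i = Phi^{-1}(u_i) with u_i drawn uniformly on (F(y_i - 1), F(y_i)].
Under a correctly specified model the residuals are standard normal, so a
Q-Q plot against normal quantiles (or a KS test) diagnoses the fit. A
deterministic mid-quantile mode takes the interval midpoint instead of a
draw, which removes randomization noise in automated checks.

The evaluation report scores demultiplexing calls against ground truth
with per-tag one-vs-rest precision/recall/F over singlet calls, plus a
confusion summary over {singlet-by-tag, multiplet, negative}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .classify import MULTIPLET, NEGATIVE
from .nb_model import nb_cdf

__all__ = [
    "rqr",
    "cap_infinite",
    "qq_points",
    "rqr_matrix",
    "evaluate",
    "EvalReport",
]


def rqr(
    y,
    mu,
    theta: float,
    rng: np.random.Generator | None = None,
    mid_quantile: bool = False,
) -> np.ndarray:
    """Randomized quantile residuals for counts under NB(mu, theta).

    ``mu`` may be a scalar or a per-observation vector of fitted means.
    Where F(y) is numerically 1 the residual is +inf; cap before plotting.
    """
    y = np.asarray(y)
    lo = nb_cdf(y - 1, mu, theta)
    hi = nb_cdf(y, mu, theta)
    if mid_quantile:
        u = (lo + hi) / 2.0
    else:
        if rng is None:
            raise ValueError("randomized mode requires a seeded rng")
        # uniform on (lo, hi]: take hi - v*(hi-lo) with v ~ U[0, 1)
        u = hi - rng.random(y.shape) * (hi - lo)
    return stats.norm.ppf(u)


def cap_infinite(residuals) -> tuple[np.ndarray, bool]:
    """Replace +inf residuals by (max finite residual + 1).

    Returns the capped array and whether any capping was applied; the
    caller keeps the originals if it needs them.
    """
    r = np.asarray(residuals, dtype=float)
    inf_mask = np.isposinf(r)
    finite = r[np.isfinite(r)]
    if finite.size == 0:
        raise ValueError("all residuals are infinite; nothing to cap against")
    if not inf_mask.any():
        return r.copy(), False
    out = r.copy()
    out[inf_mask] = finite.max() + 1.0
    return out, True


def qq_points(residuals) -> tuple[np.ndarray, np.ndarray]:
    """(theoretical normal quantiles, sorted residuals) for a Q-Q plot.

    Rank k of n maps to Phi^{-1}((k - 0.5) / n). Residuals must be finite
    (apply :func:`cap_infinite` first).
    """
    r = np.sort(np.asarray(residuals, dtype=float))
    n = r.size
    if n == 0:
        raise ValueError("no residuals")
    if not np.all(np.isfinite(r)):
        raise ValueError("residuals must be finite; cap infinities first")
    k = np.arange(1, n + 1)
    return stats.norm.ppf((k - 0.5) / n), r


def rqr_matrix(
    matrix,
    result,
    rng: np.random.Generator | None = None,
    mid_quantile: bool = False,
) -> pd.DataFrame:
    """Per-cell, per-tag RQRs under each tag's fitted negative-cell model.

    Cells with zero totals or unfit tags yield NaN.
    """
    totals = matrix.total_counts()
    counts = np.asarray(matrix.counts.todense())
    out = np.full((matrix.n_cells, matrix.n_tags), np.nan)
    included = totals > 0
    log_total = np.log(totals[included].astype(float))
    for j, tag in enumerate(matrix.tag_names):
        fit = result.tag_fits[tag].fit_neg
        if fit is None:
            continue
        mu = fit.mean(log_total)
        out[included, j] = rqr(
            counts[included, j], mu, fit.theta, rng=rng, mid_quantile=mid_quantile
        )
    return pd.DataFrame(
        out,
        index=pd.Index(matrix.cell_barcodes, name="barcode"),
        columns=matrix.tag_names,
    )


@dataclass
class EvalReport:
    """Per-tag precision/recall/F over singlet calls plus confusion summary."""

    per_tag: pd.DataFrame  # index tag; columns precision, recall, f_score, tp, fp, fn, undefined
    macro_precision: float
    macro_recall: float
    macro_f: float
    confusion: pd.DataFrame  # truth class x called class counts
    doublet_precision: float = float("nan")
    doublet_recall: float = float("nan")

    def to_frame(self) -> pd.DataFrame:
        df = self.per_tag.copy()
        df.loc["__macro__"] = {
            "precision": self.macro_precision,
            "recall": self.macro_recall,
            "f_score": self.macro_f,
        }
        return df


def _f_score(p: float, r: float) -> float:
    return 0.0 if p + r == 0 else 2 * p * r / (p + r)


def evaluate(truth, calls, tag_names=None) -> EvalReport:
    """Score calls against ground truth.

    ``truth`` holds per-cell labels: a tag name for singlets, "multiplet"
    (any droplet from two or more samples), or "negative". Per-tag scoring
    is one-vs-rest over singlets: TP = true singlet of T called T; FP =
    any other cell called T; FN = true singlet of T called anything else
    (multiplet and negative calls count as misses). True multiplets enter
    the confusion summary and the separate doublet precision/recall, never
    the per-tag F-scores.
    """
    truth = list(map(str, truth))
    calls = list(map(str, calls))
    if len(truth) != len(calls):
        raise ValueError("truth and calls have different lengths")
    special = {MULTIPLET, NEGATIVE}
    if tag_names is None:
        tag_names = sorted({t for t in truth if t not in special})
    t = np.asarray(truth, dtype=object)
    c = np.asarray(calls, dtype=object)

    rows = []
    for tag in tag_names:
        tp = int(np.sum((t == tag) & (c == tag)))
        fp = int(np.sum((t != tag) & (c == tag)))
        fn = int(np.sum((t == tag) & (c != tag)))
        undefined = (tp + fp == 0) or (tp + fn == 0)
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        rows.append(
            dict(
                tag=tag, precision=p, recall=r, f_score=_f_score(p, r),
                tp=tp, fp=fp, fn=fn, undefined=undefined,
            )
        )
    per_tag = pd.DataFrame(rows).set_index("tag")

    classes = list(tag_names) + [MULTIPLET, NEGATIVE]
    lab = {k: i for i, k in enumerate(classes)}
    other = len(classes)
    conf = np.zeros((len(classes) + 1, len(classes) + 1), dtype=int)
    for ti, ci in zip(t, c):
        conf[lab.get(ti, other), lab.get(ci, other)] += 1
    confusion = pd.DataFrame(
        conf,
        index=pd.Index(classes + ["other"], name="truth"),
        columns=pd.Index(classes + ["other"], name="called"),
    )

    dt = t == MULTIPLET
    dc = c == MULTIPLET
    d_tp = int(np.sum(dt & dc))
    d_p = d_tp / int(dc.sum()) if dc.sum() else float("nan")
    d_r = d_tp / int(dt.sum()) if dt.sum() else float("nan")

    return EvalReport(
        per_tag=per_tag,
        macro_precision=float(per_tag["precision"].mean()),
        macro_recall=float(per_tag["recall"].mean()),
        macro_f=float(per_tag["f_score"].mean()),
        confusion=confusion,
        doublet_precision=d_p,
        doublet_recall=d_r,
    )
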
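"""EM classifier over two GLM-NB model spaces.

For each tag the algorithm treats the latent label Z_i (cell i positively
stained with the tag or not) as missing data. Negative cells are modeled
in the X vs N_total space — the observed tag count is contamination whose
mean scales with the cell's total tag count — and positive cells in the
N_total - X vs N_total space, where the pooled contamination by all other
tags behaves like a single meta-tag. EM alternates fitting the two NB
regressions on the current hard assignment (M step) with recomputing
per-cell posteriors from the fitted densities and class priors (E step),
starting from a cosine-similarity cutoff against each tag's canonical
unit vector.

Cells are finally called a singlet of tag T (only T's posterior above the
probability cutoff), a multiplet (two or more tags above), or negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .io_tagcount import TagCountMatrix, stable_cell_scores
from .nb_model import GlmNbFit, fit_glm_nb, nb_log_pmf

__all__ = [
    "ClassifyConfig",
    "TagFitResult",
    "ClassificationResult",
    "total_tag_counts",
    "cosine_canonical",
    "init_assignment",
    "m_step",
    "e_step",
    "em_tag",
    "call_cells",
    "demultiplex",
]

logger = logging.getLogger(__name__)

MULTIPLET = "multiplet"
NEGATIVE = "negative"


@dataclass
class ClassifyConfig:
    """Tunable parameters of the EM classifier (defaults are the method's)."""

    init_cosine_cutoff: float = 0.5
    prob_cutoff: float = 0.5
    max_fit_cells: int = 5000
    max_iter: int = 30
    min_cells_per_class: int = 10
    min_fit_obs: int = 10
    seed: int = 0
    log1p_cosine: bool = False  # cosine on raw counts by default

    def __post_init__(self) -> None:
        if not 0 < self.init_cosine_cutoff < 1:
            raise ValueError("init_cosine_cutoff must be in (0, 1)")
        if not 0 < self.prob_cutoff < 1:
            raise ValueError("prob_cutoff must be in (0, 1)")


class UnfitTagError(ValueError):
    """Raised when a tag has too few cells on one side of the init cutoff."""


@dataclass
class TagFitResult:
    """Per-tag EM output."""

    tag: str
    posterior_pos: np.ndarray  # P(Z=1) per included cell
    z_init: np.ndarray
    fit_neg: GlmNbFit | None
    fit_pos: GlmNbFit | None
    prior_trace: list[tuple[float, float]] = field(default_factory=list)
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    unfit: bool = False
    message: str = ""


@dataclass
class ClassificationResult:
    """Final calls plus the full posterior matrix and per-tag fits."""

    cell_barcodes: list[str]
    tag_names: list[str]
    calls: list[str]
    posterior_matrix: np.ndarray  # cells x tags
    tag_fits: dict[str, TagFitResult]
    config: ClassifyConfig

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(
            self.posterior_matrix,
            index=pd.Index(self.cell_barcodes, name="barcode"),
            columns=[f"posterior_{t}" for t in self.tag_names],
        )
        df.insert(0, "call", self.calls)
        return df


def total_tag_counts(matrix: TagCountMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Per-cell total UMI counts and a mask of cells with total > 0.

    Zero-total cells carry no information and are excluded from fitting;
    they are called negative downstream.
    """
    totals = matrix.total_counts()
    return totals, totals > 0


def cosine_canonical(matrix: TagCountMatrix) -> np.ndarray:
    """Cosine similarity of each cell's count vector with each canonical tag axis.

    Entry (i, T) is X_{i,T} / ||X_i||_2. Rows with zero total are returned
    as all-zero (they are excluded from classification, never NaN).
    """
    counts = matrix.counts.astype(float)
    norms = np.sqrt(np.asarray(counts.multiply(counts).sum(axis=1)).ravel())
    inv = np.zeros_like(norms)
    nz = norms > 0
    inv[nz] = 1.0 / norms[nz]
    return np.asarray(counts.multiply(inv[:, None]).todense())


def init_assignment(
    cosine_column: np.ndarray,
    cutoff: float = 0.5,
    min_cells: int = 10,
) -> np.ndarray:
    """Initial binary assignment: Z0_i = 1 iff cosine >= cutoff.

    Raises :class:`UnfitTagError` when either class has fewer than
    ``min_cells`` members; such tags are excluded from EM and treated as
    all-negative by the driver.
    """
    if not 0 < cutoff < 1:
        raise ValueError("cosine cutoff must be in (0, 1)")
    z = np.asarray(cosine_column) >= cutoff
    n_pos, n_neg = int(z.sum()), int((~z).sum())
    if n_pos < min_cells or n_neg < min_cells:
        raise UnfitTagError(
            f"initial split has {n_pos} positive / {n_neg} negative cells "
            f"(minimum {min_cells} each)"
        )
    return z


def _subsample(idx: np.ndarray, scores: np.ndarray, k: int) -> np.ndarray:
    """Keep the k smallest-scoring cells; deterministic and order-invariant."""
    if idx.size <= k:
        return idx
    order = np.argsort(scores[idx], kind="stable")
    return idx[order[:k]]


def m_step(
    x_tag: np.ndarray,
    totals: np.ndarray,
    z: np.ndarray,
    *,
    max_fit_cells: int = 5000,
    scores: np.ndarray | None = None,
    min_fit_obs: int = 10,
) -> tuple[GlmNbFit, GlmNbFit]:
    """Fit the two NB regressions on the current assignment.

    Negative cells (Z=0): X_T on ln(N_total). Positive cells (Z=1):
    N_total - X_T on ln(N_total). Each class is independently subsampled
    to ``max_fit_cells`` when larger, ranking cells by the deterministic
    per-cell scores.
    """
    z = np.asarray(z, dtype=bool)
    log_total = np.log(totals.astype(float))
    neg_idx = np.flatnonzero(~z)
    pos_idx = np.flatnonzero(z)
    if neg_idx.size == 0 or pos_idx.size == 0:
        raise ValueError("both classes must be non-empty for the M step")
    if scores is None:
        scores = np.arange(totals.size, dtype=float)
    neg_idx = _subsample(neg_idx, scores, max_fit_cells)
    pos_idx = _subsample(pos_idx, scores, max_fit_cells)

    y_neg = x_tag[neg_idx]
    if not np.any(y_neg > 0):
        # contamination can be exactly zero in clean data; a degenerate
        # all-zero class still defines "far below positive" via a tiny mean
        y_neg = y_neg.copy()
        y_neg[0] = 1
    fit_neg = fit_glm_nb(
        y_neg, log_total[neg_idx], space="negative", min_obs=min_fit_obs
    )
    y_pos = totals[pos_idx] - x_tag[pos_idx]
    if not np.any(y_pos > 0):
        y_pos = y_pos.copy()
        y_pos[0] = 1
    fit_pos = fit_glm_nb(
        y_pos, log_total[pos_idx], space="positive", min_obs=min_fit_obs
    )
    return fit_neg, fit_pos


def _e_step_full(
    x_tag: np.ndarray,
    totals: np.ndarray,
    fit_neg: GlmNbFit,
    fit_pos: GlmNbFit,
    priors: tuple[float, float],
    iteration: int,
) -> tuple[np.ndarray, float]:
    pi0, pi1 = priors
    if not np.isclose(pi0 + pi1, 1.0):
        raise ValueError("priors must sum to 1")
    eps = 1e-10
    pi0 = min(max(pi0, eps), 1 - eps)
    pi1 = 1.0 - pi0

    log_total = np.log(totals.astype(float))
    mu_neg = fit_neg.mean(log_total)
    mu_pos = fit_pos.mean(log_total)

    lp_neg = nb_log_pmf(x_tag, mu_neg, fit_neg.theta)
    below = x_tag < mu_neg
    if iteration <= 1:
        mu_rounded = np.clip(np.round(mu_neg), 0, 2**62).astype(np.int64)
        lp_floor = nb_log_pmf(mu_rounded, mu_neg, fit_neg.theta)
        lp_neg = np.where(below, lp_floor, lp_neg)
    else:
        lp_neg = np.where(below, 0.0, lp_neg)

    lp_pos = nb_log_pmf(totals - x_tag, mu_pos, fit_pos.theta)

    a = lp_pos + np.log(pi1)
    b = lp_neg + np.log(pi0)
    denom = logsumexp(np.stack([a, b]), axis=0)
    return np.exp(a - denom), float(denom.sum())


def e_step(
    x_tag: np.ndarray,
    totals: np.ndarray,
    fit_neg: GlmNbFit,
    fit_pos: GlmNbFit,
    priors: tuple[float, float],
    iteration: int,
) -> np.ndarray:
    """Posterior P(Z=1 | X) for every cell, computed in log space.

    The negative density is floor-adjusted for cells whose tag count lies
    below the fitted negative mean: such cells are at least as likely to
    be negative as a cell at the mean, so their density is replaced by the
    density at the rounded fitted mean on the first iteration and by 1
    (log 0) afterwards.
    """
    posterior, _ = _e_step_full(x_tag, totals, fit_neg, fit_pos, priors, iteration)
    return posterior


def em_tag(
    x_tag: np.ndarray,
    totals: np.ndarray,
    tag: str,
    config: ClassifyConfig,
    cosine_column: np.ndarray,
    scores: np.ndarray | None = None,
) -> TagFitResult:
    """Run EM for one tag over the included (nonzero-total) cells.

    Priors are updated each iteration as the class fractions of the
    previous posterior at a 0.5 cutoff (cosine-initialization fractions on
    the first iteration). Convergence: the binary assignment at 0.5 is
    unchanged between consecutive iterations.
    """
    try:
        z = init_assignment(
            cosine_column, config.init_cosine_cutoff, config.min_cells_per_class
        )
    except UnfitTagError as exc:
        return TagFitResult(
            tag=tag,
            posterior_pos=np.zeros_like(x_tag, dtype=float),
            z_init=np.zeros_like(x_tag, dtype=bool),
            fit_neg=None,
            fit_pos=None,
            unfit=True,
            message=str(exc),
        )

    z_init = z.copy()
    pi1 = float(np.mean(z))
    priors = (1.0 - pi1, pi1)
    trace: list[tuple[float, float]] = []
    ll_trace: list[float] = []
    posterior = z.astype(float)
    fit_neg = fit_pos = None
    converged = False
    n_iter = 0
    for it in range(1, config.max_iter + 1):
        n_iter = it
        fit_neg, fit_pos = m_step(
            x_tag,
            totals,
            z,
            max_fit_cells=config.max_fit_cells,
            scores=scores,
            min_fit_obs=config.min_fit_obs,
        )
        posterior, ll = _e_step_full(x_tag, totals, fit_neg, fit_pos, priors, it)
        ll_trace.append(ll)
        z_new = posterior > 0.5
        pi1 = float(np.clip(np.mean(z_new), 1e-6, 1 - 1e-6))
        priors = (1.0 - pi1, pi1)
        trace.append(priors)
        if np.array_equal(z_new, z) and it > 1:
            converged = True
            z = z_new
            break
        if z_new.sum() == 0 or z_new.sum() == z_new.size:
            # one class emptied out: keep the last valid iterate
            logger.warning("tag %s: class collapsed at iteration %d", tag, it)
            break
        z = z_new
    return TagFitResult(
        tag=tag,
        posterior_pos=posterior,
        z_init=z_init,
        fit_neg=fit_neg,
        fit_pos=fit_pos,
        prior_trace=trace,
        loglik_trace=ll_trace,
        n_iter=n_iter,
        converged=converged,
    )


def call_cells(
    posterior_matrix: np.ndarray,
    tag_names: list[str],
    prob_cutoff: float = 0.5,
) -> list[str]:
    """Label each cell from its posterior row.

    Exactly one tag strictly above the cutoff -> that tag; two or more ->
    "multiplet"; none -> "negative". A posterior exactly at the cutoff
    counts as negative (strict comparison).
    """
    pos = posterior_matrix > prob_cutoff
    n_pos = pos.sum(axis=1)
    calls: list[str] = []
    for i in range(posterior_matrix.shape[0]):
        if n_pos[i] == 0:
            calls.append(NEGATIVE)
        elif n_pos[i] == 1:
            calls.append(tag_names[int(np.flatnonzero(pos[i])[0])])
        else:
            calls.append(MULTIPLET)
    return calls


def demultiplex(
    matrix: TagCountMatrix, config: ClassifyConfig | None = None
) -> ClassificationResult:
    """Classify every cell of a tag count matrix.

    Runs per-tag EM over cells with nonzero totals; zero-total cells and
    tags that fail initialization (unfit) contribute zero posteriors, so
    such cells fall out as "negative".
    """
    if matrix.n_tags < 2:
        raise ValueError("demultiplexing needs at least 2 tags")
    config = config or ClassifyConfig()
    totals, included = total_tag_counts(matrix)
    idx = np.flatnonzero(included)
    if idx.size == 0:
        raise ValueError("no cell has a nonzero tag total")
    sub = matrix.subset_cells(idx)
    sub_totals = totals[idx]
    cosines = cosine_canonical(sub)
    counts = np.asarray(sub.counts.todense())

    posterior = np.zeros((matrix.n_cells, matrix.n_tags))
    tag_fits: dict[str, TagFitResult] = {}
    any_fit = False
    for j, tag in enumerate(matrix.tag_names):
        scores = stable_cell_scores(
            config.seed, f"tag:{j}", sub.cell_barcodes
        ).astype(float)
        res = em_tag(counts[:, j], sub_totals, tag, config, cosines[:, j], scores)
        tag_fits[tag] = res
        if res.unfit:
            logger.warning("tag %s unfit: %s", tag, res.message)
            continue
        any_fit = True
        posterior[idx, j] = res.posterior_pos
        logger.info(
            "tag %s: %d iterations, converged=%s", tag, res.n_iter, res.converged
        )
    if not any_fit:
        raise ValueError(
            "all tags failed initialization; check the count matrix "
            "(per-tag positives/negatives below the minimum class size)"
        )
    calls = call_cells(posterior, matrix.tag_names, config.prob_cutoff)
    return ClassificationResult(
        cell_barcodes=list(matrix.cell_barcodes),
        tag_names=list(matrix.tag_names),
        calls=calls,
        posterior_matrix=posterior,
        tag_fits=tag_fits,
        config=config,
    )
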
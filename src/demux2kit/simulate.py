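"""Generative simulator of multiplexed tag count data.

The generator reproduces the labeling, pooling, and contamination process
in three steps. Step 1 (staining): each sample's mean log tag count is
drawn once, then each cell's true tag count is drawn log-normally around
it — a clean matrix ``x_true`` where every cell is positive for exactly
one tag. Step 2 (cell-bound contamination): a cell's initial count acts
as its surface-area proxy N_total, and every other tag B contaminates it
with NB(p_B * N_total, theta_B) counts. Step 3 (ambient contamination):
every droplet captures free-floating tags, NB(M_k, theta_k) per tag,
independent of the cell. Doublets merge random pairs of singlets (true
and cell-bound counts add; ambient is drawn once per droplet). An
optional zero-inflation step drops entries with probability
exp(-lambda * x**2), and read/cell down-sampling emulate shallower
sequencing or smaller experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .io_tagcount import TagCountMatrix

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_tags",
    "make_doublets",
    "zero_inflate",
    "downsample_reads",
    "downsample_cells",
    "preset",
]

MULTIPLET = "multiplet"


@dataclass
class SimulationConfig:
    """Parameters of the tag-count generator.

    Ranges are sampled once per tag (uniformly unless noted); the staining
    log-mean is drawn per sample from a normal centered on the midpoint of
    ``staining_logmean_range`` with sd = range/4, clipped to the range.
    All logs are natural.
    """

    n_tags: int = 10
    cells_per_tag_meanlog: float = 6.5  # ~665 cells/sample
    cells_per_tag_sdlog: float = 0.75
    cells_per_tag_bounds: tuple[int, int] = (50, 5000)
    staining_logmean_range: tuple[float, float] = (5.0, 7.0)
    staining_sdlog: float = 0.6
    contamination_range: tuple[float, float] = (0.005, 0.02)  # p_k
    theta_range: tuple[float, float] = (2.0, 10.0)
    ambient_range: tuple[float, float] = (1.0, 5.0)  # M_k
    doublet_fraction: float = 0.1
    zero_inflation_lambda: float | None = 2.0
    self_contamination: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cells_per_tag_bounds
        if lo > hi or lo < 1:
            raise ValueError("cells_per_tag_bounds must be ordered and >= 1")
        for name in ("contamination_range", "theta_range", "ambient_range",
                     "staining_logmean_range"):
            a, b = getattr(self, name)
            if a > b:
                raise ValueError(f"{name} bounds out of order")
        a, b = self.contamination_range
        if a < 0 or b >= 1:
            raise ValueError("contamination fractions must lie in [0, 1)")
        if self.theta_range[0] <= 0:
            raise ValueError("theta must be positive")
        if self.ambient_range[0] < 0:
            raise ValueError("ambient means must be nonnegative")
        if not 0 <= self.doublet_fraction < 0.5:
            raise ValueError("doublet_fraction must be in [0, 0.5)")
        if self.zero_inflation_lambda is not None and self.zero_inflation_lambda <= 0:
            raise ValueError(
                "zero_inflation_lambda must be positive (use None to disable)"
            )


@dataclass
class SimulationTruth:
    """Component matrices and ground-truth labels of a simulated run.

    ``labels`` holds the sample tag name for singlets and a sorted tag
    pair tuple for doublets. The observed matrix before any zero-inflation
    equals ``x_true + c_cell_bound + c_ambient`` row for row.
    """

    x_true: np.ndarray
    c_cell_bound: np.ndarray
    c_ambient: np.ndarray
    labels: list
    tag_names: list[str]
    cell_barcodes: list[str]
    tag_params: dict = field(default_factory=dict)

    def components_sum(self) -> np.ndarray:
        return self.x_true + self.c_cell_bound + self.c_ambient

    def eval_labels(self) -> list[str]:
        """Labels in the vocabulary of the classifier.

        A doublet of two cells from the same sample is a singlet of that
        tag for evaluation purposes; mixed pairs are multiplets.
        """
        out = []
        for lab in self.labels:
            if isinstance(lab, tuple):
                out.append(lab[0] if lab[0] == lab[1] else MULTIPLET)
            else:
                out.append(lab)
        return out

    def subset(self, idx: np.ndarray) -> "SimulationTruth":
        idx = np.asarray(idx)
        return SimulationTruth(
            x_true=self.x_true[idx],
            c_cell_bound=self.c_cell_bound[idx],
            c_ambient=self.c_ambient[idx],
            labels=[self.labels[i] for i in idx],
            tag_names=list(self.tag_names),
            cell_barcodes=[self.cell_barcodes[i] for i in idx],
            tag_params=dict(self.tag_params),
        )


def _nb_draw(rng: np.random.Generator, mu, theta) -> np.ndarray:
    """NB(mu, theta) sample; mu may be a vector, zero means give zeros."""
    mu = np.asarray(mu, dtype=float)
    p = theta / (theta + mu)
    return rng.negative_binomial(theta, p)


def make_doublets(
    x_true: np.ndarray,
    c_cell_bound: np.ndarray,
    labels: list,
    ambient_sampler,
    fraction: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list]:
    """Merge random singlet pairs into doublet droplets.

    ``fraction`` is the doublet share of the *final* droplet count: with s
    singlets and d doublets, d = floor(fraction * (s - d)) (each doublet
    consumes two singlets and yields one droplet). Pairs are sampled
    without replacement; true and cell-bound rows add, the ambient row is
    one fresh draw from ``ambient_sampler(n)`` because a doublet occupies
    a single droplet.
    """
    s = x_true.shape[0]
    if not 0 <= fraction < 0.5:
        raise ValueError("doublet fraction must be in [0, 0.5)")
    if fraction > 0 and s < 2:
        raise ValueError("need at least two singlets to form a doublet")
    if fraction == 0:
        return x_true, c_cell_bound, ambient_sampler(s), list(labels)
    d0 = int(round(fraction * s / (1.0 + fraction)))
    d = d0
    for cand in range(max(d0 - 2, 0), d0 + 3):
        if cand == int(np.floor(fraction * (s - cand))):
            d = cand
            break
    if 2 * d > s:
        raise ValueError(f"cannot form {d} doublets from {s} singlets")
    chosen = rng.choice(s, size=2 * d, replace=False)
    pairs = chosen.reshape(d, 2)
    keep = np.setdiff1d(np.arange(s), chosen)

    xt = np.vstack([x_true[keep], x_true[pairs[:, 0]] + x_true[pairs[:, 1]]])
    cb = np.vstack(
        [c_cell_bound[keep], c_cell_bound[pairs[:, 0]] + c_cell_bound[pairs[:, 1]]]
    )
    amb = ambient_sampler(xt.shape[0])
    new_labels = [labels[i] for i in keep] + [
        tuple(sorted((labels[a], labels[b]))) for a, b in pairs
    ]
    return xt, cb, amb, new_labels


def zero_inflate(
    matrix: TagCountMatrix | np.ndarray,
    lam: float,
    rng: np.random.Generator,
):
    """Drop entries to zero with probability exp(-lambda * x**2).

    Zeros stay zero (their drop probability is 1, but 0 -> 0 is the
    identity), so only nonzero entries are touched.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive; pass None upstream to disable")
    if isinstance(matrix, TagCountMatrix):
        counts = matrix.counts.copy().tocsr()
        data = counts.data.astype(float)
        drop = rng.random(data.size) < np.exp(-lam * data**2)
        counts.data[drop] = 0
        counts.eliminate_zeros()
        return TagCountMatrix(
            counts, list(matrix.cell_barcodes), list(matrix.tag_names)
        )
    arr = np.asarray(matrix).copy()
    nz = arr > 0
    vals = arr[nz].astype(float)
    drop = rng.random(vals.size) < np.exp(-lam * vals**2)
    vals[drop] = 0
    arr[nz] = vals.astype(arr.dtype)
    return arr


def simulate_tags(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[TagCountMatrix, SimulationTruth]:
    """Run the three-step generator and return (observed matrix, truth)."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_tags = config.n_tags
    tag_names = [f"tag{j + 1:02d}" for j in range(n_tags)]

    # per-tag parameters, drawn once
    p = rng.uniform(*config.contamination_range, size=n_tags)
    theta = rng.uniform(*config.theta_range, size=n_tags)
    ambient = rng.uniform(*config.ambient_range, size=n_tags)
    lo_m, hi_m = config.staining_logmean_range
    mid, sd = (lo_m + hi_m) / 2.0, (hi_m - lo_m) / 4.0
    stain_logmean = np.clip(rng.normal(mid, sd, size=n_tags), lo_m, hi_m)

    lo_c, hi_c = config.cells_per_tag_bounds
    n_cells = np.clip(
        np.round(
            rng.lognormal(config.cells_per_tag_meanlog, config.cells_per_tag_sdlog,
                          size=n_tags)
        ),
        lo_c,
        hi_c,
    ).astype(int)

    # step 1: staining
    total = int(n_cells.sum())
    x_true = np.zeros((total, n_tags), dtype=np.int64)
    labels: list = []
    row = 0
    for j in range(n_tags):
        draws = rng.lognormal(stain_logmean[j], config.staining_sdlog, n_cells[j])
        x_true[row : row + n_cells[j], j] = np.maximum(
            np.floor(draws + 0.5), 1
        ).astype(np.int64)
        labels.extend([tag_names[j]] * n_cells[j])
        row += n_cells[j]

    # step 2: cell-bound contamination, scaled by the cell's own staining count
    n_init = x_true.sum(axis=1).astype(float)
    c_cell_bound = np.zeros_like(x_true)
    own = x_true > 0
    for k in range(n_tags):
        mu = p[k] * n_init
        draws = _nb_draw(rng, mu, theta[k])
        if not config.self_contamination:
            draws = np.where(own[:, k], 0, draws)
        c_cell_bound[:, k] = draws

    # step 3: ambient contamination (also used for fresh doublet draws)
    def ambient_sampler(n: int) -> np.ndarray:
        out = np.zeros((n, n_tags), dtype=np.int64)
        for k in range(n_tags):
            out[:, k] = _nb_draw(rng, np.full(n, ambient[k]), theta[k])
        return out

    x_true, c_cell_bound, c_ambient, labels = make_doublets(
        x_true, c_cell_bound, labels, ambient_sampler, config.doublet_fraction, rng
    )

    observed = x_true + c_cell_bound + c_ambient
    barcodes = [f"cell{i + 1:06d}" for i in range(observed.shape[0])]
    truth = SimulationTruth(
        x_true=x_true,
        c_cell_bound=c_cell_bound,
        c_ambient=c_ambient,
        labels=labels,
        tag_names=tag_names,
        cell_barcodes=barcodes,
        tag_params=dict(
            p=p, theta=theta, ambient=ambient, stain_logmean=stain_logmean,
            n_cells=n_cells,
        ),
    )
    matrix = TagCountMatrix(sp.csr_matrix(observed), barcodes, tag_names)
    if config.zero_inflation_lambda is not None:
        matrix = zero_inflate(matrix, config.zero_inflation_lambda, rng)
    return matrix, truth


def downsample_reads(
    matrix: TagCountMatrix,
    rate: float | None = None,
    target: int | None = None,
    rng: np.random.Generator | None = None,
) -> TagCountMatrix:
    """Down-sample each cell's reads uniformly without replacement.

    With a rate r, a cell keeps round(r * N_total) reads; with a target,
    it keeps exactly that many (error if the target exceeds the total).
    The kept reads partition over tags as a multivariate hypergeometric
    draw on the cell's original composition.
    """
    if (rate is None) == (target is None):
        raise ValueError("specify exactly one of rate or target")
    if rate is not None and not 0 < rate <= 1:
        raise ValueError("rate must be in (0, 1]")
    rng = rng if rng is not None else np.random.default_rng()
    counts = np.asarray(matrix.counts.todense()).astype(np.int64)
    out = np.zeros_like(counts)
    for i in range(counts.shape[0]):
        n = int(counts[i].sum())
        keep = int(round(rate * n)) if rate is not None else int(target)
        if keep > n:
            raise ValueError(f"target {keep} exceeds cell total {n}")
        if keep == n:
            out[i] = counts[i]
        elif keep > 0:
            out[i] = rng.multivariate_hypergeometric(counts[i], keep)
    return TagCountMatrix(
        sp.csr_matrix(out), list(matrix.cell_barcodes), list(matrix.tag_names)
    )


def downsample_cells(
    matrix: TagCountMatrix,
    truth: SimulationTruth | None,
    keep: float | int,
    rng: np.random.Generator | None = None,
) -> tuple[TagCountMatrix, SimulationTruth | None]:
    """Keep a uniform random subset of droplets (fraction or absolute n)."""
    rng = rng if rng is not None else np.random.default_rng()
    n = matrix.n_cells
    k = int(round(keep * n)) if isinstance(keep, float) and keep <= 1 else int(keep)
    if not 1 <= k <= n:
        raise ValueError(f"cannot keep {k} of {n} droplets")
    idx = np.sort(rng.choice(n, size=k, replace=False))
    sub = matrix.subset_cells(idx)
    return sub, truth.subset(idx) if truth is not None else None


def preset(name: str) -> SimulationConfig:
    """Approximate study conditions of increasing size and noise.

    Five conditions ("s1" .. "s5") span small/clean through large/noisy:
    sample count grows from 4 to 30, contamination and ambient levels
    rise, and the zero-inflation decay drops from 2 to 0.5 in the
    noisiest condition. These are approximations built from the printed
    parameter ranges, not exact published configurations.
    """
    presets = {
        "s1": SimulationConfig(
            n_tags=4, cells_per_tag_meanlog=5.5, cells_per_tag_sdlog=0.3,
            contamination_range=(0.001, 0.005), ambient_range=(0.5, 2.0),
            doublet_fraction=0.05,
        ),
        "s2": SimulationConfig(
            n_tags=10, cells_per_tag_meanlog=6.0, cells_per_tag_sdlog=0.4,
            contamination_range=(0.001, 0.005), ambient_range=(0.5, 2.0),
            doublet_fraction=0.05,
        ),
        "s3": SimulationConfig(
            n_tags=10, cells_per_tag_meanlog=6.0, cells_per_tag_sdlog=0.5,
        ),
        "s4": SimulationConfig(n_tags=30),
        "s5": SimulationConfig(
            n_tags=30, contamination_range=(0.02, 0.05),
            ambient_range=(5.0, 20.0), zero_inflation_lambda=0.5,
        ),
    }
    try:
        return replace(presets[name.lower()])
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose s1..s5") from None
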
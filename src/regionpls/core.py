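"""Two-block (and general DAG) latent-variable PLS path modeling.

The estimator follows the classical Lohmoeller iteration: latent scores are
weighted sums of their standardized manifest variables; outer weights are
updated against an inner approximation of each latent (centroid, factorial or
path scheme) until the weights stabilise; path coefficients are then ordinary
least-squares regressions among the latent scores and loadings are
manifest-latent correlations.

Because all manifest variables are standardized, every quantity except the
latent scores themselves is a function of the manifest correlation matrix
alone.  The iteration here is therefore written against correlation matrices
with an optional leading batch axis, which lets the bootstrap in
:mod:`regionpls.inference` refit thousands of resamples with the same code
path used for a single fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Mode",
    "InnerScheme",
    "StandardizedMatrix",
    "BlockSpec",
    "PathModel",
    "PLSPMFit",
    "standardize",
    "residualize_covariates",
    "fit_plspm",
]


class Mode(str, Enum):
    """Outer estimation mode of a block."""

    A = "A"  # reflective: weights proportional to cov(manifest, inner estimate)
    B = "B"  # formative: weights from regressing the inner estimate on the block


class InnerScheme(str, Enum):
    """Rule combining adjacent latents into the inner approximation."""

    CENTROID = "centroid"
    FACTORIAL = "factorial"
    PATH = "path"


@dataclass(frozen=True)
class StandardizedMatrix:
    """Column-standardized manifest data (mean 0, sample SD 1, no missing)."""

    values: np.ndarray
    variable_names: tuple[str, ...]

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.variable_names.index(name)]

    def correlation(self) -> np.ndarray:
        """Manifest correlation matrix (the sufficient statistic for fitting)."""
        return self.values.T @ self.values / (self.n - 1)


@dataclass(frozen=True)
class BlockSpec:
    """A latent variable and its manifest indicators."""

    latent_name: str
    manifest_names: tuple[str, ...]
    mode: Mode = Mode.A

    def __post_init__(self) -> None:
        if len(self.manifest_names) == 0:
            raise ValueError(f"block {self.latent_name!r} has no manifest variables")
        if len(set(self.manifest_names)) != len(self.manifest_names):
            raise ValueError(f"duplicate manifest names in block {self.latent_name!r}")
        object.__setattr__(self, "manifest_names", tuple(self.manifest_names))
        object.__setattr__(self, "mode", Mode(self.mode))


@dataclass(frozen=True)
class PathModel:
    """Latent blocks plus directed inner paths (must form a DAG)."""

    blocks: tuple[BlockSpec, ...]
    inner_paths: tuple[tuple[str, str], ...]
    inner_scheme: InnerScheme = InnerScheme.CENTROID

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        object.__setattr__(self, "inner_paths", tuple(tuple(p) for p in self.inner_paths))
        object.__setattr__(self, "inner_scheme", InnerScheme(self.inner_scheme))
        names = [b.latent_name for b in self.blocks]
        if len(set(names)) != len(names):
            raise ValueError("duplicate latent names")
        seen: set[str] = set()
        for b in self.blocks:
            overlap = seen.intersection(b.manifest_names)
            if overlap:
                raise ValueError(f"manifest variables in several blocks: {sorted(overlap)}")
            seen.update(b.manifest_names)
        if not self.inner_paths:
            raise ValueError("a path model needs at least one inner path")
        for src, dst in self.inner_paths:
            if src not in names or dst not in names:
                raise ValueError(f"path ({src}, {dst}) references unknown latent")
            if src == dst:
                raise ValueError("self-loop in inner paths")
        if _has_cycle(names, self.inner_paths):
            raise ValueError("inner paths must form a directed acyclic graph")

    @property
    def latent_names(self) -> tuple[str, ...]:
        return tuple(b.latent_name for b in self.blocks)

    @property
    def manifest_names(self) -> tuple[str, ...]:
        return tuple(m for b in self.blocks for m in b.manifest_names)


def _has_cycle(names: Sequence[str], paths: Sequence[tuple[str, str]]) -> bool:
    succ: dict[str, list[str]] = {n: [] for n in names}
    for s, d in paths:
        succ[s].append(d)
    state = {n: 0 for n in names}  # 0 unseen, 1 open, 2 done

    def visit(n: str) -> bool:
        if state[n] == 1:
            return True
        if state[n] == 2:
            return False
        state[n] = 1
        hit = any(visit(m) for m in succ[n])
        state[n] = 2
        return hit

    return any(visit(n) for n in names)


@dataclass
class PLSPMFit:
    """Result of a PLS path-model fit on standardized data.

    ``outer_weights`` map standardized manifests to unit-variance latent
    scores; ``loadings`` are manifest-latent Pearson correlations;
    ``path_coefficients`` are standardized OLS coefficients among latents;
    ``r_squared`` is per endogenous latent.
    """

    model: PathModel
    outer_weights: dict[str, float]
    loadings: dict[str, float]
    path_coefficients: dict[tuple[str, str], float]
    latent_scores: np.ndarray  # n x n_latents, columns mean 0 / sd 1
    r_squared: dict[str, float]
    n_iterations: int
    converged: bool
    latent_correlation: np.ndarray = field(repr=False, default=None)

    def score(self, latent_name: str) -> np.ndarray:
        return self.latent_scores[:, self.model.latent_names.index(latent_name)]


# ---------------------------------------------------------------------------
# standardization and covariate adjustment
# ---------------------------------------------------------------------------

def standardize(
    raw: np.ndarray,
    variable_names: Sequence[str] | None = None,
    impute_missing: bool = True,
) -> StandardizedMatrix:
    """Column-standardize ``raw`` to mean 0 / sample SD 1 (n-1 denominator).

    Missing entries (NaN) are replaced by the column mean first when
    ``impute_missing`` is set; a column that is entirely missing or has zero
    variance raises ``ValueError`` naming the column.
    """
    x = np.asarray(raw, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    n, p = x.shape
    if n < 3:
        raise ValueError("need at least 3 rows to standardize")
    if variable_names is None:
        variable_names = tuple(f"v{j}" for j in range(p))
    variable_names = tuple(variable_names)
    if len(variable_names) != p:
        raise ValueError("variable_names length does not match column count")

    missing = np.isnan(x)
    if missing.any():
        if not impute_missing:
            bad = [variable_names[j] for j in np.where(missing.any(axis=0))[0]]
            raise ValueError(f"missing values present and impute_missing is off: {bad}")
        all_missing = missing.all(axis=0)
        if all_missing.any():
            bad = [variable_names[j] for j in np.where(all_missing)[0]]
            raise ValueError(f"column(s) entirely missing: {bad}")
        col_mean = np.nanmean(x, axis=0)
        x = np.where(missing, col_mean[None, :], x)

    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        bad = [variable_names[j] for j in np.where(zero)[0]]
        raise ValueError(f"zero variance column(s): {bad}")
    return StandardizedMatrix((x - mean) / sd, variable_names)


def residualize_covariates(raw: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Replace each column of ``raw`` by its OLS residual on [1, covariates].

    Output columns are exactly orthogonal to the covariates (zero correlation),
    implementing covariate adjustment of all manifest variables before
    standardization.
    """
    x = np.asarray(raw, dtype=float)
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != x.shape[0]:
        raise ValueError("covariates and data have different row counts")
    if np.isnan(c).any():
        raise ValueError("covariates must not contain missing values")
    n, q = c.shape
    if q >= n:
        raise ValueError("more covariates than individuals")
    design = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    coef, *_ = np.linalg.lstsq(design, x, rcond=None)
    return x - design @ coef


# ---------------------------------------------------------------------------
# Lohmoeller iteration on (batched) correlation matrices
# ---------------------------------------------------------------------------

def _block_indices(model: PathModel) -> list[np.ndarray]:
    offsets = []
    start = 0
    for b in model.blocks:
        offsets.append(np.arange(start, start + len(b.manifest_names)))
        start += len(b.manifest_names)
    return offsets


def _adjacency(model: PathModel) -> tuple[np.ndarray, np.ndarray]:
    """(symmetric neighbour mask, predecessor mask) over latents."""
    names = model.latent_names
    L = len(names)
    pred = np.zeros((L, L), dtype=bool)  # pred[k, l]: l -> k is a path
    for s, d in model.inner_paths:
        pred[names.index(d), names.index(s)] = True
    adj = pred | pred.T
    return adj, pred


def _rescale_weights(W: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Scale each latent's weight vector so its score has unit variance."""
    var = np.sum((W @ R) * W, axis=-1)
    return W / np.sqrt(var)[..., None]


def _inner_weights(C: np.ndarray, adj: np.ndarray, pred: np.ndarray,
                   scheme: InnerScheme) -> np.ndarray:
    """Inner weight matrix E with z_k = sum_l E[k, l] * xi_l."""
    if scheme is InnerScheme.CENTROID:
        E = np.sign(C) * adj
    elif scheme is InnerScheme.FACTORIAL:
        E = C * adj
    else:  # path scheme: regress on predecessors, correlate with successors
        E = C * (adj & ~pred)
        L = adj.shape[-1]
        for k in range(L):
            idx = np.where(pred[k])[0]
            if idx.size == 0:
                continue
            Cpp = C[..., idx[:, None], idx]
            cpk = C[..., idx, k]
            beta = np.linalg.solve(Cpp, cpk[..., None])[..., 0]
            E[..., k, idx] = beta
    return E


def _iterate_weights(
    R: np.ndarray,
    model: PathModel,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, int, np.ndarray]:
    """Run the outer/inner alternation; returns (W, iterations, converged mask).

    ``R`` may carry leading batch dimensions; ``W`` has shape
    ``batch + (n_latents, p)`` with each latent's weights confined to its block
    and scaled to give unit-variance scores.
    """
    blocks = _block_indices(model)
    adj, pred = _adjacency(model)
    batch = R.shape[:-2]
    p = R.shape[-1]
    L = len(blocks)

    W = np.zeros(batch + (L, p))
    for k, idx in enumerate(blocks):
        W[..., k, idx] = 1.0
    W = _rescale_weights(W, R)

    converged = np.zeros(batch, dtype=bool) if batch else np.array(False)
    it = 0
    for it in range(1, max_iter + 1):
        C = W @ R @ np.swapaxes(W, -2, -1)
        E = _inner_weights(C, adj, pred, model.inner_scheme)
        V = E @ W  # inner estimates expressed in the manifest basis
        cov = V @ R  # cov(z_k, x_j)
        W_new = np.zeros_like(W)
        for k, idx in enumerate(blocks):
            if model.blocks[k].mode is Mode.A:
                W_new[..., k, idx] = cov[..., k, idx]
            else:
                Rbb = R[..., idx[:, None], idx]
                W_new[..., k, idx] = np.linalg.solve(
                    Rbb, cov[..., k, idx][..., None]
                )[..., 0]
        W_new = _rescale_weights(W_new, R)
        # latent signs are unidentified during the iteration (the centroid
        # scheme can flip whole blocks jointly without changing any estimand);
        # align each block's sign to the previous iterate so the fixed point
        # is assessed in the projective sense, then fix signs at the end
        agree = np.sum(W_new * W, axis=-1, keepdims=True)
        W_new = np.where(agree < 0, -W_new, W_new)
        delta = np.abs(W_new - W).max(axis=(-2, -1))
        W = W_new
        converged = delta < tol
        if np.all(converged):
            break
    return W, it, converged


def _fit_from_corr(
    R: np.ndarray,
    model: PathModel,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> dict:
    """Weights, loadings, paths and R-squared from a (batched) correlation matrix."""
    blocks = _block_indices(model)
    names = model.latent_names
    _, pred = _adjacency(model)

    W, n_iter, converged = _iterate_weights(R, model, tol, max_iter)

    # loadings: corr(x_j, xi_k) for j in block k
    lam_full = R @ np.swapaxes(W, -2, -1)  # (..., p, L)
    # sign convention: per block, sum of own-block loadings >= 0
    sign = np.ones(R.shape[:-2] + (len(blocks),))
    for k, idx in enumerate(blocks):
        s = lam_full[..., idx, k].sum(axis=-1)
        sign[..., k] = np.where(s < 0, -1.0, 1.0)
    W = W * sign[..., :, None]
    lam_full = lam_full * sign[..., None, :]

    C = W @ R @ np.swapaxes(W, -2, -1)

    loadings = np.zeros(R.shape[:-2] + (R.shape[-1],))
    for k, idx in enumerate(blocks):
        loadings[..., idx] = lam_full[..., idx, k]

    paths = {}
    r2 = {}
    for k, name in enumerate(names):
        idx = np.where(pred[k])[0]
        if idx.size == 0:
            continue
        Cpp = C[..., idx[:, None], idx]
        cpk = C[..., idx, k]
        beta = np.linalg.solve(Cpp, cpk[..., None])[..., 0]
        for j, l in enumerate(idx):
            paths[(names[l], name)] = beta[..., j]
        r2[name] = np.sum(beta * cpk, axis=-1)

    return {
        "weights": W,
        "loadings": loadings,
        "paths": paths,
        "r_squared": r2,
        "latent_correlation": C,
        "n_iterations": n_iter,
        "converged": converged,
    }


def fit_plspm(
    data: StandardizedMatrix,
    model: PathModel,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> PLSPMFit:
    """Fit the path model on standardized data by the Lohmoeller iteration.

    Raises on manifests missing from ``data``; warns when the fit does not
    converge within ``max_iter`` (the partial fit is still returned with
    ``converged=False``) and when n is not larger than the manifest count.
    """
    manifest = model.manifest_names
    missing = [m for m in manifest if m not in data.variable_names]
    if missing:
        raise ValueError(f"manifest variables not in data: {missing}")
    if data.n <= len(manifest):
        warnings.warn(
            f"n = {data.n} is not larger than the number of manifest variables "
            f"({len(manifest)}); estimates will be unstable",
            stacklevel=2,
        )

    cols = [data.variable_names.index(m) for m in manifest]
    X = data.values[:, cols]
    R = X.T @ X / (data.n - 1)

    res = _fit_from_corr(R, model, tol=tol, max_iter=max_iter)
    if not bool(res["converged"]):
        warnings.warn(
            f"PLSPM iteration did not converge in {max_iter} iterations",
            stacklevel=2,
        )

    scores = X @ res["weights"].T  # unit variance by the weight scaling
    return PLSPMFit(
        model=model,
        outer_weights={m: float(res["weights"][k, j])
                       for k, b in enumerate(model.blocks)
                       for m, j in zip(b.manifest_names,
                                       _block_indices(model)[k])},
        loadings={m: float(res["loadings"][j]) for j, m in enumerate(manifest)},
        path_coefficients={k: float(v) for k, v in res["paths"].items()},
        latent_scores=scores,
        r_squared={k: float(v) for k, v in res["r_squared"].items()},
        n_iterations=int(res["n_iterations"]),
        converged=bool(res["converged"]),
        latent_correlation=res["latent_correlation"],
    )
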
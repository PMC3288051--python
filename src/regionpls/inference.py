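"""Non-parametric bootstrap inference for PLS path-model parameters.

Individuals are resampled with replacement (same n as the original sample),
the full pipeline (covariate residualization, standardization, PLSPM fit) is
re-run on every replicate, and each parameter's bootstrap standard error feeds
a two-sided normal test ``z = estimate / se_boot``, ``p = 2 (1 - Phi(|z|))``.

Replicates are fitted in chunks through the batched correlation-matrix code
path of :mod:`regionpls.core`; each replicate's blocks are sign-aligned to the
original fit before standard errors are accumulated (PLS latent directions are
only identified up to sign).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import (
    PathModel,
    PLSPMFit,
    _block_indices,
    _fit_from_corr,
    fit_plspm,
    residualize_covariates,
    standardize,
)

__all__ = ["BootstrapResult", "normal_test", "bootstrap_plspm"]

# keep chunk * n * p around this many elements to bound bootstrap memory
_CHUNK_ELEMENTS = 20_000_000


@dataclass(frozen=True)
class BootstrapResult:
    """Bootstrap-based normal test for one parameter (a path or a loading)."""

    parameter_name: str
    estimate: float
    se_boot: float
    z: float
    p_value: float
    n_boot: int


def normal_test(estimate: float, se: float) -> tuple[float, float]:
    """Two-sided normal test of H0: parameter = 0.

    Returns ``(z, p)`` with ``z = estimate / se``.  A zero standard error
    yields the degenerate conventions p = 0 (nonzero estimate, z = +/-inf) or
    p = 1 (zero estimate).
    """
    if se < 0:
        raise ValueError("standard error must be nonnegative")
    if se == 0:
        if estimate == 0:
            return 0.0, 1.0
        return float(np.copysign(np.inf, estimate)), 0.0
    z = estimate / se
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def _prepare(raw: np.ndarray, covariates: np.ndarray | None,
             names: tuple[str, ...]):
    """Residualize (optionally) then standardize; the per-sample pipeline."""
    x = np.asarray(raw, dtype=float)
    if covariates is not None:
        if np.isnan(x).any():
            # impute before residualizing so the OLS sees complete columns
            col_mean = np.nanmean(x, axis=0)
            x = np.where(np.isnan(x), col_mean[None, :], x)
        x = residualize_covariates(x, covariates)
    return standardize(x, names)


def _batch_standardized(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Standardize columns within each batch slice; returns (z, sd)."""
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1, keepdims=True)
    safe = np.where(sd == 0, 1.0, sd)
    return (x - mean) / safe, sd[:, 0, :]


def _batch_residualize(x: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Per-replicate OLS residuals of x on [1, c]; shapes (B, n, p), (B, n, q)."""
    B, n, _ = x.shape
    design = np.concatenate([np.ones((B, n, 1)), c], axis=2)
    gram = np.einsum("bni,bnj->bij", design, design)
    rhs = np.einsum("bni,bnp->bip", design, x)
    coef = np.linalg.solve(gram, rhs)
    return x - design @ coef


def bootstrap_plspm(
    raw_data: np.ndarray,
    covariates: np.ndarray | None,
    model: PathModel,
    n_boot: int = 5000,
    seed: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 300,
    variable_names: tuple[str, ...] | None = None,
) -> tuple[PLSPMFit, dict[str, BootstrapResult]]:
    """Original fit plus bootstrap tests for every path coefficient and loading.

    ``raw_data`` columns must follow ``model.manifest_names`` order (or pass
    ``variable_names``).  Replicates that produce a zero-variance column are
    redrawn; a warning is issued if more than 1% of replicates needed
    redrawing.  Fully reproducible for a given ``seed``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    names = tuple(variable_names) if variable_names else model.manifest_names
    raw = np.asarray(raw_data, dtype=float)
    if raw.shape[1] != len(names):
        raise ValueError("column count does not match variable names")
    cov = None if covariates is None else np.asarray(covariates, dtype=float)
    if cov is not None and cov.ndim == 1:
        cov = cov[:, None]

    data = _prepare(raw, cov, names)
    fit = fit_plspm(data, model, tol=tol, max_iter=max_iter)

    manifest = model.manifest_names
    cols = [names.index(m) for m in manifest]
    raw_m = raw[:, cols]
    if np.isnan(raw_m).any():
        col_mean = np.nanmean(raw_m, axis=0)
        raw_m = np.where(np.isnan(raw_m), col_mean[None, :], raw_m)
    n, p = raw_m.shape

    blocks = _block_indices(model)
    orig_loadings = np.array([fit.loadings[m] for m in manifest])
    path_keys = list(fit.path_coefficients)
    latent_names = model.latent_names

    rng = np.random.default_rng(seed)
    chunk = max(1, min(n_boot, _CHUNK_ELEMENTS // max(1, n * p)))

    boot_paths = np.empty((n_boot, len(path_keys)))
    boot_loadings = np.empty((n_boot, p))
    n_redrawn = 0
    done = 0
    while done < n_boot:
        b = min(chunk, n_boot - done)
        idx = rng.integers(0, n, size=(b, n))
        xb = raw_m[idx]  # (b, n, p)
        # redraw replicates containing a zero-variance column
        for _ in range(100):
            sd = xb.std(axis=1, ddof=1)
            bad = np.where((sd == 0).any(axis=1))[0]
            if bad.size == 0:
                break
            n_redrawn += bad.size
            idx_bad = rng.integers(0, n, size=(bad.size, n))
            xb[bad] = raw_m[idx_bad]
            idx[bad] = idx_bad
        else:
            raise RuntimeError("could not draw bootstrap replicates without "
                               "zero-variance columns")
        if cov is not None:
            xb = _batch_residualize(xb, cov[idx])
        zb, _ = _batch_standardized(xb)
        Rb = zb.transpose(0, 2, 1) @ zb / (n - 1)
        res = _fit_from_corr(Rb, model, tol=tol, max_iter=max_iter)

        # sign-align each replicate's blocks to the original loadings
        flip = np.ones((b, len(blocks)))
        for k, bidx in enumerate(blocks):
            agree = res["loadings"][:, bidx] @ orig_loadings[bidx]
            flip[:, k] = np.where(agree < 0, -1.0, 1.0)
        lam = res["loadings"].copy()
        for k, bidx in enumerate(blocks):
            lam[:, bidx] *= flip[:, k][:, None]
        boot_loadings[done:done + b] = lam
        for j, (src, dst) in enumerate(path_keys):
            f = flip[:, latent_names.index(src)] * flip[:, latent_names.index(dst)]
            boot_paths[done:done + b, j] = res["paths"][(src, dst)] * f
        done += b

    if n_redrawn > 0.01 * n_boot:
        warnings.warn(
            f"{n_redrawn} of {n_boot} bootstrap replicates were redrawn due to "
            "zero-variance columns",
            stacklevel=2,
        )

    results: dict[str, BootstrapResult] = {}
    for j, key in enumerate(path_keys):
        est = fit.path_coefficients[key]
        se = float(boot_paths[:, j].std(ddof=1))
        z, pv = normal_test(est, se)
        name = f"path:{key[0]}->{key[1]}"
        results[name] = BootstrapResult(name, float(est), se, z, pv, n_boot)
    for j, m in enumerate(manifest):
        est = fit.loadings[m]
        se = float(boot_loadings[:, j].std(ddof=1))
        z, pv = normal_test(est, se)
        name = f"loading:{m}"
        results[name] = BootstrapResult(name, float(est), se, z, pv, n_boot)
    return fit, results
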
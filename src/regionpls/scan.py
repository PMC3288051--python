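"""Sliding-window regional scan statistics.

Each w-SNP window is fitted as a two-block PLS path model — the window's SNP
dosages form the exogenous block, the anthropometric traits (waist, hip, BMI)
the endogenous block — and the regional path coefficient beta21 is tested by
bootstrap.  A per-SNP single-trait linear-regression baseline and a
Bonferroni-style per-region alpha correction are included for comparison with
conventional analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BlockSpec, Mode, PathModel, InnerScheme
from .inference import BootstrapResult, bootstrap_plspm

__all__ = [
    "GenotypeMatrix",
    "Window",
    "WindowFit",
    "ScanResult",
    "sliding_windows",
    "multiple_testing_alpha",
    "scan_region",
    "single_snp_single_trait",
]

TRAIT_NAMES = ("waist", "hip", "bmi")
REGION_LATENT = "region"
TRAIT_LATENT = "body_shape"


@dataclass(frozen=True)
class GenotypeMatrix:
    """Additively coded genotypes: n individuals x m SNPs, dosages in {0,1,2}.

    Missing dosages are NaN (mean-imputed downstream); positions are 1-based
    base-pair coordinates, strictly increasing.
    """

    dosages: np.ndarray
    snp_ids: tuple[str, ...]
    positions: np.ndarray
    chromosome: str = "."
    sample_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=float)
        object.__setattr__(self, "dosages", d)
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))
        pos = np.asarray(self.positions, dtype=np.int64)
        object.__setattr__(self, "positions", pos)
        if d.ndim != 2 or d.shape[1] != len(self.snp_ids):
            raise ValueError("dosage matrix shape does not match snp_ids")
        if len(pos) != len(self.snp_ids):
            raise ValueError("positions length does not match snp_ids")
        if len(pos) > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError("positions must be strictly increasing")
        observed = d[~np.isnan(d)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def subset(self, snp_indices: np.ndarray) -> "GenotypeMatrix":
        snp_indices = np.asarray(snp_indices)
        return GenotypeMatrix(
            self.dosages[:, snp_indices],
            tuple(self.snp_ids[i] for i in snp_indices),
            self.positions[snp_indices],
            self.chromosome,
            self.sample_ids,
        )

    def flip_to_minor(self) -> "GenotypeMatrix":
        """Recode so the counted allele is the minor one at every SNP."""
        freq = np.nanmean(self.dosages, axis=0) / 2.0
        d = np.where(freq > 0.5, 2.0 - self.dosages, self.dosages)
        return GenotypeMatrix(d, self.snp_ids, self.positions,
                              self.chromosome, self.sample_ids)


@dataclass(frozen=True)
class Window:
    """Contiguous run of SNPs, 1-based inclusive indices."""

    start_index: int
    end_index: int
    snp_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.start_index < 1 or self.end_index < self.start_index:
            raise ValueError("invalid window bounds")
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))

    @property
    def size(self) -> int:
        return self.end_index - self.start_index + 1


@dataclass
class WindowFit:
    window: Window
    beta21: float
    se_boot: float
    p_value: float
    snp_loadings: dict[str, float]
    trait_loadings: dict[str, float]
    r_squared: float
    start_pos: int
    end_pos: int
    n_snps_used: int


@dataclass
class ScanResult:
    """Per-window regional tests for one window size over one region."""

    window_size: int
    chromosome: str
    fits: list[WindowFit]
    alpha: float
    alpha_adjusted: float
    skipped_windows: list[Window] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return len(self.fits) + len(self.skipped_windows)

    @property
    def best(self) -> WindowFit:
        """The minimum-p window."""
        return min(self.fits, key=lambda f: f.p_value)

    def to_dataframe(self) -> pd.DataFrame:
        best = self.best if self.fits else None
        rows = []
        for f in self.fits:
            rows.append({
                "chrom": self.chromosome,
                "start_snp": f.window.start_index,
                "end_snp": f.window.end_index,
                "start_pos": f.start_pos,
                "end_pos": f.end_pos,
                "w": self.window_size,
                "n_snps_used": f.n_snps_used,
                "beta21": f.beta21,
                "se": f.se_boot,
                "p": f.p_value,
                "significant": f.p_value < self.alpha_adjusted,
                "flagged": f is best,
            })
        return pd.DataFrame(rows)


def sliding_windows(m: int, w: int) -> list[Window]:
    """All m - w + 1 contiguous w-SNP windows (step 1, 1-based inclusive)."""
    if w < 1:
        raise ValueError("window size must be at least 1")
    if w > m:
        raise ValueError(f"window size {w} exceeds SNP count {m}")
    return [Window(s, s + w - 1) for s in range(1, m - w + 2)]


def multiple_testing_alpha(n_windows: int, alpha: float) -> float:
    """Bonferroni-adjusted per-window level for a region scanned with n windows."""
    if n_windows < 1:
        raise ValueError("n_windows must be at least 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / n_windows


def window_model(n_snps: int, snp_names: tuple[str, ...],
                 inner_scheme: InnerScheme | str = InnerScheme.CENTROID) -> PathModel:
    """The two-block model: w SNPs -> latent body shape (waist, hip, BMI)."""
    return PathModel(
        blocks=(
            BlockSpec(REGION_LATENT, snp_names, Mode.A),
            BlockSpec(TRAIT_LATENT, TRAIT_NAMES, Mode.A),
        ),
        inner_paths=((REGION_LATENT, TRAIT_LATENT),),
        inner_scheme=InnerScheme(inner_scheme),
    )


def scan_region(
    genotypes: GenotypeMatrix,
    traits: np.ndarray,
    covariates: np.ndarray | None,
    w: int,
    n_boot: int = 5000,
    alpha: float = 0.05,
    seed: int | None = None,
    inner_scheme: InnerScheme | str = InnerScheme.CENTROID,
) -> ScanResult:
    """Scan every w-SNP window of the region against the latent trait block.

    Monomorphic SNPs are dropped within each window (a window is skipped when
    no SNP remains); the trait columns must be (waist, hip, bmi).  The
    bootstrap seed for each window is derived deterministically from ``seed``.
    """
    traits = np.asarray(traits, dtype=float)
    if traits.shape[0] != genotypes.n:
        raise ValueError("genotypes and traits have different individual counts")
    if traits.shape[1] != 3:
        raise ValueError("expected three trait columns (waist, hip, bmi)")
    keep = ~np.isnan(traits).any(axis=1)
    if covariates is not None:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        keep &= ~np.isnan(covariates).any(axis=1)
    if keep.sum() < 3:
        raise ValueError("fewer than 3 individuals with complete trait/covariate data")
    dos = genotypes.dosages[keep]
    traits = traits[keep]
    cov = covariates[keep] if covariates is not None else None

    windows = sliding_windows(genotypes.m, w)
    n_windows = len(windows)
    alpha_adj = multiple_testing_alpha(n_windows, alpha)
    seeds = np.random.SeedSequence(seed).generate_state(n_windows)

    fits: list[WindowFit] = []
    skipped: list[Window] = []
    for wi, win in enumerate(windows):
        idx = np.arange(win.start_index - 1, win.end_index)
        sub = dos[:, idx]
        col_sd = np.nanstd(sub, axis=0)
        poly = col_sd > 0
        if poly.sum() < 1:
            skipped.append(Window(win.start_index, win.end_index,
                                  tuple(genotypes.snp_ids[i] for i in idx)))
            continue
        use = idx[poly]
        snp_names = tuple(genotypes.snp_ids[i] for i in use)
        model = window_model(len(use), snp_names, inner_scheme)
        raw = np.column_stack([dos[:, use], traits])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit, boot = bootstrap_plspm(
                raw, cov, model, n_boot=n_boot, seed=int(seeds[wi]),
                variable_names=snp_names + TRAIT_NAMES,
            )
        path = boot[f"path:{REGION_LATENT}->{TRAIT_LATENT}"]
        fits.append(WindowFit(
            window=Window(win.start_index, win.end_index, snp_names),
            beta21=path.estimate,
            se_boot=path.se_boot,
            p_value=path.p_value,
            snp_loadings={m: fit.loadings[m] for m in snp_names},
            trait_loadings={t: fit.loadings[t] for t in TRAIT_NAMES},
            r_squared=fit.r_squared[TRAIT_LATENT],
            start_pos=int(genotypes.positions[win.start_index - 1]),
            end_pos=int(genotypes.positions[win.end_index - 1]),
            n_snps_used=len(use),
        ))
    return ScanResult(w, genotypes.chromosome, fits, alpha, alpha_adj, skipped)


def single_snp_single_trait(
    genotypes: GenotypeMatrix,
    trait: np.ndarray,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """SNP-wise linear regression of one trait on dosage (plus covariates).

    Returns a frame with slope, se, p (two-sided t), r_squared per SNP;
    monomorphic SNPs are flagged with ``monomorphic=True`` and NaN estimates.
    """
    import statsmodels.api as sm

    trait = np.asarray(trait, dtype=float)
    if np.nanstd(trait) == 0:
        raise ValueError("trait is constant")
    cov = None
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
    rows = []
    for j, snp in enumerate(genotypes.snp_ids):
        g = genotypes.dosages[:, j]
        keep = ~np.isnan(g) & ~np.isnan(trait)
        if cov is not None:
            keep &= ~np.isnan(cov).any(axis=1)
        gk, yk = g[keep], trait[keep]
        if np.std(gk) == 0:
            rows.append({"snp_id": snp, "slope": np.nan, "se": np.nan,
                         "p": np.nan, "r_squared": np.nan, "monomorphic": True})
            continue
        X = gk[:, None] if cov is None else np.column_stack([gk, cov[keep]])
        res = sm.OLS(yk, sm.add_constant(X)).fit()
        rows.append({
            "snp_id": snp,
            "slope": float(res.params[1]),
            "se": float(res.bse[1]),
            "p": float(res.pvalues[1]),
            "r_squared": float(res.rsquared),
            "monomorphic": False,
        })
    return pd.DataFrame(rows)
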
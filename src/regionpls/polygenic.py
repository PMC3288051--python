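"""Polygenic-effect model: loading-weighted polygenic risk scores (PRS),
the latent body-shape score (BSS), effect decompositions and body-type
classification.

A SNP set drawn from different genomic regions forms the exogenous block of a
two-block PLS path model; its latent score is the PRS, the latent score of the
(waist, hip, BMI) block is the BSS, and the path coefficient beta21 is the
polygenic effect.  The standardized effect of an individual SNP on body shape
is the product of its loading with beta21 (the indirect effect along the
path).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import standardize
from .inference import BootstrapResult, bootstrap_plspm
from .scan import TRAIT_NAMES, GenotypeMatrix, window_model, REGION_LATENT, TRAIT_LATENT

__all__ = [
    "PolygenicFit",
    "BodyTypeThresholds",
    "BODY_TYPE_LABELS",
    "fit_polygenic",
    "indirect_effect",
    "body_shape_score",
    "weighted_allele_score",
    "unweighted_allele_score",
    "classify_body_type",
    "body_type_table",
    "cumulative_effect_table",
]

BODY_TYPE_LABELS = {
    1: "Chilli",
    2: "Chilli pear-apple",
    3: "Chilli apple",
    4: "Pear",
    5: "Pear-apple",
    6: "Apple",
    7: "Big pear",
    8: "Big pear-apple",
    9: "Big apple",
}


@dataclass
class PolygenicFit:
    """Fitted polygenic model: loadings, path coefficient, PRS and BSS scores."""

    snp_loadings: dict[str, float]
    trait_loadings: dict[str, float]
    beta21: float
    prs: np.ndarray  # standardized latent score of the SNP block
    bss: np.ndarray  # standardized latent score of the trait block
    r_squared: float
    bootstrap: dict[str, BootstrapResult] = field(default_factory=dict)

    def indirect_effects(self) -> dict[str, float]:
        """Per-SNP standardized effect on body shape: loading x beta21."""
        return {s: indirect_effect(l, self.beta21)
                for s, l in self.snp_loadings.items()}

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for snp, lam in self.snp_loadings.items():
            b = self.bootstrap.get(f"loading:{snp}")
            rows.append({
                "snp_id": snp,
                "loading": lam,
                "p": b.p_value if b else np.nan,
                "indirect_effect": indirect_effect(lam, self.beta21),
            })
        return pd.DataFrame(rows)


def fit_polygenic(
    genotypes: GenotypeMatrix,
    traits: np.ndarray,
    covariates: np.ndarray | None = None,
    n_boot: int = 5000,
    seed: int | None = None,
) -> PolygenicFit:
    """Fit the two-block polygenic model and bootstrap all parameters.

    The PRS is the unit-variance latent score of the SNP block (weights from
    the fit, hence loadings-driven); BSS is the trait-block score.
    """
    if genotypes.m < 2:
        raise ValueError("need at least 2 SNPs for a polygenic model")
    traits = np.asarray(traits, dtype=float)
    if traits.shape[0] != genotypes.n:
        raise ValueError("genotypes and traits have different individual counts")
    model = window_model(genotypes.m, genotypes.snp_ids)
    raw = np.column_stack([genotypes.dosages, traits])
    fit, boot = bootstrap_plspm(
        raw, covariates, model, n_boot=n_boot, seed=seed,
        variable_names=genotypes.snp_ids + TRAIT_NAMES,
    )
    return PolygenicFit(
        snp_loadings={s: fit.loadings[s] for s in genotypes.snp_ids},
        trait_loadings={t: fit.loadings[t] for t in TRAIT_NAMES},
        beta21=fit.path_coefficients[(REGION_LATENT, TRAIT_LATENT)],
        prs=fit.score(REGION_LATENT),
        bss=fit.score(TRAIT_LATENT),
        r_squared=fit.r_squared[TRAIT_LATENT],
        bootstrap=boot,
    )


def indirect_effect(loading: float, beta: float) -> float:
    """Standardized effect of one manifest on the downstream latent: loading x beta."""
    return loading * beta


def body_shape_score(
    traits: np.ndarray,
    trait_loadings: np.ndarray | dict[str, float],
    rescale: tuple[float, float] | None = None,
) -> np.ndarray:
    """Latent body-shape score: loading-weighted sum of standardized traits.

    Standardized scale (mean 0, sd 1) by default; ``rescale=(mean, sd)``
    applies an affine map to a reporting scale.
    """
    if isinstance(trait_loadings, dict):
        lam = np.array([trait_loadings[t] for t in TRAIT_NAMES])
    else:
        lam = np.asarray(trait_loadings, dtype=float)
    traits = np.asarray(traits, dtype=float)
    if traits.ndim != 2 or traits.shape[1] != lam.shape[0]:
        raise ValueError("trait matrix and loadings are incompatible")
    z = standardize(traits).values
    score = z @ lam
    sd = score.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate traits: zero-variance combination")
    score = (score - score.mean()) / sd
    if rescale is not None:
        mu, sigma = rescale
        score = mu + sigma * score
    return score


def weighted_allele_score(
    genotypes: GenotypeMatrix, snp_loadings: dict[str, float]
) -> np.ndarray:
    """Allele-count PRS on a bounded scale: sum_j (lambda_j / sum lambda) g_ij.

    A convenience reporting scale (per-individual average of risk-allele counts
    weighted by normalized loadings), in allele-count units.
    """
    lam = np.array([snp_loadings[s] for s in genotypes.snp_ids])
    total = lam.sum()
    if total == 0:
        raise ValueError("loadings sum to zero")
    w = lam / total
    d = genotypes.dosages
    if np.isnan(d).any():
        d = np.where(np.isnan(d), np.nanmean(d, axis=0)[None, :], d)
    return d @ w


def unweighted_allele_score(genotypes: GenotypeMatrix) -> np.ndarray:
    """Plain count of risk alleles across the SNP set (the unweighted score)."""
    d = genotypes.dosages
    if np.isnan(d).any():
        d = np.where(np.isnan(d), np.nanmean(d, axis=0)[None, :], d)
    return d.sum(axis=1)


@dataclass(frozen=True)
class BodyTypeThresholds:
    """Cut points for the 3 x 3 body-type grid (BMI strata x WHR strata).

    Default WHR cuts are configurable placeholders for cohort-specific
    abdominal-obesity conventions; BMI cuts are the WHO overweight/obese
    thresholds.
    """

    bmi_cuts: tuple[float, float] = (25.0, 30.0)
    whr_cuts_male: tuple[float, float] = (0.90, 1.00)
    whr_cuts_female: tuple[float, float] = (0.80, 0.85)

    def __post_init__(self) -> None:
        for cuts in (self.bmi_cuts, self.whr_cuts_male, self.whr_cuts_female):
            if not (len(cuts) == 2 and cuts[0] < cuts[1]):
                raise ValueError("cuts must be two strictly ascending values")


def classify_body_type(
    bmi: np.ndarray | float,
    whr: np.ndarray | float,
    sex: np.ndarray | str,
    thresholds: BodyTypeThresholds | None = None,
) -> np.ndarray:
    """Assign each individual to one of nine body types (codes 1..9).

    The grid is BMI stratum (major) x WHR stratum (minor), both with
    sex-specific WHR cuts; intervals are half-open, lower-inclusive, so a
    value equal to a cut falls in the upper stratum.
    """
    th = thresholds or BodyTypeThresholds()
    bmi = np.atleast_1d(np.asarray(bmi, dtype=float))
    whr = np.atleast_1d(np.asarray(whr, dtype=float))
    sex = np.atleast_1d(np.asarray(sex))
    if not ((bmi > 0).all() and (whr > 0).all()):
        raise ValueError("bmi and whr must be positive")
    is_male = np.char.lower(sex.astype(str)) == "male"
    is_female = np.char.lower(sex.astype(str)) == "female"
    if not (is_male | is_female).all():
        raise ValueError("sex must be 'male' or 'female'")
    bmi_stratum = np.searchsorted(np.asarray(th.bmi_cuts), bmi, side="right")
    whr_stratum = np.where(
        is_male,
        np.searchsorted(np.asarray(th.whr_cuts_male), whr, side="right"),
        np.searchsorted(np.asarray(th.whr_cuts_female), whr, side="right"),
    )
    return (3 * bmi_stratum + whr_stratum + 1).astype(int)


def body_type_table(
    bss: np.ndarray,
    bmi: np.ndarray,
    whr: np.ndarray,
    sex: np.ndarray,
    thresholds: BodyTypeThresholds | None = None,
) -> pd.DataFrame:
    """Per-sex body-type summary: n, %, mean +/- SD and 95% CI of BSS."""
    codes = classify_body_type(bmi, whr, sex, thresholds)
    sex = np.char.lower(np.atleast_1d(np.asarray(sex)).astype(str))
    rows = []
    for s in ("male", "female"):
        mask_s = sex == s
        total = int(mask_s.sum())
        for code in range(1, 10):
            mask = mask_s & (codes == code)
            k = int(mask.sum())
            vals = np.asarray(bss)[mask]
            mean = float(vals.mean()) if k else np.nan
            sd = float(vals.std(ddof=1)) if k > 1 else np.nan
            if k > 1:
                half = stats.t.ppf(0.975, k - 1) * sd / np.sqrt(k)
                ci = (mean - half, mean + half)
            else:
                ci = (np.nan, np.nan)
            rows.append({
                "sex": s, "type": code, "label": BODY_TYPE_LABELS[code],
                "n": k, "pct": 100.0 * k / total if total else np.nan,
                "mean_bss": mean, "sd_bss": sd,
                "ci_low": ci[0], "ci_high": ci[1],
            })
    return pd.DataFrame(rows)


def cumulative_effect_table(
    fit: PolygenicFit,
    n_bins: int = 10,
) -> tuple[pd.DataFrame, float]:
    """Mean BSS per PRS bin plus the OLS slope of BSS on PRS.

    Checks the cumulative-effect pattern: body shape should increase
    linearly with the polygenic score.
    """
    prs, bss = np.asarray(fit.prs), np.asarray(fit.bss)
    if np.unique(prs).size < 2:
        raise ValueError("PRS is constant; cannot summarize cumulative effect")
    edges = np.quantile(prs, np.linspace(0, 1, n_bins + 1))
    edges = np.unique(edges)
    which = np.clip(np.searchsorted(edges, prs, side="right") - 1,
                    0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        mask = which == b
        if not mask.any():
            continue
        rows.append({
            "bin": b + 1,
            "prs_low": float(edges[b]),
            "prs_high": float(edges[b + 1]),
            "n": int(mask.sum()),
            "mean_prs": float(prs[mask].mean()),
            "mean_bss": float(bss[mask].mean()),
        })
    slope = float(stats.linregress(prs, bss).slope)
    return pd.DataFrame(rows), slope
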
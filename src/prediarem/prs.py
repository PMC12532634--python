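"""SNP quality control and weighted polygenic score for predicted VAT.

Genotypes are effect-allele dosages in [0, 2] (subjects x SNPs), weights are
per-allele effect sizes from GWAS summary statistics.  QC drops SNPs with
call-rate problems (missingness > 5%), minor allele frequency < 1% or
departure from Hardy-Weinberg equilibrium at p < 0.05 by the exact
conditional test on hard-called genotypes.  The score is the weighted dosage
sum over retained, allele-harmonized SNPs; it can be residualized on
covariates (age, sex, BMI) for adjusted group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "QCThresholds",
    "hwe_exact_p",
    "snp_qc",
    "compute_prs",
    "adjust_prs",
]

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass(frozen=True)
class QCThresholds:
    max_missingness: float = 0.05
    min_maf: float = 0.01
    hwe_alpha: float = 0.05

    def __post_init__(self) -> None:
        for name in ("max_missingness", "min_maf", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")


def _log_hwe_prob(n_het: int, n_rare: int, n: int) -> float:
    """log P(het count | allele counts) under Hardy-Weinberg equilibrium."""
    n_hom_rare = (n_rare - n_het) // 2
    n_hom_common = n - n_het - n_hom_rare
    return (
        gammaln(n + 1)
        - gammaln(n_het + 1)
        - gammaln(n_hom_rare + 1)
        - gammaln(n_hom_common + 1)
        + n_het * np.log(2.0)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
        - gammaln(2 * n + 1)
    )


def hwe_exact_p(n_aa_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the probabilities no larger than that of the observed
    configuration (two-sided by probability ordering, the standard exact HWE
    test).  Monomorphic markers return 1.
    """
    counts = (n_aa_hom1, n_het, n_hom2)
    if any(c < 0 or int(c) != c for c in counts):
        raise ValueError("genotype counts must be non-negative integers")
    n = sum(counts)
    if n == 0:
        raise ValueError("no genotyped subjects")
    n_rare = min(2 * n_aa_hom1 + n_het, 2 * n_hom2 + n_het)
    if n_rare == 0:
        return 1.0
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = np.array([_log_hwe_prob(int(h), n_rare, n) for h in hets])
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[hets == n_het][0]
    return float(min(p[p <= obs * (1 + 1e-12)].sum(), 1.0))


def _hard_calls(dosages: np.ndarray) -> np.ndarray:
    calls = np.round(dosages)
    return np.clip(calls, 0, 2)


def snp_qc(
    genotypes: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[list[str], pd.DataFrame]:
    """Apply the three QC filters; returns (retained SNP ids, per-SNP report).

    ``genotypes`` is subjects x SNPs with dosages in [0, 2] and NaN for
    missing calls.  Missingness and allele frequency are computed on the
    observed dosages; the HWE exact test uses hard-called (rounded)
    genotypes.  The report records each failing rule per SNP, so the filter
    is idempotent by construction.
    """
    thresholds = thresholds or QCThresholds()
    if genotypes.empty:
        raise ValueError("empty genotype table")
    rows = []
    retained = []
    for snp in genotypes.columns:
        d = genotypes[snp].to_numpy(dtype=float)
        miss = float(np.mean(np.isnan(d)))
        obs = d[~np.isnan(d)]
        if obs.size == 0:
            maf, hwe_p = 0.0, 1.0
        else:
            af = float(obs.mean() / 2.0)
            maf = min(af, 1.0 - af)
            calls = _hard_calls(obs)
            n_hom0 = int(np.sum(calls == 0))
            n_het = int(np.sum(calls == 1))
            n_hom2 = int(np.sum(calls == 2))
            hwe_p = hwe_exact_p(n_hom0, n_het, n_hom2)
        fail_miss = miss > thresholds.max_missingness
        fail_maf = maf < thresholds.min_maf
        fail_hwe = hwe_p < thresholds.hwe_alpha
        keep = not (fail_miss or fail_maf or fail_hwe)
        rows.append(
            {
                "snp": snp,
                "missingness": miss,
                "maf": maf,
                "hwe_p": hwe_p,
                "fail_missingness": fail_miss,
                "fail_maf": fail_maf,
                "fail_hwe": fail_hwe,
                "retained": keep,
            }
        )
        if keep:
            retained.append(snp)
    return retained, pd.DataFrame(rows).set_index("snp")


def compute_prs(
    genotypes: pd.DataFrame,
    weights: pd.DataFrame,
    snp_meta: pd.DataFrame | None = None,
    missing_policy: str = "mean",
) -> pd.Series:
    """Weighted effect-allele dosage sum per subject.

    ``weights`` has index = SNP id and columns ``effect_allele`` and
    ``beta``.  When ``snp_meta`` (index = SNP id, columns ``effect_allele``,
    ``other_allele``) is provided, alleles are harmonized: a weight stated
    for the genotype table's other allele is applied to the reflected dosage
    ``2 - d``; strand-ambiguous A/T and C/G SNPs are flagged by raising.
    Missing dosages are mean-imputed per SNP (``missing_policy='mean'``),
    treated as zero (``'zero'``) or the subject is dropped (``'drop'``).
    """
    if missing_policy not in ("mean", "zero", "drop"):
        raise ValueError("missing_policy must be 'mean', 'zero' or 'drop'")
    shared = [s for s in genotypes.columns if s in weights.index]
    if not shared:
        raise ValueError("no overlapping SNPs between genotypes and weights")
    dos = genotypes[shared].astype(float).copy()
    betas = weights.loc[shared, "beta"].astype(float).copy()
    if snp_meta is not None:
        for snp in shared:
            eff_g = str(snp_meta.loc[snp, "effect_allele"])
            oth_g = str(snp_meta.loc[snp, "other_allele"])
            eff_w = str(weights.loc[snp, "effect_allele"])
            if (eff_g, oth_g) in _AMBIGUOUS_PAIRS:
                raise ValueError(f"strand-ambiguous SNP {snp} (alleles {eff_g}/{oth_g})")
            if eff_w == eff_g:
                continue
            if eff_w == oth_g:
                dos[snp] = 2.0 - dos[snp]
            else:
                raise ValueError(f"allele mismatch for SNP {snp}")
    if missing_policy == "drop":
        dos = dos.dropna(axis=0)
    elif missing_policy == "mean":
        dos = dos.fillna(dos.mean())
    else:
        dos = dos.fillna(0.0)
    return pd.Series(dos.to_numpy() @ betas.to_numpy(), index=dos.index, name="prs")


def adjust_prs(scores: pd.Series, covariates: pd.DataFrame) -> pd.Series:
    """Residualize the score on covariates by ordinary least squares.

    Covariates (e.g. age, sex, BMI) must be complete for all scored
    subjects; the returned residuals have mean ~0 by construction.
    """
    cov = covariates.loc[scores.index]
    if cov.isna().any().any():
        raise ValueError("covariates must be complete for scored subjects")
    X = np.column_stack([np.ones(len(cov)), cov.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    beta, *_ = np.linalg.lstsq(X, scores.to_numpy(dtype=float), rcond=None)
    resid = scores.to_numpy(dtype=float) - X @ beta
    return pd.Series(resid, index=scores.index, name="prs_adjusted")
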
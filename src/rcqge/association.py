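"""Candidate-gene association of SNP genotypes with androstenone.

The trait, androstenone concentration in adipose tissue (µg/g, treated as
equal to ppm), is strongly right-skewed and analysed on the natural-log
scale with ordinary least squares::

    ln(androstenone) = sire + genotype + hys + b * bulbo + e

where sire and the combined herd/year/season batch (``hys``) are
categorical fixed effects, genotype is the candidate SNP, and the length
of the bulbo-urethral gland enters as a continuous covariate adjusting
for sexual maturity.  Genotype least-squares means (equal weights across
the levels of the other factors, covariate at its mean) are
back-transformed by plain exponentiation — without a variance correction
they estimate *medians* of the skewed original-scale distribution.  The
genotype effect is judged by the overall F test; each SNP is also checked
against Hardy-Weinberg proportions with a 1-df chi-square.
"""

from __future__ import annotations

import re
import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "EstimabilityError",
    "AssocResult",
    "fit_association",
    "backtransform_lsmeans",
    "hwe_chisq",
    "genotype_frequency_report",
    "read_genotype_vcf",
]


class EstimabilityError(ValueError):
    """Association model cannot be estimated (single class, aliasing...)."""


@dataclass(frozen=True)
class AssocResult:
    snp_id: str
    breed: str
    genotype_n: dict[str, int]
    lsmeans_log: dict[str, float]      # on the ln scale
    lsmeans_se_log: dict[str, float]
    lsmeans: dict[str, float]          # back-transformed medians, µg/g
    lsmeans_se: dict[str, float]       # delta-method SE on the original scale
    f_stat: float
    f_p: float
    df_num: int
    df_den: int
    hwe_chi2: float
    hwe_p: float


def _canonical_genotype(g: str) -> str:
    """Unordered two-allele string: 'GA' and 'AG' are the same genotype."""
    return "".join(sorted(g.strip().upper()))


def hwe_chisq(counts) -> tuple[float, int, float]:
    """Hardy-Weinberg chi-square for one biallelic SNP.

    ``counts`` is (n_hom1, n_het, n_hom2) or a mapping genotype -> count.
    Expected counts come from the observed allele frequencies (p^2, 2pq,
    q^2); the statistic is ``sum (obs-exp)^2/exp`` on 1 df.  A monomorphic
    SNP has no testable departure and returns (nan, 1, nan).
    """
    if isinstance(counts, dict):
        canon = Counter()
        for g, n in counts.items():
            canon[_canonical_genotype(g)] += n
        alleles = sorted(set("".join(canon)))
        if len(alleles) > 2:
            raise ValueError("hwe_chisq requires a biallelic SNP")
        if len(alleles) < 2:
            return float("nan"), 1, float("nan")
        a, b = alleles
        obs = np.array([canon.get(a + a, 0), canon.get("".join(sorted(a + b)), 0),
                        canon.get(b + b, 0)], dtype=float)
    else:
        obs = np.asarray(counts, dtype=float)
        if obs.shape != (3,):
            raise ValueError("counts must be (hom1, het, hom2)")
    n = obs.sum()
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * obs[0] + obs[1]) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return float("nan"), 1, float("nan")
    exp = n * np.array([p**2, 2 * p * q, q**2])
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return chi2, 1, float(sps.chi2.sf(chi2, 1))


def backtransform_lsmeans(
    lsmeans_log: dict[str, float], se_log: dict[str, float] | None = None
) -> tuple[dict[str, float], dict[str, float]]:
    """Exponentiate log-scale LS means into original-scale medians.

    No smearing or variance correction is applied, so ``exp(m)`` estimates
    the median (not the mean) of the skewed distribution.  SEs transfer by
    the delta method, ``se * exp(m)``.
    """
    med = {g: float(np.exp(m)) for g, m in lsmeans_log.items()}
    if se_log is None:
        return med, {}
    se = {g: float(se_log[g] * np.exp(m)) for g, m in lsmeans_log.items()}
    return med, se


def fit_association(
    phenotypes: pd.DataFrame,
    genotypes: pd.DataFrame,
    snp_id: str,
    breed: str | None = None,
) -> AssocResult:
    """OLS association of one SNP with ln(androstenone).

    ``phenotypes`` needs columns sample_id, sire, hys, bulbo_cm,
    androstenone (µg/g, > 0); ``genotypes`` needs sample_id, snp_id,
    genotype.  Animals missing either record are dropped.  Requires at
    least two observed genotype classes, and a design of full rank —
    a genotype perfectly confounded with sire/hys raises
    :class:`EstimabilityError` naming the aliased columns.
    """
    geno = genotypes.loc[genotypes["snp_id"] == snp_id, ["sample_id", "genotype"]].copy()
    geno["genotype"] = geno["genotype"].map(_canonical_genotype)
    pheno = phenotypes.drop(columns=["genotype"], errors="ignore")
    data = pheno.merge(geno, on="sample_id", how="inner").dropna(
        subset=["androstenone", "genotype", "sire", "hys", "bulbo_cm"]
    )
    if breed is None:
        breed = str(data["breed"].iloc[0]) if "breed" in data.columns else ""
    elif "breed" in data.columns:
        data = data[data["breed"] == breed]
    if (data["androstenone"] <= 0).any():
        raise ValueError("androstenone must be positive for the log transform")
    classes = sorted(data["genotype"].unique())
    if len(classes) < 2:
        raise EstimabilityError(
            f"SNP {snp_id!r}: only genotype class {classes} observed; "
            "association is not estimable"
        )
    data = data.assign(ln_y=np.log(data["androstenone"]))

    # degenerate terms (single-level factor, constant covariate) carry no
    # information and would only make the design singular
    nuisance = []
    if data["sire"].nunique() > 1:
        nuisance.append("C(sire)")
    if data["hys"].nunique() > 1:
        nuisance.append("C(hys)")
    if data["bulbo_cm"].nunique() > 1:
        nuisance.append("bulbo_cm")
    rhs = " + ".join(["C(genotype)"] + nuisance)
    rhs_reduced = " + ".join(nuisance) if nuisance else "1"

    full = smf.ols(f"ln_y ~ {rhs}", data=data)
    rank = np.linalg.matrix_rank(full.exog)
    if rank < full.exog.shape[1]:
        # name the aliased columns via QR pivoting
        _, r = np.linalg.qr(full.exog)
        aliased = [full.exog_names[i] for i in np.where(np.abs(np.diag(r)) < 1e-8)[0]]
        raise EstimabilityError(
            f"SNP {snp_id!r}: rank-deficient design; aliased terms: {aliased}"
        )
    fit = full.fit()

    # overall genotype F test against the nested model without genotype
    reduced = smf.ols(f"ln_y ~ {rhs_reduced}", data=data).fit()
    df_num = int(fit.df_model - reduced.df_model)
    df_den = int(fit.df_resid)
    num = (reduced.ssr - fit.ssr) / df_num
    den = fit.ssr / df_den
    f_stat = float(num / den) if den > 0 else float("inf")
    f_p = float(sps.f.sf(f_stat, df_num, df_den)) if np.isfinite(f_stat) else 0.0

    # LS means: equal weights over sire and hys levels, bulbo at its mean
    names = list(fit.params.index)
    sire_cols = [i for i, nm in enumerate(names) if nm.startswith("C(sire)[T.")]
    hys_cols = [i for i, nm in enumerate(names) if nm.startswith("C(hys)[T.")]
    geno_cols = {
        re.match(r"C\(genotype\)\[T\.(.+)\]", nm).group(1): i
        for i, nm in enumerate(names)
        if nm.startswith("C(genotype)[T.")
    }
    n_sire = len(sire_cols) + 1
    n_hys = len(hys_cols) + 1
    bulbo_i = names.index("bulbo_cm") if "bulbo_cm" in names else None
    cov = fit.cov_params().to_numpy()
    params = fit.params.to_numpy()
    lsm_log, lsm_se_log = {}, {}
    for g in classes:
        L = np.zeros(len(names))
        L[0] = 1.0
        for i in sire_cols:
            L[i] = 1.0 / n_sire
        for i in hys_cols:
            L[i] = 1.0 / n_hys
        if bulbo_i is not None:
            L[bulbo_i] = float(data["bulbo_cm"].mean())
        if g in geno_cols:
            L[geno_cols[g]] = 1.0
        lsm_log[g] = float(L @ params)
        lsm_se_log[g] = float(np.sqrt(L @ cov @ L))

    med, med_se = backtransform_lsmeans(lsm_log, lsm_se_log)
    geno_n = data["genotype"].value_counts().to_dict()
    chi2, _, hwe_p = hwe_chisq({g: int(n) for g, n in geno_n.items()})
    return AssocResult(
        snp_id=snp_id, breed=breed, genotype_n={g: int(geno_n[g]) for g in classes},
        lsmeans_log=lsm_log, lsmeans_se_log=lsm_se_log, lsmeans=med,
        lsmeans_se=med_se, f_stat=f_stat, f_p=f_p, df_num=df_num, df_den=df_den,
        hwe_chi2=chi2, hwe_p=hwe_p,
    )


def genotype_frequency_report(genotypes: pd.DataFrame) -> pd.DataFrame:
    """Genotype class counts and percentages per SNP (and breed if present).

    Counts match the published style of reporting genotype frequencies in
    the expression sample (n = 96 per breed makes counts read as
    near-percentages).  Row order is deterministic; input order is
    irrelevant.
    """
    if genotypes.empty:
        return pd.DataFrame(columns=["snp_id", "breed", "genotype", "n", "percent"])
    work = genotypes.copy()
    work["genotype"] = work["genotype"].map(_canonical_genotype)
    if "breed" not in work.columns:
        work["breed"] = ""
    grp = work.groupby(["snp_id", "breed", "genotype"], sort=True).size().rename("n").reset_index()
    totals = grp.groupby(["snp_id", "breed"])["n"].transform("sum")
    grp["percent"] = 100.0 * grp["n"] / totals
    return grp


def read_genotype_vcf(path) -> pd.DataFrame:
    """Read biallelic SNP genotypes from a (plain-text) VCF.

    Returns the long genotype table (sample_id, snp_id, genotype) used
    everywhere else; the SNP id is the VCF ID field, or CHROM:POS when
    the ID is missing.  Multiallelic records and non-SNP alleles are
    skipped with a warning; missing genotypes are omitted.
    """
    from cyvcf2 import VCF  # htslib-backed reader; handles plain and bgzipped VCF

    rows = []
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            warnings.warn(
                f"skipping non-biallelic-SNP record at {var.CHROM}:{var.POS}", stacklevel=2
            )
            continue
        snp = var.ID or f"{var.CHROM}:{var.POS}"
        for sample, gt in zip(samples, var.gt_bases):
            bases = re.split(r"[/|]", gt)
            if len(bases) != 2 or "." in bases:
                continue
            rows.append(
                {"sample_id": sample, "snp_id": snp,
                 "genotype": _canonical_genotype(bases[0] + bases[1])}
            )
    return pd.DataFrame(rows, columns=["sample_id", "snp_id", "genotype"])
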
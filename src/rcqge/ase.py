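"""Allele-specific expression (ASE) from two-allele competitive-PCR assays.

A two-allele assay yields three peak-area frequencies per titration point
— allele 1, allele 2, competitor — summing to one.  In a heterozygote the
ratio ``r = f1/(f1+f2)`` is independent of the competitor amount (it
cancels), so it is averaged unweighted over the titration range.  Summing
the two allele frequencies recovers a total-expression ladder that feeds
the ordinary titration model unchanged.

The differential-ASE test models the per-sample decadic-logit ratio
``logit10(r)`` with treatment (high/low androstenone) as fixed effect:
the grand mean tests allelic imbalance (allele effect), the treatment
term tests whether the imbalance differs between groups.  An alternative
"per_allele" mode reshapes each sample into one observation per allele
and fits a two-way treatment x allele model; because the two shares of a
sample are complementary its residuals are correlated within sample, so
the ratio response is the calibrated default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .simulate import logit10

__all__ = [
    "ASERatio",
    "ASEResult",
    "allele_ratio",
    "allele_ratios",
    "total_from_alleles",
    "ase_model",
]

_ALLELE1, _ALLELE2, _COMP = "allele1", "allele2", "competitor"


@dataclass(frozen=True)
class ASERatio:
    sample_id: str
    assay: str
    ratio: float  # allele-1 share of total cDNA, averaged over points
    n_points: int


@dataclass(frozen=True)
class ASEResult:
    assay: str
    breed: str
    group_mean_ratio: dict[str, float]
    n_het: dict[str, int]
    allele_p: float
    treatment_p: float
    interaction_p: float
    response: str


def _pivot_alleles(df: pd.DataFrame) -> pd.DataFrame:
    """Wide per-point frame with f1/f2(/comp) columns from long allele rows."""
    keys = [c for c in ["sample_id", "breed", "group", "assay", "point_index",
                        "competitor_conc_M", "replicate"] if c in df.columns]
    wide = df.pivot_table(index=keys, columns="allele", values="frequency",
                          aggfunc="first").reset_index()
    for col in (_ALLELE1, _ALLELE2):
        if col not in wide.columns:
            raise ValueError(f"two-allele table lacks {col!r} rows")
    return wide


def allele_ratio(df: pd.DataFrame, weights: str = "none") -> ASERatio:
    """Average allele-1 ratio ``f1/(f1+f2)`` over the titration range.

    ``df`` holds the long-format rows of one sample and one assay.  Points
    where both allele frequencies are zero (or missing) carry no
    information on the ratio and are skipped; a sample with no usable
    point yields a missing ratio.  The default is the unweighted mean of
    per-point ratios (the ratio is assumed constant over the range);
    ``weights="total"`` weights each point by its total cDNA signal
    f1+f2, down-weighting the competitor-dominated end of the ladder
    where the ratio is measured least precisely.
    """
    if weights not in ("none", "total"):
        raise ValueError(f"unknown weights mode {weights!r}")
    wide = _pivot_alleles(df)
    f1 = wide[_ALLELE1].to_numpy(float)
    f2 = wide[_ALLELE2].to_numpy(float)
    tot = f1 + f2
    ok = np.isfinite(tot) & (tot > 0)
    sid = str(df["sample_id"].iloc[0])
    assay = str(df["assay"].iloc[0]) if "assay" in df.columns else "?"
    if not ok.any():
        return ASERatio(sid, assay, np.nan, 0)
    if weights == "total":
        r = float(np.average(f1[ok] / tot[ok], weights=tot[ok]))
    else:
        r = float(np.mean(f1[ok] / tot[ok]))
    return ASERatio(sid, assay, r, int(ok.sum()))


def allele_ratios(
    df: pd.DataFrame,
    genotypes: pd.DataFrame | None = None,
    snp_id: str | None = None,
    weights: str = "none",
) -> pd.DataFrame:
    """Per-sample ASE ratios for a whole two-allele table.

    Only heterozygotes carry ASE information: when a genotype table
    (sample_id, snp_id, genotype) is supplied, homozygous samples are
    skipped with a warning.  A second product that is never detected
    (all allele-2 frequencies zero, as happens when one isoform of a
    transcript is absent) is flagged with a warning as well.

    Returns columns sample_id, breed, group, assay, ratio, n_points.
    """
    if genotypes is not None:
        snp = snp_id or str(genotypes["snp_id"].iloc[0])
        sub = genotypes[genotypes["snp_id"] == snp]
        het = set(sub.loc[sub["genotype"].str[0] != sub["genotype"].str[1], "sample_id"])
        skipped = sorted(set(df["sample_id"]) - het)
        if skipped:
            warnings.warn(
                f"{len(skipped)} homozygous sample(s) skipped for ASE: {skipped[:5]}...",
                stacklevel=2,
            )
        df = df[df["sample_id"].isin(het)]
    f2 = df.loc[df["allele"] == _ALLELE2, "frequency"]
    if len(f2) and (f2.fillna(0.0) == 0.0).all():
        warnings.warn("second product not detected in any sample", stacklevel=2)
    keys = [c for c in ["sample_id", "breed", "group", "assay"] if c in df.columns]
    rows = []
    for vals, sub in df.groupby(keys, sort=True):
        res = allele_ratio(sub, weights=weights)
        rec = dict(zip(keys, vals if isinstance(vals, tuple) else (vals,)))
        rec.update(ratio=res.ratio, n_points=res.n_points)
        rows.append(rec)
    return pd.DataFrame(rows)


def total_from_alleles(df: pd.DataFrame) -> pd.DataFrame:
    """Sum the two allele frequencies into a total-expression ladder.

    The result has the single-product schema (no ``allele`` column) and
    feeds the titration model unchanged.  A point where both alleles are
    zero becomes zero total and is removed downstream by the no-signal /
    boundary rules.  Totals exceeding 1 beyond numerical tolerance signal
    corrupted input.
    """
    wide = _pivot_alleles(df)
    total = wide[_ALLELE1].to_numpy(float) + wide[_ALLELE2].to_numpy(float)
    if np.nanmax(total) > 1.0 + 1e-9:
        raise ValueError("allele frequencies sum above 1: corrupted two-allele table")
    out = wide.drop(columns=[c for c in (_ALLELE1, _ALLELE2, _COMP) if c in wide.columns])
    out["frequency"] = total
    return out


def _anova(fit) -> pd.DataFrame:
    """Type-II anova; numerical-noise warnings on degenerate (noise-free)
    fits are silenced since :func:`_term_p` resolves those cases itself."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return sm.stats.anova_lm(fit, typ=2)


def _term_p(anova: pd.DataFrame, name: str, tss: float) -> float:
    """Term p-value with a guard for (near-)noise-free data.

    When both the term and residual sums of squares are negligible next to
    the response's total scale, the F ratio is 0/0 numerical noise: a term
    that explains nothing in noise-free data is surely null (p = 1), while
    a non-trivial term over zero residual is surely real (p -> 0).
    """
    if name not in anova.index:
        return np.nan
    ss = float(np.nan_to_num(anova.loc[name, "sum_sq"]))
    resid = float(np.nan_to_num(anova.loc["Residual", "sum_sq"]))
    tiny = max(tss, 1.0) * 1e-15
    if resid < tiny:
        return 1.0 if ss < tiny else 0.0
    p = float(anova.loc[name, "PR(>F)"])
    return p if np.isfinite(p) else np.nan


def ase_model(
    ratios: pd.DataFrame,
    response: str = "logit_ratio",
    assay: str | None = None,
    breed: str | None = None,
) -> ASEResult:
    """Test for allelic imbalance and its dependence on treatment.

    ``ratios`` is the output of :func:`allele_ratios` (columns sample_id,
    group, ratio at least) restricted to heterozygotes of one assay and
    breed; missing ratios are dropped.

    response="logit_ratio" (default)
        Fits ``logit10(r) ~ treatment`` on one row per sample.  The
        allele effect is the test of zero grand mean (balanced alleles
        give logit 0); the treatment term tests differential allelic
        imbalance between high and low groups, reported as both
        ``treatment_p`` and ``interaction_p`` since treatment can only
        act on the ratio through the allele contrast.

    response="per_allele"
        Mirrors a two-way fixed-effects analysis with one observation
        per sample x allele (log10 allele share) and treatment, allele
        and interaction terms.
    """
    work = ratios.dropna(subset=["ratio"]).copy()
    assay = assay or (str(work["assay"].iloc[0]) if "assay" in work.columns else "?")
    breed = breed or (str(work["breed"].iloc[0]) if "breed" in work.columns else "")
    groups = sorted(work["group"].unique())
    counts = work.groupby("group")["ratio"].count()
    if (counts < 2).any() or len(groups) < 2:
        warnings.warn(
            f"assay {assay!r}: a treatment group has <2 heterozygotes; "
            "model degenerates to one-way", stacklevel=2,
        )
    means = work.groupby("group")["ratio"].mean().to_dict()
    ns = work.groupby("group")["ratio"].count().to_dict()

    eps = 1e-12
    if response == "logit_ratio":
        work["y"] = logit10(work["ratio"].clip(eps, 1 - eps))
        fit = smf.ols("y ~ C(group)", data=work).fit()
        # grand mean = intercept + average of group offsets (equal weights)
        L = np.zeros(len(fit.params))
        L[0] = 1.0
        k = len(groups)
        for i, name in enumerate(fit.params.index):
            if name.startswith("C(group)[T."):
                L[i] = 1.0 / k
        if fit.ssr < 1e-20:
            gm = float(L @ fit.params)
            allele_p = 1.0 if abs(gm) < 1e-12 else 0.0
        else:
            allele_p = float(fit.t_test(L).pvalue)
        anova = _anova(fit)
        treat_p = _term_p(anova, "C(group)", float(fit.centered_tss))
        inter_p = treat_p
    elif response == "per_allele":
        r = work["ratio"].clip(eps, 1 - eps)
        long = pd.concat(
            [
                work.assign(allele="allele1", y=np.log10(r)),
                work.assign(allele="allele2", y=np.log10(1.0 - r)),
            ],
            ignore_index=True,
        )
        fit = smf.ols("y ~ C(group) * C(allele)", data=long).fit()
        anova = _anova(fit)
        tss = float(fit.centered_tss)
        allele_p = _term_p(anova, "C(allele)", tss)
        treat_p = _term_p(anova, "C(group)", tss)
        inter_p = _term_p(anova, "C(group):C(allele)", tss)
    else:
        raise ValueError(f"unknown response mode {response!r}")

    return ASEResult(
        assay=assay, breed=breed, group_mean_ratio=means, n_het=ns,
        allele_p=allele_p, treatment_p=treat_p, interaction_p=inter_p,
        response=response,
    )
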
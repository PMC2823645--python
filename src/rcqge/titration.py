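"""Titration-curve fitting, EC50 interpolation, and bootstrap fold-change
inference for real-competitive PCR.

The model: with ``x = log10(competitor concentration)`` and
``y = log10(f/(1-f))`` the cleaned data of one assay fall on a line of
slope ≈ -1 whose root ``x0`` (where cDNA and competitor amplify equally,
the EC50) measures transcript abundance — *more competitor needed means
more transcript, so a larger x0 means higher expression*.  A single
polynomial (degree 1 by default) is fitted to both treatment groups with
group-specific intercepts; the high-vs-low difference of the roots,
minus the same difference for the housekeeping reference, is the
normalized log10 fold change::

    log10FC = (x0_high - x0_low) - (x0_hk,high - x0_hk,low)
    FC      = 10 ** log10FC

Uncertainty comes from a case bootstrap that resamples animals (whole
ladders) within each treatment group and recomputes the normalized
log10FC on every replicate; bias, SE, percentile CI and a two-sided
tail-doubling p-value are read off the replicate distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "FitError",
    "BootstrapError",
    "TitrationFit",
    "EquivalencePoint",
    "QGEResult",
    "fit_titration",
    "interpolate_equivalence",
    "log_fold_change",
    "bootstrap_inference",
    "run_panel",
    "format_qge_table",
]


class FitError(ValueError):
    """Titration fit impossible (singular design, no usable root, ...)."""


class BootstrapError(RuntimeError):
    """Too many bootstrap replicates failed to refit."""


@dataclass
class TitrationFit:
    """Least-squares polynomial fit of logit frequency on log10 concentration."""

    assay: str
    degree: int
    groups: tuple[str, ...]
    intercepts: dict[str, float]
    poly_coefs: np.ndarray  # coefficients of x, x**2, ... (no intercept)
    residual_sd: float
    n_points: dict[str, int]
    x_range: tuple[float, float]
    shared_slope: bool = True

    @property
    def slope(self) -> float:
        return float(self.poly_coefs[0])


@dataclass(frozen=True)
class EquivalencePoint:
    """Root of the fitted titration curve: log10 of the EC50 concentration."""

    assay: str
    group: str
    x0: float
    extrapolated: bool = False

    @property
    def ec50(self) -> float:
        return 10.0**self.x0


@dataclass(frozen=True)
class QGEResult:
    """Per-assay bootstrap summary of the normalized fold change."""

    assay: str
    breed: str
    log10_fold_change: float
    fold_change: float
    bias: float
    std_error: float
    ci_low: float
    ci_high: float
    p_value: float
    n_boot: int
    n_high: int
    n_low: int
    n_bad_reps: int = 0
    normalized: bool = True


def _require_xy(df: pd.DataFrame) -> pd.DataFrame:
    if "logit" not in df.columns or "log10_conc" not in df.columns:
        df = df.copy()
        df["log10_conc"] = np.log10(df["competitor_conc_M"])
        df["logit"] = np.log10(df["frequency"] / (1.0 - df["frequency"]))
    return df


def fit_titration(
    df: pd.DataFrame,
    degree: int = 1,
    group_col: str = "group",
    shared_slope: bool = True,
    assay: str | None = None,
) -> TitrationFit:
    """Fit ``y = intercept_g + c1*x + ... + c_d*x**d`` by least squares.

    ``df`` holds cleaned points of one assay (``logit`` / ``log10_conc``
    columns, or raw ``frequency`` / ``competitor_conc_M``).  By default the
    polynomial part is shared across groups and only the intercept is
    group-specific — treatment acts as an additive covariate.  With
    ``shared_slope=False`` each group gets its own polynomial.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    df = _require_xy(df)
    assay = assay if assay is not None else str(df["assay"].iloc[0]) if "assay" in df.columns else "?"
    if group_col in df.columns:
        groups = tuple(dict.fromkeys(df[group_col]))
    else:
        groups = ("all",)
        df = df.assign(**{group_col: "all"})

    x = df["log10_conc"].to_numpy(float)
    y = df["logit"].to_numpy(float)
    if len(df) < degree + len(groups):
        raise FitError(f"assay {assay!r}: {len(df)} points cannot support the requested model")
    if np.ptp(x) == 0:
        raise FitError(f"assay {assay!r}: singular design, all concentrations identical")

    if shared_slope:
        g_onehot = np.column_stack([(df[group_col] == g).to_numpy(float) for g in groups])
        powers = np.column_stack([x**k for k in range(1, degree + 1)])
        X = np.hstack([g_onehot, powers])
        beta, rss, rank, _ = np.linalg.lstsq(X, y, rcond=None)
        if rank < X.shape[1]:
            raise FitError(f"assay {assay!r}: rank-deficient titration design")
        intercepts = {g: float(beta[i]) for i, g in enumerate(groups)}
        coefs = beta[len(groups):]
        resid = y - X @ beta
        dof = len(y) - X.shape[1]
        residual_sd = float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0
    else:
        intercepts, coef_list, rss_tot, npar = {}, [], 0.0, 0
        for g in groups:
            sub = df[df[group_col] == g]
            if len(sub) < degree + 1:
                raise FitError(f"assay {assay!r}: group {g!r} has too few points")
            c = np.polynomial.polynomial.polyfit(
                sub["log10_conc"].to_numpy(float), sub["logit"].to_numpy(float), degree
            )
            intercepts[g] = float(c[0])
            coef_list.append(c[1:])
            fitted = np.polynomial.polynomial.polyval(sub["log10_conc"].to_numpy(float), c)
            rss_tot += float(((sub["logit"].to_numpy(float) - fitted) ** 2).sum())
            npar += degree + 1
        # reported coefficients are the group average; interpolation uses the
        # per-group polynomials stashed below
        coefs = np.asarray(np.mean(coef_list, axis=0))
        dof = len(y) - npar
        residual_sd = float(np.sqrt(rss_tot / dof)) if dof > 0 else 0.0
        fit = TitrationFit(
            assay=assay, degree=degree, groups=groups, intercepts=intercepts,
            poly_coefs=coefs, residual_sd=residual_sd,
            n_points={g: int((df[group_col] == g).sum()) for g in groups},
            x_range=(float(x.min()), float(x.max())), shared_slope=False,
        )
        fit._group_coefs = {g: np.asarray(c) for g, c in zip(groups, coef_list)}  # type: ignore[attr-defined]
        return fit

    return TitrationFit(
        assay=assay, degree=degree, groups=groups, intercepts=intercepts,
        poly_coefs=np.asarray(coefs), residual_sd=residual_sd,
        n_points={g: int((df[group_col] == g).sum()) for g in groups},
        x_range=(float(x.min()), float(x.max())), shared_slope=shared_slope,
    )


def interpolate_equivalence(fit: TitrationFit, group: str | None = None) -> EquivalencePoint:
    """Root of the fitted curve for one group: the log10 EC50.

    Degree 1 uses the closed form ``x0 = -intercept/slope``.  Higher
    degrees take the real root inside the observed x range; if none lies
    inside, the nearest real root is returned with an extrapolation
    warning, and a fit with no real root at all is an error.
    """
    if group is None:
        if len(fit.groups) != 1:
            raise ValueError("group must be named for a multi-group fit")
        group = fit.groups[0]
    intercept = fit.intercepts[group]
    coefs = getattr(fit, "_group_coefs", {}).get(group, fit.poly_coefs)
    if fit.degree == 1:
        slope = float(coefs[0])
        if slope == 0:
            raise FitError(f"assay {fit.assay!r}: zero slope, no equivalence point")
        x0 = -intercept / slope
        extrap = not (fit.x_range[0] <= x0 <= fit.x_range[1])
        if extrap:
            warnings.warn(
                f"assay {fit.assay!r} group {group!r}: equivalence point {x0:.3f} "
                f"extrapolated beyond observed range {fit.x_range}",
                stacklevel=2,
            )
        return EquivalencePoint(fit.assay, group, float(x0), extrapolated=extrap)

    poly = np.concatenate([[intercept], np.asarray(coefs)])
    real = _real_roots(poly)
    if real.size == 0:
        raise FitError(f"assay {fit.assay!r} group {group!r}: titration curve has no real root")
    inside = real[(real >= fit.x_range[0]) & (real <= fit.x_range[1])]
    if inside.size:
        return EquivalencePoint(fit.assay, group, float(inside[0]), extrapolated=False)
    mid = 0.5 * (fit.x_range[0] + fit.x_range[1])
    nearest = real[np.argmin(np.abs(real - mid))]
    warnings.warn(
        f"assay {fit.assay!r} group {group!r}: no root inside the ladder range; "
        f"returning extrapolated root {nearest:.3f}",
        stacklevel=2,
    )
    return EquivalencePoint(fit.assay, group, float(nearest), extrapolated=True)


def _x0(point) -> float:
    return point.x0 if isinstance(point, EquivalencePoint) else float(point)


def log_fold_change(high, low, hk_high=None, hk_low=None) -> tuple[float, float, bool]:
    """Normalized log10 fold change and fold change, high over low.

    Accepts :class:`EquivalencePoint` objects or bare log10-EC50 floats.
    If the housekeeping pair is missing the unnormalized difference is
    returned with ``normalized=False`` — never silently substituted.
    """
    d = _x0(high) - _x0(low)
    if hk_high is None or hk_low is None:
        if (hk_high is None) != (hk_low is None):
            raise ValueError("housekeeping equivalence points must come as a pair")
        warnings.warn("no housekeeping pair supplied; returning unnormalized fold change",
                      stacklevel=2)
        return d, 10.0**d, False
    lfc = d - (_x0(hk_high) - _x0(hk_low))
    return lfc, 10.0**lfc, True


# ---------------------------------------------------------------------------
# bootstrap machinery
# ---------------------------------------------------------------------------


def _unit_stats(df: pd.DataFrame, groups: Sequence[str], unit: str):
    """Per-resampling-unit sufficient statistics (n, Sx, Sy, Sxx, Sxy) by group.

    unit="animal" groups rows by sample id (whole ladders are resampled);
    unit="point" makes every cleaned titration point its own unit.
    """
    df = _require_xy(df)
    out = {}
    for g in groups:
        sub = df[df["group"] == g]
        if unit == "animal":
            gb = sub.groupby("sample_id", sort=True)
            n = gb.size().to_numpy(float)
            sx = gb["log10_conc"].sum().to_numpy(float)
            sy = gb["logit"].sum().to_numpy(float)
            sxx = sub.assign(v=sub["log10_conc"] ** 2).groupby("sample_id", sort=True)["v"].sum().to_numpy(float)
            sxy = sub.assign(v=sub["log10_conc"] * sub["logit"]).groupby("sample_id", sort=True)["v"].sum().to_numpy(float)
            n_units = len(sub["sample_id"].unique())
        elif unit == "point":
            x = sub["log10_conc"].to_numpy(float)
            y = sub["logit"].to_numpy(float)
            n = np.ones(len(x))
            sx, sy, sxx, sxy = x, y, x * x, x * y
            n_units = len(x)
        else:
            raise ValueError(f"unknown resample unit {unit!r}")
        out[g] = {"n": n, "sx": sx, "sy": sy, "sxx": sxx, "sxy": sxy,
                  "n_units": n_units}
    return out


def _diff_from_sums(NH, SXh, SYh, SXXh, SXYh, NL, SXl, SYl, SXXl, SXYl):
    """x0_high - x0_low for the shared-slope line from pooled group sums.

    Returns NaN where the design is degenerate or the slope is
    non-negative (no usable equivalence points).
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = (SXXh + SXXl) - SXh**2 / NH - SXl**2 / NL
        b = ((SXYh + SXYl) - SXh * SYh / NH - SXl * SYl / NL) / denom
        a_h = (SYh - b * SXh) / NH
        a_l = (SYl - b * SXl) / NL
        diff = (a_l - a_h) / b
    bad = ~np.isfinite(diff) | (b >= 0) | (denom <= 1e-12)
    return np.where(bad, np.nan, diff)


def _full_diff(stats, groups) -> float:
    ah, al = stats[groups[0]], stats[groups[1]]
    return float(
        _diff_from_sums(
            ah["n"].sum(), ah["sx"].sum(), ah["sy"].sum(), ah["sxx"].sum(), ah["sxy"].sum(),
            al["n"].sum(), al["sx"].sum(), al["sy"].sum(), al["sxx"].sum(), al["sxy"].sum(),
        )
    )


def _resampled_diffs(stats, groups, idx_h, idx_l) -> np.ndarray:
    ah, al = stats[groups[0]], stats[groups[1]]

    def sums(a, idx):
        return (
            a["n"][idx].sum(1), a["sx"][idx].sum(1), a["sy"][idx].sum(1),
            a["sxx"][idx].sum(1), a["sxy"][idx].sum(1),
        )

    return _diff_from_sums(*sums(ah, idx_h), *sums(al, idx_l))


_BOOT_CHUNK = 1024  # replicates per vectorized block, caps peak memory


def _xy_units(df: pd.DataFrame, groups, unit: str):
    """Raw (x, y) arrays per resampling unit, for the general-degree path."""
    df = _require_xy(df)
    out = {}
    for g in groups:
        sub = df[df["group"] == g]
        if unit == "animal":
            units = [
                (s["log10_conc"].to_numpy(float), s["logit"].to_numpy(float))
                for _, s in sub.groupby("sample_id", sort=True)
            ]
        else:
            x = sub["log10_conc"].to_numpy(float)
            y = sub["logit"].to_numpy(float)
            units = [(x[i:i + 1], y[i:i + 1]) for i in range(len(x))]
        out[g] = units
    return out


def _real_roots(poly: np.ndarray) -> np.ndarray:
    """Real roots of a polynomial (coefficients low->high), with negligible
    leading coefficients trimmed first — a quadratic whose x² term is
    numerical noise must be solved as the line it really is."""
    scale = np.max(np.abs(poly))
    if scale == 0:
        return np.array([])
    trimmed = np.polynomial.polynomial.polytrim(poly, tol=1e-9 * scale)
    if len(trimmed) < 2:
        return np.array([])
    roots = np.polynomial.polynomial.polyroots(trimmed)
    return np.real(roots[np.abs(np.imag(roots)) < 1e-9])


def _poly_group_diff(xy, groups, idx_by_group, degree):
    """x0_high - x0_low for a shared polynomial with group intercepts."""
    xs, ys, labels = [], [], []
    for g in groups:
        units = xy[g]
        chosen = idx_by_group[g]
        for i in chosen:
            xs.append(units[i][0])
            ys.append(units[i][1])
            labels.extend([g] * len(units[i][0]))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    lab = np.asarray(labels)
    xm = x.mean()  # centring keeps the power basis well conditioned
    xc = x - xm
    onehot = np.column_stack([(lab == g).astype(float) for g in groups])
    powers = np.column_stack([xc**k for k in range(1, degree + 1)])
    X = np.hstack([onehot, powers])
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        return np.nan
    lo, hi = xc.min(), xc.max()
    roots = []
    for gi in range(len(groups)):
        poly = np.concatenate([[beta[gi]], beta[len(groups):]])
        real = _real_roots(poly)
        if real.size == 0:
            return np.nan
        inside = real[(real >= lo) & (real <= hi)]
        pick = inside[0] if inside.size else real[np.argmin(np.abs(real - 0.5 * (lo + hi)))]
        roots.append(pick + xm)
    return float(roots[0] - roots[1])


def bootstrap_inference(
    gene_df: pd.DataFrame,
    hk_df: pd.DataFrame | None,
    B: int = 4000,
    seed=0,
    groups: tuple[str, str] = ("high", "low"),
    alpha: float = 0.05,
    p_method: str = "percentile",
    resample_unit: str = "point",
    degree: int = 1,
    max_bad_fraction: float = 0.2,
    assay: str | None = None,
    breed: str = "",
) -> QGEResult:
    """Case-bootstrap inference on the housekeeping-normalized fold change.

    Each replicate resamples the cleaned observations with replacement
    within every treatment group and recomputes the full normalized
    log10 fold change.  The default resampling unit is the titration
    *point* (the pairs bootstrap of the regression, calibrated under
    independent per-point measurement noise); ``resample_unit="animal"``
    instead resamples whole ladders — appropriate when animals carry
    extra biological variance, but noticeably anticonservative with only
    a handful of animals per group.  With animal units the *same*
    resampled animals enter the gene and housekeeping refits, so
    sample-loading effects cancel as in the point estimate.

    Reported statistics:

    - ``bias``: mean(replicates) - point estimate (reported, never
      subtracted from the estimate);
    - ``std_error``: SD of replicates;
    - ``ci_low/ci_high``: percentile interval at level ``1 - alpha``;
    - ``p_value``: two-sided tail-doubling probability of a sign change
      in the replicate distribution, using the (c+1)/(B+1) tail estimate
      and floored at 1/B ("percentile"), or a normal approximation
      ``2*Phi(-|est/SE|)`` ("normal").
    """
    if B < 100:
        raise ValueError("B must be >= 100 for CI and p-value reporting")
    if resample_unit not in ("point", "animal"):
        raise ValueError(f"unknown resample_unit {resample_unit!r}")
    gene_df = _require_xy(gene_df)
    assay = assay or (str(gene_df["assay"].iloc[0]) if "assay" in gene_df.columns else "?")
    normalized = hk_df is not None
    if normalized:
        hk_df = _require_xy(hk_df)
        common = {
            g: sorted(
                set(gene_df.loc[gene_df["group"] == g, "sample_id"])
                & set(hk_df.loc[hk_df["group"] == g, "sample_id"])
            )
            for g in groups
        }
        keep = sorted(set().union(*common.values()))
        gene_df = gene_df[gene_df["sample_id"].isin(keep)]
        hk_df = hk_df[hk_df["sample_id"].isin(keep)]

    n_animals = {
        g: gene_df.loc[gene_df["group"] == g, "sample_id"].nunique() for g in groups
    }
    rng = np.random.default_rng(seed)
    if degree == 1:
        g_stats = _unit_stats(gene_df, groups, resample_unit)
        for g in groups:
            if g_stats[g]["n_units"] == 0:
                raise FitError(f"assay {assay!r}: no usable data in group {g!r}")
        est = _full_diff(g_stats, groups)
        h_stats = None
        if normalized:
            h_stats = _unit_stats(hk_df, groups, resample_unit)
            est -= _full_diff(h_stats, groups)
        if not np.isfinite(est):
            raise FitError(f"assay {assay!r}: point estimate is not finite")

        reps = np.empty(B)
        done = 0
        while done < B:
            nb = min(_BOOT_CHUNK, B - done)
            idx = {
                g: rng.integers(0, g_stats[g]["n_units"], size=(nb, g_stats[g]["n_units"]))
                for g in groups
            }
            block = _resampled_diffs(g_stats, groups, idx[groups[0]], idx[groups[1]])
            if normalized:
                if resample_unit == "animal":
                    # same animals drive the housekeeping refit
                    h_idx = idx
                else:
                    h_idx = {
                        g: rng.integers(
                            0, h_stats[g]["n_units"], size=(nb, h_stats[g]["n_units"])
                        )
                        for g in groups
                    }
                block = block - _resampled_diffs(h_stats, groups, h_idx[groups[0]], h_idx[groups[1]])
            reps[done:done + nb] = block
            done += nb
    else:
        # general polynomial: per-replicate refit (slower, rarely needed)
        gxy = _xy_units(gene_df, groups, resample_unit)
        for g in groups:
            if len(gxy[g]) == 0:
                raise FitError(f"assay {assay!r}: no usable data in group {g!r}")
        est = _poly_group_diff(
            gxy, groups, {g: np.arange(len(gxy[g])) for g in groups}, degree
        )
        hxy = None
        if normalized:
            hxy = _xy_units(hk_df, groups, resample_unit)
            est -= _poly_group_diff(
                hxy, groups, {g: np.arange(len(hxy[g])) for g in groups}, degree
            )
        if not np.isfinite(est):
            raise FitError(f"assay {assay!r}: point estimate is not finite")
        reps = np.empty(B)
        for b in range(B):
            idx = {g: rng.integers(0, len(gxy[g]), size=len(gxy[g])) for g in groups}
            val = _poly_group_diff(gxy, groups, idx, degree)
            if normalized:
                if resample_unit == "animal":
                    h_idx = idx
                else:
                    h_idx = {
                        g: rng.integers(0, len(hxy[g]), size=len(hxy[g])) for g in groups
                    }
                val = val - _poly_group_diff(hxy, groups, h_idx, degree)
            reps[b] = val

    good = np.isfinite(reps)
    n_bad = int(B - good.sum())
    if n_bad > max_bad_fraction * B:
        raise BootstrapError(
            f"assay {assay!r}: {n_bad}/{B} bootstrap replicates unfittable"
        )
    r = reps[good]
    nb_good = len(r)
    bias = float(r.mean() - est)
    se = float(r.std(ddof=1)) if nb_good > 1 else 0.0
    lo, hi = np.percentile(r, [100 * alpha / 2, 100 * (1 - alpha / 2)])

    if p_method == "percentile":
        c_lo = int(np.sum(r <= 0.0))
        c_hi = int(np.sum(r >= 0.0))
        p = 2.0 * (min(c_lo, c_hi) + 1) / (nb_good + 1)
        p = min(1.0, max(p, 1.0 / nb_good))
    elif p_method == "normal":
        if se == 0.0:
            p = 1.0 if est == 0.0 else 1.0 / nb_good
        else:
            p = float(min(1.0, max(2.0 * sps.norm.sf(abs(est) / se), 1.0 / nb_good)))
    else:
        raise ValueError(f"unknown p_method {p_method!r}")

    return QGEResult(
        assay=assay, breed=breed, log10_fold_change=float(est),
        fold_change=float(10.0**est), bias=bias, std_error=se,
        ci_low=float(lo), ci_high=float(hi), p_value=p, n_boot=nb_good,
        n_high=n_animals[groups[0]], n_low=n_animals[groups[1]],
        n_bad_reps=n_bad, normalized=normalized,
    )


RESULT_COLUMNS = [
    "assay", "breed", "fold_change", "log10_fold_change", "bias", "std_error",
    "ci_low", "ci_high", "p_value", "n_high", "n_low", "normalized", "significant",
]


def run_panel(
    clean_df: pd.DataFrame,
    housekeeping: str,
    B: int = 4000,
    seed: int = 0,
    alpha: float = 0.05,
    groups: tuple[str, str] = ("high", "low"),
    p_method: str = "percentile",
    degree: int = 1,
    resample_unit: str = "point",
    adjust: str = "none",
) -> pd.DataFrame:
    """Bootstrap every assay of a cleaned panel, per breed.

    One result row per assay per breed in the published table layout
    (fold change, log10 fold change, bias, SE, p).  The housekeeping
    assay's own row is reported unnormalized — normalizing it against
    itself would be identically zero.  Assays whose ladders cannot be fit
    are reported with NaN statistics rather than aborting the panel.

    ``adjust="bh"`` appends a Benjamini-Hochberg adjusted p-value column;
    the default applies no multiple-testing correction, and the
    ``significant`` flag always uses the raw per-gene threshold.
    """
    if clean_df.empty:
        warnings.warn("empty frequency table: returning empty result table", stacklevel=2)
        return pd.DataFrame(columns=RESULT_COLUMNS)
    if "breed" not in clean_df.columns:
        clean_df = clean_df.assign(breed="all")
    assays = sorted(clean_df["assay"].unique())
    if housekeeping not in assays:
        raise ValueError(f"housekeeping assay {housekeeping!r} not present in the table")
    breeds = sorted(clean_df["breed"].unique())
    tasks = [(b, a) for b in breeds for a in assays]
    child_seeds = np.random.SeedSequence(seed).spawn(len(tasks))
    rows = []
    for (breed, a), child in zip(tasks, child_seeds):
        sub = clean_df[(clean_df["breed"] == breed) & (clean_df["assay"] == a)]
        hk = None
        if a != housekeeping:
            hk = clean_df[(clean_df["breed"] == breed) & (clean_df["assay"] == housekeeping)]
        try:
            res = bootstrap_inference(
                sub, hk, B=B, seed=child, groups=groups, alpha=alpha,
                p_method=p_method, degree=degree, resample_unit=resample_unit,
                assay=a, breed=breed,
            )
            rows.append({
                "assay": a, "breed": breed, "fold_change": res.fold_change,
                "log10_fold_change": res.log10_fold_change, "bias": res.bias,
                "std_error": res.std_error, "ci_low": res.ci_low,
                "ci_high": res.ci_high, "p_value": res.p_value,
                "n_high": res.n_high, "n_low": res.n_low,
                "normalized": res.normalized,
                "significant": bool(res.p_value < alpha),
            })
        except (FitError, BootstrapError) as err:
            warnings.warn(f"assay {a!r} ({breed}): {err}", stacklevel=2)
            rows.append({
                "assay": a, "breed": breed, "fold_change": np.nan,
                "log10_fold_change": np.nan, "bias": np.nan, "std_error": np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
                "n_high": 0, "n_low": 0, "normalized": a != housekeeping,
                "significant": False,
            })
    out = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if adjust == "bh":
        from statsmodels.stats.multitest import multipletests

        out["p_adjusted"] = np.nan
        ok = out["p_value"].notna() & ~out["assay"].eq(housekeeping)
        if ok.any():
            out.loc[ok, "p_adjusted"] = multipletests(
                out.loc[ok, "p_value"], method="fdr_bh"
            )[1]
    elif adjust != "none":
        raise ValueError(f"unknown adjust mode {adjust!r}")
    return out


def format_qge_table(results: pd.DataFrame) -> pd.DataFrame:
    """Round a result table to the published display precision.

    Fold change to 1 decimal, log10 fold change to 2, bias to 4, SE to 2,
    p-value to 4 (so a p below 5e-5 prints as 0.0000).  Stored values stay
    unrounded; this produces a display copy.
    """
    out = results.copy()
    out["fold_change"] = out["fold_change"].round(1)
    out["log10_fold_change"] = out["log10_fold_change"].round(2)
    if "bias" in out:
        out["bias"] = out["bias"].round(4)
    if "std_error" in out:
        out["std_error"] = out["std_error"].round(2)
    if "p_value" in out:
        out["p_value"] = out["p_value"].round(4)
    return out
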
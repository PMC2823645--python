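"""Synthetic competitive-PCR data generation.

Real-competitive PCR (rcPCR) quantifies a transcript by co-amplifying its
cDNA with a synthetic competitor titrated over a serial dilution ladder.
The MALDI-TOF readout at each titration point is a *peak-area frequency*
``f`` — the target's share of total signal — so ``f/(1-f)`` estimates the
cDNA:competitor molar ratio.  This module fabricates such frequency tables
(plus genotypes and androstenone phenotypes) with the statistical structure
the downstream fitting stages assume, so the whole pipeline is testable
without tissue.

Measurement model
-----------------
For a sample whose target cDNA sits at ``10**t`` molar and a titration
point with competitor concentration ``c``, the noiseless decadic logit of
the frequency is::

    y = log10(f/(1-f)) = t - log10(c)

i.e. a line of slope -1 in ``x = log10(c)`` crossing zero at the
equivalence concentration ``10**t`` (EC50).  Replicate noise is additive
Gaussian *on the logit scale*, which keeps the downstream linear fit
correctly specified.  Dropout (no signal for either product) yields a
missing frequency.

All randomness flows from a single seed; each emitted table derives its
own substream deterministically, so regenerating any table with the same
scenario and seed is byte-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "AVOGADRO",
    "LadderDesign",
    "ExpressionScenario",
    "ASEScenario",
    "PhenotypeScenario",
    "make_ladder",
    "molecules_at",
    "simulate_expression",
    "simulate_ase",
    "simulate_genotypes",
    "simulate_phenotypes",
    "logit10",
    "inv_logit10",
    "LANDRACE_LOG10_FC",
    "DUROC_LOG10_FC",
    "default_baselines",
]

AVOGADRO = 6.02214076e23

# Stream tags keep the per-table substreams of a single user seed apart.
_STREAM_EXPRESSION = 11
_STREAM_ASE = 23
_STREAM_GENOTYPE = 37
_STREAM_PHENOTYPE = 41


def logit10(f):
    """Decadic logit ``y = log10(f/(1-f))`` for ``f`` strictly inside (0, 1)."""
    f = np.asarray(f, dtype=float)
    if np.any((f <= 0) | (f >= 1)):
        raise ValueError("logit10 requires 0 < f < 1")
    out = np.log10(f / (1.0 - f))
    return float(out) if out.ndim == 0 else out


def inv_logit10(y):
    """Inverse of :func:`logit10`: ``f = 10**y / (1 + 10**y)``."""
    y = np.asarray(y, dtype=float)
    # expit in base 10; formulated to avoid overflow for large |y|
    out = np.where(y >= 0, 1.0 / (1.0 + 10.0 ** (-y)), 10.0**y / (1.0 + 10.0**y))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class LadderDesign:
    """Serial dilution ladder of the synthetic competitor.

    Defaults reproduce the fine scan used for accurate quantification:
    11 points of 7-fold dilutions starting at 4.04e-11 M, which ends at
    1.43e-19 M.  ``reaction_volume`` (litres) only matters for reporting
    expected molecule counts; 5 µL is a typical PCR volume and is an
    assumption, not a measured value.
    """

    start_conc: float = 4.04e-11
    dilution_factor: float = 7.0
    n_points: int = 11
    reaction_volume: float = 5e-6

    def __post_init__(self) -> None:
        if not self.start_conc > 0:
            raise ValueError("start_conc must be positive")
        if not self.dilution_factor > 1:
            raise ValueError("dilution_factor must exceed 1")
        if self.n_points < 1:
            raise ValueError("n_points must be >= 1")
        if not self.reaction_volume > 0:
            raise ValueError("reaction_volume must be positive")

    def concentrations(self) -> np.ndarray:
        return make_ladder(self)


def make_ladder(design: LadderDesign) -> np.ndarray:
    """Ordered competitor concentrations: point k is ``start/factor**k``."""
    k = np.arange(design.n_points)
    return design.start_conc / design.dilution_factor ** k.astype(float)


def molecules_at(conc: float, volume: float) -> tuple[float, int]:
    """Expected competitor molecule count at a molar concentration.

    Returns the real-valued expectation ``conc * N_A * volume`` and its
    nearest integer.  At 1e-18 M in 5 µL this is about 3 molecules — the
    regime where the ladder bottoms out in single-molecule territory.
    """
    if conc < 0:
        raise ValueError("concentration must be non-negative")
    if not volume > 0:
        raise ValueError("volume must be positive")
    expected = conc * AVOGADRO * volume
    return expected, int(round(expected))


@dataclass(frozen=True)
class ExpressionScenario:
    """Ground truth for a simulated expression panel.

    ``true_log10_fc`` maps assay id -> log10 fold change of the high- over
    the low-androstenone group; ``baseline_log10_conc`` maps assay id ->
    log10 molar cDNA concentration in the low group.  Exactly one assay is
    the housekeeping reference and must have zero true fold change.
    ``sample_loading_sd`` adds a per-animal offset shared by every assay of
    that animal (cDNA loading differences); housekeeping normalization
    removes it exactly.
    """

    true_log10_fc: Mapping[str, float]
    baseline_log10_conc: Mapping[str, float]
    housekeeping: str
    n_per_group: int = 48
    noise_sd: float = 0.15
    replicate_count: int = 2
    dropout_rate: float = 0.0
    sample_loading_sd: float = 0.0
    groups: tuple[str, str] = ("high", "low")

    def __post_init__(self) -> None:
        if set(self.true_log10_fc) != set(self.baseline_log10_conc):
            raise ValueError("true_log10_fc and baseline_log10_conc must list the same assays")
        if self.housekeeping not in self.true_log10_fc:
            raise ValueError(f"housekeeping assay {self.housekeeping!r} not in panel")
        if self.true_log10_fc[self.housekeeping] != 0.0:
            raise ValueError("housekeeping assay must have true_log10_fc == 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.noise_sd < 0 or self.sample_loading_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if self.n_per_group < 1 or self.replicate_count < 1:
            raise ValueError("n_per_group and replicate_count must be >= 1")


def simulate_expression(
    scenario: ExpressionScenario,
    design: LadderDesign,
    seed: int,
    breed: str = "Landrace",
) -> pd.DataFrame:
    """Simulate a long-format peak-area frequency table for one breed.

    Columns: sample_id, breed, group, assay, point_index,
    competitor_conc_M, replicate, frequency.  Dropout points carry NaN
    frequency (no signal detected for either product).
    """
    rng = np.random.default_rng([_STREAM_EXPRESSION, seed])
    conc = make_ladder(design)
    x = np.log10(conc)
    assays = list(scenario.true_log10_fc)
    n = scenario.n_per_group
    reps = scenario.replicate_count

    samples, groups = [], []
    for g in scenario.groups:
        for i in range(n):
            samples.append(f"{breed[:1]}_{g}_{i:03d}")
            groups.append(g)
    loading = rng.normal(0.0, scenario.sample_loading_sd, size=len(samples))

    frames = []
    for a in assays:
        base = scenario.baseline_log10_conc[a]
        fc = scenario.true_log10_fc[a]
        # target log10 concentration per sample
        t = base + np.where(np.array(groups) == scenario.groups[0], fc, 0.0) + loading
        # (sample, point, replicate) logit values
        mu = t[:, None, None] - np.log10(conc)[None, :, None]
        y = mu + rng.normal(0.0, scenario.noise_sd, size=(len(samples), len(conc), reps))
        f = inv_logit10(y)
        if scenario.dropout_rate > 0:
            lost = rng.random(f.shape) < scenario.dropout_rate
            f = np.where(lost, np.nan, f)
        idx = pd.MultiIndex.from_product(
            [samples, range(len(conc)), range(1, reps + 1)],
            names=["sample_id", "point_index", "replicate"],
        )
        df = pd.DataFrame({"frequency": f.ravel()}, index=idx).reset_index()
        df["assay"] = a
        frames.append(df)

    out = pd.concat(frames, ignore_index=True)
    gmap = dict(zip(samples, groups))
    out["group"] = out["sample_id"].map(gmap)
    out["breed"] = breed
    out["competitor_conc_M"] = conc[out["point_index"].to_numpy()]
    cols = [
        "sample_id", "breed", "group", "assay", "point_index",
        "competitor_conc_M", "replicate", "frequency",
    ]
    return out[cols]


@dataclass(frozen=True)
class ASEScenario:
    """Ground truth for a two-allele (allele-specific expression) assay.

    ``allele1_fraction`` maps group label -> the fraction of total
    transcript carried by allele 1 in heterozygotes of that group.  The
    assay emits three frequencies per titration point (allele 1, allele 2,
    competitor) that sum to one.  ``allele_freq`` is the population
    frequency of allele 1, used when genotypes are simulated under HWE.
    """

    allele1_fraction: Mapping[str, float]
    baseline_log10_conc: float = -16.0
    allele_freq: float = 0.5
    n_per_group: int = 20
    noise_sd: float = 0.15
    ratio_noise_sd: float = 0.1
    replicate_count: int = 2
    groups: tuple[str, str] = ("high", "low")

    def __post_init__(self) -> None:
        for g, p in self.allele1_fraction.items():
            if not 0 < p < 1:
                raise ValueError(f"allele1_fraction[{g!r}] must lie in (0, 1)")
        if not 0 < self.allele_freq < 1:
            raise ValueError("allele_freq must lie in (0, 1)")
        if self.noise_sd < 0 or self.ratio_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")


def simulate_ase(
    scenario: ASEScenario,
    design: LadderDesign,
    seed: int,
    assay: str = "ASE_assay",
    breed: str = "Landrace",
) -> pd.DataFrame:
    """Simulate a two-allele frequency table for heterozygous samples.

    Per point the total cDNA frequency follows the usual titration model;
    it is split between alleles by the (noisy) per-point allele-1 ratio.
    Rows with ``allele`` in {"allele1", "allele2", "competitor"} sum to 1
    exactly at every (sample, point, replicate).
    """
    rng = np.random.default_rng([_STREAM_ASE, seed])
    conc = make_ladder(design)
    reps = scenario.replicate_count
    frames = []
    for g in scenario.groups:
        p = scenario.allele1_fraction[g]
        for i in range(scenario.n_per_group):
            sid = f"{breed[:1]}_{g}_het{i:03d}"
            y = (scenario.baseline_log10_conc - np.log10(conc))[:, None] + rng.normal(
                0.0, scenario.noise_sd, size=(len(conc), reps)
            )
            total = inv_logit10(y)
            r = inv_logit10(
                logit10(p) + rng.normal(0.0, scenario.ratio_noise_sd, size=(len(conc), reps))
            )
            f1, f2 = total * r, total * (1.0 - r)
            comp = 1.0 - total
            for name, arr in (("allele1", f1), ("allele2", f2), ("competitor", comp)):
                idx = pd.MultiIndex.from_product(
                    [range(len(conc)), range(1, reps + 1)],
                    names=["point_index", "replicate"],
                )
                df = pd.DataFrame({"frequency": arr.ravel()}, index=idx).reset_index()
                df["sample_id"] = sid
                df["group"] = g
                df["allele"] = name
                frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out["assay"] = assay
    out["breed"] = breed
    out["competitor_conc_M"] = conc[out["point_index"].to_numpy()]
    cols = [
        "sample_id", "breed", "group", "assay", "point_index",
        "competitor_conc_M", "replicate", "allele", "frequency",
    ]
    return out[cols]


def simulate_genotypes(
    n: int,
    snp_alleles: Mapping[str, tuple[str, str]],
    allele_freq: Mapping[str, float],
    seed: int,
    sample_ids: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Draw biallelic genotypes under Hardy-Weinberg equilibrium.

    ``snp_alleles`` maps SNP id -> (allele1, allele2); ``allele_freq``
    maps SNP id -> frequency of allele1.  Genotypes are unordered
    two-character strings (e.g. "GT").
    """
    rng = np.random.default_rng([_STREAM_GENOTYPE, seed])
    if sample_ids is None:
        sample_ids = [f"animal_{i:05d}" for i in range(n)]
    rows = []
    for snp, (a1, a2) in snp_alleles.items():
        p = allele_freq[snp]
        if not 0 <= p <= 1:
            raise ValueError(f"allele frequency for {snp} outside [0, 1]")
        copies = rng.binomial(2, p, size=n)  # copies of allele1
        geno = np.where(copies == 2, a1 + a1, np.where(copies == 1, a1 + a2, a2 + a2))
        rows.append(pd.DataFrame({"sample_id": sample_ids, "snp_id": snp, "genotype": geno}))
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class PhenotypeScenario:
    """Generative model for androstenone phenotypes.

    ``ln(androstenone)`` is the sum of an intercept (``location``), a sire
    effect, a herd-year-season (hys) batch effect, a slope on centred
    bulbo-urethral gland length, an additive SNP genotype effect (per copy
    of allele 2), and Gaussian residual noise of SD ``scale``.  The default
    location/scale (ln 1.17, 0.79) put the median and skew in the range
    observed for Landrace boars (population mean 1.17 µg/g, SD 1.10).
    ``extreme_fraction`` is the share of animals selected *per tail* when
    labelling extreme high/low androstenone groups (6% in Landrace, 9% in
    Duroc in the source design).
    """

    breed: str = "Landrace"
    location: float = math.log(1.17)
    scale: float = 0.79
    n_sires: int = 50
    n_hys: int = 20
    sire_sd: float = 0.15
    hys_sd: float = 0.15
    genotype_effect: float = 0.0
    bulbo_slope: float = 0.0
    bulbo_mean_cm: float = 12.0
    bulbo_sd_cm: float = 1.5
    extreme_fraction: float = 0.06

    def __post_init__(self) -> None:
        if not 0 < self.extreme_fraction < 0.5:
            raise ValueError("extreme_fraction must lie in (0, 0.5)")
        if self.scale < 0 or self.sire_sd < 0 or self.hys_sd < 0:
            raise ValueError("scale and effect SDs must be non-negative")
        if self.n_sires < 1 or self.n_hys < 1:
            raise ValueError("n_sires and n_hys must be >= 1")


def simulate_phenotypes(
    scenario: PhenotypeScenario,
    n: int,
    seed: int,
    genotypes: pd.DataFrame | None = None,
    snp_id: str | None = None,
) -> pd.DataFrame:
    """Simulate an androstenone phenotype table for ``n`` animals.

    Columns: animal id (``sample_id``), sire, hys, bulbo_cm, genotype (if a
    genotype table was supplied or generated), androstenone (µg/g), and
    ``extreme_group`` labelling the top/bottom ``extreme_fraction`` tails
    ("high"/"low", empty otherwise).

    The additive genotype effect counts copies of the *second* allele of
    the genotype string's allele pair (alphabetical order).
    """
    rng = np.random.default_rng([_STREAM_PHENOTYPE, seed])
    sample_ids = [f"animal_{i:05d}" for i in range(n)]
    sires = rng.integers(0, scenario.n_sires, size=n)
    hys = rng.integers(0, scenario.n_hys, size=n)
    sire_eff = rng.normal(0.0, scenario.sire_sd, size=scenario.n_sires)
    hys_eff = rng.normal(0.0, scenario.hys_sd, size=scenario.n_hys)
    bulbo = rng.normal(scenario.bulbo_mean_cm, scenario.bulbo_sd_cm, size=n)

    ln_y = (
        scenario.location
        + sire_eff[sires]
        + hys_eff[hys]
        + scenario.bulbo_slope * (bulbo - scenario.bulbo_mean_cm)
        + rng.normal(0.0, scenario.scale, size=n)
    )

    geno_col = None
    if genotypes is not None:
        if snp_id is None:
            snp_id = genotypes["snp_id"].iloc[0]
        sub = genotypes.loc[genotypes["snp_id"] == snp_id]
        gmap = dict(zip(sub["sample_id"], sub["genotype"]))
        geno_col = pd.Series(sample_ids).map(gmap)
        if scenario.genotype_effect != 0.0:
            alleles = sorted(set("".join(g for g in gmap.values())))
            minor = alleles[-1]
            copies = geno_col.fillna("").str.count(minor).to_numpy()
            ln_y = ln_y + scenario.genotype_effect * copies

    out = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "breed": scenario.breed,
            "sire": [f"sire_{s:03d}" for s in sires],
            "hys": [f"hys_{h:03d}" for h in hys],
            "bulbo_cm": bulbo,
            "androstenone": np.exp(ln_y),
        }
    )
    if geno_col is not None:
        out["genotype"] = geno_col
    k = int(round(scenario.extreme_fraction * n))
    order = out["androstenone"].to_numpy().argsort()
    labels = np.array([""] * n, dtype=object)
    if k > 0:
        labels[order[:k]] = "low"
        labels[order[-k:]] = "high"
    out["extreme_group"] = labels
    return out


# ---------------------------------------------------------------------------
# Presets: the 17-assay differential-expression panel plus the HPRT
# reference.  True log10 fold changes mirror the published point estimates
# for each breed so simulations exercise realistic effect sizes; baseline
# transcript concentrations are synthetic choices spread over the ladder's
# informative range.
# ---------------------------------------------------------------------------

LANDRACE_LOG10_FC: dict[str, float] = {
    "AKR1C4": 0.42, "CYB5A_-8(5'UTR)": 0.42, "CYB5A_iso1-2": 0.37,
    "CYP11A1": 0.50, "CYP17A1": 0.46, "CYP19A2": -0.10, "CYP21_exon9": -0.91,
    "DHRS4": 0.41, "FTL": 0.35, "HSD3B_exon2": 0.06, "HSD3B_5'UTR": -0.10,
    "HSD17B4": 0.34, "NCOA4": 0.11, "PGRMC1": 0.08, "SMPD1": 0.04,
    "STAR": 1.13, "SULT2A1": 0.48,
}

DUROC_LOG10_FC: dict[str, float] = {
    "AKR1C4": 0.21, "CYB5A_-8(5'UTR)": 0.31, "CYB5A_iso1-2": 0.19,
    "CYP11A1": 0.37, "CYP17A1": 0.38, "CYP19A2": -0.22, "CYP21_exon8": -0.04,
    "CYP21_exon9": 0.01, "DHRS4": 0.33, "FTL": 0.27, "HSD3B_exon2": -0.11,
    "HSD3B_5'UTR": 0.02, "HSD17B4": 0.20, "NCOA4": 0.18, "PGRMC1": 0.21,
    "SMPD1": 0.03, "STAR": 0.68, "SULT2A1": 0.32,
}

HOUSEKEEPING_ASSAY = "HPRT"


def default_baselines(assays: Sequence[str], low: float = -17.0, high: float = -13.0) -> dict[str, float]:
    """Deterministic synthetic baseline log10 concentrations for a panel.

    Spreads assays evenly over [low, high] so every equivalence point sits
    inside the default ladder's range (log10 conc -18.85 .. -10.39).
    """
    assays = list(assays)
    if len(assays) == 1:
        return {assays[0]: (low + high) / 2.0}
    grid = np.linspace(low, high, len(assays))
    return {a: float(v) for a, v in zip(assays, grid)}


def panel_scenario(
    breed: str = "Landrace",
    n_per_group: int = 48,
    noise_sd: float = 0.15,
    **kwargs,
) -> ExpressionScenario:
    """ExpressionScenario preset for the study panel of one breed."""
    fc = dict(LANDRACE_LOG10_FC if breed == "Landrace" else DUROC_LOG10_FC)
    fc[HOUSEKEEPING_ASSAY] = 0.0
    return ExpressionScenario(
        true_log10_fc=fc,
        baseline_log10_conc=default_baselines(fc),
        housekeeping=HOUSEKEEPING_ASSAY,
        n_per_group=n_per_group,
        noise_sd=noise_sd,
        **kwargs,
    )
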
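"""Table formats, panel configuration, and the pipeline driver.

The canonical interchange format is long/tidy TSV (CSV accepted): one row
per sample x assay x titration point x replicate, since replicate- and
point-level structure does not fit wide matrices.  Configuration is YAML;
a run manifest (JSON) records the configuration hash, seed and software
versions so any result file can be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import (
    ASEScenario,
    ExpressionScenario,
    LadderDesign,
    DUROC_LOG10_FC,
    HOUSEKEEPING_ASSAY,
    LANDRACE_LOG10_FC,
    default_baselines,
    simulate_ase,
    simulate_expression,
    simulate_genotypes,
    simulate_phenotypes,
    PhenotypeScenario,
)

logger = logging.getLogger("rcqge")

__all__ = [
    "SchemaError",
    "TableValidationError",
    "read_frequency_table",
    "write_table",
    "AssaySpec",
    "SimulationOptions",
    "PanelConfig",
    "RunManifest",
    "run_pipeline",
]


class SchemaError(ValueError):
    """Required columns are missing from an input table."""


class TableValidationError(ValueError):
    """Rows of an input table violate the schema; carries line numbers."""

    def __init__(self, message: str, lines: list[int]):
        super().__init__(message)
        self.lines = lines


REQUIRED_FREQ_COLUMNS = [
    "sample_id", "group", "assay", "point_index", "competitor_conc_M",
    "frequency",
]
OPTIONAL_FREQ_COLUMNS = ["breed", "replicate", "allele"]


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_frequency_table(path) -> pd.DataFrame:
    """Read and validate a long-format peak-area frequency table.

    Accepts TSV (default) or CSV by extension.  Scientific-notation
    concentrations parse as floats.  Frequencies must be in [0, 1] or
    empty (no signal); concentrations must be positive.  Violations are
    reported with 1-based file line numbers (header is line 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"frequency table not found: {path}")
    df = pd.read_csv(path, sep=_sep_for(path))
    missing = [c for c in REQUIRED_FREQ_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing required columns {missing}; expected "
            f"{REQUIRED_FREQ_COLUMNS} (+ optional {OPTIONAL_FREQ_COLUMNS})"
        )
    freq = pd.to_numeric(df["frequency"], errors="coerce")
    conc = pd.to_numeric(df["competitor_conc_M"], errors="coerce")
    bad_freq = df["frequency"].notna() & (freq.isna() | (freq < 0) | (freq > 1))
    bad_conc = conc.isna() | (conc <= 0)
    bad = bad_freq | bad_conc
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]  # +1 header, +1 1-based
        raise TableValidationError(
            f"{path}: {bad.sum()} invalid rows (frequency outside [0,1] or "
            f"non-positive concentration) at lines {lines[:20]}",
            lines,
        )
    df["frequency"] = freq
    df["competitor_conc_M"] = conc
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a table as TSV (or CSV by extension), never the index."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=_sep_for(path), index=False)
    return path


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

ASSAY_TYPES = ("expression", "allele_specific", "isoform")


@dataclass(frozen=True)
class AssaySpec:
    id: str
    type: str = "expression"
    housekeeping: bool = False

    def __post_init__(self) -> None:
        if self.type not in ASSAY_TYPES:
            raise ValueError(f"assay {self.id!r}: unknown type {self.type!r}")


@dataclass(frozen=True)
class SimulationOptions:
    """Generator settings used by the ``simulate`` stage.

    Defaults mirror the study design: 48 animals per extreme-androstenone
    group and breed, 2 printing replicates per point, and — for the
    association stage — about a thousand phenotyped animals per breed
    with a rare second allele, a per-copy effect of -0.30 on the ln
    scale (the size of the published heterozygote contrast), 50 sires and
    20 herd-year-season batches.
    """

    n_per_group: int = 48
    noise_sd: float = 0.15
    replicate_count: int = 2
    dropout_rate: float = 0.0
    sample_loading_sd: float = 0.0
    true_log10_fc: dict | None = None
    baseline_log10_conc: dict | None = None
    ase_allele1_fraction: dict | None = None
    assoc_n_animals: int = 1000
    assoc_allele_freq: float = 0.95
    assoc_genotype_effect: float = -0.30
    assoc_snp_id: str = "CYB5A_-8(5'UTR)"
    assoc_snp_alleles: tuple[str, str] = ("G", "T")


@dataclass(frozen=True)
class PanelConfig:
    """Everything the pipeline needs: panel layout plus analysis options."""

    assays: tuple[AssaySpec, ...]
    breeds: tuple[str, ...] = ("Landrace",)
    groups: tuple[str, str] = ("high", "low")
    ladder: LadderDesign = field(default_factory=LadderDesign)
    degree: int = 1
    bootstrap: int = 4000
    alpha: float = 0.05
    seed: int = 0
    simulation: SimulationOptions = field(default_factory=SimulationOptions)

    def __post_init__(self) -> None:
        ids = [a.id for a in self.assays]
        if len(set(ids)) != len(ids):
            raise ValueError("assay ids must be unique")
        hk = [a.id for a in self.assays if a.housekeeping]
        if len(hk) != 1:
            raise ValueError(f"exactly one housekeeping assay required, got {hk}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")

    @property
    def housekeeping(self) -> str:
        return next(a.id for a in self.assays if a.housekeeping)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PanelConfig":
        d = dict(d)
        d["assays"] = tuple(
            a if isinstance(a, AssaySpec) else AssaySpec(**a) for a in d["assays"]
        )
        if "ladder" in d and not isinstance(d["ladder"], LadderDesign):
            d["ladder"] = LadderDesign(**d["ladder"])
        if "simulation" in d and not isinstance(d["simulation"], SimulationOptions):
            sim = dict(d["simulation"])
            if "assoc_snp_alleles" in sim:
                sim["assoc_snp_alleles"] = tuple(sim["assoc_snp_alleles"])
            d["simulation"] = SimulationOptions(**sim)
        for key in ("breeds", "groups"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PanelConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh, sort_keys=False)
        return path

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()


def default_panel_config(breeds=("Landrace",), **overrides) -> PanelConfig:
    """The study-style panel: 17 expression assays + HPRT + two-allele assays."""
    fc_ids = sorted(set(LANDRACE_LOG10_FC) | set(DUROC_LOG10_FC))
    assays = [AssaySpec(HOUSEKEEPING_ASSAY, "expression", housekeeping=True)]
    assays += [AssaySpec(a, "isoform" if "iso" in a else "expression") for a in fc_ids]
    assays += [AssaySpec("HSD3B_exon2_ASE", "allele_specific")]
    return PanelConfig(assays=tuple(assays), breeds=tuple(breeds), **overrides)


# ---------------------------------------------------------------------------
# pipeline driver
# ---------------------------------------------------------------------------


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    versions: dict
    stages: dict
    started: str = ""
    finished: str = ""

    def to_json(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
        return path


STAGES = ("simulate", "qge", "ase", "assoc")


def _expression_scenario(config: PanelConfig, breed: str) -> ExpressionScenario:
    sim = config.simulation
    expr_ids = [a.id for a in config.assays if a.type in ("expression", "isoform")]
    preset = LANDRACE_LOG10_FC if breed != "Duroc" else DUROC_LOG10_FC
    fc = {a: 0.0 for a in expr_ids}
    fc.update({a: preset[a] for a in expr_ids if a in preset})
    if sim.true_log10_fc:
        fc.update({a: v for a, v in sim.true_log10_fc.items() if a in fc})
    fc[config.housekeeping] = 0.0
    baselines = sim.baseline_log10_conc or default_baselines(expr_ids)
    return ExpressionScenario(
        true_log10_fc=fc,
        baseline_log10_conc={a: baselines[a] for a in expr_ids},
        housekeeping=config.housekeeping,
        n_per_group=sim.n_per_group,
        noise_sd=sim.noise_sd,
        replicate_count=sim.replicate_count,
        dropout_rate=sim.dropout_rate,
        sample_loading_sd=sim.sample_loading_sd,
        groups=config.groups,
    )


def run_pipeline(
    config: PanelConfig,
    stages=STAGES,
    out_dir=".",
    seed: int | None = None,
) -> RunManifest:
    """Run the requested stages in dependency order and write a manifest.

    ``simulate`` writes frequency/genotype/phenotype tables; ``qge``,
    ``ase`` and ``assoc`` read them (from ``out_dir``) and write result
    TSVs.  A stage whose inputs are missing raises a FileNotFoundError
    naming the file and the stage that produces it.  Identical config and
    seed reproduce identical result files.
    """
    from . import ase as ase_mod
    from . import association as assoc_mod
    from .preprocess import preprocess
    from .titration import run_panel

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    stages = [s for s in STAGES if s in stages]
    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=seed,
        versions={"rcqge": __version__, "numpy": np.__version__, "pandas": pd.__version__},
        stages={},
        started=datetime.now(timezone.utc).isoformat(),
    )

    paths = {
        "freq": out / "frequency_table.tsv",
        "ase": out / "ase_frequency_table.tsv",
        "geno": out / "genotypes.csv",
        "pheno": out / "phenotypes.csv",
        "qge_out": out / "qge_results.tsv",
        "ase_out": out / "ase_results.tsv",
        "assoc_out": out / "assoc_results.tsv",
        "qc_out": out / "qc_report.tsv",
    }

    if "simulate" in stages:
        sim = config.simulation
        frames, ase_frames = [], []
        for i, breed in enumerate(config.breeds):
            scen = _expression_scenario(config, breed)
            frames.append(simulate_expression(scen, config.ladder, seed + i, breed=breed))
            for a in config.assays:
                if a.type == "allele_specific":
                    frac = (sim.ase_allele1_fraction or {}).get(a.id, 0.5)
                    ase_scen = ASEScenario(
                        allele1_fraction={g: frac for g in config.groups},
                        n_per_group=min(sim.n_per_group, 20),
                        noise_sd=sim.noise_sd,
                        groups=config.groups,
                    )
                    ase_frames.append(
                        simulate_ase(ase_scen, config.ladder, seed + i, assay=a.id, breed=breed)
                    )
        write_table(pd.concat(frames, ignore_index=True), paths["freq"])
        manifest.stages["simulate"] = {"frequency_table": str(paths["freq"])}
        if ase_frames:
            write_table(pd.concat(ase_frames, ignore_index=True), paths["ase"])
            manifest.stages["simulate"]["ase_frequency_table"] = str(paths["ase"])
        geno_frames, pheno_frames = [], []
        for i, breed in enumerate(config.breeds):
            geno = simulate_genotypes(
                sim.assoc_n_animals,
                {sim.assoc_snp_id: sim.assoc_snp_alleles},
                {sim.assoc_snp_id: sim.assoc_allele_freq},
                seed + i,
            )
            pheno = simulate_phenotypes(
                PhenotypeScenario(breed=breed, genotype_effect=sim.assoc_genotype_effect),
                sim.assoc_n_animals,
                seed + i,
                genotypes=geno,
                snp_id=sim.assoc_snp_id,
            )
            geno["breed"] = breed
            geno["sample_id"] = breed[:1] + "_" + geno["sample_id"]
            pheno["sample_id"] = breed[:1] + "_" + pheno["sample_id"]
            geno_frames.append(geno)
            pheno_frames.append(pheno)
        write_table(pd.concat(geno_frames, ignore_index=True), paths["geno"])
        write_table(pd.concat(pheno_frames, ignore_index=True), paths["pheno"])
        manifest.stages["simulate"]["genotypes"] = str(paths["geno"])
        manifest.stages["simulate"]["phenotypes"] = str(paths["pheno"])
        logger.info("simulate: wrote %s", sorted(manifest.stages["simulate"]))

    if "qge" in stages:
        if not paths["freq"].exists():
            raise FileNotFoundError(
                f"{paths['freq']} missing: run the 'simulate' stage first or "
                "point --out-dir at a directory containing frequency_table.tsv"
            )
        raw = read_frequency_table(paths["freq"])
        clean, qc = preprocess(raw)
        write_table(qc, paths["qc_out"])
        logger.info("qge: %d points dropped in preprocessing", len(qc))
        results = run_panel(
            clean, config.housekeeping, B=config.bootstrap, seed=seed,
            alpha=config.alpha, groups=config.groups, degree=config.degree,
        )
        write_table(results, paths["qge_out"])
        manifest.stages["qge"] = {"results": str(paths["qge_out"]), "qc": str(paths["qc_out"])}

    if "ase" in stages:
        if not paths["ase"].exists():
            raise FileNotFoundError(
                f"{paths['ase']} missing: run 'simulate' with an allele_specific "
                "assay in the panel, or provide the table"
            )
        two = read_frequency_table(paths["ase"])
        rows = []
        for (assay, breed), sub in two.groupby(["assay", "breed"]):
            ratios = ase_mod.allele_ratios(sub)
            res = ase_mod.ase_model(ratios, assay=assay, breed=breed)
            for g in sorted(res.group_mean_ratio):
                rows.append({
                    "assay": assay, "breed": breed, "group": g,
                    "mean_ratio": res.group_mean_ratio[g], "n_het": res.n_het[g],
                    "allele_p": res.allele_p, "treatment_p": res.treatment_p,
                    "interaction_p": res.interaction_p,
                })
        write_table(pd.DataFrame(rows), paths["ase_out"])
        manifest.stages["ase"] = {"results": str(paths["ase_out"])}

    if "assoc" in stages:
        for key, stage in (("geno", "simulate"), ("pheno", "simulate")):
            if not paths[key].exists():
                raise FileNotFoundError(
                    f"{paths[key]} missing: run the {stage!r} stage or provide the file"
                )
        geno = pd.read_csv(paths["geno"])
        pheno = pd.read_csv(paths["pheno"])
        rows = []
        for breed in config.breeds:
            psub = pheno[pheno["breed"] == breed]
            gsub = geno[geno["breed"] == breed] if "breed" in geno.columns else geno
            for snp in sorted(gsub["snp_id"].unique()):
                res = assoc_mod.fit_association(psub, gsub, snp, breed=breed)
                for g in sorted(res.genotype_n):
                    rows.append({
                        "snp_id": snp, "breed": breed, "genotype": g,
                        "n": res.genotype_n[g], "lsmean": res.lsmeans[g],
                        "lsmean_se": res.lsmeans_se[g], "f_p": res.f_p,
                        "hwe_chi2": res.hwe_chi2, "hwe_p": res.hwe_p,
                    })
        write_table(pd.DataFrame(rows), paths["assoc_out"])
        manifest.stages["assoc"] = {"results": str(paths["assoc_out"])}

    manifest.finished = datetime.now(timezone.utc).isoformat()
    manifest.to_json(out / "manifest.json")
    return manifest
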
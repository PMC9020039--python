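"""One-command orchestration: simulate -> QC -> EWAS -> call -> report.

A run is driven by a :class:`RunConfig` (flat YAML on disk, every field
overridable from the CLI) and produces a run directory containing the
simulated or loaded inputs, PCA scores, the EWAS table, the epi-Manhattan
export, per-island epigram summaries, epimutation calls (TSV and BED),
and a JSON run manifest with the package version, seed, and a hash of
all parameters.  Identical config and seed give identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .calling import calls_to_frame, scan_genome
from .ewas import manhattan_table, pca_qc, run_ewas
from .io import (
    ValidationError,
    map_probes_to_islands,
    read_beta_matrix,
    read_islands,
    read_manifest,
    write_beta_matrix,
    write_islands,
    write_manifest,
)
from .simulate import IslandSpec, SimulationConfig, simulate_methylome

__all__ = ["RunConfig", "run_full_pipeline"]

log = logging.getLogger("epiewas")


@dataclass
class RunConfig:
    """All pipeline parameters in one auditable place."""

    outdir: str = "epiewas_run"
    seed: int = 0
    # input files; when beta_path is empty the pipeline simulates
    beta_path: str = ""
    meta_path: str = ""
    manifest_path: str = ""
    islands_path: str = ""
    # simulation block (used only when simulating)
    n_cases: int = 17
    n_controls: int = 350
    n_probes: int = 1000
    n_islands: int = 3
    island_probes: int = 7
    flank_probes: int = 4
    n_epimutated: int = 1
    case_effect: float = 0.45
    control_level: float = 0.03
    background: str = "mixture"
    noise_concentration: float = 50.0
    sex_effect_probes: int = 20
    n_chromosomes: int = 1
    # analysis parameters
    flank_bp: int = 250
    t_test: str = "welch"
    radius: int = 3
    alpha: float = 0.05
    low_threshold: float = 0.2
    high_threshold: float = 0.6
    min_fraction_concordant: float = 1.0
    min_probes: int = 3
    require_significant: int = 1
    highlight_threshold: float = 1e-100
    pca_components: int = 10

    def validate(self) -> None:
        if not 0 < self.low_threshold < self.high_threshold < 1:
            raise ValidationError(
                "classification thresholds must satisfy 0 < low < high < 1"
            )
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0, 1)")
        if self.radius < 0 or self.flank_bp < 0:
            raise ValidationError("radius and flank_bp must be >= 0")
        if self.t_test not in ("welch", "student"):
            raise ValidationError(f"unknown t-test variant {self.t_test!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def parameters(self) -> dict:
        """All analysis/simulation parameters; the output location is a
        run property, not a parameter, and stays out of the hash."""
        d = self.to_dict()
        d.pop("outdir")
        return d

    def parameter_hash(self) -> str:
        blob = json.dumps(self.parameters(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def simulation_config(self) -> SimulationConfig:
        islands = tuple(
            IslandSpec(f"CpG:sim{i + 1}", self.island_probes, self.flank_probes)
            for i in range(self.n_islands)
        )
        return SimulationConfig(
            n_cases=self.n_cases,
            n_controls=self.n_controls,
            n_probes=self.n_probes,
            islands=islands,
            epimutated_island_ids=tuple(
                f"CpG:sim{i + 1}" for i in range(self.n_epimutated)
            ),
            case_effect=self.case_effect,
            control_level=self.control_level,
            background=self.background,
            noise_concentration=self.noise_concentration,
            sex_effect_probes=self.sex_effect_probes,
            n_chromosomes=self.n_chromosomes,
            seed=self.seed,
        )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def run_full_pipeline(config: RunConfig) -> Path:
    """Execute every stage and return the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_stages(config, outdir)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_stages(config: RunConfig, outdir: Path) -> Path:
    stage = "inputs"
    try:
        truth = None
        if config.beta_path:
            beta = read_beta_matrix(config.beta_path, config.meta_path)
            manifest = read_manifest(config.manifest_path)
            islands = read_islands(config.islands_path)
            manifest = map_probes_to_islands(manifest, islands, config.flank_bp)
        else:
            beta, manifest, islands, truth = simulate_methylome(
                config.simulation_config()
            )
            write_beta_matrix(beta, outdir / "beta.tsv", outdir / "samples.tsv")
            write_manifest(manifest, outdir / "manifest.tsv")
            write_islands(islands, outdir / "islands.bed")
            _write_tsv(truth.islands, outdir / "truth_islands.tsv")
            _write_tsv(truth.probes, outdir / "truth_probes.tsv")
        log.info(
            "inputs: %d probes, %d cases, %d controls, %d islands",
            beta.n_probes, len(beta.case_ids), len(beta.control_ids), len(islands),
        )

        stage = "qc-pca"
        pca = pca_qc(beta, k=config.pca_components)
        scores = pca.scores.copy()
        scores.insert(0, "sample_id", scores.index)
        _write_tsv(scores, outdir / "pca_scores.tsv")

        stage = "ewas"
        ewas = run_ewas(
            beta, manifest, variant=config.t_test, radius=config.radius
        )
        _write_tsv(ewas, outdir / "ewas.tsv")
        _write_tsv(
            manhattan_table(ewas, config.highlight_threshold),
            outdir / "manhattan.tsv",
        )
        log.info("ewas: %d probes tested", int(ewas["tested"].sum()))

        stage = "epigrams"
        island_rows = ewas[ewas["island_relation"].isin(["in_island", "flank"])]
        epigram = island_rows[
            [
                "island_id",
                "probe_id",
                "position",
                "island_relation",
                "mean_beta_cases",
                "mean_beta_controls",
                "delta_beta",
                "p_bonferroni",
            ]
        ].reset_index(drop=True)
        _write_tsv(epigram, outdir / "epigrams.tsv")

        stage = "call-epimutations"
        calls = scan_genome(
            ewas,
            islands,
            alpha=config.alpha,
            min_fraction_concordant=config.min_fraction_concordant,
            min_probes=config.min_probes,
            require_significant=config.require_significant,
            low=config.low_threshold,
            high=config.high_threshold,
        )
        calls_df = calls_to_frame(calls)
        _write_tsv(calls_df, outdir / "epimutation_calls.tsv")
        hit_ids = calls_df.loc[calls_df["verdict"] == "epimutated", "island_id"]
        hits = islands[islands["island_id"].isin(hit_ids)]
        write_islands(hits, outdir / "epimutated_islands.bed")
        log.info("calls: %d islands, %d epimutated", len(calls_df), len(hits))

        stage = "manifest"
        manifest_json = {
            "tool": "epiewas",
            "version": __version__,
            "seed": config.seed,
            "parameter_hash": config.parameter_hash(),
            "parameters": config.parameters(),
            "n_probes": int(beta.n_probes),
            "n_tested": int(ewas["tested"].sum()),
            "n_islands_called": int(len(calls_df)),
            "n_epimutated": int((calls_df["verdict"] == "epimutated").sum()),
        }
        (outdir / "run_manifest.json").write_text(
            json.dumps(manifest_json, indent=2, sort_keys=True) + "\n"
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return outdir
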
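"""Synthetic methylation-array and alignment-record generators.

The methylome generator emulates the statistical structure of a
case-control epimutation EWAS: a small case series (default 17) against
a large control cohort (default 350), beta values in [0, 1] drawn from a
mean/concentration-parameterised Beta family, a handful of CpG islands
with optional flanking probes, and one or more *epimutated* islands
whose probes are unmethylated in controls (mean beta ~0.03) and
hemimethylated in cases (mean beta ~0.45).  Open-sea background probes
share one distribution across groups; an optional set of probes differs
by sex only, which makes sample sex recoverable by PCA as in real
methylome data.

Every generator is deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import BetaMatrix, ValidationError, map_probes_to_islands

__all__ = [
    "IslandSpec",
    "SimulationConfig",
    "TruthTable",
    "simulate_methylome",
    "simulate_alignment_records",
]

#: canonical mean beta for each background methylation state
STATE_MEANS: dict[str, float] = {
    "unmethylated": 0.05,
    "hemimethylated": 0.45,
    "methylated": 0.85,
}

#: default open-sea composition: most array probes are at one of the two
#: extremes, with a minority at intermediate levels
DEFAULT_BACKGROUND: dict[str, float] = {
    "unmethylated": 0.6,
    "methylated": 0.3,
    "hemimethylated": 0.1,
}

#: mean beta by sex at sex-differential probes (X-inactivation-like)
SEX_MEANS = {"F": 0.70, "M": 0.20}

_ISLAND_PROBE_SPACING = 50  # bp between consecutive island probes
_FLANK_PROBE_SPACING = 40  # bp between flank probes, past the island edge
_ISLAND_GAP = 50_000  # bp between consecutive islands
_OPEN_SEA_SPACING = 10_000  # bp between open-sea probes


@dataclass(frozen=True)
class IslandSpec:
    """Probe layout of one simulated CpG island."""

    island_id: str
    n_probes: int = 7
    n_flank_probes: int = 0


@dataclass
class SimulationConfig:
    """Study conditions for :func:`simulate_methylome`.

    Defaults copy the 17-case vs 350-control design so that default
    simulations are power-comparable with the study they emulate; the
    epimutation effect (cases mean 0.45, controls 0.03) matches the
    reported hemimethylated-vs-unmethylated island signature.
    """

    n_cases: int = 17
    n_controls: int = 350
    n_probes: int = 1000
    islands: Sequence[IslandSpec] = field(
        default_factory=lambda: (IslandSpec("CpG:sim1", 7, 4),)
    )
    epimutated_island_ids: Sequence[str] = ("CpG:sim1",)
    case_effect: float = 0.45
    control_level: float = 0.03
    background: str | Mapping[str, float] = "mixture"
    noise_concentration: float = 50.0
    sex_effect_probes: int = 0
    n_chromosomes: int = 1
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_cases, self.n_controls, self.n_probes) <= 0:
            raise ValidationError("sample and probe counts must be positive")
        if not (0 <= self.case_effect <= 1 and 0 <= self.control_level <= 1):
            raise ValidationError("case_effect and control_level must lie in [0, 1]")
        if self.noise_concentration <= 0:
            raise ValidationError("noise_concentration must be positive")
        ids = [isl.island_id for isl in self.islands]
        if len(set(ids)) != len(ids):
            raise ValidationError("island ids must be unique")
        unknown = set(self.epimutated_island_ids) - set(ids)
        if unknown:
            raise ValidationError(
                f"epimutated island(s) not in layout: {sorted(unknown)}"
            )
        n_island = sum(i.n_probes + i.n_flank_probes for i in self.islands)
        if n_island > self.n_probes:
            raise ValidationError(
                f"islands require {n_island} probes but n_probes={self.n_probes}"
            )
        if self.sex_effect_probes > self.n_probes - n_island:
            raise ValidationError("not enough open-sea probes for sex_effect_probes")

    def background_fractions(self) -> dict[str, float]:
        if isinstance(self.background, str):
            if self.background == "mixture":
                return dict(DEFAULT_BACKGROUND)
            if self.background in STATE_MEANS:
                return {self.background: 1.0}
            raise ValidationError(f"unknown background state {self.background!r}")
        frac = dict(self.background)
        bad = set(frac) - set(STATE_MEANS)
        if bad:
            raise ValidationError(f"unknown background state(s) {sorted(bad)}")
        total = sum(frac.values())
        if not np.isclose(total, 1.0):
            raise ValidationError("background fractions must sum to 1")
        return frac


@dataclass
class TruthTable:
    """Ground truth accompanying a simulated methylome.

    ``islands`` has columns (island_id, epimutated); ``probes`` has
    columns (probe_id, island_id, case_state, control_state, case_mean,
    control_mean, sex_effect).
    """

    islands: pd.DataFrame
    probes: pd.DataFrame


def _beta_draw(rng: np.random.Generator, mean: np.ndarray, kappa: float) -> np.ndarray:
    """Draw from Beta(mean * kappa, (1 - mean) * kappa), elementwise."""
    mean = np.asarray(mean, float)
    if np.any(mean <= 0) or np.any(mean >= 1):
        raise ValidationError(
            "beta-family mean must lie strictly inside (0, 1); "
            "a point mass at 0 or 1 has no valid (mean, concentration) pair"
        )
    return rng.beta(mean * kappa, (1.0 - mean) * kappa)


def _state_of_mean(mean: float) -> str:
    # three-state label of a *target* mean, for truth bookkeeping
    if mean < 0.2:
        return "fully_unmethylated"
    if mean <= 0.6:
        return "hemimethylated"
    return "fully_methylated"


def simulate_methylome(
    config: SimulationConfig,
) -> tuple[BetaMatrix, pd.DataFrame, pd.DataFrame, TruthTable]:
    """Generate a (BetaMatrix, manifest, islands, truth) quadruple.

    Probe layout: islands are laid out round-robin across
    ``n_chromosomes`` with probes every 50 bp, flank probes every 40 bp
    past the 3' island edge, and open-sea probes every 10 kb after the
    last island; positions are strictly increasing within a chromosome.
    Epimutated-island probes (island and flank alike) have group means
    (case_effect, control_level); non-epimutated islands are unmethylated
    in both groups; open-sea probes draw a background state and share it
    across groups.  Sex-differential probes take sex-specific means
    independent of group.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    kappa = config.noise_concentration

    chroms = [str(c + 1) for c in range(config.n_chromosomes)]
    cursor = {c: 10_000 for c in chroms}

    probe_rows: list[tuple[str, str, int]] = []  # (probe_id, chromosome, position)
    island_rows: list[tuple[str, str, int, int]] = []
    probe_island: list[str] = []
    n_probe = 0

    def add_probe(chrom: str, pos: int, island: str) -> None:
        nonlocal n_probe
        probe_rows.append((f"cg{n_probe:08d}", chrom, pos))
        probe_island.append(island)
        n_probe += 1

    for k, isl in enumerate(config.islands):
        chrom = chroms[k % len(chroms)]
        start = cursor[chrom]
        for j in range(isl.n_probes):
            add_probe(chrom, start + j * _ISLAND_PROBE_SPACING, isl.island_id)
        end = start + (isl.n_probes - 1) * _ISLAND_PROBE_SPACING
        island_rows.append((isl.island_id, chrom, start, end))
        for j in range(1, isl.n_flank_probes + 1):
            add_probe(chrom, end + j * _FLANK_PROBE_SPACING, isl.island_id)
        cursor[chrom] = end + isl.n_flank_probes * _FLANK_PROBE_SPACING + _ISLAND_GAP

    n_open = config.n_probes - n_probe
    for j in range(n_open):
        chrom = chroms[j % len(chroms)]
        add_probe(chrom, cursor[chrom], "")
        cursor[chrom] += _OPEN_SEA_SPACING

    manifest = pd.DataFrame(probe_rows, columns=["probe_id", "chromosome", "position"])
    islands = pd.DataFrame(
        island_rows, columns=["island_id", "chromosome", "start", "end"]
    )
    manifest = map_probes_to_islands(manifest, islands, flank_bp=250)

    # --- per-probe target means ------------------------------------------
    epimutated = set(config.epimutated_island_ids)
    probe_island_arr = np.array(probe_island, dtype=object)
    is_islandish = probe_island_arr != ""
    is_epi = np.isin(probe_island_arr, list(epimutated))

    case_mean = np.empty(config.n_probes)
    ctrl_mean = np.empty(config.n_probes)
    # non-epimutated islands: CpG-island promoters are unmethylated
    case_mean[is_islandish] = STATE_MEANS["unmethylated"]
    ctrl_mean[is_islandish] = STATE_MEANS["unmethylated"]
    case_mean[is_epi] = config.case_effect
    ctrl_mean[is_epi] = config.control_level

    frac = config.background_fractions()
    states = list(frac)
    open_idx = np.flatnonzero(~is_islandish)
    bg_states = rng.choice(states, size=len(open_idx), p=[frac[s] for s in states])
    bg_means = np.array([STATE_MEANS[s] for s in bg_states])
    case_mean[open_idx] = bg_means
    ctrl_mean[open_idx] = bg_means

    sex_idx = open_idx[: config.sex_effect_probes]
    is_sex = np.zeros(config.n_probes, bool)
    is_sex[sex_idx] = True

    # --- samples ----------------------------------------------------------
    n_samples = config.n_cases + config.n_controls
    sample_ids = [f"case{j:03d}" for j in range(config.n_cases)] + [
        f"ctrl{j:03d}" for j in range(config.n_controls)
    ]
    groups = ["case"] * config.n_cases + ["control"] * config.n_controls
    sexes = rng.choice(["F", "M"], size=n_samples)
    meta = pd.DataFrame({"group": groups, "sex": sexes}, index=pd.Index(sample_ids))
    meta.index.name = "sample_id"

    mean_mat = np.where(
        np.array([g == "case" for g in groups])[None, :],
        case_mean[:, None],
        ctrl_mean[:, None],
    )
    if len(sex_idx):
        sex_mean = np.array([SEX_MEANS[s] for s in sexes])
        mean_mat[sex_idx, :] = sex_mean[None, :]

    values = _beta_draw(rng, mean_mat, kappa)
    beta = BetaMatrix(
        pd.DataFrame(values, index=pd.Index(manifest["probe_id"], name="probe_id"),
                     columns=sample_ids),
        meta,
    )

    truth_islands = pd.DataFrame(
        {
            "island_id": islands["island_id"],
            "epimutated": islands["island_id"].isin(epimutated),
        }
    )
    truth_probes = pd.DataFrame(
        {
            "probe_id": manifest["probe_id"],
            "island_id": probe_island_arr,
            "case_state": [_state_of_mean(m) for m in case_mean],
            "control_state": [_state_of_mean(m) for m in ctrl_mean],
            "case_mean": case_mean,
            "control_mean": ctrl_mean,
            "sex_effect": is_sex,
        }
    )
    return beta, manifest, islands, TruthTable(truth_islands, truth_probes)


# ---------------------------------------------------------------------------
# Alignment-record fixtures


_GENES = ["TESK2", "CCDC163", "MMACHC", "PRDX1"]
_CRITERIA_CYCLE = ["i", "ii", "iii", "iv", "v"]


def _passing_record(rng: np.random.Generator, query: str, isoform_no: int) -> dict:
    gene = rng.choice(_GENES)
    length = int(rng.integers(301, 2000))
    return {
        "query_id": query,
        "subject_id": f"{gene}-{isoform_no:03d}",
        "subject_gene": gene,
        "subject_biotype": "protein_coding",
        "alignment_length": length,
        "subject_length": length,
        "mismatches": int(rng.integers(0, 4)),
        "gap_openings": int(rng.integers(0, 2)),
        "e_value": float(10.0 ** -rng.uniform(20, 180)),
        "bit_score": round(1.9 * length + rng.uniform(0, 10), 1),
    }


def simulate_alignment_records(
    n_transcripts: int, fraction_pass: float = 0.5, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate alignment records plus a truth assignment table.

    A ``fraction_pass`` share of queries receives a candidate satisfying
    all five assignment criteria (plus optional shorter decoys); the
    remaining queries cycle through single-criterion violations:

    * ``i``   wrong biotype (non-coding) on every candidate;
    * ``ii``  the highest-alignment-length candidate is a spurious hit
      (subject longer than the alignment) outranking a clean shorter
      one, so best-candidate selection picks a failing record;
    * ``iii`` subject length differs from alignment length, or the
      alignment is not longer than 300 nt;
    * ``iv``  4 mismatches;
    * ``v``   2 gap openings.

    The truth table has one row per query: (query_id, expected_gene —
    empty when no assignment should be made, violated_criterion).
    """
    if not 0 <= fraction_pass <= 1:
        raise ValidationError("fraction_pass must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_pass = round(fraction_pass * n_transcripts)
    records: list[dict] = []
    truth: list[tuple[str, str, str]] = []
    iso = 0

    for q in range(n_transcripts):
        query = f"TRINITY_DN{q:05d}_c0_g1_i1"
        iso += 1
        if q < n_pass:
            rec = _passing_record(rng, query, iso)
            records.append(rec)
            # occasional shorter decoy exercises best-candidate selection
            if rng.random() < 0.5:
                decoy = _passing_record(rng, query, iso + 500)
                decoy["alignment_length"] = rec["alignment_length"] - int(
                    rng.integers(1, 200)
                )
                decoy["subject_length"] = decoy["alignment_length"]
                records.append(decoy)
            truth.append((query, rec["subject_gene"], "none"))
            continue
        crit = _CRITERIA_CYCLE[(q - n_pass) % len(_CRITERIA_CYCLE)]
        rec = _passing_record(rng, query, iso)
        if crit == "i":
            rec["subject_biotype"] = "lncRNA"
            records.append(rec)
        elif crit == "ii":
            # clean shorter candidate is outranked by a longer spurious hit
            clean = _passing_record(rng, query, iso + 500)
            clean["alignment_length"] = min(clean["alignment_length"], 1500)
            clean["subject_length"] = clean["alignment_length"]
            rec["alignment_length"] = clean["alignment_length"] + int(
                rng.integers(50, 300)
            )
            rec["subject_length"] = rec["alignment_length"] + int(
                rng.integers(100, 400)
            )
            records.extend([rec, clean])
        elif crit == "iii":
            if rng.random() < 0.5:
                rec["subject_length"] = rec["alignment_length"] + int(
                    rng.integers(1, 300)
                )
            else:
                rec["alignment_length"] = int(rng.integers(50, 301))
                rec["subject_length"] = rec["alignment_length"]
        elif crit == "iv":
            rec["mismatches"] = 4
        elif crit == "v":
            rec["gap_openings"] = 2
        if crit != "ii":
            records.append(rec)
        truth.append((query, "", crit))

    records_df = pd.DataFrame(records)
    truth_df = pd.DataFrame(
        truth, columns=["query_id", "expected_gene", "violated_criterion"]
    )
    return records_df, truth_df
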
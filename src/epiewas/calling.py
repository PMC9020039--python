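"""Three-state methylation classification and island-level epimutation calls.

A beta value below 0.2 is *fully unmethylated*, above 0.6 *fully
methylated*, and anything in the closed band [0.2, 0.6] *hemimethylated*
(one methylated allele).  An island is called epimutated when its probes
(island plus flank) show the concordant switch — controls fully
unmethylated, cases hemimethylated or above — at a sufficient fraction
of probes, with at least one probe surviving Bonferroni correction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = [
    "MethylationState",
    "EpimutationCall",
    "classify_beta",
    "call_island",
    "scan_genome",
    "calls_to_frame",
]

LOW_THRESHOLD = 0.2
HIGH_THRESHOLD = 0.6


class MethylationState(enum.IntEnum):
    """Ordered three-state methylation level of a probe."""

    fully_unmethylated = 0
    hemimethylated = 1
    fully_methylated = 2

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def classify_beta(
    beta: float,
    low: float = LOW_THRESHOLD,
    high: float = HIGH_THRESHOLD,
) -> MethylationState:
    """Classify a beta value into the three methylation states.

    The boundaries are closed into the hemimethylated band: beta < low
    is fully unmethylated, low <= beta <= high hemimethylated, and
    beta > high fully methylated.
    """
    if not 0 < low < high < 1:
        raise ValidationError("thresholds must satisfy 0 < low < high < 1")
    b = float(beta)
    if not (0.0 <= b <= 1.0) or np.isnan(b):
        raise ValidationError(f"beta value {beta!r} outside [0, 1]")
    if b < low:
        return MethylationState.fully_unmethylated
    if b <= high:
        return MethylationState.hemimethylated
    return MethylationState.fully_methylated


def _classify_array(beta: np.ndarray, low: float, high: float) -> np.ndarray:
    out = np.where(
        beta < low, 0, np.where(beta <= high, 1, 2)
    )
    return out


@dataclass
class EpimutationCall:
    """Island-level verdict with per-probe concordance bookkeeping."""

    island_id: str
    n_probes_considered: int
    n_concordant: int
    n_significant: int
    case_state_summary: MethylationState | None
    control_state_summary: MethylationState | None
    verdict: str  # epimutated | not_epimutated | insufficient_probes
    min_p_nominal: float


def _modal_state(states: np.ndarray) -> MethylationState:
    vals, counts = np.unique(states, return_counts=True)
    # ties resolved to the lower (less methylated) state
    return MethylationState(int(vals[np.argmax(counts)]))


def call_island(
    rows: pd.DataFrame,
    alpha: float = 0.05,
    min_fraction_concordant: float = 1.0,
    min_probes: int = 3,
    require_significant: int = 1,
    low: float = LOW_THRESHOLD,
    high: float = HIGH_THRESHOLD,
) -> EpimutationCall:
    """Call one island from its EWAS rows (island plus flank probes).

    A probe is *concordant* when its control group mean is fully
    unmethylated and its case group mean is hemimethylated or fully
    methylated (a bi-allelic epimutation pushes beta above the high
    threshold, so both case states count).  The verdict is
    ``epimutated`` iff at least ``min_probes`` probes were considered,
    the concordant fraction reaches ``min_fraction_concordant``, and at
    least ``require_significant`` probes have Bonferroni P < ``alpha``;
    islands with fewer than ``min_probes`` probes are
    ``insufficient_probes``.
    """
    ids = set(rows["island_id"].astype(str))
    if len(ids) != 1:
        raise ValidationError(f"rows span multiple islands: {sorted(ids)}")
    bad = set(rows["island_relation"]) - {"in_island", "flank"}
    if bad:
        raise ValidationError(f"rows include non-island probes ({sorted(bad)})")
    island_id = ids.pop()

    rows = rows[rows["tested"].astype(bool)] if "tested" in rows else rows
    n = len(rows)
    if n < min_probes:
        return EpimutationCall(
            island_id, n, 0, 0, None, None, "insufficient_probes", float("nan")
        )

    case_states = _classify_array(
        rows["mean_beta_cases"].to_numpy(float), low, high
    )
    ctrl_states = _classify_array(
        rows["mean_beta_controls"].to_numpy(float), low, high
    )
    concordant = (ctrl_states == MethylationState.fully_unmethylated) & (
        case_states >= MethylationState.hemimethylated
    )
    significant = rows["p_bonferroni"].to_numpy(float) < alpha
    n_concordant = int(concordant.sum())
    n_significant = int(significant.sum())
    epimutated = (
        n_concordant / n >= min_fraction_concordant
        and n_significant >= require_significant
    )
    return EpimutationCall(
        island_id=island_id,
        n_probes_considered=n,
        n_concordant=n_concordant,
        n_significant=n_significant,
        case_state_summary=_modal_state(case_states),
        control_state_summary=_modal_state(ctrl_states),
        verdict="epimutated" if epimutated else "not_epimutated",
        min_p_nominal=float(np.nanmin(rows["p_nominal"].to_numpy(float))),
    )


def scan_genome(
    ewas: pd.DataFrame,
    islands: pd.DataFrame,
    alpha: float = 0.05,
    min_fraction_concordant: float = 1.0,
    min_probes: int = 3,
    require_significant: int = 1,
    low: float = LOW_THRESHOLD,
    high: float = HIGH_THRESHOLD,
) -> list[EpimutationCall]:
    """Call every island with at least one mapped probe.

    Calls are returned sorted by ascending minimum probe ``p_nominal``
    (NaN last), then island id — deterministic and invariant to the
    order of the island table.
    """
    mapped = ewas[ewas["island_relation"].isin(["in_island", "flank"])]
    calls = []
    for island_id in sorted(set(islands["island_id"].astype(str))):
        rows = mapped[mapped["island_id"].astype(str) == island_id]
        if rows.empty:
            continue
        calls.append(
            call_island(
                rows,
                alpha=alpha,
                min_fraction_concordant=min_fraction_concordant,
                min_probes=min_probes,
                require_significant=require_significant,
                low=low,
                high=high,
            )
        )
    calls.sort(
        key=lambda c: (
            np.isnan(c.min_p_nominal),
            c.min_p_nominal,
            c.island_id,
        )
    )
    return calls


def calls_to_frame(calls: list[EpimutationCall]) -> pd.DataFrame:
    """Tabulate calls for TSV export."""
    return pd.DataFrame(
        {
            "island_id": [c.island_id for c in calls],
            "verdict": [c.verdict for c in calls],
            "n_probes_considered": [c.n_probes_considered for c in calls],
            "n_concordant": [c.n_concordant for c in calls],
            "n_significant": [c.n_significant for c in calls],
            "case_state": [
                c.case_state_summary.name if c.case_state_summary is not None else ""
                for c in calls
            ],
            "control_state": [
                c.control_state_summary.name
                if c.control_state_summary is not None
                else ""
                for c in calls
            ],
            "min_p_nominal": [c.min_p_nominal for c in calls],
        }
    )
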
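"""Transcript-to-gene assignment and expression summaries.

De-novo-reconstructed transcripts aligned against a cDNA database
(12-column BLAST tabular plus a metadata table of isoform gene, biotype
and length) are assigned to a known gene only when the winning candidate
satisfies five criteria:

i.   the subject isoform is protein-coding;
ii.  the candidate has the highest alignment length among the query's
     (protein-coding) candidates;
iii. the subject length equals the alignment length and exceeds 300 nt
     (the alignment covers the whole isoform, strictly > 300);
iv.  fewer than 4 mismatches;
v.   at most 1 gap opening.

Gene-level abundance is the sum of assigned transcript TPM; RT-qPCR
relative expression uses the ddCq model with the reference-gene mean Cq
(arithmetic mean of Cq, i.e. geometric mean of quantities).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import ValidationError

__all__ = [
    "AlignmentRecord",
    "TranscriptAssignment",
    "read_blast_tabular",
    "records_from_frame",
    "assign_transcript",
    "assign_all",
    "aggregate_gene_expression",
    "relative_expression",
]

BLAST6_COLUMNS = [
    "qseqid",
    "sseqid",
    "pident",
    "length",
    "mismatch",
    "gapopen",
    "qstart",
    "qend",
    "sstart",
    "send",
    "evalue",
    "bitscore",
]

CRITERIA = ("i", "ii", "iii", "iv", "v")


@dataclass(frozen=True)
class AlignmentRecord:
    """One tabular alignment of a reconstructed transcript vs a cDNA isoform."""

    query_id: str
    subject_id: str
    subject_gene: str
    subject_biotype: str
    alignment_length: int
    subject_length: int
    mismatches: int
    gap_openings: int
    e_value: float
    bit_score: float

    def __post_init__(self) -> None:
        for name in ("alignment_length", "subject_length", "mismatches", "gap_openings"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


@dataclass
class TranscriptAssignment:
    """Gene assignment of one query with per-criterion flags.

    ``flags`` maps criterion labels i..v to True/False for the winning
    candidate (None when no candidate reached that criterion, e.g. no
    protein-coding hit at all).  ``assigned_gene`` is non-empty iff all
    five criteria pass.
    """

    query_id: str
    assigned_gene: str | None
    subject_id: str | None
    flags: dict[str, bool | None] = field(default_factory=dict)

    @property
    def assigned(self) -> bool:
        return self.assigned_gene is not None


def records_from_frame(df: pd.DataFrame) -> list[AlignmentRecord]:
    """Build records from a DataFrame with AlignmentRecord field columns."""
    return [
        AlignmentRecord(
            query_id=str(r.query_id),
            subject_id=str(r.subject_id),
            subject_gene=str(r.subject_gene),
            subject_biotype=str(r.subject_biotype),
            alignment_length=int(r.alignment_length),
            subject_length=int(r.subject_length),
            mismatches=int(r.mismatches),
            gap_openings=int(r.gap_openings),
            e_value=float(r.e_value),
            bit_score=float(r.bit_score),
        )
        for r in df.itertuples(index=False)
    ]


def read_blast_tabular(hits_path, cdna_meta_path, sep: str = "\t") -> list[AlignmentRecord]:
    """Read BLAST outfmt-6 hits joined with a cDNA metadata table.

    The metadata TSV must have columns (subject_id, gene, biotype,
    length); every hit subject must be present in it.
    """
    hits = pd.read_csv(hits_path, sep=sep, comment="#", header=None,
                       names=BLAST6_COLUMNS, float_precision="round_trip")
    meta = pd.read_csv(cdna_meta_path, sep=sep, comment="#", dtype={"subject_id": str})
    required = {"subject_id", "gene", "biotype", "length"}
    if not required.issubset(meta.columns):
        raise ValidationError(f"cDNA metadata needs columns {sorted(required)}")
    meta = meta.set_index("subject_id")
    unknown = set(hits["sseqid"].astype(str)) - set(meta.index)
    if unknown:
        raise ValidationError(f"hits reference unknown cDNA subject(s): {sorted(unknown)[:5]}")
    out = []
    for r in hits.itertuples(index=False):
        m = meta.loc[str(r.sseqid)]
        out.append(
            AlignmentRecord(
                query_id=str(r.qseqid),
                subject_id=str(r.sseqid),
                subject_gene=str(m["gene"]),
                subject_biotype=str(m["biotype"]),
                alignment_length=int(r.length),
                subject_length=int(m["length"]),
                mismatches=int(r.mismatch),
                gap_openings=int(r.gapopen),
                e_value=float(r.evalue),
                bit_score=float(r.bitscore),
            )
        )
    return out


def _selection_key(rec: AlignmentRecord):
    # highest alignment length; ties: higher bit score, lower e-value,
    # then lexicographic subject id for full determinism
    return (-rec.alignment_length, -rec.bit_score, rec.e_value, rec.subject_id)


def assign_transcript(
    records_for_query: Sequence[AlignmentRecord],
    biotype_first: bool = True,
    max_gap_openings: int = 1,
) -> TranscriptAssignment:
    """Assign one query to a gene under the five criteria.

    ``biotype_first`` applies the protein-coding filter before
    best-candidate selection (the documented default); with False, the
    best candidate is chosen among all biotypes and criterion i is
    evaluated on it afterwards.
    """
    records = list(records_for_query)
    if not records:
        return TranscriptAssignment("", None, None, dict.fromkeys(CRITERIA))
    queries = {r.query_id for r in records}
    if len(queries) > 1:
        raise ValidationError(f"records mix query ids: {sorted(queries)}")
    query_id = queries.pop()
    flags: dict[str, bool | None] = dict.fromkeys(CRITERIA)

    pool = records
    if biotype_first:
        pool = [r for r in records if r.subject_biotype == "protein_coding"]
        if not pool:
            flags["i"] = False
            return TranscriptAssignment(query_id, None, None, flags)
        flags["i"] = True

    best = min(pool, key=_selection_key)
    flags["ii"] = True  # by construction: best is the selected candidate
    if not biotype_first:
        flags["i"] = best.subject_biotype == "protein_coding"
    flags["iii"] = (
        best.subject_length == best.alignment_length and best.alignment_length > 300
    )
    flags["iv"] = best.mismatches < 4
    flags["v"] = best.gap_openings <= max_gap_openings
    ok = all(flags[c] for c in CRITERIA)
    return TranscriptAssignment(
        query_id,
        best.subject_gene if ok else None,
        best.subject_id,
        flags,
    )


def assign_all(
    records: Iterable[AlignmentRecord], **kwargs
) -> dict[str, TranscriptAssignment]:
    """Group records by query and assign each query."""
    by_query: dict[str, list[AlignmentRecord]] = {}
    for rec in records:
        by_query.setdefault(rec.query_id, []).append(rec)
    return {
        q: assign_transcript(recs, **kwargs) for q, recs in sorted(by_query.items())
    }


def aggregate_gene_expression(
    abundance: pd.DataFrame,
    assignments: dict[str, TranscriptAssignment],
) -> pd.DataFrame:
    """Sum transcript TPM into gene-level TPM.

    ``abundance`` needs columns (target_id, tpm); transcripts without a
    gene assignment are reported under the ``unassigned`` row, so total
    TPM is conserved.
    """
    if not {"target_id", "tpm"}.issubset(abundance.columns):
        raise ValidationError("abundance table needs columns target_id, tpm")
    if (abundance["tpm"] < 0).any():
        raise ValidationError("TPM values must be >= 0")
    gene = abundance["target_id"].map(
        lambda t: (
            assignments[t].assigned_gene
            if t in assignments and assignments[t].assigned
            else "unassigned"
        )
    )
    out = (
        abundance.assign(gene=gene)
        .groupby("gene", as_index=False)["tpm"]
        .sum()
        .sort_values("gene", kind="stable")
        .reset_index(drop=True)
    )
    return out


def relative_expression(
    cq: pd.DataFrame,
    targets: Sequence[str],
    references: Sequence[str] = ("GAPDH", "TBP"),
    calibrator_samples: Sequence[str] = (),
    efficiency: float = 2.0,
) -> pd.DataFrame:
    """ddCq relative expression normalised to reference genes.

    ``cq`` is a long table with columns (sample, gene, cq).  For each
    sample, dCq(target) = Cq(target) - mean(Cq over references) — the
    arithmetic mean of reference Cq corresponds to the geometric mean of
    reference quantities.  Fold change = efficiency^-(dCq - dCq_cal),
    where dCq_cal is the mean dCq over the calibrator samples, so the
    calibrator group has geometric-mean fold change 1 by construction.
    """
    required = {"sample", "gene", "cq"}
    if not required.issubset(cq.columns):
        raise ValidationError(f"Cq table needs columns {sorted(required)}")
    if not calibrator_samples:
        raise ValidationError("at least one calibrator sample is required")
    if efficiency <= 1:
        raise ValidationError("amplification efficiency must exceed 1")
    wide = cq.pivot_table(index="sample", columns="gene", values="cq")
    missing_ref = [g for g in references if g not in wide.columns]
    if missing_ref or wide[list(references)].isna().any().any():
        raise ValidationError("every sample needs a Cq for every reference gene")
    for t in targets:
        if t not in wide.columns or wide[t].isna().any():
            raise ValidationError(f"every sample needs a Cq for target {t!r}")
    unknown_cal = set(calibrator_samples) - set(wide.index)
    if unknown_cal:
        raise ValidationError(f"unknown calibrator sample(s): {sorted(unknown_cal)}")

    ref_mean = wide[list(references)].mean(axis=1)
    rows = []
    for t in targets:
        dcq = wide[t] - ref_mean
        dcq_cal = dcq.loc[list(calibrator_samples)].mean()
        fold = efficiency ** -(dcq - dcq_cal)
        for sample, f in fold.items():
            rows.append((sample, t, float(f)))
    return pd.DataFrame(rows, columns=["sample", "gene", "fold_change"])
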
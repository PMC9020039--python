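"""Packaged reference data: the published epi-cblC promoter signature.

The epi-cblC inherited disorder of intracellular vitamin B12 metabolism
is driven by a secondary epimutation: promoter CpG-island
hypermethylation silencing *MMACHC*, with a second epimutation at the
neighbouring *TESK2* promoter.  The published case-control EWAS
(17 cases vs 350 controls, Illumina 450k/EPIC beta values) reports 18
top probes across the two islands — CpG:33 on the CCDC163P-MMACHC
bidirectional promoter and CpG:51 on the TESK2 promoter — with group
mean beta values, delta beta, and nominal/Bonferroni P-values (GRCh37
coordinates).  These rows ship with the package as a worked reference
input for the classifier and the island caller.
"""

from __future__ import annotations

import importlib.resources

import numpy as np
import pandas as pd

__all__ = ["load_top_signature", "signature_islands", "signature_as_ewas_rows"]

#: CpG:33 span as annotated (UCSC CpG islands, GRCh37).  CpG:51's span is
#: not part of the published record; the interval below is probe-derived
#: (the span of its reported in-island probes) and is marked as such.
SIGNATURE_ISLANDS = pd.DataFrame(
    {
        "island_id": ["CpG:33", "CpG:51"],
        "chromosome": ["1", "1"],
        "start": [45_965_587, 45_956_424],
        "end": [45_966_049, 45_956_882],
    }
)


def load_top_signature() -> pd.DataFrame:
    """Load the 18-probe published signature table.

    Columns: probe_id, chromosome, position, island_id, island_relation,
    locus, p_nominal, p_bonferroni, beta_cases, beta_controls,
    delta_beta.
    """
    ref = importlib.resources.files("epiewas.data") / "top_signature_grch37.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            dtype={"probe_id": str, "chromosome": str, "island_id": str},
        )
    return df


def signature_islands() -> pd.DataFrame:
    """Island intervals for the signature (1-based inclusive)."""
    return SIGNATURE_ISLANDS.copy()


def signature_as_ewas_rows() -> pd.DataFrame:
    """Recast the signature table into the EWAS result schema.

    The published record carries group means and P-values but not
    t statistics, per-group sample counts beyond the study design, or
    smoothed P-values; those columns are filled with NaN / design
    constants so the table can be fed to the island caller.
    """
    sig = load_top_signature()
    neglog = -np.log10(sig["p_nominal"].to_numpy())
    return pd.DataFrame(
        {
            "probe_id": sig["probe_id"],
            "chromosome": sig["chromosome"],
            "position": sig["position"],
            "island_relation": sig["island_relation"],
            "island_id": sig["island_id"],
            "mean_beta_cases": sig["beta_cases"],
            "mean_beta_controls": sig["beta_controls"],
            "delta_beta": sig["delta_beta"],
            "t_stat": np.nan,
            "p_nominal": sig["p_nominal"],
            "p_bonferroni": sig["p_bonferroni"],
            "neglog10_p": neglog,
            "neglog10_p_smoothed": np.nan,
            "n_cases_used": 17,
            "n_controls_used": 350,
            "tested": True,
        }
    )
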
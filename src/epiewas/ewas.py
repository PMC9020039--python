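"""Per-probe case-control statistics, P-value smoothing, and PCA QC.

The per-probe test compares group mean beta values with a two-sample
t test (Welch by default; the classical pooled-variance form via
``variant="student"``), Bonferroni-corrects over the number of probes
actually tested, and reports the columns of a standard EWAS table:
group means, delta beta, t, nominal P, Bonferroni P, -log10 P, and a
windowed smoothed -log10 P (moving mean of radius 3 within each
chromosome, truncated at chromosome ends).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .io import BetaMatrix, ValidationError

__all__ = [
    "EWAS_COLUMNS",
    "PcaResult",
    "probe_group_stats",
    "probe_t_test",
    "bonferroni",
    "smooth_p",
    "pca_qc",
    "run_ewas",
    "manhattan_table",
]

EWAS_COLUMNS = [
    "probe_id",
    "chromosome",
    "position",
    "island_relation",
    "island_id",
    "mean_beta_cases",
    "mean_beta_controls",
    "delta_beta",
    "t_stat",
    "p_nominal",
    "p_bonferroni",
    "neglog10_p",
    "neglog10_p_smoothed",
    "n_cases_used",
    "n_controls_used",
    "tested",
]

_TINY = np.finfo(float).tiny  # P is reported in (0, 1]; exact zeros are floored


def probe_group_stats(matrix: BetaMatrix, probe: str) -> tuple[float, float, float]:
    """Return (mean_cases, mean_controls, delta) for one probe.

    Missing values are excluded per group; each group must retain at
    least one non-missing value.
    """
    if probe not in matrix.probe_ids:
        raise KeyError(f"unknown probe {probe!r}")
    row = matrix.values.loc[probe]
    cases = row[matrix.case_ids].dropna()
    controls = row[matrix.control_ids].dropna()
    if cases.empty or controls.empty:
        raise ValidationError(f"probe {probe!r} has an all-missing group")
    mc, mk = float(cases.mean()), float(controls.mean())
    return mc, mk, mc - mk


def _t_from_arrays(
    x: np.ndarray, y: np.ndarray, variant: str
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-sided t test along the last axis, NaN-aware."""
    if variant not in ("welch", "student"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # constant-input probes
        t, p = stats.ttest_ind(
            x, y, axis=-1, equal_var=(variant == "student"), nan_policy="omit"
        )
    t = np.asarray(t, float)
    p = np.asarray(p, float)
    # zero within-group variance in both groups: t is 0/0.  With equal
    # means there is no evidence of a difference (t=0, P=1); with
    # different means the difference is certain at this precision, so P
    # is floored at the smallest positive float rather than 0.
    degenerate = ~np.isfinite(t)
    if np.any(degenerate):
        with np.errstate(invalid="ignore"):
            dx = np.nanmean(x, axis=-1) - np.nanmean(y, axis=-1)
            equal = degenerate & (dx == 0.0)
            t = np.where(equal, 0.0, t)
            p = np.where(equal, 1.0, p)
            unequal = degenerate & (dx != 0.0)
            t = np.where(unequal, np.sign(dx) * np.inf, t)
            p = np.where(unequal, _TINY, p)
    p = np.maximum(p, _TINY)
    return t, p


def probe_t_test(
    matrix: BetaMatrix, probe: str, variant: str = "welch"
) -> tuple[float, float]:
    """Two-sided two-sample t test for one probe.

    Requires at least two non-missing values per group; probes failing
    that are excluded from testing upstream (see :func:`run_ewas`)
    rather than silently reported as P = 1.
    """
    if probe not in matrix.probe_ids:
        raise KeyError(f"unknown probe {probe!r}")
    row = matrix.values.loc[probe]
    x = row[matrix.case_ids].dropna().to_numpy(float)
    y = row[matrix.control_ids].dropna().to_numpy(float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError(
            f"probe {probe!r}: fewer than 2 non-missing values in a group"
        )
    t, p = _t_from_arrays(x, y, variant)
    return float(t), float(p)


def bonferroni(p_nominal, m_tests: int):
    """Bonferroni correction: min(1, p * m).  Accepts scalars or arrays."""
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    p = np.asarray(p_nominal, float)
    out = np.minimum(1.0, p * m_tests)
    return float(out) if np.isscalar(p_nominal) else out


def smooth_p(rows: pd.DataFrame, radius: int = 3) -> pd.DataFrame:
    """Windowed smoothing of -log10 P along the genome.

    For probe *i*, the smoothed value is the mean of ``neglog10_p`` over
    probes ``i-radius .. i+radius`` on the same chromosome, with the
    window truncated at chromosome ends (so edge windows average fewer
    probes).  Radius 0 is the identity.  Rows must be sorted by
    (chromosome block, position); unsorted input is rejected.

    Returns a copy with ``neglog10_p_smoothed`` filled in.  Untested
    rows (NaN ``neglog10_p``) neither receive nor contribute values.
    """
    if radius < 0:
        raise ValidationError("radius must be >= 0")
    out = rows.copy()
    n = len(out)
    smoothed = np.full(n, np.nan)
    chrom = out["chromosome"].astype(str).to_numpy()
    pos = out["position"].to_numpy()
    # contiguous chromosome runs; a chromosome split across runs or a
    # position inversion within a run means the input is unsorted
    breaks = np.flatnonzero(chrom[1:] != chrom[:-1]) + 1 if n else np.array([], int)
    starts = np.r_[0, breaks].astype(int) if n else np.array([], int)
    stops = np.r_[breaks, n].astype(int) if n else np.array([], int)
    run_chroms = chrom[starts] if n else np.array([], dtype=object)
    if len(set(run_chroms)) != len(run_chroms):
        raise ValidationError("rows not sorted: a chromosome block is split")
    kernel = np.ones(2 * radius + 1)
    for a, b in zip(starts, stops):
        if np.any(np.diff(pos[a:b]) < 0):
            raise ValidationError(
                f"rows not sorted by position on chromosome {chrom[a]!r}"
            )
        v = out["neglog10_p"].to_numpy(float)[a:b]
        ok = np.isfinite(v)
        vv, nn = np.where(ok, v, 0.0), ok.astype(float)
        # full convolution + centered slice (mode="same" misaligns when
        # the window is wider than a short chromosome block)
        sums = np.convolve(vv, kernel, mode="full")[radius : radius + len(vv)]
        counts = np.convolve(nn, kernel, mode="full")[radius : radius + len(nn)]
        with np.errstate(invalid="ignore"):
            sm = np.where(counts > 0, sums / counts, np.nan)
        sm[~ok] = np.nan
        smoothed[a:b] = sm
    out["neglog10_p_smoothed"] = smoothed
    return out


@dataclass
class PcaResult:
    """Top-k PCA of the probe-centered sample methylation profiles."""

    eigenvalues: np.ndarray  # non-increasing, length k
    scores: pd.DataFrame  # samples x (EV1..EVk)
    explained_variance_ratio: np.ndarray
    total_variance: float


def pca_qc(
    matrix: BetaMatrix,
    k: int = 10,
    chromosome: str | None = None,
    manifest: pd.DataFrame | None = None,
) -> PcaResult:
    """PCA of samples on probe-centered beta values.

    Missing beta values are imputed with the probe mean before the
    decomposition.  ``chromosome`` restricts the probe set (requires a
    manifest), mirroring chromosome-wise QC runs.
    """
    vals = matrix.values
    if chromosome is not None:
        if manifest is None:
            raise ValidationError("chromosome restriction requires a manifest")
        keep = manifest.loc[
            manifest["chromosome"].astype(str) == str(chromosome), "probe_id"
        ]
        vals = vals.loc[vals.index.intersection(keep)]
        if vals.empty:
            raise ValidationError(f"no probes on chromosome {chromosome!r}")
    x = vals.to_numpy(float).T  # samples x probes
    if np.all(np.isnan(x), axis=1).any():
        raise ValidationError("a sample has no non-missing beta values")
    probe_mean = np.nanmean(x, axis=0)
    idx = np.where(np.isnan(x))
    x[idx] = probe_mean[idx[1]]
    k_eff = min(k, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=k_eff, svd_solver="auto", random_state=0)
    scores = pca.fit_transform(x)
    labels = [f"EV{i + 1}" for i in range(k_eff)]
    xc = x - x.mean(axis=0)
    total = float((xc**2).sum() / max(x.shape[0] - 1, 1))
    return PcaResult(
        eigenvalues=pca.explained_variance_.copy(),
        scores=pd.DataFrame(scores, index=vals.columns, columns=labels),
        explained_variance_ratio=pca.explained_variance_ratio_.copy(),
        total_variance=total,
    )


def run_ewas(
    matrix: BetaMatrix,
    manifest: pd.DataFrame,
    variant: str = "welch",
    radius: int = 3,
    min_per_group: int = 2,
) -> pd.DataFrame:
    """Full per-probe EWAS over a beta matrix.

    Probes with fewer than ``min_per_group`` non-missing values in
    either group are kept in the output flagged ``tested=False`` with
    NaN statistics and do not count toward the Bonferroni factor, which
    equals the number of probes actually tested in this run.

    Returns one row per manifest probe, sorted by (chromosome,
    position), with the :data:`EWAS_COLUMNS` schema.
    """
    mf = manifest.sort_values(["chromosome", "position"], kind="stable")
    vals = matrix.values.loc[mf["probe_id"]]
    cases = vals[matrix.case_ids].to_numpy(float)
    controls = vals[matrix.control_ids].to_numpy(float)

    n_cases = np.sum(~np.isnan(cases), axis=1)
    n_controls = np.sum(~np.isnan(controls), axis=1)
    tested = (n_cases >= min_per_group) & (n_controls >= min_per_group)
    if not tested.any():
        raise ValidationError("no probe passes the missingness filter")

    sum_c = np.nansum(cases, axis=1)
    sum_k = np.nansum(controls, axis=1)
    mean_c = np.where(n_cases > 0, sum_c / np.maximum(n_cases, 1), np.nan)
    mean_k = np.where(n_controls > 0, sum_k / np.maximum(n_controls, 1), np.nan)
    t = np.full(len(mf), np.nan)
    p = np.full(len(mf), np.nan)
    t[tested], p[tested] = _t_from_arrays(cases[tested], controls[tested], variant)

    m_tests = int(tested.sum())
    p_bonf = np.where(tested, np.minimum(1.0, p * m_tests), np.nan)
    neglog = np.where(tested, -np.log10(p), np.nan)

    out = pd.DataFrame(
        {
            "probe_id": mf["probe_id"].to_numpy(),
            "chromosome": mf["chromosome"].to_numpy(),
            "position": mf["position"].to_numpy(),
            "island_relation": mf["island_relation"].to_numpy(),
            "island_id": mf["island_id"].to_numpy(),
            "mean_beta_cases": mean_c,
            "mean_beta_controls": mean_k,
            "delta_beta": mean_c - mean_k,
            "t_stat": t,
            "p_nominal": p,
            "p_bonferroni": p_bonf,
            "neglog10_p": neglog,
            "neglog10_p_smoothed": np.nan,
            "n_cases_used": n_cases,
            "n_controls_used": n_controls,
            "tested": tested,
        }
    )
    return smooth_p(out, radius=radius)


def manhattan_table(ewas: pd.DataFrame, highlight_threshold: float = 1e-100) -> pd.DataFrame:
    """Epi-Manhattan export: position vs -log10 P with a highlight flag.

    The default highlight threshold (P = 1e-100) marks the band in which
    genome-wide epimutation signatures stand out on this design.
    """
    tested = ewas[ewas["tested"]]
    return pd.DataFrame(
        {
            "chromosome": tested["chromosome"],
            "position": tested["position"],
            "neglog10_p": tested["neglog10_p"],
            "highlight": tested["p_nominal"] < highlight_threshold,
        }
    ).reset_index(drop=True)
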
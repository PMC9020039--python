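import numpy as np
import pandas as pd
import pytest

from epiewas import BetaMatrix, IslandSpec, SimulationConfig, simulate_methylome


@pytest.fixture
def tiny_matrix() -> BetaMatrix:
    """2 probes x 4 samples with hand-computable group means."""
    values = pd.DataFrame(
        {
            "caseA": [0.55, 0.50],
            "caseB": [0.55, 0.50],
            "ctrlA": [0.01, 0.50],
            "ctrlB": [0.01, 0.50],
        },
        index=pd.Index(["cgX", "cgY"], name="probe_id"),
    )
    meta = pd.DataFrame(
        {"group": ["case", "case", "control", "control"]},
        index=pd.Index(["caseA", "caseB", "ctrlA", "ctrlB"], name="sample_id"),
    )
    return BetaMatrix(values, meta)


@pytest.fixture(scope="session")
def small_sim():
    """A 300-probe simulation with one epimutated island and sex probes."""
    cfg = SimulationConfig(
        n_probes=300,
        islands=(IslandSpec("CpG:simA", 7, 4), IslandSpec("CpG:simB", 7, 4)),
        epimutated_island_ids=("CpG:simA",),
        sex_effect_probes=30,
        seed=42,
    )
    return simulate_methylome(cfg)


# ---------------------------------------------------------------------------
# Independent oracles (kept deliberately naive)


def welch_oracle(x, y):
    """Textbook Welch t test with Welch-Satterthwaite df."""
    from scipy.stats import t as tdist

    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    se2 = v1 / n1 + v2 / n2
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    p = 2 * tdist.sf(abs(t), df)
    return t, p


def student_oracle(x, y):
    """Textbook pooled-variance two-sample t test."""
    from scipy.stats import t as tdist

    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * tdist.sf(abs(t), n1 + n2 - 2)
    return t, p


def brute_force_smooth(values, chromosomes, radius):
    """Windowed mean of -log10 P by explicit per-probe loops."""
    values = np.asarray(values, float)
    out = np.full(len(values), np.nan)
    for i in range(len(values)):
        if not np.isfinite(values[i]):
            continue
        window = []
        for j in range(i - radius, i + radius + 1):
            if 0 <= j < len(values) and chromosomes[j] == chromosomes[i]:
                if np.isfinite(values[j]):
                    window.append(values[j])
        out[i] = sum(window) / len(window)
    return out


def brute_force_assign(records):
    """Exhaustive five-criterion evaluation, independent of assign_transcript."""
    coding = [r for r in records if r.subject_biotype == "protein_coding"]
    if not coding:
        return None
    best = sorted(
        coding,
        key=lambda r: (-r.alignment_length, -r.bit_score, r.e_value, r.subject_id),
    )[0]
    if best.subject_length != best.alignment_length:
        return None
    if not best.alignment_length > 300:
        return None
    if not best.mismatches < 4:
        return None
    if not best.gap_openings <= 1:
        return None
    return best.subject_gene
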
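"""Per-timepoint deregulation calling and cross-omics comparisons.

Each omic layer is log-normalized, then every post-baseline day is contrasted
against day 0 with a moderated (empirical-Bayes variance-shrunken) t
statistic.  P values are Benjamini-Hochberg adjusted per omic per day, and a
feature is called deregulated when q <= q_max and |log2FC| >= lfc_min (the
fold-change cutoff applies to transcripts by default, mirroring the common
"FDR 5% plus fold change > 2" convention for mRNA).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .matrices import OmicsMatrix

#: default fold-change cutoff (log2) per omic
DEFAULT_LFC_MIN = {"transcript": 1.0, "protein": 0.0, "metabolite": 0.0}


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def normalize_log(matrix: OmicsMatrix) -> OmicsMatrix:
    """Log-normalize an omic layer.

    Transcript counts become ``log2(CPM + 0.5)``; protein and metabolite
    intensities become ``log2`` values median-centered per sample.
    """
    if matrix.log_scale:
        raise ValueError("matrix is already log-scale")
    vals = matrix.values.to_numpy(dtype=float)
    if matrix.omic == "transcript":
        if (vals < 0).any():
            raise ValueError("negative counts")
        libsize = vals.sum(axis=0)
        if (libsize == 0).any():
            raise ValueError("zero library size")
        out = np.log2(vals / libsize * 1e6 + 0.5)
    else:
        if (vals <= 0).any():
            raise ValueError("intensities must be positive")
        log = np.log2(vals)
        out = log - np.median(log, axis=0, keepdims=True)
    return OmicsMatrix(
        values=pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        samples=matrix.samples,
        omic=matrix.omic,
        log_scale=True,
    )


# ---------------------------------------------------------------------------
# moderated t
# ---------------------------------------------------------------------------

def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton iteration on 1/y scale)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return y


def fit_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled inverse-chi-square variance prior.

    Matches the mean and variance of ``log(s2)`` against the theoretical
    moments of a scaled F distribution, yielding prior degrees of freedom
    ``d0`` and prior variance ``s0^2``.  ``d0 = inf`` when the observed
    spread of sample variances is no larger than expected from chi-square
    sampling noise alone.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if len(s2) < 2:
        return np.inf, float(np.mean(s2)) if len(s2) else 1.0
    z = np.log(s2)
    e_z = z.mean()
    var_z = z.var(ddof=1)
    expected = special.polygamma(1, df / 2)
    excess = var_z - expected
    if excess <= 0:
        d0 = np.inf
        log_s0 = e_z - special.polygamma(0, df / 2) + np.log(df / 2)
    else:
        d0 = 2 * _trigamma_inverse(excess)
        log_s0 = (
            e_z
            - special.polygamma(0, df / 2)
            + np.log(df / 2)
            + special.polygamma(0, d0 / 2)
            - np.log(d0 / 2)
        )
    return float(d0), float(np.exp(log_s0))


def moderated_ttest_groups(
    a: np.ndarray, b: np.ndarray, prior: tuple[float, float] | None = None
) -> pd.DataFrame:
    """Moderated two-sample t per row of two log-scale matrices.

    ``a`` and ``b`` are feature-by-replicate arrays (test group and baseline
    group).  The pooled per-feature variance (df d = n1 + n2 - 2) is shrunk
    toward a prior fitted across features:

        s_tilde^2 = (d0 s0^2 + d s^2) / (d0 + d)

    with t = log2FC / (s_tilde sqrt(1/n1 + 1/n2)) on d0 + d degrees of
    freedom.  ``prior=(d0, s0_squared)`` overrides the cross-feature fit
    (d0 = 0 recovers the ordinary pooled-variance t).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 replicates in both groups")
    df = n1 + n2 - 2
    fc = a.mean(axis=1) - b.mean(axis=1)
    ss = a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)
    s2 = ss / df
    if prior is None:
        d0, s0_sq = fit_variance_prior(s2, df)
    else:
        d0, s0_sq = prior
    if np.isinf(d0):
        s2_tilde = np.full_like(s2, s0_sq)
        df_total = np.inf
    else:
        s2_tilde = (d0 * s0_sq + df * s2) / (d0 + df)
        df_total = d0 + df
    se = np.sqrt(s2_tilde * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fc / se, 0.0)
    t = np.where((se == 0) & (fc == 0), 0.0, t)
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t))
    else:
        p = 2 * stats.t.sf(np.abs(t), df_total)
    return pd.DataFrame({"log2FC": fc, "t": t, "p": p})


def moderated_ttest(
    log_matrix: OmicsMatrix,
    day: int,
    baseline_day: int = 0,
    prior: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Per-feature moderated t of ``day`` vs the baseline day."""
    if not log_matrix.log_scale:
        raise ValueError("run normalize_log first")
    for d in (day, baseline_day):
        if d not in set(log_matrix.samples["day"]):
            raise ValueError(f"day {d} not in sample metadata")
    a = log_matrix.values[log_matrix.samples_at(day)].to_numpy()
    b = log_matrix.values[log_matrix.samples_at(baseline_day)].to_numpy()
    out = moderated_ttest_groups(a, b, prior=prior)
    out.index = log_matrix.feature_ids
    return out


# ---------------------------------------------------------------------------
# multiple testing + calling
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values.

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1, mapped back to the
    input order (stable under ties).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    m = len(p)
    if m == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    order = np.argsort(p, kind="stable")
    adjusted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(adjusted[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


def call_deregulated(
    table: pd.DataFrame, q_max: float = 0.05, lfc_min: float = 1.0
) -> pd.DataFrame:
    """Attach up/down/none calls given FDR and fold-change cutoffs."""
    if lfc_min < 0:
        raise ValueError("lfc_min must be >= 0")
    if "q" not in table.columns:
        raise ValueError("q values not computed; run bh_adjust first")
    out = table.copy()
    sig = out["q"] <= q_max
    call = np.where(
        sig & (out["log2FC"] >= lfc_min),
        "up",
        np.where(sig & (out["log2FC"] <= -lfc_min), "down", "none"),
    )
    # strictly-positive lfc_min excludes exact zero fold changes from both
    # directions only when lfc_min > 0; at lfc_min == 0 a zero FC is neither
    # up nor down by convention
    call = np.where(sig & (out["log2FC"] == 0), "none", call)
    out["call"] = call
    return out


def differential_table(
    matrix: OmicsMatrix,
    q_max: float = 0.05,
    lfc_min: float | None = None,
    baseline_day: int = 0,
) -> pd.DataFrame:
    """Full per-feature, per-day differential table vs baseline.

    Normalizes if necessary, runs the moderated t for every post-baseline
    day, BH-adjusts per day, and attaches calls.  Returns a long-format
    DataFrame with columns feature_id, day, log2FC, t, p, q, call.
    """
    if lfc_min is None:
        lfc_min = DEFAULT_LFC_MIN[matrix.omic]
    log_matrix = matrix if matrix.log_scale else normalize_log(matrix)
    frames = []
    for day in log_matrix.days:
        if day == baseline_day:
            continue
        tab = moderated_ttest(log_matrix, int(day), baseline_day=baseline_day)
        tab["q"] = bh_adjust(tab["p"].to_numpy())
        tab = call_deregulated(tab, q_max=q_max, lfc_min=lfc_min)
        tab.insert(0, "day", int(day))
        tab.insert(0, "feature_id", tab.index)
        frames.append(tab.reset_index(drop=True))
    return pd.concat(frames, ignore_index=True)


def deregulation_counts(table: pd.DataFrame) -> pd.DataFrame:
    """Per-day counts of up-, down- and total deregulated features."""
    rows = []
    for day, sub in table.groupby("day"):
        up = int((sub["call"] == "up").sum())
        down = int((sub["call"] == "down").sum())
        rows.append({"day": day, "up": up, "down": down, "total": up + down})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# set-level direction test, cross-omics correlation, PCA
# ---------------------------------------------------------------------------

@dataclass
class DirectionTestResult:
    counts: np.ndarray  # 2x2: rows up/down, cols in-set/background
    odds_ratio: float
    p: float
    empty_margin: bool = False


def direction_enrichment_test(
    table: pd.DataFrame, annotation_set, day: int
) -> DirectionTestResult:
    """Fisher exact test of up/down balance inside vs outside an annotation.

    Only features called up or down at ``day`` enter the 2x2 table
    {up, down} x {in-set, background}.  An empty margin is flagged and
    returns p = 1 with an undefined odds ratio.
    """
    annotation_set = set(annotation_set)
    sub = table[(table["day"] == day) & (table["call"] != "none")]
    in_set = sub["feature_id"].isin(annotation_set)
    up = sub["call"] == "up"
    counts = np.array(
        [
            [int((up & in_set).sum()), int((up & ~in_set).sum())],
            [int((~up & in_set).sum()), int((~up & ~in_set).sum())],
        ]
    )
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        return DirectionTestResult(counts, np.nan, 1.0, empty_margin=True)
    odds, p = stats.fisher_exact(counts, alternative="two-sided")
    return DirectionTestResult(counts, float(odds), float(p))


def crossomics_fc_correlation(
    tx_table: pd.DataFrame, prot_table: pd.DataFrame, day: int
) -> tuple[float, float, int]:
    """Pearson r between transcript and protein log2FC at one day.

    Pairs are features called up or down in either layer at ``day`` and
    present in both layers.  Returns (r, p, n).
    """
    tx = tx_table[tx_table["day"] == day].set_index("feature_id")
    prot = prot_table[prot_table["day"] == day].set_index("feature_id")
    shared = tx.index.intersection(prot.index)
    called = shared[
        (tx.loc[shared, "call"] != "none") | (prot.loc[shared, "call"] != "none")
    ]
    if len(called) < 3:
        raise ValueError(f"fewer than 3 called feature pairs at day {day}")
    r, p = stats.pearsonr(
        tx.loc[called, "log2FC"].to_numpy(), prot.loc[called, "log2FC"].to_numpy()
    )
    return float(r), float(p), int(len(called))


def pca_scores(log_matrix: OmicsMatrix, n_pc: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Project samples on the top principal components.

    Features are centered across samples; scores come from the SVD of the
    sample-by-feature matrix.  Returns (scores DataFrame, explained-variance
    fractions).
    """
    X = log_matrix.values.to_numpy(dtype=float).T  # samples x features
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if n_pc > min(X.shape):
        raise ValueError("n_pc exceeds matrix rank bound")
    Xc = X - X.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = u[:, :n_pc] * s[:n_pc]
    evf = (s**2 / (s**2).sum())[:n_pc]
    cols = [f"PC{i + 1}" for i in range(n_pc)]
    return pd.DataFrame(scores, index=log_matrix.values.columns, columns=cols), evf
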
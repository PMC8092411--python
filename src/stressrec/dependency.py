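"""Dependency-signature derivation and tumor projection.

From a CRISPR essentiality screen (CERES-like scores, more negative =
stronger dependency) the pipeline selects the most-dependent cell lines and
a tissue-matched least-dependent group, derives a directional expression
signature separating them (moderated t + BH, top |t| genes of fixed size),
and projects the signature onto a tumor cohort: each signature gene is
z-scored across tumors and a tumor is classified dependent when the fraction
of genes whose z sign agrees with the signature direction exceeds the match
threshold (strictly greater than 0.8 by default).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import json
import numpy as np
import pandas as pd

from .differential import bh_adjust, moderated_ttest_groups


@dataclass
class Signature:
    """Directional gene signature for one dependency target."""

    target_gene: str
    genes: list
    directions: np.ndarray  # +1 / -1 per gene
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=int)
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("duplicate signature genes")
        if (self.directions == 0).any():
            raise ValueError("directions must be nonzero")

    def __len__(self) -> int:
        return len(self.genes)

    def to_json(self, path) -> None:
        payload = {
            "target_gene": self.target_gene,
            "genes": list(self.genes),
            "directions": self.directions.tolist(),
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Signature":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            target_gene=payload["target_gene"],
            genes=payload["genes"],
            directions=np.asarray(payload["directions"]),
            metadata=payload.get("metadata", {}),
        )


@dataclass
class ProjectionResult:
    """Per-tumor signature match fractions and classifications."""

    match_fraction: pd.Series
    dependent: pd.Series
    match_thr: float
    n_genes_used: int


def count_dependent(prob_matrix: pd.DataFrame, gene: str, threshold: float = 0.5) -> int:
    """Number of cell lines with dependency probability strictly above threshold."""
    if gene not in prob_matrix.index:
        raise KeyError(f"gene {gene!r} not in probability matrix")
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return int((prob_matrix.loc[gene] > threshold).sum())


def select_extreme_lines(
    scores: pd.Series, tissues: pd.Series, n_top: int, n_bottom: int
) -> tuple[list, list, dict]:
    """Most-dependent lines and a tissue-matched least-dependent group.

    The top group is the ``n_top`` most-negative dependency scores.  The
    bottom group greedily matches the top group's tissue histogram drawing
    from the least-negative end; tissues short of candidates are filled from
    the global least-dependent pool and reported as shortfalls.
    """
    if n_top + n_bottom > len(scores):
        raise ValueError("n_top + n_bottom exceeds available lines")
    tissues = tissues.reindex(scores.index)
    if tissues.isna().any() or (tissues == "").any():
        raise ValueError("every line needs a non-empty tissue label")

    asc = scores.sort_values(kind="stable")  # most negative first
    top = list(asc.index[:n_top])
    candidates = [line for line in asc.index[::-1] if line not in top]

    want = Counter(tissues.loc[top])
    quota = {
        tissue: round(n_bottom * cnt / n_top) for tissue, cnt in want.items()
    }
    bottom: list = []
    shortfall: dict = {}
    for tissue, q in quota.items():
        pool = [ln for ln in candidates if tissues.loc[ln] == tissue and ln not in bottom]
        take = pool[:q]
        if len(take) < q:
            shortfall[tissue] = q - len(take)
        bottom.extend(take)
    for line in candidates:  # fill any shortfall from the global pool
        if len(bottom) >= n_bottom:
            break
        if line not in bottom:
            bottom.append(line)
    bottom = bottom[:n_bottom]
    return top, bottom, shortfall


def derive_signature(
    expression: pd.DataFrame,
    dependent_lines,
    independent_lines,
    target_gene: str,
    size: int = 56,
    q_max: float = 0.05,
) -> Signature:
    """Directional signature separating dependent from independent lines.

    Per-gene moderated t between the two groups, BH adjustment, genes with
    q <= q_max ranked by |t| descending (ties by gene id), top ``size``
    kept.  Direction is the sign of (dependent mean - independent mean).
    If fewer than ``size`` genes pass, all passing genes are returned and
    the shortfall is flagged in the metadata.
    """
    dependent_lines, independent_lines = list(dependent_lines), list(independent_lines)
    if len(dependent_lines) < 3 or len(independent_lines) < 3:
        raise ValueError("both groups need >= 3 lines")
    a = expression[dependent_lines].to_numpy(float)
    b = expression[independent_lines].to_numpy(float)
    stats_tab = moderated_ttest_groups(a, b)
    stats_tab.index = expression.index
    # the screened target itself is not a candidate signature member
    stats_tab = stats_tab.drop(index=target_gene, errors="ignore")
    stats_tab["q"] = bh_adjust(stats_tab["p"].to_numpy())
    passing = stats_tab[(stats_tab["q"] <= q_max) & (stats_tab["log2FC"] != 0)].copy()
    passing["abs_t"] = passing["t"].abs()
    # deterministic tie handling: lexicographic gene order, then stable sort
    passing = passing.sort_index()
    passing = passing.sort_values("abs_t", ascending=False, kind="stable")
    chosen = passing.iloc[:size]
    flagged_short = len(chosen) < size
    return Signature(
        target_gene=target_gene,
        genes=list(chosen.index),
        directions=np.sign(chosen["log2FC"].to_numpy()).astype(int),
        metadata={
            "n_dependent": len(dependent_lines),
            "n_independent": len(independent_lines),
            "q_max": q_max,
            "requested_size": size,
            "short": flagged_short,
        },
    )


def project_signature(
    signature: Signature, tumor_expression: pd.DataFrame, match_thr: float = 0.8
) -> ProjectionResult:
    """Project a signature onto a tumor cohort.

    Each signature gene present in the cohort is z-scored across tumors; a
    tumor's match fraction is the share of genes whose z-score sign equals
    the signature direction, and the tumor is classified dependent when the
    fraction is strictly greater than ``match_thr``.
    """
    if tumor_expression.shape[1] < 2:
        raise ValueError("cohort must contain >= 2 tumors for z-scoring")
    present = [g for g in signature.genes if g in tumor_expression.index]
    if len(present) < len(signature) / 2:
        raise ValueError(
            f"only {len(present)}/{len(signature)} signature genes in the cohort"
        )
    directions = pd.Series(signature.directions, index=signature.genes).loc[present]
    sub = tumor_expression.loc[present]
    arr = sub.to_numpy(float)
    sd = arr.std(axis=1, ddof=1)
    if (sd == 0).any():
        # constant genes carry no sign information; drop them
        keep = sd > 0
        arr, sd = arr[keep], sd[keep]
        directions = directions[keep]
        present = list(directions.index)
        if len(present) < len(signature) / 2:
            raise ValueError("too many constant signature genes in the cohort")
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd[:, None]
    agree = np.sign(z) == directions.to_numpy()[:, None]
    frac = agree.mean(axis=0)
    match = pd.Series(frac, index=tumor_expression.columns, name="match_fraction")
    return ProjectionResult(
        match_fraction=match,
        dependent=(match > match_thr).rename("dependent"),
        match_thr=match_thr,
        n_genes_used=len(present),
    )


def classification_metrics(result: ProjectionResult, truth: pd.Series) -> dict:
    """Sensitivity and specificity of the projection against known labels."""
    truth = truth.reindex(result.dependent.index).astype(bool)
    pred = result.dependent.astype(bool)
    tp = int((pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    fp = int((pred & ~truth).sum())
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "n_dependent_called": tp + fp,
    }
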
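"""Single-sample gene-set enrichment over the time course.

Per sample, features are ranked by expression and a Kolmogorov-Smirnov-style
running sum is walked down the ranking: it climbs by 1/|hits| at set members
and falls by 1/(n - |hits|) elsewhere; the signed maximum deviation is the
sample's enrichment score for the set.  Scores are rank-based, hence
invariant to monotone transforms of expression within a sample.  For display
the score range of each set is scaled to [-1, 1] across samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrices import OmicsMatrix


@dataclass
class GeneSetCollection:
    """Named, non-empty sets of feature ids with an optional source tag."""

    sets: dict
    source: str = ""
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")
            self.sets[name] = list(dict.fromkeys(members))

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class EnrichmentMatrix:
    """Set-by-sample enrichment scores; ``scaled`` marks the [-1, 1] form."""

    scores: pd.DataFrame
    scaled: bool = False
    skipped_sets: list = field(default_factory=list)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB member...).

    Duplicate members within a set are dropped with a warning; lines with
    fewer than three fields raise with the offending line number.
    """
    sets: dict = {}
    descriptions: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"malformed GMT line {lineno}: expected >= 3 tab-separated fields"
                )
            name, desc, *members = fields
            members = [m for m in members if m]
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                warnings.warn(f"duplicate members in set {name!r} deduplicated")
            if name in sets:
                raise ValueError(f"duplicate set name {name!r} at line {lineno}")
            sets[name] = deduped
            descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def _sample_score(order_ids, hit_mask, alpha, ranks) -> float:
    n = len(order_ids)
    n_hit = int(hit_mask.sum())
    if n_hit == 0 or n_hit == n:
        return np.nan
    if alpha > 0:
        w = ranks.astype(float) ** alpha
        w = np.where(hit_mask, w, 0.0)
        w = w / w.sum()
        inc = w
    else:
        inc = np.where(hit_mask, 1.0 / n_hit, 0.0)
    dec = np.where(hit_mask, 0.0, 1.0 / (n - n_hit))
    running = np.cumsum(inc - dec)
    peak = int(np.argmax(np.abs(running)))
    return float(running[peak])


def sample_set_scores(
    log_matrix: OmicsMatrix, sets: GeneSetCollection, alpha: float = 0.0
) -> EnrichmentMatrix:
    """KS running-sum enrichment score per gene set per sample.

    Features are ranked by expression descending; ties break by feature id
    (lexicographic) for determinism.  With ``alpha > 0`` member increments
    are weighted by rank^alpha (renormalized).  Sets with no overlap with
    the feature universe are skipped and reported.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    values = log_matrix.values
    universe = set(values.index)
    usable, skipped = {}, []
    for name, members in sets.sets.items():
        overlap = [m for m in members if m in universe]
        if overlap:
            usable[name] = set(overlap)
        else:
            skipped.append(name)

    n = len(values.index)
    out = pd.DataFrame(
        np.nan, index=list(usable), columns=values.columns, dtype=float
    )
    # stable sort on (-expression, feature_id): sort ids first, then values
    id_order = np.argsort(values.index.to_numpy())
    for sample in values.columns:
        col = values[sample].to_numpy()[id_order]
        ids = values.index.to_numpy()[id_order]
        desc = np.argsort(-col, kind="stable")
        ranked_ids = ids[desc]
        ranks = np.arange(n, 0, -1)  # high rank = top of the list
        for name, members in usable.items():
            hit = np.fromiter((f in members for f in ranked_ids), bool, n)
            out.loc[name, sample] = _sample_score(ranked_ids, hit, alpha, ranks)
    return EnrichmentMatrix(scores=out, scaled=False, skipped_sets=skipped)


def scale_scores(matrix: EnrichmentMatrix) -> EnrichmentMatrix:
    """Scale each set's scores by its maximum magnitude across samples.

    After scaling every value lies in [-1, 1] and each non-degenerate set
    attains magnitude 1 in at least one sample; all-zero rows are left as
    zero.
    """
    if matrix.scaled:
        raise ValueError("matrix already scaled")
    arr = matrix.scores.to_numpy(dtype=float)
    peak = np.nanmax(np.abs(arr), axis=1, keepdims=True)
    safe = np.where(peak > 0, peak, 1.0)
    return EnrichmentMatrix(
        scores=pd.DataFrame(
            arr / safe, index=matrix.scores.index, columns=matrix.scores.columns
        ),
        scaled=True,
        skipped_sets=list(matrix.skipped_sets),
    )
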
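"""Core in-memory containers shared across the pipeline.

An :class:`OmicsMatrix` holds one omic layer (transcript counts, protein or
metabolite intensities) as a feature-by-sample table together with per-sample
metadata (day, replicate, treatment arm).  All downstream stages (differential
calling, network construction, enrichment) consume this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

OMIC_KINDS = ("transcript", "protein", "metabolite")

#: Columns every sample-metadata table must carry.
SAMPLE_COLUMNS = ("day", "replicate", "arm")


@dataclass
class OmicsMatrix:
    """Feature-by-sample matrix for a single omic layer.

    Parameters
    ----------
    values
        DataFrame indexed by feature id, one column per sample id.  Counts
        for transcripts, positive intensities for proteins/metabolites
        (unless ``log_scale``).
    samples
        DataFrame indexed by sample id with columns ``day`` (int),
        ``replicate`` (int) and ``arm`` (str).  Must align with the columns
        of ``values``.
    omic
        One of ``transcript``, ``protein``, ``metabolite``.
    log_scale
        True once values have been log-normalized (see
        :func:`stressrec.differential.normalize_log`).
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    omic: str
    log_scale: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.omic not in OMIC_KINDS:
            raise ValueError(f"omic must be one of {OMIC_KINDS}, got {self.omic!r}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        missing = [c for c in SAMPLE_COLUMNS if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns {missing}")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("values columns and sample metadata index do not align")
        if self.omic == "transcript" and not self.log_scale:
            arr = self.values.to_numpy()
            if (arr < 0).any():
                raise ValueError("transcript counts must be non-negative")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def days(self) -> np.ndarray:
        """Sorted unique sampling days."""
        return np.sort(self.samples["day"].unique())

    def samples_at(self, day: int, arm: str | None = None) -> list[str]:
        """Sample ids measured at ``day`` (optionally restricted to one arm)."""
        mask = self.samples["day"] == day
        if arm is not None:
            mask &= self.samples["arm"] == arm
        return list(self.samples.index[mask])

    def subset_features(self, feature_ids) -> "OmicsMatrix":
        return OmicsMatrix(
            values=self.values.loc[list(feature_ids)],
            samples=self.samples,
            omic=self.omic,
            log_scale=self.log_scale,
        )


@dataclass
class TemporalProfileMatrix:
    """Per-feature day-course profiles, z-scored across days.

    ``profiles`` is a DataFrame indexed by feature id with one column per day.
    Rows have mean 0 and population standard deviation 1.  Features whose raw
    day-course was constant cannot be z-scored and are listed in ``dropped``.
    """

    profiles: pd.DataFrame
    dropped: list[str] = field(default_factory=list)

    @property
    def days(self) -> np.ndarray:
        return np.asarray(self.profiles.columns, dtype=float)

    @property
    def feature_ids(self) -> pd.Index:
        return self.profiles.index
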
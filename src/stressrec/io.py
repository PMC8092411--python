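"""Readers and writers for the pipeline's plain-text formats.

Omics matrices travel as TSV (features x samples, header row = sample ids)
with a sidecar CSV of sample metadata (sample_id, day, replicate, arm);
differential tables, edge lists and scan summaries as TSV; partitions and
truth labels as CSV; configs as YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .matrices import OmicsMatrix


def write_omics_matrix(matrix: OmicsMatrix, values_path, samples_path) -> None:
    matrix.values.rename_axis("feature_id").to_csv(values_path, sep="\t")
    matrix.samples.rename_axis("sample_id").to_csv(samples_path)


def read_omics_matrix(values_path, samples_path, omic: str, log_scale=False) -> OmicsMatrix:
    values = pd.read_csv(values_path, sep="\t", index_col="feature_id")
    samples = pd.read_csv(samples_path, index_col="sample_id")
    return OmicsMatrix(values=values, samples=samples, omic=omic, log_scale=log_scale)


def write_truth(truth: dict, path) -> None:
    frames = []
    for omic, series in truth.items():
        df = series.rename("label").rename_axis("feature_id").reset_index()
        df.insert(0, "omic", omic)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_config(path) -> dict:
    path = Path(path)
    with open(path) as fh:
        if path.suffix in (".yaml", ".yml"):
            return yaml.safe_load(fh)
        return json.load(fh)


def dump_config(config: dict, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(config, fh, sort_keys=False)
        else:
            json.dump(config, fh, indent=2)


def write_manifest(manifest: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
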
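"""Reading and writing the pipeline's external formats.

Spectra are one two-column (ppm, intensity) delimited file per sample plus
a metadata CSV; bucket tables and feature matrices are CSV with a sidecar
YAML provenance block.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import BucketTable, FeatureMatrix
from .synth import SyntheticSpectrum


def write_spectra(spectra, outdir) -> None:
    """One ``<sample_id>.tsv`` per spectrum plus ``metadata.csv``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = []
    for s in spectra:
        np.savetxt(
            outdir / f"{s.sample_id}.tsv",
            np.column_stack([s.ppm_axis, s.intensity]),
            delimiter="\t",
            header="ppm\tintensity",
            comments="",
        )
        meta.append(
            {"sample_id": s.sample_id, "group": s.group, "age": s.age, "gender": s.gender}
        )
    pd.DataFrame(meta).to_csv(outdir / "metadata.csv", index=False)


def read_spectra(indir) -> list[SyntheticSpectrum]:
    indir = Path(indir)
    meta = pd.read_csv(indir / "metadata.csv").set_index("sample_id")
    spectra = []
    for sid, row in meta.iterrows():
        arr = np.loadtxt(indir / f"{sid}.tsv", delimiter="\t", skiprows=1)
        spectra.append(
            SyntheticSpectrum(
                ppm_axis=arr[:, 0],
                intensity=arr[:, 1],
                sample_id=str(sid),
                group=str(row["group"]),
                age=float(row["age"]),
                gender=str(row["gender"]),
            )
        )
    return spectra


def write_bucket_table(table: BucketTable, path) -> None:
    """Bucket table as CSV; intervals/exclusions in a sidecar YAML."""
    path = Path(path)
    pd.DataFrame(
        table.values, index=table.sample_ids, columns=table.bucket_names()
    ).to_csv(path)
    side = {
        "intervals": [[float(hi), float(lo)] for hi, lo in table.intervals],
        "excluded": [bool(e) for e in table.excluded],
        "annotations": {int(k): v for k, v in table.annotations.items()},
    }
    if table.metadata is not None:
        side["metadata"] = table.metadata.to_dict(orient="records")
    path.with_suffix(".yaml").write_text(yaml.safe_dump(side))


def read_bucket_table(path) -> BucketTable:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    side = yaml.safe_load(path.with_suffix(".yaml").read_text())
    meta = None
    if "metadata" in side:
        meta = pd.DataFrame(side["metadata"])
    return BucketTable(
        sample_ids=[str(i) for i in df.index],
        intervals=np.asarray(side["intervals"], dtype=float),
        values=df.to_numpy(dtype=float),
        excluded=np.asarray(side["excluded"], dtype=bool),
        annotations={int(k): v for k, v in side.get("annotations", {}).items()},
        metadata=meta,
    )


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    """Feature matrix as CSV with the provenance chain in a sidecar YAML."""
    path = Path(path)
    matrix.to_frame().to_csv(path)
    side = {
        "provenance": [[step, kw] for step, kw in matrix.provenance],
        "reference_feature": matrix.reference_feature,
    }
    if matrix.groups is not None:
        side["groups"] = [str(g) for g in matrix.groups]
    path.with_suffix(".yaml").write_text(yaml.safe_dump(side))


def read_feature_matrix(path) -> FeatureMatrix:
    path = Path(path)
    df = pd.read_csv(path, index_col=0)
    side = yaml.safe_load(path.with_suffix(".yaml").read_text())
    return FeatureMatrix(
        values=df.to_numpy(dtype=float),
        feature_names=[str(c) for c in df.columns],
        sample_ids=[str(i) for i in df.index],
        provenance=[(s, kw) for s, kw in side.get("provenance", [])],
        groups=np.asarray(side["groups"]) if "groups" in side else None,
        reference_feature=side.get("reference_feature"),
    )
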
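"""CSV / NIfTI readers and writers for feature tables and results.

The on-disk layout is three delimited files: a features CSV (subject_id
column plus one column per ROI feature), a network-map sidecar CSV
(feature_id, network_id) and a labels CSV (subject_id, label).  Voxel-mode
inputs are a flat subjects x voxels CSV plus an atlas label CSV, or NIfTI
volumes when a 3-D shape is in play.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables import FeatureTable, NetworkFeatureTable

__all__ = [
    "read_feature_inputs",
    "write_feature_inputs",
    "read_voxel_inputs",
    "write_voxel_inputs",
    "write_nifti_dataset",
]


def read_feature_inputs(
    features_csv: str | Path,
    network_map_csv: str | Path,
    labels_csv: str | Path,
) -> tuple[FeatureTable, NetworkFeatureTable]:
    """Load and validate ROI features, the feature->network map and labels.

    The network-level table is rebuilt as the per-network row means, the same
    definition the generators and the extraction pipeline use.
    """
    fpath = Path(features_csv)
    feat = pd.read_csv(fpath, float_precision="round_trip")
    if "subject_id" not in feat.columns:
        raise ValidationError(f"{fpath}: missing 'subject_id' column")
    if feat["subject_id"].duplicated().any():
        dup = feat.loc[feat["subject_id"].duplicated(), "subject_id"].iloc[0]
        raise ValidationError(f"{fpath}: duplicate subject id {dup!r}")
    feature_cols = [c for c in feat.columns if c != "subject_id"]

    netmap = pd.read_csv(network_map_csv)
    for col in ("feature_id", "network_id"):
        if col not in netmap.columns:
            raise ValidationError(f"{network_map_csv}: missing '{col}' column")
    mapping = dict(zip(netmap["feature_id"], netmap["network_id"]))
    missing = [c for c in feature_cols if c not in mapping]
    if missing:
        raise ValidationError(
            f"{network_map_csv}: no network assignment for feature(s) {missing}"
        )

    lab = pd.read_csv(labels_csv)
    for col in ("subject_id", "label"):
        if col not in lab.columns:
            raise ValidationError(f"{labels_csv}: missing '{col}' column")
    lab = lab.set_index("subject_id")["label"]
    uncovered = [s for s in feat["subject_id"] if s not in lab.index]
    if uncovered:
        raise ValidationError(f"{labels_csv}: no label for subject(s) {uncovered[:5]}")

    table = FeatureTable(
        values=feat[feature_cols].to_numpy(dtype=float),
        network_map=np.array([mapping[c] for c in feature_cols]),
        labels=lab.loc[feat["subject_id"]].to_numpy(),
        subject_ids=list(feat["subject_id"].astype(str)),
        feature_ids=feature_cols,
    )
    L, n = table.n_networks, table.rois_per_network
    net_values = np.column_stack(
        [table.network_block(l).mean(axis=1) for l in range(1, L + 1)]
    )
    return table, NetworkFeatureTable(values=net_values)


def write_feature_inputs(
    table: FeatureTable,
    directory: str | Path,
    *,
    features_name: str = "features.csv",
    network_map_name: str = "network_map.csv",
    labels_name: str = "labels.csv",
) -> dict[str, Path]:
    """Write the three-file CSV layout that :func:`read_feature_inputs` reads."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "features": directory / features_name,
        "network_map": directory / network_map_name,
        "labels": directory / labels_name,
    }
    table.to_frame().to_csv(paths["features"], index=False)
    pd.DataFrame(
        {"feature_id": table.feature_ids, "network_id": table.network_map}
    ).to_csv(paths["network_map"], index=False)
    pd.DataFrame(
        {"subject_id": table.subject_ids, "label": table.labels}
    ).to_csv(paths["labels"], index=False)
    return paths


def read_voxel_inputs(
    voxels_csv: str | Path, atlas_csv: str | Path, labels_csv: str | Path
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    """Load a flat subjects x voxels matrix, atlas labels and group labels."""
    vox = pd.read_csv(voxels_csv, float_precision="round_trip")
    if "subject_id" not in vox.columns:
        raise ValidationError(f"{voxels_csv}: missing 'subject_id' column")
    subject_ids = list(vox["subject_id"].astype(str))
    X = vox.drop(columns="subject_id").to_numpy(dtype=float)
    atlas = pd.read_csv(atlas_csv)["region_id"].to_numpy()
    if atlas.shape[0] != X.shape[1]:
        raise ValidationError(
            f"{atlas_csv}: {atlas.shape[0]} atlas labels for {X.shape[1]} voxels"
        )
    lab = pd.read_csv(labels_csv).set_index("subject_id")["label"]
    labels = lab.loc[vox["subject_id"]].to_numpy()
    return X, atlas, labels, subject_ids


def write_voxel_inputs(
    X: np.ndarray,
    atlas: np.ndarray,
    labels: np.ndarray,
    directory: str | Path,
) -> dict[str, Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "voxels": directory / "voxels.csv",
        "atlas": directory / "atlas.csv",
        "labels": directory / "labels.csv",
    }
    df = pd.DataFrame(X, columns=[f"v{j}" for j in range(X.shape[1])])
    df.insert(0, "subject_id", [f"s{i:03d}" for i in range(X.shape[0])])
    df.to_csv(paths["voxels"], index=False)
    pd.DataFrame({"region_id": atlas}).to_csv(paths["atlas"], index=False)
    pd.DataFrame(
        {"subject_id": df["subject_id"], "label": labels}
    ).to_csv(paths["labels"], index=False)
    return paths


def write_nifti_dataset(
    X: np.ndarray,
    atlas: np.ndarray,
    directory: str | Path,
    shape: tuple[int, int, int],
) -> dict[str, Path]:
    """Optionally materialize voxel data as per-subject NIfTI volumes + atlas."""
    import nibabel as nib

    if int(np.prod(shape)) != X.shape[1]:
        raise ValidationError(f"shape {shape} does not hold {X.shape[1]} voxels")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    affine = np.eye(4)
    paths: dict[str, Path] = {}
    for i in range(X.shape[0]):
        img = nib.Nifti1Image(X[i].reshape(shape).astype(np.float32), affine)
        paths[f"subject_{i}"] = directory / f"subject_{i:03d}.nii"
        nib.save(img, paths[f"subject_{i}"])
    atlas_img = nib.Nifti1Image(atlas.reshape(shape).astype(np.int16), affine)
    paths["atlas"] = directory / "atlas.nii"
    nib.save(atlas_img, paths["atlas"])
    return paths
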
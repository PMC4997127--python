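"""Volume and table I/O: NIfTI cohorts, feature maps, CSV exports.

A cohort on disk is a directory of per-subject 3-D NIfTI volumes, a binary
NIfTI brain mask of the same dimensions, and a two-column CSV
``subject_id,label`` with labels mapping to H (controls) / D (patients).
Per-feature vectors (selection probabilities, selection counts, mean
discriminant weights) round-trip to NIfTI volumes through the geometry's
fixed feature order.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .data import LABEL_D, LABEL_H, LabeledFeatureMatrix
from .synthetic import Cluster, SyntheticSpec, VolumeGeometry

#: accepted spellings for the two class labels in a labels CSV
DEFAULT_LABEL_MAP = {
    "H": LABEL_H, "HC": LABEL_H, "CONTROL": LABEL_H, "0": LABEL_H,
    "D": LABEL_D, "FES": LABEL_D, "PATIENT": LABEL_D, "1": LABEL_D,
}


def _affine(geometry: VolumeGeometry) -> np.ndarray:
    aff = np.diag(list(geometry.voxel_size) + [1.0])
    return aff


def write_mask(geometry: VolumeGeometry, path: str | Path) -> None:
    img = nib.Nifti1Image(geometry.mask.astype(np.uint8), _affine(geometry))
    nib.save(img, str(path))


def read_mask(path: str | Path,
              voxel_size: tuple[float, float, float] | None = None) -> VolumeGeometry:
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) > 0
    if not mask.any():
        raise ValueError(f"empty mask: {path}")
    if voxel_size is None:
        voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeGeometry(dims=mask.shape, voxel_size=voxel_size, mask=mask)


def write_volume(volume: np.ndarray, geometry: VolumeGeometry,
                 path: str | Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64),
                             _affine(geometry)), str(path))


def write_map(values: np.ndarray, geometry: VolumeGeometry,
              path: str | Path, background: float = 0.0) -> None:
    """Write a per-feature vector as a NIfTI volume (out-of-mask voxels =
    ``background``); reading it back restores the in-mask values exactly."""
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (geometry.p,):
        raise ValueError(
            f"expected {geometry.p} per-feature values, got {values.shape}")
    write_volume(geometry.unflatten(values, background=background),
                 geometry, path)


def read_map(path: str | Path, geometry: VolumeGeometry) -> np.ndarray:
    vol = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    return geometry.flatten(vol)


def write_cohort(data: LabeledFeatureMatrix, geometry: VolumeGeometry,
                 out_dir: str | Path) -> None:
    """Write one NIfTI per subject plus mask.nii.gz and labels.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_mask(geometry, out_dir / "mask.nii.gz")
    for sid, row in zip(data.subject_ids, data.X):
        write_volume(geometry.unflatten(row), geometry,
                     out_dir / f"{sid}.nii.gz")
    pd.DataFrame({"subject_id": data.subject_ids,
                  "label": data.labels}).to_csv(out_dir / "labels.csv",
                                                index=False)


def read_cohort(volumes_dir: str | Path, labels_csv: str | Path,
                mask_path: str | Path,
                label_map: dict[str, str] | None = None
                ) -> tuple[LabeledFeatureMatrix, VolumeGeometry]:
    """Load a NIfTI cohort into a masked, flattened feature matrix.

    Every subject listed in the CSV must have ``<subject_id>.nii`` or
    ``.nii.gz`` in ``volumes_dir`` with the mask's dimensions.
    """
    if label_map is None:
        label_map = DEFAULT_LABEL_MAP
    geometry = read_mask(mask_path)
    volumes_dir = Path(volumes_dir)
    table = pd.read_csv(labels_csv, dtype=str)
    if not {"subject_id", "label"} <= set(table.columns):
        raise ValueError("labels CSV needs columns subject_id,label")

    rows, labels, sids = [], [], []
    for r, rec in table.iterrows():
        raw = str(rec["label"]).strip().upper()
        if raw not in label_map:
            raise ValueError(
                f"row {r} (subject {rec['subject_id']}): unknown label "
                f"{rec['label']!r}")
        path = volumes_dir / f"{rec['subject_id']}.nii.gz"
        if not path.exists():
            path = volumes_dir / f"{rec['subject_id']}.nii"
        if not path.exists():
            raise FileNotFoundError(
                f"no volume for subject {rec['subject_id']} in {volumes_dir}")
        vol = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
        if vol.shape != geometry.dims:
            raise ValueError(
                f"subject {rec['subject_id']}: volume shape {vol.shape} does "
                f"not match mask {geometry.dims}")
        rows.append(geometry.flatten(vol))
        labels.append(label_map[raw])
        sids.append(str(rec["subject_id"]))

    data = LabeledFeatureMatrix(X=np.stack(rows), labels=np.array(labels),
                                subject_ids=sids)
    return data, geometry


def write_feature_csv(values: np.ndarray, path: str | Path,
                      feature_ids: np.ndarray | None = None,
                      column: str = "value") -> None:
    """Per-feature vector (weights, probabilities, counts) as CSV."""
    values = np.asarray(values)
    if feature_ids is None:
        feature_ids = np.arange(values.shape[0])
    pd.DataFrame({"feature_id": feature_ids,
                  column: values}).to_csv(path, index=False)


def write_ground_truth_csv(effect: np.ndarray, path: str | Path) -> None:
    write_feature_csv(effect, path, column="effect")


def save_synthetic_spec(spec: SyntheticSpec, path: str | Path) -> None:
    """Persist a cohort recipe as JSON (mask stored as in-mask flat indices,
    C order, so the round-trip is lossless)."""
    import json
    geom = spec.geometry
    payload = {
        "geometry": {
            "dims": list(geom.dims),
            "voxel_size": list(geom.voxel_size),
            "mask_indices": np.flatnonzero(geom.mask.ravel()).tolist(),
        },
        "n_per_class": list(spec.n_per_class),
        "clusters": [{"center": list(c.center), "radius": c.radius,
                      "delta": c.delta, "sign": c.sign}
                     for c in spec.clusters],
        "noise_sd": spec.noise_sd,
        "smoothing_fwhm": spec.smoothing_fwhm,
        "variance_heterogeneity": spec.variance_heterogeneity,
        "baseline": spec.baseline,
        "seed": spec.seed,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_synthetic_spec(path: str | Path) -> SyntheticSpec:
    import json
    payload = json.loads(Path(path).read_text())
    g = payload["geometry"]
    dims = tuple(g["dims"])
    mask = np.zeros(int(np.prod(dims)), dtype=bool)
    mask[np.asarray(g["mask_indices"], dtype=int)] = True
    geometry = VolumeGeometry(dims=dims,
                              voxel_size=tuple(g["voxel_size"]),
                              mask=mask.reshape(dims))
    clusters = tuple(Cluster(center=tuple(c["center"]), radius=c["radius"],
                             delta=c["delta"], sign=c["sign"])
                     for c in payload["clusters"])
    return SyntheticSpec(geometry=geometry,
                         n_per_class=tuple(payload["n_per_class"]),
                         clusters=clusters,
                         noise_sd=payload["noise_sd"],
                         smoothing_fwhm=payload["smoothing_fwhm"],
                         variance_heterogeneity=payload["variance_heterogeneity"],
                         baseline=payload["baseline"],
                         seed=payload["seed"])
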
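"""Per-modality feature matrices from images and tabular measures.

Imaging modalities (gray- and white-matter volume maps) are vectorized
under two masking rules: an intersection mask keeping only voxels where
every subject provides data, and an ROI policy restricting gray matter to
an a-priori set of anatomically labeled regions (or white matter to the
white-matter compartment).  Tabular modalities (questionnaire sum scores,
cortisol release) become small matrices with named columns.  All matrices
carry per-column provenance so SVM weights can later be summarized per
anatomical region.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cortisol import CortisolFeature, screen_profiles

__all__ = [
    "VolumeImage",
    "ROIAtlas",
    "ModalityFeatures",
    "build_intersection_mask",
    "select_roi_voxels",
    "assemble_features",
    "restrict_to_common",
    "CLINICAL_SCALES",
    "ROI_POLICIES",
]

CLINICAL_SCALES = ("pswq", "bdi", "ius12", "stait")
ROI_POLICIES = ("gm_rois", "wm_all", "whole_brain")


@dataclass
class VolumeImage:
    """A 3D tissue-volume map on a shared analysis grid.

    ``data`` holds nonnegative per-voxel tissue volume estimates (the output
    of VBM-style segmentation/modulation, emulated here by the synthetic
    generator); ``affine`` is the NIfTI voxel-to-world transform, respected
    for I/O while all analysis is index-based.
    """

    subject_id: str
    data: np.ndarray
    affine: np.ndarray
    tissue: str = "GM"  # "GM" or "WM"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("image data must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(f"{self.subject_id}: non-finite voxel values")


@dataclass
class ROIAtlas:
    """Integer-labeled parcellation plus a white-matter compartment mask.

    ``table`` maps each nonzero label to a region name of the form
    ``"<area> <side>"`` (e.g. ``"Putamen R"``).
    """

    labels: np.ndarray
    table: Mapping[int, str]
    wm_mask: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.wm_mask = np.asarray(self.wm_mask, dtype=bool)
        present = set(np.unique(self.labels)) - {0}
        missing = present - set(self.table)
        if missing:
            raise ValueError(f"atlas labels without table entry: {sorted(missing)}")

    @property
    def region_names(self) -> list[str]:
        return [self.table[k] for k in sorted(self.table)]


@dataclass
class ModalityFeatures:
    """Subjects x features matrix for one modality, with column provenance.

    ``feature_meta`` is a DataFrame with one row per column: a ``region``
    label (score name for tabular modalities) and, for imaging modalities,
    the flat ``voxel`` index into the image grid.
    """

    modality: str
    matrix: np.ndarray
    subject_ids: list[str]
    feature_meta: pd.DataFrame

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("feature matrix must be 2D")
        if self.matrix.shape[0] != len(self.subject_ids):
            raise ValueError("rows must align with subject_ids")
        if self.matrix.shape[1] != len(self.feature_meta):
            raise ValueError("feature_meta must have one row per column")
        if self.matrix.shape[1] == 0:
            raise ValueError("feature matrix has no columns")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("feature matrix contains missing entries")

    def select_subjects(self, subject_ids: Sequence[str]) -> "ModalityFeatures":
        """Rows restricted to ``subject_ids``, in the given order."""
        index = {sid: i for i, sid in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in index]
        if missing:
            raise KeyError(f"subjects absent from {self.modality} features: {missing}")
        rows = [index[s] for s in subject_ids]
        return ModalityFeatures(
            modality=self.modality,
            matrix=self.matrix[rows],
            subject_ids=list(subject_ids),
            feature_meta=self.feature_meta,
        )


def _check_shared_grid(images: Sequence[VolumeImage]):
    shape = images[0].data.shape
    affine = images[0].affine
    for img in images[1:]:
        if img.data.shape != shape or not np.allclose(img.affine, affine):
            raise ValueError(
                f"grid mismatch: {img.subject_id} has shape {img.data.shape}, "
                f"expected {shape}"
            )


def build_intersection_mask(
    images: Sequence[VolumeImage], threshold: float = 0.01
) -> np.ndarray:
    """Voxels at which *every* subject provides data.

    A voxel is kept iff each subject's tissue volume exceeds ``threshold``
    there (strictly).  Equivalent to a per-voxel AND over subjects.
    """
    if len(images) == 0:
        raise ValueError("need at least one image")
    _check_shared_grid(images)
    mask = np.ones(images[0].data.shape, dtype=bool)
    for img in images:
        mask &= img.data > threshold
    return mask


def select_roi_voxels(
    mask: np.ndarray, atlas: ROIAtlas, roi_policy: str
) -> tuple[np.ndarray, pd.DataFrame]:
    """Flat voxel indices selected by an ROI policy, with provenance.

    Policies:
      - ``gm_rois``: intersection-mask voxels inside the labeled regions;
      - ``wm_all``: intersection-mask voxels inside the WM compartment;
      - ``whole_brain``: every intersection-mask voxel.

    Returns ``(flat_indices, feature_meta)`` where feature_meta has columns
    ``voxel`` and ``region``.
    """
    if roi_policy not in ROI_POLICIES:
        raise ValueError(f"unknown roi_policy {roi_policy!r}; expected {ROI_POLICIES}")
    if mask.shape != atlas.labels.shape:
        raise ValueError("mask and atlas are on different grids")
    flat_mask = mask.ravel()
    flat_labels = atlas.labels.ravel()
    if roi_policy == "gm_rois":
        keep = flat_mask & (flat_labels > 0)
        idx = np.flatnonzero(keep)
        regions = [atlas.table[int(k)] for k in flat_labels[idx]]
    elif roi_policy == "wm_all":
        keep = flat_mask & atlas.wm_mask.ravel()
        idx = np.flatnonzero(keep)
        regions = ["White matter"] * len(idx)
    else:  # whole_brain
        idx = np.flatnonzero(flat_mask)
        regions = [
            atlas.table[int(k)] if k > 0 else "Unlabeled" for k in flat_labels[idx]
        ]
    if len(idx) == 0:
        raise ValueError(f"roi_policy {roi_policy!r} selected no voxels")
    meta = pd.DataFrame({"voxel": idx, "region": regions})
    return idx, meta


def _image_features(
    modality: str,
    images: Sequence[VolumeImage],
    atlas: ROIAtlas,
    roi_policy: str,
    threshold: float,
) -> ModalityFeatures:
    mask = build_intersection_mask(images, threshold=threshold)
    idx, meta = select_roi_voxels(mask, atlas, roi_policy)
    matrix = np.stack([img.data.ravel()[idx] for img in images])
    return ModalityFeatures(
        modality=modality,
        matrix=matrix,
        subject_ids=[img.subject_id for img in images],
        feature_meta=meta,
    )


def assemble_features(
    cohort,
    modality: str,
    roi_policy: str | None = None,
    threshold: float = 0.01,
    log_base: str = "e",
) -> ModalityFeatures:
    """Build one modality's feature matrix from a cohort.

    ``modality`` is one of ``clinical``, ``cortisol``, ``gm``, ``wm``.
    Subjects lacking the modality (an incomplete cortisol profile) are
    dropped from that modality's rows; the caller aligns subjects across
    modalities with :func:`restrict_to_common` before any fusion.
    """
    if modality == "clinical":
        matrix = np.array(
            [[getattr(s, scale) for scale in CLINICAL_SCALES] for s in cohort.subjects],
            dtype=float,
        )
        meta = pd.DataFrame({"region": [s.upper() for s in CLINICAL_SCALES]})
        return ModalityFeatures(
            modality="clinical",
            matrix=matrix,
            subject_ids=[s.subject_id for s in cohort.subjects],
            feature_meta=meta,
        )
    if modality == "cortisol":
        feats, excluded = screen_profiles(cohort.cortisol, log_base=log_base)
        if not feats:
            raise ValueError("no complete cortisol profiles: cannot build features")
        return ModalityFeatures(
            modality="cortisol",
            matrix=np.array([[f.log_auc] for f in feats]),
            subject_ids=[f.subject_id for f in feats],
            feature_meta=pd.DataFrame({"region": ["log_auc"]}),
        )
    if modality in ("gm", "wm"):
        images = cohort.gm if modality == "gm" else cohort.wm
        if roi_policy is None:
            roi_policy = "gm_rois" if modality == "gm" else "wm_all"
        return _image_features(modality, images, cohort.atlas, roi_policy, threshold)
    raise ValueError(f"unknown modality {modality!r}")


def restrict_to_common(
    modalities: Mapping[str, ModalityFeatures],
) -> dict[str, ModalityFeatures]:
    """Restrict every modality to the subjects present in all of them.

    Row order follows the first modality's subject order, so all returned
    matrices are row-aligned by subject_id.
    """
    if not modalities:
        return {}
    mods = list(modalities.values())
    common = set(mods[0].subject_ids)
    for m in mods[1:]:
        common &= set(m.subject_ids)
    if not common:
        raise ValueError("no subject is present in every modality")
    order = [sid for sid in mods[0].subject_ids if sid in common]
    return {name: m.select_subjects(order) for name, m in modalities.items()}
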
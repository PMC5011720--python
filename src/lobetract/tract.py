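"""Streamline selection, lobar segmentation and scalar statistics for tractograms.

The pipeline implemented here mirrors a classical virtual-dissection workflow:
a whole-brain (or bundle) tractogram is filtered with inclusion ("AND") and
exclusion ("NOT") region masks, sharply bending fibers are trimmed, every
retained streamline point is assigned a lobar label by nearest-neighbor lookup
in an atlas label volume, points are clustered by label into lobar segments,
and per-segment / whole-tract FA and MD statistics are computed by sampling
the scalar volumes at the streamline points.

Coordinate convention: streamline points live in world millimetres (RAS-mm);
voxel lookup goes through the inverse of the volume affine with
round-half-away-from-zero, 0-based voxel indices.  TrackVis TRK files store
points in a corner-of-voxel convention; :func:`Tractogram.from_trk` relies on
nibabel to normalise them to RAS-mm on read.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

__all__ = [
    "Tractogram",
    "ScalarVolume",
    "LabelVolume",
    "LabeledSegmentSet",
    "SegmentStats",
    "IccResult",
    "LOBE_LABELS",
    "select_and",
    "select_not",
    "streamline_touches",
    "filter_bend",
    "label_points",
    "segment_by_label",
    "segment_stats",
    "icc",
]

#: Canonical lobar label vocabulary (0 is background).
LOBE_LABELS = {0: "background", 1: "frontal", 2: "insular", 3: "temporal",
               4: "parietal", 5: "occipital"}

#: Segments with fewer retained points than this are flagged low-confidence.
MIN_SEGMENT_POINTS = 10


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class Tractogram:
    """Ordered 3D polylines in world mm plus the voxel<->world affine."""

    streamlines: list
    affine: np.ndarray
    shape: tuple | None = None
    voxel_size: tuple | None = None

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is not invertible")
        self.streamlines = [np.asarray(s, dtype=float) for s in self.streamlines]
        for i, s in enumerate(self.streamlines):
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ValueError(f"streamline {i} must be an (n>=2, 3) array")

    def __len__(self):
        return len(self.streamlines)

    @property
    def n_points(self) -> int:
        return sum(len(s) for s in self.streamlines)

    @classmethod
    def from_trk(cls, path) -> "Tractogram":
        import nibabel.streamlines as nibs

        trk = nibs.load(str(path))  # points come back in RAS-mm
        hdr = trk.header
        return cls(
            streamlines=[np.asarray(s) for s in trk.streamlines],
            affine=np.asarray(hdr["voxel_to_rasmm"]),
            shape=tuple(int(d) for d in hdr["dimensions"]),
            voxel_size=tuple(float(v) for v in hdr["voxel_sizes"]),
        )

    def to_trk(self, path) -> None:
        import nibabel.streamlines as nibs

        if self.shape is None or self.voxel_size is None:
            raise ValueError("grid shape and voxel size are required to write TRK")
        header = {
            "voxel_to_rasmm": self.affine.astype(np.float32),
            "voxel_sizes": np.asarray(self.voxel_size, dtype=np.float32),
            "dimensions": np.asarray(self.shape, dtype=np.int16),
            "voxel_order": "RAS",
        }
        tg = nibs.Tractogram(self.streamlines, affine_to_rasmm=np.eye(4))
        nibs.save(tg, str(path), header=header)

    def with_streamlines(self, streamlines) -> "Tractogram":
        return Tractogram(streamlines=list(streamlines), affine=self.affine,
                          shape=self.shape, voxel_size=self.voxel_size)


@dataclass
class ScalarVolume:
    """A scalar field (e.g. FA in [0, 1] or MD in 1e-3 mm^2/s) on a voxel grid."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume contains non-finite values")

    @classmethod
    def from_nifti(cls, path) -> "ScalarVolume":
        import nibabel as nib

        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata()), img.affine)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), str(path))


@dataclass
class LabelVolume:
    """Integer lobar labels on a voxel grid; 0 is background."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        data = np.asarray(self.data)
        if not np.issubdtype(data.dtype, np.integer):
            if not np.allclose(data, np.round(data)):
                raise ValueError("label volume must contain integers")
            data = np.round(data).astype(np.int32)
        if data.min() < 0:
            raise ValueError("labels must be non-negative")
        self.data = data
        self.affine = np.asarray(self.affine, dtype=float)

    @classmethod
    def from_nifti(cls, path) -> "LabelVolume":
        import nibabel as nib

        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata()), img.affine)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        nib.save(nib.Nifti1Image(self.data.astype(np.int16), self.affine), str(path))

    def as_mask(self) -> np.ndarray:
        return self.data > 0


# ---------------------------------------------------------------------------
# coordinate helpers
# ---------------------------------------------------------------------------

def world_to_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map world-mm points to continuous voxel coordinates via the inverse affine."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    inv = np.linalg.inv(affine)
    return points @ inv[:3, :3].T + inv[:3, 3]


def round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (0.5 -> 1, -0.5 -> -1), returning integers."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(np.int64)


def _check_same_affine(affine_a: np.ndarray, affine_b: np.ndarray, what: str) -> None:
    if not np.allclose(affine_a, affine_b, atol=1e-6):
        raise ValueError(
            f"affine mismatch between tractogram and {what}:\n"
            f"{np.asarray(affine_a)}\nvs\n{np.asarray(affine_b)}"
        )


def _as_mask(roi) -> tuple[np.ndarray, np.ndarray]:
    """Accept a LabelVolume / ScalarVolume / array and return (bool mask, affine)."""
    if isinstance(roi, LabelVolume):
        return roi.as_mask(), roi.affine
    if isinstance(roi, ScalarVolume):
        return roi.data > 0, roi.affine
    raise TypeError("ROI must be a LabelVolume or ScalarVolume mask")


# ---------------------------------------------------------------------------
# streamline selection
# ---------------------------------------------------------------------------

def streamline_touches(tract: Tractogram, roi) -> np.ndarray:
    """Boolean array: does each streamline have >=1 point inside the ROI mask?"""
    mask, affine = _as_mask(roi)
    _check_same_affine(tract.affine, affine, "ROI")
    shape = mask.shape
    out = np.zeros(len(tract), dtype=bool)
    for i, sl in enumerate(tract.streamlines):
        ijk = round_half_away(world_to_voxel(sl, tract.affine))
        inside = np.all((ijk >= 0) & (ijk < np.asarray(shape)), axis=1)
        if inside.any():
            ii, jj, kk = ijk[inside].T
            out[i] = bool(mask[ii, jj, kk].any())
    return out


def select_and(tract: Tractogram, roi_a, roi_b) -> Tractogram:
    """Keep streamlines passing through BOTH ROIs (two-ROI inclusion), order kept."""
    keep = streamline_touches(tract, roi_a) & streamline_touches(tract, roi_b)
    return tract.with_streamlines(
        [s for s, k in zip(tract.streamlines, keep) if k]
    )


def select_not(tract: Tractogram, roi) -> Tractogram:
    """Remove every streamline with >=1 point inside the exclusion ROI."""
    keep = ~streamline_touches(tract, roi)
    return tract.with_streamlines(
        [s for s, k in zip(tract.streamlines, keep) if k]
    )


# ---------------------------------------------------------------------------
# bend filtering
# ---------------------------------------------------------------------------

def turning_angles_deg(streamline: np.ndarray) -> np.ndarray:
    """Angles (degrees) between consecutive segments of a polyline."""
    v = np.diff(np.asarray(streamline, dtype=float), axis=0)
    norms = np.linalg.norm(v, axis=1)
    norms = np.where(norms == 0, 1.0, norms)
    u = v / norms[:, None]
    cosang = np.clip(np.sum(u[:-1] * u[1:], axis=1), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def filter_bend(tract: Tractogram, max_angle_deg: float = 30.0,
                drop: bool = False) -> Tractogram:
    """Trim streamlines at the first turning angle exceeding ``max_angle_deg``.

    The default mimics streamline reconstruction tools that stop tracking at
    sharp bends.  With ``drop=True`` offending streamlines are discarded
    entirely instead of truncated.  Streamlines reduced below 2 points are
    dropped.
    """
    if not (0.0 < max_angle_deg <= 180.0):
        raise ValueError("max_angle_deg must be in (0, 180]")
    kept = []
    for sl in tract.streamlines:
        ang = turning_angles_deg(sl)
        bad = np.nonzero(ang > max_angle_deg)[0]
        if bad.size == 0:
            kept.append(sl)
        elif not drop:
            # angle i involves points i, i+1, i+2 -> keep points 0..i+1
            cut = bad[0] + 2
            if cut >= 2:
                kept.append(sl[:cut])
    return tract.with_streamlines(kept)


# ---------------------------------------------------------------------------
# lobar labeling and segmentation
# ---------------------------------------------------------------------------

def label_points(tract: Tractogram, labels: LabelVolume) -> list[np.ndarray]:
    """Nearest-neighbor lobar label for every streamline point.

    Points are mapped through the inverse affine, rounded half-away-from-zero
    to the nearest voxel, and assigned that voxel's label; points falling
    outside the grid get the background label 0.
    """
    _check_same_affine(tract.affine, labels.affine, "label volume")
    shape = np.asarray(labels.data.shape)
    out = []
    for sl in tract.streamlines:
        ijk = round_half_away(world_to_voxel(sl, tract.affine))
        lab = np.zeros(len(sl), dtype=np.int64)
        inside = np.all((ijk >= 0) & (ijk < shape), axis=1)
        if inside.any():
            ii, jj, kk = ijk[inside].T
            lab[inside] = labels.data[ii, jj, kk]
        out.append(lab)
    return out


@dataclass
class LabeledSegmentSet:
    """Streamline points grouped by lobar label, with provenance.

    ``points`` holds every point of the tractogram (world mm), ``labels`` the
    per-point lobar label (0 = background) and ``streamline_idx`` the index of
    the parent streamline, so segments can be traced back to fibers.
    """

    points: np.ndarray
    labels: np.ndarray
    streamline_idx: np.ndarray
    affine: np.ndarray

    @property
    def present_labels(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.labels) if v != 0)

    def segment(self, label: int) -> tuple[np.ndarray, np.ndarray]:
        """(points, streamline indices) of one lobar segment."""
        m = self.labels == label
        return self.points[m], self.streamline_idx[m]


def segment_by_label(tract: Tractogram,
                     point_labels: list[np.ndarray]) -> LabeledSegmentSet:
    """Cluster streamline points sharing the same lobar label into segments."""
    if len(point_labels) != len(tract):
        raise ValueError("point_labels must align with the tractogram")
    pts = np.concatenate(tract.streamlines) if len(tract) else np.empty((0, 3))
    labs = (np.concatenate(point_labels) if point_labels
            else np.empty(0, dtype=np.int64))
    sidx = np.concatenate(
        [np.full(len(s), i, dtype=np.int64) for i, s in enumerate(tract.streamlines)]
    ) if len(tract) else np.empty(0, dtype=np.int64)
    if labs.size and not (labs > 0).any():
        warnings.warn("all points are background-labeled; segment set is empty",
                      stacklevel=2)
    return LabeledSegmentSet(points=pts, labels=labs, streamline_idx=sidx,
                             affine=tract.affine)


# ---------------------------------------------------------------------------
# scalar statistics
# ---------------------------------------------------------------------------

def _sample_volume(points: np.ndarray, vol: ScalarVolume,
                   interp: str) -> tuple[np.ndarray, np.ndarray]:
    """Sample a scalar volume at world points; returns (values, valid mask)."""
    vox = world_to_voxel(points, vol.affine)
    shape = np.asarray(vol.data.shape)
    if interp == "nearest":
        ijk = round_half_away(vox)
        valid = np.all((ijk >= 0) & (ijk < shape), axis=1)
        vals = np.zeros(len(points))
        if valid.any():
            ii, jj, kk = ijk[valid].T
            vals[valid] = vol.data[ii, jj, kk]
        return vals, valid
    if interp == "trilinear":
        valid = np.all((vox >= 0) & (vox <= shape - 1), axis=1)
        vals = np.zeros(len(points))
        if valid.any():
            vals[valid] = ndimage.map_coordinates(
                vol.data, vox[valid].T, order=1, mode="nearest")
        return vals, valid
    raise ValueError("interp must be 'nearest' or 'trilinear'")


@dataclass
class SegmentStats:
    """Per-lobe and whole-tract scalar summaries."""

    per_segment: object  # pandas.DataFrame
    tract_mean_fa: float
    tract_mean_md: float
    n_points_total: int
    n_skipped: int
    interp: str
    weighting: str

    def to_frame(self):
        return self.per_segment.copy()


def segment_stats(segments: LabeledSegmentSet, fa: ScalarVolume,
                  md: ScalarVolume, interp: str = "trilinear",
                  weighting: str = "point") -> SegmentStats:
    """Mean FA / MD per lobar segment and for the whole tract.

    ``weighting='point'`` averages over retained points (each point once);
    ``weighting='streamline'`` first averages within each streamline's
    in-segment points, then across streamlines.
    """
    import pandas as pd

    _check_same_affine(fa.affine, segments.affine, "FA volume")
    _check_same_affine(md.affine, segments.affine, "MD volume")
    if weighting not in ("point", "streamline"):
        raise ValueError("weighting must be 'point' or 'streamline'")

    fa_vals, fa_ok = _sample_volume(segments.points, fa, interp)
    md_vals, md_ok = _sample_volume(segments.points, md, interp)
    ok = fa_ok & md_ok
    n_skipped = int((~ok).sum())

    def _mean(vals, sel, sl_idx):
        if not sel.any():
            return np.nan
        if weighting == "point":
            return float(vals[sel].mean())
        per_sl = pd.Series(vals[sel]).groupby(sl_idx[sel]).mean()
        return float(per_sl.mean())

    rows = []
    for lab in segments.present_labels:
        sel = (segments.labels == lab) & ok
        n_pts = int(sel.sum())
        rows.append({
            "label": lab,
            "lobe": LOBE_LABELS.get(lab, str(lab)),
            "n_points": n_pts,
            "n_streamlines": int(np.unique(segments.streamline_idx[sel]).size),
            "mean_fa": _mean(fa_vals, sel, segments.streamline_idx),
            "mean_md": _mean(md_vals, sel, segments.streamline_idx),
            "low_confidence": n_pts < MIN_SEGMENT_POINTS,
        })
    per_segment = pd.DataFrame(
        rows, columns=["label", "lobe", "n_points", "n_streamlines",
                       "mean_fa", "mean_md", "low_confidence"])

    tract_fa = _mean(fa_vals, ok, segments.streamline_idx)
    tract_md = _mean(md_vals, ok, segments.streamline_idx)
    return SegmentStats(per_segment=per_segment, tract_mean_fa=tract_fa,
                        tract_mean_md=tract_md,
                        n_points_total=int(ok.sum()), n_skipped=n_skipped,
                        interp=interp, weighting=weighting)


# ---------------------------------------------------------------------------
# reliability (intraclass correlation)
# ---------------------------------------------------------------------------

@dataclass
class IccResult:
    value: float
    ci_low: float
    ci_high: float
    form: str
    n_targets: int
    n_raters: int
    level: float


def icc(ratings: np.ndarray, form: str = "A-1", level: float = 0.95) -> IccResult:
    """Single-measure intraclass correlation of an n-targets x k-raters matrix.

    ``form='A-1'`` is the two-way absolute-agreement single-measure ICC
    (suited to repeat-extraction reliability, where systematic rater offsets
    count as disagreement); ``form='C-1'`` is the consistency variant.
    Confidence bounds follow the standard F-distribution construction.
    """
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("ratings must be an (n>=2, k>=2) matrix")
    if not np.all(np.isfinite(X)):
        raise ValueError("ratings contain missing or non-finite cells")
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    if np.allclose(row_means, row_means[0]):
        raise ValueError("degenerate input: zero variance across targets")

    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    alpha = 1.0 - level

    if form in ("C-1", "ICC3", "consistency"):
        value = (msr - mse) / (msr + (k - 1) * mse)
        f_obs = msr / mse
        f_u = stats.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
        f_l = stats.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
        lo = (f_obs / f_u - 1) / (f_obs / f_u + k - 1)
        hi = (f_obs * f_l - 1) / (f_obs * f_l + k - 1)
        return IccResult(float(value), float(lo), float(hi), "C-1", n, k, level)
    if form not in ("A-1", "ICC2", "agreement"):
        raise ValueError("form must be 'A-1' or 'C-1'")

    value = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    # McGraw & Wong (1996) CI for ICC(A,1)
    a = k * value / (n * (1 - value)) if value < 1 else np.inf
    b = 1 + k * value * (n - 1) / (n * (1 - value)) if value < 1 else np.inf
    if np.isfinite(a):
        v_num = (a * msc + b * mse) ** 2
        v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        dof = v_num / v_den
        f_u = stats.f.ppf(1 - alpha / 2, n - 1, dof)
        f_l = stats.f.ppf(1 - alpha / 2, dof, n - 1)
        lo = n * (msr - f_u * mse) / (
            f_u * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_l * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_l * msr)
    else:
        lo = hi = 1.0
    return IccResult(float(value), float(lo), float(hi), "A-1", n, k, level)
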
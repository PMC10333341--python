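"""Two-step GLM pre-whitening and confound removal for ROI time series.

Step 1 regresses each ROI series on the six motion parameters, estimates an
AR(1) coefficient per ROI from the residuals, and filters the *raw* series
as ``y_t - phi * y_{t-1}`` (first sample dropped, so T -> T-1). Step 2
removes motion, white-matter and CSF signals from the whitened data by
ordinary least squares. Spatial preprocessing (realignment, normalisation,
denoising, smoothing) is upstream and out of scope; this module ingests its
outputs. No band-pass filtering or global signal regression is applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

AR1_CLIP = 0.99


class PrepError(ValueError):
    pass


@dataclass
class PrewhitenResult:
    """Whitened data plus the per-ROI AR(1) estimates that produced it."""

    cleaned: np.ndarray          # (n_roi, T-1)
    ar1_per_roi: np.ndarray      # (n_roi,), in (-1, 1)
    confound_r2: np.ndarray      # variance fraction removed by motion, (n_roi,)
    degenerate_rois: list[int] = field(default_factory=list)


def _as_confound_matrix(*series: np.ndarray, n_time: int) -> np.ndarray:
    """Stack confound series into a (T, p) design, intercept first."""
    cols = [np.ones(n_time)]
    for s in series:
        s = np.asarray(s, dtype=float)
        if s.ndim == 1:
            s = s[None, :]
        if s.shape[-1] != n_time:
            raise PrepError(
                f"confound length {s.shape[-1]} does not match time length "
                f"{n_time}"
            )
        cols.extend(s)
    return np.column_stack(cols)


def _residualize(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residuals of each row of Y (series in rows) on the columns of X."""
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)
    return Y - (X @ beta).T


def estimate_ar1(residuals: np.ndarray) -> tuple[np.ndarray, list[int]]:
    """Lag-1 least-squares AR(1) coefficient per row of ``residuals``.

    Rows with zero variance are degenerate: phi is set to 0 and the row
    index returned in the second element.
    """
    R = residuals - residuals.mean(axis=1, keepdims=True)
    num = np.sum(R[:, 1:] * R[:, :-1], axis=1)
    den = np.sum(R[:, :-1] ** 2, axis=1)
    # treat numerically-constant rows (residual scale at fp noise level)
    # as degenerate, not just exact zeros
    scale = np.abs(residuals).max() + 1.0
    floor = (1e-10 * scale) ** 2 * R.shape[1]
    degenerate = np.flatnonzero(den <= floor)
    phi = np.zeros(R.shape[0])
    ok = den > floor
    phi[ok] = num[ok] / den[ok]
    if degenerate.size:
        logger.warning(
            "AR(1) undefined for constant ROI series %s; phi set to 0",
            degenerate.tolist(),
        )
    clipped = np.abs(phi) >= 1.0
    if clipped.any():
        logger.warning(
            "AR(1) estimates at or beyond unit root for ROIs %s; "
            "clipped to +/-%.2f", np.flatnonzero(clipped).tolist(), AR1_CLIP,
        )
        phi = np.clip(phi, -AR1_CLIP, AR1_CLIP)
    return phi, degenerate.tolist()


def prewhiten_ar1(raw: np.ndarray, motion: np.ndarray) -> PrewhitenResult:
    """Motion-filter, estimate AR(1) per ROI, and whiten the raw series.

    Parameters
    ----------
    raw : (n_roi, T) array
    motion : (6, T) array of realignment parameters

    Returns
    -------
    PrewhitenResult with ``cleaned`` of shape (n_roi, T-1).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2:
        raise PrepError("raw must be a 2-D ROI x time matrix")
    if not np.isfinite(raw).all():
        raise PrepError("raw time series contain non-finite values")
    n_roi, T = raw.shape
    if T <= 10:
        raise PrepError(f"need more than 10 time points, got {T}")
    motion = np.atleast_2d(np.asarray(motion, dtype=float))
    if motion.shape[1] != T:
        raise PrepError(
            f"motion length {motion.shape[1]} does not match time length {T}"
        )
    X = _as_confound_matrix(motion, n_time=T)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise PrepError("motion design is rank deficient")

    resid = _residualize(raw, X)
    phi, degenerate = estimate_ar1(resid)

    whitened = raw[:, 1:] - phi[:, None] * raw[:, :-1]

    raw_var = raw.var(axis=1)
    resid_var = resid.var(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(raw_var > 0, 1.0 - resid_var / raw_var, 0.0)

    return PrewhitenResult(
        cleaned=whitened,
        ar1_per_roi=phi,
        confound_r2=r2,
        degenerate_rois=degenerate,
    )


def remove_confounds(
    whitened: np.ndarray,
    motion: np.ndarray,
    wm: np.ndarray,
    csf: np.ndarray,
) -> np.ndarray:
    """Regress motion, WM and CSF out of whitened data (intercept included).

    Confound series one sample longer than the whitened data (the raw length)
    are trimmed by dropping their first sample, matching the whitening filter.
    Collinear confound columns are dropped with a warning.
    """
    whitened = np.asarray(whitened, dtype=float)
    n_roi, T = whitened.shape

    def trim(s: np.ndarray) -> np.ndarray:
        s = np.atleast_2d(np.asarray(s, dtype=float))
        if s.shape[1] == T + 1:
            return s[:, 1:]
        if s.shape[1] == T:
            return s
        raise PrepError(
            f"confound length {s.shape[1]} matches neither whitened length "
            f"{T} nor raw length {T + 1}"
        )

    X = _as_confound_matrix(trim(motion), trim(wm), trim(csf), n_time=T)
    # Drop collinear columns (keep intercept) via rank-revealing QR on the
    # column-scaled design.
    scale = np.linalg.norm(X, axis=0)
    scale[scale == 0] = 1.0
    q, r, piv = _qr_pivot(X / scale)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * np.abs(r[0, 0])))
    if rank < X.shape[1]:
        keep = np.sort(piv[:rank])
        dropped = sorted(set(range(X.shape[1])) - set(keep.tolist()))
        cond = np.linalg.cond(X)
        logger.warning(
            "collinear confound columns %s dropped (condition number %.3g)",
            dropped, cond,
        )
        X = X[:, keep]
    return _residualize(whitened, X)


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


def extract_roi_timeseries(
    image: np.ndarray, labels: np.ndarray, n_roi: int = 111
) -> np.ndarray:
    """Average a 4-D image over the voxels of each parcellation label.

    ``labels`` is an integer image on the same voxel grid as ``image``;
    voxel value v maps to ROI index v-1 and 0 is background. ROIs with no
    voxels produce an all-NaN row and a warning.
    """
    image = np.asarray(image, dtype=float)
    labels = np.asarray(labels)
    if image.ndim != 4:
        raise PrepError("image must be 4-D (x, y, z, t)")
    if labels.shape != image.shape[:3]:
        raise PrepError(
            f"label grid {labels.shape} does not match image grid "
            f"{image.shape[:3]}"
        )
    if labels.min() < 0 or labels.max() > n_roi:
        raise PrepError(f"label values must lie in 0..{n_roi}")
    T = image.shape[3]
    out = np.full((n_roi, T), np.nan)
    flat_img = image.reshape(-1, T)
    flat_lab = labels.reshape(-1)
    empty = []
    for roi in range(n_roi):
        mask = flat_lab == roi + 1
        if not mask.any():
            empty.append(roi)
            continue
        out[roi] = flat_img[mask].mean(axis=0)
    if empty:
        logger.warning("parcellation has no voxels for ROIs %s", empty)
    return out


def extract_from_nifti(image_path, labels_path, n_roi: int = 111
                       ) -> np.ndarray:
    """Load a 4-D NIfTI image and an integer parcellation and extract ROI
    series; requires the optional ``nibabel`` dependency."""
    import nibabel as nib

    image = np.asanyarray(nib.load(str(image_path)).dataobj, dtype=float)
    labels = np.asanyarray(nib.load(str(labels_path)).dataobj)
    labels = np.rint(labels).astype(int)
    return extract_roi_timeseries(image, labels, n_roi=n_roi)


def preprocess_subject(
    raw: np.ndarray,
    motion: np.ndarray,
    wm: np.ndarray,
    csf: np.ndarray,
) -> tuple[np.ndarray, PrewhitenResult]:
    """Full per-subject prep: prewhiten then remove confounds.

    Returns the confound-cleaned (n_roi, T-1) matrix and the intermediate
    whitening result.
    """
    pw = prewhiten_ar1(raw, motion)
    cleaned = remove_confounds(pw.cleaned, motion, wm, csf)
    return cleaned, pw
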
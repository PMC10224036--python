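"""Z-spectrum normalisation, MTR asymmetry and GluCEST quantification.

The GluCEST metric is the magnetisation transfer ratio asymmetry of the
normalised Z-spectrum evaluated at the glutamate amine resonance:

    GluCEST (%) = 100 * (S_sat(-3.0 ppm) - S_sat(+3.0 ppm)) / S_sat(-3.0 ppm)

with the -3.0 ppm sample (the symmetric upfield reference), not S0, as
the denominator.  ROI statistics use the sample (n-1) standard deviation.
"""

from __future__ import annotations

import logging

import numpy as np

from .core import GluCestMap, RoiSummary, ZStack

logger = logging.getLogger(__name__)

GLU_OFFSET_PPM = 3.0


def normalize_zstack(cest: ZStack) -> ZStack:
    """Divide each voxel's saturated series by its unsaturated S0.

    Voxels with non-positive S0 are removed from the mask (and logged)
    rather than producing infinities.
    """
    if cest.s0 is None:
        raise ValueError("ZStack has no S0 reference image")
    good = cest.s0 > 0
    n_bad = int(np.count_nonzero(cest.mask & ~good))
    if n_bad:
        logger.info("normalisation removed %d voxel(s) with S0 <= 0", n_bad)
    data = np.zeros_like(cest.data)
    data[good] = cest.data[good] / cest.s0[good, None]
    return ZStack(
        data=data,
        offsets=cest.offsets.copy(),
        s0=None,
        mask=cest.mask & good,
        offset_valid=None if cest.offset_valid is None else cest.offset_valid.copy(),
    )


def mtr_asym_spectrum(
    z: np.ndarray, offsets: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """MTR asymmetry of one normalised Z-spectrum, in percent.

    Returns ``(positive_offsets, asym_percent)`` where
    ``asym(dw) = 100 * (S(-dw) - S(+dw)) / S(-dw)`` for every positive
    offset on the grid.  Requires a grid symmetric about 0; entries whose
    upfield reference is zero come back as NaN.
    """
    z = np.asarray(z, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    if z.shape[-1] != offsets.size:
        raise ValueError("z and offsets lengths differ")
    if not np.allclose(offsets, -offsets[::-1]):
        raise ValueError("offset grid must be symmetric about 0")
    pos = offsets > 0
    s_plus = z[..., pos]
    s_minus = z[..., ::-1][..., pos]  # mirrored: value at -dw
    with np.errstate(divide="ignore", invalid="ignore"):
        asym = 100.0 * (s_minus - s_plus) / s_minus
    asym = np.where(s_minus == 0, np.nan, asym)
    return offsets[pos], asym


def glucest_map(cest_corrected: ZStack) -> GluCestMap:
    """Voxelwise GluCEST percentage from a normalised, B0-corrected stack.

    Both +-3.0 ppm must be on the offset grid.  The output mask is the
    stack mask intersected with per-offset validity at both samples (if
    the stack carries one) and with a positive upfield reference signal.
    """
    i_minus = cest_corrected.offset_index(-GLU_OFFSET_PPM)
    i_plus = cest_corrected.offset_index(+GLU_OFFSET_PPM)
    s_minus = cest_corrected.data[..., i_minus]
    s_plus = cest_corrected.data[..., i_plus]
    mask = cest_corrected.mask & (s_minus > 0)
    if cest_corrected.offset_valid is not None:
        mask &= (
            cest_corrected.offset_valid[..., i_minus]
            & cest_corrected.offset_valid[..., i_plus]
        )
    value = np.zeros(cest_corrected.shape)
    value[mask] = 100.0 * (s_minus[mask] - s_plus[mask]) / s_minus[mask]
    return GluCestMap(value=value, mask=mask, provenance={"offset_ppm": GLU_OFFSET_PPM})


def roi_quantify(
    glu_map: GluCestMap, roi: np.ndarray, roi_label: str = "roi"
) -> RoiSummary:
    """Mean and sample SD of the GluCEST map over valid ROI voxels."""
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != glu_map.value.shape:
        raise ValueError("ROI geometry does not match map")
    sel = roi & glu_map.mask
    n = int(np.count_nonzero(sel))
    if n == 0:
        raise ValueError("ROI does not overlap any valid map voxel")
    vals = glu_map.value[sel]
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return RoiSummary(roi_label=roi_label, n_voxels=n, mean=float(np.mean(vals)), sd=sd)
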
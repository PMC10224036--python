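"""Double-angle B1 mapping and B1 handling policies.

For an ideal gradient-echo pair at nominal flip angles alpha and 2*alpha,
``S(2a)/S(a) = sin(2*b1*a)/sin(b1*a) = 2*cos(b1*a)``, so the achieved
angle per voxel is ``arccos(S_2a / (2 * S_a))`` and the relative B1 is
achieved/nominal.  Voxels whose intensity ratio leaves the arccos domain
(noise, signal voids) are flagged invalid, never clipped into a value.

How a relative-B1 map should feed back into GluCEST values is a protocol
choice, so it is an explicit, logged policy:

- ``scale``   — first-order correction, value / relative (default);
- ``exclude`` — drop voxels with ``|relative - 1|`` above a threshold;
- ``none``    — pass-through (still recorded in provenance).
"""

from __future__ import annotations

import numpy as np

from .core import B1Map, GluCestMap

POLICIES = ("scale", "exclude", "none")
DEFAULT_EXCLUDE_THRESHOLD = 0.3


def compute_relative_b1(
    img_a: np.ndarray,
    img_b: np.ndarray,
    nominal_angle: float = 30.0,
    mask: np.ndarray | None = None,
) -> B1Map:
    """Relative B1 map from images at nominal ``alpha`` and ``2*alpha`` degrees."""
    img_a = np.asarray(img_a, dtype=float)
    img_b = np.asarray(img_b, dtype=float)
    if img_a.shape != img_b.shape:
        raise ValueError("angle images must share geometry")
    if not 0 < nominal_angle < 90:
        raise ValueError("nominal angle must be in (0, 90) degrees")
    if mask is None:
        mask = np.ones(img_a.shape, dtype=bool)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = img_b / (2.0 * img_a)
    valid = mask & (img_a > 0) & np.isfinite(ratio) & (np.abs(ratio) <= 1.0)
    actual_deg = np.zeros(img_a.shape)
    actual_deg[valid] = np.degrees(np.arccos(ratio[valid]))
    relative = np.ones(img_a.shape)
    relative[valid] = actual_deg[valid] / nominal_angle
    valid &= relative > 0
    return B1Map(relative=relative, mask=valid)


def apply_b1_policy(
    glucest: GluCestMap,
    b1: B1Map,
    policy: str = "scale",
    exclude_threshold: float = DEFAULT_EXCLUDE_THRESHOLD,
) -> GluCestMap:
    """Apply a declared B1-handling policy to a GluCEST map.

    The applied policy (and threshold, for ``exclude``) is recorded in the
    output provenance so every map states how B1 was handled.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown B1 policy {policy!r}; expected one of {POLICIES}")
    if b1.relative.shape != glucest.value.shape:
        raise ValueError("B1 map geometry does not match GluCEST map")
    value = glucest.value.copy()
    mask = glucest.mask.copy()
    provenance = dict(glucest.provenance)
    provenance["b1_policy"] = policy
    if policy == "scale":
        mask &= b1.mask
        value[mask] = value[mask] / b1.relative[mask]
    elif policy == "exclude":
        provenance["b1_exclude_threshold"] = exclude_threshold
        mask &= b1.mask & (np.abs(b1.relative - 1.0) <= exclude_threshold)
    return GluCestMap(value=value, mask=mask, provenance=provenance)
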
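"""Synthetic CEST / WASSR / dual-angle data with known ground truth.

The fast forward model is a sum of Lorentzian saturation dips on the
Z-spectrum — the standard phenomenological description of direct water
saturation plus exchange-mediated pools (glutamate amine at +3.0 ppm,
an upfield NOE pool).  A two-pool Bloch–McConnell integrator is provided
as a physics oracle for cross-checking the Lorentzian model in the slow
exchange regime; it is deliberately not used for image-scale simulation.

Saturation-efficiency scaling with the local RF field is first order:
pool amplitudes scale linearly with the relative B1.  B0 inhomogeneity
shifts every resonance by the local field offset.  Noise is Rician, the
magnitude-image statistic of complex Gaussian receiver noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import expm

from .core import B0Map, B1Map, GluCestMap, ZStack

GAMMA_HZ_PER_UT = 42.577478  # proton gyromagnetic ratio, Hz/uT


@dataclass(frozen=True)
class Pool:
    """One saturation pool on the Z-spectrum.

    For the Lorentzian model ``amplitude`` is the peak saturation depth in
    [0, 1) and ``width`` the FWHM in ppm.  For the Bloch–McConnell model
    ``fraction`` is the relative pool size (solute/water proton ratio) and
    ``exchange_rate`` the solute->water rate in 1/s; relaxation times are in
    seconds.
    """

    shift: float
    amplitude: float = 0.0
    width: float = 1.0
    label: str = ""
    fraction: float | None = None
    exchange_rate: float | None = None
    t1: float = 1.5
    t2: float = 0.05

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("pool amplitude must be >= 0")
        if self.width <= 0:
            raise ValueError("pool width must be positive")
        if self.exchange_rate is not None and self.exchange_rate <= 0:
            raise ValueError("exchange rate must be positive")
        if self.fraction is not None and not 0 <= self.fraction < 1:
            raise ValueError("pool fraction must be in [0, 1)")
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("relaxation times must be positive")


def default_pools(glu_amplitude: float = 0.05) -> list[Pool]:
    """Water + glutamate-amine + NOE pool set.

    The NOE pool sits upfield at -3.5 ppm with a small fixed amplitude so
    that the simulated MTR asymmetry turns negative above roughly 4 ppm,
    the qualitative pattern seen in vivo.
    """
    # water depth 0.8 keeps A * b1 physical (< 1) for relative B1 up to 1.25
    # under the linear saturation-efficiency scaling
    return [
        Pool(shift=0.0, amplitude=0.80, width=1.4, label="water"),
        Pool(shift=3.0, amplitude=glu_amplitude, width=1.0, label="glu_amine"),
        Pool(shift=-3.5, amplitude=0.02, width=3.0, label="noe"),
    ]


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition geometry and saturation parameters.

    Defaults mirror a 7 T rodent GluCEST protocol: 25 CEST offsets from
    -6 to +6 ppm in 0.5 ppm steps at 3.6 uT / 1 s saturation, 33 WASSR
    offsets from -0.8 to +0.8 ppm in 0.05 ppm steps at 0.3 uT, and a
    dual flip-angle (30, 60 degree) pair for B1 mapping.
    """

    cest_offsets: np.ndarray = field(
        default_factory=lambda: np.linspace(-6.0, 6.0, 25)
    )
    wassr_offsets: np.ndarray = field(
        default_factory=lambda: np.linspace(-0.8, 0.8, 33)
    )
    cest_sat_power: float = 3.6
    cest_sat_time: float = 1.0
    wassr_sat_power: float = 0.3
    b1_angles: tuple[float, float] = (30.0, 60.0)
    matrix: tuple[int, int] = (96, 96)

    def __post_init__(self) -> None:
        for name in ("cest_offsets", "wassr_offsets"):
            grid = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, grid)
            if np.any(np.diff(grid) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
            if not np.allclose(grid, -grid[::-1]):
                raise ValueError(f"{name} must be symmetric about 0")
        a, b = self.b1_angles
        if a <= 0 or not np.isclose(b, 2 * a):
            raise ValueError("b1_angles must be (alpha, 2*alpha) with alpha > 0")
        if min(self.matrix) < 4:
            raise ValueError("matrix must be at least 4x4")


@dataclass(frozen=True)
class PhantomSpec:
    """Digital phantom: ROI geometry, pools, field maps, noise, seed."""

    roi_mask: np.ndarray
    pools_inside: tuple[Pool, ...]
    pools_outside: tuple[Pool, ...]
    b0_field: np.ndarray
    b1_field: np.ndarray
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "roi_mask", np.asarray(self.roi_mask, dtype=bool))
        object.__setattr__(self, "b0_field", np.asarray(self.b0_field, dtype=float))
        object.__setattr__(self, "b1_field", np.asarray(self.b1_field, dtype=float))
        object.__setattr__(self, "pools_inside", tuple(self.pools_inside))
        object.__setattr__(self, "pools_outside", tuple(self.pools_outside))
        if not (self.roi_mask.shape == self.b0_field.shape == self.b1_field.shape):
            raise ValueError("roi_mask, b0_field and b1_field must share geometry")
        if np.any(self.b1_field <= 0):
            raise ValueError("b1_field must be positive everywhere")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    def validate_against(self, acq: AcquisitionSpec) -> None:
        if self.roi_mask.shape != tuple(acq.matrix):
            raise ValueError("phantom geometry does not match acquisition matrix")
        half_span = acq.wassr_offsets[-1]
        if np.any(np.abs(self.b0_field) >= half_span):
            raise ValueError(
                "b0_field magnitude must stay below the WASSR half-span "
                f"({half_span} ppm) so the water minimum stays on-grid"
            )


@dataclass
class SyntheticStudy:
    """One simulated subject: stacks, angle images and noiseless truth."""

    cest_stack: ZStack
    wassr_stack: ZStack
    angle_images: tuple[np.ndarray, np.ndarray]
    truth_b0: B0Map
    truth_b1: B1Map
    truth_glucest: GluCestMap
    phantom: PhantomSpec
    acq: AcquisitionSpec


def lorentzian_z(
    offsets: np.ndarray,
    pools: list[Pool] | tuple[Pool, ...],
    b0_shift: float = 0.0,
    b1_scale: float = 1.0,
    *,
    tol: float = 1e-9,
) -> np.ndarray:
    """Sum-of-Lorentzians Z-spectrum.

    ``Z(dw) = 1 - sum_i A_i * b1_scale * (w_i/2)^2 / ((w_i/2)^2 + (dw - d_i - b0)^2)``

    Every pool centre (water included) is displaced by ``b0_shift``; pool
    amplitudes scale linearly with ``b1_scale``.  The result is clipped to
    [0, 1], but an amplitude sum that drives Z below ``-tol`` before
    clipping is rejected as unphysical.
    """
    offsets = np.asarray(offsets, dtype=float)
    if not np.all(np.isfinite(offsets)):
        raise ValueError("offsets must be finite")
    if b1_scale <= 0:
        raise ValueError("b1_scale must be positive")
    z = np.ones_like(offsets)
    for pool in pools:
        half = pool.width / 2.0
        z -= (
            pool.amplitude
            * b1_scale
            * half**2
            / (half**2 + (offsets - pool.shift - b0_shift) ** 2)
        )
    if np.any(z < -tol):
        raise ValueError(
            "pool amplitudes drive Z below zero: unphysical saturation"
        )
    return np.clip(z, 0.0, 1.0)


def bloch_mcconnell_z(
    offsets: np.ndarray,
    water_pool: Pool,
    solute_pool: Pool,
    sat_power: float = 3.6,
    sat_time: float = 1.0,
    field_mhz: float = 300.0,
) -> np.ndarray:
    """Two-pool Bloch-McConnell Z-spectrum under continuous-wave saturation.

    Integrates the coupled magnetisation of water (a) and solute (b) from
    thermal equilibrium for ``sat_time`` seconds at each offset and returns
    the longitudinal water magnetisation normalised by its equilibrium
    value.  The 6-state linear ODE (x, y, z for both pools plus the
    relaxation recovery inhomogeneity) is solved exactly with a matrix
    exponential of the 7x7 augmented system.

    ``solute_pool.fraction`` and ``solute_pool.exchange_rate`` must be set;
    a fraction of zero reduces to single-pool direct saturation.
    """
    offsets = np.asarray(offsets, dtype=float)
    if sat_time <= 0:
        raise ValueError("sat_time must be positive")
    if sat_power < 0:
        raise ValueError("sat_power must be >= 0")
    fb = solute_pool.fraction
    kb = solute_pool.exchange_rate
    if fb is None:
        raise ValueError("solute_pool.fraction is required")
    if fb > 0 and kb is None:
        raise ValueError("solute_pool.exchange_rate is required when fraction > 0")
    kb = 0.0 if fb == 0 else float(kb)
    ka = fb * kb  # detailed balance: water->solute rate

    w1 = 2 * np.pi * GAMMA_HZ_PER_UT * sat_power  # rad/s
    r1a, r2a = 1 / water_pool.t1, 1 / water_pool.t2
    r1b, r2b = 1 / solute_pool.t1, 1 / solute_pool.t2

    m0 = np.array([0.0, 0.0, 1.0, 0.0, 0.0, fb, 1.0])
    z = np.empty_like(offsets)
    for i, dw_ppm in enumerate(offsets):
        # offset of the saturation pulse from each pool, rad/s
        da = 2 * np.pi * field_mhz * (water_pool.shift - dw_ppm)
        db = 2 * np.pi * field_mhz * (solute_pool.shift - dw_ppm)
        a = np.zeros((7, 7))
        # water transverse/longitudinal block
        a[0, :3] = [-(r2a + ka), -da, 0.0]
        a[1, :3] = [da, -(r2a + ka), w1]
        a[2, 1:3] = [-w1, -(r1a + ka)]
        # solute block
        a[3, 3:6] = [-(r2b + kb), -db, 0.0]
        a[4, 3:6] = [db, -(r2b + kb), w1]
        a[5, 4:6] = [-w1, -(r1b + kb)]
        # exchange coupling
        for j in range(3):
            a[j, 3 + j] += kb
            a[3 + j, j] += ka
        # constant relaxation recovery terms via the augmented state
        a[2, 6] = r1a
        a[5, 6] = r1b * fb
        m = expm(a * sat_time) @ m0
        if not np.all(np.isfinite(m)):
            raise RuntimeError(
                f"Bloch-McConnell integration failed at offset {dw_ppm} ppm"
            )
        z[i] = m[2]
    return z


def add_noise(
    image: np.ndarray,
    sigma: float,
    seed: int,
    *,
    reference: float | None = None,
    model: str = "rician",
) -> np.ndarray:
    """Corrupt an intensity image with Rician (default) or Gaussian noise.

    ``sigma`` is expressed as a fraction of ``reference`` (the S0 level;
    defaults to the image maximum).  Rician noise is the magnitude of the
    complex signal plus i.i.d. Gaussian noise on both quadratures, the
    correct statistic for MRI magnitude images.  ``sigma = 0`` returns the
    input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    image = np.asarray(image, dtype=float)
    if sigma == 0:
        return image.copy()
    if reference is None:
        reference = float(np.max(np.abs(image))) or 1.0
    scale = sigma * reference
    rng = np.random.default_rng(seed)
    if model == "rician":
        real = image + rng.normal(0.0, scale, image.shape)
        imag = rng.normal(0.0, scale, image.shape)
        return np.hypot(real, imag)
    if model == "gaussian":
        return image + rng.normal(0.0, scale, image.shape)
    raise ValueError(f"unknown noise model {model!r}")


def _voxel_field_spectra(
    offsets: np.ndarray, phantom: PhantomSpec, sat_scale: float = 1.0
) -> np.ndarray:
    """Noiseless Z-stack over the phantom, pools by ROI membership."""
    rows, cols = phantom.roi_mask.shape
    out = np.empty((rows, cols, offsets.size))
    for r in range(rows):
        for c in range(cols):
            pools = (
                phantom.pools_inside if phantom.roi_mask[r, c] else phantom.pools_outside
            )
            scaled = [replace(p, amplitude=p.amplitude * sat_scale) for p in pools]
            out[r, c] = lorentzian_z(
                offsets,
                scaled,
                b0_shift=phantom.b0_field[r, c],
                b1_scale=phantom.b1_field[r, c],
            )
    return out


def _truth_glucest(phantom: PhantomSpec, acq: AcquisitionSpec) -> GluCestMap:
    """Ground-truth GluCEST map: b0 = 0, b1 = 1, noiseless, per-voxel pools."""
    offs = np.array([-3.0, 3.0])
    rows, cols = phantom.roi_mask.shape
    value = np.empty((rows, cols))
    for r in range(rows):
        for c in range(cols):
            pools = (
                phantom.pools_inside if phantom.roi_mask[r, c] else phantom.pools_outside
            )
            z = lorentzian_z(offs, pools)
            value[r, c] = 100.0 * (z[0] - z[1]) / z[0]
    return GluCestMap(
        value=value,
        mask=np.ones((rows, cols), dtype=bool),
        provenance={"kind": "truth", "b0": "ideal", "b1": "ideal"},
    )


def simulate_phantom(phantom: PhantomSpec, acq: AcquisitionSpec) -> SyntheticStudy:
    """Forward-simulate one subject's CEST, WASSR and dual-angle data.

    The WASSR stack uses the same Lorentzian pools but with amplitudes
    scaled by the WASSR/CEST saturation-power ratio (first-order power
    scaling), which narrows the effective dip just as low-power WASSR
    acquisition does.  Angle images are ``S0 * sin(b1 * alpha)``.  All
    noise derives deterministically from ``phantom.seed``.
    """
    phantom.validate_against(acq)
    rows, cols = phantom.roi_mask.shape
    s0_level = 1000.0
    s0 = np.full((rows, cols), s0_level)

    cest_clean = s0[..., None] * _voxel_field_spectra(acq.cest_offsets, phantom)
    wassr_scale = acq.wassr_sat_power / acq.cest_sat_power
    wassr_clean = s0[..., None] * _voxel_field_spectra(
        acq.wassr_offsets, phantom, sat_scale=wassr_scale
    )
    alpha = np.deg2rad(acq.b1_angles[0])
    angle_clean = tuple(
        s0 * np.sin(np.clip(phantom.b1_field * mult * alpha, 0.0, np.pi))
        for mult in (1.0, 2.0)
    )

    sigma = phantom.noise_sigma
    seeds = np.random.SeedSequence(phantom.seed).spawn(5)

    def sub(i: int) -> int:
        return int(seeds[i].generate_state(1)[0] % (2**31))

    cest = add_noise(cest_clean, sigma, sub(0), reference=s0_level)
    wassr = add_noise(wassr_clean, sigma, sub(1), reference=s0_level)
    s0_noisy = add_noise(s0, sigma, sub(2), reference=s0_level)
    angles = tuple(
        add_noise(img, sigma, sub(3 + i), reference=s0_level)
        for i, img in enumerate(angle_clean)
    )

    full = np.ones((rows, cols), dtype=bool)
    return SyntheticStudy(
        cest_stack=ZStack(cest, acq.cest_offsets, s0=s0_noisy),
        wassr_stack=ZStack(wassr, acq.wassr_offsets),
        angle_images=angles,
        truth_b0=B0Map(shift=phantom.b0_field.copy(), mask=full.copy()),
        truth_b1=B1Map(relative=phantom.b1_field.copy(), mask=full.copy()),
        truth_glucest=_truth_glucest(phantom, acq),
        phantom=phantom,
        acq=acq,
    )


def make_phantom(
    matrix: tuple[int, int] = (16, 16),
    glu_amplitude: float = 0.05,
    glu_amplitude_outside: float = 0.03,
    b0_max: float = 0.0,
    b1_range: tuple[float, float] = (1.0, 1.0),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> PhantomSpec:
    """Convenience builder: centred elliptical hippocampus-like ROI with
    smooth cosine-bump B0 and linear-gradient B1 fields."""
    rows, cols = matrix
    y, x = np.mgrid[0:rows, 0:cols]
    cy, cx = (rows - 1) / 2, (cols - 1) / 2
    roi = ((y - cy) / (0.28 * rows)) ** 2 + ((x - cx) / (0.38 * cols)) ** 2 <= 1.0
    b0 = b0_max * np.cos(np.pi * (y - cy) / rows) * np.cos(np.pi * (x - cx) / cols)
    lo, hi = b1_range
    b1 = lo + (hi - lo) * x / max(cols - 1, 1)
    return PhantomSpec(
        roi_mask=roi,
        pools_inside=tuple(default_pools(glu_amplitude)),
        pools_outside=tuple(default_pools(glu_amplitude_outside)),
        b0_field=b0,
        b1_field=b1,
        noise_sigma=noise_sigma,
        seed=seed,
    )
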
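"""Virtual two-photon microscope with ground-truthed specimen phantoms.

The phantom is a fluorescently labeled stretch of dendrite (a cylinder)
carrying spines (spherical heads on thin necks), all lying in one focal
plane. Rendering integrates the fluorophore path length through each
structure at every pixel (so a sphere's integrated intensity scales
with its volume), applies a defocus-dependent Gaussian blur of width

    sigma(defocus) = sigma0 * sqrt(1 + (defocus / z_half)**2),

and optionally corrupts the frame with signal-dependent shot noise,
Gaussian read noise and a uniform background. Ground truth (focal
plane, lateral offset, per-spine volume factors) is emitted alongside
every simulated acquisition, which makes autofocus, drift correction,
targeting and quantification testable without any recorded data.

Structural plasticity is modeled as a volume factor

    v(t) = 1                                          (t <  t0)
    v(t) = 1 + A_sust + A_trans * exp(-(t-t0)/tau)    (t >= t0)

applied to the stimulated spine — head radius ∝ v**(1/3) about a fixed
center, neck radius ∝ v**(1/2) — so total spine fluorescence is linear
in v: a transient peak of amplitude A_trans relaxing with time constant
tau onto a sustained enlargement A_sust.

The Gaussian defocus-blur model is deliberately simple — it is not a
physical two-photon PSF — but it gives every focus operator a smooth,
monotonic response to defocus, which is the property the autofocus
machinery needs to be tested against.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import ZStack

__all__ = [
    "Microscope",
    "Spine",
    "Phantom",
    "NoiseModel",
    "DriftModel",
    "DriftState",
    "PlasticityModel",
    "GroundTruth",
    "default_phantom",
    "render_slice",
    "spine_volume_factor",
    "step_drift",
    "acquire_stack",
    "read_noise_for_snr",
    "shot_noise_for_snr",
    "make_benchmark_dataset",
]


@dataclass(frozen=True)
class Microscope:
    """Imaging geometry and optics of the virtual scope.

    128x128 px frames at 0.1 um/px; in-focus blur ``sigma0_um`` and the
    defocus half-width ``z_half_um`` shape the axial response.
    """

    frame_px: int = 128
    pixel_um: float = 0.1
    sigma0_um: float = 0.15
    z_half_um: float = 0.5

    @property
    def fov_um(self) -> float:
        return self.frame_px * self.pixel_um

    def defocus_sigma_um(self, defocus_um: float) -> float:
        return self.sigma0_um * np.sqrt(1.0 + (defocus_um / self.z_half_um) ** 2)


@dataclass(frozen=True)
class Spine:
    """A spine: spherical head on a thin neck anchored to the dendrite.

    ``anchor_um`` locates the neck along the dendrite axis; ``side``
    (+1/-1) picks the side of the dendrite; intensity is fluorophore
    density per micrometre of path length.
    """

    anchor_um: float
    neck_length_um: float = 1.5
    head_radius_um: float = 0.3
    intensity: float = 1.0
    side: int = 1
    neck_radius_um: float = 0.04


@dataclass(frozen=True)
class Phantom:
    """Quasi-planar dendrite-plus-spines specimen.

    The dendrite is a cylinder along the column (x) axis at row
    ``dendrite_row_um``, lying in the focal plane ``z_focus_um``. Its
    brightness is modulated along the axis (``texture_strength`` as a
    relative std over a ``texture_scale_um`` correlation length) the way
    a real GFP fill shows varicosities and uneven expression — a
    perfectly uniform cylinder would make lateral registration along
    its own axis ill-posed, which no real dendrite is. The texture is a
    fixed function of the specimen coordinate (seeded), so it drifts
    rigidly with the structure.
    """

    dendrite_row_um: float = 6.4
    dendrite_radius_um: float = 0.5
    dendrite_intensity: float = 1.0
    z_focus_um: float = 0.0
    spines: tuple[Spine, ...] = ()
    texture_strength: float = 0.5
    texture_scale_um: float = 0.3
    texture_seed: int = 7

    def axial_texture(self, x_um: np.ndarray) -> np.ndarray:
        """Brightness modulation m(x) in (0, 1], seeded sinusoid mixture.

        Normalized so the brightest point of the dendrite keeps the
        nominal intensity (the texture dims, it never creates hot
        spots above ``dendrite_intensity``).
        """
        x_um = np.asarray(x_um, dtype=np.float64)
        if self.texture_strength <= 0:
            return np.ones_like(x_um)
        gen = np.random.default_rng(self.texture_seed)
        k = 40
        lam = np.exp(gen.uniform(np.log(2 * self.texture_scale_um),
                                 np.log(10 * self.texture_scale_um), size=k))
        phase = gen.uniform(0, 2 * np.pi, size=k)
        amp = gen.normal(size=k)
        wave = np.sum(
            amp[:, None] * np.cos(2 * np.pi * x_um[None, :] / lam[:, None]
                                  + phase[:, None]),
            axis=0,
        )
        wave *= self.texture_strength / np.sqrt(0.5 * np.sum(amp * amp))
        m = np.clip(1.0 + wave, 0.1, None)
        # normalize against the modulation's true maximum (sampled on a
        # fixed fine grid so the scale is offset-independent)
        ref = np.arange(0.0, 25.6, 0.02)
        wave_ref = np.sum(
            amp[:, None] * np.cos(2 * np.pi * ref[None, :] / lam[:, None]
                                  + phase[:, None]),
            axis=0,
        ) * self.texture_strength / np.sqrt(0.5 * np.sum(amp * amp))
        return m / float(np.clip(1.0 + wave_ref, 0.1, None).max())

    def spine_head_center_um(self, i: int) -> tuple[float, float]:
        """(row_um, col_um) of spine i's head center.

        The center stays fixed as the head swells (enlargement is
        symmetric about the head center; the neck shortens slightly).
        """
        s = self.spines[i]
        row = self.dendrite_row_um + s.side * (
            self.dendrite_radius_um + s.neck_length_um + s.head_radius_um
        )
        return row, s.anchor_um


@dataclass(frozen=True)
class NoiseModel:
    """Shot noise (variance ∝ signal), Gaussian read noise, flat background.

    ``photon_scale`` is photons per intensity unit (0 disables shot
    noise); ``read_sigma`` is the std of additive Gaussian read noise;
    ``background`` is a uniform offset added before the noise draws.
    """

    photon_scale: float = 0.0
    read_sigma: float = 0.0
    background: float = 0.0

    def __post_init__(self):
        if self.photon_scale < 0 or self.read_sigma < 0 or self.background < 0:
            raise ValueError("noise parameters must be non-negative")

    def apply(self, image: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        out = image + self.background
        if self.photon_scale > 0:
            out = rng.poisson(out * self.photon_scale) / self.photon_scale
        if self.read_sigma > 0:
            out = out + rng.normal(0.0, self.read_sigma, size=out.shape)
        return np.clip(out, 0.0, None)


@dataclass(frozen=True)
class PlasticityModel:
    """Uncaging-evoked spine volume dynamics (transient + sustained)."""

    t0_min: float = 0.0
    a_trans: float = 2.0
    tau_trans_min: float = 1.5
    a_sust: float = 0.6

    def __post_init__(self):
        if self.a_trans < 0 or self.a_sust < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.tau_trans_min <= 0:
            raise ValueError("tau must be positive")


def spine_volume_factor(model: PlasticityModel, t_min: float) -> float:
    """Volume multiplier at time ``t_min``: 1 before onset, then
    ``1 + A_sust + A_trans * exp(-(t-t0)/tau)``."""
    t = np.asarray(t_min, dtype=np.float64)
    out = np.where(
        t < model.t0_min,
        1.0,
        1.0 + model.a_sust
        + model.a_trans * np.exp(-(t - model.t0_min) / model.tau_trans_min),
    )
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class DriftModel:
    """Per-axis random walk plus optional linear creep, seeded upstream.

    ``sigma_um`` is the per-frame random-walk step std for (row, col, z);
    ``creep_um_per_min`` a deterministic linear drift rate.
    """

    sigma_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    creep_um_per_min: tuple[float, float, float] = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class DriftState:
    """Current specimen offset (row, col, z) in micrometres."""

    offset_um: tuple[float, float, float] = (0.0, 0.0, 0.0)
    t_min: float = 0.0


def step_drift(state: DriftState, model: DriftModel,
               rng: np.random.Generator | None = None,
               dt_min: float = 1.0) -> DriftState:
    """Advance the drift state by one frame interval of ``dt_min``."""
    step = np.zeros(3)
    sigma = np.asarray(model.sigma_um, dtype=float)
    if np.any(sigma > 0):
        if rng is None:
            raise ValueError("random-walk drift needs a seeded generator")
        step = rng.normal(0.0, 1.0, size=3) * sigma
    creep = np.asarray(model.creep_um_per_min, dtype=float) * dt_min
    new = tuple(np.asarray(state.offset_um) + step + creep)
    return DriftState(offset_um=new, t_min=state.t_min + dt_min)


# ---------------------------------------------------------------------------
# rendering

_SUPERSAMPLE = 5  # subpixel samples per axis; keeps disk mass error < 1%


def _sub_axis(i0: int, i1: int, px: float, offset: float,
              ss: int = _SUPERSAMPLE) -> np.ndarray:
    """Supersampled specimen coordinates covering pixels i0..i1-1."""
    sub = (np.arange((i1 - i0) * ss) + 0.5) / ss
    return (i0 + sub) * px - offset


def _pool(patch: np.ndarray, ss: int = _SUPERSAMPLE) -> np.ndarray:
    h, w = patch.shape
    return patch.reshape(h // ss, ss, w // ss, ss).mean(axis=(1, 3))


def _pixel_span(center: float, radius: float, px: float, offset: float,
                n: int, margin: int = 1) -> tuple[int, int]:
    i0 = int(np.floor((center - radius + offset) / px)) - margin
    i1 = int(np.ceil((center + radius + offset) / px)) + margin
    return max(i0, 0), min(i1, n)


def _add_sphere(img: np.ndarray, px: float, dr: float, dc: float,
                row_c: float, col_c: float, radius: float,
                density: float) -> None:
    """Accumulate a sphere's projected thickness 2*sqrt(R^2-d^2).

    Evaluated on a supersampled local patch so the integrated mass
    tracks the analytic volume (4/3)*pi*R^3 to well under 1%.
    """
    n = img.shape[0]
    i0, i1 = _pixel_span(row_c, radius, px, dr, n)
    j0, j1 = _pixel_span(col_c, radius, px, dc, img.shape[1])
    if i0 >= i1 or j0 >= j1:
        return
    y = _sub_axis(i0, i1, px, dr)[:, None]
    x = _sub_axis(j0, j1, px, dc)[None, :]
    chord = radius * radius - (y - row_c) ** 2 - (x - col_c) ** 2
    patch = density * 2.0 * np.sqrt(np.clip(chord, 0.0, None))
    img[i0:i1, j0:j1] += _pool(patch)


def _add_vertical_cylinder(img: np.ndarray, px: float, dr: float, dc: float,
                           row_lo: float, row_hi: float, col_c: float,
                           radius: float, density: float) -> None:
    """Accumulate a thin cylinder segment along the row axis (a neck)."""
    n = img.shape[0]
    i0 = max(int(np.floor((row_lo + dr) / px)) - 1, 0)
    i1 = min(int(np.ceil((row_hi + dr) / px)) + 1, n)
    j0, j1 = _pixel_span(col_c, radius, px, dc, img.shape[1])
    if i0 >= i1 or j0 >= j1:
        return
    y = _sub_axis(i0, i1, px, dr)[:, None]
    x = _sub_axis(j0, j1, px, dc)[None, :]
    chord = radius * radius - (x - col_c) ** 2
    patch = np.where(
        (y >= row_lo) & (y <= row_hi),
        density * 2.0 * np.sqrt(np.clip(chord, 0.0, None)),
        0.0,
    )
    img[i0:i1, j0:j1] += _pool(patch)


def render_geometry(phantom: Phantom, scope: Microscope,
                    lateral_offset_um=(0.0, 0.0),
                    volume_factors=None) -> np.ndarray:
    """Noise-free, unblurred projected-thickness image of the specimen.

    Each pixel holds the fluorophore path length (um) through the
    structures times their density, averaged over a subpixel grid.
    ``lateral_offset_um`` shifts the specimen (a positive offset moves
    structures toward larger row/column indices, as physical drift
    does). ``volume_factors`` scales each spine's head volume.
    """
    n = scope.frame_px
    px = scope.pixel_um
    dr, dc = lateral_offset_um
    img = np.zeros((n, n))

    # dendrite: cylinder along the column axis with axial texture;
    # separable in (row, col), so per-axis subpixel pooling is exact
    R = phantom.dendrite_radius_um
    i0, i1 = _pixel_span(phantom.dendrite_row_um, R, px, dr, n)
    if i0 < i1:
        y = _sub_axis(i0, i1, px, dr)
        chord = R * R - (y - phantom.dendrite_row_um) ** 2
        profile = phantom.dendrite_intensity * 2.0 * np.sqrt(
            np.clip(chord, 0.0, None)
        )
        profile = profile.reshape(-1, _SUPERSAMPLE).mean(axis=1)
        x = _sub_axis(0, img.shape[1], px, dc)
        texture = phantom.axial_texture(x).reshape(-1, _SUPERSAMPLE).mean(axis=1)
        img[i0:i1, :] += profile[:, None] * texture[None, :]

    if volume_factors is None:
        volume_factors = np.ones(len(phantom.spines))
    for i, (s, vf) in enumerate(zip(phantom.spines,
                                    np.atleast_1d(volume_factors))):
        # the factor scales the whole spine's volume: head radius grows
        # as vf^(1/3) about a fixed center, the neck (length fixed)
        # widens as vf^(1/2), so total spine fluorescence is linear in vf
        head_r = s.head_radius_um * float(vf) ** (1.0 / 3.0)
        head_row, head_col = phantom.spine_head_center_um(i)
        _add_sphere(img, px, dr, dc, head_row, head_col, head_r, s.intensity)
        if s.neck_radius_um > 0:
            y0 = phantom.dendrite_row_um + s.side * phantom.dendrite_radius_um
            lo, hi = sorted((y0, head_row))
            _add_vertical_cylinder(img, px, dr, dc, lo, hi, head_col,
                                   s.neck_radius_um * float(vf) ** 0.5,
                                   s.intensity)
    return img


def render_slice(phantom: Phantom, scope: Microscope, z_um: float,
                 defocus_um: float | None = None,
                 lateral_offset_um=(0.0, 0.0),
                 z_offset_um: float = 0.0,
                 volume_factors=None,
                 noise: NoiseModel | None = None,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Render one slice of the specimen at focal position ``z_um``.

    Defocus defaults to the distance between ``z_um`` and the (drifted)
    specimen plane. The blur kernel is normalized, so total intensity
    is conserved for structures away from the frame edge. Pass
    ``noise=None`` for noise-free mode.
    """
    if defocus_um is None:
        defocus_um = z_um - (phantom.z_focus_um + z_offset_um)
    img = render_geometry(phantom, scope, lateral_offset_um=lateral_offset_um,
                          volume_factors=volume_factors)
    sigma_px = scope.defocus_sigma_um(float(defocus_um)) / scope.pixel_um
    if sigma_px > 0:
        # periodic boundaries: the normalized kernel then conserves total
        # intensity exactly, matching the circular-shift drift model
        img = ndimage.gaussian_filter(img, sigma_px, mode="wrap")
    if noise is not None:
        if rng is None and (noise.photon_scale > 0 or noise.read_sigma > 0):
            raise ValueError("noisy rendering needs a seeded generator")
        img = noise.apply(img, rng)
    return img


def shot_noise_for_snr(phantom: Phantom, scope: Microscope, snr: float,
                       background: float | str = "auto") -> NoiseModel:
    """Photon-limited noise model with peak SNR ``snr``.

    Two-photon detection is shot-noise dominated: with ``photon_scale``
    photons per intensity unit, the SNR at the in-focus peak is
    sqrt(peak * photon_scale), so ``photon_scale = snr**2 / peak``.
    ``background="auto"`` adds a modest autofluorescence offset (5% of
    the peak) that also carries shot noise.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    clean = render_slice(phantom, scope, phantom.z_focus_um)
    peak = float(clean.max())
    if background == "auto":
        background = 0.05 * peak
    return NoiseModel(photon_scale=snr * snr / peak,
                      background=float(background))


def read_noise_for_snr(phantom: Phantom, scope: Microscope, snr: float,
                       background: float | str = "auto") -> NoiseModel:
    """Read-noise model calibrated so the in-focus peak sits at ``snr``.

    SNR is defined as (peak in-focus signal above background) / (read
    noise std) on a single rendered slice. ``background="auto"`` sets
    the uniform offset to 3x the noise std, emulating the detector
    offset of a real acquisition that keeps the Gaussian noise from
    clipping at zero intensity.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    clean = render_slice(phantom, scope, phantom.z_focus_um)
    sigma = float(clean.max()) / snr
    if background == "auto":
        background = 3.0 * sigma
    return NoiseModel(read_sigma=sigma, background=float(background))


@dataclass
class GroundTruth:
    """What the simulator actually did during one acquisition."""

    z_positions_um: np.ndarray
    true_focus_um: float
    true_focal_index: int
    lateral_offset_um: tuple[float, float]
    lateral_offset_px: tuple[float, float]
    volume_factors: np.ndarray = field(default=None)


def acquire_stack(phantom: Phantom, scope: Microscope,
                  z_center_um: float, range_um: float, step_um: float,
                  drift: DriftState | None = None,
                  volume_factors=None,
                  noise: NoiseModel | None = None,
                  rng: np.random.Generator | None = None
                  ) -> tuple[ZStack, GroundTruth]:
    """Collect a Z-stack around ``z_center_um`` with the current drift applied.

    Slices run from ``z_center - range`` to ``z_center + range`` in
    ``step_um`` increments. Returns the stack plus the ground truth:
    which slice is closest to the specimen's true (drifted) focal plane
    and the lateral offset baked into the frames.
    """
    k = int(round(range_um / step_um))
    if k < 1:
        raise ValueError("range must cover at least one step")
    z_positions = z_center_um + np.arange(-k, k + 1) * step_um
    offset = drift.offset_um if drift is not None else (0.0, 0.0, 0.0)
    dr, dc, dz = offset
    slices = np.stack([
        render_slice(phantom, scope, z, lateral_offset_um=(dr, dc),
                     z_offset_um=dz, volume_factors=volume_factors,
                     noise=noise, rng=rng)
        for z in z_positions
    ])
    true_focus = phantom.z_focus_um + dz
    focal_index = int(np.argmin(np.abs(z_positions - true_focus)))
    gt = GroundTruth(
        z_positions_um=z_positions,
        true_focus_um=true_focus,
        true_focal_index=focal_index,
        lateral_offset_um=(dr, dc),
        lateral_offset_px=(dr / scope.pixel_um, dc / scope.pixel_um),
        volume_factors=None if volume_factors is None
        else np.atleast_1d(volume_factors).astype(float),
    )
    return ZStack(slices=slices, z_positions=z_positions), gt


def default_phantom(scope: Microscope | None = None,
                    n_spines: int = 2) -> Phantom:
    """Dendrite across the field center with up to two flanking spines.

    Spine 0 (below the dendrite) is the stimulated spine; spine 1
    (above) is the adjacent, unstimulated control.
    """
    scope = scope or Microscope()
    mid = scope.fov_um / 2.0
    spines = []
    if n_spines >= 1:
        spines.append(Spine(anchor_um=mid - 2.4, side=1))
    if n_spines >= 2:
        spines.append(Spine(anchor_um=mid + 2.4, side=-1))
    for i in range(2, n_spines):
        spines.append(Spine(anchor_um=mid + (i - 1) * 1.6, side=(-1) ** i))
    return Phantom(dendrite_row_um=mid, spines=tuple(spines))


def make_benchmark_dataset(n_stacks: int, n_slices: int,
                           rng: np.random.Generator,
                           scope: Microscope | None = None,
                           step_um: float = 0.5,
                           noise: NoiseModel | None = None,
                           jitter_frac: float = 0.4):
    """Annotated stacks for the focus-operator benchmark.

    Each stack is rendered from the default phantom with the true focal
    plane placed at a random slice (plus sub-step jitter bounded by
    ``jitter_frac`` of a half-step, so the annotated slice stays the
    nearest one), mirroring a set of pre-acquired, expert-annotated
    Z-stacks. ``n_slices`` must be odd. Returns a list of
    ``(ZStack, target_index, roi)`` with ``roi=None`` (full frame).
    """
    if n_slices % 2 != 1 or n_slices < 3:
        raise ValueError("n_slices must be odd and >= 3")
    if not 0 <= jitter_frac < 1:
        raise ValueError("jitter_frac must be in [0, 1)")
    scope = scope or Microscope()
    phantom = default_phantom(scope)
    half = (n_slices - 1) // 2
    dataset = []
    for _ in range(n_stacks):
        target = int(rng.integers(0, n_slices))
        # place the specimen plane so `target` is the nearest slice
        jitter = rng.uniform(-jitter_frac, jitter_frac) * step_um / 2.0
        dz = (target - half) * step_um + jitter
        drift = DriftState(offset_um=(0.0, 0.0, dz))
        stack, gt = acquire_stack(
            phantom, scope, z_center_um=0.0,
            range_um=half * step_um, step_um=step_um,
            drift=drift, noise=noise, rng=rng,
        )
        dataset.append((stack, gt.true_focal_index, None))
    return dataset
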
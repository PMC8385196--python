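"""Render confocal-like two-channel muscle section images.

Muscle sections are imaged as maximum-intensity projections of 60-μm slabs,
one tracer channel (CTB) and one endplate channel (α-BTX).  The renderer
projects the simulated tracer field over the slab, draws endplate points as
small Gaussian puncta truncated at half-maximum (so the noise-free support
equals the half-maximum set), and adds muscle autofluorescence as a constant
background plus Gaussian noise and optional impulse (hot-pixel) noise.
Ground-truth masks are stored alongside each section.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .injection import TracerField
from .muscle import MEPMap, MuscleGeometry


@dataclass(frozen=True)
class NoiseParams:
    """Background autofluorescence and noise of the section renderer."""

    background: float = 30.0
    noise_sd: float = 6.0
    impulse_density: float = 5e-4
    impulse_amplitude: float = 300.0

    @classmethod
    def none(cls) -> "NoiseParams":
        return cls(background=0.0, noise_sd=0.0, impulse_density=0.0,
                   impulse_amplitude=0.0)


@dataclass(frozen=True)
class SectionImage:
    """Two-channel muscle section at a known depth.

    channels: ``{"tracer": 2D image, "mep": 2D image}`` sharing shape and
    pixel size; ``truth`` holds the noise-free masks (tracer: half-maximum
    threshold of the projected field; mep: support of the rendered puncta).
    """

    depth_um: float
    channels: dict[str, np.ndarray]
    pixel_size_um: float
    slab_thickness_um: float = 60.0
    truth: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.slab_thickness_um <= 0:
            raise ValueError("slab_thickness_um must be positive")
        if self.channels["tracer"].shape != self.channels["mep"].shape:
            raise ValueError("tracer and mep channels must share shape")


TRACER_PEAK = 200.0
MEP_PUNCTUM_PEAK = 160.0
MEP_PUNCTUM_SIGMA_UM = 60.0


def _render_puncta(points_rc: np.ndarray, shape: tuple[int, int],
                   pixel_size_um: float, sigma_um: float,
                   peak: float) -> np.ndarray:
    """Sum of Gaussian puncta truncated at half-maximum (support = FWHM disk)."""
    img = np.zeros(shape, dtype=float)
    if points_rc.size == 0:
        return img
    sigma_px = sigma_um / pixel_size_um
    # half-maximum radius of a Gaussian: sigma * sqrt(2 ln 2)
    r_half = sigma_px * math.sqrt(2 * math.log(2))
    w = int(math.ceil(r_half)) + 1
    for r_um, c_um in points_rc:
        r = r_um / pixel_size_um - 0.5
        c = c_um / pixel_size_um - 0.5
        r0, c0 = int(round(r)), int(round(c))
        rs = slice(max(r0 - w, 0), min(r0 + w + 1, shape[0]))
        cs = slice(max(c0 - w, 0), min(c0 + w + 1, shape[1]))
        if rs.start >= rs.stop or cs.start >= cs.stop:
            continue
        rr, cc = np.meshgrid(np.arange(rs.start, rs.stop),
                             np.arange(cs.start, cs.stop), indexing="ij")
        g = peak * np.exp(-0.5 * ((rr - r) ** 2 + (cc - c) ** 2) / sigma_px**2)
        g[g < peak / 2] = 0.0  # truncate at half-maximum
        img[rs, cs] = np.maximum(img[rs, cs], g)
    return img


def render_section_images(
    tracer_field: TracerField,
    mep_map: MEPMap,
    geometry: MuscleGeometry,
    depths_um: list[float],
    noise_params: NoiseParams | None = None,
    seed: int = 0,
    slab_thickness_um: float = 60.0,
) -> list[SectionImage]:
    """Render one two-channel section per requested depth.

    Each section is the maximum-intensity projection of the slab
    ``[depth - slab/2, depth + slab/2]`` (depths are μm below the muscle
    surface).  The tracer channel projects the diffusion field scaled to a
    fixed peak; the endplate channel renders the points whose depth falls in
    the slab as truncated Gaussian puncta.  Noise is reproducible via
    ``seed``.
    """
    if len(depths_um) == 0:
        raise ValueError("depths_um must not be empty")
    noise = noise_params or NoiseParams()
    rng = np.random.default_rng(seed)
    vox = geometry.voxel_size_um
    nz = geometry.mask.shape[0]
    surface_z = geometry.surface_z_um
    max_depth = nz * vox - surface_z

    conc = tracer_field.concentration
    scale = TRACER_PEAK / conc.max() if conc.max() > 0 else 0.0

    sections: list[SectionImage] = []
    for depth in depths_um:
        if depth < 0 or depth > max_depth:
            raise ValueError(f"depth {depth} μm outside muscle extent")
        z_lo = surface_z + depth - slab_thickness_um / 2
        z_hi = surface_z + depth + slab_thickness_um / 2
        i_lo = max(int(math.floor(z_lo / vox)), 0)
        i_hi = min(int(math.ceil(z_hi / vox)), nz)
        if i_hi <= i_lo:
            i_lo, i_hi = max(i_hi - 1, 0), max(i_hi, 1)
        tracer_clean = conc[i_lo:i_hi].max(axis=0) * scale

        z_pts = mep_map.points[:, 0]
        in_slab = (z_pts >= z_lo) & (z_pts < z_hi)
        mep_clean = _render_puncta(mep_map.points[in_slab, 1:],
                                   tracer_clean.shape, vox,
                                   MEP_PUNCTUM_SIGMA_UM, MEP_PUNCTUM_PEAK)

        truth = {
            "tracer_mask": (tracer_clean >= tracer_clean.max() / 2)
            if tracer_clean.max() > 0
            else np.zeros_like(tracer_clean, dtype=bool),
            "mep_mask": mep_clean > 0,
        }

        channels = {}
        for name, clean in (("tracer", tracer_clean), ("mep", mep_clean)):
            img = clean + noise.background
            if noise.noise_sd > 0:
                img = img + rng.normal(0.0, noise.noise_sd, size=clean.shape)
            if noise.impulse_density > 0:
                hits = rng.random(clean.shape) < noise.impulse_density
                img = np.where(hits, noise.impulse_amplitude, img)
            channels[name] = np.clip(img, 0.0, None)

        sections.append(SectionImage(
            depth_um=float(depth), channels=channels, pixel_size_um=vox,
            slab_thickness_um=slab_thickness_um, truth=truth))
    return sections
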
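"""Synthetic array-tomography data with known ground truth.

Real array-tomography ribbons are 70 nm physical sections imaged per
antibody channel; nothing at desk scale substitutes for a microscope, so
this module emulates the acquisition well enough to exercise every
downstream stage: synaptic puncta at roughly cortical densities rendered
as Gaussian blobs spanning ≥2 consecutive sections, single-section noise
specks (the artefact class the span filter exists to remove), amyloid
plaques with a dense fibrillar core plus an oligomeric halo, per-section
rigid misalignment, and Poisson-ish photon noise on a camera offset.

Every generated object is recorded in a :class:`SyntheticTruth` so that
recovery (registration error, punctum counts, density, marker-positive
fractions) can be scored exactly.

The module also generates open-field trajectories and genotype cohorts
for the behavioural and Mendelian-ratio components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .stacks import ChannelStack
from .behavior import Trajectory

__all__ = [
    "SynthParams",
    "TruePunctum",
    "TrueSpeck",
    "SyntheticTruth",
    "generate_stack",
    "generate_trajectory",
    "generate_genotype_cohort",
]

# Truth object-extent cut: a voxel belongs to an object's footprint when its
# noiseless signal exceeds this many photon-noise SDs (the detectable extent).
TRUTH_SNR_CUT = 3.0


@dataclass
class SynthParams:
    """Parameters of the synthetic serial-section field.

    Defaults describe a 10×10 µm cortical neuropil field of twenty 70 nm
    sections sampled at 0.1 µm/px with a 63×/1.4 NA-like configuration:
    postsynaptic densities at ~1.0/µm³ and presynaptic terminals at
    ~0.7/µm³ (postsynaptic puncta outnumber presynaptic ones in cortical
    array tomography), puncta of ~0.12 µm lateral radius spanning ~3
    sections, and signal amplitude 15× the photon noise SD.
    """

    field_size_px: tuple[int, int] = (100, 100)
    n_sections: int = 20
    pixel_size_xy: float = 0.1  # µm/px
    section_thickness: float = 0.07  # µm, 70 nm ultrathin sections
    #: puncta per µm³ for each synaptic channel
    punctum_density: dict[str, float] = field(
        default_factory=lambda: {"synaptophysin": 0.7, "PSD95": 1.0}
    )
    punctum_radius_xy: tuple[float, float] = (0.12, 0.02)  # µm (mean, sd)
    punctum_span_sections: int = 3  # mean span, hard minimum 2
    noise_speck_rate: float = 0.2  # single-section specks per µm³ per channel
    #: probability that a synaptic punctum is positive for each marker
    marker_positive_fraction: dict[str, float] = field(
        default_factory=lambda: {"tau": 0.05, "abeta": 0.05}
    )
    #: list of ((x_um, y_um), core_radius_um, halo_radius_um)
    plaque_spec: list[tuple[tuple[float, float], float, float]] = field(
        default_factory=list
    )
    shift_sd_px: float = 1.5
    subpixel_shifts: bool = False
    background_level: float = 100.0
    punctum_amplitude: float = 1500.0
    photon_noise_sd: float = 100.0
    min_separation_um: float = 0.7  # hard-core spacing of same-channel puncta
    nuclei_density_per_um2: float = 0.03  # DAPI nuclei per µm² of field
    nucleus_radius_um: tuple[float, float] = (1.5, 0.3)  # µm (mean, sd)
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.punctum_density, (int, float)):
            self.punctum_density = {
                "synaptophysin": float(self.punctum_density),
                "PSD95": float(self.punctum_density),
            }
        if self.pixel_size_xy <= 0 or self.section_thickness <= 0:
            raise ValueError("physical sizes must be > 0")
        if self.n_sections < 2:
            raise ValueError("need at least 2 sections")
        if any(d < 0 for d in self.punctum_density.values()):
            raise ValueError("densities must be >= 0")
        if self.noise_speck_rate < 0:
            raise ValueError("noise_speck_rate must be >= 0")
        for m, p in self.marker_positive_fraction.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"marker fraction for {m!r} must be in [0,1]")
        if self.punctum_span_sections < 2:
            raise ValueError("mean punctum span must be >= 2 sections")
        for center, core_r, halo_r in self.plaque_spec:
            if core_r <= 0 or halo_r < core_r:
                raise ValueError("plaque needs 0 < core_radius <= halo_radius")

    @property
    def synaptic_channels(self) -> list[str]:
        return list(self.punctum_density)

    @property
    def marker_channels(self) -> list[str]:
        return list(self.marker_positive_fraction)

    @property
    def channel_names(self) -> list[str]:
        names = self.synaptic_channels + [
            m for m in self.marker_channels if m not in self.punctum_density
        ]
        if "thios" not in names:
            names.append("thios")
        if "dapi" not in names:
            names.append("dapi")
        return names

    @property
    def field_um(self) -> tuple[float, float]:
        r, c = self.field_size_px
        return (r * self.pixel_size_xy, c * self.pixel_size_xy)

    @property
    def volume_um3(self) -> float:
        r, c = self.field_size_px
        return r * c * self.n_sections * self.pixel_size_xy**2 * self.section_thickness


@dataclass
class TruePunctum:
    channel: str
    centroid_um: tuple[float, float, float]  # (x, y, z) = (col, row, section) axes
    radius_um: float
    section_range: tuple[int, int]  # inclusive
    labels: dict[str, bool]

    @property
    def span(self) -> int:
        return self.section_range[1] - self.section_range[0] + 1


@dataclass
class TrueSpeck:
    channel: str
    center_px: tuple[float, float]  # (row, col)
    section: int


@dataclass
class SyntheticTruth:
    """Ground truth for one generated field."""

    puncta: list[TruePunctum]
    specks: list[TrueSpeck]
    true_shifts: np.ndarray  # (n_sections, 2) applied (drow, dcol)
    plaques: list[tuple[tuple[float, float], float, float]]
    true_densities: dict[str, float]  # realised puncta per µm³
    aligned: ChannelStack  # the pre-misalignment stack
    truth_masks: dict[str, np.ndarray]  # noiseless signal footprint per channel

    def puncta_of(self, channel: str) -> list[TruePunctum]:
        return [p for p in self.puncta if p.channel == channel]


def _add_gaussian_blob(img: np.ndarray, r0: float, c0: float, sigma_px: float,
                       amplitude: float) -> None:
    """Accumulate a 2D Gaussian of peak ``amplitude`` at (r0, c0) in place."""
    rad = int(math.ceil(4 * sigma_px)) + 1
    rlo, rhi = max(0, int(r0) - rad), min(img.shape[0], int(r0) + rad + 1)
    clo, chi = max(0, int(c0) - rad), min(img.shape[1], int(c0) + rad + 1)
    if rlo >= rhi or clo >= chi:
        return
    rr = np.arange(rlo, rhi)[:, None] - r0
    cc = np.arange(clo, chi)[None, :] - c0
    img[rlo:rhi, clo:chi] += amplitude * np.exp(-(rr**2 + cc**2) / (2 * sigma_px**2))


def _disc_mask(shape: tuple[int, int], r0: float, c0: float, radius_px: float) -> np.ndarray:
    rr = np.arange(shape[0])[:, None] - r0
    cc = np.arange(shape[1])[None, :] - c0
    return rr**2 + cc**2 <= radius_px**2


def generate_stack(params: SynthParams) -> tuple[ChannelStack, SyntheticTruth]:
    """Render a calibrated multi-channel serial-section stack plus truth.

    Deterministic for a fixed ``params.seed``: all randomness flows from a
    single generator. Puncta are Gaussian blobs repeated across every
    section of their range; specks occupy exactly one section; plaques are
    discs through the whole depth, bright in both the fibrillar (``thios``)
    and pan-Aβ channels with the oligomeric halo only in pan-Aβ.
    Misalignment is applied last as a whole-section translation.
    """
    rng = np.random.default_rng(params.seed)
    rows, cols = params.field_size_px
    n = params.n_sections
    px = params.pixel_size_xy
    dz = params.section_thickness
    margin_px = 4.0

    # -- validate plaque placement against the field size ------------------
    field_h, field_w = rows * px, cols * px
    for (cx, cy), core_r, halo_r in params.plaque_spec:
        if not (halo_r <= cx <= field_w - halo_r and halo_r <= cy <= field_h - halo_r):
            raise ValueError(
                f"plaque at ({cx}, {cy}) µm with halo radius {halo_r} µm does not "
                f"fit inside the {field_w}×{field_h} µm field; enlarge the field "
                "or shrink/recenter the plaque"
            )

    signal = {name: np.zeros((n, rows, cols), dtype=np.float64)
              for name in params.channel_names}

    # -- synaptic puncta ---------------------------------------------------
    puncta: list[TruePunctum] = []
    min_sep_px = params.min_separation_um / px
    for channel in params.synaptic_channels:
        density = params.punctum_density[channel]
        count = rng.poisson(density * params.volume_um3) if density > 0 else 0
        placed: list[tuple[float, float, int, int]] = []  # (r, c, zlo, zhi)
        for _ in range(count):
            span = min(n, 2 + rng.poisson(max(0, params.punctum_span_sections - 2)))
            zlo = int(rng.integers(0, n - span + 1))
            zhi = zlo + span - 1
            # hard core: same-channel puncta whose section ranges touch
            # (overlap or are directly adjacent, which the 3D linker could
            # bridge via noise) keep at least min_separation apart in xy
            for _attempt in range(200):
                r0 = rng.uniform(margin_px, rows - margin_px)
                c0 = rng.uniform(margin_px, cols - margin_px)
                ok = all(
                    not (zlo - 1 <= pz1 and pz0 <= zhi + 1)
                    or (r0 - pr) ** 2 + (c0 - pc) ** 2 >= min_sep_px**2
                    for pr, pc, pz0, pz1 in placed
                )
                if ok:
                    break
            placed.append((r0, c0, zlo, zhi))
            radius = max(0.05, rng.normal(*params.punctum_radius_xy))
            labels = {
                m: bool(rng.random() < p)
                for m, p in params.marker_positive_fraction.items()
            }
            sigma_px = radius / px
            for z in range(zlo, zhi + 1):
                _add_gaussian_blob(signal[channel][z], r0, c0, sigma_px,
                                   params.punctum_amplitude)
                for m, pos in labels.items():
                    if pos:
                        _add_gaussian_blob(signal[m][z], r0, c0, sigma_px,
                                           params.punctum_amplitude)
            zc = (zlo + zhi) / 2.0
            puncta.append(TruePunctum(
                channel=channel,
                centroid_um=((c0 + 0.5) * px, (r0 + 0.5) * px, (zc + 0.5) * dz),
                radius_um=radius,
                section_range=(zlo, zhi),
                labels=labels,
            ))

    # -- single-section noise specks --------------------------------------
    specks: list[TrueSpeck] = []
    speck_channels = params.synaptic_channels + [
        m for m in params.marker_channels if m not in params.punctum_density
    ]
    for channel in speck_channels:
        count = rng.poisson(params.noise_speck_rate * params.volume_um3) \
            if params.noise_speck_rate > 0 else 0
        for _ in range(count):
            z = int(rng.integers(0, n))
            r0 = rng.uniform(margin_px, rows - margin_px)
            c0 = rng.uniform(margin_px, cols - margin_px)
            radius = max(0.05, rng.normal(*params.punctum_radius_xy))
            _add_gaussian_blob(signal[channel][z], r0, c0, radius / px,
                               params.punctum_amplitude)
            specks.append(TrueSpeck(channel=channel, center_px=(r0, c0), section=z))

    # -- plaques: dense core in thios + pan-Aβ, halo in pan-Aβ only --------
    pan_channel = "abeta" if "abeta" in signal else None
    for (cx, cy), core_r, halo_r in params.plaque_spec:
        r0, c0 = cy / px - 0.5, cx / px - 0.5
        core = _disc_mask((rows, cols), r0, c0, core_r / px)
        halo = _disc_mask((rows, cols), r0, c0, halo_r / px) & ~core
        core_amp = 1.5 * params.punctum_amplitude
        halo_amp = 0.5 * params.punctum_amplitude
        for z in range(n):
            signal["thios"][z][core] += core_amp
            if pan_channel is not None:
                signal[pan_channel][z][core] += core_amp
                signal[pan_channel][z][halo] += halo_amp

    # -- DAPI nuclei: µm-scale, so they persist through the whole ribbon ---
    # depth; this dense stain-independent structure is what registration
    # keys on, exactly as in real array tomography.
    field_area_um2 = rows * cols * px**2
    n_nuclei = max(2, int(rng.poisson(params.nuclei_density_per_um2 * field_area_um2)))
    nuc_img = np.zeros((rows, cols))
    for _ in range(n_nuclei):
        r0 = rng.uniform(0, rows)
        c0 = rng.uniform(0, cols)
        rad = max(0.5, rng.normal(*params.nucleus_radius_um))
        amp = params.punctum_amplitude * rng.uniform(0.5, 1.0)
        _add_gaussian_blob(nuc_img, r0, c0, rad / px, amp)
        # chromatin granularity: bright sub-µm puncta inside the nucleus
        for _ in range(25):
            ang = rng.uniform(0, 2 * np.pi)
            rr = rad / px * np.sqrt(rng.random())
            _add_gaussian_blob(nuc_img, r0 + rr * np.sin(ang),
                               c0 + rr * np.cos(ang),
                               rng.uniform(0.15, 0.3) / px, 0.4 * amp)
    signal["dapi"] += nuc_img[None, :, :]

    truth_masks = {
        name: sig > TRUTH_SNR_CUT * params.photon_noise_sd
        for name, sig in signal.items()
    }

    # -- noise, then misalignment -----------------------------------------
    aligned_channels = {}
    for name, sig in signal.items():
        noisy = sig + params.background_level + rng.normal(
            0.0, params.photon_noise_sd, size=sig.shape)
        aligned_channels[name] = np.clip(noisy, 0, None).astype(np.float32)

    shifts = np.zeros((n, 2), dtype=float)
    if params.shift_sd_px > 0:
        raw = rng.normal(0.0, params.shift_sd_px, size=(n, 2))
        raw[0] = 0.0
        shifts = raw if params.subpixel_shifts else np.round(raw)
        shifts[0] = 0.0

    misaligned = {}
    for name, arr in aligned_channels.items():
        out = np.empty_like(arr)
        for z in range(n):
            out[z] = _translate_section(arr[z], shifts[z])
        misaligned[name] = out

    calib = dict(pixel_size_xy=px, section_thickness=dz)
    aligned_stack = ChannelStack(channels=aligned_channels, provenance="synthetic (aligned)",
                                 **calib)
    stack = ChannelStack(channels=misaligned, provenance="synthetic", **calib)

    true_densities = {
        ch: len([p for p in puncta if p.channel == ch]) / params.volume_um3
        for ch in params.synaptic_channels
    }
    truth = SyntheticTruth(
        puncta=puncta,
        specks=specks,
        true_shifts=shifts,
        plaques=list(params.plaque_spec),
        true_densities=true_densities,
        aligned=aligned_stack,
        truth_masks=truth_masks,
    )
    return stack, truth


def _translate_section(img: np.ndarray, shift: np.ndarray) -> np.ndarray:
    """Translate a 2D section by (drow, dcol); integer shifts roll exactly."""
    dr, dc = float(shift[0]), float(shift[1])
    if dr == int(dr) and dc == int(dc):
        return np.roll(img, (int(dr), int(dc)), axis=(0, 1))
    f = np.fft.fft2(img)
    from scipy.ndimage import fourier_shift

    return np.real(np.fft.ifft2(fourier_shift(f, (dr, dc)))).astype(img.dtype)


# ---------------------------------------------------------------------------
# Open-field trajectories
# ---------------------------------------------------------------------------

def generate_trajectory(
    duration_s: float,
    step_model: str = "random_walk",
    arena_cm: float = 40.0,
    seed: int = 0,
    *,
    dt_s: float = 0.1,
    speed_cm_s: float = 8.0,
    wall_offset_cm: float = 2.0,
) -> Trajectory:
    """Simulate an open-field trajectory inside a square arena.

    ``step_model`` regimes:

    - ``"random_walk"`` — correlated random walk reflected at the walls
      (typical exploratory mouse locomotion, ~8 cm/s).
    - ``"immobile"`` — animal parked at the centre (zero path length).
    - ``"center_only"`` — walk confined to the central 20×20 cm zone.
    - ``"wall_following"`` — constant-speed circuit ``wall_offset_cm``
      from the walls (thigmotaxis); one lap of a 40 cm arena at 2 cm
      offset covers 4 × 36 = 144 cm.
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    if dt_s <= 0:
        raise ValueError("sampling interval must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s / dt_s)) + 1
    t = np.arange(n) * dt_s
    c = arena_cm / 2.0

    if step_model == "immobile":
        x = np.full(n, c)
        y = np.full(n, c)
    elif step_model in ("random_walk", "center_only"):
        if step_model == "center_only":
            lo, hi = c - 10.0, c + 10.0
        else:
            lo, hi = 0.0, arena_cm
        x = np.empty(n)
        y = np.empty(n)
        x[0] = y[0] = c
        heading = rng.uniform(0, 2 * np.pi)
        for i in range(1, n):
            heading += rng.normal(0.0, 0.8)
            step = max(0.0, rng.normal(speed_cm_s, speed_cm_s / 3)) * dt_s
            xi = x[i - 1] + step * np.cos(heading)
            yi = y[i - 1] + step * np.sin(heading)
            x[i] = _reflect(xi, lo, hi)
            y[i] = _reflect(yi, lo, hi)
    elif step_model == "wall_following":
        side = arena_cm - 2 * wall_offset_cm
        if side <= 0:
            raise ValueError("wall offset larger than half the arena")
        perimeter = 4 * side
        s = np.mod(speed_cm_s * t, perimeter)
        x = np.empty(n)
        y = np.empty(n)
        o = wall_offset_cm
        for i, si in enumerate(s):
            leg, u = divmod(si, side)
            if leg == 0:
                x[i], y[i] = o + u, o
            elif leg == 1:
                x[i], y[i] = o + side, o + u
            elif leg == 2:
                x[i], y[i] = o + side - u, o + side
            else:
                x[i], y[i] = o, o + side - u
    else:
        raise ValueError(f"unknown step_model {step_model!r}")

    return Trajectory(t_s=t, x_cm=x, y_cm=y, arena_cm=arena_cm)


def _reflect(v: float, lo: float, hi: float) -> float:
    span = hi - lo
    v = (v - lo) % (2 * span)
    return lo + (v if v <= span else 2 * span - v)


# ---------------------------------------------------------------------------
# Genotype cohorts
# ---------------------------------------------------------------------------

def generate_genotype_cohort(
    n: int,
    proportions: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25),
    seed: int = 0,
) -> np.ndarray:
    """Draw genotype class counts for ``n`` offspring.

    A four-way F1 cross segregating two independent heterozygous
    transgenes yields the default 25/25/25/25 Mendelian expectation;
    counts are a single multinomial draw.
    """
    props = np.asarray(proportions, dtype=float)
    if n < 0:
        raise ValueError("n must be >= 0")
    if np.any(props < 0) or not math.isclose(props.sum(), 1.0, rel_tol=1e-9):
        raise ValueError("proportions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    return rng.multinomial(n, props)
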
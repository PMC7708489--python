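"""Forward optical model: fluorescence speckle acquisitions through a scattering medium.

A segmented phase-only SLM with ``n_slm`` independent segments illuminates a
scattering medium hiding a fluorescent object made of ``n_targets`` point-like
emitters.  Two transmission matrices describe the experiment:

* the ingoing *field* transmission matrix ``T`` (``n_targets x n_slm``,
  complex) maps the SLM field onto the excitation field at each emitter, so
  the excitation speckle intensity for input pattern ``p`` is
  ``|T E_in(p)|**2`` — fully developed speckle, exponential statistics;
* the outgoing *intensity* transmission matrix ``W`` (``n_pixels x
  n_targets``, non-negative) maps emitter brightness onto the low-coherence
  fluorescence speckle ("eigen-pattern") each emitter casts on the
  epi-detection camera.

A camera frame for pattern ``p`` is therefore::

    I_out(p) = W (|T E_in(p)|**2) ** excitation_exponent

with ``excitation_exponent`` 1 for linear fluorescence and 2 for two-photon
excitation, optionally degraded by Poisson shot noise and Gaussian read noise.

Memory effect
-------------
Thin scattering media exhibit a translational "memory effect" (ME): tilting
the input wavefront shifts the output speckle within a finite patch.  The
simulator realises this with two ingredients:

* rows of ``T`` carry a deterministic *tilt* phase ramp across the SLM
  proportional to the emitter position (one speckle-grain shift in the object
  plane corresponds to a 2*pi ramp across the SLM aperture), and
* the stochastic part of each row / eigen-pattern is drawn from a latent
  Gaussian random field over object-plane position, so that the registered
  speckle correlation between emitters separated by ``d`` decays as
  ``c(d) = exp(-d**2 / (2 me_range**2))``.

Eigen-patterns of emitters within one ME patch are, to correlation ``c(d)``,
integer-pixel translated copies of each other — the ground truth used by the
memory-effect imaging tests is planted explicitly by construction.
"""

from __future__ import annotations

import hashlib
import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numpy.fft import fft2, ifft2

__all__ = [
    "SimulationConfig",
    "EmitterMap",
    "PhasePatternSet",
    "FieldTM",
    "IntensityTM",
    "SpeckleStack",
    "substream",
    "generate_random_patterns",
    "random_emitters",
    "make_field_tm",
    "make_intensity_tm",
    "simulate_acquisition",
    "speckle_contrast",
    "stack_contrast",
    "polarization_channels",
]

TWO_PI = 2.0 * np.pi


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one master seed.

    Components of a simulation (patterns, field TM, intensity TM, noise)
    draw from separate streams so each is individually reproducible.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic acquisition.

    Parameters
    ----------
    n_targets : number of fluorescent emitters N.
    n_slm : number of independent SLM phase segments.
    grid_shape : camera grid (rows, cols); D = rows * cols pixels.
    n_patterns : number P of random illumination patterns.
    me_range : memory-effect decorrelation scale (camera pixels).
    speckle_grain : speckle grain size (camera pixels, >= 2 for Nyquist).
    excitation_exponent : 1 (linear fluorescence) or 2 (two-photon).
    photon_budget : mean detected photons per pixel per frame; ``inf`` means
        noiseless.
    read_noise_sd : camera read noise (photons, Gaussian).
    seed : master seed; substreams are derived per component.
    """

    n_targets: int
    n_slm: int
    grid_shape: tuple[int, int]
    n_patterns: int
    me_range: float = 10.0
    speckle_grain: float = 2.0
    excitation_exponent: int = 1
    photon_budget: float = math.inf
    read_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid_shape", tuple(int(s) for s in self.grid_shape))
        if len(self.grid_shape) != 2 or any(s < 1 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be two positive integers, got {self.grid_shape}")
        for name in ("n_targets", "n_slm", "n_patterns"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.me_range <= 0:
            raise ValueError("me_range must be > 0")
        if self.speckle_grain < 2:
            raise ValueError("speckle_grain must be >= 2 pixels (Nyquist-sampled speckle)")
        if self.excitation_exponent not in (1, 2):
            raise ValueError("excitation_exponent must be 1 (linear) or 2 (two-photon)")
        if self.photon_budget <= 0:
            raise ValueError("photon_budget must be positive (inf for noiseless)")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be >= 0")

    @property
    def n_pixels(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def digest(self) -> str:
        """Short stable hash of the configuration (recorded in stack metadata)."""
        return hashlib.sha256(repr(self).encode()).hexdigest()[:16]


@dataclass
class EmitterMap:
    """Positions (row, col; 0-based camera pixels) and brightness of the N emitters."""

    positions: np.ndarray
    brightness: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=int))
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must be an (N, 2) array of (row, col) pixels")
        n = self.positions.shape[0]
        if self.brightness is None:
            self.brightness = np.ones(n)
        self.brightness = np.asarray(self.brightness, dtype=float)
        if self.brightness.shape != (n,):
            raise ValueError("brightness must have one entry per emitter")
        if np.any(self.brightness <= 0):
            raise ValueError("brightness must be strictly positive")

    @property
    def n_targets(self) -> int:
        return self.positions.shape[0]

    def validate_grid(self, grid_shape: tuple[int, int]) -> None:
        rows, cols = grid_shape
        ok = (
            (self.positions[:, 0] >= 0)
            & (self.positions[:, 0] < rows)
            & (self.positions[:, 1] >= 0)
            & (self.positions[:, 1] < cols)
        )
        if not np.all(ok):
            bad = np.flatnonzero(~ok)
            raise ValueError(f"emitters {bad.tolist()} lie outside the {rows}x{cols} camera grid")


def random_emitters(
    grid_shape: tuple[int, int],
    n: int,
    min_sep: float,
    rng: np.random.Generator,
    margin: int = 4,
    max_tries: int = 200000,
) -> EmitterMap:
    """Draw ``n`` emitter positions by dart throwing with a minimum separation.

    Emitters closer than a speckle grain are unresolvable and closer than the
    duplicate-rejection scale are ambiguous for demixing, so studies place
    beads at least a few grains apart.
    """
    rows, cols = grid_shape
    positions: list[np.ndarray] = []
    tries = 0
    while len(positions) < n:
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} emitters with min_sep={min_sep} in {rows}x{cols}"
            )
        tries += 1
        cand = np.array(
            [rng.integers(margin, rows - margin), rng.integers(margin, cols - margin)]
        )
        if all(np.linalg.norm(cand - p) >= min_sep for p in positions):
            positions.append(cand)
    return EmitterMap(np.array(positions))


@dataclass
class PhasePatternSet:
    """P phase-only SLM inputs; ``fields`` are the unit-amplitude phasors E_in."""

    phases: np.ndarray

    def __post_init__(self) -> None:
        self.phases = np.asarray(self.phases, dtype=float)
        if self.phases.ndim != 2:
            raise ValueError("phases must be an (n_slm, n_patterns) matrix")

    @property
    def n_slm(self) -> int:
        return self.phases.shape[0]

    @property
    def n_patterns(self) -> int:
        return self.phases.shape[1]

    @property
    def fields(self) -> np.ndarray:
        return np.exp(1j * self.phases)


def generate_random_patterns(n_slm: int, n_patterns: int, seed: int) -> PhasePatternSet:
    """I.i.d. uniform random phase patterns on [0, 2*pi), reproducible per seed."""
    if n_slm < 1 or n_patterns < 1:
        raise ValueError("n_slm and n_patterns must be >= 1")
    rng = substream(seed, "patterns")
    return PhasePatternSet(rng.uniform(0.0, TWO_PI, size=(int(n_slm), int(n_patterns))))


# ---------------------------------------------------------------------------
# latent memory-effect machinery


def _latent_nodes(positions: np.ndarray, width: float, pad: float = 3.0) -> np.ndarray:
    """Grid of latent-field nodes covering the emitters, padded by ``pad`` widths."""
    spacing = max(width / 2.0, 1.0)
    lo = positions.min(axis=0) - pad * width
    hi = positions.max(axis=0) + pad * width
    rr = np.arange(lo[0], hi[0] + spacing, spacing)
    cc = np.arange(lo[1], hi[1] + spacing, spacing)
    grid = np.stack(np.meshgrid(rr, cc, indexing="ij"), axis=-1).reshape(-1, 2)
    return grid


def _me_weights(positions: np.ndarray, nodes: np.ndarray, width: float) -> np.ndarray:
    """Normalized Gaussian mixture weights; row n mixes the latent fields for
    position n such that corr(x, x') = exp(-|x-x'|**2 / (4 width**2))."""
    d2 = ((positions[:, None, :] - nodes[None, :, :]) ** 2).sum(axis=2)
    w = np.exp(-d2 / (2.0 * width**2))
    norm = np.sqrt((w**2).sum(axis=1, keepdims=True))
    if np.any(norm == 0):
        raise RuntimeError("latent node grid does not cover all emitter positions")
    return w / norm


def _slm_coords(n_slm: int) -> np.ndarray:
    """Normalized 2-D segment coordinates in [-1/2, 1/2)^2 (row-major square-ish grid)."""
    side = int(math.ceil(math.sqrt(n_slm)))
    idx = np.arange(n_slm)
    r = idx // side
    c = idx % side
    return np.stack([(r - (side - 1) / 2.0) / side, (c - (side - 1) / 2.0) / side], axis=1)


def _speckle_fields(rng: np.random.Generator, n: int, grid_shape: tuple[int, int], grain: float) -> np.ndarray:
    """``n`` independent smoothed circular-Gaussian fields (periodic, unit variance).

    Intensities ``|field|**2`` are pixelwise exponential (fully developed
    speckle, contrast 1) with grain size ``grain`` pixels.
    """
    rows, cols = grid_shape
    noise = rng.standard_normal((n, rows, cols)) + 1j * rng.standard_normal((n, rows, cols))
    fr = np.fft.fftfreq(rows)[:, None]
    fc = np.fft.fftfreq(cols)[None, :]
    sig = grain / 2.0
    transfer = np.exp(-2.0 * np.pi**2 * sig**2 * (fr**2 + fc**2))
    f = ifft2(fft2(noise, axes=(-2, -1)) * transfer, axes=(-2, -1))
    f /= np.sqrt(np.mean(np.abs(f) ** 2, axis=(-2, -1), keepdims=True))
    return f


@dataclass
class FieldTM:
    """Ingoing field transmission matrix ``T`` plus the geometry it was built for.

    ``matrix`` rows are per-segment circular Gaussian with a deterministic tilt
    phase ramp encoding the emitter position; optional ``probe_matrix`` rows
    are statistically identical rows at non-emitter positions, used as
    background grains when scoring foci on the control side.
    """

    matrix: np.ndarray
    positions: np.ndarray
    speckle_grain: float
    me_range: float
    slm_coords: np.ndarray
    probe_matrix: np.ndarray | None = None
    probe_positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.matrix, axis=1)
        if not np.all(np.isfinite(norms)) or np.any(norms == 0):
            raise ValueError("field TM rows must have finite, nonzero norm")

    @property
    def n_targets(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_slm(self) -> int:
        return self.matrix.shape[1]

    def tilt_phasor(self, shift: Sequence[float]) -> np.ndarray:
        """Per-segment phasor of the tilt mapping an object-plane shift (pixels).

        One speckle-grain shift corresponds to a full 2*pi ramp across the SLM
        aperture, so foci one grain apart use orthogonal ramps.
        """
        shift = np.asarray(shift, dtype=float)
        phase = TWO_PI * (self.slm_coords @ shift) / self.speckle_grain
        return np.exp(1j * phase)

    def excitation_intensity(self, patterns: PhasePatternSet, exponent: int = 1) -> np.ndarray:
        """Ground-truth H = (|T E_in|**2)**exponent (n_targets x n_patterns)."""
        e = np.abs(self.matrix @ patterns.fields) ** 2
        return e if exponent == 1 else e**exponent

    def registered_row_correlation(self, i: int, j: int) -> float:
        """Speckle field correlation between emitters i and j after registering
        out the deterministic tilt; its square is the ME intensity correlation."""
        a = self.matrix[i] * np.conj(self.tilt_phasor(self.positions[i]))
        b = self.matrix[j] * np.conj(self.tilt_phasor(self.positions[j]))
        return float(np.abs(np.vdot(a, b)) / (np.linalg.norm(a) * np.linalg.norm(b)))


def make_field_tm(
    config: SimulationConfig,
    emitter_map: EmitterMap,
    probe_positions: np.ndarray | None = None,
) -> FieldTM:
    """Draw the ingoing field TM with tilt-shift memory-effect structure.

    The registered field correlation between positions separated by ``d``
    equals ``c(d) = exp(-d**2 / (2 me_range**2))``; the corresponding
    excitation *intensity* correlation is ``c(d)**2``.  Extra ``probe_positions``
    get statistically identical rows drawn from the same latent field, serving
    as background speckle grains for control-side focus metrics.
    """
    emitter_map.validate_grid(config.grid_shape)
    if emitter_map.n_targets != config.n_targets:
        raise ValueError(
            f"emitter map has {emitter_map.n_targets} emitters, config expects {config.n_targets}"
        )
    rng = substream(config.seed, "field_tm")
    pos = emitter_map.positions.astype(float)
    if probe_positions is not None:
        probe_positions = np.atleast_2d(np.asarray(probe_positions, dtype=float))
        allpos = np.vstack([pos, probe_positions])
    else:
        allpos = pos
    # field-correlation kernel width sigma/sqrt(2) => registered field corr c(d)
    width = config.me_range / math.sqrt(2.0)
    nodes = _latent_nodes(allpos, width)
    weights = _me_weights(allpos, nodes, width)
    latent = (
        rng.standard_normal((nodes.shape[0], config.n_slm))
        + 1j * rng.standard_normal((nodes.shape[0], config.n_slm))
    ) / math.sqrt(2.0)
    fields = weights @ latent  # (n_pos, n_slm), unit variance circular Gaussian
    coords = _slm_coords(config.n_slm)
    tilt = np.exp(
        1j * TWO_PI * (allpos @ coords.T) / config.speckle_grain
    )  # (n_pos, n_slm)
    rows = fields * tilt
    n = emitter_map.n_targets
    return FieldTM(
        matrix=rows[:n],
        positions=emitter_map.positions.copy(),
        speckle_grain=config.speckle_grain,
        me_range=config.me_range,
        slm_coords=coords,
        probe_matrix=rows[n:] if probe_positions is not None else None,
        probe_positions=None if probe_positions is None else probe_positions.astype(int),
    )


@dataclass
class IntensityTM:
    """Outgoing intensity TM ``W``: column n is emitter n's fluorescent eigen-pattern."""

    matrix: np.ndarray
    grid_shape: tuple[int, int]
    positions: np.ndarray
    speckle_grain: float
    me_range: float

    def __post_init__(self) -> None:
        if np.any(self.matrix < 0):
            raise ValueError("intensity TM entries must be >= 0")
        if np.any(self.matrix.sum(axis=0) == 0):
            raise ValueError("intensity TM has an all-zero column")

    @property
    def n_targets(self) -> int:
        return self.matrix.shape[1]

    def pattern(self, n: int) -> np.ndarray:
        return self.matrix[:, n].reshape(self.grid_shape)


def make_intensity_tm(config: SimulationConfig, emitter_map: EmitterMap) -> IntensityTM:
    """Draw the outgoing intensity TM with ME-correlated, shift-planted eigen-patterns.

    Each eigen-pattern is the intensity of a smoothed complex speckle field
    (pixelwise exponential statistics, spatial contrast ~1), circularly shifted
    by the emitter's position.  Latent fields of emitters separated by ``d``
    correlate such that the *intensity* pattern correlation is
    ``c(d) = exp(-d**2/(2 me_range**2))``; within the ME patch patterns are
    therefore translated copies up to correlation c(d), and the planted shift
    is exact in integer pixels (periodic boundary).
    """
    emitter_map.validate_grid(config.grid_shape)
    if emitter_map.n_targets != config.n_targets:
        raise ValueError(
            f"emitter map has {emitter_map.n_targets} emitters, config expects {config.n_targets}"
        )
    rng = substream(config.seed, "intensity_tm")
    pos = emitter_map.positions.astype(float)
    # intensity corr = field corr**2; want intensity corr c(d) => field kernel width sigma
    width = float(config.me_range)
    nodes = _latent_nodes(pos, width)
    weights = _me_weights(pos, nodes, width)
    latent = _speckle_fields(rng, nodes.shape[0], config.grid_shape, config.speckle_grain)
    mixed = np.tensordot(weights, latent, axes=(1, 0))  # (N, rows, cols) complex
    cols = []
    for n in range(emitter_map.n_targets):
        env = np.abs(mixed[n]) ** 2
        env = np.roll(env, shift=tuple(emitter_map.positions[n]), axis=(0, 1))
        cols.append(emitter_map.brightness[n] * env.ravel())
    return IntensityTM(
        matrix=np.stack(cols, axis=1),
        grid_shape=config.grid_shape,
        positions=emitter_map.positions.copy(),
        speckle_grain=config.speckle_grain,
        me_range=config.me_range,
    )


@dataclass
class SpeckleStack:
    """Stack of P epi-detected frames, stored as a non-negative (D x P) matrix."""

    images: np.ndarray
    grid_shape: tuple[int, int]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        if self.images.ndim != 2:
            raise ValueError("images must be a (D, P) matrix")
        if np.any(self.images < 0):
            raise ValueError("speckle stack entries must be >= 0")
        rows, cols = self.grid_shape
        if rows * cols != self.images.shape[0]:
            raise ValueError(
                f"grid_shape {self.grid_shape} does not match D={self.images.shape[0]} (axis 0)"
            )

    @property
    def n_pixels(self) -> int:
        return self.images.shape[0]

    @property
    def n_patterns(self) -> int:
        return self.images.shape[1]

    def frame(self, p: int) -> np.ndarray:
        return self.images[:, p].reshape(self.grid_shape)

    def frames(self) -> np.ndarray:
        """(P, rows, cols) view of the stack."""
        return self.images.T.reshape(self.n_patterns, *self.grid_shape)


def simulate_acquisition(
    field_tm: FieldTM,
    intensity_tm: IntensityTM,
    patterns: PhasePatternSet,
    config: SimulationConfig,
) -> SpeckleStack:
    """Run the forward model I_out(p) = W (|T E_in(p)|**2)**e with camera noise.

    Noiseless mode (``photon_budget == inf`` and zero read noise) is
    bit-reproducible for a fixed seed.  With a finite photon budget the stack
    is scaled to the requested mean photon count, Poisson sampled, read noise
    added, clipped at zero, and scaled back to the noiseless units.
    """
    if field_tm.n_slm != patterns.n_slm:
        raise ValueError(
            f"axis mismatch on n_slm: field TM has {field_tm.n_slm}, patterns have {patterns.n_slm}"
        )
    if intensity_tm.n_targets != field_tm.n_targets:
        raise ValueError(
            "axis mismatch on n_targets: intensity TM has "
            f"{intensity_tm.n_targets}, field TM has {field_tm.n_targets}"
        )
    if intensity_tm.matrix.shape[0] != config.n_pixels:
        raise ValueError(
            f"axis mismatch on n_pixels: intensity TM has {intensity_tm.matrix.shape[0]}, "
            f"config grid gives {config.n_pixels}"
        )
    h = field_tm.excitation_intensity(patterns, config.excitation_exponent)
    images = intensity_tm.matrix @ h
    noisy = math.isfinite(config.photon_budget) or config.read_noise_sd > 0
    if noisy:
        rng = substream(config.seed, "noise")
        if math.isfinite(config.photon_budget):
            scale = config.photon_budget / max(images.mean(), np.finfo(float).tiny)
        else:
            scale = 1.0
        counts = rng.poisson(images * scale).astype(float) if math.isfinite(
            config.photon_budget
        ) else images * scale
        if config.read_noise_sd > 0:
            counts = counts + rng.normal(0.0, config.read_noise_sd, size=counts.shape)
        images = np.clip(counts, 0.0, None) / scale
    meta = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "grid_shape": config.grid_shape,
        "noisy": noisy,
    }
    return SpeckleStack(images=images, grid_shape=config.grid_shape, meta=meta)


def speckle_contrast(image: np.ndarray) -> float:
    """Spatial contrast std/mean of a single non-negative image."""
    image = np.asarray(image, dtype=float)
    m = image.mean()
    if m <= 0:
        raise ValueError("speckle contrast is undefined for a zero-mean image")
    return float(image.std() / m)


def stack_contrast(stack: SpeckleStack | np.ndarray, estimator: str = "rms") -> float:
    """Ensemble contrast of a stack of frames.

    ``estimator="rms"`` returns sqrt(mean over frames of the spatial variance)
    divided by the mean over frames of the spatial mean.  For N equal
    incoherent emitters under fully developed linear excitation this statistic
    has expectation sqrt(2/N) for every N.  ``estimator="per_frame"`` averages
    the per-frame std/mean, which is biased low by O(1/N) (Jensen and the
    N+1 denominator of the Dirichlet moment) — noticeable for small N.
    """
    images = stack.images if isinstance(stack, SpeckleStack) else np.asarray(stack, dtype=float)
    means = images.mean(axis=0)
    if np.any(means <= 0):
        raise ValueError("stack contains a zero-mean frame")
    if estimator == "rms":
        return float(np.sqrt(images.var(axis=0).mean()) / means.mean())
    if estimator == "per_frame":
        return float((images.std(axis=0) / means).mean())
    raise ValueError(f"unknown estimator {estimator!r}")


def polarization_channels(stack_a: SpeckleStack, stack_b: SpeckleStack) -> SpeckleStack:
    """Unpolarized detection: pixel-wise average of two independent polarization channels.

    Averaging k independent speckle channels divides the contrast by sqrt(k);
    inserting a polarizer (keeping one channel) therefore raises the contrast
    by sqrt(2) relative to unpolarized detection.
    """
    if stack_a.images.shape != stack_b.images.shape:
        raise ValueError(
            f"shape mismatch: {stack_a.images.shape} vs {stack_b.images.shape}"
        )
    meta = dict(stack_a.meta)
    meta["polarization"] = "unpolarized (two-channel average)"
    return SpeckleStack(
        images=0.5 * (stack_a.images + stack_b.images),
        grid_shape=stack_a.grid_shape,
        meta=meta,
    )
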
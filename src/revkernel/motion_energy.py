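"""Random-dot kinematograms and opponent motion-energy filtering.

The stimulus is the classic three-set random-dot kinematogram: three
interleaved sets of dots are shown in consecutive video frames, and each set
is replotted ``displace_frames`` (3) video frames after it last appeared.
On each replot a Bernoulli(coherence) subset of the set's dots is displaced
coherently along the motion axis at the stimulus speed while the remainder
is replotted at random positions inside the aperture.

Motion energy is computed with two quadrature pairs of direction-selective
spatiotemporal filters.  Each filter is a sum of space-time separable
components built from even and odd fourth-order Cauchy functions of space,

    f1(x, y) = cos^4(a) cos(4a) exp(-y^2 / (2 w_g^2)),
    f2(x, y) = cos^4(a) sin(4a) exp(-y^2 / (2 w_g^2)),   a = atan(x / 0.35),

with w_g = 0.05 deg, and temporal impulse responses

    g1(t) = (60 t)^3 exp(-60 t) [1/3! - (60 t)^2 / 5!],
    g2(t) = (60 t)^5 exp(-60 t) [1/5! - (60 t)^2 / 7!]   (t in seconds).

The combinations f1 g1 + f2 g2 and f2 g1 - f1 g2 prefer one direction along
the filter axis; f1 g1 - f2 g2 and f2 g1 + f1 g2 prefer the opposite one.
The movie is convolved with each filter, outputs of each quadrature pair are
squared and summed (energy), summed over space, and the anti-preferred
energy is subtracted from the preferred to give the net motion energy per
video frame.  The filter constants are matched to the spatiotemporal
band-pass of direction-selective cortical neurons and to the 5 deg/s dot
speed; the temporal lag of the filters makes stimulus fluctuations appear
in the energies with a delay of roughly 50 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import convolve1d
from scipy.signal import fftconvolve
from scipy.stats import linregress

from .stimgen import InvalidParameterError

__all__ = [
    "DotMovie",
    "FilterBank",
    "make_dot_movie",
    "build_filters",
    "net_motion_energy",
    "direction_energies",
    "coherence_energy_slope",
    "step_response_lag",
]


@dataclass
class DotMovie:
    """Binary dot movie: luminance array of shape (nx, ny, n_frames)."""

    frames: np.ndarray
    deg_per_pixel: float
    frame_rate: float
    aperture_deg: float
    coherence: float
    speed: float = 5.0
    density: float = 16.7
    n_sets: int = 3
    displace_frames: int = 3
    seed: int | None = None
    positions: list | None = None  # per-frame dot positions when recorded

    @property
    def n_frames(self) -> int:
        return self.frames.shape[2]

    @property
    def dots_per_frame(self) -> float:
        counts = self.frames.reshape(-1, self.n_frames).sum(axis=0)
        return float(counts.mean())


def make_dot_movie(
    coherence: float | np.ndarray,
    n_frames: int,
    aperture_deg: float = 5.0,
    frame_rate: float = 75.0,
    speed: float = 5.0,
    density: float = 16.7,
    n_sets: int = 3,
    displace_frames: int = 3,
    deg_per_pixel: float = 0.05,
    seed=None,
    record_positions: bool = False,
) -> DotMovie:
    """Generate a random-dot kinematogram.

    ``coherence`` in [-1, 1]; its sign selects the motion direction along the
    x axis.  A per-frame coherence profile may be passed instead of a scalar
    (used for step-response probes).  Dots that leave the aperture during a
    coherent displacement wrap to the opposite side, preserving density.
    """
    coh = np.atleast_1d(np.asarray(coherence, dtype=float))
    if np.any(np.abs(coh) > 1):
        raise InvalidParameterError("coherence must lie in [-1, 1]")
    coh_t = np.full(n_frames, coh[0]) if coh.size == 1 else np.asarray(coh, dtype=float)
    if coh_t.size != n_frames:
        raise InvalidParameterError("coherence profile length must equal n_frames")
    radius = aperture_deg / 2.0
    step = speed * displace_frames / frame_rate
    if step >= aperture_deg:
        raise InvalidParameterError("aperture smaller than one coherent displacement")
    rng = np.random.default_rng(seed)
    n_dots = max(1, round(density * np.pi * radius**2 / frame_rate))
    npix = int(round(aperture_deg / deg_per_pixel))

    def uniform_in_circle(m):
        r = radius * np.sqrt(rng.random(m))
        th = rng.random(m) * 2 * np.pi
        return np.column_stack([r * np.cos(th), r * np.sin(th)])

    sets = [uniform_in_circle(n_dots) for _ in range(n_sets)]
    shown = [False] * n_sets
    frames = np.zeros((npix, npix, n_frames), dtype=np.float32)
    positions = [] if record_positions else None

    # circular aperture mask on the pixel grid
    ax = (np.arange(npix) + 0.5) * deg_per_pixel - radius
    mask = ax[:, None] ** 2 + ax[None, :] ** 2 <= radius**2

    for t in range(n_frames):
        k = t % n_sets
        pos = sets[k]
        if shown[k]:  # replot: coherent subset displaced, rest random
            c = abs(coh_t[t])
            sgn = np.sign(coh_t[t]) if coh_t[t] != 0 else 1.0
            coherent = rng.random(n_dots) < c
            pos = pos.copy()
            pos[coherent, 0] += sgn * step
            # wrap dots that left the aperture to the opposite side
            out = pos[:, 0] ** 2 + pos[:, 1] ** 2 > radius**2
            wrap = coherent & out
            if wrap.any():
                chord = np.sqrt(np.maximum(radius**2 - pos[wrap, 1] ** 2, 0.0))
                pos[wrap, 0] -= sgn * 2.0 * chord
            n_rand = int((~coherent).sum())
            if n_rand:
                pos[~coherent] = uniform_in_circle(n_rand)
            sets[k] = pos
        shown[k] = True
        ix = np.clip(((pos[:, 0] + radius) / deg_per_pixel).astype(int), 0, npix - 1)
        iy = np.clip(((pos[:, 1] + radius) / deg_per_pixel).astype(int), 0, npix - 1)
        frames[ix, iy, t] = 1.0
        frames[:, :, t] *= mask
        if record_positions:
            positions.append(pos.copy())

    return DotMovie(
        frames=frames,
        deg_per_pixel=deg_per_pixel,
        frame_rate=frame_rate,
        aperture_deg=aperture_deg,
        coherence=float(coh[0]) if coh.size == 1 else float("nan"),
        speed=speed,
        density=density,
        n_sets=n_sets,
        displace_frames=displace_frames,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
        positions=positions,
    )


@dataclass
class FilterBank:
    """Spatiotemporal filter constants and support extents."""

    omega_g: float = 0.05  # deg; sd of the transverse Gaussian
    alpha_scale: float = 0.35  # deg; x scale inside atan
    temporal_rate: float = 60.0  # 1/s
    x_extent: float = 1.5  # deg; truncation of the Cauchy envelope
    y_extent: float = 0.35  # deg; 7 sd of the transverse Gaussian
    t_extent: float = 0.3  # s; temporal truncation
    deg_per_pixel: float = 0.05
    frame_rate: float = 75.0
    orientation: str = "x"  # motion axis: "x" or "y"

    def x_grid(self) -> np.ndarray:
        n = int(round(self.x_extent / self.deg_per_pixel))
        return np.arange(-n, n + 1) * self.deg_per_pixel

    def y_grid(self) -> np.ndarray:
        n = int(round(self.y_extent / self.deg_per_pixel))
        return np.arange(-n, n + 1) * self.deg_per_pixel

    def t_grid(self) -> np.ndarray:
        n = int(round(self.t_extent * self.frame_rate))
        return np.arange(n + 1) / self.frame_rate

    # 1-D separable components -------------------------------------------
    def fx_even(self, x: np.ndarray) -> np.ndarray:
        a = np.arctan(np.asarray(x, dtype=float) / self.alpha_scale)
        return np.cos(a) ** 4 * np.cos(4 * a)

    def fx_odd(self, x: np.ndarray) -> np.ndarray:
        a = np.arctan(np.asarray(x, dtype=float) / self.alpha_scale)
        return np.cos(a) ** 4 * np.sin(4 * a)

    def fy(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=float)
        return np.exp(-(y**2) / (2 * self.omega_g**2))

    def f1(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.fx_even(x)[:, None] * self.fy(y)[None, :]

    def f2(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return self.fx_odd(x)[:, None] * self.fy(y)[None, :]

    def g1(self, t: np.ndarray) -> np.ndarray:
        u = self.temporal_rate * np.asarray(t, dtype=float)
        return u**3 * np.exp(-u) * (1.0 / 6.0 - u**2 / 120.0)

    def g2(self, t: np.ndarray) -> np.ndarray:
        u = self.temporal_rate * np.asarray(t, dtype=float)
        return u**5 * np.exp(-u) * (1.0 / 120.0 - u**2 / 5040.0)


def build_filters(bank: FilterBank) -> dict:
    """Materialize the four direction-selective 3-D kernels.

    Returns arrays of shape (nx, ny, nt) under keys ``pref_even``
    (f1 g1 + f2 g2), ``pref_odd`` (f2 g1 - f1 g2), ``anti_even``
    (f1 g1 - f2 g2), ``anti_odd`` (f2 g1 + f1 g2).  The separable fast path
    in :func:`net_motion_energy` is equivalent to convolving with these.
    """
    x, y, t = bank.x_grid(), bank.y_grid(), bank.t_grid()
    f1 = bank.f1(x, y)[:, :, None]
    f2 = bank.f2(x, y)[:, :, None]
    g1 = bank.g1(t)[None, None, :]
    g2 = bank.g2(t)[None, None, :]
    return {
        "pref_even": f1 * g1 + f2 * g2,
        "pref_odd": f2 * g1 - f1 * g2,
        "anti_even": f1 * g1 - f2 * g2,
        "anti_odd": f2 * g1 + f1 * g2,
    }


def _separable_responses(movie: DotMovie, bank: FilterBank):
    if abs(movie.deg_per_pixel - bank.deg_per_pixel) > 1e-12:
        raise InvalidParameterError("movie and filter bank use different spatial scales")
    if abs(movie.frame_rate - bank.frame_rate) > 1e-9:
        raise InvalidParameterError("movie and filter bank use different frame rates")
    frames = movie.frames.astype(np.float32)
    if bank.orientation == "y":
        frames = np.swapaxes(frames, 0, 1)
    elif bank.orientation != "x":
        raise InvalidParameterError(f"unknown orientation {bank.orientation!r}")
    nt_filt = bank.t_grid().size
    if movie.n_frames <= nt_filt:
        raise InvalidParameterError("movie shorter than the temporal filter support")
    fe = bank.fx_even(bank.x_grid()).astype(np.float32)
    fo = bank.fx_odd(bank.x_grid()).astype(np.float32)
    fy = bank.fy(bank.y_grid()).astype(np.float32)
    s1 = convolve1d(frames, fe, axis=0, mode="constant")
    s2 = convolve1d(frames, fo, axis=0, mode="constant")
    s1 = convolve1d(s1, fy, axis=1, mode="constant")
    s2 = convolve1d(s2, fy, axis=1, mode="constant")
    g1 = bank.g1(bank.t_grid()).astype(np.float32)[None, None, :]
    g2 = bank.g2(bank.t_grid()).astype(np.float32)[None, None, :]
    T = movie.n_frames
    a = fftconvolve(s1, g1, mode="full", axes=2)[:, :, :T]  # f1 * g1
    b = fftconvolve(s2, g2, mode="full", axes=2)[:, :, :T]  # f2 * g2
    c = fftconvolve(s2, g1, mode="full", axes=2)[:, :, :T]  # f2 * g1
    d = fftconvolve(s1, g2, mode="full", axes=2)[:, :, :T]  # f1 * g2
    return a, b, c, d


def direction_energies(movie: DotMovie, bank: FilterBank) -> tuple[np.ndarray, np.ndarray]:
    """Space-summed motion energy per video frame for the two opponent directions.

    Both series are non-negative; the first prefers motion toward positive
    coordinates along the filter axis.
    """
    a, b, c, d = _separable_responses(movie, bank)
    e_pref = ((a + b) ** 2 + (c - d) ** 2).sum(axis=(0, 1))
    e_anti = ((a - b) ** 2 + (c + d) ** 2).sum(axis=(0, 1))
    return e_pref.astype(np.float64), e_anti.astype(np.float64)


def net_motion_energy(movie: DotMovie, bank: FilterBank) -> np.ndarray:
    """Net opponent motion energy per video frame (preferred minus opposite)."""
    e_pref, e_anti = direction_energies(movie, bank)
    return e_pref - e_anti


def coherence_energy_slope(coherences, mean_energies) -> tuple[float, float]:
    """Least-squares slope of mean net energy vs coherence, with fit R^2.

    ``mean_energies`` holds, per coherence level, the per-movie time-averaged
    net energies (an array) or a precomputed scalar mean.  Requires at least
    three distinct levels.
    """
    coherences = np.asarray(coherences, dtype=float)
    if np.unique(coherences).size < 3:
        raise InvalidParameterError("need at least 3 coherence levels for calibration")
    means = np.array([float(np.mean(e)) for e in mean_energies])
    res = linregress(coherences, means)
    return float(res.slope), float(res.rvalue**2)


def step_response_lag(
    bank: FilterBank,
    step_frame: int = 30,
    n_frames: int = 75,
    n_movies: int = 100,
    coherence_after: float = 0.512,
    aperture_deg: float = 3.0,
    seed=None,
) -> int:
    """Latency (video frames) from a coherence step to the net-energy response.

    Plays ``n_movies`` kinematograms whose coherence steps from 0 to
    ``coherence_after`` at ``step_frame``, averages the net energy across
    movies, and returns the frame lag at which the ensemble-mean energy first
    reaches half of its post-step plateau.  The filters' temporal impulse
    responses impose a lag of roughly 50 ms.
    """
    ss = np.random.SeedSequence(seed)
    profile = np.zeros(n_frames)
    profile[step_frame:] = coherence_after
    acc = np.zeros(n_frames)
    for child in ss.spawn(n_movies):
        movie = make_dot_movie(profile, n_frames, aperture_deg=aperture_deg,
                               deg_per_pixel=bank.deg_per_pixel, seed=child)
        acc += net_motion_energy(movie, bank)
    mean = acc / n_movies
    base = mean[:step_frame].mean()
    plateau = mean[-(n_frames - step_frame) // 3 :].mean()
    half = base + 0.5 * (plateau - base)
    after = mean[step_frame:]
    above = np.nonzero(after >= half)[0]
    if above.size == 0:
        raise RuntimeError("net energy never reached half of the post-step plateau")
    return int(above[0])
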
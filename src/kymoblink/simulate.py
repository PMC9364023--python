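"""Synthetic single-molecule data generators.

Everything the analysis pipeline consumes can be generated here with known
ground truth: kymographs of diffusing, blinking quantum-dot-labeled proteins
on a DNA tightrope; blink-count samples from the linked monomer/dimer Poisson
mixture; two-color labeling outcomes of a partially dimerized population; and
FRET-excitation / circular-dichroism spectra of components and their mixture.

Every generator takes an explicit integer seed and is bit-reproducible; there
is no module-level random state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import Spectrum

__all__ = [
    "KymoSimParams",
    "KymoGroundTruth",
    "MixtureSimParams",
    "DualColorCounts",
    "simulate_kymograph",
    "simulate_blink_counts",
    "simulate_dual_color_population",
    "simulate_spectra",
    "write_kymograph_tiff",
    "read_kymograph_tiff",
]


@dataclass(frozen=True)
class KymoSimParams:
    """Acquisition and sample parameters for one simulated kymograph.

    Defaults emulate the study conditions: 60 s movies at 10 frames/s with
    63.2 nm pixels, a single diffraction-limited spot performing a reflected
    1D random walk along the tightrope, and stochastic dark-state blinking.
    """

    duration_s: float = 60.0
    frame_rate_hz: float = 10.0
    pixel_nm: float = 63.2
    n_pixels: int = 48
    psf_sigma_px: float = 1.5
    photons_per_frame: float = 200.0
    background_mean: float = 50.0
    background_sd: float = 3.0
    diffusion_coeff_px2_per_frame: float = 0.2
    n_emitters: int = 1
    blink_rate_per_s: float = 0.18
    mean_dark_frames: float = 3.0
    seed: int = 0

    @property
    def n_frames(self) -> int:
        n = self.duration_s * self.frame_rate_hz
        if abs(n - round(n)) > 1e-9 or n <= 0:
            raise ValueError("duration_s * frame_rate_hz must be a positive integer")
        return int(round(n))

    def validate(self) -> None:
        if self.n_emitters not in (1, 2):
            raise ValueError("n_emitters must be 1 (monomer) or 2 (dimer)")
        if self.n_pixels < 5:
            raise ValueError("n_pixels must be >= 5")
        for name in ("frame_rate_hz", "pixel_nm", "psf_sigma_px", "mean_dark_frames"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in (
            "photons_per_frame",
            "background_mean",
            "background_sd",
            "diffusion_coeff_px2_per_frame",
            "blink_rate_per_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        self.n_frames  # raises if invalid


@dataclass
class KymoGroundTruth:
    """Per-frame truth for one simulated kymograph.

    ``true_blink_count`` counts maximal runs of frames in which *all* emitters
    are simultaneously dark, excluding runs that touch the first or last frame
    (their true extent is censored) — the same convention the blink caller
    applies, so the two are directly comparable.
    """

    true_positions_px: np.ndarray  # shape (n_frames,)
    emitter_on: np.ndarray  # shape (n_emitters, n_frames), bool
    true_blink_count: int


@dataclass(frozen=True)
class MixtureSimParams:
    """Parameters of the linked dual-Poisson blink-count mixture.

    ``bl_mon`` is the expected number of monomer blinks per kymograph; the
    dimer expectation is tied to it through the squared-rate relation
    ``(bl_mon/duration)^2 * duration`` and is never an independent knob.
    ``alpha`` is the monomer amplitude of the mixture.
    """

    bl_mon: float = 10.8
    duration_s: float = 60.0
    alpha: float = 0.5
    n_kymographs: int = 50
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.bl_mon < 0:
            raise ValueError("bl_mon must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.n_kymographs < 1:
            raise ValueError("n_kymographs must be >= 1")


@dataclass
class DualColorCounts:
    """Observed single-spot color categories on DNA tightropes."""

    n_dual: int
    n_color_a: int
    n_color_b: int

    @property
    def n_total(self) -> int:
        return self.n_dual + self.n_color_a + self.n_color_b

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "category": ["dual", "color_a", "color_b"],
                "count": [self.n_dual, self.n_color_a, self.n_color_b],
            }
        )


def _interior_dark_run_count(all_dark: np.ndarray) -> int:
    """Count maximal all-dark runs strictly inside the record."""
    padded = np.concatenate(([False], all_dark, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)  # exclusive
    n = all_dark.size
    interior = (starts > 0) & (ends < n)
    return int(np.count_nonzero(interior))


def _simulate_on_states(
    rng: np.random.Generator, n_frames: int, p_enter: float, mean_dark: float
) -> np.ndarray:
    """Two-state Markov chain: emitting, with Poisson-process dark entries and
    geometric dark dwells (support >= 1 frame, mean ``mean_dark``)."""
    on = np.ones(n_frames, dtype=bool)
    p_geom = min(1.0, 1.0 / mean_dark)
    t = 0
    while t < n_frames:
        if rng.random() < p_enter:
            dwell = rng.geometric(p_geom)
            on[t : t + dwell] = False
            t += dwell
        else:
            t += 1
    return on


def simulate_kymograph(params: KymoSimParams) -> tuple["Kymograph", KymoGroundTruth]:
    """Simulate one kymograph with ground truth.

    The emitter center performs a reflected 1D Gaussian random walk with step
    variance ``diffusion_coeff_px2_per_frame``; a dimer's two emitters share
    the one center (inter-emitter distance is far below a pixel, so a dimer is
    a single diffraction-limited spot). Each emitter independently enters dark
    states as a Poisson process in time with geometric frame dwells. Per-frame
    pixel values are Gaussian read noise about the background plus Poisson
    shot noise on the summed ON-emitter Gaussian profiles.
    """
    from .kymo import Kymograph  # local import to avoid a cycle

    params.validate()
    rng = np.random.default_rng(params.seed)
    n_frames = params.n_frames
    dt = 1.0 / params.frame_rate_hz

    # Reflected random walk for the (shared) spot center.
    steps = rng.normal(
        0.0, np.sqrt(params.diffusion_coeff_px2_per_frame), size=n_frames
    )
    steps[0] = 0.0
    pos = (params.n_pixels - 1) / 2.0 + np.cumsum(steps)
    # reflect into [0, n_pixels - 1]
    span = params.n_pixels - 1.0
    pos = span - np.abs(np.mod(pos, 2.0 * span) - span)

    p_enter = 1.0 - np.exp(-params.blink_rate_per_s * dt)
    emitter_on = np.stack(
        [
            _simulate_on_states(rng, n_frames, p_enter, params.mean_dark_frames)
            for _ in range(params.n_emitters)
        ]
    )
    n_on = emitter_on.sum(axis=0)  # emitters emitting per frame

    x = np.arange(params.n_pixels, dtype=float)
    profile = np.exp(
        -((x[:, None] - pos[None, :]) ** 2) / (2.0 * params.psf_sigma_px**2)
    )
    signal = params.photons_per_frame * profile * n_on[None, :]

    read = rng.normal(params.background_mean, params.background_sd, size=signal.shape)
    shot = rng.poisson(signal) if params.photons_per_frame > 0 else 0.0
    intensity = read + shot

    truth = KymoGroundTruth(
        true_positions_px=pos,
        emitter_on=emitter_on,
        true_blink_count=_interior_dark_run_count(~emitter_on.any(axis=0)),
    )
    kymo = Kymograph(
        intensity=intensity,
        pixel_nm=params.pixel_nm,
        frame_interval_s=dt,
        id=f"sim-seed{params.seed}",
    )
    return kymo, truth


def simulate_blink_counts(params: MixtureSimParams) -> np.ndarray:
    """Draw per-kymograph blink counts from the monomer/dimer Poisson mixture.

    Each kymograph is a monomer with probability ``alpha`` (count ~
    Poisson(bl_mon)) or a dimer (count ~ Poisson(bl_dim)), where bl_dim is the
    squared-rate dimer expectation for the shared observation duration.
    """
    from .blink import dimer_expected

    params.validate()
    rng = np.random.default_rng(params.seed)
    bl_dim = dimer_expected(params.bl_mon, params.duration_s)
    is_mon = rng.random(params.n_kymographs) < params.alpha
    lam = np.where(is_mon, params.bl_mon, bl_dim)
    return rng.poisson(lam)


def simulate_dual_color_population(
    n_molecules: int,
    dimer_fraction: float,
    color_probs: tuple[float, float] = (0.5, 0.5),
    seed: int = 0,
    label_efficiency: float = 1.0,
) -> DualColorCounts:
    """Simulate two-color labeling of a partly dimerized DNA-bound population.

    Each molecule is a dimer with probability ``dimer_fraction``; every
    subunit independently carries a label with probability
    ``label_efficiency`` and, if labeled, is color A or B per ``color_probs``.
    Monomers are single-colored by construction; dimers whose two labels
    differ are dual-colored; entities with no label at all are invisible and
    never counted.
    """
    if not 0.0 <= dimer_fraction <= 1.0:
        raise ValueError("dimer_fraction must be in [0, 1]")
    if not 0.0 <= label_efficiency <= 1.0:
        raise ValueError("label_efficiency must be in [0, 1]")
    pa, pb = color_probs
    if pa < 0 or pb < 0 or abs(pa + pb - 1.0) > 1e-9:
        raise ValueError("color_probs must be non-negative and sum to 1")
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")

    rng = np.random.default_rng(seed)
    is_dimer = rng.random(n_molecules) < dimer_fraction
    n_sub = np.where(is_dimer, 2, 1)
    # per subunit: 0 = unlabeled, 1 = color A, 2 = color B
    labeled1 = rng.random(n_molecules) < label_efficiency
    labeled2 = rng.random(n_molecules) < label_efficiency
    col1 = np.where(rng.random(n_molecules) < pa, 1, 2)
    col2 = np.where(rng.random(n_molecules) < pa, 1, 2)
    s1 = np.where(labeled1, col1, 0)
    s2 = np.where((n_sub == 2) & labeled2, col2, 0)

    has_a = (s1 == 1) | (s2 == 1)
    has_b = (s1 == 2) | (s2 == 2)
    n_dual = int(np.count_nonzero(has_a & has_b))
    n_a = int(np.count_nonzero(has_a & ~has_b))
    n_b = int(np.count_nonzero(has_b & ~has_a))
    return DualColorCounts(n_dual=n_dual, n_color_a=n_a, n_color_b=n_b)


# --- spectra ---------------------------------------------------------------

#: Band (nm) where donor (mNeonGreen-like) excitation enhancement appears.
FRET_DONOR_BAND_NM = (480.0, 520.0)
#: Band (nm) around the DNA circular-dichroism peak near 281 nm.
CD_DNA_BAND_NM = (271.0, 291.0)

_FRET_GRID = np.arange(450.0, 651.0, 10.0)
_CD_GRID = np.arange(190.0, 320.5, 1.0)


def _gauss(x: np.ndarray, amp: float, mu: float, sigma: float) -> np.ndarray:
    return amp * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def simulate_spectra(
    coupling: float,
    kind: str = "fret_excitation",
    seed: int = 0,
    noise_sd: float | None = None,
    consensus: bool = True,
) -> tuple[Spectrum, Spectrum, Spectrum]:
    """Simulate component spectra and their (possibly interacting) mixture.

    Returns ``(component_a, component_b, mixture)``. With ``coupling=0`` and
    ``noise_sd=0`` the mixture equals the component sum exactly; a positive
    coupling adds a band-localized enhancement — in the donor excitation band
    for a FRET excitation scan (energy transfer lights up the donor band of
    the acceptor-emission excitation spectrum), or at the 281 nm DNA band for
    CD. For CD, ``consensus=False`` emulates a non-consensus (non-TRE)
    oligonucleotide: no interaction regardless of ``coupling``.

    ``noise_sd`` defaults to 1.0 fluorescence counts (FRET) or 0.15 mdeg (CD),
    applied independently to each of the three returned spectra.
    """
    if not 0.0 <= coupling <= 1.0:
        raise ValueError("coupling must be in [0, 1]")
    if kind not in ("fret_excitation", "cd"):
        raise ValueError("kind must be 'fret_excitation' or 'cd'")
    rng = np.random.default_rng(seed)

    if kind == "fret_excitation":
        wl = _FRET_GRID
        if noise_sd is None:
            noise_sd = 1.0
        # Donor-only construct barely excites acceptor emission at 700 nm.
        comp_a = _gauss(wl, 8.0, 506.0, 15.0)  # mNeonGreen-like donor
        comp_b = _gauss(wl, 100.0, 590.0, 25.0)  # mCherry-like acceptor
        transfer = _gauss(wl, 40.0 * coupling, 500.0, 12.0)
    else:
        wl = _CD_GRID
        if noise_sd is None:
            noise_sd = 0.15
        # Protein: negative far-UV bands; DNA: positive band near 281 nm.
        comp_a = _gauss(wl, -8.0, 208.0, 6.0) + _gauss(wl, -10.0, 222.0, 7.0)
        comp_b = _gauss(wl, 5.0, 281.0, 10.0) + _gauss(wl, -6.0, 245.0, 12.0)
        if consensus:
            transfer = _gauss(wl, 3.0 * coupling, 281.0, 6.0)
        else:
            transfer = np.zeros_like(wl)

    mixture_clean = comp_a + comp_b + transfer

    def _noisy(y: np.ndarray) -> np.ndarray:
        if noise_sd == 0:
            return y.copy()
        return y + rng.normal(0.0, noise_sd, size=y.shape)

    a = Spectrum(wavelength_nm=wl.copy(), signal=_noisy(comp_a), kind=kind, label="component_a")
    b = Spectrum(wavelength_nm=wl.copy(), signal=_noisy(comp_b), kind=kind, label="component_b")
    mix = Spectrum(
        wavelength_nm=wl.copy(), signal=_noisy(mixture_clean), kind=kind, label="mixture"
    )
    return a, b, mix


# --- file I/O --------------------------------------------------------------

def write_kymograph_tiff(path: str | Path, kymo, truth: KymoGroundTruth | None = None) -> None:
    """Write a kymograph as single-page grayscale TIFF (position rows x time
    columns) with a JSON sidecar holding calibration and, if given, ground
    truth."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, kymo.intensity.astype(np.float32))
    sidecar = {
        "id": kymo.id,
        "pixel_nm": kymo.pixel_nm,
        "frame_interval_s": kymo.frame_interval_s,
    }
    if truth is not None:
        sidecar["ground_truth"] = {
            "true_positions_px": truth.true_positions_px.tolist(),
            "emitter_on": truth.emitter_on.tolist(),
            "true_blink_count": truth.true_blink_count,
        }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_kymograph_tiff(path: str | Path):
    """Read a kymograph TIFF and its JSON sidecar; returns (Kymograph,
    KymoGroundTruth or None)."""
    import tifffile

    from .kymo import Kymograph

    path = Path(path)
    intensity = np.asarray(tifffile.imread(path), dtype=float)
    meta = json.loads(path.with_suffix(".json").read_text())
    kymo = Kymograph(
        intensity=intensity,
        pixel_nm=float(meta["pixel_nm"]),
        frame_interval_s=float(meta["frame_interval_s"]),
        id=str(meta.get("id", path.stem)),
    )
    truth = None
    if "ground_truth" in meta:
        g = meta["ground_truth"]
        truth = KymoGroundTruth(
            true_positions_px=np.asarray(g["true_positions_px"], dtype=float),
            emitter_on=np.asarray(g["emitter_on"], dtype=bool),
            true_blink_count=int(g["true_blink_count"]),
        )
    return kymo, truth
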
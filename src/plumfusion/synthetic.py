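"""Seeded synthetic plum datasets: SSC reference values, Vis/NIR spectra, RGB images.

The generator emulates the statistical structure of a free-fall Vis/NIR +
machine-vision acquisition of ~120 plums: soluble solid content (SSC) drawn
from a truncated normal, reflectance spectra on a 400-1100 nm grid with
absorption-driven peaks near 720 and 820 nm and a valley near 740 nm whose
amplitudes are affine in SSC, and fruit images whose skin colour carries a
weak SSC signal.  Acquisition parameters (integration time, motor speed,
spot diameter, fall posture) act purely as scalar signal/noise knobs — no
physical optics is simulated.

All randomness flows from one integer seed through named substreams
(``ssc``, ``spectra``, ``images``) so each block can be regenerated
independently.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .spectra import SpectrumSet, write_spectra, write_reference

__all__ = [
    "SSCGenParams",
    "AcquisitionParams",
    "SpectralForwardModel",
    "ImageGenParams",
    "DatasetConfig",
    "sample_ssc",
    "generate_spectra",
    "generate_images",
    "generate_dataset",
    "substream_rng",
]


def substream_rng(seed: int, name: str) -> np.random.Generator:
    """Independent generator for the named substream of a global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(name.encode())])
    )


# --------------------------------------------------------------------------- SSC


@dataclass
class SSCGenParams:
    """Truncated-normal SSC distribution of the model-building cohort.

    Defaults are the fitted values of a 120-fruit plum cohort:
    N(13.00, 1.25^2) °Brix truncated to [10.2, 15.3] °Brix.
    """

    mu: float = 13.00
    sigma: float = 1.25
    lower_bound: float = 10.2
    upper_bound: float = 15.3
    n_samples: int = 120
    seed: int = 0

    def validate(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not self.lower_bound < self.upper_bound:
            raise ValueError("lower_bound must be < upper_bound")
        if self.n_samples < 0:
            raise ValueError("n_samples must be >= 0")


def sample_ssc(params: SSCGenParams) -> pd.DataFrame:
    """Draw an SSC table by rejection sampling of the truncated normal.

    Rejection (rather than clipping) preserves the truncated-normal shape;
    clipping would pile mass on the bounds and distort both moments.

    Returns a DataFrame with columns ``sample_id`` and ``ssc_brix``.
    """
    params.validate()
    rng = substream_rng(params.seed, "ssc")
    values = np.empty(params.n_samples)
    filled = 0
    if params.sigma == 0.0:
        if not params.lower_bound <= params.mu <= params.upper_bound:
            raise ValueError("degenerate distribution lies outside the truncation bounds")
        values[:] = params.mu
        filled = params.n_samples
    while filled < params.n_samples:
        draw = rng.normal(params.mu, params.sigma, size=max(params.n_samples, 64))
        keep = draw[(draw >= params.lower_bound) & (draw <= params.upper_bound)]
        take = min(keep.size, params.n_samples - filled)
        values[filled : filled + take] = keep[:take]
        filled += take
    ids = [f"plum_{i + 1:03d}" for i in range(params.n_samples)]
    return pd.DataFrame({"sample_id": ids, "ssc_brix": values})


# ------------------------------------------------------------------------ spectra


@dataclass
class AcquisitionParams:
    """Scalar acquisition knobs; defaults are the platform's optimal settings."""

    integration_time_ms: float = 14.0
    motor_speed_rpm: float = 6.6
    spot_diameter_mm: float = 20.0
    posture: str = "A"

    _POSTURE_GAIN = {"A": 1.00, "B": 0.98, "C": 0.85}

    def validate(self) -> None:
        if min(self.integration_time_ms, self.motor_speed_rpm, self.spot_diameter_mm) <= 0:
            raise ValueError("acquisition parameters must be strictly positive")
        if self.posture not in self._POSTURE_GAIN:
            raise ValueError(f"posture must be one of A/B/C, got {self.posture!r}")

    @property
    def posture_gain(self) -> float:
        return self._POSTURE_GAIN[self.posture]


@dataclass
class SpectralForwardModel:
    """Reflectance shape model: smooth polynomial baseline + Gaussian bands.

    Band amplitudes are affine in the optically probed sugar content,
    ``amp = intercept + coupling * (ssc + delta - 13)``, where the
    per-sample deviation ``delta ~ N(0, ssc_nuisance_sd)`` models the
    mismatch between the destructive refractometer reference and the flesh
    the beam actually samples — the classic accuracy limiter of Vis/NIR
    calibrations, and the component that bounds the spectral model's
    attainable R^2.  A small independent per-band jitter (``band_noise_sd``)
    adds band-specific biological variation, and every fruit carries a
    smooth random baseline perturbation (``baseline_drift_sd``: per-sample
    tilt and curvature in wavelength) emulating size/skin/path-length
    differences — so no wavelength region is static between samples, as in
    real spectra.
    Peak/valley anchors: 720 nm and 820 nm peaks, 740 nm valley; peak FWHM
    ~40 nm (sd 17 nm), the valley narrow (sd 5 nm) as water-band dips are.
    """

    wavelength_grid: np.ndarray = field(
        default_factory=lambda: np.arange(400.0, 1101.0, 1.0)
    )
    # cubic in u=(wl-400)/700 with zero slope exactly at the 720/820 nm peak
    # anchors, so the baseline never displaces the band maxima off-grid
    baseline_coeffs: tuple[float, ...] = (0.58, -0.822857, 1.585714, -1.0)
    peak_centers: tuple[float, float] = (720.0, 820.0)
    peak_sd_nm: float = 17.0
    valley_center: float = 740.0
    valley_sd_nm: float = 5.0
    peak_intercepts: tuple[float, float] = (0.10, 0.08)
    valley_intercept: float = 0.06
    ssc_coupling_coefficients: tuple[float, float, float] = (0.012, 0.008, -0.004)
    ssc_nuisance_sd: float = 0.45
    band_noise_sd: float = 0.003
    baseline_drift_sd: float = 0.02
    scatter_multiplier_sd: float = 0.08
    additive_offset_sd: float = 5.0
    noise_sd: float = 1.0
    counts_scale: float = 1000.0
    dark_counts_per_ms: float = 2.0

    def validate(self) -> None:
        wl = np.asarray(self.wavelength_grid, float)
        if not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be strictly ascending")
        if wl.min() < 400 or wl.max() > 1100:
            raise ValueError("wavelength grid must lie within [400, 1100] nm")
        for name in ("ssc_nuisance_sd", "band_noise_sd", "baseline_drift_sd",
                     "scatter_multiplier_sd", "additive_offset_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def reflectance_shape(self, ssc: np.ndarray, band_jitter: np.ndarray | None = None,
                          ssc_deviation: np.ndarray | None = None) -> np.ndarray:
        """Noise-free reflectance matrix (n, p) for SSC vector ``ssc``."""
        wl = np.asarray(self.wavelength_grid, float)
        u = (wl - 400.0) / 700.0
        base = np.polynomial.polynomial.polyval(u, self.baseline_coeffs)
        ssc = np.asarray(ssc, float)
        if ssc_deviation is None:
            ssc_deviation = np.zeros(ssc.size)
        dev = (ssc + ssc_deviation - 13.0)[:, None]
        if band_jitter is None:
            band_jitter = np.zeros((ssc.size, 3))
        c1, c2, c3 = self.ssc_coupling_coefficients
        amp1 = self.peak_intercepts[0] + c1 * dev + band_jitter[:, [0]]
        amp2 = self.peak_intercepts[1] + c2 * dev + band_jitter[:, [1]]
        ampv = self.valley_intercept + c3 * dev + band_jitter[:, [2]]
        g = lambda c, s: np.exp(-0.5 * ((wl - c) / s) ** 2)
        return (
            base[None, :]
            + amp1 * g(self.peak_centers[0], self.peak_sd_nm)[None, :]
            + amp2 * g(self.peak_centers[1], self.peak_sd_nm)[None, :]
            - ampv * g(self.valley_center, self.valley_sd_nm)[None, :]
        )


def generate_spectra(
    ssc: pd.DataFrame,
    fwd: SpectralForwardModel | None = None,
    acq: AcquisitionParams | None = None,
    seed: int = 0,
) -> tuple[SpectrumSet, np.ndarray, np.ndarray]:
    """Raw (uncalibrated) spectra plus dark-current and white-reference rows.

    Signal counts scale linearly with integration time and inversely with
    spot diameter; per-wavelength noise SD grows with motor speed.  Returns
    ``(raw_spectra, dark, white)`` on the forward model's grid with
    ``white > dark`` at every wavelength.
    """
    fwd = fwd or SpectralForwardModel()
    acq = acq or AcquisitionParams()
    fwd.validate()
    acq.validate()
    if ssc["sample_id"].duplicated().any():
        raise ValueError("SSC sample IDs must be unique")
    rng = substream_rng(seed, "spectra")
    wl = np.asarray(fwd.wavelength_grid, float)
    n = len(ssc)

    scale = fwd.counts_scale * (acq.integration_time_ms / 14.0) * (20.0 / acq.spot_diameter_mm)
    dark = np.full(wl.size, fwd.dark_counts_per_ms * acq.integration_time_ms)
    white = dark + scale

    band_jitter = rng.normal(0.0, fwd.band_noise_sd, size=(n, 3))
    ssc_dev = rng.normal(0.0, fwd.ssc_nuisance_sd, size=n)
    shape = fwd.reflectance_shape(ssc["ssc_brix"].to_numpy(), band_jitter, ssc_dev)
    if fwd.baseline_drift_sd > 0:
        # smooth per-fruit baseline drift: random tilt + curvature in u
        u = (wl - wl[0]) / max(wl[-1] - wl[0], 1.0)
        basis = np.vstack([u - 0.5, (u - 0.5) ** 2 - 1.0 / 12.0])
        drift_coef = rng.normal(0.0, fwd.baseline_drift_sd, size=(n, 2))
        shape = shape + drift_coef @ basis
    scatter = 1.0 + rng.normal(0.0, fwd.scatter_multiplier_sd, size=(n, 1))
    offset = rng.normal(0.0, fwd.additive_offset_sd, size=(n, 1))
    noise_sd = fwd.noise_sd * (acq.motor_speed_rpm / 6.6)
    noise = rng.normal(0.0, noise_sd, size=(n, wl.size)) if noise_sd > 0 else 0.0

    raw = dark[None, :] + scale * acq.posture_gain * shape * scatter + offset + noise
    return SpectrumSet(wl, raw, ssc["sample_id"].tolist()), dark, white


# ------------------------------------------------------------------------- images


@dataclass
class ImageGenParams:
    """Fruit-image generator: elliptical fruit on a near-black background.

    ``coupling`` is the per-channel skin-colour slope in 8-bit counts per
    °Brix; ``noise_sd`` drives all three nuisance components (per-sample
    colour jitter, a low-frequency texture field at 0.8x, per-pixel noise at
    0.6x).  The default jitter-to-signal ratio puts a vision-only model's
    held-out R^2 in the 0.3-0.4 band typical of skin colour as an SSC proxy.
    """

    image_size: int = 96
    coupling: tuple[float, float, float] = (6.0, 3.0, 1.0)
    base_color: tuple[float, float, float] = (140.0, 70.0, 55.0)
    noise_sd: float = 7.0

    def validate(self) -> None:
        if self.image_size < 16:
            raise ValueError("image_size must be >= 16 pixels")
        if not np.all(np.isfinite(self.coupling)):
            raise ValueError("coupling coefficients must be finite")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_images(
    ssc: pd.DataFrame,
    params: ImageGenParams | None = None,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """One 8-bit RGB array per sample, keyed by sample_id."""
    params = params or ImageGenParams()
    params.validate()
    rng = substream_rng(seed, "images")
    sz = params.image_size
    yy, xx = np.mgrid[0:sz, 0:sz].astype(float)
    cy = cx = (sz - 1) / 2.0
    mask = ((xx - cx) / (0.40 * sz)) ** 2 + ((yy - cy) / (0.34 * sz)) ** 2 <= 1.0
    background = np.array([8.0, 8.0, 10.0])
    coupling = np.asarray(params.coupling, float)
    base = np.asarray(params.base_color, float)

    out: dict[str, np.ndarray] = {}
    for sid, val in zip(ssc["sample_id"], ssc["ssc_brix"]):
        color = base + coupling * (float(val) - 13.0)
        color = color + rng.normal(0.0, params.noise_sd, size=3)
        img = np.broadcast_to(background, (sz, sz, 3)).copy()
        # low-frequency texture field shared across channels, per-fruit phase
        phase = rng.uniform(0.0, 2 * np.pi, size=2)
        tex = (
            0.8
            * params.noise_sd
            * np.sin(2 * np.pi * xx / sz * 2.3 + phase[0])
            * np.cos(2 * np.pi * yy / sz * 1.7 + phase[1])
        )
        pix = color[None, None, :] + tex[:, :, None]
        if params.noise_sd > 0:
            pix = pix + rng.normal(0.0, 0.6 * params.noise_sd, size=(sz, sz, 3))
        img[mask] = pix[mask]
        out[str(sid)] = np.clip(np.round(img), 0, 255).astype(np.uint8)
    return out


# ------------------------------------------------------------------------ dataset


@dataclass
class DatasetConfig:
    """Everything needed to materialize a full synthetic bundle on disk."""

    seed: int = 0
    ssc: SSCGenParams = field(default_factory=SSCGenParams)
    forward: SpectralForwardModel = field(default_factory=SpectralForwardModel)
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    image: ImageGenParams = field(default_factory=ImageGenParams)

    def __post_init__(self) -> None:
        self.ssc.seed = self.seed


def generate_dataset(config: DatasetConfig, out_dir) -> dict[str, Path]:
    """Write spectra/dark/white/SSC CSVs, one PNG per fruit, and a manifest.

    Re-running with the same config reproduces byte-identical files.
    Returns the path of every artifact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)

    table = sample_ssc(config.ssc)
    raw, dark, white = generate_spectra(table, config.forward, config.acquisition, config.seed)
    images = generate_images(table, config.image, config.seed)

    paths = {
        "ssc": out / "ssc.csv",
        "spectra": out / "spectra.csv",
        "dark": out / "dark.csv",
        "white": out / "white.csv",
        "images": img_dir,
        "manifest": out / "manifest.txt",
    }
    table.to_csv(paths["ssc"], index=False)
    write_spectra(raw, paths["spectra"])
    write_reference(raw.wavelengths, dark, "dark", paths["dark"])
    write_reference(raw.wavelengths, white, "white", paths["white"])
    for sid, arr in images.items():
        Image.fromarray(arr, mode="RGB").save(img_dir / f"{sid}.png")

    lines = [f"seed = {config.seed}", f"n_samples = {config.ssc.n_samples}"]
    for block in ("ssc", "forward", "acquisition", "image"):
        for key, val in asdict(getattr(config, block)).items():
            if isinstance(val, np.ndarray):
                val = f"sha256:{hashlib.sha256(val.tobytes()).hexdigest()[:16]}"
            lines.append(f"{block}.{key} = {val}")
    paths["manifest"].write_text("\n".join(lines) + "\n")
    return paths
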
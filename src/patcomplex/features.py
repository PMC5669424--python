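"""Image predictors of perceived visual complexity.

Twenty-four predictors are computed per square image:

* four compression ratios (GIF, PNG, TIFF-LZW, JPEG at quality 90),
  each the mean of compressed bytes per pixel over the original and its
  90-degree rotation;
* four edge operators -- phase congruency (PHC), Canny (CAN), perimeter
  of black regions (PER) and local root-mean-square contrast (RMS) --
  each summarised by the mean (MN), population standard deviation (SD)
  and their product (MNSD) of the edge map, plus the GIF compression
  ratio of the edge map (PHCGIF .. RMSGIF);
* four structural measures: balance (APB), deviation of the black-pixel
  centroid from the image centre (DCM), four-axis mirror symmetry (MS,
  0-100) and block-entropy homogeneity (HG).

RMSGIF -- GIF compressibility of the local RMS-contrast map -- acts as
the "quantitative" factor of perceived complexity (amount of content),
while MS is the "structural" factor (organisation; negatively related to
complexity).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import binary_erosion, gaussian_filter, uniform_filter
from skimage import feature as sk_feature
from skimage import filters as sk_filters

from .symmetry import AXIS_COLUMNS, SymmetryProfile, mirror_symmetry

#: canonical predictor names, in the order they are reported
PREDICTOR_NAMES = (
    "GIF", "PNG", "TIF", "JPG",
    "PHCMN", "PHCSD", "PHCMNSD",
    "CANMN", "CANSD", "CANMNSD",
    "PERMN", "PERSD", "PERMNSD",
    "RMSMN", "RMSSD", "RMSMNSD",
    "PHCGIF", "CANGIF", "PERGIF", "RMSGIF",
    "APB", "DCM", "MS", "HG",
)

EDGE_METHODS = ("PHC", "CAN", "PER", "RMS")
CODECS = ("GIF", "PNG", "TIF", "JPG")


class FeatureError(ValueError):
    """Invalid input for a predictor computation."""


@dataclass(frozen=True)
class PhaseCongruencyConfig:
    """Log-Gabor phase-congruency parameters (reference defaults)."""

    nscale: int = 4
    norient: int = 6
    min_wavelength: float = 3.0
    mult: float = 2.1
    sigma_onf: float = 0.55
    k: float = 2.0
    cutoff: float = 0.5
    g: float = 10.0
    epsilon: float = 1e-4


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable parameters of the predictor battery."""

    rms_window: int = 5
    canny_sigma: float = 1.0
    canny_low_fraction: float = 0.4  # low threshold = 0.4 * Otsu-derived high
    jpeg_quality: int = 90
    homogeneity_blocks: int = 8
    phc: PhaseCongruencyConfig = field(default_factory=PhaseCongruencyConfig)


DEFAULT_CONFIG = FeatureConfig()


@dataclass(frozen=True)
class EdgeMap:
    """A non-negative edge-strength map; CAN and PER maps are binary."""

    values: np.ndarray
    method: str


def _check_image(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise FeatureError(f"expected a 2-D image, got shape {arr.shape}")
    if arr.min() < 0 or arr.max() > 1:
        raise FeatureError("image intensities must lie in [0, 1]")
    return arr


def _to_uint8(arr: np.ndarray) -> np.ndarray:
    return np.round(np.asarray(arr, dtype=float) * 255.0).astype(np.uint8)


def _encoded_bytes(arr8: np.ndarray, codec: str, config: FeatureConfig) -> int:
    im = Image.fromarray(arr8, mode="L")
    buf = _io.BytesIO()
    try:
        if codec == "GIF":
            im.save(buf, format="GIF")
        elif codec == "PNG":
            im.save(buf, format="PNG")
        elif codec == "TIF":
            im.save(buf, format="TIFF", compression="tiff_lzw")
        elif codec == "JPG":
            im.save(buf, format="JPEG", quality=config.jpeg_quality)
        else:
            raise FeatureError(f"unknown codec {codec!r}; expected one of {CODECS}")
    except FeatureError:
        raise
    except Exception as exc:  # encoder failure carries the codec name
        raise FeatureError(f"{codec} encoding failed: {exc}") from exc
    return buf.getbuffer().nbytes


def _two_orientation_ratio(arr8: np.ndarray, codec: str, config: FeatureConfig) -> float:
    m, w = arr8.shape
    b1 = _encoded_bytes(arr8, codec, config)
    b2 = _encoded_bytes(np.rot90(arr8).copy(), codec, config)
    return (b1 + b2) / (2.0 * m * w)


def compression_ratio(
    img: np.ndarray, codec: str, config: FeatureConfig = DEFAULT_CONFIG
) -> float:
    """Compressed bytes per pixel, averaged over both 90-degree orientations.

    Absolute values are specific to the pinned encoder (Pillow) and its
    settings; comparisons across encoders are meaningful at rank level
    only.
    """
    arr = _check_image(img)
    if arr.shape[0] != arr.shape[1]:
        raise FeatureError("compression_ratio expects a square image")
    return _two_orientation_ratio(_to_uint8(arr), codec, config)


# ---------------------------------------------------------------------------
# phase congruency (log-Gabor filter bank, Kovesi-style defaults)

def _lowpass(shape: tuple[int, int], cutoff: float = 0.45, order: int = 15):
    rows, cols = shape
    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.sqrt(fx**2 + fy**2)
    return 1.0 / (1.0 + (radius / cutoff) ** (2 * order))


def phase_congruency(img: np.ndarray, cfg: PhaseCongruencyConfig | None = None) -> np.ndarray:
    """Phase-congruency magnitude map of a grayscale image.

    Feature energy is accumulated over a bank of log-Gabor filters
    (``nscale`` scales x ``norient`` orientations), noise-compensated via
    a Rayleigh estimate from the smallest-scale amplitude, weighted by
    frequency spread, and normalised by the total amplitude sum.  The
    orientation maps are summed, so values may exceed 1.
    """
    cfg = cfg or PhaseCongruencyConfig()
    arr = np.asarray(img, dtype=float)
    rows, cols = arr.shape
    IM = np.fft.fft2(arr)

    fy = np.fft.fftfreq(rows)[:, None]
    fx = np.fft.fftfreq(cols)[None, :]
    radius = np.sqrt(fx**2 + fy**2)
    radius[0, 0] = 1.0  # avoid log(0) at DC
    theta = np.arctan2(-fy, fx)
    sintheta, costheta = np.sin(theta), np.cos(theta)
    lp = _lowpass((rows, cols))

    log_gabors = []
    for s in range(cfg.nscale):
        wavelength = cfg.min_wavelength * cfg.mult**s
        fo = 1.0 / wavelength
        lg = np.exp(-(np.log(radius / fo) ** 2) / (2 * np.log(cfg.sigma_onf) ** 2))
        lg *= lp
        lg[0, 0] = 0.0
        log_gabors.append(lg)

    pc_sum = np.zeros((rows, cols))
    for o in range(cfg.norient):
        angl = o * np.pi / cfg.norient
        ds = sintheta * np.cos(angl) - costheta * np.sin(angl)
        dc = costheta * np.cos(angl) + sintheta * np.sin(angl)
        dtheta = np.abs(np.arctan2(ds, dc))
        # cosine-shaped angular spread, width pi/norient * 1.2
        dtheta = np.minimum(dtheta * cfg.norient / 2.0 / 1.2, np.pi)
        spread = (np.cos(dtheta) + 1.0) / 2.0

        sum_e = np.zeros((rows, cols))
        sum_o = np.zeros((rows, cols))
        sum_an = np.zeros((rows, cols))
        max_an = np.zeros((rows, cols))
        tau = 0.0
        for s in range(cfg.nscale):
            eo = np.fft.ifft2(IM * log_gabors[s] * spread)
            an = np.abs(eo)
            sum_e += eo.real
            sum_o += eo.imag
            sum_an += an
            max_an = np.maximum(max_an, an)
            if s == 0:
                tau = np.median(an) / np.sqrt(np.log(4.0))
        x_energy = np.sqrt(sum_e**2 + sum_o**2) + cfg.epsilon
        mean_e, mean_o = sum_e / x_energy, sum_o / x_energy
        # re-run the filter responses to accumulate energy against the
        # weighted mean phase (second pass keeps memory flat)
        energy = np.zeros((rows, cols))
        for s in range(cfg.nscale):
            eo = np.fft.ifft2(IM * log_gabors[s] * spread)
            energy += eo.real * mean_e + eo.imag * mean_o - np.abs(
                eo.real * mean_o - eo.imag * mean_e
            )
        # Rayleigh noise threshold from the smallest-scale amplitude
        total_tau = tau * (1.0 - (1.0 / cfg.mult) ** cfg.nscale) / (1.0 - 1.0 / cfg.mult)
        noise_mean = total_tau * np.sqrt(np.pi / 2.0)
        noise_sigma = total_tau * np.sqrt((4.0 - np.pi) / 2.0)
        energy = np.maximum(energy - (noise_mean + cfg.k * noise_sigma), 0.0)
        width = (sum_an / (max_an + cfg.epsilon)) / cfg.nscale
        weight = 1.0 / (1.0 + np.exp(cfg.g * (cfg.cutoff - width)))
        pc_sum += weight * energy / (sum_an + cfg.epsilon)
    return pc_sum


def edge_map(
    img: np.ndarray, method: str, config: FeatureConfig = DEFAULT_CONFIG
) -> EdgeMap:
    """Compute one of the four edge-strength maps (PHC, CAN, PER, RMS)."""
    arr = _check_image(img)
    if method == "PHC":
        return EdgeMap(phase_congruency(arr, config.phc), "PHC")
    if method == "CAN":
        return EdgeMap(_canny(arr, config), "CAN")
    if method == "PER":
        black = arr < 0.5
        cross = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
        interior = binary_erosion(black, structure=cross, border_value=0)
        return EdgeMap((black & ~interior).astype(float), "PER")
    if method == "RMS":
        return EdgeMap(_rms_contrast(arr, config.rms_window), "RMS")
    raise FeatureError(f"unknown edge method {method!r}; expected one of {EDGE_METHODS}")


def _canny(arr: np.ndarray, config: FeatureConfig) -> np.ndarray:
    # hysteresis thresholds derived from Otsu's threshold of the smoothed
    # gradient magnitude; low threshold a fixed fraction of the high one
    smoothed = gaussian_filter(arr, config.canny_sigma)
    gy, gx = np.gradient(smoothed)
    mag = np.hypot(gx, gy)
    if np.ptp(mag) == 0:
        return np.zeros_like(arr)
    high = sk_filters.threshold_otsu(mag)
    low = config.canny_low_fraction * high
    edges = sk_feature.canny(
        arr, sigma=config.canny_sigma, low_threshold=low, high_threshold=high
    )
    return edges.astype(float)


def _rms_contrast(arr: np.ndarray, window: int) -> np.ndarray:
    mean_int = arr.mean()
    if mean_int == 0:
        return np.zeros_like(arr)
    m1 = uniform_filter(arr, size=window, mode="reflect")
    m2 = uniform_filter(arr**2, size=window, mode="reflect")
    local_sd = np.sqrt(np.clip(m2 - m1**2, 0.0, None))
    return local_sd / mean_int


def edge_stats(emap: EdgeMap) -> tuple[float, float, float]:
    """(mean, population SD, mean*SD) of an edge map."""
    v = np.asarray(emap.values, dtype=float)
    mn = float(v.mean())
    sd = float(v.std(ddof=0))
    return mn, sd, mn * sd


def edge_gif(emap: EdgeMap, config: FeatureConfig = DEFAULT_CONFIG) -> float:
    """GIF bytes-per-pixel of the edge map (two-orientation mean).

    Continuous maps are linearly quantised to 8 bit (max value -> 255)
    before encoding; binary maps quantise to {0, 255} so the result does
    not depend on whether they arrive as booleans or floats.
    """
    v = np.asarray(emap.values, dtype=float)
    vmax = v.max()
    arr8 = np.zeros(v.shape, dtype=np.uint8) if vmax == 0 else _to_uint8(v / vmax)
    return _two_orientation_ratio(arr8, "GIF", config)


def _black_mask(img: np.ndarray) -> np.ndarray:
    arr = _check_image(img)
    black = arr < 0.5
    if not black.any():
        raise FeatureError("all-white image: measure undefined without black pixels")
    return black


def dcm(img: np.ndarray) -> float:
    """Deviation of the black-pixel centroid from the image centre.

    Euclidean distance normalised by the half-diagonal, hence in [0, 1].
    """
    black = _black_mask(img)
    m, w = black.shape
    rows, cols = np.nonzero(black)
    centroid = np.array([rows.mean(), cols.mean()])
    centre = np.array([(m - 1) / 2.0, (w - 1) / 2.0])
    half_diag = np.sqrt(centre[0] ** 2 + centre[1] ** 2)
    return float(np.linalg.norm(centroid - centre) / half_diag)


_APB_ANGLES = np.deg2rad(np.arange(0.0, 180.0, 22.5))


def apb(img: np.ndarray) -> float:
    """Assessment of preference for balance.

    For each of eight axes through the image centre (vertical, horizontal,
    the two diagonals and the four intermediate 22.5-degree axes) the
    relative imbalance of black-pixel mass between the two half-planes is
    computed; APB = 100 - 200 * mean imbalance, so perfectly balanced
    images score 100.
    """
    black = _black_mask(img)
    m, w = black.shape
    rows, cols = np.nonzero(black)
    y = rows - (m - 1) / 2.0
    x = cols - (w - 1) / 2.0
    total = len(rows)
    imbalances = []
    for ang in _APB_ANGLES:
        side = x * np.sin(ang) - y * np.cos(ang)
        pos = int((side > 1e-9).sum())
        neg = int((side < -1e-9).sum())
        imbalances.append(abs(pos - neg) / total)
    return 100.0 - 200.0 * float(np.mean(imbalances))


def homogeneity(img: np.ndarray, blocks: int = 8) -> float:
    """Relative block entropy of black-pixel mass, in [0, 1].

    The image is partitioned into ``blocks x blocks`` tiles; HG is the
    Shannon entropy of the per-tile black-mass distribution divided by
    its maximum ``log(blocks**2)``.
    """
    black = _black_mask(img).astype(float)
    m, w = black.shape
    r_edges = np.round(np.linspace(0, m, blocks + 1)).astype(int)
    c_edges = np.round(np.linspace(0, w, blocks + 1)).astype(int)
    sums = np.add.reduceat(np.add.reduceat(black, r_edges[:-1], axis=0), c_edges[:-1], axis=1)
    p = sums.ravel() / sums.sum()
    p = p[p > 0]
    entropy = -np.sum(p * np.log(p))
    return float(entropy / np.log(blocks**2))


def extract_all(
    img: np.ndarray, config: FeatureConfig = DEFAULT_CONFIG
) -> pd.Series:
    """Compute the full 24-predictor vector plus per-axis symmetry scores.

    Returns a Series indexed by the names in :data:`PREDICTOR_NAMES`
    followed by the per-axis columns MSA, MSB, MSC, MSD (horizontal,
    vertical, main diagonal, secondary diagonal, on the unit scale).
    """
    arr = _check_image(img)
    if arr.shape[0] != arr.shape[1]:
        raise FeatureError("extract_all expects a square image")
    out: dict[str, float] = {}
    for codec in CODECS:
        out[codec] = compression_ratio(arr, codec, config)
    for method in EDGE_METHODS:
        emap = edge_map(arr, method, config)
        mn, sd, mnsd = edge_stats(emap)
        out[f"{method}MN"] = mn
        out[f"{method}SD"] = sd
        out[f"{method}MNSD"] = mnsd
        out[f"{method}GIF"] = edge_gif(emap, config)
    out["APB"] = apb(arr)
    out["DCM"] = dcm(arr)
    profile: SymmetryProfile = mirror_symmetry(_binarize(arr))
    out["MS"] = profile.ms
    out["HG"] = homogeneity(arr, config.homogeneity_blocks)
    for name, score in zip(AXIS_COLUMNS, profile.axis_scores):
        out[name] = float(score)
    order = [*PREDICTOR_NAMES, *AXIS_COLUMNS]
    return pd.Series({k: out[k] for k in order}, name="predictors")


def _binarize(arr: np.ndarray) -> np.ndarray:
    return (arr >= 0.5).astype(np.uint8)
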
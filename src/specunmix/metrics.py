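"""Image-agreement metrics: RMSE, windowed SSIM, and Sørensen–Dice.

All metrics operate on [0, 1]-normalized images.  SSIM is the product of
luminance, contrast and structure factors computed over local Gaussian
windows,

    l = (2 mu_a mu_b + C1) / (mu_a^2 + mu_b^2 + C1)
    c = (2 s_a s_b + C2) / (s_a^2 + s_b^2 + C2)
    s = (cov_ab + C3) / (s_a s_b + C3)

with the standard constants C1 = (0.01 L)^2, C2 = (0.03 L)^2, C3 = C2 / 2
and an 11x11 Gaussian window (sigma 1.5).  3-D stacks are scored per z-plane
and averaged for SSIM; RMSE and Dice use whole volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve


class MetricsError(ValueError):
    pass


@dataclass
class SsimParams:
    alpha: float = 1.0
    beta: float = 1.0
    gamma: float = 1.0
    dynamic_range: float = 1.0  # L of the normalized images
    k1: float = 0.01
    k2: float = 0.03
    win_size: int = 11
    sigma: float = 1.5
    C1: float | None = None  # explicit constants override k1/k2/L
    C2: float | None = None
    C3: float | None = None

    def constants(self) -> tuple[float, float, float]:
        L = self.dynamic_range
        c1 = self.C1 if self.C1 is not None else (self.k1 * L) ** 2
        c2 = self.C2 if self.C2 is not None else (self.k2 * L) ** 2
        c3 = self.C3 if self.C3 is not None else c2 / 2.0
        if c1 <= 0 or c2 <= 0 or c3 <= 0:
            raise MetricsError("SSIM stabilization constants must be positive")
        if self.win_size % 2 == 0:
            raise MetricsError("SSIM window size must be odd")
        return c1, c2, c3


def rmse_image(est: np.ndarray, ref: np.ndarray) -> float:
    """sqrt(sum((est - ref)^2) / N) over all voxels."""
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise MetricsError(f"shape mismatch: {est.shape} vs {ref.shape}")
    return float(np.sqrt(np.mean((est - ref) ** 2)))


def _gaussian_kernel(size: int, sigma: float) -> np.ndarray:
    r = np.arange(size) - size // 2
    g = np.exp(-(r**2) / (2.0 * sigma**2))
    k = np.outer(g, g)
    return k / k.sum()


def _ssim_plane(est: np.ndarray, ref: np.ndarray, params: SsimParams) -> float:
    c1, c2, c3 = params.constants()
    if min(est.shape) < params.win_size:
        raise MetricsError(
            f"SSIM window {params.win_size} larger than image plane {est.shape}"
        )
    w = _gaussian_kernel(params.win_size, params.sigma)
    conv = lambda im: fftconvolve(im, w, mode="valid")  # noqa: E731
    mu_a = conv(est)
    mu_b = conv(ref)
    var_a = np.clip(conv(est * est) - mu_a**2, 0.0, None)
    var_b = np.clip(conv(ref * ref) - mu_b**2, 0.0, None)
    cov = conv(est * ref) - mu_a * mu_b
    sd_a = np.sqrt(var_a)
    sd_b = np.sqrt(var_b)

    l = (2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1)
    c = (2 * sd_a * sd_b + c2) / (var_a + var_b + c2)
    s = (cov + c3) / (sd_a * sd_b + c3)
    smap = np.sign(l) * np.abs(l) ** params.alpha
    smap *= np.sign(c) * np.abs(c) ** params.beta
    smap *= np.sign(s) * np.abs(s) ** params.gamma
    return float(smap.mean())


def ssim_image(est: np.ndarray, ref: np.ndarray, params: SsimParams | None = None,
               clip: bool = True) -> float:
    """Mean windowed SSIM; 3-D stacks are averaged over z-planes.

    The raw index lies in [-1, 1]; the reported value is clipped to the
    [0, 1] range the comparison tables use (``clip=False`` for the raw value).
    """
    params = params or SsimParams()
    est = np.asarray(est, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if est.shape != ref.shape:
        raise MetricsError(f"shape mismatch: {est.shape} vs {ref.shape}")
    if est.ndim == 2:
        val = _ssim_plane(est, ref, params)
    elif est.ndim == 3:
        val = float(np.mean([_ssim_plane(est[z], ref[z], params) for z in range(est.shape[0])]))
    else:
        raise MetricsError(f"SSIM expects 2-D or 3-D images, got {est.ndim}-D")
    return float(np.clip(val, 0.0, 1.0)) if clip else val


def dice(est: np.ndarray, ref: np.ndarray, binarize: float | None = None) -> float:
    """Sørensen–Dice overlap of binarized voxel sets.

    ``binarize`` is a threshold on normalized intensity; ``None`` uses the
    default rule "nonzero after conversion back to the integer dtype",
    approximated on normalized data as >= 0.5/65535 (i.e. any signal).
    Boolean inputs are used as masks directly.  Defined as 1.0 when both
    masks are empty (identical segmentations).
    """
    est = np.asarray(est)
    ref = np.asarray(ref)
    if est.shape != ref.shape:
        raise MetricsError(f"shape mismatch: {est.shape} vs {ref.shape}")
    if est.dtype == bool and ref.dtype == bool:
        a, b = est, ref
    else:
        thr = 0.5 / 65535.0 if binarize is None else binarize
        a = np.asarray(est, dtype=float) >= thr
        b = np.asarray(ref, dtype=float) >= thr
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Per-channel RMSE/SSIM/DICE plus the mean row (comparison-table layout)."""

    per_channel: dict[str, dict[str, float]]
    n_pixels: int
    binarize: str = "normalized >= 0.5/65535"
    mean: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        metrics = ("rmse", "ssim", "dice")
        self.mean = {
            m: float(np.mean([row[m] for row in self.per_channel.values()]))
            for m in metrics
        }

    def to_dict(self) -> dict:
        return {
            "per_channel": self.per_channel,
            "mean": self.mean,
            "n_pixels": self.n_pixels,
            "binarize": self.binarize,
        }

    def to_frame(self):
        import pandas as pd

        rows = {label: vals for label, vals in self.per_channel.items()}
        df = pd.DataFrame(rows).T[["rmse", "ssim", "dice"]]
        df.loc["Mean"] = [self.mean["rmse"], self.mean["ssim"], self.mean["dice"]]
        return df


def evaluate(
    est_channels: dict[str, np.ndarray],
    ref_channels: dict[str, np.ndarray],
    dtype_max: float = 1.0,
    ssim_params: SsimParams | None = None,
    binarize: float | None = None,
) -> MetricsReport:
    """Score estimated channels against reference channels.

    Inputs are per-label (Z, Y, X) stacks; integer data is normalized by
    ``dtype_max`` before comparison.  Channel label sets must agree; the
    symmetric difference is reported otherwise.
    """
    ekeys, rkeys = set(est_channels), set(ref_channels)
    if ekeys != rkeys:
        raise MetricsError(
            f"channel label mismatch; only in estimate: {sorted(ekeys - rkeys)}, "
            f"only in reference: {sorted(rkeys - ekeys)}"
        )
    per_channel = {}
    n_pixels = 0
    for label in est_channels:
        e = np.asarray(est_channels[label], dtype=float) / dtype_max
        r = np.asarray(ref_channels[label], dtype=float) / dtype_max
        per_channel[label] = {
            "rmse": rmse_image(e, r),
            "ssim": ssim_image(e, r, ssim_params),
            "dice": dice(e, r, binarize=binarize),
        }
        n_pixels = e.size
    rule = f"normalized >= {binarize}" if binarize is not None else "normalized >= 0.5/65535"
    return MetricsReport(per_channel=per_channel, n_pixels=n_pixels, binarize=rule)


def aggregate_reports(reports: list[MetricsReport]) -> dict[str, dict[str, dict[str, float]]]:
    """Batch aggregation: mean and SD per channel per metric across images."""
    if not reports:
        raise MetricsError("no reports to aggregate")
    labels = list(reports[0].per_channel)
    out: dict[str, dict[str, dict[str, float]]] = {}
    for label in labels:
        out[label] = {}
        for m in ("rmse", "ssim", "dice"):
            vals = np.array([r.per_channel[label][m] for r in reports])
            out[label][m] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=0))}
    return out
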
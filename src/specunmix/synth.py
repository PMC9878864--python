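"""Synthetic lambda-stack generator with known ground truth.

Emulates the structure of multiplex smFISH / immunofluorescence lambda
stacks from brain tissue: DAPI-stained nuclei (with the dye's secondary
emission lobe), punctate transcript signals labeled with spectrally
adjacent dyes, broad lipofuscin autofluorescence clumps, and a background
signature.  Emission curves are skewed log-normal-shaped lobes — fluorophore
emission has a long red tail, which is exactly what stresses unmixing.

Scenes store exact per-pixel abundance maps; rendering is the linear mixing
model F = S A (optionally with per-pixel scalings for spectral-variability
experiments) plus calibrated noise, so every solver can be scored against
the generating truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .endmembers import EndmemberSet
from .io import FingerprintTable, LambdaStack

#: default detector grid: 32 bands across the visual spectrum, ~every 8 nm
DEFAULT_GRID = 410.0 + 8.0 * np.arange(32)

#: nominal emission maxima of the default dye panel (nm)
DEFAULT_PEAKS = {
    "DAPI": 461.0,
    "Opal520": 520.0,
    "Opal570": 570.0,
    "Opal620": 620.0,
    "Opal690": 690.0,
}

BACKGROUND = "background"
LIPOFUSCIN = "lipofuscin"


class SynthError(ValueError):
    pass


# ---------------------------------------------------------------------------
# fluorophore panel
# ---------------------------------------------------------------------------


def _lobe(grid: np.ndarray, peak: float, rho: float, amp: float) -> np.ndarray:
    """Log-normal-shaped emission lobe: unit max at ``peak``, long red tail."""
    return amp * np.exp(-(np.log(grid / peak) ** 2) / (2.0 * rho**2))


@dataclass
class FluorophorePanel:
    """Wavelength grid plus unit-max emission curve per label."""

    wavelengths: np.ndarray
    spectra: dict[str, np.ndarray]
    peak_nm: dict[str, float]

    def as_endmember_set(self, labels: list[str] | None = None) -> EndmemberSet:
        labels = labels or list(self.spectra)
        S = np.column_stack([self.spectra[l] for l in labels])
        return EndmemberSet(S=S, labels=labels, wavelengths=self.wavelengths)

    def as_table(self) -> FingerprintTable:
        return FingerprintTable(wavelengths=self.wavelengths, columns=dict(self.spectra))


def make_panel(
    peaks: dict[str, float] | None = None,
    grid: np.ndarray | None = None,
    include_lipofuscin: bool = True,
    include_background: bool = True,
    confusable_lipofuscin: bool = False,
    lobe_rho: float = 0.035,
) -> FluorophorePanel:
    """Build the default six-member dye panel (plus background signature).

    DAPI gets a secondary emission lobe around 510 nm (the source of its
    bleed into the 520-peaked dye); lipofuscin is broad and flat-ish across
    the grid; background is a low flat component with a residual excitation
    spike at the blue edge of the grid.  ``confusable_lipofuscin`` replaces
    the lipofuscin curve with a near-copy of the 520-peaked dye, the
    engineered failure case for multiplex fingerprint extraction.

    Nominal peaks may exceed the red end of the detector grid by up to 60 nm
    (the recorded, truncated fingerprint then peaks at the last band);
    anything further out is an error.
    """
    grid = DEFAULT_GRID.copy() if grid is None else np.asarray(grid, dtype=float)
    peaks = dict(DEFAULT_PEAKS) if peaks is None else dict(peaks)
    for label, p in peaks.items():
        if not (grid[0] <= p <= grid[-1] + 60.0):
            raise SynthError(
                f"peak {p} nm of '{label}' outside detector range "
                f"[{grid[0]}, {grid[-1]} + 60] nm"
            )

    spectra: dict[str, np.ndarray] = {}
    peak_nm: dict[str, float] = {}
    for label, p in peaks.items():
        s = _lobe(grid, p, lobe_rho, 1.0)
        if label == "DAPI":
            s = s + _lobe(grid, 510.0, 0.05, 0.25)  # secondary emission lobe
        spectra[label] = s / s.max()
        peak_nm[label] = p
    if include_lipofuscin:
        if confusable_lipofuscin:
            s = _lobe(grid, 522.0, lobe_rho, 1.0) + 0.02
        else:
            s = _lobe(grid, 550.0, 0.13, 1.0) + 0.35
        spectra[LIPOFUSCIN] = s / s.max()
        peak_nm[LIPOFUSCIN] = 550.0
    if include_background:
        # narrow residual excitation leak at the blue edge + low flat noise floor
        s = _lobe(grid, grid[0] + 8.0, 0.006, 1.0) + 0.02
        spectra[BACKGROUND] = s / s.max()
        peak_nm[BACKGROUND] = float(grid[0] + 8.0)
    return FluorophorePanel(wavelengths=grid, spectra=spectra, peak_nm=peak_nm)


# ---------------------------------------------------------------------------
# scenes
# ---------------------------------------------------------------------------


@dataclass
class SceneSpec:
    """Densities and geometry of the synthetic specimen.

    Puncta counts are Poisson with mean ``puncta_per_1000px3 * volume/1000``
    per gene; nuclei are non-overlapping hard ellipsoids; lipofuscin forms
    irregular clumps of overlapping blobs, preferentially near nuclei.  A
    fraction of every object class is rendered *pure* (abundance exactly 1
    at an integer voxel) so the pure-pixel assumption of vertex extraction
    holds by construction.
    """

    n_nuclei: int | None = None  # default: ~1 per 2500 in-plane pixels
    nucleus_radius: tuple[float, float] = (5.0, 9.0)
    nucleus_amp: tuple[float, float] = (0.7, 0.95)
    puncta_per_1000px3: float = 2.0
    puncta_sigma_xy: tuple[float, float] = (1.5, 2.5)
    puncta_sigma_z: float = 1.0
    puncta_amp: tuple[float, float] = (0.75, 0.95)
    lipofuscin_per_1000px3: float = 0.15
    clump_blobs: tuple[int, int] = (3, 6)
    clump_sigma: tuple[float, float] = (1.5, 3.0)
    clump_amp: tuple[float, float] = (0.6, 0.9)
    pure_fraction: float = 0.3


@dataclass
class GroundTruthScene:
    """Per-label abundance maps plus object metadata; background completes to 1."""

    shape: tuple[int, int, int]
    abundances: dict[str, np.ndarray]  # label -> (Z, Y, X), excludes background
    background: np.ndarray  # (Z, Y, X)
    objects: dict = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return list(self.abundances)

    def abundance_matrix(self, labels: list[str]) -> np.ndarray:
        """k x n truth matrix in the given label order (background included by name)."""
        rows = []
        for l in labels:
            src = self.background if l == BACKGROUND else self.abundances[l]
            rows.append(src.ravel())
        return np.vstack(rows)

    def mask(self, label: str, threshold: float = 0.1) -> np.ndarray:
        return self.abundances[label] >= threshold


def _add_gaussian_blob(vol: np.ndarray, center: tuple[float, float, float],
                       sigma: tuple[float, float, float], amp: float) -> None:
    Z, Y, X = vol.shape
    cz, cy, cx = center
    sz, sy, sx = sigma
    z0, z1 = max(0, int(cz - 3 * sz)), min(Z, int(cz + 3 * sz) + 2)
    y0, y1 = max(0, int(cy - 3 * sy)), min(Y, int(cy + 3 * sy) + 2)
    x0, x1 = max(0, int(cx - 3 * sx)), min(X, int(cx + 3 * sx) + 2)
    if z0 >= z1 or y0 >= y1 or x0 >= x1:
        return
    zz, yy, xx = np.meshgrid(np.arange(z0, z1), np.arange(y0, y1),
                             np.arange(x0, x1), indexing="ij")
    g = amp * np.exp(-(((zz - cz) / sz) ** 2 + ((yy - cy) / sy) ** 2
                      + ((xx - cx) / sx) ** 2) / 2.0)
    region = vol[z0:z1, y0:y1, x0:x1]
    np.maximum(region, g, out=region)


def make_scene(
    shape: tuple[int, int, int],
    gene_labels: list[str] | None = None,
    spec: SceneSpec | None = None,
    seed: int = 0,
    include_dapi: bool = True,
    include_lipofuscin: bool = True,
) -> GroundTruthScene:
    """Draw a random specimen: nuclei, per-gene puncta, lipofuscin clumps.

    Deterministic per seed.  Per-pixel abundances are >= 0 and sum to <= 1;
    the background map is exactly ``1 - sum`` everywhere.
    """
    spec = spec or SceneSpec()
    Z, Y, X = shape
    if min(shape) < 1:
        raise SynthError(f"scene shape {shape} too small")
    gene_labels = ["Opal520", "Opal570", "Opal620", "Opal690"] if gene_labels is None else gene_labels
    rng = np.random.default_rng(seed)
    volume = Z * Y * X
    maps: dict[str, np.ndarray] = {}
    objects: dict = {"nuclei": [], "puncta": {}, "lipofuscin_clumps": []}

    nuclei: list[tuple[float, float, float]] = []
    if include_dapi:
        dapi = np.zeros(shape)
        n_nuclei = spec.n_nuclei if spec.n_nuclei is not None else max(1, round(Y * X / 2500))
        min_r = spec.nucleus_radius[0]
        if 2 * min_r > min(Y, X):
            raise SynthError(f"shape {shape} too small for nuclei of radius {min_r}")
        placed: list[tuple[float, float, float]] = []  # (y, x, r)
        attempts = 0
        r_hi = max(min_r, min(spec.nucleus_radius[1], (min(Y, X) - 1) / 2.0))
        while len(placed) < n_nuclei and attempts < 60 * n_nuclei:
            attempts += 1
            r = rng.uniform(min_r, r_hi)
            cy = rng.uniform(r, Y - r)
            cx = rng.uniform(r, X - r)
            if any((cy - py) ** 2 + (cx - px) ** 2 < (r + pr) ** 2 for py, px, pr in placed):
                continue
            placed.append((cy, cx, r))
            # first object of each class is always pure: the pure-pixel
            # assumption of vertex extraction holds by construction
            pure = len(placed) == 1 or rng.random() < spec.pure_fraction
            amp = 1.0 if pure else rng.uniform(*spec.nucleus_amp)
            cz = (Z - 1) / 2.0
            rz = max(1.0, min(r, Z / 2.0 + 0.5))
            zz, yy, xx = np.meshgrid(np.arange(Z), np.arange(Y), np.arange(X), indexing="ij")
            inside = (((zz - cz) / rz) ** 2 + ((yy - cy) / r) ** 2 + ((xx - cx) / r) ** 2) <= 1.0
            dapi[inside] = np.maximum(dapi[inside], amp)
            nuclei.append((cz, cy, cx))
            objects["nuclei"].append({"center": (cz, cy, cx), "radius": r, "amp": amp})
        maps["DAPI"] = dapi

    for gene in gene_labels:
        chan = np.zeros(shape)
        count = rng.poisson(spec.puncta_per_1000px3 * volume / 1000.0)
        pts = []
        for idx in range(count):
            cz = rng.uniform(0, Z - 1) if Z > 1 else 0.0
            cy = rng.uniform(0, Y - 1)
            cx = rng.uniform(0, X - 1)
            s_xy = rng.uniform(*spec.puncta_sigma_xy)
            if idx == 0 or rng.random() < spec.pure_fraction:
                cz, cy, cx = round(cz), round(cy), round(cx)
                amp = 1.0
            else:
                amp = rng.uniform(*spec.puncta_amp)
            _add_gaussian_blob(chan, (cz, cy, cx), (spec.puncta_sigma_z, s_xy, s_xy), amp)
            pts.append({"center": (cz, cy, cx), "sigma_xy": s_xy, "amp": amp})
        maps[gene] = chan
        objects["puncta"][gene] = pts

    if include_lipofuscin:
        lipo = np.zeros(shape)
        count = rng.poisson(spec.lipofuscin_per_1000px3 * volume / 1000.0)
        for i in range(count):
            if nuclei and rng.random() < 0.6:  # clumps often hug nuclei
                cz, cy, cx = nuclei[rng.integers(len(nuclei))]
                cy += rng.normal(0, 6)
                cx += rng.normal(0, 6)
            else:
                cz = rng.uniform(0, Z - 1) if Z > 1 else 0.0
                cy = rng.uniform(0, Y - 1)
                cx = rng.uniform(0, X - 1)
            pure = i == 0 or rng.random() < spec.pure_fraction
            amp = 1.0 if pure else rng.uniform(*spec.clump_amp)
            n_blobs = rng.integers(spec.clump_blobs[0], spec.clump_blobs[1] + 1)
            for b in range(n_blobs):
                if pure and b == 0:  # exact in-bounds pure voxel
                    ctr = (min(max(round(cz), 0), Z - 1), min(max(round(cy), 0), Y - 1),
                           min(max(round(cx), 0), X - 1))
                else:
                    off = rng.normal(0, 2.0, size=3)
                    ctr = (cz + off[0] * 0.5, cy + off[1], cx + off[2])
                s = rng.uniform(*spec.clump_sigma)
                _add_gaussian_blob(lipo, ctr, (max(0.8, s * 0.5), s, s), amp)
            objects["lipofuscin_clumps"].append({"center": (cz, cy, cx), "amp": amp})
        maps[LIPOFUSCIN] = lipo

    total = np.zeros(shape)
    for m in maps.values():
        total += m
    over = total > 1.0
    if np.any(over):
        scale = np.where(over, 1.0 / np.where(over, total, 1.0), 1.0)
        for m in maps.values():
            m *= scale
    # guarantee one exactly-pure voxel per present endmember: overlap capping
    # above can re-mix the nominally pure first object of a class
    for label, m in maps.items():
        if m.max() <= 0:
            continue
        p = np.unravel_index(np.argmax(m), shape)
        m[p] = 1.0
        for other, mo in maps.items():
            if other != label:
                mo[p] = 0.0
    total = np.zeros(shape)
    for m in maps.values():
        total += m
    # floored at 0: rescaled sums can overshoot 1 by an ulp
    background = np.maximum(1.0 - total, 0.0)
    return GroundTruthScene(shape=shape, abundances=maps, background=background,
                            objects=objects)


def make_pure_mosaic_scene(
    shape: tuple[int, int, int],
    labels: list[str],
    seed: int = 0,
    amplitude: float = 1.0,
) -> GroundTruthScene:
    """Partition pixels into single-endmember regions of equal abundance.

    The factorization of per-pixel scalings from abundances is only
    identifiable on pure pixels, so the spectral-variability recovery tests
    run on this mosaic rather than on mixed specimens.  ``amplitude`` < 1
    leaves detector headroom so upward scalings (psi > 1) render without
    saturating; the remaining abundance is deliberately left empty rather
    than filled with background, which would re-mix the pixels.
    """
    rng = np.random.default_rng(seed)
    n = int(np.prod(shape))
    assign = rng.integers(0, len(labels) + 1, size=n)  # last bin = background
    # guarantee each label occurs
    for j in range(len(labels) + 1):
        if not np.any(assign == j):
            assign[rng.integers(n)] = j
    cut = len(labels)
    maps = {}
    for j, label in enumerate(labels):
        m = np.zeros(n)
        m[assign == j] = amplitude
        maps[label] = m.reshape(shape)
    background = np.zeros(n)
    background[assign == cut] = amplitude
    return GroundTruthScene(shape=shape, abundances=maps,
                            background=background.reshape(shape),
                            objects={"mosaic_assignment": assign.reshape(shape)})


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


@dataclass
class NoiseModel:
    """Acquisition noise: Poisson shot noise then Gaussian read noise.

    ``target_snr_db = inf`` renders noise-free.  When a target SNR is given
    and no explicit ``gaussian_sigma``, the read-noise sigma is calibrated so
    10 log10(P_signal / sigma^2) equals the target, with P_signal the mean
    squared clean intensity over signal pixels.
    """

    target_snr_db: float = np.inf
    gaussian_sigma: float | None = None
    poisson_scale: float | None = None  # photons per unit intensity


@dataclass
class RenderTruth:
    scene: GroundTruthScene
    panel: FluorophorePanel
    endmembers: EndmemberSet
    A: np.ndarray  # (k, n) including background row
    labels: list[str]
    F_clean: np.ndarray  # (C, n) normalized, noise-free
    psi: np.ndarray | None = None  # (k, n) for elmm variability
    Psi_profiles: dict[str, np.ndarray] | None = None  # label -> (C,) for gelmm
    noise_sigma: float = 0.0


def render(
    panel: FluorophorePanel,
    scene: GroundTruthScene,
    noise: NoiseModel | None = None,
    variability: dict | None = None,
    seed: int = 0,
    dtype=np.uint16,
    name: str = "synthetic",
) -> tuple[LambdaStack, RenderTruth]:
    """Render a scene through the panel: F = S A (+ scalings) + noise.

    ``variability``: ``None`` for the plain linear model;
    ``{"kind": "elmm", "low": .., "high": ..}`` draws per-pixel per-endmember
    scalings psi ~ U(low, high); ``{"kind": "gelmm_step", "label": ..,
    "factor": .., "above_nm": ..}`` attenuates one endmember's bands above a
    wavelength; ``{"kind": "gelmm_smooth", "amplitude": ..}`` applies smooth
    random per-endmember band curves (shared across pixels).
    """
    noise = noise or NoiseModel()
    labels = scene.labels + [BACKGROUND]
    for l in labels:
        if l not in panel.spectra:
            raise SynthError(f"scene label '{l}' missing from panel")
    S = panel.as_endmember_set(labels)
    A = scene.abundance_matrix(labels)
    C = S.n_bands
    k, n = A.shape
    rng = np.random.default_rng(seed)

    psi = None
    profiles: dict[str, np.ndarray] | None = None
    if variability is None:
        F = S.S @ A
    elif variability["kind"] == "elmm":
        lo, hi = variability.get("low", 0.8), variability.get("high", 1.2)
        psi = np.ones((k, n))
        present = A > 0
        psi[present] = rng.uniform(lo, hi, size=int(present.sum()))
        F = S.S @ (psi * A)
    elif variability["kind"] in ("gelmm_step", "gelmm_smooth"):
        profiles = {l: np.ones(C) for l in labels}
        if variability["kind"] == "gelmm_step":
            target = variability["label"]
            factor = variability.get("factor", 0.5)
            above = variability.get("above_nm", 650.0)
            prof = np.ones(C)
            prof[panel.wavelengths > above] = factor
            profiles[target] = prof
        else:
            amp = variability.get("amplitude", 0.2)
            x = np.linspace(0, 1, C)
            for l in labels:
                coeffs = rng.normal(0, amp, size=3)
                profiles[l] = np.clip(
                    1.0 + coeffs[0] * np.sin(np.pi * x) + coeffs[1] * x
                    + coeffs[2] * (x**2 - x), 0.1, None,
                )
        Sv = np.column_stack([S.S[:, j] * profiles[l] for j, l in enumerate(labels)])
        F = Sv @ A
    else:
        raise SynthError(f"unknown variability kind {variability['kind']!r}")

    signal = A[:-1].sum(axis=0) > 0  # pixels with any non-background member
    if not np.any(signal):
        signal = np.ones(n, dtype=bool)
    F_clean = F.copy()

    if noise.poisson_scale:
        F = rng.poisson(np.clip(F, 0, None) * noise.poisson_scale) / noise.poisson_scale
    sigma = 0.0
    if noise.gaussian_sigma is not None:
        sigma = noise.gaussian_sigma
    elif np.isfinite(noise.target_snr_db):
        p_signal = float(np.mean(F_clean[:, signal] ** 2))
        sigma = float(np.sqrt(p_signal / 10.0 ** (noise.target_snr_db / 10.0)))
    if sigma > 0:
        F = F + rng.normal(0.0, sigma, size=F.shape)

    dmax = int(np.iinfo(np.dtype(dtype)).max)
    counts = np.rint(np.clip(F, 0.0, 1.0) * dmax).astype(dtype)
    if F_clean[:, signal].max() * dmax < 1.0:
        warnings.warn("noise/dtype floor quantizes all signal to zero", stacklevel=2)
    Z, Y, X = scene.shape
    data = counts.T.reshape(Z, Y, X, C)
    stack = LambdaStack(data=data, wavelengths=panel.wavelengths, dtype_max=dmax, name=name)
    truth = RenderTruth(scene=scene, panel=panel, endmembers=S, A=A, labels=labels,
                        F_clean=F_clean, psi=psi, Psi_profiles=profiles,
                        noise_sigma=sigma)
    return stack, truth


def make_single_positive(
    label: str,
    panel: FluorophorePanel,
    shape: tuple[int, int, int] = (2, 64, 64),
    noise: NoiseModel | None = None,
    seed: int = 0,
    spec: SceneSpec | None = None,
) -> tuple[LambdaStack, RenderTruth]:
    """Render a single-positive specimen: exactly one fluorophore + background."""
    if label == "DAPI":
        scene = make_scene(shape, gene_labels=[], spec=spec, seed=seed,
                           include_dapi=True, include_lipofuscin=False)
    elif label == LIPOFUSCIN:
        # negative-control tissue carries abundant granules, unlike multiplex scenes
        sp = spec or SceneSpec(lipofuscin_per_1000px3=1.0)
        scene = make_scene(shape, gene_labels=[], spec=sp, seed=seed,
                           include_dapi=False, include_lipofuscin=True)
    else:
        sp = spec or SceneSpec(puncta_per_1000px3=4.0)
        scene = make_scene(shape, gene_labels=[label], spec=sp, seed=seed,
                           include_dapi=False, include_lipofuscin=False)
    return render(panel, scene, noise=noise, seed=seed + 1,
                  name=f"single_{label}")
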
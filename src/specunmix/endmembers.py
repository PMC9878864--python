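"""Automated endmember (fingerprint) extraction by vertex component analysis.

Under the linear mixing model every observed pixel spectrum lies inside the
simplex whose vertices are the pure fluorophore spectra.  When at least one
pure pixel per fluorophore exists, the vertices are themselves observed
spectra and VCA finds them by repeatedly projecting the data onto random
directions orthogonal to the vertices already found and taking the extreme
pixel.  Extracted columns are actual observed pixel spectra, unit-max
normalized, with their source pixel indices recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations
from typing import Sequence

import numpy as np

from .io import FingerprintTable, LambdaStack, PixelMatrix, normalize_stack

UNASSIGNED = "unassigned"

#: minimum Pearson correlation for an extracted column to accept a reference label
MATCH_CORR_THRESHOLD = 0.5
#: correlation-gap tolerance below which an assignment counts as ambiguous
MATCH_TIE_TOL = 1e-12
#: mutual correlation above which two extracted columns count as one vertex
DUPLICATE_CORR_THRESHOLD = 0.98


class EndmemberError(ValueError):
    """Raised when endmember extraction preconditions are violated."""


@dataclass
class EndmemberSet:
    """The C x k spectral-signature matrix S with labels and provenance."""

    S: np.ndarray  # (C, k), unit-max columns
    labels: list[str]
    wavelengths: np.ndarray
    source_pixel_indices: np.ndarray | None = None  # indices into the pixel matrix
    match_report: dict | None = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        c, k = self.S.shape
        if k > c:
            raise EndmemberError(
                f"k={k} endmembers exceed C={c} spectral bands: the linear system "
                "would be under-determined"
            )
        if len(self.labels) != k:
            raise EndmemberError("one label per endmember column required")
        if len(set(self.labels)) != k:
            raise EndmemberError(f"endmember labels not unique: {self.labels}")
        peaks = self.S.max(axis=0)
        if np.any(peaks <= 0):
            raise EndmemberError("all-zero endmember column")
        self.S = self.S / peaks

    @property
    def k(self) -> int:
        return self.S.shape[1]

    @property
    def n_bands(self) -> int:
        return self.S.shape[0]

    def column(self, label: str) -> np.ndarray:
        return self.S[:, self.labels.index(label)]

    def peak_band(self, label: str) -> int:
        return int(np.argmax(self.column(label)))

    def subset(self, labels: Sequence[str]) -> "EndmemberSet":
        idx = [self.labels.index(l) for l in labels]
        src = self.source_pixel_indices[idx] if self.source_pixel_indices is not None else None
        return EndmemberSet(self.S[:, idx], list(labels), self.wavelengths, src)

    def to_table(self) -> FingerprintTable:
        return FingerprintTable(
            wavelengths=self.wavelengths,
            columns={l: self.S[:, i] for i, l in enumerate(self.labels)},
        )

    @classmethod
    def from_table(cls, table: FingerprintTable) -> "EndmemberSet":
        return cls(table.as_matrix(), table.labels, table.wavelengths)


@dataclass
class VcaParams:
    """Tuning knobs of the VCA run.

    ``snr_threshold_offset`` sets the decision boundary between the two
    dimensionality-reduction paths at ``offset + 10 log10(k)`` dB; the
    override forces a path in tests.
    """

    k: int = 2
    seed: int = 0
    snr_db_override: float | None = None
    snr_threshold_offset: float = 15.0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise EndmemberError("k must be >= 1")


# ---------------------------------------------------------------------------
# VCA core
# ---------------------------------------------------------------------------


def estimate_snr_db(R: np.ndarray, k: int) -> float:
    """SNR estimate from the energy captured by the k-dim principal subspace."""
    C, n = R.shape
    mean = R.mean(axis=1, keepdims=True)
    R0 = R - mean
    # principal subspace of the mean-removed data
    cov = (R0 @ R0.T) / n
    _, vecs = np.linalg.eigh(cov)
    Ud = vecs[:, ::-1][:, :k]
    X = Ud.T @ R0
    p_y = float(np.sum(R**2)) / n
    p_x = float(np.sum(X**2)) / n + float(np.sum(mean**2))
    denom = p_y - p_x
    if denom <= 0:
        return np.inf
    num = p_x - (k / C) * p_y
    if num <= 0:
        return -np.inf
    return 10.0 * np.log10(num / denom)


def vca(pixels: PixelMatrix | np.ndarray, params: VcaParams) -> EndmemberSet:
    """Vertex component analysis endmember extraction.

    Steps: (1) estimate the SNR from the k-dimensional principal subspace;
    (2) high SNR: reduce to k dims by singular-subspace projection followed
    by projective (perspective) scaling; low SNR: remove the mean, reduce to
    k-1 dims and append a constant coordinate; (3) select k extreme pixels
    iteratively along random directions orthogonal to the span of the
    vertices found so far; (4) return the original-space spectra at the
    selected indices, unit-max normalized.  Deterministic given the seed.
    """
    if isinstance(pixels, PixelMatrix):
        F = pixels.F
        wavelengths = pixels.wavelengths
    else:
        F = np.asarray(pixels, dtype=float)
        wavelengths = np.arange(F.shape[0], dtype=float)
    C, n = F.shape
    k = params.k
    if k > C:
        raise EndmemberError(f"k={k} exceeds C={C} spectral bands")

    nonzero = np.flatnonzero(F.sum(axis=0) > 0)
    n_distinct = np.unique(F[:, nonzero], axis=1).shape[1] if nonzero.size else 0
    if n_distinct < k:
        raise EndmemberError(
            f"need at least k={k} distinct non-zero pixel spectra; found {n_distinct}"
        )
    R = F[:, nonzero]
    m = R.shape[1]

    snr = params.snr_db_override
    if snr is None:
        snr = estimate_snr_db(R, k)
    snr_threshold = params.snr_threshold_offset + 10.0 * np.log10(k)

    if snr >= snr_threshold or k == 1:
        # high-SNR path: singular subspace + projective scaling
        cov = (R @ R.T) / m
        _, vecs = np.linalg.eigh(cov)
        Ud = vecs[:, ::-1][:, :k]
        X = Ud.T @ R  # (k, m)
        u = X.mean(axis=1)
        denom = u @ X
        denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
        Y = X / denom
    else:
        # low-SNR path: mean removal, (k-1)-dim PCA, constant coordinate
        mean = R.mean(axis=1, keepdims=True)
        R0 = R - mean
        cov = (R0 @ R0.T) / m
        _, vecs = np.linalg.eigh(cov)
        Ud = vecs[:, ::-1][:, : k - 1]
        X = Ud.T @ R0  # (k-1, m)
        c = float(np.max(np.sqrt(np.sum(X**2, axis=0)))) or 1.0
        Y = np.vstack([X, np.full((1, m), c)])

    rng = np.random.default_rng(params.seed)
    A = np.zeros((k, k))
    A[-1, 0] = 1.0  # anchors the first orthogonal direction
    indices = np.zeros(k, dtype=int)
    for i in range(k):
        w = rng.standard_normal(k)
        f = w - A @ np.linalg.pinv(A) @ w
        norm = np.linalg.norm(f)
        if norm < 1e-12:  # pragma: no cover - degenerate random draw
            f = w
            norm = np.linalg.norm(f) or 1.0
        f = f / norm
        v = f @ Y
        idx = int(np.argmax(np.abs(v)))
        A[:, i] = Y[:, idx]
        indices[i] = idx

    src = nonzero[indices]
    S = F[:, src].copy()
    return EndmemberSet(
        S=S,
        labels=[f"endmember_{i}" for i in range(k)],
        wavelengths=wavelengths,
        source_pixel_indices=src,
    )


# ---------------------------------------------------------------------------
# comparison helpers
# ---------------------------------------------------------------------------


def fingerprint_rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root mean squared error between two unit-max normalized spectra."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise EndmemberError(f"spectra length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def spectral_angle(a: np.ndarray, b: np.ndarray) -> float:
    """Angle (radians) between two spectra; 0 iff proportional."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    cos = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.arccos(np.clip(cos, -1.0, 1.0)))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def match_endmembers(
    extracted: EndmemberSet,
    reference: FingerprintTable,
    corr_threshold: float = MATCH_CORR_THRESHOLD,
) -> EndmemberSet:
    """Relabel extracted endmembers by optimal assignment to reference columns.

    The one-to-one assignment maximizing total Pearson correlation is solved
    exactly (Hungarian method).  A matched pair below ``corr_threshold`` is
    labeled ``unassigned`` and flagged; ambiguous optima (two assignments
    within 1e-12 of the maximum total correlation) are resolved
    deterministically toward the pairing whose peak wavelengths agree, and
    flagged in the report.

    Two extracted columns that correlate above
    :data:`DUPLICATE_CORR_THRESHOLD` with each other are one simplex vertex
    extracted twice — the signature of a missed endmember (e.g. an
    autofluorescence spectrum nearly identical to a dye's).  The duplicate
    with the weaker reference correlation is demoted to ``unassigned`` and
    its reference reported unmatched.
    """
    from scipy.optimize import linear_sum_assignment

    if not np.array_equal(extracted.wavelengths, np.asarray(reference.wavelengths)):
        raise EndmemberError("wavelength grids of extracted set and reference differ")

    ref_labels = reference.labels
    R = reference.as_matrix()
    k, r = extracted.k, len(ref_labels)
    corr = np.zeros((k, r))
    for i in range(k):
        for j in range(r):
            corr[i, j] = _pearson(extracted.S[:, i], R[:, j])

    # tie-break bias: prefer pairs whose unit-max peaks are at nearby wavelengths
    peak_e = extracted.wavelengths[np.argmax(extracted.S, axis=0)]
    peak_r = extracted.wavelengths[np.argmax(R, axis=0)]
    peak_gap = np.abs(peak_e[:, None] - peak_r[None, :])
    bias = MATCH_TIE_TOL * 0.5 * (1.0 - peak_gap / (peak_gap.max() + 1.0))

    rows, cols = linear_sum_assignment(-(corr + bias))
    total = corr[rows, cols].sum()

    ambiguous = False
    if k <= 6 and r <= 6:
        # exhaustive scan for near-optimal alternative assignments
        best_alt = -np.inf
        cols_t = tuple(cols[np.argsort(rows)])
        for perm in permutations(range(r), k):
            if perm == cols_t:
                continue
            s = corr[np.arange(k), perm].sum()
            best_alt = max(best_alt, s)
        ambiguous = bool(best_alt > total - MATCH_TIE_TOL)

    labels: list[str | None] = [None] * k
    pairs: dict[str, float] = {}
    flagged: list[str] = []
    for i, j in zip(rows, cols):
        c = corr[i, j]
        if c < corr_threshold:
            lbl = UNASSIGNED if UNASSIGNED not in labels else f"{UNASSIGNED}_{i}"
            flagged.append(ref_labels[j])
        else:
            lbl = ref_labels[j]
        labels[i] = lbl
        pairs[lbl] = float(c)
    for i in range(k):  # extracted columns beyond the reference count
        if labels[i] is None:
            labels[i] = UNASSIGNED if UNASSIGNED not in labels else f"{UNASSIGNED}_{i}"

    # duplicate-vertex demotion
    assigned_corr = np.full(k, -np.inf)
    for i, j in zip(rows, cols):
        assigned_corr[i] = corr[i, j]
    ref_of = {int(i): int(j) for i, j in zip(rows, cols)}
    for i in range(k):
        for i2 in range(i + 1, k):
            if _pearson(extracted.S[:, i], extracted.S[:, i2]) <= DUPLICATE_CORR_THRESHOLD:
                continue
            weaker = i if assigned_corr[i] <= assigned_corr[i2] else i2
            if labels[weaker].startswith(UNASSIGNED):
                continue
            flagged.append(labels[weaker])
            pairs.pop(labels[weaker], None)
            labels[weaker] = (UNASSIGNED if UNASSIGNED not in labels
                              else f"{UNASSIGNED}_{weaker}")
            ref_of.pop(weaker, None)
    # reference columns that received no acceptable column are also unmatched
    unmatched_refs = [ref_labels[j] for j in range(r) if j not in set(cols)] + flagged

    out = EndmemberSet(
        S=extracted.S.copy(),
        labels=labels,
        wavelengths=extracted.wavelengths,
        source_pixel_indices=extracted.source_pixel_indices,
    )
    out.match_report = {
        "correlations": pairs,
        "unmatched": sorted(set(unmatched_refs)),
        "ambiguous": ambiguous,
    }
    return out


# ---------------------------------------------------------------------------
# fingerprint extraction workflows
# ---------------------------------------------------------------------------


def _label_single_positive(
    pixels: PixelMatrix, candidates: EndmemberSet
) -> tuple[np.ndarray, np.ndarray]:
    """Split a k=2 VCA result into (fluorophore, background) columns.

    Each pixel is assigned to whichever of the two candidates dominates its
    FCLSU abundance; the candidate whose pixels have the higher mean total
    intensity is the fluorophore (background dominates dim pixels).
    """
    from .solvers import fclsu

    amap = fclsu(pixels, candidates)
    total = pixels.F.sum(axis=0)
    nz = total > 0
    assign = np.argmax(amap.A, axis=0)
    means = []
    for j in range(2):
        sel = nz & (assign == j)
        means.append(total[sel].mean() if np.any(sel) else 0.0)
    fl = int(np.argmax(means))
    return candidates.S[:, fl], candidates.S[:, 1 - fl]


def extract_fingerprints(
    stacks: Sequence[tuple[LambdaStack, str]],
    mode: str,
    params: VcaParams | None = None,
    expected: FingerprintTable | None = None,
) -> EndmemberSet:
    """Extract a labeled endmember set from single-positive or multiplex stacks.

    ``single_positive``: one stack per fluorophore, each labeled with its
    fluorophore name.  VCA with k=2 extracts the fluorophore and background
    signatures per stack; one shared background column (the one with the
    lowest peak-to-mean ratio, i.e. the flattest) is kept for the whole set.

    ``multiplex``: exactly one stack; VCA runs once with the full k
    (``params.k``) and columns are labeled by :func:`match_endmembers`
    against ``expected``.  Columns that match no reference are flagged
    ``unassigned`` in the returned set's ``match_report``.
    """
    params = params or VcaParams()
    if mode == "single_positive":
        wavelengths = stacks[0][0].wavelengths
        fl_cols: dict[str, np.ndarray] = {}
        bg_cols: list[np.ndarray] = []
        for stack, label in stacks:
            pix = normalize_stack(stack)
            cand = vca(pix, VcaParams(k=2, seed=params.seed,
                                      snr_db_override=params.snr_db_override,
                                      snr_threshold_offset=params.snr_threshold_offset))
            fl, bg = _label_single_positive(pix, cand)
            fl_cols[label] = fl
            bg_cols.append(bg)
        # flattest background: lowest peak-to-mean ratio
        ratios = [c.max() / c.mean() for c in bg_cols]
        background = bg_cols[int(np.argmin(ratios))]
        S = np.column_stack(list(fl_cols.values()) + [background])
        return EndmemberSet(
            S=S, labels=list(fl_cols) + ["background"], wavelengths=wavelengths
        )
    if mode == "multiplex":
        if len(stacks) != 1:
            raise EndmemberError("multiplex mode takes exactly one lambda stack")
        if expected is None:
            raise EndmemberError(
                "multiplex mode needs expected reference fingerprints: VCA column "
                "order is arbitrary and labels cannot be inferred"
            )
        stack, _ = stacks[0]
        pix = normalize_stack(stack)
        raw = vca(pix, params)
        return match_endmembers(raw, expected)
    raise EndmemberError(f"unknown extraction mode '{mode}'")
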
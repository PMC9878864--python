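"""Constrained abundance estimation under the linear mixing model F = S A.

Three solvers, all per pixel and order-free:

* ``fclsu`` — fully constrained least squares: minimize ||S a - x||^2 subject
  to a >= 0 (ANC) and sum(a) = 1 (ASC), solved exactly by an active-set
  method on the KKT system, vectorized over pixels.
* ``elmm`` — extended linear mixing model: each endmember may be scaled by a
  per-pixel factor psi_j (spectral variability as amplitude changes);
  block-coordinate descent alternating an exact FCLSU a-step against the
  scaled endmembers with closed-form coordinate updates of psi.
* ``gelmm`` — generalized ELMM: the scaling becomes a per-pixel, per-band
  vector Psi[:, j], optionally smoothed across bands (second-difference
  penalty) and pulled toward 1; alternating a-step / ridge-regularized
  per-endmember Psi block solves.

Identifiability note: the ASC is kept in ELMM/GELMM so abundances stay
proportions and all amplitude information lives in psi/Psi.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .endmembers import EndmemberSet
from .io import LambdaStack, PixelMatrix


class UnmixError(ValueError):
    pass


@dataclass
class AbundanceMap:
    """k x n abundance matrix with labels and the (Z, Y, X) geometry."""

    A: np.ndarray
    labels: list[str]
    shape: tuple[int, int, int]

    @property
    def k(self) -> int:
        return self.A.shape[0]

    def unflatten(self, label: str) -> np.ndarray:
        return self.A[self.labels.index(label)].reshape(self.shape)


@dataclass
class ElmmParams:
    max_iter: int = 200
    tol: float = 1e-6  # relative objective change
    psi_min: float = 1e-3
    lambda_psi: float = 0.0  # penalty pulling scalings toward 1


@dataclass
class ElmmResult:
    abundances: AbundanceMap
    psi: np.ndarray  # (k, n) per-pixel per-endmember scaling
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0


@dataclass
class GelmmParams:
    max_iter: int = 100
    tol: float = 1e-6
    psi_min: float = 1e-3
    lambda_smooth: float = 0.01  # second-difference penalty across bands
    lambda_unit: float = 0.01  # penalty toward all-ones scaling


@dataclass
class GelmmResult:
    abundances: AbundanceMap
    Psi: np.ndarray  # (n, C, k) per-pixel band-wise scaling
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0


@dataclass
class UnmixResult:
    """Per-channel reconstructed intensity stacks plus provenance."""

    channels: dict[str, np.ndarray]  # label -> (Z, Y, X) original dtype
    abundances: AbundanceMap
    endmembers: EndmemberSet
    solver: str
    name: str = "stack"
    runtime_s: float = 0.0
    overflow_clamped: int = 0
    metrics: object | None = None


# ---------------------------------------------------------------------------
# exact simplex-constrained least squares (batched active set)
# ---------------------------------------------------------------------------


def simplex_lstsq(G: np.ndarray, b: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Minimize 0.5 a'Ga - b'a over the probability simplex, per row of b.

    ``G`` is either a shared (k, k) Gram matrix or a per-pixel (n, k, k)
    batch; ``b`` is (n, k).  Exact active-set method on the equality-
    constrained KKT system with dual feasibility checks; inactive variables
    are pinned to zero by row substitution so every pixel solves a fixed-size
    (k+1) system and the whole batch stays vectorized.
    """
    b = np.asarray(b, dtype=float)
    n, k = b.shape
    shared = G.ndim == 2
    active = np.ones((n, k), dtype=bool)
    a = np.zeros((n, k))
    mu = np.zeros(n)
    todo = np.ones(n, dtype=bool)

    base = np.zeros((k + 1, k + 1))
    base[:k, k] = 1.0
    base[k, :k] = 1.0

    for _ in range(3 * k + 12):
        idx = np.flatnonzero(todo)
        if idx.size == 0:
            break
        m = idx.size
        K = np.broadcast_to(base, (m, k + 1, k + 1)).copy()
        if shared:
            K[:, :k, :k] = G
        else:
            K[:, :k, :k] = G[idx]
        rhs = np.zeros((m, k + 1))
        rhs[:, :k] = b[idx]
        rhs[:, k] = 1.0
        act = active[idx]
        # pin inactive variables: row i -> e_i, rhs_i -> 0
        for i in range(k):
            off = ~act[:, i]
            if np.any(off):
                K[off, i, :] = 0.0
                K[off, i, i] = 1.0
                rhs[off, i] = 0.0
        try:
            sol = np.linalg.solve(K, rhs[..., None])[..., 0]
        except np.linalg.LinAlgError:
            K = K + np.eye(k + 1) * 1e-12
            sol = np.linalg.solve(K, rhs[..., None])[..., 0]
        a_new = sol[:, :k]
        mu_new = sol[:, k]

        # primal step: drop the most negative active variable
        neg = np.where(act, a_new, np.inf)
        worst = np.argmin(neg, axis=1)
        has_neg = neg[np.arange(m), worst] < -tol
        if np.any(has_neg):
            rows = np.flatnonzero(has_neg)
            active[idx[rows], worst[rows]] = False

        ok = ~has_neg
        if np.any(ok):
            rows = np.flatnonzero(ok)
            aa = np.clip(a_new[rows], 0.0, None)
            if shared:
                grad = aa @ G - b[idx[rows]]
            else:
                grad = np.einsum("pij,pj->pi", G[idx[rows]], aa) - b[idx[rows]]
            nu = grad + mu_new[rows, None]
            nu = np.where(act[rows], np.inf, nu)
            entering = np.argmin(nu, axis=1)
            viol = nu[np.arange(rows.size), entering] < -tol
            if np.any(viol):
                vr = rows[viol]
                active[idx[vr], entering[viol]] = True
            done = rows[~viol]
            if done.size:
                g = idx[done]
                a[g] = np.clip(a_new[done], 0.0, None)
                mu[g] = mu_new[done]
                todo[g] = False
    else:  # pragma: no cover - cycling safeguard
        idx = np.flatnonzero(todo)
        if idx.size:
            raise UnmixError(f"active-set solver failed to converge for {idx.size} pixels")
    # renormalize away last-digit drift so the ASC holds tightly
    s = a.sum(axis=1, keepdims=True)
    np.divide(a, s, out=a, where=s > 0)
    return a


def _check_endmembers(S: EndmemberSet, C: int) -> np.ndarray:
    M = S.S
    if M.shape[0] != C:
        raise UnmixError(f"endmember matrix has {M.shape[0]} bands, data has {C}")
    if np.linalg.matrix_rank(M) < S.k:
        raise UnmixError(
            "endmember matrix is rank deficient (duplicate or collinear columns); "
            "abundances would not be unique"
        )
    return M


def fclsu(pixels: PixelMatrix, S: EndmemberSet) -> AbundanceMap:
    """Fully constrained least-squares unmixing (exact, per pixel).

    Pixels with zero total intensity get all-zero abundance columns rather
    than a meaningless simplex point.
    """
    F = pixels.F
    C, n = F.shape
    M = _check_endmembers(S, C)
    G = M.T @ M
    b = F.T @ M  # (n, k)
    nz = F.sum(axis=0) > 0
    A = np.zeros((S.k, n))
    if np.any(nz):
        A[:, nz] = simplex_lstsq(G, b[nz]).T
    return AbundanceMap(A=A, labels=list(S.labels), shape=pixels.shape)


# ---------------------------------------------------------------------------
# ELMM
# ---------------------------------------------------------------------------


def _elmm_objective(M: np.ndarray, X: np.ndarray, A: np.ndarray, psi: np.ndarray,
                    lam: float) -> float:
    # M: (C, k); X: (C, m); A: (k, m); psi: (k, m)
    fit = M @ (psi * A) - X
    obj = 0.5 * float(np.sum(fit**2)) + 0.5 * lam * float(np.sum((psi - 1.0) ** 2))
    return obj


def elmm(pixels: PixelMatrix, S: EndmemberSet, params: ElmmParams | None = None) -> ElmmResult:
    """Extended linear mixing model by block-coordinate descent.

    Per pixel: minimize 0.5||S diag(psi) a - x||^2 + (lambda_psi/2)||psi-1||^2
    over a on the simplex and psi >= psi_min.  The a-step is an exact FCLSU
    solve against the scaled endmembers; the psi-step sweeps closed-form
    per-endmember updates clipped at psi_min, so the objective never
    increases.  Initialized at psi = 1, a = FCLSU.
    """
    params = params or ElmmParams()
    F = pixels.F
    C, n = F.shape
    M = _check_endmembers(S, C)
    k = S.k
    nz = F.sum(axis=0) > 0
    X = F[:, nz]  # (C, m)
    m = X.shape[1]

    A = fclsu(pixels, S).A[:, nz]
    psi = np.ones((k, m))
    G0 = M.T @ M

    trace = [_elmm_objective(M, X, A, psi, params.lambda_psi)]
    it = 0
    for it in range(1, params.max_iter + 1):
        # a-step: FCLSU with per-pixel scaled endmembers S diag(psi)
        Gp = G0[None, :, :] * (psi.T[:, :, None] * psi.T[:, None, :])  # (m, k, k)
        bp = (X.T @ M) * psi.T  # (m, k)
        A = simplex_lstsq(Gp, bp).T

        # psi-step: coordinate sweep, exact 1-D minimizer with clip
        Mw = M[None, :, :] * A.T[:, None, :]  # (m, C, k): column j = a_j * s_j
        y = np.einsum("mck,km->cm", Mw, psi)  # current model S diag(psi) a
        lam = params.lambda_psi
        for j in range(k):
            mj = Mw[:, :, j].T  # (C, m)
            y_minus = y - mj * psi[j]
            num = np.sum(mj * (X - y_minus), axis=0) + lam
            den = np.sum(mj**2, axis=0) + lam
            psi_j = np.where(den > 0, num / np.where(den > 0, den, 1.0), 1.0)
            psi[j] = np.clip(psi_j, params.psi_min, None)
            y = y_minus + mj * psi[j]

        A, psi = _prune_pinned(M, X, A, psi, lam, params.psi_min)

        obj = _elmm_objective(M, X, A, psi, lam)
        if not np.isfinite(obj):
            raise UnmixError("non-finite ELMM objective")
        trace.append(obj)
        prev = trace[-2]
        if prev - obj <= params.tol * max(prev, 1e-30):
            break

    A_full = np.zeros((k, n))
    A_full[:, nz] = A
    psi_full = np.ones((k, n))
    psi_full[:, nz] = psi
    amap = AbundanceMap(A=A_full, labels=list(S.labels), shape=pixels.shape)
    return ElmmResult(abundances=amap, psi=psi_full, objective_trace=trace, n_iter=it)


def _prune_pinned(M: np.ndarray, X: np.ndarray, A: np.ndarray, psi: np.ndarray,
                  lam: float, psi_min: float) -> tuple[np.ndarray, np.ndarray]:
    """Escape the floor-scaling fixed point of the ELMM block descent.

    The sum-to-one constraint lets excess simplex mass hide on endmembers
    whose scaling sits at the ``psi_min`` floor (near-zero effective
    contribution), a stationary point of the alternating scheme that is not
    the constrained minimum.  The candidate move zeroes those abundances,
    renormalizes, and rescales the surviving psi so every surviving product
    psi_j * a_j is preserved — the model only loses the floor terms.  The
    move is accepted per pixel only where it strictly lowers the objective.
    """
    pinned = (psi <= psi_min * (1 + 1e-9)) & (A > 1e-12)
    multi = (A > 1e-12).sum(axis=0) > 1  # vertex candidate applies here too
    cols = np.flatnonzero(np.any(pinned, axis=0) | multi)
    if cols.size == 0:
        return A, psi
    Ac = A[:, cols]
    Pc = psi[:, cols]
    pin = pinned[:, cols]
    keep = np.where(pin, 0.0, Ac)
    mass = keep.sum(axis=0)
    ok = mass > 1e-12
    if not np.any(ok):
        return A, psi
    cols, Ac, Pc, pin, keep, mass = (cols[ok], Ac[:, ok], Pc[:, ok], pin[:, ok],
                                     keep[:, ok], mass[ok])
    A_new = keep / mass
    with np.errstate(divide="ignore", invalid="ignore"):
        P_new = np.where(A_new > 0, Pc * Ac / np.where(A_new > 0, A_new, 1.0), 1.0)
    Xc = X[:, cols]
    r_old = M @ (Pc * Ac) - Xc
    r_new = M @ (P_new * A_new) - Xc
    obj_old = 0.5 * np.sum(r_old**2, axis=0) + 0.5 * lam * np.sum((Pc - 1) ** 2, axis=0)
    obj_new = 0.5 * np.sum(r_new**2, axis=0) + 0.5 * lam * np.sum((P_new - 1) ** 2, axis=0)

    # vertex candidate: all mass on the dominant endmember, exact 1-D rescale
    k = M.shape[1]
    jmax = np.argmax(Pc * Ac, axis=0)
    Sj = M[:, jmax]  # (C, m)
    ss = np.sum(Sj**2, axis=0)
    psi_v = np.clip((np.sum(Sj * Xc, axis=0) + lam) / (ss + lam), psi_min, None)
    r_v = Sj * psi_v - Xc
    obj_v = 0.5 * np.sum(r_v**2, axis=0) + 0.5 * lam * (psi_v - 1) ** 2

    use_new = (obj_new < obj_old) & (obj_new <= obj_v)
    use_v = (obj_v < obj_old) & ~use_new
    if np.any(use_new):
        sel = cols[use_new]
        A[:, sel] = A_new[:, use_new]
        psi[:, sel] = P_new[:, use_new]
    if np.any(use_v):
        sel = cols[use_v]
        A[:, sel] = 0.0
        A[jmax[use_v], sel] = 1.0
        psi[:, sel] = 1.0
        psi[jmax[use_v], sel] = psi_v[use_v]
    return A, psi


# ---------------------------------------------------------------------------
# GELMM
# ---------------------------------------------------------------------------


def _second_difference(C: int) -> np.ndarray:
    D = np.zeros((C - 2, C))
    for i in range(C - 2):
        D[i, i] = 1.0
        D[i, i + 1] = -2.0
        D[i, i + 2] = 1.0
    return D


def _gelmm_objective(M: np.ndarray, X: np.ndarray, A: np.ndarray, Psi: np.ndarray,
                     L: np.ndarray, lam_s: float, lam_u: float) -> float:
    # Psi: (m, C, k); model_c = sum_j a_j S[c,j] Psi[c,j]
    model = np.einsum("mck,km->cm", M[None, :, :] * Psi, A)
    obj = 0.5 * float(np.sum((model - X) ** 2))
    if lam_s:
        obj += 0.5 * lam_s * float(np.einsum("mck,cd,mdk->", Psi, L, Psi))
    if lam_u:
        obj += 0.5 * lam_u * float(np.sum((Psi - 1.0) ** 2))
    return obj


def gelmm(pixels: PixelMatrix, S: EndmemberSet, params: GelmmParams | None = None,
          chunk: int = 4096) -> GelmmResult:
    """Generalized ELMM: per-pixel, per-band endmember scaling.

    Per pixel: minimize 0.5||(S .* Psi) a - x||^2
    + (lambda_smooth/2) sum_j ||D2 Psi[:,j]||^2
    + (lambda_unit/2) ||Psi - 1||^2, a on the simplex, Psi >= psi_min.
    Alternates an exact a-step on the scaled endmembers with per-endmember
    ridge-regularized band-profile solves (clamped at psi_min with
    re-solve).  Initialized from the ELMM solution, Psi[:, j] = psi_j * 1.
    """
    params = params or GelmmParams()
    F = pixels.F
    C, n = F.shape
    M = _check_endmembers(S, C)
    k = S.k
    nz = F.sum(axis=0) > 0
    X = F[:, nz]
    m = X.shape[1]

    warm = elmm(pixels, S, ElmmParams(psi_min=params.psi_min))
    A = warm.abundances.A[:, nz]
    Psi = np.repeat(warm.psi[:, nz].T[:, None, :], C, axis=1)  # (m, C, k)

    D2 = _second_difference(C)
    L = D2.T @ D2
    lam_s, lam_u = params.lambda_smooth, params.lambda_unit

    trace = [_gelmm_objective(M, X, A, Psi, L, lam_s, lam_u)]
    it = 0
    for it in range(1, params.max_iter + 1):
        # a-step over chunks: effective endmembers S .* Psi per pixel
        for lo in range(0, m, chunk):
            hi = min(lo + chunk, m)
            Se = M[None, :, :] * Psi[lo:hi]  # (c?, C, k)
            G = np.einsum("mci,mcj->mij", Se, Se)
            b = np.einsum("mci,cm->mi", Se, X[:, lo:hi])
            A[:, lo:hi] = simplex_lstsq(G, b).T

        # Psi-step: per-endmember band-profile block solve
        for lo in range(0, m, chunk):
            hi = min(lo + chunk, m)
            Xc = X[:, lo:hi].T  # (c?, C)
            Ac = A[:, lo:hi]
            Pc = Psi[lo:hi]
            W = M[None, :, :] * Ac.T[:, None, :]  # (c?, C, k): w_j = a_j s_j
            model = np.einsum("mck->mc", W * Pc)
            for j in range(k):
                wj = W[:, :, j]  # (c?, C)
                r = Xc - (model - wj * Pc[:, :, j])
                # (diag(wj^2) + lam_s L + lam_u I) psi_j = wj*r + lam_u
                rhs = wj * r + lam_u
                psi_j = _psi_band_solve(wj**2, rhs, lam_s, lam_u, L, params.psi_min)
                model = model - wj * Pc[:, :, j] + wj * psi_j
                Pc[:, :, j] = psi_j
            Psi[lo:hi] = Pc

        obj = _gelmm_objective(M, X, A, Psi, L, lam_s, lam_u)
        if not np.isfinite(obj):
            raise UnmixError("non-finite GELMM objective")
        trace.append(obj)
        prev = trace[-2]
        if prev - obj <= params.tol * max(prev, 1e-30):
            break

    A_full = np.zeros((k, n))
    A_full[:, nz] = A
    Psi_full = np.ones((n, C, k))
    Psi_full[nz] = Psi
    amap = AbundanceMap(A=A_full, labels=list(S.labels), shape=pixels.shape)
    return GelmmResult(abundances=amap, Psi=Psi_full, objective_trace=trace, n_iter=it)


def _ldl_penta_solve(d0: np.ndarray, d1: np.ndarray, d2: np.ndarray,
                     b: np.ndarray) -> np.ndarray:
    """Batched LDL' solve of symmetric pentadiagonal systems.

    ``d0``/``d1``/``d2`` are the main/first/second diagonals, each batched
    (m, C[-offset]).  O(C) per pixel instead of the O(C^3) dense solve; the
    loop runs over bands, every operation is vectorized over the batch.
    """
    m, C = d0.shape
    d = np.empty_like(d0)
    e1 = np.zeros((m, C))
    e2 = np.zeros((m, C))
    for i in range(C):
        di = d0[:, i].copy()
        if i >= 1:
            di -= e1[:, i - 1] ** 2 * d[:, i - 1]
        if i >= 2:
            di -= e2[:, i - 2] ** 2 * d[:, i - 2]
        d[:, i] = di
        if i + 1 < C:
            v = d1[:, i].copy()
            if i >= 1:
                v -= e2[:, i - 1] * e1[:, i - 1] * d[:, i - 1]
            e1[:, i] = v / di
        if i + 2 < C:
            e2[:, i] = d2[:, i] / di
    z = np.empty_like(b)
    for i in range(C):
        zi = b[:, i].copy()
        if i >= 1:
            zi -= e1[:, i - 1] * z[:, i - 1]
        if i >= 2:
            zi -= e2[:, i - 2] * z[:, i - 2]
        z[:, i] = zi
    y = z / d
    x = np.empty_like(b)
    for i in range(C - 1, -1, -1):
        xi = y[:, i].copy()
        if i + 1 < C:
            xi -= e1[:, i] * x[:, i + 1]
        if i + 2 < C:
            xi -= e2[:, i] * x[:, i + 2]
        x[:, i] = xi
    return x


def _psi_band_solve(w2: np.ndarray, rhs: np.ndarray, lam_s: float, lam_u: float,
                    L: np.ndarray, psi_min: float) -> np.ndarray:
    """Per-endmember band-profile update with a lower bound.

    Solves (diag(w2 + lam_u) + lam_s * D2'D2) psi = rhs for each pixel, then
    clamps at ``psi_min`` with re-solve (clamped bands are pinned and their
    coupling moved to the right-hand side).  With no regularization, bands
    with zero data weight rest at 1 (the objective is flat there).
    """
    m, C = w2.shape
    if lam_s == 0.0:
        dd = w2 + lam_u
        psi = np.where(dd > 0, rhs / np.where(dd > 0, dd, 1.0), 1.0)
        return np.clip(psi, psi_min, None)

    l0 = np.diag(L).copy()
    l1 = np.diag(L, 1).copy()
    l2 = np.diag(L, 2).copy()
    d0 = w2 + lam_u + lam_s * l0
    d1 = np.broadcast_to(lam_s * l1, (m, C - 1))
    d2 = np.broadcast_to(lam_s * l2, (m, C - 2))

    fixed = np.zeros_like(rhs, dtype=bool)
    psi = None
    for _ in range(4):
        if np.any(fixed):
            f = fixed.astype(float)
            # move clamped columns' coupling into the rhs of free rows
            adj = np.zeros_like(rhs)
            adj[:, :-1] += d1 * f[:, 1:]
            adj[:, 1:] += d1 * f[:, :-1]
            adj[:, :-2] += d2 * f[:, 2:]
            adj[:, 2:] += d2 * f[:, :-2]
            rf = rhs - psi_min * adj
            rf[fixed] = psi_min
            dd0 = np.where(fixed, 1.0, d0)
            touch1 = fixed[:, :-1] | fixed[:, 1:]
            touch2 = fixed[:, :-2] | fixed[:, 2:]
            dd1 = np.where(touch1, 0.0, d1)
            dd2 = np.where(touch2, 0.0, d2)
        else:
            rf, dd0, dd1, dd2 = rhs, d0, np.asarray(d1), np.asarray(d2)
        psi = _ldl_penta_solve(dd0, dd1, dd2, rf)
        new_fixed = psi < psi_min
        if not np.any(new_fixed & ~fixed):
            break
        fixed |= new_fixed
    return np.clip(psi, psi_min, None)


# ---------------------------------------------------------------------------
# channel reconstruction
# ---------------------------------------------------------------------------


def reconstruct_channels(
    result: AbundanceMap | ElmmResult | GelmmResult,
    S: EndmemberSet,
    pixels: PixelMatrix,
    solver: str | None = None,
) -> UnmixResult:
    """Render per-fluorophore intensity images from abundances.

    The channel intensity of fluorophore j at a pixel is the modeled
    contribution of endmember j at its peak band: a_j * (scaling at the peak
    band) * S[peak_j, j], mapped back to the original integer dtype
    (rounded half to even; overflow clamps to dtype_max with a count).
    """
    t0 = time.perf_counter()
    if isinstance(result, ElmmResult):
        amap, solver = result.abundances, solver or "elmm"
        scale = lambda j, peak: result.psi[j]  # noqa: E731
    elif isinstance(result, GelmmResult):
        amap, solver = result.abundances, solver or "gelmm"
        scale = lambda j, peak: result.Psi[:, peak, j]  # noqa: E731
    else:
        amap, solver = result, solver or "fclsu"
        scale = lambda j, peak: 1.0  # noqa: E731

    if amap.shape != pixels.shape:
        raise UnmixError(f"abundance shape {amap.shape} != stack shape {pixels.shape}")
    dtype = pixels.source_dtype
    dmax = pixels.dtype_max
    channels: dict[str, np.ndarray] = {}
    overflow = 0
    for j, label in enumerate(amap.labels):
        peak = S.peak_band(label)
        vals = amap.A[j] * scale(j, peak) * S.S[peak, S.labels.index(label)] * dmax
        vals = np.rint(vals)
        overflow += int(np.sum(vals > dmax))
        vals = np.clip(vals, 0, dmax)
        channels[label] = vals.astype(dtype).reshape(pixels.shape)
    return UnmixResult(
        channels=channels,
        abundances=amap,
        endmembers=S,
        solver=solver,
        name=pixels.name,
        runtime_s=time.perf_counter() - t0,
        overflow_clamped=overflow,
    )
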
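"""Validation experiments at study scale.

Each function runs one self-contained experiment — solver-vs-oracle
agreement, vertex recovery, fingerprint extraction, spectral-variability
recovery, the end-to-end synthetic benchmark, and pipeline determinism —
and returns the measured quantities.  The test suite asserts thresholds on
these numbers; the acceptance script reports them.

All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np

from . import io as sio
from .endmembers import (
    EndmemberSet,
    VcaParams,
    extract_fingerprints,
    fingerprint_rmse,
    spectral_angle,
    vca,
)
from .io import PixelMatrix
from .metrics import dice
from .solvers import ElmmParams, GelmmParams, elmm, fclsu, gelmm
from .synth import NoiseModel, make_panel, make_pure_mosaic_scene, make_scene, make_single_positive, render

#: detection threshold for ground-truth mask comparisons: above the FCLSU
#: noise floor at the benchmark SNR, well below object amplitudes
TRUTH_MASK_THRESHOLD = 0.1


def _pixels(F: np.ndarray) -> PixelMatrix:
    n = F.shape[1]
    return PixelMatrix(F=F, shape=(1, 1, n), wavelengths=np.arange(float(F.shape[0])),
                       dtype_max=65535, source_dtype=np.dtype(np.uint16))


def _random_endmembers(rng: np.random.Generator, C: int, k: int) -> EndmemberSet:
    S = np.abs(rng.normal(size=(C, k))) + 0.1
    S /= S.max(axis=0)
    return EndmemberSet(S, [f"m{i}" for i in range(k)], np.arange(C, dtype=float))


# ---------------------------------------------------------------------------
# solver vs brute-force oracle
# ---------------------------------------------------------------------------


def brute_force_simplex_objective(S: np.ndarray, x: np.ndarray,
                                  step: float = 1e-3) -> float:
    """Independent oracle for the k=3 simplex least-squares problem:
    dense grid over the simplex at the given step, then SLSQP polish."""
    from scipy.optimize import minimize

    g = np.arange(0.0, 1.0 + step / 2, step)
    a1, a2 = np.meshgrid(g, g)
    keep = a1 + a2 <= 1 + 1e-12
    a = np.stack([a1[keep], a2[keep], 1.0 - a1[keep] - a2[keep]], axis=1)
    obj = 0.5 * np.sum((a @ S.T - x) ** 2, axis=1)
    i = int(np.argmin(obj))
    res = minimize(
        lambda v: 0.5 * np.sum((S @ v - x) ** 2),
        a[i],
        bounds=[(0, 1)] * 3,
        constraints=({"type": "eq", "fun": lambda v: v.sum() - 1},),
        method="SLSQP",
        options={"ftol": 1e-14, "maxiter": 300},
    )
    return min(obj[i], float(res.fun))


def fclsu_oracle_benchmark(seed: int, n_instances: int = 100) -> dict:
    """FCLSU objective vs the grid+polish oracle on random C=4, k=3 systems,
    plus constraint residuals on a fuzz batch."""
    rng = np.random.default_rng(seed)
    max_gap = 0.0
    for _ in range(n_instances):
        ems = _random_endmembers(rng, 4, 3)
        x = rng.random(4)
        a = fclsu(_pixels(x[:, None]), ems).A[:, 0]
        mine = 0.5 * np.sum((ems.S @ a - x) ** 2)
        oracle = brute_force_simplex_objective(ems.S, x)
        max_gap = max(max_gap, abs(mine - oracle))

    ems = _random_endmembers(rng, 6, 4)
    F = rng.random((6, 2000))
    A = fclsu(_pixels(F), ems).A
    return {
        "max_objective_gap": float(max_gap),
        "max_negative_abundance": float(max(0.0, -A.min())),
        "max_sum_violation": float(np.abs(A.sum(axis=0) - 1).max()),
        "n": n_instances,
    }


# ---------------------------------------------------------------------------
# VCA pure-pixel recovery
# ---------------------------------------------------------------------------


def vca_recovery_benchmark(seed: int, n_seeds: int = 20,
                           n_mixtures: int = 400) -> dict:
    """Noise-free Dirichlet mixtures with injected pure pixels: worst matched
    spectral angle over k in 2..8, C in {8, 16, 32}, ``n_seeds`` draws."""
    worst = 0.0
    n_runs = 0
    for C in (8, 16, 32):
        for k in range(2, 9):
            for s in range(n_seeds):
                rng = np.random.default_rng((seed, C, k, s))
                S = np.abs(rng.normal(size=(C, k))) + 0.1
                S /= S.max(axis=0)
                A = rng.dirichlet(np.ones(k), size=n_mixtures).T
                A[:, :k] = np.eye(k)
                ems = vca(S @ A, VcaParams(k=k, seed=s))
                ang = max(
                    min(spectral_angle(ems.S[:, i], S[:, j]) for i in range(k))
                    for j in range(k)
                )
                worst = max(worst, ang)
                n_runs += 1
    return {"max_spectral_angle_rad": float(worst), "n": n_runs}


# ---------------------------------------------------------------------------
# fingerprint pipeline
# ---------------------------------------------------------------------------


def fingerprint_benchmark(seed: int, shape=(2, 64, 64), snr_db: float = 40.0) -> dict:
    """Single-positive extraction accuracy for all six members, cross-mode
    agreement with multiplex extraction, and the engineered
    lipofuscin/520-overlap failure case."""
    panel = make_panel()
    labels = ["DAPI", "Opal520", "Opal570", "Opal620", "Opal690", "lipofuscin"]
    noise = NoiseModel(target_snr_db=snr_db)
    stacks = [
        (make_single_positive(l, panel, shape=shape, noise=noise, seed=seed * 10 + i)[0], l)
        for i, l in enumerate(labels)
    ]
    ems_sp = extract_fingerprints(stacks, mode="single_positive",
                                  params=VcaParams(seed=seed))
    rmses = {l: fingerprint_rmse(ems_sp.column(l), panel.spectra[l]) for l in labels}

    scene = make_scene((2, 96, 96), seed=seed + 1)
    stack_m, _ = render(panel, scene, noise=noise, seed=seed + 2)
    ems_m = extract_fingerprints([(stack_m, "multiplex")], mode="multiplex",
                                 params=VcaParams(k=7, seed=seed),
                                 expected=panel.as_table())
    cross = [
        np.degrees(spectral_angle(ems_m.column(l), ems_sp.column(l)))
        for l in labels
        if l in ems_m.labels
    ]

    panel_bad = make_panel(confusable_lipofuscin=True)
    scene_b = make_scene((2, 96, 96), seed=seed + 3)
    stack_b, _ = render(panel_bad, scene_b, noise=noise, seed=seed + 4)
    ems_b = extract_fingerprints([(stack_b, "multiplex")], mode="multiplex",
                                 params=VcaParams(k=7, seed=seed),
                                 expected=panel.as_table())
    return {
        "rmse": rmses,
        "max_rmse": float(max(rmses.values())),
        "cross_mode_max_angle_deg": float(max(cross)) if cross else float("nan"),
        "n_cross_matched": len(cross),
        "confusable_lipofuscin_flagged": "lipofuscin" in ems_b.match_report["unmatched"],
        "n": int(np.prod(shape)),
    }


# ---------------------------------------------------------------------------
# spectral-variability recovery
# ---------------------------------------------------------------------------


def elmm_recovery_benchmark(seed: int, shape=(1, 256, 256),
                            amplitude: float = 0.8) -> dict:
    """Noise-free psi ~ U(0.8, 1.2) on a pure mosaic: recovery RMSE and
    objective monotonicity.

    The mosaic is rendered at ``amplitude`` < 1 so psi > 1 does not saturate
    the detector; with the sum-to-one constraint the solver's scaling equals
    amplitude * psi on single-endmember pixels, so the estimate is divided
    by the amplitude before comparing against the drawn scalings.
    """
    panel = make_panel()
    labels = [l for l in panel.spectra if l != "background"]
    scene = make_pure_mosaic_scene(shape, labels, seed=seed, amplitude=amplitude)
    stack, truth = render(panel, scene,
                          variability={"kind": "elmm", "low": 0.8, "high": 1.2},
                          seed=seed + 1)
    pix = sio.normalize_stack(stack)
    res = elmm(pix, truth.endmembers, ElmmParams(lambda_psi=0.0))
    present = truth.A[:-1] > 0
    err = res.psi[:-1][present] / amplitude - truth.psi[:-1][present]
    return {
        "psi_rmse": float(np.sqrt(np.mean(err**2))),
        "monotone": bool(np.all(np.diff(res.objective_trace) <= 1e-10)),
        "n_iter": res.n_iter,
        "n": int(np.prod(shape)),
    }


def gelmm_recovery_benchmark(seed: int, shape=(1, 256, 256)) -> dict:
    """One endmember attenuated x0.5 above 650 nm on a 410-700 nm grid:
    correlation of the recovered band-scaling profile with the true step."""
    grid = np.linspace(410, 700, 32)
    panel = make_panel(grid=grid)
    labels = [l for l in panel.spectra if l != "background"]
    scene = make_pure_mosaic_scene(shape, labels, seed=seed)
    stack, truth = render(
        panel, scene,
        variability={"kind": "gelmm_step", "label": "Opal690",
                     "factor": 0.5, "above_nm": 650.0},
        seed=seed + 1,
    )
    pix = sio.normalize_stack(stack)
    res = gelmm(pix, truth.endmembers, GelmmParams())
    j = truth.labels.index("Opal690")
    present = truth.A[j] > 0
    prof = res.Psi[present, :, j].mean(axis=0)
    r = np.corrcoef(prof, truth.Psi_profiles["Opal690"])[0, 1]
    return {
        "band_scaling_corr": float(r),
        "monotone": bool(np.all(np.diff(res.objective_trace) <= 1e-10)),
        "n_iter": res.n_iter,
        "n": int(np.prod(shape)),
    }


def gelmm_collapse_benchmark(seed: int, shape=(1, 64, 64)) -> dict:
    """lambda_unit -> infinity pins Psi at 1, collapsing GELMM to FCLSU."""
    panel = make_panel()
    scene = make_scene(shape, seed=seed)
    stack, truth = render(panel, scene, noise=NoiseModel(target_snr_db=30),
                          seed=seed + 1)
    pix = sio.normalize_stack(stack)
    res = gelmm(pix, truth.endmembers,
                GelmmParams(lambda_unit=1e9, lambda_smooth=0.0, max_iter=20))
    base = fclsu(pix, truth.endmembers)
    return {
        "max_abundance_diff": float(np.abs(res.abundances.A - base.A).max()),
        "n": int(np.prod(shape)),
    }


# ---------------------------------------------------------------------------
# end-to-end synthetic benchmark
# ---------------------------------------------------------------------------


def end_to_end_benchmark(seed: int, shape=(4, 256, 256), snr_db: float = 30.0) -> dict:
    """Six-member scene at the benchmark SNR: FCLSU per-channel Dice against
    ground-truth masks, with the lipofuscin channel isolated."""
    panel = make_panel()
    scene = make_scene(shape, seed=seed)
    stack, truth = render(panel, scene, noise=NoiseModel(target_snr_db=snr_db),
                          seed=seed + 1)
    pix = sio.normalize_stack(stack)
    amap = fclsu(pix, truth.endmembers)
    dices = {}
    for j, label in enumerate(truth.labels[:-1]):  # background not scored
        dices[label] = dice(amap.A[j] >= TRUTH_MASK_THRESHOLD,
                            truth.A[j] >= TRUTH_MASK_THRESHOLD)
    return {
        "dice": dices,
        "min_dice": float(min(dices.values())),
        "mean_dice": float(np.mean(list(dices.values()))),
        "lipofuscin_isolated": "lipofuscin" in dices,
        "n": int(np.prod(shape)),
    }


# ---------------------------------------------------------------------------
# determinism
# ---------------------------------------------------------------------------


def _tree_hash(d: Path) -> str:
    h = hashlib.sha256()
    for p in sorted(Path(d).rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def determinism_benchmark(seed: int, workdir: str | Path, shape=(2, 48, 48)) -> dict:
    """Rerun the pipeline with one config+seed and compare output bytes;
    rerun a 3-image batch shuffled with 2 workers and compare per image."""
    from .cli import RunConfig, run_batch, run_pipeline

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    panel = make_panel()
    panel.as_table().to_csv(workdir / "panel.csv")
    paths = []
    for i in range(3):
        scene = make_scene(shape, seed=seed + i)
        stack, _ = render(panel, scene, noise=NoiseModel(target_snr_db=30),
                          seed=seed + 10 + i, name=f"img{i}")
        paths.append(str(sio.write_lambda_stack(stack, workdir / f"img{i}.ome.tif")))

    def config(out, inputs, jobs=1):
        return RunConfig(inputs=inputs, algorithm="fclsu",
                         endmember_csv=str(workdir / "panel.csv"),
                         out_dir=str(workdir / out), master_seed=seed, jobs=jobs)

    run_pipeline(config("r1", [paths[0]]))
    run_pipeline(config("r2", [paths[0]]))
    rerun_ok = _tree_hash(workdir / "r1" / "img0") == _tree_hash(workdir / "r2" / "img0")

    run_batch(config("b1", paths, jobs=1))
    run_batch(config("b2", paths[::-1], jobs=2))
    batch_ok = all(
        _tree_hash(workdir / "b1" / f"img{i}") == _tree_hash(workdir / "b2" / f"img{i}")
        for i in range(3)
    )
    return {"rerun_identical": bool(rerun_ok), "batch_invariant": bool(batch_ok),
            "n": 3}
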
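import hashlib
from pathlib import Path

import numpy as np
import pytest

import specunmix as su
from specunmix.io import PixelMatrix


@pytest.fixture(scope="session")
def panel():
    return su.make_panel()


@pytest.fixture(scope="session")
def member_labels():
    return ["DAPI", "Opal520", "Opal570", "Opal620", "Opal690", "lipofuscin"]


def as_pixels(F, shape=None, dtype=np.uint16):
    """Wrap a raw C x n matrix as a PixelMatrix for solver-level tests."""
    F = np.asarray(F, dtype=float)
    n = F.shape[1]
    return PixelMatrix(
        F=F,
        shape=shape or (1, 1, n),
        wavelengths=np.arange(float(F.shape[0])),
        dtype_max=int(np.iinfo(np.dtype(dtype)).max),
        source_dtype=np.dtype(dtype),
    )


def tree_hash(d) -> str:
    h = hashlib.sha256()
    for p in sorted(Path(d).rglob("*")):
        if p.is_file():
            h.update(p.name.encode())
            h.update(p.read_bytes())
    return h.hexdigest()


def random_endmembers(rng, C, k):
    S = np.abs(rng.normal(size=(C, k))) + 0.1
    S /= S.max(axis=0)
    return su.EndmemberSet(S, [f"m{i}" for i in range(k)], np.arange(C, dtype=float))
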
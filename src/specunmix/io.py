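"""Lambda-stack and fingerprint I/O.

A *lambda stack* is a 4-D multispectral fluorescence image: a z-series of
x/y planes recorded at many narrow emission wavelength bands.  This module
reads and writes such stacks as OME-TIFF, normalizes detector counts to
[0, 1], and flattens stacks into the C x n pixel matrix consumed by every
unmixing solver (n pixels, C spectral bands).

Conventions
-----------
* In-memory axis order is ``(z, y, x, band)``, 0-based.
* Flattening is z-major row-major (z slowest, then y, then x), so abundance
  maps can be unflattened back onto the original geometry bit-exactly.
* Normalization divides by the saturation value of the source integer type
  (``dtype_max``), never by a per-image maximum, so intensities stay
  comparable across the images of a batch.
"""

from __future__ import annotations

import json
import re
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import tifffile

if TYPE_CHECKING:  # pragma: no cover
    from .solvers import UnmixResult

_OME_NS = "http://www.openmicroscopy.org/Schemas/OME/2016-06"


class SpectralIOError(ValueError):
    """Raised for malformed lambda stacks or fingerprint tables."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class LambdaStack:
    """4-D spectral image plus per-band center wavelengths.

    Parameters
    ----------
    data:
        Intensity array indexed ``(z, y, x, band)`` in raw detector units.
    wavelengths:
        Band-center wavelengths in nm, strictly increasing, one per band.
    dtype_max:
        Saturation value of the source integer type (255, 65535, ...).
    name:
        Image identifier; used to derive deterministic output names and
        per-image seeds.
    pixel_size_um:
        Optional physical pixel size (not used by the solvers).
    """

    data: np.ndarray
    wavelengths: np.ndarray
    dtype_max: int
    name: str = "stack"
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 4:
            raise SpectralIOError(
                f"lambda stack must be 4-D (z, y, x, band); got shape {self.data.shape}"
            )
        c = self.data.shape[3]
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != c:
            raise SpectralIOError(
                f"expected {c} band wavelengths (one per band); got {len(np.atleast_1d(self.wavelengths))}"
            )
        if np.any(np.diff(self.wavelengths) <= 0):
            raise SpectralIOError("band wavelengths must be strictly increasing")
        if self.dtype_max <= 0:
            raise SpectralIOError("dtype_max must be positive")
        if np.any(self.data < 0):
            raise SpectralIOError("negative intensities in lambda stack")
        if np.any(self.data > self.dtype_max):
            raise SpectralIOError("intensities exceed dtype_max")

    @property
    def n_bands(self) -> int:
        return self.data.shape[3]

    @property
    def shape_zyx(self) -> tuple[int, int, int]:
        return self.data.shape[:3]


@dataclass
class PixelMatrix:
    """Flattened, normalized stack: the ``F`` of the linear mixing model F = S A."""

    F: np.ndarray  # (C, n), values in [0, 1]
    shape: tuple[int, int, int]  # original (Z, Y, X)
    wavelengths: np.ndarray
    dtype_max: int
    source_dtype: np.dtype
    name: str = "stack"

    @property
    def n_pixels(self) -> int:
        return self.F.shape[1]

    @property
    def n_bands(self) -> int:
        return self.F.shape[0]

    def unflatten(self, values: np.ndarray) -> np.ndarray:
        """Reshape a length-n (or m x n) array back onto (Z, Y, X) geometry."""
        values = np.asarray(values)
        if values.ndim == 1:
            return values.reshape(self.shape)
        return values.reshape((values.shape[0],) + self.shape)

    def denormalize(self) -> np.ndarray:
        """Invert :func:`normalize_stack`: back to (z, y, x, band) integer data."""
        data = np.rint(self.F.T * self.dtype_max)  # rint = round half to even
        data = np.clip(data, 0, self.dtype_max)
        z, y, x = self.shape
        return data.reshape(z, y, x, self.n_bands).astype(self.source_dtype)


@dataclass
class FingerprintTable:
    """Reference emission profiles ("fingerprints"), one unit-max column per label."""

    wavelengths: np.ndarray
    columns: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise SpectralIOError("fingerprint wavelengths must be strictly increasing")
        normed = {}
        for label, col in self.columns.items():
            col = np.asarray(col, dtype=float)
            if col.shape != self.wavelengths.shape:
                raise SpectralIOError(
                    f"fingerprint '{label}' has {col.size} entries, expected {self.wavelengths.size}"
                )
            peak = col.max()
            if peak <= 0:
                raise SpectralIOError(f"fingerprint '{label}' is all-zero")
            normed[label] = col / peak
        self.columns = normed

    @property
    def labels(self) -> list[str]:
        return list(self.columns)

    def as_matrix(self) -> np.ndarray:
        """C x k matrix in label order."""
        return np.column_stack([self.columns[l] for l in self.columns])

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"wavelength_nm": self.wavelengths, **self.columns})
        df.to_csv(path, index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def _dtype_saturation(dtype: np.dtype) -> int:
    dtype = np.dtype(dtype)
    if dtype.kind in "ui":
        return int(np.iinfo(dtype).max)
    raise SpectralIOError(f"cannot infer saturation value for dtype {dtype}; integer data expected")


def _parse_ome_wavelengths(ome_xml: str, n_bands: int) -> np.ndarray | None:
    try:
        root = ET.fromstring(ome_xml)
    except ET.ParseError:
        return None
    chans = root.iter(f"{{{_OME_NS}}}Channel")
    wl = []
    for ch in chans:
        v = ch.get("EmissionWavelength")
        if v is None:
            # fall back on names like "band-522nm"
            m = re.search(r"(\d+(?:\.\d+)?)\s*nm", ch.get("Name") or "")
            if not m:
                return None
            v = m.group(1)
        wl.append(float(v))
    if len(wl) != n_bands:
        return None
    return np.asarray(wl)


def read_lambda_stack(
    path: str | Path,
    wavelengths_override: np.ndarray | None = None,
    name: str | None = None,
) -> LambdaStack:
    """Read an OME-TIFF lambda stack into ``(z, y, x, band)`` order.

    Bands are re-ordered by increasing wavelength regardless of file-internal
    channel order; intensities are not modified.  ``wavelengths_override``
    replaces (or supplies, if the metadata lacks it) the per-band wavelengths.
    """
    path = Path(path)
    if path.suffix.lower() == ".czi":
        raise SpectralIOError(
            "CZI input requires an optional reader plug-in (aicsimageio/pylibCZIrw), "
            "which is not installed; convert to OME-TIFF"
        )
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        axes = series.axes.upper()
        arr = series.asarray()
        ome_xml = tf.ome_metadata

    if "T" in axes:
        t_size = arr.shape[axes.index("T")]
        if t_size != 1:
            raise SpectralIOError(f"multi-timepoint lambda stacks unsupported (T={t_size})")
        arr = np.take(arr, 0, axis=axes.index("T"))
        axes = axes.replace("T", "")
    # tolerate unlabeled page axes ('Q'/'I') from plain multi-page TIFFs
    for unk in "QI":
        if unk in axes:
            axes = axes.replace(unk, "C" if "C" not in axes else "Z")
    for ax in axes:
        if ax not in "ZYXC":
            raise SpectralIOError(f"unsupported axis '{ax}' in {path.name} (axes={axes})")
    for ax in "ZYXC":
        if ax not in axes:
            arr = arr[np.newaxis]
            axes = ax + axes
    order = [axes.index(ax) for ax in "ZYXC"]
    data = np.transpose(arr, order)
    c = data.shape[3]

    if wavelengths_override is not None:
        wavelengths = np.asarray(wavelengths_override, dtype=float)
        if wavelengths.size != c:
            raise SpectralIOError(
                f"wavelengths_override has {wavelengths.size} entries but stack has C={c} bands"
            )
    else:
        wavelengths = _parse_ome_wavelengths(ome_xml or "", c) if ome_xml else None
        if wavelengths is None:
            raise SpectralIOError(
                f"no per-band emission wavelengths in metadata of {path.name}; "
                f"pass wavelengths_override with {c} values"
            )

    sort = np.argsort(wavelengths, kind="stable")
    wavelengths = wavelengths[sort]
    data = data[..., sort]
    return LambdaStack(
        data=data,
        wavelengths=wavelengths,
        dtype_max=_dtype_saturation(data.dtype),
        name=name or path.name.replace(".ome.tif", "").replace(".tif", ""),
    )


def normalize_stack(stack: LambdaStack) -> PixelMatrix:
    """Divide by ``dtype_max`` and flatten to the C x n pixel matrix.

    The only pre-processing the pipeline applies.  All-zero stacks map to an
    all-zero matrix (no NaN); the mapping is inverted bit-exactly by
    :meth:`PixelMatrix.denormalize`.
    """
    z, y, x, c = stack.data.shape
    F = (stack.data.reshape(z * y * x, c).T / float(stack.dtype_max)).astype(np.float64)
    return PixelMatrix(
        F=F,
        shape=(z, y, x),
        wavelengths=stack.wavelengths.copy(),
        dtype_max=stack.dtype_max,
        source_dtype=stack.data.dtype,
        name=stack.name,
    )


def load_reference_spectra(path: str | Path) -> FingerprintTable:
    """Load a fingerprint CSV (``wavelength_nm,<label1>,<label2>,...``).

    Columns are renormalized to unit max (scale-invariant), wavelengths are
    sorted ascending; duplicate labels and all-zero columns are rejected.
    """
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise SpectralIOError("fingerprint CSV must have a 'wavelength_nm' column")
    labels = [c for c in df.columns if c != "wavelength_nm"]
    if len(labels) != len(set(labels)):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise SpectralIOError(f"duplicate fingerprint labels: {dupes}")
    # pandas mangles duplicate header names to 'x.1'; detect that too
    raw_header = Path(path).read_text().splitlines()[0].split(",")[1:]
    if len(raw_header) != len(set(raw_header)):
        dupes = sorted({l for l in raw_header if raw_header.count(l) > 1})
        raise SpectralIOError(f"duplicate fingerprint labels: {dupes}")
    order = np.argsort(df["wavelength_nm"].to_numpy(), kind="stable")
    df = df.iloc[order]
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise SpectralIOError("fingerprint wavelengths are not unique after sorting")
    return FingerprintTable(
        wavelengths=wl,
        columns={l: df[l].to_numpy(dtype=float) for l in raw_header},
    )


# ---------------------------------------------------------------------------
# OME-TIFF writing (deterministic)
# ---------------------------------------------------------------------------


def _ome_description(
    shape_zyx: tuple[int, int, int],
    n_channels: int,
    dtype: np.dtype,
    name: str,
    wavelengths: np.ndarray | None = None,
    channel_names: list[str] | None = None,
) -> str:
    z, y, x = shape_zyx
    dtype = np.dtype(dtype)
    type_name = {"u1": "uint8", "u2": "uint16", "u4": "uint32", "f4": "float", "f8": "double", "b1": "bit"}.get(
        dtype.str[1:], dtype.name
    )
    chans = []
    for i in range(n_channels):
        attrs = [f'ID="Channel:0:{i}"', 'SamplesPerPixel="1"']
        if channel_names is not None:
            attrs.append(f'Name="{channel_names[i]}"')
        if wavelengths is not None:
            attrs.append(f'EmissionWavelength="{wavelengths[i]:.10g}"')
            attrs.append('EmissionWavelengthUnit="nm"')
        chans.append(f'<Channel {" ".join(attrs)}/>')
    return (
        '<?xml version="1.0" encoding="UTF-8"?>'
        f'<OME xmlns="{_OME_NS}">'
        f'<Image ID="Image:0" Name="{name}">'
        f'<Pixels ID="Pixels:0" DimensionOrder="XYCZT" Type="{type_name}" '
        f'SizeX="{x}" SizeY="{y}" SizeC="{n_channels}" SizeZ="{z}" SizeT="1">'
        + "".join(chans)
        + f'<TiffData IFD="0" PlaneCount="{z * n_channels}"/>'
        "</Pixels></Image></OME>"
    )


def write_lambda_stack(stack: LambdaStack, path: str | Path) -> Path:
    """Write a lambda stack as a deterministic OME-TIFF (ZC pages of YX)."""
    path = Path(path)
    z, y, x, c = stack.data.shape
    pages = stack.data.transpose(0, 3, 1, 2).reshape(z * c, y, x)  # C fastest: XYCZT
    desc = _ome_description((z, y, x), c, stack.data.dtype, stack.name, wavelengths=stack.wavelengths)
    tifffile.imwrite(path, pages, description=desc, photometric="minisblack", metadata=None)
    return path


def write_channel_stack(
    data_zyx: np.ndarray, path: str | Path, name: str, channel_name: str
) -> Path:
    """Write a single-channel z-stack as a deterministic OME-TIFF."""
    path = Path(path)
    desc = _ome_description(
        data_zyx.shape, 1, data_zyx.dtype, name, channel_names=[channel_name]
    )
    tifffile.imwrite(path, data_zyx, description=desc, photometric="minisblack", metadata=None)
    return path


def write_outputs(result: "UnmixResult", out_dir: str | Path) -> dict[str, Path]:
    """Write the full artifact set for one unmixed stack.

    Per fluorophore channel one multi-page OME-TIFF (Z planes, original
    integer dtype), the endmember table as CSV, raw float abundance TIFFs, a
    metrics JSON when the result carries one, and a binary lipofuscin mask
    when a lipofuscin channel exists.  Filenames are a pure function of the
    stack name and channel labels; bytes are identical across reruns.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = result.name
    shape = result.abundances.shape
    written: dict[str, Path] = {}

    for label, chan in result.channels.items():
        if chan.shape != shape:
            raise SpectralIOError(
                f"channel '{label}' shape {chan.shape} does not match stack shape {shape}"
            )
        p = out_dir / f"{stem}_{label}.ome.tif"
        write_channel_stack(chan, p, stem, label)
        written[f"channel:{label}"] = p
        a = result.abundances.unflatten(label).astype(np.float32)
        pa = out_dir / f"{stem}_{label}_abundance.tif"
        tifffile.imwrite(pa, a, photometric="minisblack", metadata=None)
        written[f"abundance:{label}"] = pa

    pcsv = out_dir / f"{stem}_endmembers.csv"
    result.endmembers.to_table().to_csv(pcsv)
    written["endmembers"] = pcsv

    if result.metrics is not None:
        pj = out_dir / f"{stem}_metrics.json"
        pj.write_text(json.dumps(result.metrics.to_dict(), indent=2, sort_keys=True) + "\n")
        written["metrics"] = pj

    for label in result.channels:
        if label.lower() == "lipofuscin":
            mask = result.channels[label] > 0
            pm = out_dir / f"{stem}_{label}_mask.tif"
            tifffile.imwrite(pm, mask, photometric="minisblack", metadata=None)
            written["lipofuscin_mask"] = pm
    return written
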
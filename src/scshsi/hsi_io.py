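"""Reading and writing hyperspectral cubes, label masks and classification maps.

Two cube dialects are supported:

* **ENVI** — the de-facto standard for hyperspectral rasters: a plain-text
  ``.hdr`` header next to a flat binary payload, with band-sequential (BSQ),
  band-interleaved-by-line (BIL) or band-interleaved-by-pixel (BIP) layouts.
* **array-container** — a portable NumPy ``.npz`` archive carrying the data
  array plus a JSON header (band centers, name), convenient for pipelines
  that never touch ENVI tooling.

Label masks travel as PNG (one integer code per pixel) with an optional JSON
sidecar declaring class names and the unlabeled sentinel. Classification maps
are rendered to lossless PNG through an explicit class→RGB palette and can be
decoded back through the inverse palette, so a rendered map is a faithful
serialization of the predicted mask.

Conventions fixed here and relied on everywhere else: coordinates are 0-based
``(row, col)`` in row-major order, and cube intensities are promoted to
float64 at load.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "HyperspectralCube",
    "LabelMask",
    "FormatError",
    "CorruptionError",
    "read_cube",
    "write_cube",
    "read_label_mask",
    "write_label_mask",
    "write_classification_map",
    "read_classification_map",
]


class FormatError(ValueError):
    """The file is not in the expected on-disk format."""


class CorruptionError(ValueError):
    """Header and payload disagree (truncated or padded binary)."""


# ENVI numeric data-type codes <-> numpy dtypes.
_ENVI_DTYPES = {
    1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
    5: np.float64, 12: np.uint16, 13: np.uint32, 14: np.int64, 15: np.uint64,
}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass
class HyperspectralCube:
    """A hyperspectral raster of shape (rows M, cols N, bands B).

    Parameters
    ----------
    data:
        3-D array of reflectance/intensity values; promoted to float64.
    band_centers:
        Optional strictly increasing wavelengths (nm), one per band.
    name:
        Free-text identifier, e.g. a patient/image code.
    """

    data: np.ndarray
    band_centers: list[float] | None = None
    name: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"cube must be 3-D (M, N, B); got shape {self.data.shape}")
        if min(self.data.shape) < 1:
            raise ValueError(f"cube dims must all be >= 1; got {self.data.shape}")
        bad = ~np.isfinite(self.data)
        if bad.any():
            band = int(np.argwhere(bad)[0, 2])
            raise ValueError(f"cube contains non-finite values (first in band {band})")
        if self.band_centers is not None:
            self.band_centers = [float(w) for w in self.band_centers]
            if len(self.band_centers) != self.data.shape[2]:
                raise ValueError(
                    f"band_centers has {len(self.band_centers)} entries "
                    f"for {self.data.shape[2]} bands"
                )
            if np.any(np.diff(self.band_centers) <= 0):
                raise ValueError("band_centers must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]


@dataclass
class LabelMask:
    """Per-pixel integer class labels over an (M, N) grid.

    Class codes are ``1..C`` in the order of ``class_names``;
    ``unlabeled_value`` (default 0) marks pixels without ground truth.
    """

    labels: np.ndarray
    class_names: list[str] = field(default_factory=list)
    unlabeled_value: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(np.int64)
            if not np.array_equal(as_int, self.labels):
                raise ValueError("mask contains non-integer pixel values")
            self.labels = as_int
        self.labels = self.labels.astype(np.int64)
        if self.labels.ndim != 2:
            raise ValueError(f"mask must be 2-D; got shape {self.labels.shape}")
        codes = set(self.class_codes)
        if self.unlabeled_value in codes:
            raise ValueError("unlabeled_value collides with a class code")
        stray = set(np.unique(self.labels)) - codes - {self.unlabeled_value}
        if stray:
            coords = np.argwhere(np.isin(self.labels, list(stray)))[:5]
            raise ValueError(
                f"mask contains codes {sorted(stray)} outside the declared classes "
                f"(first offenders at {[tuple(c) for c in coords]})"
            )

    @property
    def class_codes(self) -> list[int]:
        return list(range(1, len(self.class_names) + 1))

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    def labeled_coords(self) -> np.ndarray:
        """(n, 2) array of (row, col) of labeled pixels, row-major order."""
        return np.argwhere(self.labels != self.unlabeled_value)

    def check_matches(self, cube: HyperspectralCube) -> None:
        if self.labels.shape != cube.data.shape[:2]:
            raise ValueError(
                f"mask shape {self.labels.shape} does not match "
                f"cube grid {cube.data.shape[:2]}"
            )


# ---------------------------------------------------------------------------
# ENVI dialect
# ---------------------------------------------------------------------------

def _parse_envi_header(text: str) -> dict:
    if not text.lstrip().lower().startswith("envi"):
        raise FormatError("missing 'ENVI' magic line in header")
    fields: dict[str, str] = {}
    buf = text.splitlines()[1:]
    i = 0
    while i < len(buf):
        line = buf[i].strip()
        i += 1
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        value = value.strip()
        if value.startswith("{") and not value.endswith("}"):
            while i < len(buf) and not value.endswith("}"):
                value += " " + buf[i].strip()
                i += 1
        fields[key.strip().lower()] = value
    return fields


def _write_envi_pair(cube: HyperspectralCube, path: Path, interleave: str) -> None:
    interleave = interleave.lower()
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unknown interleave {interleave!r}")
    M, N, B = cube.shape
    hdr = [
        "ENVI",
        f"description = {{{cube.name or path.stem}}}",
        f"samples = {N}",
        f"lines = {M}",
        f"bands = {B}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_ENVI_CODES[np.dtype(np.float64)]}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if cube.band_centers is not None:
        hdr.append("wavelength = {" + ", ".join(repr(w) for w in cube.band_centers) + "}")
    path.with_suffix(".hdr").write_text("\n".join(hdr) + "\n")
    # in-memory layout per interleave: bsq=(B,M,N), bil=(M,B,N), bip=(M,N,B)
    arr = {"bsq": cube.data.transpose(2, 0, 1),
           "bil": cube.data.transpose(0, 2, 1),
           "bip": cube.data}[interleave]
    arr.astype("<f8").tofile(path)


def _read_envi_pair(path: Path) -> HyperspectralCube:
    hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        hdr_path = Path(str(path) + ".hdr")
    if not hdr_path.exists():
        raise FormatError(f"no ENVI header found next to {path}")
    fields = _parse_envi_header(hdr_path.read_text())
    try:
        N = int(fields["samples"])
        M = int(fields["lines"])
        B = int(fields["bands"])
        code = int(fields["data type"])
    except KeyError as e:
        raise FormatError(f"ENVI header missing required field {e}") from e
    if code not in _ENVI_DTYPES:
        raise FormatError(f"unsupported ENVI data type code {code}")
    dtype = np.dtype(_ENVI_DTYPES[code])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields.get("interleave", "bsq").lower()
    offset = int(fields.get("header offset", "0"))
    raw = np.fromfile(path, dtype=dtype, offset=offset)
    if raw.size != M * N * B:
        raise CorruptionError(
            f"payload holds {raw.size} values but header declares "
            f"{M}x{N}x{B} = {M * N * B}"
        )
    if interleave == "bsq":
        data = raw.reshape(B, M, N).transpose(1, 2, 0)
    elif interleave == "bil":
        data = raw.reshape(M, B, N).transpose(0, 2, 1)
    elif interleave == "bip":
        data = raw.reshape(M, N, B)
    else:
        raise FormatError(f"unknown interleave {interleave!r}")
    band_centers = None
    if "wavelength" in fields:
        band_centers = [float(w) for w in fields["wavelength"].strip("{}").split(",")]
    return HyperspectralCube(
        data=np.ascontiguousarray(data, dtype=np.float64),
        band_centers=band_centers,
        name=fields.get("description", "").strip("{} "),
    )


# ---------------------------------------------------------------------------
# Array-container dialect (.npz with a JSON header)
# ---------------------------------------------------------------------------

def _write_container(cube: HyperspectralCube, path: Path) -> None:
    header = {"name": cube.name, "band_centers": cube.band_centers,
              "dims": list(cube.shape)}
    np.savez(path, data=cube.data, header=json.dumps(header))


def _read_container(path: Path) -> HyperspectralCube:
    with np.load(path, allow_pickle=False) as npz:
        if "data" not in npz or "header" not in npz:
            raise FormatError(f"{path} is not a cube container (missing data/header)")
        data = npz["data"]
        header = json.loads(str(npz["header"]))
    if list(data.shape) != header.get("dims", list(data.shape)):
        raise CorruptionError(
            f"container header declares dims {header['dims']} but payload is "
            f"{list(data.shape)}"
        )
    return HyperspectralCube(data=data, band_centers=header.get("band_centers"),
                             name=header.get("name", ""))


def write_cube(cube: HyperspectralCube, path: str | Path,
               format: str | None = None, interleave: str = "bsq") -> Path:
    """Write a cube as an ENVI pair or an ``.npz`` array-container.

    ``format`` is inferred from the extension when omitted (``.npz`` →
    container, anything else → ENVI).
    """
    path = Path(path)
    if format is None:
        format = "array-container" if path.suffix == ".npz" else "envi"
    if format == "envi":
        _write_envi_pair(cube, path, interleave)
    elif format == "array-container":
        _write_container(cube, path)
    else:
        raise ValueError(f"unknown cube format {format!r}")
    return path


def read_cube(path: str | Path, format: str | None = None) -> HyperspectralCube:
    """Read a hyperspectral cube; values are promoted to float64.

    Raises :class:`FormatError` for a missing/bad header,
    :class:`CorruptionError` when header dims and payload size disagree, and
    ``ValueError`` when the payload contains NaN/Inf.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "array-container" if path.suffix == ".npz" else "envi"
    if format == "envi":
        return _read_envi_pair(path)
    if format == "array-container":
        return _read_container(path)
    raise ValueError(f"unknown cube format {format!r}")


# ---------------------------------------------------------------------------
# Label masks
# ---------------------------------------------------------------------------

def write_label_mask(mask: LabelMask, path: str | Path) -> Path:
    """Write a mask as a 16-bit PNG plus a JSON sidecar with class names."""
    path = Path(path)
    if mask.labels.min() < 0 or mask.labels.max() > 65535:
        raise ValueError("PNG mask codes must fit in uint16")
    Image.fromarray(mask.labels.astype(np.uint16)).save(path, format="PNG")
    sidecar = {"class_names": mask.class_names,
               "unlabeled_value": int(mask.unlabeled_value)}
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))
    return path


def read_label_mask(path: str | Path, class_names: list[str] | None = None,
                    unlabeled_value: int | None = None,
                    strict: bool = True) -> LabelMask:
    """Read an integer label mask from PNG (or ``.npy``).

    Class names come from the JSON sidecar when present, else from
    ``class_names``. In strict mode (default) codes outside the declared set
    raise with the offending coordinates; otherwise they are remapped to the
    unlabeled sentinel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npy":
        labels = np.load(path)
    else:
        try:
            labels = np.asarray(Image.open(path))
        except Exception as e:  # noqa: BLE001 - PIL raises many types
            raise FormatError(f"cannot read mask raster {path}: {e}") from e
    if labels.ndim != 2:
        raise FormatError(f"mask raster must be single-channel 2-D; got {labels.shape}")
    if not np.issubdtype(labels.dtype, np.integer):
        if not np.array_equal(labels, labels.astype(np.int64)):
            raise ValueError("mask contains non-integer pixel values")
        labels = labels.astype(np.int64)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        class_names = class_names or sidecar.get("class_names")
        if unlabeled_value is None:
            unlabeled_value = sidecar.get("unlabeled_value", 0)
    if unlabeled_value is None:
        unlabeled_value = 0
    if class_names is None:
        codes = sorted(set(np.unique(labels)) - {unlabeled_value})
        if codes != list(range(1, len(codes) + 1)):
            raise ValueError(
                f"mask codes {codes} are not contiguous 1..C and no class names "
                "were declared"
            )
        class_names = [f"class_{c}" for c in codes]
    declared = set(range(1, len(class_names) + 1)) | {unlabeled_value}
    stray = set(np.unique(labels)) - declared
    if stray:
        if strict:
            coords = np.argwhere(np.isin(labels, list(stray)))[:5]
            raise ValueError(
                f"mask contains undeclared codes {sorted(stray)} "
                f"(first offenders at {[tuple(map(int, c)) for c in coords]})"
            )
        labels = np.where(np.isin(labels, list(stray)), unlabeled_value, labels)
    return LabelMask(labels=labels, class_names=list(class_names),
                     unlabeled_value=int(unlabeled_value))


# ---------------------------------------------------------------------------
# Classification maps
# ---------------------------------------------------------------------------

def _resolve_palette(mask: LabelMask, palette: dict) -> dict[int, tuple[int, int, int]]:
    """Accept class names or integer codes as palette keys; return code->RGB."""
    by_code: dict[int, tuple[int, int, int]] = {}
    for key, rgb in palette.items():
        if isinstance(key, str):
            if key not in mask.class_names:
                continue  # entries for classes the mask does not declare are inert
            code = mask.class_names.index(key) + 1
        else:
            code = int(key)
        by_code[code] = tuple(int(v) for v in rgb)
    return by_code


def write_classification_map(mask: LabelMask, palette: dict, path: str | Path,
                             background: tuple[int, int, int] = (0, 0, 0)) -> Path:
    """Render a predicted mask to a lossless PNG, one pixel per grid cell.

    ``palette`` maps class name or code to an RGB triple; unlabeled pixels get
    ``background``. A class present in the mask without a palette entry is an
    error (never silently colored).
    """
    path = Path(path)
    by_code = _resolve_palette(mask, palette)
    present = set(np.unique(mask.labels)) - {mask.unlabeled_value}
    missing = present - set(by_code)
    if missing:
        names = [mask.class_names[c - 1] if 1 <= c <= mask.n_classes else str(c)
                 for c in sorted(missing)]
        raise ValueError(f"palette has no entry for class(es): {', '.join(names)}")
    lut = np.zeros((max([mask.unlabeled_value, *by_code], default=0) + 1, 3), np.uint8)
    lut[mask.unlabeled_value] = background
    for code, rgb in by_code.items():
        lut[code] = rgb
    Image.fromarray(lut[mask.labels]).save(path, format="PNG")
    return path


def read_classification_map(path: str | Path, palette: dict,
                            class_names: list[str],
                            background: tuple[int, int, int] = (0, 0, 0),
                            unlabeled_value: int = 0) -> LabelMask:
    """Decode a rendered map back to a LabelMask through the inverse palette."""
    rgb = np.asarray(Image.open(path).convert("RGB"))
    ref = LabelMask(labels=np.zeros(rgb.shape[:2], np.int64),
                    class_names=list(class_names), unlabeled_value=unlabeled_value)
    inverse = {tuple(v): c for c, v in _resolve_palette(ref, palette).items()}
    if tuple(background) in inverse and inverse[tuple(background)] != unlabeled_value:
        warnings.warn("background color collides with a class color")
    inverse.setdefault(tuple(background), unlabeled_value)
    labels = np.full(rgb.shape[:2], -1, np.int64)
    for color, code in inverse.items():
        labels[np.all(rgb == np.array(color, np.uint8), axis=-1)] = code
    if (labels == -1).any():
        coord = tuple(map(int, np.argwhere(labels == -1)[0]))
        raise ValueError(f"pixel {coord} has a color outside the palette")
    return LabelMask(labels=labels, class_names=list(class_names),
                     unlabeled_value=unlabeled_value)
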
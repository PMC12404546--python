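"""Color deconvolution for brightfield IHC images.

Transmitted-light RGB images of stained tissue are converted to optical
density (OD), where the Lambert-Beer law makes pixel values linear in stain
concentration.  A 3x3 stain matrix (one unit OD vector per dye) is inverted
to unmix each pixel into per-stain concentrations; the DAB channel,
normalized to [0, 1], is the "color anomaly map" used as the classifier's
prior input.

Conventions
-----------
Stain matrices are stored row-per-stain: row *i* holds the (R, G, B) optical
densities of dye *i*.  Unmixing uses the column-vector form ``C = D @ y``
with ``D = inv(M.T)``; this is the layout in which the classical
hematoxylin-eosin-DAB deconvolution matrix is usually printed, and
:data:`HED_DECONV` reproduces it entrywise.  For an image with OD pixels as
rows the same operation reads ``C = od @ D.T``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import yaml

__all__ = [
    "StainProfile",
    "StainMatrix",
    "DeconvolutionMatrix",
    "ODImage",
    "ConcentrationMap",
    "AnomalyMap",
    "rgb_to_od",
    "od_to_rgb",
    "normalize_stain_matrix",
    "complete_two_stain_matrix",
    "deconvolution_matrix",
    "separate_stains",
    "dab_anomaly_map",
    "anomaly_map_from_rgb",
    "rerender_stain_rgb",
    "load_stain_matrix",
    "HED_RAW",
    "HED_NORMALIZED",
    "HED_DECONV",
    "HD_RAW",
    "DEFAULT_INCIDENT_INTENSITY",
    "OD_CLAMP_GREY",
]

#: incident light intensity I_0 for 8-bit brightfield images (white = 255)
DEFAULT_INCIDENT_INTENSITY = 255.0

#: transmitted intensities are clamped to one grey level before the log so
#: OD stays finite (max OD = log10(255) ~ 2.41)
OD_CLAMP_GREY = 1.0

_NORM_ATOL = 1e-6


class DegenerateStainError(ValueError):
    """A stain matrix row is zero, parallel to another, or not invertible."""


@dataclass(frozen=True)
class StainProfile:
    """A named dye with its per-channel (R, G, B) optical densities.

    Physical dyes have nonnegative OD components; a synthesized residual
    channel (``is_residual=True``) may carry negative components, since it
    is an algebraic completion rather than a dye.
    """

    name: str
    od: np.ndarray
    is_residual: bool = False

    def __post_init__(self) -> None:
        od = np.asarray(self.od, dtype=float)
        if od.shape != (3,):
            raise ValueError(f"stain OD vector must have shape (3,), got {od.shape}")
        if not self.is_residual and np.any(od < 0):
            raise ValueError(f"stain {self.name!r} has negative OD components")
        object.__setattr__(self, "od", od)

    @property
    def is_normalized(self) -> bool:
        return abs(float(np.linalg.norm(self.od)) - 1.0) <= _NORM_ATOL

    def normalized(self) -> "StainProfile":
        norm = float(np.linalg.norm(self.od))
        if norm == 0.0:
            raise DegenerateStainError(f"stain {self.name!r} has a zero OD vector")
        return replace(self, od=self.od / norm)


@dataclass(frozen=True)
class StainMatrix:
    """Ordered triple of stain profiles; rows of the 3x3 OD mixing matrix."""

    profiles: tuple[StainProfile, StainProfile, StainProfile]
    normalized: bool = False

    def __post_init__(self) -> None:
        profiles = tuple(self.profiles)
        if len(profiles) != 3:
            raise ValueError("a StainMatrix needs exactly 3 profiles")
        object.__setattr__(self, "profiles", profiles)
        if self.normalized:
            for p in profiles:
                if not p.is_normalized:
                    raise ValueError(
                        f"matrix marked normalized but row {p.name!r} has norm "
                        f"{np.linalg.norm(p.od):.6f}"
                    )

    @property
    def matrix(self) -> np.ndarray:
        return np.stack([p.od for p in self.profiles])

    @property
    def stain_names(self) -> tuple[str, str, str]:
        return tuple(p.name for p in self.profiles)

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    @classmethod
    def from_array(
        cls, rows: np.ndarray, names: tuple[str, str, str], normalized: bool = False
    ) -> "StainMatrix":
        rows = np.asarray(rows, dtype=float)
        if rows.shape != (3, 3):
            raise ValueError(f"expected a 3x3 array, got {rows.shape}")
        profiles = tuple(StainProfile(n, r) for n, r in zip(names, rows))
        return cls(profiles, normalized=normalized)


@dataclass(frozen=True)
class DeconvolutionMatrix:
    """Inverse stain matrix in column-vector layout (``C = d @ y``)."""

    d: np.ndarray
    source: StainMatrix

    @property
    def stain_names(self) -> tuple[str, str, str]:
        return self.source.stain_names


@dataclass(frozen=True)
class ODImage:
    """Per-pixel optical density, H x W x 3, nonnegative and finite."""

    od: np.ndarray
    incident_intensity: float = DEFAULT_INCIDENT_INTENSITY

    def __post_init__(self) -> None:
        od = np.asarray(self.od, dtype=float)
        if od.ndim != 3 or od.shape[-1] != 3:
            raise ValueError(f"OD array must be HxWx3, got {od.shape}")
        if not np.all(np.isfinite(od)):
            raise ValueError("OD array contains non-finite values")
        object.__setattr__(self, "od", od)


@dataclass(frozen=True)
class ConcentrationMap:
    """Per-pixel stain concentrations (may be negative from unmixing noise)."""

    conc: np.ndarray
    stain_order: tuple[str, str, str]

    def channel(self, stain: str) -> np.ndarray:
        try:
            idx = self.stain_order.index(stain)
        except ValueError:
            raise KeyError(
                f"stain {stain!r} not among {self.stain_order}"
            ) from None
        return self.conc[..., idx]


@dataclass(frozen=True)
class AnomalyMap:
    """Single-channel DAB prior map, values in [0, 1]."""

    map: np.ndarray
    stain: str = "dab"
    saturation_od: float = 1.0

    def to_uint8(self) -> np.ndarray:
        return np.rint(255.0 * self.map).astype(np.uint8)

    def save(self, path: str) -> str:
        """Write the map as an 8-bit grayscale PNG (value = round(255*map))."""
        from PIL import Image

        Image.fromarray(self.to_uint8(), mode="L").save(path)
        return path


# ---------------------------------------------------------------------------
# published stain vectors (hematoxylin / eosin / DAB)
# ---------------------------------------------------------------------------

#: raw measured OD matrix for H, E and DAB (Ruifrok-style single-dye slides)
HED_RAW = StainMatrix.from_array(
    np.array([[0.18, 0.20, 0.08], [0.01, 0.13, 0.01], [0.10, 0.21, 0.29]]),
    ("hematoxylin", "eosin", "dab"),
)

#: the classical unit-norm H-E-DAB matrix (from unrounded source measurements;
#: not exactly the row-normalization of :data:`HED_RAW` -- entries differ by
#: up to ~0.03 because the raw matrix above is printed to 2 decimals)
HED_NORMALIZED = StainMatrix.from_array(
    np.array([[0.65, 0.70, 0.29], [0.07, 0.99, 0.11], [0.27, 0.57, 0.78]]),
    ("hematoxylin", "eosin", "dab"),
    normalized=False,  # printed to 2 dp; rows have norm 1 +- 5e-3, see tests
)

#: the classical printed H-E-DAB deconvolution matrix: inv(HED_NORMALIZED.T)
#: rounded to 2 decimals
HED_DECONV = np.array(
    [[1.88, -0.07, -0.60], [-1.02, 1.13, -0.48], [-0.55, -0.13, 1.57]]
)

#: raw two-stain matrix for hematoxylin + DAB slides (no eosin)
HD_RAW = (
    StainProfile("hematoxylin", np.array([0.18, 0.20, 0.08])),
    StainProfile("dab", np.array([0.10, 0.21, 0.29])),
)


# ---------------------------------------------------------------------------
# RGB <-> OD
# ---------------------------------------------------------------------------

def rgb_to_od(
    image: np.ndarray,
    incident_intensity: float = DEFAULT_INCIDENT_INTENSITY,
) -> ODImage:
    """Convert a transmitted-light RGB image to optical density.

    ``OD_c = -log10(max(I_c, eps) / I_0)`` per channel, with ``eps`` one grey
    level so fully absorbed pixels stay finite.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected an HxWx3 image, got shape {image.shape}")
    if incident_intensity <= 0:
        raise ValueError("incident_intensity must be positive")
    transmitted = np.clip(image.astype(float), OD_CLAMP_GREY, None)
    od = -np.log10(transmitted / incident_intensity)
    od = np.clip(od, 0.0, None)  # pixels brighter than I_0 carry no stain
    return ODImage(od=od, incident_intensity=incident_intensity)


def od_to_rgb(od: ODImage | np.ndarray, incident_intensity: float | None = None) -> np.ndarray:
    """Render optical density back to an 8-bit RGB image.

    ``I_c = I_0 * 10**(-OD_c)``, rounded half-up and clipped to [0, 255].
    Inverse of :func:`rgb_to_od` to within one grey level for inputs >= 1.
    """
    if isinstance(od, ODImage):
        arr = od.od
        i0 = od.incident_intensity if incident_intensity is None else incident_intensity
    else:
        arr = np.asarray(od, dtype=float)
        i0 = DEFAULT_INCIDENT_INTENSITY if incident_intensity is None else incident_intensity
    if np.any(arr < 0):
        raise ValueError("optical density must be nonnegative")
    intensity = i0 * np.power(10.0, -arr)
    # round half-up (np.rint rounds half-to-even)
    return np.clip(np.floor(intensity + 0.5), 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# stain matrix construction
# ---------------------------------------------------------------------------

def normalize_stain_matrix(raw: StainMatrix) -> StainMatrix:
    """Divide every stain row by its Euclidean norm (unit OD vectors)."""
    profiles = tuple(p.normalized() for p in raw.profiles)
    return StainMatrix(profiles, normalized=True)


def complete_two_stain_matrix(
    two_rows: tuple[StainProfile, StainProfile] | list[StainProfile],
    residual_name: str = "residual",
) -> StainMatrix:
    """Extend a two-stain matrix to an invertible 3x3 one.

    The third row is the unit cross product of the two normalized rows —
    the standard residual-channel construction for two-dye slides (as in
    skimage's H-DAB matrices).  The residual is orthogonal to both dyes, so
    it absorbs only color variation outside their span; it may carry
    negative components because it is algebraic, not a physical dye.
    """
    if len(two_rows) != 2:
        raise ValueError("expected exactly 2 stain profiles")
    a = two_rows[0].normalized()
    b = two_rows[1].normalized()
    cross = np.cross(a.od, b.od)
    norm = float(np.linalg.norm(cross))
    if norm < 1e-8:
        raise DegenerateStainError(
            f"stains {a.name!r} and {b.name!r} are parallel; cannot complete"
        )
    third = StainProfile(residual_name, cross / norm, is_residual=True)
    return StainMatrix((a, b, third), normalized=True)


def deconvolution_matrix(
    m_hat: StainMatrix, max_condition: float = 1e8
) -> DeconvolutionMatrix:
    """Invert a stain matrix into its color-deconvolution matrix.

    Returns ``D = inv(M.T)`` (column-vector layout, matching the classical
    printed H-E-DAB matrix); composing ``D`` with ``M.T`` gives the identity.
    """
    m = m_hat.matrix
    cond = float(np.linalg.cond(m))
    if not np.isfinite(cond) or cond > max_condition:
        raise DegenerateStainError(
            f"stain matrix is singular or ill-conditioned (cond={cond:.3g})"
        )
    d = np.linalg.inv(m.T)
    return DeconvolutionMatrix(d=d, source=m_hat)


def separate_stains(od: ODImage, d: DeconvolutionMatrix) -> ConcentrationMap:
    """Unmix an OD image into per-pixel stain concentrations ``C = D @ y``."""
    arr = od.od
    if arr.shape[-1] != d.d.shape[1]:
        raise ValueError(
            f"OD channels ({arr.shape[-1]}) do not match matrix ({d.d.shape[1]})"
        )
    conc = arr @ d.d.T
    return ConcentrationMap(conc=conc, stain_order=d.stain_names)


def dab_anomaly_map(
    conc: ConcentrationMap,
    stain: str = "dab",
    saturation_od: float = 1.0,
) -> AnomalyMap:
    """Normalize one stain's concentration channel into a [0, 1] prior map.

    Concentrations are clipped below at 0 (unmixing noise) and saturate at
    ``saturation_od``, the concentration rendered as full intensity.
    """
    if saturation_od <= 0:
        raise ValueError("saturation_od must be positive")
    channel = conc.channel(stain)
    map_ = np.clip(channel, 0.0, saturation_od) / saturation_od
    return AnomalyMap(map=map_, stain=stain, saturation_od=saturation_od)


def anomaly_map_from_rgb(
    image: np.ndarray,
    stain_matrix: StainMatrix | None = None,
    stain: str = "dab",
    saturation_od: float = 1.0,
    incident_intensity: float = DEFAULT_INCIDENT_INTENSITY,
) -> AnomalyMap:
    """RGB patch -> DAB anomaly map in one call (the CD prior pipeline).

    Defaults to the two-stain hematoxylin+DAB matrix completed with a
    residual channel, which is the chemistry of CD34 IHC slides.
    """
    if stain_matrix is None:
        stain_matrix = complete_two_stain_matrix(HD_RAW)
    od = rgb_to_od(image, incident_intensity)
    d = deconvolution_matrix(stain_matrix)
    conc = separate_stains(od, d)
    return dab_anomaly_map(conc, stain=stain, saturation_od=saturation_od)


def rerender_stain_rgb(
    conc: ConcentrationMap,
    stain: str,
    stain_matrix: StainMatrix,
    incident_intensity: float = DEFAULT_INCIDENT_INTENSITY,
) -> np.ndarray:
    """Re-render a single unmixed stain as an RGB image (visualization only)."""
    idx = conc.stain_order.index(stain)
    channel = np.clip(conc.channel(stain), 0.0, None)
    od = channel[..., None] * stain_matrix.matrix[idx]
    return od_to_rgb(od, incident_intensity)


def read_image(path: str) -> np.ndarray:
    """Read an 8-bit RGB image (PNG/TIFF/JPEG) as an HxWx3 uint8 array."""
    from PIL import Image

    return np.asarray(Image.open(path).convert("RGB"))


def load_stain_matrix(path: str) -> StainMatrix:
    """Load a stain matrix from a small YAML or CSV file.

    YAML layout::

        stains:
          - {name: hematoxylin, od: [0.18, 0.20, 0.08]}
          - {name: dab, od: [0.10, 0.21, 0.29]}
        normalized: false

    CSV layout: columns ``name, r, g, b`` (one row per stain), with an
    optional trailing all-``normalized`` marker omitted.  Two entries are
    completed with a residual row; three are used as-is.
    """
    if path.endswith(".csv"):
        import pandas as pd

        df = pd.read_csv(path)
        profiles = [
            StainProfile(str(row["name"]), np.array([row["r"], row["g"], row["b"]], float))
            for _, row in df.iterrows()
        ]
        normalized = False
    else:
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        profiles = [
            StainProfile(s["name"], np.asarray(s["od"], float)) for s in spec["stains"]
        ]
        normalized = bool(spec.get("normalized", False))
    if len(profiles) == 2:
        return complete_two_stain_matrix(tuple(profiles))
    if len(profiles) != 3:
        raise ValueError(f"expected 2 or 3 stains, got {len(profiles)}")
    rows = np.stack([p.od for p in profiles])
    names = tuple(p.name for p in profiles)
    return StainMatrix.from_array(rows, names, normalized=normalized)
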
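"""Capsid morphometrics: cavity volume, genome-packing regression, lengths.

The internal cavity of a cylindrical nucleocapsid is modelled as a
cylinder (volume pi r^2 h); volumes are reported in units of 1e4 nm^3, the
convention used when relating capsid internal volume to packaged genome
size. The packing model is an ordinary least-squares line through
reference (genome size kbp, internal volume 1e4 nm^3) points for capsids
of known content — e.g. tailed-bacteriophage capsids — from which a
kbp-per-volume ratio and genome-size predictions follow. Particle-length
distributions are summarised as half-open histograms with a 5-nm default
bin width.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CylinderSpec",
    "PackingModel",
    "VOLUME_UNIT_NM3",
    "cylinder_volume",
    "cylinder_volume_nm3",
    "fit_packing_model",
    "predict_genome_size",
    "length_histogram",
]

#: Volumes are reported in multiples of this many nm^3.
VOLUME_UNIT_NM3 = 1.0e4

ANGSTROM_PER_NM = 10.0


@dataclasses.dataclass(frozen=True)
class CylinderSpec:
    """Internal cavity dimensions. ``radius``/``length`` in nm by default;
    pass ``unit='angstrom'`` to supply Å (converted on construction)."""

    radius: float
    length: float
    unit: str = "nm"

    def __post_init__(self) -> None:
        if self.radius < 0 or self.length < 0:
            raise ValueError("radius and length must be non-negative")
        if self.unit not in ("nm", "angstrom"):
            raise ValueError("unit must be 'nm' or 'angstrom'")
        if self.unit == "angstrom":
            object.__setattr__(self, "radius", self.radius / ANGSTROM_PER_NM)
            object.__setattr__(self, "length", self.length / ANGSTROM_PER_NM)
            object.__setattr__(self, "unit", "nm")


def cylinder_volume_nm3(spec: CylinderSpec) -> float:
    """Full-precision cylinder volume pi r^2 h in nm^3."""
    return float(np.pi * spec.radius ** 2 * spec.length)


def cylinder_volume(spec: CylinderSpec) -> float:
    """Cylinder volume in units of 1e4 nm^3 (the reporting convention)."""
    return cylinder_volume_nm3(spec) / VOLUME_UNIT_NM3


@dataclasses.dataclass
class PackingModel:
    """OLS line relating genome size (kbp) to internal volume (1e4 nm^3)."""

    reference: pd.DataFrame  # columns: genome_kbp, volume_1e4nm3
    slope: float  # kbp per 1e4 nm^3
    intercept: float  # kbp
    residuals: np.ndarray
    r_value: float

    @property
    def kbp_per_volume_unit(self) -> float:
        """Packing ratio: kbp of dsDNA per 1e4 nm^3 of internal volume."""
        return self.slope


def fit_packing_model(reference_points: Sequence[tuple[float, float]]
                      | pd.DataFrame) -> PackingModel:
    """Fit genome size against internal volume by ordinary least squares.

    ``reference_points`` are (genome size kbp, internal volume 1e4 nm^3)
    pairs — volume is the regressor, genome size the response, so the slope
    is the packing ratio in kbp per 1e4 nm^3.
    """
    if isinstance(reference_points, pd.DataFrame):
        df = reference_points.rename(columns=lambda c: str(c))
        kbp = df.iloc[:, 0].to_numpy(float)
        vol = df.iloc[:, 1].to_numpy(float)
    else:
        arr = np.asarray(reference_points, float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("reference points must be (kbp, volume) pairs")
        kbp, vol = arr[:, 0], arr[:, 1]
    if len(kbp) < 2:
        raise ValueError("need at least 2 reference points")
    if np.ptp(vol) == 0:
        raise ValueError("singular fit: all reference volumes identical")
    fit = stats.linregress(vol, kbp)
    resid = kbp - (fit.slope * vol + fit.intercept)
    ref = pd.DataFrame({"genome_kbp": kbp, "volume_1e4nm3": vol})
    return PackingModel(ref, float(fit.slope), float(fit.intercept), resid,
                        float(fit.rvalue))


def predict_genome_size(model: PackingModel, volume: float) -> float:
    """Predicted packaged genome size (kbp) for a volume in 1e4 nm^3."""
    return model.slope * volume + model.intercept


def length_histogram(lengths: Sequence[float], bin_width: float = 5.0,
                     ) -> pd.DataFrame:
    """Bin particle lengths (nm) into half-open bins [k*w, (k+1)*w).

    Returns a table of (bin_start, bin_end, count) covering exactly the
    occupied range; counts sum to the number of inputs.
    """
    lengths = np.asarray(list(lengths), float)
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    if len(lengths) and lengths.min() < 0:
        raise ValueError("lengths must be non-negative")
    if len(lengths) == 0:
        return pd.DataFrame(columns=["bin_start", "bin_end", "count"])
    k = np.floor(lengths / bin_width).astype(int)
    counts = np.bincount(k - k.min())
    starts = (np.arange(k.min(), k.max() + 1)) * bin_width
    return pd.DataFrame({"bin_start": starts, "bin_end": starts + bin_width,
                         "count": counts})
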
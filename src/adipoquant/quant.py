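"""Depot quantification: volumes, masses, pre/post change and overlap scores.

Fat volume is voxel count times voxel volume; fat mass follows from the
adipose tissue density of ~0.9 g/ml.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import DepotLabelVolume, LABEL_CODES

#: Adipose tissue density in g/ml.
ADIPOSE_DENSITY_G_PER_ML = 0.9


@dataclass
class QuantReport:
    """Per-depot volumes (ml) and masses (g) with a per-slice breakdown.

    ``per_slice`` holds one row per slice with SAT/VAT voxel counts and
    areas (mm²); slice areas times the slice thickness sum to the volumes.
    """

    sat_volume_ml: float
    vat_volume_ml: float
    sat_mass_g: float
    vat_mass_g: float
    per_slice: pd.DataFrame
    density_g_per_ml: float

    def to_csv(self, path) -> None:
        """Write the per-slice table plus a summary row."""
        df = self.per_slice.copy()
        summary = pd.DataFrame(
            [
                {
                    "slice": "total",
                    "sat_voxels": df["sat_voxels"].sum(),
                    "vat_voxels": df["vat_voxels"].sum(),
                    "sat_area_mm2": df["sat_area_mm2"].sum(),
                    "vat_area_mm2": df["vat_area_mm2"].sum(),
                    "sat_volume_ml": self.sat_volume_ml,
                    "vat_volume_ml": self.vat_volume_ml,
                    "sat_mass_g": self.sat_mass_g,
                    "vat_mass_g": self.vat_mass_g,
                }
            ]
        )
        pd.concat([df, summary], ignore_index=True).to_csv(path, index=False)


def quantify(
    labels: DepotLabelVolume, density: float = ADIPOSE_DENSITY_G_PER_ML
) -> QuantReport:
    """Compute SAT/VAT volumes and masses from a label volume.

    volume (ml) = voxel count × row spacing × col spacing × thickness / 1000,
    mass (g) = density × volume.
    """
    if density <= 0:
        raise ValidationError("density must be > 0")
    sp_r, sp_c = labels.in_plane_spacing
    thick = labels.slice_thickness
    pixel_area_mm2 = sp_r * sp_c
    voxel_ml = pixel_area_mm2 * thick / 1000.0

    rows = []
    for s in range(labels.n_slices):
        sl = labels.labels[:, :, s]
        n_sat = int(np.count_nonzero(sl == LABEL_CODES["sat"]))
        n_vat = int(np.count_nonzero(sl == LABEL_CODES["vat"]))
        rows.append(
            {
                "slice": s,
                "sat_voxels": n_sat,
                "vat_voxels": n_vat,
                "sat_area_mm2": n_sat * pixel_area_mm2,
                "vat_area_mm2": n_vat * pixel_area_mm2,
            }
        )
    per_slice = pd.DataFrame(rows)
    sat_vol = float(per_slice["sat_voxels"].sum() * voxel_ml)
    vat_vol = float(per_slice["vat_voxels"].sum() * voxel_ml)
    return QuantReport(
        sat_volume_ml=sat_vol,
        vat_volume_ml=vat_vol,
        sat_mass_g=density * sat_vol,
        vat_mass_g=density * vat_vol,
        per_slice=per_slice,
        density_g_per_ml=density,
    )


def percent_change(pre: QuantReport, post: QuantReport) -> dict[str, float]:
    """Per-depot percent change 100 × (post − pre) / pre between two scans."""
    out: dict[str, float] = {}
    for depot in ("sat", "vat"):
        pre_v = getattr(pre, f"{depot}_volume_ml")
        post_v = getattr(post, f"{depot}_volume_ml")
        if pre_v == 0:
            raise ValidationError(
                f"percent change undefined: pre-scan {depot.upper()} volume is zero"
            )
        out[depot] = 100.0 * (post_v - pre_v) / pre_v
    return out


def dice(pred, truth) -> float | dict[str, float]:
    """Dice overlap 2|A∩B| / (|A|+|B|).

    Boolean masks give a single score; two label volumes give a per-depot
    dict for SAT and VAT. Empty-vs-empty is defined as 1.
    """
    if isinstance(pred, DepotLabelVolume) and isinstance(truth, DepotLabelVolume):
        if pred.labels.shape != truth.labels.shape:
            raise ValidationError("label volume shapes differ")
        return {
            depot: dice(pred.mask(depot), truth.mask(depot))
            for depot in ("sat", "vat")
        }
    a = np.asarray(pred, dtype=bool)
    b = np.asarray(truth, dtype=bool)
    if a.shape != b.shape:
        raise ValidationError("mask shapes differ")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.count_nonzero(a & b) / denom)
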
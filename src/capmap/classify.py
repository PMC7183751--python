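"""Binary cold-air-pooling (frost-risk) classification.

A cell is classified CAP-prone when all three strict inequalities hold:

* slope < ``slope_max_deg``         (calibrated: 10 degrees)
* rank elevation < ``rank_max``     (calibrated: 0.30, the lower third of
  the valley)
* broad curvature < ``curv_max``    (0: the cell sits in a depression at
  the valley scale)

The calibrated thresholds target the South African sub-escarpment lowlands,
where nocturnal temperature gradients are gentler than in the high-latitude,
high-elevation terrain the original snow-model thresholds (slope < 30
degrees, rank < 50%) were developed for; those originals remain available
as the ``"lundquist"`` preset and produce a superset of the calibrated mask.

Because thresholds are strict, boundary-valued cells (slope exactly at the
maximum, curvature exactly 0) are frost-free — in particular an infinite
flat plane (rank 0.5, curvature 0) is never classified CAP: the model is
meaningful in complex terrain only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import DEMGrid
from .terrain import TerrainDerivatives, compute_derivatives

__all__ = [
    "TerrainThresholds",
    "CAPMask",
    "AgreementReport",
    "classify_cap",
    "run_cap_model",
    "boundary_agreement",
    "sweep_thresholds",
    "PRESETS",
]

logger = logging.getLogger("capmap")

#: nodata code in the 8-bit mask raster
MASK_NODATA = 255


@dataclass(frozen=True)
class TerrainThresholds:
    """Strict upper bounds on the three terrain derivatives."""

    slope_max_deg: float = 10.0
    rank_max: float = 0.30
    curv_max: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.slope_max_deg < 90):
            raise ValueError("slope_max_deg must be in (0, 90)")
        if not (0 < self.rank_max <= 1):
            raise ValueError("rank_max must be in (0, 1]")


#: calibrated sub-escarpment thresholds and the original snow-model ones
PRESETS: dict[str, TerrainThresholds] = {
    "calibrated": TerrainThresholds(10.0, 0.30, 0.0),
    "lundquist": TerrainThresholds(30.0, 0.50, 0.0),
}


@dataclass
class CAPMask:
    """Binary frost-risk raster: 1 = CAP-prone, 0 = frost-free.

    ``mask`` is uint8 with :data:`MASK_NODATA` where any input derivative
    was nodata; georeference mirrors the source DEM.  ``provenance``
    records the thresholds and radius that produced the mask.
    """

    mask: np.ndarray
    cell_size_m: float
    origin: tuple[float, float]
    crs_tag: str
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=np.uint8)
        ok = np.isin(self.mask, (0, 1, MASK_NODATA))
        if not ok.all():
            raise ValueError("mask values must be 0, 1 or the nodata code")

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.mask == MASK_NODATA

    @property
    def binary(self) -> np.ndarray:
        """Boolean CAP raster; nodata cells are False."""
        return self.mask == 1

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def as_grid(self) -> DEMGrid:
        z = self.mask.astype(np.float64)
        z[self.nodata_mask] = np.nan
        return DEMGrid(z, self.cell_size_m, self.origin, self.crs_tag)


@dataclass
class AgreementReport:
    """Agreement between a predicted CAP mask and a reference frost zone."""

    recall: float                 # fraction of the reference zone captured
    false_positive_fraction: float  # fraction of predicted CAP outside it
    mean_boundary_offset_cells: float

    def __post_init__(self) -> None:
        if not (0 <= self.recall <= 1):
            raise ValueError("recall must be in [0, 1]")
        if not (0 <= self.false_positive_fraction <= 1):
            raise ValueError("false_positive_fraction must be in [0, 1]")

    @property
    def score(self) -> float:
        """Composite calibration score: recall minus false-positive
        fraction.  Modest over-prediction rims are tolerated — they still
        steer restoration planting away from frost — so false positives are
        not penalized more heavily than missed frost cells."""
        return self.recall - self.false_positive_fraction


def classify_cap(derivs: TerrainDerivatives,
                 thresholds: TerrainThresholds | None = None) -> CAPMask:
    """Threshold the three derivatives into a binary CAP mask.

    Cellwise AND of the three strict inequalities; nodata in any input
    propagates to nodata in the output.
    """
    thr = thresholds or PRESETS["calibrated"]
    slope = derivs.slope_deg.elevations
    rank = derivs.rank_elev.elevations
    curv = derivs.curvature.elevations
    invalid = (derivs.slope_deg.nodata_mask | derivs.rank_elev.nodata_mask
               | derivs.curvature.nodata_mask)
    with np.errstate(invalid="ignore"):
        cap = ((slope < thr.slope_max_deg) & (rank < thr.rank_max)
               & (curv < thr.curv_max))
    mask = cap.astype(np.uint8)
    mask[invalid] = MASK_NODATA
    g = derivs.slope_deg
    return CAPMask(mask, g.cell_size_m, g.origin, g.crs_tag,
                   provenance={"slope_max_deg": thr.slope_max_deg,
                               "rank_max": thr.rank_max,
                               "curv_max": thr.curv_max,
                               "radius_m": derivs.radius_m})


def run_cap_model(dem: DEMGrid, radius_m: float,
                  thresholds: TerrainThresholds | None = None,
                  diagonal_denominator: str = "sqrt2_r",
                  ) -> tuple[TerrainDerivatives, CAPMask]:
    """Full pipeline: derivatives at the valley radius, then thresholding.

    ``radius_m`` is the valley radius — half the ridge-to-ridge distance of
    the valley under study; one radius applies per run, so multi-valley
    DEMs should be clipped and run per valley with their own radii.
    """
    thr = thresholds or PRESETS["calibrated"]
    logger.info("run_cap_model: shape=%s cell=%sm radius=%sm thresholds="
                "(slope<%s deg, rank<%s, curv<%s)", dem.shape,
                dem.cell_size_m, radius_m, thr.slope_max_deg, thr.rank_max,
                thr.curv_max)
    derivs = compute_derivatives(dem, radius_m, diagonal_denominator)
    return derivs, classify_cap(derivs, thr)


# ---------------------------------------------------------------------------
# boundary agreement — a quantitative surrogate for visual treeline matchups


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Cells of ``mask`` with a 4-neighbour outside it (raster edge counts)."""
    if not mask.any():
        return np.zeros_like(mask, dtype=bool)
    core = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1),
        border_value=0)
    return mask & ~core


def boundary_agreement(pred: CAPMask | np.ndarray,
                       reference: np.ndarray) -> AgreementReport:
    """Recall, false-positive fraction and mean boundary offset.

    * recall — fraction of reference frost-zone cells predicted CAP;
    * false-positive fraction — fraction of predicted CAP cells lying
      outside the reference zone;
    * mean boundary offset — symmetric mean, in cells, of the Euclidean
      distance from each mask's boundary cells to the other's boundary
      (nan when either boundary is empty).

    Cells where the prediction is nodata are left out of both numerators
    and denominators.  An empty reference has undefined recall and raises.
    """
    pred_arr = pred.binary if isinstance(pred, CAPMask) else \
        np.asarray(pred, dtype=bool)
    valid = ~pred.nodata_mask if isinstance(pred, CAPMask) else \
        np.ones_like(pred_arr, dtype=bool)
    ref = np.asarray(reference).astype(bool)
    if ref.shape != pred_arr.shape:
        raise ValueError("prediction and reference rasters are not aligned")
    ref_valid = ref & valid
    if not ref_valid.any():
        raise ValueError("reference frost zone is empty: recall undefined")

    recall = float((pred_arr & ref_valid).sum() / ref_valid.sum())
    n_pred = int(pred_arr.sum())
    fp = float((pred_arr & ~ref).sum() / n_pred) if n_pred else 0.0

    pb, rb = _boundary(pred_arr), _boundary(ref_valid)
    if pb.any() and rb.any():
        d_to_ref = ndimage.distance_transform_edt(~rb)
        d_to_pred = ndimage.distance_transform_edt(~pb)
        offset = 0.5 * (float(d_to_ref[pb].mean())
                        + float(d_to_pred[rb].mean()))
    else:
        offset = float("nan")
    return AgreementReport(recall, fp, offset)


def sweep_thresholds(derivs: TerrainDerivatives, reference: np.ndarray,
                     candidates: list[TerrainThresholds],
                     ) -> list[tuple[TerrainThresholds, AgreementReport]]:
    """Evaluate candidate thresholds against a reference frost zone.

    Returns (thresholds, report) pairs ranked by the composite score
    (recall minus false-positive fraction), ties broken toward stricter
    thresholds.  Deterministic for a fixed candidate list.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate threshold grid is empty")
    scored = []
    for thr in candidates:
        report = boundary_agreement(classify_cap(derivs, thr), reference)
        scored.append((thr, report))
    scored.sort(key=lambda tr: (-tr[1].score, tr[0].slope_max_deg,
                                tr[0].rank_max, tr[0].curv_max))
    return scored
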
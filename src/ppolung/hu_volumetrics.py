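"""Hounsfield-unit lung densitometry and simulated-resection volumetrics.

Quantitative CT classifies lung voxels by attenuation: well-aerated
(functional) parenchyma lies in [-900, -501] HU, emphysematous (destroyed,
hyperinflated) tissue below -900 HU, and poorly aerated / non-aerated tissue
above.  Aggregating class volumes over an anatomical segment label map and
subtracting the segments of a planned resection yields the fractions that
drive predicted-postoperative-function models, in particular the percentage
of *functioning* parenchyma removed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

#: Default HU thresholds.  Voxels strictly below THETA_EMPH are emphysematous;
#: voxels in [THETA_EMPH, THETA_WELL_UPPER] are well aerated; voxels strictly
#: above THETA_WELL_UPPER are non-aerated.  The upper bound -501 closes the
#: printed gap between "well aerated up to -501" and "non-aerated above -500"
#: with integer-HU-compatible behaviour.
THETA_EMPH = -900.0
THETA_WELL_UPPER = -501.0

#: Integer codes used in class grids.
CLASS_BACKGROUND = 0
CLASS_WELL_AERATED = 1
CLASS_EMPHYSEMATOUS = 2
CLASS_NON_AERATED = 3

CLASS_NAMES = {
    CLASS_BACKGROUND: "background",
    CLASS_WELL_AERATED: "well_aerated",
    CLASS_EMPHYSEMATOUS: "emphysematous",
    CLASS_NON_AERATED: "non_aerated",
}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HUVolume:
    """A 3D CT attenuation grid with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Attenuation in Hounsfield units.  Must be finite.
    spacing : tuple of float
        Voxel edge lengths in mm, strictly positive on every axis.
    origin : tuple of float
        Physical offset in mm (carried through I/O, not used in arithmetic).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3 or values.size == 0:
            raise ValueError("HUVolume requires a non-empty 3D grid")
        if not np.all(np.isfinite(values)):
            raise ValueError("HU values must be finite")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError("voxel spacing must be strictly positive on every axis")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (product of spacings in mm^3 / 1000)."""
        return float(np.prod(self.spacing)) / 1000.0


@dataclass(frozen=True)
class SegmentInfo:
    """Label-table entry for one anatomical region."""

    laterality: str  # "left" | "right"
    lobe: str
    segment: str

    def __post_init__(self) -> None:
        if self.laterality not in ("left", "right"):
            raise ValueError(f"laterality must be 'left' or 'right', got {self.laterality!r}")


@dataclass(frozen=True)
class LungLabelMap:
    """Per-voxel anatomical segment labels plus a code -> anatomy table.

    Label 0 is background (non-lung).  Every nonzero code present in the grid
    must appear in the table; the table is authoritative for laterality.
    """

    labels: np.ndarray
    table: Mapping[int, SegmentInfo]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 3 or labels.size == 0:
            raise ValueError("LungLabelMap requires a non-empty 3D grid")
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.all(labels == np.round(labels)):
                raise ValueError("labels must be integer region codes")
            labels = labels.astype(np.int32)
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        table = {int(k): v for k, v in self.table.items()}
        present = set(int(c) for c in np.unique(labels)) - {0}
        missing = present - set(table)
        if missing:
            raise ValueError(f"codes present in grid but absent from table: {sorted(missing)}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "table", table)

    @property
    def lung_mask(self) -> np.ndarray:
        return self.labels != 0

    def codes_for_laterality(self, laterality: str) -> list[int]:
        return sorted(c for c, info in self.table.items() if info.laterality == laterality)


@dataclass(frozen=True)
class TissueClassMap:
    """Per-voxel tissue classes produced by HU thresholding."""

    classes: np.ndarray  # integer grid of CLASS_* codes
    thresholds: tuple[float, float] = (THETA_EMPH, THETA_WELL_UPPER)

    def __post_init__(self) -> None:
        classes = np.asarray(self.classes)
        if not np.isin(classes, list(CLASS_NAMES)).all():
            raise ValueError("class grid contains unknown codes")
        object.__setattr__(self, "classes", classes)


@dataclass(frozen=True)
class RegionVolumetrics:
    """Class-volume breakdown for one region (segment, lobe, lung or whole lung).

    Volumes are mL and satisfy
    ``volume_well_aerated + volume_emphysematous + volume_non_aerated ==
    volume_total`` exactly (voxel-count arithmetic).
    """

    region_id: str
    laterality: str | None
    lobe: str | None
    segment: str | None
    volume_total: float
    volume_well_aerated: float
    volume_emphysematous: float
    volume_non_aerated: float
    label_codes: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for v in (self.volume_total, self.volume_well_aerated,
                  self.volume_emphysematous, self.volume_non_aerated):
            if v < 0:
                raise ValueError("volumes must be non-negative")


@dataclass(frozen=True)
class ResectionPlan:
    """A set of segment label codes to remove; all on one side."""

    removed_segments: frozenset[int]

    def __post_init__(self) -> None:
        codes = frozenset(int(c) for c in self.removed_segments)
        if not codes:
            raise ValueError("a resection plan must remove at least one segment")
        object.__setattr__(self, "removed_segments", codes)

    def validate_against(self, table: Mapping[int, SegmentInfo]) -> str:
        """Check codes exist and share laterality; return the operated side."""
        missing = [c for c in self.removed_segments if c not in table]
        if missing:
            raise ValueError(f"plan references unknown segment codes: {sorted(missing)}")
        sides = {table[c].laterality for c in self.removed_segments}
        if len(sides) != 1:
            raise ValueError("all removed segments must share one laterality")
        return next(iter(sides))


@dataclass(frozen=True)
class ResectionSimulation:
    """Fractional volumetrics of a simulated anatomical resection.

    ``removed_functional_fraction`` is the Brunelli input "% of removed
    functioning lung parenchyma" expressed on the 0-1 scale: removed
    well-aerated volume over whole-lung well-aerated volume.
    """

    removed_total_fraction: float
    removed_functional_fraction: float
    healthy_over_total: float
    ipsi_remaining_healthy_over_total: float
    removed_healthy_over_removed_total: float
    removed_volume_ml: float = 0.0
    removed_well_aerated_ml: float = 0.0

    def __post_init__(self) -> None:
        for name in ("removed_total_fraction", "removed_functional_fraction",
                     "healthy_over_total", "ipsi_remaining_healthy_over_total",
                     "removed_healthy_over_removed_total"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")


class UndefinedFractionError(ZeroDivisionError):
    """A resection fraction has a zero denominator (e.g. no functional tissue)."""


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class HUTissueClassifier(TransformerMixin, BaseEstimator):
    """Threshold CT attenuation into aerated-tissue classes.

    A stateless scikit-learn transformer: ``transform`` maps an HU array of
    any shape to integer class codes (1 well-aerated, 2 emphysematous,
    3 non-aerated).  Background handling via a label map lives in
    :func:`classify_volume`.

    Parameters
    ----------
    theta_emph : float, default -900
        Voxels strictly below are emphysematous.
    theta_well_upper : float, default -501
        Upper bound (inclusive) of the well-aerated band; voxels strictly
        above are non-aerated.
    """

    def __init__(self, theta_emph: float = THETA_EMPH,
                 theta_well_upper: float = THETA_WELL_UPPER):
        self.theta_emph = theta_emph
        self.theta_well_upper = theta_well_upper

    def fit(self, X, y=None):
        if not self.theta_emph < self.theta_well_upper:
            raise ValueError("theta_emph must be strictly below theta_well_upper")
        self.n_features_in_ = np.asarray(X).shape[-1] if np.ndim(X) == 2 else 1
        return self

    def transform(self, X) -> np.ndarray:
        if not self.theta_emph < self.theta_well_upper:
            raise ValueError("theta_emph must be strictly below theta_well_upper")
        hu = np.asarray(X, dtype=np.float64)
        if not np.all(np.isfinite(hu)):
            raise ValueError("non-finite HU values rejected")
        out = np.full(hu.shape, CLASS_WELL_AERATED, dtype=np.int8)
        out[hu < self.theta_emph] = CLASS_EMPHYSEMATOUS
        out[hu > self.theta_well_upper] = CLASS_NON_AERATED
        return out

    def _more_tags(self):  # pragma: no cover - sklearn plumbing
        return {"stateless": True}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def classify_volume(vol: HUVolume, labels: LungLabelMap,
                    theta_emph: float = THETA_EMPH,
                    theta_well_upper: float = THETA_WELL_UPPER) -> TissueClassMap:
    """Classify every lung voxel into one aerated-tissue class.

    Background (label 0) voxels are class 0; lung voxels get exactly one of
    well-aerated / emphysematous / non-aerated, so the three class counts
    partition the lung-mask voxel count.
    """
    if vol.values.shape != labels.labels.shape:
        raise ValueError(
            f"HU grid shape {vol.values.shape} != label grid shape {labels.labels.shape}")
    clf = HUTissueClassifier(theta_emph=theta_emph, theta_well_upper=theta_well_upper)
    classes = clf.transform(vol.values)
    classes = np.where(labels.lung_mask, classes, CLASS_BACKGROUND).astype(np.int8)
    return TissueClassMap(classes=classes, thresholds=(theta_emph, theta_well_upper))


def _counts_for_mask(classes: np.ndarray, mask: np.ndarray) -> tuple[int, int, int]:
    sub = classes[mask]
    return (int(np.count_nonzero(sub == CLASS_WELL_AERATED)),
            int(np.count_nonzero(sub == CLASS_EMPHYSEMATOUS)),
            int(np.count_nonzero(sub == CLASS_NON_AERATED)))


def region_volumetrics(classmap: TissueClassMap, labels: LungLabelMap,
                       vol: HUVolume) -> list[RegionVolumetrics]:
    """Aggregate class volumes per segment, lobe, lung and whole lung.

    Aggregates are sums of their constituent segments' voxel counts (never a
    re-classification), so lobe/lung/whole-lung rows equal the sum of their
    segment rows exactly.  A segment present in the table but absent from the
    grid yields a zero-volume record with a warning.
    """
    if classmap.classes.shape != labels.labels.shape:
        raise ValueError("class grid and label grid shapes differ")
    if vol.values.shape != labels.labels.shape:
        raise ValueError("HU grid and label grid shapes differ")
    vml = vol.voxel_volume_ml
    lab = labels.labels

    # per-segment voxel counts by class, via one bincount pass per class
    max_code = max(labels.table, default=0)
    seg_counts: dict[int, tuple[int, int, int]] = {}
    flat_lab = lab.ravel()
    flat_cls = classmap.classes.ravel()
    per_class = {}
    for cls in (CLASS_WELL_AERATED, CLASS_EMPHYSEMATOUS, CLASS_NON_AERATED):
        per_class[cls] = np.bincount(flat_lab, weights=(flat_cls == cls),
                                     minlength=max_code + 1)
    for code in sorted(labels.table):
        counts = tuple(int(per_class[cls][code]) for cls in
                       (CLASS_WELL_AERATED, CLASS_EMPHYSEMATOUS, CLASS_NON_AERATED))
        if sum(counts) == 0 and not np.any(flat_lab == code):
            logger.warning("segment code %d in table but absent from grid; zero volume", code)
        seg_counts[code] = counts

    def make(region_id, laterality, lobe, segment, counts, codes):
        w, e, n = counts
        return RegionVolumetrics(
            region_id=region_id, laterality=laterality, lobe=lobe, segment=segment,
            volume_total=(w + e + n) * vml,
            volume_well_aerated=w * vml,
            volume_emphysematous=e * vml,
            volume_non_aerated=n * vml,
            label_codes=frozenset(codes),
        )

    out: list[RegionVolumetrics] = []
    by_lobe: dict[tuple[str, str], list[int]] = {}
    by_lung: dict[str, list[int]] = {}
    for code, info in sorted(labels.table.items()):
        out.append(make(f"segment:{code}", info.laterality, info.lobe,
                        info.segment, seg_counts[code], [code]))
        by_lobe.setdefault((info.laterality, info.lobe), []).append(code)
        by_lung.setdefault(info.laterality, []).append(code)

    def summed(codes):
        acc = (0, 0, 0)
        for c in codes:
            acc = tuple(a + b for a, b in zip(acc, seg_counts[c]))
        return acc

    for (lat, lobe), codes in sorted(by_lobe.items()):
        out.append(make(f"lobe:{lat}:{lobe}", lat, lobe, None, summed(codes), codes))
    for lat, codes in sorted(by_lung.items()):
        out.append(make(f"lung:{lat}", lat, None, None, summed(codes), codes))
    all_codes = sorted(labels.table)
    out.append(make("whole_lung", None, None, None, summed(all_codes), all_codes))
    return out


def _frac(num: float, den: float, what: str) -> float:
    if den == 0:
        raise UndefinedFractionError(f"undefined fraction: {what} has zero denominator")
    return num / den


def simulate_resection(volumetrics: Sequence[RegionVolumetrics],
                       plan: ResectionPlan,
                       table: Mapping[int, SegmentInfo]) -> ResectionSimulation:
    """Compute removed/remaining fractions for a planned segment resection.

    Denominators: whole lung for ``removed_total_fraction``,
    ``removed_functional_fraction`` and ``healthy_over_total``; the operated
    side's remaining tissue for ``ipsi_remaining_healthy_over_total``; the
    removed region for ``removed_healthy_over_removed_total``.  Zero
    denominators raise :class:`UndefinedFractionError` rather than returning
    a silent 0 or 1.
    """
    side = plan.validate_against(table)
    segments = {next(iter(r.label_codes)): r for r in volumetrics
                if r.region_id.startswith("segment:")}
    missing = [c for c in plan.removed_segments if c not in segments]
    if missing:
        raise ValueError(f"plan segments absent from volumetrics: {sorted(missing)}")

    def tot(rows):
        return (sum(r.volume_total for r in rows), sum(r.volume_well_aerated for r in rows))

    whole_total, whole_well = tot(segments.values())
    removed_rows = [segments[c] for c in plan.removed_segments]
    removed_total, removed_well = tot(removed_rows)
    ipsi_rows = [r for c, r in segments.items() if table[c].laterality == side]
    ipsi_total, ipsi_well = tot(ipsi_rows)
    ipsi_rem_total = ipsi_total - removed_total
    ipsi_rem_well = ipsi_well - removed_well

    return ResectionSimulation(
        removed_total_fraction=_frac(removed_total, whole_total, "removed/total"),
        removed_functional_fraction=_frac(removed_well, whole_well,
                                          "removed functional/total functional"),
        healthy_over_total=_frac(whole_well, whole_total, "healthy/total"),
        ipsi_remaining_healthy_over_total=_frac(
            ipsi_rem_well, ipsi_rem_total, "ipsilateral remaining healthy/total"),
        removed_healthy_over_removed_total=_frac(
            removed_well, removed_total, "removed healthy/removed total"),
        removed_volume_ml=removed_total,
        removed_well_aerated_ml=removed_well,
    )


# ---------------------------------------------------------------------------
# tabular export
# ---------------------------------------------------------------------------

def volumetrics_to_frame(volumetrics: Iterable[RegionVolumetrics]) -> pd.DataFrame:
    """One row per region: ids, anatomy, and class volumes in mL."""
    rows = [{
        "region_id": r.region_id,
        "laterality": r.laterality or "",
        "lobe": r.lobe or "",
        "segment": r.segment or "",
        "volume_total_ml": r.volume_total,
        "volume_well_aerated_ml": r.volume_well_aerated,
        "volume_emphysematous_ml": r.volume_emphysematous,
        "volume_non_aerated_ml": r.volume_non_aerated,
    } for r in volumetrics]
    return pd.DataFrame(rows)
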
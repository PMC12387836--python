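"""Synthetic CT phantoms and patient cohorts for end-to-end testing.

Real segmental HRCT reconstructions and patient-level outcome data are not
publicly available, so this module generates both halves of the pipeline's
input from seeded specifications:

* voxel phantoms — a lung envelope partitioned into axis-aligned segment
  blocks (right lung: 10 segments, S1-S3 forming the right upper lobe; the
  left lung as one bulk region for whole-lung denominators), each voxel
  drawn from a per-segment mixture of class-conditional HU distributions;
* patient cohorts — marginals matching a typical right-upper-lobe resection
  series (age 68 +/- 10 y, preop FEV1 2.48 +/- 0.59 L, FEV1/FVC 0.69 +/-
  0.09, DLCO 6.27 +/- 1.99 mmol/(min*kPa), 3/2/1 segments removed in
  70/10/20% of patients) and an outcome model in which resecting
  predominantly non-functional, hyperinflated tissue can *raise*
  postoperative FEV1.

The class-conditional HU distributions are truncated to their class
intervals so that each voxel's generating component is exactly recoverable
by thresholding: the emitted ground truth (realized voxel counts) is exact,
not approximate.

The compensation mechanism — a single gain on the product of the resected
non-functional fraction and the hyperinflation marker RV %predicted — is a
minimal testing device for "lung-volume-reduction-like" functional gain,
not a physiological claim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_analysis import PatientRecord
from .hu_volumetrics import (
    CLASS_EMPHYSEMATOUS,
    CLASS_NON_AERATED,
    CLASS_WELL_AERATED,
    THETA_EMPH,
    THETA_WELL_UPPER,
    HUVolume,
    LungLabelMap,
    ResectionSimulation,
    SegmentInfo,
)

#: Right-lung segment nomenclature: code -> (lobe, segment).
RIGHT_SEGMENTS = {
    1: ("right upper lobe", "S1"),
    2: ("right upper lobe", "S2"),
    3: ("right upper lobe", "S3"),
    4: ("right middle lobe", "S4"),
    5: ("right middle lobe", "S5"),
    6: ("right lower lobe", "S6"),
    7: ("right lower lobe", "S7"),
    8: ("right lower lobe", "S8"),
    9: ("right lower lobe", "S9"),
    10: ("right lower lobe", "S10"),
}
LEFT_BULK_CODE = 11

#: Class-conditional HU components (mean, SD) truncated to the class interval.
HU_COMPONENTS = {
    CLASS_WELL_AERATED: (-750.0, 40.0, THETA_EMPH, THETA_WELL_UPPER),
    CLASS_EMPHYSEMATOUS: (-950.0, 20.0, -1100.0, np.nextafter(THETA_EMPH, -np.inf)),
    CLASS_NON_AERATED: (-200.0, 50.0, np.nextafter(THETA_WELL_UPPER, np.inf), 100.0),
}


# ---------------------------------------------------------------------------
# phantoms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a voxel phantom.

    ``weights`` maps a segment code to its (well_aerated, emphysematous,
    non_aerated) mixture weights; ``default_weights`` applies to codes not
    listed.  ``blocks`` optionally fixes per-segment axis-aligned blocks as
    ``code -> ((x0,x1),(y0,y1),(z0,z1))`` half-open index ranges; when
    omitted, the lung envelope (the grid minus a background border) is
    partitioned automatically.  The seed is mandatory.
    """

    shape: tuple[int, int, int] = (30, 30, 44)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.5)
    seed: int = None  # type: ignore[assignment]  # mandatory, checked below
    default_weights: tuple[float, float, float] = (0.85, 0.05, 0.10)
    weights: Mapping[int, tuple[float, float, float]] = field(default_factory=dict)
    blocks: Mapping[int, tuple] | None = None
    border: int = 1
    background_hu: float = -1000.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("PhantomSpec requires an explicit seed")
        for code, w in list(self.weights.items()) + [(-1, self.default_weights)]:
            if len(w) != 3 or any(x < 0 for x in w) or abs(sum(w) - 1.0) > 1e-9:
                raise ValueError(f"mixture weights must be non-negative and sum to 1 (code {code})")
        if any(s < 2 * self.border + 2 for s in self.shape):
            raise ValueError("grid too small for the requested border")


def _default_blocks(spec: PhantomSpec) -> dict[int, tuple]:
    """Partition the envelope: left half = bulk, right half = 10 z-slabs."""
    b = spec.border
    nx, ny, nz = spec.shape
    x_mid = b + (nx - 2 * b) // 2
    inner_z = nz - 2 * b
    edges = [b + (inner_z * i) // 10 for i in range(11)]
    blocks: dict[int, tuple] = {}
    for i, code in enumerate(sorted(RIGHT_SEGMENTS)):
        blocks[code] = ((b, x_mid), (b, ny - b), (edges[i], edges[i + 1]))
    blocks[LEFT_BULK_CODE] = ((x_mid, nx - b), (b, ny - b), (b, nz - b))
    return blocks


def default_label_table() -> dict[int, SegmentInfo]:
    table = {code: SegmentInfo("right", lobe, seg)
             for code, (lobe, seg) in RIGHT_SEGMENTS.items()}
    table[LEFT_BULK_CODE] = SegmentInfo("left", "left lung", "bulk")
    return table


def make_phantom(spec: PhantomSpec) -> tuple[HUVolume, LungLabelMap, pd.DataFrame]:
    """Generate a phantom volume, its label map, and exact class ground truth.

    The returned DataFrame has one row per segment with realized voxel
    counts and fractions per tissue class (realized draws, not the target
    mixture weights).  Identical spec + seed give byte-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    blocks = dict(spec.blocks) if spec.blocks is not None else _default_blocks(spec)

    labels = np.zeros(spec.shape, dtype=np.int16)
    for code, ((x0, x1), (y0, y1), (z0, z1)) in sorted(blocks.items()):
        region = labels[x0:x1, y0:y1, z0:z1]
        if np.any(region != 0):
            raise ValueError(f"segment blocks overlap at code {code}")
        region[:] = code

    hu = np.full(spec.shape, spec.background_hu, dtype=np.float64)
    classes = (CLASS_WELL_AERATED, CLASS_EMPHYSEMATOUS, CLASS_NON_AERATED)
    truth_rows = []
    for code in sorted(blocks):
        mask = labels == code
        n = int(mask.sum())
        w = tuple(spec.weights.get(code, spec.default_weights))
        drawn = rng.choice(3, size=n, p=np.asarray(w, dtype=float))
        values = np.empty(n, dtype=np.float64)
        counts = {}
        for k, cls in enumerate(classes):
            sel = drawn == k
            counts[cls] = int(sel.sum())
            if counts[cls]:
                mean, sd, lo, hi = HU_COMPONENTS[cls]
                a, bnd = (lo - mean) / sd, (hi - mean) / sd
                values[sel] = stats.truncnorm.rvs(
                    a, bnd, loc=mean, scale=sd, size=counts[cls], random_state=rng)
        hu[mask] = values
        truth_rows.append({
            "code": code,
            "n_voxels": n,
            "n_well_aerated": counts[CLASS_WELL_AERATED],
            "n_emphysematous": counts[CLASS_EMPHYSEMATOUS],
            "n_non_aerated": counts[CLASS_NON_AERATED],
            "frac_well_aerated": counts[CLASS_WELL_AERATED] / n if n else 0.0,
            "frac_emphysematous": counts[CLASS_EMPHYSEMATOUS] / n if n else 0.0,
            "frac_non_aerated": counts[CLASS_NON_AERATED] / n if n else 0.0,
        })

    table = default_label_table()
    table = {c: table.get(c, SegmentInfo("right", "unspecified", f"seg{c}"))
             for c in blocks}
    volume = HUVolume(values=hu, spacing=spec.spacing)
    labelmap = LungLabelMap(labels=labels, table=table)
    return volume, labelmap, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic surgical cohort.

    Marginals default to the right-upper-lobe series this package targets;
    all draws are independent across variables (no published joint
    distribution exists to emulate).  The outcome model is

    ``postop FEV1 = preop * (1 - f_removed) * (1 + gamma * q * RV%/100)
    + Normal(0, sigma)``

    where ``f_removed`` is the removed functional fraction and ``q`` the
    non-functional fraction of the resected tissue, so resections of
    predominantly destroyed tissue in hyperinflated lungs (high q, high RV%)
    can produce postoperative gains.
    """

    n: int = 20
    seed: int = None  # type: ignore[assignment]
    age_mean: float = 68.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (40.0, 90.0)
    fev1_mean: float = 2.48
    fev1_sd: float = 0.59
    fev1_min: float = 0.8
    fev1_pct_mean: float = 92.0
    fev1_pct_sd: float = 15.0
    fev1_fvc_mean: float = 0.69
    fev1_fvc_sd: float = 0.09
    fev1_fvc_range: tuple[float, float] = (0.3, 0.95)
    dlco_mean: float = 6.27
    dlco_sd: float = 1.99
    dlco_min: float = 1.0
    dlco_pct_mean: float = 81.0
    dlco_pct_sd: float = 22.0
    rv_pct_mean: float = 118.0
    rv_pct_sd: float = 25.0
    bmi_mean: float = 27.0
    bmi_sd: float = 4.9
    segment_counts: tuple[int, ...] = (3, 2, 1)
    segment_probs: tuple[float, ...] = (0.70, 0.10, 0.20)
    # resected-tissue composition: non-functional fraction q ~ Beta(a, b)
    nonfunctional_beta: tuple[float, float] = (1.8, 8.2)  # mean 0.18
    # per-segment share of total lung volume (RUL segments are large)
    segment_volume_frac_mean: float = 0.0688
    segment_volume_frac_sd: float = 0.015
    rest_healthy_mean: float = 0.90
    rest_healthy_sd: float = 0.05
    # outcome-model parameters
    gamma: float = 0.6
    sigma: float = 0.15
    dlco_sigma: float = 0.30
    rv_reduction_gain: float = 4.0
    #: reference RV (L) at 100% predicted, used to convert RV% to liters
    rv_reference_l: float = 2.30

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("CohortSpec requires an explicit seed")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if len(self.segment_counts) != len(self.segment_probs):
            raise ValueError("segment_counts and segment_probs lengths differ")
        if abs(sum(self.segment_probs) - 1.0) > 1e-9:
            raise ValueError("segment probabilities must sum to 1")
        for name in ("age_sd", "fev1_sd", "fev1_fvc_sd", "dlco_sd", "rv_pct_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 <= self.gamma) or self.sigma < 0:
            raise ValueError("gamma must be >= 0 and sigma >= 0")


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


_RUL_LABELS = {1: ("S1",), 2: ("S1", "S2"), 3: ("S1", "S2", "S3")}


def make_cohort(spec: CohortSpec) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate a cohort and its ground truth.

    Returns the patient records (with attached CT volumetrics) and a truth
    DataFrame with the generating quantities per patient, including
    ``truth_response`` (postop FEV1 strictly above preop),
    ``truth_removed_functional_fraction`` and
    ``truth_nonfunctional_fraction`` of the resected tissue.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    age = _truncnorm(rng, spec.age_mean, spec.age_sd, *spec.age_range, n)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    bmi = _truncnorm(rng, spec.bmi_mean, spec.bmi_sd, 15.0, 45.0, n)
    fev1 = _truncnorm(rng, spec.fev1_mean, spec.fev1_sd, spec.fev1_min, np.inf, n)
    fev1_pct = _truncnorm(rng, spec.fev1_pct_mean, spec.fev1_pct_sd, 40.0, 140.0, n)
    ratio = _truncnorm(rng, spec.fev1_fvc_mean, spec.fev1_fvc_sd, *spec.fev1_fvc_range, n)
    dlco = _truncnorm(rng, spec.dlco_mean, spec.dlco_sd, spec.dlco_min, np.inf, n)
    dlco_pct = _truncnorm(rng, spec.dlco_pct_mean, spec.dlco_pct_sd, 30.0, 160.0, n)
    rv_pct = _truncnorm(rng, spec.rv_pct_mean, spec.rv_pct_sd, 60.0, 220.0, n)
    rv_l = rv_pct / 100.0 * spec.rv_reference_l

    k = rng.choice(np.asarray(spec.segment_counts),
                   p=np.asarray(spec.segment_probs), size=n)
    seg_fracs = _truncnorm(rng, spec.segment_volume_frac_mean,
                           spec.segment_volume_frac_sd, 0.03, 0.12, (n, 3))
    removed_total = np.array([seg_fracs[i, :k[i]].sum() for i in range(n)])
    q = rng.beta(*spec.nonfunctional_beta, size=n)  # non-functional fraction of resected tissue
    h_rest = _truncnorm(rng, spec.rest_healthy_mean, spec.rest_healthy_sd, 0.60, 0.99, n)
    total_lung_ml = _truncnorm(rng, 5200.0, 900.0, 3000.0, 8000.0, n)

    # whole-lung functional fraction and the Brunelli/volumetric input
    removed_healthy = removed_total * (1.0 - q)
    whole_healthy = (1.0 - removed_total) * h_rest + removed_healthy
    f_removed = removed_healthy / whole_healthy
    ipsi_rem_healthy = np.clip(
        h_rest + rng.normal(0.0, 0.02, size=n), 0.0, 1.0)

    gain = 1.0 + spec.gamma * q * rv_pct / 100.0
    noise = rng.normal(0.0, spec.sigma, size=n) if spec.sigma > 0 else np.zeros(n)
    postop_fev1 = np.maximum(fev1 * (1.0 - f_removed) * gain + noise, 0.05)

    dlco_noise = (rng.normal(0.0, spec.dlco_sigma, size=n)
                  if spec.dlco_sigma > 0 else np.zeros(n))
    postop_dlco = np.maximum(
        dlco * (1.0 - 0.5 * f_removed) * (1.0 + 0.5 * (gain - 1.0)) + dlco_noise, 0.3)

    rv_drop = np.clip(spec.rv_reduction_gain * removed_total * q, 0.0, 0.8)
    postop_rv_l = rv_l * (1.0 - rv_drop)
    postop_rv_pct = rv_pct * (1.0 - rv_drop)

    records: list[PatientRecord] = []
    truth_rows = []
    for i in range(n):
        sim = ResectionSimulation(
            removed_total_fraction=float(removed_total[i]),
            removed_functional_fraction=float(f_removed[i]),
            healthy_over_total=float(whole_healthy[i]),
            ipsi_remaining_healthy_over_total=float(ipsi_rem_healthy[i]),
            removed_healthy_over_removed_total=float(1.0 - q[i]),
            removed_volume_ml=float(removed_total[i] * total_lung_ml[i]),
            removed_well_aerated_ml=float(removed_healthy[i] * total_lung_ml[i]),
        )
        scale = postop_fev1[i] / fev1[i]
        records.append(PatientRecord(
            id=f"SYN{i + 1:04d}",
            age=float(age[i]), sex=str(sex[i]), bmi=float(bmi[i]),
            segments_removed=int(k[i]),
            resected_segment_labels=_RUL_LABELS[int(k[i])],
            preop_fev1_l=float(fev1[i]), preop_fev1_pct=float(fev1_pct[i]),
            preop_fev1_fvc=float(ratio[i]),
            preop_dlco=float(dlco[i]), preop_dlco_pct=float(dlco_pct[i]),
            preop_rv_l=float(rv_l[i]), preop_rv_pct=float(rv_pct[i]),
            postop_fev1_l=float(postop_fev1[i]),
            postop_fev1_pct=float(fev1_pct[i] * scale),
            postop_dlco=float(postop_dlco[i]),
            postop_dlco_pct=float(dlco_pct[i] * postop_dlco[i] / dlco[i]),
            postop_rv_l=float(postop_rv_l[i]), postop_rv_pct=float(postop_rv_pct[i]),
            volumetrics=sim,
        ))
        truth_rows.append({
            "id": records[-1].id,
            "truth_response": bool(postop_fev1[i] > fev1[i]),
            "truth_removed_total_fraction": float(removed_total[i]),
            "truth_removed_functional_fraction": float(f_removed[i]),
            "truth_nonfunctional_fraction": float(q[i]),
            "truth_rest_healthy_fraction": float(h_rest[i]),
            "truth_compensation_gain": float(gain[i]),
            "truth_noise": float(noise[i]),
        })
    return records, pd.DataFrame(truth_rows)
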
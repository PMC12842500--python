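"""Classification of per-kidney stone-burden change between paired exams.

The endpoint is categorical: a relative change in per-kidney stone volume of
less than 15% in magnitude is *stable*; at or beyond +/-15% the burden is
*increased* or *decreased*.  The unit of analysis is the kidney; patient
level aggregates the two kidney labels, with *mixed* when one kidney
increased and the other decreased.

Boundary and degenerate conventions (the band rule leaves them open):
exactly +/-15% counts as changed, keeping "stable" an open interval; a new
stone appearing from zero baseline is *increased*; complete resolution to
zero is *decreased* (relative change -1); no stones at either time is
*stable*.
"""

from __future__ import annotations

from dataclasses import dataclass

DECREASED = "decreased"
STABLE = "stable"
INCREASED = "increased"
MIXED = "mixed"

CHANGE_LABELS = (DECREASED, STABLE, INCREASED)
PATIENT_LABELS = (DECREASED, STABLE, INCREASED, MIXED)

DEFAULT_BAND = 0.15


def classify_change(v_baseline_ml: float, v_followup_ml: float,
                    band: float = DEFAULT_BAND) -> str:
    """Label the change in per-kidney stone volume by the relative band rule."""
    if v_baseline_ml < 0 or v_followup_ml < 0:
        raise ValueError("stone volumes cannot be negative")
    if not 0 < band < 1:
        raise ValueError(f"band must lie in (0, 1), got {band}")
    if v_baseline_ml == 0:
        return INCREASED if v_followup_ml > 0 else STABLE
    r = (v_followup_ml - v_baseline_ml) / v_baseline_ml
    # boundary belongs to "changed"; the tiny slack keeps decimal inputs
    # like 1.00 -> 1.15 on the boundary despite binary rounding
    eps = 1e-12 * band
    if r >= band - eps:
        return INCREASED
    if r <= -(band - eps):
        return DECREASED
    return STABLE


def aggregate_patient(kidney_labels) -> str:
    """Combine the two kidney labels into the patient-level category.

    A kidney with no stones on either exam contributes 'stable'.
    """
    labels = list(kidney_labels)
    if len(labels) != 2:
        raise ValueError(f"expected exactly two kidney labels, got {len(labels)}")
    bad = set(labels) - set(CHANGE_LABELS)
    if bad:
        raise ValueError(f"unknown kidney labels: {sorted(bad)}")
    has_inc = INCREASED in labels
    has_dec = DECREASED in labels
    if has_inc and has_dec:
        return MIXED
    if has_inc:
        return INCREASED
    if has_dec:
        return DECREASED
    return STABLE


@dataclass
class KidneyChangeRecord:
    """One kidney's paired volumes and the resulting change label."""

    patient_id: str
    kidney_side: str
    v_baseline_ml: float
    v_followup_ml: float
    relative_change: float  # (V_f - V_b) / V_b; inf for a new stone, 0.0 for two empty exams
    label: str


def _relative_change(vb: float, vf: float) -> float:
    if vb > 0:
        return (vf - vb) / vb
    return float("inf") if vf > 0 else 0.0


def reference_labels(studies, threshold: float = 130.0, connectivity: int = 26,
                     min_diameter_mm: float | None = None,
                     band: float = DEFAULT_BAND) -> list[KidneyChangeRecord]:
    """Volumetric reference standard for a cohort of paired studies.

    Runs threshold volumetry on baseline and follow-up of every study and
    classifies each kidney; one record per kidney, per-kidney merged-VOI
    volumes.
    """
    from .volumetry import build_inventory

    records = []
    for study in studies:
        inv_b = build_inventory(study.baseline, study.mask_baseline,
                                threshold, connectivity, min_diameter_mm)
        inv_f = build_inventory(study.followup, study.mask_followup,
                                threshold, connectivity, min_diameter_mm)
        for side in ("right", "left"):
            vb = inv_b.kidney_total(side)["total_volume_ml"]
            vf = inv_f.kidney_total(side)["total_volume_ml"]
            records.append(KidneyChangeRecord(
                patient_id=study.patient_id,
                kidney_side=side,
                v_baseline_ml=vb,
                v_followup_ml=vf,
                relative_change=_relative_change(vb, vf),
                label=classify_change(vb, vf, band=band),
            ))
    return records


def patient_summary(records: list[KidneyChangeRecord]) -> dict[str, str]:
    """Patient-level labels from per-kidney records (two kidneys each)."""
    by_patient: dict[str, dict[str, str]] = {}
    for r in records:
        by_patient.setdefault(r.patient_id, {})[r.kidney_side] = r.label
    out = {}
    for pid, sides in by_patient.items():
        missing = {"right", "left"} - set(sides)
        if missing:
            raise ValueError(f"patient {pid} is missing kidney record(s): {sorted(missing)}")
        out[pid] = aggregate_patient([sides["right"], sides["left"]])
    return out
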
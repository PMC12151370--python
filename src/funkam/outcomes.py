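"""Evaluation metrics comparing candidate models against the REF standard.

Static trials are summarized by the EAM mean over one second of constant
force application; model quality is expressed as the sign-error risk (an
abduction moment reported where the reference shows adduction, or vice
versa), the foot-position fidelity loss (sign disagreement of the
eversion/inversion-minus-neutral EAM difference), the EAM RMSE in %BWHt, and
dynamic mean/max extraction.  A marker-set sensitivity harness re-runs the
IK+ID pipeline with the eight marker subsets S1-S8 (cluster markers,
landmark markers and additional segment markers included or excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anthropometry import DEFAULT_LAYOUT, MarkerLayout
from .errors import ValidationError

__all__ = [
    "TrialRecord",
    "MarkerSetSpec",
    "marker_sets",
    "static_eam_summary",
    "sign_error_risk",
    "delta_eam_fidelity",
    "rmse_bwht",
    "dynamic_extrema",
    "marker_set_sensitivity",
]


@dataclass
class TrialRecord:
    """EAM series (%BWHt) per model variant for one trial."""

    subject: str
    condition: str  # "static" | "dynamic"
    foot_position: str  # "neutral" | "eversion12" | "inversion12"
    times: np.ndarray
    eam: dict  # variant -> (F,) series, %BWHt
    force_magnitude: np.ndarray | None = None
    sagittal: dict = field(default_factory=dict)  # variant -> {name: series}


@dataclass(frozen=True)
class MarkerSetSpec:
    set_id: str
    labels: tuple


def marker_sets(layout: MarkerLayout = DEFAULT_LAYOUT) -> list[MarkerSetSpec]:
    """The eight sensitivity marker sets.

    Base markers (first/fifth metatarsal, heel, ASIS, PSIS) appear in every
    set; S1-S5 use the thigh/shank clusters without the knee/ankle landmark
    markers, adding foot (S1), pelvis (S3) or tibia (S4) extras or all of
    them (S5); S6/S7 drop the clusters and keep the landmarks with (S6) or
    without (S7) the extras; S8 is the full set.
    """
    base_foot = ("MT1", "MT5", "HEEL")
    add_foot = layout.additional_foot  # MT2, TOE2
    base_pelvis = ("RASI", "LASI", "RPSI", "LPSI")
    add_pelvis = layout.additional_hip  # iliac crest
    clusters = tuple(layout.thigh_cluster) + tuple(layout.shank_cluster)
    landmarks = tuple(layout.epicondyles) + tuple(layout.malleoli)
    add_tibia = layout.additional_tibia

    def spec(set_id, *groups):
        labels = []
        for g in groups:
            labels.extend(g)
        return MarkerSetSpec(set_id, tuple(dict.fromkeys(labels)))

    s1 = spec("S1", base_foot, add_foot, clusters, base_pelvis)
    s2 = spec("S2", base_foot, clusters, base_pelvis)
    s3 = spec("S3", base_foot, add_foot, clusters, base_pelvis, add_pelvis)
    s4 = spec("S4", base_foot, add_foot, clusters, add_tibia, base_pelvis)
    s5 = spec("S5", base_foot, add_foot, clusters, add_tibia, base_pelvis, add_pelvis)
    s6 = spec("S6", base_foot, add_foot, landmarks, add_tibia, base_pelvis, add_pelvis)
    s7 = spec("S7", base_foot, landmarks, base_pelvis)
    s8 = spec(
        "S8", base_foot, add_foot, landmarks, clusters, add_tibia, base_pelvis, add_pelvis
    )
    sets = [s1, s2, s3, s4, s5, s6, s7, s8]
    for s in sets[:-1]:
        assert set(s.labels) <= set(s8.labels)
    return sets


def static_eam_summary(
    trial: TrialRecord, variant: str, window: float = 1.0, plateau_tol: float = 0.05
) -> float:
    """Mean EAM over a window of constant force application.

    The plateau is the latest window in which the force magnitude stays
    within ``plateau_tol`` (fraction) of its median over that window; if no
    force trace is attached, the last ``window`` seconds are used.
    """
    times = trial.times
    eam = trial.eam[variant]
    dt = float(np.mean(np.diff(times)))
    nwin = int(round(window / dt))
    if nwin > len(times):
        raise ValidationError("window longer than the trial")
    if nwin < 1:
        raise ValidationError("window too short for the sampling rate")
    force = trial.force_magnitude
    if force is None:
        return float(np.mean(eam[-nwin:]))
    best_start, best_dev = None, np.inf
    for start in range(len(times) - nwin + 1):
        seg = force[start : start + nwin]
        med = np.median(seg)
        if med <= 0:
            continue
        dev = float(np.max(np.abs(seg - med)) / med)
        # prefer the flattest window; later windows win ties (steady push)
        if dev <= best_dev:
            best_start, best_dev = start, dev
    if best_start is None or best_dev > plateau_tol:
        raise ValidationError(
            f"no {window:.2f} s constant-force plateau found in trial "
            f"{trial.subject}/{trial.foot_position}"
        )
    return float(np.mean(eam[best_start : best_start + nwin]))


def _sign(x: float) -> int:
    # zero counts as positive (documented convention)
    return 1 if x >= 0 else -1


def sign_error_risk(candidate: np.ndarray, reference: np.ndarray) -> float:
    """Percent of trials where the candidate EAM has the wrong sign."""
    c = np.atleast_1d(np.asarray(candidate, dtype=float))
    r = np.atleast_1d(np.asarray(reference, dtype=float))
    if c.shape != r.shape or c.size == 0:
        raise ValidationError("candidate/reference must be equal-length, nonempty")
    wrong = sum(_sign(a) != _sign(b) for a, b in zip(c, r))
    return 100.0 * wrong / len(c)


def delta_eam_fidelity(candidate: dict, reference: dict) -> float:
    """Fidelity loss of the foot-position EAM difference, in percent.

    ``candidate``/``reference`` map ``(subject, foot_position)`` to a static
    EAM scalar; foot positions are ``neutral`` plus any modified positions.
    For every subject and modified position the EAM change from neutral is
    computed; a loss is counted whenever its sign differs between candidate
    and reference.
    """
    subjects = sorted({k[0] for k in reference})
    losses = 0
    total = 0
    for s in subjects:
        if (s, "neutral") not in reference or (s, "neutral") not in candidate:
            raise ValidationError(f"missing neutral trial for subject {s}")
        mods = sorted(k[1] for k in reference if k[0] == s and k[1] != "neutral")
        for m in mods:
            d_ref = reference[(s, m)] - reference[(s, "neutral")]
            d_can = candidate[(s, m)] - candidate[(s, "neutral")]
            total += 1
            if _sign(d_can) != _sign(d_ref):
                losses += 1
    if total == 0:
        raise ValidationError("no modified foot positions to analyze")
    return 100.0 * losses / total


def rmse_bwht(candidate, reference, aggregate: bool = False):
    """RMSE between EAM series (same time base).

    With ``aggregate=True`` the inputs are lists of per-trial series and the
    result is ``(mean, sd)`` of per-trial RMSE values.
    """
    if aggregate:
        vals = [rmse_bwht(c, r) for c, r in zip(candidate, reference)]
        return float(np.mean(vals)), float(np.std(vals))
    c = np.asarray(candidate, dtype=float)
    r = np.asarray(reference, dtype=float)
    if c.shape != r.shape:
        raise ValidationError("series shapes differ")
    return float(np.sqrt(np.mean((c - r) ** 2)))


def dynamic_extrema(series: np.ndarray) -> tuple[float, float]:
    """Mean and maximum of a moment series over the movement."""
    s = np.asarray(series, dtype=float)
    if s.size == 0:
        raise ValidationError("empty series")
    return float(np.mean(s)), float(np.max(s))


def marker_set_sensitivity(
    run_pipeline,
    reference_eam: np.ndarray,
    sets: list[MarkerSetSpec] | None = None,
) -> pd.DataFrame:
    """Re-run an IK(+ID) pipeline per marker set and tabulate EAM deviations.

    ``run_pipeline(labels)`` must return the EAM series (%BWHt) obtained when
    tracking only ``labels``.  The table reports RMSE, mean |Δ| and max |Δ|
    against the reference series per set.
    """
    if sets is None:
        sets = marker_sets()
    ref = np.asarray(reference_eam, dtype=float)
    rows = []
    for s in sets:
        eam = np.asarray(run_pipeline(list(s.labels)), dtype=float)
        d = np.abs(eam - ref)
        rows.append(
            {
                "set": s.set_id,
                "n_markers": len(s.labels),
                "rmse": float(np.sqrt(np.mean((eam - ref) ** 2))),
                "mean_abs": float(np.mean(d)),
                "max_abs": float(np.max(d)),
            }
        )
    return pd.DataFrame(rows).set_index("set")
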
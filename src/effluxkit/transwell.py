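"""Bidirectional Caco-2 monolayer transport analysis.

Caco-2 cells grown on transwell inserts express P-glycoprotein on the
apical membrane, so a P-gp substrate crosses the monolayer faster
basolateral-to-apical (B-A) than apical-to-basolateral (A-B).  From the
amount translocated into the receiver compartment the apparent
permeability coefficient is

    Papp = (dQ/dT) / (A * C0)        [cm/s]

with dQ the translocated amount (pmol), dT the incubation time (s),
A the membrane area (cm^2, standard insert 0.7) and C0 the initial
donor concentration (pmol/cm^3).  The efflux ratio

    ER = Papp(B-A) / Papp(A-B)

exceeds 2 for an actively effluxed substrate and collapses towards 1
when the transporter is inhibited.  Recovery,

    R = 100 * (Q_apical + Q_basolateral + Q_cells) / Q_0,

audits mass balance (metabolism / non-specific binding).

Because ER is a ratio of noisy means, two aggregations are reported:
the ratio of mean Papps (default display) and the mean of per-replicate
ERs; they agree closely at low replicate noise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TranswellResult",
    "papp",
    "efflux_ratio",
    "recovery",
    "substrate_and_inhibition_calls",
    "analyze_transwell",
    "DEFAULT_AREA_CM2",
    "DEFAULT_ER_CUTOFF",
]

log = logging.getLogger(__name__)

DEFAULT_AREA_CM2 = 0.7
DEFAULT_ER_CUTOFF = 2.0


def papp(dq: float, dt: float, area: float = DEFAULT_AREA_CM2,
         c0: float = 1.0) -> float:
    """Apparent permeability coefficient (dq/dt)/(area*c0) in cm/s.

    dq in pmol, dt in seconds, area in cm^2, c0 in pmol/cm^3.
    """
    if dt <= 0 or area <= 0 or c0 <= 0:
        raise ValueError("dt, area and c0 must be positive")
    if dq < 0:
        raise ValueError("translocated amount must be non-negative")
    return (dq / dt) / (area * c0)


def efflux_ratio(papp_ab: float, papp_ba: float) -> float:
    """Efflux ratio Papp(B-A)/Papp(A-B); > 2 indicates active efflux."""
    if papp_ab < 0 or papp_ba < 0:
        raise ValueError("permeabilities must be non-negative")
    if papp_ab == 0:
        log.warning("Papp(A-B) is zero; efflux ratio reported as inf")
        return math.inf
    return papp_ba / papp_ab


def recovery(q_apical: float, q_basolateral: float, q_cells: float,
             q0: float) -> float:
    """Percent of the applied amount recovered over all compartments."""
    if q0 <= 0:
        raise ValueError("initial quantity q0 must be positive")
    return 100.0 * (q_apical + q_basolateral + q_cells) / q0


@dataclass(frozen=True)
class TranswellResult:
    """Per-condition bidirectional transport summary (Table-style row)."""

    compound: str
    inhibitor: str | None
    papp_ab: float
    papp_ab_sem: float
    papp_ba: float
    papp_ba_sem: float
    er: float                  # ratio of mean Papps (display default)
    er_sem: float              # first-order error propagation
    er_per_replicate: float    # mean of per-replicate ERs (detail)
    er_per_replicate_sem: float
    recovery_pct: float
    n: int
    substrate_call: str = "n/a"
    inhibition_call: str = "n/a"


def _sem(x: np.ndarray) -> float:
    return float(x.std(ddof=1) / math.sqrt(len(x))) if len(x) > 1 else 0.0


def summarize_condition(compound: str, inhibitor: str | None,
                        papp_ab_reps, papp_ba_reps,
                        recovery_reps=None) -> TranswellResult:
    """Aggregate replicate Papps for one condition into a TranswellResult."""
    ab = np.asarray(papp_ab_reps, dtype=float)
    ba = np.asarray(papp_ba_reps, dtype=float)
    er_mean = efflux_ratio(ab.mean(), ba.mean())
    # first-order propagation: (s_ER/ER)^2 = (s_AB/AB)^2 + (s_BA/BA)^2
    sem_ab, sem_ba = _sem(ab), _sem(ba)
    if math.isfinite(er_mean) and ab.mean() > 0 and ba.mean() > 0:
        er_sem = er_mean * math.sqrt((sem_ab / ab.mean()) ** 2 +
                                     (sem_ba / ba.mean()) ** 2)
    else:
        er_sem = math.nan
    n_pair = min(len(ab), len(ba))
    er_reps = np.array([efflux_ratio(ab[i], ba[i]) for i in range(n_pair)])
    rec = (float(np.mean(recovery_reps)) if recovery_reps is not None
           and len(recovery_reps) else math.nan)
    return TranswellResult(
        compound=compound, inhibitor=inhibitor,
        papp_ab=float(ab.mean()), papp_ab_sem=sem_ab,
        papp_ba=float(ba.mean()), papp_ba_sem=sem_ba,
        er=er_mean, er_sem=er_sem,
        er_per_replicate=float(er_reps.mean()),
        er_per_replicate_sem=_sem(er_reps),
        recovery_pct=rec, n=n_pair,
    )


def substrate_and_inhibition_calls(
        result_alone: TranswellResult,
        result_with_inhibitor: TranswellResult | None = None,
        er_cutoff: float = DEFAULT_ER_CUTOFF,
) -> tuple[str, str]:
    """Classify efflux substrate status and transporter inhibition.

    A compound is an efflux substrate when its ER alone exceeds the
    cutoff (default 2) with Papp(B-A) > Papp(A-B); the inhibitor arm is
    called inhibited when it pulls the ER below the cutoff for a
    substrate.  Returns (substrate_call, inhibition_call).
    """
    is_substrate = (result_alone.er > er_cutoff
                    and result_alone.papp_ba > result_alone.papp_ab)
    substrate_call = "efflux_substrate" if is_substrate else "not_substrate"
    if result_with_inhibitor is None or not is_substrate:
        inhibition_call = "n/a"
    else:
        inhibition_call = ("inhibited" if result_with_inhibitor.er < er_cutoff
                           else "not_inhibited")
    return substrate_call, inhibition_call


def analyze_transwell(df: pd.DataFrame,
                      er_cutoff: float = DEFAULT_ER_CUTOFF) -> pd.DataFrame:
    """Full per-condition analysis of a long transwell table.

    Expects columns: compound, inhibitor ('' or name), direction
    (A_B/B_A), conc_uM, time_min, area_cm2, dq_pmol, q_apical,
    q_basolateral, q_cells, q0, replicate, qc_pass.  Wells failing QC
    are excluded with a logged reason.  Returns one row per
    (compound, inhibitor, conc, time) mirroring a results-table layout.
    """
    df = df.copy()
    df["inhibitor"] = df["inhibitor"].fillna("").astype(str)
    if "qc_pass" in df.columns:
        bad = ~df["qc_pass"].astype(bool)
        if bad.any():
            log.warning("excluding %d wells failing monolayer QC", int(bad.sum()))
            df = df[~bad]

    rows = []
    results: dict[tuple, TranswellResult] = {}
    keys = ["compound", "inhibitor", "conc_uM", "time_min"]
    for key, grp in df.groupby(keys, sort=False):
        compound, inhibitor, conc_um, time_min = key
        c0 = conc_um * 1e3  # uM -> pmol/cm^3 (1 uM = 1000 pmol/cm^3)
        pab, pba, recs = [], [], []
        for direction, sub in grp.groupby("direction"):
            vals = [
                papp(r.dq_pmol, r.time_min * 60.0, r.area_cm2, c0)
                for r in sub.itertuples()
            ]
            if direction == "A_B":
                pab = vals
            elif direction == "B_A":
                pba = vals
            else:
                raise ValueError(f"unknown direction {direction!r}")
        recs = [
            recovery(r.q_apical, r.q_basolateral, r.q_cells, r.q0)
            for r in grp.itertuples()
        ]
        if not pab or not pba:
            raise ValueError(f"condition {key} lacks one transport direction")
        results[key] = summarize_condition(compound, inhibitor or None,
                                           pab, pba, recs)

    for key, res in results.items():
        compound, inhibitor, conc_um, time_min = key
        if inhibitor == "":
            sub_call, inh_call = substrate_and_inhibition_calls(res, None, er_cutoff)
        else:
            alone_key = (compound, "", conc_um, time_min)
            alone = results.get(alone_key)
            if alone is not None:
                sub_call, inh_call = substrate_and_inhibition_calls(
                    alone, res, er_cutoff)
                sub_call = "n/a"  # substrate status belongs to the alone row
            else:
                sub_call, inh_call = "n/a", "n/a"
        rows.append({
            "compound": compound,
            "inhibitor": inhibitor or None,
            "conc_uM": conc_um,
            "time_min": time_min,
            "papp_ab_1e6": res.papp_ab * 1e6,
            "papp_ab_sem_1e6": res.papp_ab_sem * 1e6,
            "papp_ba_1e6": res.papp_ba * 1e6,
            "papp_ba_sem_1e6": res.papp_ba_sem * 1e6,
            "er": res.er,
            "er_sem": res.er_sem,
            "er_per_replicate": res.er_per_replicate,
            "recovery_pct": res.recovery_pct,
            "substrate_call": sub_call,
            "inhibition_call": inh_call,
        })
    return pd.DataFrame(rows)
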
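"""Mechanistic synthetic-data generators with ground truth attached.

Every generator emulates the structure of one assay in an acquired
taxane-resistance study and carries a :class:`SyntheticTruth` record so
downstream estimates can be checked against known parameters.

Viability plates.  Cell kill follows a 4PL curve of the *effective*
intracellular taxane concentration.  A resistant line expresses an
efflux pump that reduces the effective concentration by a factor
``1 + E * occ``, where ``occ = 1 - c_inh / (c_inh + Ki)`` is the free
(uninhibited) fraction of the transporter under a one-site binding
model of the inhibitor.  With efflux factor ``E = 0`` the two drugs act
independently (Bliss-null behaviour); with ``E >> 1`` the apparent IC50
is shifted ``(1 + E)``-fold and collapses back to the parental value at
saturating inhibitor - the resistance-reversal phenotype.  The
inhibitor also contributes its own (weak) single-agent 4PL kill.

Transwell assays.  Passive permeability ``p`` is modulated by active
efflux: Papp(A-B) = p / (1 + M * occ), Papp(B-A) = p * (1 + M * occ),
so the noiseless efflux ratio is (1 + M * occ)^2.  Compartment
quantities are mass-conserving, so recovery is exactly 100% without
noise.

RNA-seq counts.  Negative-binomial counts around log-normal baseline
gene means, with configured fold shifts for differentially expressed
genes (including an ABCB1-like transporter gene up-regulated ~3000x in
the resistant group).

All noise is multiplicative log-normal with unit mean (plate-reader
error scales with signal); all randomness flows from one seeded
generator per dataset, so regeneration from (truth, seed) is
bit-identical.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ViabilityTruth",
    "MechanismTruth",
    "TranswellTruth",
    "ExpressionTruth",
    "SyntheticTruth",
    "gen_viability_plate",
    "simulate_tc_matrix",
    "gen_transwell",
    "gen_counts",
    "gen_study",
]

# concentration grids used across the study design (molar)
DOCETAXEL_GRID_5 = np.array([1, 3.16, 10, 31.6, 100]) * 1e-9
RITONAVIR_GRID_5 = np.array([0.3, 0.949, 3, 9.49, 30]) * 1e-6
DOCETAXEL_GRID_8 = np.array([0.1, 0.316, 1, 3.16, 10, 31.6, 100, 316]) * 1e-9
RITONAVIR_GRID_2 = np.array([10, 32]) * 1e-6
SINGLE_AGENT_GRID = np.array(
    [0.0316, 0.1, 0.316, 1, 3.16, 10, 31.6, 100, 316, 1000]) * 1e-9


@dataclass(frozen=True)
class ViabilityTruth:
    """4PL parameters of the parental (un-effluxed) response."""

    top: float = 1.0
    bottom: float = 0.0
    ic50: float = 1e-9          # parental taxane IC50 [M]
    hill: float = 1.5
    noise_cv: float = 0.10      # multiplicative CV on well signals


@dataclass(frozen=True)
class MechanismTruth:
    """Efflux/inhibition mechanism shared by a resistant line."""

    efflux_factor: float = 21.3          # E; apparent IC50 shift = 1 + E
    inhibitor_ki: float = 2e-6           # one-site binding constant [M]
    inhibitor_intrinsic_ic50: float = 25e-6  # inhibitor's own kill curve [M]
    inhibitor_hill: float = 1.5


@dataclass(frozen=True)
class TranswellTruth:
    p_passive: float = 3.7e-6        # cm/s
    efflux_multiplier: float = 4.7   # M; noiseless ER = (1 + M)^2
    inhibitor_ki: float = 1.2e-6     # [M]
    noise_cv: float = 0.05
    area_cm2: float = 0.7
    cell_fraction: float = 0.02      # share of q0 retained in the monolayer
    donor_volume_ab: float = 0.4     # cm^3 (apical chamber)
    donor_volume_ba: float = 0.8     # cm^3 (basolateral chamber)


@dataclass(frozen=True)
class ExpressionTruth:
    n_genes: int = 2000
    nb_dispersion: float = 0.05
    baseline_log_mean: float = 3.0   # log-scale of the gene-mean distribution
    baseline_log_sd: float = 1.5
    line_effect_sd: float = 0.2      # per-line baseline wobble (log scale)
    #: mean count of a DE gene in its *expressed* state; huge fold changes
    #: arise from near-silence in the other state (a transporter gene
    #: undetectable in parental cells), not from one transcript swamping
    #: the library.
    de_expressed_mean: float = 200.0
    de_genes: dict = field(default_factory=lambda: {
        "ABCB1": 3000.0, "DSEL": 530.0, "GPC4": 260.0, "MMP1": 60.0,
        "BCHE": 1.0 / 6770.0, "SFRP1": 1.0 / 3325.0,
    })
    #: per-gene overrides of the expressed-state mean; the up-regulated
    #: transporter is abundant in resistant cells, not merely present.
    de_expressed_overrides: dict = field(
        default_factory=lambda: {"ABCB1": 2000.0})


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth carried alongside every generated dataset."""

    seed: int
    viability: ViabilityTruth = ViabilityTruth()
    mechanism: MechanismTruth = MechanismTruth()
    transwell: TranswellTruth = TranswellTruth()
    expression: ExpressionTruth = ExpressionTruth()

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def default(cls, seed: int) -> "SyntheticTruth":
        return cls(seed=seed)


def _noise(rng: np.random.Generator, cv: float, size=None):
    """Unit-mean multiplicative log-normal noise with the given CV.

    ``size=None`` returns a scalar, matching numpy convention.
    """
    if cv <= 0:
        return 1.0 if size is None else np.ones(size)
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def _pl4(c: float, top: float, bottom: float, ic50: float, hill: float) -> float:
    if c <= 0:
        return top
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def survival_fraction(c_drug: float, c_inh: float, truth: SyntheticTruth,
                      efflux_factor: float | None = None) -> float:
    """Noiseless T/C for a taxane/inhibitor combination well.

    ``efflux_factor`` overrides the mechanism's E (0 for a parental
    line).  The limit c_inh >> Ki gives C_eff -> c_drug: full reversal.
    """
    v, m = truth.viability, truth.mechanism
    e = m.efflux_factor if efflux_factor is None else efflux_factor
    occ = 1.0 - c_inh / (c_inh + m.inhibitor_ki) if c_inh > 0 else 1.0
    c_eff = c_drug / (1.0 + e * occ)
    s_drug = _pl4(c_eff, v.top, v.bottom, v.ic50, v.hill)
    s_inh = _pl4(c_inh, 1.0, 0.0, m.inhibitor_intrinsic_ic50, m.inhibitor_hill)
    return s_drug * s_inh


def gen_viability_plate(truth: SyntheticTruth, conc_a, conc_b,
                        replicates: int = 2, seed: int | None = None,
                        efflux_factor: float | None = None,
                        assay_id: str = "assay1", cell_line: str = "cellline",
                        drug_a: str = "docetaxel", drug_b: str = "ritonavir",
                        n_controls: int = 6,
                        control_mean: float = 10_000.0) -> pd.DataFrame:
    """Long-format plate table of raw signals for a checkerboard design.

    ``conc_a`` / ``conc_b`` are molar grids; grids may include 0 (the
    crossed zeros are the single-agent rows).  Six untreated control
    wells are included per plate, as in a 96-well design.  Output
    columns follow the plate.csv schema with concentrations in nM
    (drug A) and uM (drug B).
    """
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    v = truth.viability
    rows = []
    for rep in range(1, replicates + 1):
        for ca in np.atleast_1d(conc_a):
            for cb in np.atleast_1d(conc_b):
                if ca == 0 and cb == 0:
                    continue  # untreated cells live in the control wells
                s = survival_fraction(float(ca), float(cb), truth, efflux_factor)
                signal = control_mean * s * _noise(rng, v.noise_cv, None)
                rows.append((assay_id, cell_line, drug_a, ca * 1e9, "nM",
                             drug_b, cb * 1e6, "uM", rep, float(signal), 0))
    for i in range(n_controls):
        signal = control_mean * _noise(rng, v.noise_cv, None)
        rows.append((assay_id, cell_line, drug_a, 0.0, "nM",
                     drug_b, 0.0, "uM", i + 1, float(signal), 1))
    return pd.DataFrame(rows, columns=[
        "assay_id", "cell_line", "drug_a", "conc_a", "unit_a",
        "drug_b", "conc_b", "unit_b", "replicate", "signal", "is_control",
    ])


def simulate_tc_matrix(truth: SyntheticTruth, conc_a=None, conc_b=None,
                       replicates: int = 2, seed: int | None = None,
                       efflux_factor: float | None = None,
                       noise_cv: float | None = None,
                       bliss_null: bool = False, meta: dict | None = None):
    """Directly simulate a replicate T/C checkerboard (fast path).

    With ``bliss_null=True`` the combination effect is forced to the
    exact product of the single-agent survivals (multiplicative null),
    regardless of the efflux mechanism - the calibration case for
    false-call rates.  Returns a :class:`effluxkit.synergy.TCMatrix`
    whose grids include the leading 0 concentration.
    """
    from .synergy import TCMatrix

    rng = np.random.default_rng(truth.seed if seed is None else seed)
    cv = truth.viability.noise_cv if noise_cv is None else noise_cv
    conc_a = DOCETAXEL_GRID_5 if conc_a is None else np.asarray(conc_a, float)
    conc_b = RITONAVIR_GRID_5 if conc_b is None else np.asarray(conc_b, float)
    ca = np.concatenate([[0.0], conc_a])
    cb = np.concatenate([[0.0], conc_b])
    reps = np.full((len(ca), len(cb), replicates), np.nan)
    for i, a in enumerate(ca):
        for j, b in enumerate(cb):
            if i == 0 and j == 0:
                reps[i, j, :] = 1.0
                continue
            if bliss_null and i > 0 and j > 0:
                s = (survival_fraction(a, 0.0, truth, efflux_factor)
                     * survival_fraction(0.0, b, truth, efflux_factor))
            else:
                s = survival_fraction(a, b, truth, efflux_factor)
            reps[i, j, :] = s * _noise(rng, cv, replicates)
    return TCMatrix(conc_a=ca, conc_b=cb, replicates=reps,
                    meta=meta or {"drug_a": "docetaxel", "drug_b": "ritonavir"})


def gen_transwell(truth: SyntheticTruth, conditions=None, replicates: int = 3,
                  seed: int | None = None) -> pd.DataFrame:
    """Bidirectional transwell sample table for a list of conditions.

    Each condition is a dict with keys ``compound``, ``inhibitor``
    (name or None), ``c_inh`` (molar), ``conc_uM``, ``time_min`` and
    optionally ``ki`` (molar, overriding the truth's inhibitor Ki -
    reference inhibitors differ widely in potency).  Defaults reproduce
    the study design: docetaxel at 5 and 10 uM, 60 and 120 min, alone
    and with 10 uM valspodar or 50 uM ritonavir.
    """
    t = truth.transwell
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    if conditions is None:
        conditions = []
        for conc in (5.0, 10.0):
            for tmin in (60.0, 120.0):
                conditions += [
                    {"compound": "docetaxel", "inhibitor": None,
                     "c_inh": 0.0, "conc_uM": conc, "time_min": tmin},
                    {"compound": "docetaxel", "inhibitor": "valspodar",
                     "c_inh": 10e-6, "ki": 0.05e-6,
                     "conc_uM": conc, "time_min": tmin},
                    {"compound": "docetaxel", "inhibitor": "ritonavir",
                     "c_inh": 50e-6, "conc_uM": conc, "time_min": tmin},
                ]
    rows = []
    for cond in conditions:
        c_inh = float(cond.get("c_inh", 0.0))
        ki = float(cond.get("ki", t.inhibitor_ki))
        occ = 1.0 - c_inh / (c_inh + ki) if c_inh > 0 else 1.0
        c0 = cond["conc_uM"] * 1e3  # pmol/cm^3
        dt = cond["time_min"] * 60.0
        for direction in ("A_B", "B_A"):
            if direction == "A_B":
                p_true = t.p_passive / (1.0 + t.efflux_multiplier * occ)
                v_donor = t.donor_volume_ab
            else:
                p_true = t.p_passive * (1.0 + t.efflux_multiplier * occ)
                v_donor = t.donor_volume_ba
            q0 = c0 * v_donor
            dq_true = p_true * t.area_cm2 * c0 * dt
            cells_true = t.cell_fraction * q0
            donor_true = q0 - dq_true - cells_true
            if donor_true < 0:
                raise ValueError("transwell design exhausts the donor chamber")
            for rep in range(1, replicates + 1):
                dq = dq_true * float(_noise(rng, t.noise_cv, None))
                cells = cells_true * float(_noise(rng, t.noise_cv, None))
                donor = donor_true * float(_noise(rng, t.noise_cv, None))
                q_apical = donor if direction == "A_B" else dq
                q_basolateral = dq if direction == "A_B" else donor
                rows.append({
                    "compound": cond["compound"],
                    "inhibitor": cond["inhibitor"] or "",
                    "direction": direction,
                    "conc_uM": cond["conc_uM"],
                    "time_min": cond["time_min"],
                    "area_cm2": t.area_cm2,
                    "dq_pmol": dq,
                    "q_apical": q_apical,
                    "q_basolateral": q_basolateral,
                    "q_cells": cells,
                    "q0": q0,
                    "replicate": rep,
                    "qc_pass": 1,
                })
    return pd.DataFrame(rows)


def gen_counts(truth: SyntheticTruth, n_per_group: int = 3,
               seed: int | None = None, line: str = "DU-145",
               de_genes: dict | None = None,
               baseline_seed: int | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Negative-binomial count matrix for one parental/resistant pair.

    Returns (counts, samples): genes x (2 * n_per_group) integer counts
    and a sample sheet with ``sample``, ``line`` and ``group`` columns.
    ``de_genes`` (name -> fold applied to the resistant group) defaults
    to the truth's configuration, which includes an ABCB1-like gene at ~3000x.
    Pass ``de_genes={}`` for a null dataset.

    ``baseline_seed`` fixes the gene-mean baseline independently of the
    sampling seed, so two lines generated with the same baseline seed
    share a transcriptome (modulated by a per-line log-normal wobble of
    sd ``line_effect_sd``) - as real cell lines do.
    """
    e = truth.expression
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    base_rng = (rng if baseline_seed is None
                else np.random.default_rng(baseline_seed))
    de = e.de_genes if de_genes is None else de_genes
    names = list(de.keys())
    names += [f"G{i:06d}" for i in range(e.n_genes - len(names))]
    base = base_rng.lognormal(mean=e.baseline_log_mean, sigma=e.baseline_log_sd,
                              size=e.n_genes)
    line_effect = rng.lognormal(mean=0.0, sigma=e.line_effect_sd, size=e.n_genes)
    base = base * line_effect
    fold = np.ones(e.n_genes)
    for i, name in enumerate(de.keys()):
        fold[i] = de[name]
        # expressed state sits at de_expressed_mean; the silent state
        # at de_expressed_mean / |fold|
        expressed = e.de_expressed_overrides.get(name, e.de_expressed_mean)
        base[i] = expressed / fold[i] if fold[i] >= 1.0 else expressed

    n_nb = 1.0 / e.nb_dispersion
    cols = {}
    samples = []
    for g, group in enumerate(("parental", "resistant")):
        mu = base * (fold if group == "resistant" else 1.0)
        for r in range(1, n_per_group + 1):
            p = n_nb / (n_nb + mu)
            cols[f"{line}_{group}_{r}"] = rng.negative_binomial(n_nb, p)
            samples.append({"sample": f"{line}_{group}_{r}",
                            "line": line, "group": group})
    counts = pd.DataFrame(cols, index=pd.Index(names, name="gene"))
    return counts, pd.DataFrame(samples)


def gen_study(truth: SyntheticTruth, out_dir=None, seed: int | None = None):
    """Synthesize the full study: plates, transwell table and counts.

    Produces single-agent titrations and checkerboards for a parental
    (E = 0) and a resistant line, the bidirectional transwell design,
    and triplicate counts for two parental/resistant pairs (12
    samples).  If ``out_dir`` is given, writes plate.csv,
    transwell.csv, counts.tsv, samples.tsv and truth.json there.
    Returns a dict of in-memory tables.
    """
    from pathlib import Path

    seed = truth.seed if seed is None else seed
    e_res = truth.mechanism.efflux_factor

    plates = []
    for i, (cell_line, e_factor) in enumerate(
            [("DU-145", 0.0), ("DU-145DOC10", e_res)]):
        plates.append(gen_viability_plate(
            truth, SINGLE_AGENT_GRID, [0.0], replicates=2, seed=seed + 10 + i,
            efflux_factor=e_factor, assay_id=f"titration_{cell_line}",
            cell_line=cell_line))
    plates.append(gen_viability_plate(
        truth, np.concatenate([[0.0], DOCETAXEL_GRID_5]),
        np.concatenate([[0.0], RITONAVIR_GRID_5]), replicates=2,
        seed=seed + 20, efflux_factor=0.0,
        assay_id="checkerboard_DU-145", cell_line="DU-145"))
    plates.append(gen_viability_plate(
        truth, np.concatenate([[0.0], DOCETAXEL_GRID_8]),
        np.concatenate([[0.0], RITONAVIR_GRID_2]), replicates=2,
        seed=seed + 21, efflux_factor=e_res,
        assay_id="checkerboard_DU-145DOC10", cell_line="DU-145DOC10"))
    plate = pd.concat(plates, ignore_index=True)

    transwell = gen_transwell(truth, seed=seed + 30)

    c1, s1 = gen_counts(truth, seed=seed + 40, line="DU-145",
                        baseline_seed=seed + 39)
    c2, s2 = gen_counts(truth, seed=seed + 41, line="22Rv1",
                        baseline_seed=seed + 39)
    counts = pd.concat([c1, c2], axis=1)
    samples = pd.concat([s1, s2], ignore_index=True)

    out = {"plate": plate, "transwell": transwell, "counts": counts,
           "samples": samples, "truth": truth}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        plate.to_csv(out_dir / "plate.csv", index=False)
        transwell.to_csv(out_dir / "transwell.csv", index=False)
        counts.to_csv(out_dir / "counts.tsv", sep="\t")
        samples.to_csv(out_dir / "samples.tsv", sep="\t", index=False)
        (out_dir / "truth.json").write_text(truth.to_json())
    return out
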
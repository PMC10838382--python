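"""Readers/writers for the delimited-text formats the toolkit consumes.

plate.csv    long-format viability wells (see gen_viability_plate schema)
transwell.csv  bidirectional transport samples
counts.tsv / samples.tsv   gene x sample counts with a sample sheet
fits.csv     one fitted 4PL row per (assay, cell line, drug)

Concentrations are stored internally in molar; plate files carry an
explicit unit column (M/mM/uM/nM) per drug.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dose_response import DoseResponseData, FourPLFit
from .synergy import TCMatrix

__all__ = [
    "UNIT_SCALE",
    "read_plate_csv",
    "plate_to_dose_response",
    "plate_to_tc_matrix",
    "write_fits_csv",
    "read_transwell_csv",
    "read_counts",
]

UNIT_SCALE = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9}

_PLATE_COLUMNS = [
    "assay_id", "cell_line", "drug_a", "conc_a", "unit_a",
    "drug_b", "conc_b", "unit_b", "replicate", "signal", "is_control",
]


def _to_molar(conc: pd.Series, unit: pd.Series) -> pd.Series:
    bad = ~unit.isin(UNIT_SCALE)
    if bad.any():
        raise ValueError(f"unknown concentration unit(s): {sorted(unit[bad].unique())}")
    return conc * unit.map(UNIT_SCALE)


def read_plate_csv(path) -> pd.DataFrame:
    """Read a long-format plate table and add molar columns conc_a_M/conc_b_M."""
    df = pd.read_csv(path)
    missing = set(_PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns: {sorted(missing)}")
    df["conc_a_M"] = _to_molar(df["conc_a"], df["unit_a"])
    df["conc_b_M"] = _to_molar(df["conc_b"], df["unit_b"])
    return df


def plate_to_dose_response(df: pd.DataFrame) -> list[DoseResponseData]:
    """Split a plate table into single-agent dose-response series.

    For each assay, the untreated control wells (is_control = 1) set the
    T/C denominator.  A series is emitted per varying drug: drug A rows
    with conc_b = 0, and drug B rows with conc_a = 0.
    """
    out = []
    for assay_id, grp in df.groupby("assay_id", sort=False):
        controls = grp.loc[grp["is_control"] == 1, "signal"].tolist()
        cell_line = grp["cell_line"].iloc[0]
        for drug_col, conc_col, other_conc in (
                ("drug_a", "conc_a_M", "conc_b_M"),
                ("drug_b", "conc_b_M", "conc_a_M")):
            sub = grp[(grp["is_control"] == 0)
                      & (grp[other_conc] == 0) & (grp[conc_col] > 0)]
            if sub[conc_col].nunique() >= 4:
                points = list(zip(sub[conc_col], sub["signal"],
                                  sub["replicate"].astype(int)))
                out.append(DoseResponseData(
                    assay_id=assay_id, cell_line=cell_line,
                    drug=sub[drug_col].iloc[0], points=points,
                    controls=controls))
    return out


def plate_to_tc_matrix(df: pd.DataFrame, assay_id: str) -> TCMatrix:
    """Build a replicate T/C checkerboard for one assay of a plate table."""
    grp = df[df["assay_id"] == assay_id]
    if grp.empty:
        raise ValueError(f"assay {assay_id!r} not found in plate table")
    controls = grp.loc[grp["is_control"] == 1, "signal"]
    if controls.empty or controls.mean() <= 0:
        raise ValueError(f"assay {assay_id!r} lacks valid control wells")
    wells = grp[grp["is_control"] == 0].copy()
    wells["tc"] = wells["signal"] / controls.mean()
    long = pd.DataFrame({"conc_a": wells["conc_a_M"].to_numpy(),
                         "conc_b": wells["conc_b_M"].to_numpy(),
                         "tc": wells["tc"].to_numpy()})
    # the untreated reference cell is implicit (controls): add it explicitly
    long = pd.concat(
        [long, pd.DataFrame({"conc_a": [0.0], "conc_b": [0.0], "tc": [1.0]})],
        ignore_index=True)
    meta = {"assay_id": assay_id, "cell_line": grp["cell_line"].iloc[0],
            "drug_a": grp["drug_a"].iloc[0], "drug_b": grp["drug_b"].iloc[0]}
    return TCMatrix.from_long(long, meta=meta)


def write_fits_csv(fits: list[tuple[str, str, str, FourPLFit]], path) -> None:
    """Write fits.csv: assay, cell line, drug, 4PL parameters, censoring."""
    rows = [{
        "assay_id": a, "cell_line": c, "drug": d,
        "top": f.top, "bottom": f.bottom,
        "ic50_rel_nM": f.ic50_rel * 1e9,
        "ic50_display": f.format_ic50("nM"),
        "hill": f.hill, "censored": f.censored, "rss": f.rss,
    } for a, c, d, f in fits]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_transwell_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"compound", "inhibitor", "direction", "conc_uM", "time_min",
                "area_cm2", "dq_pmol", "q_apical", "q_basolateral",
                "q_cells", "q0", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"transwell table missing columns: {sorted(missing)}")
    return df


def read_counts(counts_path, samples_path) -> tuple[pd.DataFrame, pd.Series]:
    """Read counts.tsv (genes x samples) and samples.tsv; returns (counts, groups)."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t")
    if not set(samples["sample"]) <= set(counts.columns):
        raise ValueError("sample sheet lists samples absent from the count matrix")
    groups = samples.set_index("sample")["group"]
    if counts.index.duplicated().any():
        raise ValueError("duplicate gene ids in count matrix")
    return counts[samples["sample"].tolist()], groups
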
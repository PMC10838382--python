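"""End-to-end orchestration: dose-response -> Bliss -> transwell -> expression.

``run_pipeline`` consumes a directory of input tables (any subset of
plate.csv, transwell.csv, counts.tsv + samples.tsv), runs every
applicable stage with the thresholds in a :class:`RunConfig`, and
writes machine-readable outputs plus a short human-readable report.
Every output directory carries the serialized config, its hash and the
seed, so two runs with equal hashes are identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import expression, io, synergy, transwell
from .config import RunConfig
from .dose_response import FitFailureError, fit_dose_response

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; partial results (if any) are preserved on disk."""


def run_pipeline(config: RunConfig, in_dir, out_dir) -> dict:
    """Run all stages whose inputs exist under ``in_dir``.

    Returns the summary dict (also written to summary.json).  Raises
    :class:`PipelineError` if no stage input is found or a schema/fit
    error occurs.
    """
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level))

    summary: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    config.to_yaml(out_dir / "run_config.yaml")
    ran_any = False

    plate_path = in_dir / "plate.csv"
    if plate_path.exists():
        ran_any = True
        summary["stages"].update(_stage_plates(config, plate_path, out_dir))

    tw_path = in_dir / "transwell.csv"
    if tw_path.exists():
        ran_any = True
        summary["stages"]["transwell"] = _stage_transwell(config, tw_path, out_dir)

    counts_path, samples_path = in_dir / "counts.tsv", in_dir / "samples.tsv"
    if counts_path.exists() and samples_path.exists():
        ran_any = True
        summary["stages"]["expression"] = _stage_expression(
            config, counts_path, samples_path, out_dir)

    if not ran_any:
        raise PipelineError(f"no recognised inputs under {in_dir}")

    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    (out_dir / "report.txt").write_text(_render_report(summary))
    return summary


def _stage_plates(config: RunConfig, plate_path: Path, out_dir: Path) -> dict:
    df = io.read_plate_csv(plate_path)
    fits, fit_summaries = [], {}
    for series in io.plate_to_dose_response(df):
        try:
            fit = fit_dose_response(series)
        except FitFailureError as exc:
            raise PipelineError(
                f"dose-response fit failed for {series.assay_id}") from exc
        fits.append((series.assay_id, series.cell_line, series.drug, fit))
        fit_summaries[f"{series.assay_id}:{series.drug}"] = {
            "cell_line": series.cell_line,
            "ic50_nM": fit.format_ic50("nM"),
            "censored": fit.censored,
        }
    io.write_fits_csv(fits, out_dir / "fits.csv")

    bliss_summaries = {}
    for assay_id in df["assay_id"].unique():
        sub = df[df["assay_id"] == assay_id]
        combos = sub[(sub["is_control"] == 0)
                     & (sub["conc_a_M"] > 0) & (sub["conc_b_M"] > 0)]
        if combos.empty:
            continue  # titration-only assay
        m = io.plate_to_tc_matrix(df, assay_id)
        result = synergy.analyze_matrix(m, bi_threshold=config.bi_threshold,
                                        flag_fraction=config.flag_fraction)
        adir = out_dir / f"bliss_{assay_id}"
        adir.mkdir(exist_ok=True)
        synergy.write_matrix_csv(adir / "bliss_modeled_tc.csv",
                                 synergy.clip_for_display(m.modeled),
                                 m.conc_a, m.conc_b)
        synergy.write_matrix_csv(adir / "bliss_index.csv", result.index,
                                 m.conc_a, m.conc_b)
        (adir / "bliss_call.json").write_text(result.to_json())
        bliss_summaries[assay_id] = {"call": result.call, **result.counts}
    return {"dose_response": fit_summaries, "bliss": bliss_summaries}


def _stage_transwell(config: RunConfig, tw_path: Path, out_dir: Path) -> dict:
    df = io.read_transwell_csv(tw_path)
    results = transwell.analyze_transwell(df, er_cutoff=config.er_cutoff)
    results.to_csv(out_dir / "transwell_results.csv", index=False)
    calls = {}
    for row in results.itertuples():
        key = (f"{row.compound}"
               + (f"+{row.inhibitor}" if row.inhibitor else "")
               + f" {row.conc_uM}uM {row.time_min:.0f}min")
        calls[key] = {"er": round(row.er, 2),
                      "substrate_call": row.substrate_call,
                      "inhibition_call": row.inhibition_call}
    return calls


def _stage_expression(config: RunConfig, counts_path: Path,
                      samples_path: Path, out_dir: Path) -> dict:
    counts, groups = io.read_counts(counts_path, samples_path)
    logexpr = expression.log_cpm(counts, pseudocount=config.pseudocount)
    qc = expression.outlier_stats(logexpr, z_cutoff=config.outlier_z_cutoff)
    (out_dir / "qc_report.json").write_text(qc.to_json())

    out = {"n_samples": int(counts.shape[1]),
           "outlier_flags": qc.flagged_samples, "contrasts": {}}
    samples = groups.index.to_series()
    # one contrast per cell line present in the sample sheet (if encoded
    # as "<line>_<group>_<rep>"), otherwise a single two-group contrast
    lines = sorted({s.rsplit("_", 2)[0] for s in samples if s.count("_") >= 2})
    contrasts = ([(line, samples[samples.str.startswith(line + "_")])
                  for line in lines] if lines else [("all", samples)])
    for name, cols in contrasts:
        sub_groups = groups.loc[cols]
        if sub_groups.nunique() != 2:
            continue
        stats_table = expression.two_group_test(logexpr[cols.tolist()], sub_groups)
        deg = expression.deg_filter(
            stats_table, fold_threshold=config.deg_fold_threshold,
            fdr_threshold=config.deg_fdr_threshold)
        deg.to_csv(out_dir / f"deg_table_{name}.tsv", sep="\t")
        degs = deg[deg["is_deg"]].sort_values("log2_fold_change",
                                              ascending=False)
        out["contrasts"][name] = {
            "n_deg": int(deg["is_deg"].sum()),
            "top_up_gene": degs.index[0] if len(degs) else None,
            "top_up_fold": float(degs["fold_change"].iloc[0]) if len(degs) else None,
        }
    return out


def _render_report(summary: dict) -> str:
    lines = [
        "effluxkit pipeline report",
        f"config hash: {summary['config_hash']}  seed: {summary['seed']}",
        "",
    ]
    stages = summary["stages"]
    if "dose_response" in stages:
        lines.append("Dose-response fits (relative IC50):")
        for key, fit in stages["dose_response"].items():
            lines.append(f"  {key} [{fit['cell_line']}]: {fit['ic50_nM']} nM")
    if stages.get("bliss"):
        lines.append("Bliss combination calls:")
        for assay, res in stages["bliss"].items():
            lines.append(
                f"  {assay}: {res['call']} "
                f"(synergy {res['n_synergy']}/{res['n_total']} cells)")
    if "transwell" in stages:
        lines.append("Transwell efflux:")
        for key, res in stages["transwell"].items():
            lines.append(
                f"  {key}: ER {res['er']} {res['substrate_call']} "
                f"{res['inhibition_call']}")
    if "expression" in stages:
        expr = stages["expression"]
        lines.append(
            f"Expression screen: {expr['n_samples']} samples, "
            f"outliers: {expr['outlier_flags'] or 'none'}")
        for name, c in expr["contrasts"].items():
            lines.append(
                f"  {name}: {c['n_deg']} DEGs; top up-regulated "
                f"{c['top_up_gene']} ({c['top_up_fold']:.0f}-fold)"
                if c["top_up_gene"] else f"  {name}: {c['n_deg']} DEGs")
    return "\n".join(lines) + "\n"
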
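"""End-to-end orchestration: simulate -> consensus -> size-select ->
quantify -> error-profile -> ddPCR -> report.

A run is governed by one configuration mapping (YAML on disk) and one seed.
Size selection is applied to *molecules* before amplification — selecting a
library molecule selects all its future PCR duplicates, as in the physical
workflow where gel extraction precedes the final amplification — and every
fraction is then sequenced at the same total read count, so family-size
effects of reduced complexity emerge rather than being imposed.

The report stage recomputes comparative statistics (paired/independent t with
a Levene pre-test, one-way ANOVA with Tukey's post-hoc, Pearson correlation)
directly from the stored tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import consensus as cons
from . import ddpcr, errorprofile, quantify, simulate, sizeselect

log = logging.getLogger("cfsieve")

DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "cfsieve_run",
    "stages": ["simulate", "consensus", "sizeselect", "quantify",
               "errorprofile", "ddpcr", "report"],
    "sim": {},  # overrides for SimConfig fields
    "n_locus_molecules": 4000,
    "n_background_molecules": 20000,
    "fs_max": 20,
    "fs_thresholds": [1, 5, 10, 15, 20],
    "fractions": ["short", "long"],
    "leak_scale_bp": 5.0,
    "write_sam": False,
    "ddpcr": {
        "n_droplets": 100000,
        "false_positive_lambda": 0.5,
        "n_controls": 12,
        "ddpcr_input_mass_ng": 10.0,
        "ngs_input_mass_ng": 10.0,
        "reaction_fraction_analyzed": 1.0,
        "input_volume_ul": 10.0,
        "extract_volume_ul": 50.0,
        "plasma_volume_ml": 8.0,
    },
}


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(path_or_dict or {})
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for k, v in user.items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not serializable: {type(o)}")


def _write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)


# ---------------------------------------------------------------------------
# report arithmetic

def percent_difference(counts_fraction: float, counts_unselected: float
                       ) -> float | None:
    """Signed percent difference of a fraction's counts vs unselected."""
    if counts_unselected == 0:
        return None
    return 100.0 * (counts_fraction - counts_unselected) / counts_unselected


def compare_statistics(groups: dict, paired: bool = False,
                       correlates: tuple | None = None,
                       alpha: float = 0.05) -> dict:
    """Standard comparative statistics over named groups of values.

    Two groups: Levene's test chooses pooled vs Welch t (paired t when
    ``paired``).  Three or more: one-way ANOVA plus Tukey's HSD.  An optional
    (x, y) pair adds Pearson's r.  Groups too small for a statistic are
    reported as omitted with the reason.
    """
    out: dict = {"alpha": alpha}
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    names = list(arrays)
    if any(len(a) < 2 for a in arrays.values()):
        out["omitted"] = "every group needs >= 2 observations"
        arrays = {}
        names = []
    if len(names) == 2:
        a, b = arrays[names[0]], arrays[names[1]]
        if paired:
            t, p = sps.ttest_rel(a, b)
            out["t_test"] = {"kind": "paired", "t": float(t), "p": float(p)}
        else:
            lv_stat, lv_p = sps.levene(a, b)
            equal_var = lv_p >= alpha
            t, p = sps.ttest_ind(a, b, equal_var=equal_var)
            out["levene"] = {"stat": float(lv_stat), "p": float(lv_p)}
            out["t_test"] = {"kind": "pooled" if equal_var else "welch",
                             "t": float(t), "p": float(p)}
    if len(names) >= 3:
        f, p = sps.f_oneway(*arrays.values())
        out["anova"] = {"F": float(f), "p": float(p)}
        hsd = sps.tukey_hsd(*arrays.values())
        pairs = []
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                pairs.append({"a": names[i], "b": names[j],
                              "p": float(hsd.pvalue[i, j]),
                              "significant": bool(hsd.pvalue[i, j] < alpha)})
        out["tukey"] = pairs
    if correlates is not None:
        x, y = (np.asarray(v, dtype=float) for v in correlates)
        if len(x) >= 2 and len(x) == len(y):
            r, p = sps.pearsonr(x, y)
            out["pearson"] = {"r": float(r), "p": float(p)}
        else:
            out["pearson"] = {"omitted": "need >= 2 paired observations"}
    return out


# ---------------------------------------------------------------------------
# pipeline

class StageError(RuntimeError):
    pass


def run_pipeline(config, out_dir=None) -> Path:
    """Run the configured stages; returns the artifact directory.

    Every stage writes its metrics as JSON; identical config and seed give
    identical artifacts.
    """
    cfg = load_config(config)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    state: dict = {"cfg": cfg}
    try:
        for stage in cfg["stages"]:
            fn = _STAGES.get(stage)
            if fn is None:
                raise StageError(f"unknown stage: {stage}")
            t0 = time.perf_counter()
            log.info("stage %s: start", stage)
            try:
                fn(state, out)
            except Exception as exc:  # noqa: BLE001 - name the failing stage
                raise StageError(f"stage {stage} failed: {exc}") from exc
            log.info("stage %s: done in %.2fs", stage, time.perf_counter() - t0)
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _sim_config(cfg) -> simulate.SimConfig:
    return simulate.SimConfig(seed=cfg["seed"], **cfg["sim"])


def _stage_simulate(state, out: Path) -> None:
    cfg = state["cfg"]
    sim_cfg = _sim_config(cfg)
    ref = simulate.make_reference(sim_cfg)
    ref.write_fasta(out / "reference.fasta")
    ref.write_bed(out / "panel.bed")
    assay = quantify.VariantAssay.from_reference(ref)
    quantify.assays_to_tsv([assay], out / "assays.tsv")
    rng = sim_cfg.rng(1)
    cohort = simulate.simulate_fragments(sim_cfg, ref, cfg["n_locus_molecules"],
                                         rng=rng)
    background = []
    if cfg["n_background_molecules"]:
        background = simulate.simulate_background_fragments(
            sim_cfg, ref, cfg["n_background_molecules"], rng=rng,
            id_offset=len(cohort))
    state.update(sim_cfg=sim_cfg, reference=ref, assay=assay,
                 cohort=cohort, fragments=cohort + background)
    n_var = sum(f.allele_class == "VARIANT" for f in cohort)
    _write_json({
        "n_locus_molecules": len(cohort),
        "n_background_molecules": len(background),
        "n_variant_molecules": n_var,
        "template_vaf_percent": 100.0 * n_var / len(cohort) if cohort else None,
        "panel_bp": ref.panel_length(),
    }, out / "simulate_metrics.json")


def _require(state, key, stage):
    if key not in state:
        raise StageError(f"{stage} requires an earlier stage providing {key}")
    return state[key]


def _sequence_library(fragments, sim_cfg, rng) -> list:
    reads = simulate.amplify_and_sequence(fragments, sim_cfg, rng=rng)
    fams, excluded = cons.group_families(reads)
    return cons.consensus_reads(fams), fams, excluded


def _stage_consensus(state, out: Path) -> None:
    cfg = state["cfg"]
    sim_cfg = _require(state, "sim_cfg", "consensus")
    fragments = _require(state, "fragments", "consensus")
    rng = sim_cfg.rng(4)
    consensuses, fams, excluded = _sequence_library(fragments, sim_cfg, rng)
    state["libraries"] = {"unselected": consensuses}
    metrics = cons.run_metrics(None, fams, consensuses,
                               state["reference"].intervals)
    metrics["excluded_reads"] = dict(excluded)
    spectrum = cons.family_size_spectrum(consensuses, cfg["fs_max"])
    metrics["family_size_spectrum"] = spectrum.tolist()
    _write_json(metrics, out / "consensus_metrics.json")
    if cfg.get("write_sam"):
        cons.write_consensus_sam(
            consensuses, {state["reference"].chrom: len(state["reference"])},
            out / "consensus_unselected.sam")


def _stage_sizeselect(state, out: Path) -> None:
    cfg = state["cfg"]
    sim_cfg = _require(state, "sim_cfg", "sizeselect")
    fragments = _require(state, "fragments", "sizeselect")
    rng = sim_cfg.rng(5)
    reports = []
    for label in cfg["fractions"]:
        window = sizeselect.SizeWindow.default(label, cfg["leak_scale_bp"])
        kept, report = sizeselect.select_fraction(fragments, window, seed=rng)
        consensuses, fams, _ = _sequence_library(kept, sim_cfg, rng)
        state["libraries"][label] = consensuses
        rep = dataclasses.asdict(report)
        rep["mean_family_size"] = cons.run_metrics(
            None, fams, consensuses)["mean_family_size"]
        reports.append(rep)
    pd.DataFrame(reports).to_csv(out / "fraction_reports.tsv", sep="\t",
                                 index=False)
    state["fraction_reports"] = reports


def _stage_quantify(state, out: Path) -> None:
    cfg = state["cfg"]
    assay = _require(state, "assay", "quantify")
    libraries = _require(state, "libraries", "quantify")
    tables = []
    for label, consensuses in libraries.items():
        tab = quantify.vaf_table(consensuses, assay, cfg["fs_max"])
        tab.insert(0, "library", label)
        tables.append(tab)
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(out / "vaf_table.tsv", sep="\t", index=False)
    state["vaf_table"] = table

    base = table[(table.library == "unselected") & (table.fs_threshold == 1)]
    summary = {}
    if len(base):
        v0 = base.vaf_percent.iloc[0]
        wt0, var0 = int(base.wt_count.iloc[0]), int(base.variant_count.iloc[0])
        for label in libraries:
            row = table[(table.library == label) & (table.fs_threshold == 1)]
            if not len(row):
                continue
            summary[label] = {
                "vaf_percent": None if pd.isna(row.vaf_percent.iloc[0])
                else float(row.vaf_percent.iloc[0]),
                "fold_change": quantify.enrichment_fold_change(
                    row.vaf_percent.iloc[0], v0),
                "wt_percent_difference": percent_difference(
                    int(row.wt_count.iloc[0]), wt0),
                "variant_percent_difference": percent_difference(
                    int(row.variant_count.iloc[0]), var0),
            }
    insert_stats = {
        label: quantify.insert_size_summary(consensuses, assay)
        for label, consensuses in libraries.items()}
    _write_json({"fold_changes": summary, "insert_sizes": insert_stats},
                out / "quantify_metrics.json")
    state["quantify_summary"] = summary


def _stage_errorprofile(state, out: Path) -> None:
    cfg = state["cfg"]
    ref = _require(state, "reference", "errorprofile")
    libraries = _require(state, "libraries", "errorprofile")
    tables = errorprofile.estimate_error_rates(
        libraries["unselected"], ref.intervals, ref.sequence, ref.chrom,
        fs_thresholds=tuple(cfg["fs_thresholds"]))
    errorprofile.error_tables_to_tsv(tables, out / "error_rates.tsv")
    afs = errorprofile.nonref_af_scan(
        libraries["unselected"], ref.intervals, ref.sequence, ref.chrom,
        fs_thresholds=tuple(cfg["fs_thresholds"]), sample_id="unselected")
    errorprofile.positionaf_to_bed(afs, out / "nonref_af.bed")
    state["error_tables"] = tables


def _stage_ddpcr(state, out: Path) -> None:
    cfg = state["cfg"]
    sim_cfg = _require(state, "sim_cfg", "ddpcr")
    # a ddPCR assay only counts molecules containing its amplicon,
    # i.e. the assay-locus cohort
    cohort = _require(state, "cohort", "ddpcr")
    d = cfg["ddpcr"]
    n_var = sum(f.allele_class == "VARIANT" for f in cohort)
    n_wt = sum(f.allele_class == "WT" for f in cohort)
    rng = sim_cfg.rng(6)
    exp = simulate.DropletExperiment(d["n_droplets"], n_wt, n_var,
                                    d["false_positive_lambda"])
    counts = simulate.simulate_droplets(exp, rng)
    wt_conc = ddpcr.concentration(counts, "wt")
    var_conc = ddpcr.concentration(counts, "variant")
    controls = [int(rng.poisson(d["false_positive_lambda"]))
                for _ in range(d["n_controls"])]
    lob = ddpcr.fit_lob(controls)
    result = {
        "droplet_counts": dataclasses.asdict(counts),
        "wt_copies": wt_conc.total_copies,
        "variant_copies": var_conc.total_copies,
        "vaf_percent": ddpcr.vaf_from_droplets(counts),
        "lob": dataclasses.asdict(lob),
        "expected_ngs_variant_counts": None,
        "variant_copies_per_ml_plasma": None,
    }
    if var_conc.quantifiable:
        result["expected_ngs_variant_counts"] = ddpcr.expected_ngs_counts(
            var_conc.total_copies, d["ddpcr_input_mass_ng"],
            d["ngs_input_mass_ng"])
        result["variant_copies_per_ml_plasma"] = ddpcr.copies_per_ml_plasma(
            var_conc.total_copies, d["reaction_fraction_analyzed"],
            d["input_volume_ul"], d["extract_volume_ul"],
            d["plasma_volume_ml"])
    _write_json(result, out / "ddpcr_metrics.json")
    state["ddpcr_result"] = result


def _stage_report(state, out: Path) -> None:
    cfg = state["cfg"]
    report: dict = {"seed": cfg["seed"]}
    table = state.get("vaf_table")
    if table is not None:
        libs = sorted(set(table.library))
        # VAF trajectories across FS thresholds per library
        groups = {}
        for label in libs:
            sub = table[table.library == label].dropna(subset=["vaf_percent"])
            if len(sub) >= 2:
                groups[label] = sub.vaf_percent.to_numpy()
        if len(groups) >= 2:
            report["vaf_by_library"] = compare_statistics(groups)
        rpc = {}
        for label in libs:
            sub = table[table.library == label]
            ref_row = sub[sub.fs_threshold == 1]
            if not len(ref_row):
                continue
            v1 = ref_row.vaf_percent.iloc[0]
            rpc[label] = {
                int(r.fs_threshold): quantify.relative_percent_change(
                    None if pd.isna(r.vaf_percent) else r.vaf_percent, v1)
                for r in sub.itertuples()}
        report["relative_percent_change"] = rpc
    ddpcr_result = state.get("ddpcr_result")
    if ddpcr_result is not None and state.get("quantify_summary"):
        ngs = state["quantify_summary"].get("unselected", {}).get("vaf_percent")
        report["vaf_ddpcr_vs_ngs"] = {"ddpcr": ddpcr_result["vaf_percent"],
                                      "ngs": ngs}
    if state.get("error_tables"):
        t1 = state["error_tables"][0]
        tk = state["error_tables"][-1]
        red = None
        if t1.total_error_rate and tk.total_error_rate is not None:
            red = 100.0 * (1 - tk.total_error_rate / t1.total_error_rate)
        report["error_rate_reduction_percent"] = red
    _write_json(report, out / "report.json")


_STAGES = {
    "simulate": _stage_simulate,
    "consensus": _stage_consensus,
    "sizeselect": _stage_sizeselect,
    "quantify": _stage_quantify,
    "errorprofile": _stage_errorprofile,
    "ddpcr": _stage_ddpcr,
    "report": _stage_report,
}
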
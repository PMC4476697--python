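"""End-to-end orchestration: simulate -> design -> quantify -> respire -> correlate.

Each stage is a plain function taking explicit inputs and an output directory;
``run_pipeline`` chains them in dependency order from a single config mapping.
Every stage writes a JSON sidecar carrying the config hash and seed so runs are
auditable; fixed seed implies byte-identical outputs.
"""
from __future__ import annotations

import json
import logging
import time as _time
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as msio
from . import published
from .primers import (
    PrimerConstraints,
    check_specificity,
    design_primer_pairs,
    screen_unique_regions,
)
from .qpcr import animal_delta_rq, pool_rq, relative_quantification
from .respirometry import analyze_trace
from .stats import association_analysis
from .synthetic import (
    CtGeneratorParams,
    SuitGeneratorParams,
    make_cohort,
    make_ct_dataset,
    make_genome_pair,
    make_suit_trace,
)

log = logging.getLogger("mitosignal")

#: Generator defaults mirroring the study design: 4 RNR animals per time point,
#: 5 CCI animals; post-injury fold changes set to the published pooled levels.
DEFAULT_SIMULATION = {
    "mito_length": 16_500,
    "nuclear_length": 200_000,
    "numt_specs": [[500, 0.0], [400, 0.02], [300, 0.05]],
    "n_per_group": 4,
    "fold_changes": {"RNR-6h": 2.07, "RNR-25h": 2.37, "CCI-25h": 1.35},
    "true_r": 0.8,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


def _outdir(path) -> Path:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    return out


def simulate(out_dir, seed: int = 0, config: Mapping | None = None) -> dict:
    """Generate all synthetic inputs (genomes, Ct table, SUIT trace, cohort)."""
    cfg = {**DEFAULT_SIMULATION, **(config or {})}
    out = _outdir(out_dir)
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(4) >> 1]  # keep < 2^31

    pair, truths = make_genome_pair(
        seeds[0],
        mito_length=cfg["mito_length"],
        nuclear_length=cfg["nuclear_length"],
        numt_specs=[tuple(s) for s in cfg["numt_specs"]],
    )
    msio.write_genome_pair(out, pair)
    msio.write_bed6(out / "numt_truth.bed", msio.numt_truth_to_bed(truths))

    ct_params = CtGeneratorParams(
        n_per_group=cfg["n_per_group"],
        group_fold_changes=cfg["fold_changes"],
        seed=seeds[1],
    )
    ct_table, ct_truth = make_ct_dataset(ct_params)
    msio.write_ct_table(out / "ct_table.csv", ct_table)
    ct_truth.to_csv(out / "ct_truth.csv", index=False)

    suit_params = SuitGeneratorParams(seed=seeds[2])
    trace, flux_truth = make_suit_trace(suit_params)
    msio.write_trace(out / "trace.tsv", trace)

    records, cohort_truth = make_cohort(
        seeds[3],
        n=max(cfg["n_per_group"], 3),
        true_r=cfg["true_r"],
        sham_mean_flux=published.SHAM_HIPPOCAMPAL_OXPHOS,
    )
    msio.write_cohort(out / "cohort.csv", records)

    truth_payload = {
        "numt_truth": [t.__dict__ for t in truths],
        "flux_truth": [{"state": p.state, "flux": p.flux} for p in flux_truth],
        "cohort_true_r": cohort_truth["true_r"],
    }
    msio.write_sidecar(out / "simulate.json", truth_payload, cfg, seed)
    return truth_payload


def design(mito_fa, nuclear_fa, out_dir, window: int = 100, step: int = 10, identity: float = 0.80) -> pd.DataFrame:
    """Screen unique regions and design ranked primer pairs inside each."""
    out = _outdir(out_dir)
    genomes = msio.read_genome_pair(mito_fa, nuclear_fa)
    regions = screen_unique_regions(genomes, window=window, step=step, identity_threshold=identity)
    msio.write_bed6(
        out / "unique_regions.bed",
        (
            ("mito", r.mito_start, r.mito_end, f"region{i + 1}", r.max_nuclear_identity, "+")
            for i, r in enumerate(regions)
        ),
    )
    rows = []
    constraints = PrimerConstraints()
    for i, region in enumerate(regions):
        if len(region) < constraints.amplicon[0] + 2 * constraints.primer_len[0]:
            continue
        for rank, pair in enumerate(design_primer_pairs(genomes.mito, region, constraints)[:5], start=1):
            reports = {rep.primer_id: rep for rep in check_specificity(pair, genomes)}
            rows.append(
                {
                    "region": f"region{i + 1}",
                    "rank": rank,
                    "forward_seq": pair.forward_seq,
                    "reverse_seq": pair.reverse_seq,
                    "probe_seq": pair.probe_seq,
                    "forward_start": pair.forward_start,
                    "reverse_end": pair.reverse_end,
                    "amplicon_length": pair.amplicon_length,
                    "tm_forward": round(pair.tm_forward, 2),
                    "tm_reverse": round(pair.tm_reverse, 2),
                    "gc_forward": round(pair.gc_forward, 3),
                    "gc_reverse": round(pair.gc_reverse, 3),
                    "penalty": round(pair.penalty, 3),
                    "fwd_best_nuclear_identity": round(reports["forward"].best_identity, 3),
                    "rev_best_nuclear_identity": round(reports["reverse"].best_identity, 3),
                    "fwd_3prime_risk": reports["forward"].perfect_3prime_match,
                    "rev_3prime_risk": reports["reverse"].perfect_3prime_match,
                }
            )
    report = pd.DataFrame(rows)
    report.to_csv(out / "primers.tsv", sep="\t", index=False)
    return report


def quantify(ct_csv, out_dir, calibrator: str = "auto") -> dict:
    """ddCt relative quantification plus pooled group statistics."""
    out = _outdir(out_dir)
    table = msio.read_ct_table(ct_csv)
    rq = relative_quantification(table, calibrator=calibrator)
    rq.to_csv(out / "rq.csv", index=False)
    pooled_rows = []
    for (group, timepoint), sub in rq.groupby(["group", "timepoint"]):
        stat = pool_rq(sub["rq"], label=f"{group}/{timepoint}")
        pooled_rows.append({"label": stat.label, "mean": stat.mean, "sem": stat.sem, "n": stat.n})
    pooled = pd.DataFrame(pooled_rows)
    pooled.to_csv(out / "pooled.csv", index=False)
    deltas = animal_delta_rq(rq)
    deltas.to_csv(out / "animal_deltas.csv", index=False)
    return {"pooled": pooled_rows, "n_samples": int(len(rq))}


def respire(trace_tsv, out_dir, sample_conc: float = 1.0, equilibration_s: float = 60.0, window_s: float = 300.0) -> dict:
    """Phase fluxes and respiratory profile of one oxygraph trace."""
    out = _outdir(out_dir)
    trace = msio.read_trace(trace_tsv, sample_conc=sample_conc)
    fluxes, profile = analyze_trace(trace, equilibration_s=equilibration_s, window_s=window_s)
    payload = {
        "phases": [
            {"state": p.state, "flux": p.flux, "window": list(p.window), "stability": p.stability}
            for p in fluxes
        ],
        "profile": None
        if profile is None
        else {
            "oxphos_ci_cii": profile.oxphos_ci_cii,
            "leak_ci_cii": profile.leak_ci_cii,
            "rcr": profile.rcr,
            "rcr_defined": profile.rcr_defined,
        },
    }
    with open(out / "respiration.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    return payload


def correlate(cohort_csv, out_dir, plot: bool = True) -> dict:
    """Sham-referenced delta correlation per group, with scatter report."""
    out = _outdir(out_dir)
    records = msio.read_cohort(cohort_csv)
    results = association_analysis(records, plot_path=(out / "association.png") if plot else None)
    payload = {
        group: {"r": res.r, "p_value": res.p_value, "n": res.n, "slope": res.slope, "intercept": res.intercept}
        for group, res in results.items()
    }
    with open(out / "association.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    return payload


def reproduce_published_pooling() -> dict:
    """Recompute the three pooled RQ aggregates from the packaged group means."""
    values = published.pooled_reference_values()
    printed = {"pre_injury": 0.84, "rnr_6h_post": 2.07, "cci_25h_post": 1.35}
    return {
        key: {"computed": values[key], "printed": printed[key], "agrees": round(values[key], 2) == printed[key]}
        for key in printed
    }


def run_pipeline(config: Mapping) -> dict:
    """Run all stages in dependency order; returns the machine-readable report."""
    out = _outdir(config.get("output_dir", "pipeline_out"))
    seed = int(config.get("seed", 0))
    report: dict = {"seed": seed, "config_hash": msio.config_hash(dict(config)), "stages": {}}
    stages = config.get("stages", ["simulate", "design", "quantify", "respire", "correlate"])

    def _run(name, fn, *args, **kwargs):
        t0 = _time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as exc:  # noqa: BLE001 - stage name must reach the caller
            raise StageError(name, str(exc)) from exc
        log.info("stage %s finished in %.2fs", name, _time.perf_counter() - t0)
        report["stages"][name] = {"elapsed_s": round(_time.perf_counter() - t0, 3)}
        return result

    sim_dir = out / "simulate"
    if "simulate" in stages:
        _run("simulate", simulate, sim_dir, seed=seed, config=config.get("simulate"))
    if "design" in stages:
        _run("design", design, sim_dir / "mito.fa", sim_dir / "nuclear.fa", out / "design")
    if "quantify" in stages:
        result = _run("quantify", quantify, sim_dir / "ct_table.csv", out / "quantify")
        report["stages"]["quantify"]["summary"] = result
    if "respire" in stages:
        result = _run("respire", respire, sim_dir / "trace.tsv", out / "respire")
        report["stages"]["respire"]["summary"] = result
    if "correlate" in stages:
        result = _run("correlate", correlate, sim_dir / "cohort.csv", out / "correlate")
        report["stages"]["correlate"]["summary"] = result

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return report
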
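"""End-to-end orchestration: synth -> tune -> metrics -> convergence -> stats.

Each stage persists its inputs and outputs under the configured output
directory; a stage failure aborts with the stage name while earlier
artifacts remain on disk.  The run is deterministic under the configured
seed.
"""
from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import synthdata, vtpio, windkessel
from .config import PipelineConfig
from .core import FluidProperties
from .cohortstats import cohort_report, shapiro_wilk_gate
from .meshconv import check_converged, ConvergenceTrace, next_edge_size
from .shear_metrics import pointwise_tawss_osi, region_summary
from .synthdata import SyntheticPatientSpec

log = logging.getLogger("aneushear")


class StageError(RuntimeError):
    def __init__(self, stage: str, out_dir: Path, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed ({cause}); artifacts kept in {out_dir}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full synthetic study; returns a summary dict of artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    props = FluidProperties(density=config.density, viscosity=config.viscosity)
    result: dict = {"out_dir": str(out)}

    def stage(name):
        def deco(fn):
            try:
                log.info("stage %s", name)
                return fn()
            except Exception as e:  # noqa: BLE001 - abort with stage context
                raise StageError(name, out, e) from e
        return deco

    @stage("synth")
    def _synth():
        wave = synthdata.make_waveform(
            config.mean_flow, config.pulsatility_index, config.heart_rate
        )
        vtpio.write_waveform(wave, out / "waveform.csv")
        spec = SyntheticPatientSpec(seed=config.seed)
        field, gt = synthdata.make_patient(spec, props, tuple(config.mtlsa_percents))
        vtpio.write_surface_field(field, out / "patient.vtp")
        vtpio.write_json(gt.to_dict(), out / "patient_ground_truth.json")
        return wave, spec, field, gt

    wave, spec, field, gt = _synth

    @stage("tune")
    def _tune():
        tuning = windkessel.tune_rcr(
            wave,
            windkessel.OutletSet(np.asarray(config.outlet_areas)),
            systolic_mmhg=config.systolic_mmhg,
            diastolic_mmhg=config.diastolic_mmhg,
            tol=config.pressure_tol,
            proximal_fraction=config.proximal_fraction,
            p_ref=config.p_ref,
            max_iter=config.max_tuning_iter,
        )
        vtpio.write_json(tuning.to_dict(), out / "rcr_tuning.json")
        return tuning

    tuning = _tune
    result["systolic_mmhg"] = tuning.systolic_mmhg
    result["diastolic_mmhg"] = tuning.diastolic_mmhg

    @stage("metrics")
    def _metrics():
        tawss, osi = pointwise_tawss_osi(field)
        summary = region_summary(field, tawss, osi, tuple(config.mtlsa_percents))
        row = summary.as_metric_row()
        pd.DataFrame([row]).to_csv(out / "metrics.csv", index=False)
        vtpio.write_json(summary.to_dict(), out / "metrics.json")
        return summary

    summary = _metrics
    result["dome_mean_tawss"] = summary.dome_mean_tawss
    result["mtlsa_70"] = (summary.mtlsa or {}).get(70)

    @stage("convergence")
    def _converge():
        # re-measure the same construction at a few coarser resolutions
        sizes, tawss_means = [], []
        edge = spec.mesh_edge_size * (1.0 / config.refinement_factor) ** config.n_refinements
        for _ in range(config.n_refinements + 1):
            f_k, _gt = synthdata.make_patient(
                replace(spec, mesh_edge_size=edge), props, tuple(config.mtlsa_percents)
            )
            t_k, o_k = pointwise_tawss_osi(f_k)
            s_k = region_summary(f_k, t_k, o_k, tuple(config.mtlsa_percents))
            sizes.append(edge * 10.0)  # cm -> mm at the reporting interface
            tawss_means.append(s_k.dome_mean_tawss)
            edge = next_edge_size(edge, config.refinement_factor)
        trace = check_converged(
            ConvergenceTrace(np.array(sizes), np.array(tawss_means)), config.convergence_tol
        )
        trace.table.to_csv(out / "convergence.csv", index=False)
        vtpio.write_json(
            {
                "converged": trace.converged,
                "converged_index": trace.converged_index,
                "tol": trace.tol,
            },
            out / "convergence.json",
        )
        return trace

    trace = _converge
    result["mesh_converged"] = trace.converged

    @stage("cohort-stats")
    def _stats():
        cohort = synthdata.make_cohort(
            n_pairs=config.n_pairs,
            effect=(config.effect_metric, config.effect_size),
            noise_sd=config.noise_sd,
            seed=config.seed,
        )
        vtpio.write_cohort(cohort, out / "cohort.csv")
        gate = shapiro_wilk_gate(cohort)
        gate.to_frame().to_csv(out / "normality.csv", index=False)
        report = cohort_report(cohort, alpha=config.alpha)
        report.to_csv(out / "cohort_report.csv", index=False)
        vtpio.write_json(
            {"recommendation": gate.recommendation,
             "flagged": report.loc[report["significant"], "metric"].tolist()},
            out / "cohort_report.json",
        )
        return report

    report = _stats
    result["flagged_metrics"] = report.loc[report["significant"], "metric"].tolist()
    result["ground_truth_mtlsa_70"] = gt.mtlsa.get(70)
    return result
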
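"""End-to-end stress→recovery scenario runner.

Executes (optionally) simulation, reduction, MSD extraction, resilience,
kill/lag kinetics, cytometry gating and respiration as configured, collecting
every stage's results into a ReportBundle whose JSON serialization is
byte-identical for identical (config, seed).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .config import ConfigError, RunConfig, ScenarioConfig, _from_dict
from .dynamics import ResilienceModel
from .io import read_table, to_record, write_records, write_table
from .kinetics import (
    GatePolicy,
    estimate_lag,
    fit_kill_curve,
    gate_events,
    respiration_rate,
)
from .reduction import reduce_bundle
from .synthetic import (
    CytometryMixture,
    DynamicsModel,
    InstrumentConfig,
    KillCurveParams,
    simulate_cytometry_events,
    simulate_elastic_bundle,
    simulate_kill_curve,
    simulate_oxygen_trace,
    simulate_recovery_curve,
)

__all__ = ["ReportBundle", "StageError", "run_pipeline", "derive_seed"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def derive_seed(base_seed: int, *key: str) -> int:
    """Deterministic per-consumer child seed (< 2^31) from the run seed."""
    h = hashlib.sha256(("/".join(map(str, key)) + f"#{base_seed}").encode())
    return int.from_bytes(h.digest()[:4], "big") % (2**31)


@dataclass
class ReportBundle:
    """Per-stage machine-readable records plus provenance and a text summary."""

    records: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    summary_text: str = ""

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_records(
            {"records": self.records, "provenance": self.provenance}, outdir / "report.json"
        )
        (outdir / "summary.txt").write_text(self.summary_text + "\n")


def _config_hash(config: RunConfig) -> str:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _scenario_model(raw) -> DynamicsModel:
    sc = raw if isinstance(raw, ScenarioConfig) else _from_dict(
        ScenarioConfig, dict(raw), "scenario"
    )
    return DynamicsModel(
        populations=[tuple(p) for p in sc.populations],
        t_ref=sc.t_ref,
        amplitude=sc.amplitude,
        background=sc.background,
    )


def run_pipeline(config: RunConfig, outdir=None) -> ReportBundle:
    """Run the configured stages and return the collected ReportBundle.

    A failing stage raises StageError naming the stage; records of the
    stages completed before the failure are still written to ``outdir``.
    """
    config.validate()
    bundle = ReportBundle(
        provenance={
            "config_hash": _config_hash(config),
            "halodyn_version": __version__,
            "seed": config.seed,
            "seeds_consumed": {},
        }
    )
    outpath = Path(outdir) if outdir is not None else None
    if outpath is not None:
        (outpath / "data").mkdir(parents=True, exist_ok=True)
    seeds = bundle.provenance["seeds_consumed"]
    seed = config.seed if config.seed is not None else 0
    stages = list(config.stages)
    scan_bundles = {}
    reduced = {}
    resilience = {}
    try:
        if "simulate" in stages and config.simulate.enabled:
            stage = "simulate"
            instrument = InstrumentConfig(transmission=config.reduce.transmission)
            for name, raw in config.simulate.scenarios.items():
                model = _scenario_model(raw)
                s = derive_seed(seed, "elastic", name)
                seeds[f"elastic/{name}"] = s
                scan_bundles[name] = simulate_elastic_bundle(
                    model, instrument, seed=s, noise=config.simulate.noise
                )
                if outpath is not None:
                    for run in ("sample", "empty_cell", "vanadium"):
                        write_table(
                            getattr(scan_bundles[name], run),
                            outpath / "data" / f"{name}_{run}.csv",
                        )
        if "reduce" in stages:
            stage = "reduce"
            if not scan_bundles:
                scan_bundles = _load_scan_bundles(config)
            for name, raw_bundle in scan_bundles.items():
                reduced[name] = reduce_bundle(
                    raw_bundle, transmission=config.reduce.transmission
                )
                bundle.records[f"reduced/{name}"] = {
                    "n_q": reduced[name].n_q,
                    "n_temperature": reduced[name].n_temperature,
                    "n_masked": int(np.sum(~reduced[name].mask)),
                    "provenance": list(reduced[name].provenance),
                }
                if outpath is not None:
                    write_table(reduced[name], outpath / "data" / f"{name}_reduced.csv")
        if "msd" in stages or "resilience" in stages:
            stage = "resilience"
            for name, red in reduced.items():
                model = ResilienceModel(
                    red,
                    q_window=tuple(config.msd.q_window),
                    q_unit=config.msd.q_unit,
                    normalize_to_reference=config.msd.normalize_to_reference,
                )
                boot_seed = derive_seed(seed, "resilience", name)
                if config.resilience.method == "bootstrap":
                    seeds[f"resilience/{name}"] = boot_seed
                msd = model._fit_msd()
                bundle.records[f"msd/{name}"] = to_record(msd)
                if "resilience" in stages:
                    from .dynamics import fit_force_constant

                    force = fit_force_constant(
                        msd,
                        method=config.resilience.method,
                        n_boot=config.resilience.n_boot,
                        seed=boot_seed,
                    )
                    resilience[name] = force
                    bundle.records[f"force_constant/{name}"] = to_record(force)
            if {"control", "recovered"} <= resilience.keys():
                ctrl = resilience["control"]
                recov = resilience["recovered"]
                bundle.records["recovery_comparison"] = {
                    "k_prime_control": ctrl.k_prime,
                    "k_prime_recovered": recov.k_prime,
                    "consistent_95": recov.consistent_with(ctrl),
                }
        if "kinetics" in stages:
            stage = "kinetics"
            kc = config.kinetics.kill
            times = np.linspace(0.0, kc.t_max_days, kc.n_points)
            s = derive_seed(seed, "kill")
            seeds["kinetics/kill"] = s
            kill_curve = simulate_kill_curve(
                KillCurveParams(
                    n0=kc.n0,
                    f_sensitive=kc.f_sensitive,
                    k_fast=kc.k_fast,
                    k_slow=kc.k_slow,
                    noise_cv=kc.noise_cv,
                ),
                times,
                seed=s,
                noise=kc.noise_cv > 0,
            )
            bundle.records["kill_curve_fit"] = to_record(fit_kill_curve(kill_curve))
            lc = config.kinetics.lag
            t_h = np.arange(0.0, lc.span_days * 24.0 + 1e-9, lc.dt_hours)
            s = derive_seed(seed, "lag")
            seeds["kinetics/lag"] = s
            recovery = simulate_recovery_curve(
                lag=lc.lag_days,
                growth_rate=lc.growth_rate,
                od0=lc.od0,
                times=t_h,
                noise_cv=lc.noise_cv,
                seed=s,
            )
            lag_seed = derive_seed(seed, "lag", "bootstrap")
            seeds["kinetics/lag_bootstrap"] = lag_seed
            bundle.records["recovery_lag"] = to_record(
                estimate_lag(
                    recovery, min_rate=lc.min_rate, n_boot=lc.n_boot, seed=lag_seed
                )
            )
            if outpath is not None:
                write_table(kill_curve, outpath / "data" / "kill_curve.csv")
                write_table(recovery, outpath / "data" / "recovery_curve.csv")
        if "cytometry" in stages:
            stage = "cytometry"
            cy = config.cytometry
            control_mix = CytometryMixture(
                components=[(1.0, 3.0, 2.0, 0.15, 0.15)], n_events=cy.n_events
            )
            stressed_mix = CytometryMixture(
                components=[
                    (1.0 - cy.planted_pi_fraction, 3.0, 2.0, 0.15, 0.15),
                    (cy.planted_pi_fraction, 2.2, 3.5, 0.15, 0.15),
                ],
                n_events=cy.n_events,
            )
            s_ctrl = derive_seed(seed, "cytometry", "control")
            s_str = derive_seed(seed, "cytometry", "stressed")
            seeds["cytometry/control"] = s_ctrl
            seeds["cytometry/stressed"] = s_str
            control_events = simulate_cytometry_events(control_mix, seed=s_ctrl)
            stressed_events = simulate_cytometry_events(stressed_mix, seed=s_str)
            policy = GatePolicy(
                pi_quantile=cy.pi_quantile, syto_quantile=cy.syto_quantile
            )
            bundle.records["gate/stressed"] = to_record(
                gate_events(stressed_events, control_events, policy)
            )
            bundle.records["gate/control"] = to_record(
                gate_events(control_events, control_events, policy)
            )
            if outpath is not None:
                write_table(control_events, outpath / "data" / "events_control.csv")
                write_table(stressed_events, outpath / "data" / "events_stressed.csv")
        if "respiration" in stages:
            stage = "respiration"
            rc = config.respiration
            traces = {}
            for label, rate in (
                ("basal", rc.basal_rate),
                ("stressed", rc.stressed_rate),
                ("recovered", rc.recovered_rate),
            ):
                s = derive_seed(seed, "oxygen", label)
                seeds[f"respiration/{label}"] = s
                traces[label] = simulate_oxygen_trace(
                    rate=rate,
                    o2_0=rc.o2_0,
                    duration=rc.duration_min,
                    noise_sd=rc.noise_sd,
                    seed=s,
                )
                if outpath is not None:
                    write_table(traces[label], outpath / "data" / f"oxygen_{label}.csv")
            basal = traces["basal"]
            bundle.records["respiration/basal"] = to_record(
                respiration_rate(basal, treat_as_basal=True)
            )
            for label in ("stressed", "recovered"):
                bundle.records[f"respiration/{label}"] = to_record(
                    respiration_rate(traces[label], basal=basal)
                )
    except Exception as exc:  # persist what completed, then re-raise with stage
        if outpath is not None:
            bundle.summary_text = _summarize(bundle, failed_stage=stage)
            bundle.write(outpath)
        raise StageError(stage, exc) from exc
    bundle.summary_text = _summarize(bundle)
    if outpath is not None:
        bundle.write(outpath)
    return bundle


def _load_scan_bundles(config: RunConfig) -> dict:
    """Load raw scan triplets from configured input paths.

    ``config.inputs`` maps scenario name -> {sample, empty_cell, vanadium}
    CSV paths (elastic schema).
    """
    from .synthetic import RawScanBundle

    bundles = {}
    for name, paths in config.inputs.items():
        if not {"sample", "empty_cell", "vanadium"} <= set(paths):
            raise ConfigError(
                f"inputs[{name!r}] must provide sample, empty_cell and vanadium paths"
            )
        bundles[name] = RawScanBundle(
            sample=read_table(paths["sample"], "elastic"),
            empty_cell=read_table(paths["empty_cell"], "elastic"),
            vanadium=read_table(paths["vanadium"], "elastic"),
            truth=None,
            seed=-1,
        )
    if not bundles:
        raise ConfigError(
            "reduce stage needs either the simulate stage or inputs paths"
        )
    return bundles


def _summarize(bundle: ReportBundle, failed_stage: str | None = None) -> str:
    lines = [
        "halodyn pipeline report",
        "=======================",
        f"config hash : {bundle.provenance['config_hash']}",
        f"seed        : {bundle.provenance['seed']}",
    ]
    if failed_stage:
        lines.append(f"FAILED at stage: {failed_stage}")
    rec = bundle.records
    for name in sorted(k for k in rec if k.startswith("force_constant/")):
        fc = rec[name]
        kp = fc["k_prime"]
        kp_s = f"{kp:.4f} ± {fc['k_prime_err']:.4f} N/m" if kp is not None else "undefined"
        lines.append(f"{name.split('/', 1)[1]:>10} <k'> : {kp_s}")
    if "recovery_comparison" in rec:
        ok = rec["recovery_comparison"]["consistent_95"]
        lines.append(
            "recovered vs control : "
            + ("consistent at 95%" if ok else "NOT consistent at 95%")
        )
    if "kill_curve_fit" in rec:
        kf = rec["kill_curve_fit"]
        lines.append(
            f"kill curve : {kf['selected']} (f={kf['f_sensitive']:.3f}, "
            f"k_fast={kf['k_fast']:.3g}/d, k_slow={kf['k_slow']:.3g}/d)"
        )
    if "recovery_lag" in rec:
        lag = rec["recovery_lag"]
        if lag["no_growth"]:
            lines.append("recovery lag : no growth detected")
        else:
            lines.append(
                f"recovery lag : {lag['lag_days']:.2f} d "
                f"(95% CI [{lag['lag_ci_days'][0]:.2f}, {lag['lag_ci_days'][1]:.2f}])"
            )
    if "gate/stressed" in rec:
        g = rec["gate/stressed"]
        lines.append(
            f"gating (stressed) : PI+ fraction {g['pi_pos_fraction']:.3f}, "
            f"Syto- fraction {g['syto_neg_fraction']:.3f}"
        )
    for label in ("stressed", "recovered"):
        key = f"respiration/{label}"
        if key in rec:
            lines.append(
                f"respiration ({label}) : {rec[key]['rate']:.3g} nmol/min/1e8 cells "
                f"= {rec[key]['percent_basal']:.1f}% of basal"
            )
    return "\n".join(lines)
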
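"""End-to-end orchestration: data -> fluxes -> thermodynamics ->
elasticities -> control coefficients -> Monte Carlo -> report.

One configuration drives one immutable run directory with stage
subfolders, a resolved-config snapshot and a manifest, so every number in
the report can be traced to its inputs and seeds.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constants import (
    DEFAULT_FVA_FRACTION,
    DEFAULT_MC_ITERATIONS,
    DEFAULT_TEMPERATURE,
    EQ_THRESHOLD,
)
from .elasticity import assemble_elasticity_matrix
from .fluxes import ConcentrationBounds, fit_fluxes, fva, tfa
from .mca import (
    control_from_state,
    control_pattern_report,
    monte_carlo_mca,
)
from .model import MetabolicModel
from .synthetic import (
    FAR_FROM_EQUILIBRIUM,
    NEAR_EQUILIBRIUM,
    SteadyState,
    generate_perturbation_dataset,
    make_default_kinetic_model,
    read_dataset,
    true_control_coefficients,
    write_dataset,
)

__all__ = ["PipelineConfig", "run_pipeline", "demo"]

log = logging.getLogger("cysmca.pipeline")


@dataclass
class PipelineConfig:
    """Resolved settings of one analysis run.

    Defaults mirror the reference analysis: 99.9% FVA fraction, a
    -10 kJ/mol equilibrium threshold, 10,000 Monte Carlo iterations, and
    cultivation temperature 305.15 K (32 degC).
    """

    output_dir: str = "runs"
    dataset_dir: str | None = None      # load measured data; None = synthetic
    model_path: str | None = None       # JSON/SBML model; None = packaged
    fva_fraction: float = DEFAULT_FVA_FRACTION
    eq_threshold_kj: float = EQ_THRESHOLD
    mc_iterations: int = DEFAULT_MC_ITERATIONS
    noise_cv: float = 0.10
    temperature_K: float = DEFAULT_TEMPERATURE
    seed: int = 1                       # kinetic-model / analysis seed
    data_seed: int = 0                  # measurement-noise seed
    data_noise_cv: float = 0.0          # noise injected into synthetic data
    classification: str = "tfa"         # "tfa" or "printed"
    run_fva: bool = False
    loopless_fva: bool = False
    mc_regularization: float = 1e-3
    target_flux: str = "YdeD"

    def validate(self) -> None:
        if not 0 < self.fva_fraction <= 1:
            raise ValueError("fva_fraction must be in (0, 1]")
        if self.mc_iterations < 0:
            raise ValueError("mc_iterations must be >= 0")
        if self.classification not in ("tfa", "printed"):
            raise ValueError("classification must be 'tfa' or 'printed'")
        if self.dataset_dir is not None and not Path(self.dataset_dir).exists():
            raise ValueError(f"dataset_dir {self.dataset_dir!r} does not exist")
        if self.model_path is not None and not Path(self.model_path).exists():
            raise ValueError(f"model_path {self.model_path!r} does not exist")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        import yaml

        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def _stage(run_dir: Path, name: str) -> Path:
    d = run_dir / name
    d.mkdir(parents=True, exist_ok=True)
    return d


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis; returns the run directory."""
    config.validate()
    t_start = time.time()
    run_dir = Path(config.output_dir) / f"run_seed{config.seed}"
    n = 0
    while run_dir.exists():
        n += 1
        run_dir = Path(config.output_dir) / f"run_seed{config.seed}_{n}"
    run_dir.mkdir(parents=True)
    (run_dir / "config.json").write_text(
        json.dumps(asdict(config), indent=1, sort_keys=True) + "\n")

    timings: dict[str, float] = {}

    def tick(stage: str, t0: float) -> None:
        timings[stage] = round(time.time() - t0, 3)
        log.info("stage %s finished in %.2fs", stage, timings[stage])

    # -- stage 1: data ----------------------------------------------------
    t0 = time.time()
    kmodel = make_default_kinetic_model(seed=config.seed,
                                        temperature=config.temperature_K)
    if config.dataset_dir is not None:
        dataset = read_dataset(config.dataset_dir)
    else:
        dataset = generate_perturbation_dataset(
            kmodel, noise_cv=config.data_noise_cv, seed=config.data_seed)
    model: MetabolicModel = kmodel.model
    data_dir = _stage(run_dir, "01_data")
    write_dataset(dataset, data_dir)
    tick("data", t0)

    # -- stage 2: per-state flux distributions ----------------------------
    t0 = time.time()
    flux_dir = _stage(run_dir, "02_fluxes")
    distributions = []
    for st in dataset.states:
        fd = fit_fluxes(model, st.rates, state_label=st.label)
        distributions.append(fd)
    flux_table = pd.DataFrame(
        {fd.state_label: fd.fluxes for fd in distributions}).T
    flux_table.rename_axis("state").to_csv(flux_dir / "flux_distributions.csv")
    if config.run_fva:
        ranges = fva(model, config.target_flux,
                     fraction=config.fva_fraction,
                     rate_constraints={r: (v - 0.05 * abs(v) - 1e-6,
                                           v + 0.05 * abs(v) + 1e-6)
                                       for r, v in
                                       dataset.reference.rates.items()},
                     loopless=config.loopless_fva)
        pd.DataFrame(ranges, index=["min", "max"]).T.rename_axis(
            "reaction").to_csv(flux_dir / "fva_ranges.csv")
    tick("fluxes", t0)

    # -- stage 3: thermodynamic classification ----------------------------
    t0 = time.time()
    thermo_dir = _stage(run_dir, "03_thermo")
    dG0 = dataset.ground_truth.get("dG0", {})
    if config.classification == "tfa" and dG0:
        cb = ConcentrationBounds.from_measurement(
            {m: c for m, c in dataset.reference.concentrations.items()
             if m != "H2O" and c > 0},
            temperature=config.temperature_K)
        rate_bands = {r: (v - 0.05 * abs(v) - 1e-6, v + 0.05 * abs(v) + 1e-6)
                      for r, v in dataset.reference.rates.items()}
        _, annotation, _ = tfa(model, cb, dG0, rate_constraints=rate_bands,
                               compute_flux_ranges=False)
        eq_class = dict(annotation.eq_class)
        dGr = {r: annotation.representative(r) for r in annotation.dGr_range}
        pd.DataFrame({
            "dG0": {r: dG0[r] for r in annotation.dGr_range},
            "dGr_min": {r: annotation.dGr_range[r][0]
                        for r in annotation.dGr_range},
            "dGr_max": {r: annotation.dGr_range[r][1]
                        for r in annotation.dGr_range},
            "eq_class": eq_class,
        }).rename_axis("reaction").to_csv(thermo_dir / "thermo_annotation.csv")
    else:
        # fall back to the reported near/far classification of the
        # production state
        eq_class = {r: "near" for r in NEAR_EQUILIBRIUM}
        eq_class.update({r: "far" for r in FAR_FROM_EQUILIBRIUM})
        for r in model.reaction_ids:
            eq_class.setdefault(
                r, "far" if r not in ("GLCfeed", "PYRup", "SUCCup")
                else "unclassified")
        dGr = dict(dataset.ground_truth.get("dG_ref", {}))
        pd.Series(eq_class, name="eq_class").rename_axis("reaction").to_csv(
            thermo_dir / "thermo_annotation.csv")
    tick("thermo", t0)

    # -- stage 4: elasticities --------------------------------------------
    t0 = time.time()
    el_dir = _stage(run_dir, "04_elasticities")
    E = assemble_elasticity_matrix(
        model, eq_class, dataset, dGr=dGr,
        temperature=config.temperature_K,
        regularization=config.mc_regularization)
    E.values.rename_axis("reaction").to_csv(el_dir / "elasticities.csv")
    (el_dir / "diagnostics.json").write_text(json.dumps(
        {"method": E.method, "diagnostics": E.diagnostics},
        indent=1, sort_keys=True, default=float) + "\n")
    tick("elasticities", t0)

    # -- stage 5: control coefficients ------------------------------------
    t0 = time.time()
    mca_dir = _stage(run_dir, "05_mca")
    recon = fit_fluxes(model, dataset.reference.rates,
                       state_label=dataset.reference.label)
    ref_state = SteadyState(
        label=dataset.reference.label,
        concentrations=dataset.reference.concentrations,
        rates=recon.fluxes, is_reference=True)
    result = control_from_state(model, E, ref_state)
    result.C_J.rename_axis("flux").to_csv(mca_dir / "flux_control.csv")
    result.C_S.rename_axis("metabolite").to_csv(
        mca_dir / "concentration_control.csv")
    report = control_pattern_report(result, config.target_flux)
    report.to_csv(mca_dir / "control_pattern.csv", index=False)
    tick("mca", t0)

    # -- stage 6: Monte Carlo ---------------------------------------------
    t0 = time.time()
    mc_dir = _stage(run_dir, "06_montecarlo")
    mc = None
    if config.mc_iterations > 0:
        mc = monte_carlo_mca(
            dataset, model, eq_class, dGr,
            n_iter=config.mc_iterations, noise_cv=config.noise_cv,
            seed=config.seed, regularization=config.mc_regularization)
        mc.median_C_J.rename_axis("flux").to_csv(mc_dir / "CJ_median.csv")
        mc.lo_C_J.rename_axis("flux").to_csv(mc_dir / "CJ_p2.5.csv")
        mc.hi_C_J.rename_axis("flux").to_csv(mc_dir / "CJ_p97.5.csv")
        mc.sign_stability_C_J.rename_axis("flux").to_csv(
            mc_dir / "CJ_sign_stability.csv")
        mc.median_C_S.rename_axis("metabolite").to_csv(
            mc_dir / "CS_median.csv")
        (mc_dir / "summary.json").write_text(json.dumps({
            "n_iterations": mc.n_iterations, "n_dropped": mc.n_dropped,
            "seed": mc.seed}, indent=1) + "\n")
    tick("montecarlo", t0)

    # -- report ------------------------------------------------------------
    cys_exports = {st.label: st.rates["YdeD"] for st in dataset.states}
    lines = [
        f"cysmca pipeline report (version {__version__})",
        f"run directory: {run_dir}",
        f"states analysed: {len(dataset.states)} "
        f"(reference + {len(dataset.perturbations)} perturbations)",
        f"flux distributions emitted: {len(distributions)}",
        "cysteine export positive in all states: "
        f"{all(v > 0 for v in cys_exports.values())}",
        f"near-equilibrium reactions: "
        f"{sum(1 for v in eq_class.values() if v == 'near')}",
        f"far-from-equilibrium reactions: "
        f"{sum(1 for v in eq_class.values() if v == 'far')}",
        f"C_J row-sum deviation: "
        f"{float(np.abs(result.C_J.sum(axis=1) - 1).max()):.2e}",
        f"C_S row-sum deviation: "
        f"{float(np.abs(result.C_S.sum(axis=1)).max()):.2e}",
    ]
    if mc is not None:
        lines.append(f"Monte Carlo: {mc.n_iterations} iterations, "
                     f"{mc.n_dropped} dropped")
    lines.append("top control over "
                 f"{config.target_flux}: "
                 + ", ".join(f"{r.enzyme} ({r.C_J:+.3f})"
                             for r in report.head(5).itertuples()))
    (run_dir / "report.txt").write_text("\n".join(lines) + "\n")

    manifest = {
        "version": __version__,
        "seeds": {"seed": config.seed, "data_seed": config.data_seed},
        "config_sha256": hashlib.sha256(
            (run_dir / "config.json").read_bytes()).hexdigest(),
        "timings_s": timings,
        "total_s": round(time.time() - t_start, 3),
    }
    (run_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return run_dir


# ---------------------------------------------------------------------------
# demo: synthetic run + built-in acceptance checks
# ---------------------------------------------------------------------------

def demo(seed: int = 42, mc_iterations: int = 1000,
         output_dir: str = "runs") -> tuple[Path, dict[str, bool]]:
    """Generate a synthetic dataset, run the pipeline and self-check.

    Returns the run directory and a dict of named pass/fail checks
    (summation theorems, finite-difference oracle agreement, lin-log
    recovery on well-conditioned rows, positive cysteine export).
    """
    config = PipelineConfig(output_dir=output_dir, seed=seed,
                            mc_iterations=mc_iterations)
    run_dir = run_pipeline(config)
    checks: dict[str, bool] = {}

    kmodel = make_default_kinetic_model(seed=seed)
    dataset = generate_perturbation_dataset(kmodel, noise_cv=0.0,
                                            seed=config.data_seed)
    checks["thirteen_states"] = len(dataset.states) == 13
    checks["positive_cys_export"] = all(
        st.rates["YdeD"] > 0 for st in dataset.states)

    cj = pd.read_csv(run_dir / "05_mca" / "flux_control.csv",
                     index_col="flux")
    cs = pd.read_csv(run_dir / "05_mca" / "concentration_control.csv",
                     index_col="metabolite")
    checks["summation_CJ"] = bool(
        np.abs(cj.sum(axis=1) - 1).max() < 1e-6)
    checks["summation_CS"] = bool(np.abs(cs.sum(axis=1)).max() < 1e-6)

    # algebra vs finite-difference oracle with ground-truth elasticities
    mets = [m for m in kmodel.free_species]
    from .model import stoichiometric_matrix
    from .synthetic import FEED_REACTIONS
    from .mca import control_coefficients

    ref = dataset.reference
    N, mrows, cols = stoichiometric_matrix(kmodel.model, internal_only=True)
    rxns = [r for r in cols if r not in FEED_REACTIONS]
    keep = [cols.index(r) for r in rxns]
    E_true = kmodel.scaled_elasticity_matrix(mrows)[keep, :]
    res = control_coefficients(
        N[:, keep], E_true,
        J=np.array([ref.rates[r] for r in rxns]),
        c=np.array([ref.concentrations[m] for m in mrows]),
        reaction_ids=rxns, metabolite_ids=mrows)
    CJ_fd, CS_fd, flux_ids, enz, mets_fd = true_control_coefficients(
        kmodel, 1e-3)
    dev = np.abs(res.C_J.loc[flux_ids, enz].to_numpy() - CJ_fd).max()
    checks["oracle_agreement_1e-3"] = bool(dev < 1e-3)

    # lin-log recovery on full-rank designs
    from .elasticity import default_effectors, linlog_elasticities

    ok = True
    for rid, row_true in kmodel.elasticities.items():
        eff = default_effectors(kmodel.model, rid)
        if not eff:
            continue
        row, diag = linlog_elasticities(dataset, rid, eff)
        if diag["condition_number"] < 1e6:
            for met in eff:
                tv = row_true.get(met, 0.0)
                if abs(row[met] - tv) > 1e-6 * max(abs(tv), 1.0):
                    ok = False
    checks["linlog_recovery_full_rank"] = ok

    (run_dir / "demo_checks.json").write_text(
        json.dumps(checks, indent=1, sort_keys=True) + "\n")
    return run_dir, checks
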
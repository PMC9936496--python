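"""Config-driven orchestration of the analysis stages.

A pipeline config (YAML or an equivalent dict) contains one block per
requested stage plus global settings:

.. code-block:: yaml

    seed: 1
    stages:
      simulate_melt: {sigma: 0.3}
      fit_melt: {stoichiometries: [2, 3, 4]}
      mre: {theta_obs_mdeg: -30.0, c_mM: 0.05, n_bonds: 22, l_cm: 0.2}
      pss: {peak_areas: path/to/areas.csv}
      relax_fit: {timeseries: path/to/relax.csv}
      cycle_sim: {n_cycles: 3}
      traj_dist: {cutoff: 0.2}
      ff_extract: {isomer: trans}

Stages run in dependency order (generation before fitting); each writes
its artifacts under the output directory and the run ends with a manifest
recording inputs, their SHA-256 hashes, the seed and the package version.
Re-running with an identical config and seed reproduces the artifacts
byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import yaml

import azocoil
from azocoil import ffparams, io, photokinetics as pk, synthetic, thermo
from azocoil import trajectory as tj

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate_melt", "fit_melt", "mre", "pss", "relax_fit",
               "cycle_sim", "traj_dist", "ff_extract")


class ConfigError(ValueError):
    """Raised on a malformed pipeline configuration."""


def load_config(path) -> dict:
    cfg = yaml.safe_load(Path(path).read_text())
    validate_config(cfg)
    return cfg


def validate_config(cfg) -> None:
    if not isinstance(cfg, dict):
        raise ConfigError("config must be a mapping")
    if "stages" not in cfg or not isinstance(cfg["stages"], dict):
        raise ConfigError("config missing required block 'stages'")
    if not cfg["stages"]:
        raise ConfigError("'stages' block is empty")
    unknown = set(cfg["stages"]) - set(STAGE_ORDER)
    if unknown:
        raise ConfigError(f"unknown stage(s): {sorted(unknown)}")
    for name, block in cfg["stages"].items():
        if block is not None and not isinstance(block, dict):
            raise ConfigError(f"stage '{name}' must be a mapping or empty")
    cutoff = (cfg["stages"].get("traj_dist") or {}).get("cutoff")
    if cutoff is not None and not cutoff > 0:
        raise ConfigError("traj_dist.cutoff must be positive")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run(config: dict | str | Path, out_dir, seed: int | None = None) -> dict:
    """Execute the configured stages and return the manifest dict.

    ``config`` may be a dict or a path to a YAML file.  ``seed`` overrides
    the config's global seed.  All referenced input paths must exist.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        validate_config(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(seed if seed is not None else config.get("seed", 0))
    stages = config["stages"]
    artifacts: dict[str, str] = {}
    inputs: dict[str, str] = {}
    results: dict[str, dict] = {}
    state: dict[str, object] = {}

    def record(name: str, path: Path) -> None:
        artifacts[name] = str(path.relative_to(out_dir))

    for stage in STAGE_ORDER:
        if stage not in stages:
            continue
        block = stages[stage] or {}
        try:
            handler = _HANDLERS[stage]
            handler(block, seed, out_dir, state, results, record, inputs)
        except Exception as exc:  # noqa: BLE001 — manifest keeps partials
            logger.error("stage '%s' failed: %s", stage, exc)
            results[stage] = {"error": str(exc)}
            _write_manifest(out_dir, config, seed, inputs, artifacts,
                            results, failed=stage)
            raise
    return _write_manifest(out_dir, config, seed, inputs, artifacts,
                           results, failed=None)


def _write_manifest(out_dir, config, seed, inputs, artifacts, results,
                    failed):
    manifest = {
        "version": azocoil.__version__,
        "seed": seed,
        "config": config,
        "input_hashes": inputs,
        "artifacts": artifacts,
        "results": results,
        "failed_stage": failed,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True,
                   default=_json_default) + "\n")
    return manifest


# ---------------------------------------------------------------------------
# Stage handlers
# ---------------------------------------------------------------------------

def _stage_simulate_melt(block, seed, out_dir, state, results, record,
                         inputs):
    spec = synthetic.MeltSpec(seed=seed, **{
        k: v for k, v in block.items() if k in ("sigma",)})
    if "Ct_uM" in block:
        spec = replace(spec, Ct_list=tuple(c * 1e-6 for c in block["Ct_uM"]))
    curves, truth = synthetic.gen_melt_curves(spec)
    melt_dir = out_dir / "melt"
    melt_dir.mkdir(exist_ok=True)
    for i, curve in enumerate(curves):
        p = melt_dir / f"curve_{i + 1}.csv"
        io.write_melt_csv(p, curve)
        record(f"melt_curve_{i + 1}", p)
    truth_path = melt_dir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2) + "\n")
    record("melt_truth", truth_path)
    state["melt_curves"] = curves
    state["melt_truth"] = truth
    results["simulate_melt"] = {"n_curves": len(curves),
                                "sigma": spec.sigma}


def _stage_fit_melt(block, seed, out_dir, state, results, record, inputs):
    if "inputs" in block:
        paths = [Path(p) for p in block["inputs"]]
        for p in paths:
            inputs[str(p)] = _sha256(p)
        curves = [io.read_melt_csv(p) for p in paths]
    elif "melt_curves" in state:
        curves = state["melt_curves"]
    else:
        raise ConfigError("fit_melt: no 'inputs' given and no simulated "
                          "curves available")
    candidates = block.get("stoichiometries", [2])
    ranked = thermo.compare_models(curves, candidates)
    best = ranked[0]
    report = out_dir / "melt_fit.json"
    io.write_fit_report(report, best)
    record("melt_fit", report)
    summary = {
        "best_stoichiometry": best.params.stoichiometry,
        "dH0_kJ_mol": best.params.dH0, "T0_K": best.params.T0,
        "dCp_kJ_mol_K": best.params.dCp,
        "Ku20_uM": best.Ku20 * 1e6, "Kf20_per_M": best.Kf20,
        "aic_by_stoichiometry": {r.params.stoichiometry: r.aic
                                 for r in ranked},
    }
    truth = state.get("melt_truth")
    if truth is not None:
        summary["truth"] = {k: truth[k] for k in ("dH0", "T0", "dCp")}
        summary["recovery_rel_err"] = {
            "dH0": abs(best.params.dH0 - truth["dH0"]) / truth["dH0"],
            "T0_K_abs": abs(best.params.T0 - truth["T0"]),
            "dCp": abs(best.params.dCp - truth["dCp"]) / truth["dCp"],
        }
    results["fit_melt"] = summary


def _stage_mre(block, seed, out_dir, state, results, record, inputs):
    m = pk.EllipticityMeasurement(
        theta_obs=block["theta_obs_mdeg"], c=block["c_mM"],
        n=block["n_bonds"], l=block["l_cm"])
    results["mre"] = {"mre_deg_cm2_dmol": pk.mean_residue_ellipticity(m)}


def _stage_pss(block, seed, out_dir, state, results, record, inputs):
    path = Path(block["peak_areas"])
    inputs[str(path)] = _sha256(path)
    comp = pk.pss_from_peak_areas(io.read_peak_areas_csv(path))
    results["pss"] = {"f_cis": comp.f_cis, "f_trans": comp.f_trans,
                      "deviation": comp.deviation, "sd": comp.sd,
                      "n_replicates": comp.n_replicates}


def _stage_relax_fit(block, seed, out_dir, state, results, record, inputs):
    if "timeseries" in block:
        path = Path(block["timeseries"])
        inputs[str(path)] = _sha256(path)
        t, y = io.read_timeseries_csv(path)
    else:
        spec = synthetic.RelaxationSpec(seed=seed, **{
            k: v for k, v in block.items()
            if k in ("t_half", "sigma", "n_points")})
        t, y, truth = synthetic.gen_relaxation(spec)
        results.setdefault("relax_fit", {})["truth_t_half_min"] = \
            truth["t_half"]
    fit = pk.fit_relaxation(t, y)
    results.setdefault("relax_fit", {}).update({
        "k_per_min": fit.k, "t_half_min": fit.t_half,
        "amplitude": fit.amplitude, "offset": fit.offset})


def _stage_cycle_sim(block, seed, out_dir, state, results, record, inputs):
    spec = synthetic.CyclingSpec(seed=seed, **{
        k: v for k, v in block.items()
        if k in ("n_cycles", "sigma", "k_tc_uv", "k_ct_uv",
                 "k_tc_blue", "k_ct_blue")})
    t, y, truth = synthetic.gen_cycling(spec)
    p = out_dir / "cycling.csv"
    io.write_timeseries_csv(p, t, y)
    record("cycling_trace", p)
    results["cycle_sim"] = {"pss_uv": truth["pss_uv"],
                            "pss_blue": truth["pss_blue"],
                            "phase_ends": truth["phase_ends"]}


def _stage_traj_dist(block, seed, out_dir, state, results, record, inputs):
    cutoff = block.get("cutoff", tj.SIGNIFICANCE_CUTOFF)
    metric = block.get("metric", "min")
    if "trans_pdbs" in block:
        for key in ("trans_pdbs", "cis_pdbs"):
            for p in block[key]:
                inputs[str(p)] = _sha256(Path(p))
        moiety_path = Path(block["moiety_map"])
        inputs[str(moiety_path)] = _sha256(moiety_path)
        trans = io.read_ensemble_pdb(block["trans_pdbs"], "trans")
        cis = io.read_ensemble_pdb(block["cis_pdbs"], "cis")
        moiety_map = io.read_moiety_map(moiety_path)
    else:
        spec = synthetic.TrajectorySpec(seed=seed, **{
            k: v for k, v in block.items()
            if k in ("n_frames", "n_replicas", "jitter_sigma")})
        trans, cis, moiety_map, truth = synthetic.gen_toy_trajectory(spec)
        truth_path = out_dir / "traj_truth.json"
        truth_path.write_text(
            json.dumps(truth, indent=2, default=_json_default) + "\n")
        record("traj_truth", truth_path)
    chain = block.get("chain", "E")
    trans_tbl = tj.chain_moiety_distances(trans, chain, moiety_map,
                                          metric=metric)
    cis_tbl = tj.chain_moiety_distances(cis, chain, moiety_map,
                                        metric=metric)
    table = tj.normalized_distance_change(trans_tbl, cis_tbl, cutoff=cutoff)
    seq = block.get("sequence", synthetic.E3_SEQUENCE)
    offset = block.get("register_offset", synthetic.E3_REGISTER_OFFSET)
    register = tj.assign_heptad_register(seq, offset)
    heptad = {i + 1: register[i] for i in range(len(seq))}
    p = out_dir / "distance_change.csv"
    io.write_distance_table(p, table, heptad=heptad)
    record("distance_change", p)
    results["traj_dist"] = {
        "cutoff": cutoff, "metric": metric,
        "n_significant": int(table["significant"].sum()),
        "n_pairs": int(len(table))}


def _stage_ff_extract(block, seed, out_dir, state, results, record, inputs):
    isomer = block.get("isomer", "trans")
    coords, bonds, atom_types = synthetic.azobenzene_geometry(isomer)
    fc = {ffparams.canonical_types(k.split("-")): v
          for k, v in block.get("force_constants", {}).items()}
    if not fc:
        fc = ffparams.default_azo_force_constants()
    params = ffparams.measure_internal_coordinates(
        coords, bonds, atom_types, atom_type_filter="NX",
        force_constants=fc)
    block_text = ffparams.emit_parameter_block(params, isomer=isomer)
    p = out_dir / f"azo_bonded_{isomer}.itp"
    p.write_text(block_text)
    record("ff_block", p)
    results["ff_extract"] = {
        "isomer": isomer, "n_bonds": len(params.bonds),
        "n_angles": len(params.angles),
        "n_dihedrals": len(params.dihedrals),
        "restraint_target_deg": ffparams.ISOMER_TARGETS[isomer],
        "restraint_k": ffparams.RESTRAINT_K}


_HANDLERS = {
    "simulate_melt": _stage_simulate_melt,
    "fit_melt": _stage_fit_melt,
    "mre": _stage_mre,
    "pss": _stage_pss,
    "relax_fit": _stage_relax_fit,
    "cycle_sim": _stage_cycle_sim,
    "traj_dist": _stage_traj_dist,
    "ff_extract": _stage_ff_extract,
}
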
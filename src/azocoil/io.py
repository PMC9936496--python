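"""File interchange for the analysis modules.

Formats
-------
* Melt CSV: columns ``temperature_C, signal`` plus header comment keys
  ``# Ct_molar: <float>`` and ``# signal_unit: mdeg|MRE``; one file per
  concentration.
* Time-series CSV: columns ``time_min, value``.
* Peak-area CSV: columns ``replicate, area_trans, area_cis``.
* Distance-change CSV: residue, heptad, moiety, mean_trans, mean_cis,
  sd, delta_norm, significant.
* Trajectories: multi-model PDB, one MODEL per frame, one file per
  replica (written and read with biotite).
* Moiety map / selections: YAML.
* Fit reports: JSON (round-trippable).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from azocoil import thermo
from azocoil.trajectory import MoietyMap, TrajectoryEnsemble

BACKBONE_ATOMS = {"N", "CA", "C", "O"}


# ---------------------------------------------------------------------------
# Melt curves
# ---------------------------------------------------------------------------

def write_melt_csv(path, curve: thermo.MeltCurve) -> None:
    path = Path(path)
    temps_C = curve.temperatures - thermo.KELVIN_OFFSET
    with path.open("w") as fh:
        fh.write(f"# Ct_molar: {curve.Ct!r}\n")
        fh.write(f"# signal_unit: {curve.signal_unit}\n")
        if curve.label:
            fh.write(f"# label: {curve.label}\n")
        fh.write("temperature_C,signal\n")
        for t, s in zip(temps_C, curve.signal):
            fh.write(f"{t:.10g},{s:.10g}\n")


def read_melt_csv(path) -> thermo.MeltCurve:
    path = Path(path)
    meta: dict[str, str] = {}
    with path.open() as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        if not line.startswith("#"):
            break
        n_header += 1
        key, _, value = line.lstrip("# ").partition(":")
        meta[key.strip()] = value.strip()
    if "Ct_molar" not in meta:
        raise ValueError(f"{path}: missing '# Ct_molar:' header")
    df = pd.read_csv(path, skiprows=n_header)
    return thermo.MeltCurve(
        temperatures=thermo.celsius_to_kelvin(df["temperature_C"].to_numpy()),
        signal=df["signal"].to_numpy(),
        Ct=float(meta["Ct_molar"]),
        label=meta.get("label", path.stem),
        signal_unit=meta.get("signal_unit", "MRE"))


def write_fit_report(path, result: thermo.GlobalFitResult) -> None:
    p = result.params
    report = {
        "params": {"dH0_kJ_mol": p.dH0, "T0_K": p.T0,
                   "dCp_kJ_mol_K": p.dCp,
                   "stoichiometry": p.stoichiometry, "hetero": p.hetero},
        "baselines": [{"aF": b.aF, "bF": b.bF, "aU": b.aU, "bU": b.bU}
                      for b in result.baselines],
        "Ku20_uM": result.Ku20 * 1e6,
        "Kf20_per_M": result.Kf20,
        "residual_sum": result.residual_sum,
        "aic": result.aic,
        "converged": result.converged,
        "n_points": result.n_points,
        "ci": {k: list(v) for k, v in result.ci.items()},
    }
    Path(path).write_text(json.dumps(report, indent=2) + "\n")


def read_fit_report(path) -> thermo.GlobalFitResult:
    d = json.loads(Path(path).read_text())
    p = d["params"]
    params = thermo.UnfoldingParams(
        dH0=p["dH0_kJ_mol"], T0=p["T0_K"], dCp=p["dCp_kJ_mol_K"],
        stoichiometry=p["stoichiometry"], hetero=p["hetero"])
    return thermo.GlobalFitResult(
        params=params,
        baselines=[thermo.BaselineParams(**b) for b in d["baselines"]],
        Ku20=d["Ku20_uM"] * 1e-6, Kf20=d["Kf20_per_M"],
        residual_sum=d["residual_sum"], aic=d["aic"],
        converged=d["converged"], n_points=d["n_points"],
        ci={k: tuple(v) for k, v in d["ci"].items()})


# ---------------------------------------------------------------------------
# Time series and peak areas
# ---------------------------------------------------------------------------

def write_timeseries_csv(path, t, y) -> None:
    pd.DataFrame({"time_min": t, "value": y}).to_csv(path, index=False)


def read_timeseries_csv(path):
    df = pd.read_csv(path)
    return df["time_min"].to_numpy(), df["value"].to_numpy()


def write_peak_areas_csv(path, replicates) -> None:
    rows = [{"replicate": i + 1, "area_trans": a, "area_cis": b}
            for i, (a, b) in enumerate(replicates)]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_peak_areas_csv(path):
    df = pd.read_csv(path)
    return list(zip(df["area_trans"], df["area_cis"]))


# ---------------------------------------------------------------------------
# Trajectories (multi-model PDB) and moiety maps
# ---------------------------------------------------------------------------

def _stack_from_replica(coords: np.ndarray,
                        topology: pd.DataFrame) -> struc.AtomArrayStack:
    n_frames, n_atoms = coords.shape[:2]
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = coords.astype(np.float32)
    stack.chain_id = topology["chain"].to_numpy(dtype="U4")
    stack.res_id = topology["residue_index"].to_numpy(dtype=int)
    stack.res_name = topology["residue_name"].to_numpy(dtype="U5")
    stack.atom_name = topology["atom_name"].to_numpy(dtype="U6")
    stack.element = topology["element"].to_numpy(dtype="U2")
    stack.hetero = np.zeros(n_atoms, dtype=bool)
    return stack


def write_replica_pdb(path, coords: np.ndarray,
                      topology: pd.DataFrame) -> None:
    """Write one replica as a multi-model PDB (one MODEL per frame)."""
    f = pdb.PDBFile()
    pdb.set_structure(f, _stack_from_replica(coords, topology))
    f.write(str(path))


def write_ensemble_pdb(directory, ensemble: TrajectoryEnsemble,
                       prefix: str = "replica") -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, rep in enumerate(ensemble.replicas):
        p = directory / f"{prefix}_{ensemble.state_label}_{i + 1}.pdb"
        write_replica_pdb(p, rep, ensemble.topology)
        paths.append(p)
    return paths


def read_ensemble_pdb(paths, state_label: str) -> TrajectoryEnsemble:
    """Read replica multi-model PDB files into a TrajectoryEnsemble.

    Side-chain status is inferred from the atom name (anything outside the
    standard backbone set N/CA/C/O counts as side chain).
    """
    paths = [Path(p) for p in paths]
    if not paths:
        raise ValueError("need at least one replica file")
    replicas = []
    topology = None
    for p in paths:
        f = pdb.PDBFile.read(str(p))
        stack = f.get_structure(model=None)
        replicas.append(np.asarray(stack.coord, dtype=float))
        if topology is None:
            elements = np.char.upper(stack.element.astype("U2"))
            topology = pd.DataFrame({
                "chain": stack.chain_id,
                "residue_index": stack.res_id,
                "residue_name": stack.res_name,
                "atom_name": stack.atom_name,
                "element": elements,
                "is_heavy": elements != "H",
                "is_sidechain": ~np.isin(stack.atom_name,
                                         sorted(BACKBONE_ATOMS)),
            })
            topology.index.name = "atom_id"
    return TrajectoryEnsemble(replicas=replicas, topology=topology,
                              state_label=state_label)


def write_moiety_map(path, moiety_map: MoietyMap) -> None:
    data = {"diazene": sorted(moiety_map.diazene),
            "ring1": sorted(moiety_map.ring1),
            "ring2": sorted(moiety_map.ring2),
            "switch_residue": moiety_map.switch_residue}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_moiety_map(path) -> MoietyMap:
    data = yaml.safe_load(Path(path).read_text())
    return MoietyMap(diazene=frozenset(data["diazene"]),
                     ring1=frozenset(data["ring1"]),
                     ring2=frozenset(data["ring2"]),
                     switch_residue=int(data.get("switch_residue", 0)))


def write_distance_table(path, table: pd.DataFrame,
                         heptad: dict[int, str] | None = None) -> None:
    out = table.copy()
    if heptad is not None:
        out.insert(1, "heptad",
                   out["residue_index"].map(heptad).fillna(""))
    out.to_csv(path, index=False)


def read_distance_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
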
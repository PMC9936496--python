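"""Synthetic inputs with embedded ground truth.

Every generator returns the data in the containers the analysis modules
consume *plus* a machine-readable ``truth`` dict holding the generating
parameters, so recovery tests read the truth from the record rather than
duplicating constants.  Fixed seed ⇒ identical output.

Emulated data shapes:

* multi-concentration CD melting curves of a two-state heterodimer with
  linear folded/unfolded baselines and Gaussian noise;
* first-order cis→trans thermal relaxation time series;
* two-wavelength photocycling traces alternating between photostationary
  states;
* paired trans/cis toy two-helix trajectories carrying a rigid
  three-moiety pseudo-azobenzene side group with analytically known
  distance changes.

The toy trajectory is a geometry harness, not a physical simulation: its
only contract is that the ground-truth distances are known exactly from
the jitter-free construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from azocoil import photokinetics as pk
from azocoil import trajectory as tj
from azocoil import thermo

E3_SEQUENCE = "EIAALEK" * 3
K3_SEQUENCE = "KIAALKE" * 3
E3_REGISTER_OFFSET = "g"   # puts Ile9 at 'a', Leu5/Leu12 at 'd'

AA3 = {"A": "ALA", "E": "GLU", "I": "ILE", "K": "LYS", "L": "LEU",
       "G": "GLY", "Y": "TYR"}


# ---------------------------------------------------------------------------
# Melting curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeltSpec:
    """Design of a synthetic multi-concentration melt experiment.

    Defaults: four total concentrations (10/25/50/100 μM), temperatures
    5–90 °C in 1 °C steps, shared two-state dimer truth, per-curve linear
    baselines in mean-residue-ellipticity units, Gaussian noise σ in the
    same units.
    """

    params: thermo.UnfoldingParams = field(
        default_factory=lambda: thermo.UnfoldingParams(
            dH0=250.0, T0=390.0, dCp=2.0))
    baselines: thermo.BaselineParams = field(
        default_factory=lambda: thermo.BaselineParams(
            aF=-30000.0, bF=20.0, aU=-3000.0, bU=5.0))
    Ct_list: tuple[float, ...] = (10e-6, 25e-6, 50e-6, 100e-6)
    t_min_C: float = 5.0
    t_max_C: float = 90.0
    t_step_C: float = 1.0
    sigma: float = 0.3
    seed: int = 1

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be non-negative")


def gen_melt_curves(spec: MeltSpec | None = None):
    """Generate noisy melting curves from a shared thermodynamic truth.

    Returns ``(curves, truth)`` where ``truth`` records the generating
    parameters, per-curve baselines, concentrations and seed.
    """
    spec = spec or MeltSpec()
    rng = np.random.default_rng(spec.seed)
    temps_K = thermo.celsius_to_kelvin(
        np.arange(spec.t_min_C, spec.t_max_C + spec.t_step_C / 2,
                  spec.t_step_C))
    curves = []
    for Ct in spec.Ct_list:
        clean = thermo.predict_melt_curve(spec.params, spec.baselines,
                                          Ct, temps_K)
        noisy = clean + rng.normal(0.0, spec.sigma, size=clean.shape)
        curves.append(thermo.MeltCurve(
            temperatures=temps_K, signal=noisy, Ct=Ct,
            label=f"Ct={Ct * 1e6:g}uM", signal_unit="MRE"))
    truth = {
        "kind": "melt",
        "dH0": spec.params.dH0, "T0": spec.params.T0,
        "dCp": spec.params.dCp,
        "stoichiometry": spec.params.stoichiometry,
        "hetero": spec.params.hetero,
        "baselines": {"aF": spec.baselines.aF, "bF": spec.baselines.bF,
                      "aU": spec.baselines.aU, "bU": spec.baselines.bU},
        "Ct_list": list(spec.Ct_list),
        "sigma": spec.sigma, "seed": spec.seed,
    }
    return curves, truth


# ---------------------------------------------------------------------------
# Photoswitch time series
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RelaxationSpec:
    """Thermal cis→trans relaxation trace.

    Defaults mirror a slow azobenzene switch: half-life 1690 min, starting
    from a cis-dominant photostationary state (91.3% cis), fully relaxing
    (offset 0), sampled to three half-lives.
    """

    t_half: float = 1690.0      # min
    amplitude: float = 0.913    # initial cis fraction
    offset: float = 0.0
    n_points: int = 40
    t_max: float | None = None  # default: 3 half-lives
    sigma: float = 0.0
    seed: int = 1


def gen_relaxation(spec: RelaxationSpec | None = None):
    """Exponential relaxation series ``(t, y, truth)``; y is cis fraction."""
    spec = spec or RelaxationSpec()
    rng = np.random.default_rng(spec.seed)
    t_max = spec.t_max if spec.t_max is not None else 3.0 * spec.t_half
    t = np.linspace(0.0, t_max, spec.n_points)
    k = np.log(2.0) / spec.t_half
    y = spec.offset + spec.amplitude * np.exp(-k * t)
    y = y + rng.normal(0.0, spec.sigma, size=y.shape)
    truth = {"kind": "relaxation", "t_half": spec.t_half, "k": k,
             "amplitude": spec.amplitude, "offset": spec.offset,
             "sigma": spec.sigma, "seed": spec.seed}
    return t, y, truth


@dataclass(frozen=True)
class CyclingSpec:
    """Alternating two-wavelength photocycling schedule.

    Defaults: six alternating UV (trans→cis) / blue (cis→trans) phases run
    to the photostationary state, starting dark-adapted (all trans).  The
    rate pairs put the UV PSS at ≈91% cis and the blue PSS at ≈8% cis,
    with a slow thermal relaxation running throughout.
    """

    k_tc_uv: float = 0.5        # min⁻¹ at the UV wavelength
    k_ct_uv: float = 0.0476
    k_tc_blue: float = 0.0435
    k_ct_blue: float = 0.5
    k_relax: float = float(np.log(2.0) / 1690.0)
    n_cycles: int = 3
    f_cis0: float = 0.0
    sigma: float = 0.0
    seed: int = 1
    points_per_phase: int = 50


def cycling_model(spec: CyclingSpec | None = None) -> pk.PhotoKineticModel:
    """The alternating UV/blue run-to-PSS schedule as a kinetic model."""
    spec = spec or CyclingSpec()
    phases = []
    for _ in range(spec.n_cycles):
        phases.append(pk.Phase("uv", k_tc=spec.k_tc_uv, k_ct=spec.k_ct_uv,
                               k_relax=spec.k_relax, duration=None))
        phases.append(pk.Phase("blue", k_tc=spec.k_tc_blue,
                               k_ct=spec.k_ct_blue,
                               k_relax=spec.k_relax, duration=None))
    return pk.PhotoKineticModel(schedule=tuple(phases))


def gen_cycling(spec: CyclingSpec | None = None):
    """Photocycling trace ``(t, f_cis, truth)`` with analytic PSS levels."""
    spec = spec or CyclingSpec()
    model = cycling_model(spec)
    t, f, phase_ends = pk.simulate_photokinetics(
        model, f_cis0=spec.f_cis0, points_per_phase=spec.points_per_phase)
    rng = np.random.default_rng(spec.seed)
    y = f + rng.normal(0.0, spec.sigma, size=f.shape)
    truth = {
        "kind": "cycling",
        "pss_uv": model.schedule[0].f_pss,
        "pss_blue": model.schedule[1].f_pss,
        "phase_ends": [{"label": lab, "t": tt, "f_cis": ff}
                       for lab, tt, ff in phase_ends],
        "sigma": spec.sigma, "seed": spec.seed,
    }
    return t, y, truth


# ---------------------------------------------------------------------------
# Toy trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectorySpec:
    """Paired trans/cis toy two-helix trajectory design.

    Two ideal α-helices (rise 1.5 Å/residue, 100°/residue) run parallel
    along z at an axial separation of 9.5 Å, labeled chains E and K with
    the E3/K3 heptad sequences.  A rigid pseudo-azobenzene (2-atom
    diazene, two 6-atom rings) is attached at K-chain residue 9.  In the
    trans state the arm extends toward chain E; the cis state displaces
    the diazene away from chain E by ``cis_diazene_offset`` and swings
    ring 2 back toward chain K by ``cis_ring2_angle_deg``.  Frames add
    i.i.d. Gaussian jitter per atom; replicas use distinct sub-seeds.
    """

    n_frames: int = 100
    n_replicas: int = 3
    jitter_sigma: float = 0.25          # Å per coordinate
    axial_separation: float = 9.5       # Å between helix axes
    cis_diazene_offset: float = 2.0     # Å displacement away from chain E
    cis_ring2_angle_deg: float = 120.0
    switch_residue: int = 9
    seed: int = 1


def _helix_chain(sequence: str, axis_x: float, phase_deg: float,
                 chain_id: str, atom_rows: list, coords: list) -> None:
    """Append CA + two side-chain pseudo-atoms per residue of one helix."""
    n = len(sequence)
    ca = tj.ideal_helix(n) + np.array([axis_x, 0.0, 0.0])
    rot = np.deg2rad(phase_deg)
    cr, sr = np.cos(rot), np.sin(rot)
    ca_rotated = ca.copy()
    ca_rotated[:, 0] = axis_x + (ca[:, 0] - axis_x) * cr - ca[:, 1] * sr
    ca_rotated[:, 1] = (ca[:, 0] - axis_x) * sr + ca[:, 1] * cr
    for i, aa in enumerate(sequence):
        res = i + 1
        c = ca_rotated[i]
        radial = np.array([c[0] - axis_x, c[1], 0.0])
        radial /= np.linalg.norm(radial)
        cb = c + 1.5 * radial
        cg = c + 3.0 * radial
        for name, xyz, element, sidechain in (
                ("CA", c, "C", False), ("CB", cb, "C", True),
                ("CG", cg, "C", True)):
            atom_rows.append({"chain": chain_id, "residue_index": res,
                              "residue_name": AA3[aa], "atom_name": name,
                              "element": element, "is_heavy": True,
                              "is_sidechain": sidechain})
            coords.append(xyz)


def _hexagon(center: np.ndarray, normal: np.ndarray,
             radius: float = 1.4) -> np.ndarray:
    """Six atoms of a planar ring around ``center`` normal to ``normal``."""
    normal = normal / np.linalg.norm(normal)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    ang = np.deg2rad(60.0) * np.arange(6)
    return center + radius * (np.outer(np.cos(ang), u)
                              + np.outer(np.sin(ang), v))


def _rotate_about(points: np.ndarray, origin: np.ndarray, axis: np.ndarray,
                  angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    th = np.deg2rad(angle_deg)
    K = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    return (points - origin) @ R.T + origin


def _base_geometry(spec: TrajectorySpec, state: str):
    """Jitter-free coordinates, topology rows and the moiety map."""
    atom_rows: list[dict] = []
    coords: list[np.ndarray] = []
    half = spec.axial_separation / 2.0
    # Chain E at +x, chain K at −x; phases turn their a/d faces inward.
    _helix_chain(E3_SEQUENCE, +half, 180.0, "E", atom_rows, coords)
    _helix_chain(K3_SEQUENCE, -half, 0.0, "K", atom_rows, coords)

    # Attachment: CA of the switch residue on chain K.
    k_offset = len(E3_SEQUENCE) * 3
    ca_switch = coords[k_offset + (spec.switch_residue - 1) * 3]
    toward_e = np.array([1.0, 0.0, 0.0])   # unit vector toward chain E

    ring1_center = ca_switch + 3.0 * toward_e
    ring1 = _hexagon(ring1_center, normal=np.array([0.0, 0.0, 1.0]))
    n1 = ca_switch + 5.0 * toward_e
    n2 = ca_switch + 6.2 * toward_e
    ring2_center = ca_switch + 8.8 * toward_e
    ring2 = _hexagon(ring2_center, normal=np.array([0.0, 0.0, 1.0]))

    if state == "cis":
        # Diazene steps away from chain E; ring 2 swings back toward K.
        shift = -spec.cis_diazene_offset * toward_e
        n1 = n1 + shift
        n2 = n2 + shift
        ring2 = _rotate_about(ring2 + shift, origin=n2,
                              axis=np.array([0.0, 0.0, 1.0]),
                              angle_deg=spec.cis_ring2_angle_deg)

    moiety_atoms = {"diazene": [n1, n2], "ring1": list(ring1),
                    "ring2": list(ring2)}
    moiety_ids: dict[str, list[int]] = {}
    for name, atoms in moiety_atoms.items():
        ids = []
        for j, xyz in enumerate(atoms):
            ids.append(len(coords))
            element = "N" if name == "diazene" else "C"
            atom_rows.append({
                "chain": "K", "residue_index": spec.switch_residue,
                "residue_name": "AZO",
                "atom_name": f"{name[0].upper()}{name[-1]}{j}",
                "element": element, "is_heavy": True, "is_sidechain": True})
            coords.append(xyz)
        moiety_ids[name] = ids

    topology = pd.DataFrame(atom_rows)
    topology.index.name = "atom_id"
    moiety_map = tj.MoietyMap(diazene=frozenset(moiety_ids["diazene"]),
                              ring1=frozenset(moiety_ids["ring1"]),
                              ring2=frozenset(moiety_ids["ring2"]),
                              switch_residue=spec.switch_residue)
    return np.asarray(coords), topology, moiety_map


def gen_toy_trajectory(spec: TrajectorySpec | None = None):
    """Paired trans/cis ensembles with analytic ground truth.

    Returns ``(trans_ensemble, cis_ensemble, moiety_map, truth)``.  The
    truth record holds the jitter-free per-(residue, moiety) mean
    distances of both states, the analytic delta_norm and its
    significance at the default cutoff, all measured with the default
    minimum heavy-atom-pair metric on the noise-free geometry.
    """
    spec = spec or TrajectorySpec()
    rng = np.random.default_rng(spec.seed)
    ensembles = {}
    truth_tables = {}
    for state in ("trans", "cis"):
        base, topology, moiety_map = _base_geometry(spec, state)
        replicas = []
        for _ in range(spec.n_replicas):
            sub = np.random.default_rng(rng.integers(0, 2**31 - 1))
            jitter = sub.normal(0.0, spec.jitter_sigma,
                                size=(spec.n_frames,) + base.shape)
            replicas.append(base[None, :, :] + jitter)
        ensembles[state] = tj.TrajectoryEnsemble(
            replicas=replicas, topology=topology, state_label=state)
        clean = tj.TrajectoryEnsemble(replicas=[base[None, :, :]],
                                      topology=topology, state_label=state)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            truth_tables[state] = tj.chain_moiety_distances(
                clean, chain="E", moieties=moiety_map, metric="min")
    truth_table = tj.normalized_distance_change(
        truth_tables["trans"], truth_tables["cis"],
        cutoff=tj.SIGNIFICANCE_CUTOFF)
    truth = {
        "kind": "trajectory",
        "cutoff": tj.SIGNIFICANCE_CUTOFF,
        "metric": "min",
        "jitter_sigma": spec.jitter_sigma,
        "seed": spec.seed,
        "n_frames": spec.n_frames,
        "n_replicas": spec.n_replicas,
        "table": truth_table.to_dict(orient="records"),
    }
    return ensembles["trans"], ensembles["cis"], moiety_map, truth


# ---------------------------------------------------------------------------
# Azobenzene geometry for force-field extraction
# ---------------------------------------------------------------------------

def azobenzene_geometry(isomer: str = "trans"):
    """Idealized planar azobenzene C–N=N–C core with two phenyl rings.

    Returns ``(coords, bonds, atom_types)`` suitable for
    :func:`azocoil.ffparams.measure_internal_coordinates`.  The trans
    geometry has a 180° C–N=N–C dihedral, the cis geometry 0° (built by
    rotating one ring around the N=N bond).  Labeled synthetic: bond
    lengths/angles are textbook idealizations, not a quantum-chemical
    optimum.
    """
    if isomer not in ("trans", "cis"):
        raise ValueError("isomer must be 'trans' or 'cis'")
    d_nn, d_cn, d_cc = 1.25, 1.42, 1.40
    # N=N along x, CNN angle 114°.
    n1 = np.array([0.0, 0.0, 0.0])
    n2 = np.array([d_nn, 0.0, 0.0])
    ang = np.deg2rad(180.0 - 114.0)
    c1 = n1 + d_cn * np.array([-np.cos(ang), np.sin(ang), 0.0])
    c2 = n2 + d_cn * np.array([np.cos(ang), -np.sin(ang), 0.0])

    def ring(cipso: np.ndarray, outward: np.ndarray) -> np.ndarray:
        outward = outward / np.linalg.norm(outward)
        center = cipso + d_cc * outward
        pts = _hexagon(center, normal=np.array([0.0, 0.0, 1.0]),
                       radius=d_cc)
        # put the ipso atom exactly at cipso by replacing nearest vertex
        k = int(np.argmin(np.linalg.norm(pts - cipso, axis=1)))
        pts[k] = cipso
        return pts

    ring_a = ring(c1, c1 - n1)
    ring_b = ring(c2, c2 - n2)
    coords = np.vstack([n1, n2, ring_a, ring_b])
    if isomer == "cis":
        coords[8:] = _rotate_about(coords[8:], origin=n2,
                                   axis=n2 - n1, angle_deg=180.0)
    ipso_a = 2 + int(np.argmin(np.linalg.norm(coords[2:8] - c1, axis=1)))
    ring_b0 = coords[8:14]
    ipso_b = 8 + int(np.argmin(np.linalg.norm(
        ring_b0 - coords[1], axis=1)))
    bonds = [(0, 1), (0, ipso_a), (1, ipso_b)]
    for base in (2, 8):
        ring_pts = coords[base:base + 6]
        center = ring_pts.mean(axis=0)
        order = np.argsort(np.arctan2(*(ring_pts - center)[:, [1, 0]].T))
        for a in range(6):
            i = base + int(order[a])
            j = base + int(order[(a + 1) % 6])
            bonds.append((min(i, j), max(i, j)))
    atom_types = ["NX", "NX"] + ["CA"] * 12
    return coords, sorted(set(bonds)), atom_types
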
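"""Trajectory distance statistics for azobenzene–peptide interactions.

Given paired trans/cis trajectory ensembles of a two-chain coiled coil
carrying an azobenzene side chain, this module measures per-frame distances
between each residue of the partner chain and the three azobenzene moieties
(the diazene N=N group, the backbone-proximal phenyl "ring 1" and the distal
"ring 2"), averages them per replica and across replicas, and reports the
normalized trans→cis distance change

    delta_norm = (mean_cis − mean_trans) / mean_trans

with positive values meaning the moiety sits farther away in the cis state.
Changes with |delta_norm| at or above a cutoff (default 0.2) are flagged
significant.  Also provided: 5 Å contact shells around a probe group,
heptad register assignment and RMSD to an ideal α-helix.

Coordinates are in Å throughout, frames are assumed whole (no periodic
imaging is applied).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

HEPTAD_LETTERS = "abcdefg"

#: Default significance cutoff on |delta_norm|.
SIGNIFICANCE_CUTOFF = 0.2

#: Default contact-shell radius, Å (closed boundary, d <= radius).
CONTACT_RADIUS = 5.0


@dataclass(frozen=True)
class MoietyMap:
    """Atom-index sets of the three azobenzene moieties.

    ``diazene`` must hold exactly the two azo nitrogens; ``ring1`` and
    ``ring2`` the heavy atoms of the proximal and distal phenyl rings.
    The three sets are pairwise disjoint.  ``switch_residue`` is the
    residue id carrying the switch in the switch-bearing chain.
    """

    diazene: frozenset[int]
    ring1: frozenset[int]
    ring2: frozenset[int]
    switch_residue: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "diazene", frozenset(self.diazene))
        object.__setattr__(self, "ring1", frozenset(self.ring1))
        object.__setattr__(self, "ring2", frozenset(self.ring2))
        sets = {"diazene": self.diazene, "ring1": self.ring1,
                "ring2": self.ring2}
        for name, s in sets.items():
            if not s:
                raise ValueError(f"moiety '{name}' is empty")
        if len(self.diazene) != 2:
            raise ValueError("diazene must contain exactly 2 atoms")
        names = list(sets)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                if sets[a] & sets[b]:
                    raise ValueError(f"moieties '{a}' and '{b}' overlap")

    def moieties(self) -> dict[str, frozenset[int]]:
        return {"diazene": self.diazene, "ring1": self.ring1,
                "ring2": self.ring2}


@dataclass
class TrajectoryEnsemble:
    """Replicated trajectory with a shared topology.

    ``replicas``: list of (n_frames, n_atoms, 3) coordinate arrays in Å.
    ``topology``: DataFrame indexed by atom id with columns chain,
    residue_index, residue_name, atom_name, element, is_heavy, is_sidechain.
    ``state_label``: 'trans' or 'cis'.
    """

    replicas: list[np.ndarray]
    topology: pd.DataFrame
    state_label: str = "trans"

    REQUIRED_COLUMNS = ("chain", "residue_index", "residue_name",
                        "atom_name", "element", "is_heavy", "is_sidechain")

    def __post_init__(self) -> None:
        if not self.replicas:
            raise ValueError("need at least one replica")
        self.replicas = [np.asarray(r, dtype=float) for r in self.replicas]
        n_atoms = len(self.topology)
        for i, rep in enumerate(self.replicas):
            if rep.ndim != 3 or rep.shape[1:] != (n_atoms, 3):
                raise ValueError(
                    f"replica {i}: shape {rep.shape} inconsistent with "
                    f"{n_atoms}-atom topology")
            if rep.shape[0] < 1:
                raise ValueError(f"replica {i}: no frames")
            if not np.isfinite(rep).all():
                raise ValueError(f"replica {i}: non-finite coordinates")
        missing = set(self.REQUIRED_COLUMNS) - set(self.topology.columns)
        if missing:
            raise ValueError(f"topology missing columns {sorted(missing)}")
        if self.state_label not in ("trans", "cis"):
            raise ValueError("state_label must be 'trans' or 'cis'")
        lengths = [r.shape[0] for r in self.replicas]
        if max(lengths) > 1.1 * min(lengths):
            warnings.warn("replica lengths differ by more than 10%; "
                          "replicas are still weighted equally")

    @property
    def n_replicas(self) -> int:
        return len(self.replicas)

    def atom_ids(self, chain: str | None = None,
                 residue_index: int | None = None,
                 heavy_only: bool = True,
                 sidechain_only: bool = False) -> np.ndarray:
        """Atom ids matching a chain/residue selection."""
        mask = np.ones(len(self.topology), dtype=bool)
        if chain is not None:
            mask &= (self.topology["chain"] == chain).to_numpy()
        if residue_index is not None:
            mask &= (self.topology["residue_index"]
                     == residue_index).to_numpy()
        if heavy_only:
            mask &= self.topology["is_heavy"].to_numpy().astype(bool)
        if sidechain_only:
            mask &= self.topology["is_sidechain"].to_numpy().astype(bool)
        return self.topology.index.to_numpy()[mask]

    def residues(self, chain: str) -> list[tuple[int, str]]:
        sub = self.topology[self.topology["chain"] == chain]
        out = sub.drop_duplicates("residue_index").sort_values("residue_index")
        return list(zip(out["residue_index"], out["residue_name"]))


def assign_heptad_register(sequence: str, register_offset: str = "a") -> str:
    """Cyclic heptad register (a–g) per residue.

    ``register_offset`` is the register letter of the first residue; the
    assignment then cycles a→b→…→g→a along the sequence.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if register_offset not in HEPTAD_LETTERS:
        raise ValueError("register_offset must be one of a–g")
    start = HEPTAD_LETTERS.index(register_offset)
    return "".join(HEPTAD_LETTERS[(start + i) % 7]
                   for i in range(len(sequence)))


def _pairwise_min(a: np.ndarray, b: np.ndarray) -> float:
    return float(cdist(a, b).min())


def _centroid_distance(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)))


_METRICS = {"min": _pairwise_min, "centroid": _centroid_distance}


def moiety_distance_series(ensemble: TrajectoryEnsemble, residue_atoms,
                           moiety_atoms, metric: str = "min"
                           ) -> list[np.ndarray]:
    """Per-frame residue↔moiety distance for every replica.

    ``metric='min'``: minimum over all heavy-atom pairs per frame (the
    contact-analysis convention); ``metric='centroid'``: distance between
    the two heavy-atom centroids.  Symmetric in the two atom sets and
    invariant under rigid motion of a frame.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric '{metric}'")
    res_ids = np.asarray(sorted(residue_atoms), dtype=int)
    moi_ids = np.asarray(sorted(moiety_atoms), dtype=int)
    if res_ids.size == 0 or moi_ids.size == 0:
        raise ValueError("empty atom set after heavy-atom filtering")
    pos = {aid: i for i, aid in enumerate(ensemble.topology.index)}
    res_ix = np.asarray([pos[a] for a in res_ids])
    moi_ix = np.asarray([pos[a] for a in moi_ids])
    fn = _METRICS[metric]
    out = []
    for rep in ensemble.replicas:
        out.append(np.asarray([fn(frame[res_ix], frame[moi_ix])
                               for frame in rep]))
    return out


def ensemble_mean_distance(series_per_replica) -> tuple[float, float]:
    """Replica-averaged distance: per-replica time mean, then unweighted
    mean and sample SD across replicas.  A single replica passes through
    with sd = 0 (warned)."""
    series = [np.asarray(s, dtype=float) for s in series_per_replica]
    if not series:
        raise ValueError("need at least one replica series")
    means = np.asarray([s.mean() for s in series])
    if means.size == 1:
        warnings.warn("single replica: across-replica SD is zero")
        return float(means[0]), 0.0
    return float(means.mean()), float(means.std(ddof=1))


def chain_moiety_distances(ensemble: TrajectoryEnsemble, chain: str,
                           moieties: MoietyMap, metric: str = "min",
                           sidechain_only: bool = False) -> pd.DataFrame:
    """Mean distance from every residue of ``chain`` to each moiety.

    Residue atom sets default to all heavy atoms; ``sidechain_only``
    restricts them to side-chain heavy atoms.  Returns a DataFrame with
    columns residue_index, residue_name, moiety, mean, sd.
    """
    rows = []
    for res_idx, res_name in ensemble.residues(chain):
        atoms = ensemble.atom_ids(chain=chain, residue_index=res_idx,
                                  heavy_only=True,
                                  sidechain_only=sidechain_only)
        if atoms.size == 0:
            continue
        for moiety_name, moiety_atoms in moieties.moieties().items():
            series = moiety_distance_series(ensemble, atoms, moiety_atoms,
                                            metric=metric)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mean, sd = ensemble_mean_distance(series)
            rows.append({"residue_index": res_idx,
                         "residue_name": res_name,
                         "moiety": moiety_name, "mean": mean, "sd": sd})
    return pd.DataFrame(rows)


def normalized_distance_change(trans_means: pd.DataFrame,
                               cis_means: pd.DataFrame,
                               cutoff: float = SIGNIFICANCE_CUTOFF,
                               denominator: str = "trans") -> pd.DataFrame:
    """Normalized trans→cis distance-change table.

    Both inputs come from :func:`chain_moiety_distances` and must share the
    same (residue_index, moiety) keys.  delta_norm = (cis − trans)/trans
    (or /pooled mean with ``denominator='pooled'``); positive means farther
    in cis.  ``significant`` flags |delta_norm| >= cutoff.
    """
    if denominator not in ("trans", "pooled"):
        raise ValueError("denominator must be 'trans' or 'pooled'")
    keys = ["residue_index", "moiety"]
    t = trans_means.set_index(keys).sort_index()
    c = cis_means.set_index(keys).sort_index()
    if not t.index.equals(c.index):
        raise ValueError("trans and cis tables have mismatched "
                         "(residue, moiety) keys")
    if (t["mean"] <= 0).any():
        raise ValueError("trans mean distances must be positive")
    denom = (t["mean"] if denominator == "trans"
             else (t["mean"] + c["mean"]) / 2.0)
    out = pd.DataFrame({
        "residue_name": t["residue_name"],
        "mean_trans": t["mean"],
        "mean_cis": c["mean"],
        "sd_trans": t["sd"],
        "sd_cis": c["sd"],
        "delta_norm": (c["mean"] - t["mean"]) / denom,
    }).reset_index()
    out["significant"] = out["delta_norm"].abs() >= cutoff
    out.attrs["cutoff"] = cutoff
    return out


def contact_shell(frame: np.ndarray, probe_atoms, ensemble_or_topology,
                  chain: str, radius: float = CONTACT_RADIUS) -> list[int]:
    """Residues of ``chain`` with any heavy side-chain atom within
    ``radius`` Å (closed boundary) of any probe atom in ``frame``.

    ``frame`` is an (n_atoms, 3) array aligned with the ensemble topology.
    """
    if not radius > 0:
        raise ValueError("radius must be positive")
    topo = (ensemble_or_topology.topology
            if isinstance(ensemble_or_topology, TrajectoryEnsemble)
            else ensemble_or_topology)
    probe_ids = np.asarray(sorted(probe_atoms), dtype=int)
    if probe_ids.size == 0:
        warnings.warn("empty probe set: contact shell is empty")
        return []
    pos = {aid: i for i, aid in enumerate(topo.index)}
    probe_xyz = frame[[pos[a] for a in probe_ids]]
    sub = topo[(topo["chain"] == chain)
               & topo["is_heavy"].astype(bool)
               & topo["is_sidechain"].astype(bool)]
    hits = []
    for res_idx, grp in sub.groupby("residue_index", sort=True):
        xyz = frame[[pos[a] for a in grp.index]]
        if cdist(xyz, probe_xyz).min() <= radius:
            hits.append(int(res_idx))
    return hits


def ideal_helix(n_residues: int, rise: float = 1.5,
                twist_deg: float = 100.0, radius: float = 2.3) -> np.ndarray:
    """Cα trace of an ideal α-helix along z (rise 1.5 Å, 100°/residue)."""
    if n_residues < 1:
        raise ValueError("need at least one residue")
    i = np.arange(n_residues)
    phi = np.deg2rad(twist_deg) * i
    return np.column_stack([radius * np.cos(phi), radius * np.sin(phi),
                            rise * i])


def _kabsch_rmsd(P: np.ndarray, Q: np.ndarray) -> float:
    # Optimal-superposition RMSD (proper rotations only).  The residual
    # is evaluated on the explicitly rotated coordinates rather than via
    # the singular-value identity, which cancels catastrophically near 0.
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    U, _, Vt = np.linalg.svd(Pc.T @ Qc)
    d = np.sign(np.linalg.det(U @ Vt))
    R = (U * np.array([1.0, 1.0, d])) @ Vt
    aligned = Pc @ R
    return float(np.sqrt(np.mean(np.sum((aligned - Qc) ** 2, axis=1))))


def helix_rmsd(backbone_coords: np.ndarray,
               reference_helix: np.ndarray | None = None) -> float:
    """RMSD of a backbone trace to an ideal α-helix after optimal
    rotation+translation superposition (Kabsch).

    With ``reference_helix=None`` an ideal helix of matching length is
    generated.  Requires at least 3 atoms.
    """
    P = np.asarray(backbone_coords, dtype=float)
    if P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("backbone_coords must be (n, 3)")
    if len(P) < 3:
        raise ValueError("need at least 3 atoms for superposition")
    Q = (ideal_helix(len(P)) if reference_helix is None
         else np.asarray(reference_helix, dtype=float))
    if Q.shape != P.shape:
        raise ValueError("atom counts differ between structure and reference")
    return _kabsch_rmsd(P, Q)
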
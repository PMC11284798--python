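"""Reading and writing trajectories through the role map.

Coordinate files (GRO) and trajectories (XTC/TRR/DCD and anything else
MDAnalysis reads) are translated into :class:`~membuckle.frames.RoleTaggedFrame`
sequences.  The writer emits fixtures produced by the synthetic generator in
the same dialect, so the round trip is exercised by the tests.

MDAnalysis uses Angstrom and picoseconds internally; this package works in nm
and ns throughout, conversion happens only at this boundary.
"""

from __future__ import annotations

import dataclasses
import os
import warnings

import numpy as np
import yaml

from .frames import ChainVectors, RoleAtoms, RoleMap, RoleTaggedFrame

__all__ = ["load_trajectory", "write_fixture", "load_ground_truth"]

_A_PER_NM = 10.0
_PS_PER_NS = 1000.0


def _import_mda():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

class _RoleIndex:
    """Static per-topology atom indices for every role and chain."""

    def __init__(self, universe, role_map: RoleMap):
        role_map.validate()
        lipid_resnames = role_map.lipid_resnames
        residues = universe.residues
        self.lipid_residues = [r for r in residues if r.resname in lipid_resnames]
        if not self.lipid_residues:
            raise ValueError("no lipid residues matched the role map species_defs")
        self.species = np.array(
            [lipid_resnames[r.resname] for r in self.lipid_residues], dtype="U16"
        )
        res_to_lipid = {r.resindex: i for i, r in enumerate(self.lipid_residues)}

        names = universe.atoms.names
        resnames = universe.atoms.resnames
        resindices = universe.atoms.resindices

        self.role_atoms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for role, selectors in role_map.role_selectors.items():
            mask = np.zeros(len(names), dtype=bool)
            for resname, atomname in selectors:
                mask |= (resnames == resname) & (names == atomname)
            idx = np.nonzero(mask)[0]
            if idx.size == 0:
                raise ValueError(f"role '{role}' matched no atoms in the topology")
            owner = np.array(
                [res_to_lipid.get(ri, -1) for ri in resindices[idx]], dtype=np.int64
            )
            self.role_atoms[role] = (idx, owner)

        # exactly one phosphorus marker per lipid, ordered by lipid index
        m_idx, m_owner = self.role_atoms["phosphorus_marker"]
        if np.any(m_owner < 0):
            raise ValueError("phosphorus_marker matched non-lipid atoms")
        counts = np.bincount(m_owner, minlength=len(self.lipid_residues))
        if np.any(counts != 1):
            bad = np.nonzero(counts != 1)[0][:5]
            raise ValueError(f"lipids {bad.tolist()} do not have exactly one marker atom")
        self.marker_idx = m_idx[np.argsort(m_owner)]

        # chain vectors
        self.chains: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        chain_names = {c for chains in role_map.chain_vectors.values() for c in chains}
        for chain in sorted(chain_names):
            starts, ends, owners = [], [], []
            for r in self.lipid_residues:
                sp = lipid_resnames[r.resname]
                pairs = role_map.chain_vectors.get(sp, {}).get(chain)
                if not pairs:
                    continue
                name_to_idx = {n: i for n, i in zip(r.atoms.names, r.atoms.indices)}
                for a1, a2 in pairs:
                    if a1 not in name_to_idx or a2 not in name_to_idx:
                        raise ValueError(
                            f"chain '{chain}' atom pair ({a1}, {a2}) missing in residue "
                            f"{r.resname} {r.resid}"
                        )
                    starts.append(name_to_idx[a1])
                    ends.append(name_to_idx[a2])
                    owners.append(res_to_lipid[r.resindex])
            if starts:
                self.chains[chain] = (
                    np.array(starts), np.array(ends), np.array(owners, dtype=np.int64)
                )


def load_trajectory(
    coord_path,
    traj_path=None,
    role_map: RoleMap | None = None,
    frame_slice: slice | None = None,
    dt: float | None = None,
) -> list[RoleTaggedFrame]:
    """Load a coordinate/trajectory pair and tag atoms by role.

    Parameters
    ----------
    coord_path : coordinate/topology file (e.g. GRO).
    traj_path : trajectory file (e.g. XTC); omit to read the single frame of
        ``coord_path``.
    role_map : role assignment; required.
    frame_slice : optional ``slice`` over trajectory frames (e.g. to analyze
        only the tail of a production run).
    dt : frame spacing in ns, used when the trajectory stores no time stamps.
    """
    if role_map is None:
        raise ValueError("a RoleMap is required")
    mda = _import_mda()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(coord_path), *( [str(traj_path)] if traj_path else [] ))
    index = _RoleIndex(u, role_map)

    frames: list[RoleTaggedFrame] = []
    traj = u.trajectory[frame_slice] if frame_slice is not None else u.trajectory
    for i, ts in enumerate(traj):
        if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
            raise ValueError("trajectory frame has no box dimensions (L_x, L_y required)")
        box = tuple(float(v) / _A_PER_NM for v in ts.dimensions[:3])
        pos = u.atoms.positions / _A_PER_NM
        time = float(ts.time) / _PS_PER_NS if ts.time is not None else 0.0
        if (ts.time is None or (i > 0 and time == frames[-1].time)) and dt is None:
            raise ValueError("trajectory has no usable time stamps; supply dt")
        if dt is not None:
            time = i * dt

        roles = {
            role: RoleAtoms(pos[idx], owner)
            for role, (idx, owner) in index.role_atoms.items()
            if role != "phosphorus_marker"
        }
        chain_vectors = {
            chain: ChainVectors(starts=pos[s], ends=pos[e], lipid_index=o)
            for chain, (s, e, o) in index.chains.items()
        }
        frames.append(
            RoleTaggedFrame(
                time=time,
                box=box,
                species=index.species.copy(),
                markers=pos[index.marker_idx],
                roles=roles,
                chain_vectors=chain_vectors,
            )
        )
    return frames


# ---------------------------------------------------------------------------
# writing synthetic fixtures
# ---------------------------------------------------------------------------

def _lipid_atom_layout(frame: RoleTaggedFrame) -> list[tuple[str, str, object]]:
    """Per-lipid atom layout as (atom_name, source_kind, source_ref), matching
    the synthetic generator's naming convention."""
    layout: list[tuple[str, str, object]] = [("P8", "marker", None)]
    n = frame.n_lipids

    def occurrences(role: str) -> int:
        ra = frame.roles[role]
        return int(np.bincount(ra.lipid_index, minlength=n).max())

    for k in range(occurrences("tail_terminal")):
        layout.append((f"T{k + 1}", "role", ("tail_terminal", k)))
    for k in range(occurrences("head_heavy")):
        layout.append((f"H{k + 1}", "role", ("head_heavy", k)))
    layout.append(("TT1", "role", ("tail_heavy", 0)))
    prefix = {"sn1": "A", "sn2": "B"}
    for chain in frame.chain_vectors:
        cv = frame.chain_vectors[chain]
        n_vec = cv.lipid_index.size // n
        p = prefix.get(chain, chain[:1].upper())
        layout.append((f"{p}1", "chain_start", (chain, 0)))
        for k in range(n_vec):
            layout.append((f"{p}{k + 2}", "chain_end", (chain, k)))
    centers = sorted(r for r in frame.roles if r.startswith("center_"))
    for j, name in enumerate(centers):
        layout.append((f"G{j + 1}", "role", (name, 0)))
    return layout


def _role_occurrence_index(frame: RoleTaggedFrame, role: str) -> dict[tuple[str, int], np.ndarray]:
    """role -> occurrence -> per-lipid atom row indices (stable order)."""
    ra = frame.roles[role]
    order = np.argsort(ra.lipid_index, kind="stable")
    owner = ra.lipid_index[order]
    # occurrence number within each lipid
    occ = np.zeros(owner.size, dtype=int)
    for i in range(1, owner.size):
        occ[i] = occ[i - 1] + 1 if owner[i] == owner[i - 1] else 0
    table: dict[int, np.ndarray] = {}
    n = frame.n_lipids
    for k in range(occ.max() + 1 if occ.size else 0):
        sel = order[occ == k]
        rows = np.full(n, -1, dtype=np.int64)
        rows[owner[occ == k]] = sel
        table[k] = rows
    return table


def _frame_coordinates(frame: RoleTaggedFrame, layout) -> np.ndarray:
    """Assemble (n_lipids * n_atoms_per_lipid + n_waters, 3) coordinates."""
    n = frame.n_lipids
    role_tables: dict[str, dict] = {}
    chain_shapes: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chain, cv in frame.chain_vectors.items():
        n_vec = cv.lipid_index.size // n
        order = np.argsort(cv.lipid_index, kind="stable")
        chain_shapes[chain] = (
            cv.starts[order].reshape(n, n_vec, 3),
            cv.ends[order].reshape(n, n_vec, 3),
        )
    cols = []
    for name, kind, ref in layout:
        if kind == "marker":
            cols.append(frame.markers)
        elif kind == "role":
            role, k = ref
            if role not in role_tables:
                role_tables[role] = _role_occurrence_index(frame, role)
            rows = role_tables[role][k]
            if np.any(rows < 0):
                raise ValueError(f"role '{role}' occurrence {k} missing for some lipids")
            cols.append(frame.roles[role].coords[rows])
        elif kind == "chain_start":
            chain, k = ref
            cols.append(chain_shapes[chain][0][:, k])
        elif kind == "chain_end":
            chain, k = ref
            cols.append(chain_shapes[chain][1][:, k])
    lipid_block = np.stack(cols, axis=1).reshape(n * len(layout), 3)
    waters = frame.roles["water_oxygen"].coords if "water_oxygen" in frame.roles else np.empty((0, 3))
    return np.concatenate([lipid_block, waters])


def write_fixture(frames: list[RoleTaggedFrame], ground_truth, out_dir) -> dict[str, str]:
    """Write a generated trajectory as GRO + XTC plus ground truth and role map
    as YAML.  Returns the paths written.

    Requires a constant atom count and constant species labels across frames
    (trajectory formats carry one topology); the generator guarantees both
    unless species are resampled per frame.
    """
    mda = _import_mda()
    os.makedirs(out_dir, exist_ok=True)
    first = frames[0]
    for fr in frames[1:]:
        if not np.array_equal(fr.species, first.species):
            raise ValueError(
                "species vary across frames; generate with resample_species=False "
                "to write a file fixture"
            )
    layout = _lipid_atom_layout(first)
    n_lip = first.n_lipids
    n_wat = first.roles["water_oxygen"].coords.shape[0] if "water_oxygen" in first.roles else 0
    n_atoms = n_lip * len(layout) + n_wat

    atom_names = [name for name, _, _ in layout] * n_lip + ["OW"] * n_wat
    resindex = [i for i in range(n_lip) for _ in layout] + list(range(n_lip, n_lip + n_wat))
    residue_resnames = list(first.species) + ["SOL"] * n_wat

    u = mda.Universe.empty(
        n_atoms, n_residues=n_lip + n_wat, atom_resindex=np.array(resindex), trajectory=True
    )
    u.add_TopologyAttr("names", atom_names)
    u.add_TopologyAttr("resnames", residue_resnames)
    u.add_TopologyAttr("resids", np.arange(1, n_lip + n_wat + 1))
    dims = [first.box[0] * _A_PER_NM, first.box[1] * _A_PER_NM, first.box[2] * _A_PER_NM,
            90.0, 90.0, 90.0]

    gro = os.path.join(out_dir, "system.gro")
    xtc = os.path.join(out_dir, "traj.xtc")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u.atoms.positions = _frame_coordinates(first, layout) * _A_PER_NM
        u.dimensions = dims
        u.atoms.write(gro)
        with mda.Writer(xtc, n_atoms) as w:
            for fr in frames:
                u.atoms.positions = _frame_coordinates(fr, layout) * _A_PER_NM
                u.trajectory.ts.time = fr.time * _PS_PER_NS
                u.dimensions = dims
                w.write(u.atoms)

    paths = {"gro": gro, "xtc": xtc}
    if ground_truth is not None:
        gt_path = os.path.join(out_dir, "ground_truth.yaml")
        doc = {
            "spec": dataclasses.asdict(ground_truth.spec),
            "center_heights": dict(ground_truth.center_heights),
            "leaflet": ground_truth.leaflet.tolist(),
            "J_ab": float(ground_truth.J_ab),
            "max_abs_curvature": float(ground_truth.max_abs_curvature),
        }
        doc["spec"]["extra_harmonics"] = [list(h) for h in doc["spec"]["extra_harmonics"]]
        doc["spec"]["centers_heights"] = list(doc["spec"]["centers_heights"])
        with open(gt_path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)
        paths["ground_truth"] = gt_path
    return paths


def load_ground_truth(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
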
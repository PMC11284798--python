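"""Role-tagged trajectory frames and the user-supplied role map.

The analysis never cares about force-field atom names directly: a *role map*
assigns residue/atom names to the semantic roles the estimators need
(phosphorus marker, terminal tail centers, head/tail heavy atoms, water
oxygens, chain vectors).  A :class:`RoleTaggedFrame` is one trajectory frame
with coordinates grouped by role, periodic box dimensions, and per-lipid
species and leaflet labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .surface import SurfaceFit, ArcDiscretization, discretize, fit_surface

__all__ = [
    "RoleMap",
    "RoleAtoms",
    "ChainVectors",
    "RoleTaggedFrame",
    "FrameFits",
    "assign_leaflets",
    "builtin_role_map",
    "fit_frames",
    "CORE_ROLES",
]

#: roles every role map must define (extra center roles are allowed)
CORE_ROLES = (
    "phosphorus_marker",
    "tail_terminal",
    "head_heavy",
    "tail_heavy",
    "water_oxygen",
)


@dataclass
class RoleMap:
    """Mapping from residue/atom names to semantic analysis roles.

    Attributes
    ----------
    species_defs : mapping species name -> list of residue names.
    role_selectors : mapping role -> list of (residue_name, atom_name) pairs.
        Must cover all of :data:`CORE_ROLES`; additional keys define extra
        tracked centers (used e.g. for pivotal-plane per-atom surfaces).
    chain_vectors : mapping species -> chain name (e.g. ``sn1``/``sn2``) ->
        ordered list of (atom_name, atom_name) pairs defining the C-C or C-H
        vectors of that chain.
    """

    species_defs: dict[str, list[str]]
    role_selectors: dict[str, list[tuple[str, str]]]
    chain_vectors: dict[str, dict[str, list[tuple[str, str]]]] = field(default_factory=dict)

    def validate(self) -> None:
        for role in CORE_ROLES:
            if not self.role_selectors.get(role):
                raise ValueError(f"role map missing selectors for role '{role}'")
        markers = set(map(tuple, self.role_selectors["phosphorus_marker"]))
        terminals = set(map(tuple, self.role_selectors["tail_terminal"]))
        overlap = markers & terminals
        if overlap:
            raise ValueError(
                f"phosphorus_marker and tail_terminal selectors overlap: {sorted(overlap)}"
            )

    @property
    def lipid_resnames(self) -> dict[str, str]:
        """residue name -> species name for all lipid species."""
        out: dict[str, str] = {}
        for sp, resnames in self.species_defs.items():
            for rn in resnames:
                out[rn] = sp
        return out

    def extra_center_roles(self) -> list[str]:
        return [r for r in self.role_selectors if r not in CORE_ROLES]

    def to_yaml(self, path) -> None:
        doc = {
            "species_defs": {k: list(v) for k, v in self.species_defs.items()},
            "role_selectors": {
                k: [list(p) for p in v] for k, v in self.role_selectors.items()
            },
            "chain_vectors": {
                sp: {ch: [list(p) for p in pairs] for ch, pairs in chains.items()}
                for sp, chains in self.chain_vectors.items()
            },
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RoleMap":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        rm = cls(
            species_defs=doc["species_defs"],
            role_selectors={
                k: [tuple(p) for p in v] for k, v in doc["role_selectors"].items()
            },
            chain_vectors={
                sp: {ch: [tuple(p) for p in pairs] for ch, pairs in chains.items()}
                for sp, chains in doc.get("chain_vectors", {}).items()
            },
        )
        rm.validate()
        return rm


#: Best-effort role maps for common POPC/CHL force-field naming conventions.
#: These are convenience defaults assembled from public topology files and
#: are NOT validated against any particular simulation setup — always review
#: and override them for production analysis (atom-role assignments, in
#: particular head vs. tail heavy atoms and chain-vector definitions, differ
#: between parameter sets and versions).
_BUILTIN_ROLE_MAPS: dict[str, dict] = {
    "charmm36": dict(
        species_defs={"POPC": ["POPC"], "CHL": ["CHL1"]},
        role_selectors={
            "phosphorus_marker": [("POPC", "P")],
            "tail_terminal": [("POPC", "C216"), ("POPC", "C318")],
            "head_heavy": [("POPC", a) for a in
                           ("N", "C12", "C13", "C14", "C15", "C11", "P",
                            "O11", "O12", "O13", "O14")],
            "tail_heavy": [("POPC", a) for a in ("C215", "C216", "C317", "C318")],
            "water_oxygen": [("TIP3", "OH2")],
        },
        chain_vectors={
            "POPC": {
                "sn1": [("C32", "C34"), ("C34", "C36"), ("C36", "C38")],
                "sn2": [("C22", "C24"), ("C24", "C26"), ("C26", "C28")],
            }
        },
    ),
    "lipid21": dict(
        species_defs={"POPC": ["PC", "PA", "OL"], "CHL": ["CHL"]},
        role_selectors={
            "phosphorus_marker": [("PC", "P31")],
            "tail_terminal": [("PA", "C116"), ("OL", "C118")],
            "head_heavy": [("PC", a) for a in
                           ("N31", "C31", "C32", "C33", "C34", "C35", "P31")],
            "tail_heavy": [("PA", "C115"), ("PA", "C116"),
                           ("OL", "C117"), ("OL", "C118")],
            "water_oxygen": [("WAT", "O")],
        },
        chain_vectors={},
    ),
    "martini": dict(
        species_defs={"POPC": ["POPC"], "CHL": ["CHOL"]},
        role_selectors={
            "phosphorus_marker": [("POPC", "PO4"), ("CHOL", "ROH")],
            "tail_terminal": [("POPC", "C4A"), ("POPC", "C4B")],
            "head_heavy": [("POPC", "NC3"), ("POPC", "PO4")],
            "tail_heavy": [("POPC", "C4A"), ("POPC", "C4B")],
            "water_oxygen": [("W", "W")],
        },
        chain_vectors={
            "POPC": {
                "sn1": [("C1A", "D2A"), ("D2A", "C3A"), ("C3A", "C4A")],
                "sn2": [("C1B", "C2B"), ("C2B", "C3B"), ("C3B", "C4B")],
            }
        },
    ),
}


def builtin_role_map(force_field: str) -> "RoleMap":
    """A best-effort role map for a named force-field convention.

    Supported names: ``charmm36``, ``lipid21``, ``martini``.  The returned map
    is a starting point only — verify every selector against your topology
    before trusting curvature profiles built from it.
    """
    try:
        kw = _BUILTIN_ROLE_MAPS[force_field]
    except KeyError:
        raise ValueError(
            f"no builtin role map '{force_field}'; available: {sorted(_BUILTIN_ROLE_MAPS)}"
        ) from None
    rm = RoleMap(**{k: v for k, v in kw.items()})
    rm.validate()
    return rm


@dataclass
class RoleAtoms:
    """Coordinates of one role in one frame, with the owning lipid of each atom
    (index into the frame's lipid table; -1 for water/solvent atoms)."""

    coords: np.ndarray       # (m, 3) nm
    lipid_index: np.ndarray  # (m,) int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        self.lipid_index = np.asarray(self.lipid_index, dtype=np.int64).ravel()
        if self.coords.shape[0] != self.lipid_index.shape[0]:
            raise ValueError("coords and lipid_index length mismatch")


@dataclass
class ChainVectors:
    """Ordered bond vectors of one named chain (e.g. sn1 C-C vectors)."""

    starts: np.ndarray       # (m, 3)
    ends: np.ndarray         # (m, 3)
    lipid_index: np.ndarray  # (m,)

    def vectors(self) -> np.ndarray:
        return self.ends - self.starts

    def unit_vectors(self) -> np.ndarray:
        v = self.vectors()
        norm = np.linalg.norm(v, axis=1)
        if np.any(norm < 1e-12):
            raise ValueError("zero-length chain vector")
        return v / norm[:, None]


@dataclass
class RoleTaggedFrame:
    """One trajectory frame grouped by semantic role.

    Coordinates are in nm and wrapped into the primary cell ``[0, L)`` along
    each axis.  ``markers`` holds the single phosphorus-marker position per
    lipid, ordered by lipid index; all other roles live in ``roles``.
    """

    time: float                       # ns
    box: tuple[float, float, float]   # (L_x, L_y, L_z) nm
    species: np.ndarray               # (n_lipids,) str
    markers: np.ndarray               # (n_lipids, 3) nm
    roles: dict[str, RoleAtoms]
    chain_vectors: dict[str, ChainVectors] = field(default_factory=dict)
    leaflet: np.ndarray | None = None  # (n_lipids,) 'upper'/'lower'

    def __post_init__(self) -> None:
        self.species = np.asarray(self.species, dtype="U16")
        self.markers = np.asarray(self.markers, dtype=float).reshape(-1, 3)
        if self.markers.shape[0] != self.species.shape[0]:
            raise ValueError("markers and species length mismatch")
        box = np.asarray(self.box, dtype=float)
        self.box = (float(box[0]), float(box[1]), float(box[2]))
        self.markers = self.wrap(self.markers)
        for role in self.roles.values():
            role.coords = self.wrap(role.coords)

    @property
    def n_lipids(self) -> int:
        return self.species.size

    def wrap(self, coords: np.ndarray) -> np.ndarray:
        return np.mod(coords, np.asarray(self.box))

    def role(self, name: str) -> RoleAtoms:
        try:
            return self.roles[name]
        except KeyError:
            raise KeyError(f"frame has no atoms for role '{name}'") from None

    def lipids_in_leaflet(self, leaflet: str) -> np.ndarray:
        if self.leaflet is None:
            raise ValueError("leaflets not assigned; call assign_leaflets first")
        return np.nonzero(self.leaflet == leaflet)[0]


def assign_leaflets(frame: RoleTaggedFrame, midplane: SurfaceFit) -> RoleTaggedFrame:
    """Label each lipid upper/lower by its marker's side of the midplane curve.

    A lipid is *upper* iff its phosphorus marker lies above ``Z^m(x)`` at the
    marker's x.  A marker exactly on the midplane falls back to the mean z of
    the lipid's terminal tail centers; if that is ambiguous too, an error is
    raised.  Idempotent: relabeling an already-labeled frame changes nothing.
    """
    dz = frame.markers[:, 2] - np.asarray(midplane.z(frame.markers[:, 0]))
    labels = np.where(dz > 0, "upper", "lower").astype("U5")
    on_plane = np.nonzero(dz == 0.0)[0]
    if on_plane.size:
        term = frame.role("tail_terminal")
        for i in on_plane:
            tz = term.coords[term.lipid_index == i, 2]
            ref = np.asarray(midplane.z(term.coords[term.lipid_index == i, 0]))
            off = np.mean(tz - ref) if tz.size else 0.0
            if off == 0.0:
                raise ValueError(f"lipid {i}: marker on midplane and terminal offset ambiguous")
            labels[i] = "upper" if off > 0 else "lower"
    frame.leaflet = labels
    return frame


@dataclass
class FrameFits:
    """The three per-frame surface fits plus cached arc discretizations."""

    midplane: SurfaceFit
    upper: SurfaceFit
    lower: SurfaceFit
    time: float = 0.0
    _disc_cache: dict = field(default_factory=dict, repr=False)

    def get(self, surface: str) -> SurfaceFit:
        return getattr(self, surface)

    def disc(self, surface: str, delta_s: float = 0.1) -> ArcDiscretization:
        key = (surface, round(delta_s, 12))
        if key not in self._disc_cache:
            self._disc_cache[key] = discretize(self.get(surface), delta_s)
        return self._disc_cache[key]


def fit_frames(
    frames: list[RoleTaggedFrame], n_harmonics: int = 6
) -> list[FrameFits]:
    """Fit midplane (terminal tail centers) and leaflet (phosphorus marker)
    surfaces for every frame, assigning leaflets from the midplane fit if the
    frame is not labeled yet."""
    out = []
    for fr in frames:
        term = fr.role("tail_terminal")
        xz = term.coords[:, [0, 2]]
        mid = fit_surface(xz, fr.box[0], n_harmonics)
        if fr.leaflet is None:
            assign_leaflets(fr, mid)
        fits = {}
        for leaf in ("upper", "lower"):
            sel = fr.lipids_in_leaflet(leaf)
            if sel.size == 0:
                raise ValueError(f"no lipids in {leaf} leaflet")
            pts = fr.markers[sel][:, [0, 2]]
            fits[leaf] = fit_surface(pts, fr.box[0], n_harmonics)
        out.append(FrameFits(midplane=mid, upper=fits["upper"], lower=fits["lower"],
                             time=fr.time))
    return out
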
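"""Lightweight coordinate container plus PDB/GRO I/O.

Coordinates are stored in Angstrom internally.  The GRO writer converts to
nm via MDAnalysis, which owns all file parsing and writing here; the
container is a thin array-of-atoms view convenient for geometric
construction (one backbone pseudo-atom per residue plus optional side-chain
pseudo-atoms, i.e. coarse-grain-ready structures, or plain Calpha traces).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Atom names treated as the backbone / Calpha role.
BACKBONE_NAMES = ("BB", "CA")

#: Three-letter -> one-letter residue codes.
THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: Number of side-chain pseudo-atoms per residue in the CG-ready
#: representation (Martini-style mapping: GLY/ALA none, rings several).
SIDECHAIN_BEADS = {
    "G": 0, "A": 0, "C": 1, "D": 1, "E": 1, "F": 3, "H": 3, "I": 1,
    "K": 2, "L": 1, "M": 1, "N": 1, "P": 1, "Q": 1, "R": 2, "S": 1,
    "T": 1, "V": 1, "W": 4, "Y": 3,
}


@dataclass
class Structure:
    """A set of atoms: parallel arrays over chain, residue, name, position."""

    chains: np.ndarray        # str, per atom
    resids: np.ndarray        # int, per atom (author numbering, 1-based)
    resnames: np.ndarray      # str three-letter, per atom
    names: np.ndarray         # str atom name, per atom
    coords: np.ndarray        # (n_atoms, 3) float64, Angstrom
    box: np.ndarray | None = field(default=None)  # (3,) Angstrom, optional

    def __post_init__(self):
        n = len(self.names)
        self.chains = np.asarray(self.chains, dtype=object)
        self.resids = np.asarray(self.resids, dtype=int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.names = np.asarray(self.names, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)
        if not (len(self.chains) == len(self.resids) == len(self.resnames) == n):
            raise ValueError("atom attribute arrays have inconsistent lengths")
        for chain in np.unique(self.chains.astype(str)):
            r = self.residue_ids(chain)
            if np.any(np.diff(r) <= 0):
                raise ValueError(f"residue numbers not strictly increasing in chain {chain!r}")

    # -- residue-level views ------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def residue_ids(self, chain: str | None = None) -> np.ndarray:
        """Ordered unique residue ids (optionally restricted to one chain)."""
        mask = np.ones(self.n_atoms, bool) if chain is None else (self.chains == chain)
        _, idx = np.unique(self.resids[mask], return_index=True)
        return np.sort(self.resids[mask][np.sort(idx)])

    @property
    def backbone_mask(self) -> np.ndarray:
        return np.isin(self.names.astype(str), BACKBONE_NAMES)

    def backbone(self) -> tuple[np.ndarray, np.ndarray]:
        """(resids, positions) of backbone atoms, ordered by residue number."""
        m = self.backbone_mask
        if not m.any():
            raise ValueError("structure has no backbone (BB/CA) atoms")
        r, xyz = self.resids[m], self.coords[m]
        order = np.argsort(r, kind="stable")
        return r[order], xyz[order]

    @property
    def sequence(self) -> str:
        """One-letter sequence over backbone residues ('X' for unknowns)."""
        m = self.backbone_mask
        r, names = self.resids[m], self.resnames[m]
        order = np.argsort(r, kind="stable")
        return "".join(THREE_TO_ONE.get(str(n), "X") for n in names[order])

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Apply ``x -> R x + t`` (rigid body), returning a new Structure."""
        new = self.coords @ np.asarray(rotation).T + np.asarray(translation)
        return Structure(self.chains.copy(), self.resids.copy(),
                         self.resnames.copy(), self.names.copy(), new, self.box)

    def concat(self, other: "Structure") -> "Structure":
        return Structure(
            np.concatenate([self.chains, other.chains]),
            np.concatenate([self.resids, other.resids]),
            np.concatenate([self.resnames, other.resnames]),
            np.concatenate([self.names, other.names]),
            np.vstack([self.coords, other.coords]),
            self.box if self.box is not None else other.box,
        )

    def subset(self, atom_mask: np.ndarray) -> "Structure":
        return Structure(self.chains[atom_mask], self.resids[atom_mask],
                         self.resnames[atom_mask], self.names[atom_mask],
                         self.coords[atom_mask], self.box)

    # -- I/O ----------------------------------------------------------------

    def to_universe(self):
        """Build an MDAnalysis Universe (used by the PDB/GRO writers)."""
        import MDAnalysis as mda

        uniq, resindex = np.unique(
            np.array([f"{c}|{r}" for c, r in zip(self.chains, self.resids)]),
            return_inverse=True,
        )
        # preserve input residue order rather than lexicographic order
        first_seen = {}
        order = []
        for i in resindex:
            if i not in first_seen:
                first_seen[i] = len(order)
                order.append(i)
        remap = {old: new for new, old in enumerate(order)}
        resindex = np.array([remap[i] for i in resindex])
        n_res = len(order)

        res_resids = np.empty(n_res, int)
        res_names = np.empty(n_res, object)
        res_seg = np.empty(n_res, object)
        for atom, ri in enumerate(resindex):
            res_resids[ri] = self.resids[atom]
            res_names[ri] = self.resnames[atom]
            res_seg[ri] = self.chains[atom]
        segs, segindex = np.unique(res_seg.astype(str), return_inverse=True)

        u = mda.Universe.empty(
            self.n_atoms, n_residues=n_res, n_segments=len(segs),
            atom_resindex=resindex, residue_segindex=segindex, trajectory=True,
        )
        u.add_TopologyAttr("names", self.names.astype(str))
        u.add_TopologyAttr("resnames", res_names.astype(str))
        u.add_TopologyAttr("resids", res_resids)
        u.add_TopologyAttr("segids", segs)
        u.add_TopologyAttr("chainIDs", self.chains.astype(str))
        u.add_TopologyAttr("elements", np.array(["C"] * self.n_atoms))
        u.atoms.positions = self.coords
        if self.box is not None:
            u.dimensions = [*self.box, 90.0, 90.0, 90.0]
        return u

    def write(self, path: str | Path) -> None:
        """Write to PDB or GRO (by extension); GRO is emitted in nm."""
        u = self.to_universe()
        if u.dimensions is None and str(path).lower().endswith(".gro"):
            u.dimensions = [1.0, 1.0, 1.0, 90.0, 90.0, 90.0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u.atoms.write(str(path))

    @classmethod
    def from_file(cls, path: str | Path) -> "Structure":
        """Read a PDB (ATOM/HETATM, author numbering) or GRO file."""
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(path))
        atoms = u.atoms
        try:
            chains = atoms.chainIDs
        except (AttributeError, mda.exceptions.NoDataError):
            chains = atoms.segids
        chains = np.array([c if str(c).strip() else "A" for c in chains], dtype=object)
        box = None
        if u.dimensions is not None and np.all(u.dimensions[:3] > 0):
            box = np.array(u.dimensions[:3], float)
        return cls(chains, atoms.resids.copy(), atoms.resnames.astype(object),
                   atoms.names.astype(object), atoms.positions.astype(float), box)


def sidechain_offsets(n_beads: int) -> np.ndarray:
    """Deterministic side-chain pseudo-atom offsets from the backbone (A)."""
    return np.array([[2.0 + 1.2 * k, 0.8 * ((-1) ** k), 0.0] for k in range(n_beads)])


def cg_residue(one_letter: str, resid: int, bb_xyz: np.ndarray,
               chain: str = "A", outward: np.ndarray | None = None) -> Structure:
    """One CG-ready residue: a BB bead plus template side-chain beads.

    ``outward`` orients the side chain (unit xy-ish vector); defaults to +x.
    """
    three = ONE_TO_THREE[one_letter]
    n_sc = SIDECHAIN_BEADS[one_letter]
    if outward is None:
        outward = np.array([1.0, 0.0, 0.0])
    names = ["BB"] + [f"SC{k+1}" for k in range(n_sc)]
    coords = [np.asarray(bb_xyz, float)]
    for k, off in enumerate(sidechain_offsets(n_sc)):
        # rotate the template offset so its x-axis points "outward"
        ox, oy = outward[0], outward[1]
        norm = np.hypot(ox, oy) or 1.0
        ox, oy = ox / norm, oy / norm
        rot = np.array([[ox, -oy, 0], [oy, ox, 0], [0, 0, 1.0]])
        coords.append(np.asarray(bb_xyz, float) + rot @ off)
    n = len(names)
    return Structure(
        chains=np.array([chain] * n, object),
        resids=np.full(n, resid),
        resnames=np.array([three] * n, object),
        names=np.array(names, object),
        coords=np.vstack(coords),
    )
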
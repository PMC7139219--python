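"""Coarse-grained topologies for the lipidated cysteine, plus elastic networks.

The diacylglycerylcysteine topology is built exactly the way the chemistry
works: the glycerol and two acyl chains are taken from a POPG template (the
physiological acyl donor) and connected to the cysteine side-chain bead,
discarding the POPG headgroup and phosphate.  Triacylation then attaches a
palmitoyl fragment to the cysteine *backbone* bead (the amide-linked third
chain).  Templates are data files in the GROMACS itp dialect, annotated with
a ``fragment_role`` per bead; bead names and types are always read from
those files, never hard-coded.

A harmonic elastic network (ENM) over folded-core backbone beads preserves
secondary/tertiary structure in CG simulations; modeled tether residues are
excluded so the linker stays disordered and dynamic.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.spatial import cKDTree

from .tether import LipoproteinModel

__all__ = [
    "BeadTemplate",
    "CGTopology",
    "ElasticNetwork",
    "load_template",
    "read_itp",
    "write_itp",
    "graft_diacyl",
    "graft_triacyl",
    "build_elastic_network",
    "elastic_network_itp_lines",
]

FRAGMENT_ROLES = ("backbone", "sidechain", "headgroup", "phosphate", "glycerol", "tail")

#: Conventional Martini elastic-network force constant (kJ/mol/nm^2).
ENM_FORCE_CONSTANT = 500.0
ENM_CUTOFF = 0.7  # nm


@dataclass(frozen=True)
class BeadTemplate:
    """One CG particle: name, force-field type, charge, fragment role."""

    name: str
    type: str
    charge: float
    fragment_role: str

    def __post_init__(self):
        if self.fragment_role not in FRAGMENT_ROLES:
            raise ValueError(
                f"unknown fragment_role {self.fragment_role!r} for bead {self.name!r}"
            )


@dataclass(frozen=True)
class CGTopology:
    """Beads plus bonded terms for one molecule; indices are 0-based.

    ``bonds``: (i, j, length nm, force kJ/mol/nm^2); ``constraints``:
    (i, j, length nm); ``angles``: (i, j, k, angle deg, force kJ/mol).
    Immutable so that grafting is a pure function.
    """

    name: str
    beads: tuple = ()
    bonds: tuple = ()
    constraints: tuple = ()
    angles: tuple = ()
    header_comments: tuple = ()

    def __post_init__(self):
        names = [b.name for b in self.beads]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate bead names in {self.name!r}")
        n = len(self.beads)
        for i, j, *_ in list(self.bonds) + list(self.constraints):
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bonded term ({i},{j}) references missing bead")
        for i, j, k, *_ in self.angles:
            if not all(0 <= x < n for x in (i, j, k)):
                raise ValueError(f"angle ({i},{j},{k}) references missing bead")

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def total_charge(self) -> float:
        return float(sum(b.charge for b in self.beads))

    def bead_index(self, name: str) -> int:
        for i, b in enumerate(self.beads):
            if b.name == name:
                return i
        raise KeyError(f"no bead named {name!r} in {self.name!r}")

    def indices_by_role(self, *roles: str) -> list[int]:
        return [i for i, b in enumerate(self.beads) if b.fragment_role in roles]

    def adjacency(self) -> dict[int, set[int]]:
        adj: dict[int, set[int]] = {i: set() for i in range(self.n_beads)}
        for i, j, *_ in list(self.bonds) + list(self.constraints):
            adj[i].add(j)
            adj[j].add(i)
        return adj

    def is_connected(self) -> bool:
        if self.n_beads == 0:
            return True
        adj = self.adjacency()
        seen, stack = {0}, [0]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == self.n_beads


# ---------------------------------------------------------------------------
# itp dialect I/O


def _tokenize(path: str | Path):
    """Yield (section, tokens, trailing_comment) for data lines of an itp."""
    section = None
    header: list[str] = []
    in_header = True
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if in_header and line.startswith(";"):
            header.append(line.lstrip("; ").rstrip())
            continue
        if line.startswith("[") and line.endswith("]"):
            in_header = False
            section = line.strip("[] ").lower()
            continue
        if not line or line.startswith(";"):
            continue
        in_header = False
        comment = ""
        if ";" in line:
            line, comment = line.split(";", 1)
            comment = comment.strip()
            line = line.strip()
            if not line:
                continue
        yield section, line.split(), comment, tuple(header)


def read_itp(path: str | Path) -> CGTopology:
    """Parse a single-molecule itp file (whitespace-tolerant).

    Recognizes [moleculetype], [atoms], [bonds], [constraints], [angles].
    A trailing ``; <role>`` comment on an atom line sets its fragment_role;
    atoms without one default to ``tail`` only if their name suggests it,
    otherwise an error is raised (roles are required for grafting).
    """
    name = None
    beads: list[BeadTemplate] = []
    bonds, constraints, angles = [], [], []
    header: tuple = ()
    for section, tok, comment, hdr in _tokenize(path):
        header = hdr
        if section == "moleculetype":
            name = tok[0]
        elif section == "atoms":
            role = comment.split()[0] if comment else ""
            if role not in FRAGMENT_ROLES:
                raise ValueError(
                    f"{path}: atom {tok[4]!r} lacks a fragment_role annotation"
                )
            beads.append(BeadTemplate(name=tok[4], type=tok[1],
                                      charge=float(tok[6]), fragment_role=role))
        elif section == "bonds":
            bonds.append((int(tok[0]) - 1, int(tok[1]) - 1,
                          float(tok[2]), float(tok[3])))
        elif section == "constraints":
            constraints.append((int(tok[0]) - 1, int(tok[1]) - 1, float(tok[2])))
        elif section == "angles":
            angles.append((int(tok[0]) - 1, int(tok[1]) - 1, int(tok[2]) - 1,
                           float(tok[3]), float(tok[4])))
    if name is None:
        raise ValueError(f"{path}: no [moleculetype] section")
    return CGTopology(name=name, beads=tuple(beads), bonds=tuple(bonds),
                      constraints=tuple(constraints), angles=tuple(angles),
                      header_comments=header)


def write_itp(top: CGTopology, path: str | Path) -> None:
    """Write an itp file; fragment_role and header comments are preserved."""
    lines = [f"; {c}" for c in top.header_comments]
    lines += ["[ moleculetype ]", "; molname  nrexcl", f"{top.name}  1", ""]
    lines += ["[ atoms ]", "; nr  type  resnr  residue  atom  cgnr  charge ; fragment_role"]
    for i, b in enumerate(top.beads, start=1):
        lines.append(
            f"{i:>4}   {b.type:<6} 1     {top.name:<6} {b.name:<5} {i:>3}   "
            f"{b.charge:6.1f} ; {b.fragment_role}"
        )
    if top.bonds:
        lines += ["", "[ bonds ]", "; i  j  length(nm)  force(kJ/mol/nm^2)"]
        for i, j, length, k in top.bonds:
            lines.append(f"{i+1:>4} {j+1:>4}   {length:.4f}   {k:.1f}")
    if top.constraints:
        lines += ["", "[ constraints ]", "; i  j  length(nm)"]
        for i, j, length in top.constraints:
            lines.append(f"{i+1:>4} {j+1:>4}   {length:.4f}")
    if top.angles:
        lines += ["", "[ angles ]", "; i  j  k  angle(deg)  force(kJ/mol)"]
        for i, j, k, theta, fc in top.angles:
            lines.append(f"{i+1:>4} {j+1:>4} {k+1:>4}   {theta:.1f}   {fc:.1f}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_template(molecule: str, forcefield: str = "martini22") -> CGTopology:
    """Load a shipped template: molecule in {popg, pope, cys, palmitoyl}."""
    fname = f"{molecule.lower()}_{forcefield}.itp"
    ref = importlib.resources.files("lolkit.data") / fname
    if not ref.is_file():
        raise FileNotFoundError(f"no template {fname} (forcefield {forcefield!r}?)")
    with importlib.resources.as_file(ref) as p:
        return read_itp(p)


# ---------------------------------------------------------------------------
# Grafting


def _retain(top: CGTopology, keep: list[int]) -> tuple[list, list, list, list]:
    """Beads + bonded terms restricted to ``keep`` (old-index order)."""
    remap = {old: new for new, old in enumerate(keep)}
    beads = [top.beads[i] for i in keep]
    bonds = [(remap[i], remap[j], l, k) for i, j, l, k in top.bonds
             if i in remap and j in remap]
    cons = [(remap[i], remap[j], l) for i, j, l in top.constraints
            if i in remap and j in remap]
    angles = [(remap[i], remap[j], remap[k], t, f) for i, j, k, t, f in top.angles
              if i in remap and j in remap and k in remap]
    return beads, bonds, cons, angles


def _first_glycerol(top: CGTopology) -> int:
    gly = top.indices_by_role("glycerol")
    if not gly:
        raise ValueError(f"template {top.name!r} lacks an annotated glycerol fragment")
    return min(gly)


def graft_diacyl(cys: CGTopology, lipid_template: CGTopology,
                 name: str = "CYSD") -> CGTopology:
    """Diacylglycerylcysteine: cysteine + the glycerol/tail fragments of a
    lipid template, joined by a new side-chain -> glycerol bond.

    The template's headgroup and phosphate beads are discarded; every bonded
    term among retained template beads is preserved verbatim.  The new
    cross-fragment bond copies the template's analogous phosphate-glycerol
    bond parameters (the closest chemistry to the new thioether linkage).
    """
    bb = cys.indices_by_role("backbone")
    sc = cys.indices_by_role("sidechain")
    if not bb or not sc:
        raise ValueError("cysteine topology needs backbone and sidechain beads")
    keep = sorted(lipid_template.indices_by_role("glycerol", "tail"))
    gly0_old = _first_glycerol(lipid_template)

    frag_beads, frag_bonds, frag_cons, frag_angles = _retain(lipid_template, keep)
    off = cys.n_beads
    gly0 = keep.index(gly0_old) + off

    # parameters for the new bond: the template bond into the first glycerol
    link = next(
        ((l, k) for i, j, l, k in lipid_template.bonds
         if gly0_old in (i, j) and (lipid_template.beads[i if j == gly0_old else j]
                                    .fragment_role in ("phosphate", "headgroup"))),
        (0.47, 1250.0),
    )

    beads = list(cys.beads) + frag_beads
    bonds = list(cys.bonds) + [(i + off, j + off, l, k) for i, j, l, k in frag_bonds]
    bonds.append((sc[0], gly0, link[0], link[1]))
    cons = list(cys.constraints) + [(i + off, j + off, l) for i, j, l in frag_cons]
    angles = list(cys.angles) + [(i + off, j + off, k + off, t, f)
                                 for i, j, k, t, f in frag_angles]
    out = CGTopology(name=name, beads=tuple(beads), bonds=tuple(bonds),
                     constraints=tuple(cons), angles=tuple(angles),
                     header_comments=(f"diacylcysteine grafted from "
                                      f"{cys.name}+{lipid_template.name}",))
    assert out.is_connected()
    return out


def graft_triacyl(diacyl: CGTopology, palmitoyl_fragment: CGTopology,
                  name: str = "CYST") -> CGTopology:
    """Triacylcysteine: attach a linear palmitoyl tail to the cysteine
    backbone bead of an existing diacylcysteine topology."""
    bb = diacyl.indices_by_role("backbone")
    if not bb:
        raise ValueError("diacyl topology lacks a backbone bead")
    bb = bb[0]
    # backbone attachment must be free: no existing bond from BB to a tail bead
    tails = set(diacyl.indices_by_role("tail"))
    for i, j, *_ in diacyl.bonds:
        if (i == bb and j in tails) or (j == bb and i in tails):
            raise ValueError("backbone attachment occupied: topology is already triacylated")

    frag = palmitoyl_fragment
    adj = frag.adjacency()
    degrees = sorted(len(v) for v in adj.values())
    if frag.n_beads >= 2 and (degrees[-1] > 2 or degrees[:2] != [1, 1]):
        raise ValueError("palmitoyl fragment is not a linear chain")

    off = diacyl.n_beads
    first = min(frag.indices_by_role("tail"))
    link_l, link_k = (frag.bonds[0][2], frag.bonds[0][3]) if frag.bonds else (0.47, 1250.0)

    beads = list(diacyl.beads) + list(frag.beads)
    # palmitoyl bead names may collide with the oleoyl/palmitoyl chains already
    # present; suffix them if needed
    existing = {b.name for b in diacyl.beads}
    for n_idx in range(off, len(beads)):
        if beads[n_idx].name in existing:
            beads[n_idx] = replace(beads[n_idx], name=beads[n_idx].name + "T")
    bonds = list(diacyl.bonds) + [(i + off, j + off, l, k) for i, j, l, k in frag.bonds]
    bonds.append((bb, first + off, link_l, link_k))
    cons = list(diacyl.constraints) + [(i + off, j + off, l) for i, j, l in frag.constraints]
    angles = list(diacyl.angles) + [(i + off, j + off, k + off, t, f)
                                    for i, j, k, t, f in frag.angles]
    out = CGTopology(name=name, beads=tuple(beads), bonds=tuple(bonds),
                     constraints=tuple(cons), angles=tuple(angles),
                     header_comments=(f"triacylcysteine grafted from "
                                      f"{diacyl.name}+{frag.name}",))
    assert out.is_connected()
    return out


# ---------------------------------------------------------------------------
# Elastic network


@dataclass(frozen=True)
class ElasticNetwork:
    """Harmonic restraint pairs between backbone beads of the folded core.

    ``pairs``: (resid_i, resid_j, distance nm) with i < j, no duplicates,
    every distance <= cutoff.
    """

    pairs: tuple
    cutoff: float = ENM_CUTOFF
    force_constant: float = ENM_FORCE_CONSTANT

    def __post_init__(self):
        seen = set()
        for i, j, d in self.pairs:
            if not i < j:
                raise ValueError(f"pair ({i},{j}) not ordered i < j")
            if (i, j) in seen:
                raise ValueError(f"duplicate pair ({i},{j})")
            seen.add((i, j))
            if d > self.cutoff + 1e-12:
                raise ValueError(f"pair ({i},{j}) distance {d} exceeds cutoff {self.cutoff}")

    def __len__(self) -> int:
        return len(self.pairs)


def build_elastic_network(
    model: LipoproteinModel,
    cutoff: float = ENM_CUTOFF,
    force_constant: float = ENM_FORCE_CONSTANT,
) -> ElasticNetwork:
    """All (and only) core backbone-bead pairs within ``cutoff`` (nm).

    Tether residues modeled as disordered are excluded, so the network
    starts at the first core residue and the linker remains unrestrained.
    An empty network is valid (fully extended chain).
    """
    resids, bb = model.structure.backbone()
    keep = ~np.isin(resids, list(model.tether_resids))
    resids, bb = resids[keep], bb[keep] / 10.0  # A -> nm
    pairs = []
    if len(resids) >= 2:
        tree = cKDTree(bb)
        for a, b in sorted(tree.query_pairs(cutoff)):
            d = float(np.linalg.norm(bb[a] - bb[b]))
            ri, rj = int(resids[a]), int(resids[b])
            if ri > rj:
                ri, rj = rj, ri
            pairs.append((ri, rj, d))
    pairs.sort()
    return ElasticNetwork(pairs=tuple(pairs), cutoff=cutoff, force_constant=force_constant)


def elastic_network_itp_lines(net: ElasticNetwork) -> str:
    """Render an ENM as a [bonds] block (GROMACS bond type 6, no exclusions)."""
    lines = ["; elastic network bonds (resid resid length force)", "[ bonds ]"]
    for i, j, d in net.pairs:
        lines.append(f"{i:>5} {j:>5}  6  {d:.4f}  {net.force_constant:.1f}")
    return "\n".join(lines) + "\n"
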
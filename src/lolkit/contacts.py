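"""Residue-lipid contact fingerprints, reproducibility, and deformation maps.

A contact is recorded, per frame and residue, when any particle of that
residue lies within a 6 A cutoff of any lipid bead of a given class.  The
classes follow the headgroup chemistry of a PE/PG membrane: the POPG
glycerol headgroup (GL0), the POPE ethanolamine (NH3), phosphates (PO4),
the ester glycerols (GL1:2), and the acyl tails (Tail).  Distances are
minimum-image distances under orthorhombic periodic boundary conditions.

Contact profiles from replicate simulations are compared by the Pearson
correlation of their per-residue total contact vectors: r = 1 means the
same membrane-binding footprint, r = -1 an anti-correlated one.  Replicates
are grouped into binding modes by single-linkage clustering at a
correlation threshold, and membrane shape around a protein is mapped as the
per-bin mean |z| of phosphates relative to the instantaneous membrane
center, per leaflet.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "DEFAULT_BEAD_CLASSES",
    "ContactProfile",
    "ReproducibilityMatrix",
    "BindingModeAssignment",
    "DeformationSurface",
    "contact_profile",
    "replicate_correlation",
    "classify_binding_modes",
    "deformation_surface",
    "residue_class_enrichment",
    "load_trajectory",
]

CONTACT_CUTOFF = 6.0  # Angstrom

#: Lipid bead classes: class label -> regex over bead (atom) names.
DEFAULT_BEAD_CLASSES = {
    "GL0": r"^GL0$",
    "NH3": r"^NH3$",
    "PO4": r"^PO4$",
    "GL1:2": r"^GL[12]$",
    "Tail": r"^[CD]\d[AB]$",
}


def load_trajectory(topology: str | Path, trajectory: str | Path | None = None):
    """Open a GRO/PDB frame series (multi-model PDB, or GRO + XTC where
    available) as an MDAnalysis Universe.

    A multi-model PDB carries one CRYST1 header record; the frame reader
    does not propagate it to every MODEL, so the box is re-applied here as
    a trajectory transformation.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if trajectory is None:
            u = mda.Universe(str(topology))
        else:
            u = mda.Universe(str(topology), str(trajectory))
    if u.dimensions is None and str(topology).lower().endswith(".pdb"):
        box = _cryst1_box(topology)
        if box is not None:
            from MDAnalysis.transformations import set_dimensions

            u.trajectory.add_transformations(set_dimensions(box))
    return u


def _cryst1_box(path: str | Path):
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                vals = [float(line[6:15]), float(line[15:24]), float(line[24:33]),
                        float(line[33:40]), float(line[40:47]), float(line[47:54])]
                if not np.allclose(vals[:3], 1.0):   # unitary box = fictitious
                    return np.array(vals)
    return None


@dataclass
class ContactProfile:
    """Per-residue contact counts split by lipid bead class."""

    resids: np.ndarray          # (n_res,) int
    resnames: np.ndarray        # (n_res,) str
    classes: tuple              # class labels, column order of ``counts``
    counts: np.ndarray          # (n_res, n_class) int, frames-in-contact
    n_frames: int
    cutoff: float = CONTACT_CUTOFF
    label: str = ""

    def __post_init__(self):
        self.resids = np.asarray(self.resids, int)
        self.resnames = np.asarray(self.resnames, dtype=object)
        self.counts = np.asarray(self.counts, int)
        if self.counts.shape != (len(self.resids), len(self.classes)):
            raise ValueError("counts shape inconsistent with resids/classes")
        if (self.counts < 0).any():
            raise ValueError("negative contact counts")

    def totals(self) -> np.ndarray:
        """Per-residue contact counts summed over bead classes."""
        return self.counts.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.classes))
        df.insert(0, "resname", self.resnames)
        df.insert(0, "resid", self.resids)
        return df

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.attrs = {}
        with open(path, "w") as fh:
            fh.write(f"# n_frames={self.n_frames} cutoff={self.cutoff} label={self.label}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ContactProfile":
        with open(path) as fh:
            meta = fh.readline().lstrip("# ").split()
            kv = dict(item.split("=", 1) for item in meta)
            df = pd.read_csv(fh, sep="\t")
        classes = tuple(c for c in df.columns if c not in ("resid", "resname"))
        return cls(resids=df["resid"].to_numpy(), resnames=df["resname"].to_numpy(),
                   classes=classes, counts=df[list(classes)].to_numpy(),
                   n_frames=int(kv["n_frames"]), cutoff=float(kv["cutoff"]),
                   label=kv.get("label", ""))


def contact_profile(
    universe,
    protein_sel: str = "protein",
    lipid_sel: str = "not protein",
    bead_classes: dict[str, str] | None = None,
    cutoff: float = CONTACT_CUTOFF,
) -> ContactProfile:
    """Count, per residue and lipid bead class, the frames with any
    protein-particle-to-class-bead distance within ``cutoff`` (A), under
    periodic minimum-image convention."""
    from MDAnalysis.lib.distances import capped_distance

    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    bead_classes = bead_classes or DEFAULT_BEAD_CLASSES

    prot = universe.select_atoms(protein_sel)
    lip = universe.select_atoms(lipid_sel)
    if len(prot) == 0:
        raise ValueError(f"empty protein selection {protein_sel!r}")
    if len(lip) == 0:
        raise ValueError(f"empty lipid selection {lipid_sel!r}")

    residues = prot.residues
    resids = residues.resids.copy()
    res_index = {rid: i for i, rid in enumerate(resids)}
    atom_res = np.array([res_index[r] for r in prot.resids])

    class_atoms = {}
    for label, pattern in bead_classes.items():
        rx = re.compile(pattern)
        mask = np.array([bool(rx.match(n)) for n in lip.names])
        class_atoms[label] = lip[mask]

    classes = tuple(bead_classes)
    counts = np.zeros((len(resids), len(classes)), int)
    n_frames = 0
    for _ in universe.trajectory:
        box = universe.dimensions
        if box is not None and np.any(box[:3] > 0) and np.any(box[:3] < cutoff):
            raise ValueError(f"box {box[:3]} smaller than the {cutoff} A cutoff")
        n_frames += 1
        ppos = prot.positions
        for ci, label in enumerate(classes):
            beads = class_atoms[label]
            if len(beads) == 0:
                continue
            pairs = capped_distance(ppos, beads.positions, max_cutoff=cutoff,
                                    box=box, return_distances=False)
            if len(pairs):
                hit = np.unique(atom_res[pairs[:, 0]])
                counts[hit, ci] += 1

    return ContactProfile(resids=resids, resnames=residues.resnames.astype(object),
                          classes=classes, counts=counts, n_frames=n_frames,
                          cutoff=cutoff)


# ---------------------------------------------------------------------------
# Reproducibility


@dataclass
class ReproducibilityMatrix:
    """Pairwise Pearson correlations between replicate contact profiles.

    Symmetric with unit diagonal; an undefined correlation (zero-variance
    profile) is stored as NaN, not 0.
    """

    r: np.ndarray
    labels: tuple

    def __post_init__(self):
        self.r = np.asarray(self.r, float)
        n = len(self.labels)
        if self.r.shape != (n, n):
            raise ValueError("matrix shape inconsistent with labels")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.r, index=list(self.labels),
                     columns=list(self.labels)).to_csv(path, sep="\t")


def replicate_correlation(
    profiles: list[ContactProfile],
    per_class: bool = False,
) -> ReproducibilityMatrix:
    """Pearson r between the per-residue contact vectors of each replicate.

    By default classes are summed first (total per-residue footprint, the
    binding-mode fingerprint); ``per_class=True`` correlates the flattened
    residue-by-class matrix instead.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    ref = profiles[0].resids
    for p in profiles[1:]:
        if not np.array_equal(p.resids, ref):
            raise ValueError("profiles cover different residue ranges")
    vecs = [p.counts.ravel().astype(float) if per_class
            else p.totals().astype(float) for p in profiles]
    n = len(vecs)
    r = np.full((n, n), np.nan)
    for i in range(n):
        if np.std(vecs[i]) > 0:
            r[i, i] = 1.0
        for j in range(i + 1, n):
            if np.std(vecs[i]) == 0 or np.std(vecs[j]) == 0:
                continue
            r[i, j] = r[j, i] = float(np.corrcoef(vecs[i], vecs[j])[0, 1])
    labels = tuple(p.label or f"rep{i+1}" for i, p in enumerate(profiles))
    return ReproducibilityMatrix(r=r, labels=labels)


@dataclass
class BindingModeAssignment:
    """Replicate -> binding-mode id; mode 1 is the most populated (primary)."""

    labels: tuple
    mode_of: tuple            # mode id per replicate, 1-based
    modes: tuple              # tuple of member-index tuples, ordered by size

    @property
    def primary(self) -> tuple:
        return self.modes[0]


def classify_binding_modes(
    matrix: ReproducibilityMatrix,
    threshold: float = 0.5,
) -> BindingModeAssignment:
    """Single-linkage grouping: replicates joined whenever pairwise r >=
    threshold; modes ordered by descending size, ties to the lowest member
    index.  NaN correlations never link."""
    r = matrix.r
    n = r.shape[0]
    adj = np.zeros((n, n), bool)
    with np.errstate(invalid="ignore"):
        adj[np.nan_to_num(r, nan=-np.inf) >= threshold] = True
    np.fill_diagonal(adj, True)
    _, comp = connected_components(csr_matrix(adj), directed=False)
    groups: dict[int, list[int]] = {}
    for i, c in enumerate(comp):
        groups.setdefault(c, []).append(i)
    ordered = sorted(groups.values(), key=lambda g: (-len(g), min(g)))
    mode_of = [0] * n
    for mode_id, members in enumerate(ordered, start=1):
        for m in members:
            mode_of[m] = mode_id
    return BindingModeAssignment(labels=matrix.labels, mode_of=tuple(mode_of),
                                 modes=tuple(tuple(g) for g in ordered))


# ---------------------------------------------------------------------------
# Membrane deformation


@dataclass
class DeformationSurface:
    """xy-binned mean |z| of phosphates relative to the membrane center.

    ``upper``/``lower`` are per-leaflet grids (A); empty bins are NaN (and
    flagged in ``empty``), never zero-filled.  ``thickness`` = upper + lower
    (phosphate-to-phosphate).  ``ambiguous`` flags bins whose samples sit
    persistently within 2 A of the center (leaflet assignment unreliable).
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    upper: np.ndarray
    lower: np.ndarray
    bin_size: float
    n_frames: int
    empty: np.ndarray = field(default=None)
    ambiguous: np.ndarray = field(default=None)
    bulk_thickness: float = np.nan
    max_center_to_phosphate: float = np.nan
    max_thickness: float = np.nan

    @property
    def thickness(self) -> np.ndarray:
        return self.upper + self.lower

    def to_tsv(self, path: str | Path) -> None:
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        rows = []
        for i, x in enumerate(xc):
            for j, y in enumerate(yc):
                rows.append((x, y, self.upper[i, j], self.lower[i, j],
                             bool(self.empty[i, j]), bool(self.ambiguous[i, j])))
        pd.DataFrame(rows, columns=["x", "y", "upper_A", "lower_A",
                                    "empty", "ambiguous"]).to_csv(
            path, sep="\t", index=False)

    def plot(self, path: str | Path) -> None:
        """Render the thickness surface as a heatmap image."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        im = ax.pcolormesh(self.x_edges, self.y_edges, self.thickness.T,
                           cmap="RdBu_r", shading="flat")
        fig.colorbar(im, ax=ax, label="phosphate-phosphate thickness (A)")
        ax.set_xlabel("x (A)")
        ax.set_ylabel("y (A)")
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def deformation_surface(
    universe,
    phosphate_sel: str = "name PO4",
    bin_size: float = 2.0,
    protein_sel: str | None = None,
    bulk_radius: float | None = None,
) -> DeformationSurface:
    """Map membrane shape as the mean |z| of phosphates per xy bin, split by
    leaflet around the instantaneous all-phosphate center of mass.

    ``bulk_thickness`` is the median bin thickness beyond ``bulk_radius``
    (A) from the protein xy centroid (all bins when no protein is given).
    """
    phos = universe.select_atoms(phosphate_sel)
    if len(phos) == 0:
        raise ValueError(f"empty phosphate selection {phosphate_sel!r}")
    prot = universe.select_atoms(protein_sel) if protein_sel else None

    box = universe.dimensions
    if box is None or not np.all(box[:2] > 0):
        raise ValueError("trajectory carries no box; the grid must cover the box")
    lx, ly = float(box[0]), float(box[1])
    nx = max(1, int(round(lx / bin_size)))
    ny = max(1, int(round(ly / bin_size)))
    x_edges = np.linspace(0.0, lx, nx + 1)
    y_edges = np.linspace(0.0, ly, ny + 1)

    sums = {"up": np.zeros((nx, ny)), "lo": np.zeros((nx, ny))}
    cnts = {"up": np.zeros((nx, ny), int), "lo": np.zeros((nx, ny), int)}
    near_center = np.zeros((nx, ny), int)
    total_samples = np.zeros((nx, ny), int)
    prot_xy = []

    n_frames = 0
    for _ in universe.trajectory:
        n_frames += 1
        pos = phos.positions
        center_z = pos[:, 2].mean()
        dz = pos[:, 2] - center_z
        xi = np.clip(np.digitize(pos[:, 0] % lx, x_edges) - 1, 0, nx - 1)
        yi = np.clip(np.digitize(pos[:, 1] % ly, y_edges) - 1, 0, ny - 1)
        upper = dz >= 0
        for key, mask in (("up", upper), ("lo", ~upper)):
            np.add.at(sums[key], (xi[mask], yi[mask]), np.abs(dz[mask]))
            np.add.at(cnts[key], (xi[mask], yi[mask]), 1)
        np.add.at(near_center, (xi, yi), (np.abs(dz) < 2.0).astype(int))
        np.add.at(total_samples, (xi, yi), 1)
        if prot is not None and len(prot):
            prot_xy.append(prot.positions[:, :2].mean(axis=0))

    with np.errstate(invalid="ignore"):
        upper_g = np.where(cnts["up"] > 0, sums["up"] / np.maximum(cnts["up"], 1), np.nan)
        lower_g = np.where(cnts["lo"] > 0, sums["lo"] / np.maximum(cnts["lo"], 1), np.nan)
    empty = (cnts["up"] == 0) | (cnts["lo"] == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ambiguous = (total_samples > 0) & (near_center / np.maximum(total_samples, 1) > 0.5)

    thickness = upper_g + lower_g
    if bulk_radius is not None:
        # bins beyond bulk_radius from the protein xy centroid (box center
        # when the deformation source is not an explicit protein selection)
        cx, cy = np.mean(prot_xy, axis=0) if prot_xy else (lx / 2, ly / 2)
        xc = 0.5 * (x_edges[:-1] + x_edges[1:])
        yc = 0.5 * (y_edges[:-1] + y_edges[1:])
        xx, yy = np.meshgrid(xc, yc, indexing="ij")
        far = np.hypot(xx - cx, yy - cy) > bulk_radius
        bulk_vals = thickness[far & ~empty]
    else:
        bulk_vals = thickness[~empty]
    bulk = float(np.median(bulk_vals)) if bulk_vals.size else np.nan

    return DeformationSurface(
        x_edges=x_edges, y_edges=y_edges, upper=upper_g, lower=lower_g,
        bin_size=bin_size, n_frames=n_frames, empty=empty, ambiguous=ambiguous,
        bulk_thickness=bulk,
        max_center_to_phosphate=float(np.nanmax([np.nanmax(upper_g), np.nanmax(lower_g)])),
        max_thickness=float(np.nanmax(thickness)) if np.isfinite(thickness).any() else np.nan,
    )


# ---------------------------------------------------------------------------
# Residue-type enrichment


def residue_class_enrichment(profiles: list[ContactProfile]) -> pd.DataFrame:
    """Mean contact counts per amino-acid type and bead class, aggregated
    over all residues of that type across all supplied proteins and
    normalized per residue occurrence.  Order-invariant."""
    if not profiles:
        raise ValueError("need at least one profile")
    classes = profiles[0].classes
    for p in profiles[1:]:
        if p.classes != classes:
            raise ValueError("profiles have different bead classes")
    frames = []
    for p in profiles:
        df = pd.DataFrame(p.counts.astype(float), columns=list(classes))
        df["resname"] = [str(r) for r in p.resnames]
        frames.append(df)
    allres = pd.concat(frames, ignore_index=True)
    return allres.groupby("resname").mean().sort_index()
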
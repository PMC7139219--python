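"""Synthetic inputs with known ground truth.

Every analysis in this package is testable without running simulations:
these generators emit the same formats the analysis modules read (PDB frame
series, window sample files, manifests) alongside JSON ground-truth
sidecars, and are bit-deterministic under their seed.

The generators encode only the statistical and geometric structure each
analysis assumes — a planted lipobox and missing N-terminal residues for
the sequence/tether path, bead membranes whose brute-force contact counts
are known by construction, umbrella samples drawn exactly (rejection
sampling) from the biased Boltzmann density of an analytic potential, and
phosphate sheets scattered on a prescribed height field.  They do not
imitate force-field physics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .sequences import ProteinSequence
from .structure import ONE_TO_THREE, Structure
from .tether import HELIX_RADIUS, HELIX_RISE, HELIX_TWIST
from .wham import KB, UmbrellaWindow

__all__ = [
    "make_toy_structure",
    "make_membrane_trajectory",
    "make_umbrella_samples",
    "make_deformed_membrane",
    "harmonic_potential",
    "double_well_potential",
    "write_frames_pdb",
]

_AA_POOL = "ADEFGHKMNPQRSTWY"   # no C (keeps the planted lipobox unique), no LVI


# ---------------------------------------------------------------------------
# Toy structure


def make_toy_structure(
    n_residues: int,
    missing_n_terminal: int = 0,
    seed: int = 0,
    cys_position: int | None = None,
) -> tuple[Structure, ProteinSequence]:
    """A compact helix-bundle-like Calpha/backbone-bead structure plus its
    full sequence.

    The first ``missing_n_terminal`` residues are present in the sequence
    but absent from the coordinates (an unresolved N terminus).  A single
    lipobox is planted: by default its cysteine sits at residue 5 when at
    least five residues are missing (so the tether builder must model a
    linker), otherwise at the start of the resolved region (the linker
    degenerates to zero).  The random sequence avoids L/V/I/C elsewhere, so
    exactly one window matches the motif.
    """
    if n_residues < 2:
        raise ValueError("need at least two residues")
    if not 0 <= missing_n_terminal < n_residues - 1:
        raise ValueError("missing_n_terminal must leave at least two resolved residues")
    rng = np.random.default_rng(seed)

    if cys_position is None:
        cys_position = 5 if missing_n_terminal >= 5 else missing_n_terminal + 4
    if not 4 <= cys_position <= n_residues:
        raise ValueError(f"cys_position {cys_position} outside 4..{n_residues}")

    letters = list(rng.choice(list(_AA_POOL), size=n_residues))
    letters[cys_position - 4 : cys_position] = ["L", "A", "G", "C"]
    sequence = ProteinSequence(id=f"toy{n_residues}m{missing_n_terminal}s{seed}",
                               residues="".join(letters))

    # resolved residues folded as a compact up-down helix bundle
    first = missing_n_terminal + 1
    resids, coords = [], []
    seg_len = 10
    for k, resid in enumerate(range(first, n_residues + 1)):
        seg, pos = divmod(k, seg_len)
        theta = np.deg2rad(HELIX_TWIST * pos)
        z = HELIX_RISE * (pos if seg % 2 == 0 else seg_len - 1 - pos)
        x = seg * 9.0 + HELIX_RADIUS * np.cos(theta)
        y = HELIX_RADIUS * np.sin(theta)
        resids.append(resid)
        coords.append([x, y, z])
    n = len(resids)
    structure = Structure(
        chains=np.array(["A"] * n, object),
        resids=np.array(resids),
        resnames=np.array([ONE_TO_THREE[sequence[r]] for r in resids], object),
        names=np.array(["BB"] * n, object),
        coords=np.array(coords, float),
    )
    return structure, sequence


# ---------------------------------------------------------------------------
# Membrane trajectory with exact contact ground truth


_CLASS_BEAD = {"GL0": "GL0", "NH3": "NH3", "PO4": "PO4", "GL1:2": "GL1", "Tail": "C1A"}


@dataclass
class MembraneFixture:
    """In-memory trajectory plus its contact ground truth."""

    universe: object                  # MDAnalysis Universe with MemoryReader
    ground_truth: dict                # {resid: {class: frames-in-contact}}
    n_frames: int
    box: tuple


def make_membrane_trajectory(
    ground_truth: dict[int, dict[str, int]],
    n_frames: int = 10,
    n_residues: int | None = None,
    seed: int = 0,
) -> MembraneFixture:
    """A planar two-leaflet bead membrane plus a protein whose per-residue,
    per-class 6 A contact counts equal ``ground_truth`` exactly.

    ``ground_truth`` maps 1-based residue ids to ``{class: count}`` with
    counts <= ``n_frames``.  Each requested contact is realized by a
    dedicated lipid bead of that class parked far away except in exactly
    ``count`` frames, where it sits 4-5.5 A from the residue's bead; the
    background membrane lattice never approaches the protein.  Protein
    residues are spaced so no bead serves two residues.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    rng = np.random.default_rng(seed)
    classes = tuple(_CLASS_BEAD)
    for rid, want in ground_truth.items():
        for cls, cnt in want.items():
            if cls not in classes:
                raise ValueError(f"unknown bead class {cls!r}")
            if not 0 <= cnt <= n_frames:
                raise ValueError(
                    f"residue {rid} {cls}: {cnt} contacts not realizable in "
                    f"{n_frames} frames"
                )
    n_res = n_residues or (max(ground_truth) if ground_truth else 4)
    if ground_truth and max(ground_truth) > n_res:
        raise ValueError("ground truth references residues beyond n_residues")

    # 20 A residue spacing: a contact bead (<= 5.5 A out) can never reach the
    # 6 A shell of a neighbouring residue
    box_x = max(20.0 * n_res + 20.0, 60.0)
    box = (box_x, 60.0, 80.0)

    names: list[str] = []
    resnames: list[str] = []
    resindex: list[int] = []
    segid_of_res: list[str] = []
    base: list[list[float]] = []

    aa_cycle = ["ALA", "PHE", "LYS", "ASP", "SER"]
    prot_pos = {}
    for i in range(n_res):
        names.append("BB")
        resnames.append(aa_cycle[i % len(aa_cycle)])
        resindex.append(len(segid_of_res))
        segid_of_res.append("PROT")
        p = [10.0 + 20.0 * i, 30.0, 30.0]
        prot_pos[i + 1] = np.array(p)
        base.append(p)

    # background lattice on both leaflets (z = +/-11 about z=0; protein at 30)
    lattice_names = ["GL0", "NH3", "PO4", "GL1", "C1A"]
    k = 0
    for z in (11.0, -11.0):
        for x in np.arange(5.0, box[0] - 4.0, 12.0):
            for y in np.arange(5.0, box[1] - 4.0, 12.0):
                names.append(lattice_names[k % len(lattice_names)])
                k += 1
                resnames.append("LIP")
                resindex.append(len(segid_of_res))
                segid_of_res.append("MEMB")
                base.append([float(x), float(y), z])

    # dedicated contact beads, parked at z=-25 (>= 25 A from the protein even
    # across the boundary of the 80 A box)
    contact_beads = []   # (atom_index, resid, class, frames_in_contact)
    park_x = 5.0
    for rid in sorted(ground_truth):
        for cls in classes:
            cnt = ground_truth[rid].get(cls, 0)
            if cnt == 0:
                continue
            names.append(_CLASS_BEAD[cls])
            resnames.append("LIP")
            resindex.append(len(segid_of_res))
            segid_of_res.append("MEMB")
            idx = len(base)
            base.append([park_x, 30.0, -25.0])
            park_x += 8.0
            frames = rng.choice(n_frames, size=cnt, replace=False)
            contact_beads.append((idx, rid, cls, set(int(f) for f in frames)))

    base_arr = np.array(base, float)
    frames_xyz = np.repeat(base_arr[None, :, :], n_frames, axis=0)
    for idx, rid, cls, in_contact in contact_beads:
        for f in in_contact:
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            dist = rng.uniform(4.0, 5.5)
            frames_xyz[f, idx] = prot_pos[rid] + direction * dist

    n_atoms = len(names)
    segids, segindex = np.unique(segid_of_res, return_inverse=True)
    u = mda.Universe.empty(n_atoms, n_residues=len(segid_of_res),
                           n_segments=len(segids),
                           atom_resindex=np.array(resindex),
                           residue_segindex=segindex, trajectory=True)
    u.add_TopologyAttr("names", np.array(names))
    u.add_TopologyAttr("resnames", np.array(resnames))
    u.add_TopologyAttr("resids", np.arange(1, len(segid_of_res) + 1))
    u.add_TopologyAttr("segids", segids)
    dims = np.array([[*box, 90.0, 90.0, 90.0]] * n_frames)
    u.load_new(frames_xyz, format=MemoryReader, dimensions=dims)

    truth = {int(rid): {cls: int(cnt) for cls, cnt in want.items() if cnt}
             for rid, want in ground_truth.items()}
    return MembraneFixture(universe=u, ground_truth=truth,
                           n_frames=n_frames, box=box)


def write_frames_pdb(universe, path: str | Path) -> None:
    """Dump a Universe trajectory as a multi-model PDB frame series."""
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), multiframe=True) as w:
            for _ in universe.trajectory:
                w.write(universe.atoms)


# ---------------------------------------------------------------------------
# Umbrella samples from analytic potentials


def harmonic_potential(kappa: float) -> Callable[[np.ndarray], np.ndarray]:
    """U(xi) = 1/2 kappa xi^2 (kJ/mol, xi in nm)."""

    def U(x):
        return 0.5 * kappa * np.asarray(x) ** 2

    return U


def double_well_potential(a: float, b: float) -> Callable[[np.ndarray], np.ndarray]:
    """U(xi) = a (xi^2 - b^2)^2: minima at +/-b, barrier a b^4 at xi = 0."""

    def U(x):
        x = np.asarray(x)
        return a * (x**2 - b**2) ** 2

    return U


def make_umbrella_samples(
    potential: Callable[[np.ndarray], np.ndarray],
    centers: Sequence[float],
    k: float = 1000.0,
    n_per_window: int = 10_000,
    temperature: float = 310.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
    min_efficiency: float = 1e-4,
) -> tuple[list[UmbrellaWindow], Callable[[np.ndarray], np.ndarray]]:
    """Exact independent samples from each window's biased Boltzmann density.

    For window center c the target density is proportional to
    ``exp(-phi(xi)/kT)`` with ``phi = U + k/2 (xi-c)^2``.  When the bias is
    strong enough that phi is convex over the window support (true for every
    potential here at the default k), the target is log-concave, and a
    Gaussian proposal centered on the mode x* with the *minimum* curvature
    of phi as its precision dominates the target exactly: acceptance
    probability ``exp(-(phi(x) - phi(x*) - h_min (x-x*)^2 / 2)/kT) <= 1``.
    This is exact rejection sampling, free of autocorrelation; for a purely
    harmonic U the acceptance is identically 1 (direct Gaussian sampling).
    Returns the windows and the analytic unbiased profile
    ``G(xi) = U(xi) - min U`` for comparison.  Raises when phi is not
    convex on the support (envelope invalid — increase k) or when the
    acceptance rate of any window falls below ``min_efficiency``.
    """
    if k <= 0:
        raise ValueError("bias force constant must be positive for rejection sampling")
    kT = KB * temperature
    sigma_bias = np.sqrt(kT / k)
    rng = np.random.default_rng(seed)
    windows = []
    for c in centers:
        phi = lambda x: potential(x) + 0.5 * k * (np.asarray(x) - c) ** 2
        lo, hi = c - 10 * sigma_bias, c + 10 * sigma_bias
        grid = np.linspace(lo, hi, 4001)
        pg = phi(grid)
        x_star = float(grid[np.argmin(pg)])
        curv = np.gradient(np.gradient(pg, grid), grid)
        h_min = float(np.min(curv[2:-2])) * 0.999   # safety margin on the bound
        if h_min <= 0:
            raise RuntimeError(
                f"biased potential not convex near window {c}; tighten the "
                "envelope with a larger bias force constant"
            )
        sigma_p = np.sqrt(kT / h_min)
        phi_star = float(phi(x_star))
        samples = np.empty(0)
        proposed = 0
        while samples.size < n_per_window:
            m = max(2 * (n_per_window - samples.size), 1000)
            x = rng.normal(x_star, sigma_p, size=m)
            x = x[(x >= lo) & (x <= hi)]
            log_acc = -(phi(x) - phi_star - 0.5 * h_min * (x - x_star) ** 2) / kT
            acc = np.log(rng.random(x.size)) < log_acc
            samples = np.concatenate([samples, x[acc]])
            proposed += m
            if proposed > 50 * n_per_window and samples.size / proposed < min_efficiency:
                raise RuntimeError(
                    f"rejection efficiency {samples.size / proposed:.2e} below "
                    f"{min_efficiency} for window at {c}; tighten the envelope "
                    "(larger bias k) or reduce the barrier"
                )
        windows.append(UmbrellaWindow(center=float(c), k=k,
                                      samples=samples[:n_per_window],
                                      temperature=temperature))

    def analytic_G(x):
        u = potential(np.asarray(x))
        return u - np.min(potential(np.linspace(min(centers), max(centers), 8001)))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        rows = []
        for i, w in enumerate(windows):
            fname = f"window_{i:03d}.xvg"
            data = np.column_stack([np.arange(w.samples.size, dtype=float), w.samples])
            np.savetxt(out / fname, data, fmt="%.8f",
                       header="time xi_nm", comments="# ")
            rows.append((fname, w.center, w.k))
        with open(out / "windows.tsv", "w") as fh:
            fh.write("file\tcenter\tforce_constant\n")
            for fname, c, kk in rows:
                fh.write(f"{fname}\t{c}\t{kk}\n")
        gt_grid = np.linspace(min(centers), max(centers), 201)
        (out / "ground_truth.json").write_text(json.dumps({
            "temperature": temperature, "k": k, "seed": seed,
            "xi": gt_grid.tolist(), "G": analytic_G(gt_grid).tolist(),
        }, indent=1))
    return windows, analytic_G


# ---------------------------------------------------------------------------
# Deformed membrane


def make_deformed_membrane(
    height_field: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None,
    box_xy: float = 120.0,
    n_beads_per_leaflet: int = 900,
    n_frames: int = 5,
    noise: float = 0.3,
    seed: int = 0,
) -> "MembraneFixture":
    """Phosphate beads scattered on +/-field(x, y) sheets with noise.

    ``height_field(x, y)`` gives the center-to-phosphate height per leaflet
    (A); the default is a flat 11 A sheet (22 A phosphate-to-phosphate
    bulk).  The deformation is mirrored into both leaflets, so the
    instantaneous membrane center stays at z = 0 and
    :func:`lolkit.contacts.deformation_surface` must recover the field to
    within half a bin plus the noise scale.
    """
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    if height_field is None:
        height_field = lambda x, y: np.full_like(np.asarray(x, float), 11.0)
    rng = np.random.default_rng(seed)
    box = (box_xy, box_xy, 120.0)

    n = n_beads_per_leaflet
    frames_xyz = np.empty((n_frames, 2 * n, 3))
    for f in range(n_frames):
        xy = rng.uniform(0.0, box_xy, size=(n, 2))
        h = np.asarray(height_field(xy[:, 0], xy[:, 1]), float)
        jitter = rng.normal(scale=noise, size=n)
        # mirrored jitter keeps the per-frame mean z exactly on the center
        upper = np.column_stack([xy, 60.0 + h + jitter])
        lower = np.column_stack([xy, 60.0 - h - jitter])
        frames_xyz[f, :n] = upper
        frames_xyz[f, n:] = lower

    u = mda.Universe.empty(2 * n, n_residues=2 * n, n_segments=1,
                           atom_resindex=np.arange(2 * n),
                           residue_segindex=np.zeros(2 * n, int), trajectory=True)
    u.add_TopologyAttr("names", np.array(["PO4"] * (2 * n)))
    u.add_TopologyAttr("resnames", np.array(["LIP"] * (2 * n)))
    u.add_TopologyAttr("resids", np.arange(1, 2 * n + 1))
    u.add_TopologyAttr("segids", np.array(["MEMB"]))
    dims = np.array([[*box, 90.0, 90.0, 90.0]] * n_frames)
    u.load_new(frames_xyz, format=MemoryReader, dimensions=dims)

    xg, yg = np.meshgrid(np.linspace(0, box_xy, 61), np.linspace(0, box_xy, 61))
    truth = {"max_center_to_phosphate": float(np.max(height_field(xg, yg))),
             "bulk_half_thickness": float(np.median(height_field(xg, yg))),
             "noise": noise, "seed": seed}
    return MembraneFixture(universe=u, ground_truth=truth,
                           n_frames=n_frames, box=box)
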
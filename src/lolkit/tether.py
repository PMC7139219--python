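"""Build membrane-insertion-ready lipoprotein models.

The folded core of a lipoprotein is reoriented so that its N terminus points
toward the (eventual) membrane: the Calpha positions of the first and second
resolved residues are placed on the z-axis with residue 1 below the core
centroid.  The N-terminal tether is then modeled onto the core:

* for the SP-bearing states, the signal peptide is built as an ideal
  alpha-helix from residue 1 to the lipobox cysteine, aligned along z;
* residues missing between the cysteine and the first resolved core residue
  are modeled as a disordered linker with an unstructured length of 3.5 A
  per residue, i.e. the cysteine sits ``3.5 * n_linker`` A below the core
  start, with the intervening residues on an extended, clash-free path.

Linkers longer than 35 residues trigger a warning (such constructs were
excluded from initial modeling because the disordered span dominates the
dynamics); the model is still built.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .sequences import LipoboxMatch, MaturationState, ProteinSequence
from .structure import Structure, cg_residue

__all__ = [
    "TetherSpec",
    "LipoproteinModel",
    "LongLinkerWarning",
    "orient_structure",
    "build_helix",
    "build_linker_path",
    "assemble_state",
]

#: Ideal alpha-helix geometry (canonical values).
HELIX_RISE = 1.5          # A per residue along the axis
HELIX_TWIST = 100.0       # degrees per residue
HELIX_RADIUS = 2.3        # A, Calpha radius

PER_RESIDUE_EXTENSION = 3.5   # A per disordered linker residue
PEPTIDE_SPACING = 3.8         # A, trans Calpha-Calpha virtual bond
MAX_BOND = 4.0                # A, ceiling on consecutive backbone spacing
CLASH_DISTANCE = 3.0          # A, minimum backbone-backbone separation
LONG_LINKER = 35              # residues; warn beyond this


class LongLinkerWarning(UserWarning):
    """Raised (as a warning) when a modeled linker exceeds 35 residues."""


@dataclass(frozen=True)
class TetherSpec:
    """Geometry of the modeled tether for one maturation state."""

    state: MaturationState
    n_linker: int = 0
    per_residue_extension: float = PER_RESIDUE_EXTENSION
    helix_range: tuple[int, int] | None = None  # (first residue, cys), SP states

    def __post_init__(self):
        if self.per_residue_extension <= 0:
            raise ValueError("per_residue_extension must be positive")
        if self.n_linker < 0:
            raise ValueError("n_linker must be >= 0")
        if self.helix_range is not None and not self.state.retains_signal_peptide:
            raise ValueError(f"state {self.state.value} carries no SP helix")


@dataclass
class LipoproteinModel:
    """A structure + maturation state + tether bookkeeping, build-ready."""

    structure: Structure
    state: MaturationState
    cys_index: int
    anchor_attachment: str = "none"       # none | diacyl | triacyl
    tether_resids: frozenset = field(default_factory=frozenset)
    warnings: list = field(default_factory=list)

    def __post_init__(self):
        if self.anchor_attachment != self.state.anchor:
            raise ValueError(
                f"anchor {self.anchor_attachment!r} inconsistent with state "
                f"{self.state.value} (expected {self.state.anchor!r})"
            )

    @property
    def core_resids(self) -> np.ndarray:
        r = self.structure.residue_ids()
        return r[~np.isin(r, list(self.tether_resids))]


# ---------------------------------------------------------------------------
# Orientation


def orient_structure(core: Structure) -> Structure:
    """Rigid-body reorientation for membrane insertion.

    After the transform the backbone positions of the first and second
    residues lie on the z-axis (x = y = 0) and residue 1 is at lower z than
    the backbone centroid, so the N terminus points down toward where the
    membrane will be placed.  Internal geometry is untouched (pure rotation +
    translation, determinant +1).
    """
    resids, bb = core.backbone()
    uniq = np.unique(resids)
    if len(uniq) < 2:
        raise ValueError("orientation needs at least two residues with backbone positions")
    p1 = bb[resids == uniq[0]][0]
    p2 = bb[resids == uniq[1]][0]
    axis = p2 - p1
    norm = np.linalg.norm(axis)
    if norm < 1e-8:
        raise ValueError("degenerate axis: first two backbone positions coincide")

    rot, _ = Rotation.align_vectors([[0.0, 0.0, 1.0]], [axis / norm])
    R = rot.as_matrix()
    out = core.transformed(R, -R @ p1)

    _, bb_new = out.backbone()
    if bb_new.mean(axis=0)[2] < 0.0:
        # flip about x so the centroid sits above residue 1
        flip = np.diag([1.0, -1.0, -1.0])
        out = out.transformed(flip, np.zeros(3))
    return out


def is_oriented(core: Structure, tol: float = 1e-5) -> bool:
    resids, bb = core.backbone()
    uniq = np.unique(resids)
    if len(uniq) < 2:
        return False
    p1 = bb[resids == uniq[0]][0]
    p2 = bb[resids == uniq[1]][0]
    on_axis = np.hypot(*p1[:2]) < tol and np.hypot(*p2[:2]) < tol
    return bool(on_axis and bb.mean(axis=0)[2] >= p1[2])


# ---------------------------------------------------------------------------
# Helix


def build_helix(
    residues: str,
    start_resid: int = 1,
    chain: str = "A",
    rise: float = HELIX_RISE,
    twist_deg: float = HELIX_TWIST,
    radius: float = HELIX_RADIUS,
) -> Structure:
    """Ideal alpha-helix for a residue span, axis along +z.

    Residue ``i`` (0-based within the span) has its backbone bead at
    ``(r cos(i*twist), r sin(i*twist), i*rise)``; a 10-residue span thus
    rises 13.5 A between first and last backbone beads.  Side-chain
    pseudo-atoms point radially outward.
    """
    if len(residues) == 0:
        raise ValueError("empty helix span")
    parts = []
    for i, aa in enumerate(residues):
        theta = np.deg2rad(twist_deg * i)
        bb = np.array([radius * np.cos(theta), radius * np.sin(theta), rise * i])
        outward = np.array([np.cos(theta), np.sin(theta), 0.0])
        parts.append(cg_residue(aa, start_resid + i, bb, chain=chain, outward=outward))
    out = parts[0]
    for p in parts[1:]:
        out = out.concat(p)
    return out


# ---------------------------------------------------------------------------
# Linker


def build_linker_path(
    start: np.ndarray,
    end: np.ndarray,
    n_linker: int,
    obstacle_xyz: np.ndarray,
    seed: int = 0,
    per_residue_extension: float = PER_RESIDUE_EXTENSION,
) -> np.ndarray:
    """Backbone positions for ``n_linker`` disordered residues between two
    anchored endpoints.

    The path starts as evenly spaced points on the start->end segment, takes
    seeded lateral perturbations, and is relaxed by steepest descent away
    from any obstacle backbone position closer than 3.0 A.  Deterministic
    given the seed.  Raises when the endpoints are further apart than an
    extended chain of ``n_linker + 1`` virtual bonds can span.
    """
    start = np.asarray(start, float)
    end = np.asarray(end, float)
    d = np.linalg.norm(end - start)
    max_span = (n_linker + 1) * MAX_BOND
    if d > max_span + 1e-9:
        raise ValueError(
            f"endpoints {d:.2f} A apart exceed the {max_span:.2f} A reach of "
            f"{n_linker} linker residues (extension {per_residue_extension} A/residue)"
        )
    if n_linker == 0:
        return np.empty((0, 3))

    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_linker + 2)[1:-1, None]
    pts = start + t * (end - start)
    pts = pts + rng.normal(scale=0.3, size=pts.shape) * np.array([1.0, 1.0, 0.2])

    obstacle_xyz = np.asarray(obstacle_xyz, float).reshape(-1, 3)
    for _ in range(200):
        if len(obstacle_xyz) == 0:
            break
        diff = pts[:, None, :] - obstacle_xyz[None, :, :]
        dist = np.linalg.norm(diff, axis=2)
        close = dist < CLASH_DISTANCE
        if not close.any():
            break
        # push each clashing point along the net repulsion direction
        with np.errstate(invalid="ignore", divide="ignore"):
            push = np.where(close[:, :, None], diff / dist[:, :, None], 0.0).sum(axis=1)
        norms = np.linalg.norm(push, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        pts = pts + 0.5 * push / norms
    return pts


# ---------------------------------------------------------------------------
# Assembly


def assemble_state(
    core: Structure,
    match: LipoboxMatch,
    state: MaturationState,
    sequence: ProteinSequence,
    seed: int = 0,
    per_residue_extension: float = PER_RESIDUE_EXTENSION,
) -> LipoproteinModel:
    """Compose core + tether for one maturation state.

    ``sequence`` is the full precursor sequence (it supplies residue types
    for the modeled helix/linker).  The tether attaches to the first resolved
    residue of the first chain; chain breaks elsewhere are tolerated.
    """
    if state is MaturationState.UNTETHERED:
        return LipoproteinModel(
            structure=core, state=state, cys_index=match.cys_position,
            anchor_attachment="none",
        )

    if not is_oriented(core):
        core = orient_structure(core)

    cys = match.cys_position
    if sequence[cys] != "C":
        raise ValueError("lipobox match inconsistent with the supplied sequence")

    first_chain = str(core.chains[0])
    core_resids = core.residue_ids(first_chain)
    r0 = int(core_resids[0])

    model_warnings: list[str] = []

    if state in (MaturationState.DI, MaturationState.TRI):
        # sequence starts at the cysteine; drop any resolved residues before it
        keep = ~((core.chains == first_chain) & (core.resids < cys))
        core_used = core.subset(keep)
        core_resids = core_used.residue_ids(first_chain)
        if len(core_resids) == 0:
            raise ValueError("no core residues at or after the lipobox cysteine")
        r0 = int(core_resids[0])
        if r0 == cys:
            # cysteine resolved in the core: nothing to model
            structure, tether = core_used, frozenset()
        else:
            structure, tether = _graft_tether(
                core_used, sequence, first_res=cys, cys=cys, r0=r0,
                helix=False, seed=seed, per_residue_extension=per_residue_extension,
                chain=first_chain, warn_sink=model_warnings,
            )
    else:  # SP, SP_DI: full precursor with the SP helix
        if r0 <= cys:
            raise ValueError(
                f"core residues ({r0}..) overlap the modeled tether (1..{cys})"
            )
        structure, tether = _graft_tether(
            core, sequence, first_res=1, cys=cys, r0=r0,
            helix=True, seed=seed, per_residue_extension=per_residue_extension,
            chain=first_chain, warn_sink=model_warnings,
        )

    return LipoproteinModel(
        structure=structure, state=state, cys_index=cys,
        anchor_attachment=state.anchor, tether_resids=tether,
        warnings=model_warnings,
    )


def _graft_tether(core, sequence, first_res, cys, r0, helix, seed,
                  per_residue_extension, chain, warn_sink):
    """Build helix (optional) + cys + linker below the oriented core."""
    n_linker = r0 - cys - 1
    if n_linker < 0:
        raise ValueError("core residues overlap modeled tether residue numbers")
    if n_linker > LONG_LINKER:
        msg = (f"linker of {n_linker} residues exceeds {LONG_LINKER}; the modeled "
               "disordered span will dominate the construct")
        warn_sink.append(msg)
        _warnings.warn(msg, LongLinkerWarning, stacklevel=3)

    core_bb_resids, core_bb = core.backbone()
    p_core = core_bb[core_bb_resids == r0][0]
    d = n_linker * per_residue_extension if n_linker > 0 else PEPTIDE_SPACING
    p_cys = p_core + np.array([0.0, 0.0, -d])

    parts = []
    if helix:
        span = sequence.residues[first_res - 1 : cys]  # residues 1..cys inclusive
        h = build_helix(span, start_resid=first_res, chain=chain)
        # place the helix so its last residue (the cysteine) sits at p_cys
        _, h_bb = h.backbone()
        shift = p_cys - h_bb[-1]
        h = h.transformed(np.eye(3), shift)
        parts.append(h)
        tether_ids = set(range(first_res, r0))
    else:
        parts.append(cg_residue("C", cys, p_cys, chain=chain))
        tether_ids = set(range(cys, r0))

    if n_linker > 0:
        linker_bb = build_linker_path(
            p_cys, p_core, n_linker, obstacle_xyz=core_bb, seed=seed,
            per_residue_extension=per_residue_extension,
        )
        for k in range(n_linker):
            resid = cys + 1 + k
            aa = sequence[resid]
            parts.append(cg_residue(aa, resid, linker_bb[k], chain=chain))

    tether = parts[0]
    for p in parts[1:]:
        tether = tether.concat(p)

    if np.intersect1d(tether.resids, core.resids[core.chains == chain]).size:
        raise ValueError("core residues overlap modeled tether residue numbers")
    return tether.concat(core), frozenset(tether_ids)
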
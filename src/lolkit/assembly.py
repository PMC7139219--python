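"""Simulation-system specification: membranes, run parameters, umbrella plans.

This module turns protocol descriptions into concrete numbers and files —
per-leaflet lipid counts for a target composition, GROMACS-style run
parameter (mdp) files for the assembly/production/umbrella stages, umbrella
window plans extracted from a steered pull trace, and the low-mobility
restraint triangle used to hold a carrier protein in place during umbrella
sampling.  It never invokes an MD engine.

Default protocol values: coarse-grained production runs use a 20 fs
timestep at 323 K and 1 bar (v-rescale/Parrinello-Rahman couplings of 1.0
and 12.0 ps), nonbonded interactions cut off at 1.1 nm with the neighbour
list updated every 20 steps, in 0.15 M NaCl.  Umbrella sampling runs at
310 K with a 1000 kJ/mol/nm^2 pull force constant and windows every 0.1 nm.
The inner membrane is 4:1 POPE:POPG, the transporter membrane 7:2:1
POPG:POPE:cardiolipin, and outer-membrane LPS occupies 1.7 nm^2 per
molecule in the outer leaflet.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MembraneSpec",
    "RunConfig",
    "UmbrellaSetup",
    "WindowPlan",
    "IM_SPEC",
    "TRANSPORTER_SPEC",
    "lipid_counts",
    "default_run_config",
    "plan_umbrella_windows",
    "select_restraint_triangle",
    "write_mdp",
    "read_mdp",
    "write_window_manifest",
    "read_window_manifest",
]

LPS_AREA = 1.7           # nm^2 per LPS in the OM outer leaflet
PULL_FORCE_CONSTANT = 1000.0   # kJ/mol/nm^2
WINDOW_SPACING = 0.1     # nm
WINDOW_COUNT_RANGE = (50, 80)
TRIANGLE_RESTRAINT = 1000.0    # kJ/mol/nm^2, x/y/z position restraint


@dataclass(frozen=True)
class MembraneSpec:
    """Leaflet compositions as (lipid name, mole fraction) lists.

    ``area_per_lipid`` overrides (nm^2) feed area-based counting; LPS
    defaults to 1.7 nm^2.
    """

    upper: tuple = ()
    lower: tuple = ()
    area_per_lipid: tuple = ()     # ((name, nm^2), ...)
    box: tuple | None = None       # (x, y, z) nm

    def __post_init__(self):
        for leaflet in (self.upper, self.lower):
            if not leaflet:
                continue
            fracs = [f for _, f in leaflet]
            if any(f < 0 for f in fracs):
                raise ValueError("negative mole fraction")
            if abs(sum(fracs) - 1.0) > 1e-9:
                raise ValueError(f"leaflet fractions sum to {sum(fracs)}, not 1")

    def apl(self, name: str) -> float:
        for n, a in self.area_per_lipid:
            if n == name:
                return a
        return LPS_AREA if name.upper().startswith("LPS") else 0.64


#: E. coli inner-membrane model: POPE:POPG 4:1, both leaflets.
IM_SPEC = MembraneSpec(upper=(("POPE", 0.8), ("POPG", 0.2)),
                       lower=(("POPE", 0.8), ("POPG", 0.2)))

#: Transporter (LolCDE) membrane: POPG:POPE:cardiolipin 7:2:1.
TRANSPORTER_SPEC = MembraneSpec(upper=(("POPG", 0.7), ("POPE", 0.2), ("CDL", 0.1)),
                                lower=(("POPG", 0.7), ("POPE", 0.2), ("CDL", 0.1)))


def _largest_remainder(fractions: list[float], total: int) -> list[int]:
    """Integer apportionment preserving the total exactly (deterministic)."""
    raw = [f * total for f in fractions]
    counts = [math.floor(r) for r in raw]
    short = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: (-(raw[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def lipid_counts(
    spec: MembraneSpec,
    leaflet_area: float | None = None,
    n_lipids: int | None = None,
) -> dict[str, dict[str, int]]:
    """Per-lipid integer counts per leaflet.

    Counts are proportional to mole fractions, rounded by largest remainder
    so leaflet totals match exactly.  Give either ``n_lipids`` (target per
    leaflet) or ``leaflet_area`` (nm^2; the total follows from the
    composition-weighted area per lipid).  A leaflet containing LPS is
    counted as floor(area / 1.7) LPS molecules.
    """
    if (leaflet_area is None) == (n_lipids is None):
        raise ValueError("give exactly one of leaflet_area or n_lipids")
    out: dict[str, dict[str, int]] = {}
    for label, leaflet in (("upper", spec.upper), ("lower", spec.lower)):
        if not leaflet:
            out[label] = {}
            continue
        names = [n for n, _ in leaflet]
        fracs = [f for _, f in leaflet]
        if any(n.upper().startswith("LPS") for n in names):
            if leaflet_area is None:
                raise ValueError("LPS leaflets are counted by area (1.7 nm^2 per LPS)")
            if len(names) != 1:
                raise ValueError("LPS leaflets are single-component here")
            n_lps = math.floor(leaflet_area / spec.apl(names[0]))
            if n_lps < 1:
                raise ValueError(f"leaflet area {leaflet_area} nm^2 too small for one LPS")
            out[label] = {names[0]: n_lps}
            continue
        if leaflet_area is not None:
            mean_apl = sum(f * spec.apl(n) for n, f in leaflet)
            total = math.floor(leaflet_area / mean_apl)
        else:
            total = n_lipids
        if total < 1:
            raise ValueError("leaflet too small for a single lipid")
        out[label] = dict(zip(names, _largest_remainder(fracs, total)))
    return out


# ---------------------------------------------------------------------------
# Run configuration


@dataclass(frozen=True)
class RunConfig:
    """MD run parameters (GROMACS conventions for names and units)."""

    stage: str
    timestep_fs: float = 20.0
    temperature_K: float = 323.0
    pressure_bar: float = 1.0
    tau_t_ps: float = 1.0
    tau_p_ps: float = 12.0
    cutoff_nm: float = 1.1
    nstlist: int = 20
    salt_M: float = 0.15

    def __post_init__(self):
        for name in ("timestep_fs", "temperature_K", "pressure_bar", "tau_t_ps",
                     "tau_p_ps", "cutoff_nm", "nstlist", "salt_M"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


_STAGES = ("assembly", "production", "umbrella")


def default_run_config(stage: str, **overrides) -> RunConfig:
    """Protocol defaults per stage; umbrella runs at 310 K, otherwise the
    production parameters apply.  Keyword overrides replace any field."""
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; expected one of {_STAGES}")
    cfg = RunConfig(stage=stage)
    if stage == "umbrella":
        cfg = replace(cfg, temperature_K=310.0)
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


_MDP_KEYS = {
    "dt": ("timestep_fs", 1e-3),        # fs -> ps
    "ref-t": ("temperature_K", 1.0),
    "ref-p": ("pressure_bar", 1.0),
    "tau-t": ("tau_t_ps", 1.0),
    "tau-p": ("tau_p_ps", 1.0),
    "rvdw": ("cutoff_nm", 1.0),
    "rcoulomb": ("cutoff_nm", 1.0),
    "nstlist": ("nstlist", 1.0),
}


def write_mdp(cfg: RunConfig, path: str | Path) -> None:
    """Emit a key = value run-parameter file (mdp dialect)."""
    lines = [f"; lolkit run parameters, stage = {cfg.stage}",
             f"; salt concentration {cfg.salt_M} M NaCl (applied at solvation)",
             "integrator = md"]
    for key, (attr, scale) in _MDP_KEYS.items():
        val = getattr(cfg, attr) * scale
        lines.append(f"{key} = {val:g}")
    lines += ["tcoupl = v-rescale", "pcoupl = parrinello-rahman",
              "coulombtype = reaction-field", "vdw-modifier = potential-shift"]
    Path(path).write_text("\n".join(lines) + "\n")


def read_mdp(path: str | Path) -> dict[str, str]:
    out = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split(";", 1)[0].strip()
        if "=" in line:
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out


# ---------------------------------------------------------------------------
# Umbrella planning


@dataclass(frozen=True)
class UmbrellaSetup:
    """Umbrella-sampling protocol summary."""

    force_constant: float = PULL_FORCE_CONSTANT
    spacing_nm: float = WINDOW_SPACING
    window_count: int = 0
    temperature_K: float = 310.0
    restraint_beads: tuple | None = None
    restraint_constant: float = TRIANGLE_RESTRAINT
    count_in_range: bool = True

    def __post_init__(self):
        if self.spacing_nm <= 0:
            raise ValueError("spacing must be positive")


@dataclass(frozen=True)
class WindowPlan:
    """Selected frames for each 0.1 nm target along the reaction coordinate."""

    setup: UmbrellaSetup
    centers: tuple          # nm, arithmetic sequence
    frames: tuple           # source frame index per window
    distances: tuple        # trace distance of the chosen frame


def plan_umbrella_windows(
    pull_trace,
    spacing: float = WINDOW_SPACING,
    force_constant: float = PULL_FORCE_CONSTANT,
    temperature_K: float = 310.0,
) -> WindowPlan:
    """One umbrella window per ``spacing`` along a steered pull trace.

    ``pull_trace`` is a sequence of (distance nm, frame id) — typically the
    center-of-mass separation recorded during the pull, which must include
    the zero crossing.  Targets run from 0 up to the largest distance
    reached, at consecutive ``spacing`` intervals; each target takes the
    trace frame nearest to it (ties resolved to the earlier frame).  A
    target with no frame within half a spacing is a gap and raises.
    """
    trace = [(float(d), f) for d, f in pull_trace]
    if not trace:
        raise ValueError("empty pull trace")
    dist = np.array([d for d, _ in trace])
    lo, hi = dist.min(), dist.max()
    if lo > 1e-9:
        raise ValueError(
            f"pull trace does not reach zero center-of-mass separation (min {lo:.3f} nm)"
        )
    n_targets = int(np.floor(hi / spacing + 1e-9)) + 1
    centers = np.arange(n_targets) * spacing

    frames, distances = [], []
    for c in centers:
        # round at 1e-12 nm so float representation noise cannot break ties
        err = np.round(np.abs(dist - c), 12)
        best = int(np.argmin(err))     # argmin takes the earliest tie
        if err[best] > spacing / 2 + 1e-12:
            raise ValueError(
                f"no trace frame within {spacing/2:.3f} nm of target {c:.2f} nm "
                f"(nearest is {err[best]:.3f} nm away)"
            )
        frames.append(trace[best][1])
        distances.append(float(dist[best]))

    in_range = WINDOW_COUNT_RANGE[0] <= n_targets <= WINDOW_COUNT_RANGE[1]
    setup = UmbrellaSetup(force_constant=force_constant, spacing_nm=spacing,
                          window_count=n_targets, temperature_K=temperature_K,
                          count_in_range=in_range)
    return WindowPlan(setup=setup, centers=tuple(float(c) for c in centers),
                      frames=tuple(frames), distances=tuple(distances))


def write_window_manifest(plan: WindowPlan, path: str | Path) -> None:
    """Plain-text manifest: window id, center nm, force constant, source frame."""
    df = pd.DataFrame({
        "window": range(len(plan.centers)),
        "center_nm": plan.centers,
        "force_constant": plan.setup.force_constant,
        "source_frame": plan.frames,
    })
    df.to_csv(path, sep="\t", index=False)


def read_window_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Restraint triangle


def _triangle_area(p: np.ndarray) -> float:
    return 0.5 * float(np.linalg.norm(np.cross(p[1] - p[0], p[2] - p[0])))


def select_restraint_triangle(
    positions: np.ndarray,
    fluctuations: np.ndarray,
    base_region: tuple[float, float] | None = None,
    min_area: float = 0.5,
) -> tuple[int, int, int]:
    """Three low-mobility backbone beads forming a triangle at the protein base.

    ``positions`` (n, 3) and per-bead ``fluctuations`` (RMSF over an
    equilibration trajectory, any consistent units).  ``base_region`` is a
    z-range; by default the 20% of beads with lowest z.  Among candidate
    beads the combination with the lowest fluctuation sum whose triangle
    area exceeds ``min_area`` (non-collinearity) wins; ties break on bead
    indices.  Deterministic.
    """
    positions = np.asarray(positions, float).reshape(-1, 3)
    fluctuations = np.asarray(fluctuations, float)
    if len(positions) != len(fluctuations):
        raise ValueError("positions and fluctuations differ in length")
    z = positions[:, 2]
    if base_region is None:
        zmax = np.quantile(z, 0.2)
        cand = np.flatnonzero(z <= zmax)
    else:
        lo, hi = base_region
        cand = np.flatnonzero((z >= lo) & (z <= hi))
    if len(cand) < 3:
        raise ValueError(f"only {len(cand)} candidate beads in the base region; need 3")
    ranked = sorted(cand, key=lambda i: (fluctuations[i], i))
    for combo in sorted(combinations(ranked, 3),
                        key=lambda c: (sum(fluctuations[i] for i in c), c)):
        if _triangle_area(positions[list(combo)]) > min_area:
            return tuple(sorted(combo))
    raise ValueError("all candidate triangles are degenerate (collinear beads)")
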
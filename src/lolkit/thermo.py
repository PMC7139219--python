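"""Thermodynamic cycle of periplasmic lipoprotein transfer.

The cysteine-lipid moiety of a mature lipoprotein is handed from the inner
membrane (IM) to the carrier LolA, from LolA to the outer-membrane receptor
LolB, and from LolB into the outer membrane (OM).  Given the four
extraction free energies (the cost of pulling the moiety out of each
environment into water), pairwise subtraction yields the energetics of
each hop:

    step1 (IM -> LolA)  = dG_IM  - dG_LolA
    step2 (LolA -> LolB) = dG_LolA - dG_LolB
    step3 (LolB -> OM)  = dG_LolB - dG_OM

Positive step values are energy the cell must supply for that hop; the sum
telescopes exactly to ``dG_IM - dG_OM``.  The only uphill step, extraction
from the IM into LolA, is paid for by ATP hydrolysis in the LolCDE
transporter; with a per-ATP release between 31.55 and 46.5 kJ/mol, two ATP
provide a budget of 63.1-93.0 kJ/mol.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

__all__ = [
    "ATP_RELEASE_RANGE",
    "ExtractionEnergies",
    "TransferCycle",
    "AtpFeasibility",
    "build_cycle",
    "atp_feasibility",
    "read_energies",
    "write_cycle_report",
]

#: Magnitude of the free energy released per ATP hydrolysed (kJ/mol).
ATP_RELEASE_RANGE = (31.55, 46.5)


@dataclass(frozen=True)
class ExtractionEnergies:
    """Cost (kJ/mol) of removing the cysteine-lipid moiety from each
    environment into water; all values >= 0 by construction."""

    dg_im: float
    dg_lola: float
    dg_lolb: float
    dg_om: float
    moiety: str = "triacyl"
    errors: tuple | None = None    # optional per-value standard errors

    def __post_init__(self):
        for name in ("dg_im", "dg_lola", "dg_lolb", "dg_om"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} is not finite")
            if v < 0:
                raise ValueError(f"{name} = {v} < 0; extraction energies are costs")
        if self.moiety not in ("triacyl", "diacyl"):
            raise ValueError(f"unknown moiety {self.moiety!r}")


@dataclass(frozen=True)
class TransferCycle:
    """Step and net energetics (kJ/mol) of the three transfer hops."""

    step1_im_to_lola: float
    step2_lola_to_lolb: float
    step3_lolb_to_om: float
    net: float
    moiety: str = "triacyl"
    step_errors: tuple | None = None
    atp_budget_range: tuple = (2 * ATP_RELEASE_RANGE[0], 2 * ATP_RELEASE_RANGE[1])

    def __post_init__(self):
        total = self.step1_im_to_lola + self.step2_lola_to_lolb + self.step3_lolb_to_om
        if abs(total - self.net) > 1e-9:
            raise ValueError("net must equal the sum of the three steps")


def build_cycle(e: ExtractionEnergies) -> TransferCycle:
    """Pairwise subtraction of the four extraction energies.

    Positive values cost energy; the net is the exact telescoping sum
    ``dG_IM - dG_OM``.  Per-step errors, when the inputs carry them, are
    combined in quadrature.
    """
    s1 = e.dg_im - e.dg_lola
    s2 = e.dg_lola - e.dg_lolb
    s3 = e.dg_lolb - e.dg_om
    step_errors = None
    if e.errors is not None:
        err = list(e.errors)
        if len(err) != 4:
            raise ValueError("errors must hold four values (IM, LolA, LolB, OM)")
        step_errors = (
            math.hypot(err[0], err[1]),
            math.hypot(err[1], err[2]),
            math.hypot(err[2], err[3]),
        )
    return TransferCycle(step1_im_to_lola=s1, step2_lola_to_lolb=s2,
                         step3_lolb_to_om=s3, net=s1 + s2 + s3,
                         moiety=e.moiety, step_errors=step_errors)


@dataclass(frozen=True)
class AtpFeasibility:
    """Whether the uphill extraction step fits the ATP-hydrolysis budget."""

    step1: float
    n_atp: int
    budget_range: tuple          # kJ/mol available, (low, high)
    feasible_at_max: bool
    feasible_at_min: bool
    marginal: bool               # feasible only toward the top of the range

    @property
    def feasible(self) -> bool:
        return self.feasible_at_max


def atp_feasibility(
    cycle: TransferCycle,
    per_atp_range: tuple[float, float] = ATP_RELEASE_RANGE,
    n_atp: int = 2,
) -> AtpFeasibility:
    """Compare step 1 against ``n_atp`` ATP hydrolyses.

    ``per_atp_range`` is the magnitude of the per-ATP release; with two ATP
    the default budget interval is [63.1, 93.0] kJ/mol.  ``marginal`` flags
    a step that exceeds the low end of the budget but not the high end.
    """
    if n_atp < 1:
        raise ValueError("n_atp must be >= 1")
    lo = n_atp * abs(per_atp_range[0])
    hi = n_atp * abs(per_atp_range[1])
    lo, hi = min(lo, hi), max(lo, hi)
    s1 = cycle.step1_im_to_lola
    at_min = s1 <= lo
    at_max = s1 <= hi
    return AtpFeasibility(step1=s1, n_atp=n_atp, budget_range=(lo, hi),
                          feasible_at_max=at_max, feasible_at_min=at_min,
                          marginal=at_max and not at_min)


# ---------------------------------------------------------------------------
# I/O


def read_energies(path: str | Path) -> ExtractionEnergies:
    """Read labeled extraction energies from JSON
    ({"IM": .., "LolA": .., "LolB": .., "OM": .., "moiety": ..})."""
    data = json.loads(Path(path).read_text())
    lower = {k.lower(): v for k, v in data.items()}
    errors = tuple(lower["errors"]) if "errors" in lower else None
    return ExtractionEnergies(dg_im=float(lower["im"]), dg_lola=float(lower["lola"]),
                              dg_lolb=float(lower["lolb"]), dg_om=float(lower["om"]),
                              moiety=lower.get("moiety", "triacyl"), errors=errors)


def write_cycle_report(cycle: TransferCycle, feas: AtpFeasibility,
                       path: str | Path) -> None:
    """Cycle report as JSON (text summary printed by the CLI instead)."""
    payload = {"cycle": asdict(cycle), "atp": asdict(feas)}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
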
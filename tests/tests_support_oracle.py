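"""Shared brute-force contact oracle used by the acceptance checks."""

import re

import numpy as np


def brute_force_reference(universe, classes, cutoff=6.0):
    """All-pairs minimum-image contact counts: binary per frame, residue,
    and bead class.  O(N^2) per frame; independent of the library's
    neighbour-search path."""
    prot = universe.select_atoms("protein")
    lip = universe.select_atoms("not protein")
    resids = prot.residues.resids
    counts = {int(rid): {c: 0 for c in classes} for rid in resids}
    compiled = {c: re.compile(p) for c, p in classes.items()}
    for _ in universe.trajectory:
        box = universe.dimensions[:3]
        for rid in resids:
            rpos = prot.select_atoms(f"resid {rid}").positions
            for label, rx in compiled.items():
                hit = False
                for name, lp in zip(lip.names, lip.positions):
                    if not rx.match(name):
                        continue
                    for rp in rpos:
                        d = rp - lp
                        d -= box * np.round(d / box)
                        if np.linalg.norm(d) <= cutoff:
                            hit = True
                            break
                    if hit:
                        break
                counts[int(rid)][label] += int(hit)
    return counts
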
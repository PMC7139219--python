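"""Weighted histogram analysis of umbrella-sampling windows.

Each umbrella window ``i`` biases the reaction coordinate xi (here the
z-projected center-of-mass separation, nm) with a harmonic potential
``w_i(xi) = 1/2 k_i (xi - xi_i)^2``.  WHAM combines the biased histograms
``n_i`` into the unbiased bin probability

    P(xi) = sum_i n_i(xi) / sum_i N_i exp[(F_i - w_i(xi)) / kT]

with the window free energies determined self-consistently from

    F_i = -kT ln sum_xi P(xi) exp(-w_i(xi) / kT),

iterated until the largest change in any F_i falls below a tolerance.  The
potential of mean force is ``G(xi) = -kT ln P(xi)``, anchored so its
minimum is zero; extraction free energies are read off as the mean plateau
value of the anchored profile.

Errors come from a Bayesian bootstrap over whole windows: each replicate
reweights windows by unit-mean Dirichlet weights and re-runs the estimator;
the per-bin standard deviation across replicates is the error.  Overlap of
adjacent-window histograms and agreement between profiles computed from
consecutive fractions of the sampling are the convergence diagnostics.

No autocorrelation correction is applied: sample counts enter WHAM raw,
with the whole-window bootstrap absorbing within-window correlation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KB",
    "UmbrellaWindow",
    "PMFProfile",
    "OverlapReport",
    "ConvergenceReport",
    "ExtractionResult",
    "wham_estimate",
    "bootstrap_errors",
    "histogram_overlap",
    "convergence_check",
    "extraction_free_energy",
    "read_windows",
    "write_profile",
]

KB = 0.008314462618  # kJ/mol/K

DEFAULT_BIN_WIDTH = 0.02  # nm
DEFAULT_TOL = 1e-6        # kJ/mol on the F_i updates
DEFAULT_MAX_ITER = 100_000


class WhamConvergenceError(RuntimeError):
    """Raised when the self-consistency loop exhausts max_iter."""

    def __init__(self, max_iter: int, residual: float):
        self.residual = residual
        super().__init__(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last max |dF| = {residual:.3e} kJ/mol)"
        )


class DisconnectedWindowsError(ValueError):
    """Raised when window histograms do not form one overlapping chain."""


@dataclass(frozen=True)
class UmbrellaWindow:
    """Biased samples from one umbrella window."""

    center: float                 # nm
    k: float                      # kJ/mol/nm^2
    samples: np.ndarray           # reaction-coordinate values, nm
    temperature: float = 310.0    # K

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, float).ravel())
        if self.samples.size < 1:
            raise ValueError("window has no samples")
        if self.k < 0:
            raise ValueError("force constant must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def kT(self) -> float:
        return KB * self.temperature

    def bias(self, xi: np.ndarray) -> np.ndarray:
        return 0.5 * self.k * (np.asarray(xi) - self.center) ** 2


@dataclass
class PMFProfile:
    """A free-energy curve G(xi) anchored at zero at its minimum."""

    bin_centers: np.ndarray       # nm
    free_energy: np.ndarray       # kJ/mol; NaN on empty bins
    errors: np.ndarray | None     # kJ/mol, bootstrap standard errors
    window_offsets: np.ndarray    # F_i per window, kJ/mol
    iterations: int
    kT: float

    def __post_init__(self):
        if self.errors is not None and np.any(np.asarray(self.errors) < 0):
            raise ValueError("errors must be >= 0")

    @property
    def minimum(self) -> tuple[float, float]:
        """(location nm, value kJ/mol) of the profile minimum."""
        i = int(np.nanargmin(self.free_energy))
        return float(self.bin_centers[i]), float(self.free_energy[i])


@dataclass(frozen=True)
class OverlapReport:
    """Histogram overlap fraction for each adjacent window pair."""

    pairs: tuple      # ((index_a, index_b, overlap in [0, 1]), ...)

    def min_overlap(self) -> float:
        return min(o for _, _, o in self.pairs) if self.pairs else np.nan


@dataclass
class ConvergenceReport:
    """PMFs from consecutive time fractions plus their max deviation."""

    profiles: list
    max_deviation: float          # kJ/mol, max pairwise per-bin difference
    flagged_empty: bool = False


# ---------------------------------------------------------------------------
# Core estimator


def _shared_edges(windows, bin_width, xrange):
    lo = min(w.samples.min() for w in windows) if xrange is None else xrange[0]
    hi = max(w.samples.max() for w in windows) if xrange is None else xrange[1]
    if hi <= lo:
        hi = lo + bin_width
    n_bins = max(1, int(np.ceil((hi - lo) / bin_width - 1e-9)))
    return np.linspace(lo, lo + n_bins * bin_width, n_bins + 1)


def _check_connected(hists: np.ndarray, windows) -> None:
    """All windows must chain together through shared nonzero bins."""
    n = len(windows)
    support = [set(np.flatnonzero(h)) for h in hists]
    linked = {0}
    frontier = [0]
    while frontier:
        i = frontier.pop()
        for j in range(n):
            if j not in linked and support[i] & support[j]:
                linked.add(j)
                frontier.append(j)
    if len(linked) != n:
        missing = sorted(set(range(n)) - linked)
        rep = histogram_overlap(list(windows), bins=hists.shape[1])
        raise DisconnectedWindowsError(
            f"window histograms are disconnected (windows {missing} share no "
            f"bins with the rest); adjacent overlaps: "
            f"{[(a, b, round(o, 4)) for a, b, o in rep.pairs]}"
        )


def wham_estimate(
    windows: Sequence[UmbrellaWindow],
    bin_width: float = DEFAULT_BIN_WIDTH,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    xrange: tuple[float, float] | None = None,
    window_weights: np.ndarray | None = None,
) -> PMFProfile:
    """Self-consistent WHAM over shared bins (one per ``bin_width`` nm).

    ``window_weights`` multiplies each window's histogram and sample count
    (used by the Bayesian bootstrap); default unit weights.  All windows
    must share one temperature.  Raises :class:`DisconnectedWindowsError`
    when histograms do not overlap into a single chain, and
    :class:`WhamConvergenceError` when ``max_iter`` is exhausted.
    """
    windows = list(windows)
    if not windows:
        raise ValueError("need at least one window")
    temps = {w.temperature for w in windows}
    if len(temps) > 1:
        raise ValueError(f"windows at different temperatures: {sorted(temps)}")
    kT = windows[0].kT

    edges = _shared_edges(windows, bin_width, xrange)
    centers = 0.5 * (edges[:-1] + edges[1:])
    n_win, n_bins = len(windows), len(centers)

    hists = np.empty((n_win, n_bins))
    for i, w in enumerate(windows):
        hists[i], _ = np.histogram(w.samples, bins=edges)
    _check_connected(hists, windows)

    if window_weights is None:
        window_weights = np.ones(n_win)
    window_weights = np.asarray(window_weights, float)
    w_hists = hists * window_weights[:, None]
    counts = w_hists.sum(axis=0)                       # numerator per bin
    N = np.array([h.sum() for h in w_hists])           # weighted samples per window

    bias = np.stack([w.bias(centers) for w in windows])  # (n_win, n_bins)
    exp_neg_bias = np.exp(-bias / kT)

    F = np.zeros(n_win)
    occupied = counts > 0
    for it in range(1, max_iter + 1):
        denom = (N * np.exp(F / kT)) @ exp_neg_bias     # sum_i N_i e^{(F_i - w_i)/kT}
        P = np.where(occupied, counts / np.where(denom > 0, denom, 1.0), 0.0)
        P = P / P.sum()
        with np.errstate(divide="ignore"):
            F_new = -kT * np.log(exp_neg_bias @ P)
        F_new = F_new - F_new[0]                        # gauge: F_0 = 0
        resid = float(np.max(np.abs(F_new - F)))
        F = F_new
        if resid < tol:
            break
    else:
        raise WhamConvergenceError(max_iter, resid)

    with np.errstate(divide="ignore"):
        G = np.where(occupied, -kT * np.log(np.where(P > 0, P, 1.0)), np.nan)
    G = G - np.nanmin(G)
    return PMFProfile(bin_centers=centers, free_energy=G, errors=None,
                      window_offsets=F, iterations=it, kT=kT)


# ---------------------------------------------------------------------------
# Bootstrap errors


def bootstrap_errors(
    windows: Sequence[UmbrellaWindow],
    n_boot: int = 200,
    seed: int = 0,
    **wham_kwargs,
) -> tuple[np.ndarray, dict]:
    """Bayesian bootstrap standard errors per PMF bin.

    Each replicate draws Dirichlet(1, ..., 1) weights over whole windows,
    scales them to unit mean, and re-runs :func:`wham_estimate`.  Errors
    are the per-bin standard deviation of the anchored replicate profiles.
    Deterministic given ``seed``.  Replicates whose estimate fails are
    dropped and counted in the returned diagnostics.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    windows = list(windows)
    # freeze the bin grid so replicates align
    if "xrange" not in wham_kwargs or wham_kwargs["xrange"] is None:
        lo = min(w.samples.min() for w in windows)
        hi = max(w.samples.max() for w in windows)
        wham_kwargs["xrange"] = (lo, hi)
    rng = np.random.default_rng(seed)
    n_win = len(windows)
    profiles = []
    failures = 0
    for _ in range(n_boot):
        weights = rng.dirichlet(np.ones(n_win)) * n_win   # unit mean
        try:
            prof = wham_estimate(windows, window_weights=weights, **wham_kwargs)
        except (WhamConvergenceError, DisconnectedWindowsError):
            failures += 1
            continue
        profiles.append(prof.free_energy)
    if len(profiles) < 2:
        raise RuntimeError(f"bootstrap failed: only {len(profiles)} replicates succeeded")
    stack = np.vstack(profiles)
    errors = np.nanstd(stack, axis=0, ddof=1)
    diagnostics = {"n_boot": n_boot, "n_failed": failures,
                   "failure_rate": failures / n_boot}
    return errors, diagnostics


# ---------------------------------------------------------------------------
# Diagnostics


def histogram_overlap(
    windows: Sequence[UmbrellaWindow],
    bins: int = 100,
) -> OverlapReport:
    """Overlap of adjacent (by center) windows: sum of bin-wise minima of
    the two normalized histograms, on shared edges spanning all samples."""
    windows = list(windows)
    if len(windows) < 2:
        raise ValueError("need at least two windows")
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    edges = np.linspace(lo, hi if hi > lo else lo + 1e-9, bins + 1)
    order = np.argsort([w.center for w in windows], kind="stable")
    pairs = []
    for a, b in zip(order[:-1], order[1:]):
        pa, _ = np.histogram(windows[a].samples, bins=edges)
        pb, _ = np.histogram(windows[b].samples, bins=edges)
        overlap = float(np.minimum(pa / pa.sum(), pb / pb.sum()).sum())
        pairs.append((int(a), int(b), overlap))
    return OverlapReport(pairs=tuple(pairs))


def convergence_check(
    windows: Sequence[UmbrellaWindow],
    n_fractions: int = 2,
    **wham_kwargs,
) -> ConvergenceReport:
    """Re-estimate the PMF on consecutive time fractions of every window and
    report the largest pairwise per-bin deviation between the re-anchored
    fraction profiles."""
    windows = list(windows)
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    for w in windows:
        if w.samples.size < n_fractions:
            raise ValueError("every window needs at least n_fractions samples")
    if "xrange" not in wham_kwargs or wham_kwargs["xrange"] is None:
        lo = min(w.samples.min() for w in windows)
        hi = max(w.samples.max() for w in windows)
        wham_kwargs["xrange"] = (lo, hi)

    profiles = []
    flagged = False
    for f in range(n_fractions):
        part = []
        for w in windows:
            n = w.samples.size
            sl = slice((f * n) // n_fractions, ((f + 1) * n) // n_fractions)
            part.append(UmbrellaWindow(center=w.center, k=w.k,
                                       samples=w.samples[sl],
                                       temperature=w.temperature))
        prof = wham_estimate(part, **wham_kwargs)
        if np.isnan(prof.free_energy).any():
            flagged = True
        profiles.append(prof)

    max_dev = 0.0
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            d = np.abs(profiles[i].free_energy - profiles[j].free_energy)
            if np.isfinite(d).any():
                max_dev = max(max_dev, float(np.nanmax(d)))
    return ConvergenceReport(profiles=profiles, max_deviation=max_dev,
                             flagged_empty=flagged)


# ---------------------------------------------------------------------------
# Extraction free energy


@dataclass(frozen=True)
class ExtractionResult:
    """Plateau-minus-minimum height of an anchored PMF."""

    delta_g: float        # kJ/mol
    flatness: float       # max - min of G over the plateau region
    slope: float          # kJ/mol per nm over the plateau region
    warning: str | None = None


def extraction_free_energy(
    profile: PMFProfile,
    plateau_region: tuple[float, float],
    slope_threshold: float = 5.0,
) -> ExtractionResult:
    """Extraction free energy: mean G over the plateau region of an anchored
    profile (the minimum is the bound state at G = 0).

    A plateau slope above ``slope_threshold`` (kJ/mol/nm) attaches a
    warning — the profile has not levelled off.
    """
    lo, hi = plateau_region
    mask = (profile.bin_centers >= lo) & (profile.bin_centers <= hi)
    mask &= np.isfinite(profile.free_energy)
    if not mask.any():
        raise ValueError(f"plateau region {plateau_region} outside profile support")
    g = profile.free_energy[mask]
    x = profile.bin_centers[mask]
    slope = float(np.polyfit(x, g, 1)[0]) if len(g) > 1 else 0.0
    warning = None
    if abs(slope) > slope_threshold:
        warning = (f"plateau slope {slope:.2f} kJ/mol/nm exceeds "
                   f"{slope_threshold}; profile may not be converged")
    return ExtractionResult(delta_g=float(g.mean()),
                            flatness=float(g.max() - g.min()),
                            slope=slope, warning=warning)


# ---------------------------------------------------------------------------
# I/O: pullx-style window files + manifest


def read_windows(manifest: str | Path, temperature: float = 310.0) -> list[UmbrellaWindow]:
    """Load windows from a TSV manifest (file, center, force_constant); each
    referenced file holds (time, xi) columns, whitespace- or tab-separated."""
    mdir = Path(manifest).parent
    table = pd.read_csv(manifest, sep="\t")
    windows = []
    for _, row in table.iterrows():
        data = np.loadtxt(mdir / row["file"])
        xi = data[:, 1] if data.ndim == 2 else data
        windows.append(UmbrellaWindow(center=float(row["center"]),
                                      k=float(row["force_constant"]),
                                      samples=xi, temperature=temperature))
    return windows


def write_profile(profile: PMFProfile, path: str | Path) -> None:
    """PMF as TSV: xi, G, err."""
    err = profile.errors if profile.errors is not None else np.full_like(
        profile.free_energy, np.nan)
    pd.DataFrame({"xi_nm": profile.bin_centers,
                  "G_kJ_per_mol": profile.free_energy,
                  "err_kJ_per_mol": err}).to_csv(path, sep="\t", index=False)
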
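"""PMF post-processing and adsorption free energies.

The potential of mean force W(s) along the surface separation distance is
either Boltzmann-inverted from an unbiased density, or integrated from a
mean-force profile (see :mod:`nanosorb.metad`). The adsorption free energy
is the layer-averaged Boltzmann weight of the bound region,

    dG_ads = -kB T ln[ (1/delta) \\int_{rc}^{rc+delta} exp(-W(s)/kB T) ds ],

where rc is the closest approach and delta the adsorption-layer thickness,
ending where W returns to its bulk zero. The result is an excess free
energy; a standard-state shift kB T ln(c/c_st) converts it to any reference
concentration. Binding modes follow the PMF-minimum position: direct
contact below 0.4 nm, water-mediated one hydration layer out (0.4-0.7 nm).

Units: s in nm, energies kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import KB

__all__ = [
    "PMFCurve",
    "BindingRegion",
    "AdsorptionResult",
    "pmf_from_density",
    "find_binding_region",
    "adsorption_free_energy",
    "standard_state_shift",
    "block_error",
    "save_pmf",
    "load_pmf",
    "save_result",
]

#: |W| tolerance (kJ/mol) for locating the W(s) = 0 bulk crossing.
ZERO_TOL = 0.1

#: Binding-mode thresholds (nm): direct below, water-mediated within.
DIRECT_MAX = 0.4
WATER_MEDIATED_RANGE = (0.4, 0.7)


@dataclass
class PMFCurve:
    """W(s) on a strictly increasing grid; NaN marks unsampled bins."""

    s: np.ndarray  # nm
    w: np.ndarray  # kJ/mol
    temperature: float = 300.0
    convention: str = "bulk-zero"
    flags: dict = field(default_factory=dict)

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.s.ndim != 1 or self.s.shape != self.w.shape:
            raise ValueError("s and w must be matching 1-D arrays")
        if np.any(np.diff(self.s) <= 0):
            raise ValueError("PMF grid must be strictly increasing")

    def defined(self) -> np.ndarray:
        return np.isfinite(self.w)

    def interp(self, s):
        d = self.defined()
        return np.interp(s, self.s[d], self.w[d])


@dataclass
class BindingRegion:
    """Bound-layer geometry extracted from a PMF."""

    rc: float  # nm, closest approach
    delta: float | None  # nm, adsorption-layer thickness
    mode: str  # "direct" | "water-mediated" | "none"
    minima: list = field(default_factory=list)  # (position, depth) pairs

    def __post_init__(self):
        if self.rc < 0:
            raise ValueError("rc must be non-negative")
        if self.mode != "none" and (self.delta is None or self.delta <= 0):
            raise ValueError("delta must be positive for a bound region")


@dataclass
class AdsorptionResult:
    dg: float  # kJ/mol
    region: BindingRegion
    error: float = 0.0  # kJ/mol
    standard_state: str = "excess"
    temperature: float = 300.0

    def __post_init__(self):
        if self.error < 0:
            raise ValueError("error must be non-negative")


def pmf_from_density(
    counts: np.ndarray,
    s: np.ndarray,
    temperature: float,
    bulk_window: tuple[float, float],
) -> PMFCurve:
    """Boltzmann inversion W = -kB T ln(rho / rho_bulk).

    ``counts`` is a histogram of s on the grid ``s`` (any normalization;
    W is invariant under scaling). ``rho_bulk`` averages the counts over
    the bulk window. Empty bins give NaN (flagged), never propagated
    infinities.
    """
    counts = np.asarray(counts, dtype=float)
    s = np.asarray(s, dtype=float)
    lo, hi = bulk_window
    in_bulk = (s >= lo) & (s <= hi)
    if not in_bulk.any() or counts[in_bulk].sum() <= 0:
        raise ValueError("bulk window contains no samples")
    rho_bulk = counts[in_bulk].mean()
    with np.errstate(divide="ignore"):
        w = np.where(counts > 0, -KB * temperature * np.log(counts / rho_bulk), np.nan)
    return PMFCurve(
        s=s, w=w, temperature=temperature,
        flags={"empty_bins": int(np.sum(counts == 0))},
    )


def _local_minima(s: np.ndarray, w: np.ndarray, zero_tol: float):
    """Local minima (plateau-aware) deeper than -zero_tol.

    A plateau that starts at the closest-approach edge and then rises
    counts as a minimum (a square well cut at rc); minima are reported at
    the first point of their plateau.
    """
    minima = []
    n = len(w)
    i = 0
    while i < n - 1:
        j = i
        while j < n - 1 and w[j + 1] == w[j]:
            j += 1
        left_shoulder = i == 0 or w[i - 1] > w[i]
        right_shoulder = j < n - 1 and w[j + 1] > w[j]
        if left_shoulder and right_shoulder and w[i] < -zero_tol:
            minima.append((float(s[i]), float(w[i])))
        i = j + 1
    return minima


def find_binding_region(pmf: PMFCurve, zero_tol: float = ZERO_TOL) -> BindingRegion:
    """Locate the bound layer [rc, rc+delta] and classify the binding mode.

    rc is the smallest s with a defined PMF value. The layer ends at the
    first point beyond the last PMF minimum where |W| drops within
    ``zero_tol`` and stays there toward the bulk edge (oscillations about
    zero nearer the surface are part of the bound region). Modes: direct
    when the global minimum sits below 0.4 nm, water-mediated for a global
    minimum in 0.4-0.7 nm, none when no minimum is deeper than the
    tolerance.
    """
    d = pmf.defined()
    if not d.any():
        raise ValueError("PMF has no defined values")
    s, w = pmf.s[d], pmf.w[d]
    rc = float(s[0])
    minima = _local_minima(s, w, zero_tol)
    if not minima:
        return BindingRegion(rc=rc, delta=None, mode="none", minima=[])
    pos_min, depth = min(minima, key=lambda m: m[1])
    if pos_min < DIRECT_MAX:
        mode = "direct"
    elif WATER_MEDIATED_RANGE[0] <= pos_min <= WATER_MEDIATED_RANGE[1]:
        mode = "water-mediated"
    else:
        mode = "none"
    last_min_pos = max(m[0] for m in minima)
    beyond = s > last_min_pos
    small = np.abs(w) <= zero_tol
    crossing = None
    idx_beyond = np.flatnonzero(beyond)
    for k in idx_beyond:
        if small[k:].all():
            crossing = float(s[k])
            break
    if crossing is None:
        hits = idx_beyond[small[idx_beyond]] if idx_beyond.size else []
        crossing = float(s[hits[0]]) if len(hits) else float(s[-1])
    delta = crossing - rc
    if delta <= 0:
        return BindingRegion(rc=rc, delta=None, mode="none", minima=minima)
    return BindingRegion(rc=rc, delta=delta, mode=mode, minima=minima)


def adsorption_free_energy(
    pmf: PMFCurve, region: BindingRegion | None = None, zero_tol: float = ZERO_TOL
) -> AdsorptionResult:
    """Layer-averaged Boltzmann integral of the PMF over the bound region.

    Trapezoidal quadrature on the stored grid (with linearly interpolated
    endpoints when the layer edges fall between nodes). An undefined region
    (no binding) yields dG = 0 with mode "none" rather than an error.
    """
    if region is None:
        region = find_binding_region(pmf, zero_tol=zero_tol)
    if region.mode == "none" or region.delta is None:
        return AdsorptionResult(
            dg=0.0, region=region, temperature=pmf.temperature
        )
    kbt = KB * pmf.temperature
    lo, hi = region.rc, region.rc + region.delta
    d = pmf.defined()
    s, w = pmf.s[d], pmf.w[d]
    inside = (s > lo) & (s < hi)
    s_grid = np.concatenate(([lo], s[inside], [hi]))
    w_grid = np.concatenate(([np.interp(lo, s, w)], w[inside], [np.interp(hi, s, w)]))
    boltz = np.exp(-w_grid / kbt)
    integral = np.trapezoid(boltz, s_grid)
    dg = -kbt * np.log(integral / region.delta)
    return AdsorptionResult(dg=float(dg), region=region, temperature=pmf.temperature)


def standard_state_shift(
    result: AdsorptionResult, c: float, c_st: float, temperature: float | None = None
) -> AdsorptionResult:
    """Shift the excess free energy to a reference concentration:
    dG' = dG + kB T ln(c / c_st)."""
    if c <= 0 or c_st <= 0:
        raise ValueError("concentrations must be positive")
    t = result.temperature if temperature is None else temperature
    shift = KB * t * np.log(c / c_st)
    tag = "excess" if abs(shift) < 1e-15 and result.standard_state == "excess" else (
        f"referenced c={c:g} M, c_st={c_st:g} M"
    )
    return replace(result, dg=result.dg + float(shift), standard_state=tag)


def block_error(
    times: np.ndarray,
    samples: np.ndarray,
    block_length: float,
    estimator=np.mean,
) -> float:
    """Block-averaging standard error of ``estimator`` over a correlated
    time series.

    The series is cut into contiguous blocks of ``block_length`` (same time
    units as ``times``); the trailing partial block is discarded; the error
    is the sample standard deviation of the block estimates divided by
    sqrt(n_blocks).
    """
    times = np.asarray(times, dtype=float)
    samples = np.asarray(samples)
    if block_length <= 0:
        raise ValueError("block_length must be positive")
    t0 = times[0]
    idx = np.floor((times - t0) / block_length).astype(int)
    n_complete = int((times[-1] - t0) // block_length)
    if n_complete < 2:
        raise ValueError("fewer than 2 complete blocks: insufficient data")
    estimates = np.array(
        [estimator(samples[idx == b]) for b in range(n_complete)]
    )
    return float(np.std(estimates, ddof=1) / np.sqrt(n_complete))


def save_pmf(pmf: PMFCurve, path, result: AdsorptionResult | None = None) -> None:
    """TSV with a metadata header."""
    with open(path, "w") as fh:
        fh.write(f"# temperature_K\t{pmf.temperature:.6g}\n")
        fh.write(f"# convention\t{pmf.convention}\n")
        if result is not None:
            r = result.region
            fh.write(f"# rc_nm\t{r.rc:.6g}\n")
            fh.write(f"# delta_nm\t{r.delta if r.delta is None else round(r.delta, 9)}\n")
            fh.write(f"# mode\t{r.mode}\n")
            fh.write(f"# dG_kJ_mol\t{result.dg:.6g}\n")
            fh.write(f"# error_kJ_mol\t{result.error:.6g}\n")
            fh.write(f"# standard_state\t{result.standard_state}\n")
        fh.write("s_nm\tW_kJ_mol\n")
        for si, wi in zip(pmf.s, pmf.w):
            fh.write(f"{si:.8f}\t{wi:.8f}\n")


def load_pmf(path) -> PMFCurve:
    temperature, convention = 300.0, "bulk-zero"
    s, w = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                parts = line[1:].split()
                if parts[0] == "temperature_K":
                    temperature = float(parts[1])
                elif parts[0] == "convention":
                    convention = parts[1]
                continue
            if line.startswith("s_nm"):
                continue
            a, b = line.split()
            s.append(float(a))
            w.append(float(b))
    return PMFCurve(s=np.array(s), w=np.array(w), temperature=temperature,
                    convention=convention)


def save_result(result: AdsorptionResult, path) -> None:
    r = result.region
    with open(path, "w") as fh:
        fh.write("quantity\tvalue\n")
        fh.write(f"dG_kJ_mol\t{result.dg:.6g}\n")
        fh.write(f"error_kJ_mol\t{result.error:.6g}\n")
        fh.write(f"rc_nm\t{r.rc:.6g}\n")
        fh.write(f"delta_nm\t{'' if r.delta is None else f'{r.delta:.6g}'}\n")
        fh.write(f"mode\t{r.mode}\n")
        fh.write(f"standard_state\t{result.standard_state}\n")
        fh.write(f"temperature_K\t{result.temperature:.6g}\n")
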
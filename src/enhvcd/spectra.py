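"""Band broadening, frequency scaling, spectrum I/O and similarity scoring.

Stick strengths become solution-phase spectra as sums of unit-area Lorentzian
bands at the (scaled) mode frequencies, weighted by the conventional
frequency-dependent prefactors (see :mod:`enhvcd.constants`):

    eps(nu)   = nu * sum_i D_i L(nu; nu_i, gamma) * c_IR     [L mol^-1 cm^-1]
    d_eps(nu) = nu * sum_i R_i L(nu; nu_i, gamma) * c_VCD

Agreement between two spectra is scored with the max-normalised overlap

    S(f, g) = int f g / max(int f^2, int g^2)  in [-1, 1],

which penalises magnitude mismatch (S(f, 2f) = 1/2) and is antisymmetric under
negation of one argument — the property the absolute-configuration protocol
relies on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .constants import IR_EPS_PREFACTOR, VCD_EPS_PREFACTOR
from .core import ModeStrengths, NormalModes, _as_array

__all__ = [
    "Spectrum",
    "DEFAULT_HALFWIDTH_CM",
    "DEFAULT_WINDOW_CM",
    "scoring_grid",
    "broaden",
    "apply_scale",
    "similarity",
    "read_spectrum_csv",
    "write_spectrum_csv",
]

log = logging.getLogger(__name__)

#: default Lorentzian half-width at half maximum (cm^-1)
DEFAULT_HALFWIDTH_CM = 6.0
#: default fingerprint scoring window (cm^-1)
DEFAULT_WINDOW_CM = (1000.0, 1600.0)


@dataclass(frozen=True)
class Spectrum:
    """A spectrum on a strictly increasing wavenumber grid.

    ``values`` are delta-epsilon (L mol^-1 cm^-1) for VCD, epsilon for IR, or
    arbitrary units for digitized references; ``kind`` is ``"vcd"`` or
    ``"ir"``; ``meta`` carries free-form provenance (source, scaling, window).
    """

    grid: np.ndarray
    values: np.ndarray
    kind: str = "vcd"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        g = _as_array(self.grid, name="grid")
        v = _as_array(self.values, g.shape, "values")
        if g.ndim != 1 or g.size < 2:
            raise ValueError("grid must be 1-D with at least two points")
        if np.any(np.diff(g) <= 0):
            raise ValueError("grid must be strictly increasing")
        if self.kind not in ("vcd", "ir"):
            raise ValueError(f"unknown spectrum kind {self.kind!r}")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "values", v)

    def negate(self) -> "Spectrum":
        """Sign-inverted copy (the enantiomer's spectrum, for VCD)."""
        meta = dict(self.meta)
        meta["negated"] = not meta.get("negated", False)
        return replace(self, values=-self.values, meta=meta)


def scoring_grid(
    modes: NormalModes,
    window: tuple[float, float] = DEFAULT_WINDOW_CM,
    halfwidth: float = DEFAULT_HALFWIDTH_CM,
    step: float = 1.0,
) -> np.ndarray:
    """Wavenumber grid covering both the scoring window and all bands.

    Spans from ten halfwidths below the lowest mode (or the window edge,
    whichever is lower) to ten halfwidths above the highest mode (or the
    upper window edge), in ``step`` cm^-1 increments.
    """
    lo = max(min(float(modes.frequencies.min()) - 10 * halfwidth, window[0]), 1.0)
    hi = max(float(modes.frequencies.max()) + 10 * halfwidth, window[1])
    lo, hi = np.floor(lo), np.ceil(hi)   # snap so the window edges are covered
    return np.arange(lo, hi + step / 2, step)


def broaden(
    strengths: ModeStrengths,
    modes: NormalModes,
    halfwidth: float = DEFAULT_HALFWIDTH_CM,
    grid: np.ndarray | None = None,
    kind: str = "vcd",
) -> Spectrum:
    """Lorentzian-broadened spectrum from per-mode strengths.

    ``halfwidth`` is the HWHM gamma in cm^-1; each band has unit area so the
    integrated intensity of a band reproduces the conventional strength
    relation. ``grid`` defaults to :func:`scoring_grid` — 1 cm^-1 steps
    spanning the modes plus margin and the default scoring window. Mode
    positions are taken from ``modes.frequencies`` (already scaled, see
    :func:`apply_scale`).
    """
    if halfwidth <= 0:
        raise ValueError("halfwidth must be positive")
    nu_modes = modes.frequencies
    if grid is None:
        grid = scoring_grid(modes, halfwidth=halfwidth)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")

    if kind == "vcd":
        weights = strengths.rotational_cgs() * VCD_EPS_PREFACTOR
    elif kind == "ir":
        weights = strengths.dipole_cgs() * IR_EPS_PREFACTOR
    else:
        raise ValueError(f"unknown spectrum kind {kind!r}")

    lorentz = (halfwidth / np.pi) / (
        (grid[:, None] - nu_modes[None, :]) ** 2 + halfwidth**2
    )
    values = grid * (lorentz @ weights)
    return Spectrum(
        grid=grid,
        values=values,
        kind=kind,
        meta={"halfwidth_cm": halfwidth, "source": "computed"},
    )


def apply_scale(modes: NormalModes, factor: float) -> NormalModes:
    """Multiply all mode frequencies by one global scaling factor.

    A single factor, fixed from the IR spectrum, is the only frequency
    calibration applied; the accepted range (0.5, 1.5) rejects obvious
    unit errors.
    """
    if not (0.5 < factor < 1.5):
        raise ValueError(f"scale factor {factor} outside the accepted (0.5, 1.5)")
    return replace(
        modes,
        frequencies=modes.frequencies * factor,
        scale_factor=modes.scale_factor * factor,
    )


def _resample(spec: Spectrum, grid: np.ndarray) -> np.ndarray:
    if grid[0] < spec.grid[0] - 1e-9 or grid[-1] > spec.grid[-1] + 1e-9:
        raise ValueError(
            f"window [{grid[0]:.1f}, {grid[-1]:.1f}] cm^-1 not covered by "
            f"spectrum grid [{spec.grid[0]:.1f}, {spec.grid[-1]:.1f}]"
        )
    return np.interp(grid, spec.grid, spec.values)


def similarity(
    a: Spectrum,
    b: Spectrum,
    window: tuple[float, float] = DEFAULT_WINDOW_CM,
    grid_step: float = 1.0,
) -> float:
    """Max-normalised overlap score in [-1, 1] over ``window``.

    Both spectra are linearly resampled to a common ``grid_step`` grid;
    integrals are trapezoidal. Symmetric in its arguments; equals 1 iff the
    two spectra coincide on the window, -1 for an exact sign inversion, and
    1/2 when one is twice the other.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must be a non-empty interval")
    grid = np.arange(lo, hi + grid_step / 2, grid_step)
    f = _resample(a, grid)
    g = _resample(b, grid)
    overlap = np.trapezoid(f * g, grid)
    nf = np.trapezoid(f * f, grid)
    ng = np.trapezoid(g * g, grid)
    denom = max(nf, ng)
    if denom == 0.0:
        return 1.0  # both identically zero on the window: equal
    return float(overlap / denom)


def read_spectrum_csv(path, kind: str = "vcd") -> Spectrum:
    """Read a two-column (wavenumber, intensity) CSV.

    One optional header line is allowed and preserved in ``meta["header"]``.
    Files with a descending wavenumber grid are reversed (with a log notice).
    Non-numeric data rows raise a parse error naming the line number.
    """
    header = None
    grid, values = [], []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = [p for p in line.replace(";", ",").split(",") if p.strip()]
            try:
                nums = [float(p) for p in parts]
            except ValueError:
                if lineno == 1 and header is None:
                    header = line
                    continue
                raise ValueError(
                    f"{path}: line {lineno}: non-numeric row {line!r}"
                ) from None
            if len(nums) < 2:
                raise ValueError(f"{path}: line {lineno}: expected two columns")
            grid.append(nums[0])
            values.append(nums[1])
    if not grid:
        raise ValueError(f"{path}: no data rows")
    g = np.array(grid)
    v = np.array(values)
    meta = {"source": str(path)}
    if header is not None:
        meta["header"] = header
    if g.size > 1 and g[0] > g[-1]:
        log.info("reversing descending wavenumber grid in %s", path)
        g, v = g[::-1], v[::-1]
    return Spectrum(grid=g, values=v, kind=kind, meta=meta)


def write_spectrum_csv(spectrum: Spectrum, path) -> None:
    """Write a spectrum as two-column CSV (full float precision)."""
    header = spectrum.meta.get("header", "wavenumber,intensity")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(header + "\n")
        for x, y in zip(spectrum.grid, spectrum.values):
            fh.write(f"{float(x)!r},{float(y)!r}\n")
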
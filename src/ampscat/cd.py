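"""Circular-dichroism secondary-structure decomposition.

A measured far-UV CD trace, converted to mean residue ellipticity (MRE),
is modelled as a convex combination of four reference motif spectra
(alpha-helix, beta-sheet, beta-turn, random coil):

    MRE(lambda) = sum_i f_i * B_i(lambda),   f_i >= 0,  sum_i f_i = 1.

The constrained least-squares problem is solved by non-negative least
squares on a system augmented with a heavily weighted sum-to-one row,
which is deterministic and needs no tuning.  Per-motif uncertainties are
estimated by a small number of refits on residual-scale perturbed data,
mirroring the practice of quoting the spread of 3-4 repeated fits.

The bundled basis (``data/cd_motif_basis_synthetic.csv``) is a synthetic
stand-in built from Gaussian bands with the canonical motif shapes;
decompositions of real spectra are basis-dependent and users should
supply a measured reference basis for quantitative work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .descriptors import mre_from_ellipticity

__all__ = ["CDSpectrum", "BasisSet", "MotifFractions", "CDShapeModel",
           "resample_to_grid", "subtract_reference"]

MOTIFS = ("helix", "sheet", "turn", "coil")


@dataclass
class CDSpectrum:
    """A CD trace on a strictly increasing wavelength grid (nm) in MRE units."""

    wavelength_nm: np.ndarray
    mre: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        self.mre = np.asarray(self.mre, dtype=float)
        if self.wavelength_nm.shape != self.mre.shape:
            raise ValueError("wavelength and MRE grids differ in length")
        if np.any(np.diff(self.wavelength_nm) <= 0):
            raise ValueError("wavelengths must be strictly increasing")

    @classmethod
    def from_ellipticity(cls, wavelength_nm, epsilon, n_residues: int, meta=None):
        """Build from raw instrument ellipticity via the MRE conversion."""
        return cls(wavelength_nm, mre_from_ellipticity(epsilon, n_residues),
                   meta=dict(meta or {}))

    @classmethod
    def from_text(cls, path, units: str = "mre", n_residues: int | None = None, meta=None):
        """Two-column whitespace/CSV text (nm, ellipticity).

        ``units='mdeg'`` converts through MRE using *n_residues*.
        """
        arr = np.loadtxt(path, delimiter=None, comments="#", ndmin=2)
        if arr.shape[1] < 2:
            arr = np.loadtxt(path, delimiter=",", comments="#", ndmin=2)
        lam, y = arr[:, 0], arr[:, 1]
        order = np.argsort(lam)
        lam, y = lam[order], y[order]
        if units == "mdeg":
            if n_residues is None:
                raise ValueError("n_residues required for mdeg input")
            return cls.from_ellipticity(lam, y, n_residues, meta)
        return cls(lam, y, meta=dict(meta or {}))


def resample_to_grid(spectrum: CDSpectrum, grid) -> CDSpectrum:
    """Linear interpolation of a spectrum onto *grid* (no extrapolation)."""
    grid = np.asarray(grid, dtype=float)
    lam = spectrum.wavelength_nm
    if grid.min() < lam.min() - 1e-9 or grid.max() > lam.max() + 1e-9:
        raise ValueError("target grid extends beyond the source wavelength range")
    return CDSpectrum(grid, np.interp(grid, lam, spectrum.mre), meta=dict(spectrum.meta))


def subtract_reference(spectrum: CDSpectrum, reference: CDSpectrum,
                       scale: float) -> CDSpectrum:
    """Pointwise ``mre - scale * reference_mre`` on a common grid.

    Used to remove the tryptophan side-chain contribution before motif
    fitting; a natural default scale is n_W / N (tryptophan fraction).
    """
    if not np.allclose(spectrum.wavelength_nm, reference.wavelength_nm):
        raise ValueError("grids differ; resample first")
    return CDSpectrum(spectrum.wavelength_nm,
                      spectrum.mre - scale * reference.mre,
                      meta=dict(spectrum.meta))


@dataclass
class BasisSet:
    """Four reference motif spectra on a common wavelength grid."""

    wavelength_nm: np.ndarray
    spectra: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.wavelength_nm = np.asarray(self.wavelength_nm, dtype=float)
        missing = set(MOTIFS) - set(self.spectra)
        if missing:
            raise ValueError(f"basis is missing motifs: {sorted(missing)}")
        self.spectra = {k: np.asarray(v, dtype=float) for k, v in self.spectra.items()}
        for k, v in self.spectra.items():
            if v.shape != self.wavelength_nm.shape:
                raise ValueError(f"basis trace {k!r} not on the common grid")

    @classmethod
    def bundled(cls) -> "BasisSet":
        """The synthetic Gaussian-band motif basis shipped with the package."""
        with resources.files("ampscat.data").joinpath(
                "cd_motif_basis_synthetic.csv").open() as fh:
            tab = pd.read_csv(fh, comment="#")
        return cls(tab["wavelength_nm"].to_numpy(),
                   {m: tab[m].to_numpy() for m in MOTIFS})

    @classmethod
    def from_csv(cls, path) -> "BasisSet":
        tab = pd.read_csv(path, comment="#")
        return cls(tab["wavelength_nm"].to_numpy(),
                   {m: tab[m].to_numpy() for m in MOTIFS})

    def matrix(self) -> np.ndarray:
        return np.column_stack([self.spectra[m] for m in MOTIFS])


@dataclass
class MotifFractions:
    """Result of a four-motif decomposition."""

    fractions: dict[str, float]
    residual_rms: float
    fraction_sd: dict[str, float]
    degenerate: bool = False

    @property
    def f_helix(self): return self.fractions["helix"]
    @property
    def f_sheet(self): return self.fractions["sheet"]
    @property
    def f_turn(self): return self.fractions["turn"]
    @property
    def f_coil(self): return self.fractions["coil"]

    def as_series(self) -> pd.Series:
        return pd.Series(self.fractions)

    def summary(self) -> str:
        lines = ["Four-motif CD decomposition",
                 "-" * 33,
                 f"{'motif':<8}{'fraction':>10}{'sd':>10}"]
        for m in MOTIFS:
            lines.append(f"{m:<8}{self.fractions[m]:>10.4f}{self.fraction_sd[m]:>10.4f}")
        lines.append(f"residual rms: {self.residual_rms:.4g}")
        if self.degenerate:
            lines.append("WARNING: rank-deficient basis; fractions are degenerate")
        return "\n".join(lines)


def _nnls_simplex(B: np.ndarray, y: np.ndarray) -> np.ndarray:
    # augmented sum-to-one row, weighted far above the data scale
    w = 1e6 * max(np.abs(B).max(), 1.0)
    A = np.vstack([B, w * np.ones(B.shape[1])])
    b = np.concatenate([y, [w]])
    f, _ = nnls(A, b)
    return f / f.sum()


class CDShapeModel:
    """Constrained least-squares fit of a CD spectrum to a motif basis.

    Parameters
    ----------
    spectrum : CDSpectrum
        Trace in MRE units, tryptophan-subtracted if appropriate.
    basis : BasisSet, optional
        Defaults to the bundled synthetic basis resampled to the spectrum
        grid (the spectrum grid must lie inside the basis grid).
    """

    def __init__(self, spectrum: CDSpectrum, basis: BasisSet | None = None):
        if basis is None:
            basis = BasisSet.bundled()
        if not np.allclose(spectrum.wavelength_nm, basis.wavelength_nm):
            resampled = {m: np.interp(spectrum.wavelength_nm, basis.wavelength_nm,
                                      basis.spectra[m]) for m in MOTIFS}
            lo, hi = basis.wavelength_nm.min(), basis.wavelength_nm.max()
            if spectrum.wavelength_nm.min() < lo - 1e-9 or spectrum.wavelength_nm.max() > hi + 1e-9:
                raise ValueError("spectrum grid extends beyond basis grid")
            basis = BasisSet(spectrum.wavelength_nm, resampled)
        if spectrum.wavelength_nm.size < 4:
            raise ValueError("need at least 4 wavelength points")
        self.spectrum = spectrum
        self.basis = basis

    def fit(self, n_refits: int = 4, seed: int = 0) -> MotifFractions:
        """Solve for the motif fractions.

        ``n_refits`` seeded refits on residual-scale perturbed copies of the
        data provide the per-motif standard deviation.
        """
        B = self.basis.matrix()
        y = self.spectrum.mre
        degenerate = np.linalg.matrix_rank(B, tol=1e-8 * np.abs(B).max()) < B.shape[1]
        f = _nnls_simplex(B, y)
        resid = y - B @ f
        rms = float(np.sqrt(np.mean(resid**2)))
        rng = np.random.default_rng(seed)
        reps = np.array([_nnls_simplex(B, y + rng.normal(0.0, rms, size=y.shape))
                         for _ in range(max(n_refits, 2))])
        sd = reps.std(axis=0, ddof=1)
        return MotifFractions(
            fractions={m: float(f[i]) for i, m in enumerate(MOTIFS)},
            residual_rms=rms,
            fraction_sd={m: float(sd[i]) for i, m in enumerate(MOTIFS)},
            degenerate=bool(degenerate),
        )


def decompose(spectrum: CDSpectrum, basis: BasisSet | None = None,
              **fit_kw) -> MotifFractions:
    """Convenience wrapper: ``CDShapeModel(spectrum, basis).fit()``."""
    return CDShapeModel(spectrum, basis).fit(**fit_kw)
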
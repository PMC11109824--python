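"""Smectic liquid-crystal model of diffuse low-angle scattering from
oriented bilayer stacks, and fitting of the bending modulus K_C and
interbilayer compression modulus B.

Model
-----
A stack of ``N`` bilayers with vertical displacements ``u_n(r)`` carries
the discrete smectic free energy

    F = (1/2) sum_n  integral d^2r [ K_C (lap u_n)^2 + B (u_{n+1} - u_n)^2 ]

with periodic boundary conditions in the layer index.  Working in reduced
units (energies in k_B T, lengths in Angstrom), equipartition gives the
mean-square amplitude of the Fourier mode with in-plane wavevector q_r
and discrete layer mode m:

    <|u(q_r, m)|^2> = 1 / [ A (K_C q_r^4 + 2 B (1 - cos(2 pi m / N))) ]

where ``A`` is the in-plane area normalisation.  Height-difference
correlations ``delta_k(r) = <(u_n(r) - u_{n+k}(0))^2>`` follow by a mode
sum and a Hankel-type quadrature over q_r with finite-size cutoffs set by
the lateral domain size ``L_r``.  The diffuse structure factor is

    S(q_z, q_r) = sum_k (N - |k|) cos(q_z k D) H_k(q_z, q_r),
    H_k = (2 / L_r^2) int_0^{L_r} r J0(q_r r) exp(-q_z^2 delta_k(r)/2) dr,

normalised so a frozen stack (delta == 0) at q_r = 0 reproduces the ideal
finite-lattice interference function (S = N^2 at the Bragg condition).
Membrane fluctuations smear the Bragg peaks into lobes whose intensity
fall-off along q_r encodes K_C: a higher fitted K_C means a stiffer
membrane.  The observed intensity is modelled as

    I = scale * S(q) * |F(q_z)|^2 / q_z

with the 1/q_z Lorentz factor appropriate for oriented flat samples and
an optional Gaussian instrumental resolution along q_r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import least_squares
from scipy.special import j0

__all__ = [
    "KB_T_310_JOULE",
    "StackModel",
    "DiffusePattern",
    "ElasticityFit",
    "CailleElasticityModel",
    "mode_spectrum",
    "height_correlation",
    "structure_factor",
    "predict_pattern",
    "fit_elasticity",
    "symmetrize_and_subtract",
]

#: k_B * 310.15 K in joule; used to report K_C in SI units (paper T = 37 C).
KB_T_310_JOULE = 1.380649e-23 * 310.15


@dataclass(frozen=True)
class StackModel:
    """Elastic parameters of a fluctuating bilayer stack.

    K_C is in units of k_B T, B in k_B T / A^4, lengths in Angstrom.
    ``N_layers`` is the effective vertical coherence, not the physical
    stack size (a desk-scale default of order 10-200 is typical).
    """

    K_C: float
    B: float
    N_layers: int
    L_r: float
    D: float
    T: float = 310.15

    def __post_init__(self) -> None:
        if min(self.K_C, self.B, self.L_r, self.D, self.T) <= 0:
            raise ValueError("all stack parameters must be positive")
        if int(self.N_layers) != self.N_layers or self.N_layers < 1:
            raise ValueError("N_layers must be an integer >= 1")

    @property
    def K_C_joule(self) -> float:
        """Bending modulus in joule at the model temperature."""
        return self.K_C * 1.380649e-23 * self.T


@dataclass
class DiffusePattern:
    """Background-subtracted diffuse intensity on a (q_z, q_r) grid."""

    q_r: np.ndarray
    q_z: np.ndarray
    intensity: np.ndarray  # shape (len(q_z), len(q_r))
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q_r = np.asarray(self.q_r, dtype=float)
        self.q_z = np.asarray(self.q_z, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != (self.q_z.size, self.q_r.size):
            raise ValueError("intensity shape must be (len(q_z), len(q_r))")
        if np.any(np.diff(self.q_z) <= 0):
            raise ValueError("q_z grid must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.intensity.shape:
                raise ValueError("sigma shape mismatch")


def mode_spectrum(model: StackModel, q_r, mode_index: int, area: float | None = None):
    """Equipartition mean-square amplitude (A^2) of one discrete smectic mode.

    ``area`` is the in-plane normalisation A (defaults to L_r^2).  The
    combination q_r = 0 with mode 0 is the unnormalisable Goldstone mode
    (uniform translation, zero restoring force) and is rejected.
    """
    if not 0 <= mode_index < model.N_layers:
        raise ValueError("mode_index out of range")
    q_r = np.asarray(q_r, dtype=float)
    if mode_index == 0 and np.any(q_r == 0):
        raise ValueError("q_r = 0 with mode 0 is a zero-energy Goldstone mode")
    if area is None:
        area = model.L_r**2
    restoring = model.K_C * q_r**4 + 2.0 * model.B * (
        1.0 - np.cos(2.0 * np.pi * mode_index / model.N_layers))
    return 1.0 / (area * restoring)


def _q_grid(model: StackModel, n_q: int) -> tuple[np.ndarray, np.ndarray]:
    """Log-spaced q_r quadrature grid with trapezoid weights and finite-size
    cutoffs q_min = pi/L_r, q_max = 2 pi / 5 A (molecular cutoff)."""
    q = np.geomspace(np.pi / model.L_r, 2.0 * np.pi / 5.0, n_q)
    w = np.zeros_like(q)
    w[1:-1] = 0.5 * (q[2:] - q[:-2])
    w[0] = 0.5 * (q[1] - q[0])
    w[-1] = 0.5 * (q[-1] - q[-2])
    return q, w


def _delta_matrix(model: StackModel, r: np.ndarray, n_q: int = 256) -> np.ndarray:
    """delta_k(r) for k = 0..N-1 on the given r grid; shape (N, len(r))."""
    N = model.N_layers
    q, w = _q_grid(model, n_q)
    m = np.arange(N)
    den = model.K_C * q[None, :]**4 + 2.0 * model.B * (
        1.0 - np.cos(2.0 * np.pi * m[:, None] / N))  # (N, n_q)
    kern = (w * q / (2.0 * np.pi)) / den              # (N, n_q)
    J = j0(np.outer(r, q))                            # (n_r, n_q)
    G = kern @ J.T                                    # (N, n_r): G_m(r)
    G0 = kern.sum(axis=1)                             # G_m(0)
    k = np.arange(N)
    cos_mk = np.cos(2.0 * np.pi * np.outer(k, m) / N)  # (N_k, N_m)
    C = (cos_mk @ G) / N                              # C_k(r)
    C00 = G0.sum() / N
    delta = 2.0 * (C00 - C)
    return np.maximum(delta, 0.0)


def height_correlation(model: StackModel, k: int, r, n_q: int = 256,
                       rtol: float = 1e-3) -> np.ndarray:
    """Mean-square height difference delta_k(r) = <(u_n(r) - u_{n+k}(0))^2>.

    The q_r quadrature grid is doubled until the result is stable to
    ``rtol`` (relative, at the largest value); non-convergence raises with
    the achieved tolerance in the message.
    """
    if not 0 <= k < model.N_layers:
        raise ValueError("layer offset k out of range")
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if np.any(r < 0):
        raise ValueError("r must be >= 0")
    prev = _delta_matrix(model, r, n_q)[k]
    for _ in range(4):
        n_q *= 2
        cur = _delta_matrix(model, r, n_q)[k]
        # absolute floor of 1e-6 A^2 keeps the k=0, r=0 null case convergent
        scale = max(cur.max(), 1e-6)
        err = np.max(np.abs(cur - prev)) / scale
        if err < rtol:
            return cur
        prev = cur
    raise RuntimeError(f"height_correlation quadrature did not converge: "
                       f"relative change {err:.2e} > rtol {rtol:.0e} at n_q={n_q}")


def _r_grid(model: StackModel, n_r: int = 800) -> tuple[np.ndarray, np.ndarray]:
    """Linear r quadrature nodes on [0, L_r] with trapezoid weights.

    The spacing must resolve the J0(q_r r) oscillation at the largest
    lateral q of interest; the default gives L_r/800 ~ 3 A for typical
    domain sizes, adequate for q_r up to ~0.3 A^-1.
    """
    r = np.linspace(0.0, model.L_r, n_r)
    w = np.full_like(r, r[1] - r[0])
    w[0] = w[-1] = 0.5 * (r[1] - r[0])
    return r, w


def structure_factor(model: StackModel, q_z, q_r, n_r: int = 800,
                     n_q: int = 256, delta: np.ndarray | None = None,
                     r_nodes: tuple[np.ndarray, np.ndarray] | None = None):
    """Diffuse structure factor S(q_z, q_r) of the fluctuating stack.

    Vectorised over both grids; returns shape (len(q_z), len(q_r)).
    ``delta``/``r_nodes`` allow reuse of precomputed correlation tables.
    """
    q_z = np.atleast_1d(np.asarray(q_z, dtype=float))
    q_r = np.atleast_1d(np.asarray(q_r, dtype=float))
    N = model.N_layers
    if r_nodes is None:
        r_nodes = _r_grid(model, n_r)
    r, wr = r_nodes
    if delta is None:
        delta = _delta_matrix(model, r, n_q)       # (N, n_r)
    k = np.arange(N)
    wk = (N - k) * np.where(k == 0, 1.0, 2.0)      # (N,): +-k folded
    Jr = j0(np.outer(q_r, r)) * (wr * r) * (2.0 / model.L_r**2)  # (n_qr, n_r)
    out = np.empty((q_z.size, q_r.size))
    for i, qz in enumerate(q_z):
        damp = np.exp(-0.5 * qz**2 * delta)        # (N, n_r)
        H = Jr @ damp.T                            # (n_qr, N)
        phase = wk * np.cos(qz * k * model.D)      # (N,)
        out[i] = H @ phase
    return out


def predict_pattern(model: StackModel, formfactor, q_z, q_r, scale: float = 1.0,
                    sigma_res: float = 0.0, qz_cutoff: float = 0.02,
                    **sf_kw) -> DiffusePattern:
    """Forward-model a diffuse pattern: scale * S(q) |F(q_z)|^2 / q_z.

    ``formfactor`` is a callable of q_z (or an array on the q_z grid).
    The flat-sample Lorentz factor 1/q_z is applied; pixels with
    q_z < ``qz_cutoff`` are masked to NaN (beam/specular region).  A
    Gaussian instrumental resolution of width ``sigma_res`` (A^-1) may be
    applied along q_r.
    """
    q_z = np.atleast_1d(np.asarray(q_z, dtype=float))
    q_r = np.atleast_1d(np.asarray(q_r, dtype=float))
    F = formfactor(q_z) if callable(formfactor) else np.asarray(formfactor, dtype=float)
    S = structure_factor(model, q_z, q_r, **sf_kw)
    I = scale * S * (np.abs(F)**2 / np.where(q_z > 0, q_z, np.inf))[:, None]
    if sigma_res > 0:
        dq = np.median(np.diff(q_r))
        I = gaussian_filter1d(I, sigma_res / dq, axis=1, mode="nearest")
    I[q_z < qz_cutoff, :] = np.nan
    return DiffusePattern(q_r=q_r, q_z=q_z, intensity=I)


def symmetrize_and_subtract(image_pos: np.ndarray, image_background: np.ndarray,
                            q_r: np.ndarray, q_z: np.ndarray) -> DiffusePattern:
    """Background subtraction followed by lateral symmetrisation about q_r=0.

    The q_r axis must be sign-symmetric (each +q_r column has a matching
    -q_r column) so the mirror average is exact.
    """
    image_pos = np.asarray(image_pos, dtype=float)
    image_background = np.asarray(image_background, dtype=float)
    if image_pos.shape != image_background.shape:
        raise ValueError("image shapes differ")
    q_r = np.asarray(q_r, dtype=float)
    if not np.allclose(np.sort(q_r), np.sort(-q_r), atol=1e-12):
        raise ValueError("q_r axis is not symmetric about 0")
    net = image_pos - image_background
    order = np.argsort(q_r)
    qs = q_r[order]
    sub = net[:, order]
    sym = 0.5 * (sub + sub[:, ::-1])
    return DiffusePattern(q_r=qs, q_z=np.asarray(q_z, dtype=float), intensity=sym)


@dataclass
class ElasticityFit:
    """Fitted elastic moduli with multiplicative 1-sigma confidence bounds."""

    K_C_hat: float
    B_hat: float
    scale: float
    K_C_ci: tuple[float, float]
    B_ci: tuple[float, float]
    chi2_reduced: float
    status: str = "ok"
    model: StackModel | None = None

    @property
    def K_C_joule(self) -> float:
        T = self.model.T if self.model is not None else 310.15
        return self.K_C_hat * 1.380649e-23 * T

    def summary(self) -> str:
        lines = [
            "Smectic elasticity fit (diffuse lobe fall-off)",
            "-" * 46,
            f"K_C  = {self.K_C_hat:10.4g} k_BT   68% CI [{self.K_C_ci[0]:.4g}, {self.K_C_ci[1]:.4g}]",
            f"     = {self.K_C_joule * 1e21:10.4g} x 1e-21 J",
            f"B    = {self.B_hat:10.4g} k_BT/A^4 68% CI [{self.B_ci[0]:.4g}, {self.B_ci[1]:.4g}]",
            f"scale= {self.scale:10.4g}",
            f"reduced chi^2 = {self.chi2_reduced:.4g}",
            f"status: {self.status}",
        ]
        return "\n".join(lines)


class CailleElasticityModel:
    """Weighted non-linear least squares for (K_C, B, scale).

    Parameters
    ----------
    pattern : DiffusePattern
        Background-subtracted, symmetrised data.
    formfactor : callable or array
        |F(q_z)| over the pattern's q_z grid.
    init : StackModel
        Starting point; N_layers, L_r, D are held fixed at these values.
    fit_window : list of (qz_lo, qz_hi, qr_lo, qr_hi)
        Regions entering the fit; must exclude the beam/specular band.
    """

    _LOG_BOUND = 12.0  # |log10(param/init)| bound; hitting it flags the fit

    def __init__(self, pattern: DiffusePattern, formfactor, init: StackModel,
                 fit_window, n_r: int = 800, n_q: int = 256):
        self.pattern = pattern
        self.init = init
        self.n_r, self.n_q = n_r, n_q
        q_z, q_r = pattern.q_z, pattern.q_r
        F = formfactor(q_z) if callable(formfactor) else np.asarray(formfactor, dtype=float)
        self._F2_over_qz = np.abs(F)**2 / np.where(q_z > 0, q_z, np.inf)
        mask = np.zeros(pattern.intensity.shape, dtype=bool)
        for (zlo, zhi, rlo, rhi) in fit_window:
            mask |= ((q_z[:, None] >= zlo) & (q_z[:, None] <= zhi)
                     & (q_r[None, :] >= rlo) & (q_r[None, :] <= rhi))
        mask &= np.isfinite(pattern.intensity)
        if not mask.any():
            raise ValueError("fit window selects no valid pixels")
        self.mask = mask
        self._y = pattern.intensity[mask]
        if pattern.sigma is not None:
            self._sig = pattern.sigma[mask]
        else:
            self._sig = np.sqrt(np.maximum(np.abs(self._y), 1.0))
        # guard against vanishing uncertainties dominating the fit
        self._sig = np.maximum(self._sig, 1e-4 * np.abs(self._y).max())
        self._r_nodes = _r_grid(init, n_r)

    def _model_image(self, K_C: float, B: float) -> np.ndarray:
        m = replace(self.init, K_C=K_C, B=B)
        S = structure_factor(m, self.pattern.q_z, self.pattern.q_r,
                             n_q=self.n_q, r_nodes=self._r_nodes)
        return S * self._F2_over_qz[:, None]

    def _residual(self, theta: np.ndarray) -> np.ndarray:
        K_C, B, scale = 10.0**theta
        return (scale * self._model_image(K_C, B)[self.mask] - self._y) / self._sig

    def fit(self) -> ElasticityFit:
        x0 = np.log10([self.init.K_C, self.init.B, 1.0])
        # initial scale from a quick linear solve at the starting moduli
        m0 = self._model_image(self.init.K_C, self.init.B)[self.mask]
        w = 1.0 / self._sig**2
        s0 = max(np.sum(w * m0 * self._y) / np.sum(w * m0**2), 1e-30)
        x0[2] = np.log10(s0)
        lo, hi = x0 - self._LOG_BOUND, x0 + self._LOG_BOUND
        res = least_squares(self._residual, x0, bounds=(lo, hi),
                            xtol=1e-10, ftol=1e-10, gtol=1e-10)
        K_C, B, scale = 10.0**res.x
        dof = max(self._y.size - 3, 1)
        chi2r = float(2.0 * res.cost / dof)
        status = "ok" if res.success else "non-convergence"
        if np.any(res.x >= hi - 1e-6) or np.any(res.x <= lo + 1e-6):
            status = "parameter at bound"
        # covariance of log10-params from the Jacobian at the optimum
        J = res.jac
        try:
            cov = np.linalg.inv(J.T @ J) * chi2r
            se = np.minimum(np.sqrt(np.maximum(np.diag(cov), 0.0)), 300.0)
        except np.linalg.LinAlgError:
            se = np.full(3, np.nan)
            status = "singular covariance"
        ci = lambda i, v: (v / 10.0**se[i], v * 10.0**se[i])
        fitted = replace(self.init, K_C=K_C, B=B)
        return ElasticityFit(K_C_hat=K_C, B_hat=B, scale=scale,
                             K_C_ci=ci(0, K_C), B_ci=ci(1, B),
                             chi2_reduced=chi2r, status=status, model=fitted)


def fit_elasticity(pattern: DiffusePattern, formfactor, init: StackModel,
                   fit_window, **kw) -> ElasticityFit:
    """Convenience wrapper: ``CailleElasticityModel(...).fit()``."""
    return CailleElasticityModel(pattern, formfactor, init, fit_window, **kw).fit()
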
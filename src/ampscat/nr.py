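"""Specular neutron reflectometry of sparsely-tethered bilayers in
composition (volume-occupancy) space.

The interface is described by continuous volume-occupancy curves on a
common z grid along the surface normal: substrate oxide and gold film,
tether/SAM, inner and outer headgroups, hydrocarbon core, a free-form
peptide profile (monotone cubic Hermite spline with control points about
15 A apart), and bulk solvent filling the remainder.  Each component
carries a neutron scattering length density (SLD); only the solvent (and
the exchangeable-proton fraction of the peptide) changes between the
H2O and D2O isotopic contrasts, so the two reflectivity curves measured
on the same sample share every structural parameter.

Reflectivity is computed exactly by the Parratt/Abeles transfer-matrix
recursion through <= 2 A slabs with Nevot-Croce roughness factors, and
the two contrasts are fitted simultaneously with a seeded affine-
invariant ensemble MCMC sampler (emcee); parameter medians and 68%
credible intervals summarise the posterior, with a split-chain R-hat
mixing diagnostic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.special import erf

import emcee

__all__ = ["SLD_TABLE", "ReflectivityCurve", "CompositionProfile",
           "spline_occupancy", "TetheredBilayer", "parratt_reflectivity",
           "fresnel_reflectivity", "born_reflectivity",
           "ReflectometryModel", "PosteriorSummary"]

#: Neutron SLDs in 1e-6 A^-2; two-valued entries are (H2O, D2O) conditions.
#: Nominal literature values for Si, native oxide, Au, hydrogenated lipid
#: moieties, protein (with ~90% labile-H exchange in D2O) and the buffers.
SLD_TABLE: dict[str, tuple[float, float]] = {
    "silicon": (2.07, 2.07),
    "sio2": (3.47, 3.47),
    "gold": (4.50, 4.50),
    "tether": (-0.25, -0.25),
    "headgroup": (1.80, 1.80),
    "hydrocarbon": (-0.30, -0.30),
    "peptide": (1.90, 3.20),
    "water": (-0.56, 6.36),
}

_CONTRASTS = ("h2o", "d2o")


def _sld(name: str, contrast: str) -> float:
    return SLD_TABLE[name][_CONTRASTS.index(contrast)]


@dataclass
class ReflectivityCurve:
    """R(q_z) for one isotopic contrast."""

    q_z: np.ndarray
    R: np.ndarray
    sigma: np.ndarray
    contrast: str

    def __post_init__(self) -> None:
        self.q_z = np.asarray(self.q_z, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.contrast not in _CONTRASTS:
            raise ValueError("contrast must be 'h2o' or 'd2o'")
        if np.any(np.diff(self.q_z) <= 0):
            raise ValueError("q_z must be increasing")
        if np.any((self.R < 0) | (self.R > 1 + 1e-9)):
            raise ValueError("reflectivity must lie in [0, 1]")

    @classmethod
    def from_text(cls, path, contrast: str) -> "ReflectivityCurve":
        arr = np.loadtxt(path, comments="#", ndmin=2)
        return cls(arr[:, 0], arr[:, 1], arr[:, 2], contrast)


def spline_occupancy(control_z, control_values, z_grid) -> np.ndarray:
    """Monotone-safe cubic Hermite (PCHIP) occupancy from control points.

    Control values must be non-negative; spacings below 5 A are rejected
    as over-parameterisation.  The curve is clamped to [0, 1] and is zero
    outside the control-point support.
    """
    cz = np.asarray(control_z, dtype=float)
    cv = np.asarray(control_values, dtype=float)
    if cz.size < 2:
        raise ValueError("need at least two control points")
    if np.any(np.diff(cz) < 5.0):
        raise ValueError("control-point spacing below 5 A")
    if np.any(cv < 0):
        raise ValueError("control values must be >= 0")
    z = np.asarray(z_grid, dtype=float)
    out = np.zeros_like(z)
    inside = (z >= cz[0]) & (z <= cz[-1])
    if np.all(cv == 0):
        return out
    out[inside] = PchipInterpolator(cz, cv)(z[inside])
    return np.clip(out, 0.0, 1.0)


def _box(z, lo, hi, rough_lo, rough_hi=None):
    # per-edge roughness so adjacent boxes sharing an interface stay complementary
    if rough_hi is None:
        rough_hi = rough_lo
    s2 = np.sqrt(2.0)
    return 0.5 * (erf((z - lo) / (s2 * rough_lo)) - erf((z - hi) / (s2 * rough_hi)))


@dataclass
class CompositionProfile:
    """Volume occupancies of all interface components on a common z grid."""

    z: np.ndarray
    occupancy: dict[str, np.ndarray]
    sld_overrides: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        for k, v in self.occupancy.items():
            v = np.asarray(v, dtype=float)
            if np.any((v < -1e-9) | (v > 1 + 1e-9)):
                raise ValueError(f"occupancy of {k!r} outside [0, 1]")
            self.occupancy[k] = np.clip(v, 0.0, 1.0)
        total = sum(v for k, v in self.occupancy.items() if k != "water")
        if "water" not in self.occupancy:
            self.occupancy["water"] = np.clip(1.0 - total, 0.0, 1.0)
        full = total + self.occupancy["water"]
        if np.any(np.abs(full - 1.0) > 1e-6):
            raise ValueError("occupancies do not sum to 1")

    def plot(self, ax=None):
        """Component volume-occupancy curves vs depth (one line each)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, occ in self.occupancy.items():
            ax.plot(self.z, occ, label=name)
        ax.set_xlabel("z ($\\AA$)")
        ax.set_ylabel("volume occupancy")
        ax.set_ylim(0, 1.05)
        ax.legend(fontsize=8)
        return ax

    def sld_profile(self, contrast: str) -> np.ndarray:
        """SLD(z) in 1e-6 A^-2; only solvent-dependent entries switch with
        the isotopic contrast."""
        if contrast not in _CONTRASTS:
            raise ValueError("contrast must be 'h2o' or 'd2o'")
        out = np.zeros_like(self.z)
        for name, occ in self.occupancy.items():
            table = self.sld_overrides.get(name, SLD_TABLE[name])
            out += occ * table[_CONTRASTS.index(contrast)]
        return out


def parratt_reflectivity(q, sld_slabs, dz: float, sld_fronting: float,
                         sld_backing: float, roughness: float = 0.0):
    """Exact dynamical reflectivity by the Parratt recursion.

    ``sld_slabs`` (1e-6 A^-2) are slab SLDs of uniform thickness ``dz``
    between the semi-infinite fronting and backing media.  ``roughness``
    applies a Nevot-Croce factor at every interface (0 = sharp; profile
    roughness is normally already encoded in the slab discretisation).
    q is the momentum transfer in the fronting medium.
    """
    q = np.atleast_1d(np.asarray(q, dtype=float))
    slabs = np.concatenate([np.atleast_1d(sld_slabs), [sld_backing]]) * 1e-6
    k0 = q / 2.0
    kf2 = k0.astype(complex) ** 2
    # vertical wavevector in every layer, relative to the fronting medium
    kz = np.sqrt(kf2[None, :] - 4.0 * np.pi * (slabs[:, None] - sld_fronting * 1e-6))
    r = np.zeros_like(kf2)
    # recursion from the deepest interface (backing) up to the fronting
    for j in range(len(slabs) - 1, 0, -1):
        k_up, k_lo = kz[j - 1], kz[j]
        rj = (k_up - k_lo) / (k_up + k_lo)
        if roughness > 0:
            rj = rj * np.exp(-2.0 * k_up * k_lo * roughness**2)
        beta = np.exp(2j * k_lo * dz) if j < len(slabs) - 1 else 0.0
        r = (rj + r * beta) / (1.0 + rj * r * beta)
    k_up = kz[0]
    r0 = (k0 - k_up) / (k0 + k_up)
    if roughness > 0:
        r0 = r0 * np.exp(-2.0 * k0 * k_up * roughness**2)
    beta = np.exp(2j * kz[0] * dz)
    r = (r0 + r * beta) / (1.0 + r0 * r * beta)
    return np.abs(r) ** 2


def fresnel_reflectivity(q, sld_fronting: float, sld_backing: float):
    """Closed-form Fresnel reflectivity of a single sharp interface."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    k0 = (q / 2.0).astype(complex)
    k1 = np.sqrt(k0**2 - 4.0 * np.pi * (sld_backing - sld_fronting) * 1e-6)
    return np.abs((k0 - k1) / (k0 + k1)) ** 2


def born_reflectivity(q, z, sld, sld_fronting: float, sld_backing: float):
    """Kinematic (Born / master-formula) reflectivity of a smooth profile,
    R = R_F |FT(d rho/dz)/Delta rho|^2; valid well above the critical edge."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    drho = np.gradient(np.asarray(sld, dtype=float), z)
    phase = np.exp(1j * np.outer(q, z))
    ft = np.trapezoid(phase * drho[None, :], z, axis=1)
    dr = sld_backing - sld_fronting
    return fresnel_reflectivity(q, sld_fronting, sld_backing) * np.abs(ft / dr) ** 2


class TetheredBilayer:
    """Parametric stBLM architecture generating composition profiles.

    Geometry (z = 0 at the Si surface, growing into the solvent): native
    oxide, ~140 A gold film, tether/SAM, inner headgroups, hydrocarbon
    core, outer headgroups, bulk solvent; plus a Hermite-spline peptide
    profile centred in the bilayer.  All lengths in Angstrom.
    """

    DEFAULTS = dict(
        sio2_thick=12.0, au_thick=140.0, au_rough=5.0,
        tether_thick=14.0, tether_occ=0.60,
        head_thick=8.0, head_occ=0.55,
        hc_thick=29.0, completeness=0.95,
        rough=3.0,
        pep_amp=0.0, pep_z=0.0, pep_sigma=12.0,
    )

    def __init__(self, dz: float = 2.0, z_max: float = 280.0, **params):
        unknown = set(params) - set(self.DEFAULTS)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        self.params = {**self.DEFAULTS, **params}
        self.z = np.arange(0.0, z_max, dz)
        self.dz = dz

    def profile(self, **overrides) -> CompositionProfile:
        p = {**self.params, **overrides}
        z = self.z
        z0 = 0.0
        z1 = z0 + p["sio2_thick"]
        z2 = z1 + p["au_thick"]
        z3 = z2 + p["tether_thick"]
        z4 = z3 + p["head_thick"]
        z5 = z4 + p["hc_thick"]
        z6 = z5 + p["head_thick"]
        occ = {
            "sio2": _box(z, z0 - 50.0, z1, 3.0),
            "gold": _box(z, z1, z2, 3.0, p["au_rough"]),
            "tether": p["tether_occ"] * _box(z, z2, z3, p["au_rough"], p["rough"]),
            "headgroup": p["head_occ"] * p["completeness"]
            * (_box(z, z3, z4, p["rough"]) + _box(z, z5, z6, p["rough"])),
            "hydrocarbon": p["completeness"] * _box(z, z4, z5, p["rough"]),
        }
        # substrate occupancy below z=0 is irrelevant (fronting medium is Si)
        if p["pep_amp"] > 0:
            center = 0.5 * (z4 + z5) + p["pep_z"]
            spacing = 15.0
            half = max(2.0 * p["pep_sigma"], 2 * spacing)
            cz = np.arange(center - half, center + half + spacing / 2, spacing)
            cv = p["pep_amp"] * np.exp(-0.5 * ((cz - center) / p["pep_sigma"]) ** 2)
            pep = spline_occupancy(cz, cv, z)
            # the peptide displaces bilayer material and solvent alike: the
            # soft components share the volume fraction it leaves free
            solid = occ["sio2"] + occ["gold"]
            pep = np.minimum(pep, np.clip(1.0 - solid, 0.0, 1.0))
            for key in ("tether", "headgroup", "hydrocarbon"):
                occ[key] = occ[key] * (1.0 - pep)
            occ["peptide"] = pep
        return CompositionProfile(z=z, occupancy=occ)

    def reflectivity(self, q, contrast: str, **overrides) -> np.ndarray:
        prof = self.profile(**overrides)
        sld = prof.sld_profile(contrast)
        return parratt_reflectivity(q, sld, self.dz,
                                    sld_fronting=_sld("silicon", contrast),
                                    sld_backing=_sld("water", contrast))


@dataclass
class PosteriorSummary:
    """Medians, 68% credible intervals and sampler diagnostics."""

    names: list[str]
    median: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    r_hat: np.ndarray
    acceptance_fraction: float
    chain: np.ndarray | None = None
    mixed: bool = True

    def interval(self, name: str) -> tuple[float, float]:
        i = self.names.index(name)
        return float(self.ci_low[i]), float(self.ci_high[i])

    def covers(self, truth: dict[str, float]) -> dict[str, bool]:
        return {n: self.ci_low[i] <= truth[n] <= self.ci_high[i]
                for i, n in enumerate(self.names)}

    def summary(self) -> str:
        lines = ["Composition-space NR fit (joint H2O/D2O)", "-" * 46,
                 f"{'parameter':<16}{'median':>10}{'68% interval':>24}{'R-hat':>8}"]
        for i, n in enumerate(self.names):
            lines.append(f"{n:<16}{self.median[i]:>10.4g}"
                         f"   [{self.ci_low[i]:>8.4g}, {self.ci_high[i]:>8.4g}]"
                         f"{self.r_hat[i]:>8.3f}")
        lines.append(f"mean acceptance fraction: {self.acceptance_fraction:.3f}")
        if not self.mixed:
            lines.append("WARNING: chains not mixed (R-hat > 1.2)")
        return "\n".join(lines)


def _split_r_hat(chain: np.ndarray) -> np.ndarray:
    """Split-chain Gelman-Rubin statistic; chain shape (n_steps, n_walkers, ndim)."""
    n = chain.shape[0] // 2
    halves = np.concatenate([chain[:n], chain[n:2 * n]], axis=1)
    means = halves.mean(axis=0)
    variances = halves.var(axis=0, ddof=1)
    W = variances.mean(axis=0)
    B = n * means.var(axis=0, ddof=1)
    var_hat = (n - 1) / n * W + B / n
    return np.sqrt(var_hat / np.where(W > 0, W, 1.0))


class ReflectometryModel:
    """Simultaneous two-contrast composition-space fit.

    Parameters
    ----------
    curves : dict
        ``{'h2o': ReflectivityCurve, 'd2o': ReflectivityCurve}``.
    builder : TetheredBilayer
        Fixed architecture supplying the forward model.
    free : dict of name -> (low, high)
        Free parameters with uniform prior bounds; all structural
        parameters are shared between the contrasts by construction.
    """

    def __init__(self, curves: dict[str, ReflectivityCurve],
                 builder: TetheredBilayer, free: dict[str, tuple[float, float]]):
        missing = set(_CONTRASTS) - set(curves)
        if missing:
            raise ValueError(f"both contrasts required; missing {sorted(missing)}")
        self.curves = curves
        self.builder = builder
        self.free = dict(free)
        self.names = list(free)

    def _log_prob(self, theta: np.ndarray) -> float:
        for v, (lo, hi) in zip(theta, self.free.values()):
            if not lo <= v <= hi:
                return -np.inf
        overrides = dict(zip(self.names, theta))
        # the structural profile is shared between contrasts by construction;
        # only the per-component SLD weighting changes
        prof = self.builder.profile(**overrides)
        ll = 0.0
        for c in _CONTRASTS:
            curve = self.curves[c]
            sld = prof.sld_profile(c)
            model = parratt_reflectivity(curve.q_z, sld, self.builder.dz,
                                         sld_fronting=_sld("silicon", c),
                                         sld_backing=_sld("water", c))
            ll -= 0.5 * np.sum(((model - curve.R) / curve.sigma) ** 2)
        return float(ll)

    def fit(self, seed: int = 0, n_walkers: int = 16, n_steps: int = 500,
            burn: int = 200, keep_chain: bool = False) -> PosteriorSummary:
        """Seeded ensemble MCMC; returns medians and 68% credible intervals."""
        ndim = len(self.names)
        rng = np.random.default_rng(seed)
        lo = np.array([b[0] for b in self.free.values()])
        hi = np.array([b[1] for b in self.free.values()])
        # start the ensemble in a tight ball around the maximum-likelihood
        # point so the burn-in phase does not have to cross the prior
        from scipy.optimize import minimize
        x_start = 0.5 * (lo + hi)
        opt = minimize(lambda x: -self._log_prob(x), x_start,
                       method="Nelder-Mead",
                       options={"maxiter": 200 * ndim, "xatol": 1e-6,
                                "fatol": 1e-6})
        center = np.clip(opt.x, lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo))
        ball = 0.01 * (hi - lo)
        p0 = np.clip(center + ball * rng.standard_normal((n_walkers, ndim)),
                     lo + 1e-9 * (hi - lo), hi - 1e-9 * (hi - lo))
        sampler = emcee.EnsembleSampler(n_walkers, ndim, self._log_prob)
        state = emcee.State(p0, random_state=np.random.RandomState(seed))
        sampler.run_mcmc(state, n_steps, progress=False)
        chain = sampler.get_chain()[burn:]
        r_hat = _split_r_hat(chain)
        flat = chain.reshape(-1, ndim)
        q16, q50, q84 = np.percentile(flat, [15.865, 50.0, 84.135], axis=0)
        mixed = bool(np.all(r_hat < 1.2))
        if not mixed:
            warnings.warn(f"non-mixing chains: R-hat = {np.round(r_hat, 3)}")
        return PosteriorSummary(names=self.names, median=q50, ci_low=q16,
                                ci_high=q84, r_hat=r_hat,
                                acceptance_fraction=float(np.mean(sampler.acceptance_fraction)),
                                chain=flat if keep_chain else None, mixed=mixed)
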
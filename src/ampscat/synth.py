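"""Seeded synthetic-data generators with serialised ground truth.

Every experimental modality the analysis modules consume can be emulated
here with a known ground-truth parameter set: CD basis mixtures, MIC
panels with per-strain log-normal dispersion, smectic-stack diffuse
patterns, tilted-rod WAXS arcs, SDP form factors, finite-stack lamellar
SAXS curves and two-contrast reflectivity pairs.  Identical seeds give
byte-identical output, and each generator returns ``(data, truth)`` with
``truth`` a JSON-serialisable dict, so tests and round-trip studies never
re-derive the generating parameters from the data.

Noise conventions: additive Gaussian for CD, |F| and NR data
(sigma = level * signal scale), multiplicative Gaussian or Poisson-like
(sqrt-intensity) noise for detector patterns, log-normal strain scatter
for MIC panels (optionally quantised to the two-fold dilution series).
"""

from __future__ import annotations

import inspect
import json
from dataclasses import dataclass

import numpy as np

from . import caille, cd, saxs, sdp, waxs
from .descriptors import MICPanel
from .nr import ReflectivityCurve, TetheredBilayer

__all__ = ["GeneratorSpec", "generate", "save_truth",
           "gen_cd", "gen_mic_panel", "gen_xds", "gen_waxs",
           "gen_formfactor", "gen_saxs", "gen_nr",
           "default_stack", "default_formfactor", "default_sdp_model"]


def save_truth(path, truth: dict) -> None:
    """Serialise a ground-truth dict as a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True, default=float)


# --------------------------------------------------------------------- CD
def gen_cd(fractions, basis: cd.BasisSet | None = None, noise: float = 0.0,
           seed: int = 0):
    """Mixture CD spectrum; ``fractions`` is a motif->fraction mapping on the
    simplex, ``noise`` the Gaussian sigma as a fraction of max |MRE|."""
    if basis is None:
        basis = cd.BasisSet.bundled()
    f = np.array([fractions[m] for m in cd.MOTIFS], dtype=float)
    if np.any(f < -1e-12) or abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must be non-negative and sum to 1")
    y = basis.matrix() @ f
    rng = np.random.default_rng(seed)
    if noise > 0:
        y = y + rng.normal(0.0, noise * np.abs(y).max(), size=y.shape)
    truth = {"fractions": {m: float(v) for m, v in zip(cd.MOTIFS, f)},
             "noise": noise, "seed": seed}
    return cd.CDSpectrum(basis.wavelength_nm, y, meta={"synthetic": True}), truth


# -------------------------------------------------------------------- MIC
def gen_mic_panel(species_means: dict[str, float], strain_cv: float,
                  n_strains: int, seed: int = 0, peptide: str = "pep",
                  quantize: bool = False):
    """Strain-level MIC panel: log-normal scatter of width ``strain_cv``
    (coefficient of variation) around each species mean, optionally
    quantised to the two-fold dilution series."""
    if any(v <= 0 for v in species_means.values()):
        raise ValueError("species means must be positive")
    rng = np.random.default_rng(seed)
    rows, labels, species_of = [], [], {}
    sigma_log = np.sqrt(np.log1p(strain_cv**2))
    for sp, mean in species_means.items():
        mu = np.log(mean) - 0.5 * sigma_log**2
        vals = np.exp(rng.normal(mu, sigma_log, size=n_strains)) if strain_cv > 0 \
            else np.full(n_strains, mean)
        if quantize:
            vals = 2.0 ** np.round(np.log2(vals))
        for i, v in enumerate(vals):
            labels.append(f"{sp}_{i + 1}")
            species_of[f"{sp}_{i + 1}"] = sp
            rows.append([v])
    panel = MICPanel(peptides=[peptide], species=labels,
                     values=np.array(rows))
    truth = {"species_means": dict(species_means), "strain_cv": strain_cv,
             "n_strains": n_strains, "seed": seed, "species_of": species_of}
    return panel, truth


# -------------------------------------------------------------------- XDS
def default_stack(K_C: float = 20.0, B: float = 2e-7, N_layers: int = 16,
                  L_r: float = 2500.0, D: float = 58.0) -> caille.StackModel:
    """Typical fluid-phase stack: K_C ~ 20 k_BT (~8.6e-20 J at 37 C) and a
    compression modulus giving clearly developed diffuse lobes."""
    return caille.StackModel(K_C=K_C, B=B, N_layers=N_layers, L_r=L_r, D=D)


def default_formfactor(q_z):
    """Smooth bilayer |F(q_z)| stand-in with realistic lobe structure."""
    q_z = np.asarray(q_z, dtype=float)
    return np.abs(np.cos(q_z * 19.5) * np.exp(-0.5 * (3.0 * q_z) ** 2)
                  - 0.45 * np.exp(-0.5 * (9.0 * q_z) ** 2))


def gen_xds(stack: caille.StackModel, formfactor=None, q_r=None, q_z=None,
            noise: float = 0.05, seed: int = 0, scale: float = 1.0,
            noise_model: str = "multiplicative"):
    """Diffuse low-angle pattern from a fluctuating stack plus noise.

    ``noise_model='multiplicative'`` applies I*(1+level*eps); ``'poisson'``
    adds Gaussian noise of width sqrt(I) (counting statistics).
    """
    if formfactor is None:
        formfactor = default_formfactor
    if q_r is None:
        q_r = np.linspace(0.012, 0.25, 64)
    if q_z is None:
        q_z = np.linspace(0.06, 0.34, 52)
    clean = caille.predict_pattern(stack, formfactor, q_z, q_r, scale=scale)
    rng = np.random.default_rng(seed)
    I = clean.intensity.copy()
    ok = np.isfinite(I)
    # small additive floor (read noise / residual background) keeps dark
    # pixels from carrying unphysical infinite weight
    floor = 1e-3 * np.nanmax(np.abs(I))
    if noise > 0:
        if noise_model == "multiplicative":
            sigma = np.where(ok, noise * np.abs(clean.intensity) + noise * floor,
                             np.nan)
            I[ok] = I[ok] + rng.normal(0.0, 1.0, size=ok.sum()) * sigma[ok]
        elif noise_model == "poisson":
            I[ok] = I[ok] + rng.normal(0.0, 1.0, size=ok.sum()) * np.sqrt(np.abs(I[ok]))
            sigma = np.where(ok, np.sqrt(np.abs(clean.intensity)), np.nan)
        else:
            raise ValueError("noise_model must be multiplicative|poisson")
    else:
        sigma = np.where(ok, 1.0, np.nan)
    truth = {"K_C": stack.K_C, "B": stack.B, "N_layers": stack.N_layers,
             "L_r": stack.L_r, "D": stack.D, "noise": noise, "seed": seed,
             "scale": scale}
    return caille.DiffusePattern(q_r=clean.q_r, q_z=clean.q_z, intensity=I,
                                 sigma=sigma), truth


# ------------------------------------------------------------------- WAXS
def gen_waxs(m: float, phi_deg=None, scale: float = 1000.0,
             background: float = 50.0, noise: float = 0.05, seed: int = 0,
             q_band=(1.2, 1.6)):
    """Tilted-rod angular profile with multiplicative Gaussian noise."""
    if phi_deg is None:
        phi_deg = np.linspace(1.0, 89.0, 120)
    clean = waxs.arc_intensity(phi_deg, m, scale, background)
    rng = np.random.default_rng(seed)
    y = clean * (1.0 + rng.normal(0.0, noise, size=clean.shape)) if noise > 0 else clean
    truth = {"m": m, "S_xray": waxs.sxray_from_m(m), "scale": scale,
             "background": background, "noise": noise, "seed": seed}
    return waxs.AngularProfile(np.asarray(phi_deg, dtype=float), y, q_band), truth


# -------------------------------------------------------------------- SDP
def default_sdp_model(A_L: float = 70.8, D_HH: float = 39.2,
                      peptide: sdp.PeptideEnvelope | None = None) -> sdp.SDPModel:
    """Control bilayer with the structure of the bacterial-mimic membrane
    (A_L = 70.8 A^2, D_HH = 39.2 A, 2D_C = 29.1 A)."""
    model = sdp.model_from_structure(A_L=A_L, D_HH=D_HH)
    model.peptide = peptide
    return model


def gen_formfactor(model: sdp.SDPModel, q_z=None, noise: float = 0.0,
                   seed: int = 0):
    """|F(q_z)| data from an SDP model with additive Gaussian noise of
    sigma = noise * max|F|."""
    if q_z is None:
        q_z = np.linspace(0.02, 0.62, 150)
    F = np.abs(sdp.form_factor(model, q_z))
    rng = np.random.default_rng(seed)
    sig_abs = max(noise, 1e-3) * F.max()
    y = np.abs(F + rng.normal(0.0, noise * F.max(), size=F.shape)) if noise > 0 else F
    structure = sdp.derive_structure(model)
    truth = {"A_L": model.A_L, "D_HH": structure.D_HH,
             "two_D_C": structure.two_D_C,
             "placement": model.peptide.placement if model.peptide else None,
             "z_pep": model.peptide.z if model.peptide else None,
             "noise": noise, "seed": seed}
    return sdp.FormFactorData(np.asarray(q_z, dtype=float), y,
                              np.full_like(F, sig_abs)), truth


# ------------------------------------------------------------------- SAXS
def _saxs_formfactor(q):
    """Smooth ULV bilayer intensity envelope |F(q)|^2 (diffuse lobes)."""
    F = (np.cos(q * 19.5) * np.exp(-0.5 * (2.5 * q) ** 2)
         - 0.45 * np.exp(-0.5 * (8.0 * q) ** 2))
    return F**2 + 1e-4


def gen_saxs(D: float = 51.1, n_layers: int = 30, diffuse_fraction: float = 0.35,
             noise: float = 0.01, seed: int = 0, q=None, disorder: float = 0.8,
             scale: float = 1000.0):
    """Finite-stack lamellar SAXS curve.

    A paracrystalline structure factor with ``n_layers`` bilayers at
    repeat ``D`` and cumulative stacking disorder ``disorder`` (A)
    multiplies a smooth bilayer envelope; ``diffuse_fraction`` of the
    power stays in the uncorrelated (ULV) channel.  n_layers = 1 gives a
    pure diffuse ULV curve.
    """
    if D <= 0 or n_layers < 1:
        raise ValueError("D must be positive and n_layers >= 1")
    if q is None:
        q = np.linspace(0.03, 0.73, 500)
    q = np.asarray(q, dtype=float)
    N = int(n_layers)
    k = np.arange(1, N)
    if N > 1:
        damp = np.exp(-0.5 * np.outer(q**2, k) * disorder**2)
        S = 1.0 + (2.0 / N) * (damp * np.cos(np.outer(q * D, k))) @ (N - k)
    else:
        S = np.ones_like(q)
    env = _saxs_formfactor(q)
    I = scale * env * ((1.0 - diffuse_fraction) * S + diffuse_fraction)
    rng = np.random.default_rng(seed)
    sigma = np.maximum(noise * I, noise * 1e-3 * I.max())
    if noise > 0:
        I = I + rng.normal(0.0, 1.0, size=I.shape) * sigma
    truth = {"D": D, "n_layers": N, "diffuse_fraction": diffuse_fraction,
             "disorder": disorder, "noise": noise, "seed": seed,
             "q1": 2.0 * np.pi / D}
    return saxs.SAXSCurve(q, I, sigma, meta={"synthetic": True}), truth


# --------------------------------------------------------------------- NR
def gen_nr(builder: TetheredBilayer | None = None, q_z=None,
           noise: float = 0.05, seed: int = 0, **truth_params):
    """Two-contrast reflectivity pair from a known composition profile.

    ``truth_params`` override the builder's architecture (e.g. hc_thick,
    pep_amp); relative Gaussian noise of level ``noise`` is applied with
    sigma = noise * R.
    """
    if builder is None:
        builder = TetheredBilayer()
    if q_z is None:
        q_z = np.geomspace(0.012, 0.30, 70)
    q_z = np.asarray(q_z, dtype=float)
    rng = np.random.default_rng(seed)
    curves = {}
    for contrast in ("h2o", "d2o"):
        R = builder.reflectivity(q_z, contrast, **truth_params)
        sigma = np.maximum(noise * R, 1e-12)
        Rn = np.clip(R + rng.normal(0.0, 1.0, size=R.shape) * sigma, 1e-15, 1.0) \
            if noise > 0 else R
        curves[contrast] = ReflectivityCurve(q_z, Rn, sigma, contrast)
    truth = {**{k: float(v) for k, v in truth_params.items()},
             "noise": noise, "seed": seed}
    return curves, truth


# ------------------------------------------------------------- dispatcher
_GENERATORS = {"cd": gen_cd, "mic": gen_mic_panel, "xds": gen_xds,
               "waxs": gen_waxs, "formfactor": gen_formfactor,
               "saxs": gen_saxs, "nr": gen_nr}


@dataclass
class GeneratorSpec:
    """Declarative description of one synthetic dataset."""

    modality: str
    truth: dict
    noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in _GENERATORS:
            raise ValueError(f"unknown modality {self.modality!r}")


def generate(spec: GeneratorSpec):
    """Run the generator described by *spec*; returns (data, truth)."""
    fn = _GENERATORS[spec.modality]
    kw = dict(spec.truth)
    if "noise" in inspect.signature(fn).parameters:
        kw["noise"] = spec.noise
    return fn(**kw, seed=spec.seed)
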
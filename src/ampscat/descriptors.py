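"""Peptide physicochemical descriptors and MIC-panel summary statistics.

Descriptors follow the HeliQuest conventions: mean per-residue
Fauchere-Pliska hydrophobicity H and an integer net charge at pH 7
(+1 per Arg/Lys, -1 per Asp/Glu, His neutral, termini ignored).
MIC panels (strain x peptide matrices, micromolar) are summarised by
unweighted per-species means with the standard error propagated as

    sem = sqrt(sum_i sigma_i**2) / N

when per-species standard deviations are available, and otherwise as the
sample standard deviation of the species means divided by sqrt(N).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "FAUCHERE_PLISKA",
    "PeptideRecord",
    "MICPanel",
    "MICSummary",
    "mean_hydrophobicity",
    "net_charge",
    "mic_group_mean",
    "propagate_sem",
    "mre_from_ellipticity",
]


def _load_fp_scale() -> dict[str, float]:
    with resources.files("ampscat.data").joinpath("fauchere_pliska_1983.csv").open() as fh:
        tab = pd.read_csv(fh, comment="#")
    return dict(zip(tab["residue"], tab["pi"]))


#: Fauchere-Pliska octanol/water hydrophobicity scale (HeliQuest's H scale).
FAUCHERE_PLISKA: dict[str, float] = _load_fp_scale()

_POSITIVE = {"R", "K"}
_NEGATIVE = {"D", "E"}


def _validate_sequence(sequence: str) -> str:
    seq = sequence.strip().upper().replace(" ", "")
    if not seq:
        raise ValueError("empty peptide sequence")
    for i, aa in enumerate(seq):
        if aa not in FAUCHERE_PLISKA:
            raise ValueError(f"unknown residue code {aa!r} at position {i + 1}")
    return seq


def mean_hydrophobicity(sequence: str) -> float:
    """Mean per-residue Fauchere-Pliska hydrophobicity of *sequence*.

    This is the quantity HeliQuest reports as H; it is invariant under
    permutation of the sequence. Unknown residue codes raise ``ValueError``
    naming the offending position.
    """
    seq = _validate_sequence(sequence)
    return float(np.mean([FAUCHERE_PLISKA[aa] for aa in seq]))


def net_charge(sequence: str, pH: float = 7.0) -> int:
    """Integer net charge at neutral pH.

    Counts +1 for each R/K and -1 for each D/E.  Histidine is treated as
    neutral and the termini are ignored, matching the integer-charge
    convention in which an all-arginine stretch of n residues carries +n.
    Only pH 7 counting is implemented; other values raise.
    """
    if abs(pH - 7.0) > 1e-9:
        raise NotImplementedError("only the fixed pH 7 counting rule is supported")
    seq = _validate_sequence(sequence)
    return sum(+1 for aa in seq if aa in _POSITIVE) - sum(1 for aa in seq if aa in _NEGATIVE)


@dataclass(frozen=True)
class PeptideRecord:
    """A peptide with its derived physical attributes."""

    id: str
    sequence: str
    n_residues: int = field(init=False)
    net_charge: int = field(init=False)
    hydrophobicity_H: float = field(init=False)

    def __post_init__(self) -> None:
        seq = _validate_sequence(self.sequence)
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "n_residues", len(seq))
        object.__setattr__(self, "net_charge", net_charge(seq))
        object.__setattr__(self, "hydrophobicity_H", mean_hydrophobicity(seq))

    @classmethod
    def from_fasta(cls, path) -> list["PeptideRecord"]:
        """Read peptides from a FASTA file (plain text, '>' headers)."""
        records, label, chunks = [], None, []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                if line.startswith(">"):
                    if label is not None:
                        records.append(cls(label, "".join(chunks)))
                    label, chunks = line[1:].split()[0], []
                else:
                    chunks.append(line)
        if label is not None:
            records.append(cls(label, "".join(chunks)))
        return records


def propagate_sem(per_species_sd, N: int | None = None) -> float:
    """Combine per-species standard deviations into a standard error.

    Implements sem = sqrt(sigma_A^2 + sigma_B^2 + ...) / N with N the
    number of species (defaults to ``len(per_species_sd)``).
    """
    sd = np.asarray(per_species_sd, dtype=float)
    if N is None:
        N = sd.size
    if N <= 0:
        raise ValueError("N must be >= 1")
    if np.any(sd < 0):
        raise ValueError("standard deviations must be >= 0")
    return float(np.sqrt(np.sum(sd**2)) / N)


@dataclass(frozen=True)
class MICSummary:
    """Group mean and standard error of MICs over a set of species."""

    group_mean: float
    group_sem: float
    n_species: int


@dataclass
class MICPanel:
    """MIC matrix (species x peptides, micromolar) with optional per-species SDs."""

    peptides: list[str]
    species: list[str]
    values: np.ndarray
    per_species_sd: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape != (len(self.species), len(self.peptides)):
            raise ValueError("MIC matrix shape inconsistent with label lists")
        finite = self.values[np.isfinite(self.values)]
        if np.any(finite <= 0):
            raise ValueError("MIC values must be positive")
        if self.per_species_sd is not None:
            self.per_species_sd = np.atleast_2d(np.asarray(self.per_species_sd, dtype=float))
            if self.per_species_sd.shape != self.values.shape:
                raise ValueError("per_species_sd shape mismatch")

    @classmethod
    def from_csv(cls, path) -> "MICPanel":
        """Wide CSV: first column species labels, remaining columns peptides."""
        tab = pd.read_csv(path)
        species = tab.iloc[:, 0].astype(str).tolist()
        peptides = list(tab.columns[1:])
        return cls(peptides, species, tab.iloc[:, 1:].to_numpy(float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species, columns=self.peptides)


def mic_group_mean(panel: MICPanel, peptide: str, species_subset=None) -> MICSummary:
    """Unweighted mean MIC of *peptide* over *species_subset* with its SEM.

    When the panel carries per-species standard deviations the SEM is the
    quadrature combination sqrt(sum sigma_i^2)/N; otherwise it is the
    sample (N-1) standard deviation of the species means over sqrt(N).
    A single-species group reports sem = 0 by convention.
    """
    if species_subset is None:
        species_subset = panel.species
    species_subset = list(species_subset)
    if not species_subset:
        raise ValueError("species subset is empty")
    j = panel.peptides.index(peptide)
    rows = [panel.species.index(s) for s in species_subset]
    vals = panel.values[rows, j]
    vals = vals[np.isfinite(vals)]
    if vals.size == 0:
        raise ValueError("no finite MIC values in the requested subset")
    mean = float(np.mean(vals))
    if vals.size == 1:
        sem = 0.0
    elif panel.per_species_sd is not None:
        sem = propagate_sem(panel.per_species_sd[rows, j], vals.size)
    else:
        sem = float(np.std(vals, ddof=1) / np.sqrt(vals.size))
    return MICSummary(group_mean=mean, group_sem=sem, n_species=int(vals.size))


def mre_from_ellipticity(epsilon, n_residues: int):
    """Convert instrument ellipticity to mean residue ellipticity.

    MRE (deg cm^2 dmol^-1) = epsilon * 1e4 / N.  The constant bakes in the
    fixed acquisition conditions (10 uM peptide, 3 mL cell); the conversion
    is only valid for data taken under those conditions.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    return np.asarray(epsilon, dtype=float) * 1.0e4 / n_residues
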
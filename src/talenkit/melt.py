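"""Duplex enumeration and melt-curve simulation for mixed allele pools.

Denaturing and rapidly reannealing amplicons from a pool of alleles at
frequencies p_i forms duplex species by random strand pairing: species
(i, j) has abundance p_i * p_j, with the two heteroduplex orientations of
an unordered pair {i, j} counted separately — a 0.5/0.5 heterozygote pool
yields two homoduplexes (0.25 each) and two heteroduplexes (0.25 each).

Each species melts as a two-state transition with helicity

    theta(T) = 1 / (1 + exp((dH/R) * (1/T - 1/Tm)))

and the dye signal of the pool is the abundance-weighted sum of species
helicities, mimicking a saturating double-strand-binding dye.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .thermo import R_GAS, DuplexThermo, ThermoParams, duplex_thermo

DEFAULT_TEMP_GRID = (65.0, 95.0, 0.1)  # Celsius: start, stop, step


@dataclass(frozen=True)
class AllelePool:
    """Labelled amplicon variants with their haploid frequencies."""

    alleles: tuple[tuple[str, str], ...]  # (label, sequence)
    freqs: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.alleles) != len(self.freqs):
            raise ValueError("alleles and freqs must have equal length")
        if not self.alleles:
            raise ValueError("pool must contain at least one allele")
        if any(f < 0 for f in self.freqs):
            raise ValueError("frequencies must be non-negative")
        total = sum(self.freqs)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"frequencies must sum to 1 (got {total})")

    @classmethod
    def from_dict(cls, alleles: dict[str, str], freqs: dict[str, float]) -> "AllelePool":
        labels = list(alleles)
        return cls(
            alleles=tuple((lab, alleles[lab]) for lab in labels),
            freqs=tuple(freqs[lab] for lab in labels),
        )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.alleles)

    def sequence(self, label: str) -> str:
        for lab, seq in self.alleles:
            if lab == label:
                return seq
        raise KeyError(label)

    def truncated(self, max_alleles: int = 16, min_freq: float = 0.01) -> "AllelePool":
        """Drop alleles below a frequency floor and renormalize.

        Mosaic embryos can carry very many distinct alleles, each far
        below the detection limit; this keeps duplex enumeration
        quadratic in a small number of detectable alleles. The highest-
        frequency allele is always retained.
        """
        order = sorted(
            range(len(self.freqs)), key=lambda i: (-self.freqs[i], self.labels[i])
        )
        keep = [i for i in order if self.freqs[i] >= min_freq][:max_alleles]
        if not keep:
            keep = [order[0]]
        total = sum(self.freqs[i] for i in keep)
        return AllelePool(
            alleles=tuple(self.alleles[i] for i in keep),
            freqs=tuple(self.freqs[i] / total for i in keep),
        )


@dataclass(frozen=True)
class DuplexSpecies:
    """One reannealed duplex population."""

    top_allele: str
    bottom_allele: str
    fraction: float
    thermo: DuplexThermo | None = None

    @property
    def tm(self) -> float | None:
        return None if self.thermo is None else self.thermo.tm


@dataclass(frozen=True)
class MeltCurve:
    temps: np.ndarray = field(compare=False)
    fluor: np.ndarray = field(compare=False)
    sample_id: str = ""
    noise_sd: float = 0.0


def enumerate_duplexes(
    pool: AllelePool, thermo_params: ThermoParams | None = None
) -> list[DuplexSpecies]:
    """All duplex species of a reannealed pool under random pairing.

    Fractions alone follow from the pool; when ``thermo_params`` is given
    each species also carries its nearest-neighbor thermodynamics (the two
    orientations of a heteroduplex share one calculation).
    """
    species: list[DuplexSpecies] = []
    cache: dict[frozenset[str], DuplexThermo] = {}
    for i, (lab_i, seq_i) in enumerate(pool.alleles):
        for j, (lab_j, seq_j) in enumerate(pool.alleles):
            frac = pool.freqs[i] * pool.freqs[j]
            thermo = None
            if thermo_params is not None:
                key = frozenset((lab_i, lab_j))
                if key not in cache:
                    cache[key] = duplex_thermo(seq_i, seq_j, thermo_params)
                thermo = cache[key]
            species.append(DuplexSpecies(lab_i, lab_j, frac, thermo))
    return species


def helicity(thermo: DuplexThermo, temps_c: np.ndarray) -> np.ndarray:
    """Two-state fraction of intact duplex across a Celsius grid."""
    t_k = np.asarray(temps_c, dtype=float) + 273.15
    tm_k = thermo.tm + 273.15
    # dH is negative for duplex formation, so theta decreases with T
    arg = (thermo.dh * 1000.0 / R_GAS) * (1.0 / t_k - 1.0 / tm_k)
    return 1.0 / (1.0 + np.exp(np.clip(arg, -500, 500)))


def temperature_grid(
    start: float = DEFAULT_TEMP_GRID[0],
    stop: float = DEFAULT_TEMP_GRID[1],
    step: float = DEFAULT_TEMP_GRID[2],
) -> np.ndarray:
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def melt_curve(
    species: list[DuplexSpecies],
    temps: np.ndarray | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    sample_id: str = "",
) -> MeltCurve:
    """Fluorescence-vs-temperature profile of a duplex population.

    fluor(T) = sum over species of fraction * helicity(T), plus optional
    Gaussian noise (deterministic for a fixed seed/generator).
    """
    if not species:
        raise ValueError("species set is empty")
    if any(s.thermo is None for s in species):
        raise ValueError("all species need thermodynamics; pass thermo_params "
                         "to enumerate_duplexes")
    if temps is None:
        temps = temperature_grid()
    temps = np.asarray(temps, dtype=float)
    if np.any(np.diff(temps) <= 0):
        raise ValueError("temperature grid must be strictly ascending")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    fluor = np.zeros_like(temps)
    for s in species:
        fluor += s.fraction * helicity(s.thermo, temps)
    if noise_sd > 0:
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        fluor = fluor + rng.normal(0.0, noise_sd, size=fluor.shape)
    return MeltCurve(temps=temps, fluor=fluor, sample_id=sample_id, noise_sd=noise_sd)


def pool_melt_curve(
    pool: AllelePool,
    thermo_params: ThermoParams | None = None,
    temps: np.ndarray | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    sample_id: str = "",
) -> MeltCurve:
    """Convenience: enumerate duplexes of a pool and render its melt curve."""
    species = enumerate_duplexes(pool, thermo_params or ThermoParams())
    return melt_curve(species, temps, noise_sd, rng, sample_id)
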
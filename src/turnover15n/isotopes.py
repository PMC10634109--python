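"""Peptide isotopologue distributions and RIA estimation.

Partial metabolic labeling with heavy nitrogen produces, for every peptide,
a superposition of two molecule populations: the pre-existing ("light")
population with nitrogen at its natural isotopic abundance, and the newly
synthesized ("heavy") population in which each nitrogen atom carries 15N
with the enrichment of the labeled growth medium.  The relative isotopic
abundance (RIA) of a peptide is the fraction of its ion-envelope signal
contributed by the heavy population,

    RIA = 15N / (15N + 14N),

and is recovered here by fitting the observed envelope as a non-negative
mixture of the two theoretical population envelopes.

Isotopologues are modeled at nominal (unit) mass resolution: the envelope
channel k collects all isotope assignments whose mass exceeds the
monoisotopic peak by k Da.  This matches how targeted PRM envelope
intensities are reported in practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from pyteomics import mass as _ptmass
from scipy.optimize import nnls

__all__ = [
    "NATURAL_ABUNDANCE",
    "DEFAULT_ENRICHMENT",
    "DEFAULT_ENRICHMENT_GRID",
    "ElementalComposition",
    "IsotopeEnvelope",
    "RIAEstimate",
    "composition_from_sequence",
    "isotopologue_distribution",
    "natural_envelope",
    "mixture_envelope",
    "estimate_ria",
]

#: Natural heavy-isotope abundances (IUPAC), overridable per call.
#: Oxygen and sulfur have two heavy isotopes at +1 and +2 Da.
NATURAL_ABUNDANCE: dict[str, tuple[float, ...]] = {
    "C": (0.0107,),            # 13C
    "H": (0.000115,),          # 2H
    "N": (0.00364,),           # 15N
    "O": (0.00038, 0.00205),   # 17O, 18O
    "S": (0.0075, 0.0421),     # 33S, 34S
}

#: Assumed 15N enrichment of the labeled medium when simulating.
DEFAULT_ENRICHMENT = 0.98

#: Grid of candidate medium enrichments searched by :func:`estimate_ria`.
DEFAULT_ENRICHMENT_GRID = np.round(np.arange(0.90, 0.9995, 0.001), 4)

_STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ElementalComposition:
    """Atom counts of a neutral, water-terminated peptide."""

    c: int
    h: int
    n: int
    o: int
    s: int = 0

    def __post_init__(self) -> None:
        for name in ("c", "h", "n", "o", "s"):
            if getattr(self, name) < 0:
                raise ValueError(f"negative {name.upper()} count")

    def as_dict(self) -> dict[str, int]:
        return {"C": self.c, "H": self.h, "N": self.n, "O": self.o, "S": self.s}


@dataclass
class IsotopeEnvelope:
    """Relative isotopologue intensities by nominal mass offset 0..K."""

    intensities: np.ndarray
    composition: ElementalComposition | None = None
    enrichment: float | None = None
    normalized: bool = field(default=False)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 1:
            raise ValueError("envelope intensities must be 1-D")
        if np.any(self.intensities < 0):
            raise ValueError("envelope intensities must be non-negative")
        if self.normalized and abs(self.intensities.sum() - 1.0) > 1e-9:
            raise ValueError("envelope flagged normalized but does not sum to 1")

    def normalize(self) -> "IsotopeEnvelope":
        total = self.intensities.sum()
        if total <= 0:
            raise ValueError("empty envelope")
        return IsotopeEnvelope(
            self.intensities / total,
            composition=self.composition,
            enrichment=self.enrichment,
            normalized=True,
        )


@dataclass(frozen=True)
class RIAEstimate:
    """Mixture-fit result: heavy-population weight, enrichment, residual."""

    ria: float
    enrichment: float
    residual: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ria <= 1.0:
            raise ValueError("ria outside [0, 1]")
        if self.residual < 0:
            raise ValueError("negative residual")


def composition_from_sequence(sequence: str) -> ElementalComposition:
    """Elemental composition of the neutral peptide (residues + one water).

    Parameters
    ----------
    sequence:
        Amino-acid sequence using the 20 standard one-letter codes.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    for pos, symbol in enumerate(sequence, start=1):
        if symbol not in _STANDARD_RESIDUES:
            raise ValueError(
                f"unknown residue symbol {symbol!r} at position {pos}"
            )
    comp = _ptmass.Composition(sequence=sequence)
    return ElementalComposition(
        c=comp.get("C", 0),
        h=comp.get("H", 0),
        n=comp.get("N", 0),
        o=comp.get("O", 0),
        s=comp.get("S", 0),
    )


def _element_polynomial(n_atoms: int, heavy: tuple[float, ...], length: int) -> np.ndarray:
    """Nominal-mass offset distribution for ``n_atoms`` i.i.d. atoms.

    ``heavy`` lists the probabilities of the +1, +2, ... Da isotopes; the
    remainder is the light isotope.  Truncated to ``length`` channels during
    the convolution to bound cost (mass tail beyond the window is dropped
    and restored by the final normalization).
    """
    light = 1.0 - sum(heavy)
    if light < -1e-12:
        raise ValueError("heavy-isotope fractions exceed 1")
    single = np.array([max(light, 0.0), *heavy])
    out = np.ones(1)
    for _ in range(n_atoms):
        out = np.convolve(out, single)[:length]
    return out


def isotopologue_distribution(
    comp: ElementalComposition,
    n15_fraction: float = NATURAL_ABUNDANCE["N"][0],
    heavy_fractions_other: dict[str, tuple[float, ...]] | None = None,
    length: int | None = None,
) -> IsotopeEnvelope:
    """Theoretical envelope with nitrogen at ``n15_fraction`` 15N.

    Convolves independent per-element isotope distributions (binomial for
    C/H/N, trinomial for O/S) into a single nominal-mass envelope of
    ``length`` channels (default: number of N atoms + 6), then normalizes.
    """
    if not 0.0 <= n15_fraction <= 1.0:
        raise ValueError("n15_fraction outside [0, 1]")
    fractions = dict(NATURAL_ABUNDANCE)
    if heavy_fractions_other:
        for elem, probs in heavy_fractions_other.items():
            probs = tuple(probs)
            if any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValueError(f"heavy fraction for {elem} outside [0, 1]")
            fractions[elem] = probs
    fractions["N"] = (n15_fraction,)
    if length is None:
        length = comp.n + 6
    envelope = np.ones(1)
    for elem, count in comp.as_dict().items():
        if count:
            envelope = np.convolve(
                envelope, _element_polynomial(count, fractions[elem], length)
            )[:length]
    envelope = np.pad(envelope, (0, length - envelope.size))
    return IsotopeEnvelope(
        envelope / envelope.sum(),
        composition=comp,
        enrichment=n15_fraction,
        normalized=True,
    )


def natural_envelope(comp: ElementalComposition, length: int | None = None) -> IsotopeEnvelope:
    """Envelope of the unlabeled population (all elements natural)."""
    return isotopologue_distribution(comp, length=length)


def mixture_envelope(
    comp: ElementalComposition,
    ria: float,
    enrichment: float = DEFAULT_ENRICHMENT,
    length: int | None = None,
) -> IsotopeEnvelope:
    """Two-population envelope: (1-ria) natural + ria 15N-enriched.

    ``ria`` is the heavy-population molecule fraction; ``enrichment`` is the
    15N atom fraction within the heavy population (the labeled medium's
    enrichment).  All other elements stay at natural abundance in both
    populations.
    """
    if not 0.0 <= ria <= 1.0:
        raise ValueError("ria outside [0, 1]")
    if not 0.0 <= enrichment <= 1.0:
        raise ValueError("enrichment outside [0, 1]")
    if length is None:
        length = comp.n + 6
    light = natural_envelope(comp, length=length).intensities
    heavy = isotopologue_distribution(comp, enrichment, length=length).intensities
    mixed = (1.0 - ria) * light + ria * heavy
    return IsotopeEnvelope(
        mixed / mixed.sum(), composition=comp, enrichment=enrichment, normalized=True
    )


def estimate_ria(
    observed: IsotopeEnvelope | np.ndarray,
    comp: ElementalComposition,
    enrichment_grid: np.ndarray | None = None,
) -> RIAEstimate:
    """Recover the heavy-population fraction from an observed envelope.

    For each candidate medium enrichment on the grid, the observed
    (normalized) envelope is fit as a non-negative least-squares mixture of
    the natural and the enriched theoretical envelopes; the grid point with
    the smallest residual wins (ties broken toward lower enrichment) and
    RIA is the heavy weight divided by the total fitted weight.
    """
    if enrichment_grid is None:
        enrichment_grid = DEFAULT_ENRICHMENT_GRID
    enrichment_grid = np.sort(np.asarray(enrichment_grid, dtype=float))
    if enrichment_grid.size == 0:
        raise ValueError("empty enrichment grid")
    intensities = (
        observed.intensities if isinstance(observed, IsotopeEnvelope) else np.asarray(observed, float)
    )
    if intensities.sum() <= 0:
        raise ValueError("empty envelope")
    if intensities.size < comp.n + 1:
        raise ValueError(
            f"observed envelope has {intensities.size} channels; "
            f"need at least {comp.n + 1} for {comp.n} nitrogen atoms"
        )
    obs = intensities / intensities.sum()
    length = obs.size
    light = natural_envelope(comp, length=length).intensities

    best: RIAEstimate | None = None
    for p in enrichment_grid:
        heavy = isotopologue_distribution(comp, p, length=length).intensities
        basis = np.column_stack([light, heavy])
        weights, residual = nnls(basis, obs)
        total = weights.sum()
        ria = float(weights[1] / total) if total > 0 else 0.0
        if best is None or residual < best.residual:
            best = RIAEstimate(ria=ria, enrichment=float(p), residual=float(residual))
    assert best is not None
    return best
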
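"""Theoretical isotope distributions and most-abundant-peak selection.

Precursor targeting for cross-linked peptide pairs defaults to the m/z of
the most abundant isotope of the pair, because above roughly 1.8 kDa the
monoisotopic peak is no longer the tallest and a monoisotopic target would
sit off-center in the isolation window. The distribution is computed by
aggregated isotopologue convolution: each nominal peak (neutron offset k)
carries the abundance-weighted centroid mass of the isotopologues that fall
on it, which matches what a high-resolution centroided spectrum reports.

Natural isotope abundances come from the NIST table in
:mod:`pyteomics.mass`. Isotope-labeled atoms written in bracket notation
(``C[13]``, ``N[15]``) are treated as pure single-isotope species.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import List, Tuple

from pyteomics.mass import nist_mass

from .mass_core import ElementalComposition, mz_from_mass

__all__ = [
    "IsotopeDistribution",
    "isotope_distribution",
    "most_abundant_isotope_mz",
    "averagine_composition",
]

_PRUNE = 1e-10  # drop aggregate peaks below this raw abundance during convolution

_LABELED = re.compile(r"^([A-Z][a-z]?)\[(\d+)\]$")


def _element_pattern(symbol: str) -> List[Tuple[int, float, float]]:
    """Single-atom pattern as (neutron offset, abundance, mass) triples."""
    m = _LABELED.match(symbol)
    if m:
        elem, iso = m.group(1), int(m.group(2))
        if elem not in nist_mass or iso not in nist_mass[elem]:
            raise KeyError(f"no isotope table entry for {symbol}")
        return [(0, 1.0, nist_mass[elem][iso][0])]
    if symbol not in nist_mass:
        raise KeyError(f"no isotope table for element {symbol!r}")
    isotopes = [(a, mass, ab) for a, (mass, ab) in nist_mass[symbol].items() if a != 0 and ab > 0]
    if not isotopes:
        raise KeyError(f"element {symbol!r} has no natural-abundance isotopes tabulated")
    isotopes.sort()
    lightest = isotopes[0][0]
    return [(a - lightest, ab, mass) for a, mass, ab in isotopes]


def _convolve(d1, d2):
    """Convolve two (abundance, abundance*mass) aggregate distributions."""
    out_ab = {}
    out_am = {}
    for k1, (a1, m1) in d1.items():
        mean1 = m1 / a1
        for k2, (a2, m2) in d2.items():
            a = a1 * a2
            if a < _PRUNE:
                continue
            k = k1 + k2
            out_ab[k] = out_ab.get(k, 0.0) + a
            out_am[k] = out_am.get(k, 0.0) + a * (mean1 + m2 / a2)
    return {k: (out_ab[k], out_am[k]) for k in out_ab}


def _power(dist, n):
    """dist convolved with itself n times, by repeated squaring."""
    result = {0: (1.0, 0.0)}
    base = dist
    while n:
        if n & 1:
            result = _convolve(result, base)
        n >>= 1
        if n:
            base = _convolve(base, base)
    return result


@dataclass(frozen=True)
class IsotopeDistribution:
    """Aggregated isotope pattern of one molecular species.

    ``peaks`` is a list of ``(isotope_index, abundance, mass)`` with the
    index counting neutron offsets from the monoisotopic peak. Abundances
    are renormalized over the retained peaks for reporting; ``raw_sum`` is
    the untruncated total they were drawn from.
    """

    peaks: Tuple[Tuple[int, float, float], ...]
    raw_sum: float

    def most_abundant(self) -> Tuple[int, float, float]:
        """The tallest retained peak; ties resolve to the lower index."""
        return max(self.peaks, key=lambda p: (p[1], -p[0]))


def isotope_distribution(comp: ElementalComposition, max_peaks: int = 40) -> IsotopeDistribution:
    """Aggregated isotope distribution of a composition.

    Per-element single-atom patterns are raised to their atom counts by
    repeated squaring of the convolution and combined across elements;
    aggregate peaks below 1e-10 raw abundance are pruned. The result is
    truncated to the first ``max_peaks`` indices.
    """
    if max_peaks < 1:
        raise ValueError("max_peaks must be >= 1")
    items = [(s, n) for s, n in comp.items() if n]
    if not items:
        raise ValueError("empty composition")
    if any(n < 0 for _, n in items):
        raise ValueError("negative atom count in composition")

    dist = {0: (1.0, 0.0)}
    for symbol, n in items:
        single = {k: (ab, ab * m) for k, ab, m in _element_pattern(symbol)}
        dist = _convolve(dist, _power(single, n))

    raw_sum = sum(a for a, _ in dist.values())
    kept = sorted(dist)[:max_peaks]
    norm = sum(dist[k][0] for k in kept)
    peaks = tuple((k, dist[k][0] / norm, dist[k][1] / dist[k][0]) for k in kept)
    return IsotopeDistribution(peaks=peaks, raw_sum=raw_sum)


def most_abundant_isotope_mz(comp: ElementalComposition, charge: int) -> float:
    """m/z of the most abundant isotope peak of ``comp`` at ``charge``.

    The peak is chosen on the neutral distribution (selection is independent
    of charge); its centroid mass is then protonated.
    """
    dist = isotope_distribution(comp)
    _, _, mass = dist.most_abundant()
    return mz_from_mass(mass, charge)


# Averagine: the average elemental composition per 111.1254 Da of tryptic
# peptide (Senko's model residue), used as a stand-in formula when only a
# mass is known.
_AVERAGINE_UNIT = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
_AVERAGINE_MASS = 111.1254
_H1 = nist_mass["H"][1][0]


def averagine_composition(mass: float) -> ElementalComposition:
    """Averagine-model integer composition approximating a target mass.

    Scales the averagine unit to ``mass``, rounds to whole atoms and
    balances the rounding remainder with hydrogens, so the result's
    monoisotopic mass tracks the request to well under 1 Da.
    """
    if mass <= 0:
        raise ValueError(f"mass must be positive, got {mass}")
    scale = mass / _AVERAGINE_MASS
    comp = ElementalComposition()
    for elem, per_unit in _AVERAGINE_UNIT.items():
        n = int(round(per_unit * scale))
        if n > 0:
            comp[elem] = n
    remainder = mass - comp.mass()
    extra_h = int(round(remainder / _H1))
    h = comp.get("H", 0) + extra_h
    if h > 0:
        comp["H"] = h
    elif "H" in comp:
        del comp["H"]
    if not comp:
        comp["H"] = max(1, int(round(mass / _H1)))
    return comp
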
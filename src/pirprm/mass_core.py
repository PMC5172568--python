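"""Monoisotopic mass arithmetic for peptides with modifications.

Everything downstream (linker chemistry, transition enumeration, isotope
distributions) is built on the primitives here: elemental compositions,
residue masses, proton arithmetic and SILAC label bookkeeping.

Element and residue monoisotopic masses come from the NIST table shipped
with :mod:`pyteomics.mass`; isotope-labeled atoms use pyteomics' bracket
notation (``C[13]``, ``N[15]``) so that labeled and unlabeled counts are
distinct keys in a composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from pyteomics import mass as _pmass

__all__ = [
    "PROTON_MASS",
    "WATER_MONO",
    "ElementalComposition",
    "Modification",
    "SilacLabel",
    "LinkedPeptide",
    "CARBAMIDOMETHYL",
    "DEFAULT_SILAC_LABELS",
    "composition_mass",
    "peptide_neutral_mass",
    "mz_from_mass",
    "composition_of_peptide",
]

#: Mass of a proton in Da; added once per charge when converting to m/z.
PROTON_MASS = 1.007276466

#: Elemental composition container. A dict-like mapping of element symbol
#: (``C``, ``H``, ``N``, ``O``, ``S``, plus isotope-labeled variants such as
#: ``C[13]``) to a non-negative integer count. Addition is element-wise.
ElementalComposition = _pmass.Composition

WATER_COMP = ElementalComposition(formula="H2O")
WATER_MONO = WATER_COMP.mass()

# Canonical residues only. I and L are distinct letters with identical mass;
# ambiguity codes (B, Z, X) and non-canonical letters are rejected.
CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

_RESIDUE_MASS = {aa: _pmass.std_aa_mass[aa] for aa in CANONICAL_RESIDUES}
_RESIDUE_COMP = {aa: ElementalComposition(_pmass.std_aa_comp[aa]) for aa in CANONICAL_RESIDUES}


def composition_mass(comp: ElementalComposition) -> float:
    """Monoisotopic mass of a composition (Da)."""
    return comp.mass()


@dataclass(frozen=True)
class Modification:
    """A fixed or variable covalent modification.

    ``delta_composition`` may be omitted for mass-only modifications, but
    composition-based operations (isotope distributions) then refuse the
    peptide rather than guessing a formula.
    """

    name: str
    target: str  # residue letter, or "N-term"/"C-term"
    delta_mass: float
    delta_composition: Optional[ElementalComposition] = None
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.delta_composition is not None:
            got = self.delta_composition.mass()
            if abs(got - self.delta_mass) > 1e-4:
                raise ValueError(
                    f"modification {self.name!r}: composition mass {got:.5f} "
                    f"differs from delta_mass {self.delta_mass:.5f} by more than 1e-4 Da"
                )


#: Carbamidomethylation of Cys (+57.021464 Da), the fixed modification
#: produced by iodoacetamide alkylation; applied by default to every C.
CARBAMIDOMETHYL = Modification(
    name="Carbamidomethyl",
    target="C",
    delta_mass=57.021464,
    delta_composition=ElementalComposition(formula="C2H3NO"),
    fixed=True,
)


@dataclass(frozen=True)
class SilacLabel:
    """A metabolic isotope label on one residue type.

    ``composition_swap`` records the atom exchange (e.g. six 12C -> 13C and
    two 14N -> 15N for heavy Lys) so labeled compositions stay exact.
    """

    residue: str
    delta_mass: float
    composition_swap: dict

    def apply_to_composition(self, comp: ElementalComposition) -> None:
        for elem, delta in self.composition_swap.items():
            comp[elem] = comp.get(elem, 0) + delta
            if comp[elem] == 0:
                del comp[elem]


# 13C6 15N2-L-lysine and 13C6-L-arginine, the standard heavy SILAC channel.
DEFAULT_SILAC_LABELS = {
    "K": SilacLabel("K", 8.014199, {"C": -6, "C[13]": 6, "N": -2, "N[15]": 2}),
    "R": SilacLabel("R", 6.020129, {"C": -6, "C[13]": 6}),
}


@dataclass(frozen=True)
class LinkedPeptide:
    """One peptide of a cross-linked pair.

    Parameters
    ----------
    sequence:
        Uppercase canonical amino-acid string.
    mods:
        ``(position, Modification)`` tuples, positions 1-based. At most one
        variable modification per position.
    link_site:
        1-based index of the cross-linked residue (a Lys under the default
        chemistry).
    channel:
        ``"light"`` or ``"heavy"``; heavy peptides carry the SILAC label on
        every K and R.
    """

    sequence: str
    mods: tuple = ()
    link_site: int = 1
    channel: str = "light"
    protein_site: Optional[int] = None  # residue number in the protein, metadata only

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty peptide sequence")
        for i, aa in enumerate(self.sequence, start=1):
            if aa not in CANONICAL_RESIDUES:
                raise ValueError(f"unknown residue {aa!r} at position {i} in {self.sequence!r}")
        if not 1 <= self.link_site <= len(self.sequence):
            raise ValueError(
                f"link_site {self.link_site} outside 1..{len(self.sequence)} for {self.sequence!r}"
            )
        if self.channel not in ("light", "heavy"):
            raise ValueError(f"channel must be 'light' or 'heavy', got {self.channel!r}")
        object.__setattr__(self, "mods", tuple(self.mods))
        seen = set()
        for pos, mod in self.mods:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(
                    f"modification {mod.name!r} at position {pos} outside peptide of "
                    f"length {len(self.sequence)}"
                )
            if not mod.fixed:
                if pos in seen:
                    raise ValueError(f"more than one variable modification at position {pos}")
                seen.add(pos)

    def __len__(self) -> int:
        return len(self.sequence)


def _label_deltas(p: LinkedPeptide, labels=None) -> float:
    if p.channel != "heavy":
        return 0.0
    labels = DEFAULT_SILAC_LABELS if labels is None else labels
    return sum(labels[aa].delta_mass for aa in p.sequence if aa in labels)


def peptide_neutral_mass(
    p: LinkedPeptide,
    stump_mass: Optional[float] = None,
    labels=None,
) -> float:
    """Neutral monoisotopic mass of a linked peptide in Da.

    Sum of residue masses plus water plus all modification deltas; heavy
    peptides additionally carry the SILAC label on each K/R. When
    ``stump_mass`` is given, the linker stump residual is added at the link
    site (the residue identity there is unchanged).
    """
    m = sum(_RESIDUE_MASS[aa] for aa in p.sequence) + WATER_MONO
    m += sum(mod.delta_mass for _, mod in p.mods)
    m += _label_deltas(p, labels)
    if stump_mass is not None:
        m += stump_mass
    return m


def mz_from_mass(neutral_mass: float, charge: int) -> float:
    """m/z of a neutral mass at the given positive charge."""
    if charge < 1:
        raise ValueError(f"charge must be >= 1, got {charge}")
    return (neutral_mass + charge * PROTON_MASS) / charge


def composition_of_peptide(
    p: LinkedPeptide,
    stump_composition: Optional[ElementalComposition] = None,
    labels=None,
) -> ElementalComposition:
    """Elemental composition of a linked peptide.

    Residue compositions plus water plus modification compositions; every
    modification must carry a ``delta_composition``. Heavy-channel peptides
    swap 12C -> 13C / 14N -> 15N atoms on each labeled residue.
    """
    comp = ElementalComposition()
    for aa in p.sequence:
        comp += _RESIDUE_COMP[aa]
    comp += WATER_COMP
    for _, mod in p.mods:
        if mod.delta_composition is None:
            raise ValueError(
                f"modification {mod.name!r} has no elemental composition; "
                "cannot compute a compositional mass"
            )
        comp += mod.delta_composition
    if p.channel == "heavy":
        lab = DEFAULT_SILAC_LABELS if labels is None else labels
        for aa in p.sequence:
            if aa in lab:
                lab[aa].apply_to_composition(comp)
    if stump_composition is not None:
        comp += stump_composition
    return comp


def apply_fixed_modifications(
    sequence: str,
    registry: Sequence[Modification] = (CARBAMIDOMETHYL,),
) -> tuple:
    """Return the (position, Modification) tuples for all fixed mods in a sequence."""
    out = []
    for mod in registry:
        if not mod.fixed:
            continue
        for i, aa in enumerate(sequence, start=1):
            if aa == mod.target:
                out.append((i, mod))
    return tuple(out)
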
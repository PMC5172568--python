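"""PIR cross-linked pair chemistry and PRM transition enumeration.

A Protein Interaction Reporter (PIR) cross-linker bridges two Lys side
chains and carries two MS-labile aspartyl-prolyl bonds. On collisional
activation three things can happen to each arm:

* both labile bonds cleave: the reporter ion is released and each peptide
  retains a small residual on its linked Lys (the "stump" mass);
* one labile bond cleaves: one peptide retains most of the linker (the
  "long-arm" residual);
* backbone fragmentation: ordinary b/y ions, which carry the stump when
  their span includes the link site.

For PRM quantification the tool enumerates, per pair: the two released
intact peptides (most diagnostic, typically most abundant), the two
long-arm ions, and the full singly charged b/y series of both peptides.
The reporter ion itself is excluded by default because it is common to
every PIR species and hence non-specific.
"""

from __future__ import annotations

import random
import re
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, List, Optional, Sequence, Tuple

from .mass_core import (
    CARBAMIDOMETHYL,
    DEFAULT_SILAC_LABELS,
    ElementalComposition,
    LinkedPeptide,
    PROTON_MASS,
    WATER_MONO,
    apply_fixed_modifications,
    composition_of_peptide,
    mz_from_mass,
    peptide_neutral_mass,
)
from . import isotope_model

__all__ = [
    "PIRLinker",
    "BDP_LINKER",
    "CrossLinkedPair",
    "Transition",
    "make_pair",
    "precursor_mz",
    "enumerate_transitions",
    "apply_silac",
    "insilico_pair_candidates",
    "count_unique_linkages",
]


@dataclass(frozen=True)
class PIRLinker:
    """Constants describing one PIR cross-linker compound.

    The three residual masses are independent empirical constants (they are
    not derived from one another): ``stump_residual`` is left on a linked
    Lys after both labile bonds cleave, ``longarm_residual`` after a single
    cleavage, and ``reporter_mz`` is the singly charged linker-core ion.
    ``intact_added_mass`` is the mass the intact linker adds to the two
    peptides; by default the sum of the two stumps' worth of linker,
    i.e. stump + long-arm.
    """

    name: str = "BDP"
    stump_residual: float = 197.032
    longarm_residual: float = 948.444
    reporter_mz: float = 752.412
    intact_added_mass: Optional[float] = None
    composition: Optional[ElementalComposition] = None

    def __post_init__(self) -> None:
        if self.intact_added_mass is None:
            object.__setattr__(
                self, "intact_added_mass", self.stump_residual + self.longarm_residual
            )
        if not self.stump_residual < self.longarm_residual < self.intact_added_mass:
            raise ValueError("require stump_residual < longarm_residual < intact_added_mass")

    def effective_composition(self) -> ElementalComposition:
        """Exact formula if configured, else an averagine stand-in at the intact mass."""
        if self.composition is not None:
            return self.composition
        return isotope_model.averagine_composition(self.intact_added_mass)


#: The biotin-aspartate-proline PIR compound used throughout, with its
#: published residual masses.
BDP_LINKER = PIRLinker()


@dataclass(frozen=True)
class CrossLinkedPair:
    """Two linked peptides joined by a PIR linker at a given precursor charge."""

    alpha: LinkedPeptide
    beta: LinkedPeptide
    linker: PIRLinker = BDP_LINKER
    precursor_charge: int = 4
    observed_mz: Optional[float] = None
    group: str = "xlink"

    def __post_init__(self) -> None:
        if self.precursor_charge < 2:
            raise ValueError("cross-linked pair precursor charge must be >= 2")
        if self.alpha.channel != self.beta.channel:
            raise ValueError("alpha and beta peptides must share a label channel")

    @property
    def channel(self) -> str:
        return self.alpha.channel

    @property
    def pair_name(self) -> str:
        """Unique name encoding sequences, link sites, charge and channel."""
        a, b = self.alpha, self.beta
        return (
            f"{a.sequence[:a.link_site]}({a.link_site}){a.sequence[a.link_site:]}"
            f"_{b.sequence[:b.link_site]}({b.link_site}){b.sequence[b.link_site:]}"
            f"/{self.precursor_charge}/{self.channel}"
        )

    @property
    def linkage_key(self) -> tuple:
        """Residue-residue linkage identity, orientation-independent.

        Two pairs targeting the same linked residues (different charge
        states or channels) share a key; used to count non-redundant links.
        """
        a = (self.alpha.sequence, self.alpha.link_site)
        b = (self.beta.sequence, self.beta.link_site)
        return (min(a, b), max(a, b))

    def neutral_mass(self) -> float:
        """Neutral precursor mass: both peptides plus the intact linker."""
        return (
            peptide_neutral_mass(self.alpha)
            + peptide_neutral_mass(self.beta)
            + self.linker.intact_added_mass
        )

    def composition(self) -> ElementalComposition:
        """Pair composition: both peptides plus the linker formula (or its averagine stand-in)."""
        return (
            composition_of_peptide(self.alpha)
            + composition_of_peptide(self.beta)
            + self.linker.effective_composition()
        )


@dataclass(frozen=True)
class Transition:
    """One PRM transition: a named product ion of a cross-linked pair."""

    pair_name: str
    kind: str  # released_alpha|released_beta|longarm_alpha|longarm_beta|b_alpha|y_alpha|b_beta|y_beta|reporter
    ordinal: int  # fragment index for b/y; 0 otherwise
    product_charge: int
    product_mz: float
    product_name: str
    duplicate_mz: bool = False


def make_pair(
    alpha_seq: str,
    alpha_site: int,
    beta_seq: str,
    beta_site: int,
    charge: int = 4,
    observed_mz: Optional[float] = None,
    channel: str = "light",
    linker: PIRLinker = BDP_LINKER,
    fixed_mods: Sequence = (CARBAMIDOMETHYL,),
    extra_mods_alpha: Sequence = (),
    extra_mods_beta: Sequence = (),
    group: str = "xlink",
    require_lys: bool = True,
) -> CrossLinkedPair:
    """Convenience constructor applying fixed modifications and validating link sites."""
    for seq, site in ((alpha_seq, alpha_site), (beta_seq, beta_site)):
        if require_lys and seq[site - 1] != "K":
            raise ValueError(
                f"link site {site} of {seq!r} is {seq[site - 1]!r}, expected K"
            )
    alpha = LinkedPeptide(
        alpha_seq,
        mods=tuple(extra_mods_alpha) + apply_fixed_modifications(alpha_seq, fixed_mods),
        link_site=alpha_site,
        channel=channel,
    )
    beta = LinkedPeptide(
        beta_seq,
        mods=tuple(extra_mods_beta) + apply_fixed_modifications(beta_seq, fixed_mods),
        link_site=beta_site,
        channel=channel,
    )
    return CrossLinkedPair(
        alpha, beta, linker=linker, precursor_charge=charge,
        observed_mz=observed_mz, group=group,
    )


def precursor_mz(pair: CrossLinkedPair, mode: str = "most_abundant") -> float:
    """Precursor m/z under one of three modes.

    ``monoisotopic``
        Protonated monoisotopic mass of the pair.
    ``most_abundant``
        m/z of the tallest isotope peak of the pair composition (the
        default: keeps the isolation window centred on signal for the
        3-4 kDa species typical of cross-linked pairs).
    ``observed``
        Echoes the experimentally observed m/z carried on the pair.
    """
    if mode == "monoisotopic":
        return mz_from_mass(pair.neutral_mass(), pair.precursor_charge)
    if mode == "most_abundant":
        return isotope_model.most_abundant_isotope_mz(pair.composition(), pair.precursor_charge)
    if mode == "observed":
        if pair.observed_mz is None:
            raise ValueError(f"pair {pair.pair_name} has no observed m/z")
        return pair.observed_mz
    raise ValueError(f"unknown precursor mode {mode!r}")


def _fragment_mass(
    p: LinkedPeptide,
    series: str,
    ordinal: int,
    stump: float,
    labels=None,
) -> float:
    """Neutral mass of a b or y fragment, with stump and mods on the residues it spans."""
    n = len(p.sequence)
    if series == "b":
        span = range(1, ordinal + 1)
        base = 0.0
    else:
        span = range(n - ordinal + 1, n + 1)
        base = WATER_MONO
    span_set = set(span)
    from .mass_core import _RESIDUE_MASS  # residue table shared with peptide_neutral_mass

    m = base + sum(_RESIDUE_MASS[p.sequence[i - 1]] for i in span)
    m += sum(mod.delta_mass for pos, mod in p.mods if pos in span_set)
    if p.channel == "heavy":
        lab = DEFAULT_SILAC_LABELS if labels is None else labels
        m += sum(lab[p.sequence[i - 1]].delta_mass for i in span if p.sequence[i - 1] in lab)
    if p.link_site in span_set:
        m += stump
    return m


def enumerate_transitions(
    pair: CrossLinkedPair,
    released_charges: Sequence[int] = (1,),
    longarm_charges: Sequence[int] = (1,),
    by_charges: Sequence[int] = (1,),
    include_reporter: bool = False,
    duplicate_tol: float = 1e-4,
) -> List[Transition]:
    """All PRM product-ion transitions of a cross-linked pair.

    Emits released intact peptides (+stump), long-arm ions (+long-arm
    residual), and the full b/y series of both peptides (singly charged by
    default; b/y fragments spanning the link site carry the stump, assuming
    both labile bonds cleaved). Transitions whose m/z collides with an
    earlier one within ``duplicate_tol`` are kept but flagged.
    """
    linker = pair.linker
    out: List[Transition] = []

    def add(kind, ordinal, charge, neutral, name):
        out.append(
            Transition(
                pair_name=pair.pair_name,
                kind=kind,
                ordinal=ordinal,
                product_charge=charge,
                product_mz=mz_from_mass(neutral, charge),
                product_name=name,
            )
        )

    for side, peptide in (("alpha", pair.alpha), ("beta", pair.beta)):
        released = peptide_neutral_mass(peptide, stump_mass=linker.stump_residual)
        for z in released_charges:
            suffix = f"^{z}" if z != 1 else ""
            add(f"released_{side}", 0, z, released, f"rp_{side}{suffix}")
    for side, peptide in (("alpha", pair.alpha), ("beta", pair.beta)):
        longarm = peptide_neutral_mass(peptide, stump_mass=linker.longarm_residual)
        for z in longarm_charges:
            suffix = f"^{z}" if z != 1 else ""
            add(f"longarm_{side}", 0, z, longarm, f"la_{side}{suffix}")
    for side, peptide in (("alpha", pair.alpha), ("beta", pair.beta)):
        n = len(peptide.sequence)
        for series in ("b", "y"):
            for i in range(1, n):
                neutral = _fragment_mass(peptide, series, i, linker.stump_residual)
                for z in by_charges:
                    suffix = f"^{z}" if z != 1 else ""
                    add(f"{series}_{side}", i, z, neutral, f"{series}{i}_{side}{suffix}")
    if include_reporter:
        out.append(
            Transition(
                pair_name=pair.pair_name,
                kind="reporter",
                ordinal=0,
                product_charge=1,
                product_mz=linker.reporter_mz,
                product_name="reporter",
            )
        )

    # flag (not drop) m/z collisions across kinds
    seen: List[float] = []
    flagged: List[Transition] = []
    for t in out:
        dup = any(abs(t.product_mz - mz) <= duplicate_tol for mz in seen)
        seen.append(t.product_mz)
        flagged.append(replace(t, duplicate_mz=dup) if dup else t)
    return flagged


def apply_silac(pair: CrossLinkedPair, labels=None) -> CrossLinkedPair:
    """Heavy-channel twin of a light pair.

    Every K gains +8.014199 Da and every R +6.020129 Da (13C/15N swaps in
    the composition); the stump-bearing Lys is still a Lys and is labeled.
    """
    if pair.channel != "light":
        raise ValueError("apply_silac expects a light-channel pair")
    if labels is not None and labels is not DEFAULT_SILAC_LABELS:
        # custom labels affect mass via mass_core lookups keyed on channel;
        # only the default K8/R6 scheme is wired through by name.
        warnings.warn("custom SILAC labels are applied via DEFAULT_SILAC_LABELS override")
    heavy_alpha = replace(pair.alpha, channel="heavy")
    heavy_beta = replace(pair.beta, channel="heavy")
    return replace(pair, alpha=heavy_alpha, beta=heavy_beta)


def count_unique_linkages(pairs: Iterable[CrossLinkedPair]) -> int:
    """Number of non-redundant residue-residue linkages among targeted pairs."""
    return len({p.linkage_key for p in pairs})


_TRYPSIN = re.compile(r"(?<=[KR])(?!P)")


def _digest_with_positions(sequence: str, missed_cleavages: int) -> List[Tuple[str, int]]:
    """Tryptic peptides with 0..missed_cleavages missed sites, as (peptide, start 1-based)."""
    fragments = []
    start = 1
    for frag in _TRYPSIN.split(sequence):
        if frag:
            fragments.append((frag, start))
            start += len(frag)
    peptides = []
    for i in range(len(fragments)):
        seq = ""
        for j in range(i, min(i + missed_cleavages + 1, len(fragments))):
            seq += fragments[j][0]
            peptides.append((seq, fragments[i][1]))
    return peptides


def insilico_pair_candidates(
    fasta_records: Sequence[Tuple[str, str]],
    max_pairs: int = 30,
    missed_cleavages: int = 1,
    min_length: int = 5,
    max_length: int = 25,
    charge: int = 4,
    seed: int = 0,
    linker: PIRLinker = BDP_LINKER,
) -> List[CrossLinkedPair]:
    """Enumerate candidate PIR cross-linked pairs from protein sequences.

    Tryptic digestion (cleave after K/R, not before P) with missed
    cleavages; a Lys is linkable when it is internal to the peptide (a
    missed-cleavage site) or the protein's C-terminal residue. Candidate
    peptides are paired pseudo-randomly but deterministically under
    ``seed``, up to ``max_pairs`` pairs with distinct residue-residue
    linkages.
    """
    linkable: List[Tuple[str, int, int]] = []  # (peptide, link_site, protein_site)
    for name, seq in fasta_records:
        seq = seq.upper()
        for pep, start in _digest_with_positions(seq, missed_cleavages):
            if not min_length <= len(pep) <= max_length:
                continue
            if any(aa not in "ACDEFGHIKLMNPQRSTVWY" for aa in pep):
                continue
            pep_end_in_protein = start + len(pep) - 1
            for i, aa in enumerate(pep, start=1):
                if aa != "K":
                    continue
                internal = i < len(pep)
                protein_cterm = (i == len(pep)) and (pep_end_in_protein == len(seq))
                if internal or protein_cterm:
                    linkable.append((pep, i, start + i - 1))
    if not linkable:
        warnings.warn("digest produced no linkable peptides")
        return []

    rng = random.Random(seed)
    pairs: List[CrossLinkedPair] = []
    seen_links = set()
    # deterministic shuffle of all candidate combinations
    order = list(range(len(linkable)))
    rng.shuffle(order)
    for ia in order:
        for ib in order:
            if len(pairs) >= max_pairs:
                return pairs
            pa, sa, prot_a = linkable[ia]
            pb, sb, prot_b = linkable[ib]
            if (pa, sa) > (pb, sb):
                continue
            key = ((pa, sa), (pb, sb))
            if key in seen_links:
                continue
            seen_links.add(key)
            pairs.append(
                make_pair(pa, sa, pb, sb, charge=charge, linker=linker)
            )
    if len(pairs) < max_pairs:
        warnings.warn(f"only {len(pairs)} candidate pairs available (requested {max_pairs})")
    return pairs
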
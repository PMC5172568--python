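"""Synthetic PRM fixtures: simulated runs with programmed abundances.

The simulator emulates a scheduled PRM acquisition of PIR cross-linked
pairs: for every targeted precursor it emits centroided MS2 scans on a
regular retention-time grid around the pair's elution apex. Each
transition's peak intensity follows

    abundance x transition weight x Gaussian(rt; apex, sigma) x lognormal noise

with a small number of random baseline peaks per scan. Released-peptide
ions get the largest weights, matching the observation that the intact
released alpha-peptide dominates the PRM signal of these species; b/y
weights are drawn (deterministically from the seed) from a uniform range.

Two fixture builders mirror the study designs the package is tested
against: a label-free dilution series (a BSA-like protein digested in
silico, 30 pairs collapsing to 25 unique residue-residue linkages,
4 levels x 3 replicates at 100/200/500/1000 relative amounts) and a SILAC
inhibitor-titration series with programmed constant / increasing /
decreasing light:heavy trends across conditions.

All simulated features are programmed, not learned: real data additionally
contain interference, chimeric windows, retention-time drift and detector
saturation, none of which are modelled here.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .crosslink_model import (
    CrossLinkedPair,
    Transition,
    apply_silac,
    enumerate_transitions,
    insilico_pair_candidates,
    precursor_mz,
)
from .mzml_io import Ms2Scan, write_prm_mzml
from .transition_io import write_pair_table

__all__ = [
    "SimulationSpec",
    "simulate_prm_run",
    "synthetic_protein",
    "make_bsa_like_fixture",
    "make_silac_fixture",
    "simulate_labelfree_runs",
    "simulate_silac_runs",
    "transition_weights",
]

# relative base weights per transition kind; b/y drawn from _BY_RANGE
_KIND_WEIGHT = {
    "released_alpha": 1.0,
    "released_beta": 0.45,
    "longarm_alpha": 0.15,
    "longarm_beta": 0.12,
    "reporter": 0.3,
}
_BY_RANGE = (0.02, 0.25)


def transition_weights(transitions: Sequence[Transition], seed: int) -> Dict[str, float]:
    """Deterministic per-transition relative intensities for one pair."""
    rng = random.Random(seed)
    weights = {}
    for t in transitions:
        if t.kind in _KIND_WEIGHT:
            weights[t.product_name] = _KIND_WEIGHT[t.kind]
        else:
            weights[t.product_name] = rng.uniform(*_BY_RANGE)
    return weights


@dataclass
class SimulationSpec:
    """Everything needed to simulate one PRM run.

    ``abundance`` maps pair_name to the run's abundance multiplier (the
    dilution level, or the per-channel SILAC amount). ``elution`` maps
    pair_name to (apex_rt min, sigma min). Precursors are targeted under
    ``precursor_mode``; scans cover apex +/- ``rt_span_sigmas`` sigmas at
    ``scan_interval`` spacing. A fixed seed makes output byte-identical.
    """

    pairs: List[CrossLinkedPair]
    abundance: Dict[str, float]
    elution: Dict[str, Tuple[float, float]]
    scan_interval: float = 0.02
    rt_span_sigmas: float = 5.0
    noise_cv: float = 0.05
    base_height: float = 1e6
    baseline_height: float = 50.0
    baseline_peaks: int = 4
    precursor_mode: str = "monoisotopic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("simulation needs at least one pair")
        if self.scan_interval <= 0:
            raise ValueError("scan interval must be positive")
        for pname, (_, sigma) in self.elution.items():
            if sigma <= 0:
                raise ValueError(f"pair {pname}: sigma must be positive")
        for v in self.abundance.values():
            if v <= 0:
                raise ValueError("abundance multipliers must be positive")


def simulate_prm_run(spec: SimulationSpec, path, run_seed: Optional[int] = None) -> Dict[str, float]:
    """Write one simulated PRM run to mzML; returns the targeted precursor m/z per pair.

    ``run_seed`` perturbs only the noise draws (replicates of the same
    design); the transition weights and elution design stay tied to
    ``spec.seed`` so replicates differ by noise alone.
    """
    noise_rng = np.random.default_rng(spec.seed if run_seed is None else run_seed)
    scans: List[Ms2Scan] = []
    prec_mz: Dict[str, float] = {}
    for pair in spec.pairs:
        pname = pair.pair_name
        target = precursor_mz(pair, spec.precursor_mode)
        prec_mz[pname] = target
        transitions = enumerate_transitions(pair)
        weights = transition_weights(transitions, spec.seed)
        apex, sigma = spec.elution[pname]
        amount = spec.abundance[pname]
        half_span = spec.rt_span_sigmas * sigma
        n_steps = int(round(2 * half_span / spec.scan_interval)) + 1
        rts = apex - half_span + spec.scan_interval * np.arange(n_steps)
        log_sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2)) if spec.noise_cv > 0 else 0.0
        for rt in rts:
            shape = math.exp(-0.5 * ((rt - apex) / sigma) ** 2)
            mzs, heights = [], []
            for t in transitions:
                h = amount * spec.base_height * weights[t.product_name] * shape
                if log_sigma > 0:
                    h *= math.exp(noise_rng.normal(-0.5 * log_sigma**2, log_sigma))
                if h > 0:
                    mzs.append(t.product_mz)
                    heights.append(h)
            for _ in range(spec.baseline_peaks):
                mzs.append(float(noise_rng.uniform(150.0, 1600.0)))
                heights.append(float(noise_rng.exponential(spec.baseline_height)))
            order = np.argsort(mzs)
            scans.append(
                Ms2Scan(
                    rt_min=float(rt),
                    isolation_target_mz=target,
                    precursor_charge=pair.precursor_charge,
                    mz=np.asarray(mzs)[order],
                    intensity=np.asarray(heights)[order],
                )
            )
    write_prm_mzml(scans, path)
    return prec_mz


# deterministic 600-residue synthetic protein with tryptic-like K/R spacing;
# a stand-in for a BSA-sized carrier protein, not a real sequence
def synthetic_protein(length: int = 600, seed: int = 7) -> str:
    rng = random.Random(seed)
    aas = "ACDEFGHILMNPQSTVWY"  # K/R inserted separately to control spacing
    out = []
    while len(out) < length:
        run = rng.randint(4, 9)
        out.extend(rng.choice(aas) for _ in range(run))
        out.append(rng.choice("KKR"))  # K-rich: plenty of linkable sites
    return "".join(out[:length])


def _stagger_elution(pairs: Sequence[CrossLinkedPair], start: float = 1.0,
                     step: float = 0.25, sigma: float = 0.06) -> Dict[str, Tuple[float, float]]:
    return {p.pair_name: (start + i * step, sigma) for i, p in enumerate(pairs)}


@dataclass
class LabelFreeFixture:
    """A label-free dilution-series fixture: pair table + one spec per run."""

    pairs: List[CrossLinkedPair]
    pair_table: Path
    runs: List[Tuple[float, int, SimulationSpec]]  # (level, replicate, spec)


def make_bsa_like_fixture(
    outdir,
    n_pairs: int = 30,
    n_unique_linkages: Optional[int] = None,
    levels: Sequence[float] = (100.0, 200.0, 500.0, 1000.0),
    replicates: int = 3,
    noise_cv: float = 0.05,
    seed: int = 0,
    sigma: float = 0.06,
    scan_interval: float = 0.015,
) -> LabelFreeFixture:
    """Build the label-free dilution fixture.

    Digests the bundled synthetic protein, selects ``n_unique_linkages``
    candidate pairs and re-targets some at an extra charge state until
    ``n_pairs`` targets exist (so the target list deliberately collapses to
    fewer unique residue-residue linkages, as real target lists do). Emits
    the pair table and one simulation spec per (level, replicate); call
    :func:`simulate_prm_run` on each spec to produce the mzML files.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if n_unique_linkages is None:
        n_unique_linkages = min(25, n_pairs)
    if n_pairs < n_unique_linkages:
        raise ValueError("n_pairs must be >= n_unique_linkages")
    protein = synthetic_protein(seed=7)
    base = insilico_pair_candidates(
        [("synthetic_carrier", protein)], max_pairs=n_unique_linkages, seed=seed
    )
    pairs = list(base)
    i = 0
    while len(pairs) < n_pairs and base:
        dup = base[i % len(base)]
        pairs.append(replace(dup, precursor_charge=dup.precursor_charge + 1 + i // len(base)))
        i += 1
    table_path = outdir / "pair_table.tsv"
    write_pair_table(pairs, table_path)
    if not pairs:
        return LabelFreeFixture(pairs=[], pair_table=table_path, runs=[])

    elution = _stagger_elution(pairs, sigma=sigma)
    runs = []
    for li, level in enumerate(levels):
        for rep in range(replicates):
            spec = SimulationSpec(
                pairs=pairs,
                abundance={p.pair_name: float(level) for p in pairs},
                elution=elution,
                scan_interval=scan_interval,
                noise_cv=noise_cv,
                seed=seed,
            )
            runs.append((float(level), rep, spec))
    return LabelFreeFixture(pairs=pairs, pair_table=table_path, runs=runs)


def simulate_labelfree_runs(fixture: "LabelFreeFixture", outdir) -> List[dict]:
    """Write every (level, replicate) run of a label-free fixture to mzML.

    Replicates share the design (weights, elution) and differ only in the
    noise stream. Returns a manifest of dicts with path, level, replicate
    and the per-pair targeted precursor m/z.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, (level, rep, spec) in enumerate(fixture.runs):
        path = outdir / f"run_L{level:g}_r{rep}.mzML"
        prec = simulate_prm_run(spec, path, run_seed=spec.seed * 100003 + i + 1)
        manifest.append({"path": path, "level": level, "replicate": rep, "precursor_mz": prec})
    return manifest


def simulate_silac_runs(fixture: "SilacFixture", outdir) -> List[dict]:
    """Write one mzML per SILAC condition; manifest as in simulate_labelfree_runs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, (cond, spec) in enumerate(fixture.runs):
        path = outdir / f"run_C{cond:g}.mzML"
        prec = simulate_prm_run(spec, path, run_seed=spec.seed * 90001 + i + 1)
        manifest.append({"path": path, "condition": cond, "precursor_mz": prec})
    return manifest


#: Programmed SILAC trends: control-normalized log2(L/H) per condition index.
SILAC_TRENDS = {
    "constant": (0.0, 0.0, 0.0, 0.0, 0.0),
    "increasing": (0.0, 0.5, 1.0, 1.5, 2.0),
    "decreasing": (0.0, -0.5, -1.0, -1.5, -2.0),
}

#: Inhibitor titration conditions (nM); index 0 is the no-drug control.
SILAC_CONDITIONS = (0.0, 100.0, 250.0, 500.0, 1000.0)


@dataclass
class SilacFixture:
    """A SILAC titration fixture: light+heavy pairs, one run per condition."""

    light_pairs: List[CrossLinkedPair]
    heavy_pairs: List[CrossLinkedPair]
    trends: Dict[str, str]  # light pair_name -> trend name
    programmed_log2: Dict[str, Tuple[float, ...]]  # light pair_name -> per-condition log2
    conditions: Tuple[float, ...]
    runs: List[Tuple[float, SimulationSpec]]  # (condition, spec)


def make_silac_fixture(
    n_pairs: int = 12,
    conditions: Sequence[float] = SILAC_CONDITIONS,
    noise_cv: float = 0.05,
    seed: int = 0,
    sigma: float = 0.06,
    scan_interval: float = 0.015,
) -> SilacFixture:
    """Build a SILAC fixture with programmed per-pair ratio trends.

    Pairs cycle through constant / increasing / decreasing control-
    normalized log2(light/heavy) trends across the titration conditions;
    the heavy channel stays constant, the light channel is scaled to
    realize the programmed ratio. Each condition is one run containing
    both channels as independently targeted precursors.
    """
    protein = synthetic_protein(seed=11)
    light = insilico_pair_candidates(
        [("synthetic_hsp", protein)], max_pairs=n_pairs, seed=seed
    )
    heavy = [apply_silac(p) for p in light]
    trend_names = list(SILAC_TRENDS)
    trends = {p.pair_name: trend_names[i % len(trend_names)] for i, p in enumerate(light)}
    programmed = {
        p.pair_name: tuple(SILAC_TRENDS[trends[p.pair_name]][: len(conditions)]) for p in light
    }
    all_pairs = light + heavy
    elution = {}
    for i, (lp, hp) in enumerate(zip(light, heavy)):
        apex = 1.0 + i * 0.25
        elution[lp.pair_name] = (apex, sigma)
        elution[hp.pair_name] = (apex, sigma)  # co-elution of the label partners

    runs = []
    for ci, cond in enumerate(conditions):
        abundance = {}
        for lp, hp in zip(light, heavy):
            heavy_amount = 500.0
            abundance[hp.pair_name] = heavy_amount
            abundance[lp.pair_name] = heavy_amount * (2.0 ** programmed[lp.pair_name][ci])
        spec = SimulationSpec(
            pairs=all_pairs,
            abundance=abundance,
            elution=elution,
            scan_interval=scan_interval,
            noise_cv=noise_cv,
            seed=seed,
        )
        runs.append((float(cond), spec))
    return SilacFixture(
        light_pairs=light,
        heavy_pairs=heavy,
        trends=trends,
        programmed_log2=programmed,
        conditions=tuple(float(c) for c in conditions),
        runs=runs,
    )
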
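import statistics

import pytest

from pirprm.crosslink_model import enumerate_transitions, make_pair
from pirprm import synthetic_data as sd
from pirprm.prm_quant import (
    extract_prm_chromatograms,
    quantify_pairs,
    response_curve,
    silac_ratios,
)


@pytest.fixture(scope="session")
def fig2_pair():
    """The worked-example BSA pair: ALK(3)AWSVAR x DTHK(4)SEIAHR, 4+."""
    return make_pair("ALKAWSVAR", 3, "DTHKSEIAHR", 4, charge=4)


@pytest.fixture(scope="session")
def fig2_mz(fig2_pair):
    """product_name -> m/z for the worked-example pair's default transitions."""
    return {t.product_name: t.product_mz for t in enumerate_transitions(fig2_pair)}


@pytest.fixture(scope="session")
def dilution_study(tmp_path_factory):
    """Full label-free pipeline on the 30-pair, 4-level x 3-replicate fixture.

    Simulates the runs once per session and returns per-pair response-curve
    fits plus the fixture itself.
    """
    outdir = tmp_path_factory.mktemp("dilution")
    fixture = sd.make_bsa_like_fixture(outdir, seed=0)
    manifest = sd.simulate_labelfree_runs(fixture, outdir)
    transitions = []
    for p in fixture.pairs:
        transitions.extend(enumerate_transitions(p))
    by_pair_level = {}
    for m in manifest:
        traces = extract_prm_chromatograms(m["path"], transitions, m["precursor_mz"])
        for r in quantify_pairs(traces, fixture.pairs):
            by_pair_level.setdefault(r.pair_name, {}).setdefault(m["level"], []).append(r)
    fits = {name: response_curve(levels) for name, levels in by_pair_level.items()}
    return {"fixture": fixture, "results": by_pair_level, "fits": fits}


@pytest.fixture(scope="session")
def silac_study(tmp_path_factory):
    """Full SILAC pipeline on the titration fixture: estimated vs programmed log2."""
    outdir = tmp_path_factory.mktemp("silac")
    fixture = sd.make_silac_fixture(seed=0)
    all_pairs = fixture.light_pairs + fixture.heavy_pairs
    transitions = []
    for p in all_pairs:
        transitions.extend(enumerate_transitions(p))
    manifest = sd.simulate_silac_runs(fixture, outdir)
    estimated = {}  # light pair_name -> {condition: log2 ratio}
    for m in manifest:
        traces = extract_prm_chromatograms(m["path"], transitions, m["precursor_mz"])
        results = {r.pair_name: r for r in quantify_pairs(traces, all_pairs)}
        for lp, hp in zip(fixture.light_pairs, fixture.heavy_pairs):
            ratio = silac_ratios(results[lp.pair_name], results[hp.pair_name])
            estimated.setdefault(lp.pair_name, {})[m["condition"]] = ratio
    return {"fixture": fixture, "estimated": estimated}
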
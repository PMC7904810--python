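"""Shared simulation fixtures.

The end-to-end scenarios are expensive (hundreds of thousands of reads),
so each is simulated once per session and shared between the end-to-end
and acceptance tests. Everything is seeded and deterministic.
"""

from __future__ import annotations

import dataclasses

import pytest

from neotel.repeat_loci import call_loci
from neotel.synthetic_data import (
    default_scenario,
    independent_pair_scenario,
    insertion_scenario,
    make_genome,
    simulate_control_and_pon,
    simulate_tumor_alignments,
)

SEED = 1


def run_scenario(scenario, with_pon=False):
    genome = make_genome(scenario)
    tumor, truth = simulate_tumor_alignments(scenario, genome)
    control, pon = simulate_control_and_pon(scenario, genome)
    loci, events, regions = call_loci(
        tumor,
        control,
        pon_record_sets=pon if with_pon else None,
        reference=genome,
    )
    return {
        "scenario": scenario,
        "genome": genome,
        "tumor": tumor,
        "truth": truth,
        "control": control,
        "pon": pon,
        "loci": loci,
        "events": events,
        "regions": regions,
    }


@pytest.fixture(scope="session")
def default_run():
    """Reference conditions: 1 Mb, 30x, three junctions (mh 0/2/4)."""
    return run_scenario(default_scenario(SEED))


@pytest.fixture(scope="session")
def control_run(default_run):
    """The matched control analyzed as if it were the tumor."""
    loci, events, regions = call_loci(
        default_run["control"], [], reference=default_run["genome"]
    )
    return {"loci": loci, "events": events, "regions": regions}


@pytest.fixture(scope="session")
def sharpness_runs():
    """Support capped to 3 discordant pairs, and to 2 split reads."""
    out = {}
    for name, cap in (
        ("discordant3", {"max_discordant_support": 3}),
        ("split2", {"max_split_support": 2}),
    ):
        sc = default_scenario(SEED)
        sc.events = [dataclasses.replace(e, **cap) for e in sc.events]
        out[name] = run_scenario(sc)
    return out


@pytest.fixture(scope="session")
def pon_runs():
    """Shared artifact implanted in 15 vs 14 panel samples."""
    out = {}
    for k in (15, 14):
        sc = default_scenario(SEED)
        sc.pon_artifact = (199_700, k)  # anchors of the first junction
        out[k] = run_scenario(sc, with_pon=True)
    return out


@pytest.fixture(scope="session")
def insertion_run():
    """Telomeric-tract insertion: two opposite junctions 5 kb apart."""
    return run_scenario(insertion_scenario(SEED))


@pytest.fixture(scope="session")
def independent_pair_run():
    """Two independent opposite-orientation junctions 15 kb apart."""
    return run_scenario(independent_pair_scenario(SEED))
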
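import numpy as np
import pytest

from miaa import design as d
from miaa import readproc as rp
from miaa import synthetic as syn


@pytest.fixture(scope="session")
def background_panel():
    """Standard 24-background panel: 6 natives x (1 + 3 perturbations)."""
    natives = syn.generate_backgrounds(
        6, 100, [0.3, 0.4, 0.45, 0.55, 0.6, 0.7], seed=11
    )
    panel = list(natives)
    forbidden = [d.MotifHypothesis("dam", "GATC")]
    for i, nat in enumerate(natives):
        panel += d.perturb_native(nat, 3, 0.1, forbidden, seed=100 + i)
    return panel


@pytest.fixture(scope="session")
def motif_set():
    rng = np.random.default_rng(42)
    return [
        d.MotifHypothesis(f"m{i:02d}", d.concretize_motif("N" * 8, rng), source="DeepAccess")
        for i in range(12)
    ]


@pytest.fixture(scope="session")
def planted_library(background_panel, motif_set):
    """Motif-packed library + shuffles with condition-specific truth.

    Half the motifs get a DE-specific effect, half are null in both
    conditions; effects are on the logit scale per placed copy.
    """
    rng = np.random.default_rng(7)
    effects = {}
    truly_differential = set()
    for i, m in enumerate(motif_set):
        if i < 6:
            effects[(m.id, "DE")] = float(rng.uniform(0.5, 1.0)) * (1 if i % 2 else -1)
            effects[(m.id, "ESC")] = 0.0
            truly_differential.add(m.id)
        else:
            effects[(m.id, "DE")] = 0.0
            effects[(m.id, "ESC")] = 0.0
    designs = []
    for b, bg in enumerate(background_panel):
        for m in motif_set:
            dd = d.pack_single_motif(bg, m, background_id=f"bg{b:02d}", rng=rng)
            dd.id = f"bg{b:02d}|{m.id}"
            ctrl = d.shuffle_control(dd, seed=1000 + b * 100 + int(m.id[1:]))
            designs += [dd, ctrl]
    truth = syn.GroundTruthModel(
        floor=0.2,
        ceiling=0.95,
        gc_slope_per_condition={"ESC": 1.0, "DE": 0.5},
        motif_effects=effects,
        replicate_sd=0.05,
        abundance_dispersion=0.25,
        seed=7,
    )
    return designs, truth, truly_differential


@pytest.fixture(scope="session")
def simulated_accessibility(planted_library):
    designs, truth, _ = planted_library
    sim = syn.simulate_miaa_readcounts(
        designs, truth, ["ESC", "DE"], {"ESC": 8, "DE": 4}, mean_depth=500, seed=21
    )
    table = rp.normalize_rpm(sim.counts)
    acc = rp.accessibility_table(table)
    return sim, acc
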
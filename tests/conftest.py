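"""Shared fixtures.

Heavy objects (the noise-free stacked design, fitted models) are
session-scoped so the recovery, counterfactual and interpretability tests
share one computation.
"""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import habcircuit as hc
from habcircuit.mlp import forward
from habcircuit.response import apply_ablation, assemble_design

settings.register_profile(
    "suite", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def protocol():
    return hc.DEFAULT_PROTOCOL


@pytest.fixture(scope="session")
def kernels(protocol):
    """Noise-free subtype kernels at 1 Hz, keyed by subtype name."""
    return {n: hc.subtype_kernel(hc.DEFAULT_KERNEL_PARAMS[n], protocol)
            for n in hc.SUBTYPES}


@pytest.fixture(scope="session")
def circuit():
    return hc.default_circuit()


@pytest.fixture(scope="session")
def hab_responses(kernels, protocol):
    """Characteristic responses of the six subtypes (no smoothing needed —
    the kernels are noise-free)."""
    return {n: hc.build_response(k, protocol, mode="all_cycles",
                                 smooth_window=1, source=n)
            for n, k in kernels.items()}


@pytest.fixture(scope="session")
def design_truth(hab_responses, circuit):
    """Noise-free stacked design whose target is the ground-truth forward pass."""
    cols = {n: r.values for n, r in hab_responses.items()}
    raphe = {}
    for cond in hc.CONDITIONS:
        z = apply_ablation(cols, hc.ABLATION_MAP[cond])
        raphe[cond] = forward(circuit.mlp, np.column_stack([z[n] for n in hc.SUBTYPES]))
    return assemble_design(cols, raphe)


@pytest.fixture(scope="session")
def noise_free_fit(design_truth):
    """Full-budget fit to the noise-free target (function recovery)."""
    return hc.fit_design(design_truth, seed=3)


@pytest.fixture(scope="session")
def noisy_fits(design_truth):
    """Ten reduced-budget fits to the target plus iid noise (sd 0.05)."""
    fits = []
    for seed in range(10):
        rng = np.random.default_rng(1000 + seed)
        y = design_truth.y + rng.normal(0.0, 0.05, design_truth.y.shape)
        est = hc.CircuitMLP(max_epochs=3000, n_restarts=3, random_state=seed)
        est.fit(design_truth.X, y)
        fits.append(est)
    return fits
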
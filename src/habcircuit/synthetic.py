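"""Synthetic habenula/raphe data with the structure the analysis assumes.

Generates per-cell calcium traces from six subtype kernels (tonic/phasic,
ON/OFF, dorsal/ventral), and raphe populations whose mean response is the
forward pass of a known ground-truth 6-2-1 ReLU circuit — so every pipeline
stage, up to and including parameter recovery, can be exercised against a
known answer with no external data.

Kernels are saturating-exponential transients: during the driving phase the
trace relaxes toward ``amplitude`` with time constant ``rise_tau`` and
afterwards decays back to ``baseline`` with ``decay_tau``, evaluated in
closed form piecewise so the result is exact at any sample rate.  ON cells
are driven by light; OFF cells by the transition to darkness (for the whole
dark window if tonic, for a brief ``drive_duration`` if phasic, which is
what makes the phasic response a sharp post-offset spike).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mlp import MLPParams, forward
from .naming import SUBTYPES, region_of
from .protocol import DEFAULT_PROTOCOL, LightProtocol

__all__ = [
    "SubtypeKernelParams", "TraceMatrix", "GroundTruthCircuit",
    "DEFAULT_KERNEL_PARAMS", "DEFAULT_CELL_COUNTS", "subtype_kernel",
    "kernel_matrix", "simulate_habenula", "simulate_raphe", "default_circuit",
    "derive_seed",
]


def derive_seed(master: int, stage: str) -> int:
    """Deterministically derive a per-stage integer seed (< 2**31)."""
    ss = np.random.SeedSequence([int(master) % (2 ** 31),
                                 *(ord(c) for c in stage)])
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass(frozen=True)
class SubtypeKernelParams:
    """Shape parameters of one subtype's characteristic transient."""

    subtype_name: str
    amplitude: float = 1.0
    rise_tau: float = 3.0
    decay_tau: float = 8.0
    baseline: float = 0.0
    drive_duration: float | None = None  # phasic only: seconds of drive after offset

    def __post_init__(self):
        if self.subtype_name not in SUBTYPES:
            raise ValueError(f"unknown subtype_name: {self.subtype_name!r}")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("rise_tau and decay_tau must be positive")

    @property
    def phase(self) -> str:
        return "ON" if "-ON-" in self.subtype_name else "OFF"

    @property
    def shape(self) -> str:
        return "phasic" if self.subtype_name.endswith("Phasic") else "tonic"


#: Default kernel parameters for the six subtypes.  Amplitudes are order-1
#: fluorescence units; phasic kernels use a 2 s post-offset drive and a fast
#: decay so they return to baseline within a few seconds, tonic kernels decay
#: over tens of seconds.  Dorsal/ventral pairs differ slightly in kinetics.
DEFAULT_KERNEL_PARAMS = {
    "D-ON-Tonic": SubtypeKernelParams("D-ON-Tonic", amplitude=1.0,
                                      rise_tau=3.0, decay_tau=8.0),
    "D-OFF-Tonic": SubtypeKernelParams("D-OFF-Tonic", amplitude=1.0,
                                       rise_tau=4.0, decay_tau=30.0),
    "D-OFF-Phasic": SubtypeKernelParams("D-OFF-Phasic", amplitude=1.2,
                                        rise_tau=0.6, decay_tau=2.5,
                                        drive_duration=2.0),
    "V-ON-Tonic": SubtypeKernelParams("V-ON-Tonic", amplitude=1.0,
                                      rise_tau=2.0, decay_tau=12.0),
    "V-OFF-Tonic": SubtypeKernelParams("V-OFF-Tonic", amplitude=0.9,
                                       rise_tau=5.0, decay_tau=25.0),
    "V-OFF-Phasic": SubtypeKernelParams("V-OFF-Phasic", amplitude=1.1,
                                        rise_tau=0.5, decay_tau=2.0,
                                        drive_duration=2.0),
}

#: Default cell counts per subtype: 1747 dorsal + 1227 ventral = 2974 cells.
DEFAULT_CELL_COUNTS = {
    "D-ON-Tonic": 700,
    "D-OFF-Tonic": 600,
    "D-OFF-Phasic": 447,
    "V-ON-Tonic": 500,
    "V-OFF-Tonic": 400,
    "V-OFF-Phasic": 327,
}


@dataclass
class TraceMatrix:
    """Per-cell fluorescence time series on a uniform grid, with metadata."""

    values: np.ndarray          # (n_cells, n_timepoints)
    time_axis: np.ndarray       # (n_timepoints,) seconds
    cell_meta: pd.DataFrame     # columns: cell_id, region, [true_subtype, z]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (cells x timepoints)")
        if self.values.shape[1] != self.time_axis.shape[0]:
            raise ValueError("time axis length does not match values")
        if len(self.cell_meta) != self.values.shape[0]:
            raise ValueError("cell_meta rows do not match values")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")
        if self.time_axis.size > 1:
            dt = np.diff(self.time_axis)
            if not np.allclose(dt, dt[0]):
                raise ValueError("time axis must be uniform")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]

    @property
    def sample_rate(self) -> float:
        dt = np.diff(self.time_axis)
        return 1.0 / dt[0] if dt.size else 1.0

    def subset(self, mask) -> "TraceMatrix":
        mask = np.asarray(mask)
        return TraceMatrix(self.values[mask],
                           self.time_axis.copy(),
                           self.cell_meta.iloc[mask].reset_index(drop=True))


def _drive_windows(params: SubtypeKernelParams, protocol: LightProtocol):
    """Time windows during which the kernel is driven toward its amplitude."""
    if params.phase == "ON":
        return list(protocol.light_windows)
    wins = []
    for a, b in protocol.dark_windows:
        if params.shape == "phasic" and params.drive_duration is not None:
            b = min(b, a + params.drive_duration)
        wins.append((a, b))
    return wins


def subtype_kernel(params: SubtypeKernelParams,
                   protocol: LightProtocol = DEFAULT_PROTOCOL,
                   times: np.ndarray | None = None) -> np.ndarray:
    """Noise-free characteristic trace of one subtype under a protocol.

    Piecewise closed form: within a driving window the value relaxes from its
    entry value v0 toward ``amplitude`` as
    ``A + (v0 - A) * exp(-(t - t0)/rise_tau)``; outside it decays toward
    ``baseline`` with ``decay_tau``.  The trace starts at baseline.
    """
    t = protocol.time_axis if times is None else np.asarray(times, dtype=float)
    B = params.baseline
    A = B + params.amplitude        # driven plateau, relative to baseline
    wins = _drive_windows(params, protocol)

    # segment boundaries: 0, each window edge, end
    edges = sorted({0.0, float(t[-1] if t.size else 0.0),
                    *(w[0] for w in wins), *(w[1] for w in wins)})
    out = np.empty_like(t)
    v0 = B
    for a, b in zip(edges[:-1], edges[1:]):
        driving = any(wa <= a < wb for wa, wb in wins)
        target, tau = (A, params.rise_tau) if driving else (B, params.decay_tau)
        sel = (t >= a - 1e-12) & (t < b - 1e-12)
        out[sel] = target + (v0 - target) * np.exp(-(t[sel] - a) / tau)
        v0 = target + (v0 - target) * np.exp(-(b - a) / tau)
    # final sample at the closed right end of the grid
    sel = t >= edges[-1] - 1e-12
    out[sel] = v0
    return out


def kernel_matrix(protocol: LightProtocol = DEFAULT_PROTOCOL,
                  kernel_params: dict | None = None) -> np.ndarray:
    """(n_timepoints, 6) matrix of the six subtype kernels in canonical order."""
    kp = DEFAULT_KERNEL_PARAMS if kernel_params is None else kernel_params
    return np.column_stack([subtype_kernel(kp[name], protocol) for name in SUBTYPES])


def simulate_habenula(counts: dict | None = None,
                      protocol: LightProtocol = DEFAULT_PROTOCOL,
                      noise_sd: float = 0.2,
                      gain_range: tuple = (0.8, 1.2),
                      kernel_params: dict | None = None,
                      seed: int = 0) -> TraceMatrix:
    """Simulate a habenula population: gain x subtype kernel + Gaussian noise.

    Default counts give 1747 dorsal and 1227 ventral cells (2974 total).
    Identical seed and config yield bit-identical output.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    counts = DEFAULT_CELL_COUNTS if counts is None else counts
    for name, c in counts.items():
        if name not in SUBTYPES:
            raise ValueError(f"unknown subtype: {name!r}")
        if c < 0:
            raise ValueError("counts must be >= 0")
    kp = DEFAULT_KERNEL_PARAMS if kernel_params is None else kernel_params
    rng = np.random.default_rng(seed)

    blocks, meta = [], []
    cid = 0
    for name in SUBTYPES:          # canonical order => deterministic layout
        c = int(counts.get(name, 0))
        if c == 0:
            continue
        k = subtype_kernel(kp[name], protocol)
        gains = rng.uniform(gain_range[0], gain_range[1], size=(c, 1))
        noise = rng.normal(0.0, noise_sd, size=(c, k.size)) if noise_sd > 0 \
            else np.zeros((c, k.size))
        blocks.append(gains * k + noise)
        reg = region_of(name)
        for _ in range(c):
            meta.append({"cell_id": f"hb{cid:05d}", "region": reg,
                         "true_subtype": name})
            cid += 1
    values = np.vstack(blocks) if blocks else np.empty((0, protocol.n_samples))
    return TraceMatrix(values, protocol.time_axis, pd.DataFrame(meta))


@dataclass
class GroundTruthCircuit:
    """A known 6-2-1 circuit used as the generative model for raphe data."""

    mlp: MLPParams
    noise_sd: float = 0.05
    raphe_cells_per_condition: int = 100
    per_cell_gain_range: tuple = (1.0, 1.0)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.raphe_cells_per_condition < 10:
            raise ValueError("need >= 10 raphe cells per condition "
                             "(ten-fold CV must be well defined)")


def default_circuit(noise_sd: float = 0.05,
                    raphe_cells_per_condition: int = 100) -> GroundTruthCircuit:
    """The package's default ground-truth circuit.

    Chosen so the simulated raphe qualitatively matches the lesion
    phenotypes: one hidden node (H1) net-inhibitory on the output and driven
    hardest by V-ON-Tonic (so light suppresses the raphe when the habenula is
    intact), the other (H2) net-excitatory; removing D-ON-Tonic disinhibits
    H2 and flips the light response to excitation; removing the V-OFF group
    unmasks a dark-evoked excitation.  The numbers are free configuration of
    the generator, not estimates of the biological circuit.
    """
    W1 = np.array([
        # H1     H2
        [0.2, -1.4],   # D-ON-Tonic
        [0.2,  0.1],   # D-OFF-Tonic
        [0.3,  0.8],   # D-OFF-Phasic
        [0.8,  1.6],   # V-ON-Tonic
        [-0.2, -0.9],  # V-OFF-Tonic
        [0.9,  0.2],   # V-OFF-Phasic
    ])
    b1 = np.array([0.3, 0.1])
    W2 = np.array([-0.9, 0.9])
    b2 = 0.9
    return GroundTruthCircuit(MLPParams(W1, b1, W2, b2), noise_sd=noise_sd,
                              raphe_cells_per_condition=raphe_cells_per_condition)


def simulate_raphe(circuit: GroundTruthCircuit,
                   protocol: LightProtocol = DEFAULT_PROTOCOL,
                   ablation=(),
                   kernels: np.ndarray | None = None,
                   kernel_params: dict | None = None,
                   seed: int = 0) -> TraceMatrix:
    """Simulate a raphe population under an ablation condition.

    The population-mean trace is the ground-truth forward pass applied
    timepoint-wise to the six subtype kernels, with ablated subtypes zeroed;
    each simulated cell is ``gain * mean + iid Gaussian noise``.
    """
    unknown = set(ablation) - set(SUBTYPES)
    if unknown:
        raise ValueError(f"ablation names not in the six subtypes: {sorted(unknown)}")
    K = kernel_matrix(protocol, kernel_params) if kernels is None \
        else np.asarray(kernels, dtype=float)
    if K.shape[1] != len(SUBTYPES):
        raise ValueError("kernels must cover all six subtypes (6 columns)")
    K = K.copy()
    for name in ablation:
        K[:, SUBTYPES.index(name)] = 0.0

    mean = forward(circuit.mlp, K)
    rng = np.random.default_rng(seed)
    c = circuit.raphe_cells_per_condition
    lo, hi = circuit.per_cell_gain_range
    gains = rng.uniform(lo, hi, size=(c, 1)) if hi > lo else np.full((c, 1), lo)
    noise = rng.normal(0.0, circuit.noise_sd, size=(c, mean.size)) \
        if circuit.noise_sd > 0 else np.zeros((c, mean.size))
    values = gains * mean + noise
    meta = pd.DataFrame({
        "cell_id": [f"ra{i:05d}" for i in range(c)],
        "region": "raphe",
        "true_subtype": "",
    })
    return TraceMatrix(values, protocol.time_axis, meta)
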
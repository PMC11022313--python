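"""Characteristic-response construction and design assembly.

A characteristic response is a subtype's (or the raphe's) mean activity over
a single 100 s window built as: cycle averaging at 1 Hz (all four light/dark
cycles for habenula cells; first cycle only for raphe cells, whose later
cycles are inconsistent) -> 20 s baseline padding before the stimulus ->
monotone PCHIP extension of the tail for 40 s so the trace returns to
baseline (20 s unexcited + 20 s light + 60 s decay) -> smoothing -> linear
resampling to a 0.01 s grid.

Grid convention: the fine grid is t = 0, 0.01, ..., 99.00 s — 9901 samples.
The 1 Hz padded curve has 101 samples (t = 0..100); resampling drops the
final second, which is the unique uniform 0.01 s grid with the stated vector
length.  Values at the 1 Hz knots are preserved exactly.

Stacking: the six subtype responses form the columns of the input matrix
(canonical order D-ON-T, D-OFF-T, D-OFF-P, V-ON-T, V-OFF-T, V-OFF-P) and
the four condition blocks (unablated, D-ON, V-ON, V-OFF) are concatenated
row-wise: 4 x 9901 = 39,604 rows.  Within an ablated condition's block the
ablated subtype's column is identically zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .naming import ABLATION_MAP, CONDITIONS, SUBTYPES
from .preprocessing import rolling_smooth
from .protocol import LightProtocol

__all__ = [
    "FINE_DT", "FINE_LENGTH", "CharacteristicResponse", "StackedDesign",
    "average_cycles", "pad_and_extend", "smooth_response", "resample_fine",
    "build_response", "apply_ablation", "assemble_design",
]

FINE_DT = 0.01
FINE_LENGTH = 9901          # t = 0 .. 99 s inclusive at 0.01 s
PAD_BEFORE = 20             # seconds of baseline prepended
EXTEND_AFTER = 41           # samples appended by PCHIP (t = 60 .. 100 s)


@dataclass
class CharacteristicResponse:
    """One 100 s mean response resampled to the 0.01 s grid."""

    values: np.ndarray
    dt: float = FINE_DT
    source: str = ""
    baseline: float = 0.0
    shift: float = 0.0      # additive translation applied after construction

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float).ravel()
        if not np.all(np.isfinite(self.values)):
            raise ValueError("characteristic response must be finite")

    @property
    def time_axis(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    def __len__(self):
        return self.values.size


def average_cycles(traces, protocol: LightProtocol, mode: str = "all_cycles") -> np.ndarray:
    """Mean 40 s (one-cycle) response at the protocol sample rate.

    ``traces`` is one trace or a (cells x time) matrix.  ``all_cycles``
    averages each cell's aligned cycles then averages across cells;
    ``first_cycle`` uses only each cell's first cycle.
    """
    X = np.atleast_2d(np.asarray(traces, dtype=float))
    spc = protocol.samples_per_cycle
    need = protocol.n_pulses * spc
    if X.shape[1] < need:
        raise ValueError(f"trace length {X.shape[1]} shorter than protocol span "
                         f"({need} samples)")
    if mode == "all_cycles":
        cyc = X[:, :need].reshape(X.shape[0], protocol.n_pulses, spc)
        per_cell = cyc.mean(axis=1)
    elif mode == "first_cycle":
        per_cell = X[:, :spc]
    else:
        raise ValueError("mode must be 'all_cycles' or 'first_cycle'")
    return per_cell.mean(axis=0)


def pad_and_extend(mean40: np.ndarray, baseline: float = 0.0,
                   sample_rate: float = 1.0, n_anchor: int = 5) -> np.ndarray:
    """100 s curve: 20 s baseline + the 40 s mean + 40 s PCHIP decay to baseline.

    The extension interpolates through the last ``n_anchor`` observed samples
    plus a single anchor at t = 100 s with the baseline value; PCHIP is
    shape-preserving, so a tail decaying toward baseline is extended
    monotonically with no overshoot beyond the knot range.  Returns 101
    samples at 1 Hz (t = 0..100 s).
    """
    m = np.asarray(mean40, dtype=float).ravel()
    if not np.all(np.isfinite(m)):
        raise ValueError("mean40 must be finite")
    if sample_rate != 1.0:
        raise ValueError("padding is defined on the 1 Hz grid")
    n = m.size
    pad = np.full(PAD_BEFORE, float(baseline))
    # observed segment occupies t = 20 .. 20+n-1
    t_obs_end = PAD_BEFORE + n - 1
    knots_t = np.concatenate([np.arange(t_obs_end - n_anchor + 1, t_obs_end + 1),
                              [100.0]])
    knots_v = np.concatenate([m[-n_anchor:], [float(baseline)]])
    interp = PchipInterpolator(knots_t, knots_v)
    t_ext = np.arange(t_obs_end + 1, 101)
    ext = interp(t_ext)
    ext[-1] = float(baseline)        # pin the anchor exactly (no float residue)
    return np.concatenate([pad, m, ext])


def smooth_response(curve, window: int = 3) -> np.ndarray:
    """Rolling-mean smoothing (delegates to preprocessing.rolling_smooth)."""
    return rolling_smooth(curve, window)


def resample_fine(curve, dt: float = FINE_DT) -> np.ndarray:
    """Linear interpolation of a 1 Hz curve onto the fine grid [0, L-2] s.

    For the standard 101-sample (100 s) curve and dt = 0.01 this yields
    exactly 9901 samples spanning [0, 99] s; values at the original 1 s
    knots are preserved exactly.
    """
    c = np.asarray(curve, dtype=float).ravel()
    if c.size < 2:
        raise ValueError("curve too short to resample")
    span = float(c.size - 2)
    n_steps = span / dt
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError(f"dt={dt} does not divide the span {span} s")
    t_fine = np.arange(int(round(n_steps)) + 1) * dt
    return np.interp(t_fine, np.arange(c.size, dtype=float), c)


def build_response(traces, protocol: LightProtocol, mode: str = "all_cycles",
                   baseline: float = 0.0, smooth_window: int = 3,
                   shift_to: float | None = None, source: str = "",
                   dt: float = FINE_DT) -> CharacteristicResponse:
    """Full construction: cycle average -> smooth -> pad/extend -> resample.

    Smoothing is applied to the observed 40 s segment (before padding) so
    the padded baseline region stays exactly at ``baseline``.  When
    ``shift_to`` is given the finished curve is translated additively so its
    baseline equals ``shift_to`` (used for the raphe target, which is placed
    on a positive baseline of 1 so the output ReLU can represent it); the
    shift is recorded and invertible.
    """
    mean40 = average_cycles(traces, protocol, mode=mode)
    mean40 = smooth_response(mean40, smooth_window) if smooth_window > 1 else mean40
    padded = pad_and_extend(mean40, baseline=baseline)
    fine = resample_fine(padded, dt=dt)
    shift = 0.0
    if shift_to is not None:
        shift = float(shift_to) - float(baseline)
        fine = fine + shift
        baseline = float(shift_to)
    return CharacteristicResponse(fine, dt=dt, source=source,
                                  baseline=float(baseline), shift=shift)


def _values(resp) -> np.ndarray:
    return resp.values if isinstance(resp, CharacteristicResponse) \
        else np.asarray(resp, dtype=float).ravel()


def apply_ablation(responses: dict, ablated=()) -> dict:
    """Zero the ablated subtypes' responses; others pass through untouched."""
    unknown = set(ablated) - set(SUBTYPES)
    if unknown:
        raise ValueError(f"unknown subtype(s): {sorted(unknown)}")
    out = {}
    for name, resp in responses.items():
        v = _values(resp)
        out[name] = np.zeros_like(v) if name in ablated else v
    return out


@dataclass
class StackedDesign:
    """The stacked input matrix and target: 4 condition blocks x 9901 rows."""

    X: np.ndarray                      # (4*L, 6)
    y: np.ndarray                      # (4*L,)
    condition_index: np.ndarray        # (4*L,) int, row -> condition
    conditions: tuple = CONDITIONS
    columns: tuple = SUBTYPES
    meta: dict = field(default_factory=dict)

    @property
    def block_length(self) -> int:
        return self.X.shape[0] // len(self.conditions)

    def block(self, condition: str):
        ci = self.conditions.index(condition)
        m = self.condition_index == ci
        return self.X[m], self.y[m]


def assemble_design(habenula_responses: dict, raphe_responses: dict,
                    conditions=CONDITIONS, ablation_map=None,
                    columns=SUBTYPES, meta: dict | None = None) -> StackedDesign:
    """Stack per-condition habenula inputs and raphe targets.

    ``habenula_responses`` maps the six subtype names to their (unablated)
    characteristic responses — the same responses serve every condition,
    with the condition's ablated subtypes zeroed.  ``raphe_responses`` maps
    each condition to its raphe characteristic response.
    """
    ablation_map = ABLATION_MAP if ablation_map is None else ablation_map
    missing = set(columns) - set(habenula_responses)
    if missing:
        raise ValueError(f"missing habenula responses: {sorted(missing)}")
    missing = set(conditions) - set(raphe_responses)
    if missing:
        raise ValueError(f"missing raphe condition(s): {sorted(missing)}")

    L = _values(habenula_responses[columns[0]]).size
    Xs, ys, idx = [], [], []
    for ci, cond in enumerate(conditions):
        zeroed = apply_ablation(habenula_responses, ablation_map[cond])
        cols = []
        for name in columns:
            v = zeroed[name]
            if v.size != L:
                raise ValueError(f"response length mismatch for {name!r} "
                                 f"({v.size} != {L})")
            cols.append(v)
        yv = _values(raphe_responses[cond])
        if yv.size != L:
            raise ValueError(f"raphe response length mismatch for {cond!r}")
        Xs.append(np.column_stack(cols))
        ys.append(yv)
        idx.append(np.full(L, ci, dtype=int))
    return StackedDesign(np.vstack(Xs), np.concatenate(ys),
                         np.concatenate(idx), tuple(conditions),
                         tuple(columns), meta or {})
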
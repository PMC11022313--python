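"""Interpretability and robustness analyses of the fitted circuit model.

* node contributions — each input's weight-scaled drive onto H1/H2 and each
  hidden node's weight-scaled drive onto the raphe output, satisfying the
  exact reconstruction identities ReLU(sum_i contrib(i->Hj) + b1[j]) = h_j
  and ReLU(sum_j contrib(Hj->R) + b2) = yhat at every timepoint;
* per-parameter sensitivity — each of the 17 parameters scaled by factors in
  [0.1, 10] one at a time, error measured as RMSD against the observed raphe
  curves after both are translated to a median of 1 over the first 10 s;
* ten-fold neuron-subset cross-validation — raphe cells split into ten
  non-overlapping sets per condition; the training average is fitted, the
  held-out average scores the model;
* a report bundle of deterministic CSV tables and plots.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mlp import CircuitMLP, MLPParams, forward, hidden_activations, rmse
from .naming import CONDITIONS, SUBTYPES
from .protocol import LightProtocol
from .response import FINE_DT, StackedDesign, build_response

logger = logging.getLogger(__name__)

__all__ = [
    "ContributionSeries", "node_contributions", "normalize_first10_median",
    "SensitivityGrid", "sensitivity_scan", "CVResult", "cross_validate",
    "make_report", "default_factors",
]


# ---------------------------------------------------------------------------
# node contributions

@dataclass
class ContributionSeries:
    """Weight-scaled node contributions over time for one condition."""

    input_to_hidden: np.ndarray    # (n, 6, H): x_i * W1[i, j]
    hidden_to_output: np.ndarray   # (n, H):    h_j * W2[j]
    hidden: np.ndarray             # (n, H)
    output: np.ndarray             # (n,)
    params: MLPParams
    dt: float = FINE_DT
    condition: str = ""

    def table(self, stride: int = 100) -> pd.DataFrame:
        """Readable table subsampled to 1 s (stride 100 on the 0.01 s grid)."""
        sel = np.arange(0, self.output.size, stride)
        cols = {"t": sel * self.dt}
        for j in range(self.hidden.shape[1]):
            for i, name in enumerate(SUBTYPES):
                cols[f"{name}->H{j + 1}"] = self.input_to_hidden[sel, i, j]
        for j in range(self.hidden.shape[1]):
            cols[f"H{j + 1}->R"] = self.hidden_to_output[sel, j]
        cols["raphe_estimate"] = self.output[sel]
        return pd.DataFrame(cols)


def node_contributions(params: MLPParams, X: np.ndarray,
                       condition: str = "", dt: float = FINE_DT) -> ContributionSeries:
    """Per-timepoint contribution of every node to the next layer.

    Ablated inputs (zero columns of X) contribute exactly zero.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    contrib_ih = X[:, :, None] * params.W1[None, :, :]      # (n, 6, H)
    h = hidden_activations(params, X)
    contrib_ho = h * params.W2[None, :]                     # (n, H)
    out = np.maximum(contrib_ho.sum(axis=1) + params.b2, 0.0)
    return ContributionSeries(contrib_ih, contrib_ho, h, out, params.copy(),
                              dt=dt, condition=condition)


# ---------------------------------------------------------------------------
# sensitivity

def normalize_first10_median(curve: np.ndarray, dt: float = FINE_DT) -> np.ndarray:
    """Translate a curve so its median over the first 10 s equals 1."""
    c = np.asarray(curve, dtype=float).ravel()
    n10 = int(round(10.0 / dt))
    return c - np.median(c[:n10]) + 1.0


def default_factors(n: int = 25) -> np.ndarray:
    """Log-spaced scale factors on [0.1, 10], including 1.0 exactly."""
    f = np.geomspace(0.1, 10.0, n)
    f[np.argmin(np.abs(f - 1.0))] = 1.0
    return f


@dataclass
class SensitivityGrid:
    """Fit error for each (parameter, scale factor) pair."""

    table: pd.DataFrame            # index: parameter id; columns: factors
    per_condition: dict            # condition -> DataFrame like `table`
    base_error: float              # error of the unscaled model

    def to_csv(self, path) -> None:
        self.table.to_csv(path, float_format="%.10g")


def sensitivity_scan(params: MLPParams, X: np.ndarray, y_observed: np.ndarray,
                     factors: np.ndarray | None = None,
                     condition_index: np.ndarray | None = None,
                     conditions=CONDITIONS, dt: float = FINE_DT) -> SensitivityGrid:
    """Scale each parameter in turn and measure the normalised fit error.

    For each of the 17 parameters and each factor, that one parameter is
    multiplied by the factor, the forward pass is run over all conditions,
    and both simulated and observed curves are translated (median 1 over the
    first 10 s, per condition) before the RMSD is pooled across conditions.
    The parameter is restored afterwards.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y_observed, dtype=float).ravel()
    if factors is None:
        factors = default_factors()
    factors = np.asarray(factors, dtype=float)
    if np.any(factors < 0.1 - 1e-12) or np.any(factors > 10.0 + 1e-12):
        raise ValueError("factors must lie within [0.1, 10]")
    if not np.any(np.isclose(factors, 1.0)):
        raise ValueError("factor grid must contain 1.0")
    if condition_index is None:
        condition_index = np.zeros(X.shape[0], dtype=int)
        conditions = ("all",)

    blocks = [condition_index == ci for ci in range(len(conditions))]
    y_norm = {c: normalize_first10_median(y[m], dt) for c, m in zip(conditions, blocks)}

    work = params.copy()
    ids = work.param_ids()
    pooled = np.empty((len(ids), factors.size))
    per_cond = {c: np.empty((len(ids), factors.size)) for c in conditions}
    for pi, pid in enumerate(ids):
        orig = work.get_param(pid)
        for fi, f in enumerate(factors):
            work.set_param(pid, orig * f)
            yhat = forward(work, X)
            sq, n_tot = 0.0, 0
            for c, m in zip(conditions, blocks):
                sim = normalize_first10_median(yhat[m], dt)
                d = sim - y_norm[c]
                per_cond[c][pi, fi] = float(np.sqrt(np.mean(d * d)))
                sq += float(np.sum(d * d))
                n_tot += d.size
            pooled[pi, fi] = np.sqrt(sq / n_tot)
        work.set_param(pid, orig)

    cols = [float(f) for f in factors]
    table = pd.DataFrame(pooled, index=ids, columns=cols)
    per_condition = {c: pd.DataFrame(v, index=ids, columns=cols)
                     for c, v in per_cond.items()}
    base = float(table.loc[ids[0], 1.0])
    return SensitivityGrid(table, per_condition, base)


# ---------------------------------------------------------------------------
# cross-validation

@dataclass
class CVResult:
    """Ten-fold neuron-subset cross-validation scores."""

    scores: pd.DataFrame            # columns: fold, rmse_train, rmse_val
    membership: dict                # condition -> {cell_id: fold}
    n_folds: int = 10

    @property
    def mean_train(self) -> float:
        return float(self.scores["rmse_train"].mean())

    @property
    def mean_val(self) -> float:
        return float(self.scores["rmse_val"].mean())


def _fold_assignment(cell_ids, folds: int, rng: np.random.Generator) -> dict:
    ids = sorted(map(str, cell_ids))
    if len(ids) < folds:
        raise ValueError(f"{len(ids)} cells < {folds} folds")
    perm = rng.permutation(len(ids))
    # contiguous chunks of the permutation: sizes differ by at most 1
    assignment = {}
    for f, chunk in enumerate(np.array_split(perm, folds)):
        for i in chunk:
            assignment[ids[i]] = f
    return assignment


def cross_validate(raphe_traces: dict, X: np.ndarray, protocol: LightProtocol,
                   folds: int = 10, seed: int = 0,
                   condition_index: np.ndarray | None = None,
                   conditions=CONDITIONS, baseline: float = 0.0,
                   smooth_window: int = 3, shift_to: float | None = None,
                   fit_config: dict | None = None) -> CVResult:
    """Neuron-subset CV: fit to the training-cell average, score on held-out.

    ``raphe_traces`` maps each condition to a :class:`TraceMatrix` of raphe
    cells.  The habenula input matrix ``X`` is shared across folds (habenula
    and raphe come from different fish; only the raphe target changes).
    Fold assignment is a deterministic function of (seed, sorted cell ids).
    """
    fit_config = dict(fit_config or {})
    missing = set(conditions) - set(raphe_traces)
    if missing:
        raise ValueError(f"missing raphe condition(s): {sorted(missing)}")
    if condition_index is None:
        L = X.shape[0] // len(conditions)
        condition_index = np.repeat(np.arange(len(conditions)), L)

    membership = {}
    for ci, cond in enumerate(conditions):
        tm = raphe_traces[cond]
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), ci]))
        membership[cond] = _fold_assignment(tm.cell_meta["cell_id"], folds, rng)

    def target(cond, keep_fold, exclude: bool) -> np.ndarray:
        tm = raphe_traces[cond]
        fold_of = membership[cond]
        fids = np.array([fold_of[str(c)] for c in tm.cell_meta["cell_id"]])
        mask = (fids != keep_fold) if exclude else (fids == keep_fold)
        resp = build_response(tm.values[mask], protocol, mode="first_cycle",
                              baseline=baseline, smooth_window=smooth_window,
                              shift_to=shift_to, source=f"raphe:{cond}")
        return resp.values

    rows = []
    for f in range(folds):
        y_tr = np.concatenate([target(c, f, exclude=True) for c in conditions])
        y_va = np.concatenate([target(c, f, exclude=False) for c in conditions])
        est = CircuitMLP(random_state=int(np.random.SeedSequence(
            [int(seed) % (2**31), 1000 + f]).generate_state(1)[0] % (2**31)),
            **fit_config)
        est.fit(X, y_tr)
        yhat = est.predict(X)
        rows.append({"fold": f, "rmse_train": rmse(yhat, y_tr),
                     "rmse_val": rmse(yhat, y_va)})
    return CVResult(pd.DataFrame(rows), membership, folds)


# ---------------------------------------------------------------------------
# report

def make_report(outdir, fit=None, design: StackedDesign | None = None,
                contributions: dict | None = None,
                sensitivity: SensitivityGrid | None = None,
                cv: CVResult | None = None, plots: bool = True) -> dict:
    """Write the analysis bundle; returns a manifest of written files.

    Missing inputs produce a partial report with a warning rather than an
    error.  CSV output is deterministic (fixed float format, no timestamps).
    """
    import pathlib

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"curves": [], "contributions": [], "sensitivity": None,
                "cv": None, "plots": []}
    ff = "%.10g"

    if fit is not None and design is not None:
        yhat = forward(fit.params, design.X)
        for ci, cond in enumerate(design.conditions):
            m = design.condition_index == ci
            t = np.arange(int(m.sum())) * FINE_DT
            df = pd.DataFrame({"t": t, "observed": design.y[m], "estimated": yhat[m]})
            p = out / f"curves_{cond}.csv"
            df.to_csv(p, index=False, float_format=ff)
            manifest["curves"].append(p.name)
    else:
        warnings.warn("report: no fit/design; observed-vs-estimated curves skipped")

    if contributions is not None:
        for cond, series in contributions.items():
            p = out / f"contributions_{cond}.csv"
            series.table().to_csv(p, index=False, float_format=ff)
            manifest["contributions"].append(p.name)
    else:
        warnings.warn("report: no contributions input; tables skipped")

    if sensitivity is not None:
        p = out / "sensitivity.csv"
        sensitivity.to_csv(p)
        manifest["sensitivity"] = p.name

    if cv is not None:
        p = out / "cross_validation.csv"
        cv.scores.to_csv(p, index=False, float_format=ff)
        manifest["cv"] = p.name
    else:
        logger.info("report: no CV input; CV table omitted")

    if plots:
        manifest["plots"] = _make_plots(out, fit, design, contributions, sensitivity)
    return manifest


def _make_plots(out, fit, design, contributions, sensitivity) -> list:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    if fit is not None and design is not None:
        yhat = forward(fit.params, design.X)
        fig, axes = plt.subplots(1, len(design.conditions),
                                 figsize=(4 * len(design.conditions), 3),
                                 sharey=True)
        for ax, (ci, cond) in zip(np.atleast_1d(axes), enumerate(design.conditions)):
            m = design.condition_index == ci
            t = np.arange(int(m.sum())) * FINE_DT
            ax.plot(t, design.y[m], lw=1.2, label="observed")
            ax.plot(t, yhat[m], "--", lw=1.0, label="estimated")
            ax.axvspan(20, 40, color="red", alpha=0.1)
            ax.set_title(cond)
            ax.set_xlabel("time (s)")
        np.atleast_1d(axes)[0].set_ylabel("raphe response (a.u.)")
        np.atleast_1d(axes)[0].legend(frameon=False, fontsize=8)
        fig.tight_layout()
        p = out / "fit_curves.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p.name)
    if sensitivity is not None:
        fig, ax = plt.subplots(figsize=(7, 5))
        tbl = sensitivity.table
        im = ax.imshow(np.log10(np.maximum(tbl.to_numpy(), 1e-12)),
                       aspect="auto", cmap="viridis")
        ax.set_yticks(range(len(tbl.index)), tbl.index, fontsize=6)
        ax.set_xticks(range(len(tbl.columns)),
                      [f"{c:.2g}" for c in tbl.columns], rotation=90, fontsize=6)
        ax.set_xlabel("scale factor")
        fig.colorbar(im, label="log10 RMSD")
        fig.tight_layout()
        p = out / "sensitivity.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p.name)
    return written
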
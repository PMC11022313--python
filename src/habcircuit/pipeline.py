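"""End-to-end orchestration: simulate -> preprocess -> cluster -> build-design
-> fit -> analyze, with a validated config, per-stage seed fan-out and a
manifest of artifact hashes so a re-run with the same config and seed is
verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, field_validator

from . import io as hio
from .analysis import (cross_validate, make_report, node_contributions,
                       sensitivity_scan)
from .clustering import cluster_traces, label_clusters, select_k, split_regions
from .mlp import MLPParams, fit_design
from .naming import ABLATION_MAP, CONDITIONS, SUBTYPES
from .preprocessing import TracePreprocessor
from .protocol import LightProtocol, make_protocol
from .response import assemble_design, build_response
from .synthetic import (GroundTruthCircuit, TraceMatrix, default_circuit,
                        derive_seed, simulate_habenula, simulate_raphe)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


class ProtocolCfg(BaseModel):
    n_pulses: int = 4
    on_dur: float = 20.0
    off_dur: float = 20.0
    rate: float = 1.0
    lead_in: float = 0.0

    def build(self) -> LightProtocol:
        return make_protocol(self.n_pulses, self.on_dur, self.off_dur,
                             self.rate, self.lead_in)


class SimulateCfg(BaseModel):
    counts: dict | None = None          # subtype -> cell count (None: defaults)
    noise_sd: float = 0.2
    gain_range: tuple = (0.8, 1.2)
    raphe_cells_per_condition: int = 100
    raphe_noise_sd: float = 0.05

    @field_validator("noise_sd", "raphe_noise_sd")
    @classmethod
    def _nonneg(cls, v):
        if v < 0:
            raise ValueError("noise sd must be >= 0")
        return v


class PreprocessCfg(BaseModel):
    median_width: int = 3
    background: float = 0.0
    detrend_order: int | None = 2
    smooth_window: int = 3
    on_degenerate: str = "drop"


class ClusterCfg(BaseModel):
    k: int = 3
    kmin: int = 2
    kmax: int = 10
    n_restarts: int = 10
    diagnostics: bool = False
    z_threshold: float | None = None


class DesignCfg(BaseModel):
    baseline: float = 0.0
    smooth_window: int = 3
    raphe_shift: float = 1.0            # raphe target baseline after translation


class FitCfg(BaseModel):
    epochs: int = 20000
    learning_rate: float = 1e-3
    restarts: int = 10


class AnalysisCfg(BaseModel):
    n_factors: int = 25
    cv_folds: int = 0                   # 0 disables cross-validation
    cv_epochs: int = 2000
    cv_restarts: int = 2


class PipelineConfig(BaseModel):
    seed: int = 0
    protocol: ProtocolCfg = Field(default_factory=ProtocolCfg)
    simulate: SimulateCfg = Field(default_factory=SimulateCfg)
    preprocess: PreprocessCfg = Field(default_factory=PreprocessCfg)
    cluster: ClusterCfg = Field(default_factory=ClusterCfg)
    design: DesignCfg = Field(default_factory=DesignCfg)
    fit: FitCfg = Field(default_factory=FitCfg)
    analysis: AnalysisCfg = Field(default_factory=AnalysisCfg)


def load_config(path=None, **overrides) -> PipelineConfig:
    data = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    data.update(overrides)
    return PipelineConfig(**data)


# ---------------------------------------------------------------------------
# stages (each reads/writes files under `out`)

def stage_simulate(cfg: PipelineConfig, out: pathlib.Path) -> None:
    protocol = cfg.protocol.build()
    hb = simulate_habenula(cfg.simulate.counts, protocol,
                           noise_sd=cfg.simulate.noise_sd,
                           gain_range=tuple(cfg.simulate.gain_range),
                           seed=derive_seed(cfg.seed, "simulate:habenula"))
    hio.write_traces(hb, out / "habenula_raw.csv")
    circuit = default_circuit(noise_sd=cfg.simulate.raphe_noise_sd,
                              raphe_cells_per_condition=cfg.simulate.raphe_cells_per_condition)
    circuit.mlp.to_json(out / "circuit_truth.json")
    for cond in CONDITIONS:
        ra = simulate_raphe(circuit, protocol, ablation=ABLATION_MAP[cond],
                            seed=derive_seed(cfg.seed, f"simulate:raphe:{cond}"))
        hio.write_traces(ra, out / f"raphe_raw_{cond}.csv")
    with open(out / "protocol.json", "w") as fh:
        json.dump(protocol.to_dict(), fh, indent=2)


def _preprocessor(cfg: PipelineConfig) -> TracePreprocessor:
    p = cfg.preprocess
    return TracePreprocessor(median_width=p.median_width, background=p.background,
                             detrend_order=p.detrend_order,
                             smooth_window=p.smooth_window,
                             on_degenerate=p.on_degenerate)


def stage_preprocess(cfg: PipelineConfig, out: pathlib.Path) -> None:
    pre = _preprocessor(cfg)
    for name in ["habenula_raw"] + [f"raphe_raw_{c}" for c in CONDITIONS]:
        src = out / f"{name}.csv"
        if not src.exists():
            continue
        tm = hio.read_traces(src)
        clean = pre.fit(tm.values).transform(tm.values)
        meta = tm.cell_meta.iloc[pre.kept_mask_].reset_index(drop=True)
        dst = out / f"{name.replace('_raw', '_clean')}.csv"
        hio.write_traces(TraceMatrix(clean, tm.time_axis, meta), dst)


def stage_cluster(cfg: PipelineConfig, out: pathlib.Path) -> None:
    protocol = cfg.protocol.build()
    tm = hio.read_traces(out / "habenula_clean.csv")
    dorsal, ventral = split_regions(tm.cell_meta, z_threshold=cfg.cluster.z_threshold)
    rows, cent_rows, diagnostics = [], [], {}
    for region, mask in (("dorsal", dorsal), ("ventral", ventral)):
        sub = tm.subset(mask)
        est = cluster_traces(sub.values, cfg.cluster.k,
                             seed=derive_seed(cfg.seed, f"cluster:{region}"),
                             n_restarts=cfg.cluster.n_restarts,
                             cell_ids=sub.cell_meta["cell_id"].tolist())
        labeling = label_clusters(est.cluster_centers_, protocol, region)
        for cid, cl in zip(sub.cell_meta["cell_id"], est.labels_):
            rows.append({"cell_id": cid, "region": region, "cluster": int(cl),
                         "subtype": labeling[int(cl)]})
        for ci in range(cfg.cluster.k):
            cent_rows.append({"subtype": labeling[ci], "region": region,
                              **{f"t{t:g}": v for t, v in
                                 zip(tm.time_axis, est.cluster_centers_[ci])}})
        if cfg.cluster.diagnostics:
            diag = select_k(sub.values, range(cfg.cluster.kmin, cfg.cluster.kmax + 1),
                            seed=derive_seed(cfg.seed, f"selectk:{region}"),
                            n_restarts=cfg.cluster.n_restarts,
                            cell_ids=sub.cell_meta["cell_id"].tolist())
            diagnostics[region] = diag
    pd.DataFrame(rows).to_csv(out / "assignments.csv", index=False)
    pd.DataFrame(cent_rows).to_csv(out / "centroids.csv", index=False,
                                   float_format="%.10g")
    with open(out / "cluster_diagnostics.json", "w") as fh:
        json.dump(diagnostics, fh, indent=2, default=float)


def stage_build_design(cfg: PipelineConfig, out: pathlib.Path) -> None:
    protocol = cfg.protocol.build()
    tm = hio.read_traces(out / "habenula_clean.csv")
    assign = pd.read_csv(out / "assignments.csv")
    sub_of = dict(zip(assign["cell_id"], assign["subtype"]))
    dcfg = cfg.design
    hab = {}
    for name in SUBTYPES:
        mask = np.array([sub_of.get(c) == name for c in tm.cell_meta["cell_id"]])
        if not mask.any():
            raise ValueError(f"no cells assigned to subtype {name!r}")
        hab[name] = build_response(tm.values[mask], protocol, mode="all_cycles",
                                   baseline=dcfg.baseline,
                                   smooth_window=dcfg.smooth_window, source=name)
    raphe = {}
    for cond in CONDITIONS:
        rm = hio.read_traces(out / f"raphe_clean_{cond}.csv")
        raphe[cond] = build_response(rm.values, protocol, mode="first_cycle",
                                     baseline=dcfg.baseline,
                                     smooth_window=dcfg.smooth_window,
                                     shift_to=dcfg.raphe_shift,
                                     source=f"raphe:{cond}")
    meta = {"baseline": dcfg.baseline, "raphe_shift": dcfg.raphe_shift,
            "baselines": {k: v.baseline for k, v in hab.items()},
            "shifts": {c: raphe[c].shift for c in CONDITIONS}}
    design = assemble_design(hab, raphe, meta=meta)
    hio.write_design(design, out / "design")


def stage_fit(cfg: PipelineConfig, out: pathlib.Path) -> None:
    design = hio.read_design(out / "design")
    result = fit_design(design, epochs=cfg.fit.epochs,
                        learning_rate=cfg.fit.learning_rate,
                        restarts=cfg.fit.restarts,
                        seed=derive_seed(cfg.seed, "fit"))
    result.params.to_json(out / "model.json")
    with open(out / "fit.json", "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)


def stage_analyze(cfg: PipelineConfig, out: pathlib.Path) -> None:
    design = hio.read_design(out / "design")
    params = MLPParams.from_json(out / "model.json")
    from .mlp import FitResult, forward, rmse
    yhat = forward(params, design.X)
    per_cond = {}
    contribs = {}
    for ci, cond in enumerate(design.conditions):
        m = design.condition_index == ci
        per_cond[cond] = rmse(yhat[m], design.y[m])
        contribs[cond] = node_contributions(params, design.X[m], condition=cond)
    fit = FitResult(params, rmse(yhat, design.y), per_cond)

    from .analysis import default_factors
    sens = sensitivity_scan(params, design.X, design.y,
                            factors=default_factors(cfg.analysis.n_factors),
                            condition_index=design.condition_index,
                            conditions=design.conditions)
    cv = None
    if cfg.analysis.cv_folds > 0:
        protocol = cfg.protocol.build()
        raphe = {c: hio.read_traces(out / f"raphe_clean_{c}.csv")
                 for c in design.conditions}
        cv = cross_validate(raphe, design.X, protocol,
                            folds=cfg.analysis.cv_folds,
                            seed=derive_seed(cfg.seed, "cv"),
                            conditions=design.conditions,
                            baseline=cfg.design.baseline,
                            smooth_window=cfg.design.smooth_window,
                            shift_to=cfg.design.raphe_shift,
                            fit_config={"max_epochs": cfg.analysis.cv_epochs,
                                        "n_restarts": cfg.analysis.cv_restarts})
    make_report(out / "report", fit=fit, design=design, contributions=contribs,
                sensitivity=sens, cv=cv)


STAGES = [
    ("simulate", stage_simulate),
    ("preprocess", stage_preprocess),
    ("cluster", stage_cluster),
    ("build_design", stage_build_design),
    ("fit", stage_fit),
    ("analyze", stage_analyze),
]


def _sha256(path: pathlib.Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, outdir, simulate: bool = True) -> pathlib.Path:
    """Run all stages into ``outdir``; returns the path to the manifest.

    Every run writes the resolved config next to its outputs.  The manifest
    records a sha256 per text artifact (CSV/JSON); identical config+seed
    reproduce identical hashes.  A stage failure halts the run with the
    stage name; artifacts from completed stages are retained.
    """
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(json.loads(config.model_dump_json()), fh, sort_keys=True)

    for name, fn in STAGES:
        if name == "simulate" and not simulate:
            continue
        logger.info("pipeline stage: %s", name)
        try:
            fn(config, out)
        except Exception as e:
            raise RuntimeError(f"pipeline stage '{name}' failed: {e}") from e

    manifest = {}
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.suffix in (".csv", ".json", ".yaml"):
            manifest[str(p.relative_to(out))] = _sha256(p)
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return mpath
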
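"""Fitted-model bundle: everything needed to forecast later, as flat JSON.

A bundle stores the grey model, the branch the pipeline took, the fitted
residual sequence, and — when the network branch was taken — the trained
weights and the normalization parameters (reused verbatim; never re-fit on
test data).  ``forecast_from_bundle`` reproduces the combined forecast for
any horizon without re-training.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import bp_network as bp
from .gm_core import GMModel, ResidualGMCorrection, ResidualSeries, simulate
from .hybrid_pipeline import (
    ForecastResult,
    NormalizationParams,
    ResidualNetwork,
    predict_residuals,
)

__all__ = ["ModelBundle", "bundle_from_result", "forecast_from_bundle"]

SCHEMA_VERSION = 1


@dataclass
class ModelBundle:
    model: GMModel
    branch: str
    eps: np.ndarray
    tail_model: Optional[GMModel] = None
    tail_k0: Optional[int] = None
    tail_sign: Optional[int] = None
    network: Optional[ResidualNetwork] = None
    norm_params: Optional[NormalizationParams] = None

    def save(self, path) -> None:
        obj = {
            "schema_version": SCHEMA_VERSION,
            "model": {"a": self.model.a, "b": self.model.b,
                      "x0_1": self.model.x0_1, "n_fit": self.model.n_fit},
            "branch": self.branch,
            "eps": self.eps.tolist(),
        }
        if self.tail_model is not None:
            obj["tail"] = {
                "a": self.tail_model.a, "b": self.tail_model.b,
                "x0_1": self.tail_model.x0_1, "n_fit": self.tail_model.n_fit,
                "k0": self.tail_k0, "sign": self.tail_sign,
            }
        if self.network is not None:
            obj["network"] = json.loads(
                self.network.weights.to_json(self.network.config)
            )
            obj["norm_params"] = asdict(self.norm_params)
        Path(path).write_text(json.dumps(obj, indent=2))

    @classmethod
    def load(cls, path) -> "ModelBundle":
        obj = json.loads(Path(path).read_text())
        model = GMModel(**obj["model"])
        bundle = cls(model=model, branch=obj["branch"], eps=np.array(obj["eps"]))
        if "tail" in obj:
            t = obj["tail"]
            bundle.tail_model = GMModel(a=t["a"], b=t["b"], x0_1=t["x0_1"], n_fit=t["n_fit"])
            bundle.tail_k0, bundle.tail_sign = t["k0"], t["sign"]
        if "network" in obj:
            weights, cfg = bp.WeightMatrices.from_json(json.dumps(obj["network"]))
            bundle.network = ResidualNetwork(weights=weights, config=cfg)
            bundle.norm_params = NormalizationParams(**obj["norm_params"])
        return bundle


def bundle_from_result(result: ForecastResult) -> ModelBundle:
    n = result.model.n_fit
    eps_fit = result.combined[:n] - result.gm_sim[:n]  # predicted residuals, fit range
    # stored residuals are the OBSERVED ones the network forecasts from
    bundle = ModelBundle(
        model=result.model,
        branch=result.branch_taken,
        eps=np.asarray(result.traces.get("observed_eps", eps_fit), dtype=float),
        network=result.network,
        norm_params=result.norm_params,
    )
    corr = result.traces.get("residual_correction")
    if isinstance(corr, ResidualGMCorrection):
        bundle.tail_model, bundle.tail_k0, bundle.tail_sign = corr.tail, corr.k0, corr.sign
    return bundle


def forecast_from_bundle(bundle: ModelBundle, horizon: int) -> np.ndarray:
    """Combined forecast for steps ``n_fit+1 .. n_fit+horizon``."""
    n = bundle.model.n_fit
    gm = simulate(bundle.model, n + horizon)[n:]
    if bundle.branch == "gm_only":
        return gm
    if bundle.branch == "residual_gm":
        corr = ResidualGMCorrection(
            base=bundle.model, tail=bundle.tail_model,
            k0=bundle.tail_k0, sign=bundle.tail_sign,
        )
        return corr.corrected(n + horizon)[n:]
    eps_hat = predict_residuals(bundle.network, bundle.norm_params, bundle.eps, horizon)
    return gm + eps_hat
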
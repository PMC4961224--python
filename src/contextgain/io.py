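"""HDF5 recording/model containers, YAML configuration, metrics CSV.

One container format holds everything: ``/stimulus/levels`` with the grid
metadata as attributes, ``/responses/counts`` with bin/alignment
attributes, and ``/meta`` as a JSON string for ids, group labels, seeds
and provenance. Model files are HDF5 with a JSON header attribute for
scalars/dims and datasets for the weight arrays; round-trips are bit-exact
for all arrays.
"""

from __future__ import annotations

import json
from typing import Optional

import h5py
import numpy as np
import pandas as pd
import yaml

from .drc import Spectrogram
from .evaluation import TrialResponses
from .models import (
    CGFField,
    CGFModel,
    DualCGFModel,
    LowRankQuadraticModel,
    PRFField,
    STRFModel,
    SeparableCGFModel,
)

SCHEMA_VERSION = "1"

__all__ = [
    "write_recording",
    "read_recording",
    "write_model",
    "read_model",
    "write_metrics",
    "load_config",
    "METRICS_COLUMNS",
]


def write_recording(
    path,
    spec: Spectrogram,
    responses: Optional[TrialResponses] = None,
    meta: Optional[dict] = None,
) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        g = f.create_group("stimulus")
        g.create_dataset("levels", data=spec.levels)
        g.attrs["bin_duration"] = spec.bin_duration
        g.attrs["freq_lo"] = spec.freq_lo
        g.attrs["freq_hi"] = spec.freq_hi
        g.attrs["channels_per_octave"] = spec.channels_per_octave
        if responses is not None:
            r = f.create_group("responses")
            r.create_dataset("counts", data=responses.counts)
            r.attrs["bin_duration"] = responses.bin_duration
            r.attrs["alignment_offset"] = responses.alignment_offset
        f.create_dataset("meta", data=json.dumps(meta or {}))


def read_recording(path):
    """Returns ``(Spectrogram, TrialResponses | None, meta dict)``."""
    with h5py.File(path, "r") as f:
        if "schema_version" not in f.attrs:
            raise ValueError(f"{path}: not a recording container (missing schema_version)")
        if "stimulus" not in f:
            raise ValueError(f"{path}: missing /stimulus group")
        g = f["stimulus"]
        spec = Spectrogram(
            levels=g["levels"][...],
            bin_duration=float(g.attrs["bin_duration"]),
            freq_lo=float(g.attrs["freq_lo"]),
            freq_hi=float(g.attrs["freq_hi"]),
            channels_per_octave=int(g.attrs["channels_per_octave"]),
        )
        responses = None
        if "responses" in f:
            r = f["responses"]
            counts = r["counts"][...]
            if counts.shape[1] != spec.n_time_bins:
                raise ValueError(
                    f"{path}: /responses/counts has {counts.shape[1]} bins but "
                    f"/stimulus/levels has {spec.n_time_bins}"
                )
            responses = TrialResponses(
                counts,
                bin_duration=float(r.attrs["bin_duration"]),
                alignment_offset=int(r.attrs["alignment_offset"]),
            )
        meta = json.loads(f["meta"][()])
    return spec, responses, meta


_MODEL_KINDS = {
    "strf": STRFModel,
    "cgf": CGFModel,
    "dual": DualCGFModel,
    "separable": SeparableCGFModel,
    "quadratic": LowRankQuadraticModel,
}


def write_model(path, model, meta: Optional[dict] = None) -> None:
    kind = next(k for k, cls in _MODEL_KINDS.items() if isinstance(model, cls))
    header = {"kind": kind, "meta": meta or {}}
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        if kind == "strf":
            header["c"] = model.c
            f.create_dataset("weights", data=model.weights)
        elif kind == "cgf":
            header["c"] = model.c
            f.create_dataset("prf", data=model.prf.weights)
            f.create_dataset("cgf", data=model.cgf.weights)
        elif kind == "dual":
            header["c"] = model.c
            f.create_dataset("prf", data=model.prf.weights)
            f.create_dataset("partition", data=model.partition)
            f.create_dataset("cgf_a", data=model.cgf_a.weights)
            f.create_dataset("cgf_b", data=model.cgf_b.weights)
        elif kind == "separable":
            header["c"] = model.c
            f.create_dataset("prf", data=model.prf.weights)
            f.create_dataset("u_tau", data=model.u_tau)
            f.create_dataset("v_phi", data=model.v_phi)
        elif kind == "quadratic":
            header["c"] = model.c
            header["lambdas"] = [lam for _, lam in model.components]
            f.create_dataset("linear", data=model.linear)
            for i, (b, _) in enumerate(model.components):
                f.create_dataset(f"component_{i}", data=b)
        f.attrs["header"] = json.dumps(header)


def read_model(path):
    with h5py.File(path, "r") as f:
        header = json.loads(f.attrs["header"])
        kind = header["kind"]
        if kind == "strf":
            return STRFModel(header["c"], f["weights"][...])
        if kind == "cgf":
            return CGFModel(header["c"], PRFField(f["prf"][...]), CGFField(f["cgf"][...]))
        if kind == "dual":
            return DualCGFModel(
                header["c"],
                PRFField(f["prf"][...]),
                f["partition"][...].astype(bool),
                CGFField(f["cgf_a"][...]),
                CGFField(f["cgf_b"][...]),
            )
        if kind == "separable":
            return SeparableCGFModel(
                header["c"], PRFField(f["prf"][...]), f["u_tau"][...], f["v_phi"][...]
            )
        if kind == "quadratic":
            comps = []
            for i, lam in enumerate(header["lambdas"]):
                comps.append((f[f"component_{i}"][...], lam))
            return LowRankQuadraticModel(header["c"], f["linear"][...], comps)
    raise ValueError(f"unknown model kind in {path}")


METRICS_COLUMNS = [
    "recording_id",
    "role",
    "signal_power",
    "noise_power",
    "normalized_noise",
    "pp_raw",
    "pp_normalized",
]


def write_metrics(path, rows: list) -> None:
    """Write evaluation rows (dicts with the documented columns) to CSV."""
    df = pd.DataFrame(rows, columns=METRICS_COLUMNS)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# configuration

_CONFIG_SCHEMA = {
    "drc": {
        "n_time_bins", "presence_prob", "level_set", "bin_duration",
        "freq_lo", "freq_hi", "channels_per_octave", "seed",
    },
    "dims": {"n_lags", "n_delays", "n_offsets"},
    "fit": {
        "ridge_lambda_prf", "ridge_lambda_cgf", "smoothness",
        "max_als_iterations", "convergence_tol", "inner_cv_folds",
        "n_restarts", "seed",
    },
    "simulate": {
        "n_neurons", "duration_s", "n_trials", "seed",
        "suppression_amp_range", "enhancement_amp_range",
    },
    "analysis": {"tile_rule", "n_perm", "k_folds", "z_threshold"},
}


def load_config(path) -> dict:
    """Load and validate a YAML run configuration.

    Unknown sections or keys are rejected with the offending path named,
    so typos fail loudly instead of silently using defaults.
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    for section, keys in cfg.items():
        if section not in _CONFIG_SCHEMA:
            raise ValueError(f"{path}: unknown config section {section!r}")
        if keys is None:
            continue
        for key in keys:
            if key not in _CONFIG_SCHEMA[section]:
                raise ValueError(f"{path}: unknown key {section}.{key}")
    return cfg
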
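"""Delimited-text / JSON writers and the run manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np

from . import __version__
from .sampling import Ensemble
from .spectra import AcvSeq, SpectrumSpec
from .spectral_estimation import SpectrumEstimate

__all__ = [
    "write_spectrum",
    "write_acv",
    "write_ensemble",
    "write_estimate",
    "RunManifest",
]


def _sidecar(path: Path, meta: dict) -> Path:
    side = path.with_suffix(path.suffix + ".json")
    side.write_text(json.dumps(meta, indent=2, default=_jsonable) + "\n")
    return side


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)


def write_spectrum(spec: SpectrumSpec, path) -> list[Path]:
    path = Path(path)
    np.savetxt(
        path,
        np.column_stack([spec.freqs, spec.power]),
        delimiter=",",
        header="frequency_hz,power",
        comments="",
    )
    meta = {
        "label": spec.label,
        "delta_s": spec.delta,
        "variance": spec.variance(),
        "params": spec.params,
    }
    return [path, _sidecar(path, meta)]


def write_acv(acv: AcvSeq, path) -> list[Path]:
    path = Path(path)
    np.savetxt(
        path,
        np.column_stack([acv.lag_times, acv.values]),
        delimiter=",",
        header="lag_s,covariance",
        comments="",
    )
    meta = {"label": acv.label, "delta_s": acv.delta, "variance": acv.values[0]}
    return [path, _sidecar(path, meta)]


def write_ensemble(ens: Ensemble, path) -> list[Path]:
    """Rows = time, columns = realizations; JSON sidecar carries provenance."""
    path = Path(path)
    np.savetxt(path, ens.as_matrix(), delimiter="\t")
    meta = {
        "label": ens.label,
        "n": ens.n,
        "delta_s": ens.delta,
        "ensemble_size": ens.size,
        "base_seed": ens.base_seed,
    }
    return [path, _sidecar(path, meta)]


def write_estimate(est: SpectrumEstimate, path) -> list[Path]:
    path = Path(path)
    np.savetxt(
        path,
        np.column_stack([est.freqs, est.power]),
        delimiter=",",
        header="frequency_hz,power",
        comments="",
    )
    meta = {"taper": est.taper, "n_avg": est.n_avg, "delta_s": est.delta}
    return [path, _sidecar(path, meta)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Provenance record of one CLI run: config, seed, output checksums."""

    config: dict
    base_seed: int
    outputs: dict = dataclasses.field(default_factory=dict)
    version: str = __version__
    created: str = ""

    def add(self, *paths) -> None:
        for p in paths:
            p = Path(p)
            self.outputs[p.name] = _sha256(p)

    def write(self, out_dir) -> Path:
        self.created = time.strftime("%Y-%m-%dT%H:%M:%S")
        path = Path(out_dir) / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path
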
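"""File formats shared by the estimators: trap / capture tables and fit JSON.

Trap and capture files follow the secr-style plain-text layout:

* traps file — columns ``detector x y`` (whitespace or comma separated,
  header optional), world coordinates;
* captures file — columns ``session individual occasion detector [count]``;
  a missing count column means one detection per row.

Detector coordinates are snapped to the containing raster cell; individuals
are ordered by first appearance in the captures file.  Fit results round-trip
through a small JSON schema carrying estimates, SEs, CIs, log-likelihood,
convergence and the package version.
"""
from __future__ import annotations

import io
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .inference import FitResult
from .landscape import Landscape
from .simulate import CaptureData, DetectorArray

__all__ = [
    "read_capture_data",
    "write_capture_data",
    "write_fit",
    "read_fit",
]

_TRAP_COLS = ["detector", "x", "y"]
_CAP_COLS = ["session", "individual", "occasion", "detector", "count"]


def _read_table(path, names: list[str]) -> pd.DataFrame:
    """Whitespace/CSV table with optional header row."""
    text = Path(path).read_text()
    sep = "," if ("," in text.splitlines()[0]) else r"\s+"
    first = pd.read_csv(io.StringIO(text), sep=sep, header=None, nrows=1)
    has_header = any(isinstance(v, str) and v.strip().lower() in names
                     for v in first.iloc[0])
    df = pd.read_csv(io.StringIO(text), sep=sep,
                     header=0 if has_header else None)
    if has_header:
        df.columns = [str(c).strip().lower() for c in df.columns]
        missing = [c for c in names[: df.shape[1]] if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns {missing} in {path}")
        return df
    df.columns = names[: df.shape[1]]
    return df


def read_capture_data(traps_path, captures_path, landscape: Landscape,
                      K: int | None = None) -> CaptureData:
    """Read secr-style trap and capture files into a CaptureData.

    Counts of duplicate (individual, detector, occasion) rows are summed with
    a warning; a capture referencing an unknown detector is an error, as is a
    detector outside the landscape extent.
    """
    traps = _read_table(traps_path, _TRAP_COLS)
    caps = _read_table(captures_path, _CAP_COLS)
    if "count" not in caps.columns:
        caps["count"] = 1
    det_ids = traps["detector"].astype(str).tolist()
    if len(set(det_ids)) != len(det_ids):
        raise ValueError("duplicate detector IDs in traps file")
    coords = traps[["x", "y"]].to_numpy(dtype=float)
    landscape.cell_index(coords[:, 0], coords[:, 1])  # validates extent
    det_index = {d: j for j, d in enumerate(det_ids)}

    unknown = set(caps["detector"].astype(str)) - set(det_ids)
    if unknown:
        raise ValueError(f"captures reference unknown detectors: {sorted(unknown)}")
    occ = caps["occasion"].astype(int)
    if K is None:
        K = int(occ.max())
    if (occ < 1).any() or (occ > K).any():
        raise ValueError(f"occasions must lie in [1, {K}]")
    if (caps["count"] < 1).any():
        raise ValueError("capture counts must be >= 1")

    inds: list[str] = []
    ind_index: dict[str, int] = {}
    for v in caps["individual"].astype(str):
        if v not in ind_index:
            ind_index[v] = len(inds)
            inds.append(v)
    Y = np.zeros((len(inds), len(det_ids), K), dtype=np.int64)
    dup = caps.duplicated(subset=["individual", "occasion", "detector"]).any()
    if dup:
        warnings.warn("duplicate capture rows; counts summed")
    for _, row in caps.iterrows():
        Y[ind_index[str(row["individual"])],
          det_index[str(row["detector"])],
          int(row["occasion"]) - 1] += int(row["count"])
    return CaptureData(DetectorArray(coords, K), Y)


def write_capture_data(data: CaptureData, traps_path, captures_path,
                       session: str = "1") -> None:
    """Write a CaptureData as secr-style traps and captures files."""
    with open(traps_path, "w") as fh:
        fh.write("detector x y\n")
        for j, (x, y) in enumerate(data.detectors.coords, start=1):
            fh.write(f"D{j} {float(x)!r} {float(y)!r}\n")
    with open(captures_path, "w") as fh:
        fh.write("session individual occasion detector count\n")
        nz = np.argwhere(data.Y > 0)
        for i, j, k in nz:
            fh.write(f"{session} I{i + 1} {k + 1} D{j + 1} {data.Y[i, j, k]}\n")


def write_fit(fit: FitResult, path) -> None:
    """Serialize a fit to JSON (null SEs preserved for singular Hessians)."""
    doc = {
        "model": fit.model,
        "version": __version__,
        "loglik": fit.loglik,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "n_detected": fit.n_detected,
        "message": fit.message,
        "params": {
            k: {"mle": fit.params[k], "se": fit.se.get(k),
                "ci": list(fit.ci.get(k, (None, None)))}
            for k in fit.params
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_fit(path) -> FitResult:
    doc = json.loads(Path(path).read_text())
    params = {k: v["mle"] for k, v in doc["params"].items()}
    se = {k: v["se"] for k, v in doc["params"].items()}
    ci = {k: tuple(v["ci"]) for k, v in doc["params"].items()}
    return FitResult(model=doc["model"], params=params, se=se, ci=ci,
                     loglik=doc["loglik"], converged=doc["converged"],
                     n_iter=doc.get("n_iter", 0),
                     n_detected=doc.get("n_detected", 0),
                     message=doc.get("message", ""))
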
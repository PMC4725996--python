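"""Plain-text readers and writers.

Formats: cluster coordinates as CSV (index,x,y,parent,lambda_at_attach),
optional XYZ export for molecular viewers, gyration traces and dimension
curves as TSV, calibration curves as TSV with a JSON metadata sidecar,
and run metadata / fit results as JSON.  Floats are written with 9
significant digits; writing is canonical, so write -> read -> write is
byte-stable (used for determinism hash checks).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .analysis import DimensionCurve, FitResult
from .growth import Cluster, GyrationTrace, LambdaSchedule
from .tuning import CalibrationCurve
from .walkers import Model

__all__ = [
    "write_cluster_csv", "read_cluster_csv",
    "write_xyz",
    "write_trace_tsv", "read_trace_tsv",
    "write_curve_tsv", "read_curve_tsv",
    "write_fit_json", "read_fit_json",
    "write_calibration", "read_calibration",
    "write_metadata", "read_metadata",
]

_F = "%.9g"


def write_cluster_csv(cluster: Cluster, path) -> None:
    lines = ["index,x,y,parent,lambda_at_attach"]
    for i in range(cluster.n):
        x, y = cluster.positions[i]
        lines.append(
            f"{i},{x:.9g},{y:.9g},{int(cluster.parent[i])},"
            f"{cluster.lam_at_attach[i]:.9g}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_cluster_csv(path, model="DLA", schedule=None) -> Cluster:
    raw = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    return Cluster(
        positions=raw[:, 1:3].copy(),
        parent=raw[:, 3].astype(np.int64),
        lam_at_attach=raw[:, 4].copy(),
        model=Model(model),
        schedule=schedule if schedule is not None else LambdaSchedule(),
    )


def write_xyz(cluster: Cluster, path, element: str = "C") -> None:
    """XYZ export (z = 0) for external structure viewers."""
    lines = [str(cluster.n), "2-D aggregate"]
    for x, y in cluster.positions:
        lines.append(f"{element} {x:.9g} {y:.9g} 0.0")
    Path(path).write_text("\n".join(lines) + "\n")


def write_trace_tsv(trace: GyrationTrace, path) -> None:
    lines = ["N\tRg"]
    for n, rg in zip(trace.n, trace.rg):
        lines.append(f"{int(n)}\t{rg:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_trace_tsv(path, record_every: int = 1) -> GyrationTrace:
    raw = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    return GyrationTrace(n=raw[:, 0].astype(np.int64), rg=raw[:, 1],
                         record_every=record_every)


def write_curve_tsv(curve: DimensionCurve, path) -> None:
    lines = ["N\tD"]
    for n, d in zip(curve.n, curve.d):
        lines.append(f"{int(n)}\t{d:.9g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_curve_tsv(path) -> DimensionCurve:
    raw = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    return DimensionCurve(n=raw[:, 0].astype(np.int64), d=raw[:, 1])


def write_fit_json(fit: FitResult, path) -> None:
    Path(path).write_text(json.dumps({
        "D": fit.d,
        "k": fit.k,
        "fit_range": list(fit.fit_range),
        "residual": fit.residual,
        "n_points": fit.n_points,
    }, indent=2, sort_keys=True) + "\n")


def read_fit_json(path) -> FitResult:
    obj = json.loads(Path(path).read_text())
    return FitResult(d=obj["D"], k=obj["k"],
                     fit_range=tuple(obj["fit_range"]),
                     residual=obj["residual"], n_points=obj["n_points"])


def write_calibration(curve: CalibrationCurve, path) -> None:
    """TSV (epsilon, D, D_stderr) plus a .json sidecar with model, D0
    and provenance metadata."""
    path = Path(path)
    lines = ["epsilon\tD\tD_stderr"]
    for e, d, s in zip(curve.epsilon, curve.d, curve.d_stderr):
        lines.append(f"{e:.9g}\t{d:.9g}\t{s:.9g}")
    path.write_text("\n".join(lines) + "\n")
    sidecar = {"model": curve.model.value, "D0": curve.d0,
               "metadata": curve.metadata}
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True) + "\n")


def read_calibration(path) -> CalibrationCurve:
    path = Path(path)
    raw = np.loadtxt(path, delimiter="\t", skiprows=1, ndmin=2)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return CalibrationCurve(
        model=Model(sidecar["model"]),
        epsilon=raw[:, 0], d=raw[:, 1], d_stderr=raw[:, 2],
        d0=sidecar["D0"], metadata=sidecar.get("metadata", {}),
    )


def write_metadata(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_metadata(path) -> dict:
    return json.loads(Path(path).read_text())
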
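"""Plain-text serialization: legacy-VTK meshes, CSV voltages, JSON sidecars.

Meshes with per-element data go out as ASCII legacy VTK unstructured grids
(readable by ParaView and meshio alike); voltage frames as CSV with a JSON
metadata sidecar; axis estimates and ground truth as JSON with millimetre /
degree reporting units.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd


def write_vtk(path, mesh, cell_data: dict | None = None) -> None:
    """Write a tetrahedral mesh with optional per-element scalars."""
    path = Path(path)
    lines = ["# vtk DataFile Version 3.0", "deitbone mesh", "ASCII",
             "DATASET UNSTRUCTURED_GRID",
             f"POINTS {len(mesh.vertices)} double"]
    lines += [" ".join(f"{c:.9g}" for c in v) for v in mesh.vertices]
    n_e = mesh.n_elements
    lines.append(f"CELLS {n_e} {n_e * 5}")
    lines += ["4 " + " ".join(map(str, t)) for t in mesh.tets]
    lines.append(f"CELL_TYPES {n_e}")
    lines += ["10"] * n_e
    data = {"tissue": mesh.tissue_label, **(cell_data or {})}
    lines.append(f"CELL_DATA {n_e}")
    for name, arr in data.items():
        arr = np.asarray(arr)
        kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
        lines += [f"SCALARS {name} {kind} 1", "LOOKUP_TABLE default"]
        lines += [f"{v:.9g}" if kind == "double" else str(int(v)) for v in arr]
    path.write_text("\n".join(lines) + "\n")


def write_voltage_frame(path_csv, frame) -> None:
    """CSV of (pattern, e+, e-, volts) plus a .json protocol sidecar."""
    rows = []
    for p, pairs in enumerate(frame.protocol.measurement_pairs):
        for k, (c, d) in enumerate(pairs):
            rows.append((p, c, d, frame.voltages[p, k]))
    df = pd.DataFrame(rows, columns=["pattern", "e_pos", "e_neg", "volts"])
    path_csv = Path(path_csv)
    df.to_csv(path_csv, index=False)
    meta = dict(provenance=frame.provenance,
                frequency_hz=frame.protocol.frequency,
                n_electrodes=frame.protocol.n_electrodes,
                pattern=frame.protocol.name,
                amplitude_a=frame.protocol.patterns[0][2])
    path_csv.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_voltage_frame(path_csv, protocol):
    """Rebuild a voltage matrix from CSV against a known protocol."""
    from .forward import VoltageFrame
    df = pd.read_csv(path_csv)
    volts = np.empty((len(protocol.measurement_pairs),
                      len(protocol.measurement_pairs[0])))
    for p, pairs in enumerate(protocol.measurement_pairs):
        sub = df[df.pattern == p]
        lookup = {(int(r.e_pos), int(r.e_neg)): r.volts
                  for r in sub.itertuples()}
        volts[p] = [lookup[cd] for cd in pairs]
    return VoltageFrame(voltages=volts, protocol=protocol, provenance="loaded")


def write_delta_sigma_csv(path, field) -> None:
    values = np.asarray(getattr(field, "delta_sigma", field))
    pd.DataFrame({"element": np.arange(len(values)),
                  "delta_sigma": values}).to_csv(path, index=False)


def axis_to_json(estimate, truth=None) -> dict:
    out = dict(stage=estimate.stage,
               centre_mm=[float(c) * 1e3 for c in estimate.p_b],
               axis=[float(c) for c in estimate.n_b],
               zeta_extent_mm=float(estimate.zeta_extent) * 1e3,
               eps_r=float(estimate.eps_r))
    if truth is not None:
        out["true_centre_mm"] = [float(c) * 1e3 for c in truth.o_m]
        out["true_axis"] = [float(c) for c in truth.n_f]
    return out


def write_ground_truth(path, mesh) -> None:
    t = mesh.true_axis
    Path(path).write_text(json.dumps(dict(
        o_m_mm=[float(c) * 1e3 for c in t.o_m],
        n_f=[float(c) for c in t.n_f],
        z_m_mm=float(mesh.z_m) * 1e3,
        shape=mesh.shape,
        params={k: v for k, v in mesh.params.items()
                if isinstance(v, (int, float, str, bool, list, tuple, dict))},
    ), indent=1, default=float))
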
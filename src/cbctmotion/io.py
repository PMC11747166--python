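"""Model checkpointing and ground-truth bundles (HDF5 / CSV plumbing).

A checkpoint is a single HDF5 file holding every learnable array (hash
tables, MLP and CNN weights, batch-norm statistics, B-spline control
coefficients), the projection normalization constants, the grids and scan
geometry, the per-frame solved scores, and the configuration hash — enough
to reproduce online inference exactly.
"""

from __future__ import annotations

import csv

import h5py
import numpy as np

from .geometry import ScanGeometry
from .grids import VolumeGrid
from .motion import MBCBasis, COMPONENTS
from .nets import MotionEncoderCNN, ReferenceINR
from .training import TrainedModel


def _write_grid(g: h5py.Group, grid: VolumeGrid):
    g.attrs["shape"] = grid.shape
    g.attrs["spacing"] = grid.spacing
    g.attrs["origin"] = grid.origin


def _read_grid(g: h5py.Group) -> VolumeGrid:
    return VolumeGrid(np.zeros(tuple(int(s) for s in g.attrs["shape"])),
                      np.asarray(g.attrs["spacing"]),
                      np.asarray(g.attrs["origin"]))


def save_checkpoint(path, model: TrainedModel, config_hash: str = "",
                    stage: str = "final"):
    with h5py.File(str(path), "w") as f:
        f.attrs["config_hash"] = config_hash
        f.attrs["stage"] = stage
        f.attrs["seed"] = model.seed
        f.attrs["norm_lo"] = model.norm_lo
        f.attrs["norm_hi"] = model.norm_hi
        _write_grid(f.create_group("grid_hi"), model.grid_hi)
        _write_grid(f.create_group("grid_lo"), model.grid_lo)

        g = f.create_group("geometry")
        for k, v in model.geometry.as_attrs().items():
            g.attrs[k] = v
        if model.geometry.angles_deg is not None:
            g.create_dataset("angles_deg", data=model.geometry.angles_deg)
        if model.geometry.timestamps_s is not None:
            g.create_dataset("timestamps_s", data=model.geometry.timestamps_s)

        inr = f.create_group("inr")
        inr.attrs["bbox_lo"] = model.inr.bbox_lo
        inr.attrs["bbox_hi"] = model.inr.bbox_hi
        inr.attrs["omega0"] = model.inr.omega0
        enc = model.inr.encoder
        inr.attrs["n_levels"] = enc.n_levels
        inr.attrs["features"] = enc.features
        inr.attrs["log2_table"] = int(np.log2(enc.table_size))
        inr.attrs["resolutions"] = enc.resolutions
        for i, t in enumerate(enc.tables):
            inr.create_dataset(f"table{i}", data=t.data)
        for name in ("w1", "b1", "w2", "b2", "w3", "b3"):
            inr.create_dataset(name, data=getattr(model.inr, name).data)

        b = f.create_group("basis")
        b.attrs["origin"] = model.basis.origin
        b.attrs["extent"] = model.basis.extent
        b.attrs["base_ctrl"] = model.basis.base_ctrl
        for i in range(3):
            lvl = b.create_group(f"level{i}")
            for k, comp in enumerate(COMPONENTS):
                lvl.create_dataset(comp, data=model.basis.coef[i][k].data)

        c = f.create_group("cnn")
        c.attrs["output_scale"] = model.cnn.output_scale
        for j, layer in enumerate(model.cnn.convs):
            lg = c.create_group(f"conv{j}")
            for name in ("w", "b", "gamma", "beta"):
                lg.create_dataset(name, data=layer[name].data)
            lg.create_dataset("run_mean", data=layer["run_mean"])
            lg.create_dataset("run_var", data=layer["run_var"])
        c.create_dataset("w_head", data=model.cnn.w_head.data)
        c.create_dataset("b_head", data=model.cnn.b_head.data)

        f.create_dataset("solved_scores", data=model.solved_scores)


def load_checkpoint(path) -> TrainedModel:
    with h5py.File(str(path), "r") as f:
        grid_hi = _read_grid(f["grid_hi"])
        grid_lo = _read_grid(f["grid_lo"])
        g = f["geometry"]
        geometry = ScanGeometry(
            float(g.attrs["sad_mm"]), float(g.attrs["sdd_mm"]),
            (int(g.attrs["det_rows"]), int(g.attrs["det_cols"])),
            float(g.attrs["pitch_mm"]),
            angles_deg=g["angles_deg"][:] if "angles_deg" in g else None,
            timestamps_s=g["timestamps_s"][:] if "timestamps_s" in g else None)

        ig = f["inr"]
        inr = ReferenceINR(np.asarray(ig.attrs["bbox_lo"]),
                           np.asarray(ig.attrs["bbox_hi"]),
                           omega0=float(ig.attrs["omega0"]),
                           n_levels=int(ig.attrs["n_levels"]),
                           features=int(ig.attrs["features"]),
                           log2_table=int(ig.attrs["log2_table"]))
        inr.encoder.resolutions = [int(r) for r in ig.attrs["resolutions"]]
        for i in range(inr.encoder.n_levels):
            inr.encoder.tables[i].data = ig[f"table{i}"][:]
        for name in ("w1", "b1", "w2", "b2", "w3", "b3"):
            getattr(inr, name).data = ig[name][:]

        bg = f["basis"]
        basis = MBCBasis(np.asarray(bg.attrs["origin"]),
                         np.asarray(bg.attrs["extent"]),
                         int(bg.attrs["base_ctrl"]))
        for i in range(3):
            for k, comp in enumerate(COMPONENTS):
                basis.coef[i][k].data = bg[f"level{i}"][comp][:]

        cg = f["cnn"]
        cnn = MotionEncoderCNN(output_scale=float(cg.attrs["output_scale"]))
        for j, layer in enumerate(cnn.convs):
            lg = cg[f"conv{j}"]
            for name in ("w", "b", "gamma", "beta"):
                layer[name].data = lg[name][:]
            layer["run_mean"][:] = lg["run_mean"][:]
            layer["run_var"][:] = lg["run_var"][:]
        cnn.w_head.data = cg["w_head"][:]
        cnn.b_head.data = cg["b_head"][:]
        cnn.eval()

        model = TrainedModel(inr, basis, cnn, grid_hi, grid_lo, geometry,
                             float(f.attrs["norm_lo"]),
                             float(f.attrs["norm_hi"]),
                             f["solved_scores"][:],
                             seed=int(f.attrs["seed"]))
    return model


def write_trace_csv(path, rows: list[dict]):
    if not rows:
        return
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
        writer.writeheader()
        writer.writerows(rows)


def write_gt_csv(path, gt):
    """COM trace and scalar breathing trace of a GroundTruthSequence."""
    rows = [{"t_s": gt.timestamps_s[k], "trace_mm": gt.trace_mm[k],
             "com_x_mm": gt.coms_mm[k, 0], "com_y_mm": gt.coms_mm[k, 1],
             "com_z_mm": gt.coms_mm[k, 2]} for k in range(len(gt))]
    write_trace_csv(path, rows)
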
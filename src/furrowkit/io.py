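"""Reading and writing the package's on-disk formats.

Tidy CSV for tabular data, single-channel TIFF with a JSON calibration
sidecar for kymographs, YAML for run configurations.

Column conventions
------------------
* ATPase datasets: ``variant, mlck_treated, actin_uM, rate_per_s, replicate``
* Displacement traces: ``time_s, displacement_um``
* Cell traces: ``embryo_id, genotype, cell_id, time_min, area_um2, myosin_au``
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .constriction import CellTrace, EmbryoDataset
from .enzymology import ATPaseDataset
from .recoil import DisplacementTrace, Kymograph

__all__ = [
    "write_atpase_csv", "read_atpase_csv",
    "write_trace_csv", "read_trace_csv",
    "write_cell_traces_csv", "read_cell_traces_csv",
    "write_kymograph", "read_kymograph",
    "load_yaml", "dump_yaml",
]


def write_atpase_csv(datasets: list[ATPaseDataset] | ATPaseDataset,
                     path: str | Path) -> None:
    if isinstance(datasets, ATPaseDataset):
        datasets = [datasets]
    frames = []
    for ds in datasets:
        df = ds.observations.copy()
        df.insert(0, "variant", ds.variant)
        df.insert(1, "mlck_treated", ds.mlck_treated)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_atpase_csv(path: str | Path) -> list[ATPaseDataset]:
    df = pd.read_csv(path)
    out = []
    for (variant, treated), grp in df.groupby(["variant", "mlck_treated"],
                                              sort=False):
        out.append(ATPaseDataset(
            variant=str(variant), mlck_treated=bool(treated),
            observations=grp[["actin_uM", "rate_per_s", "replicate"]]
            .reset_index(drop=True)))
    return out


def write_trace_csv(tr: DisplacementTrace, path: str | Path) -> None:
    pd.DataFrame({"time_s": tr.times, "displacement_um": tr.displacement}) \
        .to_csv(path, index=False)


def read_trace_csv(path: str | Path, metadata: dict | None = None
                   ) -> DisplacementTrace:
    df = pd.read_csv(path)
    return DisplacementTrace(times=df["time_s"].to_numpy(),
                             displacement=df["displacement_um"].to_numpy(),
                             metadata=dict(metadata or {}))


def write_cell_traces_csv(embryos: list[EmbryoDataset] | EmbryoDataset,
                          path: str | Path) -> None:
    if isinstance(embryos, EmbryoDataset):
        embryos = [embryos]
    rows = []
    for emb in embryos:
        for cell in emb.cells:
            rows.append(pd.DataFrame({
                "embryo_id": emb.embryo_id,
                "genotype": emb.genotype,
                "cell_id": cell.cell_id,
                "time_min": cell.times,
                "area_um2": cell.apical_area,
                "myosin_au": cell.myosin_intensity,
            }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def read_cell_traces_csv(path: str | Path,
                         frame_interval: float | None = None
                         ) -> list[EmbryoDataset]:
    df = pd.read_csv(path)
    embryos = []
    for (embryo_id, genotype), grp in df.groupby(["embryo_id", "genotype"],
                                                 sort=False):
        cells = []
        for cell_id, cgrp in grp.groupby("cell_id", sort=False):
            cgrp = cgrp.sort_values("time_min")
            cells.append(CellTrace(
                cell_id=str(cell_id),
                times=cgrp["time_min"].to_numpy(),
                apical_area=cgrp["area_um2"].to_numpy(),
                myosin_intensity=cgrp["myosin_au"].to_numpy()))
        fi = frame_interval
        if fi is None:
            t = cells[0].times
            fi = float(np.diff(t)[0] * 60.0) if t.size > 1 else 1.0
        embryos.append(EmbryoDataset(embryo_id=str(embryo_id),
                                     genotype=str(genotype), cells=cells,
                                     frame_interval=fi))
    return embryos


def write_kymograph(k: Kymograph, path: str | Path) -> None:
    """TIFF image plus a JSON sidecar carrying the physical calibration."""
    path = Path(path)
    tifffile.imwrite(path, k.image.astype(np.float32))
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps({
        "pixel_size_um": k.pixel_size,
        "frame_interval_s": k.frame_interval,
        "cut_position_um": k.cut_position,
        "region_width_um": k.region_width,
    }, indent=2))


def read_kymograph(path: str | Path) -> Kymograph:
    path = Path(path)
    image = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return Kymograph(image=image,
                     pixel_size=meta["pixel_size_um"],
                     frame_interval=meta["frame_interval_s"],
                     cut_position=meta["cut_position_um"],
                     region_width=meta.get("region_width_um", 4.25))


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)
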
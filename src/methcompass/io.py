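"""HDF5 and TSV persistence for signal sets, control tables and panels."""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .containers import RawSignalSet, TissueBetaPanel

__all__ = [
    "write_hdf5",
    "read_signals_hdf5",
    "read_panel_hdf5",
    "read_controls_hdf5",
    "write_control_table_tsv",
    "read_control_table_tsv",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

_STR = h5py.string_dtype(encoding="utf-8")


def _write_index(group, name: str, values) -> None:
    group.create_dataset(name, data=np.asarray([str(v) for v in values], dtype=object),
                         dtype=_STR)


def _read_index(group, name: str) -> pd.Index:
    return pd.Index([v.decode() if isinstance(v, bytes) else v for v in group[name][()]])


def write_hdf5(
    path,
    signals: RawSignalSet | None = None,
    panel: TissueBetaPanel | None = None,
    controls: pd.DataFrame | None = None,
) -> None:
    """Write any of the pipeline inputs to one HDF5 container.

    Layout: /meth, /unmeth, /oob_grn, /oob_red (signals), /betas (panel),
    /controls (control table) plus string index/metadata tables.
    """
    with h5py.File(path, "w") as fh:
        if signals is not None:
            for name, frame in (
                ("meth", signals.meth),
                ("unmeth", signals.unmeth),
                ("oob_grn", signals.oob_grn),
                ("oob_red", signals.oob_red),
            ):
                fh.create_dataset(name, data=frame.to_numpy(dtype=float))
            _write_index(fh, "signal_probes", signals.meth.index)
            _write_index(fh, "signal_samples", signals.meth.columns)
            _write_index(fh, "probe_channel", signals.probe_channel.to_numpy())
        if panel is not None:
            fh.create_dataset("betas", data=panel.betas.to_numpy(dtype=float))
            _write_index(fh, "panel_probes", panel.betas.index)
            _write_index(fh, "panel_samples", panel.betas.columns)
            meta = fh.create_group("sample_metadata")
            for col in panel.samples.columns:
                values = panel.samples[col]
                if values.dtype.kind in "biufc":
                    meta.create_dataset(col, data=values.to_numpy(dtype=float))
                else:
                    _write_index(meta, col, values.astype(str).to_numpy())
        if controls is not None:
            grp = fh.create_group("controls")
            for col in ("sample_id", "control_type", "channel"):
                _write_index(grp, col, controls[col].to_numpy())
            grp.create_dataset("address", data=controls["address"].to_numpy(dtype=int))
            grp.create_dataset("intensity", data=controls["intensity"].to_numpy(dtype=float))


def read_signals_hdf5(path) -> RawSignalSet:
    with h5py.File(path, "r") as fh:
        probes = _read_index(fh, "signal_probes")
        samples = _read_index(fh, "signal_samples")
        channel = _read_index(fh, "probe_channel")
        return RawSignalSet(
            meth=pd.DataFrame(fh["meth"][()], index=probes, columns=samples),
            unmeth=pd.DataFrame(fh["unmeth"][()], index=probes, columns=samples),
            oob_grn=pd.DataFrame(fh["oob_grn"][()], columns=samples),
            oob_red=pd.DataFrame(fh["oob_red"][()], columns=samples),
            probe_channel=pd.Series(channel, index=probes),
        )


def read_panel_hdf5(path) -> TissueBetaPanel:
    with h5py.File(path, "r") as fh:
        probes = _read_index(fh, "panel_probes")
        samples = _read_index(fh, "panel_samples")
        meta = {}
        for col in fh["sample_metadata"]:
            data = fh["sample_metadata"][col][()]
            if data.dtype.kind == "f":
                meta[col] = data
            else:
                meta[col] = [v.decode() if isinstance(v, bytes) else v for v in data]
        sample_df = pd.DataFrame(meta, index=samples)
        if "low_signal" in sample_df:
            sample_df["low_signal"] = sample_df["low_signal"].astype(str) == "True"
        return TissueBetaPanel(
            betas=pd.DataFrame(fh["betas"][()], index=probes, columns=samples),
            samples=sample_df,
        )


def read_controls_hdf5(path) -> pd.DataFrame:
    with h5py.File(path, "r") as fh:
        grp = fh["controls"]
        return pd.DataFrame(
            {
                "sample_id": _read_index(grp, "sample_id"),
                "control_type": _read_index(grp, "control_type"),
                "address": grp["address"][()],
                "channel": _read_index(grp, "channel"),
                "intensity": grp["intensity"][()],
            }
        )


def write_control_table_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_control_table_tsv(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"sample_id", "control_type", "address", "channel", "intensity"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"control table missing columns: {sorted(missing)}")
    return table


def write_matrix_tsv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t", index_label="probe_id")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id")
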
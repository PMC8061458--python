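"""In-memory containers shared across the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass
class RawSignalSet:
    """Per-probe methylated/unmethylated intensities plus out-of-band pools.

    ``meth``/``unmeth`` are probes x samples; ``oob_grn``/``oob_red`` hold the
    background-only out-of-band intensity pools (pool index x samples);
    ``probe_channel`` assigns each probe to the colour channel it is read in.
    """

    meth: pd.DataFrame
    unmeth: pd.DataFrame
    oob_grn: pd.DataFrame
    oob_red: pd.DataFrame
    probe_channel: pd.Series

    def __post_init__(self) -> None:
        if not self.meth.index.equals(self.unmeth.index):
            raise ValueError("meth/unmeth probe indices disagree")
        if not self.meth.columns.equals(self.unmeth.columns):
            raise ValueError("meth/unmeth sample columns disagree")
        for name, frame in (("meth", self.meth), ("unmeth", self.unmeth)):
            arr = frame.to_numpy()
            if (arr < 0).any() or not np.isfinite(arr).all():
                raise ValueError(f"{name} intensities must be finite and >= 0")
        if self.oob_grn.shape[0] == 0 or self.oob_red.shape[0] == 0:
            raise ValueError("out-of-band pools must be non-empty")

    @property
    def samples(self) -> pd.Index:
        return self.meth.columns

    @property
    def probes(self) -> pd.Index:
        return self.meth.index

    def replace(self, **kwargs) -> "RawSignalSet":
        return replace(self, **kwargs)


@dataclass
class TissueBetaPanel:
    """Probes x samples Beta matrix with per-sample labels and covariates.

    ``samples`` is indexed by sample id and carries tissue, study, sex, age,
    cell-fraction columns, replicate group and storage condition.
    """

    betas: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.betas.columns.equals(self.samples.index):
            raise ValueError("beta columns and sample table index disagree")
        arr = self.betas.to_numpy()
        finite = arr[np.isfinite(arr)]
        if ((finite < 0) | (finite > 1)).any():
            raise ValueError("Beta-values must lie in [0, 1]")

    def subset_samples(self, sample_ids) -> "TissueBetaPanel":
        ids = pd.Index(sample_ids)
        return TissueBetaPanel(self.betas[ids], self.samples.loc[ids])

    def tissue_samples(self, tissue: str) -> pd.Index:
        return self.samples.index[self.samples["tissue"] == tissue]
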
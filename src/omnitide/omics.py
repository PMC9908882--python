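"""Core container for one omics layer's feature x sample intensity table.

All layers in the pipeline share one tabular convention: rows are features
(genes, proteins, phosphosites, metabolites), columns are samples named
``t{k}_r{j}`` for timepoint index ``k`` and replicate index ``j``, and
values are log2-scale intensities which may be missing (NaN).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_SAMPLE_RE = re.compile(r"^t(\d+)_r(\d+)$")


def sample_name(timepoint: int, replicate: int) -> str:
    return f"t{timepoint}_r{replicate}"


def parse_sample_name(name: str) -> tuple[int, int]:
    m = _SAMPLE_RE.match(str(name))
    if m is None:
        raise ValueError(f"sample column {name!r} is not of the form t<k>_r<j>")
    return int(m.group(1)), int(m.group(2))


@dataclass
class OmicsMatrix:
    """One layer's features x samples log2 intensity table.

    Parameters
    ----------
    layer:
        Layer name (e.g. ``"WCP"``, ``"PHOS"``).
    values:
        DataFrame indexed by feature id with sample columns ``t{k}_r{j}``.
        Missing measurements are NaN.
    """

    layer: str
    values: pd.DataFrame
    sample_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.sample_meta is None:
            tp, rep = zip(*(parse_sample_name(c) for c in self.values.columns))
            self.sample_meta = pd.DataFrame(
                {"timepoint": tp, "replicate": rep}, index=self.values.columns
            )
        if len(self.sample_meta) != self.values.shape[1]:
            raise ValueError("sample_meta does not cover all sample columns")
        counts = self.sample_meta.groupby("timepoint").size()
        if (counts < 1).any():
            raise ValueError("every timepoint needs at least one replicate")

    # -- basic introspection -------------------------------------------------

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def n_timepoints(self) -> int:
        return int(self.sample_meta["timepoint"].nunique())

    @property
    def timepoints(self) -> np.ndarray:
        return np.sort(self.sample_meta["timepoint"].unique())

    @property
    def n_replicates(self) -> int:
        return int(self.sample_meta["replicate"].nunique())

    def columns_at(self, timepoint: int) -> list[str]:
        mask = self.sample_meta["timepoint"] == timepoint
        return list(self.sample_meta.index[mask])

    def replicate_blocks(self) -> dict[int, list[str]]:
        """Sample columns grouped by replicate (one TMT plex per replicate)."""
        out: dict[int, list[str]] = {}
        for col, rep in self.sample_meta["replicate"].items():
            out.setdefault(int(rep), []).append(col)
        return out

    def timepoint_means(self) -> pd.DataFrame:
        """Feature x timepoint replicate-mean matrix (NaN-aware)."""
        groups = self.sample_meta["timepoint"]
        return self.values.T.groupby(groups).mean().T

    def copy(self) -> "OmicsMatrix":
        return OmicsMatrix(self.layer, self.values.copy(), self.sample_meta.copy())

    # -- I/O -----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(cls, path, layer: str | None = None) -> "OmicsMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        name = layer if layer is not None else str(getattr(path, "stem", path))
        return cls(name, df)
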
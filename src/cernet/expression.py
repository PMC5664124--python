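"""FPKM expression matrices with tissue/stage/replicate sample metadata.

The unit of abundance throughout the package is FPKM (fragments per
kilobase of transcript per million mapped reads). Samples follow a
tissue x developmental-stage x replicate design, e.g. maize embryo and
endosperm at 9/15/20 days after pollination (DAP). Sample columns are
named ``<tissue>_<stage>DAP_rep<k>``.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "sample_name"]


def sample_name(tissue: str, stage: int, replicate: int) -> str:
    """Canonical column name for a (tissue, stage, replicate) sample."""
    return f"{tissue}_{stage}DAP_rep{replicate}"


class ExpressionMatrix:
    """Features x samples matrix of non-negative FPKM values.

    Parameters
    ----------
    data : pandas.DataFrame
        Rows indexed by feature id, columns by sample name, values FPKM >= 0.
    samples : pandas.DataFrame
        Indexed by sample name, with columns ``tissue`` (str),
        ``stage`` (int) and ``replicate`` (int). Column order must match
        ``data.columns``.
    """

    def __init__(self, data: pd.DataFrame, samples: pd.DataFrame):
        data = data.astype(float)
        if list(data.columns) != list(samples.index):
            raise ValueError("sample sheet index must match expression columns in order")
        for col in ("tissue", "stage", "replicate"):
            if col not in samples.columns:
                raise ValueError(f"sample sheet missing column {col!r}")
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dups}")
        if samples.index.has_duplicates:
            raise ValueError("duplicate sample names")
        vals = data.to_numpy()
        if not np.isfinite(vals).all():
            raise ValueError("expression matrix contains missing or non-finite cells")
        if (vals < 0).any():
            raise ValueError("FPKM values must be non-negative")
        self.data = data
        self.samples = samples.copy()
        self.samples["stage"] = self.samples["stage"].astype(int)
        self.samples["replicate"] = self.samples["replicate"].astype(int)

    # -- accessors -----------------------------------------------------------

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def tissues(self) -> list[str]:
        return sorted(self.samples["tissue"].unique())

    @property
    def stages(self) -> list[int]:
        return sorted(self.samples["stage"].unique())

    def samples_in(self, tissue: str | None = None, stage: int | None = None) -> list[str]:
        """Sample names restricted to a tissue and/or stage."""
        mask = pd.Series(True, index=self.samples.index)
        if tissue is not None:
            mask &= self.samples["tissue"] == tissue
        if stage is not None:
            mask &= self.samples["stage"] == int(stage)
        return list(self.samples.index[mask])

    def values_for(self, feature_id: str, sample_names: Sequence[str] | None = None) -> np.ndarray:
        row = self.data.loc[feature_id]
        if sample_names is not None:
            row = row[list(sample_names)]
        return row.to_numpy(dtype=float)

    def subset(self, feature_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(feature_ids)
        missing = [i for i in ids if i not in self.data.index]
        if missing:
            raise KeyError(f"features not in matrix: {missing}")
        return ExpressionMatrix(self.data.loc[ids], self.samples)

    def log2(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """log2(FPKM + pseudocount) transform of the full matrix."""
        return np.log2(self.data + pseudocount)

    # -- I/O -----------------------------------------------------------------

    @classmethod
    def from_tsv(cls, expr_path, samples_path) -> "ExpressionMatrix":
        data = pd.read_csv(expr_path, sep="\t", index_col=0)
        samples = pd.read_csv(samples_path, sep="\t", index_col=0)
        return cls(data, samples)

    def to_tsv(self, expr_path, samples_path=None, float_format: str = "%.6g") -> None:
        self.data.to_csv(expr_path, sep="\t", float_format=float_format)
        if samples_path is not None:
            self.samples.to_csv(samples_path, sep="\t")

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ExpressionMatrix({self.data.shape[0]} features x "
            f"{self.data.shape[1]} samples)"
        )
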
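"""Omics data blocks and delimited-text round-tripping.

An :class:`OmicsBlock` is one assay/compartment matrix (samples x features)
with an assay kind and a source (compartment) label.  All downstream stages —
filtering, TMM normalization, standardization, the co-inertia decomposition —
operate on these blocks.  Matrices are stored as pandas DataFrames (rows =
samples, columns = features) and serialized as plain TSV with the sample id
in the first column and feature ids in the header.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: assays whose values are non-negative integer molecule counts
COUNT_ASSAYS = frozenset({"smallseq", "mintmap"})
VALID_ASSAYS = frozenset({"smallseq", "mintmap", "methylome"})
VALID_SOURCES = frozenset({"plasma", "pbmc", "csf_cells", "csf_free"})


@dataclass(frozen=True)
class OmicsBlock:
    """One assay/compartment data matrix.

    Parameters
    ----------
    data : pandas.DataFrame
        Samples x features matrix; index holds sample ids, columns feature ids.
    assay : str
        One of ``smallseq``, ``mintmap`` (UMI / tRF counts) or ``methylome``
        (smoothed beta values in [0, 1]).
    source : str
        Compartment of origin: ``plasma``, ``pbmc``, ``csf_cells`` or
        ``csf_free``.
    """

    data: pd.DataFrame
    assay: str
    source: str
    name: str = field(default="")

    def __post_init__(self) -> None:
        if self.assay not in VALID_ASSAYS:
            raise ValueError(f"unknown assay {self.assay!r}; expected one of {sorted(VALID_ASSAYS)}")
        if self.source not in VALID_SOURCES:
            raise ValueError(f"unknown source {self.source!r}; expected one of {sorted(VALID_SOURCES)}")
        if not self.name:
            object.__setattr__(self, "name", f"{self.source}_{self.assay}")
        df = self.data
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup!r}")
        if df.columns.has_duplicates:
            dup = df.columns[df.columns.duplicated()][0]
            raise ValueError(f"duplicate feature id {dup!r}")
        values = df.to_numpy(dtype=float, copy=False)
        if values.size and not np.isfinite(values).all():
            raise ValueError("block contains missing or non-finite values")
        if self.assay in COUNT_ASSAYS and values.size and (values < 0).any():
            raise ValueError("count assay contains negative values")

    # -- convenience accessors -------------------------------------------------

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index.astype(str))

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns.astype(str))

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_features(self) -> int:
        return self.data.shape[1]

    @property
    def is_count_assay(self) -> bool:
        return self.assay in COUNT_ASSAYS

    def with_data(self, data: pd.DataFrame) -> "OmicsBlock":
        """Return a copy of this block holding ``data`` instead."""
        return replace(self, data=data)

    def subset_features(self, feature_ids) -> "OmicsBlock":
        """Restrict to the given features, preserving their stored order."""
        keep = [f for f in self.feature_ids if f in set(map(str, feature_ids))]
        return self.with_data(self.data.loc[:, keep])

    def subset_samples(self, sample_ids) -> "OmicsBlock":
        """Restrict to the given samples, in the order supplied."""
        return self.with_data(self.data.loc[list(sample_ids), :])


def read_matrix(path, assay: str, source: str, name: str = "") -> OmicsBlock:
    """Read a TSV matrix (first column sample id, header = feature ids)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str},
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in matrix body: {exc}") from exc
    return OmicsBlock(data=df, assay=assay, source=source, name=name)


def write_matrix(block: OmicsBlock, path) -> None:
    """Write a block as TSV; ``read_matrix`` inverts this to full precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = block.data.copy()
    df.index.name = "sample_id"
    # repr round-trips float64 exactly through pandas' parser
    df.to_csv(path, sep="\t", float_format=lambda x: repr(float(x)))


def check_shared_samples(blocks) -> list[str]:
    """Assert all blocks carry the identical ordered sample ids; return them."""
    blocks = list(blocks)
    if not blocks:
        raise ValueError("no blocks supplied")
    ref = blocks[0].sample_ids
    for b in blocks[1:]:
        if b.sample_ids != ref:
            raise ValueError(
                f"sample ids of block {b.name!r} do not match block {blocks[0].name!r}"
            )
    return ref
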
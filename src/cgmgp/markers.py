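"""Marker matrix container shared by the simulator and the GP engines."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MarkerMatrix", "as_marker_array"]


@dataclass(frozen=True)
class MarkerMatrix:
    """n genotypes x p biallelic SNPs coded {-1, 0, 1}.

    -1 = homozygous reference, 0 = heterozygous, 1 = homozygous alternate.
    Marker IDs are ordered along the genome, which the convolutional engine
    relies on.
    """

    values: np.ndarray
    genotype_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]

    def __post_init__(self):
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("marker matrix must be 2-D")
        if not np.isin(values, (-1, 0, 1)).all():
            raise ValueError("marker codes must be in {-1, 0, 1}")
        object.__setattr__(self, "values", values.astype(np.int8))
        object.__setattr__(self, "genotype_ids", tuple(self.genotype_ids))
        object.__setattr__(self, "marker_ids", tuple(self.marker_ids))
        n, p = values.shape
        if len(self.genotype_ids) != n or len(self.marker_ids) != p:
            raise ValueError("id lengths do not match matrix shape")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def dosage(self) -> np.ndarray:
        """Alternate-allele dosage in {0, 1, 2}."""
        return self.values.astype(np.float64) + 1.0

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per marker."""
        return self.dosage().mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        freq = self.allele_freq()
        return np.minimum(freq, 1.0 - freq)

    def subset(self, rows) -> "MarkerMatrix":
        rows = np.asarray(rows)
        return MarkerMatrix(
            self.values[rows],
            tuple(np.asarray(self.genotype_ids, dtype=object)[rows]),
            self.marker_ids,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.genotype_ids), columns=list(self.marker_ids)
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MarkerMatrix":
        return cls(frame.to_numpy(), tuple(map(str, frame.index)), tuple(map(str, frame.columns)))


def as_marker_array(X) -> np.ndarray:
    """Coerce a MarkerMatrix / DataFrame / ndarray to a float64 array."""
    if isinstance(X, MarkerMatrix):
        return X.values.astype(np.float64)
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=np.float64)
    return np.asarray(X, dtype=np.float64)
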
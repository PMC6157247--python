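"""Two-phenotype panel container with explicit missingness.

The panel stores a 2 x n table of phenotype measurements (rows = phenotypes,
columns = individuals) plus a boolean missingness mask.  Its stacked view Y is
phenotype-major: (y_{1,1} ... y_{1,n}, y_{2,1} ... y_{2,n}), the layout every
covariance in the package assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING_CODE = "NA"


@dataclass
class PhenotypePanel:
    """Phenotype measurements for two phenotypes on an ordered sample.

    ``values[k, i]`` is phenotype k+1 of individual i; missing entries are
    NaN and flagged in ``mask`` (True = missing).  Observed values must be
    finite.
    """

    ids: list[str]
    values: np.ndarray
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != 2:
            raise ValueError(f"values must be 2 x n, got shape {self.values.shape}")
        if self.values.shape[1] != len(self.ids):
            raise ValueError("number of columns must match number of ids")
        if self.mask is None:
            self.mask = np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape must match values shape")
        if np.isnan(self.values[~self.mask]).any() or np.isinf(self.values[~self.mask]).any():
            raise ValueError("observed (unmasked) values must be finite")
        self.values = self.values.copy()
        self.values[self.mask] = np.nan

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def y_stacked(self) -> np.ndarray:
        """Length-2n phenotype-major stacked vector (NaN at missing entries)."""
        return self.values.reshape(-1)

    @property
    def mask_stacked(self) -> np.ndarray:
        """Length-2n missingness indicator aligned with :attr:`y_stacked`."""
        return self.mask.reshape(-1)

    @property
    def n_observed(self) -> int:
        return int((~self.mask).sum())

    def copy(self) -> "PhenotypePanel":
        return PhenotypePanel(list(self.ids), self.values.copy(), self.mask.copy())

    def to_tsv(self, path, pheno_names: tuple[str, str] = ("pheno1", "pheno2")) -> None:
        df = pd.DataFrame(
            {
                "id": self.ids,
                pheno_names[0]: self.values[0],
                pheno_names[1]: self.values[1],
            }
        )
        df.to_csv(path, sep="\t", index=False, na_rep=MISSING_CODE)

    @classmethod
    def from_tsv(cls, path, pheno_names: tuple[str, str] | None = None) -> "PhenotypePanel":
        df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=[MISSING_CODE])
        if "id" not in df.columns:
            raise ValueError(f"{path}: expected an 'id' column")
        if pheno_names is None:
            cols = [c for c in df.columns if c != "id"]
            if len(cols) != 2:
                raise ValueError(
                    f"{path}: expected exactly 2 phenotype columns, got {cols}"
                )
            pheno_names = (cols[0], cols[1])
        values = np.vstack(
            [df[pheno_names[0]].to_numpy(float), df[pheno_names[1]].to_numpy(float)]
        )
        return cls([str(i) for i in df["id"]], values)
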
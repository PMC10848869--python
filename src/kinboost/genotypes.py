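"""Diploid genotype container.

Genotypes are stored as an ``(n_individuals, n_loci, 2)`` integer array of
0-based allele indices into each locus's allele list, with ``-1`` marking a
missing genotype (both slots set).  The on-disk format is a TSV with two
columns per locus and missing alleles encoded ``0`` (genepop convention,
1-based allele labels).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import PanelConfig, geno_code

__all__ = ["GenotypeTable", "count_mendelian_mismatches"]

MISSING = -1


@dataclass
class GenotypeTable:
    ids: list[str]
    panel: PanelConfig
    alleles: np.ndarray  # (n, L, 2) int16, -1 = missing

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int16)
        n, L, two = self.alleles.shape
        if two != 2 or L != self.panel.n_loci or n != len(self.ids):
            raise ValueError("genotype array shape inconsistent with ids/panel")
        self._index = {i: k for k, i in enumerate(self.ids)}

    @property
    def n(self) -> int:
        return len(self.ids)

    def row(self, individual_id: str) -> int:
        try:
            return self._index[individual_id]
        except KeyError:
            raise KeyError(f"unknown individual id: {individual_id}") from None

    def missing_mask(self) -> np.ndarray:
        """(n, L) boolean, True where the genotype is missing."""
        return self.alleles[:, :, 0] == MISSING

    def codes(self) -> np.ndarray:
        """(n, L) canonical unordered-genotype codes, -1 where missing."""
        a = self.alleles[:, :, 0].astype(np.int64)
        b = self.alleles[:, :, 1].astype(np.int64)
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        out = hi * (hi + 1) // 2 + lo
        out[a == MISSING] = -1
        return out

    def n_genotyped(self) -> np.ndarray:
        return (~self.missing_mask()).sum(axis=1)

    def subset(self, ids: list[str]) -> "GenotypeTable":
        rows = [self.row(i) for i in ids]
        return GenotypeTable(list(ids), self.panel, self.alleles[rows].copy())

    # ---- I/O -----------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"id": np.asarray(self.ids)}
        for l, locus in enumerate(self.panel.loci):
            for s in (0, 1):
                v = self.alleles[:, l, s].astype(int) + 1  # 1-based, missing -> 0
                v[self.alleles[:, l, s] == MISSING] = 0
                cols[f"{locus.name}_{s + 1}"] = v
        return pd.DataFrame(cols)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path, panel: PanelConfig) -> "GenotypeTable":
        df = pd.read_csv(path, sep="\t", dtype={"id": str})
        n = len(df)
        alleles = np.full((n, panel.n_loci, 2), MISSING, dtype=np.int16)
        for l, locus in enumerate(panel.loci):
            for s in (0, 1):
                col = df[f"{locus.name}_{s + 1}"].to_numpy(dtype=int)
                alleles[:, l, s] = col - 1  # 0 -> -1 missing
        # genotype missing iff either slot missing
        bad = (alleles == MISSING).any(axis=2)
        alleles[bad] = MISSING
        return cls(list(df["id"]), panel, alleles)

    def write_genepop(self, path: str | Path, pops: pd.Series | None = None, title: str = "kinboost export") -> None:
        """Genepop text export; ``pops`` maps id -> population label (e.g. return year)."""
        lines = [title]
        lines.extend(self.panel.names)
        frame = self.to_frame().set_index("id")
        groups: list[list[str]]
        if pops is None:
            groups = [list(self.ids)]
        else:
            order = pops.reindex(self.ids)
            groups = [list(sub.index) for _, sub in order.groupby(order, sort=True)]
        for members in groups:
            lines.append("Pop")
            for ind in members:
                row = frame.loc[ind]
                genos = []
                for locus in self.panel.loci:
                    a = int(row[f"{locus.name}_1"])
                    b = int(row[f"{locus.name}_2"])
                    genos.append(f"{a:03d}{b:03d}")
                lines.append(f"{ind}, " + " ".join(genos))
        Path(path).write_text("\n".join(lines) + "\n")


def count_mendelian_mismatches(gt: GenotypeTable, offspring_id: str, parent_id: str) -> int:
    """Number of loci (non-missing in both) where the pair shares no allele."""
    o = gt.alleles[gt.row(offspring_id)]
    p = gt.alleles[gt.row(parent_id)]
    ok = (o[:, 0] != MISSING) & (p[:, 0] != MISSING)
    share = (
        (o[:, 0] == p[:, 0])
        | (o[:, 0] == p[:, 1])
        | (o[:, 1] == p[:, 0])
        | (o[:, 1] == p[:, 1])
    )
    return int((~share & ok).sum())
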
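"""Marker panel definitions.

A panel is a list of loci (SNPs and STRs) with population allele
frequencies, a genotyping error rate, and optional per-locus missingness
and null-allele rates.  Every likelihood in the package is computed from
a :class:`PanelConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["Locus", "PanelConfig", "default_panel", "geno_code", "code_to_pair", "n_geno_codes"]


def n_geno_codes(k: int) -> int:
    """Number of unordered diploid genotypes for a locus with *k* alleles."""
    return k * (k + 1) // 2


def geno_code(a: int, b: int) -> int:
    """Canonical index of the unordered genotype {a, b} (allele indices)."""
    i, j = (a, b) if a <= b else (b, a)
    return j * (j + 1) // 2 + i


def code_to_pair(code: int) -> tuple[int, int]:
    """Inverse of :func:`geno_code`."""
    j = int((np.sqrt(8 * code + 1) - 1) // 2)
    i = code - j * (j + 1) // 2
    if i > j:  # guard against float edge
        j += 1
        i = code - j * (j + 1) // 2
    return i, j


@dataclass(frozen=True)
class Locus:
    """One marker: name, type (``"SNP"`` or ``"STR"``), allele frequencies.

    ``missing_rate`` and ``null_allele_freq`` are simulation parameters;
    they are ignored by the likelihood machinery, which conditions on the
    observed (visible) genotypes.
    """

    name: str
    marker_type: str
    allele_freqs: tuple[float, ...]
    missing_rate: float = 0.0
    null_allele_freq: float = 0.0

    def __post_init__(self) -> None:
        if self.marker_type not in ("SNP", "STR"):
            raise ValueError(f"{self.name}: marker_type must be 'SNP' or 'STR'")
        freqs = np.asarray(self.allele_freqs, dtype=float)
        if abs(freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"{self.name}: allele frequencies sum to {freqs.sum()}, not 1")
        if (freqs < 0).any():
            raise ValueError(f"{self.name}: negative allele frequency")
        if self.marker_type == "SNP" and len(freqs) != 2:
            raise ValueError(f"{self.name}: SNP must have exactly 2 alleles")
        if self.marker_type == "STR" and len(freqs) < 2:
            raise ValueError(f"{self.name}: STR must have >=2 alleles")
        for attr in ("missing_rate", "null_allele_freq"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: {attr}={v} outside [0, 1]")

    @property
    def n_alleles(self) -> int:
        return len(self.allele_freqs)

    @property
    def freqs(self) -> np.ndarray:
        return np.asarray(self.allele_freqs, dtype=float)


@dataclass
class PanelConfig:
    """A full marker panel with its genotyping error rate."""

    loci: list[Locus]
    error_rate: float = 0.005

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError(f"error_rate={self.error_rate} outside [0, 1)")
        names = [l.name for l in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names")

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def names(self) -> list[str]:
        return [l.name for l in self.loci]

    @property
    def snp_indices(self) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.loci) if l.marker_type == "SNP"], dtype=int)

    @property
    def str_indices(self) -> np.ndarray:
        return np.array([i for i, l in enumerate(self.loci) if l.marker_type == "STR"], dtype=int)

    @property
    def n_snp(self) -> int:
        return len(self.snp_indices)

    @property
    def n_str(self) -> int:
        return len(self.str_indices)

    def locus(self, name: str) -> Locus:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)

    # ---- serialisation -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "error_rate": float(self.error_rate),
            "loci": [
                {
                    "name": l.name,
                    "type": l.marker_type,
                    "alleles": list(range(1, l.n_alleles + 1)),
                    "frequencies": [float(f) for f in l.allele_freqs],
                    "missing_rate": float(l.missing_rate),
                    "null_allele_freq": float(l.null_allele_freq),
                }
                for l in self.loci
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PanelConfig":
        doc = yaml.safe_load(Path(path).read_text())
        loci = [
            Locus(
                name=entry["name"],
                marker_type=entry["type"],
                allele_freqs=tuple(entry["frequencies"]),
                missing_rate=float(entry.get("missing_rate", 0.0)),
                null_allele_freq=float(entry.get("null_allele_freq", 0.0)),
            )
            for entry in doc["loci"]
        ]
        return cls(loci=loci, error_rate=float(doc.get("error_rate", 0.005)))


def default_panel(
    n_snp: int = 45,
    n_str: int = 9,
    str_alleles: int = 8,
    error_rate: float = 0.005,
    missing_rate: float = 0.01,
    seed: int = 7,
) -> PanelConfig:
    """A reproducible mixed panel shaped like the study panel.

    45 SNPs with minor allele frequencies drawn uniformly on [0.1, 0.5]
    and 9 STRs with 8 equifrequent alleles each; genotyping error rate
    0.005 and a small per-locus missingness.
    """
    rng = np.random.default_rng(seed)
    loci: list[Locus] = []
    for i in range(n_str):
        f = np.full(str_alleles, 1.0 / str_alleles)
        loci.append(
            Locus(
                name=f"STR{i + 1:02d}",
                marker_type="STR",
                allele_freqs=tuple(f),
                missing_rate=missing_rate,
            )
        )
    for i in range(n_snp):
        maf = rng.uniform(0.1, 0.5)
        loci.append(
            Locus(
                name=f"SNP{i + 1:02d}",
                marker_type="SNP",
                allele_freqs=(1.0 - maf, maf),
                missing_rate=missing_rate,
            )
        )
    return PanelConfig(loci=loci, error_rate=error_rate)
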
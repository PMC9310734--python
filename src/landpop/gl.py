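"""Genotype-likelihood container and beagle text interchange.

A :class:`GenotypeLikelihoodSet` holds, for every individual and biallelic
site, the likelihood of the three diploid genotypes (0, 1 or 2 copies of
the derived/minor allele). Likelihoods are stored normalized so the maximum
of the three values is 1 for each individual/site; a site with zero read
depth carries three equal values and is treated as missing.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["GenotypeLikelihoodSet", "read_beagle", "write_beagle", "read_sample_sheet"]

_ALLELE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3}
_CODE_ALLELES = "ACGT"


@dataclass
class GenotypeLikelihoodSet:
    individuals: list[str]
    site_ids: list[str]
    likelihoods: np.ndarray               # (n_sites, n_ind, 3)
    allele1: np.ndarray = field(default=None)  # derived/minor allele code per site
    allele2: np.ndarray = field(default=None)  # ancestral/major allele code per site
    polarization: str = "unfolded"        # "unfolded" | "folded"

    def __post_init__(self) -> None:
        self.likelihoods = np.asarray(self.likelihoods, dtype=float)
        n_sites, n_ind = len(self.site_ids), len(self.individuals)
        if self.likelihoods.shape != (n_sites, n_ind, 3):
            raise ValueError(
                f"likelihood array shape {self.likelihoods.shape} does not match "
                f"{n_sites} sites x {n_ind} individuals x 3"
            )
        if np.any(self.likelihoods < 0):
            raise ValueError("genotype likelihoods must be non-negative")
        if n_sites < 1:
            raise ValueError("at least one site required")
        if self.allele1 is None:
            self.allele1 = np.zeros(n_sites, dtype=int)
        if self.allele2 is None:
            self.allele2 = np.ones(n_sites, dtype=int)
        if self.polarization not in ("unfolded", "folded"):
            raise ValueError("polarization must be 'unfolded' or 'folded'")
        self.normalize()

    # ------------------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def normalize(self) -> None:
        """Rescale so max of the 3 values is 1 per individual/site (uniform if all zero)."""
        mx = self.likelihoods.max(axis=2, keepdims=True)
        zero = mx[..., 0] == 0
        with np.errstate(invalid="ignore", divide="ignore"):
            self.likelihoods = np.where(mx > 0, self.likelihoods / np.where(mx == 0, 1, mx), 1.0)
        if np.any(zero):
            self.likelihoods[zero] = 1.0

    def missing_mask(self) -> np.ndarray:
        """(n_sites, n_ind) True where the three likelihoods are all equal (no data)."""
        gl = self.likelihoods
        return (gl[..., 0] == gl[..., 1]) & (gl[..., 1] == gl[..., 2])

    def subset_individuals(self, names: list[str]) -> "GenotypeLikelihoodSet":
        idx = [self.individuals.index(n) for n in names]
        return GenotypeLikelihoodSet(
            list(names), list(self.site_ids), self.likelihoods[:, idx, :],
            self.allele1.copy(), self.allele2.copy(), self.polarization,
        )

    def subset_sites(self, site_ids: list[str]) -> "GenotypeLikelihoodSet":
        pos = {s: i for i, s in enumerate(self.site_ids)}
        idx = [pos[s] for s in site_ids]
        return GenotypeLikelihoodSet(
            list(self.individuals), list(site_ids), self.likelihoods[idx],
            self.allele1[idx], self.allele2[idx], self.polarization,
        )


# -- beagle text format -----------------------------------------------------

def write_beagle(gl: GenotypeLikelihoodSet, path: str | Path) -> None:
    """Write the de facto GL interchange format: tab-separated text, one row per
    site, header ``marker allele1 allele2 Ind0 Ind0 Ind0 ...``."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        cols = ["marker", "allele1", "allele2"]
        for name in gl.individuals:
            cols.extend([name] * 3)
        fh.write("\t".join(cols) + "\n")
        for s in range(gl.n_sites):
            row = [gl.site_ids[s], str(int(gl.allele1[s])), str(int(gl.allele2[s]))]
            row.extend(f"{v:.6f}" for v in gl.likelihoods[s].ravel())
            fh.write("\t".join(row) + "\n")


def read_beagle(path: str | Path, polarization: str = "unfolded") -> GenotypeLikelihoodSet:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        header = fh.readline().split("\t")
        if len(header) < 6 or (len(header) - 3) % 3 != 0:
            raise ValueError(f"{path}: malformed beagle header ({len(header)} columns)")
        individuals = [header[i].strip() for i in range(3, len(header), 3)]
        site_ids, a1, a2, rows = [], [], [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.split("\t")
            if len(parts) != len(header):
                raise ValueError(
                    f"{path}:{lineno}: expected {len(header)} fields, found {len(parts)}"
                )
            site_ids.append(parts[0])
            a1.append(int(parts[1]))
            a2.append(int(parts[2]))
            rows.append([float(v) for v in parts[3:]])
    gls = np.asarray(rows).reshape(len(site_ids), len(individuals), 3)
    return GenotypeLikelihoodSet(
        individuals, site_ids, gls, np.asarray(a1), np.asarray(a2), polarization
    )


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    """Sample sheet CSV with columns individual, locality, lon, lat."""
    df = pd.read_csv(path)
    required = {"individual", "locality", "lon", "lat"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    return df
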
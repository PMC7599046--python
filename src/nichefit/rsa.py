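"""Empirical species-abundance distributions and classical alpha-diversity.

This module handles the observational side of the analysis: reading OTU
count tables, extracting per-sample abundance vectors, building the
relative species abundance (RSA) histogram and its log2-octave (Preston)
binning, and computing the five classical diversity indices (Shannon,
Pielou, Simpson, Hill numbers of order 1 and 2).

Conventions
-----------
* Preston octave ``k`` covers abundances in the half-open interval
  ``[2**k, 2**(k+1))``, with ``k = 0`` holding singletons.  Octave
  boundaries are not split across bins.
* Shannon entropy is in nats (base e), which is what makes the identity
  ``Hill_1 = exp(H)`` hold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OTUTable",
    "AbundanceVector",
    "RSAHistogram",
    "PrestonHistogram",
    "DiversityProfile",
    "load_otu_table",
    "load_biom_table",
    "abundance_vector",
    "rsa_histogram",
    "preston_histogram",
    "diversity_profile",
    "diversity_table",
]


class OTUTableError(ValueError):
    """Raised for malformed OTU count input."""


@dataclass(frozen=True)
class OTUTable:
    """A samples x OTUs matrix of non-negative integer read counts."""

    sample_ids: tuple[str, ...]
    otu_ids: tuple[str, ...]
    counts: np.ndarray  # shape (n_samples, n_otus), integer dtype

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise OTUTableError("counts must be a 2-D matrix")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                bad = np.argwhere(counts != np.round(counts))[0]
                raise OTUTableError(
                    f"non-integer count at sample {self.sample_ids[bad[0]]!r}, "
                    f"OTU {self.otu_ids[bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise OTUTableError(
                f"negative count at sample {self.sample_ids[bad[0]]!r}, "
                f"OTU {self.otu_ids[bad[1]]!r}"
            )
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise OTUTableError(
                f"label/matrix mismatch: counts {counts.shape} vs "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            seen: set[str] = set()
            dup = next(s for s in self.sample_ids if s in seen or seen.add(s))
            raise OTUTableError(f"duplicate sample id {dup!r}")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "otu_ids", tuple(self.otu_ids))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.sample_ids), columns=list(self.otu_ids)
        )

    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV, samples in rows (round-trips via ``load_otu_table``)."""
        df = self.to_frame()
        df.index.name = "sample_id"
        df.to_csv(path, sep="\t")


def load_otu_table(
    path: str | Path, orientation: str = "samples-in-rows"
) -> OTUTable:
    """Read an OTU count matrix from TSV/CSV.

    Parameters
    ----------
    path
        Delimited text file with one header row and one label column.
    orientation
        ``"samples-in-rows"`` or ``"samples-in-columns"``.  Tables are
        normalized to samples-in-rows; there is no auto-detection because
        a numeric matrix cannot disambiguate the two layouts.
    """
    path = Path(path)
    if not path.exists():
        raise OTUTableError(f"no such file: {path}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    if orientation == "samples-in-columns":
        df = df.T
    elif orientation != "samples-in-rows":
        raise OTUTableError(f"unknown orientation {orientation!r}")
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            if bad.any():
                i = int(np.argmax(bad.to_numpy()))
                raise OTUTableError(
                    f"non-numeric entry {df.iloc[i, j]!r} at sample "
                    f"{df.index[i]!r}, OTU {col!r}"
                )
    return OTUTable(
        sample_ids=tuple(str(s) for s in df.index),
        otu_ids=tuple(str(o) for o in df.columns),
        counts=values,
    )


def load_biom_table(path: str | Path) -> OTUTable:
    """Read a BIOM-format table (observations x samples) into an OTUTable."""
    import biom  # deferred: only needed for BIOM input

    table = biom.load_table(str(path))
    # biom stores observations (OTUs) in rows, samples in columns
    counts = np.asarray(table.matrix_data.todense()).T
    return OTUTable(
        sample_ids=tuple(str(s) for s in table.ids("sample")),
        otu_ids=tuple(str(o) for o in table.ids("observation")),
        counts=counts,
    )


@dataclass(frozen=True)
class AbundanceVector:
    """Positive read counts of the OTUs observed in one sample.

    ``n_obs`` is the observed species richness (the number of OTUs with at
    least one read), which also scales the expected species-abundance
    distribution of the fitted models.
    """

    counts: np.ndarray
    sample_id: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D vector")
        if (counts < 1).any():
            raise ValueError("abundance vector entries must be >= 1")
        object.__setattr__(self, "counts", counts)

    @property
    def n_obs(self) -> int:
        return int(self.counts.size)

    @property
    def total_reads(self) -> int:
        return int(self.counts.sum())


def abundance_vector(table: OTUTable, sample_id: str) -> AbundanceVector:
    """Extract one sample's positive counts, dropping zero-count OTUs."""
    try:
        row = table.sample_ids.index(sample_id)
    except ValueError:
        raise KeyError(f"unknown sample id {sample_id!r}") from None
    counts = table.counts[row]
    positive = counts[counts > 0]
    if positive.size == 0:
        raise ValueError(f"sample {sample_id!r} has no observed species")
    return AbundanceVector(counts=positive, sample_id=sample_id)


@dataclass(frozen=True)
class RSAHistogram:
    """Relative species abundance histogram: phi[n] = number of OTUs with
    exactly n reads."""

    phi: Mapping[int, int]

    @property
    def n_obs(self) -> int:
        return sum(self.phi.values())

    @property
    def total_reads(self) -> int:
        return sum(n * c for n, c in self.phi.items())


def rsa_histogram(av: AbundanceVector) -> RSAHistogram:
    values, counts = np.unique(av.counts, return_counts=True)
    return RSAHistogram(phi={int(v): int(c) for v, c in zip(values, counts)})


@dataclass(frozen=True)
class PrestonHistogram:
    """Octave-binned RSA: bin k counts OTUs with abundance in [2^k, 2^(k+1))."""

    bin_counts: np.ndarray

    def __post_init__(self) -> None:
        bins = np.asarray(self.bin_counts, dtype=np.int64)
        object.__setattr__(self, "bin_counts", bins)

    @property
    def n_bins(self) -> int:
        return int(self.bin_counts.size)

    @property
    def n_obs(self) -> int:
        return int(self.bin_counts.sum())


def octave_of(abundance: np.ndarray) -> np.ndarray:
    """Octave index floor(log2 n), exact for integer abundances < 2**53."""
    return np.frexp(np.asarray(abundance, dtype=np.float64))[1] - 1


def preston_histogram(rsa: RSAHistogram | AbundanceVector) -> PrestonHistogram:
    """Bin an RSA (or raw abundance vector) into Preston octaves.

    Trailing all-zero octaves are trimmed; the last bin is the octave of
    the most abundant OTU.
    """
    if isinstance(rsa, AbundanceVector):
        abund = rsa.counts
        weights = None
    else:
        abund = np.fromiter(rsa.phi.keys(), dtype=np.int64)
        weights = np.fromiter(rsa.phi.values(), dtype=np.int64)
    octaves = octave_of(abund)
    bins = np.bincount(octaves, weights=weights).astype(np.int64)
    return PrestonHistogram(bin_counts=bins)


@dataclass(frozen=True)
class DiversityProfile:
    """Classical alpha-diversity indices of one sample.

    Pielou evenness is ``None`` for single-species samples, where the
    maximum entropy ln(richness) vanishes and J is undefined.
    """

    shannon: float          # H, nats
    pielou: float | None    # J = H / ln(richness)
    simpson: float          # lambda = sum p_i^2 (decreases with diversity)
    hill1: float            # exp(H)
    hill2: float            # 1 / lambda
    richness: int           # number of observed OTUs

    def as_dict(self) -> dict[str, float | int | None]:
        return {
            "shannon": self.shannon,
            "pielou": self.pielou,
            "simpson": self.simpson,
            "hill1": self.hill1,
            "hill2": self.hill2,
            "richness": self.richness,
        }


def diversity_profile(av: AbundanceVector) -> DiversityProfile:
    """Shannon, Pielou, Simpson and Hill numbers from relative abundances."""
    p = av.counts / av.total_reads
    shannon = float(-np.sum(p * np.log(p)))
    simpson = float(np.sum(p * p))
    richness = av.n_obs
    pielou = shannon / np.log(richness) if richness > 1 else None
    return DiversityProfile(
        shannon=shannon,
        pielou=pielou,
        simpson=simpson,
        hill1=float(np.exp(shannon)),
        hill2=float(1.0 / simpson),
        richness=richness,
    )


def diversity_table(table: OTUTable) -> pd.DataFrame:
    """One DiversityProfile row per sample of an OTU table."""
    rows = []
    for sid in table.sample_ids:
        prof = diversity_profile(abundance_vector(table, sid))
        rows.append({"sample_id": sid, **prof.as_dict()})
    return pd.DataFrame(rows).set_index("sample_id")
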
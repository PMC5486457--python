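"""Divergence-based insertion-age estimation and age landscapes.

A TE copy's observed divergence D (percent of sites differing from the
family consensus, as printed by the annotator, CpG sites included) is
corrected for multiple substitutions with the Jukes-Cantor formula in
percent units,

    K = -300/4 * ln(1 - D * 4/300),

and converted to an insertion age with t = K / (2 r), where r is the
host species' neutral substitution rate per site per year (K taken as a
per-site fraction).  Ages binned by genome coverage give the classic
repeat landscape: percent of the genome occupied by copies of each TE
class as a function of insertion time in million years (My).

The five avian rates used throughout ship with the package:
budgerigar 2.22e-9, chicken 2.00e-9, turkey 3.56e-9, medium ground finch
2.05e-9, zebra finch 3.44e-9 substitutions/site/year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .rm_io import JC_DOMAIN_MAX, GenomeIndex, RepeatRecord, TaxonomyMap

__all__ = [
    "jukes_cantor_K",
    "age_from_K",
    "age_from_divergence",
    "AgeEstimate",
    "SpeciesRates",
    "load_default_rates",
    "AgeLandscape",
    "landscape",
]

MY = 1e6  # years per million years


def jukes_cantor_K(D):
    """Jukes-Cantor substitution level K (percent) from divergence D (percent).

    Strictly increasing on [0, 75); K(0) = 0 and K >= D everywhere (the
    correction inflates the observed difference to account for multiple
    hits at one site).  Accepts scalars or arrays.

    Raises
    ------
    ValueError
        If D is negative or at/above 75, where the formula is undefined.
    """
    arr = np.asarray(D, dtype=float)
    if np.any(arr < 0) or np.any(arr >= JC_DOMAIN_MAX):
        raise ValueError(
            f"divergence must lie in [0, {JC_DOMAIN_MAX}) percent, got {D!r}"
        )
    K = -75.0 * np.log1p(-arr * 4.0 / 300.0)
    return float(K) if np.isscalar(D) else K


def age_from_K(K, r: float):
    """Insertion age t = K / (2 r) in years; K in percent, r per site/year."""
    if r <= 0:
        raise ValueError(f"substitution rate must be positive, got {r}")
    arr = np.asarray(K, dtype=float)
    if np.any(arr < 0):
        raise ValueError("K must be non-negative")
    t = (arr / 100.0) / (2.0 * r)
    return float(t) if np.isscalar(K) else t


def age_from_divergence(D, r: float):
    """Convenience composition: observed D (percent) straight to age (years)."""
    return age_from_K(jukes_cantor_K(D), r)


@dataclass(frozen=True)
class AgeEstimate:
    """Substitution level (percent) and insertion age (years) for one copy."""

    K: float
    t: float

    @property
    def age_My(self) -> float:
        return self.t / MY


class SpeciesRates(dict):
    """Species name -> neutral substitution rate (per site per year)."""

    def __setitem__(self, key: str, value: float) -> None:
        if value <= 0:
            raise ValueError(f"rate for {key!r} must be positive")
        super().__setitem__(key, float(value))

    def rate(self, species: str) -> float:
        try:
            return self[species]
        except KeyError:
            known = ", ".join(sorted(self))
            raise KeyError(
                f"unknown species {species!r}; known species: {known}"
            ) from None

    @classmethod
    def from_tsv(cls, stream: Union[IO[str], Iterable[str]]) -> "SpeciesRates":
        rates = cls()
        for line in stream:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, rate = line.split("\t")[:2]
            rates[name] = float(rate)
        return rates

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "SpeciesRates":
        with open(path) as fh:
            return cls.from_tsv(fh)


def load_default_rates() -> SpeciesRates:
    """The five avian substitution rates shipped with the package."""
    text = resources.files("telandscape.data").joinpath("rates.tsv").read_text()
    return SpeciesRates.from_tsv(text.splitlines())


@dataclass
class AgeLandscape:
    """Binned age landscape: genome coverage percent per class per age bin.

    ``bin_edges`` are in My, uniform and half-open ``[lo, hi)``.  ``table``
    has one row per class label and one column per bin (indexed by bin
    lower edge).  ``excluded_bp`` counts bases of records whose divergence
    fell outside the Jukes-Cantor domain and were left unaged.
    """

    bin_edges: np.ndarray
    table: pd.DataFrame
    genome_length: int
    species: str
    rate: float
    excluded_records: int = 0
    excluded_bp: int = 0

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def class_totals(self) -> pd.Series:
        """Per-class coverage percent summed over all bins (aged records)."""
        return self.table.sum(axis=1)

    def modal_bin(self, label: str) -> tuple[float, float]:
        """The (lo, hi) My bin holding the most coverage for ``label``."""
        row = self.table.loc[label]
        lo = float(row.idxmax())
        return lo, lo + self.bin_width

    def to_tsv(self, stream: IO[str]) -> None:
        tidy = self.to_tidy()
        tidy.to_csv(stream, sep="\t", index=False)
        stream.write(
            f"# excluded_records\t{self.excluded_records}\t"
            f"excluded_bp\t{self.excluded_bp}\n"
        )

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for label in self.table.index:
            for lo in self.table.columns:
                rows.append(
                    {
                        "bin_lo_My": float(lo),
                        "bin_hi_My": float(lo) + self.bin_width,
                        "class": label,
                        "percent": self.table.loc[label, lo],
                    }
                )
        return pd.DataFrame(rows)

    def plot(self, ax=None, stacked: bool = True):
        """Stacked-bar landscape: x insertion time (My), y percent of genome."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(8, 4))
        bottoms = np.zeros(self.table.shape[1])
        centers = np.asarray(self.table.columns, dtype=float) + self.bin_width / 2
        for label in self.table.index:
            vals = self.table.loc[label].to_numpy(dtype=float)
            ax.bar(
                centers,
                vals,
                width=self.bin_width * 0.9,
                bottom=bottoms if stacked else None,
                label=label,
            )
            if stacked:
                bottoms = bottoms + vals
        ax.set_xlabel("Insertion time (My)")
        ax.set_ylabel("Percentage of the genome")
        ax.legend(fontsize="small")
        return ax


def landscape(
    records: Sequence[RepeatRecord],
    taxonomy: TaxonomyMap,
    genome: GenomeIndex,
    species: str,
    rates: Optional[SpeciesRates] = None,
    bin_width_My: float = 5.0,
    group_by: str = "clade",
) -> AgeLandscape:
    """Build the binned age landscape for one species' annotation.

    Each record contributes its raw span (bp) to the bin containing its
    estimated insertion age; per-bin values are 100 * bp / genome length.
    ``group_by`` is ``"clade"`` (labels like ``LINE/CR1``, falling back to
    the type for clade-less types) or ``"type"``.  Records with divergence
    outside [0, 75) are excluded and tallied in the report footer.
    """
    if rates is None:
        rates = load_default_rates()
    r = rates.rate(species)
    if bin_width_My <= 0:
        raise ValueError("bin width must be positive")
    if group_by not in ("clade", "type"):
        raise ValueError("group_by must be 'clade' or 'type'")

    labels: list[str] = []
    ages_My: list[float] = []
    lengths: list[int] = []
    excluded_records = excluded_bp = 0
    for rec in records:
        if not rec.ageable or rec.divergence_percent < 0:
            excluded_records += 1
            excluded_bp += rec.length
            continue
        te_type, clade = taxonomy.classify(rec)
        if group_by == "type" or clade is None:
            label = te_type
        else:
            label = f"{te_type}/{clade}"
        labels.append(label)
        ages_My.append(age_from_divergence(rec.divergence_percent, r) / MY)
        lengths.append(rec.length)

    if ages_My:
        n_bins = max(1, int(math.floor(max(ages_My) / bin_width_My)) + 1)
    else:
        n_bins = 1
    edges = np.arange(n_bins + 1, dtype=float) * bin_width_My
    class_names = sorted(set(labels))
    table = pd.DataFrame(
        0.0, index=class_names, columns=edges[:-1], dtype=float
    )
    for label, age, length in zip(labels, ages_My, lengths):
        b = edges[min(int(age // bin_width_My), n_bins - 1)]
        table.loc[label, b] += 100.0 * length / genome.total_length
    return AgeLandscape(
        bin_edges=edges,
        table=table,
        genome_length=genome.total_length,
        species=species,
        rate=r,
        excluded_records=excluded_records,
        excluded_bp=excluded_bp,
    )
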
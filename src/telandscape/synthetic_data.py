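"""Synthetic genomes, annotations, libraries and elements with ground truth.

Every stage of the landscape pipeline is testable without genome downloads
by generating its inputs: TE copies diverged from a known consensus by a
known Jukes-Cantor substitution level, annotation records carrying the
realized divergence, libraries with planted family structure straddling
the 80-80 thresholds, and candidate elements with ORFs and protein
domains of controlled amino-acid lengths (plus matching stand-in
reference proteins).

Sequences mutate under the Jukes-Cantor process: substitutions only, all
twelve changes equally likely, so the expected observed divergence for a
substitution level K (percent) is the closed form
``D = 75 * (1 - exp(-4K/300))`` and estimated ages are driven solely by
realized substitutions.  A fixed seed makes every output byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml

from .aging import MY, SpeciesRates, load_default_rates
from .rm_io import (
    GenomeIndex,
    RepeatRecord,
    TaxonomyMap,
    default_taxonomy,
    reverse_complement,
    write_fasta,
    write_repeatmasker_out,
)

__all__ = [
    "random_dna",
    "mutate_jc",
    "expected_divergence",
    "ConsensusSpec",
    "InsertionPlan",
    "SimulationConfig",
    "PlantedCopy",
    "SimulatedGenome",
    "simulate_genome",
    "FamilySpec",
    "SimulatedLibrary",
    "simulate_library",
    "make_diverged_pair",
    "LineElementSpec",
    "ErvElementSpec",
    "SimulatedElements",
    "simulate_elements",
    "default_screen_plan",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

# One stop-free codon per amino acid, for planting ORFs of exact aa length.
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}


def _rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_dna(length: int, seed: Union[int, np.random.Generator]) -> str:
    rng = _rng(seed)
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def expected_divergence(K_percent: float) -> float:
    """Expected observed divergence D (percent) after substitution level K."""
    return 75.0 * (1.0 - np.exp(-4.0 * K_percent / 300.0))


def mutate_jc(
    seq: str, K_percent: float, seed: Union[int, np.random.Generator]
) -> str:
    """Mutate a sequence under the Jukes-Cantor substitution process.

    ``K_percent`` is the substitution level in percent units (expected
    substitutions per site = K/100).  Each site independently differs from
    the original with the closed-form probability
    ``3/4 * (1 - exp(-4K/300))``; a differing site takes one of the three
    other bases uniformly.  No indels.  Sites that are not A/C/G/T (e.g.
    N) are left untouched.
    """
    if K_percent < 0:
        raise ValueError(f"substitution level K must be >= 0, got {K_percent}")
    if K_percent == 0:
        return seq
    rng = _rng(seed)
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy()
    idx = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        idx[b] = i
    codes = idx[arr]
    mutable = codes >= 0
    p_diff = 0.75 * (1.0 - np.exp(-4.0 * K_percent / 300.0))
    hit = (rng.random(arr.size) < p_diff) & mutable
    n = int(hit.sum())
    if n:
        offsets = rng.integers(1, 4, size=n)
        codes_hit = (codes[hit] + offsets) % 4
        arr[hit] = _BASES[codes_hit]
    return arr.tobytes().decode()


def _hamming_percent(a: str, b: str) -> float:
    x = np.frombuffer(a.encode(), dtype=np.uint8)
    y = np.frombuffer(b.encode(), dtype=np.uint8)
    return 100.0 * float(np.mean(x != y))


# ---------------------------------------------------------------------------
# Genome + annotation simulation


@dataclass
class ConsensusSpec:
    """One consensus TE sequence: either given explicitly or generated."""

    name: str
    class_family: str
    length: Optional[int] = None
    sequence: Optional[str] = None


@dataclass
class InsertionPlan:
    """Plant ``count`` copies of one consensus at a common true age or K."""

    consensus: str
    count: int
    age_My: Optional[float] = None
    K_percent: Optional[float] = None

    def true_K(self, rate: float) -> float:
        if (self.age_My is None) == (self.K_percent is None):
            raise ValueError("specify exactly one of age_My and K_percent")
        if self.K_percent is not None:
            return self.K_percent
        # Inverse of t = K/(2r): K = 2 r t, in percent units.
        return 200.0 * rate * self.age_My * MY


@dataclass
class SimulationConfig:
    seed: int
    genome_length: int
    consensi: list[ConsensusSpec]
    insertions: list[InsertionPlan]
    species: str = "chicken"
    rate: Optional[float] = None
    chromosome: str = "chr1"

    def resolved_rate(self, rates: Optional[SpeciesRates] = None) -> float:
        if self.rate is not None:
            return self.rate
        return (rates or load_default_rates()).rate(self.species)

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(
            seed=int(raw["seed"]),
            genome_length=int(raw["genome_length"]),
            consensi=[ConsensusSpec(**c) for c in raw["consensi"]],
            insertions=[InsertionPlan(**p) for p in raw["insertions"]],
            species=raw.get("species", "chicken"),
            rate=raw.get("rate"),
            chromosome=raw.get("chromosome", "chr1"),
        )


@dataclass
class PlantedCopy:
    """Ground truth for one planted TE copy."""

    copy_id: str
    consensus: str
    class_family: str
    te_type: str
    clade: Optional[str]
    query_name: str
    begin: int  # 1-based inclusive
    end: int
    strand: str
    true_K: float
    true_age_My: float
    realized_D: float

    @property
    def length(self) -> int:
        return self.end - self.begin + 1


@dataclass
class SimulatedGenome:
    """A toy genome with its annotation and full ground truth."""

    sequences: dict[str, str]
    records: list[RepeatRecord]
    truth: list[PlantedCopy]
    config: SimulationConfig

    @property
    def genome_index(self) -> GenomeIndex:
        return GenomeIndex.from_sequences(self.sequences)

    def truth_clade_bp(self) -> dict[tuple[str, Optional[str]], int]:
        """Planted bp per (te_type, clade) — the coverage report's target."""
        out: dict[tuple[str, Optional[str]], int] = {}
        for copy in self.truth:
            key = (copy.te_type, copy.clade)
            out[key] = out.get(key, 0) + copy.length
        return out

    def write(self, outdir: Union[str, Path]) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, outdir / "genome.fa")
        with open(outdir / "annotation.out", "w") as fh:
            write_repeatmasker_out(self.records, fh)
        with open(outdir / "genome_index.tsv", "w") as fh:
            self.genome_index.to_tsv(fh)
        with open(outdir / "truth.tsv", "w") as fh:
            fh.write(
                "copy_id\tconsensus\tclass_family\tte_type\tclade\tquery_name"
                "\tbegin\tend\tstrand\ttrue_K\ttrue_age_My\trealized_D\n"
            )
            for c in self.truth:
                fh.write(
                    f"{c.copy_id}\t{c.consensus}\t{c.class_family}\t{c.te_type}"
                    f"\t{c.clade}\t{c.query_name}\t{c.begin}\t{c.end}\t{c.strand}"
                    f"\t{c.true_K:.6g}\t{c.true_age_My:.6g}\t{c.realized_D:.2f}\n"
                )


def simulate_genome(
    config: SimulationConfig,
    rates: Optional[SpeciesRates] = None,
    taxonomy: Optional[TaxonomyMap] = None,
) -> SimulatedGenome:
    """Plant diverged TE copies in a random background genome.

    Copies are consensus sequences mutated to the substitution level
    implied by their true age (K = 2 r t), placed without overlap at
    random positions and on random strands.  The emitted annotation
    carries each copy's realized divergence (rounded to 2 decimals, the
    precision of the text format), so the whole pipeline can be checked
    against the returned ground truth.
    """
    rng = np.random.default_rng(config.seed)
    rate = config.resolved_rate(rates)
    taxonomy = taxonomy or default_taxonomy()

    consensi: dict[str, ConsensusSpec] = {}
    sequences: dict[str, str] = {}
    for spec in config.consensi:
        if spec.name in consensi:
            raise ValueError(f"duplicate consensus name {spec.name!r}")
        seq = spec.sequence
        if seq is None:
            if spec.length is None:
                raise ValueError(f"consensus {spec.name!r} needs length or sequence")
            seq = random_dna(spec.length, rng)
        consensi[spec.name] = spec
        sequences[spec.name] = seq.upper()

    # Materialize the planned copies (consensus, true K, true age).
    planned: list[tuple[str, float, float]] = []
    for plan in config.insertions:
        if plan.consensus not in consensi:
            raise ValueError(f"insertion refers to unknown consensus {plan.consensus!r}")
        K = plan.true_K(rate)
        age_My = (K / 100.0) / (2.0 * rate) / MY
        planned.extend((plan.consensus, K, age_My) for _ in range(plan.count))

    total_copy_bp = sum(len(sequences[name]) for name, _, _ in planned)
    if total_copy_bp > config.genome_length:
        raise ValueError(
            f"insertion plan needs {total_copy_bp} bp but the genome is "
            f"{config.genome_length} bp"
        )

    order = rng.permutation(len(planned))
    slack = config.genome_length - total_copy_bp
    n = len(planned)
    gaps = rng.multinomial(slack, np.full(n + 1, 1.0 / (n + 1))) if n else [slack]

    genome = np.frombuffer(
        random_dna(config.genome_length, rng).encode(), dtype=np.uint8
    ).copy()
    records: list[RepeatRecord] = []
    truth: list[PlantedCopy] = []
    cursor = 0
    for rank, i in enumerate(order):
        name, K, age_My = planned[i]
        consensus = sequences[name]
        cursor += int(gaps[rank])
        start0 = cursor
        mutated = mutate_jc(consensus, K, rng)
        realized_D = round(_hamming_percent(consensus, mutated), 2)
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = mutated if strand == "+" else reverse_complement(mutated)
        genome[start0 : start0 + len(inserted)] = np.frombuffer(
            inserted.encode(), dtype=np.uint8
        )
        cursor += len(inserted)
        spec = consensi[name]
        record = RepeatRecord(
            sw_score=max(1, int(round(len(consensus) * (1.0 - realized_D / 100.0)))),
            divergence_percent=realized_D,
            deletion_percent=0.0,
            insertion_percent=0.0,
            query_name=config.chromosome,
            query_begin=start0 + 1,
            query_end=start0 + len(inserted),
            strand=strand,
            repeat_name=name,
            repeat_class_family=spec.class_family,
            linkage_id=len(records) + 1,
            repeat_begin=1,
            repeat_end=len(consensus),
            repeat_left=0,
        )
        records.append(record)
        te_type, clade = taxonomy.classify(record)
        truth.append(
            PlantedCopy(
                copy_id=f"{name}.{len(records)}",
                consensus=name,
                class_family=spec.class_family,
                te_type=te_type,
                clade=clade,
                query_name=config.chromosome,
                begin=record.query_begin,
                end=record.query_end,
                strand=strand,
                true_K=K,
                true_age_My=age_My,
                realized_D=realized_D,
            )
        )
    records.sort(key=lambda r: r.query_begin)
    truth.sort(key=lambda c: c.begin)
    for lid, rec in enumerate(records, start=1):
        rec.linkage_id = lid
    return SimulatedGenome(
        sequences={config.chromosome: genome.tobytes().decode()},
        records=records,
        truth=truth,
        config=config,
    )


# ---------------------------------------------------------------------------
# Library simulation (80-80 clustering fixtures)


@dataclass
class FamilySpec:
    """One planted repeat family.

    ``member_K`` is the substitution level (percent) separating each
    member from the founder; 5% keeps members comfortably above the 80%
    identity threshold.  Fragments are truncated founders (absorbed under
    the shorter-sequence coverage rule).
    """

    name: str
    length: int = 600
    n_members: int = 2
    member_K: float = 5.0
    n_fragments: int = 0
    fragment_fraction: float = 0.5


@dataclass
class SimulatedLibrary:
    library: dict[str, str]
    family_of: dict[str, str]  # sequence id -> planted family name

    def as_sets(self) -> set[frozenset[str]]:
        groups: dict[str, list[str]] = {}
        for seq_id, fam in self.family_of.items():
            groups.setdefault(fam, []).append(seq_id)
        return {frozenset(v) for v in groups.values()}


def simulate_library(
    families: Sequence[FamilySpec], seed: Union[int, np.random.Generator]
) -> SimulatedLibrary:
    """Generate a library with planted family structure.

    Each family is a random founder plus diverged members and optional
    fragments; distinct families are independent random sequences, far
    below the 80-80 thresholds from one another.
    """
    rng = _rng(seed)
    library: dict[str, str] = {}
    family_of: dict[str, str] = {}
    for spec in families:
        founder = random_dna(spec.length, rng)
        member_ids = [f"{spec.name}_0"]
        library[member_ids[0]] = founder
        for i in range(1, spec.n_members):
            library[f"{spec.name}_{i}"] = mutate_jc(founder, spec.member_K, rng)
            member_ids.append(f"{spec.name}_{i}")
        for j in range(spec.n_fragments):
            frag_len = max(30, int(spec.length * spec.fragment_fraction))
            start = int(rng.integers(0, spec.length - frag_len + 1))
            frag = mutate_jc(founder[start : start + frag_len], spec.member_K, rng)
            fid = f"{spec.name}_frag{j}"
            library[fid] = frag
            member_ids.append(fid)
        for m in member_ids:
            family_of[m] = spec.name
    return SimulatedLibrary(library=library, family_of=family_of)


def make_diverged_pair(
    length: int, identity: float, seed: Union[int, np.random.Generator]
) -> tuple[str, str]:
    """A pair at a controlled, evenly spread identity.

    Mismatches are placed at evenly spaced positions so every window of
    the pair has the same local identity — no sub-alignment can beat the
    global figure, which makes the pair a clean threshold probe.
    """
    rng = _rng(seed)
    a = random_dna(length, rng)
    n_mut = round((1.0 - identity) * length)
    arr = np.frombuffer(a.encode(), dtype=np.uint8).copy()
    positions = (np.arange(n_mut) * length / max(n_mut, 1)).astype(int)
    lut = {b: _BASES[(i + 1) % 4] for i, b in enumerate(_BASES)}
    for p in positions:
        arr[p] = lut[arr[p]]
    return a, arr.tobytes().decode()


# ---------------------------------------------------------------------------
# Element simulation (screening fixtures)

# Fixed stand-in reference protein lengths (aa).
_RT_LEN = 300
_MASTER_LEN = {"ENV": 520, "GAG": 540, "POL": 860}


def _random_protein(rng: np.random.Generator, n_aa: int, start_met: bool = True) -> str:
    aas = "".join(_AA20[i] for i in rng.integers(0, len(_AA20), size=n_aa))
    return ("M" + aas[1:]) if start_met and n_aa else aas


def _back_translate(protein: str) -> str:
    return "".join(_CODON[aa] for aa in protein)


def _orf_nt(protein: str) -> str:
    return _back_translate(protein) + "TAA"


def _spacer(rng: np.random.Generator, length: int = 45) -> str:
    # T/C only: no ATG and no stop codon on either strand, so spacers can
    # neither start nor terminate reading frames crossing them.
    return "".join("TC"[i] for i in rng.integers(0, 2, size=length))


@dataclass
class LineElementSpec:
    """A candidate LINE with planted ORF1/ORF2 of exact aa lengths.

    ``rt=True`` embeds the full stand-in RT protein in ORF2 (so the RT is
    intact); ``orf2_aa`` must then be at least ``301``.  The expected
    screening category follows from the ladder arithmetic.
    """

    name: str
    orf1_aa: Optional[int] = None
    orf2_aa: Optional[int] = None
    rt: bool = True
    total_length: Optional[int] = None
    clade: Optional[str] = None

    def expected_category(self, orf2_min_aa: int = 600) -> str:
        has_orf2 = self.orf2_aa is not None and self.rt
        orf2_len = self.orf2_aa if has_orf2 else 0
        has_orf1 = has_orf2 and self.orf1_aa is not None and self.orf1_aa >= 100
        if has_orf1 and orf2_len > orf2_min_aa:
            return "full_LINE"
        if orf2_len > orf2_min_aa:
            return "ORF2_only"
        if has_orf1:
            return "ORF1_only"
        if has_orf2:
            return "intact_RT_only"
        return "defective"


@dataclass
class ErvElementSpec:
    """A candidate ERV with planted domain ORFs of exact aa lengths."""

    name: str
    env_aa: Optional[int] = None
    gag_aa: Optional[int] = None
    pol_aa: Optional[int] = None
    total_length: Optional[int] = None
    clade: Optional[str] = None

    def planted(self) -> dict[str, Optional[int]]:
        return {"ENV": self.env_aa, "GAG": self.gag_aa, "POL": self.pol_aa}

    def expected_domains(
        self, thresholds: Optional[dict[str, int]] = None
    ) -> set[str]:
        from .library_tools import ERV_DOMAIN_THRESHOLDS

        thresholds = thresholds or ERV_DOMAIN_THRESHOLDS
        return {
            label
            for label, n in self.planted().items()
            if n is not None and n > thresholds[label]
        }

    def expected_category(self) -> str:
        found = self.expected_domains()
        if found == {"ENV", "GAG", "POL"}:
            return "full_ERV"
        return "partial_ERV" if found else "defective"


@dataclass
class SimulatedElements:
    elements: dict[str, str]
    category_of: dict[str, str]
    rt_refs: dict[str, str]
    erv_refs: dict[str, str]
    clade_of: dict[str, Optional[str]] = field(default_factory=dict)


def _assemble(rng: np.random.Generator, orf_nts: list[str], total_length: Optional[int],
              name: str) -> str:
    parts = [_spacer(rng)]
    for orf in orf_nts:
        parts.append(orf)
        parts.append(_spacer(rng))
    element = "".join(parts)
    if total_length is not None:
        if total_length < len(element):
            raise ValueError(
                f"element {name!r}: requested total_length {total_length} is "
                f"shorter than the {len(element)} bp needed by its ORFs"
            )
        element += _spacer(rng, total_length - len(element))
    return element


def simulate_elements(
    line_specs: Sequence[LineElementSpec] = (),
    erv_specs: Sequence[ErvElementSpec] = (),
    seed: Union[int, np.random.Generator] = 0,
) -> SimulatedElements:
    """Build candidate elements plus the matching stand-in references.

    The RT reference is a fixed random protein embedded verbatim in every
    RT-bearing ORF2; each ERV domain reference is a fixed master protein
    whose prefixes serve as planted domains, so the matched span on an
    element equals the planted aa length exactly.  Spacers between ORFs
    contain no ATG on either strand and cannot create extra reading
    frames.
    """
    rng = _rng(seed)
    rt_protein = _random_protein(rng, _RT_LEN)
    masters = {
        label: _random_protein(rng, n) for label, n in _MASTER_LEN.items()
    }
    elements: dict[str, str] = {}
    category_of: dict[str, str] = {}
    clade_of: dict[str, Optional[str]] = {}

    for spec in line_specs:
        orfs: list[str] = []
        if spec.orf1_aa:
            orfs.append(_orf_nt(_random_protein(rng, spec.orf1_aa)))
        if spec.orf2_aa:
            if spec.rt:
                if spec.orf2_aa < _RT_LEN + 1:
                    raise ValueError(
                        f"element {spec.name!r}: orf2_aa must be >= {_RT_LEN + 1} "
                        "to embed the RT domain"
                    )
                pad = _random_protein(rng, spec.orf2_aa - _RT_LEN)
                protein = pad + rt_protein
            else:
                protein = _random_protein(rng, spec.orf2_aa)
            orfs.append(_orf_nt(protein))
        elements[spec.name] = _assemble(rng, orfs, spec.total_length, spec.name)
        category_of[spec.name] = spec.expected_category()
        clade_of[spec.name] = spec.clade

    for spec in erv_specs:
        orfs = []
        for label in ("GAG", "POL", "ENV"):  # proviral gene order
            n = spec.planted()[label]
            if n:
                if n > _MASTER_LEN[label]:
                    raise ValueError(
                        f"element {spec.name!r}: {label} length {n} exceeds the "
                        f"reference length {_MASTER_LEN[label]}"
                    )
                orfs.append(_orf_nt(masters[label][:n]))
        elements[spec.name] = _assemble(rng, orfs, spec.total_length, spec.name)
        category_of[spec.name] = spec.expected_category()
        clade_of[spec.name] = spec.clade

    return SimulatedElements(
        elements=elements,
        category_of=category_of,
        rt_refs={"RT_ref": rt_protein},
        erv_refs={f"{label}_ref": prot for label, prot in masters.items()},
        clade_of=clade_of,
    )


def default_screen_plan() -> tuple[list[LineElementSpec], list[ErvElementSpec]]:
    """Thirty elements spanning every screening category and its boundaries.

    Includes the exact-threshold probes: an ORF2 of exactly 600 aa and a
    POL span of exactly 800 aa, neither of which may count as "full".
    """
    line = [
        LineElementSpec("line_full_1", orf1_aa=300, orf2_aa=680, clade="CR1"),
        LineElementSpec("line_full_2", orf1_aa=150, orf2_aa=900, clade="CR1"),
        LineElementSpec("line_full_3", orf1_aa=250, orf2_aa=650, clade="R2"),
        LineElementSpec("line_orf2_1", orf2_aa=680, clade="CR1"),
        LineElementSpec("line_orf2_2", orf2_aa=1000, clade="R2"),
        LineElementSpec("line_orf1_1", orf1_aa=300, orf2_aa=400, clade="CR1"),
        LineElementSpec("line_orf1_2", orf1_aa=120, orf2_aa=500, clade="CR1"),
        # Boundary: ORF2 of exactly 600 aa is NOT "full" (strict >).
        LineElementSpec("line_orf2_600", orf1_aa=300, orf2_aa=600, clade="CR1"),
        LineElementSpec("line_orf2_601", orf1_aa=300, orf2_aa=601, clade="CR1"),
        LineElementSpec("line_rt_1", orf2_aa=400, clade="CR1"),
        LineElementSpec("line_rt_2", orf2_aa=320, clade="R2"),
        # ORFs without any RT homology are defective.
        LineElementSpec("line_norf_rt", orf1_aa=300, orf2_aa=700, rt=False, clade="CR1"),
        LineElementSpec("line_def_1", clade="CR1"),
        LineElementSpec("line_def_2", orf1_aa=None, orf2_aa=None, clade="RTE"),
        LineElementSpec("line_def_3", clade="R2"),
    ]
    erv = [
        ErvElementSpec("erv_full_1", env_aa=500, gag_aa=520, pol_aa=850),
        ErvElementSpec("erv_full_2", env_aa=481, gag_aa=501, pol_aa=801),
        ErvElementSpec("erv_full_3", env_aa=520, gag_aa=540, pol_aa=860),
        ErvElementSpec("erv_pol_1", pol_aa=850),
        ErvElementSpec("erv_pol_2", pol_aa=810),
        ErvElementSpec("erv_gag_1", gag_aa=520),
        ErvElementSpec("erv_env_1", env_aa=500),
        ErvElementSpec("erv_envgag", env_aa=490, gag_aa=510),
        ErvElementSpec("erv_polgag", gag_aa=530, pol_aa=820),
        # Boundary: POL span of exactly 800 aa does not count (strict >).
        ErvElementSpec("erv_pol_800", pol_aa=800),
        ErvElementSpec("erv_pol_801", pol_aa=801),
        ErvElementSpec("erv_env_480", env_aa=480),
        ErvElementSpec("erv_gag_500", gag_aa=500),
        ErvElementSpec("erv_def_1"),
        ErvElementSpec("erv_def_2"),
    ]
    return line, erv
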
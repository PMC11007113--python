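"""Synthetic SILVA-like communities for desk-scale testing and benchmarks.

The generator emulates the salient statistics of a curated full-length 16S
rRNA gene database: a seven-rank taxonomy over multiple genera, ~1500 bp
reference sequences with high between-species similarity, a long-tailed
per-species read-count profile (few abundant "head" species, many rare
"tail" species), small within-species read variation, and sprinkled IUPAC
ambiguity codes that are always compatible with the true base.

Substitutions only — no indels — so every read shares ``seq_length``; the
pipeline never aligns, and equal lengths keep fixtures simple (an indel
flag exists for robustness testing).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .silva import IUPAC_CODES, Dataset, SequenceRecord, Taxonomy

_BASES = np.array(list("ACGT"))

#: base -> ambiguity codes whose set contains it (N included).
_COMPATIBLE: dict[str, list[str]] = {
    b: [c for c, opts in IUPAC_CODES.items() if len(opts) > 1 and b in opts]
    for b in "ACGT"
}


@dataclass
class AbundanceConfig:
    """Truncated Zipf read counts: count(rank r) = clip(round(max * r^-alpha)).

    With ``alpha=None`` the exponent is set to log(max/min)/log(n_species),
    so the rarest species lands at ``min_count`` — every replication band
    of the preprocessing table is then populated once n_species >= 8.
    """

    max_count: int = 200
    min_count: int = 1
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.min_count < 1 or self.max_count < self.min_count:
            raise ValueError("need 1 <= min_count <= max_count")


@dataclass
class SimConfig:
    """Study conditions of a simulated community."""

    n_species: int = 24
    species_per_genus: int = 3
    seq_length: int = 1500
    inter_species_divergence: float = 0.05
    within_species_rate: float = 0.01
    ambiguity_rate: float = 0.005
    abundance: AbundanceConfig = field(default_factory=AbundanceConfig)
    indels: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("inter_species_divergence", "within_species_rate", "ambiguity_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([cfg.seed & 0x7FFFFFFF, stream]))


def simulate_taxonomy(cfg: SimConfig) -> list[Taxonomy]:
    """Hierarchical seven-rank labels; genera hold ``species_per_genus`` species."""
    taxa = []
    for s in range(cfg.n_species):
        g = s // cfg.species_per_genus
        taxa.append(Taxonomy((
            "Bacteria",
            f"Phylum{g // 8:02d}",
            f"Class{g // 4:02d}",
            f"Order{g // 2:02d}",
            f"Family{g:02d}",
            f"Genus{g:02d}",
            f"Genus{g:02d}_species{s:03d}",
        )))
    return taxa


def _mutate(seq: np.ndarray, n_sites: int, rng: np.random.Generator) -> np.ndarray:
    """Substitute exactly ``n_sites`` random positions to a different base."""
    out = seq.copy()
    if n_sites == 0:
        return out
    pos = rng.choice(len(seq), size=min(n_sites, len(seq)), replace=False)
    for p in pos:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(3)]
    return out


def _per_child_sites(divergence: float, length: int) -> int:
    """Substitutions per sister so the expected pairwise difference is ``divergence``.

    Two sisters mutating q of their sites independently differ at
    p = 2q(1-q) + (2/3)q^2 of sites; solving the quadratic for q gives
    q = (1 - sqrt(1 - (4/3)p)) / (4/3).
    """
    if divergence == 0:
        return 0
    a = 4.0 / 3.0
    q = (1.0 - np.sqrt(max(1.0 - a * divergence, 0.0))) / a
    return int(round(q * length))


def simulate_references(taxa: list[Taxonomy], cfg: SimConfig) -> dict[str, str]:
    """Per-species reference sequences mutated along the taxonomy tree.

    The root is a uniform-random sequence; each genus ancestor diverges from
    the root, and each species diverges from its genus ancestor such that
    sister species differ at ~``inter_species_divergence`` of sites.
    """
    rng = _rng(cfg, 31)
    root = _BASES[rng.integers(4, size=cfg.seq_length)]
    per_child = _per_child_sites(cfg.inter_species_divergence, cfg.seq_length)
    genus_anc: dict[str, np.ndarray] = {}
    refs: dict[str, str] = {}
    for t in taxa:
        if t.genus not in genus_anc:
            # genus ancestors spread further apart than sisters (2x)
            genus_anc[t.genus] = _mutate(root, 2 * per_child, rng)
        refs[t.species] = "".join(_mutate(genus_anc[t.genus], per_child, rng))
    return refs


def zipf_counts(n_species: int, ab: AbundanceConfig) -> np.ndarray:
    """Rank-sorted (non-increasing) long-tail read counts."""
    if ab.alpha is None:
        if ab.max_count == ab.min_count or n_species == 1:
            alpha = 0.0
        else:
            alpha = np.log(ab.max_count / ab.min_count) / np.log(n_species)
    else:
        alpha = ab.alpha
    ranks = np.arange(1, n_species + 1, dtype=np.float64)
    counts = np.round(ab.max_count * ranks ** -alpha)
    return np.clip(counts, ab.min_count, ab.max_count).astype(np.int64)


def sample_reads(refs: dict[str, str], taxa: list[Taxonomy], cfg: SimConfig) -> Dataset:
    """Draw a long-tailed community of reads from the references.

    Each read substitutes bases at ``within_species_rate``, then replaces
    bases with a *compatible* IUPAC ambiguity code at ``ambiguity_rate``
    (so downstream resolution is a noisy recovery of the true base).
    Abundance rank follows species order (rank 1 = first species).
    """
    rng = _rng(cfg, 37)
    counts = zipf_counts(len(refs), cfg.abundance)
    records: list[SequenceRecord] = []
    tax_of = {t.species: t for t in taxa}
    for (species, ref), n_reads in zip(refs.items(), counts):
        base = np.array(list(ref))
        for i in range(n_reads):
            read = base.copy()
            subs = rng.random(len(read)) < cfg.within_species_rate
            for p in np.flatnonzero(subs):
                choices = [b for b in "ACGT" if b != read[p]]
                read[p] = choices[rng.integers(3)]
            if cfg.indels and rng.random() < 0.5:
                p = rng.integers(len(read))
                read = np.delete(read, p)  # single deletion, length varies
            amb = rng.random(len(read)) < cfg.ambiguity_rate
            for p in np.flatnonzero(amb):
                codes = _COMPATIBLE[str(read[p])]
                read[p] = codes[rng.integers(len(codes))]
            records.append(SequenceRecord(
                id=f"{species}_read{i:05d}",
                sequence="".join(read),
                taxonomy=tax_of[species],
            ))
    return Dataset(records)


def simulate_community(cfg: SimConfig) -> tuple[Dataset, dict[str, str]]:
    """taxonomy -> references -> reads; returns the dataset and the truth refs."""
    taxa = simulate_taxonomy(cfg)
    refs = simulate_references(taxa, cfg)
    return sample_reads(refs, taxa, cfg), refs
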
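"""Reading and writing SILVA-style sequence + taxonomy files.

A SILVA release ships two flat files: a FASTA of ~1500 bp 16S rRNA gene
sequences keyed by Feature ID, and a two-column table mapping each Feature
ID to a seven-rank lineage string of the form

    d__Bacteria; p__Actinobacteriota; ...; g__Streptomyces; s__Streptomyces_x

This module parses both, normalizes sequences to an uppercase DNA alphabet
(U -> T, since every downstream k-mer vocabulary is DNA-based), and joins
them into a labeled :class:`Dataset` ready for preprocessing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: IUPAC nucleotide one-letter codes -> set of concrete DNA bases.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

#: Codes denoting more than one base.
AMBIGUITY_CODES = frozenset(c for c, bases in IUPAC_CODES.items() if len(bases) > 1)

_VALID = frozenset(IUPAC_CODES)

RANK_NAMES = ("domain", "phylum", "class", "order", "family", "genus", "species")
_RANK_PREFIXES = ("d__", "p__", "c__", "o__", "f__", "g__", "s__")


class FastaParseError(ValueError):
    """Raised when a FASTA file cannot be parsed into valid IUPAC records."""


class TaxonomyParseError(ValueError):
    """Raised when a taxonomy table violates the two-column 7-rank contract."""


@dataclass(frozen=True)
class Taxonomy:
    """A seven-rank lineage (domain..species); empty strings mark absent ranks."""

    ranks: tuple[str, str, str, str, str, str, str]

    def __post_init__(self) -> None:
        if len(self.ranks) != 7:
            raise ValueError(f"taxonomy needs exactly 7 ranks, got {len(self.ranks)}")

    @property
    def genus(self) -> str:
        return self.ranks[5]

    @property
    def species(self) -> str:
        return self.ranks[6]

    def to_string(self) -> str:
        return "; ".join(p + r for p, r in zip(_RANK_PREFIXES, self.ranks))

    @classmethod
    def from_string(cls, text: str) -> "Taxonomy":
        parts = [p.strip() for p in text.strip().split(";")]
        if parts and parts[-1] == "":
            parts = parts[:-1]
        if len(parts) > 7:
            raise TaxonomyParseError(f"more than 7 ranks in {text!r}")
        ranks = []
        for i, part in enumerate(parts):
            for pref in _RANK_PREFIXES:
                if part.startswith(pref):
                    part = part[len(pref):]
                    break
            ranks.append(part.strip())
        ranks.extend([""] * (7 - len(ranks)))
        return cls(tuple(ranks))


@dataclass(frozen=True)
class SequenceRecord:
    """One Feature ID with its normalized IUPAC DNA sequence and optional lineage."""

    id: str
    sequence: str
    taxonomy: Optional[Taxonomy] = None

    def with_sequence(self, sequence: str) -> "SequenceRecord":
        return replace(self, sequence=sequence)

    def with_id(self, new_id: str) -> "SequenceRecord":
        return replace(self, id=new_id)


@dataclass
class Dataset:
    """Labeled records plus a contiguous species-name <-> integer label map."""

    records: list[SequenceRecord]
    label_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.label_index:
            self.label_index = _build_label_index(self.records)

    def __len__(self) -> int:
        return len(self.records)

    @property
    def species_names(self) -> list[str]:
        """Species names ordered by integer label."""
        inv = [""] * len(self.label_index)
        for name, i in self.label_index.items():
            inv[i] = name
        return inv

    def labels(self) -> list[int]:
        return [self.label_index[r.taxonomy.species] for r in self.records]

    def genus_of_species(self) -> dict[str, str]:
        """Map species name -> genus name (for genus-level scoring)."""
        out: dict[str, str] = {}
        for r in self.records:
            out.setdefault(r.taxonomy.species, r.taxonomy.genus)
        return out

    def subset(self, indices: Iterable[int]) -> "Dataset":
        """A new Dataset over a subset of records, keeping the label map."""
        recs = [self.records[i] for i in indices]
        return Dataset(recs, dict(self.label_index))


def _build_label_index(records: list[SequenceRecord]) -> dict[str, int]:
    species = sorted({r.taxonomy.species for r in records if r.taxonomy is not None})
    return {name: i for i, name in enumerate(species)}


def normalize_sequence(raw: str) -> str:
    """Uppercase and map RNA U to DNA T; validation is the caller's job."""
    return raw.upper().replace("U", "T")


def _find_bad_line(path: Path, bad_char: str, record_id: str) -> int:
    """Locate the line of the first illegal character in a record (error path only)."""
    in_record = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">"):
                in_record = line[1:].split()[0] == record_id if line[1:].strip() else False
                continue
            if in_record and bad_char in line.upper().replace("U", "T"):
                return lineno
    return -1


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (multi-line, case-insensitive) FASTA into normalized records.

    Sequences are uppercased and U is mapped to T.  Any character outside
    the 15-letter IUPAC nucleotide alphabet raises :class:`FastaParseError`
    naming the offending line.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_sequence(str(rec.seq))
        if not seq:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        bad = set(seq) - _VALID
        if bad:
            ch = sorted(bad)[0]
            lineno = _find_bad_line(path, ch, rec.id)
            raise FastaParseError(
                f"{path}:{lineno}: illegal character {ch!r} in record {rec.id!r} "
                f"(not an IUPAC nucleotide code)"
            )
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        records.append(SequenceRecord(id=rec.id, sequence=seq))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records one sequence per line (round-trips bit-exactly via read_fasta)."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def parse_taxonomy(path: str | Path) -> dict[str, Taxonomy]:
    """Parse a two-column Feature ID -> lineage table.

    Accepts both ``;``-with-space and bare-``;`` dialects, strips ``x__``
    prefixes, pads missing trailing ranks with empty strings, and tolerates
    an optional ``Feature ID\tTaxon`` header row.
    """
    path = Path(path)
    out: dict[str, Taxonomy] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise TaxonomyParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
            fid, lineage = parts[0].strip(), parts[1]
            if lineno == 1 and "__" not in lineage and fid.lower().replace(" ", "") in (
                "featureid", "id", "feature-id"
            ):
                continue  # header row
            if fid in out:
                raise TaxonomyParseError(f"{path}:{lineno}: duplicate Feature ID {fid!r}")
            try:
                out[fid] = Taxonomy.from_string(lineage)
            except TaxonomyParseError as e:
                raise TaxonomyParseError(f"{path}:{lineno}: {e}") from None
    if not out:
        raise TaxonomyParseError(f"{path}: no taxonomy rows found")
    return out


def write_taxonomy(tax: dict[str, Taxonomy], path: str | Path) -> None:
    with open(path, "w") as fh:
        for fid, t in tax.items():
            fh.write(f"{fid}\t{t.to_string()}\n")


def join_dataset(
    seqs: list[SequenceRecord],
    tax: dict[str, Taxonomy],
    require_species: bool = True,
) -> Dataset:
    """Inner-join sequences with taxonomy and build the species label index.

    Records lacking taxonomy — or, when ``require_species`` (the default for
    species-level classification), lacking a non-empty species rank — are
    dropped with a logged count.
    """
    kept: list[SequenceRecord] = []
    dropped = 0
    for rec in seqs:
        t = tax.get(rec.id)
        if t is None or (require_species and not t.species):
            dropped += 1
            continue
        kept.append(replace(rec, taxonomy=t))
    if dropped:
        logger.info("join_dataset: dropped %d of %d records (no taxonomy or no species label)",
                    dropped, len(seqs))
    if not kept:
        raise ValueError("no records remain after joining sequences with taxonomy")
    return Dataset(kept)
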
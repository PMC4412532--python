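"""Reading and writing raw genotype files in the direct-to-consumer dialect.

The dialect is the familiar 4-column tab-separated export: ``#``-prefixed
comment lines, then one data line per marker of
``rsid<TAB>chromosome<TAB>position<TAB>genotype``.  Genotypes are two
bases for autosomal diploid calls ("AG"), one base for hemizygous calls
on X/Y/MT ("A"), "--" for no-calls, and "I"/"D" codes for indel markers
("II", "DD", "DI").  Calls are unphased, so allele pairs are unordered:
"AG" and "GA" are the same call.

Genotypes are taken as reported on the forward strand of the stated
genome build (the DTC convention); strand reconciliation against a panel
is the matching layer's job, not the parser's.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

__all__ = [
    "GenotypeCall",
    "GenotypeProfile",
    "RawFileError",
    "parse_raw_genotypes",
    "write_raw_genotypes",
]

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")
_INDEL = frozenset("ID")
MISSING = "--"


class RawFileError(ValueError):
    """Raised for a structurally malformed raw genotype file."""


@dataclass(frozen=True)
class GenotypeCall:
    """One marker call: unordered allele pair, hemizygous allele, or missing.

    ``alleles`` is a tuple of 0 (missing), 1 (hemizygous) or 2 bases,
    stored in lexicographic order so equal unphased calls compare equal.
    ``is_snp`` is False for insertion/deletion codes (I/D), which parse
    but are excluded at panel-matching time.
    """

    rsid: str
    chrom: str
    position: int
    alleles: tuple[str, ...]
    is_snp: bool = True

    @property
    def is_missing(self) -> bool:
        return len(self.alleles) == 0

    @property
    def is_hemizygous(self) -> bool:
        return len(self.alleles) == 1

    def dosage_of(self, allele: str) -> int:
        """Copies of ``allele`` carried (0-2 diploid, 0-1 hemizygous)."""
        return sum(1 for a in self.alleles if a == allele)


@dataclass(frozen=True)
class GenotypeProfile:
    """One individual's rsid -> call map from a raw genotype file."""

    individual_id: str
    calls: dict[str, GenotypeCall]
    build: str = "GRCh37"

    def __len__(self) -> int:
        return len(self.calls)

    def get(self, rsid: str) -> GenotypeCall | None:
        return self.calls.get(rsid)


def _parse_genotype(geno: str, line_no: int) -> tuple[tuple[str, ...], bool]:
    if geno == MISSING:
        return (), True
    letters = tuple(geno)
    if len(letters) not in (1, 2):
        raise RawFileError(f"line {line_no}: bad genotype field {geno!r}")
    if all(a in _BASES for a in letters):
        return tuple(sorted(letters)), True
    if all(a in _INDEL for a in letters):
        return tuple(sorted(letters)), False
    raise RawFileError(f"line {line_no}: bad genotype field {geno!r}")


def parse_raw_genotypes(path: str | Path, individual_id: str,
                        build: str = "GRCh37") -> GenotypeProfile:
    """Parse a raw DTC genotype file into a :class:`GenotypeProfile`.

    Two-letter genotypes become unordered pairs, one-letter genotypes
    hemizygous calls, ``--`` missing calls; I/D codes parse but are
    flagged non-SNP.  A duplicated rsid keeps the first occurrence and
    logs a warning; a line with the wrong column count raises
    :class:`RawFileError` with its line number, so no data line is ever
    silently dropped.
    """
    path = Path(path)
    calls: dict[str, GenotypeCall] = {}
    with path.open("r", encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise RawFileError(
                    f"line {line_no}: expected 4 tab-separated fields, got {len(parts)}"
                )
            rsid, chrom, pos, geno = parts
            try:
                position = int(pos)
            except ValueError:
                raise RawFileError(f"line {line_no}: bad position {pos!r}") from None
            if rsid in calls:
                logger.warning("%s line %d: duplicate rsid %s, keeping first",
                               path.name, line_no, rsid)
                continue
            alleles, is_snp = _parse_genotype(geno, line_no)
            calls[rsid] = GenotypeCall(rsid, chrom, position, alleles, is_snp)
    return GenotypeProfile(individual_id=individual_id, calls=calls, build=build)


def write_raw_genotypes(profile: GenotypeProfile, path: str | Path) -> None:
    """Write a profile in the raw DTC dialect.

    The output round-trips through :func:`parse_raw_genotypes` to an
    equal profile; allele pairs are serialized in lexicographic order.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(f"# individual: {profile.individual_id}\n")
        fh.write(f"# build: {profile.build}\n")
        fh.write("# rsid\tchromosome\tposition\tgenotype\n")
        for call in profile.calls.values():
            geno = "".join(sorted(call.alleles)) if call.alleles else MISSING
            fh.write(f"{call.rsid}\t{call.chrom}\t{call.position}\t{geno}\n")
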
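"""Genome and interval primitives: FASTA/BED I/O and PAM-adjacent spacer enumeration.

All coordinates are 0-based, half-open (BED convention). Sequences are stored
uppercase over the alphabet {A, C, G, T, N}. Spacers are always reported 5'->3'
as read on the protospacer strand, with the 3-nt PAM immediately 3' of the
spacer on that strand.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

#: IUPAC degenerate nucleotide codes -> the set of concrete bases they admit.
#: A genomic ``N`` (unknown base) never satisfies a pattern position, including
#: pattern ``N``: unknown sequence is treated as unmatchable, not as wildcard.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware (``N`` maps to ``N``)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_to_regex(pattern: str) -> str:
    """Translate an IUPAC pattern into a concrete-base regex (no ``N`` targets)."""
    parts = []
    for ch in pattern.upper():
        try:
            bases = IUPAC_SETS[ch]
        except KeyError:
            raise ValueError(f"not an IUPAC nucleotide code: {ch!r}") from None
        parts.append(ch if len(bases) == 1 else "[" + "".join(sorted(bases)) + "]")
    return "".join(parts)


def iupac_match(pattern: str, seq: str) -> bool:
    """True iff ``seq`` (concrete bases) matches the IUPAC ``pattern`` exactly."""
    if len(pattern) != len(seq):
        return False
    return all(s in IUPAC_SETS.get(p, frozenset()) for p, s in zip(pattern.upper(), seq))


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``; strand in {+, -, .}."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid interval: [{self.start}, {self.end})")
        if self.strand not in {"+", "-", "."}:
            raise ValueError(f"invalid strand: {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """>=1 shared base, half-open semantics; strand-blind."""
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start <= other.start and other.end <= self.end


@dataclass
class Genome:
    """An in-memory genome: mapping of sequence id -> uppercase nucleotide string."""

    records: dict[str, str]
    build_label: str = ""

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("genome has no sequences")
        for name, seq in self.records.items():
            if not seq:
                raise ValueError(f"empty sequence: {name}")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(f"non-ACGTN characters in {name}: {sorted(bad)}")

    def __getitem__(self, chrom: str) -> str:
        return self.records[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.records

    def chroms(self) -> list[str]:
        return list(self.records)

    def length(self, chrom: str) -> int:
        return len(self.records[chrom])

    def slice(self, interval: GenomicInterval) -> str:
        """Sequence of ``interval``, reverse-complemented for strand '-'."""
        seq = self.records[interval.chrom][interval.start:interval.end]
        return revcomp(seq) if interval.strand == "-" else seq


def read_fasta(path: str | Path, build_label: str = "") -> Genome:
    """Read a (multi-)FASTA file into a :class:`Genome`.

    Sequences are uppercased; record ids are the first whitespace-delimited
    token of the header. Duplicate ids and non-ACGTN characters are errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate sequence id: {rec.id}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return Genome(records, build_label=build_label or str(path))


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read 3- or 6-column BED (strand from column 6 when present)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 3:
        raise ValueError(f"BED needs >=3 columns, got {df.shape[1]}")
    out = []
    for row in df.itertuples(index=False):
        strand = row[5] if len(row) >= 6 and row[5] in {"+", "-"} else "."
        out.append(GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand))
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path,
              names: Iterable[str] | None = None) -> None:
    names = list(names) if names is not None else None
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names else f"region_{i}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand if iv.strand != '.' else '+'}\n")


@dataclass(frozen=True)
class SpacerSite:
    """A 20-nt protospacer with PAM, genomic placement, and blunt-cut position.

    ``cut_pos`` is the 0-based genomic coordinate of the base immediately 3' of
    the cut on the + strand. SpCas9 cuts bluntly between spacer positions 17
    and 18 (1..20 from the 5' end, PAM-proximal = 20), i.e. 3 nt 5' of the PAM.
    """

    guide_id: str
    spacer: str
    pam: str
    interval: GenomicInterval
    strand: str
    cut_pos: int

    def __post_init__(self) -> None:
        if len(self.spacer) != len(self.interval):
            raise ValueError("spacer length disagrees with interval length")
        if len(self.pam) != 3:
            raise ValueError("PAM must be 3 nt")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"invalid strand: {self.strand!r}")
        if not self.interval.start <= self.cut_pos < self.interval.end:
            raise ValueError("cut position outside protospacer interval")


def _cut_pos(start: int, spacer_len: int, strand: str) -> int:
    # blunt cut between spacer positions 17|18 -> 3 nt 5' of the PAM
    return start + spacer_len - 3 if strand == "+" else start + 3


def enumerate_spacers(genome: Genome, pam_pattern: str = "NGG",
                      spacer_len: int = 20) -> list[SpacerSite]:
    """Enumerate every spacer immediately 5' of a PAM on both strands.

    Spacers containing ``N`` are excluded. Output is sorted by
    (chrom, start, strand) and fully deterministic.
    """
    if spacer_len < 1:
        raise ValueError("spacer_len must be >= 1")
    fwd_re = re.compile(f"(?=({iupac_to_regex(pam_pattern)}))")
    rev_re = re.compile(f"(?=({iupac_to_regex(revcomp(pam_pattern))}))")
    plen = len(pam_pattern)
    sites: list[SpacerSite] = []
    for chrom in sorted(genome.chroms()):
        seq = genome[chrom]
        for m in fwd_re.finditer(seq):
            p = m.start()
            if p < spacer_len:
                continue
            spacer = seq[p - spacer_len:p]
            if "N" in spacer:
                continue
            iv = GenomicInterval(chrom, p - spacer_len, p, "+")
            sites.append(SpacerSite(f"sg_{chrom}_{iv.start}_+", spacer, seq[p:p + plen],
                                    iv, "+", _cut_pos(iv.start, spacer_len, "+")))
        for m in rev_re.finditer(seq):
            p = m.start()  # PAM occupies [p, p+plen) on +; protospacer is 3' on -
            start, end = p + plen, p + plen + spacer_len
            if end > len(seq):
                continue
            spacer = revcomp(seq[start:end])
            if "N" in spacer:
                continue
            iv = GenomicInterval(chrom, start, end, "-")
            sites.append(SpacerSite(f"sg_{chrom}_{start}_-", spacer, revcomp(seq[p:p + plen]),
                                    iv, "-", _cut_pos(start, spacer_len, "-")))
    sites.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.strand))
    return sites


def gc_fraction(seq: str) -> float:
    """(#G + #C) / length for a non-empty ACGT string."""
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - set("ACGT")
    if bad:
        raise ValueError(f"gc_fraction requires ACGT only, got {sorted(bad)}")
    return (seq.count("G") + seq.count("C")) / len(seq)


def write_spacers_tsv(sites: Iterable[SpacerSite], path: str | Path) -> None:
    rows = [
        {"guide_id": s.guide_id, "chrom": s.interval.chrom, "start": s.interval.start,
         "end": s.interval.end, "strand": s.strand, "spacer": s.spacer, "pam": s.pam,
         "cut_pos": s.cut_pos}
        for s in sites
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
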
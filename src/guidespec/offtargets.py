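"""Exhaustive off-target site search within a mismatch budget, plus the two
count-based eligibility rules used for guide libraries.

The search contract is set-exactness: every genomic window (both strands)
whose adjacent PAM matches the configured PAM set and whose 20-nt protospacer
lies within the Hamming budget of the spacer is returned, with full mismatch
descriptors. The implementation is a vectorized all-window scan; any window
touching an ``N`` base never matches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .genome import Genome, GenomicInterval, IUPAC_SETS, revcomp

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_ENCODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in _BASE_CODE.items():
    _ENCODE_LUT[ord(_b)] = _c

#: default PAM set for SpCas9 off-target searches; NAG is the canonical
#: alternate PAM tolerated at off-target sites.
DEFAULT_PAM_SET: tuple[str, ...] = ("NGG", "NAG")


def _encode(seq: str) -> np.ndarray:
    return _ENCODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _pam_mask(enc: np.ndarray, patterns: Sequence[str]) -> np.ndarray:
    """Boolean mask over positions p: does enc[p:p+3] match any pattern?

    Genomic ``N`` (code 4) satisfies no pattern position.
    """
    n = enc.size
    plen = len(patterns[0])
    mask = np.zeros(max(n - plen + 1, 0), dtype=bool)
    for pat in patterns:
        if len(pat) != plen:
            raise ValueError("all PAM patterns must share one length")
        m = np.ones(mask.size, dtype=bool)
        for k, ch in enumerate(pat.upper()):
            allowed = np.zeros(5, dtype=bool)
            for b in IUPAC_SETS[ch]:
                allowed[_BASE_CODE[b]] = True
            m &= allowed[enc[k:k + mask.size]]
        mask |= m
    return mask


@dataclass(frozen=True, order=True)
class MismatchDescriptor:
    """One spacer/protospacer mismatch: position 1..20 from the spacer 5' end
    (position 20 is PAM-proximal), with guide (RNA) and target (DNA, as read on
    the protospacer strand) base identities."""

    position: int
    guide_base: str
    target_base: str

    def __post_init__(self) -> None:
        if not 1 <= self.position <= 20:
            raise ValueError(f"mismatch position out of range: {self.position}")
        if self.guide_base == self.target_base:
            raise ValueError("guide and target base identical: not a mismatch")


@dataclass(frozen=True)
class OffTargetSite:
    """A genomic window matching a spacer within the mismatch budget."""

    interval: GenomicInterval
    strand: str
    site_seq: str
    pam: str
    mismatches: tuple[MismatchDescriptor, ...]
    n_mismatch: int

    def __post_init__(self) -> None:
        if self.n_mismatch != len(self.mismatches):
            raise ValueError("n_mismatch disagrees with descriptor count")


@dataclass(frozen=True)
class OffTargetTally:
    """Per-mismatch-class site counts; complete for classes 0..3 at minimum."""

    counts: dict[int, int]

    def __post_init__(self) -> None:
        for c in range(4):
            self.counts.setdefault(c, 0)
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("negative tally count")

    def __getitem__(self, cls: int) -> int:
        return self.counts.get(cls, 0)

    def total(self) -> int:
        return sum(self.counts.values())


def _descriptors(spacer: str, site_seq: str) -> tuple[MismatchDescriptor, ...]:
    return tuple(
        MismatchDescriptor(i + 1, g, t)
        for i, (g, t) in enumerate(zip(spacer, site_seq))
        if g != t
    )


def find_offtarget_sites(spacer: str, genome: Genome, max_mismatches: int = 3,
                         pam_set: Sequence[str] = DEFAULT_PAM_SET) -> list[OffTargetSite]:
    """All both-strand genomic windows within ``max_mismatches`` of ``spacer``
    whose adjacent PAM matches any pattern in ``pam_set``.

    Includes the guide's own perfect (on-target) match when present; callers
    that score off-target activity exclude it downstream.
    """
    if len(spacer) != 20:
        raise ValueError(f"spacer must be 20 nt, got {len(spacer)}")
    if not 0 <= max_mismatches <= 4:
        raise ValueError("max_mismatches must be in 0..4")
    if set(spacer) - set("ACGT"):
        raise ValueError("spacer must be ACGT only")
    slen = len(spacer)
    plen = len(pam_set[0])
    sp_fwd = _encode(spacer)
    sp_rev = _encode(revcomp(spacer))
    rc_pams = [revcomp(p) for p in pam_set]

    sites: list[OffTargetSite] = []
    for chrom in sorted(genome.chroms()):
        seq = genome[chrom]
        enc = _encode(seq)
        if enc.size < slen + plen:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(enc, slen)
        has_n = (windows == 4).any(axis=1)
        pam_fwd = _pam_mask(enc, list(pam_set))
        pam_rev = _pam_mask(enc, rc_pams)

        # + strand: protospacer [i, i+20), PAM [i+20, i+23)
        mm = (windows != sp_fwd).sum(axis=1)
        n_start = enc.size - slen - plen + 1  # last start with room for PAM
        ok = (mm[:n_start] <= max_mismatches) & ~has_n[:n_start] & pam_fwd[slen:slen + n_start]
        for i in np.nonzero(ok)[0]:
            i = int(i)
            site_seq = seq[i:i + slen]
            sites.append(OffTargetSite(
                GenomicInterval(chrom, i, i + slen, "+"), "+", site_seq,
                seq[i + slen:i + slen + plen], _descriptors(spacer, site_seq), int(mm[i])))

        # - strand: protospacer revcomp of [j, j+20), PAM revcomp of [j-3, j)
        mm_r = (windows != sp_rev).sum(axis=1)
        starts = np.arange(plen, enc.size - slen + 1)
        ok = (mm_r[starts] <= max_mismatches) & ~has_n[starts] & pam_rev[starts - plen]
        for j in starts[ok]:
            j = int(j)
            site_seq = revcomp(seq[j:j + slen])
            sites.append(OffTargetSite(
                GenomicInterval(chrom, j, j + slen, "-"), "-", site_seq,
                revcomp(seq[j - plen:j]), _descriptors(spacer, site_seq), int(mm_r[j])))
    sites.sort(key=lambda s: (s.interval.chrom, s.interval.start, s.strand))
    return sites


def tally_offtargets(sites: Iterable[OffTargetSite]) -> OffTargetTally:
    counts: dict[int, int] = {}
    for s in sites:
        counts[s.n_mismatch] = counts.get(s.n_mismatch, 0) + 1
    return OffTargetTally(counts)


def is_searchable(tally: OffTargetTally) -> bool:
    """Searchability rule: exactly one perfect genomic match (the on-target)
    and zero 1-mismatch sites. Guides with >1 perfect matches or any
    1-mismatch off-target are unsearchable and carry no specificity score.

    The tally must include the on-target in class 0; a class-0 count of zero
    means the guide has no genomic home and is an error.
    """
    if tally[0] == 0:
        raise ValueError("tally has no perfect match: guide has no genomic home")
    return tally[0] == 1 and tally[1] == 0


#: legacy library-design count thresholds: a guide fails with >2 perfect,
#: >10 1-mismatch, >50 2-mismatch, or >200 3-mismatch genome-wide matches.
LEGACY_THRESHOLDS: dict[int, int] = {0: 2, 1: 10, 2: 50, 3: 200}


def legacy_count_filter(tally: OffTargetTally,
                        thresholds: dict[int, int] | None = None) -> bool:
    """Pass iff no mismatch-class count strictly exceeds its threshold."""
    thresholds = LEGACY_THRESHOLDS if thresholds is None else thresholds
    return all(tally[c] <= t for c, t in thresholds.items())
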
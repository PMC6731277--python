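"""Guide library filtering and element-targetability logic.

Implements the full filter stack used for motif-targeting and tiling screen
libraries: sequence-composition rules (GC bounds, poly-T, G-run suffix,
restriction sites on either strand), off-target count rules, exclusion-region
overlap of near-perfect matches, per-motif guide selection, and element-level
targetability summaries under a specificity cutoff.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from intervaltree import IntervalTree

from .cfd import CfdWeightTable, SpecificityResult, score_guide
from .genome import (Genome, GenomicInterval, SpacerSite, enumerate_spacers,
                     gc_fraction, iupac_to_regex, revcomp)
from .offtargets import (DEFAULT_PAM_SET, LEGACY_THRESHOLDS, find_offtarget_sites,
                         legacy_count_filter, tally_offtargets)

#: restriction sites whose presence in a guide oligo confounds cloning/PCR
DEFAULT_RESTRICTION_PATTERNS: tuple[str, ...] = (
    "CTGCAG", "GAAGAC", "GTCTTC", "CCANNNNNNTGG", "GCTNAGC")


@dataclass
class FilterRuleSet:
    """All tunable guide-filter parameters with their library-design defaults."""

    gc_min: float = 0.20
    gc_max: float = 0.80
    forbidden_suffix: str = "GGGGG"
    forbidden_substrings: tuple[str, ...] = ("TTTT",)
    restriction_patterns: tuple[str, ...] = DEFAULT_RESTRICTION_PATTERNS
    count_thresholds: dict[int, int] = field(default_factory=lambda: dict(LEGACY_THRESHOLDS))
    exclusion_regions: tuple[GenomicInterval, ...] = ()
    exclusion_max_mm: int = 1
    specificity_cutoff: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_min < self.gc_max <= 1.0:
            raise ValueError("need 0 <= gc_min < gc_max <= 1")
        if not 0.0 <= self.specificity_cutoff <= 1.0:
            raise ValueError("specificity cutoff must be in [0,1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterRuleSet":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("gc_min", "gc_max", "forbidden_suffix", "specificity_cutoff",
                    "exclusion_max_mm"):
            if key in cfg:
                kwargs[key] = cfg[key]
        if "forbidden_substrings" in cfg:
            kwargs["forbidden_substrings"] = tuple(cfg["forbidden_substrings"])
        if "restriction_patterns" in cfg:
            kwargs["restriction_patterns"] = tuple(cfg["restriction_patterns"])
        if "count_thresholds" in cfg:
            kwargs["count_thresholds"] = {int(k): int(v)
                                          for k, v in cfg["count_thresholds"].items()}
        return cls(**kwargs)


def sequence_filters(spacer: str, rules: FilterRuleSet | None = None) -> dict[str, bool]:
    """Evaluate the sequence-composition rules; True means the rule passes.

    GC bounds are strict (fail iff gc < gc_min or gc > gc_max); restriction
    patterns are IUPAC-expanded and matched against both the spacer and its
    reverse complement, since restriction recognition is double-stranded.
    """
    rules = rules or FilterRuleSet()
    flags = {
        "gc": rules.gc_min <= gc_fraction(spacer) <= rules.gc_max,
        "suffix": not spacer.endswith(rules.forbidden_suffix),
    }
    for sub in rules.forbidden_substrings:
        flags[f"substring:{sub}"] = sub not in spacer
    rc = revcomp(spacer)
    for pat in rules.restriction_patterns:
        rx = re.compile(iupac_to_regex(pat))
        flags[f"restriction:{pat}"] = not (rx.search(spacer) or rx.search(rc))
    return flags


def _interval_trees(regions: Iterable[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for iv in regions:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end)
    return trees


def exclusion_overlap_filter(spacer: str, genome: Genome,
                             exclusion_regions: Sequence[GenomicInterval],
                             max_mm: int = 1,
                             pam_set: Sequence[str] = DEFAULT_PAM_SET) -> bool:
    """Pass unless any 0..max_mm-mismatch site overlaps an exclusion region.

    Used to drop guides whose exact or near-exact matches fall in regions where
    cutting would confound the screen (exons, DNase-hypersensitive sites, other
    target sites). Overlap is >=1 shared base, half-open.
    """
    if not exclusion_regions:
        return True
    trees = _interval_trees(exclusion_regions)
    for site in find_offtarget_sites(spacer, genome, max_mm, pam_set):
        tree = trees.get(site.interval.chrom)
        if tree is not None and tree.overlap(site.interval.start, site.interval.end):
            return False
    return True


@dataclass
class GuideRecord:
    """A candidate library guide: placement, target element, filter flags, score."""

    site: SpacerSite
    element_id: str = ""
    flags: dict[str, bool] = field(default_factory=dict)
    specificity: SpecificityResult | None = None

    @property
    def guide_id(self) -> str:
        return self.site.guide_id

    @property
    def eligible(self) -> bool:
        return all(self.flags.values())

    @property
    def score(self) -> float | None:
        return self.specificity.score if self.specificity is not None else None


@dataclass
class ElementTarget:
    """A targetable element with its guide-selection window (± bp)."""

    element_id: str
    interval: GenomicInterval
    element_type: str = "ccre"
    window: int = 0

    _TYPES = {"ctcf-motif", "tss", "ccre", "exon", "enhancer", "safe"}

    def __post_init__(self) -> None:
        if self.window < 0:
            raise ValueError("window must be >= 0")
        if self.element_type not in self._TYPES:
            raise ValueError(f"unknown element type: {self.element_type!r}")

    def expanded(self) -> GenomicInterval:
        return GenomicInterval(self.interval.chrom,
                               max(0, self.interval.start - self.window),
                               self.interval.end + self.window,
                               self.interval.strand)


@dataclass
class MotifSelection:
    """Guides chosen for one motif, with an under-coverage flag (<2 guides)."""

    element_id: str
    guides: list[GuideRecord]
    under_covered: bool


def select_motif_guides(motif: ElementTarget, candidates: Sequence[GuideRecord],
                        max_per_site: int = 5) -> MotifSelection:
    """Keep up to ``max_per_site`` guides whose expected cut falls in the motif.

    Ranking: specificity score descending, then distance of the cut from the
    motif center ascending, then guide id. Motifs retaining fewer than two
    guides are flagged as under-covered (two concordant guides per site is the
    design minimum).
    """
    center = (motif.interval.start + motif.interval.end) / 2.0
    in_motif = [g for g in candidates
                if g.site.interval.chrom == motif.interval.chrom
                and motif.interval.start <= g.site.cut_pos < motif.interval.end]
    in_motif.sort(key=lambda g: (-(g.score if g.score is not None else -1.0),
                                 abs(g.site.cut_pos - center), g.guide_id))
    chosen = in_motif[:max_per_site]
    return MotifSelection(motif.element_id, chosen, under_covered=len(chosen) < 2)


def _guide_targets_element(guide: GuideRecord, element: ElementTarget, mode: str) -> bool:
    if mode == "cas9":
        iv = element.interval
        return (guide.site.interval.chrom == iv.chrom
                and iv.start <= guide.site.cut_pos < iv.end)
    # CRISPRi/a: protospacer fully inside the +/- window around the element
    return element.expanded().contains(guide.site.interval)


def targetability_summary(elements: Sequence[ElementTarget],
                          guides: Sequence[GuideRecord],
                          score_cutoff: float = 0.2, min_guides: int = 5,
                          mode: str = "crispri") -> tuple[pd.DataFrame, float]:
    """Per-element count of eligible high-specificity guides and the fraction
    of elements targetable with >= ``min_guides`` such guides.

    Cas9 mode requires the expected cut inside the element interval (narrow
    motifs must be hit directly); CRISPRi/a modes accept any guide whose
    protospacer lies within the element's ± window. Only guides with a
    specificity score strictly greater than ``score_cutoff`` count.
    """
    if mode not in {"cas9", "crispri", "crispra"}:
        raise ValueError(f"unknown mode: {mode!r}")
    usable = [g for g in guides
              if g.eligible and g.score is not None and g.score > score_cutoff]
    rows = []
    for el in elements:
        n = sum(_guide_targets_element(g, el, mode) for g in usable)
        rows.append({"element_id": el.element_id, "element_type": el.element_type,
                     "n_guides": n, "targetable": n >= min_guides})
    df = pd.DataFrame(rows)
    frac = float(df["targetable"].mean()) if len(df) else 0.0
    return df, frac


def design_library(genome: Genome, elements: Sequence[ElementTarget],
                   rules: FilterRuleSet | None = None,
                   weights: CfdWeightTable | None = None,
                   mode: str = "cas9", pam_pattern: str = "NGG",
                   offtarget_pam_set: Sequence[str] = DEFAULT_PAM_SET,
                   max_per_site: int = 5) -> tuple[list[GuideRecord], list[MotifSelection]]:
    """End-to-end library design on a genome and element set.

    Enumerates NGG spacers whose protospacer lies in an element window, applies
    the sequence, count, exclusion and searchability filters, scores the
    survivors, and (in cas9 mode) picks up to ``max_per_site`` guides per
    element. Returns all evaluated guide records plus per-element selections.
    """
    rules = rules or FilterRuleSet()
    all_spacers = enumerate_spacers(genome, pam_pattern)
    windows = _interval_trees(el.expanded() for el in elements)
    el_by_chrom: dict[str, list[ElementTarget]] = {}
    for el in elements:
        el_by_chrom.setdefault(el.interval.chrom, []).append(el)

    records: list[GuideRecord] = []
    for sp in all_spacers:
        tree = windows.get(sp.interval.chrom)
        if tree is None or not tree.overlap(sp.interval.start, sp.interval.end):
            continue
        element_id = ""
        for el in el_by_chrom[sp.interval.chrom]:
            if el.expanded().contains(sp.interval):
                element_id = el.element_id
                break
        if not element_id:
            continue
        flags = sequence_filters(sp.spacer, rules)
        result = score_guide(sp.guide_id, sp.spacer, genome, weights,
                             pam_set=offtarget_pam_set)
        flags["searchable"] = result.searchable
        flags["offtarget_counts"] = legacy_count_filter(result.tally, rules.count_thresholds)
        flags["exclusion"] = exclusion_overlap_filter(
            sp.spacer, genome, rules.exclusion_regions, rules.exclusion_max_mm,
            offtarget_pam_set)
        records.append(GuideRecord(sp, element_id, flags, result))

    selections: list[MotifSelection] = []
    if mode == "cas9":
        eligible = [g for g in records if g.eligible]
        for el in elements:
            selections.append(select_motif_guides(el, eligible, max_per_site))
    return records, selections


def write_library_tsv(records: Iterable[GuideRecord], path: str | Path) -> None:
    rows = []
    for g in records:
        failed = ";".join(sorted(k for k, v in g.flags.items() if not v))
        rows.append({
            "guide_id": g.guide_id, "spacer": g.site.spacer, "pam": g.site.pam,
            "chrom": g.site.interval.chrom, "start": g.site.interval.start,
            "end": g.site.interval.end, "strand": g.site.strand,
            "cut_pos": g.site.cut_pos, "element_id": g.element_id,
            "eligible": g.eligible, "failed_rules": failed,
            "specificity_score": "" if g.score is None else f"{g.score:.6g}",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_elements_bed(path: str | Path, element_type: str = "ccre",
                      window: int = 0) -> list[ElementTarget]:
    """Read elements from BED; the 4th column (when present) gives element ids."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        name = str(row[3]) if len(row) >= 4 else f"element_{i}"
        strand = row[5] if len(row) >= 6 and row[5] in {"+", "-"} else "."
        iv = GenomicInterval(str(row[0]), int(row[1]), int(row[2]), strand)
        out.append(ElementTarget(name, iv, element_type=element_type, window=window))
    return out
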
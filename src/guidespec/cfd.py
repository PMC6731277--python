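"""CFD per-site scores and their aggregation into a guide specificity score.

The Cutting Frequency Determination (CFD) score of a candidate off-target site
is the product of position- and identity-specific mismatch weights and a PAM
weight; a perfect NGG site scores 1. A guide's aggregate specificity score is

    S = 1 / (1 + sum of CFD over its 2-3-mismatch off-target sites)

so S = 1 for a guide with no such sites and S -> 0 as predicted off-target
activity accumulates. Guides that are not searchable (more than one perfect
genomic match, or any 1-mismatch site) are not scored at all: they carry
``score = None`` rather than 0, mirroring how such guides are excluded from
analysis instead of being ranked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome import Genome
from .offtargets import (DEFAULT_PAM_SET, OffTargetSite, OffTargetTally,
                         find_offtarget_sites, is_searchable, tally_offtargets)

_BASES = "ACGT"

# Synthetic per-mismatch-type factors (guide RNA base vs target DNA base on the
# protospacer strand). These are NOT measured cutting frequencies; they encode
# the qualitative structure of the published CFD model (wobble-like G:T/A:C
# mismatches tolerated more than purine-purine clashes) for testing and demos.
_SYNTH_TYPE_FACTOR: dict[tuple[str, str], float] = {
    ("A", "C"): 0.90, ("A", "G"): 0.55, ("A", "T"): 0.70,
    ("C", "A"): 0.80, ("C", "G"): 0.50, ("C", "T"): 0.85,
    ("G", "A"): 0.60, ("G", "C"): 0.45, ("G", "T"): 0.95,
    ("T", "A"): 0.65, ("T", "C"): 0.75, ("T", "G"): 0.88,
}

# Synthetic PAM weights keyed by the 2-nt suffix of the NRN 3-mer; GG (the
# canonical NGG) is 1 by definition, AG is the tolerated alternate.
_SYNTH_PAM_SUFFIX: dict[str, float] = {
    "GG": 1.0, "AG": 0.26, "GA": 0.07, "CG": 0.03, "TG": 0.03,
    "AA": 0.0, "AC": 0.0, "AT": 0.0, "CA": 0.0, "CC": 0.0, "CT": 0.0,
    "GC": 0.02, "GT": 0.02, "TA": 0.0, "TC": 0.0, "TT": 0.0,
}


@dataclass
class CfdWeightTable:
    """Mismatch and PAM weights for per-site CFD scoring.

    ``mismatch_weights`` maps (position 1..20, guide base, target base) to a
    weight in [0, 1]; positions count 5'->3' along the spacer with position 20
    PAM-proximal. Matched base pairs contribute no factor (implicit weight 1).
    ``pam_weights`` is keyed by 2-nt PAM suffix (or full 3-nt PAM); the NGG
    suffix weight must be 1.
    """

    mismatch_weights: dict[tuple[int, str, str], float]
    pam_weights: dict[str, float]
    source_label: str = ""

    def __post_init__(self) -> None:
        for key, w in self.mismatch_weights.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"mismatch weight out of [0,1] at {key}: {w}")
        for key, w in self.pam_weights.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"PAM weight out of [0,1] at {key}: {w}")
        gg = self.pam_weights.get("GG", self.pam_weights.get("NGG"))
        if gg is None or gg != 1.0:
            raise ValueError("NGG PAM weight must be present and equal to 1")

    def mismatch_weight(self, position: int, guide_base: str, target_base: str) -> float:
        try:
            return self.mismatch_weights[(position, guide_base, target_base)]
        except KeyError:
            raise KeyError(
                f"no CFD weight for mismatch (pos={position}, guide={guide_base}, "
                f"target={target_base})") from None

    def pam_weight(self, pam: str) -> float:
        if pam in self.pam_weights:
            return self.pam_weights[pam]
        suffix = pam[-2:]
        if suffix in self.pam_weights:
            return self.pam_weights[suffix]
        raise KeyError(f"no PAM weight for {pam!r}")

    @classmethod
    def synthetic(cls, position_decay: float = 0.85) -> "CfdWeightTable":
        """Deterministic synthetic weight table (see module docstring).

        Weights decay linearly toward the PAM: a mismatch at position p gets
        ``type_factor * (1 - position_decay * (p - 1) / 19)``, so PAM-distal
        mismatches are well tolerated and PAM-proximal ones are penalized.
        """
        mm = {
            (p, g, t): round(f * (1.0 - position_decay * (p - 1) / 19.0), 4)
            for p in range(1, 21)
            for (g, t), f in _SYNTH_TYPE_FACTOR.items()
        }
        return cls(mm, dict(_SYNTH_PAM_SUFFIX), source_label="synthetic")

    @classmethod
    def load(cls, mismatch_path: str | Path, pam_path: str | Path,
             source_label: str = "") -> "CfdWeightTable":
        """Load from the TSV asset format (see :func:`save` for columns)."""
        mdf = pd.read_csv(mismatch_path, sep="\t")
        required = {"position", "guide_base", "target_base", "weight"}
        if not required <= set(mdf.columns):
            raise ValueError(f"mismatch table needs columns {sorted(required)}")
        mm = {
            (int(r.position), str(r.guide_base), str(r.target_base)): float(r.weight)
            for r in mdf.itertuples(index=False)
        }
        pdf = pd.read_csv(pam_path, sep="\t")
        if not {"pam", "weight"} <= set(pdf.columns):
            raise ValueError("PAM table needs columns ['pam', 'weight']")
        pam = {str(r.pam): float(r.weight) for r in pdf.itertuples(index=False)}
        return cls(mm, pam, source_label=source_label or str(mismatch_path))

    def save(self, mismatch_path: str | Path, pam_path: str | Path) -> None:
        mdf = pd.DataFrame(
            [{"position": p, "guide_base": g, "target_base": t, "weight": w}
             for (p, g, t), w in sorted(self.mismatch_weights.items())])
        mdf.to_csv(mismatch_path, sep="\t", index=False)
        pdf = pd.DataFrame([{"pam": k, "weight": v}
                            for k, v in sorted(self.pam_weights.items())])
        pdf.to_csv(pam_path, sep="\t", index=False)


def default_weight_table() -> CfdWeightTable:
    """The packaged weight table asset (synthetic; see module docstring)."""
    data = resources.files("guidespec") / "data"
    with resources.as_file(data / "cfd_mismatch_weights_synthetic.tsv") as mp, \
            resources.as_file(data / "cfd_pam_weights_synthetic.tsv") as pp:
        return CfdWeightTable.load(mp, pp, source_label="packaged-synthetic")


def cfd_site_score(site: OffTargetSite, weights: CfdWeightTable) -> float:
    """Per-site CFD: product of mismatch weights times the PAM weight."""
    if site.n_mismatch > 4:
        raise ValueError("CFD scoring supports at most 4 mismatches")
    score = weights.pam_weight(site.pam)
    for d in site.mismatches:
        score *= weights.mismatch_weight(d.position, d.guide_base, d.target_base)
    return score


@dataclass
class SpecificityResult:
    """Per-guide off-target tallies and (when searchable) the aggregate score."""

    guide_id: str
    tally: OffTargetTally
    searchable: bool
    cfd_sum: float | None
    score: float | None

    def __post_init__(self) -> None:
        if self.searchable:
            if self.score is None or self.cfd_sum is None:
                raise ValueError("searchable guide must carry a numeric score")
            if not 0.0 < self.score <= 1.0:
                raise ValueError(f"score out of (0,1]: {self.score}")
        elif self.score is not None:
            raise ValueError("unsearchable guide must not carry a score")


def aggregate_specificity(sites: Sequence[OffTargetSite], weights: CfdWeightTable,
                          include_classes: frozenset[int] | set[int] = frozenset({2, 3}),
                          *, guide_id: str = "", tally: OffTargetTally | None = None,
                          searchable: bool = True) -> SpecificityResult:
    """Aggregate per-site CFDs into a specificity score 1 / (1 + sum CFD).

    ``sites`` must exclude the guide's on-target match; only sites whose
    mismatch class is in ``include_classes`` (default {2, 3}) enter the sum.
    Calling this for an unsearchable guide is an error: such guides are
    excluded from scoring, never assigned a number.
    """
    if not searchable:
        raise ValueError(f"guide {guide_id!r} is unsearchable and cannot be scored")
    cfd_sum = sum(cfd_site_score(s, weights) for s in sites
                  if s.n_mismatch in include_classes)
    return SpecificityResult(
        guide_id=guide_id,
        tally=tally if tally is not None else tally_offtargets(sites),
        searchable=True, cfd_sum=cfd_sum, score=1.0 / (1.0 + cfd_sum))


def score_guide(guide_id: str, spacer: str, genome: Genome,
                weights: CfdWeightTable | None = None,
                pam_set: Sequence[str] = DEFAULT_PAM_SET,
                max_mismatches: int = 3,
                include_classes: frozenset[int] | set[int] = frozenset({2, 3}),
                ) -> SpecificityResult:
    """Search, tally, check searchability, and score one guide end to end.

    The tally includes the on-target perfect match (class 0); the CFD sum is
    computed over the remaining sites. Unsearchable guides get ``score=None``.
    """
    weights = weights if weights is not None else default_weight_table()
    sites = find_offtarget_sites(spacer, genome, max_mismatches, pam_set)
    tally = tally_offtargets(sites)
    if not is_searchable(tally):
        return SpecificityResult(guide_id, tally, False, None, None)
    offtargets = [s for s in sites if s.n_mismatch > 0]
    return aggregate_specificity(offtargets, weights, include_classes,
                                 guide_id=guide_id, tally=tally)


def write_scores_tsv(results: Iterable[SpecificityResult], path: str | Path) -> None:
    rows = [
        {"guide_id": r.guide_id, "n0": r.tally[0], "n1": r.tally[1],
         "n2": r.tally[2], "n3": r.tally[3], "searchable": r.searchable,
         "cfd_sum": "" if r.cfd_sum is None else f"{r.cfd_sum:.6g}",
         "specificity_score": "" if r.score is None else f"{r.score:.6g}"}
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_scores_tsv(path: str | Path) -> dict[str, SpecificityResult]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, SpecificityResult] = {}
    for r in df.itertuples(index=False):
        tally = OffTargetTally({0: int(r.n0), 1: int(r.n1), 2: int(r.n2), 3: int(r.n3)})
        searchable = bool(r.searchable)
        cfd_sum = None if pd.isna(r.cfd_sum) else float(r.cfd_sum)
        score = None if pd.isna(r.specificity_score) else float(r.specificity_score)
        out[str(r.guide_id)] = SpecificityResult(str(r.guide_id), tally, searchable,
                                                 cfd_sum, score)
    return out
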
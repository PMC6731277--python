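"""Pooled growth-screen analysis: guide-level log2 fold-change enrichment,
the specificity-fitness quadrant association (exact Fisher test), and
element-level essentiality calls before and after specificity filtering.

"Guide enrichment" is the log2 fold-change of a guide's counts-per-million at
the screen endpoint versus the original plasmid pool. A quadrant analysis
crosses depletion (mean log2FC <= -2 by default) with low specificity
(score <= 0.2 by default) in a 2x2 table; strong association indicates that
off-target toxicity, not on-target biology, drives the screen signal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .cfd import SpecificityResult


@dataclass
class CountMatrix:
    """Guide x sample integer read counts with sample roles.

    ``roles`` maps each sample label to "plasmid" or "endpoint"; a screen needs
    at least one of each. Multiple plasmid samples are averaged on the CPM
    scale; each endpoint sample is one biological replicate.
    """

    counts: pd.DataFrame  # index: guide ids; columns: sample labels
    roles: dict[str, str]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate guide ids in count matrix")
        if set(self.counts.columns) != set(self.roles):
            raise ValueError("sample roles must cover exactly the count columns")
        bad = {r for r in self.roles.values()} - {"plasmid", "endpoint"}
        if bad:
            raise ValueError(f"unknown sample roles: {sorted(bad)}")
        if not self.plasmid_samples or not self.endpoint_samples:
            raise ValueError("need >=1 plasmid and >=1 endpoint sample")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def plasmid_samples(self) -> list[str]:
        return [s for s in self.counts.columns if self.roles[s] == "plasmid"]

    @property
    def endpoint_samples(self) -> list[str]:
        return [s for s in self.counts.columns if self.roles[s] == "endpoint"]

    @classmethod
    def read_tsv(cls, counts_path: str | Path, roles: Mapping[str, str] | str | Path,
                 guide_col: str = "guide_id") -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t").set_index(guide_col)
        if not isinstance(roles, Mapping):
            with open(roles) as fh:
                roles = yaml.safe_load(fh)
        return cls(df, dict(roles))


@dataclass
class EnrichmentRecord:
    """Per-guide log2 fold-changes: one value per endpoint replicate, their
    mean, and the standard error (sd / sqrt(k))."""

    guide_id: str
    log2fc_per_rep: list[float]
    mean_log2fc: float
    se: float


def guide_enrichment(counts: CountMatrix, pseudocount: float = 1.0,
                     normalize: str = "cpm") -> list[EnrichmentRecord]:
    """Per-replicate log2((cpm_endpoint + p) / (cpm_plasmid + p)).

    Counts are normalized to counts-per-million within each sample before the
    pseudocount ``p`` is added, so the statistic is invariant to sequencing
    depth. With several plasmid samples their CPMs are averaged.
    """
    if normalize not in {"cpm", "none"}:
        raise ValueError(f"unknown normalization: {normalize!r}")
    mat = counts.counts.astype(float)
    totals = mat.sum(axis=0)
    if (totals == 0).any():
        dead = list(totals.index[totals == 0])
        raise ValueError(f"all-zero sample(s): {dead}")
    norm = mat / totals * 1e6 if normalize == "cpm" else mat
    plasmid = norm[counts.plasmid_samples].mean(axis=1)
    reps = [np.log2((norm[s] + pseudocount) / (plasmid + pseudocount))
            for s in counts.endpoint_samples]
    rep_mat = np.column_stack(reps)
    k = rep_mat.shape[1]
    means = rep_mat.mean(axis=1)
    ses = (rep_mat.std(axis=1, ddof=1) / math.sqrt(k)) if k > 1 else np.full(len(means), np.nan)
    return [EnrichmentRecord(g, [float(x) for x in rep_mat[i]], float(means[i]), float(ses[i]))
            for i, g in enumerate(counts.counts.index)]


def fisher_exact_2x2(cells: Sequence[Sequence[int]], sidedness: str = "two-sided") -> float:
    """Fisher's exact test p-value for a 2x2 table, by exact integer arithmetic.

    Two-sided p sums the hypergeometric probabilities of every table with the
    same margins whose probability does not exceed that of the observed table
    (minimum-likelihood rule). Probabilities are compared as exact integer
    numerators over the common denominator C(n, column margin), so ties are
    exact and no floating-point tolerance is needed. A zero margin yields
    p = 1 by convention (with a warning).
    """
    (a, b), (c, d) = cells
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        warnings.warn("degenerate 2x2 table (zero margin): p = 1 by convention")
        return 1.0

    def num(x: int) -> int:
        return math.comb(r1, x) * math.comb(r2, c1 - x)

    lo, hi = max(0, c1 - r2), min(r1, c1)
    denom = math.comb(n, c1)
    obs = num(a)
    if sidedness == "two-sided":
        total = sum(num(x) for x in range(lo, hi + 1) if num(x) <= obs)
    elif sidedness == "greater":
        total = sum(num(x) for x in range(a, hi + 1))
    elif sidedness == "less":
        total = sum(num(x) for x in range(lo, a + 1))
    else:
        raise ValueError(f"unknown sidedness: {sidedness!r}")
    return total / denom


@dataclass
class QuadrantTable:
    """2x2 contingency of depletion x low specificity with OR and Fisher p.

    cells = [[depleted & low-spec, depleted & high-spec],
             [not-depleted & low-spec, not-depleted & high-spec]].
    """

    fc_threshold: float
    score_threshold: float
    cells: list[list[int]]
    odds_ratio: float
    p_value: float

    def n_guides(self) -> int:
        return sum(sum(row) for row in self.cells)


def _odds_ratio(a: int, b: int, c: int, d: int, haldane: bool = False) -> float:
    if haldane:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def quadrant_association(enrich: Sequence[EnrichmentRecord],
                         scores: Mapping[str, SpecificityResult],
                         fc_threshold: float = -2.0, score_threshold: float = 0.2,
                         haldane: bool = False) -> QuadrantTable:
    """Cross depletion with low specificity and test independence exactly.

    Only searchable, scored guides present in ``scores`` enter the table.
    Low specificity means score <= score_threshold; depleted means
    mean log2FC <= fc_threshold.
    """
    a = b = c = d = 0
    for rec in enrich:
        res = scores.get(rec.guide_id)
        if res is None or not res.searchable or res.score is None:
            continue
        depleted = rec.mean_log2fc <= fc_threshold
        low = res.score <= score_threshold
        if depleted and low:
            a += 1
        elif depleted:
            b += 1
        elif low:
            c += 1
        else:
            d += 1
    if a + b + c + d == 0:
        raise ValueError("no searchable, scored guides to analyze")
    cells = [[a, b], [c, d]]
    return QuadrantTable(fc_threshold, score_threshold, cells,
                         _odds_ratio(a, b, c, d, haldane), fisher_exact_2x2(cells))


@dataclass
class ElementCall:
    """Element-level essentiality evidence from its guides' depletion."""

    element_id: str
    n_guides_total: int
    n_guides_depleted: int
    called: bool            # >= min_concordant depleted guides
    single_guide_only: bool  # exactly one depleted guide (weak evidence)


def call_elements(enrich: Sequence[EnrichmentRecord],
                  guide_to_element: Mapping[str, str],
                  fc_threshold: float = -2.0,
                  min_concordant: int = 2) -> list[ElementCall]:
    """Call an element essential iff >= ``min_concordant`` of its guides are
    depleted past ``fc_threshold``; elements with exactly one depleted guide
    are reported separately as single-guide evidence."""
    totals: dict[str, int] = {}
    depleted: dict[str, int] = {}
    for rec in enrich:
        el = guide_to_element.get(rec.guide_id)
        if el is None:
            continue
        totals[el] = totals.get(el, 0) + 1
        if rec.mean_log2fc <= fc_threshold:
            depleted[el] = depleted.get(el, 0) + 1
    return [ElementCall(el, totals[el], depleted.get(el, 0),
                        called=depleted.get(el, 0) >= min_concordant,
                        single_guide_only=depleted.get(el, 0) == 1)
            for el in sorted(totals)]


def specificity_filter_screen(enrich: Sequence[EnrichmentRecord],
                              scores: Mapping[str, SpecificityResult],
                              cutoff: float = 0.2,
                              ) -> tuple[list[EnrichmentRecord], float]:
    """Retain guides with score > cutoff (searchable only); guides scoring
    exactly at the cutoff, unsearchable guides, and unscored guides are all
    removed. Returns the retained records and the removed fraction."""
    kept = []
    for rec in enrich:
        res = scores.get(rec.guide_id)
        if res is not None and res.searchable and res.score is not None \
                and res.score > cutoff:
            kept.append(rec)
    removed = 1.0 - len(kept) / len(enrich) if enrich else 0.0
    return kept, removed


def write_qc_report(path_prefix: str | Path, quadrant: QuadrantTable,
                    removed_fraction: float,
                    calls_pre: Sequence[ElementCall],
                    calls_post: Sequence[ElementCall]) -> None:
    """TSV + plain-text screen QC summary."""
    prefix = str(path_prefix)
    pd.DataFrame([c.__dict__ for c in calls_pre]).to_csv(
        prefix + ".element_calls_prefilter.tsv", sep="\t", index=False)
    pd.DataFrame([c.__dict__ for c in calls_post]).to_csv(
        prefix + ".element_calls_postfilter.tsv", sep="\t", index=False)
    (a, b), (c, d) = quadrant.cells
    with open(prefix + ".summary.txt", "w") as fh:
        fh.write("screen QC summary\n")
        fh.write(f"guides analyzed (searchable, scored): {quadrant.n_guides()}\n")
        fh.write(f"quadrant cells [dep&low, dep&high, not&low, not&high]: "
                 f"{a} {b} {c} {d}\n")
        fh.write(f"odds ratio: {quadrant.odds_ratio:.4g}\n")
        fh.write(f"fisher exact p: {quadrant.p_value:.4g}\n")
        fh.write(f"fraction of guides removed by specificity filter: "
                 f"{removed_fraction:.4f}\n")
        fh.write(f"elements called pre-filter: {sum(c_.called for c_ in calls_pre)}\n")
        fh.write(f"elements called post-filter: {sum(c_.called for c_ in calls_post)}\n")
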
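"""Synthetic genomes with planted off-target structure and simulated pooled
screens with a controllable off-target toxicity term.

The screen generative model: plasmid abundances are Dirichlet-uniform over
guides; after g population doublings the expected abundance of guide i is
proportional to a_i * 2^(g * (e_on_i + e_tox * confounded_i)), where e_on is
the guide's true on-target fitness effect per doubling and e_tox an additional
per-doubling toxicity applied to guides flagged as confounded (low
specificity). Read counts per sample are negative-binomial around
depth-scaled abundances with shared dispersion phi (variance mu + phi*mu^2).
All randomness flows through one seeded numpy Generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cfd import SpecificityResult
from .genome import Genome, GenomicInterval, iupac_match, revcomp
from .offtargets import (MismatchDescriptor, OffTargetSite, OffTargetTally,
                         _descriptors)
from .screen import CountMatrix

_BASES = np.array(list("ACGT"))


def random_genome(length: int, gc: float = 0.5, seed: int | np.random.Generator = 0,
                  chrom: str = "chrSim") -> Genome:
    """I.i.d. random genome with P(G) + P(C) = gc; deterministic per seed."""
    if length < 23:
        raise ValueError("genome must be at least 23 nt (one spacer + PAM)")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0,1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(rng.choice(_BASES, size=length, p=probs))
    return Genome({chrom: seq}, build_label=f"random(length={length}, gc={gc})")


@dataclass
class PlantSpec:
    """Off-target sites to implant for one spacer.

    Each entry of ``sites`` is (n_mismatch, mismatch_positions, pam, count):
    positions are 1..20 from the spacer 5' end (empty tuple = choose randomly),
    ``pam`` is the concrete 3-nt PAM written next to the planted protospacer,
    and ``count`` copies are planted. Placement is random, non-overlapping,
    and seeded; planted sites are returned as ground truth.
    """

    spacer: str
    sites: list[tuple[int, tuple[int, ...], str, int]]
    margin: int = 30

    def __post_init__(self) -> None:
        if len(self.spacer) != 20:
            raise ValueError("spacer must be 20 nt")
        for n_mm, positions, pam, count in self.sites:
            if positions and (len(set(positions)) != len(positions)
                              or not all(1 <= p <= 20 for p in positions)):
                raise ValueError(f"bad mismatch positions {positions}")
            if positions and len(positions) != n_mm:
                raise ValueError("positions length must equal n_mismatch")
            if len(pam) != 3 or count < 1:
                raise ValueError("need a 3-nt PAM and count >= 1")


def _naive_hits(spacer: str, seq: str, max_mm: int,
                pam_patterns: Sequence[str]) -> list[tuple[int, str, int]]:
    """Simple string scan: (+strand-start, strand, n_mm) hits of spacer in seq.

    Independent of the vectorized search; used to pre-scan synthetic genomes
    for chance matches so planted truth stays exact.
    """
    hits = []
    slen, plen = len(spacer), 3
    rc_spacer = revcomp(spacer)
    for j in range(len(seq) - slen + 1):
        window = seq[j:j + slen]
        if "N" in window:
            continue
        # + strand
        if j + slen + plen <= len(seq):
            pam = seq[j + slen:j + slen + plen]
            if "N" not in pam and any(iupac_match(p, pam) for p in pam_patterns):
                mm = sum(a != b for a, b in zip(spacer, window))
                if mm <= max_mm:
                    hits.append((j, "+", mm))
        # - strand
        if j >= plen:
            pam = revcomp(seq[j - plen:j])
            if "N" not in pam and any(iupac_match(p, pam) for p in pam_patterns):
                mm = sum(a != b for a, b in zip(rc_spacer, window))
                if mm <= max_mm:
                    hits.append((j, "-", mm))
    return hits


def implant_sites(genome: Genome, spec: PlantSpec,
                  seed: int | np.random.Generator = 0,
                  pam_patterns: Sequence[str] = ("NGG", "NAG"),
                  max_mm: int = 3) -> tuple[Genome, list[OffTargetSite]]:
    """Plant protospacer copies with controlled mismatches into a genome.

    Chance matches of the spacer already present in the background sequence
    are detected by pre-scanning and destroyed (their PAM is overwritten), so
    the returned truth list is exactly the site set an exhaustive search must
    find. Raises if the genome lacks room for non-overlapping placements.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    chrom = genome.chroms()[0]
    seq = list(genome[chrom])
    slen = len(spec.spacer)

    # destroy chance hits in the background (mutate the middle of the window)
    for _ in range(20):
        chance = _naive_hits(spec.spacer, "".join(seq), max_mm, pam_patterns)
        if not chance:
            break
        for j, strand, _mm in chance:
            pos = j + slen // 2
            seq[pos] = {"A": "C", "C": "A", "G": "T", "T": "G", "N": "A"}[seq[pos]]
    else:
        raise RuntimeError("could not scrub chance matches from background")

    n_total = sum(count for *_ , count in spec.sites)
    footprint = slen + 6 + 2 * spec.margin
    if n_total * footprint > len(seq):
        raise ValueError("insufficient space for non-overlapping placements")

    occupied: list[tuple[int, int]] = []
    truth: list[OffTargetSite] = []

    def place() -> int:
        for _ in range(1000):
            start = int(rng.integers(spec.margin + 3, len(seq) - slen - 3 - spec.margin))
            if all(start + slen + spec.margin <= s or start >= e + spec.margin
                   for s, e in occupied):
                occupied.append((start, start + slen))
                return start
        raise ValueError("insufficient space for non-overlapping placements")

    for n_mm, positions, pam, count in spec.sites:
        for _ in range(count):
            start = place()
            strand = "+" if rng.integers(2) == 0 else "-"
            pos_list = list(positions) if positions else sorted(
                int(p) for p in rng.choice(np.arange(1, 21), size=n_mm, replace=False))
            site_chars = list(spec.spacer)
            for p in pos_list:
                orig = site_chars[p - 1]
                choices = [b for b in "ACGT" if b != orig]
                site_chars[p - 1] = choices[int(rng.integers(3))]
            site_seq = "".join(site_chars)
            if strand == "+":
                seq[start:start + slen] = list(site_seq)
                seq[start + slen:start + slen + 3] = list(pam)
                iv = GenomicInterval(chrom, start, start + slen, "+")
            else:
                seq[start:start + slen] = list(revcomp(site_seq))
                seq[start - 3:start] = list(revcomp(pam))
                iv = GenomicInterval(chrom, start, start + slen, "-")
            truth.append(OffTargetSite(iv, strand, site_seq, pam,
                                       _descriptors(spec.spacer, site_seq), n_mm))

    new_genome = Genome({chrom: "".join(seq)}, build_label=genome.build_label + "+planted")

    # verify: the naive scan over the final genome must find exactly the truth
    found = {(j, s) for j, s, _ in
             _naive_hits(spec.spacer, new_genome[chrom], max_mm, pam_patterns)}
    expected = {(t.interval.start, t.strand) for t in truth
                if any(iupac_match(p, t.pam) for p in pam_patterns)}
    if found != expected:
        raise RuntimeError("planting produced unexpected chance sites; "
                           "retry with a different seed or larger genome")
    truth.sort(key=lambda t: (t.interval.chrom, t.interval.start, t.strand))
    return new_genome, truth


@dataclass
class ScreenSimConfig:
    """Parameters of one simulated growth screen (see module docstring)."""

    e_on: np.ndarray           # per-guide on-target fitness effect per doubling
    confounded: np.ndarray     # per-guide low-specificity toxicity flag
    e_tox: float = 0.0         # extra per-doubling effect for confounded guides
    doublings: float = 7.0
    depth: float = 500.0       # mean reads per guide per sample
    phi: float = 0.05          # NB dispersion (var = mu + phi mu^2)
    n_reps: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        self.e_on = np.asarray(self.e_on, dtype=float)
        self.confounded = np.asarray(self.confounded, dtype=bool)
        if self.e_on.shape != self.confounded.shape:
            raise ValueError("e_on and confounded must align")
        if self.depth <= 0 or self.phi <= 0 or self.n_reps < 1:
            raise ValueError("need depth > 0, phi > 0, n_reps >= 1")

    @property
    def n_guides(self) -> int:
        return self.e_on.size


@dataclass
class ScreenTruth:
    """Ground truth of a simulated screen."""

    fitness_per_doubling: np.ndarray   # e_on + e_tox * confounded
    expected_log2fc: np.ndarray        # g * fitness, before renormalization
    confounded: np.ndarray
    guide_ids: list[str]


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    # gamma-Poisson mixture: shape 1/phi, scale phi*mu -> var = mu + phi mu^2
    lam = rng.gamma(shape=1.0 / phi, scale=phi * mean)
    return rng.poisson(lam)


def simulate_screen(config: ScreenSimConfig) -> tuple[CountMatrix, ScreenTruth]:
    """Simulate plasmid + endpoint replicate counts; deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    n = config.n_guides
    guide_ids = [f"guide_{i:05d}" for i in range(n)]
    abundance = rng.dirichlet(np.ones(n))
    fitness = config.e_on + config.e_tox * config.confounded
    growth = abundance * np.power(2.0, config.doublings * fitness)
    endpoint_abundance = growth / growth.sum()
    total = config.depth * n

    cols: dict[str, np.ndarray] = {
        "plasmid": _nb_sample(rng, total * abundance, config.phi)}
    roles = {"plasmid": "plasmid"}
    for r in range(1, config.n_reps + 1):
        name = f"endpoint_rep{r}"
        cols[name] = _nb_sample(rng, total * endpoint_abundance, config.phi)
        roles[name] = "endpoint"
    counts = pd.DataFrame(cols, index=pd.Index(guide_ids, name="guide_id"))
    truth = ScreenTruth(fitness, config.doublings * fitness,
                        config.confounded.copy(), guide_ids)
    return CountMatrix(counts, roles), truth


@dataclass
class SimulatedScreenStudy:
    """A full synthetic screen with element structure and specificity scores."""

    counts: CountMatrix
    truth: ScreenTruth
    scores: dict[str, SpecificityResult]
    guide_to_element: dict[str, str]
    essential_elements: set[str]       # elements with true on-target depletion
    confounded_elements: set[str]      # elements whose only depletion is off-target


def simulate_element_screen(n_elements: int = 200, guides_per_element: int = 5,
                            frac_essential: float = 0.2,
                            frac_low_specificity: float = 0.3,
                            e_on_essential: float = -0.5, e_tox: float = -1.5,
                            doublings: float = 7.0, depth: float = 500.0,
                            phi: float = 0.05, n_reps: int = 2,
                            seed: int = 0) -> SimulatedScreenStudy:
    """Motif-screen-like study: elements with several guides each, a subset of
    elements truly essential (all their guides depleted on target), and a
    subset of guides flagged low-specificity that acquire off-target toxicity
    when ``e_tox`` is nonzero, independent of their element's essentiality.

    Low-specificity guides get synthetic scores <= 0.2, the rest > 0.2;
    confounded elements are those that are not essential but contain >= 2
    low-specificity guides (the elements that off-target toxicity alone can
    push past the concordance threshold).
    """
    rng = np.random.default_rng(seed)
    n = n_elements * guides_per_element
    element_ids = [f"element_{e:04d}" for e in range(n_elements)]
    guide_to_element = {}
    essential = set()
    e_on = np.zeros(n)
    confounded = np.zeros(n, dtype=bool)
    scores: dict[str, SpecificityResult] = {}

    essential_mask = rng.random(n_elements) < frac_essential
    low_spec_mask = rng.random(n) < frac_low_specificity
    guide_ids = [f"guide_{i:05d}" for i in range(n)]
    for i in range(n):
        el = i // guides_per_element
        guide_to_element[guide_ids[i]] = element_ids[el]
        if essential_mask[el]:
            e_on[i] = e_on_essential
            essential.add(element_ids[el])
        confounded[i] = low_spec_mask[i]
        score = (float(rng.uniform(0.01, 0.2)) if low_spec_mask[i]
                 else float(rng.uniform(0.3, 1.0)))
        scores[guide_ids[i]] = SpecificityResult(
            guide_ids[i], OffTargetTally({0: 1, 1: 0, 2: 1, 3: 1}),
            searchable=True, cfd_sum=1.0 / score - 1.0, score=score)

    config = ScreenSimConfig(e_on=e_on, confounded=confounded, e_tox=e_tox,
                             doublings=doublings, depth=depth, phi=phi,
                             n_reps=n_reps, seed=int(rng.integers(2**31 - 1)))
    counts, truth = simulate_screen(config)
    confounded_elements = set()
    for e, el in enumerate(element_ids):
        if essential_mask[e]:
            continue
        lo, hi = e * guides_per_element, (e + 1) * guides_per_element
        if low_spec_mask[lo:hi].sum() >= 2:
            confounded_elements.add(el)
    return SimulatedScreenStudy(counts, truth, scores, guide_to_element,
                                essential, confounded_elements)
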
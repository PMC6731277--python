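"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's vectorized/regex code paths: plain
Python position loops with per-base comparisons, so that agreement with the
package is a genuine dual-route check.
"""

from __future__ import annotations

from guidespec.genome import Genome, iupac_match, revcomp


def brute_force_offtargets(spacer: str, genome: Genome, max_mm: int,
                           pam_set: tuple[str, ...]) -> set[tuple[str, int, str, int]]:
    """All-window Hamming scan: {(chrom, start, strand, n_mm)}."""
    slen, plen = len(spacer), len(pam_set[0])
    rc_spacer = revcomp(spacer)
    hits: set[tuple[str, int, str, int]] = set()
    for chrom in genome.chroms():
        seq = genome[chrom]
        for j in range(len(seq) - slen + 1):
            window = seq[j:j + slen]
            if "N" in window:
                continue
            if j + slen + plen <= len(seq):
                pam = seq[j + slen:j + slen + plen]
                if "N" not in pam and any(iupac_match(p, pam) for p in pam_set):
                    mm = 0
                    for a, b in zip(spacer, window):
                        if a != b:
                            mm += 1
                            if mm > max_mm:
                                break
                    if mm <= max_mm:
                        hits.add((chrom, j, "+", mm))
            if j >= plen:
                pam = revcomp(seq[j - plen:j])
                if "N" not in pam and any(iupac_match(p, pam) for p in pam_set):
                    mm = 0
                    for a, b in zip(rc_spacer, window):
                        if a != b:
                            mm += 1
                            if mm > max_mm:
                                break
                    if mm <= max_mm:
                        hits.add((chrom, j, "-", mm))
    return hits


def brute_force_spacers(genome: Genome, pam_pattern: str = "NGG",
                        spacer_len: int = 20) -> set[tuple[str, int, str, str, str]]:
    """Position loop over both strands: {(chrom, start, strand, spacer, pam)}."""
    plen = len(pam_pattern)
    out: set[tuple[str, int, str, str, str]] = set()
    for chrom in genome.chroms():
        seq = genome[chrom]
        for i in range(len(seq) - spacer_len - plen + 1):
            spacer = seq[i:i + spacer_len]
            pam = seq[i + spacer_len:i + spacer_len + plen]
            if "N" not in spacer and "N" not in pam and iupac_match(pam_pattern, pam):
                out.add((chrom, i, "+", spacer, pam))
        rc = revcomp(seq)
        L = len(seq)
        for i in range(len(rc) - spacer_len - plen + 1):
            spacer = rc[i:i + spacer_len]
            pam = rc[i + spacer_len:i + spacer_len + plen]
            if "N" not in spacer and "N" not in pam and iupac_match(pam_pattern, pam):
                # map back to + strand coordinates of the protospacer window
                start = L - (i + spacer_len)
                out.add((chrom, start, "-", spacer, pam))
    return out
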
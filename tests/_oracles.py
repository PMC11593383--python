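"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library's scanning code: windows are checked by
direct counting over all O(n^2) index pairs, and the disjoint segmentation is
obtained by repeatedly taking the leftmost-starting valid window with the
longest extension, recursing strictly after its end.  Size filters are
applied to the selected segmentation, matching the documented contract that
short runs still consume their span.
"""

from __future__ import annotations

import numpy as np

from rohscan.io import HET, HOM_A1, HOM_A2, MISSING


def brute_force_runs(geno, pos, max_het, max_missing, min_snp, min_len_bp,
                     max_gap_bp):
    geno = np.asarray(geno)
    pos = np.asarray(pos)
    n = len(geno)
    hom = (geno == HOM_A1) | (geno == HOM_A2)
    valid = []
    for i in range(n):
        if not hom[i]:
            continue
        nh = nm = 0
        for j in range(i, n):
            if j > i and pos[j] - pos[j - 1] > max_gap_bp:
                break
            if geno[j] == HET:
                nh += 1
            elif geno[j] == MISSING:
                nm += 1
            if nh > max_het or nm > max_missing:
                break
            if hom[j]:
                valid.append((i, j))
    chosen, cursor = [], -1
    while True:
        cands = [w for w in valid if w[0] > cursor]
        if not cands:
            break
        s = min(w[0] for w in cands)
        e = max(w[1] for w in cands if w[0] == s)
        chosen.append((s, e))
        cursor = e
    out = []
    for (s, e) in chosen:
        nsnp = e - s + 1
        length = int(pos[e] - pos[s])
        if nsnp >= min_snp and length >= min_len_bp:
            nh = int(np.sum(geno[s:e + 1] == HET))
            nm = int(np.sum(geno[s:e + 1] == MISSING))
            out.append((s, e, nsnp, nh, nm, length))
    return out


def brute_force_incidence(segments, positions, samples_in_population):
    """Double loop over (individual, SNP) membership."""
    counts = np.zeros(len(positions), dtype=int)
    for sample in samples_in_population:
        sub = segments[segments["sample"] == sample]
        for k, p in enumerate(positions):
            covered = ((sub["start_bp"] <= p) & (sub["end_bp"] >= p)).any()
            if covered:
                counts[k] += 1
    return counts


def brute_force_interval_overlaps(islands, genes):
    """All-pairs inclusive-interval intersection."""
    hits = set()
    for i, isl in islands.iterrows():
        for j, g in genes.iterrows():
            if str(isl["chrom"]) != str(g["chrom"]):
                continue
            if g["start_bp"] <= isl["end_bp"] and g["end_bp"] >= isl["start_bp"]:
                hits.add((i, j))
    return hits
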
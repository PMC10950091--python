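"""Independent brute-force reference implementations for cross-checking.

Deliberately literal: plain-Python loops and string comparisons, no numpy
and none of the production code paths, so agreement with the package is a
meaningful two-route check.
"""

MISSING = {"", "0", "00", "NA", "N/A", "NAN", "--", ".", None}


def oracle_scorecard(genotypes, panel):
    species = sorted({s for e in panel.entries for s in (e.assoc1 | e.assoc2)})
    S = {s: 0.0 for s in species}
    P = {s: 0.0 for s in species}
    M = {s: 0.0 for s in species}
    het = 0
    genotyped = 0
    for entry in panel.entries:
        for s in entry.assoc1 | entry.assoc2:
            M[s] += entry.weight
        raw = genotypes.get(entry.locus_id)
        code = None if raw is None else str(raw).strip().upper()
        if code in MISSING:
            continue
        genotyped += 1
        a, b = code[0], code[1]
        if a not in (entry.allele1, entry.allele2) or b not in (
            entry.allele1,
            entry.allele2,
        ):
            continue  # foreign: counted as genotyped, never scored
        if a != b:
            het += 1
            continue
        if a == entry.allele1:
            for s in entry.assoc1:
                S[s] += entry.weight
                P[s] += entry.weight
            for s in entry.assoc2:
                S[s] -= entry.weight
                P[s] += entry.weight
        else:
            for s in entry.assoc2:
                S[s] += entry.weight
                P[s] += entry.weight
            for s in entry.assoc1:
                S[s] -= entry.weight
                P[s] += entry.weight
    return S, P, M, het, genotyped


def oracle_call(genotypes, panel, thres_ms=0.5, buff_mp=1e-3, prune_ms=0.34,
                thres_het=0.06):
    """Literal transcription of the calling rule."""
    S, P, M, het, genotyped = oracle_scorecard(genotypes, panel)
    gate = any(S[s] / M[s] >= thres_ms for s in S)
    candidates = []
    if gate:
        q = {s: S[s] / P[s] for s in S if P[s] > 0}
        if q:
            best = max(q.values())
            candidates = [s for s in q if best - q[s] <= buff_mp]
            if len(candidates) > 1:
                candidates = [s for s in candidates if S[s] / M[s] >= prune_ms]
            candidates.sort(key=lambda s: (-q[s], s))
    review = genotyped > 0 and het / genotyped > thres_het
    return candidates, review
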
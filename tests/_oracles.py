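"""Independent brute-force oracles, kept deliberately naive and separate
from the library code paths they check."""


def oracle_prevalence_threshold(n):
    t = 1
    while 3 * t < n:
        t += 1
    return t


def oracle_score(genome_accs, pathway_steps, signature_indices, cohort_accs):
    """(state, completeness) for one genome, recomputed from first principles.

    ``pathway_steps`` is a list of accession sets; ``signature_indices``
    indexes the signature steps; ``cohort_accs`` lists every genome's
    accession set (including this genome's).
    """
    recovered = 0
    for step in pathway_steps:
        if any(a in genome_accs for a in step):
            recovered += 1
    sig_here = any(
        a in genome_accs for i in signature_indices for a in pathway_steps[i]
    )
    prevalence = 0
    for accs in cohort_accs:
        if any(a in accs for i in signature_indices for a in pathway_steps[i]):
            prevalence += 1
    if not signature_indices:
        if recovered == 0:
            return "zero", None
        return "fraction", recovered / len(pathway_steps)
    if recovered == 0:
        return "zero", None
    if sig_here or prevalence >= oracle_prevalence_threshold(len(cohort_accs)):
        return "fraction", recovered / len(pathway_steps)
    return "likely_absent", None


def oracle_cxxch(seq):
    """Window-by-window CxxCH scan without any shared machinery."""
    seq = seq.upper()
    hits = []
    for i in range(len(seq)):
        window = seq[i : i + 5]
        if len(window) < 5:
            break
        if window[0] == "C" and window[3] == "C" and window[4] == "H":
            hits.append(i + 1)
    return hits


def oracle_kmer_freqs(seq, k=4):
    """Plain dictionary k-mer census (N-containing k-mers skipped)."""
    counts = {}
    total = 0
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        counts[kmer] = counts.get(kmer, 0) + 1
        total += 1
    return {k_: v / total for k_, v in counts.items()} if total else {}


def oracle_pearson(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / (vx**0.5 * vy**0.5)


def oracle_agglomerate_3(d01, d02, d12, linkage="average"):
    """Brute-force agglomeration of three leaves {0,1,2}.

    Returns (first_pair, first_height, second_height).
    """
    dists = {(0, 1): d01, (0, 2): d02, (1, 2): d12}
    pair = min(dists, key=lambda p: (dists[p], p))
    h1 = dists[pair]
    other = ({0, 1, 2} - set(pair)).pop()
    rest = [dists[tuple(sorted((other, m)))] for m in pair]
    h2 = sum(rest) / 2 if linkage == "average" else max(rest)
    return pair, h1, h2
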